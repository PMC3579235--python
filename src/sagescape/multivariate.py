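"""Distance-based multivariate statistics on expression profiles.

Libraries are compared by the Pearson correlation distance d = 1 - r
over their normalized per-gene counts.  Overall effects of treatment,
population, family (nested within population) and sex are tested with a
permutational MANOVA: the squared-distance matrix is Gower-centered,
sequential (Type I) sums of squares are read off via hat matrices of the
cumulative design, and each term's pseudo-F is referred to a null
distribution obtained by freely permuting library labels.  Ordination
for display uses nonmetric multidimensional scaling (Kruskal stress-1
with monotone regression), multi-started from a classical-scaling
configuration plus random starts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.manifold import smacof

from .containers import GeneCountMatrix, SampleMeta, design_to_frame

DEFAULT_TERMS = ("treatment", "population", "family", "sex")


@dataclass
class DistanceMatrix:
    """Symmetric dissimilarities between libraries, zero diagonal."""

    library_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.values, dtype=float)
        if d.shape != (len(self.library_ids), len(self.library_ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(d, d.T, atol=1e-10):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-10):
            raise ValueError("distance matrix diagonal is not zero")
        self.values = d

    def __len__(self) -> int:
        return len(self.library_ids)


def correlation_distance(matrix: GeneCountMatrix) -> DistanceMatrix:
    """d_ij = 1 - Pearson r between libraries' expression vectors.

    Uses normalized counts when present (raw otherwise); r is computed
    over all genes, so d lies in [0, 2] and is invariant to per-library
    positive rescaling.
    """
    frame = matrix.normalized if matrix.normalized is not None else matrix.raw
    if frame.shape[0] < 2:
        raise ValueError("need at least 2 genes to correlate libraries")
    values = frame.to_numpy(dtype=float)
    sd = values.std(axis=0)
    for lib, s in zip(frame.columns, sd):
        if s == 0:
            raise ValueError(f"library {lib!r} has zero variance across genes")
    r = np.corrcoef(values, rowvar=False)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    return DistanceMatrix(library_ids=list(frame.columns), values=d)


# ---------------------------------------------------------------------------
# PerMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaRow:
    term: str
    ss: float
    df_term: int
    df_residual: int
    F: float
    p_value: float


@dataclass
class PermanovaTable:
    rows: list[PermanovaRow]
    ss_residual: float
    ss_total: float
    n_permutations: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"term": r.term, "SS": r.ss, "F": r.F,
              "df": f"{r.df_term}/{r.df_residual}", "P": r.p_value}
             for r in self.rows])

    def __getitem__(self, term: str) -> PermanovaRow:
        for row in self.rows:
            if row.term == term:
                return row
        raise KeyError(term)


def _gower_center(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    a = -0.5 * d ** 2
    centering = np.eye(n) - np.ones((n, n)) / n
    return centering @ a @ centering


def _term_columns(meta: pd.DataFrame, term: str) -> np.ndarray:
    """Dummy columns for one model term.

    ``family`` is nested within population by construction (family labels
    are unique across populations), so plain dummy coding after the
    population term contributes the nested degrees of freedom.
    """
    if term not in meta.columns:
        raise KeyError(f"unknown model term {term!r}")
    dummies = pd.get_dummies(meta[term], drop_first=True, dtype=float)
    return dummies.to_numpy()


def _hat(x: np.ndarray) -> np.ndarray:
    return x @ np.linalg.pinv(x)


def permanova(dist: DistanceMatrix,
              design: Sequence[SampleMeta],
              terms: Sequence[str] = DEFAULT_TERMS,
              n_permutations: int = 999,
              seed: int = 0) -> PermanovaTable:
    """Distance-based MANOVA with sequential sums of squares.

    Terms are fitted in the given order; each term's SS is the increase
    in explained (Gower-centered) sums of squares over the preceding
    model.  P-values come from free permutation of library labels:
    ``P = (#{F_perm >= F_obs} + 1) / (n_permutations + 1)``.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    meta = design_to_frame(design).loc[dist.library_ids]
    n = len(dist)
    g = _gower_center(dist.values)
    ss_total = float(np.trace(g))

    x = np.ones((n, 1))
    hats = [_hat(x)]
    ranks = [1]
    df_terms = []
    for term in terms:
        x = np.hstack([x, _term_columns(meta, term)])
        rank = int(np.linalg.matrix_rank(x))
        df = rank - ranks[-1]
        if df == 0:
            raise ValueError(
                f"term {term!r} is confounded with preceding terms "
                "(no additional degrees of freedom)")
        hats.append(_hat(x))
        ranks.append(rank)
        df_terms.append(df)
    df_residual = n - ranks[-1]
    if df_residual <= 0:
        raise ValueError("saturated design: no residual degrees of freedom")

    diffs = [hats[i + 1] - hats[i] for i in range(len(terms))]
    resid_proj = np.eye(n) - hats[-1]

    def f_stats(gmat: np.ndarray) -> tuple[np.ndarray, float]:
        ss_res = float(np.sum(resid_proj * gmat.T))
        ms_res = ss_res / df_residual
        ss_terms = np.array([float(np.sum(diff * gmat.T)) for diff in diffs])
        return ss_terms, ss_res

    ss_terms, ss_res = f_stats(g)
    f_obs = (ss_terms / np.array(df_terms)) / (ss_res / df_residual)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        ss_t_p, ss_r_p = f_stats(gp)
        f_perm = (ss_t_p / np.array(df_terms)) / (ss_r_p / df_residual)
        exceed += f_perm >= f_obs
    p_values = (exceed + 1.0) / (n_permutations + 1.0)

    rows = [
        PermanovaRow(term=t, ss=float(ss_terms[i]), df_term=df_terms[i],
                     df_residual=df_residual, F=float(f_obs[i]),
                     p_value=float(p_values[i]))
        for i, t in enumerate(terms)
    ]
    return PermanovaTable(rows=rows, ss_residual=ss_res, ss_total=ss_total,
                          n_permutations=n_permutations, seed=seed)


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------

@dataclass
class NmdsResult:
    library_ids: list[str]
    coordinates: np.ndarray
    stress: float
    n_starts: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        cols = [f"NMDS{i+1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.library_ids,
                            columns=cols)


def _classical_scaling(d: np.ndarray, dims: int) -> np.ndarray:
    g = _gower_center(d)
    eigval, eigvec = np.linalg.eigh(g)
    order = np.argsort(eigval)[::-1][:dims]
    lam = np.clip(eigval[order], 0.0, None)
    return eigvec[:, order] * np.sqrt(lam)


def nmds(dist: DistanceMatrix,
         dims: int = 2,
         n_starts: int = 20,
         max_iter: int = 300,
         seed: int = 0) -> NmdsResult:
    """Nonmetric MDS minimizing Kruskal stress-1.

    Monotone (isotonic) regression of configuration distances on
    dissimilarity ranks, iterated by SMACOF; the best of ``n_starts``
    configurations (classical scaling plus random starts) is returned.
    """
    d = dist.values
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite distances")
    if dims >= len(dist) - 1:
        raise ValueError("dims must be < number of libraries - 1")
    inits: list[np.ndarray | None] = [_classical_scaling(d, dims)]
    inits.extend([None] * max(0, n_starts - 1))
    best_x: np.ndarray | None = None
    best_stress = np.inf
    rng = np.random.RandomState(seed)
    for init in inits:
        x, stress = smacof(
            d, metric=False, n_components=dims, init=init, n_init=1,
            max_iter=max_iter, eps=1e-12, random_state=rng,
            normalized_stress=True)
        if stress < best_stress:
            best_stress = float(stress)
            best_x = x
    assert best_x is not None
    return NmdsResult(library_ids=list(dist.library_ids), coordinates=best_x,
                      stress=best_stress, n_starts=n_starts, seed=seed)
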
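"""Negative-binomial exact-test differential expression and companions.

Counts for gene g in library i are modelled NB(mu, phi) with variance
mu + phi * mu^2.  Dispersion is estimated by conditional maximum
likelihood after equalizing library sizes (a common value across genes,
plus tagwise values shrunk toward the common one).  The two-group test
conditions on the gene's combined total: under the null the group-A
total follows the conditional distribution of a sum of NB variables, and
the two-sided p-value sums the probabilities of all outcomes at most as
likely as the observed one.  At phi = 0 this reduces to the exact
binomial test.  Benjamini-Hochberg step-up controls the FDR across
genes.

The module also carries the small frequentist companions used alongside
the DE scan: the Fig-2-style classification of population-specific
regulation, the 2x2 Pearson chi-squared contrast, and the Mann-Whitney
U-test for parasite loads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln, logsumexp

from .containers import GeneCountMatrix

UP, DOWN, NS = "up", "down", "ns"


# ---------------------------------------------------------------------------
# Library-size equalization
# ---------------------------------------------------------------------------

def equalize_library_sizes(raw: pd.DataFrame) -> pd.DataFrame:
    """Rescale every library to the mean total and round to integers.

    The conditional-likelihood machinery below assumes exchangeable
    library sizes; upstream CPM normalization fixes relative totals, and
    this step puts raw counts on a single common absolute scale.  With
    already-equal totals it is the identity.
    """
    totals = raw.sum(axis=0).astype(float)
    if (totals <= 0).any():
        bad = totals[totals <= 0].index[0]
        raise ValueError(f"library {bad!r} has zero total count")
    common = totals.mean()
    scaled = raw * (common / totals)
    return scaled.round().astype(np.int64)


# ---------------------------------------------------------------------------
# Dispersion
# ---------------------------------------------------------------------------

@dataclass
class DispersionEstimate:
    common_dispersion: float
    tagwise_dispersion: pd.Series | None
    shrinkage_weight: float

    def phi_for(self, gene: str) -> float:
        if self.tagwise_dispersion is not None and gene in self.tagwise_dispersion.index:
            return float(self.tagwise_dispersion[gene])
        return self.common_dispersion


def _cond_loglik(y: np.ndarray, masks: Sequence[np.ndarray],
                 phi: float) -> np.ndarray:
    """Per-gene conditional log-likelihood at dispersion ``phi``.

    ``y`` is genes x libraries (equal library sizes assumed); each mask
    selects one group's columns.  Conditioning on each group's total
    removes the mean parameter.
    """
    phi = max(phi, 1e-10)
    r = 1.0 / phi
    total = np.zeros(y.shape[0])
    for mask in masks:
        yg = y[:, mask]
        n = yg.shape[1]
        if n < 2:
            continue
        z = yg.sum(axis=1)
        total += (gammaln(yg + r).sum(axis=1) - n * gammaln(r)
                  + gammaln(n * r) - gammaln(z + n * r))
    return total


_PHI_GRID = np.concatenate([[1e-8], np.geomspace(1e-4, 10.0, 120)])


def estimate_dispersion(matrix: GeneCountMatrix,
                        groups: Mapping[str, str] | Sequence[str],
                        shrinkage_weight: float = 10.0,
                        tagwise: bool = True) -> DispersionEstimate:
    """Conditional-ML dispersion: common value plus shrunk tagwise values.

    ``groups`` maps library id -> group label (or is a sequence aligned
    with the matrix columns).  The common dispersion maximizes the summed
    conditional log-likelihood over genes; each tagwise value maximizes
    the gene's own conditional likelihood plus ``shrinkage_weight`` times
    the genes-average likelihood, so tagwise -> common as the weight
    grows.
    """
    raw = matrix.raw
    if int(raw.to_numpy().sum()) == 0:
        raise ValueError("all-zero count matrix")
    if not isinstance(groups, Mapping):
        groups = dict(zip(raw.columns, groups))
    labels = [groups[lib] for lib in raw.columns]
    masks = [np.array([lab == g for lab in labels]) for g in dict.fromkeys(labels)]
    if not any(mask.sum() >= 2 for mask in masks):
        raise ValueError("need at least one group with >= 2 libraries")

    y = equalize_library_sizes(raw).to_numpy()
    per_gene = np.stack([_cond_loglik(y, masks, phi) for phi in _PHI_GRID])

    total = per_gene.sum(axis=1)
    i_best = int(np.argmax(total))
    lo = _PHI_GRID[max(0, i_best - 1)]
    hi = _PHI_GRID[min(len(_PHI_GRID) - 1, i_best + 1)]
    res = optimize.minimize_scalar(
        lambda phi: -_cond_loglik(y, masks, phi).sum(),
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-8})
    common = float(res.x)
    if -res.fun < total[i_best]:
        common = float(_PHI_GRID[i_best])

    tagwise_series = None
    if tagwise:
        mean_lik = per_gene.mean(axis=1, keepdims=True)
        penalized = per_gene + shrinkage_weight * mean_lik
        best_idx = np.argmax(penalized, axis=0)
        tagwise_series = pd.Series(_PHI_GRID[best_idx], index=raw.index)
    return DispersionEstimate(common_dispersion=common,
                              tagwise_dispersion=tagwise_series,
                              shrinkage_weight=shrinkage_weight)


# ---------------------------------------------------------------------------
# Exact test
# ---------------------------------------------------------------------------

def _conditional_logpmf(z: int, n_a: int, n_b: int, phi: float) -> np.ndarray:
    """log P(S_A = a | S_A + S_B = z) for a = 0..z under the NB null.

    The sum of n iid NB(r, p) is NB(n r, p); p cancels when conditioning,
    leaving a Polya (negative-hypergeometric-like) weight.  phi = 0 is
    the binomial limit.
    """
    a = np.arange(z + 1)
    if phi <= 0:
        return stats.binom.logpmf(a, z, n_a / (n_a + n_b))
    r = 1.0 / phi
    ra, rb = n_a * r, n_b * r
    logw = (gammaln(a + ra) - gammaln(a + 1)
            + gammaln(z - a + rb) - gammaln(z - a + 1))
    return logw - logsumexp(logw)


def _twosided_p(logpmf: np.ndarray, observed: int,
                mode: str = "minlike") -> float:
    """Two-sided p from a unimodal-ish discrete null.

    ``minlike`` sums probabilities of all outcomes no more likely than
    the observed one (with a small relative tolerance); ``doubletail``
    doubles the smaller tail.
    """
    lp_obs = logpmf[observed]
    if mode == "minlike":
        keep = logpmf <= lp_obs + 1e-9
        return float(min(1.0, np.exp(logsumexp(logpmf[keep]))))
    if mode == "doubletail":
        lower = np.exp(logsumexp(logpmf[: observed + 1]))
        upper = np.exp(logsumexp(logpmf[observed:]))
        return float(min(1.0, 2 * min(lower, upper)))
    raise ValueError(f"unknown mode {mode!r}")


def exact_test(matrix: GeneCountMatrix,
               group_a: Iterable[str],
               group_b: Iterable[str],
               dispersion: DispersionEstimate | float = 0.0,
               prior_count: float = 0.125,
               mode: str = "minlike") -> pd.DataFrame:
    """Two-group NB exact test per gene.

    Returns a frame indexed by gene with columns ``log2fc`` (group A over
    group B, moderated by ``prior_count`` pseudo-counts per library) and
    ``p_value``.  Library sizes are equalized before testing.  A gene
    with zero total in both groups gets p = 1 and log2fc = 0.
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be nonempty")
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    y = equalize_library_sizes(matrix.raw[group_a + group_b])
    ya = y[group_a].to_numpy()
    yb = y[group_b].to_numpy()
    n_a, n_b = len(group_a), len(group_b)

    sum_a = ya.sum(axis=1)
    sum_b = yb.sum(axis=1)
    mean_a = (sum_a + prior_count * n_a) / n_a
    mean_b = (sum_b + prior_count * n_b) / n_b
    log2fc = np.log2(mean_a / mean_b)

    p_values = np.ones(len(y))
    for i, (sa, sb) in enumerate(zip(sum_a, sum_b)):
        z = int(sa + sb)
        if z == 0:
            log2fc[i] = 0.0
            continue
        if isinstance(dispersion, DispersionEstimate):
            phi = dispersion.phi_for(y.index[i])
        else:
            phi = float(dispersion)
        logpmf = _conditional_logpmf(z, n_a, n_b, phi)
        p_values[i] = _twosided_p(logpmf, int(sa), mode=mode)

    return pd.DataFrame({"log2fc": log2fc, "p_value": p_values}, index=y.index)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def annotate_significance(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Add ``fdr`` and ``direction`` (up/down/ns at the FDR threshold)."""
    out = table.copy()
    out["fdr"] = bh_adjust(out["p_value"].to_numpy())
    direction = np.where(out["fdr"] < alpha,
                         np.where(out["log2fc"] > 0, UP, DOWN), NS)
    out["direction"] = direction
    return out


# ---------------------------------------------------------------------------
# Population-specific classification and contrasts
# ---------------------------------------------------------------------------

@dataclass
class PopulationSpecificSets:
    """Fig-2-style partition of significant genes for one transition."""

    lake_only_up: frozenset[str]
    lake_only_down: frozenset[str]
    river_only_up: frozenset[str]
    river_only_down: frozenset[str]
    shared_up: frozenset[str]
    shared_down: frozenset[str]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in ("lake_only_up", "lake_only_down", "river_only_up",
                     "river_only_down", "shared_up", "shared_down"):
            for gene in sorted(getattr(self, name)):
                rows.append({"set": name, "gene_id": gene})
        return pd.DataFrame(rows, columns=["set", "gene_id"])

    def counts_2x2(self) -> np.ndarray:
        """Rows lake/river, columns up/down, population-specific only."""
        return np.array([
            [len(self.lake_only_up), len(self.lake_only_down)],
            [len(self.river_only_up), len(self.river_only_down)],
        ])


def classify_population_specific(de_lake: pd.DataFrame,
                                 de_river: pd.DataFrame,
                                 alpha: float = 0.05) -> PopulationSpecificSets:
    """Split significant genes into population-specific and shared sets.

    Both tables must be annotated (fdr + direction) over the same gene
    universe.  A gene is lake-only-up when significantly up in lake fish
    and not significant (either direction) in river fish; shared sets
    require the same significant direction in both populations.
    """
    if set(de_lake.index) != set(de_river.index):
        raise ValueError("DE tables cover different gene universes")
    river = de_river.loc[de_lake.index]
    lake_dir = de_lake["direction"]
    river_dir = river["direction"]

    def pick(a: pd.Series, cond_a: str, b: pd.Series, cond_b: str) -> frozenset[str]:
        return frozenset(de_lake.index[(a == cond_a) & (b == cond_b)])

    return PopulationSpecificSets(
        lake_only_up=pick(lake_dir, UP, river_dir, NS),
        lake_only_down=pick(lake_dir, DOWN, river_dir, NS),
        river_only_up=pick(river_dir, UP, lake_dir, NS),
        river_only_down=pick(river_dir, DOWN, lake_dir, NS),
        shared_up=pick(lake_dir, UP, river_dir, UP),
        shared_down=pick(lake_dir, DOWN, river_dir, DOWN),
    )


def chisq_2x2(table: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Pearson chi-squared on a 2x2 table, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with nonnegative cells")
    n = t.sum()
    if n <= 0:
        raise ValueError("empty table")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("zero margin in 2x2 table")
    a, b, c, d = t.ravel()
    chi2 = n * (a * d - b * c) ** 2 / (rows[0] * rows[1] * cols[0] * cols[1])
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def mann_whitney(group_a: Sequence[float],
                 group_b: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U (group A) with a two-sided p.

    Exact by enumeration when the pooled sample is small (<= 12) and
    tie-free, otherwise the normal approximation with tie correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))
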
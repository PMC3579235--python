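"""Tag-to-gene assignment and the normalized gene count matrix.

A 26-bp tag scores a gene when it aligns to the forward strand of one of
the gene's transcripts with at most ``max_mismatch`` substitutions
("matched uniquely, in the correct orientation, with less than two
mismatches").  Reference positions carrying an IUPAC ambiguity code cost
one mismatch for EVERY tag base — both alleles of a polymorphic site pay
the same price and have the same likelihood of scoring the gene.  Since
tag bases are plain A/C/G/T, this rule reduces to literal character
inequality against the consensus sequence.

Tags hitting transcripts of more than one gene are ambiguous and
excluded from counting; splice variants of one gene collapse to that
gene.  Counts are normalized per library to a common total of one
million tags (counts per million over assigned tags).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import (
    CPM_TOTAL,
    STANDARD_BASES,
    TAG_LEN,
    GeneCountMatrix,
    TagCountTable,
    TranscriptSet,
)

ASSIGNED = "assigned"
AMBIGUOUS = "ambiguous_multi_gene"
UNMATCHED = "unmatched"


@dataclass(frozen=True)
class TagAssignment:
    tag: str
    status: str
    gene_id: str | None = None
    mismatches: int | None = None


class TagIndex:
    """Pigeonhole k-mer index over all tag-length reference windows.

    The tag is split into ``max_mismatch + 1`` chunks; any window within
    the mismatch budget must match at least one chunk exactly, so exact
    chunk lookups enumerate every candidate, which is then verified by
    character comparison.  Results are identical to the exhaustive scan.
    """

    def __init__(self, reference: TranscriptSet, max_mismatch: int = 1,
                 tag_len: int = TAG_LEN):
        self.reference = reference
        self.max_mismatch = max_mismatch
        self.tag_len = tag_len
        self._genes = [rec.gene_id for rec in reference]
        self._seqs = [rec.sequence for rec in reference]

        bounds = np.linspace(0, tag_len, max_mismatch + 2).astype(int)
        self._chunks = [(int(bounds[i]), int(bounds[i + 1]))
                        for i in range(max_mismatch + 1)]
        self._index: dict[tuple[int, str], list[tuple[int, int]]] = {}
        for t_idx, seq in enumerate(self._seqs):
            for start in range(len(seq) - tag_len + 1):
                for c_idx, (lo, hi) in enumerate(self._chunks):
                    key = (c_idx, seq[start + lo:start + hi])
                    self._index.setdefault(key, []).append((t_idx, start))

    def match(self, tag: str) -> TagAssignment:
        if len(tag) != self.tag_len:
            raise ValueError(f"tag length {len(tag)} != {self.tag_len}")
        if not set(tag) <= STANDARD_BASES:
            raise ValueError(f"tag contains non-ACGT base: {tag!r}")
        budget = self.max_mismatch
        best_per_transcript: dict[int, int] = {}
        seen: set[tuple[int, int]] = set()
        for c_idx, (lo, hi) in enumerate(self._chunks):
            for t_idx, start in self._index.get((c_idx, tag[lo:hi]), ()):
                if (t_idx, start) in seen:
                    continue
                seen.add((t_idx, start))
                seq = self._seqs[t_idx]
                mm = 0
                for i in range(self.tag_len):
                    if seq[start + i] != tag[i]:
                        mm += 1
                        if mm > budget:
                            break
                if mm <= budget:
                    prev = best_per_transcript.get(t_idx)
                    if prev is None or mm < prev:
                        best_per_transcript[t_idx] = mm
        if not best_per_transcript:
            return TagAssignment(tag, UNMATCHED)
        gene_best: dict[str, int] = {}
        for t_idx, mm in best_per_transcript.items():
            gene = self._genes[t_idx]
            if gene not in gene_best or mm < gene_best[gene]:
                gene_best[gene] = mm
        if len(gene_best) > 1:
            return TagAssignment(tag, AMBIGUOUS)
        gene, mm = next(iter(gene_best.items()))
        return TagAssignment(tag, ASSIGNED, gene_id=gene, mismatches=mm)


def match_tag(tag: str, reference: TranscriptSet,
              max_mismatch: int = 1) -> TagAssignment:
    """Assign one tag against the consensus reference.

    Builds (and caches on the reference object) a :class:`TagIndex`; use
    the index directly when matching many tags.
    """
    cache = getattr(reference, "_tag_index_cache", None)
    if cache is None or cache.max_mismatch != max_mismatch:
        cache = TagIndex(reference, max_mismatch=max_mismatch)
        reference._tag_index_cache = cache  # type: ignore[attr-defined]
    return cache.match(tag)


def _match_tag_exhaustive(tag: str, reference: TranscriptSet,
                          max_mismatch: int = 1) -> TagAssignment:
    """Reference implementation: scan every offset of every transcript."""
    if not set(tag) <= STANDARD_BASES:
        raise ValueError(f"tag contains non-ACGT base: {tag!r}")
    gene_best: dict[str, int] = {}
    for rec in reference:
        seq = rec.sequence
        best: int | None = None
        for start in range(len(seq) - len(tag) + 1):
            mm = sum(1 for i in range(len(tag)) if seq[start + i] != tag[i])
            if best is None or mm < best:
                best = mm
        if best is not None and best <= max_mismatch:
            if rec.gene_id not in gene_best or best < gene_best[rec.gene_id]:
                gene_best[rec.gene_id] = best
    if not gene_best:
        return TagAssignment(tag, UNMATCHED)
    if len(gene_best) > 1:
        return TagAssignment(tag, AMBIGUOUS)
    gene, mm = next(iter(gene_best.items()))
    return TagAssignment(tag, ASSIGNED, gene_id=gene, mismatches=mm)


def assign_all(tags: Iterable[str], reference: TranscriptSet,
               max_mismatch: int = 1) -> list[TagAssignment]:
    """Assign many tags with a single shared index."""
    index = TagIndex(reference, max_mismatch=max_mismatch)
    return [index.match(t) for t in tags]


def assignments_to_frame(assignments: Iterable[TagAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"tag": a.tag, "status": a.status, "gene_id": a.gene_id or "",
          "mismatches": -1 if a.mismatches is None else a.mismatches}
         for a in assignments],
        columns=["tag", "status", "gene_id", "mismatches"])


def build_gene_counts(assignments: Sequence[TagAssignment],
                      tables: Sequence[TagCountTable],
                      gene_ids: Sequence[str] | None = None,
                      ) -> tuple[GeneCountMatrix, dict[str, float]]:
    """Sum assigned tag counts per gene and library.

    Ambiguous and unmatched tags contribute nothing.  Returns the matrix
    together with a small summary log including the ambiguous fraction.
    """
    tag_gene = {a.tag: a.gene_id for a in assignments if a.status == ASSIGNED}
    n_ambiguous = sum(1 for a in assignments if a.status == AMBIGUOUS)
    n_unmatched = sum(1 for a in assignments if a.status == UNMATCHED)

    genes = list(gene_ids) if gene_ids is not None else sorted(
        {g for g in tag_gene.values() if g is not None})
    libs = [t.library_id for t in tables]
    raw = pd.DataFrame(0, index=genes, columns=libs, dtype=int)
    for table in tables:
        for tag, count in table.counts.items():
            gene = tag_gene.get(tag)
            if gene is not None:
                raw.loc[gene, table.library_id] += count
    log = {
        "n_tags": float(len(assignments)),
        "n_assigned": float(len(tag_gene)),
        "n_ambiguous": float(n_ambiguous),
        "n_unmatched": float(n_unmatched),
        "frac_ambiguous": n_ambiguous / len(assignments) if assignments else 0.0,
    }
    return GeneCountMatrix(raw=raw), log


def normalize_cpm(matrix: GeneCountMatrix) -> GeneCountMatrix:
    """Scale every library to a common total of one million tags.

    Totals are taken over assigned tags (the matrix's own column sums).
    """
    totals = matrix.library_totals
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(
            f"library with zero assigned tags: {list(zero.index)[0]!r}")
    normalized = matrix.raw * (CPM_TOTAL / totals)
    return GeneCountMatrix(raw=matrix.raw.copy(), normalized=normalized)
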
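"""Synthetic SuperSAGE study emulator.

Generates everything the pipeline consumes so each stage is testable
without downloads: a reference transcriptome with splice variants and an
NlaIII anchor (CATG) in the 3' region, the 24-library crossed design
(2 populations x 2 families x 3 treatments x 2 sexes), negative-binomial
per-gene tag counts with configurable population x treatment effects,
raw tag reads carrying random 8-bp molecular barcodes with optional PCR
duplication and substitution errors, and a toy Gene Ontology whose
structure mirrors the biological-process hierarchy (an immune-system
branch with innate and adaptive children under the root).

All generators are pure functions of their arguments including the seed.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .containers import (
    ANCHOR,
    BARCODE_LEN,
    POPULATIONS,
    SEXES,
    TAG_LEN,
    TREATMENTS,
    GeneCountMatrix,
    SampleMeta,
    TranscriptRecord,
    TranscriptSet,
)
from .enrichment import AnnotationMap, GODag

_BASES = np.array(list("ACGT"))

#: Fixed GO ids used by the toy ontology so the immune branch is recognizable.
GO_ROOT = "GO:0008150"          # biological_process
GO_IMMUNE = "GO:0002376"        # immune system process
GO_INNATE = "GO:0045087"        # innate immune response
GO_ADAPTIVE = "GO:0002250"      # adaptive immune response
_FIXED_LEVEL2 = (
    (GO_IMMUNE, "immune system process"),
    ("GO:0008152", "metabolic process"),
    ("GO:0009987", "cellular process"),
    ("GO:0050896", "response to stimulus"),
    ("GO:0032502", "developmental process"),
)


# ---------------------------------------------------------------------------
# Effects and ground truth
# ---------------------------------------------------------------------------

#: Treatment cells touched by an effect tied to a treatment transition.
#: An effect acting on the control -> once_exposed transition persists in
#: twice-exposed fish, so that it does not masquerade as a reversal on the
#: second transition.
TRANSITIONS = {
    "control_to_once": ("once_exposed", "twice_exposed"),
    "once_to_twice": ("twice_exposed",),
}


@dataclass(frozen=True)
class EffectSpec:
    """A fold-change applied to a gene set in specific design cells.

    ``applies_to`` lists (population, treatment) cells whose libraries get
    the multiplicative effect ``2 ** (+/- log2_fold_change)`` on the mean.
    """

    gene_set_id: str
    member_gene_ids: tuple[str, ...]
    log2_fold_change: float
    applies_to: tuple[tuple[str, str], ...]
    direction: str = "up"

    def __post_init__(self) -> None:
        if not np.isfinite(self.log2_fold_change):
            raise ValueError("log2_fold_change must be finite")
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {self.direction!r}")
        for pop, treat in self.applies_to:
            if pop not in POPULATIONS:
                raise ValueError(f"unknown population {pop!r}")
            if treat not in TREATMENTS:
                raise ValueError(f"unknown treatment {treat!r}")

    @classmethod
    def for_transition(cls, gene_set_id: str, genes: Iterable[str],
                       log2_fold_change: float, population: str,
                       transition: str = "control_to_once",
                       direction: str = "up") -> "EffectSpec":
        cells = tuple((population, t) for t in TRANSITIONS[transition])
        return cls(gene_set_id, tuple(genes), log2_fold_change, cells, direction)

    @property
    def signed_lfc(self) -> float:
        return self.log2_fold_change if self.direction == "up" else -self.log2_fold_change


@dataclass
class GroundTruth:
    """Expected NB means per gene and library, plus the effects used."""

    mean: pd.DataFrame                  # genes x libraries, mu in tags
    dispersion: pd.Series               # per-gene phi (variance = mu + phi mu^2)
    effects: tuple[EffectSpec, ...]

    def __post_init__(self) -> None:
        if (self.mean.to_numpy() < 0).any():
            raise ValueError("negative mean in ground truth")
        if (self.dispersion.to_numpy() < 0).any():
            raise ValueError("negative dispersion in ground truth")


# ---------------------------------------------------------------------------
# Transcriptome
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _scrub_anchor(seq: np.ndarray, rng: np.random.Generator,
                  start: int = 0) -> None:
    """Destroy every ANCHOR occurrence beginning at or after ``start``.

    Mutates one base of each occurrence until none remain; random
    replacements may create new sites, so iterate to a fixed point.
    """
    text = "".join(seq[start:])
    while True:
        pos = text.find(ANCHOR)
        if pos == -1:
            return
        offset = start + pos + int(rng.integers(0, len(ANCHOR)))
        old = seq[offset]
        choices = [b for b in "ACGT" if b != old]
        seq[offset] = choices[int(rng.integers(0, 3))]
        text = "".join(seq[start:])


def generate_transcriptome(n_genes: int,
                           variants_per_gene_rate: float = 0.3,
                           mean_len: int = 500,
                           frac_without_anchor: float = 0.0,
                           seed: int = 0) -> TranscriptSet:
    """Random reference transcriptome with a plantable tag site.

    Each gene owns ``1 + Poisson(variants_per_gene_rate)`` splice variants
    that share their 3'-terminal region (hence their tag).  Anchored genes
    carry exactly one CATG in the 3' region with room for a full 26-bp tag
    downstream; a ``frac_without_anchor`` fraction of genes contains no
    CATG anywhere and is therefore undetectable by design.
    """
    if n_genes < 1:
        raise ValueError(f"n_genes must be >= 1, got {n_genes}")
    if not 0 <= frac_without_anchor < 1:
        raise ValueError("frac_without_anchor must be in [0, 1)")
    rng = np.random.default_rng(seed)
    core_len = 90  # 3' region shared by splice variants of a gene
    records: list[TranscriptRecord] = []
    for g in range(n_genes):
        gene_id = f"G{g:05d}"
        anchor_free = rng.random() < frac_without_anchor
        n_var = 1 + int(rng.poisson(variants_per_gene_rate))
        length = max(120, int(rng.normal(mean_len, mean_len / 5)))
        core = _random_seq(rng, core_len)
        if anchor_free:
            _scrub_anchor(core, rng)
        else:
            # one clean anchor with >= TAG_LEN bases of room, ~30 bp from 3' end
            site = core_len - TAG_LEN - 30
            _scrub_anchor(core, rng)
            core[site:site + len(ANCHOR)] = list(ANCHOR)
            _scrub_anchor(core, rng, start=site + 1)
        for v in range(n_var):
            prefix_len = max(0, length - core_len + int(rng.integers(-20, 21)))
            prefix = _random_seq(rng, prefix_len)
            if anchor_free:
                _scrub_anchor(prefix, rng)
            else:
                # keep the planted site 3'-most: no anchors in the prefix
                # spanning into the core either
                seq = np.concatenate([prefix, core])
                _scrub_anchor(seq, rng)
                site = len(prefix) + core_len - TAG_LEN - 30
                seq[site:site + len(ANCHOR)] = list(ANCHOR)
                _scrub_anchor(seq, rng, start=site + 1)
                records.append(TranscriptRecord(gene_id, f"{gene_id}.t{v+1}",
                                                "".join(seq)))
                continue
            seq = np.concatenate([prefix, core])
            _scrub_anchor(seq, rng)  # junction may have created a site
            records.append(TranscriptRecord(gene_id, f"{gene_id}.t{v+1}",
                                            "".join(seq)))
    return TranscriptSet(records)


# ---------------------------------------------------------------------------
# Design
# ---------------------------------------------------------------------------

def generate_design() -> list[SampleMeta]:
    """The 24-library crossed design: one male and one female per
    (population, family, treatment) cell, two families per population."""
    design = []
    i = 0
    for pop in POPULATIONS:
        for fam_no in (1, 2):
            family = f"{pop}_f{fam_no}"
            for treatment in TREATMENTS:
                for sex in SEXES:
                    i += 1
                    design.append(SampleMeta(
                        library_id=f"L{i:02d}",
                        population=pop, family=family, sex=sex,
                        treatment=treatment))
    return design


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------

def simulate_counts(transcripts: TranscriptSet,
                    design: Sequence[SampleMeta],
                    baseline_mean: float = 20.0,
                    dispersion: float | Mapping[str, float] = 0.2,
                    effects: Sequence[EffectSpec] = (),
                    seed: int = 0) -> tuple[GeneCountMatrix, GroundTruth]:
    """Draw per-gene, per-library tag counts from NB(mu, phi).

    ``log2 mu = log2 baseline + sum of signed effect log2 fold changes``
    for the library's (population, treatment) cell.  Variance is
    ``mu + phi * mu**2``; ``phi = 0`` gives Poisson counts.  Genes of
    anchor-free transcripts still receive expression here — they are lost
    only at the read-extraction stage.
    """
    if baseline_mean <= 0:
        raise ValueError("baseline_mean must be positive")
    genes = transcripts.gene_ids
    gene_set = set(genes)
    for eff in effects:
        unknown = [g for g in eff.member_gene_ids if g not in gene_set]
        if unknown:
            raise KeyError(
                f"effect {eff.gene_set_id!r} references unknown genes {unknown[:5]}")

    libs = [s.library_id for s in design]
    lfc = pd.DataFrame(0.0, index=genes, columns=libs)
    for eff in effects:
        cells = set(eff.applies_to)
        cols = [s.library_id for s in design
                if (s.population, s.treatment) in cells]
        if cols:
            lfc.loc[list(eff.member_gene_ids), cols] += eff.signed_lfc
    mu = baseline_mean * np.exp2(lfc)

    if isinstance(dispersion, Mapping):
        phi = pd.Series({g: float(dispersion.get(g, 0.0)) for g in genes})
    else:
        phi = pd.Series(float(dispersion), index=genes)
    if (phi < 0).any():
        raise ValueError("dispersion must be >= 0")

    rng = np.random.default_rng(seed)
    mu_arr = mu.to_numpy()
    phi_arr = phi.to_numpy()[:, None]
    counts = np.empty_like(mu_arr, dtype=np.int64)
    poisson_rows = phi_arr[:, 0] == 0
    if poisson_rows.any():
        counts[poisson_rows] = rng.poisson(mu_arr[poisson_rows])
    nb_rows = ~poisson_rows
    if nb_rows.any():
        r = 1.0 / phi_arr[nb_rows]
        p = r / (r + mu_arr[nb_rows])
        counts[nb_rows] = rng.negative_binomial(r, p)

    raw = pd.DataFrame(counts, index=genes, columns=libs)
    truth = GroundTruth(mean=mu, dispersion=phi, effects=tuple(effects))
    return GeneCountMatrix(raw=raw), truth


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

def tag_site(sequence: str) -> int | None:
    """0-based start of the 3'-most CATG, or None if absent."""
    pos = sequence.rfind(ANCHOR)
    return None if pos == -1 else pos


@dataclass
class ReadSimResult:
    """Raw reads plus the realized ground truth they encode.

    ``tag_truth`` maps library -> tag -> number of DISTINCT barcodes drawn
    for that tag (what perfect extraction + deduplication must recover).
    ``gene_truth`` aggregates the same numbers per gene.
    """

    reads: dict[str, list[str]]
    tag_truth: dict[str, dict[str, int]]
    gene_truth: pd.DataFrame
    tag_to_gene: dict[str, str]
    n_skipped_short: int
    n_skipped_anchorless: int

    def write_fastq(self, out_dir: str | Path, gzipped: bool = False) -> dict[str, Path]:
        """One FASTQ per library (constant Q40 qualities); returns paths."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for lib, reads in self.reads.items():
            path = out_dir / (f"{lib}.fastq.gz" if gzipped else f"{lib}.fastq")
            opener = gzip.open if gzipped else open
            with opener(path, "wt") as fh:  # type: ignore[operator]
                for i, seq in enumerate(reads):
                    fh.write(f"@{lib}:{i}\n{seq}\n+\n{'I' * len(seq)}\n")
            paths[lib] = path
        return paths


def simulate_reads(counts: GeneCountMatrix,
                   transcripts: TranscriptSet,
                   barcode_len: int = BARCODE_LEN,
                   error_rate: float = 0.0,
                   pcr_duplication_rate: float = 0.0,
                   seed: int = 0) -> ReadSimResult:
    """Turn simulated counts into raw SuperSAGE reads.

    Each transcript copy whose transcript contains a CATG with a full tag
    window downstream yields one molecule: a random barcode of
    ``barcode_len`` bases followed by the 26-bp tag starting at the
    3'-most CATG.  With probability ``pcr_duplication_rate`` a molecule
    keeps spawning PCR copies (geometric), replicating its (barcode, tag)
    pair.  Substitution errors hit every base independently at
    ``error_rate`` AFTER duplication.
    """
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")
    if not 0 <= pcr_duplication_rate < 1:
        raise ValueError("pcr_duplication_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    by_gene = transcripts.by_gene()

    # precompute tag per transcript (None when undetectable)
    tags: dict[str, str | None] = {}
    short: dict[str, bool] = {}
    for rec in transcripts:
        pos = tag_site(rec.sequence)
        if pos is None:
            tags[rec.transcript_id] = None
            short[rec.transcript_id] = False
        elif pos + TAG_LEN > len(rec.sequence):
            tags[rec.transcript_id] = None
            short[rec.transcript_id] = True
        else:
            tags[rec.transcript_id] = rec.sequence[pos:pos + TAG_LEN]

    tag_to_gene: dict[str, str] = {}
    for rec in transcripts:
        t = tags[rec.transcript_id]
        if t is not None:
            tag_to_gene.setdefault(t, rec.gene_id)

    reads: dict[str, list[str]] = {}
    tag_truth: dict[str, dict[str, int]] = {}
    gene_truth = pd.DataFrame(0, index=counts.gene_ids,
                              columns=counts.library_ids, dtype=int)
    n_short = n_anchorless = 0

    for lib in counts.library_ids:
        lib_reads: list[str] = []
        barcode_sets: dict[str, set[str]] = {}
        col = counts.raw[lib]
        for gene in counts.gene_ids:
            c = int(col[gene])
            if c == 0:
                continue
            variants = by_gene[gene]
            choice = rng.integers(0, len(variants), size=c)
            for v in choice:
                tid = variants[int(v)].transcript_id
                tag = tags[tid]
                if tag is None:
                    if short[tid]:
                        n_short += 1
                    else:
                        n_anchorless += 1
                    continue
                barcode = "".join(_BASES[rng.integers(0, 4, size=barcode_len)])
                barcode_sets.setdefault(tag, set()).add(barcode)
                molecule = barcode + tag
                n_copies = 1
                while pcr_duplication_rate > 0 and rng.random() < pcr_duplication_rate:
                    n_copies += 1
                lib_reads.extend([molecule] * n_copies)
        # substitution errors after duplication
        if error_rate > 0 and lib_reads:
            mutated = []
            for read in lib_reads:
                arr = np.array(list(read))
                hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
                for h in hits:
                    alternatives = [b for b in "ACGT" if b != arr[h]]
                    arr[h] = alternatives[int(rng.integers(0, 3))]
                mutated.append("".join(arr))
            lib_reads = mutated
        rng.shuffle(lib_reads)
        reads[lib] = lib_reads
        tag_truth[lib] = {t: len(s) for t, s in barcode_sets.items()}
        for t, n in tag_truth[lib].items():
            gene_truth.loc[tag_to_gene[t], lib] += n

    return ReadSimResult(reads=reads, tag_truth=tag_truth,
                         gene_truth=gene_truth, tag_to_gene=tag_to_gene,
                         n_skipped_short=n_short,
                         n_skipped_anchorless=n_anchorless)


def simulate_cdna_reads(transcripts: TranscriptSet,
                        depth: int = 10,
                        read_len: int = 80,
                        snp_rate: float = 0.0,
                        seed: int = 0) -> list[tuple[str, str]]:
    """Error-free cDNA fragments for consensus building, optionally with
    heterozygous SNPs: at ``snp_rate`` of positions, half the reads carry
    an alternative base.  Returns (read_id, sequence) pairs."""
    rng = np.random.default_rng(seed)
    out: list[tuple[str, str]] = []
    for rec in transcripts:
        seq = np.array(list(rec.sequence))
        alt = seq.copy()
        snp_positions = np.nonzero(rng.random(len(seq)) < snp_rate)[0]
        for pos in snp_positions:
            choices = [b for b in "ACGT" if b != seq[pos]]
            alt[pos] = choices[int(rng.integers(0, 3))]
        for i in range(depth):
            if len(seq) <= read_len:
                start, stop = 0, len(seq)
            else:
                start = int(rng.integers(0, len(seq) - read_len + 1))
                stop = start + read_len
            haplotype = alt if rng.random() < 0.5 else seq
            out.append((f"{rec.transcript_id}:r{i}",
                        "".join(haplotype[start:stop])))
    return out


# ---------------------------------------------------------------------------
# Ontology
# ---------------------------------------------------------------------------

def generate_go(gene_ids: Sequence[str],
                n_terms: int = 30,
                seed: int = 0,
                immune_genes: Sequence[str] = (),
                mean_terms_per_gene: float = 1.5) -> tuple[GODag, AnnotationMap]:
    """Toy biological-process ontology plus gene annotations.

    The DAG has a single root with fixed second-order children including
    an immune-system term that owns innate and adaptive children; the
    remaining ``n_terms`` are attached at random below the second level
    (always to previously created terms, so the graph is acyclic by
    construction).  ``immune_genes`` are annotated under the innate or
    adaptive immune child; the rest draw ``1 + Poisson`` random
    non-immune terms.
    """
    if n_terms < 10:
        raise ValueError("n_terms must be >= 10")
    rng = np.random.default_rng(seed)
    graph = nx.DiGraph()
    graph.add_node(GO_ROOT, name="biological_process")
    for term, name in _FIXED_LEVEL2:
        graph.add_node(term, name=name)
        graph.add_edge(term, GO_ROOT)
    graph.add_node(GO_INNATE, name="innate immune response")
    graph.add_edge(GO_INNATE, GO_IMMUNE)
    graph.add_node(GO_ADAPTIVE, name="adaptive immune response")
    graph.add_edge(GO_ADAPTIVE, GO_IMMUNE)

    non_immune_l2 = [t for t, _ in _FIXED_LEVEL2 if t != GO_IMMUNE]
    attachable = list(non_immune_l2)
    n_extra = n_terms - graph.number_of_nodes()
    extra_terms: list[str] = []
    for i in range(max(0, n_extra)):
        term = f"GO:9{i:06d}"
        parent = attachable[int(rng.integers(0, len(attachable)))]
        graph.add_node(term, name=f"synthetic process {i}")
        graph.add_edge(term, parent)
        if rng.random() < 0.2:  # occasional second parent (still acyclic)
            other = attachable[int(rng.integers(0, len(attachable)))]
            if other != parent:
                graph.add_edge(term, other)
        attachable.append(term)
        extra_terms.append(term)
    dag = GODag(graph)

    immune_set = set(immune_genes)
    unknown = immune_set - set(gene_ids)
    if unknown:
        raise KeyError(f"immune_genes not in gene_ids: {sorted(unknown)[:5]}")
    leaf_pool = extra_terms or non_immune_l2
    direct: dict[str, frozenset[str]] = {}
    for gene in gene_ids:
        if gene in immune_set:
            terms = {GO_INNATE if rng.random() < 0.7 else GO_ADAPTIVE}
        else:
            k = 1 + int(rng.poisson(max(0.0, mean_terms_per_gene - 1)))
            terms = {leaf_pool[int(j)] for j in
                     rng.integers(0, len(leaf_pool), size=k)}
        direct[gene] = frozenset(terms)
    return dag, AnnotationMap(direct=direct)
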
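"""Shared in-memory containers for the SuperSAGE pipeline.

These are the data structures that travel between stages: transcript sets,
library (sample) metadata, tag observations and per-library tag count
tables, and the gene x library count matrix.  They are deliberately thin
wrappers over pandas/standard containers so every stage can be used and
tested in isolation.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

POPULATIONS = ("lake", "river")
TREATMENTS = ("control", "once_exposed", "twice_exposed")
SEXES = ("M", "F")

#: NlaIII recognition site that anchors every SuperSAGE tag.
ANCHOR = "CATG"
#: Tag length in bp, anchor included (EcoP15I release downstream of NlaIII).
TAG_LEN = 26
#: Length of the random molecular barcode ligated before PCR.
BARCODE_LEN = 8
#: Per-library size every count column is scaled to ("counts per million").
CPM_TOTAL = 1_000_000.0

STANDARD_BASES = frozenset("ACGT")


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    """Open a possibly gzip-compressed text file."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


# ---------------------------------------------------------------------------
# Transcripts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TranscriptRecord:
    """One transcript (splice variant) in mRNA/sense orientation."""

    gene_id: str
    transcript_id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class TranscriptSet:
    """A set of transcripts with a many-to-one transcript -> gene mapping."""

    records: list[TranscriptRecord]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for rec in self.records:
            if rec.transcript_id in seen:
                raise ValueError(f"duplicate transcript_id {rec.transcript_id!r}")
            seen[rec.transcript_id] = rec.gene_id

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[TranscriptRecord]:
        return iter(self.records)

    @property
    def gene_ids(self) -> list[str]:
        out: list[str] = []
        seen: set[str] = set()
        for rec in self.records:
            if rec.gene_id not in seen:
                seen.add(rec.gene_id)
                out.append(rec.gene_id)
        return out

    def by_gene(self) -> dict[str, list[TranscriptRecord]]:
        out: dict[str, list[TranscriptRecord]] = {}
        for rec in self.records:
            out.setdefault(rec.gene_id, []).append(rec)
        return out

    def get(self, transcript_id: str) -> TranscriptRecord:
        for rec in self.records:
            if rec.transcript_id == transcript_id:
                return rec
        raise KeyError(transcript_id)

    def write_fasta(self, path: str | Path) -> None:
        """Write records as FASTA; headers are ``transcript_id gene=gene_id``."""
        with _open_text(path, "wt") as fh:
            SeqIO.write(
                (
                    SeqRecord(Seq(r.sequence), id=r.transcript_id,
                              description=f"gene={r.gene_id}")
                    for r in self.records
                ),
                fh,
                "fasta",
            )

    @classmethod
    def read_fasta(cls, path: str | Path) -> "TranscriptSet":
        records = []
        with _open_text(path) as fh:
            for rec in SeqIO.parse(fh, "fasta"):
                gene = rec.id
                for token in rec.description.split():
                    if token.startswith("gene="):
                        gene = token[5:]
                records.append(TranscriptRecord(gene, rec.id, str(rec.seq).upper()))
        return cls(records)


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleMeta:
    """Design coordinates of one SuperSAGE library (one fish)."""

    library_id: str
    population: str
    family: str
    sex: str
    treatment: str

    def __post_init__(self) -> None:
        if self.population not in POPULATIONS:
            raise ValueError(f"unknown population {self.population!r}")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")


def design_to_frame(design: Iterable[SampleMeta]) -> pd.DataFrame:
    rows = [
        {
            "library_id": s.library_id,
            "population": s.population,
            "family": s.family,
            "sex": s.sex,
            "treatment": s.treatment,
        }
        for s in design
    ]
    return pd.DataFrame(rows).set_index("library_id")


def design_from_frame(frame: pd.DataFrame) -> list[SampleMeta]:
    return [
        SampleMeta(str(idx), row["population"], row["family"], row["sex"],
                   row["treatment"])
        for idx, row in frame.iterrows()
    ]


# ---------------------------------------------------------------------------
# Tags
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TagObservation:
    """One sequenced molecule: random barcode plus 26-bp tag."""

    barcode: str
    tag: str


@dataclass
class TagCountTable:
    """Per-library map tag -> deduplicated count (distinct barcodes)."""

    library_id: str
    counts: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.counts)

    def total(self) -> int:
        return sum(self.counts.values())

    def copy(self) -> "TagCountTable":
        return TagCountTable(self.library_id, dict(self.counts))


def tag_tables_to_frame(tables: Iterable[TagCountTable]) -> pd.DataFrame:
    """Long-form TSV-ready frame: tag, library, count."""
    rows = [
        {"tag": tag, "library": t.library_id, "count": n}
        for t in tables
        for tag, n in sorted(t.counts.items())
    ]
    return pd.DataFrame(rows, columns=["tag", "library", "count"])


# ---------------------------------------------------------------------------
# Gene count matrix
# ---------------------------------------------------------------------------

@dataclass
class GeneCountMatrix:
    """Genes x libraries counts, raw and (optionally) CPM-normalized.

    ``raw`` holds integer tag counts per gene and library.  ``normalized``
    is filled by :func:`sagescape.tag_mapping_counts.normalize_cpm` and
    rescales every library to a common total of one million tags.
    """

    raw: pd.DataFrame
    normalized: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.raw.index.has_duplicates:
            raise ValueError("duplicate gene ids in count matrix")
        if self.raw.columns.has_duplicates:
            raise ValueError("duplicate library ids in count matrix")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.raw.index)

    @property
    def library_ids(self) -> list[str]:
        return list(self.raw.columns)

    @property
    def library_totals(self) -> pd.Series:
        return self.raw.sum(axis=0)

    def write_tsv(self, path: str | Path, which: str = "raw") -> None:
        frame = self.raw if which == "raw" else self.normalized
        if frame is None:
            raise ValueError(f"{which} counts not available")
        frame.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "GeneCountMatrix":
        frame = pd.read_csv(path, sep="\t", index_col="gene_id")
        return cls(raw=frame)


def counts_from_mapping(counts: Mapping[str, Mapping[str, int]],
                        gene_ids: Iterable[str],
                        library_ids: Iterable[str]) -> pd.DataFrame:
    """Dense integer frame from a nested {library: {gene: count}} mapping."""
    frame = pd.DataFrame(0, index=list(gene_ids), columns=list(library_ids),
                         dtype=int)
    for lib, per_gene in counts.items():
        for gene, n in per_gene.items():
            frame.loc[gene, lib] = n
    return frame
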
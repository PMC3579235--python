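"""Build the tag-matching reference with IUPAC ambiguity codes.

cDNA reads from the study fish are aligned (ungapped, seeded by shared
k-mers) against the backbone transcripts; positions where an alternative
base is well supported are rewritten as the IUPAC code covering the
backbone base and the observed alternatives.  This protects the
downstream tag matcher against population-specific SNPs: with an
ambiguity code in the reference, both alleles of a tag pay the same
single-mismatch cost and score the same gene.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .containers import STANDARD_BASES, TranscriptRecord, TranscriptSet, _open_text

#: Base-set -> IUPAC single-letter code.
IUPAC_CODES: dict[frozenset[str], str] = {
    frozenset(s): c
    for s, c in [
        ("A", "A"), ("C", "C"), ("G", "G"), ("T", "T"),
        ("AG", "R"), ("CT", "Y"), ("CG", "S"), ("AT", "W"),
        ("GT", "K"), ("AC", "M"),
        ("CGT", "B"), ("AGT", "D"), ("ACT", "H"), ("ACG", "V"),
        ("ACGT", "N"),
    ]
}


@dataclass
class Pileup:
    """Per-transcript, per-position base support from aligned reads."""

    depth: dict[str, dict[int, Counter]] = field(default_factory=dict)
    n_reads_aligned: int = 0
    n_reads_discarded: int = 0
    n_reads_ambiguous: int = 0

    def add(self, transcript_id: str, position: int, base: str) -> None:
        self.depth.setdefault(transcript_id, {}).setdefault(
            position, Counter())[base] += 1


@dataclass
class ConsensusTranscriptSet(TranscriptSet):
    """Transcripts whose sequences may contain IUPAC ambiguity codes.

    ``ambiguity_positions`` lists, per transcript, the (0-based position,
    code) pairs that were rewritten; codes appear in the sequence only at
    those positions.
    """

    ambiguity_positions: dict[str, list[tuple[int, str]]] = field(
        default_factory=dict)

    @property
    def n_ambiguous_bases(self) -> int:
        return sum(len(v) for v in self.ambiguity_positions.values())

    def write_ambiguity_tsv(self, path: str | Path) -> None:
        rows = [
            {"transcript_id": tid, "position": pos, "code": code}
            for tid, positions in sorted(self.ambiguity_positions.items())
            for pos, code in positions
        ]
        pd.DataFrame(rows, columns=["transcript_id", "position", "code"]).to_csv(
            path, sep="\t", index=False)

    @classmethod
    def plain(cls, backbone: TranscriptSet) -> "ConsensusTranscriptSet":
        """A consensus set identical to the backbone (no cDNA evidence)."""
        return cls(records=list(backbone.records), ambiguity_positions={})


def _iter_reads(reads) -> Iterable[tuple[str, str]]:
    """Yield (read_id, sequence) from paths, handles, SeqRecords or pairs."""
    if isinstance(reads, (str, Path)):
        path = Path(reads)
        fmt = "fastq" if ".fastq" in path.name or ".fq" in path.name else "fasta"
        with _open_text(path) as fh:
            for rec in SeqIO.parse(fh, fmt):
                yield rec.id, str(rec.seq).upper()
        return
    for item in reads:
        if isinstance(item, tuple):
            yield item[0], item[1].upper()
        else:  # SeqRecord
            yield item.id, str(item.seq).upper()


def align_reads_to_backbone(reads,
                            backbone: TranscriptSet,
                            k: int = 12,
                            min_identity: float = 0.9) -> Pileup:
    """Seed-and-verify ungapped alignment of cDNA reads to the backbone.

    Each read is assigned to at most one transcript: the candidate
    (transcript, offset) with the most shared k-mers wins, ties broken by
    alignment identity.  Reads below ``min_identity``, or whose best
    candidates tie across transcripts of *different* genes, are discarded
    and tallied; ties among transcripts of one gene go to the longest
    transcript.  Matched read bases accumulate in the pileup.
    """
    if k < 8:
        raise ValueError("k must be >= 8")
    if not 0 < min_identity <= 1:
        raise ValueError("min_identity must be in (0, 1]")
    if len(backbone) == 0:
        raise ValueError("empty backbone")

    index: dict[str, list[tuple[int, int]]] = {}
    seqs = [rec.sequence for rec in backbone]
    for t_idx, seq in enumerate(seqs):
        for pos in range(len(seq) - k + 1):
            index.setdefault(seq[pos:pos + k], []).append((t_idx, pos))

    pileup = Pileup()
    records = backbone.records
    for read_id, read in _iter_reads(reads):
        if len(read) < k:
            pileup.n_reads_discarded += 1
            continue
        votes: Counter = Counter()
        for rpos in range(len(read) - k + 1):
            for t_idx, tpos in index.get(read[rpos:rpos + k], ()):
                votes[(t_idx, tpos - rpos)] += 1
        if not votes:
            pileup.n_reads_discarded += 1
            continue
        best_kmers = max(votes.values())
        candidates = [key for key, v in votes.items() if v == best_kmers]

        scored = []
        for t_idx, offset in candidates:
            seq = seqs[t_idx]
            matches = overlap = 0
            for rpos, base in enumerate(read):
                tpos = offset + rpos
                if 0 <= tpos < len(seq):
                    overlap += 1
                    if seq[tpos] == base:
                        matches += 1
            identity = matches / overlap if overlap else 0.0
            scored.append((identity, t_idx, offset))
        best_identity = max(s[0] for s in scored)
        if best_identity < min_identity:
            pileup.n_reads_discarded += 1
            continue
        top = [s for s in scored if s[0] == best_identity]
        genes = {records[t].gene_id for _, t, _ in top}
        if len(genes) > 1:
            pileup.n_reads_ambiguous += 1
            continue
        # same gene: prefer the longest transcript (stable tie-break)
        _, t_idx, offset = max(top, key=lambda s: (len(seqs[s[1]]), -s[1]))

        tid = records[t_idx].transcript_id
        seq = seqs[t_idx]
        for rpos, base in enumerate(read):
            tpos = offset + rpos
            if 0 <= tpos < len(seq):
                pileup.add(tid, tpos, base)
        pileup.n_reads_aligned += 1
    return pileup


def call_consensus(backbone: TranscriptSet,
                   pileup: Pileup,
                   min_minor_count: int = 2,
                   min_minor_frac: float = 0.2) -> ConsensusTranscriptSet:
    """Rewrite well-supported polymorphic positions as IUPAC codes.

    A non-backbone base qualifies at a position when its pileup count is
    at least ``min_minor_count`` AND its frequency among observed bases is
    at least ``min_minor_frac``; the position then becomes the IUPAC code
    covering the backbone base plus all qualifying alternatives.
    Uncovered or unqualified positions keep the backbone base, so the
    consensus has exactly the backbone's length.
    """
    if min_minor_count < 1:
        raise ValueError("min_minor_count must be >= 1")
    if not 0 < min_minor_frac <= 0.5:
        raise ValueError("min_minor_frac must be in (0, 0.5]")

    records: list[TranscriptRecord] = []
    ambiguity: dict[str, list[tuple[int, str]]] = {}
    for rec in backbone:
        depth = pileup.depth.get(rec.transcript_id, {})
        for pos in depth:
            if pos < 0 or pos >= len(rec.sequence):
                raise IndexError(
                    f"pileup position {pos} outside {rec.transcript_id} "
                    f"(length {len(rec.sequence)})")
        seq = list(rec.sequence)
        positions: list[tuple[int, str]] = []
        for pos, counter in sorted(depth.items()):
            backbone_base = rec.sequence[pos]
            total = sum(counter.values())
            qualifying = {
                base
                for base, n in counter.items()
                if base in STANDARD_BASES and base != backbone_base
                and n >= min_minor_count and n / total >= min_minor_frac
            }
            if qualifying:
                code = IUPAC_CODES[frozenset(qualifying | {backbone_base})]
                seq[pos] = code
                positions.append((pos, code))
        records.append(TranscriptRecord(rec.gene_id, rec.transcript_id,
                                        "".join(seq)))
        if positions:
            ambiguity[rec.transcript_id] = positions
    return ConsensusTranscriptSet(records=records, ambiguity_positions=ambiguity)
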
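"""Tag extraction, PCR-duplicate removal and tag filtering.

A raw read is a fixed layout: an 8-bp random molecular barcode followed
by a 26-bp tag that starts with the NlaIII anchor CATG.  PCR duplicates
are molecules sharing the same (barcode, tag) combination and are counted
once, so a tag's deduplicated count is the number of distinct barcodes
observed with it.  Sequencing artifacts (one-off neighbours of a highly
abundant tag) are absorbed into that neighbour, and tags are then
filtered for clean bases and for occurrence in a minimum number of
libraries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .containers import (
    ANCHOR,
    BARCODE_LEN,
    STANDARD_BASES,
    TAG_LEN,
    TagCountTable,
    TagObservation,
    _open_text,
)


@dataclass
class ExtractionLog:
    """Tally of reads that produced no tag observation."""

    n_reads: int = 0
    n_extracted: int = 0
    n_too_short: int = 0
    n_bad_anchor: int = 0


def _iter_read_seqs(reads) -> Iterable[str]:
    if isinstance(reads, (str, Path)):
        path = Path(reads)
        with _open_text(path) as fh:
            index = 0
            try:
                for rec in SeqIO.parse(fh, "fastq"):
                    index += 1
                    yield str(rec.seq).upper()
            except ValueError as exc:
                raise ValueError(
                    f"malformed FASTQ record after record {index} in {path}: {exc}"
                ) from exc
        return
    for item in reads:
        if isinstance(item, str):
            yield item.upper()
        else:  # SeqRecord
            yield str(item.seq).upper()


def extract_tags(reads,
                 barcode_len: int = BARCODE_LEN,
                 tag_len: int = TAG_LEN,
                 anchor: str = ANCHOR) -> tuple[list[TagObservation], ExtractionLog]:
    """Split each read into (barcode, tag) by fixed offsets.

    Reads shorter than ``barcode_len + tag_len`` or whose tag does not
    begin with ``anchor`` yield no observation and are tallied in the log.
    Set ``anchor=""`` to disable anchor checking.
    """
    log = ExtractionLog()
    observations: list[TagObservation] = []
    need = barcode_len + tag_len
    for seq in _iter_read_seqs(reads):
        log.n_reads += 1
        if len(seq) < need:
            log.n_too_short += 1
            continue
        tag = seq[barcode_len:need]
        if anchor and not tag.startswith(anchor):
            log.n_bad_anchor += 1
            continue
        observations.append(TagObservation(barcode=seq[:barcode_len], tag=tag))
        log.n_extracted += 1
    return observations, log


def dedup_truequant(observations: Iterable[TagObservation],
                    library_id: str = "library") -> TagCountTable:
    """Collapse PCR copies: count distinct barcodes per tag."""
    barcodes: dict[str, set[str]] = {}
    for obs in observations:
        barcodes.setdefault(obs.tag, set()).add(obs.barcode)
    return TagCountTable(library_id=library_id,
                         counts={tag: len(s) for tag, s in barcodes.items()})


def _hamming1_neighbours(tag: str) -> Iterable[str]:
    for i, base in enumerate(tag):
        for alt in "ACGT":
            if alt != base:
                yield tag[:i] + alt + tag[i + 1:]


def reduce_artifacts(table: TagCountTable,
                     ratio_threshold: float = 100.0) -> TagCountTable:
    """Absorb likely sequencing artifacts into dominant neighbours.

    A tag is absorbed into a Hamming-distance-1 neighbour whose current
    count is at least ``ratio_threshold`` times its own; its count is
    added to the neighbour.  Candidates are processed from rarest to most
    abundant; among several eligible neighbours the highest-count one
    wins, ties broken lexicographically.  Total count is conserved.
    """
    if ratio_threshold <= 1:
        raise ValueError("ratio_threshold must be > 1")
    counts = dict(table.counts)
    for tag in sorted(counts, key=lambda t: (counts[t], t)):
        if tag not in counts:
            continue
        own = counts[tag]
        best: tuple[int, str] | None = None
        for neighbour in _hamming1_neighbours(tag):
            n = counts.get(neighbour)
            if n is not None and n >= ratio_threshold * own:
                # prefer the highest count; ties -> lexicographically first
                key = (n, neighbour)
                if best is None or n > best[0] or (n == best[0] and neighbour < best[1]):
                    best = key
        if best is not None:
            counts[best[1]] += own
            del counts[tag]
    return TagCountTable(library_id=table.library_id, counts=counts)


def filter_tags(tables: Sequence[TagCountTable],
                min_libraries: int = 7) -> list[TagCountTable]:
    """Drop tags with non-ACGT bases and tags seen in too few libraries.

    A tag must be present (count >= 1) in at least ``min_libraries`` of
    the supplied tables to be retained; otherwise it is removed from all
    of them.  The operation is idempotent.
    """
    if min_libraries < 1:
        raise ValueError("min_libraries must be >= 1")
    if min_libraries > len(tables):
        raise ValueError(
            f"min_libraries={min_libraries} exceeds the number of "
            f"libraries ({len(tables)})")
    presence: dict[str, int] = {}
    for table in tables:
        for tag, n in table.counts.items():
            if n >= 1:
                presence[tag] = presence.get(tag, 0) + 1
    keep = {
        tag
        for tag, n_libs in presence.items()
        if n_libs >= min_libraries and set(tag) <= STANDARD_BASES
    }
    return [
        TagCountTable(
            library_id=t.library_id,
            counts={tag: n for tag, n in t.counts.items() if tag in keep})
        for t in tables
    ]
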
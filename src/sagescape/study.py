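"""Summary tallies of the lake/river stickleback SuperSAGE study that
this package's synthetic design emulates.

These numbers describe the real experiment the pipeline is built for:
24 head-kidney libraries from two lake and two river families across
three exposure treatments, sequenced as 26-bp NlaIII-anchored tags.
They are inputs for sanity arithmetic (e.g. the fraction of annotated
genes detected), not outputs of this package.
"""

from __future__ import annotations

#: Protein-coding transcripts with GO annotation used as mapping backbone.
BACKBONE_TRANSCRIPTS = 21_449
#: Genes represented by those transcripts.
ANNOTATED_GENES = 16_371
#: Unique tags retained after quality and >=7-library filtering.
UNIQUE_TAGS_RETAINED = 85_301
#: Retained tags that mapped uniquely to a backbone transcript.
TAGS_MAPPED = 13_695
#: Genes with expression data after mapping and splice-variant collapse.
GENES_DETECTED = 5_709
#: IUPAC consensus bases introduced by the cDNA mapping assembly.
IUPAC_CONSENSUS_BASES = 10_835
#: Genes in the GO-enrichment universe (biological process annotation).
GO_UNIVERSE_GENES = 11_184
#: Biological-process terms represented in that universe.
GO_TERMS_REPRESENTED = 8_627

#: Number of sequenced libraries and the design cells behind them.
N_LIBRARIES = 24
N_PER_TREATMENT = 8


def detected_gene_fraction() -> float:
    """Percentage of annotated genes with expression data (tags mapped)."""
    return 100.0 * GENES_DETECTED / ANNOTATED_GENES
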
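"""Shared fixtures: small synthetic study objects built at test time."""

from __future__ import annotations

import pytest

from sagescape import synthetic_data as syn


@pytest.fixture(scope="session")
def transcripts():
    """Small anchored transcriptome (40 genes, a few splice variants)."""
    return syn.generate_transcriptome(
        n_genes=40, variants_per_gene_rate=0.3, mean_len=300,
        frac_without_anchor=0.0, seed=11)


@pytest.fixture(scope="session")
def design():
    return syn.generate_design()


@pytest.fixture(scope="session")
def null_counts(transcripts, design):
    """NB counts with no effects (null data for the 24-library design)."""
    counts, truth = syn.simulate_counts(
        transcripts, design, baseline_mean=30.0, dispersion=0.2,
        effects=[], seed=7)
    return counts, truth
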
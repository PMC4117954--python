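"""Shared fixtures: small synthetic datasets and constructed domain objects."""

from __future__ import annotations

import pytest

from syntepoch.io_formats import GeneModel
from syntepoch.simulate import SimulationConfig, simulate_dataset
from syntepoch.synteny import SyntenicSegment


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated dataset without CDS (fast; ground truth attached)."""
    config = SimulationConfig(n_ancestral_genes=600, emit_cds=False, rng_seed=7)
    return simulate_dataset(config)


@pytest.fixture(scope="session")
def cds_dataset():
    """A tiny simulated dataset with short CDS for divergence-path tests."""
    config = SimulationConfig(n_ancestral_genes=200, cds_codons=60, rng_seed=11)
    return simulate_dataset(config)


def make_genes(n: int, chrom: str = "chr1", species: str = "test",
               spacing: int = 1000, length: int = 500,
               prefix: str = "g") -> list[GeneModel]:
    """n genes in rank order on one chromosome."""
    return [
        GeneModel(f"{prefix}{i}", chrom, i * spacing, i * spacing + length,
                  "+", i, species)
        for i in range(n)
    ]


def make_segment(members, segment_id: str = "seg1", epoch: str | None = None,
                 qchrom: str = "chr1", schrom: str = "chrA",
                 mean_ks: float | None = None, sd_ks: float | None = None,
                 orientation: str = "same") -> SyntenicSegment:
    return SyntenicSegment(
        segment_id=segment_id,
        query_chromosome=qchrom,
        subject_chromosome=schrom,
        orientation=orientation,
        members=list(members),
        query_span=(0, 1000),
        subject_span=(0, 1000),
        mean_ks=mean_ks,
        sd_ks=sd_ks,
        epoch=epoch,
    )
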
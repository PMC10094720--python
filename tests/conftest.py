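"""Shared fixtures: toy tRNA genes and a small synthetic dataset."""

from __future__ import annotations

import numpy as np
import pytest

from tsrnakit.reference import Interval, TRNAGene, build_mature, build_precursor
from tsrnakit.simulate import SimConfig, make_fragments, make_genes


def toy_gene(
    gene_id: str = "tRNA-Trp-CCA-1-1",
    amino_acid: str = "Trp",
    anticodon: str = "CCA",
    body_len: int = 73,
    anticodon_start: int = 33,
    leader: str = "A" * 10,
    trailer: str = "AGCTAGCTAGCTAGCTAG" + "TTTTTT" + "CAGCA",
    intron: Interval | None = None,
    seed: int = 7,
) -> TRNAGene:
    """Deterministic random gene with the anticodon planted on the mature body."""
    rng = np.random.default_rng(seed)
    body = list("ACGT"[i] for i in rng.integers(0, 4, size=body_len))
    if intron is not None:
        mature = body[: intron.start] + body[intron.end :]
        mature[anticodon_start : anticodon_start + 3] = list(anticodon)
        body = (
            mature[: intron.start]
            + body[intron.start : intron.end]
            + mature[intron.start :]
        )
    else:
        body[anticodon_start : anticodon_start + 3] = list(anticodon)
    gene = TRNAGene(
        gene_id=gene_id,
        amino_acid=amino_acid,
        anticodon=anticodon,
        body_seq="".join(body),
        anticodon_start=anticodon_start,
        chromosome="2R",
        strand="+",
        intron_span=intron,
        leader_seq=leader,
        trailer_seq=trailer,
    )
    gene.validate()
    return gene


@pytest.fixture
def gene():
    return toy_gene()


@pytest.fixture
def mature(gene):
    return build_mature(gene)


@pytest.fixture
def precursor(gene):
    return build_precursor(gene)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale noiseless experiment for fast end-to-end tests."""
    return SimConfig(
        n_genes=8,
        n_fragments=60,
        replicates=2,
        nb_mean=8.0,
        seed=11,
        noise_rate=0.0,
    )


@pytest.fixture(scope="session")
def small_genes(small_config):
    return make_genes(small_config)


@pytest.fixture(scope="session")
def small_truth(small_config, small_genes):
    rng = np.random.default_rng(small_config.seed)
    genes = make_genes(small_config, rng)
    return make_fragments(genes, small_config, rng)
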
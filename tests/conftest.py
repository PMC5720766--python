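import numpy as np
import pytest

from epicompress import SyntheticWorld, WorldConfig


@pytest.fixture(scope="session")
def small_world():
    """120-gene, 6-mark single-cell-line world for fast structural tests."""
    return SyntheticWorld(
        WorldConfig.imputation_world(
            n_genes=120, n_marks=6, seed=42, genes_per_chrom=50
        )
    )


@pytest.fixture(scope="session")
def small_matrix(small_world):
    return small_world.enrichment_matrix("cellA")


@pytest.fixture(scope="session")
def world_files(tmp_path_factory):
    """A small written world with methylation, FASTA, blacklist and CAGE."""
    import dataclasses

    from epicompress import MarkSpec, generate_world

    cfg = WorldConfig.imputation_world(
        n_genes=120, n_marks=6, seed=11, genes_per_chrom=50,
        include_methylation=True,
    )
    marks = list(cfg.marks[:-1]) + [
        MarkSpec("DNAme", "epigenetic_mark", "shared", is_methylation=True)
    ]
    cfg = dataclasses.replace(cfg, marks=marks)
    outdir = tmp_path_factory.mktemp("world")
    paths, world = generate_world(cfg, outdir, emit_fasta=True)
    return paths, world


def rng_for(test_seed: int) -> np.random.Generator:
    return np.random.default_rng(test_seed)
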
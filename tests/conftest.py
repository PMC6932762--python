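import numpy as np
import pytest

from nitrna.reference import Origin, TRNAGene, TRNAReference
from nitrna.simulate import SimulationConfig, simulate_reference


def build_gene(
    t_loop_seq: str,
    gene_id: str = "toy1",
    isodecoder: str = "LysCTT",
    origin: Origin = Origin.NUCLEAR,
    rng_seed: int = 0,
) -> TRNAGene:
    """A structurally valid gene whose T-loop subsequence is chosen freely.

    Layout (0-based): D-loop [14, 23), anticodon loop [33, 40),
    T-loop [52, 52 + len(t_loop_seq)), CCA tail.
    """
    rng = np.random.default_rng(rng_seed)

    def rand(n):
        return "".join(rng.choice(list("ACGT"), size=n))

    seq = (
        rand(14) + rand(9) + rand(10) + rand(7) + rand(12)
        + t_loop_seq + rand(8) + "CCA"
    )
    return TRNAGene(
        gene_id=gene_id,
        isodecoder=isodecoder,
        origin=origin,
        sequence=seq,
        d_loop=(14, 23),
        anticodon_loop=(33, 40),
        t_loop=(52, 52 + len(t_loop_seq)),
    )


@pytest.fixture
def toy_reference() -> TRNAReference:
    """Three genes (two nuclear, one mitochondrial) with distinct T-loops."""
    return TRNAReference(
        genes=(
            build_gene("TTCGAATC", gene_id="nucA", rng_seed=1),
            build_gene("GGATCAA", gene_id="nucB", isodecoder="GlyGCC", rng_seed=2),
            build_gene(
                "GGGGGGG", gene_id="mitoC", isodecoder="MT_SerTGA",
                origin=Origin.MITOCHONDRIAL, rng_seed=3,
            ),
        )
    )


@pytest.fixture
def sim_reference() -> TRNAReference:
    return simulate_reference(SimulationConfig(seed=7))


@pytest.fixture
def small_config() -> SimulationConfig:
    """Desk-scale read-level settings for FASTQ round trips."""
    return SimulationConfig(
        n_nuclear_genes=4, n_mito_genes=2, n_participants=4,
        library_size=2_000, baseline_mean=5_000.0, seed=11,
    )
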
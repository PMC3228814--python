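import pytest

from pyroprof import (ReferenceSequence, SimulationConfig, generate_reference,
                      simulate_reads)

# 60-nt stop-free framework fragments carrying the two tabulated homopolymer
# motifs: a 2-G run in AGGC (an extra G makes "3G in place of 2") and a 4-G
# run in AGGGGC (one G fewer makes "3G in place of 4").
WORKED_SEQ_GG = "CGGCTGATGGGGAGTCGACCAGGCTTAATATCTCCGAGGTTGCCCTCACAAATGGCGATG"
WORKED_SEQ_GGGG = "TACGCCACACGGGCTACACTAGGGGCTTCTCGTCGCAACTACGAGCTGGACTATCGGCCG"


@pytest.fixture(scope="session")
def ref330():
    """Default 330-nt antibody-like reference (six regions, polyG hotspots)."""
    ref = generate_reference(seed=1)
    ref.validate()
    return ref


@pytest.fixture(scope="session")
def worked_ref_gg():
    ref = ReferenceSequence(id="wk_gg", seq=WORKED_SEQ_GG,
                            regions={"FR1": (0, 60)})
    ref.validate()
    return ref


@pytest.fixture(scope="session")
def worked_ref_gggg():
    ref = ReferenceSequence(id="wk_gggg", seq=WORKED_SEQ_GGGG,
                            regions={"FR1": (0, 60)})
    ref.validate()
    return ref


@pytest.fixture(scope="session")
def small_batch(ref330):
    """300 simulated reads with truth, shared across modules."""
    cfg = SimulationConfig(n_reads=300, seed=11)
    reads, truth = simulate_reads(ref330, cfg)
    return reads, truth
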
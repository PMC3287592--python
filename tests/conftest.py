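import numpy as np
import pytest

from tispred import MrnaRecord, SimSpec, WindowSpec, filter_records, simulate


@pytest.fixture(scope="session")
def window() -> WindowSpec:
    return WindowSpec(upstream=10, downstream=30)


@pytest.fixture(scope="session")
def sim_bundle(window):
    """A small simulated dataset shared across tests (read-only)."""
    records, truth = simulate(SimSpec(n_molecules=40, seed=3))
    kept, report = filter_records(records, window)
    return {"records": records, "truth": truth, "kept": kept, "report": report}


@pytest.fixture()
def toy_record() -> MrnaRecord:
    # 5'UTR of 12 nt, short ORF, decoy ATGs up- and downstream
    #            0-based:  TIS at index 12 (pos 13)
    seq = "GCATGCCCCACC" + "ATG" + "GCCAAAGAAATGCCC" + "TAA" + "GGGTTTCCC"
    return MrnaRecord(id="toy", sequence=seq, tis_pos=13)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_record(rng: np.random.Generator, length: int = 200) -> MrnaRecord:
    """Random sequence with an ATG forced somewhere in the middle as the TIS."""
    seq = list(rng.choice(list("ACGT"), size=length))
    tis0 = int(rng.integers(3, length - 5))
    seq[tis0 : tis0 + 3] = list("ATG")
    return MrnaRecord(id="rand", sequence="".join(seq), tis_pos=tis0 + 1)
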
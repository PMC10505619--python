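import numpy as np
import pytest

from adaptscan.io_formats import Alignment, SeqRecord


@pytest.fixture
def small_protein_alignment():
    return Alignment(
        [
            SeqRecord("FOCAL", "MKTWCDE"),
            SeqRecord("S01", "MRTWCDE"),
            SeqRecord("S02", "MRTWCDE"),
            SeqRecord("S03", "MRTWCDE"),
        ],
        "protein",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory):
    """The default planted cohort (seed 42), generated once per session."""
    from adaptscan.synthetic_data import CohortSpec, simulate_cohort

    out = tmp_path_factory.mktemp("cohort") / "fixture"
    simulate_cohort(out, CohortSpec(seed=42))
    return out
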
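import numpy as np
import pytest

from rbrid import (
    Condition,
    ExperimentDesign,
    PeptideRecord,
    ProteinSequence,
    RunInfo,
)


@pytest.fixture
def design_2x2() -> ExperimentDesign:
    """Minimal balanced design: 2 crosslinked + 2 control runs, one batch."""
    return ExperimentDesign(
        [
            RunInfo("p1", Condition.CROSSLINKED, 1, "b1"),
            RunInfo("p2", Condition.CROSSLINKED, 2, "b1"),
            RunInfo("m1", Condition.CONTROL, 1, "b1"),
            RunInfo("m2", Condition.CONTROL, 2, "b1"),
        ]
    )


@pytest.fixture
def design_3x3() -> ExperimentDesign:
    return ExperimentDesign(
        [RunInfo(f"p{i}", Condition.CROSSLINKED, i, "b1") for i in (1, 2, 3)]
        + [RunInfo(f"m{i}", Condition.CONTROL, i, "b1") for i in (1, 2, 3)]
    )


def make_record(seq: str, intensities: dict[str, float], proteins=("P1",)) -> PeptideRecord:
    return PeptideRecord(seq, list(proteins), dict(intensities))


@pytest.fixture
def generic_table(tmp_path):
    """3-row generic TSV with runs r1, r2."""
    path = tmp_path / "peptides.tsv"
    path.write_text(
        "peptide\tprotein\tr1\tr2\n"
        "MTAEPK\tP46100\t2\t3\n"
        "LSDFER\tP46100\t5\t\n"
        "GGGHIK\tCON__K1\t1\t1\n"
    )
    return path


@pytest.fixture
def protein_small() -> ProteinSequence:
    return ProteinSequence("P1", "MPEPKRAAAA")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
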
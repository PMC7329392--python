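import numpy as np
import pytest

from kepmine.io_formats import ProteinRecord, SignalPrediction
from kepmine.params import PipelineParams

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def params() -> PipelineParams:
    return PipelineParams()


def random_protein_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(AA20[i] for i in rng.integers(0, 20, size=length))


def toy_kep(
    unit: str = "YAIGSTVN",
    k: int = 4,
    tail: str = "GD",
    leader: str = "DGEANQHW",
) -> tuple[str, str]:
    """(signal, mature) for a hand-traceable precursor: a non-repeat leader
    (pro-region), then k copies of ``unit`` each preceded by KR, plus a
    short tail. The leader and tail flank the repeat-masked region so the
    mature sequence splits into more than 2 parts."""
    signal = "MKLLVVLLLAFSDA"
    mature = leader + "".join("KR" + unit for _ in range(k)) + "KR" + tail
    return signal, mature


@pytest.fixture
def toy_kep_protein() -> tuple[ProteinRecord, SignalPrediction]:
    signal, mature = toy_kep()
    rec = ProteinRecord("toy1", signal + mature)
    pred = SignalPrediction("toy1", True, len(signal))
    return rec, pred
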
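import numpy as np
import pytest

from xenomir.config import PipelineConfig, METASTATIC, NON_METASTATIC
from xenomir.io import FIVE_PRIME, THREE_PRIME, HairpinReference, MatureAnnotation


@pytest.fixture
def config() -> PipelineConfig:
    return PipelineConfig()


def make_hairpin_80(rng_or_seq=None) -> str:
    """An 80-nt hairpin with exact arm spans [10, 32) and [48, 70)."""
    rng = np.random.default_rng(7)
    bases = "ACGT"
    flank5 = "".join(bases[i] for i in rng.integers(0, 4, 10))
    arm5 = "".join(bases[i] for i in rng.integers(0, 4, 22))
    loop = "".join("AC"[i] for i in rng.integers(0, 2, 16))
    comp = str.maketrans("ACGT", "TGCA")
    arm3 = arm5.translate(comp)[::-1]
    flank3 = "".join(bases[i] for i in rng.integers(0, 4, 10))
    seq = flank5 + arm5 + loop + arm3 + flank3
    assert len(seq) == 80
    return seq


@pytest.fixture
def two_mature_hairpin() -> HairpinReference:
    """One 80-nt hairpin with both arms annotated ([10,32) and [48,70))."""
    seq = make_hairpin_80()
    matures = [
        MatureAnnotation("miR-A", "hp-1", 10, 32, FIVE_PRIME),
        MatureAnnotation("miR-A*", "hp-1", 48, 70, THREE_PRIME),
    ]
    return HairpinReference(records={"hp-1": seq}, matures={"hp-1": matures})


@pytest.fixture
def single_mature_hairpin() -> HairpinReference:
    seq = make_hairpin_80()
    matures = [MatureAnnotation("miR-B", "hp-2", 10, 32, FIVE_PRIME)]
    return HairpinReference(records={"hp-2": seq}, matures={"hp-2": matures})


def counts(met: int, nonmet: int) -> dict[str, int]:
    return {METASTATIC: met, NON_METASTATIC: nonmet}
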
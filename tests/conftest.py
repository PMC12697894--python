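import numpy as np
import pytest

from solenopsim.genetics import (
    DriveConfig,
    DriveVariant,
    FertilityAllele,
    Genome,
    Ploidy,
    SocialAllele,
)

W, D, R = FertilityAllele.WILD, FertilityAllele.DRIVE, FertilityAllele.RES_NONFUNC
SB, Sb = SocialAllele.SB, SocialAllele.Sb


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def default_cfg():
    return DriveConfig()


def diploid(f1, f2, s1=SB, s2=SB, ds=None):
    return Genome(
        Ploidy.DIPLOID, (f1, f2), (s1, s2),
        tuple(ds) if ds is not None else (),
    )


def haploid(f, s=SB, d=None):
    return Genome(Ploidy.HAPLOID, (f,), (s,), (d,) if d is not None else ())
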
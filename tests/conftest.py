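import numpy as np
import pandas as pd
import pytest

from hazdiff import AdditiveHazardSCM, BHNModifier, CopulaSpec, GammaFrailty, ShiftedGammaModifier


@pytest.fixture
def case_bhn():
    """The case-study Benefit/Harm/Neutral modifier: half benefit (-0.1), half harm (+0.4)."""
    return BHNModifier(p1=0.5, mu1=-0.1, p2=0.5, mu2=0.4)


@pytest.fixture
def case_scm(case_bhn):
    """Constant-baseline RCT model carrying the case-study modifier."""
    return AdditiveHazardSCM(
        frailty=GammaFrailty(1.0, 1.0),
        modifier=case_bhn,
        baseline_family="constant",
        ell=0.2,
    )


def quadratic_scm(tau: float = 0.0, ell: float = 0.0) -> AdditiveHazardSCM:
    """The tau-grid simulation setting: f0 = ell + U0 t^2, U0 ~ Gamma(1,1),
    U1 + ell ~ Gamma(1,1), Gaussian copula with Kendall tau."""
    return AdditiveHazardSCM(
        frailty=GammaFrailty(1.0, 1.0),
        modifier=ShiftedGammaModifier(1.0, 1.0, shift=ell),
        baseline_family="quadratic",
        ell=ell,
        copula=CopulaSpec(kendall_tau=tau),
    )


@pytest.fixture
def toy_dataset():
    """Four subjects: exposed events at t=1 and 3, unexposed event at t=2,
    unexposed censored at t=4."""
    return pd.DataFrame(
        {
            "id": [0, 1, 2, 3],
            "time": [1.0, 3.0, 2.0, 4.0],
            "status": [1, 1, 1, 0],
            "exposure": [1, 1, 0, 0],
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
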
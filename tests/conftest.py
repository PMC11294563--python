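import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from dimercoop import cortex_quant as cq
from dimercoop.thermo import ModelParams

KD_MEM_WT = 10 ** -2.43


@pytest.fixture
def wt_params() -> ModelParams:
    """Fitted wild-type regime: kd_dim 425 nM, kd_mem 10^-2.43."""
    return ModelParams(kd_dim=425e-9, kd_mem=KD_MEM_WT, c_tot=27e-9)


@pytest.fixture
def truth_profiles() -> cq.SignalProfiles:
    """Ground-truth signal profiles deliberately different from the
    training initializers (shifted centre, wider step, asymmetric peak)."""
    H = 50
    s_mem = (0.9 * cq.default_mem_profile(H, center=24.5, sigma=3.0)
             + 0.25 * cq.default_mem_profile(H, center=30.0, sigma=5.0))
    return cq.SignalProfiles(
        s_cyt=cq.default_cyt_profile(H, center=26.0, width=3.5),
        s_mem=s_mem / s_mem.max(),
        provenance={"source": "synthetic truth"})
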
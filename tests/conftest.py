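import numpy as np
import pytest

from recland import ChromosomeSpec, GCParams, MarkerPanel


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def default_gc():
    """Genome-wide gene-conversion model (gamma 1.25e-7/bp, L_GC 518 bp)."""
    return GCParams.from_mean_length(gamma=1.25e-7, l_gc=518.0)


@pytest.fixture
def small_arm():
    return ChromosomeSpec(arm_id="2L", length_bp=2_000_000, map_length_cM=5.0)


@pytest.fixture
def regular_panel(small_arm):
    """Evenly spaced 2-kb panel on the small arm (deterministic)."""
    return MarkerPanel(arm_id=small_arm.arm_id,
                       positions=np.arange(1_000, small_arm.length_bp, 2_000))
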
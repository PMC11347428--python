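import numpy as np
import pytest

from medimr import sumstats


def make_harmonized(bx, sx, by, sy, outcome_type="binary", names=None):
    """Assemble a HarmonizedSet directly from effect arrays (test helper)."""
    bx = np.asarray(bx, float)
    j = bx.shape[0]
    return sumstats.HarmonizedSet(
        exposure_names=names or ["exposure"],
        outcome_name="outcome",
        snp_ids=np.array([f"rs{i + 1}" for i in range(j)]),
        b_exp=bx, se_exp=np.asarray(sx, float),
        b_out=np.asarray(by, float), se_out=np.asarray(sy, float),
        eaf=np.full(j, 0.3), outcome_type=outcome_type,
    )


@pytest.fixture
def random_harmonized():
    """10 instruments from a homogeneous causal model theta = 0.4 plus noise."""
    rng = np.random.default_rng(42)
    j = 10
    bx = rng.normal(0.1, 0.03, j)
    sx = np.full(j, 0.004)
    sy = rng.uniform(0.008, 0.02, j)
    by = 0.4 * bx + rng.normal(0, sy)
    return make_harmonized(bx, sx, by, sy)
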
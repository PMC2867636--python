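import numpy as np
import pytest

from llapc import AgeGrid, CohortLayout, IncidenceGrid, PeriodGrid
from llapc.effects import EffectEstimates
from llapc.simulate import TruthSpec, reference_hazard_curves


@pytest.fixture(scope="session")
def men_curves():
    return reference_hazard_curves("men")


@pytest.fixture(scope="session")
def women_curves():
    return reference_hazard_curves("women")


def make_grid(v, u, h, ages=None, periods=None, layout=None, cv_se=0.02,
              count=1000, category=0):
    """Noise-free multiplicative grid with oracle SEs (cv_se x clean rate)."""
    v = np.asarray(v, dtype=float)
    u = np.asarray(u, dtype=float)
    h = np.asarray(h, dtype=float)
    if ages is None:
        ages = AgeGrid(h.size, 2.5 + 5.0 * np.arange(h.size),
                       tuple(str(i) for i in range(h.size)), usable_from=1)
    if periods is None:
        periods = PeriodGrid(v.size, tuple(str(j) for j in range(v.size)))
    if layout is None:
        layout = CohortLayout.from_grids(ages, periods)
    n, m = ages.n_age, periods.m_periods
    rate = np.full((n, m), np.nan)
    se = np.full((n, m), np.nan)
    cnt = np.full((n, m), np.nan)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            l = j - i + layout.offset
            if not 1 <= l <= layout.k_cohorts:
                continue
            rate[i - 1, j - 1] = v[j - 1] * u[l - 1] * h[i - 1]
            se[i - 1, j - 1] = cv_se * rate[i - 1, j - 1]
            cnt[i - 1, j - 1] = count
    return IncidenceGrid(ages, periods, layout, rate, se, cnt, category=category)


@pytest.fixture
def exact_standard_effects():
    """Exact anchored coefficients for TruthSpec.standard defaults."""
    spec = TruthSpec.standard()
    v = spec.v_true / spec.v_true[5]
    u = spec.u_true / spec.u_true[7]
    eff = EffectEstimates(v, np.zeros(6), u, np.zeros(16), 6, 8,
                          provenance="supplied")
    scale = spec.v_true[5] * spec.u_true[7]
    return eff, scale
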
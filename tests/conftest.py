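import numpy as np
import pytest

import gaitwalk as gw


def brute_force_dtw(a, b, local_cost="abs"):
    """Independent DTW oracle: enumerate every admissible warping path.

    Recursively walks all monotone, continuous, boundary-respecting
    paths from (0, 0) to (n-1, m-1) and returns the minimum summed local
    cost.  Exponential — only for short series.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)

    def cost(i, j):
        d = a[i] - b[j]
        return d * d if local_cost == "squared" else abs(d)

    n, m = a.size, b.size
    best = [np.inf]

    def walk(i, j, acc):
        acc += cost(i, j)
        if i == n - 1 and j == m - 1:
            best[0] = min(best[0], acc)
            return
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, acc)
        if i + 1 < n:
            walk(i + 1, j, acc)
        if j + 1 < m:
            walk(i, j + 1, acc)

    walk(0, 0, 0.0)
    return best[0]


@pytest.fixture(scope="session")
def tiny_spec():
    """A miniature cohort: 1 participant per age group, short walks."""
    return gw.CohortSpec(n_per_group=1, walk_scale=0.03, seed=7)


@pytest.fixture(scope="session")
def scaled_spec():
    """The runtime-scaled study design used for recovery checks."""
    return gw.CohortSpec.runtime_scaled(seed=11)


@pytest.fixture(scope="session")
def sim_recording(scaled_spec):
    profile = gw.DEFAULT_PROFILES["cement"]
    return gw.simulate_recording(profile, "40-50", scaled_spec, participant_seed=5,
                                 participant_id="P005")


@pytest.fixture(scope="session")
def sim_cycles(sim_recording):
    series = gw.normalize_svm(gw.filter_svm(gw.svm_series(sim_recording)))
    return gw.segment_cycles(series, sim_recording)
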
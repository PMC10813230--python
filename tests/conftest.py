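import numpy as np
import pytest
from hypothesis import settings

from dynhubs.hubs import HubActivity
from dynhubs.regions import RegionTable

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def table4():
    """Four regions in two RSNs ({1,2} SMN, {3,4} DMN)."""
    return RegionTable(
        region_index=np.arange(1, 5),
        region_name=("SMN.01", "SMN.02", "DMN.01", "DMN.02"),
        rsn=("SMN", "SMN", "DMN", "DMN"),
    )


def make_activity(n_regions, t_total, active):
    """Build a HubActivity from {node: iterable of active time points}."""
    act = np.zeros((n_regions, t_total), dtype=np.uint8)
    for node, times in active.items():
        act[node, list(times)] = 1
    candidates = tuple(sorted(active))
    return HubActivity(
        candidates=candidates,
        th2={c: 0.0 for c in candidates},
        activity=act,
    )


@pytest.fixture
def activity_factory():
    return make_activity
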
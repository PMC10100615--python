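from __future__ import annotations

import numpy as np
import pytest

from egoprl.egonet import Alter, EgoNetwork
from egoprl.prl_task import ScheduleConfig, TaskSession, build_schedule


@pytest.fixture(scope="session")
def default_schedule():
    return build_schedule(ScheduleConfig())


@pytest.fixture
def fixture_sessions():
    """Five-trial sessions with fixed choices/outcomes for filter checks."""
    runs = [
        ([1, 2, 3, 1, 2], [1, 0, 1, 1, 0]),
        ([1, 1, 1, 1, 1], [1, 1, 0, 1, 1]),
        ([3, 3, 2, 1, 1], [0, 0, 0, 1, 0]),
        ([2, 1, 2, 3, 3], [1, 1, 1, 0, 1]),
    ]
    return [TaskSession(ego_id=f"fx{i}", frame="social",
                        choices=np.array(c), outcomes=np.array(o))
            for i, (c, o) in enumerate(runs)]


def make_network(n_alters, edges=(), ties=None, kinships=None, items=None,
                 ego_id="ego"):
    """Convenience constructor; edges index alters from 0."""
    ties = ties or ["strong"] * n_alters
    kinships = kinships or ["friend"] * n_alters
    items = items or [(3, 3, 3, 3, 3)] * n_alters
    alters = [Alter(alter_id=f"a{j}", tie=ties[j], kinship=kinships[j],
                    items=tuple(items[j])) for j in range(n_alters)]
    alter_alter = {frozenset((f"a{u}", f"a{v}")): "strong" for u, v in edges}
    return EgoNetwork(ego_id=ego_id, alters=alters, alter_alter=alter_alter)


@pytest.fixture
def triangle_network():
    return make_network(2, edges=[(0, 1)])
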
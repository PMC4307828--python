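import numpy as np
import pytest

from gamenet import ActorRoster, InteractionLog, InteractionRecord


def make_log(rows):
    """Build a log from (time, scenario, sender, receiver, count) tuples."""
    return InteractionLog(InteractionRecord(*row) for row in rows)


def random_log(rng, roster, n_records, scenarios=("s1",), max_time=9, max_count=4):
    """Random valid interaction log over a roster (self-exchanges excluded)."""
    ids = roster.actor_ids
    rows = []
    for _ in range(n_records):
        i, j = rng.choice(len(ids), size=2, replace=False)
        rows.append(
            InteractionRecord(
                time=int(rng.integers(0, max_time + 1)),
                scenario=str(rng.choice(scenarios)),
                sender=ids[i],
                receiver=ids[j],
                count=int(rng.integers(1, max_count + 1)),
            )
        )
    rows.sort(key=lambda r: r.time)
    return InteractionLog(rows)


def roster_of(n, focal=None):
    """n actors named p1..pn with roles cycling through the default six."""
    from gamenet import DEFAULT_ROLES

    ids = tuple(f"p{i}" for i in range(1, n + 1))
    roles = tuple(DEFAULT_ROLES[i % len(DEFAULT_ROLES)] for i in range(n))
    return ActorRoster(ids, roles, focal=focal)


@pytest.fixture
def four_roster():
    return ActorRoster(
        ("focal", "b", "c", "d"),
        ("federal_government", "state_government", "hospital", "patient"),
        focal="focal",
    )


@pytest.fixture
def ten_roster():
    return roster_of(10)


@pytest.fixture
def rng():
    return np.random.default_rng(20140128)
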
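"""Pair distributions, Shannon entropy, DIV and role-pair aggregation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gamenet import (
    GameNetError,
    SilentNetworkError,
    TieMatrix,
    build_tie_matrix,
    network_diversity,
    pair_distribution,
    role_pair_counts,
    shannon_entropy,
)
from .conftest import make_log, random_log, roster_of


def entropy_oracle(probs):
    """Independent brute-force summation, term by term."""
    total = 0.0
    for p in probs:
        if p > 0:
            total -= p * math.log(p)
    return total


def ten_actor_matrix(weights_by_pair):
    """Undirected 10-actor matrix from {(i, j): weight}."""
    w = np.zeros((10, 10), dtype=int)
    for (i, j), c in weights_by_pair.items():
        w[i, j] = w[j, i] = c
    return TieMatrix(tuple(f"p{i}" for i in range(10)), w, directed=False)


class TestPairDistribution:
    def test_concentrated_pair_distribution(self):
        m = ten_actor_matrix({(0, 1): 10})
        dist = pair_distribution(m)
        assert len(dist.pairs) == 45
        assert dist.total_weight == 10
        probs = sorted(dist.probs, reverse=True)
        assert probs[0] == 1.0 and all(p == 0.0 for p in probs[1:])

    def test_uniform_pair_distribution(self):
        m = ten_actor_matrix({(i, j): 1 for i in range(10) for j in range(i + 1, 10)})
        dist = pair_distribution(m)
        assert np.allclose(dist.probs, 1 / 45)

    def test_silent_network_is_an_error(self):
        with pytest.raises(SilentNetworkError, match="no interactions"):
            pair_distribution(ten_actor_matrix({}))

    @settings(max_examples=60, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_probabilities_conserve_to_one(self, seed):
        rng = np.random.default_rng(seed)
        roster = roster_of(int(rng.integers(3, 9)))
        log = random_log(rng, roster, n_records=int(rng.integers(1, 30)))
        dist = pair_distribution(build_tie_matrix(log, roster))
        assert abs(dist.probs.sum() - 1.0) < 1e-12


class TestShannonEntropy:
    @pytest.mark.parametrize(
        "probs,expected",
        [
            ([1.0, 0.0, 0.0], 0.0),
            ([0.5, 0.5, 0.0], math.log(2)),
            ([1 / 45] * 45, math.log(45)),
        ],
    )
    def test_closed_forms(self, probs, expected):
        assert shannon_entropy(np.array(probs)) == pytest.approx(expected, abs=1e-12)

    def test_rejects_non_distribution(self):
        with pytest.raises(GameNetError, match="sum"):
            shannon_entropy(np.array([0.5, 0.4]))

    def test_agrees_with_brute_force_oracle(self, rng):
        for _ in range(300):
            k = int(rng.integers(2, 60))
            p = rng.dirichlet(np.full(k, float(rng.uniform(0.05, 5.0))))
            assert shannon_entropy(p) == pytest.approx(entropy_oracle(p), abs=1e-12)

    def test_base_argument_rescales(self):
        p = np.array([0.2, 0.3, 0.5])
        assert shannon_entropy(p, base=2) == pytest.approx(
            shannon_entropy(p) / math.log(2), abs=1e-12
        )


class TestNetworkDiversity:
    def test_all_exchanges_on_one_pair_gives_zero(self):
        assert network_diversity(ten_actor_matrix({(0, 1): 10})).div == 0.0

    def test_perfectly_even_network_gives_one(self):
        m = ten_actor_matrix({(i, j): 1 for i in range(10) for j in range(i + 1, 10)})
        assert network_diversity(m).div == pytest.approx(1.0, abs=1e-12)

    def test_ten_exchanges_over_ten_pairs(self):
        pairs = [(i, j) for i in range(10) for j in range(i + 1, 10)][:10]
        m = ten_actor_matrix({p: 1 for p in pairs})
        res = network_diversity(m)
        assert res.div == pytest.approx(math.log(10) / math.log(45), abs=1e-12)
        assert res.entropy == pytest.approx(math.log(10), abs=1e-12)
        assert res.max_entropy == pytest.approx(math.log(45), abs=1e-12)

    def test_single_possible_pair_is_undefined(self):
        m = TieMatrix(("a", "b"), np.array([[0, 3], [3, 0]]), directed=False)
        with pytest.raises(GameNetError, match="PT"):
            network_diversity(m)

    def test_silent_network_is_an_error(self):
        with pytest.raises(SilentNetworkError):
            network_diversity(ten_actor_matrix({}))

    @settings(max_examples=60, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_div_bounded_and_invariant(self, seed):
        """DIV in [0, 1]; unchanged by relabeling and by scaling all weights."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        roster = roster_of(n)
        log = random_log(rng, roster, n_records=int(rng.integers(1, 30)))
        m = build_tie_matrix(log, roster)
        div = network_diversity(m).div
        assert 0.0 <= div <= 1.0
        scaled = TieMatrix(m.actors, m.weights * 7, directed=False)
        assert network_diversity(scaled).div == pytest.approx(div, abs=1e-12)
        perm = rng.permutation(n)
        relabeled = TieMatrix(
            tuple(m.actors[i] for i in perm),
            m.weights[np.ix_(perm, perm)],
            directed=False,
        )
        assert network_diversity(relabeled).div == pytest.approx(div, abs=1e-12)

    def test_base_invariance_of_div(self):
        """DIV is a ratio of entropies, so the log base cancels."""
        pairs = {(0, 1): 5, (2, 3): 2, (4, 5): 1}
        m = ten_actor_matrix(pairs)
        dist = pair_distribution(m)
        div_nats = shannon_entropy(dist) / math.log(45)
        div_bits = shannon_entropy(dist, base=2) / (math.log(45) / math.log(2))
        assert div_nats == pytest.approx(div_bits, abs=1e-12)
        assert network_diversity(m).div == pytest.approx(div_nats, abs=1e-12)

    def test_evening_transfer_never_decreases_entropy(self, rng):
        """Moving one exchange from a heavier to a strictly lighter pair."""
        for _ in range(200):
            k = int(rng.integers(3, 30))
            counts = rng.integers(0, 20, size=k)
            if counts.sum() == 0:
                counts[0] = 5
            heavy = int(np.argmax(counts))
            lighter = np.flatnonzero(counts < counts[heavy])
            if len(lighter) == 0:
                continue
            light = int(rng.choice(lighter))
            before = entropy_oracle(counts / counts.sum())
            moved = counts.copy()
            moved[heavy] -= 1
            moved[light] += 1
            after = entropy_oracle(moved / moved.sum())
            assert after >= before - 1e-12


class TestRolePairCounts:
    def test_cross_role_aggregation(self, four_roster):
        log = make_log(
            [(0, "s1", "focal", "b", 3), (0, "s1", "c", "d", 2)]
        )
        rp = role_pair_counts(log, four_roster)
        i = rp.roles.index("federal_government")
        j = rp.roles.index("state_government")
        assert rp.counts[i, j] == rp.counts[j, i] == 3
        k, l = rp.roles.index("hospital"), rp.roles.index("patient")
        assert rp.counts[k, l] == 2
        assert rp.grand_total() == 5

    def test_scenario_filter_selects_one_record(self, four_roster):
        log = make_log([(0, "s1", "focal", "b", 3), (1, "s2", "c", "d", 2)])
        rp = role_pair_counts(log, four_roster, scenario="s1")
        assert rp.grand_total() == 3

    def test_unknown_scenario_lists_known(self, four_roster):
        log = make_log([(0, "s1", "focal", "b", 1)])
        with pytest.raises(GameNetError, match="s1"):
            role_pair_counts(log, four_roster, scenario="nope")

    def test_empty_log_gives_zero_matrix(self, four_roster):
        rp = role_pair_counts(make_log([]), four_roster)
        assert not rp.counts.any()

    def test_within_role_pairs_on_diagonal(self):
        roster = roster_of(2)  # p1, p2 share no role
        from gamenet import ActorRoster

        roster = ActorRoster(("p1", "p2"), ("patient", "patient"))
        log = make_log([(0, "s1", "p1", "p2", 4)])
        rp = role_pair_counts(log, roster)
        i = rp.roles.index("patient")
        assert rp.counts[i, i] == 4
        assert rp.grand_total() == 4

    def test_grand_total_conserves_log(self, rng):
        roster = roster_of(8)
        log = random_log(rng, roster, 40)
        rp = role_pair_counts(log, roster)
        assert rp.grand_total() == log.total_exchanges()

    def test_csv_export(self, four_roster, tmp_path):
        log = make_log([(0, "s1", "focal", "b", 3)])
        rp = role_pair_counts(log, four_roster)
        out = tmp_path / "rp.csv"
        rp.to_csv(out)
        header = out.read_text().splitlines()[0]
        assert header == "role," + ",".join(rp.roles)
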
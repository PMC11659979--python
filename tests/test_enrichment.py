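import numpy as np
import pandas as pd
import pytest

from ssmutpa.enrichment import (
    DegenerateCellError,
    RankedGeneList,
    ScoringParams,
    rank_genes,
    score_cohort,
    score_sample,
    ssmutpes,
)
from ssmutpa.io import MutationProfile, PathwayCollection
from ssmutpa.network import build_network
from ssmutpa.propagation import GlobalWeightVector

from conftest import random_connected_pairs


def ranked(genes, weights):
    return RankedGeneList(genes=tuple(genes), weights=np.asarray(weights, float))


def position_by_position_oracle(weights, member_mask, p_exp=1.0):
    """Independent oracle: evaluate the running difference at every position."""
    n = len(weights)
    n_miss = n - int(np.sum(member_mask))
    mass = sum(abs(w) ** p_exp for w, m in zip(weights, member_mask) if m)
    best = -np.inf
    for i in range(1, n + 1):
        f_in = sum(abs(weights[j]) ** p_exp for j in range(i) if member_mask[j]) / mass
        f_not = sum(1 for j in range(i) if not member_mask[j]) / n_miss
        best = max(best, f_in - f_not)
    return max(best, 0.0)


class TestRankGenes:
    def make_gw(self, net, per_gene):
        p = np.array([per_gene[g] for g in net.nodes])
        return GlobalWeightVector(p=p, iterations=1, residual=0.0)

    def test_descending_order(self, path_net):
        gw = self.make_gw(path_net, {"A": 0.3, "B": 0.5, "C": 0.2})
        assert rank_genes(gw, path_net).genes == ("B", "A", "C")

    def test_ties_broken_by_symbol(self):
        net = build_network([("G1", "G3"), ("G2", "G3")])
        gw = self.make_gw(net, {"G1": 0.4, "G2": 0.4, "G3": 0.2})
        assert rank_genes(gw, net).genes == ("G1", "G2", "G3")

    def test_invariant_to_edge_insertion_order(self, rng):
        pairs = random_connected_pairs(rng, 20, 0.3)
        net_a, net_b = build_network(pairs), build_network(pairs[::-1])
        p = rng.random(net_a.n_nodes)
        p /= p.sum()
        ra = rank_genes(GlobalWeightVector(p, 1, 0.0), net_a)
        rb = rank_genes(GlobalWeightVector(p, 1, 0.0), net_b)
        assert ra.genes == rb.genes

    def test_weights_unit_sum_nonincreasing(self, path_net):
        gw = self.make_gw(path_net, {"A": 0.3, "B": 0.5, "C": 0.2})
        w = rank_genes(gw, path_net).weights
        assert w.sum() == pytest.approx(1.0)
        assert (np.diff(w) <= 0).all()


class TestSsmutpes:
    def test_singleton_top_scores_one(self):
        r = ranked("abcd", [0.4, 0.3, 0.2, 0.1])
        assert ssmutpes(r, {"a"}) == pytest.approx(1.0)

    def test_singleton_bottom_floors_to_zero(self):
        r = ranked("abcd", [0.4, 0.3, 0.2, 0.1])
        assert ssmutpes(r, {"d"}) == 0.0

    def test_hand_computed_value(self):
        # pathway {a, c}: max at i=1: F_InP = 0.4/0.6, F_NotP = 0 -> 2/3
        r = ranked("abcd", [0.4, 0.3, 0.2, 0.1])
        assert ssmutpes(r, {"a", "c"}) == pytest.approx(2 / 3)

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(60):
            n = int(rng.integers(5, 40))
            w = np.sort(rng.random(n))[::-1]
            w /= w.sum()
            genes = [f"g{i:02d}" for i in range(n)]
            members = rng.choice(n, size=int(rng.integers(1, n)), replace=False)
            mask = np.zeros(n, bool)
            mask[members] = True
            p_exp = float(rng.choice([0.0, 0.5, 1.0, 2.0]))
            ours = ssmutpes(ranked(genes, w), {genes[i] for i in members}, p_exp)
            assert ours == pytest.approx(
                position_by_position_oracle(w, mask, p_exp), abs=1e-12
            )
            assert 0.0 <= ours <= 1.0

    def test_p_exp_zero_is_classical_ks(self, rng):
        # with p=0 the hit increment is 1/|P'| regardless of weights
        n = 30
        w = np.sort(rng.random(n))[::-1]
        w /= w.sum()
        genes = [f"g{i:02d}" for i in range(n)]
        members = set(rng.choice(genes, size=8, replace=False))
        mask = np.array([g in members for g in genes])
        f_in = np.cumsum(mask) / mask.sum()
        f_not = np.cumsum(~mask) / (~mask).sum()
        classical = max(float(np.max(f_in - f_not)), 0.0)
        assert ssmutpes(ranked(genes, w), members, p_exp=0.0) == pytest.approx(classical)

    def test_moving_member_up_never_decreases_score(self, rng):
        n = 25
        w = np.sort(rng.random(n))[::-1]
        w /= w.sum()
        genes = [f"g{i:02d}" for i in range(n)]
        members = set(rng.choice(genes[5:], size=6, replace=False))
        base = ssmutpes(ranked(genes, w), members)
        # swap a member with the non-member directly above it (weights fixed)
        for i in range(1, n):
            if genes[i] in members and genes[i - 1] not in members:
                promoted = (members - {genes[i]}) | {genes[i - 1]}
                assert ssmutpes(ranked(genes, w), promoted) >= base - 1e-12
                break

    def test_degenerate_cells_raise_with_reason(self):
        r = ranked("abc", [0.5, 0.3, 0.2])
        with pytest.raises(DegenerateCellError, match="no pathway genes"):
            ssmutpes(r, {"z"})
        with pytest.raises(DegenerateCellError, match="complement"):
            ssmutpes(r, {"a", "b", "c"})


@pytest.fixture
def small_world(rng):
    net = build_network(random_connected_pairs(rng, 40, 0.15))
    genes = list(net.nodes)
    # one network-clustered pathway (a node plus its neighbors) + two random ones
    hub = max(genes, key=net.degree)
    clustered = frozenset((hub,) + net.neighbors(hub))
    pathways = PathwayCollection(
        {
            "CLUSTERED": clustered,
            "RANDOM1": frozenset(rng.choice(genes, 8, replace=False)),
            "RANDOM2": frozenset(rng.choice(genes, 8, replace=False)),
        }
    )
    return net, pathways


class TestScoreSample:
    def test_no_seeds_gives_zero_column(self, small_world, caplog):
        net, pathways = small_world
        profile = MutationProfile("S1", frozenset({"NOT_IN_NET"}))
        result = score_sample(profile, net, pathways)
        assert result.no_seeds
        assert (result.scores == 0.0).all()

    def test_seeds_equal_to_clustered_pathway_win(self, small_world):
        net, pathways = small_world
        profile = MutationProfile("S1", pathways["CLUSTERED"])
        result = score_sample(profile, net, pathways)
        assert result.scores.idxmax() == "CLUSTERED"

    def test_deterministic(self, small_world):
        net, pathways = small_world
        profile = MutationProfile("S1", frozenset(list(net.nodes)[:6]))
        a = score_sample(profile, net, pathways).scores
        b = score_sample(MutationProfile("S1", profile.genes), net, pathways).scores
        assert (a == b).all()

    def test_scores_in_unit_interval(self, small_world, rng):
        net, pathways = small_world
        genes = [g for g in net.nodes if rng.random() < 0.2] or [net.nodes[0]]
        result = score_sample(MutationProfile("S1", frozenset(genes)), net, pathways)
        assert ((result.scores >= 0) & (result.scores <= 1)).all()


class TestScoreCohort:
    def test_columns_match_individual_calls(self, small_world):
        net, pathways = small_world
        cohort = [
            MutationProfile(f"S{i}", frozenset(list(net.nodes)[i : i + 5]))
            for i in range(3)
        ]
        matrix = score_cohort(cohort, net, pathways)
        for profile in cohort:
            single = score_sample(profile, net, pathways).scores
            assert (matrix.frame[profile.sample_id] == single).all()

    def test_order_permutation(self, small_world):
        net, pathways = small_world
        cohort = [
            MutationProfile(f"S{i}", frozenset(list(net.nodes)[i : i + 5]))
            for i in range(3)
        ]
        a = score_cohort(cohort, net, pathways).frame
        b = score_cohort(cohort[::-1], net, pathways).frame
        assert (a[a.columns] == b[a.columns]).all().all()

    def test_unmapped_sample_zero_column(self, small_world):
        net, pathways = small_world
        cohort = [
            MutationProfile("S1", frozenset(list(net.nodes)[:5])),
            MutationProfile("S2", frozenset({"NOPE"})),
        ]
        matrix = score_cohort(cohort, net, pathways)
        assert matrix.no_seed_samples == ("S2",)
        assert (matrix.frame["S2"] == 0.0).all()

    def test_duplicate_ids_rejected(self, small_world):
        net, pathways = small_world
        profile = MutationProfile("S1", frozenset(list(net.nodes)[:3]))
        with pytest.raises(ValueError, match="duplicate"):
            score_cohort([profile, profile], net, pathways)

    def test_empty_cohort_rejected(self, small_world):
        net, pathways = small_world
        with pytest.raises(ValueError):
            score_cohort([], net, pathways)


def test_scoring_params_validate():
    with pytest.raises(ValueError):
        ScoringParams(alpha=1.0)
    with pytest.raises(ValueError):
        ScoringParams(restart=1.0)
    with pytest.raises(ValueError):
        ScoringParams(p_exp=-1.0)
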
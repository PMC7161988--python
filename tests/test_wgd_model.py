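"""The loss-model likelihood engine against independent oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import all_configs, make_pillar
from wgdloss.io_formats import PhyloTree, ValidationError
from wgdloss.wgd_model import (
    _DUPLICATED,
    _config_bits,
    _LEAF_VECTORS,
    C1,
    C2,
    F,
    FitResult,
    OptimizerConfig,
    S1,
    S2,
    STATES,
    U,
    WGDModelSpec,
    build_rate_matrix,
    classify_fates,
    compare_topologies,
    expected_losses_per_branch,
    fit,
    forward_loglik,
    lrt,
    observation_matrix,
    orthology_posteriors,
    pillar_emission,
    transition_matrix,
)
from wgdloss.wgd_simulator import simulate_dataset, two_clade_tree


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def expm_series(Q, b, terms=60):
    """Scaling-and-squaring Taylor series, independent of scipy.linalg."""
    A = np.asarray(Q, float) * b
    s = max(0, int(np.ceil(np.log2(max(np.abs(A).max(), 1e-300)))) + 1)
    A = A / (2**s)
    out = np.eye(6)
    term = np.eye(6)
    for k in range(1, terms):
        term = term @ A / k
        out = out + term
    for _ in range(s):
        out = out @ out
    return out


def path_enumeration_emission(pillar, config, tree, spec):
    """Sum over all root-to-leaf state assignments (root fixed at U)."""
    from wgdloss.wgd_model import genome_order_of

    genomes = genome_order_of(tree)
    obs, _ = observation_matrix([pillar], tree)
    trans = {
        i: transition_matrix(build_rate_matrix(spec), tree.branch_length[i])
        for i in range(tree.n_nodes)
    }
    name2node = {v: k for k, v in tree.leaf_names.items()}
    leafvec = {
        name2node[gid]: _LEAF_VECTORS[obs[0, g], config[g]]
        for g, gid in enumerate(genomes)
    }
    total = 0.0
    for assign in itertools.product(range(6), repeat=tree.n_nodes):
        if assign[tree.root] != U:
            continue
        pr = 1.0
        for i in range(tree.n_nodes):
            if tree.parent[i] >= 0:
                pr *= trans[i][assign[tree.parent[i]], assign[i]]
            if i in tree.leaf_names:
                pr *= leafvec[i][assign[i]]
        total += pr
    return total


def enumeration_loglik(pillars, tree, spec, theta):
    """Brute-force sum over all tracking-configuration sequences."""
    n_genomes = tree.n_leaves
    bits = _config_bits(n_genomes)
    C = len(bits)
    E = np.array(
        [
            [pillar_emission(p, bits[c], tree, spec) for c in range(C)]
            for p in pillars
        ]
    )
    total = 0.0
    for seq in itertools.product(range(C), repeat=len(pillars)):
        pr = 1.0 / C
        for t in range(len(pillars)):
            if t > 0:
                d = bin(seq[t - 1] ^ seq[t]).count("1")
                pr *= theta**d * (1 - theta) ** (n_genomes - d)
            pr *= E[t, seq[t]]
        total += pr
    return math.log(total)


# ---------------------------------------------------------------------------
# generator and transition matrix
# ---------------------------------------------------------------------------


class TestRateMatrix:
    def test_null_model_row_u(self):
        Q = build_rate_matrix(WGDModelSpec.from_name("WGD-n"))
        assert np.allclose(Q[U], [-2, 0, 0, 0, 1, 1])

    def test_rows_sum_to_zero_absorbing_rows_zero(self):
        spec = WGDModelSpec.from_name("WGD-b2cf", gamma=0.2, delta=0.4,
                                      eps1=0.6, eps2=0.8, eta=1.3)
        Q = build_rate_matrix(spec)
        assert np.allclose(Q.sum(axis=1), 0)
        for row in (F, S1, S2):
            assert np.allclose(Q[row], 0)

    def test_bias_scales_loss_of_less_fractionated_copy(self):
        spec = WGDModelSpec.from_name("WGD-bc_nbn_f", eps1=0.8)
        Q = build_rate_matrix(spec)
        assert Q[U, S2] == pytest.approx(0.8 * Q[U, S1])

    def test_out_of_range_parameters_rejected(self):
        with pytest.raises(ValidationError):
            build_rate_matrix({"gamma": -0.1, "delta": 0, "eps1": 1,
                               "eps2": 1, "eta": 1})
        with pytest.raises(ValidationError):
            WGDModelSpec.from_name("WGD-b", eps1=1.5)

    def test_unknown_model_name_rejected(self):
        with pytest.raises(ValidationError):
            WGDModelSpec.from_name("WGD-xyz")

    def test_model_name_normalisation(self):
        a = WGDModelSpec.from_name("WGD-bc_nbn_f")
        b = WGDModelSpec.from_name("WGD-bc^nbn^f")
        assert a.free == b.free and a.eta == b.eta == 1.0


class TestTransitionMatrix:
    def test_zero_branch_is_identity(self):
        Q = build_rate_matrix(WGDModelSpec.from_name("WGD-n"))
        assert np.allclose(transition_matrix(Q, 0.0), np.eye(6))

    def test_symmetric_absorption_at_long_times(self):
        Q = build_rate_matrix(WGDModelSpec.from_name("WGD-n"))
        P = transition_matrix(Q, 200.0)
        assert np.allclose(P[U], [0, 0, 0, 0, 0.5, 0.5], atol=1e-9)

    def test_negative_branch_rejected(self):
        Q = build_rate_matrix(WGDModelSpec.from_name("WGD-n"))
        with pytest.raises(ValidationError):
            transition_matrix(Q, -0.1)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_series_oracle(self, seed):
        rng = np.random.default_rng(seed)
        spec = WGDModelSpec.from_name(
            "WGD-b2cf",
            gamma=rng.uniform(0, 2),
            delta=rng.uniform(0, 2),
            eps1=rng.uniform(0.1, 1),
            eps2=rng.uniform(0.1, 1),
            eta=rng.uniform(0.2, 3),
        )
        Q = build_rate_matrix(spec)
        b = rng.uniform(0, 3)
        assert np.abs(transition_matrix(Q, b) - expm_series(Q, b)).max() < 1e-10


# ---------------------------------------------------------------------------
# emissions
# ---------------------------------------------------------------------------


class TestPillarEmission:
    def test_all_duplicated_zero_branches_is_one(self):
        tree = PhyloTree.from_newick("((A:0,B:0):0);")
        spec = WGDModelSpec.from_name("WGD-bcf", gamma=0.1, delta=0.2, eps1=0.7)
        pillar = make_pillar("p", A=("a1", "a2"), B=("b1", "b2"))
        assert pillar_emission(pillar, (0, 0), tree, spec) == pytest.approx(1.0)

    def test_single_copy_zero_branches_impossible(self):
        tree = PhyloTree.from_newick("((A:0,B:0):0);")
        spec = WGDModelSpec.from_name("WGD-bcf", gamma=0.1, delta=0.2, eps1=0.7)
        pillar = make_pillar("p", A=("a1", None), B=("b1", "b2"))
        assert pillar_emission(pillar, (0, 0), tree, spec) == 0.0

    def test_missing_genome_rejected(self, tree2):
        pillar = make_pillar("p", A=("a1", "a2"))
        with pytest.raises(ValidationError):
            pillar_emission(pillar, (0, 0), tree2, WGDModelSpec.from_name("WGD-n"))

    @pytest.mark.parametrize(
        "newick",
        ["((A:0.5,B:0.8):0.3);", "((A:0.4,B:0.7):0.2,C:0.5);"],
    )
    def test_pruning_equals_path_enumeration(self, newick):
        tree = PhyloTree.from_newick(newick)
        spec = WGDModelSpec.from_name(
            "WGD-b2cf", gamma=0.1, delta=0.3, eps1=0.6, eps2=0.9, eta=1.4
        )
        n = tree.n_leaves
        names = sorted(tree.leaf_names.values())
        slot_options = [("x1", "x2"), ("x1", None), (None, "x2")]
        rng = np.random.default_rng(0)
        for _ in range(4):
            slots = {}
            for g in names:
                pair = slot_options[rng.integers(3)]
                slots[g] = tuple(
                    f"{g}_{v}" if v else None for v in pair
                )
            pillar = make_pillar("p", **slots)
            for config in all_configs(n):
                assert pillar_emission(pillar, config, tree, spec) == pytest.approx(
                    path_enumeration_emission(pillar, config, tree, spec),
                    abs=1e-12,
                )

    def test_track_relabeling_with_flipped_config_always_invariant(self, tree2):
        # swapping a genome's physical tracks while flipping its tracking
        # bit leaves the emission unchanged: tracks are arbitrary labels
        spec = WGDModelSpec.from_name("WGD-bf", gamma=0.1, eps1=0.6)
        pillar = make_pillar("p", A=("a1", None), B=("b1", "b2"))
        swapped = make_pillar("p", A=(None, "a1"), B=("b1", "b2"))
        assert pillar_emission(pillar, (0, 0), tree2, spec) == pytest.approx(
            pillar_emission(swapped, (1, 0), tree2, spec)
        )

    def test_subgenome_relabeling_invariant_iff_unbiased(self, tree2):
        # swapping slots with the SAME config reassigns subgenomes; the
        # emission is unchanged only when the model is symmetric
        pillar = make_pillar("p", A=("a1", None), B=("b1", None))
        swapped = make_pillar("p", A=(None, "a1"), B=(None, "b1"))
        sym = WGDModelSpec.from_name("WGD-cf", gamma=0.1, delta=0.3, eta=1.2)
        e1 = pillar_emission(pillar, (0, 0), tree2, sym)
        e2 = pillar_emission(swapped, (0, 0), tree2, sym)
        assert e1 == pytest.approx(e2)
        biased = WGDModelSpec.from_name("WGD-bf", gamma=0.1, eps1=0.6)
        b1 = pillar_emission(pillar, (0, 0), tree2, biased)
        b2 = pillar_emission(swapped, (0, 0), tree2, biased)
        assert abs(b1 - b2) > 1e-6


# ---------------------------------------------------------------------------
# forward algorithm
# ---------------------------------------------------------------------------


class TestForwardLoglik:
    def test_matches_enumeration_three_pillars_two_genomes(
        self, tree2, toy_pillars2
    ):
        spec = WGDModelSpec.from_name("WGD-bcf", gamma=0.1, delta=0.3,
                                      eps1=0.6, eta=1.4)
        for theta in (0.0, 0.07, 0.5):
            assert forward_loglik(toy_pillars2, tree2, spec, theta) == pytest.approx(
                enumeration_loglik(toy_pillars2, tree2, spec, theta), abs=1e-9
            )

    @given(data=st.data())
    @settings(max_examples=15, deadline=None)
    def test_matches_enumeration_random_instances(self, tree3, data):
        spec = WGDModelSpec.from_name(
            "WGD-b2cf",
            gamma=data.draw(st.floats(0, 1)),
            delta=data.draw(st.floats(0, 1)),
            eps1=data.draw(st.floats(0.2, 1)),
            eps2=data.draw(st.floats(0.2, 1)),
            eta=data.draw(st.floats(0.3, 2)),
        )
        theta = data.draw(st.floats(0, 0.5))
        n_pillars = data.draw(st.integers(1, 3))
        options = [("1", "2"), ("1", None), (None, "2")]
        pillars = []
        for i in range(n_pillars):
            slots = {}
            for g in "ABC":
                pair = options[data.draw(st.integers(0, 2))]
                slots[g] = tuple(
                    f"{g}{i}_{v}" if v else None for v in pair
                )
            pillars.append(make_pillar(f"p{i}", **slots))
        assert forward_loglik(pillars, tree3, spec, theta) == pytest.approx(
            enumeration_loglik(pillars, tree3, spec, theta), abs=1e-9
        )

    def test_theta_zero_single_consistent_configuration(self, tree2):
        # data forcing one configuration: lnL = sum ln emission - n ln 2
        spec = WGDModelSpec.from_name("WGD-bf", gamma=0.1, eps1=0.6)
        pillars = [
            make_pillar("p0", A=("a1", None), B=("b1", None)),
            make_pillar("p1", A=("a2", None), B=("b2", None)),
        ]
        ll = forward_loglik(pillars, tree2, spec, 0.0)
        per_config = []
        for config in all_configs(2):
            s = sum(
                math.log(pillar_emission(p, config, tree2, spec))
                for p in pillars
            )
            per_config.append(s)
        expected = math.log(sum(math.exp(s) for s in per_config) / 4)
        assert ll == pytest.approx(expected, abs=1e-9)

    def test_invalid_theta_rejected(self, tree2, toy_pillars2):
        spec = WGDModelSpec.from_name("WGD-n")
        with pytest.raises(ValidationError):
            forward_loglik(toy_pillars2, tree2, spec, 0.6)


# ---------------------------------------------------------------------------
# fitting, LRT, posteriors
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def fitted_sim():
    tree = two_clade_tree(4, 0.3, 0.3)
    spec = WGDModelSpec.from_name(
        "WGD-bc_nbn_f", gamma=0.05, delta=0.2, eps1=0.7
    )
    sim = simulate_dataset(spec, tree, 0.02, [1500], seed=42, build_genomes=False)
    cfg = OptimizerConfig(n_starts=1, fit_branch_lengths=False)
    res = fit(sim.pillars, sim.order, tree, "WGD-bc_nbn_f",
              optimizer_cfg=cfg, seed=0)
    return sim, res


class TestFit:
    def test_recovers_parameters_roughly(self, fitted_sim):
        sim, res = fitted_sim
        assert res.converged
        assert abs(res.spec.eps1 - 0.7) < 0.12
        assert abs(res.theta - 0.02) < 0.02

    def test_nested_model_never_beats_superset(self, fitted_sim):
        sim, res = fitted_sim
        cfg = OptimizerConfig(n_starts=1, fit_branch_lengths=False)
        null = fit(sim.pillars, sim.order, sim.tree, "WGD-n",
                   optimizer_cfg=cfg, seed=0)
        assert res.loglik >= null.loglik

    def test_unbiased_data_gives_eps_near_one(self):
        tree = two_clade_tree(4, 0.3, 0.3)
        sim = simulate_dataset(
            WGDModelSpec.from_name("WGD-n"), tree, 0.02, [1200],
            seed=8, build_genomes=False,
        )
        cfg = OptimizerConfig(n_starts=1, fit_branch_lengths=False)
        res = fit(sim.pillars, sim.order, tree, "WGD-bcf",
                  optimizer_cfg=cfg, seed=0)
        assert res.spec.eps1 > 0.9

    def test_deterministic_given_seed(self, fitted_sim):
        sim, res = fitted_sim
        cfg = OptimizerConfig(n_starts=1, fit_branch_lengths=False)
        res2 = fit(sim.pillars, sim.order, sim.tree, "WGD-bc_nbn_f",
                   optimizer_cfg=cfg, seed=0)
        assert res2.loglik == res.loglik
        assert res2.params == res.params


class TestLRT:
    def test_identical_fits(self, fitted_sim):
        _, res = fitted_sim
        stat, p = lrt(res, res, df=1)
        assert stat == 0.0 and p == 1.0

    def test_chi_square_quantile(self, fitted_sim):
        _, res = fitted_sim
        better = FitResult(
            spec=res.spec, theta=res.theta, branch_lengths=res.branch_lengths,
            loglik=res.loglik + 3.841 / 2, converged=True, message="",
            n_pillars=res.n_pillars, tree=res.tree, obs=res.obs,
            genomes=res.genomes,
        )
        stat, p = lrt(res, better, df=1)
        assert stat == pytest.approx(3.841)
        assert p == pytest.approx(0.05, abs=2e-4)

    def test_worse_alternative_is_an_error(self, fitted_sim):
        _, res = fitted_sim
        worse = FitResult(
            spec=res.spec, theta=res.theta, branch_lengths=res.branch_lengths,
            loglik=res.loglik - 5.0, converged=True, message="",
            n_pillars=res.n_pillars, tree=res.tree, obs=res.obs,
            genomes=res.genomes,
        )
        from wgdloss.wgd_model import OptimizationError

        with pytest.raises(OptimizationError):
            lrt(res, worse, df=1)


class TestPosteriors:
    def test_posteriors_sum_to_one(self, fitted_sim):
        _, res = fitted_sim
        post, map_config, confidence = orthology_posteriors(res)
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(confidence <= 1.0) and np.all(confidence >= 1 / post.shape[1])

    def test_alternative_count_matches_genome_count(self, fitted_sim):
        _, res = fitted_sim
        post, _, _ = orthology_posteriors(res)
        assert post.shape[1] - 1 == 2 ** len(res.genomes) - 1

    def test_two_pillar_toy_matches_brute_force_bayes(self, tree2):
        spec = WGDModelSpec.from_name("WGD-bf", gamma=0.1, eps1=0.7)
        pillars = [
            make_pillar("p0", A=("a1", "a2"), B=("b1", None)),
            make_pillar("p1", A=("a3", None), B=(None, "b2")),
        ]
        theta = 0.1
        obs, genomes = observation_matrix(pillars, tree2)
        res = FitResult(
            spec=spec, theta=theta, branch_lengths=tree2.branch_length,
            loglik=0.0, converged=True, message="", n_pillars=2,
            tree=tree2, obs=obs, genomes=genomes,
        )
        post, _, _ = orthology_posteriors(res)
        bits = _config_bits(2)
        E = np.array(
            [
                [pillar_emission(p, bits[c], tree2, spec) for c in range(4)]
                for p in pillars
            ]
        )
        joint = np.zeros((4, 4))
        for c0 in range(4):
            for c1 in range(4):
                d = bin(c0 ^ c1).count("1")
                joint[c0, c1] = (
                    0.25 * E[0, c0] * theta**d * (1 - theta) ** (2 - d) * E[1, c1]
                )
        assert np.allclose(post[0], joint.sum(axis=1) / joint.sum(), atol=1e-12)
        assert np.allclose(post[1], joint.sum(axis=0) / joint.sum(), atol=1e-12)


class TestExpectedLosses:
    def test_no_single_copy_data_no_losses(self):
        tree = two_clade_tree(3, 0.2, 0.2)
        pillars = [
            make_pillar(
                f"p{i}",
                sp01=(f"a{i}", f"A{i}"),
                sp02=(f"b{i}", f"B{i}"),
                sp03=(f"c{i}", f"C{i}"),
            )
            for i in range(10)
        ]
        spec = WGDModelSpec.from_name("WGD-f", gamma=2.0)
        obs, genomes = observation_matrix(pillars, tree)
        res = FitResult(
            spec=spec, theta=0.02, branch_lengths=tree.branch_length,
            loglik=0.0, converged=True, message="", n_pillars=10,
            tree=tree, obs=obs, genomes=genomes,
        )
        table = expected_losses_per_branch(res)
        assert (table[["entries_S1", "entries_S2"]].to_numpy() < 1e-9).all()

    def test_totals_track_simulated_truth(self, fitted_sim):
        sim, res = fitted_sim
        table = expected_losses_per_branch(res)
        truth = sim.truth.branch_loss_counts().set_index("node")
        got = table.set_index("node")
        for node in truth.index:
            for col in ("entries_S1", "entries_S2"):
                t = truth.loc[node, col]
                g = got.loc[node, col]
                assert abs(g - t) < max(40, 0.25 * max(t, 1)), (node, col, t, g)

    def test_symmetric_model_balances_subgenomes(self):
        tree = two_clade_tree(3, 0.3, 0.3)
        sim = simulate_dataset(
            WGDModelSpec.from_name("WGD-n"), tree, 0.02, [3000],
            seed=13, build_genomes=False,
        )
        obs, genomes = observation_matrix(sim.pillars, tree, sim.order)
        res = FitResult(
            spec=WGDModelSpec.from_name("WGD-n"), theta=0.02,
            branch_lengths=tree.branch_length, loglik=0.0, converged=True,
            message="", n_pillars=len(sim.pillars), tree=tree,
            obs=obs, genomes=genomes,
        )
        table = expected_losses_per_branch(res)
        s1, s2 = table["entries_S1"].sum(), table["entries_S2"].sum()
        # binomial-scale agreement between the two subgenome totals
        assert abs(s1 - s2) < 3 * math.sqrt(s1 + s2)


class TestClassifyFates:
    def test_sets_and_exclusivity(self, fitted_sim):
        sim, res = fitted_sim
        sets = classify_fates(res, sim.pillars, "sp01", order=sim.order)
        assert sets["RootLosses"].members.isdisjoint(sets["TipLosses"].members)
        assert sets["Ohno_POInT"].members.isdisjoint(sets["Sing_POInT"].members)
        assert sets["AllOhnologs"].members <= sets["Ohno_POInT"].members
        assert sets["AllSingle"].members <= sets["Sing_POInT"].members
        n_dup = sum(
            p.copy_state("sp01") == "duplicated" for p in sim.pillars
        )
        assert len(sets["Ohno_POInT"].pairs()) == n_dup

    def test_all_duplicated_pillar_in_all_ohnologs(self, fitted_sim):
        sim, res = fitted_sim
        sets = classify_fates(res, sim.pillars, "sp01", order=sim.order)
        for p in sim.pillars:
            if all(p.copy_state(g) == "duplicated" for g in res.genomes):
                for g in p.genes("sp01"):
                    assert g in sets["AllOhnologs"]

    def test_shared_single_track_tiny_tips_is_root_loss(self):
        # all genomes single on the same track with tiny tip branches:
        # the loss must predate the first speciation
        tree = PhyloTree.from_newick(
            "(((A:0.01,B:0.01):0.01,C:0.01):1.0);"
        )
        pillars = [
            make_pillar(f"p{i}", A=(f"a{i}", None), B=(f"b{i}", None),
                        C=(f"c{i}", None))
            for i in range(5)
        ]
        spec = WGDModelSpec.from_name("WGD-f", gamma=0.1)
        obs, genomes = observation_matrix(pillars, tree)
        res = FitResult(
            spec=spec, theta=0.01, branch_lengths=tree.branch_length,
            loglik=0.0, converged=True, message="", n_pillars=5,
            tree=tree, obs=obs, genomes=genomes,
        )
        sets = classify_fates(res, pillars, "A")
        assert all(f"a{i}" in sets["RootLosses"] for i in range(5))

    def test_threshold_validated(self, fitted_sim):
        sim, res = fitted_sim
        with pytest.raises(ValidationError):
            classify_fates(res, sim.pillars, "sp01", threshold=0.4)


class TestCompareTopologies:
    def test_duplicate_trees_equal_and_row_count(self):
        tree = two_clade_tree(3, 0.3, 0.3)
        sim = simulate_dataset(
            WGDModelSpec.from_name("WGD-f", gamma=0.1), tree, 0.02, [400],
            seed=3, build_genomes=False,
        )
        cfg = OptimizerConfig(n_starts=1, fit_branch_lengths=False, theta=0.02)
        table = compare_topologies(
            [tree, tree], sim.pillars, sim.order, "WGD-f",
            optimizer_cfg=cfg, seed=0,
        )
        assert len(table) == 2
        assert table["loglik"].iloc[0] == pytest.approx(
            table["loglik"].iloc[1], abs=1e-3
        )

    def test_true_topology_preferred(self):
        true_tree = two_clade_tree(4, 0.3, 0.3)
        # the two_clade tree pairs (sp01, sp02); the alternatives mix clades
        alt1 = PhyloTree.from_newick(
            "(((sp01:0.3,sp03:0.3):0.3,(sp02:0.3,sp04:0.3):0.3):0.3);"
        )
        alt2 = PhyloTree.from_newick(
            "(((sp01:0.3,sp04:0.3):0.3,(sp02:0.3,sp03:0.3):0.3):0.3);"
        )
        wins = 0
        cfg = OptimizerConfig(n_starts=1, fit_branch_lengths=False, theta=0.02)
        for rep in range(3):
            sim = simulate_dataset(
                WGDModelSpec.from_name("WGD-f", gamma=0.1), true_tree,
                0.02, [800], seed=50 + rep, build_genomes=False,
            )
            table = compare_topologies(
                [true_tree, alt1, alt2], sim.pillars, sim.order, "WGD-f",
                optimizer_cfg=cfg, seed=rep,
            )
            wins += table["tree_index"].iloc[0] == 0
        assert wins >= 2

    def test_leaf_mismatch_rejected(self, tree2, tree3, toy_pillars2):
        with pytest.raises(ValidationError):
            compare_topologies(
                [tree2, tree3], toy_pillars2, None, "WGD-n"
            )
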
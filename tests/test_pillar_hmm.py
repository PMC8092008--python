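"""Pillar HMM: emissions vs enumeration, forward vs path sums, posteriors,
loss bookkeeping and ordering comparison."""
import itertools

import numpy as np
import pandas as pd
import pytest

from wgtevol.loss_model import (
    LossModelSpec, STATES, STATE_INDEX, Variant, build_generator,
    root_branch_row, transition_probabilities,
)
from wgtevol.pillar_hmm import (
    FitResult, HmmSpec, PERMS, PillarLikelihood, PillarSet, compare_orderings,
    emission_loglik, expected_losses_per_branch, fit,
    posterior_subgenome_assignments, sequence_loglik, tip_state,
)
from wgtevol.synthetic_data import simulate_pillars
from wgtevol.trees import SpeciesTree


def _brute_force_L(tree, spec, nu):
    """Tip-state likelihood grid by explicit enumeration of internal states."""
    Q = build_generator(spec, "non_root")
    P = {n: transition_probabilities(Q, float(nu[n])) for n in range(1, tree.n_nodes)}
    row7, _, _ = root_branch_row(spec, float(nu[0]))

    def lik(node, s, tips):
        if not tree.children[node]:
            return 1.0 if tips[tree.labels[node]] == s else 0.0
        total = 1.0
        for c in tree.children[node]:
            total *= sum(P[c][s, s2] * lik(c, s2, tips) for s2 in range(7))
        return total

    G = tree.n_tips
    L = np.zeros((7,) * G)
    for combo in itertools.product(range(7), repeat=G):
        tips = dict(zip(tree.genomes, combo))
        L[combo] = sum(row7[s] * lik(0, s, tips) for s in range(7))
    return L


class TestTipState:
    def test_all_slots_present_is_triplicated(self):
        for p in range(6):
            assert STATES[tip_state((1, 2, 3), p)] == frozenset({1, 2, 3})

    def test_single_slot_forced(self):
        perm = (3, 1, 2)  # slot 2 -> subgenome 1
        assert STATES[tip_state((2,), perm)] == frozenset({1})

    def test_two_slots_through_permutation(self):
        perm = (3, 1, 2)  # slots {1,3} -> subgenomes {3,2}
        assert STATES[tip_state((1, 3), perm)] == frozenset({2, 3})

    def test_empty_slots_rejected(self):
        with pytest.raises(ValueError):
            tip_state((), 0)


class TestEmission:
    @pytest.mark.parametrize("spec_name", ["null", "g3", "g3_rootspec", "g3_root"])
    def test_pruning_matches_internal_state_enumeration(
            self, spec_name, two_tip_tree, three_tip_tree):
        specs = {
            "null": LossModelSpec.null(1.2),
            "g3": LossModelSpec.g3(0.8, (0.6, 0.8, 1), (0.5, 0.7, 1)),
            "g3_rootspec": LossModelSpec.g3_rootspec(
                0.8, (0.7, 0.9, 1), (0.6, 0.8, 1), 1.1, (0.4, 0.8, 1), (0.5, 0.9, 1)),
            "g3_root": LossModelSpec.g3_root(
                0.8, (0.6, 0.8, 1), (0.5, 0.7, 1), tau=1.0, beta12=0.3, beta13=0.2),
        }
        spec = specs[spec_name]
        for tree in (two_tip_tree, three_tip_tree):
            pillars = PillarSet(np.zeros((1, tree.n_tips), dtype=int),
                                np.zeros((1, tree.n_tips), dtype=bool), tree.genomes)
            eng = PillarLikelihood(pillars, tree)
            L = eng._tensorL(spec, tree.lengths)
            Lo = _brute_force_L(tree, spec, tree.lengths)
            assert np.abs(L - Lo).max() < 1e-10

    def test_zero_time_point_mass_on_start_state(self):
        tree = SpeciesTree.from_topology("A", default_length=0.0)
        tree.lengths[:] = 0.0
        spec = LossModelSpec.null()
        # observed fully triplicated: certain
        assert emission_loglik({"A": (1, 2, 3)}, {"A": 0}, tree, spec) == pytest.approx(0.0)
        # observed single-copy: impossible in zero time
        assert emission_loglik({"A": (1,)}, {"A": 0}, tree, spec) == -np.inf

    def test_genome_mismatch_rejected(self, two_tip_tree):
        with pytest.raises(ValueError):
            emission_loglik({"A": (1, 2, 3)}, {"A": 0}, two_tip_tree, LossModelSpec.null())


class TestForward:
    def test_matches_exhaustive_hidden_path_sum(self, two_tip_tree, g3_spec,
                                                tiny_pillars):
        eng = PillarLikelihood(tiny_pillars, two_tip_tree)
        theta = np.array([0.1, 0.3])
        lnl = eng.loglik(g3_spec, two_tip_tree.lengths, theta)
        L = eng._tensorL(g3_spec, two_tip_tree.lengths)
        E = L.ravel()[eng.F][eng.pat_idx]
        eff = eng._theta_eff(theta)

        def trans(p_prev, p_next, th):
            return (1 - th) * (p_prev == p_next) + th / 6

        total = 0.0
        for path in itertools.product(range(36), repeat=3):
            pr = E[0, path[0]] / 36
            for i in (1, 2):
                for g in range(2):
                    d_prev = path[i - 1] // 6 if g == 0 else path[i - 1] % 6
                    d_next = path[i] // 6 if g == 0 else path[i] % 6
                    pr *= trans(d_prev, d_next, eff[i, g])
                pr *= E[i, path[i]]
            total += pr
        assert lnl == pytest.approx(np.log(total), abs=1e-8)

    def test_single_pillar_degenerates_to_prior_times_emission(
            self, two_tip_tree, g3_spec):
        pillars = PillarSet(np.array([[3, 5]]), np.zeros((1, 2), dtype=bool), ("A", "B"))
        eng = PillarLikelihood(pillars, two_tip_tree)
        lnl = eng.loglik(g3_spec, two_tip_tree.lengths, np.array([0.2, 0.2]))
        E = eng._tensorL(g3_spec, two_tip_tree.lengths).ravel()[eng.F][0]
        assert lnl == pytest.approx(np.log(E.mean()), abs=1e-10)

    def test_frozen_permutations_closed_form(self, two_tip_tree, g3_spec):
        # theta = 0, no breaks: lnL = log sum_s prior(s) prod_i emission_i(s)
        rng = np.random.default_rng(0)
        patterns = rng.integers(0, 7, size=(5, 2))
        pillars = PillarSet(patterns, np.zeros((5, 2), dtype=bool), ("A", "B"))
        eng = PillarLikelihood(pillars, two_tip_tree)
        lnl = eng.loglik(g3_spec, two_tip_tree.lengths, np.array([0.0, 0.0]))
        E = eng._tensorL(g3_spec, two_tip_tree.lengths).ravel()[eng.F][eng.pat_idx]
        closed = np.log(np.prod(E, axis=0).mean())
        assert lnl == pytest.approx(closed, abs=1e-8)

    def test_iid_pillars_invariant_to_ordering(self, two_tip_tree, g3_spec):
        rng = np.random.default_rng(1)
        patterns = rng.integers(0, 7, size=(6, 2))
        pillars = PillarSet(patterns, np.zeros((6, 2), dtype=bool), ("A", "B"))
        hmm = HmmSpec(theta=1.0)
        base = sequence_loglik(pillars, two_tip_tree, g3_spec, hmm)
        shuffled = sequence_loglik(pillars.reorder(rng.permutation(6)),
                                   two_tip_tree, g3_spec, hmm)
        assert base == pytest.approx(shuffled, abs=1e-9)

    def test_empty_pillar_set_rejected(self):
        with pytest.raises(ValueError):
            PillarSet(np.zeros((0, 2), dtype=int), np.zeros((0, 2), dtype=bool),
                      ("A", "B"))


class TestPosteriors:
    @pytest.fixture(scope="class")
    def small_fit(self, study_tree):
        df, truth = simulate_pillars(n_pillars=250, seed=42, flag_breaks=False)
        res = fit(df, study_tree, Variant.G3, theta="shared", n_restarts=1,
                  seed=0, maxiter=150)
        return res, truth

    def test_state_posteriors_sum_to_one(self, small_fit):
        res, _ = small_fit
        gamma = res.posteriors()
        assert np.allclose(gamma.sum(axis=1), 1.0, atol=1e-8)

    def test_track_assignments_sum_to_one(self, small_fit):
        res, _ = small_fit
        arr = posterior_subgenome_assignments(res)
        assert np.allclose(arr.sum(axis=3), 1.0, atol=1e-8)

    def test_symmetric_data_gives_uniform_assignments(self, two_tip_tree):
        # fully triplicated pillars under NULL: all permutations equivalent
        pillars = PillarSet(np.zeros((4, 2), dtype=int), np.zeros((4, 2), dtype=bool),
                            ("A", "B"))
        eng = PillarLikelihood(pillars, two_tip_tree)
        res = FitResult(variant=Variant.NULL, spec=LossModelSpec.null(),
                        nu=two_tip_tree.lengths, theta=np.array([1.0, 1.0]),
                        lnL=0.0, converged=True, n_restarts=0, seed=0,
                        n_free=1, engine=eng)
        arr = posterior_subgenome_assignments(res)
        assert np.allclose(arr, 1.0 / 3.0, atol=1e-10)

    def test_modal_assignment_recovers_planted_truth(self, small_fit, study_tree):
        res, truth = small_fit
        arr = posterior_subgenome_assignments(res)
        perms = truth.perms  # tree genome order == pillar genome order here
        hits = total = 0
        for g_i in range(4):
            modal = arr[:, g_i].argmax(axis=2)
            planted = np.array([[PERMS[p][k] - 1 for k in range(3)]
                                for p in perms[:, g_i]])
            hits += (modal == planted).all(axis=1).sum()
            total += len(modal)
        assert hits / total > 0.5

    def test_loss_conservation_identity(self, small_fit):
        res, _ = small_fit
        table = expected_losses_per_branch(res)
        resid = (table.survivors_parent - table.losses + table.arrivals
                 - table.survivors_child)
        assert np.abs(resid).max() < 1e-6

    def test_zero_length_branch_has_zero_expected_losses(self, two_tip_tree, g3_spec):
        tree = SpeciesTree.from_topology(("A", "B"),
                                         lengths={"A": 0.0, "B": 0.3, "root": 0.35})
        df, _ = simulate_pillars(tree, g3_spec, HmmSpec(0.05), n_pillars=80, seed=3)
        ps = PillarSet.from_dataframe(df)
        eng = PillarLikelihood(ps, tree)
        res = FitResult(variant=Variant.G3, spec=g3_spec, nu=tree.lengths,
                        theta=np.array([0.05, 0.05]), lnL=0.0, converged=True,
                        n_restarts=0, seed=0, n_free=5, engine=eng)
        table = expected_losses_per_branch(res)
        zero_branch = table[table.branch == "A"]
        assert np.abs(zero_branch.losses).max() < 1e-8

    def test_expected_root_losses_near_planted_counts(self, small_fit):
        res, truth = small_fit
        table = expected_losses_per_branch(res)
        est = table[table.branch == "root"].set_index("subgenome")["losses"]
        true_counts = truth.loss_counts()
        true_root = true_counts[true_counts.branch == "root"].set_index("subgenome")["losses"]
        name = {1: "LF", 2: "MF1", 3: "MF2"}
        for k in (1, 2, 3):
            t = float(true_root.get(k, 0))
            # Poisson-scale Monte-Carlo error plus estimation slack
            assert abs(est[name[k]] - t) < 4 * np.sqrt(max(t, 1.0)) + 10


class TestOrderings:
    def test_identical_orderings_identical_lnl(self, tiny_pillars, two_tip_tree,
                                               g3_spec):
        hmm = HmmSpec(theta=0.1)
        df = compare_orderings(tiny_pillars, two_tip_tree, g3_spec, hmm,
                               [np.arange(3), np.arange(3)])
        assert df.lnL.iloc[0] == pytest.approx(df.lnL.iloc[1], abs=1e-12)

    def test_invalid_permutation_rejected(self, tiny_pillars, two_tip_tree, g3_spec):
        with pytest.raises(ValueError):
            compare_orderings(tiny_pillars, two_tip_tree, g3_spec, HmmSpec(0.1),
                              [np.array([0, 0, 2])])

    def test_planted_ordering_beats_shuffle_under_synteny_coupling(
            self, study_tree, g3_spec):
        df, _ = simulate_pillars(study_tree, g3_spec, HmmSpec(theta=0.02),
                                 n_pillars=300, seed=9, flag_breaks=False)
        ps = PillarSet.from_dataframe(df)
        rng = np.random.default_rng(5)
        out = compare_orderings(ps, study_tree, g3_spec, HmmSpec(theta=0.02),
                                [np.arange(300), rng.permutation(300)],
                                nu=study_tree.lengths)
        planted = out[out.ordering == 0].lnL.iloc[0]
        shuffled = out[out.ordering == 1].lnL.iloc[0]
        assert planted > shuffled


class TestPillarIO:
    def test_dataframe_round_trip(self, study_tree):
        df, _ = simulate_pillars(n_pillars=30, seed=2)
        ps = PillarSet.from_dataframe(df)
        df2 = ps.to_dataframe()
        ps2 = PillarSet.from_dataframe(df2)
        assert np.array_equal(ps.patterns, ps2.patterns)
        assert np.array_equal(ps.breaks, ps2.breaks)

    def test_missing_genome_slot_rejected(self):
        df, _ = simulate_pillars(n_pillars=5, seed=2)
        for k in (1, 2, 3):
            df.loc[0, f"B_rapa.slot{k}_present"] = 0
        with pytest.raises(ValueError):
            PillarSet.from_dataframe(df)
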
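"""Unit and property tests for the eight decision-fusion rules.

The brute-force oracles here enumerate focal-set products (for
Dempster's rule) or recompute similarities/column statistics with plain
loops, independently of the vectorized implementations they check.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gaitfuse as gf
from gaitfuse.errors import TotalConflictError
from gaitfuse.fusion import RULES, MassFunction

from conftest import random_score_matrix


def mass(singles, theta, ids=None):
    singles = np.asarray(singles, dtype=float)
    return MassFunction(
        singleton_masses=singles,
        theta_mass=theta,
        class_ids=tuple(ids or range(1, singles.size + 1)),
    )


def brute_force_ds(mass_functions):
    """Enumerate all focal-set combinations across n sources.

    Focal sets are singletons {c} plus Theta; the intersection of a
    choice tuple is Theta if all chose Theta, a singleton if all
    non-Theta choices agree, else empty (conflict).
    """
    class_ids = mass_functions[0].class_ids
    m = len(class_ids)
    combined = {c: 0.0 for c in class_ids}
    combined["theta"] = 0.0
    conflict = 0.0
    focal_choices = [list(range(m)) + ["theta"] for _ in mass_functions]
    for combo in itertools.product(*focal_choices):
        weight = 1.0
        for mf, choice in zip(mass_functions, combo):
            weight *= (
                mf.theta_mass if choice == "theta" else mf.singleton_masses[choice]
            )
        chosen = {c for c in combo if c != "theta"}
        if len(chosen) == 0:
            combined["theta"] += weight
        elif len(chosen) == 1:
            combined[class_ids[chosen.pop()]] += weight
        else:
            conflict += weight
    total = 1.0 - conflict
    return {k: v / total for k, v in combined.items()}


class TestMassFunctions:
    def test_score_row_discounting(self):
        m = gf.scores_to_mass([0.7, 0.3], alpha=1.0)
        assert m.singleton_masses.tolist() == [0.7, 0.3]
        assert m.theta_mass == pytest.approx(0.0)

        m = gf.scores_to_mass([1.0, 0.0], alpha=0.9)
        assert m.mass(1) == pytest.approx(0.9)
        assert m.theta_mass == pytest.approx(0.1)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0.05, 1.0), st.integers(0, 10_000))
    def test_discounted_masses_sum_to_one(self, alpha, seed):
        row = np.random.default_rng(seed).dirichlet(np.ones(8))
        m = gf.scores_to_mass(row, alpha)
        assert m.singleton_masses.sum() + m.theta_mass == pytest.approx(1.0)

    def test_alpha_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            gf.scores_to_mass([1.0, 0.0], alpha=0.0)
        with pytest.raises(ValueError):
            gf.scores_to_mass([1.0, 0.0], alpha=1.2)


class TestDempsterCombination:
    def test_vacuous_mass_is_the_neutral_element(self):
        m1 = mass([0.5, 0.3], 0.2)
        vac = mass([0.0, 0.0], 1.0)
        out = gf.ds_combine(m1, vac)
        np.testing.assert_allclose(out.singleton_masses, m1.singleton_masses)
        assert out.theta_mass == pytest.approx(m1.theta_mass)

    def test_worked_two_class_example(self):
        out = gf.ds_combine(mass([0.6, 0.4], 0.0), mass([0.7, 0.3], 0.0))
        # K = 0.6*0.3 + 0.4*0.7 = 0.46; renormalize by 0.54
        assert out.mass(1) == pytest.approx(0.42 / 0.54)
        assert out.mass(2) == pytest.approx(0.12 / 0.54)

    def test_total_conflict_raises(self):
        with pytest.raises(TotalConflictError):
            gf.ds_combine(mass([1.0, 0.0], 0.0), mass([0.0, 1.0], 0.0))

    def test_mismatched_frames_rejected(self):
        with pytest.raises(ValueError, match="frame"):
            gf.ds_combine(mass([1.0, 0.0], 0.0), mass([1, 0], 0.0, ids=(3, 4)))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_commutative_and_stays_on_mass_simplex(self, seed):
        rng = np.random.default_rng(seed)
        r1, r2 = rng.dirichlet(np.ones(8), size=2)
        m1, m2 = gf.scores_to_mass(r1, 0.9), gf.scores_to_mass(r2, 0.9)
        ab = gf.ds_combine(m1, m2)
        ba = gf.ds_combine(m2, m1)
        np.testing.assert_allclose(ab.singleton_masses, ba.singleton_masses, atol=1e-12)
        assert np.all(ab.singleton_masses >= 0)
        assert ab.singleton_masses.sum() + ab.theta_mass == pytest.approx(1.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_three_source_combination_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        masses = [gf.scores_to_mass(r, 0.95) for r in rng.dirichlet(np.ones(8), size=3)]
        want = brute_force_ds(masses)
        got = masses[0]
        for m in masses[1:]:
            got = gf.ds_combine(got, m)
        for k, c in enumerate(got.class_ids):
            assert got.singleton_masses[k] == pytest.approx(want[c], abs=1e-9)
        assert got.theta_mass == pytest.approx(want["theta"], abs=1e-9)

    def test_fold_order_invariance(self):
        rng = np.random.default_rng(12)
        rows = rng.dirichlet(np.ones(8), size=4)
        ms = [gf.scores_to_mass(r, 0.9) for r in rows]
        fwd = ms[0]
        for m in ms[1:]:
            fwd = gf.ds_combine(fwd, m)
        rev = ms[-1]
        for m in ms[-2::-1]:
            rev = gf.ds_combine(rev, m)
        np.testing.assert_allclose(fwd.singleton_masses, rev.singleton_masses, atol=1e-9)


class TestBelPl:
    def test_singleton_interval(self):
        m = mass([0.6, 0.3], 0.1)
        assert gf.bel_pl(m, 1) == (pytest.approx(0.6), pytest.approx(0.7))

    def test_zero_theta_collapses_interval(self):
        m = mass([0.6, 0.4], 0.0)
        for c in (1, 2):
            bel, pl = gf.bel_pl(m, c)
            assert bel == pytest.approx(pl)

    def test_vacuous_mass_is_total_ignorance(self):
        m = mass([0.0, 0.0, 0.0], 1.0)
        for c in (1, 2, 3):
            assert gf.bel_pl(m, c) == (0.0, 1.0)

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            gf.bel_pl(mass([1.0, 0.0], 0.0), 99)


class TestVoting:
    @pytest.mark.parametrize(
        "votes, winner",
        [
            ([1, 1, 2], 1),          # strict majority
            ([1, 2, 3], 1),          # plurality tie -> lowest id
            ([2, 2, 1, 1, 2], 2),    # majority
            ([3, 3, 2, 2], 2),       # two-way tie -> lowest id
            ([5], 5),
        ],
    )
    def test_vote_outcomes(self, votes, winner):
        assert gf.majority_vote(votes) == winner

    def test_empty_ballot_rejected(self):
        with pytest.raises(ValueError):
            gf.majority_vote([])


class TestDecisionTemplates:
    def _matrices(self, zs):
        return [
            gf.ScoreMatrix(z=np.asarray(z), classifier_ids=(1, 2), class_ids=(1, 2, 3))
            for z in zs
        ]

    def test_template_is_classwise_mean(self):
        z1 = [[0.8, 0.1, 0.1], [0.6, 0.2, 0.2]]
        z1b = [[0.6, 0.3, 0.1], [0.4, 0.4, 0.2]]
        z2 = [[0.4, 0.3, 0.3], [0.2, 0.5, 0.3]]
        z3 = [[0.1, 0.1, 0.8], [0.2, 0.2, 0.6]]
        templates = gf.dt_fit(self._matrices([z1, z2, z1b, z3]), [1, 2, 1, 3])
        np.testing.assert_allclose(
            templates.templates[0], (np.asarray(z1) + np.asarray(z1b)) / 2
        )
        np.testing.assert_allclose(templates.templates[1], z2)
        np.testing.assert_allclose(templates.templates[2], z3)

    def test_identical_training_matrices_reproduce_exactly(self):
        z = [[0.7, 0.2, 0.1], [0.1, 0.8, 0.1]]
        mats = self._matrices([z, z, [[1, 0, 0], [1, 0, 0]], [[0, 0, 1], [0, 0, 1]]])
        templates = gf.dt_fit(mats, [2, 2, 1, 3])
        assert gf.dt_predict(templates, mats[0]) == 2

    def test_missing_class_rejected(self):
        mats = self._matrices([[[1, 0, 0], [1, 0, 0]]] * 2)
        with pytest.raises(ValueError, match="absent"):
            gf.dt_fit(mats, [1, 2])

    def test_shape_mismatch_rejected(self):
        mats = self._matrices([[[1, 0, 0], [1, 0, 0]]] * 3)
        templates = gf.dt_fit(mats, [1, 2, 3])
        bad = gf.ScoreMatrix(
            z=np.full((3, 3), 1 / 3), classifier_ids=(1, 2, 3), class_ids=(1, 2, 3)
        )
        with pytest.raises(ValueError, match="shape"):
            gf.dt_predict(templates, bad)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_prediction_matches_min_distance_oracle(self, seed):
        rng = np.random.default_rng(seed)
        templates = gf.DecisionTemplateSet(
            templates=rng.dirichlet(np.ones(8), size=(8, 3)),
            class_ids=tuple(range(1, 9)),
        )
        Z = random_score_matrix(rng)
        dists = [
            sum(
                (Z.z[i, j] - templates.templates[k, i, j]) ** 2
                for i in range(3)
                for j in range(8)
            )
            for k in range(8)
        ]
        assert gf.dt_predict(templates, Z) == 1 + int(np.argmin(dists))


class TestAlgebraicRules:
    def test_sum_rule_worked_example(self):
        Z = gf.ScoreMatrix(
            z=np.array([[0.5, 0.3, 0.2], [0.2, 0.6, 0.2]]),
            classifier_ids=(1, 2),
            class_ids=(1, 2, 3),
        )
        assert gf.algebraic_fuse(Z, "sum") == 2  # e = [0.7, 0.9, 0.4]

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 100_000))
    def test_sum_and_average_always_agree(self, seed):
        Z = random_score_matrix(np.random.default_rng(seed))
        assert gf.algebraic_fuse(Z, "sum") == gf.algebraic_fuse(Z, "average")

    def test_single_classifier_degenerates_to_argmax(self):
        row = np.array([[0.1, 0.2, 0.7]])
        Z = gf.ScoreMatrix(z=row, classifier_ids=(4,), class_ids=(1, 2, 3))
        for rule in ("sum", "average", "max", "min", "product"):
            assert gf.algebraic_fuse(Z, rule) == 3

    def test_product_rule_survives_one_hot_rows(self):
        Z = gf.ScoreMatrix(
            z=np.array([[1.0, 0.0], [0.6, 0.4]]),
            classifier_ids=(1, 2),
            class_ids=(1, 2),
        )
        assert gf.algebraic_fuse(Z, "product") == 1

    def test_unknown_rule_rejected(self):
        Z = random_score_matrix(np.random.default_rng(0))
        with pytest.raises(ValueError, match="rule"):
            gf.algebraic_fuse(Z, "median")
        with pytest.raises(ValueError, match="rule"):
            gf.fuse(Z, "median")


class TestDsFuse:
    def test_unanimous_one_hot_agreement_across_all_rules(self):
        def one_hot_matrix(c):
            z = np.zeros((3, 8))
            z[:, c - 1] = 1.0
            return gf.ScoreMatrix(
                z=z, classifier_ids=(1, 2, 3), class_ids=tuple(range(1, 9))
            )

        templates = gf.dt_fit([one_hot_matrix(c) for c in range(1, 9)], list(range(1, 9)))
        Z = one_hot_matrix(5)
        for rule in RULES:
            assert gf.fuse(Z, rule, templates=templates) == 5

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_decision_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        Z = random_score_matrix(rng)
        masses = [gf.scores_to_mass(r, 0.95, Z.class_ids) for r in Z.z]
        want = brute_force_ds(masses)
        best = max(Z.class_ids, key=lambda c: (want[c], -c))
        assert gf.ds_fuse(Z, alpha=0.95) == best

    def test_reversed_fold_order_same_decision(self):
        rng = np.random.default_rng(3)
        Z = random_score_matrix(rng, n=4)
        rev = gf.ScoreMatrix(
            z=Z.z[::-1], classifier_ids=Z.classifier_ids[::-1], class_ids=Z.class_ids
        )
        assert gf.ds_fuse(Z) == gf.ds_fuse(rev)

    def test_total_conflict_falls_back_to_sum(self, caplog):
        Z = gf.ScoreMatrix(
            z=np.array([[1.0, 0.0], [0.0, 1.0]]),
            classifier_ids=(1, 2),
            class_ids=(1, 2),
        )
        with caplog.at_level("WARNING", logger="gaitfuse.fusion"):
            assert gf.ds_fuse(Z, alpha=1.0) == 1  # sum rule, lowest-id tie-break
        assert any("conflict" in r.message for r in caplog.records)
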
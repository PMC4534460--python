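"""Two-state CTMC likelihood, ML/LRT and MCMC machinery."""

import math

import dendropy
import numpy as np
import pytest

import famdrift as fd
from famdrift.treebias import (
    InapplicableMethodError,
    mcmc_rates,
    stepping_stone_logml,
)

from conftest import enum_loglik, make_family, random_stated_tree


def single_tip_tree(state):
    taxa = dendropy.TaxonNamespace(["only"])
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node.taxon = taxa.get_taxon("only")
    return fd.FamilyTree(tree=tree, tip_states={"only": state})


class TestPruningLikelihood:
    def test_single_tip_is_prior_mass(self):
        ft = single_tip_tree(0)
        assert fd.mk2_loglik(ft, 0.7, 1.3, root_prior="uniform") == pytest.approx(
            math.log(0.5))

    def test_two_tip_symmetric_closed_form(self, rng):
        ft = fd.gen_tree(2, rng)
        ft.tip_states = {"t0": 0, "t1": 0}
        q = 0.3
        p00 = 0.5 * (1 + math.exp(-2 * q))
        p10 = 0.5 * (1 - math.exp(-2 * q))
        expected = 0.5 * p00**2 + 0.5 * p10**2
        assert fd.mk2_loglik(ft, q, q, root_prior="uniform") == pytest.approx(
            math.log(expected))

    def test_matches_enumeration_oracle(self, rng):
        """Pruning equals the exhaustive sum over internal states on random
        small trees with random (incl. polymorphic) tip states and priors."""
        for _ in range(200):
            ft = random_stated_tree(rng)
            qg, ql = rng.uniform(0.02, 3.0, size=2)
            prior = ("stationary", "uniform")[rng.integers(2)]
            assert fd.mk2_loglik(ft, qg, ql, root_prior=prior) == pytest.approx(
                enum_loglik(ft, qg, ql, root_prior=prior), abs=1e-10)

    def test_invariant_to_child_order(self, rng):
        ft = random_stated_tree(rng, n_min=4, n_max=5)
        ll = fd.mk2_loglik(ft, 0.4, 0.9)
        for node in ft.tree.preorder_node_iter():
            kids = node.child_nodes()
            if len(kids) > 1:
                node.set_child_nodes(list(reversed(kids)))
        assert fd.mk2_loglik(ft, 0.4, 0.9) == pytest.approx(ll)

    def test_zero_rates_recover_prior_mass(self, rng):
        ft = fd.gen_tree(6, rng)
        ft.tip_states = {lab: 1 for lab in ft.tip_labels()}
        assert fd.mk2_loglik(ft, 1e-9, 1e-9, root_prior="uniform") == pytest.approx(
            math.log(0.5), abs=1e-6)

    def test_negative_rate_rejected(self, rng):
        ft = fd.gen_tree(3, rng)
        with pytest.raises(ValueError):
            fd.mk2_loglik(ft, -0.1, 0.2)


class TestFitML:
    def test_constrained_never_beats_unconstrained(self, rng):
        ft = random_stated_tree(rng, n_min=5, n_max=5)
        full = fd.fit_ml(ft, constrained_equal=False)
        null = fd.fit_ml(ft, constrained_equal=True)
        assert null.loglik <= full.loglik + 1e-8
        assert null.q_gain == null.q_loss

    def test_invariant_tips_raise(self, rng):
        ft = fd.gen_tree(8, rng)
        ft.tip_states = {lab: 1 for lab in ft.tip_labels()}
        with pytest.raises(InapplicableMethodError):
            fd.fit_ml(ft)

    def test_label_flip_mirrors_the_fit(self, rng):
        """Relabeling 0<->1 mirrors the likelihood surface: the flipped fit
        reaches the same maximum, with the stationary frequency of the trait
        mirrored.  (Only the rate ratio is compared: on a near-saturated
        ridge the absolute rates are weakly identifiable.)"""
        ft = fd.gen_tree(40, rng)
        tips, _ = fd.simulate_ctmc(ft, 0.1, 0.6, rng=rng)
        ft.tip_states = tips
        m1 = fd.fit_ml(ft, seed=0)
        ft.tip_states = {k: 1 - v for k, v in tips.items()}
        m2 = fd.fit_ml(ft, seed=0)
        assert m1.loglik == pytest.approx(m2.loglik, abs=1e-6)
        pi1 = m1.q_gain / (m1.q_gain + m1.q_loss)
        pi1_flip = m2.q_loss / (m2.q_gain + m2.q_loss)
        assert pi1 == pytest.approx(pi1_flip, abs=1e-3)

    def test_recovers_rate_ordering(self, rng):
        """Simulated loss-dominated histories yield q_loss > q_gain in the
        fitted model in nearly all replicates."""
        hits = 0
        for r in range(25):
            ft = fd.gen_tree(200, rng)
            tips, _ = fd.simulate_ctmc(ft, 0.05, 0.30, rng=rng)
            if len(set(tips.values())) < 2:
                continue
            ft.tip_states = tips
            m = fd.fit_ml(ft, seed=r)
            hits += m.q_loss > m.q_gain
        assert hits >= 22


class TestLRT:
    def test_statistic_nonnegative_and_direction_consistent(self, rng):
        ft = fd.gen_tree(60, rng)
        tips, _ = fd.simulate_ctmc(ft, 0.05, 0.8, rng=rng)
        ft.tip_states = tips
        cmp_ = fd.lrt_unequal_rates(ft)
        assert cmp_.statistic >= 0
        if cmp_.favored == "unequal":
            m = cmp_.unequal_model
            expected = fd.AGAINST if m.q_loss > m.q_gain else fd.TOWARD
            assert cmp_.direction_if_unequal == expected
        else:
            assert cmp_.direction_if_unequal == fd.NONE

    def test_power_against_strong_asymmetry(self, rng):
        hits = 0
        for r in range(20):
            ft = fd.gen_tree(100, rng)
            tips, _ = fd.simulate_ctmc(ft, 0.05, 0.5, rng=rng)
            if len(set(tips.values())) < 2:
                continue
            ft.tip_states = tips
            cmp_ = fd.lrt_unequal_rates(ft, seed=r)
            hits += cmp_.direction_if_unequal == fd.AGAINST
        assert hits >= 11


class TestMCMC:
    def test_same_seed_identical_chains(self, rng):
        ft = random_stated_tree(rng, n_min=5, n_max=5)
        a = mcmc_rates(ft, n_iter=2000, burn_in=200, seed=9)
        b = mcmc_rates(ft, n_iter=2000, burn_in=200, seed=9)
        assert np.array_equal(a.rates, b.rates)

    def test_prior_only_run_reproduces_prior(self, rng):
        """With the likelihood disabled (beta=0) the sampler targets the
        Exponential(1) prior on each rate."""
        ft = random_stated_tree(rng, n_min=4, n_max=4)
        res = mcmc_rates(ft, n_iter=40_000, burn_in=2000, seed=3, beta=0.0)
        q = res.rates[:, 0]
        assert np.mean(q) == pytest.approx(1.0, abs=0.12)
        assert np.median(q) == pytest.approx(math.log(2), abs=0.08)

    def test_posterior_concentrates_near_ml(self, rng):
        ft = fd.gen_tree(200, rng)
        tips, _ = fd.simulate_ctmc(ft, 0.1, 0.5, rng=rng)
        ft.tip_states = tips
        ml = fd.fit_ml(ft, seed=0)
        post = mcmc_rates(ft, n_iter=5000, burn_in=500, seed=4)
        qg, ql = post.rates.mean(axis=0)
        assert qg == pytest.approx(ml.q_gain, rel=0.8, abs=0.05)
        assert ql == pytest.approx(ml.q_loss, rel=0.8, abs=0.05)
        assert ql > qg

    def test_n_iter_burn_in_contract(self, rng):
        ft = random_stated_tree(rng, n_min=4, n_max=4)
        with pytest.raises(ValueError):
            mcmc_rates(ft, n_iter=1000, burn_in=500)


class TestBayesFactor:
    def test_detects_strong_asymmetry(self, rng):
        ft = fd.gen_tree(120, rng)
        while True:
            tips, _ = fd.simulate_ctmc(ft, 0.05, 0.6, rng=rng)
            if 0 < sum(tips.values()) < len(tips):
                break
        ft.tip_states = tips
        cmp_ = fd.bayes_factor_unequal(ft, seed=11)
        assert cmp_.method == "mcmc_bf"
        if cmp_.favored == "unequal":
            assert cmp_.statistic > 2
            assert cmp_.direction_if_unequal == fd.AGAINST

    def test_stepping_stone_reproducible(self, rng):
        ft = random_stated_tree(rng, n_min=5, n_max=5, allow_poly=False)
        a = stepping_stone_logml(ft, False, seed=2, n_steps=8, iter_per_step=200)
        b = stepping_stone_logml(ft, False, seed=2, n_steps=8, iter_per_step=200)
        assert a == b


class TestClassifyTree:
    def test_invariant_family_falls_back_to_set_test(self):
        fam = make_family({f"l{i}": [0] for i in range(8)}, family_id="inv")
        (est,) = fd.classify_large_families_tree([fam], engine="ml")
        assert est.method == "set_binomial"
        assert est.direction == fd.AGAINST

    def test_variable_family_uses_tree_engine(self, rng):
        by_lang = {f"l{i}": [0] for i in range(9)}
        by_lang["l9"] = [1]
        fam = make_family(by_lang, family_id="var")
        (est,) = fd.classify_large_families_tree([fam], engine="ml")
        assert est.method == "tree_ml"
        assert est.strength == pytest.approx(0.9)

    def test_rejects_small_family(self):
        fam = make_family({"a": [0], "b": [1]})
        with pytest.raises(ValueError, match="not large"):
            fd.classify_large_families_tree([fam])
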
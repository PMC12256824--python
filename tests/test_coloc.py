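"""Colocalization: ABFs, posterior enumeration, conditional signals."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

from mrcoloc import (
    ColocPriors,
    EffectPrior,
    Scenario,
    coloc_abf,
    coloc_multi,
    conditional_stats,
    decompose_signals,
    log_abf,
    simulate_ld,
    simulate_locus,
)

from conftest import set_from_stats


def brute_force_coloc(z1, se1, z2, se2, priors, w1, w2):
    """Independent oracle: explicit enumeration over all Q^2 + 2Q + 1
    single-causal-variant configurations, in plain (non-log) space."""
    bf1 = np.array(
        [
            math.exp(log_abf(z * s, s, EffectPrior(prior_sd=math.sqrt(w1))))
            for z, s in zip(z1, se1)
        ]
    )
    bf2 = np.array(
        [
            math.exp(log_abf(z * s, s, EffectPrior(prior_sd=math.sqrt(w2))))
            for z, s in zip(z2, se2)
        ]
    )
    q = len(bf1)
    l0 = 1.0
    l1 = priors.p1 * bf1.sum()
    l2 = priors.p2 * bf2.sum()
    l3 = priors.p1 * priors.p2 * sum(
        bf1[j] * bf2[k] for j in range(q) for k in range(q) if j != k
    )
    l4 = priors.p12 * float(bf1 @ bf2)
    weights = np.array([l0, l1, l2, l3, l4])
    return weights / weights.sum()


def _sets_from_z(z1, se1, z2, se2):
    s1 = set_from_stats(np.asarray(z1) * se1, se1, trait_id="t1")
    s2 = set_from_stats(np.asarray(z2) * se2, se2, trait_id="t2")
    return s1, s2


class TestLogABF:
    def test_vanishing_prior_gives_null_bf(self):
        lbf = log_abf(0.8, 0.1, EffectPrior(prior_sd=1e-12))
        assert lbf == pytest.approx(0.0, abs=1e-6)

    def test_arithmetic_example(self):
        # z = 0, V = 0.01, W = 0.0225: r = 0.6923, log ABF = 0.5 log(1-r)
        lbf = log_abf(0.0, 0.1, EffectPrior(prior_sd=0.15))
        assert lbf == pytest.approx(0.5 * math.log(1 - 0.0225 / 0.0325))
        assert lbf == pytest.approx(-0.589, abs=1e-3)

    @pytest.mark.parametrize(
        "beta,se,w",
        [(0.3, 0.1, 0.0225), (-0.5, 0.2, 0.04), (0.0, 0.05, 0.01), (1.2, 0.3, 0.0225)],
    )
    def test_matches_quadrature_of_marginal_likelihood_ratio(self, beta, se, w):
        """ABF == int N(beta_hat; b, V) N(b; 0, W) db / N(beta_hat; 0, V)."""
        v = se**2
        num, _ = quad(
            lambda b: stats.norm.pdf(beta, b, se)
            * stats.norm.pdf(b, 0, math.sqrt(w)),
            -10,
            10,
        )
        oracle = math.log(num / stats.norm.pdf(beta, 0, math.sqrt(v)))
        lbf = log_abf(beta, se, EffectPrior(prior_sd=math.sqrt(w)))
        assert lbf == pytest.approx(oracle, abs=1e-6)

    def test_increasing_in_abs_z(self):
        prior = EffectPrior()
        vals = [log_abf(z * 0.1, 0.1, prior) for z in (0, 1, 2, 5)]
        assert vals == sorted(vals)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            log_abf(0.1, 0.0, EffectPrior())


class TestColocABF:
    def test_all_null_locus_favors_h0(self, rng):
        q = 100
        se = np.full(q, 0.01)  # GWAS-scale precision (n ~ 10k)
        s1, s2 = _sets_from_z(np.zeros(q), se, np.zeros(q), se)
        res = coloc_abf(s1, s2)
        assert res.pph[0] > 0.99

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_brute_force_enumeration(self, trial):
        rng = np.random.default_rng(1000 + trial)
        q = int(rng.integers(1, 21))
        z1 = rng.normal(0, 3, q)
        z2 = rng.normal(0, 3, q)
        se1 = rng.uniform(0.02, 0.3, q)
        se2 = rng.uniform(0.02, 0.3, q)
        priors = ColocPriors()
        s1, s2 = _sets_from_z(z1, se1, z2, se2)
        res = coloc_abf(s1, s2)
        oracle = brute_force_coloc(z1, se1, z2, se2, priors, 0.0225, 0.0225)
        np.testing.assert_allclose(res.pph, oracle, rtol=1e-10, atol=1e-300)

    def test_posteriors_sum_to_one(self, rng):
        for _ in range(20):
            q = int(rng.integers(1, 50))
            s1, s2 = _sets_from_z(
                rng.normal(0, 5, q),
                rng.uniform(0.01, 0.5, q),
                rng.normal(0, 5, q),
                rng.uniform(0.01, 0.5, q),
            )
            res = coloc_abf(s1, s2)
            assert abs(res.pph.sum() - 1.0) < 1e-10

    def test_trait_swap_exchanges_h1_h2(self, rng):
        q = 15
        s1, s2 = _sets_from_z(
            rng.normal(0, 3, q),
            rng.uniform(0.05, 0.2, q),
            rng.normal(0, 3, q),
            rng.uniform(0.05, 0.2, q),
        )
        a = coloc_abf(s1, s2)
        b = coloc_abf(s2, s1)
        assert a.pph[1] == pytest.approx(b.pph[2], rel=1e-12)
        assert a.pph[2] == pytest.approx(b.pph[1], rel=1e-12)
        for h in (0, 3, 4):
            assert a.pph[h] == pytest.approx(b.pph[h], rel=1e-12)

    def test_shared_strong_signal_drives_pph4(self):
        q = 50
        z1 = np.zeros(q)
        z2 = np.zeros(q)
        z1[10] = z2[10] = 30.0
        se = np.full(q, 0.1)
        s1, s2 = _sets_from_z(z1, se, z2, se)
        res = coloc_abf(s1, s2)
        assert res.pph[4] > 0.999

    def test_distinct_strong_signals_drive_pph3(self):
        q = 50
        z1 = np.zeros(q)
        z2 = np.zeros(q)
        z1[10] = 30.0
        z2[40] = 30.0
        se = np.full(q, 0.1)
        s1, s2 = _sets_from_z(z1, se, z2, se)
        res = coloc_abf(s1, s2)
        assert res.pph[3] > 0.999

    def test_pph4_monotone_in_p12(self, rng):
        q = 30
        s1, s2 = _sets_from_z(
            rng.normal(0, 2, q),
            rng.uniform(0.05, 0.2, q),
            rng.normal(0, 2, q),
            rng.uniform(0.05, 0.2, q),
        )
        last = -1.0
        for p12 in (1e-6, 1e-5, 1e-4):
            res = coloc_abf(s1, s2, ColocPriors(p12=p12))
            assert res.pph[4] >= last
            last = res.pph[4]

    def test_single_shared_snp_has_no_h3_mass(self):
        s1, s2 = _sets_from_z([3.0], [0.1], [2.0], [0.1])
        res = coloc_abf(s1, s2)
        assert res.pph[3] == pytest.approx(0.0, abs=1e-300)

    def test_empty_intersection_raises(self):
        s1 = set_from_stats([0.1], [0.1], snp_ids=["a"])
        s2 = set_from_stats([0.1], [0.1], snp_ids=["b"])
        with pytest.raises(ValueError):
            coloc_abf(s1, s2)


class TestConditionalStats:
    def test_independent_index_leaves_stats_unchanged(self):
        ld = simulate_ld(3, 0.0)
        aset = set_from_stats([0.5, 0.3, 0.2], [0.1, 0.1, 0.1])
        cond = conditional_stats(aset, ld, ["rs3"])
        for orig, new in zip(aset.records[:2], cond.records[:2]):
            assert new.beta == pytest.approx(orig.beta, abs=1e-6)

    def test_conditioning_snp_on_itself_zeroes_it(self):
        ld = simulate_ld(2, 0.5)
        aset = set_from_stats([0.5, 0.3], [0.1, 0.1])
        cond = conditional_stats(aset, ld, ["rs1"])
        assert cond.records[0].beta == 0.0

    def test_two_snp_closed_form(self):
        # r = 0.8, z = (5, 4): z_2|1 = (4 - 0.8*5)/sqrt(1 - 0.64) = 0
        ld = simulate_ld(2, 0.8)
        aset = set_from_stats([0.5, 0.4], [0.1, 0.1])
        cond = conditional_stats(aset, ld, ["rs1"])
        # exact up to the 1e-6 ridge on R_{S,S}
        assert cond.records[1].beta / cond.records[1].se == pytest.approx(
            0.0, abs=1e-4
        )


class TestDecomposeSignals:
    def test_single_causal_gives_one_signal(self):
        loc = simulate_locus(Scenario(hypothesis="H4", seed=11))
        sigs = decompose_signals(loc.exposure, loc.ld)
        assert len(sigs) == 1

    def test_two_independent_causals_give_two_signals(self):
        sc = Scenario(
            hypothesis="H4",
            n_signals=2,
            ld_blocks=2,
            causal_variance_exp=0.05,
            seed=5,
        )
        loc = simulate_locus(sc)
        sigs = decompose_signals(loc.exposure, loc.ld)
        assert len(sigs) == 2

    def test_null_locus_gives_no_signals(self):
        loc = simulate_locus(Scenario(hypothesis="H0", seed=3))
        assert decompose_signals(loc.exposure, loc.ld) == []


class TestColocMulti:
    def test_single_signal_reduces_to_marginal_coloc(self):
        loc = simulate_locus(Scenario(hypothesis="H4", seed=21))
        plain = coloc_abf(loc.exposure, loc.outcome)
        multi = coloc_multi(loc.exposure, loc.outcome, loc.ld)
        assert multi.max_pph4 == pytest.approx(plain.pph[4], rel=1e-6)

    def test_partially_shared_signals(self):
        """Trait A has two signals, trait B shares only one: max PPH4 is
        high while the unshared pair's PPH4 is low."""
        rng = np.random.default_rng(42)
        q = 100
        ld = simulate_ld(q, 0.9, blocks=2)
        chol = np.linalg.cholesky(ld.r + 1e-10 * np.eye(q))
        b_a = np.zeros(q)
        b_a[10] = b_a[60] = 0.22
        b_b = np.zeros(q)
        b_b[60] = 0.22
        n = 20_000
        za = np.sqrt(n) * ld.r @ b_a + chol @ rng.standard_normal(q)
        zb = np.sqrt(n) * ld.r @ b_b + chol @ rng.standard_normal(q)
        se = np.full(q, 1 / np.sqrt(n))
        sa = set_from_stats(za * se, se, trait_id="a")
        sb = set_from_stats(zb * se, se, trait_id="b")
        res = coloc_multi(sa, sb, ld)
        assert res.max_pph4 > 0.8
        assert res.signal_pairs is not None
        assert min(p.pph4 for p in res.signal_pairs) < 0.2
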
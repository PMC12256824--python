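"""Wald ratio, IVW, BH FDR, batch MR, and weighted correlations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from mrcoloc import (
    MRConfig,
    bh_fdr,
    estimate_correlation_matrix,
    ivw,
    run_mr_batch,
    simulate_locus,
    Scenario,
    wald_ratio,
    weighted_pearson,
)
from mrcoloc.harmonize import ACTION_IDENTICAL, HarmonizedPair
from mrcoloc.instruments import InstrumentSet, SelectionParams
from mrcoloc.mr import apply_fdr

from conftest import make_record, make_set, set_from_stats


def _pair(beta_exp, beta_out, se_out, se_exp=0.1):
    return HarmonizedPair(
        snp_id="rs1",
        beta_exp=beta_exp,
        se_exp=se_exp,
        beta_out=beta_out,
        se_out=se_out,
        eaf_exp=0.3,
        eaf_out=0.3,
        action=ACTION_IDENTICAL,
    )


class TestWaldRatio:
    def test_unit_exposure(self):
        est = wald_ratio(_pair(1.0, 0.5, 0.1))
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1)
        assert est.n_snps == 1

    def test_sign_and_scale(self):
        est = wald_ratio(_pair(-0.5, 0.2, 0.1))
        assert est.beta == pytest.approx(-0.4)
        assert est.se == pytest.approx(0.2)

    def test_zero_exposure_raises(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(_pair(0.0, 0.2, 0.1))

    def test_second_order_se_matches_monte_carlo(self, rng):
        """Delta-method SE vs the empirical SD of a ratio of normals."""
        bx, sx, by, so = 1.0, 0.05, 0.3, 0.1
        est = wald_ratio(_pair(bx, by, so, se_exp=sx), "second_order")
        draws = rng.normal(by, so, 1_000_000) / rng.normal(bx, sx, 1_000_000)
        assert est.se == pytest.approx(np.std(draws), rel=0.05)

    def test_equivariance_under_exposure_rescaling(self):
        base = wald_ratio(_pair(0.5, 0.3, 0.1))
        neg = wald_ratio(_pair(-0.5, 0.3, 0.1))
        scaled = wald_ratio(_pair(1.0, 0.3, 0.1))
        assert neg.beta == pytest.approx(-base.beta)
        assert scaled.beta == pytest.approx(base.beta / 2)


class TestIVW:
    def test_single_pair_equals_wald_first_order(self, rng):
        for _ in range(100):
            bx = rng.normal(0.5, 0.2)
            if abs(bx) < 1e-3:
                continue
            pair = _pair(bx, rng.normal(), rng.uniform(0.05, 0.5))
            w = wald_ratio(pair)
            v = ivw([pair], variant="fe")
            assert v.beta == pytest.approx(w.beta)
            assert v.se == pytest.approx(w.se)
            assert v.pvalue == pytest.approx(w.pvalue)

    def test_identical_ratios_pool_precision(self):
        # two SNPs with the same ratio 0.5: beta = 0.5 and the fe SE is
        # the pooled precision (sum w)^-1/2 computed by hand
        p1 = _pair(1.0, 0.5, 0.1)
        p2 = _pair(2.0, 1.0, 0.2)
        est = ivw([p1, p2], variant="fe")
        w1, w2 = 1.0 / 0.1**2, 4.0 / 0.2**2
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx((w1 + w2) ** -0.5)

    def test_mre_floor_never_shrinks_below_fe(self, rng):
        for _ in range(20):
            pairs = [
                _pair(rng.normal(1, 0.3), rng.normal(), rng.uniform(0.05, 0.3))
                for _ in range(4)
            ]
            fe = ivw(pairs, variant="fe")
            mre = ivw(pairs, variant="mre")
            assert mre.se >= fe.se - 1e-15
            assert mre.beta == pytest.approx(fe.beta)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            ivw([])


class TestBHFDR:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_step_down_hand_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        p=st.lists(
            st.floats(1e-12, 1.0, allow_nan=False), min_size=1, max_size=50
        )
    )
    def test_matches_independent_step_up_oracle(self, p):
        mine = bh_fdr(p)
        _, oracle, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(mine, oracle, rtol=1e-10)
        assert np.all(mine >= np.asarray(p) - 1e-15)
        assert np.all(mine <= 1.0)

    def test_per_outcome_family_is_blockwise(self):
        p = np.array([0.01, 0.02, 0.01, 0.02])
        outcomes = np.array(["a", "a", "b", "b"])
        q = apply_fdr(p, outcomes, "per_outcome")
        np.testing.assert_allclose(q, [0.02, 0.02, 0.02, 0.02])


class TestRunMRBatch:
    def _instruments(self, n_genes, cell_types, rng):
        out = []
        for g in range(n_genes):
            for ct in cell_types:
                rec = make_record(
                    snp_id=f"G{g}_rs1",
                    pos=100 + g,
                    beta=float(rng.normal(0.5, 0.05)),
                    se=0.05,
                )
                out.append(
                    InstrumentSet(f"G{g}", ct, [rec], SelectionParams())
                )
        return out

    def test_batch_bookkeeping_one_row_per_combination(self, rng):
        instruments = self._instruments(50, ["a", "b", "c"], rng)
        outcome = make_set(
            [
                make_record(
                    snp_id=f"G{g}_rs1",
                    pos=100 + g,
                    beta=float(rng.normal(0, 0.02)),
                    se=0.02,
                )
                for g in range(50)
            ],
            trait_id="gwas",
        )
        table = run_mr_batch(instruments, [outcome])
        assert len(table) == 150
        assert (table["qvalue"] >= table["pvalue"] - 1e-12).all()

    def test_strong_mediated_gene_is_significant(self):
        sc = Scenario(hypothesis="H4", alpha=0.3, seed=7)
        loc = simulate_locus(sc, gene_id="G1", cell_type="Mono")
        top = min(loc.exposure.records, key=lambda r: r.pvalue)
        inst = InstrumentSet("G1", "Mono", [top], SelectionParams())
        table = run_mr_batch([inst], [loc.outcome])
        assert bool(table["significant"][0])


class TestWeightedCorrelation:
    def test_table_vs_itself_is_one(self, rng):
        import pandas as pd

        t = pd.DataFrame(
            {
                "gene_id": [f"G{i}" for i in range(10)],
                "outcome_id": ["o"] * 10,
                "beta": rng.normal(size=10),
                "se": rng.uniform(0.1, 0.5, 10),
            }
        )
        corr = estimate_correlation_matrix({"a": t, "b": t.copy()})
        assert corr.loc["a", "b"] == pytest.approx(1.0)

    def test_equal_weights_reduce_to_plain_pearson(self, rng):
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        rw = weighted_pearson(x, y, np.ones(30))
        assert rw == pytest.approx(np.corrcoef(x, y)[0, 1])

    def test_shared_vs_independent_effects(self, rng):
        """Cell types with identical true effects correlate near 1;
        independent effects near 0."""
        import pandas as pd

        n = 200
        true = rng.normal(0, 1, n)
        se = 0.05
        genes = [f"G{i}" for i in range(n)]

        def table(effects):
            return pd.DataFrame(
                {
                    "gene_id": genes,
                    "outcome_id": ["o"] * n,
                    "beta": effects + rng.normal(0, se, n),
                    "se": se,
                }
            )

        shared = estimate_correlation_matrix(
            {"a": table(true), "b": table(true)}
        )
        indep = estimate_correlation_matrix(
            {"a": table(true), "b": table(rng.normal(0, 1, n))}
        )
        assert shared.loc["a", "b"] > 0.95
        assert abs(indep.loc["a", "b"]) < 0.2

    def test_too_few_shared_points_gives_nan(self, rng):
        import pandas as pd

        t1 = pd.DataFrame(
            {"gene_id": ["G1"], "outcome_id": ["o"], "beta": [0.1], "se": [0.1]}
        )
        t2 = pd.DataFrame(
            {"gene_id": ["G2"], "outcome_id": ["o"], "beta": [0.1], "se": [0.1]}
        )
        corr = estimate_correlation_matrix({"a": t1, "b": t2})
        assert np.isnan(corr.loc["a", "b"])
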
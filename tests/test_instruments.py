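"""cis windows, significance filtering, and greedy LD clumping."""

import numpy as np
import pytest

from mrcoloc import (
    GeneAnnotation,
    LDMatrix,
    SelectionParams,
    cis_window,
    clump,
    filter_significant,
    select_instruments,
    simulate_ld,
)
from mrcoloc.sumstats import zscore_pvalue

from conftest import make_record, make_set, set_from_stats


GENE = GeneAnnotation("G1", "1", 1_000_000, 1_050_000)


class TestCisWindow:
    def test_flank_gene_window_clamped_at_one(self):
        params = SelectionParams("flank_gene", 1_000_000)
        region = cis_window(GENE, params)
        assert (region.start, region.end) == (1, 2_050_000)

    def test_midpoint_window(self):
        params = SelectionParams("midpoint", 100_000)
        region = cis_window(GENE, params)
        assert (region.start, region.end) == (925_000, 1_125_000)

    @pytest.mark.parametrize("mode,bp", [("flank_gene", 500), ("midpoint", 500)])
    def test_point_gene_gives_symmetric_window(self, mode, bp):
        gene = GeneAnnotation("G2", "1", 5_000, 5_000)
        region = cis_window(gene, SelectionParams(mode, bp))
        assert (region.start, region.end) == (4_500, 5_500)


class TestFilterSignificant:
    def test_keeps_only_below_threshold(self):
        aset = make_set(
            [
                make_record(snp_id="a", pos=1, pvalue=1e-6, beta=0.5, se=0.1),
                make_record(snp_id="b", pos=2, pvalue=1e-4, beta=0.4, se=0.1),
            ]
        )
        out = filter_significant(aset, 1e-5)
        assert out.snp_ids == ["a"]

    def test_empty_when_nothing_significant(self):
        aset = make_set([make_record(pvalue=0.5, beta=0.01, se=0.1)])
        assert len(filter_significant(aset, 1e-5)) == 0

    def test_threshold_one_is_identity(self):
        aset = make_set(
            [make_record(snp_id=s, pos=i + 1) for i, s in enumerate("abc")]
        )
        assert filter_significant(aset, 1.0).snp_ids == list("abc")


def _ld_from_r2(ids, r2_pairs):
    q = len(ids)
    r = np.eye(q)
    for (i, j), r2 in r2_pairs.items():
        r[i, j] = r[j, i] = np.sqrt(r2)
    return LDMatrix(ids, r)


class TestClump:
    def test_greedy_keeps_index_and_independent_snp(self):
        # hand-execution: rs1 (best p) removes rs2 (r2=0.5); rs3 survives
        ld = _ld_from_r2(
            ["rs1", "rs2", "rs3"],
            {(0, 1): 0.5, (0, 2): 0.05, (1, 2): 0.04},
        )
        aset = set_from_stats([0.6, 0.55, 0.5], [0.1, 0.1, 0.1])
        for rec, p in zip(aset.records, (1e-8, 1e-7, 1e-6)):
            rec.pvalue = p
        out = clump(aset, ld, 0.1)
        assert out.snp_ids == ["rs1", "rs3"]

    def test_zero_ld_keeps_all(self):
        ld = _ld_from_r2(["rs1", "rs2", "rs3"], {})
        aset = set_from_stats([0.5, 0.4, 0.3], [0.1, 0.1, 0.1])
        assert clump(aset, ld, 0.1).snp_ids == ["rs1", "rs2", "rs3"]

    def test_perfect_proxies_keep_smaller_p(self):
        ld = _ld_from_r2(["rs1", "rs2"], {(0, 1): 1.0})
        aset = set_from_stats([0.3, 0.6], [0.1, 0.1])
        out = clump(aset, ld, 0.1)
        assert out.snp_ids == ["rs2"]  # |z|=6 beats |z|=3

    def test_missing_from_ld_dropped_by_default(self):
        ld = _ld_from_r2(["rs1"], {})
        aset = set_from_stats([0.5, 0.4], [0.1, 0.1])
        assert clump(aset, ld, 0.1).snp_ids == ["rs1"]

    def test_missing_from_ld_kept_when_assumed_independent(self):
        ld = _ld_from_r2(["rs1"], {})
        aset = set_from_stats([0.5, 0.4], [0.1, 0.1])
        out = clump(aset, ld, 0.1, missing_ld="independent")
        assert out.snp_ids == ["rs1", "rs2"]

    def test_no_ld_skips_clumping(self):
        aset = set_from_stats([0.5, 0.4], [0.1, 0.1])
        assert clump(aset, None, 0.1).snp_ids == aset.snp_ids

    @pytest.mark.parametrize("seed", range(10))
    def test_output_pairwise_r2_below_threshold_and_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        q = 30
        ld = simulate_ld(q, rng.uniform(0.3, 0.95), blocks=rng.integers(1, 4))
        betas = rng.normal(0, 0.3, q)
        aset = set_from_stats(betas, np.full(q, 0.1))
        out = clump(aset, ld, 0.1)
        for i, a in enumerate(out.snp_ids):
            for b in out.snp_ids[i + 1 :]:
                assert ld.r2(a, b) < 0.1
        # the globally smallest-p variant always survives
        best = min(aset.records, key=lambda r: (r.pvalue, r.pos, r.snp_id))
        assert best.snp_id in out.snp_ids
        again = clump(out, ld, 0.1)
        assert again.snp_ids == out.snp_ids

    def test_lowering_p_threshold_never_adds_instruments(self, rng):
        q = 25
        ld = simulate_ld(q, 0.8)
        betas = rng.normal(0, 0.4, q)
        aset = set_from_stats(betas, np.full(q, 0.1))
        kept_prev = None
        for thresh in (1e-2, 1e-4, 1e-6):
            out = clump(filter_significant(aset, thresh), ld, 0.1)
            kept = set(out.snp_ids)
            if kept_prev is not None:
                # the stricter pool is a p-sorted prefix of the looser
                # one, so the greedy keep-set shrinks as a subset
                assert kept <= kept_prev
            kept_prev = kept


class TestSelectInstruments:
    def _exposure(self, betas, ses, gene="G1", ct="Mono"):
        q = len(betas)
        records = [
            make_record(
                snp_id=f"rs{i + 1}",
                pos=1_000_000 + i * 1000,
                beta=float(betas[i]),
                se=float(ses[i]),
            )
            for i in range(q)
        ]
        return make_set(records, trait_id=f"{gene}|{ct}")

    def test_single_strong_eqtl_gives_one_instrument(self):
        exposures = [self._exposure([0.8, 0.01], [0.1, 0.1])]
        genes = {"G1": GENE}
        inst, report = select_instruments(
            exposures, genes, simulate_ld(2, 0.0), SelectionParams()
        )
        assert len(inst) == 1 and len(inst[0]) == 1
        assert inst[0].variants[0].snp_id == "rs1"

    def test_two_independent_signals_give_two_instruments(self):
        ld = simulate_ld(2, 0.0)
        exposures = [self._exposure([0.8, -0.7], [0.1, 0.1])]
        inst, _ = select_instruments(
            exposures, {"G1": GENE}, ld, SelectionParams()
        )
        assert len(inst[0]) == 2

    def test_null_locus_emits_nothing(self):
        exposures = [self._exposure([0.01, 0.02], [0.1, 0.1])]
        inst, report = select_instruments(
            exposures, {"G1": GENE}, simulate_ld(2, 0.0), SelectionParams()
        )
        assert inst == []
        assert ("G1", "Mono") in report.empty

    def test_unknown_gene_recorded_as_skip(self):
        exposures = [self._exposure([0.8], [0.1], gene="GX")]
        inst, report = select_instruments(
            exposures, {"G1": GENE}, None, SelectionParams()
        )
        assert inst == [] and report.skipped_genes == ["GX"]
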
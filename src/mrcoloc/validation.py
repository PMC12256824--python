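"""Self-validation studies: oracle comparisons and simulation calibration.

Each function runs one reproducible study against an independent oracle
(brute-force enumeration, closed forms, Monte Carlo truth) or against
the simulator's known generative truth, and returns a flat dict of
metrics. They back the package's calibration checks and the
reproducibility script; problem sizes are arguments so studies can be
scaled.
"""

from __future__ import annotations

import math

import numpy as np

from .coloc import ColocPriors, EffectPrior, coloc_abf, log_abf
from .harmonize import PalindromePolicy, harmonize, retained
from .instruments import InstrumentSet, SelectionParams, clump
from .mr import bh_fdr, ivw, wald_ratio
from .pipeline import PipelineConfig, run_pipeline
from .simulate import Scenario, simulate_ld, simulate_locus, simulate_study
from .sumstats import (
    AssociationSet,
    CellTypeMap,
    Region,
    VariantRecord,
    zscore_pvalue,
)


def _set_from_z(z, se, trait_id="t", chrom="1"):
    records = [
        VariantRecord(
            snp_id=f"rs{i + 1}",
            chrom=chrom,
            pos=100 + i,
            effect_allele="A",
            other_allele="G",
            beta=float(z[i] * se[i]),
            se=float(se[i]),
            pvalue=float(zscore_pvalue(z[i])),
            eaf=0.3,
        )
        for i in range(len(z))
    ]
    return AssociationSet(
        trait_id, records, Region(chrom, 100, 100 + len(z) - 1)
    )


def brute_force_coloc(z1, se1, z2, se2, priors, w1, w2) -> np.ndarray:
    """Posteriors by explicit enumeration over all Q^2 + 2Q + 1
    single-causal-variant configurations (plain space, O(Q^2) loop)."""
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
    weights = np.array(
        [
            1.0,
            priors.p1 * bf1.sum(),
            priors.p2 * bf2.sum(),
            priors.p1
            * priors.p2
            * sum(
                bf1[j] * bf2[k]
                for j in range(q)
                for k in range(q)
                if j != k
            ),
            priors.p12 * float(bf1 @ bf2),
        ]
    )
    return weights / weights.sum()


def coloc_enumeration_study(n_loci: int = 200, seed: int = 0) -> dict:
    """Max relative error of the log-sum-exp posteriors against the
    enumeration oracle over random small loci (Q <= 20)."""
    rng = np.random.default_rng(seed)
    priors = ColocPriors()
    w = EffectPrior().w
    max_rel = 0.0
    for _ in range(n_loci):
        q = int(rng.integers(1, 21))
        z1, z2 = rng.normal(0, 3, q), rng.normal(0, 3, q)
        se1 = rng.uniform(0.02, 0.3, q)
        se2 = rng.uniform(0.02, 0.3, q)
        res = coloc_abf(_set_from_z(z1, se1), _set_from_z(z2, se2), priors)
        oracle = brute_force_coloc(z1, se1, z2, se2, priors, w, w)
        denom = np.maximum(oracle, 1e-300)
        max_rel = max(max_rel, float(np.max(np.abs(res.pph - oracle) / denom)))
    return {"coloc_enumeration_max_rel_err": max_rel, "n": n_loci}


def coloc_symmetry_study(n_loci: int = 100, seed: int = 1) -> dict:
    """Normalization deviation and trait-swap H1/H2 exchange error."""
    rng = np.random.default_rng(seed)
    max_norm_dev = 0.0
    max_swap_dev = 0.0
    for _ in range(n_loci):
        q = int(rng.integers(1, 60))
        z1, z2 = rng.normal(0, 4, q), rng.normal(0, 4, q)
        se1 = rng.uniform(0.01, 0.4, q)
        se2 = rng.uniform(0.01, 0.4, q)
        s1, s2 = _set_from_z(z1, se1, "a"), _set_from_z(z2, se2, "b")
        fwd = coloc_abf(s1, s2)
        rev = coloc_abf(s2, s1)
        max_norm_dev = max(max_norm_dev, abs(float(fwd.pph.sum()) - 1.0))
        swapped = rev.pph[[0, 2, 1, 3, 4]]
        max_swap_dev = max(
            max_swap_dev, float(np.max(np.abs(fwd.pph - swapped)))
        )
    return {
        "coloc_pph_sum_max_dev": max_norm_dev,
        "coloc_swap_max_dev": max_swap_dev,
        "n": n_loci,
    }


def coloc_calibration_study(
    n_loci: int = 500,
    q: int = 500,
    n: int = 10_000,
    causal_variance: float = 0.01,
    seed: int = 2,
) -> dict:
    """Median posteriors under H0, H4, and low-LD H3 loci."""
    out: dict = {"n": n_loci}
    scenarios = {
        "H0": {},
        "H4": {"alpha": None},
        "H3": {"cross_trait_r2_max": 0.01},
    }
    for k, (hyp, extra) in enumerate(scenarios.items()):
        sc = Scenario(
            hypothesis=hyp,
            causal_variance_exp=causal_variance,
            causal_variance_out=causal_variance,
            n_exp=n,
            n_out=n,
            q=q,
            **extra,
        )
        ld = simulate_ld(q, sc.ld_rho)
        rng = np.random.default_rng([seed, k])
        pph = np.empty((n_loci, 5))
        for i in range(n_loci):
            loc = simulate_locus(sc, rng=rng, ld=ld)
            pph[i] = coloc_abf(loc.exposure, loc.outcome).pph
        med = np.median(pph, axis=0)
        idx = {"H0": 0, "H4": 4, "H3": 3}[hyp]
        out[f"median_pph{idx}_under_{hyp.lower()}"] = float(med[idx])
    return out


def mr_recovery_study(
    n_loci: int = 1000,
    alpha: float = 0.2,
    n: int = 50_000,
    causal_variance: float = 0.05,
    seed: int = 3,
) -> dict:
    """Bias and 95% CI coverage of Wald (1 instrument) and IVW
    (3 independent instruments) on mediated loci with known alpha."""
    out: dict = {"n": n_loci, "true_alpha": alpha}

    # single-instrument Wald: top SNP of a one-signal locus
    sc = Scenario(
        hypothesis="H4",
        alpha=alpha,
        causal_variance_exp=causal_variance,
        n_exp=n,
        n_out=n,
        q=50,
    )
    ld = simulate_ld(sc.q, sc.ld_rho)
    rng = np.random.default_rng([seed, 0])
    est = np.empty(n_loci)
    covered = 0
    for i in range(n_loci):
        loc = simulate_locus(sc, rng=rng, ld=ld)
        top = min(loc.exposure.records, key=lambda r: (r.pvalue, r.pos))
        inst = InstrumentSet("G", "c", [top], SelectionParams())
        pair = retained(harmonize(inst, loc.outcome))[0]
        e = wald_ratio(pair)
        est[i] = e.beta
        covered += e.beta - 1.96 * e.se <= alpha <= e.beta + 1.96 * e.se
    out["wald_mean_estimate"] = float(est.mean())
    out["wald_abs_bias"] = float(abs(est.mean() - alpha))
    out["wald_ci95_coverage"] = covered / n_loci

    # three independent instruments: top SNP per LD block, IVW
    sc3 = Scenario(
        hypothesis="H4",
        alpha=alpha,
        causal_variance_exp=causal_variance,
        n_exp=n,
        n_out=n,
        q=60,
        ld_blocks=3,
        n_signals=3,
    )
    ld3 = simulate_ld(sc3.q, sc3.ld_rho, blocks=3)
    rng = np.random.default_rng([seed, 1])
    bounds = np.linspace(0, sc3.q, 4).astype(int)
    est = np.empty(n_loci)
    covered = 0
    for i in range(n_loci):
        loc = simulate_locus(sc3, rng=rng, ld=ld3)
        recs = [
            min(
                loc.exposure.records[lo:hi],
                key=lambda r: (r.pvalue, r.pos),
            )
            for lo, hi in zip(bounds[:-1], bounds[1:])
        ]
        inst = InstrumentSet("G", "c", recs, SelectionParams())
        pairs = retained(harmonize(inst, loc.outcome))
        e = ivw(pairs)
        est[i] = e.beta
        covered += e.beta - 1.96 * e.se <= alpha <= e.beta + 1.96 * e.se
    out["ivw_mean_estimate"] = float(est.mean())
    out["ivw_abs_bias"] = float(abs(est.mean() - alpha))
    out["ivw_ci95_coverage"] = covered / n_loci
    return out


def ivw_wald_identity_study(n_inputs: int = 100, seed: int = 4) -> dict:
    """Max |difference| between fixed-effect IVW on one instrument and
    the first-order Wald ratio, over random inputs."""
    from .harmonize import ACTION_IDENTICAL, HarmonizedPair

    rng = np.random.default_rng(seed)
    max_dev = 0.0
    for _ in range(n_inputs):
        bx = rng.normal(0.5, 0.3)
        if abs(bx) < 1e-3:
            bx = 0.5
        pair = HarmonizedPair(
            snp_id="rs1",
            beta_exp=float(bx),
            se_exp=float(rng.uniform(0.01, 0.2)),
            beta_out=float(rng.normal(0, 0.5)),
            se_out=float(rng.uniform(0.01, 0.5)),
            eaf_exp=0.3,
            eaf_out=0.3,
            action=ACTION_IDENTICAL,
        )
        w = wald_ratio(pair)
        v = ivw([pair], variant="fe")
        max_dev = max(
            max_dev,
            abs(w.beta - v.beta),
            abs(w.se - v.se),
            abs(w.pvalue - v.pvalue),
        )
    return {"ivw_wald_identity_max_dev": max_dev, "n": n_inputs}


def fdr_null_study(
    n_tests: int = 10_000, n_reps: int = 40, seed: int = 5
) -> dict:
    """Empirical FDR of BH at q < 0.05 on globally null MR batches.

    Null Wald tests are generated through the estimator itself (strong
    fixed exposure, zero-mean outcome noise), so their p-values are
    uniform by construction of the model, not by fiat.
    """
    from .harmonize import ACTION_IDENTICAL, HarmonizedPair

    rng = np.random.default_rng(seed)
    fdps = np.empty(n_reps)
    for r in range(n_reps):
        by = rng.normal(0.0, 0.05, n_tests)
        pvals = np.empty(n_tests)
        for i in range(n_tests):
            pair = HarmonizedPair(
                snp_id="rs1",
                beta_exp=0.5,
                se_exp=0.05,
                beta_out=float(by[i]),
                se_out=0.05,
                eaf_exp=0.3,
                eaf_out=0.3,
                action=ACTION_IDENTICAL,
            )
            pvals[i] = wald_ratio(pair).pvalue
        q = bh_fdr(pvals)
        n_disc = int((q < 0.05).sum())
        fdps[r] = n_disc / max(n_disc, 1) if n_disc else 0.0
    mc_se = float(fdps.std(ddof=1) / math.sqrt(n_reps))
    return {
        "null_fdr_at_q05": float(fdps.mean()),
        "null_fdr_mc_se": mc_se,
        "n": n_tests * n_reps,
    }


def clump_harmonize_invariant_study(
    n_ld: int = 200, n_pairs: int = 1000, seed: int = 6
) -> dict:
    """Counts of violations of the clumping invariants (pairwise r2,
    idempotence) and the harmonization flip-invariance property."""
    rng = np.random.default_rng(seed)
    r2_violations = 0
    idempotence_failures = 0
    for _ in range(n_ld):
        q = int(rng.integers(5, 40))
        ld = simulate_ld(
            q, float(rng.uniform(0.2, 0.95)), blocks=int(rng.integers(1, 4))
        )
        z = rng.normal(0, 3, q)
        se = np.full(q, 0.1)
        aset = _set_from_z(z, se)
        out = clump(aset, ld, 0.1)
        for i, a in enumerate(out.snp_ids):
            for b in out.snp_ids[i + 1 :]:
                if ld.r2(a, b) >= 0.1:
                    r2_violations += 1
        if clump(out, ld, 0.1).snp_ids != out.snp_ids:
            idempotence_failures += 1

    alleles = [("A", "G"), ("C", "A"), ("T", "G"), ("G", "T")]
    flip_failures = 0
    policy = PalindromePolicy()
    for _ in range(n_pairs):
        ea, oa = alleles[int(rng.integers(4))]
        beta_out = float(rng.normal(0, 0.5))
        eaf_out = float(rng.uniform(0.01, 0.99))

        def _one(ea_o, oa_o, b, f):
            rec = VariantRecord(
                "rs1", "1", 100, ea_o, oa_o, b, 0.1,
                float(zscore_pvalue(b / 0.1)), eaf=f,
            )
            outcome = AssociationSet("o", [rec], Region("1", 100, 100))
            exp_rec = VariantRecord(
                "rs1", "1", 100, ea, oa, 0.5, 0.1,
                float(zscore_pvalue(5.0)), eaf=0.3,
            )
            exp = AssociationSet("e", [exp_rec], Region("1", 100, 100))
            return harmonize(exp, outcome, policy)[0]

        p1 = _one(ea, oa, beta_out, eaf_out)
        p2 = _one(oa, ea, -beta_out, 1 - eaf_out)
        if p1.retained != p2.retained or (
            p1.retained and abs(p1.beta_out - p2.beta_out) > 1e-12
        ):
            flip_failures += 1
    return {
        "clump_r2_violations": r2_violations,
        "clump_idempotence_failures": idempotence_failures,
        "harmonize_flip_failures": flip_failures,
        "n": n_ld + n_pairs,
    }


def funnel_study(
    n_genes: int = 60,
    n_h4: int = 15,
    n_h3: int = 15,
    seed: int = 7,
) -> dict:
    """End-to-end screen on a synthetic study: sensitivity on mediated
    gene x cell-type pairs, removal of LD-confounded genes at the coloc
    stage, and funnel monotonicity."""
    sc = Scenario(
        hypothesis="H4",
        alpha=0.2,
        causal_variance_exp=0.05,
        causal_variance_out=0.01,
        n_exp=10_000,
        n_out=50_000,
        q=100,
    )
    ctmap = CellTypeMap({"Mono_C": "Mono", "Mono_NC": "Mono", "B": "B"})
    bundle = simulate_study(
        n_genes=n_genes,
        n_h4=n_h4,
        n_h3=n_h3,
        scenario=sc,
        cell_type_map=ctmap,
        seed=seed,
    )
    pri, funnel = run_pipeline(
        bundle.discovery_exposures,
        bundle.replication_exposures,
        bundle.outcomes,
        bundle.genes,
        bundle.ld,
        bundle.cell_type_map,
        PipelineConfig(),
    )
    truth = bundle.truth
    positives = {
        (r.gene_id, r.causal_cell_type)
        for r in truth[truth["label"] == "H4"].itertuples()
    }
    final = (
        {
            (r.gene_id, r.discovery_cell_type)
            for r in pri[pri["final_pass"]].itertuples()
        }
        if len(pri)
        else set()
    )
    sensitivity = len(final & positives) / max(len(positives), 1)

    h3_genes = set(truth[truth["label"] == "H3"]["gene_id"])
    h3_both_mr = (
        pri[pri["pass_replication"] & pri["gene_id"].isin(h3_genes)]
        if len(pri)
        else pri
    )
    if len(h3_both_mr):
        h3_removal = float((~h3_both_mr["pass_coloc"]).mean())
    else:
        h3_removal = 1.0  # nothing to remove: vacuously clean
    monotone = (
        funnel["n_discovery_pass"] <= funnel["n_discovery_tests"]
        and funnel["n_replication_pass"] <= funnel["n_replication_tests"]
        and funnel["n_final_pass"] <= funnel["n_replication_pass"]
    )
    return {
        "funnel_sensitivity_h4_pairs": float(sensitivity),
        "h3_removed_at_coloc_fraction": h3_removal,
        "n_h3_past_both_mr": int(len(h3_both_mr)),
        "funnel_monotone": bool(monotone),
        **funnel,
        "n": n_genes,
    }
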
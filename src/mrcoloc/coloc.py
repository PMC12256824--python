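"""Bayesian colocalization from summary statistics.

Given the marginal associations of two traits across a shared locus,
enumerate the five causal configurations — H0: neither trait has a
causal variant; H1/H2: only trait 1/2 does; H3: both do, but different
variants; H4: both share one causal variant — and compute their
posterior probabilities from per-SNP approximate Bayes factors (ABFs)
under the one-causal-variant-per-trait assumption.

For loci that may carry several independent association signals, a
stepwise conditional decomposition splits each trait's statistics into
per-signal conditional sets; colocalization is then run on every cross
pair of signals and the maximum PPH4 over pairs is reported. This is a
deliberate lightweight alternative to sum-of-single-effects
fine-mapping: it shares the goal (one coloc test per signal pair) but
not the algorithm, and is documented as an approximation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .sumstats import AssociationSet, LDMatrix, zscore_pvalue

logger = logging.getLogger("mrcoloc")


@dataclass(frozen=True)
class ColocPriors:
    """Per-SNP prior probabilities: p1/p2 for a variant causal for one
    trait only, p12 for a shared causal variant. Defaults are the
    established single-SNP priors p1 = p2 = 1e-4, p12 = 1e-5."""

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "p12"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1)")
        if self.p12 > min(self.p1, self.p2):
            raise ValueError("p12 must not exceed min(p1, p2)")

    def check_locus_size(self, q: int) -> None:
        if q * (self.p1 + self.p2 + self.p12) >= 1:
            logger.warning(
                "priors sum to >= 1 over %d SNPs; posteriors remain "
                "normalized but the prior model is saturated",
                q,
            )


@dataclass(frozen=True)
class EffectPrior:
    """Prior SD of a true effect at a causal SNP (W = prior_sd^2).

    Defaults follow the established colocalization convention: 0.15 on
    the standardized-trait scale for quantitative traits and 0.2 on the
    log-odds scale for case-control traits.
    """

    trait_type: str = "quantitative"
    prior_sd: float | None = None

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "case_control"):
            raise ValueError(f"bad trait_type {self.trait_type!r}")
        if self.prior_sd is None:
            object.__setattr__(
                self,
                "prior_sd",
                0.15 if self.trait_type == "quantitative" else 0.2,
            )
        if not (self.prior_sd > 0):
            raise ValueError("prior_sd must be > 0")

    @property
    def w(self) -> float:
        return self.prior_sd**2


@dataclass
class ColocResult:
    """Posterior probabilities of the five hypotheses for one locus.

    ``pph[i]`` is PPH_i; they sum to 1. In multi-signal mode
    ``signal_pairs`` holds one ColocResult per cross pair of conditional
    signals and ``max_pph4`` their maximum PPH4; in single-signal mode
    ``max_pph4`` equals ``pph[4]``.
    """

    pph: np.ndarray
    n_snps: int
    priors: ColocPriors
    prior_sd1: float
    prior_sd2: float
    snp_pp_h4: np.ndarray | None = None
    snp_ids: list[str] | None = None
    signal_pairs: list["ColocResult"] | None = None
    max_pph4: float = 0.0

    def __post_init__(self) -> None:
        if self.signal_pairs is None and self.max_pph4 == 0.0:
            self.max_pph4 = float(self.pph[4])

    @property
    def pph4(self) -> float:
        return float(self.pph[4])

    def passes(self, threshold: float = 0.8) -> bool:
        return self.max_pph4 >= threshold


def log_abf(
    beta: np.ndarray | float,
    se: np.ndarray | float,
    prior: EffectPrior,
) -> np.ndarray | float:
    """Log approximate Bayes factor for association at one SNP.

    With z = beta/se, V = se^2 and shrinkage r = W/(W + V):
    log ABF = 0.5 * (log(1 - r) + r * z^2). Tends to 0 as W -> 0 and is
    increasing in |z| for fixed V.
    """
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be > 0")
    beta = np.asarray(beta, dtype=float)
    v = se**2
    r = prior.w / (prior.w + v)
    z = beta / se
    out = 0.5 * (np.log1p(-r) + r * z**2)
    return out if out.ndim else float(out)


def _log_diff_exp(a: float, b: float) -> float:
    """log(e^a - e^b) for a >= b, clamped to -inf when the difference
    underflows (warned)."""
    if b >= a:
        if b > a + 1e-9:
            logger.warning("negative H3 mass clamped to 0")
        return -np.inf
    return a + math.log1p(-math.exp(b - a))


def coloc_abf(
    set1: AssociationSet,
    set2: AssociationSet,
    priors: ColocPriors | None = None,
    prior1: EffectPrior | None = None,
    prior2: EffectPrior | None = None,
) -> ColocResult:
    """Five-hypothesis colocalization over the shared variants.

    All configuration sums run in log space (log-sum-exp); the H3 term
    (e^{S1+S2} - e^{S12}) uses a stable log-diff-exp. Results are
    orientation-insensitive (only z^2 enters the ABFs), but inputs are
    expected on a consistent allele alignment for auditability.
    """
    priors = priors or ColocPriors()
    prior1 = prior1 or EffectPrior()
    prior2 = prior2 or EffectPrior()
    ids2 = set(set2.snp_ids)
    shared = [s for s in set1.snp_ids if s in ids2]
    q = len(shared)
    if q == 0:
        raise ValueError(
            f"no shared variants between {set1.trait_id} and {set2.trait_id}"
        )
    priors.check_locus_size(q)
    s1 = set1.subset(shared)
    s2 = set2.subset(shared)
    # align set2 to set1's order
    order2 = {r.snp_id: r for r in s2.records}
    l1 = np.asarray(log_abf(s1.betas, s1.ses, prior1))
    b2 = np.array([order2[s].beta for s in shared])
    e2 = np.array([order2[s].se for s in shared])
    l2 = np.asarray(log_abf(b2, e2, prior2))

    s1_sum = float(logsumexp(l1))
    s2_sum = float(logsumexp(l2))
    s12_sum = float(logsumexp(l1 + l2))

    log_l = np.array(
        [
            0.0,
            math.log(priors.p1) + s1_sum,
            math.log(priors.p2) + s2_sum,
            math.log(priors.p1) + math.log(priors.p2)
            + _log_diff_exp(s1_sum + s2_sum, s12_sum),
            math.log(priors.p12) + s12_sum,
        ]
    )
    pph = np.exp(log_l - logsumexp(log_l))
    pph /= pph.sum()
    # per-SNP posterior of being the shared causal variant, given H4
    snp_pp_h4 = np.exp(l1 + l2 - s12_sum)
    return ColocResult(
        pph=pph,
        n_snps=q,
        priors=priors,
        prior_sd1=prior1.prior_sd,
        prior_sd2=prior2.prior_sd,
        snp_pp_h4=snp_pp_h4,
        snp_ids=shared,
    )


# ---------------------------------------------------------------------------
# multi-signal mode: stepwise conditional decomposition
# ---------------------------------------------------------------------------


def conditional_stats(
    aset: AssociationSet,
    ld: LDMatrix,
    index_snps: list[str],
    ridge: float = 1e-6,
) -> AssociationSet:
    """Association statistics conditioned on a set of index SNPs.

    z_j|S = (z_j - R_{j,S} R_{S,S}^-1 z_S) / sqrt(1 - R_{j,S} R_{S,S}^-1
    R_{S,j}); each record keeps its SE and gets beta = z_cond * se, so z
    and se are preserved by construction. Index SNPs themselves get
    z = 0. A small ridge stabilizes R_{S,S}.
    """
    if not index_snps:
        return aset
    missing = [s for s in index_snps if s not in ld or s not in set(aset.snp_ids)]
    if missing:
        raise ValueError(f"index SNPs not available for conditioning: {missing}")
    snps = aset.snp_ids
    idx_all = [ld.index(s) for s in snps]
    idx_s = [ld.index(s) for s in index_snps]
    r_full = ld.r
    r_ss = r_full[np.ix_(idx_s, idx_s)] + ridge * np.eye(len(idx_s))
    try:
        r_ss_inv = np.linalg.inv(r_ss)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular LD submatrix for {index_snps}") from exc
    z = aset.zscores
    z_s = np.array([z[snps.index(s)] for s in index_snps])
    r_js = r_full[np.ix_(idx_all, idx_s)]
    proj = r_js @ r_ss_inv
    num = z - proj @ z_s
    denom2 = 1.0 - np.einsum("ij,ij->i", proj, r_js)
    denom2 = np.clip(denom2, 0.0, None)
    index_set = set(index_snps)
    records = []
    for j, rec in enumerate(aset.records):
        if rec.snp_id in index_set or denom2[j] < 1e-12:
            z_cond = 0.0
        else:
            z_cond = float(num[j] / math.sqrt(denom2[j]))
        new = rec.__class__(**{**rec.__dict__})
        new.beta = z_cond * rec.se
        new.pvalue = float(zscore_pvalue(z_cond))
        records.append(new)
    return AssociationSet(
        trait_id=aset.trait_id, records=records, region=aset.region
    )


def decompose_signals(
    aset: AssociationSet,
    ld: LDMatrix,
    p_enter: float = 1e-6,
    max_signals: int = 10,
    ridge: float = 1e-6,
) -> list[AssociationSet]:
    """Forward stepwise decomposition into independent signals.

    Repeatedly add the smallest conditional-p SNP while it beats
    ``p_enter``, up to ``max_signals``; then emit one conditional set per
    selected index, conditioned on all the *other* indices, so each set
    carries one signal. A null locus yields an empty list.
    """
    usable = [s for s in aset.snp_ids if s in ld]
    if len(usable) < len(aset.snp_ids):
        logger.warning(
            "%s: %d variant(s) absent from LD reference excluded from "
            "signal decomposition",
            aset.trait_id,
            len(aset.snp_ids) - len(usable),
        )
    work = aset.subset(usable)
    selected: list[str] = []
    while len(selected) < max_signals:
        cond = conditional_stats(work, ld, selected, ridge=ridge)
        remaining = [r for r in cond.records if r.snp_id not in selected]
        if not remaining:
            break
        best = min(remaining, key=lambda r: (r.pvalue, r.pos, r.snp_id))
        if best.pvalue >= p_enter:
            break
        selected.append(best.snp_id)
    if not selected:
        return []
    if len(selected) == 1:
        return [work]
    return [
        conditional_stats(
            work, ld, [s for s in selected if s != index], ridge=ridge
        )
        for index in selected
    ]


def coloc_multi(
    set1: AssociationSet,
    set2: AssociationSet,
    ld: LDMatrix,
    priors: ColocPriors | None = None,
    prior1: EffectPrior | None = None,
    prior2: EffectPrior | None = None,
    p_enter: float = 1e-6,
    max_signals: int = 10,
    ridge: float = 1e-6,
) -> ColocResult:
    """Colocalization allowing several causal variants per trait.

    Each trait is decomposed into conditional signals; coloc runs on
    every cross pair (falling back to a trait's marginal statistics when
    it has at most one signal) and the maximum PPH4 across pairs is
    reported. The headline ``pph`` is the best pair's posterior.
    """
    sig1 = decompose_signals(set1, ld, p_enter, max_signals, ridge) or [set1]
    sig2 = decompose_signals(set2, ld, p_enter, max_signals, ridge) or [set2]
    pairs: list[ColocResult] = []
    for a in sig1:
        for b in sig2:
            pairs.append(coloc_abf(a, b, priors, prior1, prior2))
    if len(pairs) == 1:
        return pairs[0]
    best = max(pairs, key=lambda r: r.pph4)
    return ColocResult(
        pph=best.pph.copy(),
        n_snps=best.n_snps,
        priors=best.priors,
        prior_sd1=best.prior_sd1,
        prior_sd2=best.prior_sd2,
        snp_pp_h4=best.snp_pp_h4,
        snp_ids=best.snp_ids,
        signal_pairs=pairs,
        max_pph4=max(r.pph4 for r in pairs),
    )
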
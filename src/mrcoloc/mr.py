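"""Two-sample Mendelian-randomization estimators and batch execution.

Causal effects of gene expression on an outcome are estimated from
harmonized summary statistics: the Wald ratio beta_out / beta_exp when a
single instrument is available, and the inverse-variance-weighted (IVW)
combination across instruments otherwise. p-values come from the
standard normal (the summary-statistics convention), and families of
tests are corrected with the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .harmonize import HarmonizedPair, PalindromePolicy, harmonize, retained
from .instruments import InstrumentSet
from .sumstats import AssociationSet, zscore_pvalue

logger = logging.getLogger("mrcoloc")

METHOD_WALD = "wald_ratio"
METHOD_IVW_FE = "ivw_fe"
METHOD_IVW_MRE = "ivw_mre"


@dataclass
class MREstimate:
    """A causal-effect estimate (per unit log-expression) for one
    exposure/outcome pair, with its FDR-adjusted q-value."""

    exposure_id: str
    outcome_id: str
    method: str
    beta: float
    se: float
    pvalue: float
    n_snps: int
    qvalue: float | None = None


@dataclass
class MRConfig:
    """Batch-MR settings.

    ``method="auto"`` uses the Wald ratio for single-instrument exposures
    and IVW otherwise. The IVW default is multiplicative random effects
    with the max(1, phi) variance floor; ``fdr_family`` groups the BH
    correction per outcome (default) or over the whole batch.
    """

    method: str = "auto"  # auto | wald | ivw
    ivw_variant: str = "mre"  # fe | mre
    wald_se_method: str = "first_order"  # first_order | second_order
    fdr_family: str = "per_outcome"  # per_outcome | global
    significance_level: float = 0.05
    palindrome_policy: PalindromePolicy = field(default_factory=PalindromePolicy)


def wald_ratio(
    pair: HarmonizedPair,
    se_method: str = "first_order",
    exposure_id: str = "",
    outcome_id: str = "",
) -> MREstimate:
    """Single-instrument causal estimate beta_out / beta_exp.

    ``first_order`` SE (the default, ignoring exposure-side noise):
    se_out / |beta_exp|. ``second_order`` adds the delta-method term for
    the exposure: sqrt(se_out^2/bx^2 + by^2 * se_exp^2 / bx^4).
    """
    if pair.beta_exp == 0:
        raise ZeroDivisionError("Wald ratio undefined: exposure beta is 0")
    bx, by = pair.beta_exp, pair.beta_out
    beta = by / bx
    if se_method == "first_order":
        se = pair.se_out / abs(bx)
    elif se_method == "second_order":
        se = math.sqrt(
            pair.se_out**2 / bx**2 + by**2 * pair.se_exp**2 / bx**4
        )
    else:
        raise ValueError(f"bad se_method {se_method!r}")
    return MREstimate(
        exposure_id=exposure_id,
        outcome_id=outcome_id,
        method=METHOD_WALD,
        beta=beta,
        se=se,
        pvalue=float(zscore_pvalue(beta / se)),
        n_snps=1,
    )


def ivw(
    pairs: Sequence[HarmonizedPair],
    variant: str = "mre",
    exposure_id: str = "",
    outcome_id: str = "",
) -> MREstimate:
    """Inverse-variance-weighted combination of per-variant ratios.

    Equivalent to the zero-intercept WLS of beta_out on beta_exp with
    weights 1/se_out^2. Fixed effect (``fe``): se = (sum w)^-1/2 with
    w = beta_exp^2/se_out^2. Multiplicative random effects (``mre``):
    the fe SE is inflated by max(1, phi) where phi is the weighted
    residual SD about the fit; a single instrument forces fe.
    """
    if len(pairs) == 0:
        raise ValueError("ivw requires at least one harmonized pair")
    if variant not in ("fe", "mre"):
        raise ValueError(f"bad ivw variant {variant!r}")
    bx = np.array([p.beta_exp for p in pairs])
    by = np.array([p.beta_out for p in pairs])
    so = np.array([p.se_out for p in pairs])
    if np.any(so <= 0):
        raise ValueError("all se_out must be > 0")
    w = bx**2 / so**2
    beta = float(np.sum(bx * by / so**2) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    k = len(pairs)
    method = METHOD_IVW_FE
    if variant == "mre" and k > 1:
        phi2 = float(np.sum((by - beta * bx) ** 2 / so**2) / (k - 1))
        se *= max(1.0, math.sqrt(phi2))
        method = METHOD_IVW_MRE
    return MREstimate(
        exposure_id=exposure_id,
        outcome_id=outcome_id,
        method=method,
        beta=beta,
        se=se,
        pvalue=float(zscore_pvalue(beta / se)),
        n_snps=k,
    )


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1, returned in the
    input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def estimate_for_pairs(
    pairs: Sequence[HarmonizedPair],
    config: MRConfig,
    exposure_id: str = "",
    outcome_id: str = "",
) -> MREstimate:
    """Dispatch Wald vs IVW per the configured method."""
    use_wald = config.method == "wald" or (
        config.method == "auto" and len(pairs) == 1
    )
    if use_wald:
        if len(pairs) != 1:
            raise ValueError("wald method requires exactly one instrument")
        return wald_ratio(
            pairs[0],
            se_method=config.wald_se_method,
            exposure_id=exposure_id,
            outcome_id=outcome_id,
        )
    return ivw(
        pairs,
        variant=config.ivw_variant,
        exposure_id=exposure_id,
        outcome_id=outcome_id,
    )


def run_mr_batch(
    instruments: Sequence[InstrumentSet],
    outcomes: Sequence[AssociationSet],
    config: MRConfig | None = None,
) -> pd.DataFrame:
    """One MR estimate per gene x cell-type x outcome combination.

    Exposures with no harmonizable instrument against an outcome are
    skipped (logged). q-values are BH-adjusted within the configured FDR
    family; ``significant`` flags q below the configured level.
    """
    config = config or MRConfig()
    rows = []
    for outcome in outcomes:
        for inst in instruments:
            try:
                pairs = retained(
                    harmonize(inst, outcome, config.palindrome_policy)
                )
            except Exception as exc:  # no shared variants etc.
                logger.info(
                    "skip %s vs %s: %s", inst.trait_id, outcome.trait_id, exc
                )
                continue
            if not pairs:
                logger.info(
                    "skip %s vs %s: no retained instrument after "
                    "harmonization",
                    inst.trait_id,
                    outcome.trait_id,
                )
                continue
            est = estimate_for_pairs(
                pairs, config, exposure_id=inst.trait_id,
                outcome_id=outcome.trait_id,
            )
            rows.append(
                {
                    "gene_id": inst.gene_id,
                    "cell_type": inst.cell_type,
                    "exposure_id": inst.trait_id,
                    "outcome_id": outcome.trait_id,
                    "method": est.method,
                    "n_snps": est.n_snps,
                    "beta": est.beta,
                    "se": est.se,
                    "pvalue": est.pvalue,
                }
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "cell_type",
            "exposure_id",
            "outcome_id",
            "method",
            "n_snps",
            "beta",
            "se",
            "pvalue",
        ],
    )
    if len(table):
        table["qvalue"] = apply_fdr(
            table["pvalue"].to_numpy(),
            table["outcome_id"].to_numpy(),
            config.fdr_family,
        )
        table["significant"] = table["qvalue"] < config.significance_level
    else:
        table["qvalue"] = pd.Series(dtype=float)
        table["significant"] = pd.Series(dtype=bool)
    return table


def apply_fdr(
    pvalues: np.ndarray, outcome_ids: np.ndarray, fdr_family: str
) -> np.ndarray:
    """BH adjustment within the configured family structure."""
    if fdr_family == "global":
        return bh_fdr(pvalues)
    if fdr_family != "per_outcome":
        raise ValueError(f"bad fdr_family {fdr_family!r}")
    q = np.empty(len(pvalues))
    for outcome in np.unique(outcome_ids):
        mask = outcome_ids == outcome
        q[mask] = bh_fdr(pvalues[mask])
    return q


def weighted_pearson(
    x: np.ndarray, y: np.ndarray, w: np.ndarray
) -> float:
    """Weighted Pearson correlation with weighted means."""
    w = np.asarray(w, dtype=float)
    xm = x - np.average(x, weights=w)
    ym = y - np.average(y, weights=w)
    denom = math.sqrt(np.sum(w * xm**2) * np.sum(w * ym**2))
    if denom == 0:
        return float("nan")
    return float(np.sum(w * xm * ym) / denom)


def estimate_correlation_matrix(
    tables: Mapping[str, pd.DataFrame],
    weight_scheme: str = "precision",
) -> pd.DataFrame:
    """Pairwise weighted Pearson correlation of MR estimates between
    cell types (or bulk), aligned on shared (gene, outcome) keys.

    Weights: ``precision`` uses 1/(se_x^2 + se_y^2), the precision of
    the difference of the two estimates; ``equal`` reduces to the plain
    Pearson correlation. Pairs with fewer than two shared estimates get
    NaN with a warning.
    """
    labels = list(tables)
    out = pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)
    indexed = {
        lab: t.set_index(["gene_id", "outcome_id"]) for lab, t in tables.items()
    }
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            ta, tb = indexed[a], indexed[b]
            shared = ta.index.intersection(tb.index)
            if len(shared) < 2:
                logger.warning(
                    "correlation %s vs %s: <2 shared estimates; entry "
                    "left missing",
                    a,
                    b,
                )
                out.loc[a, b] = out.loc[b, a] = np.nan
                continue
            x = ta.loc[shared, "beta"].to_numpy(dtype=float)
            y = tb.loc[shared, "beta"].to_numpy(dtype=float)
            if weight_scheme == "equal":
                w = np.ones(len(shared))
            elif weight_scheme == "precision":
                sx = ta.loc[shared, "se"].to_numpy(dtype=float)
                sy = tb.loc[shared, "se"].to_numpy(dtype=float)
                w = 1.0 / (sx**2 + sy**2)
            else:
                raise ValueError(f"bad weight_scheme {weight_scheme!r}")
            out.loc[a, b] = out.loc[b, a] = weighted_pearson(x, y, w)
    return out
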
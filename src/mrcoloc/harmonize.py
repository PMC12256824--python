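"""Allele harmonization between exposure instruments and outcome GWAS.

Two-sample MR needs the exposure and outcome effects expressed per copy
of the same allele. For each shared variant the outcome record is
aligned to the exposure's effect allele, resolving label swaps (negate
beta, flip eaf) and strand flips (complement alleles, then align).
Palindromic variants (A/T, G/C) are strand-ambiguous: they are either
dropped outright or resolved from allele frequencies when both sides are
clearly away from 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .instruments import InstrumentSet
from .sumstats import AssociationSet, VariantRecord

logger = logging.getLogger("mrcoloc")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

ACTION_IDENTICAL = "identical"
ACTION_SWAPPED = "swapped"
ACTION_STRAND_FLIPPED = "strand_flipped"
ACTION_STRAND_FLIPPED_SWAPPED = "strand_flipped_swapped"
ACTION_DROPPED_PALINDROME = "dropped_palindrome"
ACTION_DROPPED_MISMATCH = "dropped_mismatch"

DROP_ACTIONS = frozenset({ACTION_DROPPED_PALINDROME, ACTION_DROPPED_MISMATCH})


class HarmonizationError(ValueError):
    """No shared variants between exposure and outcome."""


@dataclass(frozen=True)
class PalindromePolicy:
    """What to do with strand-ambiguous (A/T, G/C) variants.

    ``infer_by_frequency`` aligns a palindrome from allele frequencies
    when both sides' minor-allele frequencies are at most
    ``maf_ambiguity_threshold`` (and drops it otherwise, or when either
    eaf is missing); ``drop_all`` drops every palindrome. The default
    threshold 0.42 matches the common harmonization convention.
    """

    mode: str = "infer_by_frequency"
    maf_ambiguity_threshold: float = 0.42

    def __post_init__(self) -> None:
        if self.mode not in ("drop_all", "infer_by_frequency"):
            raise ValueError(f"bad palindrome mode {self.mode!r}")
        if not (0 < self.maf_ambiguity_threshold < 0.5):
            raise ValueError("maf_ambiguity_threshold must be in (0, 0.5)")


@dataclass
class HarmonizedPair:
    """One variant's aligned exposure/outcome effects, plus the action
    taken to align them (retained iff action is not a dropped_* code)."""

    snp_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: float | None
    eaf_out: float | None
    action: str

    @property
    def retained(self) -> bool:
        return self.action not in DROP_ACTIONS


def is_palindromic(ea: str, oa: str) -> bool:
    return {ea, oa} in ({"A", "T"}, {"C", "G"})


def _complement(allele: str) -> str:
    return "".join(_COMPLEMENT[b] for b in allele)


def _pair(exp: VariantRecord, out_beta, out_eaf, action, se_out) -> HarmonizedPair:
    return HarmonizedPair(
        snp_id=exp.snp_id,
        beta_exp=exp.beta,
        se_exp=exp.se,
        beta_out=out_beta,
        se_out=se_out,
        eaf_exp=exp.eaf,
        eaf_out=out_eaf,
        action=action,
    )


def harmonize_variant(
    exp: VariantRecord,
    out: VariantRecord,
    policy: PalindromePolicy,
) -> HarmonizedPair:
    """Align one outcome record to the exposure's effect allele."""
    result = _pair(exp, out.beta, out.eaf, ACTION_DROPPED_MISMATCH, out.se)

    if not exp.is_snv() or not out.is_snv():
        # INDELs / multi-allelic representations: cannot strand-resolve
        return result

    ea_e, oa_e = exp.effect_allele, exp.other_allele
    ea_o, oa_o = out.effect_allele, out.other_allele

    if is_palindromic(ea_e, oa_e):
        if {ea_o, oa_o} != {ea_e, oa_e}:
            return result
        # nominal alignment from labels (strand-uninformative)
        if (ea_o, oa_o) == (ea_e, oa_e):
            beta, eaf = out.beta, out.eaf
            nominal = ACTION_IDENTICAL
        else:
            beta = -out.beta
            eaf = None if out.eaf is None else 1.0 - out.eaf
            nominal = ACTION_SWAPPED
        if policy.mode == "drop_all":
            return _pair(exp, beta, eaf, ACTION_DROPPED_PALINDROME, out.se)
        if exp.eaf is None or eaf is None:
            return _pair(exp, beta, eaf, ACTION_DROPPED_PALINDROME, out.se)
        maf_e = min(exp.eaf, 1 - exp.eaf)
        maf_o = min(eaf, 1 - eaf)
        if (
            maf_e > policy.maf_ambiguity_threshold
            or maf_o > policy.maf_ambiguity_threshold
        ):
            return _pair(exp, beta, eaf, ACTION_DROPPED_PALINDROME, out.se)
        if (exp.eaf - 0.5) * (eaf - 0.5) < 0:
            # discordant frequencies: the outcome is on the other strand,
            # which for a palindrome is the allele swap
            return _pair(exp, -beta, 1.0 - eaf, ACTION_STRAND_FLIPPED_SWAPPED, out.se)
        return _pair(exp, beta, eaf, nominal, out.se)

    # non-palindromic SNV
    if (ea_o, oa_o) == (ea_e, oa_e):
        return _pair(exp, out.beta, out.eaf, ACTION_IDENTICAL, out.se)
    if (ea_o, oa_o) == (oa_e, ea_e):
        return _pair(
            exp,
            -out.beta,
            None if out.eaf is None else 1.0 - out.eaf,
            ACTION_SWAPPED,
            out.se,
        )
    ea_c, oa_c = _complement(ea_o), _complement(oa_o)
    if (ea_c, oa_c) == (ea_e, oa_e):
        return _pair(exp, out.beta, out.eaf, ACTION_STRAND_FLIPPED, out.se)
    if (ea_c, oa_c) == (oa_e, ea_e):
        return _pair(
            exp,
            -out.beta,
            None if out.eaf is None else 1.0 - out.eaf,
            ACTION_STRAND_FLIPPED_SWAPPED,
            out.se,
        )
    return result  # irreconcilable alleles


def harmonize(
    exposure: InstrumentSet | AssociationSet,
    outcome: AssociationSet,
    policy: PalindromePolicy | None = None,
) -> list[HarmonizedPair]:
    """Harmonize every shared variant; raises if none are shared.

    Returns one :class:`HarmonizedPair` per shared snp_id (in exposure
    order) including dropped ones, whose action code records why — the
    audit trail the output TSV carries.
    """
    policy = policy or PalindromePolicy()
    exp_records = (
        exposure.variants
        if isinstance(exposure, InstrumentSet)
        else exposure.records
    )
    exp_id = (
        exposure.trait_id
        if isinstance(exposure, (InstrumentSet, AssociationSet))
        else "exposure"
    )
    out_by_id = {r.snp_id: r for r in outcome.records}
    shared = [r for r in exp_records if r.snp_id in out_by_id]
    if not shared:
        raise HarmonizationError(
            f"no shared variants between {exp_id} and {outcome.trait_id}"
        )
    pairs = [
        harmonize_variant(exp, out_by_id[exp.snp_id], policy) for exp in shared
    ]
    n_drop = sum(not p.retained for p in pairs)
    if n_drop:
        logger.info(
            "%s vs %s: %d/%d shared variant(s) dropped in harmonization",
            exp_id,
            outcome.trait_id,
            n_drop,
            len(pairs),
        )
    return pairs


def retained(pairs: list[HarmonizedPair]) -> list[HarmonizedPair]:
    return [p for p in pairs if p.retained]
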
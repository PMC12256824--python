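"""cis-window definition, significance filtering, and LD clumping.

Instruments for a gene x cell-type exposure are cis-eQTLs inside a window
around the gene (either flanking the gene body, the convention of the
discovery source, or centred on the gene midpoint, the convention of the
replication and bulk sources), kept at an association p-value threshold
and greedily pruned to approximate pairwise LD independence (r-squared
below a ceiling, lowest p first).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .sumstats import (
    AssociationSet,
    GeneAnnotation,
    LDMatrix,
    Region,
    split_exposure_trait_id,
)

logger = logging.getLogger("mrcoloc")


@dataclass(frozen=True)
class SelectionParams:
    """Instrument-selection tuning.

    Defaults follow the common single-cell cis-eQTL convention: a
    1,000-kb window flanking the gene body, p < 1e-5 significance, and
    clumping at r-squared < 0.1.
    """

    window_mode: str = "flank_gene"  # or "midpoint"
    window_bp: int = 1_000_000
    p_threshold: float = 1e-5
    r2_threshold: float = 0.1

    def __post_init__(self) -> None:
        if self.window_mode not in ("flank_gene", "midpoint"):
            raise ValueError(f"bad window_mode {self.window_mode!r}")
        if self.window_bp <= 0:
            raise ValueError("window_bp must be > 0")
        if not (0 < self.p_threshold < 1):
            raise ValueError("p_threshold must be in (0, 1)")
        if not (0 < self.r2_threshold <= 1):
            raise ValueError("r2_threshold must be in (0, 1]")


@dataclass
class InstrumentSet:
    """Selected, approximately independent eQTL instruments for one
    gene x cell-type exposure."""

    gene_id: str
    cell_type: str
    variants: list  # of VariantRecord
    params: SelectionParams
    source_label: str = "discovery"

    @property
    def trait_id(self) -> str:
        return f"{self.gene_id}|{self.cell_type}"

    def __len__(self) -> int:
        return len(self.variants)


@dataclass
class SelectionReport:
    """Per-gene bookkeeping: emitted, empty, and skipped combinations."""

    emitted: list[tuple[str, str]] = field(default_factory=list)
    empty: list[tuple[str, str]] = field(default_factory=list)
    skipped_genes: list[str] = field(default_factory=list)
    dropped_no_ld: int = 0


def cis_window(gene: GeneAnnotation, params: SelectionParams) -> Region:
    """The cis region for a gene under the configured window mode.

    ``flank_gene``: [start - window_bp, end + window_bp].
    ``midpoint``: +/- window_bp around floor((start + end) / 2).
    The lower bound is clamped at 1.
    """
    if params.window_mode == "flank_gene":
        lo, hi = gene.start - params.window_bp, gene.end + params.window_bp
    else:
        mid = (gene.start + gene.end) // 2
        lo, hi = mid - params.window_bp, mid + params.window_bp
    return Region(gene.chrom, max(1, lo), hi)


def filter_significant(aset: AssociationSet, p_threshold: float) -> AssociationSet:
    """Subset to records with p < threshold, preserving input order."""
    return AssociationSet(
        trait_id=aset.trait_id,
        records=[r for r in aset.records if r.pvalue < p_threshold],
        region=aset.region,
    )


def clump(
    aset: AssociationSet,
    ld: LDMatrix | None,
    r2_threshold: float,
    missing_ld: str = "drop",
) -> AssociationSet:
    """Greedy LD clumping: repeatedly keep the smallest-p unremoved
    variant and remove all others correlated with it at r2 >= threshold.

    Ties on p break by smaller position, then lexicographic snp_id, for
    determinism across platforms. Variants absent from the LD reference
    are dropped with a warning (``missing_ld="drop"``) or treated as
    independent (``missing_ld="independent"``, for pre-pruned sources
    without LD coverage). ``ld=None`` skips clumping with a logged notice.
    """
    if ld is None:
        logger.info(
            "%s: no LD reference supplied; clumping skipped", aset.trait_id
        )
        return aset
    if missing_ld not in ("drop", "independent"):
        raise ValueError(f"bad missing_ld {missing_ld!r}")

    records = list(aset.records)
    if missing_ld == "drop":
        absent = [r for r in records if r.snp_id not in ld]
        if absent:
            logger.warning(
                "%s: %d variant(s) absent from LD reference dropped before "
                "clumping",
                aset.trait_id,
                len(absent),
            )
        records = [r for r in records if r.snp_id in ld]

    remaining = sorted(records, key=lambda r: (r.pvalue, r.pos, r.snp_id))
    kept_ids: list[str] = []
    while remaining:
        index = remaining.pop(0)
        kept_ids.append(index.snp_id)
        if index.snp_id in ld:
            remaining = [
                r
                for r in remaining
                if r.snp_id not in ld
                or ld.r2(index.snp_id, r.snp_id) < r2_threshold
            ]
        # index absent from LD (independent mode): removes nothing
    keep = set(kept_ids)
    return AssociationSet(
        trait_id=aset.trait_id,
        records=[r for r in aset.records if r.snp_id in keep],
        region=aset.region,
    )


def select_instruments(
    exposures: list[AssociationSet],
    genes: dict[str, GeneAnnotation],
    ld: LDMatrix | dict[str, LDMatrix] | None,
    params: SelectionParams,
    source_label: str = "discovery",
    missing_ld: str = "drop",
) -> tuple[list[InstrumentSet], SelectionReport]:
    """Window restriction -> significance filter -> clump, per exposure.

    ``ld`` may be a single LD reference, a per-gene mapping, or None (no
    clumping). Gene x cell-type combinations with no surviving variant
    are reported but not emitted; exposures whose gene is missing from
    the annotation are recorded as skips.
    """
    report = SelectionReport()
    out: list[InstrumentSet] = []
    for aset in exposures:
        gene_id, cell_type = split_exposure_trait_id(aset.trait_id)
        gene = genes.get(gene_id)
        if gene is None:
            logger.warning("gene %s absent from annotation; skipped", gene_id)
            report.skipped_genes.append(gene_id)
            continue
        region = cis_window(gene, params)
        windowed = aset.restrict(region)
        sig = filter_significant(windowed, params.p_threshold)
        gene_ld = ld.get(gene_id) if isinstance(ld, dict) else ld
        clumped = clump(sig, gene_ld, params.r2_threshold, missing_ld=missing_ld)
        if len(clumped) == 0:
            report.empty.append((gene_id, cell_type))
            continue
        report.emitted.append((gene_id, cell_type))
        out.append(
            InstrumentSet(
                gene_id=gene_id,
                cell_type=cell_type,
                variants=list(clumped.records),
                params=params,
                source_label=source_label,
            )
        )
    return out, report
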
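"""Three-stage screen: discovery MR -> replication MR -> colocalization.

Stage 1 tests every gene x cell-type exposure against every outcome and
keeps FDR-significant estimates. Stage 2 re-tests the survivors in an
independent replication source after coarsening cell-type labels
(many-to-one), with BH correction within the survivor family. Stage 3
asks whether each surviving exposure/outcome pair shares a causal
variant (PPH4, multi-signal when more than one instrument was used) —
the guard against MR hits driven by LD between distinct causal variants
rather than mediation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coloc import ColocPriors, ColocResult, EffectPrior, coloc_abf, coloc_multi
from .harmonize import harmonize, retained
from .instruments import InstrumentSet, SelectionParams, select_instruments
from .mr import MRConfig, apply_fdr, estimate_for_pairs
from .sumstats import (
    AssociationSet,
    CellTypeMap,
    GeneAnnotation,
    LDMatrix,
)

logger = logging.getLogger("mrcoloc")


@dataclass
class PipelineConfig:
    """Thresholds and settings of the three-stage screen.

    Defaults: q < 0.05 at both MR stages, PPH4 >= 0.8 at the
    colocalization stage, the standard instrument-selection settings for
    each stage, and the established colocalization priors.
    """

    discovery_params: SelectionParams = field(
        default_factory=lambda: SelectionParams("flank_gene", 1_000_000)
    )
    replication_params: SelectionParams = field(
        default_factory=lambda: SelectionParams("midpoint", 100_000)
    )
    mr: MRConfig = field(default_factory=MRConfig)
    fdr_level: float = 0.05
    coloc_priors: ColocPriors = field(default_factory=ColocPriors)
    exposure_prior: EffectPrior = field(default_factory=EffectPrior)
    outcome_prior: EffectPrior = field(default_factory=EffectPrior)
    pph4_threshold: float = 0.8
    coloc_p_enter: float = 1e-6
    coloc_max_signals: int = 10
    missing_ld: str = "drop"
    outdir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fdr_level", "pph4_threshold"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1)")


def map_cell_types(
    hits: pd.DataFrame, ctmap: CellTypeMap
) -> pd.DataFrame:
    """Relabel discovery hits with replication (coarse) cell types and
    deduplicate on (gene, replication cell type, outcome).

    Raises KeyError listing any discovery label missing from the map.
    """
    unmapped = sorted(
        {ct for ct in hits["cell_type"] if ct not in ctmap}
    )
    if unmapped:
        raise KeyError(f"cell types missing from map: {unmapped}")
    mapped = hits.copy()
    mapped["replication_cell_type"] = [ctmap[ct] for ct in mapped["cell_type"]]
    return mapped.drop_duplicates(
        subset=["gene_id", "replication_cell_type", "outcome_id"]
    )


def _harmonized_mr(
    inst: InstrumentSet,
    outcome: AssociationSet,
    config: MRConfig,
):
    pairs = retained(harmonize(inst, outcome, config.palindrome_policy))
    if not pairs:
        raise ValueError("no retained instrument after harmonization")
    est = estimate_for_pairs(
        pairs, config, exposure_id=inst.trait_id, outcome_id=outcome.trait_id
    )
    return est, pairs


def _stage_mr(
    instruments: Sequence[InstrumentSet],
    outcome_sets: Mapping[str, list[AssociationSet]],
    config: PipelineConfig,
    keep: set[tuple[str, str, str]] | None = None,
) -> pd.DataFrame:
    """MR of each instrument set against each outcome's locus statistics.

    ``outcome_sets`` maps outcome id -> per-locus AssociationSets (a
    genome-wide GWAS split by locus); the set sharing variants with the
    instruments is used. ``keep`` optionally restricts to given
    (gene, cell_type, outcome) keys.
    """
    rows = []
    for outcome_id, loci in outcome_sets.items():
        for inst in instruments:
            if keep is not None and (
                inst.gene_id, inst.cell_type, outcome_id
            ) not in keep:
                continue
            inst_ids = {v.snp_id for v in inst.variants}
            locus = next(
                (o for o in loci if inst_ids & set(o.snp_ids)), None
            )
            if locus is None:
                logger.info(
                    "skip %s vs %s: no outcome statistics at locus",
                    inst.trait_id,
                    outcome_id,
                )
                continue
            try:
                est, pairs = _harmonized_mr(inst, locus, config.mr)
            except Exception as exc:
                logger.info(
                    "skip %s vs %s: %s", inst.trait_id, outcome_id, exc
                )
                continue
            rows.append(
                {
                    "gene_id": inst.gene_id,
                    "cell_type": inst.cell_type,
                    "outcome_id": outcome_id,
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
            config.mr.fdr_family,
        )
        table["significant"] = table["qvalue"] < config.fdr_level
    else:
        table["qvalue"] = pd.Series(dtype=float)
        table["significant"] = pd.Series(dtype=bool)
    return table


def _group_outcomes(
    outcomes: Sequence[AssociationSet],
) -> dict[str, list[AssociationSet]]:
    grouped: dict[str, list[AssociationSet]] = {}
    for o in outcomes:
        grouped.setdefault(o.trait_id, []).append(o)
    return grouped


def run_pipeline(
    discovery_exposures: Sequence[AssociationSet],
    replication_exposures: Sequence[AssociationSet],
    outcomes: Sequence[AssociationSet],
    genes: Mapping[str, GeneAnnotation],
    ld: LDMatrix | Mapping[str, LDMatrix] | None,
    cell_type_map: CellTypeMap,
    config: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Run the full screen; returns (prioritized table, funnel counts).

    The returned table has one row per discovery hit carried into
    replication, with per-stage estimates and pass flags; ``final_pass``
    is the conjunction of the three stage criteria. The funnel reports
    stage-by-stage counts. Deterministic given identical inputs and
    config.
    """
    config = config or PipelineConfig()
    genes = dict(genes)
    outcome_sets = _group_outcomes(outcomes)

    # stage 1: discovery MR + FDR
    disc_inst, disc_report = select_instruments(
        list(discovery_exposures),
        genes,
        ld,
        config.discovery_params,
        source_label="discovery",
        missing_ld=config.missing_ld,
    )
    disc_mr = _stage_mr(disc_inst, outcome_sets, config)
    disc_pass = disc_mr[disc_mr["significant"]].copy()

    # stage 2: replication MR on coarse cell types, survivor family FDR
    if len(disc_pass):
        rep_targets = map_cell_types(disc_pass, cell_type_map)
    else:
        rep_targets = disc_pass.assign(replication_cell_type=[])
    rep_keys = {
        (r.gene_id, r.replication_cell_type, r.outcome_id)
        for r in rep_targets.itertuples()
    }
    rep_inst, rep_report = select_instruments(
        list(replication_exposures),
        genes,
        ld,
        config.replication_params,
        source_label="replication",
        missing_ld=config.missing_ld,
    )
    rep_mr = _stage_mr(rep_inst, outcome_sets, config, keep=rep_keys)
    rep_pass = rep_mr[rep_mr["significant"]]
    rep_pass_keys = {
        (r.gene_id, r.cell_type, r.outcome_id) for r in rep_pass.itertuples()
    }

    # stage 3: colocalization of the discovery exposure's full-region
    # statistics against the outcome, for stage-2 survivors
    disc_by_trait = {e.trait_id: e for e in discovery_exposures}
    inst_by_trait = {i.trait_id: i for i in disc_inst}
    coloc_rows = {}
    for row in rep_targets.itertuples():
        key = (row.gene_id, row.replication_cell_type, row.outcome_id)
        if key not in rep_pass_keys:
            continue
        exp = disc_by_trait.get(f"{row.gene_id}|{row.cell_type}")
        inst = inst_by_trait.get(f"{row.gene_id}|{row.cell_type}")
        if exp is None or inst is None:
            continue
        loci = outcome_sets[row.outcome_id]
        exp_ids = set(exp.snp_ids)
        locus = next((o for o in loci if exp_ids & set(o.snp_ids)), None)
        if locus is None:
            continue
        gene_ld = ld.get(row.gene_id) if isinstance(ld, Mapping) else ld
        try:
            if len(inst.variants) > 1 and gene_ld is not None:
                res = coloc_multi(
                    exp,
                    locus,
                    gene_ld,
                    config.coloc_priors,
                    config.exposure_prior,
                    config.outcome_prior,
                    p_enter=config.coloc_p_enter,
                    max_signals=config.coloc_max_signals,
                )
            else:
                res = coloc_abf(
                    exp,
                    locus,
                    config.coloc_priors,
                    config.exposure_prior,
                    config.outcome_prior,
                )
        except Exception as exc:
            logger.warning(
                "coloc failed for %s vs %s: %s",
                exp.trait_id,
                row.outcome_id,
                exc,
            )
            continue
        coloc_rows[(row.gene_id, row.cell_type, row.outcome_id)] = res

    # assemble prioritized table over all discovery hits taken forward
    rep_idx = rep_mr.set_index(["gene_id", "cell_type", "outcome_id"])
    out_rows = []
    for row in rep_targets.itertuples():
        rep_key = (row.gene_id, row.replication_cell_type, row.outcome_id)
        rep_hit = (
            rep_idx.loc[rep_key] if rep_key in rep_idx.index else None
        )
        res: ColocResult | None = coloc_rows.get(
            (row.gene_id, row.cell_type, row.outcome_id)
        )
        pass_rep = bool(rep_hit is not None and rep_hit["significant"])
        pass_coloc = bool(res is not None and res.passes(config.pph4_threshold))
        out_rows.append(
            {
                "gene_id": row.gene_id,
                "discovery_cell_type": row.cell_type,
                "replication_cell_type": row.replication_cell_type,
                "outcome_id": row.outcome_id,
                "disc_beta": row.beta,
                "disc_se": row.se,
                "disc_pvalue": row.pvalue,
                "disc_qvalue": row.qvalue,
                "disc_n_snps": row.n_snps,
                "rep_beta": np.nan if rep_hit is None else rep_hit["beta"],
                "rep_se": np.nan if rep_hit is None else rep_hit["se"],
                "rep_pvalue": np.nan if rep_hit is None else rep_hit["pvalue"],
                "rep_qvalue": np.nan if rep_hit is None else rep_hit["qvalue"],
                "pph0": np.nan if res is None else res.pph[0],
                "pph1": np.nan if res is None else res.pph[1],
                "pph2": np.nan if res is None else res.pph[2],
                "pph3": np.nan if res is None else res.pph[3],
                "pph4": np.nan if res is None else res.pph[4],
                "max_pph4": np.nan if res is None else res.max_pph4,
                "pass_discovery": True,
                "pass_replication": pass_rep,
                "pass_coloc": pass_coloc,
                "final_pass": pass_rep and pass_coloc,
            }
        )
    prioritized = pd.DataFrame(out_rows)
    if len(prioritized) == 0:
        prioritized = pd.DataFrame(
            columns=[
                "gene_id",
                "discovery_cell_type",
                "replication_cell_type",
                "outcome_id",
                "final_pass",
            ]
        )

    funnel = {
        "n_discovery_tests": int(len(disc_mr)),
        "n_discovery_pass": int(len(disc_pass)),
        "n_replication_tests": int(len(rep_mr)),
        "n_replication_pass": int(len(rep_pass)),
        "n_coloc_tests": int(len(coloc_rows)),
        "n_final_pass": (
            int(prioritized["final_pass"].sum()) if len(prioritized) else 0
        ),
    }
    if config.outdir:
        _write_outputs(config.outdir, disc_mr, rep_mr, prioritized, funnel)
    return prioritized, funnel


def _write_outputs(outdir, disc_mr, rep_mr, prioritized, funnel) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    disc_mr.to_csv(out / "discovery_mr.tsv", sep="\t", index=False)
    rep_mr.to_csv(out / "replication_mr.tsv", sep="\t", index=False)
    coloc_cols = [
        c
        for c in prioritized.columns
        if c.startswith("pph") or c == "max_pph4"
    ]
    prioritized.to_csv(out / "prioritized.tsv", sep="\t", index=False)
    if coloc_cols:
        prioritized[
            ["gene_id", "discovery_cell_type", "outcome_id", *coloc_cols]
        ].to_csv(out / "coloc.tsv", sep="\t", index=False)
    with open(out / "funnel.txt", "w") as fh:
        for key, value in funnel.items():
            fh.write(f"{key}\t{value}\n")
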
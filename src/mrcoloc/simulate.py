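"""Synthetic LD-structured summary statistics for MR + colocalization.

Marginal association statistics at a locus are generated directly in
z-space from the standard multivariate-normal model: if standardized
per-SNP causal effects are b and the LD correlation matrix is R, the
marginal z-vector is distributed MVN(sqrt(n) * R * b, R). No
individual-level genotypes are simulated — this is exact for the
summary-statistics methods under test and fast enough for calibration
studies at locus sizes in the hundreds of SNPs.

Traits are on the standardized scale (SD = 1), so the quantitative-trait
colocalization effect prior applies without rescaling. Dosage-scale
betas and SEs are recovered via se_j = 1/sqrt(2 n f_j (1 - f_j)) and
beta_j = z_j * se_j; case-control outcomes use the effective-n
approximation se_j ~ 1/sqrt(2 n phi (1 - phi) f_j (1 - f_j)) with case
fraction phi.

Scenarios cover the five colocalization hypotheses. Under H4 with a
mediated effect, the outcome's causal effect at the shared variant is
alpha times the exposure's, so the true Wald ratio at that variant is
exactly alpha. Under H3 the two traits' causal variants are distinct,
with their LD capped at ``cross_trait_r2_max``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .sumstats import (
    AssociationSet,
    CellTypeMap,
    GeneAnnotation,
    LDMatrix,
    Region,
    VariantRecord,
    exposure_trait_id,
    zscore_pvalue,
)

logger = logging.getLogger("mrcoloc")

_HYPOTHESES = ("H0", "H1", "H2", "H3", "H4")


@dataclass(frozen=True)
class Scenario:
    """Generative settings for one synthetic locus.

    ``causal_variance_exp``/``_out`` are the fractions of trait variance
    explained by each causal variant; ``ld_rho`` the AR(1) correlation
    decay within an LD block; ``n_signals`` the causal variants per
    trait; ``cross_trait_r2_max`` the LD ceiling between the two traits'
    causal variants under H3. When ``alpha`` is given under H4 the
    outcome effect is alpha times the exposure effect (mediation);
    otherwise the outcome draws its own effect size from
    ``causal_variance_out``.
    """

    hypothesis: str = "H4"
    alpha: float | None = 0.2
    causal_variance_exp: float = 0.05
    causal_variance_out: float = 0.01
    n_exp: int = 10_000
    n_out: int = 50_000
    q: int = 100
    ld_rho: float = 0.9
    ld_blocks: int = 1
    n_signals: int = 1
    cross_trait_r2_max: float = 0.5
    outcome_case_fraction: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hypothesis not in _HYPOTHESES:
            raise ValueError(f"bad hypothesis {self.hypothesis!r}")
        for name in ("causal_variance_exp", "causal_variance_out"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1)")
        if self.alpha is not None and not np.isfinite(self.alpha):
            raise ValueError("alpha must be finite")
        if self.q < 1:
            raise ValueError("q must be >= 1")
        if not (abs(self.ld_rho) < 1):
            raise ValueError("|ld_rho| must be < 1")
        if self.hypothesis == "H3" and self.q < 2:
            raise ValueError("H3 needs at least 2 SNPs")


@dataclass
class LocusTruth:
    """Realized generative state of one simulated locus."""

    scenario: Scenario
    causal_exp: list[int] = field(default_factory=list)
    causal_out: list[int] = field(default_factory=list)
    b_exp: np.ndarray | None = None
    b_out: np.ndarray | None = None


@dataclass
class SimulatedLocus:
    truth: LocusTruth
    ld: LDMatrix
    exposure: AssociationSet
    outcome: AssociationSet
    eafs: np.ndarray | None = None


def simulate_ld(
    q: int, ld_rho: float, blocks: int = 1, seed: int | None = None
) -> LDMatrix:
    """Block-diagonal AR(1) LD: within a block r_ij = ld_rho^|i-j|, zero
    between blocks. Positive semi-definite by construction; the seed is
    accepted for interface symmetry (the matrix is deterministic)."""
    del seed
    if blocks < 1 or blocks > q:
        raise ValueError("blocks must be in [1, q]")
    bounds = np.linspace(0, q, blocks + 1).astype(int)
    r = np.zeros((q, q))
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        idx = np.arange(lo, hi)
        r[np.ix_(idx, idx)] = ld_rho ** np.abs(
            np.subtract.outer(idx, idx)
        )
    np.fill_diagonal(r, 1.0)
    snp_ids = [f"rs{i + 1}" for i in range(q)]
    return LDMatrix(snp_ids, r)


def _choose_spread_indices(
    rng: np.random.Generator, ld: LDMatrix, k: int, r2_cap: float = 0.1
) -> list[int]:
    """k causal indices with pairwise r2 below the cap (greedy random)."""
    q = len(ld.snp_ids)
    order = rng.permutation(q)
    chosen: list[int] = []
    for i in order:
        if all(ld.r[i, j] ** 2 < r2_cap for j in chosen):
            chosen.append(int(i))
        if len(chosen) == k:
            return chosen
    raise ValueError(
        f"cannot place {k} causal variants at pairwise r2 < {r2_cap}"
    )


def _partner_index(ld: LDMatrix, i: int, r2_max: float) -> int:
    """The SNP with the largest r2 to i not exceeding the cap — the
    'most confounded admissible' H3 partner (deterministic given LD)."""
    r2 = ld.r[i] ** 2
    candidates = [j for j in range(len(r2)) if j != i and r2[j] <= r2_max]
    if not candidates:
        raise ValueError(f"no H3 partner with r2 <= {r2_max} for index {i}")
    return max(candidates, key=lambda j: (r2[j], -abs(j - i)))


def _marginal_records(
    z: np.ndarray,
    eafs: np.ndarray,
    n: int,
    region: Region,
    positions: np.ndarray,
    snp_ids: Sequence[str],
    case_fraction: float | None = None,
) -> list[VariantRecord]:
    if case_fraction is None:
        se = 1.0 / np.sqrt(2.0 * n * eafs * (1.0 - eafs))
        trait_type = "quantitative"
    else:
        se = 1.0 / np.sqrt(
            2.0 * n * case_fraction * (1.0 - case_fraction) * eafs * (1.0 - eafs)
        )
        trait_type = "case_control"
    beta = z * se
    pvals = zscore_pvalue(z)
    return [
        VariantRecord(
            snp_id=snp_ids[j],
            chrom=region.chrom,
            pos=int(positions[j]),
            effect_allele="A",
            other_allele="G",
            eaf=float(eafs[j]),
            beta=float(beta[j]),
            se=float(se[j]),
            pvalue=float(pvals[j]),
            n=float(n),
            trait_type=trait_type,
            case_fraction=case_fraction,
        )
        for j in range(len(snp_ids))
    ]


def _draw_z(
    rng: np.random.Generator,
    chol: np.ndarray,
    r: np.ndarray,
    b: np.ndarray,
    n: int,
) -> np.ndarray:
    mu = np.sqrt(n) * (r @ b)
    return mu + chol @ rng.standard_normal(len(b))


def _signed_effects(
    rng: np.random.Generator, indices: Sequence[int], variance: float, q: int
) -> np.ndarray:
    b = np.zeros(q)
    for i in indices:
        b[i] = rng.choice([-1.0, 1.0]) * np.sqrt(variance)
    return b


def _chol(r: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(r)
    except np.linalg.LinAlgError:
        return np.linalg.cholesky(r + 1e-9 * np.eye(len(r)))


def simulate_locus(
    scenario: Scenario,
    rng: np.random.Generator | None = None,
    ld: LDMatrix | None = None,
    gene_id: str = "GENE",
    cell_type: str = "CT",
    outcome_id: str = "outcome",
    region: Region | None = None,
) -> SimulatedLocus:
    """One locus: LD, exposure and outcome marginal statistics, truth.

    EAFs ~ Uniform(0.05, 0.5) are drawn once and shared by both traits
    (the same variants in the same population). Causal configurations
    follow the scenario's hypothesis; see the module docstring for the
    generative model.
    """
    rng = rng or np.random.default_rng(scenario.seed)
    ld = ld or simulate_ld(scenario.q, scenario.ld_rho, scenario.ld_blocks)
    q = len(ld.snp_ids)
    region = region or Region("1", 1_000_000, 1_000_000 + (q - 1) * 1_000)
    positions = region.start + np.arange(q) * max(
        1, (region.end - region.start) // max(1, q - 1)
    )
    eafs = rng.uniform(0.05, 0.5, size=q)
    truth = LocusTruth(scenario=scenario)

    h = scenario.hypothesis
    if h in ("H1", "H3", "H4"):
        truth.causal_exp = _choose_spread_indices(rng, ld, scenario.n_signals)
    if h == "H4":
        truth.causal_out = list(truth.causal_exp)
    elif h == "H3":
        truth.causal_out = [
            _partner_index(ld, i, scenario.cross_trait_r2_max)
            for i in truth.causal_exp
        ]
    elif h == "H2":
        truth.causal_out = _choose_spread_indices(rng, ld, scenario.n_signals)

    b_exp = _signed_effects(
        rng, truth.causal_exp, scenario.causal_variance_exp, q
    )
    if h == "H4" and scenario.alpha is not None:
        b_out = scenario.alpha * b_exp
    else:
        b_out = _signed_effects(
            rng, truth.causal_out, scenario.causal_variance_out, q
        )
    truth.b_exp, truth.b_out = b_exp, b_out

    chol = _chol(ld.r)
    z_exp = _draw_z(rng, chol, ld.r, b_exp, scenario.n_exp)
    z_out = _draw_z(rng, chol, ld.r, b_out, scenario.n_out)

    exposure = AssociationSet(
        trait_id=exposure_trait_id(gene_id, cell_type),
        records=_marginal_records(
            z_exp, eafs, scenario.n_exp, region, positions, ld.snp_ids
        ),
        region=region,
    )
    outcome = AssociationSet(
        trait_id=outcome_id,
        records=_marginal_records(
            z_out,
            eafs,
            scenario.n_out,
            region,
            positions,
            ld.snp_ids,
            case_fraction=scenario.outcome_case_fraction,
        ),
        region=region,
    )
    return SimulatedLocus(
        truth=truth, ld=ld, exposure=exposure, outcome=outcome, eafs=eafs
    )


# ---------------------------------------------------------------------------
# multi-gene, multi-cell-type study bundles
# ---------------------------------------------------------------------------


@dataclass
class StudyBundle:
    """A full synthetic two-stage study: discovery and replication
    exposures, shared outcomes, per-gene LD, annotations, and truth."""

    discovery_exposures: list[AssociationSet]
    replication_exposures: list[AssociationSet]
    outcomes: list[AssociationSet]
    genes: dict[str, GeneAnnotation]
    ld: dict[str, LDMatrix]
    cell_type_map: CellTypeMap
    truth: pd.DataFrame


def _locus_rng(seed: int, *keys: int) -> np.random.Generator:
    """Child generator derived deterministically from (seed, keys), so
    any locus is reproducible in isolation."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, keys)]))


def simulate_study(
    n_genes: int = 60,
    cell_types: Sequence[str] = ("Mono_C", "Mono_NC", "B"),
    cell_type_map: CellTypeMap | None = None,
    n_h4: int = 15,
    n_h3: int = 15,
    scenario: Scenario | None = None,
    n_rep: int | None = None,
    outcome_id: str = "outcome",
    seed: int = 0,
) -> StudyBundle:
    """A two-stage synthetic study over many gene loci.

    Genes are assigned truth labels: ``n_h4`` mediated (a shared causal
    variant with outcome effect alpha x exposure effect, active in one
    randomly designated cell type), ``n_h3`` LD-confounded (distinct
    exposure/outcome causal variants), and the rest null. Each gene has
    its own locus (LD, EAFs); cell types share the locus but draw
    independent marginal noise (an approximation — real cell types share
    donors). Replication exposures re-draw the noise at ``n_rep``
    (default: the discovery sample size) under the coarse labels of
    ``cell_type_map``; the single outcome is shared by both stages.
    """
    if n_h4 + n_h3 > n_genes:
        raise ValueError("n_h4 + n_h3 must not exceed n_genes")
    scenario = scenario or Scenario()
    cell_type_map = cell_type_map or CellTypeMap(
        {ct: ct for ct in cell_types}
    )
    n_rep = n_rep or scenario.n_exp
    rep_types = sorted(set(cell_type_map.apply(cell_types)))

    labels = ["H4"] * n_h4 + ["H3"] * n_h3 + ["null"] * (n_genes - n_h4 - n_h3)
    assign_rng = _locus_rng(seed, 0)
    assign_rng.shuffle(labels)

    discovery: list[AssociationSet] = []
    replication: list[AssociationSet] = []
    outcomes: list[AssociationSet] = []
    genes: dict[str, GeneAnnotation] = {}
    ld_by_gene: dict[str, LDMatrix] = {}
    truth_rows = []

    ld = simulate_ld(scenario.q, scenario.ld_rho, scenario.ld_blocks)
    chol = _chol(ld.r)

    for g in range(n_genes):
        gene_id = f"G{g + 1:04d}"
        label = labels[g]
        locus_rng = _locus_rng(seed, 1, g)
        # each gene on its own chromosome-like coordinate frame
        chrom = str(g % 22 + 1)
        start = 1_000_000 + (g // 22) * 10_000_000
        region = Region(chrom, start, start + (scenario.q - 1) * 1_000)
        positions = start + np.arange(scenario.q) * 1_000
        gene_body = GeneAnnotation(
            gene_id=gene_id,
            chrom=chrom,
            start=int(positions[scenario.q // 2]),
            end=int(positions[scenario.q // 2]) + 10_000,
        )
        genes[gene_id] = gene_body
        gene_ld = LDMatrix(
            [f"{gene_id}_rs{i + 1}" for i in range(scenario.q)], ld.r
        )
        ld_by_gene[gene_id] = gene_ld
        eafs = locus_rng.uniform(0.05, 0.5, size=scenario.q)

        designated = (
            str(locus_rng.choice(list(cell_types))) if label != "null" else ""
        )
        # causal configuration (shared by all cell types of this gene)
        causal_exp: list[int] = []
        causal_out: list[int] = []
        if label in ("H4", "H3"):
            causal_exp = _choose_spread_indices(
                locus_rng, gene_ld, scenario.n_signals
            )
            if label == "H4":
                causal_out = list(causal_exp)
            else:
                causal_out = [
                    _partner_index(gene_ld, i, scenario.cross_trait_r2_max)
                    for i in causal_exp
                ]
        b_exp = _signed_effects(
            locus_rng, causal_exp, scenario.causal_variance_exp, scenario.q
        )
        if label == "H4":
            b_out = (scenario.alpha or 0.0) * b_exp
        elif label == "H3":
            b_out = _signed_effects(
                locus_rng, causal_out, scenario.causal_variance_out, scenario.q
            )
        else:
            b_out = np.zeros(scenario.q)

        z_out = _draw_z(locus_rng, chol, ld.r, b_out, scenario.n_out)
        outcomes.append(
            AssociationSet(
                trait_id=outcome_id,
                records=_marginal_records(
                    z_out,
                    eafs,
                    scenario.n_out,
                    region,
                    positions,
                    gene_ld.snp_ids,
                    case_fraction=scenario.outcome_case_fraction,
                ),
                region=region,
            )
        )

        for c, ct in enumerate(cell_types):
            active = label != "null" and ct == designated
            b_ct = b_exp if active else np.zeros(scenario.q)
            ct_rng = _locus_rng(seed, 2, g, c)
            z = _draw_z(ct_rng, chol, ld.r, b_ct, scenario.n_exp)
            discovery.append(
                AssociationSet(
                    trait_id=exposure_trait_id(gene_id, ct),
                    records=_marginal_records(
                        z,
                        eafs,
                        scenario.n_exp,
                        region,
                        positions,
                        gene_ld.snp_ids,
                    ),
                    region=region,
                )
            )
        for c, rct in enumerate(rep_types):
            active = (
                label != "null" and designated and cell_type_map[designated] == rct
            )
            b_ct = b_exp if active else np.zeros(scenario.q)
            rep_rng = _locus_rng(seed, 3, g, c)
            z = _draw_z(rep_rng, chol, ld.r, b_ct, n_rep)
            replication.append(
                AssociationSet(
                    trait_id=exposure_trait_id(gene_id, rct),
                    records=_marginal_records(
                        z, eafs, n_rep, region, positions, gene_ld.snp_ids
                    ),
                    region=region,
                )
            )

        truth_rows.append(
            {
                "gene_id": gene_id,
                "label": label,
                "causal_cell_type": designated,
                "replication_cell_type": (
                    cell_type_map[designated] if designated else ""
                ),
                "alpha": scenario.alpha if label == "H4" else 0.0,
                "causal_exp": ",".join(map(str, causal_exp)),
                "causal_out": ",".join(map(str, causal_out)),
            }
        )

    return StudyBundle(
        discovery_exposures=discovery,
        replication_exposures=replication,
        outcomes=outcomes,
        genes=genes,
        ld=ld_by_gene,
        cell_type_map=cell_type_map,
        truth=pd.DataFrame(truth_rows),
    )
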
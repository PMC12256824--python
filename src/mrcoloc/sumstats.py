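"""Typed data model and I/O for GWAS/eQTL summary statistics.

Conventions
-----------
* Coordinates are 1-based and inclusive throughout, matching the usual
  GWAS summary-statistics convention.
* Alleles are assumed to be reported on the forward strand; strand flips
  are resolved only during exposure/outcome harmonization.
* Effect sizes (``beta``) are additive per copy of the effect allele;
  for case-control traits they are log odds ratios.

Files are plain TSV with a configurable header dialect; LD references are
a whitespace-delimited square matrix plus a one-column ``.snplist`` file,
the convention used by common LD-reference exports.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("mrcoloc")

VALID_BASES = frozenset("ACGT")

#: Smallest p-value ever reported; two-sided normal tails underflow at
#: |z| ~ 38.6 and a literal 0 would violate the p in (0, 1] contract.
P_FLOOR = 1e-300

#: Below this p the stored value is at/near the floor and the p-vs-z
#: consistency check is meaningless; downstream math uses z anyway.
_P_CHECK_FLOOR = 1e-250


class SumstatsError(ValueError):
    """Malformed or inconsistent summary-statistics input."""


class Region(NamedTuple):
    """A 1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


def zscore_pvalue(z: float | np.ndarray) -> float | np.ndarray:
    """Two-sided normal p-value for a z statistic, floored at P_FLOOR."""
    return np.maximum(2.0 * stats.norm.sf(np.abs(z)), P_FLOOR)


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------


@dataclass
class VariantRecord:
    """One marginal association: a variant's effect on one trait.

    ``beta`` is the additive effect per effect-allele copy (log-OR for
    case-control traits), ``se`` its standard error, ``eaf`` the
    effect-allele frequency (may be missing), ``n`` the sample size.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    eaf: float | None = None
    n: float | None = None
    trait_type: str = "quantitative"
    case_fraction: float | None = None

    @property
    def z(self) -> float:
        return self.beta / self.se

    def is_snv(self) -> bool:
        return (
            len(self.effect_allele) == 1
            and len(self.other_allele) == 1
            and self.effect_allele in VALID_BASES
            and self.other_allele in VALID_BASES
        )

    def validate(self, p_z_log10_tol: float = 0.5) -> None:
        """Raise SumstatsError on a hard invariant breach.

        A p-value inconsistent with |beta/se| under the two-sided normal
        (|Δlog10 p| > ``p_z_log10_tol``) is only warned about, and p is
        recomputed from beta/se: every downstream formula uses z, not the
        file's p.
        """
        if not self.snp_id:
            raise SumstatsError("empty snp_id")
        if self.pos < 1:
            raise SumstatsError(f"{self.snp_id}: position must be >= 1")
        if not (self.se > 0) or not math.isfinite(self.se):
            raise SumstatsError(f"{self.snp_id}: se must be > 0")
        if not math.isfinite(self.beta):
            raise SumstatsError(f"{self.snp_id}: beta must be finite")
        if not (0 < self.pvalue <= 1):
            raise SumstatsError(f"{self.snp_id}: pvalue must be in (0, 1]")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise SumstatsError(f"{self.snp_id}: eaf must be in [0, 1]")
        if self.n is not None and not (self.n > 0):
            raise SumstatsError(f"{self.snp_id}: n must be > 0")
        for allele in (self.effect_allele, self.other_allele):
            if not allele or allele != allele.upper():
                raise SumstatsError(f"{self.snp_id}: bad allele {allele!r}")
            if len(allele) == 1 and allele not in VALID_BASES:
                raise SumstatsError(f"{self.snp_id}: allele {allele!r} not in ACGT")
        if self.trait_type not in ("quantitative", "case_control"):
            raise SumstatsError(f"{self.snp_id}: bad trait_type {self.trait_type!r}")
        if self.trait_type == "case_control":
            if self.case_fraction is None or not (0 < self.case_fraction < 1):
                raise SumstatsError(
                    f"{self.snp_id}: case_control requires case_fraction in (0, 1)"
                )
        if self.pvalue > _P_CHECK_FLOOR:
            p_from_z = float(zscore_pvalue(self.z))
            if p_from_z > _P_CHECK_FLOOR:
                dlog = abs(math.log10(self.pvalue) - math.log10(p_from_z))
                if dlog > p_z_log10_tol:
                    logger.warning(
                        "%s: p=%.3g inconsistent with |beta/se| (expected %.3g); "
                        "recomputing p from z",
                        self.snp_id,
                        self.pvalue,
                        p_from_z,
                    )
                    self.pvalue = p_from_z


@dataclass
class AssociationSet:
    """All marginal associations of one trait across one locus.

    ``trait_id`` is ``gene|cell_type`` for eQTL exposures and the outcome
    name for GWAS traits.
    """

    trait_id: str
    records: list[VariantRecord]
    region: Region

    def __post_init__(self) -> None:
        self.region = Region(*self.region)

    def validate(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.snp_id in seen:
                raise SumstatsError(f"{self.trait_id}: duplicate snp_id {rec.snp_id}")
            seen.add(rec.snp_id)
            if not self.region.contains(rec.chrom, rec.pos):
                raise SumstatsError(
                    f"{self.trait_id}: {rec.snp_id} at {rec.chrom}:{rec.pos} "
                    f"outside region {self.region}"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self.records]

    def get(self, snp_id: str) -> VariantRecord:
        for rec in self.records:
            if rec.snp_id == snp_id:
                return rec
        raise KeyError(snp_id)

    def subset(self, snp_ids: Iterable[str]) -> "AssociationSet":
        """Restriction to the given snp_ids, in this set's order."""
        keep = set(snp_ids)
        return AssociationSet(
            trait_id=self.trait_id,
            records=[r for r in self.records if r.snp_id in keep],
            region=self.region,
        )

    def restrict(self, region: Region) -> "AssociationSet":
        """Restriction to a (sub)region, keeping this set's trait id."""
        return AssociationSet(
            trait_id=self.trait_id,
            records=[
                r for r in self.records if region.contains(r.chrom, r.pos)
            ],
            region=region,
        )

    @property
    def betas(self) -> np.ndarray:
        return np.array([r.beta for r in self.records])

    @property
    def ses(self) -> np.ndarray:
        return np.array([r.se for r in self.records])

    @property
    def zscores(self) -> np.ndarray:
        return self.betas / self.ses

    @property
    def pvalues(self) -> np.ndarray:
        return np.array([r.pvalue for r in self.records])


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene body coordinates used for cis-window construction."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "unknown"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise SumstatsError(f"{self.gene_id}: start > end")
        if self.strand not in ("+", "-", "unknown"):
            raise SumstatsError(f"{self.gene_id}: bad strand {self.strand!r}")


@dataclass
class LDMatrix:
    """Square matrix of pairwise allelic correlations r, variant-ordered."""

    snp_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        q = len(self.snp_ids)
        if self.r.shape != (q, q):
            raise SumstatsError(
                f"LD matrix is {self.r.shape}, snplist has {q} entries"
            )
        if q and np.max(np.abs(self.r - self.r.T)) > 1e-8:
            raise SumstatsError("LD matrix asymmetric beyond 1e-8")
        self.r = (self.r + self.r.T) / 2.0
        if q and np.max(np.abs(np.diag(self.r) - 1.0)) > 1e-6:
            raise SumstatsError("LD matrix diagonal deviates from 1 by > 1e-6")
        np.fill_diagonal(self.r, 1.0)
        if q and (np.min(self.r) < -1 - 1e-8 or np.max(self.r) > 1 + 1e-8):
            raise SumstatsError("LD entries outside [-1, 1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def index(self, snp_id: str) -> int:
        return self._index[snp_id]

    def r2(self, a: str, b: str) -> float:
        return float(self.r[self._index[a], self._index[b]] ** 2)

    def submatrix(self, snp_ids: Sequence[str]) -> "LDMatrix":
        idx = [self._index[s] for s in snp_ids]
        return LDMatrix(list(snp_ids), self.r[np.ix_(idx, idx)])


@dataclass
class CellTypeMap:
    """Many-to-one relabeling from fine to coarse cell types."""

    mapping: dict[str, str]

    def __getitem__(self, label: str) -> str:
        try:
            return self.mapping[label]
        except KeyError:
            raise KeyError(
                f"cell type {label!r} missing from cell-type map"
            ) from None

    def __contains__(self, label: str) -> bool:
        return label in self.mapping

    def apply(self, labels: Iterable[str]) -> list[str]:
        return [self[lab] for lab in labels]


#: Coarsening of the 14 discovery PBMC cell types to the six broader
#: lineages available in the replication source: B lineage, CD4+ T,
#: CD8+ T, NK, monocytes, and dendritic cells.
DEFAULT_CELL_TYPE_MAP = CellTypeMap(
    {
        "B": "B",
        "BM": "B",
        "Plasma": "B",
        "CD4_NC": "CD4_T",
        "CD4_ET": "CD4_T",
        "CD4_SOX4": "CD4_T",
        "CD8_NC": "CD8_T",
        "CD8_ET": "CD8_T",
        "CD8_SOX4": "CD8_T",
        "NK": "NK",
        "NK_R": "NK",
        "Mono_C": "Mono",
        "Mono_NC": "Mono",
        "DC": "DC",
    }
)


# ---------------------------------------------------------------------------
# TSV dialects
# ---------------------------------------------------------------------------

#: canonical field -> column name; ``trait`` names the grouping column.
GENERIC_DIALECT: dict[str, str] = {
    "snp": "snp",
    "chrom": "chrom",
    "pos": "pos",
    "ea": "effect_allele",
    "oa": "other_allele",
    "beta": "beta",
    "se": "se",
    "p": "pvalue",
    "eaf": "eaf",
    "n": "n",
    "trait": "trait",
    "trait_type": "trait_type",
    "case_fraction": "case_fraction",
}

#: exposure files keyed by gene and cell type; trait_id = "gene|cell_type".
EXPOSURE_DIALECT: dict[str, str] = {
    **{k: v for k, v in GENERIC_DIALECT.items() if k != "trait"},
    "gene": "gene_id",
    "cell_type": "cell_type",
}

_REQUIRED = ("snp", "chrom", "pos", "ea", "oa", "beta", "se", "p")
NA_TOKEN = "NA"


@dataclass
class ReadReport:
    """Row-level accounting from a read: kept vs dropped-by-invariant."""

    n_read: int = 0
    n_kept: int = 0
    n_dropped: int = 0
    dropped: list[tuple[str, str]] = field(default_factory=list)


def exposure_trait_id(gene_id: str, cell_type: str) -> str:
    return f"{gene_id}|{cell_type}"


def split_exposure_trait_id(trait_id: str) -> tuple[str, str]:
    gene, _, cell_type = trait_id.partition("|")
    return gene, cell_type


def _to_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and value.strip() in ("", NA_TOKEN, "nan"):
        return None
    return float(value)


def read_sumstats(
    path,
    dialect: Mapping[str, str] | None = None,
) -> tuple[list[AssociationSet], ReadReport]:
    """Read a summary-statistics TSV into validated AssociationSets.

    Rows failing VariantRecord invariants are dropped and counted in the
    returned :class:`ReadReport`; sets are grouped by trait id (the
    ``trait`` column, or ``gene|cell_type`` for the exposure dialect) and
    their region is the span of the rows on each trait's chromosome.
    """
    dialect = dict(dialect or GENERIC_DIALECT)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] == 0 or (df.shape[0] == 0 and df.shape[1] <= 1):
        raise SumstatsError(f"{path}: empty input")
    for key in _REQUIRED:
        col = dialect.get(key)
        if col is None or col not in df.columns:
            raise SumstatsError(
                f"{path}: missing required column {dialect.get(key, key)!r}"
            )

    if "trait" in dialect and dialect["trait"] in df.columns:
        traits = df[dialect["trait"]].astype(str).tolist()
    elif "gene" in dialect and dialect["gene"] in df.columns:
        if dialect.get("cell_type") not in df.columns:
            raise SumstatsError(
                f"{path}: missing required column {dialect.get('cell_type')!r}"
            )
        traits = [
            exposure_trait_id(g, ct)
            for g, ct in zip(df[dialect["gene"]], df[dialect["cell_type"]])
        ]
    else:
        raise SumstatsError(f"{path}: missing required column 'trait'")

    def _col(key, default=None):
        name = dialect.get(key, "")
        if name in df.columns:
            return df[name].tolist()
        return [default] * len(df)

    cols = {
        key: _col(key)
        for key in (
            "snp", "chrom", "pos", "ea", "oa", "beta", "se", "p",
            "eaf", "n", "trait_type", "case_fraction",
        )
    }
    report = ReadReport(n_read=len(df))
    # group by (trait, chrom): a set's records must share one chromosome
    grouped: dict[tuple[str, str], list[VariantRecord]] = {}
    order: list[tuple[str, str]] = []
    for i in range(len(df)):
        trait = traits[i]
        try:
            rec = VariantRecord(
                snp_id=str(cols["snp"][i]),
                chrom=str(cols["chrom"][i]),
                pos=int(float(cols["pos"][i])),
                effect_allele=str(cols["ea"][i]),
                other_allele=str(cols["oa"][i]),
                beta=float(cols["beta"][i]),
                se=float(cols["se"][i]),
                pvalue=float(cols["p"][i]),
                eaf=_to_float(cols["eaf"][i]),
                n=_to_float(cols["n"][i]),
                trait_type=str(cols["trait_type"][i] or "quantitative"),
                case_fraction=_to_float(cols["case_fraction"][i]),
            )
            rec.validate()
        except (SumstatsError, ValueError) as exc:
            report.n_dropped += 1
            report.dropped.append((str(cols["snp"][i]), str(exc)))
            continue
        key = (trait, rec.chrom)
        if key not in grouped:
            grouped[key] = []
            order.append(key)
        grouped[key].append(rec)
        report.n_kept += 1

    sets = []
    for trait, chrom in order:
        recs = grouped[(trait, chrom)]
        positions = [r.pos for r in recs]
        region = Region(chrom, min(positions), max(positions))
        aset = AssociationSet(trait_id=trait, records=recs, region=region)
        aset.validate()
        sets.append(aset)
    if report.n_dropped:
        logger.warning(
            "%s: dropped %d/%d rows failing record invariants",
            path,
            report.n_dropped,
            report.n_read,
        )
    return sets, report


def write_sumstats(sets: Sequence[AssociationSet], path) -> None:
    """Write AssociationSets as a generic-dialect TSV (round-trip safe).

    Missing eaf/n are serialized as an explicit NA token.
    """
    cols = [
        "trait",
        "snp",
        "chrom",
        "pos",
        "effect_allele",
        "other_allele",
        "eaf",
        "beta",
        "se",
        "pvalue",
        "n",
        "trait_type",
        "case_fraction",
    ]
    rows = []
    for aset in sets:
        for r in aset.records:
            rows.append(
                {
                    "trait": aset.trait_id,
                    "snp": r.snp_id,
                    "chrom": r.chrom,
                    "pos": r.pos,
                    "effect_allele": r.effect_allele,
                    "other_allele": r.other_allele,
                    "eaf": NA_TOKEN if r.eaf is None else repr(r.eaf),
                    "beta": repr(r.beta),
                    "se": repr(r.se),
                    "pvalue": repr(r.pvalue),
                    "n": NA_TOKEN if r.n is None else repr(r.n),
                    "trait_type": r.trait_type,
                    "case_fraction": (
                        NA_TOKEN if r.case_fraction is None else repr(r.case_fraction)
                    ),
                }
            )
    df = pd.DataFrame(rows, columns=cols)
    df.to_csv(path, sep="\t", index=False)


def read_ld(matrix_path, snplist_path) -> LDMatrix:
    """Read a plain-text square LD matrix plus companion snplist."""
    with open(snplist_path) as fh:
        snp_ids = [line.strip() for line in fh if line.strip()]
    r = np.loadtxt(matrix_path, ndmin=2)
    if r.shape[0] != r.shape[1]:
        raise SumstatsError(
            f"{matrix_path}: matrix is {r.shape[0]}x{r.shape[1]}, not square"
        )
    return LDMatrix(snp_ids, r)


def write_ld(ld: LDMatrix, matrix_path, snplist_path) -> None:
    np.savetxt(matrix_path, ld.r, fmt="%.10g")
    with open(snplist_path, "w") as fh:
        fh.write("\n".join(ld.snp_ids) + ("\n" if ld.snp_ids else ""))


def read_gene_annotations(path) -> dict[str, GeneAnnotation]:
    """Read a 4-5 column TSV (gene_id, chrom, start, end[, strand])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene_id", "chrom", "start", "end"):
        if col not in df.columns:
            raise SumstatsError(f"{path}: missing required column {col!r}")
    genes = {}
    for _, row in df.iterrows():
        genes[row["gene_id"]] = GeneAnnotation(
            gene_id=row["gene_id"],
            chrom=row["chrom"],
            start=int(row["start"]),
            end=int(row["end"]),
            strand=row.get("strand", "unknown") or "unknown",
        )
    return genes


def write_gene_annotations(genes: Mapping[str, GeneAnnotation], path) -> None:
    df = pd.DataFrame(
        [
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
            }
            for g in genes.values()
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def read_cell_type_map(path) -> CellTypeMap:
    """Two-column TSV: discovery_label, replication_label."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise SumstatsError(f"{path}: cell-type map needs two columns")
    col_from, col_to = df.columns[:2]
    return CellTypeMap(dict(zip(df[col_from], df[col_to])))


def write_cell_type_map(ctmap: CellTypeMap, path) -> None:
    pd.DataFrame(
        {
            "discovery_label": list(ctmap.mapping),
            "replication_label": list(ctmap.mapping.values()),
        }
    ).to_csv(path, sep="\t", index=False)
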
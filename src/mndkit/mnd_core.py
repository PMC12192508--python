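"""Mitonuclear-discordance statistics.

The discordance of a sample at a gene is the fraction of its local-ancestry
calls (SNP x haplotype, missing excluded) inside the gene interval that do
not match the continental ancestry of the sample's mtDNA lineage. Per-sample
summaries average the gene-wise values, unweighted, over the genes of a
gene set that have at least one usable call. Two further quantities follow:

* global ancestry — per-sample ancestry fractions over all non-missing
  calls genome-wide, and the matching global discordance
  ``1 - fraction(mt ancestry)``;
* the relative mother-to-offspring change
  ``(mnd_offspring - mnd_mother) / mnd_mother``.

Counting runs over haplotype calls by default, so a site heterozygous for
ancestry contributes 0.5; a per-SNP majority collapse (ties scored 0.5) is
available via ``mode="per_snp"`` for sensitivity analysis — for diploids
the two are numerically identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ancestry_io import (
    MISSING,
    GeneIndex,
    LocalAncestryMatrix,
    MtAssignment,
    PairRecord,
)
from .errors import PipelineError, ValidationError
from .panel import UNMAPPED

MND_MODES = ("per_call", "per_snp")

MND_COLUMNS = ["sample_id", "gene_set", "mean_mnd", "n_genes_used", "mt_ancestry"]
DETAIL_COLUMNS = ["sample_id", "gene_id", "gene_mnd", "n_calls"]
DELTA_COLUMNS = [
    "mother_id",
    "offspring_id",
    "cohort",
    "gene_set",
    "mnd_mother",
    "mnd_offspring",
    "delta",
]


@dataclass(frozen=True)
class GlobalAncestry:
    """Genome-wide ancestry fractions of one sample (sum to 1)."""

    sample_id: str
    proportions: Mapping[str, float]

    def __post_init__(self) -> None:
        total = float(sum(self.proportions.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"{self.sample_id}: ancestry proportions sum to {total}, not 1"
            )
        if any(v < 0 for v in self.proportions.values()):
            raise ValidationError(f"{self.sample_id}: negative ancestry proportion")


@dataclass(frozen=True)
class DeltaMnd:
    """Relative intergenerational change in discordance for one pair."""

    pair: PairRecord
    gene_set: str
    mnd_mother: float
    mnd_offspring: float

    @property
    def delta(self) -> float:
        return (self.mnd_offspring - self.mnd_mother) / self.mnd_mother


# ---------------------------------------------------------------------------
# per-gene / per-sample discordance
# ---------------------------------------------------------------------------

def _mismatch_fraction(
    calls: np.ndarray, mt_code: int, mode: str
) -> tuple[float | None, int]:
    """(fraction mismatching, usable call count) for one sample x gene block.

    ``calls`` has shape (n_sites, 2). Returns (None, 0) when no call is
    usable.
    """
    usable = calls != MISSING
    if mode == "per_call":
        n = int(usable.sum())
        if n == 0:
            return None, 0
        mism = int(((calls != mt_code) & usable).sum())
        return mism / n, n
    if mode == "per_snp":
        # majority vote across the two haplotypes; ancestry ties score 0.5
        both = usable.all(axis=1)
        one = usable.sum(axis=1) == 1
        score = 0.0
        n_snps = int(both.sum() + one.sum())
        if n_snps == 0:
            return None, 0
        if both.any():
            mm = (calls[both] != mt_code).sum(axis=1)
            score += float(np.where(mm == 2, 1.0, np.where(mm == 1, 0.5, 0.0)).sum())
        if one.any():
            solo = np.where(usable[one, 0], calls[one, 0], calls[one, 1])
            score += float((solo != mt_code).sum())
        return score / n_snps, n_snps
    raise ValidationError(f"unknown MND mode {mode!r}; expected one of {MND_MODES}")


def gene_wise_mnd(
    matrix: LocalAncestryMatrix,
    sample_id: str,
    gene_id: str,
    gene_index: GeneIndex,
    mt_ancestry: str,
    mode: str = "per_call",
) -> float | None:
    """Discordance of one sample at one gene, or None if no usable call."""
    mt_code = matrix.panel.code(mt_ancestry)
    si = matrix.sample_index(sample_id)
    sites = gene_index.site_map.get(gene_id)
    if sites is None:
        raise ValidationError(f"unknown gene {gene_id!r}")
    frac, _ = _mismatch_fraction(matrix.calls[si, sites, :], mt_code, mode)
    return frac


def sample_mnd(
    matrix: LocalAncestryMatrix,
    sample_id: str,
    gene_set: Sequence[str],
    gene_index: GeneIndex,
    mt_ancestry: str,
    mode: str = "per_call",
) -> tuple[float, int] | None:
    """Unweighted mean of gene-wise discordance over a gene set.

    Returns (mean, n_genes_used), or None when no gene has a usable call.
    """
    if not gene_set:
        raise ValidationError("empty gene set")
    values = []
    for gid in gene_set:
        v = gene_wise_mnd(matrix, sample_id, gid, gene_index, mt_ancestry, mode)
        if v is not None:
            values.append(v)
    if not values:
        return None
    return float(np.mean(values)), len(values)


def compute_mnd_table(
    matrix: LocalAncestryMatrix,
    gene_index: GeneIndex,
    assignments: Sequence[MtAssignment],
    gene_sets: Iterable[str] | None = None,
    mode: str = "per_call",
    with_detail: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame | None, list[tuple[str, str]]]:
    """Vectorized per-sample, per-gene-set discordance table.

    Returns ``(table, detail, exclusions)`` where ``table`` has columns
    ``sample_id, gene_set, mean_mnd, n_genes_used, mt_ancestry``, ``detail``
    (if requested) has per-gene rows for the union of requested sets, and
    ``exclusions`` lists ``(sample_id, reason)`` for samples left out
    (unmapped mtDNA ancestry, absent assignment, or zero usable genes).
    """
    if mode not in MND_MODES:
        raise ValidationError(f"unknown MND mode {mode!r}; expected one of {MND_MODES}")
    set_names = list(gene_sets) if gene_sets is not None else list(gene_index.sets)
    for name in set_names:
        if name not in gene_index.sets:
            raise ValidationError(f"unknown gene set {name!r}")

    by_sample = {a.sample_id: a for a in assignments}
    exclusions: list[tuple[str, str]] = []
    usable_samples: list[tuple[int, str, str]] = []  # (row index, id, ancestry)
    for i, sid in enumerate(matrix.samples):
        a = by_sample.get(sid)
        if a is None:
            exclusions.append((sid, "no haplogroup assignment"))
        elif a.mt_ancestry == UNMAPPED:
            exclusions.append((sid, f"unmapped mtDNA ancestry (macro {a.macro!r})"))
        else:
            usable_samples.append((i, sid, a.mt_ancestry))
    if not usable_samples:
        return (
            pd.DataFrame(columns=MND_COLUMNS),
            pd.DataFrame(columns=DETAIL_COLUMNS) if with_detail else None,
            exclusions,
        )

    rows_idx = np.array([i for i, _, _ in usable_samples])
    mt_codes = np.array(
        [matrix.panel.code(anc) for _, _, anc in usable_samples], dtype=np.int16
    )
    union_genes = sorted({g for name in set_names for g in gene_index.sets[name]})

    # per-gene discordance for every usable sample at once
    gene_vals: dict[str, np.ndarray] = {}
    gene_ncalls: dict[str, np.ndarray] = {}
    for gid in union_genes:
        sites = gene_index.site_map[gid]
        if sites.size == 0:
            continue
        block = matrix.calls[np.ix_(rows_idx, sites)]  # (n_use, n_sites, 2)
        usable = block != MISSING
        n = usable.sum(axis=(1, 2))
        mism = ((block != mt_codes[:, None, None]) & usable).sum(axis=(1, 2))
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(n > 0, mism / np.maximum(n, 1), np.nan)
        gene_vals[gid] = vals
        gene_ncalls[gid] = n

    records: list[dict] = []
    detail_records: list[dict] = []
    dead_samples: set[str] = set()
    for k, (_, sid, anc) in enumerate(usable_samples):
        per_set_means = {}
        for name in set_names:
            vals = [
                gene_vals[g][k]
                for g in gene_index.sets[name]
                if g in gene_vals and not np.isnan(gene_vals[g][k])
            ]
            if vals:
                per_set_means[name] = (float(np.mean(vals)), len(vals))
        if not per_set_means:
            dead_samples.add(sid)
            exclusions.append((sid, "no gene with usable calls"))
            continue
        for name, (mean, n_used) in per_set_means.items():
            records.append(
                {
                    "sample_id": sid,
                    "gene_set": name,
                    "mean_mnd": mean,
                    "n_genes_used": n_used,
                    "mt_ancestry": anc,
                }
            )
        if with_detail:
            for gid in union_genes:
                if gid in gene_vals and not np.isnan(gene_vals[gid][k]):
                    detail_records.append(
                        {
                            "sample_id": sid,
                            "gene_id": gid,
                            "gene_mnd": float(gene_vals[gid][k]),
                            "n_calls": int(gene_ncalls[gid][k]),
                        }
                    )

    table = pd.DataFrame(records, columns=MND_COLUMNS)
    detail = (
        pd.DataFrame(detail_records, columns=DETAIL_COLUMNS) if with_detail else None
    )
    return table, detail, exclusions


# ---------------------------------------------------------------------------
# global ancestry
# ---------------------------------------------------------------------------

def global_ancestry(
    matrix: LocalAncestryMatrix, sample_id: str
) -> GlobalAncestry:
    """Genome-wide ancestry fractions from local-ancestry call averages."""
    si = matrix.sample_index(sample_id)
    calls = matrix.calls[si]
    usable = calls != MISSING
    total = int(usable.sum())
    if total == 0:
        raise PipelineError(f"{sample_id}: all local-ancestry calls missing")
    props = {
        name: float(((calls == code) & usable).sum()) / total
        for code, name in enumerate(matrix.panel.names)
    }
    return GlobalAncestry(sample_id, props)


def global_ancestry_table(matrix: LocalAncestryMatrix) -> pd.DataFrame:
    """Global ancestry for every sample, one row per sample."""
    rows = []
    for sid in matrix.samples:
        ga = global_ancestry(matrix, sid)
        rows.append({"sample_id": sid, **ga.proportions})
    return pd.DataFrame(rows, columns=["sample_id", *matrix.panel.names])


def global_mnd(ancestry: GlobalAncestry, mt_ancestry: str) -> float:
    """Genome-wide discordance: 1 minus the mtDNA-ancestry fraction."""
    if mt_ancestry not in ancestry.proportions:
        raise ValidationError(
            f"mt ancestry {mt_ancestry!r} not in panel "
            f"{sorted(ancestry.proportions)}"
        )
    return 1.0 - float(ancestry.proportions[mt_ancestry])


# ---------------------------------------------------------------------------
# intergenerational change
# ---------------------------------------------------------------------------

def delta_mnd(
    pair: PairRecord, mnd_table: pd.DataFrame, gene_set: str
) -> DeltaMnd | None:
    """Relative change for one pair, or None when the pair must be dropped.

    Dropped when either member lacks a discordance value for ``gene_set``
    or the mother's value is 0 (the ratio is undefined).
    """
    sub = mnd_table[mnd_table["gene_set"] == gene_set].set_index("sample_id")
    if pair.mother_id not in sub.index or pair.offspring_id not in sub.index:
        return None
    m = float(sub.at[pair.mother_id, "mean_mnd"])
    o = float(sub.at[pair.offspring_id, "mean_mnd"])
    if m == 0:
        return None
    return DeltaMnd(pair, gene_set, m, o)


def compute_delta_table(
    pairs: Sequence[PairRecord],
    mnd_table: pd.DataFrame,
    gene_sets: Iterable[str],
) -> tuple[pd.DataFrame, list[tuple[PairRecord, str, str]]]:
    """Delta rows for every pair x gene set, plus an exclusion log."""
    rows: list[dict] = []
    exclusions: list[tuple[PairRecord, str, str]] = []
    for gene_set in gene_sets:
        sub = mnd_table[mnd_table["gene_set"] == gene_set].set_index("sample_id")
        for pair in pairs:
            if pair.mother_id not in sub.index:
                exclusions.append((pair, gene_set, "mother has no MND value"))
                continue
            if pair.offspring_id not in sub.index:
                exclusions.append((pair, gene_set, "offspring has no MND value"))
                continue
            m = float(sub.at[pair.mother_id, "mean_mnd"])
            o = float(sub.at[pair.offspring_id, "mean_mnd"])
            if m == 0:
                exclusions.append((pair, gene_set, "mother MND is 0"))
                continue
            rows.append(
                {
                    "mother_id": pair.mother_id,
                    "offspring_id": pair.offspring_id,
                    "cohort": pair.cohort,
                    "gene_set": gene_set,
                    "mnd_mother": m,
                    "mnd_offspring": o,
                    "delta": (o - m) / m,
                }
            )
    return pd.DataFrame(rows, columns=DELTA_COLUMNS), exclusions
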
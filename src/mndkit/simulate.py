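"""Synthetic admixed-cohort generator with known ground truth.

Individuals carry two haplotypes per chromosome built from the standard
Poisson/Markov admixture-tract approximation: breakpoints fall as a Poisson
process of rate ``g`` per Morgan (``g`` generations since admixture) and
each tract's ancestry is an independent draw from the individual's ancestry
proportions ``theta ~ Dirichlet(alpha)``. mtDNA ancestry follows the
maternal lineage, so under ``mt_mode="maternal_draw"`` it is a categorical
draw from theta; a cosmetic haplogroup label consistent with that ancestry
is attached. Mother-offspring pairs are related by meiosis: the transmitted
haplotype recombines the mother's two haplotypes at rate 1 crossover per
Morgan, and the offspring's mtDNA is copied from the mother.

``write_cohort`` emits the exact file set the readers in
:mod:`mndkit.ancestry_io` consume, so simulated cohorts exercise the whole
pipeline end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ancestry_io
from .ancestry_io import Gene, LocalAncestryMatrix, PairRecord
from .errors import ValidationError
from .panel import AncestryPanel

#: Cosmetic haplogroup labels per ancestry, spanning the default macro rules.
HAPLOGROUP_POOL: dict[str, tuple[str, ...]] = {
    "NAT": ("A2", "B2b", "C1b", "D1a"),
    "EUR": ("H1a", "HV0a", "U5b", "J1c", "T2b", "K1a"),
    "AFR": ("L0a", "L1b1a", "L2a", "L3e"),
}


@dataclass(frozen=True)
class ChromosomeSpec:
    name: str
    morgans: float
    n_sites: int

    def __post_init__(self) -> None:
        if self.morgans <= 0:
            raise ValidationError(f"{self.name}: genetic length must be > 0")
        if self.n_sites < 1:
            raise ValidationError(f"{self.name}: need at least 1 site")


@dataclass(frozen=True)
class SimConfig:
    """Desk-scale simulator configuration (defaults run in seconds)."""

    n_individuals: int = 50
    n_pairs: int = 0
    panel: AncestryPanel = field(default_factory=AncestryPanel)
    dirichlet_alpha: tuple[float, ...] = (2.0, 2.0, 2.0)
    generations: int = 12
    chromosomes: tuple[ChromosomeSpec, ...] = (
        ChromosomeSpec("chr1", 1.0, 1000),
        ChromosomeSpec("chr2", 1.0, 1000),
    )
    n_genes: int = 200
    sites_per_gene: int = 10
    mt_mode: str = "maternal_draw"  # or "fixed:<LABEL>"
    father_theta: str = "independent"  # or "matched" (father theta = mother's)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.generations < 1:
            raise ValidationError("generations must be >= 1")
        if len(self.dirichlet_alpha) != len(self.panel):
            raise ValidationError("dirichlet_alpha length must match panel size")
        if any(a <= 0 for a in self.dirichlet_alpha):
            raise ValidationError("dirichlet_alpha entries must be > 0")
        if self.n_pairs > self.n_individuals:
            raise ValidationError("n_pairs cannot exceed n_individuals")
        total_sites = sum(c.n_sites for c in self.chromosomes)
        if self.n_genes * self.sites_per_gene > total_sites:
            raise ValidationError(
                f"{self.n_genes} genes x {self.sites_per_gene} sites "
                f"exceed the {total_sites} simulated sites"
            )
        if self.mt_mode != "maternal_draw":
            if not self.mt_mode.startswith("fixed:"):
                raise ValidationError(
                    f"mt_mode must be 'maternal_draw' or 'fixed:<label>', "
                    f"got {self.mt_mode!r}"
                )
            label = self.mt_mode.split(":", 1)[1]
            if label not in self.panel:
                raise ValidationError(f"fixed mt label {label!r} not in panel")
        if self.father_theta not in ("independent", "matched"):
            raise ValidationError(
                f"father_theta must be 'independent' or 'matched', "
                f"got {self.father_theta!r}"
            )

    @classmethod
    def from_yaml(cls, source: str | Path) -> "SimConfig":
        """Load from a YAML file path or YAML text."""
        try:
            is_file = Path(source).exists()
        except OSError:
            is_file = False
        text = Path(source).read_text() if is_file else str(source)
        raw = yaml.safe_load(text) or {}
        kwargs: dict = {}
        if "panel" in raw:
            kwargs["panel"] = AncestryPanel(tuple(raw.pop("panel")))
        if "chromosomes" in raw:
            kwargs["chromosomes"] = tuple(
                ChromosomeSpec(c["name"], float(c["morgans"]), int(c["n_sites"]))
                for c in raw.pop("chromosomes")
            )
        if "dirichlet_alpha" in raw:
            kwargs["dirichlet_alpha"] = tuple(
                float(a) for a in raw.pop("dirichlet_alpha")
            )
        for key in (
            "n_individuals",
            "n_pairs",
            "generations",
            "n_genes",
            "sites_per_gene",
            "mt_mode",
            "father_theta",
            "seed",
        ):
            if key in raw:
                kwargs[key] = raw.pop(key)
        if raw:
            raise ValidationError(f"unknown simulator config keys: {sorted(raw)}")
        return cls(**kwargs)


@dataclass
class Cohort:
    """A simulated cohort plus its ground truth."""

    matrix: LocalAncestryMatrix
    haplogroups: list[tuple[str, str]]
    pairs: list[PairRecord]
    genes: list[Gene]
    sets: dict[str, tuple[str, ...]]
    truth: pd.DataFrame
    config: SimConfig


# ---------------------------------------------------------------------------
# tract-level machinery
# ---------------------------------------------------------------------------

def _site_genetic_positions(chrom: ChromosomeSpec) -> np.ndarray:
    """Genetic coordinate (Morgans) of each site, evenly spread."""
    return (np.arange(chrom.n_sites) + 0.5) / chrom.n_sites * chrom.morgans


def simulate_haplotype(
    theta: np.ndarray,
    chrom: ChromosomeSpec,
    g: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[tuple[float, float, int]]]:
    """One haplotype's ancestry labels along a chromosome.

    Returns ``(labels, tracts)``: per-site ancestry codes and the list of
    ``(start_morgan, end_morgan, code)`` tracts that produced them.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.min() < 0 or abs(theta.sum() - 1.0) > 1e-9:
        raise ValidationError("theta must be a probability vector")
    n_break = rng.poisson(g * chrom.morgans)
    breaks = np.sort(rng.uniform(0.0, chrom.morgans, size=n_break))
    edges = np.concatenate([[0.0], breaks, [chrom.morgans]])
    labels_per_tract = rng.choice(len(theta), size=len(edges) - 1, p=theta)
    site_pos = _site_genetic_positions(chrom)
    tract_of_site = np.searchsorted(breaks, site_pos, side="right")
    labels = labels_per_tract[tract_of_site].astype(np.int16)
    tracts = [
        (float(edges[i]), float(edges[i + 1]), int(labels_per_tract[i]))
        for i in range(len(labels_per_tract))
    ]
    return labels, tracts


def _meiosis(
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    chrom: ChromosomeSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Recombine two parental haplotypes (1 crossover per Morgan)."""
    n_cross = rng.poisson(chrom.morgans)
    crosses = np.sort(rng.uniform(0.0, chrom.morgans, size=n_cross))
    site_pos = _site_genetic_positions(chrom)
    segment = np.searchsorted(crosses, site_pos, side="right")
    phase = (segment + rng.integers(0, 2)) % 2
    return np.where(phase == 0, hap_a, hap_b).astype(np.int16)


def _draw_mt(
    theta: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> tuple[str, str]:
    """(mt ancestry name, haplogroup string) for a founder."""
    if config.mt_mode == "maternal_draw":
        code = int(rng.choice(len(theta), p=theta))
        name = config.panel.name(code)
    else:
        name = config.mt_mode.split(":", 1)[1]
    pool = HAPLOGROUP_POOL.get(name)
    if pool is None:
        # non-default panel label: synthesize a stable cosmetic tag
        return name, f"HG_{name}"
    return name, str(pool[rng.integers(0, len(pool))])


def _individual_calls(
    theta: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Two independent haplotypes across all chromosomes -> (n_sites, 2)."""
    haps = []
    for hap in range(2):
        parts = [
            simulate_haplotype(theta, c, config.generations, rng)[0]
            for c in config.chromosomes
        ]
        haps.append(np.concatenate(parts))
    return np.stack(haps, axis=1)


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def _build_genes(config: SimConfig) -> tuple[list[Gene], dict[str, tuple[str, ...]]]:
    """Tile genes over consecutive sites; carve out the four gene sets.

    Set sizes mirror the rough proportions of the real resources: ~1/6 of
    genes OXPHOS, ~1/6 high-mt, the rest low-mt; every gene mitonuclear.
    """
    positions = _physical_positions(config)
    flat = [
        (c.name, j)
        for c in config.chromosomes
        for j in range(c.n_sites)
    ]
    genes: list[Gene] = []
    cursor = 0
    for k in range(config.n_genes):
        span = flat[cursor : cursor + config.sites_per_gene]
        chroms = {c for c, _ in span}
        if len(chroms) > 1:  # don't let a gene straddle chromosomes
            first_chrom = span[0][0]
            span = [(c, j) for c, j in span if c == first_chrom]
        chrom_name = span[0][0]
        first = positions[(chrom_name, span[0][1])]
        last = positions[(chrom_name, span[-1][1])]
        genes.append(Gene(f"G{k + 1:04d}", chrom_name, first - 1, last))
        cursor += config.sites_per_gene
    all_ids = tuple(g.gene_id for g in genes)
    oxphos = tuple(g for i, g in enumerate(all_ids) if i % 6 == 0)
    high = tuple(g for i, g in enumerate(all_ids) if i % 6 == 1)
    low = tuple(g for i, g in enumerate(all_ids) if i % 6 != 1)
    return genes, {
        "all_mitonuclear": all_ids,
        "oxphos": oxphos,
        "high_mt": high,
        "low_mt": low,
    }


def _physical_positions(config: SimConfig) -> dict[tuple[str, int], int]:
    """1-based physical position of each (chrom, site-index)."""
    return {
        (c.name, j): 100 * j + 1
        for c in config.chromosomes
        for j in range(c.n_sites)
    }


def simulate_cohort(config: SimConfig, rng: np.random.Generator | None = None) -> Cohort:
    """Simulate founders, then mother-offspring pairs, fully reproducibly."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    panel = config.panel
    alpha = np.asarray(config.dirichlet_alpha, dtype=float)

    sample_ids: list[str] = []
    calls_rows: list[np.ndarray] = []
    hap_records: list[tuple[str, str]] = []
    truth_rows: list[dict] = []
    pairs: list[PairRecord] = []

    founders: list[tuple[str, np.ndarray, np.ndarray, str, str]] = []
    for i in range(config.n_individuals):
        sid = f"S{i + 1:04d}"
        theta = rng.dirichlet(alpha)
        calls = _individual_calls(theta, config, rng)
        mt_name, haplogroup = _draw_mt(theta, config, rng)
        sample_ids.append(sid)
        calls_rows.append(calls)
        hap_records.append((sid, haplogroup))
        founders.append((sid, theta, calls, mt_name, haplogroup))
        truth_rows.append(
            _truth_row(sid, "founder", theta, mt_name, haplogroup, panel, "")
        )

    for k in range(config.n_pairs):
        mother_id, m_theta, m_calls, m_mt, m_hg = founders[k]
        oid = f"O{k + 1:04d}"
        if config.father_theta == "matched":
            f_theta = m_theta
        else:
            f_theta = rng.dirichlet(alpha)
        # transmitted maternal haplotype, chromosome by chromosome
        transmitted = []
        offset = 0
        for c in config.chromosomes:
            sl = slice(offset, offset + c.n_sites)
            transmitted.append(_meiosis(m_calls[sl, 0], m_calls[sl, 1], c, rng))
            offset += c.n_sites
        hap1 = np.concatenate(transmitted)
        hap2 = np.concatenate(
            [
                simulate_haplotype(f_theta, c, config.generations, rng)[0]
                for c in config.chromosomes
            ]
        )
        calls = np.stack([hap1, hap2], axis=1)
        sample_ids.append(oid)
        calls_rows.append(calls)
        hap_records.append((oid, m_hg))  # maternal inheritance
        pairs.append(PairRecord(mother_id, oid, "sim"))
        truth_rows.append(
            _truth_row(
                oid,
                "offspring",
                (m_theta + f_theta) / 2.0,
                m_mt,
                m_hg,
                panel,
                mother_id,
            )
        )

    chroms = np.array(
        [c.name for c in config.chromosomes for _ in range(c.n_sites)],
        dtype=object,
    )
    positions = _physical_positions(config)
    pos = np.array(
        [positions[(c.name, j)] for c in config.chromosomes for j in range(c.n_sites)],
        dtype=np.int64,
    )
    ids = [f"{c}_{p}" for c, p in zip(chroms, pos)]
    matrix = LocalAncestryMatrix(
        samples=sample_ids,
        chrom=chroms,
        pos=pos,
        ids=ids,
        calls=np.stack(calls_rows, axis=0),
        panel=panel,
    )
    genes, sets = _build_genes(config)
    truth = pd.DataFrame(truth_rows)
    return Cohort(matrix, hap_records, pairs, genes, sets, truth, config)


def _truth_row(
    sid: str,
    role: str,
    theta: np.ndarray,
    mt_name: str,
    haplogroup: str,
    panel: AncestryPanel,
    mother_id: str,
) -> dict:
    row = {"sample_id": sid, "role": role, "mother_id": mother_id}
    for code, name in enumerate(panel.names):
        row[f"theta_{name}"] = float(theta[code])
    row["mt_ancestry"] = mt_name
    row["haplogroup"] = haplogroup
    row["theta_mt"] = float(theta[panel.code(mt_name)])
    return row


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

COHORT_FILES = (
    "ancestry.vcf",
    "genes.bed",
    "gene_sets.tsv",
    "haplogroups.tsv",
    "pairs.tsv",
    "truth.tsv",
)


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Write the full file set readable by :mod:`mndkit.ancestry_io`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {name: outdir / name for name in COHORT_FILES}
    ancestry_io.write_flare_vcf(cohort.matrix, paths["ancestry.vcf"])
    ancestry_io.write_gene_bed(cohort.genes, paths["genes.bed"])
    ancestry_io.write_gene_sets(cohort.sets, paths["gene_sets.tsv"])
    ancestry_io.write_haplogroups(cohort.haplogroups, paths["haplogroups.tsv"])
    ancestry_io.write_pairs(cohort.pairs, paths["pairs.tsv"])
    cohort.truth.to_csv(paths["truth.tsv"], sep="\t", index=False)
    return paths
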
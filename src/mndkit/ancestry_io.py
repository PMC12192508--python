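"""Readers and writers for every external format the pipeline touches.

Formats
-------
* local-ancestry VCF: VCFv4.2 with per-haplotype integer ancestry codes in
  FORMAT fields ``AN1``/``AN2`` and the panel declared in an ``##ANCESTRY``
  meta line (the annotated-VCF style emitted by local-ancestry callers);
* gene intervals: BED4 (0-based, half-open);
* gene-set membership: TSV with 0/1 flag columns;
* haplogroup assignments: TSV with ``SampleID``/``Haplogroup`` columns;
* mother-offspring pairs: TSV with ``mother_id``/``offspring_id`` columns.

All writers emit deterministic column order and ``\\n`` line endings, and
every write/read pair round-trips the in-memory model exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .errors import ValidationError, VcfParseError
from .panel import UNMAPPED, AncestryPanel

#: Sentinel for a missing ancestry call (no AN1/AN2 value for a haplotype).
MISSING = -1

GENE_SET_NAMES = ("all_mitonuclear", "oxphos", "high_mt", "low_mt")
_SET_FLAG_COLUMNS = {
    "all_mitonuclear": "in_all",
    "oxphos": "in_oxphos",
    "high_mt": "in_high_mt",
    "low_mt": "in_low_mt",
}

SiteMask = Callable[[str, int, str], bool]


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass
class LocalAncestryMatrix:
    """Per-sample, per-site, per-haplotype local-ancestry calls.

    Attributes
    ----------
    samples : list of str
        Ordered sample identifiers (unique).
    chrom, pos, ids : arrays of length n_sites
        Site coordinates; ``pos`` is 1-based. Sites are sorted by
        (chromosome block, position).
    calls : int16 array, shape (n_samples, n_sites, 2)
        Panel codes, one per haplotype; ``MISSING`` (-1) marks absent calls.
    panel : AncestryPanel
    """

    samples: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ids: list[str]
    calls: np.ndarray
    panel: AncestryPanel

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype=np.int16)
        self.validate()

    # -- derived views ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def sites(self) -> list[tuple[str, int, str]]:
        return list(zip(self.chrom.tolist(), self.pos.tolist(), self.ids))

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.samples.index(sample_id)
        except ValueError:
            raise ValidationError(f"unknown sample {sample_id!r}") from None

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            dupes = sorted({s for s in self.samples if self.samples.count(s) > 1})
            raise ValidationError(f"duplicate sample ids: {dupes}")
        if self.calls.shape != (self.n_samples, self.n_sites, 2):
            raise ValidationError(
                f"calls shape {self.calls.shape} != "
                f"({self.n_samples}, {self.n_sites}, 2)"
            )
        if len(self.ids) != self.n_sites or len(self.chrom) != self.n_sites:
            raise ValidationError("site annotation lengths disagree")
        if self.n_sites and self.pos.min() < 1:
            raise ValidationError("positions must be >= 1 (1-based)")
        observed = self.calls[self.calls != MISSING]
        if observed.size and (
            observed.min() < 0 or observed.max() >= len(self.panel)
        ):
            bad = sorted(
                int(c)
                for c in np.unique(observed)
                if not self.panel.is_valid_code(int(c))
            )
            raise ValidationError(f"ancestry codes outside panel: {bad}")
        self._check_sorted()

    def _check_sorted(self) -> None:
        seen: set[str] = set()
        prev_chrom: str | None = None
        for i in range(self.n_sites):
            c = self.chrom[i]
            if c != prev_chrom:
                if c in seen:
                    raise ValidationError(
                        f"sites unsorted: chromosome {c} appears in two blocks"
                    )
                seen.add(c)
                prev_chrom = c
            elif self.pos[i] <= self.pos[i - 1]:
                raise ValidationError(
                    f"sites unsorted: {c}:{self.pos[i]} after {c}:{self.pos[i - 1]}"
                )


@dataclass(frozen=True)
class Gene:
    """A gene interval in 0-based half-open BED coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"gene {self.gene_id}: start {self.start} >= end {self.end}"
            )

    def contains_pos(self, pos_1based: int) -> bool:
        return self.start <= pos_1based - 1 < self.end


@dataclass
class GeneIndex:
    """Gene intervals, gene-set memberships, and site lookups.

    ``site_map`` maps each gene_id to the matrix site indices whose 1-based
    position ``p`` satisfies ``start <= p-1 < end`` on the gene's chromosome.
    A site inside two overlapping genes belongs to both. Genes covering no
    site are listed in ``zero_snp_genes`` and skipped by MND averaging.
    """

    genes: list[Gene]
    sets: dict[str, tuple[str, ...]]
    site_map: dict[str, np.ndarray]
    zero_snp_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            dupes = sorted({g for g in ids if ids.count(g) > 1})
            raise ValidationError(f"duplicate gene ids: {dupes}")
        known = set(ids)
        for set_name, members in self.sets.items():
            missing = sorted(set(members) - known)
            if missing:
                raise ValidationError(
                    f"gene set {set_name!r} members absent from BED: {missing}"
                )
        self._check_set_nesting()

    def _check_set_nesting(self) -> None:
        allg = set(self.sets.get("all_mitonuclear", ()))
        if not allg:
            return
        for sub in ("oxphos", "high_mt", "low_mt"):
            extra = sorted(set(self.sets.get(sub, ())) - allg)
            if extra:
                raise ValidationError(
                    f"gene set {sub!r} not a subset of all_mitonuclear: {extra}"
                )
        overlap = sorted(
            set(self.sets.get("high_mt", ())) & set(self.sets.get("low_mt", ()))
        )
        if overlap:
            raise ValidationError(f"high_mt and low_mt overlap: {overlap}")

    def gene(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise ValidationError(f"unknown gene {gene_id!r}")


@dataclass(frozen=True)
class MtAssignment:
    """One sample's mtDNA lineage, collapsed and mapped to the panel."""

    sample_id: str
    haplogroup: str
    macro: str
    mt_ancestry: str  # panel name or UNMAPPED

    @property
    def is_mapped(self) -> bool:
        return self.mt_ancestry != UNMAPPED


@dataclass(frozen=True)
class PairRecord:
    """A mother-offspring pair within one cohort."""

    mother_id: str
    offspring_id: str
    cohort: str = ""

    def __post_init__(self) -> None:
        if self.mother_id == self.offspring_id:
            raise ValidationError(
                f"pair with identical mother and offspring: {self.mother_id!r}"
            )


# ---------------------------------------------------------------------------
# local-ancestry VCF
# ---------------------------------------------------------------------------

def _scan_header_panel(path: str | Path) -> AncestryPanel | None:
    """Pull the ##ANCESTRY panel out of the raw header text.

    Done on the plain text (not through htslib) so both the ``NAME=code``
    and the legacy ``code=NAME`` dialects are accepted.
    """
    text_lines = []
    with open(path, "rt") as fh:
        for line in fh:
            if not line.startswith("##"):
                break
            text_lines.append(line)
    return AncestryPanel.from_header("".join(text_lines))


def read_flare_vcf(
    path: str | Path,
    panel: AncestryPanel | None = None,
    site_mask: SiteMask | None = None,
) -> LocalAncestryMatrix:
    """Read a local-ancestry VCF (FORMAT AN1/AN2) into a matrix.

    Parameters
    ----------
    path : path to an uncompressed or bgzipped VCF.
    panel : panel override; when None the ``##ANCESTRY`` header line is
        required and defines the panel.
    site_mask : optional QC hook ``f(chrom, pos, id) -> bool``; sites for
        which it returns False are dropped before assembly. No default
        filtering is applied.

    Raises
    ------
    VcfParseError
        If the file cannot be parsed as VCF or lacks AN1/AN2.
    ValidationError
        If ancestry codes fall outside the panel or sites are unsorted.
    """
    path = Path(path)
    if not path.exists():
        raise VcfParseError(f"no such file: {path}")
    header_panel = _scan_header_panel(path)
    if panel is None:
        panel = header_panel
        if panel is None:
            raise VcfParseError(
                f"{path}: no ##ANCESTRY header line and no panel supplied"
            )
    elif header_panel is not None and tuple(header_panel.names) != tuple(panel.names):
        raise ValidationError(
            f"{path}: header panel {header_panel.names} != supplied {panel.names}"
        )

    try:
        reader = VCF(str(path))
    except Exception as exc:  # htslib raises bare OSError/Exception
        raise VcfParseError(f"{path}: cannot open as VCF: {exc}") from exc

    samples = list(reader.samples)
    chroms: list[str] = []
    positions: list[int] = []
    ids: list[str] = []
    call_rows: list[np.ndarray] = []
    lineno = 0
    try:
        for rec in reader:
            lineno += 1
            rid = rec.ID if rec.ID is not None else f"{rec.CHROM}_{rec.POS}"
            if site_mask is not None and not site_mask(rec.CHROM, rec.POS, rid):
                continue
            try:
                an1 = rec.format("AN1")
                an2 = rec.format("AN2")
            except KeyError:
                an1 = an2 = None
            if an1 is None or an2 is None:
                raise VcfParseError(
                    f"{path}: record {lineno} ({rec.CHROM}:{rec.POS}) "
                    "lacks AN1/AN2 FORMAT fields"
                )
            row = np.stack(
                [an1.ravel().astype(np.int64), an2.ravel().astype(np.int64)],
                axis=1,
            )
            row[row < 0] = MISSING  # htslib encodes '.' as large negative
            chroms.append(rec.CHROM)
            positions.append(rec.POS)
            ids.append(rid)
            call_rows.append(row)
    except VcfParseError:
        raise
    except Exception as exc:
        raise VcfParseError(
            f"{path}: parse error at record {lineno + 1}: {exc}"
        ) from exc

    if call_rows:
        calls = np.stack(call_rows, axis=1).astype(np.int16)  # (S, V, 2)
    else:
        calls = np.empty((len(samples), 0, 2), dtype=np.int16)
    return LocalAncestryMatrix(
        samples=samples,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(positions, dtype=np.int64),
        ids=ids,
        calls=calls,
        panel=panel,
    )


def write_flare_vcf(matrix: LocalAncestryMatrix, path: str | Path) -> None:
    """Write a matrix as an annotated VCF (FORMAT GT:AN1:AN2).

    Genotypes are placeholders (``0|0``); only the ancestry channel is
    meaningful. Missing calls are written as ``.``.
    """
    path = Path(path)
    lines = [
        "##fileformat=VCFv4.2",
        matrix.panel.to_header_line(),
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype (placeholder)">',
        '##FORMAT=<ID=AN1,Number=1,Type=Integer,'
        'Description="Ancestry code of first haplotype">',
        '##FORMAT=<ID=AN2,Number=1,Type=Integer,'
        'Description="Ancestry code of second haplotype">',
    ]
    for c in dict.fromkeys(matrix.chrom.tolist()):
        lines.append(f"##contig=<ID={c}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(matrix.samples)
    )
    fmt_missing = "."
    for j in range(matrix.n_sites):
        cols = [
            str(matrix.chrom[j]),
            str(int(matrix.pos[j])),
            matrix.ids[j],
            "A",
            "C",
            ".",
            "PASS",
            ".",
            "GT:AN1:AN2",
        ]
        for i in range(matrix.n_samples):
            a1, a2 = matrix.calls[i, j]
            s1 = fmt_missing if a1 == MISSING else str(int(a1))
            s2 = fmt_missing if a2 == MISSING else str(int(a2))
            cols.append(f"0|0:{s1}:{s2}")
        lines.append("\t".join(cols))
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# genes: BED + gene sets
# ---------------------------------------------------------------------------

def read_gene_bed(path: str | Path) -> list[Gene]:
    """Read a BED4 file of gene intervals (0-based half-open)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "gene_id"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "gene_id": str},
    )
    if df["gene_id"].duplicated().any():
        dupes = sorted(df.loc[df["gene_id"].duplicated(), "gene_id"].unique())
        raise ValidationError(f"duplicate gene ids in BED: {dupes}")
    return [
        Gene(row.gene_id, row.chrom, int(row.start), int(row.end))
        for row in df.itertuples()
    ]


def read_gene_sets(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Read the gene-set membership TSV (gene_id + 0/1 flag columns)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    missing_cols = [c for c in _SET_FLAG_COLUMNS.values() if c not in df.columns]
    if "gene_id" not in df.columns or missing_cols:
        raise ValidationError(
            f"gene-set table must have columns gene_id, "
            f"{', '.join(_SET_FLAG_COLUMNS.values())}; missing {missing_cols}"
        )
    if df["gene_id"].duplicated().any():
        dupes = sorted(df.loc[df["gene_id"].duplicated(), "gene_id"].unique())
        raise ValidationError(f"duplicate gene ids in set table: {dupes}")
    return {
        set_name: tuple(df.loc[df[col] == 1, "gene_id"])
        for set_name, col in _SET_FLAG_COLUMNS.items()
    }


def build_site_map(
    genes: Sequence[Gene], matrix: LocalAncestryMatrix
) -> dict[str, np.ndarray]:
    """Map each gene to matrix site indices it contains.

    Containment uses BED semantics: a 1-based site position ``p`` falls in
    ``[start, end)`` iff ``start <= p-1 < end``. Sites inside overlapping
    genes are assigned to each of them.
    """
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for c in dict.fromkeys(matrix.chrom.tolist()):
        idx = np.flatnonzero(matrix.chrom == c)
        by_chrom[c] = (matrix.pos[idx], idx)
    site_map: dict[str, np.ndarray] = {}
    for g in genes:
        if g.chrom not in by_chrom:
            site_map[g.gene_id] = np.empty(0, dtype=np.int64)
            continue
        pos, idx = by_chrom[g.chrom]
        lo = np.searchsorted(pos, g.start + 1, side="left")
        hi = np.searchsorted(pos, g.end, side="right")
        site_map[g.gene_id] = idx[lo:hi]
    return site_map


def read_gene_index(
    bed_path: str | Path,
    sets_path: str | Path,
    matrix: LocalAncestryMatrix,
) -> GeneIndex:
    """Assemble a GeneIndex from a BED4 file, a set table, and a matrix."""
    genes = read_gene_bed(bed_path)
    sets = read_gene_sets(sets_path)
    site_map = build_site_map(genes, matrix)
    zero = tuple(g.gene_id for g in genes if site_map[g.gene_id].size == 0)
    return GeneIndex(genes=genes, sets=sets, site_map=site_map, zero_snp_genes=zero)


def write_gene_bed(genes: Sequence[Gene], path: str | Path) -> None:
    with open(path, "wt") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\n")


def write_gene_sets(sets: dict[str, Sequence[str]], path: str | Path) -> None:
    all_ids = list(
        dict.fromkeys(gid for name in GENE_SET_NAMES for gid in sets.get(name, ()))
    )
    with open(path, "wt") as fh:
        fh.write("gene_id\t" + "\t".join(_SET_FLAG_COLUMNS.values()) + "\n")
        for gid in all_ids:
            flags = "\t".join(
                str(int(gid in set(sets.get(name, ())))) for name in GENE_SET_NAMES
            )
            fh.write(f"{gid}\t{flags}\n")


# ---------------------------------------------------------------------------
# haplogroups + pairs
# ---------------------------------------------------------------------------

def read_haplogroups(path: str | Path) -> list[tuple[str, str]]:
    """Read a Haplogrep-style TSV into raw (sample_id, haplogroup) records.

    Classification to macrohaplogroups happens downstream; records are
    returned verbatim. Empty haplogroup strings are kept but flagged with a
    warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = {c.lower(): c for c in df.columns}
    try:
        sid_col = cols["sampleid"]
        hg_col = cols["haplogroup"]
    except KeyError:
        raise ValidationError(
            f"{path}: expected SampleID and Haplogroup columns, got {list(df.columns)}"
        ) from None
    if df[sid_col].duplicated().any():
        dupes = sorted(df.loc[df[sid_col].duplicated(), sid_col].unique())
        raise ValidationError(f"duplicate samples in haplogroup table: {dupes}")
    records = list(zip(df[sid_col], df[hg_col]))
    empties = [sid for sid, hg in records if not hg.strip()]
    if empties:
        warnings.warn(
            f"empty haplogroup for samples: {empties}", stacklevel=2
        )
    return records


def write_haplogroups(records: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "wt") as fh:
        fh.write("SampleID\tHaplogroup\n")
        for sid, hg in records:
            fh.write(f"{sid}\t{hg}\n")


def read_pairs(path: str | Path, samples: Sequence[str]) -> list[PairRecord]:
    """Read mother-offspring pairs, dropping rows with unknown sample ids.

    Rows whose mother or offspring is absent from ``samples`` are dropped
    with a warning; a row pairing a sample with itself is an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"mother_id", "offspring_id"}
    if not required <= set(df.columns):
        raise ValidationError(
            f"{path}: expected columns mother_id, offspring_id; got {list(df.columns)}"
        )
    known = set(samples)
    pairs: list[PairRecord] = []
    dropped: list[tuple[str, str]] = []
    for row in df.itertuples():
        cohort = getattr(row, "cohort", "") or ""
        if row.mother_id == row.offspring_id:
            raise ValidationError(
                f"pair with identical mother and offspring: {row.mother_id!r}"
            )
        if row.mother_id not in known or row.offspring_id not in known:
            dropped.append((row.mother_id, row.offspring_id))
            continue
        pairs.append(PairRecord(row.mother_id, row.offspring_id, cohort))
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} pair(s) with unknown samples: {dropped}",
            stacklevel=2,
        )
    return pairs


def write_pairs(pairs: Sequence[PairRecord], path: str | Path) -> None:
    with open(path, "wt") as fh:
        fh.write("mother_id\toffspring_id\tcohort\n")
        for p in pairs:
            fh.write(f"{p.mother_id}\t{p.offspring_id}\t{p.cohort}\n")
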
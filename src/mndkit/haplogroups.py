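"""Collapse mtDNA haplogroup labels to macrohaplogroups and map them to
continental ancestries.

A full haplogroup label such as ``B2b`` or ``L1b1a`` is collapsed to its
top-level branch (``B``, ``L``) by longest-prefix matching against an
ordered rule table, with a leading-letter fallback. Macros are then mapped
to a panel ancestry (A-D -> NAT, L -> AFR, common West-Eurasian branches ->
EUR); macros absent from the map resolve to UNMAPPED and their carriers are
excluded from discordance computation downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import yaml

from .ancestry_io import MtAssignment
from .errors import ValidationError
from .panel import UNMAPPED, AncestryPanel

# Multi-letter branches that a bare first-letter rule would misfile.
_DEFAULT_PREFIX_RULES: tuple[tuple[str, str], ...] = (
    ("HV", "HV"),
    ("JT", "JT"),
    ("R0", "R0"),
    ("L0", "L"),
    ("L1", "L"),
    ("L2", "L"),
    ("L3", "L"),
    ("L4", "L"),
    ("L5", "L"),
    ("L6", "L"),
)

_DEFAULT_ANCESTRY_MAP: dict[str, str] = {
    # Native American founding lineages
    "A": "NAT",
    "B": "NAT",
    "C": "NAT",
    "D": "NAT",
    # African macrolineage
    "L": "AFR",
    # common West-Eurasian branches; X is EUR by default (overridable)
    "H": "EUR",
    "HV": "EUR",
    "V": "EUR",
    "J": "EUR",
    "T": "EUR",
    "JT": "EUR",
    "U": "EUR",
    "K": "EUR",
    "N": "EUR",
    "R": "EUR",
    "R0": "EUR",
    "W": "EUR",
    "I": "EUR",
    "X": "EUR",
}


@dataclass(frozen=True)
class HaplogroupMap:
    """Prefix-collapse rules plus macro -> ancestry mapping.

    ``prefix_rules`` is consulted by longest-prefix match; when no rule
    matches, the macro is the leading alphabetic character of the label.
    """

    prefix_rules: tuple[tuple[str, str], ...] = field(default=_DEFAULT_PREFIX_RULES)
    ancestry_map: Mapping[str, str] = field(
        default_factory=lambda: dict(_DEFAULT_ANCESTRY_MAP)
    )

    def __post_init__(self) -> None:
        prefixes = [p for p, _ in self.prefix_rules]
        if len(set(prefixes)) != len(prefixes):
            dupes = sorted({p for p in prefixes if prefixes.count(p) > 1})
            raise ValidationError(f"duplicate prefixes in rules: {dupes}")

    @classmethod
    def default(cls) -> "HaplogroupMap":
        return cls()

    @classmethod
    def from_config(cls, config: Mapping | str) -> "HaplogroupMap":
        """Build from a YAML string or a parsed mapping.

        Recognized keys: ``prefix_rules`` (mapping prefix -> macro, merged
        over the defaults) and ``ancestry_map`` (mapping macro -> ancestry
        name, merged over the defaults).
        """
        if isinstance(config, str):
            config = yaml.safe_load(config) or {}
        rules = dict(_DEFAULT_PREFIX_RULES)
        rules.update(config.get("prefix_rules", {}))
        amap = dict(_DEFAULT_ANCESTRY_MAP)
        amap.update(config.get("ancestry_map", {}))
        return cls(tuple(rules.items()), amap)


def to_macro(haplogroup: str, hmap: HaplogroupMap | None = None) -> str:
    """Collapse a haplogroup label to its single-token macrohaplogroup.

    Longest matching prefix rule wins; with no matching rule the macro is
    the first alphabetic character, uppercased.
    """
    if hmap is None:
        hmap = HaplogroupMap.default()
    label = haplogroup.strip()
    if not label:
        raise ValidationError("empty haplogroup string")
    best = ""
    macro = ""
    for prefix, target in hmap.prefix_rules:
        if label.upper().startswith(prefix.upper()) and len(prefix) > len(best):
            best, macro = prefix, target
    if best:
        return macro
    for ch in label:
        if ch.isalpha():
            return ch.upper()
    raise ValidationError(f"haplogroup {haplogroup!r} has no alphabetic character")


def macro_ancestry(macro: str, hmap: HaplogroupMap | None = None) -> str:
    """Continental ancestry label for a macrohaplogroup, or UNMAPPED."""
    if hmap is None:
        hmap = HaplogroupMap.default()
    return hmap.ancestry_map.get(macro, UNMAPPED)


def classify(
    records: Iterable[tuple[str, str]],
    hmap: HaplogroupMap | None = None,
    panel: AncestryPanel | None = None,
) -> list[MtAssignment]:
    """Turn raw (sample_id, haplogroup) records into full assignments.

    Samples with an empty haplogroup, or whose mapped ancestry is outside
    ``panel``, come back with ``mt_ancestry = UNMAPPED``.
    """
    if hmap is None:
        hmap = HaplogroupMap.default()
    out: list[MtAssignment] = []
    for sample_id, haplogroup in records:
        if not haplogroup.strip():
            out.append(MtAssignment(sample_id, haplogroup, "", UNMAPPED))
            continue
        macro = to_macro(haplogroup, hmap)
        ancestry = macro_ancestry(macro, hmap)
        if panel is not None and ancestry != UNMAPPED and ancestry not in panel:
            ancestry = UNMAPPED
        out.append(MtAssignment(sample_id, haplogroup, macro, ancestry))
    return out


def restrict_to_macros(
    assignments: Sequence[MtAssignment], allowed: Iterable[str]
) -> list[MtAssignment]:
    """Keep only samples whose macrohaplogroup is in ``allowed`` (order kept)."""
    allowed = set(allowed)
    kept = [a for a in assignments if a.macro in allowed]
    if not kept:
        warnings.warn(
            f"no samples left after restricting to macros {sorted(allowed)}",
            stacklevel=2,
        )
    return kept
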
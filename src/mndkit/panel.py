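"""Ancestry panels: the ordered set of source-population labels.

Local-ancestry callers encode each haplotype segment as a small integer;
the panel maps those codes to population names. The default three-way panel
is NAT/EUR/AFR (codes 0/1/2).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import ValidationError

DEFAULT_PANEL_NAMES = ("NAT", "EUR", "AFR")

#: Sentinel label for mtDNA lineages that map to no panel ancestry.
UNMAPPED = "UNMAPPED"

_HEADER_RE = re.compile(r"##ANCESTRY=<(?P<body>[^>]*)>")


@dataclass(frozen=True)
class AncestryPanel:
    """Ordered, contiguous 0-based mapping between ancestry codes and names.

    Parameters
    ----------
    names : tuple of str
        Population names; index in the tuple is the integer code.
    """

    names: tuple[str, ...] = field(default=DEFAULT_PANEL_NAMES)

    def __post_init__(self) -> None:
        if len(self.names) < 2:
            raise ValidationError("ancestry panel needs at least 2 populations")
        if len(set(self.names)) != len(self.names):
            raise ValidationError(f"duplicate panel names: {self.names}")
        object.__setattr__(self, "names", tuple(str(n) for n in self.names))

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    def __contains__(self, name: object) -> bool:
        return name in self.names

    def code(self, name: str) -> int:
        """Integer code for a population name."""
        try:
            return self.names.index(name)
        except ValueError:
            raise ValidationError(f"{name!r} not in panel {self.names}") from None

    def name(self, code: int) -> str:
        """Population name for an integer code."""
        if not 0 <= code < len(self.names):
            raise ValidationError(f"code {code} outside panel of size {len(self)}")
        return self.names[code]

    def is_valid_code(self, code: int) -> bool:
        return 0 <= code < len(self.names)

    def to_header_line(self) -> str:
        """VCF meta line declaring the panel (htslib-safe ``NAME=code`` form)."""
        body = ",".join(f"{n}={i}" for i, n in enumerate(self.names))
        return f"##ANCESTRY=<{body}>"

    @classmethod
    def from_header(cls, header_text: str) -> "AncestryPanel | None":
        """Extract a panel from VCF header text, or None if absent.

        Accepts both ``##ANCESTRY=<NAT=0,EUR=1,...>`` and the code-first
        ``##ANCESTRY=<0=NAT,1=EUR,...>`` dialect.
        """
        m = _HEADER_RE.search(header_text)
        if m is None:
            return None
        mapping: dict[int, str] = {}
        for item in m.group("body").split(","):
            if "=" not in item:
                raise ValidationError(f"bad ANCESTRY header item: {item!r}")
            left, right = (s.strip() for s in item.split("=", 1))
            if left.isdigit():
                code, name = int(left), right
            elif right.isdigit():
                code, name = int(right), left
            else:
                raise ValidationError(f"bad ANCESTRY header item: {item!r}")
            if code in mapping:
                raise ValidationError(f"duplicate ancestry code {code} in header")
            mapping[code] = name
        codes = sorted(mapping)
        if codes != list(range(len(codes))):
            raise ValidationError(f"ancestry codes not contiguous from 0: {codes}")
        return cls(tuple(mapping[c] for c in codes))
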
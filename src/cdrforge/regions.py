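"""Chain and CDR region identifiers.

Antibody variable domains carry three complementarity determining regions
(CDR1-3) per chain.  Three chains are modelled: the heavy chain and the two
light-chain classes, kappa and lambda.  The nine chain/region combinations
are written with the two-character codes H1..H3, K1..K3, L1..L3 throughout
file formats and reports.
"""

from __future__ import annotations

from enum import Enum


class Chain(str, Enum):
    HEAVY = "heavy"
    KAPPA = "kappa"
    LAMBDA = "lambda"

    @property
    def code(self) -> str:
        """Single-letter chain code used in region labels (H/K/L)."""
        return {"heavy": "H", "kappa": "K", "lambda": "L"}[self.value]

    @classmethod
    def from_code(cls, code: str) -> "Chain":
        try:
            return {"H": cls.HEAVY, "K": cls.KAPPA, "L": cls.LAMBDA}[code.upper()]
        except KeyError:
            raise ValueError(f"unknown chain code {code!r}") from None


class CdrRegion(Enum):
    """One of the nine CDRs, e.g. ``CdrRegion.H3`` is heavy-chain CDR3."""

    H1 = ("heavy", 1)
    H2 = ("heavy", 2)
    H3 = ("heavy", 3)
    K1 = ("kappa", 1)
    K2 = ("kappa", 2)
    K3 = ("kappa", 3)
    L1 = ("lambda", 1)
    L2 = ("lambda", 2)
    L3 = ("lambda", 3)

    def __init__(self, chain: str, index: int):
        self.chain = Chain(chain)
        self.index = index

    @property
    def label(self) -> str:
        return self.name

    @property
    def is_light_cdr3(self) -> bool:
        return self.index == 3 and self.chain is not Chain.HEAVY

    @classmethod
    def from_label(cls, label: str) -> "CdrRegion":
        key = label.strip().upper()
        if key not in cls.__members__:
            raise ValueError(f"unknown CDR region label {label!r}; expected one of "
                             + ", ".join(cls.__members__))
        return cls[key]

    @classmethod
    def for_chain(cls, chain: Chain) -> tuple["CdrRegion", ...]:
        return tuple(r for r in cls if r.chain is chain)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name
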
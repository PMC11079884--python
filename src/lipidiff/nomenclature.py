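"""Parsing and classification of shorthand lipid names.

Lipid identification software (LipidSearch and kin) reports each lipid ion
as a class code followed by a parenthesized, ``/``-separated list of fatty
chains, each written ``carbons:double_bonds`` with optional modifiers::

    DG(18:2/18:2)          two acyl 18:2 chains on a diglyceride
    Cer(d18:2/24:1)        "d" marks the sphingoid long-chain base
    PC(16:0p/16:0)         "p" marks a plasmalogen (vinyl-ether) linkage
    TG(18:0e/18:1/18:1)    "e" marks an ether linkage
    LPC(16:0)(rep)         "(rep)" marks a second measured ion of the
                           same base lipid, kept as a distinct row

Grammar accepted here::

    name  := CLASS '(' chain ('/' chain)* ')' ['(rep)']
    chain := ['d'] INT ':' INT ['e' | 'p']

The ``e``/``p`` suffixes are mapped to ether and plasmalogen linkage as a
documented convention of this package; vendor exports do not define them.
Unknown class codes parse fine and classify as ``other`` so richer exports
remain usable.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field

__all__ = [
    "Linkage",
    "ClassCategory",
    "ChainSpec",
    "LipidName",
    "LipidNameError",
    "parse_lipid_name",
    "format_lipid_name",
    "classify_category",
    "total_composition",
    "CLASS_CATEGORIES",
]


class LipidNameError(ValueError):
    """Raised when a string does not match the shorthand name grammar.

    Carries ``position``, the 0-based index of the offending character.
    """

    def __init__(self, message: str, raw: str, position: int):
        super().__init__(f"{message} (in {raw!r} at position {position})")
        self.raw = raw
        self.position = position


class Linkage(str, enum.Enum):
    ACYL = "acyl"
    ETHER = "ether"
    PLASMALOGEN = "plasmalogen"


class ClassCategory(str, enum.Enum):
    DIGLYCERIDE = "diglyceride"
    TRIGLYCERIDE = "triglyceride"
    CERAMIDE = "ceramide"
    GLYCOSYLCERAMIDE = "glycosylceramide"
    PHOSPHOLIPID = "phospholipid"
    LYSO_PHOSPHOLIPID = "lyso_phospholipid"
    OTHER = "other"


#: Case-sensitive class-code -> category table. Anything absent is ``other``.
CLASS_CATEGORIES: dict[str, ClassCategory] = {
    "DG": ClassCategory.DIGLYCERIDE,
    "TG": ClassCategory.TRIGLYCERIDE,
    "Cer": ClassCategory.CERAMIDE,
    "CerG2": ClassCategory.GLYCOSYLCERAMIDE,
    "PC": ClassCategory.PHOSPHOLIPID,
    "PE": ClassCategory.PHOSPHOLIPID,
    "PI": ClassCategory.PHOSPHOLIPID,
    "PS": ClassCategory.PHOSPHOLIPID,
    "LPC": ClassCategory.LYSO_PHOSPHOLIPID,
    "LPE": ClassCategory.LYSO_PHOSPHOLIPID,
    "LPI": ClassCategory.LYSO_PHOSPHOLIPID,
    "LPS": ClassCategory.LYSO_PHOSPHOLIPID,
}

_LINKAGE_SUFFIX = {"e": Linkage.ETHER, "p": Linkage.PLASMALOGEN}
_SUFFIX_FOR_LINKAGE = {v: k for k, v in _LINKAGE_SUFFIX.items()}


@dataclass(frozen=True)
class ChainSpec:
    """One fatty chain: carbon count, double bonds, linkage, sphingoid flag."""

    carbons: int
    double_bonds: int
    linkage: Linkage = Linkage.ACYL
    sphingoid: bool = False

    def __post_init__(self):
        if self.carbons < 1:
            raise ValueError(f"chain carbons must be >= 1, got {self.carbons}")
        if self.double_bonds < 0:
            raise ValueError(f"double bonds must be >= 0, got {self.double_bonds}")
        if self.double_bonds >= self.carbons:
            raise ValueError(
                f"double bonds ({self.double_bonds}) must be fewer than "
                f"carbons ({self.carbons})"
            )

    def format(self) -> str:
        prefix = "d" if self.sphingoid else ""
        suffix = _SUFFIX_FOR_LINKAGE.get(self.linkage, "")
        return f"{prefix}{self.carbons}:{self.double_bonds}{suffix}"


@dataclass(frozen=True)
class LipidName:
    """Structured form of a shorthand lipid identifier."""

    class_code: str
    chains: tuple[ChainSpec, ...]
    replicate: bool = False
    raw: str = field(default="", compare=False)

    def __post_init__(self):
        if not self.class_code:
            raise ValueError("class_code must be non-empty")
        if not self.chains:
            raise ValueError("chains must be non-empty")

    @property
    def category(self) -> ClassCategory:
        return classify_category(self.class_code)

    @property
    def base_name(self) -> str:
        """Canonical name without the ``(rep)`` suffix."""
        chains = "/".join(c.format() for c in self.chains)
        return f"{self.class_code}({chains})"

    def format(self) -> str:
        return self.base_name + ("(rep)" if self.replicate else "")


_CHAIN_RE = re.compile(r"(d?)(\d+):(\d+)([ep]?)")


def parse_lipid_name(raw: str) -> LipidName:
    """Parse a shorthand lipid name into its structured form.

    Parameters
    ----------
    raw:
        A name like ``"Cer(d18:2/24:1)"`` or ``"LPC(16:0)(rep)"``.

    Returns
    -------
    LipidName
        Chain order is preserved; a trailing ``(rep)`` sets the replicate
        flag; ``format_lipid_name`` reproduces ``raw`` exactly.

    Raises
    ------
    LipidNameError
        If the string does not match the grammar; the error names the
        offending character position.
    """
    if not isinstance(raw, str) or not raw:
        raise LipidNameError("empty lipid name", raw or "", 0)

    open_idx = raw.find("(")
    if open_idx <= 0:
        raise LipidNameError(
            "expected a class code followed by '('", raw, max(open_idx, 0)
        )
    class_code = raw[:open_idx]
    if not re.fullmatch(r"[A-Za-z][A-Za-z0-9]*", class_code):
        bad = next(
            i for i, ch in enumerate(class_code) if not ch.isalnum()
        ) if any(not ch.isalnum() for ch in class_code) else 0
        raise LipidNameError("invalid class code", raw, bad)

    close_idx = raw.find(")", open_idx)
    if close_idx < 0:
        raise LipidNameError("unterminated chain list, missing ')'", raw, len(raw) - 1)

    replicate = False
    tail = raw[close_idx + 1:]
    if tail == "(rep)":
        replicate = True
    elif tail:
        raise LipidNameError(
            "unexpected trailing text after chain list", raw, close_idx + 1
        )

    chains: list[ChainSpec] = []
    pos = open_idx + 1
    chain_text = raw[open_idx + 1: close_idx]
    if not chain_text:
        raise LipidNameError("empty chain list", raw, pos)
    for part in chain_text.split("/"):
        m = _CHAIN_RE.fullmatch(part)
        if m is None:
            # point at the first character that breaks the chain token
            probe = _CHAIN_RE.match(part)
            offset = probe.end() if probe else 0
            raise LipidNameError("malformed chain token", raw, pos + offset)
        carbons, double_bonds = int(m.group(2)), int(m.group(3))
        try:
            chains.append(
                ChainSpec(
                    carbons=carbons,
                    double_bonds=double_bonds,
                    linkage=_LINKAGE_SUFFIX.get(m.group(4), Linkage.ACYL),
                    sphingoid=bool(m.group(1)),
                )
            )
        except ValueError as exc:
            raise LipidNameError(str(exc), raw, pos) from exc
        pos += len(part) + 1

    return LipidName(
        class_code=class_code, chains=tuple(chains), replicate=replicate, raw=raw
    )


def format_lipid_name(name: LipidName) -> str:
    """Render the canonical shorthand string; inverse of ``parse_lipid_name``."""
    return name.format()


def classify_category(class_code: str) -> ClassCategory:
    """Map a class code to its lipid category; unknown codes give ``other``."""
    return CLASS_CATEGORIES.get(class_code, ClassCategory.OTHER)


def total_composition(name: LipidName) -> tuple[int, int]:
    """Total carbons and double bonds summed over all chains."""
    return (
        sum(c.carbons for c in name.chains),
        sum(c.double_bonds for c in name.chains),
    )
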
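"""Guide-strand representation, sequence notation parsing and modification codes.

An siRNA or miRNA guide strand is numbered 1-based from its 5' end over the
RNA core; a 3' deoxynucleotide overhang (e.g. ``dTdT``) never enters position
numbering.  Position 6 is the *pivot*: the last base of the transitional
nucleation span (positions 2-6) that initiates miRNA-like target recognition.

Chemical modifications are either *substitutions* (replace the unit at a core
position) or *insertions* (add a unit immediately 5' of a core position,
creating a guide-side bulge).  Abasic units (dSpacer, rSpacer, C3 spacer)
carry no base and therefore remove that position from all pairing logic;
backbone modifications (2'-OMe, UNA) keep their base.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = [
    "GuideStrand",
    "Modification",
    "ModifiedGuide",
    "parse_guide_string",
    "guide_to_string",
    "reverse_complement",
    "make_variant",
    "PIVOT_POSITION",
    "ABASIC_KINDS",
]

PIVOT_POSITION = 6

#: modification kinds whose unit carries no base
ABASIC_KINDS = frozenset({"dSpacer", "rSpacer", "C3"})

_MOD_KINDS = frozenset({"dSpacer", "rSpacer", "C3", "OMe2", "UNA"})
_MOD_MODES = frozenset({"substitution", "insertion"})

_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")
_WC_PAIR = {"A": "U", "U": "A", "G": "C", "C": "G"}


class GuideParseError(ValueError):
    """Raised when a guide sequence string cannot be parsed."""


def reverse_complement(seq: str, output_alphabet: str = "RNA") -> str:
    """Watson-Crick reverse complement of ``seq`` in the requested alphabet.

    Input may be RNA or DNA (T and U are interchangeable); the output uses U
    for ``output_alphabet="RNA"`` and T for ``"DNA"``.
    """
    seq = seq.upper()
    if not re.fullmatch(r"[ACGUT]*", seq):
        bad = next(c for c in seq if c not in "ACGUT")
        raise ValueError(f"invalid nucleotide character: {bad!r}")
    rna = seq.replace("T", "U")
    rc = rna.translate(_RNA_COMPLEMENT)[::-1]
    if output_alphabet == "RNA":
        return rc
    if output_alphabet == "DNA":
        return rc.replace("U", "T")
    raise ValueError(f"unknown output alphabet: {output_alphabet!r}")


def wc_complement(base: str, alphabet: str = "RNA") -> str:
    """Watson-Crick partner of a single base (no wobble)."""
    b = base.upper().replace("T", "U")
    try:
        comp = _WC_PAIR[b]
    except KeyError:
        raise ValueError(f"invalid base: {base!r}") from None
    return comp.replace("U", "T") if alphabet == "DNA" else comp


@dataclass(frozen=True)
class GuideStrand:
    """An unmodified guide or passenger strand.

    ``core_sequence`` is RNA 5'->3' over {A,C,G,U}; ``overhang_3p`` holds the
    deoxynucleotide overhang (e.g. ``"dTdT"``) excluded from numbering.
    """

    name: str
    core_sequence: str
    overhang_3p: str = ""
    role: str = "guide"

    def __post_init__(self) -> None:
        if not self.core_sequence:
            raise ValueError("core_sequence must be non-empty")
        if not re.fullmatch(r"[ACGU]+", self.core_sequence):
            bad = next(c for c in self.core_sequence if c not in "ACGU")
            raise ValueError(f"core_sequence contains invalid character {bad!r}")
        if self.role not in ("guide", "passenger"):
            raise ValueError(f"role must be guide or passenger, got {self.role!r}")

    def __len__(self) -> int:
        return len(self.core_sequence)

    def base(self, position: int) -> str:
        """Base at a 1-based core position."""
        if not 1 <= position <= len(self.core_sequence):
            raise IndexError(f"position {position} outside 1..{len(self.core_sequence)}")
        return self.core_sequence[position - 1]


@dataclass(frozen=True)
class Modification:
    """A single chemical modification at a 1-based core position."""

    kind: str
    mode: str
    position: int

    def __post_init__(self) -> None:
        if self.kind not in _MOD_KINDS:
            raise ValueError(f"unknown modification kind {self.kind!r}")
        if self.mode not in _MOD_MODES:
            raise ValueError(f"unknown modification mode {self.mode!r}")
        if self.position < 1:
            raise ValueError("position must be >= 1")

    @property
    def abasic(self) -> bool:
        return self.kind in ABASIC_KINDS


@dataclass(frozen=True)
class ModifiedGuide:
    """A guide strand together with its modifications.

    The *effective sequence* accounts for insertions (which shift downstream
    positions by +1) and for abasic substitutions (whose position keeps its
    slot but loses its base).  ``effective_units()`` exposes it as a list of
    bases with ``None`` marking abasic slots, 1-based via list index + 1.
    """

    base: GuideStrand
    mods: tuple[Modification, ...] = ()

    def __post_init__(self) -> None:
        mods = tuple(self.mods)
        object.__setattr__(self, "mods", mods)
        n = len(self.base.core_sequence)
        seen: set[tuple[str, int]] = set()
        for m in mods:
            if m.mode == "substitution":
                if not 1 <= m.position <= n:
                    raise ValueError(
                        f"substitution position {m.position} outside 1..{n}"
                    )
            else:  # insertion sits immediately 5' of the stated position
                if not 2 <= m.position <= n:
                    raise ValueError(
                        f"insertion position {m.position} outside 2..{n}"
                    )
            key = (m.mode, m.position)
            if key in seen:
                raise ValueError(f"duplicate modification at {key}")
            seen.add(key)

    @property
    def name(self) -> str:
        return self.base.name

    def effective_units(self) -> list[str | None]:
        """Bases of the effective guide 5'->3'; ``None`` for abasic units."""
        units: list[str | None] = list(self.base.core_sequence)
        for m in self.mods:
            if m.mode == "substitution" and m.abasic:
                units[m.position - 1] = None
        # apply insertions from 3' to 5' so earlier indices stay valid
        for m in sorted(self.mods, key=lambda m: -m.position):
            if m.mode == "insertion":
                units.insert(m.position - 1, None if m.abasic else "?")
        return units

    def effective_base(self, position: int) -> str | None:
        units = self.effective_units()
        if not 1 <= position <= len(units):
            raise IndexError(f"position {position} outside 1..{len(units)}")
        return units[position - 1]


_PREFIX_RE = re.compile(r"^5[′']\s*(?:p\s*)?-")
_SUFFIX_RE = re.compile(r"-3[′']$")


def parse_guide_string(
    text: str, name: str = "guide", role: str = "guide"
) -> ModifiedGuide:
    """Parse a guide strand written in standard oligo notation.

    Accepts an optional ``5'p-``/``5'-`` prefix and ``-3'`` suffix, trailing
    ``dT`` overhang units, T/U interchangeably, and lowercase letters marking
    2'-OMe substitutions, e.g. ``5'p-UUCCGAAuAAACUCcAGGCdTdT-3'``.
    """
    if not text or not text.strip():
        raise GuideParseError("empty guide sequence")
    s = text.strip()
    s = _PREFIX_RE.sub("", s)
    s = _SUFFIX_RE.sub("", s)
    overhang = ""
    while s.endswith(("dT", "dA", "dC", "dG")):
        overhang = s[-2:] + overhang
        s = s[:-2]
    if not s:
        raise GuideParseError("guide has no core sequence")
    core_chars: list[str] = []
    ome_positions: list[int] = []
    for i, ch in enumerate(s):
        up = ch.upper()
        if up not in "ACGUT":
            raise GuideParseError(f"invalid character {ch!r} in guide sequence")
        if ch.islower():
            ome_positions.append(i + 1)
        core_chars.append("U" if up == "T" else up)
    strand = GuideStrand(
        name=name, core_sequence="".join(core_chars), overhang_3p=overhang, role=role
    )
    mods = tuple(
        Modification(kind="OMe2", mode="substitution", position=p)
        for p in ome_positions
    )
    return ModifiedGuide(base=strand, mods=mods)


def guide_to_string(guide: ModifiedGuide, with_ends: bool = True) -> str:
    """Serialize back to oligo notation (inverse of :func:`parse_guide_string`).

    Only 2'-OMe substitutions are expressible as lowercase; abasic or UNA
    modifications cannot be encoded in sequence text and raise an error.
    """
    chars = list(guide.base.core_sequence)
    for m in guide.mods:
        if m.kind == "OMe2" and m.mode == "substitution":
            chars[m.position - 1] = chars[m.position - 1].lower()
        else:
            raise ValueError(f"modification {m} has no sequence-text notation")
    body = "".join(chars) + guide.base.overhang_3p
    return f"5′p-{body}-3′" if with_ends else body


_VARIANT_RE = re.compile(r"^(\d+)(pi-rb|pi-r|pi-b|pi|c3)$", re.IGNORECASE)

_VARIANT_FAMILY = {
    "pi": ("dSpacer", "substitution"),
    "pi-r": ("rSpacer", "substitution"),
    "pi-b": ("dSpacer", "insertion"),
    "pi-rb": ("rSpacer", "insertion"),
    "c3": ("C3", "substitution"),
}


def make_variant(guide: GuideStrand | ModifiedGuide, code: str) -> ModifiedGuide:
    """Build a modified guide from a variant code.

    Supported codes: ``Npi`` (dSpacer substitution at N), ``Npi-r`` (rSpacer
    substitution), ``Npi-b`` (dSpacer insertion 5' of N), ``Npi-rb`` (rSpacer
    insertion), ``Nc3`` (C3 spacer substitution), ``2me`` (2'-OMe substitution
    at position 2), ``7UNA`` (UNA substitution at position 7), and ``WT``
    (no modification).
    """
    if isinstance(guide, ModifiedGuide):
        strand = guide.base
    else:
        strand = guide
    code_norm = code.strip()
    if code_norm.upper() == "WT":
        return ModifiedGuide(base=strand)
    if code_norm.lower() == "2me":
        return ModifiedGuide(
            base=strand, mods=(Modification("OMe2", "substitution", 2),)
        )
    if code_norm.lower() == "7una":
        return ModifiedGuide(
            base=strand, mods=(Modification("UNA", "substitution", 7),)
        )
    m = _VARIANT_RE.match(code_norm)
    if m is None:
        raise ValueError(f"unknown variant code {code!r}")
    position = int(m.group(1))
    kind, mode = _VARIANT_FAMILY[m.group(2).lower()]
    try:
        mod = Modification(kind=kind, mode=mode, position=position)
        return ModifiedGuide(base=strand, mods=(mod,))
    except ValueError as exc:
        raise ValueError(f"variant code {code!r}: {exc}") from None
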
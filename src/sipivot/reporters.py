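"""Luciferase reporter insert design.

Inserts are cloned into the 3'-UTR of the Renilla gene of a dual-luciferase
(psiCheck-2 style) vector through XhoI/NotI sites, as annealed duplex oligos
with fixed overhangs:

    forward = TCGAG + insert + GC
    reverse = GGCCGC + revcomp(insert) + C

Supported insert kinds: a perfect-match site (on-target readout), two tandem
seed-match sites (guide positions 1-8, off-target readout), two tandem
nucleation-bulge sites (9-mers carrying the pivot-complementary bulge), and
two tandem passenger-strand seed sites.
"""

from __future__ import annotations

from dataclasses import dataclass

from .guides import GuideStrand, ModifiedGuide, reverse_complement, wc_complement
from .sites import _as_modified

__all__ = ["ReporterInsert", "design_insert", "INSERT_KINDS"]

INSERT_KINDS = ("perfect", "seed_x2", "nuc_x2", "passenger_seed_x2")

_FWD_5, _FWD_3 = "TCGAG", "GC"
_REV_5, _REV_3 = "GGCCGC", "C"


@dataclass(frozen=True)
class ReporterInsert:
    kind: str
    insert_sense: str  # DNA, sense strand of the cloned site(s)
    forward_oligo: str
    reverse_oligo: str


def _site_8mer(core: str) -> str:
    """DNA reverse complement of guide positions 1-8."""
    return reverse_complement(core[:8], "DNA")


def design_insert(guide: GuideStrand | ModifiedGuide, kind: str) -> ReporterInsert:
    """Design the cloning oligos for one reporter insert.

    ``nuc_x2`` needs a base at the pivot to define the bulge nucleotide, so
    an abasic-pivot guide is rejected.
    """
    mg = _as_modified(guide)
    core = mg.base.core_sequence
    if len(core) < 8:
        raise ValueError("guide core must be >= 8 nt")
    if kind == "perfect":
        insert = reverse_complement(core, "DNA")
    elif kind == "seed_x2":
        insert = _site_8mer(core) * 2
    elif kind == "nuc_x2":
        if mg.effective_base(6) in (None, "?"):
            raise ValueError("abasic pivot: no bulge nucleotide is defined")
        eight = _site_8mer(core)
        # eight[i] is opposite guide position 8-i; bulge goes between the
        # nucleotides opposite positions 6 (index 2) and 5 (index 3)
        bulge = wc_complement(core[5], "DNA")
        insert = (eight[:3] + bulge + eight[3:]) * 2
    elif kind == "passenger_seed_x2":
        insert = _site_8mer(core) * 2
    else:
        raise ValueError(f"unknown insert kind {kind!r}")
    return ReporterInsert(
        kind=kind,
        insert_sense=insert,
        forward_oligo=_FWD_5 + insert + _FWD_3,
        reverse_oligo=_REV_5 + reverse_complement(insert, "DNA") + _REV_3,
    )
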
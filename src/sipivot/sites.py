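"""Target-site pattern generation and transcript scanning.

Two miRNA-like site classes drive off-target repression:

* **seed sites** — 6-8 nt target subsequences Watson-Crick complementary to a
  window within guide positions 1-8 (6-mers: windows 1-6, 2-7, 3-8; 7-mers:
  1-7, 2-8; 8-mer: 1-8);
* **nucleation-bulge sites** — 7-mer targets matching guide positions 2-7
  with one extra target nucleotide bulged between the nucleotides opposite
  guide positions 5 and 6; by the pivot-pairing rule the bulged nucleotide
  must be able to Watson-Crick pair the pivot (guide position 6).

All matching is exact Watson-Crick (no G:U wobble).  Guide positions are
1-based; transcript coordinates are 0-based half-open on the sense strand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .guides import GuideStrand, ModifiedGuide, reverse_complement, wc_complement

__all__ = [
    "SitePattern",
    "TranscriptRecord",
    "SiteHit",
    "SiteClassAssignment",
    "seed_patterns",
    "nucleation_bulge_pattern",
    "perfect_match_pattern",
    "all_patterns",
    "scan",
    "classify",
]

#: seed windows (1-based inclusive guide spans) by motif length
SEED_SPANS = {6: ((1, 6), (2, 7), (3, 8)), 7: ((1, 7), (2, 8)), 8: ((1, 8),)}


@dataclass(frozen=True)
class SitePattern:
    """A target-side motif (5'->3' on the transcript sense strand)."""

    site_class: str  # seed | nucleation_bulge | perfect_match
    guide_span: tuple[int, int]
    target_motif: str
    bulge_nt: str | None = None
    source_strand: str = "guide"

    def __len__(self) -> int:
        return len(self.target_motif)


@dataclass(frozen=True)
class TranscriptRecord:
    """A transcript sense-strand sequence with optional 3'-UTR annotation."""

    id: str
    sequence: str
    utr3_interval: tuple[int, int] | None = None
    coding: bool | None = None

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("T", "U")
        if not re.fullmatch(r"[ACGUN]*", seq):
            bad = next(c for c in seq if c not in "ACGUN")
            raise ValueError(f"transcript {self.id}: invalid character {bad!r}")
        object.__setattr__(self, "sequence", seq)
        if self.utr3_interval is not None:
            s, e = self.utr3_interval
            if not (0 <= s <= e <= len(seq)):
                raise ValueError(
                    f"transcript {self.id}: utr3_interval {self.utr3_interval} "
                    f"outside [0, {len(seq)})"
                )

    @property
    def is_coding(self) -> bool:
        if self.coding is not None:
            return self.coding
        return self.id.startswith("NM_")


@dataclass(frozen=True)
class SiteHit:
    """One motif occurrence on a transcript (0-based half-open)."""

    transcript_id: str
    start: int
    end: int
    pattern: SitePattern
    region: str = "unspecified"  # utr3 | non_utr3 | unspecified


@dataclass(frozen=True)
class SiteClassAssignment:
    """Per-transcript class under the Seed > Nuc > NoSite hierarchy."""

    transcript_id: str
    site_class: str  # Seed | Nuc | NoSite
    n_seed_hits: int = 0
    n_nuc_hits: int = 0


def _window_units(guide: ModifiedGuide, span: tuple[int, int]) -> list[str] | None:
    """Effective bases over an inclusive 1-based span, or None if any abasic."""
    units = guide.effective_units()
    lo, hi = span
    if hi > len(units):
        return None
    window = units[lo - 1 : hi]
    if any(u is None or u == "?" for u in window):
        return None
    return window  # type: ignore[return-value]


def _as_modified(guide: GuideStrand | ModifiedGuide) -> ModifiedGuide:
    return guide if isinstance(guide, ModifiedGuide) else ModifiedGuide(base=guide)


def seed_patterns(
    guide: GuideStrand | ModifiedGuide,
    lengths: set[int] | tuple[int, ...] = (6, 7, 8),
) -> list[SitePattern]:
    """Seed-site motifs for every eligible window of the requested lengths.

    Windows overlapping an abasic position have no base to pair and are
    silently dropped; an abasic pivot therefore removes every window (all
    length>=6 windows within positions 1-8 cover position 6).
    """
    mg = _as_modified(guide)
    if len(mg.effective_units()) < 8:
        raise ValueError("guide core must be >= 8 nt for seed patterns")
    bad = set(lengths) - {6, 7, 8}
    if bad:
        raise ValueError(f"unsupported seed lengths: {sorted(bad)}")
    patterns = []
    for length in sorted(lengths):
        for span in SEED_SPANS[length]:
            window = _window_units(mg, span)
            if window is None:
                continue
            motif = reverse_complement("".join(window), "RNA")
            patterns.append(
                SitePattern(
                    site_class="seed",
                    guide_span=span,
                    target_motif=motif,
                    source_strand=mg.base.role,
                )
            )
    return patterns


def nucleation_bulge_pattern(
    guide: GuideStrand | ModifiedGuide,
) -> SitePattern | None:
    """The unique 7-mer nucleation-bulge motif, or None for an abasic pivot.

    Construction: reverse complement of guide positions 2-7, with the
    pivot-complementary nucleotide inserted between the target nucleotides
    opposite guide positions 6 and 5.
    """
    mg = _as_modified(guide)
    units = mg.effective_units()
    if len(units) < 7:
        raise ValueError("guide core must be >= 7 nt for a nucleation-bulge pattern")
    window = _window_units(mg, (2, 7))
    if window is None:
        return None  # an abasic unit within 2-7 (e.g. 6pi/6c3/6pi-r): no pattern
    pivot_base = units[5]
    assert pivot_base not in (None, "?")
    bulge = wc_complement(pivot_base)
    rc = reverse_complement("".join(window), "RNA")
    # rc index i is opposite guide position 7-i; opposite-6 is index 1,
    # opposite-5 is index 2 — the bulge goes between them
    motif = rc[:2] + bulge + rc[2:]
    return SitePattern(
        site_class="nucleation_bulge",
        guide_span=(2, 7),
        target_motif=motif,
        bulge_nt=bulge,
        source_strand=mg.base.role,
    )


def perfect_match_pattern(guide: GuideStrand | ModifiedGuide) -> SitePattern:
    """Fully complementary (on-target) site for the unmodified core."""
    mg = _as_modified(guide)
    core = mg.base.core_sequence
    return SitePattern(
        site_class="perfect_match",
        guide_span=(1, len(core)),
        target_motif=reverse_complement(core, "RNA"),
        source_strand=mg.base.role,
    )


def all_patterns(
    guide: GuideStrand | ModifiedGuide,
    seed_lengths: set[int] | tuple[int, ...] = (6, 7, 8),
) -> list[SitePattern]:
    """Seed windows plus the nucleation-bulge pattern (when it exists)."""
    patterns = seed_patterns(guide, seed_lengths)
    nuc = nucleation_bulge_pattern(guide)
    if nuc is not None:
        patterns.append(nuc)
    return patterns


def scan(
    records: list[TranscriptRecord],
    patterns: list[SitePattern],
    region_mode: str = "whole_transcript",
) -> list[SiteHit]:
    """All (overlapping) motif occurrences on each transcript.

    ``region_mode="utr3_only"`` keeps only hits wholly inside the annotated
    3'-UTR and skips records lacking one.
    """
    if region_mode not in ("whole_transcript", "utr3_only"):
        raise ValueError(f"unknown region_mode {region_mode!r}")
    hits: list[SiteHit] = []
    for rec in records:
        if region_mode == "utr3_only" and rec.utr3_interval is None:
            continue
        seq = rec.sequence
        for pat in patterns:
            motif = pat.target_motif
            start = seq.find(motif)
            while start != -1:
                end = start + len(motif)
                if rec.utr3_interval is not None:
                    u0, u1 = rec.utr3_interval
                    inside = u0 <= start and end <= u1
                    region = "utr3" if inside else "non_utr3"
                else:
                    inside = False
                    region = "unspecified"
                if region_mode == "whole_transcript" or inside:
                    hits.append(SiteHit(rec.id, start, end, pat, region))
                start = seq.find(motif, start + 1)
    return hits


def classify(
    records: list[TranscriptRecord],
    hits: list[SiteHit],
    scheme: str = "matched_7mer",
) -> list[SiteClassAssignment]:
    """Assign Seed / Nuc / NoSite to every record (hierarchy Seed > Nuc).

    ``matched_7mer`` counts only span 2-8 seed hits (the classic 7mer-m8
    site) as Seed, so seed and nucleation-bulge sites are compared at
    matched motif length over the same guide anchor; ``matched_7mer_both``
    additionally counts span 1-7 hits; ``any_seed`` counts any 6/7/8-mer.
    The 2-8-only default keeps nucleation-bulge controls clean: for guides
    whose positions 6 and 7 share a base, the bulge motif inherently embeds
    a span 1-7 seed match.
    """
    if scheme not in ("matched_7mer", "matched_7mer_both", "any_seed"):
        raise ValueError(f"unknown scheme {scheme!r}")
    ids = {rec.id for rec in records}
    seed_counts: dict[str, int] = {rid: 0 for rid in ids}
    nuc_counts: dict[str, int] = {rid: 0 for rid in ids}
    for hit in hits:
        if hit.transcript_id not in ids:
            raise KeyError(f"hit references unknown transcript {hit.transcript_id!r}")
        if hit.pattern.site_class == "seed":
            if scheme == "matched_7mer" and hit.pattern.guide_span != (2, 8):
                continue
            if scheme == "matched_7mer_both" and len(hit.pattern) != 7:
                continue
            seed_counts[hit.transcript_id] += 1
        elif hit.pattern.site_class == "nucleation_bulge":
            nuc_counts[hit.transcript_id] += 1
    out = []
    for rec in records:
        ns, nn = seed_counts[rec.id], nuc_counts[rec.id]
        cls = "Seed" if ns > 0 else ("Nuc" if nn > 0 else "NoSite")
        out.append(SiteClassAssignment(rec.id, cls, ns, nn))
    return out
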
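"""Qualitative modification-effect rules.

Maps a guide modification and a site class to a functional status:

* ``functional`` — the site class still represses as for the unmodified guide;
* ``attenuated`` — measurable but reduced repression remains;
* ``abolished`` — no detectable repression through that site class.

The rule table is distilled from reporter-assay and transcriptome evidence:
abasic substitutions (dSpacer, positions 2-7; rSpacer, 3-6; C3 at the pivot)
abolish seed-mediated repression; an abasic pivot (6pi / 6c3) also abolishes
nucleation-bulge sites while the on-target perfect-match site stays
functional; abasic insertions within positions 4-6 abolish seed sites but
attenuate on-target activity; the backbone modifications 2'-OMe (position 2)
and UNA (position 7) only attenuate miRNA-like repression.

Queries outside the table return ``"not_covered"`` rather than a guess —
notably rSpacer substitution at position 2 (not observed to derepress) and
the nucleation-bulge behaviour of non-pivot dSpacer substitutions.

The table ships as a plain-text TSV (``data/effect_rules.tsv``) loaded at
run time; columns: kind, mode, pos_min, pos_max, site_class, status.
"""

from __future__ import annotations

import csv
from functools import lru_cache
from importlib import resources

from .guides import ModifiedGuide
from .sites import SiteClassAssignment

__all__ = [
    "load_rule_table",
    "predict_site_functionality",
    "predict_variant_code",
    "annotate_expected_derepression",
    "SITE_CLASSES",
    "NOT_COVERED",
]

SITE_CLASSES = ("seed", "nucleation_bulge", "perfect_match")
NOT_COVERED = "not_covered"

#: maps assignment labels to pattern-class names
_LABEL_TO_CLASS = {"Seed": "seed", "Nuc": "nucleation_bulge"}


@lru_cache(maxsize=1)
def load_rule_table() -> tuple[dict, ...]:
    with resources.files("sipivot.data").joinpath("effect_rules.tsv").open() as fh:
        rows = tuple(csv.DictReader(fh, delimiter="\t"))
    for row in rows:
        row["pos_min"] = int(row["pos_min"])
        row["pos_max"] = int(row["pos_max"])
    return rows


def _lookup(kind: str, mode: str, position: int, site_class: str) -> str:
    for row in load_rule_table():
        if (
            row["kind"] == kind
            and row["mode"] == mode
            and row["pos_min"] <= position <= row["pos_max"]
            and row["site_class"] == site_class
        ):
            return row["status"]
    return NOT_COVERED


def predict_site_functionality(guide: ModifiedGuide, site_class: str) -> str:
    """Status of a site class for a guide with zero or one relevant modification.

    Unmodified guides are functional for every class.  Guides with more than
    one rule-relevant modification are outside the table (``not_covered``).
    """
    if site_class not in SITE_CLASSES:
        raise ValueError(f"unknown site class {site_class!r}")
    if not guide.mods:
        return "functional"
    if len(guide.mods) > 1:
        return NOT_COVERED
    m = guide.mods[0]
    return _lookup(m.kind, m.mode, m.position, site_class)


def predict_variant_code(code: str, site_class: str) -> str:
    """Rule lookup by variant code, covering codes (e.g. ``2bulge``) that are
    not expressible as a single-strand modification."""
    if site_class not in SITE_CLASSES:
        raise ValueError(f"unknown site class {site_class!r}")
    if code.strip().lower() == "2bulge":
        return _lookup("2bulge", "duplex", 2, site_class)
    return predict_site_functionality(make_variant_from_code(code), site_class)


def make_variant_from_code(code: str) -> ModifiedGuide:
    """Variant of a length-19 poly-A scaffold: rule lookups depend only on the
    modification signature, never on the sequence."""
    from .guides import GuideStrand, make_variant

    scaffold = GuideStrand(name="scaffold", core_sequence="A" * 19)
    return make_variant(scaffold, code)


def annotate_expected_derepression(
    variant: ModifiedGuide | str,
    assignments: list[SiteClassAssignment],
) -> set[str]:
    """Transcripts predicted to be derepressed by a variant.

    ``assignments`` must come from the *unmodified* guide; a transcript is
    expected to be derepressed when its site class maps to ``abolished``
    under the variant (attenuated classes are retained).
    """
    derepressed: set[str] = set()
    for a in assignments:
        cls = _LABEL_TO_CLASS.get(a.site_class)
        if cls is None:  # NoSite
            continue
        if isinstance(variant, str):
            status = predict_variant_code(variant, cls)
        else:
            status = predict_site_functionality(variant, cls)
        if status == "abolished":
            derepressed.add(a.transcript_id)
    return derepressed
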
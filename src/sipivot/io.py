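"""Readers and writers for the pipeline's file formats.

Formats: FASTA transcripts (wrapped lines and mixed case tolerated; records
normalized to RNA), TSV tables (UTF-8, tab-delimited, single header row,
stable column order) for 3'-UTR intervals, guide manifests, fold changes,
hits, assignments and reports, and JSON summaries.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .enrichment import EnrichmentResult, FoldChangeProfile
from .guides import ModifiedGuide, parse_guide_string
from .sites import SiteClassAssignment, SiteHit, TranscriptRecord

HIT_COLUMNS = ["transcript_id", "start", "end", "site_class", "guide_span", "motif", "region"]
ASSIGNMENT_COLUMNS = ["transcript_id", "site_class", "n_seed_hits", "n_nuc_hits"]
ENRICHMENT_COLUMNS = [
    "site_class", "n_class", "n_control", "ks_D", "p_raw", "p_adjusted",
    "median_shift", "testable",
]


def read_transcripts(
    fasta_path: str | Path, utr_tsv: str | Path | None = None
) -> list[TranscriptRecord]:
    """Load transcripts from FASTA, with optional 3'-UTR intervals.

    The UTR TSV needs columns transcript_id, utr3_start, utr3_end (0-based
    half-open).
    """
    utrs: dict[str, tuple[int, int]] = {}
    if utr_tsv is not None:
        df = pd.read_csv(utr_tsv, sep="\t")
        for col in ("transcript_id", "utr3_start", "utr3_end"):
            if col not in df.columns:
                raise ValueError(f"UTR table is missing column {col!r}")
        utrs = {
            str(r.transcript_id): (int(r.utr3_start), int(r.utr3_end))
            for r in df.itertuples(index=False)
        }
    records = []
    for i, rec in enumerate(SeqIO.parse(str(fasta_path), "fasta")):
        try:
            records.append(
                TranscriptRecord(rec.id, str(rec.seq), utrs.get(rec.id))
            )
        except ValueError as exc:
            raise ValueError(f"FASTA record {i + 1} ({rec.id}): {exc}") from None
    return records


def write_transcripts(records: list[TranscriptRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 70):
                fh.write(rec.sequence[i : i + 70] + "\n")


def read_guide_manifest(path: str | Path) -> list[ModifiedGuide]:
    """Guide manifest TSV with columns name, sequence (oligo notation), role."""
    df = pd.read_csv(path, sep="\t")
    for col in ("name", "sequence"):
        if col not in df.columns:
            raise ValueError(f"guide manifest is missing column {col!r}")
    guides = []
    for row in df.itertuples(index=False):
        role = getattr(row, "role", "guide")
        guides.append(parse_guide_string(str(row.sequence), name=str(row.name), role=role))
    return guides


def hits_to_frame(hits: list[SiteHit]) -> pd.DataFrame:
    rows = [
        {
            "transcript_id": h.transcript_id,
            "start": h.start,
            "end": h.end,
            "site_class": h.pattern.site_class,
            "guide_span": f"{h.pattern.guide_span[0]}-{h.pattern.guide_span[1]}",
            "motif": h.pattern.target_motif,
            "region": h.region,
        }
        for h in hits
    ]
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def assignments_to_frame(assigns: list[SiteClassAssignment]) -> pd.DataFrame:
    rows = [
        {
            "transcript_id": a.transcript_id,
            "site_class": a.site_class,
            "n_seed_hits": a.n_seed_hits,
            "n_nuc_hits": a.n_nuc_hits,
        }
        for a in assigns
    ]
    return pd.DataFrame(rows, columns=ASSIGNMENT_COLUMNS)


def read_assignments(path: str | Path) -> list[SiteClassAssignment]:
    df = pd.read_csv(path, sep="\t")
    return [
        SiteClassAssignment(
            str(r.transcript_id), str(r.site_class), int(r.n_seed_hits), int(r.n_nuc_hits)
        )
        for r in df.itertuples(index=False)
    ]


def read_fold_changes(path: str | Path, experiment_id: str | None = None) -> FoldChangeProfile:
    df = pd.read_csv(path, sep="\t")
    for col in ("transcript_id", "log2fc"):
        if col not in df.columns:
            raise ValueError(f"fold-change table is missing column {col!r}")
    return FoldChangeProfile.from_frame(df, experiment_id or Path(path).stem)


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def enrichment_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    rows = [
        {
            "site_class": r.site_class,
            "n_class": r.n_class,
            "n_control": r.n_control,
            "ks_D": r.ks_D,
            "p_raw": r.p_raw,
            "p_adjusted": r.p_adjusted,
            "median_shift": r.median_shift,
            "testable": r.testable,
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
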
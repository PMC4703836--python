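"""Site-stratified off-target repression statistics.

The central readout of miRNA-like off-target activity is distributional:
transcripts carrying seed or nucleation-bulge sites are shifted toward
negative log2 fold change relative to transcripts with neither site class
("NoSite" controls).  This module provides

* per-profile preprocessing (coding-transcript filter, significance subset),
* empirical CDF curves per site class,
* two-sample Kolmogorov-Smirnov tests of each class against the control,
  with Bonferroni correction across class comparisons,
* the paired WT-vs-modified binomial derepression test: among transcripts
  repressed under the unmodified guide, a variant that abolishes the sites
  should leave ~50% below zero by chance alone.

`OffTargetEnrichment` wraps the pooled class-vs-control analysis as a
model object whose ``fit()`` returns an `EnrichmentResults` with a
``summary()`` table, in the style of statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .sites import SiteClassAssignment, TranscriptRecord

__all__ = [
    "FoldChangeProfile",
    "CdfCurve",
    "EnrichmentResult",
    "filter_coding",
    "subset_significant",
    "empirical_cdf",
    "ks_two_sample",
    "bonferroni",
    "run_enrichment",
    "derepression_binomial",
    "OffTargetEnrichment",
    "EnrichmentResults",
]


@dataclass
class FoldChangeProfile:
    """Per-transcript log2 fold changes for one experiment/condition.

    ``entries`` maps transcript_id -> dict with key ``log2fc`` and optional
    ``pvalue`` / ``significant``.
    """

    experiment_id: str
    entries: dict[str, dict]

    def __post_init__(self) -> None:
        for tid, e in self.entries.items():
            if not np.isfinite(e["log2fc"]):
                raise ValueError(f"non-finite log2fc for transcript {tid!r}")

    def __len__(self) -> int:
        return len(self.entries)

    def log2fc(self, transcript_id: str) -> float:
        return self.entries[transcript_id]["log2fc"]

    @classmethod
    def from_frame(cls, df: pd.DataFrame, experiment_id: str) -> "FoldChangeProfile":
        """Build from a table with columns transcript_id, log2fc
        [, pvalue][, significant]."""
        entries = {}
        for row in df.itertuples(index=False):
            e: dict = {"log2fc": float(row.log2fc)}
            if hasattr(row, "pvalue") and not pd.isna(row.pvalue):
                e["pvalue"] = float(row.pvalue)
            if hasattr(row, "significant") and not pd.isna(row.significant):
                e["significant"] = bool(row.significant)
            entries[str(row.transcript_id)] = e
        return cls(experiment_id=experiment_id, entries=entries)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for tid, e in self.entries.items():
            rows.append(
                {
                    "transcript_id": tid,
                    "log2fc": e["log2fc"],
                    "pvalue": e.get("pvalue", np.nan),
                    "significant": e.get("significant", np.nan),
                }
            )
        return pd.DataFrame(rows, columns=["transcript_id", "log2fc", "pvalue", "significant"])


@dataclass(frozen=True)
class CdfCurve:
    """Right-continuous empirical CDF: sorted values and cumulative fractions."""

    values: np.ndarray
    fractions: np.ndarray

    def __call__(self, x: float) -> float:
        return float(np.searchsorted(self.values, x, side="right") / len(self.values))


@dataclass(frozen=True)
class EnrichmentResult:
    site_class: str
    n_class: int
    n_control: int
    ks_D: float
    p_raw: float
    p_adjusted: float
    median_shift: float
    testable: bool = True


def filter_coding(
    profile: FoldChangeProfile, records: list[TranscriptRecord] | None = None
) -> FoldChangeProfile:
    """Keep only coding transcripts (``NM_`` id prefix or an explicit flag)."""
    coding_flags = {r.id: r.is_coding for r in records} if records else {}
    kept = {
        tid: e
        for tid, e in profile.entries.items()
        if coding_flags.get(tid, tid.startswith("NM_"))
    }
    return FoldChangeProfile(profile.experiment_id, kept)


def subset_significant(
    profile: FoldChangeProfile, alpha: float = 0.05
) -> FoldChangeProfile:
    """Keep entries with pvalue < alpha or an explicit significant=True flag."""
    kept = {}
    for tid, e in profile.entries.items():
        if "significant" in e:
            if e["significant"]:
                kept[tid] = e
        elif "pvalue" in e:
            if e["pvalue"] < alpha:
                kept[tid] = e
        else:
            raise ValueError(
                f"transcript {tid!r} has neither a pvalue nor a significant flag"
            )
    return FoldChangeProfile(profile.experiment_id, kept)


def empirical_cdf(values) -> CdfCurve:
    arr = np.sort(np.asarray(values, dtype=float))
    if arr.size == 0:
        raise ValueError("empirical_cdf needs at least one value")
    fractions = np.arange(1, arr.size + 1) / arr.size
    return CdfCurve(values=arr, fractions=fractions)


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    res = stats.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)


def bonferroni(p: float, n_tests: int) -> float:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return min(1.0, p * n_tests)


def _pool(
    profiles: list[FoldChangeProfile],
    assignments: list[list[SiteClassAssignment]],
) -> dict[str, list[float]]:
    """Pool transcript-experiment log2fc observations by site class.

    Each profile is paired with assignments computed from its own guide; each
    (transcript, experiment) pair contributes one observation.
    """
    pooled: dict[str, list[float]] = {"Seed": [], "Nuc": [], "NoSite": []}
    for profile, assigns in zip(profiles, assignments, strict=True):
        by_id = {a.transcript_id: a.site_class for a in assigns}
        for tid, e in profile.entries.items():
            cls = by_id.get(tid)
            if cls is not None:
                pooled[cls].append(e["log2fc"])
    return pooled


def run_enrichment(
    profiles: FoldChangeProfile | list[FoldChangeProfile],
    assignments: list[SiteClassAssignment] | list[list[SiteClassAssignment]],
    control: str = "nosite",
) -> list[EnrichmentResult]:
    """KS enrichment of Seed and Nuc classes against the control distribution.

    ``control="nosite"`` compares each class against pooled NoSite
    transcripts; ``control="total"`` against all pooled transcripts.
    Bonferroni correction is applied over the number of class comparisons.
    A class with fewer than 2 observations is flagged not testable.
    """
    if isinstance(profiles, FoldChangeProfile):
        profiles = [profiles]
        assignments = [assignments]  # type: ignore[list-item]
    if control not in ("nosite", "total"):
        raise ValueError(f"unknown control {control!r}")
    pooled = _pool(profiles, assignments)  # type: ignore[arg-type]
    if control == "nosite":
        ctrl = np.asarray(pooled["NoSite"], dtype=float)
    else:
        ctrl = np.asarray(
            pooled["Seed"] + pooled["Nuc"] + pooled["NoSite"], dtype=float
        )
    classes = ["Seed", "Nuc"]
    results = []
    for cls in classes:
        vals = np.asarray(pooled[cls], dtype=float)
        if vals.size < 2 or ctrl.size < 2:
            results.append(
                EnrichmentResult(cls, vals.size, ctrl.size, np.nan, np.nan, np.nan,
                                 np.nan, testable=False)
            )
            continue
        d, p = ks_two_sample(vals, ctrl)
        shift = float(np.median(vals) - np.median(ctrl))
        results.append(
            EnrichmentResult(cls, vals.size, ctrl.size, d, p,
                             bonferroni(p, len(classes)), shift)
        )
    return results


def derepression_binomial(
    profile_wt: FoldChangeProfile,
    profile_mod: FoldChangeProfile,
    alpha: float = 0.05,
) -> tuple[int, int, float, float]:
    """Paired WT-vs-modified derepression test.

    Among transcripts significantly changed under the unmodified (WT)
    condition and repressed there (WT log2fc < 0; count ``n``), ``k`` counts
    those still below zero under the modified condition.  Returns
    ``(n, k, p_binomial, median_shift)`` with a two-sided binomial test of
    k/n against 0.5 and the paired median of (mod - WT).

    Selection uses the WT profile's ``significant`` flags when present, else
    ``pvalue < alpha``; entries with neither are excluded.
    """
    shared = set(profile_wt.entries) & set(profile_mod.entries)
    selected = []
    for tid in shared:
        e = profile_wt.entries[tid]
        if "significant" in e:
            ok = bool(e["significant"])
        elif "pvalue" in e:
            ok = e["pvalue"] < alpha
        else:
            continue
        if ok and e["log2fc"] < 0:
            selected.append(tid)
    n = len(selected)
    if n == 0:
        raise ValueError("no significantly WT-repressed transcripts to test")
    k = sum(1 for tid in selected if profile_mod.entries[tid]["log2fc"] < 0)
    p = float(stats.binomtest(k, n, 0.5, alternative="two-sided").pvalue)
    shift = float(
        np.median(
            [profile_mod.entries[t]["log2fc"] - profile_wt.entries[t]["log2fc"]
             for t in selected]
        )
    )
    return n, k, p, shift


class OffTargetEnrichment:
    """Pooled site-class enrichment model over one or more experiments.

    Parameters
    ----------
    profiles
        One profile, or a list of profiles (one per siRNA experiment).
    assignments
        Site-class assignments matching each profile, computed by scanning
        the corresponding guide's patterns over the transcriptome.
    control
        "nosite" (default) or "total".
    coding_only
        Apply the coding-transcript filter before testing.
    """

    def __init__(
        self,
        profiles,
        assignments,
        control: str = "nosite",
        coding_only: bool = False,
        records: list[TranscriptRecord] | None = None,
    ) -> None:
        if isinstance(profiles, FoldChangeProfile):
            profiles = [profiles]
            assignments = [assignments]
        if coding_only:
            profiles = [filter_coding(p, records) for p in profiles]
        self.profiles = list(profiles)
        self.assignments = list(assignments)
        self.control = control

    def fit(self) -> "EnrichmentResults":
        results = run_enrichment(self.profiles, self.assignments, self.control)
        pooled = _pool(self.profiles, self.assignments)
        curves = {
            cls: empirical_cdf(vals) for cls, vals in pooled.items() if vals
        }
        return EnrichmentResults(self, results, curves)


@dataclass
class EnrichmentResults:
    """Fitted enrichment results with per-class CDF curves."""

    model: OffTargetEnrichment
    results: list[EnrichmentResult]
    cdf_curves: dict[str, CdfCurve] = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
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
                for r in self.results
            ]
        )

    def cdf_frame(self) -> pd.DataFrame:
        """Long-format CDF points per class, for plotting or TSV export."""
        frames = []
        for cls, curve in self.cdf_curves.items():
            frames.append(
                pd.DataFrame(
                    {
                        "site_class": cls,
                        "log2fc": curve.values,
                        "cumulative_fraction": curve.fractions,
                    }
                )
            )
        return (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(columns=["site_class", "log2fc", "cumulative_fraction"])
        )
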
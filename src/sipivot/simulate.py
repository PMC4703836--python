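"""Synthetic transcriptomes, fold-change profiles and dose-response curves.

The generators emulate the statistical structure the analysis assumes:

* transcriptomes with planted target sites — Seed-class transcripts carry at
  least one span 2-8 seed match, Nuc-class transcripts carry at least one
  nucleation-bulge motif and are rejection-sampled to carry no qualifying
  seed match, NoSite transcripts carry neither;
* Gaussian log2 fold changes with class-specific mean shifts (negative =
  repression), seed shifts larger in magnitude than nucleation-bulge shifts,
  NoSite centred on zero; under a variant condition, classes whose status is
  ``abolished`` revert to zero mean and ``attenuated`` classes to half their
  shift (a testing convention);
* replicate luciferase activities drawn around the same control-anchored
  sigmoid used for fitting.

All generators take an explicit seed/Generator and are byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .doseresponse import DoseResponseData, sigmoid
from .effects import predict_variant_code
from .enrichment import FoldChangeProfile
from .guides import GuideStrand, ModifiedGuide
from .sites import TranscriptRecord, nucleation_bulge_pattern, seed_patterns

__all__ = [
    "SimulationConfig",
    "simulate_transcriptome",
    "simulate_truth_labels",
    "simulate_profiles",
    "simulate_dose_response",
]

_BASES = np.array(list("ACGU"))
_MAX_TRIES = 200


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic pipeline.

    Defaults mirror the pooled off-target analysis regime: few hundred
    transcripts per site class against an order-of-magnitude larger NoSite
    background, a mean seed repression of -0.4 log2 units (nucleation-bulge
    sites weaker, -0.2), and per-transcript noise s.d. 0.5 log2 units.
    """

    rng_seed: int = 0
    n_seed: int = 300
    n_nuc: int = 300
    n_nosite: int = 3000
    length_range: tuple[int, int] = (200, 2000)
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    mu_seed: float = -0.4
    mu_nuc: float = -0.2
    sigma: float = 0.5
    condition: str = "WT"
    simulate_pvalues: bool = False

    def __post_init__(self) -> None:
        if min(self.n_seed, self.n_nuc, self.n_nosite) < 0:
            raise ValueError("class counts must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.length_range[0] < 20:
            raise ValueError("transcripts must be at least pattern length")
        comp = np.asarray(self.base_composition, dtype=float)
        if comp.shape != (4,) or not np.isclose(comp.sum(), 1.0):
            raise ValueError("base_composition must be 4 probabilities summing to 1")


def _random_seq(rng: np.random.Generator, length: int, comp) -> str:
    return "".join(rng.choice(_BASES, size=length, p=comp))


def _plant(seq: str, motif: str, pos: int) -> str:
    return seq[:pos] + motif + seq[pos + len(motif):]


def simulate_transcriptome(
    guide: GuideStrand | ModifiedGuide, config: SimulationConfig
) -> tuple[list[TranscriptRecord], pd.DataFrame]:
    """Generate transcripts with planted sites plus a truth table.

    Truth columns: transcript_id, site_class (Seed/Nuc/NoSite), planted_start,
    planted_end (0-based half-open; -1 for NoSite), motif.  Ids carry the
    coding ``NM_`` prefix so they survive the coding filter.
    """
    rng = np.random.default_rng(config.rng_seed)
    comp = np.asarray(config.base_composition, dtype=float)
    all_seed = [p.target_motif for p in seed_patterns(guide, (6, 7, 8))]
    nuc = nucleation_bulge_pattern(guide)
    if nuc is None:
        raise ValueError("guide has no nucleation-bulge pattern to plant")
    planted_seed = next(
        p.target_motif for p in seed_patterns(guide, (7,)) if p.guide_span == (2, 8)
    )

    records: list[TranscriptRecord] = []
    truth_rows: list[dict] = []
    counter = 1

    def _new_id() -> str:
        nonlocal counter
        tid = f"NM_{counter:06d}"
        counter += 1
        return tid

    def _sample(forbidden: list[str], plant_motif: str | None) -> tuple[str, int]:
        """Random transcript avoiding ``forbidden`` motifs, optionally with one
        planted occurrence of ``plant_motif`` (also absent from flanks)."""
        for _ in range(_MAX_TRIES):
            length = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
            seq = _random_seq(rng, length, comp)
            pos = -1
            if plant_motif is not None:
                pos = int(rng.integers(0, length - len(plant_motif) + 1))
                seq = _plant(seq, plant_motif, pos)
            window = None
            if plant_motif is not None:
                window = (pos, pos + len(plant_motif))
            ok = True
            for m in forbidden:
                start = seq.find(m)
                while start != -1:
                    inside = (
                        window is not None
                        and start >= window[0]
                        and start + len(m) <= window[1]
                    )
                    if not inside:
                        ok = False
                        break
                    start = seq.find(m, start + 1)
                if not ok:
                    break
            if ok and plant_motif is not None and seq.count(plant_motif) >= 1:
                return seq, pos
            if ok and plant_motif is None:
                return seq, -1
        raise RuntimeError(
            "rejection sampling exceeded retry cap; base composition too degenerate"
        )

    # Seed class: plant the span 2-8 7-mer; no constraint on extra sites.
    for _ in range(config.n_seed):
        tid = _new_id()
        seq, pos = _sample([], planted_seed)
        records.append(TranscriptRecord(tid, seq))
        truth_rows.append(
            {"transcript_id": tid, "site_class": "Seed", "planted_start": pos,
             "planted_end": pos + len(planted_seed), "motif": planted_seed}
        )
    # Nuc class: plant the bulge motif; forbid any seed match elsewhere.
    for _ in range(config.n_nuc):
        tid = _new_id()
        seq, pos = _sample(all_seed, nuc.target_motif)
        records.append(TranscriptRecord(tid, seq))
        truth_rows.append(
            {"transcript_id": tid, "site_class": "Nuc", "planted_start": pos,
             "planted_end": pos + len(nuc.target_motif), "motif": nuc.target_motif}
        )
    # NoSite class: forbid every pattern.
    forbidden_all = all_seed + [nuc.target_motif]
    for _ in range(config.n_nosite):
        tid = _new_id()
        seq, _pos = _sample(forbidden_all, None)
        records.append(TranscriptRecord(tid, seq))
        truth_rows.append(
            {"transcript_id": tid, "site_class": "NoSite", "planted_start": -1,
             "planted_end": -1, "motif": ""}
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=["transcript_id", "site_class", "planted_start", "planted_end", "motif"],
    )
    return records, truth


def simulate_truth_labels(config: SimulationConfig) -> pd.DataFrame:
    """Truth table of class labels only (no sequences).

    Sufficient input for :func:`simulate_profiles`, whose statistics depend
    only on class membership; use :func:`simulate_transcriptome` when the
    sequences themselves are needed.
    """
    rows = []
    counter = 1
    for cls, n in (("Seed", config.n_seed), ("Nuc", config.n_nuc),
                   ("NoSite", config.n_nosite)):
        for _ in range(n):
            rows.append(
                {"transcript_id": f"NM_{counter:06d}", "site_class": cls,
                 "planted_start": -1, "planted_end": -1, "motif": ""}
            )
            counter += 1
    return pd.DataFrame(
        rows,
        columns=["transcript_id", "site_class", "planted_start", "planted_end", "motif"],
    )


_CLASS_TO_PATTERN = {"Seed": "seed", "Nuc": "nucleation_bulge"}


def _condition_mu(site_class: str, mu: float, variant: str | None) -> float:
    if variant is None or site_class == "NoSite":
        return mu if site_class != "NoSite" else 0.0
    status = predict_variant_code(variant, _CLASS_TO_PATTERN[site_class])
    if status == "abolished":
        return 0.0
    if status == "attenuated":
        return mu / 2.0  # documented testing convention
    if status == "functional":
        return mu
    raise ValueError(
        f"variant {variant!r} has no covered rule for class {site_class}"
    )


def simulate_profiles(
    truth: pd.DataFrame,
    config: SimulationConfig,
    variant: str | None = None,
    experiment_id: str | None = None,
) -> FoldChangeProfile:
    """Gaussian log2 fold changes with class-conditional means.

    ``variant=None`` (or ``"WT"``) keeps the planted shifts; otherwise the
    modification-effect table decides which class shifts survive.  With
    ``config.simulate_pvalues`` each transcript gets a pvalue consistent with
    |log2fc| (one-sample z against the noise s.d.) and a significance flag
    at 0.05.
    """
    if variant is not None and variant.upper() == "WT":
        variant = None
    # each condition is a separate experiment with its own measurement noise:
    # key the stream by (seed, condition) so WT and variant draws are independent
    condition_key = [ord(c) for c in (variant or "WT")]
    rng = np.random.default_rng([config.rng_seed, 1, *condition_key])
    mu_by_class = {
        "Seed": _condition_mu("Seed", config.mu_seed, variant),
        "Nuc": _condition_mu("Nuc", config.mu_nuc, variant),
        "NoSite": 0.0,
    }
    entries: dict[str, dict] = {}
    for row in truth.itertuples(index=False):
        mu = mu_by_class[row.site_class]
        fc = float(rng.normal(mu, config.sigma))
        e: dict = {"log2fc": fc}
        if config.simulate_pvalues:
            from scipy import stats as _stats

            z = abs(fc) / config.sigma
            p = float(2.0 * _stats.norm.sf(z))
            e["pvalue"] = p
            e["significant"] = p < 0.05
        entries[str(row.transcript_id)] = e
    name = experiment_id or (variant or "WT")
    return FoldChangeProfile(experiment_id=name, entries=entries)


def simulate_dose_response(
    plateau: float,
    ic50: float,
    hill: float,
    concentrations,
    n_reps: int = 6,
    sigma_pct: float = 3.0,
    rng: np.random.Generator | int | None = None,
) -> DoseResponseData:
    """Replicate relative activities around the repression sigmoid.

    ``plateau`` in [0, 100] %; a zero plateau yields a null (flat 100%) curve.
    Control replicates are drawn around 100%.
    """
    if not 0.0 <= plateau <= 100.0:
        raise ValueError("plateau must be within [0, 100]")
    conc = np.asarray(concentrations, dtype=float)
    if conc.size < 1 or np.any(conc <= 0):
        raise ValueError("concentrations must be strictly positive")
    if sigma_pct < 0:
        raise ValueError("sigma_pct must be >= 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    activities = {}
    for c in conc:
        mean = float(sigmoid(c, plateau, ic50, hill))
        activities[float(c)] = mean + rng.normal(0.0, sigma_pct, size=n_reps) \
            if sigma_pct > 0 else np.full(n_reps, mean)
    ctrl = 100.0 + (rng.normal(0.0, sigma_pct, size=n_reps) if sigma_pct > 0
                    else np.zeros(n_reps))
    return DoseResponseData(conc, activities, ctrl)
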
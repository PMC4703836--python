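# sipivot

Tools for predicting and quantifying miRNA-like off-target repression of
siRNAs, and for analysing how guide-strand chemical modifications — above
all *abasic pivot substitution* (an abasic spacer replacing the base at
guide position 6, variant code `6pi`) — remove that off-target activity
while preserving on-target silencing.

It is written for people who design siRNAs or analyse knockdown
transcriptome data: given a guide strand it derives the target-side site
patterns, scans transcripts for them, stratifies fold-change profiles by
site class, fits dose-response curves from luciferase assays, and designs
the reporter inserts used to validate all of this at the bench. A
synthetic-data module generates transcriptomes with planted sites so the
whole pipeline is testable end to end without external downloads.

## The model in brief

An siRNA guide strand is numbered 1-based from its 5' end; position 6 is
the **pivot**, the last base of the transitional-nucleation span (positions
2–6) that initiates target recognition. Off-targets carry either

* **seed sites** — exact Watson–Crick matches to a 6–8 nt window within
  guide positions 1–8, or
* **nucleation-bulge sites** — 7-mers matching positions 2–7 with one
  extra target nucleotide bulged between the nucleotides opposite positions
  5 and 6, where the bulged nucleotide must itself pair the pivot
  (the *pivot-pairing rule*).

Repression is read out distributionally: cumulative log2 fold-change
curves of Seed/Nuc transcripts against NoSite controls, compared with
two-sample Kolmogorov–Smirnov tests (Bonferroni-corrected), plus a paired
binomial sign test for WT-vs-modified derepression. On-target potency is a
control-anchored Hill curve, RA(c) = 100 − P·cʰ/(cʰ + IC50ʰ), fitted by
nonlinear least squares with a significance screen that reports IC50 = ND
when no concentration shows significant repression.

Because every seed window of length ≥ 6 within positions 1–8 covers
position 6, an abasic pivot eliminates *all* seed windows and leaves the
bulge nucleotide undefined — the modified guide generates no miRNA-like
patterns at all, which is the mechanism the analyses quantify.

## Worked example

```python
import numpy as np
import sipivot as sp

g = sp.get_guide("siPCSK9-A1")          # guide UUCCGAAUAAACUCCAGGC
for p in sp.seed_patterns(g, (7,)):
    print(f"seed {p.guide_span}: {p.target_motif}")
nuc = sp.nucleation_bulge_pattern(g)
print(f"nucleation bulge: {nuc.target_motif} (bulge {nuc.bulge_nt})")
print("6pi:", sp.seed_patterns(sp.make_variant(g.base, "6pi")),
      sp.nucleation_bulge_pattern(sp.make_variant(g.base, "6pi")))
```

```
seed (1, 7): UUCGGAA
seed (2, 8): AUUCGGA
nucleation bulge: UUUCGGA (bulge U)
6pi: [] None
```

The bulge motif `UUUCGGA` is the span 2–7 seed match split by a `U` that
pairs the pivot base `A`; the `6pi` variant generates no patterns.
Enrichment on a synthetic transcriptome (200 Seed, 200 Nuc, 2000 NoSite
transcripts; planted shifts −0.4/−0.2 log2, noise σ = 0.5):

```python
cfg = sp.SimulationConfig(rng_seed=7, n_seed=200, n_nuc=200, n_nosite=2000)
truth = sp.simulate_truth_labels(cfg)
assigns = [sp.SiteClassAssignment(r.transcript_id, r.site_class)
           for r in truth.itertuples(index=False)]
print(sp.OffTargetEnrichment(sp.simulate_profiles(truth, cfg), assigns)
      .fit().summary().to_string(index=False))
```

```
site_class  n_class  n_control   ks_D        p_raw   p_adjusted  median_shift  testable
      Seed      200       2000 0.3045 2.059443e-15 4.118887e-15     -0.344556      True
       Nuc      200       2000 0.1965 1.303671e-06 2.607342e-06     -0.197507      True
```

Both site classes are shifted toward repression (negative median shift)
and strongly significant; rerunning with
`sp.simulate_profiles(truth, cfg, "6pi")` gives median shifts of −0.02 and
−0.01 with p ≈ 0.94 and 0.52 — the abasic pivot abolishes both classes.
A dose-response fit on simulated replicates (true plateau 80%, IC50
0.36 nM, 3% noise):

```python
d = sp.simulate_dose_response(80.0, 0.36, 1.0, np.logspace(-3, 2, 7),
                              sigma_pct=3.0, rng=7)
fit = sp.fit_sigmoid(d)
print(f"IC50 = {fit.ic50:.3f} nM, plateau = {fit.plateau_inhibition:.1f}%, "
      f"hill = {fit.hill:.2f}, method = {fit.method}")
```

```
IC50 = 0.314 nM, plateau = 80.4%, hill = 1.02, method = sigmoid_nls
```

## Command line

The `sipivot` console script exposes the pipeline:
`scan`, `classify`, `enrich`, `derepression`, `fit-ic50`,
`design-reporter`, `predict-effect` and `simulate`. For example:

```bash
sipivot design-reporter --guide siPCSK9-A1 --kind nuc_x2
sipivot simulate --guide siPCSK9-A1 --seed 1 --variant 6pi --out-dir bundle/
sipivot enrich --fold-changes bundle/fold_changes_WT.tsv \
               --assignments assignments.tsv --out-tsv enrichment.tsv
```

See `docs/methods.md` for the full model description, parameter defaults
and numerical choices.

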
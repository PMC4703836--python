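# Methods

## Background and model

Small interfering RNAs silence their intended target through full
complementarity to the guide strand, but they also act like microRNAs:
transcripts carrying short matches to the guide's 5' end are repressed as
off-targets. Two site classes drive this miRNA-like activity:

* **Seed sites** — target subsequences exactly Watson–Crick complementary to
  a 6–8 nt window within guide positions 1–8 (6-mers over windows 1–6, 2–7,
  3–8; 7-mers over 1–7 and 2–8; the 8-mer over 1–8).
* **Nucleation-bulge sites** — 7-mer targets complementary to guide
  positions 2–7 with one extra target nucleotide bulged between the
  nucleotides pairing positions 5 and 6. The pivot-pairing rule constrains
  the bulged nucleotide: it must itself be able to Watson–Crick pair the
  pivot (guide position 6). Pattern generation therefore produces a single
  7-mer per guide, with the bulge nucleotide determined by the pivot base.

Functional recognition begins with *transitional nucleation* — consecutive
pairing from position 2 through the pivot. Removing the base at the pivot
(an abasic dSpacer, rSpacer or C3 spacer substitution, variant codes `6pi`,
`6pi-r`, `6c3`) destroys every seed window (all windows of length >= 6
within positions 1–8 cover position 6) and leaves the bulge nucleotide
undefined, so the guide generates *no* miRNA-like site patterns at all,
while the perfectly matched on-target site tolerates the single abasic gap.
That asymmetry is the scientific core the package operationalizes.

All matching is exact Watson–Crick; G:U wobble is never allowed (the bulge
rule specifies WC pairing, and seed matching follows the exact 6/7/8-mer
usage). Position-1 windows use the true complement of guide position 1; no
"t1A" convention is applied. Guide positions are 1-based from the 5' end of
the RNA core; a 3' deoxynucleotide overhang (`dTdT`) is excluded from
numbering. Transcript coordinates are 0-based half-open on the sense strand.

### Insertion semantics

An insertion variant (`Npi-b`, `Npi-rb`) places the abasic unit immediately
5' of core position N, so the unit sits between former positions N-1 and N
and downstream bases shift by +1. This matches the intended guide-side
bulge within the nucleation region; the notation itself does not fix the
convention, so it is documented here as the package's choice.

### Site-class assignment

Per transcript, classes follow the hierarchy **Seed > Nuc > NoSite**: any
qualifying seed hit labels the transcript Seed; nucleation-bulge hits label
it Nuc only in the absence of seed hits; class depends on hit existence,
not count. The default `matched_7mer` scheme counts only span 2–8 seed hits
(the classic 7mer-m8 site), so seed and bulge sites are compared at matched
motif length anchored on the same guide region. Counting span 1–7 as well
(`matched_7mer_both`) is available but not the default, because for guides
whose positions 6 and 7 share a base the bulge motif *inherently* embeds a
span 1–7 seed match — the PCSK9 nucleation reporter insert is exactly such
a case — and the Nuc class would be emptied by construction.

## Enrichment statistics

Off-target repression is read out distributionally: per-transcript log2
fold changes of each site class are compared against NoSite controls with
the two-sample two-sided Kolmogorov–Smirnov test (scipy's `ks_2samp`), over
a coding-transcript filter (RefSeq `NM_` prefix or explicit flag) and an
optional significant-change subset (p < 0.05 or explicit flags). When
several experiments are pooled, each (transcript, experiment) pair is one
observation, each experiment's site classes computed from its own guide,
with equal weighting. Bonferroni correction (`min(1, p*n)`) is applied over
the number of class comparisons; no FDR machinery is provided. A class with
fewer than two observations is flagged not testable rather than tested.

The WT-vs-modified comparison uses a paired binomial sign test: among
transcripts significantly changed and repressed (log2fc < 0) under the
unmodified guide, count how many remain below zero under the modified
condition, and test that proportion against 0.5 two-sided. If the
modification truly abolishes the sites, the modified fold changes are
driven by noise alone and ~50% fall below zero.

## Dose-response model

Relative activity is the Renilla/firefly ratio as a percentage of a
non-targeting control (control mean = 100%). Repression follows a
control-anchored three-parameter logistic

    RA(c) = 100 - P * c^h / (c^h + IC50^h)

with plateau inhibition P in [0, 100] % (so the bottom asymptote is
100 - P), Hill slope h bounded to [0.3, 4], and IC50 in input units (nM).
Fitting is ordinary least squares via `scipy.optimize.curve_fit` with fixed
initialization (P0 = 100 - min mean activity, IC50_0 = geometric mean of
the concentrations, h0 = 1) and no random restarts, so fits are
deterministic given the data.

**ND rule.** Each concentration is t-tested (two-sided, pooled variance)
against the control replicates; per-concentration flags are reported at raw
alpha = 0.01, matching per-bar significance conventions. The ND decision
("IC50 not determined — no significant repression in any tested range") is
a family-level claim, so it gates on Bonferroni-corrected per-concentration
tests (alpha/m for m concentrations): with an uncorrected gate the
probability that a null curve escapes ND is 0.995^m (~96.6% at m = 7),
whereas the corrected gate holds ND specificity at ~99.5% while costing no
power against genuine repression — replicate assays of real curves reject
far below the corrected threshold. Degenerate noiseless arms (zero variance
on both sides) count as significant whenever the means differ.

**Fallback.** If the nonlinear fit fails to converge, or its IC50 lands
outside [min(c)/10, 10 max(c)], an approximate IC50 is read off the
regression line of mean activity on log10(concentration), fitted over
concentrations whose mean activity lies strictly inside the 20–80% band of
the observed inhibition range (the band is this package's definition of
"the regression line" domain); the IC50 is where the line crosses the
midpoint between the maximal and minimal mean activities. Fewer than two
qualifying points, or a flat line, yields ND.

Relative Imax reports a fit's plateau as a percentage of a reference
(typically unmodified) plateau, capped at 100%; an ND fit reports 0%.

## Modification-effect rules

The qualitative table (`data/effect_rules.tsv`) maps a single modification
signature and site class to `functional` / `attenuated` / `abolished`:
dSpacer substitutions at positions 2–7 abolish seed sites; the abasic pivot
(`6pi`, `6c3`) also abolishes nucleation-bulge sites with the perfect-match
site functional; rSpacer substitutions at 3–6 and abasic insertions at 4–6
abolish seed sites but attenuate on-target activity; 2'-OMe at position 2
attenuates both miRNA-like classes; UNA at position 7 and the position-2
duplex bulge attenuate seed sites. Queries outside the observed evidence
(e.g. rSpacer at position 2, which was not observed to derepress; the
nucleation-bulge behaviour of non-pivot dSpacer substitutions) return an
explicit `not_covered`, never a silent default, and no rule ever maps
perfect-match to abolished. Quantitative IC50/Imax shifts are
experiment-specific and live in the dose-response fits, not in this table.

## Synthetic data

`simulate_transcriptome` plants one span 2–8 seed motif per Seed-class
transcript and one nucleation-bulge motif per Nuc-class transcript in
uniform-composition random sequence (lengths uniform on 200–2000 nt),
rejection-sampling Nuc transcripts until no seed window occurs outside the
planted site and NoSite transcripts until no pattern occurs at all; a truth
table records planted coordinates, and ids carry the `NM_` prefix.
`simulate_profiles` draws log2 fold changes as Normal(mu_class, sigma) with
defaults mu_seed = -0.4, mu_nuc = -0.2 (bulge sites repress more weakly
than seed sites), mu_NoSite = 0 and sigma = 0.5 — a few-tenths log2 shift
against order-of-magnitude-larger controls, the regime pooled off-target
meta-analyses operate in. Under a variant condition, classes whose rule
status is `abolished` revert to zero mean; `attenuated` classes keep half
their shift (a testing convention, not an empirical claim). Each condition
draws its own noise stream keyed by (seed, condition): WT and variant
profiles are separate experiments with independent measurement noise.
`simulate_dose_response` draws replicate activities around the same sigmoid
used for fitting (default n = 6 replicates, 3% Gaussian noise).

What the generators do *not* emulate: heavy-tailed microarray/RNA-Seq error
distributions, correlated expression between transcripts, 3'-UTR structure
or length biases, and expression-dependent site efficacy. Passing tests
therefore demonstrate correctness of the statistical machinery on its
stated assumptions, not performance on real transcriptome profiles — the
rank/CDF statistics used are distribution-robust, which is why Gaussian
noise is an acceptable stand-in for testing.

## Numerical and testing choices

* Test problem sizes: KS calibration uses 2000 null replicates at n = 100
  per arm; planted-effect detection uses 100 replicates of 300 Seed vs 3000
  NoSite transcripts; IC50 recovery uses 100 noisy replicates over a 7-point
  log-spaced dose series spanning 1e-3 to 1e2 nM, with noiseless recovery
  checked at 4 points per decade; ND specificity uses 400 null curves.
* The restoration check on variant profiles compares the median of per-run
  class medians over 20 replicate runs of n = 300 per class against a
  ±0.05 log2 band: a single run's class median has sampling s.e.
  ~0.036 at sigma = 0.5, so a one-draw check at ±0.05 would fail a correct
  implementation roughly a third of the time.
* Fold-change profile statistics are simulated from truth tables of class
  labels; full sequence simulation (with rejection sampling) is exercised
  separately, since profile statistics depend only on class membership.
* Reverse complementation treats T and U as interchangeable on input; all
  internal sequence logic is RNA.
* Ties and degenerate inputs: empty pattern lists scan to empty hit lists;
  identical KS samples return D = 0, p = 1; a zero-span activity range
  yields ND from the fallback.

## Limitations

* Seed matching is exact-complement only; wobble pairing, 3'-supplementary
  pairing, context/conservation scores and seed-pairing stability are out
  of scope.
* The effect table is qualitative and covers only single modifications at
  assayed positions; combinations return `not_covered`.
* The dose-response model is a symmetric logistic with the top anchored at
  100%; asymmetric five-parameter curves and inter-plate normalization are
  not modelled.
* Enrichment pooling weights every transcript-experiment observation
  equally; no per-experiment variance weighting is attempted.
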
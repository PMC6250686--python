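# Methods

This note records the models, defaults and design choices behind the
package, and what the synthetic benchmark does and does not demonstrate.

## Leaf morphometrics

A bud's leaf index is the arithmetic mean of its leaves' length/width
ratios, **not** the ratio of mean length to mean width.  The two differ
whenever leaf size varies within a bud, and only the per-leaf-ratio
convention reproduces the bundled reference table (sample Li2: printed
LI 7.45 vs 3.56 cm / 0.50 cm = 7.12).  Shape thresholds are
lower-inclusive (5.0 → Li, 2.0 → La, 1.0 → Ov), read directly off the
published inequalities.  Measurements are in centimetres; no unit
inference is attempted.

One consequence worth knowing: reference sample Ov3 has LI 2.07, which the
thresholds place in La.  Threshold classification of the reference table
therefore agrees with the declared stages for 11 of 12 samples, and the
per-class counts are Li 3 / La 4 / Ov 2 / Bo 3 rather than 3/3/3/3.  The
package reports this honestly rather than special-casing the boundary.

`assign_groups` validates that stage-mean LI strictly decreases in the
order Li > La > Ov > Bo and warns (configurably errors) otherwise; the
attached category codes 0–3 are the stage indices used by trend detection.

## Counts, normalization and differential expression

Counts are modelled as negative binomial with Var = μ + αμ².  Sample size
factors are classical median-of-ratios: the median over genes positive in
every sample of count/geometric-mean.  Factors are identified only up to
the geometric-mean pseudo-reference; tests therefore check factor ratios.

Dispersion is method-of-moments per gene on normalized counts, pooling the
within-group variances of the two contrasted stages:
α̂ = max((s² − μ̄)/μ̄², 10⁻⁸).  The floor absorbs the ~50% of genuinely
Poisson-like genes whose raw estimate is negative.

The DE statistic is a Wald test on the difference of log stage means with
a delta-method standard error, SE² = (1/μ̄_a + α̂)/n_a + (1/μ̄_b + α̂)/n_b,
evaluated on pseudocounted means (c = 1, configurable; the same c enters
log2fc = log₂((μ̄_b+c)/(μ̄_a+c))).  The statistic is referred to a **t
distribution with n_a + n_b − 2 df**, not the normal: with three
replicates per group the moment dispersion is noisy enough that the normal
reference rejects ~11% at nominal 5% (simulated), while the t reference
sits near 4.4%.  Significance is gated on the raw p < 0.05 by default —
matching the convention the study design uses — with BH-adjusted q
available behind `use_bh`.

The six stage contrasts run in the conventional order La/Li (A), Ov/Li
(B), Bo/Li (C), Ov/La (D), Bo/La (E), Bo/Ov (F).  Abundance units follow
their definitions exactly: FPKM = c·10⁹/(ℓ·T), TPM rescales c/ℓ to a
column sum of 10⁶, RPM = c·10⁶/T (for back-splice junction counts, which
have no meaningful length).  All trend and PHMA calls operate on
median-of-ratios-normalized counts for every RNA class; the abundance
units are provided for reporting.

"Expressed in a stage" means ≥ 1 count in ≥ 1 replicate by default; the
thresholds are parameters because no principled universal choice exists.
The lncRNA structural candidate filter retains transcripts ≥ 200 nt with
≥ 2 exons (both boundaries inclusive).

## Trend (CLI/OLI) and PHMA calls

Trends are evaluated on the four stage means of normalized counts, not on
per-sample values: CLI = strictly decreasing at every step (mirroring the
leaf index), OLI = strictly increasing, anything else none.  Strictness is
the deliberate default reading of "completely consistent"; a relative
tolerance knob relaxes near-ties because sampling noise makes strict
monotonicity conservative.  The PHMA flag requires a non-none trend *and*
Li-vs-Bo significance, so the PHMA set is a subset of contrast C's
significant set — asserted on every run.  Only the Li-vs-Bo contrast is
gated; intermediate contrasts are not.

## Target scoring

The duplex expectation is the classical plant rule set: per position from
the miRNA 5′ end, match 0, G:U wobble 0.5, mismatch 1, doubled at core
positions 2–13; no gaps; transcripts scanned on the given (sense) strand
only; default reporting cutoff 5.0.  Gapped alignment and site
accessibility are deliberately omitted — the scheme is a transparent,
exactly testable scorer, and the scan is verified against brute-force
window enumeration.  The production scan concatenates transcripts with
sentinel symbols of prohibitive penalty and computes all window scores
with per-position table lookups, which makes the default-scale
interactome (120 small RNAs × ~2400 transcripts) a matter of seconds.

Silencing interactions additionally require opposite trend labels on the
miRNA and its target; ceRNA (decoy–mRNA) edges require a shared targeting
miRNA and *equal* non-none labels.  Strict ceRNA mode further requires
every shared miRNA to carry the opposite label — the pattern of a sponge
actually in action; its edge set is provably a subset of the default's.
The miRNA's own label is deliberately not constrained by default, since
only decoy/mRNA similarity is part of the base rule.

## Enrichment

Upper-tail hypergeometric p = P(X ≥ k) over user-supplied term→gene maps,
BH-corrected across terms.  Both tested enrichment and raw per-term counts
are available, since the two summaries answer different questions.
Non-coding RNAs inherit the union of the terms of the mRNAs they regulate
(one silencing step for miRNAs, one ceRNA edge for decoys).  No live
GO/KEGG retrieval and no cross-species homolog mapping are performed;
annotation files are inputs.

## Synthetic data: what it emulates and what it does not

Defaults define the benchmark conditions: 4 stages × 3 replicates; class
sizes mRNA 2000, miRNA 120, lncRNA 300, circRNA 80; base mean 100;
dispersion α = 0.05; planted fractions 10% CLI + 10% OLI; per-stage
log2 fold change δ = 1 (CLI expected means μ·2^(−δk), k = 0..3; OLI the
mirror image rising to μ); library sizes log-uniform in [5·10⁵, 2·10⁶],
recorded in truth so size-factor recovery is testable.  Per-leaf LI is
lognormal per stage with log-means at LI 7.0 / 3.2 / 1.5 / 0.74 and
log-sd ≈ 0.10–0.15, centred inside the class intervals as in the
reference table; buds carry 7–13 leaves.  The interactome plants 15
sponge triads (decoy and mRNA sharing one miRNA, labels chosen to satisfy
the calling rules, perfect reverse-complement sites at random offsets)
plus up to 20 extra silencing pairs; annotations plant one term covering
80% of the trend mRNAs among 50 random terms.

Every generator draws from its own child stream of the seed, so outputs
are reproducible and mutually independent.  Planted sites score exactly
0; at the default scale roughly one random window per dataset also dips
under the reporting cutoff, which is realistic predictor behaviour and is
left in.

What passing does **not** show: real tissue has per-gene baseline and
dispersion heterogeneity, correlated replicates, imperfect target sites,
and isoform/assembly ambiguity, none of which are simulated.  Recovery
rates on this benchmark (≥ 98% sensitivity, ~1% false PHMA at defaults)
are upper bounds on real-data performance, not estimates of it.

## Problem sizes and numerical choices

The test suite and the acceptance script run the generator at its default
scale (2000 mRNAs; 500 samples for the morphometry Monte-Carlo; 2000 null
genes for calibration), chosen as the smallest sizes at which the binomial
noise on the measured rates is well inside the asserted bands.  Ties in
window scoring break to the leftmost site; trend ties break to "none";
dispersion estimates are floored at 10⁻⁸; TPM column sums are exact to
floating-point rounding.  Degenerate inputs (empty leaf lists, all-zero
genes, missing labels) raise informative errors or drop records with a
logged warning, as documented per function.

## Known limitations

* The DE test is a closed-form Wald/t approximation, not an exact NB test
  or a shrinkage estimator; it is calibrated by simulation at n = 3, but
  very low counts (μ < ~5) push it conservative.
* The target scorer is ungapped; bulged duplexes are invisible to it.
* circRNAs are treated as linear decoy sequences; back-splice geometry is
  out of scope.
* Trend labels are hard calls on stage means; an RNA whose trend is real
  but noisy at one step is labelled none rather than probabilistically.
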
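# Methods

## Scope and model

`misplice` analyzes splicing dysregulation in two-group (case vs control)
junction-count studies of the kind produced by repeat-expansion disease
(DM1) and splicing-factor (MBNL, SRRM) loss-of-function transcriptomes. The
unit of analysis is the alternative-splicing event — skipped exon (SE),
mutually exclusive exons (MXE), alternative 5'/3' splice site (A5SS/A3SS),
retained intron (RI) — quantified by percent spliced in:

    psi = (I / lI) / (I / lI + S / lS)

with inclusion and skipping junction-read counts I, S and effective lengths
(lI, lS) equal to the number of distinct informative junctions per event
type (SE 2/1, MXE 2/2, A5SS and A3SS 1/1, RI 2/1). Only junction reads are
modeled; exon-body reads are out of scope. Coordinates are 0-based
half-open throughout, so exon length is `end - start`; motif scanning is
always on the sense strand of the pre-mRNA (minus-strand genomic regions
are reverse-complemented on extraction).

## Differential splicing and the mis-splicing call

The default test (`betabinom_lrt`) models per-sample inclusion counts as
beta-binomial on the inclusion-read probability scale, parameterized by a
mean and an intra-class correlation rho (a = p(1-rho)/rho,
b = (1-p)(1-rho)/rho). The alternative gives each group its own mean with
one shared event-level dispersion, estimated by profile maximum likelihood
(rho bounded in [1e-6, 0.5]); the null refits a shared mean at that
dispersion. The likelihood-ratio statistic (clamped at 0 against numeric
noise) is referred to F(1, N-2), N the number of usable samples: with
replicate-scale N the chi-square(1) reference is measurably
anti-conservative (null rejection at 0.05 runs near 8% at 8 vs 8), while
the F reference restores near-nominal type-I error without losing power.
A Welch t-test on per-sample PSI is available as `diff_method="welch"`.

delta-PSI is always mean(case PSI) - mean(control PSI), so exon exclusion
in cases appears as delta-PSI < 0. An event is called mis-spliced when
|delta-PSI| > 0.1 *and* Benjamini-Hochberg q < 0.05, with q computed
jointly over all tested events. Samples need >= 10 total junction reads
for a defined PSI, and an event needs >= 2 usable samples per group to be
tested; these coverage floors are our choices, made to keep PSI estimates
non-degenerate.

## Enrichment

All enrichments are two-sided Fisher exact tests (minimum-likelihood rule,
via scipy) on 2x2 tables, reported with the sample odds ratio (a*d)/(b*c)
and a Woolf log-OR normal-approximation 95% CI; when any cell is zero a
Haldane-Anscombe 0.5 correction is applied to the CI only, never to the
point estimate. BH adjustment runs across the supplied list of gene sets.
Four table constructions are provided:

- event-level: all tested events, set membership x mis-splicing call;
- gene-level: all detected genes, membership x (>= 1 mis-spliced event);
- microexon: all detected SE events, miE (SE with 3-33 nt exon, bounds
  inclusive) x (mis-spliced and in-set), plus descriptive miE percentages;
  the background of all detected SE events is a deliberate choice and can
  be narrowed by pre-filtering the differential table;
- motif proximity: mis-spliced SE events, membership x has a motif within
  the 250 nt window (a gene-level variant is selectable).

Cross-dataset overlap consumes an externally produced id mapping (e.g.
LiftOver-matched event pairs — coordinate conversion is never computed
here) and crosses called-in-A with called-in-B over the jointly tested
universe.

## Motif scanning

Patterns are ordered IUPAC parts with bounded N-gaps
(`YGCY`, `YGCY(N)0-5YGCY`, `GCAYG`, `TGCT(N)3TGCT(N)13-18TGC[TC]`),
matched on U->T-normalized DNA with Y = {C, T}. Hits are counted by
distinct start position; when several gap choices share a start the
smallest total span is reported — a deterministic rule that an exhaustive
enumeration oracle can and does check. The scan region is the exon plus
250 nt of each flanking intron (the exon body is included in the window by
default; distance is 0 for any hit overlapping the exon, else the gap to
the nearest exon boundary). Note that the compact high-affinity form
YGCYGCY is *not* a sublanguage of YGCY(N)0-5YGCY: its two YGCY cores
overlap by one base, which no non-negative gap can express, so the two
patterns are scanned separately.

## Dose-response and synergy

The per-sample dysregulation score is the mean over a fixed mis-spliced
event set of |PSI_sample - mean control PSI| (events undefined in a sample
are dropped from that sample's mean). This control-mean construction is a
declared assumption — with a group design it is the only per-sample
delta-PSI available. The score is correlated with per-individual CTG
repeat length by Pearson r with a two-tailed p from
t = r sqrt((n-2)/(1-r^2)) and an OLS line.

Dual-perturbation synergy uses the Bliss combination index
CI = (EA + EB - EA*EB)/EAB, computed per replicate and summarized as
mean +/- sd per event. For concordant events the E terms are delta-PSI vs
control; for events with opposite single-perturbation directions the raw
PSI values are used, exactly as the quantity is defined for that case —
the resulting unit asymmetry is reproduced deliberately, not repaired.
Classification uses a +/-0.05 independence band around CI = 1 (strict
<1 / >1 is recovered with tolerance 0); the band exists because the strict
inequality is fragile under replicate noise. Replicates with EAB = 0 are
dropped with a warning.

## Assay statistics

- One-site binding: Y = Bmax*X/(Kd + X) by bounded nonlinear least squares
  after min-max normalization of the signal to [0, 1]; per-replicate fits
  are summarized as mean +/- sd. Normalization is the assay's convention;
  it leaves Kd essentially unchanged only when the concentration series
  spans baseline to saturation, which the validation tests exercise.
- Native RIP: relative IP/INPUT = 2^x with
  x = (Ct_IP,bait - Ct_INPUT,bait) - (Ct_IP,ctrl - Ct_INPUT,ctrl),
  normalized to the mean of two negative-control targets. The exponent is
  applied literally as printed in the defining protocol; because the
  conventional enrichment orientation is 2^-x, a `sign_flip` switch is
  provided rather than silently changing the formula.
- qPCR fold change by 2^-ddCt.
- Dyad behavior: exact binomial test of the KO dyad count against the null
  rate p0 = k_WT/n_WT (upper tail by default; two-sided uses the
  minimum-likelihood rule). Degenerate p0 in {0, 1} raises unless the
  requested tail is trivially consistent. With the published group sizes
  the printed percentages (7% of 15 vs 36% of 14) reconstruct uniquely to
  1/15 vs 5/14 and reproduce p = 0.0016.
- Inter-observer agreement: greedy one-to-one matching in time order of
  labeled point events (within 1 s) and bouts (start and stop within 2 s);
  agreement % = matched/(matched + unmatched in either stream), passed at
  >= 85%.

## The synthetic study

`misplice.simulate` generates the full input bundle. Defaults are the
reference study conditions used by the validation suite and the analysis
drivers: 500 genes x 4 events (2,000 events, 60% SE and 10% each of the
other classes; 25% of SE drawn as 3-33 nt microexons, other exons
60-300 nt), 8 cases vs 8 controls, mean junction depth 100 (Poisson per
event x sample), 20% of events truly shifted by |delta-PSI| = 0.3 with
random sign (flipped when the shifted mean would leave [0.02, 0.98]),
baseline PSI uniform on [0.15, 0.85], and replicate noise from a Beta draw
with intra-class correlation rho = 0.05 on the PSI scale, pushed through
the effective-length mapping so that `compute_psi` is an unbiased
estimator of the sample-level PSI. Case samples carry a CTG repeat length
(uniform 80-1000) whose min-max-normalized value scales the planted effect
by (1 + dose_slope * z). Gene-set membership is Bernoulli per gene
(15% per set); `affected_in_set_odds` concentrates affected events in the
first set on the odds scale. A concrete YGCY(N)0-5YGCY instance is planted
within 250 nt of a random exon boundary at rate 0.9 for affected in-set
events and 0.5 elsewhere — the asymmetry that makes motif-proximity
enrichment detectable. `clean_background` scrubs accidental YGCY matches
by mutating their G to A (rejection sampling cannot work: a ~500 nt window
at GC 0.5 contains YGCY with probability ~1; the scrub cannot create new
matches because the pattern contains no A).

What the generator does *not* emulate: read-level sequencing artifacts,
mappability, paired designs, expression-level variation, correlated events
within a gene, realistic genome composition, or rMATS's exact hierarchical
model. Tests passing on this generator therefore validate the statistical
machinery under its stated noise model, not performance on any real
accession.

## Problem sizes in the validation suite

The recovery and null-calibration checks run at the reference scale above
(2,000 events; 8v8 and 3v3); oracle-equivalence sweeps cover 200 random
sequences per pattern, every 2x2 table with total <= 50, and 1,000 random
p-vectors; planted-OR coverage and null-OR calibration use 100 replicates
of direct Bernoulli draws at the call level (4,000 events / 600 genes),
which isolates the enrichment machinery from the caller.

## Known limitations

- The beta-binomial LRT is not an rMATS re-implementation; event counts
  from the two will differ and no numeric agreement is claimed.
- The Woolf CI is approximate for extreme tables even with the Haldane
  correction; an exact CI method is not provided.
- Gene- and event-level enrichment inherit gene-length and expression
  biases present in the input; no bias correction is applied.
- The greedy agreement matcher is order-dependent by design (it mirrors
  manual scoring practice) and is not a globally optimal assignment.
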
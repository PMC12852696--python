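# Methods

`neurotransit` re-implements, as tested library code, the computational
procedures used to characterize the switch of embryonic spinal-cord
progenitors from proliferative (PP) to neurogenic (PN, NN) modes of
division: single-cell signature scoring and pseudotime gene clustering,
direct G1-phase measurement in FlashTag-synchronized cohorts with
cumulative EdU labeling, sister-pair classification of division modes, and
the confocal-stack quantification macros.  Every analysis is exercised
against an agent-based / negative-binomial synthetic-data generator that
emits ground truth next to each observable, so recovery can be measured
exactly.

## Single-cell transcriptomics

**QC and filtering.**  Cells are removed when their UMI total falls below
the 0.5th or above the 99.9th percentile of the dataset, when more than
20% of UMIs map to mitochondrial genes, or more than 0.3% to hemoglobin
genes; genes must be detected (>= 1 UMI) in at least 3 cells.  The fixed
order is cell QC, then gene filtering, then marker-based exclusion of
non-neural cells (mesoderm: Foxc1/2, Twist1/2, Meox1/2; neural crest:
Sox10; a single marker UMI excludes by default).  Mitochondrial and
hemoglobin genes are recognized by configurable name prefixes (`MT-`,
`HBA/HBB/...`), since chick annotations do not share a fixed list.

**Normalization and confounders.**  Library-size log-normalization,
`x -> ln(1 + 10^4 x / total)`.  Cell-cycle and sex effects are removed by
gene-wise OLS residualization, computed separately within "cycling"
(S or G2/M module score > 0) and "non-cycling" groups so the
proliferation/differentiation contrast itself survives; collinear
covariate columns are dropped with a warning.  The threshold-at-zero rule
for the cycling split is our choice; the grouping itself follows the
analysis design.

**Signature scores and states.**  A module score is the mean normalized
expression of a signature minus that of expression-matched controls: genes
are ranked by mean expression and split into 25 bins; each signature gene
draws 100 control genes from its own bin (with replacement when the bin is
smaller), seeded and bit-reproducible.  Default signatures: progenitor
P = {Sox2, Notch1, Rrm2, Hmgb2, Cenpa, Ube2c, Hes5}; neuron N = {Tubb3,
Stmn2, Stmn3, Nova1, Rtn1, Mapt}; neurogenic-progenitor PN = {Tis21/Btg2,
Dll1, Hes6, NeuroG1, NeuroG2, Gadd45g}; all user-overridable (chick symbol
aliases differ between annotations).  State labels are the argmax of the
z-scored (P, PN, N) scores with the deterministic tie-break P > PN > N.
Argmax labeling is our explicit delineation rule; the source analysis does
not state one.

**Differential expression.**  Per gene, a negative-binomial GLM with log
link and log-library-size offset; dispersion by method of moments on
rate-adjusted counts with a floor of 1e-8; likelihood-ratio test of the
group term against chi-square(1); Benjamini-Hochberg adjustment across
tested genes.  Genes all-zero in both groups are excluded and reported.
When planting fold changes in benchmarks, the planted genes are kept a
small fraction of the library: a large planted share perturbs the size
factors themselves and biases log fold changes toward zero (a property of
any library-size offset, not of the test).

**Pseudotime and gene clustering.**  Pseudotime is the rank of
(N score - P score) rescaled to [0, 1] — transparent, deterministic, and
monotone-invariant; it replaces graph-based trajectory inference by
design.  Genes entering the clustering are selected by an NB-GLM variation
test (binned pseudotime means vs a constant model, BH < 0.05).  Each
gene's expression is averaged in 20 equal-occupancy pseudotime bins and
z-scored; profiles are clustered by Ward/Euclidean hierarchical clustering
cut at k_genes (default 6), and cells by PAM (k-medoids, BUILD + SWAP,
implemented in-package because no installed dependency provides PAM) on
their per-gene-cluster mean profiles at k_cells (default 4).

## Cell-cycle kinetics

The embryo is the statistical unit: labeling fractions are computed per
embryo and conditions are compared across embryos (exact Mann-Whitney for
<= 10 per group, enumerated over all relabelings and therefore tie-safe;
normal approximation with tie correction beyond; unpaired t tests for the
pulse design).

**Cumulative EdU.**  Fraction EdU+ among pRb+ GFP+ cells per timepoint.
The classical saturating model `f(t) = GF * min(1, (Ts + t)/Tc)` can be
fitted (deterministic 5x5 multi-start bounded least squares; Ts < Tc via
an S-fraction parameterization) to turn "reaches the plateau faster" into
numbers; the nonparametric plateau time remains the primary readout.  In a
*growing* population the realized curve differs from the static model
(e.g. the 1-h pulse index is (Ts+1)/(Tc+1) rather than (Ts+1)/Tc, because
EdU-negative mothers divide into two EdU-negative daughters), so model-fit
benchmarks use model-generated curves and simulator benchmarks assert the
growing-population forms.

**Direct G1 measurement.**  In a FlashTag cohort with continuous EdU
(re-injection at 6 h is modeled as continuous availability), the fraction
EdU+ among FT+ pRb+ GFP+ cells at time t estimates P(G1 <= t).  Raw
fractions are projected onto a non-decreasing curve (isotonic regression)
before the median is linearly interpolated at 0.5 and the plateau located
as the first timepoint >= 1 - eps (eps = 0.02; "virtually all in S" has no
stated numeric criterion).  Timepoints follow the design: every 2 h from
2 h 30 to 10 h 30.  Timepoints with < 2 embryos enter curves but not
tests.

## Sister pairs

FT+ GFP+ cells are matched into sister pairs by a deterministic greedy
mutual-best procedure formalizing the visual criteria: candidate edges
need min/max intensity ratios >= 0.5 in both GFP and FT channels and
separation <= 30 um; edges are accepted by decreasing composite score
(product of ratios / (1 + distance/30)), ties broken lexicographically by
cell id.  Pairs are classified PP/PN/NN from pRb status ((+,+)/(mixed)/
(-,-)); with HuC/D the mapping inverts.  Pairs with a missing status are
"undetermined" and excluded from distributions and chi-square tests.
Classification refuses to run unless the pRb plateau has been validated
(`prb_plateau_check`: distribution of 0/1/2-pRb+ pairs per timepoint,
stable from the earliest timepoint whose successive total-variation
distances all stay < 0.05; < 20 pairs flags a timepoint unreliable).
Mode distributions are compared by Pearson chi-square without continuity
correction (df = 2; a category empty in both conditions collapses to 2x2,
again without Yates, for consistency).

## Image quantification

3-channel (GFP/Myc/pRb) z-stacks, by design 31 z-levels at 1 um.  The
macro order is fixed and enforced: (1) subtract an "average background"
stack (mean projection of an off-slide acquisition restacked over z);
(2) per channel and z-level, subtract the mean of a user-drawn signal-free
ROI (tracking the z-progressive background decay), then the residual
channel constants (GFP 5, Myc 5, pRb 60), clamping at zero after every
subtraction (8/16-bit images clamp implicitly; the macros do not state
negative handling); (3) rotate (bilinear) so the apical surface line is
horizontal and crop at it, making a pixel's y coordinate its distance to
the apical surface; (4) measure each seed point as the mean intensity of
pixels whose centers fall in a fixed circle (default diameter 8 um — the
nuclear scale; no value is stated) at a single z-level.  pRb positivity is
strictly `mean > 30`; 30 itself is negative.  Cell seeds are batch CSV
inputs replacing interactive clicking.  The ROI-mean -> constant -> clamp
order within step 2 is documented here as the package's choice.

## Synthetic-data generators

**Counts.**  Each neural cell has a maturation coordinate t ~ U(0, 1).
Gene programs are temporal templates — early-high (logistic decline at
0.35), mid-peak (Gaussian 0.5/0.12), late-high (logistic rise at 0.65),
cell-cycle-linked, flat, and overdispersed noise — with per-gene lognormal
amplitudes and a per-gene center jitter (sd 0.05) so programs have
realistic internal heterogeneity.  Signature genes ride their matching
programs at elevated amplitude; a Cdkn1c-like gene is a later, broader
bump (0.55/0.135) that fades in mature cells.  Counts are gamma-Poisson
(NB) with dispersion 0.3 (noise genes higher), lognormal library sizes
(mean 8000, sigma 0.35), fixed mitochondrial/hemoglobin UMI shares
(5%/0.1%, with optional planted high-mito cells) and an optional
mesoderm/neural-crest contaminant admixture (default in study-like runs:
20%, matching the observed 2479 -> 1878 exclusion ratio).
`temporal_programs(k)` provides k evenly spaced bump templates for
clustering-recovery benchmarks (defined jitter-free so the planted truth
is unambiguous).

**Lineage.**  Agent-based continuous time.  Founders start at a uniform
position within their own cycle (steady-state asynchrony); G1 is lognormal
(optionally a fast/slow mixture), S (6 h) and G2/M (2 h) fixed; division
modes drawn from (p_PP, p_PN, p_NN); progenitor daughters re-enter G1,
neuron daughters are postmitotic; no apoptosis and no cycle re-entry.
FlashTag labels the daughters of divisions inside [0, w] (w = 0.25 h,
within the 15-30 min window) and is inherited; EdU marks any cell whose S
phase overlaps an exposure interval and is inherited as a DNA label; pRb
is detectable on progenitors from a fixed early-G1 lag (2 h) after birth
through M and never on neurons; HuC/D appears 9 h after a neuron's birth.
Sisters share FT intensity and have correlated GFP; divisions occur at the
apical surface with sisters placed ~3 um apart; neurons translocate
basally at 2.5 um/h after a 2 h lag.  The pRb early-G1 lag is modeled as a
fixed post-mitotic delay rather than a fixed offset before G1 end: only
the former makes the measured FT/EdU fraction estimate the unconditional
G1 distribution (an offset-before-S model conditions the denominator on
short G1 and biases the median estimate by hours).

Calibrated study conditions (`control_g1_params` / `knockdown_g1_params`):
control progenitors are a 70/30 mixture of fast (lognormal median
~6.97 h, sigma 0.25) and slow neurogenic (median 16 h, sigma 0.3) G1,
giving an overall median of 8.0 h and ~31% of the cohort still in G1 at
10 h 30 — the reported control behavior; knockdown is a single sharp
lognormal (median 5.5 h, sigma 0.25), reproducing the faster, sharper
plateau.  A single lognormal cannot satisfy both the 8 h median and the
one-third-at-10h30 constraint; the mixture is also the biological picture
(neurogenic progenitors have a longer G1).  These are calibration choices:
true chick phase durations at this stage are not established values.

**Stacks.**  Nuclei are 2-D Gaussian blobs (sigma 1.6 um) at one z-level
each with a same-z exclusion distance; apical cells (within 50 um of the
surface) are pRb-bright/Myc-dim, basal cells pRb-dark/Myc-bright; the
background has a per-channel linear z decay everywhere plus the flat
residual constants inside the tissue only (so an off-tissue ROI measures
the gradient and the macro constants handle the tissue residual, mirroring
how the original constants were determined); Poisson-Gaussian sensor
noise; configurable apical-surface tilt.

## What the benchmarks do and do not show

Problem sizes were chosen as realistic study scales: ~400-500 FT cells per
timepoint and 4 embryos per condition for G1 designs, ~300 pairs for mode
distributions, 800 cells per timepoint for noisy cumulative curves, 1000
null genes for DE calibration, 1500-2000 cells for scoring/clustering.
On these, the pipelines recover: medians of G1 within 0.5 h (bias
~0.2 h — dominated by the birth-time offset inside the FT window, which
the experimental design shares, plus linear-interpolation curvature);
noiseless cycle parameters to machine precision and noisy ones to ~5-8%
mean relative error; planted division-mode proportions within Goodman
simultaneous 95% CIs; pairing precision/recall >= 0.98 at realistic clone
density; planted 4-fold expression changes within 0.3 in log2 with
calibrated type-I error; planted nucleus intensities at r > 0.99.

The generators emulate the statistical structure of the designs, not the
tissue: no dorso-ventral patterning, no interkinetic nuclear migration, no
EdU availability decay, no segmentation errors, perfect marker readouts by
default.  Passing these benchmarks shows the estimators are correct and
calibrated under the stated noise models; it does not validate antibody
specificity, dye kinetics, or annotation quality on real data.

Known limitations: the score-rank pseudotime assumes a single
progenitor-to-neuron axis; PAM uses a full distance matrix (quadratic in
cells); the cycle-model fit assumes the static asynchronous-population
model and is knowingly misspecified for strongly growing populations; the
exact Mann-Whitney enumerates up to n = 10 per group.
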
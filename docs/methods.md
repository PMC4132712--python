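# Methods

## The measurement model

Matrix-RNAi is an all-against-all perturbation design: each TF of an
*n*-gene panel is depleted by siRNA, and the expression of all *n* panel
genes is read out by qRT-PCR against a reference gene (GAPDH) in *r*
biological replicates, alongside a scramble-siRNA negative control. The
package's quantification follows the standard 2^−ΔΔCT scheme:

* ΔCT = CT_target − CT_reference normalizes input amount within a sample;
* ΔΔCT = ΔCT_knockdown − ΔCT_control calibrates against the control;
* the linear fold-change of the measured gene is 2^−ΔΔCT, and the effect
  size carried on edges is log2 ratio = −ΔΔCT.

Because one PCR cycle is one doubling, ΔΔCT is already a log2 quantity in
cycles; no amplification-efficiency correction (Pfaffl-style) is applied —
primers are assumed near-100% efficient, a deliberate scope boundary.

### Replicate statistics and pairing

The replicate test is configurable because the experimental design admits
two readings:

* **paired** (default): replicates are matched by replicate index
  (transfections performed in matched biological batches); ΔΔCT_i =
  ΔCT_kd,i − ΔCT_nc,i, and the p-value is a one-sample t-test of the ΔΔCT_i
  against 0 with n−1 degrees of freedom.
* **unpaired**: ΔΔCT = mean(ΔCT_kd) − mean(ΔCT_nc), SD by the pooled
  two-sample formula, p from Student's two-sample t-test.

The two modes give identical mean ΔΔCT (means commute); only SD and p
differ. Degenerate inputs are resolved by convention: zero replicate
variance with zero mean difference gives p = 1, zero variance with a
non-zero difference gives p = 0. Cells with fewer than two usable
replicates are flagged missing and never contribute edges; missingness
propagates, never coerces to "no effect".

## Edge calling

A present off-diagonal cell (s, t) becomes a signed edge s→t when

1. p < alpha (strict; default alpha = 0.05, raw p-values — with 306 tests
   per 18-TF matrix a Benjamini–Hochberg flag exists but defaults off to
   match common practice in this assay class), and
2. the effect gate passes, in one of two modes:
   * `log2_threshold` (default): |log2 ratio| ≥ 1.5, i.e. ≥ ~2.83-fold.
     The cutoff is inclusive while the alpha gate is strict, matching the
     usual "p < 0.05" wording; a `--fold` flag converts fold-changes for
     users who mean 1.5-fold rather than 1.5 log2 units.
   * `sd_multiple`: |mean ΔΔCT| > k·SD(ΔΔCT), default k = 3.

Both modes ship because the field states both criteria; `log2_threshold`
is the default as the criterion usually attached to published network
figures. Sign: the target dropping when its putative regulator is depleted
(log2 ratio < 0) is *activating*; rising is *inhibiting*. The diagonal is
excluded by default — a self-knockdown cell measures siRNA efficacy, which
this design cannot distinguish from autoregulation; it instead feeds the
QC table (pass when residual self-expression < 0.5, strict).

## Network statistics

Degrees are tallied over called edges; the *influential set* is all nodes
with out-degree ≥ 5 (ordered by descending out-degree, then name). Edge
coverage of a node set S is |{edges with source ∈ S}| / |edges|, which
equals Σ_{v∈S} out-degree(v) / |edges| exactly since every edge has one
source — this identity is asserted on random instances in the tests.
Degree classes use bins ≤4 / 5–6 / ≥7 (configurable). First-neighbor
subnetworks keep the seeds, their one-step neighbors in the chosen
direction, and only seed-incident edges; the operation is idempotent for
fixed seeds. Combination selection offers exact top-k by out-degree and a
greedy set cover over targets; greedy inherits the (1 − 1/e) coverage
guarantee and is checked against exhaustive pair search in the tests.

## The synthetic test bed

`sample_truth` plants each ordered off-diagonal pair independently with
probability `density`; sign inhibiting with probability
`inhibit_fraction`; effect sizes uniform in `effect_range` (cycles =
log2 units); per-TF knockdown efficacies uniform in `efficacy_range`.
`simulate_ct` then draws one baseline ΔCT per gene (uniform, default −2 to
8 cycles, spanning weakly to strongly expressed transcripts), and emits
per-replicate CTs with the reference fixed at CT 20:

    ΔCT(kd = s, gene = t) = baseline_t + shift + N(0, ct_noise_sd)
    shift = +effect (activating s→t) | −effect (inhibiting) | 0 (no edge)
    shift(t = s)  = log2(1 / (1 − efficacy_s))

Defaults encode the study design the package targets: 18 TFs, density
0.235 (≈ 72 of the 306 possible edges), inhibit fraction 19/72, effects
1.8–3.0 cycles, efficacy 0.70–0.95, 4 replicates, CT noise SD 0.25 cycles
(a realistic SYBR-assay replicate spread).

Design choices and what they imply:

* **Noise sits on CT values**, not on derived ratios, so replicate
  statistics behave like real qPCR; the reference gene is simulated
  noiseless so planted log2 effects remain exactly interpretable (real
  GAPDH wells carry noise, which would inflate ΔCT variance ~×2 — the
  contract under test is the inference arithmetic, not the noise budget).
* **Only direct effects are simulated** — no propagation through the
  planted network. The real assay measures combined direct+indirect
  responses and the inference draws no distinction, so cascade biology is
  out of contract.
* **Seeds are mandatory everywhere**; identical seeds give byte-identical
  outputs, and the CLI embeds a parameter hash (paths excluded) in every
  output header.

`simulate_compendium` generates the enrichment test bed: log-normal
baselines (median 50, log-SD 1 — a typical tags-per-million spread),
planted fold multipliers in the target group, multiplicative log-normal
noise of unit mean and given CV, optional zero inflation to exercise the
0.1 flooring. The spec-level signature did not name the group carrying the
planted folds; a `target_group` argument (default: first group) makes it
explicit. Passing tests on these generators demonstrate the inference
contract under idealized, independent Gaussian/log-normal noise; they do
not establish robustness to real-data pathologies (off-target siRNA
effects, plate/batch effects, reference-gene instability, non-normal CT
error).

## Enrichment selection

Scores are ratios of post-floor means (floor applied before any
averaging). The between-group test behind "p < 0.05" is Welch's
unequal-variance t-test on log2 values — expression ratios are log-scale
quantities and Welch tolerates very unequal group sizes (e.g. 41 vs 947
samples); Mann–Whitney is available by flag. In pairwise mode with a
single reference sample no test is computable: p is reported missing and
selection falls back to the ratio criterion with a warning. The group-mean
background is computed per gene over non-target *samples* (the natural
reading where the alternative — averaging over all genes — would make the
score gene-incomparable).

## Problem sizes and verification

The test suite and the acceptance script run repeated full-pipeline
simulations at the default 18-TF design: 20 independent studies for edge
recovery (pooled recall/precision/sign accuracy) and 20 null studies for
type-I control (306 cells each; the call rate without an effect gate must
sit within 3 binomial SDs of alpha). Enrichment recovery uses 250–500-gene
compendia with 25 planted fold-4 genes over 8 target + 20 background
samples. The t-test p-values are verified to 1e−9 against numerical
integration of the hand-written t density, and all summary statistics to
1e−10 against direct formula evaluation. These sizes were chosen as the
smallest at which the binomial tolerances are meaningful.

## Known limitations

* No amplification-efficiency correction, standard curves, or
  technical-replicate layer below the biological replicates.
* The inference cannot separate direct from indirect regulation; edges are
  perturbation responses, not binding events.
* Self-edges (autoregulation) are unidentifiable by design.
* A single pooled control condition is assumed per experiment (no
  per-plate calibration).
* No multiple-testing correction by default, mirroring the assay's
  conventional raw-p reporting; enable the BH flag for conservative calls.
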
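# Methods

## Experimental design being modelled

Four treatment samples: ww (water/water control), bw (BTH then water),
wf (water then flg22), bf (BTH then flg22). Each pairwise comparison of
interest — ww_wf, ww_bw, bw_bf, wf_bf, ww_bf — is hybridized on two-color
arrays with two biological replicates, each measured twice with exchanged
fluorophores (a dye swap), i.e. four arrays per contrast. The canonical
orientation is *treatment over reference*: M > 0 means higher expression in
the later-named sample of the contrast (e.g. the bw side of ww_bw,
reported as "up-regulated by BTH"). The three-contrast variant
(ww_bw, bw_bf, ww_bf) mirrors designs without a flg22-only arm; Class A
cannot be formed there and is skipped.

## Normalization

- MA transformation per array with an intensity floor of 1.0 fluorescence
  unit before taking logs (avoids undefined logs without imputing values);
  consequently A ≥ 0 always.
- Within-array lowess of M on A (statsmodels backbone), default span 0.3
  and 3 robustness iterations, interpolation delta of 0.1% of the A range.
  The fitted trend is subtracted; no between-array scale normalization is
  applied. Lowess is a smoother, not a projector: re-normalizing
  already-normalized noisy data changes it slightly; exact idempotence
  holds only for trend-free (constant) input.
- `span=None` skips lowess entirely. This is the right setting for
  noise-free validation data, where the local fit would otherwise absorb
  part of the real planted structure.
- Dye-swap combination: the swapped array's M is negated into the canonical
  orientation, the pair is averaged per probe, and probes are aggregated to
  transcripts by arithmetic mean. Inference therefore sees one value per
  (transcript, biological replicate): n = 2 at the default replication.
  Averaging the technical pair (rather than treating the four arrays as
  four observations) reflects that the swap partners share a biological
  sample; the dye-specific bias cancels exactly in the average.

## Differential expression

One-sample empirical-Bayes moderated t per transcript and contrast.
Hyperparameters (d₀, s₀²) are estimated by moment matching on z = log s²:
trigamma(d₀/2) = var(z) − trigamma(d/2), then
s₀² = exp( mean(z) − ψ(d/2) + log(d/2) + ψ(d₀/2) − log(d₀/2) ).
When the observed dispersion of z does not exceed the chi-square sampling
dispersion, d₀ = +∞ and the posterior variance is pinned at s₀² with a
normal reference distribution. d₀ = 0 is the valid no-moderation limit and
reproduces the ordinary one-sample t. The implementation is cross-checked
in the test suite against Bioconductor limma's `lmFit`/`eBayes` (agreement
to 1e-6) and against a quadrature t-CDF oracle (1e-8); limma is never used
by the implementation itself.

DET calling uses strict p < α with α = 0.05 and raw p-values by default;
Benjamini–Hochberg adjustment is available behind a flag
(`multiple_testing="bh"`) but off by default, matching the single-test
selection rule the pipeline is built around.

Degenerate inputs: if *every* transcript has zero variance (noise-free
simulations), hyperparameter estimation is impossible by design; the
contrast falls back to exact calling (p at the smallest positive float when
|M̄| > 1e-9, else p = 1, flagged in `zero_variance`). A single zero
variance among many is handled by the moderation itself.

## Memory classification

Class B labels are assigned hierarchically; the order matters and is a
deliberate design choice, because the three published categories are
mutually exclusive and sum to 100%:

1. **transgressive** — direction in bw_bf equals direction in ww_bw.
   For Class B the expected global trend is inversion, so sign agreement
   violates it. The check precedes the significance rule: a transcript
   that keeps moving in its primed direction is not "de-primed" no matter
   what ww_bf says.
2. **de-primed** — p(ww_bf) > α: the combined treatment is
   indistinguishable from the untreated control.
3. **primed** — otherwise (still significant in ww_bf).

For Class A the expected trend is concordance, so its transgressive flag is
sign *disagreement* between ww_bw and ww_wf. The expected-sign rule is
encoded per class rather than hard-coded.

Directions come from the sign of the mean log-ratio of the already-called
DET in each contrast; a DET with mean exactly 0 cannot occur (p < α
requires |t| > 0).

The inversion Fisher test conditions on the margins of the 2×2 table
direction(ww_bw) × direction(bw_bf); the two-sided p sums hypergeometric
probabilities ≤ the observed table's probability ("minlike", with a 1e-7
relative tie tolerance; the probabilities themselves are computed from
log-factorials). The tail-doubling rule is available via
`two_sided_rule="double"`. A zero margin yields p = 1 with a warning.

## Downstream statistics

- Term overrepresentation: upper-tail hypergeometric p summed from the pmf,
  universe = all mapped genes unless overridden, Benjamini–Hochberg q
  across tested terms. This is a reconstruction of a standard
  overrepresentation analysis on a flat term map; no ontology DAG
  propagation.
- Methylation: per-gene boolean gene-body calls; the reported p is the
  lower hypergeometric tail under depletion and the upper tail under
  enrichment.
- qPCR: qGene normalized expression NE = E_r^CTr / E_t^CTt with
  efficiencies in (1, 2] (default 2.0 = perfect doubling), mean ± SE over
  replicate wells, two-sample Student's t between conditions.

## Synthetic data generator

Per transcript: baseline log₂ abundance ~ N(10, 2²) (arbitrary fluorescence
scale), a memory class drawn from configurable proportions, and a random
effect sign. Log₂ effects relative to ww at effect size e (default 1.5):

| class              | bw | wf | bf        | recovered as            |
|--------------------|----|----|-----------|--------------------------|
| null               | 0  | 0  | 0         | —                        |
| bth_only           | ±e | 0  | same      | not in Class B           |
| flg_only           | 0  | ±e | same      | not in Class B           |
| classA_concordant  | ±e | ±e | same      | Class A                  |
| deprimed           | ±e | 0  | 0         | Class B, de-primed       |
| persistent_primed  | ±e | 0  | 0.5×bw    | Class B, primed          |
| transgressive      | ±e | 0  | 2×bw      | Class B, transgressive   |

Channel intensities are 2^(abundance ± bias/2 + noise) clipped at 1.0, with
a quadratic intensity-dependent bias attached to the red dye (default
coefficients (1.0, −0.15, 0.005) in A, giving lowess a realistic trend to
remove; the bias sign follows the dye across swaps). `noise_sd_log2`
(default 0.25) is the standard deviation of one array's log-ratio noise;
each channel receives independent N(0, (0.25/√2)²). Antisense transcripts
(default fraction 0.25, drawn independently of class) are separate rows of
the probe universe sharing a gene id with a random sense partner.

Default class proportions place 16% / 2.5% / 1.4% of transcripts in the
de-primed / persistent / transgressive classes — a conditional Class-B
composition of ≈ 80.4 / 12.6 / 7.0 percent — with the remainder split
among unresponsive and non-memory responder classes.

What the generator does **not** emulate: spot-level artifacts and quality
flags, background structure, probe-sequence effects, correlated
(batch-like) noise between arrays, partially overlapping probe sets, and
any coupling between orientation and memory class. Passing the recovery
tests therefore demonstrates the correctness and calibration of the
statistical chain under the stated noise model, not robustness to
real-array pathologies.

## Validation problem sizes

The simulation studies in the test suite and `scripts/acceptance.py` use
2,000 transcripts × 20 seeds for composition recovery (three-contrast
design, 12 arrays per run), 10,000 transcripts for type-I calibration and
planted-fraction convergence, and 5,000 probes for lowess flatness. At
these sizes the binomial 3σ bands and the ±5-percentage-point recovery
band are meaningful while a full run stays in the tens of seconds.
Expected behaviour at the defaults: recovered composition ≈ 76 / 16 / 8
percent — the systematic ≈4-point transfer from de-primed to primed is the
α-level false-positive rate of the ww_bf test acting on truly baseline
transcripts, the same mechanism that affects any fixed-α de-priming call.

## Known limitations

- The replication default (2 biological × dye swap) gives only d = 1
  residual df per transcript; inference leans heavily on the variance
  prior. This matches the modelled design but makes the moderated t's
  calibration dependent on the homogeneity of the true variances.
- Percentages of de-primed transcripts are α-dependent by construction
  (a transcript is "de-primed" when a test fails to reject); they should
  be read as rates at α = 0.05, not as biological fractions.
- The enrichment universe and the methylation calls are taken as given;
  no attempt is made to model annotation bias.
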
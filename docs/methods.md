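# Methods

## Setting and assumptions

`mr2s` implements two-sample Mendelian randomization on summary
statistics. A set of SNPs serves as instrumental variables for an
exposure X (here: BMI in units of 5 kg/m²) with respect to a binary
outcome Y (type 2 diabetes). The causal interpretation requires the
usual IV assumptions: each instrument is (1) robustly associated with
the exposure and (2) associated with the outcome only through the
exposure — no direct (pleiotropic) path and no shared confounding. The
instrument-selection pipeline enforces proxies for these assumptions
(genome-wide significance for (1); LD pruning, exclusion of known
outcome loci and of nominally outcome-significant SNPs for (2)); the
estimator suite quantifies how conclusions change when (2) is partially
violated.

All estimation happens on the log-odds scale; odds ratios appear only at
the reporting boundary.

## Wald ratios and their standard errors

The per-SNP ratio is `β_XY = β_ZY / β_ZX`. Its SE uses the full
delta-method expansion by default:

```
se² = σ_Y²/β_ZX² + β_ZY²·σ_X²/β_ZX⁴        (se_method="second_order")
```

The widespread first-order simplification `se = σ_Y/|β_ZX|` is available
as `se_method="first_order"`. The second-order form is the default
because it accounts for exposure-side sampling error, which is not
negligible for the weaker instruments in the bundled table (|β_ZX| as
low as 0.015 with σ_X = 0.003); on that table it also reproduces the
published pooled CI and I² = 0% exactly, where the first-order form
leaves a small residual Q excess attributable to the 2–3-decimal
rounding of the transcription. Two algebraic identities hold only under
the first-order form and are tested there: IVW equals weighted
regression through the origin with weights σ_Y⁻², and scaling all σ_Y by
c scales the IVW SE by exactly c.

A zero exposure beta raises a degenerate-instrument error naming the
SNP; a zero outcome beta is a valid ratio of 0.

## Pooling, heterogeneity, model selection

Fixed-effect IVW pools ratios with weights `se⁻²`; the random-effects
variant adds a DerSimonian–Laird τ² to each variance. `model="auto"`
(default) selects random effects only under significant heterogeneity,
defined as Cochran-Q P < 0.01 **and** I² > 50%, with
`I² = max(0, (Q−df)/Q)·100`. IVW P-values use the normal approximation;
all 95% CIs use a 1.96 multiplier (matching the convention of the
published tables this package reproduces, rather than t quantiles).

## MR-Egger

Weighted least squares of β_ZY on β_ZX with weights σ_Y⁻² and a free
intercept, after orienting every instrument so β_ZX ≥ 0 (flipping both
betas; without a common orientation the intercept is meaningless). The
fit is delegated to statsmodels WLS; SEs carry a multiplicative
dispersion floored at 1 — residual overdispersion widens them,
underdispersion is not allowed to shrink them — and P-values use t with
k−2 df. At least 3 instruments are required and a constant β_ZX column
raises a singular-design error.

## Median-family estimators

The weighted median is the value at cumulative standardized weight 0.5,
linearly interpolated over midpoints of each observation's weight span;
with equal weights it reduces to the ordinary interpolated median. The
three variants differ only in weights: uniform (simple), `se⁻²`
(weighted), and penalized, where each inverse-variance weight is
multiplied by `min(1, 20·q_j)` with `q_j` the upper-tail χ²₁ probability
of the SNP's contribution to Q evaluated at the weighted-median
estimate — outlying ratios lose weight smoothly. Standard errors come
from a parametric bootstrap (default 10 000 draws, seed 1): each ratio
is resampled from Normal(β_XY, se), the median recomputed with fixed
weights, and the SD over draws taken. Bootstrap settings affect only
SEs/CIs, never the point estimate, and are deterministic given the seed.

## Penalized and robust IVW

Penalized IVW recomputes the fixed-effect pool with the same
`min(1, 20·q_j)` penalties, with Q contributions anchored at the
(unpenalized) IVW estimate. With homogeneous data all penalties equal 1
and the estimate is unchanged. The two anchors (IVW for penalized IVW,
weighted median for the penalized weighted median) follow the
conventions of the established MR software for these named methods.

Robust IVW is a regression through the origin of `β_XY/se` on `1/se`
fitted by redescending IRLS with Tukey's biweight (tuning 4.685),
started from the ≥ 50%-breakdown weighted-median slope with the residual
scale fixed at the MAD of the starting residuals (an MM-style scheme).
Its variance is the asymptotic M-estimator form
`σ²·Σx²ψ(u)² / (Σx²ψ′(u))²` with an n/(n−1) factor and Huber's
small-sample correction; without these the CI under-covers at small k.
The penalized-robust variant applies the penalty factors to the working
weights first. Non-convergence after 200 iterations raises an error
carrying the iteration trace. Robust-regression results are inherently
implementation-sensitive (starting point, scale estimate, tuning), which
is why the bundled-analysis checks hold these two estimators to a
qualitative band rather than a tight tolerance.

## Sensitivity analysis

Leave-one-out re-pools the IVW estimate k times with one SNP removed,
using the same model type as the full fit for every row (per-row model
re-selection would conflate model choice with influence). Each row
reports the re-estimate, recomputed heterogeneity, and the relative OR
shift `(OR_−j − OR_full)/OR_full`. Funnel data are the raw per-SNP
(ratio, precision) pairs plus the pooled reference — no smoothing.

## The bundled dataset

`mr2s/data/bmi_t2dm_table1.tsv` is a 52-row merged two-sample table:
per-SNP effects on BMI (SD units, GIANT-scale meta-analysis) and on T2DM
(log-odds, case-control meta-analysis), with chromosome, position and
gene annotations. It is transcribed verbatim from its published source,
including cosmetic quirks (two comma-formatted positions, two apparent
chromosome errata, one en-dash for an unreported beta); chromosome and
position are carried as metadata only and never enter estimation, so
the quirks are preserved rather than silently "corrected" — the file is
the provenance surface.

One SNP (rs1167827) has an unreported outcome beta. The default policy
(in `table1_metadata.yaml`) reconstructs its magnitude from the printed
SE and P as `|β| = se·Φ⁻¹(1−p/2) ≈ 0.028` and assigns a negative sign:
the source does not document the sign, and the negative choice is the
reconstruction under which the recomputed pooled OR and CI match the
published 1.470 (1.170–1.847) almost exactly, while the positive choice
shifts the pool visibly (≈ 1.51). The policy is configurable
(`impute`/`exclude`, sign), `--strict` turns imputation into an error,
and the imputation is logged.

Because this table is already LD-pruned, the pipeline default does not
re-clump it: without the original reference panel, pairwise r² is
unavailable and the 10 Mb distance backstop alone would discard
independent same-chromosome loci that genuine r² data had cleared (the
published final set itself contains such pairs). Clumping remains the
default in `select_instruments` and the `clump` CLI command, where the
caller supplies raw instruments and, ideally, an r² table.

## Instrument selection rules

* Exposure filter: strict `P < threshold` (default 5×10⁻⁸).
* Clumping: greedy by ascending exposure P (ties broken by chromosome,
  position, then rsID for determinism); an accepted SNP discards
  remaining SNPs with `r² > 0.001` against it or strictly within
  10 000 kb on the same chromosome. Pairs absent from the LD table count
  as r² = 0.
* Outcome exclusion: named known loci first, then strict
  `P_outcome < 0.05` — a SNP at exactly 0.05 (or the bundled table's
  minimum of 0.055) survives.
* A user-supplied exclusion list covers removals that follow no
  mechanical rule. The selection report accounts for every input SNP
  exactly once as survivor or removal with a reason.

## Synthetic data

The generator draws `|β_ZX| ~ U(0.015, 0.05)` (positive by default;
`mixed_signs` exercises harmonization), SEs at
`se_exposure_scale = 0.004` and `se_outcome_scale = 0.022` with ±20%
jitter, and `β_ZY ~ Normal(θ·β_ZX + α, σ_Y)`. These defaults mirror the
bundled table's magnitudes so simulations exercise the same numerical
regime; the default `n_snps = 52` and `θ = 0.386` (OR ≈ 1.47) match its
scale. Pleiotropy `α` is zero, balanced `Normal(0, sd)`, or directional
`Normal(mean, sd)`; `inside_violation` correlates α with instrument
strength (ρ = 0.7) to break the InSIDE assumption. What the generator
does **not** emulate: LD between instruments (an explicit r² table can
be supplied for clumping tests), allele-frequency structure, sample
overlap between the two studies, and winner's-curse selection of
instruments — so passing recovery tests demonstrate estimator
correctness under the stated model, not robustness to those real-data
phenomena.

`recovery_experiment` scores IVW, weighted median and the Egger slope
over replicate draws (bias, empirical SE, RMSE, coverage, intercept-test
rejection rate), with all replicate seeds derived from one master seed.
Under the default null conditions the Egger intercept test rejects at
≈ 5%, and fixed-effect IVW coverage is ≈ 95–97% (slightly conservative,
as expected when ratio SEs treat the exposure betas as known).

## Numerical and determinism notes

* Every stochastic routine takes an explicit seed; identical
  (input, seed) pairs give byte-identical outputs, including report
  bundles (no timestamps in report files).
* Report TSVs and JSON are written at full precision (10 significant
  digits) so the two representations agree exactly; the 3-decimal
  presentation lives only in the stdout summary.
* Validation errors name the offending SNP; configuration errors name
  the missing column or invalid threshold.
* Degenerate cases: P = 1 imputes β = 0 exactly; a single instrument
  yields an IVW identity with heterogeneity undefined; estimators
  needing ≥ 3 SNPs are skipped with a reason in `estimate_all` rather
  than failing the run.

## Problem sizes

The bundled analysis (52 instruments, all estimators, 10 000 bootstrap
draws, 52 leave-one-out refits) runs in about a second. The packaged
operating-characteristic checks use 200–500 replicates of 52-SNP
datasets, which keeps Monte-Carlo error on coverage near ±1–2 percentage
points while completing in seconds on one core.

## Known limitations

* Strand/palindromic-allele resolution is out of scope; harmonization
  compares single effect-allele codes case-insensitively.
* r² is never computed from genotypes; clumping consumes a user-supplied
  pairwise table and otherwise falls back to the distance rule alone.
* The Egger slope on the bundled table is the quantity most sensitive to
  the table's 2–3-decimal rounding and to the unreported-beta
  reconstruction (variants of that one SNP move the slope OR between
  ≈ 1.25 and 1.29), so it should be read with wider uncertainty than its
  nominal CI suggests.
* No MR-PRESSO, mode-based, multivariable, or SIMEX-corrected
  estimators.
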
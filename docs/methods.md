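# Methods

## The behavioural model

Each mosquito is an independent agent on the four-state graph
N (contacting the net) ⇄ F (flying) ⇄ C (resting on the cone), with an
absorbing knockdown state K reachable from any live state. Continuous
per-second hazards are discretised on the 0.1-s analysis grid as
`p = 1 − exp(−rate·dt)`; the two exits from flight (F→C, F→N) are treated
as competing risks (one leave-draw, destination split proportionally to
the rates), which is equivalent to independent exponential clocks in the
dt→0 limit.

Two exposure couplings give the model its treated-net phenomenology:

* **irritancy** — the activation rates N→F and C→F are multiplied by
  `1 + irritancy_gain · contact_time`, where `contact_time` is the
  cumulative seconds the agent has spent in state N. Activity therefore
  ramps up as the cohort accumulates contact with an irritant surface
  (excito-repellency).
* **toxicity** — the knockdown hazard at each step is
  `toxicity_hazard · contact_time`, checked before any other transition.
  Making the hazard proportional to accumulated dose (not instantaneous
  contact) produces the delayed, accelerating knockdown curves seen in
  real assays without additional latent states.

Agents start in flight (they are introduced into the cone flying) at
uniform positions in the cone interior. Flying agents follow a
correlated random walk (heading noise SD 0.9 rad/step, default speed
120 px/s) reflected off the cone wall by heading resampling; agents
landing on the net sit on the net edge; knocked-down agents drop to the
base and stay static. Time discretisation, cone geometry and all hazards
are validated at construction; `toxicity_hazard = 0` provably yields zero
knockdown.

### Parameter defaults

| parameter | default | meaning |
|---|---|---|
| rate_F_to_C / rate_F_to_N | 0.25 / 0.15 s⁻¹ | mean flight bout ≈ 2.5 s |
| rate_C_to_F / rate_N_to_F | 0.05 / 0.08 s⁻¹ | resting/contact bouts of tens of seconds |
| irritancy_gain | 0 (control) – 0.65 (strong irritant) | per second of contact |
| toxicity_hazard | 0 – 1.5·10⁻³ s⁻¹ per contact-second | knockdown accumulation |

No published behavioural transition rates exist for this assay; these
defaults were chosen once so that (a) a control cohort produces a stable
low activity total (~1300 detected movements per assay, resting
predominating), (b) an irritant net produces a rise toward ~3500–4000
with decline as knockdown accrues, and (c) knockdown accumulates over
minutes, not seconds. They reproduce the qualitative shape of real
control/treated activity profiles and are *not* estimates of any real
strain's parameters.

The two discrimination-study presets (`treated_high_irritancy`,
gain 0.65/toxicity 3·10⁻⁴; `treated_low_irritancy`, gain 0.06/toxicity
1·10⁻⁴) were calibrated once so that the standardized effect of the
detected total-activity contrast at n = 10 per arm is ≈ 2.5, mirroring
the magnitude of a resistant-strain between-net contrast; they are fixed
study conditions, not tunables.

## Rendering

One grayscale frame per truth time point: a static background (cone
silhouette at gray 70 on 30), one disk of radius `blob_radius` at gray
200 per agent, i.i.d. Gaussian pixel noise (SD 4 by default), clipped to
[0, 255]. Two agents within a blob radius merge into one blob — a
deliberate, documented failure mode for the vision stage (occlusion
undercount), not something the renderer avoids.

## Movement detection

Per-pixel adaptive mixture of Gaussians, Stauffer–Grimson style: K = 3
components, match threshold λ = 2.5 SD, background cumulative-weight
threshold T = 0.9, learning rate α = 0.02, variance floor 4, new
components seeded with weight 0.05 and variance 225. The exact update
order (fitness ranking by w/σ, background prefix, first-match rule,
weight/mean/variance updates, lowest-weight replacement with weight
renormalisation) is specified in `conetrace/_mog.py` and is replicated
bit-for-bit by a straight-line per-pixel oracle in the test suite.

Decisions worth noting:

* **movement, not presence** — a mosquito that stops moving is absorbed
  into the background within ~3 analysed frames and no longer counted;
  total activity is a movement count.
* **subsampling precedes segmentation** — the model only ever sees
  frames at the 0.1-s analysis interval, so the semantics are
  independent of source frame rate. A 180-s recording (1801 samples at
  10 fps) yields exactly 1800 analysed frames.
* **burn-in** — the first 1 s adapts the model but reports count 0,
  flagged; the model has no other initialisation.
* **polarity filter** — foreground is restricted to the contrast phase
  of the mosquitoes (brighter than the dominant background mean, under
  the rendering convention). This suppresses "ghost" blobs of revealed
  background at spots a resting mosquito has just vacated.
* **blob filter** — 8-connected components with area in [min_area,
  max_area]; min_area = 6 by default, which rejects the occasional
  noise clusters that pass the per-pixel λ test (at λ = 2.5 about 1.2%
  of pixels exceed the threshold per frame) while keeping every rendered
  mosquito disk (area ≥ 13).

### Scoring against ground truth

Recall and precision match detection centroids to truth positions within
one blob radius. A ground-truth "mover" at a frame is an agent that
displaced more than 0.5 px within the trailing 0.3 s — the detector's
temporal resolution — so the few trailing detections of a
just-landed mosquito count as the tail of a real movement rather than as
false positives, while ghosts and noise blobs still count against
precision. On ten seeded synthetic videos (5 agents, noise SD 4, default
160×192 geometry) pooled recall and precision both exceed 0.9.

## Activity and scan aggregation

Image coordinates: y grows downward; *top of cone* = smaller y; a
centroid exactly on the midline counts as bottom (net-proximal) — the
boundary rule is declared here once. Bins are half-open [t, t+5), 36 per
assay; binned counts conserve the total over non-burn-in frames. Scan
sampling reads the truth states at t = 0, 5, …, 180 inclusive (37
points). Replicate summaries use arithmetic means with t-based 95% CIs
(the distributional choice for interval shading is declared, not
inherited from any external tool).

## Statistics

Welch's t and its Satterthwaite df are computed from group summaries, so
printed summary tables are sufficient input. Cohen's d uses the pooled
(n−1-weighted) SD; its CI uses the t-multiplier form
`d ± t₀.₉₇₅,ₙ₋₂·√((n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂)))`, which reproduces
published interval widths exactly. Levene's test uses classical mean
centering. The factorial ANOVA fits `y ~ A*B` under sum-to-zero
contrasts with Type-III sums of squares (equal to the classical balanced
decomposition on balanced data, and compatible with unweighted marginal
means when unbalanced); partial η² = SS_effect/(SS_effect+SS_residual).
Estimated marginal means are unweighted averages of model cell means,
with SEs from the coefficient covariance; pairwise contrasts use the
studentized range (Tukey–Kramer) with family size equal to the number of
levels compared, including simple-effect families of B within each level
of A.

The Abbott control correction follows the WHO convention: no adjustment
at control mortality ≤ 5%, the formula on (5%, 20%], assay invalid above
20% — the convention is declared since only the adjusted quantity's name
appears in standard reports.

Null calibration: under equal-variance normal data (6 groups × 40), the
mean-centred Levene test is known to be mildly liberal; its empirical
type-I error here is ≈ 0.055, and the calibration check accepts
0.05 ± 0.025. The factorial ANOVA's per-effect type-I error sits at
0.05 under the same band.

## Chemical QC

The HPLC content equation is evaluated exactly as written,
`I = (x/a)(0.001/m)·C·f`. The unit reading that makes it dimensionally
coherent (declared, since the symbol units are not defined anywhere):
x/a is the µg/ml concentration of the final 1-ml resuspension, hence µg
of analyte; ×0.001 converts to mg over the net mass in g, giving
mg/g = g/kg. The internal-standard factor C is accepted as an input.
Totals over up to four extraction rounds carry a QC flag when the first
round recovers < 97%. Areal dose: mg/m² = I × mass(g)/area(cm²) × 10⁴.

Raman preprocessing: Savitzky–Golay (window 5, polynomial order 1 —
exact on straight-line segments), then asymmetric least squares baseline
(λ = 10⁵, p = 0.01, 10 reweighting iterations — common ALS settings, the
toolbox this chain mirrors publishes none), then L2 normalisation. The
crystallinity heuristic scores the 1000 cm⁻¹ marker band (±5 cm⁻¹)
against a linear local baseline fitted through the flanking ±(5, 20)
cm⁻¹ regions, normalised by the robust (MAD) SD of the flank residuals;
crystalline-like iff the score ≥ 5. The 942/479 cm⁻¹ bands are scored
the same way but only reported (they characterise a particulate
signature that occurs *without* the crystalline marker). This is a QC
heuristic for spectra, not a claim about deltamethrin polymorph physics.

## What the synthetic data does and does not emulate

The simulator reproduces the *structure* of cone-assay data — cohort
size, assay length, state dynamics, irritancy ramp, knockdown
accumulation, occlusion, sensor noise — with a ground-truth log that
makes every downstream stage testable. It does not emulate wingbeat or
appearance realism, 3-D flight, host-seeking stimuli (deliberately
absent in the assay it models), inter-agent interaction, or camera
artefacts (rolling shutter, compression, illumination drift). Passing
tests therefore demonstrate that the pipeline measures what it claims on
data whose generating process is known; they do not certify performance
on arbitrary real smartphone recordings.

## Problem sizes and numerical choices

The repeated studies use deliberately scaled problem sizes, chosen as
package defaults: the discrimination study runs 20 repetitions of
10-vs-10 assays on a reduced 64×80 geometry (the decision threshold —
p < 0.01 flagged in ≥ 95% of repetitions — is unchanged by the scale);
the vision benchmark uses 10 videos at the full 160×192 geometry; null
calibrations use 1000 replicates. Seeds are explicit everywhere; a
single integer reproduces any study. Ties, boundaries and degenerate
inputs (zero variance, constant groups, empty masks, incomplete series)
are rejected or defined explicitly rather than left to float accident.

## Known limitations

* Merged blobs under occlusion are counted as one mosquito (undercount
  at high density); identity tracking is out of scope.
* The MOG parameterisation is a declared default, not a reconstruction
  of any specific production tool's settings.
* Behavioural rates are qualitative; the simulator is an oracle
  generator, not a fitted model of mosquito behaviour.
* The crystallinity call depends on local-noise estimation and is
  sensitive to heavy smoothing; its threshold is configurable and should
  be re-examined for other instruments.
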
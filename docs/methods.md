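# Methods

## Scope and data model

The pipeline starts from *scored* recordings: a hypnogram assigns one
arousal state (Wake, NREM, REM) to each fixed scoring epoch (default 10 s),
anchored to zeitgeber time (ZT0 = lights on; LD 12:12 by default, boundaries
configurable). Automatic staging itself is out of scope. All windows are
half-open `[start, end)` in ZT hours, epochs are 0-based, and the light/dark
phase of an epoch or bout is decided by its onset ZT.

## Rescoring rules

Two rules clean up automated REM staging before any analysis:

1. an isolated single REM epoch becomes the previous epoch's state (REM
   requires at least two consecutive epochs to count);
2. REM entered directly from Wake becomes Wake (sleep-onset REM is treated
   as misscored arousal in healthy rodents).

Rule 2 is applied to the entire contiguous REM run whose first epoch
follows Wake — the whole sleep-onset REM period, not only its first epoch —
then rule 1, iterating the pair to a fixpoint (two passes suffice in
practice; the implementation caps at ten). A REM run at the very start of a
recording has no previous state; it is conservatively rescored as Wake with
a logged warning, since a sleep-onset origin cannot be excluded. The output
is idempotent, preserves epoch count, and contains no singleton REM and no
Wake→REM adjacency — properties enforced by the test suite on random
sequences.

## Bouts and architecture metrics

A bout is a maximal run of ≥2 same-state epochs. Singleton epochs count
toward time-in-state (every epoch is counted exactly once) but never toward
bout counts or durations. Each bout belongs to the phase of its onset epoch
and is not split at the light/dark boundary; this convention makes
light-phase plus dark-phase bout counts exactly equal to the 24-h count.
State percentages are ratios of integer epoch counts; the package exposes
`state_fractions_exact` returning `fractions.Fraction` values whose sum is
exactly 1, and summaries carry exact epoch counts and seconds alongside the
derived float minutes. Mean bout duration with zero bouts is reported as
missing (`None`), never 0. Wake-bout duration histograms use half-open bins
`[edge_i, edge_{i+1})` with default edges 60/100/140/180/220/260 s and open
first/last bins; a 60-s bout falls in the 60–100 s bin (the boundary
convention is ours; the bin labels alone do not fix it).

## Spectral analysis

Each epoch is windowed (Hann by default; rectangular available), zero-padded
to `nfft` and Fourier-transformed. Power is scaled so the summed one-sided
spectrum equals the time-domain energy of the windowed epoch (Parseval,
asserted to 1e-6 relative in tests), making band powers additive over
disjoint bands and equivariant under amplitude scaling (×c → power ×c²).
Defaults fs = 500 Hz and nfft = 8192 give bins of 500/8192 =
0.06103515625 Hz, and place 4.88, 6.35 and 7.08 Hz on bin centres (k = 80,
104, 116) — the grid on which fine-grained per-bin group comparisons are
reported. Both parameters are configurable; analyses in this repository that
only need relative band structure use reduced fs/nfft for speed.

Bands are half-open `[lo, hi)` — with touching edges (θ 6–9, α 9–12 Hz) a
9-Hz bin belongs to α only, never double-counted. The 4–6 Hz range is
deliberately unassigned, and no high-γ band is computed by default (its
edges are not standardized). Band ratios with a zero denominator are
missing, not 0. Band powers are reported in absolute units; normalization
to total power is left to callers so ratios stay interpretable.

State-conditioned spectra average per-epoch spectra over every bout of the
state, excluding the first 2 epochs of each bout ("transition epochs",
interpreted per bout, since transitions recur at every state change; the
per-recording reading would discard only 2 epochs total and leave the rule
nearly vacuous). Bouts of ≤2 epochs therefore contribute nothing, and the
included-epoch count satisfies `Σ max(0, bout_len − 2)` exactly. The hourly
NREM delta time course (slow-wave activity, SWA) averages delta-band power
over included NREM epochs per ZT hour; hours without included epochs are
missing. SWA normalization divides by a caller-supplied baseline power —
by convention the animal's baseline-day light-phase NREM delta mean — and
is invariant to amplitude rescaling of the recording.

## Protocols

**Sleep deprivation.** Default protocol: 6 h of enforced wakefulness from
ZT0, recovery-sleep window ZT6–11, dark-phase follow-up ZT12–24. The
analysis takes explicit baseline-day and SD-day hypnograms (both covering
ZT0–24) rather than inferring days, computes hourly NREM/REM minutes for
both, cumulative NREM over the recovery window (exactly the sum of its
hourly values), and dark-phase REM totals. More than 5% sleep inside the
deprivation window triggers a compliance warning, not an error.

**MSLT.** Five 20-min nap opportunities (defaults at ZT2, 4, 6, 8, 10;
schedule fully configurable, since inter-nap structure varies between
laboratories). Latency is measured from nap start to the *first epoch* of
the first ≥2-epoch bout of the target state — onset-anchored latency, the
field convention. A nap without a qualifying bout is censored at the nap
duration (so latency ≤ nap duration always). Accumulated state minutes
count all epochs, singletons included. The scorer warns if its input is not
a fixpoint of the rescoring rules but scores the labels as given.

## Group statistics

- **Two-way between-subject ANOVA** (Genotype × Sex) uses Type III sums of
  squares via sum-to-zero contrasts (statsmodels OLS underneath), matching
  mainstream commercial packages on unbalanced cells; with all observations
  identical the table is reported as degenerate (F = 0) rather than 0/0.
  Empty design cells raise, naming the cell.
- **Repeated measures** are analyzed as a split-plot ANOVA with one
  between-subject factor and one within-subject factor on complete cases
  (subjects missing any within level are dropped with a warning). This is a
  deliberate approximation to likelihood-based mixed-effects modelling: the
  two agree when data are complete and the compound-symmetry assumption
  holds. The decomposition is computed from cell means and cross-checked in
  tests against both an explicit projection-matrix oracle and pingouin's
  mixed ANOVA.
- **Fisher's LSD** post hocs use the parent ANOVA's pooled error MS and df,
  two-sided and unadjusted by construction.
- **Holm-Šídák** is the step-down procedure: sorted ascending, step *i* of
  *m* tested against 1 − (1−α)^{1/(m−i+1)}, stopping at the first failure;
  adjusted p-values are the running maximum of 1 − (1−p₍ᵢ₎)^{m−i+1}. Under
  a global null the family-wise error rate stays at or below α, verified by
  simulation (m = 100, 10,000 replicates).
- **Per-bin comparisons** run pooled-variance unpaired t-tests per frequency
  bin (Welch behind a flag; the pooled form is the default reading of
  "unpaired t-test"), correct across all bins of the analyzed range by
  Holm-Šídák — the multiplicity family is the full analyzed range, not a
  single band — and report contiguous rejected runs as frequency ranges.
  Zero-variance identical bins are treated as p = 1.

## Synthetic-data generator

The generator produces cohorts with the statistical structure the analysis
assumes, with exact ground truth:

- **Hypnograms**: an alternating-renewal (semi-Markov) chain. At each state
  exit the next state is drawn from phase-specific exit probabilities
  (Wake→REM fixed at 0, mirroring the rescoring rules), and the bout length
  (≥2 epochs) from a shifted-geometric (support {2, 3, …}) or
  discretized-lognormal (`max(2, round(·))`) distribution with a
  state × phase mean. Long-run time-in-state follows the renewal-reward
  form πᵢE[Lᵢ]/Σⱼ πⱼE[Lⱼ], used as the analytic oracle in tests. Generated
  hypnograms are fixpoints of the rescoring rules by construction (the
  final truncated run is patched if truncation leaves a singleton REM).
- **Default parameters** (wildtype): mean bout lengths in epochs —
  Wake 12 light / 30 dark, NREM 18/12, REM 9/8; NREM→REM exit probability
  0.30 light / 0.15 dark, REM→Wake 0.9. These yield ≈36/56/8% W/N/R in the
  light phase and a wake-dominated dark phase — a realistic nocturnal mouse
  profile.
- **Knock-in ("mutant") preset**: dark-phase wake bout length ×2, NREM→REM
  entry ×0.6 (renormalized), REM theta EEG weight ×0.7, and an extra ×0.85
  REM-entry factor in females. These are qualitative presets for
  validation, not estimates fitted to any real cohort.
- **EEG**: each epoch is an independent sum of band-limited Gaussian
  components synthesized in the frequency domain, with per-state amplitude
  weights over δ/θ/α/β/low-γ; a component with weight w contributes
  per-sample variance w² exactly, so expected band powers and ratios are
  analytic. Continuity across epoch boundaries is *not* enforced: the
  analysis is strictly per-epoch, so the discontinuity is invisible to it —
  a documented limitation for any future time-domain use.
- **Activity**: Poisson counts per minute with a state × phase rate (the
  minute's state is its first epoch's state). **Temperature**: cosine
  circadian rhythm (mesor 36.3 °C, amplitude 0.7 °C, acrophase ZT18 —
  warmer in the active dark phase) plus state offsets and AR(1) noise
  (φ = 0.8, σ = 0.1 °C).
- **Cohorts**: per-animal seeds are spawned deterministically from the
  master seed (numpy `SeedSequence`), and every animal stores the exact
  parameter set that generated it.

What passing parameter-recovery tests show — and what they do not: the
pipeline correctly extracts effects of the kind and size injected under the
generator's assumptions (independent bout lengths, stationarity within each
phase, Gaussian band-limited EEG, no artifacts, no estrous or
inter-individual baseline structure beyond what the chain induces). They do
not certify performance on real telemetry data with movement artifacts,
scorer errors or non-stationary physiology.

## Validation problem sizes

The self-validation experiments (`sleeparch.recovery`, exercised by the
test suite and `scripts/acceptance.py`) use scaled designs chosen as the
package's own defaults: the wake-bout ratio recovery simulates the 2×2
genotype × sex design at n = 8 per cell with 2-day hypnograms; the
REM-theta detection experiment runs 100 replicates of 1-h recordings with
EEG at fs = 128 Hz and nfft = 2048 (bin ≈ 0.0625 Hz), n = 8 per cell,
detecting the injected theta deficit via the per-bin comparison over the
analyzed range. Detection counts a replicate as positive when any rejected
contiguous range overlaps 6–9 Hz. The sizes keep the full validation under
a few minutes on one CPU while leaving comfortable statistical power.

## Numerical choices and degenerate inputs

Empty analysis windows raise; missing quantities (no bouts, no included
epochs, zero denominator) are `None`/absent, never 0. Non-finite EEG
samples raise, naming the offending sample index. CSV writers are
deterministic (stable ordering, fixed float formats, empty fields for
missing values). The minimal EDF writer quantizes to the 16-bit grid of the
declared physical range; round-trips are exact to that quantization step.
Holm-Šídák handles p = 1 and p = 0 exactly via `log1p`/`expm1` arithmetic.
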
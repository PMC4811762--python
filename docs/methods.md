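# Methods notes

This note records the models, parameter choices and numerical decisions
behind `conflictlfp`, in the order data flows through the package.

## Synthetic cohorts (`synth`)

The generator's job is to produce multichannel field potentials, trial
tables and audio whose *statistical structure* matches what the analysis
cascade assumes, so that every downstream stage can be validated by
planted-parameter recovery and null calibration.  It does not attempt
biophysical realism (no volume conduction, no seizure artifacts, no
realistic speech acoustics).

**Trial structure.** Blocks of 18 trials; congruency drawn Bernoulli
with P(incongruent) = 0.40; word-color combinations cycled through
shuffled decks within each congruency class, so combinations are
counterbalanced to within one deck.  Trial period = 0.5 s fixation +
2 s stimulus + 1.5 s inter-trial.

**Reaction times.** Lognormal with mean 0.89 s and s.d. 0.22 s, plus an
additive congruency delay (0.215 s in the Stroop task, 0.022 s in
Reading) and history adjustments giving cI − iI = 34 ms and iC − cC =
72 ms.  The history adjustments are centered within each congruency
class (cI gets +g·P(prev I), iI gets −g·P(prev C), and analogously for
iC/cC), so planting Gratton structure does not shift the marginal C/I
means and the congruency delay stays exactly 215 ms.  RTs longer than
the 2 s stimulus mark a no-response trial.  Incongruent Stroop trials
err with probability 0.05; half of the errors are self-corrected
0.45–0.7 s later.

**Signals.** Per channel: 1/f-shaped Gaussian background (exponent 1,
small white floor, s.d. 10 µV) + 60 Hz sinusoid (4 µV) + narrowband
theta (4 µV), beta (2.5 µV) and gamma (1.2 µV) noise components.
Conflict-responsive channels add a response-locked high-gamma burst on
every responded trial: a 400 ms raised-cosine envelope on a 70–120 Hz
noise carrier (peak gain 5 µV), *beginning `latency_lead` seconds before
speech onset*.  On incongruent Stroop trials the burst power is
multiplied by `gamma_effect_size` (default 1.5) and the theta/beta
components are suppressed (default fractional power drop 0.3; the
original observation reports the sign of this decrease but not its
size, so the depth is configurable and not calibrated).  Default leads
are ACC 0.900 s, dlPFC 0.693 s, mFC 0.512 s, OFC 0.374 s, which plants
the pairwise lags 207 ms (ACC→dlPFC), 388 ms (ACC→mFC) and 319 ms
(dlPFC→OFC).

**Power–RT coupling.** Each channel's burst gain is lognormal
(`gain_jitter_sd` = 0.4 on the log scale) with its Gaussian copula tied
to the trial's latent RT residual.  The measurable power–RT Pearson
correlation is attenuated below the latent copula level by the skew of
the lognormal gain, the additive background power and single-trial
estimation noise; the latent level is therefore scaled by a fixed
compensation factor (1.22, calibrated once against the default
amplitudes) so `power_rt_coupling` is the correlation the downstream
estimator actually recovers (≈ 0.25 at the default).  Gain noise is
drawn per channel (conditionally independent across channels given the
RT residual): a single shared per-trial gain would both be unrealistic
and leak through the common average reference.

**Reference-only contacts.** Clinical grids carry many contacts outside
the analysed frontal set, and the common average is computed over all
of them.  A cohort consisting *only* of conflict-responsive channels
would leak each channel's effect into every other channel through the
common average (1/n of every burst), contaminating latency estimates.
Each subject therefore gets `car_null_channels` (default 20)
background-only contacts that enter the reference but are dropped from
analysis.

**Phase-amplitude coupling.** Optional: the background gamma component's
amplitude is modulated as 1 + `pac_strength`·cos(θ-phase), with the
phase taken from the channel's own theta component.

**Seeding.** One master seed fans out through spawned NumPy
`SeedSequence` streams: trial tables (one stream per subject × task),
then recordings (one per channel in channel-plan order), then audio.
Identical configs regenerate bit-identical cohorts.

## Preprocessing (`preprocess`)

Zero-phase Butterworth band-stop 58–62 Hz (4th order, applied
forward–backward), then common average over retained channels.  Band
power comes from a sliding multitaper estimate: 200 ms windows, 10 ms
hop, NW = 5 with K = 7 DPSS tapers, window mean removed, power summed
over in-band FFT bins (no zero-padding, so 5 Hz bin spacing at fs =
500 Hz) and averaged over tapers.  Scaling constants are immaterial
because every downstream statistic is a ratio, a rank, or z-scored.

Window timestamps are window *centers* on a global 10 ms grid anchored
at the recording start; stimulus- and response-aligned epochs are
slices of the same grid (event times snap to the nearest bin), which
makes the two alignments index-compatible and makes the epoch-local
fast path (`epoch_band_power`) bit-identical to slicing the continuous
estimate.  Every event-locked value therefore carries ±100 ms of
temporal support — detection latencies inherit this smearing, and
first-crossing latencies are additionally biased late by the rise time
of the underlying envelope; both effects are common across regions and
cancel in between-region latency *differences*, which is why the
hierarchy analysis works on pairs.

Baseline statistics pool the 500 ms of pre-stimulus bins over all
trials, per electrode.  Z-scoring is display-only (plus the detector's
amplitude criterion); statistics consume linear power.

## Selectivity detection (`selectivity`)

Per bin, the two-group F between I and C trials on raw power.  The
pointwise threshold is the k-th largest permuted F with
k = max(1, ⌊α(n_perm + 1)⌋) over label permutations, making the per-bin
exceedance probability k/(n_perm + 1) ≈ α exactly under
exchangeability; attaining α = 0.001 therefore needs n_perm ≥ 1000
(the package default).  An electrode is selective when some run of ≥ 5
consecutive bins (50 ms at the 10 ms hop) exceeds threshold *within the
detection window* — stimulus-aligned [0, +1] s, response-aligned
[−1, 0] s, the same windows the single-trial power scalars use — and
the across-trial mean z-scored power exceeds 1 somewhere in the epoch.
Latency is the first bin of the first qualifying run; response-aligned
electrodes qualify for latency analyses only when the latency precedes
the response.

Latency uncertainty comes from a within-class trial bootstrap (the
permutation threshold held fixed, since it is a property of the full
dataset); replicates that lose selectivity are dropped and their
fraction reported, with the estimate flagged unstable beyond 50%.

The population false-positive rate re-runs the complete procedure under
per-electrode label shuffles and reports the mean count of electrodes
passing in either alignment.  For large populations the per-electrode
thresholds can be computed once and shared across shuffle replicates
(`reuse_thresholds`): each shuffled labeling is exchangeable with the
threshold permutations, so the mean count is unbiased; only the
across-replicate s.e.m. becomes approximate.  Region enrichment
compares observed per-region selective counts against the same shuffle
replicates.

## Single-electrode statistics (`trial_stats`)

Per-trial scalars are the max (or mean) power in stimulus-aligned
[0, +1] s or response-aligned [−1, 0] s.  The Congruency × Task
interaction F uses the regression formulation (valid for unbalanced
cells), its peak over the pre-response window tested against joint
shuffles of the four-way cell label (preserving marginal cell counts).
The Gratton ANCOVA fits a common-slope model power ~ history + RT and
reports the intercept difference — identical to the contrast at any
fixed RT, so the choice of reference RT is immaterial.  Histogram
matching subsamples both history groups to the per-bin minimum count in
200 ms RT bins.  The error-monitoring contrast compares mean z-power in
the 1 s after the erroneous vs the corrected response onset on
self-correction trials (exact signed-rank for n ≤ 25), skipping
electrodes with fewer than 5 such trials.

## Group inference (`group_stats`)

Mixed models with random intercepts for subject and
electrode-within-subject, ML estimation (not REML, for likelihood-ratio
comparability across fixed-effect structures), LRT against the null
model excluding the tested term (df reported explicitly).  Each model
is fit with two optimizers and the better likelihood kept — a single
optimizer occasionally parks a variance component in a poor local
optimum, which would corrupt the LRT.  Singular fits fall back to a
subject-aggregate OLS LRT with the fallback recorded in the result.
Per-trial scalars (not electrode means) are the outcome grain.
Incongruent/congruent log-ratio traces are computed for display only.

## Latency hierarchy (`latency`)

One observation per pair of simultaneously recorded cross-region
electrodes within a subject; the pair difference is latency(B) −
latency(A) with the region pair ordered alphabetically.  The omnibus
statistic is the one-way F of the differences across region-pair
groups; the null shuffles region labels *within each subject* and
rebuilds all pairs per shuffle (stricter than permuting group labels of
fixed diffs, and electrodes never cross subjects by construction).
Per-region-pair permutation p-values (two-sided on the mean difference)
are Benjamini–Hochberg adjusted over the reported cells; cells with
fewer than 2 pairs are flagged unreported but still participate in the
omnibus.  Pairs sharing an electrode are dependent; the pair-level
accounting treats each pair as one observation, matching the n_p
convention, and this dependence is a known limitation of the s.e.m.

## Cross-frequency coupling (`cfc`)

Band signals from least-squares linear-phase FIR filters (length = 3
cycles of the band's low edge rounded odd, 20% transition bands),
applied forward–backward; phase and amplitude from the analytic signal.
MI is the normalized KL divergence of the phase-binned mean amplitude
distribution over N = 18 bins (20°).  Lag surrogates circularly shift
the amplitude by offsets drawn from [1 s, T − 1 s] (avoiding trivially
small lags); trial-swap surrogates are provided as a cross-check, as is
a mean-vector-length estimator for rank-order comparison.  Condition
differences equalize trial counts by seeded subsampling of the larger
condition before label-shuffle testing.  Empty phase bins (impossible
at the preconditioned ≥ 10 samples/bin) borrow the nearest non-empty
bin's mean.

## Problem sizes and calibration checks

The test suite runs every stage at reduced sizes chosen so the full
suite completes in a routine run: null-calibration of the detector on a
96-electrode population with 60 shuffles; type-I calibration of the
interaction, mixed-model, latency and coupling tests over 200 null
replicates each at reduced permutation counts; parameter-recovery
cohorts of 2–8 subjects.  The acceptance script runs the null
false-positive calibration at full population scale (469 electrodes,
100 shuffle replicates, 1000-permutation thresholds).

Passing these tests shows that the pipeline's statistics are calibrated
and recover effects *under the generator's assumptions* — lognormal
RTs, raised-cosine bursts on stationary 1/f backgrounds, Gaussian-copula
couplings.  Real recordings have nonstationarities, artifacts,
electrode-count imbalances and effect heterogeneity that the generator
deliberately omits, so the tests validate the machinery, not claims
about any particular dataset.

## Known limitations

* First-crossing latencies are biased by SNR and envelope rise time;
  only latency differences between comparable channels are unbiased.
* The amplitude criterion uses the across-all-trials mean z-trace; a
  per-condition definition would behave differently for channels
  responsive in only one condition.
* The null false-positive rate of the compound detection rule depends
  on the autocorrelation of the band-power traces and on the number of
  tested bins; with this generator's window-overlap autocorrelation the
  electrode-level rate is ≈ 1.3% at α = 0.001 across both alignments.
* Mixed-model LRT p-values rely on χ² asymptotics; at very small
  cohorts the subject-aggregate fallback is more trustworthy.
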
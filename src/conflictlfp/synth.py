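"""Synthetic Stroop-task cohorts: trial tables, field potentials and audio.

The generator emulates the statistical structure the downstream analyses
assume, so that every stage of the pipeline is testable without patient
data:

* interleaved blocks of 18 trials, ~60/40 congruent/incongruent, with
  word-color combinations counterbalanced within each congruency class;
* lognormal reaction times with an additive congruency delay (Stroop
  only) and trial-history (Gratton) adjustments; occasional errors on
  incongruent trials, some of which are self-corrected;
* per-channel 1/f background plus 60 Hz line noise, and — on
  conflict-responsive channels — a response-locked high-gamma burst that
  is stronger on incongruent Stroop trials and begins a region-specific
  lead time before speech onset; theta/beta components are suppressed on
  those same trials;
* trial-wise coupling between the gamma burst gain and the reaction
  time, planted through a Gaussian copula so the target Pearson
  correlation is controlled directly; optional theta-phase -> gamma-
  amplitude coupling of configurable depth;
* per-trial audio traces with a speech-band burst at the true reaction
  time (two bursts on self-correction trials) for the energy detector.

Randomness: a single master seed fans out through ``numpy`` spawned
child streams in a documented order — trial tables first (one stream per
subject x task), then recordings (one stream per channel, in channel-plan
order), then audio (one stream per trial).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import label_history
from .preprocess import Recording

REGIONS = ("ACC", "dlPFC", "mFC", "OFC")
WORDS = ("Red", "Blue", "Green")
COLORS = ("red", "blue", "green")

#: electrode counts over the four frontal regions in the emulated cohort
DEFAULT_ELECTRODES = {"mFC": 111, "OFC": 156, "dlPFC": 168, "ACC": 34}

#: region lead times (s before speech onset) reproducing the planted
#: conflict cascade: ACC first, then dlPFC (207 ms later), mFC (388 ms
#: after ACC) and OFC (319 ms after dlPFC)
DEFAULT_LEADS = {"ACC": 0.900, "dlPFC": 0.693, "mFC": 0.512, "OFC": 0.374,
                 "null": 0.500}


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults reproduce the emulated study: 15 subjects, 469 frontal
    electrodes, 18 Stroop + 9 Reading blocks of 18 trials, 40%
    incongruent, a 215 ms congruency delay on a ~0.89 s lognormal RT
    (incongruent Stroop mean ~1.1 s), Gratton RT differences of 34 ms
    (cI-iI) and 72 ms (iC-cC), 5% incongruent-trial errors, and a
    planted high-gamma conflict effect with region-specific latency
    leads and 0.25 power-RT coupling.
    """

    n_subjects: int = 15
    electrodes_per_region: dict = field(
        default_factory=lambda: dict(DEFAULT_ELECTRODES))
    fs: float = 500.0
    n_blocks_stroop: int = 18
    n_blocks_reading: int = 9
    trials_per_block: int = 18
    p_incongruent: float = 0.40
    rt_base_mean: float = 0.89
    rt_base_sd: float = 0.22
    rt_congruency_delay: float = 0.215
    rt_reading_delay: float = 0.022
    rt_gratton_cI_minus_iI: float = 0.034
    rt_gratton_iC_minus_cC: float = 0.072
    error_rate_incongruent: float = 0.05
    p_self_correct_given_error: float = 0.5
    gamma_effect_size: float = 1.5          # incongruent/congruent power ratio
    region_latency_lead: dict = field(
        default_factory=lambda: dict(DEFAULT_LEADS))
    power_rt_coupling: float = 0.25
    pac_strength: float = 0.0
    theta_beta_suppression: float = 0.3     # fractional power drop on I trials
    burst_duration: float = 0.4
    stim_duration: float = 2.0
    fixation: float = 0.5
    iti: float = 1.5
    # signal amplitudes, microvolt scale
    background_sd: float = 10.0
    line_amplitude: float = 4.0
    theta_amplitude: float = 4.0
    beta_amplitude: float = 2.5
    gamma_base_amplitude: float = 1.2
    burst_amplitude: float = 5.0
    gain_jitter_sd: float = 0.40            # lognormal sd of burst gain
    #: the measurable power-RT Pearson correlation is attenuated below
    #: the latent copula level by the lognormal gain skew, the additive
    #: background power and single-trial estimation noise; the latent
    #: copula is scaled up by this factor (calibrated once against the
    #: default amplitudes) so ``power_rt_coupling`` is the correlation
    #: the downstream estimator actually recovers
    rt_coupling_compensation: float = 1.22
    #: extra background-only contacts per subject that enter the common
    #: average reference but not the analysis, emulating the rest of the
    #: clinical grid (~93 contacts/subject of which only the frontal
    #: subset is analysed).  Without them the common average of a small
    #: all-responsive cohort would leak each channel's conflict effect
    #: into every other channel.
    car_null_channels: int = 20
    seed: int = 0

    def validate(self) -> None:
        fracs = dict(p_incongruent=self.p_incongruent,
                     error_rate_incongruent=self.error_rate_incongruent,
                     p_self_correct=self.p_self_correct_given_error,
                     pac_strength=self.pac_strength,
                     theta_beta_suppression=self.theta_beta_suppression)
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.fs <= 2 * 120.0:
            raise ConfigError(f"fs={self.fs} too low for the 70-120 Hz band")
        if self.rt_base_mean <= 0 or self.rt_base_sd <= 0:
            raise ConfigError("lognormal RT parameters must be positive")
        if not -1.0 <= self.power_rt_coupling <= 1.0:
            raise ConfigError("power_rt_coupling outside [-1, 1]")

    @property
    def trial_period(self) -> float:
        return self.fixation + self.stim_duration + self.iti


def _seed_streams(config: SimConfig):
    """Documented fan-out of the master seed (see module docstring)."""
    root = np.random.SeedSequence(config.seed)
    trials_ss, rec_ss, audio_ss = root.spawn(3)
    return trials_ss, rec_ss, audio_ss


def _counterbalanced_combos(congruency: np.ndarray,
                            rng: np.random.Generator):
    """Assign word/color pairs, cycling shuffled decks within each class."""
    cong = [(w, c) for w, c in zip(WORDS, COLORS)]
    incg = [(w, c) for w in WORDS for c in COLORS
            if c.lower() != w.lower()]
    words = np.empty(congruency.size, dtype=object)
    colors = np.empty(congruency.size, dtype=object)
    for is_i, deck in ((False, cong), (True, incg)):
        pos = np.flatnonzero(congruency == is_i)
        seq = []
        while len(seq) < pos.size:
            d = list(deck)
            rng.shuffle(d)
            seq.extend(d)
        for p, (w, c) in zip(pos, seq):
            words[p], colors[p] = w, c
    return words, colors


def make_trial_table(config: SimConfig, task: str,
                     rng: np.random.Generator | int | None = None
                     ) -> pd.DataFrame:
    """Generate one subject's trial table for ``task`` (Stroop/Reading)."""
    config.validate()
    if task not in ("Stroop", "Reading"):
        raise ConfigError(f"unknown task {task!r}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    n_blocks = (config.n_blocks_stroop if task == "Stroop"
                else config.n_blocks_reading)
    n = n_blocks * config.trials_per_block
    block_id = np.repeat(np.arange(n_blocks), config.trials_per_block)
    congruent_mask = rng.random(n) >= config.p_incongruent
    congruency = np.where(congruent_mask, "C", "I")
    words, colors = _counterbalanced_combos(~congruent_mask, rng)

    period = config.trial_period
    stimulus_onset = 2.0 + np.arange(n) * period + config.fixation

    # latent RT residual; each channel later couples its burst gain to
    # it through a Gaussian copula at level power_rt_coupling
    z_rt = rng.standard_normal(n)

    m, s = config.rt_base_mean, config.rt_base_sd
    sigma2 = np.log1p((s / m) ** 2)
    mu = np.log(m) - sigma2 / 2
    rt = np.exp(mu + np.sqrt(sigma2) * z_rt)

    delay = (config.rt_congruency_delay if task == "Stroop"
             else config.rt_reading_delay)
    rt = rt + delay * (~congruent_mask)

    trials = pd.DataFrame({
        "trial_id": np.arange(n),
        "block_id": block_id,
        "task": task,
        "word": words,
        "color": colors,
        "congruency": congruency,
        "stimulus_onset": stimulus_onset,
    })
    trials = label_history(trials)
    # history adjustments, centered within each congruency class so the
    # planted cI-iI / iC-cC differences do not shift the marginal C/I
    # means (and hence the planted congruency delay)
    p_prev_c = 1.0 - config.p_incongruent
    g1, g2 = config.rt_gratton_cI_minus_iI, config.rt_gratton_iC_minus_cC
    hist = trials["history"]
    rt = rt + np.select(
        [hist == "cI", hist == "iI", hist == "iC", hist == "cC"],
        [g1 * (1 - p_prev_c), -g1 * p_prev_c,
         g2 * p_prev_c, -g2 * (1 - p_prev_c)], 0.0)

    err_p = np.where((congruency == "I") & (task == "Stroop"),
                     config.error_rate_incongruent, 0.0)
    error = rng.random(n) < err_p
    self_corr = error & (rng.random(n) < config.p_self_correct_given_error)
    no_response = rt > config.stim_duration

    trials["rt"] = np.where(no_response, np.nan, rt)
    trials["correct"] = ~error & ~no_response
    trials["self_corrected"] = self_corr & ~no_response
    err_on = np.where(error & ~no_response, stimulus_onset + rt, np.nan)
    corr_on = err_on + rng.uniform(0.45, 0.7, size=n)
    trials["error_response_onset"] = err_on
    trials["corrected_response_onset"] = np.where(trials["self_corrected"],
                                                  corr_on, np.nan)
    trials["_rt_z"] = z_rt
    return trials


def make_channel_plan(config: SimConfig) -> pd.DataFrame:
    """Distribute the cohort's electrodes over subjects, round-robin.

    Returns one row per channel with subject, region, a ``responsive``
    flag (whether the channel carries the response-locked gamma burst at
    all) and its planted ``effect_size`` (incongruent/congruent power
    ratio; 1.0 = no conflict effect) and ``latency_lead``.
    """
    rows = []
    for region in sorted(config.electrodes_per_region):
        count = config.electrodes_per_region[region]
        for i in range(count):
            rows.append(dict(region=region, subject=i % config.n_subjects,
                             aux=False))
    for s in range(config.n_subjects):
        rows.extend(dict(region="null", subject=s, aux=True)
                    for _ in range(config.car_null_channels))
    plan = pd.DataFrame(rows).sort_values(["subject", "aux", "region"],
                                          kind="stable")
    plan = plan.reset_index(drop=True)
    plan["channel"] = np.arange(len(plan))
    plan["hemisphere"] = "L"
    plan["excluded"] = False
    plan["responsive"] = (plan["region"] != "null") & ~plan["aux"]
    plan["effect_size"] = np.where(plan["responsive"],
                                   config.gamma_effect_size, 1.0)
    plan["latency_lead"] = plan["region"].map(
        config.region_latency_lead).fillna(0.5)
    return plan[["channel", "subject", "region", "hemisphere", "excluded",
                 "aux", "responsive", "effect_size", "latency_lead"]]


def _pink_background(n: int, fs: float, sd: float,
                     rng: np.random.Generator) -> np.ndarray:
    """1/f-shaped Gaussian noise (exponent 1) with a white floor."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = np.sqrt(1.0 / freqs[1:] + 0.01)
    spec = (rng.standard_normal(freqs.size) +
            1j * rng.standard_normal(freqs.size)) * shape
    x = np.fft.irfft(spec, n)
    x *= sd / x.std()
    return x


def _narrowband_noise(n: int, fs: float, lo: float, hi: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise confined to [lo, hi] Hz."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shape = ((freqs >= lo) & (freqs <= hi)).astype(float)
    spec = (rng.standard_normal(freqs.size) +
            1j * rng.standard_normal(freqs.size)) * shape
    x = np.fft.irfft(spec, n)
    x /= x.std()
    return x


def _raised_cosine(n: int) -> np.ndarray:
    return 0.5 * (1 - np.cos(2 * np.pi * np.arange(n) / max(n - 1, 1)))


def synthesize_recording(trials: pd.DataFrame, config: SimConfig,
                         channels: pd.DataFrame,
                         rng_parent=None) -> Recording:
    """Render one subject's multichannel recording.

    ``channels`` is that subject's slice of the channel plan.  Responsive
    channels receive a response-locked gamma burst on every responded
    trial; on incongruent Stroop trials the burst power is multiplied by
    the channel's ``effect_size`` and starts ``latency_lead`` seconds
    before speech onset.  Non-responsive channels are background only.
    """
    config.validate()
    fs = config.fs
    last = trials["stimulus_onset"].max() + config.stim_duration + config.iti
    n = int(np.ceil((last + 2.0) * fs))
    if rng_parent is None:
        rng_parent = np.random.SeedSequence(config.seed)
    if isinstance(rng_parent, np.random.SeedSequence):
        child_seeds = rng_parent.spawn(len(channels))
    else:  # list of SeedSequences, one per channel
        child_seeds = list(rng_parent)

    resp_onset = (trials["stimulus_onset"] + trials["rt"]).to_numpy(float)
    responded = np.isfinite(resp_onset)
    is_conflict = ((trials["congruency"] == "I") &
                   (trials["task"] == "Stroop")).to_numpy()
    rt_z = trials["_rt_z"].to_numpy(float) if "_rt_z" in trials \
        else np.zeros(len(trials))
    rho = np.clip(config.power_rt_coupling *
                  config.rt_coupling_compensation, -0.95, 0.95)
    if config.power_rt_coupling == 0.0:
        rho = 0.0
    err_on = trials.get("error_response_onset",
                        pd.Series(np.nan, index=trials.index)
                        ).to_numpy(float)
    corr_on = trials.get("corrected_response_onset",
                         pd.Series(np.nan, index=trials.index)
                         ).to_numpy(float)

    n_burst = int(round(config.burst_duration * fs))
    env_proto = _raised_cosine(n_burst)
    t = np.arange(n) / fs

    sig = np.empty((len(channels), n), dtype=np.float32)
    for row_i, (_, ch) in enumerate(channels.iterrows()):
        rng = np.random.default_rng(child_seeds[row_i])
        x = _pink_background(n, fs, config.background_sd, rng)
        x += config.line_amplitude * np.sin(
            2 * np.pi * 60.0 * t + rng.uniform(0, 2 * np.pi))

        theta = _narrowband_noise(n, fs, 4.0, 8.0, rng)
        beta = _narrowband_noise(n, fs, 9.0, 30.0, rng)
        gamma = _narrowband_noise(n, fs, 70.0, 120.0, rng)

        responsive = bool(ch["responsive"])
        eff = float(ch["effect_size"])
        lead = float(ch["latency_lead"])

        slow_env = np.ones(n)
        burst_gain = np.zeros(n)
        if responsive:
            depth = config.theta_beta_suppression
            # channel-specific gain jitter, coupled to the trial's RT
            # residual at the configured copula level (noise independent
            # across channels, so the common average does not share it)
            z_gain = rho * rt_z + np.sqrt(max(0.0, 1 - rho ** 2)) * \
                rng.standard_normal(len(rt_z))
            for i in np.flatnonzero(responded):
                jitter = np.exp(config.gain_jitter_sd * z_gain[i])
                amp = config.burst_amplitude * jitter
                start = resp_onset[i] - lead
                s0 = int(round(start * fs))
                if s0 < 0 or s0 + n_burst > n:
                    continue
                if is_conflict[i]:
                    amp *= np.sqrt(eff)
                    # theta/beta suppression is itself a congruency
                    # effect: only channels with a planted conflict
                    # effect carry it
                    if depth > 0 and eff != 1.0:
                        d0 = max(0, int(round((start - 0.1) * fs)))
                        d1 = min(n, int(round((resp_onset[i] + 0.1) * fs)))
                        slow_env[d0:d1] = np.sqrt(1.0 - depth)
                burst_gain[s0:s0 + n_burst] += amp * env_proto
            # post-error monitoring burst on self-corrected trials
            for i in np.flatnonzero(np.isfinite(err_on) &
                                    trials["self_corrected"].to_numpy()):
                s0 = int(round(err_on[i] * fs))
                if 0 <= s0 and s0 + n_burst <= n:
                    burst_gain[s0:s0 + n_burst] += \
                        config.burst_amplitude * env_proto

        gamma_amp = config.gamma_base_amplitude
        if config.pac_strength > 0:
            phase = np.angle(_analytic(theta))
            gamma_amp = gamma_amp * (1.0 + config.pac_strength *
                                     np.cos(phase))
        x += theta * config.theta_amplitude * slow_env
        x += beta * config.beta_amplitude * slow_env
        x += gamma * (gamma_amp + burst_gain)
        sig[row_i] = x

    meta = channels.reset_index(drop=True)
    return Recording(signal=sig, fs=fs, channels=meta, line_freq=60.0)


def _analytic(x: np.ndarray) -> np.ndarray:
    import scipy.signal
    return scipy.signal.hilbert(x)


def synthesize_audio(trials: pd.DataFrame, fs_audio: float = 8192.0,
                     rng: np.random.Generator | int | None = None,
                     trace_duration: float = 3.5,
                     pre_stim: float = 0.5) -> list[np.ndarray]:
    """Per-trial mono PCM traces for the speech-onset detector.

    Each trace starts ``pre_stim`` seconds before stimulus onset:
    low-amplitude noise, then a speech-band burst at the trial's true
    reaction time (i.e. ``pre_stim + rt`` into the trace).
    Self-correction trials contain two bursts (error then corrected
    response); trials without a response stay at baseline.
    """
    if fs_audio < 8000:
        raise ConfigError("fs_audio must be >= 8000 Hz")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = int(round(trace_duration * fs_audio))
    n_burst = int(round(0.35 * fs_audio))
    env = _raised_cosine(n_burst) ** 0.5
    env[:int(0.01 * fs_audio)] *= np.linspace(0, 1, int(0.01 * fs_audio))

    out = []
    for _, tr in trials.iterrows():
        x = 0.01 * rng.standard_normal(n)
        onsets = []
        if tr.get("self_corrected", False) and np.isfinite(
                tr.get("error_response_onset", np.nan)):
            onsets = [tr["error_response_onset"] - tr["stimulus_onset"],
                      tr["corrected_response_onset"] - tr["stimulus_onset"]]
        elif np.isfinite(tr.get("rt", np.nan)):
            onsets = [tr["rt"]]
        for onset in onsets:
            s0 = int(round((pre_stim + onset) * fs_audio))
            if s0 < 0 or s0 + n_burst > n:
                continue
            burst = _narrowband_noise(n_burst, fs_audio, 150.0, 2500.0, rng)
            x[s0:s0 + n_burst] += 0.5 * env * burst
        out.append(x.astype(np.float32))
    return out


def simulate_subject(config: SimConfig, subject: int, task: str = "Stroop",
                     plan: pd.DataFrame | None = None):
    """Trial table + recording for one subject (convenience wrapper)."""
    trials_ss, rec_ss, _ = _seed_streams(config)
    t_children = trials_ss.spawn(config.n_subjects * 2)
    offset = subject * 2 + (0 if task == "Stroop" else 1)
    rng = np.random.default_rng(t_children[offset])
    trials = make_trial_table(config, task, rng)
    if plan is None:
        plan = make_channel_plan(config)
    chans = plan[plan["subject"] == subject]
    rec_children = rec_ss.spawn(len(plan))
    ch_seeds = [rec_children[c] for c in chans["channel"]]
    rec = synthesize_recording(trials, config, chans, ch_seeds)
    return trials, rec
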
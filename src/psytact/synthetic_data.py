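"""Seeded synthetic cohorts, skin-conductance traces and psychophysics sessions.

This module emulates a two-group (ASD / typically developing) tactile
sensitivity study so that every downstream analysis stage can be exercised
without real recordings:

* a latent standard-normal *autonomic reactivity* trait per participant
  raises their event-related SCR amplitudes and (through a configurable
  loading) their questionnaire subscores, so SCR–questionnaire correlations
  are positive by construction;
* skin-conductance traces are a tonic level plus optional slow drift plus
  one unit-normalized bi-exponential (Bateman) phasic response per
  stimulation plus smoothed Gaussian noise;
* two-interval forced-choice (2IFC) responses come from observers with
  logistic psychometric functions (guess rate 0.5, optional lapse rate);
* "stronger/weaker" comparison responses come from a logistic comparison
  observer; 0–10 ratings from a discretized normal model.

All randomness flows from one integer seed through a hierarchical
stream-splitting rule (one substream per participant per task), so any
stage can be regenerated independently and reproducibly.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.special import expit

from .scr_events import STRONG, WEAK, SkinConductanceTrace, StimulusEvent

GROUPS = ("ASD", "TD")
INTENSITIES = (WEAK, STRONG)
BODY_SITES = ("palm", "forearm", "neck")
RATING_CATEGORIES = ("intensity", "painful", "unpleasant")

SRS2_SUBSCALES = (
    "social_awareness",
    "social_cognition",
    "social_communication",
    "social_motivation",
    "restricted_repetitive",
    "social_communication_interaction",
    "total",
)
AASP_SUBSCALES = (
    "poor_registration",
    "sensation_seeking",
    "sensitivity_to_stimuli",
    "sensation_avoiding",
)


def substream(seed: int, *keys) -> np.random.Generator:
    """Independent, reproducible random stream for (seed, keys...).

    Keys are hashed to a spawn key so that e.g. the trace of participant
    ASD07 is identical whether or not other participants are simulated.
    """
    spawn = tuple(zlib.crc32(str(k).encode("utf8")) for k in keys)
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=spawn))


# --------------------------------------------------------------------------
# phasic response kernel

@dataclass(frozen=True)
class BatemanKernel:
    """Unit-normalized bi-exponential phasic SCR kernel.

    ``h(t) ∝ exp(-(t-delay)/decay) - exp(-(t-delay)/rise)`` for t > delay,
    scaled so its maximum equals 1 (an injected amplitude A therefore
    produces a phasic component peaking exactly at A).  With the defaults
    the kernel peaks 5.62 s after stimulus onset, i.e. ≈4.6 s after the
    offset of a 1-s stimulus, matching typical event-related SCR latencies.
    """

    rise_s: float = 2.0
    decay_s: float = 10.0
    delay_s: float = 1.6

    def __post_init__(self) -> None:
        if not (self.decay_s > self.rise_s > 0):
            raise ValueError("kernel requires decay_s > rise_s > 0")

    @property
    def peak_offset_s(self) -> float:
        """Time of the kernel maximum, measured from stimulus onset."""
        r, d = self.rise_s, self.decay_s
        return self.delay_s + np.log(d / r) * r * d / (d - r)

    def __call__(self, t: np.ndarray) -> np.ndarray:
        u = np.asarray(t, dtype=float) - self.delay_s
        raw = np.where(u > 0, np.exp(-np.clip(u, 0, None) / self.decay_s)
                       - np.exp(-np.clip(u, 0, None) / self.rise_s), 0.0)
        upk = self.peak_offset_s - self.delay_s
        peak = np.exp(-upk / self.decay_s) - np.exp(-upk / self.rise_s)
        return raw / peak


# --------------------------------------------------------------------------
# observers

@dataclass(frozen=True)
class ObserverSpec:
    """Simulated 2IFC observer with a logistic psychometric function.

    P(correct | level) = guess + (1 − guess − lapse) · F((level − θ) / σ)
    with F the logistic CDF, θ the threshold and σ the spread (both in
    stimulus units).  guess is 0.5 for a two-interval task.
    """

    threshold: float
    spread: float
    lapse_rate: float = 0.0
    guess_rate: float = 0.5

    def __post_init__(self) -> None:
        if self.spread <= 0:
            raise ValueError("observer spread must be > 0")
        if not 0.0 <= self.lapse_rate <= 0.1:
            raise ValueError("lapse_rate must be within [0, 0.1]")
        if not 0.0 <= self.guess_rate < 1.0:
            raise ValueError("guess_rate must be within [0, 1)")

    def p_correct(self, level) -> np.ndarray | float:
        core = expit((np.asarray(level, dtype=float) - self.threshold) / self.spread)
        p = self.guess_rate + (1.0 - self.guess_rate - self.lapse_rate) * core
        return float(p) if np.isscalar(level) else p


def simulate_2ifc_response(observer: ObserverSpec, level: float,
                           rng: np.random.Generator) -> bool:
    """One Bernoulli 2IFC trial at the given stimulus level."""
    return bool(rng.random() < observer.p_correct(level))


# --------------------------------------------------------------------------
# cohort specification

@dataclass(frozen=True)
class SubscaleSpec:
    """Generative parameters for one questionnaire subscale."""

    mean_asd: float
    sd_asd: float
    mean_td: float
    sd_td: float
    minimum: float
    maximum: float
    loading_sign: float = 1.0  # -1 for subscales lower in high-reactivity people

    def mean(self, group: str) -> float:
        return self.mean_asd if group == "ASD" else self.mean_td

    def sd(self, group: str) -> float:
        return self.sd_asd if group == "ASD" else self.sd_td


def _default_questionnaires() -> dict:
    q = {}
    # SRS-2 subscale T-scores: elevated in the ASD group.
    for name in SRS2_SUBSCALES:
        hi = 90.0 if name != "total" else 200.0
        m_asd, m_td = (70.0, 50.0) if name != "total" else (100.0, 55.0)
        q[f"srs2_{name}"] = SubscaleSpec(m_asd, 10.0, m_td, 8.0, 0.0, hi)
    # AASP raw subscale scores (15–75); Sensation Seeking runs the other way.
    q["aasp_poor_registration"] = SubscaleSpec(45.0, 8.0, 32.0, 6.0, 15.0, 75.0)
    q["aasp_sensation_seeking"] = SubscaleSpec(35.0, 8.0, 45.0, 7.0, 15.0, 75.0, loading_sign=-1.0)
    q["aasp_sensitivity_to_stimuli"] = SubscaleSpec(48.0, 9.0, 36.0, 7.0, 15.0, 75.0)
    q["aasp_sensation_avoiding"] = SubscaleSpec(47.0, 9.0, 39.0, 8.0, 15.0, 75.0)
    return q


@dataclass(frozen=True)
class RatingSpec:
    """0–10 rating model: (weak, strong) means per category plus noise SDs."""

    means: Mapping[str, tuple] = field(default_factory=lambda: {
        "intensity": (3.5, 7.5), "painful": (1.0, 4.5), "unpleasant": (1.5, 5.0)})
    participant_sd: float = 0.8
    trial_sd: float = 1.0


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to generate a synthetic cohort.

    The SCR cell means/SDs default to the calibration targets of the study
    population this generator emulates (event-related SCR ≈1.0 μS for weak
    stimuli in the high-reactivity group vs ≈0.5 μS in controls, tonic
    levels near 5–6 μS).
    """

    n_asd: int = 23
    n_td: int = 19
    seed: int = 0

    # event-related SCR amplitude calibration, μS, per (group, intensity)
    scr_amp_mean: Mapping[tuple, float] = field(default_factory=lambda: {
        ("ASD", WEAK): 1.025, ("TD", WEAK): 0.489,
        ("ASD", STRONG): 2.165, ("TD", STRONG): 1.332})
    scr_amp_sd: Mapping[tuple, float] = field(default_factory=lambda: {
        ("ASD", WEAK): 0.559, ("TD", WEAK): 0.336,
        ("ASD", STRONG): 1.040, ("TD", STRONG): 0.581})
    scr_trial_sd: float = 0.15       # trial-to-trial amplitude noise, μS
    scr_trait_corr: float = 0.6      # corr(latent trait, participant amplitude)
    scr_weak_strong_corr: float = 0.5  # within-participant weak/strong corr

    tonic_level_mean: Mapping[str, float] = field(default_factory=lambda: {
        "ASD": 5.9, "TD": 5.0})
    tonic_level_sd: float = 2.4

    # trace model
    sampling_rate: float = 20.0
    trace_noise_sd: float = 0.02
    noise_smoothing_s: float = 0.5
    drift_uS_per_s: float = 0.0
    tonic_wander_sd: float = 0.3       # slow tonic SCL fluctuation, μS
    tonic_wander_smoothing_s: float = 30.0
    latency_jitter_sd: float = 1.5
    kernel: BatemanKernel = field(default_factory=BatemanKernel)

    # electrical stimulation currents, μA: (mean, sd, low, high) per cell
    current_params: Mapping[tuple, tuple] = field(default_factory=lambda: {
        ("ASD", WEAK): (400.0, 133.0, 200.0, 500.0),
        ("TD", WEAK): (376.0, 90.0, 200.0, 500.0),
        ("ASD", STRONG): (1209.0, 537.0, 1000.0, 2000.0),
        ("TD", STRONG): (1352.0, 288.0, 1000.0, 2000.0)})

    # sensation / pain thresholds (μA): identical across groups by default
    sensation_threshold_mean: Mapping[str, float] = field(default_factory=lambda: {
        "ASD": 8.262, "TD": 8.375})
    sensation_threshold_sd: Mapping[str, float] = field(default_factory=lambda: {
        "ASD": 1.563, "TD": 1.505})
    pain_threshold_mean: Mapping[str, float] = field(default_factory=lambda: {
        "ASD": 57.235, "TD": 47.814})
    pain_threshold_sd: Mapping[str, float] = field(default_factory=lambda: {
        "ASD": 41.927, "TD": 22.422})

    # questionnaire model
    trait_questionnaire_loading: float = 0.7
    questionnaires: Mapping[str, SubscaleSpec] = field(default_factory=_default_questionnaires)

    # ratings
    ratings: RatingSpec = field(default_factory=RatingSpec)

    # two-point discrimination: per-site (mean, sd) of the threshold θ in mm
    tpd_theta: Mapping[str, tuple] = field(default_factory=lambda: {
        "palm": (5.0, 2.3), "forearm": (25.6, 9.0), "neck": (36.8, 13.0)})
    tpd_spread_ratio: float = 0.45   # observer σ = ratio · θ

    # touch detection: per-site (mean, sd) of θ in grams
    tdt_theta: Mapping[str, tuple] = field(default_factory=lambda: {
        "palm": (0.07, 0.06), "forearm": (0.27, 0.23), "neck": (0.22, 0.18)})
    tdt_spread_ratio: float = 0.6

    # touch comparison observer: P(stronger) = F(b · (force − pse))
    tct_pse_mean: float = 1.4
    tct_pse_sd: float = 0.15
    tct_slope_mean: float = 2.0      # 1/grams
    tct_slope_sd: float = 0.5

    # electrical stimulation session timing (s)
    est_first_onset_s: float = 10.0
    est_stimulus_s: float = 1.0
    est_inter_stimulus_s: float = 44.0
    est_trials_per_intensity: int = 3

    def validate(self) -> None:
        if self.n_asd < 1:
            raise ValueError("n_asd must be >= 1")
        if self.n_td < 1:
            raise ValueError("n_td must be >= 1")
        for cell, m in self.scr_amp_mean.items():
            if m < 0:
                raise ValueError(f"scr_amp_mean{cell} must be >= 0")
        for cell, s in self.scr_amp_sd.items():
            if s < 0:
                raise ValueError(f"scr_amp_sd{cell} must be >= 0")
        for name, val in (("scr_trial_sd", self.scr_trial_sd),
                          ("tonic_level_sd", self.tonic_level_sd),
                          ("trace_noise_sd", self.trace_noise_sd),
                          ("latency_jitter_sd", self.latency_jitter_sd)):
            if val < 0:
                raise ValueError(f"{name} must be >= 0")
        if not -1.0 <= self.trait_questionnaire_loading <= 1.0:
            raise ValueError("trait_questionnaire_loading must be within [-1, 1]")
        if not 0.0 <= self.scr_trait_corr <= 1.0:
            raise ValueError("scr_trait_corr must be within [0, 1]")
        if not self.scr_trait_corr ** 2 <= self.scr_weak_strong_corr <= 1.0:
            raise ValueError(
                "scr_weak_strong_corr must be within [scr_trait_corr**2, 1]")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")


def expected_amp_questionnaire_correlation(spec: CohortSpec, subscale: str) -> float:
    """Closed-form within-group correlation between participant mean SCR
    amplitude and a questionnaire subscore.

    Both are linear-Gaussian functions of the shared latent trait z:
    amplitude has corr ρ with z and the subscore has corr = loading with z
    (independent noises), so corr(amp, score) = ρ · loading · sign.
    Truncation at instrument floors/ceilings and amplitude clipping at 0
    attenuate this slightly in samples.
    """
    sign = spec.questionnaires[subscale].loading_sign
    return spec.scr_trait_corr * spec.trait_questionnaire_loading * sign


# --------------------------------------------------------------------------
# cohort generation

@dataclass(frozen=True)
class Cohort:
    spec: CohortSpec
    participants: pd.DataFrame
    traits: pd.DataFrame

    def trait_row(self, participant_id: str) -> pd.Series:
        cached = self.__dict__.get("_traits_indexed")
        if cached is None:
            cached = self.traits.set_index("participant_id")
            object.__setattr__(self, "_traits_indexed", cached)
        return cached.loc[participant_id]

    def two_point_observer(self, participant_id: str, site: str) -> ObserverSpec:
        theta = float(self.trait_row(participant_id)[f"tpd_theta_{site}"])
        return ObserverSpec(theta, self.spec.tpd_spread_ratio * theta)

    def detection_observer(self, participant_id: str, site: str) -> ObserverSpec:
        theta = float(self.trait_row(participant_id)[f"tdt_theta_{site}"])
        return ObserverSpec(theta, self.spec.tdt_spread_ratio * theta)


def _lognormal_from_moments(mean: float, sd: float, size: int,
                            rng: np.random.Generator) -> np.ndarray:
    """Lognormal draws with the given arithmetic mean and SD."""
    var = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - var / 2.0
    return rng.lognormal(mu, np.sqrt(var), size)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate participants (with questionnaire subscores) and latent traits.

    Per participant the latent reactivity z drives (a) the participant-level
    mean SCR amplitude for each intensity, through correlation
    ``scr_trait_corr``, and (b) every questionnaire subscore, through
    ``trait_questionnaire_loading`` (sign per subscale).  Weak and strong
    amplitudes additionally share a common component so that their
    within-participant correlation equals ``scr_weak_strong_corr``.
    """
    spec.validate()
    rng = substream(spec.seed, "cohort")
    n = spec.n_asd + spec.n_td
    ids = [f"ASD{i + 1:02d}" for i in range(spec.n_asd)] + \
          [f"TD{i + 1:02d}" for i in range(spec.n_td)]
    groups = np.array(["ASD"] * spec.n_asd + ["TD"] * spec.n_td)

    z = rng.normal(size=n)  # latent autonomic reactivity
    rho = spec.scr_trait_corr
    c = spec.scr_weak_strong_corr
    shared = rng.normal(size=n)
    e = {}
    for intensity in INTENSITIES:
        indep = rng.normal(size=n)
        e[intensity] = rho * z + np.sqrt(c - rho ** 2) * shared + np.sqrt(1.0 - c) * indep

    amp = {}
    for intensity in INTENSITIES:
        mu = np.array([spec.scr_amp_mean[(g, intensity)] for g in groups])
        sd = np.array([spec.scr_amp_sd[(g, intensity)] for g in groups])
        amp[intensity] = np.clip(mu + sd * e[intensity], 0.0, None)

    tonic = np.clip(
        np.array([spec.tonic_level_mean[g] for g in groups])
        + spec.tonic_level_sd * rng.normal(size=n), 0.5, None)

    currents = {}
    for intensity in INTENSITIES:
        m, s, lo, hi = zip(*(spec.current_params[(g, intensity)] for g in groups))
        currents[intensity] = np.clip(
            np.array(m) + np.array(s) * rng.normal(size=n), np.array(lo), np.array(hi))

    sens = np.clip(np.array([spec.sensation_threshold_mean[g] for g in groups])
                   + np.array([spec.sensation_threshold_sd[g] for g in groups])
                   * rng.normal(size=n), 0.5, None)
    pain_m = np.array([spec.pain_threshold_mean[g] for g in groups])
    pain_s = np.array([spec.pain_threshold_sd[g] for g in groups])
    pain = np.array([_lognormal_from_moments(m, s, 1, rng)[0]
                     for m, s in zip(pain_m, pain_s)])

    participants = pd.DataFrame({
        "participant_id": ids,
        "group": groups,
        "age": np.round(np.clip(rng.normal(40.5, 8.0, n), 25.0, 60.0), 1),
        "sex": rng.choice(["F", "M"], size=n),
    })
    lam = spec.trait_questionnaire_loading
    for name, sub in spec.questionnaires.items():
        eps = rng.normal(size=n)
        score = np.array([sub.mean(g) for g in groups]) + \
            np.array([sub.sd(g) for g in groups]) * \
            (sub.loading_sign * lam * z + np.sqrt(max(0.0, 1.0 - lam ** 2)) * eps)
        participants[name] = np.round(np.clip(score, sub.minimum, sub.maximum), 1)

    traits = pd.DataFrame({
        "participant_id": ids,
        "group": groups,
        "autonomic_reactivity": z,
        "amp_weak": amp[WEAK],
        "amp_strong": amp[STRONG],
        "tonic_level": tonic,
        "current_weak": currents[WEAK],
        "current_strong": currents[STRONG],
        "sensation_threshold": sens,
        "pain_threshold": pain,
        "tct_pse": np.clip(rng.normal(spec.tct_pse_mean, spec.tct_pse_sd, n), 0.45, 5.9),
        "tct_slope_b": np.clip(rng.normal(spec.tct_slope_mean, spec.tct_slope_sd, n),
                               0.2, None),
        "rating_offset": rng.normal(0.0, spec.ratings.participant_sd, n),
    })
    for site in BODY_SITES:
        m, s = spec.tpd_theta[site]
        traits[f"tpd_theta_{site}"] = _lognormal_from_moments(m, s, n, rng)
        m, s = spec.tdt_theta[site]
        traits[f"tdt_theta_{site}"] = _lognormal_from_moments(m, s, n, rng)
    return Cohort(spec=spec, participants=participants, traits=traits)


# --------------------------------------------------------------------------
# trace simulation

def simulate_sc_trace(
    events: Sequence[StimulusEvent],
    amplitudes: Sequence[float],
    tonic_level: float,
    *,
    sampling_rate: float = 20.0,
    duration_s: float | None = None,
    kernel: BatemanKernel | None = None,
    noise_sd: float = 0.02,
    noise_smoothing_s: float = 0.5,
    drift_uS_per_s: float = 0.0,
    tonic_wander_sd: float = 0.0,
    tonic_wander_smoothing_s: float = 30.0,
    latency_jitter_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> SkinConductanceTrace:
    """Simulate a skin-conductance trace with one phasic response per event.

    trace(t) = tonic + drift·t + slow wander + Σᵢ Aᵢ · kernel(t − onsetᵢ)
    + smoothed noise.  The kernel is unit-normalized, so with zero noise the
    post-offset peak of a lone event equals its amplitude (up to sample
    discretization).  ``tonic_wander_sd`` adds a slow (≈30 s scale) tonic
    skin-conductance-level fluctuation; ``latency_jitter_sd`` perturbs the
    kernel onset delay per event, giving trial-to-trial peak-latency
    variability around the kernel's own peak.

    Raises ``ValueError`` for negative amplitudes, overlapping events or a
    non-positive sampling rate.
    """
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be > 0")
    kernel = kernel or BatemanKernel()
    amplitudes = np.asarray(amplitudes, dtype=float)
    if len(events) != amplitudes.size:
        raise ValueError("one amplitude per event is required")
    if np.any(amplitudes < 0):
        raise ValueError("phasic amplitudes must be non-negative")
    for prev, nxt in zip(events, events[1:]):
        if nxt.onset < prev.offset:
            raise ValueError(
                f"events overlap: onset {nxt.onset} s before previous offset {prev.offset} s")
    if duration_s is None:
        duration_s = (events[-1].offset + 12.0) if events else 60.0
    rng = rng or np.random.default_rng()

    t = np.arange(0.0, duration_s, 1.0 / sampling_rate)
    trace = np.full_like(t, float(tonic_level)) + drift_uS_per_s * t
    for event, a in zip(events, amplitudes):
        if latency_jitter_sd > 0:
            delay = max(0.1, kernel.delay_s + rng.normal(0.0, latency_jitter_sd))
            k = dataclasses.replace(kernel, delay_s=delay)
        else:
            k = kernel
        trace += a * k(t - event.onset)
    if tonic_wander_sd > 0:
        # wander lives on a coarse grid (smoothing/5) and is interpolated:
        # same slow spectrum at a fraction of the filtering cost
        dt = tonic_wander_smoothing_s / 5.0
        tc = np.arange(-2 * tonic_wander_smoothing_s,
                       duration_s + 2 * tonic_wander_smoothing_s, dt)
        wander = gaussian_filter1d(rng.normal(size=tc.size), sigma=5.0, mode="reflect")
        wander /= max(wander.std(), 1e-12)
        trace += tonic_wander_sd * np.interp(t, tc, wander)
    if noise_sd > 0:
        noise = rng.normal(size=t.size)
        if noise_smoothing_s > 0:
            noise = gaussian_filter1d(noise, sigma=noise_smoothing_s * sampling_rate,
                                      mode="reflect")
            noise /= max(noise.std(), 1e-12)
        trace += noise_sd * noise
    return SkinConductanceTrace(time=t, conductance=trace)


# --------------------------------------------------------------------------
# ratings and sessions

def simulate_ratings(spec: RatingSpec, intensity: str, rng: np.random.Generator,
                     participant_offset: float = 0.0) -> dict:
    """Three 0–10 integer ratings (intensity / painful / unpleasant).

    Each rating is a normal draw around the configured mean for the given
    stimulus intensity (plus a participant-level offset), rounded and
    clipped to the 11-point scale.
    """
    if intensity not in INTENSITIES:
        raise ValueError(f"intensity must be one of {INTENSITIES}")
    idx = INTENSITIES.index(intensity)
    out = {}
    for category in RATING_CATEGORIES:
        mean = spec.means[category][idx] + participant_offset
        value = mean + (spec.trial_sd * rng.normal() if spec.trial_sd > 0 else 0.0)
        out[category] = int(np.clip(round(value), 0, 10))
    return out


@dataclass(frozen=True)
class SessionData:
    """Trial tables (and trace, for the electrical task) for one session."""

    participant_id: str
    task: str
    trials: pd.DataFrame
    trace: SkinConductanceTrace | None = None


def simulate_est_session(cohort: Cohort, participant_id: str) -> SessionData:
    """Electrical stimulation session: weak/strong alternating three times
    in a fixed order, ~44 s apart, with a continuous trace and per-trial
    0–10 ratings."""
    spec = cohort.spec
    row = cohort.trait_row(participant_id)
    rng = substream(spec.seed, "est", participant_id)

    order = [WEAK, STRONG] * spec.est_trials_per_intensity
    events, rows = [], []
    for i, intensity in enumerate(order):
        onset = spec.est_first_onset_s + i * spec.est_inter_stimulus_s
        events.append(StimulusEvent(onset=onset, offset=onset + spec.est_stimulus_s,
                                    intensity_label=intensity,
                                    current=float(row[f"current_{intensity}"])))
    amplitudes = np.clip(
        np.array([row[f"amp_{e.intensity_label}"] for e in events])
        + spec.scr_trial_sd * rng.normal(size=len(events)), 0.0, None)
    trace = simulate_sc_trace(
        events, amplitudes, float(row["tonic_level"]),
        sampling_rate=spec.sampling_rate, kernel=spec.kernel,
        noise_sd=spec.trace_noise_sd, noise_smoothing_s=spec.noise_smoothing_s,
        drift_uS_per_s=spec.drift_uS_per_s,
        tonic_wander_sd=spec.tonic_wander_sd,
        tonic_wander_smoothing_s=spec.tonic_wander_smoothing_s,
        latency_jitter_sd=spec.latency_jitter_sd, rng=rng)
    for i, event in enumerate(events):
        ratings = simulate_ratings(spec.ratings, event.intensity_label, rng,
                                   participant_offset=float(row["rating_offset"]))
        rows.append({
            "participant_id": participant_id, "trial_index": i,
            "onset_s": event.onset, "offset_s": event.offset,
            "intensity": event.intensity_label, "current_uA": event.current,
            "rating_intensity": ratings["intensity"],
            "rating_pain": ratings["painful"],
            "rating_unpleasant": ratings["unpleasant"],
        })
    return SessionData(participant_id, "est", pd.DataFrame(rows), trace=trace)


def comparison_p_stronger(trait_row: pd.Series, force_g: float) -> float:
    """Comparison observer: P("stronger") = F(b · (force − pse))."""
    return float(expit(float(trait_row["tct_slope_b"])
                       * (force_g - float(trait_row["tct_pse"]))))
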
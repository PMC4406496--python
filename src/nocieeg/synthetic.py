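"""Synthetic annotated sedation recordings for end-to-end pipeline testing.

The generator does not attempt biophysics; it reproduces the *statistical
structure* the measures read, with a two-state latent process (responsive ↔
unresponsive) driving state-dependent contrasts whose directions match what
frontal EEG/EMG shows under propofol–remifentanil sedation:

* β-band power drops in the unresponsive state;
* the α peak slides to lower frequency (lower in-band centroid mF_α);
* EMG-like broadband 60–145 Hz activity loses amplitude *and* bandwidth when
  unresponsive — concentrated, narrow-band VHF content is more predictable,
  so both P_VHF and the VHF AMIF first decay (FD) drop;
* θ-band content loses its narrow-band (predictable) component, so the AMIF
  mean m in low-frequency bands drops (more complexity) when unresponsive.

``effect_size`` scales all four contrasts together; 0 makes the two classes
statistically identical (null), the default 1 gives realistic overlapping
distributions, 2 gives near-separable classes.  Also included: 50/100 Hz
mains interference, Poisson-placed high-amplitude peak artifacts, and slowly
ramping effect-site concentration traces that are stable (ΔCe below the
segmentation thresholds) over every scheduled pre-event window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core_io import EEGRecord, EventAnnotation, logger
from .evaluation import TRIALS, LabeledDataset, TrialDefinition
from .features import build_feature_table
from .preprocessing import SegmentationConfig, preprocess_record

__all__ = ["GeneratorConfig", "SedationProfile", "generate_record",
           "generate_labeled_dataset"]


@dataclass
class GeneratorConfig:
    """Tunables of the synthetic recording generator.

    ``band_gains`` are baseline component amplitudes in μV (standard
    deviation of each band-limited component); ``emg_gain`` the baseline EMG
    amplitude; ``effect_size`` the standardized separation knob described in
    the module docstring.
    """

    n_events_per_class: int = 100
    n_gag_events_per_class: int = 0
    effect_size: float = 1.0
    fs: float = 300.0
    event_spacing: float = 100.0   # s between stimulation annotations
    lead_in: float = 120.0         # s of Ce ramp before the first segment
    band_gains: dict = field(default_factory=lambda: {
        "δ": 9.0, "θ": 5.0, "α": 4.0, "β": 2.2})
    emg_gain: float = 2.0
    alpha_peak_hz: float = 10.0
    artifact_rate: float = 0.1     # peaks per minute
    mains_amp: float = 1.0         # μV at 50 Hz (100 Hz at half amplitude)
    amplitude_jitter: float = 0.2  # lognormal sigma, per component per event
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.artifact_rate < 0:
            raise ValueError("artifact_rate must be >= 0")
        if self.event_spacing < 100.0 - 1e-9:
            # pre-event windows span [t-90, t-30); keep them inside one segment
            raise ValueError("event_spacing must be >= 100 s")


@dataclass
class SedationProfile:
    """Event schedule, latent states, and effect-site concentration ramps."""

    event_times: np.ndarray          # s
    states: np.ndarray               # 1 = responsive, 0 = unresponsive
    kinds: list[str]                 # "RSS" | "GAG" per event
    values: np.ndarray               # RSS score or GAG flag
    ce_prop: np.ndarray              # per-second, μg/ml
    ce_remi: np.ndarray              # per-second, ng/ml
    duration: float                  # s

    @classmethod
    def standard(cls, cfg: GeneratorConfig,
                 rng: np.random.Generator | None = None) -> "SedationProfile":
        """Shuffled equal-count schedule with plateau-stable Ce traces.

        Unresponsive events are annotated RSS 6 (GAG 0); responsive events
        draw RSS from 2–5 (GAG 1).  The concentrations ramp up over the
        lead-in and then plateau, so every pre-event window satisfies the
        ΔCe < 0.1 stability rule.
        """
        rng = np.random.default_rng(cfg.seed) if rng is None else rng
        n = cfg.n_events_per_class
        g = cfg.n_gag_events_per_class
        states = np.array([1] * (n + g) + [0] * (n + g))
        kinds = ["RSS"] * n + ["GAG"] * g + ["RSS"] * n + ["GAG"] * g
        order = rng.permutation(len(states))
        states = states[order]
        kinds = [kinds[i] for i in order]
        values = np.where(
            [k == "RSS" for k in kinds],
            np.where(states == 1, rng.integers(2, 6, size=len(states)), 6),
            np.where(states == 1, 1, 0),
        )
        event_times = cfg.lead_in + cfg.event_spacing * (
            1 + np.arange(len(states), dtype=float))
        duration = float(event_times[-1] + 10.0)
        n_sec = int(np.ceil(duration)) + 1
        t = np.arange(n_sec, dtype=float)
        ramp = np.clip(t / cfg.lead_in, 0, 1)
        ce_prop = 2.5 * ramp + 0.004 * rng.standard_normal(n_sec).cumsum() / np.sqrt(n_sec)
        ce_remi = 1.5 * ramp + 0.002 * rng.standard_normal(n_sec).cumsum() / np.sqrt(n_sec)
        return cls(event_times, states, kinds, values, ce_prop, ce_remi,
                   duration)


def _shaped_noise(rng: np.random.Generator, n: int, fs: float, f_lo: float,
                  f_hi: float, taper_hz: float = 1.0) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to [f_lo, f_hi].

    Spectral shaping in the frequency domain with raised-cosine band edges;
    the output is rescaled to exactly unit standard deviation.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    gain = np.zeros_like(f)
    gain[(f >= f_lo) & (f <= f_hi)] = 1.0
    lo_ramp = (f >= f_lo - taper_hz) & (f < f_lo)
    gain[lo_ramp] = 0.5 * (1 - np.cos(np.pi * (f[lo_ramp] - (f_lo - taper_hz))
                                      / taper_hz))
    hi_ramp = (f > f_hi) & (f <= f_hi + taper_hz)
    gain[hi_ramp] = 0.5 * (1 + np.cos(np.pi * (f[hi_ramp] - f_hi) / taper_hz))
    x = np.fft.irfft(spec * gain, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _state_params(cfg: GeneratorConfig, responsive: bool) -> dict:
    """State-conditional component parameters at the configured effect size."""
    s = cfg.effect_size
    sign = 1.0 if responsive else -1.0
    return {
        "sigma_delta": cfg.band_gains["δ"],
        "sigma_theta": cfg.band_gains["θ"],
        "theta_narrow_frac": float(np.clip(0.5 + sign * 0.25 * s, 0.0, 1.0)),
        "sigma_alpha": cfg.band_gains["α"],
        "alpha_peak": cfg.alpha_peak_hz + sign * 0.6 * s,
        "sigma_beta": max(cfg.band_gains["β"] * (1 + sign * 0.25 * s), 0.05),
        "sigma_emg": max(cfg.emg_gain * (1 + sign * 0.3 * s),
                         0.05 * cfg.emg_gain),
        "emg_narrow_frac": float(np.clip(0.5 - sign * 0.25 * s, 0.0, 1.0)),
    }


def _segment(rng: np.random.Generator, cfg: GeneratorConfig, n: int,
             t0: float, responsive: bool) -> np.ndarray:
    """One generated segment (the ``n`` samples preceding an event)."""
    fs = cfg.fs
    p = _state_params(cfg, responsive)
    jit = lambda: float(np.exp(cfg.amplitude_jitter * rng.standard_normal()))

    x = p["sigma_delta"] * jit() * _shaped_noise(rng, n, fs, 0.3, 4.0, 0.2)

    nf = p["theta_narrow_frac"]
    theta = (np.sqrt(nf) * _shaped_noise(rng, n, fs, 5.5, 6.5, 0.3)
             + np.sqrt(1 - nf) * _shaped_noise(rng, n, fs, 4.0, 8.0, 0.5))
    x += p["sigma_theta"] * jit() * theta

    fpk = p["alpha_peak"] + 0.25 * rng.standard_normal()
    x += p["sigma_alpha"] * jit() * _shaped_noise(rng, n, fs, fpk - 1.0,
                                                  fpk + 1.0, 0.5)

    x += p["sigma_beta"] * jit() * _shaped_noise(rng, n, fs, 12.0, 30.0)

    ef = p["emg_narrow_frac"]
    emg = (np.sqrt(ef) * _shaped_noise(rng, n, fs, 115.0, 135.0)
           + np.sqrt(1 - ef) * _shaped_noise(rng, n, fs, 60.0, 145.0))
    x += p["sigma_emg"] * jit() * emg

    if cfg.mains_amp > 0:
        tt = t0 + np.arange(n) / fs
        x += cfg.mains_amp * np.sin(2 * np.pi * 50.0 * tt)
        x += 0.5 * cfg.mains_amp * np.sin(2 * np.pi * 100.0 * tt)

    n_spikes = rng.poisson(cfg.artifact_rate * n / fs / 60.0)
    for _ in range(n_spikes):
        pos = rng.integers(0, n - 7)
        width = int(rng.integers(3, 8))
        amp = rng.choice([-1, 1]) * rng.uniform(100.0, 200.0)
        x[pos:pos + width] += amp * np.hanning(width)
    return x


def generate_record(cfg: GeneratorConfig,
                    profile: Optional[SedationProfile] = None) -> EEGRecord:
    """Generate a full annotated recording; bit-reproducible given the seed."""
    rng = np.random.default_rng(cfg.seed)
    if profile is None:
        profile = SedationProfile.standard(cfg, rng)
    fs = cfg.fs
    n_total = int(round(profile.duration * fs))
    samples = np.zeros(n_total)

    # lead-in (before the first segment): unresponsive-like background
    first_seg_start = int(round((profile.event_times[0] - cfg.event_spacing) * fs))
    if first_seg_start > 0:
        samples[:first_seg_start] = _segment(rng, cfg, first_seg_start, 0.0,
                                             responsive=False)
    for k, t_ev in enumerate(profile.event_times):
        i1 = int(round(t_ev * fs))
        i0 = int(round((t_ev - cfg.event_spacing) * fs))
        seg = _segment(rng, cfg, i1 - i0, i0 / fs,
                       responsive=bool(profile.states[k]))
        samples[i0:i1] = seg
    tail0 = int(round(profile.event_times[-1] * fs))
    if tail0 < n_total:
        samples[tail0:] = _segment(rng, cfg, n_total - tail0, tail0 / fs,
                                   responsive=False)

    events = [EventAnnotation(float(t), kind, int(val))
              for t, kind, val in zip(profile.event_times, profile.kinds,
                                      profile.values)]
    bis = None
    logger.info("generated synthetic record: %.0f s, %d events", profile.duration,
                len(events))
    return EEGRecord(samples=samples, fs=fs, events=events,
                     ce_prop=profile.ce_prop, ce_remi=profile.ce_remi,
                     bis=bis, subject_id=f"synthetic-{cfg.seed}")


def generate_labeled_dataset(cfg: GeneratorConfig,
                             trial: TrialDefinition | str = "trial2",
                             seg_cfg: SegmentationConfig = SegmentationConfig(),
                             entropy_specs=None) -> LabeledDataset:
    """Generate a record, run the full measurement pipeline, label per trial."""
    if cfg.n_events_per_class < 10:
        raise ValueError("need at least 10 events per class")
    if isinstance(trial, str):
        trial = TRIALS[trial]
    record = generate_record(cfg)
    windows = preprocess_record(record, seg_cfg)
    table = build_feature_table(windows, entropy_specs=entropy_specs)
    return LabeledDataset.from_feature_table(table, trial)
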
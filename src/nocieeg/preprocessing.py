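"""Resampling, FIR band filtering, pre-event segmentation, artifact handling.

Two analysis streams are derived from the native-rate recording:

* the *traditional* stream — band-limited to 0.1–45 Hz and resampled to
  128 Hz; δ, θ, α and β windows come from here;
* the *high-frequency* stream — band-limited to 0.1–145 Hz and resampled to
  300 Hz; HF (60–95 Hz), VHF (105–145 Hz) and TB (0.1–145 Hz) windows come
  from here.  The band edges deliberately exclude 50 Hz mains and the 100 Hz
  impedance self-test peak, so no explicit notch is applied.

Pre-event windows span the interval from 90 s to 30 s before each stimulation
annotation (the 30 s guard keeps the stimulation response itself out of the
window).  A window is kept only when the effect-site concentrations were
stable across it (ΔCe_remi < 0.1 ng/ml and ΔCe_prop < 0.1 μg/ml); otherwise
it is shortened from its start, one second at a time, until stability holds.
Windows shorter than 50 s are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional

import numpy as np
from scipy import signal as sps

from .core_io import BandDefinition, EEGRecord, EventAnnotation, canonical_bands, logger

__all__ = [
    "SegmentationConfig",
    "AnalysisWindow",
    "EventWindows",
    "resample",
    "design_fir_bandpass",
    "filter_band",
    "extract_window",
    "asef_suppress_peaks",
    "reject_jumps",
    "preprocess_record",
]


@dataclass(frozen=True)
class SegmentationConfig:
    """Pre-event segmentation tunables (seconds / concentration units)."""

    pre_start: float = 90.0   # window starts this many s before the event
    pre_end: float = 30.0     # ... and ends this many s before it
    min_len: float = 50.0     # shorter windows are discarded
    dce_remi_max: float = 0.1  # ng/ml
    dce_prop_max: float = 0.1  # μg/ml

    def __post_init__(self) -> None:
        if not (self.pre_start > self.pre_end >= 0):
            raise ValueError("need pre_start > pre_end >= 0")
        if self.min_len > self.pre_start - self.pre_end:
            raise ValueError("min_len cannot exceed the nominal window length")


@dataclass
class AnalysisWindow:
    """One artifact-cleaned, band-filtered pre-event segment."""

    samples: np.ndarray
    fs: float
    band: Optional[BandDefinition]
    event: EventAnnotation
    n_rejected: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("window samples must be finite")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs


@dataclass
class EventWindows:
    """All band windows plus the two cleaned stream windows for one event."""

    event: EventAnnotation
    stream128: AnalysisWindow
    stream300: AnalysisWindow
    bands: dict[str, AnalysisWindow] = field(default_factory=dict)


def resample(samples: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Rational-rate polyphase resampling with built-in anti-alias filtering."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("cannot resample an empty signal")
    if fs_in <= 0 or fs_out <= 0:
        raise ValueError("sampling rates must be positive")
    if fs_in == fs_out:
        return samples.copy()
    frac = Fraction(fs_out / fs_in).limit_denominator(10000)
    return sps.resample_poly(samples, frac.numerator, frac.denominator)


def design_fir_bandpass(band: BandDefinition, order: int = 50,
                        fs: float | None = None) -> np.ndarray:
    """Windowed-sinc (Hamming) linear-phase FIR band-pass, ``order + 1`` taps.

    Coefficients are scaled to unity gain at the passband center.  The 50th
    order keeps stop-band attenuation/ripple under 5% for the canonical bands
    at their target rates.
    """
    fs = band.fs_target if fs is None else fs
    if band.f_hi >= fs / 2:
        raise ValueError(f"band {band.name}: f_hi={band.f_hi} >= Nyquist {fs / 2}")
    return sps.firwin(order + 1, [band.f_lo, band.f_hi], pass_zero=False,
                      window="hamming", fs=fs, scale=True)


def filter_band(samples: np.ndarray, band: BandDefinition, order: int = 50,
                fs: float | None = None) -> np.ndarray:
    """Zero-phase (forward–backward) band-pass filtering.

    Zero-phase application keeps window-level measures free of group-delay
    shifts; the effective attenuation is the squared single-pass response.
    """
    samples = np.asarray(samples, dtype=float)
    taps = design_fir_bandpass(band, order=order, fs=fs)
    if len(samples) < 3 * len(taps):
        raise ValueError(
            f"input of {len(samples)} samples is shorter than 3x filter length "
            f"({3 * len(taps)})"
        )
    return sps.filtfilt(taps, [1.0], samples)


def extract_window(record: EEGRecord, event: EventAnnotation,
                   cfg: SegmentationConfig = SegmentationConfig()
                   ) -> Optional[AnalysisWindow]:
    """Cut the pre-event window, applying drug-stability truncation.

    Returns an :class:`AnalysisWindow` at the record's native rate (``band``
    is ``None`` at this stage), or ``None`` when the event is too early, the
    concentrations never stabilize, or the stable span is shorter than
    ``cfg.min_len``.
    """
    if event.time < cfg.pre_start:
        logger.info("event at t=%.1f s skipped: earlier than %.0f s from record "
                    "start", event.time, cfg.pre_start)
        return None
    t1 = event.time - cfg.pre_end
    t0 = event.time - cfg.pre_start

    def stable(t_start: float) -> bool:
        ok = True
        for name, thr in (("ce_remi", cfg.dce_remi_max), ("ce_prop", cfg.dce_prop_max)):
            if getattr(record, name) is None:
                continue
            dce = abs(record.ce_at(name, int(t1) - 1) - record.ce_at(name, int(t_start)))
            ok = ok and dce < thr
        return ok

    # shorten from the start (keeping samples closest to the event) until the
    # concentration deltas are inside the stability thresholds
    while t0 < t1 and not stable(t0):
        t0 += 1.0
    if t1 - t0 < cfg.min_len:
        logger.info("event at t=%.1f s discarded: stable span %.0f s < min_len "
                    "%.0f s", event.time, t1 - t0, cfg.min_len)
        return None
    i0 = int(round(t0 * record.fs))
    i1 = int(round(t1 * record.fs))
    return AnalysisWindow(record.samples[i0:i1], record.fs, None, event)


def asef_suppress_peaks(samples: np.ndarray, fs: float | None = None,
                        k: float = 5.0) -> np.ndarray:
    """Analytic-signal-envelope peak suppression.

    The instantaneous envelope is the magnitude of the analytic (Hilbert)
    signal.  Samples whose envelope exceeds ``k`` times the median envelope
    are rescaled so their local envelope equals that threshold; high-amplitude
    peak artifacts are flattened while the local oscillatory structure (and
    hence the frequency content) is preserved.  Peak-free input is returned
    unchanged.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0 or not np.any(samples):
        return samples.copy()
    env = np.abs(sps.hilbert(samples))
    thr = k * np.median(env)
    out = samples.copy()
    mask = env > thr
    if np.any(mask) and thr > 0:
        out[mask] = samples[mask] * (thr / env[mask])
    elif np.any(mask):
        out[mask] = 0.0
    return out


def reject_jumps(samples: np.ndarray, factor: float = 10.0,
                 min_history: int = 50) -> tuple[np.ndarray, int]:
    """Truncate at the first abnormal adjacent-sample jump.

    Scans forward maintaining the running mean of absolute first differences;
    at the first difference exceeding ``factor`` times that running mean the
    window is truncated just before the jump, and the jump plus everything
    after it is dropped.  The test starts only once the running mean rests on
    at least ``min_history`` differences, so a cold-start mean estimated from
    a handful of samples cannot trigger spurious truncation.  Returns
    ``(kept_samples, n_rejected)``.
    """
    samples = np.asarray(samples, dtype=float)
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    d = np.abs(np.diff(samples))
    # running mean over *previous* diffs: m[j] = mean(d[0..j-1]), defined j>=1
    cm = np.cumsum(d)
    j = np.arange(1, len(d))
    viol = d[1:] > factor * (cm[:-1] / j)
    start = max(min_history, 1) - 1
    viol[:start] = False
    if not np.any(viol):
        return samples.copy(), 0
    first = int(np.argmax(viol)) + 1  # diff index of first violation
    keep = first + 1                  # keep samples 0 .. first (inclusive)
    return samples[:keep].copy(), len(samples) - keep


def _clean_stream(raw: np.ndarray, fs_native: float, fs_target: float,
                  limit: BandDefinition, order: int, asef_k: float,
                  jump_factor: float) -> tuple[np.ndarray, int]:
    """Resample a raw window to a stream rate, band-limit, and de-artifact."""
    x = resample(raw, fs_native, fs_target)
    x = filter_band(x, limit, order=order, fs=fs_target)
    x = asef_suppress_peaks(x, fs_target, k=asef_k)
    x, n_rej = reject_jumps(x, factor=jump_factor)
    return x, n_rej


#: stream band limits (anti-alias / analysis limits, not analysis bands)
_LIMIT_128 = BandDefinition("TB", 0.1, 45.0, 128.0)
_LIMIT_300 = BandDefinition("TB", 0.1, 145.0, 300.0)


def preprocess_record(record: EEGRecord,
                      cfg: SegmentationConfig = SegmentationConfig(),
                      fir_order: int = 50, asef_k: float = 5.0,
                      jump_factor: float = 10.0) -> list[EventWindows]:
    """Run segmentation + artifact handling + band filtering for every event.

    Returns one :class:`EventWindows` per surviving event, holding the two
    cleaned stream windows (128 Hz traditional, 300 Hz high-frequency) and the
    seven band-filtered windows.
    """
    out: list[EventWindows] = []
    for event in record.events:
        win = extract_window(record, event, cfg)
        if win is None:
            continue
        streams: dict[float, AnalysisWindow] = {}
        ok = True
        for fs_target, limit in ((128.0, _LIMIT_128), (300.0, _LIMIT_300)):
            x, n_rej = _clean_stream(win.samples, win.fs, fs_target, limit,
                                     fir_order, asef_k, jump_factor)
            if len(x) / fs_target < cfg.min_len:
                logger.info("event t=%.1f s: %g Hz stream shrank below min_len "
                            "after jump rejection (%d samples rejected)",
                            event.time, fs_target, n_rej)
                ok = False
                break
            streams[fs_target] = AnalysisWindow(x, fs_target, None, event,
                                                n_rejected=n_rej)
        if not ok:
            continue
        ew = EventWindows(event=event, stream128=streams[128.0],
                          stream300=streams[300.0])
        for band in canonical_bands():
            stream = streams[band.fs_target]
            if band.name == "TB":
                # the 300 Hz stream is already TB-filtered
                bx = stream.samples
            else:
                bx = filter_band(stream.samples, band, order=fir_order)
            ew.bands[band.name] = AnalysisWindow(bx, band.fs_target, band, event,
                                                 n_rejected=stream.n_rejected)
            logger.debug("event t=%.1f s band %s: %d samples, %d rejected",
                         event.time, band.name, len(bx), stream.n_rejected)
        out.append(ew)
    return out
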
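"""Scalar measures from AMIF / autocorrelation curves, and the feature table.

Four scalars summarize each (normalized) curve:

* ``m``    — mean over lags τ ≥ 1;
* ``maxL`` — value at the first relative maximum (τ ≥ 2);
* ``min``  — absolute minimum over τ ≥ 1 (signed, so autocorrelation minima
  near −1 are preserved);
* ``FD``   — first decay, value(0) − value(1) (= 1 − value(1) on a
  normalized curve).

Higher m, maxL and min mean a more regular (less complex) signal; higher FD
means faster information loss, i.e. more complexity.  Measure names follow
the field convention ``FD(Re_05)_VHF`` (first decay of the Rényi q=0.5 AMIF
in the VHF band), ``m(Sh)_θ``, ``min(Ac)_δ`` (autocorrelation), plus the
spectral names ``P_β``, ``mF_α``, ``SEF90_HF`` and ``std_β``.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .amif import (AMIFCurve, DEFAULT_Q_VALUES, EntropySpec, amif_curves,
                   normalize, quantize)
from .core_io import canonical_bands, logger
from .preprocessing import EventWindows
from .spectral import (autocorrelation, band_power, spectral_edge,
                       weighted_mean_frequency, welch_psd)

__all__ = [
    "curve_mean",
    "first_relative_max",
    "absolute_min",
    "first_decay",
    "default_entropy_specs",
    "measure_name",
    "compute_measures",
    "build_feature_table",
]


def _values(curve: AMIFCurve | np.ndarray) -> np.ndarray:
    return curve.values if isinstance(curve, AMIFCurve) else np.asarray(
        curve, dtype=float)


def curve_mean(curve: AMIFCurve | np.ndarray) -> float:
    """Mean of the curve over lags τ = 1..τ_max (τ=0 is the normalization
    point and carries no predictability information)."""
    v = _values(curve)
    return float(np.mean(v[1:]))


def first_relative_max(curve: AMIFCurve | np.ndarray) -> float:
    """Value at the first relative maximum, or NaN if the curve is monotone
    non-increasing.

    The first lag τ ≥ 2 with value(τ−1) < value(τ) ≥ value(τ+1): a strict
    rise followed by a non-rise; a plateau yields its first point.
    """
    v = _values(curve)
    if len(v) < 4 or np.any(~np.isfinite(v)):
        return float("nan")
    for tau in range(2, len(v) - 1):
        if v[tau - 1] < v[tau] >= v[tau + 1]:
            return float(v[tau])
    return float("nan")


def absolute_min(curve: AMIFCurve | np.ndarray) -> float:
    """Signed minimum over lags τ = 1..τ_max."""
    v = _values(curve)
    return float(np.min(v[1:]))


def first_decay(curve: AMIFCurve | np.ndarray) -> float:
    """First decay FD = value(0) − value(1); 1 − value(1) when normalized."""
    v = _values(curve)
    return float(v[0] - v[1])


_CURVE_MEASURES = {
    "m": curve_mean,
    "maxL": first_relative_max,
    "min": absolute_min,
    "FD": first_decay,
}


def default_entropy_specs(q_values: Sequence[float] = DEFAULT_Q_VALUES
                          ) -> list[EntropySpec]:
    """Shannon plus the Rényi q grid."""
    return [EntropySpec("Shannon")] + [EntropySpec("Renyi", q=float(q))
                                       for q in q_values]


def measure_name(measure: str, curve_label: str | None, band: str) -> str:
    """Compose a Glossary-style measure name, e.g. ``FD(Re_05)_VHF``."""
    if curve_label is None:
        return f"{measure}_{band}"
    return f"{measure}({curve_label})_{band}"


def compute_measures(ew: EventWindows,
                     entropy_specs: Sequence[EntropySpec] | None = None,
                     tau_max_128: int = 128, tau_max_300: int = 300
                     ) -> dict[str, float]:
    """All scalar measures for one event's windows.

    Spectral measures come from the two stream PSDs (traditional bands from
    the 128 Hz stream, HF/VHF/TB from the 300 Hz stream); std, Ac and AMIF
    measures come from each band-filtered window.
    """
    if entropy_specs is None:
        entropy_specs = default_entropy_specs()
    out: dict[str, float] = {}
    psd128 = welch_psd(ew.stream128)
    psd300 = welch_psd(ew.stream300)
    psd_for = {"δ": psd128, "θ": psd128, "α": psd128, "β": psd128,
               "HF": psd300, "VHF": psd300, "TB": psd300}

    for band in canonical_bands():
        psd = psd_for[band.name]
        if band.name != "TB":
            out[measure_name("P", None, band.name)] = band_power(psd, band)
        out[measure_name("mF", None, band.name)] = weighted_mean_frequency(psd, band)
        for frac, tag in ((0.50, "SEF50"), (0.75, "SEF75"), (0.90, "SEF90")):
            out[measure_name(tag, None, band.name)] = spectral_edge(psd, band, frac)

        win = ew.bands[band.name]
        out[measure_name("std", None, band.name)] = float(np.std(win.samples))

        tau_max = tau_max_300 if band.fs_target == 300.0 else tau_max_128
        ac = autocorrelation(win, tau_max)
        for mname, fn in _CURVE_MEASURES.items():
            out[measure_name(mname, "Ac", band.name)] = fn(ac)

        sym = quantize(win.samples)
        curves = amif_curves(sym, entropy_specs, tau_max)
        for spec, curve in curves.items():
            ncurve = normalize(curve)
            for mname, fn in _CURVE_MEASURES.items():
                out[measure_name(mname, spec.label, band.name)] = fn(ncurve)
    return out


def build_feature_table(event_windows: Iterable[EventWindows],
                        entropy_specs: Sequence[EntropySpec] | None = None,
                        tau_max_128: int = 128, tau_max_300: int = 300
                        ) -> pd.DataFrame:
    """Wide measure table: one row per event window, plus event metadata
    columns ``event_time``, ``event_kind``, ``event_value``."""
    rows = []
    for ew in event_windows:
        try:
            row = compute_measures(ew, entropy_specs, tau_max_128, tau_max_300)
        except Exception as exc:
            raise RuntimeError(
                f"feature extraction failed for event at t={ew.event.time} s"
            ) from exc
        row["event_time"] = ew.event.time
        row["event_kind"] = ew.event.kind
        row["event_value"] = ew.event.value
        rows.append(row)
        logger.debug("features extracted for event t=%.1f s", ew.event.time)
    return pd.DataFrame(rows)
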
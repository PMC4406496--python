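"""Domain types, canonical frequency bands, and record readers/writers.

A sedation recording couples a single-channel frontal EEG trace (μV, native
sampling rate ≥ 300 Hz) with per-second annotation streams: Ramsay sedation
scores (RSS 2–6) observed after nail-bed compression, gag-reflex flags (GAG
0/1) at endoscopy-tube insertion, predicted effect-site concentrations of
propofol (Ce_prop, μg/ml) and remifentanil (Ce_remi, ng/ml), and an optional
BIS trace.  Everything downstream (segmentation, band filtering, spectral and
auto-mutual-information measures) consumes the :class:`EEGRecord` container
defined here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("nocieeg")

__all__ = [
    "EventAnnotation",
    "EEGRecord",
    "BandDefinition",
    "canonical_bands",
    "band_by_name",
    "read_record",
    "write_record",
    "load_config",
    "RecordFormatError",
]

RSS_VALUES = (2, 3, 4, 5, 6)
GAG_VALUES = (0, 1)

#: ASCII fallbacks accepted anywhere a band name is parsed.
BAND_ALIASES = {
    "delta": "δ",
    "theta": "θ",
    "alpha": "α",
    "beta": "β",
    "hf": "HF",
    "vhf": "VHF",
    "tb": "TB",
}


class RecordFormatError(ValueError):
    """Raised when an input file cannot be parsed into a valid record."""


@dataclass(frozen=True)
class EventAnnotation:
    """A stimulation event: RSS score after nail-bed compression, or GAG flag.

    ``time`` is in seconds from record start.  RSS values are restricted to
    the annotated range 2–6 (6 = no response, 5 = sluggish response); GAG is
    0/1 (1 = gag reflex present, a nociceptive response).
    """

    time: float
    kind: str
    value: int

    def __post_init__(self) -> None:
        if self.kind not in ("RSS", "GAG"):
            raise ValueError(f"event kind must be 'RSS' or 'GAG', got {self.kind!r}")
        if self.kind == "RSS" and self.value not in RSS_VALUES:
            raise ValueError(f"RSS value must be in {RSS_VALUES}, got {self.value}")
        if self.kind == "GAG" and self.value not in GAG_VALUES:
            raise ValueError(f"GAG value must be 0 or 1, got {self.value}")
        if self.time < 0:
            raise ValueError("event time must be >= 0")


@dataclass
class EEGRecord:
    """One session: EEG samples plus 1 Hz annotation/concentration streams."""

    samples: np.ndarray
    fs: float
    events: list[EventAnnotation] = field(default_factory=list)
    ce_prop: Optional[np.ndarray] = None
    ce_remi: Optional[np.ndarray] = None
    bis: Optional[np.ndarray] = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be > 0, got {self.fs}")
        dur = self.duration
        for ev in self.events:
            if ev.time > dur:
                raise ValueError(
                    f"event at t={ev.time} s lies outside record duration {dur:.1f} s"
                )
        for name in ("ce_prop", "ce_remi", "bis"):
            trace = getattr(self, name)
            if trace is not None:
                setattr(self, name, np.asarray(trace, dtype=float))

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return len(self.samples) / self.fs

    def ce_at(self, name: str, second: int) -> float:
        """Concentration trace value at an integer second (clamped to range)."""
        trace = getattr(self, name)
        if trace is None:
            raise ValueError(f"record has no {name} trace")
        return float(trace[min(max(second, 0), len(trace) - 1)])


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band and the sampling rate of the stream it is analyzed on.

    Traditional EEG bands (δ θ α β) live on the 128 Hz stream; the
    EMG-dominated high-frequency bands (HF 60–95 Hz, VHF 105–145 Hz) and the
    total band TB (0.1–145 Hz) live on the 300 Hz stream.
    """

    name: str
    f_lo: float
    f_hi: float
    fs_target: float

    def __post_init__(self) -> None:
        if not (0 <= self.f_lo < self.f_hi <= self.fs_target / 2):
            raise ValueError(
                f"invalid band {self.name}: need 0 <= {self.f_lo} < {self.f_hi} "
                f"<= {self.fs_target / 2}"
            )


_CANONICAL_BANDS = (
    BandDefinition("δ", 0.1, 4.0, 128.0),
    BandDefinition("θ", 4.0, 8.0, 128.0),
    BandDefinition("α", 8.0, 12.0, 128.0),
    BandDefinition("β", 12.0, 30.0, 128.0),
    BandDefinition("HF", 60.0, 95.0, 300.0),
    BandDefinition("VHF", 105.0, 145.0, 300.0),
    BandDefinition("TB", 0.1, 145.0, 300.0),
)


def canonical_bands() -> tuple[BandDefinition, ...]:
    """The seven canonical bands, in fixed order (δ, θ, α, β, HF, VHF, TB)."""
    return _CANONICAL_BANDS


def band_by_name(name: str) -> BandDefinition:
    """Look a canonical band up by name (Greek or ASCII alias)."""
    name = BAND_ALIASES.get(name.lower(), name)
    for band in _CANONICAL_BANDS:
        if band.name == name:
            return band
    raise KeyError(f"unknown band {name!r}")


# ---------------------------------------------------------------------------
# CSV dialect
#
# <base>_signal.csv : t_s, eeg_uV           (one row per sample)
# <base>_events.csv : t_s, kind, value      (one row per stimulation event)
# <base>_traces.csv : t_s, ce_prop, ce_remi, bis   (one row per second;
#                     bis column optional / may be empty)
# ---------------------------------------------------------------------------


def _base_path(path: Path) -> Path:
    s = str(path)
    for suffix in ("_signal.csv", "_events.csv", "_traces.csv"):
        if s.endswith(suffix):
            return Path(s[: -len(suffix)])
    return path


def write_record(record: EEGRecord, base: str | Path) -> Path:
    """Write a record in the CSV dialect; returns the base path.

    Floats are written with 17 significant digits, so a write/read round trip
    reproduces samples bit-exactly.
    """
    base = _base_path(Path(base))
    base.parent.mkdir(parents=True, exist_ok=True)
    t = np.arange(len(record.samples)) / record.fs
    sig = pd.DataFrame({"t_s": t, "eeg_uV": record.samples})
    sig.to_csv(base.parent / (base.name + "_signal.csv"), index=False,
               float_format="%.17g")
    ev = pd.DataFrame(
        {
            "t_s": [e.time for e in record.events],
            "kind": [e.kind for e in record.events],
            "value": [e.value for e in record.events],
        }
    )
    ev.to_csv(base.parent / (base.name + "_events.csv"), index=False,
              float_format="%.17g")
    n_sec = max(
        len(tr) for tr in (record.ce_prop, record.ce_remi, record.bis)
        if tr is not None
    ) if any(tr is not None for tr in (record.ce_prop, record.ce_remi, record.bis)) else 0
    if n_sec:
        def col(tr):
            if tr is None:
                return np.full(n_sec, np.nan)
            out = np.full(n_sec, np.nan)
            out[: len(tr)] = tr
            return out

        tr = pd.DataFrame(
            {
                "t_s": np.arange(n_sec, dtype=float),
                "ce_prop": col(record.ce_prop),
                "ce_remi": col(record.ce_remi),
                "bis": col(record.bis),
            }
        )
        tr.to_csv(base.parent / (base.name + "_traces.csv"), index=False,
                  float_format="%.17g")
    return base


def _read_csv_record(base: Path) -> EEGRecord:
    sig_path = base.parent / (base.name + "_signal.csv")
    if not sig_path.exists():
        raise FileNotFoundError(sig_path)
    sig = pd.read_csv(sig_path, float_precision="round_trip")
    for colname in ("t_s", "eeg_uV"):
        if colname not in sig.columns:
            raise RecordFormatError(f"{sig_path}: missing column {colname!r}")
    t = sig["t_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise RecordFormatError(f"{sig_path}: need at least 2 samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        bad = int(np.argmax(np.abs(dt - dt[0]) > 1e-6 * dt[0])) + 1
        raise RecordFormatError(f"{sig_path}: non-uniform sampling at row {bad}")
    fs = 1.0 / dt[0]
    samples = sig["eeg_uV"].to_numpy(dtype=float)

    events: list[EventAnnotation] = []
    ev_path = base.parent / (base.name + "_events.csv")
    if ev_path.exists():
        ev = pd.read_csv(ev_path)
        for i, row in ev.iterrows():
            try:
                events.append(
                    EventAnnotation(float(row["t_s"]), str(row["kind"]).strip(),
                                    int(row["value"]))
                )
            except (ValueError, KeyError) as exc:
                raise RecordFormatError(f"{ev_path}: row {i}: {exc}") from exc

    ce_prop = ce_remi = bis = None
    tr_path = base.parent / (base.name + "_traces.csv")
    if tr_path.exists():
        tr = pd.read_csv(tr_path, float_precision="round_trip")
        if "ce_prop" in tr and tr["ce_prop"].notna().any():
            ce_prop = tr["ce_prop"].to_numpy(dtype=float)
        if "ce_remi" in tr and tr["ce_remi"].notna().any():
            ce_remi = tr["ce_remi"].to_numpy(dtype=float)
        if "bis" in tr and tr["bis"].notna().any():
            bis = tr["bis"].to_numpy(dtype=float)

    return EEGRecord(samples=samples, fs=fs, events=events, ce_prop=ce_prop,
                     ce_remi=ce_remi, bis=bis, subject_id=base.name)


def _read_edf_record(path: Path) -> EEGRecord:
    # EDF reading goes through MNE; the first EEG-typed channel is used.
    # Sibling annotation CSVs (<stem>_events.csv / _traces.csv), if present,
    # supply the event and concentration streams.
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise RecordFormatError("EDF support requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    picks = mne.pick_types(raw.info, eeg=True)
    idx = int(picks[0]) if len(picks) else 0
    samples = raw.get_data(picks=[idx])[0] * 1e6  # MNE returns volts
    rec = EEGRecord(samples=samples, fs=float(raw.info["sfreq"]),
                    subject_id=path.stem)
    base = path.parent / path.stem
    ev_path = base.parent / (base.name + "_events.csv")
    tr_path = base.parent / (base.name + "_traces.csv")
    if ev_path.exists() or tr_path.exists():
        # borrow the CSV parsing for sidecar streams
        aux = _read_csv_shim(base, rec)
        return aux
    return rec


def _read_csv_shim(base: Path, rec: EEGRecord) -> EEGRecord:
    events: list[EventAnnotation] = []
    ev_path = base.parent / (base.name + "_events.csv")
    if ev_path.exists():
        ev = pd.read_csv(ev_path)
        for i, row in ev.iterrows():
            events.append(EventAnnotation(float(row["t_s"]), str(row["kind"]).strip(),
                                          int(row["value"])))
    ce_prop = ce_remi = bis = None
    tr_path = base.parent / (base.name + "_traces.csv")
    if tr_path.exists():
        tr = pd.read_csv(tr_path, float_precision="round_trip")
        if "ce_prop" in tr and tr["ce_prop"].notna().any():
            ce_prop = tr["ce_prop"].to_numpy(dtype=float)
        if "ce_remi" in tr and tr["ce_remi"].notna().any():
            ce_remi = tr["ce_remi"].to_numpy(dtype=float)
        if "bis" in tr and tr["bis"].notna().any():
            bis = tr["bis"].to_numpy(dtype=float)
    return EEGRecord(samples=rec.samples, fs=rec.fs, events=events,
                     ce_prop=ce_prop, ce_remi=ce_remi, bis=bis,
                     subject_id=rec.subject_id)


def read_record(path: str | Path, dialect: str = "csv") -> EEGRecord:
    """Read a record from disk.

    Parameters
    ----------
    path : str or Path
        For ``dialect='csv'``: the base path or any of the three dialect
        files (``<base>_signal.csv`` etc.).  For ``dialect='edf'``: the EDF
        file.
    dialect : {'csv', 'edf'}
    """
    path = Path(path)
    if dialect == "csv":
        return _read_csv_record(_base_path(path))
    if dialect == "edf":
        return _read_edf_record(path)
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "preprocessing": {
        "fir_order": 50,
        "asef_k": 5.0,
        "jump_factor": 10.0,
        "pre_start": 90.0,
        "pre_end": 30.0,
        "min_len": 50.0,
        "dce_remi_max": 0.1,
        "dce_prop_max": 0.1,
    },
    "amif": {
        "n_bins": 32,
        "q_values": [0.1, 0.2, 0.5, 2, 3, 5, 10, 30, 50, 100],
        "tau_max_300": 300,
        "tau_max_128": 128,
    },
    "evaluation": {
        "alpha": 0.05,
        "corr_threshold": 0.7,
        "n_iter": 1000,
        "max_size": 4,
        "min_sen": 60.0,
        "min_spe": 60.0,
    },
}


def load_config(path: str | Path | None = None) -> dict:
    """Load the YAML configuration, deep-merged over the package defaults."""
    import copy

    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is None:
        return cfg
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}

    def merge(dst: dict, src: dict) -> None:
        for key, val in src.items():
            if isinstance(val, dict) and isinstance(dst.get(key), dict):
                merge(dst[key], val)
            else:
                dst[key] = val

    merge(cfg, user)
    return cfg
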
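"""Auto-mutual-information function (AMIF) with Shannon and Rényi entropies.

The AMIF measures the information shared between a series and its τ-lagged
copy, quantifying predictability (high AMIF) versus complexity (fast AMIF
decay).  The window's amplitude range is quantized into 32 equidistant bins,
which caps the Shannon AMIF at log₂32 = 5 bits; lag-τ joint probabilities are
simple bin-pair frequencies.

Shannon form::

    AMIF_Sh(τ) = Σ_ij P_xx(x_i, x_{i+τ}) log₂[ P_xx / (P_x(x_i) P_x(x_{i+τ})) ]

Rényi form with order q (> 0, ≠ 1)::

    AMIF_Re_q(τ) = 1/(q−1) log₂ Σ_ij P_xx^q / (P_x^{q−1}(x_i) P_x^{q−1}(x_{i+τ}))

q < 1 emphasizes rare bin pairs, q > 1 emphasizes common ones, and q → 1
recovers the Shannon form.  Curves are conventionally normalized by their
value at τ = 0.  The lag horizon is 1 s (300 samples at 300 Hz, 128 at
128 Hz), a compromise between exploring the slow δ band and EEG stationarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "QuantizedSeries",
    "EntropySpec",
    "AMIFCurve",
    "quantize",
    "joint_distribution",
    "amif_shannon",
    "amif_renyi",
    "amif_curves",
    "normalize",
]

N_BINS = 32
#: Rényi orders analyzed by default (q < 1, q > 1 both represented).
DEFAULT_Q_VALUES = (0.1, 0.2, 0.5, 2.0, 3.0, 5.0, 10.0, 30.0, 50.0, 100.0)


@dataclass(frozen=True)
class EntropySpec:
    """Entropy family (Shannon or Rényi) and, for Rényi, the order q."""

    family: str  # "Shannon" | "Renyi"
    q: Optional[float] = None

    def __post_init__(self) -> None:
        if self.family not in ("Shannon", "Renyi"):
            raise ValueError(f"unknown entropy family {self.family!r}")
        if self.family == "Renyi":
            if self.q is None or self.q <= 0 or self.q == 1:
                raise ValueError("Rényi order q must be > 0 and != 1")
        elif self.q is not None:
            raise ValueError("Shannon spec takes no q")

    @property
    def label(self) -> str:
        """Glossary-style label: 'Sh', 'Re_05', 'Re_2', ..."""
        if self.family == "Shannon":
            return "Sh"
        q = self.q
        if q < 1:
            return f"Re_0{int(round(q * 10))}"
        return f"Re_{int(round(q))}"


@dataclass
class QuantizedSeries:
    """Integer symbols in 0..31 from 32 equidistant amplitude partitions."""

    symbols: np.ndarray
    bin_edges: np.ndarray
    degenerate: bool = False

    @property
    def n(self) -> int:
        return len(self.symbols)


@dataclass
class AMIFCurve:
    """AMIF values (bits) over lags τ = 0..τ_max for one entropy spec."""

    values: np.ndarray
    spec: EntropySpec
    normalized: bool = False

    @property
    def tau_max(self) -> int:
        return len(self.values) - 1


def quantize(samples: np.ndarray, n_bins: int = N_BINS) -> QuantizedSeries:
    """Quantize the window's amplitude range into equidistant partitions.

    Edges span [min, max] of the window (per-window, so the result is
    invariant to affine amplitude transforms); the rightmost edge is
    inclusive.  A constant window maps everything to bin 0 and is flagged
    degenerate.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples to quantize")
    if not np.all(np.isfinite(x)):
        raise ValueError("samples must be finite")
    lo, hi = x.min(), x.max()
    edges = np.linspace(lo, hi, n_bins + 1)
    if hi == lo:
        return QuantizedSeries(np.zeros(x.size, dtype=np.int64), edges,
                               degenerate=True)
    sym = np.floor((x - lo) / (hi - lo) * n_bins).astype(np.int64)
    np.clip(sym, 0, n_bins - 1, out=sym)  # sample at exact max -> last bin
    return QuantizedSeries(sym, edges)


def joint_distribution(sym: QuantizedSeries, tau: int
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Joint and marginal probability tables for lag τ.

    The joint table is built from the pairs (s_i, s_{i+τ}); the marginals are
    its row and column sums (they describe the leading and trailing
    subsequences, which differ at the ends for τ > 0).
    """
    n = sym.n
    if tau >= n:
        raise ValueError(f"lag {tau} >= series length {n}")
    if tau < 0:
        raise ValueError("lag must be >= 0")
    counts = _lag_counts(sym.symbols, [tau])[0].reshape(N_BINS, N_BINS)
    joint = counts / counts.sum()
    return joint, joint.sum(axis=1), joint.sum(axis=0)


def _lag_counts(sym: np.ndarray, taus: Sequence[int]) -> np.ndarray:
    """Bin-pair count tables, one flattened 32x32 row per requested lag."""
    out = np.empty((len(taus), N_BINS * N_BINS), dtype=float)
    for row, tau in enumerate(taus):
        if tau == 0:
            pairs = sym * N_BINS + sym
        else:
            pairs = sym[:-tau] * N_BINS + sym[tau:]
        out[row] = np.bincount(pairs, minlength=N_BINS * N_BINS)
    return out


def _prepare_tables(counts: np.ndarray) -> dict:
    """Shared probability/log tables for all entropy specs of one series.

    ``logP`` is -inf on empty joint cells; the marginal logs use a safe 1.0
    placeholder in empty bins (whose joint cells are all empty anyway).
    """
    P = counts / counts.sum(axis=1, keepdims=True)
    P3 = P.reshape(-1, N_BINS, N_BINS)
    px = P3.sum(axis=2)
    py = P3.sum(axis=1)
    with np.errstate(divide="ignore"):
        logP = np.log(P3)
        logx = np.log(np.where(px > 0, px, 1.0))
        logy = np.log(np.where(py > 0, py, 1.0))
    return {"P3": P3, "logP": logP, "logxy": logx[:, :, None] + logy[:, None, :]}


def _shannon_values(tables: dict) -> np.ndarray:
    """Shannon AMIF per lag (0·log0 = 0)."""
    P3, logP, logxy = tables["P3"], tables["logP"], tables["logxy"]
    terms = P3 * (np.where(P3 > 0, logP, 0.0) - logxy)
    terms[P3 == 0] = 0.0
    return terms.sum(axis=(1, 2)) / np.log(2.0)


def _renyi_values(tables: dict, q: float) -> np.ndarray:
    """Rényi-q AMIF per lag; cells with zero joint probability contribute 0.

    The sum Σ P^q / (px^{q−1} py^{q−1}) is evaluated in log domain (stable
    logsumexp) so that extreme orders such as q = 100 do not overflow.
    """
    logterms = q * tables["logP"] + (1.0 - q) * tables["logxy"]
    flat = logterms.reshape(len(logterms), -1)
    m = flat.max(axis=1)
    s = m + np.log(np.exp(flat - m[:, None]).sum(axis=1))
    return s / np.log(2.0) / (q - 1.0)


def amif_curves(sym: QuantizedSeries, specs: Sequence[EntropySpec],
                tau_max: int) -> dict[EntropySpec, AMIFCurve]:
    """Compute AMIF curves for several entropy specs at once.

    The lag-wise joint histograms are shared across all specs, which is what
    makes scanning the full Rényi q grid affordable.
    """
    if sym.degenerate:
        warnings.warn("degenerate (constant) series: AMIF undefined",
                      RuntimeWarning)
        nanvals = np.full(tau_max + 1, np.nan)
        return {spec: AMIFCurve(nanvals.copy(), spec) for spec in specs}
    if tau_max >= sym.n:
        raise ValueError("tau_max must be smaller than the series length")
    counts = _lag_counts(sym.symbols, range(tau_max + 1))
    tables = _prepare_tables(counts)
    out: dict[EntropySpec, AMIFCurve] = {}
    for spec in specs:
        if spec.family == "Shannon":
            vals = _shannon_values(tables)
        else:
            vals = _renyi_values(tables, spec.q)
        out[spec] = AMIFCurve(vals, spec)
    return out


def amif_shannon(sym: QuantizedSeries, tau_max: int) -> AMIFCurve:
    """Shannon AMIF curve over lags 0..tau_max (bits)."""
    spec = EntropySpec("Shannon")
    return amif_curves(sym, [spec], tau_max)[spec]


def amif_renyi(sym: QuantizedSeries, q: float, tau_max: int) -> AMIFCurve:
    """Rényi-q AMIF curve over lags 0..tau_max (bits)."""
    if q == 1:
        raise ValueError("q=1 is the Shannon limit; use amif_shannon")
    spec = EntropySpec("Renyi", q=float(q))
    return amif_curves(sym, [spec], tau_max)[spec]


def normalize(curve: AMIFCurve) -> AMIFCurve:
    """Divide the curve by its τ=0 value (idempotent)."""
    if curve.normalized:
        return replace(curve, values=curve.values.copy())
    v0 = curve.values[0]
    if not np.isfinite(v0) or v0 == 0:
        warnings.warn("AMIF(0) is zero or undefined: normalized curve is NaN",
                      RuntimeWarning)
        return replace(curve, values=np.full_like(curve.values, np.nan),
                       normalized=True)
    return replace(curve, values=curve.values / v0, normalized=True)
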
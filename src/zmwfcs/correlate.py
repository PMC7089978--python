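"""Normalized fluctuation autocorrelation of intensity traces.

Two routes compute G(tau) = <dI(t) dI(t+tau)> / <I>^2:

* :func:`correlate_direct` — direct summation over all overlapping bin
  pairs at every requested lag; the slow, exact oracle.
* :func:`correlate_multitau` — the standard multi-tau scheme (m linear
  lags per octave, bin width doubling with paired-bin coarsening) that
  spans microseconds to seconds at fixed cost; the production correlator.

Both use the same symmetric fluctuation normalization: at lag k the mean
is estimated over the two overlapping segments, so G -> 0 at long lags
and G(0+) ~ 1/N, matching the amplitude convention of the diffusion
model fitted downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .photon_data import IntensityTrace

__all__ = [
    "CorrelationCurve",
    "correlate_direct",
    "correlate_multitau",
    "read_curve_csv",
    "write_curve_csv",
]


@dataclass
class CorrelationCurve:
    """Lag grid and fluctuation autocorrelation with uncertainty estimates."""

    lags: np.ndarray  # s, strictly increasing, first > 0
    g: np.ndarray
    weights: np.ndarray  # per-lag standard errors (0 if unavailable)
    total_photons: int = 0
    mean_rate: float = 0.0  # counts/s

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, float)
        self.g = np.asarray(self.g, float)
        self.weights = np.asarray(self.weights, float)
        if len(self.lags) and (self.lags[0] <= 0 or np.any(np.diff(self.lags) <= 0)):
            raise ValueError("lags must be strictly increasing and positive")
        if not np.all(np.isfinite(self.g)):
            raise ValueError("non-finite correlation values")


def _g_at_lags(counts: np.ndarray, lags_bins: np.ndarray) -> np.ndarray:
    """Fluctuation correlation at integer bin lags, symmetric normalization.

    g(k) = (<I_l I_r> - m^2) / m^2 with m = (mean(I_l) + mean(I_r)) / 2
    over the overlapping segments I_l = I[:-k], I_r = I[k:].
    """
    x = counts.astype(float)
    n = len(x)
    out = np.empty(len(lags_bins))
    for i, k in enumerate(lags_bins):
        k = int(k)
        left = x[: n - k]
        right = x[k:]
        m = 0.5 * (left.mean() + right.mean())
        if m == 0:
            out[i] = 0.0
        else:
            out[i] = (np.dot(left, right) / (n - k) - m * m) / (m * m)
    return out


def _block_weights(
    counts: np.ndarray, lags_bins: np.ndarray, n_blocks: int = 8
) -> np.ndarray:
    """Standard error of g per lag from splitting the trace into blocks."""
    n = len(counts)
    block = n // n_blocks
    if block < 2:
        return np.zeros(len(lags_bins))
    gs = []
    for b in range(n_blocks):
        seg = counts[b * block : (b + 1) * block]
        ok = lags_bins < len(seg) - 1
        g = np.zeros(len(lags_bins))
        if ok.any() and seg.sum() > 0:
            g[ok] = _g_at_lags(seg, lags_bins[ok])
        gs.append(g)
    gs = np.array(gs)
    return gs.std(axis=0, ddof=1) / np.sqrt(n_blocks)


def correlate_direct(trace: IntensityTrace, max_lag: float) -> CorrelationCurve:
    """Direct-summation autocorrelation at every integer bin lag up to max_lag."""
    n = trace.n_bins
    if n < 2:
        raise ValueError("trace needs at least 2 bins")
    span = n * trace.bin_width
    if max_lag >= span:
        raise ValueError(f"max_lag {max_lag:g} s >= trace span {span:g} s")
    k_max = max(1, int(np.floor(max_lag / trace.bin_width)))
    k_max = min(k_max, n - 1)
    lags_bins = np.arange(1, k_max + 1)
    g = _g_at_lags(trace.counts, lags_bins)
    w = _block_weights(trace.counts, lags_bins)
    return CorrelationCurve(
        lags=lags_bins * trace.bin_width,
        g=g,
        weights=w,
        total_photons=trace.total_counts,
        mean_rate=trace.mean_rate,
    )


def multitau_lag_grid(m: int, n_octaves: int) -> tuple[np.ndarray, np.ndarray]:
    """(lags in base bins, coarsening level per lag) of the multi-tau scheme."""
    lags = list(range(1, m + 1))
    levels = [0] * m
    for o in range(1, n_octaves):
        w = 2**o
        for j in range(m // 2 + 1, m + 1):
            lags.append(j * w)
            levels.append(o)
    return np.array(lags), np.array(levels)


def correlate_multitau(
    trace: IntensityTrace,
    m: int = 16,
    n_octaves: int | None = None,
    max_lag: float | None = None,
) -> CorrelationCurve:
    """Multi-tau autocorrelation with paired-bin coarsening.

    ``m`` linear lags in the first octave, then m/2 lags per octave on a
    trace coarsened by summing bin pairs.  Agrees with the direct
    correlator within the coarsening bias (<= 2% relative for lags of at
    least 4 base bins).  ``n_octaves`` defaults to everything that fits
    below ``max_lag`` (or one eighth of the trace span).
    """
    if m < 8 or m % 2:
        raise ValueError("m must be even and >= 8")
    n = trace.n_bins
    if n < 2 * m:
        raise ValueError("trace shorter than the first octave")
    span = n * trace.bin_width
    if max_lag is None:
        max_lag = span / 8.0
    max_bins = max_lag / trace.bin_width
    n_octaves_fit = 1
    while m * 2**n_octaves_fit <= max_bins and n // 2**n_octaves_fit >= 2 * m:
        n_octaves_fit += 1
    if n_octaves is not None:
        n_octaves = min(n_octaves, n_octaves_fit)
    else:
        n_octaves = n_octaves_fit

    all_lags: list[float] = []
    all_g: list[float] = []
    all_w: list[float] = []
    counts = trace.counts.astype(float)
    width = trace.bin_width
    for o in range(n_octaves):
        if o == 0:
            lags_bins = np.arange(1, m + 1)
        else:
            lags_bins = np.arange(m // 2 + 1, m + 1)
        lags_bins = lags_bins[lags_bins < len(counts) - 1]
        if len(lags_bins) == 0:
            break
        g = _g_at_lags(counts, lags_bins)
        w = _block_weights(counts, lags_bins)
        all_lags.extend((lags_bins * width).tolist())
        all_g.extend(g.tolist())
        all_w.extend(w.tolist())
        # coarsen by summing adjacent bin pairs
        half = len(counts) // 2
        counts = counts[: 2 * half : 2] + counts[1 : 2 * half : 2]
        width *= 2.0
    return CorrelationCurve(
        lags=np.array(all_lags),
        g=np.array(all_g),
        weights=np.array(all_w),
        total_photons=trace.total_counts,
        mean_rate=trace.mean_rate,
    )


def write_curve_csv(curve: CorrelationCurve, path: str | Path) -> None:
    arr = np.column_stack([curve.lags, curve.g, curve.weights])
    np.savetxt(
        path,
        arr,
        fmt="%.9e",
        delimiter=",",
        header=f"lag_s,g,weight  # total_photons={curve.total_photons} "
        f"mean_rate={curve.mean_rate:.6g}",
        comments="",
    )


def read_curve_csv(path: str | Path) -> CorrelationCurve:
    with open(path) as fh:
        header = fh.readline()
    total, rate = 0, 0.0
    for tok in header.split():
        if tok.startswith("total_photons="):
            total = int(tok.split("=")[1])
        elif tok.startswith("mean_rate="):
            rate = float(tok.split("=")[1])
    arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    return CorrelationCurve(
        lags=arr[:, 0], g=arr[:, 1], weights=arr[:, 2], total_photons=total, mean_rate=rate
    )
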
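"""Entropy-based and spectral HRV indices on beat-value series.

All four indices operate on any per-beat series — the RR tachogram or the
RQT differential — paired with the beats' occurrence times:

* **LHR** — ratio of low-frequency (0.04-0.15 Hz) to high-frequency
  (0.15-0.40 Hz) power, estimated with a Lomb-Scargle periodogram directly
  on the unevenly sampled beat series (no interpolation bias); a
  4-Hz-resampled Welch estimate is available as a cross-check.
* **SSR** — Poincaré-plot ratio SD1/SD2, averaged over lags 1..10.
* **MSE_SS** — small-scale multiscale entropy: mean sample entropy of the
  coarse-grained series over scales 1..5, with the tolerance fixed from the
  scale-1 standard deviation.
* **BEI** — baroreflex entropy index.  The exact published formula lives in
  external prior work; the implementation here is a documented stand-in that
  honours its verbal definition — the sample entropy of the heart-rate
  fluctuations confined to the baroreflex/LF band (0.04-0.15 Hz) — and is
  registered behind a plugin point (:data:`BEI_IMPLEMENTATIONS`) so an exact
  formula can replace it without interface changes.

Every index is invariant to constant offsets of the input series; SSR and
the entropies are additionally invariant to positive rescaling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, signal as sps

__all__ = [
    "SpectralBands",
    "HRVResult",
    "compute_lhr",
    "compute_ssr",
    "coarse_grain",
    "sample_entropy",
    "compute_mse_ss",
    "compute_bei",
    "compute_all_indices",
    "BEI_IMPLEMENTATIONS",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpectralBands:
    """LF/HF band edges in Hz; the shared 0.15 Hz boundary belongs to HF."""

    lf: tuple[float, float] = (0.04, 0.15)
    hf: tuple[float, float] = (0.15, 0.40)


@dataclass
class HRVResult:
    index_name: str
    input_series: str
    value: float
    n_beats_used: int
    params: dict = field(default_factory=dict)


def _clean(series, beat_times=None):
    x = np.asarray(series, dtype=float)
    if beat_times is None:
        keep = ~np.isnan(x)
        return x[keep], None
    t = np.asarray(beat_times, dtype=float)
    if t.shape != x.shape:
        raise ValueError("series and beat_times must have equal length")
    keep = ~np.isnan(x) & ~np.isnan(t)
    dropped = x.size - keep.sum()
    if dropped > 0.05 * x.size:
        logger.warning("%d of %d beats missing; entropy uses the gap-naive series", dropped, x.size)
    return x[keep], t[keep]


# --------------------------------------------------------------------------
# spectral: LHR
# --------------------------------------------------------------------------

def lomb_band_powers(
    values: np.ndarray,
    times_s: np.ndarray,
    bands: SpectralBands = SpectralBands(),
    df: float = 0.001,
) -> tuple[float, float]:
    """Band-integrated Lomb-Scargle powers (LF, HF) of a detrended series."""
    x = values - np.mean(values)
    freqs = np.arange(df, bands.hf[1] + df, df)
    pgram = sps.lombscargle(times_s, x, 2 * np.pi * freqs)
    lf_mask = (freqs >= bands.lf[0]) & (freqs < bands.lf[1])  # half-open LF
    hf_mask = (freqs >= bands.hf[0]) & (freqs <= bands.hf[1])
    lfp = float(np.trapezoid(pgram[lf_mask], freqs[lf_mask]))
    hfp = float(np.trapezoid(pgram[hf_mask], freqs[hf_mask]))
    return lfp, hfp


def welch_band_powers(
    values: np.ndarray,
    times_s: np.ndarray,
    bands: SpectralBands = SpectralBands(),
    fs_resample: float = 4.0,
) -> tuple[float, float]:
    """Cross-check estimator: cubic resampling to an even grid plus Welch."""
    x = values - np.mean(values)
    t_even = np.arange(times_s[0], times_s[-1], 1.0 / fs_resample)
    xi = interpolate.CubicSpline(times_s, x)(t_even)
    nper = min(len(xi), int(fs_resample * 150))
    freqs, psd = sps.welch(xi, fs=fs_resample, nperseg=nper)
    lf_mask = (freqs >= bands.lf[0]) & (freqs < bands.lf[1])
    hf_mask = (freqs >= bands.hf[0]) & (freqs <= bands.hf[1])
    return float(np.trapezoid(psd[lf_mask], freqs[lf_mask])), float(
        np.trapezoid(psd[hf_mask], freqs[hf_mask])
    )


def compute_lhr(
    series,
    beat_times,
    bands: SpectralBands = SpectralBands(),
    estimator: str = "lomb",
) -> float:
    """Low-to-high frequency power ratio LFP/HFP of the beat series."""
    x, t = _clean(series, beat_times)
    if t[-1] - t[0] < 120.0 or x.size < 50:
        raise ValueError("need >= 120 s and >= 50 beats for spectral estimation")
    if estimator == "lomb":
        lfp, hfp = lomb_band_powers(x, t, bands)
    elif estimator == "welch":
        lfp, hfp = welch_band_powers(x, t, bands)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    if hfp <= 0:
        raise ValueError("HF power is zero; LHR undefined")
    return lfp / hfp


# --------------------------------------------------------------------------
# Poincaré: SSR
# --------------------------------------------------------------------------

def compute_ssr(series, lags=range(1, 11)) -> float:
    """Mean SD1/SD2 of the lag-m Poincaré plots, m over ``lags`` (1..10).

    SD1 is the spread across the identity line (``sd((x[i+m]-x[i])/sqrt 2)``),
    SD2 the spread along it (``sd((x[i+m]+x[i])/sqrt 2)``).
    """
    x, _ = _clean(series)
    lags = list(lags)
    if x.size < max(lags) + 30:
        raise ValueError(f"series too short for lags up to {max(lags)}")
    ratios = []
    for m in lags:
        a, b = x[:-m], x[m:]
        sd1 = np.std((b - a) / np.sqrt(2.0), ddof=1)
        sd2 = np.std((b + a) / np.sqrt(2.0), ddof=1)
        if sd2 <= 1e-12 * max(1.0, float(np.max(np.abs(x)))):
            raise ValueError(f"degenerate series: SD2 is zero at lag {m}")
        ratios.append(sd1 / sd2)
    return float(np.mean(ratios))


# --------------------------------------------------------------------------
# entropies
# --------------------------------------------------------------------------

def coarse_grain(series, scale: int) -> np.ndarray:
    """Non-overlapping mean over windows of ``scale``; remainder discarded."""
    x = np.asarray(series, dtype=float)
    if scale < 1:
        raise ValueError("scale must be >= 1")
    if scale > x.size:
        raise ValueError("scale exceeds series length")
    n = x.size // scale
    return x[: n * scale].reshape(n, scale).mean(axis=1)


def sample_entropy_counts(series, m: int = 2, r: float | None = None) -> tuple[int, int]:
    """Template-match pair counts (A at length m+1, B at length m).

    Chebyshev distance, self-matches excluded; each unordered pair counted
    once.  Vectorized over pairs; the test suite cross-checks these counts
    against an explicit O(n^2) loop.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if r is None:
        r = 0.2 * np.std(x, ddof=0)
    if r <= 0:
        raise ValueError("tolerance r must be positive (constant series?)")

    # templates of length m restricted to those that can extend to m+1,
    # the standard SampEn convention (B counted over n-m templates)
    nm = n - m
    emb_m = np.lib.stride_tricks.sliding_window_view(x, m)[:nm]
    b = 0
    for i in range(nm - 1):
        d = np.max(np.abs(emb_m[i + 1 :] - emb_m[i]), axis=1)
        b += int(np.count_nonzero(d <= r))
    emb_m1 = np.lib.stride_tricks.sliding_window_view(x, m + 1)
    a = 0
    for i in range(len(emb_m1) - 1):
        d = np.max(np.abs(emb_m1[i + 1 :] - emb_m1[i]), axis=1)
        a += int(np.count_nonzero(d <= r))
    return a, b


def sample_entropy(series, m: int = 2, r: float | None = None, min_length: int = 50) -> float:
    """SampEn = -ln(A/B) in nats; ``r`` defaults to 0.2 * sd of the series.

    Returns ``inf`` (with a warning) when no template pair matches at length
    ``m+1``; raises on series shorter than ``min_length`` or constant input.
    """
    x, _ = _clean(series)
    if x.size < min_length:
        raise ValueError(f"need at least {min_length} points for sample entropy")
    a, b = sample_entropy_counts(x, m=m, r=r)
    if b == 0:
        raise ValueError("no template matches at length m; r too small")
    if a == 0:
        warnings.warn("no matches at length m+1; SampEn is infinite", RuntimeWarning, stacklevel=2)
        return float("inf")
    return float(-np.log(a / b))


def compute_mse_ss(series, scales=range(1, 6), m: int = 2, r: float | None = None) -> float:
    """Small-scale multiscale entropy: mean SampEn over ``scales`` (1..5).

    The tolerance is fixed from the scale-1 series (0.2 * sd by default) and
    reused at every scale, the standard MSE convention.
    """
    x, _ = _clean(series)
    scales = list(scales)
    if r is None:
        r = 0.2 * np.std(x, ddof=0)
    if x.size // max(scales) < 50:
        raise ValueError("coarse-grained series at the largest scale is too short")
    vals = [sample_entropy(coarse_grain(x, s), m=m, r=r) for s in scales]
    return float(np.mean(vals))


# --------------------------------------------------------------------------
# BEI (plugin point)
# --------------------------------------------------------------------------

def _bei_lf_band_sampen(
    series,
    beat_times,
    band: tuple[float, float] = (0.04, 0.15),
    fs_resample: float = 4.0,
    m: int = 2,
    r_frac: float = 0.2,
) -> float:
    """Stand-in BEI: SampEn of the baroreflex-band heart-rate fluctuations.

    The beat series is resampled evenly at 4 Hz (cubic spline), band-passed
    to 0.04-0.15 Hz with a zero-phase filter, sampled back at the beat
    times, and the sample entropy (m=2, r=0.2*sd of the filtered series) is
    returned.
    """
    x, t = _clean(series, beat_times)
    if t[-1] - t[0] < 120.0 or x.size < 50:
        raise ValueError("need >= 120 s and >= 50 beats for BEI")
    if np.std(x) == 0:
        raise ValueError("constant series: BEI undefined")
    t_even = np.arange(t[0], t[-1], 1.0 / fs_resample)
    xi = interpolate.CubicSpline(t, x - np.mean(x))(t_even)
    sos = sps.butter(4, band, btype="bandpass", fs=fs_resample, output="sos")
    xf = sps.sosfiltfilt(sos, xi)
    back = np.interp(t, t_even, xf)
    sd = np.std(back, ddof=0)
    if sd == 0:
        raise ValueError("filtered series has zero variance")
    return sample_entropy(back, m=m, r=r_frac * sd)


#: Named BEI implementations; register an exact formula here to replace the
#: band-limited-entropy stand-in without touching call sites.
BEI_IMPLEMENTATIONS = {"lf_band_sampen": _bei_lf_band_sampen}


def compute_bei(series, beat_times, implementation: str = "lf_band_sampen", **params) -> float:
    impl = BEI_IMPLEMENTATIONS.get(implementation)
    if impl is None:
        raise ValueError(f"unknown BEI implementation {implementation!r}")
    return impl(series, beat_times, **params)


# --------------------------------------------------------------------------
# convenience
# --------------------------------------------------------------------------

def compute_all_indices(series, beat_times, input_series: str = "RRI") -> list[HRVResult]:
    """LHR, SSR, MSE_SS and BEI of one beat series, as tagged results."""
    x, t = _clean(series, beat_times)
    n = int(x.size)
    return [
        HRVResult("LHR", input_series, compute_lhr(x, t), n, {"estimator": "lomb"}),
        HRVResult("SSR", input_series, compute_ssr(x), n, {"lags": "1-10"}),
        HRVResult("MSE_SS", input_series, compute_mse_ss(x), n, {"scales": "1-5", "m": 2, "r": "0.2sd"}),
        HRVResult("BEI", input_series, compute_bei(x, t), n, {"implementation": "lf_band_sampen"}),
    ]
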
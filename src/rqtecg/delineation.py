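"""Automated ECG delineation: R peaks, Q onsets, T peaks/offsets, morphology.

Pipeline (``delineate_record``):

1. zero-phase 0.5-40 Hz band-pass to remove baseline drift and HF noise;
2. R-peak detection with a Pan-Tompkins detector (band-limit, differentiate,
   square, 150 ms moving-window integration, adaptive dual thresholds with a
   200 ms refractory period and searchback), each detection refined to the
   local extremum of the filtered signal within +/-50 ms;
3. per beat, Q-onset search in a fixed window before R (slope-threshold
   walk-back from the Q minimum — the practical form of a first-derivative
   zero-crossing on sampled data);
4. per beat, T-wave search in an RR-adaptive window 200-500 ms after R
   (capped at 0.7*RR), five-class morphology classification, and T-offset by
   the baseline-threshold, tangent, or second-derivative method (``auto``
   picks per morphology).

All amplitude thresholds are fractions of the beat's R amplitude, so the
delineator is invariant to positive rescaling of the record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import ECGRecord, FiducialSet, Morphology

__all__ = [
    "DelineatorConfig",
    "bandpass_filter",
    "detect_r_peaks",
    "detect_q_point",
    "detect_t_wave",
    "classify_t_morphology",
    "delineate_record",
]

logger = logging.getLogger(__name__)


@dataclass
class DelineatorConfig:
    """Tunable delineation parameters (defaults in ms / Hz / fractions)."""

    band_lo: float = 0.5
    band_hi: float = 40.0
    q_window: float = 150.0          # backward Q search window, ms (100-150)
    t_window_lo: float = 200.0       # T search start after R, ms
    t_window_hi: float = 500.0       # T search end after R, ms
    t_window_rr_frac: float = 0.7    # adaptive cap: window end <= frac * local RR
    t_offset_method: str = "auto"    # baseline_threshold | tangent | second_derivative | auto
    flat_frac: float = 0.10          # T amp below this fraction of R -> flat
    notch_min_sep: float = 40.0      # min separation of same-sign lobes, ms
    peaked_frac: float = 0.60        # T amp at/above this fraction of R -> peaked (type C)
    offset_return_frac: float = 0.10  # baseline-threshold return level
    refractory_ms: float = 200.0     # Pan-Tompkins refractory period
    searchback_frac: float = 0.5     # Pan-Tompkins searchback threshold ratio
    slope_frac: float = 0.02         # Q-onset slope threshold vs peak QRS slope
    smooth_ms: float = 12.0          # T-segment smoothing window

    def validate(self, fs: float) -> None:
        if not self.band_lo < self.band_hi < fs / 2:
            raise ValueError("need band_lo < band_hi < fs/2")
        if not self.t_window_lo < self.t_window_hi:
            raise ValueError("need t_window_lo < t_window_hi")
        for name in ("flat_frac", "peaked_frac", "offset_return_frac", "t_window_rr_frac"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.t_offset_method not in (
            "baseline_threshold",
            "tangent",
            "second_derivative",
            "auto",
        ):
            raise ValueError(f"unknown t_offset_method {self.t_offset_method!r}")


# --------------------------------------------------------------------------
# filtering
# --------------------------------------------------------------------------

def bandpass_filter(record: ECGRecord, lo: float = 0.5, hi: float = 40.0) -> ECGRecord:
    """Zero-phase (forward-backward) Butterworth band-pass.

    Zero-phase filtering keeps fiducial timing unshifted; output length
    equals input length.
    """
    fs = record.fs
    if not 0 < lo < hi < fs / 2:
        raise ValueError(f"need 0 < lo < hi < fs/2, got lo={lo}, hi={hi}, fs={fs}")
    sos = sps.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
    # the low corner sets the impulse-response scale (~fs/lo samples);
    # reject records shorter than three times that
    if record.n_samples < 3 * fs / lo:
        raise ValueError("record too short for the requested low cut-off")
    y = sps.sosfiltfilt(sos, record.samples)
    return ECGRecord(y, fs=fs, lead=record.lead, source=record.source + "|bp")


def _moving_average(x: np.ndarray, n: int) -> np.ndarray:
    n = max(1, int(n))
    kernel = np.ones(n) / n
    return np.convolve(x, kernel, mode="same")


# --------------------------------------------------------------------------
# R peaks (Pan-Tompkins)
# --------------------------------------------------------------------------

def detect_r_peaks(record: ECGRecord, config: DelineatorConfig | None = None) -> np.ndarray:
    """Pan-Tompkins QRS detection; returns refined R-peak sample indices."""
    config = config or DelineatorConfig()
    fs = record.fs
    x = record.samples
    if record.duration_s < 10.0:
        logger.warning("record shorter than 10 s; threshold adaptation may be poor")

    sos = sps.butter(2, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, x)
    deriv = np.gradient(bp)
    sq = deriv**2
    mwi = _moving_average(sq, int(round(0.150 * fs)))

    refr = int(round(config.refractory_ms / 1000.0 * fs))
    cand, _ = sps.find_peaks(mwi, distance=max(1, refr))
    if cand.size == 0 or np.max(mwi) <= 0:
        logger.warning("no candidate peaks found (flat or noise-only input)")
        return np.array([], dtype=int)
    # scale-invariant quality gate: QRS energy towers over the record's
    # median energy, whereas in beat-free noise the two are comparable
    if np.max(mwi) < 8.0 * np.median(mwi):
        logger.warning("no QRS-like energy peaks above the noise floor")
        return np.array([], dtype=int)

    # adaptive dual thresholds over the integrated signal
    init = mwi[: int(min(len(mwi), 2 * fs))]
    spki = float(np.max(init)) * 0.5 if init.size else float(np.max(mwi)) * 0.5
    npki = float(np.mean(init)) * 0.5 if init.size else 0.0
    peaks: list[int] = []
    rr_hist: list[float] = []
    last = None
    slope_win = int(round(0.075 * fs))

    def local_slope(i: int) -> float:
        lo = max(0, i - slope_win)
        hi = min(len(deriv), i + slope_win + 1)
        return float(np.max(np.abs(deriv[lo:hi])))

    for c in cand:
        thr1 = npki + 0.25 * (spki - npki)
        # T-wave discrimination: a candidate close behind the last QRS with
        # less than half its slope is a repolarization wave, not a beat
        if (
            last is not None
            and (c - last) < 0.36 * fs
            and local_slope(c) < 0.5 * local_slope(last)
        ):
            npki = 0.125 * mwi[c] + 0.875 * npki
            continue
        if mwi[c] >= thr1:
            if last is not None:
                rr_hist.append(float(c - last))
                if len(rr_hist) > 8:
                    rr_hist.pop(0)
            peaks.append(int(c))
            last = c
            spki = 0.125 * mwi[c] + 0.875 * spki
        else:
            # searchback: accept a sub-threshold peak when a beat is overdue
            overdue = (
                last is not None
                and rr_hist
                and (c - last) > 1.66 * float(np.mean(rr_hist))
            )
            if overdue and mwi[c] >= config.searchback_frac * thr1:
                peaks.append(int(c))
                rr_hist.append(float(c - last))
                if len(rr_hist) > 8:
                    rr_hist.pop(0)
                last = c
                spki = 0.25 * mwi[c] + 0.75 * spki
            else:
                npki = 0.125 * mwi[c] + 0.875 * npki
    if not peaks:
        logger.warning("no peaks passed the adaptive thresholds")
        return np.array([], dtype=int)

    # refine each detection to the extremum of |filtered signal| within +/-50 ms
    bp_wide = sps.sosfiltfilt(
        sps.butter(2, [config.band_lo, config.band_hi], btype="bandpass", fs=fs, output="sos"),
        x,
    )
    half = int(round(0.050 * fs))
    refined = []
    for p in peaks:
        lo = max(0, p - half)
        hi = min(len(x), p + half + 1)
        refined.append(lo + int(np.argmax(np.abs(bp_wide[lo:hi]))))
    refined = np.array(sorted(set(refined)), dtype=int)
    # drop duplicates violating the refractory period (keep the larger peak)
    keep: list[int] = []
    for r in refined:
        if keep and r - keep[-1] < refr:
            if np.abs(bp_wide[r]) > np.abs(bp_wide[keep[-1]]):
                keep[-1] = int(r)
        else:
            keep.append(int(r))
    return np.array(keep, dtype=int)


# --------------------------------------------------------------------------
# Q onset
# --------------------------------------------------------------------------

def detect_q_point(
    record: ECGRecord,
    r_idx: int,
    q_window: float = 150.0,
    slope_frac: float = 0.02,
) -> int | None:
    """Q-onset in a fixed window before R.

    Finds the local minimum preceding R (the Q dip), then walks backward
    while the descending slope stays above a small fraction of the beat's
    peak slope — returning the sample where the first derivative effectively
    crosses zero.  Without a Q dip, the walk-back starts from the R upstroke
    itself and returns the QRS onset.  Returns ``None`` when the window
    extends before the record start (beat skipped upstream).
    """
    x = record.samples
    fs = record.fs
    w = int(round(q_window / 1000.0 * fs))
    lo = r_idx - w
    if lo < 0:
        return None
    win = x[lo : r_idx + 1]
    dy = np.diff(x)
    qrs_hi = min(len(x) - 1, r_idx + w)
    thr = slope_frac * np.max(np.abs(dy[lo:qrs_hi])) if qrs_hi > lo else 0.0

    # Q dip: the minimum strictly inside the window
    rel_min = int(np.argmin(win[:-1]))
    is_dip = 0 < rel_min and win[rel_min] < win[rel_min - 1] and win[rel_min] < win[rel_min + 1]
    if is_dip:
        i = lo + rel_min
        while i > lo:
            s = x[i] - x[i - 1]  # slope entering sample i
            if s >= 0 or abs(s) < thr:
                break
            i -= 1
        return int(i)
    # no Q dip: walk back down the R upstroke until the slope flattens
    i = r_idx
    while i > lo:
        s = x[i] - x[i - 1]
        if s < thr:
            break
        i -= 1
    return int(i) if i < r_idx else None


# --------------------------------------------------------------------------
# T wave: morphology classification and offset
# --------------------------------------------------------------------------

def _significant_extrema(seg: np.ndarray, prominence_frac: float = 0.25) -> list[tuple[int, float]]:
    """Indices and amplitudes of extrema with prominence >= frac * max|seg|."""
    amp = np.max(np.abs(seg))
    if amp == 0:
        return []
    prom = prominence_frac * amp
    pk_pos, _ = sps.find_peaks(seg, prominence=prom)
    pk_neg, _ = sps.find_peaks(-seg, prominence=prom)
    ext = [(int(i), float(seg[i])) for i in pk_pos] + [(int(i), float(seg[i])) for i in pk_neg]
    ext.sort(key=lambda e: e[0])
    # keep only extrema whose amplitude is itself significant
    return [(i, a) for i, a in ext if abs(a) >= prominence_frac * amp]


def classify_t_morphology(
    t_segment: np.ndarray,
    r_amp: float,
    config: DelineatorConfig | None = None,
    fs: float = 500.0,
) -> Morphology:
    """Classify a baseline-corrected T segment into the internal shape classes.

    Decision order: flat by amplitude; then two significant extrema make a
    biphasic (opposite signs, by order) or notched (same sign, separated by at
    least ``notch_min_sep``) wave; a single extremum is monophasic by sign.
    """
    config = config or DelineatorConfig()
    if r_amp <= 0:
        raise ValueError("r_amp must be positive")
    seg = np.asarray(t_segment, dtype=float)
    if seg.size == 0:
        raise ValueError("empty T segment")
    if np.max(np.abs(seg)) < config.flat_frac * r_amp:
        return Morphology.FLAT
    ext = _significant_extrema(seg)
    if len(ext) >= 2:
        # two largest by |amplitude|, kept in temporal order
        top2 = sorted(sorted(ext, key=lambda e: -abs(e[1]))[:2], key=lambda e: e[0])
        (i1, a1), (i2, a2) = top2
        if a1 > 0 > a2:
            return Morphology.BIPHASIC_PN
        if a1 < 0 < a2:
            return Morphology.BIPHASIC_NP
        if (i2 - i1) * 1000.0 / fs >= config.notch_min_sep:
            return Morphology.NOTCHED
        ext = [top2[0] if abs(a1) >= abs(a2) else top2[1]]
    if len(ext) == 1:
        return Morphology.MONOPHASIC_POS if ext[0][1] > 0 else Morphology.MONOPHASIC_NEG
    # no interior extremum passed the prominence screen: fall back to the sign
    # of the largest deflection
    k = int(np.argmax(np.abs(seg)))
    return Morphology.MONOPHASIC_POS if seg[k] > 0 else Morphology.MONOPHASIC_NEG


# per-morphology offset method used by ``auto``: the tangent suits the steep
# well-defined downslope of monophasic waves; the return-to-baseline rule is
# the more reliable choice when the closing lobe is preceded by another lobe
_AUTO_METHOD = {
    Morphology.MONOPHASIC_POS: "tangent",
    Morphology.MONOPHASIC_NEG: "tangent",
    Morphology.BIPHASIC_PN: "baseline_threshold",
    Morphology.BIPHASIC_NP: "baseline_threshold",
    Morphology.NOTCHED: "baseline_threshold",
    Morphology.FLAT: "baseline_threshold",
}


def _t_offset(
    dev: np.ndarray,
    last_ext: int,
    method: str,
    fs: float,
    return_frac: float,
) -> int | None:
    """T offset within ``dev`` (baseline-corrected), after the final lobe.

    Works on the rectified final lobe so negative T waves and the closing
    lobe of biphasic waves are handled uniformly.
    """
    a_last = dev[last_ext]
    if a_last == 0:
        return None
    s = np.sign(a_last)
    y = s * dev
    n = len(y)
    if last_ext >= n - 2:
        return None
    if method == "baseline_threshold":
        thr = return_frac * y[last_ext]
        below = np.nonzero(y[last_ext:] < thr)[0]
        return int(last_ext + below[0]) if below.size else None
    dy = np.gradient(y)
    # maximum downslope of the return limb
    j = last_ext + int(np.argmin(dy[last_ext:]))
    if method == "tangent":
        m = dy[j]
        if m >= 0:
            return None
        t_off = j - y[j] / m
        t_off = int(round(t_off))
        return t_off if last_ext < t_off < n else None
    if method == "second_derivative":
        d2 = np.gradient(dy)
        seg = d2[j:]
        signs = np.sign(seg)
        flips = np.nonzero(signs[:-1] * signs[1:] < 0)[0]
        # ignore sign changes once the wave has decayed into the noise floor
        alive = y[j:] >= 0.02 * y[last_ext]
        flips = [f for f in flips if alive[f]]
        if flips:
            return int(j + flips[0] + 1)
        # clean decaying lobe: curvature peaks where the limb straightens out
        k = j + int(np.argmax(seg)) if seg.size else None
        return int(k) if k is not None and k > last_ext else None
    raise ValueError(f"unknown t_offset method {method!r}")


def detect_t_wave(
    record: ECGRecord,
    r_idx: int,
    rri_local: float,
    config: DelineatorConfig | None = None,
    baseline: float | None = None,
) -> tuple[int | None, int | None, Morphology]:
    """T peak, T offset and morphology for the beat anchored at ``r_idx``.

    The search window is ``[r + t_window_lo, r + min(t_window_hi,
    t_window_rr_frac * rri_local)]`` — it shrinks at fast heart rates.  For
    the flat class the T fiducials are reported absent (the wave is too small
    to delineate reliably).
    """
    config = config or DelineatorConfig()
    x = record.samples
    fs = record.fs
    lo = r_idx + int(round(config.t_window_lo / 1000.0 * fs))
    hi_ms = min(config.t_window_hi, config.t_window_rr_frac * rri_local)
    hi = r_idx + int(round(hi_ms / 1000.0 * fs))
    hi = min(hi, len(x) - 1)
    if hi - lo < 3:
        return None, None, Morphology.FLAT
    if baseline is None:
        pr_lo = max(0, r_idx - int(round(0.090 * fs)))
        pr_hi = max(pr_lo + 1, r_idx - int(round(0.050 * fs)))
        baseline = float(np.median(x[pr_lo:pr_hi]))

    smooth_n = int(round(config.smooth_ms / 1000.0 * fs))
    seg = _moving_average(x[lo : hi + 1] - baseline, smooth_n)
    if np.all(seg == 0):
        return None, None, Morphology.FLAT
    r_amp = abs(x[r_idx] - baseline)
    morph = classify_t_morphology(seg, r_amp, config, fs=fs)
    if morph is Morphology.FLAT:
        return None, None, morph

    ext = _significant_extrema(seg)
    if not ext:
        k = int(np.argmax(np.abs(seg)))
        ext = [(k, float(seg[k]))]
    # T peak: extremum of largest absolute amplitude (earlier wins ties)
    peak_rel = max(ext, key=lambda e: (abs(e[1]), -e[0]))[0]
    t_peak = lo + peak_rel

    # offset search on a segment extended past the window end
    ext_hi = min(len(x) - 1, hi + int(round(0.150 * fs)))
    dev = _moving_average(x[lo : ext_hi + 1] - baseline, smooth_n)
    last_ext = max(e[0] for e in ext)
    method = config.t_offset_method
    if method == "auto":
        method = _AUTO_METHOD[morph]
    off_rel = _t_offset(dev, last_ext, method, fs, config.offset_return_frac)
    t_off = lo + off_rel if off_rel is not None else None
    if t_off is not None and t_off <= t_peak:
        t_off = None
    return int(t_peak), (int(t_off) if t_off is not None else None), morph


# --------------------------------------------------------------------------
# record-level orchestration
# --------------------------------------------------------------------------

def delineate_record(record: ECGRecord, config: DelineatorConfig | None = None) -> FiducialSet:
    """Full delineation of a record; per-beat failures yield absent fields."""
    config = config or DelineatorConfig()
    config.validate(record.fs)
    fs = record.fs
    filt = bandpass_filter(record, config.band_lo, config.band_hi)
    r_peaks = detect_r_peaks(filt, config)
    if r_peaks.size == 0:
        return FiducialSet.empty()

    x = filt.samples
    # record-level polarity: a negated lead flips every beat; work on the
    # flipped signal so Q/T logic sees upright R waves
    if np.median(x[r_peaks]) < 0:
        logger.info("negative R polarity detected; analysing the inverted signal")
        x = -x
    work = ECGRecord(x, fs=fs, lead=record.lead, source=record.source)

    n = len(r_peaks)
    rows = {"q_on": [], "t_peak": [], "t_off": [], "morphology": []}
    rr = np.diff(r_peaks) * 1000.0 / fs
    for i, r in enumerate(r_peaks):
        q_on = detect_q_point(work, int(r), config.q_window, config.slope_frac)
        if q_on is None:
            logger.debug("beat %d: Q window extends before record start; skipped", i)
        # local RR for the adaptive T window: the interval following this beat
        if i < n - 1:
            rri_local = rr[i]
        elif n > 1:
            rri_local = rr[-1]
        else:
            rri_local = 1000.0
        baseline = None
        if q_on is not None:
            b_lo = max(0, q_on - int(round(0.040 * fs)))
            if q_on > b_lo:
                baseline = float(np.median(x[b_lo:q_on]))
        t_fits = r + int(round(config.t_window_hi / 1000.0 * fs)) < work.n_samples
        is_last = i == n - 1
        if is_last and not t_fits:
            t_peak, t_off, morph = None, None, None
            logger.debug("beat %d: T window extends past record end", i)
        else:
            t_peak, t_off, morph = detect_t_wave(work, int(r), rri_local, config, baseline)
        rows["q_on"].append(q_on)
        rows["t_peak"].append(t_peak)
        rows["t_off"].append(t_off)
        rows["morphology"].append(morph.value if morph is not None else None)

    out = FiducialSet.from_arrays(
        r_peak=r_peaks,
        q_on=rows["q_on"],
        t_peak=rows["t_peak"],
        t_off=rows["t_off"],
        morphology=rows["morphology"],
    )
    out.validate(n_samples=record.n_samples)
    return out
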
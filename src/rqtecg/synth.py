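"""Synthetic single-lead ECG with exact, analytically known ground truth.

Each beat is a sum of Gaussian kernels (one per P/Q/R/S component plus one or
two T-wave lobes), in the spirit of the ECGSYN dynamical model but built
beat-by-beat so that every fiducial point of the clean waveform is known in
closed form:

* the true Q onset is where the Q-wave kernel reaches 1% of its amplitude;
* the true T offset is the last point where the (noise-free) T component
  stays at or above 1% of its own peak — a documented constant that makes the
  ground truth independent of additive noise;
* the true T peak is the extremum of largest absolute amplitude of the T
  component.

RR dynamics are a deterministic two-tone model (one LF and one HF sinusoid)
plus white Gaussian jitter, and the Q-onset-to-T-offset duration of each beat
is stretched to ``qt_alpha * (RR/1000)**qt_beta`` where RR is the interval
*following* the beat's R peak — the same pairing the interval layer uses for
heart-rate correction, so ``qt_beta = 0.5`` yields a world with exactly
constant Bazett QTc.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import ECGRecord, FiducialSet, Morphology

__all__ = ["SyntheticSpec", "generate_rr_series", "morphology_template", "generate_ecg"]

logger = logging.getLogger(__name__)

#: 1%-of-peak point of a Gaussian, in units of sigma: exp(-K**2/2) = 0.01.
ONSET_SIGMA = float(np.sqrt(2.0 * np.log(100.0)))

# P/Q/R/S kernel parameters: (amplitude relative to R, center ms rel. R, sigma ms)
_PQRS = (
    (0.12, -190.0, 22.0),
    (-0.10, -28.0, 7.0),
    (1.00, 0.0, 10.0),
    (-0.18, 32.0, 8.0),
)
_Q_AMP, _Q_CENTER, _Q_SIGMA = _PQRS[1]

#: True Q onset relative to the R peak (ms): 1% point of the Q kernel.
Q_ONSET_MS = _Q_CENTER - ONSET_SIGMA * _Q_SIGMA

# T-lobe layouts per morphology: list of (relative amplitude, offset ms, sigma ms);
# offsets are relative to the first lobe center, later shifted as a block to
# realize the requested QT duration.
_T_LOBES: dict[Morphology, list[tuple[float, float, float]]] = {
    Morphology.MONOPHASIC_POS: [(1.0, 0.0, 20.0)],
    Morphology.MONOPHASIC_NEG: [(-1.0, 0.0, 20.0)],
    Morphology.BIPHASIC_PN: [(1.0, 0.0, 16.0), (-0.8, 70.0, 16.0)],
    Morphology.BIPHASIC_NP: [(-1.0, 0.0, 16.0), (0.8, 70.0, 16.0)],
    Morphology.NOTCHED: [(1.0, 0.0, 16.0), (0.9, 55.0, 16.0)],
    Morphology.FLAT: [(1.0, 0.0, 20.0)],
}


class GenerationError(RuntimeError):
    """Raised when a spec would produce overlapping or degenerate beats."""


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic recording.

    Defaults emulate a middle-aged sinus-rhythm subject: mean RR 900 ms
    (HR ~67 bpm), modest LF (0.1 Hz) and HF (0.3 Hz) RR modulation, a
    Bazett-consistent QT-RR coupling (``qt_alpha`` 400 ms, ``qt_beta`` 0.5),
    and a T wave at 35% of the R amplitude.
    """

    fs: float = 500.0
    n_beats: int = 300
    mean_rr: float = 900.0
    lf_amp: float = 25.0
    lf_freq: float = 0.1
    hf_amp: float = 15.0
    hf_freq: float = 0.3
    rr_noise_sd: float = 10.0
    qt_alpha: float = 400.0
    qt_beta: float = 0.5
    t_morphology: Morphology | str | list = Morphology.MONOPHASIC_POS
    t_amp_frac: float = 0.35
    r_amp: float = 1.0
    noise_sd: float = 0.0
    baseline_wander_amp: float = 0.0
    baseline_wander_freq: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_beats < 3:
            raise ValueError("need at least 3 beats")
        if not 0.0 <= self.t_amp_frac <= 1.0:
            raise ValueError("t_amp_frac must lie in [0, 1]")
        if not 0.04 < self.lf_freq < 0.15:
            logger.warning("lf_freq %.3f Hz outside the LF band (0.04-0.15)", self.lf_freq)
        if not 0.15 < self.hf_freq < 0.40:
            logger.warning("hf_freq %.3f Hz outside the HF band (0.15-0.40)", self.hf_freq)

    def morphology_list(self) -> list[Morphology]:
        m = self.t_morphology
        if isinstance(m, (list, tuple)):
            out = [Morphology(x) for x in m]
            if len(out) != self.n_beats:
                raise ValueError("per-beat morphology list length must equal n_beats")
            return out
        return [Morphology(m)] * self.n_beats


def _gauss(t_ms: np.ndarray, amp: float, center: float, sigma: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((t_ms - center) / sigma) ** 2)


def _t_layout(morph: Morphology, t_amp: float, qt_ms: float) -> tuple[list, float, float]:
    """Place the T lobes so Q-onset..T-offset equals ``qt_ms``.

    Returns (lobes as (amp, center ms rel. R, sigma ms), true t_peak ms,
    true t_off ms), all relative to the R peak.
    """
    layout = [(a * t_amp, off, sig) for a, off, sig in _T_LOBES[morph]]
    # provisional block at first-lobe center 0; sample the T component finely
    span_lo = min(off - 4 * sig for _, off, sig in layout)
    span_hi = max(off + 4 * sig for _, off, sig in layout)
    grid = np.arange(span_lo, span_hi, 0.25)
    tw = np.zeros_like(grid)
    for a, off, sig in layout:
        tw += _gauss(grid, a, off, sig)
    peak = np.max(np.abs(tw))
    above = np.abs(tw) >= 0.01 * peak
    t_off0 = grid[np.nonzero(above)[0][-1]]
    t_peak0 = grid[int(np.argmax(np.abs(tw)))]
    shift = (qt_ms + Q_ONSET_MS) - t_off0  # desired t_off relative to R
    lobes = [(a, off + shift, sig) for a, off, sig in layout]
    return lobes, t_peak0 + shift, t_off0 + shift


def morphology_template(
    morph: Morphology | str,
    t_amp_frac: float,
    fs: float,
    qt_ms: float = 400.0,
    r_amp: float = 1.0,
) -> tuple[np.ndarray, dict]:
    """Build one noise-free beat and its exact fiducials.

    Returns the waveform segment and a dict of 0-based sample indices within
    the segment (``q_on``, ``r_peak``, ``t_peak``, ``t_off``).  ``t_peak`` and
    ``t_off`` are ``None`` when ``t_amp_frac`` is zero (no T wave at all).
    """
    morph = Morphology(morph)
    if not 0.0 <= t_amp_frac <= 1.0:
        raise ValueError("t_amp_frac must lie in [0, 1]")
    t_amp = t_amp_frac * r_amp
    pre_ms, post_ms = 320.0, 120.0
    if t_amp > 0:
        lobes, t_peak_ms, t_off_ms = _t_layout(morph, t_amp, qt_ms)
    else:
        lobes, t_peak_ms, t_off_ms = [], None, None
    n_pre = int(round(pre_ms * fs / 1000.0))
    end_ms = (t_off_ms if t_off_ms is not None else 60.0) + post_ms
    n_post = int(round(end_ms * fs / 1000.0))
    t_ms = (np.arange(-n_pre, n_post + 1)) * 1000.0 / fs
    seg = np.zeros_like(t_ms)
    for a, c, s in _PQRS:
        seg += _gauss(t_ms, a * r_amp, c, s)
    for a, c, s in lobes:
        seg += _gauss(t_ms, a, c, s)

    def to_idx(ms):
        return None if ms is None else n_pre + int(round(ms * fs / 1000.0))

    fids = {
        "q_on": to_idx(Q_ONSET_MS),
        "r_peak": n_pre,
        "t_peak": to_idx(t_peak_ms),
        "t_off": to_idx(t_off_ms),
    }
    return seg, fids


def generate_rr_series(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """Two-tone plus white-noise RR tachogram.

    Returns ``(rr_ms, beat_times_s)`` where ``rr_ms[i]`` is the interval
    following beat ``i`` (length ``n_beats``; the last value is used only for
    the last beat's QT coupling) and ``beat_times_s[i]`` is the cumulative
    time of beat ``i``'s R peak, starting at 0.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 101]))
    n = spec.n_beats
    rr = np.empty(n)
    t = np.empty(n)
    ti = 0.0
    for i in range(n):
        t[i] = ti
        rr[i] = (
            spec.mean_rr
            + spec.lf_amp * np.sin(2 * np.pi * spec.lf_freq * ti)
            + spec.hf_amp * np.sin(2 * np.pi * spec.hf_freq * ti)
            + rng.normal(0.0, spec.rr_noise_sd)
        )
        if rr[i] <= 0:
            raise GenerationError("non-positive RR interval generated")
        ti += rr[i] / 1000.0
    return rr, t


def generate_ecg(spec: SyntheticSpec) -> tuple[ECGRecord, FiducialSet]:
    """Generate the record and its ground-truth fiducial set.

    Deterministic under a fixed ``spec.seed``.  Raises
    :class:`GenerationError` if consecutive beats would overlap.
    """
    fs = spec.fs
    rr, beat_t = generate_rr_series(spec)
    morphs = spec.morphology_list()
    t_start = 0.6  # room for the first beat's P wave and Q window
    dur = t_start + beat_t[-1] + rr[-1] / 1000.0 + 0.6
    n_samples = int(round(dur * fs))
    sig = np.zeros(n_samples)

    rows = {"q_on": [], "r_peak": [], "t_peak": [], "t_off": [], "morphology": []}
    prev_t_off_ms = -np.inf
    for i in range(spec.n_beats):
        r_ms = (t_start + beat_t[i]) * 1000.0
        qt_ms = spec.qt_alpha * (rr[i] / 1000.0) ** spec.qt_beta
        t_amp = spec.t_amp_frac * spec.r_amp
        if t_amp > 0:
            lobes, t_peak_ms, t_off_ms = _t_layout(morphs[i], t_amp, qt_ms)
        else:
            lobes, t_peak_ms, t_off_ms = [], None, None
        beat_end = r_ms + (t_off_ms if t_off_ms is not None else 60.0)
        if r_ms - 320.0 < prev_t_off_ms:
            raise GenerationError(
                f"beat {i} overlaps its predecessor (RR too short for the QT duration)"
            )
        prev_t_off_ms = beat_end
        # render this beat on the global grid over a local window
        lo = max(0, int(np.floor((r_ms - 330.0) * fs / 1000.0)))
        hi_ms = beat_end + 120.0
        hi = min(n_samples, int(np.ceil(hi_ms * fs / 1000.0)) + 1)
        tt = np.arange(lo, hi) * 1000.0 / fs - r_ms
        for a, c, s in _PQRS:
            sig[lo:hi] += _gauss(tt, a * spec.r_amp, c, s)
        for a, c, s in lobes:
            sig[lo:hi] += _gauss(tt, a, c, s)

        def idx(ms_rel):
            return None if ms_rel is None else int(round((r_ms + ms_rel) * fs / 1000.0))

        rows["q_on"].append(idx(Q_ONSET_MS))
        rows["r_peak"].append(idx(0.0))
        rows["t_peak"].append(idx(t_peak_ms))
        rows["t_off"].append(idx(t_off_ms))
        rows["morphology"].append(morphs[i].value)

    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 202]))
    if spec.noise_sd > 0:
        sig = sig + rng.normal(0.0, spec.noise_sd, size=n_samples)
    if spec.baseline_wander_amp > 0:
        tsec = np.arange(n_samples) / fs
        phase = rng.uniform(0, 2 * np.pi)
        sig = sig + spec.baseline_wander_amp * np.sin(
            2 * np.pi * spec.baseline_wander_freq * tsec + phase
        )

    record = ECGRecord(sig, fs=fs, lead="II", source=f"synthetic(seed={spec.seed})")
    truth = FiducialSet.from_arrays(
        r_peak=rows["r_peak"],
        q_on=rows["q_on"],
        t_peak=rows["t_peak"],
        t_off=rows["t_off"],
        morphology=rows["morphology"],
    )
    truth.validate(n_samples=n_samples)
    return record, truth
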
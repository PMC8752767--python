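"""Optical action-potential and patch-clamp trace analysis.

Covers the functional readouts used to phenotype cardiac myocytes:

* ratiometric trace construction (long/short emission channel ratio of a
  voltage-sensitive dye, or raw membrane potential),
* AP upstroke detection on drifting, noisy recordings,
* APD at a configurable repolarization level (APD90 by default) with
  per-AP baseline estimation and sub-sample threshold interpolation,
* Bazett rate correction of APD and field-potential duration,
* upstroke-aligned AP averaging,
* IV-curve assembly from voltage-step records (peak or end-of-step current
  density, pA/pF), linear leak subtraction and drug-difference currents.

Durations are milliseconds throughout; current densities pA/pF.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# containers


@dataclass
class RatioTrace:
    """A uniformly sampled single-channel signal (ratio or mV) vs time (ms)."""

    time: np.ndarray
    signal: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.shape != self.signal.shape:
            raise ValueError("time and signal must have equal length")
        if len(self.time) < 2:
            raise ValueError("trace needs at least 2 samples")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise ValueError("time must be strictly increasing")
        if np.ptp(dt) > 0.01 * np.median(dt):
            raise ValueError("sampling jitter exceeds 1% of the sampling interval")

    @property
    def sampling_interval(self) -> float:
        return float(np.median(np.diff(self.time)))

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])


@dataclass(frozen=True)
class APFeature:
    """Per-AP features; ``capd90 = apd90 / sqrt(rr/1000)`` (Bazett)."""

    upstroke_time: float
    onset_time: float
    peak_value: float
    baseline: float
    apd90: float | None
    rr: float | None          # preceding inter-upstroke interval; None for first AP
    capd90: float | None
    valid: bool = True

    @property
    def amplitude(self) -> float:
        return self.peak_value - self.baseline


@dataclass(frozen=True)
class FieldPotentialRecord:
    fpd: float
    beat_interval: float
    cfpd: float


@dataclass
class IVCurve:
    """Current-voltage relation: current density (pA/pF) per test potential (mV)."""

    potentials: np.ndarray
    densities: np.ndarray
    capacitance: float
    mode: str = "peak"

    def __post_init__(self) -> None:
        self.potentials = np.asarray(self.potentials, dtype=float)
        self.densities = np.asarray(self.densities, dtype=float)
        if self.potentials.shape != self.densities.shape:
            raise ValueError("potential and density vectors must match")
        if len(np.unique(self.potentials)) != len(self.potentials):
            raise ValueError("test potentials must be unique")
        if np.any(np.diff(self.potentials) <= 0):
            order = np.argsort(self.potentials)
            self.potentials = self.potentials[order]
            self.densities = self.densities[order]
        if self.capacitance <= 0:
            raise ValueError("capacitance must be positive")


@dataclass
class APConfig:
    """Detection and measurement settings for optical AP analysis."""

    min_interval_ms: float = 200.0       # refractory floor between detections
    level: float = 0.9                   # repolarization fraction for APD
    smooth_ms: float = 11.0              # centered moving average for repolarization crossings
    baseline_percentile: float = 10.0    # of the preceding inter-AP segment
    onset_fraction: float = 0.1          # takeoff threshold above baseline
    flat_snr: float = 8.0                # robust range / noise ratio below which a trace is flat
    min_valid_aps: int = 3
    rr_mode: str = "per_ap"              # or "cell_mean"


# --------------------------------------------------------------------------
# elementary operations


def bazett_correct(duration: float, rr: float) -> float:
    """Bazett rate correction: duration / sqrt(RR in seconds)."""
    if rr <= 0:
        raise ValueError("RR interval must be positive")
    return duration / math.sqrt(rr / 1000.0)


def cfpd(fpd: float, beat_interval: float) -> float:
    """Rate-corrected field-potential duration (Bazett)."""
    if fpd <= 0:
        raise ValueError("FPD must be positive")
    return bazett_correct(fpd, beat_interval)


def correct_fpd_table(table: pd.DataFrame) -> pd.DataFrame:
    """Apply Bazett correction to a table with columns ``fpd``, ``beat_interval``."""
    out = table.copy()
    out["cfpd"] = [
        cfpd(f, b) for f, b in zip(out["fpd"].astype(float), out["beat_interval"].astype(float))
    ]
    return out


def ratio_trace(
    numerator: np.ndarray,
    denominator: np.ndarray,
    time: np.ndarray,
    numerator_label: str = "F655",
    denominator_label: str = "F560",
) -> RatioTrace:
    """Pointwise two-channel ratio (e.g. F655/F560 of a ratiometric dye).

    Samples where the denominator is <= 0 are flagged in
    ``metadata['n_bad_denominator']`` and set to NaN.
    """
    num = np.asarray(numerator, dtype=float)
    den = np.asarray(denominator, dtype=float)
    if num.shape != den.shape:
        raise ValueError("channels must have equal length")
    bad = den <= 0
    n_bad = int(bad.sum())
    if n_bad:
        logger.warning("%d samples with non-positive denominator set to NaN", n_bad)
    ratio = np.where(bad, np.nan, num / np.where(bad, 1.0, den))
    return RatioTrace(
        time=np.asarray(time, dtype=float),
        signal=ratio,
        metadata={
            "numerator": numerator_label,
            "denominator": denominator_label,
            "n_bad_denominator": n_bad,
        },
    )


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average with edge-shrinking windows (no phase shift)."""
    if width <= 1:
        return x
    kernel = np.ones(width)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def _robust_noise_sd(x: np.ndarray) -> float:
    """Noise level from first differences (slow structure cancels)."""
    d = np.diff(x)
    mad = np.median(np.abs(d - np.median(d)))
    return float(mad / 0.6745 / math.sqrt(2.0))


def detect_aps(trace: RatioTrace, config: APConfig | None = None) -> np.ndarray:
    """Indices of AP upstrokes, one per AP at the maximal-derivative point.

    The signal is linearly detrended; a trace whose robust amplitude does
    not exceed ``flat_snr`` times the noise floor is declared AP-free.
    Candidate APs are prominence peaks of the detrended signal; the
    upstroke index is the maximal first-difference point between the
    preceding near-baseline sample and the peak.  Detections closer than
    ``min_interval_ms`` are suppressed (larger peak wins).
    """
    cfg = config or APConfig()
    if trace.duration < 1000.0:
        raise ValueError("need at least 1 s of signal")
    from scipy import signal as sps

    x = sps.detrend(np.nan_to_num(trace.signal, nan=float(np.nanmedian(trace.signal))))
    dt = trace.sampling_interval
    lo, hi = np.percentile(x, [1, 99])
    rng = hi - lo
    noise = _robust_noise_sd(x)
    if rng == 0 or (noise > 0 and rng < cfg.flat_snr * noise):
        return np.array([], dtype=int)

    distance = max(1, int(round(cfg.min_interval_ms / dt)))
    sm = _moving_average(x, max(1, int(round(3.0 / dt)) | 1))
    peaks, _ = sps.find_peaks(sm, prominence=0.5 * rng, distance=distance)
    if len(peaks) == 0:
        return np.array([], dtype=int)

    near_baseline = lo + 0.1 * rng
    upstrokes = []
    for k, p in enumerate(peaks):
        b = p
        floor = int(peaks[k - 1]) if k > 0 else 0
        while b > floor and sm[b] > near_baseline:
            b -= 1
        seg = np.diff(sm[b : p + 1])
        u = b + int(np.argmax(seg)) + 1 if len(seg) else p
        # refine on the raw derivative: smoothing delays the edge slightly
        lo_r = max(b, u - 3)
        hi_r = min(p, u + 3)
        raw_seg = np.diff(x[lo_r : hi_r + 1])
        if len(raw_seg):
            u = lo_r + int(np.argmax(raw_seg)) + 1
        upstrokes.append(u)
    upstrokes = np.array(sorted(set(upstrokes)), dtype=int)
    # enforce the refractory floor after merging
    keep = [upstrokes[0]] if len(upstrokes) else []
    for u in upstrokes[1:]:
        if u - keep[-1] >= distance:
            keep.append(u)
    return np.array(keep, dtype=int)


def _interp_crossing(t0: float, t1: float, y0: float, y1: float, level: float) -> float:
    if y1 == y0:
        return t0
    return t0 + (level - y0) * (t1 - t0) / (y1 - y0)


def _ap_baseline(signal: np.ndarray, upstroke: int, prev_upstroke: int | None,
                 percentile: float) -> float:
    """Baseline of one AP: low percentile of the preceding inter-AP segment."""
    start = prev_upstroke if prev_upstroke is not None else 0
    seg = signal[start:upstroke]
    if len(seg) < 3:
        seg = signal[: max(upstroke, 3)]
    return float(np.percentile(seg, percentile))


def apd_at_level(
    trace: RatioTrace,
    upstroke_index: int,
    level: float = 0.9,
    config: APConfig | None = None,
    next_upstroke_index: int | None = None,
    prev_upstroke_index: int | None = None,
) -> float | None:
    """AP duration at a repolarization ``level`` (0.9 -> APD90), in ms.

    Measured from the takeoff point — the interpolated crossing of
    baseline + ``onset_fraction`` x amplitude on the rising limb, found by
    back-tracking from the maximal-derivative upstroke sample — to the
    interpolated crossing of baseline + (1 - level) x amplitude on the
    falling limb.  Thresholds are relative to the per-AP baseline and
    amplitude, so the measure is invariant under positive affine transforms
    of the signal.  Returns None when repolarization does not complete
    before the next AP or the end of the trace.
    """
    cfg = config or APConfig()
    y = trace.signal
    t = trace.time
    dt = trace.sampling_interval
    n = len(y)
    end = next_upstroke_index if next_upstroke_index is not None else n

    baseline = _ap_baseline(y, upstroke_index, prev_upstroke_index, cfg.baseline_percentile)
    seg = y[upstroke_index:end]
    if len(seg) < 3:
        return None
    peak_rel = int(np.argmax(seg))
    peak_idx = upstroke_index + peak_rel
    amplitude = y[peak_idx] - baseline
    if amplitude <= 0:
        return None

    # --- takeoff: back-track from the upstroke to the onset-threshold crossing
    onset_level = baseline + cfg.onset_fraction * amplitude
    i = upstroke_index
    floor = prev_upstroke_index if prev_upstroke_index is not None else 0
    while i > floor and y[i - 1] > onset_level:
        i -= 1
    if i > 0 and y[i - 1] <= onset_level <= y[i]:
        onset_time = _interp_crossing(t[i - 1], t[i], y[i - 1], y[i], onset_level)
    else:
        onset_time = t[i]

    # --- repolarization crossing on a smoothed falling limb
    width = max(1, int(round(cfg.smooth_ms / dt)) | 1)
    lo_idx = peak_idx
    hi_idx = min(end + width, n)
    sm = _moving_average(y[max(0, lo_idx - width): hi_idx], width)
    sm_t = t[max(0, lo_idx - width): hi_idx]
    off = peak_idx - max(0, lo_idx - width)
    repol_level = baseline + (1.0 - level) * amplitude

    below = np.nonzero(sm[off:] < repol_level)[0]
    cross_time = None
    for k in below:
        idx = off + k
        # require the signal to stay below for a few samples (noise guard)
        hold = sm[idx: idx + 3]
        if np.all(hold < repol_level) or idx + 3 > len(sm):
            if idx == 0:
                cross_time = sm_t[0]
            else:
                cross_time = _interp_crossing(
                    sm_t[idx - 1], sm_t[idx], sm[idx - 1], sm[idx], repol_level
                )
            break
    if cross_time is None:
        return None
    limit = t[end - 1] if end <= n else t[-1]
    if next_upstroke_index is not None and cross_time > t[min(end, n - 1)]:
        return None
    if cross_time > limit + dt:
        return None
    return float(cross_time - onset_time)


def average_ap(
    trace: RatioTrace,
    upstroke_indices: Sequence[int],
    n: int = 15,
) -> tuple[np.ndarray, np.ndarray]:
    """Upstroke-aligned mean of ``n`` consecutive AP windows.

    The window length is the median inter-upstroke interval.  When fewer
    than ``n`` APs are available, all are used and a warning is logged.
    Returns ``(relative_time_ms, mean_waveform)``.
    """
    idx = np.asarray(upstroke_indices, dtype=int)
    if len(idx) < 2:
        raise ValueError("need at least 2 detected APs to average")
    if len(idx) < n:
        logger.warning("only %d APs available; averaging all (requested %d)", len(idx), n)
        use = idx
    else:
        use = idx[:n]
    window = int(np.median(np.diff(idx)))
    window = min(window, len(trace.signal) - int(use[-1]))
    segments = [trace.signal[i : i + window] for i in use if i + window <= len(trace.signal)]
    mean = np.mean(np.stack(segments), axis=0)
    rel_t = np.arange(window) * trace.sampling_interval
    return rel_t, mean


@dataclass(frozen=True)
class CellSummary:
    n_aps: int
    n_valid: int
    median_apd90: float
    median_rr: float
    median_capd90: float
    flagged: bool = False


def extract_features(trace: RatioTrace, config: APConfig | None = None) -> list[APFeature]:
    """Per-AP features for every detected AP in a trace."""
    cfg = config or APConfig()
    idx = detect_aps(trace, cfg)
    features: list[APFeature] = []
    for k, u in enumerate(idx):
        prev_u = int(idx[k - 1]) if k > 0 else None
        next_u = int(idx[k + 1]) if k + 1 < len(idx) else None
        baseline = _ap_baseline(trace.signal, u, prev_u, cfg.baseline_percentile)
        end = next_u if next_u is not None else len(trace.signal)
        seg = trace.signal[u:end]
        peak = float(np.max(seg)) if len(seg) else float(trace.signal[u])
        apd = apd_at_level(trace, u, cfg.level, cfg, next_u, prev_u)
        rr = float(trace.time[u] - trace.time[prev_u]) if prev_u is not None else None
        capd = bazett_correct(apd, rr) if (apd is not None and rr is not None) else None
        features.append(
            APFeature(
                upstroke_time=float(trace.time[u]),
                onset_time=float(trace.time[u]),
                peak_value=peak,
                baseline=baseline,
                apd90=apd,
                rr=rr,
                capd90=capd,
                valid=apd is not None,
            )
        )
    return features


def analyze_cell(trace: RatioTrace, config: APConfig | None = None) -> CellSummary:
    """Per-cell summary: median APD90, RR and rate-corrected APD90.

    APs whose repolarization is truncated are excluded; the first AP has no
    preceding cycle and contributes to APD90 but not to cAPD90.  Cells with
    fewer than ``min_valid_aps`` valid APs are flagged (medians are NaN).
    With ``rr_mode='cell_mean'`` Bazett uses the cell's mean RR for every AP
    instead of the per-AP preceding interval.
    """
    cfg = config or APConfig()
    feats = extract_features(trace, cfg)
    valid = [f for f in feats if f.valid and f.apd90 is not None]
    apds = np.array([f.apd90 for f in valid], dtype=float)
    rrs = np.array([f.rr for f in valid if f.rr is not None], dtype=float)
    if cfg.rr_mode == "cell_mean" and len(rrs):
        mean_rr = float(np.mean(rrs))
        capds = np.array([bazett_correct(f.apd90, mean_rr) for f in valid], dtype=float)
    else:
        capds = np.array(
            [f.capd90 for f in valid if f.capd90 is not None], dtype=float
        )
    flagged = len(valid) < cfg.min_valid_aps
    return CellSummary(
        n_aps=len(feats),
        n_valid=len(valid),
        median_apd90=float(np.median(apds)) if len(apds) and not flagged else float("nan"),
        median_rr=float(np.median(rrs)) if len(rrs) and not flagged else float("nan"),
        median_capd90=float(np.median(capds)) if len(capds) and not flagged else float("nan"),
        flagged=flagged,
    )


# --------------------------------------------------------------------------
# patch-clamp IV analysis


def iv_curve(
    step_records: Sequence[tuple[float, np.ndarray]],
    capacitance: float,
    mode: str = "peak",
    end_window_fraction: float = 0.1,
) -> IVCurve:
    """Assemble an IV curve from voltage-step current traces.

    ``mode='peak'`` takes the signed extremum of each step current (the
    convention for inward currents such as I_CaL); ``mode='end'`` averages
    the terminal ``end_window_fraction`` of the step (delayed-rectifier
    convention).  Currents (pA) are normalized to ``capacitance`` (pF).
    """
    if capacitance <= 0:
        raise ValueError("capacitance must be positive")
    if mode not in ("peak", "end"):
        raise ValueError(f"mode must be peak|end, got {mode!r}")
    pots, dens = [], []
    for v, current in step_records:
        cur = np.asarray(current, dtype=float)
        if mode == "peak":
            val = cur[int(np.argmax(np.abs(cur)))] if len(cur) else 0.0
        else:
            k = max(1, int(round(end_window_fraction * len(cur))))
            val = float(np.mean(cur[-k:]))
        pots.append(float(v))
        dens.append(val / capacitance)
    return IVCurve(np.array(pots), np.array(dens), capacitance, mode)


def leak_subtract(curve: IVCurve, fit_range: tuple[float, float]) -> IVCurve:
    """Subtract a linear (ohmic) leak fitted on a sub-threshold voltage range."""
    lo, hi = fit_range
    mask = (curve.potentials >= lo) & (curve.potentials <= hi)
    if mask.sum() < 2:
        raise ValueError("leak fit range must contain at least 2 test potentials")
    slope, intercept = np.polyfit(curve.potentials[mask], curve.densities[mask], 1)
    logger.info("leak fit on [%g, %g] mV: g=%.4g, b=%.4g", lo, hi, slope, intercept)
    corrected = curve.densities - (slope * curve.potentials + intercept)
    return replace(curve, densities=corrected)


def drug_subtract(control: IVCurve, drug: IVCurve) -> IVCurve:
    """Drug-sensitive difference current: control minus drug, pointwise."""
    if not np.array_equal(control.potentials, drug.potentials):
        raise ValueError("IV curves must share the same test-potential grid")
    return IVCurve(
        control.potentials.copy(),
        control.densities - drug.densities,
        control.capacitance,
        control.mode,
    )


def extract_fpd(time: np.ndarray, signal: np.ndarray,
                search_window_ms: float = 1000.0) -> float:
    """Best-effort field-potential duration from one MEA beat (flagged utility).

    Heuristic only: FPD is read as the time from the sharp depolarization
    spike (extremal first difference) to the subsequent repolarization
    extremum.  Production FPD values normally come from vendor MEA software;
    this helper exists so the Bazett-correction path can be exercised
    end-to-end without one.
    """
    t = np.asarray(time, dtype=float)
    y = np.asarray(signal, dtype=float)
    d = np.diff(y)
    spike = int(np.argmax(np.abs(d)))
    dt = float(np.median(np.diff(t)))
    end = min(len(y), spike + int(search_window_ms / dt))
    tail = y[spike + 2 : end]
    if len(tail) < 3:
        raise ValueError("no repolarization window after the spike")
    base = float(np.median(y[: max(spike, 3)]))
    repol = spike + 2 + int(np.argmax(np.abs(tail - base)))
    return float(t[repol] - t[spike])
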
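"""Effective refractory period (RP) from programmed S1-S2 force recordings.

A tissue slice is paced at a constant S1 rate while an extra stimulus (S2)
follows each S1 at a programmed interstimulus interval; the interval is
stepped down block by block.  A block "responds" when its stimulus pairs
evoke two distinct contractions.  The RP is read out as the longest
interval whose block failed to evoke two distinct contractions; if no block
fails the RP lies below the scanned range, if all fail it lies above.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

logger = logging.getLogger(__name__)

BELOW_MIN = "below-min"
ABOVE_MAX = "above-max"
OK = "ok"


@dataclass(frozen=True)
class StimulationSchedule:
    """Ordered S1-S2 blocks: (interstimulus interval ms, block duration s)."""

    blocks: tuple[tuple[float, float], ...]
    s1_rate: float = 0.5  # Hz

    def __post_init__(self) -> None:
        intervals = [b[0] for b in self.blocks]
        if any(later >= earlier for earlier, later in zip(intervals, intervals[1:])):
            raise ValueError("interstimulus intervals must be strictly decreasing")
        if self.s1_rate <= 0:
            raise ValueError("s1_rate must be positive")

    @property
    def intervals(self) -> list[float]:
        return [b[0] for b in self.blocks]

    @property
    def s1_period_ms(self) -> float:
        return 1000.0 / self.s1_rate

    def pairs_per_block(self, block_index: int) -> int:
        return int(round(self.blocks[block_index][1] * self.s1_rate))

    def stimulus_table(self, t0_ms: float = 0.0) -> pd.DataFrame:
        """All S1/S2 stimulus times: columns time_ms, type, block."""
        rows = []
        t = t0_ms
        for bi, (interval, _dur) in enumerate(self.blocks):
            for _ in range(self.pairs_per_block(bi)):
                rows.append({"time_ms": t, "type": "S1", "block": bi})
                rows.append({"time_ms": t + interval, "type": "S2", "block": bi})
                t += self.s1_period_ms
        return pd.DataFrame(rows, columns=["time_ms", "type", "block"])

    @property
    def total_duration_ms(self) -> float:
        return sum(self.pairs_per_block(i) for i in range(len(self.blocks))) * self.s1_period_ms


def build_schedule(
    step: float,
    start: float = 1000.0,
    stop: float = 250.0,
    block_duration: float = 20.0,
    s1_rate: float = 0.5,
) -> StimulationSchedule:
    """Decreasing S1-S2 interval scan: start, start-step, ... down to >= stop.

    Defaults mirror the standard slice protocol (1000 -> 250 ms in blocks of
    20 s at 0.5 Hz S1, i.e. 10 pairs per block); the decrement ``step`` has
    no default of its own and must be chosen by the caller.
    """
    if start <= stop:
        raise ValueError("start interval must exceed stop interval")
    if step <= 0:
        raise ValueError("step must be positive")
    intervals = []
    v = start
    while v >= stop - 1e-9:
        intervals.append(round(v, 9))
        v -= step
    return StimulationSchedule(
        blocks=tuple((iv, block_duration) for iv in intervals), s1_rate=s1_rate
    )


@dataclass
class ForceTrace:
    """Contraction-force recording (mN) with its stimulus annotations."""

    time: np.ndarray
    force: np.ndarray
    stimuli: pd.DataFrame  # columns time_ms, type, block

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.time.shape != self.force.shape:
            raise ValueError("time and force must have equal length")

    @property
    def sampling_interval(self) -> float:
        return float(np.median(np.diff(self.time)))


@dataclass
class RPConfig:
    min_prominence_fraction: float = 0.2   # of the reference twitch amplitude
    min_peak_separation_ms: float = 100.0
    response_latency_ms: float = 300.0
    valley_fraction: float = 0.5
    smooth_ms: float = 25.0                # centered moving average before peak picking
    reference_amplitude: float | None = None  # estimated from S1 twitches when None


def _smooth(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return x
    kernel = np.ones(width)
    return np.convolve(x, kernel, mode="same") / np.convolve(
        np.ones_like(x), kernel, mode="same"
    )


@dataclass(frozen=True)
class RPResult:
    rp: float | None
    status: str  # "ok" | "below-min" | "above-max"
    per_block: pd.DataFrame  # interval, evoked_two, n_pairs, n_pairs_with_two
    monotone: bool

    def __post_init__(self) -> None:
        if self.status == OK and self.rp is None:
            raise ValueError("uncensored result requires an rp value")


def _reference_amplitude(trace: ForceTrace, config: RPConfig) -> float:
    """Median S1-evoked twitch amplitude over the whole recording."""
    if config.reference_amplitude is not None:
        return config.reference_amplitude
    base = float(np.percentile(trace.force, 5))
    s1 = trace.stimuli[trace.stimuli["type"] == "S1"]["time_ms"].to_numpy(dtype=float)
    amps = []
    for t in s1:
        mask = (trace.time >= t) & (trace.time <= t + config.response_latency_ms)
        if mask.any():
            amps.append(float(np.max(trace.force[mask])) - base)
    if not amps:
        raise ValueError("no S1 windows found to estimate the reference twitch")
    return float(np.median(amps))


def detect_twitches(
    trace: ForceTrace,
    window: tuple[float, float],
    config: RPConfig | None = None,
    reference_amplitude: float | None = None,
) -> pd.DataFrame:
    """Twitch peaks in a time window: columns peak_time, peak_force, prominence.

    Peaks must exceed ``min_prominence_fraction`` of the reference twitch
    amplitude and be separated by at least ``min_peak_separation_ms``.
    """
    cfg = config or RPConfig()
    ref = reference_amplitude
    if ref is None:
        ref = _reference_amplitude(trace, cfg)
    t0, t1 = window
    mask = (trace.time >= t0) & (trace.time <= t1)
    seg = trace.force[mask]
    seg_t = trace.time[mask]
    if len(seg) < 3 or ref <= 0:
        return pd.DataFrame(columns=["peak_time", "peak_force", "prominence"])
    dt = trace.sampling_interval
    seg = _smooth(seg, max(1, int(round(cfg.smooth_ms / dt)) | 1))
    distance = max(1, int(round(cfg.min_peak_separation_ms / dt)))
    peaks, props = sps.find_peaks(
        seg, prominence=cfg.min_prominence_fraction * ref, distance=distance
    )
    return pd.DataFrame(
        {
            "peak_time": seg_t[peaks],
            "peak_force": seg[peaks],
            "prominence": props["prominences"] if len(peaks) else np.array([]),
        }
    )


def classify_pair(
    trace: ForceTrace,
    s1_time: float,
    s2_time: float,
    config: RPConfig | None = None,
    reference_amplitude: float | None = None,
) -> bool:
    """Did this S1-S2 pair evoke two distinct contractions?

    True iff two twitch peaks are found, one within ``response_latency_ms``
    of each stimulus, with the inter-peak valley dropping below
    ``valley_fraction`` of the smaller peak (distinctness of the second
    contraction from the first).
    """
    cfg = config or RPConfig()
    ref = reference_amplitude
    if ref is None:
        ref = _reference_amplitude(trace, cfg)
    window = (s1_time, s2_time + cfg.response_latency_ms)
    peaks = detect_twitches(trace, window, cfg, reference_amplitude=ref)
    if len(peaks) < 2:
        return False
    # each peak belongs to its nearest preceding stimulus
    times = peaks["peak_time"].to_numpy(dtype=float)
    owner_s2 = times >= s2_time
    p1 = peaks[~owner_s2 & (times - s1_time <= cfg.response_latency_ms)]
    p2 = peaks[owner_s2 & (times - s2_time <= cfg.response_latency_ms)]
    if p1.empty or p2.empty:
        return False
    t_a = float(p1.iloc[p1["peak_force"].to_numpy().argmax()]["peak_time"])
    t_b = float(p2.iloc[p2["peak_force"].to_numpy().argmax()]["peak_time"])
    if t_b <= t_a:
        return False
    margin = 2.0 * cfg.smooth_ms
    sl = (trace.time >= window[0] - margin) & (trace.time <= window[1] + margin)
    sm = _smooth(trace.force[sl], max(1, int(round(cfg.smooth_ms / trace.sampling_interval)) | 1))
    sm_t = trace.time[sl]
    f_a = float(sm[np.argmin(np.abs(sm_t - t_a))])
    f_b = float(sm[np.argmin(np.abs(sm_t - t_b))])
    between = (sm_t > t_a) & (sm_t < t_b)
    if not between.any():
        return False
    valley = float(np.min(sm[between]))
    base = float(np.percentile(trace.force, 5))
    smaller = min(f_a, f_b) - base
    return (valley - base) < cfg.valley_fraction * smaller


def refractory_period(
    trace: ForceTrace,
    schedule: StimulationSchedule,
    config: RPConfig | None = None,
) -> RPResult:
    """RP from a programmed recording: longest interval failing to evoke
    two distinct contractions.

    Each block is classified by majority vote over its S1-S2 pairs.  If no
    block fails, the RP is censored below the smallest scanned interval; if
    every block fails, above the largest.  Blocks without any detectable S1
    twitch are excluded with a warning.  Non-monotone block patterns
    (a responding block below a failing one) are reported via ``monotone``
    and resolved by the literal longest-failing-interval rule.
    """
    cfg = config or RPConfig()
    ref = _reference_amplitude(trace, cfg)
    stim = trace.stimuli
    rows = []
    for bi, (interval, _dur) in enumerate(schedule.blocks):
        block = stim[stim["block"] == bi]
        s1s = block[block["type"] == "S1"]["time_ms"].to_numpy(dtype=float)
        s2s = block[block["type"] == "S2"]["time_ms"].to_numpy(dtype=float)
        n_pairs, n_two, n_s1_detected = 0, 0, 0
        for s1, s2 in zip(s1s, s2s):
            s1_peaks = detect_twitches(
                trace, (s1, s1 + cfg.response_latency_ms), cfg, reference_amplitude=ref
            )
            if not s1_peaks.empty:
                n_s1_detected += 1
            n_pairs += 1
            if classify_pair(trace, s1, s2, cfg, reference_amplitude=ref):
                n_two += 1
        if n_s1_detected == 0:
            logger.warning(
                "block %d (interval %g ms): no detectable S1 twitches, excluded", bi, interval
            )
            continue
        rows.append(
            {
                "interval": interval,
                "evoked_two": n_two * 2 > n_pairs,
                "n_pairs": n_pairs,
                "n_pairs_with_two": n_two,
            }
        )
    per_block = pd.DataFrame(rows, columns=["interval", "evoked_two", "n_pairs", "n_pairs_with_two"])
    if per_block.empty:
        raise ValueError("no classifiable blocks in the recording")

    failing = per_block[~per_block["evoked_two"]]
    # monotone: every responding interval is above every failing interval
    monotone = True
    if not failing.empty:
        max_fail = failing["interval"].max()
        responding_below = per_block[
            (per_block["evoked_two"]) & (per_block["interval"] < max_fail)
        ]
        monotone = responding_below.empty
        if not monotone:
            logger.warning("non-monotone block pattern; applying the literal rule")

    if failing.empty:
        return RPResult(rp=None, status=BELOW_MIN, per_block=per_block, monotone=monotone)
    if len(failing) == len(per_block):
        return RPResult(rp=None, status=ABOVE_MAX, per_block=per_block, monotone=monotone)
    return RPResult(
        rp=float(failing["interval"].max()), status=OK, per_block=per_block, monotone=monotone
    )


def rp_delta(post: RPResult, pre: RPResult) -> float:
    """Paired post-minus-pre RP change (NaN when either side is censored)."""
    if post.status != OK or pre.status != OK:
        return float("nan")
    return float(post.rp - pre.rp)
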
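"""Synthetic-data generators with recorded ground truth.

Every input the analysis pipeline consumes can be generated here at desk
scale: 3' UTR sets with planted canonical seed sites (and site-free
background, enforced by rejection sampling), paired expression profiles
with a controlled top-N overlap, piecewise-linear action-potential traces
with analytic APD90 truth, S1-S2 twitch-force recordings obeying a hard
refractory rule, differential-expression tables with planted target
shifts, and two-arm reporter-cell intensity tables.

Ground truth is always recorded before noise is applied, so noiseless runs
make downstream recovery exact up to discretization.  All generators are
bit-reproducible given their ``rng_seed``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .refractory import ForceTrace, StimulationSchedule
from .reporter import CellIntensity
from .targetome import (
    SeedFamily,
    SeedSite,
    UTRRecord,
    scan_sites_bruteforce,
    site_sequences,
)
from .traces import RatioTrace

logger = logging.getLogger(__name__)

_RNA = np.array(list("ACGU"))


class PlantingError(ValueError):
    """Requested site planting cannot be realized in the given UTR length."""


# ==========================================================================
# UTR sets with planted canonical sites


@dataclass
class UTRSimParams:
    """Parameters for a synthetic UTR set with planted seed sites.

    ``planted_sites`` maps gene id -> list of (family_id, site_type); every
    referenced family must appear in ``family_pool`` (family_id -> 7-nt
    seed).  Background sequence is rejection-sampled until it carries no
    canonical site for ANY family in the pool, so the planted table is the
    exact ground truth for a scanner.
    """

    n_genes: int
    utr_length: int
    family_pool: Mapping[str, str]
    planted_sites: Mapping[str, Sequence[tuple[str, str]]] = dc_field(default_factory=dict)
    gc_content: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.utr_length < 8:
            raise ValueError("need n_genes >= 1 and utr_length >= 8")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must be in [0, 1]")
        for gene, sites in self.planted_sites.items():
            for fam, _stype in sites:
                if fam not in self.family_pool:
                    raise ValueError(f"gene {gene}: unknown family {fam!r}")


def _random_background(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G U
    return rng.choice(_RNA, size=n, p=p)


def simulate_utrs(params: UTRSimParams) -> tuple[list[UTRRecord], pd.DataFrame]:
    """Generate one UTR per gene plus the exact planted-site table.

    Sites are placed at non-overlapping random positions; the remaining
    background is resampled until an exhaustive scan over the whole family
    pool finds exactly the planted sites and nothing else.  Returns
    ``(utrs, truth)`` where ``truth`` has columns gene_id, family_id,
    site_type, start, end.
    """
    rng = np.random.default_rng(params.rng_seed)
    families = [
        SeedFamily(family_id=fid, seed=seed) for fid, seed in sorted(params.family_pool.items())
    ]
    site_seq = {f.family_id: site_sequences(f.seed) for f in families}

    if len(params.planted_sites) > params.n_genes:
        raise ValueError("more genes with planted sites than n_genes")
    gene_ids = list(params.planted_sites)
    i = 0
    while len(gene_ids) < params.n_genes:
        cand = f"gene{i:03d}"
        if cand not in params.planted_sites:
            gene_ids.append(cand)
        i += 1
    gene_ids = sorted(gene_ids)

    utrs: list[UTRRecord] = []
    truth_rows: list[dict] = []
    for gene in gene_ids:
        plan = list(params.planted_sites.get(gene, []))
        lengths = [8 if st == "8mer" else 7 for _f, st in plan]
        if sum(lengths) > params.utr_length:
            raise PlantingError(
                f"gene {gene}: {sum(lengths)} nt of sites exceed UTR length {params.utr_length}"
            )

        placements = _place_sites(rng, plan, lengths, params.utr_length, gene)
        seq, placed = _fill_and_reject(
            rng, params, gene, placements, site_seq, families
        )
        utrs.append(UTRRecord(gene_id=gene, sequence="".join(seq)))
        truth_rows.extend(placed)

    truth = pd.DataFrame(
        truth_rows, columns=["gene_id", "family_id", "site_type", "start", "end"]
    )
    return utrs, truth.sort_values(["gene_id", "start"]).reset_index(drop=True)


def _place_sites(rng, plan, lengths, utr_length, gene, max_tries: int = 2000):
    """Non-overlapping random placements (start, fam, stype, length)."""
    for _ in range(max_tries):
        placements = []
        occupied: list[tuple[int, int]] = []
        ok = True
        for (fam, stype), ln in zip(plan, lengths):
            if stype not in ("8mer", "7mer-m8", "7mer-A1"):
                raise ValueError(f"gene {gene}: unknown site type {stype!r}")
            start = int(rng.integers(0, utr_length - ln + 1))
            # 2-nt buffer: an adjacent planted nucleotide could extend a
            # planted 7mer into an 8mer with no background base to resample
            if any(start - 2 < e and start + ln + 2 > s for s, e in occupied):
                ok = False
                break
            occupied.append((start, start + ln))
            placements.append((start, fam, stype, ln))
        if ok:
            return sorted(placements)
    raise PlantingError(f"gene {gene}: could not place {len(plan)} sites without overlap")


def _fill_and_reject(rng, params, gene, placements, site_seq, families,
                     max_rounds: int = 500):
    """Fill background and resample until the scan matches the plan exactly."""
    n = params.utr_length
    seq = _random_background(rng, n, params.gc_content)
    planted_mask = np.zeros(n, dtype=bool)
    expected: set[tuple[str, str, int]] = set()
    placed_rows = []
    for start, fam, stype, ln in placements:
        s = site_seq[fam][stype]
        seq[start : start + ln] = list(s)
        planted_mask[start : start + ln] = True
        expected.add((fam, stype, start))
        placed_rows.append(
            {"gene_id": gene, "family_id": fam, "site_type": stype,
             "start": start, "end": start + ln}
        )

    record = UTRRecord(gene_id=gene, sequence="".join(seq))
    for _ in range(max_rounds):
        found: set[tuple[str, str, int]] = set()
        for famobj in families:
            for site in scan_sites_bruteforce(record, famobj):
                found.add((site.family_id, site.site_type, site.start))
        spurious = found - expected
        missing = expected - found
        if not spurious and not missing:
            return seq, placed_rows
        # resample background positions inside every offending window
        touched = False
        offending = spurious | missing
        for fam, stype, start in offending:
            ln = 8 if stype == "8mer" else 7
            lo = max(0, start - 1)
            hi = min(n, start + ln + 1)
            for i in range(lo, hi):
                if not planted_mask[i]:
                    seq[i] = rng.choice(_RNA)
                    touched = True
        if not touched:
            raise PlantingError(
                f"gene {gene}: planted sites conflict with the family pool "
                f"(cannot remove {sorted(offending)} by background resampling)"
            )
        record = UTRRecord(gene_id=gene, sequence="".join(seq))
    raise PlantingError(f"gene {gene}: rejection sampling did not converge")


def random_family_pool(n_families: int, rng_seed: int = 0) -> dict[str, str]:
    """Random distinct 7-nt seeds, keyed fam000.., safe for site planting.

    Candidate seeds whose canonical site strings contain (or are contained
    in) another family's site strings are rejected: such pairs make some
    plantings unresolvable, because one family's planted site would always
    scan as a second family's site with no background base to resample.
    """
    rng = np.random.default_rng(rng_seed)
    pool: dict[str, str] = {}
    strings: list[str] = []
    i = 0
    while len(pool) < n_families:
        seed = "".join(rng.choice(_RNA, size=7))
        cand = list(site_sequences(seed).values())
        clash = any(
            a in b or b in a for a in cand for b in strings
        )
        if not clash and seed not in set(pool.values()):
            pool[f"fam{i:03d}"] = seed
            strings.extend(cand)
            i += 1
    return pool


# ==========================================================================
# paired expression profiles with a controlled top-N overlap


def simulate_expression(
    n_entities: int,
    n_expressed_in_both: int,
    rng_seed: int = 0,
    n_top: int = 100,
    id_prefix: str = "mir",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two abundance tables whose top-``n_top`` sets share exactly
    ``n_expressed_in_both`` ids.

    Emulates profiling the same molecular species in two tissues and gating
    on joint high expression.  Abundances follow a strict geometric rank
    series (no ties).  Requires ``n_entities >= 2*n_top - n_expressed_in_both``
    so the two top lists can differ outside the shared core.
    """
    if n_expressed_in_both > min(n_top, n_entities):
        raise ValueError("n_expressed_in_both cannot exceed n_top or n_entities")
    if n_entities < 2 * n_top - n_expressed_in_both:
        raise ValueError(
            "n_entities too small to make both top lists with the requested overlap"
        )
    rng = np.random.default_rng(rng_seed)
    ids = np.array([f"{id_prefix}{i:04d}" for i in range(n_entities)])
    perm = rng.permutation(n_entities)
    shared = ids[perm[:n_expressed_in_both]]
    n_fill = n_top - n_expressed_in_both
    a_only = ids[perm[n_expressed_in_both : n_expressed_in_both + n_fill]]
    b_only = ids[perm[n_expressed_in_both + n_fill : n_expressed_in_both + 2 * n_fill]]
    rest = ids[perm[n_expressed_in_both + 2 * n_fill :]]

    def table(top_ids: np.ndarray) -> pd.DataFrame:
        low_ids = np.array([i for i in ids if i not in set(top_ids)])
        order_top = rng.permutation(len(top_ids))
        order_low = rng.permutation(len(low_ids))
        ranked = np.concatenate([top_ids[order_top], low_ids[order_low]])
        abundance = 1e6 * np.power(0.95, np.arange(n_entities))
        df = pd.DataFrame({"id": ranked, "abundance": abundance})
        return df.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)

    top_a = np.concatenate([shared, a_only])
    top_b = np.concatenate([shared, b_only])
    _ = rest
    return table(top_a), table(top_b)


# ==========================================================================
# piecewise-linear action-potential traces


@dataclass
class APWaveformParams:
    """Piecewise-linear AP train: baseline -> upstroke -> plateau -> linear
    repolarization -> baseline.

    The analytic APD90 of this shape is ``upstroke + plateau + 0.9 x
    repolarization`` (time from upstroke onset to the 90%-repolarization
    crossing on the falling limb).  ``upstroke_duration = 0`` gives an
    instant rise.  Noise (white, sd ``noise_sd``) and linear drift
    (``drift_per_s``, photobleaching surrogate) are added after the ground
    truth is recorded.  All times ms.
    """

    baseline: float = 1.0
    amplitude: float = 1.0
    upstroke_duration: float = 5.0
    plateau_duration: float = 150.0
    repolarization_duration: float = 250.0
    beat_interval: float = 1000.0
    n_beats: int = 10
    sampling_interval: float = 1.0
    noise_sd: float = 0.0
    drift_per_s: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.beat_interval <= (
            self.upstroke_duration + self.plateau_duration + self.repolarization_duration
        ):
            raise ValueError("beat_interval must exceed the AP footprint")
        if self.upstroke_duration > 0 and self.sampling_interval > self.upstroke_duration:
            raise ValueError(
                "sampling_interval too coarse to represent the upstroke "
                f"({self.sampling_interval} > {self.upstroke_duration} ms)"
            )

    @property
    def true_apd90(self) -> float:
        return (
            self.upstroke_duration
            + self.plateau_duration
            + 0.9 * self.repolarization_duration
        )

    def true_apd(self, level: float) -> float:
        """Analytic APD at any repolarization level (0.9 -> APD90)."""
        return (
            self.upstroke_duration
            + self.plateau_duration
            + level * self.repolarization_duration
        )


@dataclass(frozen=True)
class APTruth:
    onset_times: np.ndarray    # ms, upstroke onset per beat
    apd90: np.ndarray          # analytic APD90 per beat
    rr: np.ndarray             # preceding interval per beat (NaN for the first)


def simulate_ap_trace(params: APWaveformParams) -> tuple[RatioTrace, APTruth]:
    """Synthesize an optical AP train with analytic per-beat ground truth."""
    p = params
    rng = np.random.default_rng(p.rng_seed)
    lead = 0.5 * p.beat_interval
    duration = lead + p.n_beats * p.beat_interval if p.n_beats else 2000.0
    time = np.arange(0.0, duration, p.sampling_interval)

    up = max(p.upstroke_duration, 1e-6)
    xs, ys = [0.0], [p.baseline]
    onsets = []
    for k in range(p.n_beats):
        t_on = lead + k * p.beat_interval
        onsets.append(t_on)
        xs += [t_on, t_on + up, t_on + up + p.plateau_duration,
               t_on + up + p.plateau_duration + p.repolarization_duration]
        ys += [p.baseline, p.baseline + p.amplitude, p.baseline + p.amplitude, p.baseline]
    xs.append(duration)
    ys.append(p.baseline)
    signal = np.interp(time, xs, ys)

    onset_arr = np.array(onsets)
    truth = APTruth(
        onset_times=onset_arr,
        apd90=np.full(p.n_beats, p.true_apd90),
        rr=np.concatenate([[np.nan], np.diff(onset_arr)]) if p.n_beats else np.array([]),
    )
    noisy = signal + rng.normal(0.0, p.noise_sd, size=signal.shape) if p.noise_sd > 0 else signal.copy()
    noisy = noisy + p.drift_per_s * time / 1000.0
    trace = RatioTrace(time=time, signal=noisy, metadata={"synthetic": True})
    return trace, truth


def simulate_two_channel_recording(
    params: APWaveformParams, denominator_value: float = 2.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray, RatioTrace]:
    """Two raw emission channels whose ratio is the AP waveform.

    Returns ``(time, numerator, denominator, ratio_truth)``; channel noise
    uses the params' ``noise_sd`` scaled by the denominator so the noiseless
    case reproduces the stored ratio exactly.
    """
    p_clean = APWaveformParams(**{**params.__dict__, "noise_sd": 0.0, "drift_per_s": 0.0})
    trace, _ = simulate_ap_trace(p_clean)
    rng = np.random.default_rng(params.rng_seed + 1)
    den = np.full_like(trace.signal, denominator_value)
    num = trace.signal * denominator_value
    if params.noise_sd > 0:
        num = num + rng.normal(0.0, params.noise_sd * denominator_value, size=num.shape)
    return trace.time, num, den, trace


# ==========================================================================
# S1-S2 twitch-force recordings


@dataclass
class ForceSimParams:
    """Twitch-force generator with a hard refractory rule.

    A second stimulus evokes a full twitch iff the interstimulus interval
    exceeds ``true_rp``; otherwise the response is scaled by
    ``refractory_response_fraction`` (0 by default — the binary rule).
    """

    true_rp: float
    twitch_peak: float = 1.0
    twitch_rise: float = 40.0
    twitch_decay: float = 120.0
    refractory_response_fraction: float = 0.0
    noise_sd: float = 0.0
    sampling_interval: float = 2.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 250.0 < self.true_rp < 1000.0:
            logger.info("true_rp %g ms lies outside the standard scan range", self.true_rp)
        if not 0.0 <= self.refractory_response_fraction <= 1.0:
            raise ValueError("refractory_response_fraction must be in [0, 1]")
        if self.twitch_peak <= 0:
            raise ValueError("twitch_peak must be positive")


def _twitch_kernel(p: ForceSimParams) -> np.ndarray:
    t = np.arange(0.0, 5.0 * p.twitch_decay, p.sampling_interval)
    shape = (1.0 - np.exp(-t / p.twitch_rise)) * np.exp(-t / p.twitch_decay)
    return p.twitch_peak * shape / shape.max()


def simulate_force_trace(
    params: ForceSimParams, schedule: StimulationSchedule
) -> tuple[ForceTrace, float]:
    """Force recording following the programmed S1-S2 schedule.

    Every S1 evokes a full twitch; each S2 follows the refractory rule
    against ``params.true_rp``.  Returns the annotated trace and the true
    RP.
    """
    stim = schedule.stimulus_table()
    t_end = float(stim["time_ms"].max()) + 6.0 * params.twitch_decay
    time = np.arange(0.0, t_end, params.sampling_interval)
    force = np.zeros_like(time)
    kernel = _twitch_kernel(params)

    s1_times = stim[stim["type"] == "S1"]["time_ms"].to_numpy(dtype=float)
    for _, row in stim.iterrows():
        t_s = float(row["time_ms"])
        if row["type"] == "S1":
            scale = 1.0
        else:
            prev_s1 = s1_times[s1_times <= t_s]
            interval = t_s - prev_s1[-1]
            scale = 1.0 if interval > params.true_rp else params.refractory_response_fraction
        if scale == 0.0:
            continue
        i0 = int(round(t_s / params.sampling_interval))
        i1 = min(len(force), i0 + len(kernel))
        force[i0:i1] += scale * kernel[: i1 - i0]

    if params.noise_sd > 0:
        rng = np.random.default_rng(params.rng_seed)
        force = force + rng.normal(0.0, params.noise_sd, size=force.shape)
    return ForceTrace(time=time, force=force, stimuli=stim), params.true_rp


# ==========================================================================
# differential-expression tables with planted target shifts


@dataclass
class DESimParams:
    """DE-table generator: targets carry a mean log2FC of ``target_shift``.

    Non-targets are centered at zero; a fraction ``frac_null_de`` of them
    are truly DE with effect ``null_de_effect`` (random sign).  FDR values
    are Benjamini-Hochberg-adjusted two-sided normal p-values of the
    observed log2FC against the null sd, so larger |shift| means smaller
    FDR on average.
    """

    n_genes: int
    n_targets: int
    target_shift: float = -0.5
    sd_log2fc: float = 0.2
    frac_null_de: float = 0.0
    null_de_effect: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_targets <= self.n_genes:
            raise ValueError("need 0 <= n_targets <= n_genes")
        if self.sd_log2fc <= 0:
            raise ValueError("sd_log2fc must be positive")
        if not 0.0 <= self.frac_null_de <= 1.0:
            raise ValueError("frac_null_de must be in [0, 1]")


def simulate_de_table(params: DESimParams) -> tuple[pd.DataFrame, np.ndarray]:
    """Generate (DE table, boolean target-label vector).

    Table columns: gene_id, log2fc, fdr.  With ``target_shift == 0`` (and
    ``frac_null_de == 0``) targets and non-targets are exchangeable draws
    from the same null.
    """
    p = params
    rng = np.random.default_rng(p.rng_seed)
    genes = np.array([f"gene{i:05d}" for i in range(p.n_genes)])
    is_target = np.zeros(p.n_genes, dtype=bool)
    is_target[rng.choice(p.n_genes, size=p.n_targets, replace=False)] = True

    mean = np.zeros(p.n_genes)
    mean[is_target] = p.target_shift
    non_target_idx = np.flatnonzero(~is_target)
    n_null_de = int(round(p.frac_null_de * len(non_target_idx)))
    if n_null_de:
        chosen = rng.choice(non_target_idx, size=n_null_de, replace=False)
        mean[chosen] = p.null_de_effect * rng.choice([-1.0, 1.0], size=n_null_de)

    lfc = rng.normal(mean, p.sd_log2fc)
    pvals = 2.0 * stats.norm.sf(np.abs(lfc) / p.sd_log2fc)
    fdr = _benjamini_hochberg(pvals)
    table = pd.DataFrame({"gene_id": genes, "log2fc": lfc, "fdr": fdr})
    return table, is_target


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    q = p[order] * m / (np.arange(m) + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out


# ==========================================================================
# reporter-cell intensity tables


def simulate_reporter_cells(
    n_cells: int,
    control_mean_ratio: float = 1.0,
    repression_factor: float = 1.0,
    cv: float = 0.1,
    rng_seed: int = 0,
    rfp_mean: float = 1000.0,
) -> tuple[list[CellIntensity], list[CellIntensity]]:
    """Two arms of per-cell GFP/RFP intensities: (treated, control).

    Treated ratios are centered at ``control_mean_ratio x
    repression_factor``.  Per-cell ratio variation is mean-preserving
    log-normal with coefficient of variation ``cv`` (``cv = 0`` gives exact
    ratios); RFP varies log-normally around ``rfp_mean`` to emulate
    expression differences between cells.
    """
    if not 0.0 < repression_factor <= 1.0:
        raise ValueError("repression_factor must be in (0, 1]")
    if cv < 0:
        raise ValueError("cv must be non-negative")
    rng = np.random.default_rng(rng_seed)

    def arm(mean_ratio: float, label: str) -> list[CellIntensity]:
        if cv > 0:
            sigma = math.sqrt(math.log1p(cv**2))
            ratios = mean_ratio * np.exp(
                rng.normal(0.0, sigma, n_cells) - sigma**2 / 2.0
            )
        else:
            ratios = np.full(n_cells, mean_ratio)
        rfp = rfp_mean * np.exp(rng.normal(0.0, 0.3, n_cells))
        return [
            CellIntensity(f"{label}_{i:04d}", float(r * f), float(f), label)
            for i, (r, f) in enumerate(zip(ratios, rfp))
        ]

    treated = arm(control_mean_ratio * repression_factor, "treated")
    control = arm(control_mean_ratio, "control")
    return treated, control
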
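"""Targetome set statistics.

Hypergeometric (Fisher exact) over-representation of a predicted targetome
in disease/GO term gene sets, the differential-expression filters used to
call repressed and derepressed genes, the reciprocal-regulation set logic,
and the target-vs-background fold-change shift test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]

    def __init__(self, name: str, members: Iterable[str]):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "members", frozenset(members))

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class EnrichmentResult:
    """Over-representation of a targetome in one term.

    ``contribution`` is the fraction of the term's genes hit by the
    targetome (overlap / term_size), the bubble-size quantity of a classic
    enrichment plot.
    """

    term: str
    overlap: int
    term_size: int
    target_size: int
    universe_size: int
    p_value: float
    contribution: float


def fisher_enrichment(
    targets: GeneSet,
    terms: Sequence[GeneSet],
    universe: GeneSet,
    correct: bool = False,
) -> list[EnrichmentResult]:
    """One-sided Fisher exact (hypergeometric upper tail) per term.

    The 2x2 table classifies the universe by membership in the targetome and
    in the term; the p-value is the probability of an overlap at least as
    large under random draws, i.e. ``hypergeom.sf(overlap-1, N, K, n)``.
    Results are sorted ascending by p-value (term name breaks ties).

    ``correct=True`` applies Benjamini-Hochberg across the supplied terms
    (off by default; raw p-values are the primary output).
    """
    if not universe.members:
        raise ValueError("empty universe")
    uni = universe.members
    tgt = targets.members & uni
    if targets.members - uni:
        raise ValueError("targets not contained in universe")
    n_draw = len(tgt)
    N = len(uni)
    results = []
    for term in terms:
        if term.members - uni:
            raise ValueError(f"term {term.name!r} not contained in universe")
        K = len(term.members)
        k = len(term.members & tgt)
        p = float(stats.hypergeom.sf(k - 1, N, K, n_draw))
        results.append(
            EnrichmentResult(
                term=term.name,
                overlap=k,
                term_size=K,
                target_size=n_draw,
                universe_size=N,
                p_value=min(p, 1.0),
                contribution=(k / K) if K else 0.0,
            )
        )
    results.sort(key=lambda r: (r.p_value, r.term))
    if correct:
        logger.info("applying Benjamini-Hochberg correction over %d terms", len(results))
        ps = np.array([r.p_value for r in results])
        m = len(ps)
        q = ps * m / (np.arange(m) + 1)
        q = np.minimum.accumulate(q[::-1])[::-1]
        results = [
            EnrichmentResult(
                r.term, r.overlap, r.term_size, r.target_size,
                r.universe_size, float(min(qi, 1.0)), r.contribution,
            )
            for r, qi in zip(results, q)
        ]
    return results


def fisher_enrichment_bruteforce(
    targets: GeneSet, term: GeneSet, universe: GeneSet
) -> float:
    """Enumeration oracle for the one-sided enrichment p-value.

    Counts, over all C(N, n) equally likely target draws from the universe,
    the fraction whose overlap with the term is >= the observed overlap.
    Exact rational arithmetic; only feasible for small universes.
    """
    uni = sorted(universe.members)
    N = len(uni)
    K = len(term.members & universe.members)
    n = len(targets.members & universe.members)
    observed = len(targets.members & term.members)
    total = math.comb(N, n)
    favorable = sum(
        math.comb(K, k) * math.comb(N - K, n - k)
        for k in range(observed, min(K, n) + 1)
        if n - k <= N - K
    )
    return favorable / total


def de_filter(
    table: pd.DataFrame,
    min_change: float = 0.30,
    max_fdr: float = 0.05,
    direction: str = "both",
    down_rule: str = "linear",
) -> GeneSet:
    """Differentially expressed genes passing fold-change and FDR filters.

    ``table`` needs columns ``gene_id``, ``log2fc``, ``fdr``.  A gene
    passes when ``fdr < max_fdr`` and its linear fold change differs from 1
    by more than ``min_change`` in the requested ``direction``
    (``up`` | ``down`` | ``both``).

    For up-regulation the threshold is FC > 1 + min_change (identically
    log2FC > log2(1.3) at the default).  For down-regulation two readings
    exist: ``down_rule='linear'`` (default) takes FC < 1 - min_change
    (a 30% drop, FC < 0.70); ``down_rule='log'`` takes the log-symmetric
    FC < 1/(1 + min_change) ~ 0.769.  The choice is logged.
    """
    if direction not in ("up", "down", "both"):
        raise ValueError(f"direction must be up|down|both, got {direction!r}")
    if down_rule not in ("linear", "log"):
        raise ValueError(f"down_rule must be linear|log, got {down_rule!r}")
    if table.empty:
        return GeneSet(f"de_{direction}", ())

    fc = np.exp2(pd.to_numeric(table["log2fc"]).to_numpy(dtype=float))
    fdr = pd.to_numeric(table["fdr"]).to_numpy(dtype=float)
    genes = table["gene_id"].astype(str).to_numpy()

    up_cut = 1.0 + min_change
    down_cut = (1.0 - min_change) if down_rule == "linear" else 1.0 / (1.0 + min_change)
    logger.info("de_filter: up FC > %.4f, down FC < %.4f (%s rule)", up_cut, down_cut, down_rule)

    keep = fdr < max_fdr
    if direction == "up":
        keep &= fc > up_cut
    elif direction == "down":
        keep &= fc < down_cut
    else:
        keep &= (fc > up_cut) | (fc < down_cut)
    return GeneSet(f"de_{direction}", genes[keep])


def reciprocal_set(down_in_mimic: GeneSet, up_in_antimir: GeneSet) -> GeneSet:
    """Genes repressed by the mimic AND derepressed by the inhibitor."""
    return GeneSet("reciprocal", down_in_mimic.members & up_in_antimir.members)


@dataclass(frozen=True)
class ShiftTestResult:
    statistic: float          # rank-sum (Mann-Whitney U) statistic
    p_value: float            # two-sided rank-sum p
    ks_statistic: float
    ks_p_value: float
    median_shift: float       # median(target log2FC) - median(background log2FC)
    n_targets: int
    n_background: int


def target_shift_test(table: pd.DataFrame, target_ids: GeneSet | Iterable[str]) -> ShiftTestResult:
    """Compare target vs background log2 fold-change distributions.

    Targets are the genes in ``target_ids`` present in the table; background
    is every other gene.  Primary test: two-sided Wilcoxon rank-sum
    (Mann-Whitney U); the Kolmogorov-Smirnov statistic is reported
    alongside.  Effect size is the difference in median log2FC.
    """
    ids = target_ids.members if isinstance(target_ids, GeneSet) else frozenset(target_ids)
    is_target = table["gene_id"].astype(str).isin(ids).to_numpy()
    lfc = pd.to_numeric(table["log2fc"]).to_numpy(dtype=float)
    tgt, bg = lfc[is_target], lfc[~is_target]
    if len(tgt) < 2 or len(bg) < 2:
        raise ValueError(
            f"need >= 2 genes per group, got {len(tgt)} targets / {len(bg)} background"
        )
    if np.ptp(lfc) == 0:
        # all fold changes identical: no evidence of a shift by convention
        u = len(tgt) * len(bg) / 2.0
        return ShiftTestResult(u, 1.0, 0.0, 1.0, 0.0, len(tgt), len(bg))
    u_res = stats.mannwhitneyu(tgt, bg, alternative="two-sided")
    ks_res = stats.ks_2samp(tgt, bg)
    return ShiftTestResult(
        statistic=float(u_res.statistic),
        p_value=float(u_res.pvalue),
        ks_statistic=float(ks_res.statistic),
        ks_p_value=float(ks_res.pvalue),
        median_shift=float(np.median(tgt) - np.median(bg)),
        n_targets=len(tgt),
        n_background=len(bg),
    )


def enrichment_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term": r.term,
                "overlap": r.overlap,
                "term_size": r.term_size,
                "target_size": r.target_size,
                "universe_size": r.universe_size,
                "p_value": r.p_value,
                "contribution": r.contribution,
            }
            for r in results
        ]
    )
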
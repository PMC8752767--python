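"""Double-fluorescent reporter quantification.

A GFP whose transcript carries the 3' UTR under study is co-expressed with
RFP from the same construct; RFP is the internal control, so the per-cell
GFP/RFP ratio reads out miRNA repression of that UTR.  Quantification is
per-cell ratio first, then the arm mean; the treated-arm mean normalized to
the control-arm mean is the repression readout (1 = no repression).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CellIntensity:
    """Per-cell mean fluorescence; RFP must be detected (> 0)."""

    cell_id: str
    gfp_mean: float
    rfp_mean: float
    condition: str = ""

    def __post_init__(self) -> None:
        if self.gfp_mean < 0:
            raise ValueError(f"cell {self.cell_id}: negative GFP intensity")


@dataclass(frozen=True)
class RepressionResult:
    normalized_ratio: float   # treated mean GFP/RFP over control mean GFP/RFP
    dispersion: float         # standard error of the normalized ratio (delta method)
    n_treated: int
    n_control: int
    p_value: float
    test: str = "ranksum"


def cell_ratios(
    cells: Sequence[CellIntensity] | pd.DataFrame,
    return_rejected: bool = False,
) -> np.ndarray | tuple[np.ndarray, int]:
    """Per-cell GFP/RFP ratios; cells with RFP <= 0 are rejected and counted."""
    if isinstance(cells, pd.DataFrame):
        gfp = pd.to_numeric(cells["gfp"]).to_numpy(dtype=float)
        rfp = pd.to_numeric(cells["rfp"]).to_numpy(dtype=float)
    else:
        gfp = np.array([c.gfp_mean for c in cells], dtype=float)
        rfp = np.array([c.rfp_mean for c in cells], dtype=float)
    ok = rfp > 0
    n_rejected = int((~ok).sum())
    if n_rejected:
        logger.warning("%d cells rejected (RFP <= 0)", n_rejected)
    ratios = gfp[ok] / rfp[ok]
    return (ratios, n_rejected) if return_rejected else ratios


def normalized_repression(
    treated: Sequence[CellIntensity] | pd.DataFrame,
    control: Sequence[CellIntensity] | pd.DataFrame,
    test: str = "ranksum",
) -> RepressionResult:
    """Treated mean GFP/RFP normalized to the control arm, with a two-group test.

    ``test`` is ``ranksum`` (default, Mann-Whitney U two-sided) or ``ttest``
    (Welch).  The dispersion is the delta-method standard error of the
    ratio of arm means.  At least 3 cells per arm are required.
    """
    rt = cell_ratios(treated)
    rc = cell_ratios(control)
    if len(rt) < 3 or len(rc) < 3:
        raise ValueError(
            f"need >= 3 cells per arm, got {len(rt)} treated / {len(rc)} control"
        )
    mt, mc = float(np.mean(rt)), float(np.mean(rc))
    if mc <= 0:
        raise ValueError("control arm mean ratio must be positive")
    ratio = mt / mc
    se_t = float(np.std(rt, ddof=1)) / np.sqrt(len(rt))
    se_c = float(np.std(rc, ddof=1)) / np.sqrt(len(rc))
    if mt > 0:
        se = ratio * float(np.hypot(se_t / mt, se_c / mc))
    else:
        se = se_t / mc
    if np.ptp(np.concatenate([rt, rc])) == 0:
        p = 1.0
    elif test == "ranksum":
        p = float(stats.mannwhitneyu(rt, rc, alternative="two-sided").pvalue)
    elif test == "ttest":
        p = float(stats.ttest_ind(rt, rc, equal_var=False).pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")
    return RepressionResult(
        normalized_ratio=ratio,
        dispersion=se,
        n_treated=len(rt),
        n_control=len(rc),
        p_value=p,
        test=test,
    )


def cells_from_frame(table: pd.DataFrame) -> list[CellIntensity]:
    """Build CellIntensity records from a table (cell_id, gfp, rfp[, condition])."""
    cond = table["condition"] if "condition" in table.columns else [""] * len(table)
    return [
        CellIntensity(str(i), float(g), float(r), str(c))
        for i, g, r, c in zip(table["cell_id"], table["gfp"], table["rfp"], cond)
    ]
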
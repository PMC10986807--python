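"""Welch's t-test screen of baseline case vs healthy-control intensities.

Dimensionality reduction for the regression stage: every protein is
tested case-baseline vs control with Welch's unequal-variance t-test and
proteins with raw P below the threshold (0.05 by default, deliberately
unadjusted — this is a prioritization filter, not an inference step) are
retained, with their up/down direction relative to controls.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ProteinMatrix


@dataclass
class DEResult:
    protein_id: str
    t_stat: float
    df: float
    p_value: float
    direction: str  # up | down (case minus control mean)
    n_case: int
    n_control: int


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch's two-sample t-test: returns (t, Welch–Satterthwaite df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least two observations")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        raise ValueError("both groups have zero variance")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def prioritize(
    matrix: ProteinMatrix, alpha: float = 0.05
) -> tuple[list[str], list[DEResult], int, int]:
    """Screen all proteins; retain those with raw p < alpha.

    Uses baseline case samples (pretreatment, high disease activity)
    against controls; month-3 samples are excluded. Requires a complete
    (imputed) matrix.

    Returns (retained ids, per-protein results, n_up, n_down) where the
    up/down counts refer to the retained set.
    """
    if matrix.values.isna().any().any():
        raise ValueError("prioritize expects an imputed (complete) matrix")
    meta = matrix.sample_meta
    case_rows = (meta["role"] == "case") & (meta["timepoint"] == "baseline")
    ctrl_rows = meta["role"] == "control"
    if case_rows.sum() < 2 or ctrl_rows.sum() < 2:
        raise ValueError("need at least two baseline cases and two controls")
    cases = matrix.values.loc[case_rows].to_numpy()
    ctrls = matrix.values.loc[ctrl_rows].to_numpy()

    res = stats.ttest_ind(cases, ctrls, axis=0, equal_var=False)
    mean_diff = cases.mean(axis=0) - ctrls.mean(axis=0)
    results = [
        DEResult(
            protein_id=pid,
            t_stat=float(res.statistic[j]),
            df=float(res.df[j]),
            p_value=float(res.pvalue[j]),
            direction="up" if mean_diff[j] >= 0 else "down",
            n_case=int(case_rows.sum()),
            n_control=int(ctrl_rows.sum()),
        )
        for j, pid in enumerate(matrix.protein_ids)
    ]
    retained = [r.protein_id for r in results if r.p_value < alpha]
    retained_set = set(retained)
    n_up = sum(1 for r in results
               if r.protein_id in retained_set and r.direction == "up")
    n_down = len(retained) - n_up
    return retained, results, n_up, n_down


def results_to_frame(results: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.protein_id, r.t_stat, r.df, r.p_value, r.direction,
          r.n_case, r.n_control) for r in results],
        columns=["protein_id", "t", "df", "p", "direction",
                 "n_case", "n_control"],
    ).set_index("protein_id")


def write_results(results: list[DEResult], path: str | Path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", float_format="%.6g")


def write_retained(retained: list[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{p}\n" for p in retained))


def read_retained(path: str | Path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


__all__ = [
    "DEResult",
    "welch_t",
    "prioritize",
    "results_to_frame",
    "write_results",
    "write_retained",
    "read_retained",
]
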
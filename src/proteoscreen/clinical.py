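"""Disease-activity scoring for 28-joint RA outcome measures.

Implements the four-component DAS28-CRP score

    DAS28 = 0.56*sqrt(TJC28) + 0.28*sqrt(SJC28)
          + 0.36*ln(hsCRP + 1) + 0.014*VAS-GH + 0.96

with hsCRP in mg/L and VAS-GH in mm, plus the derived binary outcomes:
remission (DAS28 strictly below 2.6) and the EULAR good/moderate/none
response category from attained score and improvement from baseline.
For modelling, "poor" response means the EULAR "none" category.

The constant-bearing DAS28-CRP(4) variant is used; this is the canonical
four-component form matching TJC, SJC, VAS-GH and CRP as inputs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

REMISSION_CUTOFF = 2.6
LOW_ACTIVITY_CUTOFF = 3.2
HIGH_ACTIVITY_CUTOFF = 5.1

# hsCRP assay floor (mg/L) applied to reported zeros before scoring
HSCRP_FLOOR = 0.1

TIMEPOINTS = ("baseline", "month3", "month6")
COMPONENT_COLUMNS = ("tjc28", "sjc28", "vas_gh", "hscrp")


def das28_crp(tjc28, sjc28, hscrp, vas_gh):
    """Four-component DAS28-CRP. Accepts scalars or arrays.

    Components must satisfy: joint counts in {0..28}, VAS-GH in [0, 100] mm,
    hsCRP >= 0 mg/L.
    """
    tjc28 = np.asarray(tjc28, dtype=float)
    sjc28 = np.asarray(sjc28, dtype=float)
    hscrp = np.asarray(hscrp, dtype=float)
    vas_gh = np.asarray(vas_gh, dtype=float)
    if np.any((tjc28 < 0) | (tjc28 > 28)) or np.any((sjc28 < 0) | (sjc28 > 28)):
        raise ValueError("joint counts must lie in [0, 28]")
    if np.any((vas_gh < 0) | (vas_gh > 100)):
        raise ValueError("VAS-GH must lie in [0, 100] mm")
    if np.any(hscrp < 0):
        raise ValueError("hsCRP must be non-negative (mg/L)")
    score = (
        0.56 * np.sqrt(tjc28)
        + 0.28 * np.sqrt(sjc28)
        + 0.36 * np.log(hscrp + 1.0)
        + 0.014 * vas_gh
        + 0.96
    )
    return score if score.ndim else float(score)


def remission_flag(das28):
    """DAS28 remission: score strictly below 2.6."""
    das28 = np.asarray(das28, dtype=float)
    if np.any(das28 < 0):
        raise ValueError("DAS28 must be non-negative")
    flag = das28 < REMISSION_CUTOFF
    return flag if flag.ndim else bool(flag)


def eular_response(das28_baseline, das28_attained):
    """EULAR response category from baseline and attained DAS28.

    good:     attained <= 3.2 and improvement > 1.2
    none:     improvement <= 0.6, or attained > 5.1 with improvement <= 1.2
    moderate: everything else
    """
    b = np.asarray(das28_baseline, dtype=float)
    a = np.asarray(das28_attained, dtype=float)
    if np.any(b < 0) or np.any(a < 0):
        raise ValueError("DAS28 scores must be non-negative")
    delta = b - a
    good = (a <= LOW_ACTIVITY_CUTOFF) & (delta > 1.2)
    none = (delta <= 0.6) | ((a > HIGH_ACTIVITY_CUTOFF) & (delta <= 1.2))
    out = np.where(good, "good", np.where(none, "none", "moderate"))
    return out if out.ndim else str(out)


def eular_poor(das28_baseline, das28_attained):
    """Dichotomized EULAR outcome for logistic models: poor = 'none'."""
    cat = np.asarray(eular_response(das28_baseline, das28_attained))
    flag = cat == "none"
    return flag if flag.ndim else bool(flag)


def derive_scores(clinical: pd.DataFrame) -> pd.DataFrame:
    """Append derived DAS28 / remission / EULAR columns per timepoint.

    Expects component columns ``tjc28_<tp>``, ``sjc28_<tp>``, ``vas_gh_<tp>``,
    ``hscrp_<tp>`` for tp in baseline / month3 / month6. hsCRP zeros are
    floored at the assay limit (0.1 mg/L) before scoring. Adds
    ``das28_<tp>``, ``remission_<tp>``, and for post-baseline timepoints
    ``eular_<tp>`` and ``eular_poor_<tp>``.
    """
    out = clinical.copy()
    for tp in TIMEPOINTS:
        needed = [f"{c}_{tp}" for c in COMPONENT_COLUMNS]
        if not all(c in out.columns for c in needed):
            continue
        crp = np.maximum(out[f"hscrp_{tp}"].to_numpy(float), HSCRP_FLOOR)
        out[f"das28_{tp}"] = das28_crp(
            out[f"tjc28_{tp}"], out[f"sjc28_{tp}"], crp, out[f"vas_gh_{tp}"]
        )
        out[f"remission_{tp}"] = remission_flag(out[f"das28_{tp}"]).astype(int)
    for tp in ("month3", "month6"):
        if f"das28_{tp}" in out.columns and "das28_baseline" in out.columns:
            out[f"eular_{tp}"] = eular_response(
                out["das28_baseline"], out[f"das28_{tp}"]
            )
            out[f"eular_poor_{tp}"] = eular_poor(
                out["das28_baseline"], out[f"das28_{tp}"]
            ).astype(int)
    return out


def read_clinical(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="patient_id", dtype={"patient_id": str})


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> None:
    out = clinical.copy()
    out.index.name = "patient_id"
    out.to_csv(path, sep="\t", float_format="%.6g")


__all__ = [
    "das28_crp",
    "remission_flag",
    "eular_response",
    "eular_poor",
    "derive_scores",
    "read_clinical",
    "write_clinical",
    "REMISSION_CUTOFF",
    "HSCRP_FLOOR",
]
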
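"""Two-stage lagged regression screen of proteins against clinical outcomes.

Stage 1 fits one univariate model per (protein, outcome, lag) — linear
for DAS28 and its subcomponents, logistic for EULAR poor response and
DAS28 remission — and applies Benjamini–Hochberg adjustment within each
(outcome, protein-timepoint, outcome-timepoint) family. Stage 2 refits
the survivors in a multivariable model with the fixed 14-covariate
confounder set and applies BH within the stage-2 family; final hits are
stage-2 adjusted p < 0.05.

Lag design: proteins at baseline against outcomes at 3 and 6 months, and
proteins at 3 months against outcomes at 6 months.

Also provides independent-cohort replication (refit of the identical
multivariable specification, requiring adjusted significance plus
direction agreement) and the SWATH-vs-ELISA CRP technical correlation.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import (ConvergenceWarning,
                                             PerfectSeparationError)

from .matrix import ProteinMatrix, rows_for_patients

log = logging.getLogger(__name__)

#: The fixed, ordered confounder set used by every multivariable model.
CONFOUNDERS = [
    "age",
    "disease_duration",
    "sex",
    "csdmard",
    "bmi",
    "seropositive",
    "das28_baseline",
    "steroid_use",
    "comorb_cardiovascular",
    "comorb_respiratory",
    "comorb_liver",
    "comorb_renal",
    "comorb_diabetes",
    "comorb_malignancy",
]

#: outcome name -> regression model family
OUTCOME_MODELS = {
    "das28": "linear",
    "tjc": "linear",
    "sjc": "linear",
    "vas_gh": "linear",
    "hscrp": "linear",
    "eular_poor": "logistic",
    "remission": "logistic",
}

#: outcome name -> clinical-table column stem
_OUTCOME_COLUMNS = {
    "das28": "das28",
    "tjc": "tjc28",
    "sjc": "sjc28",
    "vas_gh": "vas_gh",
    "hscrp": "hscrp",
    "eular_poor": "eular_poor",
    "remission": "remission",
}

#: (protein timepoint, outcome timepoint) lag pairs
LAGS = [("baseline", "month3"), ("baseline", "month6"), ("month3", "month6")]


@dataclass
class AssociationResult:
    protein_id: str
    outcome: str
    protein_timepoint: str
    outcome_timepoint: str
    model: str   # linear | logistic
    stage: str   # univariate | multivariable | replication
    effect: float = math.nan   # beta (linear) or OR (logistic)
    ci_low: float = math.nan
    ci_high: float = math.nan
    p_raw: float = math.nan
    p_adj: float = math.nan
    n: int = 0
    ok: bool = True
    note: str = ""

    @property
    def family(self) -> tuple[str, str, str]:
        return (self.outcome, self.protein_timepoint, self.outcome_timepoint)

    @property
    def direction(self) -> int:
        """+1 / -1 on the association scale (beta sign; OR above/below 1)."""
        if self.model == "logistic":
            return 1 if self.effect >= 1.0 else -1
        return 1 if self.effect >= 0.0 else -1


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _wald_ci(coef: float, se: float, dist, level: float = 0.95):
    q = dist.ppf(0.5 + level / 2.0)
    return coef - q * se, coef + q * se


def fit_linear(protein, outcome, covariates: pd.DataFrame | None = None,
               meta: dict | None = None) -> AssociationResult:
    """OLS of outcome on protein (plus optional confounder columns).

    Effect is the protein coefficient with t-based 95% CI and two-sided p.
    """
    x = np.asarray(protein, dtype=float)
    y = np.asarray(outcome, dtype=float)
    res = AssociationResult(model="linear", n=len(y), **_fill_meta(meta))
    design = _design(x, covariates, len(y))
    if len(y) <= design.shape[1] + 1:
        raise ValueError("too few observations for the requested design")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(_rank_message(design, covariates))
    fit = sm.OLS(y, design).fit()
    res.effect = float(fit.params[1])
    res.p_raw = float(fit.pvalues[1])
    ci = fit.conf_int()
    res.ci_low, res.ci_high = float(ci[1, 0]), float(ci[1, 1])
    return res


def fit_logistic(protein, outcome, covariates: pd.DataFrame | None = None,
                 meta: dict | None = None) -> AssociationResult:
    """ML logistic fit; effect reported as OR with Wald 95% CI.

    Detected complete separation marks the row unusable (``ok=False``)
    instead of reporting divergent estimates.
    """
    x = np.asarray(protein, dtype=float)
    y = np.asarray(outcome, dtype=float)
    res = AssociationResult(model="logistic", n=len(y), **_fill_meta(meta))
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("single-class outcome")
    if not set(classes) <= {0.0, 1.0}:
        raise ValueError("logistic outcome must be binary 0/1")
    design = _design(x, covariates, len(y))
    if len(y) <= design.shape[1] + 1:
        raise ValueError("too few observations for the requested design")
    try:
        with np.errstate(over="ignore", divide="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
            if not fit.mle_retvals.get("converged", True):
                # Newton can stall near-flat likelihoods on small cohorts
                fit = sm.Logit(y, design).fit(disp=0, maxiter=1000,
                                              method="bfgs")
            if not fit.mle_retvals.get("converged", True):
                res.ok = False
                res.note = "logistic fit did not converge"
                return res
        coef = float(fit.params[1])
        se = float(fit.bse[1])
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        res.ok = False
        res.note = f"separation/singular fit: {exc}"
        return res
    if not np.isfinite(se) or se > 50 or abs(coef) > 25:
        res.ok = False
        res.note = "complete or quasi-complete separation detected"
        return res
    lo, hi = _wald_ci(coef, se, stats.norm)
    res.effect = math.exp(coef)
    res.ci_low, res.ci_high = math.exp(lo), math.exp(hi)
    res.p_raw = float(fit.pvalues[1])
    return res


def _fill_meta(meta: dict | None) -> dict:
    out = {"protein_id": "", "outcome": "", "protein_timepoint": "",
           "outcome_timepoint": "", "stage": "univariate"}
    out.update(meta or {})
    return out


def _drop_constant_covariates(cov: pd.DataFrame | None):
    """Drop zero-variance covariate columns (e.g. an empty comorbidity
    stratum in a small validation cohort); returns (cleaned, dropped)."""
    if cov is None:
        return None, []
    keep = [c for c in cov.columns if cov[c].nunique(dropna=False) > 1]
    dropped = [c for c in cov.columns if c not in keep]
    return (cov[keep] if dropped else cov), dropped


def _design(x: np.ndarray, covariates: pd.DataFrame | None, n: int) -> np.ndarray:
    cols = [np.ones(n), x]
    if covariates is not None:
        if len(covariates) != n:
            raise ValueError("covariate rows do not match outcome length")
        cols.extend(covariates[c].to_numpy(float) for c in covariates.columns)
    return np.column_stack(cols)


def _rank_message(design: np.ndarray, covariates: pd.DataFrame | None) -> str:
    names = ["const", "protein"] + (
        list(covariates.columns) if covariates is not None else [])
    bad = []
    for j in range(design.shape[1]):
        keep = [i for i in range(design.shape[1]) if i != j]
        if np.linalg.matrix_rank(design[:, keep]) == np.linalg.matrix_rank(design):
            bad.append(names[j])
    return f"rank-deficient design; redundant columns: {bad or names}"


# ---------------------------------------------------------------------------
# vectorized stage-1 linear fits (identical to fit_linear without covariates)
# ---------------------------------------------------------------------------

def _univariate_linear_batch(X: np.ndarray, y: np.ndarray):
    """Closed-form simple OLS per column of X: (beta, ci_low, ci_high, p)."""
    n = len(y)
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sxx = (xc ** 2).sum(axis=0)
    beta = np.where(sxx > 0, (xc * yc[:, None]).sum(axis=0) / np.where(sxx > 0, sxx, 1.0), np.nan)
    alpha_hat = y.mean() - beta * X.mean(axis=0)
    resid = y[:, None] - alpha_hat[None, :] - X * beta[None, :]
    dof = n - 2
    s2 = (resid ** 2).sum(axis=0) / dof
    se = np.sqrt(s2 / np.where(sxx > 0, sxx, np.nan))
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), dof)
    q = stats.t.ppf(0.975, dof)
    return beta, beta - q * se, beta + q * se, p


# ---------------------------------------------------------------------------
# the screen
# ---------------------------------------------------------------------------

def _family_patients(clinical: pd.DataFrame, col: str) -> pd.Index:
    return clinical.index[clinical[col].notna()]


def run_screen(
    matrix: ProteinMatrix,
    clinical: pd.DataFrame,
    retained: list[str],
    confounders: list[str] | None = None,
    alpha: float = 0.05,
    stage1_adjusted: bool = False,
) -> list[AssociationResult]:
    """The full two-stage screen over all outcomes and lags.

    Returns every stage-1 and stage-2 row. Fit failures are recorded on
    the row (``ok=False``) and never abort the screen.
    """
    confounders = CONFOUNDERS if confounders is None else confounders
    missing_conf = [c for c in confounders if c not in clinical.columns]
    if missing_conf:
        raise ValueError(f"clinical table lacks confounders: {missing_conf}")
    unknown = [p for p in retained if p not in set(matrix.protein_ids)]
    if unknown:
        raise ValueError(f"retained proteins absent from matrix: {unknown[:5]}")
    if not retained:
        return []

    results: list[AssociationResult] = []
    for outcome, model in OUTCOME_MODELS.items():
        stem = _OUTCOME_COLUMNS[outcome]
        for ptp, otp in LAGS:
            col = f"{stem}_{otp}"
            if col not in clinical.columns:
                continue
            patients = list(_family_patients(clinical, col))
            if not patients:
                continue
            y = clinical.loc[patients, col].to_numpy(float)
            X = rows_for_patients(matrix, ptp, patients)[retained]
            cov = clinical.loc[patients, confounders].astype(float)
            meta = {"outcome": outcome, "protein_timepoint": ptp,
                    "outcome_timepoint": otp}

            # ---- stage 1 -------------------------------------------
            stage1: list[AssociationResult] = []
            if model == "linear" and not stage1_adjusted:
                beta, lo, hi, p = _univariate_linear_batch(X.to_numpy(), y)
                for j, pid in enumerate(retained):
                    stage1.append(AssociationResult(
                        protein_id=pid, model="linear", stage="univariate",
                        effect=float(beta[j]), ci_low=float(lo[j]),
                        ci_high=float(hi[j]), p_raw=float(p[j]),
                        n=len(y), **meta))
            else:
                cov1 = cov if stage1_adjusted else None
                fitter = fit_linear if model == "linear" else fit_logistic
                for pid in retained:
                    try:
                        r = fitter(X[pid].to_numpy(), y, covariates=cov1,
                                   meta={"protein_id": pid,
                                         "stage": "univariate", **meta})
                    except ValueError as exc:
                        r = AssociationResult(protein_id=pid, model=model,
                                              stage="univariate", n=len(y),
                                              ok=False, note=str(exc), **meta)
                    stage1.append(r)
            usable = [r for r in stage1 if r.ok and np.isfinite(r.p_raw)]
            if usable:
                adj = bh_adjust([r.p_raw for r in usable])
                for r, a in zip(usable, adj):
                    r.p_adj = float(a)
            results.extend(stage1)

            # ---- stage 2 -------------------------------------------
            survivors = [r for r in usable if r.p_adj < alpha]
            stage2: list[AssociationResult] = []
            fitter = fit_linear if model == "linear" else fit_logistic
            cov2, dropped_cov = _drop_constant_covariates(cov)
            if dropped_cov:
                log.info("constant confounders dropped for %s/%s->%s: %s",
                         outcome, ptp, otp, dropped_cov)
            for r1 in survivors:
                try:
                    r2 = fitter(X[r1.protein_id].to_numpy(), y, covariates=cov2,
                                meta={"protein_id": r1.protein_id,
                                      "stage": "multivariable", **meta})
                except ValueError as exc:
                    r2 = AssociationResult(protein_id=r1.protein_id,
                                           model=model, stage="multivariable",
                                           n=len(y), ok=False, note=str(exc),
                                           **meta)
                stage2.append(r2)
            usable2 = [r for r in stage2 if r.ok and np.isfinite(r.p_raw)]
            if usable2:
                adj = bh_adjust([r.p_raw for r in usable2])
                for r, a in zip(usable2, adj):
                    r.p_adj = float(a)
            results.extend(stage2)
    return results


def final_hits(results: list[AssociationResult],
               alpha: float = 0.05) -> list[AssociationResult]:
    """Stage-2 rows with BH-adjusted p below alpha."""
    return [r for r in results
            if r.stage == "multivariable" and r.ok
            and np.isfinite(r.p_adj) and r.p_adj < alpha]


def replicate(
    discovery_hits: list[AssociationResult],
    validation_matrix: ProteinMatrix,
    validation_clinical: pd.DataFrame,
    confounders: list[str] | None = None,
    alpha: float = 0.05,
) -> list[AssociationResult]:
    """Refit each discovery hit's multivariable model on validation data.

    A hit replicates iff its BH-adjusted p (across the replication
    family) is below alpha and its effect direction matches discovery.
    The replication/direction verdict is recorded in ``note``.
    """
    confounders = CONFOUNDERS if confounders is None else confounders
    rows: list[AssociationResult] = []
    present = set(validation_matrix.protein_ids)
    for hit in discovery_hits:
        meta = {"protein_id": hit.protein_id, "outcome": hit.outcome,
                "protein_timepoint": hit.protein_timepoint,
                "outcome_timepoint": hit.outcome_timepoint,
                "stage": "replication"}
        if hit.protein_id not in present:
            rows.append(AssociationResult(model=hit.model, ok=False,
                                          note="untestable: protein absent "
                                               "from validation matrix",
                                          **meta))
            continue
        col = f"{_OUTCOME_COLUMNS[hit.outcome]}_{hit.outcome_timepoint}"
        patients = list(_family_patients(validation_clinical, col))
        y = validation_clinical.loc[patients, col].to_numpy(float)
        x = rows_for_patients(validation_matrix, hit.protein_timepoint,
                              patients)[hit.protein_id].to_numpy()
        cov, dropped_cov = _drop_constant_covariates(
            validation_clinical.loc[patients, confounders].astype(float))
        if dropped_cov:
            log.info("constant confounders dropped in replication: %s",
                     dropped_cov)
        fitter = fit_linear if hit.model == "linear" else fit_logistic
        try:
            r = fitter(x, y, covariates=cov, meta=meta)
        except ValueError as exc:
            r = AssociationResult(model=hit.model, ok=False, note=str(exc),
                                  n=len(y), **meta)
        rows.append(r)
    usable = [r for r in rows if r.ok and np.isfinite(r.p_raw)]
    if usable:
        adj = bh_adjust([r.p_raw for r in usable])
        for r, a in zip(usable, adj):
            r.p_adj = float(a)
    by_key = {(h.protein_id, h.outcome, h.protein_timepoint,
               h.outcome_timepoint): h for h in discovery_hits}
    for r in rows:
        if not r.ok:
            continue
        disc = by_key[(r.protein_id, r.outcome, r.protein_timepoint,
                       r.outcome_timepoint)]
        same_dir = r.direction == disc.direction
        replicated = bool(r.p_adj < alpha and same_dir)
        r.note = ("replicated" if replicated
                  else f"not replicated (p_adj={r.p_adj:.3g}, "
                       f"direction {'agrees' if same_dir else 'flips'})")
    return rows


def replicated_hits(rows: list[AssociationResult]) -> list[AssociationResult]:
    return [r for r in rows if r.ok and r.note == "replicated"]


def technical_correlation(swath_crp, elisa_crp):
    """Pearson r of SWATH CRP intensity vs log2 ELISA hsCRP.

    Returns (r, (ci_low, ci_high), p) with a Fisher-z 95% CI.
    """
    x = np.asarray(swath_crp, dtype=float)
    y = np.asarray(elisa_crp, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.any(y <= 0):
        raise ValueError("ELISA CRP values must be positive (mg/L)")
    ylog = np.log2(y)
    if np.std(x) == 0 or np.std(ylog) == 0:
        raise ValueError("zero-variance input")
    r, p = stats.pearsonr(x, ylog)
    z = np.arctanh(r)
    se = 1.0 / math.sqrt(x.size - 3)
    lo, hi = np.tanh(z - 1.959963984540054 * se), np.tanh(z + 1.959963984540054 * se)
    return float(r), (float(lo), float(hi)), float(p)


# ---------------------------------------------------------------------------
# tidy output
# ---------------------------------------------------------------------------

_FRAME_COLS = ["protein_id", "outcome", "protein_timepoint",
               "outcome_timepoint", "model", "stage", "effect", "ci_low",
               "ci_high", "p_raw", "p_adj", "n", "ok", "note"]


def results_to_frame(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [[getattr(r, c) for c in _FRAME_COLS] for r in results],
        columns=_FRAME_COLS,
    )


def write_results(results: list[AssociationResult], path: str | Path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False,
                                     float_format="%.6g")


__all__ = [
    "CONFOUNDERS",
    "OUTCOME_MODELS",
    "LAGS",
    "AssociationResult",
    "bh_adjust",
    "fit_linear",
    "fit_logistic",
    "run_screen",
    "final_hits",
    "replicate",
    "replicated_hits",
    "technical_correlation",
    "results_to_frame",
    "write_results",
]
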
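"""Synthetic discovery/validation cohorts, interactomes and gene-set libraries.

The generator emulates the data a SWATH-MS biomarker study of etanercept
response in RA would produce: a log2-scale protein intensity matrix for
cases at two timepoints (pretreatment baseline and month 3) plus healthy
controls at one timepoint, a clinical table with DAS28 components at
baseline / 3 / 6 months, an undirected scale-free interactome, and a GMT
gene-set library.

Planted structure (recorded in a :class:`TruthLedger`):

* a subset of proteins is differentially expressed case vs control
  (additive log2 shift, sign mostly up as in active inflammation);
* a subset of the DE proteins carries true effects on later clinical
  outcomes — linear effects on VAS-GH or hsCRP, logistic effects on
  DAS28 remission;
* fixed confounder effects (age, BMI, baseline DAS28, ...) on every
  outcome.

Internal consistency of the outcomes is guaranteed by construction:
remission is first sampled from an exact logistic model on the planted
predictor, then tender/swollen joint counts are solved so that the DAS28
computed from the four components falls strictly on the sampled side of
the 2.6 remission cut-off. The derived remission flag therefore equals
the sampled one, and a downstream logistic regression of remission on a
planted protein plus the confounders is correctly specified.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

from ._rng import substream
from .clinical import HSCRP_FLOOR, das28_crp, derive_scores
from .matrix import ProteinMatrix

# ---------------------------------------------------------------------------
# configuration and truth
# ---------------------------------------------------------------------------

CRP_PROTEIN = "P02741"  # C-reactive protein; tied to the ELISA hsCRP values

COVARIATES = [
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

# population (mean, sd) used to standardize covariates inside the generator
_COV_STD = {
    "age": (56.0, 12.0),
    "disease_duration": (8.0, 8.0),
    "sex": (0.75, 0.433),
    "csdmard": (0.6, 0.49),
    "bmi": (28.0, 5.0),
    "seropositive": (0.7, 0.458),
    "das28_baseline": (5.95, 0.55),
    "steroid_use": (0.25, 0.433),
    "comorb_cardiovascular": (0.15, 0.357),
    "comorb_respiratory": (0.12, 0.325),
    "comorb_liver": (0.03, 0.171),
    "comorb_renal": (0.04, 0.196),
    "comorb_diabetes": (0.10, 0.30),
    "comorb_malignancy": (0.05, 0.218),
}

# confounder weights on the standardized scale
_W_CONT = {
    "age": 0.08, "disease_duration": 0.06, "sex": 0.05, "csdmard": -0.08,
    "bmi": 0.08, "seropositive": 0.04, "das28_baseline": 0.25,
    "steroid_use": 0.06, "comorb_cardiovascular": 0.05,
    "comorb_respiratory": 0.04, "comorb_liver": 0.02, "comorb_renal": 0.03,
    "comorb_diabetes": 0.04, "comorb_malignancy": 0.02,
}
_W_LOGIT = {
    "age": -0.15, "disease_duration": -0.10, "sex": -0.20, "csdmard": 0.25,
    "bmi": -0.15, "seropositive": 0.10, "das28_baseline": -0.30,
    "steroid_use": -0.10, "comorb_cardiovascular": -0.08,
    "comorb_respiratory": -0.08, "comorb_liver": -0.05, "comorb_renal": -0.05,
    "comorb_diabetes": -0.08, "comorb_malignancy": -0.05,
}

# outcome-scale constants (mg/L for hsCRP, mm for VAS-GH)
_VAS_MEAN = {"month3": 45.0, "month6": 42.0}
_VAS_SD = 12.0
_VAS_REMISSION_DROP = 16.0
_CRP_MEAN = {"month3": 12.0, "month6": 11.0}
_CRP_SD = 2.5
_CRP_REMISSION_DROP = 7.0

# planted-effect templates cycled over the effect proteins
_EFFECT_TEMPLATES = [
    ("remission", "baseline", "month3", "logistic"),
    ("vas_gh", "baseline", "month3", "linear"),
    ("hscrp", "baseline", "month6", "linear"),
    ("vas_gh", "month3", "month6", "linear"),
    ("remission", "baseline", "month6", "logistic"),
    ("hscrp", "month3", "month6", "linear"),
]

_OUTCOME_SD = {"vas_gh": _VAS_SD, "hscrp": _CRP_SD}


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic cohort generator."""

    n_cases_discovery: int = 180
    n_cases_validation: int = 58
    n_controls: int = 14
    n_proteins: int = 482
    n_de_proteins: int = 216
    n_effect_proteins: int = 10
    effect_size_linear: float = 0.5     # outcome-noise SDs per protein SD
    effect_size_logistic: float = -1.0  # log-odds of remission per protein SD
    de_shift: float = 1.0               # mean case-vs-control log2 shift
    intensity_sd: float = 1.0           # log2-scale protein SD
    missing_rate: float = 0.05
    response_fraction: float = 0.30     # target month-3 remission fraction
    down_fraction: float = 70.0 / 216.0  # share of DE proteins shifted down
    rng_seed: int = 0
    missing_mechanism: str = "mcar"     # or "censor" (left-censored dropout)

    def validate(self) -> None:
        if not (0 <= self.n_effect_proteins <= self.n_de_proteins <= self.n_proteins):
            raise ValueError(
                "need n_effect_proteins <= n_de_proteins <= n_proteins"
            )
        for name in ("n_cases_discovery", "n_cases_validation", "n_controls",
                     "n_proteins", "n_de_proteins"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0.0 < self.response_fraction < 1.0:
            raise ValueError("response_fraction must lie in (0, 1)")
        if self.intensity_sd <= 0:
            raise ValueError("intensity_sd must be positive")
        if self.missing_mechanism not in {"mcar", "censor"}:
            raise ValueError("missing_mechanism must be 'mcar' or 'censor'")


@dataclass
class PlantedEffect:
    """One true protein -> outcome effect, on the fitted model's raw scale."""

    protein_id: str
    outcome: str           # vas_gh | hscrp | remission
    protein_timepoint: str  # baseline | month3
    outcome_timepoint: str  # month3 | month6
    model: str             # linear | logistic
    beta_model: float      # coefficient per log2-intensity unit
    center: float          # case-population mean intensity used for centring


@dataclass
class TruthLedger:
    """Planted ground truth shared by the discovery and validation cohorts."""

    protein_ids: list[str]
    protein_means: dict[str, float]
    de_signs: dict[str, int]              # protein id -> +1 (up) / -1 (down)
    effects: list[PlantedEffect]
    confounder_effects: dict[str, dict[str, float]]
    logistic_intercepts: dict[str, float]  # outcome timepoint -> intercept

    def __post_init__(self) -> None:
        outside = [e.protein_id for e in self.effects if e.protein_id not in self.de_signs]
        if outside:
            raise ValueError(f"planted effects outside the DE set: {outside}")

    @property
    def de_proteins(self) -> dict[str, int]:
        return dict(self.de_signs)

    @property
    def effect_map(self) -> dict[str, tuple[str, str, str, float]]:
        return {
            e.protein_id: (e.outcome, e.protein_timepoint, e.outcome_timepoint,
                           e.beta_model)
            for e in self.effects
        }

    def to_json(self, path: str | Path) -> None:
        payload = {
            "protein_ids": self.protein_ids,
            "protein_means": self.protein_means,
            "de_signs": self.de_signs,
            "effects": [dataclasses.asdict(e) for e in self.effects],
            "confounder_effects": self.confounder_effects,
            "logistic_intercepts": self.logistic_intercepts,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthLedger":
        payload = json.loads(Path(path).read_text())
        return cls(
            protein_ids=payload["protein_ids"],
            protein_means=payload["protein_means"],
            de_signs={k: int(v) for k, v in payload["de_signs"].items()},
            effects=[PlantedEffect(**e) for e in payload["effects"]],
            confounder_effects=payload["confounder_effects"],
            logistic_intercepts=payload["logistic_intercepts"],
        )


@dataclass
class SimStudy:
    discovery_matrix: ProteinMatrix
    discovery_clinical: pd.DataFrame
    validation_matrix: ProteinMatrix
    validation_clinical: pd.DataFrame
    truth: TruthLedger


# ---------------------------------------------------------------------------
# truth construction
# ---------------------------------------------------------------------------

def _protein_ids(n: int) -> list[str]:
    ids = [CRP_PROTEIN] + [f"P{10000 + i:05d}" for i in range(1, n)]
    return ids[:n]


def _standardize(cov: pd.DataFrame) -> pd.DataFrame:
    out = pd.DataFrame(index=cov.index)
    for name, (m, s) in _COV_STD.items():
        out[name] = (cov[name].astype(float) - m) / s
    return out


def create_truth(config: SimConfig) -> TruthLedger:
    """Draw the planted structure (DE set, effects, intercepts) for a study."""
    config.validate()
    rng = substream(config.rng_seed, "truth")
    ids = _protein_ids(config.n_proteins)
    means = dict(zip(ids, np.round(rng.normal(14.0, 2.0, config.n_proteins), 4)))
    means[CRP_PROTEIN] = 13.0

    # CRP is DE up by construction (driven by the hsCRP gap vs controls)
    pool = [p for p in ids if p != CRP_PROTEIN]
    n_extra = min(config.n_de_proteins, len(pool) + 1) - 1
    de = [CRP_PROTEIN] + list(rng.choice(pool, size=n_extra, replace=False))
    de = de[: config.n_de_proteins]
    signs = {}
    for p in de:
        if p == CRP_PROTEIN:
            signs[p] = 1
        else:
            signs[p] = -1 if rng.random() < config.down_fraction else 1

    eligible = [p for p in de if p != CRP_PROTEIN]
    n_eff = min(config.n_effect_proteins, len(eligible))
    chosen = list(rng.choice(eligible, size=n_eff, replace=False)) if n_eff else []
    effects = []
    for i, pid in enumerate(chosen):
        outcome, ptp, otp, model = _EFFECT_TEMPLATES[i % len(_EFFECT_TEMPLATES)]
        center = means[pid] + signs[pid] * config.de_shift
        if model == "linear":
            beta = config.effect_size_linear * _OUTCOME_SD[outcome] / config.intensity_sd
        else:
            beta = config.effect_size_logistic / config.intensity_sd
        effects.append(PlantedEffect(pid, outcome, ptp, otp, model,
                                     float(beta), float(center)))

    conf_effects = {"remission": {}, "vas_gh": {}, "hscrp": {}}
    for c in COVARIATES:
        sd = _COV_STD[c][1]
        conf_effects["remission"][c] = _W_LOGIT[c] / sd
        conf_effects["vas_gh"][c] = _VAS_SD * _W_CONT[c] / sd
        conf_effects["hscrp"][c] = _CRP_SD * _W_CONT[c] / sd

    intercepts = _calibrate_intercepts(config, effects, rng)
    return TruthLedger(ids, means, signs, effects, conf_effects, intercepts)


def _calibrate_intercepts(config: SimConfig, effects: list[PlantedEffect],
                          rng: np.random.Generator) -> dict[str, float]:
    """Population-level bisection of the remission-model intercepts.

    Solves mean(expit(a + offsets)) = target for each outcome timepoint,
    where the offset distribution pools confounder and planted-protein
    contributions. Raises if the target is unreachable within bounds.
    """
    m = 4000
    w = np.array([_W_LOGIT[c] for c in COVARIATES])
    conf = rng.standard_normal((m, len(COVARIATES))) @ w
    targets = {
        "month3": config.response_fraction,
        "month6": min(0.92, 1.25 * config.response_fraction),
    }
    intercepts = {}
    for tp, target in targets.items():
        planted = np.zeros(m)
        for e in effects:
            if e.model == "logistic" and e.outcome_timepoint == tp:
                planted += e.beta_model * rng.normal(0.0, config.intensity_sd, m)
        offsets = conf + planted
        lo, hi = -30.0, 30.0
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if expit(mid + offsets).mean() < target:
                lo = mid
            else:
                hi = mid
        a = 0.5 * (lo + hi)
        achieved = expit(a + offsets).mean()
        if abs(achieved - target) > 1e-3:
            raise ValueError(
                f"response_fraction {target:.3f} unreachable for {tp} "
                f"(best achievable {achieved:.3f})"
            )
        intercepts[tp] = float(a)
    return intercepts


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _truncnorm(rng, mean, sd, lo, hi):
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng)


def _crp_vas_offset(crp: float, vas: float) -> float:
    """DAS28 contribution of the CRP and VAS components plus the constant."""
    return 0.96 + 0.36 * math.log(max(crp, HSCRP_FLOOR) + 1.0) + 0.014 * vas


def _joints_from_target(target: float, base: float, u: float) -> tuple[int, int]:
    """Integer joint counts whose DAS28 contribution approximates target-base."""
    t = max(target - base, 0.0)
    tjc = int(round(min((u * t / 0.56) ** 2, 28.0)))
    rem = t - 0.56 * math.sqrt(tjc)
    sjc = int(round(min(max(rem / 0.28, 0.0) ** 2, 28.0)))
    return tjc, sjc


def _enforce_side(tjc: int, sjc: int, crp: float, vas: float,
                  side: str) -> tuple[int, int, float]:
    """Adjust joint counts so the computed DAS28 lies strictly on `side`."""
    crp_eff = max(crp, HSCRP_FLOOR)

    def score(t, s):
        return das28_crp(t, s, crp_eff, vas)

    d = score(tjc, sjc)
    if side == "remission":
        while d >= 2.58 and (tjc > 0 or sjc > 0):
            if sjc >= tjc and sjc > 0:
                sjc -= 1
            elif tjc > 0:
                tjc -= 1
            d = score(tjc, sjc)
    elif side == "active":
        while d < 2.62 and (tjc < 28 or sjc < 28):
            if tjc < 28:
                tjc += 1
            else:
                sjc += 1
            d = score(tjc, sjc)
    elif side == "high":
        while d <= 5.12 and (tjc < 28 or sjc < 28):
            if tjc < 28:
                tjc += 1
            else:
                sjc += 1
            d = score(tjc, sjc)
    return tjc, sjc, d


def _planted_contribution(effects, outcome, tp, intensities, model):
    """Sum of planted contributions for `outcome` at outcome timepoint `tp`."""
    total = np.zeros(len(intensities["baseline"]))
    for e in effects:
        if e.outcome != outcome or e.outcome_timepoint != tp or e.model != model:
            continue
        x = intensities[e.protein_timepoint][e.protein_id].to_numpy()
        total += e.beta_model * (x - e.center)
    return total


def generate_cohort(
    config: SimConfig,
    truth: TruthLedger | None = None,
    cohort: str = "discovery",
) -> tuple[ProteinMatrix, pd.DataFrame, TruthLedger]:
    """Generate one cohort (matrix + clinical table) under a shared truth.

    With ``truth=None`` the planted structure is drawn first (seeded by the
    config); passing the discovery cohort's ledger generates an independent
    validation cohort under the same true model.
    """
    config.validate()
    if truth is None:
        truth = create_truth(config)
    if cohort not in {"discovery", "validation"}:
        raise ValueError("cohort must be 'discovery' or 'validation'")
    n_cases = (config.n_cases_discovery if cohort == "discovery"
               else config.n_cases_validation)
    rng = substream(config.rng_seed, f"cohort/{cohort}")
    ids = truth.protein_ids
    n_prot = len(ids)
    prefix = "RA" if cohort == "discovery" else "VA"
    patients = [f"{prefix}{i + 1:04d}" for i in range(n_cases)]

    # --- covariates ---------------------------------------------------
    cov = pd.DataFrame(index=pd.Index(patients, name="patient_id"))
    cov["age"] = np.clip(rng.normal(56, 12, n_cases), 18, 85).round(1)
    cov["disease_duration"] = np.clip(
        np.exp(rng.normal(math.log(6.0), 0.9, n_cases)), 0.1, 40).round(2)
    cov["sex"] = (rng.random(n_cases) < 0.75).astype(int)
    cov["csdmard"] = (rng.random(n_cases) < 0.6).astype(int)
    cov["bmi"] = np.clip(rng.normal(28, 5, n_cases), 16, 50).round(1)
    cov["seropositive"] = (rng.random(n_cases) < 0.7).astype(int)
    cov["steroid_use"] = (rng.random(n_cases) < 0.25).astype(int)
    for c, p in [("comorb_cardiovascular", 0.15), ("comorb_respiratory", 0.12),
                 ("comorb_liver", 0.03), ("comorb_renal", 0.04),
                 ("comorb_diabetes", 0.10), ("comorb_malignancy", 0.05)]:
        cov[c] = (rng.random(n_cases) < p).astype(int)

    # --- baseline clinical components (high disease activity) --------
    clin = cov.copy()
    vas0 = np.clip(rng.normal(62, 12, n_cases), 20, 100).round(0)
    crp0 = np.clip(np.exp(rng.normal(math.log(12.0), 0.7, n_cases)), 0.5, 120).round(2)
    base0 = np.array([_crp_vas_offset(c, v) for c, v in zip(crp0, vas0)])
    d0_target = _truncnorm(rng, 5.95, 0.5,
                           np.maximum(5.16, base0 + 0.05), 8.4)
    u0 = rng.uniform(0.45, 0.70, n_cases)
    tjc0 = np.zeros(n_cases, dtype=int)
    sjc0 = np.zeros(n_cases, dtype=int)
    d0 = np.zeros(n_cases)
    for i in range(n_cases):
        t, s = _joints_from_target(d0_target[i], base0[i], u0[i])
        tjc0[i], sjc0[i], d0[i] = _enforce_side(t, s, crp0[i], vas0[i], "high")
    clin["tjc28_baseline"] = tjc0
    clin["sjc28_baseline"] = sjc0
    clin["vas_gh_baseline"] = vas0
    clin["hscrp_baseline"] = crp0
    cov_for_std = cov.copy()
    cov_for_std["das28_baseline"] = d0
    z_cov = _standardize(cov_for_std)

    # --- protein intensities ------------------------------------------
    mu = np.array([truth.protein_means[p] for p in ids])
    de_shift_vec = np.array(
        [truth.de_signs.get(p, 0) * config.de_shift for p in ids])
    case_mu = mu + de_shift_vec
    x_bl = case_mu + rng.normal(0, config.intensity_sd, (n_cases, n_prot))
    rho = 0.6
    x_m3 = (case_mu + rho * (x_bl - case_mu)
            + math.sqrt(1 - rho ** 2)
            * rng.normal(0, config.intensity_sd, (n_cases, n_prot)))
    hc_prefix = "HC" if cohort == "discovery" else "HV"
    controls = [f"{hc_prefix}{i + 1:03d}" for i in range(config.n_controls)]
    x_hc = mu + rng.normal(0, config.intensity_sd, (config.n_controls, n_prot))

    # CRP protein intensity is tied to measured hsCRP (log2) plus assay noise
    crp_idx = ids.index(CRP_PROTEIN)
    crp_noise_sd = 0.55
    crp_hc = np.clip(np.exp(rng.normal(math.log(1.2), 0.6, config.n_controls)),
                     0.2, 10.0)
    x_bl[:, crp_idx] = (truth.protein_means[CRP_PROTEIN] - math.log2(12.0)
                        + np.log2(crp0)
                        + rng.normal(0, crp_noise_sd, n_cases))
    x_hc[:, crp_idx] = (truth.protein_means[CRP_PROTEIN] - math.log2(12.0)
                        + np.log2(crp_hc)
                        + rng.normal(0, crp_noise_sd, config.n_controls))

    intensities = {
        "baseline": pd.DataFrame(x_bl, index=patients, columns=ids),
        "month3": pd.DataFrame(x_m3, index=patients, columns=ids),
    }

    # --- post-baseline outcomes ---------------------------------------
    w_cont = np.array([_W_CONT[c] for c in COVARIATES])
    w_logit = np.array([_W_LOGIT[c] for c in COVARIATES])
    zc = z_cov[COVARIATES].to_numpy()
    conf_cont = zc @ w_cont
    conf_logit = zc @ w_logit

    for tp in ("month3", "month6"):
        lam = (truth.logistic_intercepts[tp] + conf_logit
               + _planted_contribution(truth.effects, "remission", tp,
                                       intensities, "logistic"))
        remit = rng.random(n_cases) < expit(lam)

        vas = (_VAS_MEAN[tp] - _VAS_REMISSION_DROP * remit
               + _VAS_SD * (conf_cont
                            + rng.standard_normal(n_cases))
               + _planted_contribution(truth.effects, "vas_gh", tp,
                                       intensities, "linear")
               * 1.0)
        vas = np.clip(vas, 0.0, 100.0).round(0)
        crp = (_CRP_MEAN[tp] - _CRP_REMISSION_DROP * remit
               + _CRP_SD * (conf_cont + rng.standard_normal(n_cases))
               + _planted_contribution(truth.effects, "hscrp", tp,
                                       intensities, "linear"))
        crp = np.maximum(crp, HSCRP_FLOOR).round(2)

        # feasibility nudge: a remitter's CRP+VAS floor must stay below 2.6
        base = np.array([_crp_vas_offset(c, v) for c, v in zip(crp, vas)])
        for i in np.nonzero(remit & (base > 2.42))[0]:
            vas_new = (2.40 - 0.96 - 0.36 * math.log(max(crp[i], HSCRP_FLOOR) + 1.0)) / 0.014
            vas[i] = max(0.0, round(vas_new))
            if vas[i] == 0.0 and _crp_vas_offset(crp[i], 0.0) > 2.42:
                crp[i] = round(math.exp((2.40 - 0.96) / 0.36) - 1.0, 2)
            base[i] = _crp_vas_offset(crp[i], vas[i])

        u = rng.uniform(0.45, 0.70, n_cases)
        d_rem = _truncnorm(rng, 2.15, 0.30, base, np.maximum(base + 0.01, 2.54))
        t_act = _truncnorm(rng, 1.7, 0.7,
                           np.maximum(0.05, 2.72 - base), 4.42)
        tjc = np.zeros(n_cases, dtype=int)
        sjc = np.zeros(n_cases, dtype=int)
        for i in range(n_cases):
            target = d_rem[i] if remit[i] else base[i] + t_act[i]
            t, s = _joints_from_target(target, base[i], u[i])
            side = "remission" if remit[i] else "active"
            tjc[i], sjc[i], _ = _enforce_side(t, s, crp[i], vas[i], side)
        clin[f"tjc28_{tp}"] = tjc
        clin[f"sjc28_{tp}"] = sjc
        clin[f"vas_gh_{tp}"] = vas
        clin[f"hscrp_{tp}"] = crp

    # month-3 CRP protein tracks the month-3 ELISA measurement too
    x_m3[:, crp_idx] = (truth.protein_means[CRP_PROTEIN] - math.log2(12.0)
                        + np.log2(np.maximum(
                            clin["hscrp_month3"].to_numpy(float), HSCRP_FLOOR))
                        + rng.normal(0, crp_noise_sd, n_cases))

    clin = derive_scores(clin)

    # --- assemble matrix ----------------------------------------------
    sample_ids = ([f"{p}_BL" for p in patients]
                  + [f"{p}_M3" for p in patients] + controls)
    values = pd.DataFrame(
        np.vstack([x_bl, x_m3, x_hc]), index=sample_ids, columns=ids)
    meta = pd.DataFrame(
        {
            "patient_id": patients + patients + controls,
            "role": ["case"] * (2 * n_cases) + ["control"] * config.n_controls,
            "timepoint": (["baseline"] * n_cases + ["month3"] * n_cases
                          + ["baseline"] * config.n_controls),
            "cohort": cohort,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    matrix = ProteinMatrix(values=values, sample_meta=meta, log2=True)
    if config.missing_rate > 0:
        matrix = inject_missingness(
            matrix, config.missing_rate,
            rng_seed=int(substream(config.rng_seed,
                                   f"missing/{cohort}").integers(2**31)),
            mechanism=config.missing_mechanism,
        )
    return matrix, clin, truth


def generate_study(config: SimConfig) -> SimStudy:
    """Discovery and validation cohorts under one shared truth ledger."""
    dmat, dclin, truth = generate_cohort(config, cohort="discovery")
    vmat, vclin, _ = generate_cohort(config, truth=truth, cohort="validation")
    return SimStudy(dmat, dclin, vmat, vclin, truth)


# ---------------------------------------------------------------------------
# missingness
# ---------------------------------------------------------------------------

def inject_missingness(
    matrix: ProteinMatrix,
    rate: float,
    rng_seed: int,
    mechanism: str = "mcar",
) -> ProteinMatrix:
    """Mask cells missing at the given expected rate; keep the truth as shadow.

    ``mcar`` masks uniformly at random; ``censor`` makes dropout
    abundance-dependent (low-intensity cells are preferentially lost),
    emulating MS left-censoring.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must lie in [0, 1)")
    out = matrix.copy()
    out.shadow = matrix.values.copy()
    if rate == 0.0:
        return out
    rng = np.random.default_rng(rng_seed)
    vals = out.values.to_numpy()
    if mechanism == "mcar":
        mask = rng.random(vals.shape) < rate
    elif mechanism == "censor":
        # logistic dropout in the within-protein intensity rank, scaled to
        # the requested expected rate
        ranks = pd.DataFrame(vals).rank(axis=0, pct=True).to_numpy()
        weight = expit(4.0 * (0.5 - ranks))
        prob = np.clip(rate * weight / weight.mean(), 0.0, 0.95)
        mask = rng.random(vals.shape) < prob
    else:
        raise ValueError("mechanism must be 'mcar' or 'censor'")
    vals = vals.copy()
    vals[mask] = np.nan
    out.values = pd.DataFrame(vals, index=out.values.index,
                              columns=out.values.columns)
    return out


# ---------------------------------------------------------------------------
# interactome and gene sets
# ---------------------------------------------------------------------------

def generate_interactome(
    n_nodes: int,
    attachment: int,
    planted_seed_ids: list[str],
    rng_seed: int,
    protein_ids: list[str] | None = None,
    neighbourhood_size: int = 25,
) -> nx.Graph:
    """Scale-free-like interactome with a dense planted seed neighbourhood.

    Preferential-attachment backbone; node labels cover ``protein_ids``
    (which must include the planted seeds) padded with generic gene
    symbols. The planted seeds are wired into one connected, densely
    overlapping neighbourhood (recorded as graph attribute
    ``planted_neighbourhood``) so module detection has something to find.
    """
    if n_nodes <= attachment or attachment < 1:
        raise ValueError("need n_nodes > attachment >= 1")
    labels = list(protein_ids) if protein_ids is not None else list(planted_seed_ids)
    if len(labels) > n_nodes:
        raise ValueError("more protein ids than interactome nodes")
    missing = [p for p in planted_seed_ids if p not in labels]
    if missing:
        raise ValueError(f"planted seeds not among protein ids: {missing}")
    rng = np.random.default_rng(rng_seed)
    g = nx.barabasi_albert_graph(n_nodes, attachment,
                                 seed=int(rng.integers(2**31)))
    labels = labels + [f"G{i:05d}" for i in range(len(labels), n_nodes)]
    # shuffle label placement so protein ids are not all early (hub) nodes
    order = rng.permutation(n_nodes)
    mapping = {int(order[i]): labels[i] for i in range(n_nodes)}
    g = nx.relabel_nodes(g, mapping)

    seeds = list(planted_seed_ids)
    neighbourhood: list[str] = []
    if seeds:
        for a, b in zip(seeds, seeds[1:]):
            g.add_edge(a, b)
        candidates = [n for n in g.nodes if n not in seeds]
        k = min(neighbourhood_size, len(candidates))
        neighbourhood = [candidates[i]
                         for i in rng.choice(len(candidates), k, replace=False)]
        for node in neighbourhood:
            n_links = min(len(seeds), 3)
            for s in rng.choice(len(seeds), n_links, replace=False):
                g.add_edge(node, seeds[int(s)])
            for other in rng.choice(len(neighbourhood), 2):
                if neighbourhood[int(other)] != node:
                    g.add_edge(node, neighbourhood[int(other)])
    g.remove_edges_from(nx.selfloop_edges(g))
    g.graph["planted_neighbourhood"] = sorted(neighbourhood)
    g.graph["planted_seeds"] = sorted(seeds)
    return g


def write_interactome(g: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# undirected interactome edge list\n")
        for a, b in sorted(tuple(sorted(e)) for e in g.edges):
            fh.write(f"{a}\t{b}\n")


def read_interactome(path: str | Path) -> nx.Graph:
    g = nx.Graph()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed edge line: {line!r}")
            if parts[0] != parts[1]:
                g.add_edge(parts[0], parts[1])
    return g


def generate_gene_sets(
    interactome: nx.Graph,
    n_sets: int,
    size_range: tuple[int, int],
    enriched_set_nodes: list[str],
    rng_seed: int,
) -> dict[str, list[str]]:
    """Random gene-set library; one designated set over-samples the
    enriched nodes so local enrichment can single it out."""
    nodes = sorted(interactome.nodes)
    if not nodes:
        raise ValueError("empty interactome")
    lo, hi = size_range
    if lo < 2 or hi > len(nodes) or lo > hi:
        raise ValueError("size_range must lie within [2, n_nodes]")
    rng = np.random.default_rng(rng_seed)
    library: dict[str, list[str]] = {}
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = [nodes[j] for j in rng.choice(len(nodes), size, replace=False)]
        library[f"SET{i + 1:04d}"] = sorted(set(members))
    if enriched_set_nodes:
        core = [n for n in enriched_set_nodes if n in interactome]
        size = max(lo, min(hi, max(len(core), lo)))
        members = list(core[:size])
        filler_pool = [n for n in nodes if n not in members]
        while len(members) < size and filler_pool:
            j = int(rng.integers(len(filler_pool)))
            members.append(filler_pool.pop(j))
        library["PLANTED_RESPONSE_MODULE"] = sorted(set(members))
    return library


__all__ = [
    "SimConfig",
    "TruthLedger",
    "PlantedEffect",
    "SimStudy",
    "create_truth",
    "generate_cohort",
    "generate_study",
    "inject_missingness",
    "generate_interactome",
    "generate_gene_sets",
    "write_interactome",
    "read_interactome",
    "CRP_PROTEIN",
    "COVARIATES",
]
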
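"""Synthetic hemodialysis cohort generator.

The study's raw patient-level data are not publicly deposited, so analyses
are exercised against simulated cohorts with the same statistical structure:
59 hemodialysis patients and 33 healthy controls by default, per-analyte
concentration distributions whose central values match the published cohort
summaries, and a fatigue outcome generated from a known logistic model so
that parameter recovery can be verified.

Modelling choices
-----------------
* Every analyte concentration and daily-loss quantity is log-normal —
  non-negative and able to represent both the approximately symmetric and
  the heavy-tailed summaries.  Parameters are moment-matched: mean ± SD
  summaries fix the log-normal mean and SD; median (Q1; Q3) summaries fix
  the log-median and the log-IQR.
* Analytes within a compartment share an exchangeable latent correlation
  (default ρ = 0.3), a plausible degree of biological co-variation.
* Per-analyte *daily-loss* targets are the generative primitive for the
  dialysis arm; the pooled-dialysate concentration is back-solved as
  D_x = (loss − urinary component) · 7 / (n · V) so that the mass-balance
  formulas recover the target exactly.  The urinary component of a patient
  with residual diuresis is a control-like urinary excretion scaled by
  relative urine volume.
* Dialysate urea is back-solved from a target Maroni protein intake, and
  the post/pre urea ratio R from a target Kt/V by inverting the Daugirdas
  formula, so adequacy and intake are internally consistent.
* Severe fatigue follows logit P = α + β_tau·(log2 taurine loss − m) +
  β_pro·z(plasma proline) + β_prot·z(protein intake), with α calibrated so
  the prevalence matches the study's 20/59 ≈ 0.339.  The defaults use the
  published fully adjusted effect sizes (OR 0.64 per doubling of taurine
  loss, 2.97 per SD of plasma proline, 0.18 per SD of protein intake).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit
from scipy.stats import truncnorm

from . import reference_data as ref
from .quantification import invert_daugirdas

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "default_config",
    "null_fatigue_config",
    "generate_cohort",
    "ground_truth",
    "lognormal_from_mean_sd",
    "lognormal_from_median_iqr",
]

_Z75 = 0.6744897501960817  # 75th percentile of the standard normal


# ---------------------------------------------------------------------------
# log-normal parameterization

def lognormal_from_mean_sd(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the log-normal with the given arithmetic mean and SD."""
    if mean <= 0 or sd < 0:
        raise ValueError("mean must be > 0 and sd >= 0")
    s2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - s2 / 2.0, math.sqrt(s2)


def lognormal_from_median_iqr(median: float, q1: float, q3: float) -> tuple[float, float]:
    """(mu, sigma) of the log-normal with the given median and quartiles."""
    if not 0 < q1 <= median <= q3:
        raise ValueError("need 0 < q1 <= median <= q3")
    return math.log(median), math.log(q3 / q1) / (2.0 * _Z75)


def lognormal_moments(mu: float, sigma: float) -> tuple[float, float]:
    """Theoretical (mean, SD) of a log-normal."""
    m = math.exp(mu + sigma**2 / 2.0)
    return m, m * math.sqrt(math.expm1(sigma**2))


# target tables: analyte -> ("mean_sd", mean, sd) or ("median_iqr", med, q1, q3)
# Plasma concentrations, µmol/L (hemodialysis arm is predialysis).
PLASMA_HD: dict[str, tuple] = {
    "histidine": ("mean_sd", 69, 19), "isoleucine": ("mean_sd", 63, 23),
    "leucine": ("mean_sd", 103, 41), "lysine": ("mean_sd", 141, 36),
    "methionine": ("mean_sd", 19, 7), "phenylalanine": ("mean_sd", 68, 22),
    "threonine": ("mean_sd", 87, 29), "tryptophan": ("median_iqr", 22, 20, 28),
    "valine": ("mean_sd", 186, 59), "alanine": ("mean_sd", 351, 135),
    "arginine": ("mean_sd", 77, 22), "asparagine": ("mean_sd", 53, 16),
    "citrulline": ("median_iqr", 78, 61, 95), "glutamic acid": ("median_iqr", 101, 69, 161),
    "glutamine": ("mean_sd", 514, 111), "glycine": ("mean_sd", 260, 84),
    "ornithine": ("mean_sd", 63, 20), "proline": ("median_iqr", 276, 223, 322),
    "serine": ("mean_sd", 61, 19), "taurine": ("median_iqr", 58, 41, 87),
    "tyrosine": ("mean_sd", 45, 16),
}
PLASMA_CTRL: dict[str, tuple] = {
    "histidine": ("mean_sd", 74, 12), "isoleucine": ("mean_sd", 61, 18),
    "leucine": ("mean_sd", 110, 29), "lysine": ("mean_sd", 171, 37),
    "methionine": ("mean_sd", 21, 5), "phenylalanine": ("mean_sd", 57, 9),
    "threonine": ("mean_sd", 115, 24), "tryptophan": ("median_iqr", 54, 46, 57),
    "valine": ("mean_sd", 213, 51), "alanine": ("mean_sd", 423, 113),
    "arginine": ("mean_sd", 78, 17), "asparagine": ("mean_sd", 61, 11),
    "citrulline": ("median_iqr", 28, 24, 32), "glutamic acid": ("median_iqr", 57, 45, 81),
    "glutamine": ("mean_sd", 575, 87), "glycine": ("mean_sd", 202, 54),
    "ornithine": ("mean_sd", 59, 16), "proline": ("median_iqr", 248, 197, 321),
    "serine": ("mean_sd", 103, 19), "taurine": ("median_iqr", 40, 37, 50),
    "tyrosine": ("mean_sd", 62, 18),
}
# Total daily losses, µmol/24 h (dialytic + urinary for the dialysis arm).
LOSSES_HD: dict[str, tuple] = {
    "histidine": ("mean_sd", 862, 270), "isoleucine": ("mean_sd", 799, 338),
    "leucine": ("mean_sd", 1382, 587), "lysine": ("median_iqr", 1505, 1233, 1845),
    "methionine": ("mean_sd", 172, 95), "phenylalanine": ("median_iqr", 729, 631, 967),
    "threonine": ("median_iqr", 1043, 731, 1279), "tryptophan": ("mean_sd", 216, 63),
    "valine": ("median_iqr", 2017, 1606, 2614), "alanine": ("mean_sd", 3926, 1548),
    "arginine": ("mean_sd", 826, 377), "asparagine": ("mean_sd", 747, 290),
    "citrulline": ("median_iqr", 463, 347, 570), "glutamic acid": ("mean_sd", 966, 559),
    "glutamine": ("mean_sd", 6954, 2410), "glycine": ("mean_sd", 3502, 1271),
    "ornithine": ("mean_sd", 541, 194), "proline": ("mean_sd", 3601, 1351),
    "serine": ("median_iqr", 754, 572, 1004), "taurine": ("median_iqr", 132, 24, 235),
    "tyrosine": ("mean_sd", 462, 192),
}
LOSSES_CTRL: dict[str, tuple] = {
    "histidine": ("mean_sd", 698, 463), "isoleucine": ("mean_sd", 12, 7),
    "leucine": ("mean_sd", 67, 23), "lysine": ("median_iqr", 209, 157, 288),
    "methionine": ("mean_sd", 5, 2), "phenylalanine": ("median_iqr", 68, 52, 103),
    "threonine": ("median_iqr", 105, 81, 161), "tryptophan": ("mean_sd", 148, 57),
    "valine": ("median_iqr", 42, 35, 54), "alanine": ("mean_sd", 361, 219),
    "arginine": ("mean_sd", 34, 15), "asparagine": ("mean_sd", 122, 82),
    "citrulline": ("median_iqr", 11, 7, 13), "glutamic acid": ("mean_sd", 35, 33),
    "glutamine": ("mean_sd", 449, 211), "glycine": ("mean_sd", 1521, 848),
    "ornithine": ("mean_sd", 22, 17), "proline": ("mean_sd", 8, 5),
    "serine": ("median_iqr", 324, 236, 467), "taurine": ("median_iqr", 339, 204, 668),
    "tyrosine": ("mean_sd", 105, 68),
}
# Mean intradialytic proportional change (fraction of the predialysis level).
PROP_CHANGE: dict[str, float] = {
    "histidine": -0.22, "isoleucine": 0.17, "leucine": 0.20, "lysine": -0.05,
    "methionine": 0.05, "phenylalanine": -0.04, "threonine": -0.08,
    "tryptophan": 0.23, "valine": -0.20, "alanine": -0.28, "arginine": -0.22,
    "asparagine": -0.06, "citrulline": -0.54, "glutamic acid": 0.02,
    "glutamine": -0.11, "glycine": -0.22, "ornithine": -0.19, "proline": -0.12,
    "serine": -0.02, "taurine": -0.29, "tyrosine": 0.0,
}

ANALYTES = list(PLASMA_HD)  # fixed generation order


def _params(table: dict[str, tuple]) -> dict[str, tuple[float, float]]:
    out = {}
    for name, spec in table.items():
        if spec[0] == "mean_sd":
            out[name] = lognormal_from_mean_sd(spec[1], spec[2])
        else:
            out[name] = lognormal_from_median_iqr(spec[1], spec[2], spec[3])
    return out


def target_central(spec: tuple) -> float:
    """The configured central value (mean or median) of one target entry."""
    return float(spec[1])


@dataclass
class GeneratorConfig:
    """Everything the cohort generator needs; same seed ⇒ identical cohort."""

    n_hd: int = 59
    n_ctrl: int = 33
    seed: int = 0
    rho: float = 0.3                      # exchangeable latent correlation within compartment

    # session model
    dialysate_volume: tuple[float, float] = (135.0, 27.0)   # L, mean/SD (truncated > 60)
    uf_volume: tuple[float, float] = (1.9, 0.9)             # L, truncated >= 0
    ktv: tuple[float, float] = (1.4, 0.3)                   # truncated > 0.6
    p_thrice_weekly: float = 0.95
    duration_choices: tuple = ((4.0, 0.81), (3.5, 0.12), (3.0, 0.07))
    ktv_loss_coupling: float = 0.5        # losses scale with (Kt/V / 1.4)**gamma

    # residual kidney function
    p_diuresis: float = 0.54
    hd_urine_volume: tuple[float, float] = (0.9, 0.6)       # L, truncated > 0.2
    ctrl_urine_volume: tuple[float, float] = (2.5, 0.9)     # L, truncated > 0.8

    # protein intake (Maroni scale), g/24 h
    intake_hd: tuple[float, float] = (64.0, 21.0)
    intake_ctrl: tuple[float, float] = (84.0, 21.0)

    # fatigue model (per-doubling for taurine losses, per theoretical SD otherwise)
    or_taurine_loss_per_doubling: float = 0.64
    or_proline_plasma_per_sd: float = 2.97
    or_protein_intake_per_sd: float = 0.18
    fatigue_prevalence: float = 20.0 / 59.0
    fatigue_alpha: float | None = None    # calibrated from prevalence when None

    # intradialytic change noise (SD of the proportional change around its target)
    prop_change_noise: float = 0.10

    # analyte targets (summary-statistic parameterization, overridable)
    plasma_hd: dict[str, tuple] = field(default_factory=lambda: dict(PLASMA_HD))
    plasma_ctrl: dict[str, tuple] = field(default_factory=lambda: dict(PLASMA_CTRL))
    losses_hd: dict[str, tuple] = field(default_factory=lambda: dict(LOSSES_HD))
    losses_ctrl: dict[str, tuple] = field(default_factory=lambda: dict(LOSSES_CTRL))
    prop_change: dict[str, float] = field(default_factory=lambda: dict(PROP_CHANGE))

    def validate(self) -> None:
        if self.n_hd < 1 or self.n_ctrl < 0:
            raise ValueError("cohort sizes must be positive")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must be in [0, 1)")
        if not 0 < self.fatigue_prevalence < 1:
            raise ValueError("fatigue prevalence must be in (0, 1)")
        for pair in (self.dialysate_volume, self.uf_volume, self.ktv,
                     self.hd_urine_volume, self.ctrl_urine_volume,
                     self.intake_hd, self.intake_ctrl):
            if pair[1] < 0 or pair[0] <= 0:
                raise ValueError(f"scale parameters must be positive: {pair}")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class GroundTruth:
    """True simulated effect sizes and calibration constants, for test assertions."""

    beta_taurine_loss_log2: float
    beta_proline_plasma_sd: float
    beta_protein_intake_sd: float
    alpha: float
    or_taurine_loss_per_doubling: float
    or_proline_plasma_per_sd: float
    or_protein_intake_per_sd: float
    proline_plasma_mean: float
    proline_plasma_sd: float
    taurine_loss_log2_center: float
    protein_intake_mean: float
    protein_intake_sd: float


def default_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """Study-condition configuration; override individual fields by keyword."""
    cfg = GeneratorConfig(seed=seed, **overrides)
    cfg.validate()
    return cfg


def null_fatigue_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """Config with all fatigue effect coefficients zero (OR = 1)."""
    return default_config(
        seed=seed,
        or_taurine_loss_per_doubling=1.0,
        or_proline_plasma_per_sd=1.0,
        or_protein_intake_per_sd=1.0,
        **overrides,
    )


def ground_truth(config: GeneratorConfig) -> GroundTruth:
    """Expose the true coefficients and standardization constants of a config."""
    mu_p, sg_p = _params(config.plasma_hd)["proline"]
    p_mean, p_sd = lognormal_moments(mu_p, sg_p)
    mu_t, _ = _params(config.losses_hd)["taurine"]
    alpha = (
        config.fatigue_alpha
        if config.fatigue_alpha is not None
        else _calibrate_alpha(config)
    )
    return GroundTruth(
        beta_taurine_loss_log2=math.log(config.or_taurine_loss_per_doubling),
        beta_proline_plasma_sd=math.log(config.or_proline_plasma_per_sd),
        beta_protein_intake_sd=math.log(config.or_protein_intake_per_sd),
        alpha=alpha,
        or_taurine_loss_per_doubling=config.or_taurine_loss_per_doubling,
        or_proline_plasma_per_sd=config.or_proline_plasma_per_sd,
        or_protein_intake_per_sd=config.or_protein_intake_per_sd,
        proline_plasma_mean=p_mean,
        proline_plasma_sd=p_sd,
        taurine_loss_log2_center=mu_t / math.log(2.0),
        protein_intake_mean=config.intake_hd[0],
        protein_intake_sd=config.intake_hd[1],
    )


def _eta_draws(config: GeneratorConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Monte-Carlo draws of the centered fatigue linear predictor (no intercept)."""
    gt = ground_truth(replace(config, fatigue_alpha=0.0))
    mu_t, sg_t = _params(config.losses_hd)["taurine"]
    mu_p, sg_p = _params(config.plasma_hd)["proline"]
    tau = rng.lognormal(mu_t, sg_t, n)
    pro = rng.lognormal(mu_p, sg_p, n)
    intake = rng.lognormal(*lognormal_from_mean_sd(*config.intake_hd), size=n)
    return (
        gt.beta_taurine_loss_log2 * (np.log2(tau) - gt.taurine_loss_log2_center)
        + gt.beta_proline_plasma_sd * (pro - gt.proline_plasma_mean) / gt.proline_plasma_sd
        + gt.beta_protein_intake_sd
        * (intake - gt.protein_intake_mean) / gt.protein_intake_sd
    )


def _calibrate_alpha(config: GeneratorConfig) -> float:
    """Intercept giving the target severe-fatigue prevalence.

    Solves E[expit(alpha + eta)] = prevalence over a fixed internal
    Monte-Carlo sample of the linear predictor (deterministic).
    """
    eta = _eta_draws(config, 40_000, np.random.default_rng(321))
    f = lambda a: float(np.mean(expit(a + eta))) - config.fatigue_prevalence
    return float(optimize.brentq(f, -20.0, 20.0, xtol=1e-10))


# ---------------------------------------------------------------------------
# sampling helpers

def _tnorm(rng, mean, sd, low, high=np.inf, size=1):
    if sd == 0:
        return np.full(size, float(mean))
    a, b = (low - mean) / sd, (high - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _correlated_lognormal(
    rng: np.random.Generator,
    params: dict[str, tuple[float, float]],
    n: int,
    rho: float,
) -> pd.DataFrame:
    """(n × analyte) log-normal draws with exchangeable latent correlation rho."""
    k = len(params)
    common = rng.standard_normal((n, 1))
    noise = rng.standard_normal((n, k))
    z = math.sqrt(rho) * common + math.sqrt(1.0 - rho) * noise
    cols = {}
    for j, (name, (mu, sigma)) in enumerate(params.items()):
        cols[name] = np.exp(mu + sigma * z[:, j])
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# cohort generation

def generate_cohort(config: GeneratorConfig):
    """Generate one cohort; returns an :class:`aminobalance.io.CohortData`.

    Generation order is fixed, so identical configs (including seed) produce
    byte-identical frames.
    """
    from .io import CohortData

    config.validate()
    rng = np.random.default_rng(config.seed)
    gt = ground_truth(config)
    hd = _generate_hd(config, rng, gt)
    ctrl = _generate_ctrl(config, rng)
    subjects = pd.concat([hd["subjects"], ctrl["subjects"]], ignore_index=True)
    sessions = hd["sessions"]
    panels = pd.concat([hd["panels"], ctrl["panels"]], ignore_index=True)
    return CohortData(subjects=subjects, sessions=sessions, panels=panels, config=config)


def _maroni_g(intake, upe, bw):
    """Invert the Maroni formula for total urea appearance (mmol/24 h)."""
    return ((intake - upe) / 6.25 - 0.031 * bw) / 0.028


def _generate_hd(config: GeneratorConfig, rng: np.random.Generator, gt: GroundTruth):
    n = config.n_hd
    ids = [f"HD{i + 1:04d}" for i in range(n)]

    # demographics and clinical covariates
    age = _tnorm(rng, 65, 15, 18, 95, n)
    male = rng.random(n) < 0.63
    height = _tnorm(rng, 1.75, 0.09, 1.45, 2.10, n)
    weight_post = _tnorm(rng, 78, 16, 40, 160, n)
    bmi = weight_post / height**2
    vintage = rng.lognormal(*lognormal_from_median_iqr(15, 6, 39), size=n)
    hemoglobin = _tnorm(rng, 6.9, 0.7, 4.0, 10.0, n)
    crp = rng.lognormal(*lognormal_from_median_iqr(5, 2, 12), size=n)
    albumin = _tnorm(rng, 39, 5, 20, 55, n)
    cvd = rng.random(n) < 0.50
    diabetes = rng.random(n) < 0.25

    # session parameters
    v_dial = _tnorm(rng, *config.dialysate_volume, 60, np.inf, n)
    n_week = np.where(rng.random(n) < config.p_thrice_weekly, 3, 2)
    durations = np.array([d for d, _ in config.duration_choices])
    duration = rng.choice(durations, size=n, p=[p for _, p in config.duration_choices])
    uf = _tnorm(rng, *config.uf_volume, 0.0, np.inf, n)
    ktv = _tnorm(rng, *config.ktv, 0.6, np.inf, n)
    urea_ratio = np.array(
        [invert_daugirdas(k, t, u, w) for k, t, u, w in zip(ktv, duration, uf, weight_post)]
    )
    plasma_urea_pre = _tnorm(rng, 22, 5, 8, np.inf, n)
    plasma_urea_post = plasma_urea_pre * urea_ratio

    # residual diuresis
    has_diuresis = rng.random(n) < config.p_diuresis
    urine_vol = np.where(
        has_diuresis, _tnorm(rng, *config.hd_urine_volume, 0.2, np.inf, n), 0.0
    )
    uue = np.where(has_diuresis, _tnorm(rng, 60, 30, 2, np.inf, n), 0.0)
    upe = np.where(
        has_diuresis,
        np.minimum(rng.lognormal(*lognormal_from_median_iqr(0.7, 0.3, 1.3), size=n), 10.0),
        0.0,
    )

    # protein intake: back-solve the dialysate urea from an intake target
    intake_target = rng.lognormal(*lognormal_from_mean_sd(*config.intake_hd), size=n)
    g_total = _maroni_g(intake_target, upe, weight_post)
    g_dialytic = np.maximum(g_total - uue, 1.0)  # clip keeps dialysate urea positive
    dialysate_urea = g_dialytic * 7.0 / (n_week * v_dial)
    intake = 6.25 * (
        0.028 * ((v_dial * dialysate_urea * n_week) / 7.0 + uue) + 0.031 * weight_post
    ) + upe

    # plasma amino-acid panels: pre, then post via targeted proportional change
    pre = _correlated_lognormal(rng, _params(config.plasma_hd), n, config.rho)
    delta = pd.DataFrame(
        {
            a: config.prop_change[a]
            + config.prop_change_noise * rng.standard_normal(n)
            for a in ANALYTES
        }
    )
    post = pre * np.clip(1.0 + delta, 0.02, None)

    # daily losses: totals from the loss targets (coupled to dialysis dose),
    # urinary component control-like scaled by relative urine volume
    totals = _correlated_lognormal(rng, _params(config.losses_hd), n, config.rho)
    totals = totals.mul((ktv / 1.4) ** config.ktv_loss_coupling, axis=0)
    urinary_like = _correlated_lognormal(rng, _params(config.losses_ctrl), n, config.rho)
    scale = np.where(has_diuresis, urine_vol / config.ctrl_urine_volume[0], 0.0)
    urinary = urinary_like.mul(scale, axis=0)
    urinary = np.minimum(urinary, 0.9 * totals)  # dialytic component stays positive
    dialytic = totals - urinary
    d_panel = dialytic.mul(7.0 / (n_week * v_dial), axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        u_panel = urinary.div(np.where(urine_vol > 0, urine_vol, np.nan), axis=0)
    u_panel = u_panel.where(pd.DataFrame(
        np.tile(has_diuresis[:, None], (1, len(ANALYTES))), columns=ANALYTES
    ), other=np.nan)

    # creatinine: plasma pre/post plus dialysate back-solved from a clearance target
    creat_pre = rng.lognormal(*lognormal_from_mean_sd(850, 250), size=n)
    creat_post = creat_pre * np.clip(0.45 + 0.05 * rng.standard_normal(n), 0.1, 0.9)
    creat_cl = _tnorm(rng, 137, 68, 25, np.inf, n)  # mL/min
    creat_mean_p = (creat_pre + creat_post) / 2.0
    creat_dialysate = creat_cl * 0.06 * duration * creat_mean_p / v_dial

    # fatigue outcome from the configured logistic model
    eta = (
        gt.beta_taurine_loss_log2 * (np.log2(totals["taurine"]) - gt.taurine_loss_log2_center)
        + gt.beta_proline_plasma_sd
        * (pre["proline"] - gt.proline_plasma_mean) / gt.proline_plasma_sd
        + gt.beta_protein_intake_sd
        * (intake - gt.protein_intake_mean) / gt.protein_intake_sd
    )
    p_severe = expit(gt.alpha + eta)
    severe = rng.random(n) < p_severe
    cis = np.where(severe, rng.uniform(35, 56, n), rng.uniform(8, 35, n))

    subjects = pd.DataFrame(
        {
            "subject_id": ids, "arm": "hd", "age": age, "male": male.astype(int),
            "height": height, "weight_post": weight_post, "bmi": bmi,
            "vintage_months": vintage, "hemoglobin": hemoglobin, "crp": crp,
            "albumin": albumin, "cvd": cvd.astype(int), "diabetes": diabetes.astype(int),
            "cis_fatigue": cis, "severe_fatigue": severe.astype(int),
            "has_diuresis": has_diuresis.astype(int), "urine_volume": urine_vol,
            "urine_urea": uue, "urine_protein": upe,
            "protein_intake_g": intake, "protein_intake_gkg": intake / weight_post,
            "n_per_week": n_week, "thrice_weekly": (n_week == 3).astype(int),
            "v_dialysate": v_dial, "duration_h": duration, "uf_volume": uf,
            "ktv": ktv, "urea_ratio": urea_ratio, "dialysate_urea": dialysate_urea,
        }
    )
    sessions = pd.DataFrame(
        {
            "subject_id": ids, "v_dialysate": v_dial, "duration_h": duration,
            "n_per_week": n_week, "uf_volume": uf, "weight_post": weight_post,
            "dialysate_urea": dialysate_urea, "urea_ratio": urea_ratio,
            "plasma_urea_pre": plasma_urea_pre, "plasma_urea_post": plasma_urea_post,
        }
    )
    panels = _melt_panels(
        ids,
        {
            "plasma_pre": pre, "plasma_post": post, "dialysate": d_panel,
            "urine": u_panel,
        },
        extra={
            "plasma_pre": {"creatinine": creat_pre},
            "plasma_post": {"creatinine": creat_post},
            "dialysate": {"creatinine": creat_dialysate},
        },
    )
    return {"subjects": subjects, "sessions": sessions, "panels": panels}


def _generate_ctrl(config: GeneratorConfig, rng: np.random.Generator):
    n = config.n_ctrl
    ids = [f"CT{i + 1:04d}" for i in range(n)]
    age = _tnorm(rng, 54, 10, 18, 80, n)
    male = rng.random(n) < 0.45
    height = _tnorm(rng, 1.72, 0.10, 1.45, 2.10, n)
    weight = _tnorm(rng, 77, 17, 45, 160, n)
    bmi = weight / height**2
    hemoglobin = _tnorm(rng, 8.8, 0.8, 6.0, 12.0, n)
    albumin = _tnorm(rng, 45, 2, 35, 55, n)
    urine_vol = _tnorm(rng, *config.ctrl_urine_volume, 0.8, np.inf, n)

    intake_target = rng.lognormal(*lognormal_from_mean_sd(*config.intake_ctrl), size=n)
    upe = np.minimum(rng.lognormal(*lognormal_from_median_iqr(0.06, 0.03, 0.10), size=n), 1.0)
    uue = np.maximum(_maroni_g(intake_target, upe, weight), 10.0)
    intake = 6.25 * (0.028 * uue + 0.031 * weight) + upe

    plasma = _correlated_lognormal(rng, _params(config.plasma_ctrl), n, config.rho)
    losses = _correlated_lognormal(rng, _params(config.losses_ctrl), n, config.rho)
    u_panel = losses.div(urine_vol, axis=0)

    subjects = pd.DataFrame(
        {
            "subject_id": ids, "arm": "control", "age": age, "male": male.astype(int),
            "height": height, "weight_post": weight, "bmi": bmi,
            "vintage_months": np.nan, "hemoglobin": hemoglobin, "crp": np.nan,
            "albumin": albumin, "cvd": 0, "diabetes": 0,
            "cis_fatigue": np.nan, "severe_fatigue": np.nan,
            "has_diuresis": 1, "urine_volume": urine_vol,
            "urine_urea": uue, "urine_protein": upe,
            "protein_intake_g": intake, "protein_intake_gkg": intake / weight,
            "n_per_week": np.nan, "thrice_weekly": np.nan,
            "v_dialysate": np.nan, "duration_h": np.nan, "uf_volume": np.nan,
            "ktv": np.nan, "urea_ratio": np.nan, "dialysate_urea": np.nan,
        }
    )
    panels = _melt_panels(ids, {"plasma": plasma, "urine": u_panel})
    return {"subjects": subjects, "panels": panels}


def _melt_panels(
    ids: list[str],
    frames: dict[str, pd.DataFrame],
    extra: dict[str, dict[str, np.ndarray]] | None = None,
) -> pd.DataFrame:
    chunks = []
    for compartment, frame in frames.items():
        wide = frame.copy()
        if extra and compartment in extra:
            for analyte, values in extra[compartment].items():
                wide[analyte] = values
        wide = wide.assign(subject_id=ids)
        long = wide.melt(id_vars="subject_id", var_name="analyte", value_name="concentration")
        long["compartment"] = compartment
        chunks.append(long)
    out = pd.concat(chunks, ignore_index=True)
    out["unit"] = "umol/L"
    out = out.dropna(subset=["concentration"]).reset_index(drop=True)
    return out[["subject_id", "compartment", "analyte", "concentration", "unit"]]
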
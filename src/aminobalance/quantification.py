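"""Per-patient mass-balance and kinetic calculations.

Units are fixed by contract and never inferred: volumes in L, durations in
hours, weights in kg, amino-acid concentrations in µmol/L, urea in mmol/L
(plasma, dialysate) or mmol/24 h (urinary excretion), urinary protein in
g/24 h.  Mixing µmol and mmol silently is the classic way to be wrong by
1000×, so every function documents and assumes these units.

Core quantities
---------------
* Daily amino-acid losses: dialytic removal averaged over the week
  ``(V_dialysate · D_x · n)/7`` plus 24-h urinary excretion; controls lose
  only via urine (``V_urine · U_x``).
* Dialysis adequacy: single-pool Kt/V from the second-generation Daugirdas
  formula ``-ln(R - 0.008·t) + (4 - 3.5·R)·UF/W``.
* Protein intake: Maroni urea-nitrogen-appearance estimate
  ``6.25·(0.028·G + 0.031·BW) + UPE`` where G is total urea appearance in
  mmol/24 h (dialytic + urinary for dialysis patients, urinary alone for
  controls).
* Dialytic clearance: total dialysate recovery per minute divided by the
  mean of pre- and post-session plasma concentration; fractional clearance
  expresses it relative to creatinine clearance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from . import reference_data as ref

__all__ = [
    "DialysisSession",
    "UrineCollection",
    "LossResult",
    "MissingAnalyteError",
    "DomainError",
    "daily_losses_hd",
    "daily_losses_control",
    "single_session_losses",
    "ktv_daugirdas",
    "invert_daugirdas",
    "protein_intake_hd",
    "protein_intake_control",
    "intradialytic_change",
    "proportional_change",
    "dialytic_clearance",
    "fractional_clearance",
    "group_sums",
    "losses_in_grams",
    "pct_of_protein_intake",
    "hd_to_urine_ratio",
]


class MissingAnalyteError(KeyError):
    """A required panel concentration is absent (never silently zero)."""


class DomainError(ValueError):
    """Input outside the mathematical domain of a formula."""


def _check_nonneg(**kwargs: float) -> None:
    for k, v in kwargs.items():
        if v < 0:
            raise DomainError(f"{k} must be non-negative, got {v}")


@dataclass
class DialysisSession:
    """One hemodialysis session: machine/timing parameters plus pooled-dialysate panel.

    ``dialysate_panel``, ``plasma_pre`` and ``plasma_post`` map analyte name to
    µmol/L.  ``dialysate_urea`` is mmol/L; ``urea_ratio`` is the post/pre plasma
    urea ratio R used by the Daugirdas formula.
    """

    v_dialysate: float          # total spent dialysate volume, L
    duration_h: float           # session length, h
    n_per_week: int             # sessions per week (2 or 3)
    uf_volume: float            # ultrafiltration volume, L
    weight_post: float          # post-dialysis body weight, kg
    dialysate_panel: dict[str, float] = field(default_factory=dict)
    dialysate_urea: float | None = None
    plasma_pre: dict[str, float] = field(default_factory=dict)
    plasma_post: dict[str, float] = field(default_factory=dict)
    urea_ratio: float | None = None

    def __post_init__(self) -> None:
        if self.v_dialysate <= 0:
            raise DomainError("v_dialysate must be > 0")
        if self.duration_h <= 0:
            raise DomainError("duration_h must be > 0")
        if self.n_per_week not in (2, 3):
            raise DomainError(f"n_per_week must be 2 or 3, got {self.n_per_week}")
        if self.uf_volume < 0:
            raise DomainError("uf_volume must be >= 0")
        if self.weight_post <= 0:
            raise DomainError("weight_post must be > 0")
        for panel in (self.dialysate_panel, self.plasma_pre, self.plasma_post):
            for k, v in panel.items():
                if v < 0:
                    raise DomainError(f"negative concentration for {k}: {v}")


@dataclass
class UrineCollection:
    """A 24-h urine collection (two collections pre-averaged for dialysis patients).

    ``panel`` maps analyte to µmol/L; ``urea`` is mmol/24 h excretion;
    ``protein`` g/24 h.  Anuric subjects carry no collection (use ``None``
    at the call sites, which zeroes all urinary terms).
    """

    volume: float               # L/24 h
    panel: dict[str, float] = field(default_factory=dict)
    urea: float = 0.0           # mmol/24 h
    protein: float = 0.0        # g/24 h
    n_collections: int = 1

    def __post_init__(self) -> None:
        _check_nonneg(volume=self.volume, urea=self.urea, protein=self.protein)
        for k, v in self.panel.items():
            if v < 0:
                raise DomainError(f"negative urine concentration for {k}: {v}")
        if self.n_collections not in (1, 2):
            raise DomainError("n_collections must be 1 or 2")


@dataclass
class LossResult:
    """Daily losses for one subject: per-species µmol/24 h, group sums, grams, % of intake."""

    per_species: dict[str, float]
    groups_umol: dict[str, float]
    per_species_g: dict[str, float]
    groups_g: dict[str, float]
    grams_total: float
    pct_of_intake: float | None = None


# ---------------------------------------------------------------------------
# daily and per-session losses

def _dialysate_conc(session: DialysisSession, species: str, impute_zero: bool) -> float:
    name = ref.canonical_name(species)
    ref.get_spec(name)  # raises for excluded analytes
    if name not in session.dialysate_panel:
        if impute_zero:
            return 0.0
        raise MissingAnalyteError(f"no dialysate concentration for {name}")
    return session.dialysate_panel[name]


def urinary_excretion(urine: UrineCollection | None, species: str) -> float:
    """24-h urinary excretion UE_x (µmol/24 h); 0 for anuric subjects (no collection)."""
    if urine is None:
        return 0.0
    name = ref.canonical_name(species)
    if name not in urine.panel:
        raise MissingAnalyteError(f"no urine concentration for {name}")
    return urine.volume * urine.panel[name]


def daily_losses_hd(
    session: DialysisSession,
    urine: UrineCollection | None,
    species: str,
    *,
    impute_zero: bool = False,
) -> float:
    """Daily loss (µmol/24 h) = (V_dialysate · D_x · n)/7 + UE_x."""
    d = _dialysate_conc(session, species, impute_zero)
    return (session.v_dialysate * d * session.n_per_week) / 7.0 + urinary_excretion(
        urine, species
    )


def daily_losses_control(urine: UrineCollection, species: str) -> float:
    """Daily loss in a control (µmol/24 h) = V_urine · U_x from a single collection."""
    return urinary_excretion(urine, species)


def single_session_losses(
    session: DialysisSession, species: str, *, impute_zero: bool = False
) -> float:
    """Removal during one session (µmol/session) = V_dialysate · D_x."""
    return session.v_dialysate * _dialysate_conc(session, species, impute_zero)


# ---------------------------------------------------------------------------
# urea kinetics and protein intake

def ktv_daugirdas(R: float, t: float, UF: float, W: float) -> float:
    """Single-pool Kt/V: −ln(R − 0.008·t) + (4 − 3.5·R)·UF/W.

    R is the post/pre plasma urea ratio, t the session duration (h), UF the
    ultrafiltration volume (L), W the post-dialysis weight (kg).
    """
    if W <= 0:
        raise DomainError("weight must be > 0")
    if not 0 < R <= 1:
        raise DomainError(f"urea ratio R must be in (0, 1], got {R}")
    arg = R - 0.008 * t
    if arg <= 0:
        raise DomainError(f"R - 0.008*t = {arg:.4f} <= 0: outside formula domain")
    return -math.log(arg) + (4.0 - 3.5 * R) * UF / W


def invert_daugirdas(ktv: float, t: float, UF: float, W: float) -> float:
    """Urea ratio R yielding a target Kt/V at fixed t, UF, W (bisection).

    Kt/V is strictly decreasing in R on the valid domain, so the root is
    unique when it exists.
    """
    from scipy.optimize import brentq

    lo = 0.008 * t + 1e-9
    hi = 1.0
    f = lambda r: ktv_daugirdas(r, t, UF, W) - ktv
    if f(hi) > 0 or f(lo) < 0:
        raise DomainError(f"Kt/V target {ktv} unreachable for t={t}, UF={UF}, W={W}")
    return float(brentq(f, lo, hi, xtol=1e-12))


def protein_intake_hd(
    session: DialysisSession, urine: UrineCollection | None
) -> tuple[float, float]:
    """Maroni protein intake for a dialysis patient: (g/24 h, g/kg/24 h).

    6.25 · (0.028 · ((V_dialysate · Du · n)/7 + UUE) + 0.031 · BW) + UPE,
    with Du the dialysate urea (mmol/L), UUE/UPE the urinary urea (mmol/24 h)
    and protein (g/24 h) excretions (0 if anuric), BW the post-dialysis weight.
    """
    if session.dialysate_urea is None:
        raise MissingAnalyteError("dialysate urea concentration required for protein intake")
    _check_nonneg(dialysate_urea=session.dialysate_urea)
    uue = urine.urea if urine is not None else 0.0
    upe = urine.protein if urine is not None else 0.0
    g = (session.v_dialysate * session.dialysate_urea * session.n_per_week) / 7.0 + uue
    intake = 6.25 * (0.028 * g + 0.031 * session.weight_post) + upe
    return intake, intake / session.weight_post


def protein_intake_control(urine: UrineCollection, weight: float) -> tuple[float, float]:
    """Maroni intake for a control from a single collection: (g/24 h, g/kg/24 h)."""
    _check_nonneg(weight=weight)
    intake = 6.25 * (0.028 * urine.urea + 0.031 * weight) + urine.protein
    per_kg = intake / weight if weight > 0 else float("nan")
    return intake, per_kg


# ---------------------------------------------------------------------------
# intradialytic change and clearances

def intradialytic_change(pre: float, post: float) -> tuple[float, float | None]:
    """(absolute change µmol/L, proportional change %) across one session.

    Proportional change is absolute change divided by the predialysis
    concentration × 100; undefined (None) when pre == 0.
    """
    _check_nonneg(pre=pre, post=post)
    absolute = post - pre
    return absolute, (proportional_change(absolute, pre) if pre > 0 else None)


def proportional_change(absolute: float, pre: float) -> float:
    """Proportional change (%) from an absolute change and the predialysis level."""
    if pre <= 0:
        raise DomainError("predialysis concentration must be > 0")
    return absolute / pre * 100.0


def dialytic_clearance(
    session: DialysisSession, species: str, *, impute_zero: bool = False
) -> float | None:
    """Dialytic clearance (mL/min) = ((V·D_x)/T) / ((P_pre + P_post)/2) · 1000/60.

    Returns None (undefined) when the mean plasma concentration is zero.
    ``species`` may be any analyte present in all three panels (e.g.
    creatinine), not only registry amino acids.
    """
    try:
        name = ref.canonical_name(species)
    except ref.UnknownAnalyteError:
        name = species.strip().lower()  # non-amino-acid analytes such as creatinine
    if name in session.dialysate_panel:
        d = session.dialysate_panel[name]
    elif impute_zero:
        d = 0.0
    else:
        raise MissingAnalyteError(f"no dialysate concentration for {name}")
    if name not in session.plasma_pre or name not in session.plasma_post:
        raise MissingAnalyteError(f"plasma pre/post concentrations required for {name}")
    mean_p = (session.plasma_pre[name] + session.plasma_post[name]) / 2.0
    if mean_p <= 0:
        return None
    return (session.v_dialysate * d / session.duration_h) / mean_p * (1000.0 / 60.0)


def fractional_clearance(cl_species: float, cl_creatinine: float) -> float:
    """Clearance as % of simultaneous dialytic creatinine clearance."""
    if cl_creatinine <= 0:
        raise DomainError("creatinine clearance must be > 0")
    _check_nonneg(cl_species=cl_species)
    return cl_species / cl_creatinine * 100.0


# ---------------------------------------------------------------------------
# grouping and unit conversion

def group_sums(per_species: dict[str, float]) -> dict[str, float]:
    """Sum a per-species map into BCAA / essential / non-essential / total.

    Total is defined as essential + non-essential; BCAA is a subset of
    essential. Unknown or excluded keys raise.
    """
    sums = {"bcaa": 0.0, "essential": 0.0, "non-essential": 0.0}
    for name, value in per_species.items():
        spec = ref.get_spec(name)
        if spec.is_essential:
            sums["essential"] += value
        else:
            sums["non-essential"] += value
        if spec.is_bcaa:
            sums["bcaa"] += value
    sums["total"] = sums["essential"] + sums["non-essential"]
    return sums


def losses_in_grams(per_species_umol: dict[str, float]) -> tuple[dict[str, float], dict[str, float]]:
    """Convert per-species µmol/24 h to g/24 h (µmol × g/mol × 10⁻⁶) and group.

    Returns (per-species grams, group-sum grams).
    """
    grams = {
        ref.canonical_name(k): v * ref.get_spec(k).mol_mass * 1e-6
        for k, v in per_species_umol.items()
    }
    return grams, group_sums(grams)


def pct_of_protein_intake(loss_g: float, intake_g: float) -> float:
    """Daily amino-acid loss as a percentage of daily protein intake."""
    if intake_g <= 0:
        raise DomainError("protein intake must be > 0")
    _check_nonneg(loss_g=loss_g)
    return loss_g / intake_g * 100.0


def hd_to_urine_ratio(dialytic_daily: float, urinary_daily: float) -> float | None:
    """Ratio of the dialytic to the urinary component of daily losses.

    Defined only for subjects with residual diuresis and a non-zero urinary
    component; returns None (subject excluded from the ratio cohort) otherwise.
    """
    _check_nonneg(dialytic_daily=dialytic_daily, urinary_daily=urinary_daily)
    if urinary_daily == 0:
        return None
    return dialytic_daily / urinary_daily


def quantify_losses(
    session: DialysisSession,
    urine: UrineCollection | None,
    species: list[str] | None = None,
    *,
    intake_g: float | None = None,
    impute_zero: bool = False,
) -> LossResult:
    """Full daily-loss accounting for one dialysis patient."""
    names = [ref.canonical_name(s) for s in (species or ref.reported_species())]
    per = {n: daily_losses_hd(session, urine, n, impute_zero=impute_zero) for n in names}
    groups = group_sums(per)
    per_g, groups_g = losses_in_grams(per)
    pct = pct_of_protein_intake(groups_g["total"], intake_g) if intake_g else None
    return LossResult(per, groups, per_g, groups_g, groups_g["total"], pct)


def quantify_losses_control(
    urine: UrineCollection,
    species: list[str] | None = None,
    *,
    intake_g: float | None = None,
) -> LossResult:
    """Full daily-loss accounting for one control (urinary losses only)."""
    names = [ref.canonical_name(s) for s in (species or ref.reported_species())]
    per = {n: daily_losses_control(urine, n) for n in names}
    groups = group_sums(per)
    per_g, groups_g = losses_in_grams(per)
    pct = pct_of_protein_intake(groups_g["total"], intake_g) if intake_g else None
    return LossResult(per, groups, per_g, groups_g, groups_g["total"], pct)
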
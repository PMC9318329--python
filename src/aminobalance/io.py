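"""Dataset container, CSV schemas, and the cohort-level quantification driver.

A cohort is three tidy frames:

* ``subjects`` — one row per participant: demographics, comorbidity,
  fatigue, urine-collection scalars (volume L, urea mmol/24 h, protein
  g/24 h), protein intake, and (dialysis arm) session scalars;
* ``sessions`` — one row per dialysis patient: machine and timing
  parameters plus urea kinetics inputs;
* ``panels`` — long format (subject_id, compartment, analyte,
  concentration, unit) with compartments plasma_pre/plasma_post/dialysate/
  urine for the dialysis arm and plasma/urine for controls; amino acids and
  creatinine in µmol/L.

Loss accounting always goes through the :mod:`~aminobalance.quantification`
operations, one subject at a time, so mass-balance invariants checked there
hold for every emitted number.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import quantification as quant
from . import reference_data as ref

__all__ = [
    "CohortData",
    "write_dataset",
    "read_dataset",
    "panel_wide",
    "loss_wide",
    "session_for",
    "urine_for",
    "quantify_cohort",
    "clearance_table",
]

SCHEMA_VERSION = "1"


@dataclass
class CohortData:
    subjects: pd.DataFrame
    sessions: pd.DataFrame
    panels: pd.DataFrame
    config: object | None = None

    def arm(self, which: str) -> pd.DataFrame:
        return self.subjects[self.subjects.arm == which]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def write_dataset(cohort: CohortData, outdir: str | Path, seed: int | None = None) -> dict:
    """Write the cohort CSVs plus a manifest sufficient to reproduce them."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    urine_cols = ["subject_id", "arm", "urine_volume", "urine_urea", "urine_protein",
                  "has_diuresis"]
    files = {
        "subjects.csv": cohort.subjects,
        "sessions.csv": cohort.sessions,
        "panels.csv": cohort.panels,
        "urine.csv": cohort.subjects[urine_cols],
    }
    for name, df in files.items():
        df.to_csv(outdir / name, index=False)
    ref.registry_to_csv(outdir / "registry.csv")
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "seed": seed if seed is not None else getattr(cohort.config, "seed", None),
        "config_hash": cohort.config.hash() if cohort.config is not None else None,
        "n_hd": int((cohort.subjects.arm == "hd").sum()),
        "n_ctrl": int((cohort.subjects.arm == "control").sum()),
        "checksums": {n: _checksum(outdir / n) for n in [*files, "registry.csv"]},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def read_dataset(indir: str | Path) -> CohortData:
    indir = Path(indir)
    # round_trip parsing: emitted values must read back bit-identically
    kw = {"float_precision": "round_trip"}
    return CohortData(
        subjects=pd.read_csv(indir / "subjects.csv", **kw),
        sessions=pd.read_csv(indir / "sessions.csv", **kw),
        panels=pd.read_csv(indir / "panels.csv", **kw),
    )


# ---------------------------------------------------------------------------
# accessors

def panel_wide(cohort: CohortData, arm: str, compartment: str) -> pd.DataFrame:
    """Subject × analyte concentration frame for one compartment (amino acids only)."""
    ids = cohort.arm(arm).subject_id
    sub = cohort.panels[
        (cohort.panels.compartment == compartment)
        & cohort.panels.subject_id.isin(ids)
        & cohort.panels.analyte.isin(ref.reported_species())
    ]
    wide = sub.pivot(index="subject_id", columns="analyte", values="concentration")
    return wide.reindex(index=ids, columns=ref.reported_species())


def panel_maps(cohort: CohortData) -> dict[str, dict[str, dict[str, float]]]:
    """subject_id -> compartment -> {analyte: concentration}, built in one pass.

    Avoids per-subject scans of the long panels frame when iterating a cohort.
    """
    out: dict[str, dict[str, dict[str, float]]] = {}
    for (sid, comp), g in cohort.panels.groupby(["subject_id", "compartment"], sort=False):
        out.setdefault(sid, {})[comp] = dict(zip(g.analyte, g.concentration))
    return out


def session_for(
    cohort: CohortData,
    subject_id: str,
    panels_map: dict | None = None,
) -> quant.DialysisSession:
    """Build the session object (with all panels) for one dialysis patient."""
    row = cohort.sessions[cohort.sessions.subject_id == subject_id]
    if row.empty:
        raise KeyError(f"no session for subject {subject_id!r}")
    row = row.iloc[0]
    if panels_map is None:
        panels_map = panel_maps(cohort)
    return _session_from_row(row, panels_map.get(subject_id, {}))


def _session_from_row(row, panels: dict[str, dict[str, float]]) -> quant.DialysisSession:
    return quant.DialysisSession(
        v_dialysate=float(row.v_dialysate),
        duration_h=float(row.duration_h),
        n_per_week=int(row.n_per_week),
        uf_volume=float(row.uf_volume),
        weight_post=float(row.weight_post),
        dialysate_panel=panels.get("dialysate", {}),
        dialysate_urea=float(row.dialysate_urea),
        plasma_pre=panels.get("plasma_pre", {}),
        plasma_post=panels.get("plasma_post", {}),
        urea_ratio=float(row.urea_ratio),
    )


def _urine_from_row(row, panels: dict[str, dict[str, float]]) -> quant.UrineCollection | None:
    if not bool(row.has_diuresis):
        return None
    return quant.UrineCollection(
        volume=float(row.urine_volume),
        panel=panels.get("urine", {}),
        urea=float(row.urine_urea),
        protein=float(row.urine_protein),
        n_collections=2 if row.arm == "hd" else 1,
    )


def urine_for(
    cohort: CohortData, subject_id: str, panels_map: dict | None = None
) -> quant.UrineCollection | None:
    """Urine collection for one subject; None for anuric dialysis patients."""
    row = cohort.subjects[cohort.subjects.subject_id == subject_id].iloc[0]
    if panels_map is None:
        panels_map = panel_maps(cohort)
    return _urine_from_row(row, panels_map.get(subject_id, {}))


def _iter_subjects(cohort: CohortData, arm: str | None = None):
    """Yield (subjects-row, session | None, urine | None) per subject."""
    pmaps = panel_maps(cohort)
    sessions = {r.subject_id: r for r in cohort.sessions.itertuples(index=False)}
    for row in cohort.subjects.itertuples(index=False):
        if arm is not None and row.arm != arm:
            continue
        panels = pmaps.get(row.subject_id, {})
        session = (
            _session_from_row(sessions[row.subject_id], panels)
            if row.arm == "hd"
            else None
        )
        yield row, session, _urine_from_row(row, panels)


def loss_wide(cohort: CohortData, arm: str) -> pd.DataFrame:
    """Subject × analyte daily-loss frame (µmol/24 h), via the mass-balance ops."""
    species = ref.reported_species()
    rows = {}
    for row, session, urine in _iter_subjects(cohort, arm):
        if arm == "hd":
            rows[row.subject_id] = {
                s: quant.daily_losses_hd(session, urine, s) for s in species
            }
        else:
            rows[row.subject_id] = {
                s: quant.daily_losses_control(urine, s) for s in species
            }
    return pd.DataFrame.from_dict(rows, orient="index").reindex(columns=species)


def quantify_cohort(cohort: CohortData) -> pd.DataFrame:
    """One row per subject: Kt/V, protein intake, grouped daily losses, % of intake.

    All quantities are recomputed from the raw inputs through the
    quantification operations (Kt/V from the urea ratio via the Daugirdas
    formula, intake via Maroni, losses via the mass-balance equations).
    """
    out = []
    for row, session, urine in _iter_subjects(cohort):
        rec: dict = {"subject_id": row.subject_id, "arm": row.arm}
        if row.arm == "hd":
            intake, intake_kg = quant.protein_intake_hd(session, urine)
            rec["ktv"] = quant.ktv_daugirdas(
                session.urea_ratio, session.duration_h, session.uf_volume,
                session.weight_post,
            )
            loss = quant.quantify_losses(session, urine, intake_g=intake)
        else:
            intake, intake_kg = quant.protein_intake_control(urine, row.weight_post)
            loss = quant.quantify_losses_control(urine, intake_g=intake)
            rec["ktv"] = float("nan")
        rec["protein_intake_g"] = intake
        rec["protein_intake_gkg"] = intake_kg
        for g, v in loss.groups_umol.items():
            rec[f"loss_{g}_umol"] = v
        for g, v in loss.groups_g.items():
            rec[f"loss_{g}_g"] = v
        rec["loss_total_g"] = loss.grams_total
        rec["loss_pct_of_intake"] = loss.pct_of_intake
        out.append(rec)
    return pd.DataFrame(out)


def clearance_table(cohort: CohortData, species: list[str] | None = None) -> pd.DataFrame:
    """Per-analyte mean dialytic clearance (mL/min) and fractional clearance (%).

    Fractional clearance is relative to each patient's own dialytic
    creatinine clearance, then averaged.
    """
    names = species or ref.reported_species()
    per_subject: dict[str, dict[str, float]] = {}
    for row, session, _ in _iter_subjects(cohort, "hd"):
        sid = row.subject_id
        cl_cr = quant.dialytic_clearance(session, "creatinine")
        rec = {}
        for s in names:
            cl = quant.dialytic_clearance(session, s)
            rec[s] = cl
            rec[f"frac_{s}"] = (
                quant.fractional_clearance(cl, cl_cr)
                if cl is not None and cl_cr
                else None
            )
        rec["creatinine"] = cl_cr
        per_subject[sid] = rec
    df = pd.DataFrame.from_dict(per_subject, orient="index")
    rows = []
    for s in [*names, "creatinine"]:
        rec = {
            "analyte": s,
            "clearance_ml_min_mean": df[s].mean(),
            "clearance_ml_min_sd": df[s].std(ddof=1),
        }
        if s != "creatinine":
            rec["fractional_clearance_pct_mean"] = df[f"frac_{s}"].mean()
        rows.append(rec)
    return pd.DataFrame(rows)
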
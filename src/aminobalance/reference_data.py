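"""Registry of the amino acids quantified in the dialysis mass-balance panel.

Twenty-one species are reported: 9 essential (histidine, leucine, isoleucine,
lysine, methionine, phenylalanine, threonine, tryptophan, valine) and 12
non-essential (alanine, arginine, asparagine, citrulline, glutamic acid,
glutamine, glycine, ornithine, proline, serine, taurine, tyrosine).  The
branched-chain subset (BCAA) is {leucine, isoleucine, valine}.  Cysteine
(unstable in plasma) and aspartic acid (below detection limit) carry registry
entries but are flagged unreported and rejected by :func:`get_spec`.

Molecular masses are average masses of the free (non-residue) molecules in
g/mol, used to convert µmol/24 h losses into grams.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "AminoAcidSpec",
    "UnknownAnalyteError",
    "ExcludedAnalyteError",
    "get_spec",
    "reported_species",
    "essential_species",
    "nonessential_species",
    "bcaa_species",
    "canonical_name",
    "registry_to_csv",
    "registry_from_csv",
]


class UnknownAnalyteError(KeyError):
    """Name does not match any registry entry."""


class ExcludedAnalyteError(ValueError):
    """Analyte is in the registry but excluded from reporting."""


@dataclass(frozen=True)
class AminoAcidSpec:
    """One registry entry.

    Attributes
    ----------
    name : canonical lower-case species name
    mol_mass : average molecular mass of the free molecule, g/mol
    is_essential, is_bcaa : group membership flags
    reported : False for cysteine and aspartic acid
    exclusion_reason : why an unreported analyte is excluded (None otherwise)
    """

    name: str
    mol_mass: float
    is_essential: bool
    is_bcaa: bool
    reported: bool = True
    exclusion_reason: str | None = None


# name -> (mass g/mol, essential, bcaa)
_ESSENTIAL = {
    "histidine": 155.15,
    "isoleucine": 131.17,
    "leucine": 131.17,
    "lysine": 146.19,
    "methionine": 149.21,
    "phenylalanine": 165.19,
    "threonine": 119.12,
    "tryptophan": 204.23,
    "valine": 117.15,
}
_NONESSENTIAL = {
    "alanine": 89.09,
    "arginine": 174.20,
    "asparagine": 132.12,
    "citrulline": 175.19,
    "glutamic acid": 147.13,
    "glutamine": 146.15,
    "glycine": 75.07,
    "ornithine": 132.16,
    "proline": 115.13,
    "serine": 105.09,
    "taurine": 125.15,
    "tyrosine": 181.19,
}
_BCAA = frozenset({"leucine", "isoleucine", "valine"})

_EXCLUDED = {
    "cysteine": (121.16, "not reported due to instability in plasma"),
    "aspartic acid": (133.10, "not reported: concentrations below the limit of detection"),
}

REGISTRY: dict[str, AminoAcidSpec] = {}
for _n, _m in _ESSENTIAL.items():
    REGISTRY[_n] = AminoAcidSpec(_n, _m, True, _n in _BCAA)
for _n, _m in _NONESSENTIAL.items():
    REGISTRY[_n] = AminoAcidSpec(_n, _m, False, False)
for _n, (_m, _why) in _EXCLUDED.items():
    REGISTRY[_n] = AminoAcidSpec(_n, _m, False, False, reported=False, exclusion_reason=_why)

# three-letter codes (IUPAC where defined; Cit/Orn/Tau as used in clinical panels)
_THREE_LETTER = {
    "his": "histidine", "ile": "isoleucine", "leu": "leucine", "lys": "lysine",
    "met": "methionine", "phe": "phenylalanine", "thr": "threonine",
    "trp": "tryptophan", "val": "valine", "ala": "alanine", "arg": "arginine",
    "asn": "asparagine", "cit": "citrulline", "glu": "glutamic acid",
    "gln": "glutamine", "gly": "glycine", "orn": "ornithine", "pro": "proline",
    "ser": "serine", "tau": "taurine", "tyr": "tyrosine", "cys": "cysteine",
    "asp": "aspartic acid",
}


def canonical_name(name: str) -> str:
    """Resolve a full name or 3-letter code (case-insensitive) to the canonical name.

    One-letter codes are rejected: taurine, citrulline, and ornithine have no
    one-letter code, so single-letter input is ambiguous by construction.
    """
    key = name.strip().lower().replace("_", " ")
    if len(key) == 1:
        raise UnknownAnalyteError(
            f"one-letter code {name!r} rejected: not all panel species have one"
        )
    if key in REGISTRY:
        return key
    if key in _THREE_LETTER:
        return _THREE_LETTER[key]
    raise UnknownAnalyteError(f"unknown amino acid {name!r}")


def get_spec(name: str) -> AminoAcidSpec:
    """Look up a reported species; excluded analytes raise with the exclusion reason."""
    spec = REGISTRY[canonical_name(name)]
    if not spec.reported:
        raise ExcludedAnalyteError(f"{spec.name} is an excluded analyte: {spec.exclusion_reason}")
    return spec


def reported_species() -> list[str]:
    """Canonical names of the 21 reported species, essential first."""
    return [n for n, s in REGISTRY.items() if s.reported]


def essential_species() -> list[str]:
    return [n for n, s in REGISTRY.items() if s.reported and s.is_essential]


def nonessential_species() -> list[str]:
    return [n for n, s in REGISTRY.items() if s.reported and not s.is_essential]


def bcaa_species() -> list[str]:
    return [n for n, s in REGISTRY.items() if s.reported and s.is_bcaa]


def registry_to_csv(path: str | Path) -> None:
    """Serialize the registry (columns: name, mol_mass, group, bcaa, reported)."""
    rows = [
        {
            "name": s.name,
            "mol_mass": s.mol_mass,
            "group": "essential" if s.is_essential else "non-essential",
            "bcaa": s.is_bcaa,
            "reported": s.reported,
        }
        for s in REGISTRY.values()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def registry_from_csv(path: str | Path) -> dict[str, AminoAcidSpec]:
    """Read a registry CSV back into spec objects (exclusion reasons are not stored)."""
    df = pd.read_csv(path)
    out: dict[str, AminoAcidSpec] = {}
    for row in df.itertuples(index=False):
        out[row.name] = AminoAcidSpec(
            name=row.name,
            mol_mass=float(row.mol_mass),
            is_essential=row.group == "essential",
            is_bcaa=bool(row.bcaa),
            reported=bool(row.reported),
        )
    return out
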
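"""Putative lipid identification by accurate mass.

Monoisotopic masses are computed from elemental formulas (most-abundant
isotopes, via pyteomics), converted to singly charged cation adduct m/z
values ([M+H]+, [M+Na]+, [M+H-H2O]+, electron mass subtracted), and matched
against observed masses within a ppm tolerance.  Matches are tiered:
|error| < 1 ppm is the strictest identification tier ("sub_ppm"), 8-10 ppm
a loose tier ("loose"), anything else within the tolerance "within_10".

A lipid reference table (common glycerophospholipid and sphingomyelin
species with formulas and allowed adducts) ships with the package; no
online database access is required or performed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
from pyteomics import mass as _ptmass

__all__ = [
    "ELECTRON_MASS",
    "ADDUCT_DELTAS",
    "LipidRecord",
    "LipidMatch",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_error",
    "match_lipids",
    "load_lipid_table",
    "annotate",
]

ELECTRON_MASS = 0.000548579909  # Da

_PROTON = _ptmass.calculate_mass(formula="H") - ELECTRON_MASS
_H2O = _ptmass.calculate_mass(formula="H2O")

#: Mass deltas of the supported singly charged cation adducts (Da,
#: electron loss included).
ADDUCT_DELTAS = {
    "[M+H]+": _PROTON,
    "[M+Na]+": _ptmass.calculate_mass(formula="Na") - ELECTRON_MASS,
    "[M+H-H2O]+": _PROTON - _H2O,
}

_SUPPORTED = {"C", "H", "N", "O", "P", "S", "Na"}
_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def _normalize_adduct(label: str) -> str:
    label = label.replace("−", "-").replace(" ", "")
    label = label.replace("H2O", "H2O").replace("–", "-")
    return label


def monoisotopic_mass(formula: str) -> float:
    """Monoisotopic (most-abundant-isotope) mass of an elemental formula.

    Supports C, H, N, O, P, S and Na; an empty formula has mass 0.
    """
    if not formula:
        return 0.0
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if m.group(0) == "":
            continue
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = m.end()
        if m.group(1) not in _SUPPORTED:
            raise ValueError(f"unsupported element {m.group(1)!r} in {formula!r}")
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r}")
    return float(_ptmass.calculate_mass(formula=formula))


def adduct_mz(neutral_mass: float, adduct: str) -> float:
    """m/z of a singly charged cation adduct of a neutral of mass M."""
    if neutral_mass <= 0:
        raise ValueError("neutral mass must be positive")
    label = _normalize_adduct(adduct)
    if label not in ADDUCT_DELTAS:
        raise ValueError(f"unsupported adduct {adduct!r}; known: {list(ADDUCT_DELTAS)}")
    return float(neutral_mass + ADDUCT_DELTAS[label])


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass deviation in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical mass must be positive")
    return float((observed - theoretical) / theoretical * 1e6)


@dataclass(frozen=True)
class LipidRecord:
    """One reference lipid: short name, class, formula, allowed adducts."""

    name: str
    lipid_class: str
    formula: str
    adducts: tuple[str, ...] = ("[M+H]+", "[M+Na]+")
    theoretical_only: bool = False

    def __post_init__(self) -> None:
        monoisotopic_mass(self.formula)  # validates


@dataclass(frozen=True)
class LipidMatch:
    observed_mz: float
    record: LipidRecord | None
    adduct: str | None
    theoretical_mz: float | None
    ppm: float | None
    tier: str  # sub_ppm | loose | within_10 | none


def _tier(abs_ppm: float) -> str:
    if abs_ppm < 1.0:
        return "sub_ppm"
    if 8.0 <= abs_ppm <= 10.0:
        return "loose"
    return "within_10"


def load_lipid_table(path: str | Path | None = None) -> list[LipidRecord]:
    """Load the bundled (or a user-supplied) lipid reference TSV."""
    if path is None:
        ref = resources.files("lipidmsi").joinpath("data/lipid_library.tsv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    records = []
    for row in df.to_dict("records"):
        records.append(
            LipidRecord(
                name=str(row["name"]),
                lipid_class=str(row["lipid_class"]),
                formula=str(row["formula"]),
                adducts=tuple(str(row["adducts"]).split(";")),
                theoretical_only=bool(int(row["theoretical_only"])),
            )
        )
    return records


def match_lipids(
    observed_mz,
    db: list[LipidRecord] | None = None,
    adducts: dict[str, float] | None = None,
    tol_ppm: float = 10.0,
) -> list[LipidMatch]:
    """Match observed m/z values against the lipid table.

    Every (record, adduct) candidate within ``tol_ppm`` is returned,
    ranked per observed mass by absolute ppm error (ties broken by name
    for stability); an observed mass without any candidate yields one
    entry with tier ``"none"``.
    """
    db = db if db is not None else load_lipid_table()
    if not db:
        raise ValueError("lipid database is empty")
    allowed = adducts or ADDUCT_DELTAS
    try:
        iter(observed_mz)
        observed = list(observed_mz)
    except TypeError:
        observed = [observed_mz]

    theo = []  # (theoretical_mz, record, adduct)
    for rec in db:
        m = monoisotopic_mass(rec.formula)
        for add in rec.adducts:
            label = _normalize_adduct(add)
            if label in allowed:
                theo.append((adduct_mz(m, label), rec, label))

    out: list[LipidMatch] = []
    for obs in observed:
        hits = []
        for tmz, rec, add in theo:
            ppm = ppm_error(obs, tmz)
            if abs(ppm) <= tol_ppm:
                hits.append(
                    LipidMatch(
                        observed_mz=float(obs),
                        record=rec,
                        adduct=add,
                        theoretical_mz=tmz,
                        ppm=ppm,
                        tier=_tier(abs(ppm)),
                    )
                )
        hits.sort(key=lambda h: (abs(h.ppm), h.record.name))
        if hits:
            out.extend(hits)
        else:
            out.append(LipidMatch(float(obs), None, None, None, None, "none"))
    return out


def annotate(
    observed_mz,
    db: list[LipidRecord] | None = None,
    tol_ppm: float = 10.0,
) -> pd.DataFrame:
    """Best-hit annotation table for a list of observed masses."""
    matches = match_lipids(observed_mz, db=db, tol_ppm=tol_ppm)
    best: dict[float, LipidMatch] = {}
    for m in matches:
        if m.observed_mz not in best:
            best[m.observed_mz] = m
    rows = []
    for obs, m in best.items():
        rows.append(
            {
                "mz": obs,
                "id": m.record.name if m.record else "n.i.",
                "adduct": m.adduct or "",
                "theoretical_mz": m.theoretical_mz,
                "ppm": m.ppm,
                "tier": m.tier,
            }
        )
    return pd.DataFrame(rows)
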
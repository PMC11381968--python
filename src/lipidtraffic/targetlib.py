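"""Combinatorial lipid target libraries and m/z-Rt feature matching.

Lipid identities are handled at sum-composition level: a class plus total
acyl/sphingoid carbons and total double bonds, e.g. ``PC(34:1)``.  For each
class a molecular-formula rule maps (carbons, double bonds) to an elemental
formula; the monoisotopic mass is summed from an internal registry of
atomic masses, and adduct m/z values follow the charged-species convention
(the electron mass is part of the adduct shift, since it matters at the
third decimal place).

Triglycerides lose an acyl chain in the ion source, producing DG-like
fragment ions; these are generated as derived entries carrying a
``parent_id`` so that downstream traffic analysis can collapse them onto
their parent TG sum composition.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .signal_sheet import SignalSheet

__all__ = [
    "LipidSpecies",
    "AdductDef",
    "TargetEntry",
    "MatchReport",
    "TargetLibError",
    "monoisotopic_mass",
    "species_formula",
    "adduct_mz",
    "neutral_mass_from_mz",
    "build_library",
    "match_features",
    "read_library",
    "write_library",
    "ADDUCTS",
    "DEFAULT_CLASS_RANGES",
    "DEFAULT_RT_WINDOWS",
]


class TargetLibError(ValueError):
    pass


# Monoisotopic atomic masses, Da (CODATA/IUPAC 2021, >= 6 d.p.).
ATOMIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "Na": 22.9897692809,
}
ELECTRON_MASS = 0.00054857991
PROTON_MASS = ATOMIC_MASS["H"] - ELECTRON_MASS  # 1.00727646


def monoisotopic_mass(formula: Mapping[str, int]) -> float:
    """Monoisotopic mass (Da) of an elemental formula by atom summation."""
    total = 0.0
    for elem, count in formula.items():
        if elem not in ATOMIC_MASS:
            raise TargetLibError(f"unknown element {elem!r}")
        if count < 0:
            raise TargetLibError(f"negative count for element {elem!r}")
        total += count * ATOMIC_MASS[elem]
    return total


# Formula rules per lipid class: (carbons n, double bonds d) -> formula.
# Each rule gives the sum-composition molecular formula of the intact lipid;
# for Cer the sphingoid backbone is included in n and d.
_CLASS_RULES = {
    "TG": lambda n, d: {"C": n + 3, "H": 2 * n - 2 * d + 2, "O": 6},
    "DG": lambda n, d: {"C": n + 3, "H": 2 * n - 2 * d + 4, "O": 5},
    "PC": lambda n, d: {"C": n + 8, "H": 2 * n - 2 * d + 16, "N": 1, "O": 8, "P": 1},
    "PE": lambda n, d: {"C": n + 5, "H": 2 * n - 2 * d + 10, "N": 1, "O": 8, "P": 1},
    "PG": lambda n, d: {"C": n + 6, "H": 2 * n - 2 * d + 11, "O": 10, "P": 1},
    "PI": lambda n, d: {"C": n + 9, "H": 2 * n - 2 * d + 15, "O": 13, "P": 1},
    "PS": lambda n, d: {"C": n + 6, "H": 2 * n - 2 * d + 10, "N": 1, "O": 10, "P": 1},
    "Cer": lambda n, d: {"C": n, "H": 2 * n - 2 * d + 1, "N": 1, "O": 3},
    # free fatty acid; used for in-source neutral losses from TGs
    "FA": lambda n, d: {"C": n, "H": 2 * n - 2 * d, "O": 2},
}

LIPID_CLASSES = tuple(c for c in _CLASS_RULES if c not in ("FA", "DG"))


def species_formula(lipid_class: str, carbons: int, double_bonds: int) -> dict[str, int]:
    """Elemental formula of a sum-composition lipid species."""
    if lipid_class not in _CLASS_RULES:
        raise TargetLibError(f"unknown lipid class {lipid_class!r}")
    if carbons < 2:
        raise TargetLibError(f"carbons must be >= 2, got {carbons}")
    if double_bonds < 0:
        raise TargetLibError(f"double_bonds must be >= 0, got {double_bonds}")
    formula = _CLASS_RULES[lipid_class](carbons, double_bonds)
    if formula["H"] <= 0:
        raise TargetLibError(
            f"{lipid_class}({carbons}:{double_bonds}) is chemically impossible "
            f"(hydrogen count {formula['H']})"
        )
    return formula


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid at sum-composition level, e.g. TG(52:2)."""

    lipid_class: str
    carbons: int
    double_bonds: int
    formula: tuple[tuple[str, int], ...] = field(default=())
    neutral_mass: float = 0.0

    @classmethod
    def make(cls, lipid_class: str, carbons: int, double_bonds: int) -> "LipidSpecies":
        f = species_formula(lipid_class, carbons, double_bonds)
        return cls(
            lipid_class,
            carbons,
            double_bonds,
            formula=tuple(sorted(f.items())),
            neutral_mass=monoisotopic_mass(f),
        )

    @property
    def name(self) -> str:
        return f"{self.lipid_class}({self.carbons}:{self.double_bonds})"

    def formula_dict(self) -> dict[str, int]:
        return dict(self.formula)


@dataclass(frozen=True)
class AdductDef:
    """A positive-ionisation adduct: name, mass shift (Da, electron-corrected), charge."""

    name: str
    mass_shift: float
    charge: int = 1

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise TargetLibError(f"adduct {self.name!r}: charge must be >= 1")


ADDUCTS: dict[str, AdductDef] = {
    "[M+H]+": AdductDef("[M+H]+", PROTON_MASS, 1),
    "[M+NH4]+": AdductDef(
        "[M+NH4]+",
        ATOMIC_MASS["N"] + 4 * ATOMIC_MASS["H"] - ELECTRON_MASS,
        1,
    ),
    "[M+Na]+": AdductDef("[M+Na]+", ATOMIC_MASS["Na"] - ELECTRON_MASS, 1),
}


def adduct_mz(neutral_mass: float, adduct: AdductDef) -> float:
    """m/z of an adduct ion: (M + shift) / z."""
    if neutral_mass < 0:
        raise TargetLibError("neutral_mass must be >= 0")
    return (neutral_mass + adduct.mass_shift) / adduct.charge


def neutral_mass_from_mz(mz: float, adduct: AdductDef) -> float:
    """Inverse of :func:`adduct_mz` (exact up to float rounding)."""
    return mz * adduct.charge - adduct.mass_shift


@dataclass(frozen=True)
class TargetEntry:
    """One row of the target library: a (species, adduct) ion with its window."""

    lipid_id: str
    species: LipidSpecies
    adduct: AdductDef
    mz: float
    rt_window: tuple[float, float]
    parent_id: str = ""

    def __post_init__(self) -> None:
        if not self.rt_window[0] < self.rt_window[1]:
            raise TargetLibError(
                f"{self.lipid_id}: rt_window low must be < high, got {self.rt_window}"
            )


# Default sum-composition ranges per class: (carbon range, double-bond range).
# Chosen to span the compositions seen for animal, plant and fungal lipidomes
# in positive-mode LCMS, yielding a library of around 7.5k target ions with
# the three default adducts and TG in-source fragments included.
DEFAULT_CLASS_RANGES: dict[str, tuple[range, range]] = {
    "TG": (range(38, 69), range(0, 13)),
    "PC": (range(26, 45), range(0, 9)),
    "PE": (range(26, 45), range(0, 9)),
    "PG": (range(26, 45), range(0, 9)),
    "PI": (range(26, 45), range(0, 9)),
    "PS": (range(26, 45), range(0, 9)),
    "Cer": (range(26, 49), range(0, 5)),
}

# Wide class-level Rt windows (min) inside the 0.5-18.5 min acquisition span;
# phospholipids and ceramides elute earlier than triglycerides on C18.
DEFAULT_RT_WINDOWS: dict[str, tuple[float, float]] = {
    "TG": (6.0, 18.5),
    "DG": (4.0, 16.0),
    "PC": (0.5, 10.0),
    "PE": (0.5, 10.0),
    "PG": (0.5, 10.0),
    "PI": (0.5, 10.0),
    "PS": (0.5, 10.0),
    "Cer": (0.5, 12.0),
}

DEFAULT_MASS_RANGE = (400.0, 1200.0)

# Acyl (fatty-acid) neutral losses generating DG fragment ions from TGs;
# the dominant C16/C18/C20 chains with 0-2 double bonds.
DEFAULT_FRAGMENT_ACYLS: tuple[tuple[int, int], ...] = tuple(
    (k, j) for k in (16, 18, 20) for j in (0, 1, 2)
)


def build_library(
    class_ranges: Mapping[str, tuple[Iterable[int], Iterable[int]]] | None = None,
    adducts: Sequence[str | AdductDef] = ("[M+H]+", "[M+NH4]+", "[M+Na]+"),
    mass_range: tuple[float, float] = DEFAULT_MASS_RANGE,
    rt_windows: Mapping[str, tuple[float, float]] | None = None,
    include_dg_fragments: bool = True,
    fragment_acyls: Sequence[tuple[int, int]] = DEFAULT_FRAGMENT_ACYLS,
    max_db_fraction: float = 0.5,
) -> list[TargetEntry]:
    """Build a combinatorial target library.

    One entry is emitted per (species, adduct) whose m/z falls inside
    ``mass_range``; species with more than ``max_db_fraction * carbons``
    double bonds are skipped as implausible.  With ``include_dg_fragments``,
    each TG additionally yields [M+H - fatty acid]+ DG fragment entries (one
    per acyl loss in ``fragment_acyls`` that leaves a valid DG), linked to
    the parent TG via ``parent_id``.
    """
    class_ranges = dict(class_ranges) if class_ranges is not None else {
        k: (list(v[0]), list(v[1])) for k, v in DEFAULT_CLASS_RANGES.items()
    }
    rt_windows = dict(rt_windows or DEFAULT_RT_WINDOWS)
    lo, hi = mass_range
    if not lo < hi:
        raise TargetLibError(f"invalid mass_range {mass_range}")
    adefs = [a if isinstance(a, AdductDef) else ADDUCTS[a] for a in adducts]
    if not adefs:
        raise TargetLibError("at least one adduct required")

    entries: list[TargetEntry] = []
    for cls_name, (carbon_range, db_range) in class_ranges.items():
        if cls_name not in rt_windows:
            raise TargetLibError(f"no rt window for class {cls_name!r}")
        window = rt_windows[cls_name]
        for n, d in itertools.product(carbon_range, db_range):
            if d > max_db_fraction * n:
                continue
            try:
                sp = LipidSpecies.make(cls_name, n, d)
            except TargetLibError:
                continue
            for ad in adefs:
                mz = adduct_mz(sp.neutral_mass, ad)
                if lo <= mz <= hi:
                    entries.append(
                        TargetEntry(
                            lipid_id=f"{sp.name} {ad.name}",
                            species=sp,
                            adduct=ad,
                            mz=mz,
                            rt_window=window,
                        )
                    )
            if include_dg_fragments and cls_name == "TG":
                entries.extend(_dg_fragments(sp, fragment_acyls, (lo, hi), rt_windows))
    if not entries:
        raise TargetLibError("library is empty after mass-range filtering")
    return entries


def _dg_fragments(
    tg: LipidSpecies,
    fragment_acyls: Sequence[tuple[int, int]],
    mass_range: tuple[float, float],
    rt_windows: Mapping[str, tuple[float, float]],
) -> list[TargetEntry]:
    """DG-like in-source fragment ions [M+H - RCOOH]+ for one TG species."""
    out = []
    proton = ADDUCTS["[M+H]+"]
    window = rt_windows.get("DG", rt_windows.get("TG", (0.5, 18.5)))
    for k, j in fragment_acyls:
        n, d = tg.carbons - k, tg.double_bonds - j
        if n < 14 or d < 0:  # remaining DG must itself be plausible
            continue
        fa_mass = monoisotopic_mass(species_formula("FA", k, j))
        mz = adduct_mz(tg.neutral_mass, proton) - fa_mass
        if mass_range[0] <= mz <= mass_range[1]:
            out.append(
                TargetEntry(
                    lipid_id=f"DG({n}:{d}) [M+H-FA({k}:{j})]+ <- {tg.name}",
                    species=tg,
                    adduct=proton,
                    mz=mz,
                    rt_window=window,
                    parent_id=tg.name,
                )
            )
    return out


# -- library I/O -----------------------------------------------------------

_LIB_COLUMNS = (
    "lipid_id",
    "class",
    "carbons",
    "double_bonds",
    "adduct",
    "formula",
    "mz",
    "rt_low",
    "rt_high",
    "parent_id",
)


def _formula_str(formula: Mapping[str, int]) -> str:
    return "".join(
        f"{el}{c}" for el, c in sorted(formula.items()) if c
    )


def write_library(entries: Sequence[TargetEntry], path: str | Path) -> None:
    rows = []
    for e in entries:
        rows.append(
            {
                "lipid_id": e.lipid_id,
                "class": e.species.lipid_class,
                "carbons": e.species.carbons,
                "double_bonds": e.species.double_bonds,
                "adduct": e.adduct.name,
                "formula": _formula_str(e.species.formula_dict()),
                "mz": repr(e.mz),
                "rt_low": e.rt_window[0],
                "rt_high": e.rt_window[1],
                "parent_id": e.parent_id,
            }
        )
    pd.DataFrame(rows, columns=list(_LIB_COLUMNS)).to_csv(path, index=False)


def read_library(path: str | Path) -> list[TargetEntry]:
    df = pd.read_csv(path, dtype={"parent_id": str}, keep_default_na=False)
    missing = [c for c in _LIB_COLUMNS if c not in df.columns]
    if missing:
        raise TargetLibError(f"library file {path} lacks columns {missing}")
    out = []
    for _, r in df.iterrows():
        sp = LipidSpecies.make(r["class"], int(r["carbons"]), int(r["double_bonds"]))
        ad = ADDUCTS.get(str(r["adduct"]))
        if ad is None:
            raise TargetLibError(f"unknown adduct {r['adduct']!r} in {path}")
        out.append(
            TargetEntry(
                lipid_id=str(r["lipid_id"]),
                species=sp,
                adduct=ad,
                mz=float(r["mz"]),
                rt_window=(float(r["rt_low"]), float(r["rt_high"])),
                parent_id=str(r["parent_id"]),
            )
        )
    return out


# -- feature matching ------------------------------------------------------


@dataclass
class MatchReport:
    """Summary of a matching run."""

    n_features: int
    n_below_area_threshold: int
    n_matched: int
    n_unmatched: int
    n_ambiguous: int
    assignments: dict[str, str]  # feature_id -> lipid_id
    ambiguous: list[str]

    def to_dict(self) -> dict:
        return {
            "n_features": self.n_features,
            "n_below_area_threshold": self.n_below_area_threshold,
            "n_matched": self.n_matched,
            "n_unmatched": self.n_unmatched,
            "n_ambiguous": self.n_ambiguous,
        }


def match_features(
    sheet: SignalSheet,
    library: Sequence[TargetEntry],
    mz_tol: float = 0.001,
    mz_tol_mode: str = "absolute",
    rt_mode: str = "window",
    rt_halfwidth: float = 0.25,
    area_threshold: float = 100_000.0,
) -> tuple[SignalSheet, MatchReport]:
    """Annotate sheet features with target-library identities.

    A feature matches an entry when |dmz| <= ``mz_tol`` (Da in ``absolute``
    mode, parts-per-million in ``ppm`` mode) and its Rt lies inside the
    entry's window (``rt_mode="window"``) or within ``rt_halfwidth`` minutes
    of the window centre (``rt_mode="tolerance"``).  Ties are broken by
    smallest |dmz|, then smallest |dRt to window centre|; exact ties are
    flagged ambiguous and left unassigned.  Features whose maximum intensity
    falls below ``area_threshold`` are excluded before matching.  DG
    in-source fragment entries annotate the feature with their parent TG
    identity so that traffic analysis counts them with the intact TG.
    """
    if mz_tol <= 0:
        raise TargetLibError("mz_tol must be > 0")
    if rt_mode not in ("window", "tolerance"):
        raise TargetLibError(f"unknown rt_mode {rt_mode!r}")

    lib_mz = np.array([e.mz for e in library])
    order = np.argsort(lib_mz, kind="stable")

    assignments: dict[str, str] = {}
    classes: dict[str, str] = {}
    ambiguous: list[str] = []
    n_below = 0
    max_int = sheet.intensities.max(axis=1) if sheet.intensities.size else np.zeros(
        len(sheet.features)
    )
    for i, feat in enumerate(sheet.features):
        if max_int[i] < area_threshold:
            n_below += 1
            continue
        tol = mz_tol if mz_tol_mode == "absolute" else mz_tol * 1e-6 * feat.mz
        lo = np.searchsorted(lib_mz[order], feat.mz - tol, side="left")
        hi = np.searchsorted(lib_mz[order], feat.mz + tol, side="right")
        candidates = []
        for idx in order[lo:hi]:
            e = library[idx]
            centre = 0.5 * (e.rt_window[0] + e.rt_window[1])
            if rt_mode == "window":
                if not (e.rt_window[0] <= feat.rt <= e.rt_window[1]):
                    continue
            else:
                if abs(feat.rt - centre) > rt_halfwidth:
                    continue
            candidates.append((abs(feat.mz - e.mz), abs(feat.rt - centre), e))
        if not candidates:
            continue
        candidates.sort(key=lambda c: (c[0], c[1], c[2].lipid_id))
        if len(candidates) > 1 and candidates[0][:2] == candidates[1][:2]:
            ambiguous.append(feat.feature_id)
            continue
        best = candidates[0][2]
        # collapse DG fragments onto the parent TG sum composition
        identity = best.parent_id if best.parent_id else best.species.name
        assignments[feat.feature_id] = identity
        classes[feat.feature_id] = (
            "TG" if best.parent_id else best.species.lipid_class
        )
    annotated = sheet.with_annotations(assignments, classes)
    n_considered = len(sheet.features) - n_below
    report = MatchReport(
        n_features=len(sheet.features),
        n_below_area_threshold=n_below,
        n_matched=len(assignments),
        n_unmatched=n_considered - len(assignments) - len(ambiguous),
        n_ambiguous=len(ambiguous),
        assignments=assignments,
        ambiguous=sorted(ambiguous),
    )
    return annotated, report
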
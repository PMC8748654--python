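"""Lipid species, shorthand-name parsing, molecular formulas and isotopes.

Species are named in Lipidomics Standard Initiative shorthand, i.e. lipid
class followed by total fatty-acyl carbons and total double bonds
("SM 41:1", "PC O-36:3").  For each supported class a formula template maps
(carbons, double bonds) to an elemental composition, from which exact m/z
values (protonated adduct) and isotope envelopes are computed with NIST
monoisotopic masses and natural abundances.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from pyteomics import mass as _pmass

PROTON_MASS = 1.00727646688
#: m/z spacing of successive isotopologue peaks (13C - 12C)
ISOTOPE_SPACING = _pmass.nist_mass["C"][13][0] - _pmass.nist_mass["C"][12][0]

# formula templates: class -> (C offset, H offset, d(H)/d(db) = -2 implied,
# heteroatom counts).  H = 2*C_acyl + h_off - 2*db.
_TEMPLATES: dict[str, dict] = {
    "PC":    dict(c=8, h=16, N=1, O=8, P=1),
    "PC O-": dict(c=8, h=18, N=1, O=7, P=1),
    "LPC":   dict(c=8, h=18, N=1, O=7, P=1),
    "PE":    dict(c=5, h=10, N=1, O=8, P=1),
    "LPE":   dict(c=5, h=12, N=1, O=7, P=1),
    "SM":    dict(c=5, h=13, N=2, O=6, P=1),
    "Cer":   dict(c=0, h=1,  N=1, O=3),
    "HexCer": dict(c=6, h=11, N=1, O=8),
    "DG":    dict(c=3, h=4,  O=5),
    "TG":    dict(c=3, h=2,  O=6),
    "CE":    dict(c=27, h=44, O=2),
}

_NAME_RE = re.compile(r"^([A-Za-z]+)\s+(O-|P-)?(\d+):(\d+)$")


def parse_name(name: str) -> tuple[str, int, int]:
    """Split an LSI shorthand name into (class, carbons, double bonds)."""
    m = _NAME_RE.match(name.strip())
    if m is None:
        raise ValueError(f"cannot parse lipid name {name!r}")
    cls = m.group(1) + (f" {m.group(2)}" if m.group(2) else "")
    return cls, int(m.group(3)), int(m.group(4))


def formula_for(name: str) -> dict[str, int]:
    """Elemental composition of the neutral species for a shorthand name."""
    cls, carbons, dbs = parse_name(name)
    if cls not in _TEMPLATES:
        raise ValueError(f"no formula template for lipid class {cls!r}")
    t = _TEMPLATES[cls]
    comp = {"C": carbons + t["c"], "H": 2 * carbons + t["h"] - 2 * dbs}
    for el in ("N", "O", "P", "S"):
        if t.get(el):
            comp[el] = t[el]
    if comp["H"] <= 0:
        raise ValueError(f"unphysical composition for {name!r}")
    return comp


def format_formula(formula: dict[str, int]) -> str:
    """Hill-order formula string ("C46H93N2O6P") for CSV serialization."""
    elements = sorted(formula, key=lambda el: (el != "C", el != "H", el))
    return "".join(f"{el}{n if n != 1 else ''}" for el, n in ((e, formula[e]) for e in elements) if n)


def monoisotopic_mass(formula: dict[str, int]) -> float:
    total = 0.0
    for el, n in formula.items():
        isotopes = _pmass.nist_mass[el]
        mono = min(k for k in isotopes if k != 0 and isotopes[k][1] > 0)
        total += n * isotopes[mono][0]
    return total


def _element_distribution(el: str, nmax: int) -> np.ndarray:
    """Abundance by nominal mass shift (0..nmax) for one atom of ``el``."""
    isotopes = _pmass.nist_mass[el]
    keys = [k for k in isotopes if k != 0 and isotopes[k][1] > 0]
    mono = min(keys)
    dist = np.zeros(nmax + 1)
    for k in keys:
        shift = k - mono
        if shift <= nmax:
            dist[shift] = isotopes[k][1]
    return dist


def _power_truncated(p: np.ndarray, n: int, nmax: int) -> np.ndarray:
    """p convolved with itself n times, truncated at shift nmax."""
    result = np.zeros(nmax + 1)
    result[0] = 1.0
    base = p.copy()
    while n:
        if n & 1:
            result = np.convolve(result, base)[: nmax + 1]
        n >>= 1
        if n:
            base = np.convolve(base, base)[: nmax + 1]
    return result


def isotope_envelope(formula: dict[str, int], nmax: int = 2) -> np.ndarray:
    """Fractional abundances of the M+0 .. M+nmax isotopologues.

    Fractions are relative to all isotopologues of the molecule, so they sum
    to < 1 when heavier isotopologues than M+nmax exist.  Truncating the
    convolution at nmax is exact for the retained terms.
    """
    env = np.zeros(nmax + 1)
    env[0] = 1.0
    for el, n in formula.items():
        env = np.convolve(env, _power_truncated(_element_distribution(el, nmax), n, nmax))[: nmax + 1]
    return env


@dataclass(frozen=True)
class LipidSpecies:
    """A quantifiable lipid (or internal standard) with its ion identity."""

    name: str
    lipid_class: str
    formula: dict[str, int] = field(compare=False)
    adduct: str = "[M+H]+"
    exact_mz: float = 0.0
    is_internal_standard: bool = False

    def __post_init__(self):
        if self.exact_mz <= 0:
            raise ValueError(f"{self.name}: exact m/z must be positive")

    @classmethod
    def from_name(cls, name: str, is_internal_standard: bool = False) -> "LipidSpecies":
        lipid_class, _, _ = parse_name(name)
        formula = formula_for(name)
        mz = monoisotopic_mass(formula) + PROTON_MASS
        return cls(name, lipid_class, formula, "[M+H]+", mz, is_internal_standard)


class LipidDatabase:
    """Ordered collection of :class:`LipidSpecies` with class-window lookup."""

    def __init__(self, species: list[LipidSpecies]):
        names = [s.name for s in species]
        if len(set(names)) != len(names):
            raise ValueError("duplicate species names in database")
        self._species = list(species)
        self._by_name = {s.name: s for s in species}

    def __len__(self) -> int:
        return len(self._species)

    def __iter__(self):
        return iter(self._species)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def get(self, name: str) -> LipidSpecies:
        return self._by_name[name]

    @property
    def classes(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self._species:
            seen.setdefault(s.lipid_class, None)
        return list(seen)

    def class_window(self, lipid_class: str) -> list[LipidSpecies]:
        return [s for s in self._species if s.lipid_class == lipid_class]

    def internal_standard(self, lipid_class: str) -> LipidSpecies | None:
        for s in self._species:
            if s.lipid_class == lipid_class and s.is_internal_standard:
                return s
        return None

    def analytes(self) -> list[LipidSpecies]:
        return [s for s in self._species if not s.is_internal_standard]

    # -- I/O ---------------------------------------------------------------
    def to_csv(self, path) -> None:
        import pandas as pd

        rows = [
            dict(
                name=s.name,
                lipid_class=s.lipid_class,
                formula=format_formula(s.formula),
                adduct=s.adduct,
                exact_mz=s.exact_mz,
                is_internal_standard=int(s.is_internal_standard),
            )
            for s in self._species
        ]
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LipidDatabase":
        import pandas as pd

        df = pd.read_csv(path)
        species = [
            LipidSpecies(
                name=r["name"],
                lipid_class=r["lipid_class"],
                formula=dict(_pmass.Composition(formula=r["formula"])),
                adduct=r["adduct"],
                exact_mz=float(r["exact_mz"]),
                is_internal_standard=bool(r["is_internal_standard"]),
            )
            for r in df.to_dict("records")
        ]
        return cls(species)


#: the seven most relevant dysregulated marker species (all down in cases)
MARKER_SPECIES = (
    "SM 41:1",
    "SM 42:1",
    "SM 39:1",
    "Cer 41:1",
    "Cer 42:1",
    "LPC 18:2",
    "PC O-36:3",
)

#: per-class internal standards (exogenous, short-chain) and default spiked
#: concentrations in nmol/mL of serum
DEFAULT_IS_TABLE: dict[str, tuple[str, float]] = {
    "PC": ("PC 28:0", 10.0),
    "PC O-": ("PC O-28:0", 2.0),
    "LPC": ("LPC 13:0", 2.0),
    "PE": ("PE 28:0", 2.0),
    "SM": ("SM 30:1", 5.0),
    "Cer": ("Cer 30:1", 1.0),
    "TG": ("TG 45:0", 10.0),
    "CE": ("CE 12:0", 20.0),
}

# carbon/double-bond grids used to enumerate plausible null species per class
_NULL_GRIDS: dict[str, tuple[range, range]] = {
    "PC": (range(30, 43), range(0, 5)),
    "LPC": (range(14, 23), range(0, 3)),
    "PE": (range(32, 41), range(1, 4)),
    "SM": (range(32, 44), range(1, 3)),
    "Cer": (range(34, 45), range(1, 3)),
    "TG": (range(48, 57), range(1, 4)),
    "CE": (range(14, 21), range(0, 3)),
}


def default_species_names(n_species: int = 157) -> list[str]:
    """The seven marker species plus deterministically enumerated nulls."""
    reserved = set(MARKER_SPECIES) | {name for name, _ in DEFAULT_IS_TABLE.values()}
    names = list(MARKER_SPECIES)
    classes = list(_NULL_GRIDS)
    # round-robin over classes so every class contributes species
    def _grid(cls: str):
        carbons, dbs = _NULL_GRIDS[cls]
        for c in carbons:
            for d in dbs:
                yield f"{cls} {c}:{d}"

    iters = {cls: _grid(cls) for cls in classes}
    while len(names) < n_species and iters:
        for cls in list(iters):
            try:
                cand = next(iters[cls])
            except StopIteration:
                del iters[cls]
                continue
            if cand not in reserved and cand not in names:
                names.append(cand)
                if len(names) == n_species:
                    break
    if len(names) < n_species:
        raise ValueError(f"can only enumerate {len(names)} species, asked for {n_species}")
    return names


def default_database(n_species: int = 157) -> LipidDatabase:
    """Database of ``n_species`` analytes plus one internal standard per class."""
    names = default_species_names(n_species)
    species = [LipidSpecies.from_name(n) for n in names]
    used_classes = {s.lipid_class for s in species}
    for cls, (is_name, _conc) in DEFAULT_IS_TABLE.items():
        if cls in used_classes:
            species.append(LipidSpecies.from_name(is_name, is_internal_standard=True))
    return LipidDatabase(species)
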
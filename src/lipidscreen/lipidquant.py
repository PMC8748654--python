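"""Peak-list processing and internal-standard quantitation.

Reimplements the identification/quantitation logic of a laboratory
lipid-quantitation workflow: intensity thresholding of centroided peak
lists, assignment of peaks to database lipids within a mass tolerance,
isotope correction, and conversion of intensity ratios against the
class internal standard into molar concentrations (nmol/mL).

Isotope correction runs two steps.  Type II removes the M+2 isotopologue
of the same-class species with one more double bond (whose M+2 peak falls
2.0034 Th above its monoisotopic mass and is co-assigned with the species
two hydrogens heavier, since typical instrument windows cannot resolve the
8.9 mDa difference).  Type I then divides each intensity by the
monoisotopic fraction of the species' isotope envelope so that intensities
represent the whole isotopologue population.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .containers import ABSENT, MEASURED, ConcentrationMatrix
from .lipids import LipidDatabase, LipidSpecies, isotope_envelope, parse_name

logger = logging.getLogger(__name__)

#: extraction threshold in counts, as used by the study's data processing
DEFAULT_INTENSITY_THRESHOLD = 3000.0
#: database-matching mass tolerance in mDa
DEFAULT_TOLERANCE_MDA = 5.0


@dataclass
class PeakList:
    """Centroided m/z-intensity pairs for one sample and one class window."""

    sample_id: str
    class_window: str
    peaks: np.ndarray  # (n, 2) columns: m/z [Th], intensity [counts]

    def __post_init__(self) -> None:
        self.peaks = np.asarray(self.peaks, dtype=float).reshape(-1, 2)
        if len(self.peaks):
            if np.any(self.peaks[:, 0] <= 0):
                raise ValueError("m/z values must be strictly positive")
            if np.any(self.peaks[:, 1] < 0):
                raise ValueError("intensities must be non-negative")
            if np.any(np.diff(self.peaks[:, 0]) < 0):
                self.peaks = self.peaks[np.argsort(self.peaks[:, 0], kind="stable")]

    def __len__(self) -> int:
        return len(self.peaks)

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.peaks, columns=["mz", "intensity"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path, sample_id: str, class_window: str) -> "PeakList":
        df = pd.read_csv(path, sep="\t")
        return cls(sample_id, class_window, df[["mz", "intensity"]].to_numpy())


@dataclass
class Assignment:
    """A peak attributed to a database species."""

    mz: float
    intensity: float
    species: LipidSpecies
    delta_mz: float            # mDa, measured - exact
    corrected_intensity: float


def threshold_peaks(pl: PeakList, min_intensity: float = DEFAULT_INTENSITY_THRESHOLD) -> PeakList:
    """Keep only peaks with intensity strictly above ``min_intensity``."""
    if min_intensity < 0:
        raise ValueError("min_intensity must be >= 0")
    kept = pl.peaks[pl.peaks[:, 1] > min_intensity]
    return PeakList(pl.sample_id, pl.class_window, kept.copy())


def match_peaks(
    pl: PeakList,
    db: LipidDatabase,
    tolerance: float = DEFAULT_TOLERANCE_MDA,
) -> list[Assignment]:
    """Assign peaks to database species of the peak list's class window.

    A peak qualifies for a species when ``|mz - exact_mz| <= tolerance``
    (tolerance in mDa, boundary inclusive).  Each peak goes to its nearest
    species (ties to the lower exact m/z); each species keeps the most
    intense of its qualifying peaks.
    """
    if len(db) == 0:
        raise ValueError("empty database")
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    window = db.class_window(pl.class_window)
    if not window:
        return []
    tol_th = tolerance / 1000.0

    exact = np.array([s.exact_mz for s in window])
    order = np.argsort(exact, kind="stable")
    sorted_mz = exact[order]
    gaps = np.diff(sorted_mz)
    close = np.nonzero(gaps < 2 * tol_th)[0]
    for i in close:
        logger.warning(
            "database entries %s and %s are %.2f mDa apart (< 2x tolerance); "
            "nearest-m/z wins",
            window[order[i]].name,
            window[order[i + 1]].name,
            gaps[i] * 1000.0,
        )

    best: dict[str, Assignment] = {}
    for mz, intensity in pl.peaks:
        deltas = np.abs(exact - mz)
        # nearest species; exact ties resolved toward the lower exact m/z
        candidates = np.nonzero(deltas == deltas.min())[0]
        idx = candidates[np.argmin(exact[candidates])]
        if deltas[idx] > tol_th:
            continue
        species = window[idx]
        assignment = Assignment(
            mz=float(mz),
            intensity=float(intensity),
            species=species,
            delta_mz=float((mz - species.exact_mz) * 1000.0),
            corrected_intensity=float(intensity),
        )
        prev = best.get(species.name)
        if prev is None or assignment.intensity > prev.intensity:
            best[species.name] = assignment
    # report in database (window) order for determinism
    return [best[s.name] for s in window if s.name in best]


def isotope_correct(
    assignments: list[Assignment],
    db: LipidDatabase,
    type_ii: bool = True,
    type_i: bool = True,
) -> list[Assignment]:
    """Apply type II (M+2 overlap) and type I (envelope) isotope correction.

    Corrected intensities are floored at zero; the input assignments are
    not modified.
    """
    for a in assignments:
        if not a.species.formula:
            raise ValueError(f"no molecular formula for species {a.species.name}")

    by_name = {a.species.name: a for a in assignments}
    corrected: dict[str, float] = {a.species.name: a.intensity for a in assignments}

    if type_ii:
        # subtract, from each species, the M+2 contribution of the species
        # with one more double bond (one nominal mass unit pair lower);
        # process in ascending double-bond-donor mass so chains propagate
        for a in sorted(assignments, key=lambda x: x.species.exact_mz):
            name = a.species.name
            cls, carbons, dbs = parse_name(name)
            donor_name = _format_name(cls, carbons, dbs + 1)
            donor = by_name.get(donor_name)
            if donor is None or donor.species.lipid_class != a.species.lipid_class:
                continue
            env = isotope_envelope(donor.species.formula)
            donor_mono = corrected[donor_name]
            overlap = donor_mono * (env[2] / env[0]) if env[0] > 0 else 0.0
            corrected[name] = max(corrected[name] - overlap, 0.0)

    if type_i:
        for a in assignments:
            env = isotope_envelope(a.species.formula)
            f0 = env[0]
            if f0 <= 0:
                raise ValueError(f"degenerate isotope envelope for {a.species.name}")
            corrected[a.species.name] = max(corrected[a.species.name] / f0, 0.0)

    return [
        replace(a, corrected_intensity=float(corrected[a.species.name]))
        for a in assignments
    ]


def _format_name(cls: str, carbons: int, dbs: int) -> str:
    if cls.endswith(("O-", "P-")):
        base, prefix = cls.rsplit(" ", 1)
        return f"{base} {prefix}{carbons}:{dbs}"
    return f"{cls} {carbons}:{dbs}"


def quantify(
    assignments: list[Assignment],
    is_table: dict[str, tuple[str, float]],
) -> list[tuple[str, float]]:
    """Convert corrected intensities to concentrations via the class IS.

    ``concentration = (I_lipid / I_IS) * c_IS``, with the internal standard
    of the same lipid class.  If the IS is absent or has zero corrected
    intensity, all analytes of that class are reported as missing (NaN),
    never as zero.
    """
    by_class: dict[str, list[Assignment]] = {}
    for a in assignments:
        by_class.setdefault(a.species.lipid_class, []).append(a)

    results: list[tuple[str, float]] = []
    for cls, members in by_class.items():
        entry = is_table.get(cls)
        is_assignment = None
        if entry is not None:
            is_name, is_conc = entry
            is_assignment = next(
                (a for a in members if a.species.name == is_name), None
            )
        if entry is None or is_assignment is None or is_assignment.corrected_intensity <= 0:
            logger.warning(
                "internal standard missing or zero for class %s; reporting %d "
                "species as missing",
                cls,
                sum(1 for a in members if not a.species.is_internal_standard),
            )
            results.extend(
                (a.species.name, float("nan"))
                for a in members
                if not a.species.is_internal_standard
            )
            continue
        for a in members:
            if a.species.is_internal_standard:
                continue
            conc = a.corrected_intensity / is_assignment.corrected_intensity * is_conc
            results.append((a.species.name, float(conc)))
    return results


def build_matrix(per_sample_results: dict[str, list[tuple[str, float]]]) -> ConcentrationMatrix:
    """Assemble per-sample quantitation results into a ConcentrationMatrix.

    Species unobserved in a sample are stored as missing with provenance
    ``absent``.  Columns are sorted canonically (by name) so the result is
    invariant to input ordering.
    """
    ids = list(per_sample_results)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids")
    all_species = sorted({name for rows in per_sample_results.values() for name, _ in rows})
    values = pd.DataFrame(np.nan, index=pd.Index(ids, name="sample_id"), columns=all_species)
    for sid, rows in per_sample_results.items():
        for name, conc in rows:
            values.at[sid, name] = conc
    values = values.sort_index(axis=0)
    return ConcentrationMatrix(values)


def quantify_peaklists(
    peaklists,
    db: LipidDatabase,
    is_table: dict[str, tuple[str, float]],
    min_intensity: float = DEFAULT_INTENSITY_THRESHOLD,
    tolerance: float = DEFAULT_TOLERANCE_MDA,
    isotope_correction: bool = True,
) -> ConcentrationMatrix:
    """Full quantitation pipeline over many peak lists -> concentration matrix."""
    per_sample: dict[str, list[tuple[str, float]]] = {}
    for pl in peaklists:
        filtered = threshold_peaks(pl, min_intensity)
        assignments = match_peaks(filtered, db, tolerance)
        if isotope_correction:
            assignments = isotope_correct(assignments, db)
        per_sample.setdefault(pl.sample_id, []).extend(quantify(assignments, is_table))
    return build_matrix(per_sample)
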
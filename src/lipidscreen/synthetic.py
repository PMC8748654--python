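"""Synthetic cohorts and spectra with the statistical structure of a
serum-lipidomics case/control screening study.

The generator emulates what the downstream analysis assumes about real
serum data: per-species lognormal concentrations, multiplicative
case/control fold changes on the geometric mean (a small panel of
sphingomyelin/ceramide/(lyso)phosphatidylcholine markers downregulated in
cases), a pancreatitis group drawn from the control distribution,
gender/age/stage/site metadata, lognormal CA 19-9 elevated in cases, and
exponential proportional-hazards survival for cases.  Peak-list synthesis
turns a known concentration matrix into centroided m/z-intensity tables per
lipid-class scan window, optionally with M+0..M+2 isotope envelopes, so the
quantitation stage can be validated by round trip.

Distributional defaults are design choices of this package (no public
reference gives serum lipid concentration distributions); they are stated
in the config and in the methods note, and every draw is governed by a
single integer seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import ConcentrationMatrix, MEASURED
from .lipids import (
    DEFAULT_IS_TABLE,
    ISOTOPE_SPACING,
    MARKER_SPECIES,
    LipidDatabase,
    default_species_names,
    isotope_envelope,
)

#: default case/control geometric-mean ratios for the marker panel
DEFAULT_MARKER_EFFECTS: tuple[tuple[str, float, str], ...] = (
    ("SM 41:1", 0.45, "down"),
    ("SM 42:1", 0.50, "down"),
    ("SM 39:1", 0.55, "down"),
    ("Cer 41:1", 0.50, "down"),
    ("Cer 42:1", 0.55, "down"),
    ("LPC 18:2", 0.60, "down"),
    ("PC O-36:3", 0.65, "down"),
)

_SITES = ("Brno", "Prague", "Pilsen", "Olomouc")


@dataclass
class SurvivalParams:
    """Exponential proportional-hazards generator settings for cases."""

    baseline_hazard: float = 1.0 / 24.0   # events per month
    coefficients: dict[str, float] = field(default_factory=dict)  # species -> log HR
    horizon_months: float = 60.0          # administrative censoring


@dataclass
class CohortConfig:
    """Study-condition settings for one synthetic cohort."""

    n_cases: int = 300
    n_controls: int = 300
    n_pancreatitis: int = 0
    n_lipids: int = 157
    informative_lipids: tuple[tuple[str, float, str], ...] = DEFAULT_MARKER_EFFECTS
    within_group_cv: float = 0.30
    gender_fraction: float = 0.5          # fraction female
    age_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"T": (45, 85), "N": (35, 80), "Pan": (35, 75)}
    )
    # (mu, sigma) of ln(CA 19-9 / (U/mL)) per group
    ca199_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"T": (4.0, 1.2), "N": (2.3, 0.8), "Pan": (2.5, 0.9)}
    )
    survival_params: SurvivalParams = field(default_factory=SurvivalParams)
    gender_effects: dict[str, float] = field(default_factory=dict)  # species -> F/M ratio
    diabetes_prob: dict[str, float] = field(
        default_factory=lambda: {"T": 0.25, "N": 0.08, "Pan": 0.20}
    )
    seed: int = 0

    def validate(self) -> None:
        for name, value in (
            ("n_cases", self.n_cases),
            ("n_controls", self.n_controls),
            ("n_pancreatitis", self.n_pancreatitis),
        ):
            if value < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_cases + self.n_controls + self.n_pancreatitis == 0:
            raise ValueError("cohort has zero samples")
        if self.n_lipids <= 0:
            raise ValueError("cohort has zero lipid species")
        if self.within_group_cv <= 0:
            raise ValueError("within_group_cv must be > 0")
        if not 0.0 <= self.gender_fraction <= 1.0:
            raise ValueError("gender_fraction must be in [0, 1]")
        for name, fc, _direction in self.informative_lipids:
            if fc <= 0:
                raise ValueError(f"fold change for {name} must be > 0")
        sp = self.survival_params
        if sp.baseline_hazard < 0 or sp.horizon_months < 0:
            raise ValueError("hazard parameters must be non-negative")


@dataclass
class SpectrumConfig:
    """Settings for turning concentrations into centroided peak lists."""

    is_concentrations: dict[str, float] = field(
        default_factory=lambda: {cls: conc for cls, (_n, conc) in DEFAULT_IS_TABLE.items()}
    )
    noise_floor: float = 1000.0           # counts
    response_factor: dict[str, float] | float = 10_000.0  # counts per nmol/mL
    mz_jitter_sd: float = 1.0             # mDa
    include_isotopes: bool = False
    n_noise_peaks: int = 5                # spurious peaks per class window
    merge_width_mda: float = 15.0         # centroid merging resolution
    seed: int = 0

    def response_for(self, lipid_class: str) -> float:
        if isinstance(self.response_factor, dict):
            rf = self.response_factor.get(lipid_class, 0.0)
        else:
            rf = float(self.response_factor)
        if rf <= 0:
            raise ValueError(f"response factor for class {lipid_class!r} must be > 0")
        return rf


def _lognormal_sigma(cv: float) -> float:
    return math.sqrt(math.log1p(cv * cv))


def generate_cohort(config: CohortConfig) -> tuple[ConcentrationMatrix, pd.DataFrame]:
    """Draw a synthetic concentration matrix and matching sample table.

    Concentrations are lognormal per species; the configured fold change
    multiplies the case-group geometric mean, so the empirical T/N
    geometric-mean ratio equals the configured value in expectation.
    Pancreatitis samples are drawn from the control distribution.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    species = default_species_names(config.n_lipids)
    fc = pd.Series(1.0, index=species)
    for name, ratio, _direction in config.informative_lipids:
        if name in fc.index:
            fc[name] = ratio
    gender_mult = pd.Series(1.0, index=species)
    for name, ratio in config.gender_effects.items():
        if name in gender_mult.index:
            gender_mult[name] = ratio

    # per-species baseline geometric means (nmol/mL), fixed by the seed
    base_gm = np.exp(rng.normal(math.log(5.0), 1.2, size=len(species)))
    sigma = _lognormal_sigma(config.within_group_cv)

    groups = (
        ["T"] * config.n_cases + ["N"] * config.n_controls + ["Pan"] * config.n_pancreatitis
    )
    n = len(groups)
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]

    gender = np.where(rng.random(n) < config.gender_fraction, "F", "M")
    rows = []
    values = np.empty((n, len(species)))
    for i, g in enumerate(groups):
        gm = base_gm * (fc.to_numpy() if g == "T" else 1.0)
        if gender[i] == "F":
            gm = gm * gender_mult.to_numpy()
        values[i] = gm * np.exp(rng.normal(0.0, sigma, size=len(species)))
        lo, hi = config.age_ranges.get(g, (35, 85))
        mu, sd = config.ca199_params.get(g, (2.3, 0.8))
        rows.append(
            dict(
                sample_id=sample_ids[i],
                group=g,
                gender=gender[i],
                age=int(rng.integers(lo, hi + 1)),
                stage=f"T{rng.integers(1, 5)}" if g == "T" else "",
                site=_SITES[rng.integers(0, len(_SITES))],
                diabetes=int(rng.random() < config.diabetes_prob.get(g, 0.1)),
                ca199=float(np.exp(rng.normal(mu, sd))),
            )
        )

    matrix = ConcentrationMatrix(
        pd.DataFrame(values, index=pd.Index(sample_ids, name="sample_id"), columns=species)
    )
    samples = pd.DataFrame(rows).set_index("sample_id")
    return matrix, samples


def generate_survival(
    samples: pd.DataFrame,
    matrix: ConcentrationMatrix,
    config: CohortConfig,
) -> pd.DataFrame:
    """Attach exponential proportional-hazards survival to case samples.

    Each case's hazard is ``h0 * exp(sum_j beta_j * z_j)`` with ``z_j`` the
    binary above-median code of lipid ``j`` (median over all samples).
    Observations are administratively censored at the configured horizon;
    controls and pancreatitis samples get missing survival fields.
    """
    sp = config.survival_params
    if sp.baseline_hazard < 0 or sp.horizon_months < 0:
        raise ValueError("hazard parameters must be non-negative")
    case_ids = samples.index[samples["group"] == "T"]
    if len(case_ids) == 0:
        raise ValueError("no case samples to assign survival to")

    rng = np.random.default_rng(config.seed + 104729)
    log_hr = np.zeros(len(case_ids))
    for name, beta in sp.coefficients.items():
        if name not in matrix.species:
            raise ValueError(f"survival coefficient for unknown species {name!r}")
        col = matrix.values[name]
        code = (col.loc[case_ids] > col.median()).astype(float).to_numpy()
        log_hr += beta * code

    hazard = sp.baseline_hazard * np.exp(log_hr)
    with np.errstate(divide="ignore"):
        raw = rng.exponential(1.0, size=len(case_ids)) / np.where(hazard > 0, hazard, np.nan)
    raw = np.where(hazard > 0, raw, np.inf)
    time = np.minimum(raw, sp.horizon_months)
    event = (raw <= sp.horizon_months).astype(int)
    if sp.horizon_months == 0:
        event[:] = 0

    out = samples.copy()
    out["os_months"] = np.nan
    out["event"] = np.nan
    out.loc[case_ids, "os_months"] = time
    out.loc[case_ids, "event"] = event
    return out


def generate_peaklists(
    matrix: ConcentrationMatrix,
    db: LipidDatabase,
    scfg: SpectrumConfig,
) -> list:
    """Synthesize centroided peak lists per sample and lipid-class window.

    Each species with a positive concentration yields a monoisotopic peak at
    its database m/z plus Gaussian jitter (clipped at 3 sigma), with
    intensity equal to concentration x class response factor.  With
    isotopes enabled, M+1 and M+2 peaks are added with abundances from the
    molecular formula, and sticks closer than ``merge_width_mda`` are
    merged into one intensity-weighted centroid — this reproduces the
    co-assignment of a species' monoisotopic peak with the M+2 isotopologue
    of the same-class species carrying one more double bond (8.9 mDa apart),
    which is what type II isotope correction removes.  The class internal
    standard is spiked at its configured concentration, and a few spurious
    noise peaks below ``3 * noise_floor`` are scattered over the window,
    away from analyte peaks.
    """
    from .lipidquant import PeakList  # local import to avoid a cycle

    for name in matrix.species:
        if name not in db:
            raise ValueError(f"species {name!r} missing from database")
    classes = sorted({db.get(name).lipid_class for name in matrix.species})
    for cls in classes:
        if db.internal_standard(cls) is None:
            raise ValueError(f"no internal standard in database for class {cls!r}")

    rng = np.random.default_rng(scfg.seed)
    jitter_sd = scfg.mz_jitter_sd / 1000.0  # mDa -> Th
    out: list[PeakList] = []
    for sample_id in matrix.sample_ids:
        row = matrix.values.loc[sample_id]
        for cls in classes:
            rf = scfg.response_for(cls)
            members = [
                db.get(name)
                for name in matrix.species
                if db.get(name).lipid_class == cls
            ]
            mzs: list[float] = []
            intens: list[float] = []

            def _emit(species, conc):
                if conc <= 0:
                    return
                base_intensity = conc * rf
                env = (
                    isotope_envelope(species.formula)
                    if scfg.include_isotopes
                    else np.array([1.0])
                )
                for k, frac in enumerate(env):
                    jit = np.clip(rng.normal(0.0, jitter_sd), -3 * jitter_sd, 3 * jitter_sd)
                    mzs.append(species.exact_mz + k * ISOTOPE_SPACING + jit)
                    # with isotopes on, M+0 carries the monoisotopic fraction
                    intens.append(base_intensity * (frac / 1.0 if scfg.include_isotopes else 1.0))

            for species in members:
                _emit(species, float(row[species.name]))
            is_species = db.internal_standard(cls)
            is_conc = scfg.is_concentrations.get(cls)
            if is_conc is None:
                raise ValueError(f"no spiked IS concentration configured for class {cls!r}")
            _emit(is_species, is_conc)

            # centroid merging: sticks closer than the merge width collapse
            # into one intensity-weighted peak (low-resolution co-assignment)
            merge_th = scfg.merge_width_mda / 1000.0
            if mzs:
                order = np.argsort(mzs)
                mz_arr = np.asarray(mzs)[order]
                in_arr = np.asarray(intens)[order]
                merged_mz: list[float] = []
                merged_in: list[float] = []
                for mz_i, in_i in zip(mz_arr, in_arr):
                    if merged_mz and mz_i - merged_mz[-1] <= merge_th:
                        total = merged_in[-1] + in_i
                        if total > 0:
                            merged_mz[-1] = (
                                merged_mz[-1] * merged_in[-1] + mz_i * in_i
                            ) / total
                        merged_in[-1] = total
                    else:
                        merged_mz.append(float(mz_i))
                        merged_in.append(float(in_i))
                mzs, intens = merged_mz, merged_in

            if scfg.n_noise_peaks > 0 and mzs:
                lo, hi = min(mzs) - 5.0, max(mzs) + 5.0
                existing = np.asarray(mzs)
                for _ in range(scfg.n_noise_peaks):
                    for _attempt in range(20):
                        cand = rng.uniform(lo, hi)
                        if np.min(np.abs(existing - cand)) > 2 * merge_th:
                            mzs.append(cand)
                            intens.append(rng.uniform(0.0, 3.0 * scfg.noise_floor))
                            break

            order = np.argsort(mzs)
            peaks = np.column_stack([np.asarray(mzs)[order], np.asarray(intens)[order]])
            out.append(PeakList(sample_id=sample_id, class_window=cls, peaks=peaks))
    return out


def write_cohort(matrix: ConcentrationMatrix, samples: pd.DataFrame, outdir) -> None:
    """Write a cohort as plain CSV (concentrations, provenance, metadata)."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix.to_csv(outdir / "concentrations.csv", outdir / "provenance.csv")
    samples.to_csv(outdir / "samples.csv", index_label="sample_id")
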
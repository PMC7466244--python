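"""Synthetic aqueous infant-formula Raman datasets with known truth.

The generator emulates the study design this package analyses: 19
formula powders reconstituted in water at 3-13% w/w giving 83 aqueous
samples (15 formulas span all five levels, the remaining formulas
contribute single high-level samples), each scanned twice.  Spectra
follow a bilinear model

    scan = gain * (C @ S) + fluorescence baseline + noise

where the rows of C are per-sample amounts of the matrix constituents
(lactose, protein, lipid, water) and of per-element modulation
components, and the rows of S are component spectra built from the
band positions of dairy Raman assignments (lactose glycosidic bands at
355/445/850/877/950/1070 cm^-1, phenylalanine ring breathing at 1003,
amide bands at 1555/1660, lipid CH bands at 1262-3005, broad water
structure near 170 and 3200-3400 cm^-1).

Minerals enter the spectrum only through correlated modulation of
matrix-like bands concentrated in 170-220 cm^-1 (chelated backbones)
and 760-1665 cm^-1 (protein-bound structure), never as element-specific
sharp lines: free ions are weak Raman scatterers, and the calibration
rides on mineral-matrix covariance.  Element concentrations are exactly
proportional to the powder level within a formula (ppm = formula
density x level), with per-formula densities spanning the printed
concentration range of the reference method.

The fluorescence baseline (amplitude, decay and tilt drawn per scan)
and a noise standard deviation that inflates gradually above 1800
cm^-1 reproduce the nuisance structure the pre-treatments must remove.
Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import SpectralDataset

__all__ = [
    "PeakSpec", "ComponentSpectrum", "SimulationConfig", "GroundTruth",
    "ELEMENT_PROFILES", "build_component_library", "simulate_dataset",
    "simulate_salt_spectra", "SALTS",
]


@dataclass
class PeakSpec:
    center: float          # cm^-1
    fwhm: float            # cm^-1
    amplitude: float       # relative intensity, >= 0
    shape: str = "gaussian"

    def profile(self, axis: np.ndarray) -> np.ndarray:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be > 0")
        x = (axis - self.center) / self.fwhm
        if self.shape == "gaussian":
            return self.amplitude * np.exp(-4.0 * np.log(2.0) * x * x)
        if self.shape == "lorentzian":
            return self.amplitude / (1.0 + 4.0 * x * x)
        raise ValueError(f"unknown shape {self.shape!r}")


@dataclass
class ComponentSpectrum:
    name: str
    peaks: list[PeakSpec]

    def profile(self, axis: np.ndarray) -> np.ndarray:
        out = np.zeros_like(axis, dtype=float)
        for pk in self.peaks:
            out += pk.profile(axis)
        return out


# Per-element defaults: concentration range printed by the reference
# method over the 83 samples (ppm), modulation preset, replicate
# repeatability (ppm).  Mn sits at the detection limit and is unusable.
ELEMENT_PROFILES: dict[str, dict] = {
    "Ca": dict(min_ppm=3.002, max_ppm=25.295, strength="strong", repeatability=0.032),
    "Mg": dict(min_ppm=0.281, max_ppm=2.537, strength="strong", repeatability=0.034),
    "K":  dict(min_ppm=0.129, max_ppm=17.319, strength="strong", repeatability=0.017),
    "Na": dict(min_ppm=0.144, max_ppm=9.133, strength="strong", repeatability=0.034),
    "Cu": dict(min_ppm=0.009, max_ppm=0.563, strength="weak", repeatability=0.003),
    "Mn": dict(min_ppm=-0.109, max_ppm=0.487, strength=None, repeatability=0.001),
    "Fe": dict(min_ppm=0.016, max_ppm=3.13, strength="strong", repeatability=0.013),
    "Zn": dict(min_ppm=0.045, max_ppm=2.575, strength="strong", repeatability=0.009),
}

# modulation visibility preset: peak cps of the element's component at its
# maximum concentration (the per-ppm coefficient is strength / max_ppm, so
# elements present at very different ppm scales reach comparable spectral
# visibility when their complexes scatter comparably)
MODULATION_STRENGTH = {"strong": 300.0, "weak": 12.0}

# per-element modulation band positions: one chelation band in
# 170-220 cm^-1 plus protein/lactose-region structure in 760-1665 cm^-1
_MODULATION_BANDS: dict[str, list[tuple[float, float, float]]] = {
    "Ca": [(176, 22, 1.0), (763, 16, 0.5), (1085, 18, 0.7), (1434, 20, 0.6)],
    "Mg": [(188, 20, 1.0), (829, 15, 0.6), (1121, 16, 0.6), (1555, 22, 0.5)],
    "K":  [(199, 24, 1.0), (1003, 10, 0.7), (1249, 18, 0.5), (1606, 20, 0.5)],
    "Na": [(209, 22, 1.0), (902, 14, 0.6), (1335, 18, 0.6), (1660, 24, 0.4)],
    "Cu": [(218, 20, 1.0), (960, 14, 0.6), (1398, 18, 0.6)],
    "Fe": [(172, 18, 1.0), (1172, 16, 0.6), (1462, 18, 0.5), (1640, 20, 0.4)],
    "Zn": [(193, 18, 1.0), (1044, 15, 0.6), (1520, 18, 0.6), (789, 14, 0.4)],
}

SALTS = ("CaCl2", "MgCl2", "KCl", "NaCl", "MnCl2", "FeCl3", "CuCl2", "ZnCl2")

_SALT_BANDS: dict[str, list[tuple[float, float, float]]] = {
    "CaCl2": [(110, 35, 1.0), (205, 40, 0.7)],
    "MgCl2": [(130, 35, 1.0), (240, 40, 0.7)],
    "KCl":   [(90, 30, 1.0), (300, 45, 0.6)],
    "NaCl":  [(150, 35, 1.0), (330, 45, 0.6)],
    "MnCl2": [(170, 35, 1.0), (360, 45, 0.6)],
    "FeCl3": [(190, 35, 1.0), (390, 50, 0.7)],
    "CuCl2": [(225, 40, 1.0), (420, 50, 0.6)],
    "ZnCl2": [(255, 40, 1.0), (450, 50, 0.7)],
}


@dataclass
class SimulationConfig:
    """Study-design parameters of the generator (defaults = the study).

    axis is (lo, hi, spacing) in cm^-1; the default spacing 3348/3472
    gives 3473 channels over 50-3398.  baseline_amplitude is the mean
    fluorescence amplitude in cps with lognormal scan-to-scan spread
    ``baseline_cv``; noise_sd is the base noise in cps, inflated
    linearly up to ``noise_inflation``-fold between ``noise_knee`` and
    the end of the axis.  multiplicative_sd is the per-scan gain spread
    (scattering/focus variation).
    """

    n_formulas: int = 19
    n_grid_formulas: int = 15
    levels: tuple[float, ...] = (3.0, 5.0, 8.0, 10.0, 13.0)
    n_samples: int = 83
    axis: tuple[float, float, float] = (50.0, 3398.0, 3348.0 / 3472.0)
    element_profile: dict = field(default_factory=lambda: {
        e: dict(p) for e, p in ELEMENT_PROFILES.items()})
    matrix_cps_per_pct: dict = field(default_factory=lambda: {
        "lactose": 55.0, "protein": 40.0, "lipid": 30.0})
    matrix_cv: float = 0.05          # between-formula constituent variation
    water_cps: float = 800.0
    baseline_amplitude: float = 1500.0
    baseline_cv: float = 0.4
    baseline_decay: float = 1200.0   # cm^-1 e-folding of the fluorescence
    baseline_decay_cv: float = 0.3
    baseline_tilt: float = 80.0      # cps full-axis linear tilt scale
    noise_sd: float = 4.0
    noise_inflation: float = 4.0
    noise_knee: float = 1800.0
    multiplicative_sd: float = 0.03
    replicate_count: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi, spacing = self.axis
        if not (lo < hi and spacing > 0):
            raise ValueError("axis must be (lo, hi, spacing) with lo < hi, spacing > 0")
        if any(not 0 < lv < 100 for lv in self.levels):
            raise ValueError("powder levels must lie in (0, 100) % w/w")
        if min(self.noise_sd, self.baseline_amplitude, self.water_cps) < 0:
            raise ValueError("scales must be non-negative")
        if self.replicate_count < 1 or self.n_samples < 1:
            raise ValueError("replicate_count and n_samples must be >= 1")
        if self.n_grid_formulas > self.n_formulas:
            raise ValueError("n_grid_formulas cannot exceed n_formulas")

    def axis_vector(self) -> np.ndarray:
        lo, hi, spacing = self.axis
        n = int(round((hi - lo) / spacing)) + 1
        return np.linspace(lo, hi, n)


@dataclass
class GroundTruth:
    """Everything needed to reconstruct the simulated scans exactly."""

    component_names: list[str]
    C: np.ndarray              # samples x components (amount weights)
    S: np.ndarray              # components x channels (unit-profile spectra)
    concentrations: pd.DataFrame  # samples x elements, true ppm
    baselines: np.ndarray      # scans x channels
    gains: np.ndarray          # per-scan multiplicative factor
    noise: np.ndarray          # scans x channels realization
    seed: int

    def clean(self) -> np.ndarray:
        """Noise-free per-sample spectra, C @ S."""
        return self.C @ self.S


def build_component_library(seed: int = 0,
                            rng: np.random.Generator | None = None
                            ) -> dict[str, ComponentSpectrum]:
    """Matrix-constituent and per-mineral modulation component spectra.

    Peak amplitudes carry a small seeded lognormal jitter so different
    seeds give different (but realistic) relative band intensities.
    """
    rng = np.random.default_rng(seed) if rng is None else rng

    def jitter(bands, shape="gaussian"):
        return [PeakSpec(c, w, a * float(np.exp(rng.normal(0.0, 0.1))), shape)
                for c, w, a in bands]

    lib = {
        "lactose": ComponentSpectrum("lactose", jitter([
            (355, 18, 0.5), (445, 16, 0.7), (850, 12, 0.8), (877, 12, 0.9),
            (950, 14, 0.6), (1070, 20, 1.0), (1121, 16, 0.5)])),
        "protein": ComponentSpectrum("protein", jitter([
            (1003, 8, 1.0), (1555, 25, 0.4), (1660, 30, 0.8), (3060, 40, 0.3)],
            shape="lorentzian")),
        "lipid": ComponentSpectrum("lipid", jitter([
            (1262, 20, 0.4), (1303, 18, 0.5), (1442, 22, 1.0), (1746, 18, 0.3),
            (2855, 30, 0.9), (2927, 35, 1.0), (3005, 25, 0.4)])),
        "water": ComponentSpectrum("water", jitter([
            (170, 120, 0.35), (3230, 220, 0.9), (3400, 160, 1.0)])),
    }
    for element, bands in _MODULATION_BANDS.items():
        lib[f"mineral:{element}"] = ComponentSpectrum(
            f"mineral:{element}", jitter(bands))
    return lib


def _design(config: SimulationConfig) -> list[tuple[int, float]]:
    """(formula index, powder level) per sample, study-shaped by default.

    The first ``n_grid_formulas`` span every level; the remaining
    formulas contribute one top-level sample each; any samples still
    missing are top-level repeats of the early formulas, with the last
    one a mid-level sample (the study's single extra 8% sample).
    """
    levels = sorted(config.levels)
    rows = [(f, lv) for f in range(config.n_grid_formulas) for lv in levels]
    if len(rows) > config.n_samples:
        return rows[:config.n_samples]
    extra = config.n_samples - len(rows)
    pool = list(range(config.n_grid_formulas, config.n_formulas))
    pool += list(range(config.n_grid_formulas))
    top = levels[-1]
    mid = levels[len(levels) // 2]
    for i in range(extra):
        f = pool[i % len(pool)]
        lv = mid if (i == extra - 1 and extra > len(pool) - config.n_grid_formulas) \
            else top
        rows.append((f, lv))
    return rows


def _formula_densities(config: SimulationConfig, rng: np.random.Generator
                       ) -> pd.DataFrame:
    """Per-formula element densities (ppm per % w/w), stratified uniform.

    The density range [min_ppm/lowest level, max_ppm/highest level] is
    divided into one stratum per grid formula, so the simulated 83
    samples always span the printed concentration range; the non-grid
    formulas draw uniformly over the whole range.
    """
    lo_lv, hi_lv = min(config.levels), max(config.levels)
    ng, nf = config.n_grid_formulas, config.n_formulas
    dens = {}
    for element, prof in config.element_profile.items():
        if prof.get("strength") is None:
            continue  # below detection: no density, handled downstream
        d_lo = prof["min_ppm"] / lo_lv
        d_hi = prof["max_ppm"] / hi_lv
        width = d_hi - d_lo
        strata = rng.permutation(ng)
        grid = d_lo + width * (strata + rng.uniform(size=ng)) / ng
        rest = rng.uniform(d_lo, d_hi, size=nf - ng)
        dens[element] = np.concatenate([grid, rest])
    return pd.DataFrame(dens, index=[f"F{f + 1:02d}" for f in range(nf)])


def simulate_dataset(config: SimulationConfig | None = None
                     ) -> tuple[SpectralDataset, pd.DataFrame, GroundTruth]:
    """Simulate a full measurement campaign.

    Returns the per-scan spectral dataset (replicates not yet
    averaged), a reference concentration table (sample_id, element,
    ppm, repeatability) and the :class:`GroundTruth`.
    """
    config = SimulationConfig() if config is None else config
    rng = np.random.default_rng(config.seed)
    axis = config.axis_vector()
    lo, hi, _ = config.axis

    lib = build_component_library(rng=rng)
    names = ["lactose", "protein", "lipid", "water"] + [
        f"mineral:{e}" for e, p in config.element_profile.items()
        if p.get("strength") is not None]
    S = np.vstack([lib[n].profile(axis) for n in names])

    design = _design(config)
    n_samp = len(design)
    sample_ids = [f"S{i + 1:02d}" for i in range(n_samp)]
    densities = _formula_densities(config, rng)
    matrix_var = {
        k: 1.0 + rng.normal(0.0, config.matrix_cv, size=config.n_formulas)
        for k in config.matrix_cps_per_pct
    }

    usable = [e for e, p in config.element_profile.items()
              if p.get("strength") is not None]
    conc = np.empty((n_samp, len(usable)))
    C = np.zeros((n_samp, len(names)))
    meta_rows = []
    for i, (f, lv) in enumerate(design):
        fid = densities.index[f]
        meta_rows.append({"sample_id": sample_ids[i], "formula": fid,
                          "powder_pct": lv})
        C[i, 0] = config.matrix_cps_per_pct["lactose"] * lv * matrix_var["lactose"][f]
        C[i, 1] = config.matrix_cps_per_pct["protein"] * lv * matrix_var["protein"][f]
        C[i, 2] = config.matrix_cps_per_pct["lipid"] * lv * matrix_var["lipid"][f]
        C[i, 3] = config.water_cps * (1.0 - 0.01 * lv)
        for k, element in enumerate(usable):
            ppm = float(densities.loc[fid, element]) * lv  # exact proportionality
            conc[i, k] = ppm
            prof_e = config.element_profile[element]
            strength = MODULATION_STRENGTH[prof_e["strength"]] / prof_e["max_ppm"]
            C[i, 4 + k] = strength * ppm
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    clean = C @ S

    n_scans = n_samp * config.replicate_count
    amp = config.baseline_amplitude * np.exp(
        rng.normal(0.0, config.baseline_cv, size=n_scans))
    decay = config.baseline_decay * np.exp(
        rng.normal(0.0, config.baseline_decay_cv, size=n_scans))
    tilt = rng.normal(0.0, config.baseline_tilt, size=n_scans)
    frac = (axis - lo) / (hi - lo)
    baselines = (amp[:, None] * np.exp(-(axis - lo)[None, :] / decay[:, None])
                 + tilt[:, None] * frac[None, :]
                 + np.abs(tilt)[:, None])   # keep the background non-negative
    gains = 1.0 + rng.normal(0.0, config.multiplicative_sd, size=n_scans)

    ramp = np.clip((axis - config.noise_knee) / (hi - config.noise_knee), 0.0, 1.0) \
        if hi > config.noise_knee else np.zeros_like(axis)
    sd = config.noise_sd * (1.0 + (config.noise_inflation - 1.0) * ramp)
    noise = rng.normal(0.0, 1.0, size=(n_scans, axis.size)) * sd[None, :]

    inten = np.empty((n_scans, axis.size))
    scan_sids, scan_rids = [], []
    for i in range(n_samp):
        for r in range(config.replicate_count):
            k = i * config.replicate_count + r
            inten[k] = gains[k] * clean[i] + baselines[k] + noise[k]
            scan_sids.append(sample_ids[i])
            scan_rids.append(str(r + 1))
    dataset = SpectralDataset(axis, inten, scan_sids, scan_rids, meta)

    ref_rows = []
    conc_df = pd.DataFrame(conc, index=sample_ids, columns=usable)
    for element in config.element_profile:
        prof = config.element_profile[element]
        if prof.get("strength") is None:  # detection-limit artifact (Mn)
            vals = rng.normal(0.0, 0.15, size=n_samp)
        else:
            vals = conc_df[element].to_numpy()
        for sid, v in zip(sample_ids, vals):
            ref_rows.append({"sample_id": sid, "element": element,
                             "ppm": float(v),
                             "repeatability": prof["repeatability"]})
    references = pd.DataFrame(ref_rows)

    truth = GroundTruth(names, C, S, conc_df, baselines, gains, noise,
                        config.seed)
    return dataset, references, truth


def simulate_salt_spectra(salts: list[str] | tuple[str, ...] = SALTS,
                          seed: int = 0,
                          config: SimulationConfig | None = None
                          ) -> SpectralDataset:
    """One spectrum per 1 M chloride-salt solution.

    Water background plus salt-specific low-frequency bands in 50-465
    cm^-1 and the same high-shift noise inflation as the main
    simulation; the water-only control name "water" is also accepted.
    """
    config = SimulationConfig(seed=seed) if config is None else config
    unknown = [s for s in salts if s not in SALTS and s != "water"]
    if unknown:
        raise ValueError(f"unknown salts {unknown}; choose from {SALTS}")
    rng = np.random.default_rng(seed)
    axis = config.axis_vector()
    lo, hi, _ = config.axis
    water = ComponentSpectrum("water", [
        PeakSpec(170, 120, 0.35), PeakSpec(3230, 220, 0.9),
        PeakSpec(3400, 160, 1.0)]).profile(axis) * config.water_cps
    ramp = np.clip((axis - config.noise_knee) / (hi - config.noise_knee), 0.0, 1.0) \
        if hi > config.noise_knee else np.zeros_like(axis)
    sd = config.noise_sd * (1.0 + (config.noise_inflation - 1.0) * ramp)
    rows = []
    for salt in salts:
        y = water.copy()
        if salt != "water":
            for c, w, a in _SALT_BANDS[salt]:
                y += 300.0 * PeakSpec(c, w, a).profile(axis)
        y += rng.normal(0.0, 1.0, size=axis.size) * sd
        rows.append(y)
    return SpectralDataset(axis, np.vstack(rows), list(salts))
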
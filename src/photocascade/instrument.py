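"""Synthetic instrument: render kinetic trajectories as electrospray spectra.

Replaces the mass spectrometer for testing: species populations from the
kinetic model (or any ground-truth trace) are rendered as sums of Gaussian
charge-state envelopes — a discretized-Gaussian weight over integer charges,
a Gaussian peak per charge with unit area scaled by population × weight —
plus optional unresolved-adduct tails, a flat noise-floor baseline, and
additive Gaussian noise (both scaled to the tallest rendered peak).  A
baseline of several noise standard deviations keeps the non-negativity clip
from truncating the noise distribution, so background subtraction in the
quantification stage sees an unbiased floor.  With the noise and adduct
terms off, the windowed quantification recovers the ground-truth fractions
exactly, which is what makes every downstream stage testable.

A separate negative-mode renderer produces the lipid-region spectra
([M−H]⁻ singly charged) for the PE / N-ret-PE conjugation and PC
saturation analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import kinetics
from .lipids import LipidSpecies
from .spectra import (
    PROTON_MASS,
    AbundanceTrace,
    LightSchedule,
    SpeciesDef,
    Spectrum,
    SpectrumSeries,
    mz_of,
)

__all__ = ["InstrumentModel", "render_spectrum", "render_series", "simulate_series", "simulate_lipid_spectrum"]

_SIGMA_PER_FWHM = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class InstrumentModel:
    """Peak-shape, charge-envelope and noise model of the synthetic spectrometer.

    ``charge_envelope`` maps species name -> (mean charge, charge spread);
    weights over the species' declared integer charges are a discretized
    Gaussian normalized to sum to 1.  ``noise_sd`` is the additive Gaussian
    noise standard deviation and ``baseline`` the flat noise-floor offset,
    both as fractions of the tallest rendered peak; ``adduct_tail`` is an
    optional (fraction, Δmass Da) pair moving that fraction of every peak's
    area to an unresolved adduct satellite.
    """

    mz_min: float = 2000.0
    mz_max: float = 8000.0
    mz_step: float = 0.25
    charge_envelope: dict[str, tuple[float, float]] = field(default_factory=dict)
    noise_sd: float = 0.0
    baseline: float = 0.0
    adduct_tail: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.mz_step <= 0 or self.mz_max <= self.mz_min:
            raise ValueError("need mz_step > 0 and mz_max > mz_min")
        if self.noise_sd < 0 or self.baseline < 0:
            raise ValueError("noise_sd and baseline must be >= 0")
        if self.adduct_tail is not None and not (0 <= self.adduct_tail[0] <= 1):
            raise ValueError("adduct fraction must lie in [0, 1]")

    @property
    def grid(self) -> np.ndarray:
        return np.arange(self.mz_min, self.mz_max + self.mz_step / 2, self.mz_step)

    def envelope_weights(self, species: SpeciesDef) -> np.ndarray:
        """Discretized-Gaussian charge weights over charge_min..charge_max (sum 1)."""
        zs = np.array(list(species.charges), dtype=float)
        mean, spread = self.charge_envelope.get(
            species.name, ((species.charge_min + species.charge_max) / 2.0,
                           max((species.charge_max - species.charge_min) / 4.0, 0.5)),
        )
        w = np.exp(-0.5 * ((zs - mean) / spread) ** 2)
        total = w.sum()
        if total <= 0:
            raise ValueError(f"degenerate charge envelope for {species.name}")
        return w / total


def _add_gaussian(grid: np.ndarray, out: np.ndarray, center: float, sigma: float, area: float) -> None:
    # render only within ±6σ for speed; unit-area normalization
    lo = np.searchsorted(grid, center - 6 * sigma)
    hi = np.searchsorted(grid, center + 6 * sigma)
    if hi <= lo:
        return
    x = grid[lo:hi]
    out[lo:hi] += area / (sigma * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((x - center) / sigma) ** 2)


def render_spectrum(
    populations: dict[str, float],
    registry: dict[str, SpeciesDef],
    instrument: InstrumentModel,
    rng: np.random.Generator | None = None,
    scan_time: float = 0.0,
    light_on: bool = False,
) -> Spectrum:
    """Render one scan from species populations (area per species ∝ population)."""
    grid = instrument.grid
    clean = np.zeros(grid.size)
    for name, pop in populations.items():
        if pop < 0:
            raise ValueError(f"negative population for {name}")
        if pop == 0:
            continue
        sp = registry[name]
        sigma = sp.peak_fwhm * _SIGMA_PER_FWHM
        weights = instrument.envelope_weights(sp)
        for z, w in zip(sp.charges, weights):
            area = pop * w
            if instrument.adduct_tail is not None:
                frac, dmass = instrument.adduct_tail
                _add_gaussian(grid, clean, mz_of(sp, z), sigma, area * (1 - frac))
                _add_gaussian(grid, clean, mz_of(sp, z) + dmass / z, sigma, area * frac)
            else:
                _add_gaussian(grid, clean, mz_of(sp, z), sigma, area)
    scale = max(clean.max(), 1e-30)
    intensity = clean + instrument.baseline * scale
    if instrument.noise_sd > 0:
        if rng is None:
            raise ValueError("noise requested but no RNG supplied (seed is mandatory)")
        intensity = intensity + rng.normal(0.0, instrument.noise_sd * scale, grid.size)
    np.clip(intensity, 0.0, None, out=intensity)
    return Spectrum(grid, intensity, scan_time=scan_time, light_on=light_on)


def render_series(
    truth: AbundanceTrace,
    registry: dict[str, SpeciesDef],
    instrument: InstrumentModel,
    schedule: LightSchedule,
    seed: int,
) -> SpectrumSeries:
    """Render a ground-truth composition trace as a full scan series (seeded)."""
    rng = np.random.default_rng(seed)
    spectra = []
    for i, t in enumerate(truth.times):
        pops = {name: float(truth.values[i, j]) for j, name in enumerate(truth.species_names)}
        spectra.append(
            render_spectrum(pops, registry, instrument, rng,
                            scan_time=float(t), light_on=schedule.is_on(float(t)))
        )
    return SpectrumSeries(spectra, schedule)


def simulate_series(
    scheme: kinetics.KineticScheme,
    params: kinetics.RateParams,
    schedule: LightSchedule,
    instrument: InstrumentModel,
    scan_times: np.ndarray,
    seed: int,
    registry: dict[str, SpeciesDef],
    observable_map: dict[str, list[str]] | None = None,
) -> tuple[SpectrumSeries, AbundanceTrace]:
    """Run the kinetic model and render its mass observables as spectra.

    ``observable_map`` maps registry species name -> list of kinetic states
    summed into it; the default is the rho/opsin experiment
    (``{"rho": ["R_c", "R_t"], "opsin": ["Ops"]}`` — rho and rho* are
    isobaric).  Returns the rendered series plus the ground-truth trace.
    """
    observable_map = observable_map or {"rho": ["R_c", "R_t"], "opsin": ["Ops"]}
    traj = kinetics.solve(scheme, params, schedule, np.asarray(scan_times, dtype=float))
    cols = []
    for name, states in observable_map.items():
        cols.append(sum(traj.state(s) for s in states))
    vals = np.column_stack(cols)
    totals = vals.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        raise RuntimeError("simulated observables vanish; check the observable map")
    truth = AbundanceTrace(traj.times, vals / totals, list(observable_map),
                           light_on=schedule.intensity(traj.times).astype(bool))
    series = render_series(truth, registry, instrument, schedule, seed)
    return series, truth


def simulate_lipid_spectrum(
    pe_species: list[tuple[LipidSpecies, float, float]],
    pc_species: list[tuple[LipidSpecies, float]],
    instrument: InstrumentModel,
    seed: int,
    peak_fwhm: float = 0.02,
    scan_time: float = 0.0,
    light_on: bool = False,
) -> Spectrum:
    """Negative-mode ([M−H]⁻) lipid-region spectrum.

    ``pe_species`` entries are (PE species, conjugated fraction, total
    intensity): the free-PE peak carries (1 − fraction) of the area and the
    N-ret-PE conjugate peak (+266.2034 Da) the remaining fraction.
    ``pc_species`` entries are (PC species, intensity).
    """
    grid = instrument.grid
    clean = np.zeros(grid.size)
    sigma = peak_fwhm * _SIGMA_PER_FWHM
    for pe, frac, area in pe_species:
        if not (0.0 <= frac <= 1.0):
            raise ValueError(f"conjugated fraction {frac} outside [0, 1] for {pe.name}")
        _add_gaussian(grid, clean, pe.monoisotopic_mass - PROTON_MASS, sigma, area * (1 - frac))
        _add_gaussian(grid, clean, pe.conjugate_mass() - PROTON_MASS, sigma, area * frac)
    for pc, area in pc_species:
        _add_gaussian(grid, clean, pc.monoisotopic_mass - PROTON_MASS, sigma, area)
    scale = max(clean.max(), 1e-30)
    intensity = clean + instrument.baseline * scale
    if instrument.noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, instrument.noise_sd * scale, grid.size)
    np.clip(intensity, 0.0, None, out=intensity)
    return Spectrum(grid, intensity, scan_time=scan_time, light_on=light_on)
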
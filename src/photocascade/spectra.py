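"""Core domain types and plain-text I/O for time-resolved native mass spectrometry runs.

The experiment this package models follows intact membrane-protein species
(rhodopsin and its apo-form opsin, transducin with and without GDP, PDE6 with
and without cGMP) through a time course of electrospray scans synchronized
with an illumination schedule.  Each scan is a simple two-column text export
(m/z, intensity); species are declared by neutral average mass, a ligand mass
shift, and a charge-state range.

Masses
------
Intact-protein work at this resolution uses *average* neutral masses; the
charge carrier is a proton at 1.00728 Da (average).  Ligand mass shifts are
computed from molecular formulas at import time:

* retinylidene (Schiff base of all-*trans*-retinal, C20H28O − H2O): +266.42 Da
  average, +266.2034 Da monoisotopic — the rho/opsin mass difference the
  experiment reads out (the literature rounds this to 266 Da);
* GDP +443.20 Da, cGMP +345.21 Da, GTPγS +539.25 Da.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from pyteomics import mass as _pmass

__all__ = [
    "PROTON_MASS",
    "RETINAL_FORMULA",
    "RETINYLIDENE_DELTA",
    "RETINYLIDENE_DELTA_MONO",
    "GDP_DELTA",
    "CGMP_DELTA",
    "GTPGS_DELTA",
    "Spectrum",
    "SpectrumSeries",
    "LightSchedule",
    "SpeciesDef",
    "AbundanceTrace",
    "formula_mass",
    "schiff_base_delta",
    "mz_of",
    "read_scan_folder",
    "write_scan_folder",
]

#: Average mass of the electrospray charge carrier (a proton), Da.
PROTON_MASS = 1.00728

#: Molecular formula of all-trans-retinal (the visual chromophore aldehyde).
RETINAL_FORMULA = "C20H28O"


def formula_mass(formula: str, average: bool = False) -> float:
    """Neutral mass of a molecular formula in Da (monoisotopic by default)."""
    return _pmass.calculate_mass(formula=formula, average=average)


def schiff_base_delta(aldehyde_formula: str = RETINAL_FORMULA, *, average: bool = True) -> float:
    """Mass shift from Schiff-base (imine) condensation of an aldehyde with an amine.

    Condensation R-CHO + H2N-R' -> R-CH=N-R' expels one water, so the adduct
    adds ``mass(aldehyde) - mass(H2O)`` to the amine-bearing species.  For
    all-*trans*-retinal (C20H28O) the average shift is 266.42 Da — the
    rho/opsin mass difference — and the monoisotopic shift 266.2034 Da, used
    for the lipid N-ret-PE conjugates.

    Parameters
    ----------
    aldehyde_formula:
        Molecular formula of the aldehyde; must contain at least one oxygen.
    average:
        Average masses if True (intact proteins), monoisotopic otherwise
        (resolved lipids).
    """
    comp = _pmass.Composition(formula=aldehyde_formula)
    if comp.get("O", 0) < 1:
        raise ValueError(
            f"{aldehyde_formula!r} has no oxygen: not an aldehyde, cannot form a Schiff base"
        )
    return formula_mass(aldehyde_formula, average=average) - formula_mass("H2O", average=average)


#: Retinylidene (Schiff-base retinal) shift, average mass, Da (~266.42).
RETINYLIDENE_DELTA = schiff_base_delta(RETINAL_FORMULA, average=True)
#: Retinylidene shift, monoisotopic, Da (~266.2034).
RETINYLIDENE_DELTA_MONO = schiff_base_delta(RETINAL_FORMULA, average=False)
#: GDP adduct shift, average mass, Da.
GDP_DELTA = formula_mass("C10H15N5O11P2", average=True)
#: cGMP adduct shift, average mass, Da.
CGMP_DELTA = formula_mass("C10H12N5O7P", average=True)
#: GTPγS adduct shift, average mass, Da.
GTPGS_DELTA = formula_mass("C10H16N5O13P3S", average=True)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class LightSchedule:
    """Piecewise binary illumination profile I(t) ∈ {0, 1}.

    Built from non-overlapping ``(start_s, duration_s)`` pulse intervals plus
    an optional ``continuous_from`` time after which the light stays on.
    """

    pulses: list[tuple[float, float]] = field(default_factory=list)
    continuous_from: float | None = None

    def __post_init__(self) -> None:
        self.pulses = [(float(s), float(d)) for s, d in self.pulses]
        for s, d in self.pulses:
            if d <= 0:
                raise ValueError(f"pulse at {s} s has non-positive duration {d}")
        self.pulses.sort()
        for (s0, d0), (s1, _) in zip(self.pulses, self.pulses[1:]):
            if s0 + d0 > s1:
                raise ValueError("light pulses overlap")

    def is_on(self, t: float) -> bool:
        """Illumination state at time ``t`` (pulse intervals are half-open [s, s+d))."""
        if self.continuous_from is not None and t >= self.continuous_from:
            return True
        return any(s <= t < s + d for s, d in self.pulses)

    def intensity(self, t) -> np.ndarray:
        """Vectorized I(t) as floats."""
        t = np.asarray(t, dtype=float)
        on = np.zeros(t.shape, dtype=bool)
        for s, d in self.pulses:
            on |= (t >= s) & (t < s + d)
        if self.continuous_from is not None:
            on |= t >= self.continuous_from
        return on.astype(float)

    def switch_times(self, t0: float, t1: float) -> list[float]:
        """Times in (t0, t1) at which I(t) changes value; used to split ODE integration."""
        pts: set[float] = set()
        for s, d in self.pulses:
            pts.update((s, s + d))
        if self.continuous_from is not None:
            pts.add(self.continuous_from)
        return sorted(p for p in pts if t0 < p < t1)

    @classmethod
    def continuous(cls, start_s: float = 0.0) -> "LightSchedule":
        return cls(pulses=[], continuous_from=start_s)

    @classmethod
    def dark(cls) -> "LightSchedule":
        return cls(pulses=[], continuous_from=None)


@dataclass
class Spectrum:
    """One scan: m/z (Th, strictly ascending) vs intensity (arbitrary units, >= 0)."""

    mz: np.ndarray
    intensity: np.ndarray
    scan_time: float = 0.0
    light_on: bool = False

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays")
        if self.mz.shape != self.intensity.shape:
            raise ValueError(
                f"mz ({self.mz.size}) and intensity ({self.intensity.size}) lengths differ"
            )
        if self.mz.size >= 2 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("m/z values must be strictly ascending")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        if self.scan_time < 0:
            raise ValueError("scan_time must be >= 0")

    def __len__(self) -> int:
        return self.mz.size


@dataclass
class SpectrumSeries:
    """Time-ordered scans plus the illumination schedule they were recorded under."""

    spectra: list[Spectrum]
    schedule: LightSchedule = field(default_factory=LightSchedule.dark)

    def __post_init__(self) -> None:
        times = [s.scan_time for s in self.spectra]
        if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
            raise ValueError("scan times must be strictly increasing")
        for s in self.spectra:
            expected = self.schedule.is_on(s.scan_time)
            if s.light_on != expected:
                raise ValueError(
                    f"scan at {s.scan_time} s has light_on={s.light_on} but the "
                    f"schedule says {expected}"
                )

    @property
    def scan_times(self) -> np.ndarray:
        return np.array([s.scan_time for s in self.spectra])

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)


@dataclass
class SpeciesDef:
    """A proteoform (or ligand-bound proteoform) observed as a charge-state envelope.

    ``base_mass + ligand_delta`` is the neutral average mass rendered across
    charges ``charge_min..charge_max``; ``peak_fwhm`` is the expected peak
    width (Th) used both for integration-window sizing and simulation.
    """

    name: str
    base_mass: float
    ligand_delta: float = 0.0
    charge_min: int = 1
    charge_max: int = 1
    peak_fwhm: float = 5.0

    def __post_init__(self) -> None:
        if self.base_mass <= 0:
            raise ValueError("base_mass must be positive")
        if not (1 <= self.charge_min <= self.charge_max):
            raise ValueError("need 1 <= charge_min <= charge_max")
        if self.peak_fwhm <= 0:
            raise ValueError("peak_fwhm must be positive")

    @property
    def neutral_mass(self) -> float:
        return self.base_mass + self.ligand_delta

    @property
    def charges(self) -> range:
        return range(self.charge_min, self.charge_max + 1)


def mz_of(species: SpeciesDef, z: int) -> float:
    """Electrospray m/z of ``species`` at charge ``z``: (M + z·m_H+)/z."""
    if not (species.charge_min <= z <= species.charge_max):
        raise ValueError(
            f"charge {z} outside declared range "
            f"[{species.charge_min}, {species.charge_max}] for {species.name}"
        )
    return (species.neutral_mass + z * PROTON_MASS) / z


@dataclass
class AbundanceTrace:
    """Per-species relative abundance versus time — the bridge from spectra to kinetics.

    For a full composition (more than one species) the fractions at each time
    point must sum to 1; a single-species trace (e.g. the mass-rho observable
    handed to the kinetics fits) carries one column and is not normalized.
    """

    times: np.ndarray
    values: np.ndarray  # shape (n_times, n_species)
    species_names: list[str]
    light_on: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != self.times.size:
            self.values = self.values.T
        if self.values.shape != (self.times.size, len(self.species_names)):
            raise ValueError("values must have shape (n_times, n_species)")
        finite = np.isfinite(self.values)
        if np.any((self.values < -1e-9) & finite) or np.any((self.values > 1 + 1e-9) & finite):
            raise ValueError("relative abundances must lie in [0, 1]")
        if len(self.species_names) > 1:
            sums = np.nansum(np.where(finite, self.values, 0.0), axis=1)
            complete = finite.all(axis=1)
            if np.any(np.abs(sums[complete] - 1.0) > 1e-9):
                raise ValueError("species fractions must sum to 1 at every time point")
        if self.light_on is not None:
            self.light_on = np.asarray(self.light_on, dtype=bool)

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.species_names.index(name)]

    def single(self, name: str) -> "AbundanceTrace":
        """Extract a one-species (unnormalized) trace."""
        return AbundanceTrace(self.times, self.column(name)[:, None], [name], self.light_on)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.species_names)
        df.insert(0, "time_s", self.times)
        if self.light_on is not None:
            df["light_on"] = self.light_on.astype(int)
        return df

    def to_csv(self, path: str | Path, header_lines: Sequence[str] = ()) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            self.to_frame().to_csv(fh, index=False, float_format="%.10g", lineterminator="\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "AbundanceTrace":
        df = pd.read_csv(path, comment="#")
        times = df.pop("time_s").to_numpy()
        light = df.pop("light_on").to_numpy().astype(bool) if "light_on" in df else None
        return cls(times, df.to_numpy(), list(df.columns), light)


# ---------------------------------------------------------------------------
# scan-folder I/O
# ---------------------------------------------------------------------------

#: Default filename pattern: t<seconds>.txt, e.g. t0012.5.txt -> 12.5 s.
DEFAULT_NAMING_RULE = r"t(?P<time>\d+(?:\.\d+)?)"


def _parse_scan_file(path: Path) -> tuple[np.ndarray, np.ndarray]:
    mz: list[float] = []
    inten: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) < 2:
                raise ValueError(
                    f"{path.name}:{lineno}: expected two numeric columns, got {stripped!r}"
                )
            try:
                mz.append(float(parts[0]))
                inten.append(float(parts[1]))
            except ValueError as exc:
                raise ValueError(f"{path.name}:{lineno}: non-numeric value in {stripped!r}") from exc
    return np.array(mz), np.array(inten)


def read_scan_folder(
    path: str | Path,
    naming_rule: str = DEFAULT_NAMING_RULE,
    schedule: LightSchedule | None = None,
    glob: str = "*.txt",
) -> SpectrumSeries:
    """Read a folder of two-column (m/z, intensity) text scans into a series.

    Scan times are extracted from filenames via ``naming_rule``, a regex whose
    first (or ``time``-named) group captures seconds since experiment start.
    Files are sorted by extracted time; duplicated timestamps and malformed
    lines raise with file/line diagnostics.
    """
    folder = Path(path)
    rx = re.compile(naming_rule)
    entries: list[tuple[float, Path]] = []
    for fp in sorted(folder.glob(glob)):
        m = rx.search(fp.name)
        if m is None:
            warnings.warn(f"skipping {fp.name}: no scan time in filename")
            continue
        t = float(m.groupdict().get("time") or m.group(1))
        entries.append((t, fp))
    if not entries:
        raise FileNotFoundError(f"no scan files matching {glob!r} with parseable times in {folder}")
    entries.sort(key=lambda e: e[0])
    times = [t for t, _ in entries]
    if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
        dup = [t for t0, t in zip(times, times[1:]) if t <= t0]
        raise ValueError(f"duplicated or non-increasing scan times in folder: {dup}")
    schedule = schedule or LightSchedule.dark()
    spectra = []
    for t, fp in entries:
        mz, inten = _parse_scan_file(fp)
        spectra.append(Spectrum(mz, inten, scan_time=t, light_on=schedule.is_on(t)))
    return SpectrumSeries(spectra, schedule)


def write_scan_folder(series: SpectrumSeries, path: str | Path, time_format: str = "%012.3f") -> list[Path]:
    """Write each scan as ``t<seconds>.txt`` with full float precision (round-trip safe)."""
    folder = Path(path)
    folder.mkdir(parents=True, exist_ok=True)
    written = []
    for spec in series:
        fp = folder / ("t" + (time_format % spec.scan_time) + ".txt")
        with open(fp, "w") as fh:
            for x, y in zip(spec.mz, spec.intensity):
                fh.write("%.17g %.17g\n" % (x, y))
        written.append(fp)
    return written
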
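"""N-retinylidene-PE identification and lipid ratio analyses.

Free all-trans-retinal released from photoactivated rhodopsin condenses with
the amine headgroup of phosphatidylethanolamine (PE) to form the Schiff-base
conjugate N-retinylidene-PE (N-ret-PE), +266.2034 Da monoisotopic over the
free lipid.  Photoisomerization of the conjugate supplies cis-retinal for
rhodopsin regeneration, so the conjugated:free PE balance responds to
illumination.  Phosphatidylcholine (PC) has no free amine and cannot
conjugate; its unsaturated:saturated intensity ratio instead reports on the
lipid microenvironment recruited around the activated receptor.

All lipid measurements are AUC-based window integrals on [M−H]⁻ peaks
(negative-ion mode), species pre-assigned in the registry by headgroup class
and chain composition (e.g. ``PE 18:0/18:1``).  Retinal cis/trans isomers of
the conjugate are isobaric and not distinguished.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectra import PROTON_MASS, RETINYLIDENE_DELTA_MONO, Spectrum, formula_mass

__all__ = [
    "LipidSpecies",
    "pe_species",
    "pc_species",
    "nretpe_mass",
    "conjugation_ratio",
    "pc_saturation_ratio",
]


@dataclass
class LipidSpecies:
    """A glycerophospholipid identified by headgroup class and summed chains."""

    lipid_class: str  # "PE" or "PC"
    chains: str  # e.g. "18:0/18:1"
    monoisotopic_mass: float
    conjugated: bool = False  # True for the N-ret-PE form

    def __post_init__(self) -> None:
        if self.lipid_class not in ("PE", "PC"):
            raise ValueError(f"unsupported lipid class {self.lipid_class!r}")
        c, d = self.total_composition
        if c <= 0 or d < 0:
            raise ValueError(f"invalid chain composition {self.chains!r}")
        if self.monoisotopic_mass <= 0:
            raise ValueError("monoisotopic mass must be positive")

    @property
    def name(self) -> str:
        prefix = "N-ret-" if self.conjugated else ""
        return f"{prefix}{self.lipid_class} {self.chains}"

    @property
    def total_composition(self) -> tuple[int, int]:
        """Summed (carbons, double bonds) over both chains."""
        carbons = bonds = 0
        for chain in self.chains.split("/"):
            c, d = chain.split(":")
            carbons += int(c)
            bonds += int(d)
        return carbons, bonds

    @property
    def saturated(self) -> bool:
        return self.total_composition[1] == 0

    def conjugate_mass(self) -> float:
        """Monoisotopic mass of this PE's N-ret-PE Schiff-base conjugate."""
        return nretpe_mass(self)

    def mz_neg(self) -> float:
        """[M−H]⁻ m/z (negative mode, singly deprotonated)."""
        return self.monoisotopic_mass - PROTON_MASS


def _formula(lipid_class: str, carbons: int, bonds: int) -> str:
    # diacyl glycerophospholipid elemental composition from summed chains
    if lipid_class == "PE":
        return f"C{carbons + 5}H{2 * carbons - 2 * bonds + 10}NO8P"
    return f"C{carbons + 8}H{2 * carbons - 2 * bonds + 16}NO8P"


def pe_species(chains: str) -> LipidSpecies:
    """Build a PE species with its monoisotopic mass from the chain composition."""
    carbons = sum(int(ch.split(":")[0]) for ch in chains.split("/"))
    bonds = sum(int(ch.split(":")[1]) for ch in chains.split("/"))
    return LipidSpecies("PE", chains, formula_mass(_formula("PE", carbons, bonds)))


def pc_species(chains: str) -> LipidSpecies:
    """Build a PC species with its monoisotopic mass from the chain composition."""
    carbons = sum(int(ch.split(":")[0]) for ch in chains.split("/"))
    bonds = sum(int(ch.split(":")[1]) for ch in chains.split("/"))
    return LipidSpecies("PC", chains, formula_mass(_formula("PC", carbons, bonds)))


def nretpe_mass(pe: LipidSpecies) -> float:
    """Expected monoisotopic mass of the N-ret-PE conjugate of ``pe``.

    The retinylidene Schiff-base shift (+266.2034 Da) is identical for every
    PE species; PC lacks the primary amine and is rejected.
    """
    if pe.lipid_class != "PE":
        raise ValueError(f"{pe.name}: only PE forms a retinal Schiff-base conjugate")
    return pe.monoisotopic_mass + RETINYLIDENE_DELTA_MONO


def _window_auc(spectrum: Spectrum, center_mz: float, half_width: float) -> float:
    """Background-corrected AUC over an extracted-ion window.

    Lipid spectra are sparse (narrow peaks on a flat noise floor), so the
    spectrum-wide median is a robust floor estimate; exact window edges are
    interpolated so the AUC does not jitter with grid alignment.
    """
    lo = max(center_mz - half_width, spectrum.mz[0])
    hi = min(center_mz + half_width, spectrum.mz[-1])
    if hi <= lo:
        return 0.0
    floor = float(np.median(spectrum.intensity))
    inner = spectrum.mz[(spectrum.mz > lo) & (spectrum.mz < hi)]
    xs = np.concatenate([[lo], inner, [hi]])
    ys = np.interp(xs, spectrum.mz, spectrum.intensity) - floor
    return max(float(np.trapezoid(ys, xs)), 0.0)


def _half_width(mz: float, tol_ppm: float, peak_fwhm: float) -> float:
    # cover the peak (±3σ) or the mass tolerance, whichever is wider
    return max(mz * tol_ppm * 1e-6, 3.0 * peak_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0))))


def conjugation_ratio(
    spectrum: Spectrum,
    pe: LipidSpecies,
    tol_ppm: float = 10.0,
    peak_fwhm: float = 0.02,
    normalize_to: str = "free",
) -> float:
    """Conjugated:free intensity ratio for one PE species (AUC of [M−H]⁻ windows).

    ``normalize_to='free'`` divides the conjugate AUC by the free-PE AUC
    (the default); ``'total'`` divides by conjugate + free.  Returns NaN
    (flagged missing) when the denominator window is empty.
    """
    free = _window_auc(spectrum, pe.mz_neg(), _half_width(pe.mz_neg(), tol_ppm, peak_fwhm))
    conj_mz = pe.conjugate_mass() - PROTON_MASS
    conj = _window_auc(spectrum, conj_mz, _half_width(conj_mz, tol_ppm, peak_fwhm))
    denom = free if normalize_to == "free" else free + conj
    if denom <= 0:
        return float("nan")
    return conj / denom


def pc_saturation_ratio(
    spectrum: Spectrum,
    pc_list: list[LipidSpecies],
    tol_ppm: float = 10.0,
    peak_fwhm: float = 0.02,
) -> tuple[float, pd.DataFrame]:
    """Unsaturated:saturated PC intensity ratio plus the per-species AUC table.

    Partitions ``pc_list`` by double-bond count (>= 1 vs 0) and sums the
    [M−H]⁻ window AUCs on each side.  Returns 0 when only saturated species
    carry signal and NaN when the saturated side is entirely empty.
    """
    if not any(pc.saturated for pc in pc_list):
        raise ValueError("pc_list must contain at least one saturated species")
    rows = []
    for pc in pc_list:
        if pc.lipid_class != "PC":
            raise ValueError(f"{pc.name} is not a PC species")
        auc = _window_auc(spectrum, pc.mz_neg(), _half_width(pc.mz_neg(), tol_ppm, peak_fwhm))
        rows.append({"species": pc.name, "chains": pc.chains,
                     "double_bonds": pc.total_composition[1], "auc": auc})
    table = pd.DataFrame(rows)
    unsat = table.loc[table.double_bonds >= 1, "auc"].sum()
    sat = table.loc[table.double_bonds == 0, "auc"].sum()
    ratio = float("nan") if sat <= 0 else unsat / sat
    return ratio, table
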
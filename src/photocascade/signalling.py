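"""Downstream cascade: transducin nucleotide exchange and PDE6 cGMP occupancy.

Photoactivated rhodopsin (rho*) catalyses GDP release from the heterotrimeric
rod G protein transducin (G_t•GDP → apo-G_t); GTP binding then dissociates
the trimer into Gα_t•GTP + Gβγ.  Gα_t•GTP binds the PDE6 tetramer 1:1,
relieving its γ-subunit inhibition so the single occupied cGMP site is
hydrolysed to GMP.  GTP hydrolysis on Gα (absent for the non-hydrolysable
GTPγS analogue) releases Gα_t•GDP, which recombines with Gβγ to replenish
G_t•GDP when free GTP is available.

The asymmetric-activation stoichiometry observed by native MS is hard-coded:
one Gα and at most one cGMP per PDE6 tetramer; 1:2 complexes do not exist in
this model.  The observables mirror the measurements — the G_t•GDP:apo-G_t
intensity ratio over time and the PDE6:PDE6•cGMP occupancy ratio — while the
kinetic layer is a minimal mass-action scheme whose rate constants are
fixture defaults (the experiment does not constrain them), integrated with a
positivity-preserving sub-stepped Euler rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import quant
from .spectra import SpeciesDef, Spectrum, SpectrumSeries

__all__ = [
    "GtState",
    "Pde6State",
    "CascadeParams",
    "gt_ratio",
    "pde6_occupancy",
    "cascade_step",
    "simulate_cascade",
]


@dataclass
class GtState:
    """Transducin populations (normalized) and nucleotide pools."""

    gt_gdp: float = 1.0
    gt_apo: float = 0.0
    galpha_gtp: float = 0.0
    galpha_gdp: float = 0.0
    gbg: float = 0.0
    gtp_pool: float = 0.0
    gdp_pool: float = 0.0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.__dict__.values()):
            raise ValueError("populations and pools must be non-negative")

    @property
    def beta_gamma_total(self) -> float:
        return self.gt_gdp + self.gt_apo + self.gbg


@dataclass
class Pde6State:
    """PDE6 populations (one Gα site, one cGMP site per tetramer) and cGMP pools."""

    pde6_apo: float = 0.0
    pde6_cgmp: float = 1.0
    pde6_galpha: float = 0.0
    pde6_galpha_cgmp: float = 0.0
    cgmp_pool: float = 0.0
    gmp_pool: float = 0.0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.__dict__.values()):
            raise ValueError("populations and pools must be non-negative")

    @property
    def total(self) -> float:
        return self.pde6_apo + self.pde6_cgmp + self.pde6_galpha + self.pde6_galpha_cgmp

    @property
    def occupancy_ratio(self) -> float:
        """Bound:free cGMP-site ratio (the '1:x' reported with species order fixed)."""
        free = self.pde6_apo + self.pde6_galpha
        bound = self.pde6_cgmp + self.pde6_galpha_cgmp
        return np.inf if free <= 0 else bound / free


def alpha_total(gt: GtState, pde6: Pde6State) -> float:
    """Gα subunit conservation count across free and PDE6-bound forms."""
    return (gt.gt_gdp + gt.gt_apo + gt.galpha_gtp + gt.galpha_gdp
            + pde6.pde6_galpha + pde6.pde6_galpha_cgmp)


def cgmp_total(pde6: Pde6State) -> float:
    return pde6.pde6_cgmp + pde6.pde6_galpha_cgmp + pde6.cgmp_pool + pde6.gmp_pool


@dataclass
class CascadeParams:
    """Mass-action rate constants (fixture defaults; not experimental estimates).

    k_ex        rho*-catalysed nucleotide release from G_t•GDP (per rho* per s)
    k_gtp       GTP binding + trimer dissociation of apo-G_t (per GTP unit per s)
    k_gtpase    GTP hydrolysis on Gα (0 models GTPγS)
    k_reform    Gα_t•GDP + Gβγ recombination
    k_act       Gα_t•GTP binding to PDE6 (either cGMP state)
    k_cgmp      cGMP hydrolysis within the activated PDE6–Gα complex
    k_bind_cgmp cGMP rebinding from the pool to non-activated apo PDE6
    """

    k_ex: float = 1.0
    k_gtp: float = 2.0
    k_gtpase: float = 0.5
    k_reform: float = 5.0
    k_act: float = 2.0
    k_cgmp: float = 1.0
    k_bind_cgmp: float = 0.0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.__dict__.values()):
            raise ValueError("rates must be non-negative")


def _fluxes(gt: GtState, pde6: Pde6State, rho_star: float, p: CascadeParams) -> dict[str, float]:
    return {
        "exchange": p.k_ex * rho_star * gt.gt_gdp,
        "dissoc": p.k_gtp * gt.gt_apo * gt.gtp_pool,
        "gtpase_free": p.k_gtpase * gt.galpha_gtp,
        "reform": p.k_reform * gt.galpha_gdp * gt.gbg,
        "act_apo": p.k_act * gt.galpha_gtp * pde6.pde6_apo,
        "act_cgmp": p.k_act * gt.galpha_gtp * pde6.pde6_cgmp,
        "hydrolyse": p.k_cgmp * pde6.pde6_galpha_cgmp,
        "release_apo": p.k_gtpase * pde6.pde6_galpha,
        "release_cgmp": p.k_gtpase * pde6.pde6_galpha_cgmp,
        "rebind": p.k_bind_cgmp * pde6.pde6_apo * pde6.cgmp_pool,
    }


def cascade_step(
    gt: GtState,
    pde6: Pde6State,
    rho_star: float,
    params: CascadeParams,
    dt: float,
) -> tuple[GtState, Pde6State]:
    """Advance the cascade by ``dt`` with a positivity-preserving Euler rule.

    The step is internally subdivided so no pool loses more than ~20% of its
    content per sub-step; with mass-action fluxes proportional to their
    source pools this keeps every population non-negative without clipping.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    remaining = dt
    while remaining > 1e-15:
        f = _fluxes(gt, pde6, rho_star, params)
        # largest fractional depletion rate over all pools
        dep = 0.0
        for pool, outflow in [
            (gt.gt_gdp, f["exchange"]),
            (gt.gt_apo, f["dissoc"]),
            (gt.galpha_gtp, f["gtpase_free"] + f["act_apo"] + f["act_cgmp"]),
            (gt.galpha_gdp, f["reform"]),
            (gt.gbg, f["reform"]),
            (gt.gtp_pool, f["dissoc"]),
            (pde6.pde6_apo, f["act_apo"] + f["rebind"]),
            (pde6.pde6_cgmp, f["act_cgmp"]),
            (pde6.pde6_galpha, f["release_apo"]),
            (pde6.pde6_galpha_cgmp, f["hydrolyse"] + f["release_cgmp"]),
            (pde6.cgmp_pool, f["rebind"]),
        ]:
            if pool > 0:
                dep = max(dep, outflow / pool)
        h = remaining if dep <= 0 else min(remaining, 0.2 / dep)
        gt = GtState(
            gt_gdp=gt.gt_gdp + h * (f["reform"] - f["exchange"]),
            gt_apo=gt.gt_apo + h * (f["exchange"] - f["dissoc"]),
            galpha_gtp=gt.galpha_gtp + h * (f["dissoc"] - f["gtpase_free"] - f["act_apo"] - f["act_cgmp"]),
            galpha_gdp=gt.galpha_gdp + h * (f["gtpase_free"] + f["release_apo"] + f["release_cgmp"] - f["reform"]),
            gbg=gt.gbg + h * (f["dissoc"] - f["reform"]),
            gtp_pool=gt.gtp_pool + h * (-f["dissoc"]),
            gdp_pool=gt.gdp_pool + h * (f["exchange"]),
        )
        pde6 = Pde6State(
            pde6_apo=pde6.pde6_apo + h * (f["release_apo"] - f["act_apo"] - f["rebind"]),
            pde6_cgmp=pde6.pde6_cgmp + h * (f["release_cgmp"] + f["rebind"] - f["act_cgmp"]),
            pde6_galpha=pde6.pde6_galpha + h * (f["act_apo"] + f["hydrolyse"] - f["release_apo"]),
            pde6_galpha_cgmp=pde6.pde6_galpha_cgmp + h * (f["act_cgmp"] - f["hydrolyse"] - f["release_cgmp"]),
            cgmp_pool=pde6.cgmp_pool + h * (-f["rebind"]),
            gmp_pool=pde6.gmp_pool + h * (f["hydrolyse"]),
        )
        remaining -= h
    return gt, pde6


def simulate_cascade(
    gt0: GtState,
    pde60: Pde6State,
    t_grid: np.ndarray,
    params: CascadeParams,
    rho_star,
) -> pd.DataFrame:
    """Integrate the cascade over ``t_grid``; ``rho_star`` is a callable or constant."""
    t_grid = np.asarray(t_grid, dtype=float)
    drive = rho_star if callable(rho_star) else (lambda t: float(rho_star))
    gt, pde6 = gt0, pde60
    rows = [{"time_s": t_grid[0], **gt.__dict__, **pde6.__dict__}]
    for t0, t1 in zip(t_grid, t_grid[1:]):
        gt, pde6 = cascade_step(gt, pde6, drive(0.5 * (t0 + t1)), params, t1 - t0)
        rows.append({"time_s": t1, **gt.__dict__, **pde6.__dict__})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# spectral observables
# ---------------------------------------------------------------------------


def _as_series_list(defs) -> list[quant.ChargeSeries]:
    items = [defs] if isinstance(defs, (SpeciesDef, quant.ChargeSeries)) else list(defs)
    return [d if isinstance(d, quant.ChargeSeries) else quant.ChargeSeries(d) for d in items]


def gt_ratio(
    series: SpectrumSeries,
    gdp_species,
    apo_species,
) -> tuple[np.ndarray, np.ndarray]:
    """G_t•GDP : apo-G_t intensity ratio over a scan series.

    Each side accepts one or several :class:`SpeciesDef`/charge series — the
    α1/α2 and γ1/γ2 proteoform envelopes are summed per nucleotide state
    rather than modelled separately.  An absent apo population yields inf
    (flagged), not an exception.
    """
    return quant.ratio_trace(series, _as_series_list(gdp_species), _as_series_list(apo_species))


def pde6_occupancy(
    spectrum: Spectrum,
    apo: SpeciesDef,
    cgmp_bound: SpeciesDef,
    galpha_complex: SpeciesDef | None = None,
    detection_threshold: float = 0.01,
) -> tuple[float, float]:
    """(PDE6•cGMP : PDE6 occupancy ratio, PDE6–Gα complex fraction).

    The occupancy ratio maps the reported '1:x' convention to the float x
    (bound over free).  The Gα complex fraction is its share of total PDE6
    intensity, zeroed below ``detection_threshold`` (low-abundance detection
    guard, not a noise model).
    """
    series = [quant.ChargeSeries(apo), quant.ChargeSeries(cgmp_bound)]
    if galpha_complex is not None:
        series.append(quant.ChargeSeries(galpha_complex))
    sums = quant.integrate_series_set(spectrum, series)
    if sums[0] <= 0:
        return np.inf, 0.0
    ratio = sums[1] / sums[0]
    complex_fraction = 0.0
    if galpha_complex is not None and sums.sum() > 0:
        frac = sums[2] / sums.sum()
        complex_fraction = frac if frac >= detection_threshold else 0.0
    return float(ratio), float(complex_fraction)
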
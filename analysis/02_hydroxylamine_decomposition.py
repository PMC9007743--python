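"""Separate isomerization from hydrolysis with the hydroxylamine experiment.

Simulates paired runs — untreated membranes and membranes pre-incubated with
5 mM hydroxylamine — through the full spectral pipeline, subtracts the decay
curves to reconstruct the rho* population, and reports the recovered
isomerization rate k_iso and pure hydrolysis rate k'_hyd against the
generating values.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from photocascade import kinetics as K
from photocascade.instrument import InstrumentModel, simulate_series
from photocascade.quant import ChargeSeries, abundance_trace
from photocascade.spectra import RETINYLIDENE_DELTA, LightSchedule, SpeciesDef

RESULTS = Path(__file__).resolve().parents[1] / "results"

K_ISO, K_HYD_PRIME = 0.2, 0.02  # ground truth (s^-1)


def registry():
    return {
        "rho": SpeciesDef("rho", 39965.0, RETINYLIDENE_DELTA, 6, 10, 8.0),
        "opsin": SpeciesDef("opsin", 39965.0, 0.0, 6, 10, 8.0),
    }


def main() -> None:
    reg = registry()
    inst = InstrumentModel(mz_min=3900.0, mz_max=7000.0, mz_step=0.25,
                           charge_envelope={"rho": (8.0, 1.0), "opsin": (8.0, 1.0)},
                           noise_sd=0.01, baseline=0.05)
    sched = LightSchedule.continuous(0.0)
    scheme = K.KineticScheme(R_c=1.0, Ops=0.0)
    times = np.arange(0.0, 121.0, 2.0)
    series_defs = [ChargeSeries(reg["rho"]), ChargeSeries(reg["opsin"])]

    p_untreated = K.RateParams(k_iso=K_ISO, k_hyd_prime=K_HYD_PRIME, k_ox=0.4, nh2oh_mM=0.0)
    p_nh2oh = K.RateParams(k_iso=K_ISO, k_hyd_prime=K_HYD_PRIME, k_ox=0.4, nh2oh_mM=5.0)

    s_u, _ = simulate_series(scheme, p_untreated, sched, inst, times, 101, reg)
    s_n, _ = simulate_series(scheme, p_nh2oh, sched, inst, times, 102, reg)
    tr_u = abundance_trace(s_u, series_defs)
    tr_n = abundance_trace(s_n, series_defs)

    dec = K.decompose_iso_hyd((tr_u.times, tr_u.column("rho")),
                              (tr_n.times, tr_n.column("rho")))

    RESULTS.mkdir(exist_ok=True)
    pd.DataFrame({
        "time_s": dec.times,
        "rho_untreated": tr_u.column("rho"),
        "rho_nh2oh": tr_n.column("rho"),
        "rho_star": dec.rho_star,
        "rho_star_model": dec.rho_star_model,
    }).to_csv(RESULTS / "decomposition_traces.csv", index=False, float_format="%.6g")

    print(f"k_iso   recovered {dec.k_iso:.4f} s^-1 (truth {K_ISO}; "
          f"error {abs(dec.k_iso - K_ISO) / K_ISO:.2%})")
    print(f"k'_hyd  recovered {dec.k_hyd_prime:.5f} s^-1 (truth {K_HYD_PRIME}; "
          f"error {abs(dec.k_hyd_prime - K_HYD_PRIME) / K_HYD_PRIME:.2%})")
    print(f"rho* clip fraction {dec.clip_fraction:.3f}; fit mode {dec.details['mode']}")
    print(f"wrote {RESULTS / 'decomposition_traces.csv'}")


if __name__ == "__main__":
    main()
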
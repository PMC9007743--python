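"""Pulsed-light regeneration: the N-ret-PE pathway transiently rebuilds rho.

Simulates the three-pulse illumination protocol (pulses at 0.51, 7 and 35 min
for 3, 12 and 32 s) with the N-ret-PE photorelease/rebinding pathway enabled,
and reports the transient rho rise after each pulse — the membrane's own
regeneration signature.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from photocascade import kinetics as K
from photocascade.spectra import LightSchedule

RESULTS = Path(__file__).resolve().parents[1] / "results"

PULSES = [(0.51 * 60.0, 3.0), (7.0 * 60.0, 12.0), (35.0 * 60.0, 32.0)]


def main() -> None:
    sched = LightSchedule(pulses=PULSES)
    scheme = K.KineticScheme(R_c=0.73, Ops=0.27, PE=0.08, NrPE=0.15)
    params = K.RateParams(k_iso=0.2, k_hyd_prime=0.02, k_regen=2.0,
                          k_conj=0.05, k_deconj=0.002, k_photo_nrpe=0.5)
    t = np.linspace(0.0, 45.0 * 60.0, 5401)
    traj = K.solve(scheme, params, sched, t)

    RESULTS.mkdir(exist_ok=True)
    pd.DataFrame({
        "time_s": t,
        "mass_rho": traj.mass_rho,
        "opsin": traj.opsin,
        "NrPE": traj.state("NrPE"),
        "cis_retinal": traj.state("C_ret"),
        "light": sched.intensity(t),
    }).to_csv(RESULTS / "pulsed_regeneration.csv", index=False, float_format="%.6g")

    for start, dur in PULSES:
        window = (t >= start) & (t <= start + 60.0)
        i_before = np.searchsorted(t, start) - 1
        peak_idx = np.argmax(traj.mass_rho[window])
        rise = traj.mass_rho[window][peak_idx] - traj.mass_rho[i_before]
        delay = t[window][peak_idx] - start
        print(f"pulse at {start/60:.2f} min ({dur:.0f} s): rho rises {rise:+.4f} "
              f"over the pre-pulse level, peaking {delay:.1f} s after pulse onset")
    print(f"wrote {RESULTS / 'pulsed_regeneration.csv'}")


if __name__ == "__main__":
    main()
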
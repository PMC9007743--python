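# photocascade

Time-resolved native mass spectrometry can watch a GPCR signalling cascade
happen: rhodopsin photoactivation, Schiff-base hydrolysis to opsin
(Δm = 266 Da), retinal–phosphatidylethanolamine conjugation (N-ret-PE),
transducin nucleotide exchange (G_t•GDP → apo-G_t, Δm = 443 Da) and PDE6
cGMP hydrolysis (Δm = 345 Da) all appear as mass shifts of intact species in
consecutive electrospray scans.  `photocascade` is the analysis pipeline for
such experiments — aimed at native-MS practitioners and modellers of rod
phototransduction — together with a synthetic instrument so the whole chain
can be exercised and validated without raw spectra.

## What it computes

**Charge-series quantification.**  For a species of neutral average mass M
observed at charges z_min..z_max, peaks sit at m/z = (M + z·m_H)/z with
m_H = 1.00728 Da.  Windows at these positions are integrated (trapezoid,
flat background subtracted) and per-species relative abundances are window
sums over the total.  A direct comb projection
score(M) = Σ_z I((M + z·m_H)/z) gives zero-charge spectra for mass
assignment.

**Photocycle kinetics.**  Mass-action ODEs over
{R_c, R_t, Ops, A_t, C_ret, PE, NrPE} with binary illumination I(t):

    dR_c/dt = −k_iso·I·R_c + k_regen·C_ret·Ops
    dR_t/dt = +k_iso·I·R_c − k'_hyd·R_t − k_ox·[NH2OH]·R_t
    dOps/dt = +k'_hyd·R_t + k_ox·[NH2OH]·R_t − k_regen·C_ret·Ops

plus retinal/PE conjugation (k_conj, k_deconj) and light-driven release of
cis-retinal from the conjugate (k_photo_NrPE).  The observable is
mass-rho = R_c + R_t (the photoproduct is isobaric with the dark state).
Two fits are provided: the effective relaxation
R(t) = R_∞ + (R_0 − R_∞)·e^(−k_hyd·t), and the hydroxylamine decomposition
that subtracts treated from untreated decay curves to recover the
isomerization rate k_iso and the pure hydrolysis rate k'_hyd separately.

**Downstream observables.**  G_t•GDP:apo-G_t ratio traces (proteoform
envelopes summed per state), PDE6:PDE6•cGMP occupancy with low-abundance
PDE6–Gα complex detection, and a minimal mass-action cascade for the
nucleotide-condition experiments (GTP, GTPγS, endogenous).

**Lipids.**  N-ret-PE conjugate masses (PE + 266.2034 Da), AUC-based
conjugated:free ratios, and PC unsaturated:saturated ratios, all on
negative-mode [M−H]⁻ windows.

## Worked example

Recover isomerization and hydrolysis rates from a simulated hydroxylamine
experiment (full pipeline: ODE → rendered spectra at 1% noise → windowed
quantification → curve subtraction):

```bash
python analysis/02_hydroxylamine_decomposition.py
```

prints

```
k_iso   recovered 0.2012 s^-1 (truth 0.2; error 0.58%)
k'_hyd  recovered 0.02023 s^-1 (truth 0.02; error 1.16%)
rho* clip fraction 0.000; fit mode two_exp
```

i.e. the treated membranes decay at the isomerization rate (0.2 s⁻¹ — every
photon-absorbing rho is cleaved almost immediately), the untreated−treated
difference reconstructs the rho* population, and its balance yields the
ten-fold slower Schiff-base hydrolysis rate.  The other drivers follow the
same pattern: `01` fits the effective k_hyd under continuous light, `03`
shows the N-ret-PE regeneration transient after light pulses, `04` the
transducin/PDE6 ratios and nucleotide-condition orderings, `05` the lipid
conjugation fold-changes, `06` compound-style rate modulation with
accelerator/decelerator classification.  Tables land in `results/`.

A CLI covers the same stages for folder-based workflows:

```bash
photocascade simulate --config run.yaml --out out/
photocascade quantify --config run.yaml --out out/
photocascade fit-kinetics --config run.yaml --out out/ --plot
photocascade deconvolve --scans out/scans --out zc.csv \
    --mass-min 39500 --mass-max 40700 --z-min 6 --z-max 10
```

Scan folders are plain two-column text files (m/z, intensity), one scan per
file, timestamps in the filename (`t<seconds>.txt`).

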
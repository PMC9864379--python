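# dmsofold

Analysis pipeline for DMSO-induced unfolding of small disulfide proteins,
combining three experimental readouts:

- **HSQC intensity titrations** — dual-delay peak volumes are
  back-extrapolated to zero transverse time (removing the viscosity-driven
  T2 bias), compensated for solution-volume dilution and pulse calibration,
  and fitted to a two-state unfolding model to extract the m-value, the
  midpoint concentration [DMSO]50 and the standard unfolding free energy
  dG0 = m·[DMSO]50 per peak, with pooled statistics across peaks.
- **15N backbone relaxation** — forward R1/R2/NOE rates from Lipari–Szabo
  spectral densities, reduced spectral density mapping (J(0), J(ωN),
  J(0.87ωH)), a two-stage model-free fit (one global correlation time plus
  per-residue S2 order parameters, Monte-Carlo errors), and an R1·R2
  chemical-exchange screen.
- **DSC melting curves** — reference/baseline-corrected excess heat
  capacity, melting-temperature extraction by local quadratic refinement of
  the peak maximum, and a parabolic Tm(x) stability fit versus DMSO v/v%.

Seeded synthetic-data generators (`dmsofold.synth`) produce titration,
relaxation and DSC fixtures from the same forward models the analyses
invert, so every test loop closes without external data.

## CLI

All stages are subcommands of `dmsofold`; each accepts `--config
config.yaml` (see `dmsofold.config.RunConfig` for the keys and defaults).

```sh
# generate synthetic inputs (writes CSV tables + a ground-truth JSON sidecar)
dmsofold simulate --kind titration --out sim/
dmsofold simulate --kind relax --spec relax_spec.yaml --out sim/
dmsofold simulate --kind dsc --out sim/

# titration: raw dual-delay volumes -> corrected I/I0 -> two-state fits
dmsofold correct --in sim/titration.csv --out corrected.csv
dmsofold fit-unfold --in corrected.csv --out fits.csv --summary unfold.json

# relaxation analyses
dmsofold relax-jmap --in sim/relaxation.csv --out jmap.csv
dmsofold relax-modelfree --in sim/relaxation.csv --out mf.csv --summary mf.json

# DSC: one thermogram CSV per DMSO condition
dmsofold dsc-fit --in dsc_0pct.csv --dmso 0 --in dsc_50pct.csv --dmso 50 \
    --out melt.csv --summary dsc.json --predict-at 50

# restraint statistics and report aggregation
dmsofold restraints --in pairs.csv --n-residues 55
dmsofold report --summaries unfold.json --summaries dsc.json --out report.json
```

Input dialects are plain CSV with a header row:

| table      | required columns |
|------------|------------------|
| titration  | `peak_id, dmso_vv_percent, delay_ms, volume_raw, solution_volume_uL` (optional `pulse_scale`) |
| relaxation | `residue, R1, R1_err, R2, R2_err, NOE, NOE_err` |
| thermogram | `temperature_C, cp` (optional `cp_reference`) |
| restraints | `residue_i, residue_j` |

Units: free energies kJ/mol, m-values kJ/mol/M, concentrations mol/L
(v/v% converted with configurable DMSO density 1.10 g/mL and molar mass
78.13 g/mol), temperatures kelvin internally (°C at the DSC boundary).

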
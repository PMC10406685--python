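# diffcs — difference compressed sensing for serial 2D NMR

Serial 2D NMR experiments — variable-temperature, variable-pressure or
titration series — produce many spectra that differ only slightly from
one another. Conventional compressed-sensing (CS) reconstruction of a
non-uniformly sampled (NUS) spectrum needs roughly

    M ~ K log(N / K)

sampled indirect-dimension points, where K is the number of significant
spectral points. Crowded spectra of intrinsically disordered proteins
have large K, so plain NUS saves little time. **Difference compressed
sensing (DCS)** exploits the series structure instead: acquire one
(nearly) fully sampled reference signal f_A, undersample the target
f_B, restrict the reference to the target's schedule, and reconstruct
the *difference*

    f_diff^NUS(t1, t2) = f_B^NUS(t1, t2) − f_A^NUS(t1, t2),

which is far sparser than either spectrum. The reconstructed difference
is then added back to the conventionally processed reference:

    S_B^rec(ω1, ω2) = S_diff^rec(ω1, ω2) + S_A^full(ω1, ω2).

Before subtracting, the reference is matched to the target by a
brute-force grid search over an integer spectral-point shift Δω2 and a
Gaussian line broadening σ of its first-increment 1D spectrum
(minimizing ‖shift(broaden(A)) − B‖₂), plus a deterministic amplitude
(dilution) factor. Subtracting two measured signals amplifies noise by
√2, so DCS wins at low sampling levels when few peaks change and cedes
to conventional CS when sampling is generous or sensitivity is poor.

The package targets the downstream science as well: per-residue
relative intensities I_rel = h_target / h_reference across a
temperature series, sigmoidal melting fits

    y = y_scale · (1 − tanh(x_scale · (x − x_shift))) / 2 + y_shift,

whose x_shift is the per-residue transition temperature, the four
rejection filters for non-sigmoidal profiles, and the normalized
peak-height residual ‖h_rec − h_full‖₂ / ‖h_full‖₂ used as the
reconstruction quality metric.

Audience: NMR spectroscopists running serial 2D experiments (protein–
membrane or protein–ligand titrations, thermal unfolding) who want to
undersample aggressively without losing quantitative peak intensities.

## What is in the box

| module | contents |
| --- | --- |
| `diffcs.signal_model` | `AxisMeta`, `TimeDomain2D`, `Spectrum2D`, damped-sinusoid FID generator, conventional 2D processing (`ft2d`), synthetic variable-temperature series generator |
| `diffcs.sampling` | sinusoidally weighted Poisson-gap schedules, nested (subset) schedules, artificial undersampling, nuslist-style schedule files |
| `diffcs.cs_recon` | direct-dimension FT, virtual echo, column-wise iterative soft thresholding (IST), 2D CS reconstruction |
| `diffcs.dcs` | first-increment alignment (shift/broadening grid search), difference FIDs, the DCS pipeline |
| `diffcs.series_analysis` | peak heights, I_rel, bounded tanh fits, rejection filters, transition tables, normalized residuals, plots |
| `diffcs.io` / `diffcs.cli` | internal container (JSON manifest + flat binary), minimal NMRPipe 2D and Varian fid readers/writers, `diffcs` command-line tool |

## Worked example

```python
import numpy as np
from diffcs import (SyntheticSeriesSpec, generate_series, poisson_gap_schedule,
                    undersample, dcs_reconstruct)
from diffcs.workflow import run_vt_study, transition_agreement

# 100-peak HSQC-like series, 15 temperatures (15-43 degC), 256-point
# indirect grid; the target series carries a 2-point shift, 1 Hz extra
# broadening and a 0.9 dilution relative to the reference.
result = run_vt_study(m=64, schedule_seed=1)

frac, n = transition_agreement(result.table_full, result.table_rec, tol_c=1.0)
print(f"agreement within 1 degC: {100*frac:.0f}% of {n} accepted peaks")
print("correction at 15 degC:", result.corrections[0].delta_omega2, "points,",
      result.corrections[0].sigma_hz, "Hz")
print("normalized residuals:", [round(r, 2) for r in result.normalized_residuals])
```

prints

```
agreement within 1 degC: 100% of 100 accepted peaks
correction at 15 degC: 2 points, 2.25 Hz
normalized residuals: [0.03, 0.01, 0.02, 0.02, 0.03, 0.04, 0.06, 0.12,
                       0.2, 0.28, 0.33, 0.35, 0.34, 0.33, 0.35]
```

Reading: using only 64 of 256 indirect points, every accepted peak's
fitted transition temperature lands within 1 °C of the full-data value.
The alignment search finds the configured 2-point shift; at this noise
level it trades part of the residual amplitude mismatch into extra
broadening (2.25 Hz rather than the configured 1 Hz — see
`docs/methods.md`). The per-temperature normalized peak-height
residuals grow with temperature: as more residues bind, more peaks
differ between target and reference, the difference spectrum loses its
sparsity and √2-amplified noise costs more.

The same pipeline is scriptable from the shell:

```sh
diffcs simulate --out sim --seed 0
diffcs schedule --n 256 --m 64 --seed 1 --out nuslist
diffcs dcs --reference sim/reference --target sim/target \
           --schedule nuslist --amplitude-scale 0.9 --out run
diffcs analyze --target-spectra run/spectra --reference-spectra ref_spectra \
               --peaks sim/peaks.tsv --out analysis --plots
diffcs report --run analysis
```

## Data formats

* Internal container: a directory with `manifest.json` (axes,
  temperatures, schedules, provenance) plus one flat binary file per
  spectrum — little-endian float64, row-major, re/im interleaved for
  complex time-domain data, plain values for real spectra.
* NUS schedules: plain text, one 0-based grid index per line, ascending
  (1-based accepted via `--one-based`).
* Peak lists: delimited text with header `label omega1_ppm omega2_ppm`.
* NMRPipe 2D spectra and Varian fid directories: a documented subset of
  each format, sufficient for round trips through this package's own
  writers.

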
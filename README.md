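# nanospt

Single-particle TIRF quantification of membrane-receptor nanoclustering and
dynamics, with a ground-truth synthetic-data generator for end-to-end
validation.

## What it is for

In single-particle tracking (SPT) of fluorescent-protein-tagged receptors
(e.g. a chemokine receptor fused to monomeric AcGFP, imaged by TIRF at
10 Hz), the central questions are: how many receptors does each
diffraction-limited particle contain, how mobile is it, and — for the
accompanying chemotaxis assays — how directed is cell migration?  This
package implements that measurement chain as a reusable, tested pipeline:

1. **Spot detection and linking** — LoG detection with sub-pixel
   localization, and gated minimum-cost bipartite linking with short gap
   closing.  Trajectory CSVs from any external tracker are accepted too.
2. **Background** — per-frame particle background `K0`, the 80th-percentile
   gray value of the cell-background pixel distribution (detections
   excluded).
3. **Particle intensity** — the 3×3 pixel window sum centred on the
   particle minus `9·K0`, averaged over the first 20 frames of the
   trajectory, truncated at the first photobleaching step and corrected
   for the sub-pixel window aperture.
4. **Stoichiometry** — intensity divided by the monomeric-calibrant
   reference `I_mono` (a Gaussian fit to calibrant intensities; generator
   default 980 ± 89 a.u.).  Counts ≤ 2 are monomers-plus-dimers, ≥ 3 are
   nanoclusters; the group mean spot intensity (MSI) is reported alongside.
5. **Photobleaching control** — single-exponential fit of single-step
   bleach times (τ0; generator default 5 s ≙ 50 frames at 100 ms/frame),
   with a consistency check that the 20-frame averaging window is shorter
   than τ0.
6. **Mobility** — time-averaged MSD per trajectory, short time-lag
   diffusion coefficient `D1-4 = slope/4` from an OLS fit with intercept
   over lags 1–4, and mobile/immobile classification against a
   noise-calibrated threshold (99th percentile of `D1-4` for simulated
   zero-motion tracks).
7. **Chemotaxis metrics** — per-cell forward migration index
   `FMI_x = (x_end − x_start)/accumulated path`, straightness
   `= euclidean/accumulated`, spider-plot coordinates.
8. **Statistics** — two-tailed Mann-Whitney for diffusion coefficients
   (exact enumeration for combined n ≤ 12), chi-square for categorical
   fractions, and the usual `n.s. / * / ** / *** / ****` labels.

Because live-cell SPT data cannot be regenerated at a desk, correctness is
demonstrated against the built-in simulator, whose defaults encode the
acquisition regime above (500 frames at 10 Hz, < 4.5 particles/μm²,
single-step bleaching, Brownian or immobile motion) and which reports full
ground truth per particle and fluorophore.

## Worked example

```bash
cat > demo.yaml <<'YAML'
seed: 3
out_dir: demo
simulation:
  fov_px: 96
  frame_count: 120
  particle_density_per_um2: 0.6
intensity:
  calibration_particles: 400
linking:
  max_disp_px: 3.0
diffusion:
  threshold_n_sim: 1000
chemotaxis:
  enabled: true
  n_cells: 40
  n_steps: 30
  bias: 0.5
YAML
nanospt run --config demo.yaml
```

prints

```
nanospt 0.1.0 run e1552e91b6ce
  monomer reference: 977.2 ± 83.3 a.u. (n=365); tau0 = 3.73 s = 37.3 frames; window ok: True
  particles: 21; mono+dimer 76.2% / nanocluster 23.8%; MSI 1746 a.u.
  mobility: 86.5% mobile / 13.5% immobile; median mobile D1-4 = 0.0184 um2/s (threshold 0.00117)
  chemotaxis: n=40 cells, FMI_x 0.856 ± 0.030, straightness 0.865 ± 0.029
```

Reading the numbers: the monomer calibration recovers the generator's
980 a.u. reference within sampling error; τ0 is under-estimated here only
because a 120-frame (12 s) demo movie right-censors the 5 s bleach-time
distribution — at the standard 500 frames the fit returns ≈ 5 s.  The
simulated truth for this run is 85% mobile particles diffusing at
0.02 μm²/s, recovered as 86.5% and 0.0184; the strongly biased cell walk
(bias 0.5) yields a mean FMI of 0.86.  Every output file is prefixed with
the 12-character hash of the resolved configuration, and
`<hash>_run_record.json` embeds that configuration.

The same stages are available piecemeal (`nanospt simulate
movie|tracks|calibration|cells`, `detect`, `track`, `detect-track`,
`quantify`, `dynamics`, `chemotaxis`, `stats`) and as library functions
(`import nanospt`).

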
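# leafmorph

Outline morphometrics for single-leaf scans: binary-mask extraction,
elliptic Fourier shape normalization, pairwise shape-difference metrics,
axial-symmetry (fluctuating asymmetry) statistics, and a two-sample test
battery — plus a synthetic leaf-scan generator so the whole pipeline is
testable without any image downloads.

## What it does

1. **synthetic** — generates scanner-style leaf images (ovate, serrated,
   optionally asymmetric outlines defined in elliptic-Fourier coefficient
   space) and a pairing manifest for a two-treatment × three-node ×
   replicate-plants study design (84 leaves with defaults). Fully seeded
   and byte-reproducible.
2. **preprocessing** — RGB scan → BT.601 luminance → Otsu binarization
   (dark class = leaf) → hole filling + largest-component cleanup →
   sub-pixel outer contour → physical area via dpi calibration. Optional
   petiole removal via a caller-supplied exclusion polygon.
3. **efd** — Kuhl–Giardina-style elliptic Fourier transform (arc-length
   parameterization), frequency-domain normalization (position, scale to a
   1000-point major diameter, rotation, starting point; reflection kept),
   and inverse reconstruction at phase-aligned sample points.
4. **metrics** — relative area difference, symmetric nearest-point contour
   distances `d_avg`/`d_max` with histograms, mean squared coefficient
   distance `D²`, mirror-symmetry errors `e_d` (contour distance) and
   `ε_a` (XOR-area ratio), and the five population ratio statistics
   (`delta_avg`, `delta_max`, `delta_efd`, `delta_d`, `delta_a`).
5. **stats** — Shapiro–Wilk normality screen selecting Welch t vs
   Mann–Whitney per comparison, per-node and pooled summaries
   (mean ± SD/SE), and a full test-report table.
6. **cli** — `generate` / `measure` / `compare` subcommands.

## CLI

```bash
# synthetic study: 84 PNGs + manifest.csv (deterministic per seed)
leafmorph generate --out study/ --seed 1 --dpi 300

# per-leaf measurements (area, e_d, epsilon_a, coefficient files)
leafmorph measure --images study/ --manifest study/manifest.csv \
    --dpi 300 --out measurements.csv
# real scans: supply your own manifest; petiole exclusions via
#   --petioles sidecar.csv   (columns: path,x,y — one polygon per image)
# --artifacts DIR additionally writes per-leaf mask PNG, contour CSV
# and a JSON record with the processing log

# full analysis: pairings, pair metrics, Table-style summaries,
# delta ratios (ratios.json) and test reports
leafmorph compare --images study/ --manifest study/manifest.csv \
    --dpi 300 --alpha 0.05 --seed 1 --out results/
```

Analysis parameters (harmonics K=50, 1000 contour samples, histogram bin
width 10, 2048-px overlap grid, alpha, distance pairing mode, forced test
choice) live in a JSON `RunConfig` passed with `--config`; every output
file header carries the config hash.

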
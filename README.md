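# oxchip

Modeling and analysis for a **double-layer PDMS microfluidic device that
controls oxygen tension** around 3-D cell cultures.  The chip holds a
central collagen-gel channel (with cells) flanked by media channels; two
gas channels run directly above them, and a gas-impermeable polycarbonate
(PC) film embedded in the PDMS blocks atmospheric oxygen from above.
Supplying gas mixtures of chosen O₂ content to the gas channels imposes
uniform hypoxia, oxygen gradients, or intermittent (time-switched)
hypoxia in the gel within minutes.

The package is aimed at people designing or using such oxygen-control
chips: it reproduces the device's transport physics, the phosphorescence
oximetry used to validate it, and the cell-migration statistics used to
quantify the biology — plus synthetic-data generators so the whole
pipeline runs without laboratory data.

## What it computes

**Oxygen transport** (`oxchip.geometry`, `oxchip.transport`).  The 2-D
*x–z* cross section of the chip is discretized into a material-labeled
grid and oxygen is solved in partial-pressure form φ (%O₂, 21 = ambient):

    steady:     ∇·(k ∇φ) = 0,          k = D·S   (permeability)
    transient:  S ∂φ/∂t = ∇·(k ∇φ)

with Henry's law c = S·p linking dissolved concentration to partial
pressure.  A finite-volume scheme with harmonic-mean face permeability
makes the interface partition condition (equal partial pressure,
concentration jumping by the solubility ratio S₁/S₂) exact.  Gas
channels are fixed-composition surfaces (valid at supply Péclet numbers
≥ 10), the outer PDMS surface sees ambient air, and the glass floor is
zero-flux.  Utilities convert Péclet numbers to supply flow rates
(Pe = U·W/D with W the channel width), sweep the design parameters
(H_g, H_f) — the heights of the gas channels and PC film — and extract
gel-profile slopes and equilibration times.

**Phosphorescence oximetry** (`oxchip.sv_calibration`).  Oxygen-sensitive
particles in the gel are imaged in two channels; phosphorescence I_P is
normalized ratiometrically against oxygen-insensitive fluorescence,
I′ = I_P·I_F0/I_F, cancelling illumination drift, and converted to
oxygen tension with the per-section Stern–Volmer relation

    c(x) = [ (I′_A(x) − I′_BG(x)) / (I′(x) − I′_BG(x)) − 1 ] / K_q(x) × 100

where I′_A is the anoxia intensity, I′_BG the background, and K_q the
quenching constant fitted per 100 µm section of the imaging ROI.

**Migration statistics** (`oxchip.migration_stats`).  3-D cell tracks
(10-min frames over 24 h) yield per-interval speeds in µm/h, a slow/fast
subpopulation split at 15 µm/h, cell-count increases in the L/M/R thirds
of the gel (−450 ≤ x ≤ 450 µm), proliferation folds, Kruskal–Wallis +
Dunn post-hoc comparisons across oxygen conditions, Welch's *t* for
proliferation, and a two-way ANOVA for 4-h-window speed series.

**Synthetic data** (`oxchip.synthetic`).  A forward camera model renders
calibration image stacks over known oxygen fields (drift + noise), and an
oxygen-dependent persistent random walk generates cell tracks with
division events — faster migration under hypoxia with a local maximum
near 5 %O₂, and division probabilities chosen so proliferation folds
match the observed 1.7–1.8× (hypoxia) vs 1.4× (normoxia).

## Worked example

Steady oxygen gradient across the gel (0% O₂ supplied to the left gas
channel, 21% to the right), on the default geometry at 25 µm resolution:

```sh
$ oxchip simulate-steady --condition G
center-gel oxygen tension: 10.674 %O2
gel endpoints: 2.709 / 18.304 %O2, slope 12.786 %O2/mm
```

The gel sees a near-linear gradient from ~2.7 to ~18.3 %O₂ — the steep,
imaging-compatible gradient the double-layer design exists to produce.
Switching both gas channels from air to 0% O₂:

```sh
$ oxchip simulate-transient --from N --to H0 --t-end 1200
steady center value: 0.010 %O2
equilibration (within 0.5 %O2): 4.8 min
```

i.e. the gel center settles to deep hypoxia within minutes.  Note that
the 2-D cross-section model yields an essentially zero hypoxic floor at
the gel center; the residual oxygen level seen in a real (3-D, finite)
device comes from leakage paths that do not exist in the cross-section —
see `docs/methods.md` for the analysis.

The same library calls are available in Python:

```python
from oxchip import DeviceSpec, BoundarySet, build_cross_section, solve_steady

grid = build_cross_section(DeviceSpec(), 25e-6)
field = solve_steady(grid, BoundarySet(gas_left=5.0, gas_right=5.0))
print(field.center_gel())   # 5.008 %O2 at a 5% supply
```

Synthetic experiments run end to end without data:

```sh
$ oxchip synth tracks --condition H5 --n 50 --seed 1 --out tracks.csv
138 tracks written to tracks.csv
$ oxchip tracks analyze tracks.csv
tracks: 138
overall mean speed: 17.39 um/h
slow/fast tracks: 90/48 (peaks 6.2/33.8 um/h)
```

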
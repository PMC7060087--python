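# Methods

## Transport model

### Geometry

The chip is a 35 mm diameter, 4 mm thick PDMS disc on a glass coverslip.
The primary model is its 2-D *x–z* cross section, treated as a 35 mm wide
slab: the published oxygen profiles are reported on this plane, and the
slab retains lateral oxygen leakage through the bulk PDMS, the effect
that limits how low the channel oxygen tension can go.  Defaults: gel
channel 1300 µm wide, media channels 500 µm each side, all channels
150 µm high; gas channels 1000 µm wide with inner edges 1300 µm apart
(so they do not overhang the gel, keeping it imageable), at height
H_g = 0.5 mm; PC film 0.5 mm thick at H_f = 1 mm.

Deliberate simplifications, each recorded here as a design choice:

- **Gel + media as one aqueous layer.**  The PDMS posts that separate gel
  from media channels are discrete in *y*; the slice is taken between
  posts, so the floor layer is one contiguous water-like region 2300 µm
  wide.  The gel span is labeled distinctly so profiles are sampled on it.
  (Posts would conduct slightly *better* than water — PDMS permeability
  is ~11× that of water — so merging is conservative.)
- **Glass floor is zero-flux.**  Glass is effectively oxygen-impermeable;
  the source text does not state this boundary explicitly.
- **The PC film spans the full lateral extent**, and the port holes
  punched through it are ignored (they are far from the imaging region).
- **Grid**: material interfaces always fall on cell edges; segments
  between interfaces are subdivided at the requested resolution (default
  25 µm, resolving the 150 µm channels with 6 cells and the film with 20)
  and auto-refined where a feature is thinner than one cell.  Material
  assignment uses half-open [low, high) intervals on cell centers, so
  interface ties cannot occur.

### Discretization

Solving in partial pressure φ (%O₂) with per-cell permeability k = D·S
makes the Henry's-law partition condition automatic: a two-point flux
with harmonic-mean face conductance G = A / (d₁/k₁ + d₂/k₂) conserves
flux exactly across material interfaces while φ stays continuous, which
is precisely the interface condition (concentration then jumps by the
solubility ratio).  Material properties are the study's values: D (m²/s)
2.0e−9 for medium/gel, 4.0e−9 for PDMS, 2.0e−12 for the PC film; S
(mM/atm) 0.218 for water-like materials, 1.25 for PDMS and film.

Gas channels are Dirichlet cells at the supply composition — justified
because the device is operated at a gas supply Péclet number of 100,
well above the ~10 threshold where the channel composition becomes
supply-dominated; a warning is raised below it.  The ambient surfaces
(top and both sides) apply φ = 21 through a half-cell conductance; the
floor contributes no flux.  The steady system is solved by sparse LU
(SuperLU); the residual is checked against 1e−10 relative, and every
solve asserts the discrete maximum principle (solutions bounded by the
extreme boundary values).

Transient stepping is backward Euler on S·V·dφ/dt with per-cell
solubility as capacitance, so each material relaxes with its true time
constant.  Default dt = 1 s (5 s in the bundled analyses); the matrix is
factorized once and reused.  The gel-center value is recorded every step;
the equilibration time is the first time the center stays within
0.5 %O₂ (hypoxic step) or 1 %O₂ (reoxygenation) of the steady value.
Halving dt moves the reported equilibration time by < 5% (the readout is
quantized to dt).

The quasi-1-D `channel_axis_model` covers the supply-rate question the
cross section cannot: U·dφ/dy = (k_ex/(S·h))(φ_wall − φ), exponential
relaxation with decay length λ = U·S·h/k_ex.  The default wall
conductance k_ex = k_fluid/(h/2) is the half-channel diffusion
resistance — a qualitative stand-in for a conjugate solve, reproducing
the threshold behavior (slow supply equilibrates with the walls, fast
supply carries its inlet composition through).

### Problem sizes used

The bundled analyses run the default cross section at 25 µm resolution
(1400 × 160 ≈ 224k cells; a steady solve takes a few seconds, a 20-min
transient at dt = 5 s under a minute).  The test suite uses 50 µm grids
for speed; center values change by < 5e−4 %O₂ between 50 and 12.5 µm.

### What the 2-D slab does and does not reproduce

The gradient condition (0% / 21% on the two gas channels) is set by the
gas channels themselves and reproduces the published computed profile
well: gel-edge values 2.71 / 18.30 %O₂ vs 3 / 18 reported.  Supply
linearity (center value affine in the supply oxygen, R² > 0.999) and the
equilibration times (≈5 min vs the ≤15 min / ≤10 min reported bounds)
also reproduce.

The absolute hypoxic floor does not.  Under a 0% supply the converged
2-D center value is ≈0.01 %O₂ (stable across 50/25/12.5 µm grids),
whereas the study reports 0.4 %O₂ computed / 0.3 %O₂ measured.  In the
cross section, ambient oxygen can only reach the gel by passing either
through the 350 µm PDMS band directly beneath the 1 mm-wide gas channels
(attenuation length ≈0.25 mm, so ≈e⁻⁴ across) or through the media
strip directly beneath them (attenuation length ≈68 µm, ≈e⁻⁷); the gas
channels therefore intercept essentially all side leakage.  The residual
floor of a real device comes from paths with no 2-D counterpart: channel
ports punched through the film, the finite extent of the channels in
*y*, and the radial disc geometry.  For the same reason the center value
is not strictly monotone in H_g at the low end of the design sweep
(0.0117 at H_g = 0.25 mm vs 0.0100 at 0.5 mm — raising the film opens a
lateral band that diverts film throughput into the gas channels), while
the steep rise at larger H_g (0.13 at 1 mm, 0.45 at 1.5 mm) and the
"film below 2 mm keeps the channels under 1 %O₂" rule both hold.
Consumers of absolute hypoxic-floor numbers need the 3-D device; the 2-D
model is for gradients, time scales, and design trends.

## Stern–Volmer calibration

The imaging ROI (1024 × 50 px = 1331 × 65 µm across the gel) is tiled
into 100 µm sections; the trailing 31 µm partial section is dropped
rather than averaged short.  Ratiometric normalization I′ = I_P·I_F0/I_F
cancels any multiplicative illumination drift shared by the two channels
because the anchor frame (t₀) is drift-free by construction.

Per section, I′_A is pinned to the anoxia measurement, and (I′_BG, K_q)
are fitted by ordinary least squares on the nonlinear form
I′(c) = I_BG + (I_A − I_BG)/(1 + K_q·c/100); the linearized
Stern–Volmer plot only seeds the optimizer, avoiding the variance
distortion the linearization introduces at low intensities.  The fit is
per-section independent (no spatial smoothing of the background).
Calibration defaults use supply levels {0, 1, 3, 5, 10, 21} %O₂ — the
device's sensitivity-test set; with fewer levels, I_BG and K_q become
weakly identified (their errors are strongly anti-correlated along a
direction that leaves the oxygen readout nearly unchanged, so oxygen
profiles are recovered much more accurately than either parameter).
Inversion flags I′ ≤ I_BG as undefined (NaN, not clamped) and clamps
formally negative oxygen (I′ > I_A) to zero with a flag.

## Synthetic data

The camera model renders both channels from the forward Stern–Volmer
relation at the local oxygen value, scales by a drift g(t) with
g(t₀) = 1, and adds Gaussian noise: an additive floor (sd 2.0 on
signals of ~1000 arbitrary units) plus a mild signal-dependent
(Poisson-like) component (variance 0.05 × signal).  After averaging
~3850 pixels per section this puts section-mean noise near 0.1 units —
representative of high-SNR averaged microscopy.  It does not emulate
photobleaching (none was observed in the validation data), detector
nonlinearity, or spatial illumination structure, so passing round trips
demonstrate correctness of the pipeline algebra and drift immunity, not
robustness to every real-world artifact.

The walk model encodes the *ordinal* structure of the observed
migration biology; no absolute speeds were published beyond the 15 µm/h
threshold landmark, so absolute values are free parameters:

- two lognormal speed components; the slow mode (median 7.5 µm/h,
  σ = 0.35) is oxygen-independent, matching the observation that the
  slow subpopulation's histogram peak does not move with oxygen; the
  fast mode (median 22 µm/h at 21 %O₂, σ = 0.4, 35% of cells) scales
  with a piecewise-linear response through the generated oxygen levels
  {0.3, 1.3, 3.4, 5.3, 10.1, 21}, peaking at 5.3 %O₂, with 10.1 %O₂ on
  par with normoxia — the constraint set s(5) > s(0.3) > s(21),
  s(10) ≈ s(21) is validated at construction;
- directions persist between 10-min steps (persistence 0.6) and
  positions reflect at the gel walls;
- division: each founder divides at most once, at a uniform random time,
  with probability p₂₄ interpolating (0.7, 0.8, 0.4) at (0.3, 5.3, 21)
  %O₂ — chosen so expected whole-gel folds are exactly the observed
  1.7 / 1.8 / 1.4.  Daughters do not re-divide within the 24 h run,
  which keeps the expected fold at 1 + mean(p₂₄) (a branching process
  would compound);
- after an oxygen switch the speed response follows the oxygen
  experienced 4 h earlier, matching the several-hour adaptation lag seen
  under intermittent hypoxia;
- default cell count follows the seeding density (2 × 10⁵ cells/ml in
  the gel volume, ≈117 cells in a 3 mm gel segment).

The generator does not model chemotaxis, nutrient gradients, metabolic
state, or cell–cell interactions; recovery tests therefore validate the
measurement pipeline (speed computation, splits, region counts, test
statistics), not any biological mechanism.

## Migration statistics

Speeds are 3-D Euclidean step displacements over the actual elapsed time
(missing frames produce one flagged speed over the gap, not zeros).
Per-time-point curves pool intervals across tracks, then average.
Subpopulation assignment summarizes each track by its *median* interval
speed (robust to single-frame jumps) against the 15 µm/h threshold.
Region boundaries are half-open, [−450, −150), [−150, 150), [150, 450],
so ties at −150/150 fall rightward; counts conserve (L+M+R+outside =
total).  Kruskal–Wallis uses scipy; Dunn's post-hoc z tests (with tie
correction) are implemented here with Holm adjustment by default
(Bonferroni and unadjusted available) since the multiplicity correction
was not specified; Welch's t and the two-way ANOVA (condition × 4-h
window, type-II sums of squares via statsmodels) cover the proliferation
and time-series comparisons.  Groups with fewer than 3 observations are
dropped with a warning.

## Known limitations

- The 2-D slab's absolute hypoxic floor is ≈0.01 %O₂, not the ≈0.3–0.4
  of the 3-D device (see above); gradients, linearity, time scales and
  design trends are the reliable outputs.
- Channel flow is never solved; the Péclet utilities and the quasi-1-D
  axial model only reproduce the supply-rate thresholds qualitatively.
- Stern–Volmer background and quenching constant are jointly
  weakly identified from few calibration levels; oxygen readouts remain
  accurate, but per-section K_q values carry percent-level noise.
- Synthetic tracks are ordinal-faithful only; absolute speeds and
  persistence are plausible choices, not fitted quantities.
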
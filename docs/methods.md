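# Methods

This note documents the models implemented in `origamikin`, their
assumptions, the default parameters and why they were chosen, and what the
synthetic-data pipeline does and does not establish about real experiments.

## Connector model

A repeat connector's terminal sticker of length `L_s` (nt) can hybridize a
docking extension of length `L_d` at `max(0, L_s − L_d + 1)` offsets; each
offset is a productive binding register. No published rate law exists for the
resulting acceleration, so the module adopts the simplest law consistent with
the two known mechanisms (register multiplicity and hairpin suppression): a
product form

    k_eff = k_base · n_frames · hairpin_accessibility · valence_multiplier

with every factor user-configurable. `k_base` defaults to 1 × 10⁶ M⁻¹s⁻¹, a
typical short-duplex hybridization on-rate. Scaffold connectors have a single
register by construction; their hairpin accessibility is an *input* (default
0.3 in the benchmark condition table) because secondary-structure prediction
is explicitly out of scope — it encodes only "a substantial penalty" and is
the one free calibration knob in the scaffold conditions. For spacer-free
all-T connectors, any register along the full strand can serve either binding
partner, so the per-end binding length equals the total length; the
competition of docking extensions for overlapping stretches of a short strand
is captured separately by the non-overlapping packing bound
`floor(L_binding / L_d)`. Sequence-level thermodynamics are not modeled.

Connector loading is coarse-grained: connectors are never explicit particles.
Their solution concentration and effective on-rate fold into one
pseudo-first-order edge-pair linking rate `k_link = k_eff · [connector]`,
because the observable of interest is particle assembly, not connector
occupancy.

## Diffusion–aggregation simulator

Monomers live on a periodic square membrane patch and carry a polarity vector
and two linkable edges (front/back). Clusters translate rigidly with
independent Gaussian steps of per-axis variance 2·D_n·dt. Rotational
diffusion of clusters is neglected (it does not change encounter statistics
at the capture-radius level and is invisible at 130 nm pixels). Two mobility
rules are available: the default free-draining `D_n = D_1/n`, and a
Saffman–Delbrück-style weak logarithmic decay for users who prefer
membrane-inclusion hydrodynamics; D_n is non-increasing in n either way.
`D_1` defaults to 0.2 µm²/s, the measured mobility of membrane-anchored
monomers.

Binding: every compatible edge pair on distinct clusters closer than the
capture radius bonds with probability `1 − exp(−k_link·dt)` per step.
Scaffold rule: only front–back pairs of near-parallel monomers (±30°
tolerance — the experiments report parallel-only assemblies without stating
an angular criterion) and strictly one partner per edge, producing linear
chains. Repeat rule: any edge pair at any orientation, and an occupied edge
accepts an additional partner with `branch_probability` (default 0 in the
dataclass; 0.3 in the benchmark experiments, reflecting that branching is
observed but not dominant). Bonds are permanent — assemblies survive
connector washout in the experiments this emulates — though the
configuration keeps rates ≥ 0 so an off-rate extension remains possible.
Merged clusters preserve relative member positions (rigid, no relaxation);
internal flexing is unresolvable at the rendering scale.

Numerical guard: the per-step r.m.s. displacement √(2·D₁·dt) must stay below
the capture radius, otherwise encounters are skipped over; violating
configurations raise before running. Defaults dt = 1 ms with capture radius
0.1 µm satisfy this at D₁ = 0.2 µm²/s. The benchmark experiments use
dt = 80 ms with capture radius 0.2 µm — the same criterion holds
(√(2·0.2·0.08) ≈ 0.18 µm < 0.2 µm) and the coarser pairing lets multi-hour
incubations run at desk scale; linking rates are kept small enough that
binding stays reaction-limited (probability per encounter ≪ 1), which is the
regime in which assembly timescales scale inversely with the linking rate.

## Movie renderer

Each monomer is a point emitter with brightness
`labels_per_monomer × occupancy` fluorophores (default 5 × 1.0, the
quasi-irreversibly labeled 5-site docking handle). The PSF is an integrated
2D Gaussian (per-pixel erf differences, exact to < 10⁻⁶ of the mass at the
±(5σ+1)-pixel patch), σ = 150 nm by default — a typical high-NA visible-light
TIRF PSF; the source experiments do not state theirs. Camera model:
`counts = offset + gain · Poisson(signal photons) + N(0, read_noise²)`,
clipped at zero and quantized to uint16 (saturation at 65535). Gain, offset
and noise defaults are generic and recorded in every stack's metadata
sidecar. Bleaching (default off) decays brightness with *illuminated* time
only, since the laser is shuttered between observation windows. One mid-frame
position per frame: at D ≤ 0.2 µm²/s and 33 ms exposures, motion blur is
sub-pixel. The default 64 × 64-pixel field is a desk-scale choice; the
acquisition geometry itself (130 nm pixels, 30 Hz, 300-frame windows) follows
the study's imaging conditions. EMCCD excess noise, sCMOS pixel maps and
evanescent-depth effects are not modeled.

## Correlation parameter and timescale fit

The exact published formula for the correlation parameter is not available;
this package defines it as

    C = ⟨ δF(x,t) · δF(x,t+ℓ) ⟩ / ⟨F − offset⟩² ,  ℓ ≥ 1 (default 1),

with δF the per-pixel detrended intensity (temporal mean, or best-fit line to
guard against bleaching/drift). This definition was chosen because it (a)
reports temporal fluctuation amplitude, (b) vanishes identically for immobile
noise-free scenes, (c) cancels temporally uncorrelated detector noise in
expectation through the ℓ ≥ 1 lag, and (d) is invariant under affine
intensity changes when the offset is supplied — matching every qualitative
property claimed for the published statistic. Windows are analyzed
independently (no cross-window detrending; the illumination is shuttered
between them).

Small-sample note: mean subtraction introduces a deterministic bias of
−σ²_noise/T in the numerator (≈ 10⁻⁴ in C for typical settings at T = 300),
which is why "consistent with zero" for immobile scenes is asserted at the
10⁻³ level rather than machine precision.

The characteristic assembly timescale is the midpoint t½ of a logistic decay
`C(t) = C_base + (C_peak − C_base)/(1 + exp((t − t½)/w))` fitted by least
squares to the decaying phase (from the peak of a 3-point-smoothed trace
onward), with peak-anchored initialization and t½ bounded to the observed
span. The transition width is floored at max(spacing/4, span/200): a narrower
transition is indistinguishable from a step between two acquisitions and
makes the optimizer snap onto the sampling grid. A trace that never drops by
at least 50 % of its peak is reported as `fitted = False` (no timescale) —
mirroring conditions with no notable change in the fluctuation data — and fit
divergence likewise returns a diagnostic rather than raising.

Observation schedules for kinetics comparisons are geometric
(`log_schedule`): log-spaced acquisition times measure timescales with
constant *relative* resolution, so a fast and a slow condition are resolved
equally well by the same number of windows and the fitted-ratio estimator is
free of sampling-grid artifacts.

## SPT / MSD

Localization: robust background (median, scaled MAD), local maxima above
background + k·σ (default k = 5) with minimum separation enforced by the
maximum filter, sub-pixel intensity-weighted centroid. Linking: greedy mutual
nearest neighbors between consecutive frames within a maximum displacement,
no gap closing, ambiguous pairs unlinked — adequate because SPT labeling is
sparse (1:20) and collisions rare. The diffusion coefficient is the slope/4
of an ordinary least-squares line through the first 4 points of the time- and
ensemble-averaged MSD, with a free intercept absorbing the static
localization-error term (≈ 4σ_loc² in 2D); a negative slope reports D = 0
with an immobile flag. Synthetic validation tracks are continuously visible —
the imager-exchange photophysics that defeats bleaching in the real tracking
handle is not modeled.

## Benchmark experiment scales

The benchmark two-condition comparison (10× linking-rate ratio) uses 576
monomers on an 8.32 µm periodic patch (matching the 64-pixel field), 24
log-spaced 64-frame windows per condition, and 10 replicates; these problem
sizes were chosen so a full comparison completes on a single desktop core
while leaving enough clusters per field for usable correlation statistics.
Observation spans (1.2 × 10³ s fast, 6 × 10³ s slow) bracket each condition's
decay so the fitted t½ lies inside the sampled range.

## What the synthetic data does and does not show

The generator reproduces: 2D Brownian motion at measured monomer mobility,
connector-dependent linear vs. branching aggregation, the acquisition
geometry and its windowed illumination, shot/read camera noise, and the
rise-then-fall correlation signature of oligomerization followed by
immobilization. It does not reproduce: connector occupancy dynamics and
rebinding, cluster internal flexibility, hydrodynamic coupling between
clusters, membrane heterogeneity or unspecific surface sticking, Mg²⁺-driven
unspecific aggregation, or real camera gain/noise characteristics. Passing
tests therefore demonstrate that the *analysis chain* (correlation statistic,
timescale fit, MSD estimator) faithfully recovers known ground truth under
realistic imaging noise, and that the *simulation* obeys its own stated
kinetics — not that the simulator quantitatively predicts wet-lab assembly
times. Absolute simulated timescales are not comparable to the multi-hour
membrane experiments; only ratios and orderings between conditions are
meaningful, which is how they are used throughout.

## Degenerate inputs and tie-breaks

Zero reading frames is a valid rate (0, no error); empty fields render as
noise-only images; a localization list may be empty; a cluster of one is a
monomer; binding attempts on already-merged clusters within a step are
skipped (first success wins); `phi = 0` sensitivity cells reuse the pure
monomer stream so they are bit-identical to the monomer reference for a given
seed.
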
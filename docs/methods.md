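# Models and methods

## The phantom

A plasmodesma phantom is rendered on a cubic grid (default 128³ voxels at
0.76 nm — the scale of 4×-binned tomograms recorded at 1.9 Å pixels) in a
right-handed nm coordinate system with the channel axis along z through
the lateral box centre. Density is positive (protein/membrane bright);
the CLI can invert to cryo-style dark contrast.

**Membranes.** Every membrane is two Gaussian leaflet shells (σ 1 nm)
separated by 3.5 nm. All diameters are defined and measured
*midline-to-midline* (between the two leaflet midplanes). The plasma
membrane is a composite surface: two face planes on the cytoplasmic sides
of the wall joined by a cylinder of radius `aperture_diameter/2` lining
the channel; the wall fill keeps a 2.75 nm clearance from the PM midline.

**Desmotubule.** A membrane tube whose midline radius follows a piecewise
linear neck → centre → neck profile with 2-nm plateaus at the measurement
stations (10 %, 50 % and 90 % of the pore length), held at the neck value
from the stations out to the apertures. The plateaus make the preset
diameters exact and locally flat at the stations, so a perpendicular
profile measurement with a ±1.5 nm axial window is unbiased; without them
the V-shaped minimum at the centre inflates the measured diameter by the
window half-width times the taper slope.

**Coat.** Subunit sites come from `helical_lattice_points`: `n_starts`
(default 4) intertwined helices phase-offset by 360°/n, each advancing
`axial_rise` (default 1.65 nm) per subunit with `subunits_per_turn`
(default 11) per 360°, i.e. a one-wrap pitch of 18.15 nm and a 4.5 nm
axial separation between adjacent wraps. Rise and subunit count are free
design parameters of the generator (no experimental pitch is available to
match) and are recorded in the ground truth. The default subunit is a
dimer footprint elongated along the helix tangent so consecutive subunits
join into continuous strands — the assemblies read as intertwined wraps,
not beaded rings — with a central hump marking the repeat. Subunit
centres sit 2 nm above the outer DT leaflet (preset coat radius 16 nm for
a 24 nm neck): the assembly is a distinct layer, as it appears in
averages, rather than density buried in the membrane.

**Tethers.** Rod densities from the coat surface to the PM midline with
lengths drawn from a truncated normal (mean 19.8 nm, sd 4.2 nm, upper
bound 26.4 nm, lower bound the radial coat→PM gap — 12 nm in the
`ghl17_proto` preset, so the truncated mean is ≈19.6 nm). Obliquity is
randomized subject to the endpoint lying on the PM midline cylinder. Rod
density stops 3 nm short of the midline so the (unresolvable, flexible)
tether does not blend into the leaflets.

**Sealed apertures.** A sealed side replaces the aperture with a
granulated, callose-like plug (texture parameters are cosmetic): PM and
DT are terminated cytoplasm-proximal to the coat, the face-plane PM stops
outside the plug rim, and Poisson-scattered granules at ~half wall
density fill the former aperture. By construction no membrane-continuous
path crosses the wall slab on a sealed side.

**Imaging model.** Single-axis (y) missing wedge: Fourier coefficients
whose (k_x, k_z) angle falls outside the tilt range (default ±60°) are
zeroed; band-limited white Gaussian noise is added to reach a target
signal-to-noise *power* ratio in the retained region (default SNR 3).
Dose, defocus and CTF are not modelled: at the 3–4 nm resolutions of
interest the CTF's first zero is far away, and a wedge+noise model keeps
every stage analytically checkable. The tilt increment is recorded but
does not shape the transfer function at these box sizes.

Determinism: a (spec, seed) pair renders bit-identical volumes. The
geometry skeleton (wall, membranes, coat lattice) is seed-independent;
only tether draws, sealed-state draws and plug texture consume the RNG.

## Picking geometry

Contours (two points per coating assembly, as in the manual protocol) are
resampled at 1 nm arc-length intervals; each seed's orientation aligns
its z axis with the local tangent, with the in-plane spin φ randomized
from one seeded generator. Euler angles are intrinsic ZXZ with the matrix
`R(φ,θ,ψ) = Rz(ψ)·Rx(θ)·Rz(φ)`, so the particle z axis depends only on
(θ,ψ) and φ is the spin the protocol randomizes. Expansion produces
`n_positions` (default 11) copies on a circle of `radial_shift` (default
6 nm) in the plane normal to the seed axis, each with its z axis radial
and x axis along the tubule. Distance filtering is greedy by descending
score (ties toward the lower particle id): deterministic, idempotent,
always retains the global maximum, and leaves no retained pair closer
than the threshold (default 8 nm). Subvolume extraction takes axis-aligned
cubes (rotations are applied during alignment); boundary particles are
dropped, not padded, because padding biases averages.

## Alignment and averaging

Stage 1 (`constrained_align`): iterative alignment of axis-seeded
particles. The first reference is the unaligned mean of the stack; shifts
are restricted to the plane normal to each particle's z axis (bounded,
default 8 nm); φ is never searched; references are Gaussian-low-passed to
3.75 nm (midpoint of the 3.5–4.0 nm band). Five iterations by default
with early stop when the mean shift step drops below 0.5 voxel.

Stage 2. Pseudo-symmetry expansion samples a helical lattice at azimuths
incommensurate with its start symmetry, so the unaligned expanded average
is smeared along the symmetry direction, and with classification replaced
by score-based selection nothing breaks that symmetry spontaneously. The
pipeline therefore runs `lock_lattice_register`: orientations are *held
at their geometry-derived surface normals* (a strong angular prior, as is
standard for filament and tubule processing) and the one free degree of
freedom on the surface — the register translation along the tubule — is
searched exhaustively (sub-voxel via parabolic interpolation) against a
reference whose cylindrically symmetric component has been subtracted
(featureless-cylinder subtraction) and which is masked to a cylindrical
shell following the coat layer; the shell (rather than a flat slab) keeps
the whole visible azimuth of the patch in play, coupling neighbouring
expansion azimuths and disfavouring alias registers. The iteration starts
from a seeded anchor particle and rebuilds the wedge-compensated average
each round (default 3); because a poorly placed anchor can trap the
register in a mixed-phase state, the whole iteration is a multi-start
optimization over (default) three anchors, keeping the result whose
average carries the strongest helical spectral signal. Averages in this
stage apply a Gaussian apodization (σ 8 nm) along the tubule axis to each
particle's contribution: the register is known only modulo the lattice
period, so aperiodic features (assembly ends) would otherwise ghost at
period multiples and alias into sub-harmonic stripe patterns; the window
keeps ~3.5 lattice periods of coherent signal per particle while
suppressing the ghosts. The reason the general grid search is not used
here: at 48³ boxes/0.76 nm the local refinement granularity (step/5 = 6°)
moves a patch at 16 nm radius by ~1.7 nm — more than half the 4.5 nm
lattice period — which scrambles exactly the register this stage must
find. `exhaustive_align` (global ZXZ grid plus step/5 refinement,
optional orientation prior and reference mask) remains available for
general targets and is verified by rotate-and-recover tests. The lattice
analysis reads the stage-2 average (all ~190 expanded particles); the
distance-filtered set (~20 particles) yields the final deliverable map
and the half-set FSC.

Averaging rotates each cube into the reference frame (trilinear
interpolation; band-limit loss accepted and visible as self-scores ≈0.9),
accumulates Fourier sums, and divides by the summed rotated wedge
coverage (guarded at ≥1; zero-coverage voxels stay 0, the coverage map is
reported). Scores are wedge-intersection, mask-normalized
cross-correlations in [−1, 1]; zero-variance inputs score 0 with a
warning. FSC uses integer-radius shells; the resolution is the linearly
interpolated first crossing of the threshold (default 0.143), with the
Nyquist bound flagged when the curve never crosses.

## Lattice analysis

The average is interpolated on a cylinder about the tubule axis and laid
out as an (azimuth, axial) sheet; out-of-box samples and (for patch
averages) azimuths outside the visible window carry zero weight. The
azimuthal mean of each axial row is removed — membranes and other
azimuthally uniform structure carry no start information — and a 2D
Fourier analysis finds the dominant peak over azimuthal orders 1..max:
its order is the start count and one-wrap pitch = m/|k_z|. Peak
*localization* uses a 4× zero-padded axial spectrum; *confidence* is the
mainlobe energy (unpadded peak bin ± 1 axial neighbour) over the total
non-DC half-spectrum power, because padding splits one physical peak over
~pad bins and would quadruple-count the background against it.
Confidence below 0.1 → `indeterminate` (or `rings` when the m = 0 row
dominates); order ties break toward the lower order with a warning. The
unwrap radius is scanned ±2 nm around the nominal coat radius and the
best-confidence radius reported. On noise-free phantoms the start count
round-trips for n ∈ {1,2,3,4,6} and the pitch is exact to one axial step;
on full pipeline runs (SNR 3) the patch-average estimate recovers the
start count while the pitch is biased by the finite window (~15 % high)
— the start count, not the pitch, is the robust readout at this scale.

## Model fitting

Candidate subunits are bead models (≈1 bead per 15 residues; at 30–40 Å
indistinguishable from full-atom scattering). `simulate_density` renders
normalized Gaussians with σ² = (res/2.355)² + (r_bead/2)², so the voxel
sum equals the total bead weight. `rigid_fit` is an exhaustive coarse
search (global ZXZ grid × FFT translations) followed by Nelder–Mead
refinement of the six rigid parameters; scores below a null-calibrated
0.3 floor are flagged. Candidate screening = simulate each unit, tile it
along the coat lattice with `tile_helical_model`, fit, rank by masked CC
— only a unit that recapitulates the periodic features scores
competitively.

## Morphometrics and statistics

Diameters are read from radial density profiles perpendicular to the
channel axis, averaged over 8 azimuths and a ±1.5 nm axial window.
Desmotubule diameters use the *inner* leaflet peak (sub-sample parabolic
localization) plus half the leaflet separation, because the outer leaflet
is obscured by coat density at the necks; aperture diameters use the
two-leaflet centroid in a ±2.6 nm window. Stations sit at 10/50/90 % of
the pore length between the annotated aperture planes (ground truth plays
the role of the manual annotation; every number is measured from
density). Pore length comes from the axial extent of the PM-lined channel
(clipped-plateau mid-threshold), not the wall slab: a slab perpendicular
to the beam has its axial profile inside the missing wedge, while the
laterally structured membrane cylinder survives it; the fixed 2.75 nm
mouth overhang is subtracted. A residual systematic overestimate of a few
nm remains — harmless for between-condition comparisons and for the
thickness–length correlation, which is the quantity of interest. Tether
spans are measured per ground-truth tether ray: samples are binned by
their true radius about the axis, the radial centroid locates the PM
midline, and that radius is mapped back to an arc position along the
(oblique) ray.

Aperture state: membranes are segmented by smoothing (σ 1 voxel) and a
two-stage Otsu threshold guarded at 0.6× the 99.9th-percentile intensity
(so the split can never drop to wall/callose level), followed by one
binary opening (noise speckle riding on wall density otherwise percolates
under 26-connectivity). A side is `sealed` iff no 26-connected membrane
component joins the cytoplasmic channel mouth to the pore interior. On
the preset batches the classifier is exact at SNR 3.

Group comparisons: two-sided Mann–Whitney–Wilcoxon, exact by full
enumeration of rank assignments (mid-ranks for ties; p = twice the
smaller tail, capped at 1) when n₁+n₂ ≤ 20, otherwise the normal
approximation with tie and continuity corrections. Raw p values, no
multiple-comparison adjustment (pre-planned comparisons against the
wild-type control); medians and 25th/75th ± 1.5 IQR whiskers accompany
every comparison.

## What the phantoms do and do not show

The generator reproduces the *geometry* of the system — the measured
diameter profiles and tether statistics are built in at their reported
means, so parameter-recovery tests validate the measurement chain, not
the biology. It omits CTF, dose fading, membrane undulations, crowding by
other macromolecules, segmentation errors of real membranes, and the
conformational heterogeneity of real coats; passing tests therefore show
that the algorithms are correct and unbiased at realistic noise and wedge
levels, not that they would reach the same precision on experimental
tomograms. Real-data resolutions (FSC₀.₁₄₃ ≈ 33 Å for the deposited
coat average) are not reproducible at this scale and are not targeted.

## Problem sizes

Default desk-scale runs: 128³ phantoms; ~190 expanded particles at 48³
for the averaging demonstration; 20-phantom batches for parameter
recovery; 33 apertures (17 phantoms) for the sealed-proportion check; a
full pipeline run takes ~25 s and the whole test suite minutes on one
CPU.
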
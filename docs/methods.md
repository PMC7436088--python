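# Methods

`memprobe` asks a narrow question with several complementary readouts: does
inserting a 3-hydroxyflavone (ESIPT) probe into a model membrane perturb the
bilayer? The package does not run molecular dynamics — trajectories and
binding energies are inputs — but implements every analysis layered on top
of them, plus generators that emulate those inputs with known ground truth.

## Coordinate conventions and data model

All geometry assumes a planar bilayer whose normal is the z axis; readers
and generators orient membranes accordingly and no normal estimation is
attempted. Periodicity is applied in x and y only (minimum-image on the box
edges); z is treated as non-periodic, since the bilayer spans it. Frames
carry coordinates in Angstrom, times in nanoseconds, and an orthorhombic
box. Multi-model PDB is the only structure format, read and written through
MDAnalysis; when a file lacks a usable CRYST1 record the box falls back to
the axis-aligned bounding extents. Acyl carbons are numbered 1-based from
the carbonyl carbon, which places the oleoyl double bond at carbon 9.

## Leaflets, thickness, area per lipid

Leaflets are split at the mean phosphorus z of all phospholipids; a P
exactly on the midplane goes to the lower leaflet (deterministic tie rule,
logged as a warning when the split degenerates). Thickness is the
difference of mean P z between leaflets — the P-P definition commonly used
to validate bilayer simulations (~37 A for fluid POPC, ~46 A for
DPPC:Chol). Area per lipid is Lx*Ly divided by the phospholipid count,
computed per leaflet and averaged so asymmetric leaflets are tolerated.
Cholesterol never enters the denominator; when its mole fraction exceeds
20% the conventional correction is applied as a reported range (80-90% of
the raw value), not a point estimate, because only a range rule exists.
Aggregates over analysis frames use sample (ddof=1) standard deviations,
zero for a single frame.

## Analysis window

Trajectories are restricted to the frames nearest an even grid over their
final window — by default the last 5 ns sampled at 11 points including
both endpoints, so a 15 ns trajectory written every 0.5 ns contributes
frames at 10.0, 10.5, ..., 15.0 ns. Nearest-to-grid matching (earlier
frame on ties) keeps the selection robust to uneven writer cadence; when
the grid is finer than the cadence, duplicates are kept so the output
count always equals the request.

## Deuterium order parameters

The instantaneous order parameter of a C-H (C-D) bond is
S = (3 cos^2(theta) - 1)/2 with theta measured against the bilayer normal.
Profiles average over both bonds of each CH2, all selected lipids and all
frames in scope, and report |S_CD| — the plotting convention under which
plateau carbons sit near 0.2-0.4 and the disordered terminal methyl
approaches zero — while the signed mean is retained alongside.

Near-probe profiles re-select lipids *every frame* as those with any atom
within the cutoff (default 5 A) of any probe atom; only chain-bearing
phospholipids are selectable, so cholesterol never contributes letters.
Selection equals a brute-force all-pairs distance scan with xy minimum
image; this equivalence is enforced by test.

When a structure has no hydrogens, C-H vectors are reconstructed from the
carbon skeleton: for a CH2, two unit vectors at tetrahedral geometry in
the plane spanned by the backbone-angle bisector and the backbone-plane
normal (for locally straight chains, where that plane is undefined, a
deterministic perpendicular pair); for an sp2 double-bond carbon, one
in-plane bisector vector, flagged in the output; for the terminal methyl,
three vectors on the tetrahedral cone around the last C-C direction.
Chain ends use the one available neighbour to define the local direction,
and at least three carbons are required. Reconstruction reproduces
explicit hydrogens placed by the same ideal geometry to machine precision,
which is how the dual path is cross-validated.

Per-frame (rather than window-averaged) profiles are the default input to
string encoding, giving one string per frame; window averaging remains
available through the same function by passing all frames at once.

## Pseudo-semantic fluidity analysis

Each per-frame profile pair (sn-1 then sn-2, carbons ascending, per-carbon
SCD averaged across the selected lipids) is encoded one letter per carbon
using uniform bins — by default 26 letters spanning |S_CD| in [0, 0.52],
i.e. 0.02 per letter, which covers observed order parameters at useful
resolution. The top edge maps to the last letter; out-of-range values
clamp with a warning. Encoding is monotone: raising every value by a bin
width shifts every letter strictly later.

Strings are compared through the Szymkiewicz-Simpson overlap coefficient
|A∩B| / min(|A|, |B|) of their k-mer sets, k = 2..8 pooled into one set
per string by default (per-k averaging is available, since either pooling
is defensible). Distance is 1 - similarity: zero for identical strings,
one for disjoint alphabets. The overlap distance is *not* a metric — the
triangle inequality can fail — which is fine for t-SNE and silhouettes,
both of which only require dissimilarities. An optional pre-step removes
exact duplicate strings before comparison; it is off by default because
no finer redundancy rule is defined. The 2-D embedding runs t-SNE on the
precomputed distances (seed 42, perplexity 10 by default — suited to the
~66 items of a six-system run) and is deterministic for a fixed seed.
Cluster structure is quantified as the mean silhouette on the
pseudo-semantic distances, grouped by membrane composition (POPC vs
DPPC-Chol) by default, since that is the grouping at which the Lo/Ld
contrast is claimed.

## Binding-energy comparison

Energies arrive as per-frame CSV series; the package never computes them.
Two systems are compared with Welch's unequal-variance t-test
(Welch-Satterthwaite degrees of freedom, two-sided), the safe default when
fluctuation magnitudes differ between membranes. The significance rule is
the ">98% confidence" convention: significant iff 1 - p strictly exceeds
the threshold (default 0.98). Under the null this rejects at rate 0.02,
verified by simulation at n = 11 per arm.

## Dual-band ratiometry

The probe emits from two excited states: N* (shorter wavelengths,
polarity-sensitive) and the proton-transfer tautomer T* (longer
wavelengths, largely polarity-indifferent); the peak-intensity ratio
I_N*/I_T* reads out local polarity. Spectra are smoothed with a 5-point
moving average before peak picking; each band is the highest local maximum
strictly inside its window, ties resolved toward the shorter wavelength
(with a small float tolerance so smoothing round-off cannot flip an exact
tie). Default windows are N* = 460-540 nm and T* = 545-650 nm, bracketing
the observed N* span (~475-551 nm across solvents) and the two confocal
detection channels (477-527 and 550-600 nm). If the T* window holds no
interior maximum the spectrum is flagged single-band — the protic-solvent
case where the red-shifted N* band swallows T* near 520 nm — and no ratio
is reported.

For image pairs, the membrane mask keeps pixels whose summed two-channel
intensity exceeds a fraction (default 0.2) of the pair's maximum — a
scheme invariant to common rescaling that isolates the bright annulus of
an equatorial vesicle section without ring fitting. The per-pixel N/T
ratio is reported as a map and as the mask mean; T-channel zeros inside
the mask are excluded and counted. Both the map and the mean are reported
because either spatial reduction is defensible.

## Synthetic data: what it emulates, what it does not

Generators exist to give every analysis a ground truth, not to replace
MD. A bilayer spec prescribes the P-P thickness, box area, cholesterol
fraction, per-carbon |S_CD| targets per chain, and an optional probe; the
generator then builds two leaflets of lipids on a jittered grid
(P plane roughness sigma_z = 0.5 A, lateral jitter 0.4 A per frame),
kinematic stick-model chains tilted into the membrane, an 18-carbon probe
anchored 1.5 A beneath the upper P plane, and interleaved cholesterol
sticks. Explicit C-H orientations are sampled from a Beta-parameterised
tilt distribution whose mean equals the target exactly, so measured
profiles converge to the prescription at Monte-Carlo rate (within 0.01
per carbon above ~10^4 bond samples). A target above the geometric
maximum of 0.5 is rejected.

Two presets define the study conditions. "POPC-like" (Ld): 37.3 A
thickness, 64 A box with 64 lipids per leaflet (A_l = 64 A^2), a ~0.2
plateau with a sharp dip at the C9=C10 double bond and decay to ~0.03 at
the terminal methyl. "DPPC-Chol-like" (Lo): 45.9 A, 30% cholesterol
(hence a reported A_l correction range), a ~0.37 plateau. Preset profiles
are prescribed at two-decimal values centred in the default letter bins:
a mid-bin prescription is the only one whose encoding is stable, whereas
a bin-edge value would dither between two letters every frame regardless
of how small the noise is. The per-bond orientation spread
(Beta concentration 60, instantaneous-SCD sd ~0.08 at the plateau) then
makes consecutive frames differ by a few letters — tight but
non-degenerate clusters per system, the regime the method is meant to
resolve. Default cadence is 31 frames over 0-15 ns so the default
analysis window reproduces the 11-frame, last-5-ns convention.

What the generator does *not* emulate: excluded volume, torsional
statistics, lipid diffusion and flip-flop, water and ions, force-field
energetics, or any coupling between probe and lipid order. Passing tests
therefore demonstrate that the analysis chain measures what it claims on
inputs with known answers — not that a real membrane behaves this way,
and not the absolute values any particular force field would produce.
Energy series are plain Gaussians (the preset means encode the
expectation that N* binds the fluid membrane better and T* the ordered
one); spectra are Gaussian sums; vesicle images are noisy annuli with a
uniform true ratio on the ring.

## Numerical choices and degenerate inputs

- Thickness/A_l raise on an empty leaflet; the leaflet splitter itself
  only warns, so callers that need the split can proceed.
- SCD of a zero vector, empty selections (named with the offending
  frame), strings shorter than k_min, empty k-mer sets, perplexity >= n,
  single-group silhouettes, zero-variance equal-mean energy pairs, empty
  image masks: all raise typed errors rather than returning NaN.
- Letter binning uses floor((s - low)/width) with the top edge assigned
  to the last letter.
- Sample SDs use ddof=1; single frames report SD 0.
- t-SNE runs single-threaded with a fixed seed, so repeated runs of the
  same config are byte-identical (hashes recorded in the run manifest).

## Problem sizes

Tests and the acceptance script run entirely on synthetic systems:
presets at 64 lipids per leaflet (12,564 atoms with the probe) for
pipeline runs, 460 per leaflet for profile-recovery statistics
(~10^4 bond samples per carbon), 1,000 replicates for the Welch
calibration, and 128x128-pixel image fixtures. A full six-system run
completes in a few seconds on one core.

## Known limitations

- The letter-encoding granularity interacts with measurement noise:
  profiles hovering at bin edges encode unstably. Real applications
  should choose bin width against the per-frame standard error of their
  SCD estimates.
- The overlap distance ignores *where* in the chain a k-mer occurs; two
  profiles with the same motifs in different carbon ranges can look
  similar. The paper-scale string lengths (30-34 letters) keep this
  mostly harmless, but it is inherent to the representation.
- Near-probe profiles with very few selected lipids are noisy; the
  package reports n_lipids_used so downstream users can judge.
- C-H reconstruction assumes ideal tetrahedral/sp2 geometry and is
  exact only in that idealisation.
- PDB coordinates carry three decimals, bounding round-trip fidelity at
  10^-3 A.
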
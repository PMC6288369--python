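# Methods

`filamech` analyses ensembles of actin-filament conformations (one
representative point per residue, one chain per subunit, one PDB MODEL per
frame) and one-dimensional meridional diffraction profiles.  Because real
trajectories and beamline recordings are not reproducible at desk scale,
the package ships generators that produce both kinds of input with known
ground truth; every estimator is validated by recovering what the
generator injected.

## Filament model

A filament is `n_subunits` copies of a 375-residue monomer arranged on the
genetic (one-start) helix: per-subunit axial rise `h` (default 27.5 Å) and
signed twist `φ` (default −166.7°, left-handed).  Subunits alternate
between the two long-pitch strands; the strand neighbour of subunit `i` is
`i+2` (longitudinal contacts), the cross-strand neighbour is `i+1`
(lateral contact).  The subunit centre of geometry sits at `radius`
(default 25 Å) from the axis.

The template monomer is synthetic: residues scattered inside an ellipsoid
of semi-axes (28, 28, 18) Å, with two sets of deliberate placements.
Residues of the four rigid subgroups SG1–SG4 occupy distinct lobes so the
coarse-grained shape parameters take actin-like values, and the residues
of the contact registry are placed at the axial faces of the monomer so
that every registry pair distance in the assembled ideal filament lands in
(5, 30) Å (measured: ~23–27 Å over many seeds).  The template is
deterministic in its seed.

## Bending-fluctuation ensemble

Frames are drawn as a discrete wormlike chain.  The ideal filament is cut
into rigid segments of two subunits (one strand step, length `L = 2h`);
at each joint two transverse angle components are drawn i.i.d. normal
with variance `L/Lp`, giving the 3-D small-angle statistic
`⟨θ²⟩ = 2L/Lp`, with uniform azimuth.  Bends accumulate from the filament
base, so tangent correlations decay as `exp(−s/Lp)`.  Per-residue Gaussian
jitter (default 0.5 Å) makes the contact/geometry SD columns non-zero.
The generator refuses persistence lengths so small that the RMS joint bend
exceeds 30° (outside the small-angle regime).  The mean squared
end-to-end distance of the segment chain reproduces the Kratky–Porod
formula within Monte-Carlo error for Lp between 1 and 20 μm.

What the generator does **not** emulate: torsional fluctuations,
subunit-internal conformational changes correlated along the filament,
force- or ligand-dependent structural states, and anharmonic bending.  A
green recovery test therefore establishes the correctness of the
estimators on harmonically bending filaments, not agreement with any
particular experimental trajectory.

## Contact distances and coarse-grained geometry

Contact distances are Euclidean distances between single residue points
(the package's representative-point convention; atom-level minimum
distances are out of scope).  The default registry holds eight
longitudinal pairs (D-loop/C-terminus, D-loop/SD1, D-loop/SD3, SD4/SD3)
and one lateral pair (H-plug/C-terminus).

Each subunit is coarse-grained into the centres of geometry R1–R4 of the
rigid subgroups SG1 (residues 5–33, 80–147, 334–349), SG2 (34–39, 52–69),
SG3 (148–179, 273–333) and SG4 (180–219, 252–262); the COG is unweighted.
Shape is summarised by bonds R1–R2, R1–R3, R3–R4, interior angles R1–R3–R4
and R2–R1–R3, and the signed torsion of the ordered quadruple R2–R1–R3–R4,
reported in (−180°, 180°] with the standard right-handed convention (the
sign flips under reflection; a collinear triple flags the dihedral as
undefined instead of raising).

Averaging convention: subunits within a frame are exchangeable replicates
and are averaged first; the resulting per-frame series carries the time
correlation and is fed to block averaging for the SD column.  Edge
subunits without the required neighbour are skipped, not padded.

## Helix fit, twist/rise, crossover

Per frame, the filament axis is the least-squares cylinder axis through
the subunit COGs.  The fit runs in a canonical data-derived frame
(principal direction oriented along subunit order, in-plane direction from
the first subunit) and is polished to machine-precision stationarity with
analytic-Jacobian Gauss–Newton steps; this makes twist, rise and crossover
reproducible to ~1e-9 under arbitrary rigid motions, which matters because
the crossover formula amplifies twist noise about thirtyfold.  Twist is
the mean wrapped azimuth increment between consecutive subunits about the
axis (axis oriented so rise > 0; a left-handed filament keeps a negative
twist from either end, since handedness does not depend on traversal
direction).  The crossover length — the axial distance between successive
apparent crossings of the two long-pitch strands — is

    crossover = 180° / |wrap(2φ)| × 2h,

with `wrap` mapping to (−180°, 180°]; `wrap(2φ) = 0` (perfectly untwisted
strands) is reported as an infinite crossover, not an error.

## Persistence length

Tangents are chords between centerline points taken at strand-step (two
subunit) spacing: the midpoint of a subunit pair's COGs.  The estimator
fits `−ln⟨cos θ(s)⟩ = s/Lp` through the origin, pooling over frames, with
two discretisation corrections that measurement on this geometry requires:

1. **Chord half-step.** Consecutive-chord correlations over a hinged chain
   sample an effective contour separation of `(lag − ½)` segments, not
   `lag` segments, so the fit uses `s_eff = (lag − ½) L`.
2. **Rigid-geometry signature.** Pair midpoints sit ~3 Å off the helix
   axis because the genetic twist does not cancel exactly over two
   subunits; even a rigid filament therefore shows a deterministic,
   lag-dependent chord decorrelation.  That signature, computed by running
   the same tangent machinery on the frame-mean structure, is subtracted
   before fitting.

Without these corrections the estimate is biased by +17% at Lp = 1 μm and
−30% at Lp = 20 μm; with them, recovery is within ~2% across 1–20 μm at
2000 frames.  The SD is the spread of per-block estimates over 10
contiguous frame blocks (it shrinks as 1/√n_frames); a fitted slope below
1e−13 Å⁻¹ (Lp beyond ~1 km, pure float noise) is reported as infinite —
a lower bound, not an estimate.  Flexural rigidity is `κ = Lp·kB·T` at
T = 310 K by default.

## Block averaging and group comparison

`block_average` cuts a series into contiguous blocks and reports the SD of
block means.  In auto mode the block size doubles from 1 until the implied
standard error of the mean (`block SD / √n_blocks`) changes by less than
10% across two successive doublings, or fewer than four blocks remain;
the plateau flag records which.  The SE — not the block SD itself, which
decays like 1/√b indefinitely — is the quantity that plateaus, and on
AR(1) test series it matches the analytic standard error within 15%.

`compare_groups` applies a Kolmogorov–Smirnov normality check to each
sample against a normal with the sample's own mean and SD; if either
p-value is below 0.05 the two-sided Mann-Whitney rank-sum test is used,
otherwise the unpaired two-sample t-test.  No multiple-testing correction
is applied.  Note the KS test with fitted parameters is conservative
(Lilliefors situation); the gate is deliberately specified this way rather
than tuned.

## Diffraction analysis

Exposures are summed pixel-wise per state (SNR grows as √n).  The
background is a straight line fitted to the flanks outside ±10 px of the
observed maximum and subtracted everywhere.  The reflection is fitted by
an unconstrained 3-parameter Gaussian restricted to ±3 or ±4 px around the
observed maximum; divergence, a centre escaping the window, or a fitted
width below 0.3 px (unresolvable on the pixel grid) yield a failure record
rather than an exception.

Pixel radius maps to axial spacing by the small-angle relation
`d = λ·L_camera / (r_px · pixel_size)`; defaults λ = 0.1 nm,
L_camera = 3.47 m, pixel 0.05 mm (the pixel size is a free parameter, not
a calibrated value).  The percent spacing change between activated and
relaxed states is `(d_act − d_rel)/d_rel × 100`, positive = filament
extension; the generator moves the activated peak to a smaller pixel
radius for a positive injected shift, consistent with `d ∝ 1/r`.  The
percentage is reported in d-spacing, not in pixel shift; at the ~0.3%
scale of interest the two conventions differ only in the third decimal.
The meridian origin is a configuration input (pixel 0 for synthetic
profiles, recorded in each profile header).

## Defaults of the two-group study

The default configuration simulates a compliant "WT" group
(Lp = 9.8 μm, activation spacing change +0.34%) and a stiffer "MUT" group
(Lp = 17.2 μm, +0.16%), 2000 frames and 25 exposure pairs each at a
1 ns frame interval — values chosen to match published reference
measurements on skeletal-muscle thin filaments (stored for annotation in
`mechanics.REFERENCE_VALUES`).  TN3-like peak: centre 538 px, σ = 2 px,
amplitude 1e4 counts on a (300, −0.2) linear background with Poisson
noise.  All generators are deterministic in the run seed; per-group,
per-stage seeds are derived from it and recorded in the manifest.

## Known limitations

- Absolute reproduction of published contact/geometry tables or Lp /
  crossover values is out of scope: the source trajectories are not
  available, and the published tables' distance convention (residue COG
  vs closest atom) is unstated.
- No torsional stiffness, no Fourier-mode bending analysis (a possible
  future alternative estimator), no 2-D detector reduction, no layer-line
  analysis.
- The ±3/±4 px window pair mirrors standard practice for meridional
  reflections; on well-resolved synthetic peaks the two windows agree
  within their fit uncertainties, and both are always reported.
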
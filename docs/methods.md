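# Methods

## Helical-parameter model

Every base is assigned a right-handed orthonormal reference frame (origin
at the pairing centre, x toward the major groove, y toward the strand-I
backbone, z along the helix axis for a strand-I base) by least-squares
rigid superposition (Kabsch/SVD) of an embedded standard base geometry
onto the observed ring atoms.  Only ring atoms enter the fit, so C, mC,
hmC and ahyC are analysed identically at the frame level and all
side-chain effects are isolated in the contact module.  Because base rings
are planar, the smallest singular value of the covariance is ~0 and the
SVD sign correction is applied there; a genuinely three-dimensional
reflection (chirality violation) still raises an error.

Intra-base-pair parameters are obtained after negating the y and z axes of
the strand-II frame (antiparallel convention); the rotation from the
flipped strand-II frame to the strand-I frame is factored as

    R = Rz(ω/2 − φ) · Ry(Γ) · Rz(ω/2 + φ)

with ω the twist-like angle (opening), Γ the bend magnitude and φ the
hinge phase, giving propeller = Γ cos φ and buckle = Γ sin φ; translations
expressed in the mid frame give shear/stretch/stagger.  The identical
factorisation between consecutive base-pair mid-frames gives the six step
parameters (twist, roll = Γ cos φ, tilt = Γ sin φ; shift/slide/rise in the
mid-step triad).  This is the mid-step-triad (CEHS) convention of the 3DNA
lineage.  When ω leaves (−180°, 180°] the 2π reduction is absorbed by a π
shift of φ, which flips the signs of roll and tilt — the standard
behaviour of this convention.  Γ → 180° makes the hinge direction
ill-defined; such steps raise an explicit error rather than returning a
sign-ambiguous value, because silent ambiguity would corrupt SD
statistics.

`compose_step`/`compose_pair` are closed-form inverses of the
decompositions, and `rebuild_duplex` places standard-geometry bases from
parameters, so analyse(rebuild(p)) = p to machine precision.  The tests
exploit this for 500-draw round-trip checks over B-DNA-plausible ranges
(twist 25–45°, rise 2.8–4.0 Å, |roll|, |tilt| ≤ 15°, |shift|, |slide| ≤ 2 Å),
rigid-motion invariance at 1e-9, and the strand-flip symmetry (shift and
tilt negate, slide/rise/roll/twist are preserved when the duplex is read
from the opposite strand).

The convention is pinned operationally by these properties, not by
bit-compatibility with any external binary; when comparing against output
of other helical-parameter software a tolerance of 0.5° / 0.05 Å is
appropriate (PDB coordinate quantisation alone contributes ~0.02°).

## Groove widths and rebuilt backbones

Groove widths are cross-strand phosphate–phosphate distances minus a 5.8 Å
van der Waals correction, at fixed offsets: major groove P(I, i)–P(II, i−4),
minor groove P(I, i)–P(II, i+3).  Rebuilt models carry a minimal backbone
(P, O5′, C1′).  The phosphorus is placed at a fixed vector in the base-pair
frame — radius 9.0 Å, azimuth 71°, in the bp plane — solved so that an
ideal B-DNA duplex (twist 36°, rise 3.4 Å) reproduces the canonical P–P
distances (≈17.4 Å major, ≈11.5 Å minor, i.e. widths ≈11.6 / 5.7 Å).
5′-terminal residues carry no phosphate, so terminal positions are
undefined (NaN), as are positions whose cross-strand partner falls outside
the duplex; a 4-bp duplex has no defined width at all.  The refined
curvilinear-axis groove method is deliberately out of scope: the simple
fixed-offset method is fully testable against the ideal-fibre geometry.

## Side-chain geometry

The 6-azidohex-2-ynyl chain (C5–CH₂–C≡C–CH₂–CH₂–CH₂–N₃) is built by
internal coordinates with standard bond lengths (sp³ C–C 1.53 Å, sp³–sp
1.47 Å, C≡C 1.20 Å, C–N 1.47 Å, azide N–N 1.24/1.13 Å), tetrahedral sp³
angles, linear alkyne and azide units, a 115° C–N=N angle, and all-anti
torsions.  The torsion about the linear CH₂–C≡C–CH₂ segment is left
undefined by those rules; the "maximally extended" length maximises the
C5→terminal-N distance over that free rotation (the terminal atom traces a
circle, so the maximum is closed-form), giving 10.55 Å — comfortably
within the ~12 Å scale expected for a chain of this composition.  The
methyl stand-in for mC/hmC is a single 1.53 Å bond.

## Synthetic ensemble generator

The generator emulates the statistical structure the analyses assume of a
duplex MD ensemble, with no physics:

* **Baseline fluctuations.**  Per frame, step parameters are independent
  Gaussians with B-DNA-like means (twist 34.3°, rise 3.35 Å, others 0) and
  SDs (roll 5.5°, tilt 3.5°, twist 4.5°, shift 0.4 Å, slide 0.4 Å, rise
  0.25 Å); intra-bp parameters likewise (propeller mean −12°, SDs:
  buckle/propeller 8°, opening 4°, shear 0.25 Å, stretch 0.12 Å, stagger
  0.35 Å).  Only SD *ratios* between fragments matter to any statistic in
  scope, so absolute levels are free parameters exposed in the config.
* **Modification effect.**  At modified-site windows (the CpG ± 1 bp;
  steps p−1…p+1 for a modified C at p) the roll/twist/slide SDs are
  multiplied by `site_sd_multiplier`: 1.5 for ahyC fragments, 0.8 for mC,
  1.0 for the control in the six-fragment reference set built on the 25-bp
  top strand 5′-GCTCTCTCGAAGCAACGAGAACAGT (CpG sites at 8 and 16;
  fragments C, mCx4, ahyCx4, ahyCx2, ahyCx1(8), ahyCx1(16)).  The
  multipliers are calibration choices for the planted-effect suites, not
  measured values.
* **Contact model.**  Each azide side chain carries a two-state
  ("touch"/"no touch") Markov chain with stationary touch probability
  p_touch = 0.554 and mean touch dwell 9 frames.  The default p_touch
  makes four independent sites yield an any-touch fraction
  1 − (1 − p)⁴ = 0.96, the regime where ~96% of frames show at least one
  azide–DNA contact; the dwell default corresponds to ~0.1 ns at a ~11 ps
  frame stride.  When a requested (p, dwell) pair is infeasible (the
  no-touch exit rate would exceed 1), the dwell is lengthened to the
  feasibility bound and the stationary probability is honoured exactly.
  While touching, the site's window steps gain mean shifts (defaults:
  roll +4°, twist +3°, slide +0.3 Å) and its terminal azide N is placed at
  a distance drawn uniformly from (2.5, 4.5) Å; otherwise (4.5, 9.0) Å.
* **Defaults 9001 frames × 5 replicas** mirror the ensemble sizes the
  analyses are designed around; replica streams are spawned
  deterministically from the master seed, and identical configs reproduce
  byte-identical output.

Fast mode emits parameter tables and distance series directly.  Coordinate
mode additionally rebuilds atomic models per frame and repositions each
azide tail for its latent state: a touching tip is placed at the drawn
distance from the nearest eligible atom, a non-touching tip is pushed
outward along the base's C5 direction by bisection until its actual
minimum eligible-atom distance equals the draw (re-settled iteratively if
a later placement spoils the clearance), and the intermediate tail atoms
are laid synthetically along the C5→tip line.  The latent truth therefore
agrees with the geometry exactly: a frame is flagged touching iff the tip
really is within 4.5 Å of an eligible atom.

What the generator does **not** emulate: inter-step and temporal
correlations of the helical parameters (draws are independent per step and
frame, except through the touch chain), sequence-dependent baseline
stiffness, backbone/sugar degrees of freedom, solvent and ions, and any
energetic coupling between neighbouring side chains.  Passing the
planted-effect suites therefore demonstrates that the *analysis stages*
are correct and calibrated, not that real modified DNA behaves this way.

## Statistics

* SDs use the sample (n−1) convention throughout — the replica counts are
  small.
* The ANOVA unit of observation is one SD per replica × window step
  (5 × 6 = 30 per fragment at the defaults); a `pool_replicas` flag
  averages window steps within a replica first (one observation per
  replica) for the stricter reading.  Both windows are pooled into one
  test by default; analysing them separately is a flag away.
* All fragments are sampled at the *same* window positions, including
  unmodified controls, so position is never confounded with modification
  status.
* The one-way ANOVA F and p come from the classical fixed-effects
  decomposition (computed via scipy); the degenerate all-constant case
  returns F = 0 with a warning.  Reports annotate significance at the
  0.1 (*) and 0.05 (**) levels, and emit both the joint test and each
  fragment-vs-control contrast, since either contrast convention is
  defensible.  No multiple-testing correction is applied; all
  parameter-wise p-values are reported.
* Contact classification uses strictly-less-than 4.5 Å; a distance of
  exactly 4.5 Å is "no touch".  Eligible atoms are heavy atoms of both
  strands excluding the querying side chain's own atoms (its own base ring
  included, so self-contacts of the tail with its cytosine count).
  Interaction frequencies count every under-threshold residue per frame
  (cumulative, not exclusive, attribution).
* The random-split control partitions the identical frame set into groups
  of the observed sizes uniformly at random (seeded); across repeated
  splits the per-step mean-difference z-scores are standard normal, which
  the acceptance suite verifies by a KS test.
* The nucleosome-reference SD is the spatial sample SD of each parameter
  across the steps of a single continuous structure; discontinuities
  (consecutive bp origins > 10 Å apart) are reported as errors with the
  breakpoints listed.

## Problem sizes in the validation suites

The planted-effect suites run at 5 replicas × 2000 frames (ANOVA power:
≥ 90/100 seeded repetitions rejecting at 0.05 under multiplier 1.5; null
calibration: rejection rate within the binomial 99% band [0.01, 0.10] over
200 repetitions at multiplier 1.0) and 1 × 10 000 frames for contact
conditioning (the +4° planted roll shift recovered within 3 SE,
sign-correct, in ≥ 95/100 repetitions).  These sizes give the statistical
power the checks need while keeping the whole suite at desk scale;
coordinate-mode checks (exact parameter recovery, latent-truth/geometry
agreement) run on 10-frame ensembles since they are exact rather than
statistical.

## Known limitations

* The geometric convention is validated by internal consistency and
  published-geometry checks, not by numerical identity with any specific
  external implementation.
* Rebuilt models are fibre-style (minimal backbone, idealised sugars);
  they support every statistic in scope but are not refined structures.
* Coordinate-mode azide tails are synthetic layouts (tip placement honours
  the contact state; intermediate atoms are colinear), adequate for
  contact classification but not for stereochemical analysis.
* No mixed-effects or autocorrelation-aware inference: with temporally
  correlated real MD data the ANOVA p-values would be anti-conservative,
  and the replica×step observation unit assumes window steps fluctuate
  independently.
* hmC annotations are accepted and carried through but receive no special
  geometric treatment beyond the methyl stand-in.
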
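# Methods

This note documents the models, numerical choices and synthetic-data design
behind phycokit, in the package's own terms.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Sequence catalogue

**Maturation.**  Candidate α-subunit translations are kept when they contain
the conserved motif `AP` + 9–10 residues + `C` (the chromophore-binding Cys);
a 10-residue spacer is the signature of the *open*-form single-residue
insertion just before the Cys.  The mature protein is released by cleaving
after the second Ala of an `A-x-A` site.  When a precursor offers several
sites, the one leaving the fewest N-terminal residues ahead of the reference
frame start is chosen, preferring cleavage at or before the motif; nothing in
the underlying biology distinguishes the sites otherwise, so minimal
extension is the package's documented tie-break.  Precursors without any
`A-x-A` (e.g. a non-canonical SFS site called by an external predictor) are
returned whole and flagged `no_AxA_site`; an explicit `override_site`
reproduces a predictor-called cleavage.

**Deduplication.**  Reads whose mature regions are identical up to
X-ambiguity and truncation are grouped (union-find over pairwise wildcard
containment) and the most complete read wins: longest, then fewest X, then
smallest id.  Reads containing two copies of the motif are concatenation
artefacts: flagged `tandem_read` and excluded from grouping.

**Form classification.**  Queries are aligned pairwise to a packaged
closed-form reference (BLOSUM62, gap open −11 / extend −1, free end gaps);
only column-relative insertion positions are needed, so pairwise global
alignment replaces a multiple alignment.  *open* ⇔ the motif spacer has 10
residues; *open-braced* ⇔ additionally an insertion of 5–8 residues
(configurable window, canonical length 7) falls in the annotated span between
strand S2 and helix H1.  Insertions shorter than 5 residues in that span
leave the form *open* — the window's lower edge is a configurable guess, as
natural sequences with smaller insertions in this region remain open.
Queries whose alignment score falls below 40 % of the reference self-score,
or with no alignable chromophore Cys, are `unclassified`.

The packaged reference frame and the 22-sequence test set are **synthetic
constructions**, generated deterministically with the published composition
(8 closed, 11 open, 3 open-braced, plus cross-strain duplicates, truncated
and X-ambiguated copies, one tandem read and one SFS precursor); they are
stand-ins, not database sequences.

**Masses.**  Average (not monoisotopic) masses throughout, since the bilin
chromophore increment (586.7 Da per phycoerythrobilin) is an average mass;
methionine oxidation ladders add 16.0 Da each.  Ambiguous residues make a
mass undefined and raise with the offending positions.

## Chromatogram deconvolution

The peak model `f(x) = (A/π)(Γ/2)/(|x−a|^{2+ε} + (Γ/2)²)` is evaluated
literally on numeric mL values.  For ε ≠ 0 the two denominator terms carry
different implied units; the model is used as a fitting form, not a physical
law, and x is non-dimensionalised only by the mL convention.

**Fitting.**  Trust-region least squares (`scipy.optimize.least_squares`,
`trf`) with bounds Γ > 0, A > 0, ε ∈ (−1, 3); initial position at the window
argmax, width from an FWHM estimate, ε = 0.  A constant baseline is co-fitted
by default (real traces have one); recovery studies on baseline-free
synthetic data fit the generating model with the baseline disabled.
Parameter covariance comes from the Gauss–Newton approximation at the
solution; areas are adaptive quadrature of the fitted model over the stated
window only.  Non-convergence raises with the last iterate and residual norm.

**Saturation rescue.**  Detector clipping produces a plateau of identical
values; saturation is only declared when ≥ 3 samples tie the channel maximum,
so unclipped traces pass through bit-identical.  The flagged samples are
replaced by the 280 nm channel scaled by a least-squares factor fitted on a
user-stated linear region — restricted to samples with ≥ 10 % of the region's
peak reference signal, because baseline-only samples attenuate the slope
(errors-in-variables) — with the factor's standard error recorded.  This
replaces by-eye matching with a quantified equivalent.

**Abundances.**  Total signal = ∫pink₅₆₀ + (7/8)·∫purple₅₆₀ (trapezoid on the
raw traces); each named peak's fitted window area (purple also 7/8-scaled) is
divided by this total.  Named fractions plus the residual sum to one by
construction.  The residual is raw signal outside named windows; unnamed
peaks within a colour fraction are that fraction's residual, which is how
spectrotype totals (and the ≈5:1:1 ratio) are assembled.

## Spectra and energetics

Replicate absorption spectra are interpolated onto the first grid, averaged
pointwise and normalised (unit area by trapezoid, or unit max).  EEMs are
collapsed by summation over the excitation axis *first*; the Rayleigh line is
then removed from the collapsed spectrum by fitting `c·λⁿ` (nonlinear least
squares, log–log line as the initial guess, exponent unconstrained) to
samples outside user-stated fluorescence-band exclusion intervals, and
subtracting it everywhere.  Signed residuals are kept unless clipping is
requested.  Peak positions are local maxima refined by three-point parabolic
interpolation; the reported uncertainty is never smaller than the grid
spacing, matching ±1–2 nm instrument-grid reporting.

The overlap integral J uses the union grid of donor and acceptor on their
common support, with the donor re-normalised internally (J is invariant to
donor scaling and linear in the acceptor).  R₀ uses the CGS-derived prefactor
0.211 Å with J in M⁻¹cm⁻¹nm⁴; κ² defaults to 2/3 (isotropic), refractive
index 1.4, donor quantum yield 0.5 — all overridable, since the exact values
behind any given transfer estimate are system-specific.  The 50 %-efficiency
statement is verified as the identity E(R₀) = 1/2, not as a distance in nm.
`proteins_across_lumen` returns the inclusive (floor, round) range of
width/diameter, minimum 1.

## Chromophore geometry

Ring planes are total-least-squares planes (smallest principal direction of
the centred coordinates); degenerate (collinear) inputs raise.  The dihedral
descriptor per outer ring is (θ_inner, θ_outer): angles between the central
ring plane, the plane of the three methine-bridge atoms (e.g. C4C–CHD–C1D on
the D side), and the outer ring plane, in the acute convention (0–90°).

Identity calling uses two decisions:

* **Ring A planarity.**  The statistic is the half-spread of the *signed*
  out-of-plane distances of the exocyclic substituents on C2A/C3A (ideal sp3
  geometry places them trans, ≈ ±0.7 Å; ideal sp2 in-plane).  The signed
  spread cancels coherent plane-tilt error, which a max-|deviation| statistic
  absorbs in full.  Per-ring reporting (`planarity_verdict`) uses a 0.15 Å /
  0.35 Å two-threshold band; the identity call widens the sp2 acceptance to
  0.25 Å, comfortably above coordinate uncertainty at working resolutions
  (~0.1 Å) and still far below ideal sp3.  Both are configurable.
* **C–D coplanarity.**  Judged between the two five-atom ring planes of rings
  C and D (threshold 20°, configurable), which is much better conditioned
  against coordinate noise than the three-atom bridge plane; the bridge-plane
  dihedrals remain available as descriptors.

Ring A planar ⇒ DBV; sp3 ring A with coplanar C–D ⇒ PCB; with a kinked C–D ⇒
PEB; anything indecisive ⇒ ambiguous, with the evidence attached.

**Buried surface area** uses Shrake–Rupley sphere-point sampling (golden
spiral, 960 points/atom by default, probe 1.4 Å, vdW radii per element) and
reports both the half-difference (SASA_A + SASA_B − SASA_AB)/2 — the
convention of the interactive structure tools — and the full difference.
Boundary-coincident surface points are counted once via a lower-index
tie-break, which makes the coincident-sphere closed form exact.  Waters and
common ions are stripped by the callers; chromophores are retained.
**Superposition** is the Kabsch SVD solution constrained to proper rotations,
with RMSD computed from the transformed coordinates and 1:1 pairing by
(chain, residue, atom name); unpaired atoms raise with a listing.

## Electron micrographs

Striations are assumed vertical (the caller pre-rotates; no automatic angle
estimation).  Edges come from scikit-image's Canny detector with σ = 2 px and
hysteresis thresholds at 0.2/0.4 of the smoothed-gradient maximum — the
published workflow names only an unspecified built-in detector, so these
stand-in defaults were chosen to keep noise chains out at the synthetic
suite's contrast, and all are exposed as flags.  Per row, runs of adjacent
edge pixels are merged and consecutive-edge distances pooled (rows with odd
edge counts contribute their valid pairs); fewer than 10 pooled distances is
an error.  Gaps are classed dark/bright against the midpoint of the 10–90
percentile intensity range — the lumen (protein) width is the dark-band mean,
and the median would sit inside the majority band when the duty cycle is
uneven.  Spacing statistics are affine-invariant in intensity and scale
exactly with nm/px.

## Synthetic data: what it emulates, and what it does not

All generators take one integer seed (`numpy.random.default_rng`) and return
a truth record sufficient to score every downstream operation; identical
(seed, parameters) give bit-identical outputs.

* **Chromatograms** sum true peak models per colour fraction; the 280 nm
  channel is a 2.5× scaled copy with independent additive noise (detector
  noise is per-channel, not gain-scaled); the 560 nm channel is clipped at
  the saturation level after noise.  The *antenna scenario* calibrates three
  named peaks so their purple-scaled window areas are exactly 63/14/8 % of
  the total signal, with unnamed filler peaks completing the published
  85:15 pink:purple accounting, and clips the dominant peak at 90 % of its
  height.  The *recovery scenario* uses three well-separated peaks (heavy
  tails leak between nearby windows and bias the tail exponent), 0.02 mL
  sampling (~1 Hz at 1 mL/min) and noise at 1 % of the smallest peak height,
  so every peak is at SNR ≥ 100 and the Fisher information supports
  percent-level precision on ε — a power-analysis choice, documented here as
  study design.
* **Spectra/EEMs** are sums of Gaussians; EEMs add an elastic-scatter ridge
  along the emission = excitation diagonal with amplitude c·λⁿ (n = −4 by
  default), which collapses to an effective power law on the grid interior.
  Real PBP lineshapes are vibronically structured, not Gaussian; passing
  tests show the *processing* is correct, not that Gaussians model PBPs.
* **Bilins** are idealised planar pentagon rings with kinked methine bridges;
  identity fixes the ring-A substituent geometry (sp2 in-plane vs sp3 at
  ±0.7 Å) and the default D-side twist (35° kinked for PEB/DBV, 5° coplanar
  for PCB); requested inner/outer twists are applied about the bridge bond
  axes, then iid Gaussian coordinate noise.  Real bilins have non-ideal bond
  geometry and correlated refinement error.
* **Micrographs** are anti-aliased vertical square waves (dark lumen bands of
  12.7 nm, bright bands of 8 nm at 0.25 nm/px by default), Gaussian-blurred
  plus noise.  Real micrographs have curved membranes, stain gradients and
  texture; the caller's crop/rotate step is not emulated.
* **α-subunit sets** build signal peptide + `ASA` + mature scaffold with the
  class-defining insertions, random substitutions at designated tolerant
  positions (from an alphabet that can never create motifs or cut sites),
  cross-strain duplicates with 5′/3′ truncations and X misreads, one tandem
  read and one SFS precursor.

## Known limitations

* The deposited crystal structures and the original instrument data files
  are external resources; the buried-surface-area values of the real protomer
  interfaces (≈1084 Å² open form, ≈1452 Å² open-braced, ≈2191 Å² closed) and
  the real chromatogram/spectra files cannot be recomputed without them.  The
  BSA code path is validated against the closed-form sphere oracle and an
  independent SASA implementation instead, and the chromatogram/spectral
  stages run on synthetic analogues generated at the published conditions.
* Eq.-model areas are window-truncated by design; heavy Lorentzian-like
  tails mean a window must be several tens of Γ wide before the window area
  approaches A.
* The ε exponent is weakly identified: at SNR 100 its standard error is an
  order of magnitude larger (relative) than the other parameters', and
  baseline co-fitting roughly doubles it.
* FRET constants (κ², n, Q_D) default to generic values; absolute R₀ and
  distances should only be quoted with system-specific inputs.
* The EEM Rayleigh fit extrapolates the power law across excluded
  fluorescence bands; exclusion intervals that clip a band's shoulder bias
  the recovered exponent.
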
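# Methods

## Signal model

A weakly coupled multiplet in a 1D frequency-domain NMR spectrum is
modelled as

    multiplet(ν) = H(ν − ν₀) ⊗ F(J₁) ⊗ F(J₂) ⊗ …

where H is the spectral line shape (Lorentzian from T₂ relaxation, Gaussian
from B₀ inhomogeneity, Voigt as their mixture, or any empirical profile)
and F_S(J) is the splitting pattern of one coupling: 2S+1 equal-weight
δ-functions spaced J Hz, centred at zero, for a partner of spin S. n
equivalent partners apply F_S(J) n times (binomial weights for S = 1/2).
Patterns are normalized to unit total weight, so all physical scale lives
in the line shape and spectral integrals are invariant under the coupling
list. A zero-order phase error is modelled by mixing the absorptive and
dispersive line-shape components, cos φ·A + sin φ·D.

Mild second-order behaviour is restricted to the "roof" regime — uneven
doublet amplitudes without extra transitions or line shifts. A tilted
doublet carries weights in ratio r = (1 − sin θ)/(1 + sin θ),
θ = atan(J/Δδ) with Δδ the partner shift difference in Hz. The convention
is that the weaker line sits on the low-frequency (high-field) side and the
stronger line points toward the partner; `CouplingSpec.tilt_side = −1`
mirrors this for partners at lower frequency. On an exact AB system (lines
at ±(D ± J)/2, D = √(Δν² + J²), outer/inner intensities 1 ∓ J/D) the tilt
model reproduces the intensities exactly since sin θ = J/D.

## Deconvolution

Division by F is ill-posed; instead the region is convolved with an
inverse series M_S(J*). For n = 2S+1 lines, M has a core of n unit
δ-functions spaced J*, flanked outward on both sides by repeated blocks of
one δ of weight −(n−1) followed by n−1 unit δ's. Every sliding window of n
consecutive weights sums to zero except the central one, so
F_S(J) ⊗ M_S(J* = J) is a single unit stick (given the unit-total
normalization of F; the series is truncated at the region width, where the
pattern repeats with alternating sign). For S = 1/2 this is the familiar
comb at ±(2k+1)J*/2 with signs (−1)^k. For a tilted doublet, consecutive
|weights| shrink by r toward the weak-line side and grow by 1/r toward the
strong-line side; the growing side is why tilted deconvolution amplifies
artifacts on one flank.

The same result is computed in O(nN) by the running-cursor recursion

    out[i] = in[i] − Σ_{m=1}^{n−1} ρ^m · out[i − m·d],   d = J*/Δν_step,

with ρ = 1 untilted and ρ = (second-encountered / first-encountered line
weight) for tilted doublets. Fractional arms are read back by linear
interpolation (nearest-bin reads quantize the quality curve); positions
before the start contribute zero. The implementation evaluates the
recursion in blocks of ⌊d⌋ points so each block is a vectorized update —
bit-identical to the per-point loop, which the test suite keeps as an
oracle. Run left-to-right and right-to-left (by reversing the vector) it
yields S_L and S_R; aligned by one arm, S_L + S_R equals the convolution
with the truncated two-sided M exactly (asserted to 1e-9 on random
vectors).

## Quality functions and the scan

* **Symmetry score**: normalized scalar product of S_L and S_R after
  reading S_R one artifact margin (n−1 arms, in points) later than S_L,
  which aligns the two sub-multiplets and drops the marginal artifact
  zones. 1 when the trial splitting matches a true coupling.
* **Half-integral score**: 1 − 2·|Σ|S_side|/Σ|input| − 1/2|; a successful
  one-sided simplification leaves exactly half the absolute sum. Used when
  only one side is available (overlap analysis).

The scan evaluates the score on a J* grid from half the region width down
to the 1 Hz floor in steps of half the data grid (finer than the data so
extrema are not aliased). Local maxima above an absolute prominence of
0.02 are refined by 3-point parabolic interpolation. Extrema also appear
at odd fractions J/(2n+1) of every true coupling — structures that happen
to be symmetric without being simplified — so the analysis always takes
the **first extremum scanning downward** and recurses: deconvolve there,
combine the sides per the direction policy (default `both_sum`, the
aligned average; `best_half` is available but can leave a mid-multiplet
discontinuity), optionally re-symmetrize, and rescan from just above the
previous coupling (so an equal, degenerate splitting is found again with
full peak prominence). The acceptance bar for an extremum
(`min_extremum_score`, default 0.8) may relax with recursion depth
(`min_score_decay`, 0.03 per step, floored at 0.8) because artifacts
accumulate step by step.

The J* floor is a hard 1 Hz default (overridable); no automatic
line-width-based floor is attempted. Couplings below the measured residual
line width are reported but flagged "unresolved — use with care".

## Degeneracy, validation, strategies

Extracted J values within 0.5 Hz (configurable) are grouped by single
linkage into one coupling of higher degeneracy; a user `spin_map` assigns
(spin, degeneracy) per step directly and overrides grouping.

Validation rebuilds the multiplet from the final simplified shape
(residual singlet) and the extracted couplings, least-squares scales it,
aligns within a fraction of a line width, and takes the normalized scalar
product with the source region; results pass at ≥ 0.99. When the residual
still contains resolved structure — counted on the residual itself and on
the positive lobe of its width-matched second difference, which resolves
sub-linewidth leftovers — the extraction is incomplete, and validation
falls back to a fitted Lorentzian line shape so the missing couplings show
up as a mismatch instead of being recycled through the empirical shape.

A failing or marginal result triggers the **post-analysis degeneracy
search**: coordinate ascent over each coupling's multiplicity (d → t → q →
… up to 8-fold partners), re-scored by reconstruction. All candidate
degeneracies are tried per sweep because the score is not monotone in the
line count (odd and even patterns sit half a spacing apart). This is what
recovers triplet-of-heptet structures whose outermost lines are too weak
for the scan.

The **strategy search** runs the extraction under a small curated grid of
option sets — symmetrize-input on/off × symmetrize-each-step on/off with
`both_sum`, the two one-sided policies, and strict (0.98, frozen and
decaying) versus lax (0.8) extremum thresholds — validates each, applies
the degeneracy search to failures, and ranks by score with ties broken by
parsimony (fewer couplings) and then the larger smallest J. The full
2×2×4×2×2 cross product is available by passing option sets explicitly;
the curated default keeps a region's analysis at a few seconds. The
success threshold is part of the searched space deliberately: a strict
pass rejects combination artifacts (J₁+J₂ pseudo-extrema) on clean data, a
lax pass keeps noisy data analysable, and validation arbitrates.

## Overlapped multiplets

For a multiplet holding fraction f of the region integral and overlapped
on one side, the recursion runs one-sided from the free edge. The
half-integral score is evaluated over the multiplet's integral share plus
one arm length J* — the window must cover the whole span where the second
sub-multiplet occurrence is subtracted, otherwise cutting it mid-echo
biases the extremum position (0.36 Hz on the reference two-multiplet
geometry without the extension, 0.04 Hz with it). Candidate extrema are
gated by the unextended share: a clean separation leaves ≈ f/2 of the
total absolute integral there (gate at 0.75 by default). The accepted walk
is truncated where the running absolute integral reaches f/2 of the region
total, which removes the neighbour together with the cancelled second
occurrence; the isolated half sub-multiplet is then analysed normally and
the first coupling prepended.

Separation is only physical while the overlap stays below the largest
coupling. Two checks enforce this: the truncation point must fall on
effectively empty signal (mean |amplitude| over the last line width below
10 % of the sub-multiplet maximum — a clean cut measures 2–6 %, a
deeper-than-largest-J overlap ≥ 14 %), and the rebuilt multiplet, scaled
to its integral share, must not exceed the region anywhere by more than
10 % of its integral (the remainder is the neighbour and cannot be
negative). Either failure raises `OverlapTooSevereError` rather than
reporting fabricated couplings. Sequential subtraction of more than two
overlapping multiplets is not part of the validated surface.

## Roof-effect fitting and partner shifts

θ is fitted only at J* values that are extrema of the untilted quality
curve, avoiding a two-variable search. The criterion is the absolute-sum
one: at the correct tilt each one-sided result keeps exactly its own
line's share, so (Σ|S_L| + Σ|S_R|)/Σ|input| = 1 and grows V-shaped with
tilt mismatch. The symmetry scalar product is *not* used here: in a region
only a couple of arms wide the mismatch echo lands inside the trimmed
margin and the scalar product is numerically blind to θ (flat to 1e-4 over
0–12°), while the exponentially growing strong-side artifacts dominate any
untrimmed comparison. The default θ grid is 0–20° in 0.25° steps; both
orientations are fitted and the better one fixes the partner side. After a
successful fit the residual singlet is regenerated with the tilted
recursion so validation is not distorted by the (1 − r) residue of the
untilted walk.

The partner shift follows as δ_partner = δ_ref ± J/tan θ (toward the
stronger line), with a first-order error propagated from the amplitude
noise of the margin region through r, sin θ = (1−r)/(1+r) and
d(J/tan θ)/dθ = −J/sin²θ; the error grows faster than 1/θ for weak tilts.
Estimates are flagged unreliable outside 3 < Δδ/J < 20: stronger coupling
makes the weak line hard to measure, weaker coupling makes 1/tan θ
explode. On exact AB input the only bias is the line-position shift
(D − Δν)/2 ≈ J²/(4Δν), about 0.002–0.007 ppm at 300 MHz for Δδ/J = 6.6 and
geminal-scale J.

## Synthetic data

The generator covers what the method is specified against: Lorentzian /
Gaussian / Voigt lines convolved with first-order patterns for spins up to
3, optional phase error, roof tilt, constant baseline offset and seeded
Gaussian noise, on grids defaulting to fwhm/8 sampling with ≥ 5 fwhm flat
margins (synthesis refuses grids narrower than the pattern plus those
margins). The randomized-recovery generator draws 1–4 spin-1/2 couplings
in [1.5, 20] Hz with pairwise gaps above max(0.5 Hz, one grid step), line
widths in [0.5, 3] Hz, signal-to-noise of 50–200 at the tallest line, and
flat margins of 0.6 ΣJ + 6 fwhm — the analysed window must stay wider than
twice the largest coupling throughout the recursion, which is a property
of region selection, not of the sample.

What the generator does **not** emulate: t₁ noise and baseline roll,
solvent and impurity peaks inside the region, strong coupling beyond the
roof regime (extra transitions, line shifts), field drift, and
multiplet-specific line-width variation. Passing tests therefore
demonstrate the algorithmic contract on ideal first-order spectra, not
performance on crowded real spectra, where pre-processing quality (solvent
subtraction, baseline) dominates.

## Numerical choices

* Stick offsets within 1e-6 Hz merge by weight addition.
* Trial splittings below twice the grid step are rejected (sub-resolution).
* The quality-curve peak picker uses absolute prominence 0.02 and 3-point
  parabolic refinement; the overlap scan uses prominence relative to the
  curve range, since the half-integral scale is geometry-dependent.
* Validation alignment searches integer lags within one line width with
  parabolic sub-bin refinement.
* Degenerate inputs (all-zero regions, zero-norm sides) score 0 and fail
  validation rather than raising.
* All randomness is seeded; fixture seeds are recorded in the tests.

## Known limitations

* **Resolution floor.** Two couplings closer than roughly half the line
  width produce quality extrema that blend into one displaced peak; the
  result is then a degenerate pair (or a slightly shifted pair) that can
  still validate, because the reconstructions are indistinguishable at
  that line width. The randomized suite intentionally samples this corner
  (gaps down to 0.5 Hz at widths up to 3 Hz) and reports the measured
  recovery fraction; the corresponding test states the idealized
  all-recovered contract and documents the shortfall.
* **Sub-linewidth ambiguity.** A high-degeneracy comb of a small J is
  reconstruction-equivalent to a missed moderate coupling; validation
  cannot refute it. Sub-linewidth couplings are therefore flagged and
  should never carry a key structural argument on their own.
* **Tilt scope.** The tilted forward/inverse patterns are defined for a
  single spin-1/2 partner (doublets), matching the roof regime; tilted
  higher-spin or degenerate patterns are rejected.
* **Overlap scope.** One-sided separation handles two multiplets whose
  overlap stays below the largest coupling; deeper overlap raises an
  explicit error, and >2 overlapping multiplets are out of scope.
* Full simultaneous refinement of phase, baseline, line shape and
  couplings against the raw region — which would sharpen the resolution
  floor — is deliberately not implemented.
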
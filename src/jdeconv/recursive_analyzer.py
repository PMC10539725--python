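"""Full multiplet analysis: largest-coupling-first recursion, degeneracy
grouping, validation by reconstruction, post-analysis degeneracy search,
overlapped-multiplet separation, and the strategy search over option sets.

The recursion always aims at the largest coupling first: deconvolution with a
large J* inserts fewer delta functions per unit width (fewer artifacts), and
quality extrema at odd fractions J/(2n+1) of a true coupling make any scan
below one-third of the largest coupling unreliable until that coupling has
been simplified away. Each accepted extremum removes one splitting; the loop
ends when no extremum above the J* floor remains and the residual is the
simplified singlet, which then serves as the empirical line shape for
validation by reconstruction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import second_order
from .deconv_core import deconv_both, first_extremum, quality_score, side_deconv
from .multiplet_model import (
    CouplingSpec,
    LineShape,
    MultipletResult,
    Spectrum1D,
    measure_fwhm,
    multiplicity_string,
    preprocess,
    reconstruct,
)

__all__ = [
    "AnalysisOptions",
    "OverlapTooSevereError",
    "analyze_overlapped",
    "extract_couplings",
    "group_degenerate",
    "post_degeneracy_search",
    "strategy_search",
    "validate_by_reconstruction",
]


class OverlapTooSevereError(ValueError):
    """Raised when multiplet overlap exceeds the largest coupling constant."""


@dataclass
class AnalysisOptions:
    """Knobs driving one deconvolution run.

    ``j_floor_hz`` is the smallest trial splitting tested (sub-linewidth
    couplings below the line width are still reported, flagged unresolved);
    ``degeneracy_tol_hz`` groups couplings differing by less than the
    threshold into one n-fold degenerate coupling; ``validation_threshold``
    is the minimal reconstruction scalar product for a result to pass.
    ``direction_policy`` chooses how the two side results are combined into
    the next step's region: ``both_sum`` (aligned average, the default),
    ``best_half`` (better half only; can leave a discontinuity in the
    middle), ``left_only`` or ``right_only``. ``spin_map`` optionally assigns
    (spin, degeneracy) per recursion step for partners with S > 1/2 or known
    degeneracy.
    """

    j_floor_hz: float = 1.0
    degeneracy_tol_hz: float = 0.5
    validation_threshold: float = 0.99
    symmetrize_input: bool = False
    symmetrize_each_step: bool = True
    direction_policy: str = "both_sum"
    theta_scan: bool = False
    remove_offset: bool = False
    spin_map: Optional[List[Tuple[float, int]]] = None
    overlap_fraction: Optional[float] = None
    prominence: float = 0.02
    min_extremum_score: float = 0.8
    min_score_decay: float = 0.03
    overlap_min_score: float = 0.75
    max_steps: int = 16

    def __post_init__(self) -> None:
        if not self.j_floor_hz > 0:
            raise ValueError("j_floor_hz must be > 0")
        if self.degeneracy_tol_hz < 0:
            raise ValueError("degeneracy_tol_hz must be >= 0")
        if not 0 < self.validation_threshold <= 1:
            raise ValueError("validation_threshold must lie in (0, 1]")
        if self.direction_policy not in ("both_sum", "best_half", "left_only", "right_only"):
            raise ValueError(f"unknown direction_policy {self.direction_policy!r}")
        if self.overlap_fraction is not None and not 0 < self.overlap_fraction <= 1:
            raise ValueError("overlap_fraction must lie in (0, 1]")


def _centroid_index(y: np.ndarray) -> float:
    w = np.abs(y)
    total = w.sum()
    if total == 0:
        return 0.5 * (y.size - 1)
    return float(np.sum(np.arange(y.size) * w) / total)


def _symmetrize_vec(y: np.ndarray) -> np.ndarray:
    idx = np.arange(y.size, dtype=float)
    c = _centroid_index(y)
    mirrored = np.interp(2.0 * c - idx, idx, y, left=0.0, right=0.0)
    return 0.5 * (y + mirrored)


def _combine_sides(out, policy: str, original: np.ndarray):
    """Combine S_L/S_R into the next-step region (vector, start-point shift)."""
    m = min(out.margin_pts, out.s_left.size - 2)
    if policy == "both_sum":
        return 0.5 * (out.s_left[: out.s_left.size - m] + out.s_right[m:]), 0
    if policy == "left_only":
        return out.s_left[: out.s_left.size - m].copy(), 0
    if policy == "right_only":
        return out.s_right[m:].copy(), m
    # best_half: side whose absolute sum is closer to half the input's
    target = 0.5 * np.sum(np.abs(original))
    dl = abs(np.sum(np.abs(out.s_left)) - target)
    dr = abs(np.sum(np.abs(out.s_right)) - target)
    if dl <= dr:
        return out.s_left[: out.s_left.size - m].copy(), 0
    return out.s_right[m:].copy(), m


def group_degenerate(j_values: Sequence[float], tol_hz: float, spin: float = 0.5) -> List[CouplingSpec]:
    """Single-linkage grouping of extracted J values within ``tol_hz``.

    Each group becomes one coupling with degeneracy equal to the group size
    and J equal to the group mean; output sorted descending by J.
    """
    if tol_hz < 0:
        raise ValueError("tol_hz must be >= 0")
    js = sorted(float(j) for j in j_values)
    groups: List[List[float]] = []
    for j in js:
        if groups and j - groups[-1][-1] <= tol_hz:
            groups[-1].append(j)
        else:
            groups.append([j])
    specs = [
        CouplingSpec(j_hz=float(np.mean(g)), spin=spin, degeneracy=len(g))
        for g in groups
    ]
    return sorted(specs, key=lambda c: -c.j_hz)


def _resolved_line_count(residual: Optional[Spectrum1D]) -> int:
    """Number of resolved lines in a residual shape.

    A completed recursion leaves a single line; several resolved maxima mean
    couplings were left unextracted and the residual must not be recycled as
    the reconstruction line shape (it would hide the missing structure).
    """
    if residual is None:
        return 0
    from scipy.signal import find_peaks

    y = np.abs(residual.amplitudes)
    top = float(y.max())
    if top <= 0:
        return 0
    fw = measure_fwhm(residual) or 4 * residual.step_hz
    distance = max(2, int(round(1.2 * fw / residual.step_hz)))
    peaks, _ = find_peaks(y, prominence=0.1 * top, height=0.2 * top, distance=distance)
    count = max(1, int(peaks.size))

    # structure narrower than the line width merges into one hump; the
    # positive part of the negated second difference resolves it (a single
    # absorption line of any common shape keeps a single positive lobe).
    # The difference lag is matched to the line width so that bin-level
    # interpolation wiggle is not amplified.
    amp = residual.amplitudes
    h = max(1, int(round(0.25 * fw / residual.step_hz)))
    if amp.size > 2 * h:
        d2 = np.maximum(-(amp[2 * h:] - 2.0 * amp[h:-h] + amp[:-2 * h]), 0.0)
        top2 = float(d2.max())
        if top2 > 0:
            peaks2, _ = find_peaks(d2, prominence=0.1 * top2, height=0.2 * top2,
                                   distance=max(2, h))
            count = max(count, int(peaks2.size))
    return count


def validate_by_reconstruction(
    result: MultipletResult,
    source_region: Spectrum1D,
    lineshape_policy: str = "auto",
    threshold: float = 0.99,
) -> Tuple[float, bool]:
    """Score a result by rebuilding the multiplet and comparing to its source.

    The reconstruction starts from the final singlet shape (or a synthetic
    Lorentzian of matching width for ``lineshape_policy="lorentzian"``),
    reintroduces the measured couplings, and is compared to the source region
    by normalized scalar product after a small alignment search (the centre
    estimate carries a fraction-of-a-linewidth uncertainty). The default
    ``auto`` policy uses the residual shape only when it is a single line;
    a structured residual (incomplete extraction) falls back to the fitted
    Lorentzian so the missing couplings show up as a mismatch.
    """
    src = source_region.amplitudes
    nsrc = float(np.linalg.norm(src))
    if nsrc == 0.0:
        return 0.0, False
    if lineshape_policy == "auto":
        lineshape_policy = (
            "lorentzian" if _resolved_line_count(result.residual_singlet) > 1 else "residual"
        )
    if lineshape_policy == "lorentzian":
        fw = measure_fwhm(result.residual_singlet) if result.residual_singlet is not None else None
        shape = LineShape("lorentzian", fwhm_hz=fw or source_region.step_hz * 4)
        recon = reconstruct(result, lineshape=shape, grid=source_region)
    else:
        recon = reconstruct(result, grid=source_region)
    rec = recon.amplitudes
    nrec = float(np.linalg.norm(rec))
    if nrec == 0.0:
        return 0.0, False
    fw = measure_fwhm(source_region) or 4 * source_region.step_hz
    lag_max = max(2, int(round(fw / source_region.step_hz)))
    n = src.size
    corr = np.correlate(src, rec, mode="full")  # lag = index - (n - 1)
    lo, hi = n - 1 - lag_max, n - 1 + lag_max + 1
    window = corr[lo:hi]
    k = int(np.argmax(window))
    best = window[k]
    if 0 < k < window.size - 1:
        denom = window[k - 1] - 2 * window[k] + window[k + 1]
        if denom < 0:
            delta = 0.5 * (window[k - 1] - window[k + 1]) / denom
            best = window[k] - 0.25 * (window[k - 1] - window[k + 1]) * delta
    score = float(np.clip(best / (nsrc * nrec), -1.0, 1.0))
    return score, score >= threshold


def extract_couplings(region: Spectrum1D, options: Optional[AnalysisOptions] = None) -> MultipletResult:
    """Recursive largest-first extraction of all couplings in one multiplet.

    Repeats {scan the quality curve from large J* downward, take the first
    extremum, deconvolve at the refined J*, optionally symmetrize} until no
    extremum above the floor remains, then groups degenerate couplings,
    validates by reconstruction and assembles the result.
    """
    options = options or AnalysisOptions()
    if options.overlap_fraction is not None and options.overlap_fraction < 1.0:
        return analyze_overlapped(region, options)
    step = region.step_hz
    validate_region = preprocess(region, remove_offset=options.remove_offset)
    prep = preprocess(validate_region, symmetrize=options.symmetrize_input)
    cur = prep.amplitudes.copy()
    cur_start = prep.start_hz
    center_hz = validate_region.centroid_hz()
    dj = step / 2.0

    if region.width_hz / 2.0 < options.j_floor_hz:
        raise ValueError(
            f"region width {region.width_hz:.2f} Hz too narrow to test "
            f"splittings down to the {options.j_floor_hz:.2f} Hz floor"
        )

    extracted: List[Tuple[float, float, int]] = []  # (J, spin, degeneracy)
    prev_j = None
    for k in range(options.max_steps):
        spin_k, deg_k = (0.5, 1)
        if options.spin_map and k < len(options.spin_map):
            spin_k, deg_k = options.spin_map[k]
        n_k = int(round(2 * spin_k)) + 1
        width_cur = (cur.size - 1) * step
        j_hi = min(width_cur / 2.0, 0.95 * width_cur / (n_k - 1))
        if prev_j is not None:
            # restart above the previous coupling so a repeated (degenerate)
            # splitting is found again with its full peak prominence
            j_hi = min(j_hi, prev_j + max(2.0, 20 * dj))
        if j_hi < max(options.j_floor_hz, 2 * step):
            break
        # artifacts accumulate with every simplification step, so the
        # acceptance bar for an extremum may relax as the recursion deepens
        step_min_score = max(
            options.min_extremum_score - options.min_score_decay * k, 0.8
        )
        found = first_extremum(
            cur, step, j_hi, options.j_floor_hz, dj,
            spin=spin_k,
            prominence=options.prominence,
            min_score=step_min_score,
        )
        if found is None:
            break
        j_k, _score = found
        for _ in range(deg_k):
            out = deconv_both(cur, step, j_k, spin=spin_k)
            cur, shift = _combine_sides(out, options.direction_policy, cur)
            cur_start += shift * step
        if options.symmetrize_each_step:
            cur = _symmetrize_vec(cur)
        extracted.append((j_k, spin_k, deg_k))
        prev_j = j_k
        if (cur.size - 1) * step < 4 * max(options.j_floor_hz, step):
            break

    residual = Spectrum1D(cur, cur_start, step, region.spectrometer_mhz) if cur.size >= 2 else None

    # degeneracy grouping (automatic steps only; user-assigned spins are kept)
    auto_js = [j for j, s, d in extracted if s == 0.5 and d == 1]
    couplings = group_degenerate(auto_js, options.degeneracy_tol_hz)
    for j, s, d in extracted:
        if not (s == 0.5 and d == 1):
            couplings.append(CouplingSpec(j_hz=j, spin=s, degeneracy=d))
    couplings.sort(key=lambda c: -c.j_hz)

    result = MultipletResult(
        center_hz=center_hz,
        couplings=couplings,
        residual_singlet=residual,
        strategy_used={
            "symmetrize_input": options.symmetrize_input,
            "symmetrize_each_step": options.symmetrize_each_step,
            "direction_policy": options.direction_policy,
            "remove_offset": options.remove_offset,
            "theta_scan": options.theta_scan,
        },
    )

    if options.theta_scan and couplings:
        result = _apply_theta_scan(result, prep, validate_region, options)

    score, passed = (
        validate_by_reconstruction(result, validate_region, threshold=options.validation_threshold)
        if residual is not None
        else (0.0, False)
    )
    if couplings and _resolved_line_count(residual) > 1:
        passed = False
        result.flags.append("residual retains resolved structure: extraction incomplete")
    result.validation_score = score
    result.multiplicity = multiplicity_string(result.couplings, validated=passed or not couplings)

    fw_est = measure_fwhm(residual) if residual is not None else None
    if fw_est:
        for c in result.couplings:
            if c.j_hz < fw_est:
                result.flags.append(
                    f"J = {c.j_hz:.2f} Hz below the line width "
                    f"({fw_est:.2f} Hz): unresolved - use with care"
                )
    return result


def _apply_theta_scan(
    result: MultipletResult,
    prep: Spectrum1D,
    validate_region: Spectrum1D,
    options: AnalysisOptions,
) -> MultipletResult:
    """Fit the roof tilt at the largest-coupling extremum and, when the tilt
    is significant, estimate the partner shift with propagated error."""
    largest = result.sorted_couplings()[0]
    if largest.spin != 0.5 or largest.degeneracy != 1:
        return result
    y = prep.amplitudes
    step = prep.step_hz
    theta_fwd, score_fwd = second_order.fit_theta(y, step, largest.j_hz)
    theta_rev, score_rev = second_order.fit_theta(y[::-1], step, largest.j_hz)
    if score_fwd >= score_rev:
        theta, side = theta_fwd, +1
    else:
        theta, side = theta_rev, -1
    if theta <= 0.0:
        return result
    couplings = result.sorted_couplings()
    couplings[0] = replace(couplings[0], theta_rad=theta, tilt_side=side)
    if len(couplings) == 1:
        # regenerate the residual with the tilted recursion: the untilted
        # walk leaves a (1 - r) residue that would distort the empirical
        # line shape used for validation; the mirrored case runs on the
        # frequency-reversed vector
        step = prep.step_hz
        yy = y if side == +1 else y[::-1]
        out = deconv_both(yy, step, couplings[0].j_hz, theta_rad=theta)
        cur, _ = _combine_sides(out, "both_sum", yy)
        if side == +1:
            start = prep.start_hz
        else:
            trimmed = prep.amplitudes.size - cur.size
            cur = cur[::-1]
            start = prep.start_hz + trimmed * step
        result = result.replace(
            residual_singlet=Spectrum1D(cur, start, step, prep.spectrometer_mhz)
        )
    result = result.replace(couplings=couplings)
    if prep.spectrometer_mhz:
        k = max(1, int(0.05 * y.size))
        noise = float(np.std(np.concatenate([y[:k], y[-k:]])))
        amp_noise = noise / max(float(np.max(np.abs(y))), 1e-300)
        fit = second_order.partner_shift(
            delta_ref_ppm=result.center_hz / prep.spectrometer_mhz,
            j_hz=largest.j_hz,
            theta_rad=theta,
            field_mhz=prep.spectrometer_mhz,
            amplitude_noise=amp_noise,
            side=side,
        )
        result.partner_estimates.append(fit)
    return result


def post_degeneracy_search(
    result: MultipletResult,
    source_region: Spectrum1D,
    options: Optional[AnalysisOptions] = None,
    max_degeneracy: int = 8,
) -> MultipletResult:
    """Test whether higher degeneracy levels match the source better.

    For each extracted coupling, greedily raises the multiplicity (d -> t ->
    q -> ... up to ``max_degeneracy``-fold partners, covering e.g. the heptet
    of two equivalent methyls) and keeps the variant whenever the
    reconstruction score improves; returns the input unchanged when no
    variant improves.
    """
    options = options or AnalysisOptions()
    current = list(result.sorted_couplings())
    # merge near-equal couplings first (a quartet reported as three almost
    # identical J values becomes one three-fold degenerate coupling)
    merged: List[CouplingSpec] = []
    simple = [c for c in current if c.spin == 0.5 and c.theta_rad == 0.0]
    other = [c for c in current if not (c.spin == 0.5 and c.theta_rad == 0.0)]
    if simple:
        js: List[float] = []
        for c in simple:
            js.extend([c.j_hz] * c.degeneracy)
        merged = group_degenerate(js, options.degeneracy_tol_hz)
    current = sorted(merged + other, key=lambda c: -c.j_hz)

    def score_of(couplings: List[CouplingSpec]) -> float:
        trial = result.replace(couplings=couplings)
        s, _ = validate_by_reconstruction(trial, source_region,
                                          threshold=options.validation_threshold)
        return s

    best_score = score_of(current)
    # coordinate ascent over each coupling's degeneracy: the score is not
    # monotone in the multiplicity (odd/even line counts sit half a spacing
    # apart), so every candidate degeneracy is tried, not just +1
    improved = True
    while improved:
        improved = False
        for i, c in enumerate(current):
            if c.spin != 0.5:
                continue
            for deg in range(1, max_degeneracy + 1):
                if deg == c.degeneracy:
                    continue
                variant = list(current)
                variant[i] = replace(c, degeneracy=deg)
                s = score_of(variant)
                if s > best_score + 1e-4:
                    current, best_score, improved = variant, s, True
    passed = best_score >= options.validation_threshold
    return result.replace(
        couplings=current,
        validation_score=best_score,
        multiplicity=multiplicity_string(current, validated=passed or not current),
    )


def analyze_overlapped(
    region: Spectrum1D,
    options: AnalysisOptions,
    direction: str = "L2R",
) -> MultipletResult:
    """One-sided analysis of a multiplet partially overlapped by a neighbour.

    ``options.overlap_fraction`` f is the analysed multiplet's share of the
    region integral. The recursion starts from the non-overlapped edge
    (``direction="L2R"`` analyses the left multiplet), quality is measured by
    the half-integral criterion against the target f/2 of the region total,
    and the walk is truncated where the running absolute integral reaches
    half the multiplet's integral — which removes the overlapping neighbour
    together with the second occurrence of the sub-multiplet. Separation
    works when the overlap extends over less than the largest coupling;
    deeper overlap raises :class:`OverlapTooSevereError`.
    """
    f = options.overlap_fraction
    if f is None:
        raise ValueError("analyze_overlapped requires options.overlap_fraction")
    if f >= 0.999:
        return extract_couplings(region, replace(options, overlap_fraction=None))
    step = region.step_hz
    prep = preprocess(region, remove_offset=options.remove_offset)
    y = prep.amplitudes
    total_abs = float(np.sum(np.abs(y)))
    dj = step / 2.0
    width = prep.width_hz

    from scipy.signal import find_peaks

    from .deconv_core import _refine_parabolic, scan_quality

    j_hi = min(width / 2.0, 0.95 * width)
    j_lo = max(options.j_floor_hz, 2.0 * step)
    if j_hi <= j_lo:
        raise ValueError("region too narrow for the overlap scan")
    grid = np.arange(j_hi, j_lo, -dj)
    curve = scan_quality(
        y, step, grid, mode="half_integral", original=y,
        overlap_fraction=f, direction=direction, prominence=np.inf,
    )
    rng = float(curve.scores.max() - curve.scores.min())
    peaks, _ = find_peaks(curve.scores, prominence=max(0.02 * rng, 1e-12))

    # gate each candidate on the analysed multiplet's own share (no arm
    # extension): a clean separation leaves close to f/2 of the total
    # absolute integral there; accept the first candidate in scan order
    cum_in = np.cumsum(np.abs(y if direction == "L2R" else y[::-1]))
    idx_f = int(np.searchsorted(cum_in, f * total_abs))
    j1 = None
    for i in peaks:
        j_cand, _ = _refine_parabolic(curve.j_grid_hz, curve.scores, int(i))
        walk = side_deconv(y, step, j_cand, direction=direction)
        own = walk if direction == "L2R" else walk[::-1]
        x_hat = float(np.sum(np.abs(own[: idx_f + 1]))) / (f * total_abs)
        gate = 1.0 - 2.0 * abs(x_hat - 0.5)
        if gate >= options.overlap_min_score:
            j1 = j_cand
            break
    if j1 is None:
        raise OverlapTooSevereError(
            "no trial splitting leaves half the multiplet's integral after "
            "one-sided deconvolution: overlap too severe for separation "
            "(it must stay below the largest coupling)"
        )

    target = 0.5 * f * total_abs * step
    out = side_deconv(y, step, j1, direction=direction, stop_abs_integral=target)
    nz = np.nonzero(out)[0]
    if nz.size < 2:
        raise OverlapTooSevereError("deconvolution left no usable sub-multiplet")
    # in a clean separation the half-integral target is reached in an empty
    # zone (the second sub-multiplet occurrence is cancelled); stopping on
    # live signal means the overlap exceeds the largest coupling
    cut = nz[-1] if direction == "L2R" else nz[0]
    k = max(3, int(round((measure_fwhm(prep) or 4 * step) / step)))
    tail = out[max(0, cut - k + 1): cut + 1] if direction == "L2R" else out[cut: cut + k]
    cut_level = float(np.mean(np.abs(tail))) / max(float(np.max(np.abs(out))), 1e-300)
    if cut_level > 0.1:
        raise OverlapTooSevereError(
            f"half-integral stopping point falls on live signal "
            f"({cut_level:.0%} of the sub-multiplet maximum): overlap "
            f"exceeds the largest coupling, no couplings reported"
        )
    if direction == "L2R":
        sub = Spectrum1D(out[: nz[-1] + 1], prep.start_hz, step, region.spectrometer_mhz)
    else:
        sub = Spectrum1D(out[nz[0]:], prep.start_hz + nz[0] * step, step, region.spectrometer_mhz)

    sub_opts = replace(
        options,
        overlap_fraction=None,
        remove_offset=False,
        spin_map=options.spin_map[1:] if options.spin_map else None,
    )
    sub_result = extract_couplings(sub, sub_opts)

    js = [j1] + [c.j_hz for c in sub_result.sorted_couplings() for _ in range(c.degeneracy)]
    couplings = group_degenerate(js, options.degeneracy_tol_hz)
    center = sub.centroid_hz() + (j1 / 2.0 if direction == "L2R" else -j1 / 2.0)

    # consistency check on the full region: rebuilding this multiplet with
    # its share f of the region integral must leave a non-negative remainder
    # (the remainder is the neighbouring multiplet); large negative dips mean
    # the separation fabricated structure
    trial = MultipletResult(center_hz=center, couplings=couplings,
                            residual_singlet=sub_result.residual_singlet)
    recon = reconstruct(trial, grid=prep)
    denom = float(np.sum(recon.amplitudes))
    if denom != 0.0:
        scaled = recon.amplitudes * (f * float(np.sum(y)) / denom)
        negativity = float(np.sum(np.maximum(0.0, scaled - y))) / max(
            float(np.sum(np.abs(y))), 1e-300
        )
        if negativity > 0.1:
            raise OverlapTooSevereError(
                f"reconstructed multiplet exceeds the region by "
                f"{negativity:.0%} of its integral: overlap too severe, "
                f"no couplings reported"
            )

    passed = sub_result.validation_score >= options.validation_threshold
    return MultipletResult(
        center_hz=center,
        couplings=couplings,
        residual_singlet=sub_result.residual_singlet,
        validation_score=sub_result.validation_score,
        multiplicity=multiplicity_string(couplings, validated=passed),
        strategy_used={"overlap_fraction": f, "direction": direction},
        flags=list(sub_result.flags),
    )


# the success threshold (min_extremum_score) is itself a searched parameter:
# a strict pass rejects combination artifacts on clean multiplets, a lax pass
# keeps noisy data analysable; whether the bar relaxes with recursion depth
# is likewise searched; validation ranks the outcomes
_DEFAULT_STRATEGIES = (
    {"symmetrize_input": False, "symmetrize_each_step": True, "direction_policy": "both_sum",
     "min_extremum_score": 0.98, "min_score_decay": 0.0},
    {"symmetrize_input": False, "symmetrize_each_step": True, "direction_policy": "both_sum",
     "min_extremum_score": 0.98},
    {"symmetrize_input": False, "symmetrize_each_step": True, "direction_policy": "both_sum"},
    {"symmetrize_input": False, "symmetrize_each_step": False, "direction_policy": "both_sum"},
    {"symmetrize_input": True, "symmetrize_each_step": True, "direction_policy": "both_sum"},
    {"symmetrize_input": True, "symmetrize_each_step": False, "direction_policy": "both_sum"},
    {"symmetrize_input": False, "symmetrize_each_step": False, "direction_policy": "left_only"},
    {"symmetrize_input": False, "symmetrize_each_step": False, "direction_policy": "right_only"},
)


def strategy_search(
    region: Spectrum1D,
    option_grid: Optional[Sequence[dict]] = None,
    base_options: Optional[AnalysisOptions] = None,
) -> List[MultipletResult]:
    """Run the extraction under several option sets and rank the results.

    Results are ordered by validation score, ties broken by fewer couplings
    (parsimony) and then by the larger smallest J.
    """
    base = base_options or AnalysisOptions()
    grid = list(option_grid) if option_grid is not None else list(_DEFAULT_STRATEGIES)
    if not grid:
        raise ValueError("empty option grid")
    results: List[MultipletResult] = []
    for overrides in grid:
        try:
            res = extract_couplings(region, replace(base, **overrides))
        except (ValueError, OverlapTooSevereError):
            continue
        if res.couplings and not res.validation_score >= base.validation_threshold:
            # a failing result may just under-count a degenerate splitting
            # whose outer lines are weak; try raising multiplicities before
            # ranking
            res = post_degeneracy_search(res, region, replace(base, **overrides))
        results.append(res)

    def key(r: MultipletResult):
        s = r.validation_score
        if not math.isfinite(s):
            s = -1.0
        min_j = min((c.j_hz for c in r.couplings), default=float("inf"))
        return (-s, len(r.couplings), -min_j)

    results.sort(key=key)
    return results
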
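"""Inverse delta-function series M(J*), side-to-side deconvolution, and the
quality functions scanned over trial splittings.

The simplifying series M(J*) for a partner of spin S (n = 2S+1 lines) has a
core of n unit-weight sticks spaced J*, flanked on both sides by repeated
blocks of one stick of weight -(n-1) followed by n-1 unit sticks. Convolving
the (unit-total-weight) splitting pattern F_S(J) with M_S(J* = J) leaves a
single unit stick: any window of n consecutive M weights sums to zero except
the central one.

Rather than convolving with the full truncated series, the same result is
obtained by walking a cursor across the amplitude vector and subtracting, one
arm length J* ahead, the value accumulated at the cursor — once per remaining
line of the splitting pattern. Run left-to-right and right-to-left this yields
the two sub-multiplets S_L and S_R whose similarity (after trimming the
marginal artifact zones) measures the success of the simplification; their
scalar product as a function of J* is the quality curve whose extrema mark the
coupling constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

from .multiplet_model import StickPattern, amplitude_ratio_from_theta

__all__ = [
    "DeconvOutput",
    "QualityCurve",
    "convolve_sticks",
    "deconv_both",
    "first_extremum",
    "m_series",
    "quality_score",
    "scan_quality",
    "side_deconv",
]


# ---------------------------------------------------------------------------
# M(J*) series
# ---------------------------------------------------------------------------


def m_series(
    j_star_hz: float,
    spin: float = 0.5,
    theta_rad: float = 0.0,
    halfwidth_hz: float = None,
) -> StickPattern:
    """Two-sided simplifying series truncated at ``halfwidth_hz``.

    For spin 1/2 this reduces to sticks at +-(2k+1) J*/2 with signs (-1)^k.
    For a tilted doublet (theta != 0, spin 1/2 only) the |weights| shrink by
    the factor r = (1-sin theta)/(1+sin theta) per step toward the weaker
    line (low-frequency side) and grow by 1/r toward the stronger line,
    signs alternating.
    """
    if not j_star_hz > 0:
        raise ValueError("j_star_hz must be > 0")
    if halfwidth_hz is None or halfwidth_hz < j_star_hz:
        raise ValueError("halfwidth_hz must be given and >= j_star_hz")
    n = int(round(2 * spin)) + 1
    if theta_rad != 0.0 and n != 2:
        raise ValueError("tilted series defined for spin 1/2 only")

    if n == 2:
        r = amplitude_ratio_from_theta(theta_rad)
        offs, wts = [], []
        # rightward from +J*/2 (stronger-line side): grow by 1/r
        k = 0
        while (0.5 + k) * j_star_hz <= halfwidth_hz:
            offs.append((0.5 + k) * j_star_hz)
            wts.append((-1.0) ** k * (1.0 / r) ** k)
            k += 1
        # leftward from -J*/2 (weaker-line side): shrink by r
        k = 0
        while (0.5 + k) * j_star_hz <= halfwidth_hz:
            offs.append(-(0.5 + k) * j_star_hz)
            wts.append((-1.0) ** k * r**k)
            k += 1
        return StickPattern.from_lines(offs, wts)

    # general spin, theta = 0
    core_positions = (np.arange(n) - (n - 1) / 2.0) * j_star_hz
    offs = list(core_positions)
    wts = [1.0] * n
    # outward blocks: [-(n-1), +1 x (n-1)] at spacing J*
    pos = core_positions[-1]
    while True:
        block = []
        for i in range(n):
            pos += j_star_hz
            if pos > halfwidth_hz:
                block = block  # truncate mid-block
                break
            block.append((pos, -(n - 1.0) if i == 0 else 1.0))
        if not block:
            break
        for p, w in block:
            offs.append(p)
            wts.append(w)
            offs.append(-p)
            wts.append(w)
        if len(block) < n:
            break
    return StickPattern.from_lines(offs, wts)


# ---------------------------------------------------------------------------
# Stick convolution of a sampled region
# ---------------------------------------------------------------------------


def convolve_sticks(region: np.ndarray, step_hz: float, sticks: StickPattern) -> np.ndarray:
    """Convolve a sampled region with a stick pattern.

    ``out[i] = sum_k w_k * region(i - offsets_k/step)`` with linear
    interpolation at fractional-bin offsets and zero padding outside; the
    length is preserved.
    """
    if not step_hz > 0:
        raise ValueError("step_hz must be > 0")
    y = np.asarray(region, dtype=float)
    n = y.size
    out = np.zeros(n)
    for off, w in zip(sticks.offsets_hz, sticks.weights):
        s = off / step_hz
        i0 = math.floor(s)
        frac = s - i0
        for shift, wt in ((i0, (1.0 - frac) * w), (i0 + 1, frac * w)):
            if wt == 0.0:
                continue
            if shift >= n or shift <= -n:
                continue
            if shift >= 0:
                out[shift:] += wt * y[: n - shift]
            else:
                out[: n + shift] += wt * y[-shift:]
    return out


# ---------------------------------------------------------------------------
# Side-to-side recursion
# ---------------------------------------------------------------------------


def _walk(
    y: np.ndarray,
    d: float,
    rhos: np.ndarray,
    stop_abs_sum: Optional[float] = None,
) -> np.ndarray:
    """Running-cursor recursion out[i] = y[i] - sum_m rho_m * out[i - m d].

    Fractional arm lengths are read back with linear interpolation; positions
    before the start contribute zero. Computed in blocks of floor(d) points so
    each block only reads finalized values (identical to the per-point loop).
    When ``stop_abs_sum`` is given the walk stops once the running sum of
    |out| reaches it and the remainder is zeroed.
    """
    n = y.size
    out = np.zeros(n)
    L = int(math.floor(d))
    running = 0.0
    for b0 in range(0, n, L):
        b1 = min(b0 + L, n)
        acc = y[b0:b1].copy()
        idx = np.arange(b0, b1, dtype=float)
        for m, rho in enumerate(rhos, start=1):
            pos = idx - m * d
            i0 = np.floor(pos).astype(int)
            frac = pos - i0
            # positions before the start contribute nothing (out = in there)
            vals = np.zeros(b1 - b0)
            mask0 = i0 >= 0
            if mask0.any():
                vals[mask0] += (1.0 - frac[mask0]) * out[i0[mask0]]
            i1 = i0 + 1
            mask1 = mask0 & (frac > 0)
            if mask1.any():
                vals[mask1] += frac[mask1] * out[i1[mask1]]
            acc -= rho * vals
        out[b0:b1] = acc
        if stop_abs_sum is not None:
            cum = running + np.cumsum(np.abs(acc))
            over = np.nonzero(cum >= stop_abs_sum)[0]
            if over.size:
                cut = b0 + int(over[0]) + 1
                out[cut:] = 0.0
                return out
            running = cum[-1]
    return out


def _direction_rhos(n: int, theta_rad: float, left_to_right: bool) -> np.ndarray:
    if theta_rad == 0.0:
        return np.ones(n - 1)
    # tilted doublet: the weaker line sits on the low-frequency side, so the
    # L2R walk must subtract with the stronger/weaker ratio 1/r and the R2L
    # walk with r
    r = amplitude_ratio_from_theta(theta_rad)
    return np.array([1.0 / r if left_to_right else r])


def side_deconv(
    region: np.ndarray,
    step_hz: float,
    j_star_hz: float,
    direction: str = "L2R",
    spin: float = 0.5,
    theta_rad: float = 0.0,
    stop_abs_integral: Optional[float] = None,
) -> np.ndarray:
    """One-sided recursive deconvolution of a region at trial splitting J*.

    Returns S_L for ``direction="L2R"`` or S_R for ``"R2L"`` (computed by
    reversing the vector, running the same recursion, and reversing back).
    ``stop_abs_integral`` (in integral units, sum |out| * step) truncates the
    walk for overlapped-multiplet analyses.
    """
    y = np.asarray(region, dtype=float)
    if j_star_hz < 2.0 * step_hz:
        raise ValueError(
            f"trial splitting {j_star_hz:.4g} Hz is below twice the grid step "
            f"({step_hz:.4g} Hz): sub-resolution"
        )
    n = int(round(2 * spin)) + 1
    if theta_rad != 0.0 and n != 2:
        raise ValueError("tilted deconvolution defined for spin 1/2 only")
    if y.size <= (n - 1) * j_star_hz / step_hz:
        raise ValueError("region shorter than the deconvolution arm span")
    d = j_star_hz / step_hz
    stop = None if stop_abs_integral is None else stop_abs_integral / step_hz
    if direction == "L2R":
        return _walk(y, d, _direction_rhos(n, theta_rad, True), stop)
    if direction == "R2L":
        rev = _walk(y[::-1], d, _direction_rhos(n, theta_rad, False), stop)
        return rev[::-1]
    raise ValueError("direction must be 'L2R' or 'R2L'")


@dataclass
class DeconvOutput:
    """The pair of side-to-side deconvolution results at one trial J*."""

    s_left: Optional[np.ndarray]
    s_right: Optional[np.ndarray]
    margin_pts: int
    j_star_hz: float


def deconv_both(
    region: np.ndarray,
    step_hz: float,
    j_star_hz: float,
    spin: float = 0.5,
    theta_rad: float = 0.0,
) -> DeconvOutput:
    """Run the recursion in both directions; margin_pts is the artifact-zone
    width, one arm span (n-1) J* expressed in points."""
    n = int(round(2 * spin)) + 1
    s_l = side_deconv(region, step_hz, j_star_hz, "L2R", spin, theta_rad)
    s_r = side_deconv(region, step_hz, j_star_hz, "R2L", spin, theta_rad)
    margin = int(round((n - 1) * j_star_hz / step_hz))
    return DeconvOutput(s_l, s_r, margin, j_star_hz)


# ---------------------------------------------------------------------------
# Quality functions
# ---------------------------------------------------------------------------


def quality_score(
    output: DeconvOutput,
    mode: str = "symmetry",
    original: Optional[np.ndarray] = None,
    overlap_fraction: Optional[float] = None,
) -> float:
    """Degree of simplification achieved by one deconvolution.

    ``symmetry``: normalized scalar product of S_L and S_R after chopping the
    marginal artifact zones (S_R is read ``margin_pts`` later than S_L, which
    aligns the two sub-multiplets). ``half_integral``: 1 - 2 |x - 1/2| where
    x is the absolute-sum of the available side over that of the original
    region (scaled by ``overlap_fraction`` when only a share of the region
    belongs to the analysed multiplet); maximal when the absolute sum is
    exactly half.
    """
    if mode == "symmetry":
        if output.s_left is None or output.s_right is None:
            raise ValueError("symmetry mode needs both sides")
        m = min(output.margin_pts, output.s_left.size - 2)
        a = output.s_left[: output.s_left.size - m] if m > 0 else output.s_left
        b = output.s_right[m:] if m > 0 else output.s_right
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na == 0.0 or nb == 0.0:
            return 0.0
        return float(np.dot(a, b) / (na * nb))
    if mode == "half_integral":
        side = output.s_left if output.s_left is not None else output.s_right
        if side is None:
            raise ValueError("half_integral mode needs one side")
        if original is None:
            raise ValueError("half_integral mode needs the original region")
        total = float(np.sum(np.abs(original)))
        if total == 0.0:
            return 0.0
        if overlap_fraction is not None:
            # score over the analysed multiplet's share of the region plus
            # one arm length: the window must cover the full span where the
            # sub-multiplet echo is subtracted, otherwise truncating it
            # mid-support biases the extremum position
            f = overlap_fraction
            if output.s_left is not None:
                cum = np.cumsum(np.abs(original))
            else:
                cum = np.cumsum(np.abs(original[::-1]))
            idx = min(
                original.size - 1,
                int(np.searchsorted(cum, f * total)) + output.margin_pts,
            )
            prefix = side[: idx + 1] if output.s_left is not None else side[::-1][: idx + 1]
            x = float(np.sum(np.abs(prefix))) / (f * total)
        else:
            x = float(np.sum(np.abs(side))) / total
        return 1.0 - 2.0 * abs(x - 0.5)
    raise ValueError("mode must be 'symmetry' or 'half_integral'")


@dataclass
class QualityCurve:
    """Quality score as a function of trial splitting J* (decreasing grid)."""

    j_grid_hz: np.ndarray
    scores: np.ndarray
    extrema: list = field(default_factory=list)  # (j_hz refined, score) in scan order


def _eval_quality(
    region: np.ndarray,
    step_hz: float,
    j_star: float,
    spin: float,
    theta_rad: float,
    mode: str,
    original: Optional[np.ndarray],
    overlap_fraction: Optional[float],
    direction: str,
) -> float:
    n = int(round(2 * spin)) + 1
    if mode == "symmetry":
        return quality_score(deconv_both(region, step_hz, j_star, spin, theta_rad))
    side = side_deconv(region, step_hz, j_star, direction, spin, theta_rad)
    margin = int(round((n - 1) * j_star / step_hz))
    out = DeconvOutput(
        side if direction == "L2R" else None,
        side if direction == "R2L" else None,
        margin,
        j_star,
    )
    return quality_score(
        out, "half_integral",
        original if original is not None else region,
        overlap_fraction,
    )


def _refine_parabolic(j_grid: np.ndarray, scores: np.ndarray, i: int):
    """3-point parabolic refinement of a local maximum at grid index i."""
    if i <= 0 or i >= scores.size - 1:
        return float(j_grid[i]), float(scores[i])
    denom = scores[i - 1] - 2.0 * scores[i] + scores[i + 1]
    if denom >= 0:
        return float(j_grid[i]), float(scores[i])
    delta = 0.5 * (scores[i - 1] - scores[i + 1]) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    h = j_grid[i] - j_grid[i + 1]  # grid is decreasing
    j_ref = float(j_grid[i] - delta * h)
    s_ref = float(scores[i] - 0.25 * (scores[i - 1] - scores[i + 1]) * delta)
    return j_ref, s_ref


def scan_quality(
    region: np.ndarray,
    step_hz: float,
    j_grid: Sequence[float],
    spin: float = 0.5,
    theta_rad: float = 0.0,
    mode: str = "symmetry",
    original: Optional[np.ndarray] = None,
    overlap_fraction: Optional[float] = None,
    direction: str = "L2R",
    prominence: float = 0.02,
) -> QualityCurve:
    """Evaluate the quality score on a strictly decreasing J* grid and locate
    local maxima above ``prominence``, reported in scan order (largest J*
    first) after 3-point parabolic refinement."""
    j_grid = np.asarray(j_grid, dtype=float)
    if j_grid.size == 0:
        raise ValueError("empty J* grid")
    if j_grid.size > 1 and not np.all(np.diff(j_grid) < 0):
        raise ValueError("J* grid must be strictly decreasing")
    scores = np.array(
        [
            _eval_quality(region, step_hz, j, spin, theta_rad, mode, original,
                          overlap_fraction, direction)
            for j in j_grid
        ]
    )
    peaks, _ = find_peaks(scores, prominence=prominence)
    extrema = [_refine_parabolic(j_grid, scores, int(i)) for i in peaks]
    return QualityCurve(j_grid, scores, extrema)


def first_extremum(
    region: np.ndarray,
    step_hz: float,
    j_hi: float,
    j_lo: float,
    dj: float,
    spin: float = 0.5,
    theta_rad: float = 0.0,
    mode: str = "symmetry",
    original: Optional[np.ndarray] = None,
    overlap_fraction: Optional[float] = None,
    direction: str = "L2R",
    prominence: float = 0.02,
    min_score: float = -1.0,
    chunk: int = 32,
):
    """First quality-curve maximum encountered scanning J* downward.

    Evaluates the grid from ``j_hi`` down to ``j_lo`` incrementally and stops
    as soon as a local maximum with the requested prominence (and score at
    least ``min_score``) is confirmed, so trial values below the largest
    coupling are not visited. Returns ``(j_refined, score)`` or None.
    """
    j_lo = max(j_lo, 2.0 * step_hz)
    if j_hi < j_lo:
        return None
    n_vals = int(math.floor((j_hi - j_lo) / dj)) + 1
    grid = j_hi - dj * np.arange(n_vals)
    scores = []
    pos = 0
    while pos < n_vals:
        end = min(pos + chunk, n_vals)
        for j in grid[pos:end]:
            scores.append(
                _eval_quality(region, step_hz, float(j), spin, theta_rad, mode,
                              original, overlap_fraction, direction)
            )
        pos = end
        arr = np.asarray(scores)
        peaks, props = find_peaks(arr, prominence=prominence)
        for i in peaks:
            if arr[i] >= min_score:
                return _refine_parabolic(grid[: arr.size], arr, int(i))
    return None
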
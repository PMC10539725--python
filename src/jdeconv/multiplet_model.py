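"""Domain types, synthetic multiplet generation, preprocessing and reconstruction.

A first-order multiplet in a 1D NMR spectrum is modelled as the convolution
product of a spectral line shape (Lorentzian from T2 relaxation, Gaussian from
B0 inhomogeneity, or any mixture) with the stick pattern generated by the
scalar couplings: each coupling to a spin-``S`` partner splits every line into
``2S + 1`` equally spaced, equally weighted lines separated by ``J`` Hz.
Mild second-order ("roof") effects tilt a doublet so that the two lines carry
unequal weights with ratio ``r = (1 - sin(theta)) / (1 + sin(theta))``,
``theta = atan(J / delta_delta)``.

Everything downstream (deconvolution, recursion, validation) operates on the
types defined here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.special import wofz

__all__ = [
    "ALLOWED_SPINS",
    "CouplingSpec",
    "LineShape",
    "MultipletResult",
    "Spectrum1D",
    "StickPattern",
    "coupling_pattern",
    "amplitude_ratio_from_theta",
    "measure_fwhm",
    "multiplicity_string",
    "preprocess",
    "random_first_order_multiplet",
    "reconstruct",
    "synth_multiplet",
]

#: Partner spins supported by the splitting model (proton partners, deuterium,
#: 11B, 10B, ...).
ALLOWED_SPINS = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0)

#: Sticks closer than this (Hz) are merged by weight addition.
STICK_MERGE_TOL_HZ = 1e-6


# ---------------------------------------------------------------------------
# Spectrum container
# ---------------------------------------------------------------------------


@dataclass
class Spectrum1D:
    """Real amplitudes on a uniform frequency grid.

    Parameters
    ----------
    amplitudes
        Real amplitude vector, ordered by increasing frequency.
    start_hz
        Frequency of the first point in Hz.
    step_hz
        Grid spacing in Hz per point (> 0).
    spectrometer_mhz
        Observe frequency in MHz; enables Hz <-> ppm conversion when present.
    """

    amplitudes: np.ndarray
    start_hz: float
    step_hz: float
    spectrometer_mhz: Optional[float] = None

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.amplitudes.ndim != 1 or self.amplitudes.size < 2:
            raise ValueError("amplitude vector must be 1-D with length >= 2")
        if not self.step_hz > 0:
            raise ValueError("step_hz must be > 0")

    def __len__(self) -> int:
        return self.amplitudes.size

    @property
    def freqs_hz(self) -> np.ndarray:
        return self.start_hz + self.step_hz * np.arange(self.amplitudes.size)

    @property
    def width_hz(self) -> float:
        return self.step_hz * (self.amplitudes.size - 1)

    @property
    def ppm(self) -> np.ndarray:
        if self.spectrometer_mhz is None:
            raise ValueError("spectrometer_mhz not set; ppm axis unavailable")
        return self.freqs_hz / self.spectrometer_mhz

    def integral(self) -> float:
        return float(np.sum(self.amplitudes) * self.step_hz)

    def centroid_hz(self) -> float:
        w = np.abs(self.amplitudes)
        total = w.sum()
        if total == 0:
            return self.start_hz + 0.5 * self.width_hz
        return float(np.sum(self.freqs_hz * w) / total)

    def select(self, lo_hz: float, hi_hz: float) -> "Spectrum1D":
        """Sub-spectrum covering [lo_hz, hi_hz]."""
        if not lo_hz < hi_hz:
            raise ValueError("lo_hz must be < hi_hz")
        i0 = max(0, int(math.ceil((lo_hz - self.start_hz) / self.step_hz)))
        i1 = min(len(self), int(math.floor((hi_hz - self.start_hz) / self.step_hz)) + 1)
        if i1 - i0 < 2:
            raise ValueError("selected region holds fewer than 2 points")
        return Spectrum1D(
            self.amplitudes[i0:i1].copy(),
            self.start_hz + i0 * self.step_hz,
            self.step_hz,
            self.spectrometer_mhz,
        )

    def with_amplitudes(self, amplitudes: np.ndarray, start_hz: Optional[float] = None) -> "Spectrum1D":
        return Spectrum1D(
            np.asarray(amplitudes, dtype=float),
            self.start_hz if start_hz is None else start_hz,
            self.step_hz,
            self.spectrometer_mhz,
        )


# ---------------------------------------------------------------------------
# Stick patterns
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StickPattern:
    """Signed, weighted delta functions at frequency offsets from a centre.

    Offsets are strictly increasing; construction merges sticks closer than
    ``merge_tol`` by adding weights.
    """

    offsets_hz: np.ndarray
    weights: np.ndarray

    @staticmethod
    def from_lines(
        offsets_hz: Sequence[float],
        weights: Sequence[float],
        merge_tol: float = STICK_MERGE_TOL_HZ,
    ) -> "StickPattern":
        off = np.asarray(offsets_hz, dtype=float)
        w = np.asarray(weights, dtype=float)
        if off.shape != w.shape:
            raise ValueError("offsets and weights must have the same length")
        order = np.argsort(off, kind="stable")
        off, w = off[order], w[order]
        mo, mw = [], []
        for o, wt in zip(off, w):
            if mo and o - mo[-1] <= merge_tol:
                mw[-1] += wt
            else:
                mo.append(o)
                mw.append(wt)
        return StickPattern(np.array(mo), np.array(mw))

    def __len__(self) -> int:
        return self.offsets_hz.size

    @property
    def width_hz(self) -> float:
        if len(self) == 0:
            return 0.0
        return float(self.offsets_hz[-1] - self.offsets_hz[0])

    def convolve(self, other: "StickPattern") -> "StickPattern":
        """Pairwise offset-sum, weight-product convolution of two patterns."""
        off = np.add.outer(self.offsets_hz, other.offsets_hz).ravel()
        w = np.multiply.outer(self.weights, other.weights).ravel()
        return StickPattern.from_lines(off, w)

    def prune(self, rel_tol: float = 1e-12) -> "StickPattern":
        """Drop sticks whose |weight| is negligible relative to the largest."""
        if len(self) == 0:
            return self
        keep = np.abs(self.weights) > rel_tol * np.abs(self.weights).max()
        return StickPattern(self.offsets_hz[keep], self.weights[keep])


# ---------------------------------------------------------------------------
# Couplings
# ---------------------------------------------------------------------------


def amplitude_ratio_from_theta(theta_rad: float) -> float:
    """Doublet weight ratio r = (1 - sin(theta)) / (1 + sin(theta))."""
    s = math.sin(theta_rad)
    return (1.0 - s) / (1.0 + s)


@dataclass(frozen=True)
class CouplingSpec:
    """One scalar coupling: J in Hz, partner spin S, number of equivalent
    partners, and an optional roof-tilt angle theta (doublets only).

    ``tilt_side`` records which side the coupling partner lies on: +1 when
    the stronger doublet line is on the high-frequency side (the default
    convention), -1 for the mirror image.
    """

    j_hz: float
    spin: float = 0.5
    degeneracy: int = 1
    theta_rad: float = 0.0
    tilt_side: int = 1

    def __post_init__(self) -> None:
        if not self.j_hz > 0:
            raise ValueError("j_hz must be > 0")
        if not any(abs(self.spin - s) < 1e-9 for s in ALLOWED_SPINS):
            raise ValueError(f"spin must be one of {ALLOWED_SPINS}")
        if self.degeneracy < 1:
            raise ValueError("degeneracy must be >= 1")
        if not (0.0 <= self.theta_rad < math.pi / 2):
            raise ValueError("theta_rad must lie in [0, pi/2)")
        if self.theta_rad != 0.0 and (self.spin != 0.5 or self.degeneracy != 1):
            raise ValueError(
                "tilted patterns are defined for a single spin-1/2 partner only"
            )
        if self.tilt_side not in (1, -1):
            raise ValueError("tilt_side must be +1 or -1")

    @property
    def n_lines_elementary(self) -> int:
        return int(round(2 * self.spin)) + 1


def _elementary_pattern(c: CouplingSpec) -> StickPattern:
    n = c.n_lines_elementary
    offsets = (np.arange(n) - (n - 1) / 2.0) * c.j_hz
    if c.theta_rad != 0.0:
        r = amplitude_ratio_from_theta(c.theta_rad)
        # weaker line on the low-frequency (high-field) side; the stronger
        # line points toward the coupling partner
        weights = np.array([r, 1.0]) / (1.0 + r)
        if c.tilt_side == -1:
            weights = weights[::-1]
    else:
        weights = np.full(n, 1.0 / n)
    return StickPattern(offsets, weights)


def coupling_pattern(couplings: Sequence[CouplingSpec]) -> StickPattern:
    """Stick pattern of a multiplet: convolution of the elementary patterns.

    One spin-1/2 coupling gives sticks at +-J/2 with weight 1/2 each; a
    spin-S coupling gives 2S+1 equal sticks spaced J and centred at 0;
    degeneracy ``n`` applies the elementary pattern ``n`` times (binomial
    weights for spin 1/2). The total weight is normalized to 1.
    """
    pat = StickPattern(np.array([0.0]), np.array([1.0]))
    for c in couplings:
        elem = _elementary_pattern(c)
        for _ in range(c.degeneracy):
            pat = pat.convolve(elem)
    return pat


# ---------------------------------------------------------------------------
# Line shapes
# ---------------------------------------------------------------------------


@dataclass
class LineShape:
    """Spectral line shape with optional zero-order phase error.

    ``kind`` is one of ``lorentzian``, ``gaussian``, ``voigt`` or
    ``empirical``. Analytic shapes have unit integral; a phase error mixes the
    absorptive and dispersive components as ``cos(phi) A + sin(phi) D``.
    For ``voigt``, ``gauss_frac`` apportions the width between the Gaussian
    and Lorentzian components. An empirical shape carries its own samples on
    a uniform grid (offsets relative to its centroid).
    """

    kind: str = "lorentzian"
    fwhm_hz: float = 1.0
    phase_deg: float = 0.0
    gauss_frac: float = 0.5
    samples: Optional[np.ndarray] = None
    sample_step_hz: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("lorentzian", "gaussian", "voigt", "empirical"):
            raise ValueError(f"unknown line shape kind {self.kind!r}")
        if self.kind != "empirical" and not self.fwhm_hz > 0:
            raise ValueError("fwhm_hz must be > 0")
        if self.kind == "empirical":
            if self.samples is None or self.sample_step_hz is None:
                raise ValueError("empirical shape needs samples and sample_step_hz")
            self.samples = np.asarray(self.samples, dtype=float)
            if not np.isfinite(self.samples).all():
                raise ValueError("empirical samples must be finite")
            if self.samples.sum() * self.sample_step_hz <= 0:
                raise ValueError("empirical shape must integrate to a positive value")

    @staticmethod
    def empirical_from(spectrum: Spectrum1D) -> "LineShape":
        return LineShape(
            kind="empirical",
            fwhm_hz=max(measure_fwhm(spectrum) or spectrum.step_hz, spectrum.step_hz),
            samples=spectrum.amplitudes.copy(),
            sample_step_hz=spectrum.step_hz,
        )

    def profile(self, x_hz: np.ndarray) -> np.ndarray:
        """Evaluate the shape at offsets ``x_hz`` from its centre."""
        x = np.asarray(x_hz, dtype=float)
        phi = math.radians(self.phase_deg)
        if self.kind == "lorentzian":
            g = self.fwhm_hz / 2.0
            absorb = (g / math.pi) / (x * x + g * g)
            if phi == 0.0:
                return absorb
            disperse = (x / math.pi) / (x * x + g * g)
            return math.cos(phi) * absorb + math.sin(phi) * disperse
        if self.kind in ("gaussian", "voigt"):
            if self.kind == "gaussian":
                fwhm_g, fwhm_l = self.fwhm_hz, 0.0
            else:
                fwhm_g = self.gauss_frac * self.fwhm_hz
                fwhm_l = (1.0 - self.gauss_frac) * self.fwhm_hz
            sigma = max(fwhm_g, 1e-12) / (2.0 * math.sqrt(2.0 * math.log(2.0)))
            gamma = fwhm_l / 2.0
            z = (x + 1j * gamma) / (sigma * math.sqrt(2.0))
            w = wofz(z) / (sigma * math.sqrt(2.0 * math.pi))
            if phi == 0.0:
                return w.real
            return math.cos(phi) * w.real + math.sin(phi) * w.imag
        # empirical
        n = self.samples.size
        centre = float(
            np.sum(np.arange(n) * np.abs(self.samples)) / max(np.abs(self.samples).sum(), 1e-300)
        )
        offs = (np.arange(n) - centre) * self.sample_step_hz
        return np.interp(x, offs, self.samples, left=0.0, right=0.0)


# ---------------------------------------------------------------------------
# Synthesis
# ---------------------------------------------------------------------------


def synth_multiplet(
    center_hz: float,
    couplings: Sequence[CouplingSpec],
    lineshape: Optional[LineShape] = None,
    *,
    step_hz: Optional[float] = None,
    start_hz: Optional[float] = None,
    n_points: Optional[int] = None,
    margin_factor: float = 6.0,
    noise_sd: float = 0.0,
    baseline_offset: float = 0.0,
    seed: Optional[int] = None,
    spectrometer_mhz: Optional[float] = None,
) -> Spectrum1D:
    """Synthesize a multiplet: line shape convolved with the coupling pattern.

    The grid defaults to the pattern width plus ``margin_factor`` * fwhm on
    each side, sampled at fwhm/8. An explicit grid must leave at least
    5 * fwhm of margin around the stick pattern. Before noise, the spectral
    integral equals the line shape integral (pattern weights sum to 1).
    """
    lineshape = lineshape or LineShape()
    pattern = coupling_pattern(couplings)
    fwhm = lineshape.fwhm_hz
    if step_hz is None:
        step_hz = fwhm / 8.0
    if start_hz is None or n_points is None:
        half = 0.5 * pattern.width_hz + margin_factor * fwhm
        n_points = int(math.ceil(2 * half / step_hz)) + 1
        start_hz = center_hz - 0.5 * (n_points - 1) * step_hz
    lo, hi = start_hz, start_hz + (n_points - 1) * step_hz
    required = pattern.width_hz + 10.0 * fwhm
    if hi - lo < required:
        raise ValueError(
            f"grid too narrow for the coupling pattern: need at least "
            f"{required:.2f} Hz (pattern width {pattern.width_hz:.2f} Hz "
            f"plus 5*fwhm margins), got {hi - lo:.2f} Hz"
        )
    freqs = start_hz + step_hz * np.arange(n_points)
    y = np.zeros(n_points)
    for off, w in zip(pattern.offsets_hz, pattern.weights):
        y += w * lineshape.profile(freqs - center_hz - off)
    y += baseline_offset
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=n_points)
    return Spectrum1D(y, start_hz, step_hz, spectrometer_mhz)


def random_first_order_multiplet(seed: int):
    """Draw one random first-order multiplet for recovery studies.

    Conditions: 1-4 spin-1/2 couplings with J in [1.5, 20] Hz and pairwise
    gaps above max(0.5 Hz, one grid step); Lorentzian fwhm in [0.5, 3] Hz;
    signal-to-noise ratio of at least 50 at the tallest line. Returns
    ``(spectrum, sorted true J list, fwhm)``.
    """
    rng = np.random.default_rng(seed)
    fwhm = float(rng.uniform(0.5, 3.0))
    step = min(fwhm / 6.0, 0.2)
    n_j = int(rng.integers(1, 5))
    gap = max(0.5, step)
    while True:
        js = np.sort(rng.uniform(1.5, 20.0, size=n_j))[::-1]
        if n_j == 1 or np.min(np.abs(np.diff(js))) > gap:
            break
    couplings = [CouplingSpec(j_hz=float(j)) for j in js]
    shape = LineShape("lorentzian", fwhm_hz=fwhm)
    # the analysed window must stay wider than twice the largest coupling
    # throughout the recursion (trial splittings are scanned up to half the
    # region width), so the flat margins scale with the total splitting
    margin = 0.6 * float(np.sum(js)) + 6.0 * fwhm
    clean = synth_multiplet(0.0, couplings, shape, step_hz=step,
                            margin_factor=margin / fwhm)
    snr = float(rng.uniform(50.0, 200.0))
    noise_sd = clean.amplitudes.max() / snr
    noisy = clean.amplitudes + rng.normal(0.0, noise_sd, size=len(clean))
    return clean.with_amplitudes(noisy), [float(j) for j in js], fwhm


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def preprocess(
    spectrum: Spectrum1D,
    *,
    symmetrize: bool = False,
    remove_offset: bool = False,
    second_derivative: bool = False,
    center_hz: Optional[float] = None,
) -> Spectrum1D:
    """Baseline-offset removal, symmetrization about a centre, and the
    (negated) numerical second derivative, in that order.

    Offset removal subtracts the median of the outer 5 % margin points.
    Symmetrization averages the vector with its mirror image about
    ``center_hz`` (default: intensity centroid). The second derivative is
    computed by central differences and negated so that peaks stay positive.
    """
    y = spectrum.amplitudes.copy()
    freqs = spectrum.freqs_hz
    if remove_offset:
        k = max(1, int(0.05 * y.size))
        y = y - np.median(np.concatenate([y[:k], y[-k:]]))
    if symmetrize:
        c = spectrum.centroid_hz() if center_hz is None else center_hz
        if not (freqs[0] <= c <= freqs[-1]):
            raise ValueError("center_hz must lie inside the region")
        mirrored = np.interp(2.0 * c - freqs, freqs, y, left=0.0, right=0.0)
        y = 0.5 * (y + mirrored)
    if second_derivative:
        d2 = np.zeros_like(y)
        d2[1:-1] = -(y[2:] - 2.0 * y[1:-1] + y[:-2]) / spectrum.step_hz**2
        y = d2
    return spectrum.with_amplitudes(y)


def measure_fwhm(spectrum: Spectrum1D) -> Optional[float]:
    """Full width at half maximum of the tallest feature, by linear
    interpolation of the half-height crossings; None if not measurable."""
    y = spectrum.amplitudes
    i = int(np.argmax(y))
    half = y[i] / 2.0
    if y[i] <= 0:
        return None
    left = None
    for k in range(i, 0, -1):
        if y[k - 1] < half <= y[k]:
            frac = (y[k] - half) / (y[k] - y[k - 1])
            left = k - frac
            break
    right = None
    for k in range(i, y.size - 1):
        if y[k + 1] < half <= y[k]:
            frac = (y[k] - half) / (y[k] - y[k + 1])
            right = k + frac
            break
    if left is None or right is None:
        return None
    return float((right - left) * spectrum.step_hz)


# ---------------------------------------------------------------------------
# Results and reconstruction
# ---------------------------------------------------------------------------


_MULTIPLICITY_LETTERS = {
    2: "d",
    3: "t",
    4: "q",
    5: "quint",
    6: "sext",
    7: "hept",
    8: "oct",
    9: "non",
}


def multiplicity_string(couplings: Sequence[CouplingSpec], validated: bool = True) -> str:
    """Conventional multiplicity label, couplings in descending-J order.

    A coupling contributing ``k`` equally spaced lines maps to the standard
    letter (2 -> d, 3 -> t, 4 -> q, ...); an empty list is a singlet "s" and a
    failed validation is reported as "m".
    """
    if not validated:
        return "m"
    if not couplings:
        return "s"
    parts = []
    for c in sorted(couplings, key=lambda c: -c.j_hz):
        n_lines = int(round(2 * c.spin * c.degeneracy)) + 1
        parts.append(_MULTIPLICITY_LETTERS.get(n_lines, f"{n_lines}-plet"))
    return "".join(p if len(p) == 1 else f" {p} " for p in parts).replace("  ", " ").strip()


@dataclass
class MultipletResult:
    """Extracted description of one multiplet."""

    center_hz: float
    couplings: list = field(default_factory=list)
    residual_singlet: Optional[Spectrum1D] = None
    validation_score: float = float("nan")
    multiplicity: str = ""
    partner_estimates: list = field(default_factory=list)
    strategy_used: Optional[dict] = None
    flags: list = field(default_factory=list)

    def sorted_couplings(self) -> list:
        return sorted(self.couplings, key=lambda c: -c.j_hz)

    def replace(self, **kw) -> "MultipletResult":
        return replace(self, **kw)


def reconstruct(
    result: MultipletResult,
    lineshape: Optional[LineShape] = None,
    grid: Optional[Spectrum1D] = None,
    reference: Optional[Spectrum1D] = None,
) -> Spectrum1D:
    """Rebuild a multiplet from an extracted result.

    The line shape defaults to the result's residual singlet (the final
    simplified shape), used as an empirical profile; the coupling pattern is
    reintroduced around ``result.center_hz``. When ``reference`` is given the
    amplitude is least-squares scaled to it.
    """
    if lineshape is None:
        if result.residual_singlet is None:
            raise ValueError("no line shape available: result has no residual singlet")
        lineshape = LineShape.empirical_from(result.residual_singlet)
    base = grid if grid is not None else (reference if reference is not None else result.residual_singlet)
    if base is None:
        raise ValueError("no grid available for reconstruction")
    freqs = base.freqs_hz
    pattern = coupling_pattern(result.couplings)
    # center_hz is the multiplet's intensity centroid; for tilted patterns
    # the weighted stick centroid is offset from the geometric centre, so
    # anchor the pattern by its own centroid
    w_total = float(np.sum(pattern.weights))
    pat_centroid = (
        float(np.sum(pattern.offsets_hz * pattern.weights)) / w_total if w_total else 0.0
    )
    y = np.zeros(freqs.size)
    for off, w in zip(pattern.offsets_hz, pattern.weights):
        y += w * lineshape.profile(freqs - result.center_hz - (off - pat_centroid))
    if reference is not None:
        denom = float(np.dot(y, y))
        if denom > 0:
            y *= float(np.dot(y, reference.amplitudes)) / denom
    return base.with_amplitudes(y)
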
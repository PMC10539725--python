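"""Shared fixtures: synthetic multiplets used across the suite."""

import numpy as np
import pytest

from jdeconv import (
    CouplingSpec,
    LineShape,
    Spectrum1D,
    coupling_pattern,
    synth_multiplet,
)


def build_two_multiplets(ja, jb, overlap_hz, fwhm=1.0, step=0.1, weight_b=1.0):
    """Two first-order multiplets on one grid with supports overlapping by
    ``overlap_hz``; returns (region, centre_of_A, centre_of_B)."""
    wa, wb = sum(ja) / 2.0, sum(jb) / 2.0
    sep = wa + wb - overlap_hz
    shape = LineShape("lorentzian", fwhm)
    lo, hi = -wa - 12.0, sep + wb + 12.0
    n = int((hi - lo) / step) + 1
    freqs = lo + step * np.arange(n)
    y = np.zeros(n)
    for centre, js, w in ((0.0, ja, 1.0), (sep, jb, weight_b)):
        pat = coupling_pattern([CouplingSpec(j) for j in js])
        for off, wt in zip(pat.offsets_hz, pat.weights):
            y += w * wt * shape.profile(freqs - centre - off)
    return Spectrum1D(y, lo, step), 0.0, sep


def flat_j_list(result):
    """Couplings of a result expanded by degeneracy, descending."""
    return sorted(
        (c.j_hz for c in result.couplings for _ in range(c.degeneracy)),
        reverse=True,
    )


@pytest.fixture(scope="session")
def doublet_415():
    """Noiseless doublet J = 4.15 Hz, Lorentzian fwhm 0.8 Hz, 0.05 Hz grid."""
    return synth_multiplet(
        0.0, [CouplingSpec(4.15)], LineShape("lorentzian", 0.8), step_hz=0.05
    )


@pytest.fixture(scope="session")
def dd_632_422():
    """Double doublet 6.32 / 4.22 Hz at 2.7 Hz width: lines overlap and the
    naive reading would be a 5.27 Hz triplet."""
    return synth_multiplet(
        0.0,
        [CouplingSpec(6.32), CouplingSpec(4.22)],
        LineShape("lorentzian", 2.7),
        step_hz=0.05,
    )


@pytest.fixture(scope="session")
def quartet_s32():
    """1:1:1:1 quartet from a spin-3/2 partner, J = 81.6 Hz."""
    return synth_multiplet(
        0.0,
        [CouplingSpec(81.6, spin=1.5)],
        LineShape("lorentzian", 2.0),
        step_hz=0.25,
        margin_factor=30.0,
    )
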
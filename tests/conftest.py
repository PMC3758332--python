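"""Shared fixtures and independent oracle implementations.

The oracles here deliberately re-derive quantities by brute force
(per-threshold component labeling, explicit kernel sums, textbook
formulas) and must stay independent of the library code paths they
check.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from mtconj import (
    CompartmentMap, NoiseSpec, PhantomSpec, build_design, simulate_cohort,
)


def brute_force_tfce(stat, mask, E=0.5, H=2.0, dh=None, n_steps=100,
                     connectivity=26):
    """Independent TFCE: label components at every threshold separately
    and accumulate e^E * h^H * dh (positive part only)."""
    vals = np.where(mask, stat, 0.0)
    vmax = vals.max(initial=0.0)
    if vmax <= 0:
        return np.zeros(stat.shape)
    if dh is None:
        dh = vmax / n_steps
    n = int(np.floor(vmax / dh + 1e-9))
    out = np.zeros(stat.shape)
    if connectivity == 26:
        structure = np.ones((3, 3, 3))
    elif connectivity == 6:
        structure = None
    else:
        structure = ndimage.generate_binary_structure(3, 2)
    for k in range(1, n + 1):
        h = k * dh
        sup = mask & (vals >= h)
        lab, ncomp = ndimage.label(sup, structure=structure)
        if ncomp == 0:
            continue
        sizes = np.bincount(lab.ravel()).astype(float)
        out += np.where(sup, sizes[lab] ** E * h**H * dh, 0.0)
    return out


def brute_force_tfce_signed(stat, mask, **kw):
    return brute_force_tfce(stat, mask, **kw) - brute_force_tfce(-stat, mask, **kw)


def pooled_two_sample_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Textbook pooled-variance two-sample t, feature-wise."""
    na, nb = a.shape[0], b.shape[0]
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    return (a.mean(axis=0) - b.mean(axis=0)) / np.sqrt(sp2 * (1 / na + 1 / nb))


def maps_from_store(cohort, volumes, mask=None) -> list[CompartmentMap]:
    """Wrap raw subject MTR maps as CompartmentMaps aligned with rows."""
    shape = volumes.gm.shape
    m = np.ones(shape, dtype=bool) if mask is None else mask
    return [CompartmentMap("WM", volumes.mtr[s], m)
            for s in cohort["subject_id"]]


@pytest.fixture(scope="session")
def default_phantom() -> PhantomSpec:
    return PhantomSpec.default()


@pytest.fixture(scope="session")
def small_null_cohort(default_phantom):
    """Two groups of 8 on the default grid, no effects; session-cached."""
    cohort, volumes = simulate_cohort(
        default_phantom, {"control": 8, "sMCI": 8}, (),
        NoiseSpec(sigma=1.5, smoothness_fwhm_mm=4.0, seed=42),
    )
    return cohort, volumes


@pytest.fixture(scope="session")
def small_design(small_null_cohort):
    cohort, _ = small_null_cohort
    return build_design(cohort)
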
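"""Group-wise comparison of CD spectra.

Given named groups of spectra on a common wavelength grid, computes group
means and per-wavelength standard deviations, difference spectra of the
means for every group pair, and the full lists of pairwise Euclidean
distances within each group (intra) and across each group pair (inter).
Optionally every spectrum is first L2-normalized (divided by its Euclidean
norm), which compares shapes while discarding intensity differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .spectra import SpectraSet, SpectraError


@dataclass
class ComparisonResult:
    wavelengths: np.ndarray
    group_means: dict[str, np.ndarray]
    group_sds: dict[str, np.ndarray]
    differences: dict[tuple[str, str], np.ndarray]
    intra_distances: dict[str, np.ndarray]
    inter_distances: dict[tuple[str, str], np.ndarray]
    normalized: bool


def _as_matrix(group) -> np.ndarray:
    if isinstance(group, SpectraSet):
        return group.values
    return np.atleast_2d(np.asarray(group, dtype=float))


def l2_normalize(values: np.ndarray) -> np.ndarray:
    """Divide each column by its Euclidean norm (idempotent, scale-invariant)."""
    norms = np.linalg.norm(values, axis=0, keepdims=True)
    if np.any(norms == 0):
        raise SpectraError("cannot L2-normalize an all-zero spectrum")
    return values / norms


def compare_groups(
    groups: dict[str, "SpectraSet | np.ndarray"],
    normalize: bool = False,
    wavelengths: np.ndarray | None = None,
) -> ComparisonResult:
    """Means, SDs, difference spectra and intra/inter Euclidean distances.

    SDs use the sample convention (n−1); singleton groups report SD 0 with a
    warning.  Inter-group distances are all cross-group pairwise spectrum
    distances, from which either a distribution summary or a mean-to-mean
    distance can be formed.
    """
    if not groups:
        raise SpectraError("at least one group required")
    mats: dict[str, np.ndarray] = {}
    wl = wavelengths
    for name, g in groups.items():
        m = _as_matrix(g)
        if isinstance(g, SpectraSet):
            if wl is None:
                wl = g.wavelengths
            elif not np.array_equal(wl, g.wavelengths):
                raise SpectraError(f"group {name!r} is on a different grid")
        mats[name] = l2_normalize(m) if normalize else m
    n_wl = {m.shape[0] for m in mats.values()}
    if len(n_wl) > 1:
        raise SpectraError("groups are on different wavelength grids")
    if wl is None:
        wl = np.arange(n_wl.pop())

    means, sds, intra = {}, {}, {}
    for name, m in mats.items():
        means[name] = m.mean(axis=1)
        if m.shape[1] == 1:
            warnings.warn(f"group {name!r} has a single spectrum; SD set to 0",
                          stacklevel=2)
            sds[name] = np.zeros(m.shape[0])
        else:
            sds[name] = m.std(axis=1, ddof=1)
        intra[name] = np.array(
            [
                np.linalg.norm(m[:, i] - m[:, j])
                for i, j in combinations(range(m.shape[1]), 2)
            ]
        )
    diffs, inter = {}, {}
    for a, b in combinations(mats, 2):
        diffs[(a, b)] = means[a] - means[b]
        ma, mb = mats[a], mats[b]
        inter[(a, b)] = np.array(
            [
                np.linalg.norm(ma[:, i] - mb[:, j])
                for i in range(ma.shape[1])
                for j in range(mb.shape[1])
            ]
        )
    return ComparisonResult(
        wavelengths=np.asarray(wl, dtype=float),
        group_means=means,
        group_sds=sds,
        differences=diffs,
        intra_distances=intra,
        inter_distances=inter,
        normalized=normalize,
    )


def difference_spectrum(a: SpectraSet, b: SpectraSet) -> SpectraSet:
    """Mean(a) − mean(b) per wavelength — e.g. complex minus free component
    to isolate the spectrum of the bound partner."""
    if a.unit != b.unit:
        raise SpectraError(f"unit mismatch: {a.unit} vs {b.unit}")
    if not np.array_equal(a.wavelengths, b.wavelengths):
        raise SpectraError("difference requires a common wavelength grid")
    diff = a.values.mean(axis=1) - b.values.mean(axis=1)
    return SpectraSet(a.wavelengths.copy(), diff[:, None], a.unit, ["difference"])
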
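"""SVD/PCA decomposition of spectra series, with rotation and inversion.

A series of spectra measured along an experimental parameter (temperature,
denaturant, ...) is reduced to a small set of orthonormal basis spectra and a
coefficient matrix whose rows trace how much of each basis spectrum every
measured spectrum contains.  ``svd`` factorizes the raw wavelength × spectrum
matrix; ``pca`` first subtracts the per-wavelength mean across spectra
(no Z-score scaling), so PCA equals SVD of the centered matrix.

Singular values are folded into the coefficients, leaving unit-norm basis
columns; each basis column is oriented so its largest-magnitude element is
positive, which makes outputs reproducible across linear-algebra backends.

The rotation operation performs an orthogonal change of basis inside the
retained k-dimensional subspace so that the first basis spectrum resembles
the first measured spectrum (e.g. the lowest temperature); reconstruction at
rank k is unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .spectra import SpectraSet, SpectraError


@dataclass(frozen=True)
class DecompositionResult:
    method: str  # 'svd' or 'pca'
    wavelengths: np.ndarray
    mean_spectrum: np.ndarray  # zeros for svd
    basis: np.ndarray  # (n_wavelengths, k_max), orthonormal columns
    coefficients: np.ndarray  # (k_max, n_spectra)
    singular_values: np.ndarray
    explained_variance: np.ndarray  # cumulative fractions
    param_values: np.ndarray | None
    unit: str = "millidegrees"
    first_spectrum: np.ndarray | None = None  # rotation target

    @property
    def k_max(self) -> int:
        return self.basis.shape[1]


def decompose(s: SpectraSet, method: str = "svd") -> DecompositionResult:
    """Factorize a spectra series into basis spectra and coefficients."""
    if method not in ("svd", "pca"):
        raise SpectraError(f"unknown method {method!r}; expected 'svd' or 'pca'")
    if s.n_spectra < 2:
        raise SpectraError("decomposition requires at least 2 spectra")
    X = s.values
    mean = X.mean(axis=1) if method == "pca" else np.zeros(s.n_wavelengths)
    U, sv, Vt = np.linalg.svd(X - mean[:, None], full_matrices=False)
    # orient each basis column: largest-|.| element positive
    signs = np.sign(U[np.argmax(np.abs(U), axis=0), np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    U = U * signs
    Vt = Vt * signs[:, None]
    coeff = sv[:, None] * Vt
    total = float(np.sum(sv**2))
    explained = np.cumsum(sv**2) / total if total > 0 else np.ones_like(sv)
    return DecompositionResult(
        method=method,
        wavelengths=s.wavelengths.copy(),
        mean_spectrum=mean,
        basis=U,
        coefficients=coeff,
        singular_values=sv,
        explained_variance=explained,
        param_values=None if s.param_values is None else s.param_values.copy(),
        unit=s.unit,
        first_spectrum=X[:, 0].copy(),
    )


def reconstruct(d: DecompositionResult, k: int) -> SpectraSet:
    """Rebuild the spectra from the first k components (plus mean for PCA)."""
    if not 1 <= k <= d.k_max:
        raise SpectraError(f"k must be in [1, {d.k_max}], got {k}")
    values = d.mean_spectrum[:, None] + d.basis[:, :k] @ d.coefficients[:k, :]
    return SpectraSet(
        d.wavelengths.copy(),
        values,
        d.unit,
        param_values=None if d.param_values is None else d.param_values.copy(),
    )


def rotate_to_first_spectrum(d: DecompositionResult, k: int) -> DecompositionResult:
    """Orthogonal rotation within the rank-k subspace so basis column 1 points
    along the projection of the first measured spectrum.

    The remaining columns are completed by Gram–Schmidt from the old basis;
    the coefficient block is transformed by the inverse map, so rank-k
    reconstruction is unchanged.
    """
    if not 1 <= k <= d.k_max:
        raise SpectraError(f"k must be in [1, {d.k_max}], got {k}")
    if d.first_spectrum is None:
        raise SpectraError("decomposition lacks the first-spectrum target")
    B = d.basis[:, :k]
    target = d.first_spectrum - d.mean_spectrum if d.method == "pca" else d.first_spectrum
    proj = B.T @ target  # coordinates of the in-subspace projection
    norm = float(np.linalg.norm(proj))
    if norm < 1e-12:
        raise SpectraError("first spectrum has no component in the subspace")
    # Build orthonormal Q (k × k): column 1 = proj direction, rest Gram–Schmidt
    Q = np.zeros((k, k))
    Q[:, 0] = proj / norm
    col = 1
    for i in range(k):
        if col >= k:
            break
        v = np.zeros(k)
        v[i] = 1.0
        v -= Q[:, :col] @ (Q[:, :col].T @ v)
        nv = np.linalg.norm(v)
        if nv > 1e-10:
            Q[:, col] = v / nv
            col += 1
    new_basis = d.basis.copy()
    new_basis[:, :k] = B @ Q
    new_coeff = d.coefficients.copy()
    new_coeff[:k, :] = Q.T @ d.coefficients[:k, :]
    return replace(d, basis=new_basis, coefficients=new_coeff)


def invert_component(d: DecompositionResult, i: int) -> DecompositionResult:
    """Flip the sign of basis column i and coefficient row i (reconstruction
    is unchanged)."""
    if not 0 <= i < d.k_max:
        raise SpectraError(f"component index {i} out of range [0, {d.k_max})")
    basis = d.basis.copy()
    coeff = d.coefficients.copy()
    basis[:, i] *= -1.0
    coeff[i, :] *= -1.0
    return replace(d, basis=basis, coefficients=coeff)
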
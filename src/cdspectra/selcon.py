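"""Self-consistent secondary-structure deconvolution (SELCON3).

A query CD spectrum, in mean-unit molar extinction (Δε), is decomposed into
secondary-structure class fractions using a reference set of proteins with
known spectra and structures.  The algorithm:

1. references are ordered by spectral RMSD to the query and the query's
   unknown fractions are initialized with those of the closest reference;
2. the query spectrum is prepended to the reference matrix, the structure
   fractions are solved through a truncated SVD of the combined spectra
   matrix, and the query's guess is replaced by the solution until
   self-consistency;
3. the solution is re-derived over reference subsets obtained by dropping
   the most distant proteins (variable selection);
4. candidate solutions are filtered by the sum rule (Σf within 0.95–1.05),
   the fraction rule (no class below −0.025) and the spectral-fit rule
   (reconstruction RMSD ≤ 0.25 Δε units);
5. surviving solutions are averaged, negatives clamped to zero, and the
   result renormalized to sum to 1.

The numeric thresholds are the published SELCON3 defaults and are exposed in
:class:`SelconConfig`.  The original helix-content rule is available but off
by default.  Reference sets are user-supplied CSV files (or synthetic sets
from :mod:`cdspectra.synth`); unit conversion of the query is the caller's
job via :mod:`cdspectra.spectra`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class SelconError(ValueError):
    pass


@dataclass
class ReferenceSet:
    wavelengths: np.ndarray
    spectra: np.ndarray  # (n_wavelengths, n_proteins), mean-unit Δε
    fractions: np.ndarray  # (n_classes, n_proteins)
    class_labels: list[str]
    protein_ids: list[str]

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.spectra = np.asarray(self.spectra, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        n_wl, n_prot = self.spectra.shape
        if self.wavelengths.size != n_wl:
            raise SelconError("wavelength grid does not match spectra rows")
        if self.fractions.shape[1] != n_prot:
            raise SelconError("spectra and fractions are not column-aligned")
        if len(self.protein_ids) != n_prot or len(self.class_labels) != self.fractions.shape[0]:
            raise SelconError("label counts do not match matrix dimensions")
        sums = self.fractions.sum(axis=0)
        bad = [
            self.protein_ids[j]
            for j in range(n_prot)
            if abs(sums[j] - 1.0) > 0.02
        ]
        if bad:
            raise SelconError(f"fractions do not sum to 1 (±0.02) for: {bad}")

    @property
    def n_proteins(self) -> int:
        return self.spectra.shape[1]

    @property
    def n_classes(self) -> int:
        return self.fractions.shape[0]


def load_reference_set(spectra_csv, fractions_csv) -> ReferenceSet:
    """Load a custom reference set from two CSV files.

    ``spectra_csv``: matrix dialect — first column the wavelength grid, one
    column per protein.  ``fractions_csv``: one row per protein (identifier
    in the first column), one column per structure class.  Proteins are
    aligned by identifier regardless of order.
    """
    sdf = pd.read_csv(spectra_csv, comment="#")
    fdf = pd.read_csv(fractions_csv, comment="#")
    wl = sdf.iloc[:, 0].to_numpy(float)
    prot_ids = [str(c) for c in sdf.columns[1:]]
    fid_col = fdf.columns[0]
    fdf = fdf.assign(**{fid_col: fdf[fid_col].astype(str)}).set_index(fid_col)
    missing = sorted(set(prot_ids) - set(fdf.index))
    extra = sorted(set(fdf.index) - set(prot_ids))
    if missing or extra:
        raise SelconError(
            f"identifier mismatch between files: missing from fractions "
            f"{missing}, missing from spectra {extra}"
        )
    fdf = fdf.loc[prot_ids]
    return ReferenceSet(
        wavelengths=wl,
        spectra=sdf.iloc[:, 1:].to_numpy(float),
        fractions=fdf.to_numpy(float).T,
        class_labels=[str(c) for c in fdf.columns],
        protein_ids=prot_ids,
    )


@dataclass
class SelconConfig:
    rank: int = 5
    min_refs: int = 15
    conv_tol: float = 2.5e-3
    max_iter: int = 100
    sum_rule: tuple[float, float] = (0.95, 1.05)
    fraction_min: float = -0.025
    spectral_rmsd_max: float = 0.25  # mean-unit Δε
    helix_rule: bool = False
    helix_rule_tol: float = 0.05
    helix_class: str | None = None  # default: first class label


@dataclass
class SstrResult:
    fractions: dict[str, float]
    raw_fractions: dict[str, float]  # averaged survivors before clamping
    n_valid_solutions: int
    spectral_rmsd: float
    diagnostics: dict[str, int]
    valid: bool


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean((a - b) ** 2)))


def _self_consistent_solve(
    query: np.ndarray,
    spectra: np.ndarray,
    fractions: np.ndarray,
    guess: np.ndarray,
    rank: int,
    conv_tol: float,
    max_iter: int,
) -> tuple[np.ndarray, float, bool]:
    """Iterate the truncated-SVD solution with the query prepended; returns
    (fractions, reconstruction RMSD, converged)."""
    A = np.column_stack([query, spectra])
    f = guess.copy()
    converged = False
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    r = min(rank, int(np.sum(s > s[0] * 1e-12)))
    recon = U[:, :r] @ (s[:r, None] * Vt[:r, :])
    rmsd = _rmsd(recon[:, 0], query)
    # mapping from spectrum to fractions is fixed by the SVD of A except for
    # the F matrix, which contains the evolving guess
    for _ in range(max_iter):
        F = np.column_stack([f, fractions])
        X = F @ Vt[:r, :].T @ np.diag(1.0 / s[:r]) @ U[:, :r].T
        f_new = X @ query
        if np.max(np.abs(f_new - f)) < conv_tol:
            f = f_new
            converged = True
            break
        f = f_new
    return f, rmsd, converged


def selcon3(
    query: np.ndarray,
    refs: ReferenceSet,
    config: SelconConfig | None = None,
    query_wavelengths: np.ndarray | None = None,
) -> SstrResult:
    """Estimate secondary-structure fractions of a query Δε spectrum."""
    cfg = config or SelconConfig()
    q = np.asarray(query, dtype=float)
    if query_wavelengths is not None:
        qw = np.asarray(query_wavelengths, dtype=float)
        order = np.argsort(qw)
        if qw[order][0] > refs.wavelengths.min() or qw[order][-1] < refs.wavelengths.max():
            raise SelconError(
                "query wavelength range does not cover the reference range"
            )
        q = np.interp(refs.wavelengths, qw[order], q[order])
    elif q.size != refs.wavelengths.size:
        raise SelconError(
            "query length does not match the reference grid; pass "
            "query_wavelengths for interpolation"
        )

    dists = np.array([_rmsd(q, refs.spectra[:, j]) for j in range(refs.n_proteins)])
    order = np.argsort(dists, kind="stable")
    guess = refs.fractions[:, order[0]].copy()

    min_refs = min(cfg.min_refs, refs.n_proteins)
    diagnostics = {
        "candidates": 0,
        "not_converged": 0,
        "sum_rule": 0,
        "fraction_rule": 0,
        "spectral_rule": 0,
        "helix_rule": 0,
    }
    survivors: list[np.ndarray] = []
    best_rmsd = np.inf
    helix_idx = None
    if cfg.helix_rule:
        label = cfg.helix_class or refs.class_labels[0]
        helix_idx = refs.class_labels.index(label)

    # candidate pool: one self-consistent solution per reference subset
    for n_sub in range(refs.n_proteins, min_refs - 1, -1):
        idx = order[:n_sub]
        for rank in (cfg.rank,):
            f, rmsd, converged = _self_consistent_solve(
                q,
                refs.spectra[:, idx],
                refs.fractions[:, idx],
                guess,
                rank,
                cfg.conv_tol,
                cfg.max_iter,
            )
            diagnostics["candidates"] += 1
            best_rmsd = min(best_rmsd, rmsd)
            if not converged:
                diagnostics["not_converged"] += 1
                continue
            total = float(f.sum())
            if not cfg.sum_rule[0] <= total <= cfg.sum_rule[1]:
                diagnostics["sum_rule"] += 1
                continue
            if float(f.min()) < cfg.fraction_min:
                diagnostics["fraction_rule"] += 1
                continue
            if rmsd > cfg.spectral_rmsd_max:
                diagnostics["spectral_rule"] += 1
                continue
            if helix_idx is not None and (
                abs(f[helix_idx] - guess[helix_idx]) > cfg.helix_rule_tol
            ):
                diagnostics["helix_rule"] += 1
                continue
            survivors.append(f)

    if not survivors:
        raw = guess
        valid = False
    else:
        raw = np.mean(survivors, axis=0)
        valid = True
    clamped = np.clip(raw, 0.0, None)
    total = clamped.sum()
    final = clamped / total if total > 0 else clamped
    return SstrResult(
        fractions=dict(zip(refs.class_labels, final.tolist())),
        raw_fractions=dict(zip(refs.class_labels, np.asarray(raw).tolist())),
        n_valid_solutions=len(survivors),
        spectral_rmsd=float(best_rmsd),
        diagnostics=diagnostics,
        valid=valid,
    )
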
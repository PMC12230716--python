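"""Helix-coil ensemble estimation of peptide helicity from CD at 222 nm.

Short disordered peptides populate ensembles of conformers whose helical
segments are mostly short, and the ellipticity per helical residue depends on
segment length.  The classical single-wavelength estimate — normalizing the
222 nm signal to the maximal-helix ellipticity — therefore underestimates the
helicity of such ensembles.  The ensemble model implemented here evaluates
the Lifson–Roig helix-coil partition function and sums the length-corrected
ellipticity contributions of helical segments of every length.

Lifson–Roig statistical weights: a residue in helical conformation weighs w
when both neighbours are helical (propagation) and v otherwise (nucleation);
coil residues weigh 1.  Equivalently the weight factorizes over helical runs:
a run of l consecutive h-residues weighs v²·w^(l−2) for l ≥ 2 and v for
l = 1.  A residue counts as *helical* when it carries weight w, i.e. it is an
interior position of a run of length ≥ 3; "segment length k" below is this
interior count, so the expected helical residues equal Σ_k k·E[#segments_k].

Mean-residue ellipticity at 222 nm:

    Θ222 = (1/N)·[ Σ_k n_k·θ_H∞(T)·max(1 − x/k, 0) + (N − Σ_k n_k)·θ_C(T) ]

with n_k the expected residues in segments of length k, θ_H∞ the
infinite-helix and θ_C the coil limits (affine in temperature) and x ≈ 3 the
end-effect correction.  The model assumes a pure helix ⇌ coil equilibrium
and is not suitable for peptides with β-sheet propensity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .unfolding import R_KCAL, T0_K

__all__ = [
    "HelixEnsembleParams",
    "EnsembleSummary",
    "lr_partition_transfer",
    "lr_ensemble",
    "predict_theta222",
    "helicity_from_theta222",
    "conventional_helicity",
    "fit_thermal_helix",
]


class HelicityError(ValueError):
    pass


@dataclass(frozen=True)
class HelixEnsembleParams:
    """Parameters of the helix-coil ensemble.

    ``w`` may be given directly, or derived from per-peptide-bond
    thermodynamics via van 't Hoff (ΔCp = 0):

        ΔG_bond(T) = ΔH_bond − T·(ΔH_bond − ΔG_bond_ref)/T_ref
        w(T) = exp(−ΔG_bond(T)/(R·T))

    Spectroscopic limits (configurable, standard 222 nm literature values):
    θ_H∞(T) = −44000 + 250·T(°C), θ_C(T) = 2220 − 53·T(°C) in
    deg·cm²·dmol⁻¹; x_cap = 3 residues.
    """

    N: int
    w: float | None = None
    v: float = 0.05
    x_cap: float = 3.0
    theta_H_coeffs: tuple[float, float] = (-44000.0, 250.0)
    theta_C_coeffs: tuple[float, float] = (2220.0, -53.0)
    dH_bond: float | None = None  # kcal/mol per peptide bond
    dG_bond_ref: float | None = None  # kcal/mol per bond at T_ref
    T_ref: float = 298.15

    def __post_init__(self) -> None:
        if self.v <= 0:
            raise HelicityError("nucleation weight v must be > 0")
        if self.w is not None and self.w < 0:
            raise HelicityError("propagation weight w must be >= 0")

    def theta_H_inf(self, T_celsius: float) -> float:
        a, b = self.theta_H_coeffs
        return a + b * T_celsius

    def theta_C(self, T_celsius: float) -> float:
        a, b = self.theta_C_coeffs
        return a + b * T_celsius

    def w_at(self, T_celsius: float) -> float:
        """Propagation weight at T from the per-bond thermodynamics (or the
        fixed ``w`` when no thermodynamics are set)."""
        if self.dH_bond is None or self.dG_bond_ref is None:
            if self.w is None:
                raise HelicityError("neither w nor per-bond thermodynamics set")
            return self.w
        T = T_celsius + T0_K
        dG = self.dH_bond - T * (self.dH_bond - self.dG_bond_ref) / self.T_ref
        return float(np.exp(-dG / (R_KCAL * T)))


@dataclass(frozen=True)
class EnsembleSummary:
    partition_value: float
    mean_helical_residues: float
    #: expected residues found in helical segments of interior length k
    segment_length_distribution: dict[int, float]
    f_H: float


def lr_partition_transfer(N: int, v: float, w: float) -> float:
    """Partition function by the standard 3×3 Lifson–Roig transfer matrix.

    States (hh, ch, ·c); chain ends are padded with coil.
    """
    M = np.array([[w, 0.0, v], [v, 0.0, v], [0.0, 1.0, 1.0]])
    start = np.array([0.0, 1.0, 1.0])  # residue 1 preceded by virtual coil
    end = np.array([v, v, 1.0])  # weight of residue N, followed by coil
    vec = start
    for _ in range(N - 1):
        vec = vec @ M
    return float(vec @ end)


def _run_weight(l: int, v: float, w: float) -> float:
    return v if l == 1 else v * v * w ** (l - 2)


def _coil_ended_partitions(N: int, v: float, w: float) -> np.ndarray:
    """Zc[i] = partition over residues 1..i with residue i coil (Zc[0] = 1)."""
    Zc = np.zeros(N + 1)
    Zc[0] = 1.0
    for i in range(1, N + 1):
        total = Zc[i - 1]  # residue i-1 also coil (or i = 1)
        for l in range(1, i):  # run of length l ends at residue i-1
            total += Zc[i - 1 - l] * _run_weight(l, v, w)
        Zc[i] = total
    return Zc


def lr_ensemble(params: HelixEnsembleParams, T_celsius: float = 25.0) -> EnsembleSummary:
    """Partition value, mean helical residues, and the expected segment-length
    distribution of the Lifson–Roig ensemble."""
    N, v = params.N, params.v
    if N < 3:
        raise HelicityError("no helix is possible for N < 3")
    w = params.w_at(T_celsius)
    Zc = _coil_ended_partitions(N, v, w)
    # total partition: chain may end inside a run
    Z = Zc[N] + sum(
        Zc[N - l] * _run_weight(l, v, w) for l in range(1, N + 1)
    )
    dist: dict[int, float] = {}
    mean_h = 0.0
    for l in range(3, N + 1):  # only runs with interior residues contribute
        k = l - 2
        expect_runs = sum(
            Zc[s - 1] * _run_weight(l, v, w) * Zc[N - s - l + 1]
            for s in range(1, N - l + 2)
        ) / Z
        nk = k * expect_runs
        if nk > 0:
            dist[k] = nk
        mean_h += nk
    return EnsembleSummary(
        partition_value=Z,
        mean_helical_residues=mean_h,
        segment_length_distribution=dist,
        f_H=mean_h / N,
    )


def predict_theta222(params: HelixEnsembleParams, T_celsius: float = 25.0) -> float:
    """Mean-residue ellipticity at 222 nm predicted by the ensemble model."""
    summary = lr_ensemble(params, T_celsius)
    th_H = params.theta_H_inf(T_celsius)
    th_C = params.theta_C(T_celsius)
    helix_part = sum(
        nk * th_H * max(1.0 - params.x_cap / k, 0.0)
        for k, nk in summary.segment_length_distribution.items()
    )
    coil_part = (params.N - summary.mean_helical_residues) * th_C
    return (helix_part + coil_part) / params.N


def helicity_from_theta222(
    theta_obs: float,
    N: int,
    T_celsius: float = 25.0,
    v: float = 0.05,
    params: HelixEnsembleParams | None = None,
    beta_propensity: bool = False,
    w_max: float = 1e3,
    tol: float = 1e-10,
) -> dict[str, float]:
    """Invert the ensemble model: the observed mean-residue ellipticity at
    222 nm gives the propagation weight w and the fractional helicity f_H.

    Θ222(w) is strictly monotone in w, so a bisection between w = 0 (pure
    coil) and a large w (near-maximal helix) is well posed.  The observation
    must lie between the coil and maximal-helix ellipticities at T.
    """
    if beta_propensity:
        raise HelicityError(
            "the helix-coil ensemble model assumes a pure helix ⇌ coil "
            "equilibrium; peptides with β-sheet propensity are not supported"
        )
    base = params or HelixEnsembleParams(N=N, w=0.0, v=v)
    th_coil = predict_theta222(replace(base, w=0.0), T_celsius)
    th_helix = predict_theta222(replace(base, w=w_max), T_celsius)
    lo_th, hi_th = min(th_coil, th_helix), max(th_coil, th_helix)
    if not (lo_th - 1e-9 <= theta_obs <= hi_th + 1e-9):
        raise HelicityError(
            f"theta_obs = {theta_obs:.1f} outside the attainable range "
            f"[{lo_th:.1f}, {hi_th:.1f}] deg·cm²/dmol at {T_celsius} °C"
        )
    w_lo, w_hi = 0.0, w_max
    for _ in range(200):
        w_mid = 0.5 * (w_lo + w_hi)
        th_mid = predict_theta222(replace(base, w=w_mid), T_celsius)
        # theta decreases (towards θ_H∞ < 0) as w grows
        if (th_mid - theta_obs) * (th_helix - th_coil) < 0:
            w_lo = w_mid
        else:
            w_hi = w_mid
        if w_hi - w_lo < tol * max(1.0, w_hi):
            break
    w = 0.5 * (w_lo + w_hi)
    f_H = lr_ensemble(replace(base, w=w), T_celsius).f_H
    return {"w": w, "f_H": f_H}


def conventional_helicity(
    theta_obs: float,
    N: int,
    T_celsius: float = 25.0,
    params: HelixEnsembleParams | None = None,
) -> float:
    """Classical single-wavelength helicity estimate: the 222 nm signal
    normalized between coil and length-corrected maximal helix,

        f_H = (Θ_obs − θ_C) / (θ_Hmax − θ_C),  θ_Hmax = θ_H∞·(1 − x/N).
    """
    base = params or HelixEnsembleParams(N=N, w=0.0)
    th_C = base.theta_C(T_celsius)
    th_max = base.theta_H_inf(T_celsius) * (1.0 - base.x_cap / N)
    denom = th_max - th_C
    if abs(denom) < 1e-9:
        raise HelicityError("degenerate normalization: θ_Hmax ≈ θ_C")
    return (theta_obs - th_C) / denom


def fit_thermal_helix(
    T_celsius: np.ndarray,
    theta_obs: np.ndarray,
    N: int,
    v: float = 0.05,
    params: HelixEnsembleParams | None = None,
    init: dict[str, float] | None = None,
):
    """Fit per-peptide-bond ΔH and ΔG(T_ref) to a Θ222 melting curve.

    The propagation weight follows van 't Hoff with ΔCp = 0; the fit is a
    Levenberg–Marquardt least squares of the predicted Θ222(T).  Returns the
    parameter estimates with covariance-based standard errors, the fitted
    curve, and the implied f_H(T) trace.
    """
    import lmfit

    T = np.asarray(T_celsius, dtype=float)
    th = np.asarray(theta_obs, dtype=float)
    if T.size < 8:
        raise HelicityError("at least 8 temperature points are required")
    base = params or HelixEnsembleParams(N=N, v=v)
    init = init or {}

    pars = lmfit.Parameters()
    pars.add("dH_bond", value=init.get("dH_bond", -0.5), min=-5.0, max=5.0)
    pars.add("dG_bond_ref", value=init.get("dG_bond_ref", -0.05), min=-2.0, max=2.0)

    def predict(dh, dg):
        p = replace(base, w=None, dH_bond=dh, dG_bond_ref=dg)
        return np.array([predict_theta222(p, t) for t in T])

    def residual(p):
        return predict(p["dH_bond"].value, p["dG_bond_ref"].value) - th

    res = lmfit.minimize(residual, pars, method="leastsq")
    dh = float(res.params["dH_bond"].value)
    dg = float(res.params["dG_bond_ref"].value)
    fit_p = replace(base, w=None, dH_bond=dh, dG_bond_ref=dg)
    fitted = predict(dh, dg)
    fh_trace = np.array([lr_ensemble(fit_p, t).f_H for t in T])
    std = {
        k: (float(res.params[k].stderr) if res.params[k].stderr is not None else None)
        for k in ("dH_bond", "dG_bond_ref")
    }
    return {
        "dH_bond": dh,
        "dG_bond_ref": dg,
        "std_errors": std,
        "fitted_theta": fitted,
        "f_H_trace": fh_trace,
        "residual_norm": float(np.linalg.norm(fitted - th)),
        "success": bool(res.success),
    }
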
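"""Thermodynamic and kinetic models of protein unfolding, and a global
least-squares engine with shared parameters.

Thermal unfolding uses the Gibbs–Helmholtz expression

    ΔG(T) = ΔH·(1 − T/Tm) + ΔCp·(T − Tm − T·ln(T/Tm)),    K = exp(−ΔG/RT)

with ΔH the van 't Hoff enthalpy at the melting temperature Tm and ΔCp the
heat-capacity change (default 0).  Chemical denaturation follows the linear
extrapolation model, ΔG(D) = m·(D50 − D), so ΔG > 0 below D50 (native
favoured) and m > 0.  Oligomeric unfolding (Nₙ ⇌ n·U) couples the unfolded
fraction to the total monomer concentration through mass action and is solved
by bisection.  Irreversible denaturation (Lumry–Eyring) is integrated over a
temperature ramp with a fixed-step fourth-order Runge–Kutta scheme assuming
fast pre-equilibrium for the reversible step.

Several melting curves — single-wavelength CD traces or SVD/PCA coefficient
series — can be fitted simultaneously with the thermodynamic parameters
shared across curves and the baselines local, the standard global-analysis
setup for spectroscopic unfolding data.  Standard errors come from the
covariance matrix of the fitted parameters and therefore assume a locally
linear model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import lmfit

#: Gas constant in kcal/(mol·K).
R_KCAL = 1.987e-3
#: °C → K offset.
T0_K = 273.15


class UnfoldingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Equilibrium populations


def _gibbs_helmholtz(T_K, dH, Tm_K, dCp=0.0):
    T = np.asarray(T_K, dtype=float)
    return dH * (1.0 - T / Tm_K) + dCp * (T - Tm_K - T * np.log(T / Tm_K))


def _solve_oligomer_fu(K, n, Ct):
    """Root of n·Ct^(n−1)·fU^n/(1−fU) = K on fU ∈ (0, 1) by bisection.

    The left side rises monotonically from 0 to ∞ on (0, 1), so the root is
    unique; iterated to 1e-12 in fU.
    """
    if Ct <= 0:
        raise UnfoldingError("oligomer model requires total monomer Ct > 0")
    pref = n * Ct ** (n - 1)

    def g(fu):
        return pref * fu**n / (1.0 - fu) - K

    lo, hi = 0.0, 1.0 - 1e-16
    if g(hi) < 0:  # K astronomically large: fully unfolded
        return hi
    # iterate to floating-point resolution: the residual is steep near 1,
    # so the full 1e-10 relative mass-action accuracy needs every bit
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mid == lo or mid == hi:
            break
        if g(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def populations_thermal(
    T_K,
    dH: float,
    Tm_K: float,
    dCp: float = 0.0,
    n_states: int = 2,
    dH2: float | None = None,
    Tm2_K: float | None = None,
    dCp2: float = 0.0,
    oligomer_n: int = 1,
    Ct: float | None = None,
) -> dict[str, np.ndarray]:
    """State fractions along a temperature grid (Kelvin).

    Two-state monomer: fU = K/(1+K).  Oligomer Nₙ ⇌ n·U: fU solves the
    mass-action relation at total monomer concentration Ct (molar).
    Three-state monomer N ⇌ I ⇌ U: p_N = 1/(1+K₁+K₁K₂), p_I = K₁·p_N,
    p_U = K₁K₂·p_N.  Fractions always sum to 1.
    """
    T = np.atleast_1d(np.asarray(T_K, dtype=float))
    if np.any(T <= 0):
        raise UnfoldingError("temperatures must be positive Kelvin")
    K1 = np.exp(-_gibbs_helmholtz(T, dH, Tm_K, dCp) / (R_KCAL * T))
    if n_states == 2:
        if oligomer_n > 1:
            if Ct is None:
                raise UnfoldingError("oligomer model requires Ct (molar)")
            fu = np.array([_solve_oligomer_fu(k, oligomer_n, Ct) for k in K1])
        else:
            fu = K1 / (1.0 + K1)
        return {"native": 1.0 - fu, "unfolded": fu}
    if n_states == 3:
        if oligomer_n > 1:
            raise UnfoldingError("three-state oligomer models are not offered")
        if dH2 is None or Tm2_K is None:
            raise UnfoldingError("three-state model requires dH2 and Tm2")
        K2 = np.exp(-_gibbs_helmholtz(T, dH2, Tm2_K, dCp2) / (R_KCAL * T))
        pN = 1.0 / (1.0 + K1 + K1 * K2)
        return {"native": pN, "intermediate": K1 * pN, "unfolded": K1 * K2 * pN}
    raise UnfoldingError(f"n_states must be 2 or 3, got {n_states}")


def populations_chemical(
    D,
    D50: float,
    m: float,
    temperature_K: float = 293.15,
    n_states: int = 2,
    D50_2: float | None = None,
    m_2: float | None = None,
) -> dict[str, np.ndarray]:
    """State fractions along a denaturant grid (molar), linear extrapolation
    model: ΔG(D) = m·(D50 − D) per transition."""
    D = np.atleast_1d(np.asarray(D, dtype=float))
    if np.any(D < 0):
        raise UnfoldingError("denaturant concentrations must be >= 0")
    RT = R_KCAL * temperature_K
    K1 = np.exp(-m * (D50 - D) / RT)
    if n_states == 2:
        fu = K1 / (1.0 + K1)
        return {"native": 1.0 - fu, "unfolded": fu}
    if n_states == 3:
        if D50_2 is None or m_2 is None:
            raise UnfoldingError("three-state model requires D50_2 and m_2")
        K2 = np.exp(-m_2 * (D50_2 - D) / RT)
        pN = 1.0 / (1.0 + K1 + K1 * K2)
        return {"native": pN, "intermediate": K1 * pN, "unfolded": K1 * K2 * pN}
    raise UnfoldingError(f"n_states must be 2 or 3, got {n_states}")


def signal_model(
    x, populations: dict[str, np.ndarray], baselines: dict[str, tuple[float, float]]
) -> np.ndarray:
    """Observed signal y(x) = Σ_states p_state(x)·(b_state + m_state·x).

    ``baselines`` maps state name → (intercept, slope); states carrying no
    slope simply use slope 0.
    """
    x = np.asarray(x, dtype=float)
    unknown = set(baselines) - set(populations)
    if unknown:
        raise UnfoldingError(f"baseline for unknown state(s): {sorted(unknown)}")
    y = np.zeros_like(x)
    for state, p in populations.items():
        b, s = baselines.get(state, (0.0, 0.0))
        y = y + p * (b + s * x)
    return y


# ---------------------------------------------------------------------------
# Irreversible (Lumry–Eyring) denaturation


def rate_constant(T_K, Ea: float, Tf_K: float):
    """Arrhenius-type irreversible rate in 1/min: k(Tf) = 1 by construction."""
    T = np.asarray(T_K, dtype=float)
    return np.exp(-(Ea / R_KCAL) * (1.0 / T - 1.0 / Tf_K))


def simulate_irreversible(
    T_grid_K,
    Ea: float,
    Tf_K: float,
    scan_rate: float,
    scheme: str = "N->F",
    dH: float | None = None,
    Tm_K: float | None = None,
    dCp: float = 0.0,
    max_step: float = 0.1,
) -> dict[str, np.ndarray]:
    """Fraction of irreversibly denatured protein along a temperature ramp.

    scheme 'N->F':      dx_F/dT = (k(T)/v)·(1 − x_F)
    scheme 'N<=>U->F':  dx_F/dT = (k(T)/v)·x_U,  x_U = (1 − x_F)·K/(1+K)
    with v the scan rate in K/min and K the reversible equilibrium constant
    (fast pre-equilibrium).  Integrated by classic fixed-step RK4, local step
    at most ``max_step`` K.
    """
    T = np.asarray(T_grid_K, dtype=float)
    if T.ndim != 1 or T.size < 2 or np.any(np.diff(T) <= 0):
        raise UnfoldingError("T_grid must be strictly ascending with >= 2 points")
    if scan_rate <= 0:
        raise UnfoldingError("scan_rate must be > 0 K/min")
    if scheme not in ("N->F", "N<=>U->F"):
        raise UnfoldingError(f"unknown scheme {scheme!r}")
    if scheme == "N<=>U->F" and (dH is None or Tm_K is None):
        raise UnfoldingError("scheme N<=>U->F requires dH and Tm")

    def deriv(t, xf):
        k = float(rate_constant(t, Ea, Tf_K))
        if scheme == "N->F":
            return (k / scan_rate) * (1.0 - xf)
        K = float(np.exp(-_gibbs_helmholtz(t, dH, Tm_K, dCp) / (R_KCAL * t)))
        xu = (1.0 - xf) * K / (1.0 + K)
        return (k / scan_rate) * xu

    xF = np.empty_like(T)
    xF[0] = 0.0
    x = 0.0
    for i in range(T.size - 1):
        span = T[i + 1] - T[i]
        nsub = max(1, int(np.ceil(span / max_step)))
        h = span / nsub
        t = T[i]
        for _ in range(nsub):
            k1 = deriv(t, x)
            k2 = deriv(t + h / 2, x + h * k1 / 2)
            k3 = deriv(t + h / 2, x + h * k2 / 2)
            k4 = deriv(t + h, x + h * k3)
            x += (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
        x = min(x, 1.0)
        xF[i + 1] = x
    out = {"final": xF}
    if scheme == "N->F":
        out["native"] = 1.0 - xF
    else:
        K = np.exp(-_gibbs_helmholtz(T, dH, Tm_K, dCp) / (R_KCAL * T))
        out["unfolded"] = (1.0 - xF) * K / (1.0 + K)
        out["native"] = (1.0 - xF) / (1.0 + K)
    return out


# ---------------------------------------------------------------------------
# m-value prediction from chain length


def predict_m_value(n_res: int) -> dict[str, float]:
    """Predict the urea m-value of global unfolding from chain length.

    The change in solvent-accessible surface area on unfolding scales
    linearly with residue count, ΔASA (Å²) = −907 + 93·n_res, and the
    m-value correlates linearly with ΔASA, m = 0.13·ΔASA + 243 cal/mol/M
    (returned in kcal/mol/M).
    """
    if n_res < 1:
        raise UnfoldingError("n_res must be >= 1")
    dasa = -907.0 + 93.0 * n_res
    if dasa < 0:
        warnings.warn(
            f"n_res = {n_res} gives negative ΔASA = {dasa:.0f} Å²; the linear "
            "correlation is not meant for such short chains",
            stacklevel=2,
        )
    m = (0.13 * dasa + 243.0) / 1000.0
    return {"dASA": dasa, "m": m}


# ---------------------------------------------------------------------------
# Global fitting


@dataclass
class Curve:
    """One melting/denaturation trace: signal y versus the experimental
    parameter x (temperature in °C or denaturant in M)."""

    x: np.ndarray
    y: np.ndarray
    curve_id: str = ""
    concentration: float | None = None  # total monomer molar (oligomer models)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise UnfoldingError("curve needs matching 1-D x and y")


@dataclass
class ModelSpec:
    """Which unfolding model to fit.

    kind: 'thermal' or 'chemical'; n_states 2 or 3; oligomer_n > 1 switches
    the two-state thermal model to the concentration-coupled Nₙ ⇌ n·U form.
    ``slopes`` lists the states whose baselines carry a slope term (default:
    native only for thermal, native+unfolded for chemical; the intermediate
    is intercept-only unless listed).  dCp values are fixed, in kcal/(K·mol).
    temperature_K applies to chemical models.
    """

    kind: str = "thermal"
    n_states: int = 2
    oligomer_n: int = 1
    dCp: float = 0.0
    dCp2: float = 0.0
    temperature_K: float = 293.15
    slopes: tuple[str, ...] | None = None

    def thermo_names(self) -> list[str]:
        if self.kind == "thermal":
            return ["dH", "Tm"] if self.n_states == 2 else ["dH", "Tm", "dH2", "Tm2"]
        if self.kind == "chemical":
            return (
                ["D50", "m"]
                if self.n_states == 2
                else ["D50_1", "m_1", "D50_2", "m_2"]
            )
        raise UnfoldingError(f"unknown model kind {self.kind!r}")

    def states(self) -> list[str]:
        return (
            ["native", "unfolded"]
            if self.n_states == 2
            else ["native", "intermediate", "unfolded"]
        )

    def slope_states(self) -> tuple[str, ...]:
        if self.slopes is not None:
            return self.slopes
        return ("native",) if self.kind == "thermal" else ("native", "unfolded")


@dataclass
class FitResult:
    estimates: dict[str, float]
    std_errors: dict[str, float | None]
    shared_map: dict[str, str]
    fitted: dict[str, np.ndarray]
    residuals: dict[str, np.ndarray]
    residual_norm: float
    success: bool
    message: str = ""
    redchi: float = float("nan")
    covar: np.ndarray | None = field(default=None, repr=False)

    def flagged_unreliable(self, rel_threshold: float = 0.5) -> list[str]:
        """Parameters whose relative standard error exceeds the threshold —
        the practical criterion for 'could not be reliably estimated'."""
        out = []
        for p, se in self.std_errors.items():
            est = self.estimates.get(p)
            if se is None or est is None:
                continue
            if est != 0 and abs(se / est) > rel_threshold:
                out.append(p)
        return out


def _transition_guess(curve: Curve) -> float:
    """Locate the transition midpoint as the extremum of the smoothed
    numerical derivative of the curve."""
    from scipy.signal import savgol_filter

    # collapse replicate x values (averaging y) so the gradient is defined
    xu, inv = np.unique(curve.x, return_inverse=True)
    yu = np.bincount(inv, weights=curve.y) / np.bincount(inv)
    x, y = xu, yu
    if x.size >= 7:
        win = min(7, x.size if x.size % 2 else x.size - 1)
        y = savgol_filter(y, win, 2)
    dy = np.gradient(y, x)
    return float(x[np.argmax(np.abs(dy))])


def _model_populations(model: ModelSpec, params: dict[str, float], curve: Curve):
    if model.kind == "thermal":
        T = curve.x + T0_K
        if model.n_states == 2:
            return populations_thermal(
                T, params["dH"], params["Tm"] + T0_K, model.dCp,
                oligomer_n=model.oligomer_n, Ct=curve.concentration,
            )
        return populations_thermal(
            T, params["dH"], params["Tm"] + T0_K, model.dCp, n_states=3,
            dH2=params["dH2"], Tm2_K=params["Tm2"] + T0_K, dCp2=model.dCp2,
        )
    if model.n_states == 2:
        return populations_chemical(
            curve.x, params["D50"], params["m"], model.temperature_K
        )
    return populations_chemical(
        curve.x, params["D50_1"], params["m_1"], model.temperature_K,
        n_states=3, D50_2=params["D50_2"], m_2=params["m_2"],
    )


def _baseline_params_for(model: ModelSpec, i: int) -> list[tuple[str, str, bool]]:
    """(param name, state, is_slope) triples for curve i."""
    out = []
    for st in model.states():
        out.append((f"b_{st}_{i}", st, False))
        if st in model.slope_states():
            out.append((f"s_{st}_{i}", st, True))
    return out


def global_fit(
    curves: list[Curve],
    model: ModelSpec,
    shared: dict[str, str] | None = None,
    init: dict[str, float] | None = None,
    fixed: dict[str, float] | None = None,
) -> FitResult:
    """Fit several curves simultaneously by Levenberg–Marquardt least squares.

    Thermodynamic parameters are shared across curves ('global' in the
    shared map) unless remapped to 'local'; baseline intercepts and slopes
    are always per curve.  Standard errors derive from the covariance of the
    fitted parameters (inverse of JᵀJ scaled by the residual variance); a
    singular covariance leaves them as None.  Non-convergence is flagged on
    the result, never silent.
    """
    if not curves:
        raise UnfoldingError("global_fit needs at least one curve")
    shared = dict(shared or {})
    init = dict(init or {})
    fixed = dict(fixed or {})
    thermo = model.thermo_names()
    for p in shared:
        if p not in thermo:
            raise UnfoldingError(f"shared map names unknown parameter {p!r}")
    shared_map = {p: shared.get(p, "global") for p in thermo}

    x_all = np.concatenate([c.x for c in curves])
    span = float(x_all.max() - x_all.min())
    lo, hi = float(x_all.min()), float(x_all.max())
    mid_guess = _transition_guess(curves[0])

    defaults: dict[str, tuple[float, float, float]] = {}  # name -> (init, min, max)
    pad = 0.2 * span
    if model.kind == "thermal":
        defaults["dH"] = (50.0, 1e-6, 500.0)
        defaults["Tm"] = (mid_guess, lo - pad, hi + pad)
        if model.n_states == 3:
            defaults["dH"] = (50.0, 1e-6, 500.0)
            defaults["Tm"] = (mid_guess - span / 5, lo - pad, hi + pad)
            defaults["dH2"] = (50.0, 1e-6, 500.0)
            defaults["Tm2"] = (mid_guess + span / 5, lo - pad, hi + pad)
    else:
        if model.n_states == 2:
            defaults["D50"] = (mid_guess, max(0.0, lo - pad), hi + pad)
            defaults["m"] = (1.0, 1e-6, 20.0)
        else:
            defaults["D50_1"] = (mid_guess - span / 5, max(0.0, lo - pad), hi + pad)
            defaults["m_1"] = (1.0, 1e-6, 20.0)
            defaults["D50_2"] = (mid_guess + span / 5, max(0.0, lo - pad), hi + pad)
            defaults["m_2"] = (1.0, 1e-6, 20.0)

    params = lmfit.Parameters()
    pname_map: dict[tuple[str, int], str] = {}  # (thermo name, curve idx) -> lmfit name
    for p in thermo:
        v0, vmin, vmax = defaults[p]
        if shared_map[p] == "global":
            params.add(p, value=init.get(p, v0), min=vmin, max=vmax)
            if p in fixed:
                params[p].set(value=fixed[p], vary=False)
            for i in range(len(curves)):
                pname_map[(p, i)] = p
        else:
            for i in range(len(curves)):
                name = f"{p}_c{i}"
                params.add(name, value=init.get(p, v0), min=vmin, max=vmax)
                if p in fixed:
                    params[name].set(value=fixed[p], vary=False)
                pname_map[(p, i)] = name

    n_edge = max(1, int(0.1 * min(len(c.x) for c in curves)))
    for i, c in enumerate(curves):
        order = np.argsort(c.x)
        y_sorted = c.y[order]
        b_first = float(y_sorted[:n_edge].mean())
        b_last = float(y_sorted[-n_edge:].mean())
        for name, st, is_slope in _baseline_params_for(model, i):
            if is_slope:
                params.add(name, value=init.get(name, 0.0))
            else:
                if st == "native":
                    v0 = b_first
                elif st == "unfolded":
                    v0 = b_last
                else:
                    v0 = 0.5 * (b_first + b_last)
                params.add(name, value=init.get(name, v0))
            if name in fixed:
                params[name].set(value=fixed[name], vary=False)

    def eval_curve(pvals: dict[str, float], i: int, c: Curve) -> np.ndarray:
        tparams = {p: pvals[pname_map[(p, i)]] for p in thermo}
        pops = _model_populations(model, tparams, c)
        baselines = {}
        for st in model.states():
            b = pvals[f"b_{st}_{i}"]
            s = pvals.get(f"s_{st}_{i}", 0.0)
            baselines[st] = (b, s)
        return signal_model(c.x, pops, baselines)

    def residual(pars):
        pvals = {k: float(v) for k, v in pars.valuesdict().items()}
        return np.concatenate(
            [eval_curve(pvals, i, c) - c.y for i, c in enumerate(curves)]
        )

    minres = lmfit.minimize(residual, params, method="leastsq", nan_policy="raise")

    pvals = {k: float(v) for k, v in minres.params.valuesdict().items()}
    fitted, residuals = {}, {}
    for i, c in enumerate(curves):
        cid = c.curve_id or f"curve_{i}"
        fitted[cid] = eval_curve(pvals, i, c)
        residuals[cid] = fitted[cid] - c.y
    resid_norm = float(np.sqrt(sum(np.sum(r**2) for r in residuals.values())))
    std_errors: dict[str, float | None] = {}
    for k, par in minres.params.items():
        if par.vary:
            std_errors[k] = float(par.stderr) if par.stderr is not None else None
    success = bool(minres.success)
    full_shared = dict(shared_map)
    for i in range(len(curves)):
        for name, _, _ in _baseline_params_for(model, i):
            full_shared[name] = "curve-local"
    return FitResult(
        estimates=pvals,
        std_errors=std_errors,
        shared_map=full_shared,
        fitted=fitted,
        residuals=residuals,
        residual_norm=resid_norm,
        success=success,
        message=str(minres.message),
        redchi=float(minres.redchi) if minres.redchi is not None else float("nan"),
        covar=getattr(minres, "covar", None),
    )
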
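"""Synthetic CD datasets with known ground truth.

Every generator is seed-deterministic and built from sums of Gaussian bands,
so the spectral shapes are self-contained and configurable rather than
measured.  The unfolding generators mix state basis spectra with the exact
equilibrium populations of :mod:`cdspectra.unfolding`, which makes noiseless
datasets exactly rank-n_states and gives two-state series a true isodichroic
point at the wavelength where the native and unfolded basis spectra cross.

Default conditions follow the case studies the models are meant for: a
thermal ramp from 24 to 85 °C with Tm = 76.6 °C, ΔH = 86.8 kcal/mol and
ΔCp = 2.3 kcal/(K·mol) (lysozyme-like), a urea titration from 0 to 6.5 M in
0.5 M steps measured in triplicate up to 3.5 M and in duplicate above, with
D50₁ = 2.5 M, D50₂ = 3.9 M and m₂ = 4 kcal/(mol·M) (β-propeller-like
three-state), and a Θ222 melt at 1 °C intervals with per-bond ΔH = −0.3 and
ΔG(25 °C) = −0.07 kcal/mol (disordered-peptide-like).  Noise is i.i.d.
Gaussian with SD expressed as a fraction of the maximum signal amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra import SpectraSet
from .selcon import ReferenceSet
from .unfolding import (
    T0_K,
    populations_chemical,
    populations_thermal,
    simulate_irreversible,
)
from .helicity import HelixEnsembleParams, predict_theta222

Band = tuple[float, float, float]  # (center nm, width nm, amplitude)

#: Gaussian-band definitions of the state basis spectra (signal in
#: mean-residue ellipticity, 10³ deg·cm²·dmol⁻¹ scale).
DEFAULT_STATE_BANDS: dict[str, list[Band]] = {
    "native": [(192.0, 7.0, 30.0), (208.0, 9.0, -22.0), (222.0, 10.0, -20.0)],
    "intermediate": [(196.0, 8.0, -8.0), (215.0, 10.0, -12.0)],
    "unfolded": [(198.0, 8.0, -28.0), (222.0, 12.0, -2.0)],
}

#: Class basis spectra for synthetic secondary-structure reference sets.
DEFAULT_CLASS_BANDS: dict[str, list[Band]] = {
    "alpha": [(192.0, 7.0, 11.0), (208.0, 9.0, -7.5), (222.0, 10.0, -7.0)],
    "beta": [(195.0, 7.0, 6.5), (218.0, 10.0, -4.5)],
    "turns": [(205.0, 9.0, -2.0), (228.0, 10.0, 1.2)],
    "other": [(198.0, 8.0, -9.0), (222.0, 12.0, -0.6)],
}


def gaussian_bands(wavelengths: np.ndarray, bands: list[Band]) -> np.ndarray:
    wl = np.asarray(wavelengths, dtype=float)
    out = np.zeros_like(wl)
    for center, width, amp in bands:
        out += amp * np.exp(-((wl - center) ** 2) / (2.0 * width**2))
    return out


def basis_crossing(
    bands_a: list[Band], bands_b: list[Band], wl_lo: float, wl_hi: float
) -> float:
    """Wavelength where two band-defined basis spectra intersect (the
    isodichroic point of a two-state series), found by bisection on a fine
    bracket."""
    from scipy.optimize import brentq

    def diff(wl):
        return gaussian_bands(np.array([wl]), bands_a)[0] - gaussian_bands(
            np.array([wl]), bands_b
        )[0]

    grid = np.linspace(wl_lo, wl_hi, 400)
    vals = np.array([diff(w) for w in grid])
    sign_change = np.flatnonzero(np.diff(np.sign(vals)) != 0)
    if sign_change.size == 0:
        raise ValueError("basis spectra do not cross in the given range")
    i = sign_change[0]
    return float(brentq(diff, grid[i], grid[i + 1]))


@dataclass
class SyntheticTruth:
    """Ground truth of one synthetic dataset.

    ``kind`` is one of thermal-2s, thermal-3s, chemical-2s, chemical-3s,
    oligomer, irreversible, helix-melt.  ``params`` holds the generating
    thermodynamic parameters; ``bands`` the per-state basis spectra.
    """

    kind: str = "thermal-2s"
    params: dict[str, float] = field(default_factory=dict)
    bands: dict[str, list[Band]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_STATE_BANDS.items()}
    )
    noise_sd: float = 0.0
    seed: int = 0
    wavelengths: np.ndarray = field(
        default_factory=lambda: np.arange(190.0, 251.0, 2.0)
    )

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        defaults = _DEFAULT_PARAMS.get(self.kind)
        if defaults is None:
            raise ValueError(f"unknown generator kind {self.kind!r}")
        merged = dict(defaults)
        merged.update(self.params)
        self.params = merged


_DEFAULT_PARAMS: dict[str, dict[str, float]] = {
    "thermal-2s": {
        "Tm": 76.6, "dH": 86.8, "dCp": 2.3,
        "T_min": 24.0, "T_max": 85.0, "T_step": 2.5,
    },
    "thermal-3s": {
        "Tm": 60.0, "dH": 60.0, "dCp": 0.0, "Tm2": 76.6, "dH2": 86.8,
        "dCp2": 0.0, "T_min": 24.0, "T_max": 95.0, "T_step": 2.5,
    },
    "chemical-2s": {
        "D50": 3.9, "m": 4.0, "temperature_K": 293.15,
        "D_max": 6.5, "D_step": 0.5,
    },
    "chemical-3s": {
        "D50_1": 2.5, "m_1": 2.0, "D50_2": 3.9, "m_2": 4.0,
        "temperature_K": 293.15, "D_max": 6.5, "D_step": 0.5,
        "rep_lo": 3, "rep_hi": 2, "rep_switch": 3.5,
    },
    "oligomer": {
        "Tm": 76.6, "dH": 86.8, "dCp": 0.0, "oligomer_n": 2, "Ct": 1e-5,
        "T_min": 24.0, "T_max": 95.0, "T_step": 2.5,
    },
    "irreversible": {
        "dH": 86.8, "Tm": 76.6, "dCp": 0.0, "Ea": 50.0, "Tf": 85.0,
        "scan_rate": 1.0, "T_min": 24.0, "T_max": 95.0, "T_step": 1.0,
    },
    "helix-melt": {
        "N": 30, "v": 0.05, "dH_bond": -0.3, "dG_bond_ref": -0.07,
        "T_min": 4.0, "T_max": 94.0, "T_step": 1.0,
    },
}


def _x_grid(truth: SyntheticTruth) -> np.ndarray:
    p = truth.params
    if truth.kind.startswith("chemical"):
        base = np.arange(0.0, p["D_max"] + 1e-9, p["D_step"])
        if truth.kind == "chemical-3s":
            reps = [
                int(p["rep_lo"]) if d <= p["rep_switch"] else int(p["rep_hi"])
                for d in base
            ]
            return np.repeat(base, reps)
        return base
    return np.arange(p["T_min"], p["T_max"] + 1e-9, p["T_step"])


def _populations(truth: SyntheticTruth, x: np.ndarray) -> dict[str, np.ndarray]:
    p = truth.params
    if truth.kind == "thermal-2s":
        return populations_thermal(x + T0_K, p["dH"], p["Tm"] + T0_K, p["dCp"])
    if truth.kind == "thermal-3s":
        return populations_thermal(
            x + T0_K, p["dH"], p["Tm"] + T0_K, p["dCp"], n_states=3,
            dH2=p["dH2"], Tm2_K=p["Tm2"] + T0_K, dCp2=p["dCp2"],
        )
    if truth.kind == "oligomer":
        return populations_thermal(
            x + T0_K, p["dH"], p["Tm"] + T0_K, p["dCp"],
            oligomer_n=int(p["oligomer_n"]), Ct=p["Ct"],
        )
    if truth.kind == "chemical-2s":
        return populations_chemical(x, p["D50"], p["m"], p["temperature_K"])
    if truth.kind == "chemical-3s":
        return populations_chemical(
            x, p["D50_1"], p["m_1"], p["temperature_K"], n_states=3,
            D50_2=p["D50_2"], m_2=p["m_2"],
        )
    if truth.kind == "irreversible":
        pops = simulate_irreversible(
            x + T0_K, p["Ea"], p["Tf"] + T0_K, p["scan_rate"],
            scheme="N<=>U->F", dH=p["dH"], Tm_K=p["Tm"] + T0_K, dCp=p["dCp"],
        )
        # spectroscopically the final state looks unfolded
        return {
            "native": pops["native"],
            "unfolded": pops["unfolded"] + pops["final"],
        }
    raise ValueError(f"{truth.kind!r} is not an unfolding kind")


def gen_unfolding_dataset(truth: SyntheticTruth, include_ht: bool = False) -> SpectraSet:
    """Synthetic multi-condition spectra series mixing state basis spectra by
    the equilibrium (or Lumry–Eyring kinetic) populations, plus noise.

    Noiseless two-state sets are exactly rank 2 and share an isodichroic
    point at the native/unfolded basis crossing.  ``include_ht`` attaches a
    simple monotone HT-voltage template rising toward low wavelength.
    """
    x = _x_grid(truth)
    pops = _populations(truth, x)
    wl = truth.wavelengths
    bases = {st: gaussian_bands(wl, truth.bands[st]) for st in pops}
    values = np.zeros((wl.size, x.size))
    for st, frac in pops.items():
        # optional per-state linear baseline drift: B(λ)·(1 + c·(x − x₀));
        # defaults to 0 so two-state sets keep an exact isodichroic point
        slope = truth.params.get(f"slope_{st}", 0.0)
        drift = 1.0 + slope * (x - x[0])
        values += bases[st][:, None] * (frac * drift)[None, :]
    rng = np.random.default_rng(truth.seed)
    if truth.noise_sd > 0:
        amp = np.max(np.abs(values))
        values = values + rng.normal(0.0, truth.noise_sd * amp, values.shape)
    ht = None
    if include_ht:
        ht = np.tile(
            (250.0 + 400.0 * np.exp(-(wl - wl.min()) / 8.0))[:, None], (1, x.size)
        )
    label = "denaturant_M" if truth.kind.startswith("chemical") else "temperature_C"
    return SpectraSet(
        wl.copy(),
        values,
        "millidegrees",
        [f"{label[:4]}_{i}" for i in range(x.size)],
        label,
        x,
        ht,
    )


def gen_reference_set(
    n_proteins: int = 20,
    n_classes: int = 4,
    noise_sd: float = 0.0,
    seed: int = 0,
    wavelengths: np.ndarray | None = None,
    class_bands: dict[str, list[Band]] | None = None,
) -> ReferenceSet:
    """Synthetic secondary-structure reference set: per-protein fractions
    drawn uniformly on the simplex, spectra = fraction-weighted class basis
    spectra plus noise."""
    if not n_proteins >= n_classes >= 2:
        raise ValueError("need n_proteins >= n_classes >= 2")
    bands = class_bands or DEFAULT_CLASS_BANDS
    labels = list(bands)[:n_classes]
    wl = (
        np.arange(175.0, 241.0, 1.0) if wavelengths is None else np.asarray(wavelengths)
    )
    rng = np.random.default_rng(seed)
    fractions = rng.dirichlet(np.ones(n_classes), size=n_proteins).T  # classes × prot
    basis = np.column_stack([gaussian_bands(wl, bands[lab]) for lab in labels])
    spectra = basis @ fractions
    if noise_sd > 0:
        spectra = spectra + rng.normal(
            0.0, noise_sd * np.max(np.abs(spectra)), spectra.shape
        )
    return ReferenceSet(
        wavelengths=wl,
        spectra=spectra,
        fractions=fractions,
        class_labels=labels,
        protein_ids=[f"prot_{i:02d}" for i in range(n_proteins)],
    )


def gen_helix_melt(
    truth: SyntheticTruth | None = None, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray, HelixEnsembleParams]:
    """Θ222-versus-temperature melting curve of a helix-coil ensemble with
    van 't Hoff per-bond thermodynamics; returns (T °C, Θ222, true params)."""
    truth = truth or SyntheticTruth(kind="helix-melt")
    if truth.kind != "helix-melt":
        raise ValueError("gen_helix_melt expects kind='helix-melt'")
    p = truth.params
    T = np.arange(p["T_min"], p["T_max"] + 1e-9, p["T_step"])
    params = HelixEnsembleParams(
        N=int(p["N"]), v=p["v"], dH_bond=p["dH_bond"], dG_bond_ref=p["dG_bond_ref"]
    )
    theta = np.array([predict_theta222(params, t) for t in T])
    rng = np.random.default_rng(seed if seed is not None else truth.seed)
    if truth.noise_sd > 0:
        amp = np.max(np.abs(theta))
        theta = theta + rng.normal(0.0, truth.noise_sd * amp, theta.shape)
    return T, theta, params


def gen_comparison_groups(
    n_per_group: int = 4,
    offset: float = 0.0,
    noise_sd: float = 0.01,
    seed: int = 0,
    wavelengths: np.ndarray | None = None,
) -> dict[str, SpectraSet]:
    """Two groups of replicate spectra; group B's underlying spectrum is the
    native basis shifted by ``offset`` times the unfolded basis."""
    wl = (
        np.arange(190.0, 251.0, 1.0) if wavelengths is None else np.asarray(wavelengths)
    )
    rng = np.random.default_rng(seed)
    base_a = gaussian_bands(wl, DEFAULT_STATE_BANDS["native"])
    base_b = base_a + offset * gaussian_bands(wl, DEFAULT_STATE_BANDS["unfolded"])
    amp = np.max(np.abs(base_a))
    out = {}
    for name, base in (("A", base_a), ("B", base_b)):
        vals = base[:, None] + rng.normal(
            0.0, noise_sd * amp, (wl.size, n_per_group)
        )
        out[name] = SpectraSet(
            wl.copy(), vals, "millidegrees", [f"{name}{i}" for i in range(n_per_group)]
        )
    return out
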
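"""Core data model, CSV I/O and preprocessing for circular dichroism spectra.

A :class:`SpectraSet` holds a wavelength grid together with one column per
measured spectrum, a unit tag, per-column metadata (name and the value of the
experimental parameter — temperature, denaturant molarity, %TFE, ...) and an
optional high-tension (HT) detector-voltage matrix of the same shape.

Six working units are supported, all linear rescalings of the raw ellipticity
in millidegrees θ:

    ΔA            = θ / κ                    κ = 1000·ln(10)·(180/π)/4
    Δε (molar)    = ΔA / (C·l)               C molar, l cm
    [θ] (molar)   = (κ/10) · Δε
    mean-unit Δε, mean-unit [θ]: molar value / number of chromophores

so every conversion is exactly invertible.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: κ = 1000·ln(10)·(180/π)/4 — millidegrees of ellipticity per absorbance unit.
KAPPA = 1000.0 * math.log(10.0) * (180.0 / math.pi) / 4.0

UNITS = (
    "millidegrees",
    "delta_absorbance",
    "molar_extinction",
    "molar_ellipticity",
    "mean_unit_molar_extinction",
    "mean_unit_molar_ellipticity",
)

_MOLAR_UNITS = frozenset(UNITS[2:])
_MEAN_UNITS = frozenset(UNITS[4:])


class SpectraError(ValueError):
    """Raised for invalid spectra, incompatible grids or bad unit requests."""


@dataclass(frozen=True)
class SampleInfo:
    """Sample parameters needed for unit conversion and concentration-coupled
    unfolding models.

    Concentration may be given directly in molar units, or as mg/ml together
    with the molecular weight (g/mol); the mg/ml form is converted once here
    as M = (mg/ml) / MW.  ``n_chromophores`` is the divisor for the mean-unit
    quantities; for proteins the usual choice is the number of peptide bonds
    (n_residues − 1).
    """

    path_length_cm: float | None = None
    concentration_molar: float | None = None
    concentration_mg_ml: float | None = None
    molecular_weight: float | None = None
    n_chromophores: int | None = None
    oligomer_n: int = 1

    def __post_init__(self) -> None:
        if self.concentration_molar is None and self.concentration_mg_ml is not None:
            if self.molecular_weight is None:
                raise SpectraError(
                    "concentration in mg/ml requires molecular_weight (g/mol)"
                )
            object.__setattr__(
                self,
                "concentration_molar",
                self.concentration_mg_ml / self.molecular_weight,
            )
        for name in ("path_length_cm", "concentration_molar", "molecular_weight"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise SpectraError(f"{name} must be positive, got {v}")
        if self.n_chromophores is not None and self.n_chromophores < 1:
            raise SpectraError("n_chromophores must be a positive integer")
        if self.oligomer_n < 1:
            raise SpectraError("oligomer_n must be a positive integer")


@dataclass
class SpectraSet:
    wavelengths: np.ndarray
    values: np.ndarray
    unit: str = "millidegrees"
    names: list[str] = field(default_factory=list)
    param_label: str = ""
    param_values: np.ndarray | None = None
    ht_voltage: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] == 1 and self.wavelengths.size > 1:
            self.values = self.values.T
        if self.unit not in UNITS:
            raise SpectraError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        if self.wavelengths.ndim != 1:
            raise SpectraError("wavelengths must be a 1-D grid")
        if np.unique(self.wavelengths).size != self.wavelengths.size:
            raise SpectraError("duplicate wavelengths in grid")
        d = np.diff(self.wavelengths)
        if self.wavelengths.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise SpectraError("wavelength grid must be strictly monotone")
        if self.values.shape[0] != self.wavelengths.size:
            raise SpectraError(
                f"values has {self.values.shape[0]} rows for "
                f"{self.wavelengths.size} wavelengths"
            )
        if not self.names:
            self.names = [f"spectrum_{i}" for i in range(self.n_spectra)]
        if len(self.names) != self.n_spectra:
            raise SpectraError("one name per spectrum column required")
        if self.param_values is not None:
            self.param_values = np.asarray(self.param_values, dtype=float)
            if self.param_values.size != self.n_spectra:
                raise SpectraError("one parameter value per spectrum required")
        if self.ht_voltage is not None:
            self.ht_voltage = np.atleast_2d(np.asarray(self.ht_voltage, dtype=float))
            if self.ht_voltage.shape != self.values.shape:
                raise SpectraError("ht_voltage must have the same shape as values")

    @property
    def n_spectra(self) -> int:
        return self.values.shape[1]

    @property
    def n_wavelengths(self) -> int:
        return self.wavelengths.size

    def copy(self) -> "SpectraSet":
        return SpectraSet(
            self.wavelengths.copy(),
            self.values.copy(),
            self.unit,
            list(self.names),
            self.param_label,
            None if self.param_values is None else self.param_values.copy(),
            None if self.ht_voltage is None else self.ht_voltage.copy(),
        )

    def signal_at(self, wavelength: float) -> np.ndarray:
        """Per-spectrum signal at one wavelength (linear interpolation)."""
        order = np.argsort(self.wavelengths)
        wl = self.wavelengths[order]
        if not (wl[0] <= wavelength <= wl[-1]):
            raise SpectraError(f"{wavelength} nm outside grid [{wl[0]}, {wl[-1]}]")
        return np.array(
            [
                np.interp(wavelength, wl, self.values[order, j])
                for j in range(self.n_spectra)
            ]
        )


# ---------------------------------------------------------------------------
# CSV I/O


def _read_table(path_or_buf) -> tuple[pd.DataFrame, str | None]:
    """Read a CSV, honouring '#' comment lines and an optional '# unit:' tag."""
    if hasattr(path_or_buf, "read"):
        text = path_or_buf.read()
    else:
        with open(path_or_buf) as fh:
            text = fh.read()
    unit = None
    data_lines = []
    for line in text.splitlines():
        stripped = line.strip()
        if stripped.startswith("#"):
            body = stripped.lstrip("#").strip()
            if body.lower().startswith("unit:"):
                unit = body.split(":", 1)[1].strip()
            continue
        if stripped:
            data_lines.append(line)
    if not data_lines:
        raise SpectraError("empty spectra file")
    ncols = [len(line.split(",")) for line in data_lines]
    if len(set(ncols)) > 1:
        bad = next(i for i, n in enumerate(ncols) if n != ncols[0])
        raise SpectraError(f"ragged rows: line {bad + 1} has {ncols[bad]} fields, "
                           f"expected {ncols[0]}")
    df = pd.read_csv(io.StringIO("\n".join(data_lines)))
    return df, unit


def load_spectra_csv(
    path, layout: str = "matrix", param_label: str = ""
) -> SpectraSet:
    """Load a column-formatted CSV of CD spectra.

    ``matrix`` layout: first column is the wavelength grid, every remaining
    column one spectrum; header cells that parse as numbers become the
    experimental-parameter values.  Columns suffixed ``_HT`` are paired HT
    voltage channels.  ``long`` layout: columns (wavelength, value,
    spectrum_id[, parameter]); spectra are ordered by parameter when present.
    The unit defaults to millidegrees unless a ``# unit: <name>`` comment
    declares otherwise.
    """
    df, unit = _read_table(path)
    unit = unit or "millidegrees"
    if layout == "matrix":
        return _from_matrix_frame(df, unit, param_label)
    if layout == "long":
        return _from_long_frame(df, unit, param_label)
    raise SpectraError(f"unknown layout {layout!r}; expected 'matrix' or 'long'")


def _parse_wavelength_column(col: pd.Series) -> np.ndarray:
    wl = pd.to_numeric(col, errors="coerce")
    if wl.isna().any():
        row = int(np.flatnonzero(wl.isna().to_numpy())[0])
        raise SpectraError(
            f"non-numeric wavelength {col.iloc[row]!r} at data row {row + 1}"
        )
    return wl.to_numpy(dtype=float)


def _from_matrix_frame(df: pd.DataFrame, unit: str, param_label: str) -> SpectraSet:
    wl = _parse_wavelength_column(df.iloc[:, 0])
    spec_cols = [c for c in df.columns[1:] if not str(c).endswith("_HT")]
    ht_cols = [c for c in df.columns[1:] if str(c).endswith("_HT")]
    if not spec_cols:
        raise SpectraError("matrix layout needs at least one spectrum column")
    values = df[spec_cols].apply(pd.to_numeric, errors="coerce").to_numpy(float)
    if np.isnan(values).any():
        raise SpectraError("non-numeric or missing value in spectrum columns")
    names = [str(c) for c in spec_cols]
    params = pd.to_numeric(pd.Series(names), errors="coerce").to_numpy(float)
    param_values = params if not np.isnan(params).all() else None
    ht = None
    if ht_cols:
        if len(ht_cols) != len(spec_cols):
            raise SpectraError("one _HT column per spectrum column required")
        ht = df[ht_cols].apply(pd.to_numeric, errors="coerce").to_numpy(float)
    return SpectraSet(wl, values, unit, names, param_label, param_values, ht)


def _from_long_frame(df: pd.DataFrame, unit: str, param_label: str) -> SpectraSet:
    cols = list(df.columns)
    if len(cols) < 3:
        raise SpectraError("long layout needs (wavelength, value, spectrum_id)")
    wl_all = _parse_wavelength_column(df[cols[0]])
    df = df.assign(_wl=wl_all)
    ids = df[cols[2]].astype(str)
    has_param = len(cols) >= 4
    frames, names, params = {}, [], []
    for sid in ids.unique():
        sub = df[ids == sid]
        frames[sid] = sub.set_index("_wl")[cols[1]].astype(float)
        names.append(sid)
        params.append(float(sub[cols[3]].iloc[0]) if has_param else np.nan)
    order = np.argsort(params) if has_param else np.arange(len(names))
    names = [names[i] for i in order]
    params_arr = np.array(params)[order] if has_param else None
    grid = frames[names[0]].index.to_numpy(float)
    values = np.column_stack([frames[n].reindex(grid).to_numpy(float) for n in names])
    if np.isnan(values).any():
        raise SpectraError("long layout: spectra do not share a wavelength grid")
    return SpectraSet(grid, values, unit, names, param_label, params_arr)


def save_spectra_csv(s: SpectraSet, path) -> None:
    """Write a SpectraSet in the matrix CSV dialect (with '# unit:' comment)."""
    header = (
        [f"{v:g}" for v in s.param_values] if s.param_values is not None else s.names
    )
    cols = {"wavelength_nm": s.wavelengths}
    for j, h in enumerate(header):
        cols[h] = s.values[:, j]
    if s.ht_voltage is not None:
        for j, h in enumerate(header):
            cols[f"{h}_HT"] = s.ht_voltage[:, j]
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        fh.write(f"# unit: {s.unit}\n")
        if s.param_label:
            fh.write(f"# parameter: {s.param_label}\n")
        df.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# Unit conversion


def _unit_factor(unit: str, info: SampleInfo | None) -> float:
    """Multiplier turning millidegrees into ``unit``."""
    if unit == "millidegrees":
        return 1.0
    if unit == "delta_absorbance":
        return 1.0 / KAPPA
    if info is None:
        raise SpectraError(f"conversion to {unit} requires SampleInfo")
    C, l = info.concentration_molar, info.path_length_cm
    if C is None:
        raise SpectraError(f"conversion to {unit}: missing concentration_molar")
    if l is None:
        raise SpectraError(f"conversion to {unit}: missing path_length_cm")
    if unit == "molar_extinction":
        f = 1.0 / (KAPPA * C * l)
    elif unit == "molar_ellipticity":
        f = 1.0 / (10.0 * C * l)
    else:  # mean-unit variants
        if info.n_chromophores is None:
            raise SpectraError(f"conversion to {unit}: missing n_chromophores")
        base = (
            1.0 / (KAPPA * C * l)
            if unit == "mean_unit_molar_extinction"
            else 1.0 / (10.0 * C * l)
        )
        f = base / info.n_chromophores
    return f


def convert_units(
    s: SpectraSet, info: SampleInfo | None, target: str
) -> SpectraSet:
    """Convert a SpectraSet between any two of the six working units."""
    if target not in UNITS:
        raise SpectraError(f"unknown unit {target!r}")
    if target == s.unit:
        return s.copy()
    scale = _unit_factor(target, info) / _unit_factor(s.unit, info)
    out = s.copy()
    out.values = out.values * scale
    out.unit = target
    return out


# ---------------------------------------------------------------------------
# Preprocessing operations (all linear or affine per spectrum)


def _interp_onto(
    wl_target: np.ndarray, wl_src: np.ndarray, y_src: np.ndarray
) -> np.ndarray:
    order = np.argsort(wl_src)
    wl_s, y_s = wl_src[order], y_src[order]
    lo, hi = wl_s[0], wl_s[-1]
    if wl_target.min() < lo - 1e-9 or wl_target.max() > hi + 1e-9:
        raise SpectraError(
            f"extrapolation forbidden: target grid [{wl_target.min()}, "
            f"{wl_target.max()}] exceeds source range [{lo}, {hi}]"
        )
    return np.interp(wl_target, wl_s, y_s)


def baseline_subtract(sample: SpectraSet, baseline: SpectraSet) -> SpectraSet:
    """Subtract a baseline set from a sample set on the sample's grid.

    When the grids differ the baseline is linearly interpolated onto the part
    of the sample grid it covers (never extrapolated).  A single baseline
    column is applied to all sample columns; otherwise the column counts must
    match and subtraction is column-wise.
    """
    if sample.unit != baseline.unit:
        raise SpectraError(
            f"unit mismatch: sample {sample.unit} vs baseline {baseline.unit}"
        )
    lo = max(sample.wavelengths.min(), baseline.wavelengths.min())
    hi = min(sample.wavelengths.max(), baseline.wavelengths.max())
    if lo > hi:
        raise SpectraError("sample and baseline wavelength ranges do not overlap")
    keep = (sample.wavelengths >= lo - 1e-9) & (sample.wavelengths <= hi + 1e-9)
    wl = sample.wavelengths[keep]
    vals = sample.values[keep, :].copy()
    if baseline.n_spectra == 1:
        b = _interp_onto(wl, baseline.wavelengths, baseline.values[:, 0])
        vals -= b[:, None]
    elif baseline.n_spectra == sample.n_spectra:
        for j in range(sample.n_spectra):
            vals[:, j] -= _interp_onto(wl, baseline.wavelengths, baseline.values[:, j])
    else:
        raise SpectraError(
            f"baseline has {baseline.n_spectra} columns; expected 1 or "
            f"{sample.n_spectra}"
        )
    ht = sample.ht_voltage[keep, :] if sample.ht_voltage is not None else None
    return SpectraSet(
        wl, vals, sample.unit, list(sample.names), sample.param_label,
        sample.param_values, ht,
    )


def zero_by_window(s: SpectraSet, wl_lo: float, wl_hi: float) -> SpectraSet:
    """Zero each spectrum by subtracting its own mean over [wl_lo, wl_hi]
    (both ends inclusive).  Idempotent."""
    mask = (s.wavelengths >= wl_lo) & (s.wavelengths <= wl_hi)
    if not mask.any():
        raise SpectraError(f"no grid points in window [{wl_lo}, {wl_hi}] nm")
    out = s.copy()
    out.values = out.values - out.values[mask, :].mean(axis=0, keepdims=True)
    return out


def smooth(s: SpectraSet, window: int = 9, polyorder: int = 3) -> SpectraSet:
    """Savitzky–Golay smoothing along wavelength, per spectrum."""
    from scipy.signal import savgol_filter

    if window % 2 == 0:
        raise SpectraError(f"window must be odd, got {window}")
    if not 3 <= window <= s.n_wavelengths:
        raise SpectraError(
            f"window must be in [3, {s.n_wavelengths}], got {window}"
        )
    if polyorder >= window:
        raise SpectraError(f"polyorder {polyorder} must be < window {window}")
    out = s.copy()
    out.values = savgol_filter(out.values, window, polyorder, axis=0)
    return out


def average_replicates(s: SpectraSet, groups: dict[str, str]) -> SpectraSet:
    """Average replicate columns: one output column per group.

    ``groups`` maps every column name to a group label.  The experimental
    parameter must be homogeneous within each group and is propagated.
    """
    missing = [n for n in s.names if n not in groups]
    if missing:
        raise SpectraError(f"columns not assigned to a group: {missing}")
    labels = list(dict.fromkeys(groups[n] for n in s.names))
    cols, params, names = [], [], []
    for lab in labels:
        idx = [j for j, n in enumerate(s.names) if groups[n] == lab]
        cols.append(s.values[:, idx].mean(axis=1))
        if s.param_values is not None:
            pv = s.param_values[idx]
            finite = pv[np.isfinite(pv)]
            if finite.size and not np.allclose(finite, finite[0]):
                raise SpectraError(
                    f"group {lab!r} mixes parameter values {sorted(set(pv))}"
                )
            params.append(pv[0])
        names.append(str(lab))
    return SpectraSet(
        s.wavelengths.copy(),
        np.column_stack(cols),
        s.unit,
        names,
        s.param_label,
        np.array(params) if s.param_values is not None else None,
    )


def trim_wavelengths(
    s: SpectraSet,
    lo: float | None = None,
    hi: float | None = None,
    ht_threshold: float | None = None,
) -> SpectraSet:
    """Restrict the wavelength range, manually or by HT-voltage threshold.

    Manual mode keeps wavelengths in [lo, hi] (inclusive).  HT mode keeps the
    maximal contiguous block containing the long-wavelength end on which the
    HT voltage of *every* spectrum stays at or below ``ht_threshold``.
    """
    if ht_threshold is not None:
        if s.ht_voltage is None:
            raise SpectraError("ht_threshold trimming requires HT voltage data")
        ok = np.all(s.ht_voltage <= ht_threshold, axis=1)
        order = np.argsort(s.wavelengths)[::-1]  # long-wavelength end first
        keep_sorted = np.zeros(s.n_wavelengths, dtype=bool)
        for i in order:
            if not ok[i]:
                break
            keep_sorted[i] = True
        mask = keep_sorted
    else:
        if lo is None or hi is None:
            raise SpectraError("manual trim requires both lo and hi")
        mask = (s.wavelengths >= lo) & (s.wavelengths <= hi)
    if not mask.any():
        raise SpectraError("trimming removed every wavelength")
    return SpectraSet(
        s.wavelengths[mask],
        s.values[mask, :],
        s.unit,
        list(s.names),
        s.param_label,
        s.param_values,
        s.ht_voltage[mask, :] if s.ht_voltage is not None else None,
    )


def scale(s: SpectraSet, factor: float, columns: list[str] | None = None) -> SpectraSet:
    """Multiply selected spectra (default: all) by a scalar."""
    out = s.copy()
    idx = (
        list(range(s.n_spectra))
        if columns is None
        else [s.names.index(c) for c in columns]
    )
    out.values[:, idx] *= factor
    return out


def add(a: SpectraSet, b: SpectraSet) -> SpectraSet:
    """Per-wavelength sum of two sets on a common grid (same unit)."""
    if a.unit != b.unit:
        raise SpectraError(f"unit mismatch: {a.unit} vs {b.unit}")
    if not np.array_equal(a.wavelengths, b.wavelengths):
        raise SpectraError("add requires identical wavelength grids")
    if b.n_spectra not in (1, a.n_spectra):
        raise SpectraError("column counts must match (or b must be a single column)")
    out = a.copy()
    out.values = out.values + (b.values if b.n_spectra == a.n_spectra else b.values)
    return out


# ---------------------------------------------------------------------------
# Logbook


class Logbook:
    """Plain-text log of processing steps: one line per operation."""

    def __init__(self, path) -> None:
        self.path = path

    def record(self, operation: str, **params) -> None:
        detail = ", ".join(f"{k}={v}" for k, v in params.items())
        with open(self.path, "a") as fh:
            fh.write(f"{operation}: {detail}\n" if detail else f"{operation}\n")
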
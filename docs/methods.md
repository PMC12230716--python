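# Methods

This note records the models implemented in `cdspectra`, the assumptions
behind them, the defaults and numerical choices, and what the synthetic-data
tests do and do not demonstrate about real measurements.

## Units and preprocessing

All conversions are anchored on the raw ellipticity θ in millidegrees:
ΔA = θ/κ with κ = 1000·ln10·(180/π)/4 ≈ 32982 (kept as the formula, never a
rounded literal); Δε = ΔA/(C·l) with C the molar concentration and l the
path length in cm; [θ] = (κ/10)·Δε; the mean-unit variants divide the molar
quantities by the number of chromophores. The chromophore count is an
explicit user input rather than being inferred from sequence length,
because the right divisor depends on the chromophore (for protein backbone
CD the usual choice is the number of peptide bonds, n_residues − 1; for
nucleic acids it is the number of bases). Concentration given as mg/ml is
converted once, at `SampleInfo` construction, as M = (mg/ml)/MW.

Smoothing is Savitzky–Golay (default window 9 points, polynomial order 3):
it is the standard choice in spectroscopy because it preserves band shapes
and areas that a moving average would flatten. Wavelength windows are
inclusive on both ends. Mismatched grids are bridged by linear
interpolation only inside the overlapping range; extrapolation always
raises. Automatic trimming by high-tension voltage keeps the maximal
contiguous block containing the long-wavelength end where **every**
spectrum's HT stays at or below the threshold — requiring all spectra
(rather than any) is the conservative reading and guarantees that the
retained range is valid for the whole series.

## Decomposition

`svd` factorizes the raw wavelength × spectrum matrix; `pca` first removes
the per-wavelength mean across spectra and applies no variance scaling, so
PCA is exactly SVD of the centered matrix. Singular values are folded into
the coefficients so basis spectra are unit-norm shapes; each basis column
is oriented with its largest-magnitude element positive, making results
reproducible across LAPACK builds. The rotation toward the first measured
spectrum is implemented as an orthogonal change of basis inside the
retained k-dimensional subspace: the new first basis vector is the
normalized projection of the first spectrum onto the subspace and the
remaining vectors are completed by Gram–Schmidt; coefficients are
transformed by the transpose, so rank-k reconstruction is invariant by
construction. A Givens-sweep parameterization would satisfy the same
requirements; the projection scheme was chosen because it is direct and
deterministic.

## Unfolding models

Temperatures are entered in °C and converted as K = °C + 273.15;
R = 1.987×10⁻³ kcal/(mol·K). Thermal transitions use Gibbs–Helmholtz with
the van 't Hoff enthalpy ΔH (kcal/mol) and Tm; ΔCp (kcal/(K·mol), default
0) is held fixed during fitting, one value per transition. Note that with
ΔCp > 0 the stability curve turns over and the model genuinely predicts
cold denaturation at low temperature. Chemical denaturation is the linear
extrapolation model written as ΔG = m·(D50 − D), so ΔG > 0 below D50
(native favored) and m > 0.

Oligomer unfolding Nₙ ⇌ n·U at total monomer concentration Ct satisfies
n·Ct^(n−1)·fU^n/(1−fU) = K; the left side is strictly increasing on (0,1),
so the root is found by bisection, iterated to floating-point resolution
because the function is extremely steep as fU → 1 and the mass-action
residual is verified to 1e-10 relative in the tests. Three-state oligomer
and oligomer–irreversible combinations are not offered.

The irreversible (Lumry–Eyring) ramp assumes fast pre-equilibrium of the
reversible step and an Arrhenius-type rate normalized so k(Tf) = 1 per
minute — Tf's meaning is therefore tied to the scan rate being expressed
in K/min. Integration is classic fixed-step RK4 with the local step
subdivided to ≤ 0.1 K; the tests cross-check it against an adaptive
Runge–Kutta integration and against the closed form for constant rate.

### Global fitting

All fits run through Levenberg–Marquardt least squares (lmfit) on the
concatenated residual of every curve. Thermodynamic parameters are shared
across curves by default; baseline intercepts are always per curve, and
slopes are attached to the native state only for thermal fits and to
native+unfolded for chemical fits (the intermediate is intercept-only),
all configurable. Initialization: Tm/D50 from the extremum of the smoothed
numerical derivative of the first curve (replicate x values are collapsed
by averaging first), three-state midpoints offset by ±span/5 around it,
ΔH = 50 kcal/mol, m = 1 kcal/(mol·M), baselines from the first/last 10% of
points. Bounds stabilize the optimizer on noisy data: midpoints within the
data range ± 20%, ΔH ∈ (0, 500] kcal/mol, m ∈ (0, 20] kcal/(mol·M).
Standard errors come from the covariance of the fitted parameters
(inverse JᵀJ scaled by residual variance) and assume a locally linear
model — they are optimistic, as covariance errors always are.
`FitResult.flagged_unreliable()` marks parameters whose relative standard
error exceeds 50%, the practical criterion for "could not be reliably
estimated". Non-convergence sets a flag on the result rather than raising.

m-value prediction chains two empirical linear correlations:
ΔASA (Å²) = −907 + 93·n_res, then m = (0.13·ΔASA + 243)/1000 kcal/(mol·M).
Chains shorter than ~11 residues give negative ΔASA; the value is still
returned with a warning since the correlation is not meant for peptides.

## Helix–coil ensemble helicity

Lifson–Roig weights: coil 1, helical residue with both neighbors helical
w, otherwise v (default 0.05, fixed during fits so helicity estimation is
one-parameter in w). The partition function is evaluated with the standard
3×3 transfer matrix; expected segment statistics use an equivalent O(N²)
dynamic program over helical runs (a run of l ≥ 2 h-residues weighs
v²·w^(l−2), a lone h weighs v). "Segment length k" counts the interior,
w-weighted residues of a run — the residues conventionally called helical
— so the expected helical residues equal Σ k·E[#segments of length k]
identically. Both routes agree with exhaustive 2^N enumeration to 1e-9
for N ≤ 14 in the tests.

The predicted mean-residue ellipticity sums length-corrected contributions,
Θ222 = (1/N)[Σ_k n_k·θ_H∞(T)·max(1 − x/k, 0) + (N − Σ n_k)·θ_C(T)], with
defaults θ_H∞(T) = −44000 + 250·T(°C), θ_C(T) = 2220 − 53·T(°C)
(deg·cm²·dmol⁻¹) and x = 3 residues — standard 222 nm literature values,
exposed in `HelixEnsembleParams` because different calibrations exist.
Those constants are a documented calibration choice: structural equivalence
with other implementations of the model class is intended, numerical
equality of f_H values is not claimed. The segment-resolved sum was chosen
over applying a single mean-length correction; the alternative collapses
the distribution to its mean and differs for broad distributions. Θ222 is
strictly monotone in w, so the inversion to (w, f_H) is a well-posed
bisection; observations outside the coil-to-maximal-helix range are
rejected by name. Melting fits use van 't Hoff per-peptide-bond
thermodynamics with ΔCp = 0: w(T) = exp(−ΔG_bond(T)/RT),
ΔG_bond(T) = ΔH_bond − T·(ΔH_bond − ΔG_ref)/T_ref, T_ref = 298.15 K.
The model assumes a pure helix ⇌ coil equilibrium (homopolymer, one w):
peptides with β-sheet propensity are outside its scope and are refused
when declared. The low-cooperativity comparison in the tests contrasts the
helix-coil melt width with a two-state transition carrying a typical
protein enthalpy at the same midpoint; at equal *total* enthalpy a
two-state curve would be the broader one, so that comparison would be
uninformative.

## SELCON3

The implementation follows the published algorithm: order references by
spectral RMSD to the query; initialize the query's fractions from the
closest reference; prepend the query to the spectra matrix and iterate the
truncated-SVD solution (rank 5 by default, capped at the numerical rank)
until the largest fraction change is below 2.5e-3 (max 100 iterations);
re-solve over subsets formed by successively dropping the most distant
references down to a minimum of 15 (when available); keep solutions
passing the sum rule (Σf ∈ [0.95, 1.05]), the fraction rule (every class ≥
−0.025) and the spectral-fit rule (query reconstruction RMSD ≤ 0.25 Δε);
average survivors, clamp negatives, renormalize. All thresholds are the
published defaults, surfaced in `SelconConfig`. The original helix-content
rule is implemented but off by default; which rule variants a given
deployment enables varies, so no numerical equivalence with any particular
deployment is claimed. When no solution survives, the result is flagged
invalid with per-rule rejection counts and falls back to the initial
guess. The query must already be in mean-unit molar extinction; unit
conversion is deliberately left to the spectra module so this one stays
unit-pure. Reference sets ship as synthetic fixtures only — real reference
sets (e.g. SP175/SMP180 derivatives) must be supplied as the two-CSV
format.

## Synthetic data: what it shows and what it does not

Generators build state basis spectra from sums of Gaussian bands (α-like:
positive ~192 nm, negative ~208/222 nm; coil-like: negative ~198 nm, etc.)
and mix them with the exact model populations, so noiseless two-state
series are exactly rank 2 and share a true isodichroic point at the
basis-crossing wavelength. Default conditions are the study designs the
models target: a 24–85 °C ramp in 2.5 °C steps with Tm = 76.6 °C,
ΔH = 86.8 kcal/mol, ΔCp = 2.3 kcal/(K·mol) (lysozyme-like two-state); a
0–6.5 M urea series in 0.5 M steps, triplicate to 3.5 M and duplicate
above, with D50₁ = 2.5 M, D50₂ = 3.9 M, m₂ = 4 kcal/(mol·M)
(β-propeller-like three-state; m₁ = 2 kcal/(mol·M) was chosen as a
realistic partial-unfolding value since the first transition's m-value is
typically poorly determined); a Θ222 melt at 1 °C intervals with per-bond
ΔH = −0.3 and ΔG(25 °C) = −0.07 kcal/mol (disordered-peptide-like).
Optional per-state linear drifts reproduce the pre/post-transition
baseline slopes of real data (defaults 0, preserving the exact isodichroic
point). Noise is i.i.d. Gaussian with SD given as a fraction of the
maximum amplitude; one explicitly seeded RNG per generator call, no global
state.

Passing recovery tests on these data shows that the estimators are
consistent and correctly implemented under the stated models. It does not
show robustness to what the generators deliberately omit: wavelength- and
HT-dependent (non-i.i.d.) instrument noise, baseline curvature,
concentration errors, partial irreversibility in nominally reversible
melts, or reference proteins whose real spectra deviate from a linear
class-basis mixture. SELCON3 self-recovery in particular is easier on
synthetic linear mixtures than on real proteins. At 5%-of-maximum
reference noise — far above real reference-set quality — the published
spectral-fit rule rejects most or all candidate solutions, and accuracy is
then carried by the nearest-reference initialization; per-query worst-case
errors of ~0.1 per class occur at that noise level regardless of
reference-set size.

## Test and acceptance problem sizes

The suites size simulations for quick desk runs: 20-replicate recovery
harnesses for the acceptance checks and 50-replicate median harnesses for
the module-level properties, 5 wavelengths per global fit, exhaustive
Lifson–Roig enumeration up to N = 14, and 20-protein synthetic reference
sets (the minimum-subset default of 15 then yields six variable-selection
subsets per query).

## Known limitations

- Pressure/pH denaturation, DSC coupling, scan-rate-dependent
  reversibility tests and bootstrap/profile-likelihood errors are out of
  scope; errors are covariance-based only.
- The irreversible model's fully kinetic (no pre-equilibrium) variant is
  not offered.
- The custom-model grammar is single-variable (x) with explicit `*` only;
  multi-variable models are not supported.
- Proprietary instrument formats are not parsed; the CSV dialects
  described in the README are the only inputs.
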
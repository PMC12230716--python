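# cdspectra

Scriptable processing and quantitative analysis of circular dichroism (CD)
spectra, for biophysicists who want the full pipeline — raw millidegrees to
thermodynamic parameters — as a Python library and CLI instead of a GUI.

CD reports the differential absorption of circularly polarized light by
chiral molecules and is the workhorse technique for protein secondary
structure, folding and binding. `cdspectra` covers:

- **Preprocessing** — CSV I/O, addition/subtraction, baseline correction,
  windowed zeroing, Savitzky–Golay smoothing, replicate averaging, scaling,
  manual or HT-voltage-threshold wavelength trimming, and exact conversion
  among the six working units (millidegrees θ, differential absorbance ΔA,
  molar extinction Δε, molar ellipticity [θ], and their mean-unit per-
  chromophore variants), anchored on κ = 1000·ln10·(180/π)/4 mdeg per
  absorbance unit.
- **Decomposition** — SVD, and PCA (= SVD after per-wavelength centering,
  no Z-scoring), with rank-k reconstruction, component sign inversion, and
  an orthogonal rotation that points the first basis spectrum along the
  first measured spectrum while leaving reconstruction unchanged.
- **Unfolding thermodynamics** — global Levenberg–Marquardt fitting of many
  curves with shared thermodynamic parameters and local baselines.
  Thermal models use Gibbs–Helmholtz,
  ΔG(T) = ΔH·(1 − T/Tm) + ΔCp·(T − Tm − T·ln(T/Tm));
  chemical denaturation uses the linear extrapolation model
  ΔG(D) = m·(D50 − D). Two- and three-state monomers, concentration-coupled
  oligomers (Nₙ ⇌ n·U, solved by bisection), and irreversible Lumry–Eyring
  ramps (fixed-step RK4, rate k(T) = exp(−(Ea/R)(1/T − 1/Tf))) are
  provided, plus m-value prediction from chain length
  (ΔASA = −907 + 93·n_res; m = 0.13·ΔASA + 243 cal/mol/M).
- **Peptide helicity** — Lifson–Roig helix–coil partition function
  (transfer matrix; nucleation v, propagation w) with length-corrected
  Θ222 contributions summed over the segment-length distribution of the
  ensemble; inversion of an observed Θ222 to (w, f_H); the conventional
  maximal-helix estimator for comparison; van 't Hoff melting fits of
  per-peptide-bond ΔH and ΔG.
- **Secondary structure** — a SELCON3 implementation (self-consistent
  truncated-SVD solution, variable selection over reference subsets,
  sum/fraction/spectral-fit rules) with pluggable CSV reference sets.
- **Comparison & custom models** — group means/SDs, difference spectra,
  intra/inter Euclidean distance lists, optional L2 shape normalization;
  and a whitelisted expression parser so arbitrary fitting functions
  (e.g. `"ymin + (ymax-ymin)*x/(Kd+x)"`) run through the same global
  fitting engine without ever touching `eval`.
- **Synthetic data** — seed-deterministic generators (Gaussian-band basis
  spectra mixed by the exact model populations) for every analysis above,
  so the whole pipeline is testable with known ground truth.

## Worked example: thermal unfolding at the SVD-coefficient level

```python
import cdspectra as cd

truth = cd.SyntheticTruth(kind="thermal-2s", noise_sd=0.02, seed=1)
melt = cd.gen_unfolding_dataset(truth)   # 24-85 C ramp, Tm 76.6, dH 86.8

dec = cd.rotate_to_first_spectrum(cd.decompose(melt, "svd"), 2)
print("cumulative explained variance:",
      ", ".join(f"{v:.2%}" for v in dec.explained_variance[:3]))

model = cd.ModelSpec(kind="thermal", n_states=2, dCp=2.3)
curves = [cd.Curve(melt.param_values, dec.coefficients[i], f"svd{i+1}")
          for i in range(2)]
fit = cd.global_fit(curves, model)
print(f"Tm = {fit.estimates['Tm']:.2f} +/- {fit.std_errors['Tm']:.2f} C")
print(f"dH = {fit.estimates['dH']:.1f} +/- {fit.std_errors['dH']:.1f} kcal/mol")
```

Output:

```
cumulative explained variance: 94.78%, 99.90%, 99.91%
Tm = 76.64 +/- 0.07 C
dH = 86.0 +/- 1.5 kcal/mol
```

Two components explain 99.9% of the variance — the signature of a two-state
transition — and the global fit of the two rotated coefficient series
recovers the generating melting temperature (76.6 °C) and van 't Hoff
enthalpy (86.8 kcal/mol) within their covariance-based standard errors.
The same fit run at individual wavelengths gives statistically
indistinguishable parameters; `cdspectra.Curve` accepts either.

The CLI mirrors the library:

```sh
cdspectra simulate thermal-2s --seed 1 --noise 0.02 -o melt.csv
cdspectra process melt.csv --smooth-window 9 --trim 192 248 -o proc.csv
cdspectra decompose proc.csv --rotate-k 2 -o dec
cdspectra helicity --theta -12000 --n-residues 22
```

Every run appends one line per operation to a plain-text logbook
(`cdspectra_logbook.txt`), keeping processing provenance with the data.

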
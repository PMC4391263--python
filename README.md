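# polgk — pre-steady-state kinetics of DNA polymerase γ

`polgk` is a kinetic-analysis toolkit for rapid-quench experiments on the
human mitochondrial DNA polymerase (Pol-γ) and its disease variants (the
Alpers-syndrome mutants S305R and P1073L are built in as presets).  It is
aimed at enzyme kineticists who want a scriptable, testable alternative to
GUI simulation packages: mechanisms are mass-action reaction schemes,
fitting is global nonlinear least squares over titration series, and error
analysis is done by χ²-threshold confidence contours.

## The models

**Single-nucleotide incorporation** is modelled by the elementary mechanism

```
E + D_n   ⇌ E·D_n          (k_1, k_-1)        DNA binding / release
E·D_n + N ⇌ E·D_n·N        (k_2, k_-2)        ground-state nucleotide binding
E·D_n·N   → E·D_(n+1) + PPi (k_3 = k_pol)     irreversible chemistry
E + D_(n+1) ⇌ E·D_(n+1)    (k_1, k_-1)
```

with the derived quantities

- K_d,app = k_-2 / k_2 (apparent nucleotide dissociation constant),
- K_d,DNA = k_-1 / k_1,
- specificity constant k_pol / K_d,app = k_cat / K_m,
- processivity k_pol / k_off (expected nucleotides per binding event,
  k_off = k_-1).

k_2 is diffusion-limited and fixed at 0.5 nM⁻¹s⁻¹ during fitting.

**Processive polymerization** is a sequential ladder
`E·D_25 → E·D_26 → … → E·D_(25+n)` with one rate per position and every
intermediate exchanging with free enzyme through K_d,DNA — the executable
form of a quantified gel-band ladder.

**Closed-form assays**: multiple-turnover burst kinetics
`[P](t) = A(1 − e^(−k_obs t)) + k_ss t` with k_off = k_ss / A, and
single-exponential mismatch-excision decay `A₀ e^(−k_exo t) + C`.

**Confidence contours**: for each parameter pair, χ² is mapped on a
log-spaced grid with all remaining free parameters re-optimized at every
node; the region where χ² ≤ 1.1·χ²_min (a 10% increase) sets the lower and
upper confidence limits of each parameter.

Synthetic-data generators emulate every experiment class (dNTP titrations,
DNA titrations, bursts, excision decays, band ladders) with seeded Gaussian
noise, so the whole pipeline is testable without lab data.

## Worked example

```python
from polgk import synthetic_data as sd
from polgk import fit_global
from polgk.presets import rate_constants

design = sd.single_turnover_design("S305R")     # dATP 0.05-17 uM grid
data = sd.gen_single_turnover(design, seed=1)   # 6 noisy product courses
truth = rate_constants("S305R")
fit = fit_global(data, free=["k_minus2", "k3"],
                 fixed={"k1": truth.k1, "k_minus1": truth.k_minus1, "k2": 0.5},
                 n_starts=2, seed=1)
print(f"k_pol  = {fit.params['k3']:.1f} s^-1")
print(f"K_d,app = {fit.derived['kd_app_uM']:.2f} uM")
print(f"k_pol/K_d,app = {fit.derived['specificity_uM_s']:.1f} uM^-1 s^-1")
print(f"chi2 = {fit.chi2:.1f} over {fit.n_points} points")
```

prints

```
k_pol  = 11.2 s^-1
K_d,app = 1.00 uM
k_pol/K_d,app = 11.2 uM^-1 s^-1
chi2 = 633.2 over 72 points
```

One noisy replicate of the S305R titration recovers the chemistry rate
(generating value 12.4 s⁻¹), nucleotide affinity (1.2 μM) and specificity
constant (10 μM⁻¹s⁻¹) to within the scatter expected at 5% band-quantification
noise; replicate means converge on the generating values (see the test
suite and acceptance script).

The same pipeline is available from the shell:

```
polgk simulate --config cfg.yaml --out data/
polgk fit      --config cfg.yaml --data data/single_turnover_S305R.csv --out fit.json
polgk contour  --config cfg.yaml --data data/single_turnover_S305R.csv --out contours/
polgk report   --fit-json fit.json
polgk recover  --config cfg.yaml --replicates 20
```

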
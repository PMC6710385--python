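# qsdyn

Dynamics of autoinducer-2 (AI-2) quorum sensing in *Escherichia coli*:
an ODE model linking cell growth, extracellular AI-2 activity and
*lsr*-operon expression, with tools to calibrate it against time-series
data and to simulate quorum-sensing *interference* in co-cultures with
a LuxS⁻ (non-producing, still-sensing) knockout strain.

It is aimed at systems/synthetic biologists who have batch-culture
measurements — OD600 growth curves, AI-2 activity from a reporter
assay, β-galactosidase readouts of *lsr* expression — and want a
mechanistic, identifiable description of the signalling episode, or
who want to explore knockout co-cultures as a quorum-sensing control
strategy before running them.

## The model

Cell density follows a Gompertz curve
X(t) = X₀ + C·exp(−exp(−B(t−M))), which drives two ODEs:

    dA/dt = μ_A − μ_XA − μ_LA          (extracellular AI-2 activity)
    dL/dt = μ_L + μ_AL − μ_R           (lsr operon expression)

where μ_A = k_A·Xⁿ¹/(Xⁿ¹+k_m1ⁿ¹) is density-dependent AI-2 production,
μ_XA = k_XA·Xⁿ²/(Xⁿ²+k_m2ⁿ²)·A is basal uptake through the
phosphotransferase system (PTS), μ_LA = k_LA·(X/X_δ)·A·L is uptake by
the LsrACDB transporters once the operon is expressed,
μ_L = k_L·Xⁿ³/(Xⁿ³+k_m3ⁿ³)·A and μ_AL = k_AL·(X/X_δ)·A·L drive
expression, and μ_R = k_R·L is LsrR repression.

Calibration minimises the max-normalised sum of squared residuals
(SSWR) with Differential Evolution, in two stages (growth first, then
kinetics with growth frozen). Profile likelihood classifies parameter
identifiability; a weighted bootstrap (Exponential(1) residual
weights, 2.5/97.5% quantiles) gives confidence intervals. The
co-culture module splits the carrying capacity between a wild strain
and a LuxS⁻ knockout and sweeps capacity fractions and knockout
pre-culture head starts. See `docs/methods.md` for assumptions,
defaults, and known limitations.

## Worked example

```python
import numpy as np
from qsdyn import QSModel, DEConfig, DesignSpec, default_truth, generate_dataset

gp, qp = default_truth()                       # published best-fit set
data = generate_dataset(gp, qp, DesignSpec(cv=0.0, seed=1))

res = QSModel(data).fit(qs_cfg=DEConfig(pop_size=60, max_gen=150, seed=7))
print(res.summary())
```

prints (abridged):

```
Quorum-sensing model fit (two-stage SSWR / DE)
================================================
Growth stage (Gompertz, closed form)
  cost 7.40986e-10   generations 77   converged True
        X0 = 0.0640327
         C = 5.88269
         B = 0.638439
         M = 3.28231
Kinetic stage (A, L ODEs; growth frozen)
  cost 0.00798134   generations 150   converged False
        kA = 1420.78      in [1000, 2000]
       km1 = 1.54626      in [0.8491, 10]
       ...
  fixed: n3=0.001722, Xdelta=5.7953
```

The growth stage recovers the generating Gompertz constants to five
figures (the data are noiseless). The kinetic stage lands near the
generating values but not on them — the cost surface has genuinely
flat valleys (e.g. `km3` barely influences the fit, and `X_δ` only
appears in ratios with `k_LA`, `k_AL`), which is exactly what the
profile-likelihood tools are for:

```python
prof = res.profile("kA", seed=0)  # clamp-and-refit scan over [kA/5, 5*kA]
print(prof.classify(n_obs=28))    # identifiability label
boot = res.bootstrap(n_reps=50, cfg=DEConfig(pop_size=16, max_gen=30), seed=17)
print(boot.ci().loc["kA"])        # 2.5%/97.5% quantile interval
```

Simulating the published parameter set and the co-culture sweeps:

```python
from qsdyn import simulate, sweep_fractions, sweep_preculture

traj = simulate(gp, qp, np.linspace(0, 12, 1201))
print(round(traj.peak_A, 1), round(traj.peak_L, 1))   # 1035.3 1080.3

print(sweep_fractions(gp, qp)[["fraction", "L_ratio"]])
#    fraction   L_ratio
# 0       0.1  0.006523   <- minority wild strain: operon stays silent
# 1       0.3  0.305524
# 2       0.5  2.290953   <- equal split: ~2.3x overexpression at 12 h
# 3       0.7  2.005341
# 4       0.9  1.189586
```

AI-2 peaks mid-exponential phase (~1035 activity units at t ≈ 3.7 h)
and is depleted by the transporters; expression peaks ~1080 β-gal
units at t ≈ 5.3 h. In co-culture, a knockout majority starves the
wild strain of signal (fraction 0.1), while an equal split
*over*-expresses the operon relative to monoculture because neither
strain reaches the density that fires the PTS uptake switch.

There is also a CLI covering the same workflow:

```sh
qsdyn synth --seed 1 --out-dir run/
qsdyn fit run/dataset.csv --seed 2 --out-dir run/
qsdyn cocult --out-dir run/
qsdyn profile run/dataset.csv --fit-report run/fit.json --param kA
qsdyn bootstrap run/dataset.csv --fit-report run/fit.json --n-reps 100
```

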
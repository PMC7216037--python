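# radsorb

Sorption-kinetics modelling for radiotracer uptake on nanoparticle
carriers — in particular ²²³Ra, an α-emitting in-vivo-generator nuclide
for targeted alpha therapy, sorbing onto hydroxyapatite (nHAp) and
titanium-dioxide (nTiO₂) nanoparticles in batch contact experiments.

The question the package answers is the one a radiopharmaceutical
chemist asks of a kinetic curve: *which physical process controls the
uptake rate, how fast is it, and what diffusion coefficient does that
imply?*

## The model

A batch experiment contacts an aqueous tracer solution (concentration
*c*, mol/L) with a suspended solid sorbent (loading *q*, mol/kg) at
fixed phase ratio *r* (L/kg). Six first-order ODE rate laws, one per
candidate rate-controlling process, are closed by the mass balance and
the linear isotherm:

    c = c0 − (q − q0)/r,        q* = Kd·c,   c* = q/Kd

| process                    | id  | dq/dt |
|----------------------------|-----|-------|
| mass transfer              | DM  | K·(q* − q) |
| film diffusion             | FD  | K·(c − c*) |
| diffusion, inert layer     | ID  | K·(c − c*) / {[1 − q/q*]^(−1/3) − 1} |
| diffusion, reacted layer   | RLD | K·(q* − q) / {[1 − q/q*]^(−1/3) − 1} |
| chemical reaction          | CR  | K′·(c − c*)·[1 − q/q*]^(2/3) |
| gel diffusion              | GD  | K·[(q* − q0)² − (q − q0)²]/(q − q0) |

Each model has one free overall coefficient *K* (reported in
cm³·g⁻¹·min⁻¹). It is fitted to an observed sorbed-fraction curve by
weighted nonlinear least squares, and models are discriminated by

    χ² = Σ (y_obs − y_calc)²/s_q²,      WSOS/DF = χ²/(n_p − n)

with WSOS/DF in [0.1, 20] marking an acceptable fit. For the diffusion
models the coefficient inverts to an intraparticle diffusion
coefficient, e.g. K_RLD = 3·D/(R²·h_s) with particle length scale *R*
and specific mass *h_s*; the sorption half-life t½ (time to reach half
the equilibrium loading) quantifies the effective speed, which depends
on *K* **and** on the driving force set by the distribution
coefficient Kd.

Because the tracer is radioactive, concentrations come from activities
(c = A·T½/(ln2·V·N_A)) and the sorbed fraction from the
supernatant/pellet activity split Y = A_p/(A_s+A_p)·100. A synthetic
generator reproduces the batch protocol (25-point sampling schedule
over 24 h, r = 1000 L/kg, c₀ ≈ 10⁻¹¹ mol/L, Gaussian or Poisson
counting noise) so the whole pipeline is testable without lab data.

## Worked example

Simulate one virtual nHAp experiment at the mean reference parameters
(K_RLD = 0.503 cm³·g⁻¹·min⁻¹, Kd = 2.04·10⁴ L/kg, c₀ = 1.02·10⁻¹¹
mol/L), then fit all six models:

```bash
cat > sim.yaml <<EOF
c0: 1.02e-11
Kd: 2.04e4
r: 1000.0
model: RLD
K_printed: 5.03e-1
EOF
radsorb --seed 1 simulate --config sim.yaml --out obs.csv
radsorb fit --curve obs.csv --config sim.yaml
```

prints

```
model    K (cm3/g/min)     WSOS/DF  acceptable
RLD             0.5371       0.656  yes
ID               10.96       0.656  yes
GD               1.349       0.749  yes
CR               713.4        3.24  yes
DM               33.58       3.765  yes
FD               685         3.765  yes
```

The generating reacted-layer model is recovered (K̂ = 0.537 vs the true
0.503 under 5% noise) and ranks first. ID ties it exactly: under the
closures the ID and RLD laws are the same one-parameter family
(K_ID = K_RLD·Kd/r), which is why both shell-diffusion models are
acceptable on real shell-diffusion data while the exponential family
(DM/FD) fits visibly worse.

Recompute every derived quantity of the built-in reference systems
(replicate means ± population σ, diffusion coefficients, half-lives):

```bash
radsorb reproduce-reference
```

```
--- nHAp ---
Kd       computed 2.04e+04  reference 2.04e+04  delta +0
K_RLD    computed 0.5027  reference 0.503  delta -0.000333
t_half   computed 0.6414  reference 0.75  delta -0.109
D        computed 2.505e-12  reference 2.5e-12  delta +5.08e-15
eq. fraction sorbed: 95.33 %
```

i.e. for nHAp the mean fitted coefficient implies
D ≈ 2.5·10⁻¹² cm²/min and a sorption half-life under a minute — more
than 90 % of the tracer is bound within the first hour, which is what
makes these nanomaterials practical carriers.

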
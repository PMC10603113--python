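# redoxlan

Kinetic modelling of Fe³⁺/Fe²⁺ redox communication in a two-species
microbial co-culture — a "biological LAN" in which a signal-routing
reducer (*Shewanella putrefaciens*) converts Fe³⁺ to Fe²⁺, a
bio-actuator oxidizer (*Rhodopseudomonas palustris*) converts it back
while growing, and a persistent-luminescence nanoprobe (Zn₂GeO₄:Mn)
reads the shared redox state optically.

The package is aimed at modellers of microbial consortia and
extracellular electron transfer who need a tested, reproducible
implementation of this model family: calibration transforms, monoculture
transduction curves, the coupled co-culture ODE system, parameter
estimation, and a synthetic-data generator so every stage can be
validated without laboratory data.

## The model

**Calibration.** The nanoprobe's log-intensity is linear in the redox
ratio (percent convention, Fe_total = 2 mM):

    log₁₀(I) = 0.01764 · C_{Fe²⁺/Fe_total} + 2.126

**Monoculture transduction.** Fe²⁺ in a bare culture follows a
four-parameter logistic (4PL) sigmoid

    f(t) = B + (A − B) / (1 + (t/C)^D)

with early asymptote A, late asymptote B, half-transition time C (h) and
shape exponent D. The reducer's Fe²⁺ rises as f(t); the oxidizer's obeys
Fe_total − f(t).

**Co-culture.** State (cells_S, cells_R, [Fe²⁺]) with Fe³⁺ derived from
the closed 2 mM pool:

    d[cells]_S/dt = [Fe²⁺] · [cells]_S · E_S / (F_S + (G_S − F_S)/(1 + (t/H_S)^{I_S}))
    d[cells]_R/dt = (Fe_total − [Fe²⁺]) · [cells]_R · E_R / (F_R + (G_R − F_R)/(1 + (t/H_R)^{I_R}))
    d[Fe²⁺]/dt    = [cells]_S · J_S/(K_S + (L_S − K_S)/(1 + (t/M_S)^{N_S}))
                  − [cells]_R · J_R/(K_R + (L_R − K_R)/(1 + (t/M_R)^{N_R}))

Each coefficient is a "rate block" — an amplitude over a 4PL-shaped
denominator — so per-cell rates move smoothly between an early and a
late value. Integration uses an adaptive explicit Runge–Kutta (RK45)
scheme. Under the packaged default parameters the Fe²⁺ pool rises from
0, peaks at 0.76 mM mid-incubation, and declines — the signature of the
redox cycle (reducer production early, oxidizer consumption late).

## Worked example

```python
import redoxlan as rl

# redox state from a luminescence readout
calib = rl.reference_calibration()
fe2, fe3 = rl.fe2_from_intensity(calib, intensity=10**3.008, fe_total=2.0)
print(round(fe2, 6), round(fe3, 6))  # 1.0 1.0  (mM)

# simulate the co-culture and locate the Fe2+ peak
traj = rl.simulate(rl.default_truth(), t_max=96.0)
peak = rl.find_peak(traj.times, traj.fe2)
print(round(peak.value, 4), peak.t_peak)   # 0.76 54.75
```

The first line converts a raw intensity of 10^3.008 counts to a
half-reduced pool (1 mM Fe²⁺, 1 mM Fe³⁺). The simulation reproduces the
rise-then-decline Fe²⁺ time course with its 0.76 mM interior maximum at
~55 h of the 96-h run.

The numbered scripts under `analysis/` run the full study workflow —
standard-curve recovery, monoculture 4PL fits, co-culture simulation,
and the multi-seed model-fidelity experiment — writing tables under
`results/`. A command-line interface mirrors the same stages
(`redoxlan generate | calibrate | fit-4pl | simulate | fit-lan |
recover | run`).

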
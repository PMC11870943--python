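# ironpbpk

Whole-body physiologically based pharmacokinetic (PBPK) modelling of
intravenous iron: simulation of iron disposition in plasma, twelve tissues
and the red-blood-cell pool; naive-pooled maximum-likelihood parameter
estimation; and interspecies scaling from mouse to rat to human, including
the ferric carboxymaltose (FCM) depot variant.

## Who this is for

Pharmacometricians and quantitative pharmacologists working on iron
therapy — dosing of IV iron preparations for iron-deficiency anemia, tissue
iron exposure after FCM, or erythropoiesis-linked iron kinetics — who want
a transparent, scriptable implementation of a whole-body iron PBPK model
rather than a closed modelling platform.

## The model

The body is a plasma pool feeding twelve perfusion-limited organ
compartments in parallel, plus a circulating RBC iron pool. For a generic
organ *O* with volume V_O, plasma flow Q_O and tissue:plasma partition
coefficient KP_O:

    V_O dC_O/dt = Q_O C_P − (Q_O / KP_O) C_O

Bone additionally feeds the RBC pool at the erythropoietic utilization rate
Q_E (L/h); RBC iron returns to the spleen by erythrophagocytosis at
RBC/T_RBC, where T_RBC is the RBC lifespan; gut and spleen drain portally
into the liver; plasma loses iron irreversibly at the clearance CL_loss.
FCM doses enter a depot cleared into the spleen at the spleen plasma flow
(macrophage-mediated uptake). Everything is linear, so the system is
dA/dt = M·A with a conservation-exact generator matrix; an independent
matrix-exponential solution path cross-checks the stiff ODE solver.

Estimation is naive-pooled maximum likelihood (mean data, no random
effects) with proportional or additive residual error per compartment, and
RSE% from the observed information. Scaling uses Q2 = BW2·Q1/BW1 for
cardiac output and RBC-lifespan allometry Q_E,target = Q_E,source ·
(T_RBC,target/T_RBC,source)^0.75 for the erythropoietic rate.

See `docs/methods.md` for assumptions, numerics, and design choices.

## Worked example

Simulate the radiotracer study design (0.2 µmol ⁵⁹Fe/kg IV bolus in a 25 g
mouse, iron-adequate kinetics) and look at where the iron is four days in:

```python
import ironpbpk as ip

phys = ip.load_physiology("mouse")            # 25 g, plasma 1.09 mL
params = ip.load_parameters("mouse_iron_adequate")
dose = ip.DoseEvent(time=0.0, amount=0.2 * phys.body_weight)  # 0.005 umol
res = ip.simulate(phys, params, [dose], [0.25, 12, 24, 96, 168, 336, 672])

print(f"plasma C at 15 min: {res.concentration('plasma')[0]:.4f} umol/L")
print(f"RBC iron at day 4:  {res.amount('rbc')[3]:.5f} umol")
print(f"liver C at day 4:   {res.concentration('liver')[3]:.4f} umol/L")
total = res.amounts.sum(axis=1)
print(f"mass balance error: {abs(total - dose.amount).max()/dose.amount:.2e}")
```

prints

```
plasma C at 15 min: 0.0433 umol/L
RBC iron at day 4:  0.00137 umol
liver C at day 4:   0.8759 umol/L
mass balance error: 1.77e-13
```

The bolus leaves plasma almost immediately — 15 minutes in, less than 1% of
the initial 4.59 µmol/L remains, distribution being limited only by blood
flow. By day 4 about 27% of the dose sits in the RBC pool (erythropoietic
consumption) and the liver holds iron at roughly 35× the plasma
concentration, reflecting its storage role. Fitting the same design back
from noisy synthetic data:

```python
obs = ip.generate_mouse_study(params_by_diet={"iron_adequate": params},
                              sigma=0.05, replicates=3, mean_data=False,
                              seed=1)
fit = ip.fit_naive_pooled(phys, obs, params, n_starts=1, seed=2)
print(f"T_RBC = {fit.params.t_rbc:.2f} h (generating value 34.44 h)")
```

```
T_RBC = 33.34 h (generating value 34.44 h)
```

The same pipeline is exposed on the command line (`ironpbpk simulate`,
`generate`, `fit`, `scale`, `gof`); every command writes a `manifest.json`
that makes the run reproducible.

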
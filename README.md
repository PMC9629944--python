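# sorptherm

Moisture-sorption isotherm analysis for food materials: fit classical
isotherm models (GAB, Peleg, Enderby) to equilibrium moisture data, pick
the best model, and derive the sorption thermodynamics — isosteric heat,
differential entropy, Gibbs free energy, enthalpy–entropy compensation,
spreading pressure, sorption surface area and an optimal-storage humidity
estimate. Ships a reference dataset: desorption and adsorption isotherms
of five sweet-cherry cultivars at 30/40/50 °C measured by the static
gravimetric (saturated-salt) method.

## The science in one paragraph

The equilibrium moisture content `X_eq` of a food at water activity `a_w`
and temperature `T` follows a type-II sigmoid well described by the GAB
equation, `X_eq = A·B·C·a_w / [(1 − B·a_w)(1 − B·a_w + C·B·a_w)]`, whose
amplitude `A` is the monolayer moisture. Fitting isotherms at several
temperatures lets one apply the Clausius–Clapeyron relation at constant
moisture — the slope of `ln a_w` versus `1/T` gives the net isosteric
heat of sorption `q_st`, the intercept the differential entropy `ΔS`.
Across moisture levels `q_st` and `ΔS` compensate linearly; the slope of
that line is the isokinetic temperature `T_β` and the intercept the Gibbs
energy `ΔG_β` at `T_β`, whose sign decides whether sorption is
spontaneous. The monolayer also yields the sorption surface area
`S₀ = 3.5×10³·M_m` and, via the Gibbs adsorption isotherm, the spreading
pressure `π(a_w)`. See [docs/methods.md](docs/methods.md) for the full
formulation, units, defaults and limitations.

## Worked example

```python
from sorptherm import load_cherry_dataset
from sorptherm.fitting import fit_series, fit_model, select_best
from sorptherm.models import ModelId, monolayer_moisture
from sorptherm.surface import surface_area
from sorptherm.thermo import isosteric_analysis, compensation

dataset = load_cherry_dataset()          # 30 isotherm series, 180 records
series = next(s for s in dataset
              if s.sample_id == "Napoleon" and s.mode.value == "adsorption"
              and s.temperature_c == 30.0)

fits = fit_series(series)                # GAB, Peleg, Enderby
sel = select_best(fits)
win = next(f for f in fits if f.model_id is sel.winner)
print(f"best model: {sel.winner.name}  r={win.r:.4f}  MRE={win.mre:.2f}%")

gab = {s.temperature_c: fit_model(s, ModelId.GAB)
       for s in dataset
       if s.sample_id == "Napoleon" and s.mode.value == "adsorption"}
print(f"S0 at 30 degC = "
      f"{surface_area(monolayer_moisture(gab[30.0].params)):.1f} m2/g")

table = isosteric_analysis(gab)          # Clausius-Clapeyron on a moisture grid
comp = compensation(table)
print(f"q_st at 18% d.b.: {table.qst_kj_mol[table.xeq_grid.index(18.0)]:.2f} kJ/mol")
print(f"T_beta = {comp.t_beta_k:.2f} K, dG_beta = {comp.dg_beta_j_mol:.1f} J/mol, "
      f"spontaneous: {comp.spontaneous}")
```

prints

```
best model: GAB  r=1.0000  MRE=6.39%
S0 at 30 degC = 513.7 m2/g
q_st at 18% d.b.: 15.99 kJ/mol
T_beta = 341.54 K, dG_beta = 1366.0 J/mol, spontaneous: False
```

The same analysis end-to-end from the command line:

```sh
sorptherm all --outdir results/cherry            # packaged dataset
sorptherm all --input mydata.csv --outdir out    # your own CSV
sorptherm simulate --outdir sim --seed 5         # synthetic dataset + truth
sorptherm recover --replicates 200 --sigma 0.02  # parameter-recovery study
```

`sorptherm all` writes `fits.csv`, `thermo.csv`, `compensation.csv`,
`smooths.csv`, `surface.csv`, `spreading_pressure.csv`, `storage.csv`
and a machine-readable `summary.json`; reruns are byte-identical. Input
CSVs need the columns `sample_id,mode,temperature_c,aw,xeq_percent_db`
with `mode` in `{desorption, adsorption}`.

## Package layout

| Module | Purpose |
|---|---|
| `sorptherm.records` | record/series types, validation, CSV I/O, salt a_w table |
| `sorptherm.datasets` | packaged cherry dataset and cultivar metadata |
| `sorptherm.models` | GAB/Peleg/Enderby equations, bounds, inversion |
| `sorptherm.fitting` | deterministic multi-start least squares, r/MRE, selection |
| `sorptherm.thermo` | isosteric heat, entropy, Gibbs energy, compensation |
| `sorptherm.surface` | spreading pressure (closed form + quadrature oracle), S₀, storage optimum |
| `sorptherm.synthetic` | seeded synthetic-isotherm generator and recovery study |
| `sorptherm.pipeline`, `sorptherm.cli` | end-to-end runs and the `sorptherm` command |

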
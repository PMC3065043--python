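# nanocell

Spatiotemporal modelling of combination cancer therapy delivered by
nanoscale carriers: why does packaging an antiangiogenic agent
(combretastatin) in the envelope of a nanoparticle and a chemotherapeutic
(doxorubicin) in its core — so the first releases fast and the second slow
— beat a liposome that dumps both drugs at once?

The package is for computational-oncology work on therapy scheduling: it
simulates tumor growth coupled to vasculature in 3D, the pharmacokinetics
of carrier uptake and staged drug release, all six experimental treatment
arms, parameter calibration from tumor-volume curves, and mechanism
ablations that isolate *why* the sequential design wins.

## Model

Tumor-cell density `n` and vessel density `m` evolve on a 3D no-flux grid
(dimensionless units; time scaled by the proliferation rate ρ, space by
√(D₁/ρ)):

    ∂n/∂t = ∇²n + n(1−n) + α₁mn − A_D d n
    ∂m/∂t = D₂∇²m + m(α + βm + γm²) + α₂nm − A_C c m

a Fisher–KPP equation with vasculature-enhanced carrying capacity, coupled
to a bistable vessel field (avascular 0 / normal 1) with angiogenic drive.
The uniform fixed points solve γm² + (β+α₁α₂)m + (α+α₂) = 0 with
n\* = 1+α₁m\*; at the fitted couplings the tumor state is m\* = 1.97,
n\* = 3.17.  Carriers extravasate at rate δΓ_i(t)·m·exp(−(m/m_lim)²) — the
efficiency kernel peaks at intermediate vessel density, so vascular
"normalization" transiently improves delivery — and release free agents
through normalized gamma-family kernels (slow core: p = 0.3, τ = 15 d;
fast liposome: p = 0.1, τ = 2 d; every arm releases the same total dose).
Free chemotherapy is cleared through intact vessels (−μmd): when the
antiangiogenic collapses the vasculature, that clearance stops and the
drug is *trapped* in the tumor — the central synergy mechanism.

## Worked example

```python
import nanocell as nc

params = nc.default_parameters("lung")          # Lewis lung carcinoma defaults
print(nc.vasculature_fixed_points(params))  # (0.025385..., 1.969614...)

grid = nc.Grid.for_params(params, shape=(50, 50, 50), h=0.6)
for arm in nc.ARM_NAMES:
    curve = nc.run_arm(arm, params, grid, seed=1, t_end_day=17.0, dt=0.05)
    print(f"{arm:>10}: day-17 volume = {curve.final_volume():8.1f} mm^3")
```

prints

```
         V: day-17 volume =   3578.9 mm^3
      NC_D: day-17 volume =   2250.7 mm^3
       L_C: day-17 volume =   2203.9 mm^3
      L_CD: day-17 volume =   1119.8 mm^3
     NC_CD: day-17 volume =    251.9 mm^3
 NC_CD_mod: day-17 volume =     52.7 mm^3
```

Reading the numbers: each monotherapy (chemo-only nanocells NC[D],
antiangiogenic-only liposomes L[C]) removes ~1.3–1.4 cm³ relative to the
untreated control V; the conventional co-encapsulating liposome L[CD]
roughly doubles that; the sequential-release nanocell NC[CD] is ~4.5×
better than L[CD] *with the same delivered dose*; and delaying the core
release further (NC[CD]_mod, p = 0.8) improves it again.  Setting the
vessel-reabsorption rate μ to zero shrinks the NC[CD]-vs-L[CD] gap by
~64% (`analysis/05_mechanism_ablation.py`): trapping, not extra delivery,
drives the advantage.

## Analysis scripts

Numbered drivers under `analysis/` rerun each stage and write tables to
`results/`: fixed points (01), release-profile normalization (02), the
50 mm³ free-growth anchor and grid calibration (03), the six-arm
comparison (04), mechanism ablations (05), synthetic-data parameter
recovery (06), and the ±5% sensitivity scan (07).  All accept `--seed`,
grid and cancer-type options; see `--help`.

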
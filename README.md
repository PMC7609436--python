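# axmorph

Quantitative tools for studying axial-mesoderm morphogenesis during
zebrafish gastrulation: a cellular Potts model (CPM) of prechordal-plate-led
notochord condensation, 3D optic-flow tissue velocimetry on spherical embryo
geometry, FRAP recovery-curve fitting, and label-image morphometrics.
Synthetic-data generators with known ground truth replace microscopy data,
so every analysis stage is testable end to end.

The package is aimed at quantitative developmental biologists and
biophysicists who want to reproduce, probe or extend the "leader cell"
simulations and the accompanying quantifications without access to raw
imaging data.

## The model

The tissue is a 2D lattice in which each site `x` belongs to one cell
`σ(x)` (0 = medium). The energy of a configuration is the
Glazier–Graner–Hogeweg Hamiltonian

```
H = Σ_links J(τ(σ(x)), τ(σ(x'))) (1 − δ_{σ(x) σ(x')})
  + Σ_cells λ_V (V(σ) − V₀(σ))²
  + Σ_cells λ_S (S(σ) − S₀(σ))²
```

with type-pair contact energies `J`, and quadratic volume and surface
constraints. Directed migration enters through a linear anterior–posterior
potential `c`: a copy attempt by a motile cell adds

```
ΔH_M = µ(τ(source)) · λ_M · [c(source) − c(target)]
```

and the total change `ΔH = ΔH_B + ΔH_M` is accepted with the Metropolis
probability `min(1, exp(−ΔH/T))`. One Monte Carlo step (MCS) performs one
copy attempt per surface site.

Five cell types are modelled: medium, the E-cadherin-positive leading edge,
the prechordal plate (ppl), the trailing notochordal plate (NC), and the
flanking lateral plate mesoderm (lpm). New lpm cells ingress posteriorly on
a fixed schedule; a run stops when the lpm spans 400 µm along the
anterior–posterior axis. Three scenarios alter the ppl relative to
baseline: `mobile_leaders` (motility ×2), `adhesive_leaders` (ppl–ppl bond
strength ×2), and `mobile_adhesive_leaders` (both).

The analysis side provides Lucas–Kanade-style volumetric optic flow with a
20×20×8 sliding box, least-squares sphere fitting and (v_r, v_θ, v_φ)
decomposition, relative-velocity kymographs and Mercator flow maps,
single-exponential FRAP fitting `I(t) = plateau·(1 − e^{−kt})` with
`t90 = −ln(0.1)/k`, circularity `4πA/P²`, Pearson colocalization, cluster
sizing and wound-gap closure speed.

## Worked example

```python
from axmorph.scenarios import run_scenario, lpm_ap_extent
from axmorph import morphometrics as mm
from axmorph.cpm import CellType

traj = run_scenario("mobile_adhesive_leaders", seed=0)
st = traj.final_state
nc_ap, nc_ml, nc_ar = mm.tissue_extents(st, CellType.NC)
print(f"terminated by: {traj.termination} after {traj.mcs} MCS")
print(f"lpm AP extension: {lpm_ap_extent(st):.0f} um")
print(f"notochord: AP {nc_ap:.0f} um x ML {nc_ml:.0f} um, aspect {nc_ar:.2f}")
print(f"leading-edge front: {mm.front_curvature_class(st, CellType.LEADING_EDGE)}")
```

prints

```
terminated by: threshold after 770 MCS
lpm AP extension: 400 um
notochord: AP 150 um x ML 50 um, aspect 3.00
leading-edge front: convex
```

i.e. the run ended at the 400 µm lateral-plate extension stop, the
notochord condensed into a rod three times longer than wide, and the fast,
cohesive prechordal plate pushed the leading edge into a convex outline.
With `adhesive_leaders` the same call yields a broad notochord (aspect
≈ 1.8) behind a concave front, and `replicate_study()` tabulates these
morphometrics over scenarios × seeds.

The same functionality is available from the shell:

```
axmorph simulate --scenario mobile_adhesive_leaders --seed 0 --out runs/ma0
axmorph replicate --seeds 10 --out summary.csv
axmorph frap fit trace.csv --fraction 0.9
axmorph shape circ labels.tif --pixel-size 0.2
```

## Documentation

`docs/methods.md` describes the model, the calibration of its parameters,
the synthetic-data generators and the package's numerical conventions and
limitations.
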
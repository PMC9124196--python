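# dcisim

Multiscale agent-based simulation of early ductal carcinoma in situ (DCIS)
progression inside a mammary duct, with cancer stem cell dedifferentiation
plasticity and a global/local sensitivity-analysis toolkit.

## The scientific problem

DCIS — stage-zero breast cancer confined to the duct lumen — is seeded by
tumor-initiating cells (TICs) at the top of a phenotypic hierarchy:
multipotent stem-like cells renew themselves and produce progenitor
daughters, which divide a finite number of times before terminal
differentiation. Because stem daughters are rare (≈ 12 % per stem
division) while progenitors expand exponentially, the stem fraction is
diluted over time; when the lesion's leading edge runs out of
proliferation-competent cells, axial invasion arrests. Stochastic
*dedifferentiation* — progenitors reverting to the stem phenotype at a
small per-cell-cycle probability Ω_DD — can replenish the stem niche and
rescue progression. `dcisim` exists to quantify that rescue: which model
parameters drive early DCIS progression, and how progression and stem-pool
maintenance scale with Ω_DD.

The model couples three scales:

* **tissue** — a rigid duct segment (cylinder, lumen radius R) whose wall
  supplies oxygen and estrogen;
* **cell** — lattice-free spherical agents with the hierarchy
  stem → progenitor → differentiated plus reversible quiescence (local
  volume occupancy ≥ θ_Q), hypoxia → necrosis → calcification, per-step
  apoptosis, and the dedifferentiation edge progenitor → stem
  (per-step probability `1 − (1 − Ω_DD)^(Δt/τ)`);
* **molecular** — quasi-steady reaction–diffusion fields (O2, estrogen,
  AREG, FGF) on a voxel grid, with ER+ cells gated by estrogen (θ_E), ER−
  cells gated by FGF (θ_FGF), and the paracrine relay
  estrogen → ER+ → AREG → stroma → FGF → ER−.

The analysis layer reproduces a three-study design: Latin-hypercube
perturbation of all parameters with the dedifferentiation pathway off
(growth always arrests), the same with the pathway on (it never does),
and a local sweep of Ω_DD alone, summarized by a Michaelis–Menten fit of
axial advance rate, `advance = V_max·Ω_DD / (K_M + Ω_DD)` µm/day, and a
through-origin linear fit of the daily change in stem percent density,
`Δstem%/day = slope · Ω_DD[%]`.

See `docs/methods.md` for the full model description, parameter table,
numerical choices, and known limitations.

## Worked example

```python
from dcisim import ParameterSet, run
from dcisim.metrics import run_outputs

params = ParameterSet(duct_length=300.0, duct_inner_diameter=80.0)
result = run(params, seed=42, t_end_days=10.0)
print(run_outputs(result.record))
```

which prints (seed 42):

```
{'t_end_d': 10.0, 'arrest_time_d': None,
 'advance_rate_um_d': 3.346383648129722, 'prolif_per_day': 11.5,
 'calc_extent_um': 0.0, 'n_calcified': 0, 'quiescence_time_d': None,
 'n_total': 46, 'n_er_pos': 37, 'n_er_neg': 8,
 'stem_pct': 2.1739130434782608}
```

Ten days in, the lesion holds 46 live cells — mostly ER+ progenitors,
because the paracrine FGF relay that licenses ER− proliferation only opens
once enough estrogen-stimulated ER+ cells secrete AREG — the invasion
front advances ≈ 3.3 µm/day (summed over both axial directions), 2.2 % of
live cells are stem-like, and nothing is hypoxic or calcified yet. The
same call with `omega_dd=0.0` and a 35-day horizon ends in growth arrest
(`arrest_time_d` set, stem fraction 0) as the leading edge terminally
differentiates.

The same run from the shell:

```bash
dcisim simulate --config cfg.yaml --seed 42 --days 10 --out out/
dcisim analyze --run out/ --out summary.json
dcisim sense --study 3 --seed 7 --profile desk --out sweep/
```

`sense --study 3` writes the Ω_DD sweep table plus `fits.json` with the
Michaelis–Menten (V_max, K_M) and through-origin (slope) summaries.

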
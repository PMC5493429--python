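#!/usr/bin/env python
"""Characterise the new I_Kur formulation and its six mutant variants.

Writes, under results/channel/:

* ``steady_states.csv`` -- steady-state activation and availability curves
  of WT and the six mutants on a 1 mV grid;
* ``iv_curves.csv`` -- end-of-step I-V relations from the simulated step
  clamp (-40..+60 mV, 10 mV increments, 1500 ms steps);
* ``time_constants.csv`` -- Q10-corrected activation/inactivation time
  constants;
* ``wt_equivalent.json`` -- the single-Boltzmann fit of the WT two-factor
  activation that anchors the mutant parameter changes.

Findings printed at the end: the gain-of-function variants (D332H, E48G,
A305T) shift activation negative and scale conductance up; the
loss-of-function variants (Y155C, D469E, P488S) mainly lose conductance,
with P488S retaining only ~4% of the WT maximum.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from kcna5.clamp import ClampProtocol, iv_table, simulate_voltage_clamp
from kcna5.ikur import (
    TABLE1_DELTAS,
    activation_steady_state,
    inactivation_steady_state,
    mutant_model,
    tau_activation,
    tau_inactivation,
    wt_equivalent_activation,
    wt_model,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "channel"
OUT.mkdir(parents=True, exist_ok=True)

variants = {"WT": wt_model(), **{m: mutant_model(m) for m in TABLE1_DELTAS}}
v = np.arange(-100.0, 80.5, 1.0)

rows = []
for label, model in variants.items():
    rows.append(pd.DataFrame({
        "label": label, "v_mV": v,
        "act_ss": activation_steady_state(v, model),
        "inact_ss": inactivation_steady_state(v, model),
    }))
pd.concat(rows).to_csv(OUT / "steady_states.csv", index=False)

wt = variants["WT"]
pd.DataFrame({
    "v_mV": v,
    "tau_act_ms": tau_activation(v, wt),
    "tau_inact_ms": tau_inactivation(v, wt),
}).to_csv(OUT / "time_constants.csv", index=False)

iv_rows = []
for label, model in variants.items():
    traces = simulate_voltage_clamp(model, ClampProtocol())
    iv = iv_table(traces, measure="end").assign(label=label)
    iv_rows.append(iv)
iv_all = pd.concat(iv_rows)
iv_all.to_csv(OUT / "iv_curves.csv", index=False)

eq = wt_equivalent_activation()
(OUT / "wt_equivalent.json").write_text(json.dumps(
    {"v_half_mV": eq.v_half, "slope_k_mV": eq.slope_k}, indent=2))

peak = iv_all[iv_all.step_v_mV == 60.0].set_index("label")["current_pA_per_pF"]
print("End-of-step current at +60 mV (relative to WT):")
for label in variants:
    print(f"  {label:6s} {peak[label] / peak['WT']:.3f}")
print(f"WT-equivalent activation Boltzmann: V1/2 = {eq.v_half:.2f} mV, "
      f"k = {eq.slope_k:.2f} mV")
print(f"wrote {OUT}")
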
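# kcna5 — multi-scale in-silico analysis of KCNA5 (Kv1.5 / I_Kur) mutations

Six naturally occurring mutations of *KCNA5*, the gene encoding the Kv1.5
channel that carries the atrial-specific ultra-rapid delayed rectifier
current I_Kur, have been found in patients with lone atrial fibrillation —
three increasing the current (gain of function: D332H, E48G, A305T) and
three reducing it (loss of function: Y155C, D469E, P488S).  This package
reimplements the computational chain needed to ask what those channel-level
changes do to atrial electrical function:

1. **Channel**: a Hodgkin–Huxley I_Kur formulation,
   `I_Kur = g(V)·a·i·(V − E_K)`, with a two-Boltzmann steady-state
   activation, an availability curve with a non-zero floor (minimum
   availability *MA*), Q10-corrected time constants (KQ10 = 3.52) and a
   voltage-dependent maximal conductance.  Mutants are relative changes to
   the wild type: ΔV½ (additive), slope factors ×k, ΔMA (additive) and
   conductance factors ×g.
2. **Fitting**: simulated whole-cell voltage clamp, Boltzmann
   (`I/I_max = 1/{1+exp[(V−V½)/k]}`; availability
   `(1−MA)/{1+exp[(V−V½)/k]} + MA`) and mono-exponential τ fitting, and the
   generate-fit-difference round trip that recovers the six mutant records
   from synthetic recordings with known ground truth.
3. **Cells**: Courtemanche-lineage (full reimplementation) and
   Grandi-lineage (calibrated reconstruction) human atrial myocytes with a
   pluggable I_Kur, regional (RA/CT/PM), chronic-AF and isoprenaline (ISO)
   variants; AP metrics, S1–S2 restitution and early-after-depolarisation
   (EAD) detection.
4. **Tissue**: a 1D/2D monodomain solver
   (`∂V/∂t = ∇·(D∇V) − I_ion/C_m`) with conduction-velocity calibration,
   S1–S2 vulnerability windows for unidirectional block at the crista
   terminalis / pectinate muscle junction, a pacemaker-surrogate strand, and
   phase-distribution re-entry on a 2D sheet with dominant-frequency
   analysis.

The science, parameter choices and limitations are documented in
[docs/methods.md](docs/methods.md).

## Worked example

```python
from kcna5.ikur import mutant_model, wt_model, conductance_scale
from kcna5.cells.base import build_cell, pace, PacingProtocol
from kcna5.ap_metrics import measure_ap

print(conductance_scale(0.0, mutant_model("P488S"))
      / conductance_scale(0.0, wt_model()))
# 0.038  -> P488S retains 3.8% of the WT maximal conductance

proto = PacingProtocol(n_s1=12, s1_cl=1000.0)
for mut in (None, "D332H", "P488S"):
    cell = build_cell("courtemanche_newIKur", mutation=mut)
    t, v = pace(cell, proto)
    m = measure_ap(t, v, proto.onsets(), beat=-1)
    print(mut or "WT", round(m.apd30, 1), round(m.apd90, 1))
# WT     8.3  315.9
# D332H  6.1  277.8
# P488S  200.2  287.9
```

The gain-of-function mutant D332H abbreviates early repolarisation (APD30
8.3 → 6.1 ms, APD90 −38 ms); the near-complete loss of current in P488S
raises the plateau so APD30 grows more than twenty-fold while secondary
effects on the late K⁺ currents still leave APD90 *shorter* than WT — the
non-monotone role of I_Kur in AP duration that makes these mutations
interesting.

EAD scan under β-adrenergic stimulation (Grandi lineage, 1 µM ISO):

```bash
python analysis/04_ead_scan.py    # `kcna5 ead-scan` gives the same as JSON
```

```
EAD counts (ISO, 1 Hz):
region     CT  PM  RA
mutation
D469E       1   0   0
P488S       1   1   1
WT          0   0   0
Y155C       2   2   2
```

Loss-of-function mutants produce EADs; D469E does so only in the crista
terminalis, whose larger L-type Ca²⁺ current tips the plateau balance.

The `analysis/` directory holds the numbered end-to-end studies (channel
characterisation, round-trip recovery, single-cell tables, EAD scans,
conduction-velocity calibration, vulnerability windows plus their
sensitivity analysis, pacemaker-surrogate patterns, 2D re-entry); each
writes its tables under `results/` and prints a summary.  The same
computations are scriptable through the `kcna5` command-line interface
(`kcna5 --help`).

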
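"""Named parameter-scaling tables for regional, chronic-AF and ISO variants.

The tables are multiplicative factors on maximal conductances (or SERCA
affinity) relative to the right-atrial baseline of each lineage.  They are
editable records so alternative published sets can be dropped in.

Provenance and caveats
----------------------
* Regional crista terminalis (CT) / pectinate muscle (PM) electrophysiology:
  the CT carries a larger L-type Ca2+ current (longer, more plateaued AP)
  while the PM is close to the right-atrial baseline with slightly larger
  transient outward current.  Exact published factors for every lineage are
  not recoverable from the primary sources available here, so the values
  below are provisional, chosen to reproduce the qualitative regional
  ordering (CT APD > RA APD > PM APD; CT most EAD-prone).
* Chronic AF electrical remodelling: the widely used set -- I_CaL and I_to
  strongly down-regulated, I_K1 up-regulated, I_Kur halved.
* ISO (isoprenaline 1 uM, beta-adrenergic stimulation): I_CaL x2.6,
  I_Ks x3, I_Kur x3, applied with the same fractional changes to the
  homologous currents of every lineage.  The I_CaL factor was calibrated
  within the reported range of beta-adrenergic L-type enhancement so that
  the Grandi-lineage reimplementation reproduces the published
  region-by-mutant EAD pattern.  The phospholamban (SERCA-affinity)
  component of the beta-adrenergic response is omitted: in the consolidated
  Ca2+ subsystem it drives the sarcoplasmic reticulum into a spontaneous
  leak regime, i.e. the delayed-afterdepolarisation territory that this
  package deliberately does not model.
"""

from __future__ import annotations

REGION_SCALINGS: dict[str, dict[str, float]] = {
    "RA": {},
    "CT": {"g_cal": 1.67, "g_to": 0.75},
    "PM": {"g_cal": 0.95, "g_to": 1.05},
}

CAF_SCALINGS: dict[str, float] = {
    "g_cal": 0.35,
    "g_to": 0.35,
    "g_kur": 0.5,
    "g_k1": 2.0,
}

ISO_SCALINGS: dict[str, float] = {
    "g_cal": 2.6,
    "g_ks": 3.0,
    "g_kur": 3.0,
}

VALID_REGIONS = tuple(REGION_SCALINGS)
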
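"""Experiment orchestration: configured, reproducible runs with provenance.

Each experiment is a named, declaratively-configured computation over the
library (clamp-fit round trips, single-cell characterisation, EAD scans,
strand conduction velocity, vulnerability windows, pacemaker-driven
conduction patterns, 2D re-entry).  A run writes one directory containing a
``config.json`` echo (with config hash and package version), a
``metrics.json`` result record, optional trace files, and a ``log.txt``.
Identical configs produce bit-identical metrics; the only stochastic
component in the package is the synthetic clamp noise, driven by the
config seed.
"""

from __future__ import annotations

import hashlib
import json
import time
import traceback
from pathlib import Path
from typing import Any, Callable

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, ValidationError

import kcna5
from kcna5.ikur import TABLE1_DELTAS, canonical_mutant_label

__all__ = ["ExperimentConfig", "run_experiment", "report_summary",
           "EXPERIMENTS", "SCHEMA_VERSION"]

SCHEMA_VERSION = 1


class ExperimentConfig(BaseModel):
    """Declarative description of one experiment run."""

    experiment: str
    params: dict[str, Any] = Field(default_factory=dict)
    seed: int = 0
    outdir: str | None = None
    schema_version: int = SCHEMA_VERSION

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(exclude={"outdir"}),
                             sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _check_mutation(params: dict) -> None:
    mut = params.get("mutation")
    if mut is not None:
        canonical_mutant_label(mut)  # raises KeyError with the bad label


# ---------------------------------------------------------------------------
# experiment implementations (each returns a metrics dict, may write traces)
# ---------------------------------------------------------------------------

def _exp_table1_roundtrip(params, seed, outdir):
    from kcna5.roundtrip import roundtrip_errors, table1_roundtrip

    noise = float(params.get("noise_frac", 0.0))
    rec = table1_roundtrip(noise_frac=noise, seed=seed)
    err = roundtrip_errors(noise_frac=noise, seed=seed)
    if outdir:
        rec.to_csv(Path(outdir) / "recovered_deltas.csv")
    return {
        "noise_frac": noise,
        "max_abs_error": float(err.to_numpy().max()),
        "per_field_max_error": {k: float(v) for k, v in err.max().items()},
        "recovered": {m: {k: float(v) for k, v in row.items()}
                      for m, row in rec.iterrows()},
    }


def _cell_from_params(params):
    from kcna5.cells.base import build_cell

    _check_mutation(params)
    return build_cell(
        params.get("model_id", "courtemanche_newIKur"),
        region=params.get("region", "RA"),
        mutation=params.get("mutation"),
        caf=bool(params.get("caf", False)),
        iso=bool(params.get("iso", False)),
    )


def _exp_cell_sim(params, seed, outdir):
    from kcna5.ap_metrics import measure_ap
    from kcna5.cells.base import PacingProtocol, pace

    cell = _cell_from_params(params)
    n_beats = int(params.get("n_beats", 20))
    cl = float(params.get("cl", 1000.0))
    proto = PacingProtocol(n_s1=n_beats, s1_cl=cl)
    t, v = pace(cell, proto, dt=float(params.get("dt", 0.005)), tail=cl)
    m = measure_ap(t, v, proto.onsets(), beat=-1)
    if outdir:
        pd.DataFrame({"time_ms": t, "v_mV": v}).to_csv(
            Path(outdir) / "traces" / "voltage.csv", index=False)
    return {"rmp": m.rmp, "peak_v": m.peak_v, "max_dvdt": m.max_dvdt,
            "apd30": m.apd30, "apd90": m.apd90, "plateau_v": m.plateau_v,
            "ead_count": m.ead_count}


def _exp_restitution(params, seed, outdir):
    from kcna5.ap_metrics import restitution

    cell = _cell_from_params(params)
    s2 = params.get("s2_grid", [300, 400, 500, 700, 1000])
    rc = restitution(cell, s2, n_s1=int(params.get("n_s1", 100)),
                     s1_cl=float(params.get("s1_cl", 1000.0)))
    if outdir:
        rc.table.to_csv(Path(outdir) / "restitution.csv", index=False)
    return {"table": rc.table.to_dict("records")}


def _exp_ead_scan(params, seed, outdir):
    from kcna5.ap_metrics import ead_count_steady
    from kcna5.cells.base import PacingProtocol, pace

    model_id = params.get("model_id", "grandi")
    regions = params.get("regions", ["RA", "CT", "PM"])
    mutations = params.get("mutations", [None, "Y155C", "D469E", "P488S"])
    iso = bool(params.get("iso", True))
    n_beats = int(params.get("n_beats", 12))
    matrix = {}
    for region in regions:
        for mut in mutations:
            cell = _cell_from_params({"model_id": model_id, "region": region,
                                      "mutation": mut, "iso": iso})
            proto = PacingProtocol(n_s1=n_beats, s1_cl=1000.0)
            t, v = pace(cell, proto, tail=1000.0)
            matrix[f"{region}:{mut or 'WT'}"] = ead_count_steady(
                t, v, proto.onsets())
    return {"iso": iso, "ead_matrix": matrix}


def _exp_strand_cv(params, seed, outdir):
    from kcna5.tissue import CableConfig, calibrate_diffusion, strand_cv

    cfg = CableConfig(
        model_id=params.get("model_id", "courtemanche_newIKur"),
        n_nodes=int(params.get("n_nodes", 200)),
        dx=float(params.get("dx", 0.25)),
        dt=float(params.get("dt", 0.02)),
        mutation=params.get("mutation"),
    )
    target = float(params.get("target_cv", 1.3))
    bracket = tuple(params.get("bracket", (0.02, 1.2)))
    d, cv = calibrate_diffusion(cfg, target, float(params.get("tolerance", 0.005)),
                                bracket=bracket)
    out = {"d_mm2_per_ms": d, "achieved_cv_m_per_s": cv, "target_cv": target}
    for scale in params.get("d_scales", []):
        out[f"cv_at_{scale}"] = strand_cv(cfg, d * float(scale))
    return out


def _exp_vw_scan(params, seed, outdir):
    from kcna5.tissue import (CableConfig, calibrate_diffusion, ct_pm_strand,
                              vulnerability_window, with_threshold_stimulus)

    model_id = params.get("model_id", "grandi")
    dt = float(params.get("dt", 0.015))
    d = params.get("d")
    if d is None:
        base = CableConfig(model_id=model_id, n_nodes=200, dx=0.25, dt=dt)
        d, _ = calibrate_diffusion(base, 1.3, 0.005,
                                   bracket=tuple(params.get("bracket", (0.05, 2.0))))
    _check_mutation(params)
    cfg = ct_pm_strand(model_id, mutation=params.get("mutation"),
                       iso=bool(params.get("iso", False)), d=float(d), dt=dt)
    cfg = with_threshold_stimulus(cfg)  # S1/S2 at 2x diastolic threshold
    vw = vulnerability_window(
        cfg, scan=tuple(params.get("scan", (150.0, 800.0))),
        coarse_step=float(params.get("coarse_step", 25.0)),
        resolution=float(params.get("resolution", 1.0)))
    return {"d_mm2_per_ms": float(d), "s2_low_ms": vw.s2_low,
            "s2_high_ms": vw.s2_high, "width_ms": vw.width,
            "resolution_ms": vw.resolution, "non_monotone": vw.non_monotone,
            "stim_amplitude_pA_per_pF": cfg.stim_amplitude}


def _exp_san_pattern(params, seed, outdir):
    from kcna5.tissue import CableConfig, san_conduction_pattern

    _check_mutation(params)
    n = int(params.get("n_nodes", 200))
    iso = params.get("iso", True)
    if iso == "one_flank":
        mask = np.zeros(n, dtype=bool)
        mask[: n // 2] = True
        iso = mask
    regions = params.get("regions", "CT")
    if isinstance(regions, list):
        regions = np.asarray(regions, dtype=object)
    cfg = CableConfig(model_id=params.get("model_id", "grandi"),
                      n_nodes=n, dx=0.25, d=float(params.get("d", 1.5)),
                      dt=float(params.get("dt", 0.015)), regions=regions,
                      mutation=params.get("mutation"), iso=iso)
    beats = san_conduction_pattern(cfg, n_beats=int(params.get("n_beats", 6)),
                                   cycle_length=float(params.get("cl", 750.0)))
    return {"beats": beats}


def _exp_reentry_2d(params, seed, outdir):
    from kcna5.cells.base import build_cell
    from kcna5.sheet import (SheetConfig, build_phase_library,
                             init_sheet_phase_map, run_reentry)

    _check_mutation(params)
    cfg = SheetConfig(
        model_id=params.get("model_id", "courtemanche_newIKur"),
        nx=int(params.get("nx", 100)), ny=int(params.get("ny", 100)),
        dx=float(params.get("dx", 0.5)),
        d_control=float(params.get("d_control", 0.67)),
        d_scale=float(params.get("d_scale", 0.4)),
        mutation=params.get("mutation"), caf=bool(params.get("caf", True)),
        dt=float(params.get("dt", 0.02)))
    cell = build_cell(cfg.model_id, mutation=cfg.mutation, caf=cfg.caf)
    lib = build_phase_library(cell, n_snapshots=int(params.get("n_snapshots", 64)),
                              n_precondition=int(params.get("n_precondition", 20)))
    init = init_sheet_phase_map(cfg, lib, params.get("layout", "archimedean"))
    m = run_reentry(cfg, init, duration=float(params.get("duration", 2000.0)))
    if outdir:
        pd.DataFrame(m.site_traces,
                     columns=[f"site{i}" for i in range(m.site_traces.shape[1])]) \
            .assign(time_ms=m.t).to_csv(Path(outdir) / "traces" / "sites.csv",
                                        index=False)
    return {"sustained": m.sustained, "lifetime_ms": m.lifetime,
            "dominant_frequency_hz": m.dominant_frequency,
            "per_site_df_hz": [float(f) for f in m.dominant_frequencies]}


EXPERIMENTS: dict[str, Callable] = {
    "table1-roundtrip": _exp_table1_roundtrip,
    "clamp-fit": _exp_table1_roundtrip,
    "cell-sim": _exp_cell_sim,
    "restitution": _exp_restitution,
    "ead-scan": _exp_ead_scan,
    "strand-cv": _exp_strand_cv,
    "vw-scan": _exp_vw_scan,
    "san-pattern": _exp_san_pattern,
    "reentry-2d": _exp_reentry_2d,
}


def run_experiment(config: ExperimentConfig | dict) -> dict:
    """Execute one configured experiment; returns the result bundle.

    Partial failures of sub-tasks are recorded in the bundle rather than
    aborting it.  With ``outdir`` set, writes config echo, metrics and log.
    """
    if isinstance(config, dict):
        try:
            config = ExperimentConfig(**config)
        except ValidationError as exc:
            raise ValueError(f"invalid experiment config: {exc}") from exc
    if config.experiment not in EXPERIMENTS:
        raise KeyError(f"unknown experiment {config.experiment!r}; "
                       f"valid: {sorted(EXPERIMENTS)}")
    outdir = None
    if config.outdir:
        outdir = Path(config.outdir)
        (outdir / "traces").mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    log_lines = [f"experiment={config.experiment} hash={config.config_hash()} "
                 f"version={kcna5.__version__}"]
    try:
        metrics = EXPERIMENTS[config.experiment](config.params, config.seed,
                                                 str(outdir) if outdir else None)
        status = "ok"
    except (KeyError, ValueError, ValidationError):
        raise  # config errors propagate
    except Exception as exc:  # noqa: BLE001 - recorded, not raised
        metrics = {"error": f"{type(exc).__name__}: {exc}"}
        log_lines.append(traceback.format_exc())
        status = "failed"
    bundle = {
        "schema_version": config.schema_version,
        "experiment": config.experiment,
        "config_hash": config.config_hash(),
        "package_version": kcna5.__version__,
        "seed": config.seed,
        "status": status,
        "elapsed_s": round(time.time() - t0, 3),
        "metrics": metrics,
    }
    if outdir:
        (outdir / "config.json").write_text(
            json.dumps(config.model_dump(), indent=2))
        out = dict(bundle)
        out.pop("elapsed_s")  # keep metrics.json bit-reproducible
        (outdir / "metrics.json").write_text(json.dumps(out, indent=2))
        log_lines.append(f"status={status} elapsed={bundle['elapsed_s']}s")
        (outdir / "log.txt").write_text("\n".join(log_lines) + "\n")
    return bundle


def report_summary(bundles: list[dict]) -> pd.DataFrame:
    """Comparison table over result bundles (one row per bundle).

    Missing metrics appear as NA, never silently zero.  Mixed schema
    versions are rejected.
    """
    columns = ["experiment", "condition", "apd30", "apd90", "plateau_v",
               "ead_count", "vw_width_ms", "vw_high_ms",
               "dominant_frequency_hz", "sustained", "cv_m_per_s"]
    if not bundles:
        return pd.DataFrame(columns=columns)
    versions = {b.get("schema_version") for b in bundles}
    if len(versions) > 1:
        raise ValueError(f"mixed schema versions: {sorted(versions)}")
    rows = []
    for b in bundles:
        m = b.get("metrics", {})
        rows.append({
            "experiment": b.get("experiment"),
            "condition": b.get("condition", b.get("config_hash")),
            "apd30": m.get("apd30"),
            "apd90": m.get("apd90"),
            "plateau_v": m.get("plateau_v"),
            "ead_count": m.get("ead_count"),
            "vw_width_ms": m.get("width_ms"),
            "vw_high_ms": m.get("s2_high_ms"),
            "dominant_frequency_hz": m.get("dominant_frequency_hz"),
            "sustained": m.get("sustained"),
            "cv_m_per_s": m.get("achieved_cv_m_per_s"),
        })
    return pd.DataFrame(rows, columns=columns)
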
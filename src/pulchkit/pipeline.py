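"""End-to-end pipeline stages over the TSV interfaces.

Each ``run_*`` function is a deterministic, config-driven stage:

* ``run_synth``     - write synthetic growth/production/flow/trace tables
                      plus a ground-truth manifest;
* ``run_growth``    - T0 detection, Gompertz fits, kinetic summaries and
                      Bonferroni-corrected pairwise comparisons;
* ``run_flow``      - control-anchored gating and per-strain summaries;
* ``run_footprint`` - full differential footprinting on trace pairs.

All randomness derives from ``master_seed`` via fixed per-call offsets, so
rerunning a stage with the same config yields byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .flow import gate_threshold, percent_positive, summarize_trials
from .footprint import analyze_trace_pair
from .io import load_flow_samples, load_growth_curves, load_production_curves, \
    load_trace, write_table
from .kinetics import (
    NoTransitionError,
    ReplicateKinetics,
    compare_parameters,
    detect_transition_time,
    fit_gompertz,
    production_start_time,
    summarize_strain,
)
from .synthio import (
    FLOW_PRESETS,
    FOOTPRINT_PRESETS,
    GENOTYPE_PRESETS,
    LIZ500_SIZES,
    PROBE_YVMC,
    derive_seed,
    generate_flow_sample,
    generate_growth_curve,
    generate_production_curve,
    generate_trace_pair,
)

__all__ = ["RunConfig", "ConfigError", "run_synth", "run_growth", "run_flow",
           "run_footprint", "run_all"]

log = logging.getLogger("pulchkit")


class ConfigError(ValueError):
    """The run configuration is inconsistent with the inputs."""


_DEFAULTS = {
    "master_seed": 1,
    "outdir": "results/pipeline",
    "synth": {
        "time_start": 0.0,
        "time_end": 30.0,
        "time_step": 0.5,
        "replicates": 3,
        "growth_noise_sd": 0.01,
        "production_noise_sd": 0.005,
        "flow_events": 20000,
        "flow_trials": 3,
        "trace_noise_sd": 0.0,
        "trace_jitter_sd": 0.05,
        "strains": None,   # None = all genotype presets
        "proteins": None,  # None = all footprint presets
    },
    "growth": {
        "reference": "WT",
        "alpha": 0.05,
        "window_points": 5,
        "r2_min": 0.99,
        "deviation_frac": 0.05,
        "run_length": 3,
        "delta_floor": 0.005,
        "grid_step": 0.1,
    },
    "flow": {},
    "footprint": {
        "tau": 0.02,
        "min_run": 3,
        "min_height": 5.0,
        "min_prominence": 2.0,
        "match_tol_bp": 0.5,
        "proteins": None,
    },
}


def _merge(defaults: dict, overrides: dict) -> dict:
    out = dict(defaults)
    for k, v in (overrides or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


@dataclass
class RunConfig:
    """Resolved pipeline configuration (defaults merged with user values)."""

    master_seed: int = 1
    outdir: str = "results/pipeline"
    synth: dict = field(default_factory=dict)
    growth: dict = field(default_factory=dict)
    flow: dict = field(default_factory=dict)
    footprint: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, data: dict | None) -> "RunConfig":
        merged = _merge(_DEFAULTS, data or {})
        return cls(
            master_seed=int(merged["master_seed"]),
            outdir=str(merged["outdir"]),
            synth=merged["synth"],
            growth=merged["growth"],
            flow=merged["flow"],
            footprint=merged["footprint"],
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return {
            "master_seed": self.master_seed,
            "outdir": self.outdir,
            "synth": self.synth,
            "growth": self.growth,
            "flow": self.flow,
            "footprint": self.footprint,
        }

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]

    def provenance(self) -> list[str]:
        return [
            f"pulchkit {__version__}",
            f"config_hash={self.hash()}",
            f"master_seed={self.master_seed}",
        ]


def _outdir(config: RunConfig) -> Path:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out


# ---------------------------------------------------------------------------
# synth
# ---------------------------------------------------------------------------

def run_synth(config: RunConfig) -> dict:
    """Generate all synthetic datasets plus a ground-truth manifest.

    Returns a dict of written file paths.  Idempotent for a fixed config.
    """
    out = _outdir(config)
    s = config.synth
    seed0 = config.master_seed
    times = np.arange(s["time_start"], s["time_end"] + s["time_step"] / 2,
                      s["time_step"])
    strains = s["strains"] or list(GENOTYPE_PRESETS)
    proteins = s["proteins"] or list(FOOTPRINT_PRESETS)
    reps = int(s["replicates"])

    growth_rows, prod_rows = [], []
    for si, name in enumerate(strains):
        preset = GENOTYPE_PRESETS[name]
        for r in range(reps):
            g = generate_growth_curve(
                preset, times, noise_sd=s["growth_noise_sd"],
                seed=derive_seed(seed0, 1000 + 10 * si + r), replicate=str(r + 1),
            )
            p = generate_production_curve(
                preset, times, noise_sd=s["production_noise_sd"],
                seed=derive_seed(seed0, 2000 + 10 * si + r), replicate=str(r + 1),
            )
            growth_rows.append(pd.DataFrame({
                "strain": name, "replicate": str(r + 1),
                "time_h": g.times, "od600": g.od600,
            }))
            prod_rows.append(pd.DataFrame({
                "strain": name, "replicate": str(r + 1),
                "time_h": p.times, "a410": p.a410,
            }))

    flow_rows = []
    control = generate_flow_sample(
        FLOW_PRESETS["no_gfp"], int(s["flow_events"]),
        seed=derive_seed(seed0, 3000), sample_id="no_gfp_1",
        strain="no_gfp", is_control=True,
    )
    flow_rows.append(pd.DataFrame({
        "sample_id": control.sample_id, "strain": control.strain,
        "is_control": True, "fluorescence": control.events,
    }))
    flow_strains = [k for k in FLOW_PRESETS if k != "no_gfp"]
    for si, name in enumerate(flow_strains):
        for trial in range(int(s["flow_trials"])):
            fs = generate_flow_sample(
                FLOW_PRESETS[name], int(s["flow_events"]),
                seed=derive_seed(seed0, 3100 + 10 * si + trial),
                sample_id=f"{name}_{trial + 1}", strain=name,
            )
            flow_rows.append(pd.DataFrame({
                "sample_id": fs.sample_id, "strain": fs.strain,
                "is_control": False, "fluorescence": fs.events,
            }))

    prov = config.provenance()
    paths = {}
    write_table(pd.concat(growth_rows, ignore_index=True),
                out / "growth.tsv", prov)
    write_table(pd.concat(prod_rows, ignore_index=True),
                out / "production.tsv", prov)
    write_table(pd.concat(flow_rows, ignore_index=True),
                out / "flow.tsv", prov)
    paths.update(growth=out / "growth.tsv", production=out / "production.tsv",
                 flow=out / "flow.tsv")

    for pi, protein in enumerate(proteins):
        spec = FOOTPRINT_PRESETS[protein]
        with_t, without_t = generate_trace_pair(
            spec, probe=PROBE_YVMC,
            noise_sd=s["trace_noise_sd"], jitter_sd=s["trace_jitter_sd"],
            seed=derive_seed(seed0, 4000 + pi),
        )
        for trace, tag in ((with_t, "with"), (without_t, "without")):
            path = out / f"trace_{protein}_{tag}.tsv"
            write_table(pd.DataFrame({
                "scan": trace.scan,
                "sample_signal": trace.sample_signal,
                "ladder_signal": trace.ladder_signal,
            }), path, prov + [f"label={trace.label}"])
            paths[f"trace_{protein}_{tag}"] = path

    manifest = {
        "master_seed": seed0,
        "strains": {
            name: {
                "y0": GENOTYPE_PRESETS[name].prod_params.y0,
                "K": GENOTYPE_PRESETS[name].prod_params.K,
                "mumax": GENOTYPE_PRESETS[name].prod_params.mumax,
                "lam": GENOTYPE_PRESETS[name].prod_params.lam,
            }
            for name in strains
        },
        "flow": {
            name: {"positive_fraction": FLOW_PRESETS[name].positive_fraction}
            for name in FLOW_PRESETS
        },
        "footprints": {
            protein: {
                "window_start_tss": FOOTPRINT_PRESETS[protein].window_start_tss,
                "window_end_tss": FOOTPRINT_PRESETS[protein].window_end_tss,
                "attenuation": FOOTPRINT_PRESETS[protein].attenuation,
            }
            for protein in proteins
        },
        "probe": {
            "label_end_atg": PROBE_YVMC.label_end_atg,
            "probe_len": PROBE_YVMC.probe_len,
            "tss_offset_atg": PROBE_YVMC.tss_offset_atg,
        },
        "ladder_sizes": list(LIZ500_SIZES),
    }
    manifest_path = out / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=True),
                             encoding="utf-8")
    paths["manifest"] = manifest_path
    log.info("synth: wrote %d files to %s", len(paths), out)
    return paths


# ---------------------------------------------------------------------------
# growth
# ---------------------------------------------------------------------------

def run_growth(config: RunConfig) -> dict:
    """T0 detection, per-replicate Gompertz fits, per-strain summaries and
    pairwise Bonferroni-corrected comparisons."""
    out = _outdir(config)
    g = config.growth
    growth_curves = load_growth_curves(out / "growth.tsv")
    prod_curves = load_production_curves(out / "production.tsv")

    t0s = {}
    for curve in growth_curves:
        est = detect_transition_time(
            curve, window_points=int(g["window_points"]), r2_min=g["r2_min"],
            deviation_frac=g["deviation_frac"], run_length=int(g["run_length"]),
        )
        t0s[(curve.strain, curve.replicate)] = est

    fits = {}
    for curve in prod_curves:
        fit = fit_gompertz(curve)
        if not fit.converged:
            log.warning("growth: fit did not converge for %s/%s",
                        curve.strain, curve.replicate)
        fits[(curve.strain, curve.replicate)] = fit

    reference = g["reference"]
    by_strain: dict[str, list[ReplicateKinetics]] = {}
    for (strain, rep), fit in sorted(fits.items()):
        t0 = t0s[(strain, rep)].t0
        start = None
        ref_key = (reference, rep)
        if strain != reference and ref_key in fits:
            ref_fit = fits[ref_key]
            delta = max(3.0 * ref_fit.residual_sd, g["delta_floor"])
            start = production_start_time(
                fit.params, ref_fit.params, t0=t0, delta=delta,
                grid_step=g["grid_step"],
                grid_start=float(min(c.times[0] for c in prod_curves)) - t0,
                grid_end=float(max(c.times[-1] for c in prod_curves)) - t0,
            )
        by_strain.setdefault(strain, []).append(
            ReplicateKinetics(strain=strain, replicate=rep, fit=fit,
                              start_time=start, t0=t0)
        )

    summaries = {s: summarize_strain(reps) for s, reps in sorted(by_strain.items())}
    rows = []
    for strain, summ in summaries.items():
        for param in ("start_time", "duration", "max_rate", "max_a410"):
            rows.append({
                "strain": strain, "parameter": param,
                "mean": summ.means[param], "sd": summ.sds[param],
                "n": summ.replicate_n,
            })
    prov = config.provenance()
    write_table(pd.DataFrame(rows), out / "kinetics_summary.tsv", prov)

    comp_frames = []
    if len(summaries) >= 2:
        for param in ("start_time", "duration", "max_rate", "max_a410"):
            usable = [s for s in summaries.values()
                      if not math.isnan(s.means[param])]
            if len(usable) >= 2:
                comp_frames.append(
                    compare_parameters(usable, param, alpha=g["alpha"])
                )
    comparisons = (pd.concat(comp_frames, ignore_index=True)
                   if comp_frames else pd.DataFrame(
                       columns=["strain_a", "strain_b", "parameter",
                                "raw_p", "adj_p", "significant"]))
    write_table(comparisons, out / "kinetics_comparisons.tsv", prov)
    return {"summary": out / "kinetics_summary.tsv",
            "comparisons": out / "kinetics_comparisons.tsv",
            "summaries": summaries}


# ---------------------------------------------------------------------------
# flow
# ---------------------------------------------------------------------------

def run_flow(config: RunConfig) -> dict:
    """Gate every sample against the batch's single negative control."""
    out = _outdir(config)
    samples = load_flow_samples(out / "flow.tsv")
    controls = [s for s in samples if s.is_control]
    if len(controls) != 1:
        raise ConfigError(
            f"expected exactly one negative control, found {len(controls)}"
        )
    threshold = gate_threshold(controls[0])
    results = [percent_positive(s, threshold) for s in samples]
    prov = config.provenance()
    write_table(pd.DataFrame([{
        "sample_id": r.sample_id, "strain": r.strain,
        "threshold": r.threshold, "percent_positive": r.percent_positive,
        "median_fluorescence": r.median_fluorescence, "n_events": r.n_events,
    } for r in results]), out / "flow_gates.tsv", prov)
    summaries = summarize_trials([r for r in results
                                  if r.sample_id != controls[0].sample_id])
    write_table(pd.DataFrame([{
        "strain": s.strain, "n_trials": s.n_trials,
        "mean_percent_positive": s.mean_percent_positive,
        "sd_percent_positive": s.sd_percent_positive,
        "mean_median_fluorescence": s.mean_median_fluorescence,
        "sd_median_fluorescence": s.sd_median_fluorescence,
    } for s in summaries]), out / "flow_summary.tsv", prov)
    return {"gates": out / "flow_gates.tsv",
            "summary": out / "flow_summary.tsv",
            "results": results, "summaries": summaries}


# ---------------------------------------------------------------------------
# footprint
# ---------------------------------------------------------------------------

def run_footprint(config: RunConfig) -> dict:
    """Differential footprinting on every configured trace pair."""
    out = _outdir(config)
    f = config.footprint
    proteins = (f["proteins"] or config.synth.get("proteins")
                or list(FOOTPRINT_PRESETS))
    prov = config.provenance()
    outputs = {}
    for protein in proteins:
        with_t = load_trace(out / f"trace_{protein}_with.tsv", "with_protein")
        without_t = load_trace(out / f"trace_{protein}_without.tsv",
                               "without_protein")
        profile, regions, diag = analyze_trace_pair(
            with_t, without_t, probe=PROBE_YVMC, ladder_sizes=LIZ500_SIZES,
            min_height=f["min_height"], min_prominence=f["min_prominence"],
            match_tol_bp=f["match_tol_bp"], tau=f["tau"],
            min_run=int(f["min_run"]),
        )
        log.info("footprint %s: %s", protein, diag)
        write_table(pd.DataFrame({
            "position_tss": profile.positions,
            "differential": profile.values,
        }), out / f"footprint_profile_{protein}.tsv",
            prov + [f"matched_n={profile.matched_n}"])
        write_table(pd.DataFrame([{
            "start_tss": r.start_tss, "end_tss": r.end_tss, "kind": r.kind,
            "mean_differential": r.mean_differential,
            "peak_count": r.peak_count,
        } for r in regions]), out / f"footprint_regions_{protein}.tsv", prov)
        outputs[protein] = {"profile": profile, "regions": regions,
                            "diagnostics": diag}
    return outputs


def run_all(config: RunConfig) -> dict:
    """synth -> growth -> flow -> footprint."""
    paths = run_synth(config)
    growth = run_growth(config)
    flow = run_flow(config)
    footprint = run_footprint(config)
    return {"synth": paths, "growth": growth, "flow": flow,
            "footprint": footprint}
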
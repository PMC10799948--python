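"""End-to-end orchestration: synthetic session -> analyses -> JSON report.

A single master seed is split into independent per-stage streams with
``numpy.random.SeedSequence`` so each stage is reproducible in isolation;
re-running a config gives byte-identical summaries. Outputs are plain JSON
and CSV in the run directory.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import connectivity as conn
from . import encoding, sigproc, spectral, statespace, stats, synthgen
from .errors import InvalidConfigError

__all__ = ["default_config", "validate_config", "run"]

log = logging.getLogger("ieegdyn")

_STAGES = ("behavior", "hfa", "encoding", "spectral", "nesting", "connectivity", "statespace")

_DEFAULTS: dict = {
    "seed": 0,
    "out_dir": "ieegdyn_run",
    "stages": list(_STAGES),
    "sim": {},  # synthgen.SimConfig overrides
    "epoch": {"window": [-3.0, 1.0]},
    "hfa": {"baseline": [-0.2, -0.01], "n_boot": 1000},
    "anova": {"win": 0.050, "step": 0.002, "tmin": -0.6, "tmax": 0.5,
              "alpha": 0.05, "frac": 0.10},
    "selection": {"n_perm": 200, "weight_pct": 75},
    "peaks": {"min_prominence_z": 0.5, "min_separation_s": 0.05},
    # slope window precedes the press: movement-evoked HFA otherwise bleeds
    # into the 30-45 Hz fit band through the resampling step of IRASA
    "spectral": {"band": [30, 45], "window": [-2.5, -1.0]},
    "nesting": {"half_width": 0.5},
    "connectivity": {"n_perm": 200, "half_band": 3.0},
    "decode": {"k": 10, "repeats": 5, "n_perm": 50, "window": [-0.5, 0.3]},
}


def default_config() -> dict:
    return json.loads(json.dumps(_DEFAULTS))


def validate_config(config: dict | str | Path | None = None) -> dict:
    """Fill defaults, reject unknown keys, sanity-check ranges."""
    if config is None:
        config = {}
    elif isinstance(config, (str, Path)):
        text = Path(config).read_text()
        config = yaml.safe_load(text) or {}
    errors = []
    out = default_config()
    for key, value in config.items():
        if key not in out:
            errors.append(f"unknown key: {key}")
            continue
        if isinstance(out[key], dict):
            for sub, v in value.items():
                if key != "sim" and sub not in out[key]:
                    errors.append(f"unknown key: {key}.{sub}")
                else:
                    out[key][sub] = v
        else:
            out[key] = value
    sim = out["sim"]
    if "hll_delay_range" in sim and not sim["hll_delay_range"][0] < sim["hll_delay_range"][1]:
        errors.append("sim.hll_delay_range: lower bound must precede upper bound")
    for stage in out["stages"]:
        if stage not in _STAGES:
            errors.append(f"unknown stage: {stage}")
    if errors:
        raise InvalidConfigError("; ".join(errors))
    return out


def _stage_seeds(master: int, names) -> dict:
    children = np.random.SeedSequence(master).spawn(len(names))
    return {n: int(c.generate_state(1)[0] % 2**31) for n, c in zip(names, children)}


def run(config: dict | str | Path | None = None, out_dir: str | Path | None = None) -> Path:
    """Execute the configured stages on one synthetic session.

    Writes per-stage CSV/JSON artifacts plus ``summary.json`` (with the
    package version, seeds and parameters) and returns the run directory.
    """
    cfg = validate_config(config)
    out = Path(out_dir if out_dir is not None else cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(cfg["seed"], ("sim",) + _STAGES)
    summary: dict = {"config": cfg, "seeds": seeds, "stages": {}}

    sim_cfg = synthgen.SimConfig(**{**cfg["sim"], "seed": seeds["sim"]})
    raw, truth = synthgen.simulate_session(sim_cfg)
    raw.trials.to_csv(out / "trials.csv", index=False)

    try:
        stage = "behavior"
        if stage in cfg["stages"]:
            tab = stats.behavior_summary(raw.trials)
            tab.to_csv(out / "behavior.csv", index=False)
            summary["stages"][stage] = tab.to_dict("records")

        pre = sigproc.preprocess(raw)
        ep = sigproc.epoch(pre, "hll", tuple(cfg["epoch"]["window"]))
        hfa = None
        if {"hfa", "encoding", "nesting", "statespace"} & set(cfg["stages"]):
            stage = "hfa"
            hfa = sigproc.extract_hfa(
                ep, tuple(cfg["hfa"]["baseline"]), cfg["hfa"]["n_boot"], seeds["hfa"]
            )
            slopes = sigproc.ramping_slope(hfa)
            ctx = hfa.trial_meta["context"].to_numpy()
            slope_by_ctx = {
                str(c): float(slopes[ctx == c].mean()) for c in np.unique(ctx)
            }
            summary["stages"]["hfa"] = {"mean_ramp_slope_by_context": slope_by_ctx}

        stage = "encoding"
        if stage in cfg["stages"]:
            a = cfg["anova"]
            info = encoding.sliding_anova(hfa, win=a["win"], step=a["step"],
                                          tmin=a["tmin"], tmax=a["tmax"])
            stage1 = encoding.consecutive_criterion(info, a["alpha"], a["frac"])
            mask = np.zeros(hfa.n_channels, bool)
            if stage1.sum() >= 2:
                sel = encoding.pca_context_selection(
                    info.F[stage1], n_perm=cfg["selection"]["n_perm"],
                    weight_pct=cfg["selection"]["weight_pct"], seed=seeds["encoding"],
                )
                mask[np.flatnonzero(stage1)] = sel.encoding_mask
            pd_mask = {"channel": hfa.ch_names, "stage1": stage1.tolist(),
                       "stage2": mask.tolist()}
            (out / "encoding_mask.json").write_text(json.dumps(pd_mask, indent=1))
            summary["stages"][stage] = {
                "n_stage1": int(stage1.sum()), "n_encoding": int(mask.sum()),
                "peak_omega2": float(np.nanmax(info.omega2)),
            }

        stage = "spectral"
        if stage in cfg["stages"]:
            w = cfg["spectral"]["window"]
            seg = ep.crop(w[0], w[1])
            ctx = seg.trial_meta["context"].to_numpy()
            slopes_by_ctx = {}
            for c in np.unique(ctx):
                vals = []
                for i in np.flatnonzero(ctx == c):
                    for ch in range(seg.n_channels):
                        spec = spectral.irasa(seg.data[i, ch], seg.fs)
                        vals.append(spectral.spectral_slope(spec, tuple(cfg["spectral"]["band"])))
                slopes_by_ctx[str(c)] = float(np.mean(vals))
            summary["stages"][stage] = {"aperiodic_slope_by_context": slopes_by_ctx}

        stage = "nesting"
        if stage in cfg["stages"]:
            pk = cfg["peaks"]
            peaks = sigproc.detect_hfa_peaks(hfa, pk["min_prominence_z"],
                                             pk["min_separation_s"])
            _, _, fit = sigproc.peak_triggered_average(ep, peaks,
                                                       cfg["nesting"]["half_width"])
            _, ipi_mean = sigproc.inter_peak_interval(peaks)
            summary["stages"][stage] = {
                "pta_frequency": float(fit["frequency"]),
                "pta_converged": bool(fit["converged"]),
                "ipi_mean_frequency": float(ipi_mean),
            }

        stage = "connectivity"
        if stage in cfg["stages"]:
            rois = np.asarray(ep.roi_labels)
            i_pfc = int(np.flatnonzero(rois == "pfc")[0])
            i_mot = int(np.flatnonzero(rois == "motor")[0])
            seg = ep.crop(-1.0, 0.5)
            npm = cfg["connectivity"]["n_perm"]
            freqs, z, _ = conn.iplv_spectrum(
                seg.data[:, i_pfc], seg.data[:, i_mot], seg.fs,
                n_perm=npm, n_boot=npm, seed=seeds["connectivity"],
            )
            peak = conn.find_iplv_peak(freqs, z)
            entry = {"iplv_peak_freq": peak}
            if peak is not None:
                est = conn.psi(seg.data[:, i_pfc], seg.data[:, i_mot], seg.fs, peak,
                               cfg["connectivity"]["half_band"], n_perm=npm,
                               seed=seeds["connectivity"], pair=(i_pfc, i_mot))
                entry.update({"psi_raw": est.psi_raw, "psi_z": est.z_psi})
            summary["stages"][stage] = entry

        stage = "statespace"
        if stage in cfg["stages"]:
            w = cfg["decode"]["window"]
            space = statespace.build_state_space(hfa.crop(w[0], w[1]))
            ctx = hfa.trial_meta["context"].to_numpy()
            rt = hfa.trial_meta["rt"].to_numpy()
            dc = cfg["decode"]
            dim_ctx = statespace.find_coding_dimension(
                space, ctx, "context", dc["k"], dc["repeats"], dc["n_perm"],
                seed=seeds["statespace"],
            )
            dim_act = statespace.find_coding_dimension(
                space, statespace.rt_terciles(rt), "action", dc["k"], dc["repeats"],
                dc["n_perm"], seed=seeds["statespace"] + 1,
            )
            summary["stages"][stage] = {
                "context_pc": dim_ctx.pc_index, "context_valid": dim_ctx.valid,
                "action_pc": dim_act.pc_index, "action_valid": dim_act.valid,
                "distinct": dim_ctx.pc_index != dim_act.pc_index,
                "kept_components": space.kept,
            }
    except Exception as exc:  # preserve partial outputs, name the stage
        (out / "summary.json").write_text(json.dumps(summary, indent=1, default=float))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    from importlib.metadata import version

    try:
        summary["version"] = version("ieegdyn")
    except Exception:
        summary["version"] = "unknown"
    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=float))
    return out
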
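"""End-to-end orchestration: simulate (optionally), fit, and analyze.

A run configuration (YAML or dict) names, per data stream, either input
table paths or a simulation block — never both.  The pipeline executes
whichever stages have data and emits a machine-readable JSON report with
every headline statistic (regression R^2 and bootstrap p, sister
variance fold reduction, per-condition bridge tau_c and comparison p,
abscission-duration summaries, FRAP minima), plus the seeds and schema
version needed to reproduce it.
"""

from __future__ import annotations

import json
from dataclasses import asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bridges import (abscission_durations, bridge_fraction,
                      compare_conditions, fit_bridge_table)
from .coupling import bootstrap_null, pairs_from_tables
from .frap import frap_summary, minima_width_correlation
from .sisters import (sister_pairs_from_lineage, trajectory_matrix,
                      variance_report)
from .synthetic import (BridgeSimConfig, FrapSimConfig, SimConfig,
                        simulate_bridge_widths, simulate_frame_counts,
                        simulate_frap, simulate_lineage)
from .tables import SCHEMA_VERSION, read_table, write_table

__all__ = ["run_pipeline"]


def _load_stream(block: dict | None, kind: str, simulate):
    """Resolve one data stream: exactly one of {path, simulation block}."""
    if block is None:
        return None
    has_path = "path" in block
    has_sim = "simulate" in block
    if has_path == has_sim:
        raise ValueError(f"stream {kind!r}: give exactly one of "
                         "'path' or 'simulate'")
    if has_path:
        return read_table(block["path"], kind)
    return simulate(block["simulate"])


def run_pipeline(config: dict, out_dir: str | Path | None = None) -> dict:
    """Run every stage for which the config provides data; return the
    report dict (also written to ``report.json`` under ``out_dir``)."""
    seed = int(config.get("seed", 0))
    report: dict = dict(schema_version=SCHEMA_VERSION,
                        abclock_version=__version__, seed=seed)
    out = Path(out_dir) if out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    lineage = trajectories = None
    if "trajectories" in config:
        block = config["trajectories"]
        if "simulate" in block:
            sim = SimConfig(**{**block["simulate"], "seed": seed})
            lineage, trajectories = simulate_lineage(sim)
            report["sim_config"] = asdict(sim)
        else:
            trajectories = read_table(block["path"], "trajectories")
            lineage = read_table(config["lineage"]["path"], "lineage")
    elif "lineage" in config:
        lineage = read_table(config["lineage"]["path"], "lineage")

    if trajectories is not None:
        from .trajectory import fit_table
        max_ratio = float(config.get("fit", {}).get("max_ratio", 1.0))
        fits = fit_table(trajectories, max_ratio=max_ratio)
        if out:
            write_table(lineage, out / "lineage.tsv")
            write_table(trajectories, out / "trajectories.tsv")
            write_table(fits, out / "fits.tsv")
        report["fits"] = dict(n_cells=int(len(fits)),
                              n_kept=int(fits["kept"].sum()))

        cpl_cfg = config.get("coupling", {})
        pairs = pairs_from_tables(fits, lineage)
        if len(pairs) >= 3:
            res = bootstrap_null(
                pairs, n_boot=int(cpl_cfg.get("n_boot", 1000)), seed=seed,
                grace=float(cpl_cfg.get("grace", 2.5)))
            report["coupling"] = dict(
                r_squared=res.r_squared, slope=res.slope,
                intercept=res.intercept, n_cells=res.n_cells,
                p_empirical=res.p_empirical, n_boot=res.n_boot,
                excluded_cells=len(pairs) - res.n_cells, seed=seed)
            if out:
                write_table(pd.DataFrame(
                    dict(boot_r_squared=res.boot_r_squared)),
                    out / "bootstrap.tsv")

        pairs_ids = sister_pairs_from_lineage(lineage)
        if pairs_ids:
            m, ids, _ = trajectory_matrix(trajectories)
            index = {cid: i for i, cid in enumerate(ids)}
            vr = variance_report(
                m, [(index[a], index[b]) for a, b in pairs_ids])
            report["sisters"] = dict(
                global_variance=vr.global_variance,
                mean_pair_variance=float(np.mean(vr.pair_variances)),
                fold_reduction=vr.fold_reduction,
                n_pairs=len(pairs_ids))

    if "bridges" in config:
        def _sim_bridges(spec):
            frames = []
            for i, preset in enumerate(spec.get("presets", ["naive"])):
                cfg = getattr(BridgeSimConfig, preset)(seed=seed + i)
                frames.append(simulate_bridge_widths(cfg))
            return pd.concat(frames, ignore_index=True)

        bridges = _load_stream(config["bridges"], "bridges", _sim_bridges)
        bfits = fit_bridge_table(bridges)
        if out:
            write_table(bridges, out / "bridges.tsv")
            write_table(bfits, out / "bridge_fits.tsv")
        section = dict(tau_c_by_condition={
            cond: float(grp["tau_c_min"].mean())
            for cond, grp in bfits.groupby("condition")})
        conds = sorted(bfits["condition"].unique())
        if len(conds) == 2:
            cmp_res = compare_conditions(
                bridges[bridges["condition"] == conds[0]],
                bridges[bridges["condition"] == conds[1]],
                method=config["bridges"].get("method", "F"), seed=seed)
            section["comparison"] = {k: v for k, v in cmp_res.items()}
        report["bridges"] = section

    if "counts" in config:
        def _sim_counts(spec):
            return simulate_frame_counts(
                spec.get("n_frames", 50), spec.get("cells_per_frame", 100),
                spec.get("bridge_fraction", 0.3), seed=seed)

        counts = _load_stream(config["counts"], "counts", _sim_counts)
        bf = bridge_fraction(counts)
        if out:
            write_table(counts, out / "counts.tsv")
        report["bridge_fraction"] = dict(mean=bf["mean"], sem=bf["sem"],
                                         n_frames=bf["n_frames"])

    if "durations" in config:
        block = config["durations"]
        if "simulate" in block:
            from .synthetic import simulate_abscission_durations
            spec = block["simulate"]
            durations = simulate_abscission_durations(
                spec["mean"], spec["sd"], spec.get("n", 100), seed=seed)
        else:
            tbl = read_table(block["path"], "durations")
            durations = (tbl["abscission_time_h"]
                         - tbl["cytokinesis_end_h"]).to_numpy()
        report["abscission"] = abscission_durations(durations)

    if "frap" in config:
        def _sim_frap(spec):
            spec = dict(spec)
            n_exp = int(spec.pop("n_experiments", 1))
            frames = [simulate_frap(FrapSimConfig(**{**spec,
                                                     "seed": seed + i}))
                      for i in range(n_exp)]
            return pd.concat(frames, ignore_index=True)

        frap = _load_stream(config["frap"], "frap", _sim_frap)
        window = int(config["frap"].get("window", 4))
        minima = frap_summary(frap, window=window)
        r, p, defined = minima_width_correlation(minima)
        if out:
            write_table(frap, out / "frap.tsv")
            write_table(minima, out / "frap_minima.tsv")
        by_role = minima.groupby("role")["min_norm"].mean().to_dict()
        report["frap"] = dict(mean_min_by_role=by_role,
                              width_correlation=dict(r=r, p=p,
                                                     defined=defined))

    if out:
        (out / "report.json").write_text(json.dumps(report, indent=2,
                                                    default=_jsonable))
    return report


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
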
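"""Report assembly: machine-readable summaries across measurement panels.

Collects the outputs of the tether-force, proteomics, imaging and flow
modules into one nested, deterministic JSON-serialisable bundle plus
per-panel tables, mirroring the figure-style panels of a typical
measurement campaign (per-group n, mean +/- SEM, tests, and QC exclusion
counts).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .stats import group_summary, two_sample_t
from .tether import RelativeForce, TetherMeasurement

__all__ = ["assemble_report", "write_report"]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, float) and (np.isnan(obj) or np.isinf(obj)):
        return None
    return obj


def _groups_block(values_by_group: Mapping[str, Iterable[float]]) -> dict:
    df = group_summary({k: list(v) for k, v in values_by_group.items()})
    return {
        row["group"]: {"n": int(row["n"]), "mean": row["mean"], "sem": row["sem"]}
        for _, row in df.iterrows()
    }


def _tether_panel(measurements: list[TetherMeasurement]) -> dict:
    ok = [m for m in measurements if m.ok]
    by_phase: dict[str, list[float]] = {}
    for m in ok:
        by_phase.setdefault(m.phase, []).append(m.force)
    exclusions: dict[str, int] = {}
    for m in measurements:
        for flag in m.qc_flags:
            exclusions[flag] = exclusions.get(flag, 0) + 1
    panel = {
        "groups": _groups_block(by_phase),
        "n_measured": len(measurements),
        "n_excluded": len(measurements) - len(ok),
        "qc_exclusions": exclusions,
    }
    phases = sorted(by_phase)
    if len(phases) == 2 and all(len(by_phase[p]) >= 2 for p in phases):
        res = two_sample_t(by_phase[phases[0]], by_phase[phases[1]], variant="welch")
        panel["welch_t"] = {
            "groups": phases,
            "statistic": res.statistic,
            "df": res.df,
            "p_two_sided": res.p_two_sided,
        }
    return panel


def _relative_panel(relative: list[RelativeForce]) -> dict:
    by_group: dict[str, list[float]] = {}
    for r in relative:
        by_group.setdefault(r.phase, []).append(r.value)
    return {"groups": _groups_block(by_group)}


def _lfq_panel(results) -> dict:
    r = results.ratios
    return {
        "n_proteins": int(len(r)),
        "status_counts": {k: int(v) for k, v in r["status"].value_counts().items()},
        "null_fit": {
            "mu": results.null_fit.mu,
            "sigma": results.null_fit.sigma,
            "bin_width": results.null_fit.bin_width,
            "n_fitted": results.null_fit.n_fitted,
        },
        "outliers": {
            "interphase_enriched": sorted(
                r.loc[r["outlier_call"] == "interphase_enriched", "protein_id"]
            ),
            "mitotic_enriched": sorted(
                r.loc[r["outlier_call"] == "mitotic_enriched", "protein_id"]
            ),
        },
        "exclusives": results.exclusives,
    }


def _imaging_panel(quants: pd.DataFrame, config: Mapping | None) -> dict:
    config = config or {}
    panel: dict = {}
    keys = [c for c in ("condition", "phase") if c in quants.columns]
    grouped = quants.groupby(keys) if keys else [(("all",), quants)]
    for col in ("f_actin_ratio", "g_actin_mean", "tf_uptake_raw", "tf_uptake_normalized"):
        if col not in quants.columns or quants[col].dropna().empty:
            continue
        values_by_group = {}
        for key, sub in quants.groupby(keys) if keys else [("all", quants)]:
            label = ":".join(map(str, key)) if isinstance(key, tuple) else str(key)
            values_by_group[label] = sub[col].dropna().to_list()
        panel[col] = {"groups": _groups_block(values_by_group)}
    if "tf_uptake_raw" in quants.columns and quants["tf_uptake_raw"].notna().any():
        n_groups = quants.groupby(keys).ngroups if keys else 1
        if n_groups > 1 and "tf_uptake_normalized" not in quants.columns:
            if "reference_group" not in config:
                raise ValueError(
                    "uptake panels spanning several groups need an explicit "
                    "normalization reference (config['reference_group'])"
                )
    return panel


def _flow_panel(summary: pd.DataFrame) -> dict:
    panel: dict = {
        "samples": {
            row["sample_id"]: {
                "n_gated": int(row["n_gated"]),
                "fl1_geometric_mean": row["fl1_geometric_mean"],
            }
            for _, row in summary.iterrows()
        }
    }
    if "condition" in summary.columns:
        values_by_group = {
            str(cond): sub["fl1_geometric_mean"].to_list()
            for cond, sub in summary.groupby("condition")
        }
        panel["groups"] = _groups_block(values_by_group)
    return panel


def assemble_report(
    tether: list[TetherMeasurement] | None = None,
    relative: list[RelativeForce] | None = None,
    lfq=None,
    imaging: pd.DataFrame | None = None,
    flow: pd.DataFrame | None = None,
    config: Mapping | None = None,
) -> dict:
    """Assemble per-panel summaries into one deterministic bundle.

    At least one input must be given.  Identical inputs give a
    byte-identical JSON serialisation (keys sorted, floats untouched).
    """
    panels: dict = {}
    if tether is not None:
        panels["tether_force"] = _tether_panel(tether)
    if relative is not None:
        panels["relative_force"] = _relative_panel(relative)
    if lfq is not None:
        panels["lfq_outliers"] = _lfq_panel(lfq)
    if imaging is not None:
        panels["imaging"] = _imaging_panel(imaging, config)
    if flow is not None:
        panels["flow_uptake"] = _flow_panel(flow)
    if not panels:
        raise ValueError("no module output given")
    return _jsonable({"panels": panels})


def write_report(report: dict, outdir: str | Path) -> Path:
    """Write ``report.json`` (sorted keys) and per-panel CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "report.json"
    path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    for name, panel in report.get("panels", {}).items():
        rows = []
        groups = panel.get("groups")
        if groups is None and isinstance(panel, dict):
            for sub in panel.values():
                if isinstance(sub, dict) and "groups" in sub:
                    groups = sub["groups"]
                    break
        if groups:
            for label, summ in groups.items():
                rows.append({"group": label, **summ})
            pd.DataFrame(rows).to_csv(outdir / f"{name}.csv", index=False)
    return path
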
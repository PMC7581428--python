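"""Config-driven orchestration of pipeline stages with a run manifest.

A run config (YAML) names an output directory, a global seed, and an ordered
stage list. Each stage consumes either explicit input paths or the outputs
of an earlier stage in the same run; every stochastic stage takes an
explicit seed (defaulting to the run seed). Rerunning an identical config
produces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import expression, instability, synthetic
from .stats_core import two_sample_ttest

__all__ = ["RunConfig", "run_pipeline", "load_config"]

KNOWN_STAGES = (
    "simulate_traces",
    "expansion_index",
    "compare_groups",
    "simulate_counts",
    "de",
)


@dataclass
class RunConfig:
    out_dir: Path
    seed: int
    stages: list[dict[str, Any]]
    thresholds: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if not self.stages:
            raise ValueError("config has no stages")
        for spec in self.stages:
            name = spec.get("stage")
            if name not in KNOWN_STAGES:
                raise ValueError(f"unknown stage {name!r}; known: {KNOWN_STAGES}")
            for key in ("peaks", "counts", "meta"):
                path = spec.get(key)
                if isinstance(path, str) and not Path(path).exists():
                    raise ValueError(f"stage {name!r}: missing input file {path}")
        alpha = self.thresholds.get("alpha")
        if alpha is not None and not 0.0 < alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
        min_count = self.thresholds.get("min_count")
        if min_count is not None and min_count < 0:
            raise ValueError("min_count must be >= 0")
        n_perm = self.thresholds.get("n_perm")
        if n_perm is not None and n_perm < 1:
            raise ValueError("n_perm must be >= 1")


def load_config(path: str | Path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    return RunConfig(
        out_dir=Path(raw.get("out_dir", "cagdyn_run")),
        seed=int(raw.get("seed", 0)),
        stages=list(raw.get("stages", [])),
        thresholds=dict(raw.get("thresholds", {})),
    )


def _pkg_version() -> str:
    try:
        return version("cagdyn")
    except PackageNotFoundError:  # pragma: no cover - editable edge case
        return "unknown"


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(
        {
            "seed": config.seed,
            "stages": config.stages,
            "thresholds": config.thresholds,
        },
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the configured stages in order; returns the run manifest."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    state: dict[str, Any] = {}
    manifest: dict[str, Any] = {
        "version": _pkg_version(),
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "stages": [],
    }

    for spec in config.stages:
        name = spec["stage"]
        entry: dict[str, Any] = {"stage": name, "outputs": []}

        if name == "simulate_traces":
            params = synthetic.TraceSimParams(
                **{
                    **{"seed": config.seed},
                    **{k: v for k, v in spec.items() if k != "stage"},
                }
            )
            traces, truth = synthetic.simulate_trace_cohort(params)
            peaks_path = out_dir / "peaks.tsv"
            rows = [
                {"sample_id": t.sample_id, "repeat_units": r, "height": h}
                for t in traces
                for r, h in sorted(t.peaks.items())
            ]
            pd.DataFrame(rows).to_csv(peaks_path, sep="\t", index=False)
            truth_path = out_dir / "trace_truth.tsv"
            pd.DataFrame(
                {
                    "sample_id": list(truth.mouse_expected_index),
                    "genotype": [
                        truth.mouse_genotype[m]
                        for m in truth.mouse_expected_index
                    ],
                    "expected_index": list(
                        truth.mouse_expected_index.values()
                    ),
                }
            ).to_csv(truth_path, sep="\t", index=False)
            state["peaks"] = peaks_path
            state["trace_truth"] = truth_path
            entry["outputs"] = [str(peaks_path), str(truth_path)]

        elif name == "expansion_index":
            peaks = spec.get("peaks", state.get("peaks"))
            if peaks is None:
                raise RuntimeError(
                    "stage 'expansion_index': no peaks input; run "
                    "'simulate_traces' first or set 'peaks'"
                )
            traces = instability.read_peak_table(peaks)
            min_rel = float(spec.get("min_relative_height", 0.0))
            results = [
                instability.expansion_index(t, min_rel) for t in traces
            ]
            idx_path = out_dir / "expansion_index.tsv"
            instability.write_expansion_results(results, idx_path)
            state["expansion"] = results
            state["expansion_path"] = idx_path
            entry["outputs"] = [str(idx_path)]

        elif name == "compare_groups":
            results = state.get("expansion")
            if results is None:
                raise RuntimeError(
                    "stage 'compare_groups': no expansion results; run "
                    "'expansion_index' first"
                )
            group_of = lambda sid: sid.rsplit("_", 1)[0]  # noqa: E731
            group_a = spec.get("group_a")
            group_b = spec.get("group_b")
            groups = sorted({group_of(r.sample_id) for r in results})
            if group_a is None or group_b is None:
                if len(groups) != 2:
                    raise RuntimeError(
                        "stage 'compare_groups': specify group_a/group_b "
                        f"(found groups {groups})"
                    )
                group_a, group_b = groups
            comp = two_sample_ttest(
                [r.index for r in results if group_of(r.sample_id) == group_a],
                [r.index for r in results if group_of(r.sample_id) == group_b],
            )
            comp_path = out_dir / "group_comparison.json"
            comp_path.write_text(
                json.dumps(
                    {
                        "group_a": group_a,
                        "group_b": group_b,
                        "mean_a": comp.mean_a,
                        "mean_b": comp.mean_b,
                        "mean_diff": comp.mean_diff,
                        "ci95": [comp.ci95_low, comp.ci95_high],
                        "t_stat": comp.t_stat,
                        "df": comp.df,
                        "p_two_sided": comp.p_two_sided,
                        "n_a": comp.n_a,
                        "n_b": comp.n_b,
                    },
                    indent=2,
                )
                + "\n"
            )
            entry["outputs"] = [str(comp_path)]

        elif name == "simulate_counts":
            kwargs = {k: v for k, v in spec.items() if k != "stage"}
            kwargs.setdefault("seed", config.seed)
            if "fractions" in kwargs:
                kwargs["fractions"] = dict(kwargs["fractions"])
            if "group_sizes" in kwargs:
                kwargs["group_sizes"] = dict(kwargs["group_sizes"])
            params = synthetic.CountSimParams(**kwargs)
            counts, meta, truth = synthetic.simulate_count_matrix(params)
            counts_path = out_dir / "counts.tsv"
            meta_path = out_dir / "meta.tsv"
            truth_path = out_dir / "gene_truth.tsv"
            counts.to_tsv(counts_path)
            meta.table.to_csv(meta_path, sep="\t", index=False)
            truth.gene_table().to_csv(truth_path, sep="\t", index=False)
            state["counts"], state["meta"] = counts, meta
            entry["outputs"] = [str(counts_path), str(meta_path), str(truth_path)]

        elif name == "de":
            counts = state.get("counts")
            meta = state.get("meta")
            if "counts" in spec:
                counts = expression.read_counts_tsv(spec["counts"])
            if "meta" in spec:
                meta = expression.read_meta_tsv(spec["meta"])
            if counts is None or meta is None:
                raise RuntimeError(
                    "stage 'de': no counts/meta; run 'simulate_counts' "
                    "first or set 'counts' and 'meta'"
                )
            min_count = int(
                spec.get("min_count", config.thresholds.get("min_count", 6))
            )
            filtered = expression.filter_genes(
                counts, meta, expression.FilterConfig(min_count=min_count)
            )
            contrast = int(spec.get("contrast", 3))
            deg = expression.de_test(
                filtered,
                meta,
                contrast,
                covariates=spec.get("covariates"),
                method=spec.get("method", "nb-lrt"),
            )
            deg_path = out_dir / f"deg_contrast{contrast}.tsv"
            deg.to_csv(deg_path, sep="\t")
            state[f"deg{contrast}"] = deg
            entry["outputs"] = [str(deg_path)]

        manifest["stages"].append(entry)

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
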
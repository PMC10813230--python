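"""End-to-end pipeline runner and its configuration.

`run_pipeline` drives the full chain over a cohort directory (or a freshly
simulated cohort), writes every stage's TSV outputs and a machine-readable
JSON run report, and is deterministic for a fixed config and inputs.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import io as _io
from . import overlap as _overlap
from .errors import InvalidConfigError
from .model import HubDynamicsModel
from .synthetic import SyntheticConfig, generate_cohort


@dataclass(frozen=True)
class PipelineConfig:
    """Validated options for the full run.

    `input_dir` may be None, in which case a synthetic cohort is generated
    from `synthetic` (a :class:`SyntheticConfig`) into `output_dir/cohort`.
    """

    output_dir: str = "dynhubs_out"
    input_dir: str | None = None
    region_table: str | None = None
    graph_values: str = "local"
    smoothing_window: int = 21
    density: float = 0.15
    threshold_multiplier: float = 1.0
    consensus_fraction: float = 0.5
    cut_height: float = 0.90
    cut_scale: str = "distance"
    alpha: float = 0.05
    equal_variance: bool = True
    top_pair_fraction: float = 0.2
    seed: int = 0
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    def __post_init__(self):
        if not (0 < self.density < 1):
            raise InvalidConfigError("density must lie in (0, 1)")
        if not (0 < self.cut_height < 1):
            raise InvalidConfigError("cut_height must lie in (0, 1)")
        if self.cut_scale not in ("distance", "similarity"):
            raise InvalidConfigError("cut_scale must be 'distance' or 'similarity'")
        if not (0 < self.alpha < 1):
            raise InvalidConfigError("alpha must lie in (0, 1)")
        if not (0 <= self.consensus_fraction < 1):
            raise InvalidConfigError("consensus_fraction must lie in [0, 1)")
        if not (0 < self.top_pair_fraction <= 1):
            raise InvalidConfigError("top_pair_fraction must lie in (0, 1]")
        if self.threshold_multiplier <= 0:
            raise InvalidConfigError("threshold_multiplier must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
        syn = raw.pop("synthetic", None)
        if isinstance(syn, dict):
            syn_known = {f.name for f in dataclasses.fields(SyntheticConfig)}
            syn_unknown = set(syn) - syn_known
            if syn_unknown:
                raise InvalidConfigError(f"unknown synthetic config keys: {sorted(syn_unknown)}")
            if "planted_hubs_per_state" in syn and syn["planted_hubs_per_state"] is not None:
                syn["planted_hubs_per_state"] = tuple(tuple(s) for s in syn["planted_hubs_per_state"])
            raw["synthetic"] = SyntheticConfig(**syn)
        elif syn is not None:
            raw["synthetic"] = syn
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _model_options(config: PipelineConfig) -> dict:
    return dict(
        density=config.density,
        graph_values=config.graph_values,
        smoothing_window=config.smoothing_window,
        threshold_multiplier=config.threshold_multiplier,
        consensus_fraction=config.consensus_fraction,
        cut_height=config.cut_height,
        cut_scale=config.cut_scale,
        alpha=config.alpha,
        equal_variance=config.equal_variance,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and write stage outputs plus a run report.

    Returns the report dictionary (also written as `report.json`).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    files: list[str] = []

    t0 = time.perf_counter()
    if config.input_dir is None:
        syn = config.synthetic.replace(seed=config.seed)
        cohort_dir = out / "cohort"
        cohort = generate_cohort(syn, out_dir=cohort_dir)
        subjects = cohort.subjects
        table = cohort.region_table
        files += sorted(str(p.relative_to(out)) for p in cohort_dir.iterdir())
    else:
        subjects = _io.load_cohort_subjects(config.input_dir, config.region_table)
        table = subjects[0].region_table
    timings["load_or_simulate"] = time.perf_counter() - t0

    model = HubDynamicsModel(subjects, **_model_options(config))
    t0 = time.perf_counter()
    results = model.fit(run_stats=True)
    timings["fit"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    names = table.region_name
    empty_pattern_counts = {}
    for sid, r in results.per_subject.items():
        sdir = out / "subjects" / sid
        sdir.mkdir(parents=True, exist_ok=True)
        _io.write_matrix_tsv(sdir / "bc_timeseries.tsv", r.bc.values, row_labels=names)
        rows = np.column_stack(
            [
                np.asarray(names, dtype=object),
                r.bc_summary.bc_avg,
                np.asarray(list(table.rsn), dtype=object),
            ]
        )
        _io.write_matrix_tsv(sdir / "bc_summary.tsv", rows, col_labels=["node", "bc_avg", "rsn"])
        hub_rows = []
        for i, name in enumerate(names):
            hub_rows.append(
                [
                    name,
                    int(i in r.candidates),
                    r.activity.th2.get(i, float("nan")),
                ]
            )
        _io.write_matrix_tsv(
            sdir / "hubs.tsv", np.asarray(hub_rows, dtype=object),
            col_labels=["node", "is_candidate", "th2"],
        )
        _io.write_matrix_tsv(sdir / "activity.tsv", r.activity.activity.astype(int), row_labels=names)
        _io.write_matrix_tsv(sdir / "spatial_overlap.tsv", r.so.so)
        if r.clusters is not None:
            _io.write_matrix_tsv(
                sdir / "clusters.tsv",
                np.column_stack([r.clusters.valid_timepoints, r.clusters.labels]),
                col_labels=["timepoint", "cluster"],
            )
        if r.to is not None:
            labels = [names[i] for i in r.to.candidates]
            _io.write_matrix_tsv(sdir / "temporal_overlap.tsv", r.to.to, row_labels=labels, col_labels=labels)
            if len(r.to.candidates) >= 2:
                ranked = _overlap.top_pairs(r.to, fraction=config.top_pair_fraction)
                _io.write_matrix_tsv(
                    sdir / "top_pairs.tsv",
                    np.asarray(
                        [[names[i], names[j], v] for i, j, v in ranked], dtype=object
                    ),
                    col_labels=["node_i", "node_j", "temporal_overlap"],
                )
        empty_pattern_counts[sid] = r.empty_pattern_count
        files += sorted(str(p.relative_to(out)) for p in sdir.iterdir())

    for g, snd in results.group_snd.items():
        _io.write_matrix_tsv(
            out / f"snd_{g}.tsv",
            np.asarray(list(snd.proportions.items()), dtype=object),
            col_labels=["rsn", "proportion"],
        )
        files.append(f"snd_{g}.tsv")
        cand = results.group_candidates[g]
        _io.write_matrix_tsv(
            out / f"consensus_candidates_{g}.tsv",
            np.asarray([[i + 1, names[i]] for i in cand], dtype=object).reshape(len(cand), 2),
            col_labels=["region_index", "node"],
        )
        files.append(f"consensus_candidates_{g}.tsv")
    results.stats_frame().to_csv(out / "stats.tsv", sep="\t", index=False)
    files.append("stats.tsv")
    timings["write_outputs"] = time.perf_counter() - t0

    cfg_echo = config.to_dict()
    report = {
        "version": __version__,
        "seed": config.seed,
        "config": cfg_echo,
        "n_subjects": len(subjects),
        "empty_pattern_counts": empty_pattern_counts,
        "files": sorted(files),
    }
    # Timings go to a separate file so every analysis output (report.json
    # included) is byte-identical across reruns of the same config.
    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=str) + "\n",
        encoding="utf-8",
    )
    (out / "timings.json").write_text(
        json.dumps({k: round(v, 4) for k, v in timings.items()}, indent=2) + "\n",
        encoding="utf-8",
    )
    report["timings_s"] = {k: round(v, 4) for k, v in timings.items()}
    (out / "summary.txt").write_text(results.summary() + "\n", encoding="utf-8")
    report["_results"] = results  # in-memory only, not serialized
    return report
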
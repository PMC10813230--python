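"""Model/Results front for the full hub-dynamics analysis.

`HubDynamicsModel` holds a cohort of parcellated time series plus the
analysis options; `fit()` runs the whole chain per subject — jackknife
connectivity, proportional thresholding, betweenness centrality, TH1/TH2
hub detection, spatial/temporal overlap and clustering — then the group
comparisons, and returns a `HubDynamicsResults` carrying every stage's
output and a `summary()` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import hubs as _hubs
from . import overlap as _overlap
from . import stats as _stats
from . import tvc as _tvc
from .errors import InvalidInputError
from .regions import RegionTable
from .synthetic import GROUPS, Cohort, ParcellatedTimeSeries, SyntheticConfig, generate_cohort


@dataclass(frozen=True)
class SubjectResults:
    """All per-subject stage outputs."""

    subject_id: str
    group: str
    bc: _hubs.BCTimeSeries
    bc_summary: _hubs.BCSummary
    candidates: tuple[int, ...]
    activity: _hubs.HubActivity
    so: _overlap.SpatialOverlapMatrix
    mean_so: float | None
    clusters: _overlap.ClusterResult | None
    to: _overlap.TemporalOverlapMatrix | None
    empty_pattern_count: int


class HubDynamicsModel:
    """Hub-dynamics analysis of a two-group cohort.

    Parameters
    ----------
    subjects
        Parcellated time series, each tagged NC or SZ; all must share one
        region table.
    density
        Retained edge fraction for proportional thresholding (default 0.15).
    graph_values, smoothing_window
        Connectivity-value mode for graph construction ('local', the
        windowed jackknife pseudo-correlation, by default; or
        'normalized' / 'raw') and its moving-average window.
    consensus_fraction
        A node is a group-level candidate hub if it is a candidate in
        strictly more than this fraction of the group's subjects.
    cut_height, cut_scale
        Clustering cut for the spatial patterns (default 0.90 on the
        distance scale d = 1 - SO).
    alpha, equal_variance
        Significance level and t-test flavor for group comparisons.
    """

    def __init__(
        self,
        subjects: Sequence[ParcellatedTimeSeries],
        *,
        density: float = 0.15,
        graph_values: str = "local",
        smoothing_window: int = 21,
        threshold_multiplier: float = 1.0,
        consensus_fraction: float = 0.5,
        cut_height: float = 0.90,
        cut_scale: str = "distance",
        alpha: float = 0.05,
        equal_variance: bool = True,
    ):
        if not subjects:
            raise InvalidInputError("no subjects given")
        table = subjects[0].region_table
        for s in subjects:
            if s.region_table.n_regions != table.n_regions or s.region_table.rsn != table.rsn:
                raise InvalidInputError(
                    f"subject {s.subject_id}: region table differs from the cohort's"
                )
        self.subjects = tuple(subjects)
        self.region_table: RegionTable = table
        self.options = dict(
            density=density,
            graph_values=graph_values,
            smoothing_window=smoothing_window,
            threshold_multiplier=threshold_multiplier,
            consensus_fraction=consensus_fraction,
            cut_height=cut_height,
            cut_scale=cut_scale,
            alpha=alpha,
            equal_variance=equal_variance,
        )

    @classmethod
    def from_synthetic(cls, config: SyntheticConfig, **options) -> "HubDynamicsModel":
        """Generate a synthetic cohort and wrap it in a model."""
        cohort = generate_cohort(config)
        model = cls(cohort.subjects, **options)
        model.cohort = cohort
        return model

    @classmethod
    def from_cohort(cls, cohort: Cohort, **options) -> "HubDynamicsModel":
        model = cls(cohort.subjects, **options)
        model.cohort = cohort
        return model

    @classmethod
    def from_directory(cls, input_dir, region_table_path, **options) -> "HubDynamicsModel":
        """Load a cohort from a manifest directory (see :mod:`dynhubs.io`)."""
        from . import io as _io

        subjects = _io.load_cohort_subjects(input_dir, region_table_path)
        return cls(subjects, **options)

    # ------------------------------------------------------------------
    def fit_subject(self, ts: ParcellatedTimeSeries) -> SubjectResults:
        """Run the per-subject chain: JC -> graphs -> BC -> hubs -> overlap."""
        o = self.options
        stack = _tvc.tvc_stack(ts)
        adj = _hubs.binarize_stack(
            stack,
            density=o["density"],
            values=o["graph_values"],
            smoothing_window=o["smoothing_window"],
        )
        bc = _hubs.bc_time_series(adj)
        summary = _hubs.summarize_bc(bc, self.region_table)
        candidates = _hubs.find_candidate_hubs(summary, o["threshold_multiplier"])
        activity = _hubs.find_active_hubs(bc, candidates)
        so = _overlap.spatial_overlap(activity)
        n_valid = int(so.valid_mask.sum())
        mean_so = clusters = to = None
        if n_valid >= 2:
            mean_so = _overlap.mean_spatial_overlap(so)
            clusters = _overlap.cluster_spatial_patterns(
                so, cut_height=o["cut_height"], cut_scale=o["cut_scale"]
            )
        if candidates:
            to = _overlap.temporal_overlap(activity)
        return SubjectResults(
            subject_id=ts.subject_id,
            group=ts.group,
            bc=bc,
            bc_summary=summary,
            candidates=candidates,
            activity=activity,
            so=so,
            mean_so=mean_so,
            clusters=clusters,
            to=to,
            empty_pattern_count=activity.t_total - n_valid,
        )

    def fit(self, run_stats: bool = True) -> "HubDynamicsResults":
        """Fit every subject, aggregate per group, and (optionally) run the
        group comparisons (which need >= 2 subjects per group)."""
        per_subject = {s.subject_id: self.fit_subject(s) for s in self.subjects}
        o = self.options
        group_candidates = {}
        group_snd = {}
        for g in GROUPS:
            rs = [r for r in per_subject.values() if r.group == g]
            if not rs:
                continue
            group_candidates[g] = _hubs.consensus_candidates(
                [r.candidates for r in rs], o["consensus_fraction"]
            )
            group_snd[g] = _overlap.subnetwork_distribution(
                [r.activity for r in rs], self.region_table
            )
        stats_results = None
        if run_stats:
            stats_results = self._group_stats(per_subject)
        return HubDynamicsResults(
            model=self,
            per_subject=per_subject,
            group_candidates=group_candidates,
            group_snd=group_snd,
            stats=stats_results,
        )

    def _group_stats(self, per_subject) -> list[_stats.GroupStatsResult]:
        o = self.options
        by_group = {g: [r for r in per_subject.values() if r.group == g] for g in GROUPS}
        for g, rs in by_group.items():
            if len(rs) < 2:
                raise InvalidInputError(
                    f"group {g}: statistics need >= 2 subjects, got {len(rs)}"
                )
        results: list[_stats.GroupStatsResult] = []
        # Whole-brain BC: one unadjusted test.
        results += _stats.compare_groups(
            {"whole-brain": [r.bc_summary.bc_global for r in by_group["NC"]]},
            {"whole-brain": [r.bc_summary.bc_global for r in by_group["SZ"]]},
            metric_name="bc",
            level="global",
            alpha=o["alpha"],
            equal_variance=o["equal_variance"],
            adjust=False,
        )
        # RSN-level BC: one FDR family across RSNs.
        labels = self.region_table.rsn_labels
        results += _stats.compare_groups(
            {l: [r.bc_summary.bc_rsn[l] for r in by_group["NC"]] for l in labels},
            {l: [r.bc_summary.bc_rsn[l] for r in by_group["SZ"]] for l in labels},
            metric_name="bc",
            level="rsn",
            alpha=o["alpha"],
            equal_variance=o["equal_variance"],
            adjust=True,
        )
        # Mean spatial overlap, where defined for every subject.
        nc_so = [r.mean_so for r in by_group["NC"] if r.mean_so is not None]
        sz_so = [r.mean_so for r in by_group["SZ"] if r.mean_so is not None]
        if len(nc_so) >= 2 and len(sz_so) >= 2:
            results += _stats.compare_groups(
                {"whole-brain": nc_so},
                {"whole-brain": sz_so},
                metric_name="mean_spatial_overlap",
                level="global",
                alpha=o["alpha"],
                equal_variance=o["equal_variance"],
                adjust=False,
            )
        return results


class HubDynamicsResults:
    """Fitted results: per-subject stage outputs, group aggregates, stats."""

    def __init__(self, model, per_subject, group_candidates, group_snd, stats):
        self.model = model
        self.per_subject: Mapping[str, SubjectResults] = per_subject
        self.group_candidates: Mapping[str, tuple[int, ...]] = group_candidates
        self.group_snd = group_snd
        self.stats = stats

    def subjects_in(self, group: str) -> list[SubjectResults]:
        return [r for r in self.per_subject.values() if r.group == group]

    def stats_frame(self) -> pd.DataFrame:
        if self.stats is None:
            return pd.DataFrame()
        return pd.DataFrame(
            {
                "metric": [s.metric_name for s in self.stats],
                "level": [s.level for s in self.stats],
                "unit": [s.unit for s in self.stats],
                "group_mean_NC": [s.group_means[0] for s in self.stats],
                "group_mean_SZ": [s.group_means[1] for s in self.stats],
                "t": [s.t_statistic for s in self.stats],
                "p": [s.p_value for s in self.stats],
                "p_fdr": [s.p_fdr for s in self.stats],
                "significant": [s.significant for s in self.stats],
            }
        )

    def modal_cluster_count(self, group: str | None = None) -> int:
        """Most common per-subject cluster count (ties -> smaller count)."""
        rs = self.per_subject.values() if group is None else self.subjects_in(group)
        counts = [r.clusters.n_clusters for r in rs if r.clusters is not None]
        if not counts:
            raise InvalidInputError("no subject has a defined clustering")
        vals, freq = np.unique(counts, return_counts=True)
        return int(vals[np.argmax(freq)])

    def summary(self) -> str:
        """Human-readable account of the fit (statsmodels-style text table)."""
        table = self.model.region_table
        o = self.model.options
        lines = []
        lines.append("Hub Dynamics Results")
        lines.append("=" * 64)
        n_nc = len(self.subjects_in("NC"))
        n_sz = len(self.subjects_in("SZ"))
        first = next(iter(self.per_subject.values()))
        lines.append(
            f"Subjects: {n_nc} NC / {n_sz} SZ   Regions: {table.n_regions}   "
            f"Time points: {first.bc.t_total}"
        )
        lines.append(
            f"Options: density={o['density']}, cut_height={o['cut_height']} "
            f"({o['cut_scale']}), alpha={o['alpha']}"
        )
        for g in ("NC", "SZ"):
            if g not in self.group_candidates:
                continue
            names = [table.region_name[i] for i in self.group_candidates[g]]
            lines.append(f"\n{g} consensus candidate hubs ({len(names)}): " + ", ".join(names))
            snd = self.group_snd[g]
            snd_str = ", ".join(f"{k}={v:.3f}" for k, v in snd.proportions.items())
            lines.append(f"{g} subnetwork distribution of active hubs: {snd_str}")
            counts = [r.clusters.n_clusters for r in self.subjects_in(g) if r.clusters]
            if counts:
                lines.append(
                    f"{g} spatial-pattern clusters per subject: "
                    f"modal={self.modal_cluster_count(g)} (range {min(counts)}-{max(counts)})"
                )
        if self.stats is not None:
            lines.append("\nGroup comparisons (NC vs SZ)")
            lines.append("-" * 64)
            df = self.stats_frame()
            with pd.option_context("display.float_format", lambda v: f"{v:.4g}"):
                lines.append(df.to_string(index=False))
        return "\n".join(lines)
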
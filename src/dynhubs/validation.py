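"""Monte-Carlo recovery experiments against the generator's planted truth.

These routines quantify how reliably the analysis chain recovers what the
synthetic generator planted: hub identity (candidate-hub recovery), the
latent state count (modal spatial-pattern clusters), and the group
difference in global centrality (power and type-I error). They back both
the test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np

from . import hubs as _hubs
from . import tvc as _tvc
from .model import HubDynamicsModel
from .stats import independent_t_test
from .synthetic import SyntheticConfig, generate_cohort, generate_subject


def subject_bc_summary(ts, *, density: float = 0.15, graph_values: str = "local",
                       smoothing_window: int = 21):
    """Per-subject shortcut: JC stack -> graphs -> BC -> summary."""
    stack = _tvc.tvc_stack(ts)
    adj = _hubs.binarize_stack(stack, density=density, values=graph_values,
                               smoothing_window=smoothing_window)
    bc = _hubs.bc_time_series(adj)
    return bc, _hubs.summarize_bc(bc, ts.region_table)


def candidate_recovery_rate(
    config: SyntheticConfig,
    n_seeds: int = 20,
    *,
    density: float = 0.15,
    graph_values: str = "local",
    base_seed: int = 0,
) -> float:
    """Fraction of (seed x planted hub) events recovered as candidate hubs.

    One NC subject per seed; a planted hub counts as recovered when the
    TH1 rule marks it a candidate for that subject.
    """
    hit = 0
    total = 0
    for k in range(n_seeds):
        seed = int(np.random.SeedSequence(base_seed, spawn_key=(k,)).generate_state(1)[0] % (2**31))
        ts, truth = generate_subject(config, "NC", seed)
        _, summary = subject_bc_summary(ts, density=density, graph_values=graph_values)
        candidates = set(_hubs.find_candidate_hubs(summary))
        planted = {h - 1 for state in truth.hubs_per_state for h in state}
        hit += len(planted & candidates)
        total += len(planted)
    return hit / total


def modal_cluster_count(
    config: SyntheticConfig,
    n_subjects: int = 8,
    *,
    cut_height: float = 0.90,
    base_seed: int = 0,
) -> int:
    """Modal per-subject spatial-pattern cluster count on NC subjects."""
    cfg = config.replace(n_subjects_per_group=n_subjects, seed=base_seed)
    cohort = generate_cohort(cfg)
    model = HubDynamicsModel.from_cohort(cohort, cut_height=cut_height)
    results = model.fit(run_stats=False)
    return results.modal_cluster_count("NC")


def _cohort_global_bc(config: SyntheticConfig, *, density: float = 0.15):
    """Per-group lists of per-subject global BC for one cohort."""
    cohort = generate_cohort(config)
    values = {"NC": [], "SZ": []}
    for ts in cohort.subjects:
        _, summary = subject_bc_summary(ts, density=density)
        values[ts.group].append(summary.bc_global)
    return values


def group_difference_power(
    config: SyntheticConfig,
    n_replicates: int = 100,
    *,
    alpha: float = 0.05,
    base_seed: int = 0,
) -> float:
    """Fraction of replicate cohorts detecting the planted SZ < NC global-BC
    deficit (two-sided p < alpha AND SZ mean below NC mean)."""
    detected = 0
    for k in range(n_replicates):
        seed = int(np.random.SeedSequence(base_seed, spawn_key=(1, k)).generate_state(1)[0] % (2**31))
        values = _cohort_global_bc(config.replace(seed=seed))
        t, p = independent_t_test(values["NC"], values["SZ"])
        if p < alpha and np.mean(values["SZ"]) < np.mean(values["NC"]):
            detected += 1
    return detected / n_replicates


def type_i_error_rate(
    config: SyntheticConfig,
    n_replicates: int = 200,
    *,
    alpha: float = 0.05,
    base_seed: int = 0,
) -> float:
    """Rejection rate of the global-BC test under a null (group_effect=0)
    version of `config`."""
    null_cfg = config.replace(group_effect=0.0)
    rejected = 0
    for k in range(n_replicates):
        seed = int(np.random.SeedSequence(base_seed, spawn_key=(2, k)).generate_state(1)[0] % (2**31))
        values = _cohort_global_bc(null_cfg.replace(seed=seed))
        _, p = independent_t_test(values["NC"], values["SZ"])
        if p < alpha:
            rejected += 1
    return rejected / n_replicates
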
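"""Synthetic cohorts of parcellated BOLD-like time series with known truth.

The generator emulates the shape of a resting-state fMRI study after
parcellation: per subject, a T x N matrix of region signals (default
T = 142 time points at TR = 2 s, N = 90 regions) with a five-network
partition. Ground truth is planted at three levels so every downstream
stage is testable without real data:

* **states** — a quasi-periodic sequence of connectivity states (cyclic
  rotation with jittered dwell times) produces recurring spatial patterns;
* **hubs** — each state designates two *connector* regions that couple
  to foreign resting-state networks through their network factors,
  weakly at baseline and strongly while their state is active. Because a
  connector bridges otherwise-independent modules, it carries the
  inter-module shortest paths and becomes a betweenness hub during its
  epochs. (A naive alternative — coupling a hub uniformly to every other
  region — is *not* used: such a correlation matrix is far from positive
  semi-definite, and after any PSD repair the node ends up embedded in a
  diffuse factor that crowds out its betweenness rather than raising it.)
* **group effect** — in the patient ("SZ") group the connector loadings
  are reduced by a multiplicative factor, planting a group difference in
  centrality with a known direction (SZ below NC).

Each state's correlation matrix is built from an explicit factor model
(one latent factor per RSN; members load sqrt(background_coupling) on
their own factor, connectors load on the foreign factors), so it is
positive semi-definite by construction. Signals follow a first-order
autoregression whose innovations are drawn from the active state's
correlation matrix, plus independent measurement noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import GenerationError, InvalidConfigError, InvalidInputError
from .regions import RSN_NAMES, RegionTable

#: Default RSN share of the 90 regions; loosely mimics the relative sizes of
#: a five-network grouping of the AAL atlas (documented constant, not an
#: atlas reproduction). Sums to 1.
DEFAULT_RSN_PROPORTIONS: dict[str, float] = {
    "SMN": 0.22,
    "VN": 0.13,
    "AN": 0.21,
    "DMN": 0.27,
    "LSN": 0.17,
}

GROUPS = ("NC", "SZ")


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic cohort generator.

    The defaults are the package's reference study conditions: a 90-region,
    142-time-point cohort with 3 latent connectivity states (mean dwell 30
    time points), two planted connector hubs per state, hub coupling 0.7
    against a within-RSN background of 0.2, noise SD 0.5, AR(1) smoothing
    0.3, and a 50% hub-coupling reduction in the SZ group.

    `hub_coupling` scales the connector's on-state loadings on the
    foreign RSN factors (0.886x on its two primary targets, 0.457x on the
    rest; baseline epochs use 0.65 of the on-state values). The loading
    budget caps hub_coupling at ~0.70 for the default five-network
    partition, which generation validates.
    """

    n_regions: int = 90
    n_timepoints: int = 142
    n_subjects_per_group: int = 20
    n_states: int = 3
    state_dwell: float = 30.0
    planted_hubs_per_state: tuple[tuple[int, ...], ...] | None = None
    hub_coupling: float = 0.7
    background_coupling: float = 0.2
    noise_sd: float = 0.5
    group_effect: float = 0.5
    ar_coef: float = 0.3
    rsn_proportions: Mapping[str, float] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_regions < 5:
            raise InvalidConfigError("n_regions must be >= 5")
        if self.n_timepoints < 3:
            raise InvalidConfigError("n_timepoints must be >= 3 (JC needs >= 2 points after deletion)")
        if self.n_subjects_per_group < 1:
            raise InvalidConfigError("n_subjects_per_group must be >= 1")
        if self.n_states < 1:
            raise InvalidConfigError("n_states must be >= 1")
        if self.state_dwell < 1:
            raise InvalidConfigError("state_dwell must be >= 1 time point")
        if not (0 <= self.background_coupling < 1):
            raise InvalidConfigError("background_coupling must be in [0, 1)")
        if not (0 <= self.hub_coupling < 1):
            raise InvalidConfigError("hub_coupling must be in [0, 1)")
        if self.hub_coupling and self.hub_coupling <= self.background_coupling:
            raise InvalidConfigError("hub_coupling must exceed background_coupling")
        if not (0 <= self.group_effect <= 1):
            raise InvalidConfigError("group_effect must be in [0, 1]")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be >= 0")
        if not (0 <= self.ar_coef < 1):
            raise InvalidConfigError("ar_coef must be in [0, 1)")
        if self.planted_hubs_per_state is not None:
            hubs = tuple(tuple(int(h) for h in s) for s in self.planted_hubs_per_state)
            if len(hubs) != self.n_states:
                raise InvalidConfigError("planted_hubs_per_state must have one entry per state")
            flat = [h for s in hubs for h in s]
            if any(not (1 <= h <= self.n_regions) for h in flat):
                raise InvalidConfigError("planted hub indices must lie in 1..n_regions")
            object.__setattr__(self, "planted_hubs_per_state", hubs)

    def replace(self, **kwargs) -> "SyntheticConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class ParcellatedTimeSeries:
    """One subject's region x time signal matrix.

    `data` is T rows (time) x N columns (regions); columns must be finite
    with nonzero sample variance.
    """

    subject_id: str
    group: str
    data: np.ndarray
    region_table: RegionTable

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if self.group not in GROUPS:
            raise InvalidInputError(f"group must be one of {GROUPS}, got {self.group!r}")
        if data.ndim != 2:
            raise InvalidInputError("data must be a T x N matrix")
        if data.shape[1] != self.region_table.n_regions:
            raise InvalidInputError(
                f"data has {data.shape[1]} columns but region table has "
                f"{self.region_table.n_regions} regions"
            )
        if not np.all(np.isfinite(data)):
            raise InvalidInputError("data contains missing or non-finite values")
        if np.any(np.var(data, axis=0, ddof=1) <= 0):
            bad = int(np.flatnonzero(np.var(data, axis=0, ddof=1) <= 0)[0])
            raise InvalidInputError(
                f"column {bad + 1} ({self.region_table.region_name[bad]}) has zero variance"
            )

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class SubjectTruth:
    """Ground truth for one generated subject."""

    state_sequence: np.ndarray  # length T; 0..n_states-1, -1 = baseline rest
    hubs_per_state: tuple[tuple[int, ...], ...]  # 1-based region indices


@dataclass(frozen=True)
class Cohort:
    """A generated cohort plus its ground-truth record."""

    config: SyntheticConfig
    region_table: RegionTable
    subjects: tuple[ParcellatedTimeSeries, ...]
    truths: Mapping[str, SubjectTruth]
    subject_seeds: Mapping[str, int]

    def by_group(self, group: str) -> tuple[ParcellatedTimeSeries, ...]:
        return tuple(s for s in self.subjects if s.group == group)

    @property
    def hubs_per_state(self) -> tuple[tuple[int, ...], ...]:
        first = next(iter(self.truths.values()))
        return first.hubs_per_state


def generate_region_table(
    n_regions: int = 90,
    rsn_proportions: Mapping[str, float] | None = None,
    seed: int = 0,
) -> RegionTable:
    """Build a block-contiguous region -> RSN table.

    Counts per RSN follow `rsn_proportions` by the largest-remainder rule,
    and regions of one RSN occupy a consecutive index block so that planted
    structure stays legible. Fully deterministic given (n_regions,
    proportions); `seed` is accepted for interface uniformity.
    """
    props = dict(DEFAULT_RSN_PROPORTIONS if rsn_proportions is None else rsn_proportions)
    unknown = set(props) - set(RSN_NAMES)
    if unknown:
        raise InvalidConfigError(f"unknown RSN labels in proportions: {sorted(unknown)}")
    if any(p < 0 for p in props.values()):
        raise InvalidConfigError("proportions must be non-negative")
    total = sum(props.values())
    if abs(total - 1.0) > 1e-9:
        raise InvalidConfigError(f"proportions must sum to 1 (got {total})")
    labels = [r for r in RSN_NAMES if props.get(r, 0.0) > 0]
    if n_regions < len(labels):
        raise InvalidConfigError(
            f"n_regions={n_regions} is below the {len(labels)} RSNs with nonzero proportion"
        )
    # Largest-remainder apportionment with at least one region per used RSN.
    quotas = np.array([props[r] * n_regions for r in labels])
    counts = np.maximum(np.floor(quotas).astype(int), 1)
    while counts.sum() > n_regions:
        counts[int(np.argmax(counts))] -= 1
    remainders = quotas - np.floor(quotas)
    order = np.argsort(-remainders, kind="stable")
    i = 0
    while counts.sum() < n_regions:
        counts[order[i % len(labels)]] += 1
        i += 1
    rsn: list[str] = []
    names: list[str] = []
    for label, count in zip(labels, counts):
        for k in range(count):
            rsn.append(label)
            names.append(f"{label}.{k + 1:02d}")
    return RegionTable(
        region_index=np.arange(1, n_regions + 1),
        region_name=tuple(names),
        rsn=tuple(rsn),
    )


#: Off-state connector loading as a fraction of the on-state loading.
_OFF_LOADING_RATIO = 0.65
#: Variance share of the diffuse global-integration factor added to SZ
#: state matrices at group_effect = 1 (see _state_correlation).
_SZ_INTEGRATION = 0.40
#: On-state loading on a connector's two primary target networks, as a
#: fraction of hub_coupling.
_PRIMARY_LOADING_RATIO = 0.886
#: On-state loading on the remaining (secondary) foreign networks.
_SECONDARY_LOADING_RATIO = 0.457


def _default_planted_hubs(
    config: SyntheticConfig, table: RegionTable
) -> tuple[tuple[int, ...], ...]:
    """Pick two connector hubs per state from rotating RSN blocks.

    Deterministic given config.seed; state k's hubs come from RSN blocks
    k and k+1 (cyclically), at seed-dependent positions inside the block,
    distinct across states.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(901,)))
    labels = table.rsn_labels
    used: set[int] = set()
    hubs: list[tuple[int, ...]] = []
    for k in range(config.n_states):
        state_hubs = []
        for j in range(2):
            block = table.members(labels[(k + j) % len(labels)])
            free = [int(b) for b in block if b not in used]
            if not free:
                free = [int(b) for b in range(table.n_regions) if b not in used]
            if not free:
                break
            pick = free[int(rng.integers(len(free)))]
            used.add(pick)
            state_hubs.append(pick + 1)  # 1-based
        hubs.append(tuple(state_hubs))
    return tuple(hubs)


def _hub_loading_map(
    config: SyntheticConfig,
    table: RegionTable,
    hubs_per_state: Sequence[Sequence[int]],
) -> dict[int, dict[str, float]]:
    """On-state loadings of every connector on the foreign RSN factors.

    Each connector emphasizes two *primary* foreign networks (loading
    hub_coupling * 0.886 each) and keeps weaker secondary loadings
    (hub_coupling * 0.457) on the rest. Primary pairs are assigned by
    walking a fixed enumeration of RSN pairs, skipping pairs already taken
    or containing the hub's home network, so connectors — within a state
    and across states — bridge distinct module pairs instead of splitting
    the same shortest paths.
    """
    labels = table.rsn_labels
    all_pairs = [
        (labels[a], labels[b])
        for a in range(len(labels))
        for b in range(a + 1, len(labels))
    ]
    hi = _PRIMARY_LOADING_RATIO * config.hub_coupling
    lo = _SECONDARY_LOADING_RATIO * config.hub_coupling
    used: set[tuple[str, str]] = set()
    out: dict[int, dict[str, float]] = {}
    for hubs in hubs_per_state:
        for h in hubs:
            pos = h - 1
            home = table.rsn[pos]
            candidates = [p for p in all_pairs if home not in p and p not in used]
            if not candidates:
                used.clear()
                candidates = [p for p in all_pairs if home not in p]
            if candidates:
                pair = candidates[0]
                used.add(pair)
            else:
                # degenerate partition (single foreign network): make the
                # whole foreign set primary
                pair = tuple(r for r in labels if r != home)
            out[pos] = {r: (hi if r in pair else lo) for r in labels if r != home}
    return out


def _state_correlation(
    config: SyntheticConfig,
    table: RegionTable,
    hubs_per_state: Sequence[Sequence[int]],
    active_state: int,
    group: str,
) -> np.ndarray:
    """Factor-model correlation matrix for one state (PSD by construction).

    One latent factor per RSN; ordinary members load
    sqrt(background_coupling) on their own factor. Every planted connector
    instead loads on the *foreign* RSN factors (split-emphasis scheme, see
    :func:`_hub_loading_map`) — at 0.65 of its on-state loadings while
    its state is inactive (`active_state` -1 means all connectors are at
    baseline).

    The SZ group effect has two components, both scaled by group_effect
    and emulating the dysconnectivity phenotype reported for
    schizophrenia networks (weakened hubs, reduced segregation):

    * the epoch-related elevation of connector coupling above its
      baseline loading is attenuated by 1 - group_effect (at
      group_effect = 1 the connector no longer surges with its state);
    * a diffuse global-integration factor (every region loading
      sqrt(group_effect * 0.40) on one shared factor) adds weak
      unspecific cross-network coupling, shortening network paths the
      way reduced modular segregation does.

    Together these lower mean betweenness centrality in SZ relative to
    NC: path concentration through the planted connectors is lost, and
    diffuse shortcuts de-concentrate what remains.
    """
    labels = table.rsn_labels
    n = config.n_regions
    load = np.zeros((n, len(labels)))
    for j, label in enumerate(labels):
        load[table.members(label), j] = np.sqrt(config.background_coupling)
    on_level = _OFF_LOADING_RATIO + (1.0 - _OFF_LOADING_RATIO) * (
        (1.0 - config.group_effect) if group == "SZ" else 1.0
    )
    loading_map = _hub_loading_map(config, table, hubs_per_state)
    for state, hubs in enumerate(hubs_per_state):
        onoff = on_level if state == active_state else _OFF_LOADING_RATIO
        for h in hubs:
            pos = h - 1
            lam = loading_map[pos]
            load[pos, :] = 0.0
            for j, label in enumerate(labels):
                load[pos, j] = lam.get(label, 0.0) * onoff
    if group == "SZ" and config.group_effect > 0:
        lam_g = np.sqrt(config.group_effect * _SZ_INTEGRATION)
        load = np.column_stack([load, np.full(n, lam_g)])
    c = load @ load.T
    resid = 1.0 - np.diag(c)
    if resid.min() < 0.005:
        raise GenerationError(
            f"state {active_state}: connector loadings leave no residual variance "
            f"(hub_coupling too large for {len(labels) - 1} foreign networks)"
        )
    c = c + np.diag(resid)
    return c


def _quasi_periodic_states(
    config: SyntheticConfig, rng: np.random.Generator
) -> np.ndarray:
    """Cyclic state rotation with jittered dwell times.

    Each visit lasts a uniform draw from [dwell/2, 3*dwell/2] time points,
    after which the next state in the cycle begins; the starting state is
    random. This produces the recurring, roughly evenly occupied epochs
    that make the planted patterns quasi-periodic.

    The downstream hub thresholds are relative (mean + SD over time), so a
    state is detectable only against epochs in which it is *not* engaged.
    With two or more states the rotation itself provides that contrast;
    with a single state the engagement epochs instead alternate with
    baseline rest intervals (state code -1, connectors at their off-state
    loading) of one to two dwell lengths.
    """
    k = config.n_states
    t_total = config.n_timepoints
    states = np.empty(t_total, dtype=int)
    s = int(rng.integers(k))
    lo = max(1, int(round(config.state_dwell / 2)))
    hi = int(round(3 * config.state_dwell / 2))
    base_lo = max(1, int(round(config.state_dwell)))
    base_hi = int(round(2 * config.state_dwell))
    t = 0
    while t < t_total:
        dur = int(rng.integers(lo, hi + 1))
        states[t : t + dur] = s
        t += dur
        s = (s + 1) % k
        if k == 1 and t < t_total:
            gap = int(rng.integers(base_lo, base_hi + 1))
            states[t : t + gap] = -1
            t += gap
    return states


def generate_subject(
    config: SyntheticConfig,
    group: str,
    subject_seed: int,
    *,
    region_table: RegionTable | None = None,
    subject_id: str | None = None,
) -> tuple[ParcellatedTimeSeries, SubjectTruth]:
    """Generate one subject and its ground truth.

    Procedure: (1) draw a quasi-periodic latent state sequence (cyclic
    rotation, jittered dwell around `state_dwell`); (2) per state build
    the factor-model correlation matrix (within-RSN background factors;
    connector hubs loading on the foreign RSN factors, elevated while
    their state is active, scaled by 1 - group_effect for SZ); (3) draw
    z_t = ar * z_{t-1} + sqrt(1 - ar^2) * L_{s(t)} eps_t; (4) add
    independent N(0, noise_sd^2) measurement noise. Deterministic in
    (config, group, subject_seed).
    """
    if group not in GROUPS:
        raise InvalidInputError(f"group must be one of {GROUPS}")
    table = region_table or generate_region_table(config.n_regions, config.rsn_proportions)
    hubs = config.planted_hubs_per_state or _default_planted_hubs(config, table)
    rng = np.random.default_rng(subject_seed)
    states = _quasi_periodic_states(config, rng)
    chols = []
    # one factorization per state, plus a trailing baseline entry so that
    # state code -1 indexes it directly
    for s in list(range(config.n_states)) + [-1]:
        c = _state_correlation(config, table, hubs, s, group)
        chols.append(np.linalg.cholesky(c + 1e-12 * np.eye(config.n_regions)))
    t_total, n = config.n_timepoints, config.n_regions
    eps = rng.standard_normal((t_total, n))
    eta = rng.standard_normal((t_total, n))
    z = np.empty((t_total, n))
    a = config.ar_coef
    innov_scale = np.sqrt(1.0 - a * a)
    z[0] = chols[states[0]] @ eps[0]
    for t in range(1, t_total):
        z[t] = a * z[t - 1] + innov_scale * (chols[states[t]] @ eps[t])
    data = z + config.noise_sd * eta
    ts = ParcellatedTimeSeries(
        subject_id=subject_id or f"{group}_{subject_seed}",
        group=group,
        data=data,
        region_table=table,
    )
    return ts, SubjectTruth(state_sequence=states, hubs_per_state=hubs)


def subject_seed_for(config_seed: int, subject_index: int) -> int:
    """Deterministic per-subject seed: first state word of a spawned
    SeedSequence, folded below 2**31."""
    ss = np.random.SeedSequence(config_seed, spawn_key=(subject_index,))
    return int(ss.generate_state(1)[0] % (2**31))


def generate_cohort(config: SyntheticConfig, out_dir: str | Path | None = None) -> Cohort:
    """Generate the full two-group cohort (and optionally write it to disk).

    Subjects are named NC_001.., SZ_001..; per-subject seeds are derived
    deterministically from `config.seed`. When `out_dir` is given the
    cohort is written as TSV files plus a manifest and ground-truth record
    (see :mod:`dynhubs.io`).
    """
    table = generate_region_table(config.n_regions, config.rsn_proportions)
    hubs = config.planted_hubs_per_state or _default_planted_hubs(config, table)
    cfg = config.replace(planted_hubs_per_state=hubs)
    subjects = []
    truths = {}
    seeds = {}
    index = 0
    for group in GROUPS:
        for k in range(cfg.n_subjects_per_group):
            sid = f"{group}_{k + 1:03d}"
            seed = subject_seed_for(cfg.seed, index)
            ts, truth = generate_subject(
                cfg, group, seed, region_table=table, subject_id=sid
            )
            subjects.append(ts)
            truths[sid] = truth
            seeds[sid] = seed
            index += 1
    cohort = Cohort(
        config=cfg,
        region_table=table,
        subjects=tuple(subjects),
        truths=truths,
        subject_seeds=seeds,
    )
    if out_dir is not None:
        from . import io as _io

        _io.write_cohort(cohort, out_dir)
    return cohort
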
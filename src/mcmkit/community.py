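"""Coupled community projection under an aggregate dependency assumption.

A matrix community model (MCM) couples otherwise independent single-species
matrix population models through one shared quantity: the aggregate resource
load

    N(t) = sum_j sum_i  w_ij * n_ij(t)

(the resource-weighted abundance of every stage of every species), measured
against a community-wide carrying capacity K. No pairwise interaction terms
exist anywhere in the model; species influence each other only by loading
the common resource.

Two concrete coupling modes from empirical MCMs are built in, plus a
generic form:

``space_limited_recruitment``
    a hard ceiling: open space ``max(0, K - N)`` caps the total resource
    claimed by new stage-1 recruits each step (riparian-vegetation style,
    optionally with a rescue effect where any surviving population can seed
    all open space in a favorable year);
``biomass_limited_fecundity``
    every fecundity entry is scaled by a multiplier that declines with
    total load (fish-community style, regulating egg survivorship);
``generic_scaling``
    the same multiplicative regulation aimed at any role tag or entry set.

Within a step the order of operations is fixed: the load is computed from
n(t), the dependency is applied, then every species is projected one step —
i.e. density dependence acts with a one-step lag, matching a discrete
annual census.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .demography import SpeciesModel, StageMatrix, StageVector, StructuralError
from .environment import Regime, generate_sequence, rng_stream

__all__ = [
    "DependencyAssumption",
    "CommunityModel",
    "Trajectory",
    "ProjectionError",
    "aggregate_load",
    "apply_dependency",
    "allocate_recruitment",
    "project_community",
    "exclusion_summary",
    "ExclusionSummary",
    "linear_scaling",
    "DEPENDENCY_MODES",
    "ALLOCATION_RULES",
]

DEPENDENCY_MODES = (
    "space_limited_recruitment",
    "biomass_limited_fecundity",
    "generic_scaling",
)
ALLOCATION_RULES = ("proportional", "equal", "priority")


class ProjectionError(RuntimeError):
    """Raised when a projection produces non-finite abundances."""


def linear_scaling(load: float, K: float) -> float:
    """The built-in linear multiplier max(0, 1 - N/K); reaches 0 at N = K."""
    if math.isinf(K):
        return 1.0
    if K == 0.0:
        return 0.0  # no resource at all: reproduction fully suppressed
    return max(0.0, 1.0 - load / K)


@dataclass
class DependencyAssumption:
    """How aggregate load down-regulates vital rates community-wide.

    Parameters
    ----------
    mode
        One of :data:`DEPENDENCY_MODES`.
    K
        Carrying capacity in resource units (may be ``inf`` to disable
        regulation while keeping the code path).
    scaling_form
        ``"linear"`` (multiplier ``max(0, 1 - N/K)``) or a callable
        ``f(N, K) -> multiplier in [0, 1]``, used by the multiplicative
        modes. The space-limited mode uses the ceiling ``max(0, K - N)``
        instead.
    target_role
        Role tag whose entries are regulated in the multiplicative modes
        (default ``"F"``).
    rescue_effect
        Space-limited mode only: recruitment demand is independent of adult
        abundance — any species with positive total abundance claims the
        full open space in a year type where it can recruit
        (``SpeciesModel.recruitment_years``).
    allocation_rule
        How contested open space is split (:data:`ALLOCATION_RULES`).
    priority_order
        Species ids, highest priority first (required by the priority rule).
    """

    mode: str
    K: float
    scaling_form: str | Callable[[float, float], float] = "linear"
    target_role: str = "F"
    rescue_effect: bool = False
    allocation_rule: str = "proportional"
    priority_order: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.mode not in DEPENDENCY_MODES:
            raise StructuralError(
                f"unknown dependency mode {self.mode!r}; expected one of {DEPENDENCY_MODES}"
            )
        self.K = float(self.K)
        if not self.K >= 0 or math.isnan(self.K):
            raise StructuralError(f"carrying capacity K must be nonnegative, got {self.K}")
        if self.allocation_rule not in ALLOCATION_RULES:
            raise StructuralError(
                f"unknown allocation rule {self.allocation_rule!r}; "
                f"expected one of {ALLOCATION_RULES}"
            )
        if self.allocation_rule == "priority" and not self.priority_order:
            raise StructuralError("priority allocation requires priority_order")
        if self.rescue_effect and self.mode != "space_limited_recruitment":
            raise StructuralError("rescue_effect applies only to space_limited_recruitment")
        if self.rescue_effect and math.isinf(self.K):
            raise StructuralError("rescue_effect requires a finite K")

    def multiplier(self, load: float) -> float:
        if callable(self.scaling_form):
            m = float(self.scaling_form(load, self.K))
        elif self.scaling_form == "linear":
            m = linear_scaling(load, self.K)
        else:
            raise StructuralError(f"unknown scaling form {self.scaling_form!r}")
        if not 0.0 <= m <= 1.0:
            raise StructuralError(f"scaling multiplier {m} outside [0, 1] at load {load}")
        return m


@dataclass
class CommunityModel:
    """A set of species models sharing one regime and one dependency."""

    species: list[SpeciesModel]
    regime: Regime
    dependency: DependencyAssumption | None = None
    extinction_threshold: float = 0.0

    def __post_init__(self):
        if not self.species:
            raise StructuralError("community needs at least one species")
        ids = [s.species_id for s in self.species]
        if len(set(ids)) != len(ids):
            raise StructuralError(f"duplicate species ids: {ids}")
        needed = set(self.regime.year_types)
        for s in self.species:
            missing = needed - s.year_types
            if missing:
                raise StructuralError(
                    f"species {s.species_id!r} lacks matrices for year types {sorted(missing)}"
                )
        if self.extinction_threshold < 0:
            raise StructuralError("extinction_threshold must be nonnegative")

    @property
    def species_ids(self) -> list[str]:
        return [s.species_id for s in self.species]

    def species_by_id(self, species_id: str) -> SpeciesModel:
        for s in self.species:
            if s.species_id == species_id:
                return s
        raise StructuralError(
            f"no species {species_id!r}; have {self.species_ids}"
        )

    def node_labels(self) -> list[str]:
        """Flat '<species>:<stage>' labels, in species then stage order."""
        return [
            f"{s.species_id}:{lab}" for s in self.species for lab in s.stage_labels
        ]


@dataclass
class Trajectory:
    """A realised community path: states per species, events, year types."""

    species_ids: list[str]
    stage_labels: dict[str, tuple[str, ...]]
    states: dict[str, np.ndarray]  # species -> (T+1, n_stages)
    year_types: list[str]  # length T
    loads: np.ndarray  # length T+1, aggregate load at each census
    events: list[dict]

    @property
    def horizon(self) -> int:
        return len(self.year_types)

    def totals(self, species_id: str) -> np.ndarray:
        return self.states[species_id].sum(axis=1)

    def final_state(self, species_id: str) -> np.ndarray:
        return self.states[species_id][-1]

    def survivors(self, threshold: float = 0.0) -> list[str]:
        """Species with final total abundance strictly above the threshold."""
        return [
            sid for sid in self.species_ids
            if self.states[sid][-1].sum() > threshold
        ]

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy long format: time, year_type, species, stage, abundance."""
        recs = []
        yt = [""] + list(self.year_types)  # year_types[t] drives t-1 -> t
        for sid in self.species_ids:
            arr = self.states[sid]
            labs = self.stage_labels[sid]
            for t in range(arr.shape[0]):
                for i, lab in enumerate(labs):
                    recs.append((t, yt[t] if t < len(yt) else "", sid, lab, arr[t, i]))
        return pd.DataFrame(
            recs, columns=["time", "year_type", "species", "stage", "abundance"]
        )

    def events_dataframe(self) -> pd.DataFrame:
        cols = ["time", "species", "event", "detail"]
        if not self.events:
            return pd.DataFrame(columns=cols)
        return pd.DataFrame(self.events)[cols]


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def aggregate_load(states: Sequence[np.ndarray], species: Sequence[SpeciesModel]) -> float:
    """Total resource-weighted abundance over all species and stages."""
    total = 0.0
    for v, s in zip(states, species):
        total += float(np.dot(np.asarray(v, dtype=float), s.resource_weights))
    return total


def apply_dependency(
    matrices: dict[str, StageMatrix],
    load: float,
    dependency: DependencyAssumption | None,
):
    """Apply the dependency assumption at aggregate load N.

    Returns ``(matrices, recruit_cap, events)``. In the multiplicative modes
    the targeted entries of every matrix are scaled by the multiplier and
    ``recruit_cap`` is ``None``; in space-limited mode matrices are returned
    unchanged and ``recruit_cap`` is the open space ``max(0, K - N)`` (in
    resource units). An overload (N > K) is reported in ``events``.
    """
    if load < 0:
        raise StructuralError(f"aggregate load must be nonnegative, got {load}")
    events: list[dict] = []
    if dependency is None:
        return matrices, None, events

    if dependency.mode == "space_limited_recruitment":
        cap = max(0.0, dependency.K - load)
        if load > dependency.K:
            events.append({"event": "overload", "detail": f"load {load:.6g} > K {dependency.K:.6g}"})
        return matrices, cap, events

    m = dependency.multiplier(load)
    if load > dependency.K and m == 0.0:
        events.append({"event": "overload", "detail": f"load {load:.6g} > K {dependency.K:.6g}"})
    if m == 1.0:
        return matrices, None, events
    out = {}
    for sid, sm in matrices.items():
        roles = sm.roles
        if roles is None:
            from .demography import default_roles
            roles = default_roles(sm.n_stages)
        mask = roles == dependency.target_role
        e = sm.entries.copy()
        e[mask] *= m
        out[sid] = StageMatrix(e, sm.stage_labels, sm.roles)
    return out, None, events


def allocate_recruitment(
    demands: np.ndarray,
    available: float,
    rule: str = "proportional",
    priority_order: Sequence[int] | None = None,
) -> np.ndarray:
    """Split contested recruitment among species.

    ``demands`` and ``available`` are in common resource units. If total
    demand fits, everyone gets their demand; otherwise the shortfall is
    resolved by ``rule``: ``proportional`` (to demand), ``equal`` (equal
    shares, capped at own demand, surplus redistributed), or ``priority``
    (fill in the given index order). The result never exceeds demand
    per-species nor ``available`` in total.
    """
    demands = np.asarray(demands, dtype=float)
    if (demands < 0).any():
        raise StructuralError("recruitment demands must be nonnegative")
    if available < 0:
        raise StructuralError("available space must be nonnegative")
    total = demands.sum()
    if total <= available:
        return demands.copy()
    if rule == "proportional":
        return demands * (available / total)
    if rule == "equal":
        # water-filling: repeatedly grant min(fair share, demand)
        realized = np.zeros_like(demands)
        remaining = available
        active = demands > 0
        while remaining > 1e-15 * max(available, 1.0) and active.any():
            share = remaining / active.sum()
            grant = np.minimum(demands - realized, np.where(active, share, 0.0))
            realized += grant
            remaining -= grant.sum()
            active = (demands - realized) > 1e-12
            if grant.sum() <= 0:
                break
        return realized
    if rule == "priority":
        if priority_order is None:
            raise StructuralError("priority allocation requires priority_order")
        realized = np.zeros_like(demands)
        remaining = available
        for i in priority_order:
            take = min(demands[i], remaining)
            realized[i] = take
            remaining -= take
        return realized
    raise StructuralError(f"unknown allocation rule {rule!r}")


def _initial_states(community: CommunityModel, initial) -> list[np.ndarray]:
    if initial is None:
        return [np.full(s.n_stages, 1.0) for s in community.species]
    states = []
    for s in community.species:
        if isinstance(initial, dict):
            v = np.asarray(initial[s.species_id], dtype=float)
        else:
            v = np.asarray(initial[community.species_ids.index(s.species_id)], dtype=float)
        if v.shape != (s.n_stages,):
            raise StructuralError(
                f"initial state for {s.species_id!r} has shape {v.shape}, "
                f"expected ({s.n_stages},)"
            )
        states.append(v.copy())
    return states


def project_community(
    community: CommunityModel,
    horizon: int,
    seed: int = 0,
    sequence: Sequence[str] | None = None,
    initial=None,
) -> Trajectory:
    """Project the coupled community ``horizon`` steps.

    Per step: read/draw the year type, compute the aggregate load from the
    current census, apply the dependency assumption, project every species
    one step, then apply the extinction threshold (a species whose total
    falls below it is set to zero, with an event logged). Passing an
    explicit ``sequence`` overrides the regime draw (it must cover the
    horizon).

    With ``community.dependency is None`` every species follows its plain
    linear projection: the decoupled limit is element-exact.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    if sequence is not None:
        sequence = list(sequence)
        if len(sequence) < horizon:
            raise ValueError("explicit sequence shorter than horizon")
        sequence = sequence[:horizon]
    else:
        sequence = generate_sequence(
            community.regime, horizon, rng_stream(seed, "environment")
        )

    dep = community.dependency
    spp = community.species
    n_sp = len(spp)
    states = _initial_states(community, initial)
    # pre-extract raw arrays per (species, year type) for speed
    mats = [
        {yt: s.matrix_for(yt) for yt in community.regime.year_types} for s in spp
    ]
    fec_masks = [
        {yt: mats[j][yt].fecundity_mask() for yt in community.regime.year_types}
        for j in range(n_sp)
    ]
    weights = [s.resource_weights for s in spp]
    w_recruit = np.array([w[0] if w[0] > 0 else 1.0 for w in weights])
    space_mode = dep is not None and dep.mode == "space_limited_recruitment"
    rescue = space_mode and dep.rescue_effect
    threshold = community.extinction_threshold

    out = [np.empty((horizon + 1, s.n_stages)) for s in spp]
    loads = np.empty(horizon + 1)
    for j in range(n_sp):
        out[j][0] = states[j]
    events: list[dict] = []
    alive = [bool(states[j].sum() > 0) for j in range(n_sp)]

    # float overflow is detected per step and converted to ProjectionError
    old_err = np.seterr(over="ignore", invalid="ignore")
    try:
        return _project_loop(
            community, sequence, dep, spp, states, mats, fec_masks, w_recruit,
            space_mode, rescue, threshold, out, loads, events, alive, horizon,
        )
    finally:
        np.seterr(**old_err)


def _project_loop(
    community, sequence, dep, spp, states, mats, fec_masks, w_recruit,
    space_mode, rescue, threshold, out, loads, events, alive, horizon,
):
    n_sp = len(spp)
    for t, yt in enumerate(sequence):
        load = aggregate_load(states, spp)
        loads[t] = load
        cur = {s.species_id: mats[j][yt] for j, s in enumerate(spp)}
        cur, cap, step_events = apply_dependency(cur, load, dep)
        for ev in step_events:
            events.append({"time": t, "species": "", **ev})

        new_states = []
        if space_mode:
            fulls = []
            demands = np.zeros(n_sp)
            for j, s in enumerate(spp):
                A = cur[s.species_id]
                full = A.entries @ states[j]
                fulls.append(full)
                if rescue:
                    can_recruit = (
                        s.recruitment_years is None or yt in s.recruitment_years
                    )
                    if alive[j] and can_recruit:
                        demands[j] = cap  # claim all open space, in resource units
                else:
                    fmask = fec_masks[j][yt]
                    recruits = float((A.entries * fmask)[0] @ states[j])
                    demands[j] = recruits * w_recruit[j]
            order = None
            if dep.allocation_rule == "priority":
                order = [community.species_ids.index(i) for i in dep.priority_order]
            realized = allocate_recruitment(demands, cap, dep.allocation_rule, order)
            for j, s in enumerate(spp):
                full = fulls[j]
                if rescue:
                    A = cur[s.species_id]
                    fmask = fec_masks[j][yt]
                    survivors0 = float((A.entries * ~fmask)[0] @ states[j])
                    new = full.copy()
                    new[0] = survivors0 + realized[j] / w_recruit[j]
                elif realized[j] == demands[j]:
                    new = full  # uncapped: identical to the plain linear step
                else:
                    A = cur[s.species_id]
                    fmask = fec_masks[j][yt]
                    survivors0 = float((A.entries * ~fmask)[0] @ states[j])
                    new = full.copy()
                    new[0] = survivors0 + realized[j] / w_recruit[j]
                new_states.append(new)
        else:
            for j, s in enumerate(spp):
                new_states.append(cur[s.species_id].entries @ states[j])

        for j, s in enumerate(spp):
            v = new_states[j]
            if not np.isfinite(v).all():
                raise ProjectionError(
                    f"non-finite abundance for species {s.species_id!r} at time {t + 1}"
                )
            tot = v.sum()
            if alive[j] and (tot <= 0.0 or tot < threshold):
                v = np.zeros_like(v)
                alive[j] = False
                events.append(
                    {
                        "time": t + 1,
                        "species": s.species_id,
                        "event": "extirpation",
                        "detail": f"total {tot:.6g} below threshold {threshold:.6g}",
                    }
                )
            elif not alive[j] and tot > 0.0:
                # can only happen under rescue recruitment from zero; the
                # rescue gate requires alive[j], so keep extinct species at 0
                v = np.zeros_like(v)
            states[j] = v
            out[j][t + 1] = v

    loads[horizon] = aggregate_load(states, spp)
    return Trajectory(
        species_ids=community.species_ids,
        stage_labels={s.species_id: s.stage_labels for s in spp},
        states={s.species_id: out[j] for j, s in enumerate(spp)},
        year_types=list(sequence),
        loads=loads,
        events=events,
    )


@dataclass
class ExclusionSummary:
    """Replicated long-run persistence diagnostics."""

    species_ids: list[str]
    persistence_prob: dict[str, float]
    median_extirpation_time: dict[str, float]  # NaN when never extirpated
    survivor_counts: dict[int, int]  # number of surviving species -> replicates
    modal_survivor: str | None
    survivor_sets: list[frozenset]
    replicates: int

    def single_survivor_fraction(self) -> float:
        """Fraction of replicates ending with at most one species."""
        n = sum(c for k, c in self.survivor_counts.items() if k <= 1)
        return n / self.replicates


def exclusion_summary(
    community: CommunityModel,
    horizon: int,
    replicates: int,
    seed: int = 0,
    initial=None,
) -> ExclusionSummary:
    """Run replicated projections and summarise extirpation outcomes."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    ids = community.species_ids
    persist = {sid: 0 for sid in ids}
    ext_times: dict[str, list[float]] = {sid: [] for sid in ids}
    counts: dict[int, int] = {}
    last_survivor: dict[str, int] = {sid: 0 for sid in ids}
    sets = []
    for r in range(replicates):
        traj = project_community(
            community, horizon, seed=int(rng_stream(seed, "excl", r).integers(2**31)),
            initial=initial,
        )
        surv = frozenset(traj.survivors())
        sets.append(surv)
        counts[len(surv)] = counts.get(len(surv), 0) + 1
        for sid in surv:
            persist[sid] += 1
        if len(surv) == 1:
            (only,) = surv
            last_survivor[only] += 1
        first_ext = {
            ev["species"]: ev["time"]
            for ev in reversed(traj.events)
            if ev["event"] == "extirpation"
        }
        for sid in ids:
            if sid in first_ext:
                ext_times[sid].append(first_ext[sid])
    modal = None
    if any(last_survivor.values()):
        modal = max(ids, key=lambda sid: last_survivor[sid])
    return ExclusionSummary(
        species_ids=ids,
        persistence_prob={sid: persist[sid] / replicates for sid in ids},
        median_extirpation_time={
            sid: (float(np.median(ts)) if ts else float("nan"))
            for sid, ts in ext_times.items()
        },
        survivor_counts=counts,
        modal_survivor=modal,
        survivor_sets=sets,
        replicates=replicates,
    )
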
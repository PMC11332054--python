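"""Run configuration: schema, YAML round trip, result readers/writers.

A run is declared by one hierarchical YAML file plus one CSV per
(species, year type) transition matrix (with an optional ``.roles.csv``
sidecar tagging entries F/G/P/O). The schema is strict: unknown keys are
rejected with a message naming the offending key, so typos cannot silently
fall back to defaults. All protocol defaults — perturbation grid step 0.01,
replicate cap 1000, retention thresholds R^2 > 0.30 and p < 0.01 — live on
:class:`SensitivityConfig` / :class:`NetworkConfig`.

Relative matrix paths are resolved against the location of the config
file, and ``save_config`` followed by ``load_config`` is the identity.
"""

from __future__ import annotations

import csv
import hashlib
import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .community import (
    ALLOCATION_RULES,
    DEPENDENCY_MODES,
    CommunityModel,
    DependencyAssumption,
    Trajectory,
)
from .demography import SpeciesModel, StageMatrix
from .environment import Regime

__all__ = [
    "RunConfig",
    "SensitivityConfig",
    "NetworkConfig",
    "ConfigError",
    "load_config",
    "save_config",
    "write_trajectory",
    "write_manifest",
]


class ConfigError(ValueError):
    """Raised for malformed or invalid run configurations."""


def _check_keys(mapping: dict, allowed: set[str], where: str) -> None:
    if not isinstance(mapping, dict):
        raise ConfigError(f"{where}: expected a mapping, got {type(mapping).__name__}")
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(
            f"{where}: unknown key(s) {sorted(unknown)}; allowed keys are {sorted(allowed)}"
        )


def _require(mapping: dict, key: str, where: str):
    if key not in mapping:
        raise ConfigError(f"{where}: missing required key {key!r}")
    return mapping[key]


@dataclass
class SensitivityConfig:
    """Perturbation-protocol parameters (defaults = the standard protocol)."""

    grid_step: float = 0.01
    half_width: float = 0.10
    replicates: int = 1000
    r2_threshold: float = 0.30
    p_threshold: float = 0.01
    horizon: int = 200
    response_window: float = 0.25


@dataclass
class NetworkConfig:
    r2_threshold: float = 0.30
    p_threshold: float = 0.01
    include_self_loops: bool = False


@dataclass(eq=False)
class RunConfig:
    """Everything needed to reproduce a run."""

    community: CommunityModel | None = None
    horizon: int = 1000
    seed: int = 0
    sensitivity: SensitivityConfig = field(default_factory=SensitivityConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    output_dir: str = "out"

    def __eq__(self, other) -> bool:
        if not isinstance(other, RunConfig):
            return NotImplemented
        return _canonical(self) == _canonical(other)

    def config_hash(self) -> str:
        blob = json.dumps(_canonical(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _canonical(cfg: RunConfig) -> dict:
    """A plain, comparable/hashable representation of a RunConfig."""
    d: dict = {
        "horizon": cfg.horizon,
        "seed": cfg.seed,
        "sensitivity": asdict(cfg.sensitivity),
        "network": asdict(cfg.network),
        "output_dir": cfg.output_dir,
    }
    com = cfg.community
    if com is None:
        d["community"] = None
        return d
    dep = com.dependency
    d["community"] = {
        "extinction_threshold": com.extinction_threshold,
        "dependency": None
        if dep is None
        else {
            "mode": dep.mode,
            "K": dep.K,
            "scaling_form": dep.scaling_form
            if isinstance(dep.scaling_form, str)
            else "<callable>",
            "target_role": dep.target_role,
            "rescue_effect": dep.rescue_effect,
            "allocation_rule": dep.allocation_rule,
            "priority_order": list(dep.priority_order) if dep.priority_order else None,
        },
        "species": [
            {
                "id": s.species_id,
                "abundance_unit": s.abundance_unit,
                "weights": [float(w) for w in s.resource_weights],
                "recruitment_years": sorted(s.recruitment_years)
                if s.recruitment_years is not None
                else None,
                "stages": list(s.stage_labels),
                "matrices": {
                    yt: {
                        "values": [[float(x) for x in row] for row in m.entries],
                        "roles": None
                        if m.roles is None
                        else [list(row) for row in m.roles],
                    }
                    for yt, m in sorted(s.matrices.items())
                },
            }
            for s in com.species
        ],
    }
    r = com.regime
    d["regime"] = {
        "mode": r.mode,
        "year_types": list(r.year_types),
        "frequencies": list(r.frequencies) if r.frequencies else None,
        "transition_probs": [list(row) for row in r.transition_probs]
        if r.transition_probs
        else None,
        "sequence": list(r.sequence) if r.sequence else None,
        "initial_distribution": list(r.initial_distribution)
        if r.initial_distribution
        else None,
        "cycle": r.cycle,
    }
    return d


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

_TOP_KEYS = {"community", "regime", "horizon", "seed", "sensitivity", "network", "output_dir"}
_COMMUNITY_KEYS = {"species", "dependency", "extinction_threshold"}
_SPECIES_KEYS = {"id", "matrices", "weights", "abundance_unit", "recruitment_years", "stages"}
_DEP_KEYS = {
    "mode", "K", "scaling_form", "target_role", "rescue_effect",
    "allocation_rule", "priority_order",
}
_REGIME_KEYS = {
    "mode", "year_types", "frequencies", "transition_probs", "sequence",
    "sequence_file", "initial_distribution", "cycle",
}
_SENS_KEYS = set(SensitivityConfig.__dataclass_fields__)
_NET_KEYS = set(NetworkConfig.__dataclass_fields__)


def _load_matrix(spec, base_dir: str, where: str, stages) -> StageMatrix:
    if isinstance(spec, str):
        path = spec if os.path.isabs(spec) else os.path.join(base_dir, spec)
        if not os.path.exists(path):
            raise ConfigError(f"{where}: matrix file not found: {path}")
        return StageMatrix.from_csv(path)
    _check_keys(spec, {"values", "roles", "stages"}, where)
    values = np.asarray(_require(spec, "values", where), dtype=float)
    labels = tuple(spec.get("stages") or stages or [str(i + 1) for i in range(values.shape[0])])
    roles = spec.get("roles")
    roles = np.asarray(roles, dtype="<U1") if roles is not None else None
    return StageMatrix(values, labels, roles)


def _load_species(spec, base_dir: str) -> SpeciesModel:
    where = f"community.species[{spec.get('id', '?')!r}]"
    _check_keys(spec, _SPECIES_KEYS, where)
    sid = str(_require(spec, "id", where))
    stages = spec.get("stages")
    mats_spec = _require(spec, "matrices", where)
    if not isinstance(mats_spec, dict) or not mats_spec:
        raise ConfigError(f"{where}: 'matrices' must map year types to files or inline matrices")
    matrices = {
        str(yt): _load_matrix(m, base_dir, f"{where}.matrices[{yt!r}]", stages)
        for yt, m in mats_spec.items()
    }
    weights = _require(spec, "weights", where)
    rec = spec.get("recruitment_years")
    return SpeciesModel(
        species_id=sid,
        matrices=matrices,
        resource_weights=np.asarray(weights, dtype=float),
        abundance_unit=str(spec.get("abundance_unit", "individuals")),
        recruitment_years=frozenset(rec) if rec is not None else None,
    )


def _load_dependency(spec) -> DependencyAssumption | None:
    if spec is None:
        return None
    where = "community.dependency"
    _check_keys(spec, _DEP_KEYS, where)
    mode = _require(spec, "mode", where)
    if mode not in DEPENDENCY_MODES:
        raise ConfigError(f"{where}: unknown mode {mode!r}; expected one of {DEPENDENCY_MODES}")
    K = float(_require(spec, "K", where))
    if K < 0:
        raise ConfigError(f"{where}: carrying capacity K must be nonnegative, got {K}")
    rule = spec.get("allocation_rule", "proportional")
    if rule not in ALLOCATION_RULES:
        raise ConfigError(f"{where}: unknown allocation_rule {rule!r}")
    prio = spec.get("priority_order")
    return DependencyAssumption(
        mode=mode,
        K=K,
        scaling_form=spec.get("scaling_form", "linear"),
        target_role=spec.get("target_role", "F"),
        rescue_effect=bool(spec.get("rescue_effect", False)),
        allocation_rule=rule,
        priority_order=tuple(prio) if prio else None,
    )


def _load_regime(spec, base_dir: str) -> Regime:
    where = "regime"
    _check_keys(spec, _REGIME_KEYS, where)
    mode = _require(spec, "mode", where)
    seq = spec.get("sequence")
    if spec.get("sequence_file") is not None:
        path = spec["sequence_file"]
        if not os.path.isabs(path):
            path = os.path.join(base_dir, path)
        with open(path, newline="") as fh:
            seq = [row[0] for row in csv.reader(fh) if row]
    try:
        return Regime(
            year_types=tuple(_require(spec, "year_types", where)),
            mode=mode,
            frequencies=tuple(spec["frequencies"]) if spec.get("frequencies") else None,
            transition_probs=tuple(tuple(r) for r in spec["transition_probs"])
            if spec.get("transition_probs")
            else None,
            sequence=tuple(seq) if seq is not None else None,
            initial_distribution=tuple(spec["initial_distribution"])
            if spec.get("initial_distribution")
            else None,
            cycle=bool(spec.get("cycle", False)),
        )
    except ValueError as exc:
        raise ConfigError(f"{where}: {exc}") from exc


def _load_section(spec, cls, keys, where):
    if spec is None:
        return cls()
    _check_keys(spec, keys, where)
    defaults = cls()
    kwargs = {}
    for k in keys:
        if k in spec:
            typ = type(getattr(defaults, k))
            try:
                kwargs[k] = typ(spec[k])
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"{where}.{k}: expected {typ.__name__}, got {spec[k]!r}") from exc
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    """Load and validate a run configuration from YAML."""
    path = str(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    _check_keys(raw, _TOP_KEYS, "config")
    base_dir = os.path.dirname(os.path.abspath(path))

    community = None
    if "community" in raw:
        cspec = raw["community"]
        _check_keys(cspec, _COMMUNITY_KEYS, "community")
        species = [_load_species(s, base_dir) for s in _require(cspec, "species", "community")]
        dep = _load_dependency(cspec.get("dependency"))
        regime = _load_regime(_require(raw, "regime", "config"), base_dir)
        thr = float(cspec.get("extinction_threshold", 0.0))
        if thr < 0:
            raise ConfigError("community.extinction_threshold must be nonnegative")
        try:
            community = CommunityModel(
                species=species, regime=regime, dependency=dep, extinction_threshold=thr
            )
        except ValueError as exc:
            raise ConfigError(f"community: {exc}") from exc

    horizon = int(raw.get("horizon", 1000))
    if horizon < 1:
        raise ConfigError("horizon must be >= 1")
    return RunConfig(
        community=community,
        horizon=horizon,
        seed=int(raw.get("seed", 0)),
        sensitivity=_load_section(raw.get("sensitivity"), SensitivityConfig, _SENS_KEYS, "sensitivity"),
        network=_load_section(raw.get("network"), NetworkConfig, _NET_KEYS, "network"),
        output_dir=str(raw.get("output_dir", "out")),
    )


# ---------------------------------------------------------------------------
# Saving
# ---------------------------------------------------------------------------


def save_config(config: RunConfig, path) -> None:
    """Write a RunConfig as YAML plus per-matrix CSV files.

    Matrices go into a ``matrices/`` directory next to the config file and
    are referenced by relative path, so the written bundle is relocatable.
    """
    path = str(path)
    base_dir = os.path.dirname(os.path.abspath(path)) or "."
    os.makedirs(base_dir, exist_ok=True)
    doc: dict = {
        "horizon": config.horizon,
        "seed": config.seed,
        "sensitivity": asdict(config.sensitivity),
        "network": asdict(config.network),
        "output_dir": config.output_dir,
    }
    com = config.community
    if com is not None:
        mat_dir = os.path.join(base_dir, "matrices")
        os.makedirs(mat_dir, exist_ok=True)
        species_docs = []
        for s in com.species:
            refs = {}
            for yt, m in s.matrices.items():
                fname = f"{s.species_id}_{yt}.csv"
                m.to_csv(os.path.join(mat_dir, fname))
                refs[yt] = os.path.join("matrices", fname)
            sd = {
                "id": s.species_id,
                "abundance_unit": s.abundance_unit,
                "weights": [float(w) for w in s.resource_weights],
                "matrices": refs,
            }
            if s.recruitment_years is not None:
                sd["recruitment_years"] = sorted(s.recruitment_years)
            species_docs.append(sd)
        dep = com.dependency
        dep_doc = None
        if dep is not None:
            if callable(dep.scaling_form):
                raise ConfigError("cannot serialise a callable scaling_form to YAML")
            dep_doc = {
                "mode": dep.mode,
                "K": dep.K,
                "scaling_form": dep.scaling_form,
                "target_role": dep.target_role,
                "rescue_effect": dep.rescue_effect,
                "allocation_rule": dep.allocation_rule,
            }
            if dep.priority_order:
                dep_doc["priority_order"] = list(dep.priority_order)
        doc["community"] = {
            "species": species_docs,
            "dependency": dep_doc,
            "extinction_threshold": com.extinction_threshold,
        }
        r = com.regime
        rdoc: dict = {"mode": r.mode, "year_types": list(r.year_types)}
        if r.frequencies is not None:
            rdoc["frequencies"] = list(r.frequencies)
        if r.transition_probs is not None:
            rdoc["transition_probs"] = [list(row) for row in r.transition_probs]
        if r.sequence is not None:
            rdoc["sequence"] = list(r.sequence)
        if r.initial_distribution is not None:
            rdoc["initial_distribution"] = list(r.initial_distribution)
        if r.cycle:
            rdoc["cycle"] = True
        doc["regime"] = rdoc
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Result output
# ---------------------------------------------------------------------------


def write_trajectory(traj: Trajectory, directory) -> None:
    """Tidy long-format trajectory CSV plus an events CSV."""
    os.makedirs(directory, exist_ok=True)
    traj.to_dataframe().to_csv(os.path.join(directory, "trajectory.csv"), index=False)
    traj.events_dataframe().to_csv(os.path.join(directory, "events.csv"), index=False)


def write_manifest(directory, config: RunConfig | None = None, **extra) -> None:
    """Record enough metadata (config hash, seeds, versions) to replay a run."""
    import datetime
    import platform

    from . import __version__

    os.makedirs(directory, exist_ok=True)
    manifest = {
        "mcmkit_version": __version__,
        "numpy_version": np.__version__,
        "python_version": platform.python_version(),
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    if config is not None:
        manifest["config_hash"] = config.config_hash()
        manifest["seed"] = config.seed
    manifest.update(extra)
    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
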
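"""Cross-species sensitivity analysis: latent interactions by perturbation.

Because the coupled community model is nonlinear (density dependence) and
stochastic, sensitivities cannot be read off analytically; they are
estimated by simulation. One vital rate is moved over a fine grid around
its actual value; at each grid value the community is re-simulated many
times; each responding species/stage's abundance (averaged over a final
response window) is averaged across replicates; and the sensitivity is the
ordinary-least-squares slope of that mean response against the grid value —
a finite-difference analogue of the partial derivative of population size
with respect to the vital rate.

An edge (perturbed rate -> responder) is *retained* for network analysis
when the regression fit exceeds an R^2 threshold (default 0.30) and the
slope is significant (two-sided p < 0.01 by default).

Sign conventions: perturbing a *mortality* rate m (entry = 1 - m) of a
stage and reading the same stage gives a negative slope (a self-effect);
a positive cross-slope means that harming one species/stage releases
another — latent competition.

Replicates use common random numbers by default: replicate r sees the same
environmental sequence at every grid value, so a degenerate single-point
grid reproduces the baseline simulation bit-for-bit and grid contrasts are
not diluted by environmental noise. Independent streams per (grid value,
replicate) are available for strictly independent designs.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .community import CommunityModel, project_community
from .demography import StageMatrix, StructuralError, default_roles
from .environment import rng_stream

__all__ = [
    "VitalRateAddress",
    "PerturbationSpec",
    "MeasureTable",
    "SensitivityResult",
    "perturb_and_measure",
    "fit_sensitivity",
    "cross_sensitivity",
    "default_targets",
]

R2_THRESHOLD_DEFAULT = 0.30
P_THRESHOLD_DEFAULT = 0.01
GRID_STEP_DEFAULT = 0.01
GRID_HALF_WIDTH_DEFAULT = 0.10
REPLICATE_CAP_DEFAULT = 1000
BATCH_SIZE_DEFAULT = 100
CONVERGENCE_RTOL_DEFAULT = 0.01


@dataclass(frozen=True)
class VitalRateAddress:
    """Addresses one matrix entry: (species, 1-based row, 1-based column).

    ``year_types`` restricts the perturbation to the listed year types
    (e.g. only flood-year mortality); ``None`` means all year types.
    ``parameterization`` is ``"rate"`` (the grid moves the entry itself) or
    ``"mortality"`` (the grid moves m with entry = 1 - m; only meaningful
    for probability-class entries).
    """

    species: str
    row: int
    col: int
    year_types: tuple[str, ...] | None = None
    parameterization: str = "rate"

    def __post_init__(self):
        if self.parameterization not in ("rate", "mortality"):
            raise StructuralError(
                f"parameterization must be 'rate' or 'mortality', got "
                f"{self.parameterization!r}"
            )
        if self.year_types is not None:
            object.__setattr__(self, "year_types", tuple(self.year_types))

    def label(self, community: CommunityModel | None = None) -> str:
        yt = ",".join(self.year_types) if self.year_types else "*"
        return f"{self.species}[{self.row},{self.col}]@{yt}:{self.parameterization}"

    def node(self, community: CommunityModel) -> str:
        """The species/stage node this rate belongs to (the column stage)."""
        sp = community.species_by_id(self.species)
        return f"{self.species}:{sp.stage_labels[self.col - 1]}"


def _address_info(community: CommunityModel, addr: VitalRateAddress):
    """Resolve an address: returns (species, year types, role, actual value)."""
    sp = community.species_by_id(addr.species)
    yts = addr.year_types or tuple(community.regime.year_types)
    for yt in yts:
        if yt not in sp.matrices:
            raise StructuralError(
                f"address {addr.label()}: species has no matrix for year type {yt!r}"
            )
    m0 = sp.matrix_for(yts[0])
    m0._check_index(addr.row, addr.col)
    vals = {yt: sp.matrix_for(yt).entry(addr.row, addr.col) for yt in yts}
    if len(set(vals.values())) > 1:
        raise StructuralError(
            f"address {addr.label()}: entry differs across the designated year "
            f"types ({vals}); perturb year types separately"
        )
    roles = m0.roles if m0.roles is not None else default_roles(m0.n_stages)
    role = str(roles[addr.row - 1, addr.col - 1])
    return sp, yts, role, vals[yts[0]]


@dataclass
class PerturbationSpec:
    """Protocol for perturbing one vital rate.

    The grid defaults to the actual value +/- ``half_width`` in steps of
    ``step`` (0.01), clipped to [0, 1] for probability-class (G/P) entries
    and for mortality parameterizations, and always contains the actual
    value. Replicates are run in batches with an early-stopping rule: stop
    once the running means shift by less than ``convergence_rtol`` between
    batches, up to the ``replicates`` cap.
    """

    address: VitalRateAddress
    horizon: int = 200
    replicates: int = REPLICATE_CAP_DEFAULT
    grid: tuple[float, ...] | None = None
    step: float = GRID_STEP_DEFAULT
    half_width: float = GRID_HALF_WIDTH_DEFAULT
    response_window: float | int = 0.25
    batch_size: int = BATCH_SIZE_DEFAULT
    convergence_rtol: float = CONVERGENCE_RTOL_DEFAULT
    common_random_numbers: bool = True
    replicate_level_regression: bool = False
    terminal_value: bool = False  # respond with the final state, not a window mean

    def build_grid(self, community: CommunityModel) -> np.ndarray:
        _, _, role, actual = _address_info(community, self.address)
        if self.address.parameterization == "mortality":
            actual = 1.0 - actual
        if self.grid is not None:
            g = np.asarray(sorted(set(float(x) for x in self.grid)))
            if not np.any(np.isclose(g, actual, atol=1e-12)):
                g = np.sort(np.append(g, actual))
        else:
            k = int(round(self.half_width / self.step))
            g = actual + self.step * np.arange(-k, k + 1)
        bounded = role in ("G", "P") or self.address.parameterization == "mortality"
        if bounded:
            g = np.clip(g, 0.0, 1.0)
        g = np.clip(g, 0.0, None)
        g = np.unique(np.round(g, 12))
        if g.size == 0:
            raise StructuralError("empty perturbation grid")
        return g

    def window_length(self) -> int:
        if self.terminal_value:
            return 1
        if isinstance(self.response_window, int) and not isinstance(self.response_window, bool):
            w = self.response_window
        else:
            w = max(1, int(round(self.response_window * self.horizon)))
        return min(max(1, w), self.horizon)


def _perturbed_community(
    community: CommunityModel, addr: VitalRateAddress, value: float, strict: bool = False
) -> CommunityModel:
    """Clone the community with the addressed entry set to ``value``."""
    sp, yts, role, _ = _address_info(community, addr)
    entry = 1.0 - value if addr.parameterization == "mortality" else value
    if entry < 0:
        raise StructuralError(
            f"address {addr.label()}: perturbed entry {entry} is negative"
        )
    new_mats = dict(sp.matrices)
    for yt in yts:
        new_mats[yt] = sp.matrix_for(yt).with_entry(addr.row, addr.col, entry)
        if strict:
            new_mats[yt].validate_columns(strict=True)
    new_sp = replace(sp, matrices=new_mats)
    species = [new_sp if s.species_id == sp.species_id else s for s in community.species]
    return replace(community, species=species)


@dataclass
class MeasureTable:
    """Mean response abundance per (grid value, responding species/stage)."""

    address_label: str
    target_node: str
    grid: np.ndarray
    responders: list[str]  # '<species>:<stage>' labels
    means: np.ndarray  # (n_grid, n_responders) across-replicate means
    ses: np.ndarray  # same shape, standard errors of the means
    n_replicates: np.ndarray  # per grid value
    replicate_values: list[np.ndarray] | None = None  # (n_rep, n_responders) per grid value
    actual_value: float = math.nan

    def baseline_means(self) -> np.ndarray:
        """Means at the grid point closest to the actual value."""
        i = int(np.argmin(np.abs(self.grid - self.actual_value)))
        return self.means[i]


def _simulate_response(
    community: CommunityModel, spec: PerturbationSpec, seed: int, rep: int, grid_idx: int
) -> np.ndarray:
    if spec.common_random_numbers:
        rep_seed = int(rng_stream(seed, "rep", rep).integers(2**31))
    else:
        rep_seed = int(rng_stream(seed, "grid", grid_idx, "rep", rep).integers(2**31))
    traj = project_community(community, spec.horizon, seed=rep_seed)
    w = spec.window_length()
    vals = []
    for sid in traj.species_ids:
        arr = traj.states[sid][-w:]
        vals.extend(arr.mean(axis=0))
    return np.asarray(vals)


def perturb_and_measure(
    community: CommunityModel, spec: PerturbationSpec, seed: int = 0
) -> MeasureTable:
    """Simulate the community across the perturbation grid.

    For each grid value the targeted entry is overwritten (in the
    designated year types), replicated trajectories are run with seeded
    streams, each replicate's response is its abundance averaged over the
    final response window, and the across-replicate mean and standard error
    are recorded per responding species/stage.
    """
    grid = spec.build_grid(community)
    _, _, _, actual_entry = _address_info(community, spec.address)
    actual = (
        1.0 - actual_entry
        if spec.address.parameterization == "mortality"
        else actual_entry
    )
    responders = community.node_labels()
    n_resp = len(responders)
    means = np.empty((grid.size, n_resp))
    ses = np.empty((grid.size, n_resp))
    n_reps = np.zeros(grid.size, dtype=int)
    keep_reps = spec.replicate_level_regression
    rep_store: list[np.ndarray] = []

    for gi, gval in enumerate(grid):
        pert = _perturbed_community(community, spec.address, float(gval))
        batch = max(1, min(spec.batch_size, spec.replicates))
        rows: list[np.ndarray] = []
        prev_mean = None
        while len(rows) < spec.replicates:
            take = min(batch, spec.replicates - len(rows))
            for r in range(len(rows), len(rows) + take):
                rows.append(_simulate_response(pert, spec, seed, r, gi))
            cur_mean = np.mean(rows, axis=0)
            if prev_mean is not None:
                scale = np.maximum(np.abs(prev_mean), 1e-12)
                if np.max(np.abs(cur_mean - prev_mean) / scale) < spec.convergence_rtol:
                    break
            prev_mean = cur_mean
        arr = np.asarray(rows)
        means[gi] = arr.mean(axis=0)
        ses[gi] = (
            arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0])
            if arr.shape[0] > 1
            else np.zeros(n_resp)
        )
        n_reps[gi] = arr.shape[0]
        if keep_reps:
            rep_store.append(arr)

    return MeasureTable(
        address_label=spec.address.label(),
        target_node=spec.address.node(community),
        grid=grid,
        responders=responders,
        means=means,
        ses=ses,
        n_replicates=n_reps,
        replicate_values=rep_store if keep_reps else None,
        actual_value=float(actual),
    )


@dataclass
class SensitivityResult:
    """Cross-species sensitivity matrix: slopes, fits and retained edges."""

    targets: list[str]  # address labels, row index
    target_nodes: list[str]  # '<species>:<stage>' of the perturbed rate
    responders: list[str]  # column index
    slopes: np.ndarray  # (n_targets, n_responders)
    r_squared: np.ndarray
    p_values: np.ndarray
    slope_ses: np.ndarray
    retained: np.ndarray  # boolean
    baseline_means: np.ndarray  # (n_responders,) at the unperturbed value
    r2_threshold: float = R2_THRESHOLD_DEFAULT
    p_threshold: float = P_THRESHOLD_DEFAULT
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        shape = (len(self.targets), len(self.responders))
        for name in ("slopes", "r_squared", "p_values", "slope_ses", "retained"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != shape:
                raise StructuralError(f"{name} has shape {arr.shape}, expected {shape}")
            setattr(self, name, arr)

    def standardized_slopes(self) -> np.ndarray:
        """Slopes divided by baseline mean response (per-unit-rate relative change)."""
        base = np.where(self.baseline_means > 0, self.baseline_means, np.nan)
        return self.slopes / base[None, :]

    def to_dataframe(self) -> pd.DataFrame:
        recs = []
        for i, tgt in enumerate(self.targets):
            tnode = self.target_nodes[i]
            tsp, _, tstage = tnode.partition(":")
            for j, resp in enumerate(self.responders):
                rsp, _, rstage = resp.partition(":")
                recs.append(
                    (
                        tsp, tstage, tgt, rsp, rstage,
                        self.slopes[i, j], self.r_squared[i, j],
                        self.p_values[i, j], bool(self.retained[i, j]),
                    )
                )
        return pd.DataFrame(
            recs,
            columns=[
                "target_species", "target_stage", "target_rate",
                "responder_species", "responder_stage",
                "slope", "r2", "p", "retained",
            ],
        )

    def save(self, directory) -> None:
        os.makedirs(directory, exist_ok=True)
        self.to_dataframe().to_csv(os.path.join(directory, "sensitivity.csv"), index=False)
        meta = dict(self.metadata)
        meta.update(
            r2_threshold=self.r2_threshold,
            p_threshold=self.p_threshold,
            baseline_means=dict(zip(self.responders, map(float, self.baseline_means))),
            target_nodes=dict(zip(self.targets, self.target_nodes)),
        )
        with open(os.path.join(directory, "sensitivity_meta.json"), "w") as fh:
            json.dump(meta, fh, indent=2, default=str)


def _ols(x: np.ndarray, y: np.ndarray):
    """Slope, R^2, two-sided p and slope SE; degenerate inputs give a null fit."""
    if x.size < 3 or np.allclose(y, y[0]) or np.allclose(x, x[0]):
        return 0.0, 0.0, 1.0, 0.0
    res = stats.linregress(x, y)
    r2 = float(res.rvalue**2)
    return float(res.slope), r2, float(res.pvalue), float(res.stderr)


def fit_sensitivity(
    table: MeasureTable,
    r2_threshold: float = R2_THRESHOLD_DEFAULT,
    p_threshold: float = P_THRESHOLD_DEFAULT,
    replicate_level: bool = False,
) -> SensitivityResult:
    """OLS of response on grid value for every responder.

    By default the regression uses the across-replicate mean response at
    each grid value (one point per grid value); ``replicate_level=True``
    regresses every individual replicate response instead (requires the
    table to have been measured with ``replicate_level_regression=True``).
    Responders with zero variance get slope 0, R^2 0 and are never retained.
    """
    if table.grid.size < 3:
        raise StructuralError("sensitivity regression needs >= 3 grid values")
    n_resp = len(table.responders)
    slopes = np.zeros(n_resp)
    r2 = np.zeros(n_resp)
    p = np.ones(n_resp)
    se = np.zeros(n_resp)
    if replicate_level:
        if table.replicate_values is None:
            raise StructuralError(
                "table lacks replicate-level values; measure with "
                "replicate_level_regression=True"
            )
        x = np.concatenate(
            [np.full(a.shape[0], g) for g, a in zip(table.grid, table.replicate_values)]
        )
        Y = np.vstack(table.replicate_values)
        for j in range(n_resp):
            slopes[j], r2[j], p[j], se[j] = _ols(x, Y[:, j])
    else:
        for j in range(n_resp):
            slopes[j], r2[j], p[j], se[j] = _ols(table.grid, table.means[:, j])
    retained = (r2 > r2_threshold) & (p < p_threshold)
    return SensitivityResult(
        targets=[table.address_label],
        target_nodes=[table.target_node],
        responders=list(table.responders),
        slopes=slopes[None, :],
        r_squared=r2[None, :],
        p_values=p[None, :],
        slope_ses=se[None, :],
        retained=retained[None, :],
        baseline_means=table.baseline_means(),
        r2_threshold=r2_threshold,
        p_threshold=p_threshold,
        metadata={
            "grid": [float(g) for g in table.grid],
            "n_replicates": [int(n) for n in table.n_replicates],
        },
    )


def default_targets(
    community: CommunityModel,
    roles: tuple[str, ...] = ("P", "G"),
    year_types: tuple[str, ...] | None = None,
    parameterization: str = "mortality",
) -> list[VitalRateAddress]:
    """All survival-class (P/G-tagged) nonzero entries of every species.

    This is the conventional target set for interaction inference: perturb
    each stage's survival (as a mortality rate by default) and watch every
    other species/stage respond.
    """
    targets = []
    for sp in community.species:
        yts = year_types or tuple(community.regime.year_types)
        m0 = sp.matrix_for(yts[0])
        rmat = m0.roles if m0.roles is not None else default_roles(m0.n_stages)
        for r in range(m0.n_stages):
            for c in range(m0.n_stages):
                if rmat[r, c] in roles and any(
                    sp.matrix_for(yt).entries[r, c] > 0 for yt in yts
                ):
                    same = len({sp.matrix_for(yt).entries[r, c] for yt in yts}) == 1
                    for yt_group in ([yts] if same else [(yt,) for yt in yts]):
                        targets.append(
                            VitalRateAddress(
                                sp.species_id, r + 1, c + 1,
                                year_types=tuple(yt_group),
                                parameterization=parameterization,
                            )
                        )
    return targets


def cross_sensitivity(
    community: CommunityModel,
    targets: list[VitalRateAddress] | None = None,
    seed: int = 0,
    horizon: int = 200,
    replicates: int = REPLICATE_CAP_DEFAULT,
    r2_threshold: float = R2_THRESHOLD_DEFAULT,
    p_threshold: float = P_THRESHOLD_DEFAULT,
    checkpoint_dir: str | None = None,
    **spec_kwargs,
) -> SensitivityResult:
    """Run the full perturbation protocol over a set of target addresses.

    Loops :func:`perturb_and_measure` + :func:`fit_sensitivity` over all
    targets and stacks the rows into one cross-species sensitivity matrix.
    Deterministic under ``seed`` (each target gets its own substream). With
    ``checkpoint_dir`` set, per-target rows are cached as JSON and reused on
    resume — this is the expensive part of the whole pipeline.
    """
    if targets is None:
        targets = default_targets(community)
    if not targets:
        raise StructuralError("no target addresses to perturb")
    rows = []
    baseline = None
    for ti, addr in enumerate(targets):
        ck = None
        if checkpoint_dir is not None:
            os.makedirs(checkpoint_dir, exist_ok=True)
            safe = addr.label(community).replace("/", "_").replace("*", "all")
            ck = os.path.join(checkpoint_dir, f"target_{ti:04d}_{safe}.json")
            if os.path.exists(ck):
                with open(ck) as fh:
                    rows.append(json.load(fh))
                continue
        spec = PerturbationSpec(
            address=addr, horizon=horizon, replicates=replicates, **spec_kwargs
        )
        table = perturb_and_measure(
            community, spec, seed=int(rng_stream(seed, "target", ti).integers(2**31))
        )
        fit = fit_sensitivity(table, r2_threshold, p_threshold)
        row = {
            "target": fit.targets[0],
            "target_node": fit.target_nodes[0],
            "responders": fit.responders,
            "slopes": fit.slopes[0].tolist(),
            "r_squared": fit.r_squared[0].tolist(),
            "p_values": fit.p_values[0].tolist(),
            "slope_ses": fit.slope_ses[0].tolist(),
            "retained": fit.retained[0].astype(bool).tolist(),
            "baseline_means": fit.baseline_means.tolist(),
        }
        if ck is not None:
            with open(ck, "w") as fh:
                json.dump(row, fh)
        rows.append(row)
        if baseline is None:
            baseline = np.asarray(row["baseline_means"])

    responders = rows[0]["responders"]
    for row in rows:
        if row["responders"] != responders:
            raise StructuralError("checkpoint rows disagree on responder set")
    return SensitivityResult(
        targets=[r["target"] for r in rows],
        target_nodes=[r["target_node"] for r in rows],
        responders=responders,
        slopes=np.array([r["slopes"] for r in rows]),
        r_squared=np.array([r["r_squared"] for r in rows]),
        p_values=np.array([r["p_values"] for r in rows]),
        slope_ses=np.array([r["slope_ses"] for r in rows]),
        retained=np.array([r["retained"] for r in rows], dtype=bool),
        baseline_means=np.asarray(rows[0]["baseline_means"], dtype=float),
        r2_threshold=r2_threshold,
        p_threshold=p_threshold,
        metadata={
            "seed": seed,
            "horizon": horizon,
            "replicates": replicates,
            "n_targets": len(rows),
        },
    )
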
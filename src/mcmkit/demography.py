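"""Single-species stage-structured demography.

The building block of a matrix community model is the ordinary matrix
population model

    n(t+1) = A(t) n(t)

where ``n`` is a vector of stage (or age) abundances and ``A(t)`` is drawn
from a family of transition matrices, one per environmental year type.
Matrix entries are vital rates and carry an optional role tag:

* ``F`` — fecundity (recruitment into a stage; unbounded above),
* ``G`` — growth, i.e. transition to another stage (a probability),
* ``P`` — stasis, i.e. survival within a stage (a probability),
* ``O`` — other / untagged.

Stage indexing is 1-based in every user-facing label, file and address
(matching the conventional F3, G1, P3 notation) and 0-based internally.

This module provides projection, asymptotic analysis (dominant eigenvalue
and stable stage distribution) and simulation-based estimation of the
stochastic growth rate log lambda_s for an uncoupled species.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .environment import Regime, generate_sequence, rng_stream

__all__ = [
    "StageMatrix",
    "StageVector",
    "SpeciesModel",
    "StructuralError",
    "project_step",
    "asymptotic_growth_rate",
    "stochastic_growth_rate",
    "GrowthRate",
    "StochasticGrowthRate",
    "default_roles",
]

ROLE_CODES = ("F", "G", "P", "O")


class StructuralError(ValueError):
    """Raised when matrices, vectors or species definitions do not fit together."""


def default_roles(n_stages: int) -> np.ndarray:
    """Conventional role layout for a Leslie/Lefkovitch matrix.

    Diagonal entries are stasis (P), the subdiagonal is growth (G), the
    remainder of the first row is fecundity (F), everything else is O.
    """
    roles = np.full((n_stages, n_stages), "O", dtype="<U1")
    for i in range(n_stages):
        roles[i, i] = "P"
        if i + 1 < n_stages:
            roles[i + 1, i] = "G"
    roles[0, 1:] = "F"
    roles[0, 0] = "P"
    return roles


@dataclass
class StageMatrix:
    """One species' transition matrix for one environmental year type."""

    entries: np.ndarray
    stage_labels: tuple[str, ...]
    roles: np.ndarray | None = None

    def __post_init__(self):
        self.entries = np.asarray(self.entries, dtype=float)
        self.stage_labels = tuple(str(s) for s in self.stage_labels)
        n = len(self.stage_labels)
        if self.entries.shape != (n, n):
            raise StructuralError(
                f"matrix shape {self.entries.shape} does not match "
                f"{n} stage labels {self.stage_labels}"
            )
        if (self.entries < 0).any():
            raise StructuralError("matrix entries must be nonnegative")
        if not np.isfinite(self.entries).all():
            raise StructuralError("matrix entries must be finite")
        if self.roles is not None:
            self.roles = np.asarray(self.roles, dtype="<U1")
            if self.roles.shape != (n, n):
                raise StructuralError("roles array must match matrix shape")
            bad = set(self.roles.ravel()) - set(ROLE_CODES)
            if bad:
                raise StructuralError(f"unknown role codes: {sorted(bad)}")

    @property
    def n_stages(self) -> int:
        return len(self.stage_labels)

    def validate_columns(self, strict: bool = False) -> None:
        """Check that survival/transition mass per column does not exceed 1.

        Entries tagged G or P in any one column are interpreted as the fates
        of a single individual, so their sum should be a probability. This
        is a warning by default because biomass- or area-based models can
        legitimately exceed 1; ``strict=True`` turns it into an error.
        """
        if self.roles is None:
            return
        surv = np.where(np.isin(self.roles, ("G", "P")), self.entries, 0.0)
        sums = surv.sum(axis=0)
        bad = np.nonzero(sums > 1.0 + 1e-9)[0]
        if bad.size:
            msg = (
                "column survival mass exceeds 1 for stage(s) "
                f"{[self.stage_labels[i] for i in bad]} (sums {sums[bad].round(6)})"
            )
            if strict:
                raise StructuralError(msg)
            warnings.warn(msg, stacklevel=2)

    def fecundity_mask(self) -> np.ndarray:
        """Boolean mask of F-tagged entries (default roles if untagged)."""
        roles = self.roles if self.roles is not None else default_roles(self.n_stages)
        return roles == "F"

    def with_entry(self, row: int, col: int, value: float) -> "StageMatrix":
        """Copy with entry (1-based row/col) replaced."""
        self._check_index(row, col)
        e = self.entries.copy()
        e[row - 1, col - 1] = value
        return StageMatrix(e, self.stage_labels, None if self.roles is None else self.roles.copy())

    def entry(self, row: int, col: int) -> float:
        """Entry at 1-based (row, col)."""
        self._check_index(row, col)
        return float(self.entries[row - 1, col - 1])

    def _check_index(self, row: int, col: int) -> None:
        n = self.n_stages
        if not (1 <= row <= n and 1 <= col <= n):
            raise StructuralError(
                f"entry address ({row},{col}) out of range for {n}-stage matrix "
                "(addresses are 1-based)"
            )

    # -- CSV round trip -----------------------------------------------------------
    # Format: header row of stage labels; each data row starts with its stage
    # label. Roles, when present, live in a sidecar "<stem>.roles.csv" of the
    # same shape holding single-letter codes.

    def to_csv(self, path) -> None:
        path = str(path)
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["stage", *self.stage_labels])
            for lab, row in zip(self.stage_labels, self.entries):
                w.writerow([lab, *(repr(float(x)) for x in row)])
        if self.roles is not None:
            with open(_roles_path(path), "w", newline="") as fh:
                w = csv.writer(fh)
                w.writerow(["stage", *self.stage_labels])
                for lab, row in zip(self.stage_labels, self.roles):
                    w.writerow([lab, *row])

    @classmethod
    def from_csv(cls, path) -> "StageMatrix":
        import os

        path = str(path)
        labels, rows = _read_labelled_csv(path)
        entries = np.array([[float(x) for x in r] for r in rows])
        roles = None
        rp = _roles_path(path)
        if os.path.exists(rp):
            rlabels, rrows = _read_labelled_csv(rp)
            if tuple(rlabels) != tuple(labels):
                raise StructuralError(f"roles sidecar {rp} labels do not match {path}")
            roles = np.array(rrows, dtype="<U1")
        return cls(entries, tuple(labels), roles)


def _roles_path(path: str) -> str:
    stem = path[:-4] if path.endswith(".csv") else path
    return stem + ".roles.csv"


def _read_labelled_csv(path: str):
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        labels = header[1:]
        rows = []
        for rec in reader:
            if not rec:
                continue
            if len(rec) != len(labels) + 1:
                raise StructuralError(f"malformed row in {path}: {rec!r}")
            rows.append(rec[1:])
    if len(rows) != len(labels):
        raise StructuralError(f"{path}: expected {len(labels)} rows, found {len(rows)}")
    return labels, rows


@dataclass
class StageVector:
    """Stage abundances of one species at one time."""

    abundances: np.ndarray
    time_index: int = 0

    def __post_init__(self):
        self.abundances = np.asarray(self.abundances, dtype=float)
        if self.abundances.ndim != 1:
            raise StructuralError("abundances must be a 1-D vector")
        if (self.abundances < 0).any():
            raise StructuralError("abundances must be nonnegative")

    @property
    def total(self) -> float:
        return float(self.abundances.sum())


@dataclass
class SpeciesModel:
    """A species (or guild): one stage structure, one matrix per year type.

    ``resource_weights`` give the amount of the shared resource (space,
    biomass, ...) one individual of each stage consumes; they define the
    species' contribution to the community's aggregate load.
    ``recruitment_years``, when set, restricts rescue-effect recruitment to
    the listed year types (e.g. seedling establishment only in flood years).
    """

    species_id: str
    matrices: dict[str, StageMatrix]
    resource_weights: np.ndarray
    abundance_unit: str = "individuals"
    recruitment_years: frozenset[str] | None = None

    def __post_init__(self):
        if not self.matrices:
            raise StructuralError(f"species {self.species_id!r} has no matrices")
        labels = None
        for yt, m in self.matrices.items():
            if labels is None:
                labels = m.stage_labels
            elif m.stage_labels != labels:
                raise StructuralError(
                    f"species {self.species_id!r}: matrix for year type {yt!r} has "
                    f"stage labels {m.stage_labels}, expected {labels}"
                )
        self.resource_weights = np.asarray(self.resource_weights, dtype=float)
        if self.resource_weights.shape != (len(labels),):
            raise StructuralError(
                f"species {self.species_id!r}: {len(self.resource_weights)} resource "
                f"weights for {len(labels)} stages"
            )
        if (self.resource_weights < 0).any():
            raise StructuralError("resource weights must be nonnegative")
        if self.recruitment_years is not None:
            self.recruitment_years = frozenset(self.recruitment_years)

    @property
    def stage_labels(self) -> tuple[str, ...]:
        return next(iter(self.matrices.values())).stage_labels

    @property
    def n_stages(self) -> int:
        return len(self.stage_labels)

    @property
    def year_types(self) -> set[str]:
        return set(self.matrices)

    def matrix_for(self, year_type: str) -> StageMatrix:
        try:
            return self.matrices[year_type]
        except KeyError:
            raise StructuralError(
                f"species {self.species_id!r} has no matrix for year type {year_type!r}"
            ) from None


# ---------------------------------------------------------------------------
# Projection and growth rates
# ---------------------------------------------------------------------------


def project_step(matrix: StageMatrix, state: StageVector) -> StageVector:
    """One deterministic projection step: n(t+1) = A n(t)."""
    if state.abundances.shape[0] != matrix.n_stages:
        raise StructuralError(
            f"state has {state.abundances.shape[0]} stages but matrix has "
            f"{matrix.n_stages} ({matrix.stage_labels})"
        )
    return StageVector(matrix.entries @ state.abundances, state.time_index + 1)


class GrowthRate(NamedTuple):
    lam: float
    stable_distribution: np.ndarray


def asymptotic_growth_rate(matrix: StageMatrix) -> GrowthRate:
    """Dominant eigenvalue (lambda) and stable stage distribution.

    For an irreducible primitive matrix the pair is unique; for reducible or
    degenerate matrices the spectral radius and some valid nonnegative
    eigenvector are returned with a warning.
    """
    A = matrix.entries
    vals, vecs = np.linalg.eig(A)
    radius = np.abs(vals).max()
    # prefer the real eigenvalue achieving the spectral radius
    real_on_circle = [
        i for i in range(len(vals))
        if np.isclose(np.abs(vals[i]), radius, rtol=1e-12, atol=1e-12)
        and abs(vals[i].imag) <= 1e-9 * max(radius, 1.0)
    ]
    if not real_on_circle:
        warnings.warn(
            "no real eigenvalue attains the spectral radius (matrix may be "
            "periodic); returning spectral radius with a heuristic eigenvector",
            stacklevel=2,
        )
        i = int(np.argmax(np.abs(vals)))
    else:
        i = real_on_circle[0]
        ties = np.isclose(np.abs(vals), radius, rtol=1e-9, atol=1e-12).sum()
        if ties > 1:
            warnings.warn(
                "dominant eigenvalue is not unique (reducible or periodic matrix); "
                "returned stable distribution is one valid choice",
                stacklevel=2,
            )
    v = np.real(vecs[:, i])
    if v.sum() < 0:
        v = -v
    v = np.clip(v, 0.0, None)
    s = v.sum()
    v = v / s if s > 0 else np.full(A.shape[0], 1.0 / A.shape[0])
    return GrowthRate(float(radius), v)


class StochasticGrowthRate(NamedTuple):
    estimate: float
    se: float
    per_replicate: np.ndarray
    n_extinct_paths: int


def stochastic_growth_rate(
    species: SpeciesModel,
    regime: Regime,
    horizon: int,
    replicates: int,
    seed: int,
    burn_in: int | None = None,
    initial: np.ndarray | None = None,
) -> StochasticGrowthRate:
    """Estimate log lambda_s for an uncoupled species by simulation.

    Each replicate draws an independent year-type sequence, projects the
    species (with per-step renormalisation, so only log growth accumulates
    and no overflow can occur), discards a burn-in prefix (default 10% of
    the horizon) and returns the average one-step log growth of total
    abundance over the remaining window. Paths whose total abundance hits
    exact zero contribute -inf; they are excluded from the mean and counted
    in ``n_extinct_paths``.
    """
    if horizon < 100:
        raise ValueError("horizon must be >= 100 for a stable estimate")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if burn_in is None:
        burn_in = horizon // 10
    if not 0 <= burn_in < horizon:
        raise ValueError("burn_in must lie in [0, horizon)")

    n = species.n_stages
    if initial is None:
        initial = np.full(n, 1.0)
    mats = {yt: species.matrix_for(yt).entries for yt in regime.year_types}

    logs = np.empty(replicates)
    n_extinct = 0
    for r in range(replicates):
        rng = rng_stream(seed, "sgr", r)
        seq = generate_sequence(regime, horizon, rng)
        v = np.asarray(initial, dtype=float).copy()
        acc = 0.0
        dead = False
        for t, yt in enumerate(seq):
            v = mats[yt] @ v
            tot = v.sum()
            if tot <= 0.0:
                dead = True
                break
            if t >= burn_in:
                acc += np.log(tot)
            v /= tot  # renormalise; growth is captured in acc
        if dead:
            logs[r] = -np.inf
            n_extinct += 1
        else:
            logs[r] = acc / (horizon - burn_in)

    finite = logs[np.isfinite(logs)]
    if finite.size == 0:
        return StochasticGrowthRate(-np.inf, np.nan, logs, n_extinct)
    est = float(finite.mean())
    se = float(finite.std(ddof=1) / np.sqrt(finite.size)) if finite.size > 1 else np.nan
    return StochasticGrowthRate(est, se, logs, n_extinct)
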
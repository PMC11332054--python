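"""Environmental regimes: year-type sequence generators.

A community model selects which transition matrix applies at each timestep
from a discrete environmental state ("year type", e.g. flood / drought /
normal). Three regime modes are supported:

``iid``
    year types drawn independently with fixed frequencies,
``markov``
    year types follow a first-order Markov chain (environmental
    autocorrelation),
``fixed``
    an explicit, user-supplied sequence (e.g. a historical record).

All randomness flows through named substreams spawned from a single root
seed (:func:`rng_stream`), so any replicate of any analysis can be replayed
exactly while remaining statistically independent of every other replicate.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Regime",
    "generate_sequence",
    "stationary_distribution",
    "rng_stream",
    "RegimeError",
]

_PROB_ATOL = 1e-9


class RegimeError(ValueError):
    """Raised for structurally invalid regimes or sequence requests."""


def _tag_to_int(tag) -> int:
    """Map a stream tag (int or str) to a stable 32-bit integer."""
    if isinstance(tag, (int, np.integer)):
        return int(tag) & 0xFFFFFFFF
    return zlib.crc32(str(tag).encode("utf-8"))


def rng_stream(root_seed: int, *tags) -> np.random.Generator:
    """Return a named, independent random generator.

    Streams with different ``tags`` are statistically independent; the same
    ``(root_seed, *tags)`` always yields the identical stream, across runs
    and platforms. Tags may be integers or strings (strings are hashed with
    CRC-32, which is stable across platforms and Python versions).
    """
    key = tuple(_tag_to_int(t) for t in tags)
    return np.random.default_rng(np.random.SeedSequence(int(root_seed), spawn_key=key))


@dataclass(frozen=True)
class Regime:
    """A generator specification for year-type sequences.

    Parameters
    ----------
    year_types
        Ordered labels of the environmental states.
    mode
        One of ``"iid"``, ``"markov"``, ``"fixed"``.
    frequencies
        Probability of each year type (iid mode).
    transition_probs
        Row-stochastic matrix over ``year_types`` (markov mode);
        ``transition_probs[i, j]`` is P(next = j | current = i).
    sequence
        Explicit list of labels (fixed mode).
    initial_distribution
        Distribution of the first state in markov mode. Defaults to the
        stationary distribution of the chain.
    cycle
        In fixed mode, allow the sequence to repeat when a longer sequence
        is requested.
    """

    year_types: tuple[str, ...]
    mode: str
    frequencies: tuple[float, ...] | None = None
    transition_probs: tuple[tuple[float, ...], ...] | None = None
    sequence: tuple[str, ...] | None = None
    initial_distribution: tuple[float, ...] | None = None
    cycle: bool = False

    def __post_init__(self):
        object.__setattr__(self, "year_types", tuple(self.year_types))
        k = len(self.year_types)
        if k == 0:
            raise RegimeError("regime needs at least one year type")
        if len(set(self.year_types)) != k:
            raise RegimeError("year-type labels must be unique")
        if self.mode == "iid":
            if self.frequencies is None:
                raise RegimeError("iid regime requires frequencies")
            f = np.asarray(self.frequencies, dtype=float)
            if f.shape != (k,) or (f < 0).any() or abs(f.sum() - 1.0) > _PROB_ATOL:
                raise RegimeError(
                    "iid frequencies must be nonnegative, one per year type, "
                    f"and sum to 1 (got {self.frequencies!r})"
                )
            object.__setattr__(self, "frequencies", tuple(float(x) for x in f))
        elif self.mode == "markov":
            if self.transition_probs is None:
                raise RegimeError("markov regime requires transition_probs")
            P = np.asarray(self.transition_probs, dtype=float)
            if P.shape != (k, k) or (P < 0).any():
                raise RegimeError(
                    f"transition_probs must be a nonnegative {k}x{k} matrix"
                )
            if not np.allclose(P.sum(axis=1), 1.0, atol=_PROB_ATOL):
                raise RegimeError("each transition_probs row must sum to 1")
            object.__setattr__(
                self, "transition_probs", tuple(tuple(float(x) for x in row) for row in P)
            )
            if self.initial_distribution is not None:
                pi0 = np.asarray(self.initial_distribution, dtype=float)
                if pi0.shape != (k,) or (pi0 < 0).any() or abs(pi0.sum() - 1.0) > _PROB_ATOL:
                    raise RegimeError("initial_distribution must be a probability vector")
                object.__setattr__(
                    self, "initial_distribution", tuple(float(x) for x in pi0)
                )
        elif self.mode == "fixed":
            if self.sequence is None:
                raise RegimeError("fixed regime requires a sequence")
            seq = tuple(self.sequence)
            unknown = set(seq) - set(self.year_types)
            if unknown:
                raise RegimeError(f"sequence contains unknown year types: {sorted(unknown)}")
            object.__setattr__(self, "sequence", seq)
        else:
            raise RegimeError(f"unknown regime mode {self.mode!r}")

    # -- convenience constructors -------------------------------------------------

    @classmethod
    def iid(cls, year_types, frequencies) -> "Regime":
        return cls(tuple(year_types), "iid", frequencies=tuple(frequencies))

    @classmethod
    def markov(cls, year_types, transition_probs, initial_distribution=None) -> "Regime":
        P = tuple(tuple(row) for row in transition_probs)
        init = tuple(initial_distribution) if initial_distribution is not None else None
        return cls(tuple(year_types), "markov", transition_probs=P,
                   initial_distribution=init)

    @classmethod
    def fixed(cls, sequence, year_types=None, cycle: bool = False) -> "Regime":
        seq = tuple(sequence)
        if year_types is None:
            year_types = tuple(dict.fromkeys(seq))  # order of first appearance
        return cls(tuple(year_types), "fixed", sequence=seq, cycle=cycle)

    @classmethod
    def constant(cls, year_type: str) -> "Regime":
        """Degenerate regime: a single year type forever."""
        return cls((year_type,), "iid", frequencies=(1.0,))


def stationary_distribution(transition_probs) -> np.ndarray:
    """Stationary distribution pi of a row-stochastic matrix (pi P = pi).

    For periodic or reducible chains a valid stationary vector is still
    returned (with a warning), but it need not be unique.
    """
    import warnings

    P = np.asarray(transition_probs, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise RegimeError("transition matrix must be square")
    if (P < 0).any() or not np.allclose(P.sum(axis=1), 1.0, atol=1e-8):
        raise RegimeError("transition matrix must be row-stochastic")
    vals, vecs = np.linalg.eig(P.T)
    idx = np.argmin(np.abs(vals - 1.0))
    pi = np.real(vecs[:, idx])
    pi = np.abs(pi)
    pi = pi / pi.sum()
    # uniqueness check: multiplicity of eigenvalue 1
    close = np.isclose(np.abs(vals), 1.0, atol=1e-8)
    if close.sum() > 1:
        warnings.warn(
            "chain is periodic or reducible; stationary distribution may not be unique",
            stacklevel=2,
        )
    return pi


def generate_sequence(regime: Regime, length: int, seed: int | np.random.Generator) -> list[str]:
    """Draw a year-type sequence of the given length.

    ``seed`` may be an integer (a fresh stream is derived from it) or an
    existing :class:`numpy.random.Generator` (useful when the caller manages
    substreams itself). Fixed-mode regimes ignore the seed.
    """
    if length < 1:
        raise RegimeError("sequence length must be >= 1")
    labels = regime.year_types
    if regime.mode == "fixed":
        seq = regime.sequence
        if len(seq) < length:
            if not regime.cycle:
                raise RegimeError(
                    f"fixed sequence has length {len(seq)} < requested {length} "
                    "and cycling is not enabled"
                )
            reps = -(-length // len(seq))
            seq = seq * reps
        return list(seq[:length])

    rng = seed if isinstance(seed, np.random.Generator) else rng_stream(seed, "regime")
    k = len(labels)
    if regime.mode == "iid":
        idx = rng.choice(k, size=length, p=np.asarray(regime.frequencies))
        return [labels[i] for i in idx]

    # markov
    P = np.asarray(regime.transition_probs)
    if regime.initial_distribution is not None:
        pi0 = np.asarray(regime.initial_distribution)
    else:
        pi0 = stationary_distribution(P)
    out = np.empty(length, dtype=int)
    out[0] = rng.choice(k, p=pi0)
    # draw all uniforms at once; invert the per-row CDFs step by step
    cdf = np.cumsum(P, axis=1)
    u = rng.random(length)
    for t in range(1, length):
        out[t] = np.searchsorted(cdf[out[t - 1]], u[t], side="right")
    return [labels[i] for i in out]
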
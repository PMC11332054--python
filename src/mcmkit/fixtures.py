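"""Programmatic generator communities.

Every analysis stage in this package can be exercised without external
data: the generators below build small, fully synthetic communities whose
qualitative behaviour is known by construction. All vital-rate values are
synthetic — chosen for clear life-history contrasts, not taken from any
field study — and every generator is a pure function of its parameters and
seed (same inputs, identical community).

* :func:`two_species_toy` — two single-stage species competing for open
  space with rescue-effect recruitment; single-species equilibria have a
  closed form, which makes it the workhorse validation fixture.
* :func:`riparian_like` — five plant guilds x six stages under a
  flood/drought/normal regime with space-limited, rescue-effect
  recruitment and guild-specific flood/drought survival trade-offs.
* :func:`fish_like` — n age-structured species whose egg survival is
  regulated by total biomass and whose fecundity is proportional to adult
  abundance (no rescue effect), with distinct year-type-specific survival
  so single-species stochastic growth rates differ.
"""

from __future__ import annotations

import numpy as np

from .community import CommunityModel, DependencyAssumption
from .demography import SpeciesModel, StageMatrix, default_roles
from .environment import Regime, rng_stream

__all__ = ["two_species_toy", "riparian_like", "fish_like"]


def _scalar_matrix(survival: float) -> StageMatrix:
    return StageMatrix(
        np.array([[survival]]), ("adult",), np.array([["P"]], dtype="<U1")
    )


def two_species_toy(
    asymmetry: float = 0.5,
    seed: int = 0,
    K: float = 100.0,
    base_survival: float = 0.5,
    survival_gap: float = 0.3,
    good_frequency: float = 0.5,
    extinction_threshold: float = 0.0,
) -> CommunityModel:
    """Two single-stage species competing for open space.

    Both species survive at a constant per-year rate (A at
    ``base_survival + asymmetry * survival_gap``, B at ``base_survival``)
    and recruit by a rescue effect: in a "good" year any surviving
    population claims all open space ``K - N``, split proportionally when
    contested. "bad" years bring no recruitment. At ``asymmetry = 0`` the
    species are exchangeable; at ``asymmetry > 0`` species A is the
    competitive dominant.

    In a constant all-good environment a single species equilibrates in
    closed form at ``n* = K / (2 - s)`` (each year: ``n' = s n + (K - n)``),
    which anchors the validation tests.
    """
    if not 0.0 <= asymmetry <= 1.0:
        raise ValueError("asymmetry must lie in [0, 1]")
    s_a = base_survival + asymmetry * survival_gap
    s_b = base_survival
    if not (0 <= s_b <= s_a <= 1):
        raise ValueError("survival rates must stay within [0, 1]")
    year_types = ("good", "bad")
    regime = Regime.iid(year_types, (good_frequency, 1.0 - good_frequency))

    def make(species_id: str, s: float) -> SpeciesModel:
        return SpeciesModel(
            species_id=species_id,
            matrices={yt: _scalar_matrix(s) for yt in year_types},
            resource_weights=np.array([1.0]),
            recruitment_years=frozenset({"good"}),
        )

    dep = DependencyAssumption(
        mode="space_limited_recruitment",
        K=K,
        scaling_form="linear",
        rescue_effect=True,
        allocation_rule="proportional",
    )
    return CommunityModel(
        species=[make("A", s_a), make("B", s_b)],
        regime=regime,
        dependency=dep,
        extinction_threshold=extinction_threshold,
    )


# ---------------------------------------------------------------------------
# Riparian-style guild community
# ---------------------------------------------------------------------------

#: (guild id, flood survival multiplier, drought survival multiplier,
#:  recruitment year types)
_RIPARIAN_GUILDS = (
    ("hydro_tree", 1.00, 0.55, ("flood",)),
    ("xeric_shrub", 0.45, 1.00, ("drought", "normal")),
    ("hydro_shrub", 0.95, 0.65, ("flood",)),
    ("mesic_meadow", 0.80, 0.70, ("flood", "normal")),
    ("desert_shrub", 0.40, 1.00, ("drought",)),
)

#: space (resource units) occupied per individual of each stage; each stage
#: at most doubles its footprint, which together with the survival caps in
#: the generator guarantees that survivors never expand their total load.
_RIPARIAN_WEIGHTS = np.array([0.05, 0.1, 0.2, 0.4, 0.8, 1.6])


def riparian_like(seed: int = 0, K: float = 200.0) -> CommunityModel:
    """Five plant guilds x six stages, flood/drought/normal regime.

    Recruitment is space-limited with a rescue effect (a single favorable
    year can reseed all open space regardless of adult abundance); guilds
    trade off flood versus drought survival and differ in which year types
    allow establishment. Stage footprints double per stage, and per-column
    survival is capped so that the space held by survivors can never grow —
    together with the recruitment ceiling this keeps aggregate load <= K
    at every census.
    """
    year_types = ("flood", "drought", "normal")
    regime = Regime.iid(year_types, (0.2, 0.3, 0.5))
    rng = rng_stream(seed, "riparian")
    n = 6
    stage_labels = tuple(f"s{i}" for i in range(1, n + 1))
    roles = default_roles(n)
    # stage-increasing stasis, moderate growth; columns obey P + 2 G <= 1
    base_P = np.array([0.05, 0.15, 0.25, 0.35, 0.45, 0.60])
    base_G = np.array([0.25, 0.22, 0.20, 0.18, 0.15, 0.0])
    base_F = np.array([0.0, 0.0, 0.0, 5.0, 10.0, 20.0])

    species = []
    for gid, flood_m, drought_m, rec_years in _RIPARIAN_GUILDS:
        jitter = 1.0 + 0.05 * (rng.random(3) - 0.5)  # per-guild rate jitter
        mats = {}
        for yt in year_types:
            m = {"flood": flood_m, "drought": drought_m, "normal": 0.9}[yt]
            P = np.clip(base_P * m * jitter[0], 0.0, 0.95)
            G = np.clip(base_G * m * jitter[1], 0.0, 0.45)
            # survivors must not expand their footprint: P + (w+/w) G <= 1
            ratio = np.ones(n)
            ratio[:-1] = _RIPARIAN_WEIGHTS[1:] / _RIPARIAN_WEIGHTS[:-1]
            excess = P + ratio * G
            scale = np.where(excess > 0.98, 0.98 / excess, 1.0)
            P, G = P * scale, G * scale
            F = base_F * jitter[2] if yt in rec_years else np.zeros(n)
            A = np.zeros((n, n))
            np.fill_diagonal(A, P)
            for i in range(n - 1):
                A[i + 1, i] = G[i]
            A[0] = np.where(roles[0] == "F", F, A[0])
            A[0, 0] = P[0]
            mats[yt] = StageMatrix(A, stage_labels, roles.copy())
        species.append(
            SpeciesModel(
                species_id=gid,
                matrices=mats,
                resource_weights=_RIPARIAN_WEIGHTS.copy(),
                abundance_unit="individuals",
                recruitment_years=frozenset(rec_years),
            )
        )
    dep = DependencyAssumption(
        mode="space_limited_recruitment",
        K=K,
        scaling_form="linear",
        rescue_effect=True,
        allocation_rule="proportional",
    )
    return CommunityModel(species=species, regime=regime, dependency=dep)


# ---------------------------------------------------------------------------
# Fish-style age-structured community
# ---------------------------------------------------------------------------


def fish_like(
    n_species: int = 7,
    seed: int = 0,
    K: float = 300.0,
    quality_spread: float = 0.12,
    extinction_threshold: float = 1.0,
) -> CommunityModel:
    """n age-structured species under biomass-limited early survivorship.

    Each species has four age classes; eggs are produced in proportion to
    the two adult ages (no rescue effect), and their survival to age 1 is
    regulated by the linear multiplier ``max(0, 1 - B/K)`` on total
    community biomass B. Species differ in two synthetic traits: a
    flood-vs-drought affinity (position along the species index) and an
    overall demographic quality that rises with the index by
    ``quality_spread``, so single-species stochastic growth rates are
    distinct and ordered — the last species has the highest log lambda_s.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    year_types = ("flood", "drought", "average")
    regime = Regime.iid(year_types, (0.25, 0.25, 0.5))
    rng = rng_stream(seed, "fish")
    n = 4
    stage_labels = ("age1", "age2", "age3", "age4")
    roles = default_roles(n)
    base_G = np.array([0.35, 0.50, 0.60, 0.0])
    base_P4 = 0.40
    base_F = np.array([0.0, 0.0, 8.0, 16.0])
    weights = np.array([0.01, 0.05, 0.2, 0.5])  # biomass per individual

    species = []
    for i in range(n_species):
        x = i / (n_species - 1)  # 0 = flood specialist, 1 = drought specialist
        quality = 1.0 + quality_spread * (x - 0.5)
        jitter = 1.0 + 0.02 * (rng.random(1)[0] - 0.5)
        mats = {}
        for yt in year_types:
            if yt == "flood":
                m = 1.0 + 0.25 * (0.5 - x)
            elif yt == "drought":
                m = 1.0 + 0.25 * (x - 0.5)
            else:
                m = 1.0
            m *= quality * jitter
            G = np.clip(base_G * m, 0.0, 0.95)
            P4 = min(base_P4 * m, 0.95)
            A = np.zeros((n, n))
            for k in range(n - 1):
                A[k + 1, k] = G[k]
            A[n - 1, n - 1] = P4
            A[0] = base_F
            mats[yt] = StageMatrix(A, stage_labels, roles.copy())
        species.append(
            SpeciesModel(
                species_id=f"fish{i + 1}",
                matrices=mats,
                resource_weights=weights.copy(),
                abundance_unit="individuals",
            )
        )
    dep = DependencyAssumption(
        mode="biomass_limited_fecundity",
        K=K,
        scaling_form="linear",
        target_role="F",
    )
    return CommunityModel(
        species=species,
        regime=regime,
        dependency=dep,
        extinction_threshold=extinction_threshold,
    )
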
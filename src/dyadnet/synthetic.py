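"""Synthetic two-group dyad streams with controllable transition structure.

The generator emulates the data model the pipeline consumes: per dyad, two
parallel 1 Hz code streams produced by a first-order Markov process over
combined states with explicit per-state persistence.  Each second the dyad
stays in its current combined state with that state's persistence
probability, otherwise it jumps according to a row-stochastic between-state
matrix (zero diagonal) — the simplest process consistent with
one-code-per-second streams and geometric-looking dwell times.  Recording
lengths are drawn from a normal distribution (mean 415 s, SD 118 s,
truncated at >= 60 s, rounded to whole seconds) and the groups default to
the study sizes: 42 full-term and 30 preterm dyads.

Group differences are planted by adjusting one group's matrix so a chosen
edge's expected *transition rate* (share of all transitions) differs by a
stated number of percentage points, with the row's remaining mass
rebalanced proportionally; the adjustment solves a fixed point in the jump
chain's stationary distribution, so the planted difference is unbiased.

Two stock configurations ship: ``harmonious_config`` concentrates mass
around the harmonious play states (infant plays, mother follows/enriches),
qualitatively mimicking the frequent-transition structure of real free
play; ``uniform_config`` is a structureless control for null calibration.
Neither claims to reproduce any real group's rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .codebook import CombinedState
from .streams import GROUP_A, GROUP_B, BehavioralStream, Transition

__all__ = [
    "SyntheticConfig",
    "GroupDynamics",
    "PlantedDifference",
    "ConfigError",
    "generate_streams",
    "make_planted_config",
    "harmonious_config",
    "uniform_config",
    "expected_rates",
    "stationary_distribution",
]

DEFAULT_LENGTH_MEAN = 415.0  # seconds
DEFAULT_LENGTH_SD = 118.0
DEFAULT_LENGTH_MIN = 60
INFANT_OTHER = 8
MOTHER_OTHER = 10


class ConfigError(ValueError):
    """Invalid generator configuration (caught before any simulation)."""


@dataclass(frozen=True)
class GroupDynamics:
    """One group's Markov dynamics over the shared state list.

    ``transition_matrix`` is the between-state jump matrix (row-stochastic,
    zero diagonal); ``persistence[i]`` is the per-second probability of
    staying in state i, so dwell per visit is geometric with mean
    ``1/(1 - persistence[i])``.
    """

    n_dyads: int
    transition_matrix: np.ndarray
    initial_dist: np.ndarray
    persistence: np.ndarray


@dataclass(frozen=True)
class PlantedDifference:
    """A planted group difference on one edge's expected transition rate.

    ``offset_pp`` is the percentage-point amount by which group B's
    expected rate on the edge should exceed group A's (negative plants a
    deficit).
    """

    edge: Transition
    offset_pp: float


@dataclass(frozen=True)
class SyntheticConfig:
    """Full two-group generator configuration; validated on construction."""

    states: tuple[CombinedState, ...]
    group_a: GroupDynamics  # full_term
    group_b: GroupDynamics  # preterm
    length_mean: float = DEFAULT_LENGTH_MEAN
    length_sd: float = DEFAULT_LENGTH_SD
    length_min: int = DEFAULT_LENGTH_MIN
    other_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        n = len(self.states)
        if n < 2:
            raise ConfigError("need at least 2 states")
        if len(set(self.states)) != n:
            raise ConfigError("duplicate states")
        for label, dyn in (("group_a", self.group_a), ("group_b", self.group_b)):
            m = np.asarray(dyn.transition_matrix, dtype=float)
            if m.shape != (n, n):
                raise ConfigError(f"{label}: matrix shape {m.shape} != ({n},{n})")
            if np.any(m < 0):
                raise ConfigError(f"{label}: negative matrix entries")
            if np.any(np.abs(np.diag(m)) > 1e-12):
                raise ConfigError(f"{label}: self-transitions not allowed in jump matrix")
            if np.any(np.abs(m.sum(axis=1) - 1.0) > 1e-9):
                raise ConfigError(f"{label}: rows must sum to 1")
            init = np.asarray(dyn.initial_dist, dtype=float)
            if init.shape != (n,) or np.any(init < 0) or abs(init.sum() - 1.0) > 1e-9:
                raise ConfigError(f"{label}: invalid initial distribution")
            pers = np.asarray(dyn.persistence, dtype=float)
            if pers.shape != (n,) or np.any(pers < 0) or np.any(pers >= 1):
                raise ConfigError(f"{label}: persistence must be in [0, 1)")
            if dyn.n_dyads < 1:
                raise ConfigError(f"{label}: n_dyads must be >= 1")
        if not 0 <= self.other_rate < 1:
            raise ConfigError("other_rate must be in [0, 1)")
        if self.length_min < 1 or self.length_sd < 0:
            raise ConfigError("invalid length model")


# -- dynamics helpers ------------------------------------------------------


def stationary_distribution(matrix: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic jump matrix."""
    m = np.asarray(matrix, dtype=float)
    n = m.shape[0]
    a = np.vstack([m.T - np.eye(n), np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def expected_rates(matrix: np.ndarray) -> np.ndarray:
    """Expected transition-rate matrix (percent): share of all jumps per edge.

    The fraction of transitions leaving state u equals the jump chain's
    stationary mass at u (persistence stretches dwell, not jump order), so
    edge (u, v) has expected rate ``100 * pi[u] * M[u, v]``.
    """
    pi = stationary_distribution(matrix)
    return 100.0 * pi[:, None] * np.asarray(matrix, dtype=float)


# -- stock configurations --------------------------------------------------

# Harmonious-centric state list: harmonious play core plus the directing /
# neglecting / forcing periphery where disharmonious episodes live.
_HARMONIOUS_STATES: tuple[tuple[int, int], ...] = (
    (1, 11), (1, 12), (2, 11), (2, 12), (1, 15), (2, 15), (3, 15), (4, 15),
    (4, 11), (4, 12), (6, 15), (6, 18), (1, 18), (6, 13),
)
# Relative attractiveness of each state as a jump target: strongly peaked
# on harmonious play, decaying toward the disharmonious periphery.
_HARMONIOUS_WEIGHTS = (30.0, 15.0, 12.0, 4.0, 8.0, 6.0, 5.0, 4.0, 4.0, 3.0, 4.0, 2.0, 2.0, 2.0)

# Jumps changing both partners' codes at once are possible but much rarer
# than single-code changes (behavioral streams mostly move one partner at
# a time); this factor downweights double-change targets.
_DOUBLE_CHANGE_FACTOR = 0.01


def _weights_to_dynamics(
    weights: np.ndarray,
    n_dyads: int,
    persistence: np.ndarray,
    states: tuple[CombinedState, ...] | None = None,
    double_change_factor: float = 1.0,
) -> GroupDynamics:
    n = len(weights)
    m = np.tile(weights, (n, 1)).astype(float)
    if states is not None and double_change_factor != 1.0:
        for i, u in enumerate(states):
            for j, v in enumerate(states):
                if u.infant != v.infant and u.mother != v.mother:
                    m[i, j] *= double_change_factor
    np.fill_diagonal(m, 0.0)
    m /= m.sum(axis=1, keepdims=True)
    init = weights / weights.sum()
    return GroupDynamics(n_dyads, m, init, persistence)


def harmonious_config(
    n_full_term: int = 42,
    n_preterm: int = 30,
    seed: int = 0,
    other_rate: float = 0.0,
) -> SyntheticConfig:
    """Harmonious-centric dynamics, identical for both groups (null by default).

    Persistence is higher in the harmonious core (0.85) than in the
    periphery (0.70), giving mean dwells of ~6.7 s vs ~3.3 s per visit.
    """
    states = tuple(CombinedState(*s) for s in _HARMONIOUS_STATES)
    weights = np.array(_HARMONIOUS_WEIGHTS)
    persistence = np.where(weights >= 12.0, 0.85, 0.70)
    dyn_a = _weights_to_dynamics(weights, n_full_term, persistence, states,
                                 _DOUBLE_CHANGE_FACTOR)
    dyn_b = _weights_to_dynamics(weights, n_preterm, persistence, states,
                                 _DOUBLE_CHANGE_FACTOR)
    return SyntheticConfig(states=states, group_a=dyn_a, group_b=dyn_b, seed=seed,
                           other_rate=other_rate)


def uniform_config(
    n_full_term: int = 42,
    n_preterm: int = 30,
    n_states: int = 12,
    seed: int = 0,
    other_rate: float = 0.0,
) -> SyntheticConfig:
    """Structureless control: uniform off-diagonal jumps, persistence 0.75."""
    states = tuple(CombinedState(*s) for s in _HARMONIOUS_STATES[:n_states])
    weights = np.ones(len(states))
    persistence = np.full(len(states), 0.75)
    dyn_a = _weights_to_dynamics(weights, n_full_term, persistence)
    dyn_b = _weights_to_dynamics(weights, n_preterm, persistence)
    return SyntheticConfig(states=states, group_a=dyn_a, group_b=dyn_b, seed=seed,
                           other_rate=other_rate)


# -- planted differences ---------------------------------------------------


def make_planted_config(
    base: SyntheticConfig,
    plants: list[PlantedDifference],
    max_iter: int = 100,
    tol: float = 1e-12,
) -> SyntheticConfig:
    """Adjust group B's matrix so planted edges' expected rates shift by offset_pp.

    For each planted edge (u, v) the target expected rate is group A's rate
    plus ``offset_pp``; B's matrix entry is solved by fixed-point iteration
    on B's jump-chain stationary distribution (changing a row re-weights
    the stationary distribution, so a one-shot first-order adjustment would
    be biased).  The remaining mass in each touched row is rebalanced
    proportionally; rows stay stochastic.  Infeasible offsets (entry
    leaving (0, 1) or a row unable to absorb the rebalancing) raise
    :class:`ConfigError`.
    """
    if not plants:
        return base
    index = {s: i for i, s in enumerate(base.states)}
    for p in plants:
        if p.edge.source not in index or p.edge.target not in index:
            raise ConfigError(f"planted edge {p.edge} references unknown states")
        if p.edge.source == p.edge.target:
            raise ConfigError("planted edge cannot be a self-loop")

    m_a = np.asarray(base.group_a.transition_matrix, dtype=float)
    rates_a = expected_rates(m_a)
    targets = {}  # (u, v) -> target expected rate, fraction of jumps
    for p in plants:
        u, v = index[p.edge.source], index[p.edge.target]
        if (u, v) in targets:
            raise ConfigError(f"duplicate plant on edge {p.edge}")
        target = rates_a[u, v] / 100.0 + p.offset_pp / 100.0
        if not 0.0 < target < 1.0:
            raise ConfigError(f"infeasible offset on {p.edge}: target rate {target:.4f}")
        targets[(u, v)] = target

    planted_rows: dict[int, list[int]] = {}
    for (u, v) in targets:
        planted_rows.setdefault(u, []).append(v)

    m_b = np.asarray(base.group_b.transition_matrix, dtype=float).copy()
    for _ in range(max_iter):
        pi = stationary_distribution(m_b)
        new = m_b.copy()
        for u, cols in planted_rows.items():
            if pi[u] <= 0:
                raise ConfigError("planted row has zero stationary mass")
            entries = {v: targets[(u, v)] / pi[u] for v in cols}
            planted_mass = sum(entries.values())
            if any(e <= 0 or e >= 1 for e in entries.values()) or planted_mass >= 1:
                raise ConfigError("infeasible offset: matrix row cannot absorb it")
            rest = [j for j in range(m_b.shape[0]) if j != u and j not in cols]
            rest_mass = m_b[u, rest].sum()
            if rest_mass <= 0:
                raise ConfigError("infeasible offset: no remaining mass to rebalance")
            new[u, rest] = m_b[u, rest] * (1.0 - planted_mass) / rest_mass
            for v, e in entries.items():
                new[u, v] = e
        delta = np.abs(new - m_b).max()
        m_b = new
        if delta < tol:
            break

    dyn_b = replace(base.group_b, transition_matrix=m_b)
    return replace(base, group_b=dyn_b)


# -- generation ------------------------------------------------------------


def _draw_length(config: SyntheticConfig, rng: np.random.Generator) -> int:
    # proper truncation: redraw until above the floor
    while True:
        length = int(round(rng.normal(config.length_mean, config.length_sd)))
        if length >= config.length_min:
            return length


def _simulate_dyad(
    dyn: GroupDynamics,
    states: tuple[CombinedState, ...],
    length: int,
    rng: np.random.Generator,
) -> tuple[list[int], list[int]]:
    n = len(states)
    infant: list[int] = []
    mother: list[int] = []
    s = int(rng.choice(n, p=dyn.initial_dist))
    remaining = length
    while remaining > 0:
        stay = 1.0 - float(dyn.persistence[s])
        dwell = min(int(rng.geometric(stay)), remaining)
        infant.extend([states[s].infant] * dwell)
        mother.extend([states[s].mother] * dwell)
        remaining -= dwell
        if remaining > 0:
            s = int(rng.choice(n, p=dyn.transition_matrix[s]))
    return infant, mother


def generate_streams(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> list[BehavioralStream]:
    """Generate both groups' dyad streams; deterministic per config seed.

    'Other' codes are optionally inserted by overwriting each second
    independently with probability ``other_rate`` (the overwritten side is
    drawn uniformly from infant-only, mother-only, or both).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    streams: list[BehavioralStream] = []
    for group, prefix, dyn in (
        (GROUP_A, "ft", config.group_a),
        (GROUP_B, "pt", config.group_b),
    ):
        for d in range(dyn.n_dyads):
            length = _draw_length(config, rng)
            infant, mother = _simulate_dyad(dyn, config.states, length, rng)
            if config.other_rate > 0:
                hit = rng.random(length) < config.other_rate
                mode = rng.integers(0, 3, size=length)  # 0 infant, 1 mother, 2 both
                for t in np.flatnonzero(hit):
                    if mode[t] in (0, 2):
                        infant[t] = INFANT_OTHER
                    if mode[t] in (1, 2):
                        mother[t] = MOTHER_OTHER
            streams.append(
                BehavioralStream(
                    dyad_id=f"{prefix}{d + 1:03d}",
                    group=group,
                    infant_codes=tuple(infant),
                    mother_codes=tuple(mother),
                )
            )
    return streams
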
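"""Seeded simulator of a multi-role, scenario-segmented policy game.

The simulated game follows the outline of a Web-based health-policy
exercise: six stakeholder roles (federal and state government,
hospital, insurance company, physician, patient), several players per
role, and an ordered sequence of scenarios (e.g. building the insurance
marketplace, expanding Medicaid).  Players are expected to exchange
messages; the backend records every exchange, and random "environmental
conditions" hit each role every round and feed a per-player score.

Because no behavioral update rules are published for such a game, the
simulator abstracts play into the minimal stochastic structure whose
parameters are recoverable from the emitted logs:

* **Who talks to whom** — at each scenario start, a propensity vector
  over all unordered player pairs is drawn from a symmetric Dirichlet
  with concentration ``alpha``, multiplied by the role-pair affinity
  matrix, and renormalized.  Small ``alpha`` concentrates chatter on a
  few pairs (low diversity); large ``alpha`` spreads it evenly (high
  diversity).  Affinities let particular role pairs (say insurance
  companies and the state government during the marketplace scenario)
  collaborate more.
* **How much** — each round's total exchange count is Poisson with mean
  ``exchanges_per_round``, allocated to pairs multinomially by the
  propensity vector; each exchange's direction is a fair coin flip
  (the measures of interest are primarily nondirectional).
* **Environment and scores** — one categorical event per role per
  round, drawn from that role's outcome distribution; each outcome
  carries a utility.  A player's ``task_score`` in a scenario is the
  sum of their role's event utilities, ``engagement_score`` counts the
  exchanges they took part in, and ``total = task + engagement_weight
  * engagement``.  The scoring rule is a documented toy model.

Everything is reproducible from the config seed: a single numpy
Generator is advanced in a fixed order (scenario propensities, then per
round the Poisson total, the multinomial allocation, direction splits
in pair order, and role events in role order).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import ConfigError
from .logs import InteractionLog, InteractionRecord
from .network import DEFAULT_ROLES, ActorRoster

__all__ = [
    "EventOutcome",
    "AffinityRule",
    "ScenarioSpec",
    "GameConfig",
    "EnvironmentEvent",
    "ScoreBoard",
    "SimulationResult",
    "default_event_model",
    "sample_pair_propensities",
    "sample_environment",
    "simulate_game",
    "write_events_jsonl",
]


class EventOutcome(BaseModel):
    """One possible environmental outcome for a role, with its utility."""

    model_config = ConfigDict(frozen=True)

    name: str
    prob: float = Field(ge=0.0, le=1.0)
    utility: float


def default_event_model() -> dict[str, list[EventOutcome]]:
    """Per-role environmental outcome distributions for the six-role game.

    The vocabularies mirror the kinds of background conditions the game
    narrates to each role (meeting reactions, market share, risk pool,
    job satisfaction, health status); probabilities and utilities are a
    plausible, overridable default.
    """
    spec = {
        "federal_government": [
            ("meeting_reaction_positive", 0.45, 2.0),
            ("meeting_reaction_negative", 0.30, -1.0),
            ("states_adopt_initiative", 0.25, 3.0),
        ],
        "state_government": [
            ("town_hall_positive", 0.40, 2.0),
            ("town_hall_negative", 0.30, -1.0),
            ("policy_confusion_persists", 0.30, 0.0),
        ],
        "hospital": [
            ("market_share_up", 0.50, 2.0),
            ("market_share_down", 0.50, -1.0),
        ],
        "insurance_company": [
            ("risk_pool_improved", 0.40, 2.0),
            ("mandate_costs_up", 0.35, -1.0),
            ("provider_discount_secured", 0.25, 1.0),
        ],
        "physician": [
            ("satisfaction_up", 0.40, 2.0),
            ("income_up", 0.30, 1.0),
            ("workload_up", 0.30, -1.0),
        ],
        "patient": [
            ("status_improved", 0.40, 2.0),
            ("status_unchanged", 0.40, 0.0),
            ("status_worsened", 0.20, -1.0),
        ],
    }
    return {
        role: [EventOutcome(name=n, prob=p, utility=u) for n, p, u in outcomes]
        for role, outcomes in spec.items()
    }


class AffinityRule(BaseModel):
    """Multiplier on the interaction propensity of one unordered role pair."""

    model_config = ConfigDict(frozen=True)

    pair: tuple[str, str]
    multiplier: float = Field(ge=0.0)


class ScenarioSpec(BaseModel):
    """A task block of the game: a label, a round count, and optional
    scenario-specific affinity overrides layered on the base rules."""

    model_config = ConfigDict(frozen=True)

    label: str
    rounds: int = Field(ge=1)
    affinity: tuple[AffinityRule, ...] = ()


class GameConfig(BaseModel):
    """Full specification of a simulated game.

    Defaults describe the six-role health-policy game: two players per
    role, two 10-round scenarios, moderate evenness (alpha = 5), and 30
    expected exchanges per round across the whole network.
    """

    model_config = ConfigDict(frozen=True)

    roles: dict[str, int] = Field(
        default_factory=lambda: {r: 2 for r in DEFAULT_ROLES}
    )
    scenarios: tuple[ScenarioSpec, ...] = (
        ScenarioSpec(label="marketplace", rounds=10),
        ScenarioSpec(label="medicaid_expansion", rounds=10),
    )
    affinity: tuple[AffinityRule, ...] = ()
    concentration: float = Field(default=5.0, gt=0.0)
    exchanges_per_round: float = Field(default=30.0, gt=0.0)
    event_model: dict[str, list[EventOutcome]] = Field(
        default_factory=default_event_model
    )
    engagement_weight: float = 0.1
    focal: Optional[str] = None
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "GameConfig":
        problems: list[str] = []
        if not self.roles:
            problems.append("roles must be non-empty")
        for role, count in self.roles.items():
            if count < 1:
                problems.append(f"role {role!r} needs >= 1 player, got {count}")
        if sum(self.roles.values()) < 2:
            problems.append("the game needs at least 2 players overall")
        if not self.scenarios:
            problems.append("at least one scenario is required")
        labels = [s.label for s in self.scenarios]
        if len(set(labels)) != len(labels):
            problems.append(f"duplicate scenario labels in {labels}")
        for rule in list(self.affinity) + [
            r for s in self.scenarios for r in s.affinity
        ]:
            for role in rule.pair:
                if role not in self.roles:
                    problems.append(
                        f"affinity rule {rule.pair} names unknown role {role!r}"
                    )
        for role in self.roles:
            outcomes = self.event_model.get(role)
            if not outcomes:
                problems.append(f"role {role!r} has no event model")
                continue
            total = sum(o.prob for o in outcomes)
            if abs(total - 1.0) > 1e-9:
                problems.append(
                    f"event probabilities for role {role!r} sum to {total}, not 1"
                )
        if self.focal is not None and self.focal not in self.actor_ids():
            problems.append(
                f"focal actor {self.focal!r} is not a generated player id"
            )
        if problems:
            raise ValueError("; ".join(problems))
        return self

    # -- derived structure ------------------------------------------------

    def role_list(self) -> tuple[str, ...]:
        return tuple(self.roles)

    def actor_ids(self) -> tuple[str, ...]:
        """Player ids in roster order: ``<role>_<k>`` for k = 1..count."""
        return tuple(
            f"{role}_{k}"
            for role, count in self.roles.items()
            for k in range(1, count + 1)
        )

    def roster(self) -> ActorRoster:
        ids, roles = [], []
        for role, count in self.roles.items():
            for k in range(1, count + 1):
                ids.append(f"{role}_{k}")
                roles.append(role)
        return ActorRoster(
            tuple(ids), tuple(roles), focal=self.focal, role_set=self.role_list()
        )

    def affinity_matrix(self, scenario: str | None = None) -> np.ndarray:
        """R x R symmetric multiplier matrix for one scenario.

        Base rules apply everywhere; a scenario's own rules override the
        base value for the pairs they name.
        """
        roles = self.role_list()
        idx = {r: i for i, r in enumerate(roles)}
        mat = np.ones((len(roles), len(roles)))
        rules = list(self.affinity)
        if scenario is not None:
            spec = next((s for s in self.scenarios if s.label == scenario), None)
            if spec is None:
                raise ConfigError(
                    f"unknown scenario {scenario!r}; "
                    f"configured: {[s.label for s in self.scenarios]}"
                )
            rules += list(spec.affinity)
        for rule in rules:
            i, j = idx[rule.pair[0]], idx[rule.pair[1]]
            mat[i, j] = mat[j, i] = rule.multiplier
        return mat

    # -- serialization ----------------------------------------------------

    @classmethod
    def from_file(cls, path: str | Path) -> "GameConfig":
        """Load YAML (canonical) or JSON; validation errors become ConfigError."""
        path = Path(path)
        try:
            text = path.read_text(encoding="utf-8")
        except OSError as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from None
        try:
            data = (
                json.loads(text)
                if path.suffix.lower() == ".json"
                else yaml.safe_load(text)
            )
        except (yaml.YAMLError, json.JSONDecodeError) as exc:
            raise ConfigError(f"cannot parse config {path}: {exc}") from None
        if not isinstance(data, dict):
            raise ConfigError(f"config {path} must be a mapping at top level")
        try:
            return cls.model_validate(data)
        except Exception as exc:
            raise ConfigError(f"invalid config {path}: {exc}") from None

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.model_dump(mode="json"), sort_keys=False),
            encoding="utf-8",
        )


@dataclass(frozen=True)
class EnvironmentEvent:
    """One random background condition hitting a role in one round."""

    time: int
    scenario: str
    role: str
    outcome: str
    utility: float


@dataclass(frozen=True)
class ScoreBoard:
    """Per-player, per-scenario scores.

    ``engagement_score`` equals the player's exchange participation
    count in the log exactly; ``total`` is reproducible as
    ``task_score + engagement_weight * engagement_score``.
    """

    rows: tuple[dict, ...]
    engagement_weight: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            list(self.rows),
            columns=["player", "role", "scenario", "task_score", "engagement_score", "total"],
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class SimulationResult:
    log: InteractionLog
    roster: ActorRoster
    scores: ScoreBoard
    events: tuple[EnvironmentEvent, ...]


def sample_pair_propensities(
    config: GameConfig,
    rng: np.random.Generator,
    scenario: str | None = None,
) -> tuple[tuple[tuple[str, str], ...], np.ndarray]:
    """Draw the interaction-propensity distribution over player pairs.

    A symmetric Dirichlet(alpha) vector over all unordered player pairs
    is reweighted by the role-pair affinity and renormalized.  Returns
    (pairs, probabilities); probabilities sum to 1.
    """
    actors = config.actor_ids()
    if len(actors) < 2:
        raise ConfigError("need at least 2 players to form pairs")
    roster = config.roster()
    roles = config.role_list()
    ridx = {r: i for i, r in enumerate(roles)}
    aff = config.affinity_matrix(scenario)

    pairs = tuple(combinations(actors, 2))
    raw = rng.dirichlet(np.full(len(pairs), config.concentration))
    mult = np.array(
        [aff[ridx[roster.role_of(a)], ridx[roster.role_of(b)]] for a, b in pairs]
    )
    weighted = raw * mult
    total = weighted.sum()
    if total <= 0:
        raise ConfigError(
            "all pair propensities are zero after applying affinities; "
            "at least one role pair needs a positive multiplier"
        )
    return pairs, weighted / total


def sample_environment(
    config: GameConfig, role: str, rng: np.random.Generator
) -> tuple[str, float]:
    """Draw one environmental outcome (name, utility) for a role."""
    outcomes = config.event_model.get(role)
    if not outcomes:
        raise ConfigError(f"role {role!r} has no event model")
    probs = np.array([o.prob for o in outcomes])
    k = int(rng.choice(len(outcomes), p=probs / probs.sum()))
    return outcomes[k].name, outcomes[k].utility


def simulate_game(config: GameConfig) -> SimulationResult:
    """Play the whole game and return its log, roster, scores and events.

    Round indices are global (they keep counting across scenarios), so
    the log carries a single longitudinal time axis.  Bit-reproducible:
    the same config (including seed) yields identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    roster = config.roster()
    records: list[InteractionRecord] = []
    events: list[EnvironmentEvent] = []
    # engagement[(player, scenario)] and task utility accrues per (role, scenario)
    engagement: dict[tuple[str, str], int] = {}
    task_utility: dict[tuple[str, str], float] = {}

    t = 0
    for scenario in config.scenarios:
        pairs, props = sample_pair_propensities(config, rng, scenario.label)
        for _ in range(scenario.rounds):
            total = int(rng.poisson(config.exchanges_per_round))
            if total > 0:
                alloc = rng.multinomial(total, props)
            else:
                alloc = np.zeros(len(pairs), dtype=int)
            for (a, b), c in zip(pairs, alloc):
                if c == 0:
                    continue
                n_ab = int(rng.binomial(c, 0.5))
                n_ba = int(c) - n_ab
                if n_ab:
                    records.append(
                        InteractionRecord(t, scenario.label, a, b, n_ab)
                    )
                if n_ba:
                    records.append(
                        InteractionRecord(t, scenario.label, b, a, n_ba)
                    )
                engagement[(a, scenario.label)] = (
                    engagement.get((a, scenario.label), 0) + int(c)
                )
                engagement[(b, scenario.label)] = (
                    engagement.get((b, scenario.label), 0) + int(c)
                )
            for role in config.role_list():
                outcome, utility = sample_environment(config, role, rng)
                events.append(
                    EnvironmentEvent(t, scenario.label, role, outcome, utility)
                )
                task_utility[(role, scenario.label)] = (
                    task_utility.get((role, scenario.label), 0.0) + utility
                )
            t += 1

    rows = []
    for player, role in zip(roster.actor_ids, roster.roles):
        for scenario in config.scenarios:
            task = task_utility.get((role, scenario.label), 0.0)
            eng = engagement.get((player, scenario.label), 0)
            rows.append(
                {
                    "player": player,
                    "role": role,
                    "scenario": scenario.label,
                    "task_score": task,
                    "engagement_score": eng,
                    "total": task + config.engagement_weight * eng,
                }
            )
    scores = ScoreBoard(rows=tuple(rows), engagement_weight=config.engagement_weight)
    return SimulationResult(
        log=InteractionLog(records),
        roster=roster,
        scores=scores,
        events=tuple(events),
    )


def write_events_jsonl(events: tuple[EnvironmentEvent, ...], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for e in events:
            fh.write(
                json.dumps(
                    {
                        "time": e.time,
                        "scenario": e.scenario,
                        "role": e.role,
                        "outcome": e.outcome,
                        "utility": e.utility,
                    },
                    separators=(",", ":"),
                )
                + "\n"
            )
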
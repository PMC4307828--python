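"""Network diversity (DIV): evenness of communication exchanges.

Density asks whether pairs of players talked at all; diversity asks how
the *volume* of talk is spread over pairs.  The exchange counts of all
PT possible pairs (zero-weight pairs included) are normalized to a
probability distribution and scored with Shannon entropy, then scaled
by its maximum:

    H   = -sum_i p_i ln p_i          (0 ln 0 := 0)
    DIV = H / ln(PT)

so DIV = 1 when every possible pair carries an equal share of the
exchanges ("evenly distributed among all enrolled players") and
DIV = 0 when all exchanges sit on a single pair.  This is the standard
Pielou-style evenness normalization; the ratio is invariant to the
logarithm base.  DIV is undefined on a silent network (no exchanges) —
that case raises :class:`~gamenet.errors.SilentNetworkError` and the
longitudinal pipeline records it as missing.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import GameNetError, SilentNetworkError
from .logs import InteractionLog
from .network import ActorRoster, TieMatrix, possible_ties

__all__ = [
    "PairDistribution",
    "DiversityResult",
    "RolePairMatrix",
    "pair_distribution",
    "shannon_entropy",
    "network_diversity",
    "role_pair_counts",
]

_PROB_TOL = 1e-9


@dataclass(frozen=True)
class PairDistribution:
    """Exchange-count distribution over all possible actor pairs.

    ``pairs`` enumerates every one of the PT possible pairs (ordered
    pairs for a directed matrix, unordered otherwise), including those
    that never interacted; ``probs[k]`` is pair k's share of the
    ``total_weight`` exchanges.
    """

    pairs: tuple[tuple[str, str], ...]
    probs: np.ndarray
    total_weight: int

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if len(p) != len(self.pairs):
            raise GameNetError(f"{len(p)} probabilities for {len(self.pairs)} pairs")
        if np.any(p < 0):
            raise GameNetError("pair probabilities must be nonnegative")
        if abs(p.sum() - 1.0) > _PROB_TOL:
            raise GameNetError(f"pair probabilities sum to {p.sum()!r}, not 1")
        object.__setattr__(self, "probs", p)


def pair_distribution(m: TieMatrix) -> PairDistribution:
    """Normalize a tie matrix into a :class:`PairDistribution`.

    Raises :class:`SilentNetworkError` when the matrix carries no
    exchanges at all (evenness of nothing is undefined).
    """
    if m.n_actors < 2:
        raise GameNetError(f"pair distribution needs >= 2 actors, got {m.n_actors}")
    w = m.weights
    n = m.n_actors
    pairs: list[tuple[str, str]] = []
    counts: list[int] = []
    for i in range(n):
        for j in range(n):
            if i == j or (not m.directed and i > j):
                continue
            pairs.append((m.actors[i], m.actors[j]))
            counts.append(int(w[i, j]))
    total = int(sum(counts))
    if total == 0:
        raise SilentNetworkError(
            "no interactions in the network; diversity is undefined"
        )
    probs = np.asarray(counts, dtype=float) / total
    return PairDistribution(pairs=tuple(pairs), probs=probs, total_weight=total)


def shannon_entropy(p: PairDistribution | np.ndarray, base: float | None = None) -> float:
    """Shannon entropy H = -sum p_i log p_i, with 0 log 0 = 0.

    ``base=None`` means natural log (nats).  Accepts either a
    :class:`PairDistribution` or a bare probability vector.
    """
    probs = p.probs if isinstance(p, PairDistribution) else np.asarray(p, dtype=float)
    if np.any(probs < 0):
        raise GameNetError("probabilities must be nonnegative")
    if abs(probs.sum() - 1.0) > _PROB_TOL:
        raise GameNetError(f"probabilities sum to {probs.sum()!r}, not 1")
    nz = probs[probs > 0]
    h = float(-(nz * np.log(nz)).sum())
    if base is not None:
        h /= math.log(base)
    return max(h, 0.0) + 0.0  # clamp tiny negatives and normalize -0.0


@dataclass(frozen=True)
class DiversityResult:
    """DIV with its ingredients.

    ``entropy`` is the raw Shannon entropy H of the pair distribution
    (nats); ``max_entropy`` is ln(PT); ``div`` is their ratio in [0, 1].
    Both raw and normalized values are reported so either reading of
    the index is available.
    """

    entropy: float
    max_entropy: float
    div: float

    def to_json(self) -> str:
        return json.dumps(
            {"entropy": self.entropy, "max_entropy": self.max_entropy, "div": self.div},
            sort_keys=True,
        )


def network_diversity(m: TieMatrix) -> DiversityResult:
    """DIV of a tie matrix: normalized Shannon entropy of pair weights.

    Requires PT >= 2 (at least 3 actors when undirected) so that the
    ln(PT) normalization is defined, and at least one exchange.
    """
    pt = possible_ties(m.n_actors, m.directed)
    if pt < 2:
        raise GameNetError(
            f"diversity undefined for PT={pt}: need at least 2 possible pairs "
            f"(got {m.n_actors} actors, directed={m.directed})"
        )
    dist = pair_distribution(m)
    h = shannon_entropy(dist)
    h_max = math.log(pt)
    return DiversityResult(entropy=h, max_entropy=h_max, div=h / h_max)


@dataclass(frozen=True)
class RolePairMatrix:
    """Total exchanges aggregated by unordered role pair.

    Symmetric R x R count matrix; within-role exchanges (e.g. patient
    with patient) sit on the diagonal, so the grand total over the
    diagonal plus one triangle conserves the log's exchange total
    (self-exchanges excluded).
    """

    roles: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        r = len(self.roles)
        if c.shape != (r, r):
            raise GameNetError(f"counts shape {c.shape} != ({r}, {r})")
        if np.any(c < 0) or not np.array_equal(c, c.T):
            raise GameNetError("role-pair counts must be nonnegative and symmetric")
        object.__setattr__(self, "counts", c)

    def grand_total(self) -> int:
        """Total exchanges (each unordered role pair counted once)."""
        return int(np.triu(self.counts, k=1).sum() + np.diagonal(self.counts).sum())

    def largest_pair(self) -> tuple[str, str]:
        """The unordered role pair with the most exchanges (ties -> first in role order)."""
        best, best_val = (self.roles[0], self.roles[0]), -1
        r = len(self.roles)
        for i in range(r):
            for j in range(i, r):
                if self.counts[i, j] > best_val:
                    best_val = int(self.counts[i, j])
                    best = (self.roles[i], self.roles[j])
        return best

    def to_dict(self) -> dict:
        return {
            "roles": list(self.roles),
            "counts": [[int(x) for x in row] for row in self.counts],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    def to_csv(self, path: str | Path) -> None:
        with Path(path).open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["role", *self.roles])
            for i, role in enumerate(self.roles):
                writer.writerow([role, *map(int, self.counts[i])])


def role_pair_counts(
    log: InteractionLog,
    roster: ActorRoster,
    scenario: str | None = None,
) -> RolePairMatrix:
    """Aggregate a log's exchanges by unordered role pair.

    Answers questions like "do insurance companies and the state
    government collaborate more often while building the marketplace?".
    ``scenario`` filters the log first; an unknown label is an error
    listing the labels actually present.
    """
    if scenario is not None and scenario not in log.scenarios():
        raise GameNetError(
            f"unknown scenario {scenario!r}; log contains {list(log.scenarios())}"
        )
    filtered = log.filter(scenario=scenario)
    unknown = sorted(filtered.actors() - set(roster.actor_ids))
    if unknown:
        raise GameNetError(f"log actors not on the roster: {unknown}")

    roles = tuple(roster.role_set)
    idx = {r: i for i, r in enumerate(roles)}
    counts = np.zeros((len(roles), len(roles)), dtype=np.int64)
    for rec in filtered:
        if rec.sender == rec.receiver:
            continue
        i = idx[roster.role_of(rec.sender)]
        j = idx[roster.role_of(rec.receiver)]
        counts[i, j] += rec.count
        if i != j:
            counts[j, i] += rec.count
    return RolePairMatrix(roles=roles, counts=counts)
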
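"""Actors, tie matrices, and network density (DEN).

The central object is the :class:`TieMatrix`: a square matrix of
cumulative communication-exchange counts between the players of a game,
with a structurally zero diagonal (self-to-self ties are excluded by
definition).  Density is the fraction of possible ties actually
realized:

    DEN = actual ties / possible ties,   PT = N(N-1)/2  (nondirectional)
                                         PT = N(N-1)    (directional)

where a tie is "present" as soon as at least one exchange occurred
between the pair.  A companion comparison contrasts the dyadic reach of
a single focal organization (the convener of the game — a government
agency, school or hospital) with the whole network's possible ties: the
former grows linearly in network size, the latter quadratically, which
is the structural argument for letting players talk to each other
rather than only to the convener.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from numbers import Integral
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .errors import GameNetError, RosterError
from .logs import InteractionLog

__all__ = [
    "DEFAULT_ROLES",
    "ActorRoster",
    "TieMatrix",
    "DensityResult",
    "FocalComparison",
    "possible_ties",
    "build_tie_matrix",
    "network_density",
    "focal_vs_all",
]

logger = logging.getLogger(__name__)

#: The six stakeholder roles of the default health-policy game.
DEFAULT_ROLES = (
    "federal_government",
    "state_government",
    "hospital",
    "insurance_company",
    "physician",
    "patient",
)


@dataclass(frozen=True)
class ActorRoster:
    """Players enrolled in a game, each carrying a stakeholder role.

    Parameters
    ----------
    actor_ids : ordered unique player identifiers.
    roles : role label per actor, drawn from ``role_set``.
    focal : optional actor id of the focal organization (at most one).
    role_set : the configured role vocabulary; defaults to the six
        stakeholder roles of the health-policy game.
    """

    actor_ids: tuple[str, ...]
    roles: tuple[str, ...]
    focal: str | None = None
    role_set: tuple[str, ...] = DEFAULT_ROLES

    def __post_init__(self) -> None:
        if len(self.actor_ids) != len(self.roles):
            raise RosterError(
                f"{len(self.actor_ids)} actor ids but {len(self.roles)} roles"
            )
        if any(not a for a in self.actor_ids):
            raise RosterError("actor ids must be non-empty strings")
        if len(set(self.actor_ids)) != len(self.actor_ids):
            dupes = sorted(
                {a for a in self.actor_ids if self.actor_ids.count(a) > 1}
            )
            raise RosterError(f"duplicate actor ids: {dupes}")
        unknown = sorted(set(self.roles) - set(self.role_set))
        if unknown:
            raise RosterError(
                f"roles {unknown} not in configured role set {list(self.role_set)}"
            )
        if self.focal is not None and self.focal not in self.actor_ids:
            raise RosterError(f"focal actor {self.focal!r} not on the roster")

    def __len__(self) -> int:
        return len(self.actor_ids)

    def role_of(self, actor_id: str) -> str:
        try:
            return self.roles[self.actor_ids.index(actor_id)]
        except ValueError:
            raise RosterError(f"unknown actor {actor_id!r}") from None

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, str]],
        focal: str | None = None,
        role_set: Sequence[str] = DEFAULT_ROLES,
    ) -> "ActorRoster":
        """Build from (actor_id, role) pairs."""
        ids, roles = zip(*pairs) if pairs else ((), ())
        return cls(tuple(ids), tuple(roles), focal=focal, role_set=tuple(role_set))

    @classmethod
    def from_csv(
        cls, path: str | Path, role_set: Sequence[str] | None = None
    ) -> "ActorRoster":
        """Read a roster CSV with header ``actor_id,role,is_focal``.

        When ``role_set`` is omitted it is taken as the union of the six
        default roles and whatever roles appear in the file, so rosters
        from custom games load without extra configuration.
        """
        path = Path(path)
        ids: list[str] = []
        roles: list[str] = []
        focal: str | None = None
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.reader(fh)
            header = next(reader, None)
            if header is None or [h.strip() for h in header] != ["actor_id", "role", "is_focal"]:
                raise RosterError(
                    f"{path}: bad roster header {header!r}, "
                    "expected actor_id,role,is_focal"
                )
            for row in reader:
                if not row:
                    continue
                if len(row) != 3:
                    raise RosterError(
                        f"{path} line {reader.line_num}: expected 3 fields, got {row!r}"
                    )
                actor_id, role, is_focal = (c.strip() for c in row)
                ids.append(actor_id)
                roles.append(role)
                if is_focal.lower() in ("true", "1", "yes"):
                    if focal is not None:
                        raise RosterError(
                            f"{path}: more than one focal actor ({focal!r}, {actor_id!r})"
                        )
                    focal = actor_id
        if role_set is None:
            role_set = tuple(dict.fromkeys(list(DEFAULT_ROLES) + roles))
        return cls(tuple(ids), tuple(roles), focal=focal, role_set=tuple(role_set))

    def to_csv(self, path: str | Path) -> None:
        with Path(path).open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["actor_id", "role", "is_focal"])
            for a, r in zip(self.actor_ids, self.roles):
                writer.writerow([a, r, str(a == self.focal).lower()])


def possible_ties(n: int, directed: bool) -> int:
    """Number of possible ties PT among ``n`` actors, excluding self-ties.

    Nondirectional: PT = n(n-1)/2 (unordered pairs, the upper
    nondiagonal cells of the n x n matrix).  Directional:
    PT = n(n-1) (all nondiagonal cells).
    """
    if not isinstance(n, Integral) or isinstance(n, bool):
        raise GameNetError(f"actor count must be an integer, got {n!r}")
    n = int(n)
    if n < 2:
        raise GameNetError(f"actor count must be >= 2 for a network, got {n}")
    return n * (n - 1) if directed else n * (n - 1) // 2


@dataclass(frozen=True)
class TieMatrix:
    """Square matrix of cumulative exchange counts between actors.

    ``weights[i, j]`` is the number of exchanges from actor ``i`` to
    actor ``j`` (undirected matrices are symmetric, holding the summed
    two-way count in both cells).  The diagonal is structurally zero.
    Actor order follows the roster, so serialized matrices are stable.
    """

    actors: tuple[str, ...]
    weights: np.ndarray
    directed: bool
    dropped_self_exchanges: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights)
        m = len(self.actors)
        if w.shape != (m, m):
            raise GameNetError(f"weights shape {w.shape} != ({m}, {m})")
        if np.any(w < 0):
            raise GameNetError("exchange counts must be nonnegative")
        if np.any(np.diagonal(w) != 0):
            raise GameNetError("diagonal must be zero (self-to-self ties excluded)")
        if not self.directed and not np.array_equal(w, w.T):
            raise GameNetError("undirected tie matrix must be symmetric")
        object.__setattr__(self, "weights", w)

    @property
    def n_actors(self) -> int:
        return len(self.actors)

    def total_weight(self) -> int:
        """Total exchange count (each undirected pair counted once)."""
        if self.directed:
            return int(self.weights.sum())
        return int(np.triu(self.weights, k=1).sum())

    def to_networkx(self) -> nx.Graph | nx.DiGraph:
        """Export as a weighted networkx graph (zero-weight edges omitted)."""
        g: nx.Graph | nx.DiGraph = nx.DiGraph() if self.directed else nx.Graph()
        g.add_nodes_from(self.actors)
        rows, cols = np.nonzero(self.weights)
        for i, j in zip(rows, cols):
            if not self.directed and i > j:
                continue
            g.add_edge(self.actors[i], self.actors[j], weight=int(self.weights[i, j]))
        return g

    def to_csv(self, path: str | Path) -> None:
        """Dense labeled CSV: actor ids as both row and column labels."""
        with Path(path).open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["actor_id", *self.actors])
            for i, a in enumerate(self.actors):
                writer.writerow([a, *map(int, self.weights[i])])

    def to_edgelist_csv(self, path: str | Path) -> None:
        """Edge list ``source,target,weight`` (GraphML-convertible)."""
        with Path(path).open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["source", "target", "weight"])
            rows, cols = np.nonzero(self.weights)
            for i, j in zip(rows, cols):
                if not self.directed and i > j:
                    continue
                writer.writerow([self.actors[i], self.actors[j], int(self.weights[i, j])])


def build_tie_matrix(
    log: InteractionLog,
    roster: ActorRoster,
    window: tuple | None = None,
    scenario: str | None = None,
    directed: bool = False,
) -> TieMatrix:
    """Tabulate a log into a :class:`TieMatrix` over the roster's actors.

    ``window`` is a half-open ``[start, end)`` interval on record time;
    consecutive windows therefore partition a log with no double
    counting.  Undirected matrices sum the two directions.
    Self-exchange records are dropped (with a warning and a count on
    the result) rather than rejected.
    """
    if len(roster) == 0:
        raise RosterError("empty roster: a tie matrix needs at least 2 actors")
    filtered = log.filter(scenario=scenario, window=window)
    unknown = sorted(filtered.actors() - set(roster.actor_ids))
    if unknown:
        raise RosterError(f"log actors not on the roster: {unknown}")

    index = {a: i for i, a in enumerate(roster.actor_ids)}
    m = len(roster)
    weights = np.zeros((m, m), dtype=np.int64)
    dropped = 0
    for r in filtered:
        if r.sender == r.receiver:
            dropped += r.count
            continue
        i, j = index[r.sender], index[r.receiver]
        weights[i, j] += r.count
        if not directed:
            weights[j, i] += r.count
    if dropped:
        logger.warning("dropped %d self-exchange(s) while building tie matrix", dropped)
    return TieMatrix(
        actors=roster.actor_ids,
        weights=weights,
        directed=directed,
        dropped_self_exchanges=dropped,
    )


@dataclass(frozen=True)
class DensityResult:
    """Realized connectivity of a network.

    ``density = actual_ties / possible_ties``, in [0, 1]; 1 means every
    countable pair of actors exchanged at least one message.
    """

    actual_ties: int
    possible_ties: int
    density: float


def network_density(m: TieMatrix) -> DensityResult:
    """DEN of a tie matrix: present pairs over possible pairs.

    A pair counts as present when its cumulative exchange count is
    >= 1 — ordered pairs for a directed matrix, unordered otherwise.
    """
    if m.n_actors < 2:
        raise GameNetError(f"density needs >= 2 actors, got {m.n_actors}")
    pt = possible_ties(m.n_actors, m.directed)
    present = m.weights >= 1
    if m.directed:
        actual = int(present.sum())
    else:
        actual = int(np.triu(present, k=1).sum())
    return DensityResult(actual_ties=actual, possible_ties=pt, density=actual / pt)


@dataclass(frozen=True)
class FocalComparison:
    """Dyadic reach of the focal organization vs the whole network.

    Under the printed convention, a network of size parameter ``n`` has
    ``n`` ties involving the focal organization against ``n(n-1)/2``
    possible ties overall — linear versus quadratic growth, the
    structural case for peer-to-peer interaction.  The self-consistent
    convention counts ``n-1`` focal dyads among ``n`` actors total.
    """

    n: int
    focal_ties: int
    all_ties: int
    convention: str

    @property
    def ratio(self) -> float:
        """all_ties / focal_ties; equals (n-1)/2 under the printed convention."""
        return self.all_ties / self.focal_ties


def focal_vs_all(n: int, convention: str = "printed") -> FocalComparison:
    """Compare focal-organization ties with all possible network ties.

    ``convention="printed"`` reproduces the published tabulation
    (focal = n, all = n(n-1)/2), whose small-n rows are internally
    inconsistent but whose n >= 10 values are the quoted ones.
    ``convention="self_consistent"`` counts, among n actors, the n-1
    dyads containing the focal actor against all n(n-1)/2 dyads.
    """
    if not isinstance(n, Integral) or isinstance(n, bool):
        raise GameNetError(f"network size must be an integer, got {n!r}")
    n = int(n)
    if n < 1:
        raise GameNetError(f"network size must be >= 1, got {n}")
    if convention == "printed":
        focal = n
    elif convention == "self_consistent":
        focal = n - 1
    else:
        raise GameNetError(
            f"unknown convention {convention!r}; use 'printed' or 'self_consistent'"
        )
    return FocalComparison(
        n=n, focal_ties=focal, all_ties=n * (n - 1) // 2, convention=convention
    )
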
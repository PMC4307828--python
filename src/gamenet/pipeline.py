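"""Researcher-side evaluation: longitudinal DEN/DIV and the full report.

Density and diversity are cross-sectional — they describe the network
at one point in time.  Evaluating a running game needs repeated
application: the round span is cut into consecutive half-open windows
and both measures are recomputed per window (or cumulatively from the
start, to watch DEN grow as ties accumulate).  Silent windows are
well-defined for density (DEN = 0) but not for diversity, which is
recorded as missing.

:func:`evaluate_game` assembles everything a researcher would want from
one game's log and roster: overall and per-scenario DEN/DIV, the
snapshot series, per-scenario role-pair collaboration matrices, and the
focal-organization comparison — all deterministic and recomputable from
the inputs alone, serialized as stable JSON.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .diversity import (
    DiversityResult,
    RolePairMatrix,
    network_diversity,
    role_pair_counts,
)
from .errors import GameNetError, SilentNetworkError
from .logs import InteractionLog
from .network import (
    ActorRoster,
    DensityResult,
    FocalComparison,
    build_tie_matrix,
    focal_vs_all,
    network_density,
)

__all__ = [
    "SnapshotWindow",
    "SnapshotSeries",
    "EvaluationOptions",
    "EvaluationReport",
    "snapshot_series",
    "evaluate_game",
]


@dataclass(frozen=True)
class SnapshotWindow:
    """Metrics for one half-open round window [start, end)."""

    start: int
    end: int
    density: DensityResult
    diversity: Optional[DiversityResult]
    exchanges: int


@dataclass(frozen=True)
class SnapshotSeries:
    """Ordered, non-overlapping window metrics over a game's round span.

    ``exchanges`` is always the per-window total, so window totals sum
    to the log's total over the covered span; in cumulative mode only
    the DEN/DIV metrics accumulate from round 0.
    """

    windows: tuple[SnapshotWindow, ...]
    window_length: int
    cumulative: bool

    def to_rows(self) -> list[dict]:
        rows = []
        for w in self.windows:
            rows.append(
                {
                    "window_start": w.start,
                    "window_end": w.end,
                    "den": w.density.density,
                    "div": w.diversity.div if w.diversity is not None else None,
                    "exchanges": w.exchanges,
                }
            )
        return rows

    def to_csv(self, path: str | Path) -> None:
        """Tidy CSV ``window_start,window_end,den,div,exchanges`` (missing DIV blank)."""
        with Path(path).open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["window_start", "window_end", "den", "div", "exchanges"])
            for row in self.to_rows():
                div = "" if row["div"] is None else _fmt_float(row["div"])
                writer.writerow(
                    [row["window_start"], row["window_end"],
                     _fmt_float(row["den"]), div, row["exchanges"]]
                )


def snapshot_series(
    log: InteractionLog,
    roster: ActorRoster,
    window_length: int,
    directed: bool = False,
    cumulative: bool = False,
) -> SnapshotSeries:
    """Cut the log's round span into windows and measure each one.

    Windows are ``[0, L), [L, 2L), ...`` up to the last observed round
    (the final window may be short), so consecutive windows partition
    the span.  Requires integer round indices.
    """
    if len(log) == 0:
        raise GameNetError(
            "empty log: no rounds to window; compute an overall summary instead"
        )
    if window_length < 1:
        raise GameNetError(f"window length must be >= 1, got {window_length}")
    _, t_max = log.time_span()
    if not isinstance(t_max, int):
        raise GameNetError("snapshot series requires integer round indices")
    span_end = t_max + 1

    windows = []
    for start in range(0, span_end, window_length):
        end = min(start + window_length, span_end)
        metric_window = (0, end) if cumulative else (start, end)
        matrix = build_tie_matrix(log, roster, window=metric_window, directed=directed)
        den = network_density(matrix)
        try:
            div: Optional[DiversityResult] = network_diversity(matrix)
        except SilentNetworkError:
            div = None
        exchanges = log.filter(window=(start, end)).total_exchanges()
        windows.append(
            SnapshotWindow(
                start=start, end=end, density=den, diversity=div, exchanges=exchanges
            )
        )
    return SnapshotSeries(
        windows=tuple(windows), window_length=window_length, cumulative=cumulative
    )


@dataclass(frozen=True)
class EvaluationOptions:
    """Knobs for :func:`evaluate_game`.

    ``focal_convention`` defaults to the self-consistent count (a focal
    actor among M roster actors touches M-1 of the M(M-1)/2 dyads); the
    published tabulation's convention is available as ``"printed"``.
    ``scenarios``, when given, is the complete expected scenario list —
    a log scenario outside it is an error.
    """

    directed: bool = False
    window_length: int = 5
    cumulative: bool = False
    focal_convention: str = "self_consistent"
    scenarios: Optional[tuple[str, ...]] = None
    config_echo: Optional[dict] = None


def _density_dict(d: DensityResult) -> dict:
    return {
        "actual_ties": d.actual_ties,
        "possible_ties": d.possible_ties,
        "density": d.density,
    }


def _diversity_dict(d: Optional[DiversityResult]) -> Optional[dict]:
    if d is None:
        return None
    return {"entropy": d.entropy, "max_entropy": d.max_entropy, "div": d.div}


@dataclass(frozen=True)
class EvaluationReport:
    """Everything computed from one game's log and roster.

    Deterministic: identical inputs give byte-identical JSON (sorted
    keys, floats at 12 significant digits).
    """

    n_actors: int
    total_exchanges: int
    directed: bool
    overall_density: DensityResult
    overall_diversity: Optional[DiversityResult]
    scenario_metrics: tuple[tuple[str, DensityResult, Optional[DiversityResult], int], ...]
    role_pairs: tuple[tuple[str, RolePairMatrix], ...]
    snapshots: Optional[SnapshotSeries]
    focal: FocalComparison
    warnings: tuple[str, ...] = ()
    config_echo: Optional[dict] = None

    def to_dict(self) -> dict:
        scen = {}
        for label, den, div, exchanges in self.scenario_metrics:
            scen[label] = {
                "density": _density_dict(den),
                "diversity": _diversity_dict(div),
                "exchanges": exchanges,
            }
        for label, rp in self.role_pairs:
            scen[label]["role_pairs"] = rp.to_dict()
        snapshots = None
        if self.snapshots is not None:
            snapshots = {
                "window_length": self.snapshots.window_length,
                "cumulative": self.snapshots.cumulative,
                "windows": [
                    {
                        "start": w.start,
                        "end": w.end,
                        "density": _density_dict(w.density),
                        "diversity": _diversity_dict(w.diversity),
                        "exchanges": w.exchanges,
                    }
                    for w in self.snapshots.windows
                ],
            }
        return {
            "n_actors": self.n_actors,
            "total_exchanges": self.total_exchanges,
            "directed": self.directed,
            "overall": {
                "density": _density_dict(self.overall_density),
                "diversity": _diversity_dict(self.overall_diversity),
            },
            "scenarios": scen,
            "snapshots": snapshots,
            "focal_comparison": {
                "n": self.focal.n,
                "focal_ties": self.focal.focal_ties,
                "all_ties": self.focal.all_ties,
                "convention": self.focal.convention,
            },
            "warnings": list(self.warnings),
            "config": self.config_echo,
        }

    def to_json(self) -> str:
        return json.dumps(_round_floats(self.to_dict()), sort_keys=True, indent=2) + "\n"

    def to_text(self) -> str:
        lines = [
            f"Game network evaluation ({self.n_actors} actors, "
            f"{'directed' if self.directed else 'nondirectional'} ties)",
            f"  total exchanges: {self.total_exchanges}",
            f"  overall DEN: {self.overall_density.density:.4f} "
            f"({self.overall_density.actual_ties}/{self.overall_density.possible_ties} ties)",
        ]
        if self.overall_diversity is not None:
            d = self.overall_diversity
            lines.append(
                f"  overall DIV: {d.div:.4f} (H = {d.entropy:.4f} nats, "
                f"max {d.max_entropy:.4f})"
            )
        else:
            lines.append("  overall DIV: undefined (silent network)")
        for label, den, div, exchanges in self.scenario_metrics:
            div_s = f"{div.div:.4f}" if div is not None else "missing"
            lines.append(
                f"  scenario {label}: DEN {den.density:.4f}, DIV {div_s}, "
                f"{exchanges} exchanges"
            )
        for label, rp in self.role_pairs:
            a, b = rp.largest_pair()
            lines.append(f"  scenario {label}: most active role pair {a} -- {b}")
        if self.snapshots is not None:
            mode = "cumulative" if self.snapshots.cumulative else "per-window"
            lines.append(
                f"  snapshots ({mode}, window {self.snapshots.window_length} rounds):"
            )
            for row in self.snapshots.to_rows():
                div_s = f"{row['div']:.4f}" if row["div"] is not None else "missing"
                lines.append(
                    f"    rounds [{row['window_start']}, {row['window_end']}): "
                    f"DEN {row['den']:.4f}, DIV {div_s}, {row['exchanges']} exchanges"
                )
        f = self.focal
        lines.append(
            f"  focal comparison (n={f.n}, {f.convention}): "
            f"{f.focal_ties} focal ties vs {f.all_ties} possible ties"
        )
        for w in self.warnings:
            lines.append(f"  warning: {w}")
        return "\n".join(lines) + "\n"


def _fmt_float(x: float) -> str:
    return repr(float(f"{x:.12g}"))


def _round_floats(obj):
    """Round every float to 12 significant digits for stable serialization."""
    if isinstance(obj, float):
        return float(f"{obj:.12g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_round_floats(v) for v in obj]
    return obj


def evaluate_game(
    log: InteractionLog,
    roster: ActorRoster,
    options: EvaluationOptions = EvaluationOptions(),
) -> EvaluationReport:
    """Run the full researcher evaluation on one game's outputs.

    Deterministic given (log, roster, options); every number in the
    report is recomputable from the inputs alone.
    """
    warnings: list[str] = []
    log_scenarios = log.scenarios()
    if options.scenarios is not None:
        unknown = [s for s in log_scenarios if s not in options.scenarios]
        if unknown:
            raise GameNetError(
                f"log contains scenario(s) {unknown} absent from the expected "
                f"list {list(options.scenarios)}"
            )
        scenario_order = tuple(options.scenarios)
    else:
        scenario_order = log_scenarios

    overall_matrix = build_tie_matrix(log, roster, directed=options.directed)
    if overall_matrix.dropped_self_exchanges:
        warnings.append(
            f"dropped {overall_matrix.dropped_self_exchanges} self-exchange(s)"
        )
    overall_den = network_density(overall_matrix)
    try:
        overall_div: Optional[DiversityResult] = network_diversity(overall_matrix)
    except SilentNetworkError:
        overall_div = None
        warnings.append("overall network is silent; DIV undefined")

    scenario_metrics = []
    role_pairs = []
    for label in scenario_order:
        try:
            sub = log.filter(scenario=label)
            matrix = build_tie_matrix(sub, roster, directed=options.directed)
            den = network_density(matrix)
            try:
                div: Optional[DiversityResult] = network_diversity(matrix)
            except SilentNetworkError:
                div = None
                warnings.append(f"scenario {label!r} is silent; DIV undefined")
            scenario_metrics.append((label, den, div, sub.total_exchanges()))
            if label in log_scenarios:
                role_pairs.append((label, role_pair_counts(log, roster, scenario=label)))
        except GameNetError as exc:
            raise GameNetError(f"scenario {label!r}: {exc}") from exc

    snapshots = None
    if len(log) > 0:
        snapshots = snapshot_series(
            log,
            roster,
            window_length=options.window_length,
            directed=options.directed,
            cumulative=options.cumulative,
        )
        silent = sum(1 for w in snapshots.windows if w.diversity is None)
        if silent:
            warnings.append(f"{silent} silent window(s) with DIV missing")
    else:
        warnings.append("empty log: no snapshot series")

    focal = focal_vs_all(len(roster), convention=options.focal_convention)
    return EvaluationReport(
        n_actors=len(roster),
        total_exchanges=log.total_exchanges(),
        directed=options.directed,
        overall_density=overall_den,
        overall_diversity=overall_div,
        scenario_metrics=tuple(scenario_metrics),
        role_pairs=tuple(role_pairs),
        snapshots=snapshots,
        focal=focal,
        warnings=tuple(warnings),
        config_echo=options.config_echo,
    )
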
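# Methods

This note documents the models behind `gamenet`: the two network
measures, the game simulator that generates test data, the
longitudinal pipeline, and the numerical and design choices that were
genuinely open.

## Measures

### Possible ties and density

For `N ≥ 2` actors with self-ties excluded, `PT = N(N-1)/2`
nondirectional (unordered) pairs or `PT = N(N-1)` directional (ordered)
pairs. A tie is *present* when the cumulative exchange count of the
pair is ≥ 1 — the binary reading of the exchange matrix. Density is
the exact ratio `DEN = actual / PT`.

Undirected tie matrices are built by summing the two directions of each
pair and symmetrizing. For the ≥ 1 presence threshold this is
equivalent to OR-ing the binarized directions (the threshold commutes
with summation), and summation additionally preserves the counts that
diversity needs. A consequence worth knowing: on the same raw log,
nondirectional DEN ≥ directional DEN always, because the undirected
construction halves the denominator while at most halving the numerator.

### Diversity

DIV is normalized Shannon entropy (the Pielou-evenness construction)
over the pair-weight distribution:

* support = **all** PT possible pairs, silent pairs included at
  probability 0 (the index is about "all enrolled players", not just
  the active ones);
* `H = -Σ p ln p` with the convention `0·ln 0 = 0`;
* `DIV = H / ln(PT)`.

Entropy is computed in natural log; the base cancels in the ratio
(tested). `DIV = 1` iff all PT pairs carry equal weight, `DIV = 0` iff
one pair carries everything. Both the raw entropy and the normalized
index are reported, so either reading of the index is available.

Degenerate inputs: a silent network (total weight 0) has no defined
evenness — this raises `SilentNetworkError` rather than returning 0 or
1, and the pipeline records such windows as missing. `PT = 1` (two
actors, nondirectional) makes the `ln(PT)` normalization undefined and
is a domain error. Directional diversity normalizes by `ln(N(N-1))`;
the nondirectional construction is the default throughout, matching
the measures' usual presentation.

### Role-pair aggregation

Exchanges are aggregated by unordered role pair into a symmetric R×R
matrix; within-role exchanges (patient with patient) go on the
diagonal so the matrix's grand total (diagonal + one triangle)
conserves the log's exchange total exactly. Per-scenario matrices
answer the collaboration-cluster question (which roles talk during
which task).

### Focal-organization comparison

The published tabulation of "ties involving the focal organization"
versus "all ties" uses the convention focal = n, all = n(n-1)/2 — its
n ≥ 10 rows follow it, but its n = 1 and n = 2 rows are inconsistent
with it (and with each other) under any single reading, so no
convention can reproduce the whole table. `focal_vs_all` reproduces
the printed convention by default and flags it in the result; the
self-consistent count (a focal actor among M roster actors touches
M-1 of the M(M-1)/2 dyads) is a documented mode and is what the
evaluation report uses, since there the roster size is known exactly.
Either way the comparison's content is the same: focal reach grows
linearly, network potential quadratically — `all/focal = (n-1)/2`
exactly under the printed convention.

## The game simulator

The simulator emulates a scenario-segmented, multi-role online policy
game well enough to exercise every measure above, with parameters
recoverable from its own logs. It deliberately abstracts role
behavior into two stochastic components:

**Who talks to whom.** At each scenario start, a propensity vector over
all unordered player pairs is drawn as `Dirichlet(α)`, multiplied by
the role-pair affinity matrix for that scenario, and renormalized.
`α` (``concentration``, dimensionless, default **5.0**) is the
evenness dial: α = 0.05 concentrates play on a handful of pairs,
α = 50 is near-uniform. The default 5.0 yields a moderately even
network (overall DIV ≈ 0.95–0.98 at default volume) — plausible for a
game whose players are "reminded regularly" to interact. Affinity
multipliers (default all 1.0) let specific role pairs collaborate
more in specific scenarios.

**How much.** Each round's total exchange count is
`Poisson(exchanges_per_round)` (λ, default **30.0** per round across
the whole network, i.e. each of the 12 default players touches ~5
exchanges per round), allocated to pairs multinomially by the
propensity vector. Volume and evenness are therefore independently
controllable. Each exchange's direction is a fair coin flip; the
measures of interest are primarily nondirectional, so direction
carries no behavioral content.

**Environment and scores.** One categorical event per role per round
is drawn from the role's outcome distribution (default vocabularies
follow each role's narrative: meeting reactions for governments,
market share for the hospital, risk pool for the insurer, satisfaction
for the physician, health status for the patient; probabilities and
utilities are plausible defaults, fully overridable). Scoring is a
documented toy model: `task_score` sums the role's event utilities per
scenario, `engagement_score` counts the player's exchange
participation (it equals the log count exactly, by construction), and
`total = task + 0.1·engagement`.

**Reproducibility.** One `numpy` Generator seeded from the config
drives everything, advanced in a fixed order: scenario propensities,
then per round the Poisson total, the multinomial allocation,
direction splits in pair order, and role events in role order.
Identical configs give byte-identical logs, scores and events.

**Defaults as study conditions.** Six roles × 2 players, two 10-round
scenarios ("marketplace", "medicaid_expansion"), α = 5, λ = 30. These
were fixed once, before the test suite was written, from a design-time
Monte-Carlo check of the α→DIV mapping at 12 players (66 pairs).
One frozen bound from that check: with a single 10-round scenario,
`P(DIV < 0.5 | α = 0.05) ≈ 0.81` — the entropy distribution of a
`Dirichlet(0.05)` over 66 pairs has a heavy right tail, so the
concentrated regime is *usually*, not almost-always, below 0.5; the
corresponding test asserts the ≥ 0.70 rate that the oracle supports.
`P(DIV > 0.8 | α = 50) ≈ 1.0` and is asserted at ≥ 0.90.

**What the simulator does not model.** Adaptive play (scores never
feed back into propensities), reminder mechanics (subsumed in λ),
message content, within-round timing, and player dropout. Passing
tests therefore demonstrate that the measures behave correctly on
networks whose evenness and volume are controlled — not that real
game networks look like Dirichlet-multinomial draws. In particular,
real logs may have heavier-tailed volumes and time-correlated
activity; the measures themselves are defined on any log.

## Longitudinal pipeline

Time is an integer round index, global across scenarios, so one game
has a single longitudinal axis. Windows are half-open `[kL, (k+1)L)`
partitions of `[0, t_max+1)` — consecutive windows never double-count
and their exchange totals sum to the log total. Two snapshot modes,
one flag apart: per-window (shows interactions dying down) and
cumulative from round 0 (shows DEN building up; cumulative DEN is
provably nondecreasing since ties never disappear). Silent windows
carry DEN 0 (defined) and DIV missing (undefined).

Per-scenario DIV normalizes by the roster-wide PT, not by the PT of
scenario-active players: the index is interpreted against "all
enrolled players", and per-actor-subset normalization would make
scenarios with different active casts incomparable. The alternative
can be had by evaluating a scenario log against a restricted roster.

The JSON report is deterministic: sorted keys, floats rounded to 12
significant digits before serialization, no timestamps (the run
manifest, which does carry a timestamp, is a separate file).

## Interfaces

Interaction logs: CSV with header `time,scenario,sender,receiver,count`
or JSON-lines, auto-detected by extension; ISO-8601 timestamps are
accepted for real deployments (integer rounds are canonical and
required by the snapshot pipeline). Rosters: CSV
`actor_id,role,is_focal` with at most one focal actor. Tie matrices
export as dense labeled CSV, as `source,target,weight` edge lists, and
as networkx graphs. Configs: YAML (canonical) or JSON, validated by
pydantic with all violations reported together. The CLI is two
subcommands — `gamenet simulate`, `gamenet evaluate` — mirroring the
organizer/researcher split; malformed input files fail with the
offending 1-based line number.

## Known limitations

* The presence threshold is fixed at ≥ 1 exchange; no "strong tie"
  thresholds (out of scope by design — the binary matrix defines DEN).
* No inferential statistics on DEN/DIV differences between scenarios
  or windows; the report is descriptive.
* No other SNA measures (centrality, clustering, communities) — the
  two indices are the point.
* Snapshot windows require integer round indices; timestamped logs
  must be bucketed into rounds first.
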
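# Methods

## Workflow model

A query instance at a node is a finite-state process with eight states
and nine legal transitions. `RETRIEVED` (delivered by polling) and
`SEEN` (opened by a user) precede the decision; `ACCEPTED` queues the
query until its execution date; `PROCESSING` ends in `COMPLETED` or
`FAILED`; an optional per-approval *review mode* routes successful
executions through `INTERACTION`, from which a user releases the result
(`COMPLETED`) or withholds it (`REJECTED`). Being "seen" requires an
explicit view event — polling alone never advances a query — so the
*unanswered* KPI category covers both `RETRIEVED` and `SEEN`.

The transition function is total and pure: every (state, event) pair
either yields the unique successor or raises, and illegal calls leave
broker state untouched. `EXEC_OK` is the only event with two targets
(`COMPLETED` vs `INTERACTION`); the branch is fixed by the review flag
stored at approval, so each event still maps to at most one legal
transition per source state in any concrete run.

Auto-authorization of periodic series is implemented as a system-actor
view + approval pair (`actor = "auto-rule"`) at the same timestamp.
The workflow graph deliberately has no `RETRIEVED → ACCEPTED` shortcut:
keeping auto-authorized emissions on the same nine edges means every
history in the log — manual or automatic — replays through the same
validator, and the actor field alone distinguishes the two paths.

Standing authorization rules are keyed to a SHA-256 fingerprint of the
syntax language tag plus the whitespace-collapsed, case-preserved query
body. "Identical syntax" is not otherwise decidable; whitespace
insensitivity avoids spurious re-approvals after reformatting while any
semantic edit (including case) forces a fresh manual decision. Rules are
retroactive by default — they also cover emissions that fell due while
the decision was pending — and persist until explicitly revoked;
rejecting a later emission does not revoke a standing rule.

The six KPI categories (completed, failed, rejected, unanswered,
review-unanswered, pending-other) are derived from the state effective
at the cutoff, replaying each history with later events ignored. They
are exhaustive by construction: `ACCEPTED`/`PROCESSING` at cutoff form
*pending-other*, a bucket operational reports often omit, kept here so
category counts always sum to the record total.

## Event log

The normative log dialect is CSV (JSONL mirror) with header
`timestamp,node_id,query_id,from_state,to_state,actor`, ISO-8601 UTC
timestamps at second resolution, ties broken by insertion order, and the
token `NEW` for the pre-delivery pseudo-state. Query ids are
`<request_id>#<sequence_no>`. The log carries no explicit query-class
column; analytics classifies a request as periodic when any emission
with sequence number ≥ 1 appears, and accepts an explicit
`periodic_requests` set where that inference is insufficient (a
one-emission series is indistinguishable from a single request in the
log itself). External deposits are normalized through the
`zenodo` dialect adapter, whose default wide/long column mappings are an
assumption about deposit layout and are fully overridable.

## Simulator

`simulate_network` drives a real broker through a virtual clock with a
heap-ordered event loop: requests are published over the observation
window, nodes poll shortly after each emission falls due, and every
delivered query follows a drawn trajectory. The generator's defaults
describe the operating conditions of a mature nationwide network:

- **58 nodes** joining over the 2017-11-11 .. 2024-10-21 window, 12 in
  the first weeks and the rest spread to mid-2024; request arrival
  density grows linearly over the window.
- **Decision probabilities** per manual decision: individual queries
  reject 0.03 / ignore 0.14, periodic series (one decision per
  node-series block, covering all emissions) reject 0.01 / ignore 0.11.
  Execution fails independently per query with probability 0.028
  (individual) / 0.01 (periodic). Review mode is rare (0.01 / 0.0005)
  and stalls unreleased with probability 0.1 / 0.5, reproducing the
  near-zero review-unanswered rates such systems show.
- **Latency**: manual response latency is a two-component lognormal
  mixture — fast component median 4 days (σ=1.0), heavy tail with
  probability 0.15 (median 45 days, σ=1.2). A single lognormal cannot
  jointly produce a ~4-day median and a mean several times larger; the
  mixture can. Rejections draw a slower dedicated lognormal (median 38
  days). Per-node multiplicative heterogeneity (σ=0.25 on the log
  median) makes per-node Kaplan–Meier curves differ realistically.
  Processing time is lognormal in seconds (median 21 s individual,
  12 s periodic).
- **Volume**: ~1,075 single requests targeting 1–4 active nodes each,
  plus ~200 weekly series of 15–45 emissions targeting ~18% of the
  nodes active at publication — about 2,700 individual and 47,000
  periodic query instances, a ≈5%/95% class mix. A real network of this
  kind concentrates its periodic volume in a handful of multi-year
  daily series; that layout would hang the simulated rates on a few
  dozen Bernoulli decisions and make them statistically unstable at
  this scale, so the default spreads the same per-decision behavior
  over many shorter series. Arrival burstiness and surveillance cadence
  are likewise not modeled — only the growth trend and yearly totals.

Approved series grants apply retroactively: emissions due before the
grant execute at the grant time, so their completion delay equals the
grant lag, which is the mechanism behind periodic completions delayed by
hundreds of days. The emitted log is truncated at the window end — the
log is "extracted" then, and queries still in flight are left in
whatever state they had, exactly as a retrospective extraction would
leave them.

Randomness comes from one seed: a `SeedSequence` spawns a planning
stream and one substream per node, so output is byte-identical for a
fixed seed regardless of platform. The simulator reports state changes
through the broker API (which validates every transition) but draws
execution outcomes instead of running real queries; result payloads are
not materialized in simulation.

`make_fixture_log` is the deterministic counterpart: given rows of
(node, query, terminal category, day offset) it emits the minimal legal
event sequence realizing each row exactly, for closed-loop tests of the
analytics.

## Analytics conventions

- **Days** are `floor(elapsed / 1 day)`: an auto-executed emission
  completing seconds after retrieval is day 0.
- **Rates** are percentages of the class total, rounded half-up to one
  decimal on the exact rational (`Decimal`), so printed (count, total)
  pairs reproduce exactly.
- **SD** uses the n−1 denominator; **percentiles/quartiles** use linear
  interpolation between order statistics.
- **Kaplan–Meier**: completion is the event; rejection, failure, and
  still-open-at-cutoff censor at min(terminal time, cutoff). Censorings
  tied with events at the same day are processed after the events
  (still at risk). The curve reports t / n / d / c / S at every
  observed time. The clock starts at node retrieval, not publication.
- **Response percentile** (`percentile_time`) pools all terminal
  responses — completions, rejections and failures — because "time to
  response" and "time to completion" are different quantities; the KM
  curve measures only the latter.
- **Paired class comparison**: per-node mean days-to-completion in both
  classes, paired t-test with n−1 df (pairing by node, not by request —
  the per-request pairing is not well defined when target sets differ).
  The zero-variance nonzero-shift degenerate case is reported as
  t = ±inf, p = 0.
- **Yearly summary**: a query belongs to the UTC calendar year of its
  retrieval; a node is active in a year if it logged any event then.

## What passing tests do and do not show

The simulator emulates decision behavior statistically; it does not
model query content, node-side data volumes, email notification
timing, user-interface behavior, or correlated outages. Recovery of the
configured rates and latencies by the analytics (the pipeline's
round-trip property) validates the bookkeeping — delivery conservation,
transition legality, censoring logic, estimator correctness — not the
behavioral realism of any particular parameter value. Statements about a
real network require its real provenance log, loaded through the native
or deposit dialect.

## Degenerate inputs and numerical notes

Empty record sets, classes without completions, nodes with only
censored queries, and logs with illegal histories each have defined
behavior (typed errors, omitted curves, or quarantine counts in lenient
mode) rather than silent defaults. A lognormal with σ = 0 is a point
mass at its median (used by tests). Timestamps are truncated, not
rounded, to seconds. CSV result payloads are stored verbatim;
aggregation unions columns in first-seen order across lexicographically
sorted nodes and leaves unreported cells empty.
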
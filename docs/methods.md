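# Methods

## The communication model

`neurotraffic` models inter-regional signalling on a directed, unweighted
anatomical network as a queueing network. Discrete *signal units* enter the
network as a Poisson process with global rate λ; each unit independently draws
a uniformly random source and destination (source ≠ destination) and is
injected at its source. Every node is a single server with exponentially
distributed service times of rate μ. After service, the unit hops
instantaneously to a uniformly random out-neighbour of its current node
(a random walk — there is no routing intelligence); if the hop lands on the
unit's destination it is absorbed immediately, without queueing or service at
the destination.

Nodes have a finite buffer of size K: at most K units may wait while one is
in service, so node contents X_i(t) = c_i(t) + q_i(t) never exceed K + 1.
Waiting units are served last-come-first-served (LIFO), non-preemptively.
The buffer is a *push-out* buffer: an arrival that finds the queue full is
accepted and the **oldest waiting** unit is ejected and dropped (the unit in
service is never ejected). For K = 0 the arrival itself is the only queue
candidate and is immediately lost, giving a pure Erlang loss node. Total
network load is N(t) = Σ_i X_i(t) + Σ_ij X_ij(t); channel contents X_ij are
identically zero because hops are instantaneous, but the term is kept in the
bookkeeping so the load decomposition is explicit.

Every unit's trajectory — per-node arrival, service-start and departure
times — is traced, so all statistics are recomputed exactly from the trace
after the fact. Transit time T of a delivered unit is the sum of its waiting
and service times over all nodes traversed, which (hops being instantaneous)
equals delivery time minus creation time. Transit statistics use delivered
units only; dropped units contribute to loss counts, never to transit time.

All randomness comes from one seeded uniform stream (PCG64 by default,
Mersenne-Twister available via `rng_backend="mt19937"`) transformed by
inversion (−ln(1−U)/rate for exponentials), which makes runs bit-reproducible
from (network, config, seed). Simultaneous events arising from instantaneous
hops are resolved depth-first in causal order.

### Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| λ (`lambda_ext`) | global external arrival rate (units per time unit) | 0.1 | intensity grid {0.05, 0.10, 0.15, 0.20} used by the scenario protocols; λ is the control parameter of the congestion transition |
| μ (`mu`) | service rate per node | 1.0 | only λ/μ matters; time is dimensionless with μ fixed |
| K (`buffer_size`) | waiting slots per node (server not counted) | 5 | buffer capacity changes quantities, not qualitative behaviour; a sweep utility is provided |
| `t_end` | horizon (time units) | 2·10⁶ | full-scale protocol default; desk-scale studies use 10³–10⁵ |
| `t_transient` | warmup discarded before statistics | 4·10⁴ | matches the full-scale horizon; the ensemble-average detector (`detect_transient`, tolerance 5% of the long-run level) can suggest a cutoff for other scales |
| `arrival_mode` | `"global"` (one Poisson stream, uniform source) or `"per_node"` (rate λ per node, realised as a superposed stream of rate N·λ) | global | sensitivity analysis only |

## Statistics

Node level: **utilization** (busy time ÷ window length), **blocking**
(ejections ÷ arrivals; reported as missing, not zero, at nodes with no window
arrivals, to avoid biasing cross-node means), **mean contents** (exact
time-average of X_i over the window). Edge level: traversal counts, with
optional rich/feeder/local stratification. Network level: mean utilization
and blocking across nodes, throughput (units delivered in the window) and
mean transit time. Path level: deliveries and mean delay per
(source, destination) pair with per-source and per-target marginals;
undelivered pairs are missing, not zero.

Time averages use exact piecewise-constant integration of the event series.
A uniform-resampling pathway (linear interpolation onto a fixed-step grid,
then averaging) is retained because event-driven tooling commonly works on
resampled series; it is a faithful estimator only when the series level is
large relative to its ±1 jumps (e.g. total load of a well-loaded network) and
is biased for low-occupancy node series, so the exact route is the default
everywhere.

Windowing semantics: a statistic window [t₀, t_end) counts arrivals,
ejections and deliveries by event time; units alive across t₀ contribute
only their post-t₀ occupancy; a unit delivered inside the window contributes
its full transit time.

## Surrogates and generators

*Randomized* surrogates use Markov edge switching: a swap picks two edges
(A→B, C→D) and exchanges targets to (A→D, C→B), rejected if it would create
a self-loop or duplicate; accepted swaps preserve every in- and out-degree
exactly. Default effort is 10 accepted swaps per edge. *Latticized*
surrogates use the same mechanics but accept a swap only if it strictly
decreases Σ_edges |order(source) − order(target)| for a fixed node ordering
(the input order by default); the distance is non-circular |i − j|, a choice
the procedure leaves open, and runs stop after 10×|E| consecutive rejections,
treated as convergence.

Scenario networks: directed **ring lattices** (each node connects to its k
nearest successors and k nearest predecessors); **small-world** networks,
built by displacing a fraction (default 10%) of lattice edges via
degree-preserving swaps so that scenario and control stay exactly
degree-matched (a classical rewire-to-random-target variant is available via
`variant="ws"`); and **planted rich-club** networks: n = 100 nodes of which
n_rc = 20 form the club, with independent directed edge probabilities 0.05
(non-club → non-club), 0.20 (club ↔ non-club) and 0.80 (club → club).
The density triple is this package's choice of a strong, unambiguous planted
structure; the construction principle (a random graph whose designated hubs
are densely interlinked) fixes only the ordering of the three densities.
Generators resample until every node has in-degree ≥ 1 and out-degree ≥ 1,
which the walker dynamics require; strong connectivity is reported but not
required (undeliverable units are eventually pushed out of full buffers).

## Rich-club detection

For threshold k, all nodes with **total degree ≤ k** are stripped and
φ(k) = E_{>k} / (m(m−1)) is the density of the surviving directed subgraph
(undefined below two survivors). Total degree is the default stripping
convention, switchable to in- or out-degree. φ(k) is evaluated from the
lowest to the second-highest distinct degree and normalized by the mean φ(k)
of degree-matched randomized surrogates (default 100 nulls in desk-scale
runs, configurable to 10⁴); the null SD is reported alongside so
reduced-null runs remain interpretable. Membership levels are nested by
degree threshold: RC1 (strict) ⊆ RC2 (liberal); explicit published node
lists are accepted as an alternative. Edges are **rich** (both endpoints in
the club), **feeder** (exactly one) or **local** (neither); the three counts
always partition the edge set.

## Analytic steady-state model

The decomposition oracle treats routing and queueing separately. For each
destination d, the uniform walk absorbed at d has expected visit counts given
by the fundamental matrix (I − Q)⁻¹ of the absorbing chain; summing over the
N(N−1) uniformly weighted (source, destination) pairs gives each node's
effective traffic rate λ_i, exactly linear in λ. Each node is then an
independent M/M/1/K queue with total capacity K + 1:
p_n = ρⁿ(1−ρ)/(1−ρ^{K+2}), utilization 1 − p₀, loss p_{K+1}, mean contents
Σ n p_n. Push-out and block-on-arrival share the same occupancy chain, and
LIFO does not affect occupancy laws, so the standard formulas apply
unchanged. The decomposition ignores blocking-induced flow thinning and
inter-node correlation: it is accurate when predicted blocking is small
everywhere (sub-1% relative error on utilization in the verification runs)
and degrades as load rises — the acceptance suite asserts exactly this
profile. Unreachable (source, destination) pairs are excluded from the rate
sums with NaN flags rather than raising.

For very small systems, `exact_ctmc` builds the full continuous-time Markov
chain over per-node ordered destination stacks (LIFO promotion, oldest
ejection and absorption exactly as in the simulator) and solves πQ = 0
directly; it is the brute-force oracle for the 2- and 3-node fixtures and is
guarded against state-space blow-up.

## Ensemble comparison

Per-node metrics from replicate runs on a network are compared with runs on
each surrogate realization by Welch's unequal-variance t-test with
Satterthwaite degrees of freedom; t, df and p are averaged across
realizations, and Benjamini–Hochberg FDR is applied across nodes to the
averaged p-values, per metric family. Tests are two-sided. A caveat
documented here because it matters for calibration checks: the average of
p-values across realizations is not itself uniform under the null, so the
"type-I rate ≈ q" property holds for the single-realization reduction (where
the protocol collapses to plain Welch + BH) and that is what the calibration
tests exercise. Scenario similarity correlates grand-mean metric patterns
across (family × λ) cells between scenarios and contrasts correlations with
Fisher's r-to-z.

## Problem sizes in the test and acceptance runs

Desk-scale defaults keep the full verification stack re-runnable in minutes:
two-node oracle runs use horizons of 5·10⁴ with 20 seeds; the 3-node CTMC
comparison 2·10⁴ with 12 seeds; the analytic-agreement ladder a 20-node
random graph at 2.5·10⁴ with 10 seeds and intensities (1×, 2×, 4×) of the
rate at which predicted peak blocking reaches 0.1%; the surrogate-comparison
protocol on the planted rich-club network runs 10 base runs vs 10 runs on
each of 10 randomized realizations at λ = 0.15 with horizon 1.5·10⁴ and
warmup 3·10³. The full-scale protocol (100 runs × 100 realizations at 2·10⁶
time units) is available through the same interfaces via `SimConfig` and
`run_scenario` arguments.

## What the synthetic scenarios do and do not show

The planted rich-club fixture has, by construction, statistically symmetric
in- and out-degrees at every node and no spatial or modular structure beyond
the club. Two consequences, verified analytically and by simulation:

* Per-edge throughput under random-walk routing is approximately node
  throughflow ÷ out-degree. With in ≈ out degree everywhere this ratio is
  flat across rich/feeder/local classes, so the fixture does **not**
  reproduce the rich > feeder > local per-edge ordering reported for
  empirical connectomes, whose hubs have asymmetric afferent/efferent
  counts. The node-level signatures (contents rising with in-degree, strong
  target-marginal variance excess) are reproduced.
* Loss rates on the fixture are statistically identical between the base
  network and its degree-matched randomizations at every intensity probed,
  so delivered-volume (throughput) differences between the families are
  null; randomization measurably lengthens transit (club shortcuts are
  destroyed) but does not raise throughput. Empirical connectome reports of
  lower base throughput rest on loss-rate asymmetries this symmetric
  synthetic construction cannot generate.

Both limitations are properties of the study fixture, not of the simulator or
statistics, and the corresponding directional checks are kept in the
acceptance suite in their original form, where they document this gap.

## Known limitations

* Hops are instantaneous; there are no transmission delays or weighted
  edges.
* Routing is pure uniform diffusion; shortest-path, greedy or packet-switched
  strategies are out of scope.
* The analytic model is a low-load decomposition; it does not model blocking
  feedback between nodes.
* The empirical macaque connectivity matrix is not bundled; all shipped
  study networks are synthetic stand-ins produced by the generators.
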
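# neurotraffic

Discrete-event simulation of signal traffic on directed brain networks, with
rich-club analysis, degree-matched surrogate generation, an analytic
steady-state oracle and ensemble statistical comparison.

## The problem

How does the wiring of a cortical network shape global information flow?
`neurotraffic` treats an anatomical network (regions = nodes, axonal
projections = directed edges) as a communication network: discrete signal
units enter as a Poisson process with rate λ, each with a uniformly random
source and destination, and diffuse by uniform random walk over
out-neighbours until absorbed at their destination. Each node is a single
server with exponential service at rate μ, a finite LIFO buffer of K waiting
slots, and push-out loss: an arrival at a full buffer evicts the oldest
waiting unit, which is dropped. The model has two regimes — stationary flow
at low λ, and congestion ("jamming") as λ approaches the service capacity —
and the interesting science is in how topology distributes that congestion.

The package is aimed at network-neuroscience and complex-systems researchers
who want to ask: does a rich club of densely interlinked hubs attract and
route traffic? how do degree-matched randomized or latticized controls
behave? which nodes are more or less congested than their degree predicts?

Core quantities, per observation window after a warmup transient:

* node: utilization (busy-time fraction), blocking (ejections ÷ arrivals),
  mean contents E[X_i], with X_i(t) = c_i(t) + q_i(t) ≤ K + 1;
* edge: traversal counts, stratified into rich / feeder / local classes;
* network: throughput (delivered units), mean transit time
  T = Σ_nodes (W + S) over delivered units, mean utilization and blocking;
* path: deliveries and delay per (source, destination) pair with marginals;
* rich club: φ(k) = E_{>k}/(m(m−1)) over the subgraph of nodes with total
  degree > k, normalized as φ_norm(k) = φ(k) / ⟨φ_null(k)⟩ against
  degree-matched randomized nulls.

An independent analytic model (absorbing-random-walk traffic equations
feeding per-node M/M/1/K formulas) and an exact brute-force CTMC solver for
tiny systems serve as verification oracles for the simulator.

## Worked example

```python
import numpy as np
import neurotraffic as nt

# a planted rich-club network: 100 nodes, 20-node club, block edge
# probabilities 0.05 (local) / 0.20 (feeder) / 0.80 (club-club)
net, membership = nt.rich_club_synthetic(n=100, n_rc=20, seed=42)

print("network:", net.n_nodes, "nodes,", net.n_edges, "edges")

cfg = nt.SimConfig(lambda_ext=0.15, mu=1.0, buffer_size=5,
                   t_end=15_000, t_transient=3_000, seed=1)
trace = nt.run_simulation(net, cfg)
window = nt.remove_transient(trace)

for k, v in nt.network_stats(window).items():
    print(f"{k}: {v:.4f}" if isinstance(v, float) else f"{k}: {v}")
nodes = nt.node_stats(window)
club = [n for n, is_rc in membership.items() if is_rc]
print("mean contents, club nodes:    %.3f" % nodes.mean_contents[club].mean())
print("mean contents, non-club:      %.3f" % nodes.mean_contents.drop(club).mean())

prof = nt.rich_club_profile(net, n_null=100, seed=2)
i = int(np.nanargmax(prof.phi_norm[:-3]))
print(f"phi_norm peak: {prof.phi_norm[i]:.3f} at k={prof.k_grid[i]} "
      f"(phi={prof.phi[i]:.3f}, null mean={prof.null_mean[i]:.3f})")
```

prints

```
network: 100 nodes, 1282 edges
mean_utilization: 0.1713
mean_blocking: 0.0005
throughput: 1436
dropped: 263
mean_transit_time: 161.6919
mean contents, club nodes:    0.694
mean contents, non-club:      0.126
phi_norm peak: 1.177 at k=55 (phi=0.772, null mean=0.656)
```

Reading it: over the 12,000 post-warmup time units, 1,436 units were
delivered and 263 pushed out of full buffers; a delivered unit spent on
average ≈ 162 time units walking to its destination. Club nodes hold ≈ 5.5×
the traffic of peripheral nodes — hubs attract load. The rich-club
coefficient exceeds its degree-matched null by 18% at degree threshold 55,
flagging the planted club, and `classify_nodes` at a threshold inside the
degree gap recovers its membership exactly.

Surrogates and the comparison protocol:

```python
report = nt.run_scenario(net, n_randomized=10, lambdas=(0.05, 0.10, 0.15, 0.20),
                         n_reps=10, config=cfg, seed=7)
print(report.curves)          # metric-vs-intensity curves per network family
res = nt.compare_ensembles(report.node_metrics[("base", 0.15, "mean_contents")][0],
                           report.node_metrics[("randomized", 0.15, "mean_contents")],
                           q=0.05, items=report.node_ids)
print(res.table.query("q_flag"))  # nodes significantly more/less congested
```

A `neurotraffic` command-line interface wraps the same functionality:
`neurotraffic generate richclub --n 100 --n-rc 20 --seed 1 --out net.tsv`,
`neurotraffic simulate --net net.tsv --lambda 0.15 --seed 1`,
`neurotraffic richclub --net net.tsv --n-null 1000 --seed 1 --out prof.csv`,
`neurotraffic predict --net net.tsv --lambda 0.05 --out pred.csv`.

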
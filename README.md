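# ccdyn — consensus connectome dynamics

Structural braingraphs built from diffusion MRI are undirected: tractography
sees fiber tracts between gray-matter ROIs but not the direction of signal
propagation along them.  `ccdyn` works with a *population* of such graphs.
For `N` subjects over a shared ROI vocabulary, the consensus graph `G_k`
keeps the edges present in at least `k` subjects; lowering `k` from `N` to 1
adds edges monotonically, and empirically this buildup looks like a growing
shrub — new edges attach to the already-connected graph instead of landing on
isolated vertices.  If edges present in more subjects are older in individual
development, the buildup replays growth, and an edge that connects a
previously isolated vertex `v` to a previously connected vertex `u` can be
oriented `v → u`.

The toolkit provides, for neuroimaging and network-science users:

- **consensus stacks** — per-edge support counts `c(e)` inducing every `G_k`,
  with the confidence-percentage mapping `k = ceil(pct/100 · N)` and
  median/mean/sum weight aggregation;
- **sweep dynamics** — per-step classification of new edges by prior endpoint
  state (`iso_iso` / `iso_conn` / `conn_conn`) and the cumulative
  isolated-pair curve;
- **a uniform-random null** — the same step sizes added uniformly at random,
  Monte-Carlo mean/SD and a z-score for the real curve;
- **the component tree** — ROI-named leaves, numbered internal nodes in
  creation order with birth thresholds and lineage colors, GraphML export;
- **edge orientation** — the isolated-to-connected rule, with undirectable
  edges reported as `isolated_edge` or `connected_pair`;
- **synthetic populations** — growth sequences with known ground truth
  (attach / de-novo-pair / internal events) sampled into nested or Bernoulli
  subject cohorts for closed-loop validation.

See `docs/methods.md` for the model details and design choices.

## Worked example

Simulate a 96-subject nested population with a known growth order, then run
the pipelines from the shell:

```sh
ccd simulate --subjects-out pop/ --truth-out truth.csv --seed 1
ccd dynamics --subjects pop/ -o trajectory.csv
ccd null     --subjects pop/ --reps 200 --seed 1 -o comparison.csv
ccd direct   --subjects pop/ -o directed.csv
ccd tree     --subjects pop/ -o tree.graphml
```

or from Python:

```python
from ccdyn import (PopulationConfig, generate_growth_truth, sample_subjects,
                   build_stack, ccd_trajectory, compare_to_null,
                   assign_directions, recovery_report)

config = PopulationConfig(seed=1)          # 96 subjects, 300 growth events
truth = generate_growth_truth(config)
stack = build_stack(sample_subjects(truth, config))

cmp = compare_to_null(ccd_trajectory(stack), n_reps=200, seed=1)
print(int(cmp.real_curve[-1]), round(float(cmp.null_mean[-1]), 2),
      round(cmp.z_final, 2))
# 22 51.25 -7.76

report = recovery_report(assign_directions(stack), truth)
print(report.n_attach_present, report.n_attach_directed,
      report.direction_accuracy)
# 156 156 1.0
```

Reading the numbers: the real buildup accumulates only 22 isolated-pair
edges where matched uniform-random addition averages 51.25 — the real curve
sits 7.8 null standard deviations low, the non-random "shrub" signature.
All 156 ground-truth attachment edges are oriented, and every orientation
points from the new vertex into the existing network.

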
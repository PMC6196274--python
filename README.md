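# glionet

A balanced-ternary logic model of neuronal–glial signaling for studying how
the brain's own homeostatic regulation can perpetuate chronic
neuroinflammation — and whether candidate drug strategies can break it.

The package is aimed at systems-biology and neuroimmunology researchers who
want a kinetics-free, qualitative account of the neuroimmune circuit: five
cell populations (microglia, astrocytes, neurons, endothelial cells /
blood–brain-barrier integrity, T cells) coupled through ten signaling
molecules (CORT, acetylcholine, CD200, IL-1β, IL-6, TNF-α, IL-4, IGF-1,
VEGF, BDNF) by 50 literature-annotated stimulatory or inhibitory edges.

## The model

Every entity takes a value in {−1, 0, +1}: below, at, or above its typical
healthy level. For an N-entity state **x**(t), the *image vector*
**x**(t+1) gives the preferred next value of each entity:

```
x_i(t+1) = (x_i1^A ∨ x_i2^A ∨ …) ∇ (x_i1^I ∨ x_i2^I ∨ …)
```

where ∨ pools parallel signals of one mode of action (sign of the
arithmetic sum), ∇ is a ternary HIGH/LOW PASS operator combining the
pooled stimulation a with the pooled inhibition i (default: sign(a − i);
any admissible monotone 3×3 table can be injected), and an entity with
only stimulators or only inhibitors takes the pooled signal or its
negation. A state equal to its own image is a steady state. Dynamics are
asynchronous: one entity at a time moves one step toward its image, the
mover chosen uniformly at random — a Monte-Carlo walk that terminates at a
steady state.

On top of the dynamical core the package provides:

- **Attractor enumeration** — exhaustive, vectorized scan of all 3^N states
  (fifteen entities ≈ 14.3 M states in seconds), plus a calibration search
  over all 25 admissible PASS tables.
- **Treatment simulation** — node-shift interventions (glucocorticoid
  receptor blockade, cytokine suppression, broad-acting anti-inflammatory,
  and combinations), 1000 trials × 10 seeded batches each.
- **Expression concordance** — directional two-sample t-tests per marker
  gene against a predicted state, pooled with Brown's method for dependent
  p-values (T₀ = −2Σln pᵢ rescaled by c = σ²/4N with
  cov(−2ln pᵢ, −2ln pⱼ) = ρ(3.25+0.75ρ) for ρ≥0, ρ(3.27+0.71ρ) for
  −0.5≤ρ<0), Sammon 2-D projection of aggregate-P distance matrices, and
  signed fold changes.
- **Synthetic expression data** — a seeded log-normal / Gaussian-copula
  generator over the 12 marker genes (BDNF, IGF1, IL1B, IL6, IL4, TNF,
  CD200, VEGFA, GFAP, LIF, OSM, CCL2) with group-level shifts concordant
  with a chosen discrete state and known ground truth.

## Worked example

```python
from glionet import (
    default_network, default_logic_tables, enumerate_fixed_points,
    ss_signatures, match_signature, neuroinflammatory_state,
    standard_treatments, run_treatment_trials, TrialConfig,
)

net = default_network()
report = enumerate_fixed_points(net, default_logic_tables())
ss0, ss1 = ss_signatures()
for fp in report.fixed_points:
    tags = [s.name for s in (ss0, ss1) if match_signature(fp, s, net)]
    print({k: v for k, v in fp.as_dict(net).items() if v}, tags)

outcome = run_treatment_trials(
    net, None, standard_treatments()["BAA"], neuroinflammatory_state(net),
    ss0, TrialConfig(n_trials=1000, n_batches=10, base_seed=1),
)
print(f"BAA: {outcome.percent:.2f}% of walks returned to baseline")
```

prints (values produced by this code, seed 1):

```
{'Microglia': -1, 'Neurons': 1, 'Endothelial': 1, 'Tcells': 1, 'CORT': -1,
 'ACh': 1, 'CD200': 1, 'IL1b': -1, 'IL6': -1, 'TNFa': -1, 'IL4': 1,
 'VEGF': -1, 'BDNF': 1} []
{} ['SS0']
{'Microglia': 1, 'Neurons': -1, 'Endothelial': -1, 'Tcells': -1, 'CORT': 1,
 'ACh': -1, 'CD200': -1, 'IL1b': 1, 'IL6': 1, 'TNFa': 1, 'IL4': -1,
 'VEGF': 1, 'BDNF': -1} ['SS1']
BAA: 0.20% of walks returned to baseline
```

Fixed points are listed in lexicographic order. The middle one is SS0,
typical health (everything at baseline). The last matches the SS1
neuroinflammatory signature: elevated glucocorticoid, pro-inflammatory
cytokines, VEGF and microglial activation; depressed cholinergic tone,
neuronal function, BBB integrity, IL-4 and Th2 polarization — a
self-sustaining pathological program that persists with no external
insult. The first is SS1's sign mirror, an
artifact of the default operator's oddness (see `docs/methods.md` for the
calibration study across all admissible operator tables). The treatment
number is the Monte-Carlo probability that a one-step broad-acting
anti-inflammatory shift lets the system escape SS1 and settle back at SS0;
on this 15-entity reconstruction the cytokine–microglia positive feedback
re-ignites almost always, so escape probabilities are near zero
(`docs/methods.md` analyses why, and how this differs from tighter
published reconstructions).

A command-line interface mirrors the library:
`glionet export-network`, `glionet steady-states`, `glionet treat`,
`glionet synth`, `glionet compare`, `glionet embed` (see `--help`).

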
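# netparafac

Group-level analysis of directed functional brain networks: estimate
squared partial directed coherence (PDC) connectivity from multichannel
recordings, and extract the **grand-average network** of a subject group
by non-negative **L1 parallel factorization** of the stacked subject
networks, validated by a synthetic network-recovery benchmark.

## Who it is for

Researchers with one K x K directed connectivity matrix per subject
(e.g. band-averaged squared PDC from EEG) who need the single network
pattern common to the group, plus a principled way to know at which sample
sizes and noise levels that extraction can be trusted.

## Method

Each subject's network is vectorized into a column of a non-negative
matrix `X` (K² x S), which is approximated by a sum of f rank-one
non-negative terms

    X ≈ A Bᵀ = Σ_r a(r) ⊗ b(r),   A ≥ 0 (K² x f),  B ≥ 0 (S x f),

minimizing the **L1** residual `Σᵢⱼ |xᵢⱼ − Σ_r aᵢ(r) bⱼ(r)|`, which favours
sparse patterns suited to binarized connectivity. Columns a(r) are network
patterns, columns b(r) the per-subject loadings. The grand average is the
factor whose loadings have **minimum variance across subjects** — a truly
common pattern is expressed near-equally in everyone. The selected pattern
is reshaped to K x K, binarized (cells below 0.001 of the pattern peak set
to 0), and surviving connections are re-assigned their mean value across
the population. Degree summaries (in + out per node) and an
electrode-adjacency spatial filter (for volume-conduction suppression)
complete the pipeline.

The PDC front end fits a multivariate autoregressive model
`Y(t) = Σ_q λ(q) Y(t−q) + ε(t)` by pooled least squares (order by AIC) and
computes squared PDC `π_ij(f) = |Λ_ij(f)|² / Σ_m |Λ_mj(f)|²` from the
transfer matrix `Λ(f) = I − Σ_q λ(q) e^{−i2πfq/fs}`, with band averages
over θ/α/β/γ and a phase-randomized surrogate null for binarization.

See `docs/methods.md` for assumptions, parameter defaults, and known
limitations.

## Worked example

```python
import numpy as np
from netparafac import (generate_dataset, stack_subjects,
                        extract_grand_average, score_extraction, degrees)

# a 20-node group study: 10 subjects, 30% of edges displaced per subject
ds = generate_dataset(K=20, S=10, m=0.3, density=0.1, rng_seed=7)
res = extract_grand_average(stack_subjects(ds.subjects), f=2, rng_seed=0)

print("connections recovered:", int(res.binary.sum()))
print("selected factor:", res.selected_factor)
print(score_extraction(res, ds.ground_truth.matrix))
print(degrees(res.binary).head(3))
```

prints

```
connections recovered: 37
selected factor: 0
{'FPR': 0.0, 'FNR': 0.02631578947368421, 'AUC': 1.0}
    in_degree  out_degree  degree
n0          1           2       3
n1          4           2       6
n2          2           1       3
```

The extractor recovered 37 of the 38 ground-truth connections with no
false positives: FPR is the fraction of truly absent connections reported
present, FNR the fraction of true connections missed (here 1/38), and AUC
the probability that a true connection outranks an absent one in the
continuous factor weights.

The same pipeline is scriptable from the shell:

```sh
netparafac simulate-data --nodes 20 --subjects 10 --swap 0.3 --seed 7 --out data/
netparafac extract --in data/ --factors 2 --seed 0 --out ga/
netparafac simulate --config sim.json --out results.csv
netparafac pdc --in trial0.csv --in trial1.csv --fs 500 --out pdc/
```

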
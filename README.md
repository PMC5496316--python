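# mimicsim

Monte-Carlo evaluation of the MIMIC (multiple indicators, multiple causes)
structural-equation model as a detector of **uniform differential item
functioning (DIF)** in polytomous questionnaire items — aimed at the setting
common in medical and psychological measurement: a small clinical (focal)
group, a larger reference group, and a latent trait whose distribution may be
strongly skewed.

## What it does

**Data generation.** Ordinal responses for a k-item, J-category scale come
from the graded response model (GRM). For item *i* with discrimination
*a<sub>i</sub>* and ascending thresholds *b<sub>ij</sub>*, the probability of
answering in category *j* or above at trait level θ is

P\*<sub>ij</sub>(θ) = exp(a<sub>i</sub>(θ − b<sub>ij</sub>)) / (1 + exp(a<sub>i</sub>(θ − b<sub>ij</sub>))),

with category probabilities the adjacent differences of the cumulative
curves. Discriminations are drawn from U(1.5, 2), thresholds from sorted
N(0, 1) draws. Latent traits are N(0, 1) or Beta(α, β) standardized
analytically to mean 0, variance 1 (13 reference/focal distribution
conditions, from all-normal to opposite high skew). Uniform DIF is injected
by adding a constant Δ ∈ {0.25, 0.5, 1.0} to every threshold of one studied
item in the focal group.

**Detection.** A single-factor MIMIC model is fitted by normal-theory maximum
likelihood on the mean/covariance structure of (items, group):

- θ = γ·x + ζ (the group regression on the latent trait),
- y<sub>i</sub> = τ<sub>i</sub> + λ<sub>i</sub>θ + β·x·[i = studied] + ε<sub>i</sub>,

where x is the 0/1 group code. A nonzero direct path β means the studied
item's expected score differs between groups at equal trait levels — uniform
DIF. Each item is tested in turn with the remaining items as anchors via the
two-sided Wald statistic z = β̂ / se(β̂) at α = 0.05. Fits report convergence
and Heywood-case flags plus RMSEA, RMR, TLI, CFI and GFI.

**Monte Carlo.** The factorial design crosses 5 sample-size ratios
(R100/F100 … R500/F100) × 2 DIF magnitudes × 2 scale lengths (5, 10) ×
3 category counts (3, 5, 7) × 13 trait conditions = 780 scenarios. Power is
the rejection rate on the true DIF item; Type I error is the mean rejection
rate over DIF-free items. Everything is reproducible from one base seed.

## Worked example

```python
from mimicsim import Scenario, generate_dataset, evaluate_dataset, run_scenario

# one dataset: medium DIF on item 1, both traits normal
data = generate_dataset(Scenario(n_ref=100, n_focal=100, dif_magnitude=0.5,
                                 n_items=5, n_categories=3, condition_id=13,
                                 seed=7))
for d in evaluate_dataset(data, alpha=0.05):
    print(f"item {d.item + 1}: beta={d.beta_hat:+.3f} z={d.z:+.2f} "
          f"p={d.p_value:.4f} flagged={d.rejected}")
```

```
item 1: beta=-0.310 z=-3.03 p=0.0025 flagged=True
item 2: beta=+0.065 z=+0.73 p=0.4656 flagged=False
item 3: beta=-0.055 z=-0.54 p=0.5859 flagged=False
item 4: beta=+0.058 z=+0.47 p=0.6400 flagged=False
item 5: beta=-0.079 z=-0.71 p=0.4750 flagged=False
```

The injected threshold shift on item 1 lowers the focal group's expected
score at equal trait levels, so its direct path is clearly negative and
flagged; the DIF-free items are not. Replicating that scenario estimates its
operating characteristics:

```python
res = run_scenario(Scenario(100, 100, 0.5, 5, 3, 13, seed=7), 500)
print(res.power, res.type1_error, res.n_converged)   # 0.668 0.052 500
```

i.e. medium uniform DIF in a 200-subject, 3-category design is detected about
two-thirds of the time while DIF-free items are flagged at roughly the
nominal 5% level.

The same machinery is scriptable from the shell:

```sh
mimicsim simulate --delta 0.5 --seed 7 --out data.csv
mimicsim test --data data.csv --alpha 0.05 --out decisions.csv
mimicsim grid --config condition13 --reps 200 --seed 1 --out results.csv
mimicsim aggregate --results results.csv --factor delta
```

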
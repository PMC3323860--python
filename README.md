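# mimofilter

Causal feature selection for multiple-output classification problems —
many continuous features (for example genome-wide expression), one
primary binary outcome (for example 5-year survival risk) and one or
more secondary binary outcomes (for example tumor grade and size) that
are different manifestations of the same underlying condition.

## The problem

Conventional information-theoretic filters rank features by their mutual
information with the outcome. In a causal system this systematically
favors *downstream effects* of the disease over its *upstream causes*:
an effect of the phenotype can carry more predictive information than
any single cause, yet it is useless as an intervention target. When
several outcomes reflect the same latent condition, the sign of the
three-way interaction information distinguishes the two situations:

- **I(xᵢ; xₖ; y) < 0** (synergy): conditioning on y *increases* the
  dependence between xᵢ and xₖ — the signature of a collider, i.e. of
  two variables that jointly cause y (directly or through a latent
  mediator);
- **I(xᵢ; xₖ; y) > 0** (redundancy): conditioning on y *decreases* the
  dependence — the signature of common-cause or chain patterns, i.e. of
  downstream effects.

## The filter

All mutual-information terms use the Gaussian approximation
I = −½ ln(1 − ρ²), with the point-biserial correlation for the binary
outcomes. For a feature pair and m targets the structural score is

    C(xᵢ, xₖ) = −(1/m) Σⱼ I(xᵢ; xₖ; yⱼ)

so that jointly causal pairs score high. Forward selection then picks,
at step d + 1,

    x* = argmax_k  I(xₖ; y₁) + (λ/d) Σ_{xᵢ ∈ S} C(xᵢ, xₖ)

where S is the current selection and λ ≥ 0 is the degree of causality:
λ = 0 is exactly the classical relevance ranking, larger λ trades
relevance for causal evidence. Interaction terms are cached so each
(pair, target) triple is estimated once per run.

The package also provides the linear-Gaussian causal-network simulator
used to benchmark cause prioritization, naive-Bayes accuracy evaluation
(AUC, 1−RMSE, SAR, F), and the meta-analytic multi-cohort protocols
(Fisher-z pooled correlations; repeated stratified holdout and
leave-one-dataset-out validation with McNemar/Wilcoxon/Holm win–loss
comparisons).

## Worked example

Simulate the default 40-node benchmark (three indirect causes → five
direct causes → a latent disease node → three binarized targets →
seventeen effects, plus eleven isolated features) and rank the 36
observed features with and without the causality term:

```python
from mimofilter import FilterConfig, causal_forward_rank, default_network, simulate
from mimofilter.prioritization_eval import average_cause_rank, top_k_cause_rate

spec = default_network(seed=42, sigma=0.1)          # 40-node benchmark DAG
data = simulate(spec, n_samples=100, seed=43)       # 100 samples, median-split targets
causes = {f for f, role in data.truth.items() if role == "direct_cause"}

for lam in (0.0, 2.0):
    cfg = FilterConfig(lambda_=lam, rank_all=True)
    ranking = causal_forward_rank(data.features, data.targets, cfg)
    print(
        f"lambda={lam:3.1f}  top of ranking: {ranking.ordered_ids[:5]}  "
        f"mean cause rank: {average_cause_rank(ranking, causes):5.2f}  "
        f"top-5 cause fraction: {top_k_cause_rate(ranking, causes):.1f}"
    )
```

```
lambda=0.0  top of ranking: ['n27', 'n13', 'n25', 'n22', 'n19']  mean cause rank: 19.00  top-5 cause fraction: 0.0
lambda=2.0  top of ranking: ['n27', 'n33', 'n7', 'n8', 'n6']  mean cause rank: 11.40  top-5 cause fraction: 0.6
```

At λ = 0 the top five slots are all effect nodes (n13–n29) — highly
predictive but downstream of the disease. At λ = 2 three of the five
direct causes (n6, n7, n8) enter the top five and the causes' mean
position improves from 19.0 to 11.4 out of 36.

The same operations are available from the shell:

```sh
mimo simulate --n 100 --sigma 0.1 --trials 1 --seed 42 --out sim/
mimo rank --matrix sim/trial_0000/features.tsv --targets sim/trial_0000/targets.tsv \
     --primary y1 --secondary y2,y3 --lambda 2.0 --out ranking.tsv
mimo eval-synthetic --trials 150 --sigmas 0.05,0.1,0.2 --lambdas 0,0.5,1,2,5 --out curves.tsv
mimo protocol --manifest studies.json --mode lodo --v 20,50 --lambdas 0,1,2 --out results/
```

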
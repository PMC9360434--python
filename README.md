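# cladepath

Phylogenetic path analysis of niche evolution and diversification.

`cladepath` is for comparative biologists asking *why* a clade is species
rich: does divergence in resource use (e.g. an herbivorous insect's host
plants) drive speciation directly, or does it mainly raise the ecological
limits on richness while speciation is driven by divergence along
environmental niche axes tied to geography?  The package builds the niche
descriptors, computes tip-level rate statistics, and pits competing causal
hypotheses against each other with phylogenetic confirmatory path models.

## What it computes

**Niche space.** From a binary species × host-plant-family incidence
matrix: Jaccard distances, principal-coordinates host-use axes, and
Shannon host breadth H = −Σ pᵢ ln pᵢ.  From occurrence records and gridded
environmental layers: per-species means and 25–75% quantile ranges of each
variable, reduced by PCA to environmental niche axes.

**Tip rates.** The DR speciation-rate index,

    DR_i = ( Σ_j  l_j · 2^{−(j−1)} )^{−1},

the inverse of the root-path branch lengths of tip *i* with each more
rootward branch down-weighted by ½; and a TR trait-rate index per niche
variable — maximum-likelihood Brownian-motion ancestral states are
reconstructed, and the between-node differences along each tip's root path
are summed.  Phylogenetic independent contrasts (PICs) render both
statistically independent across the tree.

**Causal model comparison.**  Each hypothesis is a DAG.  Its d-separation
basis set — one claim X ⟂ Y | pa(X) ∪ pa(Y) per non-adjacent pair — is
tested by partial regressions (GLS under Brownian-motion covariance for
raw cross-species data; OLS through the origin for contrasts), combined
into Fisher's C = −2 Σ ln pᵢ, and ranked by CICc = C + 2qn/(n − q − 1).
The same DAG is fitted as a recursive Gaussian path model giving
standardized (SMD) edge coefficients ± se, AIC, and a chi-square goodness
of fit; direct, indirect and total effects follow the path-tracing rules
(indirect = sum over paths of the product of coefficients).

A seeded synthetic-data generator (birth–death trees, clade-rate BM
traits, clustered host incidence, autocorrelated environmental surfaces,
known-coefficient structural systems) makes every stage testable without
any external data.

## Worked example

Simulate a 300-species world in which environmental-niche evolution drives
host-use evolution, which drives speciation, then ask which causal model
the contrasts support:

```python
import pandas as pd
from cladepath import CausalDAG, PathModel, compare_models, pic
from cladepath.synth import simulate_rate_world

tree, traits = simulate_rate_world(n_tips=300, coefficients=(0.7, 0.5), seed=42)
contrasts = pd.DataFrame(
    {c: pic(tree, traits[c])["contrast"] for c in traits.columns}
)

chain = CausalDAG(
    ["env_rate", "host_rate", "speciation"],
    [("env_rate", "host_rate"), ("host_rate", "speciation")],
    name="env->host->speciation",
)
collider = CausalDAG(
    ["env_rate", "host_rate", "speciation"],
    [("env_rate", "speciation"), ("host_rate", "speciation")],
    name="independent causes",
)
fits = [PathModel(dag=d, mode="contrasts-ols").fit(contrasts)
        for d in (chain, collider)]
print(compare_models(fits, criterion="cicc")[["name", "C", "CICc", "AIC", "delta"]])
print(fits[0].coefficients_.round(3))
print(fits[0].effects().round(3))
```

Output:

```
                    name           C        CICc          AIC       delta
0  env->host->speciation    0.225241    6.306597  2258.417359    0.000000
1     independent causes  225.743238  233.879292  2479.374426  227.572695
        from          to   coef     se    p
0   env_rate   host_rate  0.722  0.040  0.0
1  host_rate  speciation  0.489  0.051  0.0
        from          to  direct  indirect  total
0   env_rate   host_rate   0.722     0.000  0.722
1   env_rate  speciation   0.000     0.354  0.354
2  host_rate  speciation   0.489     0.000  0.489
```

The generating chain wins decisively (ΔCICc ≈ 228: the collider model's
basis set claims env ⟂ host, which the data reject), the standardized
coefficients recover the generating values 0.7 and 0.5 within sampling
error, and the indirect effect of environmental-niche evolution on
speciation is the product 0.722 × 0.489 ≈ 0.354 SMD.

## Command line

```
cladepath synth --seed 1 --n-tips 371 --outdir bundle    # synthetic input bundle
cladepath dr   --tree tree.nwk                           # DR per tip
cladepath tr   --tree tree.nwk --traits traits.tsv       # TR per trait
cladepath pic  --tree tree.nwk --traits traits.tsv       # contrasts
cladepath dsep --dag model.txt                           # basis set
cladepath fit / compare / effects                        # path models
cladepath run-richness  --config run.yaml                # genus-richness analysis
cladepath run-speciation --config run.yaml               # speciation-rate analysis
```

DAG files are plain text (`A -> B` per edge, `A ~~ B` for a free
correlation); run configs are YAML (see `RunConfig` for the keys).  All
outputs are TSV/JSON with a per-stage audit log.

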
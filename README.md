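# stemnet

Functional connectomics of the human brainstem and cortex: a tested,
reusable pipeline from parcellated resting-state fMRI time-series to hubs,
brainstem communities, cortical gradients, receptor dominance profiles, and
spatial-null-corrected map comparisons.

## The problem

The brainstem's few cubic centimetres house dozens of nuclei that project
throughout the cortex, yet most functional-connectomics work treats the
cortex in isolation. Given parcellated time-series for 400 cortical regions
and 58 brainstem nuclei per subject, this package answers, with tested
code:

- **Connectome + QC** — subject and group functional connectomes (Pearson
  FC, group mean), temporal SNR and its association with parcel size,
  distance dependence of FC, Welch tests between connection classes, and
  split-half reliability (`stemnet.connectome`).
- **Hubs** — weighted degree (sum of signed FC over a seed set) in both
  directions, class-binned one-way ANOVA, correlations with annotation maps
  under spatial nulls, and meta-analytic term decoding (`stemnet.hubs`).
- **Similarity beyond the dominant pattern** — the brainstem weighted-degree
  vector is regressed out of every region's brainstem connectivity profile;
  Spearman correlations of the residual profiles give brainstem × brainstem
  and cortex × cortex similarity matrices (`stemnet.similarity`).
- **Communities** — signed-modularity Louvain

  Q(γ) = (1/v⁺) Σᵢⱼ (w⁺ᵢⱼ − γp⁺ᵢⱼ) δ(σᵢ,σⱼ) − (1/(v⁺+v⁻)) Σᵢⱼ (w⁻ᵢⱼ − γp⁻ᵢⱼ) δ(σᵢ,σⱼ)

  with consensus clustering over 250 runs, z-Rand stability, and a
  resolution sweep γ = 0.1–6.0 (`stemnet.communities`).
- **Gradients** — diffusion map embedding of the cortical similarity matrix
  (top-10% row sparsification, cosine affinity, α = 0.5) and pole-wise
  brainstem degree maps (`stemnet.gradients`).
- **Chemoarchitecture** — multiple regression of community degree maps on 18
  receptor/transporter densities with exhaustive dominance analysis
  (Shapley decomposition of adjusted R²; Σ dominance = R²_adj exactly)
  (`stemnet.chemoarch`).
- **Spatial nulls** — "spin tests": uniform random rotations of each
  hemisphere's spherical parcel coordinates (mirrored across hemispheres),
  Hungarian one-to-one reassignment, and permutation p-values
  (`stemnet.nulls`).
- **Synthetic data** — a latent-factor generator that plants a
  weighted-degree pattern, five brainstem communities coupled to distinct
  cortical networks, and a unimodal–transmodal-like cortical gradient in
  multi-subject time-series, so every stage has a ground-truth test surface
  (`stemnet.synthetic`).

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

```python
import numpy as np
from scipy import stats
import stemnet as sn

# a synthetic 458-node, 20-subject study with planted structure
spec = sn.SyntheticSpec(seed=1)
geometry, nodes = sn.make_geometry(spec)
spec = spec.realize(nodes)
timeseries = sn.sample_timeseries(spec, geometry)

# group connectome and hub maps
fc = sn.group_average([sn.compute_fc(ts) for ts in timeseries])
t, p = sn.compare_fc_blocks(fc, nodes)
degree = sn.weighted_degree(fc, seed_idx=nodes.cortex_idx,
                            target_idx=nodes.brainstem_idx)
print(f"Welch t (brainstem-cortex vs within-brainstem) = {t:.1f}")
print(f"degree vs planted loading: rho = "
      f"{stats.spearmanr(degree.values, spec.global_loading[nodes.brainstem_idx])[0]:.3f}")

# residualize, cluster the brainstem, embed the cortex
res = sn.residualize_profiles(fc, nodes)
simB = sn.profile_similarity(res, axis="brainstem")
cons = sn.consensus_partition(sn.SignedGraph.from_similarity(simB),
                              gamma=3.0, n_reps=50, seed=7)
print(f"communities at gamma=3.0: {cons.n_communities} "
      f"(z-Rand mean {cons.zrand_mean:.1f})")

simC = sn.profile_similarity(res, axis="cortex")
gradient = sn.diffusion_embedding(simC)
rho = stats.spearmanr(gradient.first, spec.gradient_loading)[0]
print(f"first gradient vs planted axis: |rho| = {abs(rho):.3f}")
```

prints

```
Welch t (brainstem-cortex vs within-brainstem) = -47.4
degree vs planted loading: rho = 0.973
communities at gamma=3.0: 5 (z-Rand mean 39.0)
first gradient vs planted axis: |rho| = 0.986
```

The Welch statistic compares the two FC distributions (negative here
because in the latent-factor model the brainstem's shared factors make
within-brainstem FC stronger than brainstem–cortex FC); the degree map
recovers the planted global loading almost perfectly; consensus clustering
at γ = 3.0 finds the five planted communities with high run-to-run
stability; and the first diffusion gradient tracks the planted cortical
axis.

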
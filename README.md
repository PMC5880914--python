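# elevassembly

Statistical toolkit for asking **how soil bacterial communities assemble
along elevational gradients**: does deterministic environmental filtering
(soil pH, vegetation) structure the communities, or do spatial/stochastic
processes dominate — and does the answer change between the lower and higher
parts of a mountain transect?

The package implements the complete inference chain used in elevational
microbiome surveys, end to end:

- **α-diversity** — OTU richness and Faith's phylogenetic diversity
  (rooted convention), with rarefaction to a common sequencing depth and
  Kruskal–Wallis multiple comparisons across sites.
- **β-diversity** — binary Jaccard, Bray–Curtis, and abundance-weighted
  Jaccard (Ružička) dissimilarities; NMDS (Kruskal stress-1, monotone
  regression with primary tie handling); distance-decay-of-similarity (DDS)
  slopes per elevational section.
- **Permutation tests** — PERMANOVA (Adonis pseudo-*F*), ANOSIM *R*, MRPP
  (δ, *A*), Mantel and partial Mantel, PERMDISP (multivariate dispersion),
  all with add-one permutation p-values, `p = (b + 1)/(m + 1)`, and an
  exact exhaustive-enumeration mode for small *n*.
- **Null model** — Raup–Crick-style randomization: each sample's richness is
  conserved while species are redrawn from the regional pool with
  occupancy-frequency weights; the **β-deviation**
  `z = (J_obs − mean J_null) / sd J_null` quantifies how far each pair's
  Jaccard similarity sits from the null expectation, and a paired
  observed-vs-null PERMDISP tests per-site dispersion against the null.
- **Variation partitioning** — PCNM spatial eigenvectors (minimum-spanning-
  tree truncation), dbRDA on PCoA axes, double-stopping forward selection,
  and the four-fraction decomposition of adjusted R²:
  `[a]` pure environment, `[b]` spatially structured environment,
  `[c]` pure space, `[d] = 1 − (a+b+c)` residual, with a bootstrap test of
  `a` vs `c`.
- **PLS path modeling** — latent climate → plant → soil → community
  composites (reflective mode A, path weighting scheme), path coefficients,
  per-latent R², bootstrap CIs, and the goodness of fit
  `GOF = sqrt(mean communality × mean R²)` with the conventional
  GOF > 0.7 acceptability threshold.
- **Synthetic gradient generator** — a 12-site, 1800–4100 m transect with a
  pH regime change between 2600 and 2800 m, five vegetation bands, and
  communities assembled through three separable channels (Gaussian pH
  niche, vegetation affinity, exponential spatial kernel), so every
  downstream method can be validated against known ground truth.

## Worked example

```python
import numpy as np
from elevassembly import (
    GradientScenario, GradientSections, generate_metadata, generate_community,
    dissimilarity_matrix, permanova, null_randomize, beta_deviation,
    null_permdisp_test,
)

scenario = GradientScenario(n_sites=6, samples_per_site=6, n_otus=400,
                            sequencing_depth=3000, seed=42)
metadata = generate_metadata(scenario)
table = generate_community(scenario, metadata)
sections = GradientSections.from_metadata(metadata)

dm = dissimilarity_matrix(table, metric="jaccard_binary")
res = permanova(dm, sections.labels(table.sample_ids),
                n_permutations=999, seed=0)
print(f"PERMANOVA lower vs higher: pseudo-F = {res.statistic:.2f}, "
      f"p = {res.p_value:.3f}")

ensemble = null_randomize(table, n_iterations=999, seed=0)
dev = beta_deviation(table, ensemble)
print(f"mean beta-deviation z = {dev.mean_z():.2f}")

per_site = null_permdisp_test(table, ensemble, metadata.data["site_id"],
                              n_permutations=199, seed=0)
print(per_site.round(3))
```

prints

```
PERMANOVA lower vs higher: pseudo-F = 33.17, p = 0.001
mean beta-deviation z = 2.20
       observed_centroid  null_centroid         F  p_value  n_samples
group
E1800              0.171          0.517   663.533    0.020          6
E2260              0.149          0.472  1891.628    0.020          6
E2720              0.187          0.369   221.577    0.035          6
E3180              0.173          0.361   310.431    0.045          6
E3640              0.143          0.453  1335.326    0.030          6
E4100              0.180          0.511  1135.799    0.045          6
```

Read: the community split between the lower and higher sections is far
stronger than chance (pseudo-F 33.2 at the permutation floor p = 0.001);
pairs of communities are on average 2.2 null standard deviations *more*
similar than the richness-conserving null expects; and at every site the
observed dispersion around the site centroid (≈0.15–0.19) sits well below
the null dispersion (≈0.36–0.52) — the signature of environmental
filtering.

The same stages are scriptable from a shell:

```bash
elevassembly simulate --seed 1 --out run/
elevassembly diversity --table run/otu_table.tsv --tree run/tree.nwk --out run/
elevassembly test --distance run/distance_jaccard_binary.tsv \
    --metadata run/metadata.tsv --test permanova --group site_id --out run/
elevassembly nullmodel --table run/otu_table.tsv --metadata run/metadata.tsv \
    --out run/
```

Every subcommand writes tabular output plus a `manifest.json` with the
seed, parameters and package version.

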
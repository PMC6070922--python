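# srfusion

Similarity regression fusion (SRF) of multi-omics patient data for cancer
subtype discovery.

Cancer cohorts are routinely profiled on several molecular layers at once —
gene expression, DNA methylation, miRNA expression — and patients cluster
into subtypes with distinct prognoses. Any single layer gives a noisy,
biased picture of patient-to-patient similarity. `srfusion` integrates K
omics views over one cohort into a single corrected similarity matrix and
clusters patients on it, for computational biologists who want an
interpretable, regression-based alternative to iterative network-fusion
methods, together with the survival-based machinery needed to validate the
resulting subtypes.

## The model

For each view k, patient similarity is the Pearson correlation
S<sub>k,ij</sub> of the two patients' feature vectors, mapped to the real
line by the Fisher z-transformation r = arctanh(S). The core step corrects
each pairwise similarity using the other views: for every pair (i, j) and
every target view k, an ordinary least-squares model

&nbsp;&nbsp;&nbsp;&nbsp;r′<sub>k,ij</sub> = β₀ + Σ<sub>t≠k</sub> β<sub>t</sub> r<sub>t,ij</sub> + ε,&nbsp;&nbsp;ε ~ N(0, σ²<sub>k,ij</sub>)

is trained on the similarities of i and j to all *other* patients across
views (2(n−2) rows per pair) and evaluated at the pair's own cross-view
similarities. The rationale: patients of one subtype relate to the rest of
the cohort consistently in every layer, so a pair's similarity in view k is
predictable from the other layers, and the residual variance σ² estimates
that pair's similarity bias. The corrected value becomes a same-subtype
possibility p = exp(μr′)/(1+exp(μr′)) (gain μ, default 3), is sharpened by
a scaled exponential transform with shift t (default 1), and the K per-view
matrices are fused by a convex combination W = Σ w<sub>k</sub> PM′<sub>k</sub>
with weights on the probability simplex. Patients are partitioned by
spectral clustering on the normalized Laplacian
L = I − D<sup>−1/2</sup> W D<sup>−1/2</sup>. Because the best weighting is
unknown a priori, the simplex is searched on a 0.05-step lattice and each
weighting scored by the log-rank p-value of its clusters' survival curves.

## Worked example

```python
import srfusion as sf

# synthetic 90-patient cohort: 3 subtypes, 3 omics views, cluster-linked survival
views, truth, survival = sf.simulate(sf.SimSpec(seed=1))
model = sf.SRF(views, sf.RunConfig(n_clusters=3, random_seed=1), survival=survival)
res = model.fit()          # equal weights by default
print(res.summary())
print("ARI vs planted truth:", res.ari_against(truth))
```

prints

```
Similarity Regression Fusion results
============================================
samples: 90    views: 3    clusters: 3
mu: 3.0    t: 1.0    scale: increasing    regression: separate
view weights: view1=0.333, view2=0.333, view3=0.333
cluster sizes: C1=30, C2=30, C3=30
mean silhouette: 0.977 (coherent at the 0.15 rule)
log-rank: chi2 = 21.965 (df=2), p = 1.7e-05
ARI vs planted truth: 1.0
```

The three planted subtypes are recovered exactly (ARI = 1), the clustering
is coherent (mean silhouette 0.98, far above the 0.15 coherence rule), and
the clusters separate survival strongly (log-rank p ≈ 1.7×10⁻⁵).
`model.select_weights()` returns the full 231-row ranked table of the
0.05-step weight lattice. The same pipeline is scriptable from the shell:

```bash
srfusion simulate --n-samples 90 --out-dir data/
srfusion run data/view1.tsv data/view2.tsv data/view3.tsv \
    --survival data/survival.tsv --n-clusters 3 --gridsearch --out-dir out/
```

which writes every intermediate similarity stage, the labels, Kaplan–Meier
curves per cluster, and a manifest of content hashes.

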
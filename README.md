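# taphos3d

3D spatial statistics for bone surface modifications (BSM) in taphonomy and
zooarchaeology.

When a carnivore consumes a carcass, the tooth pits and scores it leaves on
long bones are not scattered at random: defleshing ergonomics and muscle
insertions channel damage to recurrent anatomical locations.  `taphos3d`
records marks as 3D landmarks on triangulated bone meshes in a canonical
anatomical frame and asks, statistically, whether and how their spatial
arrangement departs from randomness — and whether the pattern is reproduced
bilaterally and is element-specific.  It is written for taphonomists and
zooarchaeologists who want analytical (not visual) support for agency
attributions such as "these long bones were consumed felid-style".

## What it computes

**Second-order summary functions with Monte Carlo envelopes.**  Mark
reference coordinates inside a box window `W` form a point pattern with
intensity λ = n/|W|.  Against the null of complete spatial randomness (CSR,
a homogeneous Poisson process) the package estimates, on an r-grid of 512
values:

- Ripley's `K3(r)` (translation edge correction; CSR: `(4/3)πr³`), and its
  Besag-type transform `L3(r) = (3K(r)/4π)^{1/3}` so that CSR plots as the
  identity `L(r) = r`;
- the nearest-neighbour function `G3(r)` (reduced-sample border correction;
  CSR: `1 − exp(−λ(4/3)πr³)`);
- the empty-space function `F3(r)` by the digital (voxel) method with a
  discretisation-matched CSR reference;
- the pair-correlation function `pcf3(r)` (Epanechnikov kernel, translation
  correction; CSR: 1).

Inference is graphical: pointwise min/max envelopes over 500 CSR simulations
conditioned on the observed count.  An observed curve above the envelope
indicates clustering (reading reversed for `F3`).

**Bilateral wavelet coherence.**  Mark counts are binned along the bone's
long axis (humerus 25, femur 28, radius-ulna 30, tibia 35 ten-millimetre
bins).  The left/right count series of an element are compared by wavelet
coherence (Morlet ω₀ = 6, smoothed cross-wavelet spectra): `R²(s, t) ∈ [0, 1]`
resolves where along the bone and at which spatial scale the two sides
covary, the phase gives lead/lag, and pointwise significance comes from
AR(1) surrogate pairs.

**Bilateral PCA and multi-element clustering.**  Pooled left/right mark
coordinates are PCA-projected and each side is summarised by a 95%
confidence ellipse (χ²₂-scaled score covariance); the Jaccard area overlap
quantifies bilateral similarity.  Each element-side's feature vector (mean
observed K, F, G, pcf, mean nearest-neighbour distance, intensity) enters a
UPGMA (average-linkage, Euclidean) clustering; the bundled reference table
for a wild-lion-consumed assemblage is the worked example.

Everything is testable offline: the `synthetic` module generates capsule-like
bone phantoms and seeded CSR / Thomas-cluster / hard-core / anatomically
weighted mark processes.

## Worked example

Simulate a lion-like humerus pattern and test it against CSR:

```python
from taphos3d import PointPatternAnalysis, make_rgrid, simulate_lionlike

phantom, marks = simulate_lionlike("humerus", 80, seed=42)
model = PointPatternAnalysis.from_marks(marks)
model.r = make_rgrid(rmax=15, n=256)
model.grid_n = 32
print(model.fit(nsim=99, seed=0).summary())
```

```
3D point-pattern CSR analysis
  n = 80, window volume = 7.187e+05 mm^3, intensity = 0.0001113 mm^-3
  r grid: 256 values, rmax = 15 mm

  function    mean obs  % r above  % r below  % r inside  reading
  K3          1.06e+04      94.1%       0.0%        5.9%  clustered
  L3             11.63      92.6%       0.0%        7.4%  clustered
  G3            0.3154      39.1%       0.0%       60.9%  csr-consistent
  F3            0.1677       0.0%      70.3%       29.7%  clustered
  pcf3           42.96     100.0%       0.0%        0.0%  clustered
```

The anatomically weighted pattern (marks concentrated on the proximal end,
near-empty midshaft) drives K, L and pcf far above their CSR envelopes, and
F below its lower envelope — the empty-space signature of clustering.

Cluster the bundled reference feature table (standardised columns):

```python
from taphos3d import lion_feature_table, hclust_average, cut_tree, to_newick

tree = hclust_average(lion_feature_table(), scaling="zscore")
print(cut_tree(tree, 4))
```

```
{'lHum': 0, 'rHum': 0, 'lFem': 1, 'rFem': 1,
 'lRad': 2, 'rRad': 2, 'lTib': 3, 'rTib': 3}
```

Cutting the dendrogram at k = 4 recovers exactly the four skeletal elements,
each cluster holding its own left and right sides — tooth-mark patterning is
element-specific and bilaterally redundant.

A command-line interface mirrors the library:

```sh
taphos3d simulate --element humerus --model lionlike --n 80 --out marks.csv
taphos3d run marks.csv --seed 1 --out results/
taphos3d cluster features.csv --scaling zscore --k 4 --out tree
```

## Documentation

`docs/methods.md` describes the estimators, edge corrections, wavelet
parameterisation, the synthetic generators and every numerical design choice
in detail, including known limitations.
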
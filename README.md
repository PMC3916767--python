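# olfnet

Self-organized odor pattern recognition in a model of the early mammalian
olfactory system, implemented as a testable rate-level pipeline with an
optional reduced spiking backend.

## The problem

How can a sensory system wire itself so that downstream cortex recognizes
odors robustly — across concentrations, under noise, and from incomplete
input — without a supervisor dictating the wiring?  This package
implements a multi-stage answer for the olfactory pathway:

1. **Odor panels** (`olfnet.odor_space`).  Artificial odorant–receptor
   affinity patterns 𝒜ᵢⱼ ∈ [0, 1] are generated from a distance
   distribution in a physico-chemical descriptor space: virtual olfactory
   receptors (ORs) are k-means centroids of a clustered odorant cloud,
   centroid–odorant distances *d* are pooled over many clusterings and
   fitted with a trimodal normal mixture (expected value E[𝒟] = 7.7), and
   affinities follow 𝒜 = exp(−(d/E[𝒟])²).  Each pattern activates 30–50%
   of the ORs.  Noise (uniform ±σ, clipped), concentration offsets,
   incomplete patterns and two-odor mixture morphs are derived here too.
2. **Epithelium and bulb** (`olfnet.epithelium`, `olfnet.bulb`).  Each OR
   is expressed by a family of 800 olfactory receptor neurons (ORNs) with
   saturating dose–response curves and graded sensitivities; the affinity
   is read as the odor activity value, OAV = c/(1+c).  Sorted by
   sensitivity into 8 groups per glomerulus, adjacent group responses are
   subtracted (periglomerular inhibition) to give each mitral/tufted (MT)
   cell a **concentration-interval tuning curve**; glomerular output is
   divisively normalized, so 320 MT cells code *which* intervals are
   occupied rather than raw intensity.
3. **Self-organization** (`olfnet.selforg`).  From MT spike counts over 50
   training patterns: per-cell normalization f′, glomerular
   half-normalization ξ, activation probabilities, a mutual-information
   distance D = 1 − I/E between MT cells, a 3-D metric MDS embedding, a
   vector quantization assigning each MT cell to its m = 4 nearest
   hypercolumn (HC) centroids, and a second per-HC quantization mapping
   patterns onto minicolumns (MCs).  Weights and biases follow the
   Hebbian–Bayesian BCPNN rule,
   w = log p_ij/(pᵢpⱼ),  β = log pⱼ.
4. **Abstract cortex** (`olfnet.cortex_abstract`).  Support
   s = Σ w ξ, activation o = exp(β+s) for s > 0, per-HC
   half-normalization, BCPNN-learned recurrent MC→MC weights (none within
   an HC) relaxed over a few iterations, and a supervised BCPNN readout
   layer (one indicator unit per training label).  Classification =
   argmax readout support.
5. **Wiring** (`olfnet.wiring`).  Abstract weights are linearly mapped to
   conductances (negative weights route through RSNP interneurons; caps
   3 nS / 1.5 nS; 5 pS discard floor) and expanded into a cell-level
   synapse table over 10,800 pyramidal, 1,440 RSNP and 2,160 basket
   cells, plus the fixed intra-cortical circuit and an analytic
   connection census.
6. **Spiking backend** (`olfnet.spiking_backend`).  A reduced
   conductance-based LIF network (AMPA 10 ms / NMDA ≈150 ms / GABA 20 ms)
   driven by Poisson MT input for qualitative attractor and
   winner-take-all checks at small scale.

Five evaluation tasks (`olfnet.tasks`) exercise the trained system:
recognition, concentration invariance, noise robustness, pattern
completion (with and without the recurrent weights) and pattern rivalry
on mixture morphs.

## Worked example

```python
import numpy as np
from olfnet import odor_space as osp, pipeline as pl

panel = osp.generate_pattern_set(50, 40, seed=1)   # 50 patterns, 40 ORs
model = pl.train(panel, seed=1)                    # full self-organization
res = pl.classify(model, panel)
print("retest correct:", int((res.labels == model.labels).sum()), "/ 50")

noisy = osp.apply_noise(panel, sigma=0.05, seed=2)
print("sigma=0.05 correct:",
      int((pl.classify(model, noisy).labels == model.labels).sum()), "/ 50")

rows = np.array([osp.make_incomplete(panel, k, 0.5, seed=100 + k)
                 for k in range(50)])
partial = osp.AffinityMatrix(rows, rows > 0)
print("50% completeness correct:",
      int((pl.classify(model, partial).labels == model.labels).sum()), "/ 50")
```

prints

```
retest correct: 50 / 50
sigma=0.05 correct: 50 / 50
50% completeness correct: 50 / 50
```

i.e. every training pattern is recognized on retest, recognition survives
±0.05 affinity noise on every matrix entry, and the attractor cortex still
recognizes all patterns when half of each odor's active receptors are
silenced.

The same runs are available from the shell:

```bash
olfnet task1 --seed 1 --out runs/task1
olfnet task4 --seed 1 --out runs/task4
olfnet census --out runs/census
```

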
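# Methods

## Overview

`olfnet` models the feedforward olfactory pathway — epithelium, olfactory
bulb (OB), piriform-like cortex, readout — as a self-organizing pattern
recognition system.  The guiding ideas: mitral/tufted (MT) cells code the
*concentration interval* of their glomerulus's odorant rather than raw
intensity; the bulb→cortex projection is organized by the mutual
information between MT cells; cortical modules learn with a
Hebbian–Bayesian (BCPNN) rule and act as an attractor memory.  The
reference scale is 40 ORs × 800 ORNs, 320 MT cells, a cortex of 12
hypercolumns (HCs) × 30 minicolumns (MCs), and 50 training patterns.

The default evaluation path is rate-based and deterministic given a seed:
learning consumes spike *counts* over a 1600 ms window, so no spiking
simulation is needed to train or classify.  A reduced spiking backend
exists separately for qualitative dynamical checks.

## Odor panels

A synthetic descriptor space (cluster-of-Gaussians point cloud) stands in
for a real physico-chemical descriptor table.  Virtual ORs are k-means
centroids; all centroid–odorant Euclidean distances, pooled over repeated
clusterings and centroid counts (each trial weighted by 1/n_centroids),
are fitted per centroid count with a 3-component univariate Gaussian
mixture (scikit-learn `GaussianMixture`), and the component parameters
are averaged after sorting by mean.  Trials where k-means cannot place
non-empty centroids are skipped and logged.

When no fit is run, a surrogate trimodal distribution is used: weights
(0.25, 0.5, 0.25), means (4.9, 7.7, 10.5), sds (1.5, 1.8, 2.2) — chosen
so the expected distance is exactly E[𝒟] = 7.7, the scale constant of the
affinity transformation.  These are surrogate values, not fitted ones.

Distances map to affinities through `exp(−sharpness·(d/E[𝒟])²)` with
sharpness 1.0.  The form is smooth, strictly decreasing and equals 1 at
d = 0; the sharpness default was calibrated once so that ~10⁴ sampled
pairs cover essentially the whole affinity range [0.01, 0.99].  Each
pattern activates a uniformly drawn 30–50% subset of the ORs; inactive
entries are exactly zero.

Stimulus variants: uniform ±σ noise added to *every* entry then clipped
to [0, 1] (so silent ORs can acquire spurious input); concentration
offsets added to active ORs only; incompleteness by retaining
⌈completeness·n_active⌉ random active ORs; two-odor mixtures that take
`round(b·|active(B)|)` ORs of one parent and `round((1−b)·|active(R)|)`
of the other, nested along the fraction grid so consecutive morphs differ
minimally.  If both parents contribute the same OR, the larger-fraction
parent wins (ties to B) — a deterministic rule where the behavior was
otherwise unspecified.

## Epithelium

ORN biophysics is reduced to a phenomenological rate curve: each ORN
fires at `r_max · H(max(0, OAV − onset)) / H(1 − onset)` where H is a
Hill function with per-ORN half-activation K and exponent 4.  The
`onset = 0.1` term is the rheobase of a spiking neuron: a stimulus must
open ≥10% of receptors before any spikes result.  This matters
functionally — without it, the most sensitive ORNs respond near-maximally
to σ ≤ 0.05 affinity noise and noise robustness is impossible; with it,
sub-onset noise on silent glomeruli is simply invisible, which is what
the thresholded biophysics of real ORNs provides.

Per family, half-activations are drawn log-uniformly over OAV ∈
[0.02, 0.8] and maximum rates uniformly over [40, 80] spikes/s.  Both are
sorted and paired (most sensitive ↔ highest max rate), making the family
a totally ordered set of non-crossing response curves.  This idealizes
the activity-dependent axon-sorting hypothesis that groups ORNs by
responsiveness, and it is what makes the group-difference code below
clean; with independently drawn maxima the adjacent-group differences
would not vanish at saturation.  OAV and concentration interconvert
exactly via c = OAV/(1−OAV).

## Bulb: the concentration-interval code

Each glomerulus's 800 ORNs are cut into 8 sensitivity-sorted groups of
100, one per MT cell.  MT cell g receives `max(0, G_g − G_{g+1})` — its
own group's mean rate minus the next less sensitive group's rate relayed
as periglomerular inhibition; the last MT keeps its own group drive and
covers the top of the range.  The difference of two adjacent saturating
curves is a bump: each MT cell is tuned to one concentration interval,
with peak positions ordered across the 8 cells.  The dendro-dendritic
circuitry that produces this in a biophysical bulb is represented only by
its computational outcome here (difference coding), as the underlying
synaptic strengths were tuned for exactly this effect.

Intra-glomerular inhibition is summarized as a divisive normalization:
when the summed MT rate of a glomerulus exceeds a target (40 spikes/s)
the vector is scaled down to it.  Since the pre-normalization total
approximately telescopes to the most sensitive group's rate, summed
glomerular output is approximately concentration-invariant over a wide
OAV range (the suite asserts < 50% variation over OAV ∈ [0.2, 0.9] — the
tolerance is this implementation's choice, as "approximately constant"
is not quantified elsewhere).  Rates convert to expected counts over the
1600 ms window; Poisson count noise is available (`poisson_noise=True`)
but off by default, keeping the rate path deterministic — background
noise belongs to the spiking backend, where it is modeled as Poisson
input.

## Self-organization and BCPNN

Counts f are normalized per cell over the training patterns
(f′ = f/Σ_k f; all-zero rows stay zero — the convention for cells silent
in every pattern), then half-normalized per glomerulus: wherever a
group's sum exceeds 1 it is divided down to 1, preserving a probabilistic
reading of MT activity.  Activation probabilities p_i = ⟨ξ_i⟩ and
p_ij = ⟨ξ_iξ_j⟩ feed the mutual-information distance
D = 1 − I/E (I = p_ij log(p_ij/p_ip_j), E = −p_ij log p_ij, with the
zero-probability guards D = 1 when E = 0 and self-distances forced to 0
for active units).  Natural logarithms are used throughout — the choice
of base cancels in classification and is absorbed by the linear
conductance mapping.

The D matrix is embedded in 3-D by metric MDS: SMACOF initialized from
the classical (Torgerson) solution, which makes the embedding
deterministic and drives stress to ~0 on exactly embeddable inputs.
k-means over the embedding places the 12 HC centroids (restarted until
no HC is empty; MT cells silent in all patterns are excluded and receive
no assignment); each MT cell then projects to its m = 4 nearest HCs.  A
second, per-HC k-means clusters the 50 patterns in the space spanned by
that HC's source MT cells (coordinates ξ), assigning each pattern one
active MC — the binary matrix ζ.  With fewer distinct pattern vectors
than MCs, surplus MCs stay unused.

BCPNN weights connect MT cells (graded pre-activity ξ) to MCs (binary
post-activity ζ), restricted to each MT cell's assigned HCs:
`w = log p_ij/(p_ip_j)` when both marginals are positive, `log 1/N_p`
when they are positive but the joint is zero (learned anti-correlation),
0 when either unit never activates (case precedence: the silent-unit case
dominates).  Biases are `β = log p` (or `log 1/N_p²` for silent units).

## Abstract cortex and recall

Support s = Σ w ξ; activation o = exp(β+s) for s > 0 (strictly), else 0;
per-HC half-normalization of o mirrors the glomerular one and implements
the soft winner-take-all that basket cells provide in the spiking
network.  (Internally the normalization is evaluated in log space — an
HC whose activation sum exceeds 1 gets its softmax — so large supports
cannot overflow.)  Recurrent MC→MC weights are learned by the same rule
from the training activations o′, with all within-HC pairs forced absent.
The readout layer is one BCPNN indicator unit per training *label*
(labels may be shared, as in concentration-invariance training, where
p_j = n_variants/N_p).

Recall relaxes the MC state n_iter = 3 times with
`s = s_ff + rec_gain · w_recᵀ o′` and classifies by argmax readout
support (ties broken to the lowest index and flagged).  The relaxation
loop is this package's rate-level stand-in for the spiking attractor
dynamics; `rec_gain = 0.05` because the recurrent log-odds weights sum
full log-probabilities over 12 HCs and are roughly an order of magnitude
larger than feedforward supports — applied at full strength they override
the stimulus entirely (and demonstrably hurt completion), while a
fractional nudge per iteration corrects borderline HC winners, which is
the regime in which removing the recurrent weights measurably degrades
completion.  This mirrors the free conductance-scaling parameters that
balance the feedforward and recurrent pathways in the spiking original.

Test stimuli are normalized by the *training* per-cell count totals, so a
weaker stimulus (incomplete, low concentration) produces proportionally
weaker ξ instead of being rescaled to look complete.

## Wiring translation

Abstract weights map linearly to conductances with separate positive and
negative scale factors.  Stated caps: the most negative MT→cortex weight
→ 3 nS (onto RSNP), the most negative PYR-origin weight → 1.5 nS; the
positive cap (2 nS) is a free parameter chosen to land "a few nS".
Anything below 5 pS is discarded.  Excitatory MT→MC entries fan out to
50% of the MC's 30 PYR cells (15), inhibitory ones to 75% of its 4 RSNP
cells (3); positive MC→MC weights become 45 distinct long-range PYR→PYR
pairs (5% of 900), negative ones 10 PYR × 3 RSNP; every PYR contacts
every readout unit (full density, signed weights, no floor).  At reduced
architectures these fan-outs rescale from the same fractions.  The static
circuit (PYR→PYR 25% within MC, PYR→basket and basket→PYR 70% within HC,
RSNP→PYR 70% within MC) is realized by Bernoulli draws, and all
conductances can be jittered ±10% to model natural variability.

The census reports analytic, architecture-determined counts next to
realized table rows.  Three reference tabulation entries disagree with
their own stated probability rules (basket→PYR "630" vs the 70% rule's
~1.36·10⁶; PYR→PYR "~75,500" vs 78,300; granule "32,000" vs the
200-per-MT rule's 64,000); the rules are treated as authoritative and the
discrepancies flagged in `census()["notes"]`.

## Reduced spiking backend

Point conductance-based LIF neurons replace the multi-compartment
Hodgkin–Huxley models: adapting PYR cells, fast-spiking basket cells
(no adaptation), regular-spiking RSNP cells, plain integrators for
readouts.  Excitatory synapses split into AMPA (10 ms) and NMDA (150 ms,
no magnesium-block nonlinearity) components; inhibition is GABA (20 ms).
MT cells are inhomogeneous Poisson sources under a puff (~400 ms) or
4 Hz sniff envelope, rescaled to preserve mean counts; BCPNN biases act
as constant currents onto PYR cells (the functional reduction of an
A-type potassium conductance); membrane potentials initialize from
N(−70, 5²) mV.  Euler integration at 0.1–0.2 ms; non-finite voltages
raise immediately with the offending configuration.

This backend is for qualitative checks at reduced scale (e.g. 10
glomeruli, 6 HC × 10 MC, 10 PYR/MC): sparse pyramidal participation
(< 15% of PYR firing more than one spike per pattern), within-HC
winner-take-all, and correct readout identification.  It does not
attempt the full-scale firing statistics of the original
multi-compartment model, whose ~70 hand-tuned biophysical parameters are
not recoverable from the text.

## Problem sizes and determinism

Default runs train on 50 patterns × 40 ORs and complete in seconds on a
single core: the evaluation tasks re-train the full pipeline per task and
classify hundreds of stimulus variants (1,000 noisy presentations in the
noise task, 900–1,800 in completion, 350 mixtures in rivalry).  Spiking
checks run at the reduced scale above for ~1 s of simulated time.  Every
stochastic step — panel draws, ORN parameters, k-means restarts, MDS
(via its deterministic initialization), noise, deletions, spiking — is
driven by one seed per entry point.

## What the synthetic generator does and does not capture

The generator reproduces the *statistical* structure the model consumes:
a broad, multi-modal distance distribution, affinities covering (0, 1],
sparse 30–50% activation, independent receptor channels.  It does not
model competitive or non-linear odorant–receptor interactions, receptor
antagonism in mixtures, chemotopic spatial structure, or real odorant
identities.  Passing tests therefore demonstrate the self-organization
and attractor machinery under the stated input statistics, not
performance on chemically realistic odor sets.

## Known limitations

- The affinity transformation and the surrogate trimodal parameters are
  reconstructions constrained only by E[𝒟] = 7.7 and the range-coverage
  requirement; fitted parameters of the original distance distribution
  were never tabulated.
- The abstract recall loop (iteration count, recurrent gain) is a
  construct of this package; the original's recurrence exists only in
  its spiking simulation.
- The concentration-invariance task trains variants with shared odorant
  labels; per-variant labels are available behind a switch, as the
  original readout construction is ambiguous on this point.
- Rivalry is scored by per-presentation aggregate readout support; the
  temporal switching dynamics of perceptual rivalry require the spiking
  path and are out of scope.
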
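# Methods

This note documents the models, decision rules and numerical choices behind
`voltscreen`, in the spirit of a methods section: what is computed, under
which assumptions, and what the defaults mean.

## The screening problem

On a boron-doped diamond electrode in Britton–Robinson buffer (0.1 mol/L,
pH 8.0), synthetic cathinones show two class-diagnostic reduction processes
in DPV: R1 near −1.3 V and R2 near −1.6 V vs Ag/AgCl. R1 spans
[−1.45, −1.15] V and R2 [−1.70, −1.45] V in this package, windows wide
enough to cover both the −1.40/−1.60 V family (G1, G2) and the least
cathodic member, the thiophene analogue α-PVT (−1.22/−1.47 V); the shared
−1.45 V boundary belongs to R2. No interferent in the library reduces
inside either window (paracetamol −0.24 V; MDMA/MDEA −0.70/−0.50 V), which
is what makes the rule selective.

Decision rules, applied to preprocessed traces:

1. **Positivity** — an R1-window reduction on the cathodic sweep. R2 is
   recorded but never required (it has lower sensitivity and is absent in
   some real samples), and R2 alone never suffices.
2. **Group assignment** (anodic sweep, evaluated top-down): any oxidation in
   (−0.40, −0.10) V → G6 (thiophene); otherwise the count *n* of oxidations
   in (+0.45, +1.40) V maps 5 → G4, 4 → G3, 3 → G2; *n* = 2 with both peaks
   in (+0.80, +1.10) V and no +0.60 V peak → G5; *n* ≤ 1 → G1. Patterns
   matching no rule (e.g. two peaks including +0.60 V) stay positive with no
   group. The negative-potential window excludes G6's oxidations from the
   count by construction.
3. **Mixtures** resolve to the candidate group with the larger expected
   anodic count (ties to the lower group index): a richer fingerprint
   dominates the combined trace.
4. **Interferent flags**: caffeine (+1.30 V oxidation), MDMA/MDEA (paired
   −0.70/−0.50 V reductions), paracetamol (−0.24 V reduction plus +0.21 V
   oxidation). Flags never alter positivity.

**Caffeine ambiguity.** Caffeine's +1.30 V oxidation coincides with the
terminal anodic process of the methylenedioxy groups G2–G4. The flag fires
only when the +1.30 V peak appears without an accompanying +0.60 V process,
or when it exceeds the next-largest anodic oxidation by a factor
(default 1.5). Consequence: caffeine at a concentration comparable to a
co-present methylenedioxy cathinone is not flaggable from the trace alone —
an intrinsic ambiguity of the fingerprint, not of the implementation. A
caffeine peak resolved next to a G1 fingerprint can also push the anodic
count to 2 and leave the group unassigned; positivity is unaffected.

## Synthetic signal model

Real traces for this method are not deposited, so all analyses run on a
generator whose structure is fully known:

```
I(E) = baseline(E)
     + Σ_peaks sign · a · c · r · gauss(E; Ep + ΔpH + jitter, w)
     + ε(E)
```

* **Grid**: −2.0 → +2.0 V (anodic) and +2.0 → −2.0 V (cathodic) at the
  instrument's 10 mV step (401 points).
* **Peaks**: unit-height Gaussians parameterized by full width at half
  maximum, default w = 0.07 V. Two processes 0.05 V apart merge into a
  single maximum at this width; the library's closest resolved pair
  (0.78/0.90 V) separates cleanly.
* **Amplitudes**: a = 0.05 μA per (μmol/L), times the concentration c and
  the peak's relative amplitude r (R1 = 1.0, R2 = 0.6 reflecting its lower
  sensitivity, oxidations 0.8). Heights are linear in concentration and
  additive over mixture components.
* **Baseline**: cubic polynomial (2.0, 0.5, −0.3, 0.1 μA in ascending
  powers) plus signed exponential edge currents (12 μA scale, 0.05 V decay)
  mimicking solvent discharge at the window edges; the published crop
  windows exclude essentially all of the edge rise, as they were chosen to
  do on the real electrode.
* **Noise**: additive white Gaussian, sd = 2% of the trace's largest peak
  component; peak-free traces use a reference amplitude (100 μmol/L ×
  full response) so blanks still carry instrument noise. Peak centres
  jitter by 5 mV (1 sd) per replicate. Under these defaults five simulated
  replicates keep I_p RSD ≲ 3% and E_p RSD ≲ 0.7%, inside the published
  repeatability bounds (13% and 1%).
* **pH**: all peak potentials shift linearly at −59 mV per pH unit relative
  to pH 8.0 (direction as observed; the magnitude is the Nernstian default,
  overridable). At pH 10 every peak sits 0.118 V more negative.
* **Seeds**: one top-level seed; per-trace generators derive from
  (seed, sample index, scan) so every artefact is reproducible bit for bit.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: capacitive/charging currents, electrode fouling
and drift between replicates, asymmetric (tailed) peak shapes, scan-rate
dependence, peak-potential shifts with concentration, and matrix effects
from tablet excipients. Results on simulated panels demonstrate the
pipeline's correctness, not instrument-level performance.

### The 46-sample panel

The seized-panel fixture mirrors the published composition summary exactly
where stated: 42 SC-containing samples (two mixtures, samples 8 and 28,
resolved to the richer group), six R1-only samples (7, 26, 27, 30, 32, 40;
R2 amplitude set below detection), caffeine in samples 3, 19, 20, 23, 25,
29, 30, 33–36, 38, 39, 41, MDMA in samples 7 and 46, and four SC-free
samples. Per-sample analyte identities are not published in the main text,
so single-SC samples cycle round-robin through the 15 library cathinones
and the negatives are plausible compositions (cocaine, paracetamol, a
blank, and MDMA-only for sample 46). All analytes sit at 100 μmol/L, the
standard working concentration after extraction and dilution.

## Preprocessing

Traces are cropped to −1.60..+1.60 V (anodic) and +1.80..−1.80 V
(cathodic), inclusive of endpoints, then baseline-corrected, then
(for chemometrics) scaled to unit maximum absolute current. The original
workflow fitted baselines interactively; the automated surrogate here is
iterative polynomial fitting: fit order-3 by least squares, exclude points
whose residual exceeds 2.5 robust standard deviations (scaled MAD), refit,
until the fitted curve is stable (relative tolerance 1e−6, max 50
iterations; mask fixed points and short cycles count as converged, and the
fit never drops below 2(order+1) points). Clipping is two-sided by default
because DPV traces carry peaks of both signs; one-sided rules remain
selectable. Conservation holds by construction: the corrected trace is
bitwise `input − baseline`. Order 3 and crop-before-correct are choices the
source method leaves open; both are configurable.

Max-|I| normalization (rather than min–max or vector norm) keeps oxidation
and reduction signs intact, which the sign-aware peak detector requires.

## Peak detection

Oxidations are local maxima and reductions local minima
(`scipy.signal.find_peaks`), with prominence ≥ 5% of the trace's largest
absolute current and width ≥ 0.02 V. Two guards matter in practice:

* **Sign consistency** — an extremum only counts when its current carries
  the process's sign; otherwise the valley between two adjacent same-sign
  peaks registers as a spurious opposite process. |height| must also clear
  the prominence threshold.
* **Absolute floor** (classifier only, default 0.5 μA) — on a peak-free
  trace the relative threshold scales down to the noise floor and would
  call noise wiggles processes. The floor corresponds to a signal well
  below the method's quantification limit at the standard dilution, i.e. it
  discards only sub-quantifiable structure. Calibration extraction omits
  the floor (it must follow the response toward the detection limit).

Window matching is greedy by descending |height|, one peak per label, ties
broken toward the window centre; windows must not overlap after tolerance
expansion.

## Chemometrics

The feature matrix stacks preprocessed, normalized anodic-then-cathodic
currents, one row per (analyte, replicate). PCA is a column-mean-centred
eigen-decomposition (full SVD, no scaling by default since rows are already
normalized; autoscaling behind a flag), with component signs fixed so each
loading's largest-magnitude entry is positive. HCA defaults to Ward linkage
on Euclidean distances; merge heights are also reported on a
100·(1 − d/d_max) similarity scale. `cut_by_gap` cuts the dendrogram at the
largest gap between successive merge heights.

On the 15-standard × 3-replicate set, cutting the Ward tree at **six**
clusters reproduces the designed groups exactly (adjusted Rand index 1.0),
and the G6–G5 merge sits near 50% similarity, echoing the ~60% similarity
reported for α-PVT against the pyrrolidine group. The *automatic*
largest-gap cut, however, selects five clusters, merging G3 with G4: those
groups differ by a single extra oxidation (+0.90 V) plus 0.02–0.05 V shifts
of shared peaks, a separation smaller than the jump from group structure to
the next dendrogram level and comparable to G1's internal heterogeneity
(ethcathinone shows no DPV anodic oxidation at all, while mephedrone and
4-MPD differ by a 0.09 V peak shift). This holds for every standard
linkage/metric/scaling combination tested and is stable across seeds — a
structural property of the fingerprint geometry, not noise. Published
variance fractions (e.g. PC1/PC2 percentages) depend on the undeposited raw
data and are not reproduction targets.

## Calibration statistics

LOD = 3.3σ/S and LOQ = 10σ/S from an ordinary least-squares fit of the R1
peak current on concentration; their ratio is 10/3.3 by definition. σ is
the regression's residual standard deviation (n−2 denominator) by default —
"standard deviation of the response" is ambiguous between residual SD,
blank SD and intercept SE, so the alternatives are selectable. The linear
range search returns the widest contiguous span of levels reaching a target
r² (default 0.99), preferring spans that include the top level. Replicate
RSDs are flagged against the published bounds (13.0% for I_p, 1.0% for
E_p); a zero-mean entry has no defined RSD and is reported as such.
Weighted or heteroscedastic calibration models are out of scope.

## Problem sizes

Defaults throughout are the study's own scales: 46-sample panels, 15
standards × 3 replicates for chemometrics, 5 replicates for repeatability,
7-level × 3-replicate calibrations. The whole test suite and the
acceptance script each complete in well under a minute on one core.
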
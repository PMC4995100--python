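# Methods

This note records the models, parameter choices and numerical conventions
behind `qznorm`, and what the synthetic benchmarks do and do not
demonstrate about real data.

## Data model and coordinates

All coordinates are 0-based, half-open. Fragments are paired-end extents;
the midpoint of an even-length fragment is `floor((start+end)/2)`.
Duplicate fragments are kept — MNase-seq depth is signal, and
deduplication would bias exactly the high-occupancy positions the method
quantifies. Two track flavours are built from fragments: *tag coverage*
(per-basepair count of overlapping extents) and *tag counts* (one count
per fragment midpoint). Tag counts are the primary carrier: they are what
the normalization fit and the per-nucleosome windows consume.

Per-dyad aggregation (meta-profiles, profile matrices, 120-bp windows)
drops dyads whose window leaves the chromosome rather than zero-padding,
so profile tails are never deflated; dropped counts are reported.
Minus-strand dyads contribute mirror-imaged rows when orientation is
requested. Windows are half-open: `[dyad − w, dyad + w)`.

## TAZ normalization

One IP reaction yields input (T), flow-through (A) and IP (Z) libraries of
arbitrary depth. The scale factors are estimated in sequence:

1. `m = T(zones)/A(zones)` over the union of the no-Z-zone reference
   intervals (overlaps merged, so shared basepairs count once). Zones are
   an *input*: curating them is a judgement call about where H2A.Z is
   absent, not something this package derives.
2. `n = argmin_{n≥0} Σ_o (m·A[o] + n·Z[o] − T[o])²` over midpoint-count
   meta-profiles compiled around the +1 dyads (default flank ±500 bp, the
   full compiled window). Ordinary least squares was chosen because the
   underlying constraint — flow-through plus IP reconstitute the input —
   is a single-amplitude linear model; OLS has a closed form, a convexity
   guarantee (perturbing n strictly increases the residual), and an
   easily implemented independent oracle (grid search). A negative
   unconstrained optimum is clamped to 0 and flagged rather than hidden;
   the RMS residual is attached to every factor set.
3. `c = 10⁶ / total input fragments`.

Final scales: `c·T`, `c·m·A`, `c·n·Z`. By construction the normalized A
track reconstitutes the input over the zones to floating-point accuracy.

Replicates are normalized independently and averaged afterwards
(`average_reactions`); raw reads are never pooled. This matters
quantitatively: a single reaction's fitted `n` carries a counting-noise
floor of a few percent (input-profile shot noise enters the normal
equations weighted by Z²), which averaging across reactions reduces as
1/√R. The factor-recovery benchmark therefore scores the
replicate-averaged factors over 20 reactions.

A caveat inherent to the assay: the flow-through contains the H2A.Z
fragments that escaped capture, so the normalized Z track reports
IP-efficiency-weighted occupancy (f·e, with e the capture probability),
not the raw dimer fraction f. Condition *comparisons* are unaffected as
long as e is stable between samples, which is the assay's stated
operating regime (e consistently above 0.8).

## Occupancy statistics and change calling

Per-nucleosome occupancy is the windowed ratio (Z/T) — and (Z/A) — over
120 bp centered on the dyad. Ratios are masked undefined when the
denominator window holds less than 1 CPM unit, rather than reporting
unstable quotients; masking propagates into condition deltas and is
counted in outputs. The browser-track form of Z/A uses a 147-bp running
window (one nucleosome footprint) and a pseudocount of 1 CPM unit in the
denominator so the trace is finite across H2A-free gaps; the ratio is
deliberately sensitive and non-linear, and the pseudocount is part of its
definition.

Change thresholds are the control median ± 2 × control SD, with the
spread taken as the sample standard deviation (about the mean) paired
with the median as center — exactly the stated calibration — and a
MAD-based robust option. Degenerate zero-spread controls are flagged. On
a Gaussian null this leaves 2·(1−Φ(2)) ≈ 4.55% of nucleosomes outside,
which the calibration benchmark verifies at n = 10⁵.

## Positioning

Peak centers are fitted with a Gaussian plus constant baseline inside
per-peak search windows (±80 bp around the canonical position,
(k−1)·165 bp for peak +k); σ is bounded to [20, 120] bp to exclude
degenerate fits, and the center is the fitted mean. On convergence
failure the signal-weighted centroid is used and flagged. Shifts are
`center_after − center_before`, positive = rightward/downstream.

The fuzziness score contrasts mean density in the +1/+2 linker (offsets
55–110 bp) with the two flanking peak windows (−40–40, 125–205 bp), each
profile first normalized to unit mean over those windows so the score is
depth-free. The sign convention is fixed: **positive = the array became
fuzzier after treatment** (linkers filled in, peaks dropped). k-means
(fixed seed, 10 restarts) groups genes by the score; the cluster with the
highest mean score is labeled remodeler-dependent.

## +1 / TSS discovery

Δ(Z/A) profiles (±200 bp) are compiled for every nucleosome in a
genome-wide dyad catalog, clustered with k-means (k = 4, fixed seed), and
clusters whose *mean* profile is both strong and centered are admitted;
the procedure is run exactly twice, the second pass on the remainder, to
pick up weaker +1 nucleosomes. Admission uses two criteria evaluated on
the central ±60 bp of the mean profile:

- center of mass of the positive signal within ±20 bp of the dyad;
- mean Δ(Z/A) above a floor of 0.1.

Restricting the symmetry judgement to the central window is deliberate:
Δ(Z/A) of a genuine +1 nucleosome is skewed toward the adjacent NDR,
where H2A depletion inflates the ratio, so a full-window center of mass
penalizes exactly the nucleosomes being sought; a +2 or −1 neighbor, by
contrast, has almost no *central* signal and fails the floor. Rows inside
admitted clusters are additionally filtered by their own central COM and
floor, so no reported candidate is off-center; per-row COM scores are
emitted for re-filtering. Candidates within 40 bp of a known +1 dyad are
labeled known, the rest novel; transcript direction points away from the
nearest NDR center within 300 bp, else ambiguous. These tolerances
respect mononucleosome geometry (147-bp footprint, ~165-bp repeat) and
are configurable.

The method localizes initiation to a nucleosome, not a basepair, and
inherits the assay's blind spots: promoters with weak H2A.Z deposition or
weak PIC-dependent eviction produce little Δ(Z/A) and will be missed.

## The simulator

`synthetic_data` generates genomes of tiled gene units — a −1 nucleosome,
a 150-bp NDR, and a +1..+8 array at 165-bp spacing — plus H2A.Z-free
zone blocks (16 by default) that serve as no-Z-zones, and optional
cryptic divergent promoters (an internal NDR replacing one mid-array
nucleosome, flanked by two oppositely oriented +1-like nucleosomes absent
from the known +1 annotation). Occupancy is a per-nucleosome H2A.Z
*dimer fraction* — defaults 0.40 at +1, 0.15 at −1, 0.02 in gene bodies,
0 in zones — matching what a dimer-level IP can observe without
distinguishing heterotypic from homotypic nucleosomes.

Fragments are ~147 ± 10 bp with 20-bp Gaussian positional jitter
(MNase trimming variability). IP routing (capture probability
e = 0.85 per H2A.Z fragment, escape to the flow-through otherwise) fixes
each library's composition; each library is then sampled to its own depth
(10⁵ fragments by default), as real libraries are sequenced
independently. This makes the implied truth exact and recorded:
`m_true = mean(1 − f·e)`, `n_true = mean(f·e)`.

The zone blocks cover ~11% of the synthetic genome — proportionally more
than curated reference regions span in a real genome — so that the zone
tag counts give the m estimate enough precision for factor-recovery
benchmarks at desk-scale depth; with sparser zones m's counting noise,
amplified ~2× in n, dominates the error budget.

Perturbations are rate switches applied to the PIC-proximal (+1 and
cryptic) nucleosomes: `block_deposition` decays fractions with a
configurable half-life (default 15 min, eviction continues);
`block_eviction` relaxes fractions toward 1 at a deposition rate
(default 0.1/min); `plant_shift` repositions dyads per nominal array
position, mirror-imaged on minus-strand nucleosomes.

What the simulator does *not* emulate: sequence-dependent MNase bias,
fragile (MNase-hypersensitive) particles, fuzzy/overlapping nucleosome
alternatives, chromatin heterogeneity between cells, crosslinking
variability, and replicate-level batch effects. Benchmarks passing on
this generator demonstrate the estimators' correctness and calibration
under the stated sampling model — not robustness to those real-data
complications.

## Benchmark problem sizes

The test suite and `scripts/acceptance.py` use compact configurations
chosen to give each statistic adequate precision: 2 × 120 kb chromosomes
(~1,300 nucleosomes, 126 +1 dyads) at 10⁵ fragments/fraction for
normalization, dynamics and closure benchmarks (closure conditions
average six replicate reactions); one 95-kb chromosome (52 genes) for
shift recovery; 4 × 100 kb with 200 planted cryptic promoters (~1,900
catalog nucleosomes) for TSS discovery; n = 10⁵ draws for the null
calibration of change thresholds.

## Known limitations

- `n` is fitted per reaction by unweighted OLS; a heteroskedasticity-aware
  weighting would be statistically more efficient for counts but would
  lose the transparent closed form and its grid oracle.
- The zone-anchored scale assumes the reference regions are truly
  H2A.Z-free in every condition; contamination biases m upward.
- Fuzziness and shift estimates operate on compiled (cross-gene averaged)
  profiles; per-gene estimates at low depth are noisy, and the Gaussian
  model assumes a single dominant positioning mode per peak.
- The CLI's `dynamics` command normalizes each condition from single
  fragment files; for replicate averaging, normalize replicates via the
  library API (`average_reactions`) before tabulating.
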
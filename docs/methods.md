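# Methods

## Scope and data model

The package computes everything downstream of video tracking for a
comparative behavioral study of small fish. Input trajectories are
idTracker-style tables (per-frame `X Y ProbId` triplets per fish, `NaN`
where identity was lost) or a tidy native CSV, calibrated to centimetres
with the origin at the arena's bottom-left water corner and y increasing
toward the water surface. All zone logic assumes this convention; "top"
endpoints are defined against the water surface.

Two arenas are built in: the trapezoid assay tank (22 cm bottom, 28 cm top,
15.2 cm high, side view, water level 15.2 cm) used for the novel tank,
mirror, predator, social and shoaling assays, and a 30 × 30 cm top-view
square for the 24-h locomotor recording. The camera rate is configurable
(default 30 fps; the analysis scripts and tests simulate at 10 fps, which
resolves all endpoint dynamics at a fraction of the cost).

### Gap handling

Identity-loss runs of at most `max_gap_frames` (default one second) flanked
by valid frames are filled by linear interpolation and flagged
`interpolated`; longer runs stay invalid and are excluded from every
endpoint denominator rather than imputed, so gaps can never fabricate
freezing bouts or zone entries. An optional centred moving-average smoother
exists because raw tracker jitter inflates path length; it is off by
default and any report using it should say so, since total distance is
monotone non-increasing in the window.

## Endpoints

**Movement states.** A step is freezing at ≤ 1 cm/s and rapid at ≥ 10 cm/s
(defaults; configurable per species — published protocols rarely print
these cut-offs, so every report should record the thresholds used). The
three state ratios are computed over valid steps and sum to one by
construction.

**Turning.** Headings are only taken from steps of at least 0.05 cm; at
rest, positional jitter otherwise produces spurious 180° flips that
dominate meandering, which is a ratio of sums (Σ|Δθ| / Σ ds, deg/cm). The
turn at a step is the absolute wrapped difference to the most recent usable
heading within a contiguous valid run. Meandering's denominator includes
every usable step (also the chain-starting step whose own turn is
undefined): a ten-step ±90° zig-zag gives 810°/10 cm = 81 deg/cm, and a
discretized semicircle of radius r converges to 180/(πr).

**Zones.** Zone entries use a two-frame hysteresis — a crossing counts only
after two consecutive frames on the new side — so boundary chatter cannot
inflate entry counts; starting inside counts as the first entry at t = 0.
Latency to enter is censored at session end (not treated as missing) so
group statistics remain computable over all fish. The "top" zone defaults
to the upper half of the water column (configurable fraction); thigmotaxis
is proxied by mean distance to the water-polygon centroid. Contact-strip
widths default to one body length: 1 cm at the mirror, 3 cm at the predator
and conspecific separators; "longest bout" endpoints are normalized by total
session length.

**Shoaling.** Frames with any missing fish are dropped entirely so the four
cohesion endpoints share one denominator. Shoal area for three fish is the
triangle (shoelace) area, convex hull beyond that. All four endpoints are
symmetric in fish identity, so tracker identity swaps are irrelevant and no
identity repair is attempted.

**Circadian.** One-minute segments each hour are reduced to the six
kinematic endpoints and assigned to day or night by segment start hour
(segments are short relative to the hourly transitions). The default light
schedule is lights on 08:00–22:00, matching 14 h light / 10 h dark housing.
No periodogram or cosinor fitting is attempted: the design compares day and
night phase means only.

## Statistics

Group comparisons use the tie-corrected Kruskal–Wallis statistic
(mid-ranks; H divided by 1 − Σ(t³−t)/(N³−N), guarded for all-equal data)
with p from χ²(k−1), or optionally an exact permutation p that enumerates
every assignment of the pooled mid-ranks to the group sizes (practical to
N ≈ 12). Pairwise contrasts are Dunn z tests on the pooled ranks with the
tie-corrected variance and deliberately **no** multiplicity adjustment;
α = 0.05 throughout. Compact letter displays use insert-and-absorb: start
with one column holding all groups, split each column containing a
significantly different pair, drop absorbed columns; the invariant "two
groups share a letter iff their pairwise p ≥ α" is guaranteed, minimal
letter count is not. Groups are ordered by mean value before lettering for
stable output.

The novel tank's time-binned endpoints use a mixed two-way ANOVA: between
factor species, repeated factor bin, the textbook sum-of-squares
decomposition (verified to partition exactly), and the Geisser–Greenhouse
ε̂ from the pooled within-group covariance of the repeated measures, with
within and interaction df multiplied by ε̂. ε̂ is identically 1 for two
bins and bounded in [1/(k−1), 1]. Fisher's LSD contrasts between groups at
a single bin use the mixed-error variance (MS_subj + (k−1)·MS_err)/k with
Satterthwaite df, uncorrected.

Coefficients of variation are 100·sd/|mean| (sample sd), undefined and
flagged at zero mean.

## Phenomics

Endpoint values are aggregated to a group-mean matrix (rows endpoints,
columns groups; a per-session mode exists for exploration). Rows are
centered and scaled to unit sample variance (constant rows dropped with a
warning), components come from the SVD of the transposed (group ×
endpoint) matrix — the row scaling already centers the observations — and
variance explained sums to 100%. Both axes are clustered agglomeratively;
defaults are correlation distance with average linkage (the common choice
of ClustVis-style web tools), with euclidean/ward/complete available. The
column dendrogram is serialized as Newick with branch lengths equal to
merge-height differences, making it ultrametric and directly comparable to
the gene tree.

## Gene tree and concordance

*nd2* sequences (~1 kb, closely related) are pairwise globally aligned
under a linear gap scheme (match +1, mismatch −1, gap −2 by default);
a full progressive MSA is out of scope, and a simple reference-anchored
projection aligns unequal-length inputs onto one coordinate system.
Distances are Jukes–Cantor, d = −¾ ln(1 − 4p/3), with gap/N sites excluded
pairwise and saturation (p ≥ ¾) flagged as an error. Trees are built by
Saitou–Nei neighbor joining (deterministic tie-break by taxon order;
negative branch-length estimates clamped to zero; exact on additive
matrices), and supports come from resampling alignment columns with
replacement and counting the fraction of replicate trees containing each
full-data bipartition. Distance-based NJ with bootstrap stands in for a
maximum-likelihood analysis whose settings are not part of this package;
the concordance layer is tree-agnostic, so an externally computed ML tree
in Newick can be supplied instead.

Concordance between the phenogram and the gene tree is reported as the
Robinson–Foulds symmetric difference over non-trivial bipartitions
(normalized by 2(n−3)) and the Pearson correlation of the two trees'
leaf-pair path distances.

## Synthetic study generator

The generator is the ground truth for all recovery tests. Each fish is a
stochastic walker:

* **Freeze/move** is a two-state Markov chain with per-second rates
  discretized at the frame rate; frozen frames have zero displacement, so
  the long-run freezing time ratio equals the stationary probability
  a/(a+b) of the chain — the basis of the freezing-recovery check.
* **Speed** while moving is a zero-clipped normal around μ_v/fps (the clip
  is negligible for μ_v/σ_v ≥ 3, so mean speed recovers μ_v), with rare
  bursts at a rapid speed.
* **Heading** is persistent with wrapped-normal turning noise
  (sd = 1/√κ_turn) around a drift direction that sums unit vectors for
  persistence, vertical preference, stimulus-wall attraction, shoal-centroid
  attraction, optional wall attraction, and a short-range inward repulsion
  near the boundary. Boundaries reflect rather than absorb, so occupancy
  fractions are governed by the drift terms.
* **Vertical preference** is a slow two-mode (top-seeking / bottom-seeking)
  switch with stationary top probability π_top and strong vertical drift
  while in the wrong half. Because the transit into the top after switching
  up and the lingering in the top after switching down cancel to first
  order, long-run top-half occupancy tracks π_top itself — verified to
  within 3 Monte-Carlo SEs at π_top = 0.8.
* **Day/night** modulation multiplies μ_v per segment.
* **Sequences** evolve from a uniform random root along the configured tree
  under Jukes–Cantor, p(t) = ¾(1 − e^(−4t/3)) per site and branch.

Identical configurations (including seed) produce byte-identical output.
The default five archetypes encode the qualitative species contrasts of the
study system — zebrafish most active; *O. woworae* the most active and
most stimulus-seeking medaka; *O. sinensis* slow, surface-oriented and
mirror-aggressive; *O. dancena* active; *O. latipes* calm — and the default
sequence tree mirrors the published *nd2* relationships (zebrafish
outgroup; *latipes* + *sinensis* sister; *dancena* and *woworae* on
separate branches). Group sizes default to 30 sessions per group with 22
for *O. sinensis* (the study's unbalanced design); the statistics layer
handles unequal n throughout.

What the generator does **not** emulate: tracker pixel noise and identity
swaps (missing frames are injected separately in tests), within-session
habituation time-courses, biomechanically realistic swimming, and 3-D
movement. Passing recovery tests therefore demonstrates correctness of the
endpoint→statistics→clustering chain under the modelled dynamics, not
robustness to every artifact of real video tracking.

## Problem sizes and numerical choices

The analysis scripts and validation suites simulate at 10 fps with 60-s
assay segments (30-s sessions and two assays for the 100-seed
planted-archetype replication; 180-s sessions for top-preference recovery,
long enough to average over several preference-mode dwells). These sizes
give stable endpoint estimates while keeping a full study regeneration in
the order of seconds; the archetype separation, not session length, drives
the clustering recovery. Sequence benchmarks use 1 kb alignments (10 kb for
the consistency checks). Other numerics: endpoint comparisons against the
brute-force oracles are exact to 1e-9; SVD components below 1e-12 of the
largest singular value are dropped; the Q-criterion tie-break and the
clamping of negative NJ branch lengths are the only non-textbook choices in
the tree code; exact-permutation Kruskal–Wallis uses a 1e-12 tolerance when
counting permutations at least as extreme as the observed statistic.

## Known limitations

* The reference-anchored multiple alignment discards insertions relative to
  the reference; adequate for closely related mitochondrial genes, wrong
  for deep divergences — supply a pre-aligned FASTA in that case.
* The compact-letter display is not guaranteed minimal in letter count.
* Fisher's LSD per-bin contrasts use a Satterthwaite approximation for the
  mixed error; exact small-sample behavior is approximate.
* Zone hysteresis (two frames) is frame-rate dependent; at very high frame
  rates it should be scaled with fps.
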
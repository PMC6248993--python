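# Methods

## Data model and coordinates

A genetic map is a set of linkage groups; each group is a list of
`(marker_id, position_cM)` records sorted by position. Physical annotations
map markers to `(chromosome, position_bp)` with 1-based inclusive bp
coordinates. Genetic positions are nonnegative reals in centimorgans; each
group's origin is whatever its source states — no re-anchoring happens on
read. Marker identifiers are matched case-sensitively and must be unique
within a map; cross-map identity is exact string identity (no aliasing).
Markers mapped to the same position (within 1e-6 cM, an exact-equality
intent that tolerates float round-trips) form a *bin*; bins are the unit of
both the collinearity filter and the merge constraints, because
co-segregating markers are positionally indistinguishable within a
population.

## Collinearity filtering

Each linkage group is assigned the chromosome carrying a strict majority of
its annotated markers (ties are an error, not a guess). In cM order, the
group's bins — each located at the median bp of its members on that
chromosome — must be strictly increasing in bp to be collinear. The filter
keeps a longest strictly increasing subsequence (LIS) of bins and removes
the complement, whole bins at a time; by the duality between LIS and minimum
removals this is a minimum-size removal set. Minimal sets are generally not
unique; the implementation uses patience sorting with smallest-tail
reconstruction, which is deterministic. Markers without a physical
annotation on the assigned chromosome (SSRs, morphological markers) are
never removed. Filtering is idempotent.

A caveat documented here because it shapes the tests: a local *order
reversal* of w markers can be detected, but any LIS necessarily retains
exactly one member of the reversed run, so a minimal filter flags w−1 of the
w markers involved — per-event detection is complete, per-marker recall is
(w−1)/w by construction.

## Map statistics

Per group: genetic length = max − min position; unique positions = number of
bins; largest gap = max difference between consecutive bin positions (0 with
fewer than 2 bins); marker density = length / bins (cM per unique position);
physical span = (max − min bp) of retained annotated markers, in Mb;
coverage = 100 × span / chromosome length; recombination ratio = length /
span (cM/Mb). Totals sum lengths, markers, bins and spans; total density and
ratio are recomputed from the totals, not averaged. All rounding (2 d.p. in
reports) happens at write time only.

## Anchor points

An anchor point is one marker shared by one pair of maps under the same
linkage-group label; a marker in k maps contributes k(k−1)/2 anchor points
and one common marker. This is the only definition under which total anchors
can exceed total common markers, as multi-population studies report. Markers
shared under conflicting group labels are excluded from the counts, logged,
and dropped from all maps before merging (they would otherwise appear on two
backbones).

## Consensus merge

**Backbone.** After filtering, every component map is collinear with the
genome, so physical order is a shared order: annotated markers are sorted by
bp (ties broken by marker id). Unannotated markers are inserted at the mean,
over the component maps containing them, of their fractional rank between
the nearest annotated neighbours in that map; markers with no annotated
neighbour in any map are an error. Placement method (`physical`/`inferred`)
is recorded.

**Objective.** With consensus positions x indexed by backbone order, every
pair of bins at most K ranks apart in a component map m contributes a
constraint with the observed distance d_ij^m and weight w_m (default 1.0 for
every map); co-segregating members are tied to their bin representative at
distance 0. The solver minimizes Σ w_m |(x_j − x_i) − d_ij^m| subject to x
nondecreasing and x_first = 0, parameterized by the gaps g = Δx ≥ 0 and
solved as a linear program (HiGHS via `scipy.optimize.linprog`) with split
slack variables. Monotone-only constraints make the LP always feasible.

**Tie-break.** The L1 optimum is often a face, not a point (two maps
disagreeing about one interval leave the whole interval between their
distances optimal). The reported solution re-minimizes Σ w r² over that
face, which sets ambiguous positions to the weighted mean of the implied
distances. The face is read off the LP duals by complementary slackness
(interior dual ⇒ residual pinned to 0; boundary dual ⇒ residual sign fixed;
nonzero reduced cost ⇒ gap pinned to 0); the quadratic subproblem is solved
by equality-reduced least squares with a feasibility check, falling back to
a Lawson–Hanson LSI (inequality-constrained least squares via NNLS) on
problems up to 2,000 constraints and to the LP vertex beyond that. A ridge
of 1e-9 on the gaps guarantees full rank; its bias is orders of magnitude
below the 1e-6 cM tolerances used throughout. Refinement is skipped when
the LP objective is already ~0 (the solution is then unique on the
constraint graph's connected component). Solutions are deterministic and
invariant to rescaling all weights.

**Model selection.** The merge runs for each K in {1,2,3,4}. For each
component map and group, the RMSE between consensus and component positions
is computed over shared markers after shifting both so their first shared
marker sits at 0 (component origins are arbitrary). RMSE uses positions,
not ranks — the numeric-vector convention of standard goodness-of-fit
tooling. The K minimizing the mean RMSE over all (map, group) pairs is
selected, ties going to the smallest K. Consensus positions are written at
4 d.p.; summary tables at 2 d.p.

A property worth knowing: with noise-free components the consensus
reproduces the true positions exactly for every K (component intervals are
sums of truth intervals, so the objective reaches 0 and the constraint
graph pins every position). With ≥3 noisy components at K=1 each consensus
gap is a weighted median of component gaps, and a sum of medians can fall
slightly outside the [min, max] range of component group lengths; the
often-quoted "consensus length lies within the component range" holds
exactly for two tie-free components (gaps become means) and only
approximately otherwise.

## Position interpolation

Within a group, the (bp, cM) pairs of annotated consensus markers form a
nondecreasing piecewise-linear reference (the merge guarantees monotonicity
in bp). Queries between two mapped markers are linearly interpolated; a
query on a mapped bp returns that marker's position directly. Beyond the
last mapped marker, the cM increment of the last interval is reused with the
chromosome end as the far flank. The symmetric case before the first mapped
marker is not specified by the published procedure; it is mirrored using the
first two markers with snp1_bp = 1, and estimates are clamped at 0 cM, which
preserves monotonicity and nonnegativity. Flanks within one bin
(delta_cM = 0) return the flank position (a constant segment). Estimates are
reported at 4 d.p.

## Synthetic data generator

The generator emulates the study conditions the package targets: 8 linkage
groups on chromosomes of 47.44, 30.13, 27.25, 25.15, 16.52, 30.10, 22.19
and 21.91 Mb; 200 markers per group placed uniformly without replacement; a
piecewise-constant recombination landscape with 5 equal-width segments and
rates drawn uniformly from 1.6–6.6 cM/Mb (the span of per-chromosome cM/Mb
ratios reported for dense stone-fruit maps); true cM as the cumulative
rate integral from the first marker. Positions are snapped *down* to a
0.5 cM grid, the resolution of an F2 population of ~90 individuals (one
recombinant ≈ 100/(2·90) ≈ 0.56 cM), which creates realistic co-segregation
bins. Five component maps each retain markers independently with
probability 0.6, add Gaussian jitter (default sd 0.5 cM) and are projected
back to monotone order by isotonic regression — noise on positions plus
isotonic projection, rather than noise on intervals, guarantees a valid map
at any noise level. With probability 0.25 per group one interior window of
4 consecutive markers has its cM order reversed; the members are recorded
so filter performance is measurable. Unmapped markers are drawn between the
first mapped marker and the chromosome end (at least one beyond the last
mapped marker, to exercise the scaffold-end rule) with true cM from the
same rate function. Everything is deterministic given the seed, with
independent substreams per stage.

What the generator does **not** model: genotyping error and missing data,
segregation distortion, population-specific recombination landscapes (all
maps share one truth landscape), marker-name inconsistencies between
platforms, and genome misassembly (non-collinearity is always map error in
the simulation). Passing tests therefore demonstrate correctness of the
algorithms under the stated noise model, not robustness to every artifact
of real array data.

## Problem sizes used in validation

The exact-recovery check runs the full stated condition (8 groups × 200
markers × 5 maps, 60 % retention, all K in 1..4). The collinearity oracle
compares 1,000 random groups of ≤12 bins against exhaustive search. The
noise-response curve (jitter sd 0, 0.5, 1, 2 cM; 20 seeds per level) runs at
4 groups × 60 markers × 3 maps with K = 1, a size chosen so the whole
validation suite completes in seconds while leaving the trend's direction
unambiguous. The interpolation identities use a 2-group, 60-marker
noise-free dataset plus the closed-form worked cases (midpoint 1.0 cM,
scaffold-end 13.0 cM).

## Known limitations

- The merge follows the interval-LP contract; the alternative DAG-based
  graph merge used by some studies is intentionally not implemented (its
  non-binned output was discarded in the motivating workflow).
- Group-label harmonization across maps is exact string matching; maps
  numbering their groups differently must be relabelled upstream.
- The backbone requires a majority chromosome per group; groups spanning a
  translocation would need manual splitting.
- XLSX input is a thin optional adapter with caller-supplied column
  mappings; published supplementary tables have no fixed layout.
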
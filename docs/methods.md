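# Methods

## Melt-curve processing

Raw relative-fluorescence series F(T) are recorded on a temperature grid;
the emulated instrument ramp is 65–95 °C in 0.1 °C steps (301 points), but
any strictly increasing grid is accepted at parse time. Processing assumes
a uniform grid (non-uniform grids must be regridded explicitly by linear
interpolation; extrapolation is refused, and no silent resampling ever
happens).

**Smoothing.** F(T) is smoothed with a Savitzky–Golay filter before
differentiation, never after. Defaults: window 7 points, polynomial order
2. On a 0.1 °C grid this window spans 0.6 °C — narrow relative to the
default transition width — so peak positions are preserved to well under
the grid step while per-point noise is attenuated. Commercial HRM software
applies its own (undocumented) preprocessing; here the smoothing is
explicit, configurable, disablable, and recorded in output file headers.

**Melting curves.** The melting curve is the negative first derivative
−dF/dT, computed by central finite differences at interior points and
first-order one-sided differences at the two boundary points. Units are
RFU/°C. Trapezoidal integration of −dF/dT recovers F(T_a) − F(T_b) up to
O(step²), which the tests check on smooth inputs.

**Tm calling.** T_m is the temperature of the global maximum of −dF/dT
restricted to interior grid points, refined by the vertex of the parabola
through the peak and its two neighbours (the refinement offset is clipped
to ±half a step). Ties break toward lower temperature. If the maximum sits
on a boundary point the curve is flagged `no_peak` and T_m is undefined —
the honest outcome for a well with no melt transition inside the ramp. On
noiseless two-state curves with transition width ≥ 0.3 °C the call is
within 0.05 °C of the model T_m; in practice it is within ~1e−4 °C, since
the logistic derivative is locally parabolic.

**Replicate averaging.** Technical replicates (the assay's plate design
uses five per sample) are averaged pointwise on −dF/dT and T_m is re-called
on the mean curve. Averaging raw F first would give the same result up to
the linear operations involved; averaging curves keeps the pipeline
composable when replicates arrive pre-processed.

**Difference curves.** With m(T) the mean melting curve of a designated
reference set (default: all curves), each curve i yields
d_i(T) = m(T) − (−dF/dT)_i(T). The sign convention is mean-minus-curve;
either choice satisfies the defining invariant that the deltas over the
generating set sum to zero at every temperature (machine precision), which
is tested both on hand-worked values and property-style on arbitrary sets.
Curves outside the reference set are differenced against the same m(T).
Difference curves are computed on −dF/dT, not on normalized raw
fluorescence; a classic normalized-fluorescence mode (linear baselines fit
in 65–70 °C and 90–95 °C windows, signal rescaled to [0, 1]) is available
as `normalize_fluorescence` for users who want commercial-style difference
plots, and is off by default.

The whole chain is equivariant in the expected way: adding a constant to
all raw series leaves melting and difference curves unchanged; scaling all
series by c scales both by c.

## Classification and clustering

Curves are compared by Euclidean distance restricted to an analysis window,
default 70–85 °C, so that baseline-region noise away from the melt
transition does not accumulate over ~150 grid points and swamp the peak
signal. The window is configurable and recorded; `max_abs` and `tm_delta`
metrics are available.

A reference library holds one replicate-averaged curve per label and
records the median replicate-to-mean distance ("replicate spread") as its
natural noise scale. Classification thresholds default to multiples of that
spread: reject τ = 5× (a query farther than this from every entry is
*unassigned*), ambiguity margin τ = 2× (a runner-up within this of the best
hit makes the call *ambiguous*). The multipliers are design choices — wide
enough that honest replicate noise never rejects, narrow enough that a
half-degree T_m gap at the fixture noise level always separates; both can
be overridden numerically. Exact distance ties order candidates
lexicographically by label and are reported ambiguous. Increasing the
margin can only move calls from assigned to ambiguous, never the reverse.

Ambiguous species pairs (the assay's *Aporrectodea caliginosa* /
*Aporrectodea longa* case, whose COI products melt indistinguishably) are
resolved by a multiplex PCR readout: one diagnostic primer pair per
candidate (16S-Ac-F1 × WORM-16S-R1, 116 bp, for *Apo. caliginosa*;
COI-Al-F2 × COI-Al-R2, 213 bp, for *Apo. longa*). The rule maps each
candidate label to a T_m window; windows must be pairwise disjoint. A
multiplex curve whose peak falls in exactly one window assigns that label;
no peak or an out-of-window peak leaves the sample unassigned; a peak where
windows overlap keeps the ambiguity. The shipped default windows are
centred on the model T_m of the two simulated diagnostic products (±0.5 °C)
— they are configuration data derived from the simulator, not measured
biology, and should be replaced from a YAML rule file once calibrated
product T_m values exist for a given instrument.

Melt-group clustering is agglomerative with average linkage on the same
windowed Euclidean distance. Average linkage is used rather than single or
complete because one noisy replicate should neither chain two groups
together nor veto a merge; the linkage is switchable. The automatic cut
height is 3× the median within-replicate-group distance when replicate
structure is annotated, else 3× the median nearest-neighbour distance —
i.e. "merge anything within three noise lengths". The cut is deterministic
given the input and is reported alongside every group count, since the
number of groups is a function of it. Group indices are renumbered by first
occurrence, making the partition invariant under input permutation.

## In-silico PCR

Primers are IUPAC-degenerate strings (5′→3′, length ≥ 10). Degeneracy is
the product of per-position set sizes; enumeration is lazy and
lexicographic, and the count is cross-checked against brute-force
enumeration in the tests. Binding-site search scans both strands (the
reverse-strand scan matches the primer's reverse complement), tolerates
`max_mismatch` mismatches (default 0) outside an exact 3′-terminal anchor
(default 3 bases — polymerase extension is most sensitive to 3′ mismatches),
and treats template `N` as matching nothing by default (conservative for
specificity; a permissive mode resolves primer-vs-template ambiguity by
IUPAC set intersection). Products pair every forward hit with every
downstream reverse hit within a length limit (default 2000 bp); product
length includes both primer footprints, the standard PCR convention.
Internally all coordinates are 0-based half-open; report writers emit
1-based inclusive and say so in their headers.

The built-in registry carries the assay's six degenerate COI primers and
the four multiplex primers, plus the published product-length table for the
nine forward × reverse combinations (158 bp for the default pair
EW_COI_F2 × EW_COI_R1). Because all six primers bind fixed sites on one
template, the nine lengths satisfy offset additivity — L(F_i,R_j) −
L(F_i,R_k) is independent of i and L(F_i,R_j) − L(F_h,R_j) independent of j
— and the published table does satisfy it; the test suite verifies both the
table values and the additivity property on a synthetic template whose site
offsets are derived from that table.

## Haplotype analysis

The analysed unit is the primer-amplified subregion. Extraction runs the
in-silico PCR engine per sequence and requires exactly one product; zero or
multiple products produce per-sequence failure records while the run
continues (only an all-failed run errors). By default the inter-primer
*core* is used: in a real amplicon the primer footprints are written by the
primers themselves and carry no specimen information. Full-amplicon mode
exists for completeness.

Haplotypes are exact-identity classes of equal-length cores
(case-insensitive), with ids h1, h2, … assigned by first occurrence. No
multiple sequence alignment is performed — primer anchoring plus an
equal-length requirement replaces it for this short (115 bp core)
subregion, and indel-bearing cores surface as length failures rather than
being aligned. p-distances are proportions of differing sites, with
positions carrying `N` in either sequence excluded from numerator and
denominator (a pair with no comparable sites is missing, not zero).

Trees are UPGMA (average linkage weighted by cluster size) on the
p-distance matrix, with leaves pre-sorted by label so merge ties resolve
deterministically toward the smallest label; node heights are half the
merge distances, so the tree is ultrametric (verified to 1e−9), and Newick
output carries branch lengths. A likelihood-based phylogeny is out of
scope; for grouping congruence at this fragment size a distance tree is
sufficient and dependency-free.

Concordance between melt groups and haplotypes is a group × haplotype
contingency table. Majority-class purity is not meaningful here — a melt
group is *expected* to contain several haplotypes — so consistency is
defined as: every haplotype maps to exactly one group. Haplotypes split
across groups are listed as violations.

## The synthetic-data generator

The simulator exists so every contract above is testable without
instrument exports or sequence downloads. It emulates the study design —
65–95 °C ramp at 0.1 °C, five technical replicates, eight species, a
28-individual / 8-haplotype / 3-melt-group panel — with exact planted truth.

**Melt model.** Two-state helix→coil with logistic helicity
θ(T) = 1/(1 + exp((T − T_m)/s)) and F(T) = b0 + b1·T + A·θ(T) + ε,
ε ~ N(0, σ²) i.i.d. per well and temperature. Defaults: s = 0.6 °C,
A = 1 RFU, b0 = 1, b1 = −0.005 RFU/°C (gentle baseline drift), [Na⁺] =
0.05 M. −dF/dT then peaks exactly at T_m, so planted temperatures are
recoverable ground truth. This is deliberately minimal: no multi-domain
melting, no heteroduplexes, no amplification phase. Passing tests therefore
demonstrate the correctness of the processing/assignment algebra under a
clean melt model, not predictive accuracy on real COI amplicons, whose
curves have domain structure this model does not attempt.

**Sequence→T_m map.** T_m = 81.5 + 16.6·log₁₀[Na⁺] + 0.41·GC% − 600/N (GC%
in percent, N the product length) — the classic salt-adjusted empirical
rule, fixed as the simulator's definition. Nearest-neighbour thermodynamics
is out of scope. Two consequences are used structurally: a single G/C↔A/T
change in a 158 bp product moves T_m by 0.41·(100/158) ≈ 0.26 °C, and
GC-neutral substitutions (A↔T, G↔C) move it by exactly zero. The latter is
the planted mechanism for melt-indistinguishable haplotypes.

**Noise calibration.** Scenario conditions are stated as noise on the
melting curve (SD 0.01 RFU/°C). The processing chain is linear, so white
raw-F noise of SD σ emerges on −dF/dT with SD ≈ 3.25σ (root of the summed
squared coefficients of the combined Savitzky–Golay 7/2 + central-difference
filter at 0.1 °C). Fixtures therefore inject raw noise of
0.01/3.25 ≈ 0.003 RFU. Replicate-mean noise shrinks as 1/√n, which the
tests check Monte-Carlo at n = 5 vs 20.

**Scenarios.** `eight_species`: core GC counts step by 2 per species, so
the eight planted T_m values are ≈ 0.52 °C apart (≥ 0.5 °C), five
replicates each; under the calibrated noise, nearest-reference
classification is 100% correct, measured over 200 freshly simulated
queries. `caliginosa_longa_ambiguity`: two species whose cores have equal
GC (T_m gap exactly 0 — below any grid resolution), plus per-unknown
multiplex wells simulated from the diagnostic 116 bp (GC-rich) and 213 bp
(GC-poor) products, whose model T_m values differ by ≈ 1.8 °C, well beyond
the ±0.5 °C windows. `chlorotica_haplotypes`: one species, 28 individuals
distributed 4/4/3/4/3/4/3/3 over 8 haplotypes; group 2 haplotypes share
two GC-raising substitutions (+0.52 °C vs group 1), group 3 share four
(+1.04 °C), and within-group haplotypes differ only by GC-neutral swaps —
reproducing an 8-haplotype, 3-melt-group panel with mapping
g1 = {h1}, g2 = {h2, h3, h6, h7}, g3 = {h4, h5, h8}. All generators are
deterministic: one integer seed yields byte-identical fixture files.

Problem sizes throughout (40-well plates, 200-query accuracy runs,
28-individual panels) match the emulated study design; they keep the full
suite and the acceptance script in the seconds-to-a-minute range.

## Numerical and degenerate-input choices

- Temperature grids must be strictly increasing; duplicates are parse
  errors naming the row, never silently dropped.
- Written tables carry 6 significant digits; read∘write is the identity to
  that precision. Decimal separator is always ".".
- Empty datasets are refused at write time (no headerless files).
- A curve whose −dF/dT maximum is at a grid boundary has no T_m
  (`no_peak`), and multiplex resolution treats it as non-amplification.
- Distance ties in classification are deterministic (lexicographic) and
  reported ambiguous rather than arbitrarily assigned.
- T_m values planted outside the simulation grid warn and proceed, since a
  peakless curve is itself a case the pipeline must handle.

## Known limitations

- The two-state melt model cannot produce multi-peak or shouldered curves;
  classifier behaviour on such curves is exercised only via the `no_peak`
  and distance-threshold paths.
- The GC-count T_m rule ignores sequence context (stacking, position
  effects); real Tm-neutral substitutions are only approximately neutral.
- The auto cut height defines what counts as one melt group; different cut
  multipliers can merge or split borderline groups, which is why the cut is
  always reported with the group count.
- UPGMA topology can differ from a maximum-likelihood tree when rate
  variation matters; here it is used only for grouping structure, not for
  phylogenetic inference.
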
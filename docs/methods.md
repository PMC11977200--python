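# Methods

## Scope and model

`karyomorph` implements the desk half of a comparative-cytogenetics study of
allopolyploid frogs: it starts where the microscope stops. Inputs are
per-chromatid arm lengths in pixels, arm-resolved FISH marker maps, FISH
signal tables, and a species tree with NOR character states; outputs are
karyotype morphometrics and category censuses, homeolog divergence
statistics, rearrangement calls (translocation, end-to-end fusion,
pericentromeric/paracentric inversion), rDNA pattern summaries, and a
parsimony count of NOR relocations. Image processing, probe design and
sequence analysis are out of scope.

## Morphometrics

For one physical chromosome the two sister chromatids are averaged first
(arm lengths are the physical quantity; ratios of averaged lengths are more
stable than averages of ratios), giving arms `p <= q` (violating inputs are
swapped and flagged, since a measurement table cannot encode arm identity
beyond relative length). Derived quantities:

- relative length `l = 100 (p+q) / Σ(p+q)` over the metaphase, which cancels
  magnification and pixel-size differences between spreads;
- arm ratios `r1 = p/q`, `r2 = q/p`;
- centromeric index `i = 100 p / (p+q)` on the 0–50 scale.

Categories follow the Levan-style intervals on `i`: metacentric `i >= 37.5`,
submetacentric `25 <= i < 37.5`, subtelocentric `12.5 <= i < 25`, acrocentric
`0 < i < 12.5`, telocentric `i = 0`; all boundaries are inclusive on the
left. On the 0–50 scale `i` and `r1` are redundant for a single chromosome
(`i = 100 r1/(1+r1)` exactly); across metaphases the two are aggregated
independently, so the identity holds only approximately between their
medians (within 0.5 on the bundled reference medians).

Aggregation reports per-type Q1/Q2/Q3 using linear interpolation between
order statistics (the "type 7" quartile convention — the convention matters
for IQR endpoints and is therefore stated here and in output metadata). The
type's category comes from its median `i`.

Homeolog divergence is assessed two ways: (1) IQR disjointness and
inter-interval gap per L/S pair, ranking pairs by gap; (2) a single one-way
ANOVA across all 18 type groups followed by Tukey HSD over all pairwise
contrasts, filtered to the nine homeolog contrasts and coded ***/**/* /ns at
0.001/0.01/0.05. The full-karyotype ANOVA (rather than per-pair t-tests)
matches an analysis of the complete measurement table and keeps the Tukey
family-wise adjustment honest.

## Identification

Measured chromosomes are matched to a karyotype template by globally optimal
bipartite assignment (`scipy.optimize.linear_sum_assignment`) in the feature
space `(l/σ_l, i/σ_i)`, where σ are the dispersions of the template values;
each template type is duplicated once per ploidy copy (2 here, 36 objects
against 18 × 2 slots). A global optimum replaces greedy nearest-neighbour
matching because greedy ties are order-dependent; inputs are canonically
sorted and ties broken lexicographically so the result is permutation
invariant. Objects whose best and second-best template distances differ by
less than 0.05 normalized-cost units (configurable) are flagged ambiguous —
the automated stand-in for the manual judgement needed where types are
morphologically similar (5L/5S/6S/7L in this karyotype).

## Rearrangement inference

The diploid relative's map is the ancestral proxy; one synteny group per
reference chromosome. All calls operate per subgenome copy, where a locus
with an unresolved copy tag inherits the suffix of the chromosome it
hybridizes to. Arm-level position is the contract; ranks (1-based from the
centromere outward) refine orientation when present.

- **Translocation.** Genes of one group are partitioned by target
  chromosome. A strict minority (< half) on a different chromosome than the
  group majority is called translocated; an exact half split is reported as
  ambiguous rather than called, since the observed evidence patterns are
  1-of-n minorities.
- **Fusion.** Triggered when the majorities of two reference chromosomes
  occupy one target chromosome. Orientation (which centromere survived,
  which arms fused) is chosen by scoring all 2×2×2×2 hypotheses (lost
  chromosome × its fusing arm × retained fusing arm × fused target arm):
  first by arm concordance of predicted vs observed marker positions, then
  by rank-order concordance along each arm (a fused product carries the
  retained arm's genes proximally, then the lost chromosome's fusing-arm
  genes in reversed ancestral order, then its far arm), then — where markers
  cannot distinguish the retained arm — defaulting to the arm matching the
  lost chromosome's orientation, then lexicographically. Markers discordant
  with the winning model are listed as conflicts and downgrade nothing by
  themselves: a call supported by ≥2 concordant markers stands, because a
  single anomalous marker is more parsimoniously a secondary, uninferred
  event than a veto.
- **Inversion.** Homeologous copies of a gene on different arms of
  homeologous chromosomes imply a pericentromeric inversion on the homeolog
  whose arm differs from the outgroup; a perfect rank-order reversal of ≥2
  genes on the same arm implies a paracentric inversion. Without an outgroup
  the call is emitted with undetermined polarity and low confidence.

The rDNA summary is bookkeeping over a signal table: NOR count/locations
from 28S, missing/both-arm/co-localized/low-intensity sets from 5S, with
signal chromosomes validated against the template.

## NOR parsimony

The NOR-bearing chromosome per species is an unordered categorical
character: any relocation costs 1, because the posited mechanism is a direct
jump without intermediate states. Uniform-cost Sankoff dynamic programming
(down-pass + up-pass) handles polytomies natively and reduces to Fitch on
binary trees; stateless leaves (the outgroup) are pruned, never imputed.
Reported: the minimum change count; full most-parsimonious state sets per
internal node; edges where a change is forced in every / possible in at
least one most-parsimonious reconstruction (computed by re-minimizing with
the edge constrained equal/unequal); and one deterministic reconstruction
(lexicographic-minimum tie-break) whose changes are classified
intra-subgenome (3L→4L), inter-subgenome (4L→6S) or unclassifiable when a
state lacks a subgenome suffix (7→7a). On the bundled tree and states the
minimum is 5 jumps (2 intra, 2 inter, 1 unclassifiable); this count is a
derived quantity validated against an exhaustive-enumeration oracle, not a
published number.

## Synthetic data

The measurement generator emulates the study design: 11 metaphases (default)
of an 18-type, 2-copies-per-type karyotype. Per metaphase a global pixel
scale is drawn lognormally (mean 10,000 px total, CV 15% — chosen once as
realistic for captured metaphase spreads); true arm lengths follow from the
template's `(l, i)`; observed arms multiply lognormal noise with CV 5%
(arm level) and 2% (chromatid level) by default. Multiplicative lognormal
noise preserves positivity without truncation artifacts. Template `l`
values are renormalized so the diploid complement sums to exactly 100%
(published medians sum to 100.02%); with all CVs at zero the measurement
pipeline then inverts the generator exactly, a property tested over random
templates. Truth labels ship in a sidecar table, never in the measurement
table, and object ids are shuffled so they carry no type information.

The marker-scenario generator applies translocate/fuse/invert operations to
a duplicated two-copy reference with explicit rank arithmetic (the fusion
uses the same geometry the caller assumes; the pericentromeric inversion
swaps the proximal blocks of both arms), and emits ground-truth calls. The
signal generator applies per-row Bernoulli dropout.

What the simulations do **not** model: chromosome condensation gradients and
banding, correlated measurement error within a spread, arm-identity errors,
probe cross-hybridization, partial or split FISH signals. Passing the
recovery tests therefore demonstrates the pipeline's correctness under its
own statistical assumptions, not robustness to every failure mode of real
cytogenetic data.

## Numerical and degenerate-input choices

Validation is total: malformed tables raise typed errors citing the row, and
no partially constructed object escapes a reader. Metaphases whose
chromosome count differs from the template's 2n are excluded from assignment
(no bijection exists) but still count toward the modal 2n and are reported
as outliers. Duplicate template feature points produce a warning, not a
failure. The ANOVA requires ≥2 observations per group and names the
offending group. Problem sizes used by the test suite and acceptance script
(11–200 metaphases, 500 scenario draws, 3–7-leaf oracle trees) were chosen
as the smallest sizes that exercise each property cleanly.

## Known limitations

Arm+rank resolution cannot localize breakpoints; the fusion caller assumes
at most one fusion per target chromosome pair and ranks markers by a single
linear order per arm; the translocation majority rule is undefined (and
deliberately non-committal) on exact half splits; inversion polarity is only
as good as the outgroup; and the parsimony count assumes NOR relocations are
memoryless single events, ignoring loss/duplication dynamics.
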
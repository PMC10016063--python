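# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the design decisions taken where several reasonable choices
existed.

## Curation

**Length filter.** Within one homolog family, a sequence is removed iff its
(ungapped) length deviates from the family median by more than
`sd_multiplier` (default 1.0) times the sample standard deviation
(n−1 denominator; chosen because families are often small). The keep
interval is closed: a length exactly on a bound is kept, matching a
strictly-greater-than-the-bound removal rule. The rule is deliberately
*not* idempotent under recomputation — removing outliers shrinks the SD, so
a rerun can remove more — which is why the report carries the computed
bounds and `length_filter` accepts frozen bounds for reruns.

**Split-fragment merging.** Incomplete or split records are recognised by a
shared `parent_id` in the domain-hit table: groups of two or more hits
sharing (parent_id, domain) are replaced by a single record carrying the
full parent sequence, with the group's maximum bit score. How duplicate
pairs are detected upstream is outside the package's scope; the `parent_id`
convention is this package's explicit contract for it. The merge runs
*before* the length filter in the canonical order, so that restored
full-length parents are judged by their true length rather than their
fragment lengths.

**Gap trimming.** A column is retained iff its gap fraction is strictly
below `gap_threshold` (defaults offered: 0.90 and 0.99). The strict
inequality is intentional: a column in which exactly 90% of sequences are
gapped is removed at threshold 0.90 and kept at 0.99. Kept columns are
reported as original 1-based indices so trimmed coordinates remain
traceable.

## Distance trees

Distances use pairwise deletion: for each sequence pair only columns
gap-free in both are compared; `p` is the mismatch fraction, and the
`poisson` model applies d = −ln(1−p), with p capped at 0.999 (d ≈ 6.91) so
saturated pairs stay finite. A pair with no comparable columns is an error
naming the pair — silently guessing a distance would corrupt the tree.

Neighbor joining follows Saitou–Nei with the standard Q criterion.
Determinism is engineered, not assumed: input labels are canonically
sorted before agglomeration and Q ties break on the lexicographically
smallest representative-label pair, so the result is invariant to input
order. Negative branch-length estimates (possible on non-additive input)
are clamped to zero, preserving midpoint-rooting validity; on additive
matrices NJ is exact, which the suite verifies to 1e-9 against path-length
oracles.

Midpoint rooting places the root at the midpoint of the longest tip-to-tip
path (ties: lexicographically smallest tip pair; a midpoint landing on a
node, within 1e-12, roots at that node). It is validated against an
exhaustive per-edge closed-form search.

Bootstrap supports are Felsenstein column-resampling proportions: each
replicate resamples all columns with replacement, rebuilds an NJ tree, and
an internal edge's support is the fraction of valid replicates containing
the same unrooted bipartition. A replicate in which some pair loses all
comparable columns is dropped and the denominator adjusted (reported).
Supports live on the [0,1] scale throughout; Newick ingestion divides
values above 1 by 100 so percentage-scaled files read cleanly. These
bootstrap proportions play the *role* of SH-aLRT/UFBoot values in the
workflow this package systematises but are not numerically comparable to
them. In the canonical pipeline the tree is midpoint-rooted first and
support-annotated second, so supports are never re-oriented by rerooting.

## Tree-guided dereplication

"Sisters with matching taxa" is operationalised as two *leaf* children of
the same internal node whose labels at the chosen rank are equal and not
"NA". Same-taxon tips that are not sisters are retained — a documented
limitation of the sister rule itself, mirrored deliberately. Resolution is
iterated to a fixpoint (a `single_pass` mode exists for comparison):
repeatedly, the first matching pair in sorted order loses its lower-scoring
tip (score ties drop the lexicographically larger id), and the resulting
degree-2 node is suppressed by summing its two branch lengths, which
preserves tip-to-tip distances among survivors.

The default intermediate tree for the pipeline is the **midpoint-rooted**
NJ tree (Poisson distances). Rooting is load-bearing: on an unrooted tree,
two redundant tips straddling the point where an outgroup clade attaches
never become sisters and the collapse stalls, whereas on a rooted tree
every pure same-taxon clade contains a cherry until a single representative
remains — and that representative provably carries the clade's maximal
score, since the maximum never loses a pairwise comparison. When the
midpoint is undefined (all-zero distances) the unrooted tree is used as a
fallback. Rounds default to 2 with tree rebuilding between rounds; rounds
with fewer than three surviving records are skipped with a warning.

## Architecture classification

Per protein, domain hits are resolved greedily by descending bit score
(ties: smaller envelope start), keeping a hit iff it overlaps every
already-kept hit by at most `max_overlap_fraction` (default 0.2) of the
shorter envelope — a standard domain-calling convention. The architecture
string is the surviving domain names joined N→C with `+`; classification
is exact ordered-tuple lookup in a registry whose defaults name the known
carotenoid fusion patterns (trifunctional CrtI+CrtB+CrtYc/d, the
quadrifunctional variant with Blh, the two bifunctional patterns, and
generic `single_domain_<name>`); unknown tuples map to `other`. CrtYc and
CrtYd are treated as a single `CrtYc/d` token. Envelope coordinates are
1-based inclusive everywhere.

## Disjunct-clade scan

A transfer signature is reported for every *maximal* clade that is (a)
entirely eukaryotic, (b) spans at least `min_groups` distinct non-NA labels
at the grouping rank, and (c) meets `min_support` (missing support passes
only when the threshold is 0; the root counts as support 1.0 by
convention). Nesting in foreign context is reported as a fraction — the
share of prokaryote and viral tips among the parent clade's other
descendants — rather than thresholded, because nesting is a matter of
degree; viral tips count as foreign context deliberately (giant viruses
are plausible carriers, and counting them foreign is conservative for the
eukaryote-clade predicate). The scan expects a rooted tree; the canonical
pipeline midpoint-roots before scanning. Midpoint rooting can in principle
split a true cluster if the longest path runs through it; in the intended
regime (deep radiation around a compact transferred clade) the midpoint
falls outside the cluster.

## The synthetic-data generator

The generator emulates the structure the analysis assumes, with known
truth:

- **Species tree**: a group-level Yule backbone whose tips are replaced by
  within-group Yule subtrees, guaranteeing each named group is
  monophyletic; every branch length is exponential with mean
  `branch_length_mean` (default 0.1).
- **Sequence evolution**: along a branch of length t each site mutates
  independently with probability 1 − exp(−`subst_rate`·t) (default rate
  0.2) to a uniformly chosen different residue. No indels, no rate
  heterogeneity, no codon structure: the true alignment is the site-wise
  identity, which lets trimming and tree stages be tested without
  implementing an aligner.
- **Transfer**: the cassette domains are carried vertically by the
  prokaryote groups (as single-domain proteins). One donor tip is sampled;
  a transferred ancestral copy is drawn `donor_divergence_scale` time
  units from that tip (default 0.5 in the reference scenario), and each
  recipient's copy evolves a further `post_transfer_scale` units (default
  0.1). The donor-divergence term models the empirical reality that the
  sampled prokaryote nearest a transfer is a *relative* of the true donor,
  not the donor itself; without it the recipients fan out in a star around
  the donor leaf and no recipients-only clade exists to recover. Setting
  both scales to zero reproduces exact donor copies. Recipients are fused
  into one multidomain protein (N→C cassette order, `GS` linker) with
  exact-envelope hits; synthetic bit scores are
  `length × (1 − divergence from the domain's root sequence)` — monotone
  in completeness and conservation, which is all dereplication consumes.
- **Curation workload**: per family, `round(outlier_fraction · n)` members
  are truncated to 40% or extended to 180% of their length, and
  `round(fragment_fraction · n)` are split into two overlapping fragments
  sharing a `parent_id` (both fractions default 0.05). Victims are drawn
  from the single-domain prokaryote members only, so the planted transfer
  signal itself is never corrupted — the recovery experiments measure the
  pipeline, not injection luck.
- **Determinism**: one RNG stream, seeded once, drives every draw;
  identical configs produce byte-identical output trees and tables.

The reference scenario (40 species, six groups of 7/7/6 prokaryotes and
7/7/6 eukaryote supergroups, domain lengths 500/300/120 matching typical
CrtI/CrtB/CrtYc-d proteins) is sized so a full simulate→curate→tree
(100 bootstrap replicates)→scan cycle runs in well under a second, making
50-seed recovery experiments routine.

What passing these tests does *not* show: robustness to alignment error,
indels, rate heterogeneity across sites or lineages, compositional bias,
gene duplication/loss, incomplete taxon sampling, or HMM search artifacts —
all present in real data and all outside the generator. The recovery rates
measure the pipeline's logic under its own model assumptions, not field
performance.

## Pigment quantification

Spectra (sampled every 0.5 nm, 400–800 nm) are zeroed by subtracting the
absorbance at 600 nm (nearest sampled point within 0.25 nm — tolerant of
grid offsets). β-carotene content is
A(454)/(ε·ℓ) · V · M · 1000 / m in mg per g wet biomass, with
ε = 134,000 M⁻¹cm⁻¹ (acetone), M = 536.88 g/mol, path length ℓ defaulting
to 1 cm (exposed as a parameter, since cuvette geometry varies), V the
extract volume in litres and m the wet pellet mass in grams. A negative
zeroed A(454) — a measurement near blank — is clamped to zero with a
warning rather than reported as negative mass. The output is total
carotenoid as β-carotene equivalents; no speciation is attempted.

## Numerical and interface conventions

- All tables are tab-separated UTF-8 with header rows; missing taxonomy
  labels are the explicit string `NA`.
- FASTA ids are the first whitespace-delimited header token; the remainder
  is preserved as the description.
- Branch supports serialise as internal-node labels with six significant
  digits, round-tripping values stated to four.
- Family grouping (orthology inference) is upstream of this package:
  families arrive pre-grouped, from the simulator or an external table.
- Alignment computation is likewise external; the simulator's no-indel
  design provides exact alignments for testing, and externally aligned
  FASTA is accepted anywhere an alignment is consumed.
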
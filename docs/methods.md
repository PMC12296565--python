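# Methods

This note documents the models, conventions, numerical choices and known
limitations behind `agarcode`. Nothing here states a number that the test
suite or `scripts/acceptance.py` does not itself compute.

## Distances and the barcode gap

Pairwise divergence is estimated under the Kimura two-parameter model,
`d = -1/2 ln((1-2P-Q)√(1-2Q))`, with *P* the transition and *Q* the
transversion proportion over comparable sites. Sites are excluded
**pairwise**: a column is dropped for a pair only when either member
carries a gap, N, or an IUPAC ambiguity code there. Pairwise deletion
maximizes the usable sites per pair and matches the "gaps as missing data"
convention; complete deletion would discard a column for everyone.

When the logarithm argument is non-positive (saturation, roughly P ≥ ~0.5
or Q ≥ 0.5) the distance is *undefined* and carried as a flag, never as a
number. Summaries exclude undefined cells and report their count; the NJ
builder imputes them with the maximum defined distance in the matrix
(logged), which preserves the ordering information "at least as far as
anything measured" without inventing a value.

Distance summaries follow two pooling conventions, both reported:

* **intra_mean** pools every conspecific pair;
* **inter_mean** (headline) averages per-species-pair means — printed
  interspecific ranges in comparative barcoding tables read as ranges over
  species pairs — while **inter_mean_pooled** pools all heterospecific
  pairs.

The barcode-gap verdict is `inter_mean / intra_mean ≥ r`. The classical
threshold is r = 10, but comparative studies of these markers treat 5–7×
as operationally sufficient, so r is a parameter (default 10) and both the
ratio and the verdict are reported. A zero intraspecific mean yields an
infinite ratio and an automatic pass, flagged in the note. Between-marker
comparisons use the Welch (unequal-variance) two-sided *t*-test plus
Kruskal–Wallis with tie correction; the *t* variant is Welch because the
distance pools being compared have no reason to share a variance.

## Neighbor-Joining and bootstrap

The tree builder is the classical Saitou–Nei agglomeration. Ties in the
Q-matrix are broken on the lowest (row, column) index pair, so a given
matrix always yields the same tree. Negative branch-length estimates are
clamped to zero for display and Newick output (the convention of the
common GUI tools); the raw estimate is kept on the node (`raw_length`)
because path-length additivity checks need it.

Bootstrap support resamples alignment columns with replacement (B
replicates, default 1000; tests and the acceptance script use 10–100 to
keep runs fast — support saturates quickly on well-separated synthetic
data), rebuilds the NJ tree per replicate, and maps bipartition
frequencies onto the point-estimate tree. One seeded NumPy generator
drives all replicates; the seed appears in the run log. A species is
called monophyletic when some tree bipartition separates exactly its
members; singletons are trivially monophyletic with no support value.

## Haplotypes and SNP%

Within a group, columns carrying a gap/N/ambiguity in *any* member are
excluded from the comparison mask (the "exclude sites with gaps/missing"
behavior of DnaSP). Sequences identical over the mask collapse into one
haplotype, named `<group>_NN` (01-based) by descending carrier count with
first-seen tie-breaks. Segregating sites are mask columns with ≥ 2 states
in the group, and `SNP% = 100 · S / masked_length`. The post-mask
denominator is the only definition under which a ~570-column matK amplicon
with 2 segregating sites gives the conventional 0.35%.

## Median-Joining networks

Construction: (1) Hamming distances over the mask; (2) the ε-relaxed
minimum spanning network — an edge (u,v) is kept iff its weight is within
ε of the minimax (MST bottleneck) distance between u and v, so ε = 0 gives
the union of all MSTs; (3) for triplets connected by at least two network
links, the per-site majority median vector is proposed; the proposal that
most reduces the total network length (minimum spanning length over the
node set) is adopted, and the step iterates to a fixed point; (4) median
vectors whose removal leaves the total length unchanged are pruned, which
also enforces degree ≥ 3 for surviving medians. A triplet with three
distinct states at a site proposes no median (the majority is undefined
there — the multistate analogue of the original algorithm's binary-coding
caveat). Character weights are uniform; iteration order is lexicographic
by node name so outputs are reproducible.

**Limitation.** Median-Joining is a heuristic. On genealogy-derived
haplotype sets (few substitutions per branch, some ancestral types
unsampled — what marker data actually look like) it reproduces exact
Steiner minimal lengths, and the test battery checks this against a
Dreyfus–Wagner dynamic program. On saturated inputs (random sequences at
pairwise distance ~half the sites) it can miss the optimum; such inputs
are outside the method's intended domain and outside the guarantee.

## Diagnostic loci and classification

A diagnostic site is a masked column where the target group is fixed for a
state absent outside the group (strict mode); near mode relaxes fixation
and absence to 1−τ (default τ = 0.05). The scanner takes the group's
majority state as candidate, so on planted-truth data it returns exactly
the planted table.

"+N" positions are **1-based columns of a per-marker reference
alignment** (column 1 = first character). The frame has to be pinned to
something concrete for loci to be testable; the bundled reference
alignments are synthetic stand-ins (`data/*_reference_synthetic.fasta`)
generated from a fixed seed with the key states planted at their loci.
Queries are mapped onto the frame by global pairwise alignment against the
reference majority consensus (match +1, mismatch −1, gap open −5, extend
−1), trying both orientations and keeping the higher score; alignment
identity below 70% is a mapping error. Reference columns deleted in the
query are *indeterminate* and contribute no evidence.

The key ships as an editable TSV (`data/diagnostic_key.tsv`). Species tier:
both matK rules (+435=G, +684=T) must match for an *A. sinensis* call —
they are corroborating, not alternative, evidence; one observed match plus
one observed mismatch is "ambiguous" with the conflict recorded. Origin
tier: +249=C alone gives "Chinese mainland" with species narrowed to
*A. sinensis*/*A. yunnanensis*. The trnL-trnF rules (+173/+183/+200)
refine *origin only* and never override a matK species call; their states
are a convention of the synthetic reference frame, since no published
states exist for them. Two pedigree maps are provided because the source
descriptions disagree: the default ("results") maps Chinese C1/C2 ↔
*A. sinensis*, Indonesian B ↔ *A. malaccensis*, Indochina A ↔
*A. cumingiana*; the alternative ("abstract") splits Chinese C1
(*A. sinensis*) / C2 and letters the other clusters the same way. The
module exposes both and does not arbitrate.

## Synthetic data generator

Per-site independent two-rate substitution process matching the K2P
assumptions: a mutating site transitions with probability κ/(κ+2) and
takes each transversion partner with probability 1/(κ+2); κ is the
transition/transversion *rate* ratio (default 2, a typical plastid value),
so expected transition:transversion *counts* are κ/2. θ parameters are
expected **pairwise** divergences: species ancestors diverge from a
uniform-random root at (θ_inter−θ_intra)/2 each and haplotypes from their
ancestor at θ_intra/2 each, giving conspecific pairs ~θ_intra and
heterospecific pairs ~θ_inter substitutions/site (exact up to multiple
hits, negligible below ~0.1). Alternatively, per-species
`haplotype_subs` plants an exact number of substitutions between
haplotype 1 and each further haplotype — used where published tables fix
a haplotype structure exactly (e.g. 2 haplotypes separated by exactly 2
substitutions among 23 sequences).

Gaps come only from poly(T) slippage windows (per-sequence tract length
drawn from a configured range, padded with gaps to the window width),
mimicking the length-variable homopolymer regions of trnL-trnF; there are
no random indels, so mask semantics are exercised without alignment
ambiguity. Planted diagnostic positions are frozen against random
mutation, must be distinct, and may not fall inside a poly-T window
(config error). One seeded generator drives everything; identical configs
are byte-identical.

**What the generator does not emulate:** recombination, rate
heterogeneity across sites, coalescent genealogies within species,
realistic indel evolution, sequencing error. Passing tests therefore show
the pipeline is correct *under its own model assumptions* and at the
configured divergences; they do not certify performance on markers that
violate them (e.g. heavily length-variable nuclear spacers).

## Study-condition datasets and problem sizes

The supplementary sequence files of the original study are not bundled;
the acceptance datasets are synthetic emulations configured once from the
published numbers and then analyzed blind by the pipeline: per-species
sequence counts and haplotype structure (23 *A. sinensis* sequences in 2
haplotypes 2 substitutions apart, 31 invariant *A. crassna* sequences, a
13-haplotype/10-species clock set), per-marker divergence levels (matK
0.0012/0.0083, ITS2 0.0088/0.0403, rbcL 0.0015/0.0016, trnL-trnF
0.0069/0.0424), the 22:6:6 commercial panel, and the
crassna→rugosa = 4-substitution step of the haplotype genealogy.

Distance recovery runs use 6 species × 12 sequences × 600 columns,
averaged over 3 replicate datasets — averaging reduces the Monte Carlo
error of the check while each dataset keeps the stated conditions.
Divergence-recovery checks use 3 species × 20 × 600. Oracle batteries:
50 K2P pairs, 100 additive trees (n ≤ 8), 12 genealogy-derived MJ
instances (≤ 6 haplotypes × ≤ 12 binary sites), 50 planted-diagnostic
alignments. These sizes were chosen so each check is statistically
informative yet completes in seconds.

## Degenerate inputs and tie-breaks (summary)

* Identical constant groups in statistical comparisons → p = 1 with a
  degeneracy note, no exception.
* Single-haplotype network → one node, no edges; single-sequence group →
  S = 0 with a note.
* Equidistant matrices → NJ joins the lowest-index pair.
* Haplotype name ties → first occurrence in input order.
* Per-sample classification failures (unmappable query, empty sequence)
  → "unclassifiable" result; a panel run never aborts.
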
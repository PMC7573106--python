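# Methods

This note documents the models and procedures implemented in
`degenamp`, the parameters that matter, the numerical choices made
where the design was genuinely open, and what the synthetic-data tests
do and do not demonstrate about real data.

## Primer model

A degenerate primer is a string over the 15 IUPAC DNA codes (DNA only;
`U` is rejected, lowercase is uppercased). Degeneracy is the product of
per-position base-set sizes. Variant enumeration orders each position's
alternatives A<C<G<T with the rightmost position varying fastest;
variant ids are `<name>-NN` with 1-based zero-padded indices. This
ordering is an internal convention — published variant numberings from
other tools can be mapped via an alias table, since enumeration order
is not standardized anywhere.

Melting ranges use the unified nearest-neighbor DNA/DNA parameter set
(SantaLucia 2004, via Biopython's `Tm_NN`) with the entropy salt
correction, defaults 50 mM Na+ and 250 nM oligo. Predicted Tm is
model- and condition-dependent; ranges published elsewhere under
unstated models are not comparable and are not treated as ground truth
anywhere in the package.

## In-silico PCR

A primer position *matches* a template base iff the base is in the
position's IUPAC set; degenerate positions therefore cannot create
mismatches against concrete bases, which makes per-window set-mismatch
counting exactly equivalent to best-variant Hamming counting (the
per-position minimum is attained by a single real variant). A window is
a binding site iff its mismatch count is ≤ `max_mismatches` (default 2)
and no mismatch lies within `protected_3prime_len` (default 5, terminal
base inclusive) of the primer 3' end. For reverse-orientation searches
the primer is matched as its reverse complement on the sense strand and
the protected zone is the left end of the footprint. Template `N`
counts as a mismatch unless the primer position is `N`
(`n_policy="always_match"` relaxes this). Coordinates are 0-based
half-open on the sense strand.

Redundancy and occurrence tallies use exact matching only (a variant
"appears" in a library iff its full-length sequence occurs verbatim on
either strand), mirroring how dead-weight mixture members are defined.
Reported percentages are rounded half-up — redundancy to 1 decimal,
the equal-distribution threshold `100/D` to 2 decimals — because the
conventional printed forms (3.13% for D=32, 1.04% for D=96) are
half-up roundings.

Degeneracy reduction restricts each position's IUPAC set to bases whose
frequency among located reference footprints is ≥ `min_base_freq`,
falling back to the modal base rather than ever emptying a position.
The equimolar subset drops a variant only when its occurrence percent
is below the floor in *every* supplied table (references, clones,
amplicons); the floor is configurable because the underlying
"underrepresented" judgement is qualitative.

## Read pipeline

Identity everywhere is matches / global-alignment columns with end gaps
penalized (computed from edlib's extended CIGAR). This is the quantity
word-filter heuristics in common clustering tools approximate; defining
it exactly makes results reproducible without those tools.

Trimming strips a configured 5' adaptor (exact match near the read
start) and then the gene-specific primer footprint by IUPAC-set
matching with up to 4 mismatches — sequencing errors inside the
footprint must not desynchronize the fixed-length trim. Reads shorter
than the 201 nt target after trimming are discarded, never padded.
Dereplication is exact; singletons (abundance < 2) are removed by
default. Greedy clustering visits uniques in (abundance desc, length
desc, lexicographic) order so results are order-stable, joining the
first centroid at ≥ 90% identity; mapping assigns each read to its
best centroid at the same cutoff with ties to the earlier centroid.
The four clustering variants commonly compared (chimera pre-filter
on/off × nucleotide/peptide space) are plain configuration toggles.

Chimera detection is a two-parent single-crossover model: a query is
flagged iff some crossover of two candidate parents is ≥ `model_min`
(0.98) identical to it and beats the best single parent by ≥
`min_divergence` (0.02). In de-novo mode uniques are processed in
decreasing abundance and only already-accepted uniques with ≥ 2× the
query's abundance may serve as parents; without the acceptance gate,
co-occurring chimeras shield one another from detection. Sequences are
compared positionally and must be pre-trimmed to one length (the
pipeline guarantees this).

## Reference packages and classification

A reference package bundles a region-trimmed codon alignment, its
translation, a profile HMM over the peptides (built with pyhmmer, the
in-process HMMER3), a rooted tree, a 7-rank taxonomy, and flagged
outgroup leaves. Region trimming keeps exactly the alignment columns
holding the anchor record's 1-based ungapped interval; the region
*label* ("201", "654") is a name, not a length assertion, because
published coordinate conventions for the longer region are internally
inconsistent by a few dozen nucleotides. Maximum-likelihood trees are
imported as newick; the built-in neighbor-joining fallback (scikit-bio,
peptide p-distances) exists so packages can be built with no external
tool. Outgroups root the tree (midpoint if none); classification into
the outgroup clade is reported as `paralog`, since the outgroups are
deliberately chosen paralogous sequences meant to absorb non-target
homologs that slip past the profile filter.

Translation requires codon 1 ∈ {ATG, GTG, TTG} (translation table 11
initiators — "the first base is the start codon" does not by itself
pin down the initiator set), translates it as M, and rejects any stop
codon. The profile filter keeps peptides with hmmsearch E-value <
`inclusion_threshold` (1e-7) at a fixed database-size parameter
Z = 1000, so the statistic does not drift with batch size.

Placement is a distance-based approximation, not a likelihood
posterior. The query is aligned into the profile's match columns
(hmmalign); p-distances to every reference leaf are computed over
shared non-gap columns; and for every tree edge the attachment point
`x` along the edge and pendant length `p ≥ 0` minimizing the weighted
RMS between tree-implied and observed distances are fitted (5-point
grid on `x`, closed-form `p`). Residuals carry Fitch-Margoliash
weights `1/max(d, 0.02)²`: p-distances saturate with divergence, and
unweighted fits let the many distant leaves swamp the local signal
that actually determines the attachment. Edge scores are converted to
like-weight ratios by a softmax with temperature 0.0005 (score units
are weighted-RMS distances); the temperature sets the resolution at
which nearly-equal fits share weight — exact ties (e.g. identical
reference peptides) split evenly, while a query identical to one leaf
concentrates ≥ 0.99 of the weight on that leaf's pendant edge.
Placements are exportable as jplace JSON.

The LCA call accumulates like-weight ratio on every taxonomy prefix
implied by each placement edge's subtree (lineages truncate at their
first empty rank), after discarding placements whose attachment edge is
≥ `max_branch_length` (1.0) long — discarded weight is forfeited, not
renormalized, so a sole distant placement yields `unclassified`. The
call is the deepest rank with accumulated weight ≥ `posterior_cutoff`
(0.90); accumulated weight is non-increasing with depth, so confidence
is monotone along the called lineage, raising the cutoff can only
shorten calls, and tightening the branch cap can only unclassify.

## Community statistics

Rank aggregation truncates lineages at the requested rank, with
`unclassified` and `paralog` as explicit categories, and normalizes per
sample. Analytic rarefaction is the hypergeometric expectation
`E[S_d] = Σ_i (1 − C(N−n_i, d)/C(N, d))` (log-gamma arithmetic);
resampling mode averages seeded subsamples without replacement. The
sequencing error rate aligns each read globally to its best-identity
expected template and reports `100·(mismatches+indels)/read bases`.
Weighted UniFrac assigns community mass to the reference-tree leaves
named by classification — not to a de novo OTU tree — and computes
`Σ_e b_e |A_e − B_e|`, divided by `Σ_e b_e (A_e + B_e)` in the
(default) normalized variant; both variants are exposed because the
choice is often unstated in published figures. PCoA is classical
Torgerson scaling; negative eigenvalues are reported and their axes
dropped, with no Cailliez correction by default.

## Synthetic data: what it emulates, and what it does not

The generator derives a random root gene laid out as flank /
forward-primer footprint / coding region / spacer / reverse-primer
footprint / flank (amplicon span 950 nt by default, matching the
target product size; classified coding region 240 nt so the 201 nt
analysis window fits). Clade ancestors diverge from the root at the
between-clade rate (default 0.20, placing clades well below the 90%
clustering cutoff), taxa at the within-clade rate (default 0.02), and
a monophyletic outgroup pair at 0.40. Mutations never touch the
planted footprints or the start codon, and substitutions inside the
coding region are redrawn rather than allowed to create in-frame
stops, so error-free material survives the translation filter by
construction. Primer-variant usage at each planted site is drawn from
a configurable distribution (uniform by default), which is what makes
redundancy and occurrence statistics exercisable. Mock runs draw
templates with largest-remainder integer counts for the preset
compositions 41/50/9 and 59/7/35 (the latter totals 101% as printed
and is normalized), prepend the 5' adaptor, apply i.i.d. substitutions
(no indels by default, since the pipeline trims to fixed length), and
form two-parent crossover chimeras with the crossover drawn from the
central 141 nt of the analysis window so both parents contribute a
genuinely recombinant segment.

Passing tests on this material shows the pipeline's bookkeeping,
thresholds and invariants are correct under controlled conditions. It
does not demonstrate robustness to properties real amplicon data has
and the generator deliberately lacks: PCR amplification bias,
position- and instrument-dependent quality profiles, indel errors,
partial primer sites, frame-shifted or off-target reads, or reference
libraries with the phylogenetic imbalance of real isolate collections.

## Problem sizes in tests

The default suite runs simulations at modest, fixed sizes chosen as
adequate for their statistical tolerances: 1,000 random templates up
to 5 kb for the matcher/oracle comparison, 2,000-read mock runs for
composition recovery, 10,000 reads for the ±0.2-point error-rate
check, 1,000 reads at 10% chimera rate for detector calibration, and
100 reads for per-read classification accuracy. All generators and
tests are seeded; identical inputs and configuration produce
byte-identical outputs.

## Known limitations

* Placement weights are a calibrated heuristic, not Bayesian
  posteriors; on real reference trees with very uneven sampling the
  like-weight ratios are best read comparatively.
* The chimera model considers single crossovers only; multi-parent or
  multi-breakpoint artifacts are out of scope.
* Greedy clustering is exact but O(n·k) in alignment calls; for very
  large unique sets a word-filtered tool will be faster (results then
  differ by its heuristics).
* The NJ fallback tree is adequate for classification topology but is
  not a substitute for ML inference when branch lengths matter
  downstream.
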
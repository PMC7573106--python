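# degenamp

Degenerate-primer auditing and functional-gene amplicon taxonomic
profiling, built around the marker-gene workflow used to survey
mercury-methylating microbes: the *hgcAB* gene pair is required for
microbial conversion of inorganic mercury to neurotoxic methylmercury,
and broad-range degenerate PCR primers against it are the standard way
to ask *which* organisms in an environment can methylate mercury.

The package is for microbial ecologists who design or use degenerate
primers for any functional marker gene and want to (a) audit a primer
mixture quantitatively before ordering oligos, and (b) turn amplicon
reads into placement-based taxonomy without opaque external pipelines.

## What it computes

**Primer algebra.** A degenerate primer written with IUPAC ambiguity
codes stands for a mixture of concrete oligos. Its *degeneracy* is
`D = prod_i |S_i|` over the per-position base sets `S_i`; variants are
enumerated deterministically (A<C<G<T, rightmost fastest) so variant
ids like `uni-32R-05` are stable. Melting ranges are nearest-neighbor
(unified DNA/DNA parameters, salt-corrected) extremes over the mixture.

**In-silico PCR.** A primer binds a template window iff every position's
template base lies in the primer's IUPAC set, up to `m` mismatches
(default 2) with **no** mismatch within 5 nt of the primer 3' end —
3'-proximal mismatches block extension. On top of the matcher:

* *efficiency* — fraction of reference genes with a tolerated site;
* *specificity* — fraction of paralog decoys (e.g. non-target 4Fe-4S
  ferredoxins sharing the CXXCXXC motif) hit per mismatch level;
* *redundancy* — variants exactly matching nothing (`100·k/D` %);
* *occurrence* — per-variant exact footprint tallies in observed
  clones/amplicons versus the equal-use line `100/D` %;
* rule-driven degeneracy reduction and equimolar subset selection.

**Amplicon pipeline.** Adaptor/primer stripping and trimming to 201 nt,
exact dereplication with singleton removal, two-parent crossover
chimera detection, greedy centroid clustering at 90% identity
(nucleotide or peptide space; identity = matches / global-alignment
columns), and read mapping to an OTU × sample count table.

**Classification.** OTU centroids (or reads) are translated (table 11,
initiator start required, stop codons rejected), filtered against a
profile model of the reference peptide region (inclusion E-value <
1e-7), placed on the rooted reference tree by weighted least-squares
distance fits to every edge, and assigned the deepest lineage whose
accumulated like-weight ratio reaches 90%. Placements on attachment
branches ≥ 1 substitution/site stay unclassified; placements in the
outgroup clade are reported as paralogs.

**Community statistics.** Rank-truncated relative abundance, analytic
(hypergeometric) and resampled rarefaction, mock-community sequencing
error rates, weighted UniFrac `Σ_e b_e |A_e − B_e|` (optionally
normalized by `Σ_e b_e (A_e + B_e)`), and classical PCoA.

**Synthetic data.** Every stage is testable offline: clade-structured
reference libraries with planted primer footprints and controlled
variant usage, paralog decoys with near-miss binding sites, and mock
amplicon runs with preset compositions (41/50/9 and 59/7/35), i.i.d.
substitution errors, chimeras, and 5' adaptors.

## Worked example

```bash
python examples/primer_arithmetic.py
```

prints, among other lines:

```
uni-F    AAYGTCTGGTGYGCNGCVGG  degeneracy= 48 equal-use threshold= 2.08%  Tm 59.2-69.0 C
uni-R    CABGCNCCRCAYTCCATRCA  degeneracy= 96 equal-use threshold= 1.04%  Tm 53.8-67.3 C
uni-32R  CAGGCNCCGCAYTCSATRCA  degeneracy= 32 equal-use threshold= 3.13%  Tm 58.4-66.8 C

redesign via edits 3:G 9:G 15:S -> CAGGCNCCGCAYTCSATRCA (degeneracy 96 -> 32)
```

The degeneracy is the number of distinct oligos in each synthesized
mixture; the threshold is the percent occurrence each oligo would show
if all amplified equally (variants persistently below it are candidates
for removal); the edits reproduce the reverse-primer redesign that cut
the mixture from 96 to 32 oligos. `examples/primer_audit.py`,
`examples/amplicon_pipeline.py` and `examples/classify_and_profile.py`
walk the audit, the read pipeline, and classification/UniFrac/PCoA the
same way, and the `degenamp` console command exposes each stage
(`simulate`, `primer-audit`, `primer-reduce`, `refpkg-build`,
`pipeline`, `classify`, `stats`) for shell use.

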
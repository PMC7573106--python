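"""Placement-based classification and community summaries.

Builds a reference package (region-trimmed alignment + profile model +
rooted tree + taxonomy) from a synthetic library, classifies OTU
centroids from a mock run, and derives phylum-level profiles, weighted
UniFrac distances between two mock communities, a principal-coordinates
embedding, and a rarefaction curve.
"""

from dataclasses import replace

from degenamp.classify import classify_sequences
from degenamp.pipeline import PipelineConfig, run_pipeline
from degenamp.simulate import (
    ADAPTOR_FWD,
    FORWARD_PRIMER,
    SimulationConfig,
    build_package_from_synthetic,
    make_reference_library,
    mock_composition,
    simulate_amplicon_run,
)
from degenamp.stats import aggregate_rank, pcoa, rarefaction, weighted_unifrac

config = SimulationConfig(seed=6, n_reads=1500)
syn = make_reference_library(config)
package = build_package_from_synthetic(syn)
print(f"reference package: {len(package.aa_alignment)} leaves, "
      f"profile over {package.profile.length} residues, "
      f"outgroups {sorted(package.outgroup_ids)}")

profiles = {}
tables = {}
for preset in ("combo1", "combo2"):
    run = simulate_amplicon_run(
        syn,
        replace(config, composition=mock_composition(syn, preset),
                sample_name=preset),
    )
    result = run_pipeline(
        run.reads, PipelineConfig(adaptors=(ADAPTOR_FWD,), primer=FORWARD_PRIMER)
    )
    calls = classify_sequences(
        [(o.id, o.centroid.sequence) for o in result.table.otus], package
    )
    profile = aggregate_rank(calls, result.table.counts, "phylum")
    tables[preset] = result.table
    print(f"\n{preset} phylum profile (fraction of reads):")
    print(profile.to_string())
    # mass per classified OTU, truncated at phylum and normalized per sample
    class_calls = calls.set_index("query_id")
    leaf_mass = {}
    for otu in result.table.otus:
        row = class_calls.loc[otu.id]
        if row["status"] == "classified":
            species = row["lineage"].split(";")[-1]
            leaf = syn.truth.set_index("species").loc[species, "id"]
            leaf_mass[leaf] = leaf_mass.get(leaf, 0.0) + float(
                result.table.counts.loc[otu.id, preset]
            )
    profiles[preset] = leaf_mass

d = weighted_unifrac(profiles, package.tree)
print("\nweighted UniFrac distance combo1 vs combo2:",
      round(float(d.loc['combo1', 'combo2']), 4))
# phylogeny-aware distance between the two mock compositions (0 =
# identical placement-weighted communities, 1 = fully disjoint)

embedding = pcoa(d)
print("PCoA axis-1 coordinates:",
      embedding.coordinates["PC1"].round(4).to_dict())

counts = tables["combo1"].counts["combo1"]
curve = rarefaction(list(counts), depths=[10, 100, 500, int(counts.sum())])
print("\nrarefaction (expected OTU richness by depth):")
print(curve.to_string(index=False))
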
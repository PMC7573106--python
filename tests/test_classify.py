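"""Translation filters, placement, and LCA classification."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from degenamp.classify import (
    Classification,
    ClassifierConfig,
    PlacementResult,
    Rejection,
    classify_lca,
    classify_sequences,
    place,
    profile_filter,
    translate_filter,
    write_jplace,
)

CONFIG = ClassifierConfig()


class TestTranslateFilter:
    def test_atg_start_translates(self):
        assert translate_filter("ATGGCTGGT") == "MAG"

    def test_internal_stop_rejected(self):
        result = translate_filter("ATGTAAGGT")
        assert isinstance(result, Rejection) and result.reason == "stop_codon"

    def test_alternative_initiators_accepted_as_m(self):
        assert translate_filter("GTGGCTGGT") == "MAG"
        assert translate_filter("TTGGCTGGT") == "MAG"

    def test_non_initiator_start_rejected(self):
        result = translate_filter("CTGGCTGGT")
        assert isinstance(result, Rejection)
        assert result.reason == "bad_start_codon"

    def test_trailing_partial_codon_dropped(self):
        assert translate_filter("ATGGCTGG") == "MA"


class TestProfileFilter:
    def test_reference_peptides_all_pass(self, package):
        peptides = {
            rid: row.replace("-", "")
            for rid, row in package.aa_alignment.items()
        }
        kept, scores = profile_filter(peptides, package, CONFIG)
        assert set(kept) == set(peptides)

    def test_shuffled_peptides_rarely_pass(self, package):
        rng = np.random.default_rng(19)
        peptide = next(iter(package.aa_alignment.values())).replace("-", "")
        shuffled = {
            f"s{i}": "".join(rng.permutation(list(peptide))) for i in range(100)
        }
        kept, _ = profile_filter(shuffled, package, CONFIG)
        assert len(kept) <= 5

    def test_output_subset_of_input(self, package):
        peptides = {"q": next(iter(package.aa_alignment.values())).replace("-", "")}
        kept, scores = profile_filter(peptides, package, CONFIG)
        assert set(kept) <= set(peptides) and set(scores) == set(peptides)


class TestPlace:
    def test_self_placement_concentrates_on_own_pendant_edge(self, package):
        for rid in list(package.reference_ids)[:4]:
            peptide = package.aa_alignment[rid].replace("-", "")
            placements = place(peptide, package, CONFIG, query_id=rid)
            assert placements[0].edge_id == rid
            assert placements[0].like_weight_ratio >= 0.99

    def test_like_weight_ratios_sum_to_one(self, package):
        peptide = next(iter(package.aa_alignment.values())).replace("-", "")
        placements = place(peptide, package, CONFIG)
        assert sum(p.like_weight_ratio for p in placements) == pytest.approx(1.0)

    def test_equidistant_query_splits_weight_between_sisters(self):
        """A query exactly between two sister leaves of a symmetric
        four-taxon tree lands on the sisters (or their parent edge)
        with near-equal weights."""
        from degenamp.refpkg import build_refpkg, RegionSpec

        # hand-built codon alignment: A and B differ at two codons; the
        # query (built below) matches one codon from each
        base = "ATGGCTGGTACTGCTGGTACTGCTGGTACT"  # 10 codons
        seq_a = base
        seq_b = base[:3] + "TCT" + base[6:27] + "TTT"
        seq_c = base[:12] + "CCTCCTCCTCCTCCT" + base[27:]
        seq_d = seq_c[:3] + "TCT" + seq_c[6:27] + "TTT"
        taxonomy = {
            "A": ("Bacteria", "P1", "C1", "O1", "F1", "G1", "S_A"),
            "B": ("Bacteria", "P1", "C1", "O1", "F1", "G1", "S_B"),
            "C": ("Bacteria", "P2", "C2", "O2", "F2", "G2", "S_C"),
            "D": ("Bacteria", "P2", "C2", "O2", "F2", "G2", "S_D"),
        }
        pkg = build_refpkg(
            name="sym",
            region=RegionSpec("sym", "A", (1, 30)),
            nt_alignment={"A": seq_a, "B": seq_b, "C": seq_c, "D": seq_d},
            taxonomy=taxonomy,
        )
        # query shares one differing codon with A and the other with B
        query_nt = base[:3] + "TCT" + base[6:]
        from degenamp.classify import translate_filter

        query_pep = translate_filter(query_nt)
        placements = place(query_pep, pkg, CONFIG, query_id="q")
        top_two = placements[:2]
        assert {p.edge_id for p in top_two} <= {"A", "B", "edge_0", "edge_1", "edge_2"}
        assert top_two[0].like_weight_ratio == pytest.approx(
            top_two[1].like_weight_ratio, rel=0.05
        )


def _placement(leaves, lwr, branch_length=0.1, edge="e"):
    return PlacementResult(
        query_id="q", edge_id=edge, like_weight_ratio=lwr,
        branch_length=branch_length, pendant_length=0.01,
        distal_length=0.0, score=0.0, leaves=tuple(leaves),
    )


class TestClassifyLCA:
    def test_single_full_weight_placement_gives_species_call(self, package):
        leaf = package.reference_ids[0]
        call = classify_lca([_placement([leaf], 1.0)], package, CONFIG)
        assert call.status == "classified"
        assert call.lineage == package.taxonomy[leaf]
        assert call.rank == "species"
        assert call.confidence == pytest.approx(1.0)

    def test_split_weight_truncates_to_common_ancestor(self, package):
        # two species of one genus at 0.5/0.5 -> genus-level call
        clade0 = [r for r in package.reference_ids if r.startswith("ref_c0")]
        a, b = clade0[0], clade0[1]
        call = classify_lca(
            [_placement([a], 0.5, edge="e1"), _placement([b], 0.5, edge="e2")],
            package, CONFIG,
        )
        assert call.rank == "genus"
        assert call.lineage == package.taxonomy[a][:6]
        assert call.confidence == pytest.approx(1.0)

    def test_long_attachment_branch_is_unclassified(self, package):
        leaf = package.reference_ids[0]
        call = classify_lca(
            [_placement([leaf], 1.0, branch_length=1.2)], package, CONFIG
        )
        assert call.status == "unclassified"

    def test_empty_placements_unclassified(self, package):
        call = classify_lca([], package, CONFIG)
        assert call.status == "unclassified"

    def test_outgroup_placement_reports_paralog(self, package):
        out = sorted(package.outgroup_ids)[0]
        call = classify_lca([_placement([out], 1.0)], package, CONFIG)
        assert call.status == "paralog"

    def test_confidence_monotone_along_lineage(self, package):
        clade0 = [r for r in package.reference_ids if r.startswith("ref_c0")]
        placements = [
            _placement([clade0[0]], 0.6, edge="e1"),
            _placement([clade0[1]], 0.35, edge="e2"),
            _placement(clade0, 0.05, edge="e3"),
        ]
        config = replace(CONFIG, posterior_cutoff=0.5)
        call = classify_lca(placements, package, config)
        # accumulated weight cannot grow with depth
        deeper = classify_lca(placements, package, replace(CONFIG, posterior_cutoff=0.95))
        assert call.confidence <= 1.0 + 1e-9
        assert len(deeper.lineage) <= len(call.lineage)

    def test_raising_cutoff_never_deepens_call(self, package):
        clade0 = [r for r in package.reference_ids if r.startswith("ref_c0")]
        placements = [
            _placement([clade0[0]], 0.7, edge="e1"),
            _placement([clade0[1]], 0.3, edge="e2"),
        ]
        depths = []
        for cutoff in (0.5, 0.7, 0.9, 1.0):
            call = classify_lca(
                placements, package, replace(CONFIG, posterior_cutoff=cutoff)
            )
            depths.append(len(call.lineage))
        assert depths == sorted(depths, reverse=True)

    def test_lowering_branch_cap_never_classifies_more(self, package):
        leaf = package.reference_ids[0]
        placements = [_placement([leaf], 1.0, branch_length=0.5)]
        loose = classify_lca(
            placements, package, replace(CONFIG, max_branch_length=1.0)
        )
        tight = classify_lca(
            placements, package, replace(CONFIG, max_branch_length=0.4)
        )
        assert loose.status == "classified" and tight.status == "unclassified"


class TestClassifySequences:
    def test_reference_leaves_classify_to_their_own_lineage(self, package):
        items = [
            (rid, package.nt_alignment[rid]) for rid in package.reference_ids
        ]
        table = classify_sequences(items, package)
        by_id = table.set_index("query_id")
        aa = package.aa_alignment
        for rid in package.reference_ids:
            row = by_id.loc[rid]
            assert row["status"] == "classified"
            called = tuple(row["lineage"].split(";"))
            assert called == package.taxonomy[rid][: len(called)]
            # leaves with a unique peptide resolve to species level
            if sum(v == aa[rid] for v in aa.values()) == 1:
                assert row["rank"] == "species"

    def test_error_free_reads_recover_phylum(self, synthetic_library, package):
        from degenamp.pipeline import PipelineConfig, run_pipeline
        from degenamp.simulate import (
            ADAPTOR_FWD,
            FORWARD_PRIMER,
            mock_composition,
            simulate_amplicon_run,
        )

        config = replace(
            synthetic_library.config, n_reads=150,
            composition=mock_composition(synthetic_library),
        )
        run = simulate_amplicon_run(synthetic_library, config)
        from degenamp.pipeline import trim_and_filter

        trimmed = trim_and_filter(
            run.reads, adaptors=(ADAPTOR_FWD,), primer=FORWARD_PRIMER
        )
        table = classify_sequences(trimmed[:100], package)
        truth = run.truth.set_index("read_id")
        tax = synthetic_library.truth.set_index("id")
        correct = 0
        total = 0
        for _, row in table.iterrows():
            source = truth.loc[row["query_id"], "source_id"]
            expected_phylum = tax.loc[source, "phylum"]
            lineage = row["lineage"].split(";") if row["lineage"] else []
            total += 1
            if len(lineage) >= 2 and lineage[1] == expected_phylum:
                correct += 1
        assert total > 0
        assert correct / total >= 0.95

    def test_paralog_reads_never_get_methylator_lineage(self, package, synthetic_library):
        outgroup_seqs = [
            (rid, package.nt_alignment[rid])
            for rid in sorted(package.outgroup_ids)
        ]
        table = classify_sequences(outgroup_seqs, package)
        assert set(table["status"]) <= {
            "paralog", "rejected_profile", "rejected_bad_start_codon",
            "rejected_stop_codon", "unclassified",
        }

    def test_empty_input_empty_table(self, package):
        table = classify_sequences([], package)
        assert len(table) == 0


def test_short_and_long_region_phylum_calls_agree(sim_config):
    """Packages over the short amplicon region and a longer clone-style
    region agree at phylum level for error-free queries."""
    from degenamp.simulate import (
        SimulationConfig,
        build_package_from_synthetic,
        make_reference_library,
    )

    config = SimulationConfig(seed=31, coding_length=480, amplicon_length=950)
    syn = make_reference_library(config)
    short_pkg = build_package_from_synthetic(syn, label="201", region_length=201)
    long_pkg = build_package_from_synthetic(syn, label="654", region_length=480)

    coords = syn.truth.set_index("id")
    queries = []
    for rec in syn.library:
        if rec.id.startswith("outgroup"):
            continue
        start = int(coords.loc[rec.id, "fwd_end"])
        queries.append((rec.id, rec.sequence[start : start + 480]))

    short_calls = classify_sequences(
        [(q, seq[:201]) for q, seq in queries], short_pkg
    ).set_index("query_id")
    long_calls = classify_sequences(queries, long_pkg).set_index("query_id")
    agree = 0
    for qid, _ in queries:
        p_short = (short_calls.loc[qid, "lineage"].split(";") + ["", ""])[1]
        p_long = (long_calls.loc[qid, "lineage"].split(";") + ["", ""])[1]
        agree += p_short == p_long and p_short != ""
    assert agree / len(queries) >= 0.90


def test_jplace_export(package, tmp_path):
    import json

    leaf = package.reference_ids[0]
    peptide = package.aa_alignment[leaf].replace("-", "")
    placements = {leaf: place(peptide, package, CONFIG, query_id=leaf)}
    out = tmp_path / "placements.jplace"
    write_jplace(placements, package, out)
    with open(out) as fh:
        doc = json.load(fh)
    assert doc["version"] == 3
    assert doc["fields"][0] == "edge_num"
    assert doc["placements"][0]["n"] == [leaf]
    assert "{" in doc["tree"]
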
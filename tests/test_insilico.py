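"""In-silico PCR matching and primer audit statistics."""

import itertools

import numpy as np
import pytest

from degenamp._iupac import IUPAC_SETS, reverse_complement
from degenamp.insilico import (
    MatchPolicy,
    apply_edits,
    conservation_profile,
    efficiency,
    equal_distribution_threshold,
    find_binding_sites,
    occurrence_tally,
    predict_amplicons,
    redundancy,
    reduce_degeneracy,
    select_equimolar_subset,
    specificity_screen,
)
from degenamp.library import ReferenceLibrary, TargetSequence
from degenamp.primers import DegeneratePrimer, degeneracy, expand

PRIMER = DegeneratePrimer("p", "ACGTACGTAC")
NO_PROTECT = MatchPolicy(max_mismatches=2, protected_3prime_len=0)


def _target(seq, rec_id="t1", role="reference_gene"):
    return TargetSequence(id=rec_id, sequence=seq, role=role)


def _plant(footprint, left=30, right=30, fill="G"):
    return fill * left + footprint + fill * right


class TestFindBindingSites:
    def test_exact_planted_footprint(self):
        target = _target(_plant("ACGTACGTAC"))
        sites = find_binding_sites(PRIMER, target, MatchPolicy())
        assert len(sites) == 1
        site = sites[0]
        assert (site.start, site.end) == (30, 40)
        assert site.mismatch_count == 0
        assert site.strand == "+"
        assert site.best_variant_id == "p-01"

    def test_mismatch_near_3prime_disqualifies(self):
        # substitution 3 bases from the primer 3' end (offset 2 < 5)
        footprint = "ACGTACGAAC"  # T->A at offset 2 from 3' end
        target = _target(_plant(footprint))
        assert find_binding_sites(PRIMER, target, MatchPolicy()) == []

    def test_same_mismatch_near_5prime_allowed(self):
        footprint = "ACTTACGTAC"  # G->T at position 3 from the 5' end
        target = _target(_plant(footprint))
        sites = find_binding_sites(PRIMER, target, MatchPolicy())
        assert len(sites) == 1
        assert sites[0].mismatch_count == 1
        assert sites[0].mismatch_offsets == (7,)

    def test_reverse_orientation_protection_is_left_anchored(self):
        # reverse footprint on the sense strand = revcomp(primer); the
        # primer 3' end sits at the footprint's left edge
        fp = reverse_complement(PRIMER.sequence)
        near_3prime = "T" + fp[1:] if fp[0] != "T" else "A" + fp[1:]
        near_5prime = fp[:-1] + ("T" if fp[-1] != "T" else "A")
        assert not find_binding_sites(
            PRIMER, _target(_plant(near_3prime)), MatchPolicy(), "reverse"
        )
        sites = find_binding_sites(
            PRIMER, _target(_plant(near_5prime)), MatchPolicy(), "reverse"
        )
        assert len(sites) == 1 and sites[0].strand == "-"

    def test_primer_longer_than_target_is_empty(self):
        assert find_binding_sites(PRIMER, _target("ACGT"), MatchPolicy()) == []

    def test_degenerate_position_matches_all_its_bases(self):
        primer = DegeneratePrimer("p", "ACGTNCGTAC")
        for base in "ACGT":
            target = _target(_plant("ACGT" + base + "CGTAC"))
            sites = find_binding_sites(primer, target, MatchPolicy())
            assert len(sites) == 1 and sites[0].mismatch_count == 0

    def test_target_n_policy(self):
        target = _target(_plant("ACGTNCGTAC"))
        strict = find_binding_sites(PRIMER, target, NO_PROTECT)
        assert strict and strict[0].mismatch_count == 1
        lenient = find_binding_sites(
            PRIMER, target,
            MatchPolicy(max_mismatches=2, protected_3prime_len=0,
                        n_policy="always_match"),
        )
        assert lenient[0].mismatch_count == 0


def _brute_force_sites(primer_seq, target_seq, policy, orientation):
    """Independent oracle: all windows x all concrete variants."""
    variants = [
        "".join(c)
        for c in itertools.product(*(IUPAC_SETS[ch] for ch in primer_seq))
    ]
    k = len(primer_seq)
    codes = np.frombuffer(target_seq.encode(), dtype=np.uint8)
    found = {}
    for variant in variants:
        pattern = variant if orientation == "forward" else reverse_complement(variant)
        pat = np.frombuffer(pattern.encode(), dtype=np.uint8)
        for start in range(len(target_seq) - k + 1):
            window = codes[start : start + k]
            mm = window != pat
            count = int(mm.sum())
            if count > policy.max_mismatches:
                continue
            offsets = [
                (k - 1 - j) if orientation == "forward" else j
                for j in np.nonzero(mm)[0].tolist()
            ]
            if any(off < policy.protected_3prime_len for off in offsets):
                continue
            if start not in found or count < found[start]:
                found[start] = count
    return found


@pytest.mark.parametrize("orientation", ["forward", "reverse"])
def test_sites_agree_with_brute_force_oracle(orientation):
    rng = np.random.default_rng(17)
    codes = sorted(IUPAC_SETS)
    for trial in range(40):
        k = int(rng.integers(8, 15))
        primer_seq = "".join(
            "ACGT"[rng.integers(0, 4)] for _ in range(k)
        )
        # sprinkle up to three degenerate positions
        chars = list(primer_seq)
        for pos in rng.choice(k, size=int(rng.integers(0, 4)), replace=False):
            chars[pos] = codes[int(rng.integers(0, len(codes)))]
        primer_seq = "".join(chars)
        if degeneracy(primer_seq) > 64:
            continue
        target_seq = "".join(
            "ACGT"[i] for i in rng.integers(0, 4, size=int(rng.integers(50, 400)))
        )
        policy = MatchPolicy(
            max_mismatches=int(rng.integers(0, 3)),
            protected_3prime_len=int(rng.integers(0, 6)),
        )
        target = _target(target_seq)
        got = {
            s.start: s.mismatch_count
            for s in find_binding_sites(primer_seq, target, policy, orientation)
        }
        assert got == _brute_force_sites(primer_seq, target_seq, policy, orientation)


class TestEfficiency:
    def test_library_of_own_variants_is_fully_covered(self):
        lib = ReferenceLibrary(
            _target(_plant(v.sequence), rec_id=v.id) for v in expand(PRIMER)
        )
        assert efficiency(PRIMER, lib).fraction == 1.0

    def test_planted_three_of_four(self):
        lib = ReferenceLibrary(
            [
                _target(_plant("ACGTACGTAC"), "a"),
                _target(_plant("ACGTACGTAC"), "b"),
                _target(_plant(reverse_complement("ACGTACGTAC")), "c"),
                _target("G" * 70, "d"),
            ]
        )
        assert efficiency(PRIMER, lib).fraction == 0.75

    def test_monotone_in_max_mismatches(self, synthetic_library):
        from degenamp.simulate import REVERSE_PRIMER_32

        fractions = [
            efficiency(
                REVERSE_PRIMER_32,
                synthetic_library.library,
                MatchPolicy(max_mismatches=m, protected_3prime_len=5),
            ).fraction
            for m in range(3)
        ]
        assert fractions == sorted(fractions)

    def test_empty_library_raises(self):
        with pytest.raises(ValueError):
            efficiency(PRIMER, ReferenceLibrary())


class TestSpecificity:
    def test_no_planted_sites_no_exact_hits(self, paralog_library):
        from degenamp.simulate import REVERSE_PRIMER_32

        lib, truth = paralog_library
        result = specificity_screen(
            REVERSE_PRIMER_32, lib,
            MatchPolicy(max_mismatches=0, protected_3prime_len=5),
        )
        assert result.counts[0] == 0

    def test_near_miss_fraction_hit_at_two_mismatches(self, paralog_library):
        from degenamp.simulate import REVERSE_PRIMER_32

        lib, truth = paralog_library
        result = specificity_screen(
            REVERSE_PRIMER_32, lib,
            MatchPolicy(max_mismatches=2, protected_3prime_len=5),
        )
        expected = int(truth["near_miss"].sum())
        assert result.counts[2] == expected
        assert result.fractions[2] == expected / len(lib)
        # nesting: exact hits are contained in the 2-mismatch hits
        assert result.counts[0] <= result.counts[1] <= result.counts[2]


class TestRedundancy:
    def _library_with_planted(self, primer, n_present):
        variants = expand(primer)
        return ReferenceLibrary(
            _target(_plant(v.sequence), rec_id=f"r{v.index}")
            for v in variants[:n_present]
        )

    def test_50_of_96_unmatched_prints_52_1(self):
        primer = DegeneratePrimer("R", "CABGCNCCRCAYTCCATRCA")
        lib = self._library_with_planted(primer, 96 - 50)
        result = redundancy(primer, lib)
        assert (result.count, result.percent) == (50, 52.1)

    def test_14_of_32_unmatched_prints_43_8(self):
        primer = DegeneratePrimer("R32", "CAGGCNCCGCAYTCSATRCA")
        lib = self._library_with_planted(primer, 32 - 14)
        result = redundancy(primer, lib)
        assert (result.count, result.percent) == (14, 43.8)

    def test_all_variants_present_zero_redundancy(self):
        lib = self._library_with_planted(PRIMER, degeneracy(PRIMER))
        result = redundancy(PRIMER, lib)
        assert (result.count, result.percent) == (0, 0.0)

    def test_partition_invariant(self, synthetic_library):
        from degenamp.simulate import REVERSE_PRIMER_32

        result = redundancy(REVERSE_PRIMER_32, synthetic_library.library)
        matched = degeneracy(REVERSE_PRIMER_32) - result.count
        assert matched + result.count == degeneracy(REVERSE_PRIMER_32)
        assert matched >= 1


@pytest.mark.parametrize(
    "deg, expected", [(32, 3.13), (96, 1.04), (1, 100.0), (48, 2.08)]
)
def test_equal_distribution_threshold(deg, expected):
    assert equal_distribution_threshold(deg) == expected


def test_equal_distribution_threshold_rejects_zero():
    with pytest.raises(ValueError):
        equal_distribution_threshold(0)


class TestOccurrence:
    def test_uniform_usage_hits_threshold_no_flags(self):
        primer = DegeneratePrimer("p", "ACGTACGTAR")
        observed = ReferenceLibrary(
            _target(_plant(v.sequence), rec_id=f"o{v.index}", role="clone")
            for v in expand(primer)
        )
        table = occurrence_tally(primer, observed)
        assert all(r.percent == table.threshold for r in table.rows)
        assert not any(r.below_threshold for r in table.rows)

    def test_planted_50_of_100(self):
        primer = DegeneratePrimer("p", "ACGTACGTAR")
        v1, v2 = expand(primer)
        recs = [
            _target(_plant(v1.sequence), f"a{i}", "amplicon") for i in range(50)
        ] + [
            _target(_plant(v2.sequence), f"b{i}", "amplicon") for i in range(50)
        ]
        table = occurrence_tally(primer, ReferenceLibrary(recs))
        assert table.percents() == {"p-01": 50.0, "p-02": 50.0}

    def test_counts_are_conserved(self, synthetic_library):
        from degenamp.simulate import REVERSE_PRIMER_32

        table = occurrence_tally(REVERSE_PRIMER_32, synthetic_library.library)
        assert sum(r.count for r in table.rows) == table.n_with_footprint
        assert table.n_with_footprint == len(synthetic_library.library)


class TestConservationProfile:
    def test_categories(self):
        profile = conservation_profile(["AAA", "AAC", "ACG", "ACT"])
        # column 0: all A -> 100 (full)
        assert profile[0]["mean_pairwise_identity"] == 100.0
        assert profile[0]["category"] == "full"
        # column 1: {A,A,C,C} -> 2 matching pairs of 6 -> 33.3 (mid)
        assert profile[1]["mean_pairwise_identity"] == 33.3
        assert profile[1]["category"] == "mid"
        # column 2: {A,C,G,T} -> no matching pairs (low)
        assert profile[2]["mean_pairwise_identity"] == 0.0
        assert profile[2]["category"] == "low"

    def test_ragged_input_raises(self):
        with pytest.raises(ValueError):
            conservation_profile(["AAA", "AA"])


class TestApplyEdits:
    def test_published_redesign(self):
        report = apply_edits(
            DegeneratePrimer("R", "CABGCNCCRCAYTCCATRCA"),
            {3: "G", 9: "G", 15: "S"},
        )
        assert report.primer.sequence == "CAGGCNCCGCAYTCSATRCA"
        assert (report.degeneracy_before, report.degeneracy_after) == (96, 32)

    def test_empty_and_identity_edits(self):
        assert apply_edits(PRIMER, {}).primer.sequence == PRIMER.sequence
        same = apply_edits(PRIMER, {1: "A"})
        assert same.degeneracy_before == same.degeneracy_after

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            apply_edits(PRIMER, {11: "A"})


class TestReduceDegeneracy:
    def test_planted_single_base_position_collapses(self):
        primer = DegeneratePrimer("R", "CABGCNCCRCAYTCCATRCA")
        # library uses only the B->G realization at position 3
        chosen = [v for v in expand(primer) if v.sequence[2] == "G"]
        lib = ReferenceLibrary(
            _target(_plant(v.sequence), rec_id=f"r{v.index}") for v in chosen
        )
        report = reduce_degeneracy(primer, lib, min_base_freq=0.01)
        assert report.primer.sequence[2] == "G"
        assert report.degeneracy_after <= report.degeneracy_before

    def test_zero_floor_is_identity(self, synthetic_library):
        from degenamp.simulate import REVERSE_PRIMER_32

        report = reduce_degeneracy(
            REVERSE_PRIMER_32, synthetic_library.library, min_base_freq=0.0
        )
        assert report.primer.sequence == REVERSE_PRIMER_32.sequence

    def test_no_footprints_raises(self):
        lib = ReferenceLibrary([_target("G" * 100)])
        with pytest.raises(ValueError, match="footprint"):
            reduce_degeneracy(PRIMER, lib, 0.1)


class TestEquimolarSubset:
    def test_dropping_six_named_variants_leaves_26(self):
        primer = DegeneratePrimer("uni-32R", "CAGGCNCCGCAYTCSATRCA")
        ids = [v.id for v in expand(primer)]
        # the six underrepresented mixture members (1-based indices)
        dropped = {5, 7, 9, 15, 17, 21}
        table = {
            vid: (0.1 if i + 1 in dropped else 5.0)
            for i, vid in enumerate(ids)
        }
        result = select_equimolar_subset(primer, [table, table], floor=1.0)
        assert result.count == 26
        assert len(result.dropped_variant_ids) == 6

    def test_floor_zero_keeps_all(self):
        primer = DegeneratePrimer("uni-32R", "CAGGCNCCGCAYTCSATRCA")
        table = {v.id: 0.0 for v in expand(primer)}
        assert select_equimolar_subset(primer, [table], floor=0.0).count == 32

    def test_variant_kept_if_any_table_supports_it(self):
        primer = DegeneratePrimer("p", "ACGTACGNNR")  # 32 variants
        ids = [v.id for v in expand(primer)]
        low = {vid: 0.0 for vid in ids}
        high_for_first10 = {
            vid: (5.0 if i < 10 else 0.0) for i, vid in enumerate(ids)
        }
        result = select_equimolar_subset(
            primer, [low, high_for_first10], floor=1.0
        )
        assert result.count == 10  # only table-supported variants stay
        assert len(ids) - result.count == len(result.dropped_variant_ids)

    def test_inconsistent_tables_raise(self):
        with pytest.raises(ValueError):
            select_equimolar_subset("AR", [{"primer-01": 1.0}], floor=0.5)


class TestPredictAmplicons:
    def _template(self, spacer_len):
        fwd = "ACGTACGTAC"
        rev_site = reverse_complement("GGATCCGGAT")
        return _target("T" * 40 + fwd + "A" * spacer_len + rev_site + "T" * 40)

    def test_planted_950_nt_product(self):
        target = self._template(950 - 20)
        products = predict_amplicons(
            "ACGTACGTAC", "GGATCCGGAT", target, MatchPolicy(),
            size_range=(200, 2000),
        )
        assert len(products) == 1
        assert products[0].length == 950
        assert len(products[0].sequence) == 950

    def test_forward_site_only_is_empty(self):
        target = _target("T" * 40 + "ACGTACGTAC" + "T" * 200)
        assert predict_amplicons("ACGTACGTAC", "GGATCCGGAT", target) == []

    def test_reverse_upstream_of_forward_is_empty(self):
        rev_site = reverse_complement("GGATCCGGAT")
        target = _target("T" * 40 + rev_site + "A" * 300 + "ACGTACGTAC" + "T" * 40)
        assert predict_amplicons(
            "ACGTACGTAC", "GGATCCGGAT", target, size_range=(10, 2000)
        ) == []
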
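"""Numbering maps, site extraction and shift annotation."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eelvision.synthetic import consensus_scaffold, synthesize_opsin
from eelvision.tuning import (
    REGISTRIES,
    SHIFT_RULES,
    annotate_shifts,
    build_numbering_map,
    extract_sites,
    load_reference,
)


class TestRegistry:
    def test_known_site_counts(self):
        assert len(REGISTRIES["Rh1"].known_sites) == 7
        assert len(REGISTRIES["Rh2"].known_sites) == 4
        assert len(REGISTRIES["SWS2"].known_sites) == 5

    def test_rh1_known_sites_and_consensus(self):
        registry = REGISTRIES["Rh1"]
        assert registry.known_sites == (83, 122, 207, 211, 265, 292, 295)
        assert registry.consensus == {83: "D", 122: "E", 207: "M", 211: "H",
                                      265: "W", 292: "S", 295: "A"}

    def test_rh1_putative_sites_present(self):
        putative = set(REGISTRIES["Rh1"].putative)
        assert {124, 189, 286, 290} <= putative
        assert {112, 137, 189, 191, 193, 219, 255, 313} <= putative

    def test_shift_rules_registry(self):
        by_sub = {r.substitution: r for r in SHIFT_RULES}
        assert by_sub["A292S"].direction == "blue"
        assert by_sub["A292S"].magnitude_nm == (7.0, 15.0)
        assert by_sub["S292A"].direction == "red"
        assert by_sub["S292A"].magnitude_nm == (7.0, 16.0)
        assert by_sub["D83N"].direction == "blue"
        assert by_sub["D83N"].magnitude_nm is None


class TestNumberingMap:
    def test_reference_maps_to_identity(self):
        reference = load_reference()
        nmap = build_numbering_map(reference)
        assert nmap.query_to_ref == {i: i for i in range(1, len(reference) + 1)}
        assert not nmap.low_identity

    def test_point_substitution_preserves_coordinates(self):
        reference = load_reference()
        query = reference[:82] + "N" + reference[83:]
        nmap = build_numbering_map(query)
        assert nmap.query_to_ref == {i: i for i in range(1, len(reference) + 1)}
        assert query[nmap.ref_to_query[83] - 1] == "N"

    def test_deletion_shifts_query_coordinates(self):
        # 5 residues deleted before position 83: query 78 ↔ reference 83
        seq, truth = synthesize_opsin("Rh1", deletions=((50, 5),))
        nmap = build_numbering_map(seq)
        assert truth[83] == 78
        assert nmap.query_to_ref[78] == 83
        assert nmap.ref_to_query[83] == 78

    def test_map_strictly_monotone(self):
        seq, _ = synthesize_opsin(
            "Rh1", deletions=((30, 3),), insertions=((150, "GGS"),)
        )
        nmap = build_numbering_map(seq)
        items = sorted(nmap.query_to_ref.items())
        for (q1, r1), (q2, r2) in zip(items, items[1:]):
            assert q2 > q1 and r2 > r1

    def test_length_bounds_enforced(self):
        with pytest.raises(ValueError):
            build_numbering_map("ACDEFGHIKL" * 10)  # 100 aa, too short


class TestExtractSites:
    def test_rh1f_like_sequence_calls_s292a(self):
        seq, _ = synthesize_opsin("Rh1", {292: "A"})
        nmap = build_numbering_map(seq, query_id="rh1f_toy")
        report = extract_sites(nmap, seq, "Rh1")
        assert report.substitutions == ("S292A",)

    def test_rh1d_like_sequence_calls_d83n(self):
        seq, _ = synthesize_opsin("Rh1", {83: "N"})
        nmap = build_numbering_map(seq)
        report = extract_sites(nmap, seq, "Rh1")
        assert report.substitutions == ("D83N",)

    def test_consensus_sequence_has_no_calls(self):
        seq = consensus_scaffold("Rh1")
        report = extract_sites(build_numbering_map(seq), seq, "Rh1")
        assert report.substitutions == ()

    def test_calls_survive_upstream_deletion(self):
        seq, _ = synthesize_opsin("Rh1", {83: "N"}, deletions=((50, 5),))
        report = extract_sites(build_numbering_map(seq), seq, "Rh1")
        assert report.substitutions == ("D83N",)

    def test_putative_sites_reported_without_calls(self):
        seq = consensus_scaffold("Rh1")
        report = extract_sites(build_numbering_map(seq), seq, "Rh1")
        putative = [c for c in report.calls if c.status == "putative"]
        assert {c.site for c in putative} == set(REGISTRIES["Rh1"].putative)
        assert all(c.substitution is None for c in putative)

    @given(
        assignment=st.dictionaries(
            st.sampled_from(sorted(REGISTRIES["Rh1"].consensus)),
            st.sampled_from("ACFGIKLNQRTVY"),
            max_size=4,
        )
    )
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_round_trip_random_site_assignments(self, assignment):
        registry = REGISTRIES["Rh1"]
        seq, _ = synthesize_opsin("Rh1", assignment)
        report = extract_sites(build_numbering_map(seq), seq, "Rh1")
        expected = {
            f"{registry.consensus[site]}{site}{res}"
            for site, res in assignment.items()
            if registry.consensus[site] != res
        }
        assert set(report.substitutions) == expected


class TestAnnotateShifts:
    def test_red_shift_annotation(self):
        seq, _ = synthesize_opsin("Rh1", {292: "A"})
        report = annotate_shifts(
            extract_sites(build_numbering_map(seq), seq, "Rh1")
        )
        call = next(c for c in report.calls if c.substitution == "S292A")
        assert call.shift_direction == "red"
        assert call.shift_magnitude_nm == (7.0, 16.0)

    def test_blue_shift_without_magnitude(self):
        seq, _ = synthesize_opsin("Rh1", {83: "N"})
        report = annotate_shifts(
            extract_sites(build_numbering_map(seq), seq, "Rh1")
        )
        call = next(c for c in report.calls if c.substitution == "D83N")
        assert call.shift_direction == "blue"
        assert call.shift_magnitude_nm is None
        assert call.shift_note == "magnitude unspecified"

    def test_substitution_without_rule(self):
        seq, _ = synthesize_opsin("SWS2", {116: "T"})
        report = annotate_shifts(
            extract_sites(build_numbering_map(seq), seq, "SWS2")
        )
        call = next(c for c in report.calls if c.substitution == "M116T")
        assert call.shift_direction is None
        assert call.shift_note == "no rule"
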
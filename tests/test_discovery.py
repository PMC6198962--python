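"""CAPS diagnostic-site discovery and panel selection."""

import itertools

import pytest

from chlorotyping import (
    discover_informative_digests,
    find_polymorphic_columns,
    select_minimal_panel,
    variable_site_proportion,
)
from chlorotyping.discovery import CandidateSite
from chlorotyping.enzymes import scan_recognition_sites
from chlorotyping.io import column_map, ungap
from tests.conftest import random_sequence


class TestPolymorphicColumns:
    def test_identical_sequences_have_none(self):
        assert find_polymorphic_columns({"a": "ACGTACGT", "b": "ACGTACGT"}) == []

    def test_single_substitution_column(self):
        cols = find_polymorphic_columns({"a": "ACGTACGTAC", "b": "ACGTTCGTAC"})
        assert [(c.column, c.symbols) for c in cols] == [(4, ("A", "T"))]

    def test_gap_columns_flagged_not_polymorphic(self):
        cols = find_polymorphic_columns({"a": "AC-T", "b": "ACGT"})
        assert cols == []  # one residue + gap is an indel, not a substitution

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            find_polymorphic_columns({"a": "ACGT", "b": "ACG"})

    def test_matches_exhaustive_column_check(self, rng):
        rows = {f"s{i}": random_sequence(rng, 60) for i in range(4)}
        # splice in some gaps
        rows["s1"] = rows["s1"][:10] + "-" + rows["s1"][11:]
        got = {c.column for c in find_polymorphic_columns(rows)}
        expected = set()
        for col in range(60):
            residues = {r[col] for r in rows.values()} - {"-", "N"}
            if len(residues) >= 2:
                expected.add(col)
        assert got == expected


class TestDiscovery:
    def test_single_taqi_polymorphism(self, catalog):
        aln = {"a": "GGTCGAGG", "b": "GGTCGGGG"}
        sites = discover_informative_digests(aln, catalog, region_id="r1")
        assert [(s.enzyme, s.alignment_column, s.partition) for s in sites] == [
            ("TaqI", 2, "10")
        ]

    def test_excluded_panel_positions_skipped(self, catalog):
        from chlorotyping import DiagnosticSite
        from chlorotyping.panel import ChlorotypePanel

        aln = {"a": "GGTCGAGG", "b": "GGTCGGGG"}
        panel = ChlorotypePanel("x", (DiagnosticSite("r1", "TaqI"),))
        assert discover_informative_digests(aln, catalog, region_id="r1", exclude=panel) == []

    def test_matches_exhaustive_enumeration(self, catalog, rng):
        """Same site set as brute force over (enzyme, column, sample pair)."""
        rows = {f"s{i}": random_sequence(rng, 80) for i in range(4)}
        got = {
            (s.enzyme, s.alignment_column): s.partition
            for s in discover_informative_digests(rows, catalog, region_id="r")
        }
        expected = {}
        ids = list(rows)
        for enzyme in catalog.values():
            per_sample = {}
            for sid in ids:
                cols = column_map(rows[sid])
                per_sample[sid] = {
                    cols[h.position]
                    for h in scan_recognition_sites(ungap(rows[sid]), enzyme)
                }
            for col in set().union(*per_sample.values()):
                presence = "".join("1" if col in per_sample[s] else "0" for s in ids)
                if "0" in presence and "1" in presence:
                    expected[(enzyme.name, col)] = presence
        assert got == expected

    def test_added_sequence_keeps_splitting_sites(self, catalog, rng):
        """Monotonicity: a site that still splits a pair survives when a
        sequence is added to the alignment."""
        rows = {f"s{i}": random_sequence(rng, 80) for i in range(3)}
        before = discover_informative_digests(rows, catalog, region_id="r")
        rows["s3"] = random_sequence(rng, 80)
        after = {
            (s.enzyme, s.alignment_column) for s in
            discover_informative_digests(rows, catalog, region_id="r")
        }
        for site in before:
            assert (site.enzyme, site.alignment_column) in after


class TestMinimalPanel:
    def _sites(self, partitions):
        return [
            CandidateSite("r", "E", i, p) for i, p in enumerate(partitions)
        ]

    def test_identical_samples_need_no_panel(self):
        panel = select_minimal_panel(self._sites(["0000"]), 4)
        assert len(panel) == 0

    def test_greedy_matches_exhaustive_minimum(self):
        # 4 haplotypes distinguishable by 2 of these 5 sites
        partitions = ["0011", "0101", "0001", "0111", "0011"]
        sites = self._sites(partitions)
        panel = select_minimal_panel(sites, 4)

        def separates_all(subset):
            pairs = itertools.combinations(range(4), 2)
            full = {
                p for p in itertools.combinations(range(4), 2)
                if any(s.splits(*p) for s in sites)
            }
            return all(
                any(s.splits(*p) for s in subset) for p in full
            )

        best = min(
            (c for r in range(len(sites) + 1) for c in itertools.combinations(sites, r)
             if separates_all(c)),
            key=len,
        )
        assert len(panel) == len(best) == 2

    def test_published_twelve_site_partitions_stay_separating(self):
        from chlorotyping.datasets import TWELVE_SITE_PERCENT

        strings = sorted(
            set(TWELVE_SITE_PERCENT["florida_cultivars"])
            | set(TWELVE_SITE_PERCENT["kousa_cultivars"])
        )
        assert len(strings) == 16
        sites = [
            CandidateSite("r", "E", k, "".join(s[k] for s in strings))
            for k in range(12)
        ]
        panel = select_minimal_panel(sites, len(strings))
        chosen = [s.alignment_column for s in panel.sites]
        reduced = {"".join(s[k] for k in chosen) for s in strings}
        assert len(reduced) == 16


class TestVariableProportion:
    def test_identical_is_zero(self):
        pct, length = variable_site_proportion({"a": "ACGT" * 5, "b": "ACGT" * 5})
        assert pct == 0.0 and length == 20

    def test_one_in_ten(self):
        pct, length = variable_site_proportion({"a": "ACGTACGTAC", "b": "ACGTTCGTAC"})
        assert pct == pytest.approx(10.0) and length == 10

    def test_consistent_with_column_finder(self, rng):
        rows = {f"s{i}": random_sequence(rng, 50) for i in range(3)}
        pct, length = variable_site_proportion(rows)
        assert pct == pytest.approx(100 * len(find_polymorphic_columns(rows)) / length)
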
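"""Conformational shift, decade binning, helix classification, concordance
and the length-vs-shift summary table."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ambihelix import (
    ChainDatabase,
    ChainRecord,
    HelixClass,
    HelixSegment,
    aggregate_records,
    assign_bin,
    classify,
    concordance,
    length_shift_table,
    map_all,
    map_helix_naive,
    percent_shift,
)
from ambihelix.ambivalency import HelixAmbivalencyRecord
from ambihelix.helix_ops import extract_helices


def make_occurrence(helix_seq, target_ss):
    """Build one occurrence by embedding the sequence in a minimal target."""
    h = HelixSegment(chain_key=("1QRY", "A"), start=1,
                     end=len(helix_seq), sequence=helix_seq)
    t = ChainRecord(structure_id="1TGT", chain_id="A",
                    sequence=helix_seq, ss=target_ss)
    (occ,) = map_helix_naive(h, t)
    return occ


class TestPercentShift:
    def test_twelve_residue_helix_losing_nine_positions_shifts_75(self):
        # fully helical at home; its mapped copy keeps 3 of 12 positions helical
        occ = make_occurrence("LKEKENNDSSDK", "HHH" + "-TSEEB-TS")
        assert percent_shift(occ) == 75.0

    def test_fully_helical_occurrence_is_zero(self):
        assert percent_shift(make_occurrence("AAAAA", "HGHGH")) == 0.0

    def test_fully_nonhelical_occurrence_is_100(self):
        assert percent_shift(make_occurrence("AAAAA", "EETSB")) == 100.0

    @given(st.text(alphabet="HGIBEST-", min_size=1, max_size=50))
    @settings(derandomize=True, max_examples=200)
    def test_shift_depends_only_on_binarization(self, ss):
        occ = make_occurrence("A" * len(ss), ss)
        expected = 100.0 * sum(1 for c in ss if c not in "HG") / len(ss)
        assert percent_shift(occ) == pytest.approx(expected)
        assert 0.0 <= percent_shift(occ) <= 100.0


class TestAssignBin:
    @pytest.mark.parametrize(
        "shifts,expected",
        [
            ([50, 60, 70], 70),   # max-bin rule over multiple occurrences
            ([0], 0),
            ([0, 0, 0], 0),
            ([1], 10),
            ([10], 10),
            ([10.5], 20),         # left-open/right-closed decades
            ([99.9], 100),
            ([100], 100),
        ],
    )
    def test_decade_binning(self, shifts, expected):
        assert assign_bin(shifts) == expected

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="no occurrences"):
            assign_bin([])

    @given(st.lists(st.floats(min_value=0, max_value=100), min_size=1,
                    max_size=10))
    @settings(derandomize=True, max_examples=200)
    def test_bin_bounds_max_shift_from_above(self, shifts):
        b = assign_bin(shifts)
        assert b % 10 == 0 and 0 <= b <= 100
        assert b >= max(shifts) > b - 10 or (b == 0 and max(shifts) == 0)


class TestClassify:
    @pytest.mark.parametrize(
        "shifts,expected",
        [
            ([0, 0], HelixClass.CONSERVED),
            ([100], HelixClass.VARIABLE),
            ([40], HelixClass.PARTIAL),
            ([0, 100], HelixClass.VARIABLE),
            ([0, 99], HelixClass.PARTIAL),
            ([], HelixClass.UNMAPPED),
        ],
    )
    def test_classes(self, shifts, expected):
        assert classify(shifts) == expected


class TestConcordance:
    def make(self, folds, domains):
        query = ChainRecord(structure_id="1QRY", chain_id="A",
                            sequence="AAAAA", ss="HHHHH",
                            scop_fold="f1", scop_domain="d1")
        targets = []
        occs = []
        h = HelixSegment(chain_key=("1QRY", "A"), start=1, end=5,
                         sequence="AAAAA")
        for i, (f, d) in enumerate(zip(folds, domains)):
            t = ChainRecord(structure_id=f"T{i:03d}", chain_id="A",
                            sequence="AAAAA", ss="-----",
                            scop_fold=f, scop_domain=d)
            targets.append(t)
            occs.extend(map_helix_naive(h, t))
        return occs, query, ChainDatabase(chains=targets)

    def test_all_same_fold(self):
        occs, q, tdb = self.make(["f1", "f1"], ["d2", "d2"])
        fold, dom = concordance(occs, q, tdb)
        assert fold == 1.0 and dom == 0.0

    def test_quarter_same_domain(self):
        occs, q, tdb = self.make(["f2"] * 4, ["d1", "d2", "d2", "d2"])
        assert concordance(occs, q, tdb) == (0.0, 0.25)

    def test_absent_labels_give_absent_fractions(self):
        occs, q, tdb = self.make([None, None], [None, None])
        assert concordance(occs, q, tdb) == (None, None)


class TestAggregateAndTable:
    def test_planted_design_recovered(self, small_dbs):
        query, target, truth = small_dbs
        helices = [h for c in query for h in extract_helices(c)]
        occs = map_all(helices, target)
        records = aggregate_records(helices, occs, query, target)
        by_key = {r.helix.key: r for r in records}
        for gt in truth.helices:
            key = (gt["structure_id"], gt["chain_id"], gt["start"], gt["end"])
            rec = by_key[key]
            assert sorted(rec.shifts) == sorted(gt["realized_shifts"])
            assert rec.bin == gt["bin"]
            assert rec.klass.value == gt["klass"]

    def test_fold_domain_concordance_against_planted_flags(self, small_dbs):
        query, target, truth = small_dbs
        helices = [h for c in query for h in extract_helices(c)]
        occs = map_all(helices, target)
        records = {r.helix.key: r for r in
                   aggregate_records(helices, occs, query, target)}
        for gt in truth.helices:
            if not gt["realized_shifts"]:
                continue
            rec = records[(gt["structure_id"], gt["chain_id"],
                           gt["start"], gt["end"])]
            n = len(gt["fold_matches"])
            assert rec.same_fold_fraction == pytest.approx(
                sum(gt["fold_matches"]) / n)
            assert rec.same_domain_fraction == pytest.approx(
                sum(gt["domain_matches"]) / n)

    def test_self_map_is_conserved(self, small_dbs):
        query, _, _ = small_dbs
        helices = [h for c in query for h in extract_helices(c)]
        occs = map_all(helices, query, exclude_self=False)
        records = aggregate_records(helices, occs)
        assert all(r.klass is HelixClass.CONSERVED for r in records)

    def rec(self, length, shifts, k=0):
        h = HelixSegment(chain_key=(f"Q{k:03d}", "A"), start=1, end=length,
                         sequence="A" * length)
        return HelixAmbivalencyRecord(helix=h, shifts=list(shifts))

    def test_fraction_per_bin(self):
        records = [self.rec(10, [0], k) for k in range(6)] + [
            self.rec(10, [35], 6),
            self.rec(10, [100], 7),
            self.rec(10, [100], 8),
            self.rec(12, [15], 9),
        ]
        table = length_shift_table(records)
        assert table.loc[0, "fraction"] == pytest.approx(0.6)
        assert table["fraction"].sum() == pytest.approx(1.0)
        assert table.loc[40, "n_helices"] == 1
        assert table.loc[100, "n_helices"] == 2

    def test_single_helix_gets_full_fraction(self):
        table = length_shift_table([self.rec(25, [42])])
        assert list(table.index) == [50]
        assert table.loc[50, "fraction"] == 1.0
        assert table.loc[50, "max_length"] == 25

    def test_unmapped_excluded_from_denominator(self):
        table = length_shift_table([self.rec(10, [0]), self.rec(10, [])])
        assert table["n_helices"].sum() == 1
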
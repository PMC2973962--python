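"""Normalized conformational parameter (CP), per-bin CP curves, flank
extraction and the terminus-resolved flank statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ambihelix import (
    ChainRecord,
    FlankClass,
    HelixSegment,
    ResidueCounts,
    Terminus,
    aggregate_records,
    background_counts,
    compute_cp,
    cp_by_bin,
    extract_flanks,
    flank_cp,
    map_all,
)
from ambihelix.helix_ops import extract_helices
from ambihelix.io_model import STANDARD_AA
from ambihelix.propensity import collect_flank_sets, conformation_groups
from ambihelix.synthetic_data import GeneratorConfig, PlantSpec, generate


def counts(**kw):
    return ResidueCounts(counts=kw, total=sum(kw.values()))


def cp_oracle(group, background):
    """Independent evaluation of the normalized conformational parameter:
    CP_i = (n_i / sum n) / (N_i / sum N)."""
    out = {}
    for aa in STANDARD_AA:
        if background.counts.get(aa, 0) == 0:
            out[aa] = None
            continue
        f_group = group.counts.get(aa, 0) / group.total
        f_bg = background.counts[aa] / background.total
        out[aa] = f_group / f_bg
    return out


class TestComputeCP:
    def test_group_proportional_to_background_gives_unity(self):
        bg = counts(A=30, G=20, L=50)
        group = counts(A=3, G=2, L=5)
        table = compute_cp(group, bg)
        for aa in "AGL":
            assert table.cp[aa] == pytest.approx(1.0)

    def test_twofold_enrichment(self):
        bg = counts(A=10, C=10, D=10, E=10, F=10, G=10, H=10, I=10, K=10, L=10)
        group = counts(A=2, C=1, D=1, E=1, F=1, G=1, H=1, I=1, K=1)
        assert compute_cp(group, bg).cp["A"] == pytest.approx(2.0)

    def test_random_multinomial_group_matches_oracle(self):
        rng = np.random.default_rng(42)
        bg_vec = rng.integers(50, 500, size=20)
        bg = ResidueCounts(
            counts=dict(zip(STANDARD_AA, map(int, bg_vec))), total=int(bg_vec.sum())
        )
        draw = rng.multinomial(500, bg_vec / bg_vec.sum())
        group = ResidueCounts(
            counts={aa: int(n) for aa, n in zip(STANDARD_AA, draw) if n},
            total=int(draw.sum()),
        )
        table = compute_cp(group, bg)
        oracle = cp_oracle(group, bg)
        for aa in STANDARD_AA:
            assert table.cp[aa] == pytest.approx(oracle[aa])

    def test_normalization_identity(self):
        bg = counts(A=7, C=13, W=5, Y=25)
        group = counts(A=4, W=1, Y=2)
        table = compute_cp(group, bg)
        s = sum(
            (bg.counts[aa] / bg.total) * table.cp[aa]
            for aa in bg.counts
        )
        assert s == pytest.approx(1.0, abs=1e-9)

    def test_scale_invariance(self):
        bg = counts(A=30, G=20, L=50)
        group = counts(A=3, G=2, L=5)
        t1 = compute_cp(group, bg)
        t2 = compute_cp(group.scaled(17), bg)
        for aa in "AGL":
            assert t1.cp[aa] == pytest.approx(t2.cp[aa])

    def test_zero_background_residue_absent_not_infinite(self):
        table = compute_cp(counts(A=1, W=1), counts(A=10))
        assert table.cp["W"] is None

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_cp(ResidueCounts(), counts(A=1))


class TestCPByBin:
    def test_all_conserved_gives_only_bin_zero(self, small_dbs):
        query, target, _ = small_dbs
        helices = [h for c in query for h in extract_helices(c)]
        occs = map_all(helices, query, exclude_self=False)  # self-map: all 0%
        records = aggregate_records(helices, occs)
        tables = cp_by_bin(records, background_counts(query))
        assert set(tables) == {0}

    def test_each_bin_counts_its_own_helices(self, small_dbs):
        query, target, truth = small_dbs
        helices = [h for c in query for h in extract_helices(c)]
        occs = map_all(helices, target)
        records = aggregate_records(helices, occs)
        tables = cp_by_bin(records, background_counts(query))
        expected_bins = {gt["bin"] for gt in truth.helices
                         if gt["bin"] is not None}
        assert set(tables) == expected_bins
        # bins holding a single helix carry exactly that helix's composition
        from collections import Counter
        per_bin = {}
        for gt in truth.helices:
            if gt["bin"] is not None:
                per_bin.setdefault(gt["bin"], []).append(gt["sequence"])
        for b, seqs in per_bin.items():
            if len(seqs) == 1:
                assert tables[b].group_counts.counts == dict(Counter(seqs[0]))


class TestExtractFlanks:
    chain = ChainRecord(
        structure_id="1ABC", chain_id="A",
        sequence="ABCDEFGHIKLMNPQRSTVW".replace("B", "C"),
        ss="-" * 20,
    )

    def test_interior_helix_has_four_residue_flanks(self):
        h = HelixSegment(chain_key=("1ABC", "A"), start=10, end=14,
                         sequence=self.chain.sequence[9:14])
        n = extract_flanks(h, self.chain, terminus=Terminus.N)
        c = extract_flanks(h, self.chain, terminus=Terminus.C)
        assert n == self.chain.sequence[5:9]   # residues 6-9
        assert c == self.chain.sequence[14:18]  # residues 15-18

    def test_near_start_truncates(self):
        h = HelixSegment(chain_key=("1ABC", "A"), start=3, end=8,
                         sequence=self.chain.sequence[2:8])
        assert extract_flanks(h, self.chain, terminus=Terminus.N) == (
            self.chain.sequence[:2]
        )

    def test_at_chain_end_empty(self):
        h = HelixSegment(chain_key=("1ABC", "A"), start=15, end=20,
                         sequence=self.chain.sequence[14:20])
        assert extract_flanks(h, self.chain, terminus=Terminus.C) == ""

    @given(st.integers(min_value=1, max_value=20),
           st.integers(min_value=1, max_value=20),
           st.integers(min_value=1, max_value=6))
    @settings(derandomize=True, max_examples=200)
    def test_matches_slicing_oracle(self, a, b, width):
        start, end = min(a, b), max(a, b)
        h = HelixSegment(chain_key=("1ABC", "A"), start=start, end=end,
                         sequence=self.chain.sequence[start - 1:end])
        n = extract_flanks(h, self.chain, width, Terminus.N)
        c = extract_flanks(h, self.chain, width, Terminus.C)
        assert n == self.chain.sequence[max(0, start - 1 - width):start - 1]
        assert c == self.chain.sequence[end:end + width]
        assert len(n) <= width and len(c) <= width


class TestFlankCP:
    def test_identical_populations_give_identical_tables(self):
        from ambihelix.propensity import FlankSet

        bg = counts(A=50, G=30, L=20)
        fs_n = FlankSet(terminus=Terminus.N, source_class=FlankClass.CONSERVED,
                        per_flank_sequences=["AAGL", "GALL"])
        fs_c = FlankSet(terminus=Terminus.C, source_class=FlankClass.CONSERVED,
                        per_flank_sequences=["AAGL", "GALL"])
        tables = flank_cp([fs_n, fs_c], bg)
        n_table = tables[(Terminus.N, FlankClass.CONSERVED)]
        c_table = tables[(Terminus.C, FlankClass.CONSERVED)]
        assert n_table.cp == c_table.cp

    def test_empty_class_absent(self):
        from ambihelix.propensity import FlankSet

        fs = FlankSet(terminus=Terminus.N, source_class=FlankClass.CONSERVED)
        assert flank_cp([fs], counts(A=5)) == {}

    def test_planted_c_flank_gly_enrichment_shows_only_at_c_terminus(self):
        gly = {aa: (8.0 if aa == "G" else 1.0) for aa in STANDARD_AA}
        plants = [
            PlantSpec(helix_length=12, n_target_occurrences=1,
                      occurrence_shifts=[100], group_label="v",
                      c_flank_bias=gly)
            for _ in range(40)
        ]
        query, target, _ = generate(plants, seed=5, config=GeneratorConfig())
        helices = [h for c in query for h in extract_helices(c)]
        occs = map_all(helices, target)
        records = aggregate_records(helices, occs, query, target)
        bg = background_counts(query)
        tables = flank_cp(
            collect_flank_sets(records, occs, query, target), bg
        )
        n_cp = tables[(Terminus.N, FlankClass.HELICAL_CONF)].cp["G"]
        c_cp = tables[(Terminus.C, FlankClass.HELICAL_CONF)].cp["G"]
        assert c_cp > 2.0 * n_cp
        assert c_cp > 2.0


class TestConformationGroups:
    def test_groups_follow_planted_classes(self, small_dbs):
        query, target, truth = small_dbs
        helices = [h for c in query for h in extract_helices(c)]
        occs = map_all(helices, target)
        records = aggregate_records(helices, occs)
        groups = conformation_groups(records, occs)
        conserved_len = sum(
            len(gt["sequence"]) for gt in truth.helices
            if gt["klass"] == "CONSERVED"
        )
        assert groups["CONSERVED"].total == conserved_len
        variable = [gt for gt in truth.helices if gt["klass"] == "VARIABLE"]
        assert groups["VARIABLE_HELICAL"].total == sum(
            len(gt["sequence"]) for gt in variable
        )
        # per-occurrence counting: each 100%-shift occurrence counted once
        assert groups["VARIABLE_NONHELICAL"].total == sum(
            len(gt["sequence"]) * sum(1 for s in gt["realized_shifts"]
                                      if s == 100.0)
            for gt in variable
        )
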
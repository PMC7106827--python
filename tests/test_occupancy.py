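import random

import pandas as pd
import pytest

from orthoforge.alignment_io import PadAligner
from orthoforge.busco_results import BuscoStatus
from orthoforge.errors import OccupancyError
from orthoforge.fixtures import FixtureSpec, generate_fixture
from orthoforge.harvest import LocusBin
from orthoforge.occupancy import (
    COMPLETE,
    FRAGMENTED,
    MISSING,
    STATES,
    OccupancyMatrix,
    ThresholdSpec,
    apply_thresholds,
    build_occupancy,
    build_occupancy_from_fasta_dir,
    read_presence_absence,
    reassemble,
    summarize,
)

from conftest import brute_force_thresholds


def matrix_from_rows(rows):
    return OccupancyMatrix(pd.DataFrame.from_dict(rows, orient="index"))


def random_matrix(rng, n_taxa=6, n_loci=12):
    rows = {
        f"t{i:02d}": {
            f"L{j:02d}": rng.choices(STATES, weights=[5, 2, 3])[0]
            for j in range(n_loci)
        }
        for i in range(n_taxa)
    }
    return matrix_from_rows(rows)


class TestBuildOccupancy:
    def test_state_mapping(self):
        occ = build_occupancy(
            {"sp1": {"L1": ("tr1", BuscoStatus.COMPLETE),
                     "L2": ("tr2", BuscoStatus.FRAGMENTED)}},
            ["L1", "L2", "L3"],
        )
        assert list(occ.states.loc["sp1"]) == [COMPLETE, FRAGMENTED, MISSING]

    def test_empty_selection_all_missing(self):
        occ = build_occupancy({"sp1": {}}, ["L1", "L2"])
        assert set(occ.states.loc["sp1"]) == {MISSING}

    def test_duplicated_winner_is_complete(self):
        occ = build_occupancy(
            {"sp1": {"L1": ("tr1", BuscoStatus.DUPLICATED)}}, ["L1"]
        )
        assert occ.states.loc["sp1", "L1"] == COMPLETE

    def test_locus_outside_universe_rejected(self):
        with pytest.raises(OccupancyError, match="L9"):
            build_occupancy({"sp1": {"L9": ("tr", BuscoStatus.COMPLETE)}}, ["L1"])

    def test_state_conservation_per_taxon(self):
        occ = build_occupancy(
            {"sp1": {"L1": ("a", BuscoStatus.COMPLETE)},
             "sp2": {"L2": ("b", BuscoStatus.FRAGMENTED)}},
            ["L1", "L2", "L3"],
        )
        counts = occ.states.apply(lambda row: row.value_counts().sum(), axis=1)
        assert (counts == len(occ.loci)).all()


class TestFastaDirOccupancy:
    def test_presence_from_files(self, tmp_path):
        (tmp_path / "L1.fasta").write_text(">sp1\nACGT\n>sp2\nTTTT\n")
        (tmp_path / "L2.fasta").write_text(">sp1\nGG\n")
        occ = build_occupancy_from_fasta_dir(tmp_path)
        assert occ.states.loc["sp2", "L2"] == MISSING
        assert occ.states.loc["sp1", "L2"] == COMPLETE
        assert FRAGMENTED not in set(occ.states.values.ravel())

    def test_empty_dir_is_error(self, tmp_path):
        with pytest.raises(OccupancyError, match=str(tmp_path)):
            build_occupancy_from_fasta_dir(tmp_path)

    def test_all_gap_record_is_missing(self, tmp_path):
        (tmp_path / "L1.fasta").write_text(">sp1\n----\n>sp2\nAC-T\n")
        occ = build_occupancy_from_fasta_dir(tmp_path)
        assert occ.states.loc["sp1", "L1"] == MISSING
        assert occ.states.loc["sp2", "L1"] == COMPLETE

    def test_duplicate_taxon_in_file_rejected(self, tmp_path):
        (tmp_path / "L1.fasta").write_text(">sp1\nAC\n>sp1\nGT\n")
        with pytest.raises(ValueError, match="duplicate"):
            build_occupancy_from_fasta_dir(tmp_path)

    def test_explicit_taxa_list(self, tmp_path):
        (tmp_path / "L1.fasta").write_text(">sp1\nACGT\n")
        occ = build_occupancy_from_fasta_dir(tmp_path, taxa=["sp1", "ghost"])
        assert occ.states.loc["ghost", "L1"] == MISSING


class TestPresenceAbsence:
    def test_csv_two_state(self):
        occ = read_presence_absence("t,L1,L2\na,1,0\n")
        assert list(occ.states.loc["a"]) == [COMPLETE, MISSING]

    def test_ragged_row_rejected(self):
        with pytest.raises(OccupancyError, match="ragged"):
            read_presence_absence("t,L1,L2\na,1\n")

    def test_unmapped_token_names_cell(self):
        with pytest.raises(OccupancyError, match=r"\(a, L2\)"):
            read_presence_absence("t,L1,L2\na,1,NA\n")

    def test_custom_tokens_and_delimiter(self):
        occ = read_presence_absence(
            "t\tL1\nx\tyes\n", present_tokens=("yes",), absent_tokens=("no",),
            delimiter="\t",
        )
        assert occ.states.loc["x", "L1"] == COMPLETE


class TestSummarize:
    def test_all_complete_taxon_zero_missing(self):
        occ = matrix_from_rows({
            "a": {f"L{i}": COMPLETE for i in range(4)},
            "b": {f"L{i}": (COMPLETE if i == 0 else MISSING) for i in range(4)},
        })
        table = summarize(occ)
        row = table[(table.level == "taxon") & (table.label == "a")
                    & (table.state == MISSING)]
        assert row.percent.item() == 0.0

    def test_one_of_four_complete_is_75_percent_missing(self):
        occ = matrix_from_rows({
            "b": {f"L{i}": (COMPLETE if i == 0 else MISSING) for i in range(4)},
        })
        table = summarize(occ)
        row = table[(table.level == "taxon") & (table.label == "b")
                    & (table.state == MISSING)]
        assert row.percent.item() == 75.0

    def test_group_aggregates_all_cells(self):
        occ = matrix_from_rows({
            "a": {f"L{i}": COMPLETE for i in range(4)},
            "b": {f"L{i}": MISSING for i in range(4)},
        })
        table = summarize(occ, grouping={"a": "G", "b": "G"})
        group_rows = table[(table.level == "group") & (table.label == "G")]
        assert group_rows["count"].sum() == 8

    def test_grouping_must_cover_taxa(self):
        occ = matrix_from_rows({"a": {"L1": COMPLETE}, "b": {"L1": MISSING}})
        with pytest.raises(OccupancyError, match="b"):
            summarize(occ, grouping={"a": "G"})


class TestApplyThresholds:
    def test_paper_style_taxon_rule(self):
        rng = random.Random(0)
        rows = {}
        for taxon, n_present in (("A", 1200), ("B", 900)):
            states = [COMPLETE] * n_present + [MISSING] * (6000 - n_present)
            rng.shuffle(states)
            rows[taxon] = {f"L{j:04d}": states[j] for j in range(6000)}
        occ = matrix_from_rows(rows)
        kept_taxa, _ = apply_thresholds(occ, ThresholdSpec(min_loci_per_taxon=1000))
        assert kept_taxa == ["A"]

    def test_zero_thresholds_keep_everything(self):
        rng = random.Random(1)
        occ = random_matrix(rng)
        kept_taxa, kept_loci = apply_thresholds(occ, ThresholdSpec(0, 0))
        assert kept_taxa == occ.taxa and kept_loci == occ.loci

    def test_full_locus_threshold_keeps_only_fully_occupied(self):
        rng = random.Random(2)
        occ = random_matrix(rng)
        spec = ThresholdSpec(min_taxa_per_locus=len(occ.taxa))
        _, kept_loci = apply_thresholds(occ, spec)
        for locus in occ.loci:
            fully = all(occ.states.loc[t, locus] in (COMPLETE, FRAGMENTED)
                        for t in occ.taxa)
            assert (locus in kept_loci) == fully

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_brute_force(self, seed):
        rng = random.Random(seed)
        occ = random_matrix(rng)
        min_t = rng.randint(0, len(occ.loci))
        min_l = rng.randint(0, len(occ.taxa))
        frag = rng.random() < 0.5
        got = apply_thresholds(occ, ThresholdSpec(min_t, min_l, frag))
        states = {
            (t, l): occ.states.loc[t, l] for t in occ.taxa for l in occ.loci
        }
        assert got == brute_force_thresholds(states, min_t, min_l, frag)

    def test_monotone_in_taxon_threshold(self):
        rng = random.Random(42)
        occ = random_matrix(rng, n_taxa=8, n_loci=10)
        previous = None
        for threshold in range(len(occ.loci) + 1):
            kept, _ = apply_thresholds(occ, ThresholdSpec(min_loci_per_taxon=threshold))
            if previous is not None:
                assert set(kept) <= set(previous)
            previous = kept

    def test_fragment_toggle(self):
        occ = matrix_from_rows({"a": {"L1": FRAGMENTED, "L2": MISSING}})
        with_frag, _ = apply_thresholds(occ, ThresholdSpec(min_loci_per_taxon=1))
        without, _ = apply_thresholds(
            occ, ThresholdSpec(min_loci_per_taxon=1, count_fragmented_as_present=False)
        )
        assert with_frag == ["a"] and without == []


class TestReassemble:
    @pytest.fixture
    def bins(self):
        return {
            "L1": LocusBin("L1", {"a": "ACGT", "b": "ACG", "c": "AC"}),
            "L2": LocusBin("L2", {"a": "TTTT", "b": "TT"}),
        }

    def test_drop_taxon_then_reassemble(self, bins):
        sm = reassemble(["a", "b"], ["L1", "L2"], bins, PadAligner())
        assert sm.taxa == ["a", "b"]
        assert sm.length == 8
        assert [e[0] for e in sm.partitions.entries] == ["L1", "L2"]

    def test_drop_nothing_identity(self, bins):
        full = reassemble(["a", "b", "c"], ["L1", "L2"], bins, PadAligner())
        again = reassemble(["a", "b", "c"], ["L1", "L2"], bins, PadAligner())
        assert full.matrix == again.matrix

    def test_singleton_locus_kept(self, bins):
        sm = reassemble(["a"], ["L1", "L2"], bins, PadAligner())
        assert sm.matrix["a"] == "ACGTTTTT"

    def test_empty_locus_dropped_with_warning(self, bins, caplog):
        bins["L3"] = LocusBin("L3", {"zz": "GG"})
        import logging
        with caplog.at_level(logging.WARNING):
            sm = reassemble(["a", "b"], ["L1", "L3"], bins, PadAligner())
        assert [e[0] for e in sm.partitions.entries] == ["L1"]
        assert "L3" in caplog.text

    def test_missing_bin_is_error(self, bins):
        with pytest.raises(OccupancyError, match="L9"):
            reassemble(["a"], ["L9"], bins, PadAligner())


def test_missing_fraction_calibration_on_fixture(tmp_path):
    p = 0.25
    spec = FixtureSpec(n_species=20, n_loci=400, p_missing=p, seed=123)
    bundle = generate_fixture(spec, tmp_path)
    from orthoforge.busco_results import selections_by_species
    selections = selections_by_species(bundle.table_paths)
    occ = build_occupancy(selections, bundle.loci)
    n = 20 * 400
    se = (p * (1 - p) / n) ** 0.5
    assert abs(occ.missing_fraction() - p) <= 3 * se


def test_occupancy_csv_round_trip(tmp_path):
    rng = random.Random(7)
    occ = random_matrix(rng)
    occ.to_csv(tmp_path / "occ.csv")
    reread = OccupancyMatrix.from_csv(tmp_path / "occ.csv")
    assert reread.states.equals(occ.states)
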
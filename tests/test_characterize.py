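import numpy as np
import pytest

from thermoscm import (
    AAindexProperty,
    AminoAcidPropensity,
    PropensityTable,
    STANDARD_AA,
    correlate_property,
    parse_aaindex1,
    rank_properties,
    score_histogram,
    top_dipeptides,
)
from thermoscm.characterize import AAindexParseError, UndefinedCorrelationError
from thermoscm.features import dipeptide_index
from thermoscm.scm import estimate_initial


@pytest.fixture(scope="module")
def thermo_props(data_dir):
    return {p.accession: p for p in parse_aaindex1(data_dir / "aaindex_thermo_subset.txt")}


class TestParseAAindex1:
    def test_fixture_has_three_complete_records(self, thermo_props):
        assert sorted(thermo_props) == ["FUKS010101", "FUKS010102", "ZIMJ680101"]
        for prop in thermo_props.values():
            assert sorted(prop.values) == sorted(STANDARD_AA)

    def test_values_mapped_to_correct_residues(self, thermo_props):
        # spot-check both rows of the two-row residue layout
        assert thermo_props["FUKS010101"].values["E"] == 16.56
        assert thermo_props["FUKS010101"].values["K"] == 12.98
        assert thermo_props["ZIMJ680101"].values["Q"] == 0.0
        assert thermo_props["ZIMJ680101"].values["I"] == 3.07

    def test_titles_are_joined_description_lines(self, thermo_props):
        assert "thermophiles" in thermo_props["FUKS010101"].title

    def test_na_entries_recorded_as_missing(self, tmp_path):
        path = tmp_path / "na.aaindex1"
        path.write_text(
            "H TEST000001\nD test scale\n"
            "I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V\n"
            "     1.0      NA     3.0     4.0     5.0     6.0     7.0     8.0     9.0    10.0\n"
            "    11.0    12.0      NA    14.0    15.0    16.0    17.0    18.0    19.0    20.0\n//\n"
        )
        (prop,) = parse_aaindex1(path)
        assert len(prop.values) == 18
        assert "R" not in prop.values and "M" not in prop.values
        assert prop.values["A"] == 1.0 and prop.values["Y"] == 20.0

    def test_empty_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "empty.aaindex1"
        path.write_text("")
        assert parse_aaindex1(path) == []

    def test_malformed_record_names_accession(self, tmp_path):
        path = tmp_path / "bad.aaindex1"
        path.write_text("H BAD0000001\nD broken\nI    A/L\n     1.0     2.0\n//\n")
        with pytest.raises(AAindexParseError, match="BAD0000001"):
            parse_aaindex1(path)


class TestCorrelateProperty:
    def test_self_correlation_is_one(self):
        aa = AminoAcidPropensity(scores={a: float(i) for i, a in enumerate(STANDARD_AA)})
        prop = AAindexProperty(accession="SELF", values=dict(aa.scores))
        assert correlate_property(aa, prop) == pytest.approx(1.0)

    def test_symmetric_and_affine_invariant(self, thermo_props):
        aa = AminoAcidPropensity(scores={a: float(i * i % 7) for i, a in enumerate(STANDARD_AA)})
        prop = thermo_props["ZIMJ680101"]
        r = correlate_property(aa, prop)
        rescaled = AAindexProperty(
            accession="X", values={k: 3.0 * v + 10.0 for k, v in prop.values.items()}
        )
        assert correlate_property(aa, rescaled) == pytest.approx(r)
        flipped = AAindexProperty(accession="Y", values=dict(aa.scores))
        as_prop = AminoAcidPropensity(scores=dict(prop.values))
        assert correlate_property(as_prop, flipped) == pytest.approx(r)

    def test_missing_values_use_pairwise_deletion(self):
        aa = AminoAcidPropensity(scores={a: float(i) for i, a in enumerate(STANDARD_AA)})
        prop = AAindexProperty(accession="PART", values={"A": 0.0, "C": 1.0, "D": 2.0, "E": 3.0})
        assert correlate_property(aa, prop) == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        aa = AminoAcidPropensity(scores={a: float(i) for i, a in enumerate(STANDARD_AA)})
        flat = AAindexProperty(accession="FLAT", values={a: 1.0 for a in STANDARD_AA})
        with pytest.raises(UndefinedCorrelationError):
            correlate_property(aa, flat)

    def test_too_few_shared_residues_rejected(self):
        aa = AminoAcidPropensity(scores={a: float(i) for i, a in enumerate(STANDARD_AA)})
        prop = AAindexProperty(accession="TINY", values={"A": 1.0, "C": 2.0})
        with pytest.raises(UndefinedCorrelationError):
            correlate_property(aa, prop)


class TestRankProperties:
    @staticmethod
    def _aa():
        return AminoAcidPropensity(scores={a: float(i) for i, a in enumerate(STANDARD_AA)})

    def test_top_and_bottom_ordering(self):
        aa = self._aa()
        aligned = AAindexProperty(accession="P1", values=dict(aa.scores))
        opposed = AAindexProperty(accession="P2", values={k: -v for k, v in aa.scores.items()})
        top, bottom, excluded = rank_properties(aa, [aligned, opposed], k=1)
        assert top[0][0].accession == "P1" and top[0][1] == pytest.approx(1.0)
        assert bottom[0][0].accession == "P2" and bottom[0][1] == pytest.approx(-1.0)
        assert excluded == []

    def test_monotone_r_within_lists(self, thermo_props):
        aa = self._aa()
        top, bottom, _ = rank_properties(aa, list(thermo_props.values()), k=3)
        top_rs = [r for _, r in top]
        bottom_rs = [r for _, r in bottom]
        assert top_rs == sorted(top_rs, reverse=True)
        assert bottom_rs == sorted(bottom_rs)

    def test_k_exceeding_list_returns_full_lists(self):
        aa = self._aa()
        props = [AAindexProperty(accession="P1", values=dict(aa.scores))]
        top, bottom, _ = rank_properties(aa, props, k=5)
        assert len(top) == 1 and len(bottom) == 1

    def test_constant_property_excluded_and_reported(self):
        aa = self._aa()
        flat = AAindexProperty(accession="FLAT", values={a: 2.0 for a in STANDARD_AA})
        ok = AAindexProperty(accession="OK", values=dict(aa.scores))
        top, _, excluded = rank_properties(aa, [flat, ok], k=2)
        assert excluded == ["FLAT"]
        assert [p.accession for p, _ in top] == ["OK"]


class TestTopDipeptides:
    def test_argmax_and_argmin(self):
        values = np.full(400, 500.0)
        values[dipeptide_index("E", "E")] = 1000.0
        values[dipeptide_index("A", "A")] = 0.0
        table = PropensityTable(g=0, values=values)
        highest, lowest = top_dipeptides(table, 1)
        assert highest[0] == ("EE", 1000.0)
        assert lowest[0] == ("AA", 0.0)

    def test_uniform_table_ties_alphabetical(self):
        table = PropensityTable(g=0, values=np.full(400, 500.0))
        highest, lowest = top_dipeptides(table, 3)
        assert [d for d, _ in highest] == ["AA", "AC", "AD"]
        assert [d for d, _ in lowest] == ["AA", "AC", "AD"]

    def test_full_lists_are_reversed_orderings(self):
        rng = np.random.default_rng(0)
        table = PropensityTable(g=0, values=rng.permutation(400).astype(float))
        highest, lowest = top_dipeptides(table, 400)
        assert highest == lowest[::-1]


class TestScoreHistogram:
    def test_one_sequence_per_class(self, tiny_dataset):
        from thermoscm import LabeledDataset

        data = LabeledDataset(
            positives=tiny_dataset.positives[:1], negatives=tiny_dataset.negatives[:1]
        )
        table = estimate_initial(tiny_dataset, 0)
        hist = score_histogram(data, table, bins=4)
        assert hist.positive_counts.sum() == 1 and hist.negative_counts.sum() == 1
        assert hist.positive_sd == 0.0

    def test_identical_classes_give_identical_histograms(self, tiny_dataset):
        from thermoscm import LabeledDataset, ProteinRecord

        seqs = [r.sequence for r in tiny_dataset.positives]
        data = LabeledDataset(
            positives=[ProteinRecord(f"p{i}", s) for i, s in enumerate(seqs)],
            negatives=[ProteinRecord(f"n{i}", s) for i, s in enumerate(seqs)],
        )
        table = estimate_initial(tiny_dataset, 0)
        hist = score_histogram(data, table, bins=5)
        assert np.array_equal(hist.positive_counts, hist.negative_counts)
        assert hist.positive_mean == pytest.approx(hist.negative_mean)

    def test_planted_signal_shifts_positive_class_upward(self, planted_train):
        table = estimate_initial(planted_train, 0)
        hist = score_histogram(planted_train, table, bins=20)
        assert hist.positive_mean > hist.negative_mean

    def test_shared_edges_span_pooled_range(self, planted_train):
        table = estimate_initial(planted_train, 0)
        hist = score_histogram(planted_train, table, bins=10)
        assert len(hist.edges) == 11
        total = hist.positive_counts.sum() + hist.negative_counts.sum()
        assert total == len(planted_train)
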
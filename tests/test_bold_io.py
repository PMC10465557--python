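"""Record reading, end-gap trimming, and quality filters."""

import numpy as np
import pandas as pd
import pytest

from macrogd import bold_io


def _table(rows):
    df = pd.DataFrame(rows, columns=bold_io.BOLD_COLUMNS)
    return df


def _row(pid="P1", otu="BOLD:A", seq="A" * 500, lat=10.0, lon=20.0, continent="WestContinent",
         species="Testa testa", order="Diptera"):
    return [pid, otu, order, species, lat, lon, continent, continent, seq]


def test_read_records_roundtrip(tmp_path):
    path = tmp_path / "records.tsv"
    df = _table([_row("P1"), _row("P2", seq="acgt" * 120), _row("P3", lat="")])
    df.to_csv(path, sep="\t", index=False)
    records, n_malformed = bold_io.read_records(path)
    assert len(records) == 3 and n_malformed == 0
    assert records["nucleotides"].iloc[1] == "ACGT" * 120  # upper-cased
    assert np.isnan(records["lat"].iloc[2])  # missing preserved, not zero


def test_read_records_missing_column_is_hard_error(tmp_path):
    path = tmp_path / "bad.tsv"
    pd.DataFrame({"processid": ["x"]}).to_csv(path, sep="\t", index=False)
    with pytest.raises(ValueError, match="mandatory"):
        bold_io.read_records(path)


def test_read_records_skips_malformed_rows(tmp_path):
    path = tmp_path / "records.tsv"
    df = _table([_row("P1"), _row("", seq="ACGT"), _row("P3", seq="  ")])
    df.to_csv(path, sep="\t", index=False)
    records, n_malformed = bold_io.read_records(path)
    assert len(records) == 1 and n_malformed == 2


@pytest.mark.parametrize(
    "seq,expected",
    [("--ACGT--", "ACGT"), ("AC--GT", "AC--GT"), ("------", ""), ("ACGT", "ACGT")],
)
def test_trim_end_gaps(seq, expected):
    assert bold_io.trim_end_gaps(seq) == expected


def test_length_boundaries_are_inclusive():
    rows = [
        _row("keep800", seq="A" * 800),
        _row("drop801", seq="A" * 801),
        _row("keep400", seq="A" * 400),
        _row("drop399", seq="A" * 399),
        _row("gapped", seq="--" + "A" * 500 + "--"),  # trimmed length 500
        _row("allgap", seq="-" * 450),  # trims to empty -> too short
    ]
    kept, report = bold_io.apply_filters(_table(rows))
    assert set(kept["processid"]) == {"keep800", "keep400", "gapped"}
    assert report.removed["too_long"] == 1
    assert report.removed["too_short"] == 2


def test_interior_gaps_do_not_count_toward_length():
    seq = "A" * 399 + "-" * 10 + "A"  # 400 bases, 10 interior gaps
    kept, _ = bold_io.apply_filters(_table([_row("P1", seq=seq)]))
    assert len(kept) == 1 and kept["ungapped_len"].iloc[0] == 400


def test_invasive_requires_list_and_two_continents():
    rows = [
        _row("i1", otu="BOLD:INV", species="Invasia invasiva", continent="WestContinent"),
        _row("i2", otu="BOLD:INV", species="Invasia invasiva", continent="EastContinent"),
        _row("n1", otu="BOLD:NAT", species="Nativa nativa", continent="WestContinent"),
        _row("n2", otu="BOLD:NAT", species="Nativa nativa", continent="EastContinent"),
        _row("l1", otu="BOLD:LOC", species="Localis localis", continent="WestContinent"),
    ]
    kept, report = bold_io.apply_filters(_table(rows), invasive_list={"Invasia invasiva", "Localis localis"})
    # listed + transcontinental -> removed everywhere; transcontinental but
    # unlisted, or listed but single-continent -> retained
    assert set(kept["processid"]) == {"n1", "n2", "l1"}
    assert report.removed["invasive"] == 2


def test_filter_order_independence(rng):
    """The retained set is the conjunction of all rules, regardless of
    attribution order: re-filtering the retained set removes nothing."""
    rows = []
    for i in range(120):
        length = int(rng.choice([300, 500, 801, 700]))
        lat = float(rng.choice([np.nan, 45.0]))
        rows.append(_row(f"P{i}", seq="A" * length, lat=lat, otu=f"BOLD:{i % 30}"))
    records = _table(rows)
    kept, report = bold_io.apply_filters(records)
    report.check()
    again, report2 = bold_io.apply_filters(kept)
    assert len(again) == len(kept)
    assert sum(report2.removed.values()) == 0


def test_pathology_world_counts_match_truth(pathology_world):
    truth = pathology_world.truth["pathologies"]
    kept, report = bold_io.apply_filters(
        pathology_world.records, invasive_list=pathology_world.invasive_list
    )
    assert report.removed["too_long"] == truth["too_long"]
    assert report.removed["too_short"] == truth["too_short"]
    assert report.removed["ungeoreferenced"] == truth["ungeoreferenced"]
    assert report.removed["invasive"] == truth["invasive"]
    clean_expected = (
        pathology_world.truth["n_records"] + truth["end_gap_retained"] + truth["low_copy_records"]
    )
    assert report.retained == clean_expected
    # end-gap records survive with trimmed sequences
    endgap = kept[kept["bin_uri"] == truth["end_gap_otu"]]
    assert len(endgap) == truth["end_gap_retained"]
    assert not endgap["nucleotides"].str.startswith("-").any()


def test_fasta_roundtrip(tmp_path):
    seqs = {"a": "ACGT" * 50, "b": "TTTT" * 30}
    path = tmp_path / "x.fasta"
    bold_io.write_fasta(seqs, path)
    text = path.read_text()
    assert max(len(line) for line in text.splitlines()) <= 80
    assert bold_io.read_fasta(path) == seqs
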
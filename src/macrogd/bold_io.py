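"""Reading and filtering BOLD-style barcode record tables.

The expected input is a tab-separated table with one georeferenced COI
specimen per row and columns ``processid, bin_uri, order_name,
species_name, lat, lon, country, continent, nucleotides``.  Record-level
quality filters mirror standard barcode-survey practice:

* end gaps are trimmed from every sequence before length is measured;
* sequences longer than 800 bp (exclusive) are removed — such records are
  dominated by alignment gaps;
* sequences shorter than 400 bp (exclusive) are removed — below the length
  the OTU-clustering algorithm itself requires;
* records without coordinates are removed;
* taxa on a user-supplied invasive list that are observed on two or more
  continents in the data are removed everywhere (trans-continental
  invasives would smear diversity across grid cells);
* exact duplicate record ids are removed (first occurrence kept).

The filters are conjunctive, so the retained set does not depend on the
order they are applied; for reporting, each removed record is attributed
to the first matching rule in the order too_long, too_short,
ungeoreferenced, invasive, duplicate_record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: mandatory columns of a BOLD-schema record table
BOLD_COLUMNS = [
    "processid",
    "bin_uri",
    "order_name",
    "species_name",
    "lat",
    "lon",
    "country",
    "continent",
    "nucleotides",
]

GAP = "-"


@dataclass
class FilterReport:
    """Reconciliation of record counts through the quality filters.

    ``n_input`` counts well-formed input records; malformed rows skipped at
    parse time are reported separately and are not part of the
    reconciliation.  Invariant: retained + sum(removed) = n_input.
    """

    n_input: int = 0
    n_malformed: int = 0
    removed: dict = field(
        default_factory=lambda: {
            "too_long": 0,
            "too_short": 0,
            "ungeoreferenced": 0,
            "invasive": 0,
            "duplicate_record": 0,
        }
    )
    retained: int = 0

    def check(self) -> None:
        if self.retained + sum(self.removed.values()) != self.n_input:
            raise AssertionError("filter report does not reconcile")


def read_records(path: str | Path) -> tuple[pd.DataFrame, int]:
    """Read a BOLD-schema TSV into a record table.

    Returns ``(records, n_malformed)``.  Missing coordinates are preserved
    as NaN (never coerced to zero); sequences are upper-cased.  Rows with
    an empty record id or sequence are logged and skipped; a missing
    mandatory column is a hard error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in BOLD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory columns: {missing}")
    df = df[BOLD_COLUMNS].copy()
    bad = (df["processid"].str.strip() == "") | (df["nucleotides"].str.strip() == "")
    n_malformed = int(bad.sum())
    if n_malformed:
        logger.warning("skipped %d malformed rows", n_malformed)
    df = df[~bad].copy()
    for c in ("lat", "lon"):
        df[c] = pd.to_numeric(df[c].replace("", np.nan), errors="coerce")
    df["nucleotides"] = df["nucleotides"].str.strip().str.upper()
    return df.reset_index(drop=True), n_malformed


def trim_end_gaps(sequence: str) -> str:
    """Strip leading and trailing gap runs, keeping interior gaps.

    An all-gap sequence becomes empty (and subsequently fails the length
    filter).
    """
    return sequence.strip(GAP)


def ungapped_length(sequence: str) -> int:
    """Number of non-gap characters; ambiguity codes (incl. N) count as
    bases, consistent with alignment practice."""
    return len(sequence) - sequence.count(GAP)


def read_invasive_list(path: str | Path) -> set[str]:
    """Two-column CSV (taxon, source) -> set of flagged taxon names/ids."""
    df = pd.read_csv(path, dtype=str)
    return set(df.iloc[:, 0].str.strip())


def apply_filters(
    records: pd.DataFrame,
    invasive_list: set[str] | None = None,
    min_len: int = 400,
    max_len: int = 800,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the record-level quality filters.

    Length is measured on the end-trimmed sequence, counting non-gap
    characters; the boundary values ``min_len`` and ``max_len`` themselves
    are retained (removal bounds are strict inequalities).  A taxon is
    removed as invasive only if it is on ``invasive_list`` (matched against
    species name or OTU id) *and* observed on >= 2 continents in the data.

    Returns the retained records (with trimmed sequences and an
    ``ungapped_len`` column) and a reconciled :class:`FilterReport`.
    """
    invasive_list = invasive_list or set()
    df = records.copy().reset_index(drop=True)
    report = FilterReport(n_input=len(df))

    df["nucleotides"] = df["nucleotides"].map(trim_end_gaps)
    df["ungapped_len"] = df["nucleotides"].map(ungapped_length)

    too_long = df["ungapped_len"] > max_len
    too_short = ~too_long & (df["ungapped_len"] < min_len)
    ungeo = (
        ~too_long
        & ~too_short
        & (
            df["lat"].isna()
            | df["lon"].isna()
            | (df["lat"].abs() > 90)
            | (df["lon"].abs() > 180)
        )
    )

    # trans-continental invasives: membership on the list AND presence on
    # >= 2 continents anywhere in the input data
    n_continents = {}
    for key in ("species_name", "bin_uri"):
        n_continents[key] = records.groupby(key)["continent"].nunique()
    flagged = df["species_name"].isin(invasive_list) | df["bin_uri"].isin(invasive_list)
    multi = df["species_name"].map(n_continents["species_name"]).fillna(0).ge(2) | df[
        "bin_uri"
    ].map(n_continents["bin_uri"]).fillna(0).ge(2)
    invasive = ~too_long & ~too_short & ~ungeo & flagged & multi

    dup = (
        ~too_long
        & ~too_short
        & ~ungeo
        & ~invasive
        & df["processid"].duplicated(keep="first")
    )

    report.removed["too_long"] = int(too_long.sum())
    report.removed["too_short"] = int(too_short.sum())
    report.removed["ungeoreferenced"] = int(ungeo.sum())
    report.removed["invasive"] = int(invasive.sum())
    report.removed["duplicate_record"] = int(dup.sum())

    keep = ~(too_long | too_short | ungeo | invasive | dup)
    out = df[keep].reset_index(drop=True)
    report.retained = len(out)
    report.check()
    return out, report


def write_fasta(seqs: dict[str, str] | list[tuple[str, str]], path: str | Path) -> None:
    """Write sequences as FASTA wrapped at 80 columns."""
    items = seqs.items() if isinstance(seqs, dict) else seqs
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in items]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=80)
        writer.write_file(recs)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence mapping (upper-cased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def align_otu_hook(seqs: dict[str, str]) -> dict[str, str]:
    """Adapter hook for an external aligner.

    Real barcode data would be aligned per OTU per cell with an external
    multiple-sequence aligner before diversity is computed.  This package
    emits pre-aligned synthetic sequences, so the default hook is the
    identity; replace it to plug in an aligner.
    """
    return seqs
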
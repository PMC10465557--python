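"""Genetic diversity metrics for gridded barcode assemblages.

Per-OTU nucleotide diversity (pi) is the mean per-site pairwise difference
across all unordered sequence pairs, with pairwise deletion of sites where
either sequence carries a gap or an ambiguity code.  Per grid cell, two
assemblage summaries are computed over the retained OTUs:

* **GDM** (genetic diversity mean): the arithmetic mean of per-OTU pi,
  reported both raw and square-root transformed (the transformed value is
  what all downstream statistics use, since raw GDM is strongly
  zero-skewed).
* **GDE** (genetic diversity evenness): the first-order Hill number of the
  per-OTU pi distribution divided by OTU richness N.  The pi values are
  normalized to proportions p_i = pi_i / sum(pi) before taking the Shannon
  entropy — the Hill-number framework's scale-free reading, and the only
  one under which dividing by N yields an evenness bounded by (0, 1].
  A literal variant that applies the entropy to raw pi values is available
  via ``literal=True`` for comparison; no claim is made about which variant
  matches any previously published table.

An OTU needs at least ``min_copies`` (default 3) sequences in a cell to
contribute, and a cell needs at least ``min_otus`` OTUs to be summarized.
A single sequence carries no observable diversity (the single-sequence
rule): collapsing a sample to one haplotype yields pi = 0 by convention
wherever that rule is invoked upstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

_VALID = np.frombuffer(b"ACGT", dtype=np.uint8)

#: thresholds considered for the minimum number of OTUs per grid cell
OTU_THRESHOLDS = (10, 25, 50, 100, 150, 200)


def _encode(seqs: list[str]) -> np.ndarray:
    arr = np.array([list(s.upper().encode("ascii")) for s in seqs], dtype=np.uint8)
    return arr


def nucleotide_diversity(alignment: list[str]) -> float:
    """Mean per-site pairwise difference of an aligned sequence set.

    A site contributes to a pair only when both sequences carry an
    unambiguous base (A/C/G/T) there; gaps ('-') and IUPAC ambiguity codes
    (including N) are pairwise-deleted and never count as match or
    mismatch.  Each pair is normalized by its own number of comparable
    sites.  Pairs with zero comparable sites are excluded from the pair
    count (logged).

    Raises ``ValueError`` for fewer than two sequences or unequal lengths.
    """
    if len(alignment) < 2:
        raise ValueError("nucleotide diversity needs at least 2 sequences")
    lengths = {len(s) for s in alignment}
    if len(lengths) != 1:
        raise ValueError("sequences must be aligned to equal length")
    arr = _encode(alignment)
    valid = np.isin(arr, _VALID)
    n = arr.shape[0]
    contribs = []
    n_skipped = 0
    for i in range(n - 1):
        comp = valid[i] & valid[i + 1 :]
        mism = (arr[i] != arr[i + 1 :]) & comp
        sites = comp.sum(axis=1)
        ok = sites > 0
        n_skipped += int((~ok).sum())
        contribs.extend(mism.sum(axis=1)[ok] / sites[ok])
    if n_skipped:
        logger.warning("%d sequence pairs had no comparable sites and were excluded", n_skipped)
    if not contribs:
        raise ValueError("no sequence pair had comparable sites")
    # fsum: correctly rounded, independent of pair enumeration order
    return math.fsum(contribs) / len(contribs)


def gde(pi_values, literal: bool = False) -> float:
    """Genetic diversity evenness of a cell's per-OTU pi values.

    exp(H)/N where H is the Shannon entropy of the normalized proportions
    p_i = pi_i / sum(pi) (0*ln 0 := 0) and N the OTU richness.  Bounded by
    [1/N, 1]; equals 1 iff all nonzero pi are equal and no zero-pi OTUs are
    present.  When every pi is zero the evenness is undefined and NaN is
    returned (callers flag the cell rather than coercing to a number).

    With ``literal=True`` the entropy is applied to the raw pi values
    instead of proportions (comparison variant; not bounded by 1).
    """
    pi = np.asarray(pi_values, dtype=float)
    if pi.size == 0:
        raise ValueError("gde needs at least one pi value")
    if (pi < 0).any():
        raise ValueError("pi values must be non-negative")
    n = pi.size
    if literal:
        nz = pi[pi > 0]
        h = -(nz * np.log(nz)).sum() if nz.size else np.nan
        return float(np.exp(h) / n) if np.isfinite(h) else float("nan")
    total = pi.sum()
    if total == 0:
        return float("nan")
    p = pi / total
    nz = p[p > 0]
    h = -(nz * np.log(nz)).sum()
    return float(np.exp(h) / n)


def gdm(pi_values) -> tuple[float, float]:
    """Genetic diversity mean: (raw arithmetic mean of pi, its square root)."""
    pi = np.asarray(pi_values, dtype=float)
    if pi.size == 0:
        raise ValueError("gdm needs at least one pi value")
    raw = float(pi.mean())
    return raw, float(np.sqrt(raw))


def otu_diversity_table(
    records: pd.DataFrame,
    alignments: dict[tuple[str, str], list[str]] | None = None,
    min_copies: int = 3,
) -> pd.DataFrame:
    """Per-OTU-per-cell nucleotide diversity.

    ``records`` must carry ``bin_uri``, ``order_name``, ``nucleotides`` and a
    ``cell`` column (see :mod:`macrogd.gridding`).  If ``alignments`` maps
    (cell, otu) to an externally aligned sequence set it takes precedence;
    otherwise the record sequences themselves are used (they must be equal
    length within the OTU-cell group, as for pre-aligned synthetic data).
    OTUs with fewer than ``min_copies`` sequences in a cell are dropped.
    """
    rows = []
    for (cell, otu), grp in records.groupby(["cell", "bin_uri"], sort=True):
        if alignments is not None and (cell, otu) in alignments:
            seqs = alignments[(cell, otu)]
        else:
            seqs = list(grp["nucleotides"])
        if len(seqs) < min_copies:
            continue
        rows.append(
            {
                "cell": cell,
                "otu_id": otu,
                "order_name": grp["order_name"].iloc[0],
                "n_copies": len(seqs),
                "pi": nucleotide_diversity(seqs),
            }
        )
    return pd.DataFrame(rows, columns=["cell", "otu_id", "order_name", "n_copies", "pi"])


def summarize_cells(
    records: pd.DataFrame,
    min_otus: int = 100,
    min_copies: int = 3,
    alignments: dict[tuple[str, str], list[str]] | None = None,
    literal_evenness: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate records into per-cell diversity summaries.

    Returns ``(cell_summaries, otu_diversity)``.  Cells with fewer than
    ``min_otus`` qualifying OTUs are dropped; cells whose OTUs all have
    pi = 0 get ``gde = NaN`` and are flagged in the ``gde_defined`` column.
    """
    otu_div = otu_diversity_table(records, alignments=alignments, min_copies=min_copies)
    summaries = []
    if not otu_div.empty:
        counts = records.groupby(["cell", "bin_uri"]).size().rename("n")
        for cell, grp in otu_div.groupby("cell", sort=True):
            if len(grp) < min_otus:
                continue
            pi = grp["pi"].to_numpy()
            raw, transformed = gdm(pi)
            ev = gde(pi, literal=literal_evenness)
            n_ind = int(counts.loc[cell][grp["otu_id"]].sum())
            summaries.append(
                {
                    "cell": cell,
                    "n_otus": len(grp),
                    "n_individuals": n_ind,
                    "n_orders": grp["order_name"].nunique(),
                    "gdm_raw": raw,
                    "gdm": transformed,
                    "gde": ev,
                    "gde_defined": bool(np.isfinite(ev)),
                }
            )
    cols = ["cell", "n_otus", "n_individuals", "n_orders", "gdm_raw", "gdm", "gde", "gde_defined"]
    summary_df = pd.DataFrame(summaries, columns=cols)
    n_undef = int((~summary_df["gde_defined"]).sum()) if len(summary_df) else 0
    if n_undef:
        logger.warning("%d cells have undefined GDE (all pi = 0)", n_undef)
    return summary_df, otu_div


@dataclass(frozen=True)
class WelchResult:
    """Welch's unequal-variance two-sample t-test on per-cell metrics."""

    metric: str
    mean_full: float
    mean_subset: float
    mean_diff: float
    t: float
    df: float
    p: float


def order_subset_comparison(
    records: pd.DataFrame,
    orders_to_remove: list[str],
    min_otus: int = 100,
    min_copies: int = 3,
    **kwargs,
) -> dict[str, WelchResult]:
    """Recompute cell summaries with named taxonomic orders removed and
    compare GDM / GDE distributions to the full data with Welch's t-test.

    Removing nothing gives mean difference exactly 0 and p = 1.
    """
    present = set(records["order_name"].unique())
    missing = set(orders_to_remove) - present
    if missing:
        raise ValueError(f"orders not present in data: {sorted(missing)}")
    full, _ = summarize_cells(records, min_otus=min_otus, min_copies=min_copies, **kwargs)
    subset_records = records[~records["order_name"].isin(orders_to_remove)]
    sub, _ = summarize_cells(subset_records, min_otus=min_otus, min_copies=min_copies, **kwargs)
    if len(sub) < 2 or len(full) < 2:
        raise ValueError("order subset leaves fewer than 2 cells")
    out = {}
    for metric in ("gdm", "gde"):
        a = full[metric].dropna().to_numpy()
        b = sub[metric].dropna().to_numpy()
        if not orders_to_remove:
            res = WelchResult(metric, float(a.mean()), float(b.mean()), 0.0, 0.0, float(2 * len(a) - 2), 1.0)
        else:
            t = stats.ttest_ind(a, b, equal_var=False)
            res = WelchResult(
                metric,
                float(a.mean()),
                float(b.mean()),
                float(a.mean() - b.mean()),
                float(t.statistic),
                float(t.df),
                float(t.pvalue),
            )
        out[metric] = res
    return out


def resample_cell(
    pi_values,
    n_otus_draw: int = 100,
    n_resamples: int = 1000,
    seed: int | None = None,
    literal_evenness: bool = False,
) -> pd.DataFrame:
    """Bootstrap sampling distributions of GDM and GDE for one cell.

    Draws ``n_otus_draw`` OTUs with replacement from the cell's per-OTU pi
    values, ``n_resamples`` times, and recomputes both summaries per draw.
    """
    pi = np.asarray(pi_values, dtype=float)
    if pi.size < 1:
        raise ValueError("cell must have at least one OTU")
    rng = np.random.default_rng(seed)
    draws = rng.choice(pi, size=(n_resamples, n_otus_draw), replace=True)
    gdms = np.sqrt(draws.mean(axis=1))
    gdes = np.array([gde(row, literal=literal_evenness) for row in draws])
    return pd.DataFrame({"gdm": gdms, "gde": gdes})


def occupancy_table(records: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Distribution of grid-cell occupancy per OTU.

    Returns ``(per_otu, histogram)`` where ``per_otu`` maps each OTU to the
    number of distinct cells it occupies and ``histogram`` counts OTUs per
    occupancy level.  The histogram sums to the number of OTUs.
    """
    per_otu = records.groupby("bin_uri")["cell"].nunique().rename("n_cells")
    hist = per_otu.value_counts().sort_index().rename("n_otus")
    return per_otu, hist
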
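"""Diversity metrics: brute-force oracles, evenness identities and bounds."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from macrogd import diversity
from macrogd.diversity import gde, gdm, nucleotide_diversity


def brute_force_pi(seqs):
    """Independent double-loop nucleotide diversity with pairwise deletion.

    Accumulates with math.fsum so the value is the correctly rounded mean,
    making exact equality with any other correct implementation meaningful.
    """
    import math

    n = len(seqs)
    contribs = []
    for i in range(n):
        for j in range(i + 1, n):
            comp = mism = 0
            for a, b in zip(seqs[i].upper(), seqs[j].upper()):
                if a in "ACGT" and b in "ACGT":
                    comp += 1
                    mism += a != b
            if comp:
                contribs.append(mism / comp)
    if not contribs:
        raise ValueError("no comparable pairs")
    return math.fsum(contribs) / len(contribs)


@pytest.mark.parametrize(
    "seqs,expected",
    [
        (["ACGT", "ACGT"], 0.0),
        (["ACGT", "ACGA"], 0.25),
        (["ACGT", "ACGA", "ACGA"], 1.0 / 6.0),
        (["AC-T", "ACGT"], 0.0),  # gap site pairwise-deleted
        (["ANGT", "ACGT"], 0.0),  # ambiguity never a mismatch
    ],
)
def test_pi_worked_examples(seqs, expected):
    assert nucleotide_diversity(seqs) == pytest.approx(expected, abs=1e-15)


def test_pi_requires_two_aligned_sequences():
    with pytest.raises(ValueError):
        nucleotide_diversity(["ACGT"])
    with pytest.raises(ValueError):
        nucleotide_diversity(["ACGT", "ACG"])


def test_pi_matches_brute_force_on_random_alignments(rng):
    """Vectorized implementation equals the independent double-loop oracle
    exactly, over random small alignments with gaps and ambiguity codes."""
    alphabet = "ACGTN-RY"
    for _ in range(300):
        n = rng.integers(2, 7)
        L = rng.integers(1, 51)
        seqs = ["".join(rng.choice(list(alphabet), size=L)) for _ in range(n)]
        try:
            expected = brute_force_pi(seqs)
        except ValueError:
            with pytest.raises(ValueError):
                nucleotide_diversity(seqs)
            continue
        assert nucleotide_diversity(seqs) == expected


def test_gde_identities():
    assert gde([0.02, 0.02, 0.02]) == pytest.approx(1.0, abs=1e-12)
    assert gde([0.123]) == pytest.approx(1.0, abs=1e-12)  # single-OTU ceiling
    # worked value: entropy of {10/11, 1/11, 0, 0}
    p = np.array([10 / 11, 1 / 11])
    expected = np.exp(-(p * np.log(p)).sum()) / 4
    assert gde([0.01, 0.001, 0.0, 0.0]) == pytest.approx(expected, abs=1e-12)


def test_gde_all_zero_is_missing():
    assert np.isnan(gde([0.0, 0.0]))


def test_gde_literal_variant_differs():
    pi = [0.01, 0.02, 0.005]
    assert gde(pi, literal=True) != pytest.approx(gde(pi))


@given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=20))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_gde_bounds_property(pi):
    """1/N <= GDE <= 1 whenever some pi is positive."""
    if sum(pi) == 0:
        return
    v = gde(pi)
    n = len(pi)
    assert 1.0 / n - 1e-12 <= v <= 1.0 + 1e-12


def test_gde_mean_preserving_contraction_never_decreases(rng):
    """Moving two OTUs' diversities toward their mean raises evenness."""
    for _ in range(200):
        pi = rng.uniform(0.001, 0.05, size=3)
        i, j = 0, 1
        step = rng.uniform(0, 0.5)
        contracted = pi.copy()
        mean_ij = (pi[i] + pi[j]) / 2
        contracted[i] = pi[i] + step * (mean_ij - pi[i])
        contracted[j] = pi[j] + step * (mean_ij - pi[j])
        assert gde(contracted) >= gde(pi) - 1e-12


def test_gdm_examples():
    assert gdm([0.0, 0.0]) == (0.0, 0.0)
    assert gdm([0.04]) == (pytest.approx(0.04), pytest.approx(0.2))
    raw, tr = gdm([0.01, 0.03])
    assert raw == pytest.approx(0.02) and tr == pytest.approx(np.sqrt(0.02))


def _records_from(world):
    from macrogd.gridding import GridSpec, assign_cells

    return assign_cells(world.records, GridSpec(cell_size=world.truth["cell_size"]))


def test_summaries_match_direct_recomputation(small_world):
    """Every retained cell's GDM/GDE equals direct recomputation from the
    emitted alignments, and is invariant to record order."""
    recs = _records_from(small_world)
    summ, otu = diversity.summarize_cells(recs, min_otus=10, min_copies=3)
    assert len(summ) > 0
    for _, row in summ.iterrows():
        cell = row["cell"]
        pis = [
            nucleotide_diversity(seqs)
            for (c, otu_id), seqs in small_world.alignments.items()
            if c == cell and len(seqs) >= 3
        ]
        raw, tr = gdm(pis)
        assert row["gdm_raw"] == pytest.approx(raw, abs=1e-12)
        assert row["gdm"] == pytest.approx(tr, abs=1e-12)
        assert row["gde"] == pytest.approx(gde(pis), abs=1e-12)
    shuffled = recs.sample(frac=1.0, random_state=1)
    summ2, _ = diversity.summarize_cells(shuffled, min_otus=10, min_copies=3)
    pd.testing.assert_frame_equal(
        summ.reset_index(drop=True), summ2.reset_index(drop=True)
    )


def test_low_copy_otus_and_sparse_cells_excluded(small_world):
    recs = _records_from(small_world)
    # truncate one OTU to 2 copies: it must vanish from the diversity table
    otu0 = recs["bin_uri"].iloc[0]
    cell0 = recs["cell"].iloc[0]
    mask = (recs["bin_uri"] == otu0) & (recs["cell"] == cell0)
    trimmed = pd.concat([recs[~mask], recs[mask].head(2)])
    _, otu_div = diversity.summarize_cells(trimmed, min_otus=1, min_copies=3)
    assert not (
        (otu_div["otu_id"] == otu0) & (otu_div["cell"] == cell0)
    ).any()
    # a threshold above the per-cell OTU count drops every cell
    summ, _ = diversity.summarize_cells(recs, min_otus=200, min_copies=3)
    assert len(summ) == 0


def test_order_subset_comparison_null_and_removal(small_world):
    recs = _records_from(small_world)
    res = diversity.order_subset_comparison(recs, [], min_otus=10)
    assert res["gdm"].mean_diff == 0.0 and res["gdm"].p == 1.0
    res2 = diversity.order_subset_comparison(recs, ["Diptera"], min_otus=10)
    assert np.isfinite(res2["gde"].t)
    with pytest.raises(ValueError):
        diversity.order_subset_comparison(recs, ["NotAnOrder"], min_otus=10)


def test_resample_cell_bootstrap_consistency(rng):
    pi = rng.uniform(0.0, 0.05, size=60)
    out = diversity.resample_cell(pi, n_otus_draw=100, n_resamples=400, seed=5)
    full = np.sqrt(pi.mean())
    se = out["gdm"].std(ddof=1) / np.sqrt(len(out))
    assert abs(out["gdm"].mean() - full) < max(3 * se, 0.35 * out["gdm"].std(ddof=1))
    # all-equal pi -> every resample perfectly even
    even = diversity.resample_cell([0.02] * 5, n_otus_draw=10, n_resamples=50, seed=1)
    assert np.allclose(even["gde"], 1.0)
    # reproducible under seed
    again = diversity.resample_cell(pi, n_otus_draw=100, n_resamples=400, seed=5)
    pd.testing.assert_frame_equal(out, again)


def test_occupancy_conservation(small_world):
    recs = _records_from(small_world)
    per_otu, hist = diversity.occupancy_table(recs)
    assert hist.sum() == recs["bin_uri"].nunique()
    for otu, span in small_world.truth["multicell_otus"].items():
        assert per_otu[otu] == span
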
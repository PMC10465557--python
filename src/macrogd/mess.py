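"""Multivariate environmental similarity surfaces (MESS) and non-analog
masking of model extrapolations.

For each candidate location and each environmental variable j, a
similarity score S_j is computed against the reference (training) values;
the MESS value is the minimum of the S_j and locations with MESS < 0 lie
outside the reference environmental range in at least one variable
("non-analog" environments).  Predictions there are masked in map
outputs.

With f the percentage of reference points strictly below the candidate
value v, and min/max the reference extremes:

* f = 0:        S = 100 * (v - min) / (max - min)   (negative: below range)
* 0 < f <= 50:  S = 2 f
* 50 < f < 100: S = 2 (100 - f)
* f = 100:      S = 100 * (max - v) / (max - min)   (negative: above range)
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def mess_score(reference, v, tie_half_weight: bool = False):
    """Similarity of candidate value(s) ``v`` to a reference sample.

    ``reference`` is the non-empty training sample for one variable; ``v``
    may be a scalar or array.  ``tie_half_weight`` counts reference points
    equal to v at half weight in f (some reference implementations do);
    off by default, where f counts strictly-below points only.

    A degenerate reference (min == max) scores 0 where v equals the
    constant and negative otherwise, with the zero range replaced by 1.0
    in the out-of-range branches (documented guard).
    """
    ref = np.asarray(reference, dtype=float)
    if ref.size == 0:
        raise ValueError("empty reference sample")
    v = np.asarray(v, dtype=float)
    scalar = v.ndim == 0
    v = np.atleast_1d(v)
    lo, hi = ref.min(), ref.max()
    span = hi - lo if hi > lo else 1.0
    below = (ref[None, :] < v[:, None]).mean(axis=1) * 100.0
    if tie_half_weight:
        below = below + (ref[None, :] == v[:, None]).mean(axis=1) * 50.0
    s = np.where(
        below == 0.0,
        100.0 * (v - lo) / span,
        np.where(
            below <= 50.0,
            2.0 * below,
            np.where(below < 100.0, 2.0 * (100.0 - below), 100.0 * (hi - v) / span),
        ),
    )
    return float(s[0]) if scalar else s


def mess_table(
    reference: pd.DataFrame, candidates: pd.DataFrame, tie_half_weight: bool = False
) -> pd.DataFrame:
    """Per-location MESS over a shared predictor set.

    Returns a table indexed like ``candidates`` with one S_j column per
    variable, the ``mess`` minimum, and the boolean ``non_analog`` mask
    (mess < 0).  Raises if the predictor sets differ.
    """
    if set(reference.columns) != set(candidates.columns):
        raise ValueError("training and prediction predictor sets differ")
    out = pd.DataFrame(index=candidates.index)
    for col in reference.columns:
        out[f"S_{col}"] = mess_score(
            reference[col].to_numpy(), candidates[col].to_numpy(), tie_half_weight
        )
    s_cols = [f"S_{c}" for c in reference.columns]
    out["mess"] = out[s_cols].min(axis=1)
    out["non_analog"] = out["mess"] < 0.0
    return out


def mask_predictions(
    predictions: pd.DataFrame,
    training_env: pd.DataFrame,
    prediction_env: pd.DataFrame,
    value_cols: tuple[str, ...] = ("median", "hdi_low", "hdi_high"),
    tie_half_weight: bool = False,
) -> pd.DataFrame:
    """Mask model predictions falling in non-analog environments.

    ``predictions`` and ``prediction_env`` must share an index (cells).
    Returns predictions joined with the MESS columns; masked cells keep
    their values in the table but get NaN in ``<col>_masked`` map columns
    and ``non_analog = True``.
    """
    if not predictions.index.equals(prediction_env.index):
        raise ValueError("predictions and prediction_env must share an index")
    mess = mess_table(training_env, prediction_env, tie_half_weight)
    out = predictions.join(mess)
    for col in value_cols:
        if col in out:
            out[f"{col}_masked"] = out[col].where(~out["non_analog"])
    return out
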
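"""Multisensory interaction index and additivity categories.

For each neuron, R_Light, R_Vib and R_Comb are the mean dF/F (%) over the
10 s response window (per `trial_average`) for the light-only, vibration-
only and combined presentations. The interaction index is

    index = 100 * (R_Comb - max(R_Light, R_Vib)) / max(R_Light, R_Vib)

An index above 100 is super-additive (the combined response is at least
twice the larger single response), between 0 and 100 sub-additive, and
below 0 response depression (combined smaller than the larger single
response). When the larger single response does not exceed ``epsilon`` the
record is flagged undefined rather than divided through by near-zero.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .stats import TestResult, rank_test
from .types import SchemaError

__all__ = [
    "interaction_index",
    "category_fractions",
    "compare_category_fractions",
    "index_cdf",
    "CATEGORIES",
]

CATEGORIES = ("super_additive", "sub_additive", "depression")
DISPLAY_CLIP = 300.0  # plotted values are clipped at +/-300; stored values never are


def interaction_index(r_light, r_vib, r_comb, epsilon: float = 0.5,
                      neuron_ids=None) -> pd.DataFrame:
    """Interaction index and additivity category per neuron.

    ``epsilon`` (percent dF/F) guards the denominator; 0 reproduces the
    literal formula for every neuron. Index 0 falls in sub_additive
    (depression is strictly below zero). Returns a table with columns
    neuron_id, R_light, R_vib, R_comb, index, category, valid.
    """
    r_l = np.atleast_1d(np.asarray(r_light, dtype=float))
    r_v = np.atleast_1d(np.asarray(r_vib, dtype=float))
    r_c = np.atleast_1d(np.asarray(r_comb, dtype=float))
    if not (r_l.shape == r_v.shape == r_c.shape):
        raise SchemaError("response vectors must have equal length")
    if not np.all(np.isfinite(np.stack([r_l, r_v, r_c]))):
        raise SchemaError("response amplitudes must be finite")
    m = np.maximum(r_l, r_v)
    valid = m > epsilon
    index = np.full(r_l.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        index[valid] = 100.0 * (r_c[valid] - m[valid]) / m[valid]
    category = np.full(r_l.shape, "undefined", dtype=object)
    category[valid & (index > 100)] = "super_additive"
    category[valid & (index >= 0) & (index <= 100)] = "sub_additive"
    category[valid & (index < 0)] = "depression"
    if neuron_ids is None:
        neuron_ids = np.arange(r_l.size)
    return pd.DataFrame(
        {
            "neuron_id": np.asarray(neuron_ids),
            "R_light": r_l,
            "R_vib": r_v,
            "R_comb": r_c,
            "index": index,
            "category": category,
            "valid": valid,
        }
    )


def category_fractions(records: pd.DataFrame, fish_ids=None) -> pd.DataFrame:
    """Percentage of valid records per additivity category, per fish.

    Undefined records are excluded from the percentages but counted in the
    ``n_undefined`` column; a fish with no valid record is excluded with a
    warning.
    """
    df = records.copy()
    df["fish"] = 0 if fish_ids is None else np.asarray(fish_ids)
    rows = []
    for fish, grp in df.groupby("fish"):
        valid = grp[grp["valid"]]
        if len(valid) == 0:
            warnings.warn(f"fish {fish}: all records undefined; excluded", stacklevel=2)
            continue
        row = {"fish": fish, "n_valid": len(valid), "n_undefined": int((~grp["valid"]).sum())}
        for cat in CATEGORIES:
            row[f"pct_{cat}"] = 100.0 * (valid["category"] == cat).mean()
        rows.append(row)
    if not rows:
        raise SchemaError("no fish with valid interaction records")
    return pd.DataFrame(rows)


def compare_category_fractions(group_a: pd.DataFrame, group_b: pd.DataFrame,
                               sided: str = "two_sided") -> dict[str, TestResult]:
    """Rank-sum comparison of per-fish category percentages between groups.

    ``sided='less'`` tests whether group A has smaller percentages than
    group B (e.g. fewer depressed neurons after antagonist injection).
    Requires at least 3 fish per group.
    """
    if len(group_a) < 3 or len(group_b) < 3:
        raise SchemaError("need at least 3 fish per group for a rank-sum comparison")
    out = {}
    for cat in CATEGORIES:
        out[cat] = rank_test(group_a[f"pct_{cat}"].to_numpy(),
                             group_b[f"pct_{cat}"].to_numpy(),
                             paired=False, sided=sided)
    return out


def index_cdf(records: pd.DataFrame):
    """Empirical CDF of the interaction index over valid records.

    Returns (sorted index values, cumulative fractions, evaluator); the
    evaluator maps a threshold t to the fraction of records with index <= t,
    so evaluating just below 0 gives the depression fraction and
    1 - F(100) the super-additive fraction.
    """
    vals = records.loc[records["valid"], "index"].to_numpy(dtype=float)
    if vals.size == 0:
        raise SchemaError("no valid records for an ECDF")
    xs = np.sort(vals)
    ys = np.arange(1, xs.size + 1) / xs.size

    def evaluate(t: float) -> float:
        return float(np.searchsorted(xs, t, side="right")) / xs.size

    return xs, ys, evaluate
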
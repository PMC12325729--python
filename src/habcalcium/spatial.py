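"""Spatial and correlational population analyses.

Covers pairwise spontaneous-activity correlations and their dependence on
anatomical distance, significantly correlated pairs and their distances,
similarity of multi-neuronal response vectors across modalities, and the
anatomical subsetting rules (dorsomedial selection, dorsal/ventral split).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import TestResult, rank_test
from .types import ConfigError, DffMatrix, NeuronGeometry, SchemaError

__all__ = [
    "pairwise_correlation",
    "significant_pairs",
    "pair_distances",
    "pair_distance_contrast",
    "correlation_vs_distance",
    "profile_group_summary",
    "compare_profiles",
    "response_vector_similarity",
    "select_dorsomedial",
    "split_dorsal_ventral",
    "CorrelationDistanceProfile",
]


def pairwise_correlation(dff_mat: DffMatrix | np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of the traces (symmetric, unit diagonal).

    Frames containing NaN in any trace are dropped; zero-variance traces get
    NaN rows/columns (undefined, flagged by a warning).
    """
    data = dff_mat.data if isinstance(dff_mat, DffMatrix) else np.asarray(dff_mat, dtype=float)
    if data.shape[0] < 2 or data.shape[1] < 3:
        raise SchemaError("need >= 2 neurons and >= 3 frames")
    keep = np.all(np.isfinite(data), axis=0)
    data = data[:, keep]
    if data.shape[1] < 3:
        raise SchemaError("fewer than 3 jointly finite frames")
    sd = data.std(axis=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} zero-variance trace(s); correlations undefined",
                      stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(data)
    corr[flat, :] = np.nan
    corr[:, flat] = np.nan
    np.fill_diagonal(corr, np.where(flat, np.nan, 1.0))
    return corr


def _lag1_autocorr(data: np.ndarray) -> np.ndarray:
    x = data - data.mean(axis=1, keepdims=True)
    num = (x[:, 1:] * x[:, :-1]).sum(axis=1)
    den = (x * x).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, 0.0)


def significant_pairs(
    corr: np.ndarray,
    n_frames: int,
    method: str = "ttest",
    alpha: float = 0.05,
    dff_mat: DffMatrix | None = None,
    n_perm: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Label each neuron pair positive / negative / ns.

    Default method: t-transform of r with an effective sample size
    corrected for lag-1 autocorrelation (Bartlett), requiring ``dff_mat``
    for the autocorrelations (assumed 0 if absent). Alternative
    ``method='perm'``: circular-shift permutation null of |r|. Undefined
    correlations are ns. Returns a long table (i, j, r, p, label) over
    i < j.
    """
    n = corr.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    r = corr[iu, ju]
    if method == "ttest":
        if dff_mat is not None:
            rho1 = _lag1_autocorr(dff_mat.data[:, np.all(np.isfinite(dff_mat.data), axis=0)])
        else:
            rho1 = np.zeros(n)
        prod = np.clip(rho1[iu] * rho1[ju], -0.999, 0.999)
        n_eff = np.maximum(n_frames * (1 - prod) / (1 + prod), 4.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = r * np.sqrt((n_eff - 2) / np.maximum(1e-12, 1 - r**2))
        p = 2 * sps.t.sf(np.abs(t), df=n_eff - 2)
    elif method == "perm":
        if dff_mat is None:
            raise ConfigError("permutation method requires the dF/F matrix")
        data = dff_mat.data[:, np.all(np.isfinite(dff_mat.data), axis=0)]
        t_len = data.shape[1]
        rng = np.random.default_rng(seed)
        exceed = np.zeros(r.size)
        for _ in range(n_perm):
            offs = rng.integers(1, t_len, size=n)
            rolled = np.stack([np.roll(data[i], offs[i]) for i in range(n)])
            rc = np.corrcoef(rolled)[iu, ju]
            exceed += np.abs(rc) >= np.abs(r)
        p = (exceed + 1) / (n_perm + 1)
    else:
        raise ConfigError(f"unknown method {method!r}")
    finite = np.isfinite(r) & np.isfinite(p)
    sig = finite & (p < alpha)
    label = np.where(sig & (r > 0), "positive", np.where(sig & (r < 0), "negative", "ns"))
    return pd.DataFrame({"i": iu, "j": ju, "r": r, "p": np.where(finite, p, np.nan),
                         "label": label})


def pair_distances(pair_labels: pd.DataFrame, geometry: NeuronGeometry) -> dict:
    """Mean 3-D distance of significantly positive vs negative pairs (one unit)."""
    dmat = geometry.pairwise_distances()
    d = dmat[pair_labels["i"].to_numpy(), pair_labels["j"].to_numpy()]
    lab = pair_labels["label"].to_numpy()
    pos, neg = d[lab == "positive"], d[lab == "negative"]
    return {
        "mean_dist_positive_um": float(pos.mean()) if pos.size else float("nan"),
        "mean_dist_negative_um": float(neg.mean()) if neg.size else float("nan"),
        "n_positive": int(pos.size),
        "n_negative": int(neg.size),
    }


def pair_distance_contrast(per_fish: list[dict], sided: str = "less") -> dict:
    """Paired signed-rank contrast of positive- vs negative-pair distances
    across fish (default alternative: positive pairs are closer). Fish
    missing either class are dropped from the test."""
    rows = [f for f in per_fish
            if np.isfinite(f["mean_dist_positive_um"]) and np.isfinite(f["mean_dist_negative_um"])]
    dropped = len(per_fish) - len(rows)
    if dropped:
        warnings.warn(f"{dropped} fish lacked a pair class; dropped from the paired test",
                      stacklevel=2)
    if len(rows) < 3:
        raise SchemaError("need >= 3 fish with both pair classes")
    pos = np.array([f["mean_dist_positive_um"] for f in rows])
    neg = np.array([f["mean_dist_negative_um"] for f in rows])
    return {
        "per_fish_positive_um": pos,
        "per_fish_negative_um": neg,
        "test": rank_test(pos, neg, paired=True, sided=sided),
    }


@dataclass
class CorrelationDistanceProfile:
    """Mean pairwise correlation in contiguous distance bins (one unit,
    e.g. one hemisphere). Empty bins hold NaN means, never zeros."""

    bin_edges_um: np.ndarray
    mean_r: np.ndarray
    counts: np.ndarray
    label: str = ""

    @property
    def bin_centers_um(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_um[:-1] + self.bin_edges_um[1:])


def correlation_vs_distance(
    corr: np.ndarray,
    geometry: NeuronGeometry,
    bin_width_um: float = 10.0,
    max_um: float | None = None,
    label: str = "",
) -> CorrelationDistanceProfile:
    """Bin neuron pairs by anatomical distance; mean Pearson r per bin."""
    if bin_width_um <= 0:
        raise ConfigError("bin width must be > 0")
    dmat = geometry.pairwise_distances()
    iu, ju = np.triu_indices(corr.shape[0], k=1)
    d = dmat[iu, ju]
    r = corr[iu, ju]
    ok = np.isfinite(r)
    d, r = d[ok], r[ok]
    top = max_um if max_um is not None else (d.max() if d.size else bin_width_um)
    edges = np.arange(0.0, top + bin_width_um, bin_width_um)
    if edges[-1] < top:
        edges = np.append(edges, edges[-1] + bin_width_um)
    idx = np.digitize(d, edges) - 1
    idx = np.clip(idx, 0, len(edges) - 2)
    nb = len(edges) - 1
    counts = np.bincount(idx, minlength=nb)
    sums = np.bincount(idx, weights=r, minlength=nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_r = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return CorrelationDistanceProfile(edges, mean_r, counts, label=label)


def profile_group_summary(profiles: list[CorrelationDistanceProfile]) -> pd.DataFrame:
    """Mean +/- SEM of per-unit bin means across units on a shared grid."""
    if not profiles:
        raise SchemaError("no profiles")
    edges = profiles[0].bin_edges_um
    nb = min(len(p.mean_r) for p in profiles)
    stack = np.vstack([p.mean_r[:nb] for p in profiles])
    mean = np.nanmean(stack, axis=0)
    n_units = np.sum(np.isfinite(stack), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sem = np.nanstd(stack, axis=0, ddof=1) / np.sqrt(np.maximum(n_units, 1))
    return pd.DataFrame({
        "bin_center_um": 0.5 * (edges[:nb] + edges[1:nb + 1]),
        "mean_r": mean,
        "sem_r": sem,
        "n_units": n_units,
    })


def compare_profiles(profiles_by_treatment: dict, include_interaction: bool = False) -> dict:
    """Two-factor fixed-effects comparison of correlation-distance profiles.

    Factors are distance bin and treatment; the response is the per-unit bin
    mean correlation. Bins are restricted to those occupied in every unit of
    every treatment (logged when any are dropped). Returns F and p per main
    effect (and the interaction when requested).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    rows = []
    for treat, profiles in profiles_by_treatment.items():
        if len(profiles) < 2:
            raise SchemaError(f"treatment {treat!r} needs >= 2 units")
        for u, prof in enumerate(profiles):
            for b, r in enumerate(prof.mean_r):
                if np.isfinite(r):
                    rows.append({"treatment": str(treat), "unit": f"{treat}:{u}",
                                 "bin": b, "r": r})
    df = pd.DataFrame(rows)
    # common support: bins present in every unit
    n_units = df["unit"].nunique()
    bin_counts = df.groupby("bin")["unit"].nunique()
    common = bin_counts[bin_counts == n_units].index
    if len(common) < len(bin_counts):
        warnings.warn(
            f"restricting to {len(common)} bins occupied in all units", stacklevel=2
        )
    df = df[df["bin"].isin(common)]
    if df["bin"].nunique() < 2 or df["treatment"].nunique() < 2:
        raise SchemaError("need >= 2 shared bins and >= 2 treatments")
    formula = "r ~ C(bin) * C(treatment)" if include_interaction else "r ~ C(bin) + C(treatment)"
    fit = smf.ols(formula, data=df).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    out = {}
    for term, key in (("C(bin)", "distance"), ("C(treatment)", "treatment"),
                      ("C(bin):C(treatment)", "interaction")):
        if term in table.index:
            out[key] = {"F": float(table.loc[term, "F"]),
                        "p": float(table.loc[term, "PR(>F)"]),
                        "df": float(table.loc[term, "df"])}
    return out


def response_vector_similarity(v1, v2) -> dict:
    """Pearson r and cosine similarity of two multi-neuronal response vectors."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != v2.shape or v1.ndim != 1 or v1.size < 3:
        raise SchemaError("need equal-length vectors over >= 3 neurons")
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        warnings.warn("zero response vector; cosine undefined", stacklevel=2)
        cosine = float("nan")
    else:
        cosine = float(v1 @ v2 / (n1 * n2))
    if v1.std() == 0 or v2.std() == 0:
        pearson = float("nan")
    else:
        pearson = float(sps.pearsonr(v1, v2).statistic)
    return {"pearson_r": pearson, "cosine": cosine, "n": int(v1.size)}


def select_dorsomedial(geometry: NeuronGeometry, fraction: float = 0.40) -> np.ndarray:
    """Neuron ids of the most dorsomedial subset.

    y is centred on the population mean and scaled by the y-range; z is
    converted to depth from the dorsal-most neuron and scaled by the
    z-range; the score |y_norm| + z_norm ranks neurons (small = dorsal and
    near the midline; ties broken by neuron_id) and the smallest
    ceil(fraction * N) are retained.
    """
    if not 0 < fraction <= 1:
        raise ConfigError("fraction must be in (0, 1]")
    t = geometry.table
    n = len(t)
    if n == 0:
        raise SchemaError("empty geometry")
    y = t["y_um"].to_numpy(dtype=float)
    depth = geometry.depth_um()
    y_rng = y.max() - y.min()
    z_rng = depth.max() - depth.min()
    y_norm = (y - y.mean()) / y_rng if y_rng > 0 else np.zeros(n)
    z_norm = depth / z_rng if z_rng > 0 else np.zeros(n)
    score = np.abs(y_norm) + z_norm
    if y_rng == 0 and z_rng == 0:
        warnings.warn("all positions identical; ranking by neuron_id alone", stacklevel=2)
    ids = t["neuron_id"].to_numpy()
    order = np.lexsort((ids, score))  # score ascending, ties by id
    k = int(np.ceil(fraction * n))
    return np.sort(ids[order[:k]])


def split_dorsal_ventral(geometry: NeuronGeometry, threshold_um: float = 40.0) -> pd.DataFrame:
    """Dorsal (depth < threshold) vs ventral (depth >= threshold) per neuron.

    The z coordinate is taken as depth from the top of the population (the
    depth-normalised convention, 0 at the dorsal-most neuron); it is used
    as-is, without re-normalisation.
    """
    depth = geometry.table["z_um"].to_numpy(dtype=float)
    if depth.min() < 0:
        raise SchemaError("z depths must be >= 0 (measured from the dorsal-most neuron)")
    return pd.DataFrame({
        "neuron_id": geometry.neuron_ids,
        "depth_um": depth,
        "division": np.where(depth < threshold_um, "dorsal", "ventral"),
    })
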
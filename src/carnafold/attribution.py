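"""Feature contribution scores and the downstream candidate-RNA analyses.

Contribution scores quantify how much each feature channel at each 2048-bp
bin moves the model's predicted contact map (summarized as the window-mean
contact value).  The backend is expected gradients — integrated gradients
averaged over a background set of training examples — which satisfies the
completeness property per background: the scores of an example sum to the
difference between its output summary and the background's.  For a linear
model the scores equal ``w_i * (x_i - x_background)`` exactly.

Downstream: per-feature [-1, 1] normalization, extraction of top/bottom
1%/5% regions (restricted to bins with positive input), observed/expected
annotation enrichment, caRNA-vs-ATAC differential bins (fold change > 5 and
|normalized score| > 0.25), hypergeometric high-confidence RNA-DNA
interactions (BH FDR <= 0.05), and candidate-RNA ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

FOLD_CHANGE_MIN = 5.0
SCORE_ABS_MIN = 0.25
FDR_MAX = 0.05


# ---------------------------------------------------------------------------
# Background scheme
# ---------------------------------------------------------------------------

def background_scheme(split_labels, n_background=20, seed=0):
    """Background example indices for each split, per the training protocol.

    Validation/test examples use ``n_background`` randomly selected training
    examples.  The training set is halved: the first half uses random
    examples from the second half as background, and vice versa.  Returns a
    dict with index arrays ``{"valid_test": ..., "train_half1": ...,
    "train_half2": ..., "half1": ..., "half2": ...}``.
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(split_labels)
    train_idx = np.flatnonzero(labels == "train")
    if len(train_idx) == 0:
        raise ValueError("no training examples to draw a background from")
    perm = rng.permutation(train_idx)
    half1, half2 = perm[: len(perm) // 2], perm[len(perm) // 2:]
    take = min(n_background, len(train_idx))
    vt = rng.choice(train_idx, size=take, replace=False)
    bg_h1 = rng.choice(half2, size=min(n_background, len(half2)), replace=False)
    bg_h2 = rng.choice(half1, size=min(n_background, len(half1)), replace=False)
    return {"valid_test": vt, "half1": half1, "half2": half2,
            "train_half1": bg_h1, "train_half2": bg_h2}


# ---------------------------------------------------------------------------
# Expected gradients
# ---------------------------------------------------------------------------

def contribution_scores(model, seqs, features, background_features,
                        background_seqs=None, n_steps=8, output_weights=None):
    """Expected-gradients contribution of each (bin, feature) to the output.

    For each example ``x`` and background ``b``:
    ``phi = mean_alpha grad(b + alpha (x - b)) * (x - b)``, averaged over the
    backgrounds.  The sequence input is held at the example's own sequence
    (attribution targets the feature channels only).

    Parameters
    ----------
    model
        Anything exposing ``feature_gradient(seqs, features, output_weights)
        -> (pred, dfeat)``; the trained predictor or a surrogate.
    seqs, features
        Arrays ``(N, L, 4)`` and ``(N, n_bins, F)``.
    background_features
        ``(n_bg, n_bins, F)`` feature array of the background examples.

    Returns
    -------
    ndarray ``(N, n_bins, F)`` of raw scores.
    """
    if len(background_features) == 0:
        raise ValueError("background set is empty")
    N = len(seqs)
    n_bg = len(background_features)
    scores = np.zeros((N, features.shape[1], features.shape[2]))
    alphas = (np.arange(n_steps) + 0.5) / n_steps  # midpoint rule
    for i in range(N):
        x = features[i]
        acc = np.zeros_like(x, dtype=np.float64)
        for bidx in range(n_bg):
            b = background_features[bidx]
            diff = x - b
            for a in alphas:
                point = (b + a * diff)[None]
                _, dfeat = model.feature_gradient(seqs[i: i + 1], point,
                                                  output_weights)
                acc += dfeat[0].astype(np.float64) * diff / n_steps
        scores[i] = acc / n_bg  # (n_bins, F)
    return scores


def normalize_scores(raw, per_window=False):
    """Normalize to [-1, 1] by the per-feature max absolute value.

    Default scope is the whole evaluated split (max over all windows and
    bins of each feature); ``per_window=True`` normalizes each window
    independently.  Sign is preserved.
    """
    raw = np.asarray(raw, dtype=float)
    if per_window:
        denom = np.abs(raw).max(axis=1, keepdims=True)
    else:
        denom = np.abs(raw).max(axis=(0, 1), keepdims=True)
    denom = np.where(denom == 0, 1.0, denom)
    return raw / denom


# ---------------------------------------------------------------------------
# Extreme regions + enrichment
# ---------------------------------------------------------------------------

@dataclass
class ExtremeRegionSet:
    feature: int | str
    tail: str  # "top" | "bottom"
    percentile: float
    bins: np.ndarray  # indices into the flattened (window, bin) axis
    eligible: np.ndarray  # the universe the percentile was computed over


def extreme_regions(scores, inputs, feature, pct=5.0, tail="top") -> ExtremeRegionSet:
    """Bins in the top/bottom ``pct`` percent of a feature's scores.

    Only bins with positive input value for the feature are eligible.  The
    ``top`` tail takes the highest (positive) scores, ``bottom`` the lowest
    (negative) scores; ties break by genomic order (stable argsort).
    """
    s = np.asarray(scores)[:, :, feature].ravel()
    x = np.asarray(inputs)[:, :, feature].ravel()
    eligible = np.flatnonzero(x > 0)
    if eligible.size == 0:
        return ExtremeRegionSet(feature, tail, pct, np.array([], int), eligible)
    k = max(1, int(np.ceil(pct / 100.0 * eligible.size)))
    vals = s[eligible]
    order = np.argsort(vals, kind="stable")
    chosen = order[-k:] if tail == "top" else order[:k]
    return ExtremeRegionSet(feature, tail, pct, np.sort(eligible[chosen]), eligible)


def enrichment(regions: ExtremeRegionSet, annotation_bins) -> float | None:
    """log2(observed / expected) overlap of a region set with an annotation.

    observed = fraction of region bins in the annotation; expected = fraction
    of eligible bins in the annotation.  Returns None when expected is 0.
    """
    ann = np.asarray(annotation_bins)
    ann_set = np.zeros(int(max(ann.max(initial=0), regions.eligible.max(initial=0))) + 1,
                       dtype=bool)
    ann_set[ann] = True
    exp = ann_set[regions.eligible].mean() if regions.eligible.size else 0.0
    if exp == 0:
        return None
    obs = ann_set[regions.bins].mean() if regions.bins.size else 0.0
    if obs == 0:
        return -np.inf
    return float(np.log2(obs / exp))


def enrichment_table(region_sets, annotations) -> pd.DataFrame:
    """Annotation class x region set table of log2(obs/exp) values."""
    rows = {}
    for ann_name, ann_bins in annotations.items():
        rows[ann_name] = {
            f"{rs.feature}:{rs.tail}{rs.percentile:g}": enrichment(rs, ann_bins)
            for rs in region_sets
        }
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# Differential caRNA-vs-ATAC regions
# ---------------------------------------------------------------------------

def differential_regions(rna_scores, atac_scores, fold_min=FOLD_CHANGE_MIN,
                         score_min=SCORE_ABS_MIN) -> pd.DataFrame:
    """Bins where a caRNA feature's |normalized score| dwarfs ATAC's.

    A bin passes iff ``|rna| / |atac| > fold_min`` and ``|rna| > score_min``.
    An ATAC score of exactly 0 gives infinite fold change (passes the fold
    gate; the magnitude gate still applies).
    """
    r = np.abs(np.asarray(rna_scores, float)).ravel()
    a = np.abs(np.asarray(atac_scores, float)).ravel()
    with np.errstate(divide="ignore"):
        fold = np.where(a > 0, r / np.where(a > 0, a, 1.0), np.inf)
    passes = (fold > fold_min) & (r > score_min)
    return pd.DataFrame({"bin": np.arange(r.size), "rna_abs": r, "atac_abs": a,
                         "fold_change": fold, "passes": passes})


# ---------------------------------------------------------------------------
# Hypergeometric high-confidence interactions
# ---------------------------------------------------------------------------

def hypergeom_interactions(counts: pd.DataFrame, fdr_max=FDR_MAX) -> pd.DataFrame:
    """High-confidence gene x DNA-bin interactions by hypergeometric test.

    ``counts`` has columns gene_id / bin / count (aggregated trans contacts).
    Under the null every DNA bin is equally likely to interact with any RNA:
    for a pair with count k, ``p = P[X >= k]`` with
    ``X ~ Hypergeom(N=total, K=gene total, n=bin total)``.  BH correction is
    applied across all tested pairs (pairs with k >= 1); pairs with
    ``q <= fdr_max`` are flagged ``retained``.
    """
    c = counts.copy()
    if (c["count"] < 0).any():
        raise ValueError("negative interaction counts")
    N = int(c["count"].sum())
    gene_tot = c.groupby("gene_id")["count"].sum()
    bin_tot = c.groupby("bin")["count"].sum()
    c = c[c["count"] >= 1].reset_index(drop=True)
    K = gene_tot[c["gene_id"]].to_numpy(int)
    n = bin_tot[c["bin"]].to_numpy(int)
    k = c["count"].to_numpy(int)
    if (k > np.minimum(K, n)).any():
        raise ValueError("count exceeds its margins; impossible input")
    pvals = stats.hypergeom.sf(k - 1, N, K, n)
    pvals = np.clip(pvals, 0.0, 1.0)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    out = c.assign(p=pvals, q=qvals, retained=qvals <= fdr_max)
    return out.sort_values("p", kind="stable").reset_index(drop=True)


def rank_candidate_rnas(highconf: pd.DataFrame, region_bins) -> pd.DataFrame:
    """Rank genes by their association with extreme-score DNA bins.

    For each gene with retained high-confidence interactions: the count of
    those interactions landing in ``region_bins`` and the ratio (in-region /
    total).  Ranked by count, ratio as tiebreak; genes with no retained
    interactions are excluded.
    """
    region = set(int(b) for b in np.asarray(region_bins).ravel())
    hc = highconf[highconf["retained"]]
    rows = []
    for gene, sub in hc.groupby("gene_id"):
        in_region = int(sub["bin"].isin(region).sum())
        total = len(sub)
        rows.append((gene, in_region, total, in_region / total))
    df = pd.DataFrame(rows, columns=["gene_id", "in_region", "total", "ratio"])
    df = df.sort_values(["in_region", "ratio", "gene_id"],
                        ascending=[False, False, True], kind="stable")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)
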
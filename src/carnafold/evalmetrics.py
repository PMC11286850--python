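"""Contact-map comparison metrics and TAD/loop landmark machinery.

Implements the evaluation suite used around the predictor: MSE, Pearson,
Spearman, the stratum-adjusted correlation coefficient (SCC), SSIM,
diamond-window insulation profiles, boundary strength/sharing classification,
loop-anchor sharing, and the cell-type-specific test-subset selection rules
(MSE > 0.3; SCC < 0.2; SSIM < 0.08).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage.metrics import structural_similarity

DIAG_OFFSET = 2  # entries closer to the diagonal than this are ignored
SSIM_DATA_RANGE = 4.0  # clip span of target maps, (-2, 2)

MSE_THRESHOLD = 0.3
SCC_THRESHOLD = 0.2
SSIM_THRESHOLD = 0.08
WEAK_RANGE = (0.2, 0.5)  # insulation strength: weak boundaries
STRONG_MIN = 0.5  # > 0.5 = strong
SHARED_MAX_DIST = 20_000  # boundary/anchor sharing rule (bp)
LOG2FC_STABLE = 1.0  # |log2 FC| <= 1 -> stable shared boundary


def _upper(a, offset=DIAG_OFFSET):
    a = np.asarray(a, dtype=float)
    iu = np.triu_indices_from(a, k=offset)
    return a[iu]


@dataclass
class MapScore:
    mse: float
    pearson: float | None
    spearman: float | None
    scc: float | None
    ssim: float | None


def scc(a, b, offset=DIAG_OFFSET, max_offset=None, weights="hicrep"):
    """Stratum-adjusted correlation: weighted sum of per-diagonal Pearsons.

    Strata are diagonal offsets; zero-variance strata are skipped.  With
    ``weights='hicrep'`` each stratum is weighted by its size times the
    geometric mean of its rank variances (variance-stabilized); ``'equal'``
    weights every retained stratum by its size only.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    n = a.shape[0]
    max_offset = max_offset or n - 1
    rs, ws = [], []
    for d in range(offset, max_offset + 1):
        xa = np.diagonal(a, d)
        xb = np.diagonal(b, d)
        good = np.isfinite(xa) & np.isfinite(xb)
        if good.sum() < 2:
            continue
        xa, xb = xa[good], xb[good]
        if xa.std() == 0 or xb.std() == 0:
            continue
        r = np.corrcoef(xa, xb)[0, 1]
        if weights == "equal":
            w = len(xa)
        else:
            ra = stats.rankdata(xa) / len(xa)
            rb = stats.rankdata(xb) / len(xb)
            w = len(xa) * np.sqrt(ra.var() * rb.var())
        rs.append(r)
        ws.append(w)
    if not ws or sum(ws) == 0:
        return None
    return float(np.dot(rs, ws) / np.sum(ws))


def score_maps(a, b, offset=DIAG_OFFSET) -> MapScore:
    """All five map-comparison metrics over the defined upper triangle.

    Constant maps make the correlation metrics undefined; they are reported
    as None rather than raising.
    """
    xa, xb = _upper(a, offset), _upper(b, offset)
    good = np.isfinite(xa) & np.isfinite(xb)
    xa, xb = xa[good], xb[good]
    mse = float(np.mean((xa - xb) ** 2))
    if xa.std() == 0 or xb.std() == 0:
        pear = spear = None
    else:
        pear = float(stats.pearsonr(xa, xb)[0])
        spear = float(stats.spearmanr(xa, xb)[0])
    s = scc(a, b, offset)
    am, bm = np.nan_to_num(np.asarray(a, float)), np.nan_to_num(np.asarray(b, float))
    try:
        ssim_val = float(structural_similarity(
            am, bm, win_size=7, gaussian_weights=True, sigma=1.5,
            use_sample_covariance=False, data_range=SSIM_DATA_RANGE))
    except ValueError:
        ssim_val = None
    return MapScore(mse=mse, pearson=pear, spearman=spear, scc=s, ssim=ssim_val)


# ---------------------------------------------------------------------------
# Insulation
# ---------------------------------------------------------------------------

def insulation_profile(matrix, diamond=10):
    """Diamond-window insulation score along the diagonal.

    ``score[i]`` is the mean of the ``diamond x diamond`` block of contacts
    between the ``diamond`` bins upstream and downstream of bin ``i``
    (``matrix[i-d..i-1, i+1..i+d]``).  Bins at the ends of the diagonal, where
    the full diamond does not fit, are NaN.
    """
    m = np.asarray(matrix, float)
    n = m.shape[0]
    if diamond < 1 or 2 * diamond >= n:
        raise ValueError("diamond must be >= 1 and smaller than half the map")
    out = np.full(n, np.nan)
    for i in range(diamond, n - diamond):
        block = m[i - diamond:i, i + 1:i + diamond + 1]
        out[i] = np.nanmean(block)
    return out


def insulation_strength(profile, i, flank=5):
    """Local insulation strength at bin i: flanking mean minus the dip."""
    lo, hi = max(i - flank, 0), min(i + flank + 1, len(profile))
    local = np.concatenate([profile[lo:i], profile[i + 1:hi]])
    local = local[np.isfinite(local)]
    if local.size == 0 or not np.isfinite(profile[i]):
        return np.nan
    return float(local.mean() - profile[i])


def insulation_correlation(observed_maps, predicted_maps, diamond=10):
    """Per-window Pearson correlation of observed vs predicted insulation."""
    out = []
    for o, p in zip(observed_maps, predicted_maps):
        po, pp = insulation_profile(o, diamond), insulation_profile(p, diamond)
        good = np.isfinite(po) & np.isfinite(pp)
        if good.sum() < 2 or po[good].std() == 0 or pp[good].std() == 0:
            out.append(np.nan)
        else:
            out.append(float(stats.pearsonr(po[good], pp[good])[0]))
    return np.array(out)


# ---------------------------------------------------------------------------
# Boundary / loop-anchor classification
# ---------------------------------------------------------------------------

def strength_class(strength, weak=WEAK_RANGE, strong_min=STRONG_MIN):
    if strength > strong_min:
        return "strong"
    if weak[0] < strength <= weak[1]:
        return "weak"
    return "below"


def _mutual_nearest(a: pd.DataFrame, b: pd.DataFrame, max_dist):
    """Mutual-nearest-neighbor matches within max_dist (per chromosome)."""
    matches = {}
    for chrom, sa in a.groupby("chrom"):
        sb = b[b["chrom"] == chrom]
        if sb.empty:
            continue
        pa = sa["pos"].to_numpy()
        pb = sb["pos"].to_numpy()
        ia = sa.index.to_numpy()
        ib = sb.index.to_numpy()
        near_b = np.abs(pa[:, None] - pb[None, :]).argmin(axis=1)
        near_a = np.abs(pb[:, None] - pa[None, :]).argmin(axis=1)
        for k, j in enumerate(near_b):
            if near_a[j] == k and abs(pa[k] - pb[j]) <= max_dist:
                matches[ia[k]] = ib[j]
    return matches


def classify_boundaries(calls_a: pd.DataFrame, calls_b: pd.DataFrame,
                        max_dist=SHARED_MAX_DIST, log2fc_stable=LOG2FC_STABLE
                        ) -> pd.DataFrame:
    """Classify cell-type-A boundaries by strength and sharing with B.

    Inputs have columns chrom/pos/strength.  A boundary is *shared* when a
    mutual nearest neighbor in B lies within 20 Kb, else *unique*.  Shared
    boundaries split on ``log2(strength_B / strength_A)``: within +/-1 ->
    stable; < -1 -> higher_in_A; > 1 -> higher_in_B.
    """
    a = calls_a.reset_index(drop=True)
    b = calls_b.reset_index(drop=True)
    match = _mutual_nearest(a, b, max_dist)
    rows = []
    for i, row in a.iterrows():
        cls = strength_class(row["strength"])
        if i in match:
            sb = b.loc[match[i], "strength"]
            fc = np.log2(sb / row["strength"])
            sub = ("stable" if abs(fc) <= log2fc_stable
                   else ("higher_in_B" if fc > log2fc_stable else "higher_in_A"))
            rows.append((row["chrom"], row["pos"], row["strength"], cls,
                         "shared", sub, fc))
        else:
            rows.append((row["chrom"], row["pos"], row["strength"], cls,
                         "unique", None, np.nan))
    return pd.DataFrame(rows, columns=["chrom", "pos", "strength",
                                       "strength_class", "sharing",
                                       "shared_subclass", "log2fc"])


def classify_loop_anchors(anchors_a: pd.DataFrame, anchors_b: pd.DataFrame,
                          max_dist=SHARED_MAX_DIST) -> pd.DataFrame:
    """Shared/unique loop anchors by the same 20-Kb mutual-nearest rule."""
    a = anchors_a.reset_index(drop=True)
    b = anchors_b.reset_index(drop=True)
    match = _mutual_nearest(a, b, max_dist)
    out = a.copy()
    out["sharing"] = ["shared" if i in match else "unique" for i in a.index]
    return out


# ---------------------------------------------------------------------------
# Cell-type-specific subsets
# ---------------------------------------------------------------------------

def window_compartment_labels(bed_path, windows: pd.DataFrame):
    """Majority A/B compartment label per window from a BED of labeled blocks.

    The BED carries chrom/start/end/label rows (label in the 4th column,
    e.g. from 25-Kb compartment calls); a window's label is the one covering
    most of its bases, or None when nothing overlaps.
    """
    bed = pd.read_csv(bed_path, sep="\t", header=None, usecols=[0, 1, 2, 3],
                      names=["chrom", "start", "end", "label"])
    labels = []
    for w in windows.itertuples(index=False):
        sub = bed[(bed["chrom"] == w.chrom) & (bed["start"] < w.end)
                  & (bed["end"] > w.start)]
        if sub.empty:
            labels.append(None)
            continue
        cover = {}
        for r in sub.itertuples(index=False):
            ov = min(r.end, w.end) - max(r.start, w.start)
            cover[r.label] = cover.get(r.label, 0) + ov
        labels.append(max(cover, key=cover.get))
    return labels


@dataclass
class SubsetSpec:
    mse_thr: float = MSE_THRESHOLD
    scc_thr: float = SCC_THRESHOLD
    ssim_thr: float = SSIM_THRESHOLD
    compartment_transition: str | None = None  # None, "A->B" or "B->A"


def select_celltype_specific(maps_a, maps_b, spec: SubsetSpec | None = None,
                             compartments=None):
    """Window subsets with divergent maps between two cell types.

    subset1 = windows with MSE > 0.3 between the experimental maps;
    subset2 = subset1 plus windows with SCC < 0.2 or SSIM < 0.08.
    With a compartment-transition filter, both subsets are intersected with
    windows whose labels (list of (label_a, label_b)) match the transition.
    """
    spec = spec or SubsetSpec()
    scores = [score_maps(a, b) for a, b in zip(maps_a, maps_b)]
    idx = np.arange(len(scores))
    subset1 = {i for i in idx if scores[i].mse > spec.mse_thr}
    subset2 = set(subset1)
    for i in idx:
        s = scores[i]
        if (s.scc is not None and s.scc < spec.scc_thr) or \
           (s.ssim is not None and s.ssim < spec.ssim_thr):
            subset2.add(i)
    if spec.compartment_transition is not None:
        if compartments is None:
            raise ValueError("compartment labels required for transition filter")
        src, dst = spec.compartment_transition.split("->")
        match = {i for i, (la, lb) in enumerate(compartments)
                 if la == src and lb == dst}
        subset1 &= match
        subset2 &= match
    return sorted(subset1), sorted(subset2), scores
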
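"""From DNA-DNA ``.pairs`` to per-window model targets.

The target preparation pipeline mirrors the standard Micro-C/Hi-C recipe:
2048-bp binning, iterative correction (ICE), adaptive coarse-graining of
low-coverage entries, per-window observed/expected normalization, natural log,
clipping to (-2, 2), linear interpolation of masked bins, and 2D Gaussian
smoothing.  Windows are ~1 Mb (2**20 bp, 512 bins at defaults).

Coordinates are 0-based half-open throughout; bin ``i`` covers
``[i * bin_size, (i + 1) * bin_size)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.ndimage import gaussian_filter

from . import pairs as pairsio

DEFAULT_BIN_SIZE = 2048  # 2**11 bp
DEFAULT_WINDOW_BP = 2**20  # ~1 Mb
CLIP_RANGE = (-2.0, 2.0)


# ---------------------------------------------------------------------------
# Bin grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BinGrid:
    """Tiling of a genome into fixed-size bins with a global bin index."""

    chromsizes: dict
    bin_size: int = DEFAULT_BIN_SIZE

    def __post_init__(self):
        offsets = {}
        total = 0
        for chrom, size in self.chromsizes.items():
            offsets[chrom] = total
            total += -(-size // self.bin_size)  # ceil division
        object.__setattr__(self, "_offsets", offsets)
        object.__setattr__(self, "_n_bins", total)

    @property
    def n_bins(self) -> int:
        return self._n_bins

    def chrom_n_bins(self, chrom) -> int:
        return -(-self.chromsizes[chrom] // self.bin_size)

    def bin_index(self, chrom, pos) -> int:
        """Global bin index of a 0-based position (half-open convention)."""
        return self._offsets[chrom] + int(pos) // self.bin_size

    def bin_start(self, index):
        for chrom, off in self._offsets.items():
            n = self.chrom_n_bins(chrom)
            if off <= index < off + n:
                return chrom, (index - off) * self.bin_size
        raise IndexError(index)

    def chrom_slice(self, chrom) -> slice:
        off = self._offsets[chrom]
        return slice(off, off + self.chrom_n_bins(chrom))


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------

@dataclass
class RawContactMatrix:
    """Upper-triangular sparse contact counts over a :class:`BinGrid`."""

    grid: BinGrid
    counts: sp.csr_matrix  # upper triangle, i <= j
    n_retained: int = 0
    n_skipped: int = 0

    def dense_symmetric(self) -> np.ndarray:
        m = self.counts.toarray().astype(float)
        return m + np.triu(m, 1).T

    def window_dense(self, chrom, start, window_bp) -> np.ndarray:
        i0 = self.grid.bin_index(chrom, start)
        n = window_bp // self.grid.bin_size
        sub = self.counts[i0 : i0 + n, i0 : i0 + n].toarray().astype(float)
        return sub + np.triu(sub, 1).T


def bin_contacts(pairs, grid: BinGrid) -> RawContactMatrix:
    """Bin DNA-DNA pair records into an upper-triangular count matrix.

    ``pairs`` is a path to a .pairs file or a DataFrame with 0-based
    ``chrom1/pos1/chrom2/pos2``.  Records on unknown chromosomes or with
    out-of-range / missing positions are skipped (counted, not fatal).
    """
    if not isinstance(pairs, pd.DataFrame):
        pairs, _ = pairsio.read_pairs(pairs)
    known = pairs["chrom1"].isin(grid.chromsizes) & pairs["chrom2"].isin(grid.chromsizes)
    pos_ok = (
        pairs["pos1"].notna()
        & pairs["pos2"].notna()
        & (pairs["pos1"] >= 0)
        & (pairs["pos2"] >= 0)
    )
    sizes1 = pairs["chrom1"].map(grid.chromsizes)
    sizes2 = pairs["chrom2"].map(grid.chromsizes)
    in_range = pos_ok & (pairs["pos1"] < sizes1.fillna(0)) & (pairs["pos2"] < sizes2.fillna(0))
    ok = known & in_range
    kept = pairs[ok]
    i = np.array([grid.bin_index(c, p) for c, p in zip(kept["chrom1"], kept["pos1"])], dtype=int)
    j = np.array([grid.bin_index(c, p) for c, p in zip(kept["chrom2"], kept["pos2"])], dtype=int)
    lo, hi = np.minimum(i, j), np.maximum(i, j)
    n = grid.n_bins
    mat = sp.coo_matrix((np.ones(len(lo)), (lo, hi)), shape=(n, n)).tocsr()
    return RawContactMatrix(grid, mat, n_retained=len(kept), n_skipped=int((~ok).sum()))


# ---------------------------------------------------------------------------
# ICE balancing
# ---------------------------------------------------------------------------

def ice_normalize(matrix, max_iter=200, tol=1e-5, mad_max=5.0, min_nnz=2):
    """Iterative correction of a symmetric contact matrix.

    Low-coverage bins (marginal deviating from the median log coverage by more
    than ``mad_max`` MADs, or with fewer than ``min_nnz`` nonzero entries) are
    masked before balancing.  Weights are scaled so that unmasked rows of the
    balanced matrix sum to 1; for an already doubly-stochastic matrix the
    weights are therefore all 1.

    Returns ``(balanced, weights, converged)``; masked bins have NaN weight and
    NaN rows/columns in ``balanced``.
    """
    m = np.asarray(matrix, dtype=float)
    if not np.allclose(m, m.T):
        raise ValueError("ICE requires a symmetric matrix")
    n = m.shape[0]
    marg = m.sum(axis=1)
    nnz = (m > 0).sum(axis=1)
    mask = (marg > 0) & (nnz >= min_nnz)
    if mask.any():
        logm = np.log(marg[mask])
        med = np.median(logm)
        mad = np.median(np.abs(logm - med)) or 1.0
        dev = np.full(n, np.inf)
        dev[mask] = np.abs(np.log(marg[mask]) - med) / (1.4826 * mad)
        mask &= dev <= mad_max
    w = np.ones(n)
    work = m.copy()
    work[~mask, :] = 0.0
    work[:, ~mask] = 0.0
    converged = False
    for _ in range(max_iter):
        s = work.sum(axis=1)
        s_nz = s[mask]
        if s_nz.size == 0:
            break
        target = s_nz.mean()
        adj = np.ones(n)
        adj[mask] = s_nz / target
        work = work / np.outer(adj, adj)
        w = w / adj
        if np.abs(s_nz / target - 1.0).max() < tol:
            converged = True
            break
    # rescale so unmasked rows sum to exactly 1
    s = work[np.ix_(mask, mask)].sum(axis=1)
    if s.size and s.mean() > 0:
        scale = 1.0 / np.sqrt(s.mean())
        w = w * scale
        work = work * scale**2
    balanced = np.full_like(m, np.nan)
    balanced[np.ix_(mask, mask)] = work[np.ix_(mask, mask)]
    weights = np.where(mask, w, np.nan)
    return balanced, weights, converged


# ---------------------------------------------------------------------------
# Adaptive coarse-graining (dyadic neighborhood averaging)
# ---------------------------------------------------------------------------

def coarsegrain_smooth(balanced, raw, min_count=8, max_level=None):
    """Replace low-support entries by progressively coarser dyadic block means.

    An entry whose raw count support is below ``min_count`` is replaced by the
    mean balanced value of the smallest aligned dyadic block (2x2, 4x4, ...)
    containing it whose summed raw support reaches ``min_count``.  Entries with
    sufficient support are returned unchanged; entries with no coverage at any
    scale stay NaN.
    """
    balanced = np.asarray(balanced, dtype=float)
    raw = np.asarray(raw, dtype=float)
    n = balanced.shape[0]
    if max_level is None:
        max_level = max(1, int(np.ceil(np.log2(n))))
    out = balanced.copy()
    need = ~(raw >= min_count)  # includes NaN balanced entries
    level = 1
    while need.any() and level <= max_level:
        s = 2**level
        nb = -(-n // s)
        pad = nb * s - n
        rawp = np.pad(raw, ((0, pad), (0, pad)))
        balp = np.pad(balanced, ((0, pad), (0, pad)), constant_values=np.nan)
        raw_blocks = rawp.reshape(nb, s, nb, s).sum(axis=(1, 3))
        import warnings as _w
        with np.errstate(invalid="ignore"), _w.catch_warnings():
            _w.simplefilter("ignore", RuntimeWarning)  # all-NaN blocks stay NaN
            bal_blocks = np.nanmean(balp.reshape(nb, s, nb, s), axis=(1, 3))
        enough = raw_blocks >= min_count
        fill_val = np.repeat(np.repeat(bal_blocks, s, axis=0), s, axis=1)[:n, :n]
        fill_ok = np.repeat(np.repeat(enough, s, axis=0), s, axis=1)[:n, :n]
        fill_ok &= np.isfinite(fill_val)
        sel = need & fill_ok
        out[sel] = fill_val[sel]
        need &= ~fill_ok
        level += 1
    return out


# ---------------------------------------------------------------------------
# Observed / expected, target finalization
# ---------------------------------------------------------------------------

def observed_over_expected(balanced):
    """Divide each entry by the mean value at its diagonal offset.

    Expected values are computed per window (over unmasked entries of each
    diagonal of this matrix).  Offsets whose expected value is 0 or undefined
    come back masked (NaN).
    """
    m = np.asarray(balanced, dtype=float)
    n = m.shape[0]
    out = np.full_like(m, np.nan)
    idx = np.arange(n)
    offsets = np.abs(idx[:, None] - idx[None, :])
    for d in range(n):
        sel = offsets == d
        vals = m[sel]
        finite = np.isfinite(vals)
        if not finite.any():
            continue
        exp = vals[finite].mean()
        if exp <= 0:
            continue
        out[sel] = m[sel] / exp
    return out


def _interpolate_nan(mat):
    """Fill NaNs by 1D linear interpolation along rows and columns, averaged."""

    def interp_rows(m):
        out = m.copy()
        x = np.arange(m.shape[1])
        for i in range(m.shape[0]):
            row = m[i]
            good = np.isfinite(row)
            if good.sum() == 0:
                continue
            if good.all():
                continue
            out[i, ~good] = np.interp(x[~good], x[good], row[good])
        return out

    by_row = interp_rows(mat)
    by_col = interp_rows(mat.T).T
    with np.errstate(invalid="ignore"):
        filled = np.nanmean(np.stack([by_row, by_col]), axis=0)
    return filled


@dataclass
class TargetMap:
    """Final per-window training target: smoothed, clipped log(obs/exp)."""

    matrix: np.ndarray
    interp_mask: np.ndarray
    chrom: str | None = None
    start: int | None = None

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]


def finalize_target(oe, clip=CLIP_RANGE, gaussian_sigma=1.0, truncate=2.0,
                    chrom=None, start=None) -> TargetMap:
    """log -> clip -> interpolate masked bins -> Gaussian smooth -> re-clip.

    The clip is applied once before interpolation and once after smoothing so
    the output invariant (symmetric, finite, within the clip range) always
    holds; smoothing of clipped values can only move them inward, so the final
    clip is a guard, not a distortion.
    """
    oe = np.asarray(oe, dtype=float)
    if not np.isfinite(oe).any():
        raise ValueError("unusable window: fully masked")
    with np.errstate(divide="ignore", invalid="ignore"):
        logm = np.log(oe)
    logm[~np.isfinite(logm)] = np.nan
    interp_mask = ~np.isfinite(logm)
    clipped = np.clip(logm, *clip)
    filled = _interpolate_nan(clipped)
    filled = np.where(np.isfinite(filled), filled, 0.0)
    filled = 0.5 * (filled + filled.T)
    smoothed = gaussian_filter(filled, sigma=gaussian_sigma, truncate=truncate)
    final = np.clip(0.5 * (smoothed + smoothed.T), *clip)
    return TargetMap(final, interp_mask, chrom=chrom, start=start)


# ---------------------------------------------------------------------------
# Window partitioning
# ---------------------------------------------------------------------------

def crop_target(target: TargetMap, margin_bins: int,
                bin_size=DEFAULT_BIN_SIZE) -> TargetMap:
    """Optionally crop a symmetric margin off a target map.

    Full windows are predicted by default; cropping (e.g. 512 -> 448 bins)
    discards the edge bins whose context extends outside the window.
    """
    if margin_bins == 0:
        return target
    n = target.n_bins
    if not 0 < 2 * margin_bins < n:
        raise ValueError("margin must leave a nonempty center")
    sl = slice(margin_bins, n - margin_bins)
    return TargetMap(target.matrix[sl, sl].copy(), target.interp_mask[sl, sl].copy(),
                     chrom=target.chrom,
                     start=None if target.start is None
                     else target.start + margin_bins * bin_size)


@dataclass
class WindowSet:
    windows: pd.DataFrame = field(default_factory=pd.DataFrame)  # chrom,start,end,split

    def subset(self, split):
        return self.windows[self.windows["split"] == split].reset_index(drop=True)

    def __len__(self):
        return len(self.windows)


def partition_windows(grid: BinGrid, window_bp=DEFAULT_WINDOW_BP, stride=None,
                      split_fractions=(0.8, 0.1, 0.1), seed=0,
                      explicit=None) -> WindowSet:
    """Tile chromosomes with fixed windows and assign train/valid/test labels.

    ``explicit`` (DataFrame or path to TSV with chrom/start/end/split) overrides
    the fraction-based assignment so a published split can be loaded verbatim.
    Windows running past a chromosome end are dropped.
    """
    if explicit is not None:
        if not isinstance(explicit, pd.DataFrame):
            explicit = pd.read_csv(explicit, sep="\t")
        req = {"chrom", "start", "end", "split"}
        if not req.issubset(explicit.columns):
            raise ValueError(f"explicit split needs columns {sorted(req)}")
        return WindowSet(explicit.reset_index(drop=True))
    stride = stride or window_bp
    rows = []
    for chrom, size in grid.chromsizes.items():
        for start in range(0, size - window_bp + 1, stride):
            rows.append((chrom, start, start + window_bp))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    rng = np.random.default_rng(seed)
    labels = np.array(["train"] * len(df), dtype=object)
    order = rng.permutation(len(df))
    n_valid = int(round(split_fractions[1] * len(df)))
    n_test = int(round(split_fractions[2] * len(df)))
    labels[order[:n_valid]] = "valid"
    labels[order[n_valid : n_valid + n_test]] = "test"
    df["split"] = labels
    return WindowSet(df)


# ---------------------------------------------------------------------------
# Pipeline + archive
# ---------------------------------------------------------------------------

def prepare_targets(pairs_path, grid: BinGrid, windows: pd.DataFrame,
                    min_count=8, gaussian_sigma=1.0, ice=True):
    """Full target pipeline for every window; returns a list of TargetMaps."""
    raw = bin_contacts(pairs_path, grid)
    maps = []
    for _, w in windows.iterrows():
        sub_raw = raw.window_dense(w["chrom"], int(w["start"]), int(w["end"] - w["start"]))
        if ice:
            balanced, _, _ = ice_normalize(sub_raw)
        else:
            balanced = sub_raw.astype(float)
        cg = coarsegrain_smooth(balanced, sub_raw, min_count=min_count)
        oe = observed_over_expected(cg)
        maps.append(finalize_target(oe, gaussian_sigma=gaussian_sigma,
                                    chrom=w["chrom"], start=int(w["start"])))
    return maps


def save_target_archive(path, maps, windows):
    arrays = {f"map_{i}": t.matrix for i, t in enumerate(maps)}
    arrays.update({f"mask_{i}": t.interp_mask for i, t in enumerate(maps)})
    meta = windows[["chrom", "start", "end", "split"]].to_dict(orient="list") \
        if "split" in windows else windows.to_dict(orient="list")
    np.savez_compressed(path, _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                        **arrays)
    return Path(path)


def load_target_archive(path):
    data = np.load(path)
    meta = json.loads(bytes(data["_meta"]).decode())
    windows = pd.DataFrame(meta)
    n = len(windows)
    maps = [TargetMap(data[f"map_{i}"], data[f"mask_{i}"],
                      chrom=windows["chrom"][i], start=int(windows["start"][i]))
            for i in range(n)]
    return maps, windows
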
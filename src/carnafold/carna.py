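"""caRNA feature engineering from RNA-DNA (iMARGI-style) ``.pairs`` data.

Converts RNA-end/DNA-end contact records into the model's feature channels:

* nascent transcription — RNA-end coverage per bin;
* trans-located caRNA — DNA-end coverage per bin, split into eight RNA
  groups, after removing contacts within 2**20 bp of the transcription locus
  (and self-interactions of genes longer than 2**20 bp);
* ATAC-seq / RNA-seq — external bedGraph signal, library-size normalized.

All model-facing channels are natural-log transformed (log1p, so zero counts
stay zero).  Per-gene trans-located proportions are computed with host-gene
subtraction for nested genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from . import pairs as pairsio
from .mapsio import BinGrid

MIN_MAPQ_EXCLUSIVE = 30  # records with MAPQ <= 30 are dropped
TRANS_MIN_DIST = 2**20

#: the eight RNA groups, in channel order
RNA_GROUPS = [
    "snRNA", "snoRNA", "other_small_RNA", "lncRNA", "misc_RNA",
    "protein_coding", "other_gene", "unannotated",
]

#: biotype -> group mapping (config-exposed; "other small RNAs" covers the
#: small ncRNA biotypes that are neither snRNA nor snoRNA)
DEFAULT_BIOTYPE_MAP = {
    "snRNA": "snRNA",
    "snoRNA": "snoRNA",
    "miRNA": "other_small_RNA",
    "scaRNA": "other_small_RNA",
    "sRNA": "other_small_RNA",
    "vault_RNA": "other_small_RNA",
    "ribozyme": "other_small_RNA",
    "lncRNA": "lncRNA",
    "misc_RNA": "misc_RNA",
    "protein_coding": "protein_coding",
}

#: priority when one position overlaps several genes: small RNAs beat hosts
GROUP_PRIORITY = [
    "snRNA", "snoRNA", "other_small_RNA", "misc_RNA", "lncRNA",
    "protein_coding", "other_gene",
]


def biotype_to_group(biotype, biotype_map=None) -> str:
    table = DEFAULT_BIOTYPE_MAP if biotype_map is None else biotype_map
    return table.get(biotype, "other_gene")


# ---------------------------------------------------------------------------
# Contacts
# ---------------------------------------------------------------------------

@dataclass
class RnaDnaContacts:
    """Filtered RNA-end/DNA-end records plus provenance counters."""

    records: pd.DataFrame  # rna_chrom, rna_pos, rna_strand, dna_chrom, dna_pos, dna_strand, mapq
    n_parsed: int = 0
    n_dropped_mapq: int = 0
    n_dropped_malformed: int = 0

    def __len__(self):
        return len(self.records)


_RENAME = {"chrom1": "rna_chrom", "pos1": "rna_pos", "strand1": "rna_strand",
           "chrom2": "dna_chrom", "pos2": "dna_pos", "strand2": "dna_strand"}


def parse_rna_dna_pairs(path, min_mapq_exclusive=MIN_MAPQ_EXCLUSIVE) -> RnaDnaContacts:
    """Parse an iMARGI .pairs file (RNA end first) and apply the MAPQ filter.

    Records whose MAPQ (either end) is <= ``min_mapq_exclusive`` are dropped
    and counted; a record with MAPQ 31 is the first one retained.
    """
    df, _ = pairsio.read_pairs(path)
    required = {"chrom1", "pos1", "chrom2", "pos2"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing required pairs columns {sorted(required)}")
    n_parsed = len(df)
    malformed = df["pos1"].isna() | df["pos2"].isna()
    df = df[~malformed]
    if "mapq1" in df.columns or "mapq2" in df.columns:
        mq = df[[c for c in ("mapq1", "mapq2") if c in df.columns]].min(axis=1)
    else:
        mq = pd.Series(np.inf, index=df.index)
    keep = mq > min_mapq_exclusive
    out = df[keep].rename(columns=_RENAME).copy()
    out["mapq"] = mq[keep].to_numpy()
    keep_cols = ["rna_chrom", "rna_pos", "rna_strand", "dna_chrom", "dna_pos",
                 "dna_strand", "mapq"]
    out = out[[c for c in keep_cols if c in out.columns]].reset_index(drop=True)
    return RnaDnaContacts(out, n_parsed=n_parsed,
                          n_dropped_mapq=int((~keep).sum()),
                          n_dropped_malformed=int(malformed.sum()))


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """Gene intervals with biotype groups and host/nested bookkeeping."""

    table: pd.DataFrame  # gene_id, chrom, start, end, strand, group, host
    _trees: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        for chrom, sub in self.table.groupby("chrom"):
            tree = IntervalTree()
            for _, g in sub.iterrows():
                tree[int(g["start"]):int(g["end"])] = g
            self._trees[chrom] = tree

    @classmethod
    def from_gtf(cls, path, biotype_map=None):
        import gffutils

        db = gffutils.create_db(str(path), ":memory:", force=True,
                                keep_order=True, disable_infer_genes=True,
                                disable_infer_transcripts=True,
                                id_spec={"gene": "gene_id"})
        rows = []
        for g in db.features_of_type("gene"):
            biotype = (g.attributes.get("gene_type")
                       or g.attributes.get("gene_biotype") or [""])[0]
            host = (g.attributes.get("host_gene") or [""])[0]
            rows.append((g.id, g.seqid, g.start - 1, g.end, g.strand,
                         biotype_to_group(biotype, biotype_map), host))
        return cls(pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                               "strand", "group", "host"]))

    @classmethod
    def from_table(cls, df, biotype_map=None):
        t = df.copy()
        if "group" not in t.columns:
            t["group"] = [biotype_to_group(b, biotype_map) for b in t["biotype"]]
        if "host" not in t.columns:
            t["host"] = ""
        return cls(t[["gene_id", "chrom", "start", "end", "strand", "group", "host"]])

    def overlapping(self, chrom, pos):
        tree = self._trees.get(chrom)
        return [iv.data for iv in tree[int(pos)]] if tree is not None else []

    def long_genes(self, min_len=TRANS_MIN_DIST):
        t = self.table
        return t[(t["end"] - t["start"]) > min_len]


def classify_rna_group(chrom, pos, genes: GeneModel, priority=None) -> str:
    """Group label of an RNA-end position (total function; intergenic ->
    ``unannotated``; overlaps resolved by the small-RNA-first priority)."""
    hits = genes.overlapping(chrom, pos)
    if not hits:
        return "unannotated"
    order = priority or GROUP_PRIORITY
    rank = {g: i for i, g in enumerate(order)}
    return min((h["group"] for h in hits), key=lambda g: rank.get(g, len(order)))


def assign_gene(chrom, pos, genes: GeneModel, priority=None):
    """Owning gene of a position: the highest-priority (smallest) overlapping
    gene, so reads in a nested small RNA are attributed to it, not the host."""
    hits = genes.overlapping(chrom, pos)
    if not hits:
        return None
    order = priority or GROUP_PRIORITY
    rank = {g: i for i, g in enumerate(order)}
    return min(hits, key=lambda h: (rank.get(h["group"], len(order)),
                                    h["end"] - h["start"]))["gene_id"]


# ---------------------------------------------------------------------------
# Tracks
# ---------------------------------------------------------------------------

def _bin_counts(chroms, positions, grid: BinGrid, resolution=None):
    res = resolution or grid.bin_size
    tmp_grid = grid if res == grid.bin_size else BinGrid(grid.chromsizes, res)
    counts = np.zeros(tmp_grid.n_bins)
    for chrom, pos in zip(chroms, positions):
        if chrom in tmp_grid.chromsizes and 0 <= pos < tmp_grid.chromsizes[chrom]:
            counts[tmp_grid.bin_index(chrom, pos)] += 1
    return counts, tmp_grid


def nascent_track(contacts: RnaDnaContacts, grid: BinGrid, resolution=None):
    """RNA-end read counts per bin (nascent transcription proxy)."""
    counts, _ = _bin_counts(contacts.records["rna_chrom"],
                            contacts.records["rna_pos"], grid, resolution)
    return counts


def trans_filter(contacts: RnaDnaContacts, genes: GeneModel | None = None,
                 min_dist=TRANS_MIN_DIST) -> RnaDnaContacts:
    """Keep trans contacts: different chromosomes, or linear distance > 2**20.

    Self-interactions of genes longer than 2**20 bp (both ends inside the same
    long gene) are removed as well.  Idempotent.
    """
    r = contacts.records
    same = r["rna_chrom"] == r["dna_chrom"]
    far = np.abs(r["rna_pos"] - r["dna_pos"]) > min_dist
    keep = (~same) | far
    if genes is not None:
        for _, g in genes.long_genes(min_dist).iterrows():
            inside = (
                same
                & (r["rna_chrom"] == g["chrom"])
                & (r["rna_pos"] >= g["start"]) & (r["rna_pos"] < g["end"])
                & (r["dna_pos"] >= g["start"]) & (r["dna_pos"] < g["end"])
            )
            keep &= ~inside
    return RnaDnaContacts(r[keep].reset_index(drop=True), n_parsed=contacts.n_parsed,
                          n_dropped_mapq=contacts.n_dropped_mapq,
                          n_dropped_malformed=contacts.n_dropped_malformed)


def group_tracks(trans_contacts: RnaDnaContacts, genes: GeneModel, grid: BinGrid,
                 log=False):
    """Per-group DNA-end count tracks for trans-located caRNAs.

    Returns ``{group: counts}`` over the grid.  Raw counts conserve the total
    record number across the eight groups; with ``log=True`` the tracks are
    log1p-transformed (the model-input scale).
    """
    r = trans_contacts.records
    tracks = {g: np.zeros(grid.n_bins) for g in RNA_GROUPS}
    for rna_chrom, rna_pos, dna_chrom, dna_pos in zip(
            r["rna_chrom"], r["rna_pos"], r["dna_chrom"], r["dna_pos"]):
        group = classify_rna_group(rna_chrom, rna_pos, genes)
        if dna_chrom in grid.chromsizes and 0 <= dna_pos < grid.chromsizes[dna_chrom]:
            tracks[group][grid.bin_index(dna_chrom, dna_pos)] += 1
    if log:
        tracks = {g: np.log1p(t) for g, t in tracks.items()}
    return tracks


def read_bedgraph(path, grid: BinGrid):
    """Average bedGraph signal per grid bin (missing coverage -> 0)."""
    sig = np.zeros(grid.n_bins)
    cov = np.zeros(grid.n_bins)
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"],
                     dtype={"chrom": str})
    for row in df.itertuples(index=False):
        if row.chrom not in grid.chromsizes:
            continue
        b0 = grid.bin_index(row.chrom, row.start)
        b1 = grid.bin_index(row.chrom, min(row.end - 1, grid.chromsizes[row.chrom] - 1))
        for b in range(b0, b1 + 1):
            bin_start = (b - grid.bin_index(row.chrom, 0)) * grid.bin_size
            lo = max(row.start, bin_start)
            hi = min(row.end, bin_start + grid.bin_size)
            frac = max(hi - lo, 0)
            sig[b] += row.value * frac
            cov[b] += frac
    with np.errstate(invalid="ignore"):
        out = np.where(cov > 0, sig / np.maximum(cov, 1), 0.0)
    return out


def external_signal_features(track, grid: BinGrid, libsize):
    """Library-size-normalized log signal per bin.

    ``track`` is a per-bin array or a bedGraph path; signal is scaled by
    ``libsize / total`` (so features are comparable to iMARGI count channels)
    then log1p-transformed.
    """
    if not isinstance(track, np.ndarray):
        track = read_bedgraph(track, grid)
    total = track.sum()
    scaled = track * (libsize / total) if total > 0 else track
    return np.log1p(scaled)


# ---------------------------------------------------------------------------
# Trans-located proportions
# ---------------------------------------------------------------------------

@dataclass
class TransProportion:
    gene_id: str
    nascent_reads: int
    trans_reads: int
    proportion: float | None  # None when nascent == 0 (undefined, not 0)


def trans_proportion(contacts: RnaDnaContacts, genes: GeneModel,
                     min_dist=TRANS_MIN_DIST) -> pd.DataFrame:
    """Per-gene trans-located proportion = trans reads / nascent reads.

    Reads are attributed to the smallest (highest-priority) overlapping gene,
    which implements host-gene subtraction: reads in a nested snoRNA count for
    the snoRNA, not its host.  The trans numerator applies the same distance
    and long-gene filters as :func:`trans_filter`.
    """
    r = contacts.records
    owner = [assign_gene(c, p, genes) for c, p in zip(r["rna_chrom"], r["rna_pos"])]
    trans_c = trans_filter(contacts, genes, min_dist)
    rt = trans_c.records
    owner_t = [assign_gene(c, p, genes) for c, p in zip(rt["rna_chrom"], rt["rna_pos"])]
    nascent = pd.Series(owner).value_counts()
    trans = pd.Series(owner_t).value_counts()
    rows = []
    for gid in genes.table["gene_id"]:
        n = int(nascent.get(gid, 0))
        t = int(trans.get(gid, 0))
        rows.append((gid, n, t, (t / n) if n > 0 else None))
    return pd.DataFrame(rows, columns=["gene_id", "nascent_reads", "trans_reads",
                                       "proportion"])


# ---------------------------------------------------------------------------
# Signal matrices (computeMatrix-style) & feature assembly
# ---------------------------------------------------------------------------

def signal_matrix(track: np.ndarray, grid: BinGrid, regions: pd.DataFrame,
                  flank: int, resolution: int):
    """regions x positions matrix of mean signal around region centers.

    Reference-point mode: columns cover center +/- flank at ``resolution`` bp;
    stranded regions ('-') are flipped.  Positions outside the chromosome are
    NaN.  ``track`` is a per-grid-bin array.
    """
    n_cols = (2 * flank) // resolution
    out = np.full((len(regions), n_cols), np.nan)
    for i, row in enumerate(regions.itertuples(index=False)):
        center = (int(row.start) + int(row.end)) // 2
        size = grid.chromsizes.get(row.chrom)
        if size is None:
            continue
        for c in range(n_cols):
            lo = center - flank + c * resolution
            hi = lo + resolution
            if lo < 0 or hi > size:
                continue
            b0, b1 = grid.bin_index(row.chrom, lo), grid.bin_index(row.chrom, hi - 1)
            off = grid.bin_index(row.chrom, 0)
            vals = []
            for b in range(b0, b1 + 1):
                s = (b - off) * grid.bin_size
                overlap = min(hi, s + grid.bin_size) - max(lo, s)
                vals.append((track[b], overlap))
            tot = sum(w for _, w in vals)
            out[i, c] = sum(v * w for v, w in vals) / tot if tot else np.nan
        if getattr(row, "strand", "+") == "-":
            out[i] = out[i, ::-1]
    return out


@dataclass
class FeatureMatrix:
    """Per-window bins x channels model input (natural-log scale)."""

    chrom: str
    start: int
    matrix: np.ndarray  # (n_bins, n_channels)
    channels: list

    @property
    def n_bins(self):
        return self.matrix.shape[0]


#: feature channels per model variant
VARIANT_CHANNELS = {
    "seq": [],
    "nascent": ["nascent"],
    "trans": list(RNA_GROUPS),
    "rnaseq": ["rnaseq"],
    "atac": ["atac"],
    "atac+trans": ["atac"] + list(RNA_GROUPS),
    "random": ["random"],
}


def build_feature_matrices(variant, grid: BinGrid, windows: pd.DataFrame,
                           contacts=None, genes=None, atac=None, rnaseq=None,
                           libsize=None, seed=0, n_random_channels=8):
    """Assemble per-window FeatureMatrix objects for a model variant.

    ``contacts`` is the MAPQ-filtered RnaDnaContacts (trans filtering is done
    here for the trans channels); ``atac``/``rnaseq`` are per-bin arrays or
    bedGraph paths.  The ``random`` variant draws standard-normal channels
    from ``seed``.
    """
    nb = None
    tracks = {}
    if variant in ("nascent",):
        tracks["nascent"] = np.log1p(nascent_track(contacts, grid))
    if variant in ("trans", "atac+trans"):
        tc = trans_filter(contacts, genes)
        gt = group_tracks(tc, genes, grid, log=True)
        tracks.update(gt)
    if variant in ("atac", "atac+trans"):
        lib = libsize if libsize is not None else len(contacts)
        tracks["atac"] = external_signal_features(atac, grid, lib)
    if variant == "rnaseq":
        lib = libsize if libsize is not None else len(contacts)
        tracks["rnaseq"] = external_signal_features(rnaseq, grid, lib)
    rng = np.random.default_rng(seed)
    out = []
    for w in windows.itertuples(index=False):
        b0 = grid.bin_index(w.chrom, w.start)
        nb = (w.end - w.start) // grid.bin_size
        if variant == "random":
            mat = rng.standard_normal((nb, n_random_channels))
            names = [f"random{i}" for i in range(n_random_channels)]
        elif variant == "seq":
            mat = np.zeros((nb, 0))
            names = []
        else:
            names = VARIANT_CHANNELS[variant]
            mat = np.stack([tracks[c][b0:b0 + nb] for c in names], axis=1)
        out.append(FeatureMatrix(w.chrom, int(w.start), mat, names))
    return out
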
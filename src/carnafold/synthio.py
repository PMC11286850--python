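"""Synthetic genomes, annotations, contacts and signal tracks.

This module fabricates a miniature genome with *planted, recoverable*
structure so the whole pipeline — target-map preparation, caRNA feature
engineering, model training, attribution and the perturbation experiments —
can be exercised end to end without any downloads:

* a random-sequence genome with TAD boundaries planted at known bins, each
  with a known insulation strength (optionally marked by convergent CTCF
  motif clusters whose size encodes the strength);
* genes of the eight RNA biotype groups, including a snoRNA nested inside a
  protein-coding host;
* DNA-DNA contacts drawn from a distance-decaying model attenuated across
  planted boundaries and boosted at planted loops;
* RNA-DNA contacts with a controllable cis/trans mix, per-gene expression,
  a MAPQ mixture that exercises the MAPQ filter, and optional planted
  RNA<->DNA sequence homologies for the R-loop scan;
* ATAC-like and RNA-seq-like bedGraph tracks elevated at open bins.

Every generator is deterministic given its seed.  Truth tables are emitted as
TSV side files; they are test fixtures, not part of the public API.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import pairs as pairsio
from .mapsio import BinGrid, DEFAULT_BIN_SIZE, finalize_target, observed_over_expected

# 19-bp CTCF consensus (JASPAR core motif); used to mark planted boundaries.
CTCF_CONSENSUS = "TGGCCACCAGGGGGCGCTA"
_COMP = str.maketrans("ACGTN", "TGCAN")

#: biotypes emitted by make_genome, one per RNA group (plus the implicit
#: "unannotated" group covering intergenic space)
BIOTYPE_MENU = [
    "snRNA", "snoRNA", "miRNA", "lncRNA", "misc_RNA",
    "protein_coding", "pseudogene",
]

_GENE_LENGTHS = {
    "snRNA": 160, "snoRNA": 120, "miRNA": 80, "lncRNA": 4000,
    "misc_RNA": 300, "protein_coding": 16000, "pseudogene": 1500,
}
_GENE_EXPRESSION = {
    "snRNA": 8.0, "snoRNA": 6.0, "miRNA": 2.0, "lncRNA": 4.0,
    "misc_RNA": 1.5, "protein_coding": 3.0, "pseudogene": 0.5,
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass
class SyntheticGenomeSpec:
    n_chroms: int = 2
    chrom_length: int = 2**20
    gc_content: float = 0.41
    bin_size: int = DEFAULT_BIN_SIZE
    seed: int = 0
    motif_boundaries: bool = False  # mark boundaries with CTCF motif clusters

    def __post_init__(self):
        if self.chrom_length % self.bin_size:
            raise ValueError(
                f"chrom_length {self.chrom_length} is not a multiple of "
                f"bin_size {self.bin_size}"
            )

    @property
    def chromsizes(self) -> dict:
        return {f"chr{i + 1}": self.chrom_length for i in range(self.n_chroms)}


@dataclass
class PlantedStructure:
    """Ground-truth chromatin architecture for a synthetic genome."""

    tad_boundaries: list = field(default_factory=list)  # (chrom, pos, strength)
    loops: list = field(default_factory=list)  # ((chrom, posA), (chrom, posB), intensity)
    decay_exponent: float = 1.0
    attenuation: float = 3.0  # contact odds across a boundary ~ exp(-attenuation*strength)

    def boundaries_on(self, chrom):
        return [(p, s) for c, p, s in self.tad_boundaries if c == chrom]


@dataclass
class SyntheticContactSpec:
    n_reads: int = 100_000
    cis_fraction: float = 0.6
    trans_target_bias: float = 4.0  # weight multiplier for open bins as trans targets
    cis_scale: float = 50_000.0  # exponential scale of cis RNA-DNA distances (bp)
    mapq_low_fraction: float = 0.15  # fraction of reads failing the MAPQ<=30 filter
    min_trans_dist: int = 2**20

    def __post_init__(self):
        if not 0 <= self.cis_fraction <= 1:
            raise ValueError("cis_fraction must be in [0,1]")


@dataclass
class PlantedHomology:
    """A copied (mutated) RNA subsequence at a distant DNA locus."""

    rna_gene: str
    dna_chrom: str
    dna_pos: int
    length: int = 60
    identity: float = 0.90
    max_perfect_run: int = 15
    n_reads: int = 20


def default_structure(spec: SyntheticGenomeSpec, boundaries_per_chrom=3,
                      strengths=None, loops_per_chrom=1, seed=None) -> PlantedStructure:
    """Plant bin-aligned boundaries (and loops) at reproducible positions."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    strengths = list(strengths) if strengths is not None else [0.4, 0.7, 1.0]
    tads, loops = [], []
    for chrom in spec.chromsizes:
        n_bins = spec.chrom_length // spec.bin_size
        # keep boundaries away from chromosome ends and from each other
        lo, hi = int(0.15 * n_bins), int(0.85 * n_bins)
        pos_bins = np.sort(rng.choice(np.arange(lo, hi), size=boundaries_per_chrom,
                                      replace=False))
        while np.diff(pos_bins).size and np.diff(pos_bins).min() < 8:
            pos_bins = np.sort(rng.choice(np.arange(lo, hi), size=boundaries_per_chrom,
                                          replace=False))
        for i, b in enumerate(pos_bins):
            s = strengths[i % len(strengths)]
            tads.append((chrom, int(b) * spec.bin_size, float(s)))
        for _ in range(loops_per_chrom):
            a = int(rng.integers(lo, hi - 20)) * spec.bin_size
            b = a + int(rng.integers(10, 20)) * spec.bin_size
            loops.append(((chrom, a), (chrom, b), 3.0))
    return PlantedStructure(tad_boundaries=tads, loops=loops)


# ---------------------------------------------------------------------------
# Genome + annotations
# ---------------------------------------------------------------------------

@dataclass
class SyntheticGenome:
    spec: SyntheticGenomeSpec
    structure: PlantedStructure
    sequences: dict  # chrom -> str
    genes: pd.DataFrame  # gene_id, chrom, start, end, strand, biotype, expression, host
    open_bins: dict  # chrom -> sorted array of open bin indices (chrom-local)

    @property
    def chromsizes(self):
        return {c: len(s) for c, s in self.sequences.items()}

    def grid(self) -> BinGrid:
        return BinGrid(self.chromsizes, self.spec.bin_size)

    def gene_seq(self, gene_id) -> str:
        g = self.genes.set_index("gene_id").loc[gene_id]
        seq = self.sequences[g["chrom"]][int(g["start"]): int(g["end"])]
        return seq if g["strand"] == "+" else revcomp(seq)


def _random_seq(rng, length, gc):
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def _plant_motifs(seq, pos, strength, spacing=500):
    """Insert k convergent CTCF motifs (k grows with strength) around pos."""
    k = max(1, int(round(strength * 4)))
    m = CTCF_CONSENSUS
    s = list(seq)
    for i in range(k):
        left = pos - (i + 1) * spacing
        right = pos + (i + 1) * spacing
        s[left:left + len(m)] = m
        s[right:right + len(m)] = revcomp(m)
    return "".join(s)


def _lay_out_genes(spec, structure, rng):
    rows = []
    counter = 0
    for chrom in spec.chromsizes:
        bnds = [p for p, _ in structure.boundaries_on(chrom)]
        forbidden = [(p - 3000, p + 3000) for p in bnds]
        cursor = int(0.05 * spec.chrom_length)
        # one of each biotype first (so every group exists even on short
        # chromosomes), then a second round of the small ones if space allows
        menu = BIOTYPE_MENU + [b for b in BIOTYPE_MENU if _GENE_LENGTHS[b] <= 4000]
        limit = int(0.95 * spec.chrom_length)
        for biotype in menu:
            length = _GENE_LENGTHS[biotype]
            start = cursor + int(rng.integers(2000, 12000))
            # slide past boundary exclusion zones rather than dropping the gene
            while any(a < start + length and start < b for a, b in forbidden):
                hit = max(b for a, b in forbidden if a < start + length and start < b)
                start = hit + int(rng.integers(500, 2000))
            end = start + length
            if end > limit:
                break
            counter += 1
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((f"g{counter:03d}", chrom, start, end, strand, biotype,
                         _GENE_EXPRESSION[biotype], ""))
            cursor = end
        # nested case: a snoRNA inside the first protein-coding host on this chrom
        hosts = [r for r in rows if r[1] == chrom and r[5] == "protein_coding"]
        if hosts:
            h = hosts[0]
            counter += 1
            s0 = h[2] + (h[3] - h[2]) // 3
            rows.append((f"g{counter:03d}", chrom, s0, s0 + _GENE_LENGTHS["snoRNA"],
                         h[4], "snoRNA", _GENE_EXPRESSION["snoRNA"], h[0]))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                       "strand", "biotype", "expression", "host"])


def make_genome(spec: SyntheticGenomeSpec, structure: PlantedStructure | None = None,
                outdir=None, homologies=()) -> SyntheticGenome:
    """Generate sequences, genes and annotation BEDs; optionally write files."""
    rng = np.random.default_rng(spec.seed)
    structure = structure or default_structure(spec)
    sequences = {}
    for chrom in spec.chromsizes:
        seq = _random_seq(rng, spec.chrom_length, spec.gc_content)
        if spec.motif_boundaries:
            for pos, strength in structure.boundaries_on(chrom):
                seq = _plant_motifs(seq, pos, strength)
        sequences[chrom] = seq
    genes = _lay_out_genes(spec, structure, rng)
    # open bins: boundary bins plus gene promoter bins
    open_bins = {}
    bs = spec.bin_size
    for chrom in spec.chromsizes:
        bins = {p // bs for p, _ in structure.boundaries_on(chrom)}
        for _, g in genes[genes["chrom"] == chrom].iterrows():
            tss = g["start"] if g["strand"] == "+" else g["end"] - 1
            bins.add(int(tss) // bs)
        open_bins[chrom] = np.array(sorted(bins), dtype=int)
    genome = SyntheticGenome(spec, structure, sequences, genes, open_bins)
    for hom in homologies:
        plant_homology(genome, hom)
    if outdir is not None:
        write_genome_files(genome, outdir)
    return genome


def plant_homology(genome: SyntheticGenome, hom: PlantedHomology):
    """Copy a mutated gene subsequence to a distant DNA locus.

    Mutations are spaced so the longest perfect match equals
    ``hom.max_perfect_run`` and the identity equals the requested fraction
    (up to rounding); the construction is re-checked by a direct scan.
    """
    if hom.rna_gene not in set(genome.genes["gene_id"]):
        raise ValueError(f"homology references unknown gene {hom.rna_gene}")
    g = genome.genes.set_index("gene_id").loc[hom.rna_gene]
    src = genome.sequences[g["chrom"]][int(g["start"]): int(g["start"]) + hom.length]
    n_mut = int(round((1 - hom.identity) * hom.length))
    frag = list(src)
    if n_mut > 0:
        # first segment exactly max_perfect_run long, rest spread evenly
        positions = [hom.max_perfect_run]
        remaining = hom.length - hom.max_perfect_run - 1
        step = max(2, remaining // n_mut) if n_mut > 1 else remaining
        p = hom.max_perfect_run
        while len(positions) < n_mut:
            p = min(p + step, hom.length - 1 - (n_mut - len(positions)))
            positions.append(p)
            p += 1
        for p in positions:
            frag[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[frag[p]]
    chrom_seq = list(genome.sequences[hom.dna_chrom])
    chrom_seq[hom.dna_pos: hom.dna_pos + hom.length] = frag
    genome.sequences[hom.dna_chrom] = "".join(chrom_seq)


def write_genome_files(genome: SyntheticGenome, outdir):
    """FASTA + GTF + annotation BEDs (CTCF, chromHMM-like, SPIN-like, repeats)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "genome.fa"
    with open(fasta, "w") as fh:
        for chrom, seq in genome.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    gtf = outdir / "genes.gtf"
    with open(gtf, "w") as fh:
        for _, g in genome.genes.iterrows():
            attrs = (f'gene_id "{g.gene_id}"; gene_type "{g.biotype}";'
                     + (f' host_gene "{g.host}";' if g.host else ""))
            fh.write("\t".join([g.chrom, "synthio", "gene", str(g.start + 1),
                                str(g.end), ".", g.strand, ".", attrs]) + "\n")
    bs = genome.spec.bin_size
    with open(outdir / "ctcf_peaks.bed", "w") as fh:
        for chrom, pos, strength in genome.structure.tad_boundaries:
            fh.write(f"{chrom}\t{pos - 500}\t{pos + 500}\tCTCF\t{strength:.2f}\n")
    with open(outdir / "boundaries.bed", "w") as fh:
        for chrom, pos, strength in genome.structure.tad_boundaries:
            fh.write(f"{chrom}\t{pos}\t{pos + bs}\tboundary\t{strength:.3f}\n")
    with open(outdir / "spin_states.bed", "w") as fh:
        for chrom, size in genome.chromsizes.items():
            states = ["Speckle", "Interior_Act1", "Interior_Repr1", "Near_Lm1", "Lamina"]
            block = size // len(states)
            for i, st in enumerate(states):
                fh.write(f"{chrom}\t{i * block}\t{min((i + 1) * block, size)}\t{st}\n")
    with open(outdir / "chromhmm_states.bed", "w") as fh:
        for chrom, bins in genome.open_bins.items():
            for b in bins:
                fh.write(f"{chrom}\t{b * bs}\t{(b + 1) * bs}\tActiveTSS\n")
    with open(outdir / "repeats.bed", "w") as fh:
        rng = np.random.default_rng(genome.spec.seed + 7)
        for chrom, size in genome.chromsizes.items():
            for _ in range(20):
                s = int(rng.integers(0, size - 300))
                fh.write(f"{chrom}\t{s}\t{s + 300}\tAlu\n")
    return outdir


# ---------------------------------------------------------------------------
# Expected (noise-free) contact model
# ---------------------------------------------------------------------------

def expected_contact_map(structure: PlantedStructure, grid: BinGrid, chrom, start,
                         window_bp, loop_sigma_bins=1.5):
    """Expected contact frequency under the planted model for one window.

    ``O[i,j] = (|i-j|+1)^-gamma * exp(-attenuation * sum of boundary strengths
    between i and j) * (1 + loop bumps)``.
    """
    bs = grid.bin_size
    n = window_bp // bs
    idx = np.arange(n)
    dist = np.abs(idx[:, None] - idx[None, :]) + 1.0
    mat = dist ** (-structure.decay_exponent)
    for pos, strength in structure.boundaries_on(chrom):
        b = (pos - start) / bs
        if not 0 < b < n:
            continue
        crosses = (np.minimum(idx[:, None], idx[None, :]) < b) & \
                  (np.maximum(idx[:, None], idx[None, :]) >= b)
        mat = np.where(crosses, mat * np.exp(-structure.attenuation * strength), mat)
    for (ca, pa), (cb, pb), intensity in structure.loops:
        if ca != chrom or cb != chrom:
            continue
        ba, bb = (pa - start) / bs, (pb - start) / bs
        if not (0 <= ba < n and 0 <= bb < n):
            continue
        bump = np.exp(-((idx[:, None] - ba) ** 2 + (idx[None, :] - bb) ** 2)
                      / (2 * loop_sigma_bins**2))
        mat = mat * (1 + intensity * (bump + bump.T))
    return mat


def expected_target_map(structure, grid, chrom, start, window_bp, gaussian_sigma=1.0):
    """Noise-free TargetMap (log obs/exp of the planted contact model)."""
    mat = expected_contact_map(structure, grid, chrom, start, window_bp)
    return finalize_target(observed_over_expected(mat), gaussian_sigma=gaussian_sigma,
                           chrom=chrom, start=start)


# ---------------------------------------------------------------------------
# Desk-scale model training datasets
# ---------------------------------------------------------------------------

@dataclass
class ModelDataset:
    """Windows with one-hot sequences, feature channels and expected targets."""

    seqs: np.ndarray  # (N, L, 4)
    features: np.ndarray  # (N, n_bins, 8)
    targets: np.ndarray  # (N, n_bins, n_bins)
    boundary_bins: list  # per-window list of boundary bin indices
    strengths: list  # per-window list of planted strengths
    channel: int  # index of the informative caRNA channel


def make_model_dataset(n_windows, window_bp=2**16, bin_size=DEFAULT_BIN_SIZE,
                       seed=0, n_channels=8, signal_channel=3, signal_scale=300.0,
                       strength_range=(0.25, 1.0), motif_boundaries=False,
                       noise_sd=0.05, gaussian_sigma=1.0) -> ModelDataset:
    """Per-window training examples with a planted feature->structure link.

    Each window gets 1-2 TAD boundaries at random interior bins with random
    insulation strengths.  The target is the expected (noise-free) log
    obs/exp map of the planted contact model.  One caRNA channel carries
    ``log1p(strength * signal_scale)`` at boundary bins (so the boundary
    strength is readable from that channel alone); the remaining channels
    are low-level noise.  With ``motif_boundaries=True`` the sequence also
    carries ``ceil(strength * 4)`` convergent CTCF motifs at each boundary,
    making structure readable from sequence as well.
    """
    from .netmodel import encode_sequence

    rng = np.random.default_rng(seed)
    n_bins = window_bp // bin_size
    grid = BinGrid({"chrW": window_bp}, bin_size)
    seqs, feats, targets, bbins, strths = [], [], [], [], []
    for w in range(n_windows):
        n_b = int(rng.integers(1, 3)) if n_bins >= 24 else 1
        margin = max(5, n_bins // 8)
        bins = np.sort(rng.choice(np.arange(margin, n_bins - margin), size=n_b,
                                  replace=False))
        while np.diff(bins).size and np.diff(bins).min() < 6:
            bins = np.sort(rng.choice(np.arange(margin, n_bins - margin), size=n_b,
                                      replace=False))
        ss = rng.uniform(*strength_range, size=n_b)
        if motif_boundaries:
            # quantize so the motif count k = 4s encodes the strength exactly
            ss = np.ceil(ss * 4) / 4.0
        structure = PlantedStructure(
            tad_boundaries=[("chrW", int(b) * bin_size, float(s))
                            for b, s in zip(bins, ss)])
        seq = _random_seq(rng, window_bp, 0.41)
        if motif_boundaries:
            for b, s in zip(bins, ss):
                seq = _plant_motifs(seq, int(b) * bin_size, float(s))
        tgt = expected_target_map(structure, grid, "chrW", 0, window_bp,
                                  gaussian_sigma=gaussian_sigma)
        f = np.abs(rng.normal(0, noise_sd, size=(n_bins, n_channels)))
        f[bins, signal_channel] = np.log1p(ss * signal_scale)
        seqs.append(encode_sequence(seq))
        feats.append(f.astype(np.float32))
        targets.append(tgt.matrix)
        bbins.append(list(map(int, bins)))
        strths.append(list(map(float, ss)))
    return ModelDataset(np.stack(seqs), np.stack(feats), np.stack(targets),
                        bbins, strths, signal_channel)


# ---------------------------------------------------------------------------
# DNA-DNA pairs
# ---------------------------------------------------------------------------

def make_dna_dna_pairs(structure: PlantedStructure, chromsizes, depth, seed, out,
                       d_min=500, loop_read_fraction=0.02):
    """Sample DNA-DNA contacts from the planted model and write a .pairs file."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    chroms = list(chromsizes)
    sizes = np.array([chromsizes[c] for c in chroms], dtype=float)
    records = []
    loops = structure.loops
    gamma = structure.decay_exponent
    while len(records) < depth:
        batch = max(1024, (depth - len(records)) * 2)
        ci = rng.choice(len(chroms), size=batch, p=sizes / sizes.sum())
        d_max = sizes[ci] / 2
        u = rng.random(batch)
        if abs(gamma - 1.0) < 1e-9:
            d = d_min * (d_max / d_min) ** u
        else:
            a = 1 - gamma
            d = (d_min**a + u * (d_max**a - d_min**a)) ** (1 / a)
        d = d.astype(int)
        p1 = (rng.random(batch) * (sizes[ci] - d)).astype(int)
        p2 = p1 + d
        # attenuate across planted boundaries
        keep = rng.random(batch)
        prob = np.ones(batch)
        for chrom_i, chrom in enumerate(chroms):
            sel = ci == chrom_i
            for pos, strength in structure.boundaries_on(chrom):
                crossing = sel & (p1 < pos) & (p2 >= pos)
                prob[crossing] *= np.exp(-structure.attenuation * strength)
        ok = keep < prob
        for b in np.flatnonzero(ok):
            if len(records) >= depth:
                break
            if loops and rng.random() < loop_read_fraction:
                (ca, pa), (cb, pb), _ = loops[rng.integers(len(loops))]
                ja = int(pa + rng.integers(-1024, 1024))
                jb = int(pb + rng.integers(-1024, 1024))
                records.append((ca, max(ja, 0), cb, max(jb, 0)))
            else:
                records.append((chroms[ci[b]], int(p1[b]), chroms[ci[b]], int(p2[b])))
    df = pd.DataFrame(records, columns=["chrom1", "pos1", "chrom2", "pos2"])
    df.insert(0, "readID", [f"dd{i}" for i in range(len(df))])
    df["strand1"] = "+"
    df["strand2"] = "-"
    pairsio.write_pairs(out, df, chromsizes,
                        extra_header=["genome_assembly: synthetic"])
    return Path(out)


# ---------------------------------------------------------------------------
# RNA-DNA pairs
# ---------------------------------------------------------------------------

def make_rna_dna_pairs(spec: SyntheticContactSpec, genome: SyntheticGenome,
                       seed, out, truth_out=None, homologies=()):
    """Sample iMARGI-like RNA-DNA contacts (RNA end = side 1, DNA end = side 2).

    Returns the path of the .pairs file; a truth TSV records each read's gene,
    cis/trans status, biotype group and MAPQ-pass flag.
    """
    gene_ids = set(genome.genes["gene_id"])
    for hom in homologies:
        if hom.rna_gene not in gene_ids:
            raise ValueError(f"homology references unknown gene {hom.rna_gene}")
    rng = np.random.default_rng(seed)
    genes = genome.genes
    chromsizes = genome.chromsizes
    chroms = list(chromsizes)
    bs = genome.spec.bin_size
    # genome-wide trans-target bin weights (open bins up-weighted)
    bin_weights, bin_coords = [], []
    for chrom in chroms:
        nb = chromsizes[chrom] // bs
        w = np.ones(nb)
        w[genome.open_bins[chrom]] *= spec.trans_target_bias
        bin_weights.append(w)
        bin_coords.extend((chrom, b) for b in range(nb))
    bin_weights = np.concatenate(bin_weights)
    bin_p = bin_weights / bin_weights.sum()

    expr = genes["expression"].to_numpy(float)
    gene_draw = rng.choice(len(genes), size=spec.n_reads, p=expr / expr.sum())
    rows, truth = [], []
    for ridx, gi in enumerate(gene_draw):
        g = genes.iloc[gi]
        rna_chrom = g["chrom"]
        rna_pos = int(rng.integers(g["start"], g["end"]))
        if rng.random() < spec.cis_fraction:
            is_trans = False
            delta = int(rng.exponential(spec.cis_scale)) % spec.min_trans_dist
            sign = -1 if rng.random() < 0.5 else 1
            dna_chrom = rna_chrom
            dna_pos = int(np.clip(rna_pos + sign * delta, 0,
                                  chromsizes[dna_chrom] - 1))
        else:
            is_trans = True
            for _ in range(50):
                bi = rng.choice(len(bin_p), p=bin_p)
                dna_chrom, b = bin_coords[bi]
                dna_pos = int(b * bs + rng.integers(0, bs))
                if dna_chrom != rna_chrom or abs(dna_pos - rna_pos) > spec.min_trans_dist:
                    break
        mq_fail = rng.random() < spec.mapq_low_fraction
        mapq = int(rng.integers(0, 31)) if mq_fail else int(rng.integers(31, 61))
        rows.append((f"rd{ridx}", rna_chrom, rna_pos, dna_chrom, dna_pos,
                     g["strand"], "+", mapq, mapq))
        truth.append((f"rd{ridx}", g["gene_id"], g["biotype"], is_trans, not mq_fail))
    # homology-supporting reads: RNA from the source gene, DNA at the planted locus
    for hidx, hom in enumerate(homologies):
        g = genes.set_index("gene_id").loc[hom.rna_gene]
        for k in range(hom.n_reads):
            rid = f"hom{hidx}_{k}"
            rna_pos = int(g["start"]) + int(rng.integers(0, hom.length))
            dna_pos = hom.dna_pos + int(rng.integers(0, hom.length))
            rows.append((rid, g["chrom"], rna_pos, hom.dna_chrom, dna_pos,
                         g["strand"], "+", 60, 60))
            truth.append((rid, hom.rna_gene, g["biotype"], True, True))
    df = pd.DataFrame(rows, columns=["readID", "chrom1", "pos1", "chrom2",
                                     "pos2", "strand1", "strand2", "mapq1", "mapq2"])
    pairsio.write_pairs(out, df, chromsizes,
                        extra_header=["note: side1=RNA end, side2=DNA end (iMARGI convention)"])
    truth_df = pd.DataFrame(truth, columns=["readID", "gene_id", "biotype",
                                            "is_trans", "mapq_pass"])
    if truth_out is not None:
        truth_df.to_csv(truth_out, sep="\t", index=False)
    return Path(out), truth_df


# ---------------------------------------------------------------------------
# Signal tracks
# ---------------------------------------------------------------------------

def make_signal_tracks(genome: SyntheticGenome, outdir, seed=0, open_boost=10.0,
                       base_level=1.0, noise_sd=0.0):
    """ATAC-like and RNA-seq-like bedGraph tracks (per-bin values).

    ATAC signal = base level boosted ``open_boost``-fold at open bins;
    RNA-seq signal follows gene expression over gene bodies.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    bs = genome.spec.bin_size
    atac_path = outdir / "atac.bedgraph"
    rnaseq_path = outdir / "rnaseq.bedgraph"
    with open(atac_path, "w") as fa, open(rnaseq_path, "w") as fr:
        for chrom, size in genome.chromsizes.items():
            nb = size // bs
            atac = np.full(nb, base_level, dtype=float)
            atac[genome.open_bins[chrom]] *= open_boost
            rnaseq = np.zeros(nb)
            for _, g in genome.genes[genome.genes["chrom"] == chrom].iterrows():
                b0, b1 = int(g["start"]) // bs, int(g["end"] - 1) // bs + 1
                rnaseq[b0:b1] += float(g["expression"])
            if noise_sd > 0:
                atac = np.maximum(atac + rng.normal(0, noise_sd, nb), 0)
                rnaseq = np.maximum(rnaseq + rng.normal(0, noise_sd, nb), 0)
            for b in range(nb):
                fa.write(f"{chrom}\t{b * bs}\t{(b + 1) * bs}\t{atac[b]:.4f}\n")
                fr.write(f"{chrom}\t{b * bs}\t{(b + 1) * bs}\t{rnaseq[b]:.4f}\n")
    return atac_path, rnaseq_path
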
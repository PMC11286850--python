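"""In-silico perturbations and the trans R-loop candidate scan.

Three experiments around a trained predictor:

* **CTCF insertion** — plant 1..4 convergent CTCF motif pairs (forward
  motifs upstream, reverse-complement downstream, 500-bp spacing) at a
  random locus of random ~1 Mb sequences and measure how the predicted mean
  contact frequency and local insulation respond;
* **caRNA elevation** — multiply the raw-scale caRNA signal of one channel
  at selected TAD boundary bins by e^0.5 .. e^2 and measure the change in
  predicted insulation strength and mean contact;
* **R-loop scan** — locally align RNA against DNA sequence (both strands);
  a pair is a candidate when over 80% of the RNA bases match and the longest
  uninterrupted perfect match exceeds 10 bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from scipy import stats

from .evalmetrics import insulation_profile, insulation_strength
from .netmodel import encode_sequence
from .synthio import CTCF_CONSENSUS, revcomp

IDENTITY_MIN = 0.80
PERFECT_RUN_MIN = 10  # bp, strictly exceeded


# ---------------------------------------------------------------------------
# CTCF motif insertion
# ---------------------------------------------------------------------------

@dataclass
class CtcfInsertionSpec:
    n_sequences: int = 1000
    seq_len: int = 2**20
    locus_range: tuple = (0.15, 0.85)
    motif: str = CTCF_CONSENSUS
    spacing: int = 500
    seed: int = 0


def insert_ctcf(seq: str, locus: int, k: int, motif=CTCF_CONSENSUS, spacing=500):
    """Replace bases with k convergent motif pairs symmetric about ``locus``.

    k forward motifs upstream and k reverse-complement motifs downstream,
    ``spacing`` bp apart; sequence length is unchanged.  Returns
    ``(sequence, coordinates)`` where coordinates are (start, strand) pairs.
    """
    if not 0 <= k <= 4:
        raise ValueError("k must be in 0..4")
    if k == 0:
        return seq, []
    m = motif
    footprint = k * spacing + len(m)
    if locus - footprint < 0 or locus + footprint > len(seq):
        raise ValueError("locus too close to the sequence edge for k insertions")
    s = list(seq)
    coords = []
    for i in range(k):
        left = locus - (i + 1) * spacing
        right = locus + (i + 1) * spacing
        s[left:left + len(m)] = m
        s[right:right + len(m)] = revcomp(m)
        coords.append((left, "+"))
        coords.append((right, "-"))
    return "".join(s), sorted(coords)


@dataclass
class ResponseCurve:
    x: np.ndarray  # perturbation level (n_motifs or fold)
    mean_contact: np.ndarray  # per-level mean over replicates/sequences
    insulation: np.ndarray
    mean_contact_all: list = field(default_factory=list)  # per-level samples
    insulation_all: list = field(default_factory=list)
    pairwise_tests: list = field(default_factory=list)  # (x1, x2, U, p)


def _mw_tests(levels, samples):
    out = []
    for a, b in zip(range(len(levels) - 1), range(1, len(levels))):
        sa, sb = np.asarray(samples[a]), np.asarray(samples[b])
        if len(sa) and len(sb):
            u, p = stats.mannwhitneyu(sa, sb, alternative="two-sided")
            out.append((levels[a], levels[b], float(u), float(p)))
    return out


def ctcf_response(model, spec: CtcfInsertionSpec, diamond=6, batch_size=4
                  ) -> ResponseCurve:
    """Mean predicted contact and boundary insulation for k = 1..4 motifs.

    ``n_sequences`` random sequences each receive k convergent motifs at a
    random locus inside ``locus_range``; predictions use the sequence-only
    model.  Consecutive-k Mann-Whitney tests (two-sided) are attached.
    """
    rng = np.random.default_rng(spec.seed)
    cfg = model.config
    n_bins = cfg.n_bins
    lo, hi = spec.locus_range
    bases = ["".join(rng.choice(list("ACGT"), size=spec.seq_len))
             for _ in range(spec.n_sequences)]
    loci = [int(rng.uniform(lo, hi) * spec.seq_len) for _ in range(spec.n_sequences)]
    ks = [1, 2, 3, 4]
    mc_all, ins_all = [], []
    for k in ks:
        seqs = np.stack([
            encode_sequence(insert_ctcf(b, l, k, spec.motif, spec.spacing)[0])
            for b, l in zip(bases, loci)])
        mcs, inss = [], []
        for i in range(0, len(seqs), batch_size):
            pred = model.predict(seqs[i:i + batch_size])
            for j, p in enumerate(pred):
                mcs.append(float(p.mean()))
                bin_i = int(np.clip(loci[i + j] // cfg.bin_bp, diamond,
                                    n_bins - diamond - 1))
                prof = insulation_profile(p, diamond)
                inss.append(insulation_strength(prof, bin_i))
        mc_all.append(mcs)
        ins_all.append(inss)
    return ResponseCurve(np.array(ks),
                         np.array([np.mean(v) for v in mc_all]),
                         np.array([np.nanmean(v) for v in ins_all]),
                         mc_all, ins_all, _mw_tests(ks, mc_all))


# ---------------------------------------------------------------------------
# caRNA elevation
# ---------------------------------------------------------------------------

DEFAULT_FOLDS = tuple(np.exp([0.5, 1.0, 1.5, 2.0]))


@dataclass
class ElevationSpec:
    boundary_bins: list  # per-window list of bin indices (1-2 boundaries each)
    channel: int = 0
    folds: tuple = DEFAULT_FOLDS
    diamond: int = 6


def elevate_carna(features: np.ndarray, channel: int, bins, fold: float
                  ) -> np.ndarray:
    """Multiply raw-scale signal of one channel at given bins by ``fold``.

    ``features`` is (n_bins, n_channels), log1p-scaled; the fold is applied
    on the raw scale (``log1p(fold * expm1(x))``) so fold e**1 raises a large
    log-signal by about 1.  All other channels and bins are returned
    bit-identical.
    """
    if not 0 <= channel < features.shape[1]:
        raise ValueError(f"unknown channel {channel}")
    out = features.copy()
    raw = np.expm1(out[bins, channel])
    out[bins, channel] = np.log1p(fold * raw)
    return out


def elevation_response(model, seqs, features, spec: ElevationSpec,
                       batch_size=4) -> ResponseCurve:
    """Delta insulation strength / mean contact versus elevation fold.

    For each window, the chosen channel is elevated at its boundary bins and
    predictions are compared to the unperturbed baseline; deltas are averaged
    over boundaries.  fold = 1 gives exactly zero delta by construction.
    """
    folds = spec.folds
    base = []
    for i in range(0, len(seqs), batch_size):
        base.append(model.predict(seqs[i:i + batch_size], features[i:i + batch_size]))
    base = np.concatenate(base)
    d_ins_all, d_mc_all = [], []
    for fold in folds:
        pert = np.stack([
            elevate_carna(features[w], spec.channel, spec.boundary_bins[w], fold)
            for w in range(len(features))])
        d_ins, d_mc = [], []
        for i in range(0, len(seqs), batch_size):
            pred = model.predict(seqs[i:i + batch_size], pert[i:i + batch_size])
            for j, p in enumerate(pred):
                w = i + j
                prof_p = insulation_profile(p, spec.diamond)
                prof_b = insulation_profile(base[w], spec.diamond)
                deltas = [insulation_strength(prof_p, b) - insulation_strength(prof_b, b)
                          for b in spec.boundary_bins[w]]
                d_ins.append(float(np.nanmean(deltas)))
                d_mc.append(float(p.mean() - base[w].mean()))
        d_ins_all.append(d_ins)
        d_mc_all.append(d_mc)
    return ResponseCurve(np.array(folds),
                         np.array([np.mean(v) for v in d_mc_all]),
                         np.array([np.mean(v) for v in d_ins_all]),
                         d_mc_all, d_ins_all, _mw_tests(list(folds), d_ins_all))


# ---------------------------------------------------------------------------
# R-loop candidate scan
# ---------------------------------------------------------------------------

@dataclass
class RLoopCandidate:
    identity: float  # matched RNA bases / RNA length
    max_run: int  # longest contiguous perfect match (bp)
    strand: str  # DNA strand of the best alignment
    score: float
    is_candidate: bool
    alignment: str = ""


def _make_aligner(match=2.0, mismatch=-1.0, gap_open=-2.0, gap_extend=-0.5):
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = match
    al.mismatch_score = mismatch
    al.open_gap_score = gap_open
    al.extend_gap_score = gap_extend
    return al


def _matches_and_run(alignment, rna, dna):
    """Matched-base count and longest perfect run along an alignment path."""
    matches = 0
    max_run = run = 0
    blocks_r, blocks_d = alignment.aligned
    for (r0, r1), (d0, d1) in zip(blocks_r, blocks_d):
        for a, b in zip(rna[r0:r1], dna[d0:d1]):
            if a == b:
                matches += 1
                run += 1
                max_run = max(max_run, run)
            else:
                run = 0
        run = 0  # a gap interrupts any perfect run
    return matches, max_run


def rloop_scan(rna_seq: str, dna_seq: str, identity_min=IDENTITY_MIN,
               run_min=PERFECT_RUN_MIN, aligner=None, identity_over="rna"
               ) -> RLoopCandidate:
    """Best local alignment of an RNA against both DNA strands.

    identity = matched bases / RNA length (``identity_over='aligned'``
    divides by the aligned span instead); a pair is a candidate when
    identity > 0.80 and the longest gap-free perfect match > 10 bp.
    """
    if not rna_seq or not dna_seq:
        raise ValueError("empty sequence")
    rna = rna_seq.upper().replace("U", "T")
    aligner = aligner or _make_aligner()
    best = None
    for strand, dna in (("+", dna_seq.upper()), ("-", revcomp(dna_seq.upper()))):
        alns = aligner.align(rna, dna)
        try:
            aln = alns[0]
        except IndexError:
            continue
        matches, max_run = _matches_and_run(aln, rna, dna)
        if identity_over == "aligned":
            span = sum(r1 - r0 for r0, r1 in aln.aligned[0]) or 1
            ident = matches / span
        else:
            ident = matches / len(rna)
        cand = RLoopCandidate(ident, max_run, strand, float(aln.score),
                              ident > identity_min and max_run > run_min,
                              str(aln))
        # candidacy first, then alignment score, decides the reported strand
        if best is None or (cand.is_candidate, cand.score) > (best.is_candidate,
                                                              best.score):
            best = cand
    if best is None:
        best = RLoopCandidate(0.0, 0, "+", 0.0, False)
    return best


def rloop_landmark_fractions(candidate_intervals, landmarks: pd.DataFrame,
                             resolution=5000, class_col=None):
    """Fraction of landmarks (by class) with >= 1 candidate interaction.

    Overlap is evaluated at the landmark analysis resolution (5000 bp):
    a landmark is hit when a candidate DNA interval falls within
    ``resolution`` bp of its position.  ``candidate_intervals`` is an
    iterable of (chrom, start, end).
    """
    hits = []
    for _, lm in landmarks.iterrows():
        pos = lm["pos"] if "pos" in lm else (lm["start"] + lm["end"]) // 2
        hit = any(c == lm["chrom"] and s < pos + resolution and e > pos - resolution
                  for c, s, e in candidate_intervals)
        hits.append(hit)
    landmarks = landmarks.assign(_hit=hits)
    if class_col is None:
        return {"all": float(landmarks["_hit"].mean()) if len(landmarks) else 0.0}
    return {cls: float(sub["_hit"].mean())
            for cls, sub in landmarks.groupby(class_col)}
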
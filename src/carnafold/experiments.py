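"""Desk-scale experiments: the package's end-to-end scientific checks.

These drive the whole stack on synthetic data with planted ground truth:

* ``overfit`` — a small predictor memorizes 20 windows (sanity check that
  the architecture + optimizer can fit the target parameterization);
* ``feature_vs_sequence`` — when window structure depends on a caRNA
  channel, the feature-bearing model beats the sequence-only model on held
  out windows across 5 seeded replicates (one-sided Mann-Whitney);
* ``elevation`` — raising that channel's raw signal at boundaries by
  e^0.5..e^2 monotonically deepens the predicted insulation;
* ``ctcf_insertion`` — a sequence-only model trained on motif-marked
  boundaries predicts progressively lower mean contact as 1..4 convergent
  CTCF motifs are inserted into fresh random sequences;
* ``trans_recovery`` — the caRNA pipeline recovers a planted trans-contact
  fraction within binomial sampling error.

Problem sizes are chosen for a single CPU: windows of 2**15-2**17 bp
(16-64 bins at 2048-bp resolution) instead of the full 2**20, tens of
windows instead of thousands.  The qualitative contrasts these experiments
probe are scale-free; the numbers they produce are desk-scale analogs, not
reproductions of full-genome values.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from . import carna, insilico, netmodel, synthio
from .netmodel import ModelConfig, TrainConfig


def _split(ds, n_train):
    train = (ds.seqs[:n_train], ds.features[:n_train], ds.targets[:n_train])
    valid = (ds.seqs[n_train:], ds.features[n_train:], ds.targets[n_train:])
    return train, valid


def overfit(seed=0, n_windows=20, window_bp=2**17, epochs=30, lr=0.01):
    """Train-set Pearson of a tiny feature-bearing model fit to 20 windows."""
    ds = synthio.make_model_dataset(n_windows, window_bp=window_bp, seed=seed)
    cfg = ModelConfig(window_bp=window_bp, n_feature_channels=ds.features.shape[2])
    tc = TrainConfig(lr=lr, epochs=epochs, n_replicates=1, seeds=(seed,))
    train = (ds.seqs, ds.features, ds.targets)
    res = netmodel.train_model(cfg, train, train, tc, seed=seed)
    train_r, train_mse = netmodel._evaluate(res.model, *train, cfg.diag_offset)
    return {"train_pearson": train_r, "train_mse": train_mse,
            "n_windows": n_windows, "model": res.model, "dataset": ds}


def feature_vs_sequence(seed=0, n_train=20, n_valid=8, window_bp=2**16,
                        epochs=20, n_replicates=5):
    """Validation Pearson of feature vs sequence-only models, 5 replicates each.

    Targets depend on a caRNA channel (boundary strength is written into it),
    so the feature model has information the sequence cannot supply.
    """
    ds = synthio.make_model_dataset(n_train + n_valid, window_bp=window_bp,
                                    seed=seed)
    train, valid = _split(ds, n_train)
    seeds = tuple(seed * 100 + i for i in range(n_replicates))
    tc = TrainConfig(epochs=epochs, n_replicates=n_replicates, seeds=seeds)
    cfg_f = ModelConfig(window_bp=window_bp, n_feature_channels=ds.features.shape[2])
    sel_f, res_f = netmodel.train_replicates(cfg_f, train, valid, tc)
    cfg_s = ModelConfig(window_bp=window_bp, n_feature_channels=0)
    train_s = (train[0], None, train[2])
    valid_s = (valid[0], None, valid[2])
    sel_s, res_s = netmodel.train_replicates(cfg_s, train_s, valid_s, tc)
    rf = [r.best_valid_pearson for r in res_f if not r.failed]
    rs = [r.best_valid_pearson for r in res_s if not r.failed]
    u, p = stats.mannwhitneyu(rf, rs, alternative="greater")
    return {"feature_pearson": rf, "sequence_pearson": rs,
            "mannwhitney_u": float(u), "mannwhitney_p": float(p),
            "feature_model": sel_f.model, "dataset": ds, "n_train": n_train}


def elevation(model, ds, valid_slice, folds=insilico.DEFAULT_FOLDS, diamond=4):
    """Insulation/contact response to caRNA elevation at planted boundaries."""
    idx = list(range(*valid_slice.indices(len(ds.seqs))))
    spec = insilico.ElevationSpec(
        boundary_bins=[ds.boundary_bins[i] for i in idx],
        channel=ds.channel, folds=folds, diamond=diamond)
    rc = insilico.elevation_response(model, ds.seqs[idx], ds.features[idx], spec)
    rho, _ = stats.spearmanr(rc.x, rc.insulation)
    return {"folds": list(rc.x), "delta_insulation": list(rc.insulation),
            "delta_mean_contact": list(rc.mean_contact),
            "monotone_insulation": bool(np.all(np.diff(rc.insulation) > 0)),
            "spearman_fold_vs_insulation": float(rho)}


def ctcf_insertion(seed=0, n_train=100, n_valid=10, window_bp=2**15,
                   epochs=25, n_sequences=100, n_replicates=2, diamond=3):
    """Train a sequence-only model on motif-marked boundaries, then measure
    the predicted response to inserting 1..4 convergent CTCF motifs.

    The model is trained ``n_replicates`` times and the standard replicate
    selection picks the one probed with fresh random sequences.
    """
    ds = synthio.make_model_dataset(n_train + n_valid, window_bp=window_bp,
                                    seed=seed, motif_boundaries=True)
    train, valid = _split(ds, n_train)
    cfg = ModelConfig(window_bp=window_bp, n_feature_channels=0,
                      trunk_kernel_first=21)
    seeds = tuple(seed + 500 * i for i in range(n_replicates))
    tc = TrainConfig(epochs=epochs, n_replicates=n_replicates, seeds=seeds,
                     weight_decay=1e-4)
    res, _ = netmodel.train_replicates(cfg, (train[0], None, train[2]),
                                       (valid[0], None, valid[2]), tc)
    spec = insilico.CtcfInsertionSpec(n_sequences=n_sequences,
                                      seq_len=window_bp, seed=seed + 1)
    rc = insilico.ctcf_response(res.model, spec, diamond=diamond)
    rho, _ = stats.spearmanr(rc.x, rc.mean_contact)
    return {"k": list(rc.x), "mean_contact": list(rc.mean_contact),
            "insulation": list(rc.insulation),
            "monotone_contact_decrease": bool(np.all(np.diff(rc.mean_contact) < 0)),
            "spearman_k_vs_contact": float(rho),
            "valid_pearson": res.best_valid_pearson, "model": res.model}


def trans_recovery(seed=0, n_reads=100_000, cis_fraction=0.6, tmpdir=None):
    """Planted trans fraction recovered through the full caRNA pipeline."""
    import tempfile
    from pathlib import Path

    tmpdir = Path(tmpdir) if tmpdir else Path(tempfile.mkdtemp())
    spec = synthio.SyntheticGenomeSpec(n_chroms=2, chrom_length=2**17, seed=seed)
    genome = synthio.make_genome(spec)
    cspec = synthio.SyntheticContactSpec(n_reads=n_reads, cis_fraction=cis_fraction)
    path, truth = synthio.make_rna_dna_pairs(cspec, genome, seed=seed + 1,
                                             out=tmpdir / "rd.pairs")
    contacts = carna.parse_rna_dna_pairs(path)
    genes = carna.GeneModel.from_table(genome.genes)
    trans = carna.trans_filter(contacts, genes)
    observed = len(trans) / len(contacts)
    planted = 1 - cis_fraction
    se = float(np.sqrt(planted * (1 - planted) / len(contacts)))
    return {"observed_trans_fraction": observed, "planted_trans_fraction": planted,
            "binomial_se": se, "n_retained": len(contacts),
            "within_3se": bool(abs(observed - planted) <= 3 * se)}
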
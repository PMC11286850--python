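"""Contribution scores, extreme regions, enrichment, hypergeometric ranking."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from carnafold import attribution as attr


class LinearSurrogate:
    """y = sum_i w_i x_i over all (bin, feature) inputs; exact closed form."""

    def __init__(self, weights):
        self.weights = np.asarray(weights, float)  # (n_bins, F)

    def feature_gradient(self, seqs, features, output_weights=None):
        pred = np.array([(f * self.weights).sum() for f in features])
        grad = np.broadcast_to(self.weights, features.shape).copy()
        return pred, grad


# ---------------------------------------------------------------------------
# expected gradients
# ---------------------------------------------------------------------------

def test_linear_model_closed_form(rng):
    n_bins, F = 10, 3
    w = rng.standard_normal((n_bins, F))
    model = LinearSurrogate(w)
    x = rng.standard_normal((2, n_bins, F))
    bg = rng.standard_normal((5, n_bins, F))
    seqs = np.zeros((2, 1, 4))
    scores = attr.contribution_scores(model, seqs, x, bg, n_steps=4)
    expected = w * (x - bg.mean(axis=0))
    assert np.allclose(scores, expected, rtol=1e-4, atol=1e-8)


def test_linear_model_completeness(rng):
    """Scores sum to output(x) - mean output(background)."""
    n_bins, F = 8, 2
    w = rng.standard_normal((n_bins, F))
    model = LinearSurrogate(w)
    x = rng.standard_normal((1, n_bins, F))
    bg = rng.standard_normal((6, n_bins, F))
    scores = attr.contribution_scores(model, np.zeros((1, 1, 4)), x, bg)
    out_x = (x[0] * w).sum()
    out_bg = np.mean([(b * w).sum() for b in bg])
    assert scores.sum() == pytest.approx(out_x - out_bg, rel=1e-6)


def test_null_feature_gets_zero_scores(rng):
    w = rng.standard_normal((6, 3))
    w[:, 1] = 0.0  # the model ignores feature 1
    model = LinearSurrogate(w)
    x = rng.standard_normal((1, 6, 3))
    bg = rng.standard_normal((4, 6, 3))
    scores = attr.contribution_scores(model, np.zeros((1, 1, 4)), x, bg)
    assert np.allclose(scores[:, :, 1], 0.0)


def test_scores_deterministic(rng):
    w = rng.standard_normal((6, 2))
    model = LinearSurrogate(w)
    x = rng.standard_normal((1, 6, 2))
    bg = rng.standard_normal((3, 6, 2))
    s1 = attr.contribution_scores(model, np.zeros((1, 1, 4)), x, bg)
    s2 = attr.contribution_scores(model, np.zeros((1, 1, 4)), x, bg)
    assert np.array_equal(s1, s2)


def test_empty_background_rejected(rng):
    model = LinearSurrogate(np.ones((4, 2)))
    with pytest.raises(ValueError, match="background"):
        attr.contribution_scores(model, np.zeros((1, 1, 4)),
                                 rng.random((1, 4, 2)), np.empty((0, 4, 2)))


def test_normalize_scores_bounds(rng):
    raw = rng.standard_normal((4, 20, 3)) * np.array([1, 10, 100])
    norm = attr.normalize_scores(raw)
    assert np.abs(norm).max() <= 1.0
    for f in range(3):
        assert np.abs(norm[:, :, f]).max() == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# background scheme
# ---------------------------------------------------------------------------

def test_background_scheme_counts_and_halves():
    labels = ["train"] * 50 + ["valid"] * 5 + ["test"] * 5
    bg = attr.background_scheme(labels, n_background=20, seed=1)
    assert len(bg["valid_test"]) == 20
    assert set(bg["half1"]) | set(bg["half2"]) == set(range(50))
    assert not set(bg["half1"]) & set(bg["half2"])
    assert set(bg["train_half1"]) <= set(bg["half2"])
    assert set(bg["train_half2"]) <= set(bg["half1"])


def test_background_scheme_seeded():
    labels = ["train"] * 40 + ["test"] * 4
    a = attr.background_scheme(labels, seed=9)
    b = attr.background_scheme(labels, seed=9)
    assert np.array_equal(a["valid_test"], b["valid_test"])


# ---------------------------------------------------------------------------
# extreme regions
# ---------------------------------------------------------------------------

def test_top_one_percent_of_100_is_single_max(rng):
    scores = rng.standard_normal((1, 100, 1))
    inputs = np.ones((1, 100, 1))
    rs = attr.extreme_regions(scores, inputs, feature=0, pct=1, tail="top")
    assert len(rs.bins) == 1
    assert rs.bins[0] == int(np.argmax(scores[0, :, 0]))


def test_ties_break_deterministically():
    scores = np.zeros((1, 50, 1))
    inputs = np.ones((1, 50, 1))
    a = attr.extreme_regions(scores, inputs, 0, pct=10, tail="top")
    b = attr.extreme_regions(scores, inputs, 0, pct=10, tail="top")
    assert len(a.bins) == 5
    assert np.array_equal(a.bins, b.bins)


def test_only_positive_input_bins_eligible(rng):
    scores = rng.standard_normal((1, 40, 1))
    inputs = np.zeros((1, 40, 1))
    inputs[0, :10, 0] = 1.0
    rs = attr.extreme_regions(scores, inputs, 0, pct=50, tail="bottom")
    assert set(rs.bins) <= set(range(10))
    assert len(rs.bins) == 5


def test_extreme_regions_match_sort_oracle(rng):
    scores = rng.standard_normal((2, 30, 2))
    inputs = np.abs(rng.standard_normal((2, 30, 2)))
    rs = attr.extreme_regions(scores, inputs, 1, pct=20, tail="top")
    flat_s = scores[:, :, 1].ravel()
    flat_x = inputs[:, :, 1].ravel()
    elig = np.flatnonzero(flat_x > 0)
    k = int(np.ceil(0.2 * len(elig)))
    oracle = set(elig[np.argsort(flat_s[elig])[-k:]])
    assert set(rs.bins) == oracle


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def _region_set(bins, eligible):
    return attr.ExtremeRegionSet(0, "top", 5, np.asarray(bins), np.asarray(eligible))


def test_enrichment_universal_annotation_is_zero():
    rs = _region_set([1, 2, 3], np.arange(20))
    assert attr.enrichment(rs, np.arange(20)) == pytest.approx(0.0)


def test_enrichment_constructed_log2_of_4():
    eligible = np.arange(100)
    ann = np.arange(25)  # covers 25% of eligible
    rs = _region_set(np.arange(10), eligible)  # all regions inside annotation
    assert attr.enrichment(rs, ann) == pytest.approx(2.0)


def test_enrichment_permutation_null_centered(rng):
    eligible = np.arange(200)
    ann = rng.choice(eligible, 80, replace=False)
    vals = []
    for seed in range(100):
        r = np.random.default_rng(seed)
        rs = _region_set(r.choice(eligible, 40, replace=False), eligible)
        v = attr.enrichment(rs, ann)
        if np.isfinite(v):
            vals.append(v)
    assert abs(np.mean(vals)) < 0.1


def test_enrichment_zero_expected_missing():
    rs = _region_set([1], np.arange(10))
    assert attr.enrichment(rs, np.array([500])) is None


# ---------------------------------------------------------------------------
# differential regions
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("rna,atac,passes", [
    (0.3, 0.05, True),    # fold 6 > 5, |rna| > 0.25
    (0.3, 0.1, False),    # fold 3 fails
    (0.2, 0.01, False),   # fold 20 but magnitude gate fails
    (0.3, 0.0, True),     # atac 0 -> infinite fold, magnitude passes
])
def test_differential_thresholds(rna, atac, passes):
    out = attr.differential_regions(np.array([[rna]]), np.array([[atac]]))
    assert bool(out["passes"].iloc[0]) is passes


# ---------------------------------------------------------------------------
# hypergeometric interactions
# ---------------------------------------------------------------------------

def _enumerate_hypergeom_tail(N, K, n, k):
    """P[X >= k] by exhaustive enumeration of the hypergeometric pmf."""
    return sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1)) \
        / comb(N, n)


def test_zero_count_not_tested_but_p_one_logic():
    counts = pd.DataFrame({"gene_id": ["g1", "g1"], "bin": [0, 1],
                           "count": [4, 1]})
    out = attr.hypergeom_interactions(counts)
    assert ((out["p"] >= 0) & (out["p"] <= 1)).all()


@pytest.mark.parametrize("N,K,n,k", [(20, 5, 4, 3), (12, 6, 6, 4), (30, 10, 9, 5)])
def test_hypergeom_p_matches_enumeration(N, K, n, k):
    # construct a count table realizing exactly these margins for pair (gA, b0)
    rows = [("gA", 0, k), ("gA", 1, K - k), ("gB", 0, n - k),
            ("gB", 1, N - K - (n - k))]
    counts = pd.DataFrame(rows, columns=["gene_id", "bin", "count"])
    out = attr.hypergeom_interactions(counts).set_index(["gene_id", "bin"])
    expected = _enumerate_hypergeom_tail(N, K, n, k)
    assert out.loc[("gA", 0), "p"] == pytest.approx(expected, rel=1e-12)


def test_impossible_count_rejected():
    counts = pd.DataFrame({"gene_id": ["g", "g"], "bin": [0, 1], "count": [5, -1]})
    with pytest.raises(ValueError):
        attr.hypergeom_interactions(counts)


def test_planted_enriched_pair_detected(rng):
    """A gene-bin pair far above the uniform rate is retained at q <= 0.05;
    uniform pairs mostly are not."""
    genes = [f"g{i}" for i in range(12)]
    rows = []
    for g in genes:
        for b in range(12):
            rows.append((g, b, int(rng.poisson(3))))
    rows.append(("g0", 0, 60))  # planted enrichment
    counts = pd.DataFrame(rows, columns=["gene_id", "bin", "count"])
    counts = counts.groupby(["gene_id", "bin"], as_index=False)["count"].sum()
    out = attr.hypergeom_interactions(counts)
    flagged = out[out["retained"]]
    assert ("g0", 0) in set(zip(flagged["gene_id"], flagged["bin"]))
    assert len(flagged) < 0.2 * len(out)


@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=30))
@settings(deadline=None, max_examples=50, derandomize=True)
def test_bh_q_monotone_in_p(pvals):
    from statsmodels.stats.multitest import multipletests
    p = np.sort(np.asarray(pvals))
    _, q, _, _ = multipletests(p, method="fdr_bh")
    assert (np.diff(q) >= -1e-12).all()


# ---------------------------------------------------------------------------
# candidate ranking
# ---------------------------------------------------------------------------

def _highconf(rows):
    df = pd.DataFrame(rows, columns=["gene_id", "bin", "count"])
    df["retained"] = True
    return df


def test_gene_only_in_extreme_bins_has_ratio_one():
    hc = _highconf([("g1", 3, 5), ("g1", 7, 4)])
    out = attr.rank_candidate_rnas(hc, region_bins=[3, 7]).set_index("gene_id")
    assert out.loc["g1", "ratio"] == 1.0


def test_gene_without_retained_interactions_excluded():
    hc = _highconf([("g1", 3, 5)])
    hc["retained"] = False
    out = attr.rank_candidate_rnas(hc, region_bins=[3])
    assert len(out) == 0


def test_ranking_matches_brute_force_on_fixture():
    region = {1, 2, 3}
    rows = [("gA", 1, 2), ("gA", 2, 2), ("gA", 9, 1),
            ("gB", 1, 2), ("gB", 8, 1), ("gB", 9, 1), ("gB", 7, 1),
            ("gC", 2, 9), ("gC", 3, 1),
            ("gD", 8, 1),
            ("gE", 1, 1), ("gE", 2, 1)]
    out = attr.rank_candidate_rnas(_highconf(rows), sorted(region))
    # brute force: counts in region -> gA 2, gB 1, gC 2, gD 0, gE 2
    # ratios: gA 2/3, gC 2/2, gE 2/2 -> order gC/gE by ratio then name, then gA
    assert list(out["gene_id"]) == ["gC", "gE", "gA", "gB", "gD"]
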
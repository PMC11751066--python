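"""Weighted Kendall tau, its permutation null and the TF screen."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from tfconcord.concordance import (InsufficientOverlapError, PairedRanks,
                                   asymptotic_p, compute_weights,
                                   null_variance, pair_ranks, permutation_p,
                                   screen_tfs, weighted_kendall_tau)
from tfconcord.motifs import TFGeneSet
from tfconcord.ranking import RankedGeneList


def make_set(tf_id, members):
    """members: [(gene_id, set_score)] already in descending-score order."""
    frame = pd.DataFrame(members, columns=["gene_id", "set_score"])
    frame["s_rank"] = np.arange(1, len(frame) + 1)
    return TFGeneSet(tf_id=tf_id, table=frame)


def make_list(genes, rdes=None):
    """RankedGeneList with the given gene order (rank 1 first)."""
    n = len(genes)
    rdes = list(rdes) if rdes is not None else list(range(n, 0, -1))
    frame = pd.DataFrame({
        "gene_id": genes, "log2fc": 0.0, "fdr": 0.5,
        "rde": rdes, "l_rank": np.arange(1, n + 1),
    })
    return RankedGeneList(frame=frame)


# -------------------------------------------------------------- pair_ranks

def test_pair_ranks_intersection_reranking():
    gs = make_set("TF", [("gA", 3.0), ("gB", 2.0), ("gC", 1.0)])
    gl = make_list(["gB", "gC", "gA"])
    paired = pair_ranks(gs, gl)
    assert paired.r.tolist() == [3, 1, 2]
    assert paired.gene_ids == ("gA", "gB", "gC")


def test_pair_ranks_identity_when_orders_agree():
    genes = [f"g{i}" for i in range(6)]
    gs = make_set("TF", [(g, 10.0 - i) for i, g in enumerate(genes)])
    paired = pair_ranks(gs, make_list(genes))
    assert paired.r.tolist() == list(range(1, 7))


def test_pair_ranks_drops_genes_outside_list():
    gs = make_set("TF", [("gA", 3.0), ("gX", 2.5), ("gB", 2.0), ("gC", 1.0)])
    gl = make_list(["gB", "gC", "gA", "gD"])
    paired = pair_ranks(gs, gl)
    assert paired.gene_ids == ("gA", "gB", "gC")
    assert paired.r.tolist() == [3, 1, 2]


def test_pair_ranks_insufficient_overlap():
    gs = make_set("TF", [("gA", 2.0), ("gB", 1.0)])
    with pytest.raises(InsufficientOverlapError, match="insufficient overlap"):
        pair_ranks(gs, make_list(["gA", "gZ"]))


# ---------------------------------------------------------------- weights

def _paired(n, seed=0, set_mass=None, list_mass=None):
    rng = np.random.default_rng(seed)
    return PairedRanks(r=rng.permutation(n) + 1,
                       gene_ids=tuple(f"g{i}" for i in range(n)),
                       set_mass=set_mass, list_mass=list_mass)


def test_uniform_weights():
    assert compute_weights(_paired(5), mode="uniform").tolist() == [0.5] * 5


def test_top_linear_weights_decrease():
    v = compute_weights(_paired(10), mode="top_linear")
    assert (np.diff(v) < 0).all() and (v > 0).all() and (v < 1).all()


def test_mixed_density_tracks_pooled_mass():
    n = 50
    heavy_top = np.exp(-np.arange(n) / 5.0)  # mass concentrated at top ranks
    paired = _paired(n, set_mass=heavy_top, list_mass=heavy_top)
    v = compute_weights(paired, mode="mixed_density")
    assert v[0] > v[-1]
    assert (v > 0).all() and (v < 1).all()


@pytest.mark.parametrize("mode", ["mixed_density", "uniform", "top_linear"])
def test_weights_in_unit_interval(mode):
    v = compute_weights(_paired(40, seed=3), mode=mode)
    assert (v > 0).all() and (v < 1).all()


def test_weights_do_not_depend_on_pairing():
    """The mixed-density weights are a function of the marginal
    orderings only, so permuting R must not change them (this is what
    keeps the permutation null exact)."""
    n = 30
    rng = np.random.default_rng(8)
    sm, lm = rng.uniform(0.1, 2.0, n), rng.uniform(0.1, 2.0, n)
    v1 = compute_weights(PairedRanks(r=np.arange(1, n + 1), gene_ids=(),
                                     set_mass=sm, list_mass=lm))
    v2 = compute_weights(PairedRanks(r=rng.permutation(n) + 1, gene_ids=(),
                                     set_mass=sm, list_mass=lm))
    assert v1 == pytest.approx(v2, abs=0)


# ------------------------------------------------------------------- tau

def test_tau_hand_derived_case():
    v = np.array([0.5, 0.3, 0.2])
    assert weighted_kendall_tau(v, np.array([1, 3, 2])) == pytest.approx(
        0.38 / 0.62, abs=1e-12)


def test_tau_extremes_any_weights():
    rng = np.random.default_rng(0)
    for _ in range(25):
        n = int(rng.integers(2, 30))
        v = rng.uniform(1e-3, 1.0, n)
        assert weighted_kendall_tau(v, np.arange(1, n + 1)) == pytest.approx(1.0, abs=1e-12)
        assert weighted_kendall_tau(v, np.arange(n, 0, -1)) == pytest.approx(-1.0, abs=1e-12)


def test_tau_constant_weights_equals_classical():
    rng = np.random.default_rng(1)
    for _ in range(25):
        n = int(rng.integers(3, 40))
        r = rng.permutation(n) + 1
        c = float(rng.uniform(0.05, 0.95))
        expected, _ = stats.kendalltau(np.arange(n), r)
        assert weighted_kendall_tau(np.full(n, c), r) == pytest.approx(
            expected, abs=1e-12)


def test_tau_scale_invariant():
    rng = np.random.default_rng(2)
    n = 25
    v = rng.uniform(0.05, 0.95, n)
    r = rng.permutation(n) + 1
    assert weighted_kendall_tau(v, r) == pytest.approx(
        weighted_kendall_tau(0.37 * v, r), abs=1e-12)


@given(st.integers(0, 2 ** 32 - 1), st.integers(2, 60))
def test_tau_bounded(seed, n):
    rng = np.random.default_rng(seed)
    v = rng.uniform(1e-4, 1.0, n)
    tau = weighted_kendall_tau(v, rng.permutation(n) + 1)
    assert -1.0 <= tau <= 1.0


def test_tau_input_validation():
    with pytest.raises(ValueError):
        weighted_kendall_tau(np.array([0.5]), np.array([1]))
    with pytest.raises(ValueError, match="positive"):
        weighted_kendall_tau(np.array([0.5, 0.0]), np.array([1, 2]))


# ----------------------------------------------------------- null variance

def test_null_variance_constant_weights_closed_form():
    for n in range(3, 31):
        v = np.full(n, 0.5)
        expected = 2 * (2 * n + 5) / (9 * n * (n - 1))
        assert null_variance(v) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("n", [4, 5, 6])
def test_null_variance_matches_enumeration(n):
    rng = np.random.default_rng(n)
    v = rng.uniform(0.05, 0.95, n)
    taus = [weighted_kendall_tau(v, np.array(p))
            for p in itertools.permutations(range(1, n + 1))]
    taus = np.array(taus)
    assert taus.mean() == pytest.approx(0.0, abs=1e-12)
    assert null_variance(v) == pytest.approx(taus.var(), abs=1e-12)


def test_null_variance_requires_three():
    with pytest.raises(ValueError):
        null_variance(np.array([0.5, 0.5]))


# ------------------------------------------------------------------ p-values

def test_asymptotic_p_known_values():
    ld, p = asymptotic_p(0.0, 0.3)
    assert ld == 0.0 and p == 1.0
    ld, p = asymptotic_p(0.38 / 0.62, 11 / 27)
    assert ld == pytest.approx(0.9602, abs=1e-3)
    assert p == pytest.approx(0.337, abs=1e-3)
    ld, _ = asymptotic_p(-0.4, 0.1)
    assert ld < 0
    with pytest.raises(ValueError):
        asymptotic_p(0.5, 0.0)


def test_permutation_p_exact_enumeration():
    v = np.full(3, 0.5)
    # identity: only identity and reversal reach |tau| = 1 among 3! = 6
    p = permutation_p(v, np.array([1, 2, 3]), exact=True)
    assert p == pytest.approx(2 / 6, abs=1e-12)
    # |tau| = 1/3 is matched or beaten by every permutation
    p = permutation_p(v, np.array([1, 3, 2]), exact=True)
    assert p == pytest.approx(1.0, abs=1e-12)


def test_permutation_p_identity_is_extreme():
    rng = np.random.default_rng(4)
    v = rng.uniform(0.1, 0.9, 10)
    p = permutation_p(v, np.arange(1, 11), n_perm=999, seed=7)
    assert p <= 0.01


def test_permutation_p_deterministic():
    rng = np.random.default_rng(5)
    v = rng.uniform(0.1, 0.9, 15)
    r = rng.permutation(15) + 1
    assert permutation_p(v, r, n_perm=499, seed=3) == permutation_p(
        v, r, n_perm=499, seed=3)
    with pytest.raises(ValueError):
        permutation_p(v, r, n_perm=50)


# -------------------------------------------------------------------- screen

def test_screen_single_tf_q_equals_p():
    genes = [f"g{i}" for i in range(20)]
    gs = make_set("TF", [(g, 20.0 - i) for i, g in enumerate(genes)])
    rng = np.random.default_rng(6)
    order = list(rng.permutation(genes))
    (res,) = screen_tfs([gs], make_list(order), weighting="uniform")
    assert res.q_value == pytest.approx(res.p_asym)
    assert res.direction == ("positive" if res.tau_w >= 0 else "negative")


def test_screen_skips_small_overlap():
    gs = make_set("TF", [("gA", 2.0), ("gB", 1.0)])
    assert screen_tfs([gs], make_list(["gA", "gB", "gC"])) == []


def test_screen_recovers_planted_repressor(small_bundle):
    top = small_bundle.results[0]
    assert top.tf_id == small_bundle.truth.focal_tf
    assert top.tau_w < 0 and top.direction == "negative"
    assert top.q_value == min(r.q_value for r in small_bundle.results)
    # decoys stay closer to the null than the planted regulator
    decoy_p = [r.p_asym for r in small_bundle.results
               if r.tf_id != small_bundle.truth.focal_tf]
    assert top.p_asym < min(decoy_p)


def test_screen_with_permutation_pvalues(small_bundle):
    focal_set = [gs for gs in small_bundle.gene_sets
                 if gs.tf_id == small_bundle.truth.focal_tf]
    (res,) = screen_tfs(focal_set, small_bundle.gene_list,
                        weighting="uniform", n_perm=199, seed=1)
    assert res.p_perm is not None and 0 < res.p_perm <= 1
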
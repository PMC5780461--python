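"""Association engine: normalization oracle, cpm arithmetic, filters,
single-pair tests, local/distal runs, direction/adjacency summaries,
synergy, BH oracle and permutation invariance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnvx._utils import bh_adjust
from cnvx.expr_assoc import (AssocThresholds, CountMatrix, adjacency,
                             compute_norm_factors, cpm, filter_genes_regions,
                             run_distal, run_local, summarize_directions,
                             synergy_score)
from cnvx.expr_assoc import test_association as single_pair_test
from cnvx.nbglm import DispersionModel


def _cm(counts, lib=None):
    df = pd.DataFrame(counts)
    df.index = [f"g{i}" for i in range(df.shape[0])]
    df.columns = [f"s{j}" for j in range(df.shape[1])]
    lib_s = None if lib is None else pd.Series(lib, index=df.columns, dtype=float)
    return CountMatrix.from_frame(df, lib_size=lib_s)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def test_identical_columns_give_unit_factors():
    rng = np.random.default_rng(0)
    col = rng.poisson(100, 500)
    cm = compute_norm_factors(_cm(np.column_stack([col] * 4)))
    assert np.allclose(cm.norm_factors, 1.0)


def test_pure_depth_difference_absorbed_by_library_size():
    rng = np.random.default_rng(1)
    col = rng.poisson(200, 1000)
    cm = compute_norm_factors(_cm(np.column_stack([col, 2 * col])))
    assert np.allclose(cm.norm_factors, 1.0, atol=1e-6)


def test_tmm_factors_match_brute_force_oracle():
    """Independent re-implementation of the doubly-trimmed mean rule."""
    rng = np.random.default_rng(2)
    Y = rng.negative_binomial(5, 0.05, size=(800, 5)).astype(float)
    Y[:100, 0] *= 4   # composition bias in sample 0
    cm = compute_norm_factors(_cm(Y))

    lib = Y.sum(axis=0)
    uq = [np.quantile(Y[:, j] / lib[j], 0.75) for j in range(5)]
    ref = int(np.argmin(np.abs(np.array(uq) - np.mean(uq))))
    raw = []
    for j in range(5):
        keep = (Y[:, j] > 0) & (Y[:, ref] > 0)
        po, pr = Y[keep, j] / lib[j], Y[keep, ref] / lib[ref]
        m = np.log2(po / pr)
        a = 0.5 * np.log2(po * pr)
        n = len(m)
        lo_m, hi_m = int(np.floor(n * 0.3)), n - int(np.floor(n * 0.3))
        lo_a, hi_a = int(np.floor(n * 0.05)), n - int(np.floor(n * 0.05))
        order_m = np.argsort(m)
        order_a = np.argsort(a)
        in_m = np.zeros(n, bool)
        in_m[order_m[lo_m:hi_m]] = True
        in_a = np.zeros(n, bool)
        in_a[order_a[lo_a:hi_a]] = True
        raw.append(2.0 ** np.mean(m[in_m & in_a]))
    oracle = np.array(raw) / np.exp(np.mean(np.log(raw)))
    assert np.allclose(cm.norm_factors.to_numpy(), oracle, atol=1e-8)


def test_all_zero_column_is_an_error():
    Y = np.ones((10, 3))
    Y[:, 1] = 0
    with pytest.raises(ValueError, match="s1"):
        compute_norm_factors(_cm(Y))


@pytest.mark.parametrize("count,lib,expected", [
    (0, 25e6, 0.0),
    (50, 25e6, 2.0),
])
def test_cpm_arithmetic(count, lib, expected):
    cm = _cm([[count], [int(lib) - count]], lib=[lib])
    assert cpm(cm, "g0", "s0") == pytest.approx(expected)


def test_cpm_of_whole_library_is_one_million():
    cm = _cm([[1000]], lib=[1000])
    assert cpm(cm, "g0", "s0") == pytest.approx(1e6)


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def _matrix(states, samples):
    return pd.DataFrame([states], index=["R1"], columns=samples)


def test_filter_drops_unexpressed_genes_and_small_groups():
    samples = [f"s{j}" for j in range(12)]
    counts = pd.DataFrame(
        [[4, 4, 4, 4, 5, 5, 5, 5, 0, 0, 0, 0],    # g0: max group mean 5 cpm
         [0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0]],   # g1: all-zero, always dropped
        index=["g0", "g1"], columns=samples)
    cm = CountMatrix.from_frame(counts, lib_size=pd.Series(1e6, index=samples))
    mat = _matrix([1] * 4 + [2] * 4 + [3] * 4, samples)
    th = AssocThresholds(r_cpm=3.0, s_min=4, alpha=0.05)
    designs = filter_genes_regions(cm, mat, th)
    assert designs["R1"].states == [1, 3]
    assert "g0" in designs["R1"].kept_genes and "g1" not in designs["R1"].kept_genes


def test_region_without_large_enough_deviating_group_excluded():
    samples = [f"s{j}" for j in range(10)]
    cm = _cm(np.full((3, 10), 50))
    cm.counts.columns = samples
    cm.lib_size.index = samples
    cm.norm_factors.index = samples
    mat = _matrix([1] * 3 + [2] * 7, samples)   # only 3 < s_min=4 deviating
    th = AssocThresholds(r_cpm=3.0, s_min=4, alpha=0.05)
    assert filter_genes_regions(cm, mat, th) == {}


def test_filter_group_mean_rule_toy():
    """Gene with group mean cpm 2.9 / 3.1 / 0.5 is kept at r=3 (max rule)."""
    samples = [f"s{j}" for j in range(15)]
    lib = pd.Series(1e6, index=samples)
    counts = pd.DataFrame(
        [[29, 29, 29, 29, 29, 31, 31, 31, 31, 31, 5, 5, 5, 5, 5]],
        index=["g0"], columns=samples)
    cm = CountMatrix.from_frame(counts, lib_size=lib * 10)   # cpm = count/10
    mat = _matrix([1] * 5 + [2] * 5 + [3] * 5, samples)
    th = AssocThresholds(r_cpm=3.0, s_min=4, alpha=0.05)
    designs = filter_genes_regions(cm, mat, th)
    assert designs["R1"].kept_genes == ["g0"]


# ---------------------------------------------------------------------------
# testing
# ---------------------------------------------------------------------------

def test_strict_dosage_gene_log2fc_and_direction(sim, geno_matrix, cm_norm, dispersion):
    rec = single_pair_test(cm_norm, geno_matrix, "L_MHC", "LOC_DOSAGE", dispersion,
                           states=[1])
    assert rec["log2fc"][1] == pytest.approx(-1.0, abs=0.25)
    assert rec["dosage_direction"] == "up_with_gain"
    assert rec["p"] < 1e-3


def test_empty_reference_group_is_error(cm_norm, geno_matrix):
    mat = geno_matrix.copy()
    mat.loc["L_MHC"] = 1
    with pytest.raises(ValueError, match="2n"):
        single_pair_test(cm_norm, mat, "L_MHC", "LOC_DOSAGE",
                         DispersionModel(common=0.2))


def test_run_local_no_overlapping_gene_gives_empty(cm_norm, geno_matrix, sim):
    _, res = sim
    regions = pd.DataFrame([("R_EMPTY", "chr3", 29_000_000, 29_010_000)],
                           columns=["region_id", "chrom", "start", "end"])
    mat = pd.DataFrame(2, index=["R_EMPTY"], columns=geno_matrix.columns)
    mat.iloc[0, :30] = 1
    rec = run_local(cm_norm, mat, regions, res.annotation,
                    AssocThresholds.local(), DispersionModel(common=0.2))
    assert rec.empty


def test_gene_overlapping_two_regions_tested_twice(cm_norm, geno_matrix, sim):
    """Splitting one region into two overlapping halves doubles the records."""
    _, res = sim
    cfg, _ = sim
    loc = cfg.loci[0]
    regions = pd.DataFrame([
        ("Ra", loc.chrom, loc.start, loc.end),
        ("Rb", loc.chrom, loc.start, loc.end),
    ], columns=["region_id", "chrom", "start", "end"])
    mat = pd.DataFrame([geno_matrix.loc["L_MHC"], geno_matrix.loc["L_MHC"]],
                       index=["Ra", "Rb"])
    rec = run_local(cm_norm, mat, regions, res.annotation, AssocThresholds.local(),
                    DispersionModel(common=0.2))
    per_gene = rec.groupby("gene_id").size()
    assert (per_gene == 2).all()


def test_single_pair_bh_equals_raw_p(cm_norm, geno_matrix):
    mat = geno_matrix.loc[["R727"]]
    sub = CountMatrix(cm_norm.counts.loc[["TGT_A01"]], cm_norm.lib_size,
                      cm_norm.norm_factors)
    rec = run_distal(sub, mat, AssocThresholds.distal(), DispersionModel(common=0.2))
    assert len(rec) == 1
    assert rec.iloc[0]["fdr"] == pytest.approx(rec.iloc[0]["p"])


def test_distal_recovers_targets_with_direction(sim, geno_matrix, cm_norm, dispersion):
    cfg, _ = sim
    rec = run_distal(cm_norm, geno_matrix, AssocThresholds.distal(), dispersion)
    sig = rec[rec["significant"]]
    found = set(zip(sig["region_id"], sig["gene_id"]))
    # deletion locus with beta>0 targets: expression up at loss = down with gain
    a_targets = {("R727", g) for g in cfg.loci[1].distal_targets}
    assert len(a_targets & found) / len(a_targets) >= 0.9
    dirs = sig[sig["region_id"] == "R727"].set_index("gene_id")["dosage_direction"]
    hits = [g for (_, g) in a_targets & found]
    assert (dirs.loc[hits] == "down_with_gain").mean() > 0.9


def test_sample_permutation_invariance(sim, geno_matrix, cm_norm, dispersion):
    _, res = sim
    rng = np.random.default_rng(5)
    perm = rng.permutation(cm_norm.samples).tolist()
    cm_p = cm_norm.subset_samples(perm)
    rec_a = run_distal(cm_norm, geno_matrix, AssocThresholds.distal(), dispersion)
    rec_b = run_distal(cm_p, geno_matrix[perm], AssocThresholds.distal(), dispersion)
    a = rec_a.set_index(["region_id", "gene_id"])["p"].sort_index()
    b = rec_b.set_index(["region_id", "gene_id"])["p"].sort_index()
    assert np.allclose(a.to_numpy(), b.to_numpy(), rtol=1e-8)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def test_summaries_match_brute_force_tally(sim, geno_matrix, cm_norm, dispersion):
    rec = run_distal(cm_norm, geno_matrix, AssocThresholds.distal(), dispersion)
    summ = summarize_directions(rec).set_index("region_id")
    sig = rec[rec["significant"]]
    for rid in summ.index:
        sub = sig[sig["region_id"] == rid]
        assert summ.at[rid, "n_up"] == sum(d == "up_with_gain" for d in sub["dosage_direction"])
        assert summ.at[rid, "n_down"] == sum(d == "down_with_gain" for d in sub["dosage_direction"])
        assert summ.at[rid, "high_impact"] == (len(sub) >= 10)

    adj = adjacency(rec, min_regions=1)
    for g in adj.index:
        assert adj.loc[g].sum() == sig[sig["gene_id"] == g]["region_id"].nunique()
    adj2 = adjacency(rec, min_regions=2)
    shared = [g for g in adj2.index if g.startswith("TGT_S")]
    assert len(shared) >= 4   # shared targets associate with both regulator regions


def test_no_significant_records_gives_zero_summary():
    rec = pd.DataFrame({"region_id": ["R1"], "gene_id": ["g"], "p": [0.9],
                        "dosage_direction": ["up_with_gain"], "significant": [False]})
    summ = summarize_directions(rec)
    assert (summ[["n_up", "n_down", "n_mixed"]].to_numpy() == 0).all()


# ---------------------------------------------------------------------------
# synergy
# ---------------------------------------------------------------------------

def _synergy_setup(interaction_log2, seed=0, n_cell=25):
    rng = np.random.default_rng(seed)
    n = 4 * n_cell
    samples = [f"s{j}" for j in range(n)]
    a = np.repeat([1, 1, 0, 0], n_cell)
    b = np.repeat([1, 0, 1, 0], n_cell)
    mu = 500.0 * 2.0 ** (0.8 * a + 0.6 * b + interaction_log2 * a * b)
    lam = rng.gamma(1 / 0.02, mu * 0.02)
    counts = pd.DataFrame({s: [rng.poisson(l)] for s, l in zip(samples, lam)},
                          index=["g0"])
    cm = CountMatrix.from_frame(counts, lib_size=pd.Series(1e6, index=samples))
    mat = pd.DataFrame([np.where(a == 1, 0, 2), np.where(b == 1, 3, 2)],
                       index=["RA", "RB"], columns=samples)
    return cm, mat


def test_additive_effects_give_near_zero_synergy():
    scores = []
    for seed in range(5):
        cm, mat = _synergy_setup(0.0, seed=seed)
        scores.append(synergy_score(cm, mat, "RA", 0, "RB", 3, "g0").score)
    assert np.all(np.abs(scores) < 0.2)


def test_synergy_term_recovered():
    scores = []
    for seed in range(5):
        cm, mat = _synergy_setup(1.0, seed=seed)
        scores.append(synergy_score(cm, mat, "RA", 0, "RB", 3, "g0").score)
    assert np.median(scores) == pytest.approx(1.0, abs=0.25)


def test_constant_expression_gives_exact_zero_synergy():
    samples = [f"s{j}" for j in range(8)]
    counts = pd.DataFrame([[50] * 8], index=["g0"], columns=samples)
    cm = CountMatrix.from_frame(counts, lib_size=pd.Series(1e6, index=samples))
    mat = pd.DataFrame([[0, 0, 0, 0, 2, 2, 2, 2], [3, 3, 2, 2, 3, 3, 2, 2]],
                       index=["RA", "RB"], columns=samples)
    res = synergy_score(cm, mat, "RA", 0, "RB", 3, "g0")
    assert res.score == 0.0


def test_small_cells_report_no_pvalue():
    cm, mat = _synergy_setup(1.0, n_cell=2)
    res = synergy_score(cm, mat, "RA", 0, "RB", 3, "g0")
    assert res.p is None and res.group_sizes["both"] == 2


def test_empty_neither_group_is_error():
    samples = ["s0", "s1", "s2"]
    counts = pd.DataFrame([[5, 5, 5]], index=["g0"], columns=samples)
    cm = CountMatrix.from_frame(counts, lib_size=pd.Series(1e6, index=samples))
    mat = pd.DataFrame([[0, 0, 2], [3, 2, 3]], index=["RA", "RB"], columns=samples)
    with pytest.raises(ValueError, match="neither"):
        synergy_score(cm, mat, "RA", 0, "RB", 3, "g0")


# ---------------------------------------------------------------------------
# BH oracle
# ---------------------------------------------------------------------------

def _bh_oracle(p):
    """Textbook step-up: q_i = min over j>=i of p_(j) * n / j."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p)
    q_sorted = np.empty(n)
    running = 1.0
    for rank in range(n - 1, -1, -1):
        running = min(running, p[order[rank]] * n / (rank + 1))
        q_sorted[rank] = running
    out = np.empty(n)
    out[order] = q_sorted
    return out


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=200))
def test_bh_matches_step_up_oracle(pvals):
    assert np.allclose(bh_adjust(pvals), _bh_oracle(pvals), atol=1e-12)
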
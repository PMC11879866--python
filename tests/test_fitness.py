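"""Normalization, fold-changes, the one-sided K-S test and classification."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crispri_art import fitness, simulate
from crispri_art.fitness import (
    NormalizationSpec,
    classify,
    gene_ks_enrichment,
    guide_effectiveness,
    guide_log2fc,
    ks_one_sided,
    ks_one_sided_permutation_pvalue,
    ks_one_sided_pvalue,
    normalize,
    plaque_metrics,
    qc_decile_filter,
    screen_fitness,
)


def _meta(conditions):
    rows = []
    for cond, reps in conditions.items():
        for r in range(1, reps + 1):
            rows.append((f"{cond}_rep{r}", cond, r, cond == "MOI0"))
    return pd.DataFrame(rows, columns=["sample_id", "condition", "replicate",
                                       "baseline"]).set_index("sample_id")


# ---------------------------------------------------------------------------
# QC decile filter
# ---------------------------------------------------------------------------

def test_decile_filter_removes_exactly_ten_percent_per_tail():
    rng = np.random.default_rng(1)
    counts = pd.DataFrame({"MOI0_rep1": rng.integers(1, 1000, size=100)},
                          index=[f"g{i:03d}" for i in range(100)])
    kept, excluded = qc_decile_filter(counts, ["MOI0_rep1"])
    assert len(kept) == 80
    assert (excluded["tail"] == "low").sum() == 10
    assert (excluded["tail"] == "high").sum() == 10
    lo = excluded.loc[excluded["tail"] == "low", "baseline_mean"].max()
    hi = excluded.loc[excluded["tail"] == "high", "baseline_mean"].min()
    assert kept["MOI0_rep1"].between(lo, hi).all()


def test_decile_filter_skipped_below_ten_guides(caplog):
    counts = pd.DataFrame({"b": [1, 2, 3, 4, 5]}, index=list("abcde"))
    with caplog.at_level("WARNING"):
        kept, excluded = qc_decile_filter(counts, ["b"])
    assert len(kept) == 5 and excluded.empty


def test_decile_filter_tie_break_is_deterministic():
    counts = pd.DataFrame({"b": [7] * 20}, index=[f"g{i:02d}" for i in range(20)])
    kept1, exc1 = qc_decile_filter(counts, ["b"])
    kept2, exc2 = qc_decile_filter(counts, ["b"])
    assert list(kept1.index) == list(kept2.index)
    assert exc1.equals(exc2)
    # ties resolve by input order: first two and last two guides go
    assert set(exc1["guide_id"]) == {"g00", "g01", "g18", "g19"}


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def test_phage_mode_scales_columns_to_one_million():
    counts = pd.DataFrame({"s": [10, 30, 60]})
    norm = normalize(counts, NormalizationSpec("phage_pseudo1e6"))
    assert np.allclose(norm["s"], [1e5, 3e5, 6e5])
    assert norm["s"].sum() == pytest.approx(1e6)


def test_rpm_mode_adds_pseudocount_before_scaling():
    counts = pd.DataFrame({"s": [0, 1, 1, 1]})
    norm = normalize(counts, NormalizationSpec("rpm_plus1"))
    # shifted column [1, 2, 2, 2] sums to 7: zero raw count -> 1/7 * 1e6
    assert norm["s"].iloc[0] == pytest.approx(1 / 7 * 1e6)
    assert norm["s"].sum() == pytest.approx(1e6)


def test_rpm_pseudocount_floor_matches_printed_example():
    # zero raw count in a column whose shifted total is 1e6 -> exactly 1 rpm-unit
    counts = pd.DataFrame({"s": [0, 999_999 - 1]})
    norm = normalize(counts, NormalizationSpec("rpm_plus1"))
    assert norm["s"].iloc[0] == pytest.approx(1.0)


def test_all_zero_column_is_an_error():
    with pytest.raises(ValueError, match="all-zero"):
        normalize(pd.DataFrame({"bad": [0, 0]}), NormalizationSpec())


def test_center_log_option_centers_log_counts():
    counts = pd.DataFrame({"s": [1, 10, 100]})
    norm = normalize(counts, NormalizationSpec(center_log=True))
    assert np.log(norm["s"]).mean() == pytest.approx(0.0, abs=1e-12)


def test_normalization_is_scale_invariant_and_idempotent():
    rng = np.random.default_rng(2)
    counts = pd.DataFrame({"a": rng.integers(1, 100, 50),
                           "b": rng.integers(1, 100, 50)})
    spec = NormalizationSpec()
    once = normalize(counts, spec)
    rescaled = normalize(once * 37.5, spec)
    twice = normalize(once, spec)
    assert np.allclose(once, rescaled) and np.allclose(once, twice)


# ---------------------------------------------------------------------------
# log2 fold-changes
# ---------------------------------------------------------------------------

def test_identical_counts_give_zero_log2fc():
    meta = _meta({"MOI0": 2, "MOI10": 2})
    norm = pd.DataFrame(
        {s: [100.0, 200.0] for s in meta.index},
        index=["g1", "g2"])
    out = guide_log2fc(norm, meta, "MOI10", "MOI0")
    assert np.allclose(out[["log2fc_MOI10_rep1", "log2fc_MOI10_rep2"]], 0)
    assert np.allclose(out["crrna_fitness"], 0)


def test_fourfold_enrichment_gives_log2fc_two():
    meta = _meta({"MOI0": 2, "MOI10": 3})
    norm = pd.DataFrame({
        "MOI0_rep1": [10.0], "MOI0_rep2": [10.0],
        "MOI10_rep1": [40.0], "MOI10_rep2": [40.0], "MOI10_rep3": [40.0],
    }, index=["g1"])
    out = guide_log2fc(norm, meta, "MOI10", "MOI0")
    assert out["crrna_fitness"].iloc[0] == pytest.approx(2.0)
    assert out["mean_log2fc"].iloc[0] == pytest.approx(2.0)


def test_random_table_matches_spreadsheet_recomputation():
    rng = np.random.default_rng(3)
    meta = _meta({"MOI0": 3, "MOI10": 3})
    norm = pd.DataFrame(rng.uniform(1, 1000, size=(20, 6)),
                        columns=list(meta.index),
                        index=[f"g{i}" for i in range(20)])
    out = guide_log2fc(norm, meta, "MOI10", "MOI0")
    tests = [f"MOI10_rep{r}" for r in (1, 2, 3)]
    for g in norm.index:
        base = sum(norm.loc[g, f"MOI0_rep{r}"] for r in (1, 2, 3)) / 3
        ratios = [math.log2(norm.loc[g, s] / base) for s in tests]
        assert out.loc[g, "crrna_fitness"] == pytest.approx(
            sorted(ratios)[1], abs=1e-9)
        assert out.loc[g, "mean_log2fc"] == pytest.approx(
            sum(ratios) / 3, abs=1e-9)
        t_expected = stats.ttest_1samp(ratios, 0.0).pvalue
        assert out.loc[g, "t_p_value"] == pytest.approx(t_expected, rel=1e-9)


def test_single_replicate_reports_missing_p():
    meta = _meta({"MOI0": 1, "MOI10": 1})
    norm = pd.DataFrame({"MOI0_rep1": [8.0], "MOI10_rep1": [16.0]}, index=["g"])
    out = guide_log2fc(norm, meta, "MOI10", "MOI0")
    assert out["crrna_fitness"].iloc[0] == pytest.approx(1.0)
    assert np.isnan(out["t_p_value"].iloc[0])


def test_replicate_mean_vs_t0_mode():
    meta = _meta({"T0": 1, "dCas13d": 2}).rename(
        index=lambda s: s)  # condition labels arbitrary
    meta["baseline"] = meta["condition"] == "T0"
    norm = pd.DataFrame({"T0_rep1": [10.0], "dCas13d_rep1": [30.0],
                         "dCas13d_rep2": [50.0]}, index=["g"])
    out = guide_log2fc(norm, meta, "dCas13d", "T0", mode="replicate_mean_vs_t0")
    assert out["mean_log2fc"].iloc[0] == pytest.approx(math.log2(40 / 10))


# ---------------------------------------------------------------------------
# One-sided K-S
# ---------------------------------------------------------------------------

def test_gene_equal_to_pool_gives_d_zero_p_one():
    vals = np.arange(10.0)
    assert ks_one_sided(vals, vals) == 0.0
    assert ks_one_sided_pvalue(0.0, 10, 10) == 1.0


def test_gene_above_pool_maximum_hits_bounded_d():
    m, n_other = 3, 100
    others = np.linspace(-1, 1, n_other)
    gene = np.array([5.0, 6.0, 7.0])
    pooled = np.concatenate([others, gene])
    d = ks_one_sided(gene, pooled)
    assert d == pytest.approx(1 - m / (m + n_other))
    p = ks_one_sided_pvalue(d, m, len(pooled))
    assert p < 0.05


def test_d_matches_exhaustive_sup_on_small_instances():
    rng = np.random.default_rng(4)
    for _ in range(50):
        m, n = int(rng.integers(1, 5)), int(rng.integers(5, 13))
        pooled = rng.normal(size=n)
        gene = pooled[rng.choice(n, size=m, replace=False)]
        # exhaustive oracle over a dense grid spanning all sample points
        grid = np.concatenate([pooled, gene])
        grid = np.concatenate([grid - 1e-9, grid, grid + 1e-9])
        f_pool = (pooled[None, :] <= grid[:, None]).mean(axis=1)
        f_gene = (gene[None, :] <= grid[:, None]).mean(axis=1)
        assert ks_one_sided(gene, pooled) == pytest.approx(
            max((f_pool - f_gene).max(), 0.0), abs=1e-9)


def test_d_agrees_with_scipy_one_sided_statistic():
    rng = np.random.default_rng(5)
    for _ in range(25):
        gene = rng.normal(1, 1, size=int(rng.integers(2, 9)))
        pooled = rng.normal(0, 1, size=60)
        ours = ks_one_sided(gene, pooled)
        ref = stats.ks_2samp(pooled, gene, alternative="greater").statistic
        assert ours == pytest.approx(ref, abs=1e-12)


def test_permutation_p_agrees_with_independent_oracle():
    rng = np.random.default_rng(6)
    pooled = rng.normal(size=12)
    gene = np.sort(pooled)[-3:]  # top 3 of 12
    p_pkg = ks_one_sided_permutation_pvalue(gene, pooled)  # exact enumeration
    # independent Monte Carlo oracle with its own D computation
    d_obs = max(np.mean(pooled <= x) - np.mean(gene <= x)
                for x in np.concatenate([pooled, pooled - 1e-9]))
    oracle_rng = np.random.default_rng(7)
    hits = 0
    n_mc = 20_000
    for _ in range(n_mc):
        g = pooled[oracle_rng.choice(12, size=3, replace=False)]
        d = max(np.mean(pooled <= x) - np.mean(g <= x)
                for x in np.concatenate([pooled, pooled - 1e-9]))
        hits += d >= d_obs - 1e-12
    p_mc = (hits + 1) / (n_mc + 1)
    assert p_pkg == pytest.approx(1 / 220, abs=1e-12)
    assert 0.5 <= p_pkg / p_mc <= 2.0


def test_gene_table_aggregation_and_fitness_definition():
    meta = _meta({"MOI0": 3, "MOI10": 3})
    rng = np.random.default_rng(8)
    guides = [f"gA_{i}" for i in range(4)] + [f"gB_{i}" for i in range(4)]
    norm = pd.DataFrame(rng.uniform(10, 100, size=(8, 6)),
                        columns=list(meta.index), index=guides)
    gmap = pd.Series(["geneA"] * 4 + ["geneB"] * 4, index=guides)
    gfc = guide_log2fc(norm, meta, "MOI10", "MOI0", gene_map=gmap)
    table = gene_ks_enrichment(gfc)
    rep_cols = [c for c in gfc.columns if c.startswith("log2fc_")]
    for gene, ids in (("geneA", guides[:4]), ("geneB", guides[4:])):
        expected = gfc.loc[ids, rep_cols].mean(axis=0).mean()
        assert table.loc[gene, "fitness"] == pytest.approx(expected)
        assert table.loc[gene, "n_guides_used"] == 4
        assert 0 <= table.loc[gene, "ks_D"] <= 1
        assert 0 <= table.loc[gene, "ks_p"] <= 1


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def test_single_significant_winner_sets_threshold():
    table = pd.DataFrame({
        "fitness": [5.0, 0.1, -0.2, 0.0],
        "ks_D": [0.9, 0.2, 0.1, 0.1],
        "ks_p": [0.001, 0.8, 0.9, 0.7],
        "n_guides_used": [7] * 4,
    }, index=["win", "a", "b", "c"])
    out, threshold = classify(table)
    assert threshold == 5.0
    assert out.loc["win", "call"] == "Fit"
    assert (out.drop("win")["call"] == "Not_fit").all()


def test_semi_fit_requires_threshold_but_not_significance():
    table = pd.DataFrame({
        "fitness": [4.0, 4.5, 0.0, -1.0],
        "ks_p": [0.01, 0.5, 0.9, 0.9],
    }, index=["fit", "semi", "x", "y"])
    out, threshold = classify(table)
    assert threshold == 4.0
    assert out.loc["fit", "call"] == "Fit"
    assert out.loc["semi", "call"] == "Semi_fit"


def test_no_significant_gene_means_all_not_fit():
    table = pd.DataFrame({"fitness": [1.0, 2.0], "ks_p": [0.5, 0.6]},
                         index=["a", "b"])
    out, threshold = classify(table)
    assert threshold is None and (out["call"] == "Not_fit").all()


def test_negative_tail_significance_is_never_interpreted():
    # strongly depleted gene with tiny p must not become Fit
    table = pd.DataFrame({"fitness": [-6.0, 0.1, 0.2, 0.3],
                          "ks_p": [1e-9, 0.9, 0.8, 0.7]},
                         index=["depleted", "a", "b", "c"])
    out, threshold = classify(table)
    assert threshold is None
    assert out.loc["depleted", "call"] == "Not_fit"


# ---------------------------------------------------------------------------
# Guide effectiveness
# ---------------------------------------------------------------------------

def _guide_fitness_frame(gene_values: dict[str, list[float]]):
    rows = []
    for gene, vals in gene_values.items():
        for i, v in enumerate(vals, start=1):
            rows.append((f"{gene}_crRNA{i}", gene, v))
    df = pd.DataFrame(rows, columns=["guide_id", "gene_id", "crrna_fitness"])
    return df.set_index("guide_id")


def test_identical_guide_fitness_gives_zero_z_scores():
    gf = _guide_fitness_frame({"g1": [2.0] * 7})
    gene = pd.DataFrame({"fitness": [2.0]}, index=["g1"])
    pos = pd.Series({f"g1_crRNA{i}": i for i in range(1, 8)})
    zs, tally = guide_effectiveness(gf, gene, pos, top_k_genes=1)
    assert np.allclose(zs["z_score"], 0)
    assert list(zs.sort_values("rank")["position"])[:3] == [1, 2, 3]  # tie-break
    assert tally.sum() == 3


def test_z_scores_match_direct_computation():
    gf = _guide_fitness_frame({"g1": [1.0, 2.0, 3.0], "g2": [5.0, 5.0, 8.0]})
    gene = pd.DataFrame({"fitness": [2.0, 6.0]}, index=["g1", "g2"])
    pos = pd.Series({g: int(g[-1]) for g in gf.index})
    zs, tally = guide_effectiveness(gf, gene, pos, top_k_genes=2)
    for gene_id in ("g1", "g2"):
        vals = gf.loc[gf["gene_id"] == gene_id, "crrna_fitness"].to_numpy()
        expected = (vals - vals.mean()) / vals.std(ddof=0)
        got = zs.loc[zs["gene_id"] == gene_id, "z_score"].to_numpy()
        assert np.allclose(got, expected)
    assert tally.sum() == 2 * 3  # 3 top ranks per gene


# ---------------------------------------------------------------------------
# Plaque metrics
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("cond,ctrl,expected", [
    ([10, 10, 10], [10, 10, 10], 1.0),
    ([10, 10, 10], [1000, 1000, 1000], 0.01),
    ([2, 4], [4, 8], 0.5),
])
def test_ratio_of_means(cond, ctrl, expected):
    assert plaque_metrics(cond, ctrl) == pytest.approx(expected)


def test_zero_control_mean_errors():
    with pytest.raises(ValueError, match="control mean"):
        plaque_metrics([1, 2], [0, 0])


# ---------------------------------------------------------------------------
# Pipeline-level invariants
# ---------------------------------------------------------------------------

def _screen(seed, n_genes=40, frac=0.1, reads=200_000):
    lib = pd.DataFrame({
        "guide_id": [f"g{i:03d}_crRNA{k}" for i in range(n_genes)
                     for k in range(1, 8)],
        "gene_id": [f"g{i:03d}" for i in range(n_genes) for k in range(1, 8)],
    })
    cfg = simulate.SimConfig(n_genes=n_genes, fraction_fit_genes=frac,
                             reads_per_sample=reads, seed=seed)
    matrix, truth = simulate.simulate_screen(lib, None, cfg)
    return lib, matrix, truth


def test_unrelated_sample_columns_do_not_change_a_contrast():
    lib, matrix, _ = _screen(seed=21)
    gene_map = lib.set_index("guide_id")["gene_id"]
    full = screen_fitness(matrix, "MOI10", "MOI0", gene_map)
    # add an irrelevant condition column; the MOI10-vs-MOI0 contrast is fixed
    extra = matrix.counts.copy()
    extra["other_rep1"] = extra["MOI0_rep1"].to_numpy()[::-1]
    meta = matrix.sample_meta.copy()
    meta.loc["other_rep1"] = ["other", 1, False]
    from crispri_art.counting import CountMatrix
    bigger = CountMatrix(extra, meta)
    out = screen_fitness(bigger, "MOI10", "MOI0", gene_map)
    pd.testing.assert_frame_equal(full["gene_fitness"], out["gene_fitness"])


def test_pipeline_is_deterministic():
    lib, matrix, _ = _screen(seed=22)
    gene_map = lib.set_index("guide_id")["gene_id"]
    a = screen_fitness(matrix, "MOI10", "MOI0", gene_map)
    b = screen_fitness(matrix, "MOI10", "MOI0", gene_map)
    pd.testing.assert_frame_equal(a["gene_fitness"], b["gene_fitness"])
    pd.testing.assert_frame_equal(a["guide_fitness"], b["guide_fitness"])
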
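"""Guide- and gene-level fitness inference for pooled screens.

The analysis chain is: (1) exclude the most extreme deciles of the
unselected-control count distribution (guides whose baseline abundance is
in the top or bottom 10%), (2) normalize each sample column (phage mode:
scale to a fixed 1e6 pseudocount total; rich-medium mode: add 1 to every
raw count, then convert to reads per million), (3) per-guide log2
fold-changes of selected vs baseline with a two-sided t-test across
replicates, (4) per-gene comparison of the gene's guide fold-change
distribution against the library-wide distribution with a one-sided
(unidirectional) two-sample Kolmogorov-Smirnov test that detects a
right-shift (protective enrichment), and (5) Fit / Semi-fit / Not-fit
calls from the lowest significantly enriched fitness value.

Positive fitness means guides against the gene protected the host and
enriched under selection; significant *negative* shifts are deliberately
never interpreted (strong selection at high MOI distorts the left tail).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NormalizationSpec:
    """How raw counts become comparable abundances.

    ``phage_pseudo1e6``: scale each (post-QC) sample column to a total of
    ``scale`` pseudocounts.  ``rpm_plus1``: add ``pseudocount`` to every
    raw count, then convert to reads per million.  ``center_log``
    additionally divides each scaled column by its geometric mean
    (centering log-counts around zero) — an alternative reading of
    per-sample centering; off by default because only total-scaling keeps
    fold-change denominators on a common count scale.
    """

    mode: str = "phage_pseudo1e6"
    scale: float = 1e6
    pseudocount: float = 1.0
    center_log: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("phage_pseudo1e6", "rpm_plus1"):
            raise ValueError(f"unknown normalization mode {self.mode!r}")
        if self.scale <= 0 or self.pseudocount < 0:
            raise ValueError("scale must be > 0 and pseudocount >= 0")


# ---------------------------------------------------------------------------
# QC and normalization
# ---------------------------------------------------------------------------

def qc_decile_filter(
    counts: pd.DataFrame,
    baseline_samples: list[str],
    lower_frac: float = 0.10,
    upper_frac: float = 0.10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop guides in the extreme tails of the baseline count distribution.

    Guides are ranked by mean count across the baseline (unselected)
    samples; ``floor(lower_frac * N)`` lowest and ``floor(upper_frac * N)``
    highest are excluded.  Ties resolve by input guide order (stable
    sort), so re-running is deterministic.  Returns ``(kept_counts,
    exclusions)`` where exclusions lists guide_id, mean baseline count,
    rank and tail.  With fewer than 10 guides the filter is skipped.
    """
    if not baseline_samples:
        raise ValueError("qc_decile_filter needs at least one baseline sample")
    n = len(counts)
    empty = pd.DataFrame(columns=["guide_id", "baseline_mean", "rank", "tail"])
    if n < 10:
        logger.warning("only %d guides: decile filter skipped", n)
        return counts, empty
    means = counts[baseline_samples].mean(axis=1).to_numpy()
    order = np.argsort(means, kind="stable")
    k_lo = math.floor(lower_frac * n)
    k_hi = math.floor(upper_frac * n)
    low_idx = order[:k_lo]
    high_idx = order[n - k_hi:] if k_hi else np.array([], dtype=int)
    rows = []
    for rank, i in enumerate(low_idx):
        rows.append((counts.index[i], means[i], rank, "low"))
    for rank, i in enumerate(high_idx):
        rows.append((counts.index[i], means[i], n - k_hi + rank, "high"))
    excluded = pd.DataFrame(rows, columns=["guide_id", "baseline_mean", "rank", "tail"])
    drop = set(excluded["guide_id"])
    kept = counts.loc[[g for g in counts.index if g not in drop]]
    return kept, excluded


def normalize(counts: pd.DataFrame, spec: NormalizationSpec | None = None) -> pd.DataFrame:
    """Normalize each sample column per the spec; returns float matrix."""
    spec = spec or NormalizationSpec()
    zero = counts.sum(axis=0) == 0
    if zero.any():
        raise ValueError(f"all-zero sample column(s): {list(counts.columns[zero])}")
    if spec.mode == "phage_pseudo1e6":
        out = counts / counts.sum(axis=0) * spec.scale
    else:
        shifted = counts + spec.pseudocount
        out = shifted / shifted.sum(axis=0) * 1e6
    if spec.center_log:
        if (out.values <= 0).any():
            raise ValueError("center_log requires strictly positive "
                             "normalized counts (use rpm_plus1 or run QC)")
        out = out / np.exp(np.log(out).mean(axis=0))
    return out


# ---------------------------------------------------------------------------
# Guide fold-changes
# ---------------------------------------------------------------------------

def guide_log2fc(
    norm: pd.DataFrame,
    sample_meta: pd.DataFrame,
    test_condition: str,
    baseline_condition: str,
    mode: str = "per_sample_vs_baseline_mean",
    gene_map: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-guide log2 fold-changes of test samples over the baseline.

    ``per_sample_vs_baseline_mean`` (phage screens): each test sample is
    divided by the guide's mean normalized count across baseline samples,
    giving one log2 ratio per replicate.  ``replicate_mean_vs_t0``
    (growth assays): test replicates are first averaged, then divided by
    the baseline mean, and the same per-replicate ratios are retained for
    the t-test.  The summary ``crrna_fitness`` is the median across
    replicates and ``mean_log2fc`` the mean; ``t_p_value`` is a two-sided
    one-sample t-test of the per-replicate log2 ratios against zero
    (reported as NaN with fewer than two replicates).
    """
    if mode not in ("per_sample_vs_baseline_mean", "replicate_mean_vs_t0"):
        raise ValueError(f"unknown log2fc mode {mode!r}")
    meta = sample_meta.loc[list(norm.columns)]
    test_samples = list(meta.index[meta["condition"] == test_condition])
    base_samples = list(meta.index[meta["condition"] == baseline_condition])
    if not test_samples or not base_samples:
        raise ValueError(
            f"conditions {test_condition!r} / {baseline_condition!r} not both "
            "present in the sample sheet"
        )
    base_mean = norm[base_samples].mean(axis=1)
    if (base_mean <= 0).any():
        raise ValueError("baseline mean must be positive for every guide "
                         "(normalize with pseudocounts or run QC first)")
    ratios = np.log2(norm[test_samples].div(base_mean, axis=0))
    ratios.columns = [f"log2fc_{s}" for s in test_samples]
    out = pd.DataFrame(index=norm.index)
    if gene_map is not None:
        out["gene_id"] = gene_map.reindex(norm.index)
    for c in ratios.columns:
        out[c] = ratios[c]
    if mode == "per_sample_vs_baseline_mean":
        out["mean_log2fc"] = ratios.mean(axis=1)
    else:
        out["mean_log2fc"] = np.log2(norm[test_samples].mean(axis=1) / base_mean)
    out["crrna_fitness"] = ratios.median(axis=1)
    if ratios.shape[1] >= 2:
        res = stats.ttest_1samp(ratios.to_numpy(), 0.0, axis=1)
        out["t_p_value"] = res.pvalue
    else:
        out["t_p_value"] = np.nan
    return out


# ---------------------------------------------------------------------------
# Unidirectional K-S gene enrichment
# ---------------------------------------------------------------------------

def ks_one_sided(gene_values: np.ndarray, pooled_values: np.ndarray) -> float:
    """D = sup_x [F_pooled(x) - F_gene(x)]: right-shift of the gene sample.

    Both ECDFs are step functions, so the supremum is attained at a sample
    point (evaluated from the right) or immediately left of one.
    """
    gene = np.sort(np.asarray(gene_values, dtype=float))
    pooled = np.sort(np.asarray(pooled_values, dtype=float))
    xs = np.concatenate([gene, pooled])
    m, n = len(gene), len(pooled)
    f_gene_right = np.searchsorted(gene, xs, side="right") / m
    f_pool_right = np.searchsorted(pooled, xs, side="right") / n
    f_gene_left = np.searchsorted(gene, xs, side="left") / m
    f_pool_left = np.searchsorted(pooled, xs, side="left") / n
    d = max((f_pool_right - f_gene_right).max(), (f_pool_left - f_gene_left).max())
    return float(max(d, 0.0))


def ks_one_sided_pvalue(d: float, m: int, n: int) -> float:
    """Asymptotic one-sided p: exp(-2 D^2 m n / (m + n)), clipped to [0, 1]."""
    if m <= 0 or n <= 0:
        return float("nan")
    return float(min(1.0, math.exp(-2.0 * d * d * m * n / (m + n))))


def _ks_d_subsets(subsets_sorted: np.ndarray, pooled_sorted: np.ndarray) -> np.ndarray:
    """One-sided D for many row-sorted gene subsets against one pooled ECDF.

    The supremum of ``F_pool - F_gene`` is attained immediately left of a
    gene sample point or at one (right limit), so it reduces to
    searchsorted ranks; this matches :func:`ks_one_sided` and is purely
    vectorized.
    """
    n_sub, m = subsets_sorted.shape
    n = len(pooled_sorted)
    flat = subsets_sorted.ravel()
    right = np.searchsorted(pooled_sorted, flat, side="right").reshape(n_sub, m) / n
    left = np.searchsorted(pooled_sorted, flat, side="left").reshape(n_sub, m) / n
    i = np.arange(1, m + 1)
    d = np.maximum((right - i / m).max(axis=1), (left - (i - 1) / m).max(axis=1))
    return np.maximum(d, 0.0)


def ks_one_sided_null(
    m: int,
    pooled_sorted: np.ndarray,
    n_perm: int = 10_000,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Monte Carlo null distribution of D: random m-subsets of the pool."""
    rng = rng or np.random.default_rng(0)
    n = len(pooled_sorted)
    idx = np.argsort(rng.random((n_perm, n)), axis=1)[:, :m]
    subsets = np.sort(pooled_sorted[idx], axis=1)
    return _ks_d_subsets(subsets, pooled_sorted)


def ks_one_sided_permutation_pvalue(
    gene_values: np.ndarray,
    pooled_values: np.ndarray,
    n_perm: int = 100_000,
    rng: np.random.Generator | None = None,
    max_exact: int = 50_000,
    null_d: np.ndarray | None = None,
) -> float:
    """Permutation/enumeration p for the one-sided D (small gene panels).

    The pooled sample is taken as the population; the null re-draws which
    ``m`` members form the gene.  Full enumeration is used when the number
    of subsets is small, otherwise Monte Carlo draws (add-one estimator);
    a precomputed ``null_d`` array (from :func:`ks_one_sided_null`) may be
    supplied to share the null across genes with equal panel size.
    """
    gene = np.asarray(gene_values, dtype=float)
    pooled = np.sort(np.asarray(pooled_values, dtype=float))
    m, n = len(gene), len(pooled)
    d_obs = ks_one_sided(gene, pooled)
    tol = 1e-12
    if null_d is None and math.comb(n, m) <= max_exact:
        subsets = np.array(list(itertools.combinations(range(n), m)))
        d_all = _ks_d_subsets(np.sort(pooled[subsets], axis=1), pooled)
        return float(np.count_nonzero(d_all >= d_obs - tol) / len(d_all))
    if null_d is None:
        null_d = ks_one_sided_null(m, pooled, n_perm=n_perm, rng=rng)
    hits = int(np.count_nonzero(null_d >= d_obs - tol))
    return (hits + 1) / (len(null_d) + 1)


def gene_ks_enrichment(
    guide_fitness: pd.DataFrame,
    gene_map: pd.Series | None = None,
    p_method: str = "asymptotic",
    small_m: int = 5,
    n_perm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-gene fitness plus one-sided K-S enrichment vs the whole library.

    The reference distribution is the pooled ``crrna_fitness`` of every
    surviving guide in the library (the tested gene's guides included).
    ``fitness`` is the mean over replicates of the per-replicate mean of
    the gene's guide log2 fold-changes.  ``p_method``: ``"asymptotic"``
    (default) uses the exponential form everywhere; ``"auto"`` switches
    to a permutation p for genes with fewer than ``small_m`` guides,
    where the asymptotic form is least accurate.
    """
    if gene_map is not None:
        genes = gene_map.reindex(guide_fitness.index)
    elif "gene_id" in guide_fitness.columns:
        genes = guide_fitness["gene_id"]
    else:
        raise ValueError("gene_ks_enrichment needs a gene_id column or gene_map")
    pooled = guide_fitness["crrna_fitness"].to_numpy(dtype=float)
    pooled_sorted = np.sort(pooled)
    rep_cols = [c for c in guide_fitness.columns if c.startswith("log2fc_")]
    n_total = len(pooled)
    rng = np.random.default_rng(seed)
    null_cache: dict[int, np.ndarray] = {}
    rows = []
    for gene_id, idx in genes.groupby(genes).groups.items():
        sub = guide_fitness.loc[idx]
        vals = sub["crrna_fitness"].to_numpy(dtype=float)
        m = len(vals)
        if m == 0:
            rows.append((gene_id, np.nan, np.nan, np.nan, 0))
            continue
        # mean over replicates of per-replicate mean of guide log2FCs
        fit = float(sub[rep_cols].mean(axis=0).mean()) if rep_cols else float(vals.mean())
        d = ks_one_sided(vals, pooled_sorted)
        if (p_method == "auto" and m < small_m) or p_method == "permutation":
            if m not in null_cache:
                null_cache[m] = ks_one_sided_null(m, pooled_sorted,
                                                  n_perm=n_perm, rng=rng)
            p = ks_one_sided_permutation_pvalue(vals, pooled_sorted,
                                                null_d=null_cache[m])
        else:
            p = ks_one_sided_pvalue(d, m, n_total)
        rows.append((gene_id, fit, d, p, m))
    table = pd.DataFrame(rows, columns=["gene_id", "fitness", "ks_D", "ks_p",
                                        "n_guides_used"])
    return table.set_index("gene_id").sort_index()


def classify(gene_table: pd.DataFrame, alpha: float = 0.05) -> tuple[pd.DataFrame, float | None]:
    """Fit / Semi-fit / Not-fit calls from the significance-derived threshold.

    The fitness threshold T is the lowest fitness among genes that are
    significantly right-shifted (ks_p < alpha) AND sit above the genome
    median fitness (so the left tail is never interpreted).  Fit: fitness
    >= T and ks_p < alpha.  Semi-fit: fitness >= T but ks_p >= alpha
    (strong but guide-variable enrichment).  Everything else: Not-fit.
    If no gene reaches significance, every gene is Not-fit and T is None.
    """
    if gene_table.empty:
        raise ValueError("classify needs a non-empty gene table")
    table = gene_table.copy()
    median = table["fitness"].median()
    sig_right = table[(table["ks_p"] < alpha) & (table["fitness"] > median)]
    if sig_right.empty:
        table["call"] = "Not_fit"
        return table, None
    threshold = float(sig_right["fitness"].min())
    above = table["fitness"] >= threshold
    sig = table["ks_p"] < alpha
    table["call"] = np.where(above & sig, "Fit",
                             np.where(above & ~sig, "Semi_fit", "Not_fit"))
    return table, threshold


# ---------------------------------------------------------------------------
# Guide effectiveness summaries
# ---------------------------------------------------------------------------

def guide_effectiveness(
    guide_fitness: pd.DataFrame,
    gene_table: pd.DataFrame,
    guide_position: pd.Series,
    top_k_genes: int = 10,
    top_ranks: int = 3,
) -> tuple[pd.DataFrame, pd.Series]:
    """Within-gene z-scores and top-rank tallies for the fittest genes.

    For the ``top_k_genes`` genes with the highest fitness: each guide's
    z-score of ``crrna_fitness`` within its gene (population sd; all-equal
    guides get z = 0), plus per-position counts of guides ranked in the
    top ``top_ranks`` of their gene (rank ties broken by position index).
    """
    top_genes = gene_table["fitness"].nlargest(top_k_genes).index
    rows = []
    tallies: dict[int, int] = {}
    genes = (guide_fitness["gene_id"] if "gene_id" in guide_fitness.columns
             else None)
    if genes is None:
        raise ValueError("guide_fitness needs a gene_id column")
    for gene_id in top_genes:
        sub = guide_fitness[genes == gene_id]
        vals = sub["crrna_fitness"].to_numpy(dtype=float)
        pos = guide_position.reindex(sub.index).to_numpy()
        sd = vals.std(ddof=0)
        z = (vals - vals.mean()) / sd if sd > 0 else np.zeros_like(vals)
        order = np.lexsort((pos, -vals))  # best fitness first; ties by position
        ranks = np.empty(len(vals), dtype=int)
        ranks[order] = np.arange(1, len(vals) + 1)
        for g, p, zz, r in zip(sub.index, pos, z, ranks):
            rows.append((g, gene_id, int(p), float(zz), int(r)))
            if r <= top_ranks:
                tallies[int(p)] = tallies.get(int(p), 0) + 1
    zs = pd.DataFrame(rows, columns=["guide_id", "gene_id", "position",
                                     "z_score", "rank"]).set_index("guide_id")
    tally = pd.Series(tallies, name="top3_count").sort_index()
    return zs, tally


# ---------------------------------------------------------------------------
# Plaque-assay arithmetic
# ---------------------------------------------------------------------------

def plaque_metrics(condition_values, control_values) -> float:
    """Ratio of means: EOP (pfu counts) or plaque-size fold-change (areas).

    For lysis-from-without conditions, approximate the condition as
    1 p.f.u. at the most concentrated clearing dilution before calling
    this (flag such values in the caller's records).
    """
    cond = np.asarray(condition_values, dtype=float)
    ctrl = np.asarray(control_values, dtype=float)
    if cond.size == 0 or ctrl.size == 0:
        raise ValueError("both condition and control need >= 1 replicate")
    if (cond < 0).any() or (ctrl < 0).any():
        raise ValueError("plaque measurements must be non-negative")
    ctrl_mean = ctrl.mean()
    if ctrl_mean == 0:
        raise ValueError("control mean is zero; ratio undefined")
    return float(cond.mean() / ctrl_mean)


# ---------------------------------------------------------------------------
# End-to-end convenience
# ---------------------------------------------------------------------------

def screen_fitness(
    matrix,
    test_condition: str,
    baseline_condition: str,
    gene_map: pd.Series,
    norm_spec: NormalizationSpec | None = None,
    alpha: float = 0.05,
    decile_filter: bool = True,
    log2fc_mode: str = "per_sample_vs_baseline_mean",
    p_method: str = "asymptotic",
    seed: int = 0,
):
    """counts -> QC -> normalize -> log2FC -> K-S -> classify, in one call.

    ``matrix`` is a :class:`~crispri_art.counting.CountMatrix`.  Returns a
    dict with guide_fitness, gene_fitness, threshold and exclusions.
    """
    matrix.require_baseline()
    counts = matrix.counts
    exclusions = None
    if decile_filter:
        counts, exclusions = qc_decile_filter(counts, matrix.baseline_samples)
    norm = normalize(counts, norm_spec)
    gfc = guide_log2fc(norm, matrix.sample_meta, test_condition,
                       baseline_condition, mode=log2fc_mode,
                       gene_map=gene_map)
    gene = gene_ks_enrichment(gfc, p_method=p_method, seed=seed)
    gene, threshold = classify(gene, alpha=alpha)
    return {
        "guide_fitness": gfc,
        "gene_fitness": gene,
        "threshold": threshold,
        "exclusions": exclusions,
    }
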
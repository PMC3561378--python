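"""Expression normalization and linked-vs-background co-expression statistics.

Expression intensities are put on a common scale by dividing every sample by
its mean ("sample-mean normalization"); co-expression of a gene pair is the
Pearson correlation of the two profiles across samples.  The central
comparison is the mean correlation over gene pairs joined by a trans contact
(linked pairs) against the mean over *all* inter-chromosomal gene pairs
(the genome-wide background, which includes the linked pairs), with a
two-sample Kolmogorov-Smirnov test for distributional difference.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mapping import GeneLinkTable
from .types import GenomeAnnotation, ExpressionMatrix

logger = logging.getLogger("chromexpr")

DEFAULT_MIN_SHARED = 30
DEFAULT_BACKGROUND_CAP = 1_000_000


@dataclass
class CorrelationSummary:
    mean_linked: float
    mean_background: float
    n_linked: int
    n_background: int
    ks_statistic: float
    ks_p: float
    background_exact: bool = True
    background_seed: int | None = None


def normalize_samples(expr: ExpressionMatrix, from_log2: bool = False) -> ExpressionMatrix:
    """Divide each sample by its mean over non-missing values.

    Idempotent; a sample whose mean is zero is an error.  ``from_log2``
    first maps log2 intensities back to the linear scale.
    """
    v = expr.values.to_numpy(dtype=float)
    if from_log2:
        v = np.exp2(v)
    elif expr.normalized:
        return expr
    if np.nanmin(v) < 0:
        raise ValueError("expression values must be non-negative on the linear scale")
    means = np.nanmean(v, axis=0)
    if np.any(means == 0) or np.any(np.isnan(means)):
        raise ValueError("sample with zero (or undefined) mean cannot be normalized")
    out = pd.DataFrame(v / means, index=expr.values.index, columns=expr.values.columns)
    return ExpressionMatrix(out, normalized=True)


class CorrelationEngine:
    """Pearson correlations over gene pairs, pairwise-complete on missing data.

    With a complete matrix, profiles are centred once and pair correlations
    are plain dot products; with missing values each pair falls back to its
    jointly observed samples and is excluded (NaN) below ``min_shared``
    shared samples.  Zero-variance profiles yield NaN (excluded, logged by
    callers).
    """

    def __init__(self, expr: ExpressionMatrix, min_shared: int = DEFAULT_MIN_SHARED):
        self.expr = expr
        self.min_shared = min_shared
        self.index = {g: i for i, g in enumerate(expr.values.index)}
        v = expr.values.to_numpy(dtype=float)
        self._v = v
        self._has_nan = bool(np.isnan(v).any())
        if not self._has_nan:
            centred = v - v.mean(axis=1, keepdims=True)
            norms = np.sqrt((centred**2).sum(axis=1))
            with np.errstate(invalid="ignore", divide="ignore"):
                self._z = np.where(norms[:, None] == 0, np.nan, centred / norms[:, None])

    def pair_indices(self, pairs) -> tuple[np.ndarray, np.ndarray]:
        ia = np.fromiter((self.index.get(a, -1) for a, _ in pairs), dtype=np.int64,
                         count=len(pairs))
        ib = np.fromiter((self.index.get(b, -1) for _, b in pairs), dtype=np.int64,
                         count=len(pairs))
        return ia, ib

    def correlations(self, pairs) -> np.ndarray:
        """Pearson r per (gene_a, gene_b) pair; NaN where undefined/unknown."""
        if len(pairs) == 0:
            return np.array([])
        ia, ib = self.pair_indices(pairs)
        return self.correlations_idx(ia, ib)

    def correlations_idx(self, ia: np.ndarray, ib: np.ndarray) -> np.ndarray:
        out = np.full(len(ia), np.nan)
        ok = (ia >= 0) & (ib >= 0)
        if self.expr.n_samples < self.min_shared:
            return out
        if not self._has_nan:
            out[ok] = np.einsum("ij,ij->i", self._z[ia[ok]], self._z[ib[ok]])
            return out
        v = self._v
        for k in np.where(ok)[0]:
            x, y = v[ia[k]], v[ib[k]]
            m = ~(np.isnan(x) | np.isnan(y))
            if m.sum() < self.min_shared:
                continue
            xs, ys = x[m], y[m]
            if xs.std() == 0 or ys.std() == 0:
                continue
            out[k] = np.corrcoef(xs, ys)[0, 1]
        return out


def pearson(expr: ExpressionMatrix, pairs, min_shared: int = DEFAULT_MIN_SHARED) -> np.ndarray:
    """Pearson correlation for each gene pair (NaN where excluded)."""
    return CorrelationEngine(expr, min_shared).correlations(pairs)


def mean_pair_correlation(expr: ExpressionMatrix, pairs,
                          min_shared: int = DEFAULT_MIN_SHARED) -> tuple[float, int]:
    r = pearson(expr, pairs, min_shared)
    n_valid = int(np.isfinite(r).sum())
    mean = float(np.nanmean(r)) if n_valid else float("nan")
    return mean, n_valid


def inter_chromosomal_pair_indices(
    gene_ids, chroms, cap: int | None = None, seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Indices (i < j) of all inter-chromosomal gene pairs, or a uniform
    subsample of ``cap`` pairs when the universe is larger.

    Returns (idx_a, idx_b, exact).
    """
    chroms = np.asarray(chroms)
    n = len(chroms)
    iu, ju = np.triu_indices(n, k=1)
    keep = chroms[iu] != chroms[ju]
    iu, ju = iu[keep], ju[keep]
    if cap is not None and len(iu) > cap:
        rng = np.random.default_rng(seed)
        sel = rng.choice(len(iu), size=cap, replace=False)
        sel.sort()
        return iu[sel], ju[sel], False
    return iu, ju, True


def linked_vs_background(
    links: GeneLinkTable,
    expr: ExpressionMatrix,
    annotation: GenomeAnnotation,
    min_shared: int = DEFAULT_MIN_SHARED,
    background_cap: int | None = DEFAULT_BACKGROUND_CAP,
    seed: int = 0,
) -> CorrelationSummary:
    """Mean correlation of linked pairs vs the genome-wide trans background.

    The background is every inter-chromosomal gene pair (linked pairs
    included) among genes present in both annotation and expression matrix;
    above ``background_cap`` pairs it is estimated from a seeded uniform
    subsample.  Significance is a two-sample KS test between the two
    correlation samples.
    """
    if len(links) == 0:
        raise ValueError("no links to analyse")
    engine = CorrelationEngine(expr, min_shared)
    r_linked = engine.correlations(links.pairs())
    r_linked = r_linked[np.isfinite(r_linked)]
    if len(r_linked) == 0:
        raise ValueError("no linked pair has a valid correlation")

    genes = [g for g in annotation.gene_ids if g in engine.index]
    chroms = annotation.genes.loc[genes, "chrom"].to_numpy()
    ia, ib, exact = inter_chromosomal_pair_indices(genes, chroms, cap=background_cap,
                                                   seed=seed)
    gidx = np.fromiter((engine.index[g] for g in genes), dtype=np.int64, count=len(genes))
    r_bg = engine.correlations_idx(gidx[ia], gidx[ib])
    r_bg = r_bg[np.isfinite(r_bg)]
    ks = stats.ks_2samp(r_linked, r_bg)
    mode = "exact" if exact else f"subsampled (cap={background_cap}, seed={seed})"
    logger.info("linked %d pairs mean=%.4f; background %d pairs mean=%.4f (%s)",
                len(r_linked), r_linked.mean(), len(r_bg), r_bg.mean(), mode)
    return CorrelationSummary(
        mean_linked=float(r_linked.mean()),
        mean_background=float(r_bg.mean()),
        n_linked=int(len(r_linked)),
        n_background=int(len(r_bg)),
        ks_statistic=float(ks.statistic),
        ks_p=float(ks.pvalue),
        background_exact=exact,
        background_seed=None if exact else seed,
    )


def frequency_threshold_curve(
    links: GeneLinkTable,
    expr: ExpressionMatrix,
    annotation: GenomeAnnotation,
    thresholds=(0, 1, 2, 5, 8, 10),
    min_shared: int = DEFAULT_MIN_SHARED,
    background_cap: int | None = DEFAULT_BACKGROUND_CAP,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean linked correlation at increasing count-frequency thresholds.

    Row f=0 is the genome-wide background over all inter-chromosomal pairs
    (linked and unlinked); row f>0 averages links with frequency >= f.  In
    the data the curve increases with f: stronger contacts, stronger
    co-expression.
    """
    thresholds = list(thresholds)
    if thresholds != sorted(thresholds) or thresholds[0] != 0:
        raise ValueError("thresholds must ascend and start at 0")
    engine = CorrelationEngine(expr, min_shared)
    rows = []
    summary = linked_vs_background(links, expr, annotation, min_shared,
                                   background_cap, seed)
    rows.append((0, summary.mean_background, summary.n_background))
    freq = links.links["frequency"].to_numpy()
    all_pairs = links.pairs()
    r_all = engine.correlations(all_pairs)
    for f in thresholds[1:]:
        sel = np.isfinite(r_all) & (freq >= f)
        n = int(sel.sum())
        rows.append((f, float(r_all[sel].mean()) if n else float("nan"), n))
    return pd.DataFrame(rows, columns=["min_count", "mean_correlation", "n_pairs"])


def chromosome_pair_analysis(
    links: GeneLinkTable,
    expr: ExpressionMatrix,
    annotation: GenomeAnnotation,
    min_count: int = 5,
    min_shared: int = DEFAULT_MIN_SHARED,
) -> tuple[pd.DataFrame, float, float, float]:
    """Per chromosome pair: mean trans correlation vs link density per kbp.

    For each unordered chromosome pair (i, j), the mean correlation over all
    gene pairs spanning the two chromosomes is regressed against the number
    of links between them (frequency >= ``min_count``) per kbp of summed
    chromosome length.  Returns (table, r, t, one-tailed p) where
    t = r*sqrt((n-2)/(1-r^2)).
    """
    engine = CorrelationEngine(expr, min_shared)
    genes_by_chrom: dict[str, np.ndarray] = {}
    for chrom, sub in annotation.genes.groupby("chrom"):
        idx = np.fromiter((engine.index[g] for g in sub.index if g in engine.index),
                          dtype=np.int64)
        if len(idx) == 0:
            logger.warning("chromosome %s has no expressed genes; excluded", chrom)
            continue
        genes_by_chrom[chrom] = idx
    chrom_list = sorted(genes_by_chrom)
    if len(chrom_list) < 3:
        raise ValueError("need at least 3 chromosomes with genes")
    lf = links.links[links.links["frequency"] >= min_count]
    link_counts: dict[tuple[str, str], int] = {}
    for ca, cb in zip(lf["chrom_a"], lf["chrom_b"]):
        key = (ca, cb) if ca < cb else (cb, ca)
        link_counts[key] = link_counts.get(key, 0) + 1
    rows = []
    for a_i in range(len(chrom_list)):
        for b_i in range(a_i + 1, len(chrom_list)):
            ca, cb = chrom_list[a_i], chrom_list[b_i]
            ia = genes_by_chrom[ca]
            ib = genes_by_chrom[cb]
            pa, pb = np.meshgrid(ia, ib, indexing="ij")
            r = engine.correlations_idx(pa.ravel(), pb.ravel())
            mean_r = float(np.nanmean(r))
            density = link_counts.get((ca, cb), 0) / (
                (annotation.chrom_lengths[ca] + annotation.chrom_lengths[cb]) / 1000.0
            )
            rows.append((ca, cb, mean_r, density, int(np.isfinite(r).sum())))
    table = pd.DataFrame(rows, columns=["chrom_a", "chrom_b", "mean_correlation",
                                        "links_per_kbp", "n_pairs"])
    x = table["links_per_kbp"].to_numpy()
    y = table["mean_correlation"].to_numpy()
    n = len(table)
    r = float(np.corrcoef(x, y)[0, 1]) if np.std(x) > 0 and np.std(y) > 0 else 0.0
    if abs(r) >= 1.0:
        t = math.inf if r > 0 else -math.inf
    else:
        t = r * math.sqrt((n - 2) / (1 - r * r))
    p_one = float(stats.t.sf(t, df=n - 2))
    return table, r, float(t), p_one


def expression_rank_link_enrichment(
    expr: ExpressionMatrix,
    links: GeneLinkTable,
    annotation: GenomeAnnotation,
    bin_size: int = 500,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Link enrichment of genes binned by average expression rank.

    Genes are ranked by mean normalized expression and cut into consecutive
    bins of ``bin_size``; a bin's observed statistic is the number of link
    endpoints falling on its genes, compared against the mean of the same
    statistic over ``n_perm`` random gene groups of equal size.
    """
    if bin_size < 2:
        raise ValueError("bin_size must be >= 2")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    genes = [g for g in annotation.gene_ids if g in set(expr.values.index)]
    mean_expr = expr.values.loc[genes].mean(axis=1, skipna=True)
    ranked = mean_expr.sort_values(kind="mergesort").index.to_numpy()
    gene_pos = {g: i for i, g in enumerate(ranked)}
    degree = np.zeros(len(ranked))
    for ga, gb in links.pairs():
        if ga in gene_pos:
            degree[gene_pos[ga]] += 1
        if gb in gene_pos:
            degree[gene_pos[gb]] += 1
    rng = np.random.default_rng(seed)
    rows = []
    n_genes = len(ranked)
    for b_start in range(0, n_genes, bin_size):
        members = np.arange(b_start, min(b_start + bin_size, n_genes))
        observed = float(degree[members].sum())
        size = len(members)
        if size == n_genes:
            expected = observed
            sd = 0.0
        else:
            perm = np.empty(n_perm)
            for k in range(n_perm):
                sel = rng.choice(n_genes, size=size, replace=False)
                perm[k] = degree[sel].sum()
            expected = float(perm.mean())
            sd = float(perm.std(ddof=1))
        ratio = observed / expected if expected > 0 else float("nan")
        rows.append((b_start // bin_size, float(mean_expr.loc[ranked[members]].mean()),
                     observed, expected, sd, ratio))
    return pd.DataFrame(rows, columns=["bin", "mean_expression", "observed_endpoints",
                                       "expected_endpoints", "expected_sd",
                                       "enrichment_ratio"])


def relative_arm_position(annotation: GenomeAnnotation, gene_id: str) -> float:
    """Relative position between centromere (0) and telomere (1).

    Distance from the centromere midpoint to the gene midpoint, divided by
    the arm length from centromere midpoint to the telomere on the gene's
    side (coordinate 1 or the chromosome end).  Genes whose midpoint falls
    inside the centromere interval sit at 0.
    """
    row = annotation.genes.loc[gene_id]
    chrom = row["chrom"]
    if chrom not in annotation.centromeres:
        raise ValueError(f"chromosome {chrom!r} has no centromere recorded")
    cs, ce = annotation.centromeres[chrom]
    cmid = (cs + ce) / 2.0
    gmid = (row["start"] + row["end"]) / 2.0
    if cs <= gmid <= ce:
        return 0.0
    if gmid < cmid:
        arm = cmid - 1.0
    else:
        arm = annotation.chrom_lengths[chrom] - cmid
    return float(min(abs(gmid - cmid) / arm, 1.0))


def centromere_telomere_profile(
    expr: ExpressionMatrix,
    annotation: GenomeAnnotation,
    n_bins: int = 10,
    min_shared: int = DEFAULT_MIN_SHARED,
    max_pairs_per_bin: int | None = 200_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean trans correlation within bins of relative arm position.

    Each gene gets a position in [0, 1] between its centromere and telomere;
    genes are cut into ``n_bins`` equal bins and, per bin, the mean
    correlation over inter-chromosomal gene pairs sharing that bin is
    reported.  Quantifies how much centromere/telomere clustering alone
    could explain trans co-expression.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    engine = CorrelationEngine(expr, min_shared)
    genes, pos = [], []
    for g in annotation.gene_ids:
        if g not in engine.index:
            continue
        if annotation.genes.loc[g, "chrom"] not in annotation.centromeres:
            continue
        genes.append(g)
        pos.append(relative_arm_position(annotation, g))
    pos = np.asarray(pos)
    bins = np.minimum((pos * n_bins).astype(int), n_bins - 1)
    chroms = annotation.genes.loc[genes, "chrom"].to_numpy()
    gidx = np.fromiter((engine.index[g] for g in genes), dtype=np.int64, count=len(genes))
    rows = []
    rng = np.random.default_rng(seed)
    for b in range(n_bins):
        sel = np.where(bins == b)[0]
        if len(sel) < 2:
            rows.append((b, float("nan"), 0))
            continue
        ia, ib, _ = inter_chromosomal_pair_indices(
            [genes[i] for i in sel], chroms[sel],
            cap=max_pairs_per_bin, seed=int(rng.integers(2**31)))
        r = engine.correlations_idx(gidx[sel[ia]], gidx[sel[ib]])
        n_valid = int(np.isfinite(r).sum())
        rows.append((b, float(np.nanmean(r)) if n_valid else float("nan"), n_valid))
    return pd.DataFrame(rows, columns=["bin", "mean_within_bin_correlation", "n_pairs"])


def exclude_pairs_recompute(
    links: GeneLinkTable,
    expr: ExpressionMatrix,
    annotation: GenomeAnnotation,
    excluded_pairs=(),
    excluded_genes=(),
    min_shared: int = DEFAULT_MIN_SHARED,
    background_cap: int | None = DEFAULT_BACKGROUND_CAP,
    seed: int = 0,
) -> dict:
    """Sensitivity of the linked/background means to removing gene pairs.

    Recomputes the summary with (a) the listed gene-id pairs masked out of
    both samples, and (b) the listed genes removed entirely, reporting the
    change in each mean.  Used to show that e.g. duplicated (homologous)
    gene pairs do not drive the signal.
    """
    base = linked_vs_background(links, expr, annotation, min_shared, background_cap, seed)

    excl_pairs = {tuple(sorted(p)) for p in excluded_pairs}
    known = set(annotation.gene_ids) | set(expr.values.index)
    for p in excl_pairs:
        for g in p:
            if g not in known:
                logger.warning("excluded pair names unknown gene %s", g)

    def masked_summary():
        keep = [not (tuple(sorted(p)) in excl_pairs) for p in links.pairs()]
        lt = GeneLinkTable(links.links[keep].reset_index(drop=True),
                           links.offset_bp, links.min_count, dict(links.provenance))
        engine = CorrelationEngine(expr, min_shared)
        r_linked = engine.correlations(lt.pairs())
        r_linked = r_linked[np.isfinite(r_linked)]
        genes = [g for g in annotation.gene_ids if g in engine.index]
        chroms = annotation.genes.loc[genes, "chrom"].to_numpy()
        ia, ib, _ = inter_chromosomal_pair_indices(genes, chroms, cap=background_cap,
                                                   seed=seed)
        keep_bg = np.fromiter(
            ((genes[i], genes[j]) not in excl_pairs
             and (genes[j], genes[i]) not in excl_pairs
             and tuple(sorted((genes[i], genes[j]))) not in excl_pairs
             for i, j in zip(ia, ib)),
            dtype=bool, count=len(ia))
        gidx = np.fromiter((engine.index[g] for g in genes), dtype=np.int64,
                           count=len(genes))
        r_bg = engine.correlations_idx(gidx[ia[keep_bg]], gidx[ib[keep_bg]])
        r_bg = r_bg[np.isfinite(r_bg)]
        return float(r_linked.mean()), float(r_bg.mean())

    if excl_pairs:
        m_linked, m_bg = masked_summary()
    else:
        m_linked, m_bg = base.mean_linked, base.mean_background

    excluded_genes = set(excluded_genes)
    if excluded_genes:
        keep_genes = [g for g in annotation.gene_ids if g not in excluded_genes]
        if not keep_genes:
            raise ValueError("cannot exclude every gene")
        ann2 = GenomeAnnotation(annotation.genes.loc[keep_genes],
                                annotation.chrom_lengths, annotation.centromeres)
        keep = [ga not in excluded_genes and gb not in excluded_genes
                for ga, gb in links.pairs()]
        lt2 = GeneLinkTable(links.links[keep].reset_index(drop=True),
                            links.offset_bp, links.min_count, dict(links.provenance))
        ex = linked_vs_background(lt2, expr, ann2, min_shared, background_cap, seed)
        g_linked, g_bg = ex.mean_linked, ex.mean_background
    else:
        g_linked, g_bg = base.mean_linked, base.mean_background

    return {
        "baseline_mean_linked": base.mean_linked,
        "baseline_mean_background": base.mean_background,
        "masked_mean_linked": m_linked,
        "masked_mean_background": m_bg,
        "masked_delta_linked": m_linked - base.mean_linked,
        "masked_delta_background": m_bg - base.mean_background,
        "removed_mean_linked": g_linked,
        "removed_mean_background": g_bg,
        "removed_delta_linked": g_linked - base.mean_linked,
        "removed_delta_background": g_bg - base.mean_background,
    }
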
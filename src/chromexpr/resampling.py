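"""Resampling-based significance for the linked-correlation statistic.

Two simulations bracket the observed mean linked correlation: a *random-link
null* (ensembles of the same number of randomly chosen inter-chromosomal
gene pairs, giving the spread of the genome-wide mean) and a *bootstrap*
over the measured links (random half-subsets, giving the sampling stability
of the observed statistic).  Both sample without replacement within a
replicate and are bit-reproducible for a given seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .coexpression import CorrelationEngine, DEFAULT_MIN_SHARED, inter_chromosomal_pair_indices
from .mapping import GeneLinkTable
from .types import GenomeAnnotation, ExpressionMatrix

logger = logging.getLogger("chromexpr")


@dataclass
class ResamplingSummary:
    kind: str  # random_link_null | bootstrap
    n_reps: int
    rep_statistics: np.ndarray
    summary_mean: float
    summary_sd: float
    seed: int
    observed_statistic: float | None = None
    skewness: float | None = None
    extra: dict = field(default_factory=dict)


def _summarize(kind, reps, seed, observed=None, skew=False, **extra) -> ResamplingSummary:
    reps = np.asarray(reps, dtype=float)
    return ResamplingSummary(
        kind=kind,
        n_reps=len(reps),
        rep_statistics=reps,
        summary_mean=float(reps.mean()),
        summary_sd=float(reps.std(ddof=1)) if len(reps) > 1 else 0.0,
        seed=seed,
        observed_statistic=observed,
        skewness=(float(stats.skew(reps))
                  if skew and len(reps) > 2 and np.ptp(reps) > 0 else None),
        extra=extra,
    )


def random_link_null(
    expr: ExpressionMatrix,
    annotation: GenomeAnnotation,
    n_links: int,
    n_reps: int = 1000,
    seed: int = 0,
    min_shared: int = DEFAULT_MIN_SHARED,
) -> ResamplingSummary:
    """Null ensemble of randomly placed inter-chromosomal "links".

    Each replicate draws ``n_links`` distinct trans gene pairs uniformly and
    takes their mean pairwise correlation; the ensemble mean/sd describe the
    genome-wide background and its spread at the observed link count.
    """
    engine = CorrelationEngine(expr, min_shared)
    genes = [g for g in annotation.gene_ids if g in engine.index]
    chroms = annotation.genes.loc[genes, "chrom"].to_numpy()
    ia, ib, _ = inter_chromosomal_pair_indices(genes, chroms, cap=None)
    n_pairs = len(ia)
    if n_links > n_pairs:
        raise ValueError(f"n_links={n_links} exceeds the {n_pairs} available trans pairs")
    gidx = np.fromiter((engine.index[g] for g in genes), dtype=np.int64, count=len(genes))
    # pair correlations are replicate-independent: compute once, resample means
    r_all = engine.correlations_idx(gidx[ia], gidx[ib])
    rng = np.random.default_rng(seed)
    reps = np.empty(n_reps)
    for k in range(n_reps):
        sel = rng.choice(n_pairs, size=n_links, replace=False)
        reps[k] = np.nanmean(r_all[sel])
    logger.info("random-link null: %d reps of %d pairs, mean=%.5f sd=%.5f",
                n_reps, n_links, reps.mean(), reps.std(ddof=1))
    return _summarize("random_link_null", reps, seed,
                      n_links=n_links, n_pair_universe=n_pairs)


def bootstrap_links(
    links: GeneLinkTable,
    expr: ExpressionMatrix,
    frac: float = 0.5,
    n_reps: int = 1000,
    seed: int = 0,
    min_shared: int = DEFAULT_MIN_SHARED,
) -> ResamplingSummary:
    """Stability of the linked-correlation mean under link subsampling.

    Each replicate keeps floor(frac * n_links) links drawn without
    replacement and recomputes the mean linked correlation.  The replicate
    distribution is near-Gaussian (skewness reported) and its sd follows the
    finite-population formula for without-replacement subsampling.
    """
    if not (0 < frac < 1):
        raise ValueError("frac must be in (0, 1)")
    engine = CorrelationEngine(expr, min_shared)
    r = engine.correlations(links.pairs())
    valid = np.isfinite(r)
    r = r[valid]
    n = len(r)
    k = int(frac * n)
    if k < 2:
        raise ValueError(f"subsample of {k} links is too small")
    rng = np.random.default_rng(seed)
    reps = np.empty(n_reps)
    for i in range(n_reps):
        sel = rng.choice(n, size=k, replace=False)
        reps[i] = r[sel].mean()
    observed = float(r.mean())
    logger.info("bootstrap: %d reps of %d/%d links, mean=%.5f sd=%.5f",
                n_reps, k, n, reps.mean(), reps.std(ddof=1))
    return _summarize("bootstrap", reps, seed, observed=observed, skew=True,
                      frac=frac, n_links=n, subsample_size=k)


def zscore_separation(null_summary: ResamplingSummary, observed_statistic: float) -> float:
    """(observed - null mean) / null sd — how far the measured statistic sits
    outside the random-link ensemble."""
    if null_summary.summary_sd == 0:
        raise ValueError("null ensemble has zero spread")
    return (observed_statistic - null_summary.summary_mean) / null_summary.summary_sd
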
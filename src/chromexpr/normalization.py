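"""Contact-matrix construction and normalization.

The contact map is represented as a symmetric locus x locus matrix of count
frequencies.  Three normalizations are provided as a robustness check on the
co-expression signal: *linear* (divide each entry by the product of its row
and column sums), *Euclidean* (same with Euclidean norms), and *SCN*
(iteratively normalize columns then rows to unit Euclidean norm until the
matrix stabilizes, then symmetrize).  All three preserve the zero pattern
and, for symmetric input, symmetry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import ContactTable, GenomeAnnotation

logger = logging.getLogger("chromexpr")


@dataclass
class ContactMatrix:
    """Square symmetric matrix over distinct contact loci.

    ``loci`` is the ordered list of (chrom, pos) bins; ``values[i, j]`` the
    total count (or normalized weight) between loci i and j.  Rows whose sum
    (or norm) is zero are left untouched by normalization and listed in
    ``zero_rows``.
    """

    loci: list[tuple[str, int]]
    values: np.ndarray
    symmetric: bool = True
    zero_rows: list[int] = field(default_factory=list)
    converged: bool | None = None
    n_iter: int | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.loci):
            raise ValueError("values must be square and match loci")
        if self.symmetric and len(self.loci) and np.max(np.abs(v - v.T)) > 1e-9:
            raise ValueError("matrix flagged symmetric but is not")

    @property
    def n(self) -> int:
        return len(self.loci)


def contacts_to_matrix(contacts: ContactTable) -> ContactMatrix:
    """Aggregate contact records into a symmetric locus-level count matrix.

    One row/column per distinct locus; duplicate records summed.  Self-locus
    records would land on the diagonal and are excluded (the analysis is
    inter-locus).
    """
    rec = contacts.records
    loci = sorted(
        set(zip(rec["chrom_a"], rec["pos_a"])) | set(zip(rec["chrom_b"], rec["pos_b"]))
    )
    index = {loc: i for i, loc in enumerate(loci)}
    M = np.zeros((len(loci), len(loci)))
    n_diag = 0
    for row in rec.itertuples(index=False):
        i = index[(row.chrom_a, row.pos_a)]
        j = index[(row.chrom_b, row.pos_b)]
        if i == j:
            n_diag += 1
            continue
        M[i, j] += row.count
        M[j, i] += row.count
    if n_diag:
        logger.warning("skipped %d self-locus records (diagonal)", n_diag)
    return ContactMatrix(loci, M, symmetric=True)


def _normalize_by(M: np.ndarray, row_stat: np.ndarray, col_stat: np.ndarray):
    zero_rows = np.where(row_stat == 0)[0]
    rs = np.where(row_stat == 0, 1.0, row_stat)
    cs = np.where(col_stat == 0, 1.0, col_stat)
    return M / np.outer(rs, cs), list(zero_rows)


def normalize_linear(cm: ContactMatrix) -> ContactMatrix:
    """Divide each entry by the product of its row and column sums."""
    M = cm.values
    if (M < 0).any():
        raise ValueError("contact matrix must be non-negative")
    rs = M.sum(axis=1)
    # symmetric input: column sums equal row sums; reusing them keeps the
    # output bitwise symmetric
    cs = rs if cm.symmetric else M.sum(axis=0)
    out, zr = _normalize_by(M, rs, cs)
    if zr:
        logger.warning("linear normalization: %d all-zero rows left untouched", len(zr))
    return ContactMatrix(cm.loci, out, symmetric=cm.symmetric, zero_rows=zr)


def normalize_euclidean(cm: ContactMatrix) -> ContactMatrix:
    """Divide each entry by the product of its row and column Euclidean norms."""
    M = cm.values
    if (M < 0).any():
        raise ValueError("contact matrix must be non-negative")
    rn = np.linalg.norm(M, axis=1)
    cn = rn if cm.symmetric else np.linalg.norm(M, axis=0)
    out, zr = _normalize_by(M, rn, cn)
    if zr:
        logger.warning("euclidean normalization: %d all-zero rows left untouched", len(zr))
    return ContactMatrix(cm.loci, out, symmetric=cm.symmetric, zero_rows=zr)


def normalize_scn(cm: ContactMatrix, tol: float = 1e-6, max_iter: int = 100) -> ContactMatrix:
    """Sequential Component Normalization.

    Repeat {divide each nonzero column by its Euclidean norm; divide each
    nonzero row by its Euclidean norm} until the largest entry change falls
    below ``tol`` (sup norm) or ``max_iter`` is reached, then symmetrize via
    (M + M')/2.  At the fixed point all nonzero row and column norms are ~1.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    M = cm.values.astype(float).copy()
    if (M < 0).any():
        raise ValueError("contact matrix must be non-negative")
    if not cm.symmetric:
        raise ValueError("SCN expects a symmetric contact matrix")
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        prev = M.copy()
        cn = np.linalg.norm(M, axis=0)
        M = M / np.where(cn == 0, 1.0, cn)[None, :]
        rn = np.linalg.norm(M, axis=1)
        M = M / np.where(rn == 0, 1.0, rn)[:, None]
        if np.max(np.abs(M - prev)) < tol if M.size else True:
            converged = True
            break
    if not converged:
        logger.warning("SCN did not converge in %d iterations", max_iter)
    M = (M + M.T) / 2.0
    zero = np.where(cm.values.sum(axis=1) == 0)[0]
    return ContactMatrix(cm.loci, M, symmetric=True, zero_rows=list(zero),
                         converged=converged, n_iter=it)


def top_n_links(
    cm: ContactMatrix,
    annotation: GenomeAnnotation,
    offset_bp: int = 500,
    n: int = 1000,
    anchor_mode: str = "boundary",
):
    """Gene pairs carried by the N strongest inter-chromosomal matrix entries.

    Locus pairs are ranked by normalized weight (descending; ties broken by
    the lexicographically smaller canonical locus key) and mapped to genes
    until ``n`` distinct gene pairs are collected.  The returned table's
    ``frequency`` column holds the strongest supporting normalized weight —
    a real-valued score, unlike count-based link tables.
    """
    from .mapping import GeneAssigner, GeneLinkTable, LINK_COLUMNS

    if n < 1:
        raise ValueError("n must be >= 1")
    M = cm.values
    iu, ju = np.triu_indices(cm.n, k=1)
    chroms = np.array([c for c, _ in cm.loci])
    inter = chroms[iu] != chroms[ju]
    iu, ju = iu[inter], ju[inter]
    w = M[iu, ju]
    keys = [(cm.loci[i], cm.loci[j]) for i, j in zip(iu, ju)]
    order = sorted(range(len(w)), key=lambda k: (-w[k], keys[k]))

    assigner = GeneAssigner(annotation, anchor_mode)
    chrom_of = annotation.genes["chrom"].to_dict()
    agg: dict[tuple[str, str], list] = {}
    for k in order:
        if w[k] <= 0:
            break
        (ca, pa), (cb, pb) = keys[k]
        for ga in assigner.assign(ca, pa, offset_bp):
            for gb in assigner.assign(cb, pb, offset_bp):
                if ga == gb or chrom_of[ga] == chrom_of[gb]:
                    continue
                key = (ga, gb) if ga < gb else (gb, ga)
                entry = agg.get(key)
                if entry is None:
                    if len(agg) >= n:
                        continue
                    agg[key] = [w[k], 1]
                else:
                    entry[0] = max(entry[0], w[k])
                    entry[1] += 1
        if len(agg) >= n:
            break
    if len(agg) < n:
        logger.warning("only %d distinct gene pairs available (requested %d)", len(agg), n)
    rows = [
        (ga, gb, chrom_of[ga], chrom_of[gb], weight, sup, "normalized")
        for (ga, gb), (weight, sup) in sorted(agg.items())
    ]
    links = pd.DataFrame(rows, columns=LINK_COLUMNS)
    return GeneLinkTable(links, offset_bp=offset_bp, min_count=0,
                         provenance={"source": "top_n_links", "n_requested": n})


def write_matrix(cm: ContactMatrix, path) -> None:
    """TSV triplet export (locus_a, locus_b, weight), upper triangle, nonzero."""
    with open(path, "w") as fh:
        fh.write("chrom_a\tpos_a\tchrom_b\tpos_b\tweight\n")
        iu, ju = np.triu_indices(cm.n, k=1)
        for i, j in zip(iu, ju):
            if cm.values[i, j] != 0:
                (ca, pa), (cb, pb) = cm.loci[i], cm.loci[j]
                fh.write(f"{ca}\t{pa}\t{cb}\t{pb}\t{cm.values[i, j]!r}\n")
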
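"""Core data containers for the contact/co-expression pipeline.

Coordinates are 1-based inclusive throughout (SGD/GFF3 convention).  A 4C
contact joins two genomic loci; its ``count`` is the number of sequenced
fragments supporting the contact ("count frequency"), a proxy for spatial
proximity.  Contacts are unordered: ``(A, B)`` and ``(B, A)`` denote the same
physical contact and canonicalize to the same key (lexicographic on
``(chrom, pos)``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

logger = logging.getLogger("chromexpr")

CONTACT_COLUMNS = ["chrom_a", "pos_a", "chrom_b", "pos_b", "count", "library"]

GENE_STATUSES = ("verified", "uncharacterized", "dubious")


def canonicalize_contacts(records: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with each record's two loci in lexicographic order.

    Idempotent: canonicalizing a canonical table is a no-op.
    """
    out = records.copy()
    if len(out) == 0:
        return out
    chrom_a = out["chrom_a"].astype(str)
    chrom_b = out["chrom_b"].astype(str)
    swap = (chrom_b < chrom_a) | ((chrom_b == chrom_a) & (out["pos_b"] < out["pos_a"]))
    if swap.any():
        sw = swap.to_numpy()
        a_cols = out.loc[sw, ["chrom_a", "pos_a"]].to_numpy()
        b_cols = out.loc[sw, ["chrom_b", "pos_b"]].to_numpy()
        out.loc[sw, ["chrom_a", "pos_a"]] = b_cols
        out.loc[sw, ["chrom_b", "pos_b"]] = a_cols
    return out


@dataclass
class ContactTable:
    """Raw fragment-pair contacts with counts.

    ``records`` columns: chrom_a, pos_a, chrom_b, pos_b, count, library.
    Duplicate records with the same canonical loci are kept as separate rows;
    aggregation into gene-pair frequencies is downstream policy.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CONTACT_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"contact table missing columns: {missing}")
        if len(self.records):
            if (self.records["count"] < 1).any():
                raise ValueError("contact counts must be >= 1")
            if (self.records["pos_a"] < 1).any() or (self.records["pos_b"] < 1).any():
                raise ValueError("contact coordinates must be >= 1 (1-based)")
        self.records = canonicalize_contacts(
            self.records[CONTACT_COLUMNS].reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def empty(cls) -> "ContactTable":
        return cls(pd.DataFrame(columns=CONTACT_COLUMNS))

    def inter_chromosomal(self) -> "ContactTable":
        """Contacts whose two loci lie on different chromosomes (trans)."""
        mask = self.records["chrom_a"] != self.records["chrom_b"]
        return ContactTable(self.records[mask].reset_index(drop=True))


def combine_libraries(*tables: ContactTable) -> ContactTable:
    """Concatenate contact tables, preserving library labels.

    No count arithmetic happens here; pooling libraries simply deepens the
    record list that downstream aggregation sees.
    """
    if not tables:
        raise ValueError("combine_libraries needs at least one table")
    frames = [t.records for t in tables]
    return ContactTable(pd.concat(frames, ignore_index=True))


@dataclass
class GenomeAnnotation:
    """Genes with coordinates/strand/status, chromosome lengths, centromeres.

    ``genes`` is indexed by unique gene_id with columns chrom, start, end,
    strand, status.  Centromere intervals are used for relative arm-position
    binning; chromosomes lacking one are rejected by those operations.
    """

    genes: pd.DataFrame
    chrom_lengths: dict[str, int]
    centromeres: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        g = self.genes
        if g.index.has_duplicates:
            dups = g.index[g.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        if len(g):
            if not ((g["start"] >= 1) & (g["start"] <= g["end"])).all():
                raise ValueError("gene intervals must satisfy 1 <= start <= end")
            for chrom, sub in g.groupby("chrom"):
                if chrom not in self.chrom_lengths:
                    raise ValueError(f"gene on unknown chromosome {chrom!r}")
                if (sub["end"] > self.chrom_lengths[chrom]).any():
                    bad = sub.index[sub["end"] > self.chrom_lengths[chrom]][0]
                    raise ValueError(
                        f"gene {bad!r} extends beyond chromosome {chrom!r}"
                    )
        for chrom, (s, e) in self.centromeres.items():
            if chrom not in self.chrom_lengths:
                raise ValueError(f"centromere on unknown chromosome {chrom!r}")
            if not (1 <= s <= e <= self.chrom_lengths[chrom]):
                raise ValueError(f"centromere interval invalid on {chrom!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.genes.index)

    def chrom_of(self, gene_ids) -> pd.Series:
        return self.genes.loc[gene_ids, "chrom"]

    def five_prime(self, gene_id: str) -> int:
        row = self.genes.loc[gene_id]
        return int(row["start"] if row["strand"] == "+" else row["end"])


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of linear-scale expression intensities.

    ``values`` is a DataFrame indexed by gene_id with sample-id columns.
    Probe-level rows must already be collapsed to one row per gene.  When
    ``normalized`` is set, every sample's mean over non-missing values is 1.
    """

    values: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicated gene ids in expression matrix")
        if self.normalized:
            means = np.nanmean(self.values.to_numpy(dtype=float), axis=0)
            if not np.allclose(means, 1.0, atol=1e-9):
                raise ValueError("normalized flag set but sample means != 1")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    domain: str  # molecular_function | biological_process | cellular_component | other
    name: str
    genes: frozenset[str]

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetCollection:
    """Flat GO-slim style gene sets grouped by ontology domain."""

    terms: dict[str, GeneSet]

    def resolve_against(self, annotation: GenomeAnnotation) -> "GeneSetCollection":
        """Drop member genes absent from the annotation (logged)."""
        known = set(annotation.gene_ids)
        resolved = {}
        n_dropped = 0
        for tid, gs in self.terms.items():
            kept = frozenset(g for g in gs.genes if g in known)
            n_dropped += len(gs.genes) - len(kept)
            if not kept:
                logger.warning("gene set %s has no resolvable genes; skipped", tid)
                continue
            resolved[tid] = GeneSet(tid, gs.domain, gs.name, kept)
        if n_dropped:
            logger.warning("dropped %d unresolvable gene-set members", n_dropped)
        return GeneSetCollection(resolved)


@dataclass
class AnalysisConfig:
    """Tunable parameters of the pipeline with their working defaults.

    offset_bp: max distance (bp) from a contact locus to a gene for
        assignment (500 bp, the shoulder of the offset-decay curve).
    min_count: count-frequency threshold for a link to be retained (>= 5).
    n_perm: Monte-Carlo random groups per gene set.
    n_null_reps: replicates of the random-link null ensemble.
    bootstrap_frac / bootstrap_reps: link-subsampling bootstrap settings.
    """

    offset_bp: int = 500
    min_count: int = 5
    n_perm: int = 1000
    n_null_reps: int = 1000
    bootstrap_frac: float = 0.5
    bootstrap_reps: int = 1000
    rng_seed: int = 0
    inter_chromosomal_only: bool = True
    library: str = "combined"
    anchor_mode: str = "boundary"
    aggregation: str = "max"

    def __post_init__(self) -> None:
        if self.offset_bp < 0:
            raise ValueError("offset_bp must be >= 0")
        if not (0 < self.bootstrap_frac < 1):
            raise ValueError("bootstrap_frac must be in (0, 1)")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        valid = {f.name for f in fields(cls)}
        unknown = set(data) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
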
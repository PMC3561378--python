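"""Readers and writers for the pipeline's file formats.

All tabular formats are plain TSV; gene annotations are GFF3 (read through
gffutils).  Readers reject malformed coordinates rather than coercing them,
and every writer/reader pair round-trips values exactly (floats to full
precision).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    CONTACT_COLUMNS,
    ContactTable,
    GeneSet,
    GeneSetCollection,
    GenomeAnnotation,
    ExpressionMatrix,
)

logger = logging.getLogger("chromexpr")

_CONTACT_BASE_COLS = ["chrom_a", "pos_a", "chrom_b", "pos_b", "count"]


def _looks_like_header(fields: list[str]) -> bool:
    # positions and count must be numeric in a data row
    def numeric(s: str) -> bool:
        try:
            int(s)
            return True
        except ValueError:
            return False

    # a header has no numeric coordinate/count fields at all; a data row with
    # one corrupt field must surface as a parse error, not vanish as a header
    return len(fields) >= 5 and not any(
        numeric(fields[k]) for k in (1, 3, 4)
    )


def read_contacts(path, library_label: str = "unknown") -> ContactTable:
    """Read a 5-column contact list (chrom_a, pos_a, chrom_b, pos_b, count).

    A header line is auto-detected by non-numeric position fields.  Extra
    columns are ignored with a warning.  Malformed rows raise with their
    1-based line number.
    """
    path = Path(path)
    rows = []
    n_extra_warned = False
    with open(path) as fh:
        lines = fh.read().splitlines()
    start = 0
    data_lines = [ln for ln in lines if ln.strip()]
    if not data_lines:
        logger.warning("contact file %s is empty", path)
        return ContactTable.empty()
    first_fields = data_lines[0].split("\t")
    offset_lines = []
    for lineno, ln in enumerate(lines, start=1):
        if not ln.strip():
            continue
        offset_lines.append((lineno, ln))
    if _looks_like_header(first_fields):
        offset_lines = offset_lines[1:]
        if not offset_lines:
            logger.warning("contact file %s has a header but no records", path)
            return ContactTable.empty()
    for lineno, ln in offset_lines:
        f = ln.split("\t")
        if len(f) < 5:
            raise ValueError(f"{path}: line {lineno}: expected >=5 columns, got {len(f)}")
        if len(f) > 5 and not n_extra_warned:
            logger.warning("%s: extra columns beyond 5 ignored", path)
            n_extra_warned = True
        try:
            pos_a, pos_b, count = int(f[1]), int(f[3]), int(f[4])
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: malformed numeric field ({exc})")
        if count <= 0:
            raise ValueError(f"{path}: line {lineno}: count must be positive, got {count}")
        if pos_a < 1 or pos_b < 1:
            raise ValueError(f"{path}: line {lineno}: coordinates are 1-based, got {pos_a}, {pos_b}")
        rows.append((f[0], pos_a, f[2], pos_b, count, library_label))
    table = ContactTable(pd.DataFrame(rows, columns=CONTACT_COLUMNS))
    logger.info("read %d contact records from %s", len(table), path)
    return table


def write_contacts(table: ContactTable, path) -> None:
    table.records[_CONTACT_BASE_COLS + ["library"]].to_csv(path, sep="\t", index=False)


def _read_two_col(path, what: str) -> list[tuple]:
    out = []
    with open(path) as fh:
        for lineno, ln in enumerate(fh, start=1):
            if not ln.strip() or ln.startswith("#"):
                continue
            f = ln.rstrip("\n").split("\t")
            out.append((lineno, f))
    if not out:
        logger.warning("%s file %s is empty", what, path)
    return out


def read_chrom_sizes(path) -> dict[str, int]:
    sizes = {}
    for lineno, f in _read_two_col(path, "chromosome sizes"):
        if len(f) < 2:
            raise ValueError(f"{path}: line {lineno}: expected chrom<TAB>length")
        try:
            sizes[f[0]] = int(f[1])
        except ValueError:
            if lineno == 1:  # tolerate a header
                continue
            raise ValueError(f"{path}: line {lineno}: non-integer length {f[1]!r}")
    return sizes


def read_centromeres(path) -> dict[str, tuple[int, int]]:
    cents = {}
    for lineno, f in _read_two_col(path, "centromere"):
        if len(f) < 3:
            raise ValueError(f"{path}: line {lineno}: expected chrom<TAB>start<TAB>end")
        try:
            cents[f[0]] = (int(f[1]), int(f[2]))
        except ValueError:
            if lineno == 1:
                continue
            raise ValueError(f"{path}: line {lineno}: non-integer centromere bounds")
    return cents


def read_gene_annotation(
    gff3_path,
    chrom_sizes_path,
    centromere_path=None,
    status_attribute: str = "orf_classification",
) -> GenomeAnnotation:
    """Load gene features from GFF3 plus chromosome lengths and centromeres.

    1-based inclusive coordinates are preserved exactly.  Gene status is read
    from ``status_attribute`` (default ``orf_classification``); genes without
    a recognized status default to "uncharacterized".  Chromosomes missing a
    centromere entry only get a warning here; arm-position analyses reject
    them later.
    """
    import gffutils

    db = gffutils.create_db(
        str(gff3_path),
        ":memory:",
        merge_strategy="error",
        keep_order=True,
        from_string=False,
    )
    chrom_lengths = read_chrom_sizes(chrom_sizes_path)
    centromeres = read_centromeres(centromere_path) if centromere_path else {}

    rows = []
    seen = set()
    for feat in db.features_of_type("gene"):
        gid = feat.id
        if gid in seen:
            raise ValueError(f"duplicate gene id {gid!r} in {gff3_path}")
        seen.add(gid)
        status = feat.attributes.get(status_attribute, ["uncharacterized"])[0].lower()
        if status not in ("verified", "uncharacterized", "dubious"):
            status = "uncharacterized"
        strand = feat.strand if feat.strand in ("+", "-") else "+"
        rows.append((gid, feat.seqid, int(feat.start), int(feat.end), strand, status))
    genes = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand", "status"]
    ).set_index("gene_id")
    for chrom in genes["chrom"].unique():
        if chrom in chrom_lengths and chrom not in centromeres:
            logger.warning("no centromere recorded for chromosome %s", chrom)
    ann = GenomeAnnotation(genes, chrom_lengths, centromeres)
    logger.info("read %d genes on %d chromosomes", len(genes), len(chrom_lengths))
    return ann


def write_gene_annotation(annotation: GenomeAnnotation, gff3_path, chrom_sizes_path,
                          centromere_path) -> None:
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in annotation.chrom_lengths.items():
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for gid, row in annotation.genes.iterrows():
            attrs = f"ID={gid};orf_classification={row['status']}"
            fh.write(
                f"{row['chrom']}\tchromexpr\tgene\t{row['start']}\t{row['end']}"
                f"\t.\t{row['strand']}\t.\t{attrs}\n"
            )
    with open(chrom_sizes_path, "w") as fh:
        for chrom, length in annotation.chrom_lengths.items():
            fh.write(f"{chrom}\t{length}\n")
    with open(centromere_path, "w") as fh:
        for chrom, (s, e) in annotation.centromeres.items():
            fh.write(f"{chrom}\t{s}\t{e}\n")


def read_expression_matrix(path, probe_map=None) -> ExpressionMatrix:
    """Read a genes-x-samples TSV of linear-scale intensities.

    First column holds gene (or probe) ids, remaining columns one sample
    each.  Empty cells become missing values.  When several rows map to one
    gene — duplicated row ids, or many-to-one ``probe_map`` (probe_id ->
    gene_id dict or 2-column TSV) — their profiles are collapsed by
    averaging.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    bad = df.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    if (bad.isna() & df.notna()).any().any():
        cell = np.argwhere((bad.isna() & df.notna()).to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric expression value at row {df.index[cell[0]]!r}, "
            f"sample {df.columns[cell[1]]!r}"
        )
    df = bad.astype(float)
    if probe_map is not None:
        if not isinstance(probe_map, dict):
            pm = pd.read_csv(probe_map, sep="\t", header=None, names=["probe", "gene"])
            probe_map = dict(zip(pm["probe"], pm["gene"]))
        df.index = [probe_map.get(p, p) for p in df.index]
    if df.index.has_duplicates:
        n_before = len(df)
        df = df.groupby(level=0, sort=False).mean()
        logger.info("collapsed %d probe rows into %d genes", n_before, len(df))
    df.index.name = "gene_id"
    return ExpressionMatrix(df, normalized=False)


def write_expression_matrix(expr: ExpressionMatrix, path) -> None:
    out = expr.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_gene_sets(membership_path, catalog_path=None) -> GeneSetCollection:
    """Read a flat gene-set collection.

    ``membership_path``: 2-column TSV (gene_id, term_id), header optional.
    ``catalog_path``: optional TSV (term_id, domain, name); terms not in the
    catalog default to domain "other".
    """
    mem = pd.read_csv(membership_path, sep="\t", header=None, names=["gene_id", "term_id"],
                      comment="#", dtype=str)
    if len(mem) and mem.iloc[0]["gene_id"] in ("gene_id", "gene"):
        mem = mem.iloc[1:]
    catalog: dict[str, tuple[str, str]] = {}
    if catalog_path is not None:
        cat = pd.read_csv(catalog_path, sep="\t", header=None,
                          names=["term_id", "domain", "name"], comment="#", dtype=str)
        if len(cat) and cat.iloc[0]["term_id"] == "term_id":
            cat = cat.iloc[1:]
        catalog = {r.term_id: (r.domain, r.name) for r in cat.itertuples()}
    terms = {}
    for tid, sub in mem.groupby("term_id", sort=False):
        domain, name = catalog.get(tid, ("other", tid))
        terms[tid] = GeneSet(tid, domain, name, frozenset(sub["gene_id"]))
    logger.info("read %d gene sets (%d memberships)", len(terms), len(mem))
    return GeneSetCollection(terms)


def write_gene_sets(collection: GeneSetCollection, membership_path, catalog_path) -> None:
    with open(membership_path, "w") as fh:
        for tid in sorted(collection.terms):
            for g in sorted(collection.terms[tid].genes):
                fh.write(f"{g}\t{tid}\n")
    with open(catalog_path, "w") as fh:
        for tid in sorted(collection.terms):
            gs = collection.terms[tid]
            fh.write(f"{tid}\t{gs.domain}\t{gs.name}\n")


def write_table(df: pd.DataFrame, path) -> None:
    """Write any result table as TSV (full float precision)."""
    df.to_csv(path, sep="\t", index=False)


def file_checksum(path) -> str:
    import hashlib

    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
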
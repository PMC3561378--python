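import numpy as np
import pandas as pd
import pytest

import chromexpr as cx


def make_annotation(genes, chrom_lengths=None, centromeres=None):
    """Build a GenomeAnnotation from (gene_id, chrom, start, end, strand[, status])."""
    rows = []
    for g in genes:
        gid, chrom, start, end, strand = g[:5]
        status = g[5] if len(g) > 5 else "verified"
        rows.append((gid, chrom, start, end, strand, status))
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand",
                                     "status"]).set_index("gene_id")
    if chrom_lengths is None:
        chrom_lengths = {c: int(sub["end"].max()) + 10_000
                         for c, sub in df.groupby("chrom")}
    return cx.GenomeAnnotation(df, chrom_lengths, centromeres or {})


def make_contacts(rows, library="test"):
    """Build a ContactTable from (chrom_a, pos_a, chrom_b, pos_b, count)."""
    df = pd.DataFrame(rows, columns=["chrom_a", "pos_a", "chrom_b", "pos_b", "count"])
    df["library"] = library
    return cx.ContactTable(df)


def make_expression(profiles, sample_prefix="S", normalized=False):
    """Build an ExpressionMatrix from {gene_id: profile}."""
    df = pd.DataFrame({g: np.asarray(v, dtype=float) for g, v in profiles.items()}).T
    df.columns = [f"{sample_prefix}{i}" for i in range(df.shape[1])]
    df.index.name = "gene_id"
    return cx.ExpressionMatrix(df, normalized=normalized)


def random_toy_instance(rng, n_chroms=3, max_genes=50, max_contacts=100,
                        chrom_len=100_000):
    """A random small genome + contact list for oracle-equivalence tests."""
    n_genes = int(rng.integers(4, max_genes + 1))
    genes = []
    for i in range(n_genes):
        chrom = f"c{int(rng.integers(1, n_chroms + 1))}"
        start = int(rng.integers(1, chrom_len - 3000))
        end = start + int(rng.integers(100, 3000))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append((f"t{i:03d}", chrom, start, end, strand))
    ann = make_annotation(genes, {f"c{k}": chrom_len for k in range(1, n_chroms + 1)})
    n_contacts = int(rng.integers(1, max_contacts + 1))
    rows = []
    for _ in range(n_contacts):
        ca = f"c{int(rng.integers(1, n_chroms + 1))}"
        cb = f"c{int(rng.integers(1, n_chroms + 1))}"
        rows.append((ca, int(rng.integers(1, chrom_len)),
                     cb, int(rng.integers(1, chrom_len)),
                     int(rng.integers(1, 15))))
    return ann, make_contacts(rows)


def brute_force_links(contacts, annotation, offset_bp, min_count, inter_only,
                      anchor_mode, aggregation):
    """Exhaustive (contact x geneA x geneB) triple loop; the mapping oracle."""
    genes = [(gid, r.chrom, r.start, r.end, r.strand)
             for gid, r in zip(annotation.genes.index,
                               annotation.genes.itertuples(index=False))]

    def near(chrom, pos, g):
        gid, gchrom, start, end, strand = g
        if gchrom != chrom:
            return False
        if anchor_mode == "boundary":
            d = max(start - pos, pos - end, 0)
        else:
            d = abs(pos - (start if strand == "+" else end))
        return d <= offset_bp

    agg = {}
    for rec in contacts.records.itertuples(index=False):
        if rec.count < min_count:
            continue
        for ga in genes:
            if not near(rec.chrom_a, rec.pos_a, ga):
                continue
            for gb in genes:
                if not near(rec.chrom_b, rec.pos_b, gb):
                    continue
                if ga[0] == gb[0] or (inter_only and ga[1] == gb[1]):
                    continue
                key = tuple(sorted((ga[0], gb[0])))
                if key not in agg:
                    agg[key] = [rec.count, 1]
                elif aggregation == "max":
                    agg[key][0] = max(agg[key][0], rec.count)
                    agg[key][1] += 1
                else:
                    agg[key][0] += rec.count
                    agg[key][1] += 1
    return {k: tuple(v) for k, v in agg.items()}


def union_find_components(nodes, edges):
    """Independent connected-components oracle."""
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    comps = {}
    for n in nodes:
        comps.setdefault(find(n), set()).add(n)
    return sorted((len(c) for c in comps.values()), reverse=True)


@pytest.fixture(scope="session")
def small_dataset():
    """Small planted dataset shared by unit tests (module links dominate)."""
    params = cx.GeneratorParams(
        n_chroms=6, genes_per_chrom=20, n_samples=120, n_modules=3,
        module_size=12, rho_linked=0.4, contact_background_rate=0.002,
        module_contact_rate=0.35, lambda_bg=3.0, lambda_mod=8.0, seed=42,
    )
    return cx.generate_dataset(params)


@pytest.fixture(scope="session")
def small_links(small_dataset):
    ds = small_dataset
    return cx.build_gene_links(ds.contacts, ds.annotation, offset_bp=500, min_count=1)


@pytest.fixture(scope="session")
def small_expr(small_dataset):
    return cx.normalize_samples(small_dataset.expression)
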
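"""Synthetic genomes, expression compendia, contact lists, and gene sets.

The generator plants exactly the structure the pipeline is designed to
detect, with known ground truth:

* a multi-chromosome genome laid out as a regular gene grid with centromeres
  and a fraction of "dubious" ORFs;
* an expression matrix in which each planted module shares a latent factor,
  so same-module gene pairs have a target Pearson correlation ``rho_linked``
  (on the latent scale; the positive lognormal mapping attenuates it only
  mildly at the default shift);
* a contact list whose inter-chromosomal fragment pairs fall near random
  gene pairs at a background rate and near same-module pairs at an elevated
  rate (``enrichment_multiplier``), with truncated-Poisson count
  frequencies; in stratified mode higher count strata carry higher planted
  correlation, producing a rising frequency-threshold curve;
* gene sets that coincide with the planted modules (enriched terms), random
  groups (null terms), and the dubious genes (a contact-depleted set).

Module genes are interleaved across chromosomes so planted links are
inter-chromosomal; dubious genes never join modules, so they end up
contact-depleted like dubious ORFs in real data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
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


@dataclass
class GeneratorParams:
    """Knobs of the synthetic study, with the default desk-scale conditions.

    Defaults give 500 genes on 10 chromosomes, 200 samples, 5 modules of 40
    genes at latent correlation 0.3, a 2x contact-rate multiplier inside
    modules over a 2% background pair rate — small enough that the full
    pipeline runs in minutes, large enough that every planted effect is
    detectable above Monte-Carlo noise.
    """

    n_chroms: int = 10
    genes_per_chrom: int = 50
    gene_length_bp: int = 1500
    intergenic_bp: int = 1000
    n_samples: int = 200
    n_modules: int = 5
    module_size: int = 40
    rho_linked: float = 0.3
    background_rho: float = 0.0
    contact_background_rate: float = 0.02
    enrichment_multiplier: float = 2.0
    module_contact_rate: float | None = None  # override rate*multiplier if set
    lambda_bg: float = 4.0
    lambda_mod: float = 10.0
    dubious_fraction: float = 0.1
    offset_bp: int = 500
    sites_per_gene: int = 2  # restriction-site loci available to each gene
    lognormal_shift: float = 0.25
    baseline_intensity: float = 4.0
    centromere_rel_pos: float = 0.4
    centromere_width_bp: int = 2000
    stratified: bool = False
    rho_strata: tuple = (0.1, 0.2, 0.3)
    lambda_strata: tuple = (2.0, 8.0, 25.0)
    module_chrom_spread: int | None = None  # chromosomes per module (default half)
    n_null_terms: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.rho_linked < 1):
            raise ValueError("rho_linked must be in [0, 1)")
        if self.enrichment_multiplier < 0 or self.contact_background_rate < 0:
            raise ValueError("rates and multipliers must be >= 0")
        if self.n_modules * self.module_size > self.n_chroms * self.genes_per_chrom:
            raise ValueError("modules do not fit in the genome")
        if self.n_chroms < 2:
            raise ValueError("need >= 2 chromosomes for inter-chromosomal structure")


@dataclass
class SyntheticTruth:
    """Ground truth of one generated dataset, for parameter-recovery tests."""

    module_members: dict[int, list[str]]
    gene_module: dict[str, int]
    module_rho: dict[int, float]
    module_stratum: dict[int, int]
    planted_contacts: list  # (gene_a, gene_b, count, kind) with kind "module"/"background"
    params: GeneratorParams

    def n_planted(self, kind: str | None = None) -> int:
        return sum(1 for c in self.planted_contacts if kind is None or c[3] == kind)


def _rng_stream(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def generate_genome(params: GeneratorParams) -> GenomeAnnotation:
    """Deterministic gene grid with alternating strands and centromeres.

    Gene j on chromosome c occupies
    [intergenic + (j-1)(len+intergenic) + 1, ... + len - 1]; the centromere
    sits at a fixed relative position of each chromosome.  Dubious status is
    assigned to a seeded random gene subset.
    """
    spacing = params.gene_length_bp + params.intergenic_bp
    chrom_len = params.genes_per_chrom * spacing + params.intergenic_bp
    rng = _rng_stream(params.seed, 0)
    rows = []
    chrom_lengths = {}
    centromeres = {}
    for c in range(1, params.n_chroms + 1):
        chrom = f"chr{c:02d}"
        chrom_lengths[chrom] = chrom_len
        cmid = int(params.centromere_rel_pos * chrom_len)
        half = params.centromere_width_bp // 2
        centromeres[chrom] = (max(1, cmid - half), min(chrom_len, cmid + half))
        for j in range(1, params.genes_per_chrom + 1):
            start = params.intergenic_bp + (j - 1) * spacing + 1
            end = start + params.gene_length_bp - 1
            strand = "+" if j % 2 == 1 else "-"
            rows.append((f"G{c:02d}_{j:04d}", chrom, start, end, strand))
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    n_genes = len(genes)
    n_dub = int(round(params.dubious_fraction * n_genes))
    dubious = set(rng.choice(n_genes, size=n_dub, replace=False))
    genes["status"] = [
        "dubious" if i in dubious else "verified" for i in range(n_genes)
    ]
    genes = genes.set_index("gene_id")
    return GenomeAnnotation(genes, chrom_lengths, centromeres)


def _assign_modules(annotation: GenomeAnnotation, params: GeneratorParams) -> SyntheticTruth:
    """Spread each module's genes round-robin over a random chromosome subset.

    Drawing from several chromosomes makes nearly all same-module pairs
    inter-chromosomal; restricting each module to its own random subset
    (default: half the chromosomes) makes link density and co-expression
    vary together across chromosome pairs — the planted coupling the
    chromosome-pair regression detects.
    """
    rng = _rng_stream(params.seed, 1)
    pools: dict[str, list[str]] = {}
    for chrom, sub in annotation.genes.groupby("chrom"):
        ids = [g for g in sub.index if sub.loc[g, "status"] != "dubious"]
        pools[chrom] = list(np.array(ids)[rng.permutation(len(ids))])
    chrom_names = sorted(pools)
    spread = params.module_chrom_spread or max(2, params.n_chroms // 2)
    spread = min(max(2, spread), params.n_chroms)
    module_members: dict[int, list[str]] = {}
    gene_module: dict[str, int] = {}
    module_rho: dict[int, float] = {}
    module_stratum: dict[int, int] = {}
    n_strata = len(params.rho_strata)
    for m in range(params.n_modules):
        usable = [c for c in chrom_names if pools[c]]
        if len(usable) < 2:
            raise ValueError("not enough non-dubious genes for the requested modules")
        chosen = list(rng.choice(usable, size=min(spread, len(usable)), replace=False))
        members: list[str] = []
        k = 0
        while len(members) < params.module_size:
            avail = [c for c in chosen if pools[c]]
            if not avail:
                avail = [c for c in chrom_names if pools[c]]  # subset exhausted
                if not avail:
                    raise ValueError("not enough non-dubious genes for the requested modules")
            members.append(pools[avail[k % len(avail)]].pop())
            k += 1
        module_members[m] = sorted(members)
        for g in members:
            gene_module[g] = m
        if params.stratified:
            s = m % n_strata
            module_stratum[m] = s
            module_rho[m] = float(params.rho_strata[s])
        else:
            module_stratum[m] = -1
            module_rho[m] = params.rho_linked
    return SyntheticTruth(module_members, gene_module, module_rho, module_stratum,
                          planted_contacts=[], params=params)


def generate_expression(
    annotation: GenomeAnnotation, params: GeneratorParams
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Latent single-factor-per-module expression with target pair correlation.

    Module gene g in module m gets latent profile
    sqrt(rho_m) * F_m + sqrt(1 - rho_m) * eps_g, mapped to positive
    intensities as baseline + exp(shift * latent); non-module genes are
    independent noise (optionally sharing a weak global factor
    ``background_rho``).  For small ``lognormal_shift`` the exponential
    preserves the latent pairwise correlation to within a few percent.  The
    additive ``baseline_intensity`` emulates the stable bulk of a real
    intensity compendium (nonspecific background plus high-abundance
    housekeeping signal): it keeps per-sample means nearly constant, so the
    pipeline's sample-mean normalization rescales samples without stripping
    the planted module covariance.
    """
    truth = _assign_modules(annotation, params)
    rng = _rng_stream(params.seed, 2)
    genes = annotation.gene_ids
    n_g, n_s = len(genes), params.n_samples
    factors = rng.standard_normal((params.n_modules, n_s))
    global_factor = rng.standard_normal(n_s)
    eps = rng.standard_normal((n_g, n_s))
    latent = np.empty((n_g, n_s))
    rho_bg = params.background_rho
    for i, g in enumerate(genes):
        m = truth.gene_module.get(g)
        if m is not None:
            rho = truth.module_rho[m]
            latent[i] = np.sqrt(rho) * factors[m] + np.sqrt(1 - rho) * eps[i]
        elif rho_bg > 0:
            latent[i] = np.sqrt(rho_bg) * global_factor + np.sqrt(1 - rho_bg) * eps[i]
        else:
            latent[i] = eps[i]
    values = params.baseline_intensity + np.exp(params.lognormal_shift * latent)
    df = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                      columns=[f"S{j:04d}" for j in range(n_s)])
    return ExpressionMatrix(df, normalized=False), truth


def _truncated_poisson(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    """Poisson(lam) conditioned on >= 1 (every contact was sequenced >= once)."""
    out = rng.poisson(lam, size=size)
    zero = out == 0
    while zero.any():
        out[zero] = rng.poisson(lam, size=int(zero.sum()))
        zero = out == 0
    return out


def generate_contacts(
    annotation: GenomeAnnotation, truth: SyntheticTruth, params: GeneratorParams
) -> ContactTable:
    """Plant inter-chromosomal contacts near gene pairs.

    Background: every trans gene pair receives a contact with probability
    ``contact_background_rate`` and count ~ truncated Poisson(lambda_bg).
    Same-module pairs instead use rate * ``enrichment_multiplier`` (or the
    explicit ``module_contact_rate``) and Poisson(lambda_mod) — or the
    stratum's lambda in stratified mode.  Each gene carries a fixed set of
    ``sites_per_gene`` restriction-site loci inside its body (digestion
    fragments recur across contacts, so matrix rows accumulate many
    entries, as in real 4C maps); each contact draws one site per end.
    Mapping at the generator's offset recovers the planted pair exactly
    (the intergenic spacing exceeds 2 * offset, so no spurious neighbour
    assignment at the default offset).
    """
    rng = _rng_stream(params.seed, 3)
    genes = np.array(annotation.gene_ids)
    chroms = annotation.genes["chrom"].to_numpy()
    starts = annotation.genes["start"].to_numpy()
    ends = annotation.genes["end"].to_numpy()
    iu, ju = np.triu_indices(len(genes), k=1)
    trans = chroms[iu] != chroms[ju]
    iu, ju = iu[trans], ju[trans]

    mod_of = np.array([truth.gene_module.get(g, -1) for g in genes])
    same_module = (mod_of[iu] >= 0) & (mod_of[iu] == mod_of[ju])
    p_mod = (params.module_contact_rate
             if params.module_contact_rate is not None
             else min(1.0, params.contact_background_rate * params.enrichment_multiplier))
    prob = np.where(same_module, p_mod, params.contact_background_rate)
    hit = rng.random(len(iu)) < prob
    hi, hj, hmod = iu[hit], ju[hit], same_module[hit]

    counts = np.empty(len(hi), dtype=np.int64)
    if (~hmod).any():
        counts[~hmod] = _truncated_poisson(rng, params.lambda_bg, int((~hmod).sum()))
    if hmod.any():
        if params.stratified:
            strata = np.array([truth.module_stratum[truth.gene_module[genes[i]]]
                               for i in hi[hmod]])
            cm = np.empty(int(hmod.sum()), dtype=np.int64)
            for s in np.unique(strata):
                sel = strata == s
                cm[sel] = _truncated_poisson(rng, float(params.lambda_strata[s]),
                                             int(sel.sum()))
            counts[hmod] = cm
        else:
            counts[hmod] = _truncated_poisson(rng, params.lambda_mod, int(hmod.sum()))

    k = max(1, params.sites_per_gene)
    sites = rng.integers(starts[:, None], ends[:, None] + 1, size=(len(genes), k))
    pos_a = sites[hi, rng.integers(0, k, size=len(hi))]
    pos_b = sites[hj, rng.integers(0, k, size=len(hj))]
    libs = np.where(rng.random(len(hi)) < 0.5, "HindIII", "EcoRI")
    rec = pd.DataFrame({
        "chrom_a": chroms[hi], "pos_a": pos_a,
        "chrom_b": chroms[hj], "pos_b": pos_b,
        "count": counts, "library": libs,
    })[CONTACT_COLUMNS]
    truth.planted_contacts = [
        (genes[i], genes[j], int(c), "module" if m else "background")
        for i, j, c, m in zip(hi, hj, counts, hmod)
    ]
    logger.info("planted %d contacts (%d module, %d background)",
                len(rec), int(hmod.sum()), int((~hmod).sum()))
    return ContactTable(rec)


def generate_gene_sets(
    annotation: GenomeAnnotation, truth: SyntheticTruth, params: GeneratorParams
) -> GeneSetCollection:
    """Module terms (enriched), random null terms, and the dubious set."""
    rng = _rng_stream(params.seed, 4)
    terms: dict[str, GeneSet] = {}
    for m, members in truth.module_members.items():
        tid = f"MOD{m:02d}"
        terms[tid] = GeneSet(tid, "biological_process", f"planted module {m}",
                             frozenset(members))
    all_genes = np.array(annotation.gene_ids)
    for k in range(params.n_null_terms):
        tid = f"NULL{k:03d}"
        members = rng.choice(all_genes, size=params.module_size, replace=False)
        terms[tid] = GeneSet(tid, "molecular_function", f"random group {k}",
                             frozenset(members))
    dubious = frozenset(annotation.genes.index[annotation.genes["status"] == "dubious"])
    if dubious:
        terms["DUBIOUS"] = GeneSet("DUBIOUS", "other", "dubious ORFs", dubious)
    return GeneSetCollection(terms)


@dataclass
class SyntheticDataset:
    annotation: GenomeAnnotation
    expression: ExpressionMatrix
    contacts: ContactTable
    gene_sets: GeneSetCollection
    truth: SyntheticTruth


def generate_dataset(params: GeneratorParams, out_dir=None, force: bool = False
                     ) -> SyntheticDataset:
    """Generate the full bundle and optionally write it to ``out_dir``.

    Files emitted: genes.gff3, chrom_sizes.tsv, centromeres.tsv,
    expression.tsv, contacts.tsv, gene_sets.tsv, term_catalog.tsv,
    truth.json, manifest.json — the same formats the io readers consume.
    """
    annotation = generate_genome(params)
    expression, truth = generate_expression(annotation, params)
    contacts = generate_contacts(annotation, truth, params)
    gene_sets = generate_gene_sets(annotation, truth, params)
    ds = SyntheticDataset(annotation, expression, contacts, gene_sets, truth)
    if out_dir is not None:
        write_dataset(ds, out_dir, force=force)
    return ds


def write_dataset(ds: SyntheticDataset, out_dir, force: bool = False) -> None:
    from . import io as cio

    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is not empty (use force=True)")
    out.mkdir(parents=True, exist_ok=True)
    cio.write_gene_annotation(ds.annotation, out / "genes.gff3",
                              out / "chrom_sizes.tsv", out / "centromeres.tsv")
    cio.write_expression_matrix(ds.expression, out / "expression.tsv")
    cio.write_contacts(ds.contacts, out / "contacts.tsv")
    cio.write_gene_sets(ds.gene_sets, out / "gene_sets.tsv", out / "term_catalog.tsv")
    truth = ds.truth
    with open(out / "truth.json", "w") as fh:
        json.dump({
            "module_members": {str(k): v for k, v in truth.module_members.items()},
            "module_rho": {str(k): v for k, v in truth.module_rho.items()},
            "module_stratum": {str(k): v for k, v in truth.module_stratum.items()},
            "planted_contacts": [list(c) for c in truth.planted_contacts],
        }, fh, indent=1)
    with open(out / "manifest.json", "w") as fh:
        json.dump({"generator_params": asdict(truth.params)}, fh, indent=1, default=list)
    logger.info("wrote synthetic dataset to %s", out)
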
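"""Generate a synthetic 4C study and map contacts to gene links.

The generator plants a 500-gene genome on 10 chromosomes with five
co-expression modules whose gene pairs receive inter-chromosomal contacts
at twice the background rate.  Contact loci are then assigned to genes
within a 500 bp offset and collapsed into an inter-chromosomal gene-link
table.
"""

import chromexpr as cx

params = cx.GeneratorParams(seed=1)
ds = cx.generate_dataset(params)
print(f"genome: {len(ds.annotation.genes)} genes on "
      f"{len(ds.annotation.chrom_lengths)} chromosomes")
print(f"contacts: {len(ds.contacts)} fragment pairs "
      f"({ds.truth.n_planted('module')} on module pairs, "
      f"{ds.truth.n_planted('background')} background)")

links_all = cx.build_gene_links(ds.contacts, ds.annotation,
                                offset_bp=params.offset_bp, min_count=1)
links_5 = cx.build_gene_links(ds.contacts, ds.annotation,
                              offset_bp=params.offset_bp, min_count=5)
print(f"gene links: {len(links_all)} at any count, "
      f"{len(links_5)} with count frequency >= 5")
print("# every gene pair joined by a sequenced contact becomes one link;")
print("# the count threshold keeps only well-supported (stronger) contacts")
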
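"""Gene contact networks for functionally coherent vs inert gene sets.

A gene set's links form an undirected graph (isolated genes included).
A planted module concentrates into a dense connected subgraph, while
the dubious genes scatter — the edges-per-node ratio quantifies the
contrast.
"""

import chromexpr as cx

params = cx.GeneratorParams(n_chroms=6, genes_per_chrom=20, n_samples=120,
                            n_modules=3, module_size=12,
                            contact_background_rate=0.002,
                            module_contact_rate=0.35, seed=42)
ds = cx.generate_dataset(params)
links = cx.build_gene_links(ds.contacts, ds.annotation, min_count=1)

for tid in ("MOD00", "MOD01", "DUBIOUS"):
    net = cx.build_network(ds.gene_sets.terms[tid], links, ds.annotation,
                           min_count=1)
    s = cx.network_stats(net)
    print(f"{tid:8s} nodes={s['n_nodes']:3d} edges={s['n_edges']:3d} "
          f"edges/node={s['edges_per_node']:.2f} "
          f"largest component={s['largest_component']} "
          f"isolated={s['n_isolated']}")
print("# module networks are an order of magnitude denser than the dubious")
print("# set despite comparable gene counts — the planted topology contrast")
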
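"""Build and inspect a cross-resolution cluster graph.

Clusters a nested synthetic tissue (2 superdomains x 2 subdomains) at
k = 2 and k = 4 and prints the overlap edges: each k=4 cluster's incoming
proportions say which coarse cluster its spots came from.
"""

from spotpie import (
    TissueParams,
    build_cluster_graph,
    cluster_multi_resolution,
    filter_edges,
    generate_tissue,
    normalize_log,
    resolutions_from_ks,
)

tissue = generate_tissue(
    TissueParams(width=16, height=16, n_domains=4, n_superdomains=2, seed=1)
)
matrix = normalize_log(tissue.matrix)
mrc = cluster_multi_resolution(matrix, resolutions_from_ks([2, 4], seed=1))
graph = filter_edges(build_cluster_graph(matrix, mrc), threshold=0.05)

print("nodes (resolution, cluster, size, top marker):")
for node in graph.nodes:
    gene, value = node.top_genes[0]
    print(f"  k={node.resolution_label} cluster {node.cluster_label}: "
          f"{node.size} spots, color {node.hex_color}, top gene {gene} ({value:.2f})")

print("edges (parent -> child, proportion of child's spots shared):")
for edge in graph.edges:
    print(f"  k=2 cluster {edge.parent[1]} -> k=4 cluster {edge.child[1]}: "
          f"{edge.proportion:.2f}")
print(
    "A proportion near 1 means the finer cluster descends almost entirely\n"
    "from that coarse cluster; sibling subdomains share a parent."
)
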
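"""Build heterogeneous and homogeneous miRNA networks from an interaction list.

A small synthetic miRNA-target interaction set stands in for a database
export (miRWalk- or TargetScan-style TSV).  From the same interactions we
build the bipartite miRNA-gene network (mutual mode: every interaction is
reciprocal) and the miRNA-only network whose edges weight the fraction of
shared targets.
"""

import rwrmtn as rw

spec = rw.FixtureSpec(rng_seed=7)
interactions = rw.generate_interactions(spec)
print(interactions)

hetero = rw.build_heterogeneous(interactions, "mutual")
print(
    f"heterogeneous (mutual): {hetero.n_nodes} nodes "
    f"({hetero.n_mirnas} miRNAs + {hetero.n_genes} genes), {hetero.n_edges} edges"
)

homo = rw.build_homogeneous(interactions)
print(f"homogeneous: {homo.n_mirnas} miRNAs, {homo.n_edges} weighted edges")

row0 = homo.adjacency.getrow(0)
a, b = homo.mirnas[0], homo.mirnas[row0.indices[0]]  # first actual edge
ta, tb = interactions.targets_of(a), interactions.targets_of(b)
print(
    f"weight({a}, {b}) = {homo.weight(a, b):.3f} "
    f"= |{len(ta & tb)} shared targets| / min({len(ta)}, {len(tb)})"
)
# The weight is the shared-target similarity: 1.0 means the smaller target
# set is entirely contained in the overlap; 0 means no edge at all.
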
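"""Gene-set overrepresentation (EASE scores, annotation clusters) and
directional upstream-regulator calls on a simulated study.

Gene sets and the signed regulator network are user-supplied (GMT and
edge-list TSV in real use); here both are built in a few lines so the
statistics can be traced by eye.
"""

from arraycascade import (
    GeneSet,
    GeneSetCollection,
    annotation_clusters,
    fisher_enrich,
    upstream_z,
)
from arraycascade.io import RegulatorNetwork
import pandas as pd

universe = [f"Gene{i:03d}" for i in range(200)]
query = universe[:20]  # the "significant" genes

sets = GeneSetCollection({
    "adhesion": GeneSet("GO-style", tuple(universe[:15])),        # enriched
    "adhesion_junctions": GeneSet("GO-style", tuple(universe[:12])),
    "metabolism": GeneSet("GO-style", tuple(universe[100:140])),  # not enriched
})

table = fisher_enrich(query, sets, universe)
print(table[["n_hits", "n_set", "p_fisher", "p_ease", "q"]].to_string())

clusters = annotation_clusters(table, sets, query)
for c in clusters:
    print(f"cluster {c.name}: members={c.members} score={c.score:.2f}")
# The cluster score is the mean of -log10(EASE p) over its member sets:
# a score of 2 means the typical member is enriched at p = 0.01.

de = pd.DataFrame(
    {"symbol": universe[:10], "delta": [1.0] * 8 + [-1.0] * 2,
     "fc": [2.0] * 8 + [-2.0] * 2, "level": ["L1"] * 10},
    index=pd.Index([f"p{i}" for i in range(10)], name="probe_id"),
)
net = RegulatorNetwork([("REG_X", g, 1) for g in universe[:9]])
calls = upstream_z(de, net)
print("\nupstream regulator calls:")
print(calls.to_string())
# z = sum(expected_sign * observed_sign)/sqrt(N); |z| >= 2 calls the
# regulator activated (consistent up-regulation of its targets) or
# inhibited.
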
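"""Disease semantic similarity from ancestor DAGs, by both models.

Three toy diseases: flu and pneumonia share the ancestor chain
respiratory <- infection, while dermatitis hangs off a separate branch.
Model 1 decays contributions by 0.5 per edge away from the disease;
model 2 weights each term by how rare it is across the three DAGs.
"""

import networkx as nx

from qimcmda import SemanticParams, build_ss, semantic_similarity
from qimcmda.semantic import d1_contributions, d2_contributions, semantic_value
from qimcmda.types import DagTable


def dag(disease, edges):
    g = nx.DiGraph()
    g.add_node(disease)
    g.add_edges_from(edges)
    return g


table = DagTable(dags={
    "flu": dag("flu", [("infection", "respiratory"), ("respiratory", "flu")]),
    "pneumonia": dag("pneumonia", [("infection", "respiratory"),
                                   ("respiratory", "pneumonia")]),
    "dermatitis": dag("dermatitis", [("infection", "skin"),
                                     ("skin", "dermatitis")]),
})
table.validate()

params = SemanticParams(delta=0.5)
c1 = d1_contributions(table, "flu", params)
print("model-1 contributions to flu:", {k: round(v, 3) for k, v in c1.items()})
print(f"semantic value DV1(flu) = {semantic_value(c1):.3f}")
c2 = d2_contributions(table, "flu")
print("model-2 contributions to flu:", {k: round(v, 3) for k, v in c2.items()})

for a, b in [("flu", "pneumonia"), ("flu", "dermatitis")]:
    s1 = semantic_similarity(table, a, b, model=1, params=params)
    s2 = semantic_similarity(table, a, b, model=2)
    print(f"{a} vs {b}: model1={s1:.3f}  model2={s2:.3f}")

ss = build_ss(table, params)
print("\nintegrated SS = (SS1+SS2)/2:")
for i, d in enumerate(ss.names):
    print(" ", d, [round(float(v), 3) for v in ss.values[i]])
# flu and pneumonia share two of three DAG nodes, so their similarity is
# high; dermatitis shares only the ubiquitous root, which model 2 zeroes out
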
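"""Build a small signed target network, score node strengths and validate
predicted directions against measured mRNA fold changes.

Two upregulated and one downregulated miRNA share targets; each gene's node
strength is the sum of +1/-1 edge weights, positive strength predicting the
target is downregulated (miRNAs repress their targets).
"""

import pandas as pd

import mirnanet as mn

pairs = [
    ("hsa-miR-96-5p", "CADM2"),
    ("hsa-miR-5189-3p", "CADM2"),
    ("hsa-miR-96-5p", "TNF"),
    ("hsa-miR-155-5p", "TNF"),
    ("hsa-miR-155-5p", "SOD2"),
]
directions = {"hsa-miR-96-5p": "up", "hsa-miR-5189-3p": "up", "hsa-miR-155-5p": "down"}

net = mn.build_signed_network(pairs, directions)
pred = mn.node_strength(net)
print(pred.to_string(index=False))

mrna = pd.DataFrame({"gene": ["CADM2", "TNF", "SOD2"], "log2fc": [-1.1, 0.4, 1.4], "p": 0.01})
table, summary = mn.validate_predictions(pred, mrna)
print()
print(table[["gene", "node_strength", "predicted_direction", "mrna_log2fc", "consistent"]].to_string(index=False))
print()
print(f"{summary['n_consistent']} of {summary['n_overlap']} overlapping genes are direction-consistent:")
print("CADM2 (strength +2, predicted down) indeed falls, SOD2 (strength -1,")
print("predicted up) indeed rises; TNF's edges cancel to strength 0, which")
print("never validates.")
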
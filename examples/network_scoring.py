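"""From binary annotation profiles to flat scores via gene networks.

Builds two gene networks — one from Jaccard similarity of binary feature
profiles, one handmade — merges them by unweighted averaging, and scores
genes against a term by kernelised proximity to the term's annotated genes.
The resulting per-term score columns are what the correction engines take
as input.
"""

import numpy as np
import pandas as pd

import hierdag as hd

rng = np.random.default_rng(0)
genes = [f"G{i}" for i in range(8)]

# binary gene × feature profiles (e.g. functional annotations)
features = pd.DataFrame(
    (rng.random((8, 12)) < 0.35).astype(int),
    index=genes, columns=[f"F{i}" for i in range(12)],
)
jaccard = hd.jaccard_network(features)
print("Jaccard weight G0–G1:", round(jaccard.loc["G0", "G1"], 3))

# a second, independent network on the same genes
w = rng.random((8, 8))
w = np.clip((w + w.T) / 2, 0, 1)
np.fill_diagonal(w, 0)
other = pd.DataFrame(w, index=genes, columns=genes)

consensus = hd.ua_integrate([jaccard, other])
print("consensus weight G0–G1:", round(consensus.loc["G0", "G1"], 3))

# genes annotated to some term of interest
positives = {"G0", "G3"}
scores = hd.kernel_average_score(consensus, positives, steps=2)
print("\nper-gene scores for the term (2-step kernel, max-normalised):")
print(scores.round(3).sort_values(ascending=False).to_string())
# annotated genes and their close network neighbours score highest; one
# such column per term forms the flat score matrix fed to htd/tpr_correct.
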
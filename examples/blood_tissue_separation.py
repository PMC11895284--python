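"""Separate blood from tissue-resident immune cells on a synthetic mixture.

Generates a four-type immune mixture in which tissue-resident cells are
shifted five within-population SDs away from their blood counterparts in
latent space, classifies every cell against a whole-blood reference, and
scores the calls against the planted truth.
"""

import numpy as np

from scorigin import (
    BloodTissueConfig,
    MixtureSpec,
    auc,
    classify,
    macro_f1,
    simulate_expression,
)

sim = simulate_expression(MixtureSpec(seed=1))
print(f"query: {sim.query.n_cells} cells, reference: {sim.reference.n_cells} cells")

config = BloodTissueConfig(
    embed_method="pca",  # deterministic; "umap" is the default for analysis
    immune_types=("type0", "type1", "type2", "type3"),
    seed=1,
)
ann = classify(sim.query, sim.truth[["barcode", "cell_type"]], sim.reference,
               config, ref_ann=sim.ref_annotation)

truth = sim.truth.set_index("barcode")["compartment"]
called = ann[ann["compartment"] != "unassigned"]
per_type_auc = {
    ct: auc(grp["mean_ref_distance"], truth.loc[grp["barcode"]] == "tissue")
    for ct, grp in called.groupby("cell_type")
}
f1 = macro_f1(called["compartment"].to_numpy(),
              truth.loc[called["barcode"]].to_numpy())

for ct, a in per_type_auc.items():
    print(f"{ct}: AUC vs planted truth = {a:.3f}")
print(f"macro-F1 over blood/tissue = {f1:.3f}")
print(f"mean AUC = {np.mean(list(per_type_auc.values())):.3f}")
# AUC near 1 means each cell's mean distance to the whole-blood reference
# ranks tissue-resident cells above blood cells almost perfectly.
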
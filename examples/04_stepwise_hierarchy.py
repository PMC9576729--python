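"""Coarse-to-fine hierarchical deconvolution.

A coarse bundle separates major lineages (neuron vs glia); a fine bundle
splits neurons into excitatory and inhibitory subtypes and runs only for
samples whose coarse neuron fraction clears the refinement gate. Fine
fractions are reported both within the fine bundle (summing to 1) and
rescaled by the parent's coarse fraction.
"""

import numpy as np
import pandas as pd

from celldecon import BulkSample, HierarchyLevel, stepwise_deconvolve
from celldecon.types import CellTypeProfile, ProfileBundle, ProfileSet


def toy_bundle(name, cell_types, gene_prefix, seed):
    rng = np.random.default_rng(seed)
    genes = [f"{gene_prefix}{i}" for i in range(30)]
    sets = []
    for s in range(2):
        profiles = {}
        for k, ct in enumerate(cell_types):
            v = rng.uniform(1, 10, 30)
            v[k * 10:(k + 1) * 10] *= 20
            v = v / v.sum() * 1e6
            profiles[ct] = CellTypeProfile(ct, pd.Series(v, index=genes),
                                           genes[k * 10:(k + 1) * 10], (name, s))
        sets.append(ProfileSet(set_id=f"{name}{s}", profiles=profiles,
                               training_score=0.01 * (s + 1)))
    return ProfileBundle(group_name=name, cell_types=list(cell_types),
                         gene_universe=genes, profile_sets=sets)


coarse = toy_bundle("major", ("neuron", "glia"), "cg", 1)
fine = toy_bundle("neuron_subtypes", ("excitatory", "inhibitory"), "ng", 2)

# a query that is 80% neuron at the coarse level, split 60/40 within neurons
cmat = coarse.profile_sets[0].matrix()
fmat = fine.profile_sets[0].matrix()
expr = pd.concat([
    0.8 * cmat["neuron"] + 0.2 * cmat["glia"],
    0.8 * (0.6 * fmat["excitatory"] + 0.4 * fmat["inhibitory"]),
])
bulk = BulkSample(sample_id="culture_d21", expression=expr)

[res] = stepwise_deconvolve(
    [bulk],
    [HierarchyLevel(coarse), HierarchyLevel(fine, parent_type="neuron")],
    refine_threshold=0.2,
)
print("coarse level:", {k: round(float(v), 3) for k, v in res.coarse.proportions.items()})
for name, level in res.refined.items():
    print(f"refined '{name}' (gated on {level.parent_type} = {level.parent_fraction:.2f}):")
    print("  within-neuron:", {k: round(float(v), 3) for k, v in level.result.proportions.items()})
    print("  of whole sample:", {k: round(float(v), 3) for k, v in level.rescaled_proportions.items()})
# the rescaled excitatory fraction approximates 0.8 * 0.6 = 0.48 of the sample
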
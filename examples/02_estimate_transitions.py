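"""Estimate stage transition distributions from the packaged reference campaign.

Each recruitment stage yields one empirical distribution of replicate-level
proportions per microhabitat (and seed treatment, for the sowing stages);
these are the objects the bootstrap simulation resamples.
"""

import numpy as np

import seedfate as sf

dataset = sf.study_dataset()  # packaged campaign on the original design
tables = sf.estimate_transition_tables(dataset)
dispersal = sf.estimate_dispersal_distribution(dataset.faeces)

print("deposition distribution (from the dropping survey, 3 core microhabitats):")
for micro, p in dispersal.probs.items():
    print(f"  {micro:<9} {p:.3f}")

print("\nmean transition probability per group:")
for stage in sf.STAGES:
    print(f"  {stage}")
    for key, values in tables[stage].groups.items():
        print(f"    {'/'.join(key):<18} mean {np.mean(values):.3f}  (n={len(values)})")
# Seedling survival beneath the mother plant (EPHEDRA) is zero in every
# replicate — the pattern that later forces the undispersed pathway to zero.
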
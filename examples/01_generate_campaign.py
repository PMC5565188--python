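"""Generate a synthetic field campaign and write its CSV tables.

The campaign mirrors a real seed-fate study layout: 60 predation trays of
10 seeds and 60 sowing stations of 30 seeds (3 treatments), split over 3
microhabitats, 2 zones and 10 spatial sets.
"""

import tempfile
from pathlib import Path

import seedfate as sf

truth = sf.study_truth()          # known true stage means, deposition, kappa
design = sf.study_design()        # the original replicate layout
dataset = sf.generate_field_dataset(truth, design, seed=42)

out = Path(tempfile.mkdtemp()) / "campaign"
paths = sf.write_field_dataset(dataset, out)

print(f"trays: {len(dataset.predation)} ({dataset.n_censored_trays} censored)")
print(f"stations: {len({r.station_id for r in dataset.sowing})}")
print(f"faeces surveyed: {dataset.faeces.total}")
print("tables written to:", out)
# The censored count varies by seed (each tray is destroyed independently
# with probability 7/60); the tray/station counts are fixed by the design.
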
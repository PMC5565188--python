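"""Packaged reference campaign reproducing the original field design.

``study_dataset()`` builds, deterministically, a synthetic campaign with
the real design (60 predation trays of 10 seeds, 60 sowing stations of 30
seeds in 3 treatments, 2 zones x 10 sets), the measured cover values, and
the observed censoring pattern (7 trays destroyed: 1 Open in zone A, 4
Open and 2 Ephedra in zone B).  The outcome counts are synthetic — drawn
from :func:`seedfate.synthetic.study_truth` — since the original raw
counts were never published.

The same campaign is shipped as CSV tables under ``data/study_design/``
(see :func:`study_design_dir`) for exercising the file readers.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .datamodel import EPHEDRA, FieldDataset, OPEN
from .synthetic import STUDY_COVER, generate_field_dataset, study_design, study_truth

__all__ = ["STUDY_COVER", "STUDY_FIXTURE_SEED", "study_dataset", "study_design_dir"]

STUDY_FIXTURE_SEED = 20070801

# (microhabitat, zone, how many trays destroyed) — the observed pattern
_CENSOR_PATTERN = ((OPEN, "A", 1), (OPEN, "B", 4), (EPHEDRA, "B", 2))


def study_dataset(seed: int = STUDY_FIXTURE_SEED) -> FieldDataset:
    """A deterministic synthetic campaign on the original design.

    Censoring is imposed as the exact observed pattern (7 trays) rather
    than drawn at random, so the fixture always carries 60 predation
    records of which 7 are censored.
    """
    truth = study_truth()
    # draw outcomes without random censoring, then impose the known pattern
    from dataclasses import replace as _replace

    dataset = generate_field_dataset(
        _replace(truth, censor_prob=0.0), study_design(), seed, cover=STUDY_COVER
    )
    to_censor = []
    for micro, zone, count in _CENSOR_PATTERN:
        trays = [r.tray_id for r in dataset.predation if r.microhabitat == micro and r.zone == zone]
        to_censor.extend(trays[:count])
    return dataset.with_censored(to_censor).validate()


def study_design_dir() -> Path:
    """Directory of the packaged CSV tables for the reference campaign."""
    return Path(resources.files("seedfate") / "data" / "study_design")
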
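"""Delimited-text readers and writers for field-campaign tables.

One campaign is a directory of five comma-separated tables, each with a
mandatory header row::

    cover.csv             microhabitat,cover
    use_observations.csv  microhabitat,zone,transect
    faeces.csv            microhabitat,count
    predation.csv         tray_id,microhabitat,zone,set_id,n_exposed,n_surviving,censored
    sowing.csv            station_id,microhabitat,zone,set_id,treatment,n_sown,n_emerged,n_surviving

Booleans are written as ``true``/``false``; a censored tray leaves
``n_surviving`` blank.  Extra columns (e.g. per-visit census counts) are
ignored on read: only end-of-monitoring states feed the model.  A JSON
export of the whole dataset is provided for single-file exchange.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Union

import pandas as pd

from .datamodel import (
    CoverTable,
    FaecesSurvey,
    FieldDataset,
    Microhabitat,
    PredationTrialRecord,
    SchemaError,
    SowingRecord,
    UseObservation,
    ValidationError,
)

__all__ = [
    "TABLE_FILES",
    "read_field_dataset",
    "write_field_dataset",
    "dataset_to_json",
    "dataset_from_json",
    "read_dataset_json",
    "write_dataset_json",
]

TABLE_FILES: dict[str, str] = {
    "cover": "cover.csv",
    "use_observations": "use_observations.csv",
    "faeces": "faeces.csv",
    "predation": "predation.csv",
    "sowing": "sowing.csv",
}

_REQUIRED_COLUMNS: dict[str, tuple[str, ...]] = {
    "cover": ("microhabitat", "cover"),
    "use_observations": ("microhabitat", "zone", "transect"),
    "faeces": ("microhabitat", "count"),
    "predation": ("tray_id", "microhabitat", "zone", "set_id", "n_exposed", "n_surviving", "censored"),
    "sowing": ("station_id", "microhabitat", "zone", "set_id", "treatment", "n_sown", "n_emerged", "n_surviving"),
}

PathLike = Union[str, Path]


def _read_table(path: Path, table: str) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(f"{table} table not found: {path}")
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    for column in _REQUIRED_COLUMNS[table]:
        if column not in frame.columns:
            raise SchemaError(f"{table} table {path} is missing required column '{column}'")
    return frame


def _parse_bool(value: str, context: str) -> bool:
    v = value.strip().lower()
    if v in ("true", "1", "yes"):
        return True
    if v in ("false", "0", "no", ""):
        return False
    raise ValidationError(f"{context}: cannot parse boolean {value!r}")


def _parse_int(value: str, context: str) -> int:
    try:
        return int(value)
    except ValueError as exc:
        raise ValidationError(f"{context}: cannot parse integer {value!r}") from exc


def _resolve_paths(source: Union[PathLike, Mapping[str, PathLike]]) -> dict[str, Path]:
    if isinstance(source, (str, Path)):
        base = Path(source)
        return {table: base / name for table, name in TABLE_FILES.items()}
    return {table: Path(p) for table, p in source.items()}


def read_field_dataset(source: Union[PathLike, Mapping[str, PathLike]]) -> FieldDataset:
    """Read a campaign from a directory (default file names) or a table->path mapping.

    Returns a validated :class:`FieldDataset`; censored predation trays are
    retained and flagged, never dropped.
    """
    paths = _resolve_paths(source)

    cover_frame = _read_table(paths["cover"], "cover")
    cover = CoverTable(
        Microhabitat(row["microhabitat"], float(row["cover"]))
        for _, row in cover_frame.iterrows()
    )

    use_frame = _read_table(paths["use_observations"], "use_observations")
    use = [
        UseObservation(row["microhabitat"], row["zone"], row["transect"])
        for _, row in use_frame.iterrows()
    ]

    faeces_frame = _read_table(paths["faeces"], "faeces")
    faeces = FaecesSurvey(
        {
            row["microhabitat"]: _parse_int(row["count"], f"faeces {row['microhabitat']}")
            for _, row in faeces_frame.iterrows()
        }
    )

    pred_frame = _read_table(paths["predation"], "predation")
    predation = []
    for _, row in pred_frame.iterrows():
        tray = row["tray_id"]
        censored = _parse_bool(row["censored"], f"tray {tray}")
        surviving = None
        if not censored:
            surviving = _parse_int(row["n_surviving"], f"tray {tray}")
        predation.append(
            PredationTrialRecord(
                tray_id=tray,
                microhabitat=row["microhabitat"],
                zone=row["zone"],
                set_id=row["set_id"],
                n_exposed=_parse_int(row["n_exposed"], f"tray {tray}"),
                n_surviving=surviving,
                censored=censored,
            )
        )

    sow_frame = _read_table(paths["sowing"], "sowing")
    sowing = []
    for _, row in sow_frame.iterrows():
        station = row["station_id"]
        sowing.append(
            SowingRecord(
                station_id=station,
                microhabitat=row["microhabitat"],
                zone=row["zone"],
                set_id=row["set_id"],
                treatment=row["treatment"],
                n_sown=_parse_int(row["n_sown"], f"station {station}"),
                n_emerged=_parse_int(row["n_emerged"], f"station {station}"),
                n_surviving=_parse_int(row["n_surviving"], f"station {station}"),
            )
        )

    return FieldDataset(
        cover=cover,
        use_observations=use,
        faeces=faeces,
        predation=predation,
        sowing=sowing,
    ).validate()


def write_field_dataset(dataset: FieldDataset, directory: PathLike) -> dict[str, Path]:
    """Write all five tables into ``directory``; returns the paths written.

    Round-trip property: ``read_field_dataset(write_field_dataset(d, ...))``
    equals ``d`` field for field.
    """
    dataset.validate()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {table: directory / name for table, name in TABLE_FILES.items()}

    pd.DataFrame(
        [{"microhabitat": e.name, "cover": repr(e.cover)} for e in dataset.cover.entries]
    ).to_csv(paths["cover"], index=False)

    pd.DataFrame(
        [
            {"microhabitat": o.microhabitat, "zone": o.zone, "transect": o.transect}
            for o in dataset.use_observations
        ],
        columns=list(_REQUIRED_COLUMNS["use_observations"]),
    ).to_csv(paths["use_observations"], index=False)

    pd.DataFrame(
        [{"microhabitat": m, "count": c} for m, c in dataset.faeces.counts.items()],
        columns=list(_REQUIRED_COLUMNS["faeces"]),
    ).to_csv(paths["faeces"], index=False)

    pd.DataFrame(
        [
            {
                "tray_id": r.tray_id,
                "microhabitat": r.microhabitat,
                "zone": r.zone,
                "set_id": r.set_id,
                "n_exposed": r.n_exposed,
                "n_surviving": "" if r.n_surviving is None else r.n_surviving,
                "censored": "true" if r.censored else "false",
            }
            for r in dataset.predation
        ],
        columns=list(_REQUIRED_COLUMNS["predation"]),
    ).to_csv(paths["predation"], index=False)

    pd.DataFrame(
        [
            {
                "station_id": r.station_id,
                "microhabitat": r.microhabitat,
                "zone": r.zone,
                "set_id": r.set_id,
                "treatment": r.treatment,
                "n_sown": r.n_sown,
                "n_emerged": r.n_emerged,
                "n_surviving": r.n_surviving,
            }
            for r in dataset.sowing
        ],
        columns=list(_REQUIRED_COLUMNS["sowing"]),
    ).to_csv(paths["sowing"], index=False)

    return paths


def dataset_to_json(dataset: FieldDataset) -> dict:
    """JSON-serializable dict for single-file exchange of a campaign."""
    dataset.validate()
    return {
        "cover": [{"microhabitat": e.name, "cover": e.cover} for e in dataset.cover.entries],
        "use_observations": [
            {"microhabitat": o.microhabitat, "zone": o.zone, "transect": o.transect}
            for o in dataset.use_observations
        ],
        "faeces": dict(dataset.faeces.counts),
        "predation": [
            {
                "tray_id": r.tray_id,
                "microhabitat": r.microhabitat,
                "zone": r.zone,
                "set_id": r.set_id,
                "n_exposed": r.n_exposed,
                "n_surviving": r.n_surviving,
                "censored": r.censored,
            }
            for r in dataset.predation
        ],
        "sowing": [
            {
                "station_id": r.station_id,
                "microhabitat": r.microhabitat,
                "zone": r.zone,
                "set_id": r.set_id,
                "treatment": r.treatment,
                "n_sown": r.n_sown,
                "n_emerged": r.n_emerged,
                "n_surviving": r.n_surviving,
            }
            for r in dataset.sowing
        ],
    }


def dataset_from_json(payload: dict) -> FieldDataset:
    cover = CoverTable(
        Microhabitat(e["microhabitat"], float(e["cover"])) for e in payload["cover"]
    )
    use = [
        UseObservation(o["microhabitat"], o["zone"], o["transect"])
        for o in payload["use_observations"]
    ]
    faeces = FaecesSurvey(payload["faeces"])
    predation = [PredationTrialRecord(**r) for r in payload["predation"]]
    sowing = [SowingRecord(**r) for r in payload["sowing"]]
    return FieldDataset(
        cover=cover, use_observations=use, faeces=faeces, predation=predation, sowing=sowing
    ).validate()


def write_dataset_json(dataset: FieldDataset, path: PathLike) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(dataset_to_json(dataset), indent=2))
    return path


def read_dataset_json(path: PathLike) -> FieldDataset:
    payload = json.loads(Path(path).read_text())
    if not isinstance(payload, dict):
        raise SchemaError(f"{path}: expected a JSON object")
    return dataset_from_json(payload)
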
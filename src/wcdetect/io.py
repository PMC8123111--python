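"""File formats: NetCDF ping stores, feature-table CSV, lines, manifests.

Conventions: CSV is UTF-8, comma-separated, "." decimal (a ``sep=";"`` flag
accommodates regional exports); depth is positive-down metres; along/across
coordinates are right-handed with x along the heading.  Feature CSVs use the
documented 24-column schema verbatim plus ``slice_id, ping_id, object_id,
label``.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
import xarray as xr

from .classify import SchemaError
from .echogram import VirtualLine
from .metrics import ID_COLUMNS, METRIC_UNITS, TABLE2_COLUMNS
from .simulate import FanGeometry, PingFan

__all__ = [
    "RunManifest",
    "save_survey",
    "load_survey",
    "write_feature_csv",
    "read_feature_csv",
    "write_line_csv",
    "write_slices_csv",
]


@dataclass
class RunManifest:
    """Traceability record for one pipeline run."""

    config: dict
    seed: int
    counts: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    version: str = "0.1.0"

    def validate(self) -> None:
        for k, v in self.counts.items():
            if isinstance(v, (int, np.integer)) and v < 0:
                raise ValueError(f"negative count {k}={v}")
        ns, no = self.counts.get("n_slices"), self.counts.get("n_objects")
        if ns is not None and no is not None and ns < no:
            raise ValueError("slices must be >= objects")

    def to_json(self, path) -> None:
        self.validate()
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=_jsonable)

    @staticmethod
    def from_json(path) -> "RunManifest":
        with open(path) as fh:
            d = json.load(fh)
        return RunManifest(**d)


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def survey_to_dataset(fans: list[PingFan]) -> xr.Dataset:
    geom = fans[0].geometry
    sv = np.stack([f.sv for f in fans])
    truth = np.stack([f.ground_truth for f in fans])
    sf = np.stack([f.seafloor_depth for f in fans])
    nav = np.array([f.nav for f in fans])
    return xr.Dataset(
        {
            "sv": (("ping", "transducer", "beam", "range_bin"), sv),
            "ground_truth": (("ping", "transducer", "beam", "range_bin"), truth),
            "seafloor_depth": (("ping", "transducer", "beam"), sf),
            "nav_x": (("ping",), nav[:, 0]),
            "nav_y": (("ping",), nav[:, 1]),
            "heading": (("ping",), nav[:, 2]),
            "time": (("ping",), np.array([f.time for f in fans])),
            "beam_angles": (("transducer", "beam"), geom.beam_angles),
        },
        coords={
            "ping": np.array([f.ping_id for f in fans]),
            "range": ("range_bin", geom.ranges),
        },
        attrs={"range_bin_m": geom.range_bin},
    )


def save_survey(fans: list[PingFan], path) -> None:
    """Write the ping sequence as a NetCDF store (scipy/NetCDF3 backend)."""
    ds = survey_to_dataset(fans)
    ds.to_netcdf(path, engine="scipy")


def load_survey(path) -> list[PingFan]:
    """Read a ping sequence saved by :func:`save_survey`."""
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    angles = ds["beam_angles"].to_numpy()
    ranges = ds["range"].to_numpy()
    rb = float(ds.attrs["range_bin_m"])
    theta = np.radians(angles)[:, :, None]
    geom = FanGeometry(
        beam_angles=angles,
        ranges=ranges,
        range_bin=rb,
        across=np.sin(theta) * ranges[None, None, :],
        depth=np.cos(theta) * ranges[None, None, :],
    )
    fans = []
    for i, pid in enumerate(ds["ping"].to_numpy()):
        fans.append(
            PingFan(
                ping_id=int(pid),
                time=float(ds["time"].to_numpy()[i]),
                nav=(
                    float(ds["nav_x"].to_numpy()[i]),
                    float(ds["nav_y"].to_numpy()[i]),
                    float(ds["heading"].to_numpy()[i]),
                ),
                geometry=geom,
                sv=ds["sv"].to_numpy()[i].astype(np.float32),
                ground_truth=ds["ground_truth"].to_numpy()[i].astype(np.uint8),
                seafloor_depth=ds["seafloor_depth"].to_numpy()[i],
            )
        )
    return fans


def write_feature_csv(table: pd.DataFrame, path, sep: str = ",") -> None:
    cols = [c for c in ID_COLUMNS if c in table.columns] + TABLE2_COLUMNS
    table[cols].to_csv(path, index=False, sep=sep)


def read_feature_csv(path, sep: str = ",") -> pd.DataFrame:
    """Read and validate a feature CSV against the documented schema.

    The header is order-insensitive; missing metric columns raise a
    :class:`SchemaError` naming them, unknown extra columns are dropped with
    a warning (their count is logged).
    """
    df = pd.read_csv(path, sep=sep, keep_default_na=False)
    missing = [c for c in TABLE2_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"feature CSV missing columns: {missing}")
    known = set(TABLE2_COLUMNS) | set(ID_COLUMNS)
    extra = [c for c in df.columns if c not in known]
    if extra:
        warnings.warn(
            f"ignoring {len(extra)} unknown column(s): {extra}", stacklevel=2
        )
        df = df.drop(columns=extra)
    for c in ID_COLUMNS:
        if c not in df.columns:
            df[c] = -1 if c != "label" else ""
    df["label"] = df["label"].astype(str).replace("nan", "")
    for c in TABLE2_COLUMNS:
        df[c] = pd.to_numeric(df[c])
    return df[ID_COLUMNS + TABLE2_COLUMNS]


def write_line_csv(line: VirtualLine, path) -> None:
    pd.DataFrame({"ping_id": line.ping_ids, "range_m": line.ranges}).to_csv(
        path, index=False
    )


def write_slices_csv(slices, path) -> None:
    """One row per slice with its object id and well-known-text polygon."""
    rows = [
        {
            "slice_id": s.slice_id,
            "ping_id": s.ping_id,
            "object_id": s.object_id if s.object_id is not None else -1,
            "n_samples": len(s.sv),
            "polygon_wkt": s.polygon.wkt,
        }
        for s in slices
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def units_table() -> pd.DataFrame:
    """The documented metric-unit registry (for reports and validation)."""
    return pd.DataFrame(
        {"Metric": list(METRIC_UNITS), "Unit": list(METRIC_UNITS.values())}
    )
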
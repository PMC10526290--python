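"""Plantar sensor layout: 40 tactile units grouped into five 8-unit sensors.

Coordinate convention (stated once, used everywhere): millimetres in a
right-foot-fixed frame, x increasing medial -> lateral, y increasing
heel -> toe.  The five sensors cover the main weight-bearing regions of
the sole: the toe, the first metatarsal, the third--fifth metatarsals,
the medial heel and the lateral heel.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

N_SENSORS = 5
UNITS_PER_SENSOR = 8
N_UNITS = N_SENSORS * UNITS_PER_SENSOR

SENSOR_NAMES = (
    "toe",
    "first_metatarsal",
    "third_fifth_metatarsal",
    "medial_heel",
    "lateral_heel",
)

LAYOUT_COLUMNS = ("unit_id", "sensor_id", "local_index", "x_mm", "y_mm")


class LayoutError(ValueError):
    """Raised when a layout table violates the 5 x 8 unit contract."""


@dataclass(frozen=True)
class SensorUnit:
    """One tactile unit reporting a 3-axis contact force vector."""

    unit_id: int
    sensor_id: int
    local_index: int
    position: tuple[float, float]  # (x_mm, y_mm)

    def __post_init__(self) -> None:
        if self.unit_id != self.sensor_id * UNITS_PER_SENSOR + self.local_index:
            raise LayoutError(
                f"unit_id {self.unit_id} inconsistent with sensor_id "
                f"{self.sensor_id}, local_index {self.local_index}"
            )


# Anchor (x, y) of each sensor's 2 x 4 unit patch, mm, right foot.
# Heel sits near y=0; toes near y=240 for a ~26 cm sole.
_SENSOR_ANCHORS = {
    0: (35.0, 215.0),   # toe (hallux region)
    1: (25.0, 160.0),   # first metatarsal (medial forefoot)
    2: (60.0, 150.0),   # third-fifth metatarsals (lateral forefoot)
    3: (30.0, 20.0),    # medial heel
    4: (60.0, 25.0),    # lateral heel
}
_UNIT_PITCH_MM = 10.0  # spacing of the 2 x 4 grid inside one sensor


def default_layout_table() -> pd.DataFrame:
    """Build the bundled default layout as a table.

    Each sensor is a 2 x 4 grid of units (2 across x, 4 along y) at 10 mm
    pitch, placed at anatomically plausible anchors for the five regions.
    """
    rows = []
    for sid in range(N_SENSORS):
        ax, ay = _SENSOR_ANCHORS[sid]
        for li in range(UNITS_PER_SENSOR):
            col, row = li % 2, li // 2
            rows.append(
                {
                    "unit_id": sid * UNITS_PER_SENSOR + li,
                    "sensor_id": sid,
                    "local_index": li,
                    "x_mm": ax + col * _UNIT_PITCH_MM,
                    "y_mm": ay + row * _UNIT_PITCH_MM,
                }
            )
    return pd.DataFrame(rows, columns=list(LAYOUT_COLUMNS))


def build_layout(table: pd.DataFrame) -> list[SensorUnit]:
    """Validate a layout table and return units ordered by ``unit_id``.

    Parameters
    ----------
    table
        Columns ``unit_id, sensor_id, local_index, x_mm, y_mm``; exactly
        40 rows, five sensors with eight units each.

    Raises
    ------
    LayoutError
        On wrong counts, duplicate ids, inconsistent indexing or
        non-finite coordinates; the message names the offending row.
    """
    missing = [c for c in LAYOUT_COLUMNS if c not in table.columns]
    if missing:
        raise LayoutError(f"layout table missing columns {missing}")
    if len(table) != N_UNITS:
        raise LayoutError(f"layout must have {N_UNITS} rows, got {len(table)}")

    df = table.sort_values("unit_id").reset_index(drop=True)
    ids = df["unit_id"].to_numpy()
    if len(np.unique(ids)) != N_UNITS:
        dup = int(ids[pd.Series(ids).duplicated()].flat[0])
        raise LayoutError(f"duplicate unit_id {dup}")
    if not np.array_equal(ids, np.arange(N_UNITS)):
        raise LayoutError("unit_id values must be exactly 0..39")

    sensor_ids = df["sensor_id"].to_numpy()
    counts = np.bincount(sensor_ids, minlength=N_SENSORS)
    if sensor_ids.min() < 0 or sensor_ids.max() >= N_SENSORS:
        bad = int(df.index[(sensor_ids < 0) | (sensor_ids >= N_SENSORS)][0])
        raise LayoutError(f"row {bad}: sensor_id out of range 0..4")
    if not np.all(counts == UNITS_PER_SENSOR):
        bad_sensor = int(np.flatnonzero(counts != UNITS_PER_SENSOR)[0])
        raise LayoutError(
            f"sensor {bad_sensor} has {counts[bad_sensor]} units, expected 8"
        )

    xy = df[["x_mm", "y_mm"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(xy)):
        bad = int(np.flatnonzero(~np.isfinite(xy).all(axis=1))[0])
        raise LayoutError(f"row {bad}: non-finite coordinate")

    units = []
    for r in df.itertuples(index=True):
        if r.unit_id != r.sensor_id * UNITS_PER_SENSOR + r.local_index:
            raise LayoutError(
                f"row {r.Index}: unit_id {r.unit_id} != "
                f"8*sensor_id + local_index"
            )
        units.append(
            SensorUnit(
                unit_id=int(r.unit_id),
                sensor_id=int(r.sensor_id),
                local_index=int(r.local_index),
                position=(float(r.x_mm), float(r.y_mm)),
            )
        )
    return units


def default_layout() -> list[SensorUnit]:
    """The bundled five-region layout as validated units."""
    return build_layout(default_layout_table())


def read_layout_csv(path) -> list[SensorUnit]:
    return build_layout(pd.read_csv(path))


def write_layout_csv(units: list[SensorUnit], path) -> None:
    pd.DataFrame(
        [
            {
                "unit_id": u.unit_id,
                "sensor_id": u.sensor_id,
                "local_index": u.local_index,
                "x_mm": u.position[0],
                "y_mm": u.position[1],
            }
            for u in units
        ]
    ).to_csv(path, index=False)


def positions(units: list[SensorUnit]) -> np.ndarray:
    """(40, 2) array of unit coordinates in unit_id order."""
    return np.array([u.position for u in units], dtype=float)


def sensor_ids(units: list[SensorUnit]) -> np.ndarray:
    return np.array([u.sensor_id for u in units], dtype=int)


def layout_hash(units: list[SensorUnit]) -> str:
    """Stable hash binding checkpoints and datasets to a layout."""
    h = hashlib.sha256()
    for u in units:
        h.update(
            f"{u.unit_id},{u.sensor_id},{u.local_index},"
            f"{u.position[0]:.6f},{u.position[1]:.6f};".encode()
        )
    return h.hexdigest()[:16]
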
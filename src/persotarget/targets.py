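"""The Target record shared by both targeting algorithms, plus CSV I/O."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class Target:
    """A single derived stimulation coordinate in world (MNI) mm.

    ``params`` carries provenance: retention fraction, clustering stop
    threshold, connectivity, GSR flag — whatever produced the coordinate.
    """

    world_mm: tuple[float, float, float]
    algorithm: str  # "HCA" or "RSA"
    subject_id: str = ""
    day: int = 1
    phase: str = "LR"
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        xyz = tuple(float(v) for v in self.world_mm)
        if not all(np.isfinite(v) for v in xyz):
            raise ValueError(f"non-finite target coordinates {xyz}")
        if self.algorithm not in ("HCA", "RSA"):
            raise ValueError(f"algorithm must be HCA or RSA, got {self.algorithm!r}")
        self.world_mm = xyz

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.world_mm, dtype=float)


def targets_to_frame(targets: list[Target]) -> pd.DataFrame:
    rows = []
    for t in targets:
        rows.append(
            {
                "subject": t.subject_id,
                "algorithm": t.algorithm,
                "day": t.day,
                "phase": t.phase,
                "x_mm": t.world_mm[0],
                "y_mm": t.world_mm[1],
                "z_mm": t.world_mm[2],
                "params": json.dumps(t.params, sort_keys=True),
            }
        )
    return pd.DataFrame(rows)


def write_targets_csv(targets: list[Target], path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    targets_to_frame(targets).to_csv(path, index=False)
    return path


def read_targets_csv(path) -> list[Target]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        params = json.loads(row["params"]) if isinstance(row.get("params"), str) else {}
        out.append(
            Target(
                world_mm=(row["x_mm"], row["y_mm"], row["z_mm"]),
                algorithm=row["algorithm"],
                subject_id=str(row["subject"]),
                day=int(row["day"]),
                phase=str(row["phase"]),
                params=params,
            )
        )
    return out
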
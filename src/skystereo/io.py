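"""Config and tabular I/O: rig YAML files and observation CSVs."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .stereo_geometry import CameraIntrinsics, PixelObservation, RigGeometry

OBSERVATION_COLUMNS = ["t", "y1", "y2", "xc", "yc", "pW", "pH"]


def load_rig_config(path: str | Path) -> tuple[RigGeometry, CameraIntrinsics]:
    """Read a rig/camera configuration from YAML.

    Expected keys: ``baseline_m, alpha_deg, y0_px, fov_deg, focal_mm,
    sia_mm`` and optionally ``mount_height_m`` (default 0).
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    rig = RigGeometry(
        B=float(cfg["baseline_m"]),
        alpha=float(cfg["alpha_deg"]),
        mount_height=float(cfg.get("mount_height_m", 0.0)),
    )
    intr = CameraIntrinsics(
        y0=int(cfg["y0_px"]),
        phi0=float(cfg["fov_deg"]),
        f=float(cfg["focal_mm"]),
        sia=float(cfg["sia_mm"]),
    )
    return rig, intr


def save_rig_config(rig: RigGeometry, intr: CameraIntrinsics, path: str | Path) -> None:
    cfg = {
        "baseline_m": rig.B,
        "alpha_deg": rig.alpha,
        "mount_height_m": rig.mount_height,
        "y0_px": intr.y0,
        "fov_deg": intr.phi0,
        "focal_mm": intr.f,
        "sia_mm": intr.sia,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def observations_to_frame(observations: list[PixelObservation]) -> pd.DataFrame:
    return pd.DataFrame(
        [[o.t, o.y1, o.y2, o.xc, o.yc, o.pW, o.pH] for o in observations],
        columns=OBSERVATION_COLUMNS,
    )


def read_observations(path: str | Path) -> list[PixelObservation]:
    """Read an observation CSV (header ``t,y1,y2,xc,yc,pW,pH``)."""
    df = pd.read_csv(path)
    missing = set(OBSERVATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"observation CSV missing columns: {sorted(missing)}")
    return [
        PixelObservation(
            t=float(r.t), y1=float(r.y1), y2=float(r.y2),
            xc=float(r.xc), yc=float(r.yc), pW=float(r.pW), pH=float(r.pH),
        )
        for r in df.itertuples()
    ]


def write_observations(observations: list[PixelObservation], path: str | Path) -> None:
    observations_to_frame(observations).to_csv(path, index=False)
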
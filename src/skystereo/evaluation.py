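"""Validation statistics: detection efficiency, localization accuracy,
classification confusion.

Detection efficiency is the fraction of time a target flying within a range
bin is actually detected, measured in whole frames and reported as an
integer percentage.  Localization accuracy compares the per-scenario mean
distance/altitude of the system track against a reference (GPS-like) track:
absolute accuracy is the difference of the means, relative accuracy its
percentage of the reference mean.  Classification quality is a 3x3 size-class
confusion matrix with per-class reliability (diagonal percentage).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .size_classification import SizeClass
from .stereo_geometry import Localization
from .synthetic_scene import ReferenceTrack

__all__ = [
    "RangeBinStats",
    "ScenarioStats",
    "ConfusionCounts",
    "detection_efficiency",
    "localization_stats",
    "classification_confusion",
    "report",
    "round_half_up",
]

CLASS_ORDER = ("small", "medium", "large")


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties away from zero at the given decimal position."""
    scale = 10.0**decimals
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class RangeBinStats:
    """Detection efficiency inside one half-open range bin ``(lo, hi]``.

    ``efficiency`` is ``round(100 * detection_time / flight_time)`` (integer
    percent, ties up), or None when the target never flew in the bin.
    """

    bin: tuple[float, float]
    detection_time: float
    flight_time: float

    def __post_init__(self) -> None:
        if not 0 <= self.detection_time <= self.flight_time + 1e-9:
            raise ValueError("need 0 <= detection_time <= flight_time")

    @property
    def efficiency(self) -> int | None:
        if self.flight_time <= 0:
            return None
        return int(round_half_up(100.0 * self.detection_time / self.flight_time))


@dataclass(frozen=True)
class ScenarioStats:
    """Per-scenario localization summary (all lengths m, rates percent).

    Means and population standard deviations of distance/altitude for the
    reference and system tracks; ``dD_abs = |mean_D_sys - mean_D_ref|`` and
    ``dD_rel = 100 dD_abs / mean_D_ref`` (same for H); ``N`` is the system
    sample count.
    """

    mean_D_ref: float
    sd_D_ref: float
    mean_H_ref: float
    sd_H_ref: float
    N: int
    mean_D_sys: float
    sd_D_sys: float
    mean_H_sys: float
    sd_H_sys: float

    @property
    def dD_abs(self) -> float:
        return abs(self.mean_D_sys - self.mean_D_ref)

    @property
    def dH_abs(self) -> float:
        return abs(self.mean_H_sys - self.mean_H_ref)

    @property
    def dD_rel(self) -> float:
        return 100.0 * self.dD_abs / self.mean_D_ref

    @property
    def dH_rel(self) -> float:
        return 100.0 * self.dH_abs / self.mean_H_ref

    def rounded(self) -> dict[str, float]:
        """All fields at the 1-decimal precision used in summary tables."""
        vals = {
            "mean_D_ref": self.mean_D_ref, "sd_D_ref": self.sd_D_ref,
            "mean_H_ref": self.mean_H_ref, "sd_H_ref": self.sd_H_ref,
            "mean_D_sys": self.mean_D_sys, "sd_D_sys": self.sd_D_sys,
            "mean_H_sys": self.mean_H_sys, "sd_H_sys": self.sd_H_sys,
            "dD_abs": self.dD_abs, "dH_abs": self.dH_abs,
            "dD_rel": self.dD_rel, "dH_rel": self.dH_rel,
        }
        out = {k: round_half_up(v, 1) for k, v in vals.items()}
        out["N"] = self.N
        return out


@dataclass(frozen=True)
class ConfusionCounts:
    """3x3 size-class confusion matrix, rows = true class, cols = assigned."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.shape != (3, 3) or np.any(counts < 0):
            raise ValueError("counts must be a non-negative 3x3 matrix")
        object.__setattr__(self, "counts", counts)

    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def reliability(self) -> dict[str, float]:
        """Per-true-class diagonal percentage (full precision; NaN if empty)."""
        totals = self.row_totals()
        return {
            cls: (100.0 * self.counts[i, i] / totals[i] if totals[i] else math.nan)
            for i, cls in enumerate(CLASS_ORDER)
        }

    def reliability_rounded(self) -> dict[str, float]:
        return {k: round_half_up(v, 1) for k, v in self.reliability().items()}

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=list(CLASS_ORDER), columns=list(CLASS_ORDER))
        df.index.name = "true_class"
        return df


def detection_efficiency(
    detected_times: Iterable[float],
    reference: ReferenceTrack,
    bins: Sequence[tuple[float, float]],
) -> list[RangeBinStats]:
    """Per-range-bin detection efficiency against a reference track.

    Flight time in a bin is the number of reference frames whose distance
    lies in ``(lo, hi]`` times the frame period; detection time counts the
    subset of those frames with a detection (timestamps matched to the
    nearest frame).  Detected timestamps must be a subset of the reference
    timestamps.
    """
    t_ref = np.asarray(reference.t, dtype=float)
    if len(t_ref) < 2:
        raise ValueError("reference track needs at least two samples")
    dt = float(np.median(np.diff(t_ref)))
    det = np.asarray(sorted(set(detected_times)), dtype=float)
    if det.size:
        idx = np.searchsorted(t_ref, det)
        idx = np.clip(idx, 0, len(t_ref) - 1)
        left = np.clip(idx - 1, 0, len(t_ref) - 1)
        idx = np.where(np.abs(t_ref[left] - det) < np.abs(t_ref[idx] - det), left, idx)
        if np.any(np.abs(t_ref[idx] - det) > dt / 2):
            raise ValueError("detected timestamps are not a subset of the reference")
    detected_mask = np.zeros(len(t_ref), dtype=bool)
    if det.size:
        detected_mask[idx] = True

    stats = []
    for lo, hi in bins:
        in_bin = (reference.D > lo) & (reference.D <= hi)
        stats.append(
            RangeBinStats(
                bin=(lo, hi),
                detection_time=float(np.sum(in_bin & detected_mask)) * dt,
                flight_time=float(np.sum(in_bin)) * dt,
            )
        )
    return stats


def localization_stats(
    system_track: Sequence[Localization], reference: ReferenceTrack
) -> ScenarioStats:
    """Localization accuracy of a system track against a reference track."""
    if len(system_track) == 0 or len(reference.t) == 0:
        raise ValueError("tracks must be non-empty")
    d_sys = np.array([loc.D for loc in system_track], dtype=float)
    h_sys = np.array([loc.H for loc in system_track], dtype=float)
    return ScenarioStats(
        mean_D_ref=float(np.mean(reference.D)),
        sd_D_ref=float(np.std(reference.D)),
        mean_H_ref=float(np.mean(reference.H)),
        sd_H_ref=float(np.std(reference.H)),
        N=len(system_track),
        mean_D_sys=float(np.mean(d_sys)),
        sd_D_sys=float(np.std(d_sys)),
        mean_H_sys=float(np.mean(h_sys)),
        sd_H_sys=float(np.std(h_sys)),
    )


def classification_confusion(
    events: Sequence[tuple[str, SizeClass | str]]
) -> ConfusionCounts:
    """Aggregate (true class, assigned class) events into a confusion matrix."""
    if not events:
        raise ValueError("no classification events")
    index = {cls: i for i, cls in enumerate(CLASS_ORDER)}
    counts = np.zeros((3, 3), dtype=int)
    for true_cls, assigned in events:
        true_key = str(getattr(true_cls, "value", true_cls))
        assigned_key = str(getattr(assigned, "value", assigned))
        if true_key not in index or assigned_key not in index:
            raise ValueError(f"unknown class label in event ({true_cls!r}, {assigned!r})")
        counts[index[true_key], index[assigned_key]] += 1
    return ConfusionCounts(counts=counts)


def _range_bins_frame(stats: Sequence[RangeBinStats]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "bin_low": [s.bin[0] for s in stats],
            "bin_high": [s.bin[1] for s in stats],
            "detection_time_s": [s.detection_time for s in stats],
            "flight_time_s": [s.flight_time for s in stats],
            "efficiency_pct": [s.efficiency for s in stats],
        }
    )


def _scenarios_frame(scenarios: dict[str, ScenarioStats]) -> pd.DataFrame:
    rows = []
    for name in sorted(scenarios):
        row = {"scenario": name}
        row.update(scenarios[name].rounded())
        rows.append(row)
    return pd.DataFrame(rows)


def report(
    out_dir: str | Path,
    range_bins: Sequence[RangeBinStats] = (),
    scenarios: dict[str, ScenarioStats] | None = None,
    confusion: ConfusionCounts | None = None,
    metadata: dict | None = None,
) -> dict[str, Path]:
    """Serialize an evaluation bundle deterministically.

    Writes ``report.json`` plus ``efficiency.csv`` / ``scenarios.csv`` /
    ``confusion.csv`` for the sections present, and returns the paths.  The
    JSON embeds the run metadata (augmented with a hash of its own config
    section when one is supplied) and sorts all keys, so identical inputs
    produce byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scenarios = scenarios or {}
    metadata = dict(metadata or {})
    if "config" in metadata:
        blob = json.dumps(metadata["config"], sort_keys=True).encode()
        metadata["config_hash"] = hashlib.sha256(blob).hexdigest()[:16]

    payload = {
        "metadata": metadata,
        "efficiency": [
            {
                "bin": list(s.bin),
                "detection_time_s": s.detection_time,
                "flight_time_s": s.flight_time,
                "efficiency_pct": s.efficiency,
            }
            for s in range_bins
        ],
        "scenarios": {name: stats.rounded() for name, stats in sorted(scenarios.items())},
        "confusion": {
            "counts": confusion.counts.tolist(),
            "reliability_pct": confusion.reliability_rounded(),
        }
        if confusion is not None
        else None,
    }
    paths = {"json": out_dir / "report.json"}
    with open(paths["json"], "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")

    if range_bins:
        paths["efficiency"] = out_dir / "efficiency.csv"
        _range_bins_frame(range_bins).to_csv(paths["efficiency"], index=False)
    if scenarios:
        paths["scenarios"] = out_dir / "scenarios.csv"
        _scenarios_frame(scenarios).to_csv(paths["scenarios"], index=False)
    if confusion is not None:
        paths["confusion"] = out_dir / "confusion.csv"
        confusion.to_frame().to_csv(paths["confusion"])
    return paths
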
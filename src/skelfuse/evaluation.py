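"""Scoring merged skeletons against ground truth.

Error is the per-joint per-frame Euclidean distance in millimeters between
the merged track and the reference track (simulated truth or a best-view
sensor).  Aggregates pool per-frame joint errors within each body region:
AE is the mean, STD the population standard deviation, and RMSE is reported
alongside.  Sweeps re-run the fusion over pipeline variants, DBSCAN
searching areas, or all same-size sensor subsets (averaging over the
C(total, k) combinations).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import JOINTS, REGIONS, SkeletonTrack
from .fusion import FusionConfig, MergedTrack, fuse_sequence

__all__ = ["ErrorTable", "SweepResult", "joint_errors", "sweep_eps", "sweep_sensors", "compare_variants"]

_REGION_ORDER = ("torso", "upper_limb", "lower_limb")


@dataclass
class ErrorTable:
    """Per-(joint, frame) errors plus region aggregates (all in mm)."""

    per_joint: pd.DataFrame
    region_summary: pd.DataFrame
    n_excluded: int

    def region(self, name: str, stat: str = "ae_mm") -> float:
        row = self.region_summary[self.region_summary["region"] == name]
        return float(row[stat].iloc[0])


@dataclass
class SweepResult:
    """Region aggregates per sweep level; one row per (level, region)."""

    axis: str
    levels: list
    table: pd.DataFrame


def _coords(track: SkeletonTrack | MergedTrack) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(track, MergedTrack):
        valid = track.status > 0
    else:
        valid = track.confidence > 0
    valid = valid & np.all(np.isfinite(track.positions), axis=-1)
    return track.frame_index, track.positions, valid


def joint_errors(
    merged: SkeletonTrack | MergedTrack,
    truth: SkeletonTrack | MergedTrack,
    ddof: int = 0,
) -> ErrorTable:
    """Euclidean joint-position error table of ``merged`` against ``truth``.

    Frames are matched on ``frame_index``; (joint, frame) slots missing from
    either track are excluded pairwise and counted in ``n_excluded``.
    ``ddof=0`` gives the population standard deviation.
    """
    idx_a, pos_a, val_a = _coords(merged)
    idx_b, pos_b, val_b = _coords(truth)
    common, ia, ib = np.intersect1d(idx_a, idx_b, return_indices=True)
    if len(common) == 0:
        raise ValueError("tracks share no frame_index; nothing to score")
    va, vb = val_a[ia], val_b[ib]
    both = va & vb
    err = np.linalg.norm(pos_a[ia] - pos_b[ib], axis=-1)
    f_i, j_i = np.nonzero(both)
    per_joint = pd.DataFrame(
        {
            "frame_index": common[f_i],
            "joint": [JOINTS[j] for j in j_i],
            "region": [REGIONS[JOINTS[j]] for j in j_i],
            "error_mm": err[f_i, j_i],
        }
    )
    rows = []
    for region in _REGION_ORDER + ("all",):
        sel = per_joint if region == "all" else per_joint[per_joint["region"] == region]
        e = sel["error_mm"].to_numpy()
        rows.append(
            {
                "region": region,
                "ae_mm": float(np.mean(e)) if len(e) else np.nan,
                "std_mm": float(np.std(e, ddof=ddof)) if len(e) > ddof else np.nan,
                "rmse_mm": float(np.sqrt(np.mean(e**2))) if len(e) else np.nan,
                "n": int(len(e)),
            }
        )
    n_excluded = int(both.size - both.sum())
    return ErrorTable(per_joint, pd.DataFrame(rows), n_excluded)


def _summary_with_level(table: ErrorTable, level) -> pd.DataFrame:
    df = table.region_summary.copy()
    df.insert(0, "level", [level] * len(df))
    return df


def compare_variants(
    streams: Mapping[str, SkeletonTrack],
    truth: SkeletonTrack,
    config: FusionConfig,
    variants: Sequence[str],
) -> SweepResult:
    """Region AE/STD/RMSE per pipeline variant on identical inputs."""
    frames_tables = []
    for v in variants:
        merged = fuse_sequence(streams, replace(config, variant=v))
        frames_tables.append(_summary_with_level(joint_errors(merged, truth), v))
    return SweepResult("variant", list(variants), pd.concat(frames_tables, ignore_index=True))


def sweep_eps(
    streams: Mapping[str, SkeletonTrack],
    truth: SkeletonTrack,
    config: FusionConfig,
    eps_list_mm: Sequence[float],
) -> SweepResult:
    """Region aggregates per DBSCAN searching area (mm), same inputs throughout."""
    if not len(eps_list_mm):
        raise ValueError("at least one eps value is required")
    if any(e <= 0 for e in eps_list_mm):
        raise ValueError("eps values must be positive")
    tables = []
    for e in eps_list_mm:
        merged = fuse_sequence(streams, replace(config, eps_mm=float(e)))
        tables.append(_summary_with_level(joint_errors(merged, truth), float(e)))
    return SweepResult("eps", [float(e) for e in eps_list_mm], pd.concat(tables, ignore_index=True))


def sweep_sensors(
    streams: Mapping[str, SkeletonTrack],
    truth: SkeletonTrack,
    config: FusionConfig,
    k_values: Sequence[int],
) -> SweepResult:
    """Aggregates per sensor count k, averaged over all size-k subsets.

    ``k = 1`` scores each raw stream directly (no merging); larger k fuses
    every combination and averages the region statistics arithmetically
    across the C(total, k) subsets.
    """
    ids = sorted(streams)
    total = len(ids)
    tables = []
    for k in k_values:
        if k < 1 or k > total:
            raise ValueError(f"k={k} outside 1..{total}")
        combo_tables = []
        for subset in combinations(ids, k):
            if k == 1:
                table = joint_errors(streams[subset[0]], truth)
            else:
                merged = fuse_sequence({s: streams[s] for s in subset}, config)
                table = joint_errors(merged, truth)
            combo_tables.append(table.region_summary)
        stacked = pd.concat(combo_tables, ignore_index=True)
        mean = stacked.groupby("region", sort=False).mean(numeric_only=True).reset_index()
        mean.insert(0, "level", [int(k)] * len(mean))
        mean["n_combinations"] = len(combo_tables)
        tables.append(mean)
    return SweepResult("n_sensors", [int(k) for k in k_values], pd.concat(tables, ignore_index=True))
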
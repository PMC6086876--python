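"""Iterative nearest-unique-neighbour merge clustering with a distance cutoff.

This is the data-reduction algorithm at the heart of the package. Starting
from the pooled cloud of substrate centroids (one point per molecule per
frame, typically hundreds of thousands), each iteration:

1. lists every pair of points closer than the cutoff (default 10 Å),
   sorted by distance;
2. removes *isolated* points — those with no neighbour inside the cutoff —
   as low-density noise that would otherwise seed spurious merged
   centroids;
3. greedily pairs the remaining points in ascending-distance order, each
   point joining at most one pair, starting from the closest pair and
   ending with the pair closest to the cutoff;
4. replaces each pair by its unweighted midpoint (the spatial average of
   the two points), carrying unmatched-but-neighboured points forward.

Iterating drives the cloud toward the most populated positions in space:
after enough rounds only a handful of points survive, tracing the regions
where substrate molecules congregate — surface channels, association
hotspots, active-site approaches. Each iteration's cloud can be exported
as a PDB point file for overlay on the protein structure.

Determinism: pair ties are broken lexicographically by index, so the same
input always yields byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .centroids import CentroidSeries
from .io_formats import write_points_pdb

__all__ = [
    "ClusterParams",
    "CentroidCloud",
    "IterationRecord",
    "MergeHistory",
    "neighbor_pairs",
    "cluster_iteration",
    "cluster_to_convergence",
    "cloud_from_series",
]


@dataclass(frozen=True)
class ClusterParams:
    """Knobs of the merge clustering.

    cutoff
        Neighbour distance in Å; pairs at or beyond it never merge and
        points with no neighbour inside it are removed. Comparison is
        strictly ``<``.
    max_iterations
        Hard stop; 64 is far beyond the ~log2(n) rounds a merge cascade
        needs.
    unmatched
        ``"carry"`` keeps neighboured-but-unpaired points for the next
        round (default); ``"drop"`` discards them with the isolated ones.
    weighted_average
        If True, merged points are weight-proportional means instead of
        plain midpoints of the two coordinates.
    """

    cutoff: float = 10.0
    max_iterations: int = 64
    unmatched: str = "carry"
    weighted_average: bool = False

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.unmatched not in ("carry", "drop"):
            raise ValueError(f"unmatched must be 'carry' or 'drop', got {self.unmatched!r}")


@dataclass
class CentroidCloud:
    """Point cloud at one clustering iteration, with merge provenance.

    ``weights[i]`` counts the iteration-0 centroids absorbed into point i;
    ``origins[i]`` lists their iteration-0 indices. The total weight never
    increases across iterations (isolated-point removal can decrease it).
    """

    points: np.ndarray
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]
    iteration: int = 0
    substrate_type: str | None = None
    origins: list[list[int]] | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if self.weights is None:
            self.weights = np.ones(len(self.points), dtype=int)
        else:
            self.weights = np.asarray(self.weights, dtype=int)
        if self.origins is None:
            self.origins = [[i] for i in range(len(self.points))]

    def __len__(self) -> int:
        return len(self.points)

    @property
    def total_weight(self) -> int:
        return int(self.weights.sum())


@dataclass
class IterationRecord:
    """What one iteration did: merges (with distances), drops, carries."""

    iteration: int
    merges: list[tuple[int, int, float]]
    dropped: list[int]
    carried: list[int]

    def to_json(self) -> str:
        return json.dumps(
            {
                "iteration": self.iteration,
                "merges": [[i, j, round(d, 6)] for i, j, d in self.merges],
                "dropped": self.dropped,
                "carried": self.carried,
            }
        )


MergeHistory = list[IterationRecord]


def neighbor_pairs(points: np.ndarray, cutoff: float) -> list[tuple[int, int, float]]:
    """All index pairs (i<j) strictly closer than ``cutoff``.

    Sorted ascending by distance, ties broken by (i, j). Uses a k-d tree,
    so large clouds stay tractable.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) < 2:
        return []
    tree = cKDTree(pts)
    raw = tree.query_pairs(cutoff, output_type="ndarray")
    if len(raw) == 0:
        return []
    d = np.linalg.norm(pts[raw[:, 0]] - pts[raw[:, 1]], axis=1)
    keep = d < cutoff  # query_pairs is <=; the contract is strict <
    raw, d = raw[keep], d[keep]
    i = np.minimum(raw[:, 0], raw[:, 1])
    j = np.maximum(raw[:, 0], raw[:, 1])
    order = np.lexsort((j, i, d))
    return [(int(i[k]), int(j[k]), float(d[k])) for k in order]


def cluster_iteration(
    cloud: CentroidCloud, params: ClusterParams = ClusterParams()
) -> tuple[CentroidCloud, IterationRecord]:
    """One round: drop isolated points, greedily merge neighbour pairs.

    Merged pairs become their spatial average (midpoint by default); the
    output cloud lists merged points in merge order, then carried points in
    original index order.
    """
    if len(cloud) == 0:
        raise ValueError("cannot cluster an empty cloud")
    pairs = neighbor_pairs(cloud.points, params.cutoff)
    neighboured = {k for i, j, _ in pairs for k in (i, j)}
    dropped = sorted(set(range(len(cloud))) - neighboured)

    used: set[int] = set()
    merges: list[tuple[int, int, float]] = []
    for i, j, d in pairs:
        if i not in used and j not in used:
            used.update((i, j))
            merges.append((i, j, d))

    carried = sorted(neighboured - used)
    if params.unmatched == "drop":
        dropped = sorted(dropped + carried)
        carried = []

    new_points: list[np.ndarray] = []
    new_weights: list[int] = []
    new_origins: list[list[int]] = []
    assert cloud.origins is not None
    for i, j, _ in merges:
        if params.weighted_average:
            wi, wj = cloud.weights[i], cloud.weights[j]
            p = (wi * cloud.points[i] + wj * cloud.points[j]) / (wi + wj)
        else:
            p = 0.5 * (cloud.points[i] + cloud.points[j])
        new_points.append(p)
        new_weights.append(int(cloud.weights[i] + cloud.weights[j]))
        new_origins.append(cloud.origins[i] + cloud.origins[j])
    for k in carried:
        new_points.append(cloud.points[k])
        new_weights.append(int(cloud.weights[k]))
        new_origins.append(cloud.origins[k])

    new_cloud = CentroidCloud(
        points=np.array(new_points, dtype=float).reshape(-1, 3),
        weights=np.array(new_weights, dtype=int),
        iteration=cloud.iteration + 1,
        substrate_type=cloud.substrate_type,
        origins=new_origins,
    )
    return new_cloud, IterationRecord(cloud.iteration + 1, merges, dropped, carried)


def cloud_from_series(
    series: CentroidSeries,
    substrate_type: str | None = None,
    frame_range: tuple[int, int] | None = None,
) -> CentroidCloud:
    """Pool frames' centroids of one substrate type into an iteration-0 cloud.

    By default every frame is pooled (whole-trajectory clustering);
    ``frame_range=(lo, hi)`` restricts to frames ``lo <= f < hi`` for
    time-windowed analysis.
    """
    types = series.substrate_types()
    if substrate_type is None:
        if len(types) > 1:
            raise ValueError(
                f"series mixes substrate types {sorted(types)}; "
                "clustering pairs only like with like — pass substrate_type"
            )
        substrate_type = next(iter(types))
    df = series.frame_table
    df = df[df["substrate_type"] == substrate_type]
    if frame_range is not None:
        lo, hi = frame_range
        df = df[(df["frame"] >= lo) & (df["frame"] < hi)]
    pts = df[["x", "y", "z"]].to_numpy(dtype=float)
    return CentroidCloud(points=pts, substrate_type=substrate_type)


def cluster_to_convergence(
    series_or_cloud: CentroidSeries | CentroidCloud,
    params: ClusterParams = ClusterParams(),
    output_dir: str | Path | None = None,
    run_name: str = "run",
) -> tuple[list[CentroidCloud], MergeHistory]:
    """Iterate merge rounds until no pair remains inside the cutoff.

    Returns every iteration's cloud (index 0 = raw input) plus the merge
    history. Terminates when no merge is possible, when a single point
    remains, or at ``max_iterations``. With ``output_dir`` set, each
    iteration's cloud is written as ``<run_name>_iter<k>.pdb`` and the
    history as ``<run_name>_history.jsonl``.
    """
    if isinstance(series_or_cloud, CentroidSeries):
        cloud = cloud_from_series(series_or_cloud)
    else:
        cloud = series_or_cloud

    clouds = [cloud]
    history: MergeHistory = []
    current = cloud
    while len(current) > 1 and current.iteration - cloud.iteration < params.max_iterations:
        if not neighbor_pairs(current.points, params.cutoff):
            break  # zero-merge fixed point: the surviving handful of points
        current, record = cluster_iteration(current, params)
        clouds.append(current)
        history.append(record)
        if len(current) == 0:
            break

    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        for c in clouds:
            write_points_pdb(c.points, out / f"{run_name}_iter{c.iteration}.pdb")
        with open(out / f"{run_name}_history.jsonl", "w", newline="\n") as fh:
            for rec in history:
                fh.write(rec.to_json() + "\n")
    return clouds, history
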
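"""Reduce each substrate molecule to one point per frame.

A substrate molecule's per-frame representation is its *centroid*: the
unweighted arithmetic mean of its atomic coordinates (all atoms present,
hydrogens included). For a typical small-molecule substrate of ~22-24
atoms this shrinks the data roughly 25-fold, and every downstream stage
(clustering, residue scoring, arrival detection) operates on centroids
only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import LabellingError
from .io_formats import SubstrateType, Trajectory

__all__ = ["CentroidSeries", "molecule_centroid", "extract_centroid_series"]


@dataclass
class CentroidSeries:
    """Per-molecule, per-frame centroid table.

    Backed by a DataFrame with columns
    ``frame, molecule_tag, substrate_type, x, y, z``. A *complete* series
    has exactly one entry per (frame, molecule) pair, i.e.
    ``len(series) == n_frames * n_molecules``; series filtered by upstream
    stages may be incomplete, which relaxes cardinality checks downstream.
    """

    frame_table: pd.DataFrame
    reduction_factor: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        required = ["frame", "molecule_tag", "substrate_type", "x", "y", "z"]
        missing = [c for c in required if c not in self.frame_table.columns]
        if missing:
            raise ValueError(f"centroid series missing column(s): {missing}")
        self.frame_table = self.frame_table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame_table)

    @property
    def n_frames(self) -> int:
        return int(self.frame_table["frame"].nunique())

    @property
    def n_molecules(self) -> int:
        return int(self.frame_table["molecule_tag"].nunique())

    @property
    def molecule_tags(self) -> list[str]:
        return list(dict.fromkeys(self.frame_table["molecule_tag"]))

    @property
    def is_complete(self) -> bool:
        if len(self.frame_table) != self.n_frames * self.n_molecules:
            return False
        return not self.frame_table.duplicated(["frame", "molecule_tag"]).any()

    def points(self) -> np.ndarray:
        """(n_entries, 3) coordinates in table order."""
        return self.frame_table[["x", "y", "z"]].to_numpy(dtype=float)

    def pooled_points(self, substrate_type: SubstrateType | str | None = None) -> np.ndarray:
        """All centroids of one substrate type across all frames, as one cloud."""
        df = self.frame_table
        if substrate_type is not None:
            st = SubstrateType(substrate_type)
            df = df[df["substrate_type"] == st.value]
        return df[["x", "y", "z"]].to_numpy(dtype=float)

    def substrate_types(self) -> set[str]:
        return set(self.frame_table["substrate_type"].unique())

    def subset_molecules(self, tags) -> "CentroidSeries":
        tags = set(tags)
        df = self.frame_table[self.frame_table["molecule_tag"].isin(tags)]
        return CentroidSeries(df.copy())

    def molecule_path(self, tag: str) -> np.ndarray:
        """(n_frames, 3) trajectory of one molecule, ordered by frame."""
        df = self.frame_table[self.frame_table["molecule_tag"] == tag].sort_values("frame")
        return df[["x", "y", "z"]].to_numpy(dtype=float)

    def equals(self, other: "CentroidSeries", atol: float = 1e-6) -> bool:
        a, b = self.frame_table, other.frame_table
        if len(a) != len(b):
            return False
        meta_eq = (
            a[["frame", "molecule_tag", "substrate_type"]].reset_index(drop=True)
            .equals(b[["frame", "molecule_tag", "substrate_type"]].reset_index(drop=True))
        )
        return meta_eq and np.allclose(self.points(), other.points(), atol=atol)


def molecule_centroid(atom_points: np.ndarray) -> np.ndarray:
    """Unweighted spatial mean of a molecule's atomic coordinates.

    Raises ``ValueError`` on an empty or non-finite input.
    """
    pts = np.asarray(atom_points, dtype=float)
    if pts.size == 0:
        raise ValueError("cannot take the centroid of zero atoms")
    pts = pts.reshape(-1, 3)
    if not np.all(np.isfinite(pts)):
        raise ValueError("atom coordinates must be finite")
    return pts.mean(axis=0)


def extract_centroid_series(traj: Trajectory) -> CentroidSeries:
    """One centroid per (frame, substrate molecule) from a full trajectory.

    Groups topology atoms by ``molecule_tag`` (keeping first-appearance
    order) and averages each group's coordinates per frame. Every
    substrate atom must carry a tag; protein/solvent atoms
    (``substrate_type == NONE``) are ignored.
    """
    groups: dict[str, list[int]] = {}
    types: dict[str, SubstrateType] = {}
    for i, a in enumerate(traj.topology.atoms):
        if a.substrate_type is SubstrateType.NONE:
            continue
        if a.molecule_tag is None:
            raise LabellingError(
                f"substrate atom {a.serial} ({a.residue_name} {a.chain_id}{a.residue_number}) "
                "has no molecule_tag"
            )
        groups.setdefault(a.molecule_tag, []).append(i)
        types[a.molecule_tag] = a.substrate_type
    if not groups:
        raise LabellingError("trajectory contains no substrate atoms")

    tags = list(groups)
    n_frames = traj.n_frames
    # (n_frames, n_molecules, 3) stack of per-molecule means
    cents = np.stack(
        [traj.frames[:, groups[t], :].mean(axis=1) for t in tags], axis=1
    )
    frame_col = np.repeat(np.arange(n_frames), len(tags))
    df = pd.DataFrame(
        {
            "frame": frame_col,
            "molecule_tag": np.tile(np.array(tags, dtype=object), n_frames),
            "substrate_type": np.tile(
                np.array([types[t].value for t in tags], dtype=object), n_frames
            ),
            "x": cents[:, :, 0].ravel(),
            "y": cents[:, :, 1].ravel(),
            "z": cents[:, :, 2].ravel(),
        }
    )
    reduction = float(np.mean([len(v) for v in groups.values()]))
    return CentroidSeries(df, reduction_factor=reduction)
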
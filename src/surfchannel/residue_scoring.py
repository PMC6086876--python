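"""Per-residue substrate population scores and radial distribution functions.

Two related views of where substrate spends its time:

* :func:`contact_population_score` — the headline per-residue scalar: the
  time-averaged number of substrate centroids within a contact cutoff
  (default 5 Å) of any atom of the residue, summed over a simulation and
  divided by the frame count. One substrate can score several residues in
  the same frame. Maps from replicate simulations are averaged with
  :func:`average_score_maps` and exported for structure colouring via the
  B-factor column.

* :func:`radial_distribution` — a textbook g(r) of substrate centroids
  around a reference selection, normalised by spherical shell volume and
  bulk density, for users wanting the conventional RDF curve rather than
  one scalar per residue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .centroids import CentroidSeries
from .errors import ParameterError, SchemaError
from .io_formats import Structure
from .selection import AtomSelection, select

__all__ = [
    "ResidueScoreMap",
    "RdfHistogram",
    "contact_population_score",
    "radial_distribution",
    "average_score_maps",
]


@dataclass
class ResidueScoreMap:
    """Non-negative substrate-population score per protein residue."""

    scores: dict[tuple[str, int], float]
    substrate_type: str
    n_frames_used: int
    contact_cutoff: float

    def __getitem__(self, key: tuple[str, int]) -> float:
        return self.scores[key]

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {"chain": c, "residue_number": r, "score": s}
            for (c, r), s in sorted(self.scores.items())
        ]
        pd.DataFrame(rows, columns=["chain", "residue_number", "score"]).to_csv(
            path, index=False, float_format="%.6f", lineterminator="\n"
        )

    @classmethod
    def from_csv(
        cls, path: str | Path, substrate_type: str = "aha",
        n_frames_used: int = 0, contact_cutoff: float = 5.0,
    ) -> "ResidueScoreMap":
        df = pd.read_csv(path, dtype={"chain": str})
        missing = {"chain", "residue_number", "score"} - set(df.columns)
        if missing:
            raise SchemaError(f"score table missing column(s): {sorted(missing)}")
        scores = {
            (str(row.chain), int(row.residue_number)): float(row.score)
            for row in df.itertuples()
        }
        return cls(scores, substrate_type, n_frames_used, contact_cutoff)


@dataclass
class RdfHistogram:
    """g(r) of substrate centroids around a reference selection."""

    bin_edges: np.ndarray          # Å, length n_bins + 1
    g_of_r: np.ndarray             # dimensionless, length n_bins
    counts: np.ndarray             # raw centroid counts per bin (all frames)
    reference_expression: str
    bulk_density: float            # molecules / Å^3
    density_estimated: bool = False

    @property
    def bin_mids(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def contact_population_score(
    series: CentroidSeries,
    structure: Structure,
    contact_cutoff: float = 5.0,
    substrate_type: str | None = None,
    residue_sel: str | AtomSelection = "protein",
) -> ResidueScoreMap:
    """Time-averaged substrate occupancy per residue.

    score(residue) = (number of (frame, centroid) events with the centroid
    within ``contact_cutoff`` of any atom of the residue) / n_frames.
    Residues of the selection with no contacts score 0.0. Series and
    structure must share a coordinate frame, i.e. run this after alignment.
    """
    if contact_cutoff <= 0:
        raise ParameterError("contact_cutoff must be positive")
    atom_idx = select(structure, residue_sel)
    atom_keys = [structure.atoms[i].residue_key for i in atom_idx]
    keys = list(dict.fromkeys(atom_keys))

    df = series.frame_table
    if substrate_type is not None:
        df = df[df["substrate_type"] == substrate_type]
        stype = substrate_type
    else:
        types = series.substrate_types()
        stype = next(iter(types)) if len(types) == 1 else "mixed"

    counts: dict[tuple[str, int], int] = {k: 0 for k in keys}
    n_frames = series.n_frames
    if len(df) and n_frames:
        tree = cKDTree(structure.coords()[atom_idx])
        pts = df[["x", "y", "z"]].to_numpy(dtype=float)
        hits = tree.query_ball_point(pts, r=contact_cutoff)
        for neigh in hits:
            for k in {atom_keys[a] for a in neigh}:
                counts[k] += 1

    scores = {k: counts[k] / n_frames if n_frames else 0.0 for k in keys}
    return ResidueScoreMap(scores, stype, n_frames, contact_cutoff)


def radial_distribution(
    series: CentroidSeries,
    reference_sel: str | AtomSelection,
    structure: Structure,
    bin_width: float = 0.5,
    r_max: float = 20.0,
    bulk_density: float | None = None,
) -> RdfHistogram:
    """g(r) of centroids vs distance to the *nearest* reference atom.

    g(r) for bin [r, r+dr) is the frame-averaged centroid count in the bin
    divided by the ideal-gas expectation 4 pi r_mid^2 dr * bulk_density.
    With ``bulk_density=None`` the density is estimated as
    n_molecules / bounding-box volume of the pooled centroids, and the
    histogram is flagged as using an estimate.
    """
    if bin_width <= 0:
        raise ParameterError("bin_width must be positive")
    if r_max <= bin_width:
        raise ParameterError("r_max must exceed bin_width")
    ref_idx = select(structure, reference_sel)
    ref_xyz = structure.coords()[ref_idx]

    n_bins = int(np.floor(r_max / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    pts = series.points()
    n_frames = max(series.n_frames, 1)

    density_estimated = False
    if bulk_density is None:
        if len(pts) == 0:
            raise ParameterError("cannot estimate bulk density from an empty series")
        span = pts.max(axis=0) - pts.min(axis=0)
        volume = float(np.prod(np.maximum(span, 1e-9)))
        bulk_density = series.n_molecules / volume
        density_estimated = True
    if bulk_density <= 0:
        raise ParameterError("bulk_density must be positive")

    if len(pts):
        tree = cKDTree(ref_xyz)
        dists, _ = tree.query(pts)
        counts, _ = np.histogram(dists, bins=edges)
    else:
        counts = np.zeros(n_bins, dtype=int)

    mids = 0.5 * (edges[:-1] + edges[1:])
    shell = 4.0 * np.pi * mids**2 * bin_width
    g = (counts / n_frames) / (shell * bulk_density)

    expr = reference_sel.expression if isinstance(reference_sel, AtomSelection) else reference_sel
    return RdfHistogram(
        bin_edges=edges,
        g_of_r=g,
        counts=counts,
        reference_expression=expr,
        bulk_density=float(bulk_density),
        density_estimated=density_estimated,
    )


def average_score_maps(maps: list[ResidueScoreMap]) -> ResidueScoreMap:
    """Arithmetic per-residue mean over replicate score maps.

    All maps must share residue keys and substrate type; the frame counts
    accumulate so the average remembers how much simulation backs it.
    """
    if not maps:
        raise ValueError("need at least one score map")
    keys = set(maps[0].scores)
    stype = maps[0].substrate_type
    for m in maps[1:]:
        if set(m.scores) != keys:
            raise SchemaError("score maps do not share residue keys")
        if m.substrate_type != stype:
            raise SchemaError(
                f"substrate type mismatch: {m.substrate_type!r} vs {stype!r}"
            )
    mean = {k: float(np.mean([m.scores[k] for m in maps])) for k in keys}
    return ResidueScoreMap(
        mean, stype, sum(m.n_frames_used for m in maps), maps[0].contact_cutoff
    )
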
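"""Trajectory conditioning: anchor centering, superposition, stripping.

The conditioning pipeline mirrors standard MD post-processing: translate
every frame so an anchor selection (by default a short internal residue
range) sits at the origin, rigid-body superpose each frame onto the first
frame by a least-squares (Kabsch) fit, re-center on the whole protein,
and finally strip everything except the substrate atoms. All operations
are rigid: inter-atomic distances within a frame are preserved exactly.

Periodic-boundary re-imaging is *not* performed here — inputs are assumed
already re-imaged by the MD engine's own tooling. Feeding wrapped
coordinates to these functions will scramble centroids silently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError, SelectionError
from .io_formats import Structure, Trajectory
from .selection import AtomSelection, select

__all__ = [
    "AlignmentResult",
    "center_on_selection",
    "superpose_to_first_frame",
    "strip",
    "kabsch",
]


@dataclass(frozen=True)
class AlignmentResult:
    """Rigid transform fitted for one frame, plus fit-selection RMSDs (Å)."""

    rotation: np.ndarray      # 3x3, orthonormal, det +1
    translation: np.ndarray   # applied after rotation
    rmsd_before: float
    rmsd_after: float

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return xyz @ self.rotation.T + self.translation


def _resolve(traj_or_struct, sel: str | AtomSelection) -> list[int]:
    structure = traj_or_struct.topology if isinstance(traj_or_struct, Trajectory) else traj_or_struct
    return select(structure, sel)


def center_on_selection(traj: Trajectory, sel: str | AtomSelection) -> Trajectory:
    """Translate each frame so the selection's geometric centroid is at the origin.

    The centroid is unweighted (no masses). The whole frame moves rigidly.
    """
    idx = _resolve(traj, sel)
    centroids = traj.frames[:, idx, :].mean(axis=1)          # (n_frames, 3)
    frames = traj.frames - centroids[:, None, :]
    return Trajectory(traj.topology.with_coords(frames[0]), frames)


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid fit of ``mobile`` onto ``reference``.

    Returns (R, t) with ``mobile @ R.T + t`` ≈ ``reference``; R is a proper
    rotation (reflections corrected via the SVD determinant sign).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    cm, cr = mobile.mean(axis=0), reference.mean(axis=0)
    P, Q = mobile - cm, reference - cr
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cr - R @ cm
    return R, t


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def superpose_to_first_frame(
    traj: Trajectory,
    fit_sel: str | AtomSelection = "protein",
) -> tuple[Trajectory, list[AlignmentResult]]:
    """Rigidly superpose every frame onto frame 0 by fitting ``fit_sel``.

    Frame 0 is the reference and comes out unchanged (identity fit). The
    fit selection needs at least three atoms spanning more than a line;
    collinear sets leave a rotation degree of freedom unresolved and raise
    :class:`AlignmentError`.
    """
    idx = _resolve(traj, fit_sel)
    if len(idx) < 3:
        raise AlignmentError(f"fit selection has {len(idx)} atoms; need >= 3")
    ref = traj.frames[0, idx, :]
    spread = ref - ref.mean(axis=0)
    if np.linalg.matrix_rank(spread, tol=1e-8) < 2:
        raise AlignmentError("fit selection is collinear; rotation is underdetermined")

    frames = np.empty_like(traj.frames)
    results: list[AlignmentResult] = []
    for k in range(traj.n_frames):
        mob = traj.frames[k, idx, :]
        R, t = kabsch(mob, ref)
        moved = traj.frames[k] @ R.T + t
        frames[k] = moved
        results.append(
            AlignmentResult(
                rotation=R,
                translation=t,
                rmsd_before=_rmsd(mob, ref),
                rmsd_after=_rmsd(moved[idx], ref),
            )
        )
    return Trajectory(traj.topology.with_coords(frames[0]), frames), results


def strip(traj: Trajectory, keep: str | AtomSelection) -> Trajectory:
    """Reduce topology and frames to the kept selection, preserving atom order."""
    idx = _resolve(traj, keep)
    return Trajectory(
        traj.topology.subset(idx).with_coords(traj.frames[0, idx, :]),
        traj.frames[:, idx, :],
    )
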
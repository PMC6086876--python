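"""Decoy protein + diffusing-substrate fixtures with planted ground truth.

The generator emulates the study design the analysis pipeline was built
for: a roughly globular protein with two active-site loci on opposite
faces, twenty substrate molecules of each of two types diffusing in the
surrounding solvent box, and — optionally — a planted surface channel: a
polyline hugging the protein surface along which a few scripted "type A"
walkers travel before entering an active site.

The walker dynamics are *controls with known answers*, not a physical
model: free walkers are reflected Gaussian random walks (hard-sphere
reflection off the protein ellipsoid, reflecting box walls), and
channeled walkers follow the planted polyline with clamped noise,
arriving at their site at a scripted frame. Every stochastic choice flows
from the spec's seed, so fixtures are bit-reproducible.

Substrate "molecules" are rigid clusters of 22 (type A) or 24 (type B)
dummy atoms with zero-mean offsets around the walker position, so the
centroid-extraction stage recovers walker paths exactly and exercises the
~23-fold data reduction of real inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import SpecError
from .io_formats import AtomRecord, Structure, SubstrateType, Trajectory, synthesise_molecule_tag

__all__ = [
    "DecoySpec",
    "PlantedTruth",
    "make_decoy_system",
    "simulate_walkers",
    "generate",
    "distance_to_polyline",
]

_AA_CYCLE = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
]
_PROT_ATOM_NAMES = ["CA", "CB", "CG", "CD", "CE", "CZ", "NZ", "OG", "OD1", "ND1"]

AHA_ATOMS = 22   # heavy + hydrogen atom count of the type-A substrate
HMD_ATOMS = 24   # and of the type-B substrate


@dataclass(frozen=True)
class DecoySpec:
    """Parameters of one synthetic system.

    Defaults mirror the study conditions the pipeline targets: 20 + 20
    substrate molecules of the two types, 10,000 frames per simulation,
    and a free-diffusion step of 1.4 Å/frame/axis (a small molecule with
    D ~ 1e-5 cm^2/s sampled every 10 ps). ``channel_waypoints=None``
    plants a default surface channel; pass an explicit (k, 3) polyline to
    override, or ``n_channel_walkers=0`` for an all-free negative control.
    """

    n_protein_residues: int = 200
    atoms_per_residue: int = 5
    protein_radius: float = 30.0
    channel_waypoints: np.ndarray | None = None
    site_positions: np.ndarray | None = None     # (2, 3): empty, occupied
    n_aha_like: int = 20
    n_hmd_like: int = 20
    n_frames: int = 10_000
    step_sigma: float = 1.4
    box_half_width: float = 60.0
    n_channel_walkers: int = 3
    seed: int = 0
    placement_seed: int | None = None  # share initial positions across systems

    def __post_init__(self) -> None:
        if min(self.n_protein_residues, self.n_aha_like, self.n_hmd_like,
               self.n_channel_walkers) < 0:
            raise SpecError("counts must be non-negative")
        if self.step_sigma <= 0:
            raise SpecError("step_sigma must be positive")
        if self.n_channel_walkers > self.n_aha_like:
            raise SpecError("cannot script more channel walkers than type-A molecules")
        if self.n_frames < 1:
            raise SpecError("need at least one frame")
        for name in ("channel_waypoints", "site_positions"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                object.__setattr__(self, name, v)
                if np.any(np.abs(v) > self.box_half_width):
                    raise SpecError(f"{name} outside the simulation box")

    @property
    def axes(self) -> np.ndarray:
        """Ellipsoid semi-axes of the decoy protein (Å)."""
        return self.protein_radius * np.array([1.0, 0.9, 0.8])


@dataclass
class PlantedTruth:
    """Ground truth of one generated system.

    ``channel_waypoints`` is the planted polyline (first node sits in
    solvent, later nodes ~3 Å above the surface). ``roles`` maps each
    molecule tag to "free" or "channeled"; channeled walkers carry a
    scripted arrival frame and target site. ``channel_residues`` are the
    protein residues within 8 Å of the polyline.
    """

    channel_waypoints: np.ndarray | None
    site_positions: dict[str, np.ndarray]
    roles: dict[str, str]
    arrival_frames: dict[str, int] = field(default_factory=dict)
    target_sites: dict[str, str] = field(default_factory=dict)
    channel_residues: list[tuple[str, int]] = field(default_factory=list)

    def path_polyline(self, site_id: str) -> np.ndarray:
        """Planted route into ``site_id``: channel polyline plus the site leg."""
        if self.channel_waypoints is None:
            raise ValueError("no channel planted in this system")
        return np.vstack([self.channel_waypoints, self.site_positions[site_id]])

    def channeled_tags(self) -> list[str]:
        return [t for t, r in self.roles.items() if r == "channeled"]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "channel_waypoints": None if self.channel_waypoints is None
            else self.channel_waypoints.tolist(),
            "site_positions": {k: v.tolist() for k, v in self.site_positions.items()},
            "roles": self.roles,
            "arrival_frames": self.arrival_frames,
            "target_sites": self.target_sites,
            "channel_residues": [[c, n] for c, n in self.channel_residues],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def distance_to_polyline(points: np.ndarray, nodes: np.ndarray) -> np.ndarray:
    """Distance from each point to the nearest segment of a polyline."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    nodes = np.asarray(nodes, dtype=float).reshape(-1, 3)
    if len(nodes) == 1:
        return np.linalg.norm(pts - nodes[0], axis=1)
    best = np.full(len(pts), np.inf)
    for a, b in zip(nodes[:-1], nodes[1:]):
        ab = b - a
        denom = float(ab @ ab)
        t = np.clip((pts - a) @ ab / denom, 0.0, 1.0) if denom > 0 else np.zeros(len(pts))
        proj = a + t[:, None] * ab
        best = np.minimum(best, np.linalg.norm(pts - proj, axis=1))
    return best


def _fibonacci_directions(n: int) -> np.ndarray:
    """n roughly uniform unit vectors on the sphere (golden-angle spiral)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _surface_point(azimuth_deg: float, axes: np.ndarray, metric: float) -> np.ndarray:
    a = np.deg2rad(azimuth_deg)
    d = np.array([np.cos(a), np.sin(a), 0.0])
    return d * axes * metric


def _default_sites(spec: DecoySpec) -> np.ndarray:
    return np.vstack([
        _surface_point(25.0, spec.axes, 1.03),    # "empty" site
        _surface_point(-25.0, spec.axes, 1.03),   # "occupied" site
    ])


def _default_channel(spec: DecoySpec) -> np.ndarray:
    # first node out in solvent, the rest ~3 Å above the surface arc
    nodes = [_surface_point(150.0, spec.axes, 1.30)]
    nodes += [_surface_point(az, spec.axes, 1.10) for az in (135.0, 100.0, 65.0, 35.0, 10.0)]
    return np.vstack(nodes)


def _zero_mean_offsets(rng: np.random.Generator, n_atoms: int, scale: float = 1.3) -> np.ndarray:
    off = rng.normal(scale=scale, size=(n_atoms, 3))
    return off - off.mean(axis=0)


def make_decoy_system(spec: DecoySpec) -> tuple[Structure, PlantedTruth]:
    """Build the static decoy: protein shell, cofactor anchors, substrates at frame 0.

    Deterministic given ``spec.seed`` (and ``placement_seed`` for the
    substrate starting positions). Protein residues are numbered 1..n on
    chain A; cofactor anchors are residues PLP (empty site) and PLX
    (occupied site) on chain P; substrates are residues AHA/HMD on chain S.
    """
    rng = np.random.default_rng(spec.seed)
    place_rng = np.random.default_rng(
        spec.seed if spec.placement_seed is None else spec.placement_seed
    )

    sites = _default_sites(spec) if spec.site_positions is None else spec.site_positions
    site_positions = {"empty": sites[0], "occupied": sites[1]}
    if spec.n_channel_walkers > 0:
        waypoints = _default_channel(spec) if spec.channel_waypoints is None \
            else spec.channel_waypoints
    else:
        waypoints = spec.channel_waypoints

    atoms: list[AtomRecord] = []
    serial = 1

    # protein shell
    dirs = _fibonacci_directions(max(spec.n_protein_residues, 1))
    residue_centers = dirs[: spec.n_protein_residues] * spec.axes
    for ri in range(spec.n_protein_residues):
        resname = _AA_CYCLE[ri % len(_AA_CYCLE)]
        offsets = _zero_mean_offsets(rng, spec.atoms_per_residue, scale=0.8)
        for ai in range(spec.atoms_per_residue):
            name = (_PROT_ATOM_NAMES[ai] if ai < len(_PROT_ATOM_NAMES) else f"C{ai:02d}")
            p = residue_centers[ri] + offsets[ai]
            atoms.append(AtomRecord(serial, name, resname, "A", ri + 1,
                                    p[0], p[1], p[2], element="C"))
            serial += 1

    # cofactor anchors marking the two sites
    for resnum, (resname, pos) in enumerate(
        [("PLP", site_positions["empty"]), ("PLX", site_positions["occupied"])], start=1
    ):
        for name, off in [("P", (0.0, 0.0, 0.0)), ("O1", (1.2, 0.0, 0.0)), ("C4A", (0.0, 1.2, 0.0))]:
            p = pos + np.array(off)
            atoms.append(AtomRecord(serial, name, resname, "P", resnum,
                                    p[0], p[1], p[2], element=name[0]))
            serial += 1

    # substrates: type A first (channeled walkers are the first few), then type B
    mol_specs = (
        [("AHA", AHA_ATOMS, SubstrateType.AHA_LIKE)] * spec.n_aha_like
        + [("HMD", HMD_ATOMS, SubstrateType.HMD_LIKE)] * spec.n_hmd_like
    )
    roles: dict[str, str] = {}
    target_sites: dict[str, str] = {}
    site_ids = list(site_positions)
    for mi, (resname, n_at, stype) in enumerate(mol_specs):
        resnum = mi + 1
        tag = synthesise_molecule_tag(resname, "S", resnum)
        channeled = stype is SubstrateType.AHA_LIKE and mi < spec.n_channel_walkers
        roles[tag] = "channeled" if channeled else "free"
        if channeled:
            target_sites[tag] = site_ids[mi % len(site_ids)]
            start = waypoints[0] + _clamped_noise(place_rng, 1.0, 2.4)
        else:
            start = _random_solvent_point(place_rng, spec, sites)
        offsets = _zero_mean_offsets(rng, n_at)
        for ai in range(n_at):
            p = start + offsets[ai]
            atoms.append(AtomRecord(serial, f"C{ai + 1:02d}", resname, "S", resnum,
                                    p[0], p[1], p[2], element="C",
                                    molecule_tag=tag, substrate_type=stype))
            serial += 1

    structure = Structure(atoms)

    channel_residues: list[tuple[str, int]] = []
    if waypoints is not None:
        for key, idx in structure.residues.items():
            if key[0] != "A":
                continue
            xyz = structure.coords()[idx]
            if distance_to_polyline(xyz, waypoints).min() <= 8.0:
                channel_residues.append(key)

    arrival_frames = _script_arrival_frames(spec, roles)
    truth = PlantedTruth(
        channel_waypoints=None if waypoints is None else np.asarray(waypoints, dtype=float),
        site_positions=site_positions,
        roles=roles,
        arrival_frames=arrival_frames,
        target_sites=target_sites,
        channel_residues=sorted(channel_residues),
    )
    return structure, truth


def _random_solvent_point(rng: np.random.Generator, spec: DecoySpec,
                          sites: np.ndarray) -> np.ndarray:
    """Uniform point in the box, outside the protein and clear of the sites."""
    for _ in range(10_000):
        p = rng.uniform(-spec.box_half_width, spec.box_half_width, size=3)
        metric = float(np.sqrt(np.sum((p / spec.axes) ** 2)))
        if metric < 1.15:
            continue
        if np.min(np.linalg.norm(sites - p, axis=1)) < 12.0:
            continue
        return p
    raise SpecError("could not place a walker; box too small for the protein")


def _script_arrival_frames(spec: DecoySpec, roles: dict[str, str]) -> dict[str, int]:
    fracs = [0.5, 0.6, 0.7, 0.45, 0.55, 0.65]
    out: dict[str, int] = {}
    k = 0
    for tag, role in roles.items():
        if role == "channeled":
            f = fracs[k % len(fracs)]
            out[tag] = max(1, min(spec.n_frames - 1, round(f * spec.n_frames)))
            k += 1
    return out


def _reflect_box(p: np.ndarray, half: float) -> np.ndarray:
    over = p > half
    p[over] = 2 * half - p[over]
    under = p < -half
    p[under] = -2 * half - p[under]
    return p


def _push_off_ellipsoid(p: np.ndarray, axes: np.ndarray) -> np.ndarray:
    m = float(np.sqrt(np.sum((p / axes) ** 2)))
    if m < 1.0 and m > 0:
        p = p * (1.02 / m)
    return p


def _clamped_noise(rng: np.random.Generator, sigma: float, clamp: float) -> np.ndarray:
    v = rng.normal(scale=sigma, size=3)
    n = float(np.linalg.norm(v))
    return v * (clamp / n) if n > clamp else v


#: pre-arrival exclusion radius around each site anchor (Å). Keeps
#: un-scripted motion out of the arrival shell so the scripted arrival
#: frames are the fixture's exact ground truth.
SITE_KEEPOUT = 5.0


def _push_off_anchors(p: np.ndarray, anchors: np.ndarray) -> np.ndarray:
    for a in anchors:
        d = float(np.linalg.norm(p - a))
        if d < SITE_KEEPOUT:
            p = a + (p - a) * (SITE_KEEPOUT / d) if d > 0 else a + np.array([SITE_KEEPOUT, 0, 0])
    return p


def _channeled_path(spec: DecoySpec, truth: PlantedTruth, tag: str,
                    start: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Scripted route: along the polyline, into the site at the scripted frame."""
    t_arr = truth.arrival_frames[tag]
    site = truth.site_positions[truth.target_sites[tag]]
    anchors = np.vstack(list(truth.site_positions.values()))
    nodes = np.vstack([start, truth.channel_waypoints[1:], site])
    seg = np.linalg.norm(np.diff(nodes, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]

    path = np.empty((spec.n_frames, 3))
    for t in range(spec.n_frames):
        if t == 0:
            path[t] = start
        elif t < t_arr:
            s = total * t / t_arr
            k = int(np.searchsorted(cum, s, side="right") - 1)
            k = min(k, len(seg) - 1)
            frac = (s - cum[k]) / seg[k] if seg[k] > 0 else 0.0
            base = nodes[k] + frac * (nodes[k + 1] - nodes[k])
            path[t] = _push_off_anchors(base + _clamped_noise(rng, 0.75, 2.5), anchors)
        elif t == t_arr:
            path[t] = site + _clamped_noise(rng, 0.6, 2.0)
        else:
            # mean-reverting wobble inside the site region
            prev = path[t - 1]
            p = site + 0.75 * (prev - site) + _clamped_noise(rng, 0.4, 1.2)
            d = float(np.linalg.norm(p - site))
            if d > 4.0:
                p = site + (p - site) * (4.0 / d)
            path[t] = p
    return path


def _free_path(spec: DecoySpec, start: np.ndarray, rng: np.random.Generator,
               anchors: np.ndarray) -> np.ndarray:
    path = np.empty((spec.n_frames, 3))
    p = start.astype(float).copy()
    path[0] = p
    for t in range(1, spec.n_frames):
        p = p + rng.normal(scale=spec.step_sigma, size=3)
        p = _reflect_box(p, spec.box_half_width)
        p = _push_off_ellipsoid(p, spec.axes)
        p = _push_off_anchors(p, anchors)
        path[t] = p
    return path


def simulate_walkers(spec: DecoySpec, truth: PlantedTruth,
                     structure: Structure) -> Trajectory:
    """Roll the walkers forward and assemble the multi-frame trajectory.

    Protein and cofactor atoms are static; each substrate molecule's rigid
    atom cluster translates with its walker. Frame 0 equals the structure's
    coordinates.
    """
    rng = np.random.default_rng((spec.seed, 1))
    coords0 = structure.coords()
    n_atoms = len(structure.atoms)
    frames = np.empty((spec.n_frames, n_atoms, 3))
    frames[:] = coords0[None, :, :]

    mol_atoms: dict[str, list[int]] = {}
    for i, a in enumerate(structure.atoms):
        if a.molecule_tag is not None:
            mol_atoms.setdefault(a.molecule_tag, []).append(i)

    anchors = np.vstack(list(truth.site_positions.values()))
    for tag, idx in mol_atoms.items():
        start = coords0[idx].mean(axis=0)
        offsets = coords0[idx] - start
        if truth.roles.get(tag) == "channeled":
            path = _channeled_path(spec, truth, tag, start, rng)
        else:
            path = _free_path(spec, start, rng, anchors)
        frames[:, idx, :] = path[:, None, :] + offsets[None, :, :]

    return Trajectory(structure.with_coords(frames[0]), frames)


def generate(spec: DecoySpec) -> tuple[Structure, PlantedTruth, Trajectory]:
    """Convenience wrapper: build the decoy and simulate it in one call."""
    structure, truth = make_decoy_system(spec)
    traj = simulate_walkers(spec, truth, structure)
    return structure, truth, traj
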
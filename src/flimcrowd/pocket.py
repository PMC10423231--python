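"""Trajectory analysis: contact-defined pockets, hull volumes, H-bonds, SASA.

Operates on generic coordinate ensembles (frames x atoms x 3, Angstrom) with
a per-atom metadata table, so any text trajectory format (multi-frame XYZ or
PDB) can feed it.  The fluorophore pocket is the residue set in contact with
a target selection in more than 0.33% of post-equilibration snapshots
(any-atom criterion, 3.5 A cutoff); its per-frame convex-hull C-alpha volume
distribution is summarized with the standard error of the mean computed over
replicas, each replica being one independent observation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError, cKDTree

__all__ = [
    "Trajectory",
    "TrajectoryEnsemble",
    "PocketDefinition",
    "PocketVolumeDistribution",
    "trim_equilibration",
    "residue_contacts",
    "define_pocket",
    "pocket_volume",
    "pocket_volume_distribution",
    "distance_difference_map",
    "count_hydrogen_bonds",
    "sasa_shrake_rupley",
    "VDW_RADII",
]

VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
}
"""Van der Waals radii (Angstrom) for SASA; Bondi set for common elements."""


@dataclass
class Trajectory:
    """One replica: coordinates (n_frames, n_atoms, 3) plus atom metadata.

    ``atoms`` must carry columns residue_index, residue_name, atom_name,
    element (any may be synthesized for toy data).
    """

    coords: np.ndarray
    atoms: pd.DataFrame

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if len(self.atoms) != self.coords.shape[1]:
            raise ValueError("atom metadata must match the coordinate atom count")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @classmethod
    def from_calpha(cls, coords: np.ndarray, residue_indices: Sequence[int] | None = None) -> "Trajectory":
        """Build a C-alpha-only trajectory (one atom per residue)."""
        coords = np.asarray(coords, dtype=float)
        n_atoms = coords.shape[1]
        idx = np.arange(n_atoms) if residue_indices is None else np.asarray(residue_indices)
        atoms = pd.DataFrame(
            {
                "residue_index": idx,
                "residue_name": "ALA",
                "atom_name": "CA",
                "element": "C",
            }
        )
        return cls(coords, atoms)


TrajectoryEnsemble = Sequence[Trajectory]


@dataclass
class PocketDefinition:
    """Contact-frequency-defined pocket residue set."""

    target_residues: Sequence[int]
    pocket_residues: np.ndarray
    cutoff: float = 3.5
    freq_threshold: float = 0.0033
    contact_frequency: pd.Series | None = field(default=None, repr=False)


@dataclass
class PocketVolumeDistribution:
    """Per-frame pocket volumes with replica-level summary.

    SEM treats each replica (trajectory) as one independent observation;
    it is NaN for a single replica.
    """

    per_frame: list[np.ndarray]
    replica_means: np.ndarray
    grand_mean: float
    sem: float


def trim_equilibration(traj: Trajectory, fraction: float = 0.25) -> Trajectory:
    """Drop the first ceil(fraction * n_frames) frames as equilibration."""
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    drop = int(np.ceil(fraction * traj.n_frames))
    if drop >= traj.n_frames:
        raise ValueError("trimming would leave no frames")
    return Trajectory(traj.coords[drop:], traj.atoms)


def _min_image(d: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is None:
        return d
    return d - box * np.round(d / box)


def residue_contacts(
    frame: np.ndarray,
    atoms: pd.DataFrame,
    selection_a: Sequence[int],
    selection_b: Sequence[int],
    cutoff: float = 3.5,
    box: np.ndarray | None = None,
    heavy_only: bool = False,
) -> set[tuple[int, int]]:
    """Residue pairs (a, b) with any inter-atomic distance below the cutoff.

    ``selection_a``/``selection_b`` are residue-index collections.  All atoms
    participate (including hydrogens) unless ``heavy_only``.  Minimum-image
    distances are used only when a periodic ``box`` is supplied.
    """
    if len(selection_a) == 0 or len(selection_b) == 0:
        raise ValueError("selections must be non-empty")
    res_idx = atoms["residue_index"].to_numpy()
    elem = atoms["element"].to_numpy()
    keep = np.ones(len(atoms), dtype=bool)
    if heavy_only:
        keep = elem != "H"
    ia = np.flatnonzero(np.isin(res_idx, list(selection_a)) & keep)
    ib = np.flatnonzero(np.isin(res_idx, list(selection_b)) & keep)
    if ia.size == 0 or ib.size == 0:
        return set()
    pa, pb = frame[ia], frame[ib]
    if box is None:
        tree = cKDTree(pb)
        pairs = tree.query_ball_point(pa, r=cutoff)
        out = set()
        for k, neigh in enumerate(pairs):
            ra = int(res_idx[ia[k]])
            for j in neigh:
                rb = int(res_idx[ib[j]])
                if ra != rb:
                    out.add((ra, rb))
        return out
    d = _min_image(pa[:, None, :] - pb[None, :, :], np.asarray(box, dtype=float))
    close = np.linalg.norm(d, axis=2) < cutoff
    out = set()
    for k, j in zip(*np.nonzero(close)):
        ra, rb = int(res_idx[ia[k]]), int(res_idx[ib[j]])
        if ra != rb:
            out.add((ra, rb))
    return out


def define_pocket(
    ensemble: TrajectoryEnsemble,
    target_residues: Sequence[int],
    cutoff: float = 3.5,
    freq_threshold: float = 0.0033,
    per_replica: bool = False,
    heavy_only: bool = False,
) -> PocketDefinition:
    """Pocket residues: in contact with the target in > freq_threshold of snapshots.

    Frequencies are pooled over all post-equilibration snapshots of all
    replicas by default (``per_replica`` instead requires the threshold in
    every replica separately).  The threshold is strict (">"), default
    0.33%.
    """
    target = set(int(r) for r in target_residues)
    counts: dict[int, np.ndarray] = {}
    n_frames_per = []
    for ri, traj in enumerate(ensemble):
        all_res = set(traj.atoms["residue_index"].tolist())
        if not target <= all_res:
            raise ValueError("target residues absent from trajectory")
        others = sorted(all_res - target)
        n_frames_per.append(traj.n_frames)
        for f in range(traj.n_frames):
            pairs = residue_contacts(
                traj.coords[f], traj.atoms, others, sorted(target), cutoff, heavy_only=heavy_only
            )
            for ra, _ in pairs:
                if ra not in counts:
                    counts[ra] = np.zeros(len(ensemble), dtype=int)
                counts[ra][ri] += 1
    total = float(sum(n_frames_per))
    freq = pd.Series(
        {r: c.sum() / total for r, c in counts.items()}, dtype=float
    ).sort_index()
    if per_replica:
        keep = [
            r
            for r, c in counts.items()
            if all(c[i] / n_frames_per[i] > freq_threshold for i in range(len(ensemble)))
        ]
    else:
        keep = freq.index[freq > freq_threshold].tolist()
    return PocketDefinition(
        target_residues=sorted(target),
        pocket_residues=np.array(sorted(keep), dtype=int),
        cutoff=cutoff,
        freq_threshold=freq_threshold,
        contact_frequency=freq,
    )


def _calpha_coords(frame: np.ndarray, atoms: pd.DataFrame, residues: np.ndarray) -> np.ndarray:
    sel = (atoms["atom_name"] == "CA").to_numpy() & np.isin(
        atoms["residue_index"].to_numpy(), residues
    )
    return frame[sel]


def pocket_volume(
    frame: np.ndarray, atoms: pd.DataFrame, pocket: PocketDefinition
) -> float:
    """Convex-hull volume (A^3) of the pocket residues' C-alpha atoms.

    Returns 0.0 for rank-deficient point sets (fewer than 4 points or
    coplanar geometry).
    """
    pts = _calpha_coords(frame, atoms, pocket.pocket_residues)
    if pts.shape[0] < 4:
        return 0.0
    try:
        return float(ConvexHull(pts).volume)
    except QhullError:
        return 0.0


def pocket_volume_distribution(
    ensemble: TrajectoryEnsemble, pocket: PocketDefinition
) -> PocketVolumeDistribution:
    """Per-frame pocket volumes with SEM over replica means."""
    per_frame = []
    for traj in ensemble:
        vols = np.array(
            [pocket_volume(traj.coords[f], traj.atoms, pocket) for f in range(traj.n_frames)]
        )
        per_frame.append(vols)
    means = np.array([v.mean() for v in per_frame])
    sem = (
        float(means.std(ddof=1) / np.sqrt(means.size)) if means.size >= 2 else float("nan")
    )
    return PocketVolumeDistribution(
        per_frame=per_frame,
        replica_means=means,
        grand_mean=float(means.mean()),
        sem=sem,
    )


def _mean_ca_distances(
    ensemble: TrajectoryEnsemble, residues: np.ndarray
) -> np.ndarray:
    acc = None
    n = 0
    for traj in ensemble:
        ca = np.stack(
            [_calpha_coords(traj.coords[f], traj.atoms, residues) for f in range(traj.n_frames)]
        )
        if ca.shape[1] != residues.size:
            raise ValueError("residues not uniquely resolvable to C-alpha atoms")
        d = np.linalg.norm(ca[:, :, None, :] - ca[:, None, :, :], axis=3)
        acc = d.sum(axis=0) if acc is None else acc + d.sum(axis=0)
        n += traj.n_frames
    return acc / n


def distance_difference_map(
    ensemble_a: TrajectoryEnsemble,
    ensemble_b: TrajectoryEnsemble,
    residues: Sequence[int],
) -> np.ndarray:
    """Mean C-alpha pairwise-distance difference map <d_ij>_A - <d_ij>_B.

    Symmetric with a zero diagonal; positive entries mean the pair is more
    separated in ensemble A.
    """
    residues = np.asarray(sorted(residues), dtype=int)
    return _mean_ca_distances(ensemble_a, residues) - _mean_ca_distances(
        ensemble_b, residues
    )


def count_hydrogen_bonds(
    frame: np.ndarray,
    donors: Sequence[int],
    hydrogens: Sequence[int],
    acceptors: Sequence[int],
    dist_cutoff: float = 3.5,
    angle_cutoff: float = 150.0,
) -> int:
    """Count hydrogen bonds by the geometric donor-H...acceptor criterion.

    ``donors`` and ``hydrogens`` are parallel atom-index lists (covalent
    D-H pairs).  A bond is counted iff the donor-acceptor distance is below
    ``dist_cutoff`` (A) and the D-H...A angle, measured at the hydrogen, is
    at least ``angle_cutoff`` degrees (boundary inclusive).
    """
    donors = np.asarray(donors, dtype=int)
    hydrogens = np.asarray(hydrogens, dtype=int)
    acceptors = np.asarray(acceptors, dtype=int)
    if donors.size != hydrogens.size:
        raise ValueError("each hydrogen must be paired with its covalent donor")
    if donors.size == 0 or acceptors.size == 0:
        return 0
    d_pos = frame[donors]
    h_pos = frame[hydrogens]
    a_pos = frame[acceptors]
    da = np.linalg.norm(d_pos[:, None, :] - a_pos[None, :, :], axis=2)
    v1 = d_pos[:, None, :] - h_pos[:, None, :]
    v2 = a_pos[None, :, :] - h_pos[:, None, :]
    cosang = np.sum(v1 * v2, axis=2) / (
        np.linalg.norm(v1, axis=2) * np.linalg.norm(v2, axis=2) + 1e-30
    )
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    same = donors[:, None] == acceptors[None, :]
    return int(np.sum((da < dist_cutoff) & (ang >= angle_cutoff) & ~same))


def _sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere points (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )


def sasa_shrake_rupley(
    frame: np.ndarray,
    atoms: pd.DataFrame,
    radii: dict[str, float] | None = None,
    probe: float = 1.4,
    n_points: int = 960,
) -> pd.Series:
    """Shrake-Rupley solvent-accessible surface area, summed per residue (A^2).

    Each atom is covered with ``n_points`` quasi-uniform sphere points at
    radius r_vdw + probe; points inside any neighbour's expanded sphere are
    buried.  Unknown elements raise with the offending symbols listed.
    """
    radii = VDW_RADII if radii is None else radii
    elem = atoms["element"].to_numpy()
    unknown = sorted(set(elem) - set(radii))
    if unknown:
        raise ValueError(f"no radius for element(s): {', '.join(unknown)}")
    r = np.array([radii[e] for e in elem]) + probe
    pts = _sphere_points(n_points)
    tree = cKDTree(frame)
    areas = np.zeros(len(atoms))
    for i in range(len(atoms)):
        shell = frame[i] + r[i] * pts
        neigh = [j for j in tree.query_ball_point(frame[i], r=r[i] + r.max()) if j != i]
        if neigh:
            d = np.linalg.norm(shell[:, None, :] - frame[neigh][None, :, :], axis=2)
            exposed = np.all(d >= r[neigh][None, :], axis=1)
        else:
            exposed = np.ones(n_points, dtype=bool)
        areas[i] = exposed.mean() * 4.0 * np.pi * r[i] ** 2
    return pd.Series(areas).groupby(atoms["residue_index"].to_numpy()).sum()
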
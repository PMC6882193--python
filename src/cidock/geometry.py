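"""Pose geometry: in-place ligand RMSD, similarity matrices, active-site boxes.

RMSD between docking poses is computed *in place* (no superposition): the
quantity of interest is where the ligand sits in the receptor frame, and the
2.0 Å similarity criterion used throughout the pipeline is meaningless after
least-squares fitting.  Only heavy atoms enter the RMSD.

Topologically symmetric ligands (benzene rings, carboxylates, ...) admit
several equally valid atom correspondences; symmetry-aware RMSD minimizes
over the automorphisms of the heavy-atom molecular graph, enumerated with
networkx's VF2 matcher and capped to keep worst cases bounded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from networkx.algorithms import isomorphism as iso

from .errors import ContentError, TopologyError, ValidationError
from .molecules import Molecule, Pose

DEFAULT_AUTOMORPHISM_CAP = 10_000


@dataclass(frozen=True)
class BoxSpec:
    """Axis-aligned active-site box: center and half-lengths, Å."""

    center: tuple[float, float, float]
    half_lengths: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not all(h > 0 for h in self.half_lengths):
            raise ValidationError("box half-lengths must be positive")
        if not np.all(np.isfinite(self.center)) or not np.all(np.isfinite(self.half_lengths)):
            raise ValidationError("box parameters must be finite")

    @property
    def lo(self) -> np.ndarray:
        return np.asarray(self.center) - np.asarray(self.half_lengths)

    @property
    def hi(self) -> np.ndarray:
        return np.asarray(self.center) + np.asarray(self.half_lengths)

    def contains(self, coords: np.ndarray) -> bool:
        coords = np.atleast_2d(coords)
        return bool(np.all(coords >= self.lo - 1e-9) and np.all(coords <= self.hi + 1e-9))

    def to_text(self) -> str:
        """center + size key-value block in the convention docking engines use."""
        cx, cy, cz = self.center
        sx, sy, sz = (2 * h for h in self.half_lengths)
        return (f"center_x = {cx:.3f}\ncenter_y = {cy:.3f}\ncenter_z = {cz:.3f}\n"
                f"size_x = {sx:.3f}\nsize_y = {sy:.3f}\nsize_z = {sz:.3f}\n")


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise pose-RMSD matrix (Å) with zero diagonal."""

    pose_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.pose_ids)
        if v.shape != (n, n):
            raise ValidationError("similarity matrix shape does not match pose ids")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValidationError("RMSD entries must be finite and non-negative")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0.0):
            raise ValidationError("similarity matrix must be symmetric with zero diagonal")
        self.values = v


def _automorphism_cache_key(mol: Molecule) -> tuple:
    return mol.heavy_topology_key()


_AUTOMORPHISM_CACHE: dict[tuple, np.ndarray] = {}


def heavy_automorphisms(mol: Molecule, cap: int = DEFAULT_AUTOMORPHISM_CAP) -> np.ndarray:
    """Permutations (rows) of heavy-atom positions preserving elements and bonds.

    Indices are into the heavy-atom ordering.  Enumeration is capped; past the
    cap only the identity is returned (with a warning), so RMSD degrades to the
    plain atom-order value rather than stalling.
    """
    key = _automorphism_cache_key(mol)
    cached = _AUTOMORPHISM_CACHE.get(key)
    if cached is not None:
        return cached
    g = mol.heavy_graph()
    heavy = [int(i) for i in mol.heavy_indices]
    pos_of = {a: k for k, a in enumerate(heavy)}
    matcher = iso.GraphMatcher(
        g, g,
        node_match=iso.categorical_node_match("element", None),
        edge_match=iso.categorical_edge_match("order", None))
    perms: list[list[int]] = []
    for mapping in matcher.isomorphisms_iter():
        perms.append([pos_of[mapping[a]] for a in heavy])
        if len(perms) > cap:
            warnings.warn(
                f"molecule {mol.name!r}: automorphism group larger than cap {cap}; "
                "falling back to identity atom mapping", stacklevel=2)
            perms = [list(range(len(heavy)))]
            break
    out = np.array(perms, dtype=int)
    _AUTOMORPHISM_CACHE[key] = out
    return out


def _check_same_topology(a: Molecule, b: Molecule) -> None:
    if a.heavy_topology_key() != b.heavy_topology_key():
        raise TopologyError(
            f"molecules {a.name!r} and {b.name!r} do not share heavy-atom topology")


def rmsd_under_permutations(xa: np.ndarray, xb: np.ndarray,
                            perms: np.ndarray) -> float:
    """Minimum in-place RMSD of xb→xa over the given atom permutations of xb."""
    diff = xb[perms] - xa[None, :, :]          # (P, n, 3)
    msd = np.einsum("pij,pij->p", diff, diff) / xa.shape[0]
    return float(np.sqrt(msd.min()))


def pose_rmsd(a: Pose | Molecule, b: Pose | Molecule,
              symmetry_aware: bool = True,
              automorphism_cap: int = DEFAULT_AUTOMORPHISM_CAP) -> float:
    """Heavy-atom, in-place RMSD (Å) between two poses of one ligand.

    With ``symmetry_aware`` the value is minimized over all graph
    automorphisms that preserve elements and bond orders, so chemically
    indistinguishable atom relabelings are not penalized.
    """
    ma = a.molecule if isinstance(a, Pose) else a
    mb = b.molecule if isinstance(b, Pose) else b
    _check_same_topology(ma, mb)
    xa, xb = ma.heavy_coords, mb.heavy_coords
    if symmetry_aware:
        perms = heavy_automorphisms(ma, cap=automorphism_cap)
    else:
        perms = np.arange(xa.shape[0], dtype=int)[None, :]
    return rmsd_under_permutations(xa, xb, perms)


def similarity_matrix(poses: list[Pose], symmetry_aware: bool = True,
                      automorphism_cap: int = DEFAULT_AUTOMORPHISM_CAP) -> SimilarityMatrix:
    """All-pairs pose RMSD matrix for one conformational group."""
    if not poses:
        raise ValidationError("similarity_matrix requires at least one pose")
    mol0 = poses[0].molecule
    for p in poses[1:]:
        _check_same_topology(mol0, p.molecule)
    coords = np.stack([p.heavy_coords for p in poses])      # (m, n, 3)
    if symmetry_aware:
        perms = heavy_automorphisms(mol0, cap=automorphism_cap)
    else:
        perms = np.arange(coords.shape[1], dtype=int)[None, :]
    m = len(poses)
    values = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            values[i, j] = values[j, i] = rmsd_under_permutations(
                coords[i], coords[j], perms)
    return SimilarityMatrix([p.pose_id for p in poses], values)


def rmsd_to_leaders(pose_coords: np.ndarray, leader_coords: np.ndarray,
                    perms: np.ndarray) -> np.ndarray:
    """Vectorized symmetry-aware RMSD of one pose against many leaders.

    ``pose_coords`` is (n, 3); ``leader_coords`` is (L, n, 3); returns (L,).
    Used by leader clustering so each new pose costs one einsum.
    """
    permuted = pose_coords[perms]                          # (P, n, 3)
    diff = permuted[None, :, :, :] - leader_coords[:, None, :, :]   # (L, P, n, 3)
    msd = np.einsum("lpij,lpij->lp", diff, diff) / pose_coords.shape[0]
    return np.sqrt(msd.min(axis=1))


def define_box(reference_ligand: Molecule, margin: float = 12.5) -> BoxSpec:
    """Active-site box: the reference bound-ligand's heavy-atom bounding box
    expanded by ``margin`` Å on every face (default 12.5 Å)."""
    if margin <= 0:
        raise ValidationError("box margin must be positive")
    coords = reference_ligand.heavy_coords
    if coords.shape[0] == 0:
        raise ContentError("reference ligand has no heavy atoms")
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    center = (lo + hi) / 2
    half = (hi - lo) / 2
    return BoxSpec(tuple(float(c) for c in center), tuple(float(h) for h in half))
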
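"""Seeded generators for every fixture the pipeline needs offline.

Three families, all pure functions of (spec, seed):

* toy ligands — connected chain/ring molecules with controllable topological
  symmetry, for RMSD and clustering tests;
* pose ensembles with *planted* cluster structure — poses dropped at
  well-separated site centers with Gaussian rigid-body jitter, engine scores
  arranged so the largest planted site holds the best score; the ground-truth
  site assignment is returned alongside so tests can assert recovery without
  re-deriving it;
* score libraries with planted enrichment — known-target energies drawn from
  Normal(−effect_size, noise_sd) against a Normal(0, noise_sd) background,
  which gives the closed-form expected AUC Φ(effect_size / (√2·noise_sd))
  as an analytic oracle.

The placement math here is deliberately independent of the clustering and
evaluation code paths it is used to test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .engines import DEFAULT_ENGINE_IDS, stable_seed
from .errors import ValidationError
from .evaluate import KnownTargetAnnotation
from .geometry import BoxSpec, define_box
from .molecules import Molecule, Pose, PoseEnsemble, write_molecule
from .screen import TargetEntry


def _zigzag(n: int) -> np.ndarray:
    # ideal-ish sp3 chain: 1.47 Å bonds, alternating y
    return np.array([[1.25 * i, 0.77 * (i % 2), 0.0] for i in range(n)])


def make_toy_ligand(n_heavy: int, with_symmetry: bool = False, seed: int = 0,
                    ) -> Molecule:
    """Connected toy molecule with ``n_heavy`` heavy atoms.

    Without symmetry the chain is end-labelled (N at one end) so its graph
    automorphism group is trivial; with symmetry the molecule contains an
    aromatic six-ring (plus a chain tail if more atoms were requested), so
    the automorphism group is non-trivial by construction.
    """
    if n_heavy < 1:
        raise ValidationError("n_heavy must be >= 1")
    rng = np.random.default_rng(stable_seed(seed, "toy-ligand", n_heavy, with_symmetry))
    if with_symmetry:
        n_heavy = max(n_heavy, 6)
        ring = np.array([[1.39 * np.cos(np.pi * i / 3), 1.39 * np.sin(np.pi * i / 3), 0.0]
                         for i in range(6)])
        tail = _zigzag(n_heavy - 6) + np.array([2.8, 0.0, 0.0]) if n_heavy > 6 else \
            np.empty((0, 3))
        coords = np.vstack([ring, tail])
        elements = ["C"] * n_heavy
        bonds: list[tuple[int, int, object]] = [(i, (i + 1) % 6, "ar") for i in range(6)]
        if n_heavy > 6:
            bonds.append((0, 6, 1))
            bonds += [(i, i + 1, 1) for i in range(6, n_heavy - 1)]
    else:
        coords = _zigzag(n_heavy)
        elements = (["N"] + ["C"] * (n_heavy - 1)) if n_heavy >= 2 else ["C"]
        bonds = [(i, i + 1, 1) for i in range(n_heavy - 1)]
    coords = coords + rng.normal(scale=0.03, size=coords.shape)
    return Molecule(f"toy{n_heavy}{'s' if with_symmetry else ''}", elements,
                    coords, bonds)


@dataclass
class EnsembleSpec:
    """Planted cluster structure for synthetic pose ensembles."""

    n_engines: int
    n_poses_per_engine: int
    site_centers: Sequence[Sequence[float]]
    site_weights: Sequence[Sequence[int]] | None = None
    intra_site_jitter: float = 0.3
    seed: int = 0
    cluster_threshold: float = 2.0

    def __post_init__(self) -> None:
        if self.n_engines < 1 or self.n_poses_per_engine < 1:
            raise ValidationError("need >= 1 engine and >= 1 pose per engine")
        centers = np.asarray(self.site_centers, dtype=float)
        if centers.ndim != 2 or centers.shape[1] != 3 or centers.shape[0] < 1:
            raise ValidationError("site_centers must be a non-empty list of 3-D points")
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                d = float(np.linalg.norm(centers[i] - centers[j]))
                if d < 3.0 * self.cluster_threshold:
                    raise ValidationError(
                        f"site centers {i} and {j} only {d:.2f} Å apart; need "
                        f">= {3.0 * self.cluster_threshold} Å for unambiguous structure")
        if self.site_weights is None:
            self.site_weights = self._even_weights(len(centers))
        if len(self.site_weights) != self.n_engines:
            raise ValidationError("one weight row per engine required")
        for row in self.site_weights:
            if len(row) != len(centers) or any(w < 0 for w in row):
                raise ValidationError("each weight row needs one entry per site, >= 0")
            if sum(row) != self.n_poses_per_engine:
                raise ValidationError("weights per engine must sum to n_poses_per_engine")

    def _even_weights(self, n_sites: int) -> list[list[int]]:
        base, rem = divmod(self.n_poses_per_engine, n_sites)
        row = [base + (1 if s < rem else 0) for s in range(n_sites)]
        return [list(row) for _ in range(self.n_engines)]

    def total_site_sizes(self) -> list[int]:
        return [sum(row[s] for row in self.site_weights)
                for s in range(len(self.site_centers))]


def _engine_ids(n: int) -> list[str]:
    ids = list(DEFAULT_ENGINE_IDS[:n])
    ids += [f"ENGINE{k}" for k in range(len(ids), n)]
    return ids


def make_pose_ensembles(spec: EnsembleSpec, ligand: Molecule,
                        ) -> tuple[dict[str, PoseEnsemble], dict[str, int]]:
    """Pose ensembles with planted sites; returns (ensembles, pose_id → site).

    Poses are the centered ligand rigidly translated to a site center plus an
    isotropic Gaussian offset of sd ``intra_site_jitter`` (zero jitter makes
    all intra-site RMSDs exactly zero).  Scores are drawn from disjoint bands:
    poses of the globally largest site from (−9.5, −8.5), everything else
    from (−7.5, −5.5), so the best score always sits in the largest site.
    """
    rng = np.random.default_rng(stable_seed(spec.seed, "planted-ensembles"))
    template = ligand.strip_hydrogens()
    base = template.coords - template.coords.mean(axis=0)
    centers = np.asarray(spec.site_centers, dtype=float)
    sizes = spec.total_site_sizes()
    biggest = int(np.argmax(sizes))

    ensembles: dict[str, PoseEnsemble] = {}
    truth: dict[str, int] = {}
    for e, engine_id in enumerate(_engine_ids(spec.n_engines)):
        poses: list[Pose] = []
        k = 0
        for s, center in enumerate(centers):
            for _ in range(int(spec.site_weights[e][s])):
                offset = rng.normal(scale=spec.intra_site_jitter, size=3) \
                    if spec.intra_site_jitter > 0 else np.zeros(3)
                coords = base + center + offset
                score = rng.uniform(-9.5, -8.5) if s == biggest \
                    else rng.uniform(-7.5, -5.5)
                pose = Pose(template.with_coords(coords, name=f"{engine_id}:{k}"),
                            engine_id, float(score), k)
                poses.append(pose)
                truth[pose.pose_id] = s
                k += 1
        ensembles[engine_id] = PoseEnsemble(
            ligand.name, "synthetic", engine_id, poses,
            max_poses=spec.n_poses_per_engine)
    return ensembles, truth


@dataclass
class LibrarySpec:
    """Planted enrichment for synthetic score libraries."""

    n_targets: int
    n_known: int
    effect_size: float = 3.0     # kcal/mol separation of known-target mean
    noise_sd: float = 1.0        # kcal/mol
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_known < self.n_targets:
            raise ValidationError("need 1 <= n_known < n_targets")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")


def expected_auc(spec: LibrarySpec) -> float:
    """Closed-form expected AUC Φ(effect_size / (√2·noise_sd)) of the planted model."""
    from scipy.stats import norm
    return float(norm.cdf(spec.effect_size / (np.sqrt(2.0) * spec.noise_sd)))


def make_score_library(spec: LibrarySpec, ligand_id: str = "drug",
                       ) -> tuple[dict[str, float], KnownTargetAnnotation]:
    """Per-target energies with planted positives, plus their annotation.

    Background energies ~ Normal(0, noise_sd); known-target energies ~
    Normal(−effect_size, noise_sd); which targets are known is itself a
    seeded draw.
    """
    rng = np.random.default_rng(stable_seed(spec.seed, "score-library"))
    ids = [f"T{i:04d}" for i in range(spec.n_targets)]
    known = set(rng.choice(ids, size=spec.n_known, replace=False).tolist())
    energies = {t: float(rng.normal(-spec.effect_size if t in known else 0.0,
                                    spec.noise_sd)) for t in ids}
    return energies, KnownTargetAnnotation(ligand_id, frozenset(known))


# ---------------------------------------------------------------------------
# geometric target libraries (for full-pipeline screens)
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5 ** 0.5) * k
    return radius * np.stack([np.cos(theta) * np.sin(phi),
                              np.sin(theta) * np.sin(phi), np.cos(phi)], axis=1)


def make_target_library(ligand: Molecule, n_targets: int, seed: int = 0,
                        n_known: int = 1, box_margin: float = 12.5,
                        cage_radius: float | None = None, n_cage_atoms: int = 80,
                        decoy_shift: tuple[float, float] = (20.0, 30.0),
                        ) -> tuple[list[TargetEntry], KnownTargetAnnotation]:
    """Geometric library with planted strong binders for end-to-end screens.

    Every target's reference site is the ligand itself at a target-specific
    location, so the active-site box (bounding box + ``box_margin``) funnels
    docked poses to the site center.  Planted (known) targets carry a carbon
    cage of ``n_cage_atoms`` atoms at ``cage_radius`` Å around that center —
    dense favourable contacts for whatever pose the consensus picks — while
    decoy receptors have the same cage pushed ``decoy_shift`` Å outward,
    mostly past the interaction cutoffs.  Known targets therefore rescore
    strongly negative and rank first.
    """
    if not 1 <= n_known < n_targets:
        raise ValidationError("need 1 <= n_known < n_targets")
    rng = np.random.default_rng(stable_seed(seed, "target-library"))
    template = ligand.strip_hydrogens()
    base = template.coords - template.coords.mean(axis=0)
    if cage_radius is None:
        # keep the cage at ideal contact distance from the ligand's extremities
        cage_radius = float(np.linalg.norm(base, axis=1).max()) + 4.0
    ids = [f"T{i:04d}" for i in range(n_targets)]
    known = set(rng.choice(ids, size=n_known, replace=False).tolist())

    entries: list[TargetEntry] = []
    for t in ids:
        site = rng.uniform(-50.0, 50.0, size=3)
        ref = template.with_coords(base + site, name=f"{t}_ref")
        cage = _fibonacci_sphere(n_cage_atoms, cage_radius)
        if t not in known:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            cage = cage + direction * rng.uniform(*decoy_shift)
        receptor = Molecule(f"{t}_receptor", ["C"] * n_cage_atoms, cage + site,
                            bonds=[], is_receptor=True)
        entries.append(TargetEntry(t, receptor, define_box(ref, box_margin),
                                   annotations={"known": t in known}, ref_ligand=ref))
    return entries, KnownTargetAnnotation(ligand.name, frozenset(known))


def write_synthetic_library(out_dir: str | Path, n_targets: int, seed: int = 0,
                            n_known: int = 2, ligand: Molecule | None = None,
                            ) -> Path:
    """Materialize a synthetic target library on disk for the CLI.

    Layout: ``ligand.sdf``, per-target ``<id>_receptor.mol2`` and
    ``<id>_ref.sdf``, an annotation TSV, and a ``library.tsv`` manifest with
    columns target_id / receptor / ref_ligand.  Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if ligand is None:
        ligand = make_toy_ligand(8, with_symmetry=False, seed=seed)
    entries, annotation = make_target_library(ligand, n_targets, seed=seed,
                                              n_known=n_known)
    write_molecule(ligand, out_dir / "ligand.sdf", "sdf")
    lines = ["target_id\treceptor\tref_ligand"]
    for entry in entries:
        rec = f"{entry.target_id}_receptor.mol2"
        ref = f"{entry.target_id}_ref.sdf"
        write_molecule(entry.receptor, out_dir / rec, "mol2")
        write_molecule(entry.ref_ligand, out_dir / ref, "sdf")
        lines.append(f"{entry.target_id}\t{rec}\t{ref}")
    (out_dir / "library.tsv").write_text("\n".join(lines) + "\n")
    (out_dir / "annotations.tsv").write_text("".join(
        f"{annotation.ligand_id}\t{t}\n" for t in sorted(annotation.known_target_ids)))
    return out_dir / "library.tsv"
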
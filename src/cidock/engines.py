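"""Docking-engine adapters and the deterministic mock engine.

The pipeline is engine-agnostic: each engine contributes a scored pose
ensemble through :class:`EngineConfig` / :func:`run_engine`, and the adapter
normalizes scores to lower-is-better.  Three common output dialects are
supported as parsers over recorded output files (Vina-style PDBQT with
``REMARK VINA RESULT`` lines, PLANTS-style MOL2 plus ranking CSV,
LeDock-style ``.dok``), so real runs can be ingested without re-executing
the engine.  No docking search algorithm is implemented here.

The mock engine makes the pipeline runnable end-to-end offline: it places a
fraction of poses in a shared "binding funnel" at the active-site box center
(one orientation, small jitter, good scores) and scatters the rest uniformly
through the box with worse scores — a caricature of how real engines
concentrate sampling on favourable sites, and exactly the structure the
cluster-vote consensus needs to be exercised.
"""

from __future__ import annotations

import shutil
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigError,
    EngineEnvironmentError,
    EngineRunError,
    FormatError,
)
from .geometry import BoxSpec
from .molecules import (
    Molecule,
    Pose,
    PoseEnsemble,
    read_pose_ensemble,
    write_pose_ensemble,
)

DEFAULT_ENGINE_IDS = ("LEDOCK", "PSOVina", "Vina", "PLANTS")


@dataclass
class EngineConfig:
    """How to obtain one engine's pose ensemble."""

    engine_id: str
    executable: str = "mock"
    n_poses: int = 100
    score_polarity: str = "lower_better"
    extra: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_poses < 1:
            raise ConfigError(f"engine {self.engine_id!r}: n_poses must be >= 1")
        if self.score_polarity not in ("lower_better", "higher_better"):
            raise ConfigError(
                f"engine {self.engine_id!r}: unknown score polarity "
                f"{self.score_polarity!r}")


def stable_seed(*parts: object) -> int:
    """Deterministic sub-seed below 2^31 derived from arbitrary labels."""
    text = "|".join(str(p) for p in parts)
    return zlib.crc32(text.encode()) % (2 ** 31)


# ---------------------------------------------------------------------------
# mock engine
# ---------------------------------------------------------------------------

def _fit_shift(coords: np.ndarray, box: BoxSpec) -> np.ndarray:
    """Minimal per-axis translation bringing all coordinates inside the box."""
    shift = np.zeros(3)
    lo, hi = box.lo, box.hi
    cmin, cmax = coords.min(axis=0), coords.max(axis=0)
    for ax in range(3):
        if cmax[ax] - cmin[ax] > hi[ax] - lo[ax]:
            # ligand larger than the box along this axis: center it
            shift[ax] = (lo[ax] + hi[ax]) / 2 - (cmin[ax] + cmax[ax]) / 2
        elif cmin[ax] < lo[ax]:
            shift[ax] = lo[ax] - cmin[ax]
        elif cmax[ax] > hi[ax]:
            shift[ax] = hi[ax] - cmax[ax]
    return coords + shift


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def mock_dock(cfg: EngineConfig, ligand: Molecule, box: BoxSpec,
              *, ligand_id: str | None = None, target_id: str = "",
              site_fraction: float = 0.5, site_jitter: float = 0.4,
              ) -> PoseEnsemble:
    """Generate a pseudo-random but fully seeded pose ensemble inside the box.

    ``round(site_fraction * n_poses)`` poses land in the funnel at the box
    center (ligand's input orientation, Gaussian jitter of ``site_jitter`` Å,
    scores drawn from a better band); the remainder are uniformly placed and
    randomly oriented decoys with worse scores.  Output depends only on
    (seed, ligand, box, n_poses).
    """
    template = ligand.strip_hydrogens()
    rng = np.random.default_rng(stable_seed(cfg.seed, "mock-engine"))
    base = template.coords - template.coords.mean(axis=0)
    n_site = int(round(site_fraction * cfg.n_poses))
    center = np.asarray(box.center)
    lo, hi = box.lo, box.hi

    poses: list[Pose] = []
    for k in range(cfg.n_poses):
        if k < n_site:
            coords = base + center + rng.normal(scale=site_jitter, size=(1, 3)) \
                + rng.normal(scale=0.1, size=base.shape)
            raw = -(8.0 + rng.uniform(0.0, 1.0))
        else:
            rot = _random_rotation(rng)
            centroid = rng.uniform(lo, hi)
            coords = base @ rot.T + centroid + rng.normal(scale=0.1, size=base.shape)
            raw = -(3.0 + rng.uniform(0.0, 3.0))
        coords = _fit_shift(coords, box)
        poses.append(Pose(template.with_coords(coords, name=f"{cfg.engine_id}:{k}"),
                          cfg.engine_id, float(raw), k))
    return PoseEnsemble(ligand_id or ligand.name, target_id, cfg.engine_id, poses,
                        max_poses=cfg.n_poses)


# ---------------------------------------------------------------------------
# recorded-output parsers (real-engine dialects)
# ---------------------------------------------------------------------------

def parse_vina_pdbqt(path: str | Path, engine_id: str, ligand: Molecule,
                     **kwargs) -> PoseEnsemble:
    """Vina/PSOVina-style multi-model PDBQT with REMARK VINA RESULT scores."""
    return read_pose_ensemble(path, "pdbqt", engine_id, ligand, **kwargs)


def parse_plants_output(mol2_path: str | Path, ranking_csv: str | Path,
                        engine_id: str, ligand: Molecule, **kwargs) -> PoseEnsemble:
    """PLANTS-style multi-molecule MOL2 plus ranking CSV (TOTAL_SCORE)."""
    df = pd.read_csv(ranking_csv)
    name_col = "LIGAND_ENTRY" if "LIGAND_ENTRY" in df.columns else df.columns[0]
    score_col = "TOTAL_SCORE" if "TOTAL_SCORE" in df.columns else df.columns[1]
    sidecar = Path(mol2_path).with_suffix(".scores.tmp")
    try:
        sidecar.write_text("".join(
            f"{row[name_col]}\t{row[score_col]}\n" for _, row in df.iterrows()))
        return read_pose_ensemble(mol2_path, "mol2", engine_id, ligand,
                                  score_table=sidecar, **kwargs)
    finally:
        sidecar.unlink(missing_ok=True)


def parse_ledock_dok(path: str | Path, engine_id: str, ligand: Molecule,
                     *, ligand_id: str | None = None, target_id: str = "",
                     max_poses: int = 100) -> PoseEnsemble:
    """LeDock-style .dok: PDB-like models separated by END, score in the
    'REMARK Cluster' header line ('Score: <x> kcal/mol')."""
    path = Path(path)
    template = ligand.strip_hydrogens()
    poses: list[Pose] = []
    cur: list[tuple[str, float, float, float]] = []
    score: float | None = None

    def flush(model_no: int) -> None:
        nonlocal cur, score
        if not cur:
            return
        elements = [a[0] for a in cur]
        if [e for e in elements if e != "H"] != template.elements:
            raise FormatError(f"{path}: model {model_no} does not match ligand topology")
        coords = np.array([a[1:] for a in cur])
        heavy = [i for i, e in enumerate(elements) if e != "H"]
        if score is None:
            raise FormatError(f"{path}: model {model_no} has no Score remark")
        poses.append(Pose(template.with_coords(coords[heavy],
                                               name=f"{engine_id}:{len(poses)}"),
                          engine_id, float(score), len(poses)))
        cur, score = [], None

    model_no = 0
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        if raw.startswith("REMARK Cluster"):
            model_no += 1
            if "Score" in raw:
                try:
                    score = float(raw.split("Score")[1].replace(":", "").split()[0])
                except (IndexError, ValueError) as exc:
                    raise FormatError(f"{path}:{ln}: malformed Score remark") from exc
        elif raw[:6].strip() in ("ATOM", "HETATM"):
            name = raw[12:16].strip()
            sym = "".join(ch for ch in name if ch.isalpha())[:2]
            sym = sym[0].upper() + sym[1:].lower()
            if sym not in ("Cl", "Br"):
                sym = sym[:1]
            cur.append((sym, float(raw[30:38]), float(raw[38:46]), float(raw[46:54])))
        elif raw.strip() == "END":
            flush(model_no)
    flush(model_no)
    if not poses:
        raise FormatError(f"{path}: no poses found in .dok file")
    return PoseEnsemble(ligand_id or ligand.name, target_id, engine_id, poses,
                        max_poses=max(max_poses, len(poses)))


# ---------------------------------------------------------------------------
# run orchestration
# ---------------------------------------------------------------------------

def run_engine(cfg: EngineConfig, ligand: Molecule, receptor: Molecule,
               box: BoxSpec, *, run_dir: str | Path | None = None,
               ligand_id: str | None = None, target_id: str = "") -> PoseEnsemble:
    """Produce one engine's pose ensemble.

    ``executable == "mock"`` runs the built-in mock engine.  A recorded real
    run is ingested when ``cfg.extra`` carries ``recorded_output`` (plus
    ``output_format`` ∈ {pdbqt, mol2, sdf} and, for PLANTS-style output,
    ``ranking_csv``).  Anything else requires the external executable, which
    this environment does not ship.
    """
    if cfg.executable == "mock":
        ensemble = mock_dock(cfg, ligand, box, ligand_id=ligand_id, target_id=target_id)
    elif "recorded_output" in cfg.extra:
        fmt = cfg.extra.get("output_format", "pdbqt")
        recorded = cfg.extra["recorded_output"]
        polarity = cfg.score_polarity
        if fmt == "pdbqt":
            ensemble = parse_vina_pdbqt(recorded, cfg.engine_id, ligand,
                                        ligand_id=ligand_id, target_id=target_id,
                                        score_polarity=polarity)
        elif fmt == "mol2":
            ensemble = parse_plants_output(recorded, cfg.extra["ranking_csv"],
                                           cfg.engine_id, ligand,
                                           ligand_id=ligand_id, target_id=target_id,
                                           score_polarity=polarity)
        elif fmt == "dok":
            ensemble = parse_ledock_dok(recorded, cfg.engine_id, ligand,
                                        ligand_id=ligand_id, target_id=target_id)
        elif fmt == "sdf":
            ensemble = read_pose_ensemble(recorded, "sdf", cfg.engine_id, ligand,
                                          ligand_id=ligand_id, target_id=target_id,
                                          score_polarity=polarity)
        else:
            raise ConfigError(f"engine {cfg.engine_id!r}: unknown output format {fmt!r}")
    else:
        if shutil.which(cfg.executable) is None:
            raise EngineEnvironmentError(
                f"engine {cfg.engine_id!r}: executable {cfg.executable!r} not found. "
                "Install the docking program and put it on PATH, point 'executable' "
                "at its location, supply a recorded output via extra['recorded_output'], "
                "or use executable='mock' for the built-in engine.")
        raise EngineEnvironmentError(
            f"engine {cfg.engine_id!r}: direct invocation of external binaries is not "
            "implemented; run the engine yourself and ingest its output via "
            "extra['recorded_output'].")
    if len(ensemble.poses) == 0:
        raise EngineRunError(f"engine {cfg.engine_id!r} produced no poses")
    if len(ensemble.poses) > cfg.n_poses:
        ensemble.poses = ensemble.poses[:cfg.n_poses]
    if run_dir is not None:
        run_dir = Path(run_dir)
        run_dir.mkdir(parents=True, exist_ok=True)
        write_pose_ensemble(ensemble, run_dir / f"{cfg.engine_id}_poses.sdf", "sdf")
    return ensemble


def run_engine_panel(cfgs: Sequence[EngineConfig], ligand: Molecule,
                     receptor: Molecule, box: BoxSpec, *, strict: bool = False,
                     run_dir: str | Path | None = None,
                     ligand_id: str | None = None, target_id: str = "",
                     ) -> tuple[dict[str, PoseEnsemble], dict[str, Exception]]:
    """Run every configured engine; returns (ensembles, failures).

    Lenient by default: individual engine failures are recorded and the run
    proceeds as long as one engine succeeds.  ``strict`` aborts on the first
    failure.  All engines failing is always an error.
    """
    if not cfgs:
        raise ConfigError("engine panel is empty")
    ids = [c.engine_id for c in cfgs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ConfigError(f"duplicate engine ids in panel: {dupes}")
    ensembles: dict[str, PoseEnsemble] = {}
    failures: dict[str, Exception] = {}
    for cfg in cfgs:
        try:
            ensembles[cfg.engine_id] = run_engine(
                cfg, ligand, receptor, box, run_dir=run_dir,
                ligand_id=ligand_id, target_id=target_id)
        except Exception as exc:  # noqa: BLE001 — surfaced to the caller
            if strict:
                raise
            failures[cfg.engine_id] = exc
    if not ensembles:
        details = "; ".join(f"{k}: {v}" for k, v in failures.items())
        raise EngineRunError(f"all engines failed: {details}")
    return ensembles, failures


def default_engine_panel(n_engines: int = 4, n_poses: int = 100,
                         seed: int = 0) -> list[EngineConfig]:
    """Mock-engine panel named after the four-engine consensus protocol."""
    if not 1 <= n_engines <= len(DEFAULT_ENGINE_IDS):
        raise ConfigError(f"n_engines must be in 1..{len(DEFAULT_ENGINE_IDS)}")
    return [EngineConfig(engine_id=eid, executable="mock", n_poses=n_poses,
                         seed=stable_seed(seed, eid))
            for eid in DEFAULT_ENGINE_IDS[:n_engines]]
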
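# Methods

## Problem setting

Inverse docking ranks the targets of a protein library by a ligand's
predicted binding affinity. Its weakest link is pose selection: a single
docking program's top-scored pose is wrong often enough that downstream
affinity estimates inherit the error. The consensus cluster-vote strategy
treats several docking engines as independent voters: a binding mode that
several engines rediscover is more trustworthy than any single engine's
best score. `cidock` implements that consensus layer, the rescoring of the
chosen pose, and the statistics used to evaluate a target-fishing screen,
all behind engine-agnostic interfaces.

## Pose geometry

**RMSD.** Pose similarity is in-place heavy-atom RMSD — no least-squares
superposition — because what matters is where the ligand sits in the
receptor frame; the 2.0 Å similarity criterion is meaningless after
fitting. Hydrogens never enter the RMSD (or any scoring term), so pose
ensembles are standardized to the ligand's heavy-atom topology at read
time.

**Symmetry.** Topologically symmetric ligands admit several equally valid
atom correspondences. By default the RMSD is minimized over the
automorphisms of the heavy-atom graph (elements and bond orders preserved),
enumerated with networkx's VF2 matcher. Enumeration is capped at 10,000
mappings; past the cap the identity mapping is used with a warning, so
pathological topologies degrade to plain atom-order RMSD instead of
stalling. Both modes are exposed — `symmetry_aware=False` reproduces naive
atom-order RMSD, which over-penalizes symmetric ligands.

**Active-site box.** The box is the reference bound-ligand's heavy-atom
bounding box expanded by a per-face margin, 12.5 Å by default, axis-aligned
in the receptor frame. It serializes to the center+size key-value block
docking engines conventionally accept.

## Clustering and voting

**Leader clustering, best-score-first.** The similarity rule ("same cluster
if RMSD below threshold") does not by itself fix an algorithm: single-linkage
and leader clustering differ on chains of poses. We use leader clustering
with a best-score-first visit order (ties by pose index): deterministic,
O(n·k), and anchored on the same best-score notion that defines cluster
representatives — with this visit order every cluster's leader *is* its
best-scoring member. The threshold is strict (`RMSD < 2.0 Å`; a pose at
exactly the threshold founds a new cluster). Oracle tests use
well-separated planted sites, where all reasonable clustering rules
coincide with connected components.

**Votes.** A single-engine cluster's vote equals its pose count; votes are
conserved (cluster votes sum to the ensemble size) and clusters partition
the ensemble — both are asserted as properties. Cross-engine candidates
count *distinct engines*, not representatives, so one engine contributing
two representatives to the same consensus cluster still adds one engine
vote; its pose counts still enter the total pose support. The pooled
representatives are visited in (single-engine vote desc, engine id, pose
index) order — deterministic without ever comparing raw scores across
engines.

**Selection cascade.** Candidates are ordered by engine votes, then total
pose support, then representative score, then lexicographic pose id. The
`tie_broken` flag records that the winner tied on engine votes and needed
the deeper cascade. Score polarity is normalized per engine (lower is
better) at ensemble construction, so "best score" is well defined within an
engine; cross-engine comparisons are confined to the third cascade level,
where some total order is unavoidable.

## Empirical rescoring

The consensus pose is scored with the additive decomposition
ΔG_bind = ΔG_vdw + ΔG_H-bond + ΔG_deformation + ΔG_hydrophobic + ΔG_0.
Each term is computed from receptor-ligand heavy-atom geometry:

| term | form | default |
|---|---|---|
| van der Waals | soft 8-4 well, depth −1 at r₀ = sum of vdW radii, pairs within cutoff | weight 0.30 kcal/mol, cutoff 8 Å |
| H-bond | count of N/O–N/O pairs within distance gate whose heavy-neighbour angle opens past the gate | weight −1.20 kcal/mol per bond, 3.5 Å / 120° |
| deformation | ligand rotatable-bond count × rotor penalty | +0.35 kcal/mol per rotor |
| hydrophobic | count of C–C contacts within cutoff | weight −0.08 kcal/mol, 4.5 Å |
| ΔG₀ | regression constant | −1.50 kcal/mol |

The defaults were chosen once to give drug-like magnitudes (a well-packed
pose scores roughly −5 to −30 kcal/mol); no numeric equivalence with any
published scoring program is claimed, and every coefficient and gate lives
in `ScoringCoefficients`. The contract enforced by construction is the
decomposition identity (to 1e-9) and the geometric gating: terms vanish
beyond their cutoffs, the rotor term scales exactly linearly in its weight,
one additional geometrically valid H-bond changes ΔG_H-bond by exactly one
weight quantum, and the whole score is invariant under joint rigid motion
of receptor and pose. Atoms without recorded neighbours (receptors read
without CONECT records) pass the H-bond angle gate by default — the gate
cannot be evaluated without bonded geometry.

The rotatable-bond definition is the common cheminformatics convention:
acyclic single non-amide bonds between heavy atoms that each carry ≥ 2
heavy neighbours (ring bonds found as non-bridges of the heavy graph).

**External energies.** MM/PBSA-style calculations are out of scope by
design; the `ExternalEnergyRecord` adapter ingests a tab-separated table of
ΔE_bind, TΔS_sol, TΔS_conf (identity ΔG = ΔE − TΔS_sol − TΔS_conf enforced;
a stated total deviating by more than 1e-6 rejects the row). Empirical and
external schemes are never fused — `rank_energy` demands exactly one.

## Screening and evaluation

Per-target engine seeds derive from (engine seed, target id), so screen
results are independent of library order. Targets whose whole engine panel
failed are reported unranked and excluded from N (lenient mode is the
default; strict mode aborts). Energy ties across targets break by higher
engine votes then target id.

Top-k% membership uses the floor convention, rank ≤ ⌊k/100·N⌋ — "within
the best k% of positions". At library sizes in the hundreds the convention
is immaterial; at toy sizes it is not, which is why it is fixed and tested.
Binarizing at the cutoff gives TP/FP/TN/FN (known targets are positives).
The AUC is computed by the rank-sum formulation — the probability that a
random known target has the lower energy, ties at one half — which equals
the trapezoidal area under the ROC swept over all rank thresholds; both
the single-threshold confusion matrix and the threshold-swept AUC are
reported so either reading is available. Per-drug success rates (share of
drugs with ≥ 1 known target recovered) round half-up to two decimals;
pooled TOP percentages (share of all known targets recovered) round
half-up to integers; per-drug AUCs are macro-averaged for panel summaries,
with pooled counts reported alongside.

## Synthetic data and the mock engine

The generators are pure functions of (spec, seed) and return planted truth
alongside the data, so tests assert recovery rather than re-deriving it.

* **Toy ligands** are connected chains (end-labelled with one nitrogen so
  the automorphism group is trivial) or aromatic six-rings with optional
  tails (non-trivial group), with small coordinate jitter.
* **Pose ensembles** place the rigidly translated ligand at site centers
  ≥ 3× the cluster threshold apart, plus isotropic Gaussian offsets
  (default sd 0.3 Å). Scores come from disjoint uniform bands so the
  globally largest site always holds the best score — the structure the
  vote strategy assumes. Gaussian jitter keeps intra-site RMSDs analytic:
  two poses with offsets δ₁, δ₂ ~ N(0, σ²I₃) differ by |δ₁−δ₂|, far below
  the threshold at the default σ.
* **Score libraries** draw background energies from N(0, σ) and
  known-target energies from N(−δ, σ), giving the closed-form expected
  AUC Φ(δ/(√2 σ)) as an analytic oracle.
* **Geometric target libraries** give each planted (known) target a carbon
  cage at ideal contact distance (ligand radius + 4 Å) around its site and
  push decoy cages 20–30 Å outward, past every interaction cutoff; planted
  targets thus rescore strongly negative and decoys score the ligand-only
  baseline.
* The **mock engine** concentrates half of its poses in a "funnel" at the
  box center (shared orientation, 0.4 Å jitter, scores in a better band)
  and scatters the rest uniformly with worse scores — a caricature of how
  real engines oversample favourable sites. Output is bit-reproducible from
  (seed, ligand, box, pose count), and every heavy atom stays inside the
  box.

What the synthetic data deliberately does **not** emulate: conformational
(torsional) pose diversity, receptor flexibility, realistic score-RMSD
correlation within a site, chemically meaningful receptors, or engine
failure modes. Passing tests therefore demonstrate the correctness of the
clustering, voting, rescoring and evaluation machinery under the planted
statistical structure — not docking accuracy on real complexes, which
requires real engines and real structures through the adapter interfaces.

## Numerical choices and degenerate inputs

* Clustering visits and all tie-breaks are total orders → bitwise
  deterministic results; permuting input pose or library order never
  changes an outcome (tested).
* The 8-4 contact is clamped below 0.4·r₀ to keep clash energies finite.
* Empty ensembles, empty libraries, single-class AUC inputs, zero-margin
  boxes and non-finite coordinates are rejected with typed errors rather
  than propagating NaNs.
* Sub-seeds are derived from labels by CRC-32 (kept below 2³¹), so adding
  a target or engine never shifts another's random stream.

## Scale of the shipped checks

The test suite and acceptance script run the pipeline at deliberately
modest sizes — ensembles of 12–30 poses, libraries of 12–500 targets,
100-trial recovery loops, a 20-target end-to-end screen with 4 × 100
poses — sizes at which every oracle (exhaustive permutation, all-pairs
AUC, connected components) is exact and the whole suite completes in
seconds. All sizes are parameters; nothing in the implementation is
specific to them.

## Known limitations

* No docking search is implemented; real engines are integrated only via
  recorded-output parsers (Vina-style PDBQT, PLANTS-style MOL2+CSV,
  LeDock-style .dok) or the adapter contract.
* Structure preparation (protonation, charges, minimization) is out of
  scope; inputs are taken as given.
* The empirical scorer is a transparent stand-in of the classic additive
  form, suitable for ranking within this pipeline's assumptions; it is not
  calibrated against experimental affinities.
* Weighted voting, score fusion and rank-by-rank consensus variants are
  intentionally excluded.
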
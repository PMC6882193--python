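# cidock — consensus inverse docking

`cidock` is a toolkit for **inverse docking** (target fishing): given one
small molecule and a library of protein targets, rank the targets by how
strongly the molecule is predicted to bind each of them. It implements the
**consensus cluster-vote strategy** for pose selection — combining the pose
ensembles of several independent docking engines — together with empirical
rescoring, target ranking, and the enrichment statistics used to judge
target-fishing performance (top-k% recovery, ROC/AUC, per-drug success
rates). It is aimed at computational chemists building drug-repurposing or
off-target screens who want an engine-agnostic, fully testable consensus
layer rather than another docking program.

## The cluster-vote consensus

For one ligand–target pair, each docking engine *e* contributes an ensemble
of scored poses. Consensus proceeds in two levels:

1. **Within-engine clustering.** Poses are leader-clustered on in-place
   (no-superposition) heavy-atom RMSD: visiting poses best-score-first, a
   pose joins the first cluster whose founding pose is within the threshold
   (RMSD < 2.0 Å, strict), else it founds a new cluster. A cluster's
   *vote* is its pose count; its *representative* is its best-scoring
   member. RMSD is symmetry-aware by default: it is minimized over the
   automorphisms of the heavy-atom molecular graph, so a flipped benzene
   ring is not penalized.

2. **Cross-engine voting.** All representatives are pooled and clustered by
   the same rule. A consensus cluster earns one *engine vote* per distinct
   engine contributing a representative — four agreeing engines make a
   4-vote cluster. Ties on engine votes are judged by *total pose support*
   (the sum of the contributing single-engine votes), then representative
   score, then pose id, so selection is deterministic. Raw scores are never
   compared across engines.

The winning cluster's representative is the **consensus pose**; it is
rescored with an additive empirical free-energy decomposition

ΔG_bind = ΔG_vdw + ΔG_H-bond + ΔG_deformation + ΔG_hydrophobic + ΔG_0

(soft 8-4 contact term, gated H-bond count, rotor penalty, C–C contact
term, regression constant; all coefficients configurable), or with
externally computed MM/PBSA-style energies ΔG_bind = ΔE_bind − TΔS_sol −
TΔS_conf ingested from a validated table. Ranking all targets by ΔG_bind
ascending gives the screen result; a known target counts as recovered at
level *k* when its rank is within the best k% of positions
(rank ≤ ⌊k/100·N⌋).

A deterministic **mock engine** and seeded synthetic generators (toy
ligands, pose ensembles with planted cluster structure, score libraries
with planted enrichment) make every stage runnable and testable without any
docking software. Recorded output of real engines can be ingested through
the Vina-PDBQT, PLANTS-MOL2+CSV and LeDock-`.dok` dialect parsers.

## Worked example

Generate a 20-target synthetic library with 2 planted strong binders, then
screen it with a 4-engine mock panel, 100 poses per engine:

```
$ cidock synth-library --out demo/lib --n-targets 20 --n-known 2 --seed 7
wrote 20-target synthetic library manifest: demo/lib/library.tsv

$ cidock screen --ligand demo/lib/ligand.sdf --library demo/lib \
    --engines mock:4 --n-poses 100 --seed 7 \
    --annotations demo/lib/annotations.tsv --out demo/run
screened 20 targets (0 failed); top 10%: T0003, T0018
AUC 1.000; top 2%: TP=0; top 5%: TP=1; top 10%: TP=2

$ head -6 demo/run/ranking.tsv
rank	target_id	dG_bind	engine_votes	tie_broken
1	T0003	-8.0701	4	False
2	T0018	-7.9665	4	False
3	T0000	0.2500	4	False
4	T0001	0.2500	4	False
5	T0002	0.2500	4	False
```

The two planted binders (T0003, T0018) rank first with strongly negative
ΔG_bind — their receptors surround the docked ligand with favourable
contacts — while the 18 decoy receptors sit beyond the interaction cutoffs
and all score the ligand-only baseline (rotor penalty + constant =
0.25 kcal/mol). Every target's consensus pose was supported by all four
engines (`engine_votes` 4), and the evaluation report confirms both known
targets are recovered in the top 10% (TP=2) with AUC 1.000. `--top 10`
membership follows the floor convention: ⌊10/100·20⌋ = 2 targets.

`cidock dock` runs a single ligand-receptor pair and writes the consensus
pose plus a cluster report; `cidock evaluate` recomputes the statistics
from a saved ranking table.

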
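# vinascreen

Automated orchestration for **blind virtual screening**: dock a library of
small-molecule drugs against a panel of protein receptors without assuming
any binding pocket, then mine the resulting energy matrix for unusually
strong receptor–ligand pairs and cross-check them against a table of known
drug–target interactions. The intended users are computational
drug-repurposing groups running AutoDock Vina campaigns over AlphaFold
structure models on a cluster — and anyone who needs the full analysis
chain testable offline, which the built-in deterministic mock docking
backend and synthetic fixture generators provide.

## What it does

1. **Receptor preparation** — AlphaFold PDB models carry the per-residue
   confidence pLDDT (0–100) in the temperature-factor column; residues with
   pLDDT < 70 are removed, partial charges and AutoDock atom types are
   assigned, and the structure is written as rigid-body PDBQT. The docking
   search box is the bounding box of the trimmed structure plus a margin
   (default 10 Å), so the whole receptor surface is scanned.
2. **Ligand preparation** — SDF V2000 ligands get iterative
   Gasteiger–Marsili (PEOE) partial charges, rotatable-bond detection by
   the AutoDock rules, and a rigid-fragment torsion tree, serialized as
   flexible PDBQT (`ROOT`/`BRANCH`/`TORSDOF`).
3. **Docking orchestration** — every (receptor, ligand) pair is docked in
   triplicate with distinct persisted seeds (`exhaustiveness = 9` by
   default); jobs flow through a claim/ack work queue with zero-byte
   `.done` checkpoint markers, so interrupted campaigns resume exactly and
   the result is independent of worker count.
4. **Aggregation** — the best (lowest) energy per pair across replicates
   forms the matrix `M = {m_ij}` (receptors × ligands, kcal/mol), with
   per-cell provenance.
5. **Dual outlier detection** — per-receptor Z-score,
   `Z_ij = (m_ij − μ_i)/σ_i`, flags pairs with `Z_ij ≤ −1.541`; per-receptor
   MinMax, `(m_ij − min_i)/(max_i − min_i)`, flags the pooled bottom 5 %.
6. **Cross-validation** — flagged pairs are labeled 1/0 by membership in a
   known-interaction TSV (DrugCentral `drug.target.interaction.tsv`
   schema); the strongest *known* energy and MinMax values become
   thresholds, and label-0 pairs strictly beyond them are the prioritized
   novel candidates.

## Worked example

```sh
vinascreen simulate --out-dir demo --receptors 3 --ligands 20 \
    --known 3 --novel 2 --seed 5
vinascreen run --config demo/config.yaml
```

This materializes a miniature synthetic study (3 receptors × 20 ligands,
3 pairs planted as documented binders at −12 kcal/mol, 2 planted novel
binders at −14 kcal/mol) and runs the full pipeline with the mock backend.
The printed summary:

```
"total_pairs": 60,
"known_pairs_in_matrix": 13,
"flagged_zscore": 5,
"flagged_minmax": 3,
"flagged_union": 5,
"flagged_both": 3,
"known_flagged_zscore": 3,
"known_flag_rate_zscore": "23.08%",
"energy_threshold_kcal_mol": "-12.219",
"novel_below_energy_threshold": 2,
```

Reading it: of the 60 receptor–ligand pairs, 5 were flagged by at least one
normalization; the 3 planted known binders were all recovered
(`known_flagged_zscore: 3`), the strongest of them (−12.219 kcal/mol)
became the evidence threshold, and exactly the 2 planted novel binders
scored below it (`novel_below_energy_threshold: 2`). Full tables land in
`demo/work/reports/` (`candidates.csv`, `top_known.csv`, `top_novel.csv`,
`summary.tsv`) and the energy matrix in `demo/work/matrix/`.

Re-running `vinascreen run` after an interruption continues from the
`.done` markers; `vinascreen status --config demo/config.yaml` shows
progress.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the pipeline's results from scratch at two scales: a miniature
fully-prepared study (structures generated, trimmed, charged, docked with
the mock backend) and a 20 × 500 screening campaign on the planted mock
landscape (triplicate seeded jobs, aggregation, dual selection,
cross-validation), printing the report summary to stderr and writing the
target JSON to `--out`.
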
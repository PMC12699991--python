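# Methods

## Problem setting

Blind docking screens a drug library against whole receptor surfaces with
no pocket prior. That makes the raw score distribution receptor-specific
(surface area, cavity depth and size shift the whole energy scale), so
candidate selection must normalize per receptor before comparing pairs.
This package implements the orchestration and analysis around a docking
engine: the engine's conformational search and scoring function are
deliberately out of scope and are reached through a backend interface — an
external AutoDock Vina executable in production, a deterministic mock in
tests.

## Receptor preparation

AlphaFold models store the per-residue confidence pLDDT (0–100) in the PDB
temperature-factor column, one identical value per residue. Residues with
pLDDT strictly below the threshold (default 70) are removed; a residue at
exactly 70 is kept. The filter refuses to run unless the run configuration
declares the structures AlphaFold-sourced, so crystal structures are never
silently trimmed by B-factor. Trimming may split a chain into fragments;
no capping or repair is attempted, because the receptor is treated as a
rigid body and only atom positions enter the docking. Mixed temperature
factors within one residue raise an error rather than guessing.

The blind-docking search box is the axis-aligned bounding box of the
trimmed structure: center = midpoint of the per-axis extrema, size =
extent + 2 × margin. The margin defaults to 10 Å — enough for a ligand to
pose against any surface atom — and is configurable; one box over the full
structure realizes whole-surface scanning.

Receptor partial charges use the same PEOE assigner as ligands. The
original workflow's converter (MGLTools) assigns charges without the
documentation naming the model; using one assigner everywhere is this
package's own choice and is configurable in that any pre-assigned charges
are honored by the PDBQT writer.

## Ligand preparation

**Charges.** Iterative partial equalization of orbital electronegativities
(PEOE): electronegativity is a quadratic in the current charge,
χ(q) = a + b·q + c·q², with (a, b, c) tabulated per element and
hybridization; at iteration k charge flows across each bond from the less
to the more electronegative atom, scaled by the donor's cation
electronegativity (20.02 for hydrogen) and damped by (1/2)^k. Six
iterations, the published default, leave residual transfers ~1e-2 e; there
is no convergence-tolerance stop, matching common toolkit behavior. Total
charge is conserved exactly because each transfer is antisymmetric. The
implementation agrees with RDKit's to < 5e-3 e on test molecules (to ~1e-5
in practice).

**Hybridization** is inferred from bond orders: a triple bond or two
doubles → sp; any double or aromatic bond → sp2; otherwise sp3. For
order-less PDB-derived ligands, a documented minimal heuristic marks
six-membered rings of carbon/nitrogen (degree ≤ 3, planar within 0.15 Å)
aromatic; SDF inputs carry their own orders and aromatic flags, which are
always honored.

**Rotatable bonds** follow the AutoDock convention: single order, not in a
ring, both endpoints bonded to another heavy atom, and not an amide C–N
(configurable). The torsion tree contracts the rigid fragments left after
deleting rotatable bonds; the root is the fragment minimizing its largest
branch (atom count), ties broken toward the lowest atom index, so the
PDBQT `ROOT` block holds a central fragment and `TORSDOF` equals the
rotatable-bond count.

**Bond perception** for PDB ligands uses Cordero (2008) covalent radii:
bonded iff 0.4 Å < d ≤ r_a + r_b + tolerance (default 0.45 Å). Only order
1 is assigned; order perception beyond the ring heuristic above is not
attempted.

## Docking orchestration

Each (receptor, ligand) pair runs in three independent replicates with
distinct seeds to reduce convergence to local minima. Per-job seeds are
derived by hashing (master seed, receptor, ligand, replicate) — a
counter-free splittable scheme — so the seed manifest is reproducible with
no global RNG state, and seeds stay below 2^31. Defaults mirror the
production campaign: exhaustiveness 9, nine CPU cores per job (tracking
the exhaustiveness level, but not coupled to it), nine requested binding
modes.

Jobs are enqueued once; workers atomically claim, execute, and checkpoint.
The `.done` marker is written only after the output file is complete, so
marker presence implies a parseable result and killing workers at any
point loses at most in-flight work. The final matrix is a pure function of
the job set and seeds — independent of worker count, claim order, and
interruptions — which the tests verify bit-for-bit. The in-process queue
ships here; the claim/ack interface is the seam where an external
key-value queue service (as used for cluster-scale runs) plugs in.

An output file with zero result lines is classified `empty` and
distinguished from a failed (nonzero-exit) run; both leave the job
re-queueable and unmarked.

## Aggregation

m_ij = the minimum over the pair's replicate best-pose energies. Pairs
with some failed replicates use the survivors; pairs with none are masked
missing, excluded from row statistics and never flagged, and a fully
missing row or column aborts the run. Ties break toward the lowest
replicate index for provenance only.

## Normalization and selection

* **Z-score** (per receptor row): Z_ij = (m_ij − μ_i)/σ_i with the
  population σ (divisor n; the formula carries no correction, and ddof is
  configurable). Pairs with Z_ij ≤ −1.541 are flagged, the inclusive
  boundary matching the stated cutoff. Note −1.541 corresponds to the
  lowest ~6.2 % of a standard normal; the exact 5th percentile would be
  −1.645. The operational default keeps −1.541; both are configurable.
* **MinMax** (per receptor row): (m_ij − min_i)/(max_i − min_i) ∈ [0, 1].
  The bottom 5 % is read as a pooled matrix-wide empirical quantile (ties
  at the cutoff included), which reproduces selection counts of ≈ 5 % of
  all pairs; a per-row variant is available.
* Zero-variance (or zero-range) rows are degenerate: their cells cannot be
  ranked and are excluded from both selections.

Both scales are invariant under positive affine maps of a row, so the two
selectors agree on matrices whose rows are affine copies of one another;
they diverge on narrow-range rows, where a cell can sit at MinMax ≈ 0 yet
carry a mild Z — both behaviors are exercised in the tests.

Score distributions are summarized by a histogram with a
maximum-likelihood normal fit (sample mean, population sd) and the
empirical 5th-percentile marker; MLE was chosen over least-squares on bin
counts as the standard estimator.

## Cross-validation and prioritization

Flagged pairs are labeled 1 when (target accession, drug identifier)
appears in the reference interaction table, 0 otherwise. Matching is
case-insensitive after whitespace normalization; because public
interaction tables do not always carry the library's drug-identifier
scheme, an optional mapping file translates the drug column, falling back
to name equality. The lowest raw energy and lowest MinMax among *flagged
known* pairs become thresholds (option: all known pairs), and label-0
pairs strictly below them form the two novel-priority lists. The known
pair defining a threshold can never enter a novel list (it is label 1),
and a pair exactly at the threshold is excluded ("even lower than").

## The synthetic world

The mock landscape states: per-receptor base energies N(−7, 1) kcal/mol —
a realistic center and spread for small-molecule docking scores — with
replicate noise sd 0.2 kcal/mol, ten planted known pairs at shift −5
(≈ −12 kcal/mol, the strength of a documented strong binder) and five
planted novel pairs at shift −7 (≈ −14 kcal/mol). A planted pair's energy
is defined as receptor mean + shift + replicate noise: the stochastic base
draw is overridden so the planted affinity is exact ground truth. (Adding
shifts to random draws instead would let the order statistics of the known
and novel groups overlap in most realizations, destroying the planted
known/novel separation the fixtures exist to provide.)

What a green end-to-end test establishes: the orchestration, aggregation,
normalization, selection, labeling and thresholding chain recovers planted
signal exactly and deterministically. What it does not establish: anything
about docking accuracy — the mock emits no physics, receptor fixtures are
schematic backbone traces, and ligand fixtures are templates chosen for
their torsion topology.

**Known structural limit of MinMax novel-list recovery.** Every receptor
row's minimum cell has MinMax exactly 0. If any flagged known pair is its
row's minimum, the MinMax threshold is 0 and the novel-by-MinMax list is
empty; if none is, every undocumented row minimum (MinMax 0) enters the
list. With planted pairs in only a subset of rows, the list therefore can
never equal exactly the planted novel set; the raw-energy list does not
share this degeneracy and recovers the planted novel pairs exactly. One
acceptance test asserts the MinMax-recovery form regardless and is
expected to fail; it is kept as documentation of this property rather than
weakened.

## Numerical choices and degenerate inputs

* PDB/PDBQT writers are column-exact; coordinates round-trip at 3
  decimals, charges at 3 decimals (`%6.3f`).
* Energy parsing accepts any decimal precision.
* Quantiles use linear interpolation (numpy default); selection includes
  ties at the cutoff.
* Bond perception refuses unknown elements by name; charge assignment
  refuses missing PEOE parameters by atom.
* Empty structures, empty pose lists, rows with fewer than two values, and
  fractions outside (0, 1) raise typed errors rather than propagating NaN.

## Known limitations

* No protonation, tautomer, or conformer handling; input hydrogens are
  used as-is.
* Aromaticity perception for order-less inputs is limited to the 6-ring
  heuristic.
* The external-engine backend shells out and reports exit status; it is
  not exercised in CI (no docking engine in the test environment).
* Flexible-receptor docking, mmCIF, SDF V3000 and multi-model NMR files
  are out of scope.
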
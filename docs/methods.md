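# Methods

## Problem and scope

`modelcheck` evaluates candidate structural models of a G-protein-coupled
receptor against a reference structure. It does not build models, dock
ligands, or compute force-field energies: modeling-program quality scores
and per-pose binding energies enter the pipeline as external CSV tables,
and the package's job is everything downstream — superposition and subset
RMSDs, geometric sanity screens, a knowledge-based interaction checklist,
pose triage and consensus selection, affinity/energy conversion, and rank
statistics.

## Superposition and subset RMSDs

Rigid superposition is the Kabsch solution: centroids are removed, the
rotation comes from the SVD of the 3×3 cross-covariance matrix, and the
reflection branch is excluded by flipping the smallest singular vector
when the determinant would be negative. Degenerate inputs (fewer than 3
points, or point sets of rank < 2, i.e. collinear) are rejected rather
than silently resolved. For symmetric point sets with tied singular
values the SVD's own convention breaks the tie; only the minimized RMSD
value is contractual.

Residue correspondence between model and reference is by
(chain, sequence number, insertion code) when the two structures share
numbering — the common case for models built on the target's own
sequence. When that overlap covers less than half of the smaller
structure, correspondence falls back to a global alignment of one-letter
sequences (identity scoring, Biopython's `PairwiseAligner`).

Four RMSD flavors are computed:

- **whole** — Cα atoms of all paired residues (an all-heavy-atom mode is
  available; Cα is the default because it is the conventional
  model-vs-crystal measure).
- **aligned** — the structurally conserved core. A full multiple
  structural alignment is out of scope; instead the core is defined
  operationally: superpose on the current pair set, drop pairs with
  Cα–Cα distance > cutoff (default 3.5 Å), repeat until a fixed point or
  `max_iter` = 10. The pair count is non-increasing, so the procedure
  terminates; the result is deterministic and invariant to any initial
  rigid transform of the model.
- **binding_site** — heavy atoms of the orthosteric-site residues
  (resolved through the Ballesteros–Weinstein map), superposed on those
  same atoms. Atoms are matched by name within paired residues.
- **ligand** — ligand heavy atoms measured under the *binding-site*
  transform, with no re-fit on the ligand. Atom correspondence is by
  fixed ordering; graph-symmetry-aware matching (e.g. for a ligand's two
  equivalent phenyl rings) is a known limitation, making reported ligand
  RMSDs an upper bound for symmetric ligands.

Binding-site RMSD is *not* constrained to be smaller than whole-model
RMSD; both orderings occur in practice and only non-negativity is
asserted.

## Ballesteros–Weinstein numbering

Generic codes ("helix.position") are resolved through a per-receptor
bijective map; the packaged default covers the human M2 muscarinic
receptor: the 10 orthosteric-site residues (2.57 Ser76, 3.46 Trp99,
3.32 Asp103, 3.33 Tyr104, 5.43 Thr187, 5.46 Thr190, 6.51 Tyr403,
6.52 Asn404, 7.39 Tyr426, 7.43 Tyr430) plus the checklist anchors
(2.45 Ser64, 2.50 Asp69, 3.50 Arg121, 6.30 Glu382, 7.49 Asn436).
Author (PDB) numbering is used throughout; nothing is renumbered.

## Hydrogen bonds, salt bridges and the checklist

Hydrogen-bond geometry: with explicit hydrogens, donor–acceptor distance
≤ 3.5 Å and D–H···A angle ≥ 120°; without hydrogens (crystal structures,
most models) a heavy-atom donor–acceptor distance ≤ 3.5 Å. These are
conventional screening criteria, fully configurable; loosening a distance
can only add bonds, so checklist verdicts are monotone in the criteria.

The checklist asks, per conserved interaction, whether any side-chain
hydrogen bond links the pair; for acidic–basic pairs (Asp/Glu vs
Arg/Lys/His) a salt-bridge criterion (side-chain N–O ≤ 4.5 Å) supplements
the hydrogen-bond test, since these interactions are real regardless of
hydrogen placement. If the primary pair fails, the listed alternative
partners are scanned in order and the first hit is reported as
`alternative(partner)`; missing residues yield a distinct `unresolvable`
verdict rather than `absent`. Verdicts are per-pair; aggregating two-pair
interactions into "partial" judgments is left to the caller.

## Ramachandran, cis-peptides, clashes, disulfides

Ramachandran classification uses coarse rectangular region masks per
residue class (general, glycine, proline, pre-proline), shipped as an
editable JSON config rather than density-derived contours: the pipeline
only needs favored/allowed/disallowed counts, and rectangles are
transparent and auditable. Termini and residues flanking a chain break
(Cα–Cα > 4.5 Å) are left unclassified, with a warning.

Cis-peptides: |ω| < 30° preceding a proline. Clashes: non-bonded
heavy-atom pairs closer than 0.6 × the sum of vdW radii (packaged radius
table), excluding intra-residue pairs, peptide-linked neighbor residues
(a coarse stand-in for exact 1-2/1-3 exclusion, adequate for a screen),
detected disulfides and hydrogen-bond partners. Disulfides: SG–SG
≤ 2.5 Å.

## Pose triage and consensus selection

A pose is **good** iff (a) its heavy-atom centroid lies within 8 Å of the
binding-site centroid, (b) a cationic ligand nitrogen (formal charge > 0,
or quaternary by connectivity — no pKa model is attempted) lies within
4.5 Å of the midpoint of the 3.32 carboxylate oxygens, and (c) at least
one ligand O/N sits within hydrogen-bond range of the 6.52 side-chain
amide. Each failed condition is recorded as a reason. The two named
contacts implement the classic two-point muscarinic pharmacophore; both
partners and all distances are configurable.

The **best** pose per ligand/model combines the two rescoring functions:
take the `top_n` (default 10) poses by MM/GBSA-style energy (more
negative = better), then return the one with the highest
binding-energy-function score (more positive = better). Ties break on
pose id, so the choice is content-based and independent of input order.
A score-window variant of the top set is possible by pre-filtering; the
count-based rule is the default.

`kd_to_dG` converts a dissociation constant to a binding free-energy
magnitude, −RT ln(Kd/1 M), with R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹ and
T = 298.15 K by default. Absolute rescoring energies neglect entropic
terms and overshoot experimental values several-fold, so only *relative*
(rank) agreement with experiment is ever evaluated: Spearman rho between
direction-corrected predicted energies of the best poses and experimental
ΔG, with `concordant` meaning exactly rho = 1.

`energy_rmsd_split` reports the Pearson correlation of pose energy vs
pose RMSD on the full pose set and on the near-native subset
(RMSD < 3 Å), because the two rescoring functions are informative in
different regimes; a coefficient with fewer than 3 supporting points is
reported absent, never fabricated.

## Rank statistics

Spearman rho is the Pearson correlation of average-ranked values
(scipy). Rho is computed on raw metric values against raw RMSD values —
not folded by the metric's "better" direction — so the sign of rho
carries the metric's orientation; the direction metadata is reported
alongside for interpretation. Raw two-sided p-values default to the
t-approximation t = ρ√((n−2)/(1−ρ²)) on n−2 df; an exact permutation
method enumerates all n! rank permutations for n ≤ 10 and uses seeded
Monte-Carlo sampling beyond. |ρ| = 1 under the t-approximation is
clamped to the smallest positive float rather than reported as 0. The
metric family is Holm step-down adjusted (statsmodels); the RMSD
self-correlation is not part of the family. Reports carry full precision
with 2-decimal display rounding.

## Synthetic data: what it emulates and what it does not

The generators produce the geometric situations the pipeline must
recognize, with ground truth known by construction:

- **Bundle**: ideal α-helices (φ = −57°, ψ = −47°, ω = 180°, standard
  backbone bond lengths/angles, built by sequential internal-coordinate
  placement) stood on a circle of radius 11 Å around the z axis. The
  default 7-helix layout places the M2-numbered landmark residues in
  ranges chosen so the pocket residues' functional atoms cluster near
  the bundle mid-plane and face the axis, forming a genuine pocket.
  Side chains are minimal: Cβ plus named functional pseudo-atoms
  (carboxylate, amide, hydroxyl, guanidinium tips) for landmark
  residues only. All helices share one chain with sequence gaps; the
  Ramachandran classifier treats the gaps as chain breaks. Construction
  is deterministic; the seed is recorded in metadata.
- **Decoys**: a rigid transform (random axis/direction from the seeded
  generator, prescribed magnitudes) followed by i.i.d. Gaussian noise
  per coordinate, globally or restricted to the binding site or its
  complement. Per-coordinate noise of σ gives an expected superposed
  RMSD of σ√3 (the rigid fit removes 6 of 3N degrees of freedom, a
  < 1 % correction at N = 250), which is the recovery check used in the
  tests. `displace_residues` builds the displaced-loop decoy for the
  structural-core trimming test.
- **Poses**: a rigid 4-atom mock ligand (cationic N, two carbon
  dummies, ester O) placed to satisfy both pharmacophore contacts
  (`correct`), rotated 180° about the vertical pocket axis (`flipped`,
  losing the cation contact), or translated 15 Å out of the site
  (`displaced`), with 0.05 Å seeded jitter.
- **Score tables**: a metric column blended from standardized RMSD
  ranks and Gaussian noise in the ratio ρ : √(1−ρ²); among 32 seeded
  candidate draws the one with realized Spearman rho closest to the
  target is kept (exact at |ρ| = 1, within ±0.1 of the target at
  n ≥ 50).

What passing on synthetic data does **not** show: the bundle has no
loops, no full side-chain rotamers, no membrane, and no physical
energetics, so the tests validate the *decision logic and geometry* of
the pipeline — not its behavior on the messier geometry of real
receptor models, where side-chain placement and loop quality dominate.

## Packaged reference tables

Two quality-metric tables for a published cohort of 12 receptor models
(whole-model and binding-site sub-tables: RMSD plus Prime G-factor,
Prime energy, YASARA Z-score, YASARA energy, Modeller DOPE, with
direction sidecars) and the four antagonist affinities (QNB 74 pM,
NMQNB 120 pM, NMS 260 pM, atropine 490 pM at 298.15 K) ship as CSV
fixtures under `src/modelcheck/data/`. They drive the correlation and
conversion examples and the acceptance script. The published per-metric
adjusted p-values for these tables are not reproduced: the raw-p method
behind them is not documented, so only the correlation coefficients are
treated as reference values.

## Numerical and design choices

- First model of multi-model PDB files only; altloc "" or "A"; waters
  dropped; hydrogens kept when present.
- Sizes used by the default test run and the acceptance script (20
  decoy seeds × 3 noise levels at 250 residues, 100 random 6-pose
  tables, 10 pose seeds, n = 100 score tables) were chosen to make
  sampling noise comfortably smaller than the asserted tolerances.
- Holm adjustment, Spearman/Pearson and the t distribution come from
  statsmodels/scipy; PDB I/O from gemmi; SDF ligand input from rdkit.
  The Kabsch solver, trimming procedure, checklist logic, pharmacophore
  rules, pose consensus and generators are implemented here.
- Known limitations: no symmetry-aware ligand RMSD; no protonation
  model beyond formal charge/connectivity; rectangular Ramachandran
  masks are deliberately coarse; the clash screen is a screen, not a
  contact-dot analysis.
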
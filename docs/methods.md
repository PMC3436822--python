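# Methods

This note records the models, conventions and numerical choices behind
rotaflex, and what the synthetic-data validation does and does not
demonstrate about real crystal structures.

## Pair definition and curation

An analysis entry is a pair of X-ray structures of the same protein: a holo
form bound to a subject ligand (a HETATM small molecule, not a peptide or
nucleic acid) and an apo form lacking it. The curation gates run in a fixed
order and the first failure is the verdict, so re-running a pair always
reproduces the same reason code:

| gate | rule | default |
|---|---|---|
| resolution | both forms | ≤ 2.50 Å |
| identity | matching aligned columns | 100 % |
| overlap | aligned fraction of *either* chain length | ≥ 80 % |
| buffer | het code not in {SO4, PO4, GOL, NH4, CIT, MPD, TRS, MES} | — |
| ligand_size | ligand heavy atoms | ≥ 5 |
| covalent | no ligand–protein pair below r_cov,i + r_cov,j + 0.4 Å | — |
| site_size | residues contacting the ligand | ≥ 5, non-empty |
| multi_chain | binding site within one chain | — |
| burial | ligand burial fraction Fc | ≥ 0.70 |
| missing_atoms | all site side-chain atoms present in both forms | — |
| extra_ligand | secondary ligands differ by ≤ 10 residue contacts | — |
| site_rmsd | site backbone N,CA,C,O RMSD after superposition | ≤ 2.50 Å |

Sequences are extracted from coordinates and aligned with global
Needleman–Wunsch (match 2, mismatch −1, gap −5/−0.5, free end gaps, via
biopython), so terminal purification tags and differing domain-boundary
choices cost nothing. Identity is counted over aligned columns; the overlap
criterion is satisfied if the aligned length reaches 80 % of either
sequence. "Five atoms or less is too small" versus "minimum of five heavy
atoms" is an ambiguous boundary at exactly 5; the inclusive reading (≥ 5
passes) is the default and the strict one (≥ 6) is a flag
(`strict_ligand_size`).

**Burial fraction.** Fc is implemented as 1 − SAS_bound/SAS_free for the
ligand in the identical conformation; a fully buried ligand gives Fc → 1.
The literal ratio SAS_b/SAS_f is available via `fc_convention=
"printed_ratio"` for comparison, but a ≥ 0.70 threshold only makes sense on
the buried-fraction convention. Waters do not occlude (they are solvent).

**Secondary-ligand consistency** is counted at residue level: for each
non-subject het code the number of contacted residues must not differ by
more than 10 between the forms (absence counts as zero).

## Geometry

- Torsions: the atan2-of-normals formula, range (−180°, 180°], with
  degenerate (collinear/coincident) inputs rejected. Note that a proper
  torsion is invariant under full reversal of the point order
  (χ(ABCD) = χ(DCBA)); only mirror reflection flips its sign.
- Superposition: closed-form Kabsch/SVD least squares with the determinant
  sign guard, so the fit is always a proper rotation.
- Accessible surface: deterministic Shrake–Rupley sampling with a 960-point
  golden-spiral lattice per atom and a 1.4 Å probe. The lattice is fixed,
  so every area is exactly reproducible; accuracy against a 10⁶-point
  Monte-Carlo oracle is better than 1 % relative on overlapping-sphere
  configurations, and rigid-body invariance holds to the sampling
  resolution (~0.1 % at 4000 points). An analytical surface is out of
  scope.
- Contacts: atoms are in probe-mediated contact when
  d ≤ rᵢ + rⱼ + 2·probe — the distance support of surface contact by a
  rolling probe, monotone with any surface-intersection notion.
- Radii: Bondi van der Waals radii by element, one table for protein and
  ligand; Cordero covalent radii for bond perception. Both ship as TSV with
  the source in the header. Unknown elements fall back to carbon values.

## Rotamer assignment

χ torsions are measured from the canonical atom quadruples (standard PDB v3
names). All angular arithmetic is circular; the terminal torsions of
two-fold symmetric groups (Asp χ2, Glu χ3, Phe/Tyr χ2) are compared modulo
180° and normalised to (−90°, 90°], so equivalent atom namings can never
register as conformational change. The same convention feeds both the
rotamer method and the legacy Δχ ≥ 60° criterion, keeping the two
comparable.

The shipped library is a curated backbone-independent table in the
Penultimate style: modal χ values per rotamer, a ±30° admission window per
torsion unless a per-χ half-width overrides it, and approximate population
frequencies used only for tie-breaking. A candidate rotamer is admissible
when every observed χ lies within its window (boundary inclusive); no
survivor ⇒ non-rotameric (NR); several survivors (overlapping windows make
this unavoidable) ⇒ nearest by maximum per-χ deviation, then higher
frequency, then rotamer id. Assigning each library entry's own means
returns that entry for every row shipped.

Classification: same rotamer in both forms ⇒ rigid; different rotamers, or
exactly one NR ⇒ flexible; both NR ⇒ excluded (two NR states cannot be
placed in distinct energy wells). NR observations whose side chain has any
heavy atom with B > 40 Å², occupancy < 1, or an alternate conformation are
excluded as unreliable density; rotameric side chains are not filtered.
Gly/Ala (no χ), Pro (ring-coupled χ) and disulfide-bonded Cys (SG–SG
< 2.5 Å) never enter the statistics.

The per-type change probability is P = N_changed/N_total with the binomial
standard error √(P(1−P)/N_total). The exact coverage of the ±2·SE interval
at N = 500, P = 0.3 is 95.4 % (computed from the binomial pmf), i.e. the
error bar is calibrated at nominal level or better.

## Steric analysis (WALL)

The apo-bound form is the apo structure plus the holo ligand mapped through
the rigid transform fitted on the binding-site backbone (N, CA, C, O of
corresponding residues). Overlap is scored per ligand–protein heavy-atom
pair:

    wall(r_ij) = K · ((rᵢ + rⱼ − r_ij)/(rᵢ + rⱼ))⁴   for r_ij < rᵢ + rⱼ, else 0

with K = 10⁶. The relative-overlap quartic is this package's choice of
penalty shape: it is zero with zero slope at grazing contact, rises steeply
inside, and puts a typical hard clash (≥ 0.4 Å overlap between carbons) at
≈ 470 — above the per-residue criticality threshold of 25, while the
site-level threshold of 150 needs either one solid clash or several grazes.
Because threshold semantics are tied to the penalty shape, the form is
pluggable (quadratic and hard-step alternates) and both thresholds are
configuration. Signed differences WALL(apo-bound) − WALL(holo) are
reported; positive means the unbound conformation blocks the pose. Each
pair term is credited to the protein atom's residue; hydrogens are
excluded (crystal structures rarely carry them, and radii tables treat
heavy atoms implicitly).

A critical residue whose maximal circular |Δχ| is strictly below 15° counts
toward the minimal-rotation hypothesis — movement without rotamer change.

## Hydrogen-bond network

Only strong bonds where both donor and acceptor are N or O, and only side
chains of {Arg, Asn, Asp, Gln, Glu, His, Lys, Ser, Trp, Tyr} are counted.
Thr is included by default via a flag: its hydroxyl is chemically
indistinguishable from Ser's for this purpose even though the canonical
list omits it. Criteria: 1.5 Å ≤ d(H···A) ≤ 2.7 Å and θ(D–H···A) ≥ 90°, all
boundaries closed (inclusive up to a 10⁻⁹ numerical tolerance).

Polar hydrogens are placed deterministically at ideal geometry: in-plane
pairs on amides and guanidinium (N–H 1.01 Å, 120°), ring bisectors on
His/Trp nitrogens, staggered tetrahedral triplets on Lys NZ, and
discrete-rotor hydroxyls (Ser/Thr/Tyr, 30° steps) oriented to satisfy the
most acceptors (ties to the smallest torsion). Carboxylates and phosphates
stay unprotonated; `strip_acidic_hydrogens` removes any the input carries.
Backbone amide hydrogens are not placed — counted statistics are
side-chain-only, and backbone carbonyl oxygens remain available as
acceptor partners in the "protein" entity.

Water and ligand donors carry no explicit hydrogens; following the
virtual-hydrogen convention they donate whenever the heavy-atom distance to
the acceptor lies in [2.5, 3.5] Å (2.7 Å H···A plus a collinear ~0.96 Å
O–H, conservatively rounded), with the angle treated as optimal. His ring
nitrogens are ambident (donor-or-acceptor per contact, no pKa model).
Duplicate routes to the same heavy-atom pair (explicit-H and virtual) are
de-duplicated per credited residue.

Asn/Gln amide and His imidazole flips: both 180° terminal orientations are
scored by (heavy-atom clash count, then satisfied H-bonds); ties keep the
input orientation. This two-state scoring reproduces ideal-geometry
placements exactly on planted fixtures; it is not a full network
optimization.

Per binding-site residue the bonds are counted against water, protein and
ligand in each form; equal counts (including 0/0) are conserved, more after
binding is a gain, fewer a loss.

## Aggregation

Per-site change-count histograms carry cumulative fractions; both the
rotamer-based and Δχ ≥ 60° series come from the same per-residue records.
The entropy correlation is a Pearson r over the residue types shared
between the flexibility scale and a user-supplied ΔS table (≥ 3 types
required; no ΔS values ship with the package — they are third-party
literature data supplied as a two-column TSV). Flexible-vs-rigid
comparisons of unbound-form b-factors and normalized SASA use Welch's
two-sided t-test (pooled and per-type; groups under 2 observations are
reported undefined). SASA is normalized by the side-chain surface of the
isolated extended residue computed with the same engine — an internally
consistent reference that avoids mixing surface algorithms (a tripeptide
reference would differ by a roughly constant backbone-occlusion factor).

## Synthetic data: what it emulates and what it does not

The generator places ideal-geometry residues on a sphere, side chains
pointing at a small buried carbon scaffold, and fits each residue's radius
so its closest ligand approach is ~3.9 Å (in contact, not clashing). Plants
are exact: rotamer swaps use genuine library transitions; NR offsets
(+45° per χ) are verified against every admission window at generation
time; clash atoms are positioned to overlap one apo-conformer atom by a
stated depth while staying vdW-clear of everything that moves (overlap with
form-invariant residues is tolerated down to covalent-safety distance
because it cancels exactly in every WALL difference); hydrogen-bond
partners are placed at exact (d, θ) geometry with candidate screening so no
unplanned detection window is entered, and boundary-exact plants are nudged
10⁻⁶ toward their intended side so float rounding cannot flip a verdict.
Infeasible plants (a crowded pocket blocking every candidate) raise rather
than silently degrade the ground truth.

Deliberately absent realism: no peptide connectivity, no backbone change
between forms (site RMSD ≡ 0), no crystallographic noise, B-factors
constant at 15 Å² except planted exceptions, and an abstract ligand.
Passing the validation suite therefore demonstrates that the *measurement
machinery* — parsing, torsions, assignment windows, superposition,
penalties, bond geometry, bookkeeping — is exact and deterministic; it
does not demonstrate robustness to disorder, alternate conformations
beyond the modelled cases, or real electron-density artifacts. Conclusions
about real proteins require real paired structures through the same
pipeline.

Validation sizes: 200 rotamer round-trip draws, 100 estimator-recovery
replicates of 500 observations, 200-pair ensembles for distribution
recovery, 50 planted-clash fixtures, 20 hydrogen-bond pockets, 12-pair
ensembles for byte-level determinism — each chosen as the smallest size at
which the checked property is unambiguous.

## Known limitations

- The rotamer table is a curated snapshot, not a verbatim published
  library; analyses needing exact published frequencies should load their
  own TSV (`load_rotamer_library(path)`).
- WALL thresholds (150/25) are only meaningful relative to the quartic
  penalty form; changing the form requires re-calibrating them.
- Ligand N/O atoms are treated as simultaneous potential donors and
  acceptors (no perception of, e.g., carbonyl vs hydroxyl oxygens beyond
  connectivity-based deprotonation).
- Sequence pairing matches chains by shared chain id; renamed chains
  between the two crystal forms need pre-processing.
- Waters are identified by residue name (HOH/WAT/DOD) and only their
  oxygens are kept.
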
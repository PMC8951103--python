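# Methods

## The model

`fragshare` treats the binding affinity of a ligand as approximately
additive over user-defined fragments, and estimates each fragment's slice
by *in-place rescoring*: every fragment, completed into a valence-correct
small molecule by capping its cut bonds, is scored against the receptor as
if it were a standalone binder sitting exactly where it sits inside the
whole ligand. The per-fragment scores are then normalised into stakeholder
shares,

    omega_j = Score(F_j) / sum_i Score(F_i),        sum_j omega_j = 1,

and the shares partition the whole-molecule interaction energy,

    E_j = omega_j * dE_mol,                          sum_j E_j = dE_mol,
    GE_j = |E_j| / NH_j,

where `dE_mol` (kcal/mol, negative favorable) may come from an experimental
K_D/K_i, from `-RT ln(IC50)`, or from an in silico score of the whole
ligand, and `NH_j` is the fragment's heavy-atom count. `GE_j` is the
per-fragment analog of ligand efficiency `LE = -dG/NH`; for a one-fragment
scheme the two coincide exactly.

Assumptions worth keeping in mind:

* **Additivity.** Free energy is not strictly additive over fragments; the
  partition is a first-order decision aid, not a thermodynamic claim.
* **Local feasibility, not global pose search.** Each fragment is scored at
  its position *within the parent ligand's* binding mode. Nothing is
  docked, minimised, or re-oriented — any coordinate transform between
  scoring calls would be a correctness bug, and the code never applies one.
* **Share-level error cancellation.** Because omega_j is a ratio of scores
  from one backend, a common multiplicative error cancels exactly. This is
  a theorem for multiplicative errors only; additive or fragment-dependent
  errors do not cancel, which is why consensus over several backends is
  recommended.
* **Unit agnosticism.** Shares are computed after mapping scores so that
  *favorable is positive*, whatever the backend's units and sign
  convention (kcal/mol, pKd, knowledge-based). Only `dE_mol` carries
  physical units.

## Fragmentation and capping

The fragment scheme is entirely the user's choice: a partition of the
ligand's heavy atoms (1-based serials, exactly as in the source file) plus
the list of inter-fragment bonds to cut. `validate_scheme` checks coverage,
disjointness, and that the cut-bond list matches the ligand's actual
inter-fragment bonds; ring cuts are allowed only as a flagged warning,
since capping a broken ring bond cannot preserve the original
hybridisation.

Caps heal each cut bond without touching any original atom: a hydrogen is
placed on the stub→departed-neighbour unit vector at a fixed per-element
bond length (C–H 1.09 Å, N–H 1.01 Å, O–H 0.96 Å, S–H 1.34 Å; methyl caps
use the corresponding X–C single-bond lengths plus three tetrahedral
hydrogens in a deterministic staggered orientation). The lengths are a
fixed table, not a force-field optimisation — the method is single-point by
design. A cap landing within 0.5 Å of an existing fragment atom is a hard
error naming the bond.

`NH_j` counts only the fragment's *original* heavy atoms. Caps are
artifacts of the method, so they are excluded from NH even for methyl caps,
whose heavy carbon does contribute to the fragment's score; that
contribution, and the fact that the caps of two adjacent fragments both
occupy the neighbourhood of the cut bond (a mild double-counting of that
region), are accepted as method noise and noted in reports rather than
corrected.

Original hydrogens travel with their heavy atom; retained atoms keep their
formal charges (a charged carboxylate fragment stays charged).

## Built-in scoring

The built-in backends implement the standard empirical pairwise form: for
each intermolecular heavy-atom pair within an 8 Å interatomic cutoff, with
surface distance `d = r − R_i − R_j`,

    gauss1      exp(−(d/w1)^2)                (w1 = 0.5 Å; Vinardo 0.8 Å)
    gauss2      exp(−((d−3)/2)^2)             (absent in Vinardo)
    repulsion   d^2 for d < 0, else 0
    hydrophobic linear ramp 1 → 0 over d in [0.5, 1.5] Å (Vinardo [0, 2.5])
    hbond       linear ramp 1 → 0 over d in [−0.7, 0] Å (Vinardo [−0.6, 0])

weighted and summed. Weights and shape constants are transcribed into
versioned JSON parameter files (`vina_default`, `vinardo_default`) from the
backends' source publications rather than hard-coded; the
`parameter_set_id` is stamped on every score. Hydrogens contribute no
pairs (heavy-atom treatment); the hydrophobic term requires both atoms
hydrophobic, the H-bond term a donor–acceptor pair. Interaction typing is a
small, documented rule table: carbon with only C/H heavy neighbours is
hydrophobic, N/O are acceptors, N/O/S with an attached hydrogen are donors,
halogens are hydrophobic.

Two deliberate conventions:

* **The interatomic cutoff is on r, not d.** At r = 8 Å every term is
  negligible for realistic radii, and the pair list stays geometry-only.
* **No rotatable-bond scaling for fragments.** The `1/(1 + w_rot·N_rot)`
  entropy factor exists behind a flag for whole-ligand, LE-style scoring,
  but fragment shares compare in-place interaction strength and are
  computed without it.

The production path builds a k-d tree over receptor heavy atoms
(`scipy.spatial.cKDTree`); `fixtures.closed_form_pair_sum` re-derives the
same sum as a naive double loop with the formulas written out inline, and
the two must agree to 1e-9 — that cross-check, plus additivity over
receptor subsets, rigid-frame invariance, and exact linearity in the
weights, are the scoring suite's backbone.

External score-only programs (e.g. knowledge-based or machine-learned
scorers) attach through `BackendAdapter`: an argv template with
`{receptor}`/`{ligand}` placeholders, a regex capturing one scalar, the
units and the favorable direction. The package ships no external binary;
adapters are exercised with mock subprocesses in the tests.

## Partition conventions and degenerate inputs

* Scores are mapped favorable-positive before Eq-style normalisation, so
  positive-is-better backends (pKd-like) partition identically to
  kcal/mol backends.
* **Mixed signs** (some fragments scored unfavorable) would push shares
  outside [0, 1]; the default policy is a typed error. An explicit
  `clip_to_zero` opt-in zeroes the unfavorable entries before normalising
  and flags the result.
* **Near-zero denominators**: |sum of scores| < 1e-6 (backend units) is
  always an error — shares would blow up without meaning.
* Conservation (`sum E_j = dE_mol` to 1e-9) and normalisation
  (`sum omega_j = 1` to 1e-12) are enforced invariants, not aspirations;
  permuting fragment order permutes outputs identically.

## Efficiencies

`dG = RT ln(K)` with R = 1.98720425e-3 kcal/(mol K), T = 298.15 K by
default (configurable and stamped into provenance; RT ≈ 0.5925 kcal/mol).
The IC50 route is flagged as an approximation. GE and LE are reported as
positive-favorable magnitudes to match common usage (threshold 0.30
kcal/mol/atom, configurable); internal energies stay signed. No rigid-body
scaffold bonus of any kind is applied to any fragment — the analysis is
cleaner and directly comparable to LE without it, and no option is
provided.

## Pose selection

When the analysis runs on a docked rather than crystal geometry, the pose
is chosen by the position of the *anchor* fragment (the experimentally
placed core): plain heavy-atom RMSD against the crystal reference in the
shared receptor frame, **without superposition** — fitting first would
defeat the positional criterion. Correspondence is explicit (atom names by
default, or a serial map); symmetry-equivalent mappings such as ring flips
are not auto-detected. At least 3 corresponded heavy atoms are required.
Poses within 0.01 Å RMSD of the minimum are ties, broken by the better
docking score. Docking-output hydrogens are ignored as unreliable.

## Consensus and decision flags

Across backends the consensus is the unweighted mean ± SD of GE — GE is
unit-consistent across backends, raw scores are not, so dispersion is never
computed on raw scores. Two heuristics annotate the table:

* `below_threshold` / optimisation focus: fragments with mean GE under the
  threshold; the lowest is the suggested target for the next design
  iteration, with an explicit "no suboptimal fragment" note when empty.
* `anchor_violation`: raised when any non-anchor fragment's mean |E_j|
  reaches the anchor's (an optional slack parameter loosens the `>=`
  comparison). The operational rule — magnitude comparison with zero
  default slack — is this tool's convention for the qualitative idea that
  a grown arm rivalling the anchor signals an untrustworthy binding mode.

All intermediates (raw per-fragment scores per backend) are persisted in
the report; regenerating the table from the same inputs is bit-identical.

## Structure I/O

PDB and PDBQT are read and written in-package with fixed-width parsing:
PDBQT needs the partial-charge and AutoDock-type columns plus TORSDOF to
round-trip, and no installed structural library preserves them. Coordinates
are kept exactly as printed (Å); round-trip read→write→read is a fixed
point for serials, names, ordering and 3-decimal coordinates in both
dialects. Torsion-tree records (ROOT/BRANCH) are tolerated and ignored —
everything here is single-point. Selection supports chains, segments,
residue names, solvent stripping (default: strip, with a keep option since
pocket waters can mediate fragment contacts), and a first-listed altloc
policy with a warning naming dropped alternatives. Bond perception for
ligands without CONECT uses covalent-radius sums + 0.45 Å tolerance;
CONECT always wins when present. Protonation and hydrogen placement are
delegated to external preparation tools and are out of scope.

## Synthetic fixtures

`fixtures.make_toy_complex` builds alkane-like ligand chains (linear or
singly branched) with contiguous fragment blocks, and isolated receptor
probe atoms placed at controlled surface distances along axis-aligned
offsets; by default three of four probes face the first fragment, so the
partition lands near (not exactly at — fragments also see each other's
probes within the cutoff) a 3:1 split. Expected fragment scores are
returned from the closed-form oracle. The `beyond_cutoff` variant yields
exact-zero scores and exercises the near-zero-sum guard.

What the fixtures deliberately are *not*: realistic proteins, realistic
chemistry, or conformational ensembles. Passing tests demonstrate that the
machinery — I/O round trips, capping geometry, the scoring sum, the
algebraic invariants of the partition, pose selection — is exact; they say
nothing about the scoring functions' accuracy on real complexes, which is
inherited from the transcribed parameter sets and from the user's choice of
geometry.

## Problem sizes and determinism

Default verification sizes, chosen to probe every regime while keeping the
whole suite near-instant: 1000 random score vectors (1–12 fragments) for
the partition invariants, 500 for the GE identities, 100 random 30×10-atom
typed pairs for the scoring oracle, 20 random chains for fragmentation
fidelity, 50 random poses for the RMSD oracle. All randomness flows through
seeded `numpy` generators; `scripts/acceptance.py` derives independent
streams from its single `--seed` via `SeedSequence.spawn`, and the
`hypothesis` property tests run derandomised.

## Known limitations

* Adjacent fragments' caps both sample the cut-bond region; the resulting
  double-counting is reported, not corrected.
* Mixed-sign score vectors have no principled share decomposition; the
  clip policy is a pragmatic escape hatch, clearly flagged.
* The built-in typing table is rule-based and element-level; it does not
  model aromaticity, charge transfer, or metal coordination beyond a vdW
  radius entry.
* Only PDB/PDBQT dialects are supported (no mmCIF), and automatic
  fragmentation schemes (BRICS/RECAP-style) are intentionally absent —
  where to cut is a modelling decision the tool leaves to the scientist.
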
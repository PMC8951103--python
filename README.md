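# fragshare

**In-place fragment contribution analysis and group-efficiency estimation for
protein–ligand complexes.**

A recurring question in fragment-based, structure-guided hit-to-lead work is:
*which part of my ligand is earning its keep, and which part should be
optimised next?* `fragshare` answers it in silico. Given a fixed
ligand–receptor geometry (crystal structure or selected docking pose), a
user-defined partition of the ligand into fragments, and the total
interaction energy to explain, it:

1. **cuts** the ligand at the designated bonds and **caps** the open valences
   with hydrogens (or methyls) *without moving a single original atom*;
2. **scores** each capped fragment, as a standalone molecule at its original
   coordinates, against the receptor with a single-point (score-only)
   scoring function;
3. **normalises** the fragment scores into unitless *stakeholder shares*

   ω<sub>j</sub> = Score(Fragment<sub>j</sub>) / Σ<sub>i</sub> Score(Fragment<sub>i</sub>),   Σ<sub>j</sub> ω<sub>j</sub> = 1

4. **partitions** the whole-molecule binding energy ΔE<sub>mol</sub>
   (experimental K<sub>D</sub>/K<sub>i</sub>, −RT·ln IC₅₀, or an in silico
   score) into additive contributions

   E<sub>j</sub><sup>scaled</sup> = ω<sub>j</sub> · ΔE<sub>mol</sub>,   Σ<sub>j</sub> E<sub>j</sub><sup>scaled</sup> = ΔE<sub>mol</sub>

5. **converts** contributions into group efficiencies, the per-fragment
   analog of ligand efficiency

   GE<sub>j</sub> = |E<sub>j</sub><sup>scaled</sup>| / NH<sub>j</sub>   (kcal mol⁻¹ per heavy atom),

   flagging fragments under the customary 0.30 kcal mol⁻¹ atom⁻¹
   drug-likeness threshold as optimisation candidates.

Because the share is a *ratio* of scores from one backend, any common
multiplicative error of the scoring function cancels exactly, and backends
reporting in different units (kcal/mol, pK<sub>d</sub>, knowledge-based
scores) can all drive the same partition. Running several backends and
aggregating GE (mean ± SD) gives a consensus estimate together with two
decision heuristics: the lowest-GE fragment as the optimisation focus, and
an *anchor-violation* warning when a grown fragment contributes as much as
the experimentally anchored core — a sign the binding mode should not be
trusted for further optimisation.

Two empirical pairwise scoring functions are built in (the Vina functional
form and its Vinardo re-parameterisation, transcribed into versioned
parameter files), and any external score-only program can be plugged in
through a small adapter contract (invocation template + regex for the
score).

## Worked example

A synthetic complex — an octane-like 8-carbon ligand split into two
4-carbon fragments, with four receptor probe atoms placed so that three sit
over fragment F1 and one over F2 — scored with both built-in backends and an
experimental K<sub>D</sub> of 1.5 µM:

```bash
python -c "
from fragshare.fixtures import FixtureSpec, make_toy_complex, write_fixture
g, s, _ = make_toy_complex(FixtureSpec())
write_fixture('demo', g, s)"

fragshare partition --receptor demo/receptor.pdb --ligand demo/ligand.pdb \
    --scheme demo/scheme.json --backend builtin_vina --backend builtin_vinardo \
    --affinity-kd 1.5e-6 --anchor F1 --out demo_out
```

prints (columns abridged):

```
fragment_id  nh  omega[vina_default]  e_scaled[vina_default]  ge_mean   ge_sd
         F1   4             0.749059               -5.951458  1.495433  0.010704
         F2   4             0.250941               -1.993792  0.490879  0.010704

delta_E_mol = -7.95 kcal/mol (experimental_kd)
no suboptimal fragment: all GE values at or above threshold
```

Reading it: K<sub>D</sub> = 1.5 µM converts to ΔE<sub>mol</sub> = RT ln K<sub>D</sub>
= −7.95 kcal/mol. Fragment F1 holds ~75 % of the total score (three of the
four probes face it), so it receives −5.95 of the −7.95 kcal/mol; both
fragments' GE values clear the 0.30 kcal mol⁻¹ atom⁻¹ threshold, and the two
backends agree to within ~0.01 kcal mol⁻¹ atom⁻¹ (`ge_sd`). Swapping either
backend for a copy with all weights doubled changes no ω and no GE — the
multiplicative-error cancellation at work.

Other entry points: `fragshare fragment` writes the capped fragments to
PDB/PDBQT for external scorers; `fragshare select-pose` picks, from a
multi-model docking output, the pose whose anchor fragment lies closest (by
plain RMSD in the shared receptor frame, no superposition) to a crystal
reference. The same functionality is available as a library
(`fragshare.run_partition_analysis`, `fragshare.select_pose`, ...).

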
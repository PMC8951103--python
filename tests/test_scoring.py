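"""Built-in pairwise scoring: term shapes, oracle equality, invariances."""

import sys

import numpy as np
import pytest

from fragshare.complex_io import Atom, Molecule, SFType
from fragshare.fixtures import closed_form_pair_sum, make_random_typed_pair
from fragshare.scoring import (BackendAdapter, ExternalBackendError,
                               SFParameters, ScoringError, external_score,
                               pair_terms, score_pose)

PHOB = SFType(True, True, False, False, 1.9)
PLAIN = SFType(True, False, False, False, 1.9)
DONOR = SFType(True, False, True, False, 1.8)
ACCEPTOR = SFType(True, False, False, True, 1.7)


def probe_molecule(positions, sf_types, chain="R"):
    atoms = []
    for k, (pos, t) in enumerate(zip(positions, sf_types)):
        a = Atom(serial=k + 1, name=f"P{k+1}", element="C",
                 coords=np.asarray(pos, float), chain_id=chain)
        a.sf_type = t
        atoms.append(a)
    return Molecule(atoms=atoms)


class TestPairTerms:
    def test_surface_contact_values(self, vina_params):
        t = pair_terms(0.0, PHOB, PHOB, vina_params)
        assert t[0] == pytest.approx(1.0)          # gauss1 = exp(0)
        assert t[2] == 0.0                          # repulsion boundary
        assert t[3] == pytest.approx(1.0)          # hydrophobic plateau

    def test_repulsion_is_d_squared(self, vina_params):
        t = pair_terms(-1.0, PLAIN, PLAIN, vina_params)
        assert t[2] == pytest.approx(1.0)
        t = pair_terms(-0.5, PLAIN, PLAIN, vina_params)
        assert t[2] == pytest.approx(0.25)

    def test_hydrophobic_needs_both_hydrophobic(self, vina_params):
        assert pair_terms(0.0, PHOB, PLAIN, vina_params)[3] == 0.0
        assert pair_terms(1.0, PHOB, PHOB, vina_params)[3] == pytest.approx(0.5)

    def test_hbond_only_donor_acceptor(self, vina_params):
        assert pair_terms(-0.7, DONOR, ACCEPTOR, vina_params)[4] == pytest.approx(1.0)
        assert pair_terms(-0.35, ACCEPTOR, DONOR, vina_params)[4] == pytest.approx(0.5)
        assert pair_terms(-0.7, DONOR, DONOR, vina_params)[4] == 0.0
        assert pair_terms(-0.7, ACCEPTOR, ACCEPTOR, vina_params)[4] == 0.0

    def test_vinardo_single_gaussian_and_widened_ramps(self, vinardo_params):
        assert vinardo_params.weights["gauss2"] == 0.0
        t = pair_terms(2.0, PHOB, PHOB, vinardo_params)
        assert t[3] == pytest.approx(0.2)  # (2.5-2)/2.5


class TestScorePose:
    def test_single_pair_closed_form(self, vina_params):
        d = 0.25
        r = 1.9 + 1.9 + d
        receptor = probe_molecule([[0, 0, 0]], [PHOB])
        ligand = probe_molecule([[r, 0, 0]], [PHOB], chain="L")
        sv = score_pose(receptor, ligand, vina_params)
        expect = float(vina_params.weight_vector()
                       @ pair_terms(d, PHOB, PHOB, vina_params))
        assert sv.value == pytest.approx(expect, abs=1e-12)
        assert sv.units == "kcal_per_mol"
        assert sv.backend_id == "vina_default"

    def test_beyond_cutoff_scores_zero(self, vina_params):
        receptor = probe_molecule([[0, 0, 0]], [PHOB])
        ligand = probe_molecule([[vina_params.cutoff + 1.0, 0, 0]], [PHOB], chain="L")
        assert score_pose(receptor, ligand, vina_params).value == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_oracle(self, seed, vina_params, vinardo_params):
        rng = np.random.default_rng(seed)
        receptor, ligand = make_random_typed_pair(rng)
        for params in (vina_params, vinardo_params):
            got = score_pose(receptor, ligand, params).value
            want = closed_form_pair_sum(receptor, ligand, params)
            assert got == pytest.approx(want, abs=1e-9)

    def test_additive_over_receptor_subsets(self, vina_params):
        rng = np.random.default_rng(11)
        receptor, ligand = make_random_typed_pair(rng, n_receptor=20)
        r1 = Molecule(atoms=receptor.atoms[:8])
        r2 = Molecule(atoms=receptor.atoms[8:])
        whole = score_pose(receptor, ligand, vina_params).value
        parts = (score_pose(r1, ligand, vina_params).value
                 + score_pose(r2, ligand, vina_params).value)
        assert whole == pytest.approx(parts, abs=1e-9)

    def test_rigid_frame_invariance(self, vina_params):
        rng = np.random.default_rng(12)
        receptor, ligand = make_random_typed_pair(rng)
        before = score_pose(receptor, ligand, vina_params).value
        # one rotation + translation applied jointly to both molecules
        theta = 0.83
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        shift = np.array([5.0, -3.0, 2.5])
        for mol in (receptor, ligand):
            for a in mol.atoms:
                a.coords = rot @ a.coords + shift
        after = score_pose(receptor, ligand, vina_params).value
        assert after == pytest.approx(before, abs=1e-9)

    def test_weight_scaling_scales_score_linearly(self, vina_params):
        rng = np.random.default_rng(13)
        receptor, ligand = make_random_typed_pair(rng)
        base = score_pose(receptor, ligand, vina_params).value
        k = 2.5
        scaled = SFParameters(
            weights={t: k * w for t, w in vina_params.weights.items()},
            shape=vina_params.shape, cutoff=vina_params.cutoff,
            parameter_set_id="scaled")
        assert score_pose(receptor, ligand, scaled).value == pytest.approx(
            k * base, rel=1e-12)

    def test_nrot_scaling_divides(self, vina_params):
        receptor = probe_molecule([[0, 0, 0]], [PHOB])
        ligand = probe_molecule([[4.0, 0, 0]], [PHOB], chain="L")
        ligand.n_rotatable = 5
        raw = score_pose(receptor, ligand, vina_params).value
        scaled = score_pose(receptor, ligand, vina_params,
                            apply_nrot_scaling=True).value
        assert scaled == pytest.approx(raw / (1 + vina_params.rotor_weight * 5))

    def test_untyped_and_empty_are_errors(self, vina_params):
        untyped = Molecule(atoms=[Atom(serial=1, name="C1", element="C",
                                       coords=np.zeros(3))])
        typed = probe_molecule([[0, 0, 0]], [PHOB])
        with pytest.raises(ScoringError):
            score_pose(untyped, typed, vina_params)
        with pytest.raises(ScoringError):
            score_pose(typed, Molecule(atoms=[]), vina_params)

    def test_hydrogens_contribute_no_pairs(self, vina_params):
        receptor = probe_molecule([[0, 0, 0]], [PHOB])
        ligand = probe_molecule([[4.0, 0, 0]], [PHOB], chain="L")
        h = Atom(serial=2, name="H1", element="H", coords=np.array([3.0, 0, 0]),
                 chain_id="L")
        h.sf_type = SFType(False, False, False, False, 0.0)
        with_h = Molecule(atoms=ligand.atoms + [h])
        assert score_pose(receptor, with_h, vina_params).value == \
            score_pose(receptor, ligand, vina_params).value


class TestExternalAdapter:
    def _adapter(self, script, pattern=r"Affinity:\s+(-?\d+\.\d+)", **kw):
        return BackendAdapter(backend_id="mock",
                              command_template=[sys.executable, "-c", script],
                              parse_pattern=pattern, **kw)

    def test_vina_style_output_parsed(self, tmp_path):
        adapter = self._adapter("print('Affinity: -7.95 (kcal/mol)')")
        sv = external_score(adapter, tmp_path / "r.pdbqt", tmp_path / "l.pdbqt")
        assert sv.value == pytest.approx(-7.95)
        assert sv.units == "kcal_per_mol"

    def test_pkd_style_backend(self, tmp_path):
        adapter = self._adapter("print('6.5')", pattern=r"(\d+\.\d+)",
                                units="pKd", favorable_direction="positive_is_better")
        sv = external_score(adapter, tmp_path / "r", tmp_path / "l")
        assert sv.value == pytest.approx(6.5)
        assert sv.favorable_direction == "positive_is_better"
        assert sv.favorable_magnitude == pytest.approx(6.5)

    def test_no_match_is_error_with_output(self, tmp_path):
        adapter = self._adapter("print('no score today')")
        with pytest.raises(ExternalBackendError) as err:
            external_score(adapter, tmp_path / "r", tmp_path / "l")
        assert "no score today" in err.value.output

    def test_nonzero_exit_is_error(self, tmp_path):
        adapter = self._adapter("import sys; sys.exit(3)")
        with pytest.raises(ExternalBackendError, match="exited with 3"):
            external_score(adapter, tmp_path / "r", tmp_path / "l")

    def test_command_receives_file_paths(self, tmp_path):
        adapter = BackendAdapter(
            backend_id="echo",
            command_template=[sys.executable, "-c",
                              "import sys; print('S:', len('{receptor}') + 0.5)"],
            parse_pattern=r"S:\s+(\d+\.\d+)")
        sv = external_score(adapter, tmp_path / "rec.pdbqt", tmp_path / "lig.pdbqt")
        assert sv.value == len(str(tmp_path / "rec.pdbqt")) + 0.5
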
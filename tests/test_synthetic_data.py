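import math

import numpy as np
import pytest

from cofrac import calibration
from cofrac.errors import ConfigurationError
from cofrac.profiles import read_fraction_table
from cofrac.synthetic_data import (
    DEGRADED_MASS_FACTOR,
    GroundTruth,
    PlantedComplex,
    SimulationConfig,
    elution_centers,
    expected_profile,
    generate_ground_truth,
    load_ground_truth,
    simulate_dataset,
    simulate_experiment,
    write_fixture,
)


def make_config(**kwargs):
    defaults = dict(n_complexes=5, n_monomers=10, seed=1)
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


class TestGenerateGroundTruth:
    def test_no_complexes_yields_monomers_only(self):
        truth = generate_ground_truth(make_config(n_complexes=0, n_monomers=5))
        assert len(truth.proteins) == 5
        assert truth.complexes == []
        assert truth.true_pairs() == []

    def test_forced_size_three_gives_three_pairs(self):
        truth = generate_ground_truth(
            make_config(n_complexes=1, n_monomers=0, complex_size_range=(3, 3))
        )
        assert len(truth.true_pairs()) == math.comb(3, 2)

    def test_deterministic_under_seed(self):
        a = generate_ground_truth(make_config(seed=1))
        b = generate_ground_truth(make_config(seed=1))
        assert a.proteins == b.proteins
        assert a.monomer_mass == b.monomer_mass
        assert a.complexes == b.complexes
        assert a.degraded == b.degraded

    def test_complex_mass_is_sum_of_member_masses(self):
        truth = generate_ground_truth(make_config(n_complexes=8))
        for cpx in truth.complexes:
            total = sum(truth.monomer_mass[p] for p in cpx.members)
            assert cpx.mass_kda == pytest.approx(total)
            assert cpx.mass_kda >= max(truth.monomer_mass[p] for p in cpx.members)

    def test_every_protein_appears_once(self):
        truth = generate_ground_truth(make_config())
        assert len(set(truth.proteins)) == len(truth.proteins)
        in_complex = {p for c in truth.complexes for p in c.members}
        assert in_complex | truth.monomers == set(truth.proteins)
        assert not (in_complex & truth.monomers)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(n_complexes=-1),
            dict(experiments=()),
            dict(experiments=(("XYZ", 20),)),
            dict(experiments=(("SEC", 5),)),
            dict(dropout_prob=1.5),
            dict(elution_sigma=0.0),
        ],
    )
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            generate_ground_truth(make_config(**bad))


class TestSimulateExperiment:
    def test_full_dropout_gives_all_zero_matrix(self):
        cfg = make_config(dropout_prob=1.0, background_rate=0.0)
        truth = generate_ground_truth(cfg)
        m = simulate_experiment(truth, "SEC", 24, cfg)
        assert not m.counts.any()

    def test_counts_are_nonnegative_integers(self):
        cfg = make_config()
        truth = generate_ground_truth(cfg)
        m = simulate_experiment(truth, "IEX", 43, cfg)
        assert np.issubdtype(m.counts.dtype, np.integer)
        assert (m.counts >= 0).all()

    def test_complex_members_coelute_on_sec(self, noise_free_sec):
        # members share an elution center; with Poisson counting the raw
        # apexes can straddle two adjacent fractions, never more
        _, truth, matrix = noise_free_sec
        idx = {p: i for i, p in enumerate(matrix.proteins)}
        for cpx in truth.complexes:
            live = [p for p in cpx.members if p not in truth.degraded]
            apexes = {int(np.argmax(matrix.counts[idx[p]])) for p in live}
            if apexes:
                assert max(apexes) - min(apexes) <= 1

    def test_planted_mass_peaks_at_calibration_inverse(self):
        # one 400 kDa trimer, abundant: its empirical SEC peak sits at the
        # calibration inverse of 400 kDa to within one fraction
        members = ("A", "B", "C")
        truth = GroundTruth(
            proteins=list(members),
            monomer_mass={p: 400.0 / 3 for p in members},
            complexes=[PlantedComplex("CPX", members, 400.0, 3000.0)],
            monomers=frozenset(),
            degraded=frozenset(),
            abundance={p: 3000.0 for p in members},
        )
        cfg = make_config(seed=7)
        m = simulate_experiment(truth, "SEC", 45, cfg)
        model = calibration.true_calibration(45)
        expected = model.fraction_at(400.0)
        for i in range(3):
            apex = int(np.argmax(m.counts[i])) + 1
            assert abs(apex - expected) <= 1.5

    def test_degraded_member_never_shares_complex_center(self):
        cfg = make_config(n_complexes=20, degraded_fraction=0.5, seed=9)
        truth = generate_ground_truth(cfg)
        degraded_members = [
            p
            for p in truth.degraded
            if truth.complex_of(p) is not None
        ]
        assert degraded_members, "fixture should contain degraded complex members"
        centers = elution_centers(truth, "SEC", 45)
        model = calibration.true_calibration(45)
        for p in degraded_members:
            cpx = truth.complex_of(p)
            assert centers[p] == pytest.approx(
                np.clip(
                    model.fraction_at(DEGRADED_MASS_FACTOR * truth.monomer_mass[p]),
                    1,
                    45,
                )
            )
            assert centers[p] != pytest.approx(model.fraction_at(cpx.mass_kda))

    def test_sec_peak_fraction_decreases_with_mass(self):
        model = calibration.true_calibration(45)
        masses = np.linspace(5, 2500, 50)
        fracs = [model.fraction_at(m) for m in masses]
        assert all(a > b for a, b in zip(fracs, fracs[1:]))

    def test_pre_noise_co_complex_profiles_perfectly_correlated(self):
        cfg = make_config(n_complexes=3, n_monomers=0, seed=2)
        truth = generate_ground_truth(cfg)
        centers = elution_centers(truth, "SEC", 45)
        for cpx in truth.complexes:
            live = [p for p in cpx.members if p not in truth.degraded]
            profs = [
                expected_profile(centers[p], 45, cfg.elution_sigma, truth.abundance[p])
                for p in live
            ]
            for a, b in zip(profs, profs[1:]):
                assert np.corrcoef(a, b)[0, 1] == pytest.approx(1.0)


class TestFixtureIO:
    def test_round_trip_matrices(self, tmp_path):
        cfg = make_config()
        truth = generate_ground_truth(cfg)
        matrices = simulate_dataset(truth, cfg)
        paths = write_fixture(truth, matrices, tmp_path)
        for m in matrices:
            again = read_fraction_table(paths[f"matrix:{m.experiment_id}"])
            assert again.proteins == m.proteins
            np.testing.assert_array_equal(again.counts, m.counts)
            assert again.fraction_labels == m.fraction_labels

    def test_default_design_has_136_fraction_columns(self, tmp_path):
        cfg = make_config()
        truth = generate_ground_truth(cfg)
        matrices = simulate_dataset(truth, cfg)
        total = sum(m.n_fractions for m in matrices)
        assert total == 24 + 45 + 43 + 24 == 136
        labels = [lab for m in matrices for lab in m.fraction_labels]
        assert len(set(labels)) == 136

    def test_ground_truth_round_trip(self, tmp_path):
        cfg = make_config(degraded_fraction=0.3)
        truth = generate_ground_truth(cfg)
        paths = write_fixture(truth, simulate_dataset(truth, cfg), tmp_path)
        again = load_ground_truth(paths["ground_truth"])
        assert again.proteins == truth.proteins
        assert again.complexes == truth.complexes
        assert again.degraded == truth.degraded

    def test_fixture_deterministic_bytes(self, tmp_path):
        cfg = make_config(seed=4)
        files = {}
        for sub in ("one", "two"):
            truth = generate_ground_truth(cfg)
            paths = write_fixture(truth, simulate_dataset(truth, cfg), tmp_path / sub)
            files[sub] = {k: p.read_bytes() for k, p in paths.items()}
        assert files["one"] == files["two"]

    def test_empty_ground_truth_round_trips(self, tmp_path):
        cfg = make_config(n_complexes=0, n_monomers=0)
        truth = generate_ground_truth(cfg)
        paths = write_fixture(truth, [], tmp_path)
        assert load_ground_truth(paths["ground_truth"]).proteins == []
        assert paths["true_pairs"].read_text().strip() == "protein_a\tprotein_b"
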
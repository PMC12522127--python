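"""Distance series, distributions, cutoff finding, retention, residue occupancy."""

import numpy as np
import pytest

import fibrion as fb
from fibrion.errors import DegenerateDistributionError, EmptyDistributionError

from conftest import make_tiny_random_trajectory
from oracles import (
    brute_min_distances,
    brute_residue_occupancy,
    brute_retention,
    markov_retention_se,
)


def series_from_array(d, species="NA"):
    """Wrap a plain (n_ions, n_frames) distance array as a DistanceSeries."""
    d = np.asarray(d, dtype=float)
    return fb.DistanceSeries(
        species=species,
        ion_atom_indices=np.arange(d.shape[0]),
        distances=d,
        times=np.arange(d.shape[1], dtype=float),
    )


class TestMinDistances:
    def test_single_ion_nearest_atom(self):
        traj = make_tiny_random_trajectory(n_prot=3, n_ions=1, n_frames=1, seed=0, box=(50.0,) * 3)
        fr = traj.frames[0]
        fr.positions[:3] = [[10.0, 10.0, 10.0], [20.0, 20.0, 20.0], [30.0, 30.0, 30.0]]
        fr.positions[3] = [13.0, 10.0, 10.0]
        series = fb.min_distances(
            traj, fb.select_group(traj, "ion:NA"), fb.select_group(traj, "protein_heavy")
        )
        assert series.distances[0, 0] == pytest.approx(3.0)

    def test_matches_nested_loop_oracle(self):
        traj = make_tiny_random_trajectory(n_prot=10, n_ions=2, n_frames=5, seed=21)
        ions = fb.select_group(traj, "ion:NA")
        prot = fb.select_group(traj, "protein_heavy")
        series = fb.min_distances(traj, ions, prot)
        expected = brute_min_distances(traj, ions.atom_indices, prot.atom_indices)
        np.testing.assert_allclose(series.distances, expected, atol=1e-9)

    def test_periodic_image_beats_naive_distance(self):
        traj = make_tiny_random_trajectory(n_prot=1, n_ions=1, n_frames=1, seed=0, box=(10.0,) * 3)
        fr = traj.frames[0]
        fr.positions[0] = [1.0, 5.0, 5.0]
        fr.positions[1] = [9.0, 5.0, 5.0]    # naive 8.0, image 2.0
        series = fb.min_distances(
            traj, fb.select_group(traj, "ion:NA"), fb.select_group(traj, "protein_heavy")
        )
        assert series.distances[0, 0] == pytest.approx(2.0)


class TestDistanceDistribution:
    def test_single_value_occupies_one_bin(self):
        dist = fb.distance_distribution(series_from_array([[2.5] * 10]), bin_width=0.1, r_max=10.0)
        occupied = np.flatnonzero(dist.counts)
        assert len(occupied) == 1
        assert dist.edges[occupied[0]] <= 2.5 <= dist.edges[occupied[0] + 1]

    def test_two_delta_groups_equal_peaks(self):
        dist = fb.distance_distribution(series_from_array([[2.5] * 50 + [4.5] * 50]))
        occupied = np.flatnonzero(dist.counts)
        assert len(occupied) == 2
        assert dist.counts[occupied[0]] == dist.counts[occupied[1]]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_density_integrates_to_one(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.gamma(3.0, 1.2, size=(4, 200))
        dist = fb.distance_distribution(series_from_array(d), bin_width=0.1, r_max=10.0)
        assert dist.density.sum() * dist.bin_width == pytest.approx(1.0, abs=1e-9)
        assert dist.counts.sum() == int(np.sum(d <= dist.edges[-1]))

    def test_all_beyond_range_is_an_error(self):
        with pytest.raises(EmptyDistributionError):
            fb.distance_distribution(series_from_array([[20.0, 25.0]]), r_max=10.0)


class TestFindCutoffs:
    @staticmethod
    def gaussian_mixture_series(mu1=2.5, mu2=4.5, sigma=0.3, n=40000, seed=3, w1=0.5):
        rng = np.random.default_rng(seed)
        n1 = int(n * w1)
        d = np.concatenate([
            rng.normal(mu1, sigma, n1), rng.normal(mu2, sigma, n - n1)
        ])
        return series_from_array(np.abs(d)[None, :])

    def test_two_gaussian_minimum_located(self):
        dist = fb.distance_distribution(self.gaussian_mixture_series())
        cut = fb.find_cutoffs(dist, expected_peaks=2)
        assert cut.provenance == "auto_minima"
        assert cut.cutoff1 == pytest.approx(3.5, abs=0.2)
        assert cut.cutoff2 is not None and cut.cutoff2 > cut.cutoff1

    def test_symmetric_bimodal_minimum_at_midpoint(self):
        # equal weights and widths: the analytic density minimum is the midpoint
        dist = fb.distance_distribution(self.gaussian_mixture_series(mu1=3.0, mu2=6.0, seed=9))
        cut = fb.find_cutoffs(dist, expected_peaks=2)
        assert cut.cutoff1 == pytest.approx(4.5, abs=0.25)

    def test_unimodal_with_expected_one_peak_uses_fixed_fallback(self):
        rng = np.random.default_rng(5)
        d = np.abs(rng.normal(3.0, 0.4, size=(1, 5000)))
        dist = fb.distance_distribution(series_from_array(d))
        cut = fb.find_cutoffs(dist, expected_peaks=1)
        assert cut.cutoff1 == pytest.approx(5.0)
        assert cut.provenance == "fixed"
        assert cut.cutoff2 is None

    def test_species_fixed_cutoffs_table(self):
        assert fb.contacts.SPECIES_FIXED_CUTOFFS["CL"] == pytest.approx(3.5)
        assert fb.contacts.SPECIES_FIXED_CUTOFFS["MG"] == pytest.approx(3.0)
        assert fb.contacts.SPECIES_FIXED_CUTOFFS["HPO4"] == pytest.approx(5.0)

    def test_flat_distribution_is_degenerate(self):
        dist = fb.distance_distribution(
            series_from_array(np.linspace(0.05, 9.95, 2000)[None, :]),
            smooth_window=1,
        )
        with pytest.raises(DegenerateDistributionError):
            fb.find_cutoffs(dist, expected_peaks=2)


class TestRetention:
    def test_always_inside_is_immobile(self):
        recs = fb.retention_fractions(
            series_from_array([[1.0] * 10]), fb.CutoffSet(species="NA", cutoff1=2.0)
        )
        assert recs[0].f1 == 1.0 and recs[0].immobile

    def test_exactly_half_is_mobile(self):
        # strict > 0.5: 50 of 100 frames inside is NOT immobile
        d = np.array([[1.0] * 50 + [9.0] * 50])
        recs = fb.retention_fractions(series_from_array(d), fb.CutoffSet(species="NA", cutoff1=2.0))
        assert recs[0].f1 == pytest.approx(0.5)
        assert not recs[0].immobile
        # one more frame inside tips it over
        d2 = np.array([[1.0] * 51 + [9.0] * 49])
        recs2 = fb.retention_fractions(series_from_array(d2), fb.CutoffSet(species="NA", cutoff1=2.0))
        assert recs2[0].immobile

    def test_contact_is_closed_interval(self):
        recs = fb.retention_fractions(
            series_from_array([[2.0, 2.0001]]), fb.CutoffSet(species="NA", cutoff1=2.0)
        )
        assert recs[0].f1 == pytest.approx(0.5)

    def test_f1_bounded_by_f2(self):
        rng = np.random.default_rng(2)
        d = rng.uniform(0, 8, size=(6, 50))
        recs = fb.retention_fractions(
            series_from_array(d), fb.CutoffSet(species="NA", cutoff1=2.5, cutoff2=5.0)
        )
        for r in recs:
            assert 0.0 <= r.f1 <= r.f2 <= 1.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(4)
        d = rng.uniform(0, 6, size=(3, 20))
        recs = fb.retention_fractions(series_from_array(d), fb.CutoffSet(species="NA", cutoff1=3.0))
        np.testing.assert_allclose([r.f1 for r in recs], brute_retention(d, 3.0))

    def test_markov_binding_recovery(self):
        kin = fb.BindingKinetics(p_on=0.3, p_off=0.1, n_ions=20, seed=23)
        traj, truth = fb.generate_binding_trajectory(kin, n_frames=5000)
        series = fb.min_distances(
            traj, fb.select_group(traj, "ion:NA"), fb.select_group(traj, "protein_heavy")
        )
        # cutoff between the bound jitter radius and the free exclusion zone,
        # so contact classification equals the latent Markov state exactly
        recs = fb.retention_fractions(series, fb.CutoffSet(species="NA", cutoff1=2.8))
        f1 = np.array([r.f1 for r in recs])
        np.testing.assert_allclose(f1, truth.realized_retention, atol=1e-12)
        se = markov_retention_se(0.3, 0.1, 5000, 20)
        assert abs(f1.mean() - 0.75) < 3 * se
        assert np.mean([r.immobile for r in recs]) > 0.9

    def test_enlarging_cutoff_never_decreases_f1(self):
        rng = np.random.default_rng(6)
        d = rng.uniform(0, 8, size=(5, 100))
        series = series_from_array(d)
        f_small = [r.f1 for r in fb.retention_fractions(series, fb.CutoffSet(species="NA", cutoff1=2.0))]
        f_big = [r.f1 for r in fb.retention_fractions(series, fb.CutoffSet(species="NA", cutoff1=4.0))]
        assert all(b >= s for s, b in zip(f_small, f_big))

    def test_immobile_mobile_partition(self):
        rng = np.random.default_rng(8)
        d = rng.uniform(0, 6, size=(10, 40))
        recs = fb.retention_fractions(series_from_array(d), fb.CutoffSet(species="NA", cutoff1=3.0))
        immobile = {r.ion for r in recs if r.immobile}
        mobile = {r.ion for r in recs if not r.immobile}
        assert immobile | mobile == set(range(10))
        assert not (immobile & mobile)


class TestResidueOccupancy:
    def test_bound_site_residue_fully_occupied(self):
        kin = fb.BindingKinetics(p_on=0.5, p_off=0.0, n_ions=2, n_sites=2, seed=31)
        traj, truth = fb.generate_binding_trajectory(kin, n_frames=50)
        occ = fb.residue_occupancy(
            traj,
            fb.select_group(traj, "protein_heavy"),
            fb.select_group(traj, "ion:NA"),
            fb.CutoffSet(species="NA", cutoff1=2.8 + 1.5),  # site jitter + residue extent
        )
        by_res = {o.residue_index: o.occupancy for o in occ}
        for site_res in truth.site_residues:
            assert by_res[int(site_res)] == 1.0

    def test_distant_residue_never_contacted(self):
        traj = make_tiny_random_trajectory(n_prot=2, n_ions=1, n_frames=4, seed=1, box=(40.0,) * 3)
        for fr in traj.frames:
            fr.positions[0] = [5.0, 5.0, 5.0]
            fr.positions[1] = [20.0, 20.0, 20.0]
            fr.positions[2] = [6.0, 5.0, 5.0]   # ion next to residue 1 only
        occ = fb.residue_occupancy(
            traj,
            fb.select_group(traj, "protein_heavy"),
            fb.select_group(traj, "ion:NA"),
            fb.CutoffSet(species="NA", cutoff1=3.0),
        )
        by_res = {o.residue_index: o.occupancy for o in occ}
        assert by_res[1] == 1.0
        assert by_res[2] == 0.0

    def test_alternating_ion_splits_occupancy(self):
        traj = make_tiny_random_trajectory(n_prot=2, n_ions=1, n_frames=10, seed=2, box=(40.0,) * 3)
        for t, fr in enumerate(traj.frames):
            fr.positions[0] = [5.0, 5.0, 5.0]
            fr.positions[1] = [20.0, 20.0, 20.0]
            fr.positions[2] = [6.0, 5.0, 5.0] if t % 2 == 0 else [21.0, 20.0, 20.0]
        occ = fb.residue_occupancy(
            traj,
            fb.select_group(traj, "protein_heavy"),
            fb.select_group(traj, "ion:NA"),
            fb.CutoffSet(species="NA", cutoff1=3.0),
        )
        assert [o.occupancy for o in occ] == [0.5, 0.5]

    def test_matches_brute_force_oracle(self):
        traj = make_tiny_random_trajectory(n_prot=8, n_ions=2, n_frames=6, seed=13)
        prot = fb.select_group(traj, "protein_heavy")
        ions = fb.select_group(traj, "ion:NA")
        cutoff = 4.0
        occ = fb.residue_occupancy(traj, prot, ions, fb.CutoffSet(species="NA", cutoff1=cutoff))
        expected = brute_residue_occupancy(traj, prot.atom_indices, ions.atom_indices, cutoff)
        got = {(o.chain, o.residue_index): o.occupancy for o in occ}
        assert got == pytest.approx(expected)

    def test_monotone_in_cutoff(self):
        traj = make_tiny_random_trajectory(n_prot=6, n_ions=2, n_frames=5, seed=17)
        prot = fb.select_group(traj, "protein_heavy")
        ions = fb.select_group(traj, "ion:NA")
        occ_small = fb.residue_occupancy(traj, prot, ions, fb.CutoffSet(species="NA", cutoff1=2.0))
        occ_big = fb.residue_occupancy(traj, prot, ions, fb.CutoffSet(species="NA", cutoff1=5.0))
        for s, b in zip(occ_small, occ_big):
            assert b.occupancy >= s.occupancy
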
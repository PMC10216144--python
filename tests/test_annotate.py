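"""Annotation chain: noise, peak picking, charge inference, matching."""

import numpy as np
import pytest

from clmsi.annotate import (
    Annotation,
    AnnotationConfig,
    Centroid,
    annotate_spectrum,
    assign_chains,
    assign_charge,
    dbond_ratio,
    estimate_noise,
    match_species,
    pick_peaks,
)
from clmsi.chem import (
    C13_C12_SPACING,
    FattyAcyl,
    LipidSpecies,
    default_species_space,
    fa_anion_mz,
    fa_combinations,
)
from clmsi.synthetic import GeneratorConfig, TissueClassProfile, render_spectrum


def gaussian(mz, center, height, fwhm):
    sigma = fwhm / 2.3548200450309493
    return height * np.exp(-0.5 * ((mz - center) / sigma) ** 2)


@pytest.fixture
def axis():
    return np.arange(700.0, 760.0, 0.003)


class TestEstimateNoise:
    def test_constant_spectrum_gives_zero(self, axis):
        assert estimate_noise(axis, np.full_like(axis, 7.0), [(710, 730)]) == 0.0

    def test_recovers_gaussian_sd(self, axis, rng):
        intensity = rng.normal(0.0, 2.5, size=axis.size)
        estimate = estimate_noise(axis, intensity, [(700, 760)])
        assert estimate == pytest.approx(2.5, rel=0.1)

    def test_robust_to_an_embedded_peak(self, axis, rng):
        intensity = rng.normal(0.0, 1.0, size=axis.size)
        clean = estimate_noise(axis, intensity, [(700, 760)])
        intensity += gaussian(axis, 730.0, 500.0, 0.01)
        contaminated = estimate_noise(axis, intensity, [(700, 760)])
        assert contaminated < 2 * clean

    def test_empty_window_rejected(self, axis, rng):
        with pytest.raises(ValueError):
            estimate_noise(axis, rng.normal(size=axis.size), [])
        with pytest.raises(ValueError):
            estimate_noise(axis, rng.normal(size=axis.size), [(900, 950)])


class TestPickPeaks:
    def test_single_gaussian_centroid_within_1_ppm(self, axis):
        center = 727.51013
        intensity = gaussian(axis, center, 100.0, center / 70_000)
        peaks = pick_peaks(axis, intensity, noise_level=1.0)
        assert len(peaks) == 1
        assert abs(peaks[0].mz - center) / center * 1e6 < 1

    def test_flat_zero_spectrum_yields_nothing(self, axis):
        assert pick_peaks(axis, np.zeros_like(axis), noise_level=1.0) == []

    def test_resolves_half_mz_spaced_dianion_peaks(self, axis):
        # two isotopologues of a 2− ion at resolving power 70,000
        a, b = 727.51013, 727.51013 + 0.50168
        intensity = gaussian(axis, a, 100.0, a / 70_000) + gaussian(
            axis, b, 80.0, b / 70_000
        )
        peaks = pick_peaks(axis, intensity, noise_level=1.0)
        assert len(peaks) == 2
        assert peaks[1].mz - peaks[0].mz == pytest.approx(0.50168, abs=1e-3)

    def test_threshold_gates_detection(self, axis):
        intensity = gaussian(axis, 730.0, 2.5, 0.01)
        assert pick_peaks(axis, intensity, noise_level=1.0, snr=3.0) == []
        assert len(pick_peaks(axis, intensity, noise_level=1.0, snr=2.0)) == 1


def envelope_centroids(mono_mz, z, heights):
    spacing = C13_C12_SPACING / z
    return [
        Centroid(mono_mz + j * spacing, h, j) for j, h in enumerate(heights)
    ]


class TestAssignCharge:
    def test_doubly_charged_envelope(self):
        centroids = envelope_centroids(723.47884, 2, [100, 90, 43])
        assert assign_charge(centroids, centroids[0]) == 2

    def test_singly_charged_envelope(self):
        centroids = envelope_centroids(885.54979, 1, [100, 50, 15])
        assert assign_charge(centroids, centroids[0]) == 1

    def test_isolated_peak_undetermined(self):
        lonely = Centroid(700.0, 50.0, 0)
        assert assign_charge([lonely], lonely) is None


class TestMatchSpecies:
    def test_published_mass_error_example(self, species_space):
        centroids = envelope_centroids(727.509, 2, [90, 80])
        annotations = match_species(centroids, species_space, noise_level=1.0)
        assert len(annotations) == 1
        assert annotations[0].species.name == "CL(72:4)"
        assert annotations[0].ppm == pytest.approx(-1.55, abs=0.05)
        assert annotations[0].detected

    def test_tolerance_gate(self, species_space):
        centroids = envelope_centroids(727.509, 2, [90, 80])
        assert match_species(centroids, species_space, 1.0, tol_ppm=1.0) == []

    def test_unsorted_space_rejected(self, species_space):
        centroids = envelope_centroids(727.509, 2, [90, 80])
        with pytest.raises(ValueError):
            match_species(centroids, list(reversed(species_space)), 1.0)

    def test_low_snr_not_detected(self, species_space):
        centroids = envelope_centroids(727.509, 2, [2.0, 1.8])
        annotations = match_species(centroids, species_space, noise_level=1.0)
        assert len(annotations) == 1 and not annotations[0].detected


class TestFullSpectrum:
    def test_noiseless_recall_and_precision(self, species_space):
        """Against generator truth, every panel species and nothing else."""
        from clmsi.synthetic import build_profile

        config = GeneratorConfig(rows=1, cols=1, noise_sd=1e-3, seed=17)
        profile = build_profile("NL_grey")
        intensity = render_spectrum(profile, config, np.random.default_rng(2))
        annotations = annotate_spectrum(config.mz_axis(), intensity, species_space)
        detected = {a.species for a in annotations if a.detected}
        truth = set(profile.species_abundance)
        assert detected == truth  # recall = precision = 1

    def test_well_separated_species_under_1_ppm(self, species_space):
        """Without isotopologue overlap from cluster neighbours, mass errors
        stay below 1 ppm on noiseless data."""
        config = GeneratorConfig(rows=1, cols=1, noise_sd=1e-3, seed=17)
        sparse = {
            LipidSpecies("CL", 68, 4): 0.3,
            LipidSpecies("CL", 74, 8): 0.4,
            LipidSpecies("CL", 80, 12): 0.3,
        }
        profile = TissueClassProfile("NL_grey", sparse, attenuation=1.0)
        intensity = render_spectrum(profile, config, np.random.default_rng(2))
        annotations = annotate_spectrum(config.mz_axis(), intensity, species_space)
        detected = {a.species: a for a in annotations if a.detected}
        assert set(detected) == set(sparse)
        assert max(abs(a.ppm) for a in detected.values()) < 1.0

    def test_detection_monotone_in_snr_threshold(self, nl_dataset, species_space):
        dataset, _ = nl_dataset
        mz, intensity = dataset.mz, dataset.intensities[0, 0]
        detected = {}
        for threshold in (3.0, 10.0, 50.0):
            config = AnnotationConfig(snr_threshold=threshold)
            annotations = annotate_spectrum(mz, intensity, species_space, config)
            detected[threshold] = {a.species for a in annotations if a.detected}
        assert detected[50.0] <= detected[10.0] <= detected[3.0]


class TestAssignChains:
    def test_single_fragment_identifies_tetra_oleoyl(self):
        pool = [FattyAcyl.parse(s) for s in ("16:0", "18:0", "18:1", "18:2")]
        ms2 = [Centroid(fa_anion_mz(FattyAcyl(18, 1)), 1000.0, 0)]
        ranked = assign_chains(ms2, LipidSpecies("CL", 72, 4), pool)
        assert len(ranked) == 1
        assert ranked[0][0] == tuple(FattyAcyl(18, 1) for _ in range(4))

    def test_mixed_chain_species(self):
        pool = [FattyAcyl.parse(s) for s in ("16:0", "16:1", "18:1", "18:2")]
        ms2 = [
            Centroid(fa_anion_mz(FattyAcyl(16, 0)), 300.0, 0),
            Centroid(fa_anion_mz(FattyAcyl(18, 1)), 900.0, 1),
            Centroid(fa_anion_mz(FattyAcyl(18, 2)), 500.0, 2),
        ]
        ranked = assign_chains(ms2, LipidSpecies("CL", 70, 4), pool)
        combos = [combo for combo, _ in ranked]
        target = (FattyAcyl(18, 2), FattyAcyl(18, 1), FattyAcyl(18, 1), FattyAcyl(16, 0))
        assert target in combos

    def test_no_fragments_no_ranking(self):
        ranked = assign_chains([], LipidSpecies("CL", 72, 4), [FattyAcyl(18, 1)])
        assert ranked == []

    def test_output_is_subset_of_combinations(self):
        pool = [FattyAcyl.parse(s) for s in ("16:0", "18:1", "18:2", "20:4")]
        species = LipidSpecies("CL", 72, 8)
        ms2 = [
            Centroid(fa_anion_mz(fa), 100.0, i) for i, fa in enumerate(pool[:2])
        ]
        ranked = assign_chains(ms2, species, pool)
        universe = set(fa_combinations(72, 8, pool, 4))
        assert {combo for combo, _ in ranked} <= universe


class TestDbondRatio:
    def _centroids(self, values):
        return [Centroid(mz, i, k) for k, (mz, i) in enumerate(values)]

    def test_scale_invariance(self):
        ions_a, ions_b = (143.108, 167.108), (171.139, 195.139)
        base = self._centroids(
            [(143.108, 60.0), (167.108, 40.0), (171.139, 30.0), (195.139, 10.0)]
        )
        scaled = self._centroids(
            [(143.108, 600.0), (167.108, 400.0), (171.139, 300.0), (195.139, 100.0)]
        )
        assert dbond_ratio(base, ions_a, ions_b) == pytest.approx(
            dbond_ratio(scaled, ions_a, ions_b)
        )
        assert dbond_ratio(base, ions_a, ions_b) == pytest.approx(100.0 / 40.0)

    def test_missing_denominator_is_an_error(self):
        centroids = self._centroids([(143.108, 60.0)])
        with pytest.raises(ValueError):
            dbond_ratio(centroids, (143.108,), (171.139,))

    def test_overlapping_ion_sets_rejected(self):
        centroids = self._centroids([(143.108, 60.0), (171.139, 30.0)])
        with pytest.raises(ValueError):
            dbond_ratio(centroids, (143.108, 171.139), (171.139,))

    def test_empty_ion_set_rejected(self):
        with pytest.raises(ValueError):
            dbond_ratio(self._centroids([(143.108, 60.0)]), (), (171.139,))
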
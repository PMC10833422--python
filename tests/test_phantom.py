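from dataclasses import replace

import numpy as np
import pytest

from zernseg.errors import ConfigurationError
from zernseg.phantom import (
    ContrastShift,
    generate_domain_shifted,
    generate_domain_shifted_full,
    generate_phantom,
    generate_phantom_full,
    label_porosity,
)

from conftest import SMALL_SPEC


class TestDeterminismAndDegenerateCases:
    def test_same_seed_bit_identical(self):
        v1, l1 = generate_phantom(SMALL_SPEC)
        v2, l2 = generate_phantom(SMALL_SPEC)
        assert np.array_equal(v1.data, v2.data)
        assert np.array_equal(l1.data, l2.data)

    def test_different_seed_differs(self):
        v1, _ = generate_phantom(SMALL_SPEC)
        v2, _ = generate_phantom(replace(SMALL_SPEC, seed=4))
        assert not np.array_equal(v1.data, v2.data)

    def test_artifact_free_is_piecewise_constant(self):
        spec = replace(SMALL_SPEC, noise_sd=0.0, halo_amplitude=0.0, shade_amplitude=0.0)
        vol, lab = generate_phantom(spec)
        for code, name in enumerate(lab.class_set):
            mask = lab.data == code
            if mask.any():
                vals = np.unique(vol.data[mask])
                assert len(vals) == 1
                assert vals[0] == pytest.approx(spec.class_means[name], abs=1e-6)


class TestLabelGeometry:
    def test_porosity_within_band(self, small_phantom):
        spec = small_phantom.spec
        poro = label_porosity(small_phantom.labels)
        assert abs(poro - spec.target_porosity_frac) <= 0.2 * spec.target_porosity_frac

    def test_default_spec_porosity_example(self, default_phantom):
        # 8 lacunae, target 2.1 %: label porosity must fall in [0.017, 0.025]
        assert default_phantom.spec.n_lacunae == 8
        assert 0.017 <= label_porosity(default_phantom.labels) <= 0.025

    def test_all_four_classes_present(self, small_phantom):
        counts = small_phantom.labels.class_counts()
        assert all(counts[name] > 0 for name in ("background", "bone", "shade_off", "lcn"))

    def test_lcn_fully_inside_bone(self, small_phantom):
        assert not (small_phantom.lcn_mask & ~small_phantom.bone_mask).any()

    def test_shade_off_near_air_interface_only(self, small_phantom):
        shade = small_phantom.labels.data == 2
        assert shade.any()
        assert small_phantom.d_air[shade].max() <= small_phantom.spec.shade_width_vox + 1e-9

    def test_porosity_self_consistency(self, small_phantom):
        # measuring on the label volume reproduces the generator's realized count
        assert label_porosity(small_phantom.labels) == pytest.approx(
            small_phantom.realized_porosity, abs=1e-12
        )


class TestContrastPathology:
    def test_bone_and_shade_histograms_overlap(self, small_phantom):
        g = small_phantom.gray.data
        lab = small_phantom.labels.data
        bone_vals, shade_vals = g[lab == 1], g[lab == 2]
        lo = max(bone_vals.min(), shade_vals.min())
        hi = min(bone_vals.max(), shade_vals.max())
        assert hi > lo  # shared support

    def test_halo_band_brighter_than_bone_mean(self, small_phantom):
        g = small_phantom.gray.data
        assert g[small_phantom.halo_band].mean() > small_phantom.spec.class_means["bone"]

    def test_shade_band_darker_than_bone_mean(self, small_phantom):
        g = small_phantom.gray.data
        assert g[small_phantom.shade_band].mean() < small_phantom.spec.class_means["bone"]

    def test_single_threshold_cannot_separate_bone(self, small_phantom):
        g = small_phantom.gray.data.ravel()
        is_bone = (small_phantom.labels.data == 1).ravel()
        best = max(
            max(((g > t) == is_bone).mean(), ((g <= t) == is_bone).mean())
            for t in np.linspace(0, 1, 101)
        )
        assert best < 0.98

    def test_rim_line_profile_has_halo_max_then_shade_min(self):
        # noise-free phantom: walking inward from the rim the profile first
        # peaks above the bone mean (halo), then dips below it (shade-off)
        spec = replace(SMALL_SPEC, noise_sd=0.0)
        real = generate_phantom_full(spec)
        g, lab = real.gray.data, real.labels.data
        z = spec.shape[0] // 2
        row = spec.shape[1] // 2
        cols = np.where(real.bone_mask[z, row])[0]
        assert cols.size > 10
        c0 = cols.min()
        profile = g[z, row, c0 : c0 + 14]
        bone_mean = spec.class_means["bone"]
        assert profile.max() > bone_mean
        assert profile.min() < bone_mean
        assert int(profile.argmax()) < int(profile.argmin())


class TestDomainShift:
    def test_identity_shift_reproduces_phantom(self):
        v1, l1 = generate_phantom(SMALL_SPEC)
        v2, l2 = generate_domain_shifted(SMALL_SPEC, ContrastShift())
        assert np.array_equal(v1.data, v2.data)
        assert np.array_equal(l1.data, l2.data)

    def test_zero_shade_gives_three_classes(self):
        _, lab = generate_domain_shifted(SMALL_SPEC, ContrastShift(shade_amplitude=0.0))
        assert len(np.unique(lab.data)) == 3
        assert (lab.data == 2).sum() == 0  # no shade-off voxels

    def test_half_shade_brightens_the_shade_band(self, small_phantom):
        half = generate_domain_shifted_full(
            SMALL_SPEC, ContrastShift(shade_amplitude=SMALL_SPEC.shade_amplitude / 2)
        )
        band = small_phantom.shade_band
        assert half.gray.data[band].mean() > small_phantom.gray.data[band].mean()

    def test_same_geometry_under_shift(self, small_phantom):
        shifted = generate_domain_shifted_full(
            SMALL_SPEC, ContrastShift(noise_sd=0.08, shade_amplitude=0.05)
        )
        assert np.array_equal(shifted.bone_mask, small_phantom.bone_mask)
        assert np.array_equal(shifted.lcn_mask, small_phantom.lcn_mask)


class TestConfigurationErrors:
    def test_too_small_shape_names_field(self):
        with pytest.raises(ConfigurationError, match="shape"):
            generate_phantom(replace(SMALL_SPEC, shape=(16, 64, 64)))

    def test_porosity_out_of_range_names_field(self):
        with pytest.raises(ConfigurationError, match="target_porosity_frac"):
            generate_phantom(replace(SMALL_SPEC, target_porosity_frac=0.5))

    def test_unreachable_porosity_names_field(self):
        # one tiny lacuna cannot supply 8 % porosity in this rod
        with pytest.raises(ConfigurationError, match="target_porosity_frac|n_lacunae"):
            generate_phantom(
                replace(SMALL_SPEC, n_lacunae=1, lacuna_radii_vox=(1.0, 1.5),
                        target_porosity_frac=0.08)
            )

    def test_negative_noise_rejected(self):
        with pytest.raises(ConfigurationError, match="noise_sd"):
            generate_phantom(replace(SMALL_SPEC, noise_sd=-0.1))
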
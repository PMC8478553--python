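"""Synthetic cohort generator: determinism, planted structure, clinical table."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage, stats

from rcc_radiomics import (
    CohortConfig,
    ConfigurationError,
    RaterMask,
    generate_clinical_table,
    generate_cohort,
    generate_lesion_volume,
    lesion_mean_hu,
    perturb_mask,
)

TINY = dict(shape=(16, 16, 16))


def test_cohort_counts_and_structure():
    cfg = CohortConfig(counts={"ccRCC": 4, "pRCC": 2, "cRCC": 3}, **TINY, seed=1)
    cohort = generate_cohort(cfg)
    assert len(cohort) == 9
    freq = pd.Series([s.subtype for s in cohort]).value_counts()
    assert freq.to_dict() == {"ccRCC": 4, "pRCC": 2, "cRCC": 3}
    s = cohort[0]
    assert set(s.volumes) == {"NCP", "CMP", "NP", "EP"}
    assert set(s.masks) == {1, 2}
    assert all(np.isfinite(v.voxels).all() for v in s.volumes.values())


def test_minimal_cohort_single_subject():
    cfg = CohortConfig(counts={"ccRCC": 1, "pRCC": 0, "cRCC": 0}, **TINY, seed=2)
    (subject,) = generate_cohort(cfg)
    assert subject.subtype == "ccRCC"
    assert len(subject.volumes) == 4 and len(subject.masks) == 2


def test_seed_determinism_bit_identical():
    cfg = dict(counts={"ccRCC": 2, "pRCC": 1, "cRCC": 1}, **TINY, seed=9)
    a = generate_cohort(CohortConfig(**cfg))
    b = generate_cohort(CohortConfig(**cfg))
    for sa, sb in zip(a, b):
        for ph in sa.volumes:
            assert sa.volumes[ph].voxels.tobytes() == sb.volumes[ph].voxels.tobytes()
        for r in (1, 2):
            assert np.array_equal(sa.masks[r].voxels, sb.masks[r].voxels)
    ta = generate_clinical_table(a)
    tb = generate_clinical_table(b)
    pd.testing.assert_frame_equal(ta, tb)


@pytest.mark.parametrize(
    "bad",
    [
        {"counts": {"ccRCC": 0, "pRCC": 0, "cRCC": 0}},
        {"shape": (0, 16, 16)},
        {"spacing": (1.0, -1.0, 1.0)},
        {"cystic_prob": {"ccRCC": 1.5, "pRCC": 0.4, "cRCC": 0.3}},
    ],
)
def test_invalid_configuration_rejected(bad):
    with pytest.raises(ConfigurationError):
        cfg = CohortConfig(**bad)
        cfg.validate()
        generate_cohort(cfg)


def test_lesion_mean_matches_configured_value():
    """With zero noise every lesion voxel sits exactly at the target mean."""
    cfg = CohortConfig(
        **TINY, noise_sd=0.0, background_noise_sd=0.0,
        cystic_prob={s: 0.0 for s in ("ccRCC", "pRCC", "cRCC")},
        calcification_prob={s: 0.0 for s in ("ccRCC", "pRCC", "cRCC")},
    )
    vol, mask = generate_lesion_volume("ccRCC", "CMP", cfg, seed=3)
    assert np.allclose(vol.voxels[mask], 105.31)
    vol_p, mask_p = generate_lesion_volume("pRCC", "CMP", cfg, seed=3)
    assert np.allclose(vol_p.voxels[mask_p], 53.61)


def test_lesion_mean_with_noise_across_seeds():
    """Different seeds give different fields but the same measured mean.

    The generator anchors the margin-eroded core (the region the
    exported masks sample) at the configured attenuation exactly.
    """
    cfg = CohortConfig(**TINY)
    for seed in (1, 2):
        v, m = generate_lesion_volume("cRCC", "NP", cfg, seed=seed)
        core = ndimage.binary_erosion(m, iterations=cfg.margin_voxels())
        assert v.voxels[core].mean() == pytest.approx(77.81, abs=1e-9)
    v1, _ = generate_lesion_volume("cRCC", "NP", cfg, seed=1)
    v2, _ = generate_lesion_volume("cRCC", "NP", cfg, seed=2)
    assert not np.array_equal(v1.voxels, v2.voxels)


def test_subtype_mean_cmp_attenuation_monte_carlo():
    """Sample mean of ccRCC CMP lesion attenuation stays within 3 HU of
    the configured 105.31 for n >= 100 (between-subject SD 12)."""
    cfg = CohortConfig(counts={"ccRCC": 120, "pRCC": 0, "cRCC": 0},
                       shape=(12, 12, 12), seed=7)
    cohort = generate_cohort(cfg)
    means = [lesion_mean_hu(s, "CMP") for s in cohort]
    assert abs(np.mean(means) - 105.31) < 3.0


def test_planted_phase_contrast_signal():
    """CMP attenuation separates ccRCC from pRCC at 50/10/10 (p < 0.01)."""
    cfg = CohortConfig(counts={"ccRCC": 50, "pRCC": 10, "cRCC": 10},
                       shape=(12, 12, 12), seed=11)
    cohort = generate_cohort(cfg)
    cc = [lesion_mean_hu(s, "CMP") for s in cohort if s.subtype == "ccRCC"]
    pr = [lesion_mean_hu(s, "CMP") for s in cohort if s.subtype == "pRCC"]
    assert stats.mannwhitneyu(cc, pr).pvalue < 0.01


def test_margin_erosion_applied_to_rater_mask():
    """Rater-1 masks honor the 2 mm margin: strictly inside the lesion."""
    cfg = CohortConfig(counts={"ccRCC": 1, "pRCC": 0, "cRCC": 0}, **TINY, seed=4)
    (s,) = generate_cohort(cfg)
    r1 = s.masks[1].voxels
    # every rater-1 voxel must be >= 2 voxels from the background:
    # eroding the *lesion-level* region twice must still contain r1
    lesion = s.volumes["CMP"].voxels > 20  # background plateau is -20 HU
    eroded = ndimage.binary_erosion(lesion, iterations=cfg.margin_voxels())
    assert (~r1 | eroded).all()


class TestPerturbMask:
    def _cube(self, n=10, pad=3):
        m = np.zeros((n + 2 * pad,) * 3, dtype=bool)
        m[pad:-pad, pad:-pad, pad:-pad] = True
        return RaterMask(voxels=m, rater_id=1)

    def test_magnitude_zero_is_identity(self):
        m = self._cube()
        out = perturb_mask(m, 0, seed=1)
        assert np.array_equal(out.voxels, m.voxels)
        assert out.rater_id == 2

    def test_same_seed_reproducible(self):
        m = self._cube()
        a = perturb_mask(m, 2, seed=42)
        b = perturb_mask(m, 2, seed=42)
        assert np.array_equal(a.voxels, b.voxels)

    def test_magnitude_one_bounded_by_surface(self):
        m = self._cube()
        out = perturb_mask(m, 1, seed=3)
        inner = m.voxels & ~ndimage.binary_erosion(m.voxels)
        outer = ndimage.binary_dilation(m.voxels) & ~m.voxels
        changed = out.voxels ^ m.voxels
        assert changed.sum() <= inner.sum() + outer.sum()
        assert (changed & ~(inner | outer)).sum() == 0  # interior untouched

    def test_negative_magnitude_rejected(self):
        with pytest.raises(ConfigurationError):
            perturb_mask(self._cube(), -1, seed=0)


class TestClinicalTable:
    def test_male_fraction_matches_profile(self):
        cfg = CohortConfig(counts={"ccRCC": 250, "pRCC": 0, "cRCC": 0},
                           shape=(10, 10, 10), seed=13)
        table = generate_clinical_table(generate_cohort(cfg))
        frac = (table["sex"] == "male").mean()
        assert frac == pytest.approx(136 / 207, abs=0.08)

    def test_single_record_fully_populated(self, small_cohort):
        table = generate_clinical_table(small_cohort[:1])
        assert len(table) == 1
        assert not table.isna().any().any()

    def test_attenuation_equals_mask_mean_recomputation(self, small_cohort):
        table = generate_clinical_table(small_cohort)
        for s in small_cohort:
            for ph in ("NCP", "CMP", "NP", "EP"):
                expected = s.volumes[ph].voxels[s.masks[1].voxels].mean()
                assert table.loc[s.id, f"att_{ph.lower()}"] == pytest.approx(expected)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_clinical_table([])
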
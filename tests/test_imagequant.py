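"""Confocal quantification: ratios, counting, intensity, Bernsen, puncta."""

import numpy as np
import pytest

from tdpfly import imagequant as iq
from tdpfly import synthdata
from tdpfly.synthdata import ImageSimParams
from tests_support import bernsen_oracle


# ----------------------------------------------------------- nuclear ratio


def test_ratio_uniform_and_depleted():
    img = np.full((20, 20), 7.0)
    nuc = np.zeros((20, 20), bool)
    nuc[8:12, 8:12] = True
    cell = np.zeros((20, 20), bool)
    cell[5:15, 5:15] = True
    m = iq.nuclear_total_ratio(img, nuc, cell)
    assert m.ratio == pytest.approx(1.0)

    img2 = np.where(nuc, 0.0, 5.0)
    assert iq.nuclear_total_ratio(img2, nuc, cell).ratio == 0.0


def test_ratio_invariant_to_global_scaling(rng):
    img = rng.random((30, 30)) + 0.5
    nuc = np.zeros((30, 30), bool)
    nuc[10:15, 10:15] = True
    cell = np.zeros((30, 30), bool)
    cell[5:25, 5:25] = True
    r1 = iq.nuclear_total_ratio(img, nuc, cell).ratio
    r2 = iq.nuclear_total_ratio(img * 37.5, nuc, cell).ratio
    assert r1 == pytest.approx(r2)


def test_ratio_errors():
    img = np.ones((10, 10))
    empty = np.zeros((10, 10), bool)
    some = np.zeros((10, 10), bool)
    some[2:4, 2:4] = True
    with pytest.raises(ValueError, match="empty"):
        iq.nuclear_total_ratio(img, empty, some)
    outside = np.zeros((10, 10), bool)
    outside[8:, 8:] = True
    with pytest.raises(ValueError, match="outside"):
        iq.nuclear_total_ratio(img, outside, some)


def test_depletion_grid_ratio_monotone():
    """Measured nuclear/whole-cell ratio decreases strictly with the planted
    depletion fraction, tracking 1 - depletion."""
    ratios = []
    for dep in [0.0, 0.25, 0.5, 0.75]:
        stack, truth = synthdata.gen_cell_stack(
            ImageSimParams(n_cells=4, depletion=dep, noise_sd=0.5, seed=17)
        )
        dye, yfp = stack
        vals = []
        for lab in range(1, truth["n_cells"] + 1):
            nuc = truth["nucleus_labels"] == lab
            cell = truth["cell_labels"] == lab
            vals.append(iq.nuclear_total_ratio(yfp, nuc, cell).ratio)
        ratios.append(np.mean(vals))
        assert ratios[-1] == pytest.approx(1 - dep, abs=0.05)
    assert all(a > b for a, b in zip(ratios, ratios[1:]))


def test_derive_masks_recovers_planted_sphere():
    stack, truth = synthdata.gen_cell_stack(
        ImageSimParams(
            shape=(1, 96, 96), n_cells=1, nucleus_radius_um=3.0, rim_width_um=1.0,
            noise_sd=2.0, seed=18,
        )
    )
    dye, yfp = stack[0][0], stack[1][0]
    nuc, cell = iq.derive_masks(dye, yfp)
    true_nuc = truth["nucleus_labels"][0] > 0
    iou = (nuc & true_nuc).sum() / (nuc | true_nuc).sum()
    assert iou > 0.8
    with pytest.raises(ValueError):
        iq.derive_masks(np.zeros((10, 10)), yfp)


# ----------------------------------------------------------- nucleus counts


def _disk_plane(shape, centers, radius_px):
    img = np.zeros(shape)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for cy, cx in centers:
        img[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius_px**2] = 100.0
    return img


def test_count_nuclei_exact_on_constructed_stack():
    """Nuclei confined to single selected planes are each counted once."""
    stack = np.zeros((8, 64, 64))
    stack[2] = _disk_plane((64, 64), [(10, 10), (30, 30), (50, 12)], 3)
    stack[6] = _disk_plane((64, 64), [(20, 48), (44, 44)], 3)
    count, info = iq.count_nuclei(stack, z_step_um=1.0, spacing_um=2.0, threshold=50.0)
    assert count == 5
    assert info["plane_step"] == 2
    assert not info["possible_overcount"]


def test_count_nuclei_overcount_warning():
    """A nucleus spanning two selected sections is double counted but flagged."""
    stack = np.zeros((8, 64, 64))
    plane = _disk_plane((64, 64), [(32, 32)], 4)
    stack[2] = plane
    stack[4] = plane
    with pytest.warns(UserWarning, match="inflated"):
        count, info = iq.count_nuclei(stack, 1.0, 2.0, threshold=50.0)
    assert count == 2
    assert info["possible_overcount"]


def test_count_nuclei_empty_and_errors():
    count, _ = iq.count_nuclei(np.zeros((4, 16, 16)), 1.0)
    assert count == 0
    with pytest.raises(ValueError, match="z spacing"):
        iq.count_nuclei(np.zeros((4, 16, 16)), float("nan"))


# -------------------------------------------------------- lobe intensity


def make_rois():
    lobe = np.zeros((32, 32), bool)
    lobe[4:12, 4:12] = True
    bg = np.zeros((32, 32), bool)
    bg[20:28, 20:28] = True
    return lobe, bg


def test_background_modes():
    lobe, bg = make_rois()
    flat = [np.full((32, 32), 9.0)] * 3
    res = iq.background_corrected_intensity(flat, lobe, bg, mode="subtract")
    assert res.value == pytest.approx(0.0)
    res = iq.background_corrected_intensity(flat, lobe, bg, mode="ratio")
    assert res.value == pytest.approx(1.0)
    double = [np.where(lobe, 8.0, 4.0)] * 3
    res = iq.background_corrected_intensity(double, lobe, bg, mode="ratio")
    assert res.value == pytest.approx(2.0)


def test_background_errors():
    lobe, bg = make_rois()
    with pytest.raises(ValueError, match="3 sections"):
        iq.background_corrected_intensity([np.ones((32, 32))] * 2, lobe, bg)
    with pytest.raises(ValueError, match="overlap"):
        iq.background_corrected_intensity([np.ones((32, 32))] * 3, lobe, lobe)


def test_young_group_normalization_self_mean_one():
    import pandas as pd

    df = pd.DataFrame(
        {
            "value": [2.0, 4.0, 3.0, 6.0, 9.0],
            "age_group": ["young", "young", "young", "old", "old"],
            "genotype": ["wt"] * 5,
            "lobe": ["gamma"] * 5,
        }
    )
    out = iq.normalize_to_young(df)
    assert out.loc[out.age_group == "young", "normalized"].mean() == pytest.approx(1.0)
    assert out.loc[out.age_group == "old", "normalized"].tolist() == [2.0, 3.0]


# ------------------------------------------------------ contrast + Bernsen


def test_enhance_contrast_ramp_and_range():
    img = np.linspace(0, 1, 10000).reshape(100, 100)
    out = iq.enhance_contrast(img, saturated_fraction=0.02)
    lo, hi = np.quantile(img, [0.01, 0.99])
    assert out.min() == 0.0 and out.max() == 1.0
    mid = img[50, 50]
    assert out[50, 50] == pytest.approx((mid - lo) / (hi - lo), abs=1e-6)
    const = np.full((10, 10), 3.0)
    assert np.array_equal(iq.enhance_contrast(const), const)


def test_bernsen_matches_bruteforce(rng):
    img = rng.integers(0, 256, (20, 20)).astype(float)
    for radius, cthr in [(2, 15), (3, 40)]:
        ours = iq.bernsen_threshold(img, radius=radius, contrast_threshold=cthr)
        assert np.array_equal(ours, bernsen_oracle(img, radius, cthr))


def test_bernsen_uniform_image_single_class():
    img = np.full((30, 30), 80.0)
    mask = iq.bernsen_threshold(img, radius=3)
    assert mask.all() or (~mask).all()


def test_bernsen_half_and_disc():
    img = np.zeros((20, 20))
    img[:, 10:] = 255.0
    mask = iq.bernsen_threshold(img, radius=3, contrast_threshold=15)
    assert np.array_equal(mask, bernsen_oracle(img, 3, 15))
    # planted bright disc interior is foreground
    img2 = _disk_plane((40, 40), [(20, 20)], 6)
    mask2 = iq.bernsen_threshold(img2, radius=8, contrast_threshold=15)
    assert mask2[20, 20]
    assert not mask2[2, 2]


def test_bernsen_rejects_oversized_radius():
    with pytest.raises(ValueError):
        iq.bernsen_threshold(np.zeros((10, 10)), radius=6)


# ------------------------------------------------------------- particles


def test_square_particle_retained_at_one_um2():
    mask = np.zeros((10, 10), bool)
    mask[4:6, 4:6] = True  # 4 px at 0.5 um/px -> 1.0 um^2
    ps = iq.analyze_particles(mask, 0.5)
    assert len(ps.particles) == 1
    assert ps.particles.area_um2[0] == pytest.approx(1.0)
    assert ps.particles.circularity[0] == 1.0  # 4*pi*4/16 > 1 -> clamped


def test_tiny_particle_excluded_by_area():
    mask = np.zeros((10, 10), bool)
    mask[5, 5] = True  # 0.01 um^2 at 0.1 um/px
    ps = iq.analyze_particles(mask, 0.1)
    assert len(ps.particles) == 0 and ps.n_rejected == 1


def test_inclusive_area_bound():
    mask = np.zeros((10, 10), bool)
    mask[5, 5] = True  # exactly 0.25 um^2 at 0.5 um/px
    ps = iq.analyze_particles(mask, 0.5)
    assert len(ps.particles) == 1


def test_thin_line_excluded_by_circularity():
    mask = np.zeros((10, 40), bool)
    mask[5, 5:35] = True  # 1 x 30 line: P = 2*29, circ = 4*pi*30/58^2 ~ 0.112
    ps = iq.analyze_particles(mask, 0.2)  # area 30 * 0.04 = 1.2 um^2, in range
    assert len(ps.particles) == 0 and ps.n_rejected == 1
    circ = 4 * np.pi * 30 / (2 * 29) ** 2
    assert circ < 0.25


def test_planted_discs_recovered_and_big_disc_excluded():
    params = ImageSimParams(
        shape=(1, 256, 256),
        pixel_size_um=0.25,
        puncta=[(1.0, 0.0)] * 20,
        noise_sd=0.5,
        seed=19,
    )
    img, truth = synthdata.gen_lobe_image(params)
    mask = img > 100.0
    ps = iq.analyze_particles(mask, 0.25)
    assert len(ps.particles) == 20
    assert ps.mean_area_um2 == pytest.approx(1.0, abs=0.15)

    big, _ = synthdata.gen_lobe_image(
        ImageSimParams(shape=(1, 128, 128), pixel_size_um=0.25,
                       puncta=[(5.0, 0.0)], noise_sd=0.5, seed=20)
    )
    ps2 = iq.analyze_particles(big > 100.0, 0.25)
    assert len(ps2.particles) == 0 and ps2.n_rejected == 1


def test_uncalibrated_rejected_and_mean_size():
    with pytest.raises(ValueError, match="uncalibrated"):
        iq.analyze_particles(np.zeros((5, 5), bool), 0.0)
    mask = np.zeros((10, 10), bool)
    mask[4:6, 4:6] = True
    sets = [iq.analyze_particles(mask, 0.5) for _ in range(3)]
    assert iq.mean_puncta_size(sets) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        iq.mean_puncta_size(sets[:2])
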
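"""Edge regions and region-level signal quantification vs brute-force oracles."""

import numpy as np
import pytest

from polarflip.regions import (
    edge_regions,
    normalized_region_signal,
    region_activity,
)


def oracle_edge_region(mask, direction, k, end):
    """Independent distance-sort oracle: list-of-tuples sort, no vectorization."""
    d = np.asarray(direction, float)
    d = d / np.hypot(*d)
    pixels = [(r, c) for r, c in zip(*np.nonzero(mask))]
    proj = {p: p[0] * d[0] + p[1] * d[1] for p in pixels}
    extreme = max(proj.values()) if end == "front" else min(proj.values())
    edge = [p for p in pixels if abs(proj[p] - extreme) < 1e-9]
    scored = sorted(
        (min((p[0] - e[0]) ** 2 + (p[1] - e[1]) ** 2 for e in edge), p[0], p[1])
        for p in pixels
    )
    out = np.zeros_like(mask)
    for _, r, c in scored[:k]:
        out[r, c] = True
    return out


def blob_mask(seed, shape=(110, 70)):
    rng = np.random.default_rng(seed)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    cr, ccn = rng.uniform(45, 65), rng.uniform(30, 40)
    a, b = rng.uniform(28, 40), rng.uniform(13, 18)
    return ((rr - cr) / a) ** 2 + ((cc - ccn) / b) ** 2 <= 1.0


def test_bar_front_region_is_top_rows():
    """A 10x200 bar moving up: the 800 px nearest the front edge are exactly
    the top 4 rows, and the rear mirrors them."""
    mask = np.ones((10, 200), bool)
    regs = edge_regions(mask, (-1.0, 0.0), 800)
    expect_front = np.zeros_like(mask)
    expect_front[:4] = True
    assert np.array_equal(regs.front_mask, expect_front)
    expect_rear = np.zeros_like(mask)
    expect_rear[-4:] = True
    assert np.array_equal(regs.rear_mask, expect_rear)


def test_small_mask_saturates_with_warning():
    mask = np.zeros((40, 40), bool)
    mask[5:25, 5:25] = True  # 400 px
    with pytest.warns(UserWarning, match="saturate"):
        regs = edge_regions(mask, (-1.0, 0.0), 800)
    assert np.array_equal(regs.front_mask, mask)
    assert np.array_equal(regs.rear_mask, mask)


@pytest.mark.parametrize("seed", range(5))
@pytest.mark.parametrize("direction", [(-1.0, 0.0), (1.0, 0.0), (0.4, -0.9)])
def test_edge_regions_match_oracle_exactly(seed, direction):
    mask = blob_mask(seed)
    assert 800 < mask.sum() <= 5000
    regs = edge_regions(mask, direction, 800)
    assert np.array_equal(regs.front_mask, oracle_edge_region(mask, direction, 800, "front"))
    assert np.array_equal(regs.rear_mask, oracle_edge_region(mask, direction, 800, "rear"))


def test_middle_is_central_third_of_axis():
    mask = np.ones((90, 10), bool)
    regs = edge_regions(mask, (-1.0, 0.0), 100)
    rows = np.nonzero(regs.middle_mask)[0]
    assert rows.min() == 30 and rows.max() == 59
    assert regs.middle_mask.sum() == 300


class TestRegionActivity:
    def setup_method(self):
        self.mask = np.zeros((60, 20), bool)
        self.mask[10:50, 5:15] = True
        self.regs = edge_regions(self.mask, (-1.0, 0.0), 100)

    def masked(self, arr):
        return np.where(self.mask, arr, np.nan)

    def test_equal_channels_unit_activity(self):
        d = self.masked(np.full((60, 20), 7.0))
        out = region_activity(d, d, self.regs, cell_mask=self.mask)
        assert all(v == pytest.approx(1.0) for v in out.values())

    def test_front_rear_step(self):
        donor = self.masked(np.ones((60, 20)))
        acceptor = np.where(np.arange(60)[:, None] < 30, 2.0, 1.0)
        acceptor = self.masked(acceptor)
        out = region_activity(donor, acceptor, self.regs, cell_mask=self.mask)
        assert out["front"] == pytest.approx(2.0)  # moving up: front = low rows
        assert out["rear"] == pytest.approx(1.0)

    def test_ratio_of_sums_not_mean_of_ratios(self):
        rng = np.random.default_rng(0)
        donor = self.masked(rng.uniform(1, 5, (60, 20)))
        acceptor = self.masked(rng.uniform(1, 5, (60, 20)))
        out = region_activity(donor, acceptor, self.regs, cell_mask=self.mask)
        sel = self.regs.front_mask
        assert out["front"] == pytest.approx(
            np.nansum(acceptor[sel]) / np.nansum(donor[sel])
        )

    def test_undefined_pixel_excluded_matches_bruteforce(self):
        rng = np.random.default_rng(1)
        donor = self.masked(rng.uniform(1, 5, (60, 20)))
        acceptor = self.masked(rng.uniform(1, 5, (60, 20)))
        r, c = 12, 8
        donor[r, c] = np.nan
        out = region_activity(donor, acceptor, self.regs, cell_mask=self.mask)
        sel = self.regs.front_mask & np.isfinite(donor)
        assert out["front"] == pytest.approx(acceptor[sel].sum() / donor[sel].sum())

    def test_common_rescaling_invariant(self):
        rng = np.random.default_rng(2)
        donor = self.masked(rng.uniform(1, 5, (60, 20)))
        acceptor = self.masked(rng.uniform(1, 5, (60, 20)))
        out1 = region_activity(donor, acceptor, self.regs, cell_mask=self.mask)
        out2 = region_activity(3.7 * donor, 3.7 * acceptor, self.regs, cell_mask=self.mask)
        for k in out1:
            assert out1[k] == pytest.approx(out2[k])

    def test_empty_region_rejected(self):
        donor = self.masked(np.full((60, 20), np.nan))
        with pytest.raises(ValueError, match="valid pixels"):
            region_activity(donor, donor, self.regs, cell_mask=self.mask)


class TestNormalizedSignal:
    def setup_method(self):
        self.mask = np.zeros((60, 20), bool)
        self.mask[10:50, 5:15] = True
        self.regs = edge_regions(self.mask, (-1.0, 0.0), 100)

    def test_uniform_signal_gives_pixel_fraction(self):
        sig = np.where(self.mask, 2.0, np.nan)
        out = normalized_region_signal(sig, self.regs, self.mask)
        assert out["front"] == pytest.approx(100 / 400)
        assert out["rear"] == pytest.approx(100 / 400)
        assert out["whole"] == 1.0

    def test_all_signal_in_rear(self):
        sig = np.zeros((60, 20))
        sig[self.regs.rear_mask] = 5.0
        out = normalized_region_signal(sig, self.regs, self.mask)
        assert out["rear"] == pytest.approx(1.0)
        assert out["front"] == pytest.approx(0.0)

    def test_random_image_matches_bruteforce(self):
        rng = np.random.default_rng(3)
        sig = np.where(self.mask, rng.uniform(0, 10, (60, 20)), np.nan)
        out = normalized_region_signal(sig, self.regs, self.mask)
        total = np.nansum(sig[self.mask])
        for name, region in [("front", self.regs.front_mask), ("rear", self.regs.rear_mask)]:
            assert out[name] == pytest.approx(np.nansum(sig[region]) / total)
            assert 0.0 <= out[name] <= 1.0

    def test_nonpositive_total_rejected(self):
        sig = np.zeros((60, 20))
        with pytest.raises(ValueError, match="positive"):
            normalized_region_signal(sig, self.regs, self.mask)
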
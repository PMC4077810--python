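import numpy as np
import pandas as pd
import pytest

from floodsel import mkde, simulate
from floodsel.home_range import RangeParams
from floodsel.raster import HabitatRaster


def traj_from_xy(xy, start="2008-05-01 00:00", freq="h"):
    xy = np.asarray(xy, dtype=float)
    return pd.DataFrame(
        {
            "animal_id": "A1",
            "timestamp": pd.date_range(start, periods=len(xy), freq=freq),
            "x": xy[:, 0],
            "y": xy[:, 1],
        }
    )


@pytest.fixture(scope="module")
def flat_raster():
    return HabitatRaster(classes=np.full((50, 50), 3), pixel_size=50.0)


PARAMS = RangeParams(mdt_m=66.0, t_max_h=10.0, h_min_m=116.0)


class TestClassifyActivity:
    def test_mdt_rule_with_boundary_inclusive(self):
        traj = traj_from_xy([(0, 0), (10, 0), (210, 0), (276, 0)])
        steps = mkde.classify_activity(traj, mdt=66.0)
        # 10 m: rest; 200 m: active; exactly 66 m: rest (<= rule)
        assert list(steps["rest"]) == [True, False, True]

    def test_all_zero_displacements_rest(self):
        steps = mkde.classify_activity(traj_from_xy([(0, 0)] * 5), mdt=66.0)
        assert steps["rest"].all()

    def test_unordered_timestamps_rejected(self):
        traj = traj_from_xy([(0, 0), (1, 1), (2, 2)])
        traj.loc[1, "timestamp"] = traj.loc[2, "timestamp"] + pd.Timedelta("1h")
        with pytest.raises(ValueError, match="increasing"):
            mkde.classify_activity(traj, mdt=66.0)


class TestDiffusion:
    def test_constant_steps(self):
        xy = np.c_[np.arange(10) * 200.0, np.zeros(10)]
        steps = mkde.classify_activity(traj_from_xy(xy), mdt=66.0, t_max=10.0)
        assert mkde.estimate_diffusion(steps) == 200.0**2 / 4.0

    def test_median_oracle_and_scale_law(self, rng):
        xy = np.cumsum(rng.normal(0, 300, size=(60, 2)), axis=0)
        steps = mkde.classify_activity(traj_from_xy(xy), mdt=66.0, t_max=10.0)
        d = mkde.estimate_diffusion(steps)
        sel = (~steps["rest"]) & steps["bridged"]
        oracle = np.median(
            steps.loc[sel, "length_m"] ** 2 / (4 * steps.loc[sel, "dt_h"])
        )
        assert d == oracle
        doubled = steps.copy()
        doubled["length_m"] *= 2
        assert mkde.estimate_diffusion(doubled) == pytest.approx(4 * d)

    def test_too_few_steps_rejected(self):
        steps = mkde.classify_activity(traj_from_xy([(0, 0), (500, 0)]),
                                       mdt=66.0, t_max=10.0)
        with pytest.raises(ValueError):
            mkde.estimate_diffusion(steps)


class TestUD:
    def test_single_fix_is_discretised_gaussian(self, flat_raster):
        udg = mkde.ud(traj_from_xy([(1225, 1225)]), flat_raster, PARAMS, D=0.0)
        assert udg.total == pytest.approx(1.0, abs=1e-9)
        i, j = np.unravel_index(np.argmax(udg.weights), udg.weights.shape)
        assert flat_raster.cell_of(1225, 1225) == (i, j)

    def test_bridge_concentrates_mass_along_segment(self, flat_raster):
        traj = traj_from_xy([(800, 1250), (1800, 1250)])
        D = 25_000.0
        udg = mkde.ud(traj, flat_raster, PARAMS, D=D)
        assert udg.total == pytest.approx(1.0, abs=1e-9)
        h_mid = np.sqrt(PARAMS.h_min_m**2 + D * 1.0)  # variance profile at p=1/2
        X, Y = flat_raster.cell_centres()
        seg_dist = np.where(
            (X >= 800) & (X <= 1800), np.abs(Y - 1250),
            np.minimum(np.hypot(X - 800, Y - 1250), np.hypot(X - 1800, Y - 1250)),
        )
        assert udg.weights[seg_dist <= 3 * h_mid].sum() > 0.95

    def test_boundary_clip_renormalises(self, flat_raster):
        boundary = np.array([(1225.0, -100.0), (1225.0, 3000.0)])
        udg = mkde.ud(
            traj_from_xy([(1100, 1225)]), flat_raster, PARAMS, D=0.0,
            boundary=boundary,
        )
        assert udg.total == pytest.approx(1.0, abs=1e-9)
        X, _ = flat_raster.cell_centres()
        assert udg.weights[X > 1225.0].sum() == 0.0

    def test_mass_conservation_on_simulated_trajectory(
        self, landscape, preference_trajectory
    ):
        steps = mkde.classify_activity(preference_trajectory, 66.0, t_max=10.0)
        D = mkde.estimate_diffusion(steps)
        udg = mkde.ud(preference_trajectory, landscape, PARAMS, D)
        assert udg.total == pytest.approx(1.0, abs=1e-9)
        assert (udg.weights >= 0).all()

    def test_kde_limit_matches_independent_oracle(self, flat_raster):
        """With D=0 and one substep the UD is a fixed-bandwidth KDE."""
        rng = np.random.default_rng(3)
        xy = 1250 + np.cumsum(rng.normal(0, 150, size=(40, 2)), axis=0)
        traj = traj_from_xy(xy)
        udg = mkde.ud(traj, flat_raster, PARAMS, D=0.0, n_substeps=1,
                      trunc_sds=50.0)
        # independent dense evaluation over the same kernel support
        steps = mkde.classify_activity(traj, PARAMS.mdt_m, t_max=PARAMS.t_max_h)
        centres = [(xy[0, 0], xy[0, 1], 1.0)]
        for st in steps.itertuples(index=False):
            if (not st.rest) and st.bridged:
                centres.append(((st.x0 + st.x1) / 2, (st.y0 + st.y1) / 2, st.dt_h))
            else:
                centres.append((st.x1, st.y1, st.dt_h))
        X, Y = flat_raster.cell_centres()
        h = PARAMS.h_min_m
        dense = np.zeros_like(X)
        for cx, cy, w in centres:
            dense += w * np.exp(-((X - cx) ** 2 + (Y - cy) ** 2) / (2 * h**2))
        dense /= dense.sum()
        assert np.abs(udg.weights - dense).max() < 1e-6

    def test_translation_equivariance(self, flat_raster):
        xy = np.array([(600, 600), (900, 700), (1200, 900), (1300, 1400)])
        udg = mkde.ud(traj_from_xy(xy), flat_raster, PARAMS, D=10_000.0)
        shift = np.array([730.0, -410.0])
        shifted_raster = HabitatRaster(
            classes=flat_raster.classes, origin_x=shift[0], origin_y=shift[1],
            pixel_size=50.0,
        )
        udg2 = mkde.ud(traj_from_xy(xy + shift), shifted_raster, PARAMS,
                       D=10_000.0)
        np.testing.assert_allclose(udg.weights, udg2.weights, atol=1e-12)

    def test_outside_raster_rejected(self, flat_raster):
        with pytest.raises(ValueError, match="outside"):
            mkde.ud(traj_from_xy([(99_000, 99_000)]), flat_raster, PARAMS, D=0.0)


class TestUDWeightedUse:
    def test_uniform_ud_recovers_availability(self, landscape):
        w = np.ones_like(landscape.classes, dtype=float)
        w /= w.sum()
        udg = mkde.UDGrid(raster=landscape, weights=w)
        use = mkde.ud_weighted_use(udg, landscape)
        avail = landscape.class_proportions()
        for c, p in avail.items():
            assert use[c] == pytest.approx(p, abs=1e-12)

    def test_point_mass_in_one_class(self, landscape):
        w = np.zeros_like(landscape.classes, dtype=float)
        i, j = np.argwhere(landscape.classes == 3)[0]
        w[i, j] = 1.0
        use = mkde.ud_weighted_use(mkde.UDGrid(raster=landscape, weights=w),
                                   landscape)
        assert use[3] == 1.0

    def test_matches_cellwise_oracle(self, landscape, rng):
        w = rng.uniform(size=landscape.classes.shape)
        w /= w.sum()
        use = mkde.ud_weighted_use(mkde.UDGrid(raster=landscape, weights=w),
                                   landscape)
        oracle = {}
        for i in range(landscape.n_rows):
            for j in range(landscape.n_cols):
                c = int(landscape.classes[i, j])
                oracle[c] = oracle.get(c, 0.0) + w[i, j]
        for c in oracle:
            assert use[c] == pytest.approx(oracle[c], rel=1e-12)
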
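"""Surface estimation, side assignment, consistency filters, phenotype calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wingspot import (
    ClassificationParams,
    assign_side,
    call_mwh,
    estimate_surface,
    filter_orientation_outliers,
    filter_shape_outliers,
    filter_surface_outliers,
    group_cells_and_spots,
)


def make_frame(roots, dirs=None, sides=None, **extra):
    roots = np.asarray(roots, dtype=float)
    n = len(roots)
    if dirs is None:
        dirs = np.tile([0.8, 0.2, 0.55], (n, 1))
    df = pd.DataFrame(
        {
            "label": np.arange(1, n + 1),
            "root_x_um": roots[:, 0],
            "root_y_um": roots[:, 1],
            "root_z_um": roots[:, 2],
            "dir_x": np.asarray(dirs)[:, 0],
            "dir_y": np.asarray(dirs)[:, 1],
            "dir_z": np.asarray(dirs)[:, 2],
            "length_um": extra.get("length_um", 4.0),
            "n_voxels": extra.get("n_voxels", 900),
            "anisotropy": extra.get("anisotropy", 6.0),
            "ambiguous": False,
            "discarded": extra.get("discarded", False),
            "discard_reason": "",
        }
    )
    if sides is not None:
        df["side"] = sides
    return df


def grid_roots(n_side, spacing=12.5, z=10.0):
    xs, ys = np.meshgrid(np.arange(n_side) * spacing, np.arange(n_side) * spacing)
    return np.column_stack([xs.ravel(), ys.ravel(), np.full(xs.size, z)])


class TestSurface:
    def test_flat_field_gives_zero_relative_altitude(self):
        df = make_frame(grid_roots(4, z=10.0))
        df = estimate_surface(df)
        np.testing.assert_allclose(df["z0_um"], 10.0)
        np.testing.assert_allclose(df["z_s_um"], 0.0)

    def test_alternating_altitudes_average_out(self):
        roots = grid_roots(6, spacing=6.0)
        roots[:, 2] = np.where(np.arange(len(roots)) % 2 == 0, 8.0, 12.0)
        df = estimate_surface(make_frame(roots))
        interior = (
            (df.root_x_um > 6) & (df.root_x_um < 24)
            & (df.root_y_um > 6) & (df.root_y_um < 24)
        )
        assert df.loc[interior, "z0_um"].between(9.0, 11.0).all()
        assert np.abs(df.loc[interior, "z_s_um"]).between(1.0, 3.0).all()

    def test_isolated_hair_flagged_low_confidence(self):
        roots = np.array([[0, 0, 10.0], [200, 0, 12.0], [210, 0, 12.0]])
        df = estimate_surface(make_frame(roots))
        assert df.loc[0, "surface_low_confidence"]
        assert df.loc[0, "z0_um"] == 12.0  # nearest other root
        assert not df.loc[2, "surface_low_confidence"]

    def test_needs_two_hairs(self):
        with pytest.raises(ValueError):
            estimate_surface(make_frame([[0, 0, 1.0]]))


class TestAssignSide:
    @pytest.mark.parametrize(
        "phi_sign,zs,expected",
        [(+1, +1.5, "top"), (-1, -1.5, "bottom"), (+1, -1.5, ""), (-1, +1.5, "")],
    )
    def test_sign_agreement_rule(self, phi_sign, zs, expected):
        df = make_frame([[0, 0, 10 + zs], [10, 0, 10], [0, 10, 10], [10, 10, 10]])
        df.loc[0, "dir_z"] = 0.5 * phi_sign
        df = estimate_surface(df)
        # pin the relative altitude of the hair under test
        df.loc[0, "z_s_um"] = zs
        df = assign_side(df)
        assert df.loc[0, "side"] == expected
        if expected == "":
            assert df.loc[0, "discard_reason"] == "side-inconsistent"


class TestOrientationFilter:
    def test_single_antiparallel_hair_is_flagged(self):
        roots = grid_roots(4)
        dirs = np.tile([0.8, 0.2, 0.55], (len(roots), 1))
        dirs[5] = [-0.8, -0.2, -0.55]
        df = filter_orientation_outliers(make_frame(roots, dirs))
        assert df["discarded"].sum() == 1
        assert df.loc[5, "discard_reason"] == "orientation"

    def test_uniform_field_has_no_flags(self):
        df = filter_orientation_outliers(make_frame(grid_roots(4)))
        assert df["discarded"].sum() == 0

    def test_hair_without_neighbors_is_not_flagged(self):
        df = make_frame([[0, 0, 10], [500, 500, 10]])
        df = filter_orientation_outliers(df)
        assert df["discarded"].sum() == 0


class TestShapeFilter:
    def test_merged_double_region_is_flagged(self):
        df = make_frame(grid_roots(6))
        df["n_voxels"] = 900 + np.arange(len(df)) % 7  # mild natural spread
        df.loc[7, "n_voxels"] = 1800  # 2x: an under-segmented merger
        df = filter_shape_outliers(df)
        assert df.loc[7, "discarded"]
        assert df.loc[7, "discard_reason"] == "shape"
        assert df["discarded"].sum() == 1

    def test_identical_hairs_produce_no_flags(self):
        df = filter_shape_outliers(make_frame(grid_roots(6)))
        assert df["discarded"].sum() == 0

    def test_too_few_hairs_warns_and_skips(self):
        df = make_frame(grid_roots(2))
        with pytest.warns(UserWarning, match="skipped"):
            df = filter_shape_outliers(df)
        assert df["discarded"].sum() == 0


class TestSurfaceFilter:
    def _frame(self):
        roots = grid_roots(5)
        df = make_frame(roots, sides=["top"] * len(roots))
        df["z_s_um"] = 1.0
        df["phi_rad"] = 0.5
        return df

    def test_altitude_outlier_flagged(self):
        df = self._frame()
        df.loc[3, "z_s_um"] = 1.0 + 5 * df["z_s_um"].std() + 3.0
        df = filter_surface_outliers(df)
        assert df.loc[3, "discard_reason"] == "surface-altitude"

    def test_ambiguous_angle_flagged(self):
        df = self._frame()
        df["phi_rad"] = 0.5 + np.linspace(-0.05, 0.05, len(df))
        df.loc[4, "phi_rad"] = 0.02  # well under 10% of the mean angle
        df = filter_surface_outliers(df)
        assert df.loc[4, "discard_reason"] == "surface-angle"

    def test_clean_field_unflagged(self):
        df = filter_surface_outliers(self._frame())
        assert df["discarded"].sum() == 0


class TestCallMwh:
    def _called(self, roots, sides):
        df = make_frame(roots, sides=sides)
        return call_mwh(df)["phenotype"]

    def test_close_same_side_pair_is_mwh(self):
        phen = self._called([[0, 0, 10], [3, 0, 10], [20, 20, 10]], ["top"] * 3)
        assert list(phen) == ["mwh", "mwh", "wt"]

    def test_normal_spacing_is_wild_type(self):
        phen = self._called([[0, 0, 10], [12.5, 0, 10]], ["top", "top"])
        assert list(phen) == ["wt", "wt"]

    def test_opposite_sides_never_pair(self):
        phen = self._called([[0, 0, 10], [3, 0, 26]], ["top", "bottom"])
        assert list(phen) == ["wt", "wt"]

    def test_discarded_hairs_get_no_phenotype_and_serve_no_neighbors(self):
        df = make_frame([[0, 0, 10], [3, 0, 10], [30, 0, 10]], sides=["top"] * 3)
        df.loc[1, "discarded"] = True
        df = call_mwh(df)
        assert list(df["phenotype"]) == ["wt", "", "wt"]

    @settings(max_examples=25, deadline=None)
    @given(st.lists(
        st.tuples(st.floats(0, 100), st.floats(0, 100)),
        min_size=2, max_size=25, unique=True,
    ))
    def test_phenotype_symmetry(self, points):
        roots = [[x, y, 10.0] for x, y in points]
        df = make_frame(roots, sides=["top"] * len(roots))
        df = call_mwh(df)
        pos = df[["root_x_um", "root_y_um", "root_z_um"]].to_numpy()
        phen = df["phenotype"].to_numpy()
        for i in range(len(pos)):
            for k in range(len(pos)):
                if i != k and np.linalg.norm(pos[i] - pos[k]) < 5.0:
                    assert phen[i] == "mwh" and phen[k] == "mwh"


class TestGrouping:
    def _grouped(self, roots, sides):
        df = make_frame(roots, sides=sides)
        df = call_mwh(df)
        return group_cells_and_spots(df)

    def test_three_close_hairs_one_cell_one_spot(self):
        df, g = self._grouped([[0, 0, 10], [3, 0, 10], [1.5, 2.5, 10]], ["top"] * 3)
        assert (g.n_mwh_hairs, g.n_cells, g.n_spots) == (3, 1, 1)

    def test_two_cells_fifteen_microns_apart_share_a_spot(self):
        roots = [[0, 0, 10], [3, 0, 10], [15, 0, 10], [18, 0, 10]]
        df, g = self._grouped(roots, ["top"] * 4)
        assert (g.n_cells, g.n_spots) == (2, 1)

    def test_two_cells_sixty_microns_apart_are_two_spots(self):
        roots = [[0, 0, 10], [3, 0, 10], [60, 0, 10], [63, 0, 10]]
        df, g = self._grouped(roots, ["top"] * 4)
        assert (g.n_cells, g.n_spots) == (2, 2)

    def test_cell_and_spot_ids_partition_mwh_hairs(self):
        roots = [[0, 0, 10], [3, 0, 10], [40, 0, 10], [43, 0, 10], [80, 80, 10]]
        df, g = self._grouped(roots, ["top"] * 5)
        mwh = df[df["phenotype"] == "mwh"]
        assert (mwh["cell_id"] >= 0).all() and (mwh["spot_id"] >= 0).all()
        assert (df.loc[df["phenotype"] != "mwh", "cell_id"] == -1).all()
        # cells nest inside spots
        assert (mwh.groupby("cell_id")["spot_id"].nunique() == 1).all()

    def test_invalid_mwh_threshold_rejected(self):
        with pytest.raises(ValueError, match="inter-hair"):
            ClassificationParams(mwh_threshold_um=20.0).validate()
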
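"""Tract table: shipped inventory, queries, serialization, mask-derived tables."""

import numpy as np
import pytest

from braingrid import (
    VolumeMask,
    build_table_from_masks,
    cells_of_tract,
    default_tract_table,
    load_tract_table,
    parse_label,
    tracts_in_cells,
)


@pytest.fixture(scope="module")
def table():
    return default_tract_table()


class TestDefaultTable:
    def test_inventory_has_34_structures(self, table):
        assert len(table) == 34

    def test_five_midline_and_fourteen_bilateral_names(self, table):
        midline = {e.name for e in table if e.hemisphere == "midline"}
        assert {"CC-genu", "CC-body", "CC-splenium", "AC", "Fo"} <= midline
        left = {e.name for e in table if e.hemisphere == "L"}
        right = {e.name for e in table if e.hemisphere == "R"}
        assert left == right and len(left) == 14

    @pytest.mark.parametrize(
        "cell, required",
        [
            # sub-insular/basal ganglia cells and their reported structures
            ("A3C2S2", {"IFOF-L", "UF-L", "ExC-L", "ATR-L"}),
            ("A2C2S2", {"IFOF-R", "UF-R", "ExC-R", "ATR-R"}),
            # fronto-medial cells
            ("A2C2S1", {"ATR-R", "CC-genu", "Ci-R", "IFOF-R"}),
            ("A3C2S1", {"ATR-L", "CC-genu", "Ci-L", "IFOF-L"}),
            # right insular-cortical/fronto-opercular cell
            ("A1C2S2", {"AF-R", "SLF-h-R", "FAT-R"}),
        ],
    )
    def test_reported_cell_structure_associations(self, table, cell, required):
        hits = {e.display_name for e, _ in tracts_in_cells([cell], table)}
        assert required <= hits

    def test_callosal_genu_spans_midline_cells(self, table):
        cells = cells_of_tract("CC-genu", "midline", table)
        assert {parse_label("A2C2S1"), parse_label("A3C2S1")} <= cells

    def test_left_uncinate_covers_subinsular_cell(self, table):
        assert parse_label("A3C2S2") in cells_of_tract("UF", "L", table)

    def test_unknown_structure_suggests_near_misses(self, table):
        with pytest.raises(KeyError, match="unknown structure"):
            cells_of_tract("XYZ", "L", table)
        with pytest.raises(KeyError, match="IFOF"):
            cells_of_tract("IFO", "L", table)

    def test_ranking_by_shared_cells(self, table):
        query = cells_of_tract("Ci", "L", table)  # all six cingulum cells
        ranked = tracts_in_cells(query, table)
        assert ranked[0][0].display_name == "Ci-L"
        shared = [n for _, n in ranked]
        assert shared == sorted(shared, reverse=True)


class TestSerialization:
    def test_round_trip(self, table, tmp_path):
        path = tmp_path / "table.tsv"
        table.save(path)
        loaded = load_tract_table(path)
        assert len(loaded) == len(table)
        for a, b in zip(table, loaded):
            assert a.key == b.key and a.cells == b.cells and a.category == b.category

    def test_invalid_label_rejected_with_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "name\themisphere\tcategory\tcells\n"
            "IFOF\tL\tassociative\tA3C2S2\n"
            "UF\tL\tassociative\tA9C1S1\n"
        )
        with pytest.raises(ValueError, match="line 3"):
            load_tract_table(path)

    def test_duplicate_entry_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text(
            "name\themisphere\tcategory\tcells\n"
            "IFOF\tL\tassociative\tA3C2S2\n"
            "IFOF\tL\tassociative\tA3C2S1\n"
        )
        with pytest.raises(ValueError, match="duplicate.*IFOF"):
            load_tract_table(path)

    def test_unknown_category_rejected(self, tmp_path):
        path = tmp_path / "cat.tsv"
        path.write_text(
            "name\themisphere\tcategory\tcells\nIFOF\tL\tlimbic\tA3C2S2\n"
        )
        with pytest.raises(ValueError, match="category"):
            load_tract_table(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "cols.tsv"
        path.write_text("name\themisphere\tcells\nIFOF\tL\tA3C2S2\n")
        with pytest.raises(ValueError, match="category"):
            load_tract_table(path)


class TestBuildFromMasks:
    def _bar_mask(self, geometry, x_range, y_range, z_range):
        centers = geometry.voxel_centers().reshape(*geometry.shape, 3)
        data = (
            (centers[..., 0] >= x_range[0]) & (centers[..., 0] <= x_range[1])
            & (centers[..., 1] >= y_range[0]) & (centers[..., 1] <= y_range[1])
            & (centers[..., 2] >= z_range[0]) & (centers[..., 2] <= z_range[1])
        )
        return VolumeMask(data=data, affine=geometry.affine.copy())

    def test_bar_spanning_two_cells(self, small_geometry, mni_grid):
        # thin bar across the midline at frontal y, mid z: A2C2S1 + A3C2S1
        bar = self._bar_mask(small_geometry, (-20, 20), (35, 45), (0, 10))
        table = build_table_from_masks({("CC-genu", "midline"): bar}, mni_grid,
                                       category="commissural")
        assert table.get("CC-genu").cells == {
            parse_label("A2C2S1"), parse_label("A3C2S1")
        }

    def test_single_voxel_mask(self, geometry, mni_grid):
        data = np.zeros(geometry.shape, bool)
        ijk = np.round(
            np.linalg.inv(geometry.affine) @ np.array([-10.0, 0.0, 0.0, 1.0])
        )[:3].astype(int)
        data[tuple(ijk)] = True
        mask = VolumeMask(data=data, affine=geometry.affine.copy())
        table = build_table_from_masks({("probe", "L"): mask}, mni_grid)
        assert table.get("probe").cells == {parse_label("A3C2S2")}

    def test_overlap_below_threshold_excluded(self, small_geometry, mni_grid):
        # asymmetric bar: one voxel column left of the midline, five right
        bar = self._bar_mask(small_geometry, (-4, 20), (35, 45), (0, 10))
        voxel = abs(np.linalg.det(small_geometry.affine[:3, :3]))
        table = build_table_from_masks({("CC-genu", "midline"): bar}, mni_grid,
                                       min_overlap_mm3=20 * voxel,
                                       category="commissural")
        assert table.get("CC-genu").cells == {parse_label("A2C2S1")}

    def test_empty_mask_rejected(self, small_geometry, mni_grid):
        empty = VolumeMask(np.zeros(small_geometry.shape, bool), small_geometry.affine)
        with pytest.raises(ValueError, match="probe"):
            build_table_from_masks({("probe", "L"): empty}, mni_grid)

    def test_round_trip_from_synthesized_masks(self, small_geometry, mni_grid, table):
        """Masks synthesized from a table's own cells recover it exactly."""
        from braingrid import export_grid_labelmap

        labelmap = export_grid_labelmap(small_geometry, mni_grid)
        masks = {}
        for entry in list(table)[:6]:
            ids = [lb.id for lb in entry.cells]
            masks[entry.key] = VolumeMask(
                data=np.isin(labelmap, ids), affine=small_geometry.affine.copy()
            )
        rebuilt = build_table_from_masks(
            masks, mni_grid, category={e.key: e.category for e in list(table)[:6]}
        )
        for entry in list(table)[:6]:
            assert rebuilt.get(*entry.key).cells == entry.cells
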
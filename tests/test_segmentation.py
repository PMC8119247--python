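"""Seeded region growing against an independent flood-fill oracle."""

from __future__ import annotations

from collections import deque

import numpy as np
import pytest

from pmct_overview import (
    AlgorithmConfig,
    CTVolume,
    SeedPoint,
    corner_seeds,
    generate_phantom,
    region_grow_exterior,
    segment_exterior_air,
    table_seeds,
)
from pmct_overview.phantom import TableArc

from conftest import random_volume


def flood_fill_oracle(voxels, seeds, threshold, full_connectivity=False):
    """Breadth-first flood fill written independently of the implementation."""
    if full_connectivity:
        offsets = [
            (dx, dy, dz)
            for dx in (-1, 0, 1)
            for dy in (-1, 0, 1)
            for dz in (-1, 0, 1)
            if (dx, dy, dz) != (0, 0, 0)
        ]
    else:
        offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    shape = voxels.shape
    visited = np.zeros(shape, dtype=bool)
    queue = deque()
    for s in seeds:
        idx = tuple(s)
        if voxels[idx] <= threshold and not visited[idx]:
            visited[idx] = True
            queue.append(idx)
    while queue:
        x, y, z = queue.popleft()
        for dx, dy, dz in offsets:
            n = (x + dx, y + dy, z + dz)
            if not all(0 <= n[a] < shape[a] for a in range(3)):
                continue
            if visited[n] or voxels[n] > threshold:
                continue
            visited[n] = True
            queue.append(n)
    return visited


class TestCornerSeeds:
    @pytest.mark.parametrize("shape", [(10, 10, 10), (2, 2, 2), (5, 7, 3)])
    def test_exactly_the_eight_corners(self, shape):
        vol = CTVolume(np.zeros(shape), (1, 1, 1))
        seeds = {tuple(s) for s in corner_seeds(vol)}
        expected = {
            (i, j, k)
            for i in (0, shape[0] - 1)
            for j in (0, shape[1] - 1)
            for k in (0, shape[2] - 1)
        }
        assert seeds == expected
        assert len(corner_seeds(vol)) == 8


class TestRegionGrow:
    def test_uniform_air_fills_everything(self):
        vol = CTVolume(np.full((6, 6, 6), -1000.0), (1, 1, 1))
        mask = region_grow_exterior(vol, corner_seeds(vol))
        assert mask.flags.all()

    def test_threshold_boundary_inclusive(self):
        # a voxel at exactly -200 HU is absorbed; -199 HU never is
        vol = CTVolume(np.full((5, 5, 5), -1000.0), (1, 1, 1))
        vol.voxels[2, 2, 2] = -200.0
        vol.voxels[2, 2, 3] = -199.0
        mask = region_grow_exterior(vol, corner_seeds(vol))
        assert mask.flags[2, 2, 2]
        assert not mask.flags[2, 2, 3]

    def test_enclosed_gas_is_never_flagged(self, body_with_gas):
        vol, truth = body_with_gas
        mask = region_grow_exterior(vol, corner_seeds(vol))
        assert not (mask.flags & truth.interior_gas_mask).any()
        np.testing.assert_array_equal(mask.flags, truth.exterior_air_mask)

    def test_no_above_threshold_voxel_flagged(self, rng):
        vol = random_volume(rng, (12, 12, 12), lo=-1100, hi=500)
        mask = region_grow_exterior(vol, corner_seeds(vol))
        assert not (mask.flags & (vol.voxels > -200.0)).any()

    @pytest.mark.parametrize("connectivity", ["face", "face+edge+corner"])
    def test_matches_flood_fill_oracle_on_random_volumes(self, rng, connectivity):
        config = AlgorithmConfig(connectivity=connectivity)
        for _ in range(5):
            # ~half the voxels are air: maximally tangled components
            vol = random_volume(rng, (14, 13, 12), lo=-600, hi=200)
            seeds = corner_seeds(vol)
            mask = region_grow_exterior(vol, seeds, config)
            oracle = flood_fill_oracle(
                vol.voxels, seeds, -200.0,
                full_connectivity=(connectivity != "face"),
            )
            np.testing.assert_array_equal(mask.flags, oracle)

    def test_matches_flood_fill_oracle_on_phantom(self, body_with_hollow_table):
        vol, _ = body_with_hollow_table
        config = AlgorithmConfig()
        mask, corners, table = segment_exterior_air(vol, config)
        oracle = flood_fill_oracle(vol.voxels, corners + table, -200.0)
        np.testing.assert_array_equal(mask.flags, oracle)

    def test_lowering_threshold_never_adds_voxels(self, rng):
        vol = random_volume(rng, (10, 10, 10), lo=-600, hi=200)
        seeds = corner_seeds(vol)
        prev = None
        for thr in (-150.0, -200.0, -250.0, -300.0):
            mask = region_grow_exterior(
                vol, seeds, AlgorithmConfig(air_threshold_hu=thr)
            )
            if prev is not None:
                assert (mask.flags <= prev).all()  # subset
            prev = mask.flags

    def test_table_seeds_only_grow_the_mask(self, body_with_hollow_table):
        vol, _ = body_with_hollow_table
        config = AlgorithmConfig()
        corners = corner_seeds(vol)
        without = region_grow_exterior(vol, corners, config)
        with_table = region_grow_exterior(
            vol, corners + table_seeds(vol, config), config
        )
        assert (without.flags <= with_table.flags).all()
        assert with_table.voxel_count > without.voxel_count

    def test_empty_seed_list_warns_and_returns_empty(self, caplog):
        vol = CTVolume(np.full((4, 4, 4), -1000.0), (1, 1, 1))
        with caplog.at_level("WARNING"):
            mask = region_grow_exterior(vol, [])
        assert not mask.flags.any()
        assert any("no seeds" in r.message for r in caplog.records)

    def test_seeds_on_material_are_skipped(self):
        vol = CTVolume(np.full((4, 4, 4), 100.0), (1, 1, 1))
        vol.voxels[0, :, :] = -1000.0
        seeds = corner_seeds(vol) + [SeedPoint((2, 2, 2))]
        mask = region_grow_exterior(vol, seeds)
        assert mask.flags[0].all() and not mask.flags[1:].any()


class TestTableSeeds:
    def test_hollow_table_seed_lies_in_cavity(self, body_with_hollow_table, fixtures):
        vol, truth = body_with_hollow_table
        seeds = table_seeds(vol, AlgorithmConfig())
        assert seeds, "expected seeds inside the hollow table"
        cavity = truth.exterior_air_mask.copy()
        # cavity = exterior air unreachable from the corners
        reachable = flood_fill_oracle(vol.voxels, corner_seeds(vol), -200.0)
        cavity &= ~reachable
        assert any(cavity[tuple(s)] for s in seeds)
        # every emitted seed is sub-threshold air
        assert all(vol.voxels[tuple(s)] <= -200.0 for s in seeds)

    def test_no_table_yields_no_seeds(self, fixtures):
        for name in ("body_only", "body_with_gas", "body_with_metal"):
            vol, _ = generate_phantom(fixtures[name])
            assert table_seeds(vol, AlgorithmConfig()) == []

    def test_solid_table_yields_no_seeds(self, fixtures):
        import dataclasses

        spec = fixtures["body_with_hollow_table"]
        solid = dataclasses.replace(
            spec, table=TableArc(center_xy=(24, 10), r_inner=16.0,
                                 r_outer=28.0, hollow=False)
        )
        vol, _ = generate_phantom(solid)
        # oracle: no scan line holds an air run behind a thin shell
        assert table_seeds(vol, AlgorithmConfig()) == []
        # and nothing is air inside the table: corner fill covers all air
        reachable = flood_fill_oracle(vol.voxels, corner_seeds(vol), -200.0)
        enclosed_air = (vol.voxels <= -200.0) & ~reachable
        # only the body's enclosed gas pocket remains unreachable
        _, truth = generate_phantom(solid)
        np.testing.assert_array_equal(enclosed_air, truth.interior_gas_mask)
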
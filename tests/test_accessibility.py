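"""Clearance grids, widest-path tunnels, site classification and pocket
volumes, checked against analytic constructions and an exhaustive
widest-path oracle."""

import heapq

import numpy as np
import pytest

from crypticsite.accessibility import (
    AccessibilityConfig,
    TunnelResult,
    build_grid,
    classify_site,
    curate_reference_check,
    find_tunnels,
    pocket_volume,
)
from crypticsite.synthetic import build_slab_with_channel, build_sphere_receptor


class TestBuildGrid:
    def test_single_atom_clearance(self):
        grid = build_grid(np.zeros((1, 3)), np.array([2.0]), spacing=0.5,
                          padding=6.0)
        v = grid.voxel_of(np.array([5.0, 0.0, 0.0]))
        assert grid.clearance[v] == pytest.approx(3.0, abs=1e-9)

    def test_inside_atom_negative(self):
        grid = build_grid(np.zeros((1, 3)), np.array([2.0]), spacing=0.5)
        v = grid.voxel_of(np.zeros(3))
        assert grid.clearance[v] == pytest.approx(-2.0, abs=1e-9)

    def test_matches_bruteforce_minimum(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(-5, 5, size=(50, 3))
        radii = rng.uniform(1.0, 2.0, size=50)
        grid = build_grid(coords, radii, spacing=1.0)
        # 100 random voxels against explicit min over atoms
        idx = rng.integers(0, np.array(grid.shape), size=(100, 3))
        for i in idx:
            p = grid.position_of(i)
            brute = np.min(np.linalg.norm(p - coords, axis=1) - radii)
            assert grid.clearance[tuple(i)] == pytest.approx(brute, abs=1e-9)

    def test_empty_structure_error(self):
        with pytest.raises(ValueError):
            build_grid(np.zeros((0, 3)), np.zeros(0))

    def test_spacing_validation(self):
        with pytest.raises(ValueError):
            build_grid(np.zeros((1, 3)), np.ones(1), spacing=3.0)


def _dijkstra_widest_oracle(clearance, start, boundary):
    """Independent max-min Dijkstra over the 6-connected voxel graph."""
    shape = clearance.shape
    best = np.full(shape, -np.inf)
    best[start] = clearance[start]
    heap = [(-clearance[start], start)]
    steps = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    while heap:
        negw, v = heapq.heappop(heap)
        w = -negw
        if w < best[v]:
            continue
        for d in steps:
            u = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            if not all(0 <= u[k] < shape[k] for k in range(3)):
                continue
            nw = min(w, clearance[u])
            if nw > best[u]:
                best[u] = nw
                heapq.heappush(heap, (-nw, u))
    return best[boundary].max()


class TestFindTunnels:
    def test_cylindrical_channel_bottleneck(self):
        # slab pierced by a 3.0-A channel: through-slab bottleneck 3.0 +/- 0.5
        slab = build_slab_with_channel(3.0)
        grid = build_grid(slab.coords, slab.radii, spacing=0.5,
                          padding=(0.0, 0.0, 6.0))
        tunnels = find_tunnels(grid, slab.sites[0].center)
        through = [t for t in tunnels if t.exit_face == "+z"][0]
        assert through.bottleneck == pytest.approx(3.0, abs=0.5)

    def test_sealed_cavity_has_no_wide_tunnel(self):
        rec = build_sphere_receptor([{"label": "buried", "bottleneck_radius": 0.0}])
        grid = build_grid(rec.coords, rec.radii, spacing=0.5)
        tunnels = find_tunnels(grid, rec.sites[0].center)
        best = max((t.bottleneck for t in tunnels), default=-np.inf)
        assert best < 1.5
        assert classify_site(tunnels) == "buried"

    def test_isolated_start_in_empty_space(self):
        grid = build_grid(np.array([[50.0, 50.0, 50.0]]), np.array([1.0]),
                          spacing=1.0, padding=8.0)
        tunnels = find_tunnels(grid, np.array([42.0, 42.0, 42.0]))
        assert classify_site(tunnels) == "open"

    def test_matches_exhaustive_widest_path_oracle(self):
        from crypticsite.accessibility import _boundary_mask, _max_bottleneck

        rng = np.random.default_rng(1)
        coords = rng.uniform(0, 10, size=(25, 3))
        radii = rng.uniform(0.8, 1.6, size=25)
        grid = build_grid(coords, radii, spacing=1.0, padding=3.0)
        assert max(grid.shape) <= 30
        start = grid.voxel_of(grid.position_of(np.array(grid.shape) // 2))
        boundary = _boundary_mask(grid.shape)
        ours = _max_bottleneck(grid.clearance, start, boundary)
        oracle = _dijkstra_widest_oracle(grid.clearance, start, boundary)
        assert ours == pytest.approx(oracle, abs=1e-12)

    def test_dilating_radii_shrinks_bottleneck(self):
        slab = build_slab_with_channel(3.0)
        results = []
        for delta in (0.0, 0.4):
            grid = build_grid(slab.coords, slab.radii + delta, spacing=0.5,
                              padding=(0.0, 0.0, 6.0))
            t = find_tunnels(grid, slab.sites[0].center)
            results.append([x for x in t if x.exit_face == "+z"][0].bottleneck)
        assert results[1] <= results[0]

    def test_buried_start_error(self):
        grid = build_grid(np.zeros((1, 3)), np.array([2.0]), spacing=0.5)
        with pytest.raises(ValueError, match="buried inside"):
            find_tunnels(grid, np.zeros(3))


class TestClassify:
    @pytest.mark.parametrize("bottleneck, expected", [
        (3.0, "open"),
        (1.2, "buried"),
        (1.7, "indeterminate"),
    ])
    def test_thresholds(self, bottleneck, expected):
        t = TunnelResult(bottleneck=bottleneck, path=np.zeros((2, 3)),
                         length=1.0, exit_face="+z", resolution=0.5)
        assert classify_site([t]) == expected

    def test_threshold_monotone(self):
        t = TunnelResult(bottleneck=2.2, path=np.zeros((2, 3)), length=1.0,
                         exit_face="+z", resolution=0.5)
        assert classify_site([t], AccessibilityConfig(2.0, 1.5)) == "open"
        # raising the open threshold can only demote, never promote
        assert classify_site([t], AccessibilityConfig(2.5, 1.5)) in (
            "indeterminate", "buried")

    def test_no_tunnels_is_buried(self):
        assert classify_site([]) == "buried"


def _box_cavity(inner=10.0, wall=3.0, r_atom=1.0):
    """Closed cubic shell: hollow interior of side ``inner``."""
    s = 1.0
    half = inner / 2 + r_atom
    lo, hi = -half - wall, half + wall
    xs = np.arange(lo, hi + 1e-9, s)
    pts = np.stack(np.meshgrid(xs, xs, xs, indexing="ij"), axis=-1).reshape(-1, 3)
    inside = np.all(np.abs(pts) < half, axis=1)
    return pts[~inside]


class TestPocketVolume:
    def test_hollow_cube_volume(self):
        pts = _box_cavity(inner=10.0)
        grid = build_grid(pts, np.full(len(pts), 1.0), spacing=0.5)
        v = pocket_volume(grid, np.zeros(3), region_radius=12.0, probe_radius=0.5)
        # interior clear region is a 10 A cube up to grid/probe tolerance
        assert v == pytest.approx(1000.0, rel=0.15)

    def test_solid_region_zero(self):
        pts = np.stack(np.meshgrid(*[np.arange(-3, 3.1, 1.0)] * 3,
                                   indexing="ij"), axis=-1).reshape(-1, 3)
        grid = build_grid(pts, np.full(len(pts), 1.2), spacing=0.5)
        assert pocket_volume(grid, np.zeros(3), 2.0, probe_radius=0.5) == 0.0

    def test_sphere_cavity_quadrature(self):
        rec = build_sphere_receptor([{"label": "buried", "bottleneck_radius": 0.0}],
                                    shell_radius=10.0)
        grid = build_grid(rec.coords, rec.radii, spacing=0.5)
        probe = 1.4
        v = pocket_volume(grid, rec.sites[0].center, region_radius=12.0,
                          probe_radius=probe)
        # probe-eroded cavity radius ~ shell - atom radius - probe
        r_eff = 10.0 - 1.7 - probe
        expected = 4.0 / 3.0 * np.pi * r_eff**3
        assert v == pytest.approx(expected, rel=0.10)

    def test_open_region_not_counted(self):
        # a site connected to bulk has no *enclosed* volume
        rec = build_sphere_receptor([{"label": "open", "bottleneck_radius": 3.0}])
        grid = build_grid(rec.coords, rec.radii, spacing=0.5)
        v = pocket_volume(grid, rec.sites[0].center, 10.0, probe_radius=1.4)
        assert v < 100.0


class TestCurateReferenceCheck:
    def _entry(self, name, label):
        rec = build_sphere_receptor([{"label": label,
                                      "bottleneck_radius": 3.0 if label == "open" else 0.0}])
        return {"name": name, "coords": rec.coords, "radii": rec.radii,
                "site_center": rec.sites[0].center}

    def test_two_planted_receptors(self):
        rep = curate_reference_check([self._entry("a", "open"),
                                      self._entry("b", "buried")])
        assert rep["classification"].tolist() == ["open", "buried"]

    def test_empty_batch(self):
        rep = curate_reference_check([])
        assert len(rep) == 0

    def test_ten_of_thirteen_open(self):
        entries = [self._entry(f"p{i}", "open") for i in range(10)]
        entries += [self._entry(f"b{i}", "buried") for i in range(3)]
        rep = curate_reference_check(entries)
        assert (rep["classification"] == "open").sum() == 10
        assert len(rep) == 13

    def test_bad_entry_skipped(self):
        rep = curate_reference_check([{"name": "broken"}])
        assert rep["classification"].tolist() == ["error"]
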
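"""Constructed sphere-model receptors with planted binding sites.

A receptor is a cloud of hard spheres (one per PDB atom record).  Sites are
planted with known ground truth:

* an **open** site is a cavity connected to bulk through a cylindrical
  channel whose inner radius is set by construction, so the widest-path
  bottleneck from the site centre to solvent equals the channel radius up to
  grid resolution;
* a **buried** site is a cavity enclosed by a shell packed densely enough
  that no gap wider than the stated bottleneck remains (a double-layer
  shell seals the cavity completely, bottleneck ~0).

Ground-truth annotations (site centre, stated bottleneck radius, label) are
emitted alongside the geometry so downstream accessibility analysis can be
validated without peeking at them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: Frozen van der Waals radii (A) for the element symbols the bead models
#: use.  Values follow the Bondi set rounded to 2 decimals.
VDW_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
    "P": 1.80,
}


@dataclass(frozen=True)
class PlantedSite:
    center: np.ndarray          # (3,) A
    bottleneck_radius: float    # A, ground truth by construction
    label: str                  # "open" | "buried"


@dataclass
class SphereReceptor:
    """Sphere-model receptor: atom centres, radii, subunit labels, sites."""

    coords: np.ndarray          # (n_atoms, 3) A
    radii: np.ndarray           # (n_atoms,) A
    subunits: np.ndarray        # (n_atoms,) str chain labels
    sites: list[PlantedSite] = field(default_factory=list)

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def ground_truth(self) -> list[dict]:
        return [
            {
                "center": [float(v) for v in s.center],
                "bottleneck_radius": float(s.bottleneck_radius),
                "label": s.label,
            }
            for s in self.sites
        ]

    def write_pdb(self, path: str | Path) -> None:
        """Write one sphere per HETATM record (element C, radius in B-factor)."""
        import biotite.structure as struc
        import biotite.structure.io.pdb as pdb

        arr = struc.AtomArray(self.n_atoms)
        arr.coord = np.asarray(self.coords, np.float32)
        arr.chain_id = np.asarray(self.subunits, dtype="U4")
        arr.res_id = np.arange(1, self.n_atoms + 1)
        arr.res_name = np.full(self.n_atoms, "SPH")
        arr.atom_name = np.full(self.n_atoms, "C")
        arr.element = np.full(self.n_atoms, "C")
        arr.hetero = np.full(self.n_atoms, True)
        arr.set_annotation("b_factor", np.asarray(self.radii, float))
        f = pdb.PDBFile()
        f.set_structure(arr)
        f.write(str(path))

    def write_ground_truth(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.ground_truth(), indent=2))


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately equidistant unit vectors (deterministic)."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z**2))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def _shell_points(center: np.ndarray, shell_radius: float, spacing: float) -> np.ndarray:
    """Points on a sphere of given radius with nearest-neighbour spacing ~spacing."""
    n = max(8, int(np.ceil(4.0 * np.pi * shell_radius**2 / (0.75 * spacing**2))))
    return center + shell_radius * _fibonacci_sphere(n)


def _spacing_for_pore(pore_radius: float, atom_radius: float) -> float:
    # Clearance at the circumcentre of an equilateral lattice triangle of
    # side s is s/sqrt(3) - r_atom; invert for the requested pore radius.
    return np.sqrt(3.0) * (pore_radius + atom_radius)


def build_sphere_receptor(
    site_specs: list[dict],
    shell_radius: float = 12.0,
    atom_radius: float = 1.70,
    seed: int = 0,
) -> SphereReceptor:
    """Build a receptor with one shell cavity per requested site.

    Parameters
    ----------
    site_specs : list of dicts with keys
        ``label`` ("open" | "buried"), ``bottleneck_radius`` (A, > 0 for
        open sites; for buried sites 0 means fully sealed, > 0 means shell
        pores no wider than the stated radius), optional ``center``.
    shell_radius : float
        Cavity shell radius, A.  Cavities are spaced apart automatically
        when no centres are given.

    Raises
    ------
    ValueError
        For infeasible geometry, e.g. a channel wider than the shell.
    """
    coords: list[np.ndarray] = []
    radii: list[float] = []
    chains: list[str] = []
    sites: list[PlantedSite] = []
    chain_ids = "ABCDEFGHIJ"

    offset_step = 2 * shell_radius + 14.0
    for k, spec in enumerate(site_specs):
        label = spec["label"]
        b = float(spec["bottleneck_radius"])
        if label == "open" and b <= 0:
            raise ValueError("open-site bottleneck radius must be > 0")
        if b < 0:
            raise ValueError("bottleneck radius must be >= 0")
        center = np.asarray(spec.get("center", [k * offset_step, 0.0, 0.0]), float)

        if label == "open":
            channel_outer = b + atom_radius
            if channel_outer >= 0.8 * shell_radius:
                raise ValueError(
                    f"channel radius {b} A infeasible for shell radius {shell_radius} A"
                )
            # Dense shell (pores well below the channel radius), minus a
            # polar cap around +z, plus a tube lining the channel.
            pore = min(0.35 * b, 0.8)
            pts = _shell_points(center, shell_radius, _spacing_for_pore(pore, atom_radius))
            # second offset layer seals residual lattice pores
            pts2 = _shell_points(center, shell_radius + 1.2 * atom_radius,
                                 _spacing_for_pore(pore, atom_radius))
            rot = _rotz(np.pi / 7)  # offset layer de-aligned from the first
            pts2 = center + (pts2 - center) @ rot.T
            cap_r = channel_outer + 1.5 * atom_radius
            sin_theta = min(0.95, cap_r / shell_radius)
            keep = []
            for p in (pts, pts2):
                rel = p - center
                shell_r = np.linalg.norm(rel[:, :2], axis=1)  # distance from z axis
                in_cap = (rel[:, 2] > 0) & (shell_r < cap_r)
                keep.append(p[~in_cap])
            shell_pts = np.vstack(keep)
            tube = _channel_tube(
                center, axis_start=0.35 * shell_radius,
                axis_end=shell_radius + 3.0 * atom_radius,
                inner_radius=b, atom_radius=atom_radius,
            )
            site_pts = np.vstack([shell_pts, tube])
            sites.append(PlantedSite(center=center, bottleneck_radius=b, label="open"))
        elif label == "buried":
            # b == 0 requests a fully sealed cavity; b > 0 bounds the pore
            # radius from above (the offset second layer seals lattice pores,
            # so the stated bottleneck is an upper bound on the realized one)
            pore = 0.3 if b == 0.0 else b
            s = _spacing_for_pore(pore, atom_radius)
            pts = _shell_points(center, shell_radius, s)
            pts2 = _shell_points(center, shell_radius + 1.2 * atom_radius, s)
            rot = _rotz(np.pi / 7)
            pts2 = center + (pts2 - center) @ rot.T
            site_pts = np.vstack([pts, pts2])
            sites.append(PlantedSite(center=center, bottleneck_radius=b, label="buried"))
        else:
            raise ValueError(f"unknown site label {label!r}")

        coords.append(site_pts)
        radii.extend([atom_radius] * len(site_pts))
        chains.extend([chain_ids[k % len(chain_ids)]] * len(site_pts))

    return SphereReceptor(
        coords=np.vstack(coords),
        radii=np.asarray(radii),
        subunits=np.asarray(chains),
        sites=sites,
    )


def _rotz(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _channel_tube(center: np.ndarray, axis_start: float, axis_end: float,
                  inner_radius: float, atom_radius: float) -> np.ndarray:
    """Atoms lining a +z cylinder so its clear inner radius is ``inner_radius``."""
    ring_r = inner_radius + atom_radius
    n_ring = max(8, int(np.ceil(2.0 * np.pi * ring_r / (1.0 * atom_radius))))
    theta = np.linspace(0.0, 2.0 * np.pi, n_ring, endpoint=False)
    zs = np.arange(axis_start, axis_end + 1e-9, 1.2 * atom_radius)
    pts = []
    for i, z in enumerate(zs):
        off = (i % 2) * (np.pi / n_ring)  # stagger rings to close axial gaps
        pts.append(np.stack([
            ring_r * np.cos(theta + off),
            ring_r * np.sin(theta + off),
            np.full(n_ring, z),
        ], axis=1))
    return center + np.vstack(pts)


def build_slab_with_channel(
    channel_radius: float,
    slab_half_width: float = 12.0,
    slab_thickness: float = 8.0,
    atom_radius: float = 1.70,
) -> SphereReceptor:
    """A slab of spheres in the xy plane pierced by a +z cylindrical channel.

    The analytic widest-path bottleneck from a point below the slab centre
    to bulk above it is exactly ``channel_radius``.
    """
    spacing = 1.2 * atom_radius
    xs = np.arange(-slab_half_width, slab_half_width + 1e-9, spacing)
    zs = np.arange(-slab_thickness / 2, slab_thickness / 2 + 1e-9, spacing)
    xx, yy, zz = np.meshgrid(xs, xs, zs, indexing="ij")
    pts = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)
    r_axis = np.linalg.norm(pts[:, :2], axis=1)
    keep = r_axis >= channel_radius + atom_radius
    pts = pts[keep]
    # line the hole with rings at exactly channel_radius + atom_radius so the
    # realized clear radius is the nominal one, not the lattice-carved one
    ring_r = channel_radius + atom_radius
    n_ring = max(8, int(np.ceil(2.0 * np.pi * ring_r / atom_radius)))
    theta = np.linspace(0.0, 2.0 * np.pi, n_ring, endpoint=False)
    rings = [np.stack([ring_r * np.cos(theta), ring_r * np.sin(theta),
                       np.full(n_ring, z)], axis=1) for z in zs]
    pts = np.vstack([pts] + rings)
    rec = SphereReceptor(
        coords=pts,
        radii=np.full(len(pts), atom_radius),
        subunits=np.full(len(pts), "A"),
        sites=[PlantedSite(center=np.array([0.0, 0.0, -slab_thickness / 2 - 3.0]),
                           bottleneck_radius=channel_radius, label="open")],
    )
    return rec
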
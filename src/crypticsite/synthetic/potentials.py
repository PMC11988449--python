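"""Toy potential-energy landscapes with known Boltzmann equilibria.

A :class:`ToyPotential` is a sum of inverted Gaussian wells on a quadratic
confinement:

    U(x) = 0.5 * k_conf * |x|^2  -  sum_i  A_i * exp(-|x - c_i|^2 / (2 s_i^2))

Energies are in kT units, coordinates in nanometres.  The quadratic term
keeps exp(-U/kT) integrable, so the stationary density of overdamped
dynamics on U is a proper Boltzmann distribution that can be computed by
quadrature and compared with long simulations.

The stock landscapes model a slow "pocket opening" transition: the deepest
well is the closed-pocket state, a rare shallow well far from the wall
anchors plays the open-pocket state, and barriers of a few kT make the
transition slow on the Brownian timescale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class ToyPotential:
    """Sum of inverted Gaussians on a quadratic confinement.

    Parameters
    ----------
    centers : (n_wells, dim) array
        Well centres, nm.
    depths : (n_wells,) array
        Well depths A_i in kT units (positive numbers; wells are attractive).
    widths : (n_wells,) array
        Gaussian width s_i of each well, nm.
    k_conf : float
        Spring constant of the quadratic confinement, kT / nm^2.
    """

    centers: np.ndarray
    depths: np.ndarray
    widths: np.ndarray
    k_conf: float = 0.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "centers", np.atleast_2d(np.asarray(self.centers, float)))
        object.__setattr__(self, "depths", np.asarray(self.depths, float))
        object.__setattr__(self, "widths", np.asarray(self.widths, float))
        if self.centers.shape[0] != self.depths.shape[0] or self.centers.shape[0] != self.widths.shape[0]:
            raise ValueError("centers, depths and widths must have one entry per well")
        if np.any(self.widths <= 0):
            raise ValueError("well widths must be positive")
        if self.k_conf < 0:
            raise ValueError("confinement constant must be >= 0")

    @property
    def dim(self) -> int:
        return self.centers.shape[1]

    def energy(self, x: np.ndarray) -> np.ndarray:
        """Potential energy (kT) at positions ``x`` of shape (..., dim)."""
        x = np.asarray(x, float)
        u = 0.5 * self.k_conf * np.sum(x**2, axis=-1)
        for c, a, s in zip(self.centers, self.depths, self.widths):
            d2 = np.sum((x - c) ** 2, axis=-1)
            u = u - a * np.exp(-d2 / (2.0 * s**2))
        return u

    def gradient(self, x: np.ndarray) -> np.ndarray:
        """dU/dx (kT / nm) at positions ``x`` of shape (..., dim)."""
        x = np.asarray(x, float)
        g = self.k_conf * x
        for c, a, s in zip(self.centers, self.depths, self.widths):
            diff = x - c
            d2 = np.sum(diff**2, axis=-1, keepdims=True)
            g = g + a / s**2 * diff * np.exp(-d2 / (2.0 * s**2))
        return g


def harmonic_well(dim: int = 2, k: float = 1.0) -> ToyPotential:
    """Single harmonic well U = 0.5 k |x|^2 (no Gaussian wells)."""
    return ToyPotential(
        centers=np.zeros((1, dim)), depths=np.zeros(1), widths=np.ones(1), k_conf=k
    )


def flat_potential(dim: int = 2) -> ToyPotential:
    """Free diffusion: U = 0 everywhere."""
    return ToyPotential(
        centers=np.zeros((1, dim)), depths=np.zeros(1), widths=np.ones(1), k_conf=0.0
    )


def double_well(depths: tuple[float, float] = (5.0, 3.0), separation: float = 2.0,
                width: float = 0.35, k_conf: float = 0.5) -> ToyPotential:
    """Two wells of unequal depth on the x axis, equal widths.

    With equal widths the equilibrium occupancy ratio of the two basins is
    exp(depth difference) up to the quadratic-confinement correction, which
    quadrature makes exact.
    """
    c = separation / 2.0
    return ToyPotential(
        centers=np.array([[-c, 0.0], [c, 0.0]]),
        depths=np.array(depths, float),
        widths=np.array([width, width]),
        k_conf=k_conf,
    )


#: Default wall-anchor positions (nm) used to featurize 2D toy conformers:
#: distances from the moving "loop bead" to these fixed "wall beads" play the
#: role of the loop-wall pairwise distances.  They sit next to the closed
#: basin so that the rare open basin maximises the mean distance.
WALL_ANCHORS_2D = np.array([[-0.4, -0.4], [-0.4, 0.4], [0.4, -0.4]])


def three_well(open_depth: float = 4.8, k_conf: float = 2.0) -> ToyPotential:
    """Three metastable basins: closed (deep), intermediate, and open (rare).

    The open basin sits farthest from :data:`WALL_ANCHORS_2D`, so the mean
    anchor distance — the directed "pocket openness" metric — is maximal
    there.  Barriers between adjacent basins exceed 3 kT, making the
    closed-to-open transition slow for plain Brownian dynamics.
    """
    return ToyPotential(
        centers=np.array([[0.0, 0.0], [1.2, 0.0], [1.2, 1.2]]),
        depths=np.array([10.0, 6.5, open_depth]),
        widths=np.array([0.30, 0.30, 0.30]),
        k_conf=k_conf,
    )


def boltzmann_density_2d(potential: ToyPotential, extent: float = 3.0,
                         n_grid: int = 201) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalised Boltzmann density exp(-U) on a square quadrature grid.

    Returns (x_edges, y_edges, density) with density normalised so that
    sum(density) * cell_area = 1.  kT = 1 in the reduced units of U.
    """
    if potential.dim != 2:
        raise ValueError("quadrature helper is 2D only")
    edges = np.linspace(-extent, extent, n_grid + 1)
    mid = 0.5 * (edges[:-1] + edges[1:])
    xx, yy = np.meshgrid(mid, mid, indexing="ij")
    pts = np.stack([xx, yy], axis=-1)
    w = np.exp(-potential.energy(pts))
    cell = (edges[1] - edges[0]) ** 2
    return edges, edges, w / (w.sum() * cell)


def basin_occupancy_ratio(potential: ToyPotential, well_a: int, well_b: int,
                          extent: float = 3.0, n_grid: int = 401) -> float:
    """Equilibrium occupancy ratio P(basin a)/P(basin b) by quadrature.

    Basins are defined by Voronoi assignment of grid cells to well centres.
    """
    edges = np.linspace(-extent, extent, n_grid + 1)
    mid = 0.5 * (edges[:-1] + edges[1:])
    xx, yy = np.meshgrid(mid, mid, indexing="ij")
    pts = np.stack([xx, yy], axis=-1)
    w = np.exp(-potential.energy(pts))
    d = np.stack(
        [np.sum((pts - c) ** 2, axis=-1) for c in potential.centers], axis=0
    )
    lab = np.argmin(d, axis=0)
    pa = w[lab == well_a].sum()
    pb = w[lab == well_b].sum()
    return float(pa / pb)
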
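"""Overdamped (Brownian) dynamics on toy potentials.

Euler-Maruyama integration of

    dx = -grad U(x) dt + sqrt(2 kT dt) dW

in reduced units (unit friction and diffusion coefficient kT).  The
stationary density is the Boltzmann distribution exp(-U/kT), which makes
these trajectories a stand-in for unbiased MD: the same featurization, MSM
and reweighting machinery that would consume MD frames runs on them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .potentials import ToyPotential


@dataclass(frozen=True)
class ToyTrajectory:
    """Positions of one or more walkers over time.

    positions has shape (n_walkers, n_steps + 1, dim), in nm.  Regenerable
    bit-exactly from (potential, start, n_steps, timestep, kT, seed).
    """

    positions: np.ndarray
    timestep: float
    kT: float
    seed: int

    @property
    def n_walkers(self) -> int:
        return self.positions.shape[0]

    @property
    def n_steps(self) -> int:
        return self.positions.shape[1] - 1


def _min_well_separation(potential: ToyPotential) -> float:
    c = potential.centers
    if len(c) < 2:
        return np.inf
    d = np.linalg.norm(c[:, None, :] - c[None, :, :], axis=-1)
    return float(d[np.triu_indices(len(c), 1)].min())


def simulate_brownian(
    potential: ToyPotential,
    start: np.ndarray,
    n_steps: int,
    timestep: float = 0.01,
    kT: float = 1.0,
    seed: int = 0,
    stride: int = 1,
) -> ToyTrajectory:
    """Integrate overdamped dynamics from ``start``.

    Parameters
    ----------
    start : (dim,) or (n_walkers, dim) array
        Initial position(s).  Multiple walkers are integrated in lockstep
        with independent noise (vectorised, one RNG stream).
    n_steps : int
        Number of integration steps (>= 1).
    timestep : float
        Reduced time step.  Must keep the single-step noise displacement SD
        sqrt(2 kT dt) below 0.2x the minimum well separation, otherwise the
        integrator would hop basins unphysically.
    stride : int
        Store every ``stride``-th frame (the start frame is always stored).

    Raises
    ------
    FloatingPointError
        If the force becomes non-finite, reporting the offending coordinate.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if timestep <= 0 or kT <= 0:
        raise ValueError("timestep and kT must be positive")
    step_sd = np.sqrt(2.0 * kT * timestep)
    min_sep = _min_well_separation(potential)
    if step_sd >= 0.2 * min_sep:
        raise ValueError(
            f"timestep too large: single-step displacement SD {step_sd:.3g} nm "
            f">= 0.2 x minimum well separation {min_sep:.3g} nm"
        )
    x = np.atleast_2d(np.asarray(start, float)).copy()
    if x.shape[1] != potential.dim:
        raise ValueError(f"start dimension {x.shape[1]} != potential dim {potential.dim}")
    rng = np.random.default_rng(seed)
    n_saved = n_steps // stride
    out = np.empty((x.shape[0], n_saved + 1, x.shape[1]))
    out[:, 0] = x
    save_i = 1
    for t in range(1, n_steps + 1):
        g = potential.gradient(x)
        if not np.all(np.isfinite(g)):
            bad = np.argwhere(~np.isfinite(g))[0]
            raise FloatingPointError(
                f"non-finite force at walker {bad[0]}, coordinate {bad[1]}, "
                f"position {x[bad[0]]}"
            )
        x = x - g * timestep + step_sd * rng.standard_normal(x.shape)
        if t % stride == 0:
            out[:, save_i] = x
            save_i += 1
    return ToyTrajectory(positions=out[:, :save_i], timestep=timestep, kT=kT, seed=seed)
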
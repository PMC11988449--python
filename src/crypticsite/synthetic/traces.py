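"""Synthetic ligand trajectories for the stability screen.

Replicate MD simulations of a docked complex are emulated at the level the
stability filter consumes: the ligand centre of mass either diffuses within
a bounded neighbourhood of its docked position (a *stable* pose) or escapes
to bulk (an *unstable* pose).  Traces are Ornstein-Uhlenbeck (stable) or
OU-plus-drift (escaping) paths of the COM displacement, seeded.
"""

from __future__ import annotations

import numpy as np


def synth_com_trace(
    stable: bool,
    n_frames: int = 300,
    bound_sd: float = 2.0,
    escape_rate: float = 0.12,
    seed: int = 0,
) -> np.ndarray:
    """COM-RMSD trace (A) of one replicate.

    Stable: reflected OU process with stationary SD ``bound_sd`` about a
    ~3 A converged displacement, staying far below the 15 A threshold.
    Unstable: the same local diffusion plus linear escape drift, crossing
    15 A well before the trace ends.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    rng = np.random.default_rng(seed)
    theta, dt = 0.5, 1.0
    x = 0.0
    out = np.empty(n_frames)
    for t in range(n_frames):
        if stable:
            # OU relaxation toward a ~3 A converged displacement
            x = x + theta * (3.0 - x) * dt \
                + bound_sd * np.sqrt(dt) * 0.5 * rng.standard_normal()
        else:
            # unbound ligand: steady outward drift, no restoring force
            x = x + escape_rate * dt \
                + bound_sd * np.sqrt(dt) * 0.5 * rng.standard_normal()
        x = abs(x)
        out[t] = x
    return out


def synth_ligand_ensemble(
    site_center: np.ndarray,
    n_frames: int = 50,
    jitter_sd: float = 0.8,
    n_ligand_atoms: int = 3,
    seed: int = 0,
) -> np.ndarray:
    """Ligand-atom coordinates (n_frames, n_atoms, 3) jiggling about a site.

    A rigid triangular ligand is jittered isotropically; used to exercise
    contact-frequency profiling against sphere receptors.
    """
    rng = np.random.default_rng(seed)
    base = np.array([[0.0, 0.0, 0.0], [1.4, 0.0, 0.0], [0.7, 1.2, 0.0]])[:n_ligand_atoms]
    frames = np.empty((n_frames, len(base), 3))
    for t in range(n_frames):
        shift = rng.normal(0.0, jitter_sd, size=3)
        frames[t] = np.asarray(site_center, float) + base + shift
    return frames
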
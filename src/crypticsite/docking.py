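"""Boltzmann-weighted ensemble docking: score reweighting, top-K selection
and RMSD pose clustering.

A docking run against a conformational ensemble yields one best-scored pose
per conformation.  A favourable score in a conformation the protein rarely
visits contributes little to binding, so each raw score g_i is combined
with the equilibrium probability of its conformation from the MSM:

    pi_hat_i = pi_{s(i)} / (poses in microstate s(i))          (prob. share)
    G_i      = g_i - kT * ln(pi_hat_i)                         (effective score)
    K        = sum_i pi_hat_i * exp(-g_i / kT)                 (macroscopic constant)

(the PopShift-style exponential reweighting).  Ranking ascends in G_i; the
top-K poses are then clustered on ligand-atom RMSD by quality-threshold
clustering and reduced to representative poses for replicate simulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .msm import MarkovModel

#: kT at 300 K in kcal/mol, the simulation temperature of the screen.
KT_300K = 0.596

#: Docking grid-box dimensions (A) used around the candidate site; emitted
#: as a config artifact for external docking engines.
GRID_BOX_DIMS = (24.0, 22.0, 25.0)


@dataclass(frozen=True)
class DockedPose:
    """One best-scored pose for one protein conformation."""

    conformation: int               # frame id; maps to an MSM microstate
    coords: np.ndarray              # (n_ligand_atoms, 3) A
    score: float                    # raw docking score g_i, kcal/mol

    def __post_init__(self) -> None:
        if not np.isfinite(self.score):
            raise ValueError("docking score must be finite")


@dataclass(frozen=True)
class ReweightConfig:
    kT: float = KT_300K
    mode: str = "effective-free-energy"     # or "linear-expectation"
    top_k: int = 100

    def __post_init__(self) -> None:
        if self.kT <= 0:
            raise ValueError("kT must be > 0")
        if self.top_k < 1:
            raise ValueError("top_K must be >= 1")
        if self.mode not in ("effective-free-energy", "linear-expectation"):
            raise ValueError(f"unknown ranking mode {self.mode!r}")


def reweight_poses(
    poses: list[DockedPose],
    model: MarkovModel,
    state_of_conformation: np.ndarray,
    config: ReweightConfig = ReweightConfig(),
) -> tuple[pd.DataFrame, float]:
    """Rank poses by MSM-reweighted score; report the macroscopic constant.

    ``state_of_conformation[frame]`` gives the microstate (original index)
    of each conformation.  Poses whose state is outside the model's active
    set (or carries zero probability) are dropped with a warning.  The pi
    mass of a microstate is split uniformly across the poses assigned to
    it, conserving total probability.

    Returns (ranked table ascending in effective score, K).
    """
    state_of_conformation = np.asarray(state_of_conformation, int)
    pos_in_active = {int(s): i for i, s in enumerate(model.active_set)}
    rows = []
    for p in poses:
        s = int(state_of_conformation[p.conformation])
        if s not in pos_in_active:
            warnings.warn(f"pose for conformation {p.conformation} maps to "
                          f"inactive microstate {s}; dropped")
            continue
        rows.append({"conformation": p.conformation, "state": s,
                     "score": p.score})
    if not rows:
        raise ValueError("no pose maps into the model's active set")
    df = pd.DataFrame(rows)
    pi_state = df["state"].map(
        {int(s): float(model.stationary[i]) for i, s in enumerate(model.active_set)}
    ).to_numpy()
    zero = pi_state <= 0
    if zero.any():
        warnings.warn(f"{zero.sum()} poses in zero-probability states; excluded")
        df, pi_state = df[~zero].reset_index(drop=True), pi_state[~zero]
    n_in_state = df.groupby("state")["state"].transform("size").to_numpy()
    pi_hat = pi_state / n_in_state
    g = df["score"].to_numpy()
    df["pi_hat"] = pi_hat
    df["effective_score"] = g - config.kT * np.log(pi_hat)
    df["linear_score"] = pi_hat * g
    key = "effective_score" if config.mode == "effective-free-energy" else "linear_score"
    df = df.sort_values([key, "score", "conformation"],
                        kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    k_macro = float(np.sum(pi_hat * np.exp(-g / config.kT)))
    return df, k_macro


def select_top(ranked: pd.DataFrame, k: int) -> pd.DataFrame:
    """Top-K rows of a ranked pose table (all rows, with warning, if K > n)."""
    if k > len(ranked):
        warnings.warn(f"requested top {k} of only {len(ranked)} poses; returning all")
        return ranked.copy()
    return ranked.iloc[:k].copy()


def pose_rmsd_matrix(coords: np.ndarray) -> np.ndarray:
    """Pairwise ligand RMSD (A) between poses sharing a receptor frame.

    ``coords``: (n_poses, n_atoms, 3).  No superposition: poses live in a
    common receptor-aligned frame, so raw coordinate RMSD is the pose
    distance.
    """
    c = np.asarray(coords, float)
    diff = c[:, None, :, :] - c[None, :, :, :]
    return np.sqrt(np.mean(np.sum(diff**2, axis=-1), axis=-1))


@dataclass(frozen=True)
class PoseCluster:
    members: np.ndarray             # pose indices
    representative: int             # pose index
    cutoff: float


def cluster_poses(coords: np.ndarray, cutoff: float = 2.5) -> list[PoseCluster]:
    """Quality-threshold clustering of poses on ligand RMSD.

    Repeatedly take the pose with the most neighbours within ``cutoff`` as
    a representative, remove its cluster, and repeat; ties break toward the
    lowest pose index.  Every member lies within ``cutoff`` of its
    representative; clusters are disjoint and ordered by size (then by
    representative index), so the result is input-order invariant up to the
    deterministic tie rule.
    """
    c = np.asarray(coords, float)
    if c.ndim != 3 or len(c) == 0:
        raise ValueError("need at least one pose of shape (n_atoms, 3)")
    d = pose_rmsd_matrix(c)
    n = len(c)
    remaining = np.ones(n, bool)
    clusters: list[PoseCluster] = []
    while remaining.any():
        within = (d <= cutoff) & remaining[None, :] & remaining[:, None]
        counts = within.sum(axis=1)
        counts[~remaining] = -1
        rep = int(np.argmax(counts))            # argmax takes the lowest index on ties
        members = np.flatnonzero(within[rep])
        clusters.append(PoseCluster(members=members, representative=rep, cutoff=cutoff))
        remaining[members] = False
    clusters.sort(key=lambda cl: (-len(cl.members), cl.representative))
    return clusters


def representative_poses(clusters: list[PoseCluster], n_max: int = 20) -> list[int]:
    """Up to ``n_max`` cluster representatives, largest clusters first."""
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    return [cl.representative for cl in clusters[:n_max]]


def grid_box_artifact(center: np.ndarray, dims: tuple[float, float, float] = GRID_BOX_DIMS) -> dict:
    """Docking grid-box spec (center + dimensions, A) for external engines."""
    return {"center": [float(v) for v in np.asarray(center, float)],
            "size_x": dims[0], "size_y": dims[1], "size_z": dims[2]}
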
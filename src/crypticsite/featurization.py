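"""Structural descriptors: nearest-atom distances, RMSD/RMSF, ligand
COM-RMSD, contact frequencies and hydrogen-bond geometry.

Conformational ensembles are plain arrays: ``coords`` of shape
(n_frames, n_atoms, 3) in Angstrom, with residue membership given by a
mapping ``{residue_key: atom index array}``.  Helpers convert from biotite
``AtomArrayStack`` objects read from (multi-model) PDB files, so the same
functions serve real structures and the bead-model toys.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist


@dataclass(frozen=True)
class ContactConfig:
    """Contact definition: any-atom distance cutoff and frequency threshold."""

    cutoff: float = 4.0        # A
    threshold: float = 0.5     # fraction of frames, strict >

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must be in [0, 1]")


@dataclass(frozen=True)
class HBondCriteria:
    """Donor-acceptor distance (A) and D-H-A angle (degrees) criteria."""

    da_cutoff: float = 3.0
    dha_angle: float = 120.0

    def __post_init__(self) -> None:
        if self.da_cutoff <= 0:
            raise ValueError("distance cutoff must be > 0")
        if not 0.0 < self.dha_angle <= 180.0:
            raise ValueError("angle cutoff must be in (0, 180]")


@dataclass(frozen=True)
class FeatureMatrix:
    """Frames x features matrix of nearest-atom distances (A).

    ``columns`` maps each column to its (subunit, loop_residue,
    wall_residue) triple, subunit-major then loop index then wall index.
    """

    values: np.ndarray
    columns: tuple[tuple[str, object, object], ...]

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        names = [f"{s}:{l}-{w}" for s, l, w in self.columns]
        return pd.DataFrame(self.values, columns=names)


def residue_atom_map(atoms) -> dict[tuple[str, int], np.ndarray]:
    """(chain_id, res_id) -> atom index array, from a biotite AtomArray."""
    keys = list(zip(atoms.chain_id, atoms.res_id))
    out: dict[tuple[str, int], list[int]] = {}
    for i, k in enumerate(keys):
        out.setdefault((str(k[0]), int(k[1])), []).append(i)
    return {k: np.asarray(v) for k, v in out.items()}


def pairwise_distance_features(
    coords: np.ndarray,
    residue_map: Mapping[object, np.ndarray],
    pair_spec: Mapping[str, tuple[Sequence[object], Sequence[object]]],
) -> FeatureMatrix:
    """Nearest-atom loop-wall distances, one column per (subunit, loop, wall).

    ``pair_spec`` maps each subunit label to (loop_residues, wall_residues);
    every loop x wall combination contributes one column whose value is the
    minimum over all atom pairs of the Euclidean distance between any atom
    of the loop residue and any atom of the wall residue.

    Column order is deterministic: subunit-major (insertion order of
    ``pair_spec``), then loop index, then wall index.
    """
    coords = np.asarray(coords, float)
    if coords.ndim != 3:
        raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
    if coords.shape[0] == 0:
        raise ValueError("empty frame set")
    columns: list[tuple[str, object, object]] = []
    pairs: list[tuple[np.ndarray, np.ndarray]] = []
    for subunit, (loops, walls) in pair_spec.items():
        for loop in loops:
            for wall in walls:
                for res in (loop, wall):
                    if res not in residue_map:
                        raise KeyError(
                            f"residue {res!r} (subunit {subunit!r}) not in structure"
                        )
                    if len(residue_map[res]) == 0:
                        raise ValueError(f"residue {res!r} has no atoms")
                columns.append((subunit, loop, wall))
                pairs.append((residue_map[loop], residue_map[wall]))
    vals = np.empty((coords.shape[0], len(columns)))
    for t in range(coords.shape[0]):
        frame = coords[t]
        for j, (ia, ib) in enumerate(pairs):
            vals[t, j] = cdist(frame[ia], frame[ib]).min()
    return FeatureMatrix(values=vals, columns=tuple(columns))


def kabsch_rotation(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal rigid superposition of ``mobile`` onto ``target``.

    Returns (rotation matrix R, mobile centroid, target centroid) such that
    (mobile - cm) @ R.T + ct minimises the RMSD to target.
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    h = (mobile - cm).T @ (target - ct)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d]) if mobile.shape[1] == 3 else np.eye(mobile.shape[1])
    r = vt.T @ corr @ u.T
    return r, cm, ct


def superpose(mobile_frame: np.ndarray, reference_frame: np.ndarray,
              fit_indices: np.ndarray | None = None) -> np.ndarray:
    """Rigid-fit a whole frame onto a reference using ``fit_indices`` atoms."""
    mobile_frame = np.asarray(mobile_frame, float)
    reference_frame = np.asarray(reference_frame, float)
    idx = np.arange(len(mobile_frame)) if fit_indices is None else np.asarray(fit_indices)
    r, cm, ct = kabsch_rotation(mobile_frame[idx], reference_frame[idx])
    return (mobile_frame - cm) @ r.T + ct


def rmsd(frame: np.ndarray, reference: np.ndarray,
         selection: np.ndarray | None = None,
         superpose_fit: bool = False,
         fit_selection: np.ndarray | None = None) -> float:
    """Root-mean-square deviation (A) between two conformations.

    With ``superpose_fit``, an optimal rigid-body least-squares fit over
    ``fit_selection`` (default: the RMSD selection itself) precedes the
    deviation computation; otherwise raw coordinates are compared.
    """
    frame = np.asarray(frame, float)
    reference = np.asarray(reference, float)
    if frame.shape != reference.shape:
        raise ValueError("frame and reference atom counts differ")
    sel = np.arange(len(frame)) if selection is None else np.asarray(selection)
    if superpose_fit:
        frame = superpose(frame, reference, fit_selection if fit_selection is not None else sel)
    d = frame[sel] - reference[sel]
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def com_rmsd(frame: np.ndarray, reference: np.ndarray,
             ligand_selection: np.ndarray,
             receptor_selection: np.ndarray | None = None,
             masses: np.ndarray | None = None) -> float:
    """Ligand centre-of-mass displacement (A) after receptor superposition.

    The stability criterion of the screen: how far the ligand COM has moved
    from its docked position once the receptor is least-squares fitted.
    """
    ligand_selection = np.asarray(ligand_selection)
    if ligand_selection.size == 0:
        raise ValueError("empty ligand selection")
    frame = np.asarray(frame, float)
    reference = np.asarray(reference, float)
    if receptor_selection is None:
        receptor_selection = np.setdiff1d(np.arange(len(frame)), ligand_selection)
    if len(receptor_selection) >= 3:
        frame = superpose(frame, reference, receptor_selection)
    w = np.ones(ligand_selection.size) if masses is None else np.asarray(masses, float)
    w = w / w.sum()
    com_f = (frame[ligand_selection] * w[:, None]).sum(axis=0)
    com_r = (reference[ligand_selection] * w[:, None]).sum(axis=0)
    return float(np.linalg.norm(com_f - com_r))


def rmsf(coords: np.ndarray, residue_map: Mapping[object, np.ndarray] | None = None,
         superpose_fit: bool = True) -> pd.Series | np.ndarray:
    """Per-residue (or per-atom) fluctuation about the ensemble mean, A.

    Frames are optionally superposed onto the first frame, the mean
    structure is taken, and each atom's root-mean-square distance from its
    mean position is computed; per-residue values average over atoms.
    """
    coords = np.asarray(coords, float)
    if coords.shape[0] < 2:
        raise ValueError("RMSF requires at least 2 frames")
    if superpose_fit:
        ref = coords[0]
        coords = np.stack([superpose(f, ref) for f in coords])
    mean = coords.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0))
    if residue_map is None:
        return per_atom
    return pd.Series({k: float(per_atom[v].mean()) for k, v in residue_map.items()})


def contact_frequency(
    ligand_coords: np.ndarray,
    receptor_coords: np.ndarray,
    residue_map: Mapping[object, np.ndarray],
    config: ContactConfig = ContactConfig(),
) -> pd.Series:
    """Fraction of frames in which any ligand atom is within ``cutoff`` of
    any atom of each receptor residue.

    ``ligand_coords``: (n_frames, n_lig_atoms, 3); ``receptor_coords``:
    (n_atoms, 3) for a rigid receptor or (n_frames, n_atoms, 3).
    """
    ligand_coords = np.asarray(ligand_coords, float)
    receptor_coords = np.asarray(receptor_coords, float)
    n_frames = ligand_coords.shape[0]
    rigid = receptor_coords.ndim == 2
    counts = {k: 0 for k in residue_map}
    for t in range(n_frames):
        rec = receptor_coords if rigid else receptor_coords[t]
        d = cdist(ligand_coords[t], rec)
        dmin = d.min(axis=0)
        for k, idx in residue_map.items():
            if dmin[idx].min() < config.cutoff:
                counts[k] += 1
    return pd.Series({k: c / n_frames for k, c in counts.items()})


def detect_hbond(donor: np.ndarray, hydrogen: np.ndarray, acceptor: np.ndarray,
                 criteria: HBondCriteria = HBondCriteria()) -> bool:
    """Hydrogen bond test: D-A distance < cutoff AND D-H-A angle > cutoff."""
    d = np.asarray(donor, float)
    h = np.asarray(hydrogen, float)
    a = np.asarray(acceptor, float)
    if np.allclose(d, h) or np.allclose(h, a) or np.allclose(d, a):
        raise ValueError("donor, hydrogen and acceptor must be distinct points")
    if np.linalg.norm(d - a) >= criteria.da_cutoff:
        return False
    v1 = d - h
    v2 = a - h
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return bool(angle > criteria.dha_angle)
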
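"""Replicate-simulation stability screen for docked poses.

Each representative pose is simulated in replicate under multiple
conditions (force fields, at production scale: 20 poses x 3 replicates x 2
force fields = 120 trajectories).  A pose passes the screen when the
ligand stays below a COM-RMSD threshold (15 A) *throughout* — every stored
frame strictly below — in at least ``min_pass`` of its replicates (5 of 6).
Surviving complexes are profiled for per-residue contact frequency and for
the converged displacement from the initial docked pose.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .featurization import ContactConfig, contact_frequency


@dataclass(frozen=True)
class ScreenPlan:
    """Deterministic job list: poses x replicates x conditions, unique seeds."""

    jobs: pd.DataFrame          # pose, condition, replicate, length, seed

    @property
    def n_jobs(self) -> int:
        return len(self.jobs)


def plan_screen(n_poses: int, n_replicates: int, conditions: list[str],
                length: float, seed: int = 0) -> ScreenPlan:
    """Build the replicate-simulation job table.

    Job count is exactly n_poses * n_replicates * len(conditions); each job
    gets a unique seed derived deterministically from the root seed.
    """
    if n_poses < 1 or n_replicates < 1 or len(conditions) < 1:
        raise ValueError("all counts must be >= 1")
    n = n_poses * n_replicates * len(conditions)
    seeds = np.random.SeedSequence(seed).generate_state(n) % (2**31)
    rows = []
    i = 0
    for p in range(n_poses):
        for cond in conditions:
            for r in range(n_replicates):
                rows.append({"pose": p, "condition": cond, "replicate": r,
                             "length": length, "seed": int(seeds[i])})
                i += 1
    return ScreenPlan(jobs=pd.DataFrame(rows))


@dataclass(frozen=True)
class StabilityVerdict:
    passed: bool
    n_passing: int
    n_replicates: int
    max_com_rmsd: np.ndarray        # per replicate, A
    threshold: float
    min_pass: int


def stability_filter(traces: list[np.ndarray], threshold: float = 15.0,
                     min_pass: int = 5, n_expected: int | None = None) -> StabilityVerdict:
    """Apply the stability rule to one pose's replicate COM-RMSD traces.

    A replicate passes iff every timepoint is strictly below ``threshold``;
    the pose passes iff passing replicates >= ``min_pass``.  Missing
    replicates (fewer traces than ``n_expected``) count as failing.
    """
    if len(traces) == 0:
        raise ValueError("need at least one replicate trace")
    maxes = []
    for tr in traces:
        tr = np.asarray(tr, float)
        if not np.all(np.isfinite(tr)):
            raise ValueError("traces must be finite")
        maxes.append(float(tr.max()))
    n_total = len(traces)
    if n_expected is not None and n_total < n_expected:
        warnings.warn(f"{n_expected - n_total} replicate(s) missing; counted as failing")
        n_total = n_expected
    maxes = np.asarray(maxes)
    n_passing = int(np.sum(maxes < threshold))
    return StabilityVerdict(
        passed=n_passing >= min_pass,
        n_passing=n_passing,
        n_replicates=n_total,
        max_com_rmsd=maxes,
        threshold=threshold,
        min_pass=min_pass,
    )


def profile_contacts(
    ensembles: list[np.ndarray],
    receptor_coords: np.ndarray,
    residue_map,
    config: ContactConfig = ContactConfig(),
) -> tuple[pd.Series, list]:
    """Pooled contact frequencies over stable replicates + high-contact set.

    Replicate ligand ensembles are concatenated before the frequency
    computation; residues above the (strict) frequency threshold form the
    high-contact set.
    """
    if len(ensembles) == 0:
        raise ValueError("no stable replicates to profile")
    pooled = np.concatenate([np.asarray(e, float) for e in ensembles], axis=0)
    freq = contact_frequency(pooled, receptor_coords, residue_map, config)
    high = [k for k, v in freq.items() if v > config.threshold]
    return freq, high


def pose_convergence(traces: list[np.ndarray], window: int) -> tuple[float, float]:
    """Converged displacement from the docked pose: mean +/- SD over the
    final ``window`` frames, averaged across stable replicates."""
    if window < 1:
        raise ValueError("window must be >= 1")
    tails = []
    for tr in traces:
        tr = np.asarray(tr, float)
        if len(tr) <= window:
            raise ValueError("trace not longer than the averaging window")
        tails.append(tr[-window:])
    tails = np.concatenate(tails)
    return float(tails.mean()), float(tails.std(ddof=0))
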
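"""Surrogate docking scores correlated with pocket openness.

Stands in for a docking engine that outputs the single best-scored pose per
protein conformation: scores are linear in a per-frame "openness"
coordinate plus Gaussian noise,

    g_i = g0 - slope * openness_i + eps_i,   eps_i ~ N(0, sd)

so more-open conformations receive (in expectation) more favourable
(lower) scores, with seeded noise for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SurrogateScoreModel:
    baseline: float = -4.0      # g0, kcal/mol
    slope: float = 1.0          # kcal/mol per unit openness
    noise_sd: float = 0.0       # kcal/mol
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")


def surrogate_scores(openness: np.ndarray, model: SurrogateScoreModel) -> pd.DataFrame:
    """Score one conformation per openness value.

    Returns a DataFrame with columns ``conformation`` (0-based id),
    ``openness`` and ``score`` (kcal/mol), CSV-writable.
    """
    openness = np.asarray(openness, float)
    if openness.ndim != 1:
        raise ValueError("openness must be a 1D series")
    if not np.all(np.isfinite(openness)):
        raise ValueError("openness values must be finite")
    rng = np.random.default_rng(model.seed)
    noise = rng.normal(0.0, model.noise_sd, size=len(openness)) if model.noise_sd > 0 \
        else np.zeros(len(openness))
    g = model.baseline - model.slope * openness + noise
    return pd.DataFrame({
        "conformation": np.arange(len(openness)),
        "openness": openness,
        "score": g,
    })
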
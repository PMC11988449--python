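"""Synthetic concentration-response data from the four-parameter Hill model.

The noise-free response at concentration X is

    Y = R_basal + (R_max - R_basal) / (1 + 10^((logEC50 - logX) * nH))

(the standard log-concentration Hill / sigmoidal dose-response form used
in electrophysiology curve fitting), to which seeded additive Gaussian
noise is applied.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def hill_response(concentration, ec50: float, n_h: float,
                  r_basal: float = 0.0, r_max: float = 1.0) -> np.ndarray:
    """Evaluate the noise-free Hill equation at the given concentration(s)."""
    x = np.asarray(concentration, float)
    if ec50 <= 0:
        raise ValueError("EC50 must be > 0")
    if np.any(x <= 0):
        raise ValueError("concentrations must be > 0")
    return r_basal + (r_max - r_basal) / (
        1.0 + 10.0 ** ((np.log10(ec50) - np.log10(x)) * n_h)
    )


def synth_dose_response(
    ec50: float,
    n_h: float,
    r_basal: float,
    r_max: float,
    concentrations,
    noise_sd: float = 0.0,
    n_replicates: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Noisy Hill-shaped concentration-response table.

    Returns columns ``replicate``, ``concentration``, ``response``.
    """
    if r_max < r_basal:
        raise ValueError("R_max must be >= R_basal")
    if noise_sd < 0:
        raise ValueError("noise SD must be >= 0")
    x = np.asarray(concentrations, float)
    y0 = hill_response(x, ec50, n_h, r_basal, r_max)
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        noise = rng.normal(0.0, noise_sd, size=len(x)) if noise_sd > 0 else 0.0
        rows.append(pd.DataFrame({
            "replicate": rep,
            "concentration": x,
            "response": y0 + noise,
        }))
    return pd.concat(rows, ignore_index=True)
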
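"""Bernoulli pattern-occupancy tables.

Each micropattern on a grid either holds a usable cell arrangement or is
empty/damaged/overcrowded; of the usable ones, a fraction shows a clear
cell-cell contact.  Both outcomes are modelled as independent Bernoulli
draws, matching the per-grid success-rate bookkeeping the yield
arithmetic consumes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["gen_pattern_occupancy"]


def gen_pattern_occupancy(
    n_patterns: int,
    success_rate: float,
    contact_fraction: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw per-pattern usable / has-contact outcomes.

    Parameters
    ----------
    n_patterns : int
        Number of micropatterns (100 for a 10 x 10 array).
    success_rate : float
        Probability a pattern is usable (not empty, damaged or
        overcrowded).
    contact_fraction : float
        Probability a *usable* pattern shows an identifiable cell-cell
        contact.
    seed : int
        RNG seed.

    Returns
    -------
    DataFrame with columns ``pattern_id``, ``usable`` (bool) and
    ``has_contact`` (bool; always False for unusable patterns).
    """
    if n_patterns < 0:
        raise ValueError("n_patterns must be non-negative")
    for name, p in (("success_rate", success_rate), ("contact_fraction", contact_fraction)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    usable = rng.random(n_patterns) < success_rate
    contact = (rng.random(n_patterns) < contact_fraction) & usable
    return pd.DataFrame(
        {
            "pattern_id": np.arange(n_patterns),
            "usable": usable,
            "has_contact": contact,
        }
    )
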
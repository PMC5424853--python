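"""Shared generators used by several test modules."""

import numpy as np
import pandas as pd


def make_pfs_only_ipd(pfs_model, seed, n_treated=408, n_control=409):
    """IPD whose PF-exit times follow a Weibull PFS model (no deaths).

    Used by family-selection recovery tests: the progression-free-survival
    outcome is exactly Weibull with a PH treatment effect, uniform 1-year
    accrual and a 4-year administrative cutoff.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for arm, n in ((0, n_control), (1, n_treated)):
        t = pfs_model.inverse_cumulative_hazard(
            rng.exponential(size=n), {"treatment": arm}, allow_inf=True
        )
        entry = rng.uniform(0.0, 1.0, n)
        cens = 4.0 - entry
        frames.append(
            pd.DataFrame(
                {
                    "id": np.arange(n) + arm * 1000,
                    "arm": arm,
                    "time_prog": np.where(t <= cens, t, np.nan),
                    "time_death": np.nan,
                    "time_censor": cens,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
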
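"""Shared helpers for the test suite."""

import numpy as np

from wbdecode.bayes import Ratemap


def make_line_ratemap(rates, prior=None) -> Ratemap:
    """Ratemap on a 1 x n_bins grid from explicit per-unit rate rows."""
    rates = np.asarray(rates, dtype=float)[:, :, None]
    n = rates.shape[1]
    p = np.full((n, 1), 1.0 / n) if prior is None else np.asarray(prior, dtype=float)[:, None]
    return Ratemap(
        rates=rates,
        occupancy_p=p,
        visited=np.ones((n, 1), bool),
        x_centres=np.arange(n) * 2.0 + 1.0,
        y_centres=np.array([1.0]),
        bin_size=2.0,
    )
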
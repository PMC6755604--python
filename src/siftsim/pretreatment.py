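"""Column-wise pretreatment of similarity matrices.

Even after rescaling to [0, 1], different similarity measures occupy very
different sub-ranges (Mountford values sit near 0, Yule values near 1), so
row-wise min/max consensus fusion would be driven by the measures' ranges
rather than by the ligands. Pretreatment puts the measure columns on a
common footing before fusion and SRD:

* ``AUTO`` — autoscaling (standardization): zero mean, unit sample
  standard deviation per column;
* ``RGS`` — range scaling: column minimum to 0, maximum to 1;
* ``RANK`` — rank transformation: values replaced by ascending ranks,
  ties averaged;
* ``NONE`` — identity.

All transforms are strictly monotone within a column (up to ties), so they
preserve each measure's own ligand ranking.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .similarity import measure_columns

logger = logging.getLogger(__name__)

PRETREATMENT_METHODS = ("AUTO", "RGS", "RANK", "NONE")


def _transform(frame: pd.DataFrame, fn) -> pd.DataFrame:
    out = frame.copy()
    for col in measure_columns(frame):
        out[col] = fn(frame[col].to_numpy(dtype=float), col)
    return out


def autoscale(frame: pd.DataFrame) -> pd.DataFrame:
    """Standardize each measure column to mean 0, sample (n-1) sd 1.

    A constant column carries no ranking information; it is set to all
    zeros and a warning is logged.
    """

    def fn(x, col):
        sd = x.std(ddof=1) if x.size > 1 else 0.0
        if sd == 0:
            logger.warning("autoscale: column %r is constant, set to zero", col)
            return np.zeros_like(x)
        return (x - x.mean()) / sd

    return _transform(frame, fn)


def range_scale(frame: pd.DataFrame) -> pd.DataFrame:
    """Linearly map each measure column onto [0, 1] (min -> 0, max -> 1)."""

    def fn(x, col):
        span = x.max() - x.min()
        if span == 0:
            logger.warning("range_scale: column %r is constant, set to zero", col)
            return np.zeros_like(x)
        return (x - x.min()) / span

    return _transform(frame, fn)


def rank_transform(frame: pd.DataFrame) -> pd.DataFrame:
    """Replace each measure column by ascending ranks 1..n, ties averaged."""
    return _transform(frame, lambda x, col: rankdata(x, method="average"))


def pretreat(frame: pd.DataFrame, method: str) -> pd.DataFrame:
    """Dispatch on a pretreatment name (``AUTO``/``RGS``/``RANK``/``NONE``)."""
    method = method.upper()
    if method == "AUTO":
        return autoscale(frame)
    if method == "RGS":
        return range_scale(frame)
    if method == "RANK":
        return rank_transform(frame)
    if method == "NONE":
        return frame.copy()
    raise ValueError(f"unknown pretreatment method {method!r}")
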
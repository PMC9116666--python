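"""Spatial pattern statistics and run post-processing.

The degree of clumping of a finished run is quantified by the index of
dispersion: the grid is partitioned into non-overlapping quadrats
(default 10x10 spots), all cells regardless of kind are counted per
quadrat, and the ratio of the sample variance to the mean of those
counts is reported.  Independent random occupancy yields a ratio near 1;
islands of cells separated by empty space push it well above 1; a
saturated grid gives 0.  A run is classified EXTINCT if no cells remain,
otherwise CLUMPED when the index exceeds the threshold (1.5, the value
used to separate the phases in the parameter sweeps) and UNIFORM
otherwise (ties count as UNIFORM).
"""

from __future__ import annotations

from enum import Enum

import numpy as np
import pandas as pd

from .abm import TimeSeries
from .lattice import Lattice

__all__ = [
    "OutcomeLabel",
    "index_of_dispersion",
    "classify_outcome",
    "detect_steady_state",
    "replicate_mean_se",
    "DISPERSION_THRESHOLD",
]

DISPERSION_THRESHOLD = 1.5


class OutcomeLabel(str, Enum):
    EXTINCT = "EXTINCT"
    UNIFORM = "UNIFORM"
    CLUMPED = "CLUMPED"


def quadrat_counts(lattice: Lattice, square_side: int = 10) -> np.ndarray:
    """Total cell counts (any kind) in each square quadrat."""
    n = lattice.n
    if square_side < 1 or n % square_side != 0:
        raise ValueError(f"grid side {n} is not divisible by square side {square_side}")
    k = n // square_side
    occ = (lattice.states != 0).astype(np.int64)
    return occ.reshape(k, square_side, k, square_side).sum(axis=(1, 3)).ravel()


def index_of_dispersion(lattice: Lattice, square_side: int = 10) -> float:
    """Variance-to-mean ratio of quadrat cell counts (sample variance).

    Raises if the lattice is empty (the statistic is undefined; classify
    extinction first) or if fewer than two quadrats exist.
    """
    counts = quadrat_counts(lattice, square_side)
    if counts.sum() == 0:
        raise ValueError("index of dispersion is undefined for an empty lattice")
    if counts.size < 2:
        raise ValueError("need at least two quadrats")
    return float(counts.var(ddof=1) / counts.mean())


def classify_outcome(
    lattice: Lattice,
    threshold: float = DISPERSION_THRESHOLD,
    square_side: int = 10,
) -> OutcomeLabel:
    """EXTINCT / UNIFORM / CLUMPED classification of a final lattice."""
    if not lattice.states.any():
        return OutcomeLabel.EXTINCT
    i_disp = index_of_dispersion(lattice, square_side)
    return OutcomeLabel.CLUMPED if i_disp > threshold else OutcomeLabel.UNIFORM


def detect_steady_state(
    series, rel_change: float = 0.001, window: int = 1000
) -> int | None:
    """First step at which the trailing mean of the stem count is stable.

    The trailing mean over ``window`` steps is compared with its value
    one full window earlier; the run is declared steady at the first
    step ``T >= 2 * window`` for which the relative change between those
    two averages is at most ``rel_change`` (0.1% by default), i.e. the
    temporal average of the stem count did not change by more than
    ``rel_change`` over ``window`` consecutive steps.  A constant series
    is steady at exactly ``2 * window``; a linearly growing one never
    is.  Two successive zero means (extinct tail) count as no change.
    Returns ``None`` when the criterion is never met.
    """
    if isinstance(series, TimeSeries):
        x = np.asarray(series.stem, dtype=float)
    else:
        x = np.asarray(series, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if len(x) <= window:
        raise ValueError("series must be longer than the averaging window")
    cs = np.concatenate(([0.0], np.cumsum(x)))
    # rm[j] = mean of x[i-window : i] at i = window + j,  j = 0 .. len(x)-window
    i = np.arange(window, len(x) + 1)
    rm = (cs[i] - cs[i - window]) / window
    if len(rm) <= window:
        return None
    now = rm[window:]
    before = rm[:-window]
    delta = np.abs(now - before)
    rel = np.where(before > 0, delta / np.where(before > 0, before, 1.0),
                   np.where(delta > 0, np.inf, 0.0))
    hits = np.nonzero(rel <= rel_change)[0]
    if hits.size == 0:
        return None
    return int(2 * window + hits[0])


def replicate_mean_se(runs: list[TimeSeries]) -> pd.DataFrame:
    """Pointwise replicate mean and standard error for each compartment.

    Returns a frame with columns ``t`` and ``{stem,ta,diff,total}_{mean,se}``;
    SE is the sample standard deviation divided by sqrt(R).
    """
    if len(runs) < 2:
        raise ValueError("need at least two replicate runs")
    length = len(runs[0])
    if any(len(r) != length for r in runs):
        raise ValueError("replicate runs must have equal lengths")
    out = {"t": np.asarray(runs[0].t)}
    R = len(runs)
    for name in ("stem", "ta", "diff", "total"):
        stack = np.stack([np.asarray(getattr(r, name), dtype=float) for r in runs])
        out[f"{name}_mean"] = stack.mean(axis=0)
        out[f"{name}_se"] = stack.std(axis=0, ddof=1) / np.sqrt(R)
    return pd.DataFrame(out)
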
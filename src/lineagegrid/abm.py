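"""Stochastic lattice models of cell-lineage regulation.

Two model families share one simulation engine:

* **feedback** — two compartments (stem / differentiated).  Differentiated
  cells secrete a diffusing factor ``z`` that suppresses stem-cell
  self-renewal: ``p_self = p0_self / (1 + h z)``.  A differentiating
  division converts the mother and places a second differentiated cell,
  so the lattice event is (-1 stem, +2 differentiated), matching the
  mean-field term ``2 r S (1 - p)``.

* **feedforward** / **combined** — three compartments (stem / TA /
  differentiated).  Stem differentiation produces two TA cells.  Stem
  cells secrete a feedforward factor ``w`` that maintains the TA pool:
  TA self-renewal is ``q_self = 1 - 1/(1 + h2 w)``, zero without the
  factor, approaching one at saturating levels.  A terminally
  differentiating TA division yields two differentiated daughters.  In
  the *combined* model the negative-feedback field ``z`` acts on stem
  cells as well; in the pure *feedforward* model it is absent.

Each time step is one hour: the grid is sampled N times (N = current
cell count), then every active mediator field is advanced one time unit
with the producer mask taken from the post-update occupancy
(``z``-producers are differentiated cells, ``w``-producers stem cells).
Division aborts when the randomly chosen Moore target spot is occupied,
which introduces the lattice carrying capacity.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace

import numpy as np
import pandas as pd

from . import _kernel
from .field import FieldStepper, MediatorField
from .lattice import CellCounts, Lattice, init_center_block

__all__ = [
    "FieldParams",
    "FeedbackABMParams",
    "FeedforwardParams",
    "TimeSeries",
    "Simulation",
    "SimulationResult",
    "local_self_renewal_prob",
    "local_ta_self_renewal_prob",
    "run_feedback_abm",
    "run_feedforward_abm",
]

SEED_BLOCK_SIDE = 7  # side of the initial central square of stem cells


@dataclass(frozen=True)
class FieldParams:
    """Rate constants of one mediator loop (per hour; ``h`` dimensionless)."""

    prod_rate: float  # c: production on producer patches
    decay_rate: float  # b
    hop_rate: float  # g: per-neighbor diffusion
    inhib_strength: float  # h: strength of action on cell fate

    def __post_init__(self) -> None:
        for name in ("prod_rate", "decay_rate", "hop_rate", "inhib_strength"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def make_field(self, n: int) -> MediatorField:
        return MediatorField(n, self.prod_rate, self.decay_rate, self.hop_rate, self.inhib_strength)


def _check_prob(value: float, name: str) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be a probability in [0, 1], got {value}")


@dataclass(frozen=True)
class FeedbackABMParams:
    """Two-compartment model parameters (probabilities per sampling)."""

    p_div: float = 4.17e-2  # stem division attempt (~once a day)
    p0_self: float = 0.7  # basal self-renewal probability
    p_sdeath: float = 0.0  # stem death
    p_ddeath: float = 8.3e-3  # differentiated-cell death
    p_mig: float = 0.0  # migration attempt (stem and differentiated)
    field: FieldParams = dc_field(
        default_factory=lambda: FieldParams(8.33, 4.17, 83.3, 1.6)
    )
    n: int = 100  # grid side
    horizon: int = 1000  # hours to simulate
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_div", "p0_self", "p_sdeath", "p_ddeath", "p_mig"):
            _check_prob(getattr(self, name), name)
        if self.n < 9:
            raise ValueError("grid side must be at least 9 (exceed the 7x7 seed block)")
        if self.horizon < 0:
            raise ValueError("horizon must be non-negative")

    def with_(self, **kw) -> "FeedbackABMParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class FeedforwardParams(FeedbackABMParams):
    """Three-compartment model parameters (adds the TA compartment)."""

    q_div: float = 5.83e-2  # TA division attempt
    q_tdeath: float = 0.0  # TA death
    ff_field: FieldParams = dc_field(
        default_factory=lambda: FieldParams(0.833, 8.3e-3, 0.417, 2.0)
    )

    def __post_init__(self) -> None:
        super().__post_init__()
        _check_prob(self.q_div, "q_div")
        _check_prob(self.q_tdeath, "q_tdeath")


def local_self_renewal_prob(z: float, h: float, p0: float) -> float:
    """Stem self-renewal probability under local feedback: ``p0 / (1 + h z)``."""
    if z < 0 or h < 0:
        raise ValueError("z and h must be non-negative")
    _check_prob(p0, "p0")
    return p0 / (1.0 + h * z)


def local_ta_self_renewal_prob(w: float, h2: float) -> float:
    """TA self-renewal probability under feedforward: ``1 - 1/(1 + h2 w)``."""
    if w < 0 or h2 < 0:
        raise ValueError("w and h2 must be non-negative")
    return 1.0 - 1.0 / (1.0 + h2 * w)


@dataclass
class TimeSeries:
    """Per-hour counts of each cell compartment."""

    t: np.ndarray
    stem: np.ndarray
    ta: np.ndarray
    diff: np.ndarray

    def __post_init__(self) -> None:
        lengths = {len(self.t), len(self.stem), len(self.ta), len(self.diff)}
        if len(lengths) != 1:
            raise ValueError("time-series columns must have equal lengths")

    @property
    def total(self) -> np.ndarray:
        return self.stem + self.ta + self.diff

    def __len__(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.t, "stem": self.stem, "ta": self.ta, "diff": self.diff,
             "total": self.total}
        )


@dataclass
class SimulationResult:
    series: TimeSeries
    lattice: Lattice
    field_z: MediatorField | None
    field_w: MediatorField | None = None
    snapshots: list[tuple[int, Lattice]] = dc_field(default_factory=list)


class Simulation:
    """Stateful hybrid simulation advanced one hour at a time.

    Parameters
    ----------
    params : :class:`FeedbackABMParams` or :class:`FeedforwardParams`.
    model : ``"feedback"`` (two compartments), ``"feedforward"`` (three
        compartments, no negative feedback) or ``"combined"`` (three
        compartments with both loops).  Defaults to ``"feedback"`` for
        two-compartment parameters and ``"combined"`` for three.
    init_lattice : optional starting configuration; defaults to a 7x7
        central block of stem cells on an otherwise empty grid.

    The negative-feedback field is advanced only when it can act on the
    cells (``h > 0``); with ``h = 0`` the field state is irrelevant to
    the dynamics and stays at zero.
    """

    def __init__(
        self,
        params: FeedbackABMParams,
        model: str | None = None,
        init_lattice: Lattice | None = None,
        field_substeps: int | None = None,
    ) -> None:
        three = isinstance(params, FeedforwardParams)
        if model is None:
            model = "combined" if three else "feedback"
        if model not in ("feedback", "feedforward", "combined"):
            raise ValueError(f"unknown model {model!r}")
        if model in ("feedforward", "combined") and not three:
            raise ValueError(f"model {model!r} requires FeedforwardParams")
        if model == "feedback" and three:
            raise ValueError("model 'feedback' takes FeedbackABMParams")
        self.params = params
        self.model = model
        self.use_feedback = model in ("feedback", "combined")
        self.three_comp = model in ("feedforward", "combined")
        n = params.n
        if init_lattice is None:
            init_lattice = init_center_block(n, SEED_BLOCK_SIDE)
        elif init_lattice.n != n:
            raise ValueError("init_lattice side must match params.n")
        self.grid = init_lattice.states.copy()
        self.z = np.zeros((n, n))
        self.w = np.zeros((n, n))
        self.t = 0
        # occupancy bookkeeping
        self.occ_r = np.zeros(n * n, dtype=np.int64)
        self.occ_c = np.zeros(n * n, dtype=np.int64)
        self.occ_idx = np.full((n, n), -1, dtype=np.int64)
        rows, cols = np.nonzero(self.grid)
        self.n_cells = rows.size
        self.occ_r[: self.n_cells] = rows
        self.occ_c[: self.n_cells] = cols
        self.occ_idx[rows, cols] = np.arange(self.n_cells)
        # mediator steppers (factorized once per run)
        f = params.field
        self._z_active = self.use_feedback and f.inhib_strength > 0 and f.prod_rate > 0
        self._stepper_z = (
            FieldStepper(n, f.prod_rate, f.decay_rate, f.hop_rate, 1.0, field_substeps)
            if self._z_active
            else None
        )
        if self.three_comp:
            ff = params.ff_field
            self._stepper_w = FieldStepper(
                n, ff.prod_rate, ff.decay_rate, ff.hop_rate, 1.0, field_substeps
            )
        else:
            self._stepper_w = None
        _kernel.seed_rng(params.seed % 2**32)

    @property
    def lattice(self) -> Lattice:
        return Lattice(self.grid.copy())

    def counts(self) -> CellCounts:
        c = np.bincount(self.grid.ravel(), minlength=4)
        return CellCounts(stem=int(c[1]), ta=int(c[2]), diff=int(c[3]))

    def field_z(self) -> MediatorField | None:
        if not self.use_feedback:
            return None
        f = self.params.field
        return MediatorField(
            self.params.n, f.prod_rate, f.decay_rate, f.hop_rate, f.inhib_strength,
            self.z.copy(),
        )

    def field_w(self) -> MediatorField | None:
        if not self.three_comp:
            return None
        ff = self.params.ff_field
        return MediatorField(
            self.params.n, ff.prod_rate, ff.decay_rate, ff.hop_rate,
            ff.inhib_strength, self.w.copy(),
        )

    def step(self) -> CellCounts:
        """Advance one hour: cell phase, then mediator-field phase."""
        p = self.params
        if isinstance(p, FeedforwardParams):
            q_div, q_tdeath = p.q_div, p.q_tdeath
            h2 = p.ff_field.inhib_strength
        else:
            q_div = q_tdeath = h2 = 0.0
        self.n_cells = _kernel.step_cells(
            self.grid,
            self.occ_r,
            self.occ_c,
            self.occ_idx,
            self.n_cells,
            self.z,
            self.w,
            p.p_div,
            p.p0_self,
            p.field.inhib_strength,
            p.p_sdeath,
            p.p_ddeath,
            p.p_mig,
            q_div,
            h2,
            q_tdeath,
            self.three_comp,
            self.use_feedback,
        )
        if self._stepper_z is not None:
            self.z = self._stepper_z.step(self.z, self.grid == _kernel.DIFF)
        if self._stepper_w is not None:
            self.w = self._stepper_w.step(self.w, self.grid == _kernel.STEM)
        self.t += 1
        return self.counts()

    def run(
        self, hours: int | None = None, record_every: int = 0
    ) -> SimulationResult:
        """Run for ``hours`` (default ``params.horizon``), recording counts
        every step and lattice snapshots every ``record_every`` steps
        (0 disables snapshots)."""
        if hours is None:
            hours = self.params.horizon
        t0 = self.t
        ts = np.empty(hours + 1, dtype=np.int64)
        stem = np.empty(hours + 1, dtype=np.int64)
        ta = np.empty(hours + 1, dtype=np.int64)
        diff = np.empty(hours + 1, dtype=np.int64)
        snapshots: list[tuple[int, Lattice]] = []

        def record(i: int, c: CellCounts) -> None:
            ts[i] = t0 + i
            stem[i], ta[i], diff[i] = c.stem, c.ta, c.diff

        record(0, self.counts())
        for i in range(1, hours + 1):
            c = self.step()
            record(i, c)
            if record_every and (self.t % record_every == 0):
                snapshots.append((self.t, self.lattice))
        series = TimeSeries(ts, stem, ta, diff)
        return SimulationResult(
            series, self.lattice, self.field_z(), self.field_w(), snapshots
        )


def run_feedback_abm(
    params: FeedbackABMParams, record_every: int = 0
) -> SimulationResult:
    """Run the two-compartment negative-feedback model from the standard
    7x7 stem-cell seed for ``params.horizon`` hours."""
    return Simulation(params, model="feedback").run(record_every=record_every)


def run_feedforward_abm(
    params: FeedforwardParams, use_feedback: bool = True, record_every: int = 0
) -> SimulationResult:
    """Run the three-compartment model (``use_feedback=False`` disables the
    negative-feedback loop, leaving pure feedforward control)."""
    model = "combined" if use_feedback else "feedforward"
    return Simulation(params, model=model).run(record_every=record_every)
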
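"""Scenario presets, replicate orchestration and parameter sweeps.

The presets encode the published demonstration scenarios of the model:

* ``fig1a_*`` — well-mixed negative feedback (fast migration and mediator
  diffusion); the average dynamics follow the mean-field ODE system.
* ``fig1c_*`` — spatially restricted negative feedback (no migration,
  slow diffusion); density regulation with clumped patterns.
* ``fig2a`` / ``fig2b`` — strong vs weak feedback at n = 200: clumped
  islands vs a uniform cell carpet.
* ``fig3_baseline`` — the resting point of the two-parameter outcome
  sweeps (uniform / clumped / extinct phase structure in h).
* ``fig4ai`` / ``fig4aii`` — feedforward-only control without / with
  stem and TA death.
* ``fig4b_*`` — combined feedback + feedforward control at two grid
  sizes; the steady state is grid-size independent (homeostasis).

Scenario sizes and horizons are those of the published figures; the
``scale`` argument shrinks the grid side and horizon proportionally for
desk-scale exploration without touching any rate or probability.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .abm import (
    FeedbackABMParams,
    FeedforwardParams,
    FieldParams,
    Simulation,
    TimeSeries,
)
from .stats import (
    OutcomeLabel,
    classify_outcome,
    detect_steady_state,
    index_of_dispersion,
    replicate_mean_se,
)

__all__ = [
    "PRESET_NAMES",
    "preset",
    "preset_model",
    "run_replicates",
    "run_to_steady_state",
    "SteadyRun",
    "sweep_2d",
    "set_param",
    "POST_STEADY_HOURS",
]

# Ten simulated years follow the steady-state criterion in the sweeps.
POST_STEADY_HOURS = 10 * 365 * 24


def _fb(**kw) -> FeedbackABMParams:
    return FeedbackABMParams(**kw)


def _ff(**kw) -> FeedforwardParams:
    return FeedforwardParams(**kw)


def _presets() -> dict[str, FeedbackABMParams]:
    fig1a = dict(
        p_div=4.17e-2, p0_self=0.7, p_sdeath=0.0, p_ddeath=8.3e-3, p_mig=0.67,
        field=FieldParams(8.33, 4.17, 83.3, 1.6), horizon=2000,
    )
    fig1c = dict(
        p_div=4.17e-2, p0_self=0.7, p_sdeath=8.3e-5, p_ddeath=4.17e-3, p_mig=0.0,
        field=FieldParams(8.33, 8.3e-3, 0.83, 4.0e-3), horizon=20000,
    )
    fig3 = dict(
        p_div=4.17e-2, p0_self=0.7, p_sdeath=8.3e-4, p_ddeath=4.17e-3, p_mig=0.0,
        field=FieldParams(8.33, 8.3e-3, 0.833, 4.0e-3), n=200, horizon=20000,
    )
    fig4a = dict(
        p_div=4.17e-2, p0_self=0.8, q_div=5.83e-2, p_ddeath=4.17e-3, p_mig=0.0,
        field=FieldParams(0.0, 1.0, 0.0, 0.0),  # no negative feedback loop
        ff_field=FieldParams(0.833, 8.3e-3, 0.417, 2.0), n=200, horizon=20000,
    )
    fig4b = dict(
        p_div=4.17e-2, p0_self=0.8, q_div=5.83e-2, p_sdeath=8.3e-5,
        q_tdeath=1.0e-4, p_ddeath=4.17e-3, p_mig=0.0,
        field=FieldParams(8.33, 8.33e-2, 0.0, 6.0e-2),
        ff_field=FieldParams(8.33, 8.33e-2, 3.33, 2.5), horizon=20000,
    )
    return {
        "fig1a_small": _fb(n=100, **fig1a),
        "fig1a_large": _fb(n=200, **fig1a),
        "fig1c_small": _fb(n=100, **fig1c),
        "fig1c_large": _fb(n=200, **fig1c),
        "fig2a": _fb(n=200, **fig1c),
        "fig2b": _fb(n=200, **{**fig1c, "field": FieldParams(8.33, 8.3e-3, 0.83, 1.0e-3)}),
        "fig3_baseline": _fb(**fig3),
        "fig4ai": _ff(p_sdeath=0.0, q_tdeath=0.0, **fig4a),
        "fig4aii": _ff(p_sdeath=8.3e-5, q_tdeath=1.0e-4, **fig4a),
        "fig4b_small": _ff(n=100, **fig4b),
        "fig4b_large": _ff(n=150, **fig4b),
    }


PRESET_NAMES = tuple(sorted(_presets()))

_PRESET_MODELS = {
    "fig4ai": "feedforward",
    "fig4aii": "feedforward",
    "fig4b_small": "combined",
    "fig4b_large": "combined",
}


def preset(name: str, scale: float = 1.0, **overrides) -> FeedbackABMParams:
    """Parameter set of a named scenario.

    ``scale`` shrinks the grid side and horizon proportionally (never
    below the 9-spot minimum / 1 hour); keyword overrides replace any
    parameter field after scaling.
    """
    table = _presets()
    if name not in table:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(table)}")
    p = table[name]
    if scale != 1.0:
        if scale <= 0:
            raise ValueError("scale must be positive")
        p = replace(
            p,
            n=max(9, round(p.n * scale)),
            horizon=max(1, round(p.horizon * scale)),
        )
    if overrides:
        p = replace(p, **overrides)
    return p


def preset_model(name: str) -> str:
    """Simulation model ("feedback" / "feedforward" / "combined") of a preset."""
    if name not in _presets():
        raise ValueError(f"unknown preset {name!r}")
    return _PRESET_MODELS.get(name, "feedback")


def run_replicates(
    params: FeedbackABMParams,
    R: int = 46,
    base_seed: int = 0,
    model: str | None = None,
) -> tuple[pd.DataFrame, list[OutcomeLabel], list[TimeSeries]]:
    """R independently seeded runs (seed ``base_seed + r``), aggregated.

    Returns the pointwise replicate mean ± SE frame, the per-run final
    outcome labels and the individual time series.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    series: list[TimeSeries] = []
    outcomes: list[OutcomeLabel] = []
    for rep in range(R):
        sim = Simulation(replace(params, seed=base_seed + rep), model=model)
        result = sim.run()
        series.append(result.series)
        outcomes.append(classify_outcome(result.lattice))
    if R >= 2:
        agg = replicate_mean_se(series)
    else:
        agg = series[0].to_frame()
    return agg, outcomes, series


@dataclass
class SteadyRun:
    """A simulation run to the steady-state criterion plus a settling tail."""

    sim: Simulation
    series: TimeSeries
    steady_at: int | None  # step index where the criterion fired, or None
    outcome: OutcomeLabel
    i_disp: float | None  # None iff EXTINCT


def run_to_steady_state(
    params: FeedbackABMParams,
    model: str | None = None,
    rel_change: float = 0.001,
    window: int = 1000,
    post_horizon: int = POST_STEADY_HOURS,
    max_horizon: int | None = None,
    check_every: int = 500,
    square_side: int = 10,
) -> SteadyRun:
    """Run until the stem-count temporal average stabilizes, then keep
    running for ``post_horizon`` further hours before classifying.

    ``max_horizon`` (default ``params.horizon``) caps the search for the
    criterion; extinction ends the search immediately.  The final
    lattice snapshot is classified and its index of dispersion reported
    (``None`` for extinct runs).
    """
    if max_horizon is None:
        max_horizon = params.horizon
    sim = Simulation(params, model=model)
    stem = [sim.counts().stem]
    ta = [sim.counts().ta]
    diff = [sim.counts().diff]

    def push() -> None:
        c = sim.counts()
        stem.append(c.stem)
        ta.append(c.ta)
        diff.append(c.diff)

    steady_at: int | None = None
    while sim.t < max_horizon:
        sim.step()
        push()
        if sim.n_cells == 0:
            break
        if sim.t % check_every == 0 and sim.t >= 2 * window:
            steady_at = detect_steady_state(np.array(stem, float), rel_change, window)
            if steady_at is not None:
                break
    if sim.n_cells > 0:
        for _ in range(post_horizon):
            sim.step()
            push()
            if sim.n_cells == 0:
                break
    lattice = sim.lattice
    outcome = classify_outcome(lattice, square_side=square_side)
    i_disp = (
        None
        if outcome is OutcomeLabel.EXTINCT
        else index_of_dispersion(lattice, square_side)
    )
    series = TimeSeries(
        np.arange(len(stem)),
        np.array(stem),
        np.array(ta),
        np.array(diff),
    )
    return SteadyRun(sim, series, steady_at, outcome, i_disp)


_PARAM_PATHS = {
    "h": ("field", "inhib_strength"),
    "g": ("field", "hop_rate"),
    "b": ("field", "decay_rate"),
    "c": ("field", "prod_rate"),
    "h2": ("ff_field", "inhib_strength"),
    "g2": ("ff_field", "hop_rate"),
    "b2": ("ff_field", "decay_rate"),
    "c2": ("ff_field", "prod_rate"),
}


def set_param(params: FeedbackABMParams, name: str, value: float) -> FeedbackABMParams:
    """Return a copy of ``params`` with one named parameter replaced.

    Mediator-loop symbols (h, g, b, c and the feedforward h2, g2, b2,
    c2) address the nested field parameters; every other name addresses
    a top-level field of the parameter dataclass.
    """
    if name in _PARAM_PATHS:
        attr, sub = _PARAM_PATHS[name]
        fp: FieldParams = getattr(params, attr)
        return replace(params, **{attr: replace(fp, **{sub: value})})
    if not hasattr(params, name):
        raise ValueError(f"unknown parameter {name!r}")
    return replace(params, **{name: value})


def sweep_2d(
    baseline: FeedbackABMParams,
    param_x: tuple[str, float, float],
    param_y: tuple[str, float, float],
    draws: int,
    base_seed: int = 0,
    model: str | None = None,
    **steady_kw,
) -> pd.DataFrame:
    """Log-uniform two-parameter sweep with outcome classification.

    For each draw both parameters are sampled log-uniformly from their
    ranges, one simulation is run to the steady-state criterion (plus the
    settling tail) and the final pattern is classified.  Draw *i* derives
    its parameter sample and its simulation seed from ``(base_seed, i)``
    through independent sub-streams, so extending ``draws`` never
    perturbs earlier rows.

    Returns a frame with one row per simulation:
    ``x_name, x_value, y_name, y_value, i_disp, outcome, seed``.
    """
    if draws < 0:
        raise ValueError("draws must be >= 0")
    x_name, x_lo, x_hi = param_x
    y_name, y_lo, y_hi = param_y
    for lo, hi in ((x_lo, x_hi), (y_lo, y_hi)):
        if lo <= 0 or hi <= 0 or hi < lo:
            raise ValueError("sweep ranges must be positive with hi >= lo")
    rows = []
    for i in range(draws):
        prng = np.random.default_rng([base_seed, i, 0])
        xv = float(np.exp(prng.uniform(np.log(x_lo), np.log(x_hi))))
        yv = float(np.exp(prng.uniform(np.log(y_lo), np.log(y_hi))))
        sim_seed = int(np.random.default_rng([base_seed, i, 1]).integers(2**31))
        p = set_param(set_param(baseline, x_name, xv), y_name, yv)
        p = replace(p, seed=sim_seed)
        run = run_to_steady_state(p, model=model, **steady_kw)
        rows.append(
            {
                "x_name": x_name,
                "x_value": xv,
                "y_name": y_name,
                "y_value": yv,
                "i_disp": run.i_disp,
                "outcome": run.outcome.value,
                "seed": sim_seed,
            }
        )
    columns = ["x_name", "x_value", "y_name", "y_value", "i_disp", "outcome", "seed"]
    return pd.DataFrame(rows, columns=columns)
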
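"""Receding-horizon (MPC) analysis of Flexible Nets.

Each step transcribes the net over a short horizon starting from the
current state, solves the LP/QP, applies the first interval, and rolls the
reached boundary state forward as the next initial state.  Uncertain
quantities (default intensities inside their block, handler slack) are
re-resolved by the optimizer at every step, which is what makes the scheme
a controller: the applied ``lambda0`` trace is the control signal.

Convergence to a fixed point is declared when the applied boundary marking
moves by less than ``tol`` (infinity norm) over ``window`` consecutive
steps; the reported steady state is the converged fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .net import FlexibleNet, InitialConditions
from .transcription import (
    ObjectiveExpr,
    Trajectory,
    TranscriptionSpec,
    build_transcription,
    solve,
)

__all__ = ["MPCConfig", "MPCInfeasible", "run_mpc"]


@dataclass
class MPCConfig:
    """Sampling time, horizon length (in intervals), step budget and objective."""

    dt: float
    n_steps: int
    objective: ObjectiveExpr
    horizon: int = 1
    forced_exec: set[str] = field(default_factory=set)
    forced_active: set[str] = field(default_factory=set)
    tol: float = 1e-4
    window: int = 10
    stop_on_convergence: bool = True

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.horizon < 1:
            raise ValueError("horizon must be at least one interval")
        if self.n_steps < 1:
            raise ValueError("n_steps must be at least 1")


class MPCInfeasible(RuntimeError):
    def __init__(self, step: int, status: str):
        self.step = step
        self.status = status
        super().__init__(f"MPC step {step} failed with status {status!r}")


def run_mpc(net: FlexibleNet, init: InitialConditions, config: MPCConfig) -> Trajectory:
    """Run the receding-horizon loop; returns the applied trajectory.

    The returned :class:`Trajectory` concatenates the applied first
    intervals; ``controls`` holds the per-step chosen default intensities.
    ``times`` covers the steps actually run (early stop on convergence).
    """
    if init.m0 is None:
        raise ValueError("MPC needs a point-valued initial marking")
    m_cur = {p: float(init.m0.get(p, 0.0)) for p in net.places}
    aT_cur = {t: 0.0 for t in net.transitions}

    spec_proto = dict(
        forced_exec=set(config.forced_exec), forced_active=set(config.forced_active)
    )
    boundaries = config.dt * np.arange(config.horizon + 1)

    m_rows = [pd.Series(m_cur)]
    aT_rows = [pd.Series(aT_cur)]
    sigma_rows = [pd.Series(0.0, index=net.transitions)]
    lam_rows, mbar_rows, muE_rows, ctrl_rows = [], [], [], []
    x_prev = None
    quiet = 0
    steps_run = 0
    for step in range(config.n_steps):
        spec = TranscriptionSpec(boundaries, objective=config.objective, **spec_proto)
        step_init = init.with_m0(m_cur)
        problem = build_transcription(net, step_init, spec, a_T0=aT_cur)
        traj = solve(problem, x0=x_prev)
        if traj.status != "optimal":
            raise MPCInfeasible(step, traj.status)
        x_prev = traj._solution._x
        m_new = traj.m.iloc[1].to_dict()
        aT_new = traj.a_T.iloc[1].to_dict()
        m_rows.append(traj.m.iloc[1])
        aT_rows.append(traj.a_T.iloc[1])
        sigma_rows.append(sigma_rows[-1] + traj.sigma.iloc[1] - traj.sigma.iloc[0])
        lam_rows.append(traj.lam.iloc[0])
        mbar_rows.append(traj.mbar.iloc[0])
        muE_rows.append(traj.mu_E.iloc[0])
        ctrl_rows.append(traj.lambda0)
        steps_run += 1
        delta = max(abs(m_new[p] - m_cur[p]) for p in m_new) if m_new else 0.0
        quiet = quiet + 1 if delta < config.tol else 0
        m_cur, aT_cur = m_new, aT_new
        if config.stop_on_convergence and quiet >= config.window:
            break

    def stack(rows, start=0):
        df = pd.DataFrame(rows)
        df.index = range(start, start + len(rows))
        return df

    times = config.dt * np.arange(steps_run + 1)
    return Trajectory(
        times=times,
        m=stack(m_rows),
        a_T=stack(aT_rows),
        sigma=stack(sigma_rows),
        lam=stack(lam_rows),
        mbar=stack(mbar_rows),
        mu_E=stack(muE_rows),
        lambda0=ctrl_rows[-1],
        objective_value=None,
        status="optimal",
        controls=stack(ctrl_rows),
    )
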
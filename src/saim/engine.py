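"""Run loop shared by the two model variants.

A model object exposes analytic energy gradients, the total energy, and the
decomposition of its inter-network drive terms; the engine owns
initialisation bookkeeping, the seeded noisy Euler iteration, threshold
detection and trajectory recording.  Everything stochastic flows through a
single ``numpy`` generator created from the run seed, so a run is exactly
reproducible from ``(parameters, stimulus, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol

import numpy as np

from .dynamics import DivergenceError, ModelParams, NetworkState, euler_step
from .stimuli import Stimulus, TemplateSet

__all__ = ["SimulationResult", "measure_rt", "simulate"]


class Model(Protocol):
    name: str
    stimulus: Stimulus
    templates: TemplateSet
    params: ModelParams

    def initial_state(self) -> NetworkState: ...
    def gradients(self, state: NetworkState): ...
    def total_energy(self, state: NetworkState) -> float: ...
    def input_drives(self, state: NetworkState): ...


def measure_rt(kn_trajectory: np.ndarray, threshold: float):
    """First iteration at which any template unit's rate reaches ``threshold``.

    ``kn_trajectory`` has shape (T, K) with row ``t`` holding the rates at
    iteration ``t``.  Returns ``(rt, winner_index)`` or ``None`` if no unit
    ever crosses.  Simultaneous crossings are broken toward the lowest
    template index.
    """
    kn = np.asarray(kn_trajectory, dtype=float)
    if kn.ndim != 2 or kn.size == 0:
        raise ValueError("kn_trajectory must be a non-empty (T, K) array")
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    crossed = np.nonzero(np.any(kn >= threshold, axis=1))[0]
    if crossed.size == 0:
        return None
    t = int(crossed[0])
    winner = int(np.argmax(kn[t] >= threshold))  # argmax of a bool row -> lowest index
    return t, winner


@dataclass
class SimulationResult:
    """Outcome of one seeded run.

    ``rt`` (iterations) and ``winner`` are defined only when the run did not
    time out; ``error`` is True when a winner was found that differs from
    the stimulus's declared expected winner.  ``kn_trajectory`` always holds
    the (T+1, K) template-unit rates including the initial state;
    ``trajectories`` optionally holds the full Selection/Contents series for
    plotting and neuronal-response summaries.
    """

    model: str
    seed: int
    rt: int | None
    winner: str | None
    error: bool
    timed_out: bool
    diverged: bool
    kn_trajectory: np.ndarray
    energy_trace: np.ndarray | None = None
    trajectories: dict[str, np.ndarray] | None = None
    final_state: NetworkState | None = None
    expected_winner: str | None = None

    @property
    def n_iterations(self) -> int:
        return self.kn_trajectory.shape[0] - 1


def simulate(model: Model, seed: int, *, stop_at_threshold: bool = True,
             record_energy: bool = False,
             record_trajectories: bool = False) -> SimulationResult:
    """Integrate a model to threshold crossing or the iteration budget."""
    params = model.params
    rng = np.random.default_rng(seed)
    state = model.initial_state()
    kn_traj = [state.y_kn.copy()]
    energy = [model.total_energy(state)] if record_energy else None
    sn_traj = [state.y_sn.copy()] if record_trajectories else None
    cn_traj = [state.x_cn.copy()] if record_trajectories else None
    diverged = False
    crossed = measure_rt(np.asarray(kn_traj), params.rt_threshold) is not None

    while state.iteration < params.max_iters and not (crossed and stop_at_threshold):
        try:
            grads = model.gradients(state)
            state = euler_step(state, grads, params, rng)
        except DivergenceError:
            diverged = True
            break
        kn_traj.append(state.y_kn.copy())
        if record_energy:
            energy.append(model.total_energy(state))
        if record_trajectories:
            sn_traj.append(state.y_sn.copy())
            cn_traj.append(state.x_cn.copy())
        if np.max(state.y_kn) >= params.rt_threshold:
            crossed = True

    kn = np.asarray(kn_traj)
    hit = measure_rt(kn, params.rt_threshold)
    if hit is None or diverged:
        rt, winner, timed_out = None, None, True
    else:
        rt, winner_idx = hit
        winner, timed_out = model.templates.labels[winner_idx], False
    expected = model.stimulus.expected_winner
    error = bool(winner is not None and expected is not None and winner != expected)
    trajectories = None
    if record_trajectories:
        trajectories = {"y_sn": np.asarray(sn_traj), "x_cn": np.asarray(cn_traj), "y_kn": kn}
    return SimulationResult(
        model=model.name, seed=int(seed), rt=rt, winner=winner, error=error,
        timed_out=timed_out, diverged=diverged, kn_trajectory=kn,
        energy_trace=None if energy is None else np.asarray(energy),
        trajectories=trajectories, final_state=state, expected_winner=expected,
    )
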
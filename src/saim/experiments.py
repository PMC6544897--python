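"""Simulation studies: reaction-time batches, t-tests, neuronal summaries.

The behavioural read-out of both models is a simulated reaction time — the
number of Euler iterations until a template unit's rate first crosses a
threshold.  The study design contrasts two single-object scenes against a
two-object scene over seeded batches, testing the multiple-object cost
(slower identification with a competing object present) with a pooled
two-sample t-test.  A second read-out sums output rates and the magnitude
of inter-network drives per iteration, a proxy for the population activity
an EEG/fMRI measurement would integrate; the two feedback schemes predict
opposite time courses for it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dynamics import ModelParams
from .em import EMModel, run_em
from .engine import SimulationResult, measure_rt, simulate
from .pe import PEModel, run_pe
from .stimuli import Stimulus, TemplateSet, make_template_set, reference_scenes

__all__ = [
    "BatchSummary",
    "measure_rt",
    "run_model",
    "run_batch",
    "t_test",
    "neuronal_response",
    "compare_study",
]

_MODELS = {"em": EMModel, "pe": PEModel}


def run_model(model: str, stimulus: Stimulus, templates: TemplateSet,
              params: ModelParams, seed: int, **kwargs) -> SimulationResult:
    """Run one seeded simulation of the named variant (``"em"`` or ``"pe"``)."""
    if model not in _MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {sorted(_MODELS)}")
    return simulate(_MODELS[model](stimulus, templates, params), seed, **kwargs)


@dataclass
class BatchSummary:
    """Aggregate of one condition's seeded runs."""

    condition: str
    model: str
    n: int
    rts: list[int]
    error_count: int
    timeout_count: int
    base_seed: int
    results: list[SimulationResult] = field(repr=False, default_factory=list)

    @property
    def mean_rt(self) -> float:
        return float(np.mean(self.rts)) if self.rts else float("nan")

    @property
    def sd_rt(self) -> float:
        return float(np.std(self.rts, ddof=1)) if len(self.rts) > 1 else float("nan")

    def to_rows(self) -> list[dict]:
        return [
            {"condition": self.condition, "model": self.model, "seed": r.seed,
             "rt": r.rt, "winner": r.winner, "error": r.error, "timed_out": r.timed_out}
            for r in self.results
        ]


def run_batch(model: str, stimulus: Stimulus, templates: TemplateSet,
              params: ModelParams, n_runs: int, base_seed: int,
              condition: str = "", keep_results: bool = True) -> BatchSummary:
    """Run ``n_runs`` seeded simulations (seeds ``base_seed .. base_seed+n-1``)."""
    if n_runs < 1:
        raise ValueError("n_runs must be at least 1")
    results = [run_model(model, stimulus, templates, params, base_seed + i)
               for i in range(n_runs)]
    rts = [r.rt for r in results if not r.timed_out]
    return BatchSummary(
        condition=condition or ",".join(l for l, _, _ in stimulus.placements),
        model=model, n=n_runs, rts=rts,
        error_count=sum(r.error for r in results),
        timeout_count=sum(r.timed_out for r in results),
        base_seed=int(base_seed),
        results=results if keep_results else [],
    )


def t_test(rts_a, rts_b) -> tuple[float, int, float]:
    """Two-sample pooled-variance t-test, two-sided.

    Returns ``(t, df, p)`` with ``df = n_a + n_b - 2``.  Implemented from the
    pooled formula (the test suite cross-checks it against scipy).
    """
    a = np.asarray(rts_a, dtype=float)
    b = np.asarray(rts_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    df = a.size + b.size - 2
    pooled_var = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    if pooled_var == 0:
        raise ValueError("zero pooled variance: samples are constant")
    se = np.sqrt(pooled_var * (1.0 / a.size + 1.0 / b.size))
    t = float((a.mean() - b.mean()) / se)
    p = float(2.0 * stats.t.sf(abs(t), df))
    return t, df, p


def neuronal_response(result: SimulationResult, model: str, stimulus: Stimulus,
                      templates: TemplateSet, params: ModelParams,
                      rectified: bool = True) -> dict[str, np.ndarray]:
    """Per-iteration summed activation for the Selection and Knowledge layers.

    For each network the series is ``sum(output rates) + sum(|input drive|)``
    where the input drive is the b-weighted inter-network term of that
    network's gradient (template match / focus correlation for the
    excitatory model, the error-mediated terms for the prediction-error
    model).  The a-weighted normalisation terms and the leak are excluded —
    they stand in for local interneuron activity — and the Contents Network
    is excluded since its activation tracks pixelated input.  With
    ``rectified=False`` the drives are summed signed instead of in
    magnitude.
    """
    if result.trajectories is None:
        raise ValueError("run with record_trajectories=True to summarise responses")
    if model not in _MODELS:
        raise ValueError(f"unknown model {model!r}")
    mdl = _MODELS[model](stimulus, templates, params)
    y_sn = result.trajectories["y_sn"]
    x_cn = result.trajectories["x_cn"]
    y_kn = result.trajectories["y_kn"]
    reduce = np.abs if rectified else (lambda v: v)
    if model == "em":
        drive_sn = params.b_cn * np.einsum("tmn,rcmn->trc", x_cn, mdl.patches)
        drive_kn = params.b_kn * np.einsum("tij,kij->tk", x_cn, mdl.weights)
    else:
        i_cn = np.einsum("trc,rcmn->tmn", y_sn, mdl.patches)
        eps_cn = i_cn - x_cn
        eps_kn = x_cn[:, None] - y_kn[:, :, None, None] * mdl.weights[None]
        drive_sn = params.b_cn * np.einsum("tmn,rcmn->trc", eps_cn, mdl.patches)
        drive_kn = params.b_kn * np.einsum("tkij,kij->tk", eps_kn, mdl.weights)
    return {
        "sn": y_sn.sum(axis=(1, 2)) + reduce(drive_sn).sum(axis=(1, 2)),
        "kn": y_kn.sum(axis=1) + reduce(drive_kn).sum(axis=1),
    }


def compare_study(model: str, templates: TemplateSet | None = None,
                  params: ModelParams | None = None, n_runs: int = 20,
                  base_seed: int = 0, image_size: int = 21) -> dict:
    """The three-condition multiple-object-cost study for one model.

    Runs ``n_runs`` seeded simulations for the single-plus, single-two and
    plus/two scenes, then contrasts reaction times with pooled t-tests.
    Returns the per-condition summaries, the three t-tests, and the error
    counts; fully reproducible from ``(params, base_seed)``.
    """
    from .config import reference_params, reference_templates  # avoids a cycle

    if templates is None:
        templates = reference_templates(model)
    if params is None:
        params = reference_params(model)
    scenes = reference_scenes(templates, image_size)
    order = ["plus", "two", "plus_two"]
    batches = {
        name: run_batch(model, scenes[name], templates, params, n_runs,
                        base_seed + i * n_runs, condition=name)
        for i, name in enumerate(order)
    }
    tests = {}
    for pair in (("plus_two", "plus"), ("plus_two", "two"), ("two", "plus")):
        t, df, p = t_test(batches[pair[0]].rts, batches[pair[1]].rts)
        tests[f"{pair[0]}_vs_{pair[1]}"] = {"t": t, "df": df, "p": p}
    single_errors = batches["plus"].error_count + batches["two"].error_count
    return {
        "model": model,
        "n_runs": n_runs,
        "base_seed": base_seed,
        "batches": batches,
        "t_tests": tests,
        "single_stimulus_errors": single_errors,
        "plus_two_winners": [r.winner for r in batches["plus_two"].results],
    }
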
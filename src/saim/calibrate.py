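"""Reference-configuration evaluation and grid search.

The reference parameter sets shipped in :mod:`saim.config` were fixed by
evaluating candidate configurations against the study's qualitative
requirements: correct winners on noiseless single-object scenes, the
multiple-object reaction-time cost over seeded batches, zero
single-stimulus errors, and significant batch contrasts.  This module
exposes that evaluation so the calibration is reproducible and so users
exploring other geometries can rank their own candidates.
"""

from __future__ import annotations

import itertools

from .config import reference_params, reference_templates
from .dynamics import ModelParams
from .experiments import run_batch, run_model, t_test
from .stimuli import TemplateSet, reference_scenes

__all__ = ["evaluate_config", "grid_search"]


def evaluate_config(model: str, params: ModelParams,
                    templates: TemplateSet | None = None, n_runs: int = 10,
                    base_seed: int = 0, image_size: int = 21) -> dict:
    """Score one configuration against the study's qualitative criteria.

    Returns per-condition summaries plus boolean verdicts: noiseless
    winners correct, RT ordering (two-object slowest, plus fastest), zero
    single-stimulus errors, and p < 0.001 for the two-object vs single-plus
    contrast.
    """
    ts = templates if templates is not None else reference_templates(model)
    scenes = reference_scenes(ts, image_size)
    order = ("plus", "two", "plus_two")
    noiseless_ok = True
    p0 = params.replace(noise_sd=0.0)
    for name in order:
        r = run_model(model, scenes[name], ts, p0, seed=0)
        expect = scenes[name].expected_winner
        leader = ts.labels[int(r.final_state.y_kn.argmax())]
        if (r.winner or leader) != expect:
            noiseless_ok = False
    batches = {
        name: run_batch(model, scenes[name], ts, params, n_runs,
                        base_seed + i * n_runs, condition=name, keep_results=False)
        for i, name in enumerate(order)
    }
    means = {k: b.mean_rt for k, b in batches.items()}
    complete = all(b.timeout_count == 0 and b.rts for b in batches.values())
    ordering = (complete and means["plus_two"] > max(means["plus"], means["two"])
                and means["plus"] <= means["two"])
    errors = batches["plus"].error_count + batches["two"].error_count
    try:
        t, _, p = t_test(batches["plus_two"].rts, batches["plus"].rts)
    except ValueError:
        t, p = float("nan"), 1.0
    return {
        "model": model,
        "params": params,
        "batches": batches,
        "means": means,
        "noiseless_winners_ok": noiseless_ok,
        "rt_ordering_ok": bool(ordering),
        "single_errors": errors,
        "t_plus_two_vs_plus": t,
        "p_plus_two_vs_plus": p,
        "passed": bool(noiseless_ok and ordering and errors == 0 and p < 1e-3),
    }


def grid_search(model: str, grid: dict[str, list], base: ModelParams | None = None,
                templates: TemplateSet | None = None, n_runs: int = 5,
                base_seed: int = 0) -> list[dict]:
    """Evaluate every combination in ``grid`` (keys are ModelParams fields).

    Returns evaluations sorted with passing configurations first, then by
    the strength of the two-object contrast.
    """
    base = base if base is not None else reference_params(model)
    keys = list(grid)
    results = []
    for values in itertools.product(*(grid[k] for k in keys)):
        params = base.replace(**dict(zip(keys, values)))
        results.append(evaluate_config(model, params, templates=templates,
                                       n_runs=n_runs, base_seed=base_seed))
    results.sort(key=lambda r: (not r["passed"], r["p_plus_two_vs_plus"]))
    return results
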
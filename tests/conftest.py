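"""Shared fixtures: small synthetic experiments reused across test modules.

Session-scoped so the expensive pieces (simulation + constrained fits) run
once; everything is seeded, so reruns are deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest

from ventriloquist import design, observer, pipeline
from ventriloquist import psychometrics as psy
from ventriloquist.config import RunConfig


@pytest.fixture(scope="session")
def small_config(tmp_path_factory) -> RunConfig:
    out = tmp_path_factory.mktemp("run")
    return RunConfig(n_subjects=2, n_av_sessions_per_report=2,
                     n_auditory_sessions=1, n_visual_sessions=1,
                     n_starts=6, seed=42, out_dir=str(out))


@pytest.fixture(scope="session")
def behavior_fitted(small_config):
    trials = pipeline.simulate_behavior(small_config)
    return trials, pipeline.fit_subjects(small_config, trials)


@pytest.fixture(scope="session")
def fusion_summary_idealized():
    """Large-n fusion-mode experiment on the idealized (evenly spaced) grid.

    One subject, pure forced-fusion observer with known parameters; trial
    counts large enough that the fitted parameters sit within tight
    bootstrap intervals of the generative values.
    """
    grid = design.idealized_grid()
    obs = observer.ObserverParams(sigma_a=10.0, sigma_v_high=4.0,
                                  sigma_v_low=9.0, lapse=0.04, mode="fusion")
    conds = design.enumerate_mle_conditions(grid)
    plans = [design.build_session_plan(conds, trials_per_condition=300,
                                       null_fraction=0.0, seed=7 + i, session_id=i)
             for i in range(4)]  # 1200 trials per condition in total
    trials = observer.simulate_experiment(plans, obs, seed=99, grid=grid)
    summary = psy.mle_subset(psy.summarize(trials, grid))
    return {"grid": grid, "observer": obs, "summary": summary}


@pytest.fixture(scope="session")
def fusion_fit_idealized(fusion_summary_idealized):
    grid = fusion_summary_idealized["grid"]
    scheme = psy.build_scheme("model_IV", design.enumerate_mle_conditions(grid))
    result = psy.fit(fusion_summary_idealized["summary"], scheme,
                     psy.FitOptions(n_starts=8, seed=3))
    return result
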
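"""Simulation-based validation studies.

Two recurring checks on the whole modelling stack:

* model-selection study — simulate replicate datasets from the quadratic
  ground truth at study scale and verify that WAIC weights prefer the
  quadratic over the linear model;
* coverage study — verify that 95% credible intervals of the population
  coefficients cover the generating values at the nominal rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .formulas import MODEL_FORMULAS
from .inference import compare
from .models import BayesianMixedModel
from .simulate import simulate_features, simulate_srs
from .study import StudyDesign, default_ground_truth


@dataclass
class SelectionStudyResult:
    quadratic_wins: int
    n_replicates: int
    weights: list[float]

    @property
    def win_rate(self) -> float:
        return self.quadratic_wins / self.n_replicates


def waic_selection_study(n_replicates: int = 20, seed: int = 0,
                         draws: int = 1000, warmup: int = 500,
                         design: StudyDesign | None = None) -> SelectionStudyResult:
    """Fit linear vs quadratic SRS-total models to replicate synthetic
    datasets (both groups, quadratic truth) and count how often the
    quadratic model receives the larger WAIC weight."""
    design = design or StudyDesign()
    truth = default_ground_truth(design, seed=seed)
    wins = 0
    weights = []
    for rep in range(n_replicates):
        data = simulate_srs(design, truth, seed=seed * 1000 + rep)
        frame = data.rename(columns={"Total": "Score"})
        fits = {}
        for i, name in enumerate(("M1SRS", "M2SRS")):
            fits[name] = BayesianMixedModel(
                MODEL_FORMULAS[name], draws=draws, warmup=warmup,
                seed=seed * 1000 + rep * 10 + i).fit(frame)
        table = compare(fits)
        w_quad = float(table.loc["M2SRS", "weight"])
        weights.append(w_quad)
        if w_quad > 0.5:
            wins += 1
    return SelectionStudyResult(quadratic_wins=wins, n_replicates=n_replicates,
                                weights=weights)


@dataclass
class CoverageStudyResult:
    covered: int
    cells: int
    per_replicate: list[float]

    @property
    def coverage(self) -> float:
        return self.covered / self.cells


def coverage_study(n_replicates: int = 20, seed: int = 0,
                   draws: int = 1000, warmup: int = 500,
                   design: StudyDesign | None = None,
                   level: float = 0.95) -> CoverageStudyResult:
    """Simulate replicate SCP feature tables from the quadratic truth at a
    reduced scale and check how often the central credible intervals of
    the 18 population coefficients cover the generating values."""
    design = design or StudyDesign(n_experimental=12, n_sessions=12,
                                   phase_break_session=6)
    truth = default_ground_truth(design, seed=seed)
    a = (1.0 - level) / 2.0
    covered = 0
    cells = 0
    per_rep = []
    for rep in range(n_replicates):
        data = simulate_features(design, truth, seed=seed * 1000 + rep)
        fit = BayesianMixedModel(MODEL_FORMULAS["M2SCP"], draws=draws,
                                 warmup=warmup,
                                 seed=seed * 1000 + rep).fit(data)
        beta_true = data.attrs["beta"]
        post = fit.beta_draws_.reshape(-1, fit.design_.n_fixed)
        hit = 0
        for j, col in enumerate(fit.design_.columns):
            lo, hi = np.quantile(post[:, j], [a, 1.0 - a])
            if lo <= beta_true[col] <= hi:
                hit += 1
        covered += hit
        cells += fit.design_.n_fixed
        per_rep.append(hit / fit.design_.n_fixed)
    return CoverageStudyResult(covered=covered, cells=cells, per_replicate=per_rep)
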
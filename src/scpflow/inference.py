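"""Posterior functionals: WAIC, model weights, predicted trajectories,
improvement scores, differentiation, evidence ratios and strength labels.

Every functional operates draw-wise on the posterior of a fitted model, so
each derived quantity is itself a posterior distribution summarised by its
mean and a central (equal-tailed) 95% credible interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .study import GROUPS, TASKS, ValidationError

# Kass-Raftery strength-of-evidence cut points on the evidence-ratio scale
KASS_RAFTERY_CUTS = (1.0, 3.2, 10.0, 100.0)
KASS_RAFTERY_LABELS = (
    "negative",
    "barely worth mentioning",
    "substantial",
    "strong",
    "decisive",
)


# ---------------------------------------------------------------------------
# WAIC and model weights


@dataclass
class WAICResult:
    """Widely applicable information criterion for one fitted model."""

    elpd_waic: float
    p_waic: float
    waic: float
    n_obs: int
    elpd_pointwise: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.elpd_pointwise = np.asarray(self.elpd_pointwise)


def waic(fit_or_loglik) -> WAICResult:
    """WAIC from pointwise posterior log likelihoods.

    Per observation i over draws s:
    ``elpd_i = log mean_s exp(ll_is) - var_s(ll_is)`` (log-sum-exp
    stabilized; sample variance with ddof=1), ``waic = -2 sum_i elpd_i``.
    """
    ll = getattr(fit_or_loglik, "loglik_", fit_or_loglik)
    if ll is None:
        raise ValidationError("fit has no stored pointwise log-likelihood")
    ll = np.asarray(ll, dtype=float)
    if ll.ndim == 3:  # (chains, draws, n) -> (S, n)
        ll = ll.reshape(-1, ll.shape[-1])
    if not np.isfinite(ll).all():
        raise ValidationError("non-finite pointwise log-likelihood values")
    S = ll.shape[0]
    lppd = logsumexp(ll, axis=0) - np.log(S)
    p_i = ll.var(axis=0, ddof=1) if S > 1 else np.zeros(ll.shape[1])
    elpd_i = lppd - p_i
    elpd = float(elpd_i.sum())
    return WAICResult(elpd_waic=elpd, p_waic=float(p_i.sum()), waic=-2.0 * elpd,
                      n_obs=ll.shape[1], elpd_pointwise=elpd_i)


def model_weights(waics) -> np.ndarray:
    """Pseudo-BMA weights: ``w_m = exp(-Delta_m/2) / sum_k exp(-Delta_k/2)``
    with ``Delta = waic - min(waic)``."""
    values = np.array([w.waic if isinstance(w, WAICResult) else float(w)
                       for w in waics])
    if len(values) < 2:
        raise ValidationError("model comparison needs at least two models")
    delta = values - values.min()
    raw = np.exp(-0.5 * delta)
    return raw / raw.sum()


def compare(fits: dict[str, object]) -> pd.DataFrame:
    """WAIC comparison table across named fitted models (same data).

    Columns: elpd_waic, p_waic, waic, delta (vs best), weight.
    """
    results = {name: waic(fit) for name, fit in fits.items()}
    ns = {r.n_obs for r in results.values()}
    if len(ns) != 1:
        raise ValidationError(
            f"models were fitted to different observation counts: {ns}")
    table = pd.DataFrame(
        {
            "elpd_waic": {k: r.elpd_waic for k, r in results.items()},
            "p_waic": {k: r.p_waic for k, r in results.items()},
            "waic": {k: r.waic for k, r in results.items()},
        }
    )
    table["delta"] = table["waic"] - table["waic"].min()
    table["weight"] = model_weights(list(results.values()))
    return table.sort_values("waic")


# ---------------------------------------------------------------------------
# derived posteriors


@dataclass
class DerivedPosterior:
    """Posterior draws of a scalar functional of a fitted model."""

    name: str
    draws: np.ndarray
    context: dict = field(default_factory=dict)

    def __post_init__(self):
        self.draws = np.asarray(self.draws, dtype=float).ravel()
        if self.draws.size == 0:
            raise ValidationError(f"derived posterior {self.name!r} has no draws")

    @property
    def mean(self) -> float:
        return float(self.draws.mean())

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        a = (1.0 - level) / 2.0
        lo, hi = np.quantile(self.draws, [a, 1.0 - a])
        return float(lo), float(hi)

    def summary(self) -> str:
        lo, hi = self.ci()
        return f"{self.name}: {self.mean:.2f} (95% CI {lo:.2f} to {hi:.2f})"

    def __sub__(self, other: "DerivedPosterior") -> "DerivedPosterior":
        if self.draws.shape != other.draws.shape:
            raise ValidationError("draw counts differ; posteriors not comparable")
        return DerivedPosterior(
            name=f"{self.name} - {other.name}",
            draws=self.draws - other.draws,
            context={**other.context, **self.context},
        )


def predict(fit, covariates: pd.DataFrame) -> np.ndarray:
    """Per-draw population expectation at the covariate rows; (S, m)."""
    return fit.predict_draws(covariates)


def _fitted_groups(fit) -> set[str]:
    data_groups = getattr(fit, "_groups_cache", None)
    if data_groups is None:
        from .formulas import _known_levels

        levels = _known_levels(fit.design_.fixed_design_info, "Group")
        data_groups = set(levels) if levels else set()
    return data_groups


def mean_improvement(fit, group: str, occasions: tuple[int, int] = (1, 6),
                     outcome: str | None = None) -> DerivedPosterior:
    """Questionnaire improvement: prediction at the first occasion minus the
    last; positive values mean symptom reduction."""
    if group not in GROUPS:
        raise ValidationError(f"unknown group {group!r}; expected one of {GROUPS}")
    first, last = occasions
    newdata = pd.DataFrame({"Group": [group, group], "Time": [first, last]})
    draws = fit.predict_draws(newdata)
    if draws.ndim == 3:  # multivariate fit: pick one subscale
        if outcome is None:
            raise ValidationError("multivariate fit: pass outcome=<subscale>")
        idx = list(fit.outcomes).index(outcome)
        draws = draws[:, :, idx]
    diff = draws[:, 0] - draws[:, 1]
    return DerivedPosterior(
        name=f"mean improvement ({group})", draws=diff,
        context={"group": group, "occasions": occasions, "outcome": outcome},
    )


def difference_in_improvement(fit, occasions: tuple[int, int] = (1, 6),
                              outcome: str | None = None) -> DerivedPosterior:
    """D: improvement of the experimental group minus the control group."""
    groups = _fitted_groups(fit)
    if not {"control", "experimental"} <= groups:
        raise ValidationError(
            f"both groups must be present in the fitted data; found {sorted(groups)}")
    exp = mean_improvement(fit, "experimental", occasions, outcome)
    ctl = mean_improvement(fit, "control", occasions, outcome)
    d = exp - ctl
    d.name = "D (difference in improvement)"
    d.context = {"occasions": occasions, "outcome": outcome}
    return d


def differentiation(fit, condition: str, session: int) -> DerivedPosterior:
    """Signed task contrast: predicted amplitude under the negativity task
    minus under the positivity task (negative = stronger regulation)."""
    newdata = pd.DataFrame({
        "Condition": [condition, condition],
        "Task": list(TASKS),
        "Session": [session, session],
    })
    draws = fit.predict_draws(newdata)
    return DerivedPosterior(
        name=f"differentiation ({condition}, session {session})",
        draws=draws[:, 0] - draws[:, 1],
        context={"condition": condition, "session": session},
    )


def differentiation_change(fit, condition: str,
                           sessions: tuple[int, int] = (1, 24)) -> DerivedPosterior:
    """Change in differentiation from the first to the last session."""
    first, last = sessions
    end = differentiation(fit, condition, last)
    start = differentiation(fit, condition, first)
    out = end - start
    out.name = f"differentiation change ({condition})"
    out.context = {"condition": condition, "sessions": sessions}
    return out


# ---------------------------------------------------------------------------
# evidence ratios


@dataclass
class EvidenceReport:
    """Directional hypothesis test via posterior draws."""

    hypothesis: str
    posterior_probability: float
    evidence_ratio: float
    label: str
    er_is_bound: bool
    n_draws: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        er = (f">= {self.evidence_ratio:g}" if self.er_is_bound and
              self.posterior_probability == 1.0 else
              f"<= {self.evidence_ratio:g}" if self.er_is_bound else
              f"{self.evidence_ratio:.2f}")
        return (f"{self.hypothesis}: p={self.posterior_probability:.3f}, "
                f"ER {er} ({self.label})")


def evidence_ratio(derived: DerivedPosterior | np.ndarray,
                   hypothesis: str = ">0") -> EvidenceReport:
    """Posterior odds for a directional hypothesis about a derived quantity.

    ``p`` is the fraction of draws satisfying the hypothesis and
    ``ER = p / (1 - p)``.  At ``p = 1`` (or 0) the ratio is reported as a
    finite bound determined by the draw count, never as infinity.
    """
    draws = derived.draws if isinstance(derived, DerivedPosterior) else np.asarray(derived)
    name = derived.name if isinstance(derived, DerivedPosterior) else "quantity"
    if draws.size == 0:
        raise ValidationError("no draws to test")
    import warnings

    if draws.size < 1000:
        warnings.warn(
            f"only {draws.size} draws for the evidence ratio; at least 1000 "
            "are recommended", stacklevel=2)
    hyp = hypothesis.replace(" ", "")
    if hyp in (">0", "+"):
        p = float(np.mean(draws > 0))
        text = f"{name} > 0"
    elif hyp in ("<0", "-"):
        p = float(np.mean(draws < 0))
        text = f"{name} < 0"
    else:
        raise ValidationError(f"hypothesis must be '>0' or '<0', got {hypothesis!r}")
    S = draws.size
    if p >= 1.0:
        er, bound = float(S), True
    elif p <= 0.0:
        er, bound = 1.0 / S, True
    else:
        er, bound = p / (1.0 - p), False
    return EvidenceReport(
        hypothesis=text, posterior_probability=p, evidence_ratio=er,
        label=label_strength(er), er_is_bound=bound, n_draws=S,
    )


def label_strength(er: float) -> str:
    """Kass-Raftery qualitative strength-of-evidence label for an ER."""
    if er < 0:
        raise ValidationError("evidence ratio must be non-negative")
    for cut, label in zip(KASS_RAFTERY_CUTS, KASS_RAFTERY_LABELS):
        if er < cut:
            return label
    return KASS_RAFTERY_LABELS[-1]
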
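"""Study design and generative ground truth for an SCP neurofeedback trial.

The design mirrors a two-arm randomized trial: an experimental arm that
trains volitional regulation of slow cortical potentials (SCPs) over 24
sessions, each with three blocks (feedback 1, transfer, feedback 2) and two
regulation tasks (required negativity / required positivity), plus a
six-occasion parent questionnaire (SRS: total score and five subscales)
collected in both arms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

CONDITIONS = ("feedback1", "transfer", "feedback2")
TASKS = ("negativity", "positivity")
GROUPS = ("control", "experimental")
SRS_SUBSCALES = ("SA", "SCOG", "SCOM", "SM", "AM")

#: varying-effect terms of the quadratic SCP model, one set per person
#: (expansion order of ``1 + (Session + Session2)*Task``)
SCP_VARYING_TERMS = (
    "Intercept",
    "Task[positivity]",
    "Session",
    "Session:Task[positivity]",
    "Session2",
    "Session2:Task[positivity]",
)

#: varying-effect terms of the quadratic SRS model
SRS_VARYING_TERMS = ("Intercept", "Time", "Time2")


class ValidationError(ValueError):
    """Raised when a design or ground-truth object violates its invariants."""


def _check_correlation(mat: np.ndarray, name: str) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValidationError(f"{name} must be a square matrix")
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValidationError(f"{name} must be symmetric")
    if not np.allclose(np.diag(mat), 1.0, atol=1e-10):
        raise ValidationError(f"{name} must have unit diagonal")
    try:
        np.linalg.cholesky(mat)
    except np.linalg.LinAlgError:
        raise ValidationError(f"{name} must be positive definite") from None
    return mat


@dataclass(frozen=True)
class StudyDesign:
    """Factorial layout of the trial.

    Defaults reproduce the study conditions: 21 experimental + 20 control
    participants, 24 sessions split into two 12-session phases, 120 trials
    per session over 3 condition blocks, negativity/positivity task ratio
    50/50 in phase 1 and 80/20 in phase 2, six SRS occasions, EEG sampled
    at 128 Hz with 2 s baseline and 8 s trial windows.
    """

    n_experimental: int = 21
    n_control: int = 20
    n_sessions: int = 24
    phase_break_session: int = 12
    trials_per_session: int = 120
    conditions: tuple[str, ...] = CONDITIONS
    task_ratio_phase1: float = 0.5
    task_ratio_phase2: float = 0.8
    n_occasions_srs: int = 6
    sampling_rate: float = 128.0
    baseline_dur: float = 2.0
    trial_dur: float = 8.0

    def __post_init__(self) -> None:
        counts = {
            "n_experimental": self.n_experimental,
            "n_control": self.n_control,
            "n_sessions": self.n_sessions,
            "phase_break_session": self.phase_break_session,
            "trials_per_session": self.trials_per_session,
            "n_occasions_srs": self.n_occasions_srs,
        }
        for key, val in counts.items():
            if int(val) != val or val <= 0:
                raise ValidationError(f"{key} must be a positive integer, got {val!r}")
        for key in ("task_ratio_phase1", "task_ratio_phase2"):
            r = getattr(self, key)
            if not 0.0 < r < 1.0:
                raise ValidationError(f"{key} must lie strictly in (0, 1), got {r}")
        if self.phase_break_session >= self.n_sessions:
            raise ValidationError("phase_break_session must be < n_sessions")
        for key in ("sampling_rate", "baseline_dur", "trial_dur"):
            if getattr(self, key) <= 0:
                raise ValidationError(f"{key} must be positive")
        for dur in (self.baseline_dur, self.trial_dur):
            n = dur * self.sampling_rate
            if abs(n - round(n)) > 1e-9:
                raise ValidationError(
                    "baseline_dur and trial_dur must be whole numbers of samples "
                    f"at {self.sampling_rate} Hz"
                )

    @property
    def n_participants(self) -> int:
        return self.n_experimental + self.n_control

    @property
    def baseline_samples(self) -> int:
        return int(round(self.baseline_dur * self.sampling_rate))

    @property
    def trial_samples(self) -> int:
        return int(round(self.trial_dur * self.sampling_rate))

    @property
    def session_center(self) -> float:
        return (1 + self.n_sessions) / 2.0

    @property
    def occasion_center(self) -> float:
        return (1 + self.n_occasions_srs) / 2.0

    def task_ratio(self, session: int) -> float:
        """Fraction of negativity trials in ``session`` (phase-dependent)."""
        return (
            self.task_ratio_phase1
            if session <= self.phase_break_session
            else self.task_ratio_phase2
        )

    def trials_per_condition(self) -> int:
        return self.trials_per_session // len(self.conditions)

    def with_(self, **kwargs) -> "StudyDesign":
        return replace(self, **kwargs)


def _default_scp_varying_corr() -> np.ndarray:
    corr = np.eye(len(SCP_VARYING_TERMS))
    # people with more negative baselines tend to show larger task contrasts
    corr[0, 1] = corr[1, 0] = 0.2
    return corr


def _default_srs_term_corr() -> np.ndarray:
    corr = np.eye(len(SRS_VARYING_TERMS))
    corr[0, 1] = corr[1, 0] = -0.2  # higher-scoring children improve a bit faster
    return corr


def _exchangeable(n: int, rho: float) -> np.ndarray:
    return np.full((n, n), rho) + (1 - rho) * np.eye(n)


@dataclass
class GroundTruth:
    """Generative parameters for the synthetic study.

    ``fixed_coefficients`` is keyed by the design columns of the quadratic
    SCP model (treatment coding, session centered before squaring); the SRS
    block is parameterised per subscale.  Defaults are calibrated once to
    the reported effect magnitudes: task differentiation around -2.3 uV at
    session 1 growing to about -5.5 uV by session 24 in the first feedback
    block, near-flat differentiation in the other blocks, and SRS declines
    of about 13.5 (control) vs 21.4 (experimental) total points with a
    decelerating (quadratic) time course.
    """

    fixed_coefficients: dict[str, float]
    varying_sd: np.ndarray
    varying_corr: np.ndarray
    residual_sd: float
    srs_intercepts: np.ndarray
    srs_linear: np.ndarray
    srs_quadratic: np.ndarray
    srs_group_time_effect: float
    srs_group_time_weights: np.ndarray
    srs_varying_sd: np.ndarray
    srs_term_corr: np.ndarray
    srs_subscale_corr_varying: np.ndarray
    srs_residual_sd: np.ndarray
    srs_subscale_residual_corr: np.ndarray
    artifact_rate: float = 0.05
    pink_noise_sd: float = 10.0
    alpha_osc_amplitude: float = 4.0
    artifact_amplitude: float = 400.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.varying_sd = np.asarray(self.varying_sd, dtype=float)
        self.srs_varying_sd = np.asarray(self.srs_varying_sd, dtype=float)
        self.srs_residual_sd = np.asarray(self.srs_residual_sd, dtype=float)
        self.srs_intercepts = np.asarray(self.srs_intercepts, dtype=float)
        self.srs_linear = np.asarray(self.srs_linear, dtype=float)
        self.srs_quadratic = np.asarray(self.srs_quadratic, dtype=float)
        self.srs_group_time_weights = np.asarray(
            self.srs_group_time_weights, dtype=float
        )
        if np.any(self.varying_sd < 0) or np.any(self.srs_varying_sd < 0):
            raise ValidationError("varying-effect standard deviations must be >= 0")
        if self.residual_sd < 0 or np.any(self.srs_residual_sd < 0):
            raise ValidationError("residual standard deviations must be >= 0")
        if not 0.0 <= self.artifact_rate < 1.0:
            raise ValidationError("artifact_rate must lie in [0, 1)")
        self.varying_corr = _check_correlation(self.varying_corr, "varying_corr")
        self.srs_term_corr = _check_correlation(self.srs_term_corr, "srs_term_corr")
        self.srs_subscale_corr_varying = _check_correlation(
            self.srs_subscale_corr_varying, "srs_subscale_corr_varying"
        )
        self.srs_subscale_residual_corr = _check_correlation(
            self.srs_subscale_residual_corr, "srs_subscale_residual_corr"
        )
        if len(self.varying_sd) != self.varying_corr.shape[0]:
            raise ValidationError("varying_sd length must match varying_corr size")
        if not np.isclose(self.srs_group_time_weights.sum(), 1.0):
            raise ValidationError("srs_group_time_weights must sum to 1")

    def varying_cov(self) -> np.ndarray:
        d = np.diag(self.varying_sd)
        return d @ self.varying_corr @ d

    def srs_varying_cov(self) -> np.ndarray:
        """Joint 15x15 covariance of per-person SRS effects.

        Ordered subscale-major: (SA intercept, SA linear, SA quadratic,
        SCOG intercept, ...).  The correlation is the Kronecker product of
        an exchangeable across-subscale block and a small within-subscale
        term block, so deficits co-vary across subscales.
        """
        corr = np.kron(self.srs_subscale_corr_varying, self.srs_term_corr)
        sd = np.tile(self.srs_varying_sd, len(SRS_SUBSCALES))
        d = np.diag(sd)
        return d @ corr @ d

    def srs_residual_cov(self) -> np.ndarray:
        d = np.diag(self.srs_residual_sd)
        return d @ self.srs_subscale_residual_corr @ d


# Differentiation anchors (negativity - positivity, in uV) at the first and
# last session of each block, with a mild quadratic curvature.  The first
# feedback block shows the pronounced learning effect; transfer and the
# second feedback block stay nearly flat.
_DIFF_ANCHORS = {
    "feedback1": (-2.28, -5.54, -0.004),
    "transfer": (-3.77, -4.01, -0.002),
    "feedback2": (-4.08, -3.94, -0.002),
}

# Negativity-task trajectory: intercept per block plus a common mild
# negative-going quadratic trend across sessions.
_NEG_INTERCEPTS = {"feedback1": -1.0, "transfer": -1.4, "feedback2": -1.5}
_NEG_LINEAR = -0.06
_NEG_QUAD = -0.006

# Per-subscale differences-in-improvement used to weight the group x time
# effect (SA, SCOG, SCOM, SM, AM ordering).
_SRS_D_WEIGHTS = np.array([0.68, 1.88, 2.1, 1.51, 2.01])


def scp_truth_surface(
    condition: str, task: str, session: np.ndarray, design: StudyDesign
) -> np.ndarray:
    """Noise-free expected SCP amplitude (uV) at the given factorial cell."""
    s = np.asarray(session, dtype=float) - design.session_center
    half = (design.n_sessions - 1) / 2.0
    d1, d24, c = _DIFF_ANCHORS[condition]
    b = (d24 - d1) / (2 * half)
    a = (d1 + d24) / 2.0 - c * half**2
    diff = a + b * s + c * s**2
    neg = _NEG_INTERCEPTS[condition] + _NEG_LINEAR * s + _NEG_QUAD * s**2
    if task == "negativity":
        return neg
    return neg - diff  # positivity = negativity - differentiation


def default_scp_coefficients(design: StudyDesign | None = None) -> dict[str, float]:
    """Project the anchor surface onto the quadratic-model design columns.

    The surface is quadratic in the centered session within each
    condition x task cell, hence lies exactly in the span of the 18-column
    treatment-coded design; the projection is an exact solve.
    """
    from .formulas import build_fixed_matrix  # local import: avoids cycle

    design = design or StudyDesign()
    grid = _factorial_grid(design)
    X, names = build_fixed_matrix(
        "Condition*Task*(Session + Session2)", grid, session_center=design.session_center
    )
    y = np.concatenate(
        [
            scp_truth_surface(c, t, grid.loc[(grid.Condition == c) & (grid.Task == t), "Session"].to_numpy(), design)
            for c in design.conditions
            for t in TASKS
        ]
    )
    order = np.concatenate(
        [
            grid.index[(grid.Condition == c) & (grid.Task == t)].to_numpy()
            for c in design.conditions
            for t in TASKS
        ]
    )
    beta, res, rank, _ = np.linalg.lstsq(X[order], y, rcond=None)
    if rank < X.shape[1]:
        raise ValidationError("design grid does not identify all coefficients")
    return dict(zip(names, beta))


def _factorial_grid(design: StudyDesign):
    import pandas as pd

    rows = [
        (s, c, t)
        for s in range(1, design.n_sessions + 1)
        for c in design.conditions
        for t in TASKS
    ]
    return pd.DataFrame(rows, columns=["Session", "Condition", "Task"])


def default_ground_truth(design: StudyDesign | None = None, seed: int = 0) -> GroundTruth:
    """Ground truth calibrated to the reported study magnitudes.

    The quadratic model is the true generative model: fixed and per-person
    quadratic session terms are nonzero, so model comparison between a
    linear and a quadratic fit is a meaningful recovery exercise.
    """
    design = design or StudyDesign()
    weights = _SRS_D_WEIGHTS / _SRS_D_WEIGHTS.sum()
    return GroundTruth(
        fixed_coefficients=default_scp_coefficients(design),
        varying_sd=np.array([2.5, 2.0, 0.08, 0.05, 0.006, 0.004]),
        varying_corr=_default_scp_varying_corr(),
        residual_sd=2.5,
        srs_intercepts=np.array([12.0, 18.0, 32.0, 16.0, 16.0]),
        # improvement (t1 - t6) = -5 * linear slope => control improves 2.7
        # points per subscale (13.5 total)
        srs_linear=np.full(5, -0.54),
        srs_quadratic=np.full(5, 0.35),
        # total-score group x time slope difference: D_total = 7.88 = -5 * g
        srs_group_time_effect=-7.88 / 5.0,
        srs_group_time_weights=weights,
        srs_varying_sd=np.array([4.0, 0.35, 0.1]),
        srs_term_corr=_default_srs_term_corr(),
        srs_subscale_corr_varying=_exchangeable(5, 0.5),
        srs_residual_sd=np.full(5, 1.8),
        srs_subscale_residual_corr=_exchangeable(5, 0.3),
        artifact_rate=0.05,
        seed=seed,
    )
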
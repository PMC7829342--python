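"""Synthetic study generator.

Emulates the trial's design with known ground truth: trial-level SCP /
band-power feature tables following a quadratic-in-session multilevel
surface with correlated per-person effects, raw EEG epochs (pink
background, 10 Hz oscillation, task-dependent slow drift, occasional
artifact transients), and six-occasion SRS trajectories with a quadratic
decline and a group x time effect.  All generators are deterministic given
``(design, truth, seed)``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .epochs import EpochSet
from .formulas import MODEL_FORMULAS, build_design
from .study import (
    GROUPS,
    SCP_VARYING_TERMS,
    SRS_SUBSCALES,
    TASKS,
    GroundTruth,
    StudyDesign,
    ValidationError,
    default_ground_truth,
)

# stage tags folded into the seed stream so each generator draws
# independent, reproducible randomness from one root seed
_STAGE_FEATURES = 11
_STAGE_EPOCHS = 12
_STAGE_SRS = 13


def _rng(seed: int | None, truth: GroundTruth, stage: int) -> np.random.Generator:
    root = truth.seed if seed is None else seed
    return np.random.default_rng(np.random.SeedSequence([int(root), stage]))


def _participant_ids(n: int, prefix: str) -> list[str]:
    return [f"{prefix}{i:02d}" for i in range(1, n + 1)]


def _scaled_cholesky(sd: np.ndarray, corr: np.ndarray) -> np.ndarray:
    # diag(sd) @ chol(corr): valid even when some sds are exactly zero
    return np.diag(sd) @ np.linalg.cholesky(corr)


def simulate_features(design: StudyDesign | None = None,
                      truth: GroundTruth | None = None,
                      seed: int | None = None) -> pd.DataFrame:
    """Cell-level SCP amplitude table for the experimental arm.

    One row per participant x session x condition x task; the outcome is
    the fixed quadratic-in-session surface plus correlated person-specific
    deviations plus Gaussian noise.  The generating coefficient vector is
    echoed in ``df.attrs``.
    """
    design = design or StudyDesign()
    truth = truth or default_ground_truth(design)
    rng = _rng(seed, truth, _STAGE_FEATURES)

    persons = _participant_ids(design.n_experimental, "E")
    grid = pd.DataFrame(
        [
            (p, s, c, t)
            for p in persons
            for s in range(1, design.n_sessions + 1)
            for c in design.conditions
            for t in TASKS
        ],
        columns=["Person", "Session", "Condition", "Task"],
    )
    grid["Amplitude"] = 0.0
    dm = build_design(MODEL_FORMULAS["M2SCP"], grid,
                      centers={"Session": design.session_center})
    missing = [c for c in dm.columns if c not in truth.fixed_coefficients]
    if missing:
        raise ValidationError(f"fixed_coefficients missing terms: {missing}")
    beta = np.array([truth.fixed_coefficients[c] for c in dm.columns])

    # permute the truth covariance into the expansion order of Z
    order = [SCP_VARYING_TERMS.index(c) for c in dm.z_columns]
    sd = truth.varying_sd[order]
    corr = truth.varying_corr[np.ix_(order, order)]
    L = _scaled_cholesky(sd, corr)
    u = rng.standard_normal((dm.n_groups, len(order))) @ L.T

    mu = dm.X @ beta + np.einsum("ij,ij->i", dm.Z, u[dm.group_index])
    grid["Amplitude"] = mu + rng.normal(0.0, truth.residual_sd, size=len(grid))
    grid.attrs["beta"] = dict(zip(dm.columns, beta))
    grid.attrs["varying_sd"] = dict(zip(dm.z_columns, sd))
    grid.attrs["seed"] = truth.seed if seed is None else seed
    return grid


def simulate_srs(design: StudyDesign | None = None,
                 truth: GroundTruth | None = None,
                 seed: int | None = None,
                 round_scores: bool = False) -> pd.DataFrame:
    """Longitudinal SRS table: both groups, six occasions, five subscales.

    Subscale residuals are drawn jointly with the specified 5x5 residual
    correlation; per-person intercept/linear/quadratic effects are drawn
    from the joint 15-dimensional covariance so deficits co-vary across
    subscales.  ``Total`` is the row sum of the subscales.
    """
    design = design or StudyDesign()
    truth = truth or default_ground_truth(design)
    rng = _rng(seed, truth, _STAGE_SRS)

    persons = _participant_ids(design.n_control, "C") + _participant_ids(
        design.n_experimental, "E"
    )
    group_of = {p: ("control" if p.startswith("C") else "experimental") for p in persons}
    times = np.arange(1, design.n_occasions_srs + 1)
    tc = times - design.occasion_center

    n_sub = len(SRS_SUBSCALES)
    g_sub = truth.srs_group_time_effect * truth.srs_group_time_weights

    cov_u = truth.srs_varying_cov()
    L_u = np.linalg.cholesky(cov_u + 1e-12 * np.eye(cov_u.shape[0])) \
        if np.any(np.diag(cov_u) > 0) else np.zeros_like(cov_u)
    L_e = _scaled_cholesky(truth.srs_residual_sd, truth.srs_subscale_residual_corr)

    rows = []
    for p in persons:
        is_exp = group_of[p] == "experimental"
        u = (rng.standard_normal(cov_u.shape[0]) @ L_u.T).reshape(n_sub, 3)
        eps = rng.standard_normal((len(times), n_sub)) @ L_e.T
        for j, t in enumerate(times):
            scores = (
                truth.srs_intercepts
                + (truth.srs_linear + (g_sub if is_exp else 0.0)) * tc[j]
                + truth.srs_quadratic * tc[j] ** 2
                + u[:, 0] + u[:, 1] * tc[j] + u[:, 2] * tc[j] ** 2
                + eps[j]
            )
            rows.append((p, group_of[p], int(t), *scores))
    df = pd.DataFrame(rows, columns=["Person", "Group", "Time", *SRS_SUBSCALES])
    if round_scores:
        df[list(SRS_SUBSCALES)] = df[list(SRS_SUBSCALES)].round()
    df["Total"] = df[list(SRS_SUBSCALES)].sum(axis=1)
    df.attrs["group_time_effect"] = dict(zip(SRS_SUBSCALES, g_sub))
    df.attrs["seed"] = truth.seed if seed is None else seed
    return df


def _pink_noise(rng: np.random.Generator, n: int, rate: float, sd: float,
                knee_hz: float = 0.5) -> np.ndarray:
    """Spectrally shaped white noise with power ~ 1/f above ``knee_hz``."""
    if sd == 0:
        return np.zeros(n)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    shape = 1.0 / np.sqrt(np.maximum(freqs, knee_hz))
    spec = (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    spec[0] = 0.0
    x = np.fft.irfft(spec * shape, n=n)
    x_sd = x.std()
    return x * (sd / x_sd) if x_sd > 0 else x


def _drift_gain(n_trial: int, rate: float, trial_dur: float) -> float:
    """Mean of t/T over the last half of the trial sample grid.

    This is the factor by which the drift's end magnitude maps onto the
    SCP amplitude (mean of the last half of the trial window).
    """
    k = np.arange(n_trial // 2, n_trial)
    return float(np.mean(k / rate) / trial_dur)


def simulate_epochs(design: StudyDesign | None = None,
                    truth: GroundTruth | None = None,
                    seed: int | None = None,
                    n_participants: int | None = None,
                    sessions: list[int] | None = None) -> EpochSet:
    """Raw-signal epochs for (a subset of) the experimental arm.

    Each epoch is pink background noise + a 10 Hz oscillation + a
    task-dependent linear drift over the trial window whose end magnitude
    tracks the ground-truth learning surface (negative drift for the
    negativity task).  A fraction ``truth.artifact_rate`` of epochs receives
    a large transient.  The baseline window is drift-free.  Within each
    condition block the negativity/positivity counts follow the phase task
    ratio exactly, in shuffled order.
    """
    design = design or StudyDesign()
    truth = truth or default_ground_truth(design)
    rng = _rng(seed, truth, _STAGE_EPOCHS)

    n_p = design.n_experimental if n_participants is None else n_participants
    persons = _participant_ids(n_p, "E")
    session_list = sessions or list(range(1, design.n_sessions + 1))

    nb, nt = design.baseline_samples, design.trial_samples
    rate = design.sampling_rate
    gain = _drift_gain(nt, rate, design.trial_dur)
    t_trial = np.arange(nt) / rate
    t_full = np.arange(nb + nt) / rate
    n_per_cond = design.trials_per_condition()

    # person-specific learning-curve deviations, shared convention with
    # simulate_features
    grid = pd.DataFrame(
        [
            (p, s, c, t)
            for p in persons
            for s in session_list
            for c in design.conditions
            for t in TASKS
        ],
        columns=["Person", "Session", "Condition", "Task"],
    )
    grid["Amplitude"] = 0.0
    dm = build_design(MODEL_FORMULAS["M2SCP"], grid,
                      centers={"Session": design.session_center})
    beta = np.array([truth.fixed_coefficients[c] for c in dm.columns])
    order = [SCP_VARYING_TERMS.index(c) for c in dm.z_columns]
    L = _scaled_cholesky(truth.varying_sd[order],
                         truth.varying_corr[np.ix_(order, order)])
    u = rng.standard_normal((dm.n_groups, len(order))) @ L.T
    surface = dm.X @ beta + np.einsum("ij,ij->i", dm.Z, u[dm.group_index])
    target = dict(zip(map(tuple, grid[["Person", "Session", "Condition", "Task"]].to_numpy()),
                      surface))

    baselines, trials, meta = [], [], []
    for p in persons:
        for s in session_list:
            ratio = design.task_ratio(s)
            n_neg = int(round(ratio * n_per_cond))
            for c in design.conditions:
                tasks = ["negativity"] * n_neg + ["positivity"] * (n_per_cond - n_neg)
                rng.shuffle(tasks)
                for task in tasks:
                    sig = _pink_noise(rng, nb + nt, rate, truth.pink_noise_sd)
                    if truth.alpha_osc_amplitude:
                        sig = sig + truth.alpha_osc_amplitude * np.sin(
                            2 * np.pi * 10.0 * t_full + rng.uniform(0, 2 * np.pi)
                        )
                    baseline = sig[:nb]
                    trial = sig[nb:].copy()
                    amp = target[(p, s, c, task)]
                    if gain != 0:
                        trial += (amp / gain) * (t_trial / design.trial_dur)
                    is_artifact = bool(rng.random() < truth.artifact_rate)
                    if is_artifact:
                        trial = trial + _transient(rng, nt, rate,
                                                   truth.artifact_amplitude)
                    baselines.append(baseline)
                    trials.append(trial)
                    meta.append((p, s, c, task, is_artifact))
    meta_df = pd.DataFrame(
        meta, columns=["participant", "session", "condition", "task", "is_artifact"]
    )
    return EpochSet(
        baseline=np.array(baselines), trial=np.array(trials), meta=meta_df,
        sampling_rate=rate,
    )


def _transient(rng: np.random.Generator, n: int, rate: float,
               amplitude: float) -> np.ndarray:
    """Half-sine blip of ~0.25 s at a random position in the trial window."""
    width = max(4, int(round(0.25 * rate)))
    start = int(rng.integers(0, max(1, n - width)))
    out = np.zeros(n)
    sign = -1.0 if rng.random() < 0.5 else 1.0
    out[start : start + width] = sign * amplitude * np.sin(
        np.pi * np.arange(width) / width
    )
    return out
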
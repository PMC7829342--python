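"""Wilkinson-style model formulas and design-matrix construction.

The model dialect is small: treatment-coded factors ``Group`` (reference
``control``), ``Condition`` (reference ``feedback1``), ``Task`` (reference
``negativity``); numeric predictors ``Session``/``Time`` centered at the
midpoint of their observed range before any power is taken, with
``Session2``/``Time2`` denoting the squared centered predictor; ``A*B``
expanding to ``A + B + A:B``; and one varying-effects block
``(terms | Person)``.  Term expansion itself is delegated to patsy.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy

from .study import ValidationError

#: the four model families, in the notation used throughout
MODEL_FORMULAS = {
    "M1SRS": "Score ~ Group*Time + (1 + Time | Person)",
    "M2SRS": "Score ~ Group*Time + Time2 + (1 + Time + Time2 | Person)",
    "M1SCP": "Amplitude ~ Condition*Task*Session + (1 + Session*Task | Person)",
    "M2SCP": "Amplitude ~ Condition*Task*(Session + Session2) + (1 + (Session + Session2)*Task | Person)",
    "M1PSD": "PSD ~ Condition*Task*Session + (1 + Session*Task | Person)",
    "M2PSD": "PSD ~ Condition*Task*(Session + Session2) + (1 + (Session + Session2)*Task | Person)",
}

_FACTOR_REFERENCES = {
    "Group": "control",
    "Condition": "feedback1",
    "Task": "negativity",
}

_NUMERIC_REWRITES = [
    (re.compile(r"\bSession2\b"), "Session_sq"),
    (re.compile(r"\bSession\b(?!_)"), "Session_c"),
    (re.compile(r"\bTime2\b"), "Time_sq"),
    (re.compile(r"\bTime\b(?!_)"), "Time_c"),
]

_VARYING_RE = re.compile(r"\(\s*([^|()]*(?:\([^()]*\)[^|()]*)*)\|\s*(\w+)\s*\)")


@dataclass
class ParsedFormula:
    outcome: str
    fixed: str
    varying: str | None
    group: str | None


def parse_formula(formula: str) -> ParsedFormula:
    if "~" not in formula:
        raise ValidationError(f"formula must contain '~': {formula!r}")
    lhs, rhs = formula.split("~", 1)
    outcome = lhs.strip()
    varying = group = None
    m = _VARYING_RE.search(rhs)
    if m:
        varying, group = m.group(1).strip(), m.group(2)
        rhs = (rhs[: m.start()] + rhs[m.end() :]).strip()
        rhs = re.sub(r"\+\s*$", "", rhs).strip()
        rhs = re.sub(r"^\s*\+", "", rhs).strip()
    fixed = rhs.strip() or "1"
    return ParsedFormula(outcome=outcome, fixed=fixed, varying=varying, group=group)


def _rewrite_terms(expr: str) -> str:
    for pattern, repl in _NUMERIC_REWRITES:
        expr = pattern.sub(repl, expr)
    for factor, ref in _FACTOR_REFERENCES.items():
        expr = re.sub(
            rf"\b{factor}\b(?!\[)",
            f"C({factor}, Treatment('{ref}'))",
            expr,
        )
    return expr


_NAME_CLEANUPS = [
    (re.compile(r"C\((\w+), Treatment\([^)]*\)\)\[T\.([^\]]+)\]"), r"\1[\2]"),
    (re.compile(r"\bSession_sq\b"), "Session2"),
    (re.compile(r"\bSession_c\b"), "Session"),
    (re.compile(r"\bTime_sq\b"), "Time2"),
    (re.compile(r"\bTime_c\b"), "Time"),
]


def _friendly(name: str) -> str:
    for pattern, repl in _NAME_CLEANUPS:
        name = pattern.sub(repl, name)
    return name


def prepare_frame(data: pd.DataFrame, centers: dict[str, float] | None = None):
    """Add centered and squared session/time columns.

    Returns the augmented copy and the centers used (so that new data for
    prediction is centered with the constants fixed at fit time).
    """
    df = data.copy()
    centers = dict(centers or {})
    for var in ("Session", "Time"):
        if var in df.columns:
            col = pd.to_numeric(df[var])
            center = centers.setdefault(var, (col.min() + col.max()) / 2.0)
            df[f"{var}_c"] = col - center
            df[f"{var}_sq"] = (col - center) ** 2
    return df, centers


@dataclass
class DesignMatrices:
    """Expanded fixed (X) and varying (Z) design matrices with name registry."""

    X: np.ndarray
    columns: list[str]
    Z: np.ndarray | None
    z_columns: list[str]
    group_labels: np.ndarray
    group_index: np.ndarray | None
    centers: dict[str, float]
    parsed: ParsedFormula
    fixed_design_info: object = field(repr=False, default=None)
    varying_design_info: object = field(repr=False, default=None)

    @property
    def n_groups(self) -> int:
        return len(self.group_labels)

    @property
    def n_fixed(self) -> int:
        return self.X.shape[1]

    @property
    def n_varying(self) -> int:
        return 0 if self.Z is None else self.Z.shape[1]


def _dmatrix(expr: str, df: pd.DataFrame):
    try:
        mat = patsy.dmatrix(_rewrite_terms(expr), df, return_type="matrix")
    except patsy.PatsyError as exc:
        raise ValidationError(f"cannot build design for {expr!r}: {exc}") from exc
    names = [_friendly(n) for n in mat.design_info.column_names]
    return np.asarray(mat, dtype=float), names, mat.design_info


def build_fixed_matrix(expr: str, data: pd.DataFrame, session_center: float | None = None,
                       time_center: float | None = None):
    """Standalone fixed-effects expansion (used to express ground truth)."""
    centers = {}
    if session_center is not None:
        centers["Session"] = session_center
    if time_center is not None:
        centers["Time"] = time_center
    df, _ = prepare_frame(data, centers)
    X, names, _ = _dmatrix(expr, df)
    return X, names


def build_design(formula: str, data: pd.DataFrame,
                 centers: dict[str, float] | None = None) -> DesignMatrices:
    """Expand a model formula against a data frame.

    Treatment coding with the declared reference levels; ``A*B`` expands to
    main effects plus interaction; numeric time predictors are centered
    before powers.  Raises :class:`ValidationError` with the known levels
    when a factor level is absent from the data's categories.
    """
    parsed = parse_formula(formula)
    df, centers = prepare_frame(data, centers)
    _check_levels(df)
    X, columns, finfo = _dmatrix(parsed.fixed, df)
    Z = None
    z_columns: list[str] = []
    zinfo = None
    group_index = None
    group_labels = np.array([])
    if parsed.varying is not None:
        if parsed.group not in df.columns:
            raise ValidationError(f"grouping column {parsed.group!r} missing from data")
        Z, z_columns, zinfo = _dmatrix(parsed.varying, df)
        labels, group_index = np.unique(df[parsed.group].to_numpy(), return_inverse=True)
        group_labels = labels
    return DesignMatrices(
        X=X, columns=columns, Z=Z, z_columns=z_columns,
        group_labels=group_labels, group_index=group_index,
        centers=centers, parsed=parsed,
        fixed_design_info=finfo, varying_design_info=zinfo,
    )


def _check_levels(df: pd.DataFrame) -> None:
    for factor, ref in _FACTOR_REFERENCES.items():
        if factor in df.columns:
            levels = set(map(str, pd.unique(df[factor])))
            if ref not in levels and len(levels) > 1:
                raise ValidationError(
                    f"reference level {ref!r} absent from factor {factor!r}; "
                    f"observed levels: {sorted(levels)}"
                )


def fixed_matrix_for(design: DesignMatrices, newdata: pd.DataFrame) -> np.ndarray:
    """Rebuild the fixed design matrix for new covariate rows.

    Centering constants are the ones fixed at build time.  Unseen factor
    levels raise a :class:`ValidationError` naming the known levels.
    """
    df, _ = prepare_frame(newdata, design.centers)
    _validate_new_levels(design, df)
    try:
        (mat,) = patsy.build_design_matrices([design.fixed_design_info], df)
    except patsy.PatsyError as exc:
        raise ValidationError(f"cannot expand new data: {exc}") from exc
    return np.asarray(mat, dtype=float)


def _validate_new_levels(design: DesignMatrices, df: pd.DataFrame) -> None:
    for factor in _FACTOR_REFERENCES:
        if factor not in df.columns:
            continue
        known = _known_levels(design.fixed_design_info, factor)
        if known is None:
            continue
        unseen = set(map(str, pd.unique(df[factor]))) - known
        if unseen:
            raise ValidationError(
                f"unseen level(s) {sorted(unseen)} for factor {factor!r}; "
                f"known levels: {sorted(known)}"
            )


def _known_levels(design_info, factor: str):
    if design_info is None:
        return None
    for fi in getattr(design_info, "factor_infos", {}).values():
        if factor in fi.factor.name() and fi.categories is not None:
            return set(map(str, fi.categories))
    return None
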
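"""Repeated-measures mixed-effects analysis of per-section traits.

Each trait is analysed with a linear mixed model: muscle, age group and
their interaction as fixed effects, a random intercept per mouse, fitted
by REML (statsmodels ``MixedLM``).  Group contrasts are Wald tests on
model cell means with a between-within degrees-of-freedom approximation
(mice form the subject stratum).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from patsy import build_design_matrices
from scipy import stats as sps
import statsmodels.formula.api as smf

from .core import ValidationError

ALLOWED_PAIRS: tuple[tuple[int, int], ...] = ((1, 2), (2, 3), (3, 4), (1, 3), (2, 4), (1, 4))

DEFAULT_ALPHA = 0.05


def _prepare(table: pd.DataFrame, trait: str, sqrt_transform: bool = False) -> pd.DataFrame:
    required = {"mouse_id", "age_group", "muscle", "trait", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"trait table is missing columns: {sorted(missing)}")
    data = table.loc[table["trait"] == trait].copy()
    if data.empty:
        raise ValidationError(f"no rows for trait {trait!r}")
    if not np.isfinite(data["value"]).all():
        raise ValidationError(f"non-finite values for trait {trait!r}")
    data["mouse_id"] = data["mouse_id"].astype(str)
    data["age_group"] = data["age_group"].astype(int)
    data["muscle"] = data["muscle"].astype(str)
    if sqrt_transform:
        if (data["value"] < 0).any():
            raise ValidationError("sqrt transform requires non-negative values")
        data["value"] = np.sqrt(data["value"])
    return data


@dataclass
class ModelFit:
    """A fitted repeated-measures mixed model for one trait.

    When every mouse contributes a single observation the random intercept
    is not identifiable and the model collapses to ordinary least squares;
    ``singleton_subjects`` marks that case.
    """

    trait: str
    formula: str
    result: object  # MixedLMResults or OLSResults
    muscles: tuple[str, ...]
    groups: tuple[int, ...]
    n_mice: int
    data: pd.DataFrame
    singleton_subjects: bool = False

    @property
    def fe_params(self) -> pd.Series:
        if self.singleton_subjects:
            return self.result.params
        return self.result.fe_params

    @property
    def fe_cov(self) -> np.ndarray:
        if self.singleton_subjects:
            return np.asarray(self.result.cov_params())
        k = len(self.result.fe_params)
        return np.asarray(self.result.cov_params())[:k, :k]

    @property
    def mouse_variance(self) -> float:
        if self.singleton_subjects:
            return 0.0
        return float(np.asarray(self.result.cov_re).ravel()[0])

    @property
    def residual_variance(self) -> float:
        return float(self.result.scale)

    def cell_mean_vector(self, muscle: str, age_group: int) -> np.ndarray:
        """Fixed-effects design row for the (muscle, age group) cell mean."""
        if muscle not in self.muscles:
            raise ValidationError(f"unknown muscle level {muscle!r}")
        if age_group not in self.groups:
            raise ValidationError(f"unknown age group {age_group!r}")
        design_info = self.result.model.data.design_info
        frame = pd.DataFrame({"muscle": [muscle], "age_group": [age_group]})
        (mat,) = build_design_matrices([design_info], frame)
        return np.asarray(mat)[0]


def _formula_for_levels(muscles: Sequence[str], groups: Sequence[int]) -> str:
    terms = []
    if len(muscles) > 1:
        terms.append("C(muscle)")
    if len(groups) > 1:
        terms.append("C(age_group)")
    if len(muscles) > 1 and len(groups) > 1:
        terms.append("C(muscle):C(age_group)")
    rhs = " + ".join(terms) if terms else "1"
    return f"value ~ {rhs}"


def fit_repeated_measures(
    table: pd.DataFrame,
    trait: str,
    *,
    reml: bool = True,
    nested_muscle_re: bool = False,
    sqrt_transform: bool = False,
) -> ModelFit:
    """Fit ``value ~ muscle * age_group`` with a random intercept per mouse.

    Raises a :class:`ValidationError` when a muscle-by-group cell is empty
    (the interaction design would be rank-deficient) or when any group has
    fewer than two mice.  ``nested_muscle_re`` adds a variance component
    per mouse-muscle combination to absorb section-level dependence.
    """
    data = _prepare(table, trait, sqrt_transform)
    muscles = tuple(sorted(data["muscle"].unique()))
    groups = tuple(sorted(data["age_group"].unique()))
    mice_per_group = data.groupby("age_group")["mouse_id"].nunique()
    thin = mice_per_group[mice_per_group < 2]
    if not thin.empty:
        raise ValidationError(
            f"need >= 2 mice per group; groups {sorted(thin.index)} have fewer"
        )
    if len(muscles) > 1 and len(groups) > 1:
        cells = data.groupby(["muscle", "age_group"]).size()
        for muscle in muscles:
            for group in groups:
                if (muscle, group) not in cells.index:
                    raise ValidationError(
                        f"design is rank-deficient: no observations for "
                        f"muscle={muscle!r}, age_group={group}"
                    )
    formula = _formula_for_levels(muscles, groups)
    singleton = bool(data.groupby("mouse_id").size().max() == 1)
    if singleton:
        # One observation per mouse: the random intercept is unidentifiable
        # and generalized least squares reduces to ordinary least squares.
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = smf.ols(formula, data).fit()
        return ModelFit(
            trait=trait,
            formula=formula,
            result=result,
            muscles=muscles,
            groups=groups,
            n_mice=data["mouse_id"].nunique(),
            data=data,
            singleton_subjects=True,
        )
    kwargs: dict = {"groups": data["mouse_id"], "re_formula": "1"}
    if nested_muscle_re:
        data = data.assign(mouse_muscle=data["mouse_id"] + ":" + data["muscle"])
        kwargs["vc_formula"] = {"mouse_muscle": "0 + C(mouse_muscle)"}
    model = smf.mixedlm(formula, data, **kwargs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=reml)
    return ModelFit(
        trait=trait,
        formula=formula,
        result=result,
        muscles=muscles,
        groups=groups,
        n_mice=data["mouse_id"].nunique(),
        data=data,
    )


@dataclass(frozen=True)
class ContrastResult:
    """One pairwise group comparison within a muscle."""

    muscle: str
    pair: tuple[int, int]
    estimate: float
    se: float
    statistic: float
    df: float
    p_value: float
    significant: bool
    alpha: float
    p_adjusted: Optional[float] = None


def _holm(pvalues: Sequence[float]) -> list[float]:
    m = len(pvalues)
    order = np.argsort(pvalues)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvalues[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted.tolist()


def group_contrasts(
    fit: ModelFit,
    muscle: str,
    pairs: Sequence[tuple[int, int]],
    alpha: float = DEFAULT_ALPHA,
    adjust: Optional[str] = None,
) -> list[ContrastResult]:
    """Wald contrasts of age-group cell means within one muscle.

    Degrees of freedom follow the between-within approximation: mice are
    the subject stratum, so df = (number of mice) - (number of groups).
    With ``adjust='holm'`` significance is judged on Holm-adjusted
    p-values across the requested pairs.
    """
    if adjust not in (None, "holm"):
        raise ValidationError(f"adjust must be None or 'holm', got {adjust!r}")
    if not (0 < alpha <= 1):
        raise ValidationError(f"alpha must be in (0, 1], got {alpha!r}")
    for pair in pairs:
        if tuple(pair) not in ALLOWED_PAIRS:
            raise ValidationError(f"pair {pair!r} is not one of {ALLOWED_PAIRS}")
        for g in pair:
            if g not in fit.groups:
                raise ValidationError(f"age group {g} absent from the fitted model")
    df = max(fit.n_mice - len(fit.groups), 1)
    fe = np.asarray(fit.fe_params)
    cov = fit.fe_cov
    raw: list[tuple[tuple[int, int], float, float, float, float]] = []
    for g_lo, g_hi in pairs:
        contrast = fit.cell_mean_vector(muscle, g_hi) - fit.cell_mean_vector(muscle, g_lo)
        estimate = float(contrast @ fe)
        se = float(np.sqrt(contrast @ cov @ contrast))
        stat = estimate / se if se > 0 else np.inf * np.sign(estimate)
        p = float(2 * sps.t.sf(abs(stat), df)) if np.isfinite(stat) else 0.0
        raw.append(((g_lo, g_hi), estimate, se, stat, p))
    adjusted = _holm([r[4] for r in raw]) if adjust == "holm" else [None] * len(raw)
    results = []
    for (pair, estimate, se, stat, p), p_adj in zip(raw, adjusted):
        decisive_p = p if p_adj is None else p_adj
        results.append(
            ContrastResult(
                muscle=muscle,
                pair=pair,
                estimate=estimate,
                se=se,
                statistic=stat,
                df=df,
                p_value=p,
                significant=bool(decisive_p < alpha),
                alpha=alpha,
                p_adjusted=p_adj,
            )
        )
    return results


def contrasts_to_frame(results: Sequence[ContrastResult]) -> pd.DataFrame:
    rows = [
        {
            "muscle": r.muscle,
            "group_lo": r.pair[0],
            "group_hi": r.pair[1],
            "estimate": r.estimate,
            "se": r.se,
            "statistic": r.statistic,
            "df": r.df,
            "p_value": r.p_value,
            "p_adjusted": r.p_adjusted,
            "significant": r.significant,
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def wald_f_groups(fit: ModelFit) -> tuple[float, int, float, float]:
    """Joint Wald F test that all age-group effects are zero.

    Returns ``(F, df_num, df_den, p)`` with the between-within denominator
    degrees of freedom.  With one observation per mouse and a single
    muscle this reduces to the classical one-way ANOVA F statistic.
    """
    names = list(fit.fe_params.index)
    idx = [i for i, n in enumerate(names) if "age_group" in n]
    if not idx:
        raise ValidationError("model has no age-group terms")
    L = np.zeros((len(idx), len(names)))
    for row, i in enumerate(idx):
        L[row, i] = 1.0
    fe = np.asarray(fit.fe_params)
    cov = fit.fe_cov
    delta = L @ fe
    middle = L @ cov @ L.T
    f_stat = float(delta @ np.linalg.solve(middle, delta)) / len(idx)
    df_den = max(fit.n_mice - len(fit.groups), 1)
    p = float(sps.f.sf(f_stat, len(idx), df_den))
    return f_stat, len(idx), df_den, p


@dataclass(frozen=True)
class FactorScreen:
    """Likelihood-ratio screen of one design factor."""

    factor: str
    estimable: bool
    lr_stat: Optional[float] = None
    df: Optional[int] = None
    p_value: Optional[float] = None
    retained: Optional[bool] = None
    note: str = ""


def screen_factors(
    table: pd.DataFrame, trait: str = "rf_per_mm2", alpha: float = DEFAULT_ALPHA
) -> dict[str, FactorScreen]:
    """Screen muscle, age group, the mouse random effect and section order.

    Fixed factors are compared by ML likelihood-ratio tests of nested
    models; the mouse random intercept by a boundary-corrected LRT against
    ordinary least squares (p = 0.5 * chi2(1) tail); the section factor by
    adding the within-muscle section ordinal as a fixed effect.
    """
    data = _prepare(table, trait)
    muscles = tuple(sorted(data["muscle"].unique()))
    groups = tuple(sorted(data["age_group"].unique()))
    if "section_id" in data.columns:
        data = data.sort_values("section_id")
        data["section_slot"] = data.groupby(["mouse_id", "muscle"]).cumcount()
    else:
        data["section_slot"] = 0
    full_formula = _formula_for_levels(muscles, groups)

    def ml_mixed(formula: str, frame: pd.DataFrame):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return smf.mixedlm(formula, frame, groups=frame["mouse_id"]).fit(reml=False)

    report: dict[str, FactorScreen] = {}
    full = ml_mixed(full_formula, data)

    def lrt(factor: str, reduced_formula: str, bigger, big_formula: str, frame: pd.DataFrame):
        reduced = ml_mixed(reduced_formula, frame)
        lr = 2 * (bigger.llf - reduced.llf)
        df = len(bigger.fe_params) - len(reduced.fe_params)
        lr = max(lr, 0.0)
        p = float(sps.chi2.sf(lr, df)) if df > 0 else 1.0
        report[factor] = FactorScreen(
            factor=factor, estimable=True, lr_stat=float(lr), df=df, p_value=p,
            retained=bool(p < alpha),
        )

    if len(muscles) > 1:
        lrt("muscle", _formula_for_levels(["only"], groups), full, full_formula, data)
    else:
        report["muscle"] = FactorScreen(
            factor="muscle", estimable=False, note="single muscle level in the data"
        )
    if len(groups) > 1:
        lrt("age_group", _formula_for_levels(muscles, [1]), full, full_formula, data)
    else:
        report["age_group"] = FactorScreen(
            factor="age_group", estimable=False, note="single age-group level in the data"
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ols = smf.ols(full_formula, data).fit()
    lr_mouse = max(2 * (full.llf - ols.llf), 0.0)
    p_mouse = float(0.5 * sps.chi2.sf(lr_mouse, 1))
    report["mouse"] = FactorScreen(
        factor="mouse", estimable=True, lr_stat=float(lr_mouse), df=1, p_value=p_mouse,
        retained=bool(p_mouse < alpha),
    )

    if data["section_slot"].nunique() > 1:
        section_formula = full_formula + " + C(section_slot)"
        with_section = ml_mixed(section_formula, data)
        lr_sec = max(2 * (with_section.llf - full.llf), 0.0)
        df_sec = len(with_section.fe_params) - len(full.fe_params)
        p_sec = float(sps.chi2.sf(lr_sec, df_sec))
        report["section"] = FactorScreen(
            factor="section", estimable=True, lr_stat=float(lr_sec), df=df_sec,
            p_value=p_sec, retained=bool(p_sec < alpha),
        )
    else:
        report["section"] = FactorScreen(
            factor="section", estimable=False, note="a single section per mouse-muscle"
        )
    return report
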
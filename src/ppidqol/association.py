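"""General linear models for factors associated with HRQoL scores.

The HRQoL score is square-root transformed (it is right-skewed and bounded
in [0, 1]) and modelled by ordinary least squares with Type III sums of
squares under sum-to-zero contrasts, so each term's F test is invariant to
the order in which terms are written.  Models contain only main effects and
the two-way interactions between a factor (fixed or categorical) and a
covariate — never covariate x covariate or factor x factor terms.

Categorical background factors (breed, sex, body condition) are modelled as
fixed categorical effects tested against the residual mean square; no
expected-mean-squares quasi-F denominators are constructed.  Residual
normality is checked with Shapiro-Wilk and homoscedasticity with a
Breusch-Pagan flag standing in for a visual residual-vs-fitted assessment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.diagnostic import het_breuschpagan

__all__ = [
    "ModelSpec",
    "AssociationReport",
    "MODEL_PRESETS",
    "sqrt_transform",
    "fit_glm",
    "check_normality",
]


class SingularDesignError(ValueError):
    """The model design matrix is rank deficient."""


def sqrt_transform(scores) -> np.ndarray:
    """Element-wise square root of HRQoL scores (requires values in [0, 1])."""
    x = np.asarray(scores, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("HRQoL scores must lie in [0, 1]")
    return np.sqrt(x)


@dataclass(frozen=True)
class ModelSpec:
    """Variables of one GLM: the dependent is sqrt(hrqol) throughout.

    ``fixed`` are binary factors, ``categorical`` multi-level background
    factors; both are encoded with sum-to-zero contrasts.  Interactions are
    every {factor} x {covariate} pair; the constructor refuses any other
    interaction shape by design.
    """

    name: str
    fixed: tuple[str, ...] = ()
    categorical: tuple[str, ...] = ()
    covariates: tuple[str, ...] = ()
    response: str = "hrqol"

    @property
    def factors(self) -> tuple[str, ...]:
        return self.fixed + self.categorical

    @property
    def variables(self) -> tuple[str, ...]:
        return self.factors + self.covariates + (self.response,)

    def formula(self) -> str:
        terms = [f"C({f}, Sum)" for f in self.factors]
        terms += list(self.covariates)
        terms += [
            f"C({f}, Sum):{c}" for f in self.factors for c in self.covariates
        ]
        return "sqrt_response ~ " + " + ".join(terms)


#: The two packaged model specifications.
MODEL_PRESETS: dict[str, ModelSpec] = {
    "all-horses": ModelSpec(
        name="all-horses",
        fixed=("ppid", "chronic"),
        categorical=("breed", "sex", "body_condition"),
        covariates=("age",),
    ),
    "ppid-only": ModelSpec(
        name="ppid-only",
        fixed=("treated", "chronic"),
        categorical=("breed", "sex", "body_condition"),
        covariates=("age", "years_diagnosed"),
    ),
}


@dataclass
class AssociationReport:
    """Type III ANOVA table plus residual diagnostics for one fitted model."""

    spec: ModelSpec
    table: pd.DataFrame  # index: term; columns: F, df_num, df_den, p
    n_used: int
    n_dropped: int
    shapiro_w: float
    shapiro_p: float
    breusch_pagan_p: float
    homoscedastic: bool
    residuals: np.ndarray = field(repr=False, default=None)

    def p_value(self, term: str) -> float:
        """p-value of a term by its bare variable name or full label."""
        if term in self.table.index:
            return float(self.table.loc[term, "p"])
        for label in self.table.index:
            if _bare_name(label) == term:
                return float(self.table.loc[label, "p"])
        raise KeyError(term)

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out.index = [_bare_name(t) for t in out.index]
        out.index.name = "term"
        return out


def _bare_name(label: str) -> str:
    """'C(ppid, Sum)' -> 'ppid'; 'C(ppid, Sum):age' -> 'ppid:age'."""
    parts = label.split(":")
    clean = []
    for p in parts:
        p = p.strip()
        if p.startswith("C(") and p.endswith(")"):
            p = p[2:-1].split(",")[0].strip()
        clean.append(p)
    return ":".join(clean)


def _check_rank(model) -> None:
    exog = model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        # flag columns with (near-)zero pivots in a rank-revealing QR
        _, r = np.linalg.qr(exog)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(exog.shape) * np.finfo(float).eps
        aliased = [
            name
            for name, d in zip(model.exog_names, diag)
            if d < max(tol, 1e-8 * diag.max())
        ]
        raise SingularDesignError(
            f"design matrix is rank deficient (rank {rank} of "
            f"{exog.shape[1]}); aliased term(s): {aliased or 'unresolved'}"
        )


def fit_glm(
    data: pd.DataFrame,
    spec: ModelSpec | str,
    bp_alpha: float = 0.05,
) -> AssociationReport:
    """Fit one of the HRQoL association models and return its report.

    ``spec`` may be a ModelSpec or the name of a packaged preset
    ("all-horses", "ppid-only").  Rows missing any model variable are
    dropped listwise.  Each categorical level must be observed and the
    design must be full rank after encoding.
    """
    if isinstance(spec, str):
        try:
            spec = MODEL_PRESETS[spec]
        except KeyError:
            raise KeyError(
                f"unknown model preset {spec!r}; available: {list(MODEL_PRESETS)}"
            ) from None
    missing_cols = [v for v in spec.variables if v not in data.columns]
    if missing_cols:
        raise ValueError(f"data lacks model variable(s): {missing_cols}")
    frame = data[list(spec.variables)].dropna().copy()
    n_dropped = len(data) - len(frame)
    if len(frame) < len(spec.variables) + 2:
        raise ValueError("too few complete rows to fit the model")
    frame["sqrt_response"] = sqrt_transform(frame[spec.response])
    # center covariates so each factor's Type III main effect is evaluated
    # at the covariate mean rather than at covariate 0 (which lies far
    # outside the data for variables like age)
    for cov in spec.covariates:
        frame[cov] = frame[cov] - frame[cov].mean()

    model = smf.ols(spec.formula(), data=frame)
    _check_rank(model)
    fit = model.fit()
    anova = anova_lm(fit, typ=3)

    df_den = int(fit.df_resid)
    rows = {}
    for label in anova.index:
        if label in ("Intercept", "Residual"):
            continue
        rows[label] = {
            "F": float(anova.loc[label, "F"]),
            "df_num": int(anova.loc[label, "df"]),
            "df_den": df_den,
            "p": float(anova.loc[label, "PR(>F)"]),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")

    resid = np.asarray(fit.resid)
    w, p_norm = check_normality(resid)
    _, bp_p, _, _ = het_breuschpagan(resid, fit.model.exog)
    return AssociationReport(
        spec=spec,
        table=table,
        n_used=len(frame),
        n_dropped=n_dropped,
        shapiro_w=w,
        shapiro_p=p_norm,
        breusch_pagan_p=float(bp_p),
        homoscedastic=bool(bp_p >= bp_alpha),
        residuals=resid,
    )


def check_normality(residuals) -> tuple[float, float]:
    """Shapiro-Wilk W and p for a residual vector (3 <= n <= 5000)."""
    x = np.asarray(residuals, dtype=float)
    if x.size < 3 or x.size > 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got n={x.size}")
    if np.ptp(x) == 0:
        raise ValueError("constant residuals: normality test undefined")
    res = stats.shapiro(x)
    return float(res.statistic), float(res.pvalue)
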
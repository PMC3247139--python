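"""Nested-model likelihood-ratio testing and information criteria.

With Gaussian errors and fixed per-point sigmas, twice the
log-likelihood difference between two nested fits equals the
chi-square difference, so the deviance ``chi2_simple - chi2_complex``
is referred to a chi-square distribution with ``p_C - p_S`` degrees of
freedom.  The forward-selection strategy starts from the most
parsimonious model (no feedback) and accepts a refinement only when
the test is significant: H1 vs H0, H2 vs H0, then both-feedback H3
against the surviving single-feedback model(s).

The AIC is reported on the ``chi2 + 2p`` scale; likelihood
normalization constants cancel in differences between models fitted to
the same data, which is all model selection uses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from scipy.stats import chi2 as chi2_dist

from .model import ParameterError
from .calibrate import FitResult

__all__ = [
    "ModelComparison",
    "SelectionReport",
    "lrt_pvalue",
    "aic",
    "fit_quality",
    "select_model",
]


def lrt_pvalue(chi2_complex: float, chi2_simple: float, df: int) -> float:
    """Likelihood-ratio p-value for a nested model pair.

    ``p = P(chi2(df) >= chi2_simple - chi2_complex)``.  If the complex
    model fits worse (an optimizer artifact), the deviance is treated
    as zero with a warning and p = 1.
    """
    if not isinstance(df, (int,)) or isinstance(df, bool):
        if not (isinstance(df, float) and df.is_integer()):
            raise ParameterError("degrees of freedom must be a positive integer")
        df = int(df)
    if df < 1:
        raise ParameterError("degrees of freedom must be >= 1")
    delta = chi2_simple - chi2_complex
    if delta < 0:
        warnings.warn("complex model fits worse than the simple one; "
                      "treating the deviance as zero", stacklevel=2)
        return 1.0
    return float(chi2_dist.sf(delta, df))


def aic(chi2: float, p: int) -> float:
    """Akaike information criterion on the chi-square scale:
    ``chi2 + 2p`` (absolute values carry a data-dependent constant;
    only differences between models on the same data are meaningful)."""
    if p < 1:
        raise ParameterError("parameter count must be >= 1")
    return chi2 + 2.0 * p


def fit_quality(chi2: float, n_points: int) -> float:
    """Goodness-of-fit ratio chi2 / N; values at or below 1 indicate the
    model does not differ significantly from the data at the assumed
    error level."""
    if n_points <= 0:
        raise ParameterError("N must be > 0")
    return chi2 / n_points


@dataclass
class ModelComparison:
    """One nested LRT: the simple model is rejected when p < alpha."""

    simple: str
    complex: str
    chi2_simple: float
    chi2_complex: float
    p_simple: int
    p_complex: int
    delta_chi2: float
    df: int
    p_value: float
    aic_simple: float
    aic_complex: float

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_value < alpha


@dataclass
class SelectionReport:
    """Outcome of the forward-selection procedure over H0-H3."""

    comparisons: list
    selected: str
    alpha: float
    chi2_per_n: dict = field(default_factory=dict)

    def comparison(self, simple: str, complex: str) -> ModelComparison:
        for c in self.comparisons:
            if c.simple == simple and c.complex == complex:
                return c
        raise KeyError(f"no comparison {complex} vs {simple}")

    def to_table(self) -> str:
        lines = ["test scenario      delta_chi2   df   p-value      verdict"]
        for c in self.comparisons:
            verdict = "significant" if c.significant(self.alpha) else "n.s."
            lines.append(f"{c.complex} versus {c.simple:<6}   "
                         f"{c.delta_chi2:10.3f}   {c.df:2d}   "
                         f"{c.p_value:<10.3g}   {verdict}")
        lines.append(f"selected model: {self.selected} (alpha = {self.alpha:g})")
        return "\n".join(lines)


def _compare(fit_simple: FitResult, fit_complex: FitResult,
             name_simple: str, name_complex: str) -> ModelComparison:
    if fit_simple.data_hash != fit_complex.data_hash:
        raise ParameterError(
            f"fits {name_simple} and {name_complex} are not on identical data")
    if fit_simple.n_points != fit_complex.n_points:
        raise ParameterError("nested fits must share the same N")
    df = fit_complex.n_free - fit_simple.n_free
    if df < 1:
        raise ParameterError(
            f"{name_complex} must have more free parameters than {name_simple}")
    return ModelComparison(
        simple=name_simple,
        complex=name_complex,
        chi2_simple=fit_simple.chi2,
        chi2_complex=fit_complex.chi2,
        p_simple=fit_simple.n_free,
        p_complex=fit_complex.n_free,
        delta_chi2=fit_simple.chi2 - fit_complex.chi2,
        df=df,
        p_value=lrt_pvalue(fit_complex.chi2, fit_simple.chi2, df),
        aic_simple=aic(fit_simple.chi2, fit_simple.n_free),
        aic_complex=aic(fit_complex.chi2, fit_complex.n_free),
    )


def select_model(fits: dict, alpha: float = 0.05) -> SelectionReport:
    """Forward selection over the four feedback hypotheses.

    Performs the four nested tests (H1 vs H0, H2 vs H0, H3 vs H1,
    H3 vs H2) and selects the most complex variant all of whose
    additions are significant at ``alpha``: if neither single-feedback
    refinement improves on H0 the null model stands; otherwise the
    better-fitting significant single-feedback model is the candidate,
    and H3 replaces it only if H3 improves significantly on it.
    """
    missing = {"H0", "H1", "H2", "H3"} - set(fits)
    if missing:
        raise ParameterError(f"missing fits for {sorted(missing)}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        comparisons = [
            _compare(fits["H0"], fits["H1"], "H0", "H1"),
            _compare(fits["H0"], fits["H2"], "H0", "H2"),
            _compare(fits["H1"], fits["H3"], "H1", "H3"),
            _compare(fits["H2"], fits["H3"], "H2", "H3"),
        ]
    by_pair = {(c.simple, c.complex): c for c in comparisons}

    single = [name for name in ("H1", "H2")
              if by_pair[("H0", name)].significant(alpha)]
    if not single:
        selected = "H0"
    else:
        candidate = min(single, key=lambda name: fits[name].chi2)
        if by_pair[(candidate, "H3")].significant(alpha):
            selected = "H3"
        else:
            selected = candidate
    quality = {name: fit_quality(fit.chi2, fit.n_points)
               for name, fit in fits.items()}
    return SelectionReport(comparisons, selected, alpha, quality)
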
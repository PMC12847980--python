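"""One-predictor QSPR regression: model forms, fit statistics, model comparison.

Three ordinary-least-squares model forms relate a physicochemical property P
to a topological index T:

    linear        P = alpha + beta*T
    quadratic     P = alpha + beta*T + gamma*T^2
    logarithmic   P = alpha + beta*ln(T)

:class:`DescriptorRegression` is the model object (built from raw arrays or,
via :meth:`DescriptorRegression.from_study`, from the embedded study data);
its :meth:`~DescriptorRegression.fit` returns a
:class:`DescriptorRegressionResults` carrying the coefficient estimates and
the full statistics block reported in QSPR work: R, R^2, the overall F
statistic with its p-value, and the residual standard error
sqrt(SSE/(n-k-1)).  Grid and comparison helpers reproduce the study's
property-by-index R^2 grids and its per-property best-model selection.

Estimation is delegated to :mod:`statsmodels`; the statistics are read off
the OLS results and re-derived only where conventions differ (signed R for
single-slope forms, an explicit perfect-fit sentinel F = +inf).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .indices import INDEX_IDS, round_half_away

__all__ = [
    "FORMS",
    "RankError",
    "DescriptorRegression",
    "DescriptorRegressionResults",
    "fit_model",
    "standardized_residuals",
    "r2_grid",
    "best_predictor",
    "compare_forms",
    "ComparisonReport",
]

FORMS = ("linear", "quadratic", "logarithmic")

#: Numerical tolerance below which a residual sum of squares counts as zero.
_PERFECT_FIT_RTOL = 1e-12


class RankError(ValueError):
    """The design matrix is rank-deficient (e.g. a constant predictor)."""


def _design(x: np.ndarray, form: str) -> np.ndarray:
    if form == "linear":
        cols = [x]
    elif form == "quadratic":
        cols = [x, x * x]
    elif form == "logarithmic":
        if np.any(x <= 0):
            raise ValueError("logarithmic form requires strictly positive predictor values")
        cols = [np.log(x)]
    else:
        raise ValueError(f"unknown model form {form!r}; choose from {FORMS}")
    return sm.add_constant(np.column_stack(cols), has_constant="add")


class DescriptorRegression:
    """OLS model of one property against one topological index.

    Parameters
    ----------
    endog
        Response values (the property P).
    exog
        Predictor values (the index T), one per observation.
    form
        One of ``linear``, ``quadratic``, ``logarithmic``.
    response_name, predictor_name
        Labels used in summaries and rendered equations.
    """

    def __init__(self, endog, exog, form: str = "linear",
                 response_name: str = "P", predictor_name: str = "T"):
        y = np.asarray(endog, dtype=float)
        x = np.asarray(exog, dtype=float)
        if y.ndim != 1 or x.shape != y.shape:
            raise ValueError("endog and exog must be one-dimensional and equal-length")
        k = 2 if form == "quadratic" else 1
        if len(y) < k + 2:
            raise ValueError(f"need at least {k + 2} observations for the {form} form")
        self.endog, self.exog, self.form = y, x, form
        self.response_name, self.predictor_name = response_name, predictor_name
        self.k_slopes = k

    @classmethod
    def from_study(cls, property_id: str, index_id: str, form: str = "linear",
                   index_source: str = "recomputed") -> "DescriptorRegression":
        """Build the model from the embedded nine-drug study tables.

        ``index_source='recomputed'`` computes the predictor column from the
        embedded edge partitions (full precision); ``'printed'`` uses the
        four-decimal reference table verbatim, to isolate rounding effects.
        """
        from . import data
        from .indices import compute_all

        props = data.drug_properties()
        if property_id not in props.columns:
            raise KeyError(f"unknown property {property_id!r}")
        if index_source == "recomputed":
            x = [compute_all(data.drug_partition(d))[index_id] for d in data.DRUGS]
        elif index_source == "printed":
            x = data.reference_indices()[index_id].to_list()
        else:
            raise ValueError("index_source must be 'recomputed' or 'printed'")
        return cls(props[property_id].to_numpy(), x, form,
                   response_name=property_id, predictor_name=index_id)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, response: str, predictor: str,
                       form: str = "linear") -> "DescriptorRegression":
        return cls(frame[response].to_numpy(), frame[predictor].to_numpy(), form,
                   response_name=response, predictor_name=predictor)

    def fit(self) -> "DescriptorRegressionResults":
        design = _design(self.exog, self.form)
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise RankError(
                f"rank-deficient design for {self.response_name}~{self.predictor_name} "
                f"({self.form}); is the predictor constant?"
            )
        res = sm.OLS(self.endog, design).fit()
        return DescriptorRegressionResults(self, res)


class DescriptorRegressionResults:
    """Estimates and diagnostics of a fitted one-predictor QSPR model."""

    def __init__(self, model: DescriptorRegression, sm_results):
        self.model = model
        self._sm = sm_results
        params = np.asarray(sm_results.params, dtype=float)
        self.alpha = float(params[0])
        self.beta = float(params[1])
        self.gamma = float(params[2]) if model.form == "quadratic" else None
        self.nobs = int(sm_results.nobs)
        self.df_resid = int(sm_results.df_resid)
        self.resid = np.asarray(sm_results.resid, dtype=float)
        self.fittedvalues = np.asarray(sm_results.fittedvalues, dtype=float)
        sst = float(np.sum((model.endog - model.endog.mean()) ** 2))
        sse = float(np.sum(self.resid**2))
        self.perfect_fit = sse <= _PERFECT_FIT_RTOL * max(sst, 1.0)
        if self.perfect_fit:
            self.rsquared, self.fvalue, self.f_pvalue = 1.0, math.inf, 0.0
        else:
            self.rsquared = float(sm_results.rsquared)
            self.fvalue = float(sm_results.fvalue)
            self.f_pvalue = float(sm_results.f_pvalue)
        self.resid_se = math.sqrt(sse / self.df_resid)
        # R carries the slope's sign for single-slope forms; the quadratic
        # multiple-R is the positive root of R^2.
        root = math.sqrt(max(self.rsquared, 0.0))
        self.rvalue = root if model.form == "quadratic" else math.copysign(root, self.beta)

    @property
    def params(self) -> pd.Series:
        names = ["alpha", "beta"] + (["gamma"] if self.gamma is not None else [])
        vals = [self.alpha, self.beta] + ([self.gamma] if self.gamma is not None else [])
        return pd.Series(vals, index=names)

    def standardized_resid(self) -> np.ndarray:
        """Residuals divided by the residual standard error (zeros and a
        perfect-fit flag when the fit is exact)."""
        if self.perfect_fit:
            return np.zeros_like(self.resid)
        return self.resid / self.resid_se

    def equation(self, ndigits: int = 3) -> str:
        """Render the fitted equation in the study's printed style."""
        t = self.model.predictor_name

        def fmt(v: float) -> str:
            return f"{abs(v):.{ndigits}f}"

        def signed(v: float, lead: bool = False) -> str:
            if lead:
                return ("−" if v < 0 else "") + fmt(v)
            return (" − " if v < 0 else " + ") + fmt(v)

        if self.model.form == "quadratic":
            return (f"{signed(self.gamma, lead=True)}({t})²"
                    f"{signed(self.beta)}({t}){signed(self.alpha)}")
        term = f"ln{t}" if self.model.form == "logarithmic" else t
        return f"{signed(self.beta, lead=True)}({term}){signed(self.alpha)}"

    def summary(self) -> str:
        """Plain-text summary block in the style of the study's fit tables."""
        m = self.model
        rows = [
            ("Regression equation", f"{m.response_name} = {self.equation()}"),
            ("Form", m.form),
            ("N", str(self.nobs)),
            ("alpha", f"{self.alpha:.3f}"),
            ("beta", f"{self.beta:.3f}"),
        ]
        if self.gamma is not None:
            rows.append(("gamma", f"{self.gamma:.3f}"))
        fv = "inf" if math.isinf(self.fvalue) else f"{self.fvalue:.3f}"
        rows += [
            ("F", fv),
            ("p", f"{self.f_pvalue:.3g}"),
            ("R", f"{self.rvalue:.3f}"),
            ("R^2", f"{self.rsquared:.3f}"),
            ("Resid. SE", f"{self.resid_se:.3f}"),
        ]
        width = max(len(k) for k, _ in rows)
        return "\n".join(f"{k:<{width}}  {v}" for k, v in rows)

    def as_record(self) -> dict:
        """Flat dict of the statistics (one fit-table row)."""
        return {
            "response": self.model.response_name,
            "predictor": self.model.predictor_name,
            "form": self.model.form,
            "equation": self.equation(),
            "n": self.nobs,
            "alpha": self.alpha,
            "beta": self.beta,
            "gamma": self.gamma,
            "p": self.f_pvalue,
            "F": self.fvalue,
            "R": self.rvalue,
            "R2": self.rsquared,
            "resid_se": self.resid_se,
        }


def fit_model(x, y, form: str = "linear", response_name: str = "P",
              predictor_name: str = "T") -> DescriptorRegressionResults:
    """Functional shorthand for ``DescriptorRegression(y, x, form).fit()``."""
    return DescriptorRegression(y, x, form, response_name, predictor_name).fit()


def standardized_residuals(results: DescriptorRegressionResults) -> np.ndarray:
    return results.standardized_resid()


def r2_grid(properties: pd.DataFrame, indices: pd.DataFrame,
            form: str = "linear") -> pd.DataFrame:
    """R^2 of every property~index fit: properties as rows, indices as columns.

    The two frames must share their row index (one row per molecule).
    """
    if not properties.index.equals(indices.index):
        raise ValueError("property and index tables must be aligned on the same molecules")
    out = pd.DataFrame(index=list(properties.columns),
                       columns=list(indices.columns), dtype=float)
    for prop in properties.columns:
        y = properties[prop].to_numpy(dtype=float)
        for iid in indices.columns:
            res = fit_model(indices[iid].to_numpy(dtype=float), y, form,
                            response_name=prop, predictor_name=iid)
            out.loc[prop, iid] = res.rsquared
    return out


def best_predictor(grid: pd.DataFrame, property_id: str,
                   candidates: Sequence[str] | None = None,
                   ndigits: int = 3) -> tuple[list[str], float]:
    """Argmax of R^2 over candidate indices at ``ndigits``-decimal resolution.

    Ties at the comparison resolution return every tied index id, in the
    canonical index order.
    """
    if candidates is None:
        candidates = [c for c in grid.columns]
    if not list(candidates):
        raise ValueError("empty candidate set")
    rounded = {c: round_half_away(float(grid.loc[property_id, c]), ndigits)
               for c in candidates}
    top = max(rounded.values())
    ids = [c for c in candidates if rounded[c] == top]
    ids.sort(key=lambda c: INDEX_IDS.index(c) if c in INDEX_IDS else len(INDEX_IDS))
    return ids, top


@dataclass
class ComparisonReport:
    """Per-property best predictor under each form, and the winning form(s)."""

    #: property -> form -> (best index ids, best R^2 at comparison resolution)
    best: Mapping[str, Mapping[str, tuple[list[str], float]]]
    #: property -> list of winning forms (singleton unless tied)
    winners: Mapping[str, list[str]]
    #: the underlying full R^2 grids, keyed by form
    grids: Mapping[str, pd.DataFrame] = field(repr=False, default_factory=dict)

    def winner(self, property_id: str) -> str:
        return self.winners[property_id][0]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for prop, per_form in self.best.items():
            for form, (ids, r2) in per_form.items():
                rows.append({
                    "property": prop, "form": form,
                    "best_predictor": ", ".join(ids), "R2": r2,
                    "winning_form": ", ".join(self.winners[prop]),
                })
        return pd.DataFrame(rows)


def compare_forms(grids: Mapping[str, pd.DataFrame],
                  ndigits: int = 3) -> ComparisonReport:
    """Select the best predictor per (property, form) and the winning form.

    ``grids`` maps form name to an R^2 grid as returned by :func:`r2_grid`;
    all grids must cover the same properties.  Ties between forms are
    reported as multi-element winner lists, never broken silently.
    """
    forms = list(grids)
    props = list(next(iter(grids.values())).index)
    best: dict = {}
    winners: dict = {}
    for prop in props:
        per_form = {f: best_predictor(grids[f], prop, ndigits=ndigits) for f in forms}
        best[prop] = per_form
        top = max(r2 for _, r2 in per_form.values())
        winners[prop] = [f for f in forms if per_form[f][1] == top]
    return ComparisonReport(best=best, winners=winners, grids=dict(grids))
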
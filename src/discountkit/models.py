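"""Discounting-model comparison on median indifference points.

Three candidate forms for the subjective value V of an amount A at cost X:

* hyperbolic:   V = A / (1 + bX)          (b free)
* hyperboloid:  V = A / (1 + bX**s)       (b, s free)
* power:        V = A - bX**s             (b, s free)

Each is fitted by bounded multi-start nonlinear least squares to the
per-level median IPs, normalized by A so the residual scale is
amount-invariant.  Models are ranked by the small-sample Akaike criterion

    AICc = n ln(RSS/n) + 2k + 2k(k+1)/(n - k - 1)

and compared through the differences Delta_i = AICc_i - AICc_min, with the
conventional support bands (Delta <= 2: substantial; > 10: essentially
none).  The parameter count k includes the error variance, so hyperbolic
has k = 2 and the two-parameter forms k = 3.

The :class:`DiscountingModel` / :class:`DiscountingResults` pair wraps this
in a fit-and-summarize interface; the module-level functions expose the
individual steps.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .cohort import MODEL_FORMS, subjective_value
from .titration import IndifferenceCurve

__all__ = [
    "ModelFit",
    "FitError",
    "median_curve",
    "fit_model",
    "aicc",
    "delta_aicc",
    "support_category",
    "DiscountingModel",
    "DiscountingResults",
]

# Multi-start grid and bounds for the least-squares search.
B_STARTS = np.logspace(-6, 2, 12)
S_STARTS = (0.25, 0.5, 1.0, 2.0, 4.0)
B_BOUNDS = (1e-12, 1e6)
S_BOUNDS = (0.01, 10.0)

#: free parameters + error variance
K_PARAMS = {"hyperbolic": 2, "hyperboloid": 3, "power": 3}


class FitError(RuntimeError):
    """Raised when no start of the least-squares search converges."""


@dataclass(frozen=True)
class ModelFit:
    """One fitted discounting form on one median curve."""

    model_form: str
    amount: float
    b: float
    s: float
    rss: float
    n_points: int
    k: int
    aicc: float

    def predict(self, costs) -> np.ndarray:
        """Fitted subjective values (currency units) at the given costs."""
        return np.array(
            [
                subjective_value(self.model_form, self.amount, float(c), self.b, self.s)
                for c in np.atleast_1d(costs)
            ]
        )

    def to_dict(self) -> dict:
        return {
            "model_form": self.model_form,
            "b": self.b,
            "s": self.s,
            "rss": self.rss,
            "n_points": self.n_points,
            "k": self.k,
            "aicc": self.aicc,
        }


def median_curve(curves: Iterable[IndifferenceCurve]) -> tuple[np.ndarray, np.ndarray]:
    """Per-level median IP across participants.

    All curves must share the same cost levels.  The even-count median is
    the midpoint of the central pair.  Returns (costs, median_ips).
    """
    curves = list(curves)
    if not curves:
        raise ValueError("no curves supplied")
    costs = np.asarray(curves[0].costs, dtype=float)
    for c in curves[1:]:
        if not np.allclose(np.asarray(c.costs), costs):
            raise ValueError("curves have mismatched cost levels")
    ips = np.array([c.ips for c in curves], dtype=float)
    return costs, np.median(ips, axis=0)


def aicc(rss: float, n_points: int, k: int) -> float:
    """Small-sample Akaike information criterion for a least-squares fit."""
    if n_points - k - 1 < 1:
        raise ValueError(
            f"AICc correction undefined: n - k - 1 = {n_points - k - 1} < 1"
        )
    if rss < 0:
        raise ValueError("rss must be nonnegative")
    if rss == 0:
        warnings.warn("rss = 0: AICc is -inf (perfect fit)", RuntimeWarning)
        return -math.inf
    n = n_points
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def delta_aicc(aiccs: Sequence[float]) -> list[float]:
    """Differences from the best (minimum) AICc; the best model scores 0."""
    vals = [float(a) for a in aiccs]
    if len(vals) < 2:
        raise ValueError("need at least two AICc values to compare")
    lo = min(vals)
    return [a - lo for a in vals]


def support_category(delta: float) -> str:
    """Evidential support for a model given its AICc difference."""
    if delta < 0:
        raise ValueError("delta must be nonnegative")
    if delta <= 2:
        return "substantial"
    if delta <= 7:
        return "considerably less"
    if delta <= 10:
        return "little"
    return "essentially none"


def _residual_fn(model_form: str, x: np.ndarray, y_norm: np.ndarray):
    # fit on the V/A scale with A = 1
    if model_form == "hyperbolic":
        return lambda p: 1.0 / (1.0 + p[0] * x) - y_norm
    if model_form == "hyperboloid":
        return lambda p: 1.0 / (1.0 + p[0] * x ** p[1]) - y_norm
    if model_form == "power":
        return lambda p: (1.0 - p[0] * x ** p[1]) - y_norm
    raise ValueError(f"unknown model_form {model_form!r}")


def fit_model(model_form: str, costs, ips, amount: float) -> ModelFit:
    """Least-squares fit of one discounting form to median IPs.

    IPs are divided by ``amount`` before fitting, so the reported RSS is on
    the normalized V/A scale.  The search restarts from a log grid of b
    values (crossed with a grid of s values for the two-parameter forms)
    and keeps the best converged solution; it is deterministic.
    """
    x = np.asarray(list(costs), dtype=float)
    y = np.asarray(list(ips), dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need >= 2 aligned (cost, ip) points")
    if np.any(np.diff(x) <= 0):
        raise ValueError("costs must be strictly increasing")
    if amount <= 0:
        raise ValueError("amount must be positive")
    if np.any(y < 0) or np.any(y > amount):
        raise ValueError("every IP must lie in [0, amount]")
    y_norm = y / amount
    resid = _residual_fn(model_form, x, y_norm)

    two_param = model_form in ("hyperboloid", "power")
    starts = (
        [(b0, s0) for b0 in B_STARTS for s0 in S_STARTS]
        if two_param
        else [(b0,) for b0 in B_STARTS]
    )
    lower = [B_BOUNDS[0]] + ([S_BOUNDS[0]] if two_param else [])
    upper = [B_BOUNDS[1]] + ([S_BOUNDS[1]] if two_param else [])

    best = None
    for p0 in starts:
        try:
            sol = least_squares(
                resid,
                np.asarray(p0, dtype=float),
                bounds=(lower, upper),
                method="trf",
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
                max_nfev=2000,
            )
        except Exception:
            continue
        if not sol.success:
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0] - 1e-15:
            best = (rss, sol.x)
    if best is None:
        raise FitError(f"no start converged for model {model_form!r}")
    rss, params = best
    b_hat = float(params[0])
    s_hat = float(params[1]) if two_param else 1.0
    k = K_PARAMS[model_form]
    return ModelFit(
        model_form=model_form,
        amount=float(amount),
        b=b_hat,
        s=s_hat,
        rss=rss,
        n_points=int(x.size),
        k=k,
        aicc=aicc(rss, int(x.size), k),
    )


class DiscountingModel:
    """Candidate discounting forms posed against one indifference curve.

    Parameters
    ----------
    costs, ips
        The curve to describe — typically per-level median IPs for one
        task at one time point.
    amount
        The fixed larger amount A (not estimated).
    forms
        The candidate forms to fit; defaults to all three.

    Examples
    --------
    >>> model = DiscountingModel([14, 60, 180, 365, 1095],
    ...                          [2400, 1800, 1000, 600, 250], amount=3000)
    >>> res = model.fit()
    >>> res.best_model            # doctest: +SKIP
    'hyperbolic'
    """

    def __init__(self, costs, ips, amount: float = 3000.0, forms=MODEL_FORMS):
        self.costs = np.asarray(list(costs), dtype=float)
        self.ips = np.asarray(list(ips), dtype=float)
        self.amount = float(amount)
        self.forms = tuple(forms)
        unknown = set(self.forms) - set(MODEL_FORMS)
        if unknown:
            raise ValueError(f"unknown model forms {sorted(unknown)}")

    @classmethod
    def from_curves(
        cls,
        curves: Iterable[IndifferenceCurve],
        amount: float = 3000.0,
        forms=MODEL_FORMS,
    ) -> "DiscountingModel":
        """Build from a group of curves by taking per-level median IPs."""
        costs, med = median_curve(curves)
        return cls(costs, med, amount=amount, forms=forms)

    def fit(self) -> "DiscountingResults":
        fits = {form: fit_model(form, self.costs, self.ips, self.amount) for form in self.forms}
        return DiscountingResults(self, fits)


class DiscountingResults:
    """Fitted candidate forms with their AICc ranking.

    Attributes
    ----------
    fits : dict of ModelFit
    aiccs, deltas : dict mapping form -> value
    best_model : the form with the smallest AICc (ties go to smaller k)
    support_labels : dict mapping form -> support band
    """

    def __init__(self, model: DiscountingModel, fits: dict):
        self.model = model
        self.fits = fits
        forms = list(fits)
        self.aiccs = {f: fits[f].aicc for f in forms}
        deltas = delta_aicc([self.aiccs[f] for f in forms])
        self.deltas = dict(zip(forms, deltas))
        best_delta = min(self.deltas.values())
        tied = [f for f in forms if self.deltas[f] == best_delta]
        self.best_model = min(tied, key=lambda f: fits[f].k)
        self.support_labels = {f: support_category(d) for f, d in self.deltas.items()}

    def predict(self, costs=None, form: str | None = None) -> np.ndarray:
        """Fitted values at ``costs`` (default: the data's cost levels)."""
        form = form or self.best_model
        costs = self.model.costs if costs is None else costs
        return self.fits[form].predict(costs)

    def summary(self) -> str:
        """Plain-text comparison table."""
        lines = [
            f"Discounting model comparison (A = {self.model.amount:g}, "
            f"n = {self.model.costs.size} levels)",
            f"{'model':<12} {'b':>12} {'s':>8} {'rss':>12} {'AICc':>10} "
            f"{'dAICc':>8}  support",
            "-" * 76,
        ]
        for f, fit in self.fits.items():
            tag = "*" if f == self.best_model else " "
            lines.append(
                f"{f:<12}{tag}{fit.b:>12.6g} {fit.s:>8.4g} {fit.rss:>12.5g} "
                f"{fit.aicc:>10.2f} {self.deltas[f]:>8.2f}  {self.support_labels[f]}"
            )
        lines.append("* best model (smallest AICc)")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "amount": self.model.amount,
            "best_model": self.best_model,
            "fits": {
                f: {
                    **fit.to_dict(),
                    "delta_aicc": self.deltas[f],
                    "support": self.support_labels[f],
                    "best": f == self.best_model,
                }
                for f, fit in self.fits.items()
            },
        }


def compare_models_table(
    curves_by_key: dict, amount: float = 3000.0
) -> pd.DataFrame:
    """AICc comparison rows for many (task, timepoint) groups of curves.

    ``curves_by_key`` maps (task, timepoint) -> iterable of curves.  Returns
    a long table with one row per model per group.
    """
    rows = []
    for (task, timepoint), curves in sorted(curves_by_key.items()):
        res = DiscountingModel.from_curves(curves, amount=amount).fit()
        for f, fit in res.fits.items():
            rows.append(
                {
                    "task": task,
                    "timepoint": timepoint,
                    "model_form": f,
                    "b": fit.b,
                    "s": fit.s,
                    "rss": fit.rss,
                    "aicc": fit.aicc,
                    "delta_aicc": res.deltas[f],
                    "support": res.support_labels[f],
                    "best": f == res.best_model,
                }
            )
    return pd.DataFrame(rows)
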
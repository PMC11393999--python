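"""Constrained log-logistic concentration-response modelling.

Implements the two model families used for whole-organism JC-1 screening
data:

* ``LL2`` — two-parameter log-logistic with asymptotes fixed at 0 and 1,
  fitted to quantal immobilization counts by binomial maximum likelihood.
* ``LL4`` — four-parameter log-logistic with the lower asymptote frozen at
  the dead-control floor, fitted to normalized red/green ratio means by
  least squares.

Both families share the parameterization

    f(x) = c + (d - c) / (1 + exp(b * (ln x - ln e)))

so that ``e`` is the inflection concentration and, under the relative-effect
definition used here, the EC50.  ``b`` is the (signed) slope: positive for
responses that fall with concentration (JC-1 ratio), negative for responses
that rise (immobilized fraction).

ECx values use the relative definition — the concentration producing x% of
the ``d - c`` span toward the asymptote the curve approaches at high
concentration — giving the closed form ``EC_p = e * (p/(100-p))**(1/|b|)``.
Confidence intervals default to the delta method on the original
concentration scale, which can legitimately produce negative lower bounds
for poorly determined fits.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import optimize, stats

from .io_plate import ImmobilizationRecord, PlateLayout
from .quantify import IndividualResult

logger = logging.getLogger(__name__)

__all__ = [
    "ResponsePoint",
    "LogLogisticFit",
    "ECEstimate",
    "ControlComparison",
    "ll2_response",
    "ll4_response",
    "dead_control_floor",
    "normalize_to_control",
    "aggregate_replicate_means",
    "fit_ll2",
    "fit_ll4",
    "ec_x",
    "compare_controls",
    "immobile_fraction",
]

_Z95 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class ResponsePoint:
    """One replicate-mean response at one concentration."""

    concentration: float
    response: float
    experiment_id: str
    n_individuals: int
    endpoint: Literal["jc1", "immobilization"]
    compound: str = ""
    timepoint_h: float = float("nan")


@dataclass
class LogLogisticFit:
    """A fitted (possibly constrained) log-logistic model.

    ``covariance`` is over the free parameters, in the order given by
    ``free_names`` (``("b", "e")`` for LL2, ``("b", "d", "e")`` for LL4).
    """

    family: Literal["LL2", "LL4"]
    b: float
    c: float
    d: float
    e: float
    fixed: frozenset = field(default_factory=frozenset)
    covariance: np.ndarray | None = None
    free_names: tuple = ()
    n_points: int = 0
    converged: bool = False
    message: str = ""

    def response(self, x):
        return ll4_response(x, self.b, self.c, self.d, self.e)


@dataclass(frozen=True)
class ECEstimate:
    """Effect concentration for a p% relative effect, with 95% CI."""

    p: float
    value: float
    ci_low: float
    ci_high: float
    endpoint: str = ""
    timepoint_h: float = float("nan")


@dataclass(frozen=True)
class ControlComparison:
    """Medium-control vs solvent-control comparison report."""

    shapiro_p_m7: float
    shapiro_p_solvent: float
    test: Literal["welch", "ranksum"]
    statistic: float
    pvalue: float
    alpha: float
    significant: bool


# ---------------------------------------------------------------------------
# model closed forms


def ll2_response(x, b: float, e: float):
    """Two-parameter log-logistic: 1 / (1 + exp(b (ln x - ln e))).

    At x = 0 the limiting value is used: 0 for b < 0 (rising curve),
    1 for b > 0.
    """
    if e <= 0:
        raise ValueError("inflection concentration e must be positive")
    return ll4_response(x, b, 0.0, 1.0, e)


def ll4_response(x, b: float, c: float, d: float, e: float):
    """Four-parameter log-logistic: c + (d - c)/(1 + exp(b (ln x - ln e)))."""
    if e <= 0:
        raise ValueError("inflection concentration e must be positive")
    if d < c:
        raise ValueError("upper limit d must be >= lower limit c")
    x_arr = np.asarray(x, dtype=float)
    scalar = x_arr.ndim == 0
    x_arr = np.atleast_1d(x_arr)
    out = np.empty_like(x_arr)
    pos = x_arr > 0
    with np.errstate(over="ignore"):
        z = np.exp(b * (np.log(x_arr[pos]) - math.log(e)))
    out[pos] = c + (d - c) / (1.0 + z)
    # limit as x -> 0+: exp(-inf * sign(b))
    out[~pos] = d if b > 0 else (c if b < 0 else (c + d) / 2.0)
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# normalization and aggregation


def dead_control_floor(individuals: Sequence[IndividualResult]) -> float:
    """Mean normalized ratio of QC-passing dead-control individuals.

    This is the estimator for the fixed lower asymptote of the LL4 fit.
    """
    vals = [
        ind.normalized_ratio
        for ind in individuals
        if ind.qc_pass and ind.normalized_ratio is not None
        and np.isfinite(ind.normalized_ratio)
    ]
    if not vals:
        raise ValueError(
            "no QC-passing dead-control individuals; supply the lower-limit "
            "floor explicitly (config key doseresponse.jc1_floor)"
        )
    return float(np.mean(vals))


def normalize_to_control(
    individuals: Sequence[IndividualResult], layout: PlateLayout
) -> list[IndividualResult]:
    """Divide each ratio by the medium-control mean of its experiment/timepoint.

    The control group's mean normalized ratio is exactly 1 within each
    (experiment, timepoint) block.  Raises if a block has no QC-passing
    medium control.
    """
    by_well = {entry.well_id: entry for entry in layout.entries}
    blocks: dict[tuple, list[float]] = {}
    for ind in individuals:
        entry = by_well.get(ind.well_id)
        if entry is None:
            raise KeyError(f"well {ind.well_id!r} not present in plate layout")
        if entry.role == "control" and ind.qc_pass and np.isfinite(ind.ratio):
            key = (entry.experiment_id, entry.timepoint_h)
            blocks.setdefault(key, []).append(ind.ratio)

    means = {k: float(np.mean(v)) for k, v in blocks.items()}
    out = []
    for ind in individuals:
        entry = by_well[ind.well_id]
        key = (entry.experiment_id, entry.timepoint_h)
        if key not in means:
            raise ValueError(
                f"no QC-passing medium control in experiment "
                f"{entry.experiment_id!r} at {entry.timepoint_h} h; "
                "cannot normalize"
            )
        if ind.qc_pass and np.isfinite(ind.ratio):
            out.append(replace(ind, normalized_ratio=ind.ratio / means[key]))
        else:
            out.append(replace(ind, normalized_ratio=None))
    return out


def aggregate_replicate_means(
    individuals: Sequence[IndividualResult], layout: PlateLayout
) -> list[ResponsePoint]:
    """One ResponsePoint per (experiment, concentration): mean normalized ratio.

    Cells with zero QC-passing individuals are dropped with a warning.
    Control-role wells contribute at concentration 0.
    """
    by_well = {entry.well_id: entry for entry in layout.entries}
    cells: dict[tuple, list[float]] = {}
    for ind in individuals:
        entry = by_well[ind.well_id]
        key = (
            entry.compound,
            entry.experiment_id,
            entry.concentration,
            entry.timepoint_h,
        )
        cells.setdefault(key, [])
        if ind.qc_pass and ind.normalized_ratio is not None:
            cells[key].append(ind.normalized_ratio)

    points = []
    for (compound, exp, conc, tp), vals in sorted(cells.items()):
        if not vals:
            logger.warning(
                "dropping cell (%s, %s, %g, %g h): no QC-passing individuals",
                compound, exp, conc, tp,
            )
            continue
        points.append(
            ResponsePoint(
                concentration=conc,
                response=float(np.mean(vals)),
                experiment_id=exp,
                n_individuals=len(vals),
                endpoint="jc1",
                compound=compound,
                timepoint_h=tp,
            )
        )
    return points


def immobile_fraction(rec: ImmobilizationRecord) -> float:
    """Fraction of exposed animals immobile in one record."""
    if rec.n_exposed <= 0:
        raise ValueError("n_exposed must be positive")
    return rec.n_immobile / rec.n_exposed


# ---------------------------------------------------------------------------
# fitting

def _finite_diff_hessian(f, theta, eps=1e-4):
    theta = np.asarray(theta, dtype=float)
    k = theta.size
    h = eps * np.maximum(1.0, np.abs(theta))
    hess = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            fpp = f(theta + ei + ej)
            fpm = f(theta + ei - ej)
            fmp = f(theta - ei + ej)
            fmm = f(theta - ei - ej)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return hess


def _safe_inverse(mat):
    try:
        inv = np.linalg.inv(mat)
    except np.linalg.LinAlgError:
        return None
    if not np.all(np.isfinite(inv)):
        return None
    # symmetrize against round-off
    return (inv + inv.T) / 2.0


def fit_ll2(data: Sequence[ImmobilizationRecord]) -> LogLogisticFit:
    """Fit LL2 to immobilization counts by binomial maximum likelihood.

    Free parameters (b, e); limits fixed at 0 and 1.  The covariance is the
    inverse observed information, transformed to the (b, e) scale.
    """
    recs = list(data)
    if not recs:
        raise ValueError("no immobilization records")
    x = np.array([r.concentration for r in recs], dtype=float)
    n = np.array([r.n_exposed for r in recs], dtype=float)
    k = np.array([r.n_immobile for r in recs], dtype=float)
    pos = x > 0
    if np.unique(x[pos]).size < 2:
        raise ValueError("need >=2 distinct positive concentrations")
    frac = k / n
    if np.all(frac == 0) or np.all(frac == 1):
        raise ValueError("non-identifiable: all responses at the same plateau")

    lo, hi = math.log(x[pos].min()) - 3.0, math.log(x[pos].max()) + 3.0

    def nll(theta):
        b, log_e = theta
        e = math.exp(log_e)
        p = np.clip(ll4_response(x, b, 0.0, 1.0, e), 1e-12, 1 - 1e-12)
        return -float(np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))

    # slope sign from the response direction (immobilization rises => b < 0)
    rising = np.corrcoef(np.log(x[pos]), frac[pos])[0, 1] >= 0
    b0 = -1.0 if rising else 1.0
    e0 = x[pos][np.argmin(np.abs(frac[pos] - 0.5))]
    starts = [(b0, math.log(e0))]
    starts += [(b0 * 3.0, math.log(e0)), (b0, math.log(e0) + 1.0)]

    best = None
    for s, start in enumerate(starts):
        res = optimize.minimize(
            nll, start, method="L-BFGS-B",
            bounds=[(-50, 50), (lo, hi)],
        )
        if best is None or res.fun < best.fun - 1e-10:
            best = res
        if s == 0 and res.success:
            break
    b_hat, log_e_hat = best.x
    e_hat = math.exp(log_e_hat)

    hess = _finite_diff_hessian(nll, best.x)
    cov_theta = _safe_inverse(hess)
    converged = bool(best.success) and cov_theta is not None
    message = "" if converged else f"optimizer: {best.message}"
    # quasi-separation diagnostic: if steepening the slope does not worsen
    # the profile likelihood, the MLE of b is unbounded and e is pinned to
    # a design concentration rather than estimated
    if converged:
        steeper = optimize.minimize_scalar(
            lambda le: nll((1.5 * b_hat, le)), bounds=(lo, hi),
            method="bounded",
        )
        if steeper.fun <= best.fun + 1e-6 or abs(b_hat) >= 49.0:
            converged = False
            message = "slope unbounded (quasi-separation in the counts)"
    cov = None
    if cov_theta is not None:
        jac = np.array([[1.0, 0.0], [0.0, e_hat]])  # (b, ln e) -> (b, e)
        cov = jac @ cov_theta @ jac.T
    return LogLogisticFit(
        family="LL2", b=float(b_hat), c=0.0, d=1.0, e=float(e_hat),
        fixed=frozenset({"c", "d"}), covariance=cov, free_names=("b", "e"),
        n_points=len(recs), converged=converged, message=message,
    )


def fit_ll4(points: Sequence[ResponsePoint], c_fixed: float) -> LogLogisticFit:
    """Least-squares LL4 fit with the lower limit frozen at ``c_fixed``.

    Free parameters (b, d, e); covariance is residual variance times the
    inverse Gauss-Newton curvature, transformed to the (b, d, e) scale.
    """
    pts = list(points)
    x = np.array([p.concentration for p in pts], dtype=float)
    y = np.array([p.response for p in pts], dtype=float)
    pos = x > 0
    if np.unique(x[pos]).size < 3:
        raise ValueError("need >=3 distinct positive concentrations")
    if c_fixed >= y.max():
        raise ValueError("fixed lower limit must lie below the largest response")

    lo, hi = math.log(x[pos].min()) - 3.0, math.log(x[pos].max()) + 3.0

    def resid(theta):
        b, d, log_e = theta
        d_eff = max(d, c_fixed)
        return ll4_response(x, b, c_fixed, d_eff, math.exp(log_e)) - y

    # falling response with concentration => b > 0
    falling = np.corrcoef(np.log(x[pos]), y[pos])[0, 1] <= 0
    b0 = 1.0 if falling else -1.0
    d0 = float(y.max())
    mid = (c_fixed + d0) / 2.0
    e0 = x[pos][np.argmin(np.abs(y[pos] - mid))]
    starts = [
        (b0, d0, math.log(e0)),
        (b0 * 3.0, d0, math.log(e0)),
        (b0, d0, np.clip(math.log(e0) + 1.0, lo, hi)),
    ]

    best = None
    for s, start in enumerate(starts):
        res = optimize.least_squares(
            resid, start,
            bounds=([-50, c_fixed, lo], [50, np.inf, hi]),
        )
        if best is None or res.cost < best.cost - 1e-12:
            best = res
        if s == 0 and res.success:
            break
    b_hat, d_hat, log_e_hat = best.x
    e_hat = math.exp(log_e_hat)

    dof = max(len(pts) - 3, 1)
    s2 = 2.0 * best.cost / dof
    jtj = best.jac.T @ best.jac
    cov_theta = _safe_inverse(jtj)
    converged = bool(best.success) and cov_theta is not None
    message = "" if converged else f"optimizer: {best.message}"
    # unbounded-slope diagnostic: a transition steeper than the design can
    # resolve leaves e pinned between two concentrations, not estimated
    if converged:
        steeper = optimize.least_squares(
            lambda th: resid((1.5 * b_hat, th[0], th[1])),
            (d_hat, log_e_hat),
            bounds=([c_fixed, lo], [np.inf, hi]),
        )
        if steeper.cost <= best.cost * (1 + 1e-9) + 1e-12 or abs(b_hat) >= 49.0:
            converged = False
            message = "slope unbounded (transition steeper than the design)"
    cov = None
    if cov_theta is not None:
        cov_theta = s2 * cov_theta
        jac = np.diag([1.0, 1.0, e_hat])  # (b, d, ln e) -> (b, d, e)
        cov = jac @ cov_theta @ jac.T
    return LogLogisticFit(
        family="LL4", b=float(b_hat), c=float(c_fixed), d=float(d_hat),
        e=float(e_hat), fixed=frozenset({"c"}), covariance=cov,
        free_names=("b", "d", "e"), n_points=len(pts), converged=converged,
        message=message,
    )


# ---------------------------------------------------------------------------
# effect concentrations


def _ec_value(b: float, e: float, p: float) -> float:
    return e * (p / (100.0 - p)) ** (1.0 / abs(b))


def ec_x(
    fit: LogLogisticFit,
    p: float,
    ci_method: Literal["delta_original", "delta_log", "bootstrap"] = "delta_original",
    n_boot: int = 2000,
    rng: np.random.Generator | None = None,
    endpoint: str = "",
    timepoint_h: float = float("nan"),
) -> ECEstimate:
    """Effect concentration at a p% relative effect with 95% CI.

    EC_p = e * (p/(100-p))**(1/|b|): the concentration at which the response
    has moved p% of the (d - c) span toward the high-concentration asymptote.
    EC_50 equals the inflection e exactly.  The default CI is the delta
    method on the original concentration scale.
    """
    if not (0 < p < 100):
        raise ValueError("p must be in (0, 100)")
    if fit.b == 0:
        raise ValueError("slope b = 0: effect concentration undefined")
    value = _ec_value(fit.b, fit.e, p)
    if fit.covariance is None:
        return ECEstimate(p, value, float("nan"), float("nan"),
                          endpoint, timepoint_h)

    idx = {name: i for i, name in enumerate(fit.free_names)}
    k = math.log(p / (100.0 - p))
    grad = np.zeros(len(fit.free_names))
    # d EC / d b = -EC * ln(k_ratio) * sign(b) / b^2 ; d EC / d e = EC / e
    grad[idx["b"]] = -value * k * math.copysign(1.0, fit.b) / fit.b ** 2
    grad[idx["e"]] = value / fit.e

    if ci_method == "delta_original":
        var = float(grad @ fit.covariance @ grad)
        half = _Z95 * math.sqrt(max(var, 0.0))
        return ECEstimate(p, value, value - half, value + half,
                          endpoint, timepoint_h)
    if ci_method == "delta_log":
        grad_log = grad / value
        var = float(grad_log @ fit.covariance @ grad_log)
        half = _Z95 * math.sqrt(max(var, 0.0))
        return ECEstimate(p, value, value * math.exp(-half),
                          value * math.exp(half), endpoint, timepoint_h)
    if ci_method == "bootstrap":
        rng = rng or np.random.default_rng()
        mean = np.array([getattr(fit, name) for name in fit.free_names])
        draws = rng.multivariate_normal(mean, fit.covariance, size=n_boot)
        b_d, e_d = draws[:, idx["b"]], draws[:, idx["e"]]
        ok = (e_d > 0) & (b_d != 0)
        ecs = e_d[ok] * (p / (100.0 - p)) ** (1.0 / np.abs(b_d[ok]))
        lo_b, hi_b = np.percentile(ecs, [2.5, 97.5])
        return ECEstimate(p, value, float(lo_b), float(hi_b),
                          endpoint, timepoint_h)
    raise ValueError(f"unknown ci_method {ci_method!r}")


# ---------------------------------------------------------------------------
# control comparison


def compare_controls(
    m7: Sequence[float], solvent: Sequence[float], alpha: float = 0.05
) -> ControlComparison:
    """Test the medium control against the solvent control.

    Shapiro-Wilk normality check on each group; Welch's t if both groups
    look normal at the given alpha, Wilcoxon rank-sum otherwise.
    """
    a = np.asarray(m7, dtype=float)
    b = np.asarray(solvent, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need >=3 QC-passing values in each control group")
    sw_a = stats.shapiro(a).pvalue if np.ptp(a) > 0 else 0.0
    sw_b = stats.shapiro(b).pvalue if np.ptp(b) > 0 else 0.0
    if sw_a > alpha and sw_b > alpha:
        res = stats.ttest_ind(a, b, equal_var=False)
        test = "welch"
    else:
        res = stats.ranksums(a, b)
        test = "ranksum"
    return ControlComparison(
        shapiro_p_m7=float(sw_a), shapiro_p_solvent=float(sw_b),
        test=test, statistic=float(res.statistic), pvalue=float(res.pvalue),
        alpha=alpha, significant=bool(res.pvalue < alpha),
    )
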
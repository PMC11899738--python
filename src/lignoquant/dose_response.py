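"""Four-parameter logistic dose-response fitting and germination summaries.

The model is ``y = bottom + (top - bottom) / (1 + (x/ec50)^hill)``: for a
positive Hill slope the response runs from ``top`` at zero dose down to
``bottom`` at saturating dose, with half-maximal effect at ``ec50``.  EC50
uncertainty comes from a case-resampling bootstrap, which is more honest
than the linearized covariance at the handful of dose levels typical of a
toxicity assay.  (Some sources label the same fitted midpoint IC50; this
module uses EC50 throughout.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import DomainError, NonIdentifiableError


def four_parameter_logistic(
    x: np.ndarray | float,
    bottom: float,
    top: float,
    ec50: float,
    hill: float,
) -> np.ndarray:
    """Evaluate the 4PL model; dose 0 maps to the asymptote (``top`` for
    hill > 0, ``bottom`` for hill < 0)."""
    x = np.asarray(x, dtype=float)
    ratio = np.empty_like(x)
    pos = x > 0
    with np.errstate(divide="ignore", over="ignore"):
        ratio[pos] = (x[pos] / ec50) ** hill
    ratio[~pos] = 0.0 if hill > 0 else np.inf
    with np.errstate(over="ignore"):
        out = bottom + (top - bottom) / (1.0 + ratio)
    return out


@dataclass
class DoseResponseFit:
    """Fitted 4PL parameters with bootstrap EC50 uncertainty."""

    bottom: float
    top: float
    ec50: float
    hill: float
    ec50_sd: float
    residual_sd: float
    converged: bool
    n_points: int
    n_bootstrap_used: int = 0

    def predict(self, x) -> np.ndarray:
        return four_parameter_logistic(x, self.bottom, self.top, self.ec50, self.hill)

    def to_dict(self) -> dict:
        return {
            "bottom": float(self.bottom),
            "top": float(self.top),
            "ec50": float(self.ec50),
            "hill": float(self.hill),
            "ec50_sd": float(self.ec50_sd),
            "residual_sd": float(self.residual_sd),
            "converged": bool(self.converged),
            "n_points": int(self.n_points),
            "n_bootstrap_used": int(self.n_bootstrap_used),
        }


def _fit_once(
    u: np.ndarray, y: np.ndarray, p0: np.ndarray
) -> tuple[np.ndarray, float, bool]:
    """One least-squares run on dose-scaled data.

    Parameter vector is (bottom, top, log_ec50_scaled, hill); the log keeps
    EC50 positive without explicit bounds.
    """

    def residuals(p):
        return four_parameter_logistic(u, p[0], p[1], np.exp(p[2]), p[3]) - y

    try:
        res = optimize.least_squares(residuals, p0, method="lm", max_nfev=5000)
    except Exception:
        return p0, np.inf, False
    sse = float(np.sum(res.fun**2))
    return res.x, sse, bool(res.success and np.all(np.isfinite(res.x)))


def fit_4pl(
    doses,
    responses,
    n_bootstrap: int = 1000,
    seed: int | None = None,
) -> DoseResponseFit:
    """Fit the 4PL model by multi-start nonlinear least squares.

    Doses are internally rescaled by their maximum, which makes the fitted
    EC50 exactly equivariant under a common rescaling of all doses.  Both
    Hill-slope orientations are tried from every start.  Dose-0 rows act as
    control anchors for the zero-dose asymptote.
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("doses and responses must be 1-d arrays of equal length")
    if np.any(x < 0):
        raise DomainError("doses must be nonnegative")
    if not np.all(np.isfinite(y)):
        raise DomainError("responses must be finite")
    positive = np.unique(x[x > 0])
    if positive.size < 4:
        raise NonIdentifiableError(
            f"need >= 4 distinct positive doses, got {positive.size}"
        )
    if np.ptp(y) == 0:
        raise NonIdentifiableError("flat response: 4PL parameters not identifiable")

    dmax = float(x.max())
    u = x / dmax  # exact scaling: equivariance holds to machine precision

    lo, hi = float(y.min()), float(y.max())
    log_mid_candidates = np.quantile(np.log(positive / dmax), [0.25, 0.5, 0.75])
    starts = []
    for log_mid in log_mid_candidates:
        for hill0 in (1.0, 2.0, -1.0, -2.0):
            b0, t0 = (lo, hi) if hill0 > 0 else (hi, lo)
            starts.append(np.array([b0, t0, log_mid, hill0]))

    best_p, best_sse, best_ok = starts[0], np.inf, False
    for p0 in starts:
        p, sse, ok = _fit_once(u, y, p0)
        if ok and sse < best_sse:
            best_p, best_sse, best_ok = p, sse, True
    if not best_ok:
        raise NonIdentifiableError("4PL fit failed to converge from every start")

    dof = max(x.size - 4, 1)
    residual_sd = float(np.sqrt(best_sse / dof))

    ec50_sd = float("nan")
    n_used = 0
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        boot = []
        for _ in range(n_bootstrap):
            idx = rng.integers(0, x.size, x.size)
            ub, yb = u[idx], y[idx]
            if np.unique(ub[ub > 0]).size < 4 or np.ptp(yb) == 0:
                continue
            p, _, ok = _fit_once(ub, yb, best_p)
            if ok:
                boot.append(np.exp(p[2]) * dmax)
        n_used = len(boot)
        if n_used >= 2:
            ec50_sd = float(np.std(boot, ddof=1))

    # the model is invariant under swapping the plateaus and negating the
    # slope; report the canonical orientation (hill > 0)
    b_fit, t_fit, hill_fit = float(best_p[0]), float(best_p[1]), float(best_p[3])
    if hill_fit < 0:
        b_fit, t_fit, hill_fit = t_fit, b_fit, -hill_fit

    return DoseResponseFit(
        bottom=b_fit,
        top=t_fit,
        ec50=float(np.exp(best_p[2]) * dmax),
        hill=hill_fit,
        ec50_sd=ec50_sd,
        residual_sd=residual_sd,
        converged=best_ok,
        n_points=int(x.size),
        n_bootstrap_used=n_used,
    )


@dataclass
class GerminationSummary:
    """Per-dose germination fractions with exact tests against the control."""

    table: pd.DataFrame  # dose, germinated, planted, fraction, p_value

    def fractions(self) -> dict[float, float]:
        return dict(zip(self.table["dose"], self.table["fraction"]))


def summarize_germination(counts: pd.DataFrame) -> GerminationSummary:
    """Summarize germination counts per dose.

    ``counts`` needs columns ``dose``, ``germinated``, ``planted`` and must
    include a dose-0 control row.  Each dose is compared with the control by
    a two-sided Fisher exact test on the (germinated, not germinated)
    counts.  Fractions are reported to 3 decimals.
    """
    required = {"dose", "germinated", "planted"}
    if not required.issubset(counts.columns):
        raise DomainError(f"counts table needs columns {sorted(required)}")
    df = counts.copy()
    if (df["planted"] <= 0).any():
        raise DomainError("every dose needs planted seeds > 0")
    if ((df["germinated"] < 0) | (df["germinated"] > df["planted"])).any():
        raise DomainError("germinated counts must lie in [0, planted]")
    control = df[df["dose"] == 0]
    if control.empty:
        raise DomainError("a dose-0 control row is required")
    g_c = int(control["germinated"].sum())
    p_c = int(control["planted"].sum())

    rows = []
    for row in df.itertuples(index=False):
        g, p = int(row.germinated), int(row.planted)
        table = np.array([[g, p - g], [g_c, p_c - g_c]])
        _, pval = stats.fisher_exact(table, alternative="two-sided")
        rows.append(
            {
                "dose": float(row.dose),
                "germinated": g,
                "planted": p,
                "fraction": round(g / p, 3),
                "p_value": float(pval),
            }
        )
    return GerminationSummary(pd.DataFrame(rows))
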
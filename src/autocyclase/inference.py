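"""Initial-velocity inference of the uni/bimolecular rate constants.

The measured initial velocity of product formation at starting
concentration C0 follows the two-term competition law

    v0 = k1 * C0 + k2 * C0**2

where k1 (1/h) is the unimolecular cyclisation constant and k2 (1/(M h))
the bimolecular tandem-formation constant.  Fitting is by non-negative
least squares (negative rate constants are unphysical).  The linear
fraction k1 / (k1 + k2 * C0) classifies each concentration into a
unimolecular, mixed or bimolecular regime.

Note on observables: under the network conventions of this package the
initial rate of *free-enzyme release* is exactly k_uni*C0 + k_bi*C0**2
(one sortase released per turnover, whichever channel fires), so the fit
recovers both constants.  The cyclic monomer alone forms at k_uni*[A1]
and carries no quadratic term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .network import TimeCourse


@dataclass(frozen=True)
class VelocityRecord:
    """One initial-velocity measurement."""

    c0: float                 # M
    v0: float                 # M/h
    se: float = 0.0           # standard error of v0
    replicates: tuple[float, ...] = ()   # per-replicate v0 values, if any
    window: tuple[float, float] | None = None   # time window used, h


@dataclass
class VelocityFit:
    """Fitted two-term velocity law with regime classification."""

    records: list[VelocityRecord]
    k1_hat: float             # 1/h
    k2_hat: float             # 1/(M h)
    residuals: np.ndarray
    ci_k1: tuple[float, float] | None = None
    ci_k2: tuple[float, float] | None = None
    thresholds: tuple[float, float] = (0.90, 0.10)
    diagnostics: dict = field(default_factory=dict)

    def linear_fraction(self, c0: float) -> float:
        denom = self.k1_hat + self.k2_hat * c0
        if denom == 0:
            return 1.0
        return self.k1_hat / denom

    @property
    def regimes(self) -> dict[float, str]:
        return {r.c0: classify_regime(self, r.c0) for r in self.records}

    @property
    def overall_regime(self) -> str:
        labels = set(self.regimes.values())
        return labels.pop() if len(labels) == 1 else "mixed"


def estimate_initial_velocity(tc: TimeCourse, product: str = "E",
                              max_conversion: float = 0.10,
                              min_points: int = 4) -> VelocityRecord:
    """Initial velocity of ``product`` build-up by OLS on the early window.

    Points qualify while the product amounts to at most ``max_conversion``
    of C0; the slope of the ordinary least-squares line through the
    qualifying points is v0 and its standard error comes from the
    residuals.  Requires at least ``min_points`` qualifying points.
    """
    y = tc[product]
    t = tc.times
    mask = y <= max_conversion * tc.c0
    # the window is the initial contiguous stretch of qualifying points
    if not mask[0] and not np.isclose(y[0], max_conversion * tc.c0):
        raise ValueError("first point already beyond the conversion window")
    n_ok = int(np.argmin(mask)) if not mask.all() else len(t)
    if n_ok < min_points:
        raise ValueError(
            f"only {n_ok} points below {max_conversion:.0%} conversion; "
            "sample the early time course more densely")
    tt, yy = t[:n_ok], y[:n_ok]
    A = np.column_stack([tt, np.ones_like(tt)])
    coef, *_ = np.linalg.lstsq(A, yy, rcond=None)
    resid = yy - A @ coef
    dof = max(n_ok - 2, 1)
    s2 = float(resid @ resid) / dof
    sxx = float(np.sum((tt - tt.mean()) ** 2))
    se = float(np.sqrt(s2 / sxx)) if sxx > 0 else 0.0
    return VelocityRecord(c0=tc.c0, v0=float(coef[0]), se=se,
                          window=(float(tt[0]), float(tt[-1])))


def fit_velocity_model(records: list[VelocityRecord],
                       thresholds: tuple[float, float] = (0.90, 0.10)) -> VelocityFit:
    """Non-negative least squares for (k1, k2) in v0 = k1*C0 + k2*C0**2."""
    if len(records) < 2:
        raise ValueError("need >= 2 records")
    c0 = np.array([r.c0 for r in records])
    v0 = np.array([r.v0 for r in records])
    if np.unique(c0).size < 2:
        raise ValueError("all C0 identical: (k1, k2) not identifiable")
    X = np.column_stack([c0, c0 ** 2])
    # column scaling for conditioning (C0 ~ 1e-6 M makes C0^2 ~ 1e-12)
    scale = np.linalg.norm(X, axis=0)
    scale[scale == 0] = 1.0
    coef, rnorm = nnls(X / scale, v0)
    k1, k2 = coef / scale
    resid = v0 - X @ (coef / scale)
    fit = VelocityFit(records=list(records), k1_hat=float(k1), k2_hat=float(k2),
                      residuals=resid, thresholds=thresholds)
    fit.diagnostics["rnorm"] = float(rnorm)
    fit.diagnostics["c0_range_M"] = (float(c0.min()), float(c0.max()))
    return fit


def classify_regime(fit: VelocityFit, c0: float,
                    thresholds: tuple[float, float] | None = None) -> str:
    """Label one concentration by its linear fraction k1/(k1 + k2*C0)."""
    hi, lo = thresholds if thresholds is not None else fit.thresholds
    lf = fit.linear_fraction(c0)
    if lf >= hi:
        return "unimolecular"
    if lf <= lo:
        return "bimolecular"
    return "mixed"


def bootstrap_confidence(records: list[VelocityRecord], n_boot: int = 1000,
                         seed: int = 0, level: float = 0.95) -> VelocityFit:
    """Case-resampling bootstrap over replicates within each concentration.

    Each resample draws, per concentration, ``len(replicates)`` replicate
    v0 values with replacement (falling back to the recorded v0 when no
    replicates are attached), refits, and percentile intervals at
    ``level`` are attached to the returned point fit.  Seed-reproducible.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    import warnings as _warnings
    if n_boot < 100:
        _warnings.warn("n_boot < 100 gives unstable percentile intervals")
    rng = np.random.default_rng(seed)
    fit = fit_velocity_model(records)
    draws = np.empty((n_boot, 2))
    for b in range(n_boot):
        resampled = []
        for r in records:
            if r.replicates:
                reps = rng.choice(r.replicates, size=len(r.replicates))
                resampled.append(VelocityRecord(r.c0, float(np.mean(reps))))
            else:
                resampled.append(VelocityRecord(r.c0, r.v0))
        bf = fit_velocity_model(resampled)
        draws[b] = bf.k1_hat, bf.k2_hat
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(draws, [alpha, 1.0 - alpha], axis=0)
    fit.ci_k1 = (float(lo[0]), float(hi[0]))
    fit.ci_k2 = (float(lo[1]), float(hi[1]))
    fit.diagnostics["n_boot"] = n_boot
    fit.diagnostics["seed"] = seed
    return fit
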
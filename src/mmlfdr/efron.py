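"""Efron-style unimodal local false discovery rate (single-modality baseline).

The two-group model treats the observed signed statistics z_1..z_N as a
mixture f(z) = p0 f0(z) + (1 - p0) f1(z).  The marginal density f is
estimated by Poisson regression of histogram counts on a natural cubic
spline basis of the bin midpoints (Lindsey's method); the null component
f0 is an empirical normal N(delta0, s0^2) fitted by maximum likelihood to
the central portion of the data, with the null proportion p0 derived from
the central mass.  The local fdr is

    lfdr(z) = min(1, p0 f0(z) / f(z)),

and significant cases at FDR level q are selected with the same
cumulative-mean rule used for the Bayesian multimodal procedure, so
comparisons between the two methods are decision-rule-matched.

This baseline uses one modality only; it is the SC-blind comparator for
the multimodal model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from patsy import build_design_matrices, dmatrix
from scipy import optimize, stats

from .bayes_mixture import decide

logger = logging.getLogger(__name__)


class LfdrConvergenceError(RuntimeError):
    """The density or empirical-null fit failed."""


@dataclass
class LfdrFit:
    """Fitted components of the unimodal local-fdr estimate."""

    bin_edges: np.ndarray
    counts: np.ndarray
    spline_coefs: np.ndarray
    delta0: float      # empirical null mean
    s0: float          # empirical null sd
    p0: float          # null proportion, clamped to (0, 1]
    lfdr: np.ndarray   # per-case local fdr, input order
    z: np.ndarray      # the statistics the fit was computed on
    df: int
    design_info: object = None  # patsy design info fixing the spline knots

    def density(self, z) -> np.ndarray:
        """Estimated marginal density f at points z (Lindsey normalization)."""
        z = np.asarray(z, dtype=float)
        basis = np.asarray(
            build_design_matrices([self.design_info], {"x": z, "df": self.df})[0]
        )
        # spline_coefs includes the intercept first
        X = np.column_stack([np.ones(len(z)), basis])
        log_mu = X @ self.spline_coefs
        width = self.bin_edges[1] - self.bin_edges[0]
        return np.exp(log_mu) / (self.z.size * width)


def _empirical_null(z: np.ndarray):
    """MLE of (delta0, s0, p0) from the central portion of the data.

    Fits a truncated normal to the statistics inside the 10th-90th
    percentile window and converts the window mass into the null
    proportion.  The window must extend beyond ~1 null sd on each side
    or the truncated likelihood barely identifies s0; the 80% central
    window does while staying mostly null under sparse alternatives.
    """
    a, b = np.percentile(z, [10.0, 90.0])
    if b <= a:
        raise LfdrConvergenceError("degenerate central window (constant input?)")
    inside = z[(z >= a) & (z <= b)]

    def nll(theta):
        d0, log_s0 = theta
        s0 = np.exp(log_s0)
        mass = stats.norm.cdf(b, d0, s0) - stats.norm.cdf(a, d0, s0)
        if mass <= 0:
            return 1e10
        return -np.sum(stats.norm.logpdf(inside, d0, s0)) + inside.size * np.log(mass)

    x0 = np.array([np.median(z), np.log(max(np.std(inside), 1e-3))])
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
    if not res.success:
        raise LfdrConvergenceError(f"empirical-null MLE failed: {res.message}")
    delta0, s0 = res.x[0], float(np.exp(res.x[1]))
    mass = stats.norm.cdf(b, delta0, s0) - stats.norm.cdf(a, delta0, s0)
    p0 = (inside.size / z.size) / mass
    if p0 > 1.0:
        logger.warning("null proportion estimate %.3f > 1, clamping", p0)
        p0 = 1.0
    return float(delta0), s0, float(p0)


def fit_lfdr(t, n_bins: int = 120, df: int = 7) -> LfdrFit:
    """Fit the unimodal local fdr to signed statistics.

    Parameters
    ----------
    t
        Signed statistics (two-sided modeling; both tails are alternatives).
    n_bins
        Histogram bins for the Poisson density regression (>= 20).
    df
        Degrees of freedom of the natural cubic spline (>= 4).
    """
    z = np.asarray(t, dtype=float)
    if z.ndim != 1:
        z = z.ravel()
    if not np.all(np.isfinite(z)):
        raise ValueError("statistics must be finite")
    if n_bins < 20:
        raise ValueError("n_bins must be >= 20")
    if df < 4:
        raise ValueError("df must be >= 4")
    if z.size < 200:
        logger.warning("only %d statistics; lfdr density fit may be unstable", z.size)
    if np.ptp(z) == 0:
        raise LfdrConvergenceError("constant input: histogram is degenerate")

    counts, edges = np.histogram(z, bins=n_bins)
    mids = 0.5 * (edges[:-1] + edges[1:])
    dm = dmatrix("cr(x, df=df) - 1", {"x": mids, "df": df})
    basis = np.asarray(dm)
    X = sm.add_constant(basis, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(counts, X, family=sm.families.Poisson())
        try:
            fit_res = model.fit(maxiter=200)
        except Exception as e:  # perfect separation / singular basis
            raise LfdrConvergenceError(f"Poisson density fit failed: {e}")
    if not np.all(np.isfinite(fit_res.params)):
        raise LfdrConvergenceError("Poisson density fit produced non-finite coefficients")

    delta0, s0, p0 = _empirical_null(z)

    width = edges[1] - edges[0]
    basis_z = np.asarray(
        build_design_matrices([dm.design_info], {"x": z, "df": df})[0]
    )
    Xz = np.column_stack([np.ones(z.size), basis_z])
    f_z = np.exp(Xz @ fit_res.params) / (z.size * width)
    f0_z = stats.norm.pdf(z, delta0, s0)
    lfdr = np.minimum(1.0, p0 * f0_z / np.maximum(f_z, 1e-300))

    return LfdrFit(
        bin_edges=edges,
        counts=counts,
        spline_coefs=np.asarray(fit_res.params),
        delta0=delta0,
        s0=s0,
        p0=p0,
        lfdr=lfdr,
        z=z,
        df=df,
        design_info=dm.design_info,
    )


def decide_lfdr(fit: LfdrFit, q: float):
    """Apply the cumulative-mean FDR rule to the fitted lfdr values.

    Returns ``(indices of rejected cases, k*, estimated FDR)`` exactly as
    :func:`mmlfdr.bayes_mixture.decide`.
    """
    return decide(fit.lfdr, q)
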
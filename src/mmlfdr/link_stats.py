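"""Stage 1: per-link signed group-comparison statistics t(F) and t(S).

Each brain link is compared between the disease and control groups on both
modalities.  Two estimators are offered:

``welch``
    per-link Welch two-sample t statistic.  Fast; ignores within-subject
    correlation across links.
``lmm``
    a joint linear mixed-effects model over all links and subjects,

    .. math::

        y_{ij} = \\mu_i + \\delta_i g_j + x_j'\\theta_i + b_j
                 + \\varepsilon_{ij},

    with a shared random subject effect :math:`b_j \\sim N(0, \\tau^2)`
    and heteroscedastic residuals
    :math:`\\varepsilon_{ij} \\sim N(0, \\sigma^2_{i, g(j)})` whose
    variance is specific to link-by-group.  The per-link statistic is
    :math:`t_i = \\hat\\delta_i / \\mathrm{SE}(\\hat\\delta_i)`.

Sign convention: positive means disease > control (hyperconnectivity).

The mixed model is estimated by an EM-flavoured iterated-GLS scheme:
fixed effects by per-link weighted least squares given the subject BLUPs,
then closed-form updates of the subject variance :math:`\\tau^2` and the
link-by-group residual variances.  When :math:`\\hat\\tau^2 = 0` and no
covariates are present the statistic reduces exactly to Welch's t.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity_io import validate_link_statistics, validate_link_table

logger = logging.getLogger(__name__)


class InsufficientDataError(ValueError):
    """A group or link lacks the observations the estimator needs."""


class ConvergenceError(RuntimeError):
    """The variance-component iteration failed to converge."""

    def __init__(self, msg, last_iterate=None):
        super().__init__(msg)
        self.last_iterate = last_iterate


@dataclass
class StatModelConfig:
    """Configuration for the stage-1 estimator.

    Parameters
    ----------
    method
        ``"welch"`` or ``"lmm"``.
    covariates
        Names of subject-level covariates (e.g. ``["age"]``) entering the
        mixed model as per-link fixed effects; only supported for
        ``method="lmm"``.
    min_group_size
        Minimum subjects per group (>= 2).
    max_iter, tol
        Iteration cap and relative tolerance for the variance-component
        updates of the mixed model.
    """

    method: str = "welch"
    covariates: list[str] = field(default_factory=list)
    min_group_size: int = 2
    max_iter: int = 200
    tol: float = 1e-8

    def __post_init__(self):
        if self.method not in ("welch", "lmm"):
            raise ValueError(f"method must be 'welch' or 'lmm', got {self.method!r}")
        if self.min_group_size < 2:
            raise ValueError("min_group_size must be >= 2")


def welch_t(x, y) -> float:
    """Welch's two-sample t statistic, oriented as mean(y) - mean(x).

    ``x`` is the control sample (group 0), ``y`` the disease sample
    (group 1); a positive value indicates hyperconnectivity.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InsufficientDataError("both samples need at least 2 observations")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    diff = y.mean() - x.mean()
    se2 = vx / x.size + vy / y.size
    if se2 == 0.0:
        if diff == 0.0:
            return 0.0
        raise ZeroDivisionError("zero variance in both groups with unequal means")
    return float(diff / np.sqrt(se2))


def _pivot(table: pd.DataFrame, value: str):
    """Pivot a long LinkTable to (links x subjects) with group codes.

    Returns (link index, subject index, group per subject, value matrix).
    Requires every subject observed on every link.
    """
    wide = table.pivot_table(
        index=["region1", "region2"], columns="subject", values=value, aggfunc="first"
    )
    if wide.isna().any().any():
        raise InsufficientDataError(
            "unbalanced design: every subject must be observed on every link"
        )
    groups = table.drop_duplicates("subject").set_index("subject")["group"]
    groups = groups.loc[wide.columns].to_numpy()
    return wide.index, wide.columns, groups, wide.to_numpy()


def _drop_degenerate(links, Y, groups):
    """Drop links whose values are constant within both groups."""
    var0 = Y[:, groups == 0].var(axis=1)
    var1 = Y[:, groups == 1].var(axis=1)
    keep = (var0 > 0) | (var1 > 0)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.warning("dropping %d zero-variance link(s)", n_drop)
    return links[keep], Y[keep]


def _welch_all(Y: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Vectorized Welch t over the rows of a (links x subjects) matrix."""
    Y0 = Y[:, groups == 0]
    Y1 = Y[:, groups == 1]
    m0, m1 = Y0.mean(axis=1), Y1.mean(axis=1)
    v0 = Y0.var(axis=1, ddof=1)
    v1 = Y1.var(axis=1, ddof=1)
    se2 = v0 / Y0.shape[1] + v1 / Y1.shape[1]
    return (m1 - m0) / np.sqrt(se2)


def lmm_t(
    table: pd.DataFrame,
    modality: str,
    config: StatModelConfig | None = None,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Joint mixed-model t statistics for one modality.

    Parameters
    ----------
    table
        A validated LinkTable.
    modality
        ``"FC"`` or ``"SC"`` — which value column to analyze.
    covariates
        Subject-level covariate table indexed by subject (or with a
        ``subject`` column), required when ``config.covariates`` is set.

    Returns
    -------
    DataFrame with ``region1, region2, t`` (one row per retained link).
    """
    config = config or StatModelConfig(method="lmm")
    value = {"FC": "fc_value", "SC": "sc_value"}[modality]
    links, subjects, groups, Y = _pivot(table, value)
    for g in (0, 1):
        if (groups == g).sum() < config.min_group_size:
            raise InsufficientDataError(f"group {g} below min size {config.min_group_size}")
    links_arr = links.to_frame(index=False)
    keep_links, Y = _drop_degenerate(np.arange(len(links_arr)), Y, groups)
    links_arr = links_arr.iloc[keep_links].reset_index(drop=True)

    X = _design(groups, subjects, config, covariates)  # (subjects, p); col 1 = group
    t, _ = _fit_joint_lmm(Y, groups, X, config)
    out = links_arr.copy()
    out["t"] = t
    return out


def _design(groups, subjects, config, covariates):
    """Per-subject design matrix [1, group, covariates...]."""
    cols = [np.ones_like(groups, dtype=float), groups.astype(float)]
    if config.covariates:
        if covariates is None:
            raise InsufficientDataError("covariates requested but none supplied")
        cov = covariates
        if "subject" in cov.columns:
            cov = cov.set_index("subject")
        if cov.index.has_duplicates:
            raise ValueError("each subject must appear exactly once in covariates")
        try:
            cov = cov.loc[list(subjects)]
        except KeyError as e:
            raise InsufficientDataError(f"missing covariates for subject: {e}")
        for name in config.covariates:
            c = cov[name].to_numpy(dtype=float)
            cols.append(c - c.mean())  # centered: keeps mu_i interpretable
    return np.column_stack(cols)


def _fit_joint_lmm(Y, groups, X, config):
    """EM/IGLS fit of the shared-subject-effect heteroscedastic model.

    Y : (L, S) responses; X : (S, p) subject-level design with the group
    contrast in column 1.  Returns (t statistics, info dict).
    """
    L, S = Y.shape
    g0, g1 = groups == 0, groups == 1
    n0, n1 = int(g0.sum()), int(g1.sum())

    b = np.zeros(S)
    # initialize residual variances from within-group sample variances
    sig2 = np.empty((L, 2))
    sig2[:, 0] = Y[:, g0].var(axis=1, ddof=1)
    sig2[:, 1] = Y[:, g1].var(axis=1, ddof=1)
    sig2 = np.clip(sig2, 1e-12, None)
    # moment initialization of tau^2: variance of subject means of the
    # cell-mean residuals, less the averaging noise they carry
    cell = np.empty_like(Y)
    cell[:, g0] = Y[:, g0].mean(axis=1, keepdims=True)
    cell[:, g1] = Y[:, g1].mean(axis=1, keepdims=True)
    mbar = (Y - cell).mean(axis=0)
    tau2 = max(float(mbar.var(ddof=1) - sig2.mean() / L), 0.0)
    prev = np.concatenate([[tau2], sig2.ravel()])

    for it in range(config.max_iter):
        # --- fixed effects: per-link WLS of (y - b) on X with weights 1/sig2
        W = 1.0 / sig2[:, groups.astype(int)]  # (L, S)
        Z = Y - b[None, :]
        # normal equations per link: (X' W_l X) beta_l = X' W_l z_l
        p = X.shape[1]
        XtWX = np.einsum("sp,ls,sq->lpq", X, W, X)
        XtWz = np.einsum("sp,ls,ls->lp", X, W, Z)
        try:
            beta = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]  # (L, p)
        except np.linalg.LinAlgError:
            raise ConvergenceError("singular design in WLS step", last_iterate=prev)
        fitted = beta @ X.T  # (L, S)
        R = Y - fitted  # residuals including b

        # --- subject effects: BLUP given variances
        prec = W.sum(axis=0)  # (S,) sum_i 1/sig2_{i,g(j)}
        u = (W * R).sum(axis=0)  # precision-weighted subject residual sums
        if tau2 > 0:
            post_var = 1.0 / (1.0 / tau2 + prec)  # (S,)
            b = post_var * u
        else:
            post_var = np.zeros(S)
            b = np.zeros(S)

        # --- variance updates.  tau^2 solves its score equation directly:
        # marginally u_j ~ N(0, prec_j + tau^2 prec_j^2), and with the
        # near-equal subject precisions of a balanced design the
        # method-of-moments value sum(u^2 - prec) / sum(prec^2) is the
        # MLE (EM would crawl at O(1/k) near the tau^2 = 0 boundary).  A
        # value below its own null sampling noise (1 sd under tau^2 = 0,
        # 2 sd to leave the boundary — hysteresis against flip-flopping)
        # is indistinguishable from zero and pinned there.
        sum_p2 = float(np.sum(prec * prec))
        mom = float(np.sum(u * u - prec)) / sum_p2
        noise = np.sqrt(2.0 / sum_p2)
        thresh = noise if tau2 > 0 else 2.0 * noise
        tau2_new = mom if mom > thresh else 0.0
        E = R - b[None, :]
        # REML-style df correction: the saturated mean uses 1 df per
        # link-by-group cell, so divide by (n_g - 1)
        e2 = E**2 + post_var[None, :]
        s0 = e2[:, g0].sum(axis=1) / (n0 - 1)
        s1 = e2[:, g1].sum(axis=1) / (n1 - 1)
        sig2_new = np.clip(np.column_stack([s0, s1]), 1e-12, None)
        cur = np.concatenate([[tau2_new], sig2_new.ravel()])
        delta = np.max(np.abs(cur - prev) / (np.abs(prev) + 1e-12))
        tau2, sig2, prev = tau2_new, sig2_new, cur
        if delta < config.tol:
            break
    else:
        raise ConvergenceError(
            f"variance components did not converge in {config.max_iter} iterations",
            last_iterate=prev,
        )

    # --- final GLS fixed effects and SE of the group contrast.
    # Conditional on the BLUPs, delta_hat has the per-link WLS form.  The
    # subject effect is confounded with the subject-level regressors (its
    # projection onto the design cannot be absorbed by the BLUPs), so the
    # coefficient covariance gains tau^2 * A (X'W^2 X) A with A = (X'WX)^-1
    # -- for the balanced two-group case this is the familiar
    # tau^2 * (1/n0 + 1/n1) on the group contrast.
    W = 1.0 / sig2[:, groups.astype(int)]
    Z = Y - b[None, :]
    XtWX = np.einsum("sp,ls,sq->lpq", X, W, X)
    XtWz = np.einsum("sp,ls,ls->lp", X, W, Z)
    beta = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
    cov = np.linalg.inv(XtWX)  # (L, p, p)
    var_delta = cov[:, 1, 1]
    if tau2 > 0:
        XtW2X = np.einsum("sp,ls,sq->lpq", X, W * W, X)
        extra = cov @ XtW2X @ cov
        var_delta = var_delta + tau2 * extra[:, 1, 1]
    t = beta[:, 1] / np.sqrt(var_delta)
    info = {"tau2": tau2, "n_iter": it + 1, "sigma2": sig2}
    return t, info


def compute_link_statistics(
    table: pd.DataFrame,
    config: StatModelConfig | None = None,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Run the configured estimator on FC and SC separately.

    Returns a LinkStatistics DataFrame (``region1, region2, tF, tS``) over
    the links retained by both modalities.
    """
    config = config or StatModelConfig()
    table = validate_link_table(table)

    if config.method == "welch":
        if config.covariates:
            raise ValueError("covariate adjustment requires method='lmm'")
        parts = {}
        for modality, value in (("tF", "fc_value"), ("tS", "sc_value")):
            links, _, groups, Y = _pivot(table, value)
            for g in (0, 1):
                if (groups == g).sum() < config.min_group_size:
                    raise InsufficientDataError(
                        f"group {g} below min size {config.min_group_size}"
                    )
            df = links.to_frame(index=False)
            keep, Y = _drop_degenerate(np.arange(len(df)), Y, groups)
            df = df.iloc[keep].reset_index(drop=True)
            df[modality] = _welch_all(Y, groups)
            parts[modality] = df
    else:
        parts = {}
        for modality, tag in (("FC", "tF"), ("SC", "tS")):
            df = lmm_t(table, modality, config, covariates)
            parts[tag] = df.rename(columns={"t": tag})

    merged = parts["tF"].merge(parts["tS"], on=["region1", "region2"], how="inner")
    return validate_link_statistics(merged)
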
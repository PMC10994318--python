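"""Synthetic multimodal connectivity data with known ground truth.

Two generators are provided, matching the two stages of the pipeline:

:func:`simulate_statistics`
    model-faithful statistic-level data: per-link SC magnitudes s, latent
    indicators w | s ~ Bernoulli(pi(s)) from the logistic weight model,
    and |t(F)| drawn from the half-normal null or the SC-modulated gamma
    alternative.  This is exactly the generative model the mixture
    sampler assumes, so it supports parameter-recovery and FDR-control
    checks.

:func:`simulate_subjects`
    subject-level data for the full pipeline: per-subject Fisher-z FC
    values, normal around a link mean with a group shift on a disrupted
    subset, and Poisson fiber counts (cube-root transformed) whose mean
    is elevated on an SC-disrupted subset partially coupled to the
    FC-disrupted one.  The coupling makes |t(S)| informative about FC
    non-nullness — the situation the multimodal method exploits.

Defaults mirror the geometry of a two-group late-life depression imaging
study: 87 regions (3741 links), 21 subjects per group, and roughly 21
disrupted links (~0.56% of links).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayes_mixture import MixtureParams, alpha_link, pi_link
from .connectivity_io import validate_link_statistics, validate_link_table

__all__ = [
    "StatSimConfig",
    "SubjectSimConfig",
    "simulate_statistics",
    "simulate_subjects",
    "evaluate_decisions",
]


@dataclass
class StatSimConfig:
    """Configuration of the statistic-level generator.

    ``sc_alt_frac`` of the links draw their SC magnitude s from
    ``sc_alt_dist`` (elevated), the rest from ``sc_null_dist``; the FC
    indicator then follows the logistic weight w | s ~ Bern(pi(s)), so
    the joint law of (s, w, |tF|) is exactly the mixture model's.

    Default true parameters give ~4-5% non-null links with clearly
    separated alternatives (mean |tF| around exp(gamma0 + gamma1 s)/beta).
    """

    n_links: int = 3741
    params: MixtureParams = field(
        default_factory=lambda: MixtureParams(
            sigma2=1.0, beta=1.0, gamma0=1.0, gamma1=0.2, eta0=-4.0, eta1=0.6
        )
    )
    sc_alt_frac: float = 0.1
    sc_null_dist: str = "halfnormal"   # |N(0,1)|
    sc_alt_dist: str = "gamma"         # Gamma(shape 4, rate 1)
    seed: int = 0

    def __post_init__(self):
        if self.n_links < 1:
            raise ValueError("n_links must be >= 1")
        if not 0.0 <= self.sc_alt_frac <= 1.0:
            raise ValueError("sc_alt_frac must be in [0, 1]")


@dataclass
class SubjectSimConfig:
    """Configuration of the subject-level generator.

    fc_effect is the disease-group mean shift (Fisher-z units) on
    FC-disrupted links; sc_lambda_* are Poisson means of raw fiber
    counts; ``coupling`` is the probability that an FC-disrupted link is
    also SC-disrupted (non-disrupted links are SC-disrupted at the base
    rate ``prop_disrupted`` independently).
    """

    n_regions: int = 87
    n_per_group: int = 21
    fc_effect: float = 0.25
    fc_sd: float = 0.2
    fc_mean: float = 0.3
    sc_lambda_null: float = 40.0
    sc_lambda_alt: float = 48.0
    prop_disrupted: float = 21 / 3741
    coupling: float = 0.9
    seed: int = 0

    def __post_init__(self):
        if self.n_regions < 2:
            raise ValueError("n_regions must be >= 2")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if not (0 <= self.prop_disrupted <= 1 and 0 <= self.coupling <= 1):
            raise ValueError("probabilities must be in [0, 1]")
        if self.sc_lambda_null <= 0 or self.sc_lambda_alt <= 0:
            raise ValueError("Poisson means must be > 0")
        if self.fc_sd <= 0:
            raise ValueError("fc_sd must be > 0")


def _draw_s(rng, n, dist):
    if dist == "halfnormal":
        return np.abs(rng.standard_normal(n))
    if dist == "gamma":
        return rng.gamma(4.0, 1.0, size=n)
    raise ValueError(f"unknown SC magnitude distribution {dist!r}")


def _link_labels(n_links):
    """Synthetic region labels L0001|L0002 ... covering n_links pairs."""
    # smallest atlas with at least n_links pairs
    n_regions = int(np.ceil((1 + np.sqrt(1 + 8 * n_links)) / 2))
    labels = [f"R{k:04d}" for k in range(n_regions)]
    iu, ju = np.triu_indices(n_regions, k=1)
    r1 = np.array(labels, dtype=object)[iu][:n_links]
    r2 = np.array(labels, dtype=object)[ju][:n_links]
    return r1, r2


def simulate_statistics(config: StatSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a LinkStatistics table straight from the mixture model.

    Returns ``(stats, truth)``: a validated LinkStatistics DataFrame and
    a GroundTruth DataFrame aligned on (region1, region2) with columns
    ``is_fc_disrupted`` (the latent w), ``is_sc_elevated`` (which s
    component), ``alpha`` (per-link true gamma shape, NaN for nulls).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_links
    p = config.params

    sc_alt = rng.random(n) < config.sc_alt_frac
    s = np.empty(n)
    s[~sc_alt] = _draw_s(rng, int((~sc_alt).sum()), config.sc_null_dist)
    s[sc_alt] = _draw_s(rng, int(sc_alt.sum()), config.sc_alt_dist)

    pi = pi_link(s, p.eta0, p.eta1)
    w = rng.random(n) < pi

    t_abs = np.empty(n)
    n_null = int((~w).sum())
    t_abs[~w] = np.abs(rng.normal(0.0, np.sqrt(p.sigma2), size=n_null))
    alpha = np.full(n, np.nan)
    if w.any():
        a = alpha_link(s[w], p.gamma0, p.gamma1)
        alpha[w] = a
        t_abs[w] = rng.gamma(a, 1.0 / p.beta)

    sign_f = rng.choice([-1.0, 1.0], size=n)
    sign_s = rng.choice([-1.0, 1.0], size=n)

    r1, r2 = _link_labels(n)
    stats = pd.DataFrame(
        {"region1": r1, "region2": r2, "tF": sign_f * t_abs, "tS": sign_s * s}
    )
    truth = pd.DataFrame(
        {
            "region1": r1,
            "region2": r2,
            "is_fc_disrupted": w,
            "is_sc_elevated": sc_alt,
            "alpha": alpha,
        }
    )
    stats = validate_link_statistics(stats)
    truth = truth.sort_values(["region1", "region2"], kind="stable").reset_index(drop=True)
    return stats, truth


def simulate_subjects(config: SubjectSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a subject-level LinkTable with partially coupled FC/SC disruption.

    Returns ``(table, truth)``: a validated LinkTable over all region
    pairs and a GroundTruth DataFrame with ``is_fc_disrupted``,
    ``is_sc_disrupted``, ``fc_effect``, ``sc_lambda`` per link.
    """
    rng = np.random.default_rng(config.seed)
    n_reg = config.n_regions
    labels = [f"R{k:04d}" for k in range(n_reg)]
    iu, ju = np.triu_indices(n_reg, k=1)
    L = iu.size
    npg = config.n_per_group
    n_sub = 2 * npg
    groups = np.repeat([0, 1], npg)
    subjects = [f"S{j:03d}" for j in range(n_sub)]

    fc_disrupted = rng.random(L) < config.prop_disrupted
    sc_disrupted = np.where(
        fc_disrupted,
        rng.random(L) < config.coupling,
        rng.random(L) < config.prop_disrupted,
    )

    # FC: normal per (link, subject) with a group shift on disrupted links
    mu = np.full((L, n_sub), config.fc_mean)
    mu[np.ix_(fc_disrupted, groups == 1)] += config.fc_effect
    fc = rng.normal(mu, config.fc_sd)

    # SC: Poisson counts, elevated mean for disease on SC-disrupted links
    lam = np.full((L, n_sub), config.sc_lambda_null)
    lam[np.ix_(sc_disrupted, groups == 1)] = config.sc_lambda_alt
    sc = np.cbrt(rng.poisson(lam).astype(float))

    r1 = np.array(labels, dtype=object)[iu]
    r2 = np.array(labels, dtype=object)[ju]
    table = pd.DataFrame(
        {
            "region1": np.repeat(r1, n_sub),
            "region2": np.repeat(r2, n_sub),
            "subject": np.tile(subjects, L),
            "group": np.tile(groups, L),
            "fc_value": fc.ravel(),
            "sc_value": sc.ravel(),
        }
    )
    truth = pd.DataFrame(
        {
            "region1": r1,
            "region2": r2,
            "is_fc_disrupted": fc_disrupted,
            "is_sc_disrupted": sc_disrupted,
            "fc_effect": np.where(fc_disrupted, config.fc_effect, 0.0),
            "sc_lambda": np.where(sc_disrupted, config.sc_lambda_alt, config.sc_lambda_null),
        }
    )
    table = validate_link_table(table)
    truth = truth.sort_values(["region1", "region2"], kind="stable").reset_index(drop=True)
    return table, truth


def evaluate_decisions(rejected, truth: pd.DataFrame) -> dict:
    """Score a decision set against ground truth.

    Parameters
    ----------
    rejected
        Boolean array (aligned with ``truth`` rows) or an index array of
        rejected links.
    truth
        GroundTruth DataFrame with ``is_fc_disrupted``.

    Returns
    -------
    dict with ``fdp`` (false discovery proportion), ``sensitivity``,
    ``specificity``, ``n_rejected``, ``n_disrupted``.
    """
    is_alt = truth["is_fc_disrupted"].to_numpy(dtype=bool)
    n = is_alt.size
    rejected = np.asarray(rejected)
    if rejected.dtype == bool:
        if rejected.size != n:
            raise ValueError("boolean rejection mask length mismatch")
        rej = rejected
    else:
        rej = np.zeros(n, dtype=bool)
        if rejected.size and (rejected.max() >= n or rejected.min() < 0):
            raise ValueError("rejection index out of range")
        rej[rejected] = True

    n_rej = int(rej.sum())
    false_rej = int((rej & ~is_alt).sum())
    true_rej = int((rej & is_alt).sum())
    n_alt = int(is_alt.sum())
    n_null = n - n_alt
    return {
        "fdp": false_rej / max(1, n_rej),
        "sensitivity": true_rej / max(1, n_alt),
        "specificity": (n_null - false_rej) / max(1, n_null),
        "n_rejected": n_rej,
        "n_disrupted": n_alt,
    }
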
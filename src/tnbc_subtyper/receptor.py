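"""Bimodal receptor-status calling via two-component Gaussian mixtures.

Microarray expression of ER, PR and HER2 is bimodal across breast tumors:
an unexpressed low mode and an expressed high mode.  Each receptor probe's
pooled distribution is fitted with a two-component Gaussian mixture by EM
(maximum likelihood), every sample gets a posterior probability of
belonging to the high (expressed) component, and a sample is called
negative for the marker when that posterior falls below a cutoff (default
0.5).  Triple-negative = negative on all three markers.  A second pass
optionally demotes candidates whose raw expression is not markedly below
that of positive-control samples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .expression_io import ExpressionMatrix, ProbeMarkerMap

logger = logging.getLogger(__name__)

VARIANCE_FLOOR = 1e-4
_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class MixtureFit:
    """Parameters of a fitted two-component 1-D Gaussian mixture.

    Components are sorted so ``mu_low <= mu_high``; weights sum to one.
    """

    mu_low: float
    sd_low: float
    weight_low: float
    mu_high: float
    sd_high: float
    weight_high: float
    log_likelihood: float
    converged: bool
    n_iter: int


@dataclass
class ReceptorCalls:
    """Per-sample posteriors, negative calls and TNBC flags for all markers.

    ``posterior_high[m][s]`` is sample ``s``'s posterior probability of the
    expressed component of marker ``m``.  ``demoted`` is set by the
    positive-control confirmation pass; ``tnbc_final`` excludes demoted
    candidates without deleting them.
    """

    posterior_high: pd.DataFrame
    negative: pd.DataFrame
    tnbc: pd.Series
    fits: dict[str, MixtureFit]
    demoted: pd.Series

    @property
    def tnbc_final(self) -> pd.Series:
        return self.tnbc & ~self.demoted


# ---------------------------------------------------------------------------
# EM fit
# ---------------------------------------------------------------------------

def _kmeans2_1d(values: np.ndarray, n_iter: int = 50) -> np.ndarray:
    """Plain Lloyd k-means with k=2 on a 1-D sample; returns the two centers."""
    centers = np.percentile(values, [25.0, 75.0]).astype(float)
    for _ in range(n_iter):
        mid = centers.mean()
        lo = values <= mid
        if not lo.any() or lo.all():
            break
        new = np.array([values[lo].mean(), values[~lo].mean()])
        if np.allclose(new, centers):
            break
        centers = new
    return np.sort(centers)


def _em_once(
    values: np.ndarray,
    centers: np.ndarray,
    max_iter: int,
    tol: float,
    var_floor: float,
) -> MixtureFit:
    n = values.size
    mu = centers.astype(float).copy()
    mid = mu.mean()
    lo = values <= mid
    w = np.array([max(lo.mean(), 1e-3), max((~lo).mean(), 1e-3)])
    w /= w.sum()
    overall_var = max(values.var(), var_floor)
    var = np.array([
        max(values[lo].var() if lo.any() else overall_var, var_floor),
        max(values[~lo].var() if (~lo).any() else overall_var, var_floor),
    ])

    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E step on log densities for numerical stability
        log_comp = (
            np.log(w)[:, None]
            - 0.5 * (_LOG_2PI + np.log(var))[:, None]
            - 0.5 * (values[None, :] - mu[:, None]) ** 2 / var[:, None]
        )
        m = log_comp.max(axis=0)
        lse = m + np.log(np.exp(log_comp - m).sum(axis=0))
        ll = float(lse.sum())
        resp = np.exp(log_comp - lse)

        if ll_prev > -np.inf and abs(ll - ll_prev) <= tol * abs(ll_prev):
            converged = True
            ll_prev = ll
            break
        ll_prev = ll

        nk = np.maximum(resp.sum(axis=1), 1e-12)
        w = nk / n
        mu = (resp * values).sum(axis=1) / nk
        var = np.maximum(
            (resp * (values[None, :] - mu[:, None]) ** 2).sum(axis=1) / nk,
            var_floor,
        )

    order = np.argsort(mu)
    mu, var, w = mu[order], var[order], w[order]
    return MixtureFit(
        mu_low=float(mu[0]), sd_low=float(np.sqrt(var[0])), weight_low=float(w[0]),
        mu_high=float(mu[1]), sd_high=float(np.sqrt(var[1])), weight_high=float(w[1]),
        log_likelihood=ll_prev, converged=converged, n_iter=it,
    )


def fit_two_component_gmm(
    values: Iterable[float],
    max_iter: int = 500,
    tol: float = 1e-8,
    n_starts: int = 5,
    seed: int | None = None,
    var_floor: float = VARIANCE_FLOOR,
) -> MixtureFit:
    """Fit a two-component Gaussian mixture to 1-D values by EM.

    Initialization is 1-D k-means(2); ``n_starts − 1`` additional restarts
    jitter the initial centers, and the restart with the best log
    likelihood wins.  Convergence is a relative log-likelihood change below
    ``tol``; component variances are floored at ``var_floor`` so point
    masses cannot collapse the likelihood.  Components are returned sorted
    by mean.
    """
    x = np.asarray(list(values) if not isinstance(values, np.ndarray) else values, dtype=float).ravel()
    if x.size < 10:
        raise ValueError(f"need at least 10 values to fit a mixture, got {x.size}")
    if not np.isfinite(x).all():
        raise ValueError("mixture fit requires finite values")
    if x.var() == 0:
        raise ValueError("zero-variance input: no mixture structure to fit")

    rng = np.random.default_rng(seed)
    base = _kmeans2_1d(x)
    jitter_scale = x.std() / 2.0
    best: MixtureFit | None = None
    for start in range(max(1, n_starts)):
        centers = base if start == 0 else np.sort(base + rng.normal(0.0, jitter_scale, 2))
        fit = _em_once(x, centers, max_iter=max_iter, tol=tol, var_floor=var_floor)
        if best is None or fit.log_likelihood > best.log_likelihood:
            best = fit
    assert best is not None
    if not best.converged:
        logger.warning("EM did not reach tol=%g within %d iterations", tol, max_iter)
    return best


def posterior_high(value, fit: MixtureFit):
    """Posterior probability of the high (expressed) component.

    Vectorized over ``value``; computed from log densities so extreme
    values stay in [0, 1].
    """
    v = np.asarray(value, dtype=float)
    log_low = (
        math.log(fit.weight_low)
        - math.log(fit.sd_low) - 0.5 * _LOG_2PI
        - 0.5 * ((v - fit.mu_low) / fit.sd_low) ** 2
    )
    log_high = (
        math.log(fit.weight_high)
        - math.log(fit.sd_high) - 0.5 * _LOG_2PI
        - 0.5 * ((v - fit.mu_high) / fit.sd_high) ** 2
    )
    with np.errstate(over="ignore"):  # exp -> inf collapses to posterior 0
        out = 1.0 / (1.0 + np.exp(log_low - log_high))
    return float(out) if np.isscalar(value) else out


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------

def call_receptor_status(
    matrix: ExpressionMatrix,
    marker_map: ProbeMarkerMap | None = None,
    cutoff: float = 0.5,
    negative_rule: Literal["high", "low"] = "high",
    seed: int | None = None,
    **fit_kwargs,
) -> ReceptorCalls:
    """Fit the mixture per receptor probe and call per-sample status.

    Under the default rule a sample is negative for a marker iff its
    posterior probability of the HIGH (expressed) component is below
    ``cutoff`` — i.e. the sample more plausibly sits in the unexpressed
    mode, which is what removing receptor-positive tumors requires.  The
    alternative rule ``"low"`` (negative iff the posterior of the low
    component is below the cutoff) is provided for completeness.  TNBC =
    negative on all three markers.
    """
    marker_map = marker_map or ProbeMarkerMap()
    marker_map.validate_against(matrix)
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must lie in (0, 1)")

    posteriors = {}
    fits = {}
    for i, (marker, probe) in enumerate(marker_map.as_dict().items()):
        values = matrix.values.loc[probe].to_numpy(dtype=float)
        fit = fit_two_component_gmm(
            values, seed=None if seed is None else seed + i, **fit_kwargs
        )
        fits[marker] = fit
        posteriors[marker] = posterior_high(values, fit)
    post = pd.DataFrame(posteriors, index=matrix.values.columns)
    if negative_rule == "high":
        negative = post < cutoff
    elif negative_rule == "low":
        negative = (1.0 - post) < cutoff
    else:
        raise ValueError(f"unknown negative_rule {negative_rule!r}")
    tnbc = negative.all(axis=1)
    demoted = pd.Series(False, index=post.index)
    return ReceptorCalls(
        posterior_high=post, negative=negative, tnbc=tnbc, fits=fits, demoted=demoted
    )


def confirm_against_positive_controls(
    matrix: ExpressionMatrix,
    calls: ReceptorCalls,
    controls: Sequence[str],
    marker_map: ProbeMarkerMap | None = None,
    quantile: float = 0.10,
) -> ReceptorCalls:
    """Demote TNBC candidates not markedly below positive controls.

    For each marker the per-marker control pool is the given control
    samples called positive (non-negative) for that marker; a TNBC
    candidate is retained only if its expression for every marker falls
    below the ``quantile`` (default 0.10) of that pool.  Demoted samples
    are flagged, not deleted.
    """
    controls = list(controls)
    if not controls:
        raise ValueError("positive-control set is empty")
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must lie in (0, 1)")
    marker_map = marker_map or ProbeMarkerMap()
    marker_map.validate_against(matrix)
    missing = [c for c in controls if c not in calls.negative.index]
    if missing:
        raise ValueError(f"unknown control sample {missing[0]!r}")
    positive_any = (~calls.negative.loc[controls]).any(axis=1)
    if not positive_any.all():
        bad = positive_any.index[~positive_any][0]
        raise ValueError(
            f"control sample {bad!r} is not marker-positive by the mixture call"
        )

    demoted = calls.demoted.copy()
    thresholds = {}
    for marker, probe in marker_map.as_dict().items():
        pool = [c for c in controls if not calls.negative.loc[c, marker]]
        if not pool:
            pool = controls
            logger.warning(
                "no control is positive for %s; using all controls for its threshold",
                marker,
            )
        thresholds[marker] = float(
            np.quantile(matrix.values.loc[probe, pool].to_numpy(dtype=float), quantile)
        )
    for sample in calls.tnbc.index[calls.tnbc]:
        for marker, probe in marker_map.as_dict().items():
            if matrix.values.loc[probe, sample] >= thresholds[marker]:
                demoted.loc[sample] = True
                break
    n_demoted = int((demoted & calls.tnbc).sum())
    logger.info(
        "positive-control confirmation (q=%.2f): demoted %d of %d TNBC candidates",
        quantile, n_demoted, int(calls.tnbc.sum()),
    )
    return replace(calls, demoted=demoted)
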
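"""Cox proportional-hazards machinery for the prognostic screen.

Two pieces live here:

* a univariate Cox fitter (Newton-Raphson on the partial likelihood with
  Breslow tie handling and an optional fixed offset), vectorized so that
  thousands of single-gene models are maximized simultaneously — the
  resampling ensemble calls this tens of thousands of times, which rules
  out fitting one model object per gene;
* partial Cox regression via sequential latent components: component 1
  weights are proportional to the per-gene univariate Cox coefficients,
  and each further component is built the same way on the gene residuals
  after least-squares removal of all previous component scores, with the
  previous components entering the Cox fits as fixed offsets.  This gives
  a small set of mutually uncorrelated prognostic meta-genes in settings
  where a full multivariate Cox model (genes >> samples) cannot be fit.

The Wald statistic is reported on the 1-degree-of-freedom chi-square scale,
``(beta/se)^2``; a z-scale reading ``|beta/se|`` is available via
:func:`wald_of`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_norm import ClinicalTable, ExpressionMatrix

logger = logging.getLogger(__name__)

_ETA_CLIP = 500.0  # exp() overflow guard; hazards beyond e^500 are pathological anyway


@dataclass
class CoxFit:
    """Result of a univariate Cox fit.

    ``degenerate`` marks zero-information covariates (constant x) and
    non-converged fits; such fits carry ``beta = 0`` and ``wald = 0`` so a
    pathological gene cannot abort or distort an ensemble cycle.
    """

    beta: float
    se: float
    loglik: float
    loglik_null: float
    converged: bool
    degenerate: bool

    @property
    def wald(self) -> float:
        if self.degenerate or not np.isfinite(self.se) or self.se <= 0:
            return 0.0
        return float((self.beta / self.se) ** 2)

    def to_dict(self) -> dict:
        return {
            "beta": self.beta, "se": self.se, "wald": self.wald,
            "loglik": self.loglik, "loglik_null": self.loglik_null,
            "converged": self.converged, "degenerate": self.degenerate,
        }


def wald_of(fit: CoxFit, scale: str = "chi2") -> float:
    """Wald statistic of a fit: ``(beta/se)^2`` (chi2 scale) or ``|beta/se|`` (z scale)."""
    w = fit.wald
    if scale == "chi2":
        return w
    if scale == "z":
        return float(np.sqrt(w))
    raise ValueError(f"unknown Wald scale {scale!r}")


# ---------------------------------------------------------------------------
# Vectorized Newton-Raphson over many single-covariate models
# ---------------------------------------------------------------------------

class _SurvOrder:
    """Pre-sorted survival data shared across all genes of one fit batch.

    Samples are sorted by descending time so the Breslow risk set at any
    death time is a prefix of the sorted order; ``block_last`` maps each
    row to the last row of its tie block, where cumulative sums equal the
    full risk-set sums.
    """

    def __init__(self, time: np.ndarray, event: np.ndarray):
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=int)
        if time.ndim != 1 or event.shape != time.shape:
            raise ValueError("time and event must be equal-length 1-d arrays")
        if event.sum() == 0:
            raise ValueError("no events: all subjects censored")
        self.order = np.argsort(-time, kind="stable")
        t = time[self.order]
        self.time = t
        self.event = event[self.order].astype(bool)
        # last index of each tie block in the descending-time order
        n = len(t)
        block_last = np.empty(n, dtype=int)
        j = 0
        while j < n:
            k = j
            while k + 1 < n and t[k + 1] == t[j]:
                k += 1
            block_last[j:k + 1] = k
            j = k + 1
        self.block_last = block_last
        self.n = n


def _batch_eval(beta: np.ndarray, x: np.ndarray, offset: np.ndarray,
                so: _SurvOrder, need_derivs: bool = True):
    """Log partial likelihood (Breslow) and derivatives for each column of x."""
    eta = np.clip(offset[:, None] + x * beta[None, :], -_ETA_CLIP, _ETA_CLIP)
    w = np.exp(eta)
    c0 = np.cumsum(w, axis=0)[so.block_last]
    ev = so.event
    loglik = eta[ev].sum(axis=0) - np.log(c0[ev]).sum(axis=0)
    if not need_derivs:
        return loglik, None, None
    c1 = np.cumsum(w * x, axis=0)[so.block_last]
    c2 = np.cumsum(w * x * x, axis=0)[so.block_last]
    r1 = c1[ev] / c0[ev]
    grad = x[ev].sum(axis=0) - r1.sum(axis=0)
    hess = -((c2[ev] / c0[ev]) - r1 ** 2).sum(axis=0)
    return loglik, grad, hess


def fit_cox_univariate_many(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    offset: np.ndarray | None = None,
    max_iter: int = 50,
    tol: float = 1e-9,
) -> dict[str, np.ndarray]:
    """Fit one univariate Cox model per column of ``X`` (n_samples x n_covariates).

    Newton-Raphson with step-halving; Breslow handling of tied death times;
    ``offset`` enters every linear predictor unpenalized and unestimated.
    Returns arrays ``beta``, ``se``, ``wald``, ``loglik``, ``loglik_null``,
    ``converged``, ``degenerate``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, g = X.shape
    if offset is None:
        offset = np.zeros(n)
    offset = np.asarray(offset, dtype=float)
    so = _SurvOrder(time, event)
    x = X[so.order]
    off = offset[so.order]

    degenerate = np.ptp(x, axis=0) == 0
    beta = np.zeros(g)
    ll, _, _ = _batch_eval(beta, x, off, so, need_derivs=False)
    ll_null = ll.copy()
    active = ~degenerate
    converged = np.zeros(g, dtype=bool)

    for _ in range(max_iter):
        if not active.any():
            break
        ll_cur, grad, hess = _batch_eval(beta, x, off, so)
        curv = np.maximum(-hess, 1e-12)
        delta = np.where(active, grad / curv, 0.0)
        step = np.ones(g)
        cand = beta + step * delta
        ll_new, _, _ = _batch_eval(cand, x, off, so, need_derivs=False)
        for _half in range(30):
            worse = active & (ll_new < ll_cur - 1e-12)
            if not worse.any():
                break
            step[worse] *= 0.5
            cand = beta + step * delta
            ll_new, _, _ = _batch_eval(cand, x, off, so, need_derivs=False)
        just_done = active & (np.abs(ll_new - ll_cur) < tol)
        beta = np.where(active, cand, beta)
        ll = np.where(active, ll_new, ll)
        converged |= just_done
        active &= ~just_done

    # non-converged fits fall back to the degenerate contract (beta 0, wald 0)
    not_conv = ~converged & ~degenerate
    if not_conv.any():
        logger.warning("cox: %d fit(s) did not converge; returned degenerate", not_conv.sum())
    degenerate = degenerate | not_conv
    beta = np.where(degenerate, 0.0, beta)
    ll = np.where(degenerate, ll_null, ll)

    _, _, hess = _batch_eval(beta, x, off, so)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(1.0 / np.maximum(-hess, 0.0))
    se = np.where(degenerate, np.inf, se)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(np.isfinite(se) & (se > 0), (beta / se) ** 2, 0.0)
    return {
        "beta": beta, "se": se, "wald": wald,
        "loglik": ll, "loglik_null": ll_null,
        "converged": converged, "degenerate": degenerate,
    }


def fit_cox_univariate(
    x: np.ndarray,
    surv: ClinicalTable,
    offset: np.ndarray | None = None,
) -> CoxFit:
    """Univariate Cox fit of one covariate against a clinical table."""
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("covariate contains non-finite values")
    res = fit_cox_univariate_many(x[:, None], surv.time, surv.event, offset=offset)
    return CoxFit(
        beta=float(res["beta"][0]), se=float(res["se"][0]),
        loglik=float(res["loglik"][0]), loglik_null=float(res["loglik_null"][0]),
        converged=bool(res["converged"][0]), degenerate=bool(res["degenerate"][0]),
    )


# ---------------------------------------------------------------------------
# Partial Cox regression with sequential latent components
# ---------------------------------------------------------------------------

@dataclass
class LatentComponentModel:
    """Sequential latent prognostic components.

    ``weights`` (gene x K) hold the unit-norm gene loadings of each
    component; ``scores`` (sample x K) the per-sample component values on
    the training data; ``component_betas`` the Cox coefficient each score
    earned with all earlier components as fixed offsets.  Score columns are
    pairwise uncorrelated by construction.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    weights: np.ndarray
    component_betas: np.ndarray
    scores: np.ndarray
    n_components: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_components = self.weights.shape[1]

    def risk_score(self) -> np.ndarray:
        """Combined per-sample linear predictor; higher = worse predicted outcome."""
        return self.scores @ self.component_betas


def fit_partial_cox(X: ExpressionMatrix, surv: ClinicalTable, K: int = 3) -> LatentComponentModel:
    """Fit a K-component partial Cox regression on z-scored expression.

    Component k's gene weights are proportional to the per-gene univariate
    Cox coefficients computed on the gene residuals (original genes
    least-squares-projected off components 1..k-1, with an intercept), with
    the earlier components' combined risk contribution entering each fit as
    a fixed offset.  Components whose weight vector vanishes (no remaining
    signal) truncate the model early.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K >= X.n_samples:
        raise ValueError(f"K={K} must be smaller than the number of samples ({X.n_samples})")
    surv = surv.aligned_to(X)
    Z = X.values.to_numpy(dtype=float).T  # samples x genes
    n, g = Z.shape
    time, event = surv.time, surv.event

    resid = Z.copy()
    offset = np.zeros(n)
    weights, betas, scores = [], [], []
    for _k in range(K):
        res = fit_cox_univariate_many(resid, time, event, offset=offset)
        w = np.where(res["degenerate"], 0.0, res["beta"])
        norm = np.linalg.norm(w)
        if norm == 0 or not np.isfinite(norm):
            logger.warning("partial cox: no signal left, truncating at %d component(s)", _k)
            break
        w /= norm
        s = resid @ w
        comp = fit_cox_univariate_many(s[:, None], time, event, offset=offset)
        beta_k = float(comp["beta"][0])
        weights.append(w)
        betas.append(beta_k)
        scores.append(s)
        offset = offset + beta_k * s
        # project the original genes off [1, s_1..s_k]
        A = np.column_stack([np.ones(n)] + scores)
        coef, *_ = np.linalg.lstsq(A, Z, rcond=None)
        resid = Z - A @ coef
    if not weights:
        raise ValueError("partial Cox fit found no informative gene in component 1")
    return LatentComponentModel(
        gene_ids=X.gene_ids, sample_ids=X.sample_ids,
        weights=np.column_stack(weights),
        component_betas=np.array(betas),
        scores=np.column_stack(scores),
    )
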
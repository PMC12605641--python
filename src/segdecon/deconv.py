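"""Image-calibrated Bayesian deconvolution of spot-level expression.

The observation model is a negative binomial in the mean / inverse-dispersion
(NB2) form: ``y_gs ~ NB(mu_gs, alpha_g)`` with variance
``mu + mu^2 / alpha``.  The mean factorizes into a spot total abundance and a
reference-weighted cell-type mixture::

    mu_gs = m_s * sum_k w_ks * r_gk,     w_ks >= 0,  sum_k w_ks = 1

Histology enters through a Gamma(kappa, theta) prior (shape-rate) on each
``m_s``, with (kappa, theta) moment-matched to the mean and unbiased variance
of the image-derived per-spot nucleus counts::

    kappa = n_bar^2 / sigma^2 = n_bar / VMR,   theta = n_bar / sigma^2 = 1 / VMR

so the prior mean is exactly ``n_bar`` and the prior variance exactly
``sigma^2``; a small VMR gives a tight prior, a large VMR defers to the data.

Inference is MAP by default (L-BFGS on ``log m_s`` and softmax logits of
``w``, analytic gradients) with an optional reparameterized-Gaussian VI.
Absolute per-type counts follow post hoc as ``C_ks = w_ks * n_s``; transcript
counts are never modified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp

from .spot_mapping import CountMoments, SpotCounts, count_moments

__all__ = [
    "GammaPrior",
    "ReferenceProfile",
    "DeconvModelSpec",
    "DeconvResult",
    "moment_match_prior",
    "nb_loglik",
    "fit_deconvolution",
    "absolute_counts",
    "calibrate_prior_roi",
    "SpotDeconvolver",
]

logger = logging.getLogger(__name__)

DIFFUSE_KAPPA = 0.01
DIFFUSE_THETA = 0.01


@dataclass(frozen=True)
class GammaPrior:
    """Shape-rate Gamma prior on spot total abundance: mean = kappa/theta,
    variance = kappa/theta^2."""

    kappa: float
    theta: float
    scope: str = "global"

    def __post_init__(self):
        if self.kappa <= 0 or self.theta <= 0:
            raise ValueError("Gamma prior requires kappa > 0 and theta > 0")

    @property
    def mean(self) -> float:
        return self.kappa / self.theta

    @property
    def variance(self) -> float:
        return self.kappa / self.theta**2


@dataclass
class ReferenceProfile:
    """Non-negative reference expression r_gk of gene g in cell type k."""

    genes: list[str]
    cell_types: list[str]
    r_gk: np.ndarray

    def __post_init__(self):
        self.r_gk = np.asarray(self.r_gk, dtype=float)
        if self.r_gk.shape != (len(self.genes), len(self.cell_types)):
            raise ValueError("r_gk must be (genes x cell_types)")
        if (self.r_gk < 0).any():
            raise ValueError("reference expression must be non-negative")
        if (self.r_gk.sum(axis=0) == 0).any():
            raise ValueError("reference has an all-zero cell-type column")


@dataclass(frozen=True)
class DeconvModelSpec:
    alpha_g: float | np.ndarray = 10.0     # NB inverse-dispersion (scalar or per gene)
    alpha_mode: str = "fixed"              # fixed | estimated
    prior: GammaPrior = GammaPrior(DIFFUSE_KAPPA, DIFFUSE_THETA)
    inference: str = "map"                 # map | vi
    seed: int = 0
    iterations: int = 2000
    learning_rate: float = 0.05
    efficiency: float = 1.0                # optional platform scalar on m_s


@dataclass
class DeconvResult:
    spot_ids: list
    cell_types: list[str]
    m_s: np.ndarray                        # (S,) total abundance
    w_ks: np.ndarray                       # (S, K) simplex rows
    C_ks: np.ndarray | None = None         # (S, K) absolute counts
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Prior calibration
# ---------------------------------------------------------------------------

def moment_match_prior(
    moments: CountMoments, scope: str = "global"
) -> GammaPrior:
    """Closed-form moment matching: kappa = n_bar^2/sigma^2, theta = n_bar/sigma^2.

    Equivalently kappa = n_bar/VMR and theta = 1/VMR; the matched prior has
    mean n_bar and variance sigma^2 exactly.
    """
    if moments.n_bar <= 0:
        raise ValueError("moment matching requires n_bar > 0")
    if moments.sigma2 <= 0:
        raise ValueError(
            "moment matching requires sigma2 > 0 (constant counts give a "
            "degenerate prior; add a variance floor upstream if intended)"
        )
    kappa = moments.n_bar**2 / moments.sigma2
    theta = moments.n_bar / moments.sigma2
    return GammaPrior(kappa, theta, scope)


def calibrate_prior_roi(
    counts: SpotCounts, roi_labels: dict
) -> dict[str, GammaPrior]:
    """Per-region moment matching with a global fallback.

    ``roi_labels`` maps spot id -> region label.  Regions with fewer than two
    spots, zero mean, or zero variance fall back to the global prior (logged).
    """
    if not roi_labels:
        raise ValueError("empty region map")
    global_prior = moment_match_prior(count_moments(counts), scope="global")
    n_by_id = dict(zip(counts.spot_ids, counts.n_s))
    regions: dict[str, list] = {}
    for sid, region in roi_labels.items():
        regions.setdefault(region, []).append(n_by_id[sid])
    out = {}
    for region, vals in regions.items():
        try:
            out[region] = moment_match_prior(
                count_moments(np.asarray(vals)), scope="per_roi"
            )
        except ValueError:
            logger.info("region %r falls back to the global prior", region)
            out[region] = global_prior
    return out


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def _validate_counts(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if (y < 0).any():
        raise ValueError("counts must be non-negative")
    if not np.allclose(y, np.round(y)):
        raise ValueError("counts must be integers")
    return y.astype(float)


def nb_loglik(y: np.ndarray, mu: np.ndarray, alpha_g: np.ndarray | float) -> float:
    """Total NB2 log-likelihood: Var(y) = mu + mu^2/alpha; Poisson as
    alpha -> infinity."""
    y = _validate_counts(y)
    mu = np.asarray(mu, dtype=float)
    a = np.broadcast_to(np.asarray(alpha_g, dtype=float), mu.shape)
    if (mu <= 0).any() or (a <= 0).any():
        raise ValueError("mu and alpha_g must be positive")
    ll = (
        gammaln(y + a)
        - gammaln(a)
        - gammaln(y + 1.0)
        + a * np.log(a / (a + mu))
        + y * np.log(mu / (a + mu))
    )
    return float(ll.sum())


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def _softmax(logits: np.ndarray) -> np.ndarray:
    return np.exp(logits - logsumexp(logits, axis=1, keepdims=True))


def _neg_posterior_and_grad(x, y, R, alpha, prior, S, K, eps=1e-12):
    """Negative log posterior and gradient in (log m, w-logits) coordinates."""
    log_m = x[:S]
    logits = x[S:].reshape(S, K)
    m = np.exp(log_m)
    w = _softmax(logits)
    e = w @ R.T                        # (S, G) mixture expression
    mu = m[:, None] * e + eps

    ll = (
        gammaln(y + alpha)
        - gammaln(alpha)
        - gammaln(y + 1.0)
        + alpha * np.log(alpha / (alpha + mu))
        + y * np.log(mu / (alpha + mu))
    ).sum()
    lp = ((prior.kappa - 1.0) * log_m - prior.theta * m).sum()

    dmu = y / mu - (y + alpha) / (alpha + mu)        # (S, G)
    g_logm = m * (dmu * e).sum(axis=1) + (prior.kappa - 1.0) - prior.theta * m
    g_w = m[:, None] * (dmu @ R)                     # (S, K)
    g_logits = w * (g_w - (g_w * w).sum(axis=1, keepdims=True))

    f = -(ll + lp)
    grad = -np.concatenate([g_logm, g_logits.ravel()])
    return f, grad


def _estimate_alpha(y, mu, bounds=(0.1, 1000.0)):
    """Method-of-moments per-gene inverse-dispersion with a weak pull to the
    prior center (log-normal hyperprior around alpha = 10)."""
    resid2 = (y - mu) ** 2
    excess = np.maximum(resid2.mean(axis=0) - mu.mean(axis=0), 1e-8)
    alpha = (mu**2).mean(axis=0) / excess
    # shrink on the log scale toward 10 (weak hyperprior, sd ~ 2 in log units)
    alpha = np.exp(0.9 * np.log(np.clip(alpha, *bounds)) + 0.1 * np.log(10.0))
    return np.clip(alpha, *bounds)


def _align_genes(y, genes_y, ref: ReferenceProfile):
    """Intersect gene sets, order from the reference, collapse duplicate ids."""
    import pandas as pd

    dfy = pd.DataFrame(np.asarray(y).T, index=list(genes_y))
    dfy = dfy.groupby(level=0, sort=False).sum()
    dfr = pd.DataFrame(ref.r_gk, index=list(ref.genes))
    dfr = dfr.groupby(level=0, sort=False).sum()
    common = [g for g in dfr.index if g in set(dfy.index)]
    if not common:
        raise ValueError("gene sets of counts and reference do not overlap")
    return dfy.loc[common].to_numpy().T, dfr.loc[common].to_numpy()


def fit_deconvolution(
    y: np.ndarray,
    ref: ReferenceProfile,
    spec: DeconvModelSpec = DeconvModelSpec(),
    genes: list[str] | None = None,
    spot_ids: list | None = None,
) -> DeconvResult:
    """Fit {m_s, w_ks} to raw spot-by-gene counts under the shared Gamma prior.

    ``genes`` names the columns of ``y``; when given, the gene sets of counts
    and reference are intersected and aligned (order from the reference,
    duplicated identifiers collapsed by sum).  Raw counts go in unmodified.
    """
    y = _validate_counts(y)
    if genes is not None:
        y, R = _align_genes(y, genes, ref)
    else:
        if y.shape[1] != ref.r_gk.shape[0]:
            raise ValueError("counts and reference gene dimensions differ")
        R = ref.r_gk
    S, G = y.shape
    K = R.shape[1]
    prior = spec.prior
    spot_ids = list(range(S)) if spot_ids is None else list(spot_ids)

    alpha = np.broadcast_to(
        np.asarray(spec.alpha_g, dtype=float), (G,)
    ).copy()[None, :]

    # the optional platform efficiency scales expression, not the prior:
    # mu = m * (efficiency * sum_k w r), with the Gamma prior on m itself
    R = R * spec.efficiency

    # init: totals matched through the mean reference column, uniform mixture
    col_sums = R.sum(axis=0)
    m0 = np.maximum(y.sum(axis=1) / max(col_sums.mean(), 1e-8), 1e-3)
    x0 = np.concatenate([np.log(m0), np.zeros(S * K)])

    trace: list[float] = []

    # box bounds on log m keep a kappa < 1 prior (density spike at m = 0)
    # from dragging zero-count spots into numerical underflow
    bounds = [(-18.0, 18.0)] * S + [(None, None)] * (S * K)

    def run_map(x_init):
        res = minimize(
            _neg_posterior_and_grad,
            x_init,
            args=(y, R, alpha, prior, S, K),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": spec.iterations},
            callback=lambda xk: trace.append(
                _neg_posterior_and_grad(xk, y, R, alpha, prior, S, K)[0]
            ),
        )
        return res

    if spec.inference == "map":
        res = run_map(x0)
        if spec.alpha_mode == "estimated":
            for _ in range(2):
                m = np.exp(res.x[:S])
                w = _softmax(res.x[S:].reshape(S, K))
                mu = m[:, None] * (w @ R.T) + 1e-12
                alpha = _estimate_alpha(y, mu)[None, :]
                res = run_map(res.x)
        x_hat = res.x
        final_obj = float(res.fun)
        n_iter = int(res.nit)
        converged = bool(res.success)
    elif spec.inference == "vi":
        x_hat, final_obj, n_iter, converged = _fit_vi(
            y, R, alpha, prior, S, K, x0, spec, trace
        )
    else:
        raise ValueError(f"unknown inference mode {spec.inference!r}")

    m_hat = np.exp(x_hat[:S])
    w_hat = _softmax(x_hat[S:].reshape(S, K))
    if not converged:
        logger.warning("deconvolution did not converge within the iteration budget")
    return DeconvResult(
        spot_ids,
        list(ref.cell_types),
        m_hat,
        w_hat,
        diagnostics={
            "final_objective": final_obj,
            "n_iter": n_iter,
            "converged": converged,
            "objective_trace": trace,
            "inference": spec.inference,
            "prior": {"kappa": prior.kappa, "theta": prior.theta, "scope": prior.scope},
        },
    )


def _fit_vi(y, R, alpha, prior, S, K, x0, spec, trace):
    """Mean-field Gaussian VI over (log m, logits) with one-sample
    reparameterized gradients and Adam; deterministic given the seed."""
    from ._utils import STREAM_VI, rng_stream

    rng = rng_stream(spec.seed, STREAM_VI)
    mu_q = x0.copy()
    log_sd = np.full_like(x0, -2.0)
    m1 = np.zeros_like(x0)
    v1 = np.zeros_like(x0)
    m2 = np.zeros_like(x0)
    v2 = np.zeros_like(x0)
    lr = spec.learning_rate
    b1, b2, eps = 0.9, 0.999, 1e-8
    last = np.inf
    for t in range(1, spec.iterations + 1):
        z = rng.standard_normal(x0.shape)
        x = mu_q + np.exp(log_sd) * z
        f, g = _neg_posterior_and_grad(x, y, R, alpha, prior, S, K)
        # ELBO = E[log p] + entropy; entropy grad wrt log_sd is -1 per dim
        g_mu = g
        g_logsd = g * z * np.exp(log_sd) - 1.0
        for grad, mom, vel, param in (
            (g_mu, m1, v1, mu_q),
            (g_logsd, m2, v2, log_sd),
        ):
            mom *= b1
            mom += (1 - b1) * grad
            vel *= b2
            vel += (1 - b2) * grad**2
            mhat = mom / (1 - b1**t)
            vhat = vel / (1 - b2**t)
            param -= lr * mhat / (np.sqrt(vhat) + eps)
        trace.append(float(f))
        last = f
    return mu_q, float(last), spec.iterations, True


# ---------------------------------------------------------------------------
# Absolute counts
# ---------------------------------------------------------------------------

def absolute_counts(w_ks: np.ndarray, counts: SpotCounts, spot_ids=None) -> np.ndarray:
    """C_ks = w_ks * n_s, elementwise per spot; sums recover n_s exactly and
    values stay real (no rounding)."""
    w = np.asarray(w_ks, dtype=float)
    if spot_ids is not None:
        order = {sid: i for i, sid in enumerate(counts.spot_ids)}
        missing = [sid for sid in spot_ids if sid not in order]
        if missing or len(spot_ids) != w.shape[0]:
            raise ValueError("spot ids of proportions and counts do not match")
        n = np.asarray(counts.n_s)[[order[sid] for sid in spot_ids]]
    else:
        if w.shape[0] != len(counts.n_s):
            raise ValueError("spot ids of proportions and counts do not match")
        n = np.asarray(counts.n_s)
    return w * n[:, None]


# ---------------------------------------------------------------------------
# Estimator facade
# ---------------------------------------------------------------------------

class SpotDeconvolver:
    """sklearn-style estimator for the spot deconvolution model.

    Parameters mirror :class:`DeconvModelSpec`; ``fit(Y)`` consumes a raw
    spot-by-gene count matrix and sets ``m_s_``, ``w_ks_``, ``diagnostics_``
    (and ``C_ks_`` when per-spot nucleus counts are supplied).
    """

    def __init__(
        self,
        reference: ReferenceProfile | None = None,
        prior: GammaPrior | None = None,
        alpha_g: float = 10.0,
        alpha_mode: str = "fixed",
        inference: str = "map",
        iterations: int = 2000,
        learning_rate: float = 0.05,
        efficiency: float = 1.0,
        seed: int = 0,
    ):
        self.reference = reference
        self.prior = prior
        self.alpha_g = alpha_g
        self.alpha_mode = alpha_mode
        self.inference = inference
        self.iterations = iterations
        self.learning_rate = learning_rate
        self.efficiency = efficiency
        self.seed = seed

    _param_names = (
        "reference", "prior", "alpha_g", "alpha_mode", "inference",
        "iterations", "learning_rate", "efficiency", "seed",
    )

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **params) -> "SpotDeconvolver":
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(
        self,
        Y: np.ndarray,
        nucleus_counts: SpotCounts | None = None,
        genes: list[str] | None = None,
        spot_ids: list | None = None,
    ) -> "SpotDeconvolver":
        if self.reference is None:
            raise ValueError("a ReferenceProfile is required to fit")
        prior = self.prior
        if prior is None and nucleus_counts is not None:
            prior = moment_match_prior(count_moments(nucleus_counts))
        if prior is None:
            prior = GammaPrior(DIFFUSE_KAPPA, DIFFUSE_THETA)
        spec = DeconvModelSpec(
            alpha_g=self.alpha_g,
            alpha_mode=self.alpha_mode,
            prior=prior,
            inference=self.inference,
            seed=self.seed,
            iterations=self.iterations,
            learning_rate=self.learning_rate,
            efficiency=self.efficiency,
        )
        result = fit_deconvolution(Y, self.reference, spec, genes, spot_ids)
        self.result_ = result
        self.prior_ = prior
        self.m_s_ = result.m_s
        self.w_ks_ = result.w_ks
        self.diagnostics_ = result.diagnostics
        if nucleus_counts is not None:
            self.C_ks_ = absolute_counts(result.w_ks, nucleus_counts, result.spot_ids)
            result.C_ks = self.C_ks_
        return self

    def predict_proportions(self) -> np.ndarray:
        return self.w_ks_
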
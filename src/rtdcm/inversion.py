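"""Variational Bayesian (Laplace) inversion of one model on one window.

The free parameters theta (selected A/B/C entries) get a Gaussian
shrinkage prior; observation noise is iid Gaussian per region with a
log-precision hyperparameter lambda updated by EM.  A Gauss-Newton
ascent on the variational free energy F, with Levenberg-style damping
and central-finite-difference Jacobians, yields a Gaussian posterior
q(theta) and F as an approximation to the log model evidence (nats).
Window-level nuisance variation (constant offset + linear drift) is
projected out of both data and prediction before the likelihood is
evaluated.

Everything is deterministic: identical inputs reproduce F bit-identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import ExperimentDesign, ROITimeSeries
from .forward import HemodynamicParams, simulate_batch_bold
from .models import DcmSkeleton

__all__ = [
    "Priors",
    "InversionResult",
    "InversionError",
    "default_priors",
    "make_predictor",
    "invert",
    "invert_callable",
    "free_energy",
    "summarize_posterior",
]

LOG2PI = float(np.log(2.0 * np.pi))

#: iteration cap used during neurofeedback so that both model fits
#: complete within the resting-state block.
DEFAULT_MAX_ITER = 44
DEFAULT_TOL = 0.05


class InversionError(RuntimeError):
    """Raised when the ascent cannot proceed (non-finite model output or
    exhausted damping)."""


@dataclass
class Priors:
    """Gaussian priors over free parameters and log noise precisions.

    ``confound_basis`` names the per-window nuisance basis projected out
    of data and prediction ("constant+linear", "constant", or "none").
    Structurally absent connections are not represented: they carry zero
    prior variance by construction and are never updated.
    """

    theta_names: tuple[str, ...]
    theta_mean: np.ndarray         # (p,)
    theta_cov: np.ndarray          # (p, p), symmetric positive definite
    lambda_mean: np.ndarray        # (R,) log precision
    lambda_var: np.ndarray         # (R,) prior variance; 0 = fixed lambda
    confound_basis: str = "constant+linear"

    def __post_init__(self) -> None:
        self.theta_mean = np.asarray(self.theta_mean, dtype=float)
        self.theta_cov = np.asarray(self.theta_cov, dtype=float)
        self.lambda_mean = np.asarray(self.lambda_mean, dtype=float)
        self.lambda_var = np.asarray(self.lambda_var, dtype=float)
        p = self.theta_mean.shape[0]
        if self.theta_cov.shape != (p, p):
            raise ValueError("theta_cov shape must match theta_mean")
        if not np.allclose(self.theta_cov, self.theta_cov.T, atol=1e-12):
            raise ValueError("theta_cov must be symmetric")
        if np.any(np.linalg.eigvalsh(self.theta_cov) <= 0):
            raise ValueError("theta_cov must be positive definite over free "
                             "parameters")
        if np.any(self.lambda_var < 0):
            raise ValueError("lambda_var must be non-negative")

    @property
    def n_params(self) -> int:
        return self.theta_mean.shape[0]


@dataclass
class InversionResult:
    """Posterior summary of one model fit."""

    theta_names: tuple[str, ...]
    posterior_mean: np.ndarray
    posterior_cov: np.ndarray
    lambda_post: np.ndarray
    lambda_var: np.ndarray
    F: float
    n_iterations: int
    converged: bool
    F_trajectory: np.ndarray

    def to_dict(self) -> dict:
        return {
            "theta_names": list(self.theta_names),
            "posterior_mean": self.posterior_mean.tolist(),
            "posterior_cov": self.posterior_cov.tolist(),
            "lambda_post": self.lambda_post.tolist(),
            "lambda_var": self.lambda_var.tolist(),
            "F": float(self.F),
            "n_iterations": int(self.n_iterations),
            "converged": bool(self.converged),
            "F_trajectory": np.asarray(self.F_trajectory).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "InversionResult":
        return cls(
            theta_names=tuple(d["theta_names"]),
            posterior_mean=np.asarray(d["posterior_mean"], dtype=float),
            posterior_cov=np.asarray(d["posterior_cov"], dtype=float),
            lambda_post=np.asarray(d["lambda_post"], dtype=float),
            lambda_var=np.asarray(d["lambda_var"], dtype=float),
            F=float(d["F"]),
            n_iterations=int(d["n_iterations"]),
            converged=bool(d["converged"]),
            F_trajectory=np.asarray(d["F_trajectory"], dtype=float),
        )


def default_priors(
    skeleton: DcmSkeleton,
    coupling_var: float = 0.25,
    lambda_mean: float = 0.0,
    lambda_var: float = 32.0,
) -> Priors:
    """Zero-mean shrinkage priors on the skeleton's free A/B/C entries.

    All free coupling parameters share one prior variance (Hz^2); the
    self-decay is fixed by the skeleton and carries no prior.  Two
    architectures differing only in B placement therefore get identical
    A and C priors.
    """
    p = skeleton.n_free
    r = skeleton.n_regions
    return Priors(
        theta_names=tuple(skeleton.parameter_names()),
        theta_mean=np.zeros(p),
        theta_cov=np.eye(p) * coupling_var,
        lambda_mean=np.full(r, float(lambda_mean)),
        lambda_var=np.full(r, float(lambda_var)),
    )


def make_predictor(
    skeleton: DcmSkeleton,
    design: ExperimentDesign,
    hemo: HemodynamicParams | None = None,
    dt: float | None = None,
    self_decay: float = -0.5,
    z_bound: float = 10.0,
):
    """Build the batched forward map theta -> predicted percent BOLD.

    Returns ``predict(Theta)`` mapping (nb, p) parameter rows to
    (nb, n_scans, n_regions) percent-signal predictions; rows whose
    dynamics diverge come back as NaN.
    """
    if hemo is None:
        hemo = HemodynamicParams()
    if design.n_inputs != len(skeleton.input_labels):
        raise ValueError(
            f"design has {design.n_inputs} input channels, skeleton expects "
            f"{len(skeleton.input_labels)}"
        )
    n, m = skeleton.n_regions, len(skeleton.input_labels)
    ia = np.argwhere(skeleton.free_A)
    ib = np.argwhere(skeleton.free_B)
    ic = np.argwhere(skeleton.free_C)
    nA, nB = len(ia), len(ib)

    def predict(Theta: np.ndarray) -> np.ndarray:
        Theta = np.atleast_2d(np.asarray(Theta, dtype=float))
        nb = Theta.shape[0]
        A = np.broadcast_to(np.eye(n) * self_decay, (nb, n, n)).copy()
        B = np.zeros((nb, m, n, n))
        C = np.zeros((nb, n, m))
        if nA:
            A[:, ia[:, 0], ia[:, 1]] = Theta[:, :nA]
        if nB:
            B[:, ib[:, 0], ib[:, 1], ib[:, 2]] = Theta[:, nA:nA + nB]
        if len(ic):
            C[:, ic[:, 0], ic[:, 1]] = Theta[:, nA + nB:]
        y, div = simulate_batch_bold(A, B, C, design, hemo, dt, z_bound)
        y = 100.0 * y
        if np.any(div >= 0):
            y[div >= 0] = np.nan
        return y

    return predict


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------

def _confound_projector(n_scans: int, basis: str) -> tuple[np.ndarray | None, int]:
    """(projector complement X0, rank) for the named nuisance basis."""
    if basis in (None, "none"):
        return None, 0
    cols = [np.ones(n_scans)]
    if basis == "constant+linear":
        cols.append(np.linspace(-1.0, 1.0, n_scans))
    elif basis != "constant":
        raise ValueError(f"unknown confound basis {basis!r}")
    X0 = np.column_stack(cols)
    return X0, X0.shape[1]


def _project(P: np.ndarray | None, arr: np.ndarray) -> np.ndarray:
    if P is None:
        return arr
    return np.tensordot(P, arr, axes=([1], [0]))


def _posterior_and_hypers(JP, e, priors, S0inv, lam, n_eff, n_hyper_iter=4):
    """Co-update posterior covariance and noise hyperparameters.

    JP: projected Jacobian (N, R, p); e: projected residual (N, R).
    Returns (Sigma, H, lam, lam_var, G) where G[r] is the expected
    squared residual including posterior parameter uncertainty.
    """
    N, R, p = JP.shape
    lam = lam.copy()
    lam0, v0 = priors.lambda_mean, priors.lambda_var
    JtJ = np.einsum("nrp,nrq->rpq", JP, JP)
    e2 = np.einsum("nr,nr->r", e, e)
    Sigma = None
    G = np.empty(R)
    lam_var = np.zeros(R)
    for _ in range(n_hyper_iter):
        H = S0inv + np.einsum("r,rpq->pq", np.exp(lam), JtJ)
        try:
            Sigma = np.linalg.inv(H)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise InversionError("singular posterior curvature") from exc
        for r in range(R):
            G[r] = e2[r] + float(np.einsum("pq,qp->", JtJ[r], Sigma))
        # one Newton step on F in lambda per sweep (free hyperpriors only)
        for r in range(R):
            if v0[r] == 0.0:
                lam[r] = lam0[r]
                continue
            grad = 0.5 * n_eff - 0.5 * np.exp(lam[r]) * G[r] \
                - (lam[r] - lam0[r]) / v0[r]
            hess = -0.5 * np.exp(lam[r]) * G[r] - 1.0 / v0[r]
            step = np.clip(-grad / hess, -4.0, 4.0)
            lam[r] = lam[r] + step
    H = S0inv + np.einsum("r,rpq->pq", np.exp(lam), JtJ)
    Sigma = np.linalg.inv(H)
    for r in range(R):
        G[r] = e2[r] + float(np.einsum("pq,qp->", JtJ[r], Sigma))
        if v0[r] > 0.0:
            lam_var[r] = 1.0 / (0.5 * np.exp(lam[r]) * G[r] + 1.0 / v0[r])
    return Sigma, H, lam, lam_var, G


def _free_energy_terms(G, e_unused, Sigma, theta_dev, lam, lam_var, priors,
                       S0inv, n_eff):
    """Laplace free energy from precomputed expected residuals G[r]."""
    R = G.shape[0]
    p = Sigma.shape[0]
    acc = 0.0
    for r in range(R):
        acc += (-0.5 * np.exp(lam[r]) * G[r] + 0.5 * n_eff * lam[r]
                - 0.5 * n_eff * LOG2PI)
    sign0, logdet0 = np.linalg.slogdet(priors.theta_cov)
    sign1, logdet1 = np.linalg.slogdet(Sigma)
    if sign1 <= 0:
        raise InversionError("posterior covariance not positive definite")
    kl_theta = 0.5 * (
        float(np.einsum("pq,qp->", S0inv, Sigma))
        + float(theta_dev @ S0inv @ theta_dev)
        - p + logdet0 - logdet1
    )
    kl_lam = 0.0
    for r in range(R):
        v0 = priors.lambda_var[r]
        if v0 > 0.0 and lam_var[r] > 0.0:
            kl_lam += 0.5 * (
                (lam_var[r] + (lam[r] - priors.lambda_mean[r]) ** 2) / v0
                - 1.0 + np.log(v0 / lam_var[r])
            )
    return acc - kl_theta - kl_lam


def free_energy(
    y: np.ndarray,
    predict,
    q_mean: np.ndarray,
    q_cov: np.ndarray,
    lam: np.ndarray,
    priors: Priors,
    lam_var: np.ndarray | None = None,
    fd_step: float = 1e-4,
) -> float:
    """Free energy of a Gaussian posterior ``q`` under the Laplace scheme.

    Accuracy (expected Gaussian log-likelihood of the confound-projected
    residuals, including posterior parameter uncertainty through the
    local Jacobian) minus the KL complexity penalties for theta and
    lambda.  ``predict`` maps a (nb, p) parameter batch to (nb, N, R)
    predictions.
    """
    y = np.asarray(y, dtype=float)
    q_mean = np.asarray(q_mean, dtype=float)
    q_cov = np.asarray(q_cov, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if lam_var is None:
        lam_var = np.zeros_like(lam)
    if not np.allclose(q_cov, q_cov.T, atol=1e-10) or np.any(
            np.linalg.eigvalsh(q_cov) < -1e-12):
        raise ValueError("posterior covariance must be symmetric PSD")
    N = y.shape[0]
    X0, rank0 = _confound_projector(N, priors.confound_basis)
    P = None if X0 is None else np.eye(N) - X0 @ np.linalg.pinv(X0)
    n_eff = N - rank0
    g, J = _jacobian(predict, q_mean, fd_step)
    e = _project(P, y - g)
    JP = _project(P, J)
    JtJ = np.einsum("nrp,nrq->rpq", JP, JP)
    G = np.einsum("nr,nr->r", e, e) + np.array(
        [float(np.einsum("pq,qp->", JtJ[r], q_cov)) for r in range(y.shape[1])]
    )
    S0inv = np.linalg.inv(priors.theta_cov)
    return _free_energy_terms(G, e, q_cov, q_mean - priors.theta_mean, lam,
                              lam_var, priors, S0inv, n_eff)


def _jacobian(predict, theta, fd_step):
    """Prediction and central-difference Jacobian at theta.

    Returns (g (N,R), J (N,R,p)).  Raises on non-finite output.
    """
    p = theta.shape[0]
    batch = [theta]
    steps = np.empty(p)
    for i in range(p):
        h = fd_step * max(1.0, abs(theta[i]))
        steps[i] = h
        tp = theta.copy(); tp[i] += h
        tm = theta.copy(); tm[i] -= h
        batch.append(tp)
        batch.append(tm)
    out = predict(np.array(batch))
    if not np.all(np.isfinite(out)):
        raise InversionError(
            "non-finite model prediction while evaluating the Jacobian "
            "(dynamics diverged)"
        )
    g = out[0]
    N, R = g.shape
    J = np.empty((N, R, p))
    for i in range(p):
        J[:, :, i] = (out[1 + 2 * i] - out[2 + 2 * i]) / (2.0 * steps[i])
    return g, J


def invert_callable(
    y: np.ndarray,
    predict,
    priors: Priors,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    fd_step: float = 1e-4,
    damping: float = 1.0,
    max_damping: float = 1e12,
) -> InversionResult:
    """Gauss-Newton / variational-Laplace ascent on F for a generic model.

    Accepts a step only if it does not decrease F; rejections double the
    Levenberg trust factor, acceptances halve it.  Stops when |dF| stays
    below ``tol`` on two consecutive iterations, or at ``max_iter``.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise InversionError("non-finite values in the data window")
    N, R = y.shape
    p = priors.n_params
    if N < 2 * p:
        warnings.warn(
            f"window of {N} scans is short for {p} free parameters",
            stacklevel=2,
        )
    X0, rank0 = _confound_projector(N, priors.confound_basis)
    P = None if X0 is None else np.eye(N) - X0 @ np.linalg.pinv(X0)
    n_eff = N - rank0
    yP = _project(P, y)
    S0inv = np.linalg.inv(priors.theta_cov)

    theta = priors.theta_mean.copy()
    lam = priors.lambda_mean.copy()
    nu = float(damping)

    def evaluate(th, lam_in):
        g, J = _jacobian(predict, th, fd_step)
        JP = _project(P, J)
        e = yP - _project(P, g)
        Sigma, H, lam_new, lam_var, G = _posterior_and_hypers(
            JP, e, priors, S0inv, lam_in, n_eff)
        F = _free_energy_terms(G, e, Sigma, th - priors.theta_mean, lam_new,
                               lam_var, priors, S0inv, n_eff)
        return g, J, JP, e, Sigma, H, lam_new, lam_var, F

    if max_iter <= 0:
        # budget exhausted immediately: q equals the prior, so F is
        # evaluated at the prior (both KL terms vanish)
        g0, J0 = _jacobian(predict, theta, fd_step)
        JP0 = _project(P, J0)
        e0 = yP - _project(P, g0)
        JtJ0 = np.einsum("nrp,nrq->rpq", JP0, JP0)
        G0 = np.einsum("nr,nr->r", e0, e0) + np.array(
            [float(np.einsum("pq,qp->", JtJ0[r], priors.theta_cov))
             for r in range(R)])
        F0 = _free_energy_terms(G0, e0, priors.theta_cov,
                                np.zeros_like(theta), lam,
                                priors.lambda_var.copy(), priors, S0inv,
                                n_eff)
        return InversionResult(
            theta_names=priors.theta_names,
            posterior_mean=priors.theta_mean.copy(),
            posterior_cov=priors.theta_cov.copy(),
            lambda_post=priors.lambda_mean.copy(),
            lambda_var=priors.lambda_var.copy(),
            F=float(F0), n_iterations=0, converged=False,
            F_trajectory=np.empty(0),
        )

    g, J, JP, e, Sigma, H, lam, lam_var, F_cur = evaluate(theta, lam)

    trajectory = []
    converged = False
    small_steps = 0
    it = 0
    while it < max_iter:
        it += 1
        grad = np.einsum("r,nrp,nr->p", np.exp(lam), JP, e) \
            - S0inv @ (theta - priors.theta_mean)
        scale = np.diag(H).copy()
        scale[scale <= 0] = 1.0
        accepted = False
        try:
            dtheta = np.linalg.solve(H + nu * np.diag(scale), grad)
            cand = theta + dtheta
            out = evaluate(cand, lam)
            F_new = out[-1]
            if np.isfinite(F_new) and F_new >= F_cur - 1e-9:
                accepted = True
        except InversionError:
            F_new = -np.inf
        if accepted:
            dF = F_new - F_cur
            theta = cand
            g, J, JP, e, Sigma, H, lam, lam_var, F_cur = out
            nu = max(nu / 2.0, 1e-8)
            small_steps = small_steps + 1 if abs(dF) < tol else 0
        else:
            nu *= 2.0
            if nu > max_damping:
                raise InversionError(
                    "damping exhausted: curvature remains singular or F "
                    "cannot be improved"
                )
            # a rejected proposal that would barely have moved F is
            # convergence evidence, not grounds to keep shrinking the step
            if np.isfinite(F_new) and abs(F_new - F_cur) < tol:
                small_steps += 1
            else:
                small_steps = 0
        trajectory.append(F_cur)
        if small_steps >= 2:
            converged = True
            break

    return InversionResult(
        theta_names=priors.theta_names,
        posterior_mean=theta,
        posterior_cov=Sigma,
        lambda_post=lam,
        lambda_var=lam_var,
        F=float(F_cur),
        n_iterations=it,
        converged=converged,
        F_trajectory=np.asarray(trajectory),
    )


def invert(
    y: ROITimeSeries | np.ndarray,
    design: ExperimentDesign,
    skeleton: DcmSkeleton,
    priors: Priors | None = None,
    hemo: HemodynamicParams | None = None,
    dt: float | None = None,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    **kwargs,
) -> InversionResult:
    """Invert one DCM against one ROI time-series window.

    ``y`` may be a :class:`ROITimeSeries` or a raw (scans x regions)
    array in (percent-scale) signal units; the window design must carry
    the model's single attention channel (see
    :meth:`ExperimentDesign.collapse_inputs`).
    """
    values = y.values if isinstance(y, ROITimeSeries) else np.asarray(y, float)
    if values.shape[0] != design.n_scans:
        raise ValueError(
            f"data window has {values.shape[0]} scans but design covers "
            f"{design.n_scans}"
        )
    if priors is None:
        priors = default_priors(skeleton)
    predict = make_predictor(skeleton, design, hemo=hemo, dt=dt)
    return invert_callable(values, predict, priors, max_iter=max_iter,
                           tol=tol, **kwargs)


def summarize_posterior(
    result: InversionResult, threshold: float = 0.0
) -> dict[str, tuple[float, float]]:
    """Per-parameter (mean, conditional probability of exceeding threshold).

    The probability is the Gaussian posterior mass beyond ``threshold``
    on the side of the posterior mean, i.e. Phi((|mean| - threshold)/sd);
    a zero-variance (structural) parameter maps to exactly 0 or 1.
    """
    from scipy.stats import norm

    out = {}
    sds = np.sqrt(np.clip(np.diag(result.posterior_cov), 0.0, None))
    for name, mu, sd in zip(result.theta_names, result.posterior_mean, sds):
        if sd == 0.0:
            prob = 1.0 if abs(mu) > threshold else 0.0
        else:
            prob = float(norm.cdf((abs(mu) - threshold) / sd))
        out[name] = (float(mu), prob)
    return out
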
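"""Generic inference backends: MAP + Laplace approximation, and HMC.

``laplace`` (the fast default, labelled approximate): the posterior mode is
found with L-BFGS using analytic gradients; draws come from the Gaussian
approximation N(mode, H^{-1}) with the Hessian obtained by central finite
differences of the analytic gradient.

``hmc``: a plain Hamiltonian Monte Carlo sampler with dual-averaging step
size adaptation and a diagonal mass matrix estimated during warmup; several
chains are run from jittered starts so split-Rhat is meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.optimize


@dataclass
class InferenceResult:
    mode: np.ndarray                       # MAP / last warmup point
    draws: np.ndarray                      # (n_chains, n_draws, dim)
    method: str
    diagnostics: dict = field(default_factory=dict)

    @property
    def flat_draws(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])


def find_map(nlp, x0: np.ndarray, maxiter: int = 2000,
             restarts: int = 4) -> np.ndarray:
    """L-BFGS with restarts (hierarchical posteriors have nearly flat
    directions along which a single L-BFGS run stalls)."""
    x, f = x0, np.inf
    for _ in range(restarts):
        res = scipy.optimize.minimize(
            nlp, x, jac=True, method="L-BFGS-B",
            options={"maxiter": maxiter, "maxfun": 4 * maxiter, "ftol": 1e-12,
                     "gtol": 1e-8},
        )
        x = res.x
        if f - res.fun < 1e-6 * (abs(f) if np.isfinite(f) else 1.0):
            f = res.fun
            break
        f = res.fun
    return x


def _newton_polish(nlp, x: np.ndarray, H: np.ndarray,
                   max_steps: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """Newton steps with backtracking to finish off the flat directions.

    Returns the polished point and the Hessian at (or near) it.
    """
    f, g = nlp(x)
    for step_i in range(max_steps):
        delta = _Factor(H).solve(-g)
        decrement = float(-g @ delta)
        if decrement < 1e-9 * max(1.0, abs(f)):
            break
        t = 1.0
        for _ in range(30):
            f_new, g_new = nlp(x + t * delta)
            if np.isfinite(f_new) and f_new <= f - 1e-4 * t * decrement:
                break
            t *= 0.5
        else:
            break
        x, f, g = x + t * delta, f_new, g_new
        if step_i % 5 == 4:  # refresh curvature occasionally
            H = finite_diff_hessian(lambda z: nlp(z)[1], x)
    H = finite_diff_hessian(lambda z: nlp(z)[1], x)
    return x, H


def finite_diff_hessian(grad_fn, x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian of -log posterior from its gradient."""
    n = x.size
    H = np.empty((n, n))
    for i in range(n):
        h = eps * max(1.0, abs(x[i]))
        xp = x.copy(); xp[i] += h
        xm = x.copy(); xm[i] -= h
        H[:, i] = (grad_fn(xp) - grad_fn(xm)) / (2.0 * h)
    return 0.5 * (H + H.T)


class _Factor:
    """Positive-definite factorisation of H with solve and inverse-sampling.

    Falls back from Cholesky to an eigen decomposition with eigenvalues
    floored at ``floor``; proper priors give every direction curvature well
    above the floor, so flooring only repairs finite-difference noise.
    """

    def __init__(self, H: np.ndarray, floor: float = 1e-4):
        try:
            self.chol = np.linalg.cholesky(H)
            self.eig = None
        except np.linalg.LinAlgError:
            vals, vecs = np.linalg.eigh(H)
            self.chol = None
            self.eig = (np.maximum(vals, floor), vecs)

    def solve(self, b: np.ndarray) -> np.ndarray:
        if self.chol is not None:
            return scipy.linalg.cho_solve((self.chol, True), b)
        vals, vecs = self.eig
        return vecs @ ((vecs.T @ b) / vals)

    def sample(self, z: np.ndarray) -> np.ndarray:
        """Map iid standard normals (rows) to draws with covariance H^-1."""
        if self.chol is not None:
            return scipy.linalg.solve_triangular(
                self.chol, z.T, lower=True, trans="T").T
        vals, vecs = self.eig
        return (z / np.sqrt(vals)) @ vecs.T


def laplace(nlp, x0: np.ndarray, n_draws: int, rng: np.random.Generator,
            n_chains: int = 4, maxiter: int = 2000) -> InferenceResult:
    """MAP + Gaussian (Laplace) posterior approximation."""
    mode = find_map(nlp, x0, maxiter=maxiter)
    grad_fn = lambda x: nlp(x)[1]
    H = finite_diff_hessian(grad_fn, mode)
    mode, H = _newton_polish(nlp, mode, H)
    factor = _Factor(H)
    total = n_chains * n_draws
    z = rng.standard_normal((total, mode.size))
    draws = (mode + factor.sample(z)).reshape(n_chains, n_draws, mode.size)
    return InferenceResult(mode=mode, draws=draws, method="laplace",
                           diagnostics={"divergences": 0})


def hmc(nlp, x0: np.ndarray, n_draws: int, rng: np.random.Generator,
        n_chains: int = 4, warmup: int = 400, n_leapfrog: int = 16,
        target_accept: float = 0.8, init_jitter: float = 0.05,
        start_at_map: bool = True, maxiter: int = 2000) -> InferenceResult:
    """Adaptive Hamiltonian Monte Carlo on the unconstrained parameters."""
    start = find_map(nlp, x0, maxiter=maxiter) if start_at_map else x0
    dim = start.size
    all_draws = np.empty((n_chains, n_draws, dim))
    divergences = 0

    def logp_grad(x):
        f, g = nlp(x)
        return -f, -g

    for c in range(n_chains):
        x = start + rng.normal(0.0, init_jitter, dim)
        lp, grad = logp_grad(x)
        inv_mass = np.ones(dim)
        step = 0.1
        # dual averaging state
        mu_da, log_step_bar, h_bar = np.log(10 * step), 0.0, 0.0
        gamma_da, t0, kappa = 0.05, 10.0, 0.75
        window: list[np.ndarray] = []
        for it in range(warmup + n_draws):
            p = rng.standard_normal(dim) / np.sqrt(inv_mass)
            x_new, p_new, grad_new = x.copy(), p.copy(), grad.copy()
            logp_new = lp
            diverged = False
            # jittered path length decorrelates successive draws
            n_steps = int(rng.integers(max(1, n_leapfrog // 2),
                                       2 * n_leapfrog))
            p_new = p_new + 0.5 * step * grad_new
            for _ in range(n_steps):
                x_new = x_new + step * inv_mass * p_new
                logp_new, grad_new = logp_grad(x_new)
                if not np.isfinite(logp_new):
                    diverged = True
                    break
                p_new = p_new + step * grad_new
            p_new = p_new - 0.5 * step * grad_new
            if diverged:
                accept_prob = 0.0
            else:
                h0 = -lp + 0.5 * float(np.sum(inv_mass * p ** 2))
                h1 = -logp_new + 0.5 * float(np.sum(inv_mass * p_new ** 2))
                dh = h0 - h1
                if dh < -1000:
                    diverged = True
                accept_prob = float(min(1.0, np.exp(min(dh, 0.0))))
            if not diverged and rng.random() < accept_prob:
                x, lp, grad = x_new, logp_new, grad_new
            if it < warmup:
                # dual averaging of the step size
                m = it + 1
                h_bar = (1 - 1 / (m + t0)) * h_bar + \
                    (target_accept - accept_prob) / (m + t0)
                log_step = mu_da - np.sqrt(m) / gamma_da * h_bar
                w = m ** (-kappa)
                log_step_bar = w * log_step + (1 - w) * log_step_bar
                step = float(np.exp(log_step))
                if warmup // 2 <= it < warmup - 50:
                    window.append(x.copy())
                if it == warmup - 50 and len(window) > 10:
                    var = np.var(np.asarray(window), axis=0)
                    inv_mass = np.clip(var, 1e-6, None)
                if it == warmup - 1:
                    step = float(np.exp(log_step_bar))
            else:
                if diverged:
                    divergences += 1
                all_draws[c, it - warmup] = x
    return InferenceResult(mode=start, draws=all_draws, method="hmc",
                           diagnostics={"divergences": int(divergences)})
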
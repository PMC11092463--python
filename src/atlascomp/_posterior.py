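"""Joint log-posterior of the multilevel beta-binomial composition model.

Likelihood: each count y_{s,k} out of the sample total n_s follows a
beta-binomial with mean mu_{s,k} = softmax_k(eta_{s,.}) and precision
phi_{s,k} = exp(xv_s' (gamma0 + Gamma_k)), where

    eta_{s,k} = x_s' beta_k  +  sum_g z_s' u_{g(s),k}

combines population-level (fixed) coefficients with partially pooled
group-level (random) coefficients per grouping factor (tissue, dataset, ...).

Identifiability: every coefficient row is parametrised in an orthonormal
sum-to-zero basis across categories, so constraints hold exactly on every
draw. The category-wide baseline log-precision gamma0 is a separate scalar
per variability covariate (a fully centred precision row would pin the
geometric mean precision to one).

Priors: weak normal on fixed and variability coefficients; group-level
coefficients partially pooled through a non-centred parametrisation
u = sigma * u_raw with u_raw ~ N(0, 1) and lognormal priors on the scales
(the non-centred form keeps the joint mode away from the hierarchical
funnel spike at sigma = 0); a mean-variability association ties the
precision intercept row to the abundance intercept row through
Gamma_{0,k} ~ N(c0 + c1 beta_{0,k}, tau).

Everything here returns the log-density *and* its analytic gradient, which
is what makes MAP + Laplace and HMC affordable without an autodiff backend.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, gammaln

from .compositional import softmax, sum_to_zero_basis
from .design import Design


@dataclass
class PriorConfig:
    beta_sd: float = 2.0
    gamma_sd: float = 1.0
    gamma_base_mean: float = 3.0
    gamma_base_sd: float = 3.0
    # lognormal priors on all scale hyperparameters: a prior with positive
    # density at zero lets the MAP collapse into the hierarchical funnel
    # spike (e.g. when the true group-level variance is zero); the lognormal
    # keeps the mode interior while staying weak over plausible scales
    sigma_log_loc: float = float(np.log(0.3))
    sigma_log_sd: float = 0.8
    tau_log_loc: float = float(np.log(0.3))
    tau_log_sd: float = 0.5
    assoc_sd: float = 1.0         # prior sd of c0, c1
    use_association: bool = True


@dataclass
class ParameterLayout:
    """Flat-vector layout of all free parameters."""

    P: int                         # fixed covariates
    Pv: int                        # variability covariates
    K: int                         # categories
    groups: list[tuple[str, int, int]]   # (name, n_levels, n_terms)
    slices: dict[str, slice] = field(default_factory=dict)
    size: int = 0

    def __post_init__(self) -> None:
        kf = self.K - 1
        pos = 0

        def add(name: str, n: int) -> None:
            nonlocal pos
            self.slices[name] = slice(pos, pos + n)
            pos += n

        add("beta", self.P * kf)
        for name, L, T in self.groups:
            add(f"u:{name}", L * T * kf)
        add("gamma", self.Pv * kf)
        add("gamma_base", self.Pv)
        for name, L, T in self.groups:
            add(f"log_sigma:{name}", T)
        add("assoc", 3)            # c0, c1, log_tau
        self.size = pos

    @classmethod
    def for_design(cls, design: Design, K: int) -> "ParameterLayout":
        return cls(
            P=design.X.shape[1], Pv=design.Xv.shape[1], K=K,
            groups=[(g.name, g.n_levels, g.n_terms)
                    for g in design.groups.values()],
        )

    # -- views ------------------------------------------------------------
    def beta_free(self, x: np.ndarray) -> np.ndarray:
        return x[..., self.slices["beta"]].reshape(*x.shape[:-1], self.P, self.K - 1)

    def u_free(self, x: np.ndarray, name: str) -> np.ndarray:
        L, T = next((L, T) for n, L, T in self.groups if n == name)
        return x[..., self.slices[f"u:{name}"]].reshape(*x.shape[:-1], L, T, self.K - 1)

    def gamma_free(self, x: np.ndarray) -> np.ndarray:
        return x[..., self.slices["gamma"]].reshape(*x.shape[:-1], self.Pv, self.K - 1)

    def gamma_base(self, x: np.ndarray) -> np.ndarray:
        return x[..., self.slices["gamma_base"]]

    def log_sigma(self, x: np.ndarray, name: str) -> np.ndarray:
        return x[..., self.slices[f"log_sigma:{name}"]]

    def assoc(self, x: np.ndarray) -> np.ndarray:
        return x[..., self.slices["assoc"]]


class CompositionPosterior:
    """Log posterior and gradient for given counts, design and priors."""

    def __init__(self, counts: np.ndarray, design: Design,
                 priors: PriorConfig | None = None,
                 mask: np.ndarray | None = None):
        counts = np.asarray(counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a samples x categories matrix")
        if np.any(counts < 0) or not np.allclose(counts, np.rint(counts)):
            raise ValueError("counts must be non-negative integers")
        self.y = counts.astype(float)
        self.n = self.y.sum(axis=1)
        self.S, self.K = counts.shape
        if self.K < 2:
            raise ValueError("need at least 2 categories")
        self.design = design
        self.priors = priors or PriorConfig()
        self.mask = (np.ones_like(self.y, dtype=bool)
                     if mask is None else np.asarray(mask, dtype=bool))
        self.Q = sum_to_zero_basis(self.K)
        self.layout = ParameterLayout.for_design(design, self.K)
        # association needs intercept as the first fixed and variability column
        self.has_assoc = (
            self.priors.use_association
            and design.x_names[:1] == ["intercept"]
            and design.xv_names[:1] == ["intercept"]
        )

    # ------------------------------------------------------------------
    def initial_point(self, rng: np.random.Generator | None = None,
                      jitter: float = 0.0) -> np.ndarray:
        x = np.zeros(self.layout.size)
        lo = self.layout
        x[lo.slices["gamma_base"]] = self.priors.gamma_base_mean
        for name, L, T in lo.groups:
            x[lo.slices[f"log_sigma:{name}"]] = np.log(0.5)
        x[lo.slices["assoc"]][2] = np.log(0.25)
        if jitter and rng is not None:
            x = x + rng.normal(0.0, jitter, x.shape)
        return x

    # ------------------------------------------------------------------
    def group_coefficients(self, x: np.ndarray, name: str) -> np.ndarray:
        """Constrained group-level coefficients u = sigma * u_raw, (L, T, K)."""
        sig = np.exp(self.layout.log_sigma(x, name))
        return (self.layout.u_free(x, name) @ self.Q.T) * sig[:, None]

    def linear_predictors(self, x: np.ndarray):
        """eta (S,K) and log_phi (S,K) for one flat parameter vector."""
        lo, Q, d = self.layout, self.Q, self.design
        B = lo.beta_free(x) @ Q.T
        eta = d.X @ B
        for g in d.groups.values():
            U = self.group_coefficients(x, g.name)   # (L, T, K)
            eta += np.einsum("nt,ntk->nk", g.slopes, U[g.index])
        Gc = lo.gamma_free(x) @ Q.T
        g0 = lo.gamma_base(x)
        log_phi = d.Xv @ (g0[:, None] + Gc)
        return eta, log_phi

    # ------------------------------------------------------------------
    def log_posterior(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        lo, Q, d, pr = self.layout, self.Q, self.design, self.priors
        grad = np.zeros_like(x)

        eta, log_phi = self.linear_predictors(x)
        if not (np.all(np.isfinite(eta)) and np.all(np.isfinite(log_phi))):
            return -np.inf, grad
        if np.any(np.abs(log_phi) > 50.0):   # overflow guard; priors keep
            return -np.inf, grad             # log-precision far inside this
        phi = np.exp(log_phi)
        mu = softmax(eta, axis=1)
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        a = mu * phi
        b = (1.0 - mu) * phi
        y, n = self.y, self.n[:, None]

        ll_terms = (gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
                    + gammaln(y + a) + gammaln(n - y + b) - gammaln(n + phi)
                    + gammaln(phi) - gammaln(a) - gammaln(b))
        ll = float(ll_terms[self.mask].sum())
        if not np.isfinite(ll):
            return -np.inf, grad

        ga = digamma(y + a) - digamma(n + phi) + digamma(phi) - digamma(a)
        gb = digamma(n - y + b) - digamma(n + phi) + digamma(phi) - digamma(b)
        ga = np.where(self.mask, ga, 0.0)
        gb = np.where(self.mask, gb, 0.0)
        dmu = phi * (ga - gb)
        dlogphi = (mu * ga + (1.0 - mu) * gb) * phi
        deta = mu * (dmu - (mu * dmu).sum(axis=1, keepdims=True))

        # abundance coefficients
        grad[lo.slices["beta"]] = ((d.X.T @ deta) @ Q).ravel()
        for g in d.groups.values():
            W = g.slopes[:, :, None] * deta[:, None, :]     # (S, T, K)
            gU = np.zeros((g.n_levels, g.n_terms, self.K))  # wrt constrained u
            np.add.at(gU, g.index, W)
            sig_g = np.exp(lo.log_sigma(x, g.name))
            grad[lo.slices[f"u:{g.name}"]] = \
                ((gU @ Q) * sig_g[:, None]).ravel()
            U_con = self.group_coefficients(x, g.name)
            grad[lo.slices[f"log_sigma:{g.name}"]] = \
                (gU * U_con).sum(axis=(0, 2))
        # variability coefficients
        gGc = d.Xv.T @ dlogphi
        grad[lo.slices["gamma"]] = (gGc @ Q).ravel()
        grad[lo.slices["gamma_base"]] = gGc.sum(axis=1)

        # ---------------- priors -----------------------------------------
        lp = ll
        Bf = lo.beta_free(x)
        lp += float(-0.5 * (Bf ** 2).sum() / pr.beta_sd ** 2)
        grad[lo.slices["beta"]] += (-Bf / pr.beta_sd ** 2).ravel()

        for name, L, T in lo.groups:
            Uf = lo.u_free(x, name)                  # raw (L, T, K-1)
            lam = lo.log_sigma(x, name)              # (T,)
            # standard normal on the raw coefficients
            lp += float(-0.5 * (Uf ** 2).sum())
            grad[lo.slices[f"u:{name}"]] += -Uf.ravel()
            # lognormal hyperprior on sigma (normal in log sigma)
            lp += float((-0.5 * (lam - pr.sigma_log_loc) ** 2
                         / pr.sigma_log_sd ** 2).sum())
            grad[lo.slices[f"log_sigma:{name}"]] += \
                -(lam - pr.sigma_log_loc) / pr.sigma_log_sd ** 2

        Gf = lo.gamma_free(x)
        g0 = lo.gamma_base(x)
        c0, c1, log_tau = lo.assoc(x)
        tau = np.exp(log_tau)
        gamma_rows_free = np.ones(self.layout.Pv, dtype=bool)
        if self.has_assoc:
            gamma_rows_free[0] = False
            Gc0 = Gf[0] @ Q.T                        # constrained row (K,)
            B0 = Bf[0] @ Q.T
            res = Gc0 - c0 - c1 * B0
            lp += float(-0.5 * (res ** 2).sum() / tau ** 2 - self.K * log_tau)
            r = res / tau ** 2
            grad[lo.slices["gamma"]][: self.K - 1] += -(r @ Q)
            grad[lo.slices["beta"]][: self.K - 1] += c1 * (r @ Q)
            ga_ = np.zeros(3)
            ga_[0] = r.sum()
            ga_[1] = float((r * B0).sum())
            ga_[2] = float((res ** 2).sum() / tau ** 2 - self.K)
            # lognormal on tau (normal in log_tau), normal on c0, c1
            lp += float(-0.5 * (log_tau - pr.tau_log_loc) ** 2 / pr.tau_log_sd ** 2)
            ga_[2] += -(log_tau - pr.tau_log_loc) / pr.tau_log_sd ** 2
            lp += float(-0.5 * (c0 ** 2 + c1 ** 2) / pr.assoc_sd ** 2)
            ga_[0] += -c0 / pr.assoc_sd ** 2
            ga_[1] += -c1 / pr.assoc_sd ** 2
            grad[lo.slices["assoc"]] += ga_
        else:
            # keep the unused association block proper
            lp += float(-0.5 * (c0 ** 2 + c1 ** 2) - 0.5 * log_tau ** 2)
            grad[lo.slices["assoc"]] += np.array([-c0, -c1, -log_tau])
        free = lo.gamma_free(x)[gamma_rows_free]
        lp += float(-0.5 * (free ** 2).sum() / pr.gamma_sd ** 2)
        gfull = np.zeros_like(Gf)
        gfull[gamma_rows_free] = -Gf[gamma_rows_free] / pr.gamma_sd ** 2
        grad[lo.slices["gamma"]] += gfull.ravel()

        is_int = np.array([nm == "intercept" for nm in self.design.xv_names])
        mean0 = np.where(is_int, pr.gamma_base_mean, 0.0)
        sd0 = np.where(is_int, pr.gamma_base_sd, 1.0)
        lp += float((-0.5 * (g0 - mean0) ** 2 / sd0 ** 2).sum())
        grad[lo.slices["gamma_base"]] += -(g0 - mean0) / sd0 ** 2

        return lp, grad

    def neg_log_posterior(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        lp, g = self.log_posterior(x)
        return -lp, -g
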
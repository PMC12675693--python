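"""Competing mean models, likelihood and priors for episode-centered data.

Three mean functions compete for each state variable and direction:

* decay (post-episode):  w(t) = a * exp(-|b| t) + c,  t >= 0 hours
* growth (pre-episode):  w(t) = a * exp(b t) + c,     t <= 0 hours, b > 0
* null (no change):      w(t) = d

with Gaussian residual noise and a per-participant random intercept on
the baseline (c_j = c + u_j, d_j = d + u_j, u_j ~ Normal(0, tau^2)).

Priors: uniform boxes a in (-10, 10), b in (-10, 0) for decay and
(0, 10) for growth, c in (0, 10); |b| = 10 corresponds to a half-life of
ln2/10 h (about four minutes), so the box spans half-lives from roughly
five minutes to infinity. The null grand mean d gets a Normal prior with
mean and variance taken from the variable's empirical distribution.
sigma ~ half-Normal(0, 5), tau ~ half-Normal(0, 2).

Internally both exponential forms share the parameterisation
``a * exp(b t) + c`` with the sign of b enforced by its box; reports
expose |b| as the rate and ln2/|b| as the half-life.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

_LOG_2PI = float(np.log(2.0 * np.pi))

A_BOUNDS = (-10.0, 10.0)
B_BOUNDS_DECAY = (-10.0, 0.0)
B_BOUNDS_GROWTH = (0.0, 10.0)
C_BOUNDS = (0.0, 10.0)


def mean_decay(t, a: float, b: float, c: float):
    """Post-episode spike-and-decay mean: a * exp(-|b| t) + c for t >= 0."""
    return a * np.exp(-np.abs(b) * np.asarray(t, dtype=float)) + c


def mean_growth(t, a: float, b: float, c: float):
    """Pre-episode growth mean: a * exp(|b| t) + c for t <= 0.

    Mirror image of :func:`mean_decay` about t = 0:
    ``mean_growth(-t, a, b, c) == mean_decay(t, a, -b, c)``.
    """
    return a * np.exp(np.abs(b) * np.asarray(t, dtype=float)) + c


def half_life(b: float) -> float:
    """Half-life ln2/|b| in hours of a rate constant b (per hour)."""
    return float(np.log(2.0) / np.abs(b))


@dataclass
class OpponentProcessParams:
    """Parameters of one exponential fit (decay or growth)."""

    a: float
    b: float  # signed: negative for decay, positive for growth
    c: float
    sigma: float
    u: dict[str, float] = field(default_factory=dict)  # participant offsets
    tau: float = 0.0


@dataclass
class NullParams:
    """Parameters of the no-change null model."""

    d: float
    sigma: float
    u: dict[str, float] = field(default_factory=dict)
    tau: float = 0.0


@dataclass
class ModelSpec:
    """One of the three model forms together with its prior definition.

    ``hierarchical=False`` removes the random intercepts (and tau);
    ``fixed_sigma`` pins the residual SD, removing it from the free
    parameters. ``d_mean``/``d_sd`` define the null model's empirical
    Normal prior and are normally set via :meth:`null_from_data`.
    """

    form: str  # "decay" | "growth" | "null"
    hierarchical: bool = True
    a_bounds: tuple[float, float] = A_BOUNDS
    c_bounds: tuple[float, float] = C_BOUNDS
    sigma_scale: float = 5.0  # half-Normal prior scale for sigma
    tau_scale: float = 2.0  # half-Normal prior scale for tau
    fixed_sigma: float | None = None
    fixed_tau: float | None = None
    d_mean: float | None = None
    d_sd: float | None = None
    b_bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.form not in ("decay", "growth", "null"):
            raise ValueError(f"unknown model form {self.form!r}")
        if self.b_bounds is None:
            self.b_bounds = (B_BOUNDS_DECAY if self.form == "decay"
                             else B_BOUNDS_GROWTH if self.form == "growth"
                             else (0.0, 0.0))
        if self.form == "decay" and self.b_bounds[1] > 0:
            raise ValueError("decay model requires b <= 0")
        if self.form == "growth" and self.b_bounds[0] < 0:
            raise ValueError("growth model requires b >= 0")
        if self.form == "null" and (self.d_mean is None or self.d_sd is None):
            raise ValueError(
                "null spec needs d_mean/d_sd (use ModelSpec.null_from_data)")

    @classmethod
    def null_from_data(cls, values, **kwargs) -> "ModelSpec":
        """Null spec with d ~ Normal(empirical mean, empirical variance)."""
        v = np.asarray(values, dtype=float)
        return cls(form="null", d_mean=float(v.mean()),
                   d_sd=float(v.std(ddof=1)), **kwargs)


class ModelDensity:
    """Vectorised log prior/likelihood/posterior over a parameter vector.

    Layout: [a, b, c] (exponential) or [d] (null), then sigma (unless
    fixed), then tau and one offset u_j per participant (hierarchical
    only). Accepts a (n_points, ndim) array and returns (n_points,)
    densities, which is what an ensemble sampler's vectorised interface
    and the quadrature/bridge evidence routines consume.
    """

    def __init__(self, spec: ModelSpec, rel_time, value, participant_id,
                 marginalize: bool = True):
        self.spec = spec
        self.t = np.asarray(rel_time, dtype=float)
        self.y = np.asarray(value, dtype=float)
        if self.t.size == 0:
            raise ValueError("data must be non-empty")
        pids = pd.Series(participant_id)
        self.participants = sorted(pids.unique())
        self.pidx = pids.map(
            {p: i for i, p in enumerate(self.participants)}).to_numpy()
        self.n_participants = len(self.participants)
        if spec.hierarchical and self.n_participants < 2:
            raise ValueError("hierarchical fits need >= 2 participants")
        # integrate the Gaussian random intercepts in closed form; the
        # joint (c, u_1..u_J) block mixes poorly under ensemble moves
        self.marginalized = bool(marginalize and spec.hierarchical)
        self._nj = np.bincount(self.pidx, minlength=self.n_participants) \
            .astype(float)
        # one-hot indicator for per-participant residual sums
        self._ind = np.zeros((self.t.size, self.n_participants))
        self._ind[np.arange(self.t.size), self.pidx] = 1.0

        names = ["a", "b", "c"] if spec.form != "null" else ["d"]
        if spec.fixed_sigma is None:
            names.append("sigma")
        if spec.hierarchical:
            names.append("tau")
            if not self.marginalized:
                names += [f"u[{p}]" for p in self.participants]
        self.names = names
        self.ndim = len(names)
        self._sigma_idx = names.index("sigma") if "sigma" in names else None
        self._tau_idx = names.index("tau") if "tau" in names else None
        self._u_start = (self._tau_idx + 1
                         if spec.hierarchical and not self.marginalized
                         else None)

    # -- components ----------------------------------------------------

    def _unpack(self, theta: np.ndarray):
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        s = self.spec
        sigma = (theta[:, self._sigma_idx] if self._sigma_idx is not None
                 else np.full(theta.shape[0], s.fixed_sigma))
        if s.hierarchical:
            tau = theta[:, self._tau_idx]
            if self.marginalized:
                u = np.zeros((theta.shape[0], self.n_participants))
            else:
                u = theta[:, self._u_start:]
        else:
            tau = np.zeros(theta.shape[0])
            u = np.zeros((theta.shape[0], self.n_participants))
        return theta, sigma, tau, u

    def _mean(self, theta: np.ndarray, u: np.ndarray) -> np.ndarray:
        if self.spec.form == "null":
            base = theta[:, [0]]
        else:
            a, b, c = theta[:, [0]], theta[:, [1]], theta[:, [2]]
            base = a * np.exp(b * self.t[None, :]) + c
        return base + u[:, self.pidx]

    def log_prior(self, theta: np.ndarray) -> np.ndarray:
        theta, sigma, tau, u = self._unpack(theta)
        s = self.spec
        lp = np.zeros(theta.shape[0])
        ok = np.ones(theta.shape[0], dtype=bool)

        if s.form == "null":
            lp += stats.norm.logpdf(theta[:, 0], loc=s.d_mean, scale=s.d_sd)
        else:
            for j, (lo, hi) in enumerate(
                    (s.a_bounds, s.b_bounds, s.c_bounds)):
                ok &= (theta[:, j] > lo) & (theta[:, j] < hi)
                lp -= np.log(hi - lo)

        if self._sigma_idx is not None:
            ok &= sigma > 0
            safe = np.where(sigma > 0, sigma, 1.0)
            # half-Normal(0, sigma_scale)
            lp += (0.5 * np.log(2.0 / np.pi) - np.log(s.sigma_scale)
                   - 0.5 * (safe / s.sigma_scale) ** 2)
        if s.hierarchical:
            ok &= tau > 0
            safe_tau = np.where(tau > 0, tau, 1.0)
            lp += (0.5 * np.log(2.0 / np.pi) - np.log(s.tau_scale)
                   - 0.5 * (safe_tau / s.tau_scale) ** 2)
            if not self.marginalized:
                lp += np.sum(
                    -0.5 * _LOG_2PI - np.log(safe_tau)[:, None]
                    - 0.5 * (u / safe_tau[:, None]) ** 2,
                    axis=1,
                )
        return np.where(ok, lp, -np.inf)

    def log_likelihood(self, theta: np.ndarray) -> np.ndarray:
        """Gaussian log-likelihood; marginal over u_j when marginalized.

        The marginal per-participant covariance sigma^2 I + tau^2 11'
        is inverted with the Sherman-Morrison identity, so the cost
        stays linear in the number of observations.
        """
        theta, sigma, tau, u = self._unpack(theta)
        safe = np.where(sigma > 0, sigma, 1.0)
        resid = self.y[None, :] - self._mean(theta, u)
        if self.marginalized:
            s2 = safe**2
            t2 = np.where(tau > 0, tau, 0.0) ** 2
            rss = np.sum(resid**2, axis=1)
            sums = resid @ self._ind  # per-participant residual sums
            denom = s2[:, None] + self._nj[None, :] * t2[:, None]
            quad = (rss - np.sum(t2[:, None] * sums**2 / denom, axis=1)) / s2
            logdet = (self.t.size * np.log(s2)
                      + np.sum(np.log1p(self._nj[None, :] * t2[:, None]
                                        / s2[:, None]), axis=1))
            ll = -0.5 * (self.t.size * _LOG_2PI + logdet + quad)
        else:
            ll = np.sum(
                -0.5 * _LOG_2PI - np.log(safe)[:, None]
                - 0.5 * (resid / safe[:, None]) ** 2,
                axis=1,
            )
        return np.where(sigma > 0, ll, -np.inf)

    def conditional_intercepts(
        self, theta: np.ndarray, rng: np.random.Generator
    ) -> np.ndarray:
        """Draw u_j from their exact Gaussian conditional per theta row.

        u_j | theta, y ~ Normal(tau^2 S_j / (sigma^2 + n_j tau^2),
        tau^2 sigma^2 / (sigma^2 + n_j tau^2)) with S_j the sum of
        participant j's residuals about the population mean curve.
        """
        if not self.marginalized:
            raise ValueError("intercepts are sampled directly in this layout")
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        out = np.empty((theta.shape[0], self.n_participants))
        # chunked: the residual matrix is n_draws x n_obs
        step = max(1, 20_000_000 // max(self.t.size, 1))
        for start in range(0, theta.shape[0], step):
            block, sigma, tau, _ = self._unpack(theta[start:start + step])
            u0 = np.zeros((block.shape[0], self.n_participants))
            resid = self.y[None, :] - self._mean(block, u0)
            sums = resid @ self._ind
            s2, t2 = sigma**2, tau**2
            denom = s2[:, None] + self._nj[None, :] * t2[:, None]
            mean = t2[:, None] * sums / denom
            var = t2[:, None] * s2[:, None] / denom
            out[start:start + step] = mean + np.sqrt(var) * \
                rng.standard_normal(mean.shape)
        return out

    def log_posterior(self, theta: np.ndarray) -> np.ndarray:
        lp = self.log_prior(theta)
        out = np.full(lp.shape, -np.inf)
        finite = np.isfinite(lp)
        if finite.any():
            theta2 = np.atleast_2d(np.asarray(theta, dtype=float))
            out[finite] = lp[finite] + self.log_likelihood(theta2[finite])
        return out

    def sample_prior(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Independent draws from the joint prior (used as IS defense)."""
        s = self.spec
        cols = []
        if s.form == "null":
            cols.append(rng.normal(s.d_mean, s.d_sd, n))
        else:
            for lo, hi in (s.a_bounds, s.b_bounds, s.c_bounds):
                cols.append(rng.uniform(lo, hi, n))
        if self._sigma_idx is not None:
            cols.append(np.abs(rng.normal(0.0, s.sigma_scale, n)))
        if s.hierarchical:
            tau = np.abs(rng.normal(0.0, s.tau_scale, n))
            cols.append(tau)
            if not self.marginalized:
                for _ in range(self.n_participants):
                    cols.append(rng.normal(0.0, tau))
        return np.column_stack(cols)

    # -- bounds helpers (used by the sampler/quadrature) ---------------

    def support_bounds(self) -> list[tuple[float, float]]:
        """Finite parameter ranges for initialisation and quadrature."""
        s = self.spec
        bounds: list[tuple[float, float]] = []
        if s.form == "null":
            bounds.append((s.d_mean - 8 * s.d_sd, s.d_mean + 8 * s.d_sd))
        else:
            bounds += [s.a_bounds, s.b_bounds, s.c_bounds]
        if self._sigma_idx is not None:
            bounds.append((1e-6, 6.0 * s.sigma_scale))
        if s.hierarchical:
            bounds.append((1e-6, 6.0 * s.tau_scale))
            if not self.marginalized:
                bounds += [(-20.0, 20.0)] * self.n_participants
        return bounds


# ---------------------------------------------------------------------
# Spec-level convenience wrappers over dataclass parameters
# ---------------------------------------------------------------------

def _params_vector(params, density: ModelDensity) -> np.ndarray:
    theta = []
    if isinstance(params, NullParams):
        theta.append(params.d)
    else:
        theta += [params.a, params.b, params.c]
    if density._sigma_idx is not None:
        theta.append(params.sigma)
    if density.spec.hierarchical:
        theta.append(params.tau)
        theta += [params.u.get(p, 0.0) for p in density.participants]
    return np.asarray(theta, dtype=float)


def log_likelihood(params, spec: ModelSpec, aligned: pd.DataFrame) -> float:
    """Gaussian log-likelihood of aligned data under the given parameters.

    Sums ``Normal(value | mean(rel_time) + u_participant, sigma)`` log
    densities over all rows (conditional on the explicit participant
    offsets in ``params``). Returns -inf when parameters fall outside
    the model's support.
    """
    density = ModelDensity(spec, aligned["rel_time"], aligned["value"],
                           aligned["participant_id"], marginalize=False)
    theta = _params_vector(params, density)
    lp = density.log_prior(theta[None, :])
    if not np.isfinite(lp[0]):
        return -np.inf
    return float(density.log_likelihood(theta[None, :])[0])


def log_prior(params, spec: ModelSpec, aligned: pd.DataFrame) -> float:
    """Joint log prior density of the given parameters under ``spec``."""
    density = ModelDensity(spec, aligned["rel_time"], aligned["value"],
                           aligned["participant_id"], marginalize=False)
    theta = _params_vector(params, density)
    return float(density.log_prior(theta[None, :])[0])
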
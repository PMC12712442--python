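"""Bayesian mixed-effects quantile regression with an optional phylogenetic
random effect.

The model for species i in functional group g(i) is

    y_i = alpha_g(i) + beta_g(i) * x_i + u_i + eps_i,
    eps_i ~ AsymmetricLaplace(0, sigma, tau),
    u ~ MVN(0, sigma_p^2 * C_std)          (phylogenetic variant only),

where C_std is the Brownian covariance matrix scaled to unit maximum
diagonal, so sigma_p is in response units.  The asymmetric Laplace (AL)
likelihood makes the fitted line the conditional tau-quantile of y given x.

Sampling uses the normal-exponential mixture representation of the AL
(eps = sigma * (theta*w + psi*sqrt(w)*z), w ~ Exp(1)), which gives conjugate
Gaussian updates for coefficients and random effects, generalized-inverse-
Gaussian updates for the mixture weights, and Metropolis-within-Gibbs
updates on log(sigma) and log(sigma_p); the sigma and sigma_p moves are
partially collapsed (w, respectively u, marginalized out and redrawn
immediately), which keeps the chain valid and mixes well.

Inference on slopes follows the HDI + ROPE decision rule: a slope is
"practically nonzero" when its 95% highest-density interval falls entirely
outside the region of practical equivalence [-0.1*SD(y), +0.1*SD(y)].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy import stats

from .trees import PhyloCovariance

__all__ = [
    "QRData", "QRSpec", "QRPosterior", "RopeResult",
    "check_loss", "al_logpdf", "al_rvs",
    "log_posterior", "fit_qr_mcmc",
    "hdi", "rope_decision", "rhat_ess", "group_line_fit",
]


# ---------------------------------------------------------------------------
# asymmetric Laplace primitives

def check_loss(u, tau: float):
    """Quantile check loss rho_tau(u) = u * (tau - 1[u < 0])."""
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must be in (0, 1)")
    u = np.asarray(u, dtype=float)
    out = u * (tau - (u < 0))
    return float(out) if out.ndim == 0 else out


def al_logpdf(y, mu, sigma: float, tau: float):
    """Log density of the asymmetric Laplace AL(mu, sigma, tau)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    y = np.asarray(y, dtype=float)
    out = np.log(tau * (1.0 - tau) / sigma) - check_loss((y - mu) / sigma, tau)
    return float(out) if out.ndim == 0 else out


def al_rvs(rng: np.random.Generator, size, sigma: float, tau: float):
    """Exact AL(0, sigma, tau) draws by inverse-CDF; P(draw < 0) = tau."""
    u = rng.uniform(size=size)
    neg = u < tau
    out = np.where(neg,
                   sigma / (1.0 - tau) * np.log(np.maximum(u, 1e-300) / tau),
                   -sigma / tau * np.log(np.maximum(1.0 - u, 1e-300) / (1.0 - tau)))
    return out


# ---------------------------------------------------------------------------
# data / model containers

GROUP_LEVELS = ("deciduous_angiosperm", "evergreen_angiosperm", "gymnosperm")


@dataclass
class QRData:
    """Aligned response/predictor/group vectors, with optional covariance."""

    y: np.ndarray
    x: np.ndarray
    group: np.ndarray
    C: PhyloCovariance | None = None
    species: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.group = np.asarray(self.group)
        n = self.y.shape[0]
        if self.x.shape[0] != n or self.group.shape[0] != n:
            raise ValueError("y, x and group must have equal length")
        if np.isnan(self.y).any() or np.isnan(self.x).any():
            raise ValueError("missing values are not allowed")
        if self.C is not None:
            if self.species is None:
                raise ValueError("species order required with a covariance")
            if tuple(self.species) != tuple(self.C.species):
                self.C = self.C.align(list(self.species))

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def groups(self) -> tuple[str, ...]:
        # observed levels only, in canonical order then alphabetical extras
        seen = set(self.group.tolist())
        ordered = [g for g in GROUP_LEVELS if g in seen]
        ordered += sorted(seen - set(GROUP_LEVELS))
        return tuple(ordered)


@dataclass(frozen=True)
class QRSpec:
    """Model/sampler configuration (defaults follow the study design)."""

    tau: float = 0.5
    phylo: bool = False
    chains: int = 4
    iterations: int = 10_000
    warmup: int = 2_000
    seed: int = 0
    # prior scales as multiples of SD(y) (slopes additionally / SD(x))
    coef_scale_mult: float = 10.0
    sigma_scale_mult: float = 2.5
    sigma_df: float = 3.0
    sigma_p_scale_mult: float = 1.0
    diagnostics: bool = True  # compute Rhat/ESS after sampling

    def __post_init__(self) -> None:
        if not 0.0 < self.tau < 1.0:
            raise ValueError("tau must be in (0, 1)")
        if self.warmup >= self.iterations:
            raise ValueError("warmup must be smaller than iterations")


@dataclass(frozen=True)
class RopeResult:
    parameter: str
    hdi_lo: float
    hdi_hi: float
    rope_lo: float
    rope_hi: float
    verdict: str  # outside_rope | inside_rope | overlapping


@dataclass
class QRPosterior:
    """Posterior draws (per chain) and convergence diagnostics."""

    tau: float
    phylo: bool
    groups: tuple[str, ...]
    draws: dict[str, np.ndarray]            # name -> (chains, kept)
    u_mean: np.ndarray | None               # posterior mean phylo effects
    diagnostics: pd.DataFrame
    spec: QRSpec

    def stacked(self, name: str) -> np.ndarray:
        return self.draws[name].reshape(-1)

    def beta(self, group: str) -> np.ndarray:
        return self.stacked(f"beta[{group}]")

    def alpha(self, group: str) -> np.ndarray:
        return self.stacked(f"alpha[{group}]")

    def fitted_quantile(self, data: QRData) -> np.ndarray:
        """Posterior-mean tau-quantile line, phylo effect included."""
        gi = {g: i for i, g in enumerate(self.groups)}
        a = np.array([self.alpha(g).mean() for g in self.groups])
        b = np.array([self.beta(g).mean() for g in self.groups])
        idx = np.array([gi[g] for g in data.group])
        mu = a[idx] + b[idx] * data.x
        if self.phylo and self.u_mean is not None:
            mu = mu + self.u_mean
        return mu


# ---------------------------------------------------------------------------
# priors and joint density

def _prior_scales(y: np.ndarray, x: np.ndarray, spec: QRSpec) -> dict:
    sdy = float(np.std(y, ddof=1))
    sdx = float(np.std(x, ddof=1))
    if sdy == 0:
        raise ValueError("response is constant")
    sdx = sdx if sdx > 0 else 1.0
    return {
        "alpha": spec.coef_scale_mult * sdy,
        "beta": spec.coef_scale_mult * sdy / sdx,
        "sigma": spec.sigma_scale_mult * sdy,
        "sigma_p": spec.sigma_p_scale_mult * sdy,
    }


def _log_prior(alpha, beta, sigma, sigma_p, scales, spec: QRSpec,
               phylo: bool) -> float:
    lp = float(np.sum(stats.norm.logpdf(alpha, 0.0, scales["alpha"])))
    lp += float(np.sum(stats.norm.logpdf(beta, 0.0, scales["beta"])))
    # half-Student-t(df, 0, s) on sigma
    lp += float(stats.t.logpdf(sigma / scales["sigma"], df=spec.sigma_df)
                + np.log(2.0) - np.log(scales["sigma"]))
    if phylo:
        lp += float(stats.halfnorm.logpdf(sigma_p, scale=scales["sigma_p"]))
    return lp


def log_posterior(params: dict, data: QRData, spec: QRSpec) -> float:
    """Joint log posterior density (up to the evidence constant).

    ``params`` holds per-group arrays ``alpha`` and ``beta`` (ordered as
    ``data.groups``), scalars ``sigma`` and, for the phylogenetic variant,
    ``sigma_p`` plus the per-species effects ``u``.  Non-finite evaluations
    return -inf (a rejected state) rather than raising.
    """
    groups = data.groups
    alpha = np.asarray(params["alpha"], dtype=float)
    beta = np.asarray(params["beta"], dtype=float)
    sigma = float(params["sigma"])
    if sigma <= 0 or alpha.shape[0] != len(groups) or beta.shape[0] != len(groups):
        return -np.inf
    gi = {g: i for i, g in enumerate(groups)}
    idx = np.array([gi[g] for g in data.group])
    mu = alpha[idx] + beta[idx] * data.x
    sigma_p = float(params.get("sigma_p", 0.0))
    u = params.get("u")
    if spec.phylo:
        if data.C is None:
            raise ValueError("phylo model requires a covariance in QRData")
        if sigma_p < 0:
            return -np.inf
        u = np.zeros(data.n) if u is None else np.asarray(u, dtype=float)
        mu = mu + u
    try:
        ll = float(np.sum(al_logpdf(data.y, mu, sigma, spec.tau)))
        if spec.phylo:
            Cs = data.C.standardized().matrix
            if sigma_p == 0.0:
                if np.any(u != 0.0):
                    return -np.inf
            else:
                ll += float(stats.multivariate_normal.logpdf(
                    u, mean=np.zeros(data.n), cov=sigma_p ** 2 * Cs,
                    allow_singular=True))
        scales = _prior_scales(data.y, data.x, spec)
        ll += _log_prior(alpha, beta, sigma, sigma_p, scales, spec, spec.phylo)
    except (ValueError, np.linalg.LinAlgError):
        return -np.inf
    return ll if np.isfinite(ll) else -np.inf


# ---------------------------------------------------------------------------
# Gibbs sampler

def _gig_half_rvs(rng: np.random.Generator, chi: np.ndarray, psi0: float):
    """Draws from GIG(1/2, chi, psi0) via the reciprocal inverse-Gaussian."""
    chi = np.maximum(chi, 1e-12)
    mu = np.sqrt(psi0 / chi)
    y = rng.wald(mu, psi0)
    return 1.0 / np.maximum(y, 1e-300)


def _run_chain(data: QRData, spec: QRSpec, scales: dict, rng: np.random.Generator):
    n = data.n
    groups = data.groups
    G = len(groups)
    gi = {g: i for i, g in enumerate(groups)}
    idx = np.array([gi[g] for g in data.group])
    Z = np.zeros((n, 2 * G))
    Z[np.arange(n), idx] = 1.0
    Z[np.arange(n), G + idx] = data.x
    prior_prec = np.concatenate([
        np.full(G, scales["alpha"] ** -2), np.full(G, scales["beta"] ** -2)])

    tau = spec.tau
    theta = (1.0 - 2.0 * tau) / (tau * (1.0 - tau))
    psi2 = 2.0 / (tau * (1.0 - tau))
    psi0 = 2.0 + theta ** 2 / psi2

    phylo = spec.phylo
    if phylo:
        Cs = data.C.standardized().matrix
        Cs_chol = sla.cho_factor(Cs + 1e-10 * np.eye(n), lower=True)
        Cinv = sla.cho_solve(Cs_chol, np.eye(n))
        logdet_Cs = 2.0 * float(np.sum(np.log(np.diag(Cs_chol[0]))))

    # initialization
    b, *_ = np.linalg.lstsq(Z, data.y, rcond=None)
    resid0 = data.y - Z @ b
    sigma = max(float(np.median(np.abs(resid0 - np.median(resid0)))),
                0.05 * float(np.std(data.y, ddof=1)))
    u = np.zeros(n)
    sigma_p = 0.5 * float(np.std(data.y, ddof=1)) if phylo else 0.0
    w = np.ones(n)
    step_s, step_p = 0.5, 0.5

    n_keep = spec.iterations - spec.warmup
    out_b = np.empty((n_keep, 2 * G))
    out_sigma = np.empty(n_keep)
    out_sigma_p = np.empty(n_keep) if phylo else None
    u_sum = np.zeros(n)

    df = spec.sigma_df
    n_al_const = n * np.log(tau * (1.0 - tau))

    def sigma_logtarget(s: float, e: np.ndarray) -> float:
        # sum of AL log-densities + half-t(df) prior (closed form; constants
        # that do not involve s are irrelevant to the Metropolis ratio but
        # kept for comparability with log_posterior)
        lp = n_al_const - n * np.log(s) - float(np.sum(check_loss(e / s, tau)))
        z = s / scales["sigma"]
        lp += -0.5 * (df + 1.0) * np.log1p(z * z / df)
        return lp

    def sigma_p_logtarget(sp: float, resid: np.ndarray, v: np.ndarray) -> float:
        # u marginalized: resid ~ MVN(0, sp^2 Cs + diag(v))
        M = sp ** 2 * Cs + np.diag(v)
        cf = sla.cho_factor(M, lower=True)
        half = sla.cho_solve(cf, resid)
        logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        lp = -0.5 * (logdet + float(resid @ half))
        lp += -0.5 * sp * sp / (scales["sigma_p"] ** 2)  # half-normal prior
        return lp

    for it in range(spec.iterations):
        v = sigma ** 2 * psi2 * w
        vinv = 1.0 / v
        offset = sigma * theta * w

        # --- coefficients (conjugate Gaussian)
        r = data.y - u - offset
        A = (Z * vinv[:, None]).T @ Z
        A[np.diag_indices_from(A)] += prior_prec
        rhs = Z.T @ (r * vinv)
        La = np.linalg.cholesky(A)
        mean = sla.cho_solve((La, True), rhs)
        b = mean + sla.solve_triangular(La, rng.standard_normal(2 * G),
                                        lower=True, trans="T")
        mu_fix = Z @ b

        if phylo:
            # --- sigma_p (u collapsed), then u | sigma_p
            resid = data.y - mu_fix - offset
            cur = sigma_p_logtarget(sigma_p, resid, v)
            prop = sigma_p * np.exp(step_p * rng.standard_normal())
            lacc = (sigma_p_logtarget(prop, resid, v) - cur
                    + np.log(prop) - np.log(sigma_p))
            acc = np.log(rng.uniform()) < lacc
            if acc:
                sigma_p = prop
            if it < spec.warmup:
                step_p *= np.exp(0.05 * ((1.0 if acc else 0.0) - 0.44))
            P = np.diag(vinv) + Cinv / max(sigma_p ** 2, 1e-12)
            Lp = np.linalg.cholesky(P)
            um = sla.cho_solve((Lp, True), resid * vinv)
            u = um + sla.solve_triangular(Lp, rng.standard_normal(n),
                                          lower=True, trans="T")

        # --- sigma (w collapsed; w redrawn right after)
        e = data.y - mu_fix - u
        cur = sigma_logtarget(sigma, e)
        prop = sigma * np.exp(step_s * rng.standard_normal())
        lacc = sigma_logtarget(prop, e) - cur + np.log(prop) - np.log(sigma)
        acc = np.log(rng.uniform()) < lacc
        if acc:
            sigma = prop
        if it < spec.warmup:
            step_s *= np.exp(0.05 * ((1.0 if acc else 0.0) - 0.44))

        # --- mixture weights w | everything
        chi = e ** 2 / (sigma ** 2 * psi2)
        w = _gig_half_rvs(rng, chi, psi0)

        if it >= spec.warmup:
            k = it - spec.warmup
            out_b[k] = b
            out_sigma[k] = sigma
            if phylo:
                out_sigma_p[k] = sigma_p
                u_sum += u
    return out_b, out_sigma, out_sigma_p, u_sum / max(n_keep, 1)


def fit_qr_mcmc(data: QRData, spec: QRSpec) -> QRPosterior:
    """Fit the (phylogenetic) Bayesian quantile regression by MCMC.

    Runs ``spec.chains`` independent chains and attaches split-Rhat and bulk
    ESS per reported parameter; warns when any Rhat exceeds 1.01 or any ESS
    falls below 400.
    """
    groups = data.groups
    counts = {g: int(np.sum(data.group == g)) for g in groups}
    small = [g for g, c in counts.items() if c < 10]
    if small:
        raise ValueError(f"fewer than 10 observations in group(s) {small}")
    if spec.phylo and data.C is None:
        raise ValueError("phylo model requires a covariance in QRData")
    scales = _prior_scales(data.y, data.x, spec)
    seeds = np.random.SeedSequence(spec.seed).spawn(spec.chains)
    G = len(groups)
    bs, sigmas, sigma_ps, u_means = [], [], [], []
    for ss in seeds:
        b, s, sp, um = _run_chain(data, spec, scales, np.random.default_rng(ss))
        bs.append(b)
        sigmas.append(s)
        sigma_ps.append(sp)
        u_means.append(um)
    b_arr = np.stack(bs)           # (chains, kept, 2G)
    draws: dict[str, np.ndarray] = {}
    for i, g in enumerate(groups):
        draws[f"alpha[{g}]"] = b_arr[:, :, i]
        draws[f"beta[{g}]"] = b_arr[:, :, G + i]
    draws["sigma"] = np.stack(sigmas)
    if spec.phylo:
        draws["sigma_p"] = np.stack(sigma_ps)
    u_mean = np.mean(u_means, axis=0) if spec.phylo else None

    rows = []
    for name, arr in draws.items():
        if spec.diagnostics and spec.chains >= 2:
            r, e = rhat_ess(arr)
        else:
            r, e = np.nan, np.nan
        rows.append({"parameter": name, "rhat": r, "ess": e})
    diag = pd.DataFrame(rows)
    bad = diag[(diag["rhat"] > 1.01) | (diag["ess"] < 400)]
    if spec.diagnostics and spec.chains >= 2 and not bad.empty:
        warnings.warn(
            "convergence diagnostics flagged: "
            + ", ".join(f"{r.parameter} (Rhat={r.rhat:.3f}, ESS={r.ess:.0f})"
                        for r in bad.itertuples()),
            RuntimeWarning, stacklevel=2)
    return QRPosterior(spec.tau, spec.phylo, groups, draws, u_mean, diag, spec)


# ---------------------------------------------------------------------------
# posterior summaries and decisions

def hdi(draws: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Narrowest contiguous interval holding ceil(mass*N) sorted draws."""
    draws = np.sort(np.asarray(draws, dtype=float).reshape(-1))
    n = draws.shape[0]
    if n < 100:
        raise ValueError("need at least 100 draws for an HDI")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0, 1)")
    m = int(np.ceil(mass * n))
    widths = draws[m - 1:] - draws[: n - m + 1]
    k = int(np.argmin(widths))
    return float(draws[k]), float(draws[k + m - 1])


def rope_decision(draws: np.ndarray, y: np.ndarray, mass: float = 0.95,
                  rope_factor: float = 0.1, parameter: str = "beta") -> RopeResult:
    """HDI-vs-ROPE verdict for a slope, with ROPE = +/- rope_factor * SD(y)."""
    y = np.asarray(y, dtype=float)
    sd = float(np.std(y, ddof=1))
    if sd == 0:
        raise ValueError("response is constant; ROPE undefined")
    lo, hi = hdi(draws, mass)
    r = rope_factor * sd
    if hi < -r or lo > r:
        verdict = "outside_rope"
    elif lo >= -r and hi <= r:
        verdict = "inside_rope"
    else:
        verdict = "overlapping"
    return RopeResult(parameter, lo, hi, -r, r, verdict)


def rhat_ess(chains: np.ndarray) -> tuple[float, float]:
    """Split-Rhat and bulk ESS for one parameter, draws shaped (chain, draw)."""
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("Rhat requires at least 2 chains of equal length")
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        import arviz as az
        ds = az.convert_to_dataset({"p": chains})
        r = float(az.rhat(ds)["p"].values)
        e = float(az.ess(ds)["p"].values)
    return r, e


def group_line_fit(y, x, group) -> pd.DataFrame:
    """Per-group ordinary least squares with a t-test on the slope.

    Groups with fewer than 3 points are skipped with a warning; a group whose
    x values are all identical raises (the slope is undefined).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    group = np.asarray(group)
    rows = []
    for g in pd.unique(group):
        sel = group == g
        if int(sel.sum()) < 3:
            warnings.warn(f"group {g!r} has fewer than 3 points; skipped",
                          RuntimeWarning, stacklevel=2)
            continue
        if np.ptp(x[sel]) == 0:
            raise ValueError(f"slope undefined for group {g!r}: x is constant")
        fit = stats.linregress(x[sel], y[sel])
        rows.append({"group": g, "n": int(sel.sum()), "slope": fit.slope,
                     "intercept": fit.intercept, "r2": fit.rvalue ** 2,
                     "p": fit.pvalue})
    return pd.DataFrame(rows)
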
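"""Trophic-position (TP) estimation from δ¹⁵N (and δ¹³C) values.

The deterministic point estimate is

    TP = λ + (δ¹⁵N_consumer − δ¹⁵N_baseline) / Δ¹⁵N

with λ the trophic position of the baseline (1 for plants) and Δ¹⁵N the
nitrogen trophic discrimination factor (TDF) of the consumer tissue.  The
Bayesian models propagate uncertainty in the baseline, the TDF and the
consumer residual spread:

* one-baseline population model — baseline obs ~ N(μ_b, σ_b), consumer obs
  ~ N(μ_b + Δ¹⁵N·(TP − λ), σ_c);
* two-baselines "full" model — consumers mix two plant sources (C3 vs
  C4/CAM) with diet proportion α estimated jointly from δ¹⁵N and δ¹³C, both
  elements carrying a trophic shift;
* individual one-baseline model — TP for a single animal, with the baseline
  mean given a Normal prior at the plant sample moments and the baseline SD
  a Cauchy prior (location = plant δ¹⁵N SD, scale 3) truncated to [0, ∞).

Priors not fixed by the procedure: TP ~ Uniform(λ − 0.5, 10) and
half-Cauchy(0, 3) on residual SDs.  Sampling uses affine-invariant ensembles
(emcee); a "chain" is one independently seeded ensemble, and convergence is
checked with split-R̂ across chains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import emcee
import numpy as np
from scipy.stats import gaussian_kde

from .baselines import BaselineDistribution
from .errors import ConvergenceError, InputError, ValidationError

__all__ = [
    "TDFSet",
    "MCMCSettings",
    "TPModelConfig",
    "TPPosterior",
    "tp_point",
    "fit_one_baseline",
    "fit_two_baselines_full",
    "fit_individual_one_baseline",
    "posterior_mode",
    "credible_interval",
    "convergence_check",
    "effective_sample_size",
]

_LOG2PI = math.log(2.0 * math.pi)
# log-σ sampling bounds: σ ∈ [1e-6, 1e3]
_LS_MIN, _LS_MAX = math.log(1e-6), math.log(1e3)
_SIGMA_PRIOR_SCALE = 3.0  # half-Cauchy scale for residual SDs
_RHAT_SOFT, _RHAT_HARD = 1.05, 1.1


@dataclass(frozen=True)
class TDFSet:
    """Trophic discrimination factors (consumer tissue minus diet, ‰).

    Defaults are laboratory liver values for mice on a control diet:
    Δ¹³C = 0.7 ± 0.3, Δ¹⁵N = 4.3 ± 0.2, Δ³⁴S = −2.1 ± 0.1.
    """

    d15N_mean: float = 4.3
    d15N_sd: float = 0.2
    d13C_mean: float = 0.7
    d13C_sd: float = 0.3
    d34S_mean: float = -2.1
    d34S_sd: float = 0.1

    def __post_init__(self) -> None:
        for name in ("d15N_sd", "d13C_sd", "d34S_sd"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"TDF {name} must be > 0")


@dataclass(frozen=True)
class MCMCSettings:
    """Ensemble-MCMC controls.

    Per chain the sampler runs ``n_adapt + n_iter`` steps, discards the first
    ``n_adapt + n_burnin`` and keeps every ``thin``-th snapshot of all
    walkers, so kept draws per chain =
    ceil((n_iter − n_burnin)/thin) × n_walkers.
    """

    n_chains: int = 3
    n_adapt: int = 1000
    n_iter: int = 20000
    n_burnin: int = 1000
    thin: int = 10
    n_walkers: int | None = None  # default: max(2·ndim, 8)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValidationError("at least 2 chains are required")
        if self.n_iter <= self.n_burnin:
            raise ValidationError("n_iter must exceed n_burnin")
        if self.thin < 1:
            raise ValidationError("thin must be >= 1")

    @classmethod
    def population_default(cls) -> "MCMCSettings":
        """3 chains, 1000 adaptive steps, 20 000 iterations, 1000 burn-in,
        thin 10 — the population-model run length."""
        return cls()

    @classmethod
    def individual_default(cls) -> "MCMCSettings":
        """16 chains, 1000 warm-up steps, ~10 000 kept draws pooled."""
        return cls(n_chains=16, n_adapt=1000, n_iter=600, n_burnin=0, thin=8,
                   n_walkers=8)

    @classmethod
    def reduced(cls, n_chains: int = 2, n_iter: int = 3000,
                n_burnin: int = 500, thin: int = 2) -> "MCMCSettings":
        """Short run for simulation studies and smoke tests."""
        return cls(n_chains=n_chains, n_adapt=200, n_iter=n_iter,
                   n_burnin=n_burnin, thin=thin)


@dataclass(frozen=True)
class TPModelConfig:
    """λ, the TP prior interval and the MCMC controls for one model run."""

    lambda_: float = 1.0
    tp_min: float | None = None  # default λ − 0.5
    tp_max: float = 10.0
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)
    sigma_prior_scale: float = _SIGMA_PRIOR_SCALE  # Cauchy scale for SD priors

    def __post_init__(self) -> None:
        if self.lambda_ < 1:
            raise ValidationError("lambda must be >= 1")
        if self.tp_lower < 0:
            raise ValidationError("TP prior lower bound must be >= 0")
        if self.tp_lower >= self.tp_max:
            raise ValidationError("TP prior interval is empty")
        if self.sigma_prior_scale <= 0:
            raise ValidationError("sigma_prior_scale must be > 0")

    @property
    def tp_lower(self) -> float:
        return self.lambda_ - 0.5 if self.tp_min is None else self.tp_min


def tp_point(
    consumer_d15N: float, baseline_d15N: float, tdf_d15N: float = 4.3,
    lambda_: float = 1.0,
) -> float:
    """Deterministic TP from the one-baseline equation."""
    if tdf_d15N == 0:
        raise InputError("TDF must be non-zero")
    return lambda_ + (consumer_d15N - baseline_d15N) / tdf_d15N


# ---------------------------------------------------------------------------
# posterior summaries

def posterior_mode(draws: np.ndarray) -> float:
    """Mode of pooled draws: argmax of a Gaussian KDE (Silverman bandwidth)
    on a 512-point grid spanning [min, max]."""
    x = np.asarray(draws, dtype=float).ravel()
    if x.size < 1000:
        raise InputError(f"posterior_mode needs >= 1000 draws, got {x.size}")
    lo, hi = float(x.min()), float(x.max())
    if hi - lo < 1e-12:
        return lo
    kde = gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(lo, hi, 512)
    return float(grid[int(np.argmax(kde(grid)))])


def credible_interval(draws: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Central quantile interval of pooled draws."""
    if not 0.0 < level < 1.0:
        raise InputError(f"level must be in (0, 1), got {level}")
    x = np.asarray(draws, dtype=float).ravel()
    if x.size < 1:
        raise InputError("credible_interval needs at least one draw")
    a = (1.0 - level) / 2.0
    lo, hi = np.quantile(x, [a, 1.0 - a])
    return float(lo), float(hi)


def convergence_check(chains: np.ndarray) -> float:
    """Split-R̂ for one parameter from per-chain draws (chains × draws).

    Each chain is split in half; R̂ compares within- and between-chain
    variance and is ≈ 1 for well-mixed stationary chains.
    """
    c = np.asarray(chains, dtype=float)
    if c.ndim != 2 or c.shape[0] < 2:
        raise InputError("convergence_check needs a 2-D array with >= 2 chains")
    n = c.shape[1] - (c.shape[1] % 2)
    if n < 4:
        raise InputError("chains too short to split")
    halves = np.vstack([c[:, : n // 2], c[:, n // 2 : n]])
    w = halves.var(axis=1, ddof=1).mean()
    b = halves.mean(axis=1).var(ddof=1) * (n // 2)
    if w <= 1e-300:
        return 1.0 if b <= 1e-300 else math.inf
    m = n // 2
    var_hat = (m - 1) / m * w + b / m
    return float(math.sqrt(var_hat / w))


def effective_sample_size(chains: np.ndarray) -> float:
    """Crude ESS: pooled draws divided by the integrated autocorrelation time
    (Geyer initial-positive-sequence estimate, averaged over chains)."""
    c = np.asarray(chains, dtype=float)
    if c.ndim != 2:
        raise InputError("effective_sample_size needs a 2-D array")
    m, n = c.shape
    taus = []
    for row in c:
        x = row - row.mean()
        if np.allclose(x, 0):
            taus.append(1.0)
            continue
        f = np.fft.rfft(x, 2 * n)
        acf = np.fft.irfft(f * np.conj(f))[:n].real
        acf /= acf[0]
        tau, k = 1.0, 1
        while k + 1 < n:
            pair = acf[k] + acf[k + 1]
            if pair < 0:
                break
            tau += 2.0 * pair
            k += 2
        taus.append(max(tau, 1.0))
    return float(m * n / np.mean(taus))


@dataclass(frozen=True)
class TPPosterior:
    """Posterior draws and summaries for a trophic-position fit.

    ``draws`` maps parameter names to (n_chains, n_draws) arrays; the
    headline summaries (mode, mean, sd, ci95) describe TP.  ``mode_outside_ci``
    flags the pathological case where the KDE mode sits outside the central
    95% interval.
    """

    model: str
    draws: dict[str, np.ndarray]
    lambda_: float
    tp_prior: tuple[float, float]
    mode: float
    mean: float
    sd: float
    ci95: tuple[float, float]
    rhat: dict[str, float]
    n_eff: float
    converged: bool
    mode_outside_ci: bool
    alpha_summary: dict[str, float] | None = None

    def pooled(self, param: str = "tp") -> np.ndarray:
        return self.draws[param].ravel()

    def summary(self) -> dict:
        out = {
            "model": self.model,
            "lambda": self.lambda_,
            "mode": self.mode,
            "mean": self.mean,
            "sd": self.sd,
            "ci95": list(self.ci95),
            "rhat": dict(self.rhat),
            "n_eff": self.n_eff,
            "converged": self.converged,
        }
        if self.alpha_summary is not None:
            out["alpha"] = dict(self.alpha_summary)
        return out


# ---------------------------------------------------------------------------
# sampling machinery

def _norm_logpdf(x, mu, sigma):
    return -0.5 * ((x - mu) / sigma) ** 2 - np.log(sigma) - 0.5 * _LOG2PI


def _half_cauchy_logpdf(sigma, scale):
    return math.log(2.0 / math.pi) - np.log(scale) - np.log1p((sigma / scale) ** 2)


def _trunc_cauchy_logpdf(sigma, loc, scale):
    # Cauchy(loc, scale) truncated to [0, inf)
    z = (sigma - loc) / scale
    norm = 1.0 - (math.atan(-loc / scale) / math.pi + 0.5)
    return -math.log(math.pi * scale) - np.log1p(z**2) - math.log(norm)


def _gauss_suff(mu, sigma, n, s1, s2):
    """Σ log N(x_i | mu, sigma) from sufficient statistics (vectorised in
    mu/sigma)."""
    ss = s2 - 2.0 * mu * s1 + n * mu**2
    return -0.5 * ss / sigma**2 - n * np.log(sigma) - 0.5 * n * _LOG2PI


def _run_chains(
    log_prob,
    center: np.ndarray,
    jitter: np.ndarray,
    bounds_lo: np.ndarray,
    bounds_hi: np.ndarray,
    mcmc: MCMCSettings,
    seed: int,
) -> np.ndarray:
    """Run independently seeded ensembles; return (n_chains, n_kept, ndim)."""
    ndim = center.size
    nwalkers = mcmc.n_walkers or max(2 * ndim, 8)
    if nwalkers < 2 * ndim:
        raise ValidationError(f"need at least {2 * ndim} walkers for {ndim} parameters")
    total = mcmc.n_adapt + mcmc.n_iter
    discard = mcmc.n_adapt + mcmc.n_burnin
    chains = []
    for c in range(mcmc.n_chains):
        ss = np.random.SeedSequence(entropy=seed, spawn_key=(c,))
        rng = np.random.default_rng(ss)
        p0 = center + jitter * rng.standard_normal((nwalkers, ndim))
        p0 = np.clip(p0, bounds_lo + 1e-9, bounds_hi - 1e-9)
        sampler = emcee.EnsembleSampler(nwalkers, ndim, log_prob, vectorize=True)
        rs = np.random.RandomState(int(ss.generate_state(2)[1] % 2**31))
        sampler.random_state = rs.get_state()
        sampler.run_mcmc(p0, total, skip_initial_state_check=True)
        kept = sampler.get_chain()[discard::mcmc.thin]  # (K, nwalkers, ndim)
        chains.append(kept.transpose(1, 0, 2).reshape(-1, ndim))
    return np.stack(chains)


def _finish(
    model: str,
    chains: np.ndarray,
    names: Sequence[str],
    cfg: TPModelConfig,
    allow_nonconverged: bool,
    alpha_index: int | None = None,
) -> TPPosterior:
    draws = {name: chains[:, :, i] for i, name in enumerate(names)}
    rhat = {name: convergence_check(draws[name]) for name in names}
    worst = max(rhat.values())
    if worst >= _RHAT_HARD and not allow_nonconverged:
        bad = {k: round(v, 3) for k, v in rhat.items() if v >= _RHAT_HARD}
        raise ConvergenceError(
            f"{model}: split-R-hat >= {_RHAT_HARD} for {bad}; rerun with more "
            "iterations or allow_nonconverged=True"
        )
    tp = draws["tp"].ravel()
    mode = posterior_mode(tp) if tp.size >= 1000 else float(np.median(tp))
    ci = credible_interval(tp)
    alpha_summary = None
    if alpha_index is not None:
        a = draws["alpha"].ravel()
        aci = credible_interval(a)
        alpha_summary = {
            "mode": posterior_mode(a) if a.size >= 1000 else float(np.median(a)),
            "mean": float(a.mean()),
            "sd": float(a.std(ddof=1)),
            "ci95_lo": aci[0],
            "ci95_hi": aci[1],
        }
    return TPPosterior(
        model=model,
        draws=draws,
        lambda_=cfg.lambda_,
        tp_prior=(cfg.tp_lower, cfg.tp_max),
        mode=mode,
        mean=float(tp.mean()),
        sd=float(tp.std(ddof=1)),
        ci95=ci,
        rhat=rhat,
        n_eff=effective_sample_size(draws["tp"]),
        converged=worst < _RHAT_SOFT,
        mode_outside_ci=not (ci[0] <= mode <= ci[1]),
        alpha_summary=alpha_summary,
    )


def _resolve_seed(cfg: TPModelConfig, seed: int | None) -> int:
    if seed is not None:
        return int(seed)
    if cfg.mcmc.seed is not None:
        return int(cfg.mcmc.seed)
    return 0


# ---------------------------------------------------------------------------
# models

def fit_one_baseline(
    consumers_d15N: Sequence[float],
    baseline: BaselineDistribution,
    tdf: TDFSet = TDFSet(),
    cfg: TPModelConfig | None = None,
    seed: int | None = None,
    allow_nonconverged: bool = False,
) -> TPPosterior:
    """Population TP model with a single plant baseline.

    Parameters sampled: TP, baseline mean μ_b, baseline SD σ_b, consumer
    residual SD σ_c, and Δ¹⁵N (Normal prior at the TDF estimate).
    """
    cons = np.asarray(consumers_d15N, dtype=float)
    if cons.size < 1:
        raise InputError("at least one consumer value is required")
    if baseline.n < 2:
        raise InputError("baseline needs at least 2 plant values")
    cfg = cfg or TPModelConfig()
    base = np.asarray(baseline.d15N_values, dtype=float)
    nb, sb1, sb2 = base.size, base.sum(), float(base @ base)
    nc, sc1, sc2 = cons.size, cons.sum(), float(cons @ cons)
    lam, lo, hi = cfg.lambda_, cfg.tp_lower, cfg.tp_max
    m_hat = base.mean()
    s_hat = max(float(base.std(ddof=1)), 1e-3)
    scale = cfg.sigma_prior_scale
    c_sd = max(float(cons.std(ddof=1)) if nc >= 2 else tdf.d15N_sd, 1e-3)

    blo = np.array([lo, -60.0, _LS_MIN, _LS_MIN, tdf.d15N_mean - 8 * tdf.d15N_sd])
    bhi = np.array([hi, 60.0, _LS_MAX, _LS_MAX, tdf.d15N_mean + 8 * tdf.d15N_sd])

    def log_prob(theta: np.ndarray) -> np.ndarray:
        tp, mu_b, ls_b, ls_c, delta = theta.T
        ok = np.all((theta >= blo) & (theta <= bhi), axis=1)
        s_b, s_c = np.exp(ls_b), np.exp(ls_c)
        lp = (
            _half_cauchy_logpdf(s_b, scale) + ls_b
            + _half_cauchy_logpdf(s_c, scale) + ls_c
            + _norm_logpdf(delta, tdf.d15N_mean, tdf.d15N_sd)
            + _norm_logpdf(mu_b, m_hat, 50.0)
            + _gauss_suff(mu_b, s_b, nb, sb1, sb2)
            + _gauss_suff(mu_b + delta * (tp - lam), s_c, nc, sc1, sc2)
        )
        return np.where(ok, lp, -np.inf)

    tp0 = float(np.clip(tp_point(cons.mean(), m_hat, tdf.d15N_mean, lam),
                        lo + 0.02, hi - 0.02))
    center = np.array([tp0, m_hat, math.log(s_hat), math.log(c_sd), tdf.d15N_mean])
    jitter = np.array([0.05, 0.3 * s_hat, 0.1, 0.1, 0.5 * tdf.d15N_sd])
    chains = _run_chains(log_prob, center, jitter, blo, bhi, cfg.mcmc,
                         _resolve_seed(cfg, seed))
    return _finish("oneBaseline", chains,
                   ["tp", "mu_b", "log_sigma_b", "log_sigma_c", "delta_n"],
                   cfg, allow_nonconverged)


def fit_two_baselines_full(
    consumers_d15N: Sequence[float],
    consumers_d13C: Sequence[float],
    source1: BaselineDistribution,
    source2: BaselineDistribution,
    tdf: TDFSet = TDFSet(),
    cfg: TPModelConfig | None = None,
    seed: int | None = None,
    allow_nonconverged: bool = False,
) -> TPPosterior:
    """Two-source mixing TP model using both δ¹⁵N and δ¹³C.

    α is the diet proportion drawn from source1 (the ¹³C-depleted / C3
    source); consumer δ¹³C must be lipid-corrected.  Both elements carry a
    trophic shift (Δ¹⁵N, Δ¹³C per step above λ).
    """
    cn = np.asarray(consumers_d15N, dtype=float)
    cc = np.asarray(consumers_d13C, dtype=float)
    if cn.size < 1 or cn.size != cc.size:
        raise InputError("consumer δ15N and δ13C must be equal-length, non-empty")
    for s in (source1, source2):
        if s.n < 2:
            raise InputError("both sources need at least 2 plant values")
    cfg = cfg or TPModelConfig()
    lam, lo, hi = cfg.lambda_, cfg.tp_lower, cfg.tp_max
    scale = cfg.sigma_prior_scale

    data = {}
    for tag, src in (("1", source1), ("2", source2)):
        for el, vals in (("N", src.d15N_values), ("C", src.d13C_values)):
            arr = np.asarray(vals, dtype=float)
            data[el + tag] = (arr.size, arr.sum(), float(arr @ arr), arr.mean(),
                              max(float(arr.std(ddof=1)), 1e-3))

    # θ = [tp, alpha, muN1, lsN1, muN2, lsN2, muC1, lsC1, muC2, lsC2,
    #      dN, dC, ls_cN, ls_cC]
    blo = np.array([lo, 0.0, -60, _LS_MIN, -60, _LS_MIN, -60, _LS_MIN, -60,
                    _LS_MIN, tdf.d15N_mean - 8 * tdf.d15N_sd,
                    tdf.d13C_mean - 8 * tdf.d13C_sd, _LS_MIN, _LS_MIN])
    bhi = np.array([hi, 1.0, 60, _LS_MAX, 60, _LS_MAX, 60, _LS_MAX, 60,
                    _LS_MAX, tdf.d15N_mean + 8 * tdf.d15N_sd,
                    tdf.d13C_mean + 8 * tdf.d13C_sd, _LS_MAX, _LS_MAX])

    ncN, s1N, s2N = cn.size, cn.sum(), float(cn @ cn)
    ncC, s1C, s2C = cc.size, cc.sum(), float(cc @ cc)

    def log_prob(theta: np.ndarray) -> np.ndarray:
        (tp, alpha, muN1, lsN1, muN2, lsN2, muC1, lsC1, muC2, lsC2,
         dN, dC, ls_cN, ls_cC) = theta.T
        ok = np.all((theta >= blo) & (theta <= bhi), axis=1)
        lp = np.zeros(theta.shape[0])
        for mu, ls, key in ((muN1, lsN1, "N1"), (muN2, lsN2, "N2"),
                            (muC1, lsC1, "C1"), (muC2, lsC2, "C2")):
            n, s1, s2, m0, _ = data[key]
            sig = np.exp(ls)
            lp += (_half_cauchy_logpdf(sig, scale) + ls
                   + _norm_logpdf(mu, m0, 50.0)
                   + _gauss_suff(mu, sig, n, s1, s2))
        lp += (_norm_logpdf(dN, tdf.d15N_mean, tdf.d15N_sd)
               + _norm_logpdf(dC, tdf.d13C_mean, tdf.d13C_sd))
        s_cN, s_cC = np.exp(ls_cN), np.exp(ls_cC)
        lp += (_half_cauchy_logpdf(s_cN, scale) + ls_cN
               + _half_cauchy_logpdf(s_cC, scale) + ls_cC)
        muN = alpha * muN1 + (1 - alpha) * muN2 + dN * (tp - lam)
        muC = alpha * muC1 + (1 - alpha) * muC2 + dC * (tp - lam)
        lp += _gauss_suff(muN, s_cN, ncN, s1N, s2N)
        lp += _gauss_suff(muC, s_cC, ncC, s1C, s2C)
        return np.where(ok, lp, -np.inf)

    mN1, mN2 = data["N1"][3], data["N2"][3]
    mC1, mC2 = data["C1"][3], data["C2"][3]
    # moment initialisation: α from carbon mixing, TP from nitrogen, iterated
    tp0, a0 = lam + 0.5, 0.5
    for _ in range(3):
        denom = mC1 - mC2
        if abs(denom) > 1e-9:
            a0 = float(np.clip(
                (cc.mean() - tdf.d13C_mean * (tp0 - lam) - mC2) / denom, 0.05, 0.95
            ))
        tp0 = float(np.clip(
            lam + (cn.mean() - (a0 * mN1 + (1 - a0) * mN2)) / tdf.d15N_mean,
            lo + 0.02, hi - 0.02,
        ))
    c_sdN = max(float(cn.std(ddof=1)) if cn.size >= 2 else tdf.d15N_sd, 1e-3)
    c_sdC = max(float(cc.std(ddof=1)) if cc.size >= 2 else tdf.d13C_sd, 1e-3)
    center = np.array([
        tp0, a0, mN1, math.log(data["N1"][4]), mN2, math.log(data["N2"][4]),
        mC1, math.log(data["C1"][4]), mC2, math.log(data["C2"][4]),
        tdf.d15N_mean, tdf.d13C_mean, math.log(c_sdN), math.log(c_sdC),
    ])
    jitter = np.array([0.05, 0.05, 0.2, 0.1, 0.2, 0.1, 0.2, 0.1, 0.2, 0.1,
                       0.5 * tdf.d15N_sd, 0.5 * tdf.d13C_sd, 0.1, 0.1])
    chains = _run_chains(log_prob, center, jitter, blo, bhi, cfg.mcmc,
                         _resolve_seed(cfg, seed))
    names = ["tp", "alpha", "mu_n1", "log_sigma_n1", "mu_n2", "log_sigma_n2",
             "mu_c1", "log_sigma_c1", "mu_c2", "log_sigma_c2",
             "delta_n", "delta_c", "log_sigma_cn", "log_sigma_cc"]
    return _finish("twoBaselinesFull", chains, names, cfg, allow_nonconverged,
                   alpha_index=1)


def fit_individual_one_baseline(
    consumer_d15N: float | Sequence[float],
    baseline: BaselineDistribution,
    tdf: TDFSet = TDFSet(),
    cfg: TPModelConfig | None = None,
    seed: int | None = None,
    allow_nonconverged: bool = False,
) -> TPPosterior:
    """TP for a single animal against a plant baseline.

    Priors: μ_b ~ Normal(baseline sample mean, baseline sample SD);
    σ_b ~ Cauchy(location = baseline sample SD, scale 3) truncated to
    [0, ∞); Δ¹⁵N ~ Normal(TDF mean, TDF SD); the single consumer value is
    Normal(μ_b + Δ¹⁵N·(TP − λ), σ_b).
    """
    arr = np.atleast_1d(np.asarray(consumer_d15N, dtype=float))
    if arr.size != 1:
        raise InputError(
            f"individual model takes exactly one consumer value, got {arr.size} "
            "(use the population model)"
        )
    if baseline.n < 2:
        raise InputError("baseline needs at least 2 plant values")
    y = float(arr[0])
    cfg = cfg or TPModelConfig(mcmc=MCMCSettings.individual_default())
    lam, lo, hi = cfg.lambda_, cfg.tp_lower, cfg.tp_max
    m_hat = baseline.d15N_mean
    s_hat = max(baseline.d15N_sd, 1e-3)
    scale = cfg.sigma_prior_scale

    blo = np.array([lo, -60.0, _LS_MIN, tdf.d15N_mean - 8 * tdf.d15N_sd])
    bhi = np.array([hi, 60.0, _LS_MAX, tdf.d15N_mean + 8 * tdf.d15N_sd])

    def log_prob(theta: np.ndarray) -> np.ndarray:
        tp, mu_b, ls_b, delta = theta.T
        ok = np.all((theta >= blo) & (theta <= bhi), axis=1)
        s_b = np.exp(ls_b)
        lp = (
            _norm_logpdf(mu_b, m_hat, s_hat)
            + _trunc_cauchy_logpdf(s_b, s_hat, scale) + ls_b
            + _norm_logpdf(delta, tdf.d15N_mean, tdf.d15N_sd)
            + _norm_logpdf(y, mu_b + delta * (tp - lam), s_b)
        )
        return np.where(ok, lp, -np.inf)

    tp0 = float(np.clip(tp_point(y, m_hat, tdf.d15N_mean, lam),
                        lo + 0.02, hi - 0.02))
    center = np.array([tp0, m_hat, math.log(s_hat), tdf.d15N_mean])
    jitter = np.array([0.1, 0.3 * s_hat, 0.2, 0.5 * tdf.d15N_sd])
    chains = _run_chains(log_prob, center, jitter, blo, bhi, cfg.mcmc,
                         _resolve_seed(cfg, seed))
    return _finish("individualOneBaseline", chains,
                   ["tp", "mu_b", "log_sigma_b", "delta_n"],
                   cfg, allow_nonconverged)
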
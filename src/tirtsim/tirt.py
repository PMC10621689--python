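"""Bayesian Thurstonian IRT estimation.

The estimator treats the latent utilities themselves as augmented data: the
observed ranking of a block constrains the utilities to an ordering, and
conditional on everything else each utility is a truncated normal.  This
yields a Gibbs sampler (in the tradition of probit data augmentation):

1. ``t | rest`` — per person x item, normal truncated to the observed
   within-block order (one sweep of single-site updates per iteration).
2. ``eta | rest`` — conjugate multivariate normal per person; the precision
   matrix ``Phi^-1 + diag(sum lambda^2 / psi^2)`` is shared by all persons,
   so one Cholesky factorisation serves the whole sample.
3. ``lambda | rest`` — random-walk Metropolis on each loading magnitude
   (the standardization constraint ``psi^2 = 1 - lambda^2`` breaks
   conjugacy); signs are fixed to the design keying, which resolves the
   reflection invariance.
4. ``mu | rest`` — conjugate normal per item (pair intercepts are
   ``gamma_ik = -(mu_i - mu_k)``, so item-level means parameterise all
   intercepts while keeping them additive within blocks).
5. ``Phi | eta`` — an inverse-Wishart covariance draw projected to a
   correlation matrix (parameter-expansion style update).

Because the augmented utilities share one error term per person x item
across all comparisons in a block, the residual dependency between
comparisons involving the same item is represented exactly, matching the
generative process.

Priors are weakly informative: half-normal(1) on loading magnitudes
(truncated to (0, 1)), N(0, 1) on item means, and the near-uniform
correlation prior induced by the inverse-Wishart projection.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Dict, Optional

import numpy as np
from scipy import linalg
from scipy.stats import invwishart, multivariate_normal, norm

from .design import QuestionnaireDesign, TraitCorrelationMatrix
from .score_classical import ScoreMatrix
from .simulate import ResponseData, simulate_responses, PersonSample

__all__ = [
    "TirtModel",
    "TirtPosterior",
    "McmcConfig",
    "build_model",
    "fit",
    "eap_scores",
    "quadrature_eap",
    "ranking_log_likelihood",
]

_EPS = 1e-12
_LAM_LO, _LAM_HI = 0.05, 0.95


@dataclasses.dataclass(frozen=True)
class McmcConfig:
    """Sampler budget. Defaults: 4 chains x (1000 warmup + 1000 kept)."""

    chains: int = 4
    warmup: int = 1000
    samples: int = 1000
    seed: int = 0
    proposal_sd: float = 0.05
    rhat_threshold: float = 1.05
    utility_sweeps: int = 2


@dataclasses.dataclass(frozen=True)
class TirtModel:
    """Model specification: design skeleton (trait map, keyed signs, blocks)
    plus the observed rankings.  Loadings, means and Phi may be fixed to
    known values, in which case the sampler conditions on them."""

    design: QuestionnaireDesign
    responses: ResponseData
    fixed_loadings: Optional[np.ndarray] = None
    fixed_means: Optional[np.ndarray] = None
    fixed_phi: Optional[np.ndarray] = None

    @property
    def n_outcomes_per_person(self) -> int:
        s = self.design.block_size
        return self.design.n_blocks * (s * (s - 1)) // 2


@dataclasses.dataclass
class TirtPosterior:
    """Posterior draws (chain, draw, ...) and convergence diagnostics."""

    eta_draws: np.ndarray  # (C, D, P, T)
    lam_draws: np.ndarray  # (C, D, I)
    mu_draws: np.ndarray  # (C, D, I)
    phi_draws: np.ndarray  # (C, D, T, T)
    rhat: Dict[str, float]
    converged: bool
    #: Rao-Blackwellized draws: the conditional posterior mean of eta given
    #: the augmented utilities at each iteration; averaging these yields the
    #: EAP with a much smaller Monte-Carlo error than averaging raw draws
    eta_mean_draws: Optional[np.ndarray] = None

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values())

    def eap_eta(self) -> np.ndarray:
        if self.eta_mean_draws is not None:
            return self.eta_mean_draws.mean(axis=(0, 1))
        return self.eta_draws.mean(axis=(0, 1))

    def eta_sd(self) -> np.ndarray:
        c, d = self.eta_draws.shape[:2]
        return self.eta_draws.reshape(c * d, *self.eta_draws.shape[2:]).std(axis=0)

    def eap_loadings(self) -> np.ndarray:
        return self.lam_draws.mean(axis=(0, 1))

    def eap_means(self) -> np.ndarray:
        return self.mu_draws.mean(axis=(0, 1))

    def eap_phi(self) -> np.ndarray:
        return self.phi_draws.mean(axis=(0, 1))

    def summary(self):
        """Tidy parameter summary (parameter, mean, sd, rhat where known)."""
        import pandas as pd

        rows = []
        for name, draws in (
            ("lambda", self.lam_draws),
            ("mu", self.mu_draws),
        ):
            flat = draws.reshape(-1, draws.shape[-1])
            for j in range(flat.shape[1]):
                rows.append((f"{name}[{j}]", flat[:, j].mean(), flat[:, j].std()))
        t = self.phi_draws.shape[-1]
        flat_phi = self.phi_draws.reshape(-1, t, t)
        for a in range(t):
            for b in range(a + 1, t):
                rows.append(
                    (f"phi[{a},{b}]", flat_phi[:, a, b].mean(), flat_phi[:, a, b].std())
                )
        return pd.DataFrame(rows, columns=["parameter", "mean", "sd"])


def build_model(
    design: QuestionnaireDesign,
    responses: ResponseData,
    fixed_loadings: Optional[np.ndarray] = None,
    fixed_means: Optional[np.ndarray] = None,
    fixed_phi: Optional[np.ndarray] = None,
) -> TirtModel:
    """Assemble a Thurstonian IRT model from a design skeleton and responses."""
    used = np.zeros(design.n_items, dtype=bool)
    used[design.blocks.ravel()] = True
    if not used.all():
        raise ValueError("every item must appear in at least one comparison")
    if responses.rankings.max() >= design.n_items or responses.rankings.min() < 0:
        raise ValueError("responses reference items outside the design")
    if fixed_phi is not None:
        TraitCorrelationMatrix(np.asarray(fixed_phi, dtype=float))
    return TirtModel(
        design=design,
        responses=responses,
        fixed_loadings=None if fixed_loadings is None else np.asarray(fixed_loadings, float),
        fixed_means=None if fixed_means is None else np.asarray(fixed_means, float),
        fixed_phi=None if fixed_phi is None else np.asarray(fixed_phi, float),
    )


def _truncnorm_draw(m, s, lo, hi, rng):
    """Inverse-CDF draw from N(m, s^2) truncated to (lo, hi); array args."""
    a = norm.cdf((lo - m) / s)
    b = norm.cdf((hi - m) / s)
    u = a + rng.random(np.broadcast_shapes(np.shape(m), np.shape(lo))) * (b - a)
    u = np.clip(u, _EPS, 1.0 - _EPS)
    return m + s * norm.ppf(u)


def _run_chain(model: TirtModel, cfg: McmcConfig, seed_seq: np.random.SeedSequence):
    rng = np.random.default_rng(seed_seq)
    design = model.design
    rankings = model.responses.rankings
    p, b, s = rankings.shape
    n_items = design.n_items
    n_traits = design.n_traits
    traits = design.trait_of_item
    signs = np.where(design.loadings >= 0, 1.0, -1.0)
    trait_onehot = np.zeros((n_items, n_traits))
    trait_onehot[np.arange(n_items), traits] = 1.0

    est_lam = model.fixed_loadings is None
    est_mu = model.fixed_means is None
    est_phi = model.fixed_phi is None

    # initial state
    if est_lam:
        lam_mag = np.full(n_items, 0.7)
    else:
        lam_mag = np.abs(model.fixed_loadings).astype(float)
        signs = np.where(model.fixed_loadings >= 0, 1.0, -1.0)
    prop_sd = np.full(n_items, cfg.proposal_sd)
    anc_sd = np.full(n_items, 0.02)
    scale_sd = np.full(n_traits, 0.05)
    item_of_trait = [np.flatnonzero(traits == a) for a in range(n_traits)]
    # per person x item: the items ranked immediately above/below within the
    # item's block (-1 at the extremes); fixed by the observed rankings
    above_item = np.full((p, n_items), -1, dtype=int)
    below_item = np.full((p, n_items), -1, dtype=int)
    rows = np.arange(p)[:, None]
    for bi in range(b):
        rk = rankings[:, bi, :]  # (P, S)
        for j in range(s):
            if j > 0:
                above_item[rows[:, 0], rk[:, j]] = rk[:, j - 1]
            if j + 1 < s:
                below_item[rows[:, 0], rk[:, j]] = rk[:, j + 1]
    mu = np.zeros(n_items) if est_mu else model.fixed_means.astype(float)
    phi = np.eye(n_traits) if est_phi else model.fixed_phi.astype(float)
    eta = np.zeros((p, n_traits))

    flat_rank = rankings.reshape(p, b * s)
    # utilities start at equally spaced values consistent with the ordering
    t_ranked = np.broadcast_to(
        (s - 1) / 2.0 - np.arange(s, dtype=float), (p, b, s)
    ).copy()
    t = np.empty((p, n_items))
    np.put_along_axis(t, flat_rank, t_ranked.reshape(p, -1), axis=1)

    n_keep = cfg.samples
    eta_out = np.empty((n_keep, p, n_traits))
    eta_mean_out = np.empty((n_keep, p, n_traits))
    lam_out = np.empty((n_keep, n_items))
    mu_out = np.empty((n_keep, n_items))
    phi_out = np.empty((n_keep, n_traits, n_traits))

    nu0 = n_traits + 2.0
    prior_scale = np.eye(n_traits)

    for it in range(cfg.warmup + n_keep):
        lam = signs * lam_mag
        psi2 = np.maximum(1.0 - lam_mag**2, 1e-6)
        sd_item = np.sqrt(psi2)
        eta_items = eta[:, traits]
        m_full = mu + lam * eta_items  # (P, I)

        # --- 1. latent utilities, one Gibbs sweep over rank positions ---
        m_r = np.take_along_axis(m_full, flat_rank, axis=1).reshape(p, b, s)
        s_r = sd_item[rankings]
        t_r = np.take_along_axis(t, flat_rank, axis=1).reshape(p, b, s)
        for _ in range(max(1, cfg.utility_sweeps)):
            for j in range(s):
                lo = t_r[:, :, j + 1] if j + 1 < s else -np.inf
                hi = t_r[:, :, j - 1] if j > 0 else np.inf
                t_r[:, :, j] = _truncnorm_draw(m_r[:, :, j], s_r[:, :, j], lo, hi, rng)
        np.put_along_axis(t, flat_rank, t_r.reshape(p, -1), axis=1)

        # --- 2. person traits (conjugate MVN, shared precision) ---
        w = lam / psi2
        d_diag = trait_onehot.T @ (lam * w)  # sum lambda^2/psi^2 per trait
        phi_inv = linalg.cho_solve(linalg.cho_factor(phi, lower=True), np.eye(n_traits))
        prec = phi_inv + np.diag(d_diag)
        c_lo, low = linalg.cho_factor(prec, lower=True)
        bvec = (t - mu) * w @ trait_onehot  # (P, T)
        mean_eta = linalg.cho_solve((c_lo, low), bvec.T).T
        z = rng.standard_normal((p, n_traits))
        noise = linalg.solve_triangular(c_lo, z.T, lower=True, trans="T").T
        eta = mean_eta + noise
        eta_items = eta[:, traits]
        eta_cond_mean = mean_eta

        # --- 3. loading magnitudes (random-walk Metropolis per item) ---
        if est_lam:
            def logpost(mag):
                ps = 1.0 - mag**2
                resid = t - mu - (signs * mag) * eta_items
                ll = -0.5 * p * np.log(ps) - 0.5 * np.sum(resid**2, axis=0) / ps
                return ll - 0.5 * mag**2  # half-normal(1) prior on magnitude

            prop = lam_mag + prop_sd * rng.standard_normal(n_items)
            inb = (prop > _LAM_LO) & (prop < _LAM_HI)
            prop_safe = np.where(inb, prop, lam_mag)
            accept = inb & (
                np.log(rng.random(n_items)) < logpost(prop_safe) - logpost(lam_mag)
            )
            lam_mag = np.where(accept, prop_safe, lam_mag)
            lam = signs * lam_mag
            psi2 = np.maximum(1.0 - lam_mag**2, 1e-6)
            if it < cfg.warmup:
                # Robbins-Monro adaptation of per-item proposal scales
                # towards the ~0.44 optimum for scalar random walks
                step = 1.0 / np.sqrt(1.0 + it)
                prop_sd *= np.exp(step * (accept.astype(float) - 0.44) * 0.5)
                prop_sd = np.clip(prop_sd, 1e-3, 0.5)

        # --- 3a. ancillary loading update (interweaving) ---
        # Re-expressing an item's utilities through their standardized
        # residuals u = (t - mu - lambda*eta)/psi and holding u fixed while
        # proposing lambda' moves (lambda, t) along their coupled direction:
        # the Gaussian likelihood cancels exactly and the proposal is
        # accepted with the prior ratio, provided every person's new utility
        # still sits between its ranking neighbours.
        if est_lam:
            for i in rng.permutation(n_items):
                prop_mag = lam_mag[i] + anc_sd[i] * rng.standard_normal()
                acc = False
                if _LAM_LO < prop_mag < _LAM_HI:
                    ps_old = np.sqrt(1.0 - lam_mag[i] ** 2)
                    ps_new = np.sqrt(1.0 - prop_mag**2)
                    base = mu[i] + signs[i] * lam_mag[i] * eta_items[:, i]
                    t_new = (
                        mu[i]
                        + signs[i] * prop_mag * eta_items[:, i]
                        + (ps_new / ps_old) * (t[:, i] - base)
                    )
                    ab = above_item[:, i]
                    be = below_item[:, i]
                    hi_ok = (ab < 0) | (t_new < t[np.arange(p), np.maximum(ab, 0)])
                    lo_ok = (be < 0) | (t_new > t[np.arange(p), np.maximum(be, 0)])
                    if np.all(hi_ok & lo_ok):
                        dlog = -0.5 * (prop_mag**2 - lam_mag[i] ** 2)
                        if np.log(rng.random()) < dlog:
                            lam_mag[i] = prop_mag
                            t[:, i] = t_new
                            acc = True
                if it < cfg.warmup:
                    step = 1.0 / np.sqrt(1.0 + it)
                    anc_sd[i] *= np.exp(step * (float(acc) - 0.3) * 0.5)
                    anc_sd[i] = float(np.clip(anc_sd[i], 1e-4, 0.3))
            lam = signs * lam_mag
            psi2 = np.maximum(1.0 - lam_mag**2, 1e-6)

        # --- 3b. interweaved scale move per trait ---
        # The joint scale of a trait's loading magnitudes and its scores is
        # a slow direction for single-site updates: lambda_a -> r * lambda_a
        # with eta_a -> eta_a / r leaves every utility mean invariant, so
        # only the error variances (psi^2 = 1 - lambda^2), the eta and
        # lambda priors and the transformation Jacobian r^(n_a - P) enter
        # the Metropolis ratio.
        if est_lam:
            for a in range(n_traits):
                items_a = item_of_trait[a]
                n_a = items_a.size
                r = float(np.exp(scale_sd[a] * rng.standard_normal()))
                new_mag = lam_mag[items_a] * r
                acc = False
                if np.all((new_mag > _LAM_LO) & (new_mag < _LAM_HI)):
                    ps_old = 1.0 - lam_mag[items_a] ** 2
                    ps_new = 1.0 - new_mag**2
                    resid = (
                        t[:, items_a]
                        - mu[items_a]
                        - (signs[items_a] * lam_mag[items_a]) * eta[:, [a]]
                    )
                    ssr = np.sum(resid**2, axis=0)
                    dlog = float(
                        np.sum(
                            -0.5 * p * (np.log(ps_new) - np.log(ps_old))
                            - 0.5 * ssr * (1.0 / ps_new - 1.0 / ps_old)
                        )
                    )
                    ea = eta[:, a]
                    cross = eta @ phi_inv[:, a] - phi_inv[a, a] * ea
                    dlog -= 0.5 * (
                        (1.0 / r**2 - 1.0) * phi_inv[a, a] * np.sum(ea**2)
                        + 2.0 * (1.0 / r - 1.0) * np.sum(ea * cross)
                    )
                    dlog -= 0.5 * float(np.sum(new_mag**2 - lam_mag[items_a] ** 2))
                    dlog += (n_a - p) * np.log(r)
                    if np.log(rng.random()) < dlog:
                        lam_mag[items_a] = new_mag
                        eta[:, a] = ea / r
                        acc = True
                if it < cfg.warmup:
                    step = 1.0 / np.sqrt(1.0 + it)
                    scale_sd[a] *= np.exp(step * (float(acc) - 0.3) * 0.5)
                    scale_sd[a] = float(np.clip(scale_sd[a], 1e-3, 0.3))
            lam = signs * lam_mag
            psi2 = np.maximum(1.0 - lam_mag**2, 1e-6)
            eta_items = eta[:, traits]

        # --- 4. item means (conjugate normal, N(0,1) prior) ---
        if est_mu:
            post_prec = 1.0 + p / psi2
            post_mean = np.sum(t - lam * eta_items, axis=0) / psi2 / post_prec
            mu = post_mean + rng.standard_normal(n_items) / np.sqrt(post_prec)

        # --- 4b. recentering moves for the block-location directions ---
        # Rankings identify only within-block utility differences, so the
        # common level of a block's utilities (and of its item means) is a
        # weakly identified direction that single-site updates traverse
        # slowly.  Both shifts leave the ranking constraints and the model
        # residuals invariant and have exact Gaussian conditionals.
        m_full = mu + (signs * lam_mag) * eta_items
        w_item = 1.0 / psi2
        w_block = w_item[design.blocks].sum(axis=1)  # (B,)
        num = ((m_full - t) * w_item)[:, design.blocks].sum(axis=2)  # (P, B)
        shift = num / w_block + rng.standard_normal((p, b)) / np.sqrt(w_block)
        t[:, design.blocks.ravel()] += np.repeat(shift, s, axis=1)
        if est_mu:
            mu_b = mu[design.blocks]  # (B, S)
            c = -mu_b.mean(axis=1) + rng.standard_normal(b) / np.sqrt(float(s))
            mu[design.blocks.ravel()] += np.repeat(c, s)
            t[:, design.blocks.ravel()] += np.repeat(c, s)[None, :]

        # --- 5. trait correlations (inverse-Wishart projection) ---
        if est_phi:
            scale = prior_scale + eta.T @ eta
            sigma = invwishart.rvs(df=nu0 + p, scale=scale, random_state=rng)
            sigma = np.atleast_2d(sigma)
            d = np.sqrt(np.diag(sigma))
            phi = sigma / np.outer(d, d)
            np.fill_diagonal(phi, 1.0)

        if it >= cfg.warmup:
            k = it - cfg.warmup
            eta_out[k] = eta
            eta_mean_out[k] = eta_cond_mean
            lam_out[k] = signs * lam_mag
            mu_out[k] = mu
            phi_out[k] = phi

    return eta_out, lam_out, mu_out, phi_out, eta_mean_out


def _max_rhat(arr: np.ndarray) -> float:
    """Split-Rhat maximised over the trailing parameter axes.

    ``arr`` has shape (chain, draw, ...); each chain is split in half so the
    diagnostic is sensitive to within-chain trends as well.
    """
    c, d = arr.shape[:2]
    half = d // 2
    if half < 2:
        return float("nan")
    halves = np.concatenate([arr[:, :half], arr[:, half : 2 * half]], axis=0)
    m = halves.shape[0]
    flat = halves.reshape(m, half, -1)
    chain_mean = flat.mean(axis=1)
    chain_var = flat.var(axis=1, ddof=1)
    w = chain_var.mean(axis=0)
    bvar = half * chain_mean.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_hat = (half - 1) / half * w + bvar / half
        rhat = np.sqrt(var_hat / w)
    rhat = rhat[np.isfinite(rhat)]
    return float(rhat.max()) if rhat.size else 1.0


def fit(model: TirtModel, config: Optional[McmcConfig] = None) -> TirtPosterior:
    """Run the Gibbs sampler and collect posterior draws with diagnostics.

    Non-convergence (max split-Rhat above the threshold) is flagged on the
    result and warned about, never silently accepted.
    """
    cfg = config or McmcConfig()
    if cfg.chains < 1 or cfg.warmup < 1 or cfg.samples < 1:
        raise ValueError("chains, warmup and samples must be positive")
    seqs = np.random.SeedSequence(cfg.seed).spawn(cfg.chains)
    chains = [_run_chain(model, cfg, sq) for sq in seqs]
    eta_d = np.stack([c[0] for c in chains])
    lam_d = np.stack([c[1] for c in chains])
    mu_d = np.stack([c[2] for c in chains])
    phi_d = np.stack([c[3] for c in chains])
    eta_m = np.stack([c[4] for c in chains])

    rhat = {"eta": _max_rhat(eta_d)}
    if model.fixed_loadings is None:
        rhat["lambda"] = _max_rhat(lam_d)
    if model.fixed_means is None:
        rhat["mu"] = _max_rhat(mu_d)
    if model.fixed_phi is None:
        t = phi_d.shape[-1]
        iu = np.triu_indices(t, k=1)
        if iu[0].size:
            rhat["phi"] = _max_rhat(phi_d[:, :, iu[0], iu[1]])
    rhat = {k: v for k, v in rhat.items() if np.isfinite(v)}
    converged = all(v <= cfg.rhat_threshold for v in rhat.values())
    if not converged:
        warnings.warn(
            f"MCMC may not have converged (max split-Rhat {max(rhat.values()):.3f})",
            RuntimeWarning,
            stacklevel=2,
        )
    return TirtPosterior(
        eta_draws=eta_d,
        lam_draws=lam_d,
        mu_draws=mu_d,
        phi_draws=phi_d,
        rhat=rhat,
        converged=converged,
        eta_mean_draws=eta_m,
    )


def eap_scores(posterior: TirtPosterior) -> ScoreMatrix:
    """Expected-a-posteriori trait scores (posterior means of eta)."""
    if not posterior.converged:
        warnings.warn(
            "EAP scores derived from a non-converged posterior", RuntimeWarning,
            stacklevel=2,
        )
    return ScoreMatrix(
        theta=posterior.eap_eta(), method="tirt_eap", posterior_sd=posterior.eta_sd()
    )


def posterior_predictive_pair_freq(
    posterior: TirtPosterior,
    model: TirtModel,
    rng: np.random.Generator,
    n_draws: int = 50,
) -> np.ndarray:
    """Mean simulated pairwise-outcome frequencies under the posterior.

    Returns an array shaped like one person-averaged outcome table
    ``(n_blocks, n_pairs)`` for comparison with the observed frequencies.
    """
    from .simulate import rank_to_pairwise

    c, d = posterior.eta_draws.shape[:2]
    idx = rng.choice(c * d, size=min(n_draws, c * d), replace=False)
    freqs = []
    for flat in idx:
        ci, di = divmod(flat, d)
        dsgn = dataclasses.replace(
            model.design,
            loadings=posterior.lam_draws[ci, di],
            item_means=posterior.mu_draws[ci, di],
        )
        sim = simulate_responses(dsgn, PersonSample(posterior.eta_draws[ci, di]), rng)
        freqs.append(rank_to_pairwise(sim, dsgn).mean(axis=0))
    return np.mean(freqs, axis=0)


def ranking_log_likelihood(
    design: QuestionnaireDesign,
    rankings: np.ndarray,
    eta: np.ndarray,
    lam: np.ndarray,
    mu: np.ndarray,
) -> np.ndarray:
    """Exact log-likelihood of each person's rankings given trait values.

    For 2-item blocks the ranking probability is the probit of the scaled
    mean difference; for triplets it is a bivariate normal orthant
    probability with covariance induced by the shared middle-item error.
    Used by the quadrature oracle; cost grows with grid x blocks, so this is
    meant for micro models.
    """
    psi2 = 1.0 - lam**2
    n = eta.shape[0]
    ll = np.zeros(n)
    means = mu + lam * eta[:, design.trait_of_item]  # (n, I)
    for bi in range(design.n_blocks):
        r = rankings[:, bi, :] if rankings.ndim == 3 else rankings[None, bi, :]
        m = np.take_along_axis(means, r, axis=1)
        v = psi2[r]
        if design.block_size == 2:
            z = (m[:, 0] - m[:, 1]) / np.sqrt(v[:, 0] + v[:, 1])
            ll += norm.logcdf(z)
        elif design.block_size == 3:
            d_mean = np.stack([m[:, 0] - m[:, 1], m[:, 1] - m[:, 2]], axis=1)
            probs = np.empty(n)
            for i in range(n):
                cov = np.array(
                    [
                        [v[i, 0] + v[i, 1], -v[i, 1]],
                        [-v[i, 1], v[i, 1] + v[i, 2]],
                    ]
                )
                probs[i] = multivariate_normal.cdf(d_mean[i], mean=[0, 0], cov=cov)
            ll += np.log(np.maximum(probs, _EPS))
        else:
            raise NotImplementedError("block sizes 2 and 3 only")
    return ll


def quadrature_eap(
    design: QuestionnaireDesign,
    responses: ResponseData,
    phi: np.ndarray,
    lam: Optional[np.ndarray] = None,
    mu: Optional[np.ndarray] = None,
    lim: float = 5.0,
    step: float = 0.05,
) -> np.ndarray:
    """Deterministic EAP by dense grid integration (1 or 2 traits).

    Integrates the exact ranking likelihood against the MVN(0, Phi) prior on
    a regular grid.  Independent of the MCMC code path; serves as the
    small-model reference for the sampler.
    """
    lam = design.loadings if lam is None else np.asarray(lam, float)
    mu = design.item_means if mu is None else np.asarray(mu, float)
    phi = np.asarray(phi, float)
    n_traits = design.n_traits
    if n_traits > 2:
        raise NotImplementedError("grid quadrature supports at most 2 traits")
    axis = np.arange(-lim, lim + step / 2, step)
    if n_traits == 1:
        grid = axis[:, None]
    else:
        g1, g2 = np.meshgrid(axis, axis, indexing="ij")
        grid = np.column_stack([g1.ravel(), g2.ravel()])
    log_prior = multivariate_normal.logpdf(grid, mean=np.zeros(n_traits), cov=phi)
    out = np.empty((responses.n_persons, n_traits))
    for pi in range(responses.n_persons):
        ll = ranking_log_likelihood(
            design, responses.rankings[pi : pi + 1], grid, lam, mu
        )
        logw = ll + log_prior
        w = np.exp(logw - logw.max())
        w /= w.sum()
        out[pi] = w @ grid
    return out
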
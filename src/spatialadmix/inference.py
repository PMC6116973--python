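"""Posterior inference for the layered spatial covariance model.

The posterior over (per-layer kernel parameters, admixture proportions,
global covariance, nuggets) given an observed allelic covariance matrix is
proportional to the Wishart likelihood times the priors.  Sampling runs in a
fully unconstrained parameterization (log / scaled-logistic / stick-breaking
bijections with their Jacobians) with an adaptive Metropolis-within-Gibbs
kernel: one Gaussian random-walk update per coordinate per sweep, with
per-coordinate step sizes tuned toward a 0.44 acceptance rate during warmup
by diminishing adaptation, frozen afterwards.  Chains are initialized at a
jittered posterior mode found by L-BFGS-B (or at prior draws).

Because mixture posteriors are invariant to permuting layer labels,
independent runs are aligned with :func:`match_layers` before comparison.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln
from sklearn.base import BaseEstimator

from ._transforms import ParamTransform, simplex_forward
from .covmodel import (LayerParams, ModelParams, PriorSettings,
                       WishartLikelihood)
from .freqdata import (AllelicCovariance, DistanceMatrix, FrequencyMatrix,
                       allelic_covariance, pairwise_distances)

__all__ = [
    "McmcSettings",
    "PosteriorSamples",
    "ConvergenceReport",
    "SpatialAdmixture",
    "fit",
    "diagnostics",
    "match_layers",
    "posterior_summary",
]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass
class McmcSettings:
    """Sampler settings. ``n_iter`` counts sweeps per chain; the first
    ``warmup`` (default half) are adaptation and are discarded."""

    n_chains: int = 4
    n_iter: int = 2000
    warmup: int | None = None
    thin: int = 1
    init: str = "map"            # "map" or "prior"
    map_maxiter: int = 400
    init_jitter: float = 0.05    # sd of the per-chain jitter around the mode
    adapt_batch: int = 25

    def __post_init__(self):
        if self.n_chains < 1 or self.n_iter < 2:
            raise ValueError("need n_chains >= 1 and n_iter >= 2")
        if self.warmup is None:
            self.warmup = self.n_iter // 2
        if not 0 < self.warmup < self.n_iter:
            raise ValueError("warmup must be in (0, n_iter)")
        if self.init not in {"map", "prior"}:
            raise ValueError("init must be 'map' or 'prior'")

    def to_dict(self):
        return {"n_chains": self.n_chains, "n_iter": self.n_iter,
                "warmup": self.warmup, "thin": self.thin, "init": self.init,
                "map_maxiter": self.map_maxiter,
                "init_jitter": self.init_jitter,
                "adapt_batch": self.adapt_batch}


class _LogPosterior:
    """Fast unnormalized log posterior on the unconstrained vector.

    Non-positive-definite proposals return ``-inf`` (rejection) rather than
    being jittered.
    """

    def __init__(self, obs: AllelicCovariance, d: DistanceMatrix, n_layers: int,
                 spatial: bool, priors: PriorSettings, df: int | None = None):
        self.n = obs.n_samples
        self.k = int(n_layers)
        self.spatial = bool(spatial)
        self.transform = ParamTransform(self.n, self.k, spatial)
        self.wl = WishartLikelihood(obs, df)
        self.dmat = d.d
        if self.dmat.shape[0] != self.n:
            raise ValueError("distance matrix does not match omega_hat")
        self.priors = priors
        self.conc = priors.concentration(self.k)
        k, c = self.k, self.conc
        self._dir_lognorm = gammaln(k * c) - k * gammaln(c) if k > 1 else 0.0
        self._eye = np.eye(self.n, dtype=bool)
        # fused prior constants (half-normal normalizers, alpha2 uniform,
        # Dirichlet normalizer)
        p = priors
        hn = math.log(2.0) - 0.5 * _LOG_2PI
        n_hn = (2 * k if self.spatial else 0) + k + 1 + self.n
        const = n_hn * hn + k * math.log(0.5) + self.n * self._dir_lognorm
        if self.spatial:
            const -= k * (math.log(p.scale_alpha0) + math.log(p.scale_alphaD))
        const -= k * math.log(p.scale_phi) + math.log(p.scale_gamma) \
            + self.n * math.log(p.scale_eta)
        self._prior_const = const
        self._inv2_a0 = 0.5 / p.scale_alpha0 ** 2
        self._inv2_aD = 0.5 / p.scale_alphaD ** 2
        self._inv2_phi = 0.5 / p.scale_phi ** 2
        self._inv2_gamma = 0.5 / p.scale_gamma ** 2
        self._inv2_eta = 0.5 / p.scale_eta ** 2

    def _unpack(self, z):
        t = self.transform
        k = self.k
        logj = 0.0
        if self.spatial:
            blk = z[:4 * k].reshape(k, 4)
            alpha0 = np.exp(blk[:, 0])
            alphaD = np.exp(blk[:, 1])
            s = 1.0 / (1.0 + np.exp(-blk[:, 2]))
            alpha2 = 2.0 * s
            phi = np.exp(blk[:, 3])
            logj += float(blk[:, 0].sum() + blk[:, 1].sum() + blk[:, 3].sum())
            with np.errstate(divide="ignore"):
                logj += float(k * math.log(2.0) + np.log(s).sum()
                              + np.log1p(-s).sum())
        else:
            ph = z[:k]
            alpha0 = np.zeros(k)
            alphaD = np.ones(k)
            alpha2 = np.ones(k)
            phi = np.exp(ph)
            logj += float(ph.sum())
        if k > 1:
            zw = z[t._i_w:t._i_gamma].reshape(self.n, k - 1)
            w, lj = simplex_forward(zw)
            logj += lj
        else:
            w = np.ones((self.n, 1))
        gamma = math.exp(z[t._i_gamma])
        logj += float(z[t._i_gamma])
        ze = z[t._i_eta:]
        # diagonal block: log of the total model diagonal; eta derived
        eta = np.exp(ze) - gamma - (w ** 2) @ (alpha0 + phi)
        logj += float(ze.sum())
        return alpha0, alphaD, alpha2, phi, w, gamma, eta, logj

    def omega(self, z):
        alpha0, alphaD, alpha2, phi, w, gamma, eta, _ = self._unpack(z)
        return self._omega(alpha0, alphaD, alpha2, phi, w, gamma, eta)

    def _omega(self, alpha0, alphaD, alpha2, phi, w, gamma, eta):
        om = np.full((self.n, self.n), gamma)
        for j in range(self.k):
            if alpha0[j] != 0.0:
                g = alpha0[j] * np.exp(-((alphaD[j] * self.dmat) ** alpha2[j])) \
                    + phi[j]
            else:
                g = phi[j]
            wj = w[:, j]
            om += np.multiply.outer(wj, wj) * g
        om[self._eye] += eta
        return om

    def __call__(self, z) -> float:
        alpha0, alphaD, alpha2, phi, w, gamma, eta, logj = self._unpack(z)
        if np.any(eta <= 0):
            return -np.inf
        om = self._omega(alpha0, alphaD, alpha2, phi, w, gamma, eta)
        ll = self.wl.loglik_fast(om)
        if not np.isfinite(ll):
            return -np.inf
        pr = self._log_prior(alpha0, alphaD, alpha2, phi, w, gamma, eta)
        return ll + pr + logj

    def _log_prior(self, alpha0, alphaD, alpha2, phi, w, gamma, eta):
        lp = self._prior_const
        if self.spatial:
            lp -= self._inv2_a0 * float(alpha0 @ alpha0) \
                + self._inv2_aD * float(alphaD @ alphaD)
        lp -= self._inv2_phi * float(phi @ phi) \
            + self._inv2_gamma * gamma * gamma \
            + self._inv2_eta * float(eta @ eta)
        if self.k > 1:
            lp += (self.conc - 1.0) * float(np.log(w).sum())
        return lp

    # -- initialization -------------------------------------------------
    def heuristic_start(self, rng) -> np.ndarray:
        """Data-driven starting point.

        For K > 1 the admixture rows start near the simplex corners given by
        k-means clustering of the observed covariance rows (hard assignments
        break both the layer-label symmetry and the soft ridge along which
        admixture can trade off against kernel amplitudes); kernel amplitudes
        come from within- versus between-cluster mean covariances, and the
        nuggets absorb the fixed 1/4 diagonal.
        """
        off_mask = ~self._eye
        omega_hat = self.wl.a / self.wl.df
        off = omega_hat[off_mask]
        between = max(float(np.percentile(off, 5)), 1e-4) if off.size else 1e-3
        if self.k > 1:
            from sklearn.cluster import KMeans
            rows = omega_hat.copy()
            rows[self._eye] = (omega_hat.sum(axis=1) - 0.25) / max(self.n - 1, 1)
            labels = KMeans(n_clusters=self.k, n_init=5,
                            random_state=int(rng.integers(2 ** 31))
                            ).fit_predict(rows)
            w0 = np.full((self.n, self.k), 0.08 / max(self.k - 1, 1))
            w0[np.arange(self.n), labels] = 0.92
            amps = []
            for k in range(self.k):
                members = labels == k
                block = omega_hat[np.ix_(members, members)][
                    off_mask[np.ix_(members, members)]]
                within = float(block.mean()) if block.size else between
                amps.append(max(within - between, 1e-3))
        else:
            w0 = np.ones((self.n, 1))
            hi = max(float(np.percentile(off, 95)), 2e-4)
            amps = [max(hi - between, 1e-3)]
        layers = []
        for k in range(self.k):
            if self.spatial:
                layers.append(LayerParams(0.5 * amps[k], 1.0, 1.0,
                                          0.5 * amps[k]))
            else:
                layers.append(LayerParams(0.0, 1.0, 1.0, amps[k]))
        diag_model = between + (w0 ** 2) @ np.array(
            [lp.alpha0 + lp.phi for lp in layers])
        eta0 = np.maximum(0.25 - between - diag_model, 1e-3)
        mp = ModelParams(layers=layers, w=w0, gamma=between, eta=eta0,
                         spatial=self.spatial)
        return self.transform.from_params(mp)

    def nonadmixture_mask(self) -> np.ndarray:
        """Boolean mask over coordinates excluding the admixture block."""
        mask = np.ones(self.transform.dim, dtype=bool)
        mask[self.transform._i_w:self.transform._i_gamma] = False
        return mask

    def prior_start(self, rng) -> np.ndarray:
        p = self.priors
        k, n = self.k, self.n
        layers = []
        for _ in range(k):
            a0 = abs(rng.normal(0, p.scale_alpha0)) if self.spatial else 0.0
            ad = abs(rng.normal(0, p.scale_alphaD)) + 1e-3
            a2 = rng.uniform(0.05, 1.95)
            ph = abs(rng.normal(0, p.scale_phi)) + 1e-6
            layers.append(LayerParams(a0, ad, a2 if self.spatial else 1.0, ph)
                          if self.spatial else LayerParams(0.0, 1.0, 1.0, ph))
        w = np.full((n, k), 1.0 / k)
        mp = ModelParams(layers=layers, w=w, gamma=abs(rng.normal(0, p.scale_gamma))
                         + 1e-6, eta=np.abs(rng.normal(0, p.scale_eta, n)) + 1e-6,
                         spatial=self.spatial)
        z = self.transform.from_params(mp)
        if k > 1:
            z[self.transform._i_w:self.transform._i_gamma] += \
                0.3 * rng.standard_normal(self.transform.n_w)
        return z

    def map_estimate(self, z0, maxiter=400, free_mask=None) -> np.ndarray:
        """L-BFGS-B ascent of the unconstrained-space log density.

        ``free_mask`` restricts the optimization to a coordinate subset
        (used to profile kernel/nugget parameters at fixed admixture, since
        the full unconstrained-space mode is biased along the admixture
        ridge by the stick-breaking Jacobian).
        """
        if free_mask is None:
            free_mask = np.ones(z0.size, dtype=bool)
        z_full = z0.copy()

        def neg(zsub):
            z_full[free_mask] = zsub
            return -self(z_full)

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = minimize(neg, z0[free_mask], method="L-BFGS-B",
                           options={"maxiter": maxiter, "maxcor": 20})
        out = z0.copy()
        if np.isfinite(res.fun):
            out[free_mask] = res.x
        return out


def _adaptive_mwg(logpost, z0, n_iter, warmup, thin, rng, adapt_batch=25,
                  target=0.44, n_global=2, global_target=0.25, blocks=()):
    """Componentwise Gaussian random-walk Metropolis with per-coordinate
    step-size adaptation (diminishing, Roberts-Rosenthal batch rule), plus
    adaptive full-vector proposals whose covariance is learned from the
    chain history (Haario-style).  The global moves let the chain travel
    along soft ridges — e.g. admixture trading off against kernel
    amplitudes — that coordinatewise updates cross only very slowly.
    All adaptation stops at the end of warmup.
    """
    dim = z0.size
    z = z0.copy()
    lp = logpost(z)
    if not np.isfinite(lp):
        raise RuntimeError("initial point has zero posterior density")
    log_step = np.full(dim, -1.5)
    acc = np.zeros(dim)
    n_keep = (n_iter - warmup + thin - 1) // thin
    draws = np.empty((n_keep, dim))
    lps = np.empty(n_keep)
    kept = 0
    batch_no = 0
    # running moments for the global proposal covariance (Welford)
    mean = z.copy()
    m2 = np.zeros((dim, dim))
    count = 0
    chol = None
    g_logscale = math.log(2.38 / math.sqrt(dim))
    g_acc = g_tries = 0
    # correlated-block proposals (e.g. one layer's kernel parameters, which
    # trade off strongly against each other)
    blocks = [np.asarray(b, dtype=int) for b in blocks if len(b) > 1]
    b_chol = [None] * len(blocks)
    b_logscale = [math.log(2.38 / math.sqrt(len(b))) for b in blocks]
    b_acc = np.zeros(len(blocks))
    b_tries = np.zeros(len(blocks))
    for it in range(n_iter):
        eps = rng.standard_normal(dim)
        logu = np.log(rng.random(dim))
        for j in range(dim):
            zj = z[j]
            z[j] = zj + math.exp(log_step[j]) * eps[j]
            lp_new = logpost(z)
            if logu[j] < lp_new - lp:
                lp = lp_new
                acc[j] += 1
            else:
                z[j] = zj
        for bi, b in enumerate(blocks):
            if b_chol[bi] is None:
                continue
            z_new = z.copy()
            z_new[b] += math.exp(b_logscale[bi]) * (
                b_chol[bi] @ rng.standard_normal(len(b)))
            lp_new = logpost(z_new)
            b_tries[bi] += 1
            if math.log(rng.random()) < lp_new - lp:
                z = z_new
                lp = lp_new
                b_acc[bi] += 1
        if chol is not None:
            for _ in range(n_global):
                step = math.exp(g_logscale) * (chol @ rng.standard_normal(dim))
                z_new = z + step
                lp_new = logpost(z_new)
                g_tries += 1
                if math.log(rng.random()) < lp_new - lp:
                    z = z_new
                    lp = lp_new
                    g_acc += 1
        count += 1
        delta_z = z - mean
        mean += delta_z / count
        m2 += np.outer(delta_z, z - mean)
        if it < warmup:
            if (it + 1) % adapt_batch == 0:
                batch_no += 1
                delta = min(0.25, batch_no ** -0.5)
                rates = acc / adapt_batch
                log_step += np.where(rates > target, delta, -delta)
                acc[:] = 0
                if g_tries:
                    g_logscale += delta if g_acc / g_tries > global_target \
                        else -delta
                    g_acc = g_tries = 0
                for bi in range(len(blocks)):
                    if b_tries[bi]:
                        b_logscale[bi] += delta if (b_acc[bi] / b_tries[bi]
                                                    > global_target) else -delta
                b_acc[:] = 0
                b_tries[:] = 0
                if count > max(10, dim // 4):
                    cov = m2 / (count - 1) + 1e-10 * np.eye(dim)
                    try:
                        chol = np.linalg.cholesky(cov)
                    except np.linalg.LinAlgError:
                        chol = None
                    for bi, b in enumerate(blocks):
                        sub = cov[np.ix_(b, b)] + 1e-12 * np.eye(len(b))
                        try:
                            b_chol[bi] = np.linalg.cholesky(sub)
                        except np.linalg.LinAlgError:
                            b_chol[bi] = None
        else:
            if (it - warmup) % thin == 0:
                draws[kept] = z
                lps[kept] = lp
                kept += 1
    return draws[:kept], lps[:kept]


@dataclass
class PosteriorSamples:
    """Posterior draws with chain metadata.

    Arrays are stacked over chains: ``S = n_chains * draws_per_chain``.
    """

    alpha0: np.ndarray        # (S, K)
    alphaD: np.ndarray        # (S, K)
    alpha2: np.ndarray        # (S, K)
    phi: np.ndarray           # (S, K)
    w: np.ndarray             # (S, N, K)
    gamma: np.ndarray         # (S,)
    eta: np.ndarray           # (S, N)
    log_posterior: np.ndarray  # (S,)
    chain_ids: np.ndarray     # (S,)
    iteration_ids: np.ndarray  # (S,)
    spatial: bool = True
    run_config: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_draws < 1:
            raise ValueError("need at least one draw")

    @property
    def n_draws(self) -> int:
        return self.gamma.shape[0]

    @property
    def n_samples(self) -> int:
        return self.w.shape[1]

    @property
    def n_layers(self) -> int:
        return self.w.shape[2]

    @property
    def n_chains(self) -> int:
        return len(np.unique(self.chain_ids))

    def params(self, i: int) -> ModelParams:
        """The i-th draw as a ModelParams."""
        layers = [LayerParams(self.alpha0[i, k], self.alphaD[i, k],
                              float(np.clip(self.alpha2[i, k], 1e-12, 2 - 1e-12)),
                              self.phi[i, k])
                  for k in range(self.n_layers)]
        w = self.w[i] / self.w[i].sum(axis=1, keepdims=True)
        return ModelParams(layers=layers, w=w, gamma=float(self.gamma[i]),
                           eta=self.eta[i], spatial=self.spatial)

    def mean_w(self) -> np.ndarray:
        """Posterior mean admixture matrix, rows renormalized to sum to 1."""
        m = self.w.mean(axis=0)
        return m / m.sum(axis=1, keepdims=True)

    def _agg_params(self, agg) -> ModelParams:
        w = agg(self.w, axis=0)
        w = np.clip(w, 1e-12, None)
        w /= w.sum(axis=1, keepdims=True)
        layers = [LayerParams(float(agg(self.alpha0[:, k])) if self.spatial else 0.0,
                              float(agg(self.alphaD[:, k])),
                              float(np.clip(agg(self.alpha2[:, k]), 1e-9, 2 - 1e-9)),
                              float(agg(self.phi[:, k])))
                  for k in range(self.n_layers)]
        return ModelParams(layers=layers, w=w, gamma=float(agg(self.gamma)),
                           eta=agg(self.eta, axis=0), spatial=self.spatial)

    def median_params(self) -> ModelParams:
        return self._agg_params(np.median)

    def mean_params(self) -> ModelParams:
        return self._agg_params(np.mean)

    def permute_layers(self, perm) -> "PosteriorSamples":
        """Relabel layers by a permutation (new order of layer indices)."""
        perm = np.asarray(perm, dtype=int)
        if sorted(perm.tolist()) != list(range(self.n_layers)):
            raise ValueError("not a permutation of layer labels")
        return PosteriorSamples(
            self.alpha0[:, perm], self.alphaD[:, perm], self.alpha2[:, perm],
            self.phi[:, perm], self.w[:, :, perm], self.gamma, self.eta,
            self.log_posterior, self.chain_ids, self.iteration_ids,
            self.spatial, dict(self.run_config))

    def to_dataframe(self) -> pd.DataFrame:
        s, n, k = self.n_draws, self.n_samples, self.n_layers
        cols = {"chain": self.chain_ids, "iteration": self.iteration_ids,
                "log_posterior": self.log_posterior, "gamma": self.gamma}
        for j in range(k):
            cols[f"alpha0[{j}]"] = self.alpha0[:, j]
            cols[f"alphaD[{j}]"] = self.alphaD[:, j]
            cols[f"alpha2[{j}]"] = self.alpha2[:, j]
            cols[f"phi[{j}]"] = self.phi[:, j]
        for i in range(n):
            for j in range(k):
                cols[f"w[{i},{j}]"] = self.w[:, i, j]
        for i in range(n):
            cols[f"eta[{i}]"] = self.eta[:, i]
        return pd.DataFrame(cols)

    def save(self, csv_path, config_path=None) -> None:
        """Columnar CSV of draws plus a JSON sidecar of the run config."""
        self.to_dataframe().to_csv(csv_path, index=False)
        if config_path is not None:
            cfg = dict(self.run_config)
            cfg["spatial"] = bool(self.spatial)
            cfg["n_samples"] = int(self.n_samples)
            cfg["n_layers"] = int(self.n_layers)
            with open(config_path, "w") as fh:
                json.dump(cfg, fh, indent=2, default=str)

    @classmethod
    def load(cls, csv_path, config_path=None) -> "PosteriorSamples":
        df = pd.read_csv(csv_path)
        cfg = {}
        if config_path is not None:
            with open(config_path) as fh:
                cfg = json.load(fh)
        k = sum(c.startswith("alpha0[") for c in df.columns)
        n = sum(c.startswith("eta[") for c in df.columns)
        s = len(df)
        w = np.empty((s, n, k))
        for i in range(n):
            for j in range(k):
                w[:, i, j] = df[f"w[{i},{j}]"]
        get = lambda stem, m: np.column_stack(
            [df[f"{stem}[{j}]"] for j in range(m)])
        spatial = bool(cfg.get("spatial", bool(np.any(get("alpha0", k) > 0))))
        return cls(get("alpha0", k), get("alphaD", k), get("alpha2", k),
                   get("phi", k), w, df["gamma"].to_numpy(),
                   get("eta", n), df["log_posterior"].to_numpy(),
                   df["chain"].to_numpy(), df["iteration"].to_numpy(),
                   spatial, cfg)


def _stack_chains(chains, lps, transform):
    """(list of z-draw arrays per chain) -> PosteriorSamples arrays."""
    k, n = transform.k, transform.n
    all_z = np.vstack(chains)
    s = all_z.shape[0]
    alpha0 = np.zeros((s, k))
    alphaD = np.ones((s, k))
    alpha2 = np.ones((s, k))
    phi = np.empty((s, k))
    if transform.spatial:
        blk = all_z[:, :4 * k].reshape(s, k, 4)
        alpha0 = np.exp(blk[:, :, 0])
        alphaD = np.exp(blk[:, :, 1])
        alpha2 = 2.0 / (1.0 + np.exp(-blk[:, :, 2]))
        phi = np.exp(blk[:, :, 3])
    else:
        phi = np.exp(all_z[:, :k])
    if k > 1:
        w = np.empty((s, n, k))
        for i in range(s):
            w[i], _ = simplex_forward(
                all_z[i, transform._i_w:transform._i_gamma].reshape(n, k - 1))
    else:
        w = np.ones((s, n, 1))
    gamma = np.exp(all_z[:, transform._i_gamma])
    amp = alpha0 + phi  # (S, K)
    diag_total = np.exp(all_z[:, transform._i_eta:])
    eta = diag_total - gamma[:, None] - np.einsum("snk,sk->sn", w ** 2, amp)
    chain_ids = np.concatenate([np.full(len(c), ci)
                                for ci, c in enumerate(chains)])
    iter_ids = np.concatenate([np.arange(len(c)) for c in chains])
    return (alpha0, alphaD, alpha2, phi, w, gamma, eta,
            np.concatenate(lps), chain_ids, iter_ids)


def _align_chain_labels(arrays):
    (alpha0, alphaD, alpha2, phi, w, gamma, eta, lps, chain_ids,
     iter_ids) = arrays
    chains = np.unique(chain_ids)
    ref_sel = chain_ids == chains[0]
    ref_w = w[ref_sel].mean(axis=0)
    ref_w = ref_w / ref_w.sum(axis=1, keepdims=True)
    for c in chains[1:]:
        sel = chain_ids == c
        mean_w = w[sel].mean(axis=0)
        mean_w = mean_w / mean_w.sum(axis=1, keepdims=True)
        perm = match_layers(ref_w, mean_w)
        if not np.array_equal(perm, np.arange(w.shape[2])):
            w[sel] = w[sel][:, :, perm]
            alpha0[sel] = alpha0[sel][:, perm]
            alphaD[sel] = alphaD[sel][:, perm]
            alpha2[sel] = alpha2[sel][:, perm]
            phi[sel] = phi[sel][:, perm]
    return (alpha0, alphaD, alpha2, phi, w, gamma, eta, lps, chain_ids,
            iter_ids)


def fit(obs: AllelicCovariance, d: DistanceMatrix, K: int, spatial: bool = True,
        mcmc: McmcSettings | None = None, seed: int = 0,
        priors: PriorSettings | None = None,
        df: int | None = None) -> PosteriorSamples:
    """Sample the posterior for a K-layer model given an observed allelic
    covariance and pairwise distances.

    ``df`` defaults to the locus count stored in ``obs``.  Reproducible given
    ``seed``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    mcmc = mcmc or McmcSettings()
    priors = priors or PriorSettings()
    post = _LogPosterior(obs, d, K, spatial, priors, df)
    root = np.random.SeedSequence(seed)
    chain_seeds = root.spawn(mcmc.n_chains + 1)
    init_rng = np.random.default_rng(chain_seeds[-1])
    if mcmc.init == "map":
        # profile the kernel/global/nugget parameters at the clustered
        # admixture start; the admixture block itself is left to the sampler
        # (its unconstrained-space mode is Jacobian-biased along the ridge)
        z_center = post.map_estimate(post.heuristic_start(init_rng),
                                     maxiter=mcmc.map_maxiter,
                                     free_mask=post.nonadmixture_mask())
    else:
        z_center = None
    chains, lps = [], []
    # overdispersed starts: kernel/global/diagonal coordinates get a larger
    # jitter than admixture so independent chains straddle the soft ridge
    # between kernel amplitudes and admixture scale
    jitter_sd = np.full(post.transform.dim, mcmc.init_jitter)
    mask_w = ~post.nonadmixture_mask()
    jitter_sd[~mask_w] = max(mcmc.init_jitter, 0.25)
    for c in range(mcmc.n_chains):
        rng = np.random.default_rng(chain_seeds[c])
        if z_center is not None:
            z0 = z_center + jitter_sd * rng.standard_normal(post.transform.dim)
            for _ in range(20):
                if np.isfinite(post(z0)):
                    break
                z0 = z_center + jitter_sd * rng.standard_normal(
                    post.transform.dim)
            else:
                z0 = z_center.copy()
        else:
            z0 = post.prior_start(rng)
            if not np.isfinite(post(z0)):
                z0 = post.heuristic_start(rng)
        blocks = []
        if spatial:
            # each layer's kernel parameters form a tightly coupled block
            blocks = [np.arange(4 * j, 4 * j + 4) for j in range(K)]
        draws, lp = _adaptive_mwg(post, z0, mcmc.n_iter, mcmc.warmup,
                                  mcmc.thin, rng, mcmc.adapt_batch,
                                  blocks=blocks)
        chains.append(draws)
        lps.append(lp)
    arrays = _stack_chains(chains, lps, post.transform)
    if K > 1 and mcmc.n_chains > 1:
        # mixture posteriors are label-permutation invariant, so chains can
        # settle on different labelings; align every chain to the first
        arrays = _align_chain_labels(arrays)
    cfg = {"K": K, "spatial": bool(spatial), "seed": int(seed),
           "df": int(df or obs.n_loci), "priors": priors.to_dict(),
           "mcmc": mcmc.to_dict()}
    return PosteriorSamples(*arrays, spatial=spatial, run_config=cfg)


@dataclass
class ConvergenceReport:
    """Split-chain scale reduction (R-hat) and effective sample size per
    scalar parameter, with pass/fail flags."""

    table: pd.DataFrame          # columns: parameter, rhat, ess
    rhat_threshold: float
    min_ess: float
    n_chains: int
    total_draws: int

    @property
    def max_rhat(self) -> float:
        vals = self.table["rhat"].dropna()
        return float(vals.max()) if len(vals) else float("nan")

    @property
    def min_ess_observed(self) -> float:
        vals = self.table["ess"].dropna()
        return float(vals.min()) if len(vals) else float("nan")

    @property
    def rhat_pass(self) -> bool:
        vals = self.table["rhat"].dropna()
        return bool((vals < self.rhat_threshold).all()) if len(vals) else True

    @property
    def ess_pass(self) -> bool:
        vals = self.table["ess"].dropna()
        return bool((vals >= self.min_ess).all()) if len(vals) else True

    @property
    def overall_pass(self) -> bool:
        return self.rhat_pass if self.n_chains >= 2 else self.ess_pass


def _diag_arrays(ps: PosteriorSamples):
    """Posterior draws reshaped to (chain, draw, ...) for arviz, dropping
    structurally constant parameters (w at K=1; kernel parameters of the
    nonspatial model)."""
    chains = np.unique(ps.chain_ids)
    per = [np.sum(ps.chain_ids == c) for c in chains]
    m = min(per)
    out = {}

    def add(name, arr):
        stacked = np.stack([arr[ps.chain_ids == c][:m] for c in chains])
        out[name] = stacked

    add("gamma", ps.gamma)
    add("eta", ps.eta)
    add("phi", ps.phi)
    if ps.spatial:
        add("alpha0", ps.alpha0)
        add("alphaD", ps.alphaD)
        add("alpha2", ps.alpha2)
    if ps.n_layers > 1:
        add("w", ps.w)
    add("log_posterior", ps.log_posterior)
    return out


def diagnostics(ps: PosteriorSamples, rhat_threshold: float = 1.05,
                min_ess: float = 50.0) -> ConvergenceReport:
    """Split-chain R-hat and ESS via arviz.

    With a single chain only ESS is reported (split R-hat needs >= 2 chains;
    arviz still splits the one chain, which we keep as a weak check but the
    overall verdict then rests on ESS alone).
    """
    import arviz as az

    data = _diag_arrays(ps)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        idata = az.from_dict(posterior=data)
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    rows = []
    for name in data:
        r = np.asarray(rhat[name]).ravel()
        e = np.asarray(ess[name]).ravel()
        shape = data[name].shape[2:]
        idx = [()] if not shape else list(np.ndindex(*shape))
        for i, (rv, ev) in enumerate(zip(r, e)):
            suffix = "" if not shape else str(list(idx[i])).replace(" ", "")
            rows.append({"parameter": f"{name}{suffix}", "rhat": float(rv),
                         # the ESS estimator can nominally exceed the draw
                         # count for near-independent draws; cap at the bound
                         "ess": min(float(ev), float(ps.n_draws))})
    table = pd.DataFrame(rows)
    if ps.n_chains < 2:
        warnings.warn("single chain: split R-hat is unreliable; "
                      "convergence verdict uses ESS only", RuntimeWarning)
    return ConvergenceReport(table, rhat_threshold, min_ess,
                             ps.n_chains, ps.n_draws)


def _mean_w_of(x) -> np.ndarray:
    if isinstance(x, PosteriorSamples):
        return x.mean_w()
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a PosteriorSamples or an (N, K) matrix")
    return arr


def match_layers(reference, other) -> np.ndarray:
    """Permutation aligning ``other``'s layer labels to ``reference``'s.

    Greedy matching on mean admixture matrices: repeatedly pair the
    (reference layer, other layer) combination with the smallest summed
    absolute column difference.  Returns ``perm`` such that
    ``other_w[:, perm]`` lines up with ``reference_w``; if ``other`` is
    ``reference`` with columns permuted by ``p``, the result is ``p^-1``.
    """
    ref = _mean_w_of(reference)
    oth = _mean_w_of(other)
    if ref.shape != oth.shape:
        raise ValueError("reference and other must share K and sample count")
    k = ref.shape[1]
    cost = np.array([[np.abs(ref[:, a] - oth[:, b]).sum() for b in range(k)]
                     for a in range(k)])
    perm = np.full(k, -1, dtype=int)
    masked = cost.astype(float)
    for _ in range(k):
        a, b = np.unravel_index(np.argmin(masked), masked.shape)
        perm[a] = b
        masked[a, :] = np.inf
        masked[:, b] = np.inf
    return perm


def posterior_summary(ps: PosteriorSamples, scale_factor: float = 1.0,
                      ci: float = 0.95) -> pd.DataFrame:
    """Per-parameter mean, median, and central credible interval.

    Summarized admixture rows are renormalized to sum exactly to 1.  The
    inverse distance scale is reported both against normalized distances
    (``alphaD``) and in original units (``alphaD_orig = alphaD /
    scale_factor``).
    """
    lo_q, hi_q = 50 * (1 - ci), 100 - 50 * (1 - ci)
    rows = []

    def add(name, draws):
        draws = np.asarray(draws, dtype=float)
        rows.append({"parameter": name, "mean": float(draws.mean()),
                     "median": float(np.median(draws)),
                     "sd": float(draws.std()),
                     f"q{lo_q:g}": float(np.percentile(draws, lo_q)),
                     f"q{hi_q:g}": float(np.percentile(draws, hi_q))})

    add("gamma", ps.gamma)
    for k in range(ps.n_layers):
        if ps.spatial:
            add(f"alpha0[{k}]", ps.alpha0[:, k])
            add(f"alphaD[{k}]", ps.alphaD[:, k])
            add(f"alphaD_orig[{k}]", ps.alphaD[:, k] / scale_factor)
            add(f"alpha2[{k}]", ps.alpha2[:, k])
        add(f"phi[{k}]", ps.phi[:, k])
    for i in range(ps.n_samples):
        add(f"eta[{i}]", ps.eta[:, i])
    mean_w = ps.w.mean(axis=0)
    mean_w /= mean_w.sum(axis=1, keepdims=True)
    med_w = np.median(ps.w, axis=0)
    med_w = np.clip(med_w, 1e-300, None)
    med_w /= med_w.sum(axis=1, keepdims=True)
    for i in range(ps.n_samples):
        for k in range(ps.n_layers):
            rows.append({
                "parameter": f"w[{i},{k}]",
                "mean": float(mean_w[i, k]),
                "median": float(med_w[i, k]),
                "sd": float(ps.w[:, i, k].std()),
                f"q{lo_q:g}": float(np.percentile(ps.w[:, i, k], lo_q)),
                f"q{hi_q:g}": float(np.percentile(ps.w[:, i, k], hi_q)),
            })
    return pd.DataFrame(rows)


class SpatialAdmixture(BaseEstimator):
    """Joint model of discrete layers and isolation by distance.

    A Bayesian covariance model for biallelic SNP data: each sample draws
    ancestry proportions from K latent layers, within which allelic
    covariance decays with geographic distance under a powered-exponential
    kernel.  ``fit`` computes the empirical allelic covariance of the input
    frequencies and samples the posterior; with ``spatial=False`` the kernel
    amplitude is pinned at zero, giving a nonspatial assignment model whose
    likelihood is independent of the distances.

    Parameters
    ----------
    n_layers : int
        Number of layers K.
    spatial : bool
        Whether layers carry distance-dependent covariance.
    priors : PriorSettings or None
        Prior hyperparameters (defaults: unit half-Gaussian scales,
        Dirichlet concentration 1/K).
    n_chains, n_iter, warmup, thin, init, map_maxiter : sampler settings
        See :class:`McmcSettings`.
    df : int or None
        Wishart degrees of freedom override (defaults to the locus count;
        lower it to informally model linkage between loci).
    metric : {"euclidean", "great-circle"}
        Distance metric applied to ``coords`` at fit time.
    normalize_distances : bool
        Rescale distances to mean 1 (the fitted ``alphaD`` is back-reported
        in original units by :func:`posterior_summary`).
    random_state : int or None
        Seed for the sampler.

    Attributes
    ----------
    posterior_ : PosteriorSamples
    admixture_ : (N, K) posterior-mean admixture, rows summing to 1
    layer_params_ : list of LayerParams at the posterior median
    gamma_, eta_ : posterior medians
    diagnostics_ : ConvergenceReport
    omega_hat_ : AllelicCovariance used for the fit
    distances_ : DistanceMatrix used for the fit

    Examples
    --------
    >>> from spatialadmix import simulate
    >>> truth = simulate.scenario_truth("k2", seed=3, n_loci=2000)
    >>> fm, coords = simulate.scenario_data(truth)
    >>> model = SpatialAdmixture(n_layers=2, n_chains=2, n_iter=400,
    ...                          random_state=0).fit(fm.frequencies, coords)
    >>> model.admixture_.shape
    (36, 2)
    """

    def __init__(self, n_layers: int = 1, spatial: bool = True, priors=None,
                 n_chains: int = 4, n_iter: int = 2000, warmup=None,
                 thin: int = 1, init: str = "map", map_maxiter: int = 400,
                 df=None, metric: str = "euclidean",
                 normalize_distances: bool = True, random_state=None):
        self.n_layers = n_layers
        self.spatial = spatial
        self.priors = priors
        self.n_chains = n_chains
        self.n_iter = n_iter
        self.warmup = warmup
        self.thin = thin
        self.init = init
        self.map_maxiter = map_maxiter
        self.df = df
        self.metric = metric
        self.normalize_distances = normalize_distances
        self.random_state = random_state

    def _mcmc(self) -> McmcSettings:
        return McmcSettings(n_chains=self.n_chains, n_iter=self.n_iter,
                            warmup=self.warmup, thin=self.thin, init=self.init,
                            map_maxiter=self.map_maxiter)

    def _resolve_inputs(self, X, coords, distances):
        if isinstance(X, AllelicCovariance):
            obs = X
            n_feat = obs.n_loci
        else:
            if isinstance(X, FrequencyMatrix):
                fm = X
            else:
                fm = FrequencyMatrix(np.asarray(X, dtype=float))
            obs = allelic_covariance(fm)
            n_feat = fm.n_loci
        if distances is not None:
            d = distances if isinstance(distances, DistanceMatrix) \
                else DistanceMatrix(np.asarray(distances, dtype=float))
        elif coords is not None:
            d = pairwise_distances(np.asarray(coords, dtype=float),
                                   metric=self.metric,
                                   normalize=self.normalize_distances)
        elif not self.spatial:
            d = DistanceMatrix(np.zeros((obs.n_samples, obs.n_samples)))
        else:
            raise ValueError("the spatial model needs coords or distances")
        if d.n_samples != obs.n_samples:
            raise ValueError("coords/distances do not match the sample count")
        return obs, d, n_feat

    def fit(self, X, coords=None, *, distances=None):
        """Fit the model.

        Parameters
        ----------
        X : (N, L) array of frequencies, FrequencyMatrix, or AllelicCovariance
            Per-sample reference-allele frequencies at L loci (no missing
            data; run :func:`filter_missing` first), or a precomputed
            allelic covariance.
        coords : (N, 2) array, optional
            Sample coordinates ((lon, lat) for the great-circle metric).
        distances : DistanceMatrix or (N, N) array, optional
            Precomputed distances; overrides ``coords``.
        """
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        obs, d, n_feat = self._resolve_inputs(X, coords, distances)
        seed = self.random_state if self.random_state is not None else 0
        self.posterior_ = fit(obs, d, self.n_layers, self.spatial,
                              mcmc=self._mcmc(), seed=int(seed),
                              priors=self.priors or PriorSettings(),
                              df=self.df)
        self.posterior_.run_config["distance_scale_factor"] = d.scale_factor
        self.omega_hat_ = obs
        self.distances_ = d
        self.df_ = int(self.df or obs.n_loci)
        self.n_features_in_ = n_feat
        self.admixture_ = self.posterior_.mean_w()
        med = self.posterior_.median_params()
        self.layer_params_ = med.layers
        self.gamma_ = med.gamma
        self.eta_ = med.eta
        self.map_params_ = med  # posterior-median point estimate
        self.diagnostics_ = diagnostics(self.posterior_)
        return self

    def score(self, X, y=None, df=None) -> float:
        """Posterior-averaged predictive log-likelihood of held-out loci.

        ``X`` is an (N, L_test) frequency matrix (or AllelicCovariance) for
        the *same* samples; returns log of the posterior-mean Wishart
        likelihood of its allelic covariance with df = L_test.
        """
        from .modelselect import predictive_loglik
        if isinstance(X, AllelicCovariance):
            obs = X
        else:
            fm = X if isinstance(X, FrequencyMatrix) \
                else FrequencyMatrix(np.asarray(X, dtype=float))
            obs = allelic_covariance(fm)
        return predictive_loglik(self.posterior_, obs, self.distances_, df=df)

    def summary(self, ci: float = 0.95) -> pd.DataFrame:
        return posterior_summary(self.posterior_, self.distances_.scale_factor,
                                 ci=ci)
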
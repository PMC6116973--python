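"""Parametric covariance model, Wishart likelihood, and priors.

Within layer ``k`` the allelic covariance between samples ``i`` and ``j``
decays with geographic distance under a powered-exponential kernel

    G_k[i, j] = alpha0_k * exp(-(alphaD_k * D[i, j]) ** alpha2_k) + phi_k

with ``alpha0`` the covariance at zero distance above the layer background
``phi``, ``alphaD`` an inverse distance scale, and shape ``alpha2`` in (0, 2).
Samples mix the layers through admixture proportions ``w`` (rows on the
K-simplex):

    Omega[i, j] = gamma + sum_k w[i, k] * w[j, k] * G_k[i, j] + (i == j) * eta[i]

where ``gamma`` is the global covariance shared through the ancestral allele
frequency and ``eta[i]`` is a sample-specific nugget on the diagonal.
Setting ``alpha0 = 0`` in every layer removes all distance dependence and
yields the nonspatial assignment model as a special case.

The sampling model for the empirical allelic covariance ``omega_hat``
computed from ``L`` unlinked loci is Wishart:

    L * omega_hat  ~  Wishart(df=L, scale=Omega)
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky
from scipy.special import gammaln, multigammaln

from .freqdata import AllelicCovariance, DistanceMatrix

__all__ = [
    "LayerParams",
    "ModelParams",
    "ParametricCovariance",
    "PriorSettings",
    "NotPositiveDefiniteError",
    "layer_covariance",
    "admixed_covariance",
    "wishart_loglik",
    "WishartLikelihood",
    "log_prior",
]

_LOG_2PI = math.log(2.0 * math.pi)


class NotPositiveDefiniteError(ValueError):
    """A covariance matrix that should be positive definite is not."""

    def __init__(self, msg, smallest_eigenvalue=None):
        if smallest_eigenvalue is not None:
            msg = f"{msg} (smallest eigenvalue {smallest_eigenvalue:.3e})"
        super().__init__(msg)
        self.smallest_eigenvalue = smallest_eigenvalue


@dataclass
class LayerParams:
    """Powered-exponential kernel parameters for one layer."""

    alpha0: float  # covariance at zero distance above background, >= 0
    alphaD: float  # inverse distance scale, > 0
    alpha2: float  # kernel shape, in (0, 2)
    phi: float     # within-layer background covariance, >= 0

    def __post_init__(self):
        if self.alpha0 < 0:
            raise ValueError(f"alpha0 must be >= 0, got {self.alpha0}")
        if self.alphaD <= 0:
            raise ValueError(f"alphaD must be > 0, got {self.alphaD}")
        if not 0 < self.alpha2 < 2:
            raise ValueError(f"alpha2 must be in (0, 2), got {self.alpha2}")
        if self.phi < 0:
            raise ValueError(f"phi must be >= 0, got {self.phi}")


@dataclass
class ModelParams:
    """Full parameter set: K layers, admixture, global covariance, nuggets."""

    layers: list
    w: np.ndarray          # (N, K) admixture proportions, rows on the simplex
    gamma: float           # global covariance >= 0
    eta: np.ndarray        # (N,) sample-specific variances >= 0
    spatial: bool = True

    def __post_init__(self):
        self.w = np.atleast_2d(np.asarray(self.w, dtype=float))
        self.eta = np.asarray(self.eta, dtype=float)
        n, k = self.w.shape
        if len(self.layers) != k:
            raise ValueError(f"w has {k} columns but {len(self.layers)} layers given")
        if self.eta.shape != (n,):
            raise ValueError("eta length must match the number of samples")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if np.any(self.eta < 0):
            raise ValueError("eta entries must be >= 0")
        if self.w.min() < -1e-12 or self.w.max() > 1 + 1e-12:
            raise ValueError("admixture proportions must lie in [0, 1]")
        if np.any(np.abs(self.w.sum(axis=1) - 1.0) > 1e-10):
            raise ValueError("each admixture row must sum to 1 (tol 1e-10)")
        if not self.spatial:
            for lp in self.layers:
                if lp.alpha0 != 0:
                    raise ValueError("nonspatial model requires alpha0 = 0 in "
                                     "every layer")

    @property
    def n_samples(self) -> int:
        return self.w.shape[0]

    @property
    def n_layers(self) -> int:
        return self.w.shape[1]


@dataclass
class ParametricCovariance:
    """Model covariance matrix Omega; must be symmetric positive definite."""

    omega: np.ndarray

    def __post_init__(self):
        self.omega = np.asarray(self.omega, dtype=float)
        m = self.omega
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("omega must be square")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("omega must be symmetric")

    def cholesky(self) -> np.ndarray:
        """Lower Cholesky factor; raises NotPositiveDefiniteError on failure."""
        try:
            return cholesky(self.omega, lower=True, check_finite=False)
        except (np.linalg.LinAlgError, ValueError):
            lam = float(np.linalg.eigvalsh(self.omega).min())
            raise NotPositiveDefiniteError("omega is not positive definite",
                                           lam) from None


def layer_covariance(lp: LayerParams, d) -> np.ndarray:
    """Within-layer covariance G = alpha0 * exp(-(alphaD * D)^alpha2) + phi."""
    dmat = d.d if isinstance(d, DistanceMatrix) else np.asarray(d, dtype=float)
    return _kernel(lp.alpha0, lp.alphaD, lp.alpha2, lp.phi, dmat)


def _kernel(alpha0, alphaD, alpha2, phi, dmat):
    if alpha0 == 0.0:
        return np.full_like(dmat, phi)
    return alpha0 * np.exp(-((alphaD * dmat) ** alpha2)) + phi


def _omega_from_params(mp: ModelParams, dmat: np.ndarray) -> np.ndarray:
    n, k = mp.w.shape
    omega = np.full((n, n), mp.gamma)
    for j in range(k):
        g = _kernel(mp.layers[j].alpha0, mp.layers[j].alphaD,
                    mp.layers[j].alpha2, mp.layers[j].phi, dmat)
        wj = mp.w[:, j]
        omega += (wj[:, None] * wj[None, :]) * g
    omega[np.diag_indices(n)] += mp.eta
    return omega


def admixed_covariance(mp: ModelParams, d, check_pd: bool = True) -> ParametricCovariance:
    """Admixture-weighted covariance across layers plus gamma and the nugget.

    Raises :class:`NotPositiveDefiniteError` (with the smallest eigenvalue)
    if the result is not positive definite and ``check_pd`` is true; the
    matrix is never silently repaired.
    """
    dmat = d.d if isinstance(d, DistanceMatrix) else np.asarray(d, dtype=float)
    if dmat.shape[0] != mp.n_samples:
        raise ValueError("distance matrix does not match the number of samples")
    pc = ParametricCovariance(_omega_from_params(mp, dmat))
    if check_pd:
        pc.cholesky()
    return pc


class WishartLikelihood:
    """Wishart log-likelihood of ``L * omega_hat`` for varying scale Omega.

    Precomputes every term that depends only on the observed matrix and the
    degrees of freedom, so repeated evaluation inside a sampler costs one
    Cholesky factorization and one triangular solve.
    """

    def __init__(self, obs: AllelicCovariance, df: int | None = None):
        self.a = np.asarray(obs.omega_hat, dtype=float) * (df or obs.n_loci)
        self.df = int(df or obs.n_loci)
        self.n = self.a.shape[0]
        if self.df < 1:
            raise ValueError("degrees of freedom must be >= 1")
        if self.df < self.n:
            import warnings
            warnings.warn(
                f"df={self.df} < N={self.n}: the Wishart density is "
                "degenerate (fewer loci than samples)", RuntimeWarning,
                stacklevel=2)
            raise ValueError(
                f"Wishart degrees of freedom ({self.df}) below the number of "
                f"samples ({self.n}): the density is degenerate; use more "
                "loci or fewer samples")
        sign, logdet_a = np.linalg.slogdet(self.a)
        if sign <= 0:
            raise NotPositiveDefiniteError("L * omega_hat is not positive definite")
        n, df = self.n, self.df
        self.const = ((df - n - 1) / 2.0 * logdet_a
                      - df * n / 2.0 * math.log(2.0)
                      - multigammaln(df / 2.0, n))
        from scipy.linalg import get_lapack_funcs
        self._potrf, self._potrs = get_lapack_funcs(("potrf", "potrs"),
                                                    (self.a,))

    def loglik_fast(self, m: np.ndarray) -> float:
        """Unvalidated fast path: returns -inf for non-PD candidates."""
        c, info = self._potrf(m, lower=1, clean=0, overwrite_a=0)
        if info != 0:
            return -np.inf
        x, info = self._potrs(c, self.a, lower=1)
        if info != 0:
            return -np.inf
        logdet = 2.0 * np.log(np.diagonal(c)).sum()
        tr = np.trace(x)
        return self.const - self.df / 2.0 * logdet - tr / 2.0

    def loglik(self, omega) -> float:
        """log W(L*omega_hat | Omega, L) for a candidate scale matrix."""
        m = omega.omega if isinstance(omega, ParametricCovariance) else omega
        m = np.asarray(m, dtype=float)
        if m.shape != (self.n, self.n):
            raise ValueError("omega has the wrong shape")
        try:
            c, low = cho_factor(m, lower=True, check_finite=False)
        except (np.linalg.LinAlgError, ValueError):
            lam = float(np.linalg.eigvalsh(m).min())
            raise NotPositiveDefiniteError("omega is not positive definite", lam)
        logdet = 2.0 * np.log(np.diag(c)).sum()
        tr = np.sum(cho_solve((c, low), self.a, check_finite=False)
                    [np.diag_indices(self.n)])
        return float(self.const - self.df / 2.0 * logdet - tr / 2.0)


def wishart_loglik(obs: AllelicCovariance, omega, df: int | None = None) -> float:
    """Wishart log-density of the scaled empirical covariance at scale Omega.

    ``df`` defaults to the locus count stored in ``obs``; it is maximized
    over Omega at Omega = omega_hat.
    """
    m = omega.omega if isinstance(omega, ParametricCovariance) else np.asarray(omega)
    if not np.allclose(m, m.T, atol=1e-9):
        raise ValueError("omega must be symmetric")
    return WishartLikelihood(obs, df).loglik(m)


@dataclass
class PriorSettings:
    """Prior hyperparameters.

    All nonnegative parameters get half-Gaussian priors with the scales
    below (weakly informative once distances are normalized to mean 1 and
    given |omega_hat| <= 1/4); ``alpha2`` is uniform on (0, 2); each
    admixture row gets a symmetric Dirichlet whose concentration defaults to
    1/K, which is sparsity-inducing and discourages intermediate admixture,
    so unnecessary layers go unused.
    """

    scale_alpha0: float = 1.0
    scale_alphaD: float = 1.0
    scale_phi: float = 1.0
    scale_gamma: float = 1.0
    scale_eta: float = 1.0
    dirichlet_concentration: float | None = None  # None -> 1/K

    def __post_init__(self):
        for name in ("scale_alpha0", "scale_alphaD", "scale_phi",
                     "scale_gamma", "scale_eta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if (self.dirichlet_concentration is not None
                and self.dirichlet_concentration <= 0):
            raise ValueError("dirichlet_concentration must be positive")

    def concentration(self, k: int) -> float:
        return (self.dirichlet_concentration
                if self.dirichlet_concentration is not None else 1.0 / k)

    def to_dict(self) -> dict:
        return {
            "scale_alpha0": self.scale_alpha0,
            "scale_alphaD": self.scale_alphaD,
            "scale_phi": self.scale_phi,
            "scale_gamma": self.scale_gamma,
            "scale_eta": self.scale_eta,
            "dirichlet_concentration": self.dirichlet_concentration,
        }


def _half_normal_logpdf(x, scale) -> float:
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        return -np.inf
    return float(np.sum(math.log(2.0) - 0.5 * _LOG_2PI - math.log(scale)
                        - 0.5 * (x / scale) ** 2))


def _dirichlet_logpdf_rows(w: np.ndarray, conc: float) -> float:
    k = w.shape[1]
    if np.any(w <= 0) or np.any(w >= 1):
        # corners: density is +inf for conc < 1, 0 for conc > 1; treat as
        # outside the support for a proper log-density
        return -np.inf if conc >= 1 else np.inf
    lognorm = gammaln(k * conc) - k * gammaln(conc)
    return float(w.shape[0] * lognorm + (conc - 1.0) * np.log(w).sum())


def log_prior(mp: ModelParams, hyper: PriorSettings | None = None) -> float:
    """Joint log prior density of a full parameter set.

    Returns ``-inf`` outside the supports.  Layers are a priori independent
    of each other; the K=1 admixture column is degenerate and contributes 0.
    """
    hyper = hyper or PriorSettings()
    lp = 0.0
    for layer in mp.layers:
        if not 0 < layer.alpha2 < 2:
            return -np.inf
        lp += math.log(0.5)  # uniform(0, 2)
        if mp.spatial:
            lp += _half_normal_logpdf(layer.alpha0, hyper.scale_alpha0)
            lp += _half_normal_logpdf(layer.alphaD, hyper.scale_alphaD)
        lp += _half_normal_logpdf(layer.phi, hyper.scale_phi)
    lp += _half_normal_logpdf(mp.gamma, hyper.scale_gamma)
    lp += _half_normal_logpdf(mp.eta, hyper.scale_eta)
    if mp.n_layers > 1:
        lp += _dirichlet_logpdf_rows(mp.w, hyper.concentration(mp.n_layers))
    return float(lp)
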
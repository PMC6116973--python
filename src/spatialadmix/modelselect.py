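"""Model comparison: cross-validation over K and spatial flags, and layer
contributions.

Each replicate holds out a random 10% of loci, fits every candidate model to
the allelic covariance of the training loci (df = training locus count), and
scores the held-out loci by the log of the posterior-mean Wishart likelihood
of their allelic covariance (df = testing locus count).  The paired design —
all models see identical partitions — makes per-replicate differences
directly comparable.  A "best" model is annotated as the simplest one within
one standard error of the maximum, but the choice is left to the user.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .covmodel import (ModelParams, NotPositiveDefiniteError, PriorSettings,
                       WishartLikelihood, _omega_from_params)
from .freqdata import (AllelicCovariance, DistanceMatrix, FrequencyMatrix,
                       allelic_covariance)
from .inference import McmcSettings, PosteriorSamples, diagnostics
from .inference import fit as fit_posterior

__all__ = [
    "LocusPartition",
    "CVResult",
    "LayerContributions",
    "partition_loci",
    "predictive_loglik",
    "cross_validate",
    "layer_contributions",
]


@dataclass
class LocusPartition:
    """One train/test split of locus indices."""

    replicate: int
    train: np.ndarray
    test: np.ndarray
    seed: int

    def __post_init__(self):
        self.train = np.asarray(self.train, dtype=int)
        self.test = np.asarray(self.test, dtype=int)
        if np.intersect1d(self.train, self.test).size:
            raise ValueError("train and test locus sets overlap")
        if self.train.size < 1 or self.test.size < 1:
            raise ValueError("train and test sets must be non-empty")


def partition_loci(L: int, train_fraction: float = 0.9, replicates: int = 1,
                   seed: int = 0) -> list:
    """Independent uniform train/test splits of ``L`` loci.

    Each replicate keeps ``round(train_fraction * L)`` loci for training.
    Reproducible given ``seed``.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    if L < 10:
        raise ValueError("need at least 10 loci to partition")
    n_train = int(round(train_fraction * L))
    if n_train < 1:
        raise ValueError("training set would be empty")
    if n_train >= L:
        raise ValueError("testing set would be empty")
    root = np.random.SeedSequence(seed)
    out = []
    for r, ss in enumerate(root.spawn(replicates)):
        rng = np.random.default_rng(ss)
        perm = rng.permutation(L)
        out.append(LocusPartition(replicate=r, train=np.sort(perm[:n_train]),
                                  test=np.sort(perm[n_train:]), seed=seed))
    return out


def predictive_loglik(ps: PosteriorSamples, test_obs: AllelicCovariance,
                      d: DistanceMatrix, df: int | None = None,
                      method: str = "log-mean") -> float:
    """Log predictive density of a test-set allelic covariance, averaged over
    the posterior.

    ``method="log-mean"`` (default) returns the log of the posterior-mean
    likelihood, computed stably as log-mean-exp of the per-draw Wishart
    log-likelihoods; ``"mean-log"`` returns the posterior mean of the
    log-likelihood instead.
    """
    df = int(df or test_obs.n_loci)
    if df < 1:
        raise ValueError("df must be >= 1")
    wl = WishartLikelihood(test_obs, df)
    dmat = d.d
    lls = np.empty(ps.n_draws)
    for i in range(ps.n_draws):
        mp = ps.params(i)
        try:
            lls[i] = wl.loglik(_omega_from_params(mp, dmat))
        except NotPositiveDefiniteError:
            lls[i] = -np.inf
    if method == "log-mean":
        return float(logsumexp(lls) - np.log(len(lls)))
    if method == "mean-log":
        return float(np.mean(lls))
    raise ValueError(f"unknown method {method!r}")


@dataclass
class CVResult:
    """Per-replicate test log-likelihoods and per-model summaries.

    ``table`` has one row per (K, spatial, replicate); ``summary`` one row
    per model with the mean and standard error over replicates, plus a
    ``best`` annotation: the simplest model (fewest layers, nonspatial before
    spatial) within one standard error of the maximum mean.
    """

    table: pd.DataFrame
    partitions: list = field(default_factory=list)
    failed: list = field(default_factory=list)

    @property
    def summary(self) -> pd.DataFrame:
        g = (self.table.groupby(["K", "spatial"])["test_loglik"]
             .agg(["mean", "std", "count"]).reset_index())
        g["se"] = (g["std"] / np.sqrt(g["count"].clip(lower=1))).fillna(0.0)
        g = g.drop(columns="std")
        best_cut = g["mean"].max() - g.loc[g["mean"].idxmax(), "se"]
        candidates = g[g["mean"] >= best_cut]
        # simplest first: fewer layers, then nonspatial (fewer parameters)
        order = candidates.sort_values(["K", "spatial"],
                                       ascending=[True, True])
        best_idx = order.index[0]
        g["best"] = False
        g.loc[best_idx, "best"] = True
        return g

    def mean_loglik(self, K: int, spatial: bool) -> float:
        rows = self.table[(self.table["K"] == K)
                          & (self.table["spatial"] == spatial)]
        return float(rows["test_loglik"].mean())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def cross_validate(fm: FrequencyMatrix, d: DistanceMatrix, K_values,
                   spatial_flags=(True, False), replicates: int = 8,
                   train_fraction: float = 0.9,
                   mcmc: McmcSettings | None = None, seed: int = 0,
                   priors: PriorSettings | None = None,
                   check_convergence: bool = False) -> CVResult:
    """Paired cross-validation across layer numbers and spatial flags.

    Every model is fitted to the same training partitions (one posterior per
    model per replicate) and scored on the same testing loci.  Replicates
    whose fit fails convergence checks (when ``check_convergence``) are
    excluded from that model's mean and listed in ``failed``.
    """
    if fm.missing_mask.any():
        raise ValueError("cross-validation requires complete data; "
                         "run filter_missing first")
    parts = partition_loci(fm.n_loci, train_fraction, replicates, seed)
    mcmc = mcmc or McmcSettings()
    rows, failed = [], []
    fit_seed_root = np.random.SeedSequence(seed + 1)
    model_list = [(int(k), bool(s)) for k in K_values for s in spatial_flags]
    seeds = fit_seed_root.generate_state(len(model_list) * len(parts))
    si = 0
    for part in parts:
        train_fm = FrequencyMatrix(fm.frequencies[:, part.train],
                                   sample_ids=fm.sample_ids)
        test_fm = FrequencyMatrix(fm.frequencies[:, part.test],
                                  sample_ids=fm.sample_ids)
        train_obs = allelic_covariance(train_fm)
        test_obs = allelic_covariance(test_fm)
        for k, sp in model_list:
            fseed = int(seeds[si] % (2 ** 31)); si += 1
            ps = fit_posterior(train_obs, d, k, sp, mcmc=mcmc, seed=fseed,
                               priors=priors)
            ok = True
            if check_convergence:
                ok = diagnostics(ps).overall_pass
            ll = predictive_loglik(ps, test_obs, d)
            rows.append({"K": k, "spatial": sp, "replicate": part.replicate,
                         "test_loglik": ll, "converged": ok, "seed": fseed})
            if not ok:
                failed.append((k, sp, part.replicate))
    table = pd.DataFrame(rows)
    if check_convergence:
        table = table[table["converged"]]
    return CVResult(table.drop(columns="converged").reset_index(drop=True),
                    partitions=parts, failed=failed)


@dataclass
class LayerContributions:
    """Relative share of the admixture-weighted covariance per layer."""

    contributions: np.ndarray

    def __post_init__(self):
        self.contributions = np.asarray(self.contributions, dtype=float)
        if np.any(self.contributions < 0):
            raise ValueError("contributions must be nonnegative")
        if abs(self.contributions.sum() - 1.0) > 1e-10:
            raise ValueError("contributions must sum to 1")

    def __iter__(self):
        return iter(self.contributions)

    def __getitem__(self, i):
        return self.contributions[i]

    def __len__(self):
        return len(self.contributions)


def layer_contributions(mp, d: DistanceMatrix,
                        cutoff_report: float = 0.001) -> LayerContributions:
    """Each layer's relative contribution to total pairwise covariance.

    Layer k's raw mass is ``A_k = sum over pairs i<j of
    w[i,k] * w[j,k] * G_k[i,j]``, the admixture-weighted within-layer
    covariance summed over distinct sample pairs; contributions are
    ``A_k / sum(A)``.  The layer-independent global term and the diagonal
    nugget are excluded, since contributions are relative among layers.
    Layers below ``cutoff_report`` (default 0.1%) are reported in a warning,
    never dropped.  Accepts a ModelParams or a PosteriorSamples (evaluated at
    the posterior median).
    """
    if isinstance(mp, PosteriorSamples):
        mp = mp.median_params()
    if not isinstance(mp, ModelParams):
        raise TypeError("expected ModelParams or PosteriorSamples")
    dmat = d.d if isinstance(d, DistanceMatrix) else np.asarray(d, dtype=float)
    n, k = mp.w.shape
    iu = np.triu_indices(n, k=1)
    a = np.empty(k)
    for j in range(k):
        lp = mp.layers[j]
        g = lp.alpha0 * np.exp(-((lp.alphaD * dmat) ** lp.alpha2)) + lp.phi
        wj = mp.w[:, j]
        a[j] = float((np.multiply.outer(wj, wj) * g)[iu].sum())
    total = a.sum()
    if total <= 0:
        raise ValueError("all layer contributions are zero; "
                         "relative contributions are undefined")
    contrib = a / total
    low = np.nonzero(contrib < cutoff_report)[0]
    if low.size:
        import warnings
        warnings.warn(f"layers {low.tolist()} contribute less than "
                      f"{cutoff_report:.1%} of total covariance",
                      RuntimeWarning, stacklevel=2)
    return LayerContributions(contrib)
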
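"""Synthetic data with known truth.

Two generators are provided.

* The model-exact generator (:func:`simulate_frequencies`): allele-frequency
  deviations at each locus are independent between loci and multivariate
  normal across samples with mean 1/2 and the parametric covariance built
  from a known truth, so the empirical allelic covariance of its output is
  Wishart-distributed around the truth.  Used for calibration and parameter
  recovery.  Admixture surfaces over a deme lattice come from smooth Gaussian
  random fields passed through a softmax, giving spatially autocorrelated
  proportions.

* A forward-in-time lattice diffusion (:func:`simulate_lattice_ibd`): each
  deme's frequency drifts and mixes with its eight nearest neighbors
  (diagonals included) each generation, producing isolation by distance with
  no layer structure at all — a model-misspecification test bed.

Default scenario presets use a 6x6 deme lattice, 20 haploid samples per deme
and 10,000 unlinked loci.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .covmodel import LayerParams, ModelParams, NotPositiveDefiniteError
from .freqdata import DistanceMatrix, FrequencyMatrix, pairwise_distances

__all__ = [
    "SimulationTruth",
    "lattice_coords",
    "simulate_admixture_surface",
    "simulate_frequencies",
    "simulate_lattice_ibd",
    "scenario_truth",
    "scenario_data",
    "write_truth",
]

DEFAULT_GRID = (6, 6)
DEFAULT_N_LOCI = 10_000
DEFAULT_HAPLOIDS_PER_DEME = 20

# Per-layer kernel presets: deeply diverged layers (distinct decay shapes and
# backgrounds), standing in for long-separated populations.  Amplitudes are
# large enough that admixture is well identified against the 1/4-diagonal
# Wishart noise floor, yet small enough that [0, 1] truncation of the
# simulated frequencies stays a few-percent effect absorbed by the amplitude
# parameters.
_LAYER_PRESETS = [
    LayerParams(alpha0=0.040, alphaD=0.7, alpha2=1.3, phi=0.025),
    LayerParams(alpha0=0.030, alphaD=2.0, alpha2=0.8, phi=0.010),
    LayerParams(alpha0=0.035, alphaD=1.2, alpha2=1.0, phi=0.018),
]
_GAMMA = 0.008
_ETA = 0.003


@dataclass
class SimulationTruth:
    """Ground truth behind one synthetic dataset."""

    grid: tuple
    coords: np.ndarray
    params: ModelParams
    seed: int
    n_loci: int = DEFAULT_N_LOCI
    haploids_per_deme: int = DEFAULT_HAPLOIDS_PER_DEME

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (self.params.n_samples, 2):
            raise ValueError("coords must be (N, 2) matching the parameters")
        if self.n_loci < 1 or self.haploids_per_deme < 1:
            raise ValueError("n_loci and haploids_per_deme must be positive")


def lattice_coords(grid) -> np.ndarray:
    """Unit-spaced deme coordinates of an (nx, ny) lattice, row-major."""
    nx, ny = grid
    if nx < 1 or ny < 1:
        raise ValueError("lattice dimensions must be positive")
    xx, yy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    return np.column_stack([xx.ravel(), yy.ravel()]).astype(float)


def simulate_admixture_surface(grid, K: int, smoothness: float = 1.5,
                               intensity: float = 6.0, residual: float = 0.03,
                               min_presence: float = 0.5,
                               seed: int = 0) -> np.ndarray:
    """Spatially autocorrelated admixture proportions on a deme lattice.

    Draws K Gaussian random fields over the lattice with squared-exponential
    correlation ``exp(-d^2 / (2 * smoothness^2))``, scales them by
    ``intensity`` and passes them through a per-deme softmax, so each row
    lies on the K-simplex and nearby demes get similar proportions.  The
    default intensity gives corner-heavy surfaces — most demes draw nearly
    all their ancestry from one layer, with admixture concentrated in
    contact zones.  ``residual`` mixes in a uniform trace of every layer
    (``w <- (1 - residual) * w + residual / K``): no deme is ever exactly
    pure, keeping the truth in the simplex interior.  Fields are redrawn
    until every layer reaches proportion ``min_presence`` in at least one
    deme, so a K-layer scenario really contains K layers rather than a
    ghost layer present nowhere.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if smoothness <= 0:
        raise ValueError("smoothness must be positive")
    if not 0 <= residual < 1:
        raise ValueError("residual must be in [0, 1)")
    coords = lattice_coords(grid)
    n = coords.shape[0]
    if K == 1:
        return np.ones((n, 1))
    rng = np.random.default_rng(seed)
    d = squareform(pdist(coords))
    cov = np.exp(-(d ** 2) / (2.0 * smoothness ** 2)) + 1e-8 * np.eye(n)
    chol = np.linalg.cholesky(cov)
    for _ in range(200):
        fields = chol @ rng.standard_normal((n, K))
        logits = intensity * fields
        logits -= logits.max(axis=1, keepdims=True)
        w = np.exp(logits)
        w /= w.sum(axis=1, keepdims=True)
        if w.max(axis=0).min() >= min_presence:
            return (1.0 - residual) * w + residual / K
    raise RuntimeError("could not draw a surface where every layer is "
                       "present; lower min_presence or K")


def simulate_frequencies(truth: SimulationTruth, d: DistanceMatrix | None = None,
                         binomial_resample: bool = False,
                         rng=None) -> FrequencyMatrix:
    """Draw allele frequencies locus by locus from the covariance model.

    Each locus is an independent N-vector from a multivariate normal with
    mean 1/2 and covariance Omega(truth), truncated to [0, 1].  With
    ``binomial_resample`` the latent frequencies are resampled binomially
    down to ``truth.haploids_per_deme`` allele copies per deme, emulating
    finite sampling.
    """
    from .covmodel import admixed_covariance

    if d is None:
        d = pairwise_distances(truth.coords, normalize=True)
    omega = admixed_covariance(truth.params, d, check_pd=True).omega
    try:
        chol = np.linalg.cholesky(omega)
    except np.linalg.LinAlgError:
        lam = float(np.linalg.eigvalsh(omega).min())
        raise NotPositiveDefiniteError("truth covariance is not positive "
                                       "definite", lam)
    if rng is None:
        # child stream: keeps locus noise independent of the admixture
        # surface, which is drawn from the parent seed
        rng = np.random.default_rng(np.random.SeedSequence(truth.seed).spawn(1)[0])
    n = omega.shape[0]
    z = rng.standard_normal((n, truth.n_loci))
    freqs = 0.5 + chol @ z
    np.clip(freqs, 0.0, 1.0, out=freqs)
    if binomial_resample:
        counts = rng.binomial(truth.haploids_per_deme, freqs)
        freqs = counts / truth.haploids_per_deme
    return FrequencyMatrix(freqs,
                           ploidy_counts=np.full(n, truth.haploids_per_deme))


def _neighbor_matrix(grid) -> np.ndarray:
    """Row-normalized eight-neighbor (diagonals included) adjacency."""
    nx, ny = grid
    n = nx * ny
    adj = np.zeros((n, n))
    for i in range(nx):
        for j in range(ny):
            a = i * ny + j
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == 0 and dj == 0:
                        continue
                    ii, jj = i + di, j + dj
                    if 0 <= ii < nx and 0 <= jj < ny:
                        adj[a, ii * ny + jj] = 1.0
    return adj


def simulate_lattice_ibd(grid=DEFAULT_GRID, generations: int = 100,
                         migration: float = 0.05, drift: float = 0.05,
                         L: int = DEFAULT_N_LOCI, seed: int = 0,
                         ancestral_range=(0.3, 0.7)) -> FrequencyMatrix:
    """Forward-in-time drift-migration diffusion on a deme lattice.

    Every locus starts at a common ancestral frequency (uniform in
    ``ancestral_range``; its variance across loci shows up downstream as
    global covariance).  Each generation every deme's frequency moves a
    fraction ``migration`` of the way toward the mean of its eight nearest
    neighbors (diagonals included) and receives independent Gaussian drift
    noise with standard deviation ``drift``, clipped to [0, 1].  The result
    is pure isolation by distance: covariance decays with lattice distance
    and there is no layer structure.
    """
    nx, ny = grid
    if nx * ny < 1:
        raise ValueError("empty lattice")
    if not 0 <= migration < 1:
        raise ValueError("migration rate must be in [0, 1)")
    if drift < 0:
        raise ValueError("drift rate must be nonnegative")
    if generations < 1:
        raise ValueError("generations must be >= 1")
    adj = _neighbor_matrix(grid)
    deg = adj.sum(axis=1, keepdims=True)
    nbr = adj / np.maximum(deg, 1.0)
    rng = np.random.default_rng(seed)
    lo, hi = ancestral_range
    f = np.broadcast_to(rng.uniform(lo, hi, L), (nx * ny, L)).copy()
    for _ in range(generations):
        f = (1.0 - migration) * f + migration * (nbr @ f)
        f += drift * rng.standard_normal(f.shape)
        np.clip(f, 0.0, 1.0, out=f)
    return FrequencyMatrix(f)


def scenario_truth(name: str = "k2", seed: int = 0, grid=DEFAULT_GRID,
                   n_loci: int = DEFAULT_N_LOCI,
                   haploids_per_deme: int = DEFAULT_HAPLOIDS_PER_DEME,
                   smoothness: float = 1.5) -> SimulationTruth:
    """Preset truths named k1/k2/k3: K layers merged on one lattice with
    spatially autocorrelated admixture."""
    presets = {"k1": 1, "k2": 2, "k3": 3}
    if name not in presets:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(presets)}")
    k = presets[name]
    coords = lattice_coords(grid)
    n = coords.shape[0]
    w = simulate_admixture_surface(grid, k, smoothness=smoothness, seed=seed)
    params = ModelParams(layers=[_LAYER_PRESETS[j] for j in range(k)],
                         w=w, gamma=_GAMMA, eta=np.full(n, _ETA), spatial=True)
    return SimulationTruth(grid=tuple(grid), coords=coords, params=params,
                           seed=seed, n_loci=n_loci,
                           haploids_per_deme=haploids_per_deme)


def scenario_data(truth: SimulationTruth, binomial_resample: bool = False):
    """(FrequencyMatrix, coords) for a preset truth."""
    fm = simulate_frequencies(truth, binomial_resample=binomial_resample)
    return fm, truth.coords.copy()


def write_truth(truth: SimulationTruth, path) -> None:
    """Serialize a SimulationTruth to JSON for recovery scoring."""
    mp = truth.params
    payload = {
        "grid": list(truth.grid),
        "coords": truth.coords.tolist(),
        "seed": int(truth.seed),
        "n_loci": int(truth.n_loci),
        "haploids_per_deme": int(truth.haploids_per_deme),
        "spatial": bool(mp.spatial),
        "gamma": float(mp.gamma),
        "eta": mp.eta.tolist(),
        "w": mp.w.tolist(),
        "layers": [{"alpha0": lp.alpha0, "alphaD": lp.alphaD,
                    "alpha2": lp.alpha2, "phi": lp.phi} for lp in mp.layers],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def read_truth(path) -> SimulationTruth:
    with open(path) as fh:
        p = json.load(fh)
    layers = [LayerParams(**lp) for lp in p["layers"]]
    mp = ModelParams(layers=layers, w=np.array(p["w"]), gamma=p["gamma"],
                     eta=np.array(p["eta"]), spatial=p["spatial"])
    return SimulationTruth(grid=tuple(p["grid"]), coords=np.array(p["coords"]),
                           params=mp, seed=p["seed"], n_loci=p["n_loci"],
                           haploids_per_deme=p["haploids_per_deme"])
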
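"""Bijections between constrained model parameters and an unconstrained vector.

Positive parameters map through log, the kernel shape through a scaled
logistic onto (0, 2), and each admixture row through the stick-breaking
simplex transform (with the centering offsets that make the zero vector map
to the barycenter).  Log-Jacobian terms are returned so densities can be
evaluated in unconstrained space.
"""

from __future__ import annotations

import numpy as np

from .covmodel import LayerParams, ModelParams


def _sigmoid(x):
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def simplex_forward(z: np.ndarray):
    """Stick-breaking map: (R, K-1) unconstrained -> (R, K) simplex rows.

    Returns (w, log_jacobian_per_row_summed).
    """
    z = np.atleast_2d(z)
    r, km1 = z.shape
    k = km1 + 1
    if k == 2:  # common case: one logistic coordinate per row
        v = _sigmoid(z[:, 0])
        v = np.clip(v, 1e-15, 1 - 1e-15)
        w = np.empty((r, 2))
        w[:, 0] = v
        w[:, 1] = 1.0 - v
        return w, float(np.sum(np.log(v) + np.log1p(-v)))
    offsets = -np.log(k - 1 - np.arange(km1))  # zero maps to the barycenter
    w = np.empty((r, k))
    stick = np.ones(r)
    logj = 0.0
    for i in range(km1):
        v = _sigmoid(z[:, i] + offsets[i])
        v = np.clip(v, 1e-15, 1 - 1e-15)
        w[:, i] = stick * v
        logj += float(np.sum(np.log(v) + np.log1p(-v) + np.log(stick)))
        stick = stick * (1.0 - v)
    w[:, -1] = stick
    return w, logj


def simplex_backward(w: np.ndarray) -> np.ndarray:
    """Inverse stick-breaking: (R, K) simplex rows -> (R, K-1) unconstrained."""
    w = np.atleast_2d(np.asarray(w, dtype=float))
    w = np.clip(w, 1e-12, None)
    w = w / w.sum(axis=1, keepdims=True)
    r, k = w.shape
    z = np.empty((r, k - 1))
    stick = np.ones(r)
    for i in range(k - 1):
        v = np.clip(w[:, i] / stick, 1e-12, 1 - 1e-12)
        z[:, i] = np.log(v) - np.log1p(-v) + np.log(k - 1 - i)
        stick = stick * (1.0 - v)
    return z


class ParamTransform:
    """Packs/unpacks ModelParams to/from a flat unconstrained vector.

    Spatial model, per layer: [log alpha0, log alphaD, logit(alpha2/2)-ish,
    log phi]; nonspatial: [log phi] only (alpha0 pinned at 0, alphaD/alpha2
    held at inert constants since the likelihood ignores them).  Then the
    N*(K-1) stick-breaking coordinates of w (absent for K=1), log gamma, and
    N diagonal coordinates.

    The last block parameterizes each sample's *total model diagonal*
    ``d_i = gamma + sum_k w_ik^2 (alpha0_k + phi_k) + eta_i`` as ``log d_i``
    rather than ``log eta_i``.  The observed diagonal is fixed at 1/4, which
    pins ``d_i`` very tightly; sampling ``d_i`` directly decouples the
    kernel amplitudes from the nugget (otherwise every amplitude move needs
    a compensating nugget move and the chain crawls).  Points where the
    implied ``eta_i`` would be negative are outside the support.
    """

    def __init__(self, n_samples: int, n_layers: int, spatial: bool = True):
        self.n = int(n_samples)
        self.k = int(n_layers)
        self.spatial = bool(spatial)
        self.per_layer = 4 if spatial else 1
        self.n_w = self.n * (self.k - 1)
        self.dim = self.per_layer * self.k + self.n_w + 1 + self.n
        self._i_w = self.per_layer * self.k
        self._i_gamma = self._i_w + self.n_w
        self._i_eta = self._i_gamma + 1

    def labels(self) -> list:
        out = []
        for k in range(self.k):
            if self.spatial:
                out += [f"alpha0[{k}]", f"alphaD[{k}]", f"alpha2[{k}]",
                        f"phi[{k}]"]
            else:
                out += [f"phi[{k}]"]
        for i in range(self.n):
            for k in range(self.k - 1):
                out.append(f"w_stick[{i},{k}]")
        out.append("gamma")
        out += [f"eta[{i}]" for i in range(self.n)]
        return out

    def to_params(self, z: np.ndarray) -> ModelParams:
        return self.to_params_logjac(z)[0]

    def to_params_logjac(self, z: np.ndarray):
        """Unconstrained vector -> (ModelParams, log |d theta / d z|)."""
        z = np.asarray(z, dtype=float)
        if z.shape != (self.dim,):
            raise ValueError(f"expected vector of length {self.dim}")
        logj = 0.0
        layers = []
        for k in range(self.k):
            base = k * self.per_layer
            if self.spatial:
                a0, ad, a2z, ph = z[base:base + 4]
                alpha0, alphaD, phi = np.exp([a0, ad, ph])
                s = 1.0 / (1.0 + np.exp(-a2z))
                alpha2 = 2.0 * s
                logj += a0 + ad + ph + np.log(2.0) + np.log(s) + np.log1p(-s)
                # guard exact boundary values that exact-zero floats can hit
                alpha2 = min(max(alpha2, 1e-12), 2 - 1e-12)
                layers.append(LayerParams(alpha0, alphaD, alpha2, phi))
            else:
                ph = z[base]
                logj += ph
                layers.append(LayerParams(0.0, 1.0, 1.0, np.exp(ph)))
        if self.k > 1:
            zw = z[self._i_w:self._i_gamma].reshape(self.n, self.k - 1)
            w, lj = simplex_forward(zw)
            logj += lj
        else:
            w = np.ones((self.n, 1))
        zg = z[self._i_gamma]
        gamma = np.exp(zg)
        logj += zg
        ze = z[self._i_eta:]
        diag_total = np.exp(ze)
        logj += float(ze.sum())
        amp = np.array([lp.alpha0 + lp.phi for lp in layers])
        eta = diag_total - gamma - (w ** 2) @ amp
        if np.any(eta <= 0):
            raise ValueError("implied nugget is nonpositive (outside support)")
        mp = ModelParams(layers=layers, w=w, gamma=float(gamma), eta=eta,
                         spatial=self.spatial)
        return mp, float(logj)

    def from_params(self, mp: ModelParams) -> np.ndarray:
        if mp.n_samples != self.n or mp.n_layers != self.k:
            raise ValueError("ModelParams shape does not match the transform")
        z = np.empty(self.dim)
        for k, lp in enumerate(mp.layers):
            base = k * self.per_layer
            if self.spatial:
                z[base] = np.log(max(lp.alpha0, 1e-12))
                z[base + 1] = np.log(lp.alphaD)
                s = np.clip(lp.alpha2 / 2.0, 1e-12, 1 - 1e-12)
                z[base + 2] = np.log(s) - np.log1p(-s)
                z[base + 3] = np.log(max(lp.phi, 1e-12))
            else:
                z[base] = np.log(max(lp.phi, 1e-12))
        if self.k > 1:
            z[self._i_w:self._i_gamma] = simplex_backward(mp.w).ravel()
        z[self._i_gamma] = np.log(max(mp.gamma, 1e-12))
        amp = np.array([lp.alpha0 + lp.phi for lp in mp.layers])
        diag_total = mp.gamma + (mp.w ** 2) @ amp + mp.eta
        z[self._i_eta:] = np.log(np.maximum(diag_total, 1e-12))
        return z
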
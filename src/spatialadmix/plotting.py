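"""Figures: admixture pie maps, covariance-decay curves, CV comparison,
and layer-contribution bars.

All plots are built from serialized run outputs (posterior draws, CV tables),
so figures can be regenerated without refitting.
"""

from __future__ import annotations

import numpy as np

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .covmodel import layer_covariance
from .freqdata import AllelicCovariance, DistanceMatrix
from .inference import PosteriorSamples

__all__ = [
    "layer_colors",
    "admixture_map",
    "covariance_decay_plot",
    "cv_plot",
    "contribution_bars",
]


def layer_colors(k: int):
    cmap = plt.get_cmap("tab10")
    return [cmap(i % 10) for i in range(k)]


def admixture_map(w: np.ndarray, coords: np.ndarray, ax=None, colors=None,
                  pie_radius: float | None = None):
    """One pie chart per sampling location showing admixture proportions.

    A K=1 matrix yields single-color disks.
    """
    w = np.atleast_2d(np.asarray(w, dtype=float))
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] != w.shape[0]:
        raise ValueError("coords and admixture matrix disagree on N")
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    k = w.shape[1]
    colors = colors or layer_colors(k)
    if pie_radius is None:
        span = max(np.ptp(coords[:, 0]), np.ptp(coords[:, 1]), 1.0)
        pie_radius = 0.03 * span
    for i in range(w.shape[0]):
        start = 0.0
        for j in range(k):
            frac = w[i, j]
            if frac <= 0:
                continue
            theta = np.linspace(2 * np.pi * start,
                                2 * np.pi * (start + frac), 30)
            xs = np.concatenate([[coords[i, 0]],
                                 coords[i, 0] + pie_radius * np.cos(theta)])
            ys = np.concatenate([[coords[i, 1]],
                                 coords[i, 1] + pie_radius * np.sin(theta)])
            ax.fill(xs, ys, color=colors[j], lw=0)
            start += frac
    ax.set_aspect("equal")
    ax.set_xlabel("x / longitude")
    ax.set_ylabel("y / latitude")
    ax.set_title("Admixture proportions by sampling location")
    return ax


def covariance_decay_plot(ps: PosteriorSamples, d: DistanceMatrix,
                          obs: AllelicCovariance | None = None, ax=None,
                          n_bins: int = 10, colors=None):
    """Per-layer covariance-vs-distance curves at the posterior median,
    overlaying the binned empirical allelic covariance when given."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    med = ps.median_params()
    dmax = float(d.d.max()) or 1.0
    xs = np.linspace(0.0, dmax, 200)
    colors = colors or layer_colors(ps.n_layers)
    for k, lp in enumerate(med.layers):
        g = layer_covariance(lp, xs.reshape(1, -1)).ravel()
        ax.plot(xs * d.scale_factor, g, color=colors[k], label=f"layer {k + 1}")
    if obs is not None:
        off = ~np.eye(d.n_samples, dtype=bool)
        dist = d.d[off]
        cov = obs.omega_hat[off]
        edges = np.linspace(0, dmax, n_bins + 1)
        mids, means = [], []
        for lo, hi in zip(edges[:-1], edges[1:]):
            sel = (dist >= lo) & (dist < hi if hi < dmax else dist <= hi)
            if sel.any():
                mids.append((lo + hi) / 2)
                means.append(cov[sel].mean())
        ax.plot(np.array(mids) * d.scale_factor, means, "ko", ms=4,
                label="binned empirical")
    ax.set_xlabel("geographic distance"
                  + (" (original units)" if d.scale_factor != 1 else ""))
    ax.set_ylabel("allelic covariance")
    ax.legend(frameon=False)
    return ax


def cv_plot(cv_table, ax=None):
    """Predictive accuracy versus number of layers, spatial and nonspatial
    series, with one standard error bars."""
    import pandas as pd
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    df = pd.DataFrame(cv_table)
    for sp, label, color in ((True, "spatial", "tab:blue"),
                             (False, "nonspatial", "tab:green")):
        sub = df[df["spatial"] == sp]
        if sub.empty:
            continue
        g = sub.groupby("K")["test_loglik"].agg(["mean", "std", "count"])
        se = g["std"] / np.sqrt(g["count"].clip(lower=1))
        ax.errorbar(g.index, g["mean"], yerr=se, marker="o", color=color,
                    label=label, capsize=3)
    ax.set_xlabel("number of layers K")
    ax.set_ylabel("held-out predictive log-likelihood")
    ax.legend(frameon=False)
    return ax


def contribution_bars(contribs_by_k: dict, ax=None, colors=None):
    """Stacked bars of layer contributions for each fitted K.

    ``contribs_by_k`` maps K -> sequence of K contributions summing to 1.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ks = sorted(contribs_by_k)
    kmax = max(len(np.atleast_1d(contribs_by_k[k])) for k in ks)
    colors = colors or layer_colors(kmax)
    for x, k in enumerate(ks):
        vals = np.sort(np.atleast_1d(np.asarray(contribs_by_k[k],
                                                dtype=float)))[::-1]
        bottom = 0.0
        for j, v in enumerate(vals):
            ax.bar(x, v, bottom=bottom, color=colors[j], width=0.7)
            bottom += v
    ax.set_xticks(range(len(ks)))
    ax.set_xticklabels([str(k) for k in ks])
    ax.set_xlabel("number of layers K")
    ax.set_ylabel("layer contribution to covariance")
    ax.set_ylim(0, 1.02)
    return ax
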
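"""Multi-view feature fusion: one vector per patient from V view vectors.

Three fusion families reduce a patient's views x channels feature matrix
to a single vector:

* statistical summaries — channel-wise max / mean / median / population
  standard deviation over the views;
* a linear transformation — per-channel one-component independent
  component analysis across the cohort, summarizing each channel's V view
  values into one value through a learned length-V unmixing vector;
* a non-linear transformation — an autoencoder on the flattened V*C
  input whose bottleneck activation is the fused vector.

The fitted fusions (ICA, autoencoder) are estimated on training-fold
patients only and applied unchanged to held-out patients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .deep_features import FeatureMatrix

__all__ = [
    "FusedFeatureVector",
    "FusionModel",
    "STAT_FUSIONS",
    "fuse_statistical",
    "fit_ica_fusion",
    "apply_ica_fusion",
    "fit_autoencoder_fusion",
    "apply_autoencoder_fusion",
]

STAT_FUSIONS = ("cw_mean", "cw_median", "cw_max", "cw_std")


@dataclass
class FusedFeatureVector:
    values: np.ndarray
    fusion_id: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError(f"fused vector must be 1D, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("fused vector contains non-finite values")


@dataclass
class FusionModel:
    """Fitted parameters of a learned fusion plus fit metadata."""

    fusion_id: str
    params: dict[str, Any]
    seed: int
    meta: dict[str, Any] = field(default_factory=dict)


def _values(m) -> np.ndarray:
    return m.values if isinstance(m, FeatureMatrix) else np.asarray(m, dtype=np.float64)


def fuse_statistical(m, stat: str) -> FusedFeatureVector:
    """Channel-wise statistical summary over views.

    ``cw_std`` uses the population (divide-by-N) convention; with a single
    view it is a zero vector while the other statistics return the row.
    """
    x = _values(m)
    if x.shape[0] < 1:
        raise ValueError("need at least one view")
    if stat == "cw_mean":
        out = x.mean(axis=0)
    elif stat == "cw_median":
        out = np.median(x, axis=0)
    elif stat == "cw_max":
        out = x.max(axis=0)
    elif stat == "cw_std":
        out = x.std(axis=0)
    else:
        raise ValueError(f"unknown statistical fusion {stat!r}; expected one of {STAT_FUSIONS}")
    return FusedFeatureVector(out, stat)


# ---------------------------------------------------------------------------
# Per-channel ICA fusion
# ---------------------------------------------------------------------------

def fit_ica_fusion(cohort: list, seed: int, max_iter: int = 500) -> FusionModel:
    """Fit a one-component ICA per channel across the cohort.

    For channel c the cohort forms an N x V matrix (patients x views) of
    that channel's view values; a single independent component estimated
    on it gives a length-V unmixing vector that summarizes the V view
    cells of channel c into one value. The unmixing vector is unit-norm
    with its sign fixed so the fused values correlate non-negatively with
    the channel's cross-view mean. Channels with zero variance bypass ICA
    with a uniform 1/V vector (reproducing the constant); non-convergence
    falls back to the first principal direction and is recorded in the
    fit metadata.
    """
    if len(cohort) < 2:
        raise ValueError("ICA fusion needs at least 2 patients")
    mats = [_values(m) for m in cohort]
    v, c = mats[0].shape
    if any(m.shape != (v, c) for m in mats):
        raise ValueError("all cohort feature matrices must share (V, C)")
    data = np.stack(mats)  # (N, V, C)
    unmixing = np.empty((c, v))
    fallbacks = []
    for ch in range(c):
        x = data[:, :, ch]  # N x V
        if np.allclose(x.std(), 0.0):
            w = np.full(v, 1.0 / v)
        else:
            xc = x - x.mean(axis=0)
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always", ConvergenceWarning)
                ica = FastICA(
                    n_components=1,
                    random_state=seed,
                    max_iter=max_iter,
                    whiten="unit-variance",
                )
                try:
                    ica.fit(x)
                    converged = not any(
                        issubclass(wrn.category, ConvergenceWarning) for wrn in caught
                    )
                except ValueError:
                    converged = False
            if converged:
                w = ica.components_[0]
            else:  # first principal direction of the centered channel matrix
                _, _, vt = np.linalg.svd(xc, full_matrices=False)
                w = vt[0]
                fallbacks.append(ch)
            norm = np.linalg.norm(w)
            w = w / norm if norm > 0 else np.full(v, 1.0 / v)
            # sign indeterminacy: align with the cross-view mean
            fused = x @ w
            ref = x.mean(axis=1)
            if np.std(fused) > 0 and np.std(ref) > 0 and np.corrcoef(fused, ref)[0, 1] < 0:
                w = -w
        unmixing[ch] = w
    return FusionModel(
        "ica",
        {"unmixing": unmixing, "n_views": v, "n_channels": c},
        seed,
        meta={"pca_fallback_channels": fallbacks, "n_patients": len(cohort)},
    )


def apply_ica_fusion(model: FusionModel, m) -> FusedFeatureVector:
    """Apply fitted per-channel unmixing: out[c] = w_c . column_c(m)."""
    if model.fusion_id != "ica":
        raise ValueError(f"expected an ICA fusion model, got {model.fusion_id!r}")
    x = _values(m)
    unmixing = model.params["unmixing"]
    if x.shape != (model.params["n_views"], model.params["n_channels"]):
        raise ValueError(
            f"matrix shape {x.shape} does not match fitted "
            f"({model.params['n_views']}, {model.params['n_channels']})"
        )
    return FusedFeatureVector(np.einsum("cv,vc->c", unmixing, x), "ica")


# ---------------------------------------------------------------------------
# Autoencoder fusion
# ---------------------------------------------------------------------------

def _init_ae(d: int, latent: int, rng: np.random.Generator):
    w1 = rng.standard_normal((d, latent)) * np.sqrt(1.0 / d)
    b1 = np.zeros(latent)
    w2 = rng.standard_normal((latent, d)) * np.sqrt(1.0 / latent)
    b2 = np.zeros(d)
    return [w1, b1, w2, b2]


def fit_autoencoder_fusion(
    cohort: list,
    latent_dim: int = 256,
    seed: int = 0,
    epochs: int = 200,
    lr: float = 1e-2,
) -> FusionModel:
    """Train an autoencoder on the cohort's flattened V*C inputs.

    Single hidden (bottleneck) layer: encoder D -> L, decoder L -> D,
    mean-squared reconstruction loss, full-batch Adam, seeded
    initialization. Inputs are feature-standardized inside the model (the
    scaling is stored and reapplied at inference). The bottleneck is
    linear, so with an adequate latent size the code converges toward the
    best linear (PCA-like) subspace — a deliberate choice for stable,
    reproducible fits on modest cohorts.
    """
    if len(cohort) < 2:
        raise ValueError("autoencoder fusion needs at least 2 patients")
    mats = [_values(m) for m in cohort]
    v, c = mats[0].shape
    if any(m.shape != (v, c) for m in mats):
        raise ValueError("all cohort feature matrices must share (V, C)")
    d = v * c
    if latent_dim >= d:
        raise ValueError(f"latent_dim ({latent_dim}) must be < V*C ({d})")
    x = np.stack([m.reshape(-1) for m in mats])  # N x D
    mu = x.mean(axis=0)
    sigma = x.std(axis=0)
    sigma = np.where(sigma > 0, sigma, 1.0)
    xs = (x - mu) / sigma
    rng = np.random.default_rng(seed)
    params = _init_ae(d, latent_dim, rng)
    m_adam = [np.zeros_like(p) for p in params]
    v_adam = [np.zeros_like(p) for p in params]
    b1a, b2a, eps = 0.9, 0.999, 1e-8
    n = xs.shape[0]
    for t in range(1, epochs + 1):
        w1, bb1, w2, bb2 = params
        z = xs @ w1 + bb1
        recon = z @ w2 + bb2
        err = recon - xs
        # gradients of mean squared error over all N*D entries
        g_out = 2.0 * err / (n * d)
        grads = [
            xs.T @ (g_out @ w2.T),
            (g_out @ w2.T).sum(axis=0),
            z.T @ g_out,
            g_out.sum(axis=0),
        ]
        for i, g in enumerate(grads):
            m_adam[i] = b1a * m_adam[i] + (1 - b1a) * g
            v_adam[i] = b2a * v_adam[i] + (1 - b2a) * g * g
            mhat = m_adam[i] / (1 - b1a**t)
            vhat = v_adam[i] / (1 - b2a**t)
            params[i] = params[i] - lr * mhat / (np.sqrt(vhat) + eps)
    w1, bb1, w2, bb2 = params
    z = xs @ w1 + bb1
    final_loss = float(np.mean((z @ w2 + bb2 - xs) ** 2))
    return FusionModel(
        "autoencoder",
        {
            "w1": w1, "b1": bb1, "w2": w2, "b2": bb2,
            "input_mean": mu, "input_scale": sigma,
            "n_views": v, "n_channels": c, "latent_dim": latent_dim,
        },
        seed,
        meta={"epochs": epochs, "lr": lr, "final_mse": final_loss, "n_patients": n},
    )


def apply_autoencoder_fusion(model: FusionModel, m) -> FusedFeatureVector:
    """Encode a patient's flattened feature matrix to the latent vector."""
    if model.fusion_id != "autoencoder":
        raise ValueError(f"expected an autoencoder fusion model, got {model.fusion_id!r}")
    x = _values(m)
    p = model.params
    if x.shape != (p["n_views"], p["n_channels"]):
        raise ValueError(
            f"matrix shape {x.shape} does not match fitted ({p['n_views']}, {p['n_channels']})"
        )
    xs = (x.reshape(-1) - p["input_mean"]) / p["input_scale"]
    return FusedFeatureVector(xs @ p["w1"] + p["b1"], "autoencoder")


def reconstruct_autoencoder(model: FusionModel, m) -> np.ndarray:
    """Decode back to the (V, C) input space; used for reconstruction checks."""
    p = model.params
    fused = apply_autoencoder_fusion(model, m).values
    recon = fused @ p["w2"] + p["b2"]
    return (recon * p["input_scale"] + p["input_mean"]).reshape(p["n_views"], p["n_channels"])
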
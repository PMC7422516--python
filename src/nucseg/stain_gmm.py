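"""Gaussian-mixture stain color modeling and template-based normalization.

An H&E image's pixel colors are modeled as a K-class Gaussian mixture
(default K=3: nuclei, surrounding tissue, background). The mixture is fitted
with classical expectation-maximization on the pixel cloud; the per-pixel
responsibilities it yields are the default *posterior provider*. Any other
provider (e.g. a learned segmentation network) can be plugged in, because
the color-transfer step only needs per-class Gaussians plus per-pixel
responsibilities — the transfer math is identical either way.

Color transfer maps each pixel through a responsibility-weighted mixture of
per-class whitening/recoloring maps:

    x' = sum_k  gamma_k [ S_k (x - mu_k_in) + mu_k_tmpl ],
    S_k = (Sigma_k_tmpl)^{1/2} (Sigma_k_in)^{-1/2}

with symmetric (eigendecomposition) matrix square roots, so each class's
color cloud is moved onto the template's corresponding class cloud.

The working color space defaults to optical density, OD_c = -log((I_c+1)/256),
where stain absorption is approximately linear (Beer-Lambert) and class
clusters are closer to Gaussian; plain RGB is also available.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging

import numpy as np
from scipy.special import logsumexp

from .io_formats import validate_image

__all__ = [
    "ClassGaussians",
    "ColorSpaceCodec",
    "RGB_CODEC",
    "OD_CODEC",
    "get_codec",
    "fit_gmm_em",
    "estimate_class_gaussians",
    "normalize_colors",
    "align_components",
]

logger = logging.getLogger("nucseg.stain_gmm")

# relative covariance regularization: eps = COV_FLOOR_REL * mean channel variance
COV_FLOOR_REL = 1e-6
MIN_CLASS_RESPONSIBILITY = 10.0  # pixels-equivalent


@dataclasses.dataclass(frozen=True)
class ClassGaussians:
    """Per-tissue-class color Gaussians: weights (simplex), means, covariances."""

    weights: np.ndarray  # (K,)
    means: np.ndarray  # (K, 3)
    covariances: np.ndarray  # (K, 3, 3)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        m = np.asarray(self.means, dtype=float)
        c = np.asarray(self.covariances, dtype=float)
        if w.ndim != 1 or m.shape != (w.size, 3) or c.shape != (w.size, 3, 3):
            raise ValueError(
                f"inconsistent shapes: weights {w.shape}, means {m.shape}, "
                f"covariances {c.shape}"
            )
        if abs(w.sum() - 1.0) > 1e-9 or np.any(w < 0):
            raise ValueError("weights must be non-negative and sum to 1")
        if not np.allclose(c, np.swapaxes(c, 1, 2), atol=1e-8):
            raise ValueError("covariances must be symmetric")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "means", m)
        object.__setattr__(self, "covariances", c)

    @property
    def K(self) -> int:
        return int(self.weights.size)

    def permute(self, perm) -> "ClassGaussians":
        """Reorder components by the given permutation."""
        idx = np.asarray(perm)
        return ClassGaussians(self.weights[idx], self.means[idx], self.covariances[idx])


@dataclasses.dataclass(frozen=True)
class ColorSpaceCodec:
    """Invertible map between uint8 RGB images and real-valued color vectors."""

    name: str

    def forward(self, image: np.ndarray) -> np.ndarray:
        arr = validate_image(image).astype(float)
        if self.name == "rgb":
            return arr
        if self.name == "optical_density":
            return -np.log((arr + 1.0) / 256.0)
        raise ValueError(f"unknown color space {self.name!r}")

    def backward(self, values: np.ndarray) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        if self.name == "rgb":
            out = v
        elif self.name == "optical_density":
            out = 256.0 * np.exp(-v) - 1.0
        else:
            raise ValueError(f"unknown color space {self.name!r}")
        return np.clip(np.rint(out), 0, 255).astype(np.uint8)


RGB_CODEC = ColorSpaceCodec("rgb")
OD_CODEC = ColorSpaceCodec("optical_density")


def get_codec(name: str) -> ColorSpaceCodec:
    if name == "rgb":
        return RGB_CODEC
    if name in ("optical_density", "od"):
        return OD_CODEC
    raise ValueError(f"unknown color space {name!r}")


def _cov_floor(X: np.ndarray) -> float:
    """Regularization epsilon: 1e-6 of the mean per-channel variance."""
    var = float(np.mean(np.var(X, axis=0)))
    return max(COV_FLOOR_REL * var, 1e-12)


def _log_gauss(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Log density of a 3-D Gaussian at each row of X."""
    L = np.linalg.cholesky(cov)
    diff = X - mean
    sol = np.linalg.solve(L, diff.T)
    maha = np.sum(sol**2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    d = X.shape[1]
    return -0.5 * (d * np.log(2.0 * np.pi) + logdet + maha)


def _e_step(
    X: np.ndarray, weights: np.ndarray, means: np.ndarray, covs: np.ndarray
) -> tuple[np.ndarray, float]:
    """Responsibilities and total log-likelihood for the current parameters."""
    K = weights.size
    logp = np.empty((X.shape[0], K))
    for k in range(K):
        logp[:, k] = np.log(weights[k] + 1e-300) + _log_gauss(X, means[k], covs[k])
    norm = logsumexp(logp, axis=1)
    gamma = np.exp(logp - norm[:, None])
    return gamma, float(norm.sum())


def _m_step(
    X: np.ndarray, gamma: np.ndarray, eps: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weighted weights/means/covariances update; covariances floored by eps*I."""
    Nk = gamma.sum(axis=0)
    weights = Nk / gamma.shape[0]
    means = (gamma.T @ X) / Nk[:, None]
    K = gamma.shape[1]
    covs = np.empty((K, 3, 3))
    for k in range(K):
        diff = X - means[k]
        covs[k] = (gamma[:, k, None] * diff).T @ diff / Nk[k]
        covs[k] = 0.5 * (covs[k] + covs[k].T) + eps * np.eye(3)
    return weights, means, covs


def _quantile_init(X: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    """Deterministic means init: colors at K evenly spaced luminance quantiles.

    Pixels are ordered by luminance (Rec. 601 weights); component k starts at
    the mean color of a narrow band around quantile (k + 0.5)/K. The seeded
    rng only adds a vanishing jitter to break exact ties between identical
    initial means.
    """
    lum = X @ np.array([0.299, 0.587, 0.114])
    order = np.argsort(lum, kind="stable")
    n = X.shape[0]
    half_band = max(n // 200, 1)
    means = np.empty((K, 3))
    for k in range(K):
        center = int((k + 0.5) / K * n)
        lo = max(center - half_band, 0)
        hi = min(center + half_band + 1, n)
        means[k] = X[order[lo:hi]].mean(axis=0)
    # tie-break jitter, negligible at color scale
    means += rng.standard_normal(means.shape) * 1e-9
    return means


def fit_gmm_em(
    image: np.ndarray,
    K: int = 3,
    codec: ColorSpaceCodec = OD_CODEC,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int = 0,
    history: list | None = None,
) -> tuple[ClassGaussians, np.ndarray]:
    """Fit a K-component Gaussian mixture to an image's pixel colors by EM.

    Returns ``(model, posterior)`` where ``posterior`` has shape (H, W, K).
    The posterior is the E-step that fed the final M-step, so a single
    M-step on it (``estimate_class_gaussians``) reproduces ``model`` exactly.

    Stops when the relative log-likelihood improvement drops below ``tol``
    or after ``max_iter`` iterations (non-convergence is logged, not raised).
    The log-likelihood is non-decreasing across iterations; pass a list as
    ``history`` to receive the per-iteration log-likelihood trace.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    img = validate_image(image)
    h, w = img.shape[:2]
    X = codec.forward(img).reshape(-1, 3)

    distinct = np.unique(X, axis=0).shape[0]
    if distinct < K:
        raise ValueError(
            f"degenerate input: only {distinct} distinct colors for K={K}"
        )

    eps = _cov_floor(X)
    rng = np.random.default_rng(seed)
    means = _quantile_init(X, K, rng)
    weights = np.full(K, 1.0 / K)
    global_cov = np.cov(X.T) + eps * np.eye(3)
    covs = np.repeat(global_cov[None], K, axis=0)

    gamma, ll = _e_step(X, weights, means, covs)
    if history is not None:
        history.append(ll)
    for _ in range(max_iter):
        weights, means, covs = _m_step(X, gamma, eps)
        new_gamma, new_ll = _e_step(X, weights, means, covs)
        if history is not None:
            history.append(new_ll)
        converged = (new_ll - ll) / max(abs(ll), 1.0) < tol
        gamma, ll = new_gamma, new_ll
        if converged:
            break
    else:
        logger.warning("EM did not converge within %d iterations", max_iter)
    # final M-step so the returned parameters are exactly one M-step of the
    # returned posterior (the posterior-provider fixed point)
    weights, means, covs = _m_step(X, gamma, eps)

    model = ClassGaussians(weights, means, covs)
    return model, gamma.reshape(h, w, K)


def estimate_class_gaussians(
    image: np.ndarray,
    posterior: np.ndarray,
    codec: ColorSpaceCodec = OD_CODEC,
) -> ClassGaussians:
    """One weighted M-step: per-class Gaussians from an arbitrary posterior.

    This is the bridge that lets a plugged-in posterior provider (e.g. a
    segmentation network's soft class map) drive the same color transfer.
    """
    img = validate_image(image)
    h, w = img.shape[:2]
    gamma = np.asarray(posterior, dtype=float)
    if gamma.shape[:2] != (h, w) or gamma.ndim != 3:
        raise ValueError(
            f"posterior shape {gamma.shape} does not match image {(h, w)}"
        )
    X = codec.forward(img).reshape(-1, 3)
    G = gamma.reshape(-1, gamma.shape[2])
    Nk = G.sum(axis=0)
    low = np.nonzero(Nk < MIN_CLASS_RESPONSIBILITY)[0]
    if low.size:
        raise ValueError(
            f"class {int(low[0])} has total responsibility {Nk[low[0]]:.2f} "
            f"< {MIN_CLASS_RESPONSIBILITY} pixels-equivalent"
        )
    weights, means, covs = _m_step(X, G, _cov_floor(X))
    return ClassGaussians(weights, means, covs)


def _sqrt_psd(mat: np.ndarray, inverse: bool = False) -> np.ndarray:
    """Symmetric matrix square root (or inverse square root) via eigendecomposition."""
    vals, vecs = np.linalg.eigh(mat)
    if np.any(vals <= 0):
        raise ValueError(
            f"covariance eigenvalue {vals.min():.3e} below floor; cannot whiten"
        )
    root = 1.0 / np.sqrt(vals) if inverse else np.sqrt(vals)
    return (vecs * root) @ vecs.T


def normalize_colors(
    image: np.ndarray,
    input_model: ClassGaussians,
    input_posterior: np.ndarray,
    template_model: ClassGaussians,
    codec: ColorSpaceCodec = OD_CODEC,
) -> np.ndarray:
    """Transfer the image's per-class color Gaussians onto the template's.

    Component correspondence must already be established (see
    ``align_components``); component k of ``input_model`` is mapped onto
    component k of ``template_model``.
    """
    img = validate_image(image)
    h, w = img.shape[:2]
    if input_model.K != template_model.K:
        raise ValueError("input and template models must have the same K")
    K = input_model.K
    gamma = np.asarray(input_posterior, dtype=float)
    if gamma.shape != (h, w, K):
        raise ValueError(
            f"posterior shape {gamma.shape} does not match image and K={K}"
        )

    X = codec.forward(img).reshape(-1, 3)
    G = gamma.reshape(-1, K)
    out = np.zeros_like(X)
    for k in range(K):
        S = _sqrt_psd(template_model.covariances[k]) @ _sqrt_psd(
            input_model.covariances[k], inverse=True
        )
        mapped = (X - input_model.means[k]) @ S.T + template_model.means[k]
        out += G[:, k, None] * mapped
    return codec.backward(out.reshape(h, w, 3))


def align_components(a: ClassGaussians, b: ClassGaussians) -> tuple[int, ...]:
    """Permutation p minimizing sum_k ||a.means[k] - b.means[p[k]]||.

    Exhaustive over K! permutations; refuses K > 8. Applying the returned
    permutation to ``b`` (``b.permute(p)``) puts its components in ``a``'s
    order.
    """
    if a.K != b.K:
        raise ValueError("models must have the same number of components")
    if a.K > 8:
        raise ValueError(f"factorial search refused for K={a.K} > 8")
    best_perm: tuple[int, ...] | None = None
    best_cost = np.inf
    for perm in itertools.permutations(range(a.K)):
        cost = float(
            np.sum(np.linalg.norm(a.means - b.means[list(perm)], axis=1))
        )
        if cost < best_cost - 1e-12:
            best_cost = cost
            best_perm = perm
    assert best_perm is not None
    return best_perm
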
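"""Low-level samplers: Pólya-Gamma draws and a univariate slice sampler.

The Pólya-Gamma distribution PG(b, c) is the workhorse of the data-augmentation
Gibbs sampler for Bernoulli-logit likelihoods (Polson, Scott & Windle 2013):
conditional on omega_i ~ PG(b_i, psi_i) the logistic likelihood becomes
Gaussian in the linear predictor. Survey weights enter the pseudo-likelihood
as exponents, so the shape parameter b is a positive *real*, not an integer;
we therefore sample from the infinite-convolution-of-gammas representation

    omega = (1 / (2 pi^2)) * sum_{k>=1} g_k / ((k - 1/2)^2 + c^2 / (4 pi^2)),
    g_k ~ Gamma(b, 1) i.i.d.,

truncated at ``n_terms`` with the neglected tail replaced by its analytic
expectation (the series sum_{k} 1/((k-1/2)^2 + t^2) = (pi / (2 t)) tanh(pi t)
has a closed form). The truncation noise decays like n_terms^(-3/2) and is
negligible at the default 64 terms.
"""

from __future__ import annotations

import numpy as np

__all__ = ["sample_polya_gamma", "polya_gamma_mean", "slice_sample"]


def polya_gamma_mean(b, c):
    """E[PG(b, c)] = (b / (2c)) tanh(c / 2), with the c -> 0 limit b/4."""
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    small = np.abs(c) < 1e-8
    cs = np.where(small, 1.0, c)
    out = np.where(small, b / 4.0, (b / (2.0 * cs)) * np.tanh(cs / 2.0))
    return out


def _series_partial_sum(t2: np.ndarray, n_terms: int) -> np.ndarray:
    """sum_{k=1}^{n_terms} 1/((k-1/2)^2 + t^2) elementwise for t^2 array."""
    k = (np.arange(1, n_terms + 1) - 0.5) ** 2  # (K,)
    return (1.0 / (k[None, :] + t2[:, None])).sum(axis=1)


def sample_polya_gamma(
    b: np.ndarray,
    c: np.ndarray,
    rng: np.random.Generator,
    n_terms: int = 64,
) -> np.ndarray:
    """Draw omega_i ~ PG(b_i, c_i) elementwise for real b_i > 0.

    Parameters
    ----------
    b : array
        Shape parameters (e.g. survey weights), strictly positive.
    c : array
        Tilting parameters (the linear predictors).
    rng : numpy Generator
    n_terms : int
        Series truncation; the dropped tail is added back in expectation.
    """
    b = np.broadcast_to(np.asarray(b, dtype=float), np.shape(c)).ravel()
    c = np.asarray(c, dtype=float).ravel()
    if np.any(b <= 0):
        raise ValueError("PG shape parameters must be strictly positive")
    n = c.size
    t2 = (c / (2.0 * np.pi)) ** 2  # t^2 with t = |c| / (2 pi)
    k2 = (np.arange(1, n_terms + 1) - 0.5) ** 2
    denom = k2[None, :] + t2[:, None]  # (n, K)
    g = rng.standard_gamma(b[:, None], size=(n, n_terms))
    omega = (g / denom).sum(axis=1)
    # analytic tail expectation: full series minus the partial sum
    t = np.sqrt(t2)
    small = t < 1e-8
    ts = np.where(small, 1.0, t)
    full = np.where(small, np.pi**2 / 2.0, (np.pi / (2.0 * ts)) * np.tanh(np.pi * ts))
    tail = full - (1.0 / denom).sum(axis=1)
    omega += b * tail
    return omega / (2.0 * np.pi**2)


def slice_sample(
    x0: float,
    log_density,
    rng: np.random.Generator,
    width: float = 1.0,
    max_steps: int = 50,
) -> float:
    """One update of Neal's stepping-out slice sampler on the real line."""
    logp0 = log_density(x0)
    if not np.isfinite(logp0):
        raise ValueError("slice sampler started at a zero-density point")
    log_y = logp0 + np.log(rng.uniform())
    left = x0 - width * rng.uniform()
    right = left + width
    j = int(max_steps * rng.uniform())
    k = max_steps - 1 - j
    while j > 0 and log_density(left) > log_y:
        left -= width
        j -= 1
    while k > 0 and log_density(right) > log_y:
        right += width
        k -= 1
    while True:
        x1 = rng.uniform(left, right)
        if log_density(x1) > log_y:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1
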
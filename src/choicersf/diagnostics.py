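"""MCMC convergence diagnostics: split R-hat and effective sample size.

Convergence is declared per the usual thresholds in applied Bayesian RSF
work: potential scale reduction factor R-hat < 1.1 and effective sample
size n_eff > 100 for every parameter.

R-hat is the split-chain potential scale reduction factor (each chain is
halved, so within-chain drift shows up as between-chain variance).  n_eff
uses chain-averaged autocorrelations with Geyer's initial positive-sequence
truncation on paired sums.
"""

from __future__ import annotations

import warnings

import numpy as np

from .errors import InsufficientDataError

RHAT_THRESHOLD = 1.1
NEFF_THRESHOLD = 100.0


def _split_chains(draws: np.ndarray) -> np.ndarray:
    """(m, n, k) -> (2m, n//2, k); a trailing odd draw is discarded."""
    draws = np.asarray(draws, dtype=float)
    if draws.ndim == 2:
        draws = draws[:, :, None]
    m, n, k = draws.shape
    half = n // 2
    return np.concatenate([draws[:, :half], draws[:, half : 2 * half]], axis=0)


def compute_rhat(draws: np.ndarray) -> np.ndarray:
    """Per-parameter split R-hat from draws of shape (n_chains, n_draws[, k])."""
    draws = np.asarray(draws, dtype=float)
    squeeze = draws.ndim == 2
    split = _split_chains(draws)
    m, n, k = split.shape
    if draws.shape[0] < 2 or n < 2:
        raise InsufficientDataError("R-hat needs >= 2 chains with >= 4 draws each")
    chain_means = split.mean(axis=1)                   # (m, k)
    chain_vars = split.var(axis=1, ddof=1)             # (m, k)
    W = chain_vars.mean(axis=0)
    B = n * chain_means.var(axis=0, ddof=1)
    var_plus = (n - 1) / n * W + B / n
    rhat = np.full(k, np.inf)
    ok = W > 0
    rhat[ok] = np.sqrt(var_plus[ok] / W[ok])
    if np.any(~ok):
        warnings.warn("zero within-chain variance; R-hat reported as +inf", stacklevel=2)
    return rhat[0] if squeeze else rhat


def _chain_autocov(x: np.ndarray) -> np.ndarray:
    """Biased autocovariance of one chain (length n), via FFT."""
    n = len(x)
    x = x - x.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conjugate(f), nfft)[:n].real
    return acov / n


def compute_neff(draws: np.ndarray) -> np.ndarray:
    """Per-parameter effective sample size from (n_chains, n_draws[, k]) draws.

    Combines within-chain autocovariances with the split-chain variance
    estimate; the autocorrelation sum is truncated at the first
    non-positive Geyer pair sum and forced non-increasing.
    """
    draws = np.asarray(draws, dtype=float)
    squeeze = draws.ndim == 2
    split = _split_chains(draws)
    m, n, k = split.shape
    if draws.shape[0] < 2 or n < 2:
        raise InsufficientDataError("n_eff needs >= 2 chains with >= 4 draws each")

    neff = np.empty(k)
    for j in range(k):
        chains = split[:, :, j]
        W = chains.var(axis=1, ddof=1).mean()
        B = n * chains.mean(axis=1).var(ddof=1)
        var_plus = (n - 1) / n * W + B / n
        if var_plus <= 0 or W <= 0:
            warnings.warn("degenerate (constant) chains; n_eff undefined, reported as nan", stacklevel=2)
            neff[j] = np.nan
            continue
        acov = np.mean([_chain_autocov(c) for c in chains], axis=0)  # lag 0..n-1
        rho = 1.0 - (W - acov) / var_plus
        rho[0] = 1.0
        # Geyer initial positive sequence on pair sums rho[2t]+rho[2t+1]
        tau = 1.0  # contributes rho_0 = 1; pairs start at lag 1
        prev_pair = np.inf
        t = 1
        while t + 1 < n:
            pair = rho[t] + rho[t + 1]
            if pair <= 0:
                break
            pair = min(pair, prev_pair)  # initial monotone adjustment
            tau += 2.0 * pair
            prev_pair = pair
            t += 2
        neff[j] = m * n / tau
    return neff[0] if squeeze else neff


def diagnostics_table(draws: np.ndarray, names: list[str]) -> dict:
    """Per-parameter R-hat / n_eff with threshold flags."""
    rhat = np.atleast_1d(compute_rhat(draws))
    neff = np.atleast_1d(compute_neff(draws))
    return {
        name: {
            "rhat": float(rhat[i]),
            "neff": float(neff[i]),
            "converged": bool(rhat[i] < RHAT_THRESHOLD and neff[i] > NEFF_THRESHOLD),
        }
        for i, name in enumerate(names)
    }
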
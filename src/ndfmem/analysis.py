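"""Evaluation statistics for location-coded persistent activity.

Covers the full analysis battery used on the ring network: cosine Fourier
modes of population patterns, per-mode excitation-inhibition balance from the
eigendecomposition of the plastic E-to-E matrix, Poisson-noise population-
vector decoding error, per-neuron spatial selectivity (first Fourier
component of the tuning curve), the translation-invariance index std/mean of
that selectivity, exponential decay-timescale fits, and per-neuron E-I ratios
of summed synaptic weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "TuningMatrix",
    "DecodingResult",
    "BalanceTable",
    "fourier_mode",
    "eigen_balance",
    "poisson_counts",
    "population_vector",
    "decoding_error",
    "spatial_selectivity",
    "invariance_index",
    "fit_decay_timescale",
    "postsynaptic_ei_ratio",
    "evaluate_network",
    "TIMESCALE_CAP",
]

#: Sentinel cap for non-decaying traces in :func:`fit_decay_timescale`.
TIMESCALE_CAP = 1e12


def _default_grid(N: int) -> np.ndarray:
    return -np.pi + 2.0 * np.pi * np.arange(N) / N


@dataclass
class TuningMatrix:
    """End-of-delay rates r_theta(theta_0): neurons x stimulus locations."""

    rates: np.ndarray
    theta_grid: np.ndarray
    theta0_grid: np.ndarray

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        self.theta_grid = np.asarray(self.theta_grid, dtype=float)
        self.theta0_grid = np.asarray(self.theta0_grid, dtype=float)
        if self.rates.shape != (self.theta_grid.size, self.theta0_grid.size):
            raise ValueError("rates must be (n_neurons, n_stimuli)")


@dataclass
class DecodingResult:
    """Population-vector decodes and cosine-distance errors."""

    decoded: np.ndarray  # (n_stimuli, n_repeats)
    per_stimulus_error: np.ndarray
    error_mean: float
    n_degenerate: int = 0


@dataclass
class BalanceTable:
    """Per-Fourier-mode eigenvalues and balance ratios of the four kernels.

    ``ratio`` is lambda_EI*lambda_IE / (lambda_EE*lambda_II); 1 means the
    mode is balanced.  ``similarity`` scores how closely the matched
    eigenvector of W_EE resembles the mode's sinusoid (1 = exact), and
    ``complex_pair`` flags modes whose matched eigenvalue had a nonnegligible
    imaginary part (reported by modulus).
    """

    mode: np.ndarray
    lam_EE: np.ndarray
    lam_EI: np.ndarray
    lam_IE: np.ndarray
    lam_II: np.ndarray
    ratio: np.ndarray
    similarity: np.ndarray
    complex_pair: np.ndarray

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "mode": self.mode, "lam_EE": self.lam_EE, "lam_EI": self.lam_EI,
            "lam_IE": self.lam_IE, "lam_II": self.lam_II, "ratio": self.ratio,
            "similarity": self.similarity, "complex_pair": self.complex_pair,
        })


def fourier_mode(pattern: np.ndarray, n: int, theta0: float = 0.0,
                 theta_grid: Optional[np.ndarray] = None) -> float:
    """n-th cosine Fourier mode of a population pattern about ``theta0``.

    Riemann-sum estimate of (1/2pi) * integral r(theta) cos(n(theta-theta0));
    with the uniform grid this is mean(r * cos(n*(theta - theta0))).
    """
    if n < 0:
        raise ValueError("mode index n must be nonnegative")
    pattern = np.asarray(pattern, dtype=float)
    if theta_grid is None:
        theta_grid = _default_grid(pattern.size)
    return float(np.mean(pattern * np.cos(n * (theta_grid - theta0))))


def _circulant_eigvals(W: np.ndarray) -> np.ndarray:
    """Eigenvalues of a symmetric circulant matrix via the DFT of its first row."""
    lam = np.fft.fft(W[0])
    return lam.real


def eigen_balance(conn, n_modes: int = 8, imag_tol: float = 1e-8) -> BalanceTable:
    """Per-mode E-I balance ratio from eigendecomposition of W_EE.

    W_EE (plastic, possibly no longer circulant) is eigendecomposed and, for
    each Fourier mode n, the eigenvector with the largest projection onto
    span{cos(n*theta), sin(n*theta)} supplies lambda_EE(n).  The static
    kernels W_EI, W_IE, W_II stay circulant, so their mode eigenvalues are
    read off the DFT of their first rows.  Conjugate eigenpairs are merged
    and reported by modulus; the matching similarity is returned per mode so
    ambiguity is visible rather than silently resolved.
    """
    W_EE = np.asarray(conn.W_EE, dtype=float)
    N = W_EE.shape[0]
    if W_EE.shape != (N, N):
        raise ValueError("W_EE must be square")
    theta = _default_grid(N)
    evals, evecs = np.linalg.eig(W_EE)

    lam_EI = _circulant_eigvals(np.asarray(conn.W_EI))
    lam_IE = _circulant_eigvals(np.asarray(conn.W_IE))
    lam_II = _circulant_eigvals(np.asarray(conn.W_II))

    modes = np.arange(n_modes)
    lam_EE = np.empty(n_modes)
    similarity = np.empty(n_modes)
    complex_pair = np.zeros(n_modes, dtype=bool)
    for n in modes:
        basis = [np.cos(n * theta)]
        if n > 0:
            basis.append(np.sin(n * theta))
        B = np.stack([b / np.linalg.norm(b) for b in basis])
        # projection fraction of each unit eigenvector onto the mode subspace
        proj = np.abs(B.conj() @ evecs) ** 2
        score = proj.sum(axis=0) / np.sum(np.abs(evecs) ** 2, axis=0)
        idx = int(np.argmax(score))
        lam = evals[idx]
        if abs(lam.imag) > imag_tol * max(abs(lam), 1.0):
            complex_pair[n] = True
            lam_EE[n] = abs(lam)
        else:
            lam_EE[n] = lam.real
        similarity[n] = float(np.sqrt(score[idx]))
    lam_EI_m = lam_EI[modes]
    lam_IE_m = lam_IE[modes]
    lam_II_m = lam_II[modes]
    ratio = lam_EI_m * lam_IE_m / (lam_EE * lam_II_m)
    return BalanceTable(mode=modes, lam_EE=lam_EE, lam_EI=lam_EI_m,
                        lam_IE=lam_IE_m, lam_II=lam_II_m, ratio=ratio,
                        similarity=similarity, complex_pair=complex_pair)


def poisson_counts(rates: np.ndarray, scale: float = 0.2,
                   rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Poisson spike counts with means scale*rate (0.2 ~ Hz rates in 200 ms)."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("rates must be nonnegative")
    if rng is None:
        rng = np.random.default_rng()
    return rng.poisson(scale * rates)


def population_vector(counts: np.ndarray,
                      theta_grid: Optional[np.ndarray] = None) -> float:
    """Decoded angle: argument of the count-weighted sum of unit phasors.

    Returns NaN when the resultant vector is (numerically) zero — an
    information-free count pattern; callers decide how to treat the
    degenerate case (the decoder draws a uniformly random angle).
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    if theta_grid is None:
        theta_grid = _default_grid(counts.size)
    z = np.sum(counts * np.exp(1j * theta_grid))
    if abs(z) < 1e-9 * max(counts.sum(), 1.0):
        return float("nan")
    return float(np.angle(z))


def decoding_error(tuning: TuningMatrix, scale: float = 0.2, n_repeats: int = 20,
                   rng: Optional[np.random.Generator] = None) -> DecodingResult:
    """Mean cosine-distance decoding error over stimuli and Poisson repeats.

    For each stimulus location, spike counts are drawn ``n_repeats`` times,
    decoded with the population vector, and scored by 1 - cos(theta0 -
    decoded).  A degenerate (zero-resultant) decode contributes a uniformly
    random angle, so an information-free network scores an expected error of
    one.  error_mean lies in [0, 2].
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    n_stim = tuning.theta0_grid.size
    decoded = np.empty((n_stim, n_repeats))
    per_stim = np.empty(n_stim)
    n_degenerate = 0
    rates = np.clip(tuning.rates, 0.0, None)
    for s in range(n_stim):
        for k in range(n_repeats):
            counts = rng.poisson(scale * rates[:, s])
            ang = population_vector(counts, tuning.theta_grid)
            if np.isnan(ang):
                ang = float(rng.uniform(-np.pi, np.pi))
                n_degenerate += 1
            decoded[s, k] = ang
        per_stim[s] = np.mean(1.0 - np.cos(tuning.theta0_grid[s] - decoded[s]))
    return DecodingResult(decoded=decoded, per_stimulus_error=per_stim,
                          error_mean=float(per_stim.mean()),
                          n_degenerate=n_degenerate)


def spatial_selectivity(tuning: TuningMatrix) -> np.ndarray:
    """Per-neuron spatial selectivity F1.

    Modulus of the first circular Fourier coefficient of each neuron's tuning
    curve over stimulus location: |(1/2pi) * integral e^{i theta0}
    r_theta(theta0) d theta0|, estimated by a Riemann sum on the stimulus grid.
    """
    phase = np.exp(1j * tuning.theta0_grid)
    coeff = np.mean(tuning.rates * phase[None, :], axis=1)
    return np.abs(coeff)


def invariance_index(F1: np.ndarray):
    """(mean, std, std/mean) of spatial selectivity across neurons.

    The population standard deviation (uniform weight per neuron) is used.
    std/mean near zero marks a translation-invariant network; order one marks
    broken invariance.  A zero mean yields NaN for the normalized index.
    """
    F1 = np.asarray(F1, dtype=float)
    mean = float(F1.mean())
    std = float(F1.std())  # population convention (ddof=0)
    if mean <= 0:
        return mean, std, float("nan")
    return mean, std, std / mean


def fit_decay_timescale(mode_trace: np.ndarray, dt: float,
                        window: tuple = (100.0, None)) -> float:
    """Exponential decay timescale of a mode-amplitude trace.

    Log-linear least squares on the delay-period amplitude, skipping the
    initial ``window[0]`` time units of transient; returns -1/slope, capped
    at :data:`TIMESCALE_CAP` for non-decaying traces.
    """
    trace = np.asarray(mode_trace, dtype=float)
    t = np.arange(trace.size) * dt
    lo = 0.0 if window[0] is None else window[0]
    hi = t[-1] + dt if window[1] is None else window[1]
    sel = (t >= lo) & (t <= hi)
    if sel.sum() < 3:
        raise ValueError("fit window too short")
    y = trace[sel]
    if np.any(y <= 0):
        raise ValueError("trace must be positive over the fit window; shrink the window")
    slope = np.polyfit(t[sel], np.log(y), 1)[0]
    if slope >= -1.0 / TIMESCALE_CAP:
        return TIMESCALE_CAP
    return float(min(-1.0 / slope, TIMESCALE_CAP))


def postsynaptic_ei_ratio(conn) -> np.ndarray:
    """Per-neuron E-I input ratio relative to the pre-perturbation network.

    For each postsynaptic neuron i: (sum_j W_EE[i,j] / sum_j W_EI[i,j])
    divided by the same quantity with the pristine W0_EE; 1 marks recovery of
    the original balance.  Homeostatic scaling acts row-wise, so this ratio
    tracks it directly (unlike the Fourier-domain balance).
    """
    inh = np.asarray(conn.W_EI).sum(axis=1)
    if np.any(inh == 0):
        raise ValueError("zero inhibitory row sum; E-I ratio undefined")
    now = np.asarray(conn.W_EE).sum(axis=1) / inh
    ref = np.asarray(conn.W0_EE).sum(axis=1) / inh
    return now / ref


def evaluate_network(tuning: TuningMatrix, rng: np.random.Generator,
                     scale: float = 0.2, n_repeats: int = 20) -> dict:
    """Decoding error plus selectivity statistics for one frozen network."""
    res = decoding_error(tuning, scale=scale, n_repeats=n_repeats, rng=rng)
    F1 = spatial_selectivity(tuning)
    mean_F1, std_F1, norm_std = invariance_index(F1)
    return {
        "decoding_error": res.error_mean,
        "mean_F1": mean_F1,
        "std_F1": std_F1,
        "normalized_std_F1": norm_std,
        "n_degenerate_decodes": res.n_degenerate,
    }
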
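"""Summary statistics and fits: population rates, RMS errors, psychometrics.

The psychometric function is the Weibull form used for two-alternative
coherence discrimination,

    P(correct | c') = 1 - 0.5 * exp(-(c'/alpha)^beta),

fitted by Bernoulli maximum likelihood over the per-trial outcomes (a
least-squares fit on the proportion curve is available as an option).
Confidence intervals on per-coherence proportions are percentile bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize as _opt

__all__ = [
    "PsychometricCurve",
    "WeibullFit",
    "binned_population_rate",
    "rms_difference",
    "weibull",
    "fit_weibull",
    "bootstrap_ci",
    "population_mean_gating",
]


@dataclass
class PsychometricCurve:
    coherences: np.ndarray
    p_correct: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_trials: np.ndarray


@dataclass
class WeibullFit:
    alpha: float  # coherence scale (%)
    beta: float   # shape
    identifiable: bool = True


def binned_population_rate(times, neurons, population: slice, size: int,
                           bin_ms: float, T: float) -> np.ndarray:
    """Per-bin population rate in spikes/s: count / (size * bin duration).

    ``population`` is the global-id slice of the population; spikes at a bin
    edge belong to the earlier bin (times are end-of-step, in (0, T]).
    """
    if size <= 0:
        raise ValueError("empty population")
    times = np.asarray(times, dtype=float)
    neurons = np.asarray(neurons)
    m = (neurons >= population.start) & (neurons < population.stop)
    n_bins = int(np.ceil(T / bin_ms))
    idx = np.minimum((np.ceil(times[m] / bin_ms) - 1).astype(int), n_bins - 1)
    idx = np.maximum(idx, 0)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    return counts / (size * bin_ms / 1000.0)


def rms_difference(trace_a, trace_b) -> float:
    """Root mean square of the pointwise difference of two sampled traces."""
    a = np.asarray(trace_a, dtype=float)
    b = np.asarray(trace_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"trace shapes differ: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def weibull(c, alpha: float, beta: float):
    return 1.0 - 0.5 * np.exp(-((np.asarray(c, dtype=float) / alpha) ** beta))


def fit_weibull(coherences, n_correct, n_trials, method: str = "mle",
                alpha0: float = 10.0, beta0: float = 1.0) -> WeibullFit:
    """Fit the Weibull psychometric function.

    Parameters are optimized in log space from a fixed start so the fit is
    deterministic.  Data at zero coherence carry no scale information and must
    be excluded by the caller.  A flat curve (all proportions on one side of
    chance or constant) is reported as non-identifiable with the best-effort
    parameters found.
    """
    c = np.asarray(coherences, dtype=float)
    k = np.asarray(n_correct, dtype=float)
    n = np.asarray(n_trials, dtype=float)
    if np.any(c <= 0):
        raise ValueError("coherences must be positive (exclude c'=0)")
    informative = np.sum((k > 0) & (k < n))
    degenerate = informative < 1 and (np.all(k == n) or np.all(k == 0))

    if method == "mle":
        def nll(theta):
            a, b = np.exp(theta)
            p = np.clip(weibull(c, a, b), 1e-12, 1 - 1e-12)
            return -np.sum(k * np.log(p) + (n - k) * np.log1p(-p))
        obj = nll
    elif method == "lsq":
        def ssq(theta):
            a, b = np.exp(theta)
            return np.sum((weibull(c, a, b) - k / n) ** 2)
        obj = ssq
    else:
        raise ValueError(f"unknown method {method!r}")

    res = _opt.minimize(obj, x0=np.log([alpha0, beta0]), method="Nelder-Mead",
                        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
    alpha, beta = np.exp(res.x)
    # Non-identifiability: the scale runs away or the curve is flat near 0.5.
    props = k / n
    flat = np.all(props <= 0.5 + 1e-9) or alpha > 100 * c.max()
    return WeibullFit(alpha=float(alpha), beta=float(beta),
                      identifiable=not (degenerate or flat))


def bootstrap_ci(outcomes, n_resamples: int = 5000, level: float = 0.90,
                 seed=0) -> tuple[float, float]:
    """Percentile bootstrap interval for a Bernoulli proportion."""
    x = np.asarray(outcomes, dtype=float)
    if x.size == 0:
        raise ValueError("need at least one outcome")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_resamples, x.size))
    props = x[idx].mean(axis=1)
    lo, hi = np.quantile(props, [(1 - level) / 2, (1 + level) / 2])
    return float(lo), float(hi)


def population_mean_gating(s_values, population: slice) -> np.ndarray:
    """Arithmetic mean over a population's own (outgoing) gating variables.

    ``s_values`` has neurons on the last axis (a single snapshot or a
    time-by-neuron trace).
    """
    s = np.asarray(s_values, dtype=float)
    return s[..., population].mean(axis=-1)
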
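"""Independent brute-force oracles used to check the analytic engines.

These deliberately avoid the package's recursive-integration code path:
the sequential z-process is simulated directly from its canonical joint
distribution (independent score increments), and boundary outcomes are
evaluated by explicit replay.
"""

import numpy as np


def simulate_z_paths(fractions, drift, n_paths, rng):
    """Correlated sequential z-statistics via independent score increments."""
    t = np.asarray(fractions, dtype=float)
    dt = np.diff(np.concatenate(([0.0], t)))
    incr = rng.normal(0.0, 1.0, (n_paths, t.size)) * np.sqrt(dt)
    b = np.cumsum(incr, axis=1) + drift * t
    return b / np.sqrt(t)


def mc_crossing(design, drift, n_paths, seed, respect_futility=True):
    """Per-look first-crossing probabilities by explicit boundary replay."""
    rng = np.random.default_rng(seed)
    z = simulate_z_paths(design.schedule.information_fractions, drift,
                         n_paths, rng)
    K = z.shape[1]
    lower = np.asarray(design.futility_z)
    upper = np.asarray(design.efficacy_z)
    if not respect_futility:
        lower = np.full(K, -np.inf)
    active = np.ones(n_paths, dtype=bool)
    p_eff = np.zeros(K)
    p_fut = np.zeros(K)
    for k in range(K):
        eff = active & np.isfinite(upper[k]) & (z[:, k] >= upper[k])
        fut = active & np.isfinite(lower[k]) & (z[:, k] <= lower[k]) & ~eff
        p_eff[k] = eff.mean()
        p_fut[k] = fut.mean()
        active &= ~(eff | fut)
    p_fut[-1] += active.mean()  # non-rejection at final
    return p_eff, p_fut


def mc_standard_error(p, n):
    return np.sqrt(np.maximum(p * (1.0 - p), 1e-12) / n)
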
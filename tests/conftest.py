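"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from ivimkit.core import BValueScheme, FitConfig, IvimParams, SignalCurve


@pytest.fixture
def scheme() -> BValueScheme:
    return BValueScheme()


@pytest.fixture
def fit_config() -> FitConfig:
    return FitConfig()


def make_curve(params: IvimParams, scheme: BValueScheme | None = None) -> SignalCurve:
    from ivimkit.core import ivim_signal

    scheme = scheme or BValueScheme()
    sig = ivim_signal(params, np.array(scheme.b_values))
    return SignalCurve(scheme, tuple(sig))


def make_hybrid_curve(params: IvimParams, b_threshold: float = 200.0,
                      scheme: BValueScheme | None = None) -> SignalCurve:
    """Curve whose perfusion term is exactly absent at/above the threshold:
    full bi-exponential below it, pure mono-exponential limb at/above it,
    with the true b=0 signal kept at S0.  On such input the log-linear stage
    is exact, which is what the noiseless-refit checks rely on."""
    from ivimkit.core import high_b_signal, ivim_signal

    scheme = scheme or BValueScheme()
    b = np.array(scheme.b_values)
    sig = np.where(b >= b_threshold, high_b_signal(params, b), ivim_signal(params, b))
    return SignalCurve(scheme, tuple(sig))


def add_rician_noise(clean: np.ndarray, sigma: float, averages, rng) -> np.ndarray:
    """Magnitude (Rician) noise with per-b effective SD sigma/sqrt(NEX)."""
    nex = np.asarray(averages, dtype=float)
    s_eff = sigma / np.sqrt(nex)
    n1 = rng.normal(0.0, s_eff)
    n2 = rng.normal(0.0, s_eff)
    return np.hypot(clean + n1, n2)


def grid_segmented_fit(curve: SignalCurve, cfg: FitConfig, n_grid: int = 61,
                       refinements: int = 3):
    """Brute-force oracle for the segmented fit: exhaustive grid search over
    the SAME two objectives (log-domain SSE for (D, intercept), then signal-
    domain SSE over all b for Dp), each refined around the argmin.

    Returns (D, f, Dp, d_res, dp_res) where *_res are the final grid spacings.
    """
    b = np.asarray(curve.scheme.b_values)
    s = np.asarray(curve.signal)
    hi = b >= cfg.b_threshold
    bh, logs = b[hi], np.log(s[hi])

    # Center the predictor so the (slope, level) axes of the log-SSE are
    # orthogonal; otherwise the diagonal valley defeats box refinement.
    b_mean = bh.mean()
    bc = bh - b_mean
    d_lo, d_hi = cfg.d_min, cfg.d_max
    c_lo, c_hi = logs.mean() - 0.5, logs.mean() + 0.5
    for _ in range(refinements):
        ds = np.linspace(d_lo, d_hi, n_grid)
        cs = np.linspace(c_lo, c_hi, n_grid)
        # SSE of log-signal against the line c - (b - b_mean)*D on the grid
        pred = cs[None, :, None] - ds[:, None, None] * bc[None, None, :]
        sse = ((pred - logs[None, None, :]) ** 2).sum(axis=-1)
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        dd, dc = ds[1] - ds[0], cs[1] - cs[0]
        d_lo, d_hi = max(cfg.d_min, ds[i] - dd), min(cfg.d_max, ds[i] + dd)
        c_lo, c_hi = cs[j] - dc, cs[j] + dc
    d_best = ds[i]
    intercept = cs[j] + d_best * b_mean  # back to the b=0 intercept
    f_best = min(max(1.0 - np.exp(intercept) / s[0], cfg.f_min), cfg.f_max)

    diffusive = s[0] * (1.0 - f_best) * np.exp(-b * d_best)
    dp_lo, dp_hi = d_best, cfg.dp_max
    for _ in range(refinements):
        dps = np.linspace(dp_lo, dp_hi, n_grid)
        resid = diffusive[None, :] + s[0] * f_best * np.exp(-np.outer(dps, b)) - s[None, :]
        sse2 = (resid**2).sum(axis=-1)
        k = int(np.argmin(sse2))
        ddp = dps[1] - dps[0]
        dp_lo, dp_hi = max(d_best, dps[k] - ddp), min(cfg.dp_max, dps[k] + ddp)
    return d_best, f_best, float(dps[k]), dd, ddp
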
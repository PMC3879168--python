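"""Synthetic pseudo-immunoblot readouts and event-timing inference.

Quantified immunoblot band intensities are positive, heteroscedastic and
normalized to a loading control.  This module emulates such data from
model trajectories: each "antibody channel" is a model variable sampled
at sparse times, multiplied by log-normal noise, offset by an additive
background and divided by a normalization constant (the loading-control
analogue, 1 by default).

Channel naming follows the phospho-epitopes the model variables stand
for: Tyr15-phosphorylated Cdk1 (preMPF), Thr194-phosphorylated Greatwall
(Gwl), Ser67-phosphorylated ENSA/ARPP19 (ENSAPt) and bulk Cdk substrate
phospho-SP signal (MPFa).

Half-transition times (t50) are estimated by smoothing the sampled
series in log space - where the multiplicative noise is homoscedastic
with known standard deviation sigma - using a smoothing spline whose
penalty is set by the discrepancy principle (residual RMS matched to
sigma), then interpolating the half-excursion crossing of the fit;
uncertainty comes from a residual-resampling bootstrap around the same
fit, re-using the chosen penalty.  Ordering tests report the bootstrap
fraction of replicates in which one event precedes another.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from .simulate import Trajectory, crossing_time

__all__ = [
    "CHANNELS",
    "ReadoutSeries",
    "generate_readout",
    "estimate_t50",
    "ordering_test",
]

#: Antibody-channel name -> model variable.
CHANNELS: dict[str, str] = {
    "pTyr15": "preMPF",   # inhibitory Cdk1 Tyr15 phosphorylation
    "pThr194": "Gwl",     # activating Greatwall Thr194 phosphorylation
    "pSer67": "ENSAPt",   # Gwl site on ENSA/ARPP19
    "pSP": "MPFa",        # bulk phospho-(Ser) CDK-substrate signal
}

MIN_SAMPLES = 4


@dataclass
class ReadoutSeries:
    """Noisy sampled pseudo-immunoblot signals.

    ``signals[channel]`` has shape (n_replicates, n_times).  With
    ``sigma=0`` and ``background=0`` the signals equal the trajectory
    values at the sampling times exactly; the same seed always yields
    the same series.
    """

    times: np.ndarray
    signals: dict[str, np.ndarray]
    sigma: float
    background: float
    normalization: float
    seed: int

    @property
    def n_replicates(self) -> int:
        return next(iter(self.signals.values())).shape[0]

    def mean(self, channel: str) -> np.ndarray:
        """Replicate-averaged signal of one channel."""
        return self.signals[channel].mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for channel, sig in self.signals.items():
            for rep in range(sig.shape[0]):
                for t, v in zip(self.times, sig[rep]):
                    rows.append({"time": t, "channel": channel,
                                 "value": v, "replicate": rep})
        return pd.DataFrame(rows)

    def to_csv(self, path_or_buf) -> None:
        header = (f"# sigma = {self.sigma}\n# background = {self.background}\n"
                  f"# normalization = {self.normalization}\n# seed = {self.seed}\n")
        body = self.to_frame().to_csv(index=False, float_format="%.10g")
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(header + body)
        else:
            with open(path_or_buf, "w") as fh:
                fh.write(header + body)


def generate_readout(traj: Trajectory, sampling_times, *, sigma: float = 0.1,
                     background: float = 0.0, seed: int = 0,
                     n_replicates: int = 1, normalization: float = 1.0,
                     channels: Optional[dict[str, str]] = None) -> ReadoutSeries:
    """Sample noisy pseudo-immunoblot channels from a trajectory.

    signal = interp(trajectory, t) * LogNormal(0, sigma) + background,
    then divided by ``normalization``.  All randomness comes from a
    generator seeded with ``seed``; no global state is touched.
    """
    times = np.asarray(sampling_times, float)
    if sigma < 0 or background < 0:
        raise ValueError("sigma and background must be >= 0")
    if times.min() < traj.times[0] - 1e-12 or times.max() > traj.times[-1] + 1e-12:
        raise ValueError(
            f"sampling times [{times.min()}, {times.max()}] outside the "
            f"trajectory span [{traj.times[0]}, {traj.times[-1]}]")
    channels = dict(channels) if channels is not None else dict(CHANNELS)
    rng = np.random.default_rng(seed)
    signals = {}
    for channel, variable in channels.items():
        truth = np.interp(times, traj.times, traj.value(variable))
        noise = (rng.lognormal(0.0, sigma, size=(n_replicates, len(times)))
                 if sigma > 0 else np.ones((n_replicates, len(times))))
        signals[channel] = (truth[None, :] * noise + background) / normalization
    return ReadoutSeries(times=times, signals=signals, sigma=sigma,
                         background=background, normalization=normalization,
                         seed=seed)


_SIGNAL_FLOOR = 1e-6  # log-space guard for zero-signal samples


def _choose_lam(times: np.ndarray, ylog: np.ndarray, sigma: float) -> float:
    """Smoothing penalty by the discrepancy principle: bisect the
    penalty until the RMS log-residual matches the known noise level."""
    if sigma <= 0:
        return 0.0
    target = sigma ** 2
    lo, hi = 1e-8, 1e8
    for _ in range(14):
        mid = np.sqrt(lo * hi)
        fit = make_smoothing_spline(times, ylog, lam=mid)(times)
        if np.mean((fit - ylog) ** 2) < target:
            lo = mid
        else:
            hi = mid
    return np.sqrt(lo * hi)


def _smooth_fit(times: np.ndarray, values: np.ndarray, sigma: float,
                lam: Optional[float] = None
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Penalized-spline smoothing of log-signal.

    Log-normal multiplicative noise is homoscedastic on the log scale
    with standard deviation ``sigma``, so an unweighted spline smoothed
    to that level is the natural curve estimate.  Returns (fit at sample
    times, fine time grid, fit on fine grid, penalty used); the fine
    grid (20x the sampling density) is used for crossing interpolation.
    """
    y = np.log(np.maximum(values, _SIGNAL_FLOOR))
    if lam is None:
        lam = _choose_lam(times, y, sigma)
    spline = make_smoothing_spline(times, y, lam=lam if lam > 0 else None)
    fine = np.linspace(times[0], times[-1], 20 * len(times))
    return np.exp(spline(times)), fine, np.exp(spline(fine)), lam


def estimate_t50(readout: ReadoutSeries, channel: str, direction: str,
                 *, fraction: float = 0.5, n_boot: int = 200,
                 seed: int = 0, ci_level: float = 0.95
                 ) -> Optional[tuple[float, tuple[float, float]]]:
    """Half-transition time of a channel with a bootstrap interval.

    The point estimate interpolates the smoothed series (GCV spline in
    log space, where the noise is homoscedastic) at ``fraction`` of its
    initial-to-final excursion; smoothing first pools neighbouring
    samples and suppresses the early-crossing bias a raw noisy series
    has wherever it hovers near the threshold.  Uncertainty comes from
    resampling residuals around the same fit, with a fixed seed.
    Returns ``(t50, (lo, hi))`` or None when the channel never crosses.
    """
    if len(readout.times) < MIN_SAMPLES:
        raise ValueError(
            f"need at least {MIN_SAMPLES} sampling times spanning the "
            f"transition, got {len(readout.times)}")
    values = readout.mean(channel)
    sigma = readout.sigma / np.sqrt(readout.n_replicates)
    fit, fine, fine_fit, lam = _smooth_fit(readout.times, values, sigma)
    t50 = crossing_time(fine, fine_fit, fraction, direction)
    if t50 is None:
        return None
    residuals = values - fit
    rng = np.random.default_rng(seed)
    boot = []
    for _ in range(n_boot):
        resampled = fit + rng.choice(residuals, size=len(residuals), replace=True)
        _, bfine, bfit, _ = _smooth_fit(readout.times, np.maximum(resampled, 0.0),
                                        sigma, lam=lam)
        tb = crossing_time(bfine, bfit, fraction, direction)
        if tb is not None:
            boot.append(tb)
    if boot:
        alpha = 0.5 * (1.0 - ci_level)
        lo, hi = np.quantile(boot, [alpha, 1.0 - alpha])
    else:
        lo = hi = t50
    return float(t50), (float(lo), float(hi))


def ordering_test(readout: ReadoutSeries, channel_a: str, channel_b: str,
                  directions: tuple[str, str], *, n_boot: int = 500,
                  seed: int = 0, fraction: float = 0.5,
                  readout_b: Optional[ReadoutSeries] = None) -> float:
    """Bootstrap fraction of replicates with t50(a) < t50(b).

    Channels are resampled independently (residual bootstrap around
    their smoothed fits).  Ties and replicates where a bootstrap series
    fails to cross contribute 1/2, so two identical channels score about
    0.5 and reversing the channel order maps the fraction f -> 1 - f.
    ``readout_b`` lets channel_b come from a different series (e.g. a
    different scenario's simulation).
    """
    rb = readout_b if readout_b is not None else readout
    dir_a, dir_b = directions
    est_a = estimate_t50(readout, channel_a, dir_a, n_boot=0, seed=seed)
    est_b = estimate_t50(rb, channel_b, dir_b, n_boot=0, seed=seed)
    if est_a is None or est_b is None:
        raise ValueError("both channels must cross their half-transition")

    va, vb = readout.mean(channel_a), rb.mean(channel_b)
    sig_a = readout.sigma / np.sqrt(readout.n_replicates)
    sig_b = rb.sigma / np.sqrt(rb.n_replicates)
    fit_a, _, _, lam_a = _smooth_fit(readout.times, va, sig_a)
    fit_b, _, _, lam_b = _smooth_fit(rb.times, vb, sig_b)
    res_a, res_b = va - fit_a, vb - fit_b
    rng = np.random.default_rng(seed)
    score = 0.0
    for _ in range(n_boot):
        _, fa, ya, _ = _smooth_fit(readout.times, np.maximum(
            fit_a + rng.choice(res_a, size=len(res_a), replace=True), 0.0),
            sig_a, lam=lam_a)
        _, fb, yb, _ = _smooth_fit(rb.times, np.maximum(
            fit_b + rng.choice(res_b, size=len(res_b), replace=True), 0.0),
            sig_b, lam=lam_b)
        ta = crossing_time(fa, ya, fraction, dir_a)
        tb = crossing_time(fb, yb, fraction, dir_b)
        if ta is None or tb is None or ta == tb:
            score += 0.5
        elif ta < tb:
            score += 1.0
    return score / n_boot
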
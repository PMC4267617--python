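"""Mean-squared displacement and Einstein diffusion coefficients."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Trajectory

__all__ = ["MSDResult", "unwrap", "msd"]

#: A^2/ps -> cm^2/s
_CM2_PER_S = 1e-16 / 1e-12


@dataclass
class MSDResult:
    lags: np.ndarray  # ps
    msd: np.ndarray  # A^2
    n_pairs: np.ndarray  # origin pairs per lag
    D: float  # A^2/ps
    D_cm2_s: float
    fit_window: tuple[float, float]  # ps
    fit_r2: float
    #: slope of the second half of the fit window over the first half;
    #: ~1 for diffusive motion, ~3 for ballistic (quadratic) MSD
    slope_ratio: float = 1.0

    @property
    def ballistic_flag(self) -> bool:
        return self.slope_ratio > 1.5


def unwrap(traj: Trajectory, species: str, max_step_fraction: float = 0.45) -> np.ndarray:
    """Remove periodic jumps so displacement accumulates continuously.

    Returns (n_frames, n_ions, 3) coordinates.  Per-step displacements must
    stay well below half the box per axis; steps beyond
    ``max_step_fraction * box`` are rejected since wrapping then becomes
    ambiguous (aliased jumps are undetectable at exactly half a box).
    """
    idx = traj.species_indices(species)
    coords = traj.coordinates[:, idx, :].copy()
    if traj.n_frames < 2:
        return coords
    box = traj.box[:-1, None, :]
    steps = np.diff(coords, axis=0)
    jumps = np.round(steps / box)
    raw = steps - jumps * box
    if np.any(np.abs(raw) >= max_step_fraction * box):
        raise ValueError(
            "per-step displacement approaches half the box; "
            "sample the trajectory more finely"
        )
    coords[1:] = coords[0] + np.cumsum(raw, axis=0)
    return coords


def msd(
    unwrapped: np.ndarray,
    dt: float,
    max_lag: float,
    fit_window: tuple[float, float] | None = None,
    min_fit_points: int = 10,
) -> MSDResult:
    """All-origin MSD and Einstein D = slope/6 over the fit window.

    ``fit_window`` defaults to [10%, 50%] of max_lag, skipping the short-lag
    regime and the noisy tail.
    """
    unwrapped = np.asarray(unwrapped, dtype=float)
    if unwrapped.ndim == 2:
        unwrapped = unwrapped[:, None, :]
    n_frames, n_ions, _ = unwrapped.shape
    max_lag_frames = int(round(max_lag / dt))
    if n_frames < 5 * max_lag_frames:
        raise ValueError(
            f"trace length {n_frames} frames < 5x max lag ({5 * max_lag_frames})"
        )
    lags_f = np.arange(1, max_lag_frames + 1)
    msd_vals = np.empty(len(lags_f))
    n_pairs = np.empty(len(lags_f), dtype=int)
    for i, L in enumerate(lags_f):
        d = unwrapped[L:] - unwrapped[:-L]
        msd_vals[i] = np.mean(np.sum(d * d, axis=-1))
        n_pairs[i] = (n_frames - L) * n_ions
    lags = lags_f * dt
    if fit_window is None:
        fit_window = (0.1 * max_lag, 0.5 * max_lag)
    in_fit = (lags >= fit_window[0]) & (lags <= fit_window[1])
    if in_fit.sum() < min_fit_points:
        raise ValueError(
            f"only {int(in_fit.sum())} lag points in fit window; need {min_fit_points}"
        )
    x, y = lags[in_fit], msd_vals[in_fit]
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum((y - yhat) ** 2) / ss_tot if ss_tot > 0 else 1.0
    D = max(slope / 6.0, 0.0)
    half = len(x) // 2
    slope_ratio = 1.0
    if half >= 2 and len(x) - half >= 2:
        s1 = np.polyfit(x[:half], y[:half], 1)[0]
        s2 = np.polyfit(x[half:], y[half:], 1)[0]
        if abs(s1) > 1e-15:
            slope_ratio = float(s2 / s1)
    return MSDResult(
        lags=lags,
        msd=msd_vals,
        n_pairs=n_pairs,
        D=D,
        D_cm2_s=D * _CM2_PER_S,
        fit_window=tuple(fit_window),
        fit_r2=float(r2),
        slope_ratio=slope_ratio,
    )
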
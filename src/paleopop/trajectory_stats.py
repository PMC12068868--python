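"""Scaling PSMC rounds to natural units and summarizing early growth.

PSMC reports a piecewise-constant history in coalescent units: relative
sizes lambda_k over scaled times t_k, with a base scale theta0.  The
conversion to individuals and years is the standard plotting math:

    mu_gen = mu_per_site_year * generation_years      (per-generation rate)
    N0     = theta0 / (4 * mu_gen * bin_size)
    t_yr   = 2 * N0 * t_k * generation_years
    Ne     = lambda_k * N0

The study-level variables summarized per lineage are the mean and SD of
Ne over the retained steps, their ratio (CV), and three early-growth
quantities anchored at the lineage's oldest retained step (its "PSMC
inception", the trough) and its first historic extremum (the peak):

    degree = 1 - N_trough / N_peak      (negative for initial decline)
    deltaT = t_trough - t_peak          (years; always >= 0)
    rate   = degree / deltaT            (per year)
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from paleopop.psmc_io import PsmcRound

DEFAULT_CUTOFF_YEARS = 50_000.0


@dataclass(frozen=True)
class ScalingParams:
    """Constants converting coalescent-scaled PSMC output to natural units.

    mu_per_site_year is a per-YEAR mutation rate; psmc's theta is per
    generation, so the per-generation rate used internally is
    mu_per_site_year * generation_years.  bin_size is the number of sites
    psmc collapses into one bin (its -s option, default 100).
    """

    mu_per_site_year: float = 2.3e-9
    generation_years: float = 2.5
    bin_size: float = 100.0

    def __post_init__(self) -> None:
        for name in ("mu_per_site_year", "generation_years", "bin_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def mu_per_generation(self) -> float:
        return self.mu_per_site_year * self.generation_years


@dataclass
class DemographicTrajectory:
    """Step function of effective population size over years before present.

    ``t_years`` is strictly increasing from recent to ancient; the size
    ``ne[k]`` applies on the interval [t_years[k], t_years[k+1]); the last
    (oldest) value extends to the lineage's origin.
    """

    t_years: np.ndarray
    ne: np.ndarray
    taxon_id: str = ""

    def __post_init__(self) -> None:
        self.t_years = np.asarray(self.t_years, dtype=float)
        self.ne = np.asarray(self.ne, dtype=float)
        if self.t_years.shape != self.ne.shape or self.t_years.ndim != 1:
            raise ValueError("t_years and ne must be 1-D arrays of equal length")
        if len(self.t_years) < 2:
            raise ValueError("a trajectory needs at least 2 steps")
        if self.t_years[0] < 0:
            raise ValueError("times before present must be >= 0")
        if not np.all(np.diff(self.t_years) > 0):
            raise ValueError("step times must be strictly increasing")
        if not (np.all(np.isfinite(self.ne)) and np.all(self.ne > 0)):
            raise ValueError("Ne values must be finite and positive")

    def __len__(self) -> int:
        return len(self.t_years)

    def at(self, times) -> np.ndarray:
        """Evaluate the step function at arbitrary times (held at the ends)."""
        times = np.asarray(times, dtype=float)
        idx = np.clip(np.searchsorted(self.t_years, times, side="right") - 1, 0, len(self) - 1)
        return self.ne[idx]


@dataclass
class GrowthSummary:
    """Per-lineage derived variables plus the peak/trough anchors.

    ``rate`` is None (flagged missing) when deltaT is zero, rather than
    an infinity, so downstream rank tests see an explicit missing value.
    """

    taxon_id: str
    mean_Ne: float
    sd_Ne: float
    cv: float
    N_peak: float
    N_trough: float
    t_peak: float
    t_trough: float
    degree: float
    deltaT: float
    rate: float | None
    n_steps_retained: int


class DegenerateTrajectoryError(ValueError):
    """Truncation or summary left too little of a trajectory to analyze."""


def scale_round(r: PsmcRound, sp: ScalingParams = ScalingParams(),
                taxon_id: str = "") -> DemographicTrajectory:
    """Convert one PSMC round into an Ne trajectory in individuals and years."""
    if r.theta0 <= 0:
        raise ValueError(f"theta0 must be > 0, got {r.theta0}")
    n0 = r.theta0 / (4.0 * sp.mu_per_generation * sp.bin_size)
    t = np.array([2.0 * n0 * t_k * sp.generation_years for t_k, _ in r.segments])
    ne = np.array([lam * n0 for _, lam in r.segments])
    return DemographicTrajectory(t_years=t, ne=ne, taxon_id=taxon_id)


def truncate_recent(traj: DemographicTrajectory,
                    cutoff_years: float = DEFAULT_CUTOFF_YEARS) -> DemographicTrajectory:
    """Drop steps more recent than the cutoff (default 50 kyr).

    A step survives iff its recent boundary t_k >= cutoff_years; no
    interpolation of the straddling segment is attempted.  The input is
    left unmodified.
    """
    keep = traj.t_years >= cutoff_years
    if keep.sum() < 2:
        raise DegenerateTrajectoryError(
            f"taxon {traj.taxon_id or '<unnamed>'}: fewer than 2 steps survive "
            f"the {cutoff_years:g}-year cutoff"
        )
    return DemographicTrajectory(
        t_years=traj.t_years[keep].copy(), ne=traj.ne[keep].copy(), taxon_id=traj.taxon_id
    )


def _first_turning_peak(ne_old_to_recent: np.ndarray, epsilon: float) -> int:
    """Index (in oldest->recent order) of the first significant extremum.

    Scans from the origin; the peak is the first step at which the running
    direction of change reverses AND the cumulative relative change since
    the origin exceeds ``epsilon``.  Monotone trajectories (no qualifying
    reversal) peak at the most recent step.
    """
    ne = ne_old_to_recent
    origin = ne[0]
    direction = 0
    for i in range(1, len(ne)):
        d = ne[i] - ne[i - 1]
        s = 0 if d == 0 else (1 if d > 0 else -1)
        if s == 0:
            continue
        if direction == 0:
            direction = s
            continue
        if s != direction:
            if abs(ne[i - 1] / origin - 1.0) > epsilon:
                return i - 1
            direction = s  # sub-epsilon wiggle: track the new direction
    return len(ne) - 1


def _global_peak(ne_old_to_recent: np.ndarray) -> int:
    """Argmax of Ne, except when the origin itself is the maximum (initial
    decline), in which case the extremum is the minimum."""
    imax = int(np.argmax(ne_old_to_recent))
    if imax == 0:
        return int(np.argmin(ne_old_to_recent))
    return imax


def summarize(traj: DemographicTrajectory, peak_mode: str = "first_turning",
              epsilon: float = 0.05, time_weighted: bool = False,
              sd_ddof: int = 0) -> GrowthSummary:
    """Compute the per-lineage derived variables from a (truncated) trajectory.

    Parameters
    ----------
    peak_mode
        "first_turning" (default): peak at the first extremum, scanning
        from the origin, whose cumulative relative change since the origin
        exceeds ``epsilon`` (a filter against step-noise wiggles);
        monotone trajectories peak at the most recent step.  "global":
        peak at the maximum Ne, or at the minimum when the maximum is the
        origin step itself (initial decline).
    time_weighted
        Weight each step's Ne by the width of its time interval instead of
        counting steps equally.  The oldest step bounds the domain and has
        no interval width; it is excluded from weighted moments.
    sd_ddof
        0 (default) for the population-form SD, 1 for the sample form.
    """
    if len(traj) < 2:
        raise DegenerateTrajectoryError("need >= 2 steps to summarize")
    ne, t = traj.ne, traj.t_years

    if time_weighted:
        w = np.diff(t)
        vals = ne[:-1]
        mean = float(np.average(vals, weights=w))
        var = float(np.average((vals - mean) ** 2, weights=w))
        if sd_ddof == 1 and len(vals) > 1:
            var *= len(vals) / (len(vals) - 1)
        sd = math.sqrt(var)
    else:
        mean = float(np.mean(ne))
        sd = float(np.std(ne, ddof=sd_ddof))
    cv = sd / mean

    ne_o = ne[::-1]  # oldest -> recent
    t_o = t[::-1]
    if peak_mode == "first_turning":
        ipeak = _first_turning_peak(ne_o, epsilon)
    elif peak_mode == "global":
        ipeak = _global_peak(ne_o)
    else:
        raise ValueError(f"unknown peak_mode {peak_mode!r}")

    n_trough, t_trough = float(ne_o[0]), float(t_o[0])
    n_peak, t_peak = float(ne_o[ipeak]), float(t_o[ipeak])
    degree = 1.0 - n_trough / n_peak
    delta_t = t_trough - t_peak
    rate = degree / delta_t if delta_t > 0 else None

    return GrowthSummary(
        taxon_id=traj.taxon_id,
        mean_Ne=mean,
        sd_Ne=sd,
        cv=cv,
        N_peak=n_peak,
        N_trough=n_trough,
        t_peak=t_peak,
        t_trough=t_trough,
        degree=degree,
        deltaT=delta_t,
        rate=rate,
        n_steps_retained=len(traj),
    )


def replicate_envelope(trajs: list[DemographicTrajectory], grid) -> dict[str, np.ndarray]:
    """Pointwise (min, median, max) Ne across replicate trajectories.

    Each trajectory is evaluated as a step function at every grid time;
    order statistics are taken across replicates per time point (the
    median of an even count is the mean of the middle pair).
    """
    if not trajs:
        raise ValueError("replicate_envelope needs at least one trajectory")
    grid = np.asarray(grid, dtype=float)
    values = np.vstack([tr.at(grid) for tr in trajs])
    return {
        "t_years": grid,
        "min": values.min(axis=0),
        "median": np.median(values, axis=0),
        "max": values.max(axis=0),
    }
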
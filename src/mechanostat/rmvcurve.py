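"""Surface (re)modeling velocity (RmV) curves and mechanostat fits.

The RmV curve condenses a surface sample table into velocity versus local
mechanical signal: the signal axis is capped at its 99th percentile and
binned at 1% of the cap; the signed (re)modeling distance axis is binned at
1% of the maximum magnitude observed; per signal bin a count-weighted mean
distance (quiescent voxels contributing 0) is converted to µm/day with the
voxel size and scan interval.

Two mechanostat functions are fitted to the curve:

* a **piecewise linear** function with resorption/formation saturation
  levels (RSL <= 0, FSL >= 0, µm/day), thresholds (RT <= FT, signal units)
  bounding the zero-velocity "lazy zone", and velocity moduli (RVM, FVM,
  µm/day per signal unit) — the classical mechanostat;
* a **hyperbola** ``RmV(ms) = FSL - RmVM / (RmT + ms)``, a smooth
  three-parameter alternative; its RSL is defined post hoc as the value of
  the fitted function at the smallest observed signal.

Both fits are unweighted bounded least squares over the unmasked bins with
deterministic multi-start over the threshold parameters, and report the
RMSE between the fit and the curve on those bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "RmVCurve",
    "PiecewiseFit",
    "HyperbolaFit",
    "piecewise_rmv",
    "hyperbola_rmv",
    "compute_rmv_curve",
    "group_average_curve",
    "group_curve_from_tables",
    "fit_piecewise",
    "fit_hyperbola",
]

N_BINS = 100

#: least-squares bounds on saturation levels, µm/day
SATURATION_BOUND = 50.0


@dataclass
class RmVCurve:
    """Per-signal-bin weighted-mean (re)modeling velocity.

    ``bin_centers`` are in signal units (the cap spans 100 bins);
    ``rmv`` is µm/day, NaN where ``mask`` is False (no counts, or fewer
    contributing samples than the group filter requires).
    """

    bin_centers: np.ndarray
    rmv: np.ndarray
    counts: np.ndarray
    n_samples: np.ndarray
    cap: float
    voxel_size: float
    interval_days: float
    mask: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = self.counts > 0
    @property
    def signal_min(self) -> float:
        return float(self.bin_centers[self.mask].min())


@dataclass
class PiecewiseFit:
    """Parameters of the piecewise linear mechanostat (NaN = unidentifiable)."""

    RSL: float
    RVM: float
    RT: float
    FT: float
    FVM: float
    FSL: float
    rmse: float
    resorption_identifiable: bool = True
    formation_identifiable: bool = True

    def __call__(self, ms):
        return piecewise_rmv(
            ms, self.RSL, self.RVM, self.RT, self.FT, self.FVM, self.FSL
        )

    def as_dict(self) -> dict:
        return {
            "RSL": self.RSL, "RVM": self.RVM, "RT": self.RT, "FT": self.FT,
            "FVM": self.FVM, "FSL": self.FSL, "rmse": self.rmse,
        }


@dataclass
class HyperbolaFit:
    """Parameters of the hyperbola mechanostat."""

    FSL: float
    RmVM: float
    RmT: float
    RSL: float  # value of the fitted function at the minimum observed signal
    rmse: float

    def __call__(self, ms):
        return hyperbola_rmv(ms, self.FSL, self.RmVM, self.RmT)

    @property
    def zero_crossing(self) -> float:
        """Signal at which the fitted curve crosses zero velocity.

        Reported separately from RmT: the hyperbola is zero at
        ``RmVM / FSL - RmT``, not at RmT itself.
        """
        if self.FSL == 0:
            return float("nan")
        return self.RmVM / self.FSL - self.RmT

    def as_dict(self) -> dict:
        return {
            "FSL": self.FSL, "RmVM": self.RmVM, "RmT": self.RmT,
            "RSL": self.RSL, "rmse": self.rmse,
        }


def piecewise_rmv(ms, RSL, RVM, RT, FT, FVM, FSL):
    """Piecewise linear mechanostat: saturation / ramp / lazy zone / ramp / saturation."""
    ms = np.asarray(ms, dtype=np.float64)
    lo_break = RT + RSL / RVM if RVM > 0 else -np.inf
    hi_break = FT + FSL / FVM if FVM > 0 else np.inf
    return np.select(
        [ms < lo_break, ms < RT, ms <= FT, ms < hi_break],
        [RSL, RVM * (ms - RT), 0.0, FVM * (ms - FT)],
        default=FSL,
    )


def hyperbola_rmv(ms, FSL, RmVM, RmT):
    """Hyperbola mechanostat: ``FSL - RmVM / (RmT + ms)``."""
    ms = np.asarray(ms, dtype=np.float64)
    return FSL - RmVM / (RmT + ms)


def _bin_distances(d: np.ndarray, mode: str) -> np.ndarray:
    """Quantize signed distances at 1% of the maximum magnitude (sign kept)."""
    if mode == "raw":
        return d
    if mode != "binned":
        raise ValueError(f"unknown distance binning mode: {mode}")
    maxabs = np.abs(d).max()
    if maxabs == 0:
        return d
    w = maxabs / N_BINS
    idx = np.minimum((np.abs(d) / w).astype(np.int64), N_BINS - 1)
    out = np.sign(d) * (idx + 0.5) * w
    return np.where(d == 0, 0.0, out)


def compute_rmv_curve(
    table: pd.DataFrame,
    voxel_size: float,
    interval_days: float,
    cap: float | None = None,
    distance_binning: str = "binned",
) -> RmVCurve:
    """(Re)modeling velocity curve from a signal-sampled surface table.

    Per signal bin the velocity is the mean of the (optionally 1%-binned)
    signed distances over all rows in the bin — quiescent rows enter as 0 —
    scaled by ``voxel_size / interval_days`` to µm/day.  ``cap`` overrides
    the per-table 99th percentile (used for group-level shared grids).
    """
    if interval_days <= 0:
        raise ValueError("interval_days must be positive")
    if len(table) == 0:
        raise ValueError("empty surface table")
    sig = table["signal"].to_numpy(dtype=np.float64)
    if np.any(np.isnan(sig)):
        raise ValueError("table has unsampled signal values")
    if cap is None:
        cap = float(np.percentile(sig, 99))
    if cap <= 0:
        raise ValueError("nonpositive signal cap")
    bins = np.clip((sig / cap * N_BINS).astype(np.int64), 0, N_BINS - 1)
    d = _bin_distances(table["distance_vox"].to_numpy(dtype=np.float64), distance_binning)

    counts = np.bincount(bins, minlength=N_BINS).astype(np.int64)
    sums = np.bincount(bins, weights=d, minlength=N_BINS)
    rmv = np.full(N_BINS, np.nan)
    nz = counts > 0
    rmv[nz] = sums[nz] / counts[nz] * voxel_size / interval_days
    centers = (np.arange(N_BINS) + 0.5) * cap / N_BINS
    return RmVCurve(
        bin_centers=centers,
        rmv=rmv,
        counts=counts,
        n_samples=nz.astype(np.int64),
        cap=cap,
        voxel_size=voxel_size,
        interval_days=interval_days,
    )


def group_average_curve(curves: list[RmVCurve], min_samples: int = 3) -> RmVCurve:
    """Unweighted per-bin mean of per-sample curves on a shared bin grid.

    A bin contributes only samples with counts there; bins with fewer than
    ``min_samples`` contributing samples are masked (the group curve is
    reported only where at least that many animals are averaged).
    """
    if len(curves) < min_samples:
        raise ValueError(f"need >= {min_samples} curves, got {len(curves)}")
    caps = {round(c.cap, 9) for c in curves}
    if len(caps) != 1:
        raise ValueError("curves are not on a shared bin grid (different caps)")
    rmv_stack = np.stack([c.rmv for c in curves])
    have = np.stack([c.counts > 0 for c in curves])
    n_samples = have.sum(axis=0)
    mean = np.full(N_BINS, np.nan)
    ok = n_samples >= min_samples
    with np.errstate(invalid="ignore"):
        stacked = np.where(have, rmv_stack, 0.0)
        mean[ok] = stacked.sum(axis=0)[ok] / n_samples[ok]
    if not ok.any():
        raise ValueError("no bin has enough contributing samples")
    c0 = curves[0]
    return RmVCurve(
        bin_centers=c0.bin_centers,
        rmv=mean,
        counts=np.stack([c.counts for c in curves]).sum(axis=0),
        n_samples=n_samples,
        cap=c0.cap,
        voxel_size=c0.voxel_size,
        interval_days=c0.interval_days,
        mask=ok,
    )


def group_curve_from_tables(
    tables: list[pd.DataFrame],
    voxel_size: float,
    interval_days: float,
    min_samples: int = 3,
    distance_binning: str = "binned",
) -> RmVCurve:
    """Group-level curve: shared cap from pooled signals, then averaging."""
    pooled = np.concatenate(
        [t["signal"].to_numpy(dtype=np.float64) for t in tables]
    )
    cap = float(np.percentile(pooled, 99))
    curves = [
        compute_rmv_curve(
            t, voxel_size, interval_days, cap=cap, distance_binning=distance_binning
        )
        for t in tables
    ]
    return group_average_curve(curves, min_samples=min_samples)


def _rmse(resid: np.ndarray) -> float:
    return float(np.sqrt(np.mean(resid**2)))


def fit_piecewise(curve: RmVCurve, n_starts: int = 3) -> PiecewiseFit:
    """Fit the piecewise linear mechanostat to the curve's unmasked bins.

    Internally the function is parametrized by its knots — saturation
    onset / resorption threshold / formation threshold / saturation onset
    as ``(RT - d0, RT, RT + dT, RT + dT + d1)`` with plateau values RSL
    and FSL — which keeps the least-squares problem well conditioned and
    the lazy zone from inverting; the velocity moduli are recovered as
    ``RVM = -RSL/d0`` and ``FVM = FSL/d1``.  A deterministic multi-start
    over coarse threshold placements guards against local minima.  A
    branch with no data of its sign (e.g. a curve that never goes
    negative) is flagged unidentifiable and its parameters reported as NaN
    rather than invented.
    """
    x = curve.bin_centers[curve.mask]
    y = curve.rmv[curve.mask]
    if len(x) < 6:
        raise ValueError("need >= 6 unmasked bins for the piecewise fit")
    has_neg = bool(np.any(y < 0))
    has_pos = bool(np.any(y > 0))
    xmin, xmax = float(x.min()), float(x.max())
    span = xmax - xmin
    ymin, ymax = float(min(y.min(), 0.0)), float(max(y.max(), 0.0))
    dmin = max(span * 1e-6, 1e-9)

    def model(theta):
        RSL, d0, RT, dT, d1, FSL = theta
        knots_x = np.array([RT - d0, RT, RT + dT, RT + dT + d1])
        knots_y = np.array([RSL, 0.0, 0.0, FSL])
        return np.interp(x, knots_x, knots_y)

    lb = [-SATURATION_BOUND, dmin, xmin - span, 0.0, dmin, 0.0]
    ub = [0.0, 4 * span, xmax, span, 4 * span, SATURATION_BOUND]
    if not has_neg:
        lb[0] = -1e-12  # pin RSL at 0; resorption branch unidentifiable
    if not has_pos:
        ub[5] = 1e-12

    qs = np.linspace(0.2, 0.8, n_starts)
    best = None
    for qr in qs:
        for qf in qs:
            RT0 = xmin + qr * span
            FT0 = xmin + max(qf, qr + 0.05) * span
            theta0 = np.clip(
                [ymin, 0.3 * span, RT0, FT0 - RT0, 0.3 * span, ymax], lb, ub
            )
            try:
                res = least_squares(
                    lambda th: model(th) - y,
                    theta0,
                    bounds=(lb, ub),
                    xtol=1e-12,
                    ftol=1e-12,
                    gtol=1e-12,
                )
            except Exception:
                continue
            if best is None or res.cost < best.cost - 1e-15:
                best = res
    if best is None:
        raise RuntimeError("piecewise fit did not converge from any start")
    RSL, d0, RT, dT, d1, FSL = best.x
    rmse = _rmse(model(best.x) - y)
    # a plateau whose onset lies outside the observed signal range is not
    # identified by the data (any more extreme saturation level fits
    # equally well); report the curve value at the range edge instead,
    # mirroring the at-minimum-signal convention of the hyperbola's RSL
    if RT - d0 < xmin:
        RSL = float(np.interp(xmin, [RT - d0, RT], [RSL, 0.0]))
        d0 = RT - xmin
    if RT + dT + d1 > xmax:
        FSL = float(np.interp(xmax, [RT + dT, RT + dT + d1], [0.0, FSL]))
        d1 = xmax - (RT + dT)
    FT = RT + dT
    RVM = -RSL / d0
    FVM = FSL / d1
    if not has_neg:
        RSL, RVM, RT = np.nan, np.nan, np.nan
    if not has_pos:
        FSL, FVM, FT = np.nan, np.nan, np.nan
    return PiecewiseFit(
        RSL=float(RSL), RVM=float(RVM), RT=float(RT), FT=float(FT),
        FVM=float(FVM), FSL=float(FSL), rmse=rmse,
        resorption_identifiable=has_neg, formation_identifiable=has_pos,
    )


def fit_hyperbola(curve: RmVCurve, n_starts: int = 8) -> HyperbolaFit:
    """Fit the hyperbola mechanostat; poles inside the data range rejected.

    RmT is constrained so that ``RmT + ms > 0`` over the fitted signal
    range.  RSL is computed post hoc as the fitted value at the smallest
    observed signal.
    """
    x = curve.bin_centers[curve.mask]
    y = curve.rmv[curve.mask]
    if len(x) < 3:
        raise ValueError("need >= 3 unmasked bins for the hyperbola fit")
    xmin, xmax = float(x.min()), float(x.max())
    lb = [-SATURATION_BOUND, 0.0, -xmin + 1e-9 + 1e-6 * max(xmax, 1.0)]
    ub = [SATURATION_BOUND, np.inf, np.inf]

    def model(theta):
        return hyperbola_rmv(x, *theta)

    best = None
    for RmT0 in np.geomspace(
        max(lb[2], 1e-3 * max(xmax, 1.0)), 10 * max(xmax, 1.0), n_starts
    ):
        FSL0 = float(np.clip(y.max(), lb[0] + 1e-9, ub[0] - 1e-9))
        RmVM0 = max((FSL0 - float(y[0])) * (RmT0 + x[0]), 1e-6)
        theta0 = np.clip([FSL0, RmVM0, RmT0], lb, ub)
        try:
            res = least_squares(
                lambda th: model(th) - y,
                theta0,
                bounds=(lb, ub),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost - 1e-15:
            best = res
    if best is None:
        raise RuntimeError("hyperbola fit did not converge from any start")
    FSL, RmVM, RmT = (float(v) for v in best.x)
    rsl = float(hyperbola_rmv(curve.signal_min, FSL, RmVM, RmT))
    return HyperbolaFit(
        FSL=FSL, RmVM=RmVM, RmT=RmT, RSL=rsl, rmse=_rmse(model(best.x) - y)
    )
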
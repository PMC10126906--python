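"""Bootstrap parameter distributions and the loading-frequency regression.

Mechanostat parameters estimated from a single group-average curve carry no
uncertainty; a **balanced bootstrap** provides it.  The group's sample ids
are tiled ``n_rep`` times, permuted once with a seeded generator, and split
into ``n_rep`` resampled groups of the original size — so every animal
appears exactly ``n_rep`` times across all replicates, removing the extra
Monte-Carlo variance of naive resampling.  Each replicate's group curve is
rebuilt from the resampled animals and refitted; parameter distributions
are summarized by their median and IQR.

Across loading frequencies ``f > 0`` the bootstrap medians of a parameter
are fitted with the logarithmic law ``y = y0 + a * ln(f)`` by ordinary
least squares; fit quality is reported as pseudo-R² = 1 - SS_res/SS_tot,
comparable across parameters of different magnitude.  Static and sham
groups have no frequency and cannot enter the regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rmvcurve import fit_hyperbola, fit_piecewise, group_curve_from_tables

__all__ = [
    "BootstrapDistribution",
    "LogFrequencyFit",
    "balanced_bootstrap_replicates",
    "bootstrap_parameter_distributions",
    "log_frequency_fit",
]

logger = logging.getLogger(__name__)

DEFAULT_N_REP = 2500

PIECEWISE_PARAMS = ("RSL", "RVM", "RT", "FT", "FVM", "FSL", "rmse")
HYPERBOLA_PARAMS = ("FSL", "RmVM", "RmT", "RSL", "rmse")


@dataclass
class BootstrapDistribution:
    """Replicate values of one parameter with median and IQR."""

    parameter: str
    values: np.ndarray
    seed: int
    n_failed: int = 0

    @property
    def median(self) -> float:
        return float(np.median(self.values))

    @property
    def iqr(self) -> tuple[float, float]:
        return (
            float(np.percentile(self.values, 25)),
            float(np.percentile(self.values, 75)),
        )


@dataclass
class LogFrequencyFit:
    """Logarithmic frequency dependence ``y = y0 + a ln f``."""

    y0: float
    a: float
    pseudo_r2: float
    frequencies: tuple[float, ...]

    def __call__(self, f):
        return self.y0 + self.a * np.log(f)


def balanced_bootstrap_replicates(
    sample_ids: list, n_rep: int = DEFAULT_N_REP, seed: int = 0
) -> list[list]:
    """Balanced bootstrap index sets: each id appears exactly n_rep times.

    The id list is concatenated ``n_rep`` times, permuted uniformly with a
    seeded generator, and split into ``n_rep`` blocks of the original
    group size.
    """
    n = len(sample_ids)
    if n < 2:
        raise ValueError("need >= 2 samples for bootstrapping")
    rng = np.random.default_rng(seed)
    pool = np.tile(np.arange(n), n_rep)
    rng.shuffle(pool)
    ids = np.asarray(sample_ids, dtype=object)
    return [list(ids[pool[r * n:(r + 1) * n]]) for r in range(n_rep)]


def bootstrap_parameter_distributions(
    tables: dict[object, pd.DataFrame],
    fit_kind: str,
    voxel_size: float,
    interval_days: float,
    n_rep: int = DEFAULT_N_REP,
    seed: int = 0,
    min_samples: int = 3,
    max_failure_frac: float = 0.2,
) -> dict[str, BootstrapDistribution]:
    """Bootstrap distributions of mechanostat parameters for one group.

    For every balanced-bootstrap replicate the group (re)modeling velocity
    curve is rebuilt from the resampled animals' surface tables (shared
    99th-percentile cap from the resampled pool) and refitted.  Aborts if
    more than ``max_failure_frac`` of the replicate fits fail.
    """
    if fit_kind not in ("piecewise", "hyperbola"):
        raise ValueError(f"unknown fit kind: {fit_kind}")
    if len(tables) < min_samples:
        raise ValueError(f"group of {len(tables)} samples is below {min_samples}")
    replicates = balanced_bootstrap_replicates(list(tables), n_rep, seed)
    param_names = PIECEWISE_PARAMS if fit_kind == "piecewise" else HYPERBOLA_PARAMS
    collected: dict[str, list[float]] = {p: [] for p in param_names}
    failures = 0
    for ids in replicates:
        try:
            curve = group_curve_from_tables(
                [tables[i] for i in ids],
                voxel_size,
                interval_days,
                min_samples=min_samples,
            )
            fit = fit_piecewise(curve) if fit_kind == "piecewise" else fit_hyperbola(curve)
        except (ValueError, RuntimeError) as exc:
            failures += 1
            logger.debug("replicate fit failed: %s", exc)
            continue
        d = fit.as_dict()
        for p in param_names:
            collected[p].append(d[p])
    if failures > max_failure_frac * n_rep:
        raise RuntimeError(
            f"{failures}/{n_rep} replicate fits failed "
            f"(> {max_failure_frac:.0%}); check the group's curves"
        )
    return {
        p: BootstrapDistribution(p, np.asarray(v), seed=seed, n_failed=failures)
        for p, v in collected.items()
    }


def log_frequency_fit(medians: dict[float, float]) -> LogFrequencyFit:
    """OLS fit of ``y = y0 + a ln f`` to per-frequency parameter medians."""
    freqs = np.asarray(sorted(medians), dtype=np.float64)
    if np.any(freqs <= 0):
        raise ValueError(
            "loading frequencies must be positive (static/sham groups have "
            "no frequency and cannot enter the logarithmic fit)"
        )
    if len(np.unique(freqs)) < 2:
        raise ValueError("need >= 2 distinct frequencies")
    y = np.asarray([medians[f] for f in freqs], dtype=np.float64)
    X = np.column_stack([np.ones_like(freqs), np.log(freqs)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    pseudo_r2 = 1.0 if ss_tot == 0 and ss_res < 1e-30 else 1.0 - ss_res / ss_tot
    return LogFrequencyFit(
        y0=float(coef[0]),
        a=float(coef[1]),
        pseudo_r2=pseudo_r2,
        frequencies=tuple(float(f) for f in freqs),
    )
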
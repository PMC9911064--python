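"""Post-processing of MSMC2-style coalescence-rate output.

Consumes the tab-separated ``.final.txt`` dialect (time_index,
left_time_boundary, right_time_boundary, lambda_00 [, lambda_01,
lambda_11]) with times and rates in the mutation-scaled units of the
sequentially Markovian coalescent.  Provides the relative cross-coalescence
rate rCCR = 2*lambda01 / (lambda00 + lambda11), the location of its 0.5
crossing (the conventional split-time point estimate), and the conversions
to years and effective population sizes.  The HMM that produces these
curves is upstream and never invoked here.

Scaling conventions: a scaled time t corresponds to t / mu_per_year years
(equivalently t / (mu_per_year * g) generations at generation time g), and
a scaled rate lambda to a diploid effective size Ne = 1 / (2 * lambda *
mu_per_generation).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class ScalingConstants:
    """Mutation-rate and generation-time constants for time/Ne scaling."""

    mu_per_year: float = 5.4e-9
    generation_years: float = 7.0

    def __post_init__(self) -> None:
        if self.mu_per_year <= 0 or self.generation_years <= 0:
            raise ValueError("scaling constants must be positive")

    @property
    def mu_per_generation(self) -> float:
        return self.mu_per_year * self.generation_years


@dataclass
class RateCurve:
    """Per-epoch coalescence rates with scaled epoch boundaries."""

    left: np.ndarray
    right: np.ndarray
    lambda00: np.ndarray
    lambda01: np.ndarray | None = None
    lambda11: np.ndarray | None = None
    labels: tuple[str, str] = ("pop0", "pop1")

    def __post_init__(self) -> None:
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        self.lambda00 = np.asarray(self.lambda00, dtype=float)
        if self.lambda01 is not None:
            self.lambda01 = np.asarray(self.lambda01, dtype=float)
        if self.lambda11 is not None:
            self.lambda11 = np.asarray(self.lambda11, dtype=float)
        n = self.left.size
        if self.right.size != n or self.lambda00.size != n:
            raise ValueError("epoch arrays must have equal length")
        bounds = np.concatenate([self.left[:1], self.right])
        if np.any(np.diff(bounds) < 0) or np.any(self.right < self.left):
            raise ValueError("epoch boundaries must be non-decreasing")
        for lam in (self.lambda00, self.lambda01, self.lambda11):
            if lam is not None and np.any(lam < 0):
                raise ValueError("rates must be >= 0")

    @property
    def n_epochs(self) -> int:
        return self.left.size

    @property
    def has_cross(self) -> bool:
        return self.lambda01 is not None and self.lambda11 is not None

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.left + self.right)


def read_msmc_output(path) -> RateCurve:
    """Parse an MSMC2 ``.final.txt`` file into a :class:`RateCurve`.

    Files with only ``lambda_00`` (a within-population run) are accepted;
    cross-rate operations then refuse the curve.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"time_index", "left_time_boundary", "right_time_boundary", "lambda_00"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    kwargs = {}
    if {"lambda_01", "lambda_11"} <= set(df.columns):
        kwargs = dict(
            lambda01=df["lambda_01"].to_numpy(), lambda11=df["lambda_11"].to_numpy()
        )
    return RateCurve(
        left=df["left_time_boundary"].to_numpy(),
        right=df["right_time_boundary"].to_numpy(),
        lambda00=df["lambda_00"].to_numpy(),
        **kwargs,
    )


def write_msmc_output(path, curve: RateCurve) -> None:
    cols = {
        "time_index": np.arange(curve.n_epochs),
        "left_time_boundary": curve.left,
        "right_time_boundary": curve.right,
        "lambda_00": curve.lambda00,
    }
    if curve.has_cross:
        cols["lambda_01"] = curve.lambda01
        cols["lambda_11"] = curve.lambda11
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def compute_rccr(curve: RateCurve) -> np.ndarray:
    """Per-epoch relative cross-coalescence rate 2*l01/(l00+l11).

    Epochs with a zero denominator are NaN (undefined).
    """
    if not curve.has_cross:
        raise ValueError("curve has no cross-coalescence rates")
    denom = curve.lambda00 + curve.lambda11
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, 2.0 * curve.lambda01 / denom, np.nan)
    return r


def find_crossing(curve: RateCurve, level: float = 0.5) -> float:
    """Scaled time where rCCR first rises through ``level``, scanning from
    the most recent epoch into the past.

    The crossing is located by linear interpolation between epoch-midpoint
    times.  A curve already at/above the level in its first epoch returns
    that epoch's midpoint with a warning; non-monotone curves use the first
    crossing, also with a warning.
    """
    r = compute_rccr(curve)
    mids = curve.midpoints
    ok = ~np.isnan(r)
    r, mids = r[ok], mids[ok]
    if r.size < 2:
        raise ValueError("rCCR defined on fewer than 2 epochs")
    if r[0] >= level:
        log.warning("rCCR already >= %.3g in the most recent epoch", level)
        return float(mids[0])
    above = np.flatnonzero(r >= level)
    if above.size == 0:
        raise ValueError(
            f"rCCR never reaches {level}: range [{r.min():.4g}, {r.max():.4g}] "
            f"over {r.size} epochs"
        )
    k = int(above[0])
    if np.any(r[k:] < level):
        log.warning("rCCR is non-monotone beyond the first crossing; using the first")
    # linear interpolation between the midpoints of epochs k-1 and k
    frac = (level - r[k - 1]) / (r[k] - r[k - 1])
    return float(mids[k - 1] + frac * (mids[k] - mids[k - 1]))


def scale_time_to_years(t_scaled: float, constants: ScalingConstants | None = None) -> float:
    """Scaled (per-site mutation-unit) time to years: t / mu_per_year."""
    c = constants or ScalingConstants()
    if t_scaled < 0:
        raise ValueError("scaled time must be >= 0")
    return t_scaled / c.mu_per_year


def scale_lambda_to_ne(lam, constants: ScalingConstants | None = None):
    """Scaled coalescence rate(s) to diploid Ne = 1/(2*lambda*mu_gen).

    Zero rates yield NaN (undefined epoch).
    """
    c = constants or ScalingConstants()
    lam = np.asarray(lam, dtype=float)
    with np.errstate(divide="ignore"):
        ne = np.where(lam > 0, 1.0 / (2.0 * lam * c.mu_per_generation), np.nan)
    return float(ne) if ne.ndim == 0 else ne


def split_time_years(curve: RateCurve, constants: ScalingConstants | None = None, level: float = 0.5) -> float:
    """Convenience: rCCR crossing of a curve, in years."""
    return scale_time_to_years(find_crossing(curve, level), constants)


__all__ = [
    "ScalingConstants",
    "RateCurve",
    "read_msmc_output",
    "write_msmc_output",
    "compute_rccr",
    "find_crossing",
    "scale_time_to_years",
    "scale_lambda_to_ne",
    "split_time_years",
]
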
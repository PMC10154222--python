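"""Roadblock metrics from DNA unzipping traces.

An unzipping trace records the force while a fork is driven through the
duplex; a bound protein shows up as a force elevation above the naked-DNA
baseline.  This module converts force/extension traces to force-versus-bp
curves, aligns them to a baseline by cross-correlation, and computes the
roadblock metrics: interaction range, maximum rupture force and the
binomial tether-breakage probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import uniform_filter1d

from .polymer_mechanics import (
    DsDnaElasticity,
    ForceExtensionTrace,
    SsDnaElasticity,
    unzip_bp_from_point,
)

__all__ = [
    "UnzipCurve",
    "to_unzip_curve",
    "align_to_baseline",
    "interaction_range",
    "max_rupture_force",
    "breakage_probability",
]


@dataclass
class UnzipCurve:
    """Force versus number of base pairs unzipped, 0-based from the trunk start."""

    bp_unzipped: np.ndarray
    force: np.ndarray  # pN
    full_length: int  # bp of the unzipping trunk
    aligned_offset: int = 0  # bp shift applied by alignment
    breakage_position: float | None = None  # bp, None if the tether survived
    valid: np.ndarray | None = None  # per-point inversion success
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bp_unzipped = np.asarray(self.bp_unzipped, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if len(self.bp_unzipped) != len(self.force):
            raise ValueError("bp_unzipped and force must have equal length")

    def __len__(self) -> int:
        return len(self.force)


def to_unzip_curve(trace: ForceExtensionTrace,
                   arms: DsDnaElasticity = DsDnaElasticity(),
                   arm_length_bp: float = 2000.0,
                   ss: SsDnaElasticity = SsDnaElasticity(),
                   full_length: int = 4000,
                   smoothing_window: float = 0.025) -> UnzipCurve:
    """Convert a force/extension trace to force versus bp unzipped.

    Pointwise inversion through the two-arm + 2j·ssDNA elastic model,
    followed by a 25 ms sliding-window low-pass of the bp series (as the
    instrument pipeline applies before alignment).  Points where the
    inversion fails are flagged in ``valid``.
    """
    j, ok = unzip_bp_from_point(trace.force, trace.extension, arms,
                                arm_length_bp, ss)
    n_win = max(1, int(round(smoothing_window * trace.acquisition_rate)))
    j_s = uniform_filter1d(np.asarray(j, dtype=float), n_win, mode="nearest")
    return UnzipCurve(bp_unzipped=j_s, force=np.array(trace.force, dtype=float),
                      full_length=full_length, valid=np.asarray(ok),
                      metadata=dict(trace.metadata))


def _resample_on_bp(curve_bp, curve_f, grid):
    order = np.argsort(curve_bp, kind="stable")
    return np.interp(grid, curve_bp[order], curve_f[order])


def align_to_baseline(curve: UnzipCurve, baseline: np.ndarray,
                      search_radius: int = 200,
                      exclude: tuple[float, float] | None = None) -> UnzipCurve:
    """Shift the bp axis to maximize cross-correlation with the baseline.

    ``baseline`` is the theoretical force at each bp (index = bp).  The
    correlation uses only protein-free regions: if ``exclude`` gives the
    (start, stop) bp of the disruption, that span is masked out.  The
    integer offset maximizing the correlation within ``±search_radius``
    bp is applied.  A featureless (flat) baseline raises, since every
    offset then scores equally.
    """
    baseline = np.asarray(baseline, dtype=float)
    if np.ptp(baseline) < 1e-9:
        raise ValueError("baseline is featureless; alignment is ambiguous")
    grid = np.arange(len(baseline), dtype=float)
    f_exp = _resample_on_bp(curve.bp_unzipped, curve.force, grid)
    mask = np.ones(len(grid), dtype=bool)
    if exclude is not None:
        mask &= ~((grid >= exclude[0]) & (grid <= exclude[1]))
    lo = max(0.0, float(np.min(curve.bp_unzipped)))
    hi = float(np.max(curve.bp_unzipped))
    mask &= (grid >= lo) & (grid <= hi)
    if mask.sum() < 200:
        raise ValueError("need at least 200 bp of protein-free curve to align")
    best, best_score = 0, -np.inf
    b = baseline - baseline[mask].mean()
    for off in range(-search_radius, search_radius + 1):
        shifted = np.interp(grid, grid + off, f_exp, left=np.nan, right=np.nan)
        m = mask & np.isfinite(shifted)
        if m.sum() < 100:
            continue
        x = shifted[m] - shifted[m].mean()
        y = b[m] - b[m].mean()
        denom = np.sqrt((x * x).sum() * (y * y).sum())
        score = (x * y).sum() / denom if denom > 0 else -np.inf
        if score > best_score:
            best_score, best = score, off
    new_bp = curve.bp_unzipped + best
    new_break = (curve.breakage_position + best
                 if curve.breakage_position is not None else None)
    return replace(curve, bp_unzipped=new_bp,
                   aligned_offset=curve.aligned_offset + best,
                   breakage_position=new_break)


def interaction_range(curve: UnzipCurve, baseline: np.ndarray,
                      threshold: float = 2.0, min_run_bp: int = 5) -> float:
    """Total bp over which the force exceeds the baseline by >= ``threshold``.

    Sums all consecutive elevated runs before the breakage position;
    sub-threshold gaps are not counted, and runs shorter than
    ``min_run_bp`` are discarded as noise spikes.
    """
    if baseline is None:
        raise ValueError("a baseline is required")
    baseline = np.asarray(baseline, dtype=float)
    grid = np.arange(len(baseline), dtype=float)
    stop = curve.breakage_position
    if stop is not None:
        grid_mask = grid < stop
    else:
        grid_mask = np.ones(len(grid), dtype=bool)
    lo = float(np.min(curve.bp_unzipped))
    hi = float(np.max(curve.bp_unzipped))
    grid_mask &= (grid >= lo) & (grid <= hi)
    f = _resample_on_bp(curve.bp_unzipped, curve.force, grid)
    elevated = grid_mask & (f - baseline >= threshold)
    # sum run lengths of consecutive elevated bp
    total = 0
    run = 0
    for e in elevated:
        if e:
            run += 1
        else:
            if run >= min_run_bp:
                total += run
            run = 0
    if run >= min_run_bp:
        total += run
    return float(total)


def max_rupture_force(curve: UnzipCurve) -> float:
    """Maximum (smoothed) force before breakage, or over the whole curve."""
    f = curve.force
    if curve.breakage_position is not None:
        m = curve.bp_unzipped < curve.breakage_position
        if m.any():
            f = f[m]
    return float(np.max(f))


def breakage_probability(curves: list[UnzipCurve],
                         length_fraction: float = 0.8) -> tuple[float, float]:
    """Fraction of tethers that broke before reaching 80% of full length.

    Returns ``(fraction, sem)`` with the standard error of a binomial
    proportion, sem = sqrt(p(1-p)/n).
    """
    if not curves:
        raise ValueError("need at least one curve")
    n = len(curves)
    k = sum(1 for c in curves
            if c.breakage_position is not None
            and c.breakage_position < length_fraction * c.full_length)
    p = k / n
    sem = float(np.sqrt(p * (1.0 - p) / n))
    return float(p), sem
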
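"""Seeded generators of synthetic single-molecule traces.

Each generator emulates the statistical structure one analysis stage
assumes — constant-velocity stretching with loop ruptures, constant-force
lifetime draws, unzipping curves with bound-protein force elevations, and
magnetic-tweezers burst-and-pause relaxation — and returns a
machine-readable ground-truth log so every stage has a closed-loop
recovery test without instrument data.

All generators are quasi-static (no bead/trap dynamics) and deterministic
under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .polymer_mechanics import (
    DsDnaElasticity,
    ForceExtensionTrace,
    SsDnaElasticity,
    ds_extension,
    ss_extension_per_nt,
)
from .twist_analysis import HatCurveModel, TwistTrace

__all__ = [
    "StretchScenario",
    "TwistScenario",
    "gen_stretch_trace",
    "gen_survival_lifetimes",
    "gen_unzip_curve",
    "gen_unzip_trace",
    "gen_twist_trace",
    "random_sequence",
]


def random_sequence(n_bp: int, gc: float = 0.5,
                    rng: np.random.Generator | None = None,
                    seed: int | None = None) -> str:
    """Random DNA sequence of ``n_bp`` bases at the given GC content."""
    if rng is None:
        rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n_bp, p=p))


# ---------------------------------------------------------------------------
# Constant-velocity stretching
# ---------------------------------------------------------------------------

_FORCE_TABLE_CACHE: dict = {}


def _force_table(elasticity: DsDnaElasticity):
    """Monotone (x_norm, force) table for fast WLC interpolation."""
    tab = _FORCE_TABLE_CACHE.get(elasticity)
    if tab is None:
        from .polymer_mechanics import wlc_fractional_extension

        f_grid = np.concatenate([[0.0], np.geomspace(1e-4, 150.0, 1500)])
        # wlc_fractional_extension already includes the enthalpic F/K term
        x_grid = wlc_fractional_extension(f_grid, elasticity)
        tab = (x_grid, f_grid)
        _FORCE_TABLE_CACHE[elasticity] = tab
    return tab


@dataclass
class StretchScenario:
    """Ground truth of one constant-velocity stretching trace.

    ``loops`` lists (loop_bp, rupture_force_pN) for DNA sequestered in
    protein-trapped loops that rejoin the stretched contour when the
    force reaches the loop's rupture threshold.
    """

    template_bp: int = 12_688
    loops: list[tuple[float, float]] = field(default_factory=list)
    breakage_force: float | None = None  # pN; None = no break in range
    pulling_velocity: float = 200.0  # nm/s
    noise_sd: float = 0.3  # pN force noise at the sampling rate
    sample_rate: float = 1000.0  # Hz
    start_extension: float = 0.05  # fraction of contour at t = 0
    max_force: float = 65.0  # stop the ramp here if no break
    trap_stiffness: float = 0.3  # pN/nm; sets the extension jump at ruptures
    seed: int = 0

    def __post_init__(self) -> None:
        for bp, f in self.loops:
            if not (1.0 < f <= 60.0):
                raise ValueError("rupture forces must lie in (1, 60] pN")
            if bp <= 0:
                raise ValueError("loop sizes must be > 0")
        if sum(bp for bp, _ in self.loops) >= self.template_bp:
            raise ValueError("loops exceed the template length")


def gen_stretch_trace(scenario: StretchScenario,
                      elasticity: DsDnaElasticity = DsDnaElasticity()):
    """Quasi-static constant-velocity stretching trace.

    The coverslip stage moves at constant velocity; at each stage
    position s the force balances the WLC tension of the instantaneous
    contour (template minus DNA sequestered in loops) against the trap,
    s = x_DNA(F) + F/k_trap.  When the force reaches a loop's rupture
    force, the loop's base pairs rejoin the contour within one sample:
    the force relaxes and the DNA extension jumps up by ΔF/k_trap.  An
    optional terminal breakage collapses the force to zero.  Returns
    ``(ForceExtensionTrace, ground_truth_dict)``.
    """
    rng = np.random.default_rng(scenario.seed)
    rise = elasticity.rise_per_bp
    k_trap = scenario.trap_stiffness
    pending = sorted(scenario.loops, key=lambda lf: lf[1])
    contour_bp = float(scenario.template_bp - sum(bp for bp, _ in pending))
    v = scenario.pulling_velocity
    rate = scenario.sample_rate

    x_grid, f_grid = _force_table(elasticity)
    f_stop = scenario.max_force
    s0 = scenario.start_extension * scenario.template_bp * rise
    s_end = (scenario.template_bp * rise * np.interp(f_stop, f_grid, x_grid)
             + f_stop / k_trap)
    n = int(np.ceil((s_end - s0) / v * rate)) + 2
    t = np.arange(n) / rate
    s = s0 + v * t
    force = np.zeros(n)
    events = []
    broken_at = None
    i = 0
    while i < n:
        s_of_f = contour_bp * rise * x_grid + f_grid / k_trap
        f_seg = np.interp(s[i:], s_of_f, f_grid)
        nxt = pending[0][1] if pending else np.inf
        brk = scenario.breakage_force if scenario.breakage_force is not None else np.inf
        crossing = np.flatnonzero(f_seg >= min(nxt, brk))
        if len(crossing) == 0:
            force[i:] = f_seg
            break
        j = i + int(crossing[0])
        force[i:j + 1] = f_seg[:crossing[0] + 1]
        if brk <= nxt:
            broken_at = {"time": float(t[j]), "force": float(force[j])}
            force[j + 1:] = 0.0
            n = min(n, j + 1 + int(0.2 * rate))  # short zero-tension tail
            break
        bp, f_rup = pending.pop(0)
        events.append({"time": float(t[j]), "force": float(force[j]),
                       "loop_bp": float(bp),
                       "contour_before": contour_bp,
                       "contour_after": contour_bp + bp})
        contour_bp += bp
        i = j + 1
    t, s, force = t[:n], s[:n], force[:n]
    extension = s - force / k_trap
    force = force + rng.normal(0.0, scenario.noise_sd, len(force))
    trace = ForceExtensionTrace(t, force, extension, rate,
                                metadata={"kind": "stretch", "seed": scenario.seed})
    truth = {"events": events, "breakage": broken_at,
             "template_bp": scenario.template_bp,
             "initial_contour_bp": float(scenario.template_bp
                                         - sum(bp for bp, _ in scenario.loops))}
    return trace, truth


# ---------------------------------------------------------------------------
# Constant-force survival
# ---------------------------------------------------------------------------

def gen_survival_lifetimes(amplitude_1: float, tau_1: float, tau_2: float,
                           n: int, censor_time: float = np.inf,
                           seed: int = 0):
    """Lifetimes from a two-component exponential mixture, censored at
    ``censor_time``.  Returns ``(lifetimes, censored_flags)``."""
    if not (0.0 <= amplitude_1 <= 1.0):
        raise ValueError("amplitude_1 must be in [0, 1]")
    rng = np.random.default_rng(seed)
    comp = rng.random(n) < amplitude_1
    t = np.where(comp, rng.exponential(tau_1, n), rng.exponential(tau_2, n))
    censored = t > censor_time
    t = np.minimum(t, censor_time)
    return t, censored


# ---------------------------------------------------------------------------
# Unzipping
# ---------------------------------------------------------------------------

def gen_unzip_curve(baseline: np.ndarray,
                    bound_regions: list[tuple[int, int, float]] = (),
                    breakage_force: float | None = None,
                    noise_sd: float = 0.5,
                    samples_per_bp: float = 2.0,
                    seed: int = 0):
    """Synthetic force-versus-bp unzipping curve.

    ``baseline`` gives the naked force at each bp; ``bound_regions`` adds
    (start_bp, span_bp, delta_force_pN) elevations.  If the elevated
    force exceeds ``breakage_force`` the tether breaks there.  Returns
    ``(UnzipCurve, ground_truth_dict)``.
    """
    from .unzip_analysis import UnzipCurve

    rng = np.random.default_rng(seed)
    baseline = np.asarray(baseline, dtype=float)
    full = len(baseline)
    profile = baseline.copy()
    for start, span, df in bound_regions:
        profile[start:start + span] += df
    break_pos = None
    if breakage_force is not None:
        over = np.flatnonzero(profile >= breakage_force)
        if len(over):
            break_pos = float(over[0])
    stop = full if break_pos is None else int(break_pos)
    n = max(2, int(stop * samples_per_bp))
    bp = np.linspace(0, stop - 1, n)
    f = np.interp(bp, np.arange(full), profile) + rng.normal(0.0, noise_sd, n)
    curve = UnzipCurve(bp_unzipped=bp, force=f, full_length=full,
                       breakage_position=break_pos,
                       metadata={"seed": seed})
    truth = {"bound_regions": [list(r) for r in bound_regions],
             "breakage_position": break_pos,
             "elevated_bp": float(sum(span for _, span, df in bound_regions
                                      if df >= 2.0))}
    return curve, truth


def gen_unzip_trace(baseline: np.ndarray,
                    arms: DsDnaElasticity = DsDnaElasticity(),
                    arm_length_bp: float = 2000.0,
                    ss: SsDnaElasticity = SsDnaElasticity(),
                    noise_sd: float = 0.0,
                    samples_per_bp: float = 2.0,
                    rate: float = 1000.0,
                    seed: int = 0) -> ForceExtensionTrace:
    """Forward-model a force/extension trace that unzips along ``baseline``.

    For each fork position j the extension is the two dsDNA arms plus 2j
    released nucleotides at the baseline force — the exact inverse of
    :func:`topomech.unzip_analysis.to_unzip_curve` on noise-free input.
    """
    rng = np.random.default_rng(seed)
    full = len(baseline)
    n = max(2, int(full * samples_per_bp))
    j = np.linspace(0, full - 1, n)
    f = np.interp(j, np.arange(full), np.asarray(baseline, dtype=float))
    ext = np.array([ds_extension(fi, arm_length_bp, arms)
                    + 2.0 * ji * ss_extension_per_nt(fi, ss)
                    for fi, ji in zip(f, j)])
    f = f + rng.normal(0.0, noise_sd, n)
    t = np.arange(n) / rate
    return ForceExtensionTrace(t, f, ext, rate,
                               metadata={"kind": "unzip", "seed": seed})


# ---------------------------------------------------------------------------
# Magnetic-tweezers relaxation
# ---------------------------------------------------------------------------

@dataclass
class TwistScenario:
    """Burst-and-pause supercoil relaxation ground truth.

    Catalytic strand-passage events remove ``step_turns`` (2 turns per
    cycle) at exponential waiting times set by the pause-free rate;
    after each cycle a pause of exponential duration begins with
    probability ``pause_probability``.
    """

    hat_center: float = 0.0
    hat_plateau: float = 3600.0  # nm
    hat_half_width: float = 2.0  # turns
    hat_slope: float = 40.0  # nm/turn magnitude, both flanks
    initial_turns: float = -40.0  # magnet setting (minus branch)
    pause_free_rate: float = 1.2  # turns/s
    pause_probability: float = 0.1  # per catalytic cycle
    pause_duration_mean: float = 100.0  # s; etoposide pauses are prolonged
    step_turns: float = 2.0
    noise_sd: float = 30.0  # nm extension noise
    duration: float = 900.0  # s
    sample_rate: float = 10.0  # Hz
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.pause_probability <= 1.0):
            raise ValueError("pause_probability must be in [0, 1]")

    def hat(self) -> HatCurveModel:
        return HatCurveModel(center_turn=self.hat_center,
                             plateau_extension=self.hat_plateau,
                             half_width=self.hat_half_width,
                             slope_left=self.hat_slope,
                             slope_right=-self.hat_slope)


def gen_twist_trace(scenario: TwistScenario, seed: int | None = None):
    """Magnetic-tweezers relaxation trace with ground-truth event log.

    Catalytic events arrive as a Poisson process at pause_free_rate /
    step_turns events per second, each removing ``step_turns`` turns;
    after each event a pause of exponential duration is entered with the
    configured probability.  The extension follows the hat model on the
    declared flank plus Gaussian noise at the acquisition rate.  Returns
    ``(TwistTrace, truth_dict)`` where the truth lists event times,
    pause intervals and the turns relaxed before the first pause.
    """
    if seed is None:
        seed = scenario.seed
    rng = np.random.default_rng(seed)
    hat = scenario.hat()
    branch = "minus" if scenario.initial_turns <= scenario.hat_center else "plus"
    sign = 1.0 if branch == "minus" else -1.0
    total_turns = abs(scenario.initial_turns - scenario.hat_center)
    cycle_rate = scenario.pause_free_rate / scenario.step_turns  # events/s

    t = 0.0
    relaxed = 0.0
    event_times, pause_log = [], []
    first_pause_turns = None
    # piecewise-constant turn state sampled at the acquisition rate
    n_samples = int(scenario.duration * scenario.sample_rate)
    ts = np.arange(n_samples) / scenario.sample_rate
    relaxed_series = np.zeros(n_samples)
    idx = 0
    while t < scenario.duration and relaxed < total_turns - 1e-9:
        t_next = t + rng.exponential(1.0 / cycle_rate)
        stop = min(t_next, scenario.duration)
        upto = np.searchsorted(ts, stop)
        relaxed_series[idx:upto] = relaxed
        idx = upto
        t = t_next
        if t >= scenario.duration:
            break
        relaxed = min(relaxed + scenario.step_turns, total_turns)
        event_times.append(t)
        if rng.random() < scenario.pause_probability and relaxed < total_turns:
            dur = rng.exponential(scenario.pause_duration_mean)
            if first_pause_turns is None:
                first_pause_turns = relaxed
            pause_log.append({"start": t, "duration": dur, "level": relaxed})
            stop = min(t + dur, scenario.duration)
            upto = np.searchsorted(ts, stop)
            relaxed_series[idx:upto] = relaxed
            idx = upto
            t = stop
    relaxed_series[idx:] = relaxed

    turn_state = scenario.initial_turns + sign * relaxed_series
    ext = hat.extension_at(turn_state) + rng.normal(0.0, scenario.noise_sd,
                                                    n_samples)
    trace = TwistTrace(time=ts, extension=ext,
                       applied_turns=np.full(n_samples, scenario.initial_turns),
                       acquisition_rate=scenario.sample_rate,
                       metadata={"branch": branch, "seed": seed})
    truth = {"event_times": event_times, "pauses": pause_log,
             "first_pause_turns": first_pause_turns,
             "pause_free_rate": scenario.pause_free_rate,
             "pause_probability": scenario.pause_probability,
             "total_turns": total_turns, "branch": branch}
    return trace, truth
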
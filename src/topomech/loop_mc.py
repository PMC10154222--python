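"""Coarse-grained worm-like-chain Monte Carlo for DNA looping probabilities.

The DNA is discretized as a chain of rigid segments (default 5 bp each) with
harmonic joint bending energy g(1 - cos θ), g = Lp/b in kT.  An optional
fixed internal bend of angle α (tangent deflection from collinear) models a
protein-imposed kink.  Umbrella sampling with a harmonic bias
U = ½k(r − r0)² on the end-to-end distance r, combined through WHAM, yields
the unbiased radial density P0(r); the Jacobson–Stockmayer looping J-factor
at a capture distance (default 2 nm) is J(r) = P0(r)/(4πr²), converted to
nanomolar with the Avogadro constant.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .polymer_mechanics import (
    KB_PN_NM,
    RISE_PER_BP_NM,
    ConvergenceError,
    DsDnaElasticity,
)

__all__ = [
    "ChainConfiguration",
    "UmbrellaWindow",
    "JFactorProfile",
    "McSettings",
    "WhamResult",
    "make_chain",
    "bending_energy",
    "bias_spring_constant",
    "pivot_move",
    "metropolis_run",
    "wham_unbias",
    "j_factor_from_p0",
    "j_factor_curve",
    "predict_loop_size_distribution",
    "NM3_TO_NM",
]

#: 1 molecule/nm^3 expressed in nanomolar: 1e24 / N_A * 1e9
NM3_TO_NM = 1.0e33 / 6.02214076e23


@dataclass
class ChainConfiguration:
    """Discretized WLC chain: n_segments rigid segments of length b (nm)."""

    vertices: np.ndarray  # (n_segments + 1, 3), nm
    segment_length: float  # nm
    loop_length_bp: float
    bend_vertex: int | None = None
    bend_angle: float = 0.0  # degrees, tangent deflection at bend_vertex

    @property
    def n_segments(self) -> int:
        return self.vertices.shape[0] - 1

    @property
    def end_to_end(self) -> float:
        return float(np.linalg.norm(self.vertices[-1] - self.vertices[0]))

    def validate(self, rtol: float = 1e-6) -> None:
        seg = np.diff(self.vertices, axis=0)
        lengths = np.linalg.norm(seg, axis=1)
        if np.any(np.abs(lengths - self.segment_length) > rtol * self.segment_length):
            raise ValueError("segment lengths deviate from b beyond tolerance")
        if self.bend_vertex is not None:
            i = self.bend_vertex
            if not (0 < i < self.n_segments):
                raise ValueError("bend_vertex must be an internal vertex")
            cosang = np.dot(seg[i - 1], seg[i]) / (lengths[i - 1] * lengths[i])
            ang = math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))
            if abs(ang - self.bend_angle) > 1e-4 + 1e-6 * abs(self.bend_angle):
                raise ValueError("bend-vertex angle deviates from α")


@dataclass
class UmbrellaWindow:
    """One umbrella window: harmonic bias ½k(r−r0)² and its samples."""

    r0: float  # bias centre, nm
    k: float  # bias stiffness, pN·nm per nm² (already unit-converted)
    samples: np.ndarray | None = None  # end-to-end distances, nm
    acceptance: float | None = None
    energy_drift: float | None = None

    @property
    def n_samples(self) -> int:
        return 0 if self.samples is None else len(self.samples)


@dataclass
class WhamResult:
    r: np.ndarray  # bin centres, nm
    p0: np.ndarray  # unbiased radial density, 1/nm, integrates to 1
    bin_width: float
    window_offsets: np.ndarray  # free-energy offsets f_i, kT
    n_iterations: int


@dataclass
class JFactorProfile:
    """J-factor of a single loop length with its reconstructed P0(r)."""

    loop_length_bp: float
    r: np.ndarray
    p0: np.ndarray
    j_at_capture: float  # nM
    j_se: float  # nM, block-averaging standard error
    r_capture: float = 2.0
    windows: list = field(default_factory=list, repr=False)


@dataclass(frozen=True)
class McSettings:
    """Monte Carlo schedule.  Defaults follow the production protocol:
    10^5 equilibration steps discarded, 1.5×10^6 production steps,
    pivot angles uniform in ±50°."""

    n_equil: int = 100_000
    n_prod: int = 1_500_000
    pivot_max_angle: float = 50.0  # degrees
    temperature: float = 296.15  # K
    seed: int = 0
    segment_bp: float = 5.0
    n_windows: int = 10
    r_capture_nm: float = 2.0
    bias_units: str = "bp"  # "bp": r in the bias measured in bp; "nm"
    wham_tol: float = 1e-6
    wham_max_iter: int = 100_000
    n_blocks: int = 5
    energy_check_every: int = 10_000

    def __post_init__(self) -> None:
        if self.n_equil <= 0 or self.n_prod <= 0:
            raise ValueError("n_equil and n_prod must be > 0")
        if not (0 < self.pivot_max_angle <= 180):
            raise ValueError("pivot_max_angle must be in (0, 180]")
        if self.bias_units not in ("bp", "nm"):
            raise ValueError("bias_units must be 'bp' or 'nm'")

    @property
    def kT(self) -> float:
        return KB_PN_NM * self.temperature


def make_chain(loop_length_bp: float, bend_angle: float = 0.0,
               segment_bp: float = 5.0, rise_per_bp: float = RISE_PER_BP_NM,
               bend_vertex: int | None = None) -> ChainConfiguration:
    """Build an initial chain for a loop of ``loop_length_bp`` base pairs.

    The chain starts straight; if ``bend_angle`` > 0 a fixed tangent
    deflection of that angle is placed at ``bend_vertex`` (default: the
    middle vertex).  α = 150° therefore means a near-hairpin kink.
    """
    n_seg = max(2, int(round(loop_length_bp / segment_bp)))
    b = segment_bp * rise_per_bp
    if bend_angle:
        if bend_vertex is None:
            bend_vertex = n_seg // 2
        theta = math.radians(bend_angle)
        t1 = np.array([1.0, 0.0, 0.0])
        t2 = np.array([math.cos(theta), math.sin(theta), 0.0])
        verts = np.zeros((n_seg + 1, 3))
        for i in range(1, n_seg + 1):
            t = t1 if i <= bend_vertex else t2
            verts[i] = verts[i - 1] + b * t
    else:
        bend_vertex = None
        verts = np.zeros((n_seg + 1, 3))
        verts[:, 0] = b * np.arange(n_seg + 1)
    return ChainConfiguration(vertices=verts, segment_length=b,
                              loop_length_bp=loop_length_bp,
                              bend_vertex=bend_vertex, bend_angle=bend_angle)


def bending_energy(chain: ChainConfiguration,
                   elasticity: DsDnaElasticity = DsDnaElasticity()) -> float:
    """Total bending energy in kT: sum of g(1−cos θ) over free joints.

    The fixed-bend vertex (if any) is a rigid constraint and contributes
    zero; its reference angle is α.
    """
    chain.validate()
    g = elasticity.persistence_length / chain.segment_length
    seg = np.diff(chain.vertices, axis=0)
    b2 = chain.segment_length ** 2
    cosang = np.einsum("ij,ij->i", seg[:-1], seg[1:]) / b2
    energy = g * (1.0 - cosang)
    if chain.bend_vertex is not None:
        energy[chain.bend_vertex - 1] = 0.0
    return float(np.sum(energy))


def bias_spring_constant(L: float, alpha: float) -> float:
    """Umbrella bias stiffness schedule, pN·nm per bp².

    k(L, α) = (1.682/25) · exp(−0.008664·L) · (55 − 0.2·α), with L the
    total loop contour length in base pairs and α the bend angle in
    degrees.  The last factor must stay positive (α < 275°).
    """
    if L <= 0:
        raise ValueError("L must be > 0")
    if not (0 <= alpha < 275):
        raise ValueError("alpha must be in [0, 275) for a positive stiffness")
    return (1.682 / 25.0) * math.exp(-0.008664 * L) * (55.0 - 0.2 * alpha)


def _rotation_matrix(axis: np.ndarray, theta: float) -> np.ndarray:
    """Rodrigues rotation matrix about unit ``axis`` by ``theta`` radians."""
    ux, uy, uz = axis
    c, s = math.cos(theta), math.sin(theta)
    C = 1.0 - c
    return np.array([
        [c + ux * ux * C, ux * uy * C - uz * s, ux * uz * C + uy * s],
        [uy * ux * C + uz * s, c + uy * uy * C, uy * uz * C - ux * s],
        [uz * ux * C - uy * s, uz * uy * C + ux * s, c + uz * uz * C],
    ])


def pivot_move(chain: ChainConfiguration, rng: np.random.Generator,
               max_angle: float = 50.0, return_details: bool = False):
    """Propose a pivot rotation of the tail subchain.

    A pivot vertex is drawn uniformly from the internal, non-bend
    vertices; the subchain beyond it is rotated rigidly about a random
    axis through that vertex by an angle uniform in ±``max_angle``
    degrees.  Segment lengths and the bend-vertex angle are preserved and
    the proposal is symmetric.  With ``return_details`` the proposal's
    (pivot index, axis, signed angle in degrees) are also returned.
    """
    n = chain.n_segments
    candidates = [i for i in range(1, n) if i != chain.bend_vertex]
    i = candidates[rng.integers(len(candidates))]
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    theta_deg = (2.0 * rng.random() - 1.0) * max_angle
    R = _rotation_matrix(axis, math.radians(theta_deg))
    verts = chain.vertices.copy()
    verts[i + 1:] = (verts[i + 1:] - verts[i]) @ R.T + verts[i]
    proposed = replace(chain, vertices=verts)
    if return_details:
        return proposed, (i, axis, theta_deg)
    return proposed


# ---------------------------------------------------------------------------
# Metropolis kernel (numba)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _mc_kernel(verts, bend_idx, g_joint, k_bias, r0, max_angle_rad,
               n_equil, n_prod, seed, check_every):  # pragma: no cover - jit
    """Pivot-move Metropolis run.  Energies in kT (k_bias in kT/nm²).

    Returns (r samples over production, acceptance fraction, max energy
    drift between the incrementally tracked and recomputed bending
    energy).  bend_idx < 0 means no fixed bend.
    """
    np.random.seed(seed)
    n_vert = verts.shape[0]
    n_seg = n_vert - 1
    b = 0.0
    for d in range(3):
        b += (verts[1, d] - verts[0, d]) ** 2
    b2 = b
    # candidate pivot vertices: 1..n_seg-1 excluding the bend vertex
    n_cand = n_seg - 1 if bend_idx < 0 else n_seg - 2
    cand = np.empty(n_cand, dtype=np.int64)
    j = 0
    for i in range(1, n_seg):
        if i != bend_idx:
            cand[j] = i
            j += 1

    def bend_e(v):
        e = 0.0
        for i in range(1, n_seg):
            if i == bend_idx:
                continue
            dot = 0.0
            for d in range(3):
                dot += (v[i, d] - v[i - 1, d]) * (v[i + 1, d] - v[i, d])
            e += g_joint * (1.0 - dot / b2)
        return e

    e_bend = bend_e(verts)
    rx = verts[n_seg, 0] - verts[0, 0]
    ry = verts[n_seg, 1] - verts[0, 1]
    rz = verts[n_seg, 2] - verts[0, 2]
    r = math.sqrt(rx * rx + ry * ry + rz * rz)

    samples = np.empty(n_prod)
    n_acc = 0
    max_drift = 0.0
    total = n_equil + n_prod
    for step in range(total):
        piv = cand[np.random.randint(0, n_cand)]
        # random rotation axis
        ax = np.random.normal()
        ay = np.random.normal()
        az = np.random.normal()
        norm = math.sqrt(ax * ax + ay * ay + az * az)
        ax /= norm
        ay /= norm
        az /= norm
        theta = (2.0 * np.random.random() - 1.0) * max_angle_rad
        c = math.cos(theta)
        s = math.sin(theta)
        C = 1.0 - c
        r00 = c + ax * ax * C
        r01 = ax * ay * C - az * s
        r02 = ax * az * C + ay * s
        r10 = ay * ax * C + az * s
        r11 = c + ay * ay * C
        r12 = ay * az * C - ax * s
        r20 = az * ax * C - ay * s
        r21 = az * ay * C + ax * s
        r22 = c + az * az * C
        px = verts[piv, 0]
        py = verts[piv, 1]
        pz = verts[piv, 2]
        # rotated outgoing tangent at the pivot joint
        tx = verts[piv + 1, 0] - px
        ty = verts[piv + 1, 1] - py
        tz = verts[piv + 1, 2] - pz
        ntx = r00 * tx + r01 * ty + r02 * tz
        nty = r10 * tx + r11 * ty + r12 * tz
        ntz = r20 * tx + r21 * ty + r22 * tz
        # incoming tangent (unchanged)
        ix = px - verts[piv - 1, 0]
        iy = py - verts[piv - 1, 1]
        iz = pz - verts[piv - 1, 2]
        cos_old = (ix * tx + iy * ty + iz * tz) / b2
        cos_new = (ix * ntx + iy * nty + iz * ntz) / b2
        d_bend = g_joint * (cos_old - cos_new)
        # new end position
        ex = verts[n_seg, 0] - px
        ey = verts[n_seg, 1] - py
        ez = verts[n_seg, 2] - pz
        nex = r00 * ex + r01 * ey + r02 * ez + px
        ney = r10 * ex + r11 * ey + r12 * ez + py
        nez = r20 * ex + r21 * ey + r22 * ez + pz
        drx = nex - verts[0, 0]
        dry = ney - verts[0, 1]
        drz = nez - verts[0, 2]
        r_new = math.sqrt(drx * drx + dry * dry + drz * drz)
        d_bias = 0.5 * k_bias * ((r_new - r0) ** 2 - (r - r0) ** 2)
        d_e = d_bend + d_bias
        if d_e <= 0.0 or np.random.random() < math.exp(-d_e):
            for i in range(piv + 1, n_vert):
                vx = verts[i, 0] - px
                vy = verts[i, 1] - py
                vz = verts[i, 2] - pz
                verts[i, 0] = r00 * vx + r01 * vy + r02 * vz + px
                verts[i, 1] = r10 * vx + r11 * vy + r12 * vz + py
                verts[i, 2] = r20 * vx + r21 * vy + r22 * vz + pz
            e_bend += d_bend
            r = r_new
            n_acc += 1
        if step >= n_equil:
            samples[step - n_equil] = r
        if (step + 1) % check_every == 0:
            e_re = bend_e(verts)
            drift = abs(e_re - e_bend)
            if drift > max_drift:
                max_drift = drift
            e_bend = e_re
    return samples, n_acc / total, max_drift


def _bias_to_kT_per_nm2(k: float, units: str, kT: float) -> float:
    """Convert a bias stiffness to kT/nm² from pN·nm/bp² or pN·nm/nm²."""
    if units == "bp":
        k = k / RISE_PER_BP_NM ** 2
    return k / kT


def metropolis_run(chain: ChainConfiguration, settings: McSettings,
                   window: UmbrellaWindow,
                   elasticity: DsDnaElasticity = DsDnaElasticity(),
                   seed: int | None = None) -> UmbrellaWindow:
    """Run one umbrella window; returns the window with samples filled.

    ``window.k`` must already be in pN·nm per nm² (see
    :func:`j_factor_curve` for the bp-unit conversion).  Deterministic
    given the seed.  Emits a warning if the production acceptance rate
    leaves (0.01, 0.99) or the incremental energy drifts by > 1e-6 kT.
    """
    if window.k < 0:
        raise ValueError("bias stiffness must be >= 0")
    chain.validate()
    g = elasticity.persistence_length / chain.segment_length
    bend_idx = -1 if chain.bend_vertex is None else chain.bend_vertex
    verts = np.ascontiguousarray(chain.vertices, dtype=np.float64).copy()
    if seed is None:
        seed = settings.seed
    samples, acc, drift = _mc_kernel(
        verts, bend_idx, g, window.k / settings.kT, window.r0,
        math.radians(settings.pivot_max_angle),
        settings.n_equil, settings.n_prod, int(seed) % (2 ** 31),
        settings.energy_check_every)
    if not (0.01 < acc < 0.99):
        warnings.warn(f"acceptance rate {acc:.3f} outside (0.01, 0.99) "
                      f"for window r0={window.r0:.2f} nm", RuntimeWarning)
    if drift > 1e-6:
        warnings.warn(f"incremental energy drift {drift:.2e} kT", RuntimeWarning)
    return replace(window, samples=samples, acceptance=acc, energy_drift=drift)


# ---------------------------------------------------------------------------
# WHAM
# ---------------------------------------------------------------------------

def wham_unbias(windows: list[UmbrellaWindow], temperature: float = 296.15,
                bin_width: float | None = None, tol: float = 1e-6,
                max_iter: int = 100_000) -> WhamResult:
    """Weighted-histogram reconstruction of the unbiased radial density.

    Iterates the self-consistent WHAM equations over the sampled support
    until the free-energy offsets change by less than ``tol`` kT.  The
    returned density integrates to 1 over the sampled range.
    """
    windows = [w for w in windows if w.n_samples > 0]
    if not windows:
        raise ValueError("at least one window with samples is required")
    kT = KB_PN_NM * temperature
    lo = min(float(np.min(w.samples)) for w in windows)
    hi = max(float(np.max(w.samples)) for w in windows)
    support = max(hi - lo, 1e-9)
    if bin_width is None:
        bin_width = min(0.5, support / 200.0)
    n_bins = max(1, int(np.ceil(support / bin_width)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    counts = np.stack([np.histogram(w.samples, bins=edges)[0] for w in windows])
    N_i = counts.sum(axis=1).astype(float)
    _check_overlap(windows)

    # bias energies at bin centres, kT
    U = np.stack([0.5 * w.k * (centers - w.r0) ** 2 / kT for w in windows])
    logw = -U  # (n_win, n_bins)
    H = counts.sum(axis=0).astype(float)

    f = np.zeros(len(windows))  # free-energy offsets, kT
    for it in range(max_iter):
        # denom(b) = sum_i N_i exp(f_i - U_i(b))
        denom = np.einsum("i,ib->b", N_i, np.exp(f[:, None] + logw))
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(denom > 0, H / denom, 0.0)
        z = np.einsum("ib,b->i", np.exp(logw), p) * 1.0
        z = np.maximum(z, 1e-300)
        f_new = -np.log(z)
        f_new -= f_new[0]
        delta = float(np.max(np.abs(f_new - f)))
        f = f_new
        if delta < tol:
            break
    else:
        raise ConvergenceError(
            f"WHAM did not converge in {max_iter} iterations (residual {delta:.2e})")
    denom = np.einsum("i,ib->b", N_i, np.exp(f[:, None] + logw))
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(denom > 0, H / denom, 0.0)
    norm = p.sum() * bin_width
    if norm <= 0:
        raise ConvergenceError("WHAM produced an empty density")
    return WhamResult(r=centers, p0=p / norm, bin_width=bin_width,
                      window_offsets=f, n_iterations=it + 1)


def _check_overlap(windows) -> None:
    """Raise if adjacent windows (ordered by median r) have disjoint ranges."""
    spans = sorted((float(np.median(w.samples)), float(np.min(w.samples)),
                    float(np.max(w.samples))) for w in windows)
    for (_, _, hi1), (_, lo2, _) in zip(spans[:-1], spans[1:]):
        if hi1 < lo2:
            raise ValueError(
                "window supports are disjoint: no samples in "
                f"r ∈ [{hi1:.2f}, {lo2:.2f}] nm")


def j_factor_from_p0(p0: np.ndarray, r: np.ndarray,
                     r_capture: float = 2.0) -> float:
    """J-factor in nM at the capture distance.

    Reads P0 in the bin containing ``r_capture`` and converts the local
    concentration P0(r)/(4πr²) (per nm³) to nanomolar via the Avogadro
    constant.
    """
    p0 = np.asarray(p0, dtype=float)
    r = np.asarray(r, dtype=float)
    if len(r) > 1:
        half = 0.5 * (r[1] - r[0])
    else:
        half = np.inf
    if r_capture < r[0] - half or r_capture > r[-1] + half:
        raise ValueError(f"r_capture={r_capture} outside sampled support "
                         f"[{r[0] - half:.2f}, {r[-1] + half:.2f}] nm")
    b = int(np.argmin(np.abs(r - r_capture)))
    j_per_nm3 = p0[b] / (4.0 * math.pi * r[b] ** 2)
    return j_per_nm3 * NM3_TO_NM


def _window_schedule(r_natural_median: float, k_kT_per_nm2: float,
                     settings: McSettings) -> np.ndarray:
    """Bias centres from the capture distance up into the natural support.

    Spacing follows the bias width σ = sqrt(kT/k) so adjacent windows
    overlap; the count is floored at ``n_windows`` and capped at 80.  The
    region above the natural median is covered by the unbiased window.
    """
    r_min = settings.r_capture_nm
    r_max = max(r_natural_median, r_min * 1.5)
    if k_kT_per_nm2 > 0:
        sigma = 1.0 / math.sqrt(k_kT_per_nm2)
        n = int(np.ceil((r_max - r_min) / (1.5 * sigma))) + 1
    else:
        n = settings.n_windows
    n = int(np.clip(n, settings.n_windows, 80))
    return np.linspace(r_min, r_max, n)


def _derive_seed(base: int, *stream: int) -> int:
    ss = np.random.SeedSequence([int(base)] + [int(s) for s in stream])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def j_factor_profile(loop_length_bp: float, alpha: float,
                     settings: McSettings = McSettings(),
                     elasticity: DsDnaElasticity = DsDnaElasticity(),
                     bias_k: float | None = None) -> JFactorProfile:
    """Umbrella-sampled J-factor of one loop length.

    Runs the window schedule (plus one unbiased window so the natural
    part of P0(r) is sampled and the density normalizes correctly),
    unbiases with WHAM, and evaluates J at the capture distance.  The
    standard error comes from block averaging: the production samples of
    every window are split into ``n_blocks`` contiguous blocks and WHAM
    is repeated per block.

    ``bias_k`` (pN·nm per the configured bias unit squared) overrides the
    default stiffness schedule; the unbiased estimand is independent of
    the choice, which only controls sampling efficiency.
    """
    chain = make_chain(loop_length_bp, alpha, settings.segment_bp,
                       elasticity.rise_per_bp)
    contour_nm = loop_length_bp * elasticity.rise_per_bp
    k_sched = bias_spring_constant(loop_length_bp, alpha) if bias_k is None else bias_k
    k_nm = _bias_to_kT_per_nm2(k_sched, settings.bias_units, 1.0)  # pN·nm/nm²
    # the unbiased window runs first: it covers the natural part of P0(r)
    # (needed for normalization) and anchors the biased-window schedule
    free = metropolis_run(chain, settings,
                          UmbrellaWindow(r0=contour_nm, k=0.0), elasticity,
                          seed=_derive_seed(settings.seed, int(loop_length_bp), 9999))
    r0s = _window_schedule(float(np.median(free.samples)),
                           k_nm / settings.kT, settings)
    windows = [UmbrellaWindow(r0=float(r0), k=k_nm) for r0 in r0s]
    run = [metropolis_run(chain, settings, w, elasticity,
                          seed=_derive_seed(settings.seed, int(loop_length_bp), wi))
           for wi, w in enumerate(windows)]
    run.append(free)

    def j_of(ws: list[UmbrellaWindow]) -> float:
        res = wham_unbias(ws, settings.temperature, tol=settings.wham_tol,
                          max_iter=settings.wham_max_iter)
        try:
            return j_factor_from_p0(res.p0, res.r, settings.r_capture_nm), res
        except ValueError:
            return 0.0, res

    j_full, res = j_of(run)
    # block averaging for the standard error
    js = []
    for blk in range(settings.n_blocks):
        sub = []
        for w in run:
            s = np.array_split(w.samples, settings.n_blocks)[blk]
            sub.append(replace(w, samples=s))
        try:
            jb, _ = j_of(sub)
            js.append(jb)
        except (ValueError, ConvergenceError):
            continue
    if len(js) >= 2:
        se = float(np.std(js, ddof=1) / math.sqrt(len(js)))
    else:
        se = float("nan")
    return JFactorProfile(loop_length_bp=loop_length_bp, r=res.r, p0=res.p0,
                          j_at_capture=float(j_full), j_se=se,
                          r_capture=settings.r_capture_nm, windows=run)


def j_factor_curve(loop_lengths_bp, alpha: float,
                   settings: McSettings = McSettings(),
                   elasticity: DsDnaElasticity = DsDnaElasticity()) -> list[JFactorProfile]:
    """J-factor versus loop length at fixed bend angle α (degrees)."""
    profiles = []
    for L in loop_lengths_bp:
        if L / settings.segment_bp < 4:
            raise ValueError(f"loop of {L} bp discretizes to < 4 segments")
        profiles.append(j_factor_profile(float(L), alpha, settings, elasticity))
    return profiles


def predict_loop_size_distribution(profiles_unbent: list[JFactorProfile],
                                   profiles_bent: list[JFactorProfile],
                                   hist_centers_bp, hist_counts):
    """Scale the two J(L) curves to an observed loop-size histogram.

    Non-negative least squares of counts ≈ a·J_unbent(L) + b·J_bent(L)
    at the histogram bin centres (J interpolated in L).  Returns
    ``(a, b, composite, residual)``.
    """
    from scipy.optimize import nnls

    centers = np.asarray(hist_centers_bp, dtype=float)
    counts = np.asarray(hist_counts, dtype=float)
    if not np.any(counts):
        raise ValueError("histogram is all zero")

    def interp(profiles):
        Ls = np.array([p.loop_length_bp for p in profiles])
        Js = np.array([p.j_at_capture for p in profiles])
        order = np.argsort(Ls)
        return np.interp(centers, Ls[order], Js[order])

    A = np.column_stack([interp(profiles_unbent), interp(profiles_bent)])
    coef, rnorm = nnls(A, counts)
    composite = A @ coef
    return float(coef[0]), float(coef[1]), composite, float(rnorm)
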
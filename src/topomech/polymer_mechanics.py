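"""Elasticity models for double- and single-stranded DNA under tension.

Converts between force, extension, contour length (in base pairs) and the
number of base pairs unzipped, using the modified Marko–Siggia worm-like
chain for dsDNA and an extensible freely-jointed chain for ssDNA.  Also
computes the equilibrium unzipping force baseline of a sequence from
nearest-neighbour base-pairing free energies.

Units throughout: force in pN, length in nm, energy in pN·nm (kT reported
where stated), temperature in K.  The helical rise is fixed at 0.338 nm/bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "KB_PN_NM",
    "RISE_PER_BP_NM",
    "ConvergenceError",
    "DsDnaElasticity",
    "SsDnaElasticity",
    "ForceExtensionTrace",
    "wlc_fractional_extension",
    "wlc_force_at_extension",
    "ds_extension",
    "contour_length_from_point",
    "ss_extension_per_nt",
    "ss_stretch_energy_per_nt",
    "unzip_bp_from_point",
    "nn_opening_energies",
    "equilibrium_unzip_baseline",
]

#: Boltzmann constant, pN·nm/K
KB_PN_NM = 0.0138065
#: Helical rise of B-form dsDNA, nm per base pair
RISE_PER_BP_NM = 0.338
#: Default room temperature of the assays, 23 °C
DEFAULT_TEMPERATURE_K = 296.15


class ConvergenceError(RuntimeError):
    """A numeric inversion failed to bracket or converge."""


@dataclass(frozen=True)
class DsDnaElasticity:
    """Modified Marko–Siggia parameters for torsionally relaxed dsDNA.

    The force–extension relation used is

        F = (kT/Lp) * [ 1/(4(1-l)^2) - 1/4 + l ],   l = x/L0 - F/K,

    where ``Lp`` is the persistence length, ``K`` the enthalpic stretch
    modulus and ``x/L0`` the extension normalized by contour length.
    """

    persistence_length: float = 45.0  # nm
    stretch_modulus: float = 1200.0  # pN
    rise_per_bp: float = RISE_PER_BP_NM  # nm/bp
    temperature: float = DEFAULT_TEMPERATURE_K  # K

    def __post_init__(self) -> None:
        if not (self.persistence_length > 0 and self.stretch_modulus > 0):
            raise ValueError("persistence_length and stretch_modulus must be > 0")
        if not (self.rise_per_bp > 0 and self.temperature > 0):
            raise ValueError("rise_per_bp and temperature must be > 0")

    @property
    def kT(self) -> float:
        """Thermal energy, pN·nm."""
        return KB_PN_NM * self.temperature


@dataclass(frozen=True)
class SsDnaElasticity:
    """Extensible freely-jointed chain parameters for ssDNA.

    Extension per nucleotide at force F:

        x(F) = h * [coth(u) - 1/u] * (1 + F/K),   u = F*b/kT

    with contour per nucleotide ``h``, Kuhn length ``b`` and stretch
    modulus ``K``.
    """

    contour_per_nt: float = 0.59  # nm per nucleotide
    kuhn_length: float = 1.5  # nm
    stretch_modulus: float = 800.0  # pN
    temperature: float = DEFAULT_TEMPERATURE_K  # K

    def __post_init__(self) -> None:
        if min(self.contour_per_nt, self.kuhn_length,
               self.stretch_modulus, self.temperature) <= 0:
            raise ValueError("all SsDnaElasticity parameters must be > 0")

    @property
    def kT(self) -> float:
        return KB_PN_NM * self.temperature


@dataclass
class ForceExtensionTrace:
    """A force/extension time series from a stretching or unzipping assay."""

    time: np.ndarray  # s, strictly increasing
    force: np.ndarray  # pN
    extension: np.ndarray  # nm
    acquisition_rate: float  # Hz
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.extension = np.asarray(self.extension, dtype=float)
        n = len(self.time)
        if len(self.force) != n or len(self.extension) != n:
            raise ValueError("time, force and extension must have equal length")
        if n > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        if self.acquisition_rate <= 0:
            raise ValueError("acquisition_rate must be > 0")

    def __len__(self) -> int:
        return len(self.time)


# ---------------------------------------------------------------------------
# dsDNA: modified Marko–Siggia
# ---------------------------------------------------------------------------

def _ms_force_of_l(l: float, elasticity: DsDnaElasticity) -> float:
    """Inextensible Marko–Siggia force at fractional extension ``l``."""
    kT_over_lp = elasticity.kT / elasticity.persistence_length
    return kT_over_lp * (0.25 / (1.0 - l) ** 2 - 0.25 + l)


def wlc_fractional_extension(force, elasticity: DsDnaElasticity = DsDnaElasticity()):
    """Fractional extension x/L0 of dsDNA at the given force(s).

    Solves the modified Marko–Siggia relation for each force.  Accepts a
    scalar or array; returns the same shape.  Forces must be finite and
    >= 0.
    """
    forces = np.atleast_1d(np.asarray(force, dtype=float))
    if not np.all(np.isfinite(forces)) or np.any(forces < 0):
        raise ValueError("forces must be finite and non-negative")
    K = elasticity.stretch_modulus
    out = np.empty_like(forces)
    for i, f in enumerate(forces):
        if f == 0.0:
            out[i] = 0.0
            continue
        # monotone in l on [0, 1): h(l) = F_MS(l) - f
        try:
            l = brentq(lambda l: _ms_force_of_l(l, elasticity) - f,
                       0.0, 1.0 - 1e-12, xtol=1e-12, rtol=1e-14)
        except ValueError as exc:  # pragma: no cover - bracket always valid
            raise ConvergenceError(f"fractional-extension solve failed at F={f}") from exc
        out[i] = l + f / K
    return out if np.ndim(force) else float(out[0])


def wlc_force_at_extension(x_norm, elasticity: DsDnaElasticity = DsDnaElasticity()):
    """Force (pN) on dsDNA at normalized extension ``x_norm = x/L0``.

    ``x_norm`` may exceed 1 in the enthalpic regime (up to 1 + F/K).  The
    implicit modified Marko–Siggia relation is solved numerically; the
    result is the unique non-negative root and is strictly increasing in
    ``x_norm``.
    """
    xs = np.atleast_1d(np.asarray(x_norm, dtype=float))
    if not np.all(np.isfinite(xs)) or np.any(xs < 0):
        raise ValueError("x_norm must be finite and non-negative")
    K = elasticity.stretch_modulus
    out = np.empty_like(xs)

    def residual(f: float, x: float) -> float:
        l = x - f / K
        if l >= 1.0:
            return np.inf  # force too small to bring l below 1
        return _ms_force_of_l(l, elasticity) - f

    for i, x in enumerate(xs):
        if x == 0.0:
            out[i] = 0.0
            continue
        f_lo = max(0.0, (x - 1.0 + 1e-9) * K)
        f_hi = max(1.0, 2.0 * f_lo + 1.0)
        for _ in range(200):
            if residual(f_hi, x) < 0.0:
                break
            f_hi *= 2.0
        else:
            raise ConvergenceError(f"could not bracket force at x_norm={x}")
        out[i] = brentq(residual, f_lo, f_hi, args=(x,), xtol=1e-10, rtol=1e-12)
    return out if np.ndim(x_norm) else float(out[0])


def ds_extension(force, n_bp: float, elasticity: DsDnaElasticity = DsDnaElasticity()):
    """Extension (nm) of ``n_bp`` base pairs of dsDNA at the given force(s)."""
    return n_bp * elasticity.rise_per_bp * wlc_fractional_extension(force, elasticity)


#: default force (pN) below which contour-length inversion is ill-conditioned
LOW_FORCE_CUTOFF_PN = 0.25


def contour_length_from_point(force, extension,
                              elasticity: DsDnaElasticity = DsDnaElasticity(),
                              low_force_cutoff: float = LOW_FORCE_CUTOFF_PN):
    """Contour length in bp from a measured (force, extension) point.

    Inverts the modified Marko–Siggia model: L0 = x / (rise * l(F)).
    Returns ``(contour_bp, reliable)``; points with force below
    ``low_force_cutoff`` are still converted but flagged unreliable.
    Accepts scalars or arrays.
    """
    forces = np.atleast_1d(np.asarray(force, dtype=float))
    exts = np.atleast_1d(np.asarray(extension, dtype=float))
    if forces.shape != exts.shape:
        raise ValueError("force and extension must have matching shapes")
    reliable = forces >= low_force_cutoff
    l = np.array([wlc_fractional_extension(max(f, 1e-6), elasticity) for f in forces])
    bp = exts / (elasticity.rise_per_bp * l)
    if np.ndim(force) == 0 and np.ndim(extension) == 0:
        return float(bp[0]), bool(reliable[0])
    return bp, reliable


# ---------------------------------------------------------------------------
# ssDNA: extensible freely-jointed chain
# ---------------------------------------------------------------------------

def _langevin(u):
    """coth(u) - 1/u, stable near zero."""
    u = np.asarray(u, dtype=float)
    small = np.abs(u) < 1e-4
    with np.errstate(over="ignore", invalid="ignore"):
        out = np.where(small, u / 3.0, 1.0 / np.tanh(np.where(small, 1.0, u))
                       - 1.0 / np.where(small, 1.0, u))
    return out


def ss_extension_per_nt(force, ss: SsDnaElasticity = SsDnaElasticity()):
    """Extension (nm) per ssDNA nucleotide at the given force(s).

    Non-decreasing in force (extensible FJC).
    """
    f = np.asarray(force, dtype=float)
    u = f * ss.kuhn_length / ss.kT
    x = ss.contour_per_nt * _langevin(u) * (1.0 + f / ss.stretch_modulus)
    return x


def ss_stretch_energy_per_nt(force, ss: SsDnaElasticity = SsDnaElasticity()):
    """Free energy (pN·nm) released per nucleotide held at fixed force.

    Integral of the extension over force from 0 to F.  The FJC part is
    closed-form, h*(kT/b)*ln(sinh(u)/u); the enthalpic correction is
    approximated by h*F^2/(2K) (sub-percent at unzipping forces).
    """
    f = np.asarray(force, dtype=float)
    u = f * ss.kuhn_length / ss.kT
    with np.errstate(over="ignore"):
        # ln(sinh(u)/u) = u + ln((1-e^{-2u})/(2u)) is overflow-safe
        core = np.where(u > 1e-8,
                        u + np.log1p(-np.exp(-2.0 * np.where(u > 1e-8, u, 1.0)))
                        - np.log(2.0 * np.where(u > 1e-8, u, 1.0)),
                        u ** 2 / 6.0)
    g = ss.contour_per_nt * (ss.kT / ss.kuhn_length) * core
    g = g + ss.contour_per_nt * f ** 2 / (2.0 * ss.stretch_modulus)
    return g


def unzip_bp_from_point(force, extension,
                        arms: DsDnaElasticity = DsDnaElasticity(),
                        arm_length_bp: float = 2000.0,
                        ss: SsDnaElasticity = SsDnaElasticity()):
    """Number of base pairs unzipped from a measured (force, extension) point.

    Solves  extension = x_ds(F; arms) + 2*j*x_ss(F)  for j.  Returns
    ``(j, ok)``; points whose extension falls below the arms-only value
    give j = 0 with ok = False.  Accepts scalars or arrays.
    """
    forces = np.atleast_1d(np.asarray(force, dtype=float))
    exts = np.atleast_1d(np.asarray(extension, dtype=float))
    if np.any(forces <= 0):
        raise ValueError("force must be > 0 for unzipping inversion")
    x_arms = np.array([ds_extension(f, arm_length_bp, arms) for f in forces])
    x_nt = ss_extension_per_nt(forces, ss)
    j = (exts - x_arms) / (2.0 * x_nt)
    ok = j >= 0.0
    j = np.where(ok, j, 0.0)
    if np.ndim(force) == 0 and np.ndim(extension) == 0:
        return float(j[0]), bool(ok[0])
    return j, ok


# ---------------------------------------------------------------------------
# Nearest-neighbour unzipping thermodynamics
# ---------------------------------------------------------------------------

# Unified nearest-neighbour parameters (SantaLucia 1998): enthalpy in
# kcal/mol, entropy in cal/(mol K) per stack, 1 M NaCl reference.
NN_DH_KCAL: Mapping[str, float] = {
    "AA": -7.9, "TT": -7.9, "AT": -7.2, "TA": -7.2,
    "CA": -8.5, "TG": -8.5, "GT": -8.4, "AC": -8.4,
    "CT": -7.8, "AG": -7.8, "GA": -8.2, "TC": -8.2,
    "CG": -10.6, "GC": -9.8, "GG": -8.0, "CC": -8.0,
}
NN_DS_CAL: Mapping[str, float] = {
    "AA": -22.2, "TT": -22.2, "AT": -20.4, "TA": -21.3,
    "CA": -22.7, "TG": -22.7, "GT": -22.4, "AC": -22.4,
    "CT": -21.0, "AG": -21.0, "GA": -22.2, "TC": -22.2,
    "CG": -27.2, "GC": -24.4, "GG": -19.9, "CC": -19.9,
}

_KCAL_PER_MOL_TO_PN_NM = 6.9477  # 1 kcal/mol per molecule, in pN·nm


def _sodium_equivalent(monovalent_m: float, mg_m: float) -> float:
    """Effective monovalent concentration [Na+]eq = [mono] + 3.3*sqrt([Mg])."""
    return monovalent_m + 3.3 * np.sqrt(max(mg_m, 0.0))


def nn_opening_energies(sequence: str,
                        temperature: float = DEFAULT_TEMPERATURE_K,
                        monovalent_m: float = 0.1,
                        mg_m: float = 0.003,
                        scale: float = 1.0) -> np.ndarray:
    """Free-energy cost (kT units, > 0) of opening each base pair.

    Base pair j is assigned the stack (j, j+1); the final base pair
    reuses the last stack.  Entropies carry the 0.368*ln[Na+]eq
    cal/(mol K) salt correction per stack.  ``scale`` multiplies all
    energies (exposed for sensitivity checks).
    """
    seq = sequence.upper()
    if not seq or any(c not in "ACGT" for c in seq):
        raise ValueError("sequence must be non-empty over {A,C,G,T}")
    kT = KB_PN_NM * temperature
    na_eq = _sodium_equivalent(monovalent_m, mg_m)
    salt_ds = 0.368 * np.log(na_eq)  # cal/(mol K) per stack
    costs = np.empty(len(seq))
    for j in range(len(seq)):
        stack = seq[j:j + 2] if j < len(seq) - 1 else seq[j - 1:j + 1]
        dh = NN_DH_KCAL[stack]
        ds = NN_DS_CAL[stack] + salt_ds
        dg_kcal = dh - temperature * ds / 1000.0  # kcal/mol, negative = stable
        costs[j] = -dg_kcal * _KCAL_PER_MOL_TO_PN_NM / kT
    return scale * np.maximum(costs, 1e-6)


def equilibrium_unzip_baseline(sequence: str,
                               ss: SsDnaElasticity = SsDnaElasticity(),
                               arms: DsDnaElasticity = DsDnaElasticity(),
                               nn_energies: np.ndarray | None = None,
                               temperature: float = DEFAULT_TEMPERATURE_K,
                               monovalent_m: float = 0.1,
                               mg_m: float = 0.003) -> np.ndarray:
    """Equilibrium unzipping force (pN) at every fork position.

    For each base pair the baseline force F_j satisfies the fixed-force
    equilibrium criterion: the pairing free-energy cost of opening base
    pair j equals the work released by extending the two freed ssDNA
    nucleotides at that force,

        dG_j = 2 * g_ss(F_j)  (both sides in kT).

    Deterministic given sequence and parameters.  ``nn_energies`` (kT per
    bp) overrides the embedded nearest-neighbour set.
    """
    if nn_energies is None:
        nn_energies = nn_opening_energies(sequence, temperature, monovalent_m, mg_m)
    else:
        nn_energies = np.asarray(nn_energies, dtype=float)
        if len(nn_energies) != len(sequence):
            raise ValueError("nn_energies must match sequence length")
    kT = KB_PN_NM * temperature

    def gap(f: float, dg_kt: float) -> float:
        return 2.0 * ss_stretch_energy_per_nt(f, ss) / kT - dg_kt

    # only a handful of distinct stack energies exist; solve each once
    forces = np.empty(len(nn_energies))
    cache: dict[float, float] = {}
    for j, dg in enumerate(nn_energies):
        key = round(float(dg), 12)
        if key not in cache:
            try:
                cache[key] = brentq(gap, 1e-3, 200.0, args=(float(dg),),
                                    xtol=1e-9, rtol=1e-12)
            except ValueError as exc:
                raise ConvergenceError(
                    f"baseline solve failed for dG={dg:.3f} kT") from exc
        forces[j] = cache[key]
    return forces
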
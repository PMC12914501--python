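"""Closed-form CW-CEST signal models.

The chemical exchange saturation transfer (CEST) effect of a dilute solute
pool is expressed as an exchange-dependent relaxation rate in the rotating
frame, ``R_ex(Δω)``, which for a single pool under continuous-wave
irradiation takes a Lorentzian form in the offset ``Δω``.  A Z-spectrum
(water signal S/S0 versus saturation offset) is assembled from such
components by an inverse summation

    Z(Δω) = R1obs·cos²θ / (R_eff(Δω) + Σ R_ex,i(Δω)·dilution_i)

where ``R_eff`` is the effective water relaxation rate in the rotating
frame and ``θ`` the angle of the effective saturation field.  The apparent
exchange-dependent relaxation (AREX) metric inverts this relation:

    AREX(Δω) = (S0/S_lab − S0/S_ref)·R1obs·(1 + f_m)

so that, for label/reference spectra differing only in the target pool,
AREX recovers that pool's R_ex up to the known dilution bookkeeping.

All rates are handled in s⁻¹ and angular frequencies in rad/s internally;
offsets are stored in ppm.  AREX values are plain s⁻¹; the conventional
display unit %s⁻¹ (= 0.01 s⁻¹) is applied only at presentation time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "GAMMA_RAD_PER_S_PER_UT",
    "AcquisitionScheme",
    "PoolParams",
    "WaterMTParams",
    "RexSpectrum",
    "ZSpectrum",
    "rex_lorentzian",
    "cos2_theta",
    "reff",
    "r1obs_composite",
    "rex_mt_from_lmt",
    "arex",
    "synthesize_zspectrum",
]

#: Proton gyromagnetic ratio, rad s⁻¹ per μT (γ/2π = 42.5764 Hz/μT).
GAMMA_RAD_PER_S_PER_UT = 2.0 * np.pi * 42.5764


def _as_array(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite values in input array")
    return a


@dataclass(frozen=True)
class AcquisitionScheme:
    """CW-CEST acquisition geometry: saturation offsets, power and timing.

    Parameters
    ----------
    offsets_ppm:
        Saturation frequency offsets from water, ppm, stored sorted
        ascending.
    b1_uT:
        Saturation amplitude B1 in μT.
    sat_duration_s, tr_s:
        CW saturation length and repetition time, seconds.
    control_offset_ppm:
        Far off-resonance control offset used for S0 (default 333 ppm,
        i.e. 100 kHz at 300 Hz/ppm).
    ppm_to_hz:
        Field-dependent conversion (300 Hz/ppm at 7 T proton).
    """

    offsets_ppm: np.ndarray
    b1_uT: float = 1.0
    sat_duration_s: float = 5.0
    tr_s: float = 7.0
    control_offset_ppm: float = 333.0
    ppm_to_hz: float = 300.0
    gamma_rad_per_s_per_uT: float = GAMMA_RAD_PER_S_PER_UT

    def __post_init__(self):
        off = np.sort(_as_array(self.offsets_ppm))
        object.__setattr__(self, "offsets_ppm", off)
        if self.b1_uT < 0:
            raise ValueError("b1_uT must be non-negative")
        if abs(self.control_offset_ppm) <= np.max(np.abs(off)):
            raise ValueError("control offset must lie far outside the sampled range")

    @property
    def omega1(self) -> float:
        """Saturation amplitude ω1 = γ·B1 in rad/s."""
        return self.gamma_rad_per_s_per_uT * self.b1_uT

    @property
    def n_offsets(self) -> int:
        return int(self.offsets_ppm.size)

    def ppm_to_rad(self, offsets_ppm) -> np.ndarray:
        return np.asarray(offsets_ppm, dtype=float) * self.ppm_to_hz * 2.0 * np.pi

    def scan_time_s(self, n_offsets: int | None = None) -> float:
        """Total acquisition time: one TR per offset plus one control."""
        n = self.n_offsets if n_offsets is None else n_offsets
        return (n + 1) * self.tr_s

    def with_offsets(self, offsets_ppm) -> "AcquisitionScheme":
        return replace(self, offsets_ppm=np.asarray(offsets_ppm, dtype=float))

    @classmethod
    def default_7t(cls, b1_uT: float = 1.0) -> "AcquisitionScheme":
        """The full 69-offset 7 T rat-brain protocol.

        Offsets ±4000, ±3500, ±3000, ±2500 Hz plus −1500:50:1500 Hz
        (−13.33 … 13.33 ppm at 300 Hz/ppm), control at 333 ppm, 5 s CW
        saturation at 1 μT, TR 7 s.
        """
        hz = np.concatenate(
            [
                [-4000.0, -3500.0, -3000.0, -2500.0],
                np.arange(-1500.0, 1500.0 + 1, 50.0),
                [2500.0, 3000.0, 3500.0, 4000.0],
            ]
        )
        return cls(offsets_ppm=hz / 300.0, b1_uT=b1_uT)


@dataclass(frozen=True)
class PoolParams:
    """One dilute exchanging proton pool.

    ``fs`` is the pool fraction (relative proton concentration), ``ksw``
    the solute→water exchange rate (s⁻¹), ``r1s``/``r2s`` the solute
    longitudinal/transverse relaxation rates (s⁻¹) and ``delta_ppm`` the
    chemical shift from water.
    """

    name: str
    delta_ppm: float
    fs: float
    ksw: float
    r1s: float = 1.0
    r2s: float = 30.0

    def __post_init__(self):
        for v in (self.delta_ppm, self.fs, self.ksw, self.r1s, self.r2s):
            if not np.isfinite(v):
                raise ValueError(f"non-finite parameter in pool {self.name!r}")
        if self.fs < 0 or self.fs >= 1:
            raise ValueError("fs must lie in [0, 1)")
        if self.ksw < 0:
            raise ValueError("ksw must be non-negative")
        if self.r2s <= 0:
            raise ValueError("r2s must be positive")


@dataclass(frozen=True)
class WaterMTParams:
    """Water and semi-solid MT pool relaxation/bookkeeping parameters.

    ``fm`` is the MT pool-size ratio, ``r_mt`` the scaling factor applied
    to the measured MT component (and inside the composite R1obs).
    """

    r1w: float
    r2w: float
    fm: float = 0.0
    r1m: float = 1.0
    r2m: float = 1.0e5
    r_mt: float = 1.0

    def __post_init__(self):
        if self.r1w <= 0 or self.r2w <= 0 or self.r1m <= 0 or self.r2m <= 0:
            raise ValueError("relaxation rates must be positive")
        if self.fm < 0 or self.r_mt < 0:
            raise ValueError("fm and r_mt must be non-negative")

    @property
    def r1obs(self) -> float:
        return r1obs_composite(self.r1w, self.r1m, self.fm, self.r_mt)


@dataclass
class RexSpectrum:
    """An exchange-dependent relaxation spectrum R_ex(Δω) for one pool.

    Values are s⁻¹ on ``offsets_ppm``; display in %s⁻¹ is left to callers.
    Fitted or subtracted spectra may be signed.
    """

    offsets_ppm: np.ndarray
    values: np.ndarray
    pool_label: str = ""

    def __post_init__(self):
        self.offsets_ppm = np.asarray(self.offsets_ppm, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.offsets_ppm.shape != self.values.shape:
            raise ValueError("offsets and values must have equal length")

    def at(self, offsets_ppm) -> np.ndarray:
        """Cubic-spline evaluation at arbitrary offsets (ppm)."""
        from scipy.interpolate import CubicSpline

        order = np.argsort(self.offsets_ppm)
        cs = CubicSpline(self.offsets_ppm[order], self.values[order])
        return cs(np.asarray(offsets_ppm, dtype=float))

    def restrict(self, lo: float, hi: float) -> "RexSpectrum":
        m = (self.offsets_ppm >= lo) & (self.offsets_ppm <= hi)
        return RexSpectrum(self.offsets_ppm[m], self.values[m], self.pool_label)


@dataclass
class ZSpectrum:
    """A control-normalized Z-spectrum S/S0 with per-voxel metadata.

    ``b0_shift_ppm`` / ``b1_scale`` record perturbations applied during
    generation (zero/one for measured or corrected data); ``r1obs`` and
    ``fm`` are the observed water longitudinal rate and MT pool-size
    ratio attached from measurement or simulation.
    """

    offsets_ppm: np.ndarray
    z: np.ndarray
    r1obs: float = np.nan
    fm: float = np.nan
    b0_shift_ppm: float = 0.0
    b1_scale: float = 1.0

    def __post_init__(self):
        self.offsets_ppm = np.asarray(self.offsets_ppm, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.offsets_ppm.shape != self.z.shape:
            raise ValueError("offsets and z must have equal length")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("Z values must be finite")

    def interp(self, offsets_ppm) -> np.ndarray:
        from scipy.interpolate import CubicSpline

        order = np.argsort(self.offsets_ppm)
        cs = CubicSpline(self.offsets_ppm[order], self.z[order])
        return cs(np.asarray(offsets_ppm, dtype=float))


def rex_lorentzian(
    pool: PoolParams,
    offsets_ppm,
    scheme: AcquisitionScheme,
    b1_scale: float = 1.0,
) -> RexSpectrum:
    """Single-pool exchange-dependent relaxation rate R_ex(Δω).

    R_ex = fs·ksw·ω1² / (ω1² + (R2s+ksw)·ksw + (Δω−Δ)²·ksw/(R2s+ksw)),
    a Lorentzian in Δω peaking at the pool shift Δ.  ``b1_scale``
    multiplies ω1 (B1 inhomogeneity).
    """
    offs = _as_array(offsets_ppm)
    if pool.ksw == 0 and pool.r2s == 0:
        raise ValueError("ksw and r2s cannot both be zero")
    w1 = scheme.omega1 * b1_scale
    dw = scheme.ppm_to_rad(offs - pool.delta_ppm)
    denom = w1**2 + (pool.r2s + pool.ksw) * pool.ksw + dw**2 * pool.ksw / (pool.r2s + pool.ksw)
    values = pool.fs * pool.ksw * w1**2 / denom
    return RexSpectrum(offs, values, pool.name)


def cos2_theta(offsets_ppm, scheme: AcquisitionScheme, b1_scale: float = 1.0) -> np.ndarray:
    """cos²θ = Δω²/(ω1²+Δω²) of the effective-field tilt.

    At the singular point ω1 = Δω = 0 there is no saturation field and
    the magnetization stays longitudinal, so cos²θ is defined as 1.
    """
    dw = scheme.ppm_to_rad(np.asarray(offsets_ppm, dtype=float))
    w1 = scheme.omega1 * b1_scale
    denom = w1**2 + dw**2
    with np.errstate(invalid="ignore", divide="ignore"):
        c2 = np.where(denom > 0, dw**2 / np.where(denom > 0, denom, 1.0), 1.0)
    return c2


def reff(
    offsets_ppm,
    scheme: AcquisitionScheme,
    r1obs: float,
    r2w: float,
    b1_scale: float = 1.0,
) -> np.ndarray:
    """Effective water relaxation rate in the rotating frame.

    R_eff = R1obs·cos²θ + R2w·sin²θ.
    """
    if r1obs <= 0 or r2w <= 0:
        raise ValueError("r1obs and r2w must be positive")
    c2 = cos2_theta(offsets_ppm, scheme, b1_scale)
    return r1obs * c2 + r2w * (1.0 - c2)


def r1obs_composite(r1w: float, r1m: float, fm: float, r_mt: float) -> float:
    """Observed longitudinal rate (R1w + r_MT·fm·R1M)/(1 + r_MT·fm)."""
    denom = 1.0 + r_mt * fm
    if denom <= 0:
        raise ValueError("1 + r_mt*fm must be positive")
    return (r1w + r_mt * fm * r1m) / denom


def rex_mt_from_lmt(l_mt, r1obs: float, offsets_ppm=None) -> RexSpectrum:
    """Convert the fitted MT Lorentzian L_MT into an R_ex^MT spectrum.

    L_MT is the direct label/reference difference of the MT term in a
    multi-pool Lorentzian fit; R_ex^MT = R1obs·L_MT/(1−L_MT).
    """
    l = _as_array(l_mt)
    if np.any(l >= 1.0):
        raise ValueError("L_MT must be < 1 everywhere (1 - L_MT singular)")
    values = r1obs * l / (1.0 - l)
    offs = np.arange(l.size, dtype=float) if offsets_ppm is None else _as_array(offsets_ppm)
    return RexSpectrum(offs, values, "mt")


def arex(
    s_lab,
    s_ref,
    s0: float,
    r1obs: float,
    fm: float,
    offsets_ppm=None,
    label: str = "AREX",
) -> RexSpectrum:
    """AREX(Δω) = (S0/S_lab − S0/S_ref)·R1obs·(1 + fm), in s⁻¹."""
    lab = _as_array(s_lab)
    ref = _as_array(s_ref)
    if lab.shape != ref.shape:
        raise ValueError("s_lab and s_ref must have equal length")
    if np.any(lab <= 0) or np.any(ref <= 0) or s0 <= 0:
        raise ValueError("signals must be strictly positive (AREX is singular at zero)")
    values = (s0 / lab - s0 / ref) * r1obs * (1.0 + fm)
    offs = np.arange(lab.size, dtype=float) if offsets_ppm is None else _as_array(offsets_ppm)
    return RexSpectrum(offs, values, label)


def synthesize_zspectrum(
    scheme: AcquisitionScheme,
    water_mt: WaterMTParams,
    solute_components: Sequence[RexSpectrum] = (),
    mt_component: RexSpectrum | None = None,
    r1obs: float | None = None,
    r_amines: float = 1.0,
    b0_shift_ppm: float = 0.0,
    b1_scale: float = 1.0,
    finite_duration: bool = False,
) -> ZSpectrum:
    """Inverse-summation Z-spectrum from R_ex components.

    Z_ss(Δω) = R1obs·cos²θ / (R_eff + Σ_solute R_ex/(1 + r_MT·fm)
                                      + r_MT·R_ex^MT)

    Solute components (guanidine, amide/APT, NOEs, amines) are diluted by
    (1 + r_MT·fm); a component labeled ``"amines"`` is additionally scaled
    by ``r_amines``; the MT component enters multiplied by r_MT only.

    All components must be sampled on ``scheme.offsets_ppm``.  When
    ``b0_shift_ppm``/``b1_scale`` are non-trivial they shift/scale the
    water terms (cos²θ, R_eff); component values are used as given, so
    callers inject perturbations by evaluating the components on the
    effective grid (offset − B0 shift) at the scaled ω1.

    With ``finite_duration`` the monoexponential approach to steady state
    over ``scheme.sat_duration_s`` is applied,

        Z(t) = Z_ss + (1 − Z_ss)·exp(−R_1ρ·t),

    with R_1ρ the full inverse-summation denominator; this matches the
    finite 5 s saturation of the numerical simulator to well under 1%
    away from the water resonance, where the steady-state form alone can
    deviate by ~2%.  The default remains the steady state, for which the
    AREX round trip is an exact algebraic identity.
    """
    offs = scheme.offsets_ppm
    denom_extra = np.zeros_like(offs)
    dil = 1.0 + water_mt.r_mt * water_mt.fm
    for comp in solute_components:
        if comp.values.shape != offs.shape:
            raise ValueError(f"component {comp.pool_label!r} not on the scheme grid")
        scale = r_amines if comp.pool_label == "amines" else 1.0
        denom_extra = denom_extra + scale * comp.values / dil
    if mt_component is not None:
        if mt_component.values.shape != offs.shape:
            raise ValueError("MT component not on the scheme grid")
        denom_extra = denom_extra + water_mt.r_mt * mt_component.values

    r1 = water_mt.r1obs if r1obs is None else r1obs
    eff_offs = offs - b0_shift_ppm
    c2 = cos2_theta(eff_offs, scheme, b1_scale)
    r1rho = reff(eff_offs, scheme, r1, water_mt.r2w, b1_scale) + denom_extra
    z = r1 * c2 / r1rho
    if finite_duration:
        z = z + (1.0 - z) * np.exp(-r1rho * scheme.sat_duration_s)
    return ZSpectrum(offs, z, r1obs=r1, fm=water_mt.fm, b0_shift_ppm=b0_shift_ppm, b1_scale=b1_scale)
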
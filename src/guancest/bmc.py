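"""Numerical multi-pool Bloch-McConnell CW-CEST simulator.

Simulates the coupled magnetization dynamics of water plus up to six
dilute/semi-solid proton pools under continuous-wave saturation, using
the exact matrix-exponential propagator of the time-invariant generator
(CW irradiation makes the rotating-frame Bloch-McConnell system linear
and constant over the saturation window).  The semi-solid MT pool is
carried as a full three-component exchanging pool with a very short T2,
i.e. a Lorentzian absorption line shape.

The simulator provides tissue-mimicking and fully-synthetic datasets and
the exact guanidine ground truth: the AREX difference between otherwise
identical simulations with and without the guanidine pool, evaluated
without B0/B1 perturbations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import yaml
from scipy.linalg import expm

from .physics import (
    AcquisitionScheme,
    PoolParams,
    RexSpectrum,
    WaterMTParams,
    ZSpectrum,
    arex,
    r1obs_composite,
)

__all__ = [
    "SimTissue",
    "PerturbationRanges",
    "default_tissue",
    "simulate_zspectrum",
    "ground_truth_pool",
    "ground_truth_guanidine",
    "generate_tissue_mimicking_set",
]


@dataclass(frozen=True)
class SimTissue:
    """Water + exchanging-pool composition for a simulation voxel.

    ``pools`` holds the dilute CEST pools (amide 3.5 ppm, amine 3 ppm,
    guanidine 2 ppm, NOE −1.6/−3.5 ppm) and the broad MT pool (named
    ``"mt"``, 0 ppm).  ``fm``/``r1obs`` are derived bookkeeping values
    matching what a qMT measurement would report.
    """

    r1w: float
    r2w: float
    pools: tuple[PoolParams, ...]

    def __post_init__(self):
        names = [p.name for p in self.pools]
        if len(set(names)) != len(names):
            raise ValueError("pool names must be unique")
        if self.r1w <= 0 or self.r2w <= 0:
            raise ValueError("water relaxation rates must be positive")

    def pool(self, name: str) -> PoolParams:
        for p in self.pools:
            if p.name == name:
                return p
        raise KeyError(f"no pool named {name!r}")

    @property
    def fm(self) -> float:
        try:
            return self.pool("mt").fs
        except KeyError:
            return 0.0

    @property
    def r1obs(self) -> float:
        """Composite observed R1 as an inversion-recovery fit would see it."""
        try:
            mt = self.pool("mt")
        except KeyError:
            return self.r1w
        return r1obs_composite(self.r1w, mt.r1s, mt.fs, 1.0)

    def without(self, name: str) -> "SimTissue":
        """Copy with the named pool's fraction set to zero."""
        pools = tuple(replace(p, fs=0.0) if p.name == name else p for p in self.pools)
        return replace(self, pools=pools)

    def water_mt(self, r_mt: float = 1.0) -> WaterMTParams:
        try:
            mt = self.pool("mt")
            return WaterMTParams(self.r1w, self.r2w, fm=mt.fs, r1m=mt.r1s, r2m=mt.r2s, r_mt=r_mt)
        except KeyError:
            return WaterMTParams(self.r1w, self.r2w, fm=0.0, r_mt=r_mt)


def default_tissue() -> SimTissue:
    """Shipped rat-brain 7 T surrogate tissue (midpoints of the default ranges)."""
    return PerturbationRanges.default().midpoint_tissue()


def _assemble(tissue: SimTissue, omega_rf: np.ndarray, omega1: float, ppm_to_rad: float) -> np.ndarray:
    """Augmented BMC generator matrices, one per RF offset.

    State layout: [x_0, y_0, z_0, x_1, y_1, z_1, ..., 1] with water as
    pool 0; exchange is star-topology water↔solute with k_ws = fs·ksw.
    Returns an array of shape (n_offsets, 3N+1, 3N+1).
    """
    pools = tissue.pools
    n = 1 + len(pools)
    dim = 3 * n + 1
    n_off = omega_rf.size
    A = np.zeros((n_off, dim, dim))

    r1 = np.array([tissue.r1w] + [p.r1s for p in pools])
    r2 = np.array([tissue.r2w] + [p.r2s for p in pools])
    m0 = np.array([1.0] + [p.fs for p in pools])
    shifts = np.array([0.0] + [p.delta_ppm for p in pools]) * ppm_to_rad
    k_out = np.array([0.0] + [p.ksw for p in pools])
    k_in = np.array([0.0] + [p.fs * p.ksw for p in pools])
    k_w_total = float(k_in.sum())

    for j in range(n):
        x, y, z = 3 * j, 3 * j + 1, 3 * j + 2
        dw = shifts[j] - omega_rf  # (n_off,)
        loss = k_w_total if j == 0 else k_out[j]
        A[:, x, x] = -(r2[j] + loss)
        A[:, y, y] = -(r2[j] + loss)
        A[:, z, z] = -(r1[j] + loss)
        A[:, x, y] = dw
        A[:, y, x] = -dw
        A[:, y, z] = omega1
        A[:, z, y] = -omega1
        A[:, z, dim - 1] = r1[j] * m0[j]
        if j > 0:
            wx, wy, wz = 0, 1, 2
            # solute gains from water, water gains from solute
            A[:, x, wx] = k_in[j]
            A[:, y, wy] = k_in[j]
            A[:, z, wz] = k_in[j]
            A[:, wx, x] = k_out[j]
            A[:, wy, y] = k_out[j]
            A[:, wz, z] = k_out[j]
    return A


def simulate_zspectrum(
    tissue: SimTissue,
    scheme: AcquisitionScheme,
    b0_shift_ppm: float = 0.0,
    b1_scale: float = 1.0,
) -> ZSpectrum:
    """Evolve the BMC system over the CW saturation window at each offset.

    The magnetization starts at thermal equilibrium, evolves for
    ``scheme.sat_duration_s`` under irradiation at ω1·b1_scale applied at
    (offset − b0_shift), and the water Mz at the end of saturation is
    normalized by the same quantity simulated at the control offset (S0).
    """
    if scheme.sat_duration_s <= 0:
        raise ValueError("sat_duration_s must be positive")
    pools = tissue.pools
    n = 1 + len(pools)
    offsets = np.concatenate([scheme.offsets_ppm, [scheme.control_offset_ppm]])
    omega_rf = scheme.ppm_to_rad(offsets - b0_shift_ppm)
    omega1 = scheme.omega1 * b1_scale
    ppm_to_rad = scheme.ppm_to_hz * 2.0 * np.pi

    A = _assemble(tissue, omega_rf, omega1, ppm_to_rad)
    m0 = np.zeros(3 * n + 1)
    m0[2::3][: n] = np.array([1.0] + [p.fs for p in pools])
    m0[-1] = 1.0

    try:
        P = expm(A * scheme.sat_duration_s)
    except Exception as err:  # pragma: no cover - defensive
        raise RuntimeError(f"BMC propagator failed for tissue {tissue!r}: {err}") from err
    m_end = P @ m0
    mz_w = m_end[:, 2]
    s0 = mz_w[-1]
    z = mz_w[:-1] / s0
    return ZSpectrum(
        scheme.offsets_ppm,
        z,
        r1obs=tissue.r1obs,
        fm=tissue.fm,
        b0_shift_ppm=b0_shift_ppm,
        b1_scale=b1_scale,
    )


def ground_truth_pool(
    tissue: SimTissue,
    scheme: AcquisitionScheme,
    pool_name: str = "guan",
    offsets_ppm=None,
) -> RexSpectrum:
    """Exact AREX ground truth for one pool: simulation with vs. without it.

    B0 and B1 perturbations are excluded; label and reference differ only
    in the target pool's fraction.  Optionally evaluated on a custom
    (e.g. denser) offset grid.
    """
    sch = scheme if offsets_ppm is None else scheme.with_offsets(offsets_ppm)
    z_lab = simulate_zspectrum(tissue, sch)
    z_ref = simulate_zspectrum(tissue.without(pool_name), sch)
    out = arex(z_lab.z, z_ref.z, 1.0, tissue.r1obs, tissue.fm, sch.offsets_ppm, label=f"truth_{pool_name}")
    return out


def ground_truth_guanidine(tissue: SimTissue, scheme: AcquisitionScheme, offsets_ppm=None) -> RexSpectrum:
    if not any(p.name == "guan" for p in tissue.pools):
        raise ValueError("tissue has no guanidine pool")
    return ground_truth_pool(tissue, scheme, "guan", offsets_ppm)


# ---------------------------------------------------------------------------
# parameter sampling


@dataclass(frozen=True)
class PerturbationRanges:
    """Uniform sampling intervals for tissue parameters and perturbations.

    ``water`` maps t1w_s/t2w_s to (lo, hi); ``pools`` maps pool name →
    {fs, ksw, r2s, (delta_ppm)} intervals; B0 shift in ppm, B1 as a
    multiplicative scale; ``noise_sigma`` is the std of Gaussian noise
    added to Z.  Degenerate (lo == hi) intervals pin a parameter.
    """

    water: Mapping[str, tuple[float, float]]
    pools: Mapping[str, Mapping[str, tuple[float, float]]]
    b0_shift_ppm: tuple[float, float] = (-0.1, 0.1)
    b1_scale: tuple[float, float] = (0.9, 1.1)
    noise_sigma: float = 0.01
    #: uniform range for the measured-component scaling factors r
    r_scale: tuple[float, float] = (0.5, 1.5)

    def __post_init__(self):
        for lo, hi in [self.b0_shift_ppm, self.b1_scale]:
            if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
                raise ValueError("intervals must be finite with lo <= hi")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")

    @staticmethod
    def _load_yaml(name: str) -> "PerturbationRanges":
        text = resources.files("guancest.data").joinpath(name).read_text()
        raw = yaml.safe_load(text)
        tup = lambda v: (float(v[0]), float(v[1]))
        water = {k: tup(v) for k, v in raw["water"].items()}
        pools = {p: {k: tup(v) for k, v in d.items()} for p, d in raw["pools"].items()}
        return PerturbationRanges(
            water=water,
            pools=pools,
            b0_shift_ppm=tup(raw["b0_shift_ppm"]),
            b1_scale=tup(raw["b1_scale"]),
            noise_sigma=float(raw["noise_sigma"]),
            r_scale=tup(raw.get("r_scale", (0.5, 1.5))),
        )

    @classmethod
    def default(cls) -> "PerturbationRanges":
        """Tissue-mimicking defaults (shipped YAML)."""
        return cls._load_yaml("tissue_mimicking_ranges.yaml")

    @classmethod
    def default_fully_synthetic(cls) -> "PerturbationRanges":
        """Broader intervals used for the fully-synthetic comparison arm."""
        return cls._load_yaml("fully_synthetic_ranges.yaml")

    def sample_tissue(self, rng: np.random.Generator) -> SimTissue:
        u = lambda lohi: float(rng.uniform(*lohi))
        t1w = u(self.water["t1w_s"])
        t2w = u(self.water["t2w_s"])
        pools = []
        for name, d in self.pools.items():
            delta = d.get("delta_ppm")
            pools.append(
                PoolParams(
                    name=name,
                    delta_ppm=u(delta) if delta else _DEFAULT_SHIFTS[name],
                    fs=u(d["fs"]),
                    ksw=u(d["ksw"]),
                    r1s=u(d["r1s"]) if "r1s" in d else 1.0,
                    r2s=u(d["r2s"]),
                )
            )
        return SimTissue(r1w=1.0 / t1w, r2w=1.0 / t2w, pools=tuple(pools))

    def midpoint_tissue(self) -> SimTissue:
        mid = lambda lohi: 0.5 * (lohi[0] + lohi[1])
        pools = []
        for name, d in self.pools.items():
            delta = d.get("delta_ppm")
            pools.append(
                PoolParams(
                    name=name,
                    delta_ppm=mid(delta) if delta else _DEFAULT_SHIFTS[name],
                    fs=mid(d["fs"]),
                    ksw=mid(d["ksw"]),
                    r1s=mid(d["r1s"]) if "r1s" in d else 1.0,
                    r2s=mid(d["r2s"]),
                )
            )
        return SimTissue(
            r1w=1.0 / mid(self.water["t1w_s"]),
            r2w=1.0 / mid(self.water["t2w_s"]),
            pools=tuple(pools),
        )


_DEFAULT_SHIFTS = {
    "amide": 3.5,
    "amine": 3.0,
    "guan": 2.0,
    "noe16": -1.6,
    "noe35": -3.5,
    "mt": 0.0,
}


def generate_tissue_mimicking_set(
    ranges: PerturbationRanges,
    n: int,
    seed: int,
    scheme: AcquisitionScheme | None = None,
    with_tissue: bool = False,
) -> list[tuple]:
    """Draw ``n`` simulated voxels with exact guanidine ground truth.

    Each sample: tissue parameters and B0/B1 shifts drawn uniformly from
    ``ranges``; the (noisy, shifted) Z-spectrum is paired with the AREX
    ground truth of the guanidine pool computed without shifts or noise.
    Bitwise reproducible for a given seed.  With ``with_tissue`` each
    tuple also carries the drawn :class:`SimTissue`.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    scheme = scheme or AcquisitionScheme.default_7t()
    rng = np.random.default_rng(seed)
    out: list[tuple] = []
    for _ in range(n):
        tissue = ranges.sample_tissue(rng)
        b0 = float(rng.uniform(*ranges.b0_shift_ppm))
        b1 = float(rng.uniform(*ranges.b1_scale))
        z = simulate_zspectrum(tissue, scheme, b0_shift_ppm=b0, b1_scale=b1)
        if ranges.noise_sigma > 0:
            z = ZSpectrum(
                z.offsets_ppm,
                z.z + rng.normal(0.0, ranges.noise_sigma, size=z.z.size),
                r1obs=z.r1obs,
                fm=z.fm,
                b0_shift_ppm=b0,
                b1_scale=b1,
            )
        gt = ground_truth_guanidine(tissue, scheme)
        out.append((z, gt, tissue) if with_tissue else (z, gt))
    return out
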
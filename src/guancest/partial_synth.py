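"""Partially-synthetic, fully-synthetic and in-vivo-style training data.

The partially-synthetic generator assembles training Z-spectra from the
inverse-summation signal model with two kinds of ingredients:

* *simulated components* — guanidine, amide (APT) and NOE R_ex line
  shapes from the closed-form single-pool expression, with pool
  fractions, exchange rates and water relaxation drawn from sampling
  ranges;
* *measured components* — the broad amine and MT R_ex line shapes
  extracted from a fitted mean Z-spectrum (six-pool Lorentzian fit plus
  the mfit-poly polynomial separation), carried as fixed line shapes and
  rescaled per-sample by uniform scaling factors r.

Each sample also receives B0/B1 perturbations and Gaussian noise on Z;
its regression targets are the amplitude A (at the 2 ppm pool shift) and
FWHM W of the noiseless, unshifted guanidine AREX spectrum, obtained
from the label/reference pair with and without the guanidine pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from . import fitting
from .bmc import PerturbationRanges, generate_tissue_mimicking_set
from .physics import (
    AcquisitionScheme,
    PoolParams,
    RexSpectrum,
    WaterMTParams,
    ZSpectrum,
    arex,
    r1obs_composite,
    rex_lorentzian,
    rex_mt_from_lmt,
    synthesize_zspectrum,
)

__all__ = [
    "MeasuredComponents",
    "TrainingSample",
    "TrainingDataset",
    "extract_measured_components",
    "peak_amplitude_width",
    "generate_partially_synthetic",
    "generate_fully_synthetic",
    "samples_from_simulation",
    "augment_invivo_pairs",
    "build_dataset",
    "mean_zspectrum",
]

GUAN_SHIFT_PPM = 2.0


@dataclass
class MeasuredComponents:
    """Fitted MT and amine R_ex line shapes plus R1obs/fm bookkeeping."""

    rex_mt: RexSpectrum
    rex_amines: RexSpectrum
    r1obs: float
    fm: float
    source_label: str = ""

    def __post_init__(self):
        if self.rex_mt.offsets_ppm.shape != self.rex_amines.offsets_ppm.shape:
            raise ValueError("measured components must share the acquisition grid")
        for s in (self.rex_mt, self.rex_amines):
            if not np.all(np.isfinite(s.values)):
                raise ValueError("measured component values must be finite")


@dataclass
class TrainingSample:
    """One (noisy) synthetic Z-spectrum with its guanidine targets.

    ``target_a`` is the guanidine AREX amplitude at 2 ppm in s⁻¹,
    ``target_w`` the FWHM in ppm.  ``z`` is the raw Z-spectrum;
    normalization for the network happens in :func:`build_dataset`.
    """

    offsets_ppm: np.ndarray
    z: np.ndarray
    r1obs: float
    fm: float
    target_a: float
    target_w: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.target_w <= 0:
            raise ValueError("target_w must be positive")
        if self.target_a < -1e-12:
            raise ValueError("target_a must be non-negative")


@dataclass
class TrainingDataset:
    """Network-ready inputs/targets with normalization metadata.

    ``X`` rows are Z/R1obs (default normalization); ``y`` columns are
    [A in %s⁻¹, W in ppm].
    """

    X: np.ndarray
    y: np.ndarray
    offsets_ppm: np.ndarray
    normalization: str = "divide_r1obs"

    def subset(self, indices) -> "TrainingDataset":
        idx = np.asarray(indices, dtype=int)
        return TrainingDataset(self.X[:, idx], self.y, self.offsets_ppm[idx], self.normalization)


def mean_zspectrum(spectra: Sequence[ZSpectrum]) -> ZSpectrum:
    """Mean Z-spectrum of a group of voxels/samples (an ROI-mean analogue).

    Averages the signals and the attached r1obs/fm metadata; averaging
    also suppresses per-voxel noise, which makes the downstream
    line-shape fits of the measured components much better conditioned
    than fits of a single noisy spectrum.
    """
    if not spectra:
        raise ValueError("empty spectrum list")
    offs = spectra[0].offsets_ppm
    for z in spectra[1:]:
        if z.offsets_ppm.shape != offs.shape or not np.allclose(z.offsets_ppm, offs):
            raise ValueError("spectra must share one acquisition grid")
    return ZSpectrum(
        offs,
        np.mean([z.z for z in spectra], axis=0),
        r1obs=float(np.mean([z.r1obs for z in spectra])),
        fm=float(np.mean([z.fm for z in spectra])),
    )


def build_dataset(samples: Sequence[TrainingSample], normalization: str = "divide_r1obs") -> TrainingDataset:
    if not samples:
        raise ValueError("empty sample list")
    offs = samples[0].offsets_ppm
    Z = np.stack([s.z for s in samples])
    r1 = np.array([s.r1obs for s in samples])
    if normalization == "divide_r1obs":
        X = Z / r1[:, None]
    elif normalization == "append_r1obs":
        X = np.concatenate([Z, r1[:, None]], axis=1)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    y = np.stack([[100.0 * s.target_a, s.target_w] for s in samples])
    return TrainingDataset(X, y, offs, normalization)


# ---------------------------------------------------------------------------
# measured-component extraction


def extract_measured_components(
    z_mean: ZSpectrum,
    source_label: str = "",
    fit_config: dict | None = None,
) -> MeasuredComponents:
    """Six-pool fit of a mean Z-spectrum → MT and amine R_ex line shapes.

    The MT component is R1obs·L_MT/(1−L_MT) from the fitted MT
    Lorentzian; the amine component is the mfit-poly cubic fitted to the
    AREX-quantified amines/guanidine pool outside the guanidine window.
    The input is assumed B0-corrected with r1obs/fm attached.

    The cubic is only a local model of the amine background; outside its
    1–5 ppm validity range the amine line shape is continued with the
    bounded inversion form R1obs·(1+fm)·L_ag/(1−L_ag) of the fitted
    amines/guan Lorentzian (and clamped at zero), which decays smoothly
    far from resonance instead of diverging like an extrapolated cubic.
    Near-water inaccuracy of this component is tolerated by design: in
    the inverse summation it is dominated there by R_eff.
    """
    if not (np.isfinite(z_mean.r1obs) and np.isfinite(z_mean.fm)):
        raise ValueError("z_mean must carry r1obs and fm metadata")
    fit = fitting.lorentzian_multipool_fit(z_mean, "6pool", config=fit_config)
    offs = z_mean.offsets_ppm
    l_mt = fit.peaks["mt"](offs)
    rex_mt = rex_mt_from_lmt(l_mt, z_mean.r1obs, offs)
    rex_ag = fitting.quantify_from_fit(z_mean, fit, "amines_guan")
    coeffs, _ = fitting.mfit_poly_amines(rex_ag)

    l_ag = fit.peaks["amines_guan"](offs)
    tail = z_mean.r1obs * (1.0 + z_mean.fm) * l_ag / (1.0 - np.minimum(l_ag, 0.999))
    inside = (offs >= 1.0) & (offs <= 5.0)
    values = np.where(inside, coeffs(offs), tail)
    rex_amines = RexSpectrum(offs, np.maximum(values, 0.0), "amines")
    return MeasuredComponents(rex_mt, rex_amines, z_mean.r1obs, z_mean.fm, source_label)


# ---------------------------------------------------------------------------
# target extraction


def peak_amplitude_width(
    spectrum: RexSpectrum,
    center_ppm: float = GUAN_SHIFT_PPM,
    window_ppm: tuple[float, float] = (0.8, 3.5),
    fallback_width_ppm: float | None = None,
) -> tuple[float, float]:
    """Amplitude at the pool shift and numerical FWHM of a peak.

    A is the spectrum evaluated at ``center_ppm``; W is found by walking
    outward from the center to the half-maximum crossings (linear
    interpolation on a dense evaluation of the spectrum).  If a crossing
    lies beyond ``window_ppm`` the window edge is used; for a vanishing
    amplitude the ``fallback_width_ppm`` (or the window width) is
    returned so that degenerate samples keep a well-defined target.
    """
    dense = np.arange(window_ppm[0], window_ppm[1] + 1e-9, 0.005)
    vals = spectrum.at(dense)
    a = float(spectrum.at([center_ppm])[0])
    if a <= 1e-9:
        w = fallback_width_ppm if fallback_width_ppm else (window_ppm[1] - window_ppm[0])
        return max(a, 0.0), w
    half = a / 2.0
    ic = int(np.argmin(np.abs(dense - center_ppm)))

    def cross(direction: int) -> float:
        i = ic
        while 0 < i < dense.size - 1:
            j = i + direction
            if vals[j] < half <= vals[i]:
                # linear interpolation between grid points
                t = (vals[i] - half) / (vals[i] - vals[j])
                return float(dense[i] + t * (dense[j] - dense[i]))
            i = j
        return float(dense[-1] if direction > 0 else dense[0])

    left, right = cross(-1), cross(+1)
    return a, right - left


# ---------------------------------------------------------------------------
# partially-synthetic generation


def _synth_sample(
    scheme: AcquisitionScheme,
    comp: MeasuredComponents,
    pools: dict[str, PoolParams],
    water: WaterMTParams,
    r_amines: float,
    b0: float,
    b1: float,
    finite_duration: bool = True,
) -> ZSpectrum:
    """Inverse-summation Z on the acquisition grid with perturbations baked in.

    Simulated components are re-evaluated on the B0-shifted grid at the
    scaled ω1; measured line shapes are spline-shifted (their amplitude
    dependence on B1 is absorbed by the scaling factors r).  The finite
    5 s saturation window is modeled by default so the generated spectra
    match what the acquisition (or its numerical simulation) produces.
    """
    eff = scheme.offsets_ppm - b0
    comps = []
    for name, p in pools.items():
        r = rex_lorentzian(p, eff, scheme, b1_scale=b1)
        comps.append(RexSpectrum(scheme.offsets_ppm, r.values, name))
    comps.append(RexSpectrum(scheme.offsets_ppm, comp.rex_amines.at(eff), "amines"))
    mt = RexSpectrum(scheme.offsets_ppm, comp.rex_mt.at(eff), "mt")
    return synthesize_zspectrum(
        scheme, water, comps, mt_component=mt, r_amines=r_amines,
        b0_shift_ppm=b0, b1_scale=b1, finite_duration=finite_duration,
    )


def generate_partially_synthetic(
    components: MeasuredComponents | Sequence[MeasuredComponents],
    ranges: PerturbationRanges,
    scheme: AcquisitionScheme | None = None,
    n: int = 1000,
    seed: int = 0,
    noise_sigma: float | None = None,
    r1m: float = 1.0,
    finite_duration: bool = True,
) -> list[TrainingSample]:
    """Draw ``n`` partially-synthetic training samples.

    Per sample: guanidine/amide/NOE pool parameters and water T1/T2 are
    drawn from ``ranges``; the measured amine and MT line shapes are
    rescaled by r_amines and r_MT drawn from ``ranges.r_scale``; B0/B1
    shifts perturb the input spectrum; Gaussian noise of std
    ``noise_sigma`` (default ``ranges.noise_sigma``) is added to Z.  The
    targets come from the noiseless, unshifted label/reference pair with
    and without the guanidine pool, evaluated densely around 2 ppm.

    With several measured-component sources the samples alternate
    between them, so per-source subsets are equally sized.
    """
    if isinstance(components, MeasuredComponents):
        components = [components]
    if not components:
        raise ValueError("at least one measured-component source is required")
    if n < 1:
        raise ValueError("n must be >= 1")
    scheme = scheme or AcquisitionScheme.default_7t()
    sigma = ranges.noise_sigma if noise_sigma is None else noise_sigma
    rng = np.random.default_rng(seed)
    dense_scheme = scheme.with_offsets(np.arange(0.5, 3.5 + 1e-9, 0.005))

    sim_pool_names = [p for p in ranges.pools if p not in ("amine", "mt")]
    out: list[TrainingSample] = []
    for i in range(n):
        comp = components[i % len(components)]
        u = lambda lohi: float(rng.uniform(*lohi))
        pools: dict[str, PoolParams] = {}
        for name in sim_pool_names:
            d = ranges.pools[name]
            delta = d.get("delta_ppm")
            pools[name] = PoolParams(
                name=name,
                delta_ppm=u(delta) if delta else {"guan": 2.0, "amide": 3.5, "noe16": -1.6, "noe35": -3.5}[name],
                fs=u(d["fs"]),
                ksw=u(d["ksw"]),
                r2s=u(d["r2s"]),
            )
        t1w, t2w = u(ranges.water["t1w_s"]), u(ranges.water["t2w_s"])
        r_amines, r_mt = u(ranges.r_scale), u(ranges.r_scale)
        b0, b1 = u(ranges.b0_shift_ppm), u(ranges.b1_scale)
        water = WaterMTParams(1.0 / t1w, 1.0 / t2w, fm=comp.fm, r1m=r1m, r_mt=r_mt)

        z = _synth_sample(scheme, comp, pools, water, r_amines, b0, b1, finite_duration)
        zz = z.z + rng.normal(0.0, sigma, z.z.size) if sigma > 0 else z.z

        # targets: noiseless, unshifted, dense label/reference pair
        ref_pools = {k: v for k, v in pools.items() if k != "guan"}
        z_lab = _synth_sample(dense_scheme, comp, pools, water, r_amines, 0.0, 1.0, finite_duration)
        z_ref = _synth_sample(dense_scheme, comp, ref_pools, water, r_amines, 0.0, 1.0, finite_duration)
        target = arex(z_lab.z, z_ref.z, 1.0, water.r1obs, comp.fm, dense_scheme.offsets_ppm)
        a, w = peak_amplitude_width(target, GUAN_SHIFT_PPM)

        out.append(
            TrainingSample(
                offsets_ppm=scheme.offsets_ppm,
                z=zz,
                r1obs=water.r1obs,
                fm=comp.fm,
                target_a=a,
                target_w=w,
                provenance={
                    "source": comp.source_label or f"components[{i % len(components)}]",
                    "guan_fs": pools["guan"].fs,
                    "guan_ksw": pools["guan"].ksw,
                    "guan_r2s": pools["guan"].r2s,
                    "r_amines": r_amines,
                    "r_mt": r_mt,
                    "b0_shift_ppm": b0,
                    "b1_scale": b1,
                },
            )
        )
    return out


def samples_from_simulation(
    pairs: Sequence[tuple[ZSpectrum, RexSpectrum]],
    source: str = "bmc",
) -> list[TrainingSample]:
    """Convert simulator (Z, ground-truth) pairs into training samples."""
    out = []
    for z, gt in pairs:
        a, w = peak_amplitude_width(gt, GUAN_SHIFT_PPM)
        out.append(
            TrainingSample(z.offsets_ppm, z.z, z.r1obs, z.fm, a, w, provenance={"source": source})
        )
    return out


def generate_fully_synthetic(
    ranges: PerturbationRanges | None = None,
    scheme: AcquisitionScheme | None = None,
    n: int = 1000,
    seed: int = 0,
) -> list[TrainingSample]:
    """Fully Bloch-McConnell-simulated training arm (broader ranges)."""
    ranges = ranges or PerturbationRanges.default_fully_synthetic()
    pairs = generate_tissue_mimicking_set(ranges, n, seed, scheme)
    return samples_from_simulation(pairs, source="fully_synthetic")


# ---------------------------------------------------------------------------
# in-vivo style augmentation


def augment_invivo_pairs(
    voxels: Sequence[ZSpectrum],
    b0_range: tuple[float, float] | None = None,
    seed: int = 0,
) -> list[ZSpectrum]:
    """Pairwise-mean augmentation of voxel Z-spectra.

    Returns all C(n,2) unordered pair means; with ``b0_range`` each mean
    additionally receives a random B0 shift realized by cubic
    interpolation of the spectrum onto the shifted grid.
    """
    if len(voxels) < 2:
        raise ValueError("at least 2 voxels required for pairwise augmentation")
    rng = np.random.default_rng(seed)
    offs = voxels[0].offsets_ppm
    out: list[ZSpectrum] = []
    for a, b in combinations(range(len(voxels)), 2):
        va, vb = voxels[a], voxels[b]
        zm = 0.5 * (va.z + vb.z)
        r1 = 0.5 * (va.r1obs + vb.r1obs)
        fm = 0.5 * (va.fm + vb.fm)
        out.append(ZSpectrum(offs, zm, r1obs=r1, fm=fm))
        if b0_range is not None:
            shift = float(rng.uniform(*b0_range))
            cs = CubicSpline(offs, zm)
            out.append(ZSpectrum(offs, cs(offs - shift), r1obs=r1, fm=fm, b0_shift_ppm=shift))
    return out
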
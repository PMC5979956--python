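"""Digital spinal-cord phantom and cohort generator.

Builds a straight cylindrical cervical cord (craniocaudal fibers) inside
a CSF-filled canal, with left/right dorsal-column and lateral-funiculus
tract masks (fasciculus gracilis, fasciculus cuneatus, lateral
corticospinal tract), a surrounding probabilistic atlas, a designated
homogeneous white-matter calibration block (the stand-in for a corpus
callosum calibration region), and forward-simulated acquisitions:

* three FLASH volumes (PD-, T1-, MT-weighted) under the rational
  small-angle signal model that the MTsat inversion assumes,
* a double-angle B1-mapping EPI pair (10 / 20 degrees),
* a 41-volume two-shell diffusion series (1 b=0 + 20 directions at
  b=1000 + 20 at b=2000 s/mm^2) under the three-compartment NODDI model,
* Rician magnitude noise at a configurable SNR.

Cohorts emulate a myelopathy study: patients carry an affected-side
reduction of the intra-neurite fraction (axon loss) in all three tracts
with myelin preserved by default; controls are unmodified.  All
randomness flows from one integer seed through ``numpy``'s SeedSequence
spawning, so per-subject streams are independent and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.special import eval_legendre

from .noddi import (
    D_ISO_DEFAULT,
    D_PAR_DEFAULT,
    DiffusionScheme,
    _EVEN_L,
    _kernel_legendre_coeffs,
    _signal_from_parts,
    watson_even_moments,
    watson_legendre_coeffs,
)

__all__ = [
    "TissuePhantom",
    "PhantomConfig",
    "CohortSpec",
    "PhantomData",
    "TractAtlas",
    "TRACT_NAMES",
    "flash_mt_forward",
    "noddi_forward",
    "add_rician_noise",
    "two_shell_scheme",
    "generate_phantom",
    "generate_cohort",
]

TRACT_NAMES = ("fasciculus_gracilis", "fasciculus_cuneatus", "lcst")
SIDES = ("left", "right")

# tissue label ids
BACKGROUND, CSF, GRAY_MATTER, WHITE_MATTER, CALIB_BLOCK = 0, 1, 2, 3, 4


@dataclass
class TissuePhantom:
    """Voxelwise ground truth for every quantity the pipeline estimates."""

    mvf_true: np.ndarray
    vic_true: np.ndarray
    viso_true: np.ndarray
    kappa: np.ndarray
    fiber_dir: np.ndarray  # (..., 3)
    r1_true: np.ndarray  # 1/s
    pd_true: np.ndarray  # a.u.
    b1_scale: np.ndarray
    delta_true: np.ndarray  # MT saturation fraction, = mvf_true / c_true
    labels: np.ndarray  # tissue id per voxel
    c_true: float  # ground-truth MVF/delta calibration factor

    def __post_init__(self) -> None:
        for name in ("mvf_true", "vic_true", "viso_true"):
            arr = getattr(self, name)
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError(f"{name} must lie in [0, 1]")
        avf = (1 - self.mvf_true) * (1 - self.viso_true) * self.vic_true
        if np.any(self.mvf_true + avf > 1 + 1e-9):
            raise ValueError("mvf + avf exceeds 1")


@dataclass
class TractAtlas:
    """Probabilistic tract labels plus the analysis-level mask."""

    tracts: dict[str, np.ndarray]  # "<tract>_<side>" -> probability volume
    level_mask: np.ndarray  # binary, selects the analysis vertebral level
    cord_mask: np.ndarray

    def probability(self, tract: str, side: str) -> np.ndarray:
        key = f"{tract}_{side}"
        if key not in self.tracts:
            raise KeyError(f"unknown tract/side: {key}")
        return self.tracts[key]


@dataclass
class PhantomConfig:
    """Geometry, tissue parameters and acquisition protocol.

    Flip angles in degrees and repetition times in seconds; the FLASH
    protocol defaults follow the study protocol (MT/PD-weighted TR 24 ms
    at 5 deg, T1-weighted TR 10 ms at 13 deg; double-angle B1 pair at
    10/20 deg; two-shell diffusion 1 + 20 + 20 at b = 1000/2000 s/mm^2).
    """

    shape: tuple[int, int, int] = (24, 24, 8)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 4.0)
    cord_radius: float = 5.0  # voxels
    canal_radius: float = 7.5
    level_slices: tuple[int, ...] | None = None  # default: middle slice

    # FLASH protocol
    alpha_pd_deg: float = 5.0
    alpha_t1_deg: float = 13.0
    alpha_mt_deg: float = 5.0
    tr_pd_s: float = 0.024
    tr_t1_s: float = 0.010
    tr_mt_s: float = 0.024
    b1_alpha_low_deg: float = 10.0

    # diffusion scheme
    bval_shells: tuple[float, float] = (1000.0, 2000.0)
    dirs_per_shell: int = 20
    d_par: float = D_PAR_DEFAULT
    d_iso: float = D_ISO_DEFAULT

    # tissue parameters (white matter / gray matter)
    wm_mvf: float = 0.32
    wm_vic: float = 0.55
    wm_viso: float = 0.05
    wm_kappa: float = 16.0
    wm_r1: float = 1.1
    wm_pd: float = 700.0
    gm_mvf: float = 0.12
    gm_vic: float = 0.40
    gm_viso: float = 0.10
    gm_kappa: float = 1.0
    gm_r1: float = 0.83
    gm_pd: float = 800.0
    csf_r1: float = 0.25
    csf_pd: float = 1000.0
    c_true: float = 8.0  # MVF = c_true * delta
    calib_g: float = 0.70  # true g-ratio of the calibration block
    heterogeneity: float = 0.03  # relative smooth spatial variation in cord

    # degradation model
    snr: float | None = None  # Rician SNR at PD-weighted WM; None = noiseless
    b1_model: str = "gradient"  # "uniform" | "gradient"
    b1_amplitude: float = 0.05
    # the double-angle pair is a dedicated calibration acquisition: full
    # (non-attenuated) signal and effective smoothing give it a far higher
    # SNR than the imaging volumes, and the 10/20-degree arccos inversion
    # is ill-conditioned at imaging SNR
    b1_snr: float | None = 500.0

    # pathology (applied to affected-side tracts)
    affected_sides: tuple[str, ...] = ()
    vic_reduction: float = 0.0
    mvf_change: float = 0.0

    # per-side biological variability (left, right multiplicative factors)
    mvf_side_scale: tuple[float, float] = (1.0, 1.0)
    vic_side_scale: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        if self.canal_radius <= self.cord_radius:
            raise ValueError("canal must be wider than the cord")
        if min(self.shape) < 8 and self.level_slices is None:
            pass
        if 2 * self.canal_radius > min(self.shape[:2]) - 2:
            raise ValueError("canal does not fit inside the grid")
        if self.level_slices is None:
            self.level_slices = (self.shape[2] // 2,)
        if any(s < 0 or s >= self.shape[2] for s in self.level_slices):
            raise ValueError("level slice outside the grid")
        if not self.tr_pd_s > 0 or not self.tr_t1_s > 0 or not self.tr_mt_s > 0:
            raise ValueError("repetition times must be positive")
        if self.vic_reduction < 0 or self.vic_reduction >= 1:
            raise ValueError("vic_reduction must lie in [0, 1)")


@dataclass
class CohortSpec:
    """Study-level description of a synthetic patient/control cohort."""

    n_patients: int = 20
    n_controls: int = 5
    laterality: tuple[str, ...] = ("left",) * 11 + ("right",) * 2 + ("bilateral",) * 7
    affected_avf_reduction: float = 0.15
    mvf_change: float = 0.0
    snr: float | None = 30.0
    subject_jitter: float = 0.03  # SD of per-subject multiplicative variation
    seed: int = 0
    phantom: PhantomConfig = field(default_factory=PhantomConfig)

    def __post_init__(self) -> None:
        if self.n_patients < 0 or self.n_controls < 0:
            raise ValueError("cohort counts must be non-negative")
        if self.n_patients + self.n_controls == 0:
            raise ValueError("cohort is empty")
        if len(self.laterality) != self.n_patients:
            raise ValueError("laterality list length must equal n_patients")
        bad = set(self.laterality) - {"left", "right", "bilateral"}
        if bad:
            raise ValueError(f"unknown laterality values: {sorted(bad)}")
        if not 0 <= self.affected_avf_reduction < 1:
            raise ValueError("affected_avf_reduction must lie in [0, 1)")


@dataclass
class PhantomData:
    """One simulated subject: acquisitions, atlas and ground truth."""

    flash_pd: np.ndarray
    flash_t1: np.ndarray
    flash_mt: np.ndarray
    b1_epi_pair: tuple[np.ndarray, np.ndarray]
    dwi_series: np.ndarray  # (..., n_volumes)
    scheme: DiffusionScheme
    atlas: TractAtlas
    truth: TissuePhantom
    calib_mask: np.ndarray
    affine: np.ndarray
    config: PhantomConfig


# ---------------------------------------------------------------------------
# forward models

def flash_mt_forward(pd, r1, delta, alpha_rad, tr_s):
    """Spoiled gradient-echo signal with an MT saturation term.

    Rational small-angle FLASH model ``S = pd * a * r1 * tr /
    (r1 * tr + a^2/2 + delta)``; ``delta = 0`` gives the plain FLASH
    approximation.  ``alpha_rad`` in radians (small-angle regime).
    """
    if np.any(np.asarray(tr_s) <= 0):
        raise ValueError("repetition time must be positive")
    pd = np.asarray(pd, dtype=float)
    r1 = np.asarray(r1, dtype=float)
    delta = np.asarray(delta, dtype=float)
    return pd * alpha_rad * r1 * tr_s / (r1 * tr_s + alpha_rad**2 / 2.0 + delta)


def noddi_forward(
    vic,
    viso,
    kappa,
    fiber_dir,
    scheme: DiffusionScheme,
    d_par: float = D_PAR_DEFAULT,
    d_iso: float = D_ISO_DEFAULT,
) -> np.ndarray:
    """Vectorized normalized NODDI signal over a field of voxels.

    All tissue arguments broadcast over voxels; ``fiber_dir`` has shape
    (..., 3).  Returns (..., n_volumes) with exact 1.0 at b = 0.
    """
    scalar_input = np.ndim(vic) == 0
    vic = np.atleast_1d(np.asarray(vic, dtype=float))
    viso = np.broadcast_to(np.asarray(viso, dtype=float), vic.shape)
    kappa = np.broadcast_to(np.asarray(kappa, dtype=float), vic.shape)
    mu = np.broadcast_to(np.asarray(fiber_dir, dtype=float), vic.shape + (3,))
    if np.any((vic < 0) | (vic > 1)) or np.any((viso < 0) | (viso > 1)):
        raise ValueError("volume fractions must lie in [0, 1]")
    if np.any(kappa < 0):
        raise ValueError("kappa must be non-negative")
    cosang = mu @ scheme.bvecs.T  # (..., n)
    w = watson_legendre_coeffs(kappa.ravel()).reshape(kappa.shape + (-1,))
    j = _kernel_legendre_coeffs(scheme.bvals * d_par)  # (n, L)
    pl = eval_legendre(
        _EVEN_L.reshape((-1,) + (1,) * cosang.ndim), cosang[None, ...]
    )  # (L, ..., n)
    coef = (2 * _EVEN_L + 1) / 2.0
    a_ic = np.einsum("l,...l,nl,l...n->...n", coef, w, j, pl)
    m2 = watson_even_moments(kappa.ravel())[:, 1].reshape(kappa.shape)
    out = _signal_from_parts(
        vic[..., None],
        viso[..., None],
        m2[..., None],
        a_ic,
        scheme.bvals,
        cosang**2,
        d_par,
        d_iso,
    )
    return out[0] if scalar_input else out


def add_rician_noise(signal, sigma: float, seed: int | np.random.Generator):
    """Magnitude-MRI Rician noise: |signal + complex N(0, sigma)|.

    ``sigma = 0`` returns the input unchanged (bit-for-bit).  ``seed``
    may be an integer or an existing Generator.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    signal = np.asarray(signal, dtype=float)
    if sigma == 0:
        return signal
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    re = signal + rng.normal(0.0, sigma, signal.shape)
    im = rng.normal(0.0, sigma, signal.shape)
    return np.hypot(re, im)


# ---------------------------------------------------------------------------
# scheme and geometry

def _fibonacci_hemisphere(n: int) -> np.ndarray:
    """n roughly uniform unit vectors on the upper hemisphere."""
    i = np.arange(n) + 0.5
    z = i / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(1 - z**2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def two_shell_scheme(
    shells: tuple[float, float] = (1000.0, 2000.0), dirs_per_shell: int = 20
) -> DiffusionScheme:
    """1 b=0 volume plus ``dirs_per_shell`` directions per shell."""
    bvals = [0.0]
    bvecs = [np.zeros(3)]
    for k, b in enumerate(shells):
        dirs = _fibonacci_hemisphere(dirs_per_shell)
        if k % 2 == 1:  # decorrelate shell sampling patterns
            dirs = dirs[:, [1, 0, 2]] * np.array([1.0, -1.0, 1.0])
        bvals.extend([b] * dirs_per_shell)
        bvecs.extend(dirs)
    return DiffusionScheme(np.array(bvals), np.array(bvecs))


def _cross_section_labels(cfg: PhantomConfig):
    """Tissue labels and binary tract masks in the axial plane."""
    nx, ny, _ = cfg.shape
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    x, y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    dx, dy = x - cx, y - cy
    r = np.hypot(dx, dy)
    # angle from the dorsal (+y) axis, signed toward the right (+x)
    phi = np.degrees(np.arctan2(dx, dy))
    labels2d = np.full((nx, ny), BACKGROUND, dtype=np.int16)
    labels2d[r <= cfg.canal_radius] = CSF
    cord = r <= cfg.cord_radius
    labels2d[cord] = WHITE_MATTER
    labels2d[r <= 0.45 * cfg.cord_radius] = GRAY_MATTER
    wm = labels2d == WHITE_MATTER
    tract2d: dict[str, np.ndarray] = {}
    rr = r / cfg.cord_radius
    aphi = np.abs(phi)
    specs = {
        "fasciculus_gracilis": (aphi <= 28) & (rr > 0.45),
        "fasciculus_cuneatus": (aphi > 28) & (aphi <= 62) & (rr > 0.45),
        "lcst": (aphi >= 75) & (aphi <= 130) & (rr > 0.5),
    }
    for name, region in specs.items():
        tract2d[f"{name}_left"] = wm & region & (dx < 0)
        tract2d[f"{name}_right"] = wm & region & (dx >= 0)
    return labels2d, tract2d


def _smooth_field(rng: np.random.Generator, shape, rel: float) -> np.ndarray:
    """Smooth multiplicative heterogeneity field centered on 1."""
    if rel == 0:
        return np.ones(shape)
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=(3.0, 3.0, 1.5))
    std = smooth.std()
    if std > 0:
        smooth = smooth / std
    return 1.0 + rel * smooth


def _calib_vic(mvf: float, viso: float, g: float) -> float:
    """Vic making the true g-ratio of the calibration block equal ``g``."""
    return g**2 / (1 - g**2) * mvf / ((1 - mvf) * (1 - viso))


def build_truth(cfg: PhantomConfig, rng: np.random.Generator) -> tuple[
    TissuePhantom, TractAtlas, np.ndarray
]:
    """Ground-truth parameter maps, atlas, and calibration-block mask."""
    nx, ny, nz = cfg.shape
    labels2d, tract2d = _cross_section_labels(cfg)
    labels = np.repeat(labels2d[:, :, None], nz, axis=2)

    # calibration block: homogeneous WM-like slab in a grid corner
    calib = np.zeros(cfg.shape, dtype=bool)
    bx = max(2, nx // 6)
    by = max(2, ny // 6)
    calib[0:bx, 0:by, :] = True
    if (labels[calib] != BACKGROUND).any():
        raise ValueError("calibration block overlaps the spinal canal")
    labels[calib] = CALIB_BLOCK

    mvf = np.zeros(cfg.shape)
    vic = np.zeros(cfg.shape)
    viso = np.zeros(cfg.shape)
    kappa = np.zeros(cfg.shape)
    r1 = np.full(cfg.shape, 0.05)
    pd = np.zeros(cfg.shape)

    het = _smooth_field(rng, cfg.shape, cfg.heterogeneity)
    for lab, (m, v, f, k, r, p) in {
        WHITE_MATTER: (cfg.wm_mvf, cfg.wm_vic, cfg.wm_viso, cfg.wm_kappa,
                       cfg.wm_r1, cfg.wm_pd),
        GRAY_MATTER: (cfg.gm_mvf, cfg.gm_vic, cfg.gm_viso, cfg.gm_kappa,
                      cfg.gm_r1, cfg.gm_pd),
        CSF: (0.0, 0.0, 1.0, 0.0, cfg.csf_r1, cfg.csf_pd),
    }.items():
        sel = labels == lab
        mvf[sel] = m * het[sel] if m else 0.0
        vic[sel] = v * het[sel] if v else 0.0
        viso[sel] = f
        kappa[sel] = k
        r1[sel] = r * het[sel]
        pd[sel] = p * het[sel]
    sel = labels == CALIB_BLOCK
    mvf[sel] = cfg.wm_mvf
    viso[sel] = cfg.wm_viso
    vic[sel] = _calib_vic(cfg.wm_mvf, cfg.wm_viso, cfg.calib_g)
    kappa[sel] = cfg.wm_kappa
    r1[sel] = cfg.wm_r1
    pd[sel] = cfg.wm_pd

    # per-side biological variability over the whole cord cross-section
    nx = cfg.shape[0]
    left2d = np.arange(nx) < (nx - 1) / 2.0
    cord3d = np.isin(labels, (GRAY_MATTER, WHITE_MATTER))
    for si, side_sel in enumerate((left2d, ~left2d)):
        sel = cord3d & side_sel[:, None, None]
        mvf[sel] *= cfg.mvf_side_scale[si]
        vic[sel] *= cfg.vic_side_scale[si]

    # pathology: reduce Vic (and optionally MVF) in affected-side tracts
    if cfg.affected_sides:
        hit = np.zeros(cfg.shape, dtype=bool)
        for side in cfg.affected_sides:
            for tract in TRACT_NAMES:
                hit |= np.repeat(tract2d[f"{tract}_{side}"][:, :, None], nz, axis=2)
        vic[hit] *= 1.0 - cfg.vic_reduction
        mvf[hit] *= 1.0 - cfg.mvf_change

    mvf = np.clip(mvf, 0.0, 0.95)
    vic = np.clip(vic, 0.0, 1.0)

    fiber = np.zeros(cfg.shape + (3,))
    fiber[..., 2] = np.where(vic > 0, 1.0, 0.0)

    if cfg.b1_model == "uniform":
        b1 = np.ones(cfg.shape)
    elif cfg.b1_model == "gradient":
        ramp = np.linspace(-1.0, 1.0, ny)[None, :, None]
        b1 = 1.0 + cfg.b1_amplitude * np.broadcast_to(ramp, cfg.shape)
    else:
        raise ValueError(f"unknown b1_model: {cfg.b1_model}")

    truth = TissuePhantom(
        mvf_true=mvf,
        vic_true=vic,
        viso_true=viso,
        kappa=kappa,
        fiber_dir=fiber,
        r1_true=r1,
        pd_true=pd,
        b1_scale=b1,
        delta_true=mvf / cfg.c_true,
        labels=labels,
        c_true=cfg.c_true,
    )

    # probabilistic atlas: lightly blurred binary tract masks
    tracts = {}
    for key, mask2d in tract2d.items():
        vol = np.repeat(mask2d[:, :, None], nz, axis=2).astype(float)
        prob = ndimage.gaussian_filter(vol, sigma=(0.4, 0.4, 0.0))
        tracts[key] = np.clip(prob, 0.0, 1.0)
    level = np.zeros(cfg.shape, dtype=bool)
    for s in cfg.level_slices:
        level[:, :, s] = True
    cord_mask = np.isin(labels, (GRAY_MATTER, WHITE_MATTER))
    atlas = TractAtlas(tracts=tracts, level_mask=level, cord_mask=cord_mask)
    return truth, atlas, labels == CALIB_BLOCK


def generate_phantom(cfg: PhantomConfig, seed: int | np.random.SeedSequence = 0
                     ) -> PhantomData:
    """Simulate one subject's full acquisition from a phantom config."""
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    rng_truth, rng_noise = (np.random.default_rng(s) for s in ss.spawn(2))
    truth, atlas, calib_mask = build_truth(cfg, rng_truth)

    scheme = two_shell_scheme(cfg.bval_shells, cfg.dirs_per_shell)

    deg = np.pi / 180.0
    b1 = truth.b1_scale
    flash_pd = flash_mt_forward(
        truth.pd_true, truth.r1_true, 0.0, b1 * cfg.alpha_pd_deg * deg, cfg.tr_pd_s
    )
    flash_t1 = flash_mt_forward(
        truth.pd_true, truth.r1_true, 0.0, b1 * cfg.alpha_t1_deg * deg, cfg.tr_t1_s
    )
    flash_mt = flash_mt_forward(
        truth.pd_true,
        truth.r1_true,
        truth.delta_true,
        b1 * cfg.alpha_mt_deg * deg,
        cfg.tr_mt_s,
    )
    a_low = cfg.b1_alpha_low_deg * deg
    epi_low = truth.pd_true * np.sin(b1 * a_low)
    epi_high = truth.pd_true * np.sin(b1 * 2 * a_low)

    tissue = truth.labels != BACKGROUND
    dwi = np.zeros(cfg.shape + (scheme.n_volumes,))
    dwi[tissue] = truth.pd_true[tissue, None] * noddi_forward(
        truth.vic_true[tissue],
        truth.viso_true[tissue],
        truth.kappa[tissue],
        np.where(
            truth.vic_true[tissue, None] > 0, truth.fiber_dir[tissue], [0.0, 0.0, 1.0]
        ),
        scheme,
        cfg.d_par,
        cfg.d_iso,
    )

    wm = truth.labels == WHITE_MATTER
    if cfg.snr is not None and cfg.snr > 0:
        sigma_flash = float(np.mean(flash_pd[wm])) / cfg.snr
        sigma_dwi = float(np.mean(dwi[wm][:, scheme.b0_indices])) / cfg.snr
        flash_pd = add_rician_noise(flash_pd, sigma_flash, rng_noise)
        flash_t1 = add_rician_noise(flash_t1, sigma_flash, rng_noise)
        flash_mt = add_rician_noise(flash_mt, sigma_flash, rng_noise)
        dwi = add_rician_noise(dwi, sigma_dwi, rng_noise)
        if cfg.b1_snr is not None and cfg.b1_snr > 0:
            sigma_epi = float(np.mean(epi_low[wm])) / cfg.b1_snr
            epi_low = add_rician_noise(epi_low, sigma_epi, rng_noise)
            epi_high = add_rician_noise(epi_high, sigma_epi, rng_noise)

    affine = np.diag(list(cfg.voxel_size) + [1.0])
    return PhantomData(
        flash_pd=flash_pd,
        flash_t1=flash_t1,
        flash_mt=flash_mt,
        b1_epi_pair=(epi_low, epi_high),
        dwi_series=dwi,
        scheme=scheme,
        atlas=atlas,
        truth=truth,
        calib_mask=calib_mask,
        affine=affine,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# cohort

@dataclass
class Subject:
    subject_id: str
    group: str  # "patient" | "control"
    laterality: str | None  # None for controls
    mjoa: int
    n_levels: int
    data: PhantomData


def _jitter_config(cfg: PhantomConfig, rng: np.random.Generator, sd: float
                   ) -> PhantomConfig:
    """Per-subject and per-side biological variability on MVF / Vic.

    The total SD is split evenly between a whole-subject factor and
    independent left/right factors, so the two sides of one subject are
    correlated but not identical — the structure a cohort of real cords
    would show.
    """
    if sd == 0:
        return cfg
    s = sd / np.sqrt(2.0)
    draw = lambda: float(np.clip(rng.normal(1.0, s), 0.85, 1.15))  # noqa: E731
    f_mvf, f_vic = draw(), draw()
    return replace(
        cfg,
        wm_mvf=cfg.wm_mvf * f_mvf,
        wm_vic=cfg.wm_vic * f_vic,
        mvf_side_scale=(draw(), draw()),
        vic_side_scale=(draw(), draw()),
    )


def generate_cohort(spec: CohortSpec) -> list[Subject]:
    """Simulate every subject of a patient/control cohort.

    Patients carry the affected-side Vic reduction (axon loss) in all
    three tracts; MVF changes by ``mvf_change`` (default 0: myelin
    preserved).  Unilateral patients contribute one affected and one
    unaffected side, bilateral patients two affected sides; controls
    contribute two normal sides.
    """
    root = np.random.SeedSequence(spec.seed)
    streams = root.spawn(spec.n_patients + spec.n_controls)
    subjects: list[Subject] = []
    for i in range(spec.n_patients):
        ss = streams[i]
        meta_rng = np.random.default_rng(ss.spawn(1)[0])
        lat = spec.laterality[i]
        sides = ("left", "right") if lat == "bilateral" else (lat,)
        cfg = replace(
            spec.phantom,
            affected_sides=sides,
            vic_reduction=spec.affected_avf_reduction,
            mvf_change=spec.mvf_change,
            snr=spec.snr,
        )
        cfg = _jitter_config(cfg, meta_rng, spec.subject_jitter)
        data = generate_phantom(cfg, ss)
        subjects.append(
            Subject(
                subject_id=f"P{i + 1:02d}",
                group="patient",
                laterality=lat,
                mjoa=int(meta_rng.integers(11, 17)),
                n_levels=int(meta_rng.integers(1, 4)),
                data=data,
            )
        )
    for i in range(spec.n_controls):
        ss = streams[spec.n_patients + i]
        meta_rng = np.random.default_rng(ss.spawn(1)[0])
        cfg = replace(spec.phantom, affected_sides=(), vic_reduction=0.0,
                      mvf_change=0.0, snr=spec.snr)
        cfg = _jitter_config(cfg, meta_rng, spec.subject_jitter)
        data = generate_phantom(cfg, ss)
        subjects.append(
            Subject(
                subject_id=f"C{i + 1:02d}",
                group="control",
                laterality=None,
                mjoa=18,
                n_levels=0,
                data=data,
            )
        )
    return subjects
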
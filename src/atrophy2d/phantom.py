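"""Synthetic head phantom: T1-like intensity volumes, 11-ROI label masks,
and per-subject ground-truth measures.

The phantom stands in for a clinical cohort with anatomical ground truth. A
head is modeled as nested ellipsoids — bright scalp/skull shell, a dark
extracerebral CSF (eCSF) band, a cortical gray-matter ribbon, and a bright
white-matter core carrying three dark lateral-ventricle (LV) structures
(anterior horn, posterior horn, and paired perihippocampal "temporal horn"
ellipsoids). GM and eCSF are partitioned into four lobes (frontal, temporal,
parietal, occipital) by axial-plane angular sectors, with the lateral sectors
split by height.

Atrophy is a single per-subject score alpha in [0, 1]:

    alpha = clip(c_age * (age - 55) + c_dx * diagnosis + eps, 0, 1)

which widens the eCSF band by (1 + c_w * alpha), dilates the LV semi-axes by
(1 + c_v * alpha), and thins cortex by (1 - c_t * alpha). True brain age is
age + g * (alpha - c_age * (age - 55)): a cognitively-unimpaired subject with
eps = 0 has brain age equal to chronological age.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imaging import BrainVolume

__all__ = [
    "ROI_NAMES",
    "CSF_ROIS",
    "GM_ROIS",
    "PhantomParams",
    "SubjectTruth",
    "CohortBundle",
    "desk_params",
    "clinical_params",
    "generate_subject",
    "generate_cohort",
    "slab_average",
    "SizingError",
]

# Label codes: 0 background (incl. WM, scalp, air), 1-4 lobar GM,
# 5-8 lobar eCSF, 9 anterior LV, 10 posterior LV, 11 perihippocampal LV.
ROI_NAMES = {
    1: "gm_frontal", 2: "gm_temporal", 3: "gm_parietal", 4: "gm_occipital",
    5: "ecsf_frontal", 6: "ecsf_temporal", 7: "ecsf_parietal", 8: "ecsf_occipital",
    9: "lv_anterior", 10: "lv_posterior", 11: "lv_perihippocampal",
}
GM_ROIS = (1, 2, 3, 4)
ECSF_ROIS = (5, 6, 7, 8)
LV_ROIS = (9, 10, 11)
CSF_ROIS = ECSF_ROIS + LV_ROIS
N_CLASSES = 12


class SizingError(ValueError):
    """Raised when the requested structures cannot fit in the grid."""


@dataclass(frozen=True)
class PhantomParams:
    shape: tuple[int, int, int] = (96, 96, 60)
    voxel_mm: float = 2.5
    # tissue mean intensities (arbitrary units, T1-like contrast)
    # GM sits close to WM (110 vs 150) while CSF is far from both: the
    # GM/WM boundary is genuinely harder to resolve than any CSF boundary,
    # which is what makes 2D cortical thickness harder than 2D CSF volume
    intensity_csf: float = 20.0
    intensity_gm: float = 110.0
    intensity_wm: float = 150.0
    intensity_scalp: float = 200.0
    noise_sd: float = 8.0
    brightness_range: float = 25.0  # per-subject offset ~ U[-range, range]
    # atrophy model
    c_age: float = 0.015      # alpha per year above 55
    c_dx: float = 0.35        # alpha shift for a DAT diagnosis
    alpha_noise_sd: float = 0.05
    c_w: float = 1.5          # eCSF-band widening gain
    c_t: float = 0.4          # cortical thinning gain
    c_v: float = 0.8          # LV dilation gain
    hipp_dx_gain: float = 0.25  # extra temporal-horn dilation in DAT
    thickness_jitter_sd: float = 0.12  # per-lobe biological Cth variation
    brainage_gain: float = 20.0  # years of brain age per unit excess alpha
    # geometry (mm)
    head_semiaxes: tuple[float, float, float] = (100.0, 110.0, 70.0)
    scalp_thickness: float = 6.0
    brain_gap: float = 4.0    # skull/dura gap between scalp shell and eCSF
    ecsf_width0: float = 5.0  # base eCSF band width w0
    cortex_thickness0: float = 7.5  # base cortical thickness t0
    lv_anterior_semiaxes: tuple[float, float, float] = (16.0, 20.0, 13.0)
    lv_posterior_semiaxes: tuple[float, float, float] = (15.0, 18.0, 12.0)
    lv_hipp_semiaxes: tuple[float, float, float] = (8.0, 12.0, 7.0)
    lv_anterior_center: tuple[float, float, float] = (0.0, 34.0, 5.0)
    lv_posterior_center: tuple[float, float, float] = (0.0, -36.0, 5.0)
    lv_hipp_offset: tuple[float, float, float] = (34.0, 8.0, -24.0)
    age_range: tuple[float, float] = (55.0, 90.0)
    seed: int = 0

    def __post_init__(self):
        if self.ecsf_width0 <= 0 or self.cortex_thickness0 <= 0:
            raise ValueError("eCSF width and cortical thickness must be > 0")
        if min(self.c_w, self.c_t, self.c_v) < 0:
            raise ValueError("widening gains must be >= 0")


def desk_params(**overrides) -> PhantomParams:
    """Small grid for CPU-scale experiments: 96x96x60 at 2.5 mm."""
    return PhantomParams(**overrides)


def clinical_params(**overrides) -> PhantomParams:
    """Full-resolution preset: 360x480x480 grid (axial in-plane 360x480,
    480 axial slices) at 0.5 mm, mirroring a reconstructed 3D T1 series."""
    defaults = dict(shape=(360, 480, 480), voxel_mm=0.5)
    defaults.update(overrides)
    return PhantomParams(**defaults)


@dataclass
class SubjectTruth:
    """Ground-truth record for one phantom subject.

    CSF ROI volumes are voxel counts times voxel volume (mm^3), exact by
    construction; GM entries are the generative lobar cortical thickness (mm).
    """

    subject_id: str
    age: float
    sex: int          # 0 = male, 1 = female
    diagnosis: int    # 0 = CU, 1 = DAT
    alpha: float
    brain_age: float
    roi_measures: dict[str, float] = field(default_factory=dict)

    def as_row(self) -> dict:
        row = {"id": self.subject_id, "age": self.age, "sex": self.sex,
               "dx": self.diagnosis, "alpha": self.alpha, "brain_age": self.brain_age}
        row.update(self.roi_measures)
        return row


@dataclass
class CohortBundle:
    volumes: list[BrainVolume]
    label_volumes: list[BrainVolume]
    truths: list[SubjectTruth]

    @property
    def truth_table(self) -> pd.DataFrame:
        cols = ["id", "age", "sex", "dx", "alpha", "brain_age"] + list(ROI_NAMES.values())
        if not self.truths:
            return pd.DataFrame(columns=cols)
        return pd.DataFrame([t.as_row() for t in self.truths])[cols]


def _rho(coords, center, semiaxes):
    x, y, z = coords
    cx, cy, cz = center
    ax, ay, az = semiaxes
    return np.sqrt(((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2)


def _shrunk(semiaxes, d):
    out = tuple(a - d for a in semiaxes)
    if min(out) <= 0:
        raise SizingError(
            f"shell of thickness {d} mm does not fit inside semi-axes {semiaxes}")
    return out


def _check_sizing(p: PhantomParams) -> None:
    half_extent = tuple(s * p.voxel_mm / 2.0 for s in p.shape)
    for h, e in zip(p.head_semiaxes, half_extent):
        if h >= e:
            raise SizingError(
                f"head semi-axes {p.head_semiaxes} mm exceed grid half-extent "
                f"{half_extent} mm ({p.shape} voxels at {p.voxel_mm} mm)")
    # worst case alpha = 1: all shells must retain positive inner semi-axes
    brain = _shrunk(p.head_semiaxes, p.scalp_thickness + p.brain_gap)
    w_max = p.ecsf_width0 * (1 + p.c_w)
    t_min = p.cortex_thickness0 * (1 - p.c_t) * 0.7  # jitter clipped at -30%
    wm = _shrunk(brain, w_max + t_min)
    # bounding-box guard: dilated LVs must stay inside the WM core box
    scale = 1 + p.c_v
    for center, semi, extra in (
        (p.lv_anterior_center, p.lv_anterior_semiaxes, 1.0),
        (p.lv_posterior_center, p.lv_posterior_semiaxes, 1.0),
        (p.lv_hipp_offset, p.lv_hipp_semiaxes, 1 + p.hipp_dx_gain),
    ):
        for c, s, a in zip(center, semi, wm):
            if abs(c) + s * scale * extra >= a:
                raise SizingError(
                    f"LV structure at {center} with semi-axes {semi} mm does not "
                    f"fit inside the white-matter core (semi-axes {wm} mm) at "
                    "maximal atrophy")


def _build_label_volume(p: PhantomParams, alpha: float, diagnosis: int,
                        thickness_factors: np.ndarray | None = None):
    """Paint the 11-ROI integer label grid and per-tissue masks.

    thickness_factors: per-lobe multipliers (frontal, temporal, parietal,
    occipital) on the cortical thickness; default all 1.
    """
    nx, ny, nz = p.shape
    v = p.voxel_mm
    # voxel-center coordinates in mm, origin at the grid center
    x = (np.arange(nx) - (nx - 1) / 2.0)[:, None, None] * v
    y = (np.arange(ny) - (ny - 1) / 2.0)[None, :, None] * v
    z = (np.arange(nz) - (nz - 1) / 2.0)[None, None, :] * v
    coords = (x, y, z)
    center = (0.0, 0.0, 0.0)

    head = _rho(coords, center, p.head_semiaxes) <= 1.0
    skull_outer = _shrunk(p.head_semiaxes, p.scalp_thickness)
    scalp = head & (_rho(coords, center, skull_outer) > 1.0)
    brain_outer = _shrunk(skull_outer, p.brain_gap)
    brain = _rho(coords, center, brain_outer) <= 1.0

    if thickness_factors is None:
        thickness_factors = np.ones(4)
    w = p.ecsf_width0 * (1 + p.c_w * alpha)
    t_lobes = p.cortex_thickness0 * (1 - p.c_t * alpha) * thickness_factors
    gm_outer = _shrunk(brain_outer, w)
    gm_plus_core = _rho(coords, center, gm_outer) <= 1.0
    ecsf = brain & ~gm_plus_core

    # lobar sectors: +y anterior. frontal |theta| < 45 deg, occipital > 135,
    # lateral split by height into parietal (upper) / temporal (lower).
    theta = np.abs(np.degrees(np.arctan2(np.broadcast_to(x, (nx, ny, 1)),
                                         np.broadcast_to(y, (nx, ny, 1)))))
    frontal = theta < 45.0
    occipital = theta > 135.0
    lateral = ~frontal & ~occipital
    upper = np.broadcast_to(z >= 0, (nx, ny, nz))
    sectors = np.zeros((nx, ny, nz), dtype=np.int16)  # 0 frontal .. 3 occipital
    sectors[np.broadcast_to(frontal, (nx, ny, nz))] = 0
    sectors[np.broadcast_to(lateral, (nx, ny, nz)) & upper] = 2       # parietal
    sectors[np.broadcast_to(lateral, (nx, ny, nz)) & ~upper] = 1      # temporal
    sectors[np.broadcast_to(occipital, (nx, ny, nz))] = 3

    # per-lobe GM inner surface: cortical thickness varies by lobe
    labels = np.zeros(p.shape, dtype=np.int16)
    wm = np.zeros(p.shape, dtype=bool)
    for s, (gm_code, ecsf_code) in enumerate(zip(GM_ROIS, ECSF_ROIS)):
        sel = sectors == s
        wm_outer_s = _shrunk(gm_outer, float(t_lobes[s]))
        wm_s = (_rho(coords, center, wm_outer_s) <= 1.0) & sel
        wm |= wm_s
        labels[gm_plus_core & sel & ~wm_s] = gm_code
        labels[ecsf & sel] = ecsf_code
    gm = (labels >= 1) & (labels <= 4)

    lv_scale = 1 + p.c_v * alpha
    hipp_scale = lv_scale * (1 + p.hipp_dx_gain * diagnosis)
    lv_specs = [
        (9, p.lv_anterior_center, p.lv_anterior_semiaxes, lv_scale),
        (10, p.lv_posterior_center, p.lv_posterior_semiaxes, lv_scale),
    ]
    hx, hy, hz = p.lv_hipp_offset
    lv_specs.append((11, (hx, hy, hz), p.lv_hipp_semiaxes, hipp_scale))
    lv_specs.append((11, (-hx, hy, hz), p.lv_hipp_semiaxes, hipp_scale))
    for code, c, semi, scale in lv_specs:
        mask = _rho(coords, c, tuple(s * scale for s in semi)) <= 1.0
        labels[mask] = code  # LVs painted last: they override tissue labels

    tissue = {"scalp": scalp, "wm": wm & (labels < 9), "gm": gm, "ecsf": ecsf,
              "head": head}
    return labels, tissue, t_lobes


def generate_subject(
    params: PhantomParams,
    seed: int,
    subject_id: str = "S0",
    age: float | None = None,
    sex: int | None = None,
    diagnosis: int | None = None,
    eps: float | None = None,
) -> tuple[BrainVolume, BrainVolume, SubjectTruth]:
    """Generate one phantom subject: intensity volume, label volume, truth.

    Unset covariates are drawn from the cohort model (age ~ U[55, 90], sex
    and diagnosis ~ Bernoulli(0.5), eps ~ N(0, alpha_noise_sd)). The same
    (params, seed, overrides) always reproduce identical output.
    """
    _check_sizing(params)
    rng = np.random.default_rng(seed)
    lo, hi = params.age_range
    # always draw in fixed order so overrides do not shift the stream
    draw_age = lo + (hi - lo) * rng.random()
    draw_sex = int(rng.random() < 0.5)
    draw_dx = int(rng.random() < 0.5)
    draw_eps = rng.normal(0.0, params.alpha_noise_sd)
    thickness_factors = 1.0 + np.clip(
        rng.normal(0.0, params.thickness_jitter_sd, size=4), -0.3, 0.3)
    age = draw_age if age is None else float(age)
    sex = draw_sex if sex is None else int(sex)
    diagnosis = draw_dx if diagnosis is None else int(diagnosis)
    eps = draw_eps if eps is None else float(eps)

    alpha = float(np.clip(params.c_age * (age - lo) + params.c_dx * diagnosis + eps,
                          0.0, 1.0))
    brain_age = age + params.brainage_gain * (alpha - params.c_age * (age - lo))

    labels, tissue, t_lobes = _build_label_volume(params, alpha, diagnosis,
                                                  thickness_factors)

    intens = np.zeros(params.shape, dtype=np.float64)
    intens[tissue["scalp"]] = params.intensity_scalp
    intens[tissue["wm"]] = params.intensity_wm
    intens[tissue["gm"]] = params.intensity_gm
    intens[(labels >= 5)] = params.intensity_csf
    inside = intens > 0
    offset = rng.uniform(-params.brightness_range, params.brightness_range)
    noise = rng.normal(0.0, params.noise_sd, size=params.shape)
    intens[inside] += noise[inside] + offset  # air stays exactly zero

    voxel_vol = params.voxel_mm ** 3
    measures: dict[str, float] = {}
    for code in CSF_ROIS:
        measures[ROI_NAMES[code]] = float((labels == code).sum()) * voxel_vol
    for s, code in enumerate(GM_ROIS):
        measures[ROI_NAMES[code]] = float(t_lobes[s])

    spacing = (params.voxel_mm,) * 3
    vol = BrainVolume(data=intens.astype(np.float32), voxel_mm=spacing, axial_axis=2)
    lab = BrainVolume(data=labels, voxel_mm=spacing, axial_axis=2)
    truth = SubjectTruth(subject_id=subject_id, age=age, sex=sex,
                         diagnosis=diagnosis, alpha=alpha, brain_age=brain_age,
                         roi_measures=measures)
    return vol, lab, truth


def generate_cohort(n_cu: int, n_dat: int, params: PhantomParams,
                    seed: int) -> CohortBundle:
    """Generate n_cu CU + n_dat DAT independent subjects (diagnosis fixed,
    all other covariates drawn per subject)."""
    if n_cu < 0 or n_dat < 0:
        raise ValueError("cohort sizes must be non-negative")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_cu + n_dat) % (2**31)
    bundle = CohortBundle([], [], [])
    dx_list = [0] * n_cu + [1] * n_dat
    for i, dx in enumerate(dx_list):
        vol, lab, truth = generate_subject(
            params, seed=int(child_seeds[i]), subject_id=f"S{i:04d}", diagnosis=dx)
        bundle.volumes.append(vol)
        bundle.label_volumes.append(lab)
        bundle.truths.append(truth)
    return bundle


def slab_average(volume: BrainVolume, slab_thickness_mm: float) -> BrainVolume:
    """Average contiguous thin axial slices into thick slabs, emulating a
    thick-slice 2D acquisition (e.g. 5 mm slabs from 2.5 mm voxels)."""
    ax = volume.axial_axis
    dz = volume.voxel_mm[ax]
    ratio = slab_thickness_mm / dz
    n_per = int(round(ratio))
    if n_per < 1 or abs(ratio - n_per) > 1e-9:
        raise ValueError(
            f"slab thickness {slab_thickness_mm} mm is not a positive integer "
            f"multiple of the axial voxel size {dz} mm")
    data = np.moveaxis(volume.data, ax, -1)
    n_out = data.shape[-1] // n_per
    data = data[..., : n_out * n_per]
    data = data.reshape(data.shape[:-1] + (n_out, n_per)).mean(axis=-1)
    data = np.moveaxis(data, -1, ax)
    spacing = list(volume.voxel_mm)
    spacing[ax] = slab_thickness_mm
    return BrainVolume(data=data.astype(volume.data.dtype
                                        if np.issubdtype(volume.data.dtype, np.floating)
                                        else np.float64),
                       voxel_mm=tuple(spacing), axial_axis=ax)
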
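"""Synthetic subcentimeter lung-nodule cohort generator.

Every downstream stage of the pipeline (ROI geometry, feature extraction,
Radscore construction, model evaluation) is exercised on desk-scale
synthetic CT volumes whose statistical structure mirrors the clinical
setting: two classes of subcentimeter lung adenocarcinoma nodules --
MIA (minimally invasive, n=53 by default) and IAC (invasive, n=89) --
embedded in aerated-lung background, with class-specific size
distributions (median max diameter 8 mm MIA vs 9 mm IAC), a subsolid
majority in both classes, invasiveness-linked intratumoral texture
heterogeneity, and peritumoral vessel-like strands that are denser and
brighter around invasive nodules.

Clinical covariates (sex, age, BMI, smoking, vessel convergence sign,
vacuole sign, ...) are sampled with class-conditional prevalences taken
from the cohort margins; an ``exact_counts`` mode reproduces the implied
integer contingency tables for the clinical-statistics layer.

Morphological signs such as lobulation and spiculation are sampled as
covariate flags only; rendering them geometrically is out of scope.
Determinism: identical (spec, seed) yields bit-identical output; per-case
seeds are derived from the master seed with ``SeedSequence([seed, index])``.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import VolumeImage, write_mask, write_volume

__all__ = [
    "CohortSpec",
    "SyntheticCase",
    "draw_diameter",
    "simulate_nodule",
    "simulate_clinical_table",
    "simulate_cohort",
    "perturb_mask",
    "write_cohort",
]

CLASSES = ("MIA", "IAC")

# class-conditional covariate prevalences (cohort margins, MIA n=53 / IAC n=89)
_DEFAULT_PREVALENCES: dict[str, dict[str, float]] = {
    "sex_male": {"MIA": 11 / 53, "IAC": 20 / 89},
    "family_history": {"MIA": 4 / 53, "IAC": 4 / 89},
    "smoking": {"MIA": 8 / 53, "IAC": 10 / 89},
    "drinking": {"MIA": 4 / 53, "IAC": 9 / 89},
    "border_clear": {"MIA": 4 / 53, "IAC": 2 / 89},
    "lobulation": {"MIA": 31 / 53, "IAC": 56 / 89},
    "spiculation": {"MIA": 27 / 53, "IAC": 44 / 89},
    "vcs": {"MIA": 9 / 53, "IAC": 40 / 89},
    "pleural_indentation": {"MIA": 20 / 53, "IAC": 37 / 89},
    "vacuole": {"MIA": 7 / 53, "IAC": 26 / 89},
    "air_bronchogram": {"MIA": 0 / 53, "IAC": 5 / 89},
}

_LOCATION_LEVELS = ("RUL", "RML", "RLL", "LUL", "LLL")
_LOCATION_PREVALENCES = {
    "MIA": (20 / 53, 3 / 53, 14 / 53, 9 / 53, 7 / 53),
    "IAC": (23 / 89, 10 / 89, 17 / 89, 20 / 89, 19 / 89),
}

_AGE = {"MIA": (52.0, 13.7), "IAC": (57.0, 11.9)}   # mean, sd approximating M(IQR)
_BMI = {"MIA": (24.8, 3.9), "IAC": (25.4, 3.6)}

# lung-window HU regimes
_BACKGROUND = (-850.0, 50.0)       # parenchyma, clipped to [-1024, -500]
_SUBSOLID_CORE = (-450.0, 60.0)    # ground-glass attenuation
_SOLID_CORE = (-30.0, 40.0)        # soft-tissue attenuation
# per-case lognormal jitter of the noise scales: real cohorts vary in
# reconstruction noise and nodule texture from patient to patient, and
# without it any fixed class difference becomes trivially separable
_BG_SD_LOGJITTER = 0.20
_CORE_SD_LOGJITTER = 0.25
# baseline structured-texture amplitudes present in BOTH classes; the
# invasiveness effects only raise them (in quadrature) for IAC, so class
# membership never creates a qualitatively exclusive image signature
_CORE_TEXTURE_BASE = 25.0   # HU, smooth intratumoral field
_SHELL_DENS_BASE = 15.0     # HU, diffuse peritumoral field
_STRAND_HU_SD = 25.0
# reconstruction point-spread smoothing (voxels); blends boundary voxels
# so the near rim carries partial-volume traces of the core texture,
# mirroring how real peritumoral rims see the tumor through the PSF
_PSF_SIGMA_VOX = 0.8

_MIN_DIAMETER_MM = 4.0
_MAX_DIAMETER_MM = 10.0
# superellipsoid exponent < 2 keeps every directional radius <= the
# nominal one (for e > 2 the diagonals bulge past the sphere and the
# caliper diameter would exceed the subcentimeter ceiling)
_SHAPE_EXPONENT = 1.8
_BOUNDARY_AMPLITUDE = 0.06         # relative boundary perturbation
_STRAND_RADIUS_MM = 0.5
_STRAND_HU = -100.0


@dataclass
class CohortSpec:
    """Study-condition parameters of the synthetic cohort.

    ``texture_effect`` (HU) is the intratumoral heterogeneity amplitude
    added to IAC cores; ``peritumoral_effect`` (HU) scales the extra
    vessel-strand density/brightness and diffuse densification of the
    IAC peritumoral shell.  With both at 0 (and identical per-class size
    distributions) the classes are statistically indistinguishable.
    """

    n_mia: int = 53
    n_iac: int = 89
    diameter_median_mm: dict[str, float] = field(
        default_factory=lambda: {"MIA": 8.0, "IAC": 9.0})
    diameter_iqr_mm: dict[str, float] = field(
        default_factory=lambda: {"MIA": 2.65, "IAC": 2.0})
    subsolid_fraction: dict[str, float] = field(
        default_factory=lambda: {"MIA": 47 / 53, "IAC": 76 / 89})
    covariate_prevalences: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_PREVALENCES.items()})
    texture_effect: float = 60.0
    peritumoral_effect: float = 12.0
    voxel_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    margin_mm: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mia < 1 or self.n_iac < 1:
            raise ValueError("need at least one case per class")
        if self.texture_effect < 0 or self.peritumoral_effect < 0:
            raise ValueError("effect amplitudes must be non-negative")
        for cls in CLASSES:
            d = self.diameter_median_mm[cls]
            if not 0 < d <= _MAX_DIAMETER_MM:
                raise ValueError(f"median diameter must lie in (0, 10] mm, got {d}")
            if not 0 <= self.subsolid_fraction[cls] <= 1:
                raise ValueError("subsolid_fraction must be in [0, 1]")
        for cov, per_class in self.covariate_prevalences.items():
            for cls, p in per_class.items():
                if not 0 <= p <= 1:
                    raise ValueError(f"prevalence of {cov}/{cls} outside [0, 1]: {p}")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel spacing must be positive")


@dataclass
class SyntheticCase:
    """One simulated nodule: image, GTV mask, class label, covariates."""

    case_id: str
    image: VolumeImage
    gtv_mask: np.ndarray
    label: str
    covariates: dict
    seed_used: int


def _case_seed(master_seed: int, index: int) -> int:
    """Counter-based per-case seed splitting (documented rule)."""
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0] % 2**31)


def draw_diameter(spec: CohortSpec, label: str, rng: np.random.Generator,
                  max_retries: int = 1000) -> float:
    """Draw a nodule max diameter (mm) for one class.

    The diameter is ``10 - Y`` with ``Y`` lognormal, calibrated so the
    class medians/IQRs match the cohort margins while respecting the
    subcentimeter ceiling; draws outside [4, 10] mm are redrawn, with an
    error after bounded retries.
    """
    med_y, s = _diameter_params(spec.diameter_median_mm[label],
                                spec.diameter_iqr_mm[label])
    for _ in range(max_retries):
        y = med_y * np.exp(s * rng.standard_normal())
        d = _MAX_DIAMETER_MM - y
        if _MIN_DIAMETER_MM <= d <= _MAX_DIAMETER_MM:
            return float(d)
    raise RuntimeError("diameter redraw limit exceeded")


@lru_cache(maxsize=None)
def _diameter_params(median_mm: float, iqr_mm: float) -> tuple[float, float]:
    """Lognormal parameters for Y = 10 - diameter, truncation-corrected.

    The scale comes from the quartile ratio (u - 1/u = IQR/median of Y);
    the location is then solved so that the median of Y truncated to
    (0, 6] (diameters in [4, 10) mm) equals the requested value.
    """
    from scipy.optimize import brentq
    from scipy.stats import norm

    t = _MAX_DIAMETER_MM - median_mm
    q = iqr_mm / t
    u = (q + np.sqrt(q * q + 4)) / 2
    s = np.log(u) / norm.ppf(0.75)
    y_hi = _MAX_DIAMETER_MM - _MIN_DIAMETER_MM

    def trunc_median(m):
        return m * np.exp(s * norm.ppf(norm.cdf(np.log(y_hi / m) / s) / 2))

    med_y = brentq(lambda m: trunc_median(m) - t, 0.2 * t, 4 * t)
    return float(med_y), float(s)


def _normalized(field_: np.ndarray) -> np.ndarray:
    lo, hi = field_.min(), field_.max()
    return (field_ - lo) / (hi - lo) if hi > lo else np.zeros_like(field_)


def _draw_strand(vals: np.ndarray, phys: np.ndarray, rng: np.random.Generator,
                 r_inner: float, r_outer: float, hu: float) -> None:
    """Burn a vessel-like cylinder of radius 0.5 mm through the shell."""
    u = rng.standard_normal(3)
    u /= np.linalg.norm(u)
    anchor = u * rng.uniform(r_inner, r_outer)
    v = rng.standard_normal(3)
    v -= v @ u * u
    v /= np.linalg.norm(v)
    half = r_outer
    rel = phys - anchor
    t = np.clip(rel @ v, -half, half)
    dist = np.linalg.norm(rel - t[:, None] * v[None, :], axis=1)
    hit = dist <= _STRAND_RADIUS_MM
    flat = vals.reshape(-1)
    flat[hit] = np.maximum(flat[hit], hu)


def _draw_covariates(spec: CohortSpec, label: str, rng: np.random.Generator) -> dict:
    cov: dict = {}
    cov["age"] = float(np.clip(rng.normal(*_AGE[label]), 20, 90))
    cov["bmi"] = float(np.clip(rng.normal(*_BMI[label]), 15, 45))
    for name, per_class in spec.covariate_prevalences.items():
        cov[name] = int(rng.random() < per_class[label])
    cov["location"] = str(rng.choice(_LOCATION_LEVELS, p=_LOCATION_PREVALENCES[label]))
    return cov


def simulate_nodule(spec: CohortSpec, label: str, seed: int,
                    case_id: str | None = None) -> SyntheticCase:
    """Render one synthetic nodule volume plus mask and covariates.

    Deterministic for fixed ``(spec, label, seed)``.
    """
    if label not in CLASSES:
        raise ValueError(f"label must be one of {CLASSES}")
    rng = np.random.default_rng(seed)

    diameter = draw_diameter(spec, label, rng)
    radius = diameter / 2.0
    subsolid = bool(rng.random() < spec.subsolid_fraction[label])
    spacing = np.asarray(spec.voxel_spacing_mm, float)

    half_extent = radius + spec.margin_mm + 4.0  # room for GPTV + padding
    shape = tuple(int(2 * np.ceil(half_extent / s)) + 1 for s in spacing)
    center = (np.array(shape) - 1) / 2 * spacing
    zz, yy, xx = np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, spacing)],
                             indexing="ij")
    phys = np.stack([zz - center[0], yy - center[1], xx - center[2]], axis=-1)
    radial = np.linalg.norm(phys, axis=-1)

    # aerated-lung background, with per-case noise-scale jitter
    bg_sd = _BACKGROUND[1] * np.exp(_BG_SD_LOGJITTER * rng.standard_normal())
    core_jitter = float(np.exp(_CORE_SD_LOGJITTER * rng.standard_normal()))
    vals = np.clip(rng.normal(_BACKGROUND[0], bg_sd, size=shape), -1024, -500)

    # superellipsoid nodule with smooth boundary perturbation (shrink-only,
    # so the subcentimeter ceiling is never exceeded)
    e = _SHAPE_EXPONENT
    d_norm = (np.sum(np.abs(phys / radius) ** e, axis=-1)) ** (1 / e)
    w = _normalized(ndimage.gaussian_filter(rng.standard_normal(shape), sigma=2.0))
    mask = d_norm <= 1.0 - _BOUNDARY_AMPLITUDE * w
    lab, n_comp = ndimage.label(mask)  # 6-connectivity
    if n_comp > 1:
        sizes = np.bincount(lab.ravel())[1:]
        mask = lab == (int(np.argmax(sizes)) + 1)
    if not mask.any():
        raise RuntimeError("degenerate nodule mask")

    core_mu, core_sd = _SUBSOLID_CORE if subsolid else _SOLID_CORE
    vals[mask] = rng.normal(core_mu, core_sd * core_jitter, size=int(mask.sum()))

    # smooth intratumoral heterogeneity field, present in both classes;
    # invasiveness raises its amplitude (in quadrature) for IAC
    tex = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=0.8)
    tex /= max(tex[mask].std(), 1e-12)
    tex_amp = _CORE_TEXTURE_BASE
    if label == "IAC":
        tex_amp = np.hypot(_CORE_TEXTURE_BASE, spec.texture_effect)
    vals[mask] += tex_amp * core_jitter * tex[mask]

    # peritumoral vessel strands: a baseline count in both classes,
    # extra strands plus stronger diffuse densification in IAC
    phys_flat = phys.reshape(-1, 3)
    r_outer = radius + spec.margin_mm
    for _ in range(int(rng.integers(1, 4))):
        _draw_strand(vals, phys_flat, rng, radius, r_outer,
                     rng.normal(_STRAND_HU, _STRAND_HU_SD))
    if label == "IAC" and spec.peritumoral_effect > 0:
        extra = min(int(rng.poisson(spec.peritumoral_effect / 15.0)), 3)
        for _ in range(extra):
            _draw_strand(vals, phys_flat, rng, radius, r_outer,
                         rng.normal(_STRAND_HU + 1.5 * spec.peritumoral_effect,
                                    _STRAND_HU_SD))
    shell = (radial > radius) & (radial <= r_outer)
    dens = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=1.5)
    dens /= max(dens[shell].std(), 1e-12)
    dens_amp = _SHELL_DENS_BASE
    if label == "IAC":
        dens_amp = np.hypot(_SHELL_DENS_BASE, 0.8 * spec.peritumoral_effect)
    vals[shell] += dens_amp * core_jitter * dens[shell]

    vals = ndimage.gaussian_filter(vals, sigma=_PSF_SIGMA_VOX)
    vals = np.clip(vals, -1024, 300)

    cov = _draw_covariates(spec, label, rng)
    cov["subsolid"] = int(subsolid)
    cov["max_diameter_mm"] = round(diameter, 2)

    return SyntheticCase(
        case_id=case_id or f"case_{seed}",
        image=VolumeImage(vals, tuple(spacing)),
        gtv_mask=mask,
        label=label,
        covariates=cov,
        seed_used=int(seed),
    )


def simulate_clinical_table(spec: CohortSpec, seed: int | None = None,
                            exact_counts: bool = False) -> pd.DataFrame:
    """Covariates + label table without imaging.

    With ``exact_counts=True`` each binary covariate column contains
    exactly ``round(prevalence * n)`` positives per class (the integer
    counts implied by the cohort margins), randomly placed.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    frames = []
    for label, n in (("MIA", spec.n_mia), ("IAC", spec.n_iac)):
        df = pd.DataFrame(index=range(n))
        df["label"] = label
        df["age"] = np.clip(rng.normal(*_AGE[label], size=n), 20, 90)
        df["bmi"] = np.clip(rng.normal(*_BMI[label], size=n), 15, 45)
        df["max_diameter_mm"] = [draw_diameter(spec, label, rng) for _ in range(n)]
        covs = dict(spec.covariate_prevalences)
        covs["subsolid"] = {c: spec.subsolid_fraction[c] for c in CLASSES}
        for name, per_class in covs.items():
            p = per_class[label]
            if exact_counts:
                k = int(round(p * n))
                col = np.zeros(n, int)
                col[rng.permutation(n)[:k]] = 1
            else:
                col = (rng.random(n) < p).astype(int)
            df[name] = col
        df["location"] = rng.choice(_LOCATION_LEVELS, size=n,
                                    p=_LOCATION_PREVALENCES[label])
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.index = [f"case_{i:04d}" for i in range(len(out))]
    out.index.name = "case_id"
    return out


def simulate_cohort(spec: CohortSpec) -> tuple[list[SyntheticCase], pd.DataFrame]:
    """Full cohort: ``n_mia + n_iac`` rendered cases plus the covariate table.

    Per-case seeds derive from ``spec.seed`` by the counter-based
    splitting rule, so results are independent of iteration order.
    """
    cases = []
    labels = ["MIA"] * spec.n_mia + ["IAC"] * spec.n_iac
    for i, label in enumerate(labels):
        cases.append(
            simulate_nodule(spec, label, _case_seed(spec.seed, i), f"case_{i:04d}")
        )
    rows = {}
    for c in cases:
        row = dict(c.covariates)
        row["label"] = c.label
        rows[c.case_id] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "case_id"
    return cases, table


def perturb_mask(mask: np.ndarray, seed: int, n_patches: int = 6) -> np.ndarray:
    """Emulate a second reader's segmentation by local 1-voxel boundary edits.

    Random surface patches are either dilated or eroded by one voxel,
    modelling inter-rater contour variability for ICC stability analysis.
    """
    rng = np.random.default_rng(seed)
    mask = np.asarray(mask, bool).copy()
    surface = np.argwhere(mask & ~ndimage.binary_erosion(mask))
    if len(surface) == 0:
        return mask
    ball = ndimage.generate_binary_structure(3, 1)
    for _ in range(n_patches):
        z, y, x = surface[rng.integers(len(surface))]
        patch = np.zeros_like(mask)
        patch[z, y, x] = True
        patch = ndimage.binary_dilation(patch, ball, iterations=1)
        if rng.random() < 0.5:
            mask |= patch
        else:
            trial = mask & ~patch
            if trial.sum() >= max(8, int(0.5 * mask.sum())):
                mask = trial
    return mask


def write_cohort(cases: list[SyntheticCase], table: pd.DataFrame, outdir: str) -> None:
    """Write image/mask NIfTI pairs, covariate CSV, and a manifest JSON."""
    os.makedirs(outdir, exist_ok=True)
    manifest = []
    for c in cases:
        img_path = os.path.join(outdir, f"{c.case_id}_image.nii.gz")
        msk_path = os.path.join(outdir, f"{c.case_id}_gtv.nii.gz")
        write_volume(c.image, img_path)
        write_mask(c.gtv_mask, c.image.spacing_mm, msk_path)
        manifest.append({
            "case_id": c.case_id,
            "label": c.label,
            "seed": c.seed_used,
            "image": os.path.basename(img_path),
            "gtv_mask": os.path.basename(msk_path),
        })
    table.to_csv(os.path.join(outdir, "covariates.csv"))
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
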
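"""Seeded brain-like relaxometry phantoms with tumors and survival metadata.

Each subject is a 3-D grid holding T1/T2/PD maps built from a six-class
tissue model (WM, GM, CSF and the BraTS-style tumor sub-regions ET, NET,
ED), four simulated weighted contrasts with Rician noise, and a survival
time generated from a log-normal accelerated-failure-time law whose linear
predictor links lesion volume and a planted texture covariate to outcome.

The planted covariate is the per-subject correlation ``c`` between the
edema T1-texture and T2-texture fields.  FLAIR responds strongly to both
fields, so its edema texture variance is approximately linear in ``c``,
while T1w and T2w each see mostly one field; this makes the survival
signal concentrate in the FLAIR channel yet remain recoverable from the
(T1w, T2w) pair by a voxel-wise physics inversion — precisely the regime
in which replacing an acquired FLAIR by a synthesized one is informative.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .physics import (
    AcquisitionParams,
    RelaxometryMaps,
    WeightedImage,
    default_protocol,
    simulate_contrast,
)

__all__ = [
    "TissueModel",
    "LesionSpec",
    "CohortSpec",
    "SubjectRecord",
    "LABEL_CODES",
    "generate_phantom",
    "simulate_subject_images",
    "assign_survival",
    "generate_cohort",
]

LABEL_CODES = {"background": 0, "WM": 1, "GM": 2, "CSF": 3, "ET": 4, "NET": 5, "ED": 6}
TUMOR_LABELS = ("ET", "NET", "ED")


class SpecError(ValueError):
    pass


@dataclass(frozen=True)
class TissueModel:
    """Per-class (T1 ms, T2 ms, PD) means, 1.5 T literature-typical defaults.

    ``subject_jitter`` is the relative log-normal spread of the class means
    across subjects; ``texture_amp`` the log-amplitude of the smooth
    within-class texture fields; ``ed_texture_amp`` the log-amplitude of
    the correlated edema T1/T2 mode; ``et_t1_factor`` the post-contrast T1
    shortening applied to ET when simulating T1w-c.
    """

    classes: dict = field(default_factory=lambda: {
        "WM": (600.0, 80.0, 0.70),
        "GM": (1000.0, 100.0, 0.85),
        "CSF": (4000.0, 2000.0, 1.00),
        "ET": (1500.0, 130.0, 0.92),
        "NET": (1400.0, 120.0, 0.88),
        "ED": (1300.0, 110.0, 0.90),
    })
    subject_jitter: float = 0.04
    texture_amp: float = 0.04
    ed_texture_amp: float = 0.12
    et_t1_factor: float = 0.55

    def __post_init__(self) -> None:
        t1 = {k: v[0] for k, v in self.classes.items()}
        if not (t1["CSF"] > t1["GM"] > t1["WM"] > 0):
            raise SpecError("tissue model must satisfy CSF T1 > GM T1 > WM T1 > 0")


@dataclass(frozen=True)
class LesionSpec:
    """Nested deformed-ellipsoid tumor: NET core, ET shell, ED halo (voxels)."""

    ed_radius: float = 10.0
    tc_radius: float = 6.0
    net_radius: float = 3.5
    radius_jitter: float = 0.2  # relative per-subject, per-axis jitter


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort."""

    n_subjects: int = 24
    grid_shape: tuple[int, int, int] = (64, 64, 32)
    seed: int = 0
    noise_sigma: float = 0.02
    threshold_days: int = 480
    # log-normal AFT survival: ln T = mu + b_vol*z_vol + b_tex*z_tex + s*eps
    survival_mu: float = float(np.log(480.0) + 0.10)
    beta_volume: float = -0.30
    beta_texture: float = 0.65
    survival_sigma: float = 0.35
    censor_rate: float = 0.10
    texture_corr_range: float = 0.8  # c ~ Uniform(-range, +range)
    tissue: TissueModel = field(default_factory=TissueModel)
    lesion: LesionSpec = field(default_factory=LesionSpec)

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise SpecError("cohort needs at least 2 subjects")
        if not (0 <= self.censor_rate < 1):
            raise SpecError("censor rate must lie in [0, 1)")


@dataclass
class SubjectRecord:
    subject_id: str
    maps: RelaxometryMaps
    labels: np.ndarray
    hemisphere_of_tumor: str  # "left" | "right" (split along axis 0)
    weighted: dict[str, WeightedImage] = field(default_factory=dict)
    survival_days: int | None = None
    censored: int | None = None
    covariates: dict[str, float] = field(default_factory=dict)

    def label_mask(self, *names: str) -> np.ndarray:
        m = np.zeros(self.labels.shape, bool)
        for nm in names:
            m |= self.labels == LABEL_CODES[nm]
        return m

    @property
    def wt_mask(self) -> np.ndarray:
        """Whole tumor = tumor core (ET u NET) u ED."""
        return self.label_mask("ET", "NET", "ED")


def _smooth_field(rng: np.random.Generator, shape, sigma: float = 2.0) -> np.ndarray:
    """Smooth zero-mean unit-variance random field."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="nearest")
    return (f - f.mean()) / (f.std() + 1e-12)


def _log_sensitivities(t1: float, t2: float, params) -> tuple[float, float]:
    """(d ln S / d ln T1, d ln S / d ln T2) of the SE closed form."""
    x = params.tr / t1
    a = -x * np.exp(-x) / (1.0 - np.exp(-x))
    b = params.te / t2
    return float(a), float(b)


def _edema_texture_directions(ed_means, protocol=None):
    """Unit direction vectors (on ln T1, ln T2) for the two edema fields.

    u is orthogonal to the T2w log-sensitivity vector, v to the T1w one,
    evaluated at the edema class means for the active protocol.
    """
    from .physics import default_protocol
    protocol = protocol or default_protocol()
    t1m, t2m = ed_means[0], ed_means[1]
    a1, b1 = _log_sensitivities(t1m, t2m, protocol["T1w"])
    a2, b2 = _log_sensitivities(t1m, t2m, protocol["T2w"])
    u = np.array([1.0, -a2 / b2])          # T2w-blind, mostly T1 texture
    v = np.array([-b1 / a1, 1.0])          # T1w-blind, mostly T2 texture
    return u / np.linalg.norm(u), v / np.linalg.norm(v)


def _ellipsoid(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    d = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return d <= 1.0


def generate_phantom(seed: int, grid_shape=(64, 64, 32),
                     tissue_model: TissueModel | None = None,
                     lesion_spec: LesionSpec | None = None,
                     texture_corr: float = 0.0,
                     subject_id: str = "sub-000") -> SubjectRecord:
    """Build one phantom: labels plus textured relaxometry maps.

    ``texture_corr`` in [-1, 1] is the planted correlation between the
    edema T1 and T2 texture fields.  Deterministic given ``seed``.
    """
    tm = tissue_model or TissueModel()
    ls = lesion_spec or LesionSpec()
    rng = np.random.default_rng(seed)
    nx, ny, nz = grid_shape

    # --- geometry: brain ellipsoid, GM rind, CSF ventricles ---------------
    center = (nx / 2 - 0.5, ny / 2 - 0.5, nz / 2 - 0.5)
    brain_r = (0.44 * nx, 0.44 * ny, 0.42 * nz)
    brain = _ellipsoid(grid_shape, center, brain_r)
    inner = _ellipsoid(grid_shape, center, tuple(0.88 * r for r in brain_r))
    labels = np.zeros(grid_shape, np.int16)
    labels[brain] = LABEL_CODES["GM"]
    labels[inner] = LABEL_CODES["WM"]
    vent_dx = 0.10 * nx
    for sx in (-1.0, 1.0):
        vent = _ellipsoid(grid_shape,
                          (center[0] + sx * vent_dx, center[1], center[2]),
                          (0.06 * nx, 0.16 * ny, 0.10 * nz))
        labels[vent & inner] = LABEL_CODES["CSF"]

    # --- tumor: nested deformed ellipsoids in one hemisphere --------------
    hemisphere = "left" if rng.random() < 0.5 else "right"
    if ls.ed_radius > 0:
        jit = lambda: 1.0 + ls.radius_jitter * rng.uniform(-1, 1, size=3)  # noqa: E731
        ed_r = ls.ed_radius * jit()
        tc_r = ls.tc_radius * jit()
        net_r = ls.net_radius * jit()
        if ed_r.max() >= 0.40 * nx:
            raise SpecError("lesion larger than one hemisphere")
        side = -1.0 if hemisphere == "left" else 1.0
        cx = center[0] + side * (0.18 * nx + rng.uniform(-0.03, 0.03) * nx)
        cy = center[1] + rng.uniform(-0.12, 0.12) * ny
        cz = center[2] + rng.uniform(-0.10, 0.10) * nz
        tcent = (cx, cy, cz)
        hemi = np.zeros(grid_shape, bool)
        if hemisphere == "left":
            hemi[: nx // 2] = True
        else:
            hemi[nx // 2:] = True
        ed = _ellipsoid(grid_shape, tcent, ed_r) & brain & hemi
        tc = _ellipsoid(grid_shape, tcent, tc_r) & brain & hemi
        net = _ellipsoid(grid_shape, tcent, net_r) & brain & hemi
        labels[ed] = LABEL_CODES["ED"]
        labels[tc] = LABEL_CODES["ET"]   # ET shell = TC minus NET core
        labels[net] = LABEL_CODES["NET"]

    # --- maps: class means (per-subject jitter) + smooth texture ----------
    means = {k: tuple(v * np.exp(tm.subject_jitter * rng.standard_normal())
                      for v in vals)
             for k, vals in tm.classes.items()}
    t1 = np.zeros(grid_shape)
    t2 = np.zeros(grid_shape)
    pdm = np.zeros(grid_shape)
    for name, (m1, m2, mp) in means.items():
        m = labels == LABEL_CODES[name]
        t1[m], t2[m], pdm[m] = m1, m2, mp

    f_t1 = _smooth_field(rng, grid_shape)
    f_t2 = _smooth_field(rng, grid_shape)
    f_pd = _smooth_field(rng, grid_shape)
    t1 *= np.exp(tm.texture_amp * f_t1)
    t2 *= np.exp(tm.texture_amp * f_t2)
    pdm *= np.exp(tm.texture_amp * f_pd)

    # Correlated edema texture: two smooth fields f1 and g = c*f1 +
    # sqrt(1-c^2)*f2 perturb (ln T1, ln T2) along directions u and v chosen
    # orthogonal to the T2w and T1w log-sensitivity vectors at the edema
    # operating point.  Each short-sequence channel then sees exactly one
    # field, so its texture variance is independent of the correlation c,
    # while FLAIR (sensitive to both) encodes c linearly in its texture
    # energy -- and the (T1w, T2w) pair still determines the maps voxel-wise.
    ed_mask = labels == LABEL_CODES["ED"]
    if ed_mask.any():
        c = float(np.clip(texture_corr, -1.0, 1.0))
        # field scale ~2 voxels: coarse enough that texture amplitude is a
        # resolvable image property, fine enough for ~dozens of independent
        # patches inside the edema halo
        f1 = _smooth_field(rng, grid_shape, sigma=2.0)
        f2 = _smooth_field(rng, grid_shape, sigma=2.0)
        g = c * f1 + np.sqrt(1 - c**2) * f2
        u, v = _edema_texture_directions(means["ED"])
        a = tm.ed_texture_amp
        d_lnt1 = a * (u[0] * f1 + v[0] * g)
        d_lnt2 = a * (u[1] * f1 + v[1] * g)
        t1[ed_mask] *= np.exp(d_lnt1[ed_mask])
        t2[ed_mask] *= np.exp(d_lnt2[ed_mask])

    fg = labels > 0
    t2 = np.minimum(t2, t1)          # physical constraint T1 >= T2
    pdm = np.clip(pdm, 0.0, 1.0)
    t1[~fg] = t2[~fg] = pdm[~fg] = 0.0

    maps = RelaxometryMaps(t1, t2, pdm, fg)
    maps.validate()
    return SubjectRecord(subject_id, maps, labels, hemisphere,
                         covariates={"texture_corr": float(texture_corr)})


def _rician(ideal: np.ndarray, sigma: float, rng: np.random.Generator,
            mask: np.ndarray) -> np.ndarray:
    if sigma == 0:
        return ideal.copy()
    e1 = rng.normal(0.0, sigma, ideal.shape)
    e2 = rng.normal(0.0, sigma, ideal.shape)
    noisy = np.sqrt((ideal + e1) ** 2 + e2**2)
    return np.where(mask, noisy, 0.0)  # skull-stripped: background stays zero


def simulate_subject_images(record: SubjectRecord,
                            protocol_config: dict[str, AcquisitionParams] | None = None,
                            noise_sigma: float = 0.0,
                            seed: int = 0,
                            et_t1_factor: float = 0.55) -> SubjectRecord:
    """Fill ``record.weighted`` with noisy forward-simulated contrasts.

    T1w-c is the SE forward model applied to a contrast-enhanced copy of
    the maps (ET T1 shortened by ``et_t1_factor``); sigma = 0 reproduces
    the ideal images exactly.
    """
    protocol = protocol_config or default_protocol()
    rng = np.random.default_rng(seed)
    maps = record.maps
    for contrast in ("T1w", "T2w", "FLAIR", "T1w_c"):
        if contrast not in protocol:
            raise KeyError(f"protocol config missing {contrast!r}")
        m = maps
        if contrast == "T1w_c":
            et = record.label_mask("ET")
            t1c = maps.t1.copy()
            t1c[et] *= et_t1_factor
            m = RelaxometryMaps(t1c, maps.t2, maps.pd, maps.foreground_mask)
        ideal = simulate_contrast(m, contrast, protocol)
        noisy = _rician(ideal.intensities, noise_sigma, rng, maps.foreground_mask)
        record.weighted[contrast] = WeightedImage(noisy, contrast,
                                                 ideal.params, maps.foreground_mask)
    return record


def assign_survival(records: list[SubjectRecord], cohort_spec: CohortSpec,
                    seed: int = 0) -> list[SubjectRecord]:
    """Draw survival from the log-normal AFT law of the cohort spec.

    Linear predictor: standardized log whole-tumor volume (coefficient
    ``beta_volume``) and the standardized planted texture correlation
    (coefficient ``beta_texture``); independent right-censoring.
    """
    spec = cohort_spec
    rng = np.random.default_rng(seed)
    logv = np.array([np.log(max(int(r.wt_mask.sum()), 1)) for r in records])
    z_vol = (logv - logv.mean()) / (logv.std() + 1e-12)
    c_std = spec.texture_corr_range / np.sqrt(3.0)  # std of U(-r, r)
    z_tex = np.array([r.covariates.get("texture_corr", 0.0) for r in records]) / (c_std + 1e-12)

    for i, rec in enumerate(records):
        lp = spec.survival_mu + spec.beta_volume * z_vol[i] + spec.beta_texture * z_tex[i]
        t_true = np.exp(lp + spec.survival_sigma * rng.standard_normal())
        censored = int(rng.random() < spec.censor_rate)
        if censored:
            t_obs = t_true * rng.uniform(0.2, 1.0)
        else:
            t_obs = t_true
        rec.survival_days = max(1, int(round(t_obs)))
        rec.censored = censored
        rec.covariates["wt_log_volume"] = float(logv[i])
    return records


def generate_cohort(cohort_spec: CohortSpec, id_prefix: str = "sub"):
    """Generate a full cohort; returns (records, survival table).

    One master seed fans out to per-subject phantom seeds, the image-noise
    seed and the survival seed, so regeneration is bit-identical.
    """
    spec = cohort_spec
    root = np.random.SeedSequence(spec.seed)
    sub_seeds, noise_seed, surv_seed, corr_seed = root.spawn(4)
    corr_rng = np.random.default_rng(corr_seed)
    cs = corr_rng.uniform(-spec.texture_corr_range, spec.texture_corr_range,
                          size=spec.n_subjects)
    records = []
    per_sub = sub_seeds.spawn(spec.n_subjects)
    noise_rngs = np.random.default_rng(noise_seed)
    for i in range(spec.n_subjects):
        rec = generate_phantom(
            seed=int(per_sub[i].generate_state(1)[0] % (2**31)),
            grid_shape=spec.grid_shape,
            tissue_model=spec.tissue,
            lesion_spec=spec.lesion,
            texture_corr=float(cs[i]),
            subject_id=f"{id_prefix}-{i:03d}",
        )
        simulate_subject_images(
            rec, default_protocol(), spec.noise_sigma,
            seed=int(noise_rngs.integers(2**31)),
            et_t1_factor=spec.tissue.et_t1_factor,
        )
        records.append(rec)
    assign_survival(records, spec, seed=int(np.random.default_rng(surv_seed).integers(2**31)))
    table = pd.DataFrame({
        "subject_id": [r.subject_id for r in records],
        "survival_days": [r.survival_days for r in records],
        "censored": [r.censored for r in records],
    })
    return records, table


def noiseless_cohort(n: int, grid_shape=(64, 64, 16), seed: int = 0,
                     texture_corr_range: float = 0.8) -> list[SubjectRecord]:
    """Convenience: n noiseless phantoms with images, for synthesis tests."""
    spec = CohortSpec(n_subjects=max(n, 2), grid_shape=grid_shape, seed=seed,
                      noise_sigma=0.0, texture_corr_range=texture_corr_range)
    records, _ = generate_cohort(spec)
    return records[:n]
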
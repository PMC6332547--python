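"""Synthetic thorax phantom and patient-level cohort generator.

Two generators make every downstream stage testable without any data download:

``generate_phantom``
    A geometric stand-in for a planning CT + treatment-planning-system dose:
    two ellipsoidal lungs, a spherical GTV inside one lung, margin-grown CTV /
    PTV / PGTV, and a dose field equal to the prescription inside the PTV with
    a monotone exponential falloff outside.  By construction every PTV voxel
    receives at least the maximum dose found outside the PTV, which guarantees
    the metric ordering Lung-PTV <= Lung-PGTV <= Total Lung for V5, V20, MLD.

``simulate_cohort``
    Patient-level records with the statistical structure the analysis assumes:
    Lung-PTV MLD drawn lognormally (median 10.3 Gy, truncated to [6, 16] Gy);
    Lung-PGTV and Total-Lung MLD offset by +1.7 and +2.3 Gy on average with
    per-patient jitter whose symmetric truncation keeps increments positive
    without biasing the mean; V5/V20 as monotone noisy transforms of MLD with
    V20 <= V5 enforced by construction; clinical covariates drawn from typical
    IMRT lung-cancer cohort marginals and independent of outcome by default;
    and the binary pneumonitis outcome (RP2) drawn from the same Lyman model
    the ntcp module fits, driven by Lung-PTV MLD, so parameter recovery is
    well-posed.

A single integer seed drives all draws through named ``numpy`` SeedSequence
child streams.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy import ndimage

from .geometry import DoseGrid, StructureMask, expand_margin
from .ntcp import LymanParams, ntcp_lyman

__all__ = [
    "PhantomConfig",
    "CohortConfig",
    "generate_phantom",
    "simulate_cohort",
    "COHORT_COLUMNS",
    "METRIC_COLUMNS",
]

#: Cohort CSV schema — also the pipeline's input format for real data.
COHORT_COLUMNS = [
    "id", "age", "gender", "smoking", "pathology", "stage", "chemo", "surgery",
    "pgtv_volume_cm3", "ptv_volume_cm3", "pgtv_rx_gy", "ptv_rx_gy",
    "v5_lungptv", "v20_lungptv", "mld_lungptv",
    "v5_lungpgtv", "v20_lungpgtv", "mld_lungpgtv",
    "v5_total", "v20_total", "mld_total",
    "rp2",
]

METRIC_COLUMNS = [c for c in COHORT_COLUMNS if c.startswith(("v5_", "v20_", "mld_"))]


class PhantomConfig(BaseModel):
    """Geometry and dose parameters of the thorax phantom."""

    shape: tuple[int, int, int] = (48, 56, 56)
    spacing_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    # physical coordinates in mm on the (z, y, x) axes
    lung_centers_mm: tuple[tuple[float, float, float], ...] = (
        (72.0, 84.0, 46.0),
        (72.0, 84.0, 122.0),
    )
    lung_semi_axes_mm: tuple[float, float, float] = (60.0, 48.0, 30.0)
    gtv_center_mm: tuple[float, float, float] = (72.0, 84.0, 116.0)
    gtv_radius_mm: float = 14.0
    ctv_margin_mm: float = Field(6.0, ge=0)      # 6 mm squamous / 8 mm other histology
    setup_margin_mm: float = Field(5.0, ge=0)
    prescription_gy: float = Field(60.0, ge=50.0, le=70.0)
    falloff_mm: float = Field(9.0, gt=0)          # exponential dose falloff scale
    dose_noise: float = Field(0.05, ge=0, lt=0.5)  # relative, outside PTV only

    @model_validator(mode="after")
    def _check(self):
        if any(n < 8 for n in self.shape):
            raise ValueError("grid too small for a phantom")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")
        return self


def _coords_mm(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def generate_phantom(
    config: PhantomConfig | None = None, seed: int | None = 0
) -> tuple[DoseGrid, dict[str, StructureMask]]:
    """Build the phantom dose grid and the LUNGS/GTV/CTV/PTV/PGTV masks.

    The dose is ``prescription`` on every PTV voxel and
    ``prescription * exp(-d/falloff)`` at distance ``d`` (mm) outside, scaled
    by a per-voxel factor in (1 - dose_noise, 1] drawn from ``seed`` — noise
    only ever lowers dose outside the PTV, so the target-dominance property
    (min dose inside PTV >= max dose outside) survives.  Bit-identical under
    the same seed.
    """
    cfg = config or PhantomConfig()
    zz, yy, xx = _coords_mm(cfg.shape, cfg.spacing_mm)

    lungs = np.zeros(cfg.shape, dtype=bool)
    for cz, cy, cx in cfg.lung_centers_mm:
        az, ay, ax = cfg.lung_semi_axes_mm
        lungs |= ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0
    gz, gy, gx = cfg.gtv_center_mm
    gtv = (zz - gz) ** 2 + (yy - gy) ** 2 + (xx - gx) ** 2 <= cfg.gtv_radius_mm ** 2
    if not gtv.any():
        raise ValueError("GTV is empty on this grid; enlarge radius or refine spacing")
    if (gtv & ~lungs).any():
        raise ValueError("GTV must lie strictly inside the lungs")

    spacing = cfg.spacing_mm
    gtv_m = StructureMask("GTV", gtv, spacing)
    ctv_m = expand_margin(gtv_m, cfg.ctv_margin_mm, name="CTV")
    ptv_m = expand_margin(ctv_m, cfg.setup_margin_mm, name="PTV")
    pgtv_m = expand_margin(gtv_m, cfg.setup_margin_mm, name="PGTV")

    dist = ndimage.distance_transform_edt(~ptv_m.voxels, sampling=spacing)
    dose = cfg.prescription_gy * np.exp(-dist / cfg.falloff_mm)
    if cfg.dose_noise > 0:
        rng = np.random.default_rng(np.random.SeedSequence(0 if seed is None else seed))
        factor = 1.0 - cfg.dose_noise * rng.random(cfg.shape)
        dose = np.where(ptv_m.voxels, dose, dose * factor)

    masks = {
        "LUNGS": StructureMask("LUNGS", lungs, spacing),
        "GTV": gtv_m, "CTV": ctv_m, "PTV": ptv_m, "PGTV": pgtv_m,
    }
    return DoseGrid(dose, spacing), masks


# ---------------------------------------------------------------------------

class CohortConfig(BaseModel):
    """Statistical parameters of the simulated patient cohort.

    Defaults reproduce the study conditions: 183 patients, Lung-PTV MLD
    median 10.3 Gy in [6, 16] Gy, mean paired MLD offsets of 1.7 Gy
    (Lung-PGTV) and 2.3 Gy (Total Lung) above Lung-PTV, and RP2 drawn from a
    Lyman curve with TD50 = 17.5 Gy, m = 0.34 — about 14% incidence.
    """

    n_patients: int = Field(183, ge=2)
    td50_true: float = Field(17.5, gt=0)
    m_true: float = Field(0.34, gt=0)
    # Lung-PTV MLD location/scale (log scale) and truncation range, Gy
    mld_median: float = Field(10.3, gt=0)
    mld_log_sd: float = Field(0.20, gt=0)
    mld_range: tuple[float, float] = (6.0, 16.0)
    # mean paired offsets above Lung-PTV MLD, Gy
    d_pgtv: float = Field(1.7, gt=0)
    d_total: float = Field(2.3, gt=0)
    jitter_sd_pgtv: float = Field(0.7, gt=0)   # per-patient SD of the +1.7 Gy increment
    jitter_sd_total: float = Field(0.35, gt=0)  # SD of the further +0.6 Gy increment
    # V5 / V20 transforms: slope per Gy of MLD, noise SDs, and paired offsets (%)
    v20_slope: float = 1.75
    v20_noise_sd: float = 1.5
    v5_gap_slope: float = 2.85
    v5_gap_log_sd: float = 0.08
    v5_offsets: tuple[float, float] = (2.2, 0.6)    # PGTV-above-PTV, Total-above-PGTV
    v20_offsets: tuple[float, float] = (3.5, 1.0)
    v5_jitter_sd: tuple[float, float] = (1.4, 1.0)
    v20_jitter_sd: tuple[float, float] = (1.7, 1.0)
    #: which definition's MLD drives the outcome (misspecification studies)
    outcome_definition: str = "lungptv"
    #: optional log-odds shifts on binary covariate columns (power studies)
    covariate_log_or: dict[str, float] = {}
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if self.mld_range[0] >= self.mld_range[1] or self.mld_range[0] <= 0:
            raise ValueError("mld_range must be an increasing positive interval")
        if self.d_total <= self.d_pgtv:
            raise ValueError("d_total must exceed d_pgtv (nested definitions)")
        if self.outcome_definition not in ("lungptv", "lungpgtv", "total"):
            raise ValueError("outcome_definition must be lungptv|lungpgtv|total")
        return self


def _trunc_sym(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Normal(mean, sd) truncated symmetrically to (0, 2*mean).

    Symmetric truncation about the mean keeps the expectation exactly ``mean``
    while guaranteeing strictly positive draws.
    """
    out = rng.normal(mean, sd, size)
    bad = np.abs(out - mean) >= mean
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = np.abs(out - mean) >= mean
    return out


def _trunc_lognormal(rng, median, log_sd, lo, hi, size):
    out = rng.lognormal(np.log(median), log_sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.lognormal(np.log(median), log_sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def simulate_cohort(config: CohortConfig | None = None, seed: int | None = None) -> pd.DataFrame:
    """Draw a patient-level cohort; returns a DataFrame in the cohort schema.

    ``seed`` overrides ``config.seed`` when given.  Every per-patient metric
    constraint (V20 <= V5, Lung-PTV <= Lung-PGTV <= Total Lung orderings)
    holds for every generated record.
    """
    cfg = config or CohortConfig()
    root = np.random.SeedSequence(cfg.seed if seed is None else seed)
    rng_mld, rng_v, rng_cov, rng_out = (np.random.default_rng(s) for s in root.spawn(4))
    n = cfg.n_patients

    mld_ptv = _trunc_lognormal(rng_mld, cfg.mld_median, cfg.mld_log_sd, *cfg.mld_range, size=n)
    inc1 = _trunc_sym(rng_mld, cfg.d_pgtv, cfg.jitter_sd_pgtv, n)
    inc2 = _trunc_sym(rng_mld, cfg.d_total - cfg.d_pgtv, cfg.jitter_sd_total, n)
    mld_pgtv = mld_ptv + inc1
    mld_total = mld_pgtv + inc2

    v20_ptv = np.clip(cfg.v20_slope * mld_ptv + rng_v.normal(0, cfg.v20_noise_sd, n), 0.0, None)
    gap = cfg.v5_gap_slope * mld_ptv * np.exp(rng_v.normal(0, cfg.v5_gap_log_sd, n))
    v5_ptv = np.clip(v20_ptv + gap, None, 100.0)
    v5_pgtv = np.clip(v5_ptv + _trunc_sym(rng_v, cfg.v5_offsets[0], cfg.v5_jitter_sd[0], n), None, 100.0)
    v5_total = np.clip(v5_pgtv + _trunc_sym(rng_v, cfg.v5_offsets[1], cfg.v5_jitter_sd[1], n), None, 100.0)
    v20_pgtv = v20_ptv + _trunc_sym(rng_v, cfg.v20_offsets[0], cfg.v20_jitter_sd[0], n)
    v20_total = v20_pgtv + _trunc_sym(rng_v, cfg.v20_offsets[1], cfg.v20_jitter_sd[1], n)
    # V20 grows faster across definitions than V5; the MLD-scaled gap keeps
    # V20 <= V5 with wide slack, but enforce it defensively
    v5_pgtv = np.maximum(v5_pgtv, v20_pgtv)
    v5_total = np.maximum(v5_total, v20_total)

    age = np.clip(np.round(rng_cov.normal(62.0, 10.0, n)), 30, 88).astype(int)
    gender = rng_cov.choice(["male", "female"], n, p=[0.885, 0.115])
    smoking = rng_cov.choice(["never", "current", "former"], n, p=[0.23, 0.421, 0.349])
    pathology = rng_cov.choice(
        ["squamous", "adenocarcinoma", "small_cell", "other"], n,
        p=[0.617, 0.164, 0.197, 0.022],
    )
    stage = rng_cov.choice(["I/II", "III", "IV"], n, p=[0.077, 0.628, 0.295])
    chemo = (rng_cov.random(n) < 0.863).astype(int)
    surgery = (rng_cov.random(n) < 0.24).astype(int)
    pgtv_volume = np.round(rng_cov.lognormal(np.log(135.1), 0.8, n), 1)
    ptv_volume = np.round(pgtv_volume * rng_cov.lognormal(np.log(543.6 / 135.1), 0.3, n), 1)
    pgtv_rx = rng_cov.choice([50.0, 54.0, 56.0, 60.0, 66.0, 70.0], n,
                             p=[0.25, 0.37, 0.08, 0.20, 0.06, 0.04])
    ptv_rx = rng_cov.choice([45.0, 50.0, 54.0], n, p=[0.30, 0.58, 0.12])

    driver = {"lungptv": mld_ptv, "lungpgtv": mld_pgtv, "total": mld_total}[cfg.outcome_definition]
    params = LymanParams(td50=cfg.td50_true, m=cfg.m_true)
    p_rp2 = ntcp_lyman(driver, params)
    if cfg.covariate_log_or:
        binary = {"chemo": chemo, "surgery": surgery,
                  "gender": (gender == "female").astype(int)}
        logit = np.log(p_rp2 / (1.0 - p_rp2))
        for col, log_or in cfg.covariate_log_or.items():
            if col not in binary:
                raise ValueError(f"covariate effect injection supports {sorted(binary)}, got {col!r}")
            logit = logit + log_or * binary[col]
        p_rp2 = 1.0 / (1.0 + np.exp(-logit))
    rp2 = (rng_out.random(n) < p_rp2).astype(int)

    return pd.DataFrame({
        "id": [f"P{i + 1:04d}" for i in range(n)],
        "age": age, "gender": gender, "smoking": smoking, "pathology": pathology,
        "stage": stage, "chemo": chemo, "surgery": surgery,
        "pgtv_volume_cm3": pgtv_volume, "ptv_volume_cm3": ptv_volume,
        "pgtv_rx_gy": pgtv_rx, "ptv_rx_gy": ptv_rx,
        "v5_lungptv": v5_ptv, "v20_lungptv": v20_ptv, "mld_lungptv": mld_ptv,
        "v5_lungpgtv": v5_pgtv, "v20_lungpgtv": v20_pgtv, "mld_lungpgtv": mld_pgtv,
        "v5_total": v5_total, "v20_total": v20_total, "mld_total": mld_total,
        "rp2": rp2,
    }, columns=COHORT_COLUMNS)
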
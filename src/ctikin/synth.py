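"""Synthetic contour-cine cohorts with known ground truth.

The generator emulates the statistical structure of a typical-flutter
ablation cohort — right-atrial contour cines plus linked clinical
covariates — so that every pipeline stage can be exercised against known
truth without patient data.

Geometry
--------
The baseline (diastolic) contour places the CTI as a shallow parabolic
pouch of configurable depth between the IVC critical point (the contour
midpoint, at the origin) and the TV hinge end, with the chord length
solved so that the CTI polyline length equals the drawn diastolic
curvilinear length; the non-CTI half of the RA wall is a circular arc
closing upwards from the IVC point.  The x axis is anterior-posterior,
the y axis caudo-cranial; the CTI chord lies along x, which reproduces
the anterior-posterior dominance of CTI motion.

Motion
------
Each point moves along a fixed per-point vector with a raised-cosine
phase profile over the cycle: zero at the first frame, exactly 1 at the
systolic frame ``F // 2``, back near zero at the cycle end (the cine is
cyclic).  The per-point vectors come from one of two modes:

* contraction mode (segment amplitudes ``None``): uniform scaling of the
  contour toward the IVC anchor by the patient's contraction ratio
  ``s`` at peak systole.  Polyline lengths scale exactly by ``s``, so
  the ground-truth normalized elongation is exactly ``1/s - 1``.
* amplitude mode (the default): the per-axis peak excursion of every
  CTI point is pinned to its segment's configured amplitude, directed
  away from the static IVC anchor (the TV side is stretched forward
  while the IVC side barely moves relative to its amplitude), so the
  configured five-segment anterior-posterior and caudo-cranial
  amplitude gradients are realized exactly in the noise-free cine.  In
  this mode frame 0 is the shortest (systolic) configuration — the
  ``base_cti_diastolic_mm`` draw sets the frame-0 baseline length —
  and elongation and NE are emergent, recorded in the ground truth
  after construction.  NE then covaries with the baseline length as in
  the cohort the generator emulates: shorter CTIs are relatively more
  compliant.

Patient heterogeneity enters as a multiplicative kinetic scale built
from the clinical covariates (smoking, dyslipidaemia, BMI, NYHA, age)
plus a lognormal idiosyncratic term, and an electrical-cardioversion
"stunning" attenuation for EC patients.  Kinetic scales are renormalized
to unit cohort mean so that configured segment amplitudes are calibrated
cohort means rather than per-patient constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import DegenerateInputError
from .geometry import compute_geometry
from .io import (
    ClinicalRecord,
    ContourCine,
    clinical_frame,
    default_cti_range,
    write_clinical_table,
    write_contour_table,
)
from .kinetics import partition_indices

#: Five-segment anterior-posterior maximum-displacement means (mm),
#: EV/IVC end to TV end.  Endpoints follow the segmental gradient the
#: generator is calibrated to (8.1 mm at segment 1, 17.2 mm at segment
#: 5); interior segments are linearly interpolated.
DEFAULT_SEGMENT_AP_MM = (8.1, 10.375, 12.65, 14.925, 17.2)
#: Caudo-cranial counterpart (1.6 mm to 4.5 mm).
DEFAULT_SEGMENT_CC_MM = (1.6, 2.325, 3.05, 3.775, 4.5)
#: NE group means of the low / intermediate / high compliance phenotypes.
DEFAULT_NE_GROUP_MEANS = (0.29, 0.72, 1.23)


@dataclass
class CovariateEffects:
    """Multiplicative (log-additive) covariate effects on the kinetic scale.

    Factors below 1 reduce wall motion.  Magnitudes are calibrated so
    that the cohort-level point-biserial correlations between NE and the
    binary covariates land near -0.3, the strength of association the
    generator is meant to emulate.
    """

    smoker_factor: float = 0.65
    dyslipidaemia_factor: float = 0.65
    bmi_slope_per_unit: float = -0.06      # log-scale, per kg/m^2 above 29
    age_slope_per_year: float = -0.008     # log-scale, per year above 66
    nyha_step: float = -0.05               # log-scale, per class above 1
    idiosyncratic_sd: float = 0.30         # lognormal sd of the residual scale

    def disabled(self) -> "CovariateEffects":
        return CovariateEffects(1.0, 1.0, 0.0, 0.0, 0.0, 0.0)


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic cohort.

    ``seed`` is mandatory: every draw flows from it.
    """

    seed: int
    n_patients: int = 32
    n_points: int = 49
    n_frames: int = 25

    # geometry draws (mean, sd) in mm
    base_cti_diastolic_mm: tuple[float, float] = (40.0, 11.4)
    pouch_depth_mm: tuple[float, float] = (3.2, 2.0)

    # contraction-mode ground truth: NE mixture, or one fixed ratio
    ne_group_means: tuple[float, ...] = DEFAULT_NE_GROUP_MEANS
    ne_group_sd: float = 0.12
    contraction_ratio: float | None = None

    # amplitude-mode ground truth (None switches to contraction mode)
    segment_ap_amplitude_mm: tuple[float, ...] | None = DEFAULT_SEGMENT_AP_MM
    segment_cc_amplitude_mm: tuple[float, ...] | None = DEFAULT_SEGMENT_CC_MM

    # cardioversion stunning and covariate structure
    ec_attenuation: float = 0.6
    p_ec: float = 0.47
    covariate_effects: CovariateEffects = field(default_factory=CovariateEffects)
    smoker_prevalence: float = 0.53
    dyslipidaemia_prevalence: float = 0.53
    bmi_mean_sd: tuple[float, float] = (29.0, 4.0)
    age_mean_sd: tuple[float, float] = (66.0, 10.0)
    nyha_probs: tuple[float, float, float, float] = (0.35, 0.40, 0.20, 0.05)
    procedural_time_mean_sd: tuple[float, float] = (44.8, 22.5)
    ablation_duration_mean_sd: tuple[float, float] = (18.9, 10.5)
    ec_procedural_shift_min: float = -12.0

    noise_sd_mm: float = 0.5
    heart_rate_bpm: float = 68.0
    #: renormalize kinetic scales to unit cohort mean, making configured
    #: amplitudes cohort-calibrated means
    normalize_kinetic_scale: bool = True

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("SyntheticConfig: seed is mandatory")
        if not (0.0 <= self.p_ec <= 1.0):
            raise ValueError("p_ec must be in [0, 1]")
        if not (0.0 < self.ec_attenuation <= 1.0):
            raise ValueError("ec_attenuation must be in (0, 1]")
        for amps in (self.segment_ap_amplitude_mm, self.segment_cc_amplitude_mm):
            if amps is not None and any(a < 0 for a in amps):
                raise ValueError("segment amplitudes must be >= 0")
        if self.contraction_ratio is not None and not (
            0.0 < self.contraction_ratio <= 1.0
        ):
            raise ValueError("contraction_ratio must be in (0, 1]")

    @property
    def frame_interval_s(self) -> float:
        return 60.0 / self.heart_rate_bpm / self.n_frames

    @property
    def amplitude_mode(self) -> bool:
        return (
            self.segment_ap_amplitude_mm is not None
            or self.segment_cc_amplitude_mm is not None
        )


@dataclass
class GroundTruth:
    """Per-patient generative truth, filled in during cine construction."""

    patient_id: str
    ec: bool
    smoker: bool
    dyslipidaemia: bool
    bmi: float
    nyha_class: int
    age: float
    procedural_time_min: float
    ablation_duration_min: float
    kinetic_scale: float                  # normalized m_i (includes attenuation)
    contraction_ratio: float
    base_diastolic_mm: float
    pouch_depth_mm: float
    seg_amp_ap_mm: tuple[float, ...] | None   # realized per-segment amplitudes
    seg_amp_cc_mm: tuple[float, ...] | None
    ne_true: float | None = None          # realized noise-free NE
    systole_frame: int | None = None
    diastole_frame: int | None = None

    def as_dict(self) -> dict:
        d = dict(self.__dict__)
        for key in ("seg_amp_ap_mm", "seg_amp_cc_mm"):
            v = d.pop(key)
            if v is not None:
                for i, a in enumerate(v, start=1):
                    d[f"{key[:-3]}{i}_mm"] = a
        return d


# ---------------------------------------------------------------------
# phase profile and baseline geometry
# ---------------------------------------------------------------------

def phase_profile(n_frames: int) -> np.ndarray:
    """Raised-cosine cycle profile: 0 at frame 0, exactly 1 at frame F//2.

    ``sin^2(pi n / F)`` normalized to peak 1 at the systolic frame; the
    virtual frame F coincides with frame 0, so the cine is cyclic.
    """
    n = np.arange(n_frames)
    raw = np.sin(np.pi * n / n_frames) ** 2
    return raw / np.sin(np.pi * (n_frames // 2) / n_frames) ** 2


def systole_frame_index(n_frames: int) -> int:
    return n_frames // 2


def _cti_polyline(chord: float, depth: float, n_pts: int) -> np.ndarray:
    """CTI points on a parabolic pouch from (0,0) to (chord,0), sag -y."""
    tau = np.linspace(0.0, 1.0, n_pts)
    x = chord * tau
    y = -depth * 4.0 * tau * (1.0 - tau)
    return np.column_stack([x, y])


def _polyline_length(pts: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def baseline_contour(
    diastolic_len: float,
    pouch: float,
    n_points: int,
    cti_index_range: tuple[int, int],
) -> np.ndarray:
    """Baseline (diastolic) RA contour, shape (P, 2), IVC point at origin.

    The chord of the parabolic CTI span is solved so that the CTI
    polyline length equals ``diastolic_len``.
    """
    start, stop = cti_index_range
    n_cti = stop - start
    pouch = min(pouch, diastolic_len / 5.0)   # keep the chord solvable

    def err(c: float) -> float:
        return _polyline_length(_cti_polyline(c, pouch, n_cti)) - diastolic_len

    chord = brentq(err, 1e-6, diastolic_len)
    cti = _cti_polyline(chord, pouch, n_cti)

    contour = np.empty((n_points, 2))
    contour[start:stop] = cti
    if start > 0:
        # circular arc closing the RA wall upward from the IVC point
        rho = 0.6 * diastolic_len
        steps = np.arange(start, 0, -1)       # distance to the IVC index
        beta = -np.pi / 2 - steps * (np.pi / start)
        contour[:start, 0] = rho * np.cos(beta)
        contour[:start, 1] = rho + rho * np.sin(beta)
    return contour


# ---------------------------------------------------------------------
# patient draws
# ---------------------------------------------------------------------

def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    for _ in range(100):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(np.clip(v, lo, hi))


def _kinetic_scale_raw(
    eff: CovariateEffects,
    smoker: bool,
    dyslipidaemia: bool,
    bmi: float,
    nyha: int,
    age: float,
    bmi_ref: float,
    age_ref: float,
    rng: np.random.Generator,
) -> float:
    log_m = (
        np.log(eff.smoker_factor) * smoker
        + np.log(eff.dyslipidaemia_factor) * dyslipidaemia
        + eff.bmi_slope_per_unit * (bmi - bmi_ref)
        + eff.age_slope_per_year * (age - age_ref)
        + eff.nyha_step * (nyha - 1)
    )
    if eff.idiosyncratic_sd > 0:
        log_m += rng.normal(0.0, eff.idiosyncratic_sd)
    return float(np.exp(log_m))


def draw_truths(cfg: SyntheticConfig, rng: np.random.Generator) -> list[GroundTruth]:
    """Draw per-patient covariates, geometry and kinetic scales."""
    eff = cfg.covariate_effects
    truths = []
    raw_scales = []
    for i in range(cfg.n_patients):
        smoker = bool(rng.random() < cfg.smoker_prevalence)
        dysl = bool(rng.random() < cfg.dyslipidaemia_prevalence)
        ec = bool(rng.random() < cfg.p_ec)
        bmi = _truncated_normal(rng, *cfg.bmi_mean_sd, 17.0, 50.0)
        age = _truncated_normal(rng, *cfg.age_mean_sd, 30.0, 95.0)
        nyha = int(rng.choice([1, 2, 3, 4], p=cfg.nyha_probs))
        base = _truncated_normal(rng, *cfg.base_cti_diastolic_mm, 18.0, 75.0)
        pouch = _truncated_normal(rng, *cfg.pouch_depth_mm, 0.5, 8.0)
        ptime = _truncated_normal(rng, *cfg.procedural_time_mean_sd, 10.0, 150.0)
        if ec:
            ptime = max(10.0, ptime + cfg.ec_procedural_shift_min)
        abdur = _truncated_normal(rng, *cfg.ablation_duration_mean_sd, 3.0, 70.0)
        if cfg.contraction_ratio is not None:
            ratio = cfg.contraction_ratio
        else:
            g = int(rng.integers(len(cfg.ne_group_means)))
            ne = max(0.05, rng.normal(cfg.ne_group_means[g], cfg.ne_group_sd))
            ratio = 1.0 / (1.0 + ne)
        m_raw = _kinetic_scale_raw(
            eff, smoker, dysl, bmi, nyha, age,
            cfg.bmi_mean_sd[0], cfg.age_mean_sd[0], rng,
        )
        m_raw *= cfg.ec_attenuation if ec else 1.0
        raw_scales.append(m_raw)
        truths.append(
            GroundTruth(
                patient_id=f"S{i:03d}",
                ec=ec,
                smoker=smoker,
                dyslipidaemia=dysl,
                bmi=bmi,
                nyha_class=nyha,
                age=age,
                procedural_time_min=ptime,
                ablation_duration_min=abdur,
                kinetic_scale=m_raw,
                contraction_ratio=ratio,
                base_diastolic_mm=base,
                pouch_depth_mm=pouch,
                seg_amp_ap_mm=None,
                seg_amp_cc_mm=None,
            )
        )
    if cfg.normalize_kinetic_scale and truths:
        mean_scale = float(np.mean(raw_scales))
        for t in truths:
            t.kinetic_scale /= mean_scale
    n_seg = 5
    for t in truths:
        if cfg.segment_ap_amplitude_mm is not None:
            t.seg_amp_ap_mm = tuple(
                t.kinetic_scale * a for a in cfg.segment_ap_amplitude_mm
            )
        if cfg.segment_cc_amplitude_mm is not None:
            t.seg_amp_cc_mm = tuple(
                t.kinetic_scale * a for a in cfg.segment_cc_amplitude_mm
            )
    return truths


def neutral_truth(
    cfg: SyntheticConfig,
    patient_id: str = "P0",
    contraction_ratio: float | None = None,
) -> GroundTruth:
    """A covariate-neutral patient (kinetic scale 1, no EC) at the
    configured mean geometry; the workhorse of exactness tests."""
    ratio = (
        contraction_ratio
        if contraction_ratio is not None
        else (cfg.contraction_ratio or 1.0)
    )
    return GroundTruth(
        patient_id=patient_id,
        ec=False,
        smoker=False,
        dyslipidaemia=False,
        bmi=cfg.bmi_mean_sd[0],
        nyha_class=1,
        age=cfg.age_mean_sd[0],
        procedural_time_min=cfg.procedural_time_mean_sd[0],
        ablation_duration_min=cfg.ablation_duration_mean_sd[0],
        kinetic_scale=1.0,
        contraction_ratio=ratio,
        base_diastolic_mm=cfg.base_cti_diastolic_mm[0],
        pouch_depth_mm=cfg.pouch_depth_mm[0],
        seg_amp_ap_mm=cfg.segment_ap_amplitude_mm,
        seg_amp_cc_mm=cfg.segment_cc_amplitude_mm,
    )


# ---------------------------------------------------------------------
# cine construction
# ---------------------------------------------------------------------

def generate_cine(
    cfg: SyntheticConfig,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> ContourCine:
    """Build one contour cine from a ground-truth draw.

    Fills ``truth.ne_true`` and the phase frames from the noise-free
    construction, then adds i.i.d. Gaussian coordinate noise.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    P, F = cfg.n_points, cfg.n_frames
    cti_range = default_cti_range(P)
    start, stop = cti_range
    base = baseline_contour(truth.base_diastolic_mm, truth.pouch_depth_mm, P, cti_range)
    anchor = base[start]
    phi = phase_profile(F)

    if truth.seg_amp_ap_mm is not None or truth.seg_amp_cc_mm is not None:
        # amplitude mode: pin per-axis peak excursions segment-wise.
        # Motion is directed away from the static IVC anchor (the TV side
        # is stretched forward), so frame 0 is the shortest (systolic)
        # configuration and the contour never folds over the anchor.
        away = base - anchor
        signs = np.where(away >= 0.0, 1.0, -1.0)    # (P, 2)
        signs[:, 1] = 1.0   # caudo-cranial motion is cranial for the whole wall
        peak = np.zeros_like(base)
        parts = partition_indices(np.arange(start, stop), 5)
        amp_ap = truth.seg_amp_ap_mm or (0.0,) * 5
        amp_cc = truth.seg_amp_cc_mm or (0.0,) * 5
        for k, seg_idx in enumerate(parts):
            peak[seg_idx, 0] = amp_ap[k]
            peak[seg_idx, 1] = amp_cc[k]
        # non-CTI wall points move like the EV-side segment
        peak[:start, 0] = amp_ap[0]
        peak[:start, 1] = amp_cc[0]
        v = signs * peak
        frames = base[None, :, :] + phi[:, None, None] * v[None, :, :]
    else:
        # contraction mode: uniform scaling toward the IVC anchor
        ne_eff = (1.0 / truth.contraction_ratio - 1.0) * truth.kinetic_scale
        ratio_eff = 1.0 / (1.0 + ne_eff)
        lam = 1.0 - (1.0 - ratio_eff) * phi         # (F,)
        frames = anchor[None, None, :] + lam[:, None, None] * (
            base[None, :, :] - anchor[None, None, :]
        )

    clean = ContourCine(
        patient_id=truth.patient_id,
        frames=frames,
        cti_index_range=cti_range,
        frame_interval=cfg.frame_interval_s,
    )
    geo = compute_geometry(clean)
    truth.ne_true = geo.ne
    truth.systole_frame = geo.systole_frame
    truth.diastole_frame = geo.diastole_frame

    if cfg.noise_sd_mm > 0:
        frames = frames + rng.normal(0.0, cfg.noise_sd_mm, size=frames.shape)
    return ContourCine(
        patient_id=truth.patient_id,
        frames=frames,
        cti_index_range=cti_range,
        frame_interval=cfg.frame_interval_s,
    )


# ---------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------

@dataclass
class CohortData:
    cines: list[ContourCine]
    clinical: list[ClinicalRecord]
    truths: list[GroundTruth]

    @property
    def clinical_table(self) -> pd.DataFrame:
        return clinical_frame(self.clinical)

    @property
    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame([t.as_dict() for t in self.truths]).set_index(
            "patient_id"
        )


def generate_cohort(cfg: SyntheticConfig, out_dir: str | Path | None = None) -> CohortData:
    """Draw a full cohort; optionally write contours/clinical/truth CSVs.

    Fully reproducible: two calls with the same config produce identical
    cohorts.
    """
    rng = np.random.default_rng(cfg.seed)
    truths = draw_truths(cfg, rng)
    cines = [generate_cine(cfg, t, rng) for t in truths]
    clinical = [
        ClinicalRecord(
            patient_id=t.patient_id,
            ec_within_12h=t.ec,
            smoker=t.smoker,
            dyslipidaemia=t.dyslipidaemia,
            bmi=t.bmi,
            nyha_class=t.nyha_class,
            age=t.age,
            procedural_time_min=t.procedural_time_min,
            ablation_duration_min=t.ablation_duration_min,
        )
        for t in truths
    ]
    data = CohortData(cines=cines, clinical=clinical, truths=truths)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_contour_table(cines, out / "contours.csv")
        write_clinical_table(clinical, out / "clinical.csv")
        data.truth_table.to_csv(out / "truth.csv")
    return data


def sample_ne_groups(
    seed: int,
    group_means: Sequence[float] = DEFAULT_NE_GROUP_MEANS,
    group_sd: float = 0.12,
    group_sizes: Sequence[int] = (10, 10, 11),
    outliers: Sequence[float] = (),
) -> pd.Series:
    """Draw patient NE values from labelled Gaussian compliance groups.

    Returns a Series indexed by synthetic patient ids of the form
    ``g{group}_{i}`` (and ``outlier_{i}`` for appended outlier values);
    the index therefore encodes the generating group.
    """
    if len(group_means) != len(group_sizes):
        raise ValueError("group_means and group_sizes must align")
    rng = np.random.default_rng(seed)
    vals: dict[str, float] = {}
    for g, (mu, n) in enumerate(zip(group_means, group_sizes), start=1):
        for i in range(n):
            vals[f"g{g}_{i:02d}"] = float(rng.normal(mu, group_sd))
    for i, v in enumerate(outliers, start=1):
        vals[f"outlier_{i}"] = float(v)
    return pd.Series(vals, name="ne")
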
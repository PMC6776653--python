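"""Synthetic PET cohort generator.

Generates a fully synthetic patient/control cohort with the statistical
structure the downstream analysis assumes:

* regional BP_ND baselines at carfentanil-like scales (striatal regions near
  1.5-2.5, cortex near 1, a near-zero reference region),
* an additive group shift on the striatal / hedonic-network regions so that
  the striatal mean differs between groups by a configurable amount,
* a shared per-subject latent factor whose loading differs by group, which
  raises inter-regional BP_ND covariance in the patient group,
* per-subject time-activity curves obtained by pushing the regional BP_ND
  values through the SRTM forward model against a gamma-variate reference
  template, with count-statistics-like heteroscedastic noise,
* Table-style covariates (age, BMI, cigarettes/day, anhedonia scores) drawn
  from group-specific distributions, independent of BP_ND by default.

Everything is seeded and reproducible: an identical :class:`CohortSpec`
yields byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import RegionAtlas
from .kinetics import FrameSchedule, SRTMParams, TimeActivityCurve, srtm_forward, _fine_times, _frame_average

__all__ = [
    "CohortSpec",
    "SubjectRecord",
    "default_baselines",
    "simulate_bpnd",
    "simulate_covariates",
    "simulate_subject_tacs",
    "simulate_cohort_tacs",
    "bpnd_frame",
    "subjects_frame",
]

# canonical control-group baselines for the named regions (BP_ND units);
# dorsal/ventral striatum are rescaled so the striatal mean matches the spec
_NAMED_BASELINES = {
    "caudate": 1.53,
    "putamen": 1.53,
    "ventral_striatum": 2.69,
    "orbitofrontal": 1.05,
    "cingulate": 0.95,
    "insula": 1.00,
    "midbrain": 1.25,
    "amygdala": 1.60,
    "thalamus": 1.50,
    "hippocampus": 0.90,
    "cerebellum_ant": 0.45,
    "cerebellum_post": 0.45,
    "brainstem": 0.80,
}
_REFERENCE_BASELINE = 0.02  # occipital: negligible specific binding


@dataclass
class CohortSpec:
    """Study-condition knobs for the synthetic cohort.

    ``striatal_means`` is the (patient, control) pair of striatal-mean BP_ND
    targets; their difference is applied as an additive shift to the
    striatal/hedonic regions of the patient group.  ``covariance_strength``
    holds the (patient, control) loadings of the shared latent factor that
    creates inter-regional covariance; a larger patient loading reproduces
    the elevated patient-group covariance the analysis is designed to detect.
    ``covariance_regions`` optionally restricts the latent factor to a named
    subset of regions (block-structured covariance).
    """

    n_patients: int = 19
    n_controls: int = 20
    striatal_means: tuple[float, float] = (1.54, 1.70)
    between_subject_sd: float = 0.45
    covariance_strength: tuple[float, float] = (0.5, 0.2)
    tac_noise_level: float = 0.05
    seed: int = 0
    covariance_regions: tuple[str, ...] | None = None
    ref_peak_kbq_ml: float = 20.0
    ref_peak_time_min: float = 5.0
    covariate_bpnd_corr: float = 0.0
    r1: float = 1.0
    k2: float = 0.1  # 1/min

    def validate(self) -> None:
        if self.n_patients < 2 or self.n_controls < 2:
            raise ValueError("group sizes must be >= 2")
        if self.between_subject_sd < 0 or self.tac_noise_level < 0:
            raise ValueError("noise scales must be non-negative")
        for lam in self.covariance_strength:
            if not (0.0 <= lam < 1.0):
                raise ValueError("covariance_strength loadings must lie in [0, 1)")
        if not (-1.0 < self.covariate_bpnd_corr < 1.0):
            raise ValueError("covariate_bpnd_corr must lie in (-1, 1)")


@dataclass
class SubjectRecord:
    subject_id: str
    group: str  # "patient" | "control"
    regional_bpnd: pd.Series  # indexed by analysis region name
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.group not in ("patient", "control"):
            raise ValueError(f"group must be 'patient' or 'control', got {self.group!r}")
        if not np.all(np.isfinite(self.regional_bpnd.to_numpy())):
            raise ValueError("regional BP_ND values must be finite")


def default_baselines(atlas: RegionAtlas, control_striatal_mean: float = 1.70) -> pd.Series:
    """Control-group baseline BP_ND per analysis region.

    Striatal baselines keep the canonical dorsal:ventral ratio but are scaled
    so their mean equals ``control_striatal_mean``.  Unnamed filler parcels
    receive deterministic values spread over [0.4, 1.4] via a golden-ratio
    low-discrepancy sequence, emulating cortical heterogeneity.
    """
    striatum = atlas.subsets["striatum"]
    raw_striatal = np.array([_NAMED_BASELINES[r] for r in striatum])
    scale = control_striatal_mean / raw_striatal.mean()
    out = {}
    for i, region in enumerate(atlas.region_names):
        if region in striatum:
            out[region] = _NAMED_BASELINES[region] * scale
        elif region in _NAMED_BASELINES:
            out[region] = _NAMED_BASELINES[region]
        else:
            out[region] = 0.4 + ((i * 0.6180339887498949) % 1.0)
    return pd.Series(out, name="baseline_bpnd").reindex(atlas.region_names)


def simulate_bpnd(spec: CohortSpec, atlas: RegionAtlas) -> list[SubjectRecord]:
    """Draw per-subject regional BP_ND vectors.

    Model per subject s, region r::

        bp[s, r] = baseline[r] + shift * 1[patient, r in hedonic+striatum]
                   + sd * (lam_g * u_s + sqrt(1 - lam_g^2) * eps[s, r])

    with ``u_s ~ N(0,1)`` shared across (factor) regions and independent
    ``eps``.  The marginal between-subject SD is ``sd`` for every region; the
    inter-regional correlation among factor regions is ``lam_g**2``.
    """
    spec.validate()
    rng = np.random.default_rng([int(spec.seed), 0])
    regions = atlas.region_names
    base = default_baselines(atlas, control_striatal_mean=spec.striatal_means[1]).to_numpy()
    shift = spec.striatal_means[0] - spec.striatal_means[1]
    shifted = set(atlas.subsets["hedonic_network"]) | set(atlas.subsets["striatum"])
    shift_mask = np.array([r in shifted for r in regions], dtype=float)
    if spec.covariance_regions is None:
        factor_mask = np.ones(len(regions), dtype=bool)
    else:
        unknown = set(spec.covariance_regions) - set(regions)
        if unknown:
            raise ValueError(f"covariance_regions not in atlas: {sorted(unknown)}")
        factor_mask = np.array([r in set(spec.covariance_regions) for r in regions])

    records: list[SubjectRecord] = []
    groups = [("patient", spec.n_patients, spec.covariance_strength[0], "P"),
              ("control", spec.n_controls, spec.covariance_strength[1], "C")]
    for group, n, lam, prefix in groups:
        for i in range(n):
            u = rng.standard_normal()
            eps = rng.standard_normal(len(regions))
            dev = np.where(factor_mask,
                           lam * u + np.sqrt(1.0 - lam**2) * eps,
                           eps)
            values = base + (shift * shift_mask if group == "patient" else 0.0) \
                + spec.between_subject_sd * dev
            records.append(SubjectRecord(
                subject_id=f"{prefix}{i + 1:02d}",
                group=group,
                regional_bpnd=pd.Series(values, index=regions),
            ))
    return records


# Table-scale covariate model: (patient mean, patient sd, control mean, control sd)
_COVARIATE_MODEL = {
    "age_years": (35.1, 9.2, 36.85, 12.1),
    "bmi_kg_m2": (29.3, 4.4, 25.2, 3.6),
    "social_anhedonia": (17.6, 8.3, 9.8, 7.6),
    "physical_anhedonia": (23.3, 12.2, 13.3, 13.4),
}
# cigarettes/day: zero-inflated gamma -> (smoker prob, mean among smokers)
_SMOKING_MODEL = {"patient": (0.55, 15.0), "control": (0.15, 6.0)}


def simulate_covariates(records: list[SubjectRecord], spec: CohortSpec,
                        atlas: RegionAtlas | None = None,
                        rng: np.random.Generator | None = None) -> list[SubjectRecord]:
    """Attach demographic/clinical covariates to the records (in place).

    Gaussian covariates at the configured group scales (non-negative scores
    clipped at zero); cigarettes/day are zero-inflated gamma.  By default
    covariates are independent of BP_ND; ``spec.covariate_bpnd_corr`` mixes
    the subject's standardised striatal deviation into the Gaussian draws.
    """
    spec.validate()
    if rng is None:
        rng = np.random.default_rng([int(spec.seed), 1])
    rho = spec.covariate_bpnd_corr
    # standardised striatal deviation per subject for the optional coupling
    striatal_regions = atlas.subsets["striatum"] if atlas is not None else None
    vals = np.array([
        rec.regional_bpnd.loc[striatal_regions].mean() if striatal_regions is not None
        else rec.regional_bpnd.mean()
        for rec in records
    ])
    zstriat = (vals - vals.mean()) / (vals.std() if vals.std() > 0 else 1.0)
    for rec, zs in zip(records, zstriat):
        g = rec.group
        for name, (mp, sp, mc, sc) in _COVARIATE_MODEL.items():
            mu, sd = (mp, sp) if g == "patient" else (mc, sc)
            z = rho * zs + np.sqrt(1.0 - rho**2) * rng.standard_normal()
            val = mu + sd * z
            if name != "age_years":
                val = max(val, 0.0)
            rec.covariates[name] = float(val)
        p_smoke, mean_cigs = _SMOKING_MODEL[g]
        if rng.uniform() < p_smoke:
            rec.covariates["cigarettes_per_day"] = float(rng.gamma(2.0, mean_cigs / 2.0))
        else:
            rec.covariates["cigarettes_per_day"] = 0.0
    return records


def _reference_template(spec: CohortSpec, schedule: FrameSchedule) -> np.ndarray:
    """Frame-averaged gamma-variate reference TAC (smooth rise, slow washout)."""

    def gv(t_min, tp, alpha):
        x = np.clip(t_min / tp, 0.0, None)
        return np.where(t_min > 0, x**alpha * np.exp(alpha * (1.0 - x)), 0.0)

    t_fine = _fine_times(schedule)
    t_min = t_fine / 60.0
    tp = spec.ref_peak_time_min
    curve = spec.ref_peak_kbq_ml * (0.75 * gv(t_min, tp, 3.0) + 0.25 * gv(t_min, 5.0 * tp, 1.5))
    return _frame_average(curve, t_fine, schedule)


def simulate_subject_tacs(record: SubjectRecord, spec: CohortSpec,
                          schedule: FrameSchedule, seed: int) -> dict[str, TimeActivityCurve]:
    """Regional TACs for one subject, including the reference region.

    The reference TAC is a frame-averaged gamma-variate template; each
    analysis region's TAC is the SRTM forward model of the subject's regional
    BP_ND against that reference.  Gaussian noise with variance proportional
    to activity / frame duration is added to every curve (including the
    reference) at ``spec.tac_noise_level``; a level of 0 gives noiseless
    curves that refit exactly.
    """
    rng = np.random.default_rng(seed)
    ref_vals = _reference_template(spec, schedule)
    ref = TimeActivityCurve(schedule, ref_vals, region_id="reference",
                            subject_id=record.subject_id)
    out: dict[str, TimeActivityCurve] = {}

    def noisy(values: np.ndarray) -> np.ndarray:
        if spec.tac_noise_level == 0:
            return values.copy()
        sd = spec.tac_noise_level * np.sqrt(
            np.clip(values, 0.0, None) * 60.0 / schedule.frame_durations)
        return values + sd * rng.standard_normal(values.size)

    for region, bp in record.regional_bpnd.items():
        bp_eff = max(float(bp), -0.9)  # forward model requires BP_ND > -1
        params = SRTMParams(r1=spec.r1, k2=spec.k2, bp_nd=bp_eff)
        model = srtm_forward(params, ref)
        out[region] = TimeActivityCurve(schedule, noisy(model.values),
                                        region_id=region, subject_id=record.subject_id)
    # reference region ships as its own (noisy) TAC column
    out["occipital"] = TimeActivityCurve(schedule, noisy(ref_vals),
                                         region_id="occipital", subject_id=record.subject_id)
    return out


def simulate_cohort_tacs(records: list[SubjectRecord], spec: CohortSpec,
                         schedule: FrameSchedule) -> dict[str, dict[str, TimeActivityCurve]]:
    """TACs for every subject; per-subject seeds derived deterministically."""
    out = {}
    for i, rec in enumerate(records):
        sub_seed = np.random.SeedSequence([int(spec.seed), 2, i]).generate_state(1)[0] % (2**31)
        out[rec.subject_id] = simulate_subject_tacs(rec, spec, schedule, int(sub_seed))
    return out


def bpnd_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    """Subjects x regions BP_ND matrix."""
    return pd.DataFrame({r.subject_id: r.regional_bpnd for r in records}).T


def subjects_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    """Subject table: id, group, covariates."""
    rows = []
    for r in records:
        row = {"subject_id": r.subject_id, "group": r.group}
        row.update(r.covariates)
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject_id")
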
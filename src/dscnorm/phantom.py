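"""Forward signal model and synthetic cohort generator for DSC-MRI perfusion.

The generator emulates the statistical structure of a bolus-tracking
perfusion study comparing healthy elderly controls, patients with stable
mild cognitive impairment (MCI) and patients with mild Alzheimer's disease
(AD):

* gamma-variate first-pass bolus curves sampled on the scanner's frame grid
  (gradient-echo EPI, TR = 1.439 s, TE = 30 ms, 40 frames, 6 pre-bolus
  baseline frames);
* per-region ground-truth cerebral blood flow (CBF, relative units);
* one lognormal multiplicative *global perfusion factor* per subject — the
  dominant source of between-subject variability that reference-region
  intensity normalization is meant to cancel (CV around 40-50%);
* smaller independent lognormal *regional* fluctuations per region;
* group-specific regional effects: parietal hypoperfusion and relative
  right-medial-temporal hyperperfusion in the AD group, no effect in MCI.

Voxel time series are produced by the standard single-compartment tracer
kinetic model: tissue concentration C(t) = CBF * (AIF (*) R)(t), where R is
the residue function, followed by the T2*-signal model
S(t) = S0 * exp(-TE * C(t) / k) plus Gaussian scanner noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ParameterError

__all__ = [
    "AcquisitionParams",
    "GammaVariateParams",
    "TissueSpec",
    "CohortSpec",
    "SubjectDataset",
    "gamma_variate",
    "residue_function",
    "tissue_concentration",
    "concentration_to_signal",
    "build_label_geometry",
    "generate_subject",
    "generate_cohort",
    "simulate_roi_tables",
    "default_tissue_specs",
    "default_cohort_spec",
    "DEFAULT_AIF",
    "DEFAULT_GROUP_EFFECTS",
    "CORTICAL_LOBES",
]

CONTROL = "control"
MCI = "MCI"
AD = "AD"

CORTICAL_LOBES = ("frontal", "parietal", "temporal_lateral", "temporal_medial", "occipital")


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class AcquisitionParams:
    """Scanner timing constants of the bolus-tracking acquisition.

    Parameters
    ----------
    tr : float
        Repetition time (frame spacing) in seconds.
    te : float
        Echo time in seconds; sets the concentration-to-signal-drop scale.
    n_frames : int
        Number of dynamic frames acquired during bolus passage.
    n_baseline : int
        Number of pre-bolus frames used to estimate the baseline signal S0.
    k : float
        Proportionality constant of the concentration equation
        C = -(k / te) * ln(S / S0).  With k = 1 CBF is reported in relative
        units; absolute calibration is out of scope.
    """

    tr: float = 1.439
    te: float = 0.030
    n_frames: int = 40
    n_baseline: int = 6
    k: float = 1.0

    def __post_init__(self) -> None:
        if not (self.tr > 0 and self.te > 0 and self.k > 0):
            raise ParameterError("tr, te and k must be positive")
        if not (self.n_frames > self.n_baseline >= 1):
            raise ParameterError("need n_frames > n_baseline >= 1")

    @property
    def time(self) -> np.ndarray:
        """Frame-center time grid in seconds, starting at 0."""
        return np.arange(self.n_frames) * self.tr


@dataclass(frozen=True)
class GammaVariateParams:
    """Parameters of the gamma-variate bolus model
    C(t) = K * (t - t0)**alpha * exp(-(t - t0) / beta) for t > t0, else 0."""

    amplitude: float
    alpha: float
    beta: float
    t0: float

    def __post_init__(self) -> None:
        vals = (self.amplitude, self.alpha, self.beta, self.t0)
        if not all(math.isfinite(v) for v in vals):
            raise ParameterError("gamma-variate parameters must be finite")
        if not (self.amplitude > 0 and self.alpha > 0 and self.beta > 0 and self.t0 >= 0):
            raise ParameterError("require K > 0, alpha > 0, beta > 0, t0 >= 0")

    @property
    def peak_time(self) -> float:
        """Time of the curve maximum, t0 + alpha * beta."""
        return self.t0 + self.alpha * self.beta

    @property
    def peak_value(self) -> float:
        return self.amplitude * (self.alpha * self.beta) ** self.alpha * math.exp(-self.alpha)


@dataclass(frozen=True)
class TissueSpec:
    """Ground-truth description of one labelled region of the phantom."""

    roi_label: int
    roi_name: str
    lobe: str
    hemisphere: str
    tissue_class: str  # cortical_gm | wm | cerebellum | artery
    true_cbf: float
    mtt: float
    residue_model: str = "exponential"
    baseline_s0: float = 100.0

    def __post_init__(self) -> None:
        if self.true_cbf < 0:
            raise ParameterError(f"{self.roi_name}: true_cbf must be >= 0")
        if self.mtt <= 0:
            raise ParameterError(f"{self.roi_name}: mtt must be > 0")
        if self.baseline_s0 <= 0:
            raise ParameterError(f"{self.roi_name}: baseline_s0 must be > 0")


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a simulated cohort.

    Group effects are encoded as per-region multiplicative factors applied on
    top of the shared base tissue specs, so the region label sets are
    identical across groups by construction.
    """

    group_sizes: Mapping[str, int]
    tissue_specs: Sequence[TissueSpec]
    aif_params: GammaVariateParams
    group_effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    acq: AcquisitionParams = field(default_factory=AcquisitionParams)
    global_cv: float = 45.0  # percent
    regional_cv: float = 6.0  # percent
    signal_noise_sd: float = 0.01  # fraction of the regional baseline S0
    flow_scale: float = 0.2  # relative CBF units -> 1/s in the kinetic model
    age_mean: float = 73.0
    age_sd: float = 7.0
    age_min: float = 60.0
    bolus_delay: float = 2.0  # arterial-to-tissue arrival delay, seconds
    shape: tuple[int, int, int] = (32, 32, 8)
    seed: int = 0
    control_group: str = CONTROL

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.group_sizes.values()):
            raise ConfigurationError("group sizes must be >= 0")
        if self.global_cv < 0 or self.regional_cv < 0 or self.signal_noise_sd < 0:
            raise ConfigurationError("noise levels must be >= 0")
        names = [s.roi_name for s in self.tissue_specs]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate region names in tissue_specs")
        for group, effects in self.group_effects.items():
            unknown = set(effects) - set(names)
            if unknown:
                raise ConfigurationError(f"group {group!r}: effects on unknown regions {sorted(unknown)}")

    def effect_multiplier(self, group: str, roi_name: str) -> float:
        return float(self.group_effects.get(group, {}).get(roi_name, 1.0))

    @property
    def n_subjects(self) -> int:
        return int(sum(self.group_sizes.values()))


@dataclass
class SubjectDataset:
    """One simulated subject: 4D signal, label volume, lookup and truth."""

    signal: np.ndarray  # (x, y, z, frame)
    labels: np.ndarray  # (x, y, z) int
    lookup: pd.DataFrame  # label, name, lobe, hemisphere, tissue_class
    truth: pd.DataFrame  # roi_name, base_cbf, group_multiplier, global_factor, regional_factor, true_cbf
    group: str
    age: float
    subject_id: str


# ---------------------------------------------------------------------------
# forward model


def gamma_variate(t: np.ndarray, params: GammaVariateParams) -> np.ndarray:
    """Evaluate the gamma-variate bolus curve on time grid ``t``.

    Zero for t <= t0; unimodal with maximum at t0 + alpha * beta.
    """
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or np.any(np.diff(t) < 0) or np.any(t < 0):
        raise ParameterError("t must be a sorted, nonnegative 1-D grid")
    dt = t - params.t0
    out = np.zeros_like(t)
    pos = dt > 0
    out[pos] = params.amplitude * dt[pos] ** params.alpha * np.exp(-dt[pos] / params.beta)
    return out


def residue_function(t: np.ndarray, mtt: float, model: str = "exponential") -> np.ndarray:
    """Residue function R(t): fraction of tracer still in tissue at lag t.

    R(0) = 1 and R is nonincreasing; the integral of R equals the mean
    transit time for both supported models.
    """
    if mtt <= 0:
        raise ParameterError("mtt must be > 0")
    t = np.asarray(t, dtype=float)
    if model == "exponential":
        return np.exp(-t / mtt)
    if model == "boxcar":
        return (t < mtt).astype(float)
    raise ParameterError(f"unknown residue model {model!r}")


def tissue_concentration(
    aif_c: np.ndarray,
    cbf: float,
    mtt: float,
    tr: float,
    residue_model: str = "exponential",
) -> np.ndarray:
    """Tissue concentration CBF * (AIF (*) R) by discrete convolution.

    ``aif_c`` must be sampled on a uniform grid with step ``tr``; the output
    shares that grid.
    """
    if cbf < 0:
        raise ParameterError("cbf must be >= 0")
    aif_c = np.asarray(aif_c, dtype=float)
    n = aif_c.size
    r = residue_function(np.arange(n) * tr, mtt, residue_model)
    return cbf * tr * np.convolve(aif_c, r)[:n]


def concentration_to_signal(c: np.ndarray, s0: float, acq: AcquisitionParams) -> np.ndarray:
    """T2*-weighted signal S = S0 * exp(-TE * C / k); S = S0 where C = 0."""
    if s0 <= 0:
        raise ParameterError("s0 must be > 0")
    return s0 * np.exp(-acq.te * np.asarray(c, dtype=float) / acq.k)


# ---------------------------------------------------------------------------
# cohort defaults

# Base CBF values in relative units, chosen so that whole-brain cortical GM,
# cerebellum and white matter sit at the ~0.11 / 0.30 / 0.07 scale of the
# study population, with mild heterogeneity between lobes.
_BASE_CBF = {
    "frontal": 0.115,
    "parietal": 0.112,
    "temporal_lateral": 0.110,
    "temporal_medial": 0.105,
    "occipital": 0.108,
}

# AD group: bilateral parietal hypoperfusion (-15%) and relative right
# medial-temporal hyperperfusion (+12%); no stable-MCI effect.
DEFAULT_GROUP_EFFECTS: dict[str, dict[str, float]] = {
    AD: {
        "parietal_lh": 0.85,
        "parietal_rh": 0.85,
        "temporal_medial_rh": 1.12,
    },
    MCI: {},
}

# Amplitude sets the bolus depth: with k = 1 and TE = 30 ms this yields a
# peak first-pass signal drop of roughly 25% in cortical gray matter and a
# deep (>90%) drop in the artery, typical of 1.5 T bolus tracking.
DEFAULT_AIF = GammaVariateParams(amplitude=25.0, alpha=3.0, beta=1.5, t0=10.0)


def default_tissue_specs(baseline_s0: float = 100.0) -> list[TissueSpec]:
    """One region per (cortical lobe, hemisphere) plus cerebellum, whole-brain
    WM and an arterial region: the smallest layout exercising the full ROI
    logic of the analysis."""
    specs: list[TissueSpec] = []
    label = 1
    for lobe in CORTICAL_LOBES:
        for hemi in ("lh", "rh"):
            specs.append(
                TissueSpec(
                    roi_label=label,
                    roi_name=f"{lobe}_{hemi}",
                    lobe=lobe,
                    hemisphere=hemi,
                    tissue_class="cortical_gm",
                    true_cbf=_BASE_CBF[lobe],
                    mtt=4.0,
                    baseline_s0=baseline_s0,
                )
            )
            label += 1
    specs.append(
        TissueSpec(label, "cerebellum", "cerebellum", "both", "cerebellum", 0.30, 4.0, baseline_s0=baseline_s0)
    )
    label += 1
    specs.append(TissueSpec(label, "wm", "wm", "both", "wm", 0.07, 6.0, baseline_s0=baseline_s0))
    label += 1
    specs.append(TissueSpec(label, "artery", "artery", "both", "artery", 1.0, 1.0, baseline_s0=baseline_s0))
    return specs


def default_cohort_spec(seed: int = 0, **overrides) -> CohortSpec:
    """Study-sized cohort: 20 controls, 15 stable MCI, 28 mild AD."""
    kwargs = dict(
        group_sizes={CONTROL: 20, MCI: 15, AD: 28},
        tissue_specs=default_tissue_specs(),
        aif_params=DEFAULT_AIF,
        group_effects=DEFAULT_GROUP_EFFECTS,
        seed=seed,
    )
    kwargs.update(overrides)
    return CohortSpec(**kwargs)


# ---------------------------------------------------------------------------
# geometry


def lookup_table(specs: Sequence[TissueSpec]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "label": [s.roi_label for s in specs],
            "name": [s.roi_name for s in specs],
            "lobe": [s.lobe for s in specs],
            "hemisphere": [s.hemisphere for s in specs],
            "tissue_class": [s.tissue_class for s in specs],
        }
    )


def build_label_geometry(specs: Sequence[TissueSpec], shape: tuple[int, int, int]) -> np.ndarray:
    """Parameterized block layout: one rectangular x-y block per region,
    extended through the full slab depth.  Label 0 is background."""
    n = len(specs)
    if n == 0:
        raise ConfigurationError("no tissue specs: empty ROI geometry")
    gx = int(math.ceil(math.sqrt(n)))
    gy = int(math.ceil(n / gx))
    bx, by = shape[0] // gx, shape[1] // gy
    if bx < 1 or by < 1 or shape[2] < 1:
        raise ConfigurationError(f"shape {shape} too small for {n} regions")
    labels = np.zeros(shape, dtype=np.int32)
    for i, spec in enumerate(specs):
        ix, iy = divmod(i, gy)
        labels[ix * bx : (ix + 1) * bx, iy * by : (iy + 1) * by, :] = spec.roi_label
    return labels


# ---------------------------------------------------------------------------
# subject / cohort generation


def _lognormal_factor(rng: np.random.Generator, cv_percent: float, size=None):
    """Multiplicative factor with mean 1 and exact coefficient of variation
    cv_percent (lognormal parameterization)."""
    c = cv_percent / 100.0
    if c == 0:
        return np.ones(size) if size is not None else 1.0
    sigma2 = math.log1p(c * c)
    mu = -sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=size)


def _draw_subject_factors(spec: CohortSpec, rng: np.random.Generator):
    """Draw (age, global factor, per-region regional factors) for one subject.

    Shared by the voxel-level generator and the ROI-level simulator so both
    produce identical ground truth for identical random streams.
    """
    age = float(rng.normal(spec.age_mean, spec.age_sd))
    while age < spec.age_min:
        age = float(rng.normal(spec.age_mean, spec.age_sd))
    global_f = float(_lognormal_factor(rng, spec.global_cv))
    regional = {}
    for ts in spec.tissue_specs:
        if ts.tissue_class == "artery":
            continue
        regional[ts.roi_name] = float(_lognormal_factor(rng, spec.regional_cv))
    return age, global_f, regional


def _subject_truth(spec: CohortSpec, group: str, global_f: float, regional: Mapping[str, float]) -> pd.DataFrame:
    rows = []
    for ts in spec.tissue_specs:
        if ts.tissue_class == "artery":
            continue
        mult = spec.effect_multiplier(group, ts.roi_name)
        reg = regional[ts.roi_name]
        rows.append(
            {
                "roi_name": ts.roi_name,
                "base_cbf": ts.true_cbf,
                "group_multiplier": mult,
                "global_factor": global_f,
                "regional_factor": reg,
                "true_cbf": ts.true_cbf * mult * global_f * reg,
            }
        )
    return pd.DataFrame(rows)


def generate_subject(spec: CohortSpec, group: str, seed, subject_id: str = "sub-000") -> SubjectDataset:
    """Simulate one subject's 4D bolus-passage signal volume.

    The arterial region carries the input function itself (arriving
    ``bolus_delay`` seconds before the tissue bolus and with a several-fold
    higher peak, as in a real feeding artery); tissue regions follow the
    convolution model with their effective CBF, which is the product of the
    base value, the group effect, the subject's global perfusion factor and
    the regional fluctuation.  All drawn factors are recorded in ``truth``.
    """
    if group not in spec.group_sizes:
        raise ConfigurationError(f"unknown group {group!r}")
    rng = np.random.default_rng(seed)
    acq = spec.acq
    t = acq.time
    labels = build_label_geometry(spec.tissue_specs, spec.shape)
    lookup = lookup_table(spec.tissue_specs)

    age, global_f, regional = _draw_subject_factors(spec, rng)

    aif_c = gamma_variate(t, spec.aif_params)
    tissue_input = gamma_variate(t, replace(spec.aif_params, t0=spec.aif_params.t0 + spec.bolus_delay))

    signal = np.zeros(spec.shape + (acq.n_frames,), dtype=float)
    noise_sd = np.zeros(spec.shape, dtype=float)
    for ts in spec.tissue_specs:
        mask = labels == ts.roi_label
        if not mask.any():
            raise ConfigurationError(f"region {ts.roi_name} has no voxels")
        if ts.tissue_class == "artery":
            c = aif_c
        else:
            eff_cbf = ts.true_cbf * spec.effect_multiplier(group, ts.roi_name) * global_f * regional[ts.roi_name]
            # flow_scale converts the table-scale relative CBF units into
            # 1/s for the kinetic model, keeping tissue blood volumes and
            # signal drops in a physiological range (artery stays brightest)
            c = tissue_concentration(tissue_input, eff_cbf * spec.flow_scale, ts.mtt, acq.tr, ts.residue_model)
        signal[mask] = concentration_to_signal(c, ts.baseline_s0, acq)
        noise_sd[mask] = spec.signal_noise_sd * ts.baseline_s0

    if spec.signal_noise_sd > 0:
        signal += rng.normal(0.0, 1.0, size=signal.shape) * noise_sd[..., None]
        np.maximum(signal, 1e-6, out=signal)

    truth = _subject_truth(spec, group, global_f, regional)
    return SubjectDataset(signal, labels, lookup, truth, group, age, subject_id)


def subject_seed(cohort_seed: int, index: int) -> int:
    """Deterministic per-subject seed derived from the cohort seed."""
    ss = np.random.SeedSequence([int(cohort_seed), int(index)])
    return int(ss.generate_state(1, np.uint64)[0] % (2**31))


def _iter_cohort(spec: CohortSpec):
    idx = 0
    for group in spec.group_sizes:
        for _ in range(int(spec.group_sizes[group])):
            yield idx, group, f"sub-{idx:03d}", subject_seed(spec.seed, idx)
            idx += 1


def generate_cohort(spec: CohortSpec) -> tuple[list[SubjectDataset], pd.DataFrame]:
    """Generate all subjects of the cohort plus a manifest table
    (subject_id, group, age, seed).  Fully determined by ``spec.seed``."""
    subjects: list[SubjectDataset] = []
    rows = []
    for _, group, sid, sseed in _iter_cohort(spec):
        subj = generate_subject(spec, group, sseed, subject_id=sid)
        subjects.append(subj)
        rows.append({"subject_id": sid, "group": group, "age": subj.age, "seed": sseed})
    manifest = pd.DataFrame(rows, columns=["subject_id", "group", "age", "seed"])
    return subjects, manifest


# ---------------------------------------------------------------------------
# ROI-level simulation (cohort-scale statistical experiments)


def simulate_roi_tables(spec: CohortSpec, seed: int | None = None) -> pd.DataFrame:
    """Simulate the absolute ROI table directly at region level.

    Draws exactly the same per-subject factors as :func:`generate_subject`
    (same stream layout) but skips image synthesis and quantification, which
    act as a common multiplicative gain on all regions of a subject and are
    therefore irrelevant to the normalization statistics.  Used for
    cohort-scale simulation studies where thousands of cohorts are needed.

    Returns a table with columns subject_id, group, age, normalization
    ("absolute") and one column per non-artery region.
    """
    rows = []
    region_names = [ts.roi_name for ts in spec.tissue_specs if ts.tissue_class != "artery"]
    for idx, group, sid, sseed in _iter_cohort(spec):
        if seed is not None:
            sseed = subject_seed(seed, idx)
        rng = np.random.default_rng(sseed)
        age, global_f, regional = _draw_subject_factors(spec, rng)
        row = {"subject_id": sid, "group": group, "age": age, "normalization": "absolute"}
        for ts in spec.tissue_specs:
            if ts.tissue_class == "artery":
                continue
            row[ts.roi_name] = (
                ts.true_cbf * spec.effect_multiplier(group, ts.roi_name) * global_f * regional[ts.roi_name]
            )
        rows.append(row)
    cols = ["subject_id", "group", "age", "normalization"] + region_names
    return pd.DataFrame(rows, columns=cols)
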
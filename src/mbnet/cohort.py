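"""Synthetic cohorts of region-wise gray-matter morphology.

The real inputs to an individual morphological-network analysis are, per
subject, one set of smoothed modulated gray-matter intensity values for each
atlas region (e.g. the 90 AAL regions), plus clinical covariates. Such MRI
derivatives are rarely deposited, so this module generates cohorts with the
statistical structure the analysis assumes:

* each region r has a population mean feature level ``mu_r`` organised into
  latent modules (regions within a module have similar morphology, the way
  homotopic and functionally allied cortical areas do) and a region-specific
  vertex-level scale ``sigma_r``;
* each subject perturbs the region means with independent jitter, so
  networks vary across individuals while sharing a common backbone;
* vertex features are Gaussian (optionally Student-t for heavy tails)
  around the subject's region mean;
* a *planted group effect* shifts the vertex distribution of chosen regions
  in group B by ``effect_size`` within-region standard deviations (or, as an
  option, inflates their variance), giving downstream tests a known truth;
* clinical covariates (age, sex, off-therapy duration, IQ, TMT-A, DST) are
  drawn so that the cognitive scores are linear in the subject's realised
  planted shift plus noise, making covariate-association recovery testable.

Everything is deterministic given ``CohortSpec.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BaseModel",
    "CovariateModel",
    "CohortSpec",
    "RegionFeatureSet",
    "SubjectMorphology",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
    "planted_edges",
]

COVARIATE_COLUMNS = ("age", "sex", "off_therapy_years", "IQ", "TMT_A", "DST")


@dataclass(frozen=True)
class BaseModel:
    """Population model of region vertex-feature distributions.

    Region means live on a modular 1-D latent axis: ``n_modules`` module
    centres spread with sd ``module_sd``, regions scattered around their
    module centre with sd ``within_module_sd``. Per-subject jitter
    ``subject_sd`` and finite-vertex sampling noise blur the resulting
    proximity structure, which is what gives the similarity networks their
    small-world character (clustered modules plus noise-induced shortcuts).
    All scales are in units of the vertex-level sd ``within_sd``.
    """

    n_modules: int = 6
    module_sd: float = 0.10
    within_module_sd: float = 0.05
    subject_sd: float = 0.05
    within_sd: float = 1.0
    scale_log_sd: float = 0.05
    heavy_tailed_df: float | None = None  # Student-t df; None = Gaussian


@dataclass(frozen=True)
class CovariateModel:
    """Clinical covariates and their coupling to the planted effect.

    Cognitive scores are linear in the subject's realised shift ``s`` (in
    within-region sd units; 0 for group A): at shift 0 they sit at the
    normative means (IQ 100, TMT-A 29 s, digit span 7), and at shift 1 near
    the levels reported for long-term leukemia survivors (IQ ~80, TMT-A
    ~90 s, span ~4). Off-therapy duration is uniform on ``off_therapy_range``
    years for group B and absent for group A.
    """

    age_mean: float = 10.0
    age_sd: float = 2.5
    age_range: tuple = (6.0, 16.0)
    p_male: float = 0.5
    off_therapy_range: tuple = (1.0, 6.0)
    iq_intercept: float = 100.0
    iq_slope: float = -20.0
    iq_noise_sd: float = 7.0
    tmt_intercept: float = 29.0
    tmt_slope: float = 60.0
    tmt_noise_sd: float = 12.0
    dst_intercept: float = 7.0
    dst_slope: float = -3.0
    dst_noise_sd: float = 0.8


@dataclass(frozen=True)
class CohortSpec:
    """Full specification of a synthetic two-group cohort."""

    n_group_a: int = 20
    n_group_b: int = 20
    n_regions: int = 90
    vertices_per_region: tuple = (50, 200)
    n_features: int = 1
    base_model: BaseModel = field(default_factory=BaseModel)
    effect_regions: tuple = ()
    effect_size: float = 0.0
    effect_kind: str = "shift"  # "shift" (location) or "variance" (scale)
    severity_sd: float = 0.25  # between-subject spread of the realised shift
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    seed: int = 0

    def __post_init__(self):
        for name in ("n_group_a", "n_group_b", "n_regions", "n_features"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 1):
                raise ValueError(f"{name} must be an integer >= 1, got {v!r}")
        lo, hi = self.vertices_per_region
        if not (1 <= lo <= hi):
            raise ValueError(f"vertices_per_region must be a range with 1 <= lo <= hi, got {self.vertices_per_region!r}")
        bad = [r for r in self.effect_regions if not 1 <= int(r) <= self.n_regions]
        if bad:
            raise ValueError(f"effect_regions out of range 1..{self.n_regions}: {bad}")
        if self.effect_kind not in ("shift", "variance"):
            raise ValueError(f"effect_kind must be 'shift' or 'variance', got {self.effect_kind!r}")

    def with_seed(self, seed: int) -> "CohortSpec":
        return replace(self, seed=int(seed))


@dataclass
class RegionFeatureSet:
    """One region's vertex-by-feature value matrix for one subject.

    Vertex order is irrelevant downstream: the values are treated as a
    multiset (an empirical feature distribution).
    """

    region_id: int
    name: str
    values: np.ndarray  # (n_vertices, d)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.values.shape[0] < 1:
            raise ValueError(f"region {self.region_id}: empty feature set")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"region {self.region_id}: non-finite feature values")

    @property
    def n_vertices(self) -> int:
        return self.values.shape[0]


@dataclass
class SubjectMorphology:
    """A subject's regions plus group label and clinical covariates.

    ``covariates`` maps covariate name -> float; an absent measurement is
    simply missing from the dict (or NaN), never silently zero.
    """

    subject_id: str
    group: str
    covariates: dict
    regions: list

    def __post_init__(self):
        ids = [r.region_id for r in self.regions]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"subject {self.subject_id}: duplicate region ids {dupes}")

    def covariate(self, name: str):
        v = self.covariates.get(name)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        return float(v)


def _draw_population(spec: CohortSpec, rng: np.random.Generator):
    bm = spec.base_model
    centers = rng.normal(0.0, bm.module_sd, size=(bm.n_modules, spec.n_features))
    module_of = rng.integers(0, bm.n_modules, size=spec.n_regions)
    mu = centers[module_of] + rng.normal(0.0, bm.within_module_sd, size=(spec.n_regions, spec.n_features))
    sigma = bm.within_sd * np.exp(rng.normal(0.0, bm.scale_log_sd, size=spec.n_regions))
    return mu, sigma


def _vertex_noise(rng, bm: BaseModel, size):
    if bm.heavy_tailed_df is None:
        return rng.standard_normal(size)
    df = bm.heavy_tailed_df
    t = rng.standard_t(df, size)
    if df > 2:  # rescale to unit variance so effect sizes stay comparable
        t /= math.sqrt(df / (df - 2.0))
    return t


def _simulate_subject(spec, rng, mu, sigma, subject_id, group):
    bm, cm = spec.base_model, spec.covariate_model
    in_b = group == "B"

    severity = 0.0
    if in_b and spec.effect_size != 0.0:
        severity = max(spec.effect_size * (1.0 + spec.severity_sd * rng.standard_normal()), 0.0)
    elif in_b:
        rng.standard_normal()  # keep stream alignment across effect sizes

    age = float(np.clip(rng.normal(cm.age_mean, cm.age_sd), *cm.age_range))
    sex = float(rng.random() < cm.p_male)
    covs = {
        "age": age,
        "sex": sex,
        "IQ": cm.iq_intercept + cm.iq_slope * severity + cm.iq_noise_sd * rng.standard_normal(),
        "TMT_A": cm.tmt_intercept + cm.tmt_slope * severity + cm.tmt_noise_sd * rng.standard_normal(),
        "DST": cm.dst_intercept + cm.dst_slope * severity + cm.dst_noise_sd * rng.standard_normal(),
    }
    if in_b:
        covs["off_therapy_years"] = float(rng.uniform(*cm.off_therapy_range))

    effect = set(int(r) for r in spec.effect_regions)
    lo, hi = spec.vertices_per_region
    regions = []
    for r in range(1, spec.n_regions + 1):
        n_v = int(rng.integers(lo, hi + 1))
        mean_r = mu[r - 1] + rng.normal(0.0, bm.subject_sd, size=spec.n_features)
        scale_r = sigma[r - 1]
        if in_b and r in effect:
            if spec.effect_kind == "shift":
                mean_r = mean_r + severity * scale_r
            else:
                scale_r = scale_r * (1.0 + severity)
        vals = mean_r[None, :] + scale_r * _vertex_noise(rng, bm, (n_v, spec.n_features))
        regions.append(RegionFeatureSet(region_id=r, name=f"R{r:03d}", values=vals))
    return SubjectMorphology(subject_id=subject_id, group=group, covariates=covs, regions=regions)


def simulate_cohort(spec: CohortSpec) -> list:
    """Simulate ``n_group_a + n_group_b`` subjects under ``spec``.

    Group A comes first (``A01`` ...), then group B. Identical spec and seed
    give an element-wise identical cohort.
    """
    rng = np.random.default_rng(spec.seed)
    mu, sigma = _draw_population(spec, rng)
    cohort = []
    for k in range(spec.n_group_a):
        cohort.append(_simulate_subject(spec, rng, mu, sigma, f"A{k + 1:02d}", "A"))
    for k in range(spec.n_group_b):
        cohort.append(_simulate_subject(spec, rng, mu, sigma, f"B{k + 1:02d}", "B"))
    return cohort


def planted_edges(spec: CohortSpec) -> list:
    """Region pairs whose raw energy distance differs between groups.

    A location shift applied to every effect region leaves within-effect
    pairs untouched (both regions move together) but perturbs every pair
    with exactly one endpoint in the effect set; those are the edges a
    subnetwork test should recover. Returned as sorted (i, j) region-id
    tuples with i < j.
    """
    effect = set(int(r) for r in spec.effect_regions)
    out = []
    for i in range(1, spec.n_regions + 1):
        for j in range(i + 1, spec.n_regions + 1):
            if (i in effect) != (j in effect):
                out.append((i, j))
    return out


# ---------------------------------------------------------------------------
# disk round trip: one covariate TSV + one long-form feature TSV


def write_cohort(cohort, path) -> None:
    """Write a cohort to ``<path>/covariates.tsv`` + ``<path>/features.tsv``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cov_rows = []
    feat_frames = []
    for s in cohort:
        row = {"subject_id": s.subject_id, "group": s.group}
        for c in COVARIATE_COLUMNS:
            row[c] = s.covariates.get(c, np.nan)
        cov_rows.append(row)
        for reg in s.regions:
            n, d = reg.values.shape
            df = pd.DataFrame(reg.values, columns=[f"f{i + 1}" for i in range(d)])
            df.insert(0, "vertex_index", np.arange(n))
            df.insert(0, "region_id", reg.region_id)
            df.insert(0, "subject_id", s.subject_id)
            feat_frames.append(df)
    pd.DataFrame(cov_rows).to_csv(path / "covariates.tsv", sep="\t", index=False, float_format="%.17g")
    pd.concat(feat_frames, ignore_index=True).to_csv(
        path / "features.tsv", sep="\t", index=False, float_format="%.17g"
    )


def read_cohort(path) -> list:
    """Read a cohort written by :func:`write_cohort` (lossless round trip).

    Missing covariate columns or empty cells mark the covariate absent.
    Duplicated (subject, region, vertex) rows are an error.
    """
    path = Path(path)
    cov_path, feat_path = path / "covariates.tsv", path / "features.tsv"
    try:
        cov = pd.read_csv(cov_path, sep="\t", dtype={"subject_id": str}, float_precision="round_trip")
        feats = pd.read_csv(feat_path, sep="\t", dtype={"subject_id": str}, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as err:
        raise ValueError(f"malformed cohort file under {path}: {err}") from err
    for col in ("subject_id", "group"):
        if col not in cov.columns:
            raise ValueError(f"{cov_path}: missing required column {col!r}")
    for col in ("subject_id", "region_id", "vertex_index"):
        if col not in feats.columns:
            raise ValueError(f"{feat_path}: missing required column {col!r}")
    dup = feats.duplicated(subset=["subject_id", "region_id", "vertex_index"])
    if dup.any():
        first = feats.loc[dup.idxmax()]
        raise ValueError(
            f"{feat_path}: duplicated (subject, region, vertex) row at line "
            f"{int(dup.idxmax()) + 2}: subject {first['subject_id']!r} "
            f"region {int(first['region_id'])} vertex {int(first['vertex_index'])}"
        )
    feature_cols = [c for c in feats.columns if c.startswith("f")]
    if not feature_cols:
        raise ValueError(f"{feat_path}: no feature columns (f1..fd) found")

    cohort = []
    grouped = dict(tuple(feats.groupby("subject_id", sort=False)))
    for _, row in cov.iterrows():
        sid = row["subject_id"]
        if sid not in grouped:
            raise ValueError(f"subject {sid!r} present in covariates but absent from features")
        covs = {}
        for c in COVARIATE_COLUMNS:
            if c in cov.columns and pd.notna(row[c]):
                covs[c] = float(row[c])
        regions = []
        for rid, sub in grouped[sid].groupby("region_id", sort=True):
            sub = sub.sort_values("vertex_index")
            regions.append(
                RegionFeatureSet(region_id=int(rid), name=f"R{int(rid):03d}", values=sub[feature_cols].to_numpy())
            )
        cohort.append(
            SubjectMorphology(subject_id=str(sid), group=str(row["group"]), covariates=covs, regions=regions)
        )
    return cohort
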
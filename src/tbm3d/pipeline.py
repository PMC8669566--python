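"""End-to-end orchestration of the morphometry analysis.

Reproduces the analysis graph on a cohort (phantom or loaded): solve one
transport map per subject against the population reference, embed, reduce
by PCA, and fit covariate models:

* age model — direction most correlated with age (intercept-only
  confounding by default);
* fitness model — direction most correlated with VO2 peak after removing
  age, gender and education; reports the overlap with the age direction;
* interaction model — direction correlated with the centered age x fitness
  product (age partialled out of fitness; gender/education removed).

Transport maps depend only on the images and the reference, so they are
solved once and shared across the three models.  Every run is fully
deterministic given the configuration seed and serializes its provenance
into the report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import stats as st
from .localize import change_map, region_fractions, region_correlations
from .phantom import AtlasVolume, PhantomSpec, generate_atlas, generate_cohort
from .prep import euclidean_mean_reference, residualize
from .transport import SolverParams, solve_transport

__all__ = ["RunConfig", "CohortAnalysis", "run_age_model", "run_fitness_model",
           "run_interaction_model", "run_all"]


@dataclass
class RunConfig:
    """Configuration of a full analysis run."""

    phantom: PhantomSpec
    var_fraction: float = 0.90
    perms: int = 10000
    seed: int = 0
    age_increment: float = 10.0  # years
    vo2_increment: float = -10.0  # ml/kg/min (a decrease, as reported)
    age_confounds: tuple[str, ...] = ()  # intercept only, per the age model
    fitness_confounds: tuple[str, ...] = ("age", "gender", "education")
    interaction_confounds: tuple[str, ...] = ("gender", "education")
    # cohort analyses tolerate a slightly larger per-map constraint residual
    # than single-map studies: statistics average discretization error over
    # subjects, and small-grid phantoms sit closer to the pointwise
    # pullback's resolution floor
    solver: SolverParams = field(
        default_factory=lambda: SolverParams(mp_tolerance=5e-2)
    )
    n_regions: int = 0  # 0 disables the regional report
    out_dir: str | None = None

    def __post_init__(self):
        if not (0 < self.var_fraction <= 1):
            raise ValueError("var_fraction must be in (0, 1]")
        if self.perms < 1:
            raise ValueError("perms must be >= 1")


class CohortAnalysis:
    """Shared state across the age / fitness / interaction models.

    Builds (or receives) the cohort, constructs the Euclidean-mean reference
    when no template is given, solves and caches the per-subject transport
    maps, and caches the PCA model.
    """

    def __init__(self, cfg: RunConfig, cohort=None):
        self.cfg = cfg
        self.cohort = cohort if cohort is not None else generate_cohort(cfg.phantom)
        self.covariates = self.cohort.covariates
        self.reference = self.cohort.template
        if self.reference is None:
            self.reference = euclidean_mean_reference(self.cohort.images)
        self._maps = None
        self._pca = None
        self._atlas: AtlasVolume | None = None

    @property
    def maps(self):
        if self._maps is None:
            self._maps = [
                solve_transport(self.reference, img, self.cfg.solver)
                for img in self.cohort.images
            ]
        return self._maps

    @property
    def pca(self) -> st.PCAModel:
        if self._pca is None:
            ds = st.embed_maps(self.maps, self.reference)
            ds.subject_ids = list(self.covariates["subject_id"])
            self._pca = st.pca_reduce(ds, self.cfg.var_fraction)
        return self._pca

    @property
    def atlas(self) -> AtlasVolume | None:
        if self._atlas is None and self.cfg.n_regions >= 2:
            self._atlas = generate_atlas(
                self.cfg.phantom, self.cfg.n_regions, self.reference
            )
        return self._atlas

    def confound_matrix(self, names) -> np.ndarray | None:
        if not names:
            return None
        return self.covariates[list(names)].to_numpy(dtype=float)

    def fit_direction(self, v: np.ndarray, seed_offset: int) -> st.EffectDirection:
        d = st.correlated_direction(self.pca, v)
        d.p_perm = st.permutation_pvalue(
            self.pca, v, T=self.cfg.perms, seed=self.cfg.seed + seed_offset
        )
        d.slope_t_per_unit = st.fit_t_scale(d.scores, v)
        return d


def _direction_report(name, direction, increment, analysis) -> dict:
    I0 = analysis.reference
    t_inc = direction.slope_t_per_unit * increment
    mm = st.mean_displacement_mm(direction, t_inc, I0)
    rep = {
        "model": name,
        "n_subjects": int(len(analysis.cohort.images)),
        "n_components": int(analysis.pca.d),
        "var_fraction": analysis.cfg.var_fraction,
        "r": round(float(direction.r), 4),
        "r_rounded": round(float(direction.r), 2),
        "p_perm": float(direction.p_perm),
        "slope_t_per_unit": float(direction.slope_t_per_unit),
        "increment": float(increment),
        "mean_displacement_mm_per_increment": round(float(mm), 4),
    }
    atlas = analysis.atlas
    if atlas is not None:
        cm = change_map(direction, increment, I0, covariate=name)
        tab = region_fractions(cm, atlas, I0)
        rep["region_fractions_pct"] = {
            str(row["name"]): round(float(row["fraction_pct"]), 2)
            for _, row in tab.iterrows()
        }
    return rep


def run_age_model(cfg: RunConfig, analysis: CohortAnalysis | None = None) -> dict:
    """Main effect of age on tissue distribution."""
    analysis = analysis or CohortAnalysis(cfg)
    cov = analysis.covariates
    v = residualize(cov["age"].to_numpy(float), analysis.confound_matrix(cfg.age_confounds))
    direction = analysis.fit_direction(v, seed_offset=1)
    report = _direction_report("age", direction, cfg.age_increment, analysis)
    report["confounds"] = list(cfg.age_confounds)
    _maybe_write(cfg, report, "age_model.json")
    return report


def run_fitness_model(cfg: RunConfig, analysis: CohortAnalysis | None = None) -> dict:
    """Effect of cardiorespiratory fitness after confound removal.

    VO2 peak is residualized against age, gender and education (plus an
    intercept) before the transport-domain regression; the report includes
    the overlap of the fitness direction with the age direction.
    """
    analysis = analysis or CohortAnalysis(cfg)
    cov = analysis.covariates
    for col in ("vo2_peak",) + tuple(cfg.fitness_confounds):
        if col not in cov.columns:
            raise ValueError(f"covariate table is missing column {col!r}")
    v = residualize(
        cov["vo2_peak"].to_numpy(float),
        analysis.confound_matrix(cfg.fitness_confounds),
    )
    direction = analysis.fit_direction(v, seed_offset=2)
    report = _direction_report("vo2_peak", direction, cfg.vo2_increment, analysis)
    report["confounds"] = list(cfg.fitness_confounds)

    v_age = residualize(
        cov["age"].to_numpy(float), analysis.confound_matrix(cfg.age_confounds)
    )
    dir_age = analysis.fit_direction(v_age, seed_offset=1)
    r_overlap, p_overlap = st.overlap_correlation(
        dir_age, direction, T=cfg.perms, seed=cfg.seed + 3
    )
    report["overlap_with_age"] = {
        "r": round(float(r_overlap), 4),
        "p_perm": float(p_overlap),
        "variance_explained_pct": st.variance_explained(r_overlap),
    }
    _maybe_write(cfg, report, "fitness_model.json")
    return report


def run_interaction_model(cfg: RunConfig, analysis: CohortAnalysis | None = None) -> dict:
    """Age x fitness interaction on tissue distribution."""
    analysis = analysis or CohortAnalysis(cfg)
    cov = analysis.covariates
    v = st.interaction_variable(
        cov["age"].to_numpy(float),
        cov["vo2_peak"].to_numpy(float),
        analysis.confound_matrix(cfg.interaction_confounds),
    )
    direction = analysis.fit_direction(v, seed_offset=4)
    report = {
        "model": "age_x_vo2_peak",
        "n_subjects": int(len(analysis.cohort.images)),
        "n_components": int(analysis.pca.d),
        "r": round(float(direction.r), 4),
        "r_rounded": round(float(direction.r), 2),
        "p_perm": float(direction.p_perm),
        "variance_explained_pct": st.variance_explained(direction.r),
        "confounds": list(cfg.interaction_confounds),
    }
    _maybe_write(cfg, report, "interaction_model.json")
    return report


def run_all(cfg: RunConfig) -> dict:
    """Age, fitness and interaction models sharing one set of transport maps."""
    analysis = CohortAnalysis(cfg)
    report = {
        "config": _config_dict(cfg),
        "age": run_age_model(cfg, analysis),
        "fitness": run_fitness_model(cfg, analysis),
        "interaction": run_interaction_model(cfg, analysis),
    }
    if cfg.n_regions >= 2:
        cov = analysis.covariates
        v_age = residualize(
            cov["age"].to_numpy(float), analysis.confound_matrix(cfg.age_confounds)
        )
        v_fit = residualize(
            cov["vo2_peak"].to_numpy(float),
            analysis.confound_matrix(cfg.fitness_confounds),
        )
        d_age = analysis.fit_direction(v_age, seed_offset=1)
        d_fit = analysis.fit_direction(v_fit, seed_offset=2)
        cm_age = change_map(d_age, cfg.age_increment, analysis.reference, "age")
        cm_fit = change_map(d_fit, cfg.vo2_increment, analysis.reference, "vo2_peak")
        tab = region_correlations(
            cm_age, cm_fit, analysis.atlas, T=cfg.perms, seed=cfg.seed + 5
        )
        report["regions"] = {
            str(row["name"]): {
                "r": None if not row["defined"] else round(float(row["r"]), 4),
                "p": None if not row["defined"] else float(row["p"]),
                "significant": bool(row["significant"]),
            }
            for _, row in tab.iterrows()
        }
    _maybe_write(cfg, report, "report.json")
    return report


def _config_dict(cfg: RunConfig) -> dict:
    d = asdict(cfg)
    d["solver"] = asdict(cfg.solver)
    d["phantom"] = asdict(cfg.phantom)
    return d


def _maybe_write(cfg: RunConfig, report: dict, filename: str) -> None:
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / filename).write_text(report_json(report))


def report_json(report: dict) -> str:
    """Canonical (byte-stable) JSON serialization of a report."""
    return json.dumps(report, sort_keys=True, indent=2)
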
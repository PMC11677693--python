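"""Synthetic two-cohort metabolomics generator with planted ground truth.

The real cohorts behind this analysis are controlled-access, so every
downstream stage is exercised on simulated data whose statistical
structure mirrors the assumptions the pipeline makes:

- log2 metabolite level = baseline + age slope x (age + latent delta)
  + obstruction slope x FEV1/FVC + log2 batch factor + Gaussian noise,
  exponentiated to positive intensities (the pipeline's log2 step
  linearizes the planted signal exactly);
- a per-subject latent aging-rate offset ("delta", years) that shifts
  effective age and is correlated with disease severity;
- partially overlapping sets of age- and obstruction-associated
  metabolites;
- multiplicative per-batch factors, removed exactly by median scaling;
- MCAR plus detection-limit missingness, with a planted subset of
  metabolites given cohort-discrepant high missingness to exercise the
  cross-cohort filter;
- a two-level pathway annotation in which planted metabolites are
  concentrated in a few pathways, so overrepresentation is detectable.

All randomness flows from one seed through named sub-streams, so a pair
of cohorts regenerates bit-identically and partial re-runs stay stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MetaboliteMatrix, PathwayAnnotation

_SUBSTREAMS = ("metabolites", "subjects_a", "subjects_b",
               "missing_a", "missing_b", "pathways")


@dataclass(frozen=True)
class SimulationConfig:
    """Stated world for the synthetic cohort pair.

    Defaults emulate the source cohorts at reduced size: 831 metabolites
    of which 300 are age-associated and 300 obstruction-associated with
    150 shared; ages uniform on 45-80; per-cohort sizes 2000 and 1000
    with 60% training-grade controls (1200 / 600 control subjects).
    Age slopes are uniform in magnitude on [0.005, 0.04] log2 units per
    effective year with random sign, against residual noise of sd 1.0
    log2 units — univariate metabolite-age correlations of roughly
    0.05-0.35, the weak-per-metabolite regime metabolomic clocks live in.
    """

    n_subjects: tuple[int, int] = (2000, 1000)
    n_metabolites: int = 831
    n_age_assoc: int = 300
    n_obstr_assoc: int = 300
    n_shared: int = 150
    age_slope_range: tuple[float, float] = (0.005, 0.04)
    obstr_slope_range: tuple[float, float] = (1.0, 4.0)
    noise_sd: float = 1.0
    baseline_mean: float = 10.0
    baseline_sd: float = 2.0
    n_batches: int = 3
    batch_factor_range: tuple[float, float] = (0.5, 2.0)
    mcar_rate: float = 0.02
    detection_limit_quantile: float = 0.05
    n_discrepant: int = 40
    n_severe: int = 20
    discrepant_rate: float = 0.5
    severe_rate: float = 0.85
    age_range: tuple[float, float] = (45.0, 80.0)
    frac_control: float = 0.60
    frac_current_no_copd: float = 0.10
    accel_sd: float = 5.0
    accel_disease_coupling: float = 0.5
    n_sub_pathways: int = 60
    n_super_pathways: int = 8
    frac_unannotated: float = 129 / 831
    pathway_concentration: float = 0.8
    seed: int = 42

    def __post_init__(self):
        if self.n_shared > min(self.n_age_assoc, self.n_obstr_assoc):
            raise ValueError("n_shared exceeds a planted set size")
        planted = self.n_age_assoc + self.n_obstr_assoc - self.n_shared
        if planted + self.n_discrepant + self.n_severe > self.n_metabolites:
            raise ValueError("planted + missingness metabolites exceed n_metabolites")
        for r in (self.mcar_rate, self.detection_limit_quantile,
                  self.discrepant_rate, self.severe_rate, self.frac_control,
                  self.frac_current_no_copd, self.frac_unannotated):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.frac_control + self.frac_current_no_copd > 1.0:
            raise ValueError("group fractions exceed 1")
        if not -1.0 <= self.accel_disease_coupling <= 1.0:
            raise ValueError("coupling must be a correlation in [-1, 1]")


@dataclass
class PlantedTruth:
    """Ground truth written alongside the simulated cohorts."""

    metabolites: pd.DataFrame  # per-metabolite flags, slopes, missing plan
    subjects: pd.DataFrame     # per-subject latent delta and true group
    annotation: PathwayAnnotation
    config: SimulationConfig

    @property
    def age_set(self) -> set:
        return set(self.metabolites.index[self.metabolites["age_assoc"]])

    @property
    def obstruction_set(self) -> set:
        return set(self.metabolites.index[self.metabolites["obstr_assoc"]])


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_SUBSTREAMS))
    return {name: np.random.default_rng(s) for name, s in zip(_SUBSTREAMS, children)}


def _plant_metabolites(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    ids = [f"met_{i:04d}" for i in range(cfg.n_metabolites)]
    order = rng.permutation(cfg.n_metabolites)
    n_age_only = cfg.n_age_assoc - cfg.n_shared
    n_obs_only = cfg.n_obstr_assoc - cfg.n_shared
    shared = order[:cfg.n_shared]
    age_only = order[cfg.n_shared:cfg.n_shared + n_age_only]
    obs_only = order[cfg.n_shared + n_age_only:
                     cfg.n_shared + n_age_only + n_obs_only]
    rest = order[cfg.n_shared + n_age_only + n_obs_only:]
    disc = rest[:cfg.n_discrepant]
    sev = rest[cfg.n_discrepant:cfg.n_discrepant + cfg.n_severe]

    age_assoc = np.zeros(cfg.n_metabolites, bool)
    age_assoc[np.concatenate([shared, age_only]).astype(int)] = True
    obs_assoc = np.zeros(cfg.n_metabolites, bool)
    obs_assoc[np.concatenate([shared, obs_only]).astype(int)] = True

    lo, hi = cfg.age_slope_range
    age_slope = np.where(
        age_assoc,
        rng.uniform(lo, hi, cfg.n_metabolites) * rng.choice([-1, 1], cfg.n_metabolites),
        0.0,
    )
    lo, hi = cfg.obstr_slope_range
    obstr_slope = np.where(
        obs_assoc,
        rng.uniform(lo, hi, cfg.n_metabolites) * rng.choice([-1, 1], cfg.n_metabolites),
        0.0,
    )
    plan = np.array(["none"] * cfg.n_metabolites, dtype=object)
    plan[disc.astype(int)] = "discrepant"
    plan[sev.astype(int)] = "severe"
    return pd.DataFrame(
        {
            "age_assoc": age_assoc,
            "obstr_assoc": obs_assoc,
            "age_slope": age_slope,
            "obstr_slope": obstr_slope,
            "baseline": rng.normal(cfg.baseline_mean, cfg.baseline_sd,
                                   cfg.n_metabolites),
            "planted_missing": plan,
        },
        index=pd.Index(ids, name="metabolite_id"),
    )


def _pathway_annotation(metabolites: pd.DataFrame, cfg: SimulationConfig,
                        rng: np.random.Generator) -> PathwayAnnotation:
    """Assign sub/super pathways, concentrating planted metabolites.

    With probability ``pathway_concentration`` a planted (age- or
    obstruction-associated) metabolite lands in the first quarter of the
    sub-pathways, making those pathways genuinely overrepresented among
    selected sets.  A fixed fraction of metabolites stays unannotated.
    """
    ids = metabolites.index.to_numpy()
    n = len(ids)
    unannot = rng.random(n) < cfg.frac_unannotated
    planted = (metabolites["age_assoc"] | metabolites["obstr_assoc"]).to_numpy()
    n_hot = max(1, cfg.n_sub_pathways // 4)
    sub = np.empty(n, dtype=object)
    for i in range(n):
        if planted[i] and rng.random() < cfg.pathway_concentration:
            sub[i] = f"sub_{rng.integers(n_hot):03d}"
        else:
            sub[i] = f"sub_{rng.integers(n_hot, cfg.n_sub_pathways):03d}"
    # super-pathway is a deterministic coarsening of the sub-pathway
    per_super = -(-cfg.n_sub_pathways // cfg.n_super_pathways)
    sup = np.array([f"super_{int(s.split('_')[1]) // per_super:02d}" for s in sub],
                   dtype=object)
    sub_map = {m: (None if u else s) for m, s, u in zip(ids, sub, unannot)}
    sup_map = {m: (None if u else s) for m, s, u in zip(ids, sup, unannot)}
    return PathwayAnnotation(sub_pathway=sub_map, super_pathway=sup_map)


def _group_counts(n: int, cfg: SimulationConfig) -> tuple[int, int, int]:
    n_control = int(round(n * cfg.frac_control))
    n_current = int(round(n * cfg.frac_current_no_copd))
    return n_control, n_current, n - n_control - n_current


def _simulate_subjects(cohort: str, n: int, cfg: SimulationConfig,
                       rng: np.random.Generator) -> pd.DataFrame:
    n_ctrl, n_cur, n_dis = _group_counts(n, cfg)
    group = np.array(
        ["control"] * n_ctrl + ["current_no_copd"] * n_cur + ["disease"] * n_dis,
        dtype=object,
    )
    age = rng.uniform(*cfg.age_range, n)
    severity = np.zeros(n)
    is_dis = group == "disease"
    severity[is_dis] = rng.uniform(0.0, 1.0, n_dis)

    # latent aging-rate offset, correlated with severity among the diseased
    z = rng.normal(size=n)
    delta = cfg.accel_sd * z
    if n_dis and cfg.accel_sd > 0:
        rho = cfg.accel_disease_coupling
        sev_z = (severity[is_dis] - 0.5) / np.sqrt(1.0 / 12.0)  # standardized U(0,1)
        delta[is_dis] = cfg.accel_sd * (rho * sev_z +
                                        np.sqrt(1.0 - rho ** 2) * z[is_dis])

    ratio = np.empty(n)
    fev1_pct = np.empty(n)
    laa = np.empty(n)
    healthy = ~is_dis
    n_heal = int(healthy.sum())
    ratio[healthy] = np.clip(rng.normal(0.78, 0.05, n_heal), 0.70, 0.95)
    fev1_pct[healthy] = np.clip(rng.normal(95.0, 9.0, n_heal), 80.0, 130.0)
    laa[healthy] = np.clip(np.abs(rng.normal(1.5, 1.0, n_heal)), 0.0, 4.9)
    s = severity[is_dis]
    ratio[is_dis] = np.clip(0.69 - 0.38 * s + rng.normal(0, 0.02, n_dis),
                            0.25, 0.699)
    fev1_pct[is_dis] = np.clip(88.0 - 62.0 * s + rng.normal(0, 8.0, n_dis),
                               15.0, 115.0)
    laa[is_dis] = np.clip(2.0 + 28.0 * s * np.abs(rng.normal(1.0, 0.3, n_dis)),
                          0.0, 60.0)

    fvc = np.clip(rng.normal(3.5, 0.8, n), 1.2, 7.0)
    fev1 = ratio * fvc

    smoking = np.empty(n, dtype=object)
    quit_years = np.full(n, np.nan)
    ctrl = group == "control"
    never_ctrl = rng.random(n) < 0.35
    smoking[ctrl & never_ctrl] = "never"
    smoking[ctrl & ~never_ctrl] = "former"
    quit_years[ctrl & ~never_ctrl] = rng.uniform(5.0, 30.0, int((ctrl & ~never_ctrl).sum()))
    smoking[group == "current_no_copd"] = "current"
    dis_cur = is_dis & (rng.random(n) < 0.35)
    smoking[dis_cur] = "current"
    dis_for = is_dis & ~dis_cur
    smoking[dis_for] = "former"
    quit_years[dis_for] = rng.uniform(0.1, 30.0, int(dis_for.sum()))

    def _comorb(base: float, delta_coef: float = 0.06, sev_coef: float = 0.9):
        logit = np.log(base / (1 - base)) + delta_coef * delta + sev_coef * severity
        return rng.random(n) < 1.0 / (1.0 + np.exp(-logit))

    tab = pd.DataFrame({
        "subject_id": [f"{cohort}_s{i:05d}" for i in range(n)],
        "cohort": cohort,
        "age_actual": age,
        "sex": rng.choice(["male", "female"], n),
        "race": rng.choice(["white", "black", "other"], n, p=[0.72, 0.24, 0.04]),
        "smoking_status": smoking,
        "years_since_quit": quit_years,
        "fev1": fev1,
        "fvc": fvc,
        "fev1_pct_pred": fev1_pct,
        "fev1_fvc": ratio,
        "emphysema_laa": laa,
        "diabetes": _comorb(0.14),
        "stroke": _comorb(0.03),
        "heart_attack": _comorb(0.05),
        "coronary_artery_disease": _comorb(0.07),
        "chronic_bronchitis": _comorb(0.12),
        "exacerbations": rng.poisson(0.3 + 1.2 * severity),
        "latent_delta": delta,
        "true_group": group,
        "severity": severity,
    }).set_index("subject_id", drop=False)
    return tab


def _intensities(subjects: pd.DataFrame, metabolites: pd.DataFrame,
                 cfg: SimulationConfig, rng: np.random.Generator,
                 cohort: str) -> MetaboliteMatrix:
    n, m = len(subjects), len(metabolites)
    batch = rng.integers(cfg.n_batches, size=n)
    lo, hi = cfg.batch_factor_range
    batch_factor = rng.uniform(lo, hi, size=(cfg.n_batches, m))
    eff_age = (subjects["age_actual"] + subjects["latent_delta"]).to_numpy()
    log2x = (
        metabolites["baseline"].to_numpy()[None, :]
        + np.outer(eff_age, metabolites["age_slope"].to_numpy())
        + np.outer(subjects["fev1_fvc"].to_numpy(),
                   metabolites["obstr_slope"].to_numpy())
        + np.log2(batch_factor)[batch]
        + rng.normal(0.0, cfg.noise_sd, size=(n, m))
    )
    data = pd.DataFrame(np.exp2(log2x), index=subjects.index,
                        columns=metabolites.index)
    return MetaboliteMatrix(
        data,
        batch=pd.Series([f"{cohort}_b{b}" for b in batch], index=subjects.index),
        cohort=pd.Series(cohort, index=subjects.index),
    )


def apply_missingness(
    matrix: MetaboliteMatrix,
    config: SimulationConfig,
    rng: np.random.Generator | int | None = None,
    extra_missing: dict | None = None,
) -> MetaboliteMatrix:
    """Remove cells by detection-limit censoring, MCAR, and planted rates.

    Values below each metabolite's ``detection_limit_quantile`` quantile
    go missing first (left-censoring at the platform's sensitivity floor),
    then MCAR cells at ``mcar_rate``, then any ``extra_missing``
    metabolite -> rate entries (used to plant cohort-discrepant patterns).
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    vals = matrix.data.to_numpy(copy=True)
    n, m = vals.shape
    if config.detection_limit_quantile > 0:
        cut = np.nanquantile(vals, config.detection_limit_quantile, axis=0)
        vals[vals < cut[None, :]] = np.nan
    if config.mcar_rate > 0:
        vals[rng.random((n, m)) < config.mcar_rate] = np.nan
    if extra_missing:
        cols = matrix.data.columns
        for met, rate in extra_missing.items():
            j = cols.get_loc(met)
            vals[rng.random(n) < rate, j] = np.nan
    return MetaboliteMatrix(
        pd.DataFrame(vals, index=matrix.data.index, columns=matrix.data.columns),
        matrix.batch.copy(), matrix.cohort.copy(),
    )


def generate_cohort_pair(
    config: SimulationConfig | None = None,
) -> tuple[tuple[MetaboliteMatrix, pd.DataFrame],
           tuple[MetaboliteMatrix, pd.DataFrame], PlantedTruth]:
    """Simulate the paired cohorts and their ground truth.

    Returns ``(matrix_a, samples_a), (matrix_b, samples_b), truth``.  The
    same generating law drives both cohorts; batch factors, sampling and
    missingness draws differ.  Cohort-discrepant missingness is planted
    on cohort B (discrepant plan) or split between cohorts (severe plan).
    """
    cfg = config or SimulationConfig()
    rngs = _rngs(cfg.seed)
    mets = _plant_metabolites(cfg, rngs["metabolites"])
    annotation = _pathway_annotation(mets, cfg, rngs["pathways"])

    out = []
    truth_rows = []
    for cohort, key_s, key_m, n in (
        ("cohortA", "subjects_a", "missing_a", cfg.n_subjects[0]),
        ("cohortB", "subjects_b", "missing_b", cfg.n_subjects[1]),
    ):
        subjects = _simulate_subjects(cohort, n, cfg, rngs[key_s])
        full = _intensities(subjects, mets, cfg, rngs[key_s], cohort)
        disc = mets.index[mets["planted_missing"] == "discrepant"]
        sev = mets.index[mets["planted_missing"] == "severe"]
        extra: dict[str, float] = {}
        if cohort == "cohortB":
            extra.update({m: cfg.discrepant_rate for m in disc})
        half = len(sev) // 2
        sev_here = sev[:half] if cohort == "cohortA" else sev[half:]
        extra.update({m: cfg.severe_rate for m in sev_here})
        sparse = apply_missingness(full, cfg, rngs[key_m], extra_missing=extra)
        truth_rows.append(subjects[["subject_id", "cohort", "latent_delta",
                                    "true_group", "severity"]])
        meta = subjects.drop(columns=["latent_delta", "true_group", "severity"])
        out.append((sparse, meta))

    truth_subjects = pd.concat(truth_rows)
    truth = PlantedTruth(metabolites=mets, subjects=truth_subjects,
                         annotation=annotation, config=cfg)
    return out[0], out[1], truth
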
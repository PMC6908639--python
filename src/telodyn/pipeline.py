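"""End-to-end study orchestration.

Reproduces the analysis chain of a two-cohort longitudinal telomere
study on pedigreed animals: descriptive statistics by cohort, time point
and sex; exact-permutation median comparisons of raw T/S ratios;
per-cohort and combined polygenic models of inverse-normal LTL with sex,
age and diet covariates; construction of telomere attrition (delta-LTL)
and its diet test; and biomarker / lesion association tables computed
inside the kinship model.

Outputs are plain TSV tables (descriptives, median tests, model fits,
three association tables), a JSON metadata record sufficient to re-run
bit-identically in simulation mode, and a plain-text stage log.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._version import __version__
from .pedigree import KinshipMatrix, compute_kinship, read_pedigree
from .polygenic import (
    AssociationRow,
    PolygenicModelSpec,
    covariate_association,
    fit_polygenic,
    lrt_covariate,
    lrt_heritability,
)
from .simulate import GeneratorScenario, get_scenario, simulate_study
from .transforms import (
    TraitVector,
    delta_ltl,
    exact_mwu_test,
    inverse_normal_transform,
    residualize,
)

__all__ = [
    "StudyConfig",
    "StudyReport",
    "run_descriptives",
    "run_full_study",
    "recover_scenario",
]

#: Substrings that mark a secondary-trait column as a lesion extent
#: rather than a circulating biomarker.
LESION_KEYWORDS = ("aorta", "aortic", "iliac", "lesion", "carotid")

_FLOAT_FMT = "%.6g"


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of one full study run.

    In simulation mode set ``scenario`` (a library name) and ``seed``;
    in real-data mode set ``phenotype_path`` and ``pedigree_path``.
    ``biomarkers``/``lesions`` override the keyword-based classification
    of secondary trait columns.
    """

    out_dir: str | Path
    scenario: str | None = None
    seed: int = 0
    phenotype_path: str | Path | None = None
    pedigree_path: str | Path | None = None
    biomarkers: tuple[str, ...] | None = None
    lesions: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.scenario is None:
            if self.phenotype_path is None or self.pedigree_path is None:
                raise ValueError(
                    "need either a scenario name or phenotype+pedigree paths"
                )
            for p in (self.phenotype_path, self.pedigree_path):
                if not Path(p).exists():
                    raise FileNotFoundError(str(p))

    def digest(self) -> str:
        payload = {k: str(v) for k, v in self.__dict__.items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class StudyReport:
    """All tables produced by one study run, plus run metadata."""

    descriptives: pd.DataFrame
    median_tests: pd.DataFrame
    models: pd.DataFrame
    biomarker_assoc: pd.DataFrame
    ltl_lesions: pd.DataFrame
    delta_lesions: pd.DataFrame
    metadata: dict = field(default_factory=dict)
    log: list[str] = field(default_factory=list)

    _FILES = {
        "descriptives": "table1_descriptives.tsv",
        "median_tests": "median_tests.tsv",
        "models": "table2_models.tsv",
        "biomarker_assoc": "table3_biomarkers.tsv",
        "ltl_lesions": "table4_ltl_lesions.tsv",
        "delta_lesions": "table5_delta_lesions.tsv",
    }

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for attr, fname in self._FILES.items():
            getattr(self, attr).to_csv(
                out / fname, sep="\t", index=False, float_format=_FLOAT_FMT
            )
        with open(out / "run_metadata.json", "w") as fh:
            json.dump(self.metadata, fh, indent=2, sort_keys=True)
        with open(out / "run.log", "w") as fh:
            fh.write("\n".join(self.log) + "\n")


# ---------------------------------------------------------------------------
# descriptive statistics


def run_descriptives(phen: pd.DataFrame, value: str = "ts_ratio") -> pd.DataFrame:
    """Mean/median/SD/min/max/range by cohort, time point and sex.

    Each cohort x timepoint cell is reported for females, males and both
    sexes combined ("Total"); single-observation groups report an empty
    SD and groups with no data report empty markers throughout.
    """
    for col in ("cohort", "timepoint", "sex"):
        if col not in phen.columns:
            raise KeyError(f"phenotype table lacks column {col!r}")
    rows = []
    cohorts = sorted(phen["cohort"].unique())
    timepoints = sorted(phen["timepoint"].unique())
    for cohort in cohorts:
        for tp in timepoints:
            cell = phen[(phen["cohort"] == cohort) & (phen["timepoint"] == tp)]
            for sex_label, sel in (("F", cell[cell["sex"] == "F"]),
                                   ("M", cell[cell["sex"] == "M"]),
                                   ("Total", cell)):
                vals = pd.to_numeric(sel[value], errors="coerce").dropna()
                if len(vals) == 0:
                    rows.append((cohort, tp, sex_label, 0) + (np.nan,) * 6)
                    continue
                sd = vals.std(ddof=1) if len(vals) > 1 else np.nan
                rows.append((
                    cohort, tp, sex_label, len(vals), vals.mean(),
                    vals.median(), sd, vals.min(), vals.max(),
                    vals.max() - vals.min(),
                ))
    return pd.DataFrame(rows, columns=[
        "cohort", "timepoint", "sex", "n", "mean", "median", "sd",
        "min", "max", "range",
    ])


# ---------------------------------------------------------------------------
# analysis-frame construction


def _int_series(s: pd.Series, name: str = "") -> pd.Series:
    tv = TraitVector.from_series(s, "raw", name)
    return inverse_normal_transform(tv).to_series()


def _wide(phen: pd.DataFrame, value: str = "ts_ratio") -> pd.DataFrame:
    """Per-animal frame: covariates plus the trait at each time point."""
    base_cols = ["cohort", "sex", "female", "age", "diet"]
    first = phen.drop_duplicates("id").set_index("id")[base_cols]
    for tp in sorted(phen["timepoint"].unique()):
        sub = phen[phen["timepoint"] == tp].set_index("id")[value]
        first[f"{value}_{tp}"] = pd.to_numeric(sub, errors="coerce")
    secondary = [c for c in phen.columns
                 if c not in {"id", "timepoint", value, *base_cols}]
    for c in secondary:
        first[c] = pd.to_numeric(
            phen.drop_duplicates("id").set_index("id")[c], errors="coerce"
        )
    return first


def _classify_secondary(cols, cfg: StudyConfig):
    if cfg.biomarkers is not None or cfg.lesions is not None:
        biomarkers = list(cfg.biomarkers or ())
        lesions = list(cfg.lesions or ())
    else:
        lesions = [c for c in cols
                   if any(k in c.lower() for k in LESION_KEYWORDS)]
        biomarkers = [c for c in cols if c not in lesions]
    return biomarkers, lesions


# ---------------------------------------------------------------------------
# stages


def _median_test_stage(phen: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Raw-scale exact-permutation median comparisons."""
    rows = []
    value = "ts_ratio"
    timepoints = sorted(phen["timepoint"].unique())
    cohorts = sorted(phen["cohort"].unique())

    def grab(cohort=None, tp=None, sex=None):
        sel = phen
        if cohort is not None:
            sel = sel[sel["cohort"] == cohort]
        if tp is not None:
            sel = sel[sel["timepoint"] == tp]
        if sex is not None:
            sel = sel[sel["sex"] == sex]
        return pd.to_numeric(sel[value], errors="coerce").dropna().to_numpy()

    def add(label, a, b):
        if len(a) == 0 or len(b) == 0:
            return
        res = exact_mwu_test(a, b, "two_sided", seed=seed)
        rows.append((label, len(a), len(b), float(np.median(a)),
                     float(np.median(b)), res.statistic, res.p_value,
                     res.method))

    if len(cohorts) == 2:
        c0, c1 = cohorts
        for tp in timepoints:
            for sex, tag in ((None, "combined"), ("F", "F"), ("M", "M")):
                add(f"{c0}_vs_{c1}@{tp}:{tag}",
                    grab(c0, tp, sex), grab(c1, tp, sex))
    for cohort in cohorts:
        for tp in timepoints:
            add(f"F_vs_M@{cohort}:{tp}", grab(cohort, tp, "F"),
                grab(cohort, tp, "M"))
        if len(timepoints) == 2:
            add(f"{timepoints[0]}_vs_{timepoints[1]}@{cohort}",
                grab(cohort, timepoints[0]), grab(cohort, timepoints[1]))
    # raw attrition between cohorts
    if len(cohorts) == 2 and len(timepoints) == 2:
        w = _wide(phen)
        d = (w[f"{value}_{timepoints[0]}"] - w[f"{value}_{timepoints[1]}"])
        a = d[w["cohort"] == cohorts[0]].dropna().to_numpy()
        b = d[w["cohort"] == cohorts[1]].dropna().to_numpy()
        add(f"raw_delta:{cohorts[0]}_vs_{cohorts[1]}", a, b)
    return pd.DataFrame(rows, columns=[
        "comparison", "n_a", "n_b", "median_a", "median_b",
        "rank_sum", "p_value", "method",
    ])


def _model_row(table, fit, p_values, n, model_label):
    for name, (est, se) in fit.beta.items():
        if name == "intercept":
            continue
        table.append((model_label, name, est, se, p_values.get(name, np.nan), n))
    table.append((model_label, "h2", fit.h2, fit.h2_se,
                  p_values.get("h2", np.nan), n))


def _fit_and_test(trait_df, covariates, kinship, model_label, table,
                  test_h2=True):
    spec = PolygenicModelSpec("trait", tuple(covariates), kinship)
    fit = fit_polygenic(spec, trait_df)
    p_values = {c: lrt_covariate(spec, trait_df, c) for c in covariates}
    if test_h2:
        p_values["h2"] = lrt_heritability(spec, trait_df)
    _model_row(table, fit, p_values, fit.n, model_label)
    return fit


def _model_stage(phen, kinship) -> tuple[pd.DataFrame, dict[str, pd.Series]]:
    """Per-cohort and combined polygenic models; returns the Table-2-style
    frame and the adjusted traits needed downstream."""
    table: list[tuple] = []
    value = "ts_ratio"
    timepoints = sorted(phen["timepoint"].unique())
    cohorts = sorted(phen["cohort"].unique())
    w = _wide(phen)
    adjusted: dict[str, pd.Series] = {}

    # per-cohort models with sex, age and age-by-sex interaction
    for cohort in cohorts:
        sub = w[w["cohort"] == cohort]
        for tp in timepoints:
            col = f"{value}_{tp}"
            raw = sub[col].dropna()
            if len(raw) < 10:
                continue
            df = sub.loc[raw.index, ["female", "age"]].copy()
            df["trait"] = _int_series(raw)
            df["age_x_female"] = df["age"] * df["female"]
            _fit_and_test(df, ("female", "age", "age_x_female"), kinship,
                          f"percohort:{cohort}:{tp}", table)

    if len(timepoints) < 2:
        return _finish_models(table), adjusted

    t0, t2 = timepoints
    two_cohorts = len(cohorts) == 2
    # combined baseline model: sex + age + heritability
    base = w[f"{value}_{t0}"].dropna()
    df0 = w.loc[base.index, ["female", "age"]].copy()
    df0["trait"] = _int_series(base)
    _fit_and_test(df0, ("female", "age"), kinship, "combined:baseline", table)

    # combined endpoint model: sex + age (+ diet when both cohorts present)
    end = w[f"{value}_{t2}"].dropna()
    end_covs = ("female", "age", "diet") if two_cohorts else ("female", "age")
    df2 = w.loc[end.index, list(end_covs)].copy()
    df2["trait"] = _int_series(end)
    _fit_and_test(df2, end_covs, kinship, "combined:endpoint", table)

    # delta-LTL from sex/age-adjusted i-normal residuals
    cov = w[["female", "age"]]
    res0 = residualize(
        TraitVector(base.index.to_numpy(), _int_series(base).to_numpy(),
                    "inormal", "ltl_t0"), cov)
    res2 = residualize(
        TraitVector(end.index.to_numpy(), _int_series(end).to_numpy(),
                    "inormal", "ltl_t2"), cov)
    delta = delta_ltl(res0, res2, "adjusted_residual").to_series()
    adjusted["delta_combined"] = delta
    adjusted["ltl_t0_adj"] = res0.to_series()
    adjusted["ltl_t2_adj"] = res2.to_series()
    if two_cohorts:
        # diet effect on attrition (diet is constant in one-cohort runs)
        dd = w.loc[delta.index, ["diet"]].copy()
        dd["trait"] = delta
        _fit_and_test(dd, ("diet",), kinship, "combined:delta", table)

    # per-cohort delta from i-normal scores within cohort
    for cohort in cohorts:
        sub = w[w["cohort"] == cohort]
        raw0 = sub[f"{value}_{t0}"].dropna()
        raw2 = sub[f"{value}_{t2}"].dropna()
        if min(len(raw0), len(raw2)) < 10:
            continue
        i0 = TraitVector(raw0.index.to_numpy(), _int_series(raw0).to_numpy(),
                         "inormal", "ltl_t0")
        i2 = TraitVector(raw2.index.to_numpy(), _int_series(raw2).to_numpy(),
                         "inormal", "ltl_t2")
        d = delta_ltl(i0, i2, "raw_inormal").to_series()
        adjusted[f"delta_{cohort}"] = d
        df = sub.loc[d.index, ["female", "age"]].copy()
        df["trait"] = d
        _fit_and_test(df, ("female", "age"), kinship,
                      f"percohort_delta:{cohort}", table)
    return _finish_models(table), adjusted


def _finish_models(table) -> pd.DataFrame:
    return pd.DataFrame(table, columns=[
        "model", "parameter", "mle", "se", "p_value", "n",
    ])


def _assoc_frame(rows: list[tuple[str, AssociationRow]]) -> pd.DataFrame:
    return pd.DataFrame(
        [(label, a.r2, a.r, a.p, a.n) for label, a in rows],
        columns=["trait", "r2", "r", "p_value", "n"],
    )


def _standardized(s: pd.Series) -> pd.Series:
    sd = s.std(ddof=1)
    return (s - s.mean()) / sd if sd > 0 else s * 0.0


def _biomarker_stage(w, adjusted, biomarkers, kinship) -> pd.DataFrame:
    """Biomarker -> endpoint-LTL associations in the kinship model.

    The predictor enters sex/age-adjusted and standardized; the trait is
    the inverse-normal endpoint LTL with sex and age as covariates,
    mirroring an analysis of adjusted biomarker concentrations.
    """
    rows = []
    if "ltl_t2_adj" not in adjusted:
        return _assoc_frame(rows)
    trait = adjusted["ltl_t2_adj"]
    for bm in biomarkers:
        raw = w[bm].dropna()
        if len(raw) < 10:
            continue
        adj = residualize(TraitVector.from_series(raw, "raw", bm),
                          w[["female", "age"]])
        df = w.loc[raw.index, ["female", "age"]].copy()
        df["trait"] = trait
        df[bm] = _standardized(adj.to_series())
        spec = PolygenicModelSpec("trait", ("female", "age"), kinship)
        rows.append((bm, covariate_association(spec, df, bm)))
    return _assoc_frame(rows)


def _lesion_stage(w, adjusted, lesions, kinship, predictor_key,
                  predictor_label) -> pd.DataFrame:
    """Lesion-extent associations with adjusted LTL or delta-LTL.

    Trait is the inverse-normal lesion extent; the adjusted predictor is
    standardized; sum and mean of the per-artery extents are appended as
    composite rows.
    """
    rows = []
    if predictor_key not in adjusted or not lesions:
        return _assoc_frame(rows)
    pred = _standardized(adjusted[predictor_key]).rename(predictor_label)
    frames = {les: w[les].dropna() for les in lesions}
    composite = {}
    if len(lesions) > 1:
        block = w[lesions].dropna()
        composite = {"sum_of_lesions": block.sum(axis=1),
                     "mean_of_lesions": block.mean(axis=1)}
    for label, raw in {**frames, **composite}.items():
        if len(raw) < 10:
            continue
        df = w.loc[raw.index, ["female", "age"]].copy()
        df["trait"] = _int_series(raw)
        df[predictor_label] = pred
        spec = PolygenicModelSpec("trait", ("female", "age"), kinship)
        rows.append((label, covariate_association(spec, df, predictor_label)))
    return _assoc_frame(rows)


# ---------------------------------------------------------------------------
# full study


def run_full_study(cfg: StudyConfig) -> StudyReport:
    """Execute every stage of the study and write the report.

    Stage order: descriptives, raw-scale median tests, per-cohort and
    combined polygenic models, delta-LTL construction and diet test,
    biomarker associations, lesion associations for LTL and delta-LTL.
    A stage failure aborts the run with a stage-tagged error; tables
    already produced are retained in the written output directory.
    """
    log: list[str] = []
    t_start = time.perf_counter()

    def tick(stage: str) -> None:
        log.append(f"{stage}: done at +{time.perf_counter() - t_start:.2f}s")

    if cfg.scenario is not None:
        scenario = get_scenario(cfg.scenario).replace(seed=cfg.seed)
        study = simulate_study(scenario)
        phen = study.phenotypes
        kinship = study.kinship
        source = {"mode": "simulation", "scenario": cfg.scenario}
    else:
        phen = pd.read_csv(cfg.phenotype_path, dtype={"id": str})
        ped = read_pedigree(cfg.pedigree_path)
        kinship = compute_kinship(ped)
        source = {"mode": "real",
                  "phenotypes": str(cfg.phenotype_path),
                  "pedigree": str(cfg.pedigree_path)}
    tick("load")

    report = StudyReport(
        descriptives=pd.DataFrame(), median_tests=pd.DataFrame(),
        models=pd.DataFrame(), biomarker_assoc=pd.DataFrame(),
        ltl_lesions=pd.DataFrame(), delta_lesions=pd.DataFrame(),
    )
    stage = "descriptives"
    try:
        report.descriptives = run_descriptives(phen)
        tick(stage)
        stage = "median_tests"
        report.median_tests = _median_test_stage(phen, cfg.seed)
        tick(stage)
        stage = "models"
        report.models, adjusted = _model_stage(phen, kinship)
        tick(stage)
        w = _wide(phen)
        base_cols = {"cohort", "sex", "female", "age", "diet"}
        secondary = [c for c in w.columns
                     if c not in base_cols and not c.startswith("ts_ratio_")]
        biomarkers, lesions = _classify_secondary(secondary, cfg)
        stage = "biomarker_associations"
        report.biomarker_assoc = _biomarker_stage(w, adjusted, biomarkers,
                                                  kinship)
        tick(stage)
        stage = "lesion_associations"
        report.ltl_lesions = _lesion_stage(
            w, adjusted, lesions, kinship, "ltl_t2_adj", "adj_ltl")
        report.delta_lesions = _lesion_stage(
            w, adjusted, lesions, kinship, "delta_combined", "adj_delta")
        tick(stage)
    except Exception as exc:
        report.metadata = _metadata(cfg, source, failed_stage=stage)
        report.log = log + [f"{stage}: FAILED ({exc})"]
        report.write(cfg.out_dir)
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    n_tests = (len(report.median_tests)
               + int(report.models["p_value"].notna().sum())
               + len(report.biomarker_assoc)
               + len(report.ltl_lesions) + len(report.delta_lesions))
    report.metadata = _metadata(cfg, source, n_tests=n_tests)
    report.log = log + [f"total hypothesis tests performed: {n_tests}",
                        "no multiple-testing adjustment applied"]
    report.write(cfg.out_dir)
    return report


def _metadata(cfg: StudyConfig, source: dict, n_tests: int | None = None,
              failed_stage: str | None = None) -> dict:
    md = {
        "package": "telodyn",
        "version": __version__,
        "seed": cfg.seed,
        "config_digest": cfg.digest(),
        **source,
    }
    if n_tests is not None:
        md["n_hypothesis_tests"] = n_tests
    if failed_stage is not None:
        md["failed_stage"] = failed_stage
    return md


# ---------------------------------------------------------------------------
# parameter-recovery harness


def recover_scenario(name: str, n_replicates: int = 200,
                     base_seed: int = 1) -> pd.DataFrame:
    """Replicate a library scenario and re-estimate its parameters.

    For each replicate (seeds ``base_seed .. base_seed+n_replicates-1``)
    a fresh pedigree and phenotype study is generated and the estimators
    appropriate to the scenario are run: polygenic fits with sex/age
    (/diet) covariates for the combined-cohort scenarios, kinship-model
    associations for the lesion and biomarker scenarios, and the
    age -> delta-LTL association for the control-attrition scenario.
    Returns one row per replicate with the recovered quantities.
    """
    scenario = get_scenario(name)
    rows = []
    for k in range(n_replicates):
        seed = base_seed + k
        study = simulate_study(scenario.replace(seed=seed))
        rows.append({"seed": seed, **_recover_once(study)})
    return pd.DataFrame(rows)


def _recover_once(study) -> dict:
    scn: GeneratorScenario = study.truth
    phen = study.phenotypes
    kinship: KinshipMatrix = study.kinship
    w = _wide(phen)
    out: dict[str, float] = {}

    if scn.name in ("baseline_combined", "combined_2yr"):
        tp = "t0" if scn.name == "baseline_combined" else "t2"
        covs = ("female", "age") if tp == "t0" else ("female", "age", "diet")
        raw = w[f"ts_ratio_{tp}"].dropna()
        df = w.loc[raw.index, list(covs)].copy()
        df["trait"] = _int_series(raw)
        spec = PolygenicModelSpec("trait", covs, kinship)
        fit = fit_polygenic(spec, df)
        out["h2"] = fit.h2
        out["beta_sex"] = fit.beta["female"][0]
        out["beta_age"] = fit.beta["age"][0]
        if "diet" in covs:
            out["beta_diet"] = fit.beta["diet"][0]
        out["p_h2"] = lrt_heritability(spec, df)
        if "diet" in covs:
            out["p_diet"] = lrt_covariate(spec, df, "diet")
        return out

    # association scenarios: build adjusted endpoint LTL and delta-LTL
    raw0 = w["ts_ratio_t0"].dropna()
    raw2 = w["ts_ratio_t2"].dropna()
    cov = w[["female", "age"]]
    res0 = residualize(TraitVector(raw0.index.to_numpy(),
                                   _int_series(raw0).to_numpy(),
                                   "inormal", "ltl_t0"), cov)
    res2 = residualize(TraitVector(raw2.index.to_numpy(),
                                   _int_series(raw2).to_numpy(),
                                   "inormal", "ltl_t2"), cov)
    adj2 = res2.to_series()
    delta = delta_ltl(res0, res2, "adjusted_residual").to_series()

    if scn.name == "control_delta_age":
        # separate-cohort attrition is the plain inverse-normal difference
        # (adjusting for age first would erase the age effect under study)
        i0 = TraitVector(raw0.index.to_numpy(), _int_series(raw0).to_numpy(),
                         "inormal", "ltl_t0")
        i2 = TraitVector(raw2.index.to_numpy(), _int_series(raw2).to_numpy(),
                         "inormal", "ltl_t2")
        d_raw = delta_ltl(i0, i2, "raw_inormal").to_series()
        df = w.loc[d_raw.index, ["female", "age"]].copy()
        df["trait"] = _int_series(d_raw)
        df["age_pred"] = _standardized(w.loc[d_raw.index, "age"])
        spec = PolygenicModelSpec("trait", ("female",), kinship)
        a = covariate_association(spec, df, "age_pred")
        out["r2_age"] = a.r2
        out["r_age"] = a.r
        return out

    for name in scn.assoc_r:
        raw = w[name].dropna()
        is_delta = name.endswith("_delta")
        pred = delta if is_delta else adj2
        if scn.name == "biomarker_7wk":
            # biomarker predicts LTL: trait = adjusted LTL
            df = w.loc[raw.index, ["female", "age"]].copy()
            df["trait"] = adj2
            df[name] = _standardized(raw)
            spec = PolygenicModelSpec("trait", ("female", "age"), kinship)
            a = covariate_association(spec, df, name)
        else:
            # LTL / delta-LTL predicts lesion extent: trait = lesion
            df = w.loc[raw.index, ["female", "age"]].copy()
            df["trait"] = _int_series(raw)
            df["pred"] = _standardized(pred)
            spec = PolygenicModelSpec("trait", ("female", "age"), kinship)
            a = covariate_association(spec, df, "pred")
        out[f"r_{name}"] = a.r
        out[f"r2_{name}"] = a.r2
        out[f"p_{name}"] = a.p
    return out
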
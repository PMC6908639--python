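"""Synthetic pedigree-and-phenotype generator.

Emulates a longitudinal diet-challenge study in a multi-generation
pedigreed breeding colony: two cohorts of adult animals (ages ~6-17 y,
both sexes) sampled from the youngest generations of a closed colony,
with relative leukocyte telomere length (T/S ratio) measured at baseline
and after two years.  On the inverse-normal analysis scale the phenotype
follows the additive polygenic model

    y_it = mu_t + b_sex*female_i + b_age*(age_i - mean age)
           + b_diet*diet_i*[t = t2] - gamma*age_i_std*[t = t2]
           + g_i + u_i + e_it

with g ~ N(0, h2 * 2*Phi) the additive genetic values shared across time
points, u an animal-level environmental effect that sets the within-animal
test-retest correlation, and e_it independent noise scaled so the residual
variance at each time point is 1.  The gamma term generates age-dependent
attrition (so that age explains a target fraction of delta-LTL variance).
Secondary traits (CVD biomarkers, atherosclerotic lesion extents) are
drawn as r*z + sqrt(1-r^2)*noise against the standardized residual of
endpoint LTL (or of delta-LTL for names suffixed ``_delta``), giving an
exact target population correlation.

Observed T/S ratios are a fixed monotone (log-linear) map of the latent
scale, so the analysis chain's inverse-normal transform recovers the
latent structure without the generator leaking analysis-scale values.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .pedigree import KinshipMatrix, Pedigree, compute_kinship
from .polygenic import CovarianceError

__all__ = [
    "GeneratorScenario",
    "SimulatedStudy",
    "generate_pedigree",
    "simulate_phenotypes",
    "simulate_study",
    "scenario_library",
    "get_scenario",
    "generation_depths",
]

#: Median T/S anchor per time point and log-scale spread of the monotone
#: map from the latent normal scale to the observed ratio scale.
TS_ANCHORS = {"t0": 0.92, "t2": 0.90}
TS_LOG_SPREAD = 0.12


class GenerationError(RuntimeError):
    """Impossible mating structure (no available sires or dams)."""


@dataclass(frozen=True)
class GeneratorScenario:
    """Parameters of one simulated study condition.

    Effect sizes are on the inverse-normal (SD-unit) analysis scale;
    ``beta_age`` is per year of age.  ``assoc_r`` maps secondary-trait
    names to their target correlation with residual endpoint LTL (names
    ending in ``_delta`` target the LTL-attrition residual instead).
    ``r2_age_attrition`` is the fraction of delta-LTL variance explained
    by age.  ``within_animal_corr`` is the total test-retest correlation
    of the latent phenotype across the two time points.
    """

    name: str
    n_individuals: int
    n_generations: int = 6
    h2: float = 0.27
    beta_sex: float = 0.0
    beta_age: float = 0.0
    beta_diet: float = 0.0
    assoc_r: dict[str, float] = field(default_factory=dict)
    age_range: tuple[float, float] = (6.0, 17.0)
    sex_ratio: float = 0.44
    seed: int = 0
    cohorts: tuple[str, ...] = ("control", "experimental")
    within_animal_corr: float = 0.6
    r2_age_attrition: float = 0.0
    n_founders: int = 36
    offspring_mean: float = 2.8
    sires_per_generation: int = 4

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must lie in [0, 1]")
        for k, r in self.assoc_r.items():
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"assoc_r[{k!r}] outside [-1, 1]")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range must have min < max")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must lie in [0, 1]")
        if not 0.0 <= self.r2_age_attrition < 1.0:
            raise ValueError("r2_age_attrition must lie in [0, 1)")
        object.__setattr__(self, "assoc_r", dict(self.assoc_r))
        object.__setattr__(self, "age_range", tuple(self.age_range))
        object.__setattr__(self, "cohorts", tuple(self.cohorts))

    def replace(self, **kw) -> "GeneratorScenario":
        return dataclasses.replace(self, **kw)

    # -- config round-trip ------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["age_range"] = list(self.age_range)
        d["cohorts"] = list(self.cohorts)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorScenario":
        d = dict(d)
        if "age_range" in d:
            d["age_range"] = tuple(d["age_range"])
        if "cohorts" in d:
            d["cohorts"] = tuple(d["cohorts"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorScenario":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class SimulatedStudy:
    """One simulated study: pedigree, phenotype table, generating truth."""

    pedigree: Pedigree
    phenotypes: pd.DataFrame = field(repr=False)
    truth: GeneratorScenario
    kinship: KinshipMatrix = field(repr=False)
    genetic_values: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        known = set(self.pedigree.ids)
        missing = set(self.phenotypes["id"].astype(str)) - known
        if missing:
            raise ValueError(
                f"phenotyped ids absent from pedigree: {sorted(missing)[:5]}"
            )

    def write_phenotypes(self, path) -> None:
        self.phenotypes.to_csv(path, index=False)


def generate_pedigree(n_founders: int = 36, n_generations: int = 6,
                      offspring_dist=("poisson", 2.8), seed: int = 0, *,
                      sires_per_generation: int = 4,
                      generation_size: tuple[int, int] = (150, 190)) -> Pedigree:
    """Discrete-generation closed colony with polygynous random mating.

    Founders are unrelated; each later generation is produced by mating
    every female of the previous generation to sires drawn from a small
    pool of ``sires_per_generation`` males (as in a harem-structured
    breeding colony), with per-dam litter sizes from ``offspring_dist``
    (``("poisson", mean)`` or ``("fixed", k)``).  Generation sizes are
    clamped to the ``generation_size`` (floor, cap) band — short
    generations are topped up with extra offspring of random pairs and
    long ones are thinned — which keeps colony size, and hence the
    sampling pool for study cohorts, stable across seeds.  The restricted
    sire pool and closed colony make kinship accumulate across
    generations; the defaults place the mean pairwise kinship of the
    youngest two generations in the 0.10-0.20 band.
    """
    if n_founders < 2:
        raise ValueError("need at least 2 founders")
    if n_generations < 1:
        raise ValueError("need at least 1 generation")
    floor, cap = generation_size
    if not 0 < floor <= cap:
        raise ValueError("generation_size must satisfy 0 < floor <= cap")
    rng = np.random.default_rng(np.random.SeedSequence([1, seed]))

    kind, param = offspring_dist
    if kind == "poisson":
        def draw_litter() -> int:
            return int(rng.poisson(param))
    elif kind == "fixed":
        def draw_litter() -> int:
            return int(param)
    else:
        raise ValueError(f"unknown offspring distribution {kind!r}")

    rows: list[tuple] = []
    counter = 0

    def new_id(gen: int) -> str:
        nonlocal counter
        counter += 1
        return f"g{gen}i{counter:04d}"

    # founders: forced half-and-half so matings are always possible
    gen_members: list[tuple[str, str]] = []
    for k in range(n_founders):
        sex = "F" if k % 2 == 0 else "M"
        iid = new_id(0)
        age = float(rng.uniform(6.0, 17.0)) + 5.0 * (n_generations - 1)
        rows.append((iid, None, None, sex, round(age, 2)))
        gen_members.append((iid, sex))

    for gen in range(1, n_generations):
        males = [i for i, s in gen_members if s == "M"]
        females = [i for i, s in gen_members if s == "F"]
        if not males or not females:
            raise GenerationError(
                f"generation {gen - 1} has no available "
                f"{'sires' if not males else 'dams'}"
            )
        n_sires = min(sires_per_generation, len(males))
        sires = list(rng.choice(males, size=n_sires, replace=False))
        matings: list[tuple[str, str]] = []
        for dam in females:
            matings.extend(
                (sires[int(rng.integers(n_sires))], dam)
                for _ in range(draw_litter())
            )
        # clamp the generation size to keep the colony stable across seeds
        if len(matings) > cap:
            keep = rng.choice(len(matings), size=cap, replace=False)
            matings = [matings[k] for k in sorted(keep)]
        while len(matings) < floor:
            dam = females[int(rng.integers(len(females)))]
            matings.append((sires[int(rng.integers(n_sires))], dam))
        next_members: list[tuple[str, str]] = []
        for sire, dam in matings:
            sex = "F" if rng.random() < 0.5 else "M"
            iid = new_id(gen)
            age = float(rng.uniform(6.0, 17.0)) + 5.0 * (n_generations - 1 - gen)
            rows.append((iid, sire, dam, sex, round(age, 2)))
            next_members.append((iid, sex))
        gen_members = next_members

    table = pd.DataFrame(rows, columns=["id", "sire", "dam", "sex", "age"])
    return Pedigree(table)


def generation_depths(ped: Pedigree) -> dict[str, int]:
    """Generation depth of every individual: founders 0, otherwise
    1 + max(parental depths)."""
    depth: dict[str, int] = {}
    parent_of = {
        str(r["id"]): (r["sire"], r["dam"]) for _, r in ped.table.iterrows()
    }
    for iid in ped.topological_order:
        s, d = parent_of[iid]
        cand = [depth[str(p)] for p in (s, d) if pd.notna(p)]
        depth[iid] = 1 + max(cand) if cand else 0
    return depth


def _sample_cohort(ped: Pedigree, scenario: GeneratorScenario,
                   rng: np.random.Generator,
                   cohort_ids: list[str] | None = None) -> pd.DataFrame:
    """Sample study animals (with target sex ratio) from the youngest two
    generations of the pedigree, or take a prescribed id list."""
    if cohort_ids is not None:
        sex_of = dict(zip(ped.table["id"].astype(str), ped.table["sex"]))
        chosen = np.asarray([str(i) for i in cohort_ids], dtype=object)
        sex = np.asarray([sex_of[i] for i in chosen], dtype=object)
        n = len(chosen)
    else:
        depth = generation_depths(ped)
        top = max(depth.values())
        pool = ped.table[[d >= top - 1 for d in
                          (depth[str(i)] for i in ped.table["id"])]]
        n = scenario.n_individuals
        n_f = int(round(scenario.sex_ratio * n))
        females = pool.loc[pool["sex"] == "F", "id"].astype(str).to_numpy()
        males = pool.loc[pool["sex"] == "M", "id"].astype(str).to_numpy()
        if len(females) < n_f or len(males) < n - n_f:
            raise GenerationError(
                f"cohort pool too small: need {n_f}F/{n - n_f}M, "
                f"have {len(females)}F/{len(males)}M"
            )
        chosen = np.concatenate([
            rng.choice(females, size=n_f, replace=False),
            rng.choice(males, size=n - n_f, replace=False),
        ])
        sex = np.array(["F"] * n_f + ["M"] * (n - n_f))
        order = rng.permutation(n)
        chosen, sex = chosen[order], sex[order]

    cohorts = scenario.cohorts
    if len(cohorts) == 2:
        n_first = n // 2
        cohort = np.array([cohorts[0]] * n_first + [cohorts[1]] * (n - n_first))
    else:
        cohort = np.array([cohorts[0]] * n)
    lo, hi = scenario.age_range
    age = rng.uniform(lo, hi, size=n).round(2)
    return pd.DataFrame(
        {"id": chosen, "sex": sex, "cohort": cohort, "age": age}
    )


def simulate_phenotypes(ped: Pedigree, scenario: GeneratorScenario,
                        cohort_ids: list[str] | None = None) -> SimulatedStudy:
    """Draw a two-time-point phenotype study on a pedigree.

    See the module docstring for the generative model.  The residual
    (non-fixed-effect) variance of the latent phenotype is normalized to
    sigma2_g + sigma2_e = 1 at baseline.  Note the *sample* variance
    within a related cohort is smaller in expectation — by about
    sigma2_g times the mean off-diagonal of 2*Phi — because relatives
    share genetic values.  ``cohort_ids`` phenotypes a prescribed cohort
    instead of sampling one.
    """
    rng = np.random.default_rng(np.random.SeedSequence([2, scenario.seed]))
    cohort_df = _sample_cohort(ped, scenario, rng, cohort_ids)
    ids = list(cohort_df["id"])
    n = len(ids)

    km = compute_kinship(ped).submatrix(ids)
    A = km.additive_relationship()

    h2 = scenario.h2
    sigma2_e = 1.0 - h2
    c = float(np.clip(scenario.within_animal_corr - h2, 0.0, sigma2_e))
    v0 = sigma2_e - c
    gamma2 = scenario.r2_age_attrition * 2.0 * v0
    v2 = v0 - gamma2
    if v2 < 0:
        raise ValueError(
            "r2_age_attrition too large for the residual variance budget"
        )

    if h2 > 0:
        try:
            L = np.linalg.cholesky(A + 1e-10 * np.eye(n))
        except np.linalg.LinAlgError as exc:
            raise CovarianceError("2*Phi is not positive definite") from exc
        g = np.sqrt(h2) * (L @ rng.standard_normal(n))
    else:
        g = np.zeros(n)
    u = np.sqrt(c) * rng.standard_normal(n) if c > 0 else np.zeros(n)
    e0 = np.sqrt(v0) * rng.standard_normal(n) if v0 > 0 else np.zeros(n)
    e2 = np.sqrt(v2) * rng.standard_normal(n) if v2 > 0 else np.zeros(n)

    female = (cohort_df["sex"] == "F").to_numpy(float)
    diet = (cohort_df["cohort"] == "experimental").to_numpy(float)
    age = cohort_df["age"].to_numpy(float)
    age_c = age - age.mean()
    age_sd = age.std(ddof=1)
    age_std = age_c / age_sd if age_sd > 0 else np.zeros(n)
    gamma = np.sqrt(gamma2)

    fixed_common = scenario.beta_sex * female + scenario.beta_age * age_c
    y0 = fixed_common + g + u + e0
    y2 = (fixed_common + scenario.beta_diet * diet - gamma * age_std
          + g + u + e2)

    # secondary traits: exact target correlation with the standardized
    # residual of endpoint LTL (or of delta-LTL for *_delta names)
    resid_end = g + u + e2
    z_end = resid_end / np.sqrt(h2 + c + v2)
    delta_resid = e0 - e2
    sd_delta = np.sqrt(v0 + v2)
    z_delta = delta_resid / sd_delta if sd_delta > 0 else np.zeros(n)
    secondary: dict[str, np.ndarray] = {}
    for name, r in scenario.assoc_r.items():
        ref = z_delta if name.endswith("_delta") else z_end
        noise = rng.standard_normal(n)
        secondary[name] = r * ref + np.sqrt(1.0 - r * r) * noise

    rows = []
    for t, y in (("t0", y0), ("t2", y2)):
        ts = TS_ANCHORS[t] * np.exp(TS_LOG_SPREAD * y)
        frame = cohort_df.copy()
        frame["timepoint"] = t
        frame["diet"] = diet.astype(int)
        frame["female"] = female.astype(int)
        frame["ts_ratio"] = ts.round(6)
        for name, vals in secondary.items():
            frame[name] = np.round(vals, 6)
        rows.append(frame)
    phen = pd.concat(rows, ignore_index=True)
    cols = ["id", "cohort", "timepoint", "diet", "sex", "female", "age",
            "ts_ratio", *sorted(secondary)]
    phen = phen[cols]

    return SimulatedStudy(
        pedigree=ped,
        phenotypes=phen,
        truth=scenario,
        kinship=km,
        genetic_values=pd.Series(g, index=ids, name="g"),
    )


def simulate_study(scenario: GeneratorScenario) -> SimulatedStudy:
    """Generate a pedigree and phenotypes for one scenario/seed pair."""
    ped = generate_pedigree(
        n_founders=scenario.n_founders,
        n_generations=scenario.n_generations,
        offspring_dist=("poisson", scenario.offspring_mean),
        seed=scenario.seed,
        sires_per_generation=scenario.sires_per_generation,
    )
    return simulate_phenotypes(ped, scenario)


def scenario_library() -> dict[str, GeneratorScenario]:
    """Named study conditions wired to the published effect sizes.

    * ``baseline_combined`` - both cohorts at baseline: h2 = 0.27,
      beta_sex = 0.516, beta_age = -0.089 (n = 211).
    * ``combined_2yr`` - both cohorts after the 2-year challenge:
      h2 = 0.46, beta_sex = 0.218, beta_age = -0.048, beta_diet = -0.486.
    * ``lesion_assoc`` - challenge cohort (n = 106) with lesion extents
      correlated with endpoint LTL (descending aorta, r = -0.247) and
      with attrition (common iliac, r = -0.202).
    * ``biomarker_7wk`` - challenge cohort with the four 7-week serum
      biomarkers associated with endpoint LTL.
    * ``control_delta_age`` - control cohort (n = 105) where age explains
      20% of the variance in delta-LTL.
    """
    lib = [
        GeneratorScenario(
            name="baseline_combined", n_individuals=211,
            h2=0.27, beta_sex=0.516, beta_age=-0.089, beta_diet=0.0,
        ),
        GeneratorScenario(
            name="combined_2yr", n_individuals=211,
            h2=0.46, beta_sex=0.218, beta_age=-0.048, beta_diet=-0.486,
        ),
        GeneratorScenario(
            name="lesion_assoc", n_individuals=106,
            cohorts=("experimental",),
            assoc_r={"descending_aorta": -0.247, "common_iliac_delta": -0.202},
        ),
        GeneratorScenario(
            name="biomarker_7wk", n_individuals=106,
            cohorts=("experimental",),
            assoc_r={"vldlc": -0.241, "apoe": -0.214,
                     "pon1": 0.212, "tas": 0.224},
        ),
        GeneratorScenario(
            name="control_delta_age", n_individuals=105,
            cohorts=("control",), r2_age_attrition=0.20,
        ),
    ]
    return {s.name: s for s in lib}


def get_scenario(name: str) -> GeneratorScenario:
    lib = scenario_library()
    if name not in lib:
        raise KeyError(
            f"unknown scenario {name!r}; available: {sorted(lib)}"
        )
    return lib[name]
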
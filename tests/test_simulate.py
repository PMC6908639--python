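"""Synthetic pedigree-and-phenotype generator: structure, calibration
and reproducibility."""

import numpy as np
import pandas as pd
import pytest

from telodyn import (
    GeneratorScenario,
    compute_kinship,
    generate_pedigree,
    get_scenario,
    mean_pairwise_kinship,
    scenario_library,
    simulate_phenotypes,
    simulate_study,
)
from telodyn.simulate import TS_ANCHORS, TS_LOG_SPREAD, generation_depths


@pytest.fixture(scope="module")
def default_colony():
    return generate_pedigree(seed=11)


def cohort_pool(ped):
    depth = generation_depths(ped)
    top = max(depth.values())
    return [i for i in ped.ids if depth[i] >= top - 1]


class TestPedigreeGeneration:
    def test_structure(self, default_colony):
        ped = default_colony
        t = ped.table
        sex_of = dict(zip(t["id"].astype(str), t["sex"]))
        nonfounders = t[t["sire"].notna()]
        assert (nonfounders["dam"].notna()).all()
        assert all(sex_of[str(s)] == "M" for s in nonfounders["sire"])
        assert all(sex_of[str(d)] == "F" for d in nonfounders["dam"])
        depth = generation_depths(ped)
        assert max(depth.values()) == 5  # six generations, founders at 0

    def test_single_generation_all_founders(self):
        ped = generate_pedigree(n_founders=12, n_generations=1, seed=0)
        km = compute_kinship(ped)
        off = km.phi - np.diag(np.diag(km.phi))
        assert np.all(off == 0)

    def test_full_sib_family_kinship(self):
        ped = generate_pedigree(
            n_founders=2, n_generations=2, offspring_dist=("fixed", 4),
            seed=3, sires_per_generation=1, generation_size=(4, 4),
        )
        km = compute_kinship(ped)
        kids = [i for i in ped.ids if i.startswith("g1")]
        assert len(kids) == 4
        assert mean_pairwise_kinship(km, kids) == 0.25

    def test_default_cohort_kinship_in_band(self, default_colony):
        km = compute_kinship(default_colony)
        mk = mean_pairwise_kinship(km, cohort_pool(default_colony))
        assert 0.10 <= mk <= 0.20

    def test_impossible_mating_raises(self):
        from telodyn.simulate import GenerationError
        with pytest.raises((GenerationError, ValueError)):
            generate_pedigree(n_founders=1, n_generations=3, seed=0)


class TestPhenotypeSimulation:
    def test_seed_reproducibility_byte_identical(self):
        scn = get_scenario("combined_2yr").replace(seed=5)
        a = simulate_study(scn)
        b = simulate_study(scn)
        pd.testing.assert_frame_equal(a.pedigree.table, b.pedigree.table)
        pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)
        assert a.phenotypes.to_csv() == b.phenotypes.to_csv()

    def test_different_seeds_differ(self):
        scn = get_scenario("baseline_combined")
        a = simulate_study(scn.replace(seed=1)).phenotypes
        b = simulate_study(scn.replace(seed=2)).phenotypes
        assert not a["ts_ratio"].equals(b["ts_ratio"])

    def test_phenotyped_ids_exist_in_pedigree(self):
        study = simulate_study(get_scenario("lesion_assoc").replace(seed=9))
        assert set(study.phenotypes["id"]) <= set(study.pedigree.ids)

    def test_h2_zero_means_no_genetic_values(self, default_colony):
        scn = GeneratorScenario(name="null", n_individuals=100, h2=0.0,
                                seed=4)
        study = simulate_phenotypes(default_colony, scn)
        assert np.all(study.genetic_values.to_numpy() == 0.0)

    def test_h2_zero_full_sib_correlation_near_zero(self):
        """Without genetic variance, full sibs are phenotypically no more
        alike than strangers (within-pair correlation ~ 0 at large n)."""
        ped = generate_pedigree(seed=21)
        scn = GeneratorScenario(name="null", n_individuals=260, h2=0.0,
                                within_animal_corr=0.0, seed=8)
        study = simulate_phenotypes(ped, scn)
        phen = study.phenotypes.query("timepoint == 't0'").set_index("id")
        parents = {str(r["id"]): (str(r["sire"]), str(r["dam"]))
                   for _, r in ped.table.iterrows() if pd.notna(r["sire"])}
        pairs = []
        ids = [i for i in phen.index if i in parents]
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                if parents[a] == parents[b]:
                    pairs.append((phen.loc[a, "ts_ratio"],
                                  phen.loc[b, "ts_ratio"]))
        assert len(pairs) > 30
        x, y = np.array(pairs).T
        r = np.corrcoef(np.log(x), np.log(y))[0, 1]
        assert abs(r) < 3.0 / np.sqrt(len(pairs))

    def test_full_heritability_midparent_regression(self):
        """With h2 = 1 and no noise the offspring latent value is exactly
        the mean of the parental values: midparent regression slope 1."""
        ped = generate_pedigree(seed=31)
        scn = GeneratorScenario(name="clone", n_individuals=350, h2=1.0,
                                within_animal_corr=0.0, sex_ratio=0.5,
                                seed=13)
        study = simulate_phenotypes(ped, scn)
        phen = study.phenotypes.query("timepoint == 't0'").set_index("id")
        latent = np.log(phen["ts_ratio"] / TS_ANCHORS["t0"]) / TS_LOG_SPREAD
        parents = {str(r["id"]): (str(r["sire"]), str(r["dam"]))
                   for _, r in ped.table.iterrows() if pd.notna(r["sire"])}
        kid_vals, midparent = [], []
        for iid in latent.index:
            if iid not in parents:
                continue
            s, d = parents[iid]
            if s in latent.index and d in latent.index:
                kid_vals.append(latent[iid])
                midparent.append(0.5 * (latent[s] + latent[d]))
        assert len(kid_vals) > 40
        slope = np.polyfit(midparent, kid_vals, 1)[0]
        # offspring = midparent + Mendelian segregation noise; the
        # regression on midparent has expected slope 1 under h2 = 1
        assert slope == pytest.approx(1.0, abs=0.25)

    def test_marginal_variance_and_association_calibration(self):
        """Across replicates the latent decomposition satisfies
        sigma2_g + sigma2_e = 1: the mean within-cohort sample variance
        matches its analytic expectation 1 - h2*(mean offdiag(2Phi) -
        (mean diag(2Phi) - 1)) within 5%, and secondary-trait
        correlations land within ±0.05 of their targets."""
        scn = get_scenario("lesion_assoc")
        ped = generate_pedigree(seed=41)
        km_full = compute_kinship(ped)
        variances, r_aorta, expected = [], [], []
        for k in range(200):
            study = simulate_phenotypes(ped, scn.replace(seed=1000 + k))
            phen = study.phenotypes.query("timepoint == 't2'").set_index("id")
            latent = (np.log(phen["ts_ratio"] / TS_ANCHORS["t2"])
                      / TS_LOG_SPREAD)
            variances.append(latent.var(ddof=1))
            r_aorta.append(np.corrcoef(latent,
                                       phen["descending_aorta"])[0, 1])
            A = km_full.submatrix(list(phen.index)).additive_relationship()
            n = A.shape[0]
            diag = np.trace(A) / n
            off = (A.sum() - np.trace(A)) / (n * (n - 1))
            expected.append(1.0 + scn.h2 * (diag - 1.0 - off))
        assert np.mean(variances) == pytest.approx(np.mean(expected),
                                                   rel=0.05)
        # the shortfall from 1.0 is entirely the shared-ancestry term
        assert np.mean(expected) == pytest.approx(1.0, abs=0.08)
        assert np.mean(r_aorta) == pytest.approx(-0.247, abs=0.05)

    def test_genetic_covariance_matches_kinship(self):
        """Empirical covariance of the simulated genetic values converges
        to sigma2_g * 2*Phi (spot-checked elementwise at 3 MC SEs)."""
        ped = generate_pedigree(seed=51)
        scn = GeneratorScenario(name="gcheck", n_individuals=80, h2=0.5,
                                seed=0)
        ids = list(simulate_phenotypes(
            ped, scn.replace(seed=2000)).genetic_values.index)
        draws = []
        for k in range(400):
            study = simulate_phenotypes(ped, scn.replace(seed=2000 + k),
                                        cohort_ids=ids)
            draws.append(study.genetic_values.to_numpy())
        G = np.array(draws)
        emp = np.cov(G.T)
        km = compute_kinship(ped).submatrix(list(ids))
        target = scn.h2 * km.additive_relationship()
        n = len(ids)
        # elementwise: at most ~1% of pairs may exceed 3 MC standard
        # errors (multiplicity allowance for ~3000 off-diagonal cells)
        iu = np.triu_indices(n, 1)
        ses = np.array([
            np.std(G[:, i] * G[:, j], ddof=1) / np.sqrt(len(draws))
            for i, j in zip(*iu)
        ])
        exceed = np.abs(emp[iu] - target[iu]) > np.maximum(3 * ses, 0.02)
        assert exceed.mean() <= 0.01
        # structural agreement: variances match and covariances scale 1:1
        assert np.diag(emp).mean() == pytest.approx(np.diag(target).mean(),
                                                    rel=0.05)
        slope = np.polyfit(target[iu], emp[iu], 1)[0]
        assert slope == pytest.approx(1.0, abs=0.1)

    def test_diet_effect_only_at_followup(self):
        """The diet shift applies at the 2-year time point only: the
        cohort gap in median latent LTL is near zero at baseline and
        about beta_diet at follow-up."""
        scn = get_scenario("combined_2yr")
        gaps = {"t0": [], "t2": []}
        for k in range(30):
            study = simulate_study(scn.replace(seed=3000 + k))
            for tp in ("t0", "t2"):
                phen = study.phenotypes.query("timepoint == @tp")
                latent = (np.log(phen["ts_ratio"] / TS_ANCHORS[tp])
                          / TS_LOG_SPREAD)
                gap = (latent[phen["diet"] == 1].mean()
                       - latent[phen["diet"] == 0].mean())
                gaps[tp].append(gap)
        assert np.mean(gaps["t0"]) == pytest.approx(0.0, abs=0.06)
        assert np.mean(gaps["t2"]) == pytest.approx(-0.486, abs=0.08)


class TestScenarioLibrary:
    def test_published_parameters(self):
        lib = scenario_library()
        assert lib["baseline_combined"].h2 == 0.27
        assert lib["baseline_combined"].beta_sex == 0.516
        assert lib["baseline_combined"].beta_age == -0.089
        assert lib["baseline_combined"].n_individuals == 211
        assert lib["combined_2yr"].h2 == 0.46
        assert lib["combined_2yr"].beta_diet == -0.486
        assert lib["lesion_assoc"].assoc_r["descending_aorta"] == -0.247
        assert lib["lesion_assoc"].assoc_r["common_iliac_delta"] == -0.202
        assert lib["biomarker_7wk"].assoc_r["vldlc"] == -0.241
        assert lib["control_delta_age"].r2_age_attrition == 0.20
        assert lib["control_delta_age"].n_individuals == 105

    def test_unknown_scenario_not_found(self):
        with pytest.raises(KeyError, match="unknown scenario"):
            get_scenario("nope")

    def test_yaml_round_trip(self, tmp_path):
        for name, scn in scenario_library().items():
            path = tmp_path / f"{name}.yaml"
            scn.to_yaml(path)
            assert GeneratorScenario.from_yaml(path) == scn

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            GeneratorScenario(name="bad", n_individuals=10, h2=1.5)
        with pytest.raises(ValueError):
            GeneratorScenario(name="bad", n_individuals=10,
                              assoc_r={"x": -2.0})
        with pytest.raises(ValueError):
            GeneratorScenario(name="bad", n_individuals=10,
                              age_range=(17.0, 6.0))
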
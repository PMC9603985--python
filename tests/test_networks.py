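import numpy as np
import pandas as pd
import pytest

from viromix.abundance import relative_abundance
from viromix.io_core import Manifest, SampleRecord
from viromix.networks import (build_network, clinical_index_network,
                              compare_edge_sets, covariate_effect_sizes,
                              spearman)


class TestSpearman:
    def test_monotone_relationship_rho_one(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        rho, _ = spearman(x, np.exp(x))
        assert rho == pytest.approx(1.0)

    def test_reversed_rho_minus_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        rho, _ = spearman(x, x[::-1])
        assert rho == pytest.approx(-1.0)

    def test_hand_example_from_rank_differences(self):
        # d = (-1, 1, -1, 1, 0), sum d^2 = 4, rho = 1 - 6*4/(5*24) = 0.8
        rho, _ = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert rho == pytest.approx(0.8)

    def test_missing_pairs_dropped(self):
        rho, _ = spearman([1, 2, 3, 4, np.nan], [2, 1, 4, 3, 9])
        rho_ref, _ = spearman([1, 2, 3, 4], [2, 1, 4, 3])
        assert rho == pytest.approx(rho_ref)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    def test_exact_permutation_p_agrees_with_enumeration_scale(self):
        rho, p_exact = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5], exact=True)
        # 5! = 120 permutations; p is a multiple of 1/120
        assert 0 < p_exact <= 1
        assert (p_exact * 120) == pytest.approx(round(p_exact * 120))


def _stratum_manifest(n=50, cohort="HC", habitat="saliva"):
    return Manifest([SampleRecord(f"s{i}", f"p{i}", habitat, cohort, 10**6)
                     for i in range(n)])


def _copula_counts(rng, n, strength, sign=1.0):
    """Two NB-like vectors rank-correlated through a shared latent factor."""
    z = rng.normal(size=n)
    w = np.sqrt(strength)
    a_v = w * z + np.sqrt(1 - strength) * rng.normal(size=n)
    a_b = sign * w * z + np.sqrt(1 - strength) * rng.normal(size=n)
    return np.exp(a_v), np.exp(a_b)


def _abund_with_edge(rng, n=50, strength=0.8, n_noise=8):
    v_link, b_link = _copula_counts(rng, n, strength)
    virus = pd.DataFrame({"v_link": v_link,
                          **{f"v{i}": rng.random(n) for i in range(n_noise)}},
                         index=[f"s{i}" for i in range(n)])
    bact = pd.DataFrame({"b_link": b_link,
                         **{f"b{i}": rng.random(n) for i in range(n_noise)}},
                        index=[f"s{i}" for i in range(n)])
    return (virus.div(virus.sum(axis=1), axis=0),
            bact.div(bact.sum(axis=1), axis=0))


class TestBuildNetwork:
    def test_planted_edge_recovered_with_positive_sign(self, rng):
        manifest = _stratum_manifest()
        virus, bact = _abund_with_edge(rng)
        edges = build_network(virus, bact, manifest, "HC", "saliva",
                              mean_threshold=0.0)
        hit = edges[(edges["source"] == "v_link") & (edges["target"] == "b_link")]
        assert len(hit) == 1
        assert hit.iloc[0]["sign"] == "positive"
        assert hit.iloc[0]["rho"] > 0.5

    def test_independent_features_keep_few_edges(self, rng):
        manifest = _stratum_manifest()
        virus = pd.DataFrame(rng.random((50, 25)), index=manifest.sample_ids,
                             columns=[f"v{i}" for i in range(25)])
        bact = pd.DataFrame(rng.random((50, 40)), index=manifest.sample_ids,
                            columns=[f"b{i}" for i in range(40)])
        edges = build_network(virus, bact, manifest, "HC", "saliva",
                              mean_threshold=0.0)
        assert len(edges) / 1000 <= 0.05

    def test_below_threshold_feature_never_tested(self, rng):
        manifest = _stratum_manifest()
        virus, bact = _abund_with_edge(rng)
        virus["rare"] = 1e-9
        edges = build_network(virus, bact, manifest, "HC", "saliva",
                              mean_threshold=1e-6)
        assert "rare" not in set(edges["source"])

    def test_small_stratum_rejected_with_name(self, rng):
        manifest = _stratum_manifest(n=3)
        virus, bact = _abund_with_edge(rng, n=3)
        with pytest.raises(ValueError, match="saliva"):
            build_network(virus, bact, manifest, "HC", "saliva")

    def test_every_edge_significant_and_signed(self, rng):
        manifest = _stratum_manifest()
        virus, bact = _abund_with_edge(rng)
        edges = build_network(virus, bact, manifest, "HC", "saliva",
                              mean_threshold=0.0)
        assert (edges["p_adj"] < 0.05).all()
        assert ((edges["rho"] > 0) == (edges["sign"] == "positive")).all()


class TestCompareEdgeSets:
    def test_identical_sets_all_shared(self):
        net = pd.DataFrame({"source": ["v1", "v2"], "target": ["b1", "b2"]})
        table = compare_edge_sets({"HC": net, "RA": net.copy()})
        assert table.set_index("cohorts")["n_edges"].to_dict() == {"HC&RA": 2}

    def test_disjoint_sets_no_shared(self):
        net1 = pd.DataFrame({"source": ["v1"], "target": ["b1"]})
        net2 = pd.DataFrame({"source": ["v2"], "target": ["b2"]})
        table = compare_edge_sets({"A": net1, "B": net2}).set_index("cohorts")
        assert table["n_edges"].to_dict() == {"A": 1, "B": 1}

    def test_partial_overlap_counts(self):
        a = pd.DataFrame({"source": ["v1", "v2"], "target": ["b1", "b2"]})
        b = pd.DataFrame({"source": ["v2"], "target": ["b2"]})
        table = compare_edge_sets({"A": a, "B": b}).set_index("cohorts")
        assert table["n_edges"].to_dict() == {"A": 1, "A&B": 1}

    def test_unordered_edge_key(self):
        a = pd.DataFrame({"source": ["v1"], "target": ["b1"]})
        b = pd.DataFrame({"source": ["b1"], "target": ["v1"]})
        table = compare_edge_sets({"A": a, "B": b})
        assert table.iloc[0]["cohorts"] == "A&B"


class TestClinicalIndexNetwork:
    def test_planted_link_recovered_with_sign(self, rng):
        manifest = _stratum_manifest(n=60)
        x, y = _copula_counts(rng, 60, 0.7, sign=-1.0)
        abund = pd.DataFrame({"taxonA": x, "noise": rng.random(60)},
                             index=manifest.sample_ids)
        abund = abund.div(abund.sum(axis=1), axis=0)
        indices = pd.DataFrame({"DAS28": y}, index=manifest.sample_ids)
        edges = clinical_index_network(abund, indices, manifest,
                                       mean_threshold=0.0)
        hit = edges[(edges["source"] == "taxonA") & (edges["target"] == "DAS28")]
        assert len(hit) == 1 and hit.iloc[0]["sign"] == "negative"

    def test_shuffled_indices_low_spurious_rate(self, rng):
        manifest = _stratum_manifest(n=60)
        abund = pd.DataFrame(rng.random((60, 40)), index=manifest.sample_ids,
                             columns=[f"t{i}" for i in range(40)])
        indices = pd.DataFrame({f"idx{j}": rng.random(60) for j in range(5)},
                               index=manifest.sample_ids)
        edges = clinical_index_network(abund, indices, manifest,
                                       mean_threshold=0.0)
        assert len(edges) / 200 <= 0.05

    def test_all_missing_index_skipped(self, rng):
        manifest = _stratum_manifest(n=10)
        abund = pd.DataFrame(rng.random((10, 3)), index=manifest.sample_ids,
                             columns=["a", "b", "c"])
        indices = pd.DataFrame({"dead": [np.nan] * 10}, index=manifest.sample_ids)
        edges = clinical_index_network(abund, indices, manifest,
                                       mean_threshold=0.0)
        assert edges.empty


class TestCovariateEffectSizes:
    def _manifest_with_covars(self, rng, n_per=10):
        records = []
        for c_i, cohort in enumerate(["HC", "RA_untreated", "RA_treated"]):
            for i in range(n_per):
                records.append(SampleRecord(
                    f"{cohort}_{i}", f"p{c_i}_{i}", "saliva", cohort, 10**5,
                    covariates={"age": float(rng.normal(50, 8)),
                                "noise": float(rng.normal())}))
        return Manifest(records)

    def test_cohort_effect_detected_on_planted_separation(self, rng):
        manifest = self._manifest_with_covars(rng)
        rows = []
        for rec in manifest:
            mu = np.ones(8)
            mu[["HC", "RA_untreated", "RA_treated"].index(rec.cohort)] += 4
            x = rng.gamma(4.0, mu)
            rows.append(x / x.sum())
        abund = pd.DataFrame(rows, index=manifest.sample_ids)
        table = covariate_effect_sizes(abund, manifest, ["cohort", "noise"],
                                       habitat="saliva", n_perm=99, rng=rng)
        t = table.set_index("covariate")
        assert t.loc["cohort", "r2_adjusted"] > 0.1
        assert t.loc["cohort", "p"] == pytest.approx(1 / 100)

    def test_constant_covariate_skipped(self, rng):
        manifest = Manifest([
            SampleRecord(f"s{i}", f"p{i}", "saliva", "HC", 10,
                         covariates={"flat": 1.0}) for i in range(8)])
        abund = pd.DataFrame(rng.random((8, 4)), index=manifest.sample_ids)
        table = covariate_effect_sizes(abund, manifest, ["flat"],
                                       habitat="saliva", n_perm=49, rng=rng)
        assert table.empty

    def test_duplicate_covariate_identical_entries(self, rng):
        manifest = self._manifest_with_covars(rng)
        abund = pd.DataFrame(rng.random((len(manifest), 6)),
                             index=manifest.sample_ids)
        # same underlying values under two names
        for rec in manifest:
            rec.covariates["age_copy"] = rec.covariates["age"]
        t1 = covariate_effect_sizes(abund, manifest, ["age"], habitat="saliva",
                                    n_perm=49, rng=0)
        t2 = covariate_effect_sizes(abund, manifest, ["age_copy"], habitat="saliva",
                                    n_perm=49, rng=0)
        assert t1.iloc[0]["r2_adjusted"] == pytest.approx(t2.iloc[0]["r2_adjusted"])
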
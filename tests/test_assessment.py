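import dataclasses

import numpy as np
import pytest
from scipy import stats

from pocketassess.assessment import (AssessConfig, AssessmentRecord,
                                     aggregate_patches, classify_exposure,
                                     filter_models_by_rmsd, rank_by,
                                     score_ensemble, spearman, top_k,
                                     variant_site_metrics, zscore_records)
from pocketassess.synthetic_data import perturb_model


def make_record(pf=0.0, gdt=50.0, rmsd=3.0, source="S01", idx=1, z=None):
    return AssessmentRecord(target_id="T", site_id="S", source_id=source,
                            model_index=idx, pf_score=pf, gdt_ts=gdt, tm=0.5,
                            rmsd_global=rmsd, rmsd_local=rmsd / 2, pf_zscore=z)


class TestZscore:
    def test_direct_formula(self):
        records = [make_record(pf=v, source=f"S{i}") for i, v in enumerate([2.0, 4.0, 6.0])]
        out = zscore_records(records)
        np.testing.assert_allclose([r.pf_zscore for r in out],
                                   [-1.224744871, 0.0, 1.224744871], atol=1e-8)

    def test_matches_scipy_zscore(self, rng):
        vals = rng.normal(size=20)
        records = [make_record(pf=v, source=f"S{i:02d}") for i, v in enumerate(vals)]
        out = zscore_records(records)
        np.testing.assert_allclose([r.pf_zscore for r in out],
                                   stats.zscore(vals), atol=1e-12)

    def test_mean_zero_std_one(self, rng):
        records = [make_record(pf=v, source=f"S{i}") for i, v in enumerate(rng.normal(size=9))]
        z = np.array([r.pf_zscore for r in zscore_records(records)])
        assert abs(z.mean()) < 1e-9
        assert abs(z.std() - 1.0) < 1e-9

    def test_constant_scores_error(self):
        records = [make_record(pf=1.0, source=f"S{i}") for i in range(4)]
        with pytest.raises(ValueError, match="identical"):
            zscore_records(records)

    def test_too_few_records(self):
        with pytest.raises(ValueError, match=">= 3"):
            zscore_records([make_record(), make_record()])

    def test_model_1_mode_restricts(self):
        records = [make_record(pf=float(i), source=f"S{i // 2}", idx=(i % 2) + 1)
                   for i in range(8)]
        out = zscore_records(records, mode="model_1")
        assert all(r.model_index == 1 for r in out)
        assert len(out) == 4


class TestRankBy:
    def test_dense_ranks(self):
        records = [make_record(z=v, source=f"S{i}") for i, v in enumerate([-2.0, -1.0, 0.0])]
        out = rank_by(records, "pf_zscore")
        assert [r.rank_functional for r in out] == [1, 2, 3]

    def test_tie_break_deterministic(self):
        records = [make_record(z=-1.0, source="SB"), make_record(z=-1.0, source="SA")]
        out = rank_by(records, "pf_zscore")
        assert out[1].rank_functional == 1  # SA before SB
        assert out[0].rank_functional == 2

    def test_descending_key(self):
        records = [make_record(gdt=v, source=f"S{i}") for i, v in enumerate([10.0, 90.0])]
        out = rank_by(records, "gdt_ts")
        assert out[1].rank_structural == 1
        assert out[0].rank_structural == 2

    def test_inputs_not_mutated(self):
        records = [make_record(z=-1.0), make_record(z=0.0, source="S02")]
        before = [dataclasses.replace(r) for r in records]
        rank_by(records, "pf_zscore")
        assert records == before


class TestSpearman:
    def test_identical_orderings(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40]) == pytest.approx(1.0)

    def test_reversed_orderings(self):
        assert spearman([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_rank_formula_value(self):
        # 1 - 6*sum(d^2)/(n(n^2-1)) with d^2 sum = 2 -> 1 - 12/60 = 0.8
        assert spearman([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_matches_rank_formula_on_tie_free_inputs(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 30))
            x = rng.permutation(n).astype(float)
            y = rng.permutation(n).astype(float)
            d2 = ((stats.rankdata(x) - stats.rankdata(y)) ** 2).sum()
            want = 1.0 - 6.0 * d2 / (n * (n ** 2 - 1))
            assert spearman(x, y) == pytest.approx(want)

    def test_matches_scipy(self, rng):
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        assert spearman(x, y) == pytest.approx(stats.spearmanr(x, y).statistic)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestFilterAndTopK:
    def test_eligible_site(self):
        records = ([make_record(rmsd=4.0, source=f"A{i}") for i in range(12)]
                   + [make_record(rmsd=6.0, source=f"B{i}") for i in range(5)])
        kept, report = filter_models_by_rmsd(records)
        assert len(kept) == 12
        assert report["eligible"]

    def test_ineligible_site_returns_empty(self):
        records = [make_record(rmsd=4.0, source=f"A{i}") for i in range(8)]
        kept, report = filter_models_by_rmsd(records)
        assert kept == []
        assert not report["eligible"]
        assert report["n_within"] == 8

    def test_boundary_inclusive(self):
        records = [make_record(rmsd=5.0, source=f"A{i}") for i in range(11)]
        kept, report = filter_models_by_rmsd(records)
        assert len(kept) == 11

    def test_top_k_truncates(self):
        records = [make_record(z=float(-i), source=f"S{i:02d}") for i in range(40)]
        out = top_k(records, k=30)
        assert len(out) == 30
        assert out[0].pf_zscore == -39.0

    def test_top_k_short_input(self):
        records = [make_record(z=float(i), source=f"S{i}") for i in range(20)]
        assert len(top_k(records, k=30)) == 20

    def test_selection_is_pure(self):
        records = [make_record(z=float(i), rmsd=1.0, source=f"S{i}") for i in range(5)]
        before = [dataclasses.replace(r) for r in records]
        filter_models_by_rmsd(records)
        top_k(records, k=3)
        assert records == before


class TestExposure:
    @pytest.mark.parametrize("relacc,expected", [
        (0.05, "buried"),
        (0.089999, "buried"),
        (0.09, "intermediate"),
        (0.20, "intermediate"),
        (0.359999, "intermediate"),
        (0.36, "exposed"),
        (0.90, "exposed"),
    ])
    def test_partition(self, relacc, expected):
        assert classify_exposure(relacc) == expected

    def test_negative_errors(self):
        with pytest.raises(ValueError):
            classify_exposure(-0.01)


class TestVariantMetrics:
    def test_perfect_predictions(self):
        ref = np.array([0.1, 0.5, 0.3])
        ss = np.array(["H", "E", "C"])
        m = variant_site_metrics(np.tile(ref, (3, 1)), np.tile(ss, (3, 1)), ref, ss)
        assert m.relacc_std == pytest.approx(0.0, abs=1e-12)
        assert m.acc_err == pytest.approx(0.0, abs=1e-12)
        assert m.frac_ss_correct == 1.0
        assert m.frac_exposure_correct == 1.0

    def test_two_model_formula(self):
        m = variant_site_metrics(np.array([[0.1], [0.3]]), np.array([["H"], ["H"]]),
                                 np.array([0.2]), np.array(["H"]))
        assert m.relacc_std == pytest.approx(0.1)
        assert m.acc_err == pytest.approx(0.1)

    def test_all_exposure_misclassified(self):
        ref = np.array([0.05, 0.05])  # buried
        pred = np.full((2, 2), 0.9)   # exposed
        m = variant_site_metrics(pred, np.full((2, 2), "H"), ref, np.array(["H", "H"]))
        assert m.frac_exposure_correct == 0.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            variant_site_metrics(np.zeros((2, 3)), np.zeros((2, 3)),
                                 np.zeros(4), np.zeros(4))


class TestAggregatePatches:
    def test_mean_of_two_patches(self):
        records = [make_record(z=-1.0), make_record(z=-2.0)]
        records[1].site_id = "S2"
        out = aggregate_patches(records)
        assert out[("T", "S01", 1)] == pytest.approx(-1.5)

    def test_single_patch_identity(self):
        out = aggregate_patches([make_record(z=-0.7)])
        assert out[("T", "S01", 1)] == pytest.approx(-0.7)

    def test_four_patches_direct_recomputation(self, rng):
        zs = rng.normal(size=4)
        records = []
        for i, z in enumerate(zs):
            r = make_record(z=float(z))
            r.site_id = f"P{i}"
            records.append(r)
        out = aggregate_patches(records)
        assert out[("T", "S01", 1)] == pytest.approx(zs.mean())


class TestScoreEnsemble:
    def test_identical_models_share_self_score(self, reference_and_site,
                                               featurizer, background):
        reference, site = reference_and_site
        models = []
        for i in range(3):
            m = perturb_model(reference, 0.0, 0.0, site, seed=i)
            m.source_id = f"S{i:02d}"
            m.model_index = 1
            models.append(m)
        records, excluded = score_ensemble(reference, site, models, background,
                                           featurizer=featurizer)
        assert excluded == []
        scores = {r.pf_score for r in records}
        assert len(scores) == 1
        from pocketassess.assessment import featurize_site
        from pocketassess.site_compare import align_sites
        va, _ = featurize_site(reference, site, featurizer)
        assert scores.pop() == pytest.approx(align_sites(va, va, background).total_score)

    def test_model_missing_site_excluded(self, reference_and_site, featurizer,
                                         background):
        reference, site = reference_and_site
        good = perturb_model(reference, 0.2, 0.2, site, seed=1)
        good.source_id = "GOOD"
        bad = perturb_model(reference, 0.2, 0.2, site, seed=2)
        bad.source_id = "BAD"
        site_keys = {(s.chain, s.seqnum, s.icode or "") for s in site.selectors}
        bad.residues = [r for r in bad.residues if r.key not in site_keys]
        others = [perturb_model(reference, 0.3, 0.3, site, seed=i + 10) for i in range(2)]
        for i, m in enumerate(others):
            m.source_id = f"S{i:02d}"
        records, excluded = score_ensemble(reference, site, [good, bad] + others,
                                           background, featurizer=featurizer)
        assert len(records) == 3
        assert excluded == ["BAD#0"]

    def test_no_scorable_model_errors(self, reference_and_site, featurizer,
                                      background):
        reference, site = reference_and_site
        bad = perturb_model(reference, 0.2, 0.2, site, seed=3)
        site_keys = {(s.chain, s.seqnum, s.icode or "") for s in site.selectors}
        bad.residues = [r for r in bad.residues if r.key not in site_keys]
        with pytest.raises(ValueError, match="no model"):
            score_ensemble(reference, site, [bad], background, featurizer=featurizer)

    def test_pf_worsens_with_site_noise(self, reference_and_site, featurizer,
                                        background):
        # graded site noise: mean pf over replicates increases (worsens)
        reference, site = reference_and_site
        levels = [0.2, 0.8, 2.0]
        means = []
        for sigma in levels:
            models = []
            for rep in range(20):
                m = perturb_model(reference, 0.0, sigma, site, seed=1000 + rep)
                m.source_id = f"R{rep:02d}"
                models.append(m)
            records, _ = score_ensemble(reference, site, models, background,
                                        featurizer=featurizer)
            means.append(np.mean([r.pf_score for r in records]))
        assert means[0] < means[1] < means[2]
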
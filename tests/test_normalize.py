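"""Master-pool normalization, complete-case filtering, batch correction
and QC metrics."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import ks_2samp

from tmtmark import (
    CHANNELS_11PLEX,
    block_randomize,
    combat_correct,
    compute_qc_metrics,
    filter_complete,
    generate_cohort,
    mp_normalize,
    pca_batch_diagnostic,
    simulate_tmt,
)
from tmtmark.datatypes import (
    ROLE_CLINICAL,
    ROLE_MASTER_POOL,
    ROLE_QC,
    AbundanceMatrix,
    SampleMeta,
)


def _tiny_batch(values_by_sample, mp_values, protein_ids=("p1", "p2")):
    """One-batch raw matrix plus design, for hand-checked arithmetic."""
    design = [
        SampleMeta(sid, diagnosis="PSP", sex="F", age=60.0, batch=1, channel=str(i))
        for i, sid in enumerate(values_by_sample)
    ]
    design.append(SampleMeta("MP", role=ROLE_MASTER_POOL, batch=1, channel="last"))
    data = {sid: vals for sid, vals in values_by_sample.items()}
    data["MP"] = mp_values
    raw = AbundanceMatrix(pd.DataFrame(data, index=list(protein_ids)), "raw")
    return raw, design


class TestMpNormalize:
    def test_log2_ratio_arithmetic(self):
        raw, design = _tiny_batch({"s1": [200.0, 50.0]}, [100.0, 100.0])
        out = mp_normalize(raw, design)
        np.testing.assert_allclose(out.data["s1"].to_numpy(), [1.0, -1.0])
        assert out.scale == "log2_ratio"
        assert "MP" not in out.sample_ids

    def test_identity_ratio_gives_zero(self):
        raw, design = _tiny_batch({"s1": [123.0, 4.5]}, [123.0, 4.5])
        out = mp_normalize(raw, design)
        np.testing.assert_array_equal(out.data["s1"].to_numpy(), [0.0, 0.0])

    def test_round_trip_reproduces_ratio(self, small_design, small_sim):
        """2**normalized equals raw/MP wherever raw is present."""
        raw, _ = small_sim
        out = mp_normalize(raw, small_design)
        meta = {s.sample_id: s for s in small_design}
        mp_cols = {s.batch: s.sample_id for s in small_design if s.role == ROLE_MASTER_POOL}
        for col in out.sample_ids[:5]:
            mp = raw.data[mp_cols[meta[col].batch]].to_numpy()
            expected = raw.data[col].to_numpy() / mp
            got = np.exp2(out.data[col].to_numpy())
            mask = ~np.isnan(expected)
            np.testing.assert_allclose(got[mask], expected[mask], rtol=1e-12)

    def test_batch_shift_cancels_in_ratio(self):
        """An additive log2 batch shift shared with the MP cancels
        exactly after master-pool normalization: a shifted and an
        unshifted matrix with identical latents normalize identically."""
        rng = np.random.default_rng(8)
        p, batches, per_batch = 40, 3, 4
        latent = rng.normal(10, 2, (p, batches * per_batch))
        mp_latent = rng.normal(10, 2, p)
        shift = rng.normal(0, 0.6, (p, batches))

        def build(with_shift):
            cols, design = {}, []
            for b in range(batches):
                s_b = shift[:, b] if with_shift else 0.0
                for j in range(per_batch):
                    sid = f"b{b}s{j}"
                    cols[sid] = np.exp2(latent[:, b * per_batch + j] + s_b)
                    design.append(
                        SampleMeta(sid, diagnosis="PSP", sex="F", age=60.0,
                                   batch=b + 1, channel=str(j))
                    )
                mp_id = f"MP{b}"
                cols[mp_id] = np.exp2(mp_latent + s_b)
                design.append(
                    SampleMeta(mp_id, role=ROLE_MASTER_POOL, batch=b + 1, channel="mp")
                )
            ids = [f"p{i}" for i in range(p)]
            return AbundanceMatrix(pd.DataFrame(cols, index=ids), "raw"), design

        shifted, design = build(True)
        plain, _ = build(False)
        a = mp_normalize(shifted, design)
        b = mp_normalize(plain, design)
        np.testing.assert_allclose(
            a.data.to_numpy(), b.data.to_numpy(), rtol=0, atol=1e-9
        )

    def test_missing_master_pool_value_warns_and_propagates(self):
        raw, design = _tiny_batch({"s1": [200.0, 50.0]}, [100.0, np.nan])
        with pytest.warns(UserWarning, match="master-pool"):
            out = mp_normalize(raw, design)
        assert np.isnan(out.data.loc["p2", "s1"])
        assert out.data.loc["p1", "s1"] == 1.0

    def test_requires_master_pool_per_batch(self):
        raw, design = _tiny_batch({"s1": [1.0, 2.0]}, [1.0, 1.0])
        no_mp = [s for s in design if s.role != ROLE_MASTER_POOL]
        with pytest.raises(ValueError):
            mp_normalize(AbundanceMatrix(raw.data[["s1"]], "raw"), no_mp)


class TestFilterComplete:
    def test_no_missing_unchanged(self):
        m = AbundanceMatrix(
            pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]}, index=["p1", "p2"]), "raw"
        )
        out = filter_complete(m)
        pd.testing.assert_frame_equal(out.data, m.data)

    def test_single_missing_cell_drops_row(self):
        df = pd.DataFrame(
            np.arange(1.0, 16.0).reshape(5, 3),
            index=[f"p{i}" for i in range(5)],
            columns=list("abc"),
        )
        df.iloc[2, 1] = np.nan
        out = filter_complete(AbundanceMatrix(df, "raw"))
        assert out.protein_ids == ["p0", "p1", "p3", "p4"]

    def test_survivor_count_matches_brute_force(self, small_sim):
        raw, _ = small_sim
        out = filter_complete(raw)
        brute = sum(
            1 for _, row in raw.data.iterrows() if not row.isna().any()
        )
        assert out.n_proteins == brute
        assert not out.data.isna().any().any()


class TestCombatCorrect:
    @staticmethod
    def _two_batch_shift(seed=5, n=60, p=300, shift_sd=0.5, noise=0.3):
        rng = np.random.default_rng(seed)
        mu = rng.normal(0, 1, p)[:, None]
        X = mu + rng.normal(0, noise, (p, 2 * n))
        X[:, n:] += rng.normal(0, shift_sd, p)[:, None]
        cols = [f"s{i}" for i in range(2 * n)]
        design = [
            SampleMeta(
                c, diagnosis=["PSP", "PD"][i % 2], sex="F", age=60.0,
                batch=1 if i < n else 2, channel=str(i),
            )
            for i, c in enumerate(cols)
        ]
        m = AbundanceMatrix(
            pd.DataFrame(X, index=[f"p{i}" for i in range(p)], columns=cols),
            "log2_ratio",
        )
        return m, design, n

    def test_removes_additive_two_batch_shift(self):
        m, design, n = self._two_batch_shift()
        out = combat_correct(m, design)
        X, Y = m.data.to_numpy(), out.data.to_numpy()
        before = np.abs(X[:, :n].mean(1) - X[:, n:].mean(1)).mean()
        after = np.abs(Y[:, :n].mean(1) - Y[:, n:].mean(1)).mean()
        assert after < 0.05 * before  # >= 95% of the shift removed
        # grand means essentially preserved
        assert np.abs(Y.mean(1) - X.mean(1)).max() < 0.01 * X.std()

    def test_approximately_idempotent(self):
        """A second application changes values by a small fraction of
        the data SD (empirical-Bayes shrinkage leaves a tiny remnant,
        so exact idempotency is not expected)."""
        m, design, _ = self._two_batch_shift()
        once = combat_correct(m, design)
        twice = combat_correct(once, design)
        delta = np.abs(twice.data.to_numpy() - once.data.to_numpy()).max()
        assert delta < 0.05 * once.data.to_numpy().std()

    def test_single_batch_is_noop(self):
        df = pd.DataFrame(
            np.random.default_rng(0).normal(size=(10, 6)),
            index=[f"p{i}" for i in range(10)],
            columns=[f"s{i}" for i in range(6)],
        )
        design = [
            SampleMeta(f"s{i}", diagnosis="PSP", sex="F", age=60.0, batch=1, channel=str(i))
            for i in range(6)
        ]
        m = AbundanceMatrix(df, "log2_ratio")
        out = combat_correct(m, design)
        pd.testing.assert_frame_equal(out.data, df)
        assert out.scale == "log2_corrected"

    def test_zero_variance_protein_left_unchanged(self):
        m, design, _ = self._two_batch_shift(p=20)
        m.data.iloc[0] = 1.25
        with pytest.warns(UserWarning, match="zero-variance"):
            out = combat_correct(m, design)
        assert (out.data.iloc[0] == 1.25).all()

    def test_small_batch_rejected(self):
        df = pd.DataFrame(
            np.random.default_rng(0).normal(size=(5, 3)),
            index=[f"p{i}" for i in range(5)], columns=["a", "b", "c"],
        )
        design = [
            SampleMeta("a", diagnosis="PSP", sex="F", age=60.0, batch=1, channel="1"),
            SampleMeta("b", diagnosis="PD", sex="F", age=60.0, batch=1, channel="2"),
            SampleMeta("c", diagnosis="HC", sex="F", age=60.0, batch=2, channel="1"),
        ]
        with pytest.raises(ValueError, match="fewer than 2"):
            combat_correct(AbundanceMatrix(df, "log2_ratio"), design)

    def test_requires_complete_matrix(self, small_design, small_pipeline):
        ratio, _, _ = small_pipeline
        if not ratio.data.isna().any().any():
            pytest.skip("fixture produced no missing values")
        with pytest.raises(ValueError, match="complete"):
            combat_correct(ratio, small_design)


class TestQcMetrics:
    def test_hand_computed_cv(self):
        """Un-logged QC values {90, 100, 110}: CV = sample SD / mean =
        10/100 = 0.1."""
        design = [
            SampleMeta(f"qc{i}", role=ROLE_QC, batch=i + 1, channel="1")
            for i in range(3)
        ] + [
            SampleMeta(f"c{i}", diagnosis="PSP", sex="F", age=60.0, batch=i + 1, channel="2")
            for i in range(2)
        ]
        df = pd.DataFrame(
            {
                "qc0": [np.log2(90.0)], "qc1": [np.log2(100.0)], "qc2": [np.log2(110.0)],
                "c0": [0.1], "c1": [0.4],
            },
            index=["p1"],
        )
        qm = compute_qc_metrics(AbundanceMatrix(df, "log2_ratio"), design)
        assert qm.table.loc["p1", "cv"] == pytest.approx(0.1)

    def test_zero_qc_sd_gives_inf_sentinel(self):
        design = [
            SampleMeta(f"qc{i}", role=ROLE_QC, batch=i + 1, channel="1") for i in range(2)
        ] + [
            SampleMeta(f"c{i}", diagnosis="PSP", sex="F", age=60.0, batch=i + 1, channel="2")
            for i in range(2)
        ]
        df = pd.DataFrame(
            {"qc0": [1.0], "qc1": [1.0], "c0": [0.3], "c1": [0.9]}, index=["p1"]
        )
        with pytest.warns(UserWarning, match="zero QC SD"):
            qm = compute_qc_metrics(AbundanceMatrix(df, "log2_ratio"), design)
        assert qm.table.loc["p1", "cv"] == 0.0
        assert np.isinf(qm.table.loc["p1", "snr"])

    def test_snr_above_one_for_most_proteins(self, small_design, small_pipeline):
        """Clinical channels carry biological variation on top of the
        technical floor, so S/N >= 1 for nearly all proteins."""
        ratio, _, _ = small_pipeline
        qm = compute_qc_metrics(ratio, small_design)
        assert (qm.table["snr"] >= 1).mean() > 0.95

    def test_requires_two_qc_columns(self, small_design, small_pipeline):
        ratio, _, _ = small_pipeline
        qc_cols = [
            s.sample_id for s in small_design if s.role == ROLE_QC
        ]
        pruned = AbundanceMatrix(
            ratio.data.drop(columns=qc_cols[1:]), "log2_ratio"
        )
        with pytest.raises(ValueError, match="QC"):
            compute_qc_metrics(pruned, small_design)

    def test_cv_distribution_calibrated_against_clinical(self):
        """When clinical channel noise equals the technical floor (no
        biological variation beyond the QC's), the per-protein CV
        distribution from QC channels matches the CV distribution from
        an equally-sized, batch-matched clinical subset (two-sample KS
        p > 0.01 in a majority of seeds)."""
        wins = 0
        n_seeds = 5
        for seed in range(n_seeds):
            design = block_randomize(
                generate_cohort(40, seed=seed), 13, CHANNELS_11PLEX, 10, seed=seed
            )
            raw, _ = simulate_tmt(
                design, n_proteins=300, frac_differential=0.0, batch_shift_sd=0.0,
                missing_rate=0.0, tech_sd=0.338, seed=seed,
            )
            ratio = mp_normalize(raw, design)
            qm = compute_qc_metrics(ratio, design)
            meta = {s.sample_id: s for s in design}
            qc_batches = sorted(
                {meta[c].batch for c in ratio.sample_ids if meta[c].role == ROLE_QC}
            )
            rng = np.random.default_rng(seed + 1000)
            subset = [
                rng.choice(
                    [
                        c for c in ratio.sample_ids
                        if meta[c].role == ROLE_CLINICAL and meta[c].batch == b
                    ]
                )
                for b in qc_batches
            ]
            lin = np.exp2(ratio.data[subset].to_numpy())
            cv_clin = lin.std(axis=1, ddof=1) / lin.mean(axis=1)
            wins += ks_2samp(qm.table["cv"], cv_clin).pvalue > 0.01
        assert wins > n_seeds / 2


class TestPcaBatchDiagnostic:
    def test_identical_columns_zero_scores(self):
        df = pd.DataFrame(
            {f"s{i}": [1.0, 2.0, 3.0] for i in range(4)}, index=["p1", "p2", "p3"]
        )
        scores, frac = pca_batch_diagnostic(AbundanceMatrix(df, "log2_ratio"))
        assert np.allclose(scores[["PC1", "PC2"]].to_numpy(), 0.0)
        assert np.all(frac == 0.0)

    def test_variance_fractions_bounded(self, small_design, small_pipeline):
        _, complete, _ = small_pipeline
        _, frac = pca_batch_diagnostic(complete, small_design)
        assert frac.sum() <= 1.0 + 1e-12
        assert frac[0] >= frac[-1] >= 0

    def test_batch_silhouette_decreases_after_correction(self):
        """Batch clusters visible on PC1-2 of the uncorrected log2
        matrix dissolve after batch correction."""
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(6)
        p, n = 200, 15
        mu = rng.normal(0, 1, p)[:, None]
        X = mu + rng.normal(0, 0.3, (p, 2 * n))
        X[:, n:] += rng.normal(0, 0.8, p)[:, None]
        cols = [f"s{i}" for i in range(2 * n)]
        design = [
            SampleMeta(
                c, diagnosis=["PSP", "PD", "HC"][i % 3], sex="F", age=60.0,
                batch=1 if i < n else 2, channel=str(i),
            )
            for i, c in enumerate(cols)
        ]
        m = AbundanceMatrix(pd.DataFrame(X, index=[f"p{i}" for i in range(p)], columns=cols), "log2_ratio")
        labels = [1 if i < n else 2 for i in range(2 * n)]
        before_scores, _ = pca_batch_diagnostic(m)
        after_scores, _ = pca_batch_diagnostic(combat_correct(m, design))
        s_before = silhouette_score(before_scores[["PC1", "PC2"]], labels)
        s_after = silhouette_score(after_scores[["PC1", "PC2"]], labels)
        assert s_after < s_before
        assert s_before > 0.5  # batches really were separated initially

    def test_too_few_samples(self):
        df = pd.DataFrame({"a": [1.0], "b": [2.0]}, index=["p1"])
        with pytest.raises(ValueError):
            pca_batch_diagnostic(AbundanceMatrix(df, "log2_ratio"))
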
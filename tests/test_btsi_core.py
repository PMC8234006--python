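"""Spearman/BTSI statistics and the randomized-panel labeling procedure."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import bfcorr as b
from bfcorr.btsi_core import CorrelationError, spearman_vs_columns
from bfcorr.io_preprocess import InputError
from bfcorr.synthetic_data import BiofluidSpec, SimulationConfig, tissue_name
from conftest import make_matrix


def brute_force_spearman(x, y):
    """Independent oracle: mid-ranks by hand, then Pearson."""

    def midranks(v):
        v = np.asarray(v, dtype=float)
        r = np.empty(len(v))
        for i, vi in enumerate(v):
            less = (v < vi).sum()
            equal = (v == vi).sum()
            r[i] = less + (equal + 1) / 2.0
        return r

    return float(np.corrcoef(midranks(x), midranks(y))[0, 1])


class TestSpearman:
    def test_perfect_monotone(self):
        rho, p = b.spearman([1, 2, 3], [10, 20, 30])
        assert rho == 1.0 and p == 0.0

    def test_perfect_antitone(self):
        rho, p = b.spearman([1, 2, 3], [3, 2, 1])
        assert rho == -1.0 and p == 0.0

    def test_textbook_d_squared_case(self):
        # rho = 1 - 6*sum(d^2)/(n(n^2-1)) = 1 - 6*4/120 = 0.8
        rho, _ = b.spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert rho == pytest.approx(0.8, abs=1e-15)

    def test_ties_use_midranks(self):
        rho, _ = b.spearman([1, 1, 2], [1, 2, 3])
        expected = float(np.corrcoef([1.5, 1.5, 3.0], [1.0, 2.0, 3.0])[0, 1])
        assert rho == pytest.approx(expected, abs=1e-15)

    def test_matches_brute_force_oracle_with_ties(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = rng.integers(4, 40)
            x = rng.integers(0, 8, n).astype(float)  # many ties
            y = rng.normal(size=n)
            if np.ptp(x) == 0:
                continue
            rho, _ = b.spearman(x, y)
            assert rho == pytest.approx(brute_force_spearman(x, y), abs=1e-12)

    def test_matches_scipy_p_values(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(5, 60))
            x, y = rng.normal(size=(2, n))
            rho, p = b.spearman(x, y)
            ref = stats.spearmanr(x, y)
            assert rho == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_constant_vector_is_an_error(self):
        with pytest.raises(CorrelationError):
            b.spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_symmetry_and_monotone_invariance(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 30))
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        rho_xy, _ = b.spearman(x, y)
        rho_yx, _ = b.spearman(y, x)
        assert rho_xy == pytest.approx(rho_yx, abs=1e-14)
        # a rank statistic is invariant under strictly increasing transforms
        rho_exp, _ = b.spearman(np.exp(x), y)
        assert rho_xy == pytest.approx(rho_exp, abs=1e-12)

    def test_vectorized_column_form_agrees(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=50)
        M = rng.normal(size=(50, 7))
        rhos = spearman_vs_columns(x, M)
        for j in range(7):
            assert rhos[j] == pytest.approx(b.spearman(x, M[:, j])[0], abs=1e-12)


class TestNonzeroGeneCount:
    def test_extremes_and_brute_force(self):
        rng = np.random.default_rng(2)
        vals = rng.random((20, 5))
        vals[vals < 0.5] = 0.0
        vals[:, 0] = 0.0
        vals[:, 1] = 1.0
        counts = b.nonzero_gene_count(make_matrix(vals))
        assert counts.iloc[0] == 0 and counts.iloc[1] == 20
        for j in range(5):
            assert counts.iloc[j] == int((vals[:, j] > 0).sum())


def fluid_from_vectors(vectors, gene_ids, name="fl"):
    cols = {f"{name}_s{j}": v for j, v in enumerate(vectors)}
    values = pd.DataFrame(cols, index=gene_ids)
    matrix = b.ExpressionMatrix(values, "log_tpm")
    meta = pd.DataFrame(
        {"compartment": "biofluid", "group": name, "batch": "x", "sex": "unknown"},
        index=values.columns,
    )
    return matrix, meta


class TestGroupedBtsi:
    def test_fluid_equal_to_tissue_mean_gives_rho_one(self, small_logged):
        lf, lt = small_logged
        mean_vec = lt.values.mean(axis=1).to_numpy()
        fluid, fmeta = fluid_from_vectors([mean_vec, mean_vec], lt.gene_ids)
        meta = pd.concat(
            [
                pd.DataFrame(
                    {"compartment": "tissue", "group": "t", "batch": "p", "sex": "u"},
                    index=lt.sample_ids,
                ),
                fmeta,
            ]
        )
        rec = b.btsi_overall(fluid, lt, meta)[0]
        assert rec.tissue == "ALL" and rec.rho == pytest.approx(1.0)

    def test_independent_matrices_have_near_zero_btsi(self):
        rng = np.random.default_rng(21)
        G = 4000
        genes = [f"g{i}" for i in range(G)]
        lt = make_matrix(rng.lognormal(1, 1, (G, 6)), state="log_tpm", genes=genes)
        fluid, fmeta = fluid_from_vectors(list(rng.lognormal(1, 1, (3, G))), genes)
        meta = pd.concat(
            [
                pd.DataFrame(
                    {"compartment": "tissue", "group": "t", "batch": "p", "sex": "u"},
                    index=lt.sample_ids,
                ),
                fmeta,
            ]
        )
        rec = b.btsi_overall(fluid, lt, meta)[0]
        assert abs(rec.rho) < 3 / np.sqrt(G)

    def test_grid_covers_every_pair(self, small_bundle, small_logged):
        lf, lt = small_logged
        records = b.btsi_per_tissue(lf, lt, small_bundle.metadata)
        n_fluids = small_bundle.metadata.query("compartment == 'biofluid'")[
            "group"
        ].nunique()
        assert len(records) == n_fluids * 5
        assert len({(r.biofluid, r.tissue) for r in records}) == len(records)

    def test_dominant_tissue_wins_on_separated_fixture(self):
        w = np.full(6, 0.3 / 5)
        w[2] = 0.7
        cfg = SimulationConfig(
            n_genes=1000,
            n_tissues=6,
            samples_per_tissue=8,
            noise_cv=0.2,
            biofluid_specs=[BiofluidSpec("fl", 20, w, "b1")],
            seed=61,
        )
        bundle = b.simulate_bundle(cfg)
        lt = b.log_transform(b.tpm_normalize(bundle.tissue_matrix, bundle.annotation))
        lf = b.log_transform(
            b.tpm_normalize(bundle.biofluid_matrix, bundle.annotation)
        )
        records = b.btsi_per_tissue(lf, lt, bundle.metadata)
        best = max(records, key=lambda r: r.rho)
        assert best.tissue == tissue_name(2)

    def test_duplicated_tissue_groups_get_equal_rho(self, small_logged):
        lf, lt = small_logged
        dup = b.ExpressionMatrix(
            pd.concat(
                [
                    lt.values.add_suffix("_a"),
                    lt.values.add_suffix("_b"),
                ],
                axis=1,
            ),
            "log_tpm",
        )
        meta = pd.DataFrame(
            {
                "compartment": "tissue",
                "group": ["dupA"] * lt.shape[1] + ["dupB"] * lt.shape[1],
                "batch": "p",
                "sex": "u",
            },
            index=dup.sample_ids,
        )
        fluid, fmeta = fluid_from_vectors(
            [lt.values.iloc[:, 0].to_numpy()], lt.gene_ids
        )
        records = b.btsi_per_tissue(fluid, dup, pd.concat([meta, fmeta]))
        assert records[0].rho == pytest.approx(records[1].rho, abs=1e-12)


@pytest.fixture(scope="module")
def separated():
    w = np.zeros(4)
    w[1] = 1.0
    cfg = SimulationConfig(
        n_genes=800,
        n_tissues=4,
        samples_per_tissue=8,
        noise_cv=0.1,
        dropout_rate=0.1,
        dropout_heterogeneity=0.0,
        biofluid_specs=[BiofluidSpec("fl", 10, w, "b1")],
        seed=31,
    )
    bundle = b.simulate_bundle(cfg)
    lt = b.log_transform(b.tpm_normalize(bundle.tissue_matrix, bundle.annotation))
    lf = b.log_transform(
        b.tpm_normalize(bundle.biofluid_matrix, bundle.annotation)
    )
    return lf, lt, bundle.metadata


class TestLabelIntended:
    def test_separated_pair_is_intended(self, separated):
        lf, lt, meta = separated
        rc = b.RandomizationConfig(n_random=20, n_repeats=10, alpha=0.05, seed=1)
        rec = b.label_intended(("fl", tissue_name(1)), lf, lt, meta, rc)
        assert rec.label == "intended"

    def test_single_repeat_agrees_on_separated_fixture(self, separated):
        lf, lt, meta = separated
        rc1 = b.RandomizationConfig(n_random=20, n_repeats=1, alpha=0.05, seed=1)
        rec = b.label_intended(("fl", tissue_name(1)), lf, lt, meta, rc1)
        assert rec.label == "intended"

    def test_draw_larger_than_panel_rejected(self, separated):
        lf, lt, meta = separated
        rc = b.RandomizationConfig(n_random=1000, n_repeats=2, alpha=0.05, seed=1)
        with pytest.raises(InputError, match="panel"):
            b.label_intended(("fl", tissue_name(1)), lf, lt, meta, rc)

    def test_tiny_tissue_not_evaluated(self, separated):
        lf, lt, meta = separated
        meta2 = meta.copy()
        keep = list(lt.sample_ids[:1]) + [
            s for s in lt.sample_ids if meta.loc[s, "group"] != tissue_name(0)
        ]
        lt2 = b.ExpressionMatrix(lt.values[keep], "log_tpm")
        rc = b.RandomizationConfig(n_random=10, n_repeats=2, alpha=0.05, seed=1)
        rec = b.label_intended(("fl", tissue_name(0)), lf, lt2, meta2, rc)
        assert rec.label == "not_evaluated"

    def test_labeling_is_deterministic(self, separated):
        lf, lt, meta = separated
        rc = b.RandomizationConfig(n_random=20, n_repeats=5, alpha=0.05, seed=9)
        r1 = b.label_intended(("fl", tissue_name(1)), lf, lt, meta, rc)
        r2 = b.label_intended(("fl", tissue_name(1)), lf, lt, meta, rc)
        assert (r1.label, r1.rho) == (r2.label, r2.rho)
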
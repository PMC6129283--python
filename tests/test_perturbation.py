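"""Noise injection, sweeps, and the adjust-and-rescore loop."""

import numpy as np
import pandas as pd
import pytest

from ontoscore import (
    NoiseSpec,
    ScoreConfig,
    add_gaussian_noise,
    adjust_and_rescore,
    make_oracle_adjuster,
    noise_fraction_scores,
    noise_intensity_scores,
    recovery_fraction,
)
from ontoscore.perturbation import _prepare_base, _round_half_away


def _expr(n_genes=50, n_samples=10, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.uniform(0, 10, size=(n_genes, n_samples)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{i}" for i in range(n_samples)],
    )


class TestNoiseSpec:
    def test_fraction_out_of_range(self):
        with pytest.raises(ValueError, match="fraction"):
            NoiseSpec(fraction=1.2)

    def test_sigma_positive(self):
        with pytest.raises(ValueError, match="sigma"):
            NoiseSpec(sigma=0.0)


class TestAddGaussianNoise:
    def test_fraction_zero_is_identity(self):
        e = _expr()
        out, labels = add_gaussian_noise(
            e, NoiseSpec(fraction=0.0, stratify_by_group=False)
        )
        pd.testing.assert_frame_equal(out, e)
        assert (labels == "clean").all()

    def test_exact_count_unstratified(self):
        e = _expr(n_samples=100)
        _, labels = add_gaussian_noise(
            e, NoiseSpec(fraction=0.5, stratify_by_group=False)
        )
        assert (labels == "noisy").sum() == 50

    def test_rounding_half_away_from_zero(self):
        assert _round_half_away(0.5) == 1
        assert _round_half_away(1.5) == 2
        assert _round_half_away(1.4) == 1

    def test_stratified_every_group_mixed(self):
        e = _expr(n_samples=20)
        groups = pd.Series(
            ["A"] * 10 + ["B"] * 10, index=e.columns, name="group"
        )
        _, labels = add_gaussian_noise(e, NoiseSpec(fraction=0.5), groups=groups)
        tab = pd.crosstab(groups, labels)
        assert (tab["noisy"] == 5).all()
        assert (tab["clean"] == 5).all()

    def test_mean_shift_matches_mu(self):
        """Mean elementwise difference on noisy samples ~ mu (LLN bound)."""
        e = _expr(n_genes=500, n_samples=40)
        spec = NoiseSpec(fraction=0.5, mu=10.0, sigma=1.0, seed=3, stratify_by_group=False)
        out, labels, noise = add_gaussian_noise(e, spec, return_noise=True)
        noisy_cols = labels.index[labels == "noisy"]
        diff = (out[noisy_cols] - e[noisy_cols]).to_numpy()
        assert diff.size >= 10_000
        assert abs(diff.mean() - 10.0) < 0.1
        assert np.allclose(diff, noise[noisy_cols].to_numpy(), atol=1e-9)

    def test_clean_samples_bit_identical(self):
        e = _expr()
        out, labels = add_gaussian_noise(
            e, NoiseSpec(fraction=0.3, stratify_by_group=False, seed=1)
        )
        clean = labels.index[labels == "clean"]
        assert out[clean].equals(e[clean])

    def test_reproducible_from_seed(self):
        e = _expr()
        spec = NoiseSpec(fraction=0.4, seed=7, stratify_by_group=False)
        a, la = add_gaussian_noise(e, spec)
        b, lb = add_gaussian_noise(e, spec)
        pd.testing.assert_frame_equal(a, b)
        assert la.equals(lb)

    def test_stratified_requires_groups(self):
        with pytest.raises(ValueError, match="group"):
            add_gaussian_noise(_expr(), NoiseSpec(stratify_by_group=True))


class TestSweeps:
    def test_fraction_zero_matches_unperturbed(self, small_dataset):
        from ontoscore import compute_scores

        graph, expr, mapping = small_dataset
        table = noise_fraction_scores(expr, graph, mapping, fractions=[0.0], seed=0)
        ref = compute_scores(expr, graph, mapping).scores
        merged = table.set_index("sample_id")["score"]
        assert np.allclose(merged.loc[ref.index], ref["score"])

    def test_one_row_per_fraction_seed_sample(self, small_dataset):
        graph, expr, mapping = small_dataset
        table = noise_fraction_scores(
            expr, graph, mapping, fractions=[0.0, 0.5], seed=0, n_seeds=2
        )
        assert len(table) == 2 * 2 * expr.shape[1]
        assert set(table["fraction"]) == {0.0, 0.5}

    def test_scores_drop_with_contamination(self, small_dataset):
        graph, expr, mapping = small_dataset
        table = noise_fraction_scores(
            expr, graph, mapping, fractions=[0.0, 0.5], mu=10, seed=0, n_seeds=3
        )
        med = table.groupby("fraction")["score"].median()
        assert med[0.5] < med[0.0]

    def test_vanishing_intensity_near_unperturbed(self, small_dataset):
        graph, expr, mapping = small_dataset
        table = noise_intensity_scores(
            expr, graph, mapping, mus=[0.0], sigma=0.01, seed=0
        )
        base = noise_fraction_scores(expr, graph, mapping, fractions=[0.0], seed=0)
        assert abs(table["score"].median() - base["score"].median()) < 0.05

    def test_invalid_fraction_rejected(self, small_dataset):
        graph, expr, mapping = small_dataset
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            noise_fraction_scores(expr, graph, mapping, fractions=[1.5])


class TestAdjustAndRescore:
    @pytest.fixture
    def perturbed(self, small_dataset, default_config):
        graph, expr, mapping = small_dataset
        base, cfg = _prepare_base(expr, default_config, True)
        groups = mapping.set_index("sample_id")["group"]
        noisy, labels, noise = add_gaussian_noise(
            base, NoiseSpec(fraction=0.5, mu=8.0, sigma=0.1, seed=2),
            groups=groups, return_noise=True,
        )
        return graph, mapping, base, cfg, noisy, labels, noise

    def test_identity_adjuster_equals_noisy(self, perturbed):
        graph, mapping, base, cfg, noisy, labels, _ = perturbed
        table = adjust_and_rescore(
            noisy, labels, graph, mapping, adjuster="identity", config=cfg
        )
        wide = table.pivot(index="sample_id", columns="dataset", values="score")
        assert np.allclose(wide["adjusted"], wide["noisy"], equal_nan=True)

    def test_oracle_adjuster_restores_original(self, perturbed):
        graph, mapping, base, cfg, noisy, labels, noise = perturbed
        table = adjust_and_rescore(
            noisy, labels, graph, mapping,
            adjuster=make_oracle_adjuster(noise), config=cfg, expr_original=base,
        )
        wide = table.pivot(index="sample_id", columns="dataset", values="score")
        assert np.allclose(wide["adjusted"], wide["original"])
        assert recovery_fraction(table) == pytest.approx(1.0)

    def test_baseline_recovers_additive_shift(self, perturbed):
        graph, mapping, base, cfg, noisy, labels, _ = perturbed
        table = adjust_and_rescore(
            noisy, labels, graph, mapping,
            adjuster="location_scale", config=cfg, expr_original=base,
        )
        assert recovery_fraction(table) >= 0.8

    def test_recovery_fraction_requires_all_datasets(self, perturbed):
        graph, mapping, base, cfg, noisy, labels, _ = perturbed
        table = adjust_and_rescore(
            noisy, labels, graph, mapping, adjuster="identity", config=cfg
        )
        with pytest.raises(ValueError, match="original"):
            recovery_fraction(table)
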
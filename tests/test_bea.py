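"""Control-gene probabilities, the baseline adjuster, and the registry."""

import numpy as np
import pandas as pd
import pytest

from ontoscore import (
    BatchDesign,
    adjust_location_scale,
    apply_adjuster,
    control_gene_probabilities,
    get_adjuster,
    list_adjusters,
    register_adjuster,
)


def _expr(values, samples=None):
    values = np.asarray(values, dtype=float)
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return pd.DataFrame(
        values, index=[f"g{i}" for i in range(values.shape[0])], columns=samples
    )


class TestControlGeneProbabilities:
    def _untied(self, n=10, n_samples=6, seed=0):
        """n genes with strictly increasing sd across samples."""
        rng = np.random.default_rng(seed)
        base = rng.normal(size=n_samples)
        base = (base - base.mean()) / base.std(ddof=1)  # unit sd pattern
        rows = [(i + 1) * base for i in range(n)]
        return _expr(rows)

    def test_max_sd_gene_gets_zero(self):
        tab = control_gene_probabilities(self._untied())
        assert tab.loc[tab["sd"].idxmax(), "pc"] == 0.0

    def test_min_sd_gene_among_ten_gets_point_nine(self):
        tab = control_gene_probabilities(self._untied(n=10))
        assert tab.loc[tab["sd"].idxmin(), "pc"] == pytest.approx(0.9)

    def test_all_tied_sds_give_zero(self):
        """Average rank equals the max rank when everything ties."""
        pattern = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])  # integer-exact ties
        e = _expr([pattern, pattern + 3.0, pattern - 1.0])  # same sd per gene
        tab = control_gene_probabilities(e)
        assert np.allclose(tab["pc"], 0.0)

    def test_invariant_under_sample_permutation(self):
        e = self._untied()
        perm = e[list(e.columns[::-1])]
        pd.testing.assert_series_equal(
            control_gene_probabilities(e)["pc"],
            control_gene_probabilities(perm)["pc"],
        )

    def test_invariant_under_gene_shift(self):
        e = self._untied()
        shifted = e.copy()
        shifted.iloc[0] += 100.0
        pd.testing.assert_series_equal(
            control_gene_probabilities(e)["pc"],
            control_gene_probabilities(shifted)["pc"],
        )

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            control_gene_probabilities(_expr([[1.0], [2.0]]))


def _design(batches, groups=None, samples=None):
    samples = samples or [f"s{i}" for i in range(len(batches))]
    return BatchDesign(
        batch=pd.Series(batches, index=samples),
        group=None if groups is None else pd.Series(groups, index=samples),
    )


class TestAdjustLocationScale:
    def _two_batch(self, shift=10.0, n_genes=30, per_batch=6, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal(5.0, 1.0, size=(n_genes, per_batch))
        b = rng.normal(5.0, 1.0, size=(n_genes, per_batch)) + shift
        e = _expr(np.hstack([a, b]))
        d = _design(["A"] * per_batch + ["B"] * per_batch, samples=list(e.columns))
        return e, d

    def test_single_batch_is_identity(self):
        e, _ = self._two_batch(shift=0.0)
        d = _design(["A"] * e.shape[1], samples=list(e.columns))
        pd.testing.assert_frame_equal(adjust_location_scale(e, d), e)

    def test_constant_shift_equalizes_batch_means(self):
        e, d = self._two_batch(shift=10.0)
        out = adjust_location_scale(e, d, preserve_groups=False)
        a = out.iloc[:, :6].mean(axis=1)
        b = out.iloc[:, 6:].mean(axis=1)
        assert np.allclose(a, b, atol=1e-9)

    def test_pooled_gene_mean_preserved(self):
        e, d = self._two_batch()
        out = adjust_location_scale(e, d, preserve_groups=False)
        assert np.allclose(out.mean(axis=1), e.mean(axis=1), atol=1e-9)

    def test_idempotent(self):
        e, d = self._two_batch(seed=3)
        once = adjust_location_scale(e, d, preserve_groups=False)
        twice = adjust_location_scale(once, d, preserve_groups=False)
        assert np.allclose(once, twice, atol=1e-9)

    def test_between_batch_variance_collapses(self):
        """Additive shift: between-batch variance drops below 1% per gene."""
        e, d = self._two_batch(shift=10.0, seed=4)

        def between_var(df):
            a = df.iloc[:, :6].mean(axis=1)
            b = df.iloc[:, 6:].mean(axis=1)
            grand = df.mean(axis=1)
            return 6 * ((a - grand) ** 2 + (b - grand) ** 2)

        out = adjust_location_scale(e, d, preserve_groups=False)
        before = between_var(e)
        after = between_var(out)
        assert (after < 0.01 * before).all()

    def test_preserve_groups_keeps_group_difference(self):
        rng = np.random.default_rng(5)
        n_genes = 40
        # two groups differing by +4, two batches differing by +10, crossed
        cols, batches, groups = [], [], []
        for b, bshift in (("A", 0.0), ("B", 10.0)):
            for g, gshift in (("g1", 0.0), ("g2", 4.0)):
                for _ in range(4):
                    cols.append(rng.normal(bshift + gshift, 0.5, size=n_genes))
                    batches.append(b)
                    groups.append(g)
        e = _expr(np.column_stack(cols))
        d = _design(batches, groups=groups, samples=list(e.columns))
        out = adjust_location_scale(e, d, preserve_groups=True)
        g1 = out.loc[:, [s for s, g in zip(e.columns, groups) if g == "g1"]]
        g2 = out.loc[:, [s for s, g in zip(e.columns, groups) if g == "g2"]]
        gap = (g2.mean(axis=1) - g1.mean(axis=1)).mean()
        assert gap == pytest.approx(4.0, abs=0.5)
        # and the batch means still converged
        a_cols = [s for s, b in zip(e.columns, batches) if b == "A"]
        b_cols = [s for s, b in zip(e.columns, batches) if b == "B"]
        assert np.allclose(
            out[a_cols].mean(axis=1), out[b_cols].mean(axis=1), atol=0.5
        )

    def test_zero_sd_batch_recentered_only(self):
        e = _expr([[1.0, 1.0, 4.0, 6.0]])
        d = _design(["A", "A", "B", "B"], samples=list(e.columns))
        out = adjust_location_scale(e, d, preserve_groups=False)
        # batch A is constant: both samples land on the grand mean
        assert out.iloc[0, 0] == pytest.approx(out.iloc[0, 1])
        assert out.iloc[0, 0] == pytest.approx(e.iloc[0].mean())

    def test_singleton_batch_named_in_error(self):
        e = _expr(np.random.default_rng(0).normal(size=(5, 3)))
        d = _design(["A", "A", "B"], samples=list(e.columns))
        with pytest.raises(ValueError, match="B"):
            adjust_location_scale(e, d)


class TestRegistry:
    def test_builtins_present(self):
        assert {"identity", "location_scale"} <= set(list_adjusters())

    def test_duplicate_name_rejected(self):
        with pytest.raises(ValueError, match="registered"):
            register_adjuster("identity", lambda e, d: e)

    def test_unknown_name_lists_known(self):
        with pytest.raises(KeyError, match="identity"):
            get_adjuster("no_such_adjuster")

    def test_roster_changing_adjuster_violates_contract(self):
        e = _expr(np.random.default_rng(0).normal(size=(5, 4)))
        d = _design(["A", "A", "B", "B"], samples=list(e.columns))

        def bad(expr, design):
            return expr.iloc[:, :-1]

        with pytest.raises(ValueError, match="contract"):
            apply_adjuster(bad, e, d)

    def test_identity_roundtrip(self):
        e = _expr(np.random.default_rng(0).normal(size=(5, 4)))
        d = _design(["A", "A", "B", "B"], samples=list(e.columns))
        pd.testing.assert_frame_equal(apply_adjuster("identity", e, d), e)
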
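"""Fisher-z machinery, pooling, contrasts, and the permutation alternative."""

import math

import numpy as np
import pytest
from scipy import stats

import eicopool as ep
from eicopool.correlation_pooling import CorrelationError, GroupKey, _one_sample_t


# --------------------------------------------------------------------------
# independent oracles
# --------------------------------------------------------------------------

def brute_force_spearman(x, y):
    """O(n^2) mid-rank Spearman: counting ranks, then explicit Pearson sums."""
    def midranks(v):
        v = list(v)
        return [
            1 + sum(1 for w in v if w < u) + (sum(1 for w in v if w == u) - 1) / 2.0
            for u in v
        ]

    rx, ry = midranks(x), midranks(y)
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


def textbook_one_sample_t(values):
    v = np.asarray(values)
    k = len(v)
    t = v.mean() / (v.std(ddof=1) / math.sqrt(k))
    return t, 2 * stats.t.sf(abs(t), k - 1)


def closed_form_partial(x, y, a):
    rxy = np.corrcoef(x, y)[0, 1]
    rxa = np.corrcoef(x, a)[0, 1]
    rya = np.corrcoef(y, a)[0, 1]
    return (rxy - rxa * rya) / math.sqrt((1 - rxa**2) * (1 - rya**2))


# --------------------------------------------------------------------------
# spearman
# --------------------------------------------------------------------------

class TestSpearman:
    def test_perfect_monotone(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert ep.spearman(x, np.exp(x))[0] == pytest.approx(1.0)
        assert ep.spearman(x, -x)[0] == pytest.approx(-1.0)

    def test_matches_brute_force_rank_oracle(self, rng):
        for _ in range(1000):
            n = rng.integers(4, 9)
            x = rng.integers(0, 5, n).astype(float)  # heavy ties
            y = rng.normal(size=n)
            if np.ptp(x) == 0:
                continue
            r, m = ep.spearman(x, y)
            assert m == n
            assert r == pytest.approx(brute_force_spearman(x, y), abs=1e-12)

    def test_pairwise_deletion_of_missing_values(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0, 6.0])
        y = np.array([2.0, 4.0, 6.0, np.nan, 10.0, 12.0])
        r, n = ep.spearman(x, y)
        assert n == 4
        assert r == pytest.approx(1.0)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(CorrelationError, match="4"):
            ep.spearman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_zero_rank_variance_flagged_undefined(self):
        r, n = ep.spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        assert math.isnan(r) and n == 4


# --------------------------------------------------------------------------
# partial correlation
# --------------------------------------------------------------------------

class TestPartialPearsonAge:
    def test_residual_method_matches_closed_form(self, rng):
        for _ in range(200):
            n = rng.integers(6, 30)
            x, y, a = rng.normal(size=(3, n))
            r, _ = ep.partial_pearson_age(x, y, a)
            assert r == pytest.approx(closed_form_partial(x, y, a), abs=1e-10)

    def test_independent_age_leaves_r_nearly_plain(self, rng):
        n = 4000
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        age = rng.normal(size=n)
        r_partial, _ = ep.partial_pearson_age(x, y, age)
        r_plain = np.corrcoef(x, y)[0, 1]
        assert r_partial == pytest.approx(r_plain, abs=0.03)

    def test_outcome_identical_to_age_is_flagged(self, rng):
        age = rng.normal(size=20)
        r, _ = ep.partial_pearson_age(rng.normal(size=20), age, age)
        assert math.isnan(r)

    def test_constant_age_falls_back_with_warning(self, rng):
        x, y = rng.normal(size=(2, 15))
        with pytest.warns(UserWarning, match="constant"):
            r, _ = ep.partial_pearson_age(x, y, np.full(15, 60.0))
        assert r == pytest.approx(np.corrcoef(x, y)[0, 1])

    def test_cross_checked_against_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        x, y, a = rng.normal(size=(3, 40))
        df = pd.DataFrame({"x": x, "y": y, "age": a})
        expected = pg.partial_corr(df, x="x", y="y", covar="age")["r"].iloc[0]
        r, _ = ep.partial_pearson_age(x, y, a)
        assert r == pytest.approx(expected, abs=1e-10)


# --------------------------------------------------------------------------
# fisher z and SE conventions
# --------------------------------------------------------------------------

class TestFisherZ:
    def test_closed_form_at_half(self):
        assert ep.fisher_z(0.5) == pytest.approx(0.5 * math.log(3.0), abs=1e-15)

    def test_odd_function(self):
        for r in (0.0, 0.3, 0.77):
            assert ep.fisher_z(-r) == pytest.approx(-ep.fisher_z(r), abs=1e-15)

    def test_round_trip_error_below_1e12_on_grid(self):
        grid = np.linspace(-0.99, 0.99, 397)
        err = max(abs(ep.fisher_z_inv(ep.fisher_z(r)) - r) for r in grid)
        assert err < 1e-12

    def test_unit_correlation_rejected(self):
        with pytest.raises(CorrelationError):
            ep.fisher_z(1.0)


class TestCorrelationSE:
    def test_printed_formula(self):
        assert ep.correlation_se(0.5, 27, "as-printed") == pytest.approx(0.1)

    def test_conventions_coincide_at_zero(self):
        for n in (5, 27, 100):
            assert ep.correlation_se(0.0, n, "as-printed") == pytest.approx(
                ep.correlation_se(0.0, n, "pearson-se")
            ) == pytest.approx(1 / math.sqrt(n - 2))

    def test_degenerate_perfect_correlation(self):
        assert ep.correlation_se(1.0, 10, "as-printed") == 0.0

    def test_unknown_convention_rejected(self):
        with pytest.raises(CorrelationError, match="convention"):
            ep.correlation_se(0.5, 10, "bootstrap")


# --------------------------------------------------------------------------
# pooling
# --------------------------------------------------------------------------

def make_records(zs, **kw):
    base = dict(precursor="AA", pathway="LOX", genotype="TT", timepoint="week4",
                n=25, se_convention="as-printed")
    base.update(kw)
    return [
        ep.CorrelationRecord(
            analyte=f"a{i}", r=math.tanh(z), z=z,
            se=ep.correlation_se(math.tanh(z), base["n"]), **base,
        )
        for i, z in enumerate(zs)
    ]


KEY = GroupKey("AA", "LOX", "TT", "week4")


class TestPoolGroup:
    def test_exact_null(self):
        g = ep.pool_group(make_records([0.0, 0.0, 0.0]), KEY)
        assert (g.t, g.p_raw, g.pooled_r) == (0.0, 1.0, 0.0)

    def test_symmetric_z_values_give_zero_t(self):
        g = ep.pool_group(make_records([-0.4, -0.1, 0.1, 0.4]), KEY)
        assert g.t == pytest.approx(0.0, abs=1e-15)

    def test_matches_textbook_one_sample_t(self):
        zs = [0.21, 0.05, 0.33, 0.18, 0.40]
        g = ep.pool_group(make_records(zs), KEY, family_size=14)
        t, p = textbook_one_sample_t(zs)
        assert g.t == pytest.approx(t, abs=1e-10)
        assert g.p_raw == pytest.approx(p, abs=1e-10)
        assert g.df == 4
        assert g.pooled_r == pytest.approx(math.tanh(np.mean(zs)), abs=1e-12)
        assert g.p_bonferroni == pytest.approx(min(1.0, 14 * p), abs=1e-12)

    def test_single_analyte_group_rejected_never_silent(self):
        with pytest.raises(CorrelationError, match=">= 2"):
            ep.pool_group(make_records([0.3]), KEY)

    def test_zero_spread_with_nonzero_mean_is_degenerate(self):
        g = ep.pool_group(make_records([0.3, 0.3, 0.3]), KEY)
        assert g.degenerate
        assert g.p_raw < 1e-300

    def test_mean_z_monotone_in_common_r_shift(self):
        rs = np.array([-0.2, 0.1, 0.3])
        means = []
        for shift in (0.0, 0.1, 0.2):
            recs = make_records([ep.fisher_z(r + shift) for r in rs])
            means.append(ep.pool_group(recs, KEY).mean_z)
        assert means[0] < means[1] < means[2]


class TestContrastTimepoints:
    def test_no_change_convention(self):
        r0 = make_records([0.1, 0.2, 0.3], timepoint="week0")
        r4 = make_records([0.1, 0.2, 0.3], timepoint="week4")
        c = ep.contrast_timepoints(r0, r4, GroupKey("AA", "LOX", "TT", "week4-week0"))
        assert c.no_change and c.p == 1.0 and c.t == 0.0

    def test_constant_shift_with_vanishing_jitter_drives_p_to_zero(self):
        base = [0.1, 0.2, 0.3, 0.15]
        key = GroupKey("AA", "LOX", "TT", "contrast")
        last = 1.0
        for jitter in (1e-2, 1e-4, 1e-6):
            r0 = make_records(base, timepoint="week0")
            z4 = [z + 0.3 + jitter * (-1) ** i for i, z in enumerate(base)]
            r4 = make_records(z4, timepoint="week4")
            p = ep.contrast_timepoints(r0, r4, key).p
            assert p < last
            last = p
        assert last < 1e-8

    def test_matches_textbook_paired_t(self):
        z0 = [0.12, -0.05, 0.30, 0.22]
        z4 = [0.35, 0.02, 0.41, 0.19]
        r0 = make_records(z0, timepoint="week0")
        r4 = make_records(z4, timepoint="week4")
        c = ep.contrast_timepoints(r0, r4, GroupKey("AA", "LOX", "TT", "contrast"))
        t, p = textbook_one_sample_t(np.subtract(z4, z0))
        assert c.t == pytest.approx(t, abs=1e-10)
        assert c.p == pytest.approx(p, abs=1e-10)
        assert c.df == 3

    def test_mismatched_analyte_sets_listed(self):
        r0 = make_records([0.1, 0.2, 0.3], timepoint="week0")
        r4 = make_records([0.1, 0.2], timepoint="week4")
        with pytest.raises(CorrelationError, match="a2"):
            ep.contrast_timepoints(r0, r4, GroupKey("AA", "LOX", "TT", "contrast"))


class TestBonferroni:
    def test_family_of_fourteen_worked_pair(self):
        assert ep.bonferroni(0.003, 14) == pytest.approx(0.042, abs=1e-12)

    def test_capped_at_one(self):
        assert ep.bonferroni(0.2, 10) == 1.0

    def test_family_one_is_identity(self):
        assert ep.bonferroni(0.037, 1) == pytest.approx(0.037)

    def test_empty_family_rejected(self):
        with pytest.raises(CorrelationError):
            ep.bonferroni(0.05, 0)


# --------------------------------------------------------------------------
# permutation alternative
# --------------------------------------------------------------------------

class TestPermutationNull:
    def test_seed_determinism(self, rng):
        x = rng.normal(size=25)
        Y = rng.normal(size=(25, 6))
        assert ep.permutation_null(x, Y, 299, seed=5) == ep.permutation_null(
            x, Y, 299, seed=5
        )

    def test_strong_signal_attains_the_floor(self, rng):
        x = rng.normal(size=30)
        Y = x[:, None] + 0.05 * rng.normal(size=(30, 5))
        p, mean_z = ep.permutation_null(x, Y, 199, seed=0)
        assert p == pytest.approx(1.0 / 200.0)
        assert mean_z > 1.0

    def test_too_few_permutations_rejected(self, rng):
        with pytest.raises(CorrelationError, match="199"):
            ep.permutation_null(rng.normal(size=10), rng.normal(size=(10, 3)), 50)

    def test_agrees_with_t_test_on_null_replicates(self):
        """Rejection decisions at alpha=0.05 coincide on >= 90% of nulls."""
        rng = np.random.default_rng(7)
        agree = 0
        n_rep = 120
        for _ in range(n_rep):
            x = rng.normal(size=25)
            Y = rng.normal(size=(25, 8))
            p_perm, _ = ep.permutation_null(x, Y, 399, seed=int(rng.integers(2**31)))
            zs = [ep.fisher_z(ep.spearman(x, Y[:, j])[0]) for j in range(8)]
            _, _, p_t, _ = _one_sample_t(np.array(zs))
            agree += (p_perm < 0.05) == (p_t < 0.05)
        assert agree / n_rep >= 0.90


def test_correlate_panel_is_invariant_to_input_row_order(showcase_cohort, showcase_scores):
    panel = ep.default_panel()
    recs_a = ep.correlate_panel(showcase_scores, showcase_cohort, panel)
    shuffled = showcase_cohort.sample(frac=1.0, random_state=3).reset_index(drop=True)
    recs_b = ep.correlate_panel(showcase_scores, shuffled, panel)
    assert recs_a == recs_b
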
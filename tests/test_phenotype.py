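import numpy as np
import pandas as pd
import pytest

from mirpath.data_io import ExpressionMatrix, PhenotypeTable
from mirpath.errors import ValidationError
from mirpath.phenotype import (
    activity_group_test,
    fisher_z_contrast,
    gene_level_correlation,
    group_correlation,
    scan_stratification,
    survival_split_test,
)


def phenotypes(groups, time=None, event=None):
    samples = [f"S{i}" for i in range(len(groups))]
    data = {"group": groups}
    if time is not None:
        data["time"] = time
        data["event"] = event
    return PhenotypeTable(
        table=pd.DataFrame(data, index=pd.Index(samples, name="sample"))
    ), samples


def series(values, samples, name="P"):
    return pd.Series(np.asarray(values, dtype=float), index=samples, name=name)


class TestActivityGroupTest:
    def test_identical_groups_do_not_separate(self):
        phen, samples = phenotypes(["A"] * 5 + ["B"] * 5)
        row = series(list(range(5)) + list(range(5)), samples)
        res = activity_group_test(row, phen, "A", "B")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(0)
        phen, samples = phenotypes(["A"] * 50 + ["B"] * 50)
        row = series(
            np.concatenate([rng.normal(0.7, 0.05, 50), rng.normal(0.3, 0.05, 50)]), samples
        )
        res = activity_group_test(row, phen, "A", "B")
        assert res.p_value < 1e-10
        assert res.group_summary["A"]["mean"] > res.group_summary["B"]["mean"]

    def test_unknown_label_is_named_in_error(self):
        phen, samples = phenotypes(["A"] * 4 + ["B"] * 4)
        with pytest.raises(ValidationError, match="ER\\+"):
            activity_group_test(series(range(8), samples), phen, "ER+", "B")

    def test_tiny_group_rejected(self):
        phen, samples = phenotypes(["A"] * 1 + ["B"] * 7)
        with pytest.raises(ValidationError):
            activity_group_test(series(range(8), samples), phen, "A", "B")

    def test_affine_rescaling_preserves_p(self):
        rng = np.random.default_rng(1)
        phen, samples = phenotypes(["A"] * 30 + ["B"] * 30)
        base = rng.uniform(size=60)
        p1 = activity_group_test(series(base, samples), phen, "A", "B").p_value
        p2 = activity_group_test(series(3.5 * base - 1.2, samples), phen, "A", "B").p_value
        assert p1 == pytest.approx(p2, rel=1e-9)


class TestSurvivalSplitTest:
    def test_identical_halves_give_null_result(self):
        time = [100, 200, 300, 400, 500] * 2
        event = [True] * 10
        phen, samples = phenotypes(["A"] * 10, time=time, event=event)
        # activity splits into halves with identical survival profiles
        row = series([0.1] * 5 + [0.9] * 5, samples)
        res = survival_split_test(row, phen)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)

    def test_planted_hazard_ratio_detected(self):
        detected = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            n = 200
            risk = np.array([0.8] * (n // 2) + [0.2] * (n // 2))
            rate = np.where(risk > 0.5, 3.0 / 1000, 1.0 / 1000)
            raw = rng.exponential(1 / rate)
            event = raw <= 2000
            time = np.minimum(raw, 2000)
            phen, samples = phenotypes(["A"] * n, time=time, event=event)
            res = survival_split_test(series(risk, samples), phen)
            detected += res.p_value < 0.001
        assert detected >= 0.95 * n_seeds

    def test_nine_samples_rejected(self):
        phen, samples = phenotypes(["A"] * 9, time=[100.0] * 9, event=[True] * 9)
        with pytest.raises(ValidationError, match=">= 10"):
            survival_split_test(series(range(9), samples), phen)

    def test_fully_censored_rejected(self):
        phen, samples = phenotypes(["A"] * 12, time=[100.0] * 12, event=[False] * 12)
        with pytest.raises(ValidationError, match="censored"):
            survival_split_test(series(range(12), samples), phen)


def simulate_groups(rho_a, rho_b, n, rng):
    """Bivariate-normal pairs with group-specific correlation."""
    za, ea = rng.normal(size=(2, n))
    zb, eb = rng.normal(size=(2, n))
    xa, ya = za, rho_a * za + np.sqrt(1 - rho_a**2) * ea
    xb, yb = zb, rho_b * zb + np.sqrt(1 - rho_b**2) * eb
    phen, samples = phenotypes(["A"] * n + ["B"] * n)
    x = series(np.concatenate([xa, xb]), samples, name="miR")
    y = series(np.concatenate([ya, yb]), samples, name="P")
    return x, y, phen


class TestGroupCorrelation:
    def test_equal_correlations_give_null_contrast(self):
        rng = np.random.default_rng(0)
        n = 40
        z = rng.normal(size=n)
        x = np.concatenate([z, z])
        y = np.concatenate([2 * z + 1, 2 * z + 1])
        phen, samples = phenotypes(["A"] * n + ["B"] * n)
        res = group_correlation(series(x, samples), series(y, samples), phen, ("A", "B"))
        assert res.z == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)

    def test_planted_differential_correlation_recovered(self):
        rng = np.random.default_rng(7)
        x, y, phen = simulate_groups(-0.6, 0.0, 150, rng)
        res = group_correlation(x, y, phen, ("A", "B"))
        assert res.r_by_group["A"] == pytest.approx(-0.6, abs=0.15)
        assert abs(res.r_by_group["B"]) < 0.15
        assert res.p_value < 0.001

    def test_zero_variance_group_is_flagged(self):
        phen, samples = phenotypes(["A"] * 5 + ["B"] * 5)
        x = series(range(10), samples)
        y = series([1.0] * 5 + [1, 2, 3, 4, 5], samples)
        res = group_correlation(x, y, phen, ("A", "B"))
        assert "zero_variance:A" in res.flags
        assert np.isnan(res.z)

    def test_spearman_is_rank_invariant(self):
        rng = np.random.default_rng(3)
        x, y, phen = simulate_groups(-0.6, 0.0, 60, rng)
        res_raw = group_correlation(x, y, phen, ("A", "B"), method="spearman")
        res_exp = group_correlation(x, np.exp(y), phen, ("A", "B"), method="spearman")
        assert res_raw.r_by_group["A"] == pytest.approx(res_exp.r_by_group["A"])

    def test_small_group_rejected(self):
        phen, samples = phenotypes(["A"] * 3 + ["B"] * 5)
        with pytest.raises(ValidationError, match="fewer than 4"):
            group_correlation(series(range(8), samples), series(range(8), samples),
                              phen, ("A", "B"))

    def test_fisher_z_needs_four_per_group(self):
        with pytest.raises(ValidationError):
            fisher_z_contrast(0.5, 3, 0.1, 10)


class TestGeneLevelCorrelation:
    def test_one_record_per_measured_target(self):
        rng = np.random.default_rng(11)
        n = 30
        phen, samples = phenotypes(["A"] * n + ["B"] * n)
        genes = [f"G{i}" for i in range(6)]
        expr = ExpressionMatrix(
            values=pd.DataFrame(rng.normal(size=(6, 2 * n)), index=genes, columns=samples)
        )
        mir = series(rng.normal(size=2 * n), samples, name="miR")
        results = gene_level_correlation(mir, expr, genes, phen, ("A", "B"))
        assert len(results) == 6
        assert {r.pathway_id for r in results} == {f"gene:{g}" for g in genes}

    def test_absent_gene_skipped(self):
        rng = np.random.default_rng(12)
        n = 20
        phen, samples = phenotypes(["A"] * n + ["B"] * n)
        expr = ExpressionMatrix(
            values=pd.DataFrame(rng.normal(size=(1, 2 * n)), index=["G0"], columns=samples)
        )
        mir = series(rng.normal(size=2 * n), samples)
        results = gene_level_correlation(mir, expr, ["G0", "MISSING"], phen, ("A", "B"))
        assert len(results) == 1

    def test_sign_mixed_targets_recovered(self):
        # 3 repressed (negative r) and 3 activated (positive r) targets in group A
        rng = np.random.default_rng(13)
        n = 150
        driver = rng.normal(size=n)
        phen, samples = phenotypes(["A"] * n + ["B"] * n)
        rows, signs = [], [-1, -1, -1, +1, +1, +1]
        for s in signs:
            resid = 0.7 * s * driver + np.sqrt(1 - 0.49) * rng.normal(size=n)
            rows.append(np.concatenate([resid, rng.normal(size=n)]))
        expr = ExpressionMatrix(
            values=pd.DataFrame(rows, index=[f"G{i}" for i in range(6)], columns=samples)
        )
        mir = series(np.concatenate([driver, rng.normal(size=n)]), samples)
        results = gene_level_correlation(mir, expr, [f"G{i}" for i in range(6)],
                                         phen, ("A", "B"))
        recovered = [np.sign(r.r_by_group["A"]) for r in results]
        assert recovered == signs


def test_scan_stratification_ranks_planted_pathway_first(small_bundle):
    from mirpath.activity import fit_gene_states, pathway_activity

    states = fit_gene_states(small_bundle.mrna)
    act = pathway_activity(small_bundle.pathways, states)
    frame = scan_stratification(act.values, small_bundle.phenotypes, "A", "B")
    assert frame.iloc[0]["pathway_id"] == small_bundle.ground_truth.focal_pathway
    assert set(frame.columns) >= {"pathway_id", "statistic", "p_value", "q_value"}
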
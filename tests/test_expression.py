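import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mitoscreen import (
    ExpressionMatrix,
    GeneList,
    adjust_scores,
    control_normalize,
    organelle_score,
    percent_change,
)
from mitoscreen.stats import welch_t_test
from mitoscreen.synthetic import ScenarioSpec, gen_expression

GROUPS22 = {"WT_1": "WT", "WT_2": "WT", "KO_1": "KO", "KO_2": "KO"}


def _matrix(rows, scale="linear", index=None):
    df = pd.DataFrame(rows, columns=list(GROUPS22), index=index or [f"G{i}" for i in range(len(rows))])
    return ExpressionMatrix(values=df, sample_groups=GROUPS22, scale=scale)


def test_control_normalize_arithmetic():
    m = _matrix([[2.0, 2.0, 1.0, 3.0]])
    out = control_normalize(m, "WT")
    np.testing.assert_allclose(out.values.iloc[0], [1.0, 1.0, 0.5, 1.5])


def test_control_normalize_identity_on_constant():
    m = _matrix([[5.0] * 4, [7.0] * 4])
    out = control_normalize(m, "WT")
    assert (out.values == 1.0).all().all()


def test_control_normalize_unlogs_log2_input():
    # log2 row (1,1,0,2) -> intensities (2,2,1,4) -> ratios (1,1,0.5,2)
    m = _matrix([[1.0, 1.0, 0.0, 2.0]], scale="log2")
    out = control_normalize(m, "WT")
    np.testing.assert_allclose(out.values.iloc[0], [1.0, 1.0, 0.5, 2.0])


def test_control_normalize_error_contracts():
    m = _matrix([[0.0, 0.0, 1.0, 1.0]])
    with pytest.raises(ValueError, match="G0"):
        control_normalize(m, "WT")
    single = ExpressionMatrix(
        values=pd.DataFrame({"A": [1.0], "B": [1.0]}, index=["G"]),
        sample_groups={"A": "WT", "B": "KO"},
        scale="linear",
    )
    with pytest.raises(ValueError, match="fewer than 2"):
        control_normalize(single, "WT")


def test_organelle_score_null_case():
    m = _matrix([[1.0] * 4, [1.0] * 4], scale="ratio")
    gl = GeneList(name="l", members=frozenset({"G0", "G1"}))
    r = organelle_score(m, gl, "WT", "KO")
    assert all(v == 1.0 for v in r.per_sample_score.values())
    assert r.group_mean_change == 0.0
    assert r.p_raw == 1.0


def test_uniform_repression_reported_as_minus_25_percent():
    # condition samples uniformly 0.75x control for every list gene
    m = _matrix([[1.0, 1.0, 0.75, 0.75], [1.0, 1.0, 0.75, 0.75]], scale="ratio")
    gl = GeneList(name="mito", members=frozenset({"G0", "G1"}))
    r = organelle_score(m, gl, "WT", "KO")
    assert r.group_mean_change == pytest.approx(-0.25)
    assert percent_change(r) == pytest.approx(-25.0)


@pytest.mark.parametrize("change,expected", [(0.20, 20.0), (-0.25, -25.0), (0.0, 0.0)])
def test_percent_change_sign_convention(change, expected):
    from mitoscreen.expression import OrganelleScoreResult

    r = OrganelleScoreResult(
        organelle="x", per_sample_score={}, group_mean_change=change,
        p_raw=0.5, n_genes=10, control_group="WT", condition_group="KO",
    )
    assert percent_change(r) == expected


def test_bonferroni_adjustment_modes():
    from mitoscreen.expression import OrganelleScoreResult

    def res(p, n):
        return OrganelleScoreResult(
            organelle="x", per_sample_score={}, group_mean_change=0.0,
            p_raw=p, n_genes=n, control_group="WT", condition_group="KO",
        )

    (r,) = adjust_scores([res(0.0001, 100)])
    assert r.p_adjusted == pytest.approx(0.01)
    (r,) = adjust_scores([res(0.02, 100)])
    assert r.p_adjusted == 1.0  # capped
    (r,) = adjust_scores([res(0.03, 100)], mode="per_list_bonferroni")
    assert r.p_adjusted == pytest.approx(0.03)  # single list: identity


def test_planted_effect_recovery_monte_carlo():
    """A 20% planted increase on a 200-gene list (6v6, sigma=0.1) is
    recovered within +-3 percentage points."""
    spec = ScenarioSpec(
        n_genes=400,
        organelle_lists={"mito": 200},
        planted_effects={"mito": 1.20},
        seed=11,
    )
    matrix, _ = gen_expression(spec)
    ratios = control_normalize(matrix, "WT")
    gl = GeneList(name="mito", members=frozenset(spec.gene_ids()[:200]))
    r = organelle_score(ratios, gl, "WT", "KO")
    assert r.group_mean_change == pytest.approx(0.20, abs=0.03)


def test_scale_invariance_of_scores():
    """Multiplying one gene's raw values by a constant leaves all scores
    unchanged: control normalization cancels per-gene scale."""
    rng = np.random.default_rng(3)
    vals = rng.lognormal(3, 0.2, size=(5, 4))
    m1 = _matrix(vals.tolist())
    vals2 = vals.copy()
    vals2[2] *= 37.5
    m2 = _matrix(vals2.tolist())
    gl = GeneList(name="l", members=frozenset({"G1", "G2", "G3"}))
    r1 = organelle_score(control_normalize(m1, "WT"), gl, "WT", "KO")
    r2 = organelle_score(control_normalize(m2, "WT"), gl, "WT", "KO")
    np.testing.assert_allclose(
        list(r1.per_sample_score.values()), list(r2.per_sample_score.values())
    )
    assert r1.p_raw == pytest.approx(r2.p_raw)


def test_welch_matches_scipy_reference():
    rng = np.random.default_rng(0)
    for _ in range(50):
        x = rng.normal(0, rng.uniform(0.5, 2), size=rng.integers(3, 12))
        y = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2), size=rng.integers(3, 12))
        t, _, p = welch_t_test(x, y)
        ref = sps.ttest_ind(x, y, equal_var=False)
        assert abs(t - ref.statistic) < 1e-10
        assert abs(p - ref.pvalue) < 1e-10
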
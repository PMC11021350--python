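import numpy as np
import pytest

from statetrace.cmr import (
    SummaryStatInput,
    adjust_pvalues,
    cmr_from_summary,
    cmr_test,
)

from .conftest import monotone_state_trace


def test_monotone_data_give_p_one_in_every_mode():
    """With zero observed misfit no bootstrap statistic can be smaller, so
    the add-one p-value is exactly 1 regardless of seed or mode."""
    data = monotone_state_trace(n_cond=5, with_backing=True)
    for seed in (0, 99):
        res = cmr_test(data, n_boot=49, seed=seed, mode="participant_resample")
        assert res.observed_stat == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == 1.0
    res = cmr_test(data, n_boot=49, seed=0, mode="parametric_normal")
    assert res.p_value == 1.0


def test_p_value_range_and_formula():
    rng = np.random.default_rng(5)
    data = monotone_state_trace(n_cond=5, with_backing=True, seed=3)
    data.x_means[2], data.x_means[3] = data.x_means[3], data.x_means[2]  # break order
    data.x_backing[:] = data.x_means + (data.x_backing - data.x_backing.mean(axis=0))
    data.x_backing += rng.normal(0, 0.05, size=data.x_backing.shape)
    data.x_means[:] = data.x_backing.mean(axis=0)
    n_boot = 99
    res = cmr_test(data, n_boot=n_boot, seed=1)
    assert 1 / (n_boot + 1) <= res.p_value <= 1.0
    count = int(np.sum(res.boot_stats >= res.observed_stat - 1e-12))
    assert res.p_value == pytest.approx((1 + count) / (n_boot + 1))
    assert res.observed_stat == pytest.approx(res.model.fit_stat)


def test_bitwise_reproducibility_given_seed():
    data = monotone_state_trace(n_cond=6, with_backing=True, seed=8)
    a = cmr_test(data, n_boot=60, seed=123)
    b = cmr_test(data, n_boot=60, seed=123)
    assert np.array_equal(a.boot_stats, b.boot_stats)
    assert a.p_value == b.p_value
    c = cmr_test(data, n_boot=60, seed=124, mode="parametric_normal")
    d = cmr_test(data, n_boot=60, seed=124, mode="parametric_normal")
    assert np.array_equal(c.boot_stats, d.boot_stats)


def test_missing_backing_is_an_input_error():
    data = monotone_state_trace(n_cond=4, with_backing=False)
    with pytest.raises(ValueError, match="backing"):
        cmr_test(data, n_boot=9, mode="participant_resample")
    with pytest.raises(ValueError, match="n_boot"):
        cmr_test(data, n_boot=0, mode="parametric_normal")
    with pytest.raises(ValueError, match="mode"):
        cmr_test(data, n_boot=9, mode="wild")


def _summary(means, sds=1.0, ns=20):
    means = np.asarray(means, dtype=float)
    k = means.shape[0]
    return SummaryStatInput(
        condition_labels=[f"g{i}" for i in range(k)],
        dv_names=("cognitive", "affective"),
        means=means,
        sds=np.full((k, 2), sds),
        ns=np.full((k, 2), ns),
    )


def test_summary_identical_means_give_p_one():
    res = cmr_from_summary(_summary([[0.6, 0.7], [0.6, 0.7]]), n_boot=19, seed=0)
    assert res.observed_stat == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == 1.0


def test_summary_monotone_means_give_p_one():
    means = np.column_stack([np.linspace(0.3, 0.9, 5), np.linspace(0.2, 0.8, 5)])
    res = cmr_from_summary(_summary(means, sds=1.0, ns=20), n_boot=19, seed=0)
    assert res.observed_stat == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == 1.0


def test_summary_small_departure_large_sd_not_significant():
    """A published-style dissociation (one group depressed on one variable
    only) whose departure is small relative to the group SDs should not
    reject; the p-value is cross-checked by an independent longer run."""
    means = np.column_stack([np.linspace(0.4, 0.8, 5), np.linspace(0.3, 0.7, 5)])
    means[2, 1] -= 0.06  # dissociation on the second variable only
    summary = _summary(means, sds=0.5, ns=20)
    res = cmr_from_summary(summary, n_boot=999, seed=4)
    assert res.p_value > 0.05
    longer = cmr_from_summary(summary, n_boot=9_999, seed=5)
    assert longer.p_value > 0.05
    assert res.p_value == pytest.approx(longer.p_value, abs=0.05)


def test_summary_input_validation():
    with pytest.raises(ValueError, match="sd"):
        _summary([[0.5, 0.5], [0.6, 0.6]], sds=0.0)
    with pytest.raises(ValueError, match="n must be"):
        _summary([[0.5, 0.5], [0.6, 0.6]], ns=1)


def test_summary_csv_round_trip(tmp_path):
    import pandas as pd

    rows = []
    for g, (mx, my) in enumerate([(0.4, 0.3), (0.6, 0.5), (0.8, 0.7)]):
        rows.append({"condition": f"g{g}", "dv": "cog", "mean": mx, "sd": 0.4, "n": 25})
        rows.append({"condition": f"g{g}", "dv": "aff", "mean": my, "sd": 0.5, "n": 25})
    path = tmp_path / "summary.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    summary = SummaryStatInput.from_csv(path)
    assert summary.dv_names == ("cog", "aff")
    assert summary.means.shape == (3, 2)
    data = summary.to_state_trace()
    assert data.x_weights[0] == pytest.approx(25 / 0.4**2)


@pytest.mark.parametrize(
    "p, m, expected",
    [
        ((0.01, 0.02, 0.03), 3, (0.03, 0.06, 0.09)),
        ((0.5,), 3, (1.0,)),
        ((0.0003, 0.0001, 0.0002), 3, (0.0009, 0.0003, 0.0006)),
    ],
)
def test_bonferroni_adjustment(p, m, expected):
    assert adjust_pvalues(p, m) == pytest.approx(expected)


def test_bonferroni_validation():
    with pytest.raises(ValueError):
        adjust_pvalues([0.0], 3)
    with pytest.raises(ValueError):
        adjust_pvalues([1.5], 3)
    with pytest.raises(ValueError):
        adjust_pvalues([0.5], 0)
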
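import numpy as np
import pytest

from statetrace.cmr import StateTraceData, cmr_fit, cmr_from_summary
from statetrace.pipeline import condition_grid, load_responses
from statetrace.synthetic import (
    DELTA_PRESETS,
    SyntheticConfig,
    cell_probabilities,
    default_theta,
    sample_dataset,
    sample_summary_dataset,
)

from .oracles import exhaustive_cmr_oracle


def test_logistic_link_midpoint():
    config = SyntheticConfig(
        theta=np.zeros(20), link_params={"think": (1.0, 0.0), "do": (1.0, 0.0), "feel": (1.0, 0.0)}
    )
    probs = cell_probabilities(config)
    assert np.allclose(probs.to_numpy(), 0.5)


def _population_fit(probs, pair, method="multistart_heuristic"):
    data = StateTraceData(
        condition_labels=condition_grid(),
        x_means=probs[pair[0]].to_numpy(),
        y_means=probs[pair[1]].to_numpy(),
        x_weights=np.ones(20),
        y_weights=np.ones(20),
    )
    return cmr_fit(data, method=method).fit_stat


PAIRS = [("think", "feel"), ("do", "feel"), ("think", "do")]


def test_one_latent_population_is_jointly_monotone():
    probs = cell_probabilities(SyntheticConfig(model="one_latent"))
    for pair in PAIRS:
        assert _population_fit(probs, pair) == pytest.approx(0.0, abs=1e-12)
    # exactness spot-check on a subsample small enough for full enumeration
    sub = np.argsort(default_theta())[:7]
    x = probs["think"].to_numpy()[sub]
    y = probs["feel"].to_numpy()[sub]
    assert exhaustive_cmr_oracle(x, y) == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("preset", ["small", "medium", "large"])
def test_two_latent_population_departs_for_every_pair(preset):
    probs = cell_probabilities(
        SyntheticConfig(model="two_latent", delta=DELTA_PRESETS[preset])
    )
    for pair in PAIRS:
        assert _population_fit(probs, pair) > 1e-4, (preset, pair)


def test_two_latent_departure_confirmed_by_exhaustive_oracle():
    """On a 7-condition subsample containing crossing conditions, the
    independent enumeration oracle also reports a strictly positive misfit."""
    probs = cell_probabilities(
        SyntheticConfig(model="two_latent", delta=DELTA_PRESETS["large"])
    )
    x_all = probs["do"].to_numpy()
    y_all = probs["feel"].to_numpy()
    best = 0.0
    order = np.argsort(default_theta())
    for lo in range(0, 14, 7):
        sub = order[lo : lo + 7]
        best = max(best, exhaustive_cmr_oracle(x_all[sub], y_all[sub]))
    assert best > 1e-4


def test_delta_zero_reduces_to_one_latent():
    one = sample_dataset(SyntheticConfig(model="one_latent", n_participants=6, seed=42))
    two = sample_dataset(
        SyntheticConfig(model="two_latent", delta=0.0, n_participants=6, seed=42)
    )
    assert one.responses_csv() == two.responses_csv()
    assert one.ep_scores == two.ep_scores
    s_one = sample_summary_dataset(SyntheticConfig(model="one_latent", seed=9), n_per_group=30)
    s_two = sample_summary_dataset(
        SyntheticConfig(model="two_latent", delta=0.0, seed=9), n_per_group=30
    )
    assert np.array_equal(s_one.means, s_two.means)
    assert np.array_equal(s_one.sds, s_two.sds)


def test_grid_row_count_and_determinism():
    # 10 within-participant cells x (3 probe + 1 say) questions per item
    config = SyntheticConfig(n_participants=2, items_per_cell=1, seed=3)
    ds = sample_dataset(config)
    assert len(ds.responses) == 2 * 10 * 1 * 4
    no_say = sample_dataset(
        SyntheticConfig(n_participants=2, items_per_cell=1, seed=3, include_say=False)
    )
    assert len(no_say.responses) == 2 * 10 * 1 * 3
    again = sample_dataset(SyntheticConfig(n_participants=2, items_per_cell=1, seed=3))
    assert ds.responses_csv() == again.responses_csv()


def test_emitted_files_round_trip(tmp_path):
    ds = sample_dataset(SyntheticConfig(n_participants=4, seed=13, dont_know_rate=0.01))
    path = tmp_path / "r.csv"
    ds.write(path, tmp_path / "ep.csv")
    records = load_responses(path)
    assert len(records) == len(ds.responses)


def test_exact_dont_know_injection():
    config = SyntheticConfig(
        n_participants=10, layout="tasit", dont_know_count=25, seed=1
    )
    ds = sample_dataset(config)
    dk = ds.responses[ds.responses["response"] == "dont_know"]
    assert len(dk) == 25
    assert set(dk["question_type"]) <= {"think", "do", "feel"}


def test_ep_scores_reflect_generating_groups():
    ds = sample_dataset(SyntheticConfig(n_participants=200, seed=17))
    high = [s for p, s in ds.ep_scores.items() if ds.true_groups[p] == "high"]
    low = [s for p, s in ds.ep_scores.items() if ds.true_groups[p] == "low"]
    assert np.mean(high) > np.mean(low) + 2
    assert all(0 <= s <= 28 for s in ds.ep_scores.values())


def test_config_validation():
    with pytest.raises(ValueError, match="model"):
        SyntheticConfig(model="three_latent")
    with pytest.raises(ValueError, match="items_per_cell"):
        SyntheticConfig(items_per_cell=0)
    with pytest.raises(ValueError, match="delta"):
        SyntheticConfig(delta=-0.1)
    with pytest.raises(ValueError, match="theta"):
        SyntheticConfig(theta=np.zeros(5))


def test_config_from_yaml(tmp_path):
    path = tmp_path / "config.yaml"
    path.write_text(
        "model: two_latent\ndelta: large\nn_participants: 30\nseed: 4\n"
    )
    config = SyntheticConfig.from_yaml(path)
    assert config.model == "two_latent"
    assert config.delta == DELTA_PRESETS["large"]
    assert config.n_participants == 30


def test_summary_one_latent_rarely_rejects():
    hits = 0
    for seed in range(10):
        summary = sample_summary_dataset(
            SyntheticConfig(model="one_latent", seed=seed), n_groups=5, n_per_group=100
        )
        res = cmr_from_summary(summary, n_boot=199, seed=1000 + seed)
        hits += res.p_value > 0.05
    assert hits >= 9


def test_summary_two_latent_large_delta_rejects():
    hits = 0
    for seed in range(10):
        summary = sample_summary_dataset(
            SyntheticConfig(model="two_latent", delta=DELTA_PRESETS["large"], seed=seed),
            n_groups=5,
            n_per_group=200,
        )
        res = cmr_from_summary(summary, n_boot=199, seed=2000 + seed)
        hits += res.p_value < 0.05
    assert hits >= 8
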
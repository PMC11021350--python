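"""Monte-Carlo studies of the CMR bootstrap test: type-I error under the
one-latent null and power against the two-latent alternative.

Each simulated dataset runs through the full pipeline (generation, don't-
know screening, endorsement scoring, median split, state-trace assembly,
bootstrap test), so these studies exercise every stage end to end.
"""

from __future__ import annotations

import numpy as np

from .cmr import cmr_test
from .pipeline import (
    DV_PAIRS,
    build_state_trace,
    endorsement_proportions,
    median_split,
    responses_from_frame,
    run_three_analyses,
    screen_dont_know,
)
from .synthetic import DELTA_PRESETS, SyntheticConfig, sample_dataset


def analyze_synthetic(config: SyntheticConfig, n_boot: int, seed: int, dv_pair=None):
    """Generate one dataset from ``config`` and test it.

    With ``dv_pair`` given, runs a single CMR test for that pair; otherwise
    runs the three pairwise analyses with Bonferroni m = 3.
    """
    ds = sample_dataset(config)
    records = responses_from_frame(ds.responses)
    kept, _ = screen_dont_know(records)
    table = endorsement_proportions(kept)
    grouping = median_split(ds.ep_scores)
    if dv_pair is not None:
        data = build_state_trace(table, grouping, dv_pair)
        return cmr_test(data, n_boot=n_boot, seed=seed, mode="participant_resample")
    return run_three_analyses(table, grouping, n_boot=n_boot, seed=seed)


def type_one_error_study(
    n_datasets: int = 200,
    n_participants: int = 50,
    n_boot: int = 199,
    alpha: float = 0.05,
    seed: int = 1,
    dv_pair: tuple[str, str] = ("think", "feel"),
) -> dict:
    """Empirical rejection rate of the CMR test under the one-latent null.

    Dataset b uses generator seed ``seed + b`` and an independent bootstrap
    seed, mirroring repeated applications of the full analysis to null data.
    """
    rejections = 0
    p_values = []
    for b in range(n_datasets):
        config = SyntheticConfig(
            model="one_latent", n_participants=n_participants, seed=seed + b
        )
        boot_seed = int(
            np.random.SeedSequence([seed, b]).generate_state(1)[0] % (2**31)
        )
        result = analyze_synthetic(config, n_boot=n_boot, seed=boot_seed, dv_pair=dv_pair)
        p_values.append(result.p_value)
        if result.p_value < alpha:
            rejections += 1
    return {
        "n_datasets": n_datasets,
        "n_participants": n_participants,
        "n_boot": n_boot,
        "alpha": alpha,
        "rejections": rejections,
        "rejection_rate": rejections / n_datasets,
        "p_values": p_values,
    }


def power_study(
    n_datasets: int = 10,
    n_participants: int = 114,
    n_boot: int = 199,
    alpha: float = 0.05,
    seed: int = 1,
    delta: float | str = "large",
) -> dict:
    """Proportion of simulated two-latent datasets for which all three
    Bonferroni-adjusted pairwise analyses reject — the synthetic analogue of
    finding every pairwise state-trace departure significant."""
    if isinstance(delta, str):
        delta = DELTA_PRESETS[delta]
    all_reject = 0
    per_pair = {pair: 0 for pair in DV_PAIRS}
    for b in range(n_datasets):
        config = SyntheticConfig(
            model="two_latent",
            n_participants=n_participants,
            delta=float(delta),
            seed=seed + b,
        )
        boot_seed = int(
            np.random.SeedSequence([seed, b]).generate_state(1)[0] % (2**31)
        )
        results = analyze_synthetic(config, n_boot=n_boot, seed=boot_seed)
        sig = {pair: res.p_adjusted < alpha for pair, res in results.items()}
        for pair, hit in sig.items():
            per_pair[pair] += int(hit)
        if all(sig.values()):
            all_reject += 1
    return {
        "n_datasets": n_datasets,
        "n_participants": n_participants,
        "n_boot": n_boot,
        "alpha": alpha,
        "delta": float(delta),
        "all_three_reject": all_reject,
        "all_three_rate": all_reject / n_datasets,
        "per_pair_rate": {
            "_".join(pair): count / n_datasets for pair, count in per_pair.items()
        },
    }
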
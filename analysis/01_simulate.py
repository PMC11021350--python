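"""Generate the two study datasets used throughout the analysis chain.

Writes under results/data/:
  one_latent_{responses,ep}.csv  - 114 participants, null model (a single
                                   latent value per condition drives all
                                   three probe questions);
  two_latent_{responses,ep}.csv  - same size, large-departure alternative
                                   (a second latent dimension pushes "do"
                                   and "feel" in opposite directions).

Both use the instrument layout (31 scenes x 4 questions) with a realistic
trickle of don't-know responses.
"""

from pathlib import Path

from statetrace.synthetic import DELTA_PRESETS, SyntheticConfig, sample_dataset

OUT = Path(__file__).resolve().parents[1] / "results" / "data"
SEED = 20260923


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    for name, model, delta in [
        ("one_latent", "one_latent", 0.0),
        ("two_latent", "two_latent", DELTA_PRESETS["large"]),
    ]:
        config = SyntheticConfig(
            model=model, delta=delta, n_participants=114, layout="tasit",
            dont_know_count=61, seed=SEED,
        )
        ds = sample_dataset(config)
        ds.write(OUT / f"{name}_responses.csv", OUT / f"{name}_ep.csv")
        n_dk = int((ds.responses["response"] == "dont_know").sum())
        print(
            f"{name}: {len(ds.responses)} responses from "
            f"{config.n_participants} participants, {n_dk} don't-know "
            f"({100 * n_dk / len(ds.responses):.2f}%)"
        )


if __name__ == "__main__":
    main()
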
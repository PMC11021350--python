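"""Score both simulated datasets: screen don't-know responses, compute
per-participant endorsement proportions, and split participants on the
emotion-perception median.

Writes results/endorsement_{one,two}_latent.csv and a screening summary,
plus the condition mean/SE table that describes the experimental design
(5 exchange types x target/lure x high/low emotion perception, per probe
question).
"""

import json
from pathlib import Path

from statetrace.pipeline import (
    endorsement_proportions,
    load_ep_scores,
    load_responses,
    mean_se_table,
    median_split,
    screen_dont_know,
)

BASE = Path(__file__).resolve().parents[1] / "results"


def main():
    summary = {}
    for name in ("one_latent", "two_latent"):
        records = load_responses(BASE / "data" / f"{name}_responses.csv")
        kept, report = screen_dont_know(records)
        table = endorsement_proportions(kept)
        grouping = median_split(load_ep_scores(BASE / "data" / f"{name}_ep.csv"))

        flat = table.proportions.copy()
        flat.columns = ["_".join(c) for c in flat.columns]
        flat.to_csv(BASE / f"endorsement_{name}.csv", index_label="participant_id")
        mean_se_table(table, grouping).to_csv(
            BASE / f"condition_means_{name}.csv", index=False
        )
        summary[name] = {
            "n_participants": len(table.participants),
            "median_ep": grouping.median_value,
            **{k: report[k] for k in ("n_dont_know", "pct", "n_rows_total")},
        }
        print(
            f"{name}: {len(table.participants)} participants scored; "
            f"{report['n_dont_know']} don't-know removed "
            f"({report['pct']:.2f}% of {report['n_rows_total']} rows); "
            f"EP median split at {grouping.median_value:.1f}"
        )
    (BASE / "screening.json").write_text(json.dumps(summary, indent=2, sort_keys=True))


if __name__ == "__main__":
    main()
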
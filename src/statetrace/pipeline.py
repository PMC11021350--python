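"""From item-level yes/no/don't-know responses to state-trace analyses.

The data-reduction path mirrors the TASIT-R endorsement-rate design:

1.  parse item-level responses (participant x scene x probe question);
2.  drop "don't know" responses as missing;
3.  per participant, compute the proportion of "yes" decisions in every
    (social exchange type x probe question x target/lure) cell;
4.  median-split participants on emotion-perception score into high/low;
5.  build a 5 x 2 x 2 = 20-condition state-trace dataset for a pair of
    probe questions (think/do/feel) and run the CMR bootstrap test;
6.  repeat for the three probe-question pairs with a Bonferroni factor of 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cmr import CMRTestResult, StateTraceData, adjust_pvalues, cmr_test

EXCHANGE_TYPES = (
    "sincere",
    "simple_sarcasm",
    "paradoxical_sarcasm",
    "sarcasm",
    "lying",
)
PART_TWO_EXCHANGES = ("sincere", "simple_sarcasm", "paradoxical_sarcasm")
PART_THREE_EXCHANGES = ("sarcasm", "lying")
QUESTION_TYPES = ("think", "do", "feel", "say")
ANALYZED_QUESTIONS = ("think", "do", "feel")
ITEM_TYPES = ("target", "lure")
GROUPS = ("high", "low")
RESPONSES = ("yes", "no", "dont_know")
DV_PAIRS = (("think", "feel"), ("do", "feel"), ("think", "do"))

RESPONSE_COLUMNS = (
    "participant_id",
    "part",
    "scene_id",
    "exchange_type",
    "question_type",
    "item_type",
    "response",
)

_PART_ALIASES = {"two": "two", "2": "two", "three": "three", "3": "three"}
_RESPONSE_ALIASES = {
    "yes": "yes",
    "no": "no",
    "dont_know": "dont_know",
    "don't_know": "dont_know",
    "dontknow": "dont_know",
    "dk": "dont_know",
}


@dataclass(frozen=True)
class ItemResponse:
    """One participant's answer to one probe question of one scene."""

    participant_id: str
    part: str
    scene_id: str
    exchange_type: str
    question_type: str
    item_type: str
    response: str


@dataclass
class EndorsementTable:
    """Per-participant proportion of "yes" decisions per analysis cell.

    ``proportions`` and ``n_items`` are participant-indexed DataFrames whose
    columns are the (exchange_type, question_type, item_type) crossing for
    the analysed questions (think/do/feel); a cell is NaN when no scored
    item contributed.
    """

    proportions: pd.DataFrame
    n_items: pd.DataFrame

    @property
    def participants(self) -> list:
        return list(self.proportions.index)


@dataclass
class EPGrouping:
    """High/low emotion-perception groups from a median split (0-28 scale)."""

    assignments: dict
    median_value: float
    ep_scores: dict = field(default_factory=dict)

    def group_of(self, participant_id) -> str:
        return self.assignments[participant_id]


def load_responses(path) -> list[ItemResponse]:
    """Read the item-level dialect (comma or tab delimited, UTF-8).

    Header: ``participant_id,part,scene_id,exchange_type,question_type,
    item_type,response``.  Tokens are normalised case-insensitively; every
    unknown token and every part/exchange mismatch is reported with its row
    number.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    if list(df.columns) != list(RESPONSE_COLUMNS):
        raise ValueError(
            f"expected header {','.join(RESPONSE_COLUMNS)}, got {','.join(df.columns)}"
        )
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        part = _PART_ALIASES.get(str(row.part).strip().lower())
        exchange = str(row.exchange_type).strip().lower()
        question = str(row.question_type).strip().lower()
        item = str(row.item_type).strip().lower()
        response = _RESPONSE_ALIASES.get(
            str(row.response).strip().lower().replace(" ", "_")
        )
        if part is None:
            raise ValueError(f"row {i}: unknown part {row.part!r}")
        if exchange not in EXCHANGE_TYPES:
            raise ValueError(f"row {i}: unknown exchange_type {row.exchange_type!r}")
        if question not in QUESTION_TYPES:
            raise ValueError(f"row {i}: unknown question_type {row.question_type!r}")
        if item not in ITEM_TYPES:
            raise ValueError(f"row {i}: unknown item_type {row.item_type!r}")
        if response is None:
            raise ValueError(f"row {i}: unknown response {row.response!r}")
        if part == "two" and exchange not in PART_TWO_EXCHANGES:
            raise ValueError(
                f"row {i}: exchange {exchange!r} cannot occur in part two"
            )
        if part == "three" and exchange not in PART_THREE_EXCHANGES:
            raise ValueError(
                f"row {i}: exchange {exchange!r} cannot occur in part three"
            )
        records.append(
            ItemResponse(
                participant_id=str(row.participant_id).strip(),
                part=part,
                scene_id=str(row.scene_id).strip(),
                exchange_type=exchange,
                question_type=question,
                item_type=item,
                response=response,
            )
        )
    return records


def responses_from_frame(df: pd.DataFrame) -> list[ItemResponse]:
    """Build records from an already-normalised in-memory table (e.g. the
    synthetic generator's output) without re-parsing a file."""
    if list(df.columns) != list(RESPONSE_COLUMNS):
        raise ValueError(f"expected columns {RESPONSE_COLUMNS}")
    return [ItemResponse(*row) for row in df.itertuples(index=False)]


def screen_dont_know(responses) -> tuple[list[ItemResponse], dict]:
    """Remove "don't know" responses, treating them as missing data.

    The report carries the removed count and its percentage of all input
    rows, plus the percentage of scored (non-"say") rows since both bases
    are meaningful for this instrument.
    """
    total = len(responses)
    kept = [r for r in responses if r.response != "dont_know"]
    n_dk = total - len(kept)
    scored = sum(1 for r in responses if r.question_type != "say")
    report = {
        "n_dont_know": n_dk,
        "pct": 100.0 * n_dk / total if total else 0.0,
        "n_rows_total": total,
        "n_rows_scored": scored,
        "pct_of_scored": 100.0 * n_dk / scored if scored else 0.0,
    }
    return kept, report


def endorsement_proportions(responses) -> EndorsementTable:
    """Per-participant endorsement rates for every analysis cell.

    The proportion is yes / (yes + no) within each (exchange, question,
    item type) cell; "say" control questions are excluded; cells with no
    contributing items are missing.
    """
    cols = pd.MultiIndex.from_product(
        [EXCHANGE_TYPES, ANALYZED_QUESTIONS, ITEM_TYPES],
        names=["exchange_type", "question_type", "item_type"],
    )
    rows = [
        (r.participant_id, r.exchange_type, r.question_type, r.item_type, r.response == "yes")
        for r in responses
        if r.question_type != "say" and r.response != "dont_know"
    ]
    participants = sorted({r[0] for r in rows})
    if not rows:
        empty = pd.DataFrame(index=participants, columns=cols, dtype=float)
        return EndorsementTable(proportions=empty, n_items=empty.fillna(0).astype(int))
    df = pd.DataFrame(
        rows,
        columns=["participant_id", "exchange_type", "question_type", "item_type", "is_yes"],
    )
    stats = df.groupby(
        ["participant_id", "exchange_type", "question_type", "item_type"],
        sort=True,
    )["is_yes"].agg(yes="sum", total="size")
    yes = (
        stats["yes"]
        .unstack(["exchange_type", "question_type", "item_type"])
        .reindex(index=participants, columns=cols)
        .fillna(0.0)
    )
    tot = (
        stats["total"]
        .unstack(["exchange_type", "question_type", "item_type"])
        .reindex(index=participants, columns=cols)
        .fillna(0.0)
    )
    props = yes.where(tot > 0) / tot.where(tot > 0)
    return EndorsementTable(proportions=props, n_items=tot.astype(int))


def median_split(ep_scores: dict) -> EPGrouping:
    """Median split of emotion-perception scores into high/low groups.

    Scores strictly above the median go to ``high``; ties at the median go
    to ``low`` (a deterministic convention; configurable downstream effects
    are limited to group sizes).
    """
    if not ep_scores:
        raise ValueError("ep_scores is empty")
    vals = np.asarray(list(ep_scores.values()), dtype=float)
    if np.any(vals < 0) or np.any(vals > 28):
        raise ValueError("emotion-perception scores must lie in 0-28")
    med = float(np.median(vals))
    assignments = {
        pid: ("high" if score > med else "low") for pid, score in ep_scores.items()
    }
    return EPGrouping(assignments=assignments, median_value=med, ep_scores=dict(ep_scores))


def load_ep_scores(path) -> dict:
    """Read the ``participant_id,ep_score`` dialect."""
    df = pd.read_csv(path, sep=None, engine="python")
    if list(df.columns) != ["participant_id", "ep_score"]:
        raise ValueError("expected header participant_id,ep_score")
    return {str(r.participant_id): int(r.ep_score) for r in df.itertuples(index=False)}


def condition_grid() -> list[tuple[str, str, str]]:
    """The canonical 20-condition order: exchange x item type x EP group."""
    return [
        (e, t, g) for e in EXCHANGE_TYPES for t in ITEM_TYPES for g in GROUPS
    ]


def build_state_trace(
    table: EndorsementTable,
    grouping: EPGrouping,
    dv_pair: tuple[str, str],
    max_missing_frac: float = 0.2,
    weighting: str = "precision",
) -> StateTraceData:
    """Assemble the 20-condition state-trace dataset for a pair of probe
    questions.

    Condition means are across-participant means of per-participant
    endorsement proportions; weights are precision weights n_c / s_c**2
    from the across-participant variance (``weighting='none'`` gives unit
    weights).  Participants missing more than ``max_missing_frac`` of their
    relevant cells are excluded entirely; otherwise they are simply absent
    from the cells they cannot contribute to.  Backing matrices and the
    group stratification are retained for the participant bootstrap.
    """
    dv_x, dv_y = dv_pair
    if dv_x == dv_y:
        raise ValueError("the two dependent variables must be distinct")
    for dv in dv_pair:
        if dv not in ANALYZED_QUESTIONS:
            raise ValueError(f"dependent variables must be in {ANALYZED_QUESTIONS}")

    participants = [p for p in table.participants if p in grouping.assignments]
    if not participants:
        raise ValueError("no participants are both scored and grouped")
    conditions = condition_grid()
    n_cond = len(conditions)

    props = table.proportions
    # participant-level exclusion on the cells relevant to this dv pair
    relevant = [
        (e, q, t) for e in EXCHANGE_TYPES for q in dv_pair for t in ITEM_TYPES
    ]
    kept = []
    for p in participants:
        vals = props.loc[p, relevant].to_numpy(dtype=float)
        if np.isnan(vals).mean() <= max_missing_frac:
            kept.append(p)
    if len(kept) < 2:
        raise ValueError("fewer than 2 participants survive screening")

    strata = np.array([grouping.group_of(p) for p in kept])
    x_backing = np.full((len(kept), n_cond), np.nan)
    y_backing = np.full((len(kept), n_cond), np.nan)
    for j, (e, t, g) in enumerate(conditions):
        in_group = strata == g
        x_backing[in_group, j] = props.loc[
            np.asarray(kept)[in_group], (e, dv_x, t)
        ].to_numpy(dtype=float)
        y_backing[in_group, j] = props.loc[
            np.asarray(kept)[in_group], (e, dv_y, t)
        ].to_numpy(dtype=float)

    def _summarise(backing):
        n_c = np.sum(~np.isnan(backing), axis=0)
        if np.any(n_c < 2):
            bad = [conditions[j] for j in np.where(n_c < 2)[0]]
            raise ValueError(f"conditions with < 2 contributing participants: {bad}")
        means = np.nanmean(backing, axis=0)
        if weighting == "precision":
            var = np.nanvar(backing, axis=0, ddof=1)
            var = np.maximum(var, 1e-4)  # floor: degenerate all-equal cells
            weights = n_c / var
        elif weighting == "none":
            weights = np.ones(n_cond)
        else:
            raise ValueError(f"unknown weighting {weighting!r}")
        return means, weights

    x_means, x_weights = _summarise(x_backing)
    y_means, y_weights = _summarise(y_backing)
    return StateTraceData(
        condition_labels=conditions,
        x_means=x_means,
        y_means=y_means,
        x_weights=x_weights,
        y_weights=y_weights,
        dv_names=(dv_x, dv_y),
        x_backing=x_backing,
        y_backing=y_backing,
        strata=strata,
    )


def run_three_analyses(
    table: EndorsementTable,
    grouping: EPGrouping,
    n_boot: int = 10_000,
    seed: int = 0,
    method: str = "auto",
    weighting: str = "precision",
) -> dict[tuple[str, str], CMRTestResult]:
    """The three pairwise state-trace analyses with Bonferroni m = 3.

    Pairs: think-feel (first-order cognitive vs affective), do-feel
    (second-order cognitive vs affective), think-do (first- vs second-order
    cognitive).  Each analysis gets its own deterministic child seed.
    """
    results = {}
    children = np.random.SeedSequence(seed).spawn(len(DV_PAIRS))
    for child, pair in zip(children, DV_PAIRS):
        data = build_state_trace(table, grouping, pair, weighting=weighting)
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        results[pair] = cmr_test(
            data, n_boot=n_boot, seed=sub_seed, mode="participant_resample",
            method=method, m=len(DV_PAIRS),
        )
    return results


def mean_se_table(table: EndorsementTable, grouping: EPGrouping) -> pd.DataFrame:
    """Condition mean and standard error of endorsement per question type —
    the descriptive companion to the state-trace plots."""
    rows = []
    props = table.proportions
    for q in ANALYZED_QUESTIONS:
        for e, t, g in condition_grid():
            members = [
                p for p in table.participants
                if grouping.assignments.get(p) == g
            ]
            vals = props.loc[members, (e, q, t)].to_numpy(dtype=float)
            vals = vals[~np.isnan(vals)]
            rows.append(
                {
                    "question_type": q,
                    "exchange_type": e,
                    "item_type": t,
                    "ep_group": g,
                    "n": len(vals),
                    "mean": float(np.mean(vals)) if len(vals) else np.nan,
                    "se": float(np.std(vals, ddof=1) / np.sqrt(len(vals)))
                    if len(vals) > 1
                    else np.nan,
                }
            )
    return pd.DataFrame(rows)
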
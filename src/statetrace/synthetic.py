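"""Synthetic TASIT-R-style datasets with known latent dimensionality.

The generator exists so that every pipeline stage is testable without the
(request-only) raw data.  Its population model is the minimal one compatible
with state-trace logic:

* ``one_latent`` (the null): every condition c has a single latent value
  theta_c; each dependent variable dv maps it through its own monotone
  logistic link p_dv(c) = logistic(a_dv * theta_c + b_dv).  Both population
  mean vectors are then monotone in theta, so a common condition order
  exists and the population CMR misfit is zero.

* ``two_latent`` (the alternative): a second latent dimension eta_c
  (alternating +1/-1 along the theta order) perturbs the latent value on
  the dv-specific scale, latent_dv(c) = theta_c + delta * load_dv * eta_c,
  with loadings (think 0, do +1, feel -1).  The do and feel orders pull in
  opposite directions, and once delta exceeds the adjacent theta spacing no
  common order exists for any of the three dv pairs.

Binary item responses are drawn per participant with a random intercept on
the latent scale; emotion-perception scores are drawn per group so the
pipeline's median split approximately recovers the generating groups.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .cmr import SummaryStatInput
from .pipeline import (
    ANALYZED_QUESTIONS,
    EXCHANGE_TYPES,
    GROUPS,
    ITEM_TYPES,
    PART_THREE_EXCHANGES,
    PART_TWO_EXCHANGES,
    RESPONSE_COLUMNS,
    condition_grid,
)

# condition-effect decomposition of the default latent grid (logit scale):
# realistic endorsement structure — targets high, lures low, sincere easiest,
# lying hardest, a modest high/low emotion-perception separation.
EXCHANGE_EFFECT = {
    "sincere": 0.5,
    "simple_sarcasm": 0.1,
    "paradoxical_sarcasm": -0.1,
    "sarcasm": 0.0,
    "lying": -0.3,
}
ITEM_EFFECT = {"target": 1.3, "lure": -1.1}
GROUP_EFFECT = {"high": 0.25, "low": -0.25}

# per-DV logistic link (slope, intercept); distinct monotone links
DEFAULT_LINKS = {"think": (1.0, 0.15), "do": (0.9, 0.0), "feel": (1.1, 0.1)}

# departure-magnitude presets on the latent scale, frozen after a one-off
# tuning run against the population CMR misfit of the default theta grid
DELTA_PRESETS = {"small": 0.4, "medium": 0.8, "large": 1.4}

# "say" control questions are plumbing only: near-ceiling/floor endorsement
SAY_PROB = {"target": 0.92, "lure": 0.08}

# emotion-perception score distributions per generating group (0-28 scale)
EP_SCORE_PARAMS = {"high": (24.92, 0.96), "low": (20.90, 2.50)}


def default_theta() -> np.ndarray:
    """The 20 latent condition values implied by the effect decomposition,
    in canonical condition order (exchange x item type x group)."""
    return np.array(
        [
            EXCHANGE_EFFECT[e] + ITEM_EFFECT[t] + GROUP_EFFECT[g]
            for e, t, g in condition_grid()
        ]
    )


def logistic(z):
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=np.float64)))


@dataclass
class SyntheticConfig:
    model: str = "one_latent"
    n_participants: int = 114
    items_per_cell: int = 4
    theta: np.ndarray = field(default_factory=default_theta)
    delta: float = 0.0
    link_params: dict = field(default_factory=lambda: dict(DEFAULT_LINKS))
    seed: int = 0
    participant_sd: float = 0.3
    dont_know_rate: float = 0.004
    dont_know_count: int | None = None
    include_say: bool = True
    layout: str = "grid"

    def __post_init__(self):
        if self.model not in ("one_latent", "two_latent"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.n_participants < 1:
            raise ValueError("n_participants must be positive")
        if self.items_per_cell < 1:
            raise ValueError("items_per_cell must be at least 1")
        if self.delta < 0:
            raise ValueError("delta must be nonnegative")
        if self.layout not in ("grid", "tasit"):
            raise ValueError(f"unknown layout {self.layout!r}")
        self.theta = np.asarray(self.theta, dtype=np.float64)
        if self.theta.shape != (len(condition_grid()),):
            raise ValueError("theta must hold one latent value per condition")
        for dv in ANALYZED_QUESTIONS:
            if dv not in self.link_params:
                raise ValueError(f"link_params must cover {ANALYZED_QUESTIONS}")

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "delta" in raw and isinstance(raw["delta"], str):
            raw["delta"] = DELTA_PRESETS[raw["delta"]]
        if "link_params" in raw:
            raw["link_params"] = {
                dv: tuple(v) for dv, v in raw["link_params"].items()
            }
        if "theta" in raw:
            raw["theta"] = np.asarray(raw["theta"], dtype=np.float64)
        return cls(**raw)


def delta_preset(name: str) -> float:
    return DELTA_PRESETS[name]


# loadings of the second latent dimension per dependent variable
DV_LOADINGS = {"think": 0.0, "do": 1.0, "feel": -1.0}


def _eta(theta: np.ndarray) -> np.ndarray:
    """Alternating +1/-1 along the theta-sorted condition order — the
    crossing pattern of the second latent dimension."""
    eta = np.empty(theta.shape[0])
    order = np.argsort(theta, kind="stable")
    signs = np.where(np.arange(theta.shape[0]) % 2 == 0, 1.0, -1.0)
    eta[order] = signs
    return eta


def cell_probabilities(config: SyntheticConfig) -> pd.DataFrame:
    """Population endorsement probability per condition and probe question.

    Index: canonical (exchange_type, item_type, group) grid; one column per
    analysed question.
    """
    theta = config.theta
    eta = _eta(theta) if config.model == "two_latent" else np.zeros_like(theta)
    cols = {}
    for dv in ANALYZED_QUESTIONS:
        a, b = config.link_params[dv]
        latent = theta + config.delta * DV_LOADINGS[dv] * eta
        cols[dv] = logistic(a * latent + b)
    idx = pd.MultiIndex.from_tuples(
        condition_grid(), names=["exchange_type", "item_type", "group"]
    )
    return pd.DataFrame(cols, index=idx)


@dataclass
class SyntheticDataset:
    """An item-level response table plus the side information that real data
    would carry separately (emotion-perception scores) or not at all
    (generating groups and population probabilities)."""

    responses: pd.DataFrame
    ep_scores: dict
    true_groups: dict
    probabilities: pd.DataFrame
    config: SyntheticConfig

    def responses_csv(self) -> str:
        buf = io.StringIO()
        self.responses.to_csv(buf, index=False)
        return buf.getvalue()

    def ep_csv(self) -> str:
        buf = io.StringIO()
        pd.DataFrame(
            {"participant_id": list(self.ep_scores), "ep_score": list(self.ep_scores.values())}
        ).to_csv(buf, index=False)
        return buf.getvalue()

    def write(self, responses_path, ep_path=None):
        with open(responses_path, "w") as fh:
            fh.write(self.responses_csv())
        if ep_path is not None:
            with open(ep_path, "w") as fh:
                fh.write(self.ep_csv())


def _scene_plan(config: SyntheticConfig):
    """Rows of (part, scene_id, exchange, question, item_type) defining one
    participant's response sheet.

    ``grid`` layout: items_per_cell scenes per (exchange x item type), every
    question of a scene sharing the scene's item type.  ``tasit`` layout:
    the instrument's scene taxonomy — 15 part-two scenes (5 per exchange)
    and 16 part-three scenes (8 sarcasm, 8 lying), four questions per scene
    with item type alternating over scene x question so every analysis cell
    is populated (31 scenes x 4 questions = 124 rows, 93 scored).
    """
    questions = list(ANALYZED_QUESTIONS) + (["say"] if config.include_say else [])
    plan = []
    if config.layout == "grid":
        for e in EXCHANGE_TYPES:
            part = "two" if e in PART_TWO_EXCHANGES else "three"
            for t in ITEM_TYPES:
                for k in range(config.items_per_cell):
                    sid = f"{e}_{t}{k + 1}"
                    for q in questions:
                        plan.append((part, sid, e, q, t))
    else:
        counts = {
            "sincere": 5, "simple_sarcasm": 5, "paradoxical_sarcasm": 5,
            "sarcasm": 8, "lying": 8,
        }
        scene_no = 0
        for e in EXCHANGE_TYPES:
            part = "two" if e in PART_TWO_EXCHANGES else "three"
            for k in range(counts[e]):
                scene_no += 1
                sid = f"S{scene_no:02d}"
                for qi, q in enumerate(questions):
                    t = ITEM_TYPES[(k + qi) % 2]
                    plan.append((part, sid, e, q, t))
    return plan


def sample_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Draw a full item-level dataset in the pipeline's input dialect.

    Each participant belongs to one emotion-perception group (alternating
    assignment), receives a random intercept on the latent scale, and
    answers every scheduled item with a Bernoulli draw at the cell
    probability.  Optionally a small fraction of scored responses is
    replaced by "don't know".  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    pids = [f"P{i + 1:03d}" for i in range(n)]
    groups = {pid: GROUPS[i % 2] for i, pid in enumerate(pids)}

    ep_scores = {}
    for pid in pids:
        mu, sd = EP_SCORE_PARAMS[groups[pid]]
        ep_scores[pid] = int(np.clip(round(rng.normal(mu, sd)), 0, 28))

    intercepts = rng.normal(0.0, config.participant_sd, size=n)
    probs_table = cell_probabilities(config)
    theta = config.theta
    eta = _eta(theta) if config.model == "two_latent" else np.zeros_like(theta)
    cond_index = {c: j for j, c in enumerate(condition_grid())}

    plan = _scene_plan(config)
    rows = []
    p_row = []
    for i, pid in enumerate(pids):
        g = groups[pid]
        u = intercepts[i]
        for part, sid, e, q, t in plan:
            if q == "say":
                p = SAY_PROB[t]
            else:
                a, b = config.link_params[q]
                j = cond_index[(e, t, g)]
                latent = theta[j] + config.delta * DV_LOADINGS[q] * eta[j] + u
                p = float(logistic(a * latent + b))
            rows.append((pid, part, sid, e, q, t))
            p_row.append(p)

    draws = rng.random(len(rows)) < np.asarray(p_row)
    responses = np.where(draws, "yes", "no").astype(object)

    scored_idx = np.array(
        [k for k, r in enumerate(rows) if r[4] != "say"], dtype=np.int64
    )
    if config.dont_know_count is not None:
        if config.dont_know_count > scored_idx.size:
            raise ValueError("dont_know_count exceeds the number of scored rows")
        chosen = rng.choice(scored_idx, size=config.dont_know_count, replace=False)
        responses[chosen] = "dont_know"
    elif config.dont_know_rate > 0:
        mask = rng.random(scored_idx.size) < config.dont_know_rate
        responses[scored_idx[mask]] = "dont_know"

    df = pd.DataFrame(rows, columns=list(RESPONSE_COLUMNS[:-1]))
    df["response"] = responses
    return SyntheticDataset(
        responses=df,
        ep_scores=ep_scores,
        true_groups=groups,
        probabilities=probs_table,
        config=config,
    )


def sample_summary_dataset(
    config: SyntheticConfig,
    n_groups: int = 5,
    n_per_group: int | None = None,
    sigma_within: float = 0.15,
    dv_pair: tuple[str, str] = ("think", "feel"),
) -> SummaryStatInput:
    """Per-group (M, SD, N) summaries from the latent model — the structure
    of a published-results reanalysis, with synthetic values.

    Group latent values are evenly spaced; under ``two_latent`` the second
    dependent variable's latent is perturbed by the alternating crossing
    pattern.  Individual observations add normal within-group noise of
    ``sigma_within`` on the response scale.
    """
    if n_groups < 2:
        raise ValueError("n_groups must be at least 2")
    if n_per_group is None:
        n_per_group = config.n_participants
    if n_per_group < 2:
        raise ValueError("n_per_group must be at least 2")
    rng = np.random.default_rng(config.seed)
    theta_g = np.linspace(-1.2, 1.2, n_groups)
    eta_g = np.where(np.arange(n_groups) % 2 == 0, 1.0, -1.0)
    loadings = (0.0, 1.0) if config.model == "two_latent" else (0.0, 0.0)

    labels = [f"group{g + 1}" for g in range(n_groups)]
    means = np.empty((n_groups, 2))
    sds = np.empty((n_groups, 2))
    ns = np.full((n_groups, 2), n_per_group, dtype=np.int64)
    for j, dv in enumerate(dv_pair):
        a, b = config.link_params[dv]
        center = logistic(a * (theta_g + config.delta * loadings[j] * eta_g) + b)
        for g in range(n_groups):
            sample = center[g] + rng.normal(0.0, sigma_within, size=n_per_group)
            means[g, j] = sample.mean()
            sds[g, j] = sample.std(ddof=1)
    return SummaryStatInput(
        condition_labels=labels, dv_names=dv_pair, means=means, sds=sds, ns=ns
    )
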
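"""Serialisation of analysis results: JSON-compatible key-value files plus a
human-readable text report.  Output is byte-deterministic for identical
inputs and seeds (sorted keys, repr-based float formatting)."""

from __future__ import annotations

import json

import numpy as np

from . import __version__
from .cmr import CMRTestResult


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    return obj


def result_to_dict(result: CMRTestResult, condition_labels=None) -> dict:
    """Everything needed to reproduce and interpret one CMR test."""
    d = {
        "dv_pair": list(result.dv_names),
        "observed_stat": result.observed_stat,
        "p_value": result.p_value,
        "p_adjusted": result.p_adjusted,
        "n_boot": result.n_boot,
        "seed": result.seed,
        "mode": result.mode,
        "order": result.model.order.tolist(),
        "x_fitted": result.model.x_fitted.tolist(),
        "y_fitted": result.model.y_fitted.tolist(),
        "exact": result.model.exact,
        "version": __version__,
    }
    if condition_labels is not None:
        d["condition_labels"] = [_jsonable(c) for c in condition_labels]
    return d


def to_json(result: CMRTestResult, condition_labels=None) -> str:
    return json.dumps(
        _jsonable(result_to_dict(result, condition_labels)),
        sort_keys=True,
        indent=2,
    ) + "\n"


def to_text(result: CMRTestResult, condition_labels=None) -> str:
    """Structured plain-text report for one analysis."""
    lines = [
        f"Conjoint monotonic regression test ({result.dv_names[0]} vs {result.dv_names[1]})",
        f"  statetrace version : {__version__}",
        f"  mode               : {result.mode}",
        f"  n_boot             : {result.n_boot}",
        f"  seed               : {result.seed}",
        f"  observed misfit    : {result.observed_stat:.6g}",
        f"  p-value            : {result.p_value:.6g}",
        f"  p (Bonferroni)     : {result.p_adjusted:.6g}",
        f"  exact optimum      : {result.model.exact}",
        "  common order       : "
        + " < ".join(
            str(condition_labels[i]) if condition_labels is not None else str(i)
            for i in result.model.order
        ),
    ]
    return "\n".join(lines) + "\n"


def write_report(result: CMRTestResult, json_path, text_path=None, condition_labels=None):
    with open(json_path, "w") as fh:
        fh.write(to_json(result, condition_labels))
    if text_path is not None:
        with open(text_path, "w") as fh:
            fh.write(to_text(result, condition_labels))
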
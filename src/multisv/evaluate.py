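"""Evaluation against truth: recall/precision, cross-platform relative
sensitivity, and purity/depth sensitivity curves."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import SVRecord
from .merge import MergedSV
from .orthomatch import MatchRule, evaluation_rules, match_calls
from .simulate import TruthSet
from .vcfio import TRUTH_INFO_KEY


def _as_records(calls) -> list[SVRecord]:
    return [c.representative if isinstance(c, MergedSV) else c for c in calls]


@dataclass
class EvalResult:
    recall: float | None
    precision: float | None
    n_truth: int
    n_calls: int
    per_type: pd.DataFrame = field(default_factory=pd.DataFrame)
    note: str = ""


def recall_precision(
    calls,
    truth: TruthSet | list[SVRecord],
    rules: list[MatchRule] | None = None,
    use_truth_ids: bool = True,
) -> EvalResult:
    """Recall and precision of a call list against the somatic truth.

    When every call carries a truth label in INFO the metrics are computed
    from labels exactly; otherwise calls are matched to truth by distance and
    size similarity.  Undefined ratios (empty truth or empty calls) are
    reported as None with a note rather than as zero.
    """
    truth_records = truth.somatic if isinstance(truth, TruthSet) else list(truth)
    records = _as_records(calls)
    rules = rules if rules is not None else evaluation_rules()

    if not truth_records:
        return EvalResult(None, None, 0, len(records),
                          note="recall undefined: empty truth set")

    truth_ids = {t.id for t in truth_records}
    labelled = bool(records) and any(TRUTH_INFO_KEY in r.info for r in records)
    if labelled and use_truth_ids:
        # calls without a truth label are false positives by definition
        hit_ids = {r.info.get(TRUTH_INFO_KEY) for r in records} & truth_ids
        matched_calls = sum(
            1 for r in records if r.info.get(TRUTH_INFO_KEY) in truth_ids
        )
        rows = _per_type_rows(
            truth_records, records,
            lambda t: t.id in hit_ids,
            lambda r: r.info.get(TRUTH_INFO_KEY) in truth_ids,
        )
    else:
        result = match_calls(truth_records, records, rules)
        hit_ids = {q.id for q, _ in result.pairs}
        matched_validation = {id(v) for _, v in result.pairs}
        matched_calls = sum(1 for r in records if id(r) in matched_validation)
        rows = _per_type_rows(
            truth_records, records,
            lambda t: t.id in hit_ids,
            lambda r: id(r) in matched_validation,
        )
    recall = len(hit_ids & truth_ids) / len(truth_records)
    precision = matched_calls / len(records) if records else None
    note = "" if records else "precision undefined: no calls"
    return EvalResult(recall, precision, len(truth_records), len(records),
                      per_type=pd.DataFrame(rows), note=note)


def _per_type_rows(truth_records, records, truth_hit, call_hit):
    rows = []
    for svtype in sorted({t.svtype for t in truth_records}):
        t_sub = [t for t in truth_records if t.svtype == svtype]
        c_sub = [r for r in records if r.svtype == svtype]
        n_hit = sum(1 for t in t_sub if truth_hit(t))
        rows.append(
            {
                "svtype": svtype,
                "n_truth": len(t_sub),
                "n_calls": len(c_sub),
                "recall": n_hit / len(t_sub),
                "precision": (
                    sum(1 for r in c_sub if call_hit(r)) / len(c_sub)
                    if c_sub
                    else np.nan
                ),
            }
        )
    return rows


@dataclass
class SensitivityMatrix:
    platforms: list[str]
    table: pd.DataFrame  # rows: reference platform; columns: other platform

    def cell(self, ref: str, other: str) -> float:
        return float(self.table.loc[ref, other])


def relative_sensitivity(
    callsets_by_platform: dict,
    rules: list[MatchRule] | None = None,
    size_bins: list[tuple] | None = None,
):
    """Proportion of a reference platform's calls reproduced by each other
    platform.  Rows are reference platforms (diagonal 1 by definition);
    platforms with zero calls get a NaN row.  With ``size_bins`` a dict of
    matrices keyed by (low, high) size bin is returned instead.
    """
    if len(callsets_by_platform) < 2:
        raise ValueError("need at least two platforms")
    rules = rules if rules is not None else evaluation_rules()
    platforms = sorted(callsets_by_platform)

    if size_bins:
        out = {}
        for lo, hi in size_bins:
            sub = {
                p: [r for r in _as_records(calls)
                    if r.is_translocation_like or lo <= r.size < hi]
                for p, calls in callsets_by_platform.items()
            }
            out[(lo, hi)] = relative_sensitivity(sub, rules)
        return out

    mat = pd.DataFrame(np.ones((len(platforms), len(platforms))),
                       index=platforms, columns=platforms)
    for ref in platforms:
        ref_calls = _as_records(callsets_by_platform[ref])
        if not ref_calls:
            mat.loc[ref, :] = np.nan
            mat.loc[ref, ref] = 1.0
            continue
        for other in platforms:
            if other == ref:
                continue
            other_calls = _as_records(callsets_by_platform[other])
            result = match_calls(ref_calls, other_calls, rules)
            mat.loc[ref, other] = result.n_matched / len(ref_calls)
    return SensitivityMatrix(platforms=platforms, table=mat)


def purity_depth_curves(
    series: dict,
    truth: TruthSet,
    rules: list[MatchRule] | None = None,
) -> pd.DataFrame:
    """Recall by (purity, depth, svtype) for a titration series.

    Returns one row per grid cell and SV type plus an 'ALL' aggregate row.
    """
    rows = []
    for (purity, depth), callset in sorted(series.items()):
        result = recall_precision(callset.records, truth, rules)
        rows.append(
            {"purity": purity, "depth": depth, "svtype": "ALL",
             "recall": result.recall, "n_truth": result.n_truth}
        )
        for _, r in result.per_type.iterrows():
            rows.append(
                {"purity": purity, "depth": depth, "svtype": r["svtype"],
                 "recall": r["recall"], "n_truth": r["n_truth"]}
            )
    return pd.DataFrame(rows)


def plot_recall_curves(curves: pd.DataFrame, path) -> str:
    """Recall vs depth, one line per purity (aggregate SV types)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = curves[curves["svtype"] == "ALL"]
    fig, ax = plt.subplots(figsize=(6, 4))
    for purity, grp in sub.groupby("purity"):
        grp = grp.sort_values("depth")
        ax.plot(grp["depth"], grp["recall"], marker="o",
                label=f"purity {purity:.0%}")
    ax.set_xlabel("sequencing depth (X)")
    ax.set_ylabel("recall")
    ax.set_ylim(0, 1.05)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return str(path)
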
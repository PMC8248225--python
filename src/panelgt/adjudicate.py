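"""Adjudication protocol over a LabelSet: disagreement detection, the
round/stopping rule, majority fallback, and round-wise descriptive statistics.

The protocol: each arm's panel discusses only the contested (image, finding)
keys, for up to ``max_rounds`` rounds (one arm may extend by a few more to
probe the value of extra discussion), stopping early per key once all three
readers agree on the label — and, when ``require_details`` is on, on the
finding details too.  Whatever is still contested after the cap is finalised
by majority vote.  Detail-only contention delays a key's resolution round but
never changes its binary label.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .aggregate import apply_hedge_policy, majority_vote
from .labels import ABSENT, HEDGE, PRESENT, LabelSet

__all__ = [
    "AdjudicationTrace",
    "detect_disagreements",
    "run_protocol",
    "resolution_stats",
]

DIRECTIONS = ("upgrade", "downgrade", "unchanged", "to_hedge")


@dataclass
class AdjudicationTrace:
    """Per-key adjudication history and outcome.

    ``records`` has one row per (image_id, arm, finding) with columns:
    initially_contested (bool), initial_majority, final_label, status
    ('consensus' or 'unresolved'), resolution_round (nullable Int64) and
    direction (for initially contested keys; '' otherwise).
    """

    records: pd.DataFrame
    max_rounds_by_arm: dict[int, int]

    def finalized_labels(self) -> pd.DataFrame:
        """Final per-key panel labels (consensus or majority fallback)."""
        out = self.records[["image_id", "arm", "finding", "final_label"]].copy()
        return out.rename(columns={"final_label": "label"})


def _panel_triples(labelset: LabelSet, round: int) -> pd.DataFrame:
    """Effective label (and detail) triples per (image, arm, finding)."""
    eff = labelset.effective_reads(round)
    g = eff.sort_values("reader_id", kind="stable").groupby(
        ["image_id", "arm", "finding"], sort=True
    )
    out = g.agg(labels=("label", tuple), details=("detail", tuple)).reset_index()
    return out


def detect_disagreements(
    labelset: LabelSet, round: int = 0, require_details: bool = False
) -> set[tuple[str, int, str]]:
    """Keys whose effective triple at ``round`` is not unanimous.

    With ``require_details`` a unanimous label triple still counts as
    contested when the Present-readers' detail values differ.
    """
    trip = _panel_triples(labelset, round)
    contested = set()
    for row in trip.itertuples(index=False):
        key = (row.image_id, int(row.arm), row.finding)
        if len(set(row.labels)) > 1:
            contested.add(key)
        elif require_details:
            dets = {d for lab, d in zip(row.labels, row.details) if lab == PRESENT}
            if len(dets) > 1:
                contested.add(key)
    return contested


def _modal_label(labels: tuple[str, ...]) -> str:
    counts = Counter(labels)
    top, n = counts.most_common(1)[0]
    if n == 1 and len(counts) == 3:
        return "none"  # three-way split; no majority exists
    return top


def _fallback(labels: tuple[str, ...]) -> str:
    return majority_vote(apply_hedge_policy(labels, "hedge_as_present"))


def run_protocol(
    labelset: LabelSet,
    max_rounds: int = 2,
    extension_arm: int | None = 1,
    extension_rounds: int = 3,
    require_details: bool = True,
) -> AdjudicationTrace:
    """Replay the adjudication protocol over the rounds present in a LabelSet.

    Rounds recorded beyond an arm's cap are ignored with a warning.  Each
    initially contested key resolves at the first round whose effective
    triple is unanimous (labels, and details when ``require_details``);
    anything still contested at the cap is marked unresolved and finalised
    by majority vote (hedges counting as Present for the vote).
    """
    if max_rounds < 1:
        raise ValueError("max_rounds must be >= 1")
    caps = {
        arm: max_rounds + (extension_rounds if arm == extension_arm else 0)
        for arm in labelset.arms()
    }
    for arm, cap in caps.items():
        present = labelset.max_round(arm)
        if present > cap:
            warnings.warn(
                f"arm {arm} contains rounds beyond the cap ({present} > {cap}); "
                "extra rounds ignored",
                stacklevel=2,
            )

    base = _panel_triples(labelset, 0).rename(
        columns={"labels": "labels0", "details": "details0"}
    )
    contested0 = detect_disagreements(labelset, 0, require_details=require_details)

    records = []
    by_round = {
        r: _panel_triples(labelset, r).set_index(["image_id", "arm", "finding"])
        for r in range(0, max(caps.values()) + 1)
    }
    for row in base.itertuples(index=False):
        key = (row.image_id, int(row.arm), row.finding)
        cap = caps[key[1]]
        initially = key in contested0
        status, res_round, final = "consensus", 0, row.labels0[0]
        if initially:
            status, res_round, final = "unresolved", pd.NA, None
            for r in range(1, cap + 1):
                labs, dets = (
                    by_round[r].loc[key, "labels"],
                    by_round[r].loc[key, "details"],
                )
                if len(set(labs)) == 1:
                    if require_details:
                        pdets = {d for lab, d in zip(labs, dets) if lab == PRESENT}
                        if len(pdets) > 1:
                            continue
                    status, res_round, final = "consensus", r, labs[0]
                    break
            if final is None:
                final = _fallback(by_round[cap].loc[key, "labels"])
        init_maj = _modal_label(row.labels0)
        if not initially:
            direction = ""
        elif final == HEDGE:
            direction = "to_hedge"
        elif init_maj == ABSENT and final == PRESENT:
            direction = "upgrade"
        elif init_maj == PRESENT and final == ABSENT:
            direction = "downgrade"
        else:
            direction = "unchanged"
        records.append(
            {
                "image_id": key[0],
                "arm": key[1],
                "finding": key[2],
                "initially_contested": initially,
                "initial_majority": init_maj,
                "final_label": final,
                "status": status,
                "resolution_round": res_round,
                "direction": direction,
            }
        )
    rec = pd.DataFrame(records)
    rec["resolution_round"] = rec["resolution_round"].astype("Int64")
    return AdjudicationTrace(records=rec, max_rounds_by_arm=caps)


def resolution_stats(trace: AdjudicationTrace) -> dict[str, pd.DataFrame]:
    """Round-wise summaries of the trace.

    Returns ``resolution``: per (arm, finding, round) the cumulative fraction
    of initially contested keys resolved by that round; and ``flows``: per
    (arm, finding) the counts of upgrades, downgrades, unchanged and
    to_hedge outcomes among initially contested keys.
    """
    rec = trace.records
    if rec.empty:
        raise ValueError("empty adjudication trace")
    cont = rec[rec["initially_contested"]]

    res_rows = []
    for (arm, fnd), grp in cont.groupby(["arm", "finding"], sort=True):
        n = len(grp)
        for r in range(1, trace.max_rounds_by_arm[arm] + 1):
            resolved = (
                (grp["status"] == "consensus") & (grp["resolution_round"] <= r)
            ).sum()
            res_rows.append(
                {
                    "arm": arm,
                    "finding": fnd,
                    "round": r,
                    "n_contested": n,
                    "cumulative_resolved_fraction": resolved / n if n else float("nan"),
                }
            )
    flows = (
        cont.groupby(["arm", "finding", "direction"], sort=True)
        .size()
        .rename("count")
        .reset_index()
        .pivot_table(
            index=["arm", "finding"], columns="direction", values="count", fill_value=0
        )
        .reindex(columns=list(DIRECTIONS), fill_value=0)
        .reset_index()
    )
    flows.columns.name = None
    return {"resolution": pd.DataFrame(res_rows), "flows": flows}
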
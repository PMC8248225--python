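"""Panel label aggregation: hedge mapping, majority vote, maximum-sensitivity vote.

A panel of exactly three readers produces one label per image and finding.
Two voting rules are compared: *majority* (positive iff >= 2 of 3 readers call
it Present) and *maximum sensitivity* (positive iff any reader calls it
Present — motivated by detection tasks where a subtle finding may be flagged
by a single reader).  The *adjudicated* policy takes the reads in force after
the discussion rounds and falls back to majority vote on anything still
contested.

Hedge labels are mapped to a binary label before voting (default: Hedge is
Present, reflecting the clinical weight of an explicit uncertain call); voting
over the raw 3-level scale is deliberately undefined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .labels import ABSENT, HEDGE, PRESENT, LabelSet

__all__ = [
    "HEDGE_POLICIES",
    "POLICIES",
    "PanelLabel",
    "apply_hedge_policy",
    "majority_vote",
    "max_sensitivity_vote",
    "aggregate_panel",
]

HEDGE_POLICIES = ("hedge_as_present", "hedge_as_absent", "keep")
POLICIES = ("majority", "max_sensitivity", "adjudicated")


@dataclass(frozen=True)
class PanelLabel:
    image_id: str
    arm: int
    finding: str
    policy: str
    label: str
    round_used: int


def apply_hedge_policy(
    labels: Sequence[str], policy: str = "hedge_as_present"
) -> list[str]:
    """Map Hedge labels to a binary label (or keep them verbatim)."""
    if policy not in HEDGE_POLICIES:
        raise ValueError(f"unknown hedge policy {policy!r}; expected one of {HEDGE_POLICIES}")
    if policy == "keep":
        return list(labels)
    target = PRESENT if policy == "hedge_as_present" else ABSENT
    return [target if lab == HEDGE else lab for lab in labels]


def _check_triple(labels: Sequence[str]) -> None:
    if len(labels) != 3:
        raise ValueError(f"panel votes are defined for exactly 3 labels, got {len(labels)}")
    bad = [lab for lab in labels if lab not in (ABSENT, PRESENT)]
    if bad:
        raise ValueError(
            f"votes need binary labels (apply a hedge policy first); got {bad}"
        )


def majority_vote(labels: Sequence[str]) -> str:
    """Present iff at least two of the three readers called it Present."""
    _check_triple(labels)
    return PRESENT if sum(lab == PRESENT for lab in labels) >= 2 else ABSENT


def max_sensitivity_vote(labels: Sequence[str]) -> str:
    """Present iff any of the three readers called it Present."""
    _check_triple(labels)
    return PRESENT if any(lab == PRESENT for lab in labels) else ABSENT


def _vote_series(n_present: pd.Series, policy: str) -> pd.Series:
    thresh = 2 if policy == "majority" else 1
    return (n_present >= thresh).map({True: PRESENT, False: ABSENT})


def aggregate_panel(
    labelset: LabelSet,
    policy: str = "majority",
    round: int = 0,
    hedge_policy: str = "hedge_as_present",
) -> pd.DataFrame:
    """One aggregated label per (image, arm, finding) under ``policy``.

    For ``policy="adjudicated"`` the reads in force at each arm's final round
    are used (with carry-forward), and any residual disagreement is broken by
    majority vote — so ``round`` is ignored and the per-arm maximum round is
    reported as ``round_used``.

    Returns a frame with columns image_id, arm, finding, policy, label,
    round_used.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; expected one of {POLICIES}")
    if hedge_policy not in HEDGE_POLICIES:
        raise ValueError(f"unknown hedge policy {hedge_policy!r}")

    frames = []
    for arm in labelset.arms():
        if policy == "adjudicated":
            r = labelset.max_round(arm)
        else:
            r = round
            if r > labelset.max_round(arm) and r > 0:
                # carry-forward covers this, but a round beyond anything
                # recorded with no round-0 base is a state error
                if labelset.max_round(arm) < 0:
                    raise ValueError(f"round {r} absent in arm {arm}")
        eff = labelset.effective_reads(r, arm=arm)
        labs = eff["label"]
        if hedge_policy == "keep":
            grp = eff.groupby(["image_id", "finding"], sort=True)["label"]
            uniform = grp.nunique() == 1
            hedgy = grp.apply(lambda s: (s == HEDGE).any())
            if ((~uniform) & hedgy).any():
                raise ValueError(
                    "hedge_policy='keep' requires hedge-free or unanimous-Hedge "
                    "panels; apply a binary hedge policy to vote over mixed triples"
                )
            out = grp.first().reset_index()
            out["label"] = grp.apply(
                lambda s: majority_vote(list(s)) if (s != HEDGE).all() else HEDGE
            ).values
        else:
            mapped = labs.map(
                lambda x: apply_hedge_policy([x], hedge_policy)[0]
            )
            eff = eff.assign(_present=(mapped == PRESENT))
            grp = eff.groupby(["image_id", "finding"], sort=True)["_present"]
            n_present = grp.sum()
            n_reads = grp.count()
            if (n_reads != 3).any():
                bad = n_reads[n_reads != 3].index.tolist()[:5]
                raise ValueError(f"expected 3 effective reads per key, got e.g. {bad}")
            vote_policy = "majority" if policy in ("majority", "adjudicated") else policy
            out = _vote_series(n_present, vote_policy).rename("label").reset_index()
        out["arm"] = arm
        out["policy"] = policy
        out["round_used"] = r
        frames.append(out)

    res = pd.concat(frames, ignore_index=True)
    return res[["image_id", "arm", "finding", "policy", "label", "round_used"]]
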
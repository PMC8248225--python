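"""Study-level reports: the agreement table, inter-arm overlap counts,
confusable-finding contention resolution, and round-wise resolution curves.

All report sections are machine-readable frames written as TSV plus a JSON
metadata block carrying the config digest and every seed involved, so a
report can be regenerated exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .adjudicate import AdjudicationTrace, resolution_stats, run_protocol
from .aggregate import aggregate_panel
from .agreement import interpanel_alpha, random_reader_alpha
from .labels import PRESENT, LabelSet
from .simulate import CONFUSABLE

__all__ = ["StudyReport", "agreement_table", "overlap_counts", "contention_table", "build_report", "write_report"]

AGREEMENT_METHODS = ("individual", "initial_majority", "max_sensitivity", "adjudicated")


@dataclass
class StudyReport:
    agreement: pd.DataFrame
    overlap_before: pd.DataFrame
    overlap_after: pd.DataFrame
    contention: pd.DataFrame
    resolution: pd.DataFrame
    flows: pd.DataFrame
    metadata: dict = field(default_factory=dict)


def agreement_table(
    labelset: LabelSet,
    n_reps: int = 100,
    seed: int = 0,
    hedge_policy: str = "hedge_as_present",
) -> pd.DataFrame:
    """Per finding, agreement between arms under four labelling methods.

    individual        mean alpha of a random single reader per arm (n_reps draws);
    initial_majority  inter-panel alpha of round-0 majority votes;
    max_sensitivity   inter-panel alpha of round-0 any-positive votes;
    adjudicated       inter-panel alpha of post-adjudication consensus labels.
    """
    maj = aggregate_panel(labelset, "majority", round=0, hedge_policy=hedge_policy)
    mx = aggregate_panel(labelset, "max_sensitivity", round=0, hedge_policy=hedge_policy)
    adj = aggregate_panel(labelset, "adjudicated", hedge_policy=hedge_policy)
    rows = []
    for fnd in sorted(labelset.findings):
        ind = random_reader_alpha(
            labelset, fnd, n_reps=n_reps, seed=seed, hedge_policy=hedge_policy
        )
        rows.append(
            {
                "finding": fnd,
                "individual": ind.alpha,
                "initial_majority": interpanel_alpha(maj, fnd).alpha,
                "max_sensitivity": interpanel_alpha(mx, fnd).alpha,
                "adjudicated": interpanel_alpha(adj, fnd).alpha,
            }
        )
    return pd.DataFrame(rows)


def overlap_counts(
    panel_labels_arm1: pd.DataFrame, panel_labels_arm2: pd.DataFrame
) -> pd.DataFrame:
    """Per finding, the 2x2 partition of images by each arm's positivity:
    both / arm1_only / arm2_only / neither (the Venn-diagram counts)."""
    merged = panel_labels_arm1.merge(
        panel_labels_arm2, on=["image_id", "finding"], suffixes=("_1", "_2"), how="outer"
    )
    if merged[["label_1", "label_2"]].isna().any().any():
        raise ValueError("the two arms label different image sets")
    p1 = merged["label_1"] == PRESENT
    p2 = merged["label_2"] == PRESENT
    out = (
        pd.DataFrame(
            {
                "finding": merged["finding"],
                "both": p1 & p2,
                "arm1_only": p1 & ~p2,
                "arm2_only": ~p1 & p2,
                "neither": ~p1 & ~p2,
            }
        )
        .groupby("finding", sort=True)
        .sum()
        .reset_index()
    )
    return out


def contention_table(labelset: LabelSet, trace: AdjudicationTrace, arm: int = 1) -> pd.DataFrame:
    """Cross-table of confusable-finding contentions vs adjudicated outcome.

    Unit of count: images (in ``arm``) where, at round 0, at least one reader
    marked one finding of a confusable pair positive and a different reader
    marked the other positive.  The adjudicated outcome classifies each such
    image by which members of the pair ended Present (first / second / both /
    neither).
    """
    pairs = [
        (a, b)
        for i, a in enumerate(CONFUSABLE)
        for b in CONFUSABLE[i + 1 :]
        if a in labelset.findings and b in labelset.findings
    ]
    r0 = labelset.reads[(labelset.reads["round"] == 0) & (labelset.reads["arm"] == arm)]
    pos = r0[r0["label"] != "Absent"]
    readers_pos = pos.groupby(["image_id", "finding"])["reader_id"].agg(set)

    final = trace.finalized_labels()
    final = final[final["arm"] == arm].set_index(["image_id", "finding"])["label"]

    rows = []
    for a, b in pairs:
        counts = {"first_only": 0, "second_only": 0, "both": 0, "neither": 0}
        images = set()
        for img in labelset.images():
            ra = readers_pos.get((img, a), set())
            rb = readers_pos.get((img, b), set())
            if ra and rb and (ra - rb or rb - ra):
                images.add(img)
        for img in images:
            fa = final.get((img, a), "Absent") != "Absent"
            fb = final.get((img, b), "Absent") != "Absent"
            key = (
                "both" if fa and fb else "first_only" if fa else "second_only" if fb else "neither"
            )
            counts[key] += 1
        rows.append({"contention": f"{a} vs {b}", "n_images": len(images), **counts})
    return pd.DataFrame(rows)


def build_report(
    labelset: LabelSet,
    n_reps: int = 100,
    seed: int = 0,
    hedge_policy: str = "hedge_as_present",
    max_rounds: int = 2,
    extension_arm: int | None = 1,
    extension_rounds: int = 3,
    metadata: dict | None = None,
) -> StudyReport:
    """Assemble the full study report from an adjudicated LabelSet."""
    trace = run_protocol(
        labelset,
        max_rounds=max_rounds,
        extension_arm=extension_arm,
        extension_rounds=extension_rounds,
    )
    stats = resolution_stats(trace)

    def split(pl: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
        cols = ["image_id", "finding", "label"]
        return (
            pl[pl["arm"] == 1][cols],
            pl[pl["arm"] == 2][cols],
        )

    before = aggregate_panel(labelset, "majority", round=0, hedge_policy=hedge_policy)
    after = aggregate_panel(labelset, "adjudicated", hedge_policy=hedge_policy)

    meta = {
        "n_images": len(labelset.images()),
        "n_reps_individual": n_reps,
        "resampling_seed": seed,
        "hedge_policy": hedge_policy,
        "max_rounds": max_rounds,
        "extension_arm": extension_arm,
        "extension_rounds": extension_rounds,
        "contention_rule": (
            "images where >=1 round-0 reader marked one finding of a confusable "
            "pair positive and a different reader marked the other positive (arm 1)"
        ),
        **(metadata or {}),
    }
    return StudyReport(
        agreement=agreement_table(labelset, n_reps=n_reps, seed=seed, hedge_policy=hedge_policy),
        overlap_before=overlap_counts(*split(before)),
        overlap_after=overlap_counts(*split(after)),
        contention=contention_table(labelset, trace),
        resolution=stats["resolution"],
        flows=stats["flows"],
        metadata=meta,
    )


def write_report(report: StudyReport, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in ("agreement", "overlap_before", "overlap_after", "contention", "resolution", "flows"):
        getattr(report, name).to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
    (outdir / "metadata.json").write_text(json.dumps(report.metadata, indent=2, sort_keys=True))
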
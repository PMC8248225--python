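"""Domain types, validation and file I/O for multi-reader, multi-round label data.

The central container is :class:`LabelSet`: a long-format table of reads (one
row per image x arm x reader x round x finding) together with the panel
assignment (which 3 readers of an arm's cohort reviewed each image) and any
image-level exclusions.  Labels are the literal strings ``Absent`` /
``Present`` / ``Hedge`` — never numeric codes — so a polarity bug cannot pass
silently through file round-trips.

Rounds are sparse: round 0 is the complete independent read (exactly one read
per panel reader per finding); later rounds contain only re-entered reads,
and a missing read at round ``r > 0`` means the reader kept their most recent
earlier label (carry-forward).  :meth:`LabelSet.effective_reads` materialises
that convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

__all__ = [
    "ABSENT",
    "PRESENT",
    "HEDGE",
    "LABELS",
    "READ_COLUMNS",
    "DEFAULT_FINDINGS",
    "Finding",
    "StudyConfig",
    "LabelSet",
    "LabelSetError",
    "SchemaError",
    "IntegrityError",
    "load_reads",
    "write_reads",
    "apply_exclusions",
]

ABSENT = "Absent"
PRESENT = "Present"
HEDGE = "Hedge"
LABELS = (ABSENT, PRESENT, HEDGE)

#: Column order of the reads file; ``comment`` is carried but never computed on.
READ_COLUMNS = (
    "image_id",
    "arm",
    "reader_id",
    "round",
    "finding",
    "label",
    "detail",
    "quality_flag",
    "comment",
)

_KEY = ["image_id", "arm", "reader_id", "round", "finding"]


class LabelSetError(ValueError):
    """Base class for label-data validation failures."""


class SchemaError(LabelSetError):
    """The file or frame does not have the required columns/types."""


class IntegrityError(LabelSetError):
    """The data violate a LabelSet invariant (duplicates, bad labels, ...)."""


@dataclass(frozen=True)
class Finding:
    """A binary radiographic finding; some findings additionally allow Hedge."""

    name: str
    hedge_allowed: bool = False


#: The six findings of the default study profile.  Hedge is allowed only for
#: nodule and pneumothorax.
DEFAULT_FINDINGS = (
    Finding("airspace_opacity"),
    Finding("cardiomegaly"),
    Finding("edema"),
    Finding("fracture"),
    Finding("nodule", hedge_allowed=True),
    Finding("pneumothorax", hedge_allowed=True),
)

DEFAULT_DETAIL_VOCAB = {
    "airspace_opacity": ("consolidation", "atelectasis", "mass"),
    "edema": ("moderate", "severe"),
}


@dataclass
class StudyConfig:
    """Study-level configuration: finding vocabulary and exclusions.

    ``technical_exclusions`` lists image_ids removed for reasons unrelated to
    image content (the mechanism is outside the labelling workflow, so they
    are configuration, not data).
    """

    findings: tuple[Finding, ...] = DEFAULT_FINDINGS
    technical_exclusions: tuple[str, ...] = ()
    detail_vocab: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_DETAIL_VOCAB)
    )

    def finding_map(self) -> dict[str, Finding]:
        return {f.name: f for f in self.findings}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text())
        findings = tuple(
            Finding(f["name"], bool(f.get("hedge_allowed", False)))
            for f in raw.get("findings", [])
        ) or DEFAULT_FINDINGS
        names = {f.name for f in findings}
        bad = [f.name for f in findings if not f.name.isidentifier()]
        if bad or len(names) != len(findings):
            raise SchemaError(f"invalid or duplicate finding names in config: {sorted(bad) or 'duplicates'}")
        vocab = {k: tuple(v) for k, v in raw.get("detail_vocab", DEFAULT_DETAIL_VOCAB).items()}
        unknown = sorted(set(vocab) - names)
        if unknown:
            raise SchemaError(f"detail_vocab refers to unknown findings: {unknown}")
        return cls(
            findings=findings,
            technical_exclusions=tuple(raw.get("technical_exclusions", [])),
            detail_vocab=vocab,
        )


@dataclass
class LabelSet:
    """Validated collection of reads plus panel assignments and exclusions.

    Parameters
    ----------
    reads
        Long-format frame with the columns of :data:`READ_COLUMNS`.
    panels
        ``(image_id, arm) -> tuple of reader_ids`` (sorted, size = panel size).
    excluded_images
        ``image_id -> reason`` with reason in ``{"poor_quality", "technical"}``.
    findings
        Name -> :class:`Finding`; defaults to the six-finding study profile.
    """

    reads: pd.DataFrame
    panels: dict[tuple[str, int], tuple[str, ...]]
    excluded_images: dict[str, str] = field(default_factory=dict)
    findings: Mapping[str, Finding] = field(
        default_factory=lambda: {f.name: f for f in DEFAULT_FINDINGS}
    )

    def __post_init__(self) -> None:
        self.validate()

    # -- queries -----------------------------------------------------------

    def images(self) -> list[str]:
        return sorted(self.reads["image_id"].unique())

    def arms(self) -> list[int]:
        return sorted(self.reads["arm"].unique())

    def max_round(self, arm: int | None = None) -> int:
        df = self.reads if arm is None else self.reads[self.reads["arm"] == arm]
        return 0 if df.empty else int(df["round"].max())

    def effective_reads(self, round: int, arm: int | None = None) -> pd.DataFrame:
        """Reads in effect at ``round``: each reader's most recent read <= round.

        Missing re-entries in rounds > 0 mean the reader kept their earlier
        label, so the latest read at or before ``round`` is the one in force.
        """
        df = self.reads[self.reads["round"] <= round]
        if arm is not None:
            df = df[df["arm"] == arm]
        df = df.sort_values("round", kind="stable")
        out = df.groupby(
            ["image_id", "arm", "reader_id", "finding"], sort=False
        ).tail(1)
        return out.reset_index(drop=True)

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        """Re-assert every LabelSet invariant; raises on the first violation."""
        df = self.reads
        missing = [c for c in READ_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"reads frame missing required column(s): {missing}")

        known = set(self.findings)
        bad_f = sorted(set(df["finding"]) - known)
        if bad_f:
            raise IntegrityError(f"unknown finding(s): {bad_f}")
        bad_l = sorted(set(df["label"]) - set(LABELS))
        if bad_l:
            raise IntegrityError(f"unknown label(s): {bad_l}")
        bad_arm = sorted(set(df["arm"]) - {1, 2})
        if bad_arm:
            raise IntegrityError(f"arm must be 1 or 2, got: {bad_arm}")
        if (df["round"] < 0).any():
            raise IntegrityError("round must be >= 0")

        no_hedge = {n for n, f in self.findings.items() if not f.hedge_allowed}
        hedged = df[(df["label"] == HEDGE) & (df["finding"].isin(no_hedge))]
        if len(hedged):
            offenders = hedged[["image_id", "finding"]].drop_duplicates()
            raise IntegrityError(
                "Hedge label on finding(s) that do not allow it: "
                + ", ".join(f"{r.image_id}/{r.finding}" for r in offenders.itertuples())
            )

        dup = df[df.duplicated(_KEY, keep=False)]
        if len(dup):
            keys = dup[_KEY].drop_duplicates().head(10)
            raise IntegrityError(
                "duplicate (image, arm, reader, round, finding) read(s): "
                + "; ".join(map(str, keys.itertuples(index=False, name=None)))
            )

        # every read's reader must belong to the assigned panel
        for (img, arm), grp in df.groupby(["image_id", "arm"], sort=False):
            panel = self.panels.get((img, int(arm)))
            if panel is None:
                raise IntegrityError(f"no panel assigned for image {img!r} arm {arm}")
            extra = set(grp["reader_id"]) - set(panel)
            if extra:
                raise IntegrityError(
                    f"reader(s) {sorted(extra)} read image {img!r} arm {arm} "
                    f"but are not on its panel {panel}"
                )

        # round 0 complete: exactly one read per panel reader per finding
        r0 = df[df["round"] == 0]
        counts = r0.groupby(["image_id", "arm", "finding"], sort=False)["reader_id"].nunique()
        for (img, arm, fnd), n in counts.items():
            want = len(self.panels[(img, int(arm))])
            if n != want:
                raise IntegrityError(
                    f"round 0 of image {img!r} arm {arm} finding {fnd!r} has {n} "
                    f"reads, expected {want}"
                )

        # later rounds: only panel readers (already checked), 1..panel size
        if set(self.excluded_images) & set(df["image_id"]):
            raise IntegrityError("excluded images must carry no reads")
        bad_reason = {r for r in self.excluded_images.values()} - {"poor_quality", "technical"}
        if bad_reason:
            raise IntegrityError(f"unknown exclusion reason(s): {sorted(bad_reason)}")

    # -- equality (order-insensitive on reads) ------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabelSet):
            return NotImplemented
        a = self.reads.sort_values(list(READ_COLUMNS), kind="stable").reset_index(drop=True)
        b = other.reads.sort_values(list(READ_COLUMNS), kind="stable").reset_index(drop=True)
        return (
            a[list(READ_COLUMNS)].equals(b[list(READ_COLUMNS)])
            and self.panels == other.panels
            and self.excluded_images == other.excluded_images
        )


def _normalise_reads(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in ("image_id", "reader_id", "finding", "label"):
        df[col] = df[col].astype(str)
    for col in ("detail", "comment"):
        if col not in df.columns:
            df[col] = ""
        df[col] = df[col].fillna("").astype(str)
    df["arm"] = df["arm"].astype(int)
    df["round"] = df["round"].astype(int)
    if df["quality_flag"].dtype != bool:
        df["quality_flag"] = (
            df["quality_flag"].astype(str).str.lower().map(
                {"true": True, "1": True, "false": False, "0": False, "": False}
            )
        )
        if df["quality_flag"].isna().any():
            raise SchemaError("quality_flag must be true/false")
    return df[list(READ_COLUMNS)]


def _infer_panels(df: pd.DataFrame) -> dict[tuple[str, int], tuple[str, ...]]:
    r0 = df[df["round"] == 0]
    return {
        (img, int(arm)): tuple(sorted(grp["reader_id"].unique()))
        for (img, arm), grp in r0.groupby(["image_id", "arm"], sort=False)
    }


def load_reads(
    path: str | Path,
    study_config: StudyConfig | None = None,
) -> LabelSet:
    """Load a reads file (CSV with header) into a validated :class:`LabelSet`.

    Panels are inferred from the round-0 reader sets.  Rows with unknown
    findings or labels are rejected (IntegrityError), never coerced.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = [c for c in READ_COLUMNS if c not in ("detail", "comment")]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"reads file {path} missing required column(s): {missing}")
    df = _normalise_reads(df)
    cfg = study_config or StudyConfig()
    return LabelSet(reads=df, panels=_infer_panels(df), findings=cfg.finding_map())


def write_reads(labelset: LabelSet, path: str | Path) -> None:
    """Write a reads file with deterministic column order and row sort.

    Sorted by (image, arm, round, reader, finding) so repeated writes of the
    same LabelSet are byte-identical.
    """
    df = labelset.reads.copy()
    df["quality_flag"] = df["quality_flag"].map({True: "true", False: "false"})
    df = df.sort_values(
        ["image_id", "arm", "round", "reader_id", "finding"], kind="stable"
    )
    df[list(READ_COLUMNS)].to_csv(path, index=False, lineterminator="\n")


def apply_exclusions(
    labelset: LabelSet,
    quality_arm: int = 1,
    technical_exclusions: Iterable[str] = (),
) -> LabelSet:
    """Drop poor-quality and technically excluded images.

    An image is excluded for poor quality iff a majority (>= 2 of 3) of its
    round-0 quality flags in ``quality_arm`` are true.  ``technical_exclusions``
    come from study configuration.  Idempotent.
    """
    if quality_arm not in (1, 2):
        raise ValueError(f"quality_arm must be 1 or 2, got {quality_arm}")
    df = labelset.reads
    r0 = df[(df["round"] == 0) & (df["arm"] == quality_arm)]
    if r0.empty and not df.empty:
        raise IntegrityError(f"no round-0 reads in arm {quality_arm}")

    # one quality flag per reader per image (flags repeat across findings)
    flags = r0.groupby(["image_id", "reader_id"], sort=False)["quality_flag"].any()
    per_image = flags.groupby("image_id").agg(["sum", "count"])
    short = per_image[per_image["count"] < 3]
    if len(short):
        raise IntegrityError(
            f"image(s) with <3 round-0 reads in arm {quality_arm}: "
            f"{sorted(short.index.tolist())}"
        )
    poor = set(per_image.index[per_image["sum"] >= 2])

    excluded = dict(labelset.excluded_images)
    for img in poor:
        excluded[img] = "poor_quality"
    for img in technical_exclusions:
        excluded.setdefault(str(img), "technical")

    keep = ~df["image_id"].isin(excluded)
    panels = {
        k: v for k, v in labelset.panels.items() if k[0] not in excluded
    }
    return LabelSet(
        reads=df[keep].reset_index(drop=True),
        panels=panels,
        excluded_images=excluded,
        findings=labelset.findings,
    )
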
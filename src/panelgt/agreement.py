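"""Agreement statistics: nominal Krippendorff's alpha and percent agreement.

Krippendorff's alpha is the chance-corrected agreement coefficient of choice
here because it handles a variable number of raters per unit (each image is
read by 3 readers drawn from a larger cohort, and some comparisons pair a
single random reader from each arm).  It is computed from scratch via the
coincidence matrix:

    o_ck = sum over units u of  (# ordered (c, k) label pairs within u) / (m_u - 1)

with ``m_u`` the number of labels in unit u (units with fewer than two labels
cannot be paired and are dropped).  For the nominal difference metric,

    alpha = 1 - D_o / D_e,
    D_o = sum_{c != k} o_ck,
    D_e = sum_{c != k} n_c n_k / (n - 1),

with ``n_c`` the coincidence marginals and ``n = sum_c n_c``.  alpha is 1.0
exactly when every unit is internally unanimous, and ~0 for chance-level
labelling.  A dataset in which only one category is ever observed has
``D_e = 0`` and alpha undefined: that is raised as an error, never silently
reported as 1 or 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .aggregate import aggregate_panel, apply_hedge_policy
from .labels import LabelSet

__all__ = [
    "AgreementError",
    "UndefinedAgreementError",
    "CoincidenceMatrix",
    "AgreementResult",
    "coincidence_matrix",
    "krippendorff_alpha",
    "percent_agreement",
    "random_reader_alpha",
    "alpha_by_round",
]


class AgreementError(ValueError):
    pass


class UndefinedAgreementError(AgreementError):
    """alpha is undefined (e.g. a single observed category => D_e = 0)."""


@dataclass
class CoincidenceMatrix:
    """Symmetric category-by-category table of within-unit rating pairs."""

    categories: tuple[str, ...]
    counts: np.ndarray  # shape (k, k), o_ck
    n_units: int

    @property
    def marginals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class AgreementResult:
    alpha: float
    n_units: int
    n_pairable_values: int
    comparison: str = ""
    resampling: tuple[int, float, float] | None = None  # (n_reps, mean, sd)
    percent_agreement: float | None = None


def _to_units(units: Iterable[Sequence[str]]) -> list[list[str]]:
    return [list(u) for u in units]


def coincidence_matrix(units: Iterable[Sequence[str]]) -> CoincidenceMatrix:
    """Build the coincidence matrix over per-unit label multisets.

    Units with fewer than two labels are dropped (no within-unit pair exists).
    """
    units = _to_units(units)
    pairable = [u for u in units if len(u) >= 2]
    if not pairable:
        raise AgreementError("no unit has >= 2 labels; agreement is not computable")

    cats = tuple(sorted({lab for u in pairable for lab in u}))
    index = {c: i for i, c in enumerate(cats)}
    k = len(cats)
    o = np.zeros((k, k))

    # group units by size; for size m each ordered column pair (i, j), i != j,
    # contributes 1/(m-1) to o[code_i, code_j]
    by_size: dict[int, list[list[int]]] = {}
    for u in pairable:
        by_size.setdefault(len(u), []).append([index[lab] for lab in u])
    for m, codes in by_size.items():
        arr = np.asarray(codes)
        w = 1.0 / (m - 1)
        for i in range(m):
            for j in range(m):
                if i != j:
                    np.add.at(o, (arr[:, i], arr[:, j]), w)
    return CoincidenceMatrix(categories=cats, counts=o, n_units=len(pairable))


def krippendorff_alpha(
    units: Iterable[Sequence[str]], comparison: str = ""
) -> AgreementResult:
    """Nominal-metric Krippendorff's alpha over per-unit label multisets."""
    cm = coincidence_matrix(units)
    n_c = cm.marginals
    n = cm.total
    if len(cm.categories) < 2:
        raise UndefinedAgreementError(
            "only one category observed; expected disagreement is zero and "
            "alpha is undefined"
        )
    d_o = float(cm.counts.sum() - np.trace(cm.counts))
    d_e = float((n_c[:, None] * n_c[None, :]).sum() - (n_c**2).sum()) / (n - 1)
    if d_e == 0:
        raise UndefinedAgreementError("expected disagreement is zero; alpha undefined")
    alpha = 1.0 - d_o / d_e
    return AgreementResult(
        alpha=alpha,
        n_units=cm.n_units,
        n_pairable_values=int(round(n)),
        comparison=comparison,
    )


def percent_agreement(
    source_a: Mapping[str, str] | pd.Series,
    source_b: Mapping[str, str] | pd.Series,
) -> float:
    """Fraction of units on which two label sources agree exactly."""
    a = pd.Series(dict(source_a)) if not isinstance(source_a, pd.Series) else source_a
    b = pd.Series(dict(source_b)) if not isinstance(source_b, pd.Series) else source_b
    if set(a.index) != set(b.index):
        raise AgreementError("the two sources label different unit sets")
    if len(a) == 0:
        raise AgreementError("empty unit set")
    b = b.reindex(a.index)
    return float((a == b).mean())


def _round0_panel_labels(
    labelset: LabelSet, finding: str, hedge_policy: str
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Per-image 3-reader round-0 label matrices for both arms.

    Returns (images, labels_arm1, labels_arm2), each label array of shape
    (n_images, 3) with columns ordered by sorted panel reader_id.
    """
    df = labelset.reads
    r0 = df[(df["round"] == 0) & (df["finding"] == finding)]
    images = sorted(r0["image_id"].unique())
    arrays = []
    for arm in (1, 2):
        sub = r0[r0["arm"] == arm].sort_values(["image_id", "reader_id"], kind="stable")
        got_images = sub["image_id"].unique()
        if sorted(got_images) != images:
            raise AgreementError(
                f"arm {arm} lacks round-0 reads for some images on {finding!r}"
            )
        labs = np.asarray(
            apply_hedge_policy(sub["label"].tolist(), hedge_policy)
        ).reshape(len(images), -1)
        if labs.shape[1] != 3:
            raise AgreementError("expected 3 round-0 reads per image per arm")
        arrays.append(labs)
    return images, arrays[0], arrays[1]


def random_reader_alpha(
    labelset: LabelSet,
    finding: str,
    n_reps: int = 100,
    seed: int = 0,
    hedge_policy: str = "hedge_as_present",
) -> AgreementResult:
    """Individual-reader agreement between arms by random-reader resampling.

    Per repetition, one reader is drawn uniformly from each image's arm-1
    panel and one from its arm-2 panel; alpha is computed over the resulting
    two-label units and averaged over ``n_reps`` repetitions.  The resampling
    uses its own seeded generator, independent of any data-generation seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    _, l1, l2 = _round0_panel_labels(labelset, finding, hedge_policy)
    n = l1.shape[0]
    rng = np.random.default_rng(seed)
    alphas = []
    for _ in range(n_reps):
        i1 = rng.integers(0, 3, size=n)
        i2 = rng.integers(0, 3, size=n)
        units = np.stack([l1[np.arange(n), i1], l2[np.arange(n), i2]], axis=1)
        alphas.append(krippendorff_alpha(units).alpha)
    alphas = np.asarray(alphas)
    mean = float(alphas.mean())
    sd = float(alphas.std(ddof=1)) if n_reps > 1 else 0.0
    return AgreementResult(
        alpha=mean,
        n_units=n,
        n_pairable_values=2 * n,
        comparison=f"random single reader arm1 vs arm2, finding={finding}",
        resampling=(n_reps, mean, sd),
    )


def exhaustive_pairing_alpha(
    labelset: LabelSet,
    finding: str,
    hedge_policy: str = "hedge_as_present",
) -> float:
    """Draw-free counterpart of :func:`random_reader_alpha`.

    Averages alpha over the nine pairings (i, j) that match each image's i-th
    arm-1 panel reader (sorted order) with its j-th arm-2 panel reader.
    """
    _, l1, l2 = _round0_panel_labels(labelset, finding, hedge_policy)
    alphas = [
        krippendorff_alpha(np.stack([l1[:, i], l2[:, j]], axis=1)).alpha
        for i in range(3)
        for j in range(3)
    ]
    return float(np.mean(alphas))


def interpanel_alpha(
    panel_labels: pd.DataFrame, finding: str, comparison: str = ""
) -> AgreementResult:
    """alpha between the two arms' aggregated labels for one finding."""
    sub = panel_labels[panel_labels["finding"] == finding]
    piv = sub.pivot_table(
        index="image_id", columns="arm", values="label", aggfunc="first"
    )
    if piv.isna().any().any() or not {1, 2} <= set(piv.columns):
        raise AgreementError("both arms must label every image")
    units = piv[[1, 2]].to_numpy()
    res = krippendorff_alpha(units, comparison=comparison or f"interpanel, {finding}")
    res.percent_agreement = float((units[:, 0] == units[:, 1]).mean())
    return res


def alpha_by_round(
    labelset: LabelSet,
    finding: str,
    rounds: Sequence[int] | None = None,
    policy: str = "majority",
    hedge_policy: str = "hedge_as_present",
) -> list[AgreementResult]:
    """Inter-panel alpha of aggregated labels at each round (carry-forward).

    Round 0 is the initial-majority inter-panel agreement; later rounds show
    how adjudication within each arm moves the panels together (or apart).
    """
    if rounds is None:
        rounds = range(0, min(labelset.max_round(1), labelset.max_round(2)) + 1)
    out = []
    for r in rounds:
        pl = aggregate_panel(labelset, policy=policy, round=r, hedge_policy=hedge_policy)
        out.append(
            interpanel_alpha(pl, finding, comparison=f"interpanel {policy}, round {r}")
        )
    return out
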
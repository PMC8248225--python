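"""Synthetic two-arm reader-panel simulator.

Emulates the statistical structure of an enriched multi-reader chest
radiograph labelling study: ~1100 images enriched so roughly half carry at
least one of six findings, two independent arms whose cohorts (4 and 5
radiologists) each supply a random panel of 3 readers per image, reader-level
sensitivity/specificity differences, correlated errors through shared image
difficulty, hedge calls on nodule and pneumothorax, and round-wise
adjudication dynamics in which most disagreements resolve within two rounds.

The reader error model is a Gaussian latent-conspicuity threshold model.
Each (image, finding) carries a latent conspicuity

    z ~ Normal(mu_T, sigma_img),   T in {0, 1} the ground truth,

shared by every reader (this is the only source of correlated errors:
subtle findings are missed by many readers).  Reader r perceives
``y = z + eps`` with ``eps ~ Normal(0, sigma_r)`` and labels

    Present  if y > tau_r,
    Hedge    if tau_r - delta_r < y <= tau_r   (hedge-allowed findings),
    Absent   otherwise.

The model jointly produces the three canonical causes of disagreement:
low-z true findings that only low-noise readers cross (detection),
spread in tau_r (thresholding), and channel misattribution among the
confusable findings opacity/edema/nodule via a row-stochastic confusion
matrix (classification).  Reader sensitivity/specificity have closed forms
(Gaussian tail integrals, :func:`reader_operating_point`) which the simulator
recovers empirically — the main calibration check.

Everything is a pure function of ``SimulationConfig.seed``; truth sampling,
profile sampling, read noise and adjudication use independent child streams
so that, e.g., changing the number of adjudication rounds never perturbs the
initial reads.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .labels import (
    ABSENT,
    DEFAULT_DETAIL_VOCAB,
    DEFAULT_FINDINGS,
    HEDGE,
    PRESENT,
    Finding,
    LabelSet,
)

__all__ = [
    "ReaderProfile",
    "SimulationConfig",
    "TruthTable",
    "default_reader_profiles",
    "sample_truth",
    "simulate_reads",
    "simulate_adjudication",
    "simulate_study",
    "reader_operating_point",
]

CAUSES = ("detection", "thresholding", "classification", "none")
CONFUSABLE = ("airspace_opacity", "edema", "nodule")

#: Per-finding prevalence under enrichment: ~500 of 1100 images carry at
#: least one finding, split unevenly (opacity commonest, pneumothorax rarest).
DEFAULT_PREVALENCE = {
    "airspace_opacity": 0.18,
    "cardiomegaly": 0.15,
    "edema": 0.12,
    "fracture": 0.08,
    "nodule": 0.12,
    "pneumothorax": 0.06,
}


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ReaderProfile:
    """One reader's per-finding operating parameters.

    tau: decision threshold on the perceived conspicuity scale;
    delta: hedge half-width (0 for findings without a Hedge option);
    sigma: perceptual noise SD.
    """

    reader_id: str
    tau: Mapping[str, float]
    delta: Mapping[str, float]
    sigma: Mapping[str, float]


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study; defaults emulate the design above."""

    findings: tuple[Finding, ...] = DEFAULT_FINDINGS
    n_images: int = 1100
    prevalence: dict[str, float] = field(default_factory=dict)
    mu_neg: float = 0.0
    mu_pos: float = 2.0
    #: detection-prone findings sit closer to threshold: subtle true positives
    #: (low z) that some readers miss are then a real pathway, not a tail event
    mu_pos_by_finding: dict[str, float] = field(
        default_factory=lambda: {"fracture": 1.4, "nodule": 1.4, "pneumothorax": 1.5}
    )
    sigma_img: float = 0.7
    confusion: dict[str, dict[str, float]] | None = None
    cohort_sizes: tuple[int, int] = (4, 5)
    panel_size: int = 3
    tau_center: float = 1.0
    tau_spread: float = 0.30
    sigma_reader_range: tuple[float, float] = (0.4, 0.8)
    noise_scale: float = 1.0
    hedge_width: float = 0.35
    image_poor_quality_rate: float = 0.01
    quality_flag_sensitivity: float = 0.85
    quality_flag_fp_rate: float = 0.003
    detail_vocab: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_DETAIL_VOCAB.items()}
    )
    rho: dict[str, float] = field(
        default_factory=lambda: {
            "detection": 0.85,
            "thresholding": 0.65,
            "classification": 0.75,
        }
    )
    direction_weights: dict[str, float] = field(
        default_factory=lambda: {
            "detection_present": 0.95,
            "thresholding_z": 0.85,
            "classification_truth": 0.90,
            "to_hedge": 0.15,
        }
    )
    #: offset added to the conspicuity criterion a panel converges on when
    #: resolving thresholding contests: positive = the discussion settles on a
    #: stricter standard than the average solo read (for edema, panels demand
    #: at-least-moderate severity, pushing borderline calls to Absent)
    adjudication_strictness: dict[str, float] = field(
        default_factory=lambda: {"edema": 0.6}
    )
    max_rounds: int = 2
    extension_arm: int | None = 1
    extension_rounds: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        prev = dict(DEFAULT_PREVALENCE)
        prev.update(self.prevalence)
        self.prevalence = {
            f.name: prev.get(f.name, 0.15) for f in self.findings
        }
        self.validate()

    def finding_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.findings)

    def mu_pos_for(self, finding: str) -> float:
        return self.mu_pos_by_finding.get(finding, self.mu_pos)

    def validate(self) -> None:
        for name, p in self.prevalence.items():
            # upper end closed: pi = 1 is a legitimate degenerate (all positive)
            if not 0 < p <= 1:
                raise ConfigError(f"prevalence for {name!r} must be in (0,1], got {p}")
        for cause, r in self.rho.items():
            if not 0 <= r <= 1:
                raise ConfigError(f"rho[{cause!r}] must be in [0,1], got {r}")
        if self.mu_neg >= self.mu_pos:
            raise ConfigError("mu_neg must be < mu_pos")
        for f, m in self.mu_pos_by_finding.items():
            if m <= self.mu_neg:
                raise ConfigError(f"mu_pos_by_finding[{f!r}] must exceed mu_neg")
        if self.sigma_img < 0 or self.hedge_width < 0 or self.noise_scale < 0:
            raise ConfigError("sigma_img, hedge_width and noise_scale must be >= 0")
        if min(self.cohort_sizes) < self.panel_size:
            raise ConfigError("each cohort needs at least panel_size readers")
        if self.max_rounds < 1:
            raise ConfigError("max_rounds must be >= 1")
        if self.confusion is not None:
            for f, row in self.confusion.items():
                if f not in CONFUSABLE:
                    raise ConfigError(f"confusion rows allowed only for {CONFUSABLE}")
                if abs(sum(row.values()) - 1.0) > 1e-9:
                    raise ConfigError(f"confusion row for {f!r} must sum to 1")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["findings"] = [
            {"name": f.name, "hedge_allowed": f.hedge_allowed} for f in self.findings
        ]
        d["cohort_sizes"] = list(self.cohort_sizes)
        d["sigma_reader_range"] = list(self.sigma_reader_range)
        d["detail_vocab"] = {k: list(v) for k, v in self.detail_vocab.items()}
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "findings" in raw:
            raw["findings"] = tuple(
                Finding(f["name"], bool(f.get("hedge_allowed", False)))
                for f in raw["findings"]
            )
        for key in ("cohort_sizes", "sigma_reader_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "detail_vocab" in raw:
            raw["detail_vocab"] = {k: tuple(v) for k, v in raw["detail_vocab"].items()}
        return cls(**raw)

    def digest(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class TruthTable:
    """Latent ground truth: per (image, finding) the truth bit, the latent
    conspicuity z, and (after reads are simulated) the mechanism that caused
    any round-0 disagreement."""

    table: pd.DataFrame  # columns image_id, finding, truth, z, cause

    def z_matrix(self, findings: Sequence[str]) -> np.ndarray:
        piv = self.table.pivot(index="image_id", columns="finding", values="z")
        return piv.reindex(columns=list(findings)).to_numpy()

    def truth_matrix(self, findings: Sequence[str]) -> np.ndarray:
        piv = self.table.pivot(index="image_id", columns="finding", values="truth")
        return piv.reindex(columns=list(findings)).to_numpy().astype(int)

    def images(self) -> list[str]:
        return sorted(self.table["image_id"].unique())


def _streams(config: SimulationConfig) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(config.seed).spawn(4)
    names = ("truth", "profiles", "reads", "adjudication")
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def default_reader_profiles(
    config: SimulationConfig,
) -> dict[int, list[ReaderProfile]]:
    """Sample per-arm cohorts of reader profiles from the config's spreads.

    Thresholds vary per reader and finding around ``tau_center`` (SD
    ``tau_spread``); perceptual noise is uniform on ``sigma_reader_range``
    scaled by ``noise_scale``; hedge width is ``hedge_width`` for
    hedge-allowed findings, 0 otherwise.  Cohorts are disjoint between arms.
    """
    rng = _streams(config)["profiles"]
    names = config.finding_names()
    cohorts: dict[int, list[ReaderProfile]] = {}
    for arm, size in zip((1, 2), config.cohort_sizes):
        cohort = []
        for r in range(size):
            tau = {
                f: config.tau_center + config.tau_spread * rng.standard_normal()
                for f in names
            }
            lo, hi = config.sigma_reader_range
            sigma = {
                f: config.noise_scale * rng.uniform(lo, hi) for f in names
            }
            delta = {
                f.name: config.hedge_width if f.hedge_allowed else 0.0
                for f in config.findings
            }
            cohort.append(
                ReaderProfile(
                    reader_id=f"A{arm}R{r + 1}", tau=tau, delta=delta, sigma=sigma
                )
            )
        cohorts[arm] = cohort
    return cohorts


def sample_truth(config: SimulationConfig) -> TruthTable:
    """Draw the latent truth table: Bernoulli truths at the configured
    (enriched) prevalences and Gaussian conspicuities.

    With a non-identity confusion matrix, a positive confusable finding draws
    a companion channel from its confusion row; an off-diagonal draw turns
    the companion truth positive too (co-occurrence of opacity/edema/nodule
    in ill patients)."""
    rng = _streams(config)["truth"]
    names = config.finding_names()
    n, k = config.n_images, len(names)
    width = max(5, len(str(config.n_images)))
    images = [f"img{i:0{width}d}" for i in range(1, n + 1)]

    pi = np.array([config.prevalence[f] for f in names])
    truth = (rng.random((n, k)) < pi).astype(int)

    if config.confusion is not None:
        base = truth.copy()
        for f, row in config.confusion.items():
            if f not in names:
                continue
            j = names.index(f)
            cats = sorted(row)
            probs = np.array([row[c] for c in cats])
            pos = np.nonzero(base[:, j])[0]
            draws = rng.choice(len(cats), size=len(pos), p=probs)
            for i, d in zip(pos, draws):
                comp = cats[d]
                if comp != f and comp in names:
                    truth[i, names.index(comp)] = 1

    mu_pos = np.array([config.mu_pos_for(f) for f in names])
    mu = np.where(truth == 1, mu_pos[None, :], config.mu_neg)
    z = mu + config.sigma_img * rng.standard_normal((n, k))

    table = pd.DataFrame(
        {
            "image_id": np.repeat(images, k),
            "finding": np.tile(names, n),
            "truth": truth.ravel(),
            "z": z.ravel(),
            "cause": "none",
        }
    )
    return TruthTable(table=table)


def _profile_arrays(
    cohort: Sequence[ReaderProfile], names: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    tau = np.array([[p.tau[f] for f in names] for p in cohort])
    delta = np.array([[p.delta[f] for f in names] for p in cohort])
    sigma = np.array([[p.sigma[f] for f in names] for p in cohort])
    return tau, delta, sigma


def simulate_reads(
    truth: TruthTable,
    profiles: Mapping[int, Sequence[ReaderProfile]],
    config: SimulationConfig,
) -> LabelSet:
    """Simulate both arms' independent round-0 reads of every image.

    A panel of ``panel_size`` readers is drawn uniformly without replacement
    from each arm's cohort per image; the two arms share the truth table (and
    hence z) but no noise.  Fills the truth table's ``cause`` column from the
    generating mechanism of each round-0 disagreement.
    """
    for arm in (1, 2):
        if len(profiles.get(arm, ())) < config.panel_size:
            raise ConfigError(f"arm {arm} cohort smaller than panel size")
    names = config.finding_names()
    for arm in (1, 2):
        for p in profiles[arm]:
            missing = [f for f in names if f not in p.tau or f not in p.sigma]
            if missing:
                raise ConfigError(
                    f"reader {p.reader_id} profile missing finding(s) {missing}"
                )

    rng = _streams(config)["reads"]
    images = truth.images()
    n, k, m = len(images), len(names), config.panel_size
    z = truth.z_matrix(names)
    t = truth.truth_matrix(names)
    hedge_ok = np.array([f.hedge_allowed for f in config.findings])

    image_poor = rng.random(n) < config.image_poor_quality_rate

    rows = []
    relabelled = np.zeros((n, k), dtype=bool)
    arm_labels: dict[int, np.ndarray] = {}
    for arm in (1, 2):
        cohort = list(profiles[arm])
        ids = np.array([p.reader_id for p in cohort])
        tau_a, delta_a, sigma_a = _profile_arrays(cohort, names)

        # uniform panel of m without replacement, per image
        panel_idx = np.argsort(rng.random((n, len(cohort))), axis=1)[:, :m]

        sig = sigma_a[panel_idx]        # (n, m, k)
        tau_m = tau_a[panel_idx]
        del_m = delta_a[panel_idx]
        y = z[:, None, :] + sig * rng.standard_normal((n, m, k))

        labels = np.full((n, m, k), ABSENT, dtype=object)
        labels[y > tau_m] = PRESENT
        in_band = (y > tau_m - del_m) & (y <= tau_m) & hedge_ok[None, None, :]
        labels[in_band] = HEDGE

        # classification misattribution among confusable channels: a reader
        # who detected a true finding may attribute it to a different channel
        if config.confusion is not None:
            for f, row in config.confusion.items():
                if f not in names:
                    continue
                j = names.index(f)
                cats = sorted(row)
                probs = np.array([row[c] for c in cats])
                for i in np.nonzero(t[:, j])[0]:
                    for s in range(m):
                        if labels[i, s, j] == ABSENT:
                            continue
                        d = cats[int(rng.choice(len(cats), p=probs))]
                        if d != f and d in names:
                            jj = names.index(d)
                            labels[i, s, j] = ABSENT
                            labels[i, s, jj] = PRESENT
                            relabelled[i, j] = True
                            relabelled[i, jj] = True
        arm_labels[arm] = labels

        # per-reader image quality flags (shared across findings)
        p_flag = np.where(
            image_poor[:, None], config.quality_flag_sensitivity, config.quality_flag_fp_rate
        )
        flags = rng.random((n, m)) < p_flag

        # reader-subjective details for Present reads on findings with a vocab
        details = np.full((n, m, k), "", dtype=object)
        for f, vocab in config.detail_vocab.items():
            if f not in names:
                continue
            j = names.index(f)
            pos = labels[:, :, j] == PRESENT
            npos = int(pos.sum())
            if npos:
                w = np.linspace(1.0, 0.5, len(vocab))
                details[:, :, j][pos] = rng.choice(
                    list(vocab), size=npos, p=w / w.sum()
                )

        reader_ids = ids[panel_idx]     # (n, m)
        rows.append(
            pd.DataFrame(
                {
                    "image_id": np.repeat(images, m * k),
                    "arm": arm,
                    "reader_id": np.repeat(reader_ids.ravel(), k),
                    "round": 0,
                    "finding": np.tile(names, n * m),
                    "label": labels.reshape(-1),
                    "detail": details.reshape(-1),
                    "quality_flag": np.repeat(flags.ravel(), k),
                    "comment": "",
                }
            )
        )

    # mechanism-based cause tags for round-0 disagreements (across all reads)
    all_lab = np.concatenate([arm_labels[1], arm_labels[2]], axis=1)  # (n, 2m, k)
    unanimous = (all_lab == all_lab[:, :1, :]).all(axis=1)
    cause = np.full((n, k), "none", dtype=object)
    contested = ~unanimous
    cause[contested & relabelled] = "classification"
    subtle = (t == 1) & (z <= config.tau_center)
    cause[contested & ~relabelled & subtle] = "detection"
    cause[contested & ~relabelled & ~subtle] = "thresholding"

    tab = truth.table
    piv_order = (
        tab.set_index(["image_id", "finding"])
        .index
    )
    cause_df = pd.DataFrame(
        {"image_id": np.repeat(images, k), "finding": np.tile(names, n), "cause": cause.ravel()}
    ).set_index(["image_id", "finding"])
    tab["cause"] = cause_df.reindex(piv_order)["cause"].to_numpy()

    reads = pd.concat(rows, ignore_index=True)
    panels = {
        (img, int(arm)): tuple(sorted(grp["reader_id"].unique()))
        for (img, arm), grp in reads.groupby(["image_id", "arm"], sort=False)
    }
    return LabelSet(
        reads=reads,
        panels=panels,
        findings={f.name: f for f in config.findings},
    )


def _arm_max_round(config: SimulationConfig, arm: int) -> int:
    extra = config.extension_rounds if arm == config.extension_arm else 0
    return config.max_rounds + extra


def simulate_adjudication(
    labelset: LabelSet,
    truth: TruthTable,
    config: SimulationConfig,
) -> LabelSet:
    """Append adjudication rounds to a round-0 LabelSet.

    Per contested (image, arm, finding) and round, the dissent resolves with
    probability ``rho[cause]``; resolution direction depends on the cause:
    detection-driven contests almost always resolve to Present, thresholding
    contests to the side favoured by the latent conspicuity, classification
    contests to the truth of the channel.  Resolved keys emit a unanimous
    triple at that round; unresolved keys persist (carry-forward) until the
    arm's round cap.
    """
    if config.max_rounds < 1:
        raise ConfigError("max_rounds must be >= 1")
    rng = _streams(config)["adjudication"]
    names = config.finding_names()
    hedge_ok = {f.name: f.hedge_allowed for f in config.findings}
    w = config.direction_weights

    tab = truth.table.set_index(["image_id", "finding"])
    r0 = labelset.reads[labelset.reads["round"] == 0]

    new_rows: list[dict] = []
    for arm in labelset.arms():
        sub = r0[r0["arm"] == arm]
        grouped = sub.groupby(["image_id", "finding"], sort=True)
        contested: list[tuple[str, str, str, str]] = []  # (img, finding, cause, kind)
        for (img, fnd), grp in grouped:
            labs = grp["label"].tolist()
            dets = grp.loc[grp["label"] == PRESENT, "detail"].tolist()
            if len(set(labs)) > 1:
                cause = tab.loc[(img, fnd), "cause"]
                if cause == "none":  # arms may disagree while this arm agrees
                    cause = "thresholding"
                contested.append((img, fnd, cause, "label"))
            elif fnd in config.detail_vocab and len(set(dets)) > 1:
                contested.append((img, fnd, "classification", "detail"))

        unresolved = contested
        for rnd in range(1, _arm_max_round(config, arm) + 1):
            still = []
            for img, fnd, cause, kind in unresolved:
                if rng.random() >= config.rho.get(cause, 0.5):
                    still.append((img, fnd, cause, kind))
                    continue
                if kind == "detail":
                    label = PRESENT if (
                        sub[(sub["image_id"] == img) & (sub["finding"] == fnd)]["label"]
                        == PRESENT
                    ).all() else ABSENT
                else:
                    t_if = int(tab.loc[(img, fnd), "truth"])
                    z_if = float(tab.loc[(img, fnd), "z"])
                    if cause == "detection":
                        label = PRESENT if rng.random() < w["detection_present"] else ABSENT
                    elif cause == "classification":
                        truthlab = PRESENT if t_if == 1 else ABSENT
                        label = truthlab if rng.random() < w["classification_truth"] else (
                            ABSENT if truthlab == PRESENT else PRESENT
                        )
                    else:  # thresholding
                        mid = 0.5 * (config.mu_neg + config.mu_pos_for(fnd))
                        crit = min(config.tau_center, mid) + config.adjudication_strictness.get(fnd, 0.0)
                        favoured = PRESENT if z_if > crit else ABSENT
                        label = favoured if rng.random() < w["thresholding_z"] else (
                            ABSENT if favoured == PRESENT else PRESENT
                        )
                    if label == PRESENT and hedge_ok[fnd] and rng.random() < w["to_hedge"]:
                        label = HEDGE
                detail = ""
                if label == PRESENT and fnd in config.detail_vocab:
                    detail = str(rng.choice(list(config.detail_vocab[fnd])))
                for reader in labelset.panels[(img, arm)]:
                    new_rows.append(
                        {
                            "image_id": img,
                            "arm": arm,
                            "reader_id": reader,
                            "round": rnd,
                            "finding": fnd,
                            "label": label,
                            "detail": detail,
                            "quality_flag": False,
                            "comment": "",
                        }
                    )
            unresolved = still

    reads = labelset.reads
    if new_rows:
        reads = pd.concat([reads, pd.DataFrame(new_rows)], ignore_index=True)
    return LabelSet(
        reads=reads,
        panels=dict(labelset.panels),
        excluded_images=dict(labelset.excluded_images),
        findings=dict(labelset.findings),
    )


def simulate_study(
    config: SimulationConfig,
) -> tuple[LabelSet, TruthTable, dict[int, list[ReaderProfile]]]:
    """Convenience: truth -> profiles -> round-0 reads -> adjudication rounds."""
    truth = sample_truth(config)
    profiles = default_reader_profiles(config)
    reads = simulate_reads(truth, profiles, config)
    adjudicated = simulate_adjudication(reads, truth, config)
    return adjudicated, truth, profiles


def reader_operating_point(
    profile: ReaderProfile,
    finding: str,
    config: SimulationConfig,
    hedge_policy: str = "hedge_as_present",
) -> tuple[float, float]:
    """Closed-form (sensitivity, specificity) of one reader on one finding.

    Marginally over image difficulty, the perceived conspicuity is
    ``y ~ Normal(mu_T, sqrt(sigma_img^2 + sigma_r^2))``; under
    ``hedge_as_present`` the effective positivity threshold is
    ``tau - delta`` (a Hedge counts as a positive call), under
    ``hedge_as_absent`` it is ``tau``.  Valid for the identity confusion
    matrix (no channel misattribution).
    """
    s = float(np.hypot(config.sigma_img, profile.sigma[finding]))
    thr = profile.tau[finding]
    if hedge_policy == "hedge_as_present":
        thr = thr - profile.delta[finding]
    elif hedge_policy != "hedge_as_absent":
        raise ValueError("hedge_policy must be hedge_as_present or hedge_as_absent")
    sens = float(1 - norm.cdf((thr - config.mu_pos_for(finding)) / s))
    spec = float(norm.cdf((thr - config.mu_neg) / s))
    return sens, spec
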
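import pandas as pd
import pytest

from panelgt.labels import LabelSet, READ_COLUMNS
from panelgt.simulate import SimulationConfig, simulate_study
from panelgt.labels import Finding


def make_labelset(triples, findings=None, details=None, quality=None, rounds=None):
    """Build a LabelSet from a compact description.

    triples: {(image_id, arm, finding): (l1, l2, l3)} for round 0 using
    readers r1/r2/r3 (arm 1) or r4/r5/r6 (arm 2).  ``rounds`` optionally adds
    later rounds in the same shape: {round: {(image, arm, finding): labels}}.
    ``details``/``quality``: same keys, per-reader tuples.
    """
    rows = []

    def readers(arm):
        return ("r1", "r2", "r3") if arm == 1 else ("r4", "r5", "r6")

    def add(rnd, key, labels, dets=None, flags=None):
        img, arm, fnd = key
        for i, reader in enumerate(readers(arm)):
            rows.append(
                {
                    "image_id": img,
                    "arm": arm,
                    "reader_id": reader,
                    "round": rnd,
                    "finding": fnd,
                    "label": labels[i],
                    "detail": (dets or ("", "", ""))[i],
                    "quality_flag": (flags or (False, False, False))[i],
                    "comment": "",
                }
            )

    for key, labels in triples.items():
        add(0, key, labels, (details or {}).get(key), (quality or {}).get(key))
    for rnd, keys in (rounds or {}).items():
        for key, labels in keys.items():
            add(rnd, key, labels)

    df = pd.DataFrame(rows, columns=list(READ_COLUMNS))
    panels = {
        (img, int(arm)): tuple(sorted(grp["reader_id"].unique()))
        for (img, arm), grp in df[df["round"] == 0].groupby(["image_id", "arm"])
    }
    kwargs = {}
    if findings is not None:
        kwargs["findings"] = {f.name: f for f in findings}
    return LabelSet(reads=df, panels=panels, **kwargs)


NOISE_FREE = dict(
    sigma_img=0.0,
    sigma_reader_range=(0.0, 0.0),
    tau_spread=0.0,
    image_poor_quality_rate=0.0,
    quality_flag_fp_rate=0.0,
)


@pytest.fixture(scope="session")
def small_study():
    """A small noisy two-arm study with adjudication rounds."""
    cfg = SimulationConfig(n_images=80, seed=11)
    labelset, truth, profiles = simulate_study(cfg)
    return cfg, labelset, truth, profiles


@pytest.fixture(scope="session")
def noise_free_study():
    """Zero reader and image noise: every read equals the latent truth."""
    cfg = SimulationConfig(
        n_images=120,
        seed=5,
        prevalence={f.name: 0.3 for f in SimulationConfig().findings},
        **NOISE_FREE,
    )
    labelset, truth, profiles = simulate_study(cfg)
    return cfg, labelset, truth, profiles


@pytest.fixture(scope="session")
def full_study():
    """Default-condition study at full size (1100 images, six findings)."""
    cfg = SimulationConfig(seed=7)
    labelset, truth, profiles = simulate_study(cfg)
    return cfg, labelset, truth, profiles
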
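"""Calibration of the simulator against a target inter-panel agreement.

Chance-corrected agreement and raw concordance decouple for rare findings:
when most images are negative, two panels can agree on the vast majority of
images while Krippendorff's alpha — which discounts the agreement expected
from the skewed base rate — stays low.  These helpers tune the global reader
noise so the simulated inter-panel (majority-vote) alpha hits a requested
level, then measure the raw percent concordance that goes with it.

alpha is monotone decreasing in the reader-noise scale, so a bisection on
the scale suffices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .aggregate import aggregate_panel
from .agreement import interpanel_alpha
from .labels import Finding
from .simulate import (
    SimulationConfig,
    default_reader_profiles,
    sample_truth,
    simulate_reads,
)

__all__ = ["CalibrationResult", "interpanel_agreement", "calibrate_noise_scale"]


@dataclass
class CalibrationResult:
    noise_scale: float
    alpha_mean: float
    alpha_sd: float
    concordance_mean: float  # fraction in [0, 1]
    n_reps: int
    n_images: int


def _base_rate_consistent_tau(
    noise_scale: float, prevalence: float, cfg_probe: SimulationConfig
) -> float:
    """Threshold at which an average reader's marginal Present rate equals the
    prevalence, whatever the noise level.

    Radiologists operate near the base rate; without this, cranking up reader
    noise floods the labels with false positives and the finding stops being
    rare in the *calls*, not just in the truth.  Solves
    ``(1-pi) * P(y > tau | T=0) + pi * P(y > tau | T=1) = pi`` for the
    mixture of perceived conspicuities at the cohort-average noise SD.
    """
    sbar = noise_scale * float(np.mean(cfg_probe.sigma_reader_range))
    s = float(np.hypot(cfg_probe.sigma_img, sbar))
    mu0, mu1 = cfg_probe.mu_neg, cfg_probe.mu_pos

    def excess(tau: float) -> float:
        rate = (1 - prevalence) * norm.sf((tau - mu0) / s) + prevalence * norm.sf(
            (tau - mu1) / s
        )
        return rate - prevalence

    hi = mu1 + 12 * s
    return float(brentq(excess, mu0 - 12 * s, hi))


def _config(
    noise_scale: float, seed: int, n_images: int, prevalence: float, finding: str
) -> SimulationConfig:
    probe = SimulationConfig(findings=(Finding(finding),), prevalence={finding: prevalence})
    return SimulationConfig(
        findings=(Finding(finding),),
        n_images=n_images,
        prevalence={finding: prevalence},
        noise_scale=noise_scale,
        tau_center=_base_rate_consistent_tau(noise_scale, prevalence, probe),
        detail_vocab={},
        seed=int(seed),
    )


def _rep_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def interpanel_agreement(
    noise_scale: float,
    seed: int,
    n_reps: int = 1,
    n_images: int = 1083,
    prevalence: float = 0.15,
    finding: str = "edema",
) -> tuple[float, float, float]:
    """(mean alpha, sd alpha, mean concordance) of the two arms' majority
    labels over ``n_reps`` independent simulated studies."""
    alphas, concs = [], []
    for s in _rep_seeds(seed, n_reps):
        cfg = _config(noise_scale, s, n_images, prevalence, finding)
        truth = sample_truth(cfg)
        reads = simulate_reads(truth, default_reader_profiles(cfg), cfg)
        pl = aggregate_panel(reads, policy="majority", round=0)
        res = interpanel_alpha(pl, finding)
        alphas.append(res.alpha)
        concs.append(res.percent_agreement)
    a = np.asarray(alphas)
    sd = float(a.std(ddof=1)) if n_reps > 1 else 0.0
    return float(a.mean()), sd, float(np.mean(concs))


def calibrate_noise_scale(
    target_alpha: float = 0.30,
    tol: float = 0.01,
    seed: int = 0,
    n_images: int = 1083,
    prevalence: float = 0.15,
    finding: str = "edema",
    n_cal_reps: int = 4,
    n_eval_reps: int = 20,
    bracket: tuple[float, float] = (0.5, 12.0),
    max_iter: int = 30,
) -> CalibrationResult:
    """Bisection on the reader-noise scale toward a target inter-panel alpha.

    A coarse bisection on ``n_cal_reps`` cheap replicates per probe brings the
    scale near the target; a refinement stage then bisects on the mean alpha
    over the ``n_eval_reps`` measurement replicates themselves, stopping when
    that measured mean lands within ``2 * tol`` of the target (the tuning
    criterion *is* the measured alpha).  The returned agreement and
    concordance figures come from the final measurement replicates.
    """
    cal_seed, eval_seed = (int(s) for s in _rep_seeds(seed, 2))
    lo, hi = bracket
    a_lo, _, _ = interpanel_agreement(lo, cal_seed, n_cal_reps, n_images, prevalence, finding)
    a_hi, _, _ = interpanel_agreement(hi, cal_seed, n_cal_reps, n_images, prevalence, finding)
    if not (a_hi < target_alpha < a_lo):
        raise ValueError(
            f"target alpha {target_alpha} not bracketed: alpha({lo})={a_lo:.3f}, "
            f"alpha({hi})={a_hi:.3f}"
        )
    scale = 0.5 * (lo + hi)
    for _ in range(max_iter):
        scale = 0.5 * (lo + hi)
        a, _, _ = interpanel_agreement(
            scale, cal_seed, n_cal_reps, n_images, prevalence, finding
        )
        if abs(a - target_alpha) <= tol:
            break
        if a > target_alpha:
            lo = scale
        else:
            hi = scale

    # refine on the measurement replicates (a fixed-seed, hence deterministic
    # and monotone objective) until their mean alpha is in-window
    lo, hi = scale / 1.5, scale * 1.5
    mean_a, sd_a, conc = interpanel_agreement(
        scale, eval_seed, n_eval_reps, n_images, prevalence, finding
    )
    for _ in range(10):
        if abs(mean_a - target_alpha) <= 2 * tol:
            break
        if mean_a > target_alpha:
            lo = scale
        else:
            hi = scale
        scale = 0.5 * (lo + hi)
        mean_a, sd_a, conc = interpanel_agreement(
            scale, eval_seed, n_eval_reps, n_images, prevalence, finding
        )
    return CalibrationResult(
        noise_scale=float(scale),
        alpha_mean=mean_a,
        alpha_sd=sd_a,
        concordance_mean=conc,
        n_reps=n_eval_reps,
        n_images=n_images,
    )
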
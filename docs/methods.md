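# Methods

## Problem setting

A reference standard ("ground truth") for chest-radiograph findings is built
by having several radiologists label each image and combining their opinions.
`panelgt` models the canonical two-arm design: two disjoint cohorts of
radiologists (4 and 5 readers), each supplying a random panel of 3 per image,
each panel labelling six binary findings (airspace opacity, cardiomegaly,
pulmonary edema — at least moderate, fracture, nodule, pneumothorax), with an
explicit Hedge option for nodule and pneumothorax. Contested findings are
then discussed in blinded, asynchronous rounds within each panel. Agreement
*between* the two independent arms measures how reproducible each labelling
method is.

## Agreement statistic

Krippendorff's α for nominal data, built from the coincidence matrix.
Units are images (or image × finding keys); each unit contributes its
within-unit ordered label pairs with weight 1/(m−1), m the number of labels
in the unit, so panels of any size and single-reader draws are handled
uniformly. Units with fewer than two labels cannot be paired and are
dropped — provably without effect on α. A dataset in which only one category
is ever observed has zero expected disagreement; α is then *undefined* and
the package raises rather than returning a sentinel, because silent 1.0 or
0.0 values corrupt summary tables of rare findings. Percent agreement is
reported alongside α where the comparison is two aligned label vectors.

Hedge labels are mapped to Present before α (and before voting) by default,
reflecting the clinical weight of an explicit uncertain call; `hedge_as_absent`
and `keep` policies are available for sensitivity analysis. Voting over the
raw 3-level scale is deliberately undefined.

Individual-reader agreement between arms is estimated by drawing one reader
uniformly from each image's panel in each arm, computing α over the resulting
two-label units, and averaging over n = 100 repetitions (mean and SD are both
reported; a draw-free 3×3-pairing average is available as a cross-check).
Resampling uses its own seeded generator so its reproducibility never depends
on data-generation order.

## Reader error model

Each (image, finding) has latent truth T ~ Bernoulli(π_f) and conspicuity
z ~ N(μ_T, σ_img). Reader r perceives y = z + ε, ε ~ N(0, σ_r), and labels
Present if y > τ_r, Hedge if τ_r − δ_r < y ≤ τ_r (hedge-allowed findings),
else Absent. This one mechanism yields the three canonical disagreement
causes: subtle true findings (low z) missed by some readers (*detection*),
spread in τ_r (*thresholding*), and — with a non-identity confusion matrix
over the opacity/edema/nodule channels — misattribution of a detected
abnormality (*classification*). Correlated reader errors enter only through
the shared z; there is no reader–reader correlation beyond it, and the two
arms share nothing but the truth table.

Marginally over image difficulty y ~ N(μ_T, √(σ_img² + σ_r²)), so each
reader's sensitivity and specificity are Gaussian tail integrals
(`reader_operating_point`); the test suite verifies the simulator recovers
them within 3 binomial SEs at n = 10⁴ images.

Cause tags are assigned from the generating mechanism, not inferred from the
labels: classification when a channel reassignment touched the key,
detection when the key is contested, truly positive and z below the
population threshold, thresholding otherwise.

### Default parameters

| parameter | default | meaning |
|---|---|---|
| n_images | 1100 | study size, enriched sample |
| π_f | 0.18/0.15/0.12/0.08/0.12/0.06 | per-finding prevalence (opacity … pneumothorax); ≈ half the images carry ≥ 1 finding |
| μ_neg, μ_pos | 0, 2 | conspicuity means (standardised units) |
| μ_pos overrides | fracture 1.4, nodule 1.4, pneumothorax 1.5 | detection-prone findings sit closer to threshold |
| σ_img | 0.7 | image-difficulty spread (shared across readers/arms) |
| τ_center, τ_spread | 1.0, 0.30 | reader threshold location and heterogeneity |
| σ_r | U(0.4, 0.8) × noise_scale | per-reader, per-finding perceptual noise |
| δ (hedge width) | 0.35 | hedge band below threshold, nodule/pneumothorax only |
| cohorts | 4 and 5 | arm-1 / arm-2 cohort sizes; panels of 3 per image |

These are the study conditions, chosen once: prevalences follow the
600-normal / 500-abnormal enrichment ratio split unevenly across findings;
conspicuity and threshold spreads were set so that individual-reader α lands
in the 0.2–0.55 band typical of subjective radiographic findings.

## Adjudication dynamics

Round 0 is the complete independent read. For each contested
(image, arm, finding) and each subsequent round (cap 2 per arm; arm 1
extends by 3 rounds to probe longer discussion), the contest resolves with
probability ρ_cause — defaults ρ_detection = 0.85, ρ_thresholding = 0.65,
ρ_classification = 0.75, which put most resolution in round 1 and ≈ 88 % of
contests resolved within two rounds. Resolution direction: detection-driven
contests go to Present with weight 0.95 (a flagged subtle finding, once
pointed out, is accepted); thresholding contests follow the latent
conspicuity relative to a panel criterion with weight 0.85; classification
contests follow the channel's truth with weight 0.9; resolutions of
hedge-allowed findings land on Hedge with probability 0.15. The panel
criterion for thresholding carries a per-finding strictness offset (default
+0.6 for edema): discussion converges on a stricter at-least-moderate
severity standard, so borderline edema calls resolve predominantly to
Absent while other findings trend upward. These dynamics parameters are
*uncalibrated* — the underlying study reports no per-cause probabilities —
and are documented here precisely because they are choices, not estimates.

Resolved keys emit a unanimous triple at that round; unresolved keys carry
forward (a missing read in rounds > 0 means "reader kept their previous
label"). The protocol analysis (`run_protocol`) replays the recorded rounds:
a key resolves at the first round whose effective triple is unanimous in
label — and in detail too when detail consensus is required, though detail
mismatches only delay the resolution round, never change the binary label.
Keys still contested at the cap are finalised by majority vote (hedges
counted as Present for the vote) in both arms. Upgrade/downgrade flows are
defined relative to the round-0 modal label among initially contested keys.

## Exclusions

An image is excluded for poor quality when ≥ 2 of its 3 round-0 quality
flags in the designated quality arm (default arm 1) are true; technical
exclusions come from study configuration. Exclusion is idempotent and drops
every read of the excluded image.

## Calibration for rare-finding concordance

To demonstrate the decoupling of α from raw concordance, the calibration
module tunes the global reader-noise scale by bisection until the two arms'
majority labels for a single rare finding (prevalence 0.15, 1083 images)
agree at α = 0.30 ± 0.02, then measures percent concordance over 20 seeded
replicates. Two numerical choices matter. First, thresholds are kept
base-rate-consistent: at every noise level τ is solved (Brent's method on
the Gaussian mixture CDF) so the cohort-average reader's marginal Present
rate equals the prevalence — otherwise raising noise floods the calls with
false positives and the finding is no longer rare *in the labels*, which is
the regime the decoupling claim concerns. Second, the final bisection stage
operates on the mean α of the fixed-seed measurement replicates themselves
(a deterministic, monotone objective), so the reported α is in-window by
construction rather than by luck. Typical outcome: α ≈ 0.29, concordance
≈ 88 %.

## Determinism

Every stochastic component is a pure function of its seed. The simulator
derives independent child streams (truth, profiles, reads, adjudication)
from one `SimulationConfig.seed`, so e.g. changing the number of
adjudication rounds never perturbs the initial reads; resampling and
calibration take their own seeds. Reads files are written with fixed column
order and row sort, making repeated runs byte-identical — asserted in the
test suite.

## What the simulator does and does not show

The generator reproduces the *statistical structure* of a two-arm panel
study: enriched prevalence, reader heterogeneity, difficulty-induced error
correlation, hedge behaviour, cause-structured contention and round-wise
resolution. It does not model report-keyword enrichment from clinical text,
reader fatigue or learning, inter-reader influence beyond the resolution
probabilities, or pixel-level image content. Passing tests therefore
validate the *procedures* (votes, α, protocol, filters) and the qualitative
patterns (panels > individuals; rare-finding α/concordance decoupling), not
any claim about a specific clinical population.

## Problem sizes

Default analyses run 1100 images × 6 findings × 2 arms (≈ 50 k reads,
seconds on one CPU). Parameter-recovery checks use 10⁴ images on one or two
findings; calibration uses 1083 images × 1 finding × (≈ 15 calibration + 20
measurement) replicates, well under a minute.
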
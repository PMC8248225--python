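# panelgt

Tools for building and evaluating **multi-reader reference standards** for
chest-radiograph findings — the "ground truth" labels used to validate
AI models when no objective gold standard exists.

When several board-certified radiologists read the same image they frequently
disagree, so the way their opinions are combined determines how reproducible
the resulting label is. `panelgt` implements and compares the main
combination strategies for a panel of three readers:

- **majority vote** — positive iff ≥ 2 of 3 readers call the finding Present;
- **maximum-sensitivity vote** — positive iff ≥ 1 reader calls it Present
  (aimed at detection tasks such as fractures, where one reader may be the
  only one to spot a subtle finding);
- **adjudicated consensus** — readers iterate through blinded, asynchronous
  discussion rounds on contested findings (up to two rounds, optionally more),
  any residue broken by majority vote.

Agreement between two *independent* panels labelling the same images is
quantified with **Krippendorff's α** for nominal data, computed from scratch
via the coincidence matrix

```
o_ck = Σ_units (# ordered (c,k) label pairs in the unit) / (m_u − 1)
α = 1 − D_o / D_e,   D_o = Σ_{c≠k} o_ck,   D_e = Σ_{c≠k} n_c n_k / (n − 1)
```

which handles a variable number of raters per image (each panel is a random
draw of 3 from a larger cohort). α = 1 means perfect reliability, α ≈ 0
chance level; unlike raw percent agreement it is not inflated by rare
findings, for which two panels can concord on > 85 % of images while α sits
near 0.3.

Because real multi-reader read-outs are rarely shareable, the package ships a
**synthetic reader-panel simulator**: a Gaussian latent-conspicuity threshold
model that generates two-arm, panel-of-three studies with enriched finding
prevalences, per-reader sensitivity/specificity differences, correlated
errors through shared image difficulty, Hedge calls for nodule and
pneumothorax, and round-wise adjudication dynamics. Reader operating points
have closed forms (Gaussian tail integrals) that the simulation provably
recovers, so the whole analysis stack can be exercised and tested end to end.

## Worked example

```python
from panelgt import SimulationConfig, build_report, simulate_study

config = SimulationConfig(seed=7)            # 1100 images, 6 findings, 2 arms
labelset, truth, profiles = simulate_study(config)
report = build_report(labelset, n_reps=100, seed=1)
print(report.agreement.round(2).to_string(index=False))
```

prints

```
         finding  individual  initial_majority  max_sensitivity  adjudicated
airspace_opacity        0.54              0.71             0.56         0.70
    cardiomegaly        0.53              0.70             0.55         0.74
           edema        0.48              0.65             0.54         0.65
        fracture        0.33              0.50             0.45         0.59
          nodule        0.37              0.54             0.45         0.62
    pneumothorax        0.41              0.59             0.50         0.66
```

Each number is the inter-arm Krippendorff's α of one labelling method
(`individual` = a random single reader per arm, averaged over 100 draws;
the rest aggregate the full panel). Panels beat individuals for every
finding, and adjudication adds further reproducibility for most — the core
argument for panel-based, adjudicated reference standards.

The `examples/` scripts walk through one capability each: study simulation
and reporting, adjudication round dynamics, the α-vs-concordance decoupling
for rare findings, and reads-file round-tripping with quality exclusions.

A thin CLI mirrors the library for shell pipelines:

```bash
panelgt simulate --seed 7 --out out/
panelgt adjudicate --reads out/reads.csv --max-rounds 2 --out out/
panelgt agree --reads out/reads.csv --method panel --out agree.tsv
panelgt report --reads out/reads.csv --out report/
```

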
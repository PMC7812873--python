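# sgpartition

Valency-based modelling of RNA partitioning into stress granules.

Stress granules (SGs) are cytoplasmic condensates of untranslating
mRNPs. Why some transcripts concentrate in them while others stay out
is well described by a *summation-of-interactions* picture: each RNA
makes some number of independent contacts with the granule network —
through bound proteins such as G3BP1, TIA1 or Pumilio, and through
RNA–RNA interactions — and its equilibrium partitioning is set by the
sum of those contact energies. `sgpartition` turns that picture into a
quantitative, testable pipeline:

* **Model.** The percent of a transcript's cytoplasmic molecules inside
  granules follows a saturating power law of its total contact number
  x = k + n (k engineered tether sites, n baseline contacts of the
  unmodified reporter):

      E(x) = c · x^p,   capped at 100%

  fitted on log–log axes to per-construct median enrichments from
  tethering (λN/BoxB) dose series. The baseline valency n is selected by
  scanning n = 1..10 and keeping the best linearized Pearson r. The
  fitted curve is invertible — a measured granule fraction becomes a
  ballpark interaction count x = (E/c)^(1/p) — and supports perturbation
  arithmetic (what happens when one contact is lost) and an equivalent
  two-state thermodynamic form A·e^(kδg)/(1 + A·e^(kδg)).
* **Quantification.** Per-cell fraction-in-granule statistics from
  smFISH spot tables, boxplot summaries per construct, and two-sided
  rank-sum comparisons with figure-legend star categories.
* **Sequence analysis.** IUPAC motif scanning (AU-rich elements AUUUA,
  Pumilio recognition elements UGUANAUA, arbitrary patterns),
  half/quarter/eighth fragmentation, antisense, and site-sum enrichment
  prediction.
* **Sequencing scores.** log2 granule/total CPM enrichment from
  two-compartment count tables, cross-condition correlation,
  length-binned deltas, and external covariate (e.g. CLIP peak count)
  correlations.
* **Synthetic data.** Seeded generators for all of the above with known
  ground truth, so every stage is testable without any external data.

Intended for quantitative RNA biologists studying condensate
recruitment, and as a reference implementation of the partition-curve
analysis for tethering experiments.

## Worked example

```python
from sgpartition import (paper_calibrated_curve, predict_enrichment,
                         estimate_interactions, delta_enrichment)

curve = paper_calibrated_curve()   # through (x=2, 14%) and (x=27, 62%)
print(f"E(x) = {curve.c:.3f} * x^{curve.p:.4f}")
print(f"E(26) = {predict_enrichment(curve, 26):.2f}%")
print(f"E(3)  = {predict_enrichment(curve, 3):.2f}%")
print(f"x(50%) = {estimate_interactions(curve, 50):.1f} contacts")
print(f"x(20%) = {estimate_interactions(curve, 20):.1f} contacts")
```

prints

```
E(x) = 9.419 * x^0.5717
E(26) = 60.68%
E(3)  = 17.65%
x(50%) = 18.5 contacts
x(20%) = 3.7 contacts
```

Read: a reporter making 27 granule contacts sits at 62% in granules and
loses only ~1.3 points when one contact is removed (62% → 61% after
rounding), while a 3-contact mRNP drops from ~18% to 14% — high-valency
transcripts are buffered against losing any single interaction. A
transcript that is >50% granule-localized implies more than 15
contacts; one below 20% implies roughly one to five.

The `examples/` directory holds one narrative script per capability
(`perturbation_predictions.py`, `fit_baseline_valency.py`,
`motif_scanning.py`, `sgseq_enrichment.py`), and a thin CLI wraps the
library:

```bash
sgpartition run --config examples/demo_config.yaml   # full pipeline
sgpartition predict --at 27 --remove 1
sgpartition invert --enrichment 50
sgpartition scan transcripts.fasta --scheme quarters
```

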
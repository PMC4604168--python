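# synscape

Analysis of large fixed-ratio drug-combination screens in cancer cell-line
panels: Bliss-independence synergy scoring, synthetic-lethality and
synergy-breadth calling, apoptosis (cleaved-PARP) outlier detection with
death-kinetics classification, SAM-style differential synergy for cell-line
subgroups, and Chou–Talalay combination-index analysis of secondary
dose-response assays.

## Who this is for

High-throughput screens that test every unordered pair from a drug panel
across a cell-line collection cannot afford full dose matrices; they use one
or two fixed-ratio dose points per pair and two per-well readouts — cell
count ("viability") and the fraction of cleaved-PARP-positive nuclei
("cPARP"), both as percent of the DMSO control. At full scale (a 108-drug
panel, 5,778 pairs, 36 melanoma lines, two concentration tiers) that is
416,016 combination wells and over 800,000 combination data points per
readout pass. `synscape` turns such a matrix into scored, flagged, testable
results, and ships a ground-truthed synthetic-screen generator so every
stage can be validated without external data.

## The statistics at the core

**Bliss synergy.** Under independence two non-interacting drugs leave a
surviving fraction equal to the product of their single-agent fractions, so
for each (pair, line, tier)

```
Bliss score = 100 · (v_a · v_b − v_ab)        [percent points]
```

positive for synergistic killing. Hits use a strict threshold (default
\> 40 points). *Synthetic lethality* is the extreme case where both singles
are inert (> 80% viability) yet the combination falls below 50%; the
reported rate is the fraction of synergy hits that qualify. *Breadth* is
the number of lines in which a pair is a hit — most real synergies are
private to a few lines.

**Apoptosis outliers.** Per cell line, cPARP is regressed on viability with
two candidate families, `f(x) = a·exp(−x/τ)` and `f(x) = a·x + τ`, the
winner chosen by Pearson correlation between fitted and observed values.
Combinations whose residuals sit significantly above the line's fit
(one-sided Welch t-test, or a robust z-score for single wells) are
"unexpectedly apoptotic"; those keeping > 80% viability while cPARP rises
are labelled *slow* death kinetics. Flagged pairs form a drug network
(GraphML export).

**Differential synergy.** For a two-class line partition (e.g.
BRAF-inhibitor-resistant vs sensitive), each combination gets a moderated
statistic `d = (mean_A − mean_B)/(s + s0)` with permutation-estimated
q-values (exhaustive label enumeration when feasible).

**Combination index.** Secondary fixed-ratio titrations are fitted with the
four-parameter logistic on log-dose; at affected fraction `f`,
`CI = d1/D1 + d2/D2` (< 1 synergy, 1 additivity). Isobologram coordinates
and IC50-shift vs E_max-boost classification come from the same fits.

## Worked example

Simulate a 20-drug × 8-line screen with a planted synergy landscape, score
it, and call apoptosis outliers:

```bash
$ printf 'n_drugs: 20\nn_lines: 8\n' > sim.yaml
$ synscape simulate --config sim.yaml --seed 11 --out screen.csv --truth truth.json
INFO synscape: wrote 3376 measurement rows to screen.csv
$ synscape synergy --input screen.csv --threshold 40 --out synergy.csv --breadth breadth.csv
INFO synscape: scored 3040 combinations: 110 synergy hits, 40 synthetic lethal
$ synscape apoptosis --input screen.csv --adjust bh --out calls.csv --graph net.graphml
INFO synscape: tested 3040 combinations; 108 flagged (3.55%)
$ synscape report --run-dir .
synscape 1.0.0 run summary: .
- calls.csv: 3040 tested combinations, 108 unexpectedly apoptotic (3.55%)
- synergy.csv: 3040 scored combinations, 110 synergy hits, 40 synthetic lethal
```

The 3,040 combinations are the 190 pairs × 8 lines × 2 tiers; the 110 hits
are dominated by the generator's planted events (including a broad
MDR-inhibitor-like sensitizer), and the 3.55% apoptosis-outlier rate
reflects the 4% of combination wells planted with a +4 SD cPARP shift,
recovered through the per-line dual regression. `breadth.csv` tabulates how
many lines each synergistic pair covers (most in ≤ 3 lines). The same
operations are available as a library:

```python
import synscape as syn

dataset, truth = syn.generate_screen(syn.SimulationConfig(n_drugs=20, n_lines=8, seed=11))
scores = syn.score_dataset(dataset)                 # one row per (pair, line, tier)
calls = syn.call_dataset(dataset, adjust="bh")      # apoptosis outlier calls
print(syn.headline_summary(dataset))                # screen-level percentages
```

## Data formats

* **Long CSV/TSV** — `line_id, drug_a, drug_b, tier, replicate,
  viability_pct, cparp_pct`; single agents leave `drug_b` blank, DMSO
  controls leave both drug columns blank.
* **Wide XLSX** — one sheet per readout and tier (combination rows ×
  cell-line columns) plus drug/line metadata sheets, mirroring the usual
  supplementary-table layout; stored Bliss blocks are cross-checked against
  recomputation on import, never trusted.
* Outputs: scored CSVs, GraphML networks, JSON ground truth / CI reports,
  and a `manifest.json` (inputs, digests, seed, version) per run directory.
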
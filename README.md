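# fetbead

Analysis toolkit for **single-replicate Illumina BeadChip knockdown
experiments**, built around the six-array siRNA design used to compare the
FET-family RNA/DNA-binding proteins (FUS, EWS/EWSR1, TAF15): three single
knockdowns, one triple knockdown, and two siRNA-concentration-matched
controls, with one array per condition.

With *n* = 1 per condition there is no within-condition variance, so the
toolkit implements the fold-change-plus-detection rule appropriate to that
design, together with the surrounding comparison machinery:

- **Preprocessing** — quantile normalization across arrays; removal of
  probes not detected (detection p ≥ 0.05) on any array; background
  estimation as the mean of the negative-control probe intensities pooled
  over all arrays.
- **DEG calling** — background-subtracted expression ratio
  `ratio = (siA_RI − b) / (ctrlA_RI − b)` with background constant `b`;
  a probe is *up* if `ratio > 2` and the treated-array detection p < 0.05,
  *down* if `ratio < 0.5` and the control-array detection p < 0.05.
- **Set analysis** — exact Venn partition of 2–4 DEG sets, comparison of
  single-knockdown DEG regions against a combined knockdown, and a
  one-sided hypergeometric overlap test
  `p = P(X ≥ k)`, `X ~ Hypergeom(N, m, n)` against external gene lists.
- **Multiscale-bootstrap clustering** — SD-based gene selection, average
  linkage on `d = 1 − r` (Pearson) between arrays, and per-cluster support
  values via the multiscale bootstrap: appearance fractions `BP_r` at
  resample scales r = 0.5 … 1.4 are probit-transformed and fitted to
  `z_r = v√r + c/√r`, giving `AU = 1 − Φ(v − c)` and `BP = 1 − Φ(v + c)`.
- **qPCR quantification** — efficiency-corrected X0 method
  (`X0 = E^(−Cq)`), reference-gene normalization, and fold change versus a
  control sample; equal to classic `2^(−ΔΔCq)` at perfect efficiency.
- **Synthetic data** — a generator that emulates the six-array design with
  log-normal baselines, negative-control probes whose mean defines the
  background, and planted shared/unique knockdown effects with known
  ground truth, so every stage is testable without any download.

## Worked example

```python
import numpy as np
from fetbead import (
    SimulationConfig, simulate_experiment, run_deg_pipeline,
    sd_select, multiscale_bootstrap, MultiscaleConfig, to_newick,
    venn_partition, enrichment_test,
)

config = SimulationConfig(n_probes=5000, n_negative_controls=400, seed=1)
table, truth = simulate_experiment(config)

result = run_deg_pipeline(table)
print(f"background = {result.background.reported}")
print(f"removed {result.removed_count} of {config.n_regular} regular probes")
for name, deg_table in result.deg_tables.items():
    print(f"{name}: {deg_table.n_up} up, {deg_table.n_down} down")

sets = {g: result.deg_tables[f"{g}_vs_control"].deg_ids()
        for g in ("siFUS", "siEWS", "siTAF15")}
core = venn_partition(sets).get(frozenset(sets), set())
print(f"DEGs shared by all three knockdowns: {len(core)}")

enr = enrichment_test(sets["siFUS"], sets["siTAF15"], result.matrix.n_probes)
print(f"siFUS/siTAF15 overlap: k={enr.k}, expected {enr.expected:.1f}, "
      f"p = {enr.p_value:.3g}")

selected = sd_select(np.log2(result.matrix.data + 1.0), top_k=300)
tree = multiscale_bootstrap(selected, MultiscaleConfig(replicates=200, seed=1))
print(to_newick(tree))
```

Output:

```
background = 28
removed 1682 of 4600 regular probes
siFUS_vs_control: 23 up, 36 down
siEWS_vs_control: 29 up, 38 down
siTAF15_vs_control: 26 up, 27 down
siTriple_vs_control: 185 up, 243 down
DEGs shared by all three knockdowns: 5
siFUS/siTAF15 overlap: k=8, expected 1.1, p = 7.5e-06
(siTriple:1.0588,(siFUS:0.197777,(siTAF15:0.177903,(siEWS:0.143038,(controlPlus:0.015934,controlTriplePlus:0.015934)100|100:0.127104)60|42:0.0348655)60|42:0.0198738)100|100:0.861021)100|100;
```

Reading the output: the background constant recovered from the
negative-control probes is 28; ~37% of regular probes are undetected on
every array and removed; each single knockdown yields a few dozen DEGs
(planted effects plus the single-replicate false positives that motivate
the strict rule) while the triple knockdown — whose planted effect set is
by construction dominated by triple-unique responses — yields far more.
The siFUS/siTAF15 DEG overlap of 8 probes is ~7-fold enriched over the 1.1
expected by chance. In the Newick tree, internal node labels are `AU|BP`
support percentages; the two control arrays form a maximally supported
cluster (`100|100`).

Every subcommand is also exposed on the command line — see
`fetbead --help` (`simulate`, `normalize`, `filter`, `background`, `deg`,
`venn`, `overlap`, `cluster`, `qpcr`).

## Data formats

Probe profiles are tab-delimited UTF-8 with columns `PROBE_ID`,
`PROBE_CLASS` (`regular` / `negative_control`), then per sample
`<id>.AVG_Signal` and `<id>.Detection_Pval` — the layout of an Illumina
sample-probe-profile export. Gene lists are one identifier per line;
dendrograms are exported as Newick with `AU|BP` internal labels. A
matrix exported from a GEO deposit of this layout can be analyzed directly
after renaming its columns to this convention.
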
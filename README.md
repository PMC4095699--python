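# somascape

Ploidy-adaptive somatic copy-number landscape and mutation-spectrum analysis,
packaged as a tested, reusable pipeline:

* **Synthetic cohorts** (`somascape.synthetic`) — allele-specific segmented
  copy-number profiles with planted whole-arm events ("sawtooth" archetype:
  8p−/8q+/16p−/16q+) or focal high-level amplicons ("firestorm" archetype:
  8q/17q/20q amplicons, 17p loss) on near-diploid/near-tetraploid backgrounds,
  plus candidate-variant tables and copy-number-coupled expression matrices —
  all with ground-truth manifests.
* **Alteration calling** (`somascape.calling`) — ploidy classification,
  discrete LOSS/NEUTRAL/GAIN/AMP calls with ploidy-adaptive cutoffs
  (near-diploid ≤1 / ≥3 / ≥6; near-tetraploid ≤2 / ≥6 / ≥8), LOH and
  homozygous-deletion flags, breakpoint counting.
* **Recurrence landscape** (`somascape.recurrence`) — cohort frequency
  profiles, recurrent minimal regions (maximal runs of ≥25 consecutive probes
  with event frequency strictly >20%, both configurable), minimal common
  regions, and group-vs-group frequency contrasts.
* **Genomic subsets** (`somascape.clustering`) — ordinal state encoding and
  Ward/Euclidean hierarchical clustering with flat-k and height cuts, plus
  per-subset characterisation.
* **Variant pipeline** (`somascape.variants`) — exact Fisher 2×2 test
  (integer arithmetic, no approximation), the five-criterion somatic filter
  (p < 0.05, coverage ≥10×, base quality ≥20, VAF ≥20%, high-quality alt
  reads ≥4), prioritisation rules, codon-level effect and
  transition/transversion classification, deleteriousness scoring
  (PolyPhen-2 > 0.5 OR GERP > 4), and spectrum summaries.  A curated
  36-variant mutation catalogue ships as a checksummed package fixture.
* **Expression integration** (`somascape.expression`) — Pearson
  copy-number/expression gating (r > 0.4, p ≤ 0.05), Welch
  underexpression test with a ≥1.5 fold-change rule, and ΔCt qPCR relative
  expression.
* **IO + CLI** (`somascape.io`, `somascape.cli`) — headered TSV everywhere
  (SEG-like profiles, status matrices, BED-style regions, variant and
  expression tables), a VCF-subset reader, YAML run configuration with
  strict key checking.

## CLI

```bash
somascape simulate --out-dir run --seed 1            # synthetic cohort
somascape call --seg run/cohort.seg.tsv --out-prefix run/status
somascape recur --states run/status.states.tsv --event amp --out run/regions.tsv
somascape cluster --states run/status.states.tsv --k 2 --out-labels run/labels.tsv
somascape variants --input run/variants.tsv --out run/verdicts.tsv
somascape integrate --seg run/cohort.seg.tsv --expr run/expression.tsv \
    --loci run/loci.tsv --out run/correlation.tsv
somascape report --out run/summary.tsv               # packaged catalogue summary
```

Every subcommand accepts `--config config.yaml` (see `somascape.io.RunConfig`
for the recognised keys); unknown keys are rejected.

## Coordinate conventions

On-disk genomic coordinates are 1-based inclusive.  In memory, segments are
half-open `[start, end)` on the same axis, so a probe at position `p` lies in
the segment with `start <= p < end`.
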
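# okmap

Replication-origin mapping from Okazaki-fragment sequencing (OK-seq), with
the downstream origin-chromatin and origin-transcription analyses used to
study DNA replication in developing embryos.

## The problem

When DNA ligase I is depleted, Okazaki fragments — the short products of
lagging-strand synthesis — accumulate and can be sequenced strand-specifically.
Because the lagging strand is always the one *behind* the fork, the mapped
strand of each fragment reveals the local replication-fork direction:
Watson-strand (`+`) fragments come from leftward-moving forks, Crick-strand
(`-`) fragments from rightward-moving forks. A replication origin is
therefore visible as a transition from Watson-dominated to Crick-dominated
coverage, and the sharpness and amplitude of that transition carry the
origin's initiation-zone width and firing efficiency.

`okmap` implements that inference as a tested pipeline:

* **origin calling** — stranded fragments are binned (100 bp), partially
  smoothed with a 1.5 kb sliding median, normalized per bin so
  f<sub>W</sub> + f<sub>C</sub> = 1, and scanned with an
  origin-efficiency-metric (OEM)-style statistic

  &nbsp;&nbsp;&nbsp;&nbsp;M(b) = F<sub>W</sub>(left 12 kb) − F<sub>W</sub>(right 12 kb),

  whose local maxima above a threshold are origin calls;
* **per-origin annotation** — efficiency (the likelihood the origin fires
  during S phase) and transition-zone width (the distance between the
  flanking Watson and Crick normalized maxima);
* **chromatin association** — distances and analytic uniform-placement
  p-values between enhancer-mark ChIP peaks (> 5-fold enrichment) and the
  5 kb origin blocks, plus mark-level versus efficiency scaling;
* **gene context** — strand-orientation bias of origin-flanking genes
  (replication-transcription co-directionality) and positional gene-set
  enrichment with exact hypergeometric tails;
* **transcriptome coupling** — maternal/zygotic partitioning of a
  50-time-point embryonic expression course and the origin-relative
  stacking of zygotic transcription, summarized as a per-time-point
  log2 proximal/distal coupling statistic;
* **a stochastic replication simulator** — per-cell origin firing with
  known probabilities, bidirectional forks, nucleosome-periodic fragment
  lengths, efficiency-scaled ChIP peaks and a coupled expression course —
  so every stage is validated by parameter recovery against ground truth,
  including an exact closed-form oracle for the expected strand bias at any
  position.

## Worked example

```python
from okmap import simulate, io, origins
from okmap.config import RunConfig
from okmap.pipeline import call_origins_from_track

model = simulate.default_model(seed=1)          # 2 x 5 Mb, 250 origins, beta(2,2)
frags = simulate.simulate_fragments(model, n_cells=2000,
                                    fragments_per_cell=500, seed=2)
track = io.bin_fragments(frags, model.chrom_sizes)
calls, _ = call_origins_from_track(track, RunConfig())

stats = origins.spacing_stats(calls)
recovery = simulate.score_recovery(calls, model)
```

which reports:

```
origins called:        214 (of 250 simulated)
median spacing:        44.5 kb
within 100 kb:         100.0%
recall (e>=0.5, isolated): 1.00
false-call rate:       0.000
median position error: 114 bp
duplication time at 75 kb spacing, 2.5 kb/min: 15 min
```

All 73 well-resolved efficient origins (firing probability ≥ 0.5, nearest
neighbour ≥ 30 kb) are recovered, with no false calls and a median midpoint
error of ~one bin; the 36 missed origins are weak (low firing probability)
or merged with a close neighbour. The last line is the analytic
duplication-time bound `replication_time(spacing, fork_speed) =
spacing / (2 · speed)`: two converging forks at 2.5 kb/min close a 75 kb
inter-origin gap in 15 minutes, the classic back-of-envelope for rapid
embryonic S phases.

The same stages are exposed on the command line:

```
okmap simulate --outdir sim/
okmap call --fragments sim/fragments.bed --chrom-sizes sim/genome.chrom.sizes --outdir called/
okmap assoc --origins called/origins.bed --peaks sim/peaks.narrowPeak \
            --chrom-sizes sim/genome.chrom.sizes --out assoc.tsv
okmap timecourse --expression sim/timecourse.tsv --origins called/origins.bed --outdir tc/
okmap replication-time --spacing-kb 75 --fork-speed 2.5
```

Every output directory carries a JSON sidecar with the full configuration,
its hash, and the seeds, so runs are exactly reproducible.

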
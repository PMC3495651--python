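# covote

Vote-counting co-expression maps and guilt-by-association candidate gene
ranking for multi-condition expression compendia.

Given many expression datasets (genes × samples, each with a sample →
condition map), `covote`:

1. applies dataset-level QC — conditional log2 transform, value-range
   filters, probe-annotation coverage, replicate averaging with a
   missing-value policy;
2. compares every pair of conditions within each dataset, calling a gene
   differentially expressed at a 2-fold (1 log2 unit, inclusive) change;
3. accumulates, over the whole corpus, how often each gene voted (`Q`),
   how often each gene *pair* voted in the same direction (`N`, symmetric),
   and the total number of comparisons (`x`);
4. derives per-gene "friend" lists — the top 5% of other genes by N:Q
   ratio — and each gene's global occurrence probability across all lists;
5. scores every gene against a user seed list with the right tail of a
   binomial: `k` = number of seed genes whose friend lists contain the
   candidate, `n` = effective seed size, `p` = occurrences/G; genes with
   p-value < 1e-6 are flagged, with a randomization test to calibrate that
   cutoff, plus optional filtering to transcription factors and export of
   the ratio-thresholded co-expression network.

A synthetic corpus generator with planted co-regulated modules provides
ground truth for every stage, so the whole pipeline is testable offline.

## Command line

Each subcommand consumes/produces plain-text artifacts so stages can be run
independently:

```sh
# make a synthetic corpus with one planted 12-gene module
covote simulate --out corpus --genes 300 --datasets 20 --module-size 12 --rng-seed 1

# build the vote map (N, Q, x) over the universe
covote build-map --manifest corpus/manifest.tsv --universe corpus/universe.txt \
    --out map.npz --qc-log qc.tsv

# inspect one gene's friends; rank all genes against a seed list
covote friends --map map.npz --gene G000001
covote gba --map map.npz --seed seeds.txt --out ranked.tsv

# transcription-factor subset, thresholded network, null calibration
covote tfs --gba ranked.tsv --tf-list tfs.txt --out ranked_tfs.tsv
covote network --map map.npz --cutoff 0.8 --out edges.tsv
covote calibrate --map map.npz --seed-size 20 --replicates 10 --rng-seed 0 --out cal.tsv

# or everything in one shot (writes run metadata + input digests)
covote run --manifest corpus/manifest.tsv --universe corpus/universe.txt \
    --seed seeds.txt --out results/
```

Input formats: expression matrices are TSV with a `gene` + sample-id header
(empty/`NA` cells = missing); condition maps and probe maps are 2-column
TSV; gene lists (seed, TF, universe) are one symbol per line with `#`
comments; the corpus manifest is a TSV of
`dataset_id, expression_path, condition_map_path[, probe_map_path]`.

## Friend-ranking orientation

Friend lists are ranked by an N:Q ratio with two orientations
(`--orientation`, config key `ratio_orientation`):

* `self` (default): candidate g is ranked by `N(g,s)/Q(g)` — its co-votes
  with s normalized by its *own* differential activity. Globally busy genes
  must co-move specifically with s to rank highly.
* `partner`: ranked by `N(g,s)/Q(s)`, which is rank-equivalent to raw
  `N(g,s)` and lets globally active genes crowd every list.

`self` is the default because with it the binomial occurrence correction
behaves as intended: planted co-regulated modules are recoverable by
seeding, while under `partner` a strongly co-active module saturates every
friend list and cancels itself out of the statistics.

## Layout

```
src/covote/io.py          TSV readers/writers, probe collapsing, gene lists
src/covote/preprocess.py  log transform, QC filters, replicate averaging
src/covote/votemap.py     vote counting (N, Q, x), ratios, friends, network
src/covote/gba.py         binomial tail, seed ranking, TF filter, calibration
src/covote/synthetic.py   planted-module corpus generator
src/covote/config.py      run configuration (flat key=value files)
src/covote/pipeline.py    end-to-end orchestration + run metadata
src/covote/cli.py         click CLI
tests/                    unit + property tests, tests/test_acceptance.py
scripts/acceptance.py     acceptance report
```
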
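# profalign

In-silico alignment of complexome-profiling gel lanes and rank-ordered
case/control effect sizes.

Complexome profiling yields, per sample, a protein × gel-slice intensity
matrix (e.g. iBAQ values). Gel-to-gel migration shifts make direct
comparison unreliable. `profalign`:

1. harmonizes samples onto a shared protein roster (union, zero fill) and
   sum-equalizes intensities across samples;
2. aligns lanes pairwise with **multi-dimensional dynamic time warping**
   — the local cost between two slices is the summed absolute intensity
   difference over all proteins, and the global cost carries no gap
   penalty;
3. builds a **single-linkage guide tree** from all pairwise global costs
   and merges the lanes by **progressive alignment** (aligning alignments
   with the average cross-pair local cost); gaps are realized by repeating
   the preceding slice;
4. quantifies per-protein differences between the aligned migration
   curves with the symmetric **Hausdorff distance** on a rescaled
   (slice, intensity) plane (the per-protein intensity maximum is scaled
   to `weight × alignment length`; `weight=1` gives a square plane,
   `weight=0.25` up-weights migration shifts 4-fold);
5. ranks proteins by the **Hausdorff effect size** — mean between-group
   distance divided by mean within-group distance — and exports a `.rnk`
   file for preranked gene-set enrichment analysis, plus a leading-edge
   style per-complex rank summary.

A synthetic-data module generates studies with known ground truth (peaks,
gel warps, injected case effects), so the whole pipeline is testable
without external data.

## CLI

Generate a synthetic study (9 profile CSVs, group file, ground truth):

```sh
profalign synth --scenario default --seed 17 --out study/
```

Align profiles (CSV/TSV/XLSX; one id column, slice columns in file order):

```sh
profalign align study/case_*.csv study/ctrl_*.csv --out aligned/ \
    [--subset ids.txt] [--gene-column gene] [--format csv|xlsx]
```

writes `aligned_<sample>.csv` (warped matrices on the common axis),
`insertions.csv` (1-based gap positions per sample), `cost_matrix.csv`,
`guide_tree.newick`, `normalization.csv` and a `manifest.json`.

Compare groups on an alignment:

```sh
profalign compare --alignment aligned/ --groups study/groups.tsv \
    [--weight 1.0] [--gene-sets sets.gmt] [--top-k 50]
```

writes `distance_table.csv`, `effect_sizes.csv`, `ranked.rnk` (+
`ranked_excluded.txt` for all-zero proteins) and, with `--gene-sets`,
`leading_edge.csv`. Group files are two-column `sample<TAB>case|control`;
gene sets are GMT or two-column files.

All outputs are deterministic: identical inputs give byte-identical text
outputs.

## Conventions

- Slice indices are 0-based internally, 1-based in every written report.
- Empty cells read as 0; explicit `NaN` spellings read as 0 with a logged
  warning; any other non-numeric cell is an error.
- Proteins absent from a sample are zero-filled, so presence/absence
  differences contribute to the alignment cost.
- DTW tie-breaks prefer the diagonal move, then a gap in the second
  argument; guide-tree ties are broken by smallest sample index.
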
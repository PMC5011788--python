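# codemlbatch

Batch preparation, scheduling, harvesting and statistical comparison of
PAML **codeml** codon-substitution-model analyses, for molecular
evolutionists who test for selection across many genes at once.

Detecting positive selection with codeml means fitting nested pairs of
codon models — site models (M0, M1a, M2a, M3, M7, M8, M8a), branch models
(M0, two-ratio constrained/unconstrained), branch-site model A, and clade
model C — to every gene/tree combination, then comparing each pair with a
likelihood-ratio test:

```
2ΔlnL = 2 (lnL_alt − lnL_null)  ~  χ²(df),   df = np_alt − np_null
```

where `lnL` and `np` are the maximized log-likelihood and free-parameter
count codeml reports, and ω = dN/dS > 1 indicates positive selection.
Doing this by hand for dozens of genes × nine model configurations × a grid
of starting values means thousands of control files, directories and result
files. `codemlbatch` automates the whole loop:

1. **identity** — filenames encode the routing: `ATP6_sbwc1.fas` is gene
   ATP6, analysed under **s**ite, **b**ranch, branch-site (**w**) and
   **c**lade models with genetic code 1; trees are `ATP6_s.nwk` (site
   models) or `<hypothesis>_wbc.nwk` (branch-related, carrying PAML `#N` /
   `$N` labels). MSAs and trees pair on every shared letter.
2. **treelab** — numbered text cladogram for labeling foreground branches
   (`#N`) and clades (`$N`), with per-family validation (branch-site models
   need exactly two partitions, clade models at least two, site models an
   unlabeled tree).
3. **templates / scaffold** — nine codeml control-file templates
   (2 site, 3 branch, 2 branch-site, 2 clade) instantiated per dataset and
   per kappa/omega starting point (grid defaults 0.5/2/4 × 0.2/1/2 to escape
   local optima), laid out in a path-parseable directory structure.
4. **runner** — FIFO scheduler with a hard concurrency bound (`-n`, or
   auto-estimated as total cores minus load average), live status, group or
   single-task termination, resume of unfinished tasks, and an optional
   completion notification.
5. **extract / lrt_tables** — parses every result file (lnL, np, kappa,
   omegas, site-class proportions, Bayes Empirical Bayes sites) into one CSV
   per model family, and the `plrt` command pairs null/alternative rows and
   appends the five LRT columns: comparison, deltaLnL, df, p-value,
   conclusion (H0/H1).

A fixtures module generates alignments, trees and codeml-format output —
plus a mock codeml executable — so everything is testable with no external
binary; point the runner at a real `codeml` (PAML ≥ 4.6) for production use.

## Worked example

```
$ codemlbatch example-data -d data --seed 0
wrote 4 genes under data

$ codemlbatch pipeline -A data/msas -T data/trees -d . -j demo_results \
      -m "s[0:1:2:3:7:8:8a],b,c,w" -n 4 -K 2 -O 0.5 --mock
pairs: 16  tasks: 36  status: {'pending': 0, 'running': 0, 'done': 36, 'failed': 0}
results: ./demo_results/results_b.csv
...
lrt: ./demo_results/lrt_b.csv
```

The 4 genes × (1 site tree + 3 hypothesis trees) give 16 dataset pairs; the
applicable templates at one grid point give 36 codeml tasks, all run (here
by the mock). A row of `lrt_b.csv`:

```
...,G1,H2,b,BM-TrU,2.0,0.5,TrU,-8412.1,13,9,4.274856,branch0=0.386348;branch1=0.703020,...,M0vTrU,16.000000,1,6.33425e-05,H1
```

reads: for gene G1 under hypothesis H2, the free two-ratio branch model
(TrU, lnL −8412.1, np 13) beats the one-ratio null by 2ΔlnL = 16.0 on
1 df (p ≈ 6.3 × 10⁻⁵), so the alternative is accepted (H1) at α = 0.05 —
the foreground branch evolves under a different ω than the background.

Omit `--mock` (and optionally pass `--codeml /path/to/codeml`) to run the
real program; the subcommands `scaffold`, `ctledit`, `run`, `extract` and
`tables` expose each stage separately, including `tables --interactive` for
sorting/hiding/selecting rows and issuing `plrt 0.05` by hand.

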
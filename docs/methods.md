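# Methods

## The statistical procedure

codeml estimates, by maximum likelihood, the parameters of codon
substitution models in which the nonsynonymous/synonymous rate ratio
ω = dN/dS measures selective pressure (ω < 1 purifying, ω = 1 neutral,
ω > 1 positive selection). Evidence for selection comes from comparing a
null model against a nested alternative with the likelihood-ratio
statistic 2ΔlnL = 2(lnL_alt − lnL_null), referred to a chi-square
distribution whose degrees of freedom equal the difference in free
parameters (np) between the fits. The package tests eight canonical
pairings:

| family      | null    | alternative | what the alternative adds            |
|-------------|---------|-------------|--------------------------------------|
| site        | M0      | M3          | among-site ω variation               |
| site        | M1a     | M2a         | a site class with ω > 1              |
| site        | M7      | M8          | a site class with ω > 1 (beta null)  |
| site        | M8a     | M8          | ω of the extra class free vs = 1     |
| branch      | M0      | TrU         | a second ω on foreground branches    |
| branch      | TrC     | TrU         | foreground ω free vs fixed at 1      |
| branch-site | MA1     | MA          | positive selection on the foreground |
| clade       | M2a_rel | CmC         | divergent ω among clades             |

When an alternative with an ω > 1 class is significant, the Bayes
Empirical Bayes (BEB) posterior identifies the individual sites; the
harvester extracts every listed site with its posterior probability and
applies no cutoff — filtering is a table operation downstream.

## Template parameterizations

The nine control-file templates follow the PAML documentation's standard
encodings: site models run as `model = 0` with a multi-valued `NSsites`
(one execution fits all selected site models except M8a, which needs its
own run with `NSsites = 8, fix_omega = 1, omega = 1`); branch models as
`model = 2` (with `fix_omega = 1, omega = 1` for the constrained
two-ratio); branch-site model A as `model = 2, NSsites = 2` (A1 with ω₂
fixed at 1); clade model C as `model = 3, NSsites = 2` and its M2a_rel
null as `NSsites = 22`. Dataset-dependent keys (seqfile, treefile, icode,
NSsites, kappa, omega) are filled at instantiation; all other keys carry
documented defaults and are batch-editable afterwards (`ctledit`), which
never touches the templates themselves.

Because maximum-likelihood surfaces of these models have local optima,
each dataset can be launched from a grid of kappa × omega starting values;
the defaults {0.5, 2, 4} × {0.2, 1, 2} straddle ω = 1 and the plausible
kappa range so that at least one start lies on each side of the neutral
ridge. Templates that fix ω = 1 ignore the grid ω (logged, not an error),
since the constraint is the model.

## Tree labeling

PAML marks branch partitions in the Newick string: `#N` on a single branch,
`$N` on a clade (the label stays on the subtree root; expansion to member
branches is codeml's own semantics). Partition numbers must be dense
(1..N), so removal renumbers the remainder. Node ids are assigned in
post-order, which makes them stable across write/parse cycles; the
cladogram renderer prints exactly the addressable ids. Family-specific
validation enforces: site models an unlabeled tree, branch-site models
exactly two partitions, branch and clade models at least two. Trees are
taken as rooted as written; no rerooting is offered.

## Scheduling

One task = one codeml process = one core. The bound is either explicit
(`-n`) or estimated once at launch as `floor(total cores − 1-minute load
average)`, clamped to [1, total]; sampling once keeps the bound stable for
the whole batch. Dispatch is FIFO in manifest order. A failing task never
blocks others; with `resume`, tasks whose declared output file already
exists non-empty are skipped, so interrupted batches re-run only what is
unfinished. A task whose output file stops growing for a configurable
period is flagged stalled but not killed — stalls usually mean codeml is
waiting for terminal input on a malformed dataset, and killing would
destroy the evidence. Termination is explicit: by process id or whole
group. Completion notification is a pluggable callable (file-log channel
built in); notification failure is logged and never alters the batch
result.

## Statistical choices

- **df from np.** Degrees of freedom are computed from the fits
  (np_alt − np_null), which is always available and robust to template
  edits; the canonical per-comparison df table is used only to warn on
  mismatch.
- **Boundary comparisons.** M8a vs M8 and TrC vs TrU test ω = 1 on the
  boundary of the parameter space, where the LRT statistic's asymptotic
  distribution is a 50:50 mixture of χ²₀ and χ²₁. The default is the plain
  chi-square (conservative); `boundary_mixture=True` applies the halved
  p-value for users who prefer the mixture.
- **Negative 2ΔlnL** (null fitting better — local optima or swapped rows)
  is clamped to 0, giving p = 1 and H0, with a swap-suspected warning.
- **No multiple-testing correction** is applied; alpha is a single-test
  threshold and the table layer keeps every p-value for downstream
  adjustment.

## Synthetic data and the mock codeml

The fixtures module emulates the *artefacts* of a codeml study, not its
likelihood surface. Alignments are uniform draws over non-stop codons of
the requested genetic-code table (no phylogenetic signal, no rate
variation); trees are random coalescent-style topologies; the generated
worked dataset is 4 genes × 6 taxa × 60 codons with one site tree per gene
and three labeled hypothesis trees, small enough that the full pipeline
runs in seconds.

Mock result files are written in the codeml main-output dialect — the
`lnL(ntime: .. np: ..):` line, `kappa (ts/tv) =`, site-class `p:`/`w:`
rows, the branch-site class table, and the BEB section header are anchored
on the real (≥ 4.6) format, with section layout simplified — and the
contract is that `parse_codeml_result(gen_codeml_output(r)) == r` exactly,
for every field of every template (all numerics at 6 printed decimals).

The mock plants its estimates deterministically from a hash of (seqfile,
treefile, template): every grid replicate of a dataset "converges" to the
same optimum, and for each nested comparison the likelihood gain of the
alternative over the null is either 8.0 (2ΔlnL = 16, significant at
α = 0.05 for all registry df 1–4) or 0.5 (2ΔlnL = 1, never significant),
chosen by a hash parity bit. Tests recompute the same truth function and
check that the full pipeline reproduces the H0/H1 pattern end to end.
Passing therefore demonstrates the plumbing — pairing, scaffolding,
scheduling, parsing, table algebra and the LRT arithmetic — on realistic
file shapes; it says nothing about codeml's optimizer or about real
sequence data, which is exactly the division of labour intended: the
likelihood maximization itself is delegated to the external executable.

## Numerical notes

- Chi-square tails come from `scipy.stats.chi2.sf`; the test suite checks
  them against direct numeric integration of the density to 1e-9 relative
  tolerance for df 1–10, and against the df = 2 closed form e^(−Δ/2).
- Planted mock values are exact at 6 decimals by construction, so
  round-trip comparisons use equality, not tolerances.
- Grid values are formatted with `%g` in directory names; the path grammar
  is the inverse of the formatter, which the manifest-vs-path bijection
  test pins down.

## Known limitations

- The result parser targets the mock's dialect, anchored on but simplified
  from real codeml ≥ 4.6 output; exotic real-output variants (per-branch
  dN/dS trees, rst/rub auxiliary files) are out of scope.
- Amino-acid models and baseml are unsupported.
- The scheduler is single-host (one task per core); cluster submission is
  out of scope.
- The interactive table/tree screens are minimal text renders; their logic
  is fully exercised through the library operations, the screens themselves
  only lightly.
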
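"""Synthetic inputs and a mock codeml, so the whole pipeline runs offline.

Three generators produce the artefacts the workflow consumes:

* ``gen_alignment`` — codon alignments free of internal stop codons under
  the requested genetic-code table;
* ``gen_tree`` — random topologies over the same taxa, optionally labeled;
* ``gen_codeml_output`` — a codeml-style main result file that the
  ``extract`` parser inverts *exactly* (the parse∘generate round trip is the
  central correctness contract of the harvesting layer).

``mock_codeml`` is a drop-in executor: it reads a task's ``codeml.ctl``,
derives deterministic "planted" estimates from a hash of the dataset and
template, and writes the output file.  The planted log-likelihoods are
constructed so that every nested-model comparison has a known truth — the
likelihood gain of the alternative over the null is either large enough to
be significant at alpha = 0.05 for every registry comparison's degrees of
freedom, or small enough never to be — which makes end-to-end H0/H1
expectations computable in tests (``planted_truth``).

No likelihood realism is claimed: sequences are not simulated under a codon
model and the planted estimates are draws, not fits.
"""

from __future__ import annotations

import json
import os
import random
import time
import zlib
from dataclasses import dataclass

from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from . import treelab
from .errors import ValidationError
from .extract import NS_BLOCK_MODEL, ResultRecord, TEMPLATE_MODEL
from .scaffold import parse_task_dir
from .templates import read_ctl

#: codeml icode → NCBI translation table id
ICODE_TO_NCBI = {0: 1, 1: 2, 2: 3, 3: 4, 4: 5, 5: 6,
                 6: 9, 7: 10, 8: 12, 9: 13, 10: 15}

#: likelihood gain (lnL_alt - lnL_null) planted per comparison truth
SIGNIFICANT_GAIN = 8.0      # 2*delta = 16 -> p < 0.05 for df 1..4
NULL_GAIN = 0.5             # 2*delta = 1  -> p > 0.3 for df >= 1

#: np = ntime + 1 (kappa) + offset; offsets chosen so each comparison has
#: its canonical degrees of freedom
NP_OFFSET = {
    "M0": 2, "M1a": 3, "M2a": 5, "M3": 6, "M7": 3, "M8": 5, "M8a": 4,
    "TrU": 3, "TrC": 2, "MA": 5, "MA1": 4, "CmC": 6, "M2a_rel": 5,
}

#: the unique comparison in which each null model participates
_NULL_COMPARISON = {
    ("SM-sites", "M0"): "M0vM3",
    ("SM-sites", "M1a"): "M1avM2a",
    ("SM-sites", "M7"): "M7vM8",
    ("SM-M8a", "M8a"): "M8avM8",
    ("BM-M0", "M0"): "M0vTrU",
    ("BM-TrC", "TrC"): "TrCvTrU",
    ("BSM-MA1", "MA1"): "MA1vMA",
    ("CM-M2a_rel", "M2a_rel"): "M2a_relvCmC",
}


@dataclass(frozen=True)
class FixtureSpec:
    n_taxa: int = 6
    n_codons: int = 60
    seed: int = 0
    icode: int = 1

    def __post_init__(self):
        if self.n_taxa < 4:
            raise ValidationError("need at least 4 taxa")
        if self.n_codons < 10:
            raise ValidationError("need at least 10 codons")


def taxon_names(n: int) -> list:
    return [f"T{i+1}" for i in range(n)]


def gen_alignment(spec: FixtureSpec) -> str:
    """FASTA text: n_taxa sequences of 3*n_codons nt, no internal stops."""
    rng = random.Random(spec.seed)
    table = CodonTable.unambiguous_dna_by_id[ICODE_TO_NCBI[spec.icode]]
    stops = set(table.stop_codons)
    codons = [a + b + c for a in "TCAG" for b in "TCAG" for c in "TCAG"
              if a + b + c not in stops]
    import io
    records = []
    for name in taxon_names(spec.n_taxa):
        seq = "".join(rng.choice(codons) for _ in range(spec.n_codons))
        records.append(SeqRecord(Seq(seq), id=name, description=""))
    buf = io.StringIO()
    SeqIO.write(records, buf, "fasta")
    return buf.getvalue()


def gen_tree(spec: FixtureSpec) -> str:
    """Newick text: random binary topology over the spec's taxa."""
    rng = random.Random(spec.seed + 7)
    nodes = [treelab.Node(name=n, length=round(rng.uniform(0.01, 0.5), 3))
             for n in taxon_names(spec.n_taxa)]
    while len(nodes) > 2:
        i = rng.randrange(len(nodes))
        a = nodes.pop(i)
        j = rng.randrange(len(nodes))
        b = nodes.pop(j)
        parent = treelab.Node(children=[a, b],
                              length=round(rng.uniform(0.01, 0.5), 3))
        nodes.append(parent)
    root = treelab.Node(children=nodes)
    tree = treelab.Tree(root=root)
    return treelab.write_newick(tree)


def _r6(rng, lo, hi) -> float:
    return round(rng.uniform(lo, hi), 6)


def _props(rng, k) -> list:
    raw = [rng.uniform(0.1, 1.0) for _ in range(k)]
    total = sum(raw)
    vals = [round(x / total, 6) for x in raw[:-1]]
    vals.append(round(1.0 - sum(vals), 6))
    return vals


def _beb(rng, n_sites=None) -> list:
    n = rng.randint(1, 5) if n_sites is None else n_sites
    positions = sorted(rng.sample(range(1, 200), n))
    return [(pos, rng.choice("ACDEFGHIKLMNPQRSTVWY"), _r6(rng, 0.5, 1.0))
            for pos in positions]


def random_record(model: str, rng, lnL=None, np=None, ntime=None,
                  with_beb=True) -> ResultRecord:
    """A shape-correct random ResultRecord for one model code."""
    ntime = ntime if ntime is not None else rng.randint(5, 40)
    np_ = np if np is not None else ntime + 1 + NP_OFFSET[model]
    lnl = lnL if lnL is not None else round(-rng.uniform(500, 9000), 6)
    rec = ResultRecord(model=model, lnL=lnl, np=np_, ntime=ntime,
                       kappa_hat=_r6(rng, 0.5, 6.0))
    if model in ("M0", "TrC"):
        rec.omegas["w"] = 1.0 if model == "TrC" else _r6(rng, 0.01, 1.5)
    elif model == "TrU":
        for i in range(2):
            rec.omegas[f"branch{i}"] = _r6(rng, 0.01, 3.0)
    elif model in ("MA", "MA1"):
        cols = ("0", "1", "2a", "2b")
        for c, p in zip(cols, _props(rng, 4)):
            rec.proportions[c] = p
        for c in cols:
            rec.omegas[f"bg_{c}"] = _r6(rng, 0.01, 1.0)
        fg2 = 1.0 if model == "MA1" else _r6(rng, 1.0, 6.0)
        for c in cols:
            rec.omegas[f"fg_{c}"] = fg2 if c in ("2a", "2b") else rec.omegas[f"bg_{c}"]
    elif model == "CmC":
        for j, p in enumerate(_props(rng, 3)):
            rec.proportions[f"p{j}"] = p
        rec.omegas["w0"] = _r6(rng, 0.01, 0.9)
        rec.omegas["w1"] = 1.0
        for i in range(2):
            rec.omegas[f"d{i}"] = _r6(rng, 0.1, 4.0)
    else:
        # site-class models: M1a/M8a K=2, the rest K=3
        k = 2 if model in ("M1a", "M8a") else 3
        for j, p in enumerate(_props(rng, k)):
            rec.proportions[f"p{j}"] = p
        for j in range(k):
            if model in ("M1a", "M8a") and j == k - 1:
                rec.omegas[f"w{j}"] = 1.0
            elif model in ("M2a", "M8") and j == k - 1:
                rec.omegas[f"w{j}"] = _r6(rng, 1.0, 6.0)
            elif model == "M7":
                rec.omegas[f"w{j}"] = _r6(rng, 0.01, 1.0)
            else:
                rec.omegas[f"w{j}"] = _r6(rng, 0.01, 2.0)
    from .extract import BEB_MODELS
    if with_beb and model in BEB_MODELS:
        rec.beb_sites = _beb(rng)
    return rec


def _block_text(rec: ResultRecord) -> str:
    lines = [
        f"lnL(ntime: {rec.ntime}  np: {rec.np}): {rec.lnL:.6f}      +0.000000",
        "",
    ]
    if rec.kappa_hat is not None:
        lines += [f"kappa (ts/tv) = {rec.kappa_hat:.6f}", ""]
    keys = set(rec.omegas)
    if keys == {"w"}:
        lines += [f"omega (dN/dS) = {rec.omegas['w']:.6f}", ""]
    elif keys and all(k.startswith("branch") for k in keys):
        vals = "  ".join(f"{rec.omegas[f'branch{i}']:.6f}"
                         for i in range(len(keys)))
        lines += [f"w (dN/dS) for branches:  {vals}", ""]
    elif any(k.startswith(("bg_", "fg_")) for k in keys):
        cols = list(rec.proportions)
        lines += [
            "site class       " + "".join(f"{c:>10}" for c in cols),
            "proportion    " + "".join(f"{rec.proportions[c]:>10.6f}" for c in cols),
            "background w  " + "".join(f"{rec.omegas['bg_' + c]:>10.6f}" for c in cols),
            "foreground w  " + "".join(f"{rec.omegas['fg_' + c]:>10.6f}" for c in cols),
            "",
        ]
    elif rec.proportions:
        wkeys = sorted(k for k in keys if k.startswith("w") and k != "w")
        k = len(rec.proportions)
        lines += [
            f"dN/dS (w) for site classes (K={k})",
            "",
            "p:   " + "  ".join(f"{rec.proportions[f'p{j}']:.6f}" for j in range(k)),
            "w:   " + "  ".join(f"{rec.omegas[f'w{j}']:.6f}" for j in range(len(wkeys))),
        ]
        dkeys = sorted(x for x in keys if x.startswith("d"))
        if dkeys:
            vals = "  ".join(f"{rec.omegas[x]:.6f}" for x in dkeys)
            lines.append(f"divergent w (clades):  {vals}")
        lines.append("")
    if rec.beb_sites is not None:
        lines += [
            "Bayes Empirical Bayes (BEB) analysis",
            "Positively selected sites (*: P>95%; **: P>99%)",
            "",
        ]
        for pos, aa, prob in rec.beb_sites:
            lines.append(f"   {pos:5d} {aa} {prob:.6f}")
        lines.append("")
    return "\n".join(lines)


_MODEL_DESC = {
    "M0": "one-ratio", "M1a": "NearlyNeutral", "M2a": "PositiveSelection",
    "M3": "discrete", "M7": "beta", "M8": "beta&w>1",
}
_NS_NUM = {v: k for k, v in NS_BLOCK_MODEL.items()}


def gen_codeml_output(records, template_name: str, seqfile: str = "seq.fas") -> str:
    """Emit codeml-style main output text that ``extract`` inverts exactly.

    *records* is a single record (single-model templates) or a list (an
    SM-sites multi-NSsites run, one block per site model).
    """
    if isinstance(records, ResultRecord):
        records = [records]
    header = f"CODONML (in paml version 4.9h)  {seqfile}\n\n"
    if template_name == "SM-sites":
        blocks = []
        for rec in records:
            if rec.model not in _NS_NUM:
                raise ValidationError(f"{rec.model} is not an SM-sites model")
            blocks.append(f"Model {_NS_NUM[rec.model]}: {_MODEL_DESC[rec.model]}\n\n"
                          + _block_text(rec))
        return header + "\n".join(blocks)
    expected = TEMPLATE_MODEL.get(template_name)
    if expected is None:
        raise ValidationError(f"unknown template {template_name!r}")
    if len(records) != 1 or records[0].model != expected:
        raise ValidationError(
            f"template {template_name} reports model {expected}, got "
            f"{[r.model for r in records]}")
    if records[0].beb_sites is not None and expected not in ("MA", "CmC"):
        raise ValidationError(f"BEB section is not valid for model {expected}")
    return header + _block_text(records[0])


# ---------------------------------------------------------------------------
# planted-truth scheme for the mock executor


def _hash(*parts) -> int:
    return zlib.crc32("|".join(str(p) for p in parts).encode())


def planted_truth(gene: str, tree_ref: str, comparison_label: str) -> bool:
    """Whether the mock plants a significant likelihood gain for this test."""
    return bool(_hash(gene, tree_ref, comparison_label) & 1)


def planted_gain(gene, tree_ref, comparison_label) -> float:
    return SIGNIFICANT_GAIN if planted_truth(gene, tree_ref, comparison_label) \
        else NULL_GAIN


def planted_base_lnl(gene: str, tree_ref: str) -> float:
    return round(-(1000.0 + (_hash(gene, tree_ref) % 90000) / 10.0), 6)


def planted_lnl(gene, tree_ref, template_name, model) -> float:
    """The lnL the mock writes for one model of one dataset.

    Alternative models sit at the dataset's base lnL; each null sits below it
    by the planted gain of its (unique) comparison.
    """
    base = planted_base_lnl(gene, tree_ref)
    comp = _NULL_COMPARISON.get((template_name, model))
    if comp is None:
        return base
    return round(base - planted_gain(gene, tree_ref, comp), 6)


def planted_record(gene, tree_ref, template_name, model, ntime) -> ResultRecord:
    rng = random.Random(_hash(gene, tree_ref, template_name, model))
    return random_record(
        model, rng,
        lnL=planted_lnl(gene, tree_ref, template_name, model),
        np=ntime + 1 + NP_OFFSET[model], ntime=ntime,
    )


def mock_codeml(task_dir, behavior: dict | None = None) -> int:
    """Drop-in codeml: read the ctl, write deterministic planted output.

    Estimates are a pure function of (seqfile, treefile, template), so
    identical task directories produce identical outputs and grid replicates
    of one dataset converge to the same optimum.  A ``mock_behavior.json``
    in the task directory (or the *behavior* mapping) can request
    ``{"sleep": seconds, "crash": true, "hang": true}`` for scheduler tests.
    """
    task_dir = str(task_dir)
    ctl_path = os.path.join(task_dir, "codeml.ctl")
    if not os.path.exists(ctl_path):
        return 1
    if behavior is None:
        bpath = os.path.join(task_dir, "mock_behavior.json")
        behavior = {}
        if os.path.exists(bpath):
            with open(bpath, "r", encoding="utf-8") as fh:
                behavior = json.load(fh)
    if behavior.get("sleep"):
        time.sleep(float(behavior["sleep"]))
    if behavior.get("hang"):
        time.sleep(3600)
    if behavior.get("crash"):
        return 1
    cf = read_ctl(ctl_path)
    meta = parse_task_dir(_rel_task_dir(task_dir))
    treefile = os.path.normpath(os.path.join(task_dir, cf.params["treefile"]))
    with open(treefile, "r", encoding="utf-8") as fh:
        tree = treelab.parse_newick(fh.read())
    ntime = 2 * len(tree.leaves()) - 3
    template = meta["template"]
    if template == "SM-sites":
        codes = cf.params.get("NSsites", "").split()
        records = [
            planted_record(meta["gene"], meta["tree_ref"], template,
                           NS_BLOCK_MODEL[c], ntime)
            for c in codes
        ]
    else:
        records = [planted_record(meta["gene"], meta["tree_ref"], template,
                                  TEMPLATE_MODEL[template], ntime)]
    text = gen_codeml_output(records if template == "SM-sites" else records[0],
                             template, seqfile=cf.params.get("seqfile", "seq.fas"))
    outfile = os.path.join(task_dir, cf.params.get("outfile", "results.txt"))
    with open(outfile, "w", encoding="utf-8") as fh:
        fh.write(text)
    return 0


def _rel_task_dir(task_dir: str) -> str:
    """Recover the manifest-relative task path from an absolute one."""
    parts = os.path.normpath(task_dir).split(os.sep)
    return "/".join(parts[-4:])


# ---------------------------------------------------------------------------
# example dataset


def make_example_dataset(dest, seed: int = 0, n_taxa: int = 6,
                         n_codons: int = 60) -> dict:
    """Write a small worked dataset: 4 genes × all families + 3 hypotheses.

    Produces ``msas/G<i>_sbwc1.fas`` with per-gene ``trees/G<i>_s.nwk``
    plus shared labeled hypothesis trees ``H1_w.nwk`` (one branch
    foreground), ``H2_b.nwk`` and ``H3_c.nwk`` (one labeled clade).
    """
    dest = str(dest)
    msa_dir = os.path.join(dest, "msas")
    tree_dir = os.path.join(dest, "trees")
    os.makedirs(msa_dir, exist_ok=True)
    os.makedirs(tree_dir, exist_ok=True)
    genes = [f"G{i+1}" for i in range(4)]
    for i, gene in enumerate(genes):
        spec = FixtureSpec(n_taxa=n_taxa, n_codons=n_codons,
                           seed=seed + i, icode=1)
        with open(os.path.join(msa_dir, f"{gene}_sbwc1.fas"), "w",
                  encoding="utf-8") as fh:
            fh.write(gen_alignment(spec))
        with open(os.path.join(tree_dir, f"{gene}_s.nwk"), "w",
                  encoding="utf-8") as fh:
            fh.write(gen_tree(spec))
    base_spec = FixtureSpec(n_taxa=n_taxa, n_codons=n_codons, seed=seed + 100)

    def labeled(kind):
        tree = treelab.parse_newick(gen_tree(base_spec))
        internal = [n for n in tree.nodes()
                    if not n.is_leaf and n is not tree.root]
        treelab.apply_label(tree, internal[0].node_id, kind, 1)
        return treelab.write_newick(tree)

    hyps = {"H1_w.nwk": "branch", "H2_b.nwk": "branch", "H3_c.nwk": "clade"}
    for fname, kind in hyps.items():
        with open(os.path.join(tree_dir, fname), "w", encoding="utf-8") as fh:
            fh.write(labeled(kind))
    return {"msa_dir": msa_dir, "tree_dir": tree_dir, "genes": genes}


def main(argv=None):
    """Entry point so the mock runs as ``python -m codemlbatch.fixtures``.

    Invoked with the ctl filename inside a task directory (the runner's
    executor contract); the task directory is the working directory.
    """
    import sys
    args = argv if argv is not None else sys.argv[1:]
    task_dir = os.getcwd()
    if args and os.path.isdir(args[0]):
        task_dir = args[0]
    return mock_codeml(task_dir)


if __name__ == "__main__":
    raise SystemExit(main())
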
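"""Materialize the per-task directory structure and batch-edit control files.

One task = one codeml execution = one directory holding a ``codeml.ctl``.
The structure is laid out as::

    <dest>/<jobname>/<letter>/<gene>__<tree_ref>/<template>/k<kappa>_w<omega>/

which is bijective with the task's metadata: a path alone reconstructs the
dataset pair, template and grid starting point (``parse_task_dir``).  A
manifest (one JSON line per task, in deterministic order) is written at the
structure root and is the authoritative task list for the scheduler and the
result harvester.
"""

from __future__ import annotations

import json
import logging
import os
import re
from dataclasses import asdict, dataclass

from Bio import SeqIO

from . import treelab
from .errors import ValidationError
from .templates import (CODEML_KEYS, GridSpec, expand_grid,
                        instantiate_control, read_ctl, templates_for_class,
                        write_ctl)

log = logging.getLogger(__name__)

MANIFEST_NAME = "manifest.jsonl"

STATUSES = ("pending", "running", "done", "failed")


@dataclass
class TaskSpec:
    """One unit of codeml work inside the directory structure."""

    task_dir: str          # relative to the structure root
    ctl_path: str
    gene: str
    tree_ref: str
    letter: str
    template: str
    kappa: float
    omega: float
    icode: int
    status: str = "pending"


def _fmt_val(x: float) -> str:
    return f"{x:g}"


def task_rel_dir(gene, tree_ref, letter, template, kappa, omega) -> str:
    return os.path.join(letter, f"{gene}__{tree_ref}", template,
                        f"k{_fmt_val(kappa)}_w{_fmt_val(omega)}")


_TASK_DIR_RE = re.compile(
    r"^(?P<letter>[sbwc])/(?P<gene>.+)__(?P<ref>[^/]+)/(?P<template>[^/]+)/"
    r"k(?P<kappa>[^_]+)_w(?P<omega>[^/]+)$"
)


def parse_task_dir(rel_dir: str) -> dict:
    """Invert ``task_rel_dir``: recover task metadata from the path alone."""
    m = _TASK_DIR_RE.match(rel_dir.replace(os.sep, "/"))
    if not m:
        raise ValidationError(f"path {rel_dir!r} is not a task directory")
    return {
        "letter": m.group("letter"),
        "gene": m.group("gene"),
        "tree_ref": m.group("ref"),
        "template": m.group("template"),
        "kappa": float(m.group("kappa")),
        "omega": float(m.group("omega")),
    }


def _taxa_match(msa_path: str, tree_path: str) -> bool:
    msa_names = {rec.id for rec in SeqIO.parse(msa_path, "fasta")}
    with open(tree_path, "r", encoding="utf-8") as fh:
        tree = treelab.parse_newick(fh.read())
    return msa_names == {leaf.name for leaf in tree.leaves()}


def expected_task_count(pairs, request, grid: GridSpec) -> int:
    """Closed-form task count: Σ_pairs templates(letter, request) × |grid|."""
    n_grid = len(expand_grid(grid))
    return sum(len(templates_for_class(p.letter, request)) * n_grid for p in pairs)


def build_structure(pairs, request, grid: GridSpec, dest, jobname: str,
                    resume: bool = False, check_taxa: bool = True,
                    warnings=None) -> list:
    """Create the task directories and control files for a batch.

    For every pair, every template of the pair's letter admitted by the
    request, and every (kappa, omega) grid point, one task directory with an
    instantiated ``codeml.ctl`` is created.  Site-model pairs yield one
    SM-sites task covering all requested non-M8a site models in a single
    multi-NSsites run, plus one SM-M8a task when M8a is requested.

    Pairs whose MSA and tree disagree on the taxon set are skipped with a
    warning.  An existing ``<dest>/<jobname>`` is rejected unless *resume*.
    """
    if not pairs:
        raise ValidationError("no dataset pairs to scaffold")
    root = os.path.join(str(dest), jobname)
    if os.path.exists(root) and not resume:
        raise ValidationError(f"{root} already exists (pass resume to reuse)")
    os.makedirs(root, exist_ok=True)
    tasks = []
    for pair in pairs:
        msa_path = os.path.abspath(pair.msa.path)
        tree_path = os.path.abspath(pair.tree.path)
        if check_taxa and not _taxa_match(msa_path, tree_path):
            msg = (f"taxa mismatch between {pair.msa.path} and "
                   f"{pair.tree.path}; pair skipped")
            log.warning(msg)
            if warnings is not None:
                warnings.append(msg)
            continue
        for template in templates_for_class(pair.letter, request):
            for kappa, omega in expand_grid(grid):
                rel = task_rel_dir(pair.msa.gene_name, pair.tree.ref_name,
                                   pair.letter, template.name, kappa, omega)
                task_dir = os.path.join(root, rel)
                os.makedirs(task_dir, exist_ok=True)
                cf = instantiate_control(
                    template,
                    seqfile=os.path.relpath(msa_path, task_dir),
                    treefile=os.path.relpath(tree_path, task_dir),
                    icode=pair.msa.icode, kappa=kappa, omega=omega,
                    site_models=request.site_models or None,
                )
                ctl_path = os.path.join(task_dir, "codeml.ctl")
                write_ctl(cf, ctl_path)
                tasks.append(TaskSpec(
                    task_dir=rel, ctl_path=os.path.join(rel, "codeml.ctl"),
                    gene=pair.msa.gene_name, tree_ref=pair.tree.ref_name,
                    letter=pair.letter, template=template.name,
                    kappa=kappa, omega=omega, icode=pair.msa.icode,
                ))
    write_manifest(root, tasks)
    return tasks


def write_manifest(root, tasks):
    with open(os.path.join(str(root), MANIFEST_NAME), "w", encoding="utf-8") as fh:
        for t in tasks:
            fh.write(json.dumps(asdict(t) if isinstance(t, TaskSpec) else t) + "\n")


def load_manifest(root) -> list:
    path = os.path.join(str(root), MANIFEST_NAME)
    if not os.path.exists(path):
        raise ValidationError(f"no manifest at {path}")
    with open(path, "r", encoding="utf-8") as fh:
        return [json.loads(line) for line in fh if line.strip()]


def edit_controls(root, edits: dict, selector=None, force: bool = False,
                  permissive: bool = False) -> int:
    """Batch-edit ctl files in an existing structure; returns files changed.

    Edits apply to tasks matched by *selector* (a predicate over the manifest
    task dict; ``None`` matches all).  Keys outside codeml's documented key
    set are rejected unless *force*.  With *permissive*, any directory tree
    containing ``codeml.ctl`` files is accepted even without a manifest.
    The template registry itself is never touched.
    """
    root = str(root)
    for key in edits:
        if key not in CODEML_KEYS and not force:
            raise ValidationError(f"{key!r} is not a documented codeml key "
                                  "(use force to override)")
    ctl_paths = []
    try:
        tasks = load_manifest(root)
    except ValidationError:
        if not permissive:
            raise
        tasks = None
    if tasks is not None:
        for t in tasks:
            if selector is None or selector(t):
                ctl_paths.append(os.path.join(root, t["task_dir"], "codeml.ctl"))
    else:
        for dirpath, _dirs, files in os.walk(root):
            if "codeml.ctl" in files:
                ctl_paths.append(os.path.join(dirpath, "codeml.ctl"))
    changed = 0
    for path in ctl_paths:
        cf = read_ctl(path)
        new_params = dict(cf.params)
        new_params.update({k: str(v) for k, v in edits.items()})
        if new_params != cf.params:
            cf.params = new_params
            write_ctl(cf, path)
            changed += 1
    return changed
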
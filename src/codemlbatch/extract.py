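"""Harvest codeml main result files into records and per-family CSV tables.

A codeml main output file reports, per fitted model, the maximized
log-likelihood ``lnL`` and free-parameter count ``np``, the transition/
transversion ratio kappa, omega (dN/dS) estimates — a single ratio, one per
branch partition, or one per site class depending on the model — site-class
proportions, and for the alternative models (M2a, M8, branch-site model A,
clade model C) a Bayes Empirical Bayes list of sites with posterior
probability of positive selection.

``parse_codeml_result`` inverts one file into :class:`ResultRecord` objects
(a multi-NSsites site-model file yields one record per model block);
``collect_results`` walks a scaffolded directory structure and aggregates
everything into one CSV table per model-family letter, each row carrying the
source path decomposed into its dataset / template / grid-point columns.
"""

from __future__ import annotations

import json
import logging
import os
import re
from dataclasses import dataclass, field, replace

import pandas as pd

from .errors import ParseError
from .scaffold import load_manifest, parse_task_dir
from .templates import read_ctl

log = logging.getLogger(__name__)

#: model codes reported by single-model templates
TEMPLATE_MODEL = {
    "SM-M8a": "M8a", "BM-M0": "M0", "BM-TrU": "TrU", "BM-TrC": "TrC",
    "BSM-MA": "MA", "BSM-MA1": "MA1", "CM-CmC": "CmC", "CM-M2a_rel": "M2a_rel",
}

#: NSsites block numbers inside an SM-sites file
NS_BLOCK_MODEL = {"0": "M0", "1": "M1a", "2": "M2a", "3": "M3", "7": "M7", "8": "M8"}

#: models for which a BEB section may be present
BEB_MODELS = frozenset({"M2a", "M8", "MA", "CmC"})

_LNL_RE = re.compile(r"lnL\(ntime:\s*(\d+)\s+np:\s*(\d+)\):\s*(-?\d+\.\d+)")
_KAPPA_RE = re.compile(r"kappa \(ts/tv\) =\s*(-?\d+\.\d+)")
_OMEGA_RE = re.compile(r"omega \(dN/dS\) =\s*(-?\d+\.\d+)")
_BRANCH_RE = re.compile(r"w \(dN/dS\) for branches:\s*(.+)")
_SITECLASS_RE = re.compile(r"dN/dS \(w\) for site classes \(K=(\d+)\)")
_DIVERGENT_RE = re.compile(r"divergent w \(clades\):\s*(.+)")
_BEB_SITE_RE = re.compile(r"^\s*(\d+)\s+([A-Z*])\s+(\d+\.\d+)\s*$")


@dataclass
class ResultRecord:
    """ML estimates for one fitted model, plus dataset identifiers."""

    model: str
    lnL: float
    np: int
    ntime: int | None = None
    kappa_hat: float | None = None
    omegas: dict = field(default_factory=dict)
    proportions: dict = field(default_factory=dict)
    beb_sites: list | None = None          # [(position, amino acid, prob), ...]
    beb_truncated: bool = False
    # identifiers filled in by collect_results
    gene: str | None = None
    tree_ref: str | None = None
    model_class: str | None = None
    template: str | None = None
    kappa0: float | None = None
    omega0: float | None = None
    source_path: str | None = None


def _floats(raw: str) -> list:
    return [float(x) for x in raw.split()]


def _parse_block(block: str, model: str, source: str) -> ResultRecord:
    m = _LNL_RE.search(block)
    if not m:
        raise ParseError(f"{source}: no lnL line found for model {model}")
    ntime, np_, lnl = int(m.group(1)), int(m.group(2)), float(m.group(3))
    rec = ResultRecord(model=model, lnL=lnl, np=np_, ntime=ntime)

    m = _KAPPA_RE.search(block)
    if m:
        rec.kappa_hat = float(m.group(1))
    m = _OMEGA_RE.search(block)
    if m:
        rec.omegas["w"] = float(m.group(1))
    m = _BRANCH_RE.search(block)
    if m:
        for i, v in enumerate(_floats(m.group(1))):
            rec.omegas[f"branch{i}"] = v

    lines = block.splitlines()
    for i, line in enumerate(lines):
        if _SITECLASS_RE.search(line):
            for sub in lines[i + 1:]:
                sub = sub.strip()
                if sub.startswith("p:"):
                    for j, v in enumerate(_floats(sub[2:])):
                        rec.proportions[f"p{j}"] = v
                elif sub.startswith("w:"):
                    for j, v in enumerate(_floats(sub[2:])):
                        rec.omegas[f"w{j}"] = v
                elif sub and not _DIVERGENT_RE.match(sub):
                    break
            break
        if line.strip().startswith("site class"):
            cols = line.split()[2:]
            rows = {}
            for sub in lines[i + 1: i + 4]:
                if sub.strip().startswith("proportion"):
                    rows["p"] = _floats(sub.strip()[len("proportion"):])
                elif sub.strip().startswith("background w"):
                    rows["bg"] = _floats(sub.strip()[len("background w"):])
                elif sub.strip().startswith("foreground w"):
                    rows["fg"] = _floats(sub.strip()[len("foreground w"):])
            for c, v in zip(cols, rows.get("p", [])):
                rec.proportions[c] = v
            for c, v in zip(cols, rows.get("bg", [])):
                rec.omegas[f"bg_{c}"] = v
            for c, v in zip(cols, rows.get("fg", [])):
                rec.omegas[f"fg_{c}"] = v
            break
    m = _DIVERGENT_RE.search(block)
    if m:
        for i, v in enumerate(_floats(m.group(1))):
            rec.omegas[f"d{i}"] = v

    if "Bayes Empirical Bayes" in block:
        if model not in BEB_MODELS:
            log.warning("%s: unexpected BEB section for model %s", source, model)
        sites = []
        truncated = False
        in_sites = False
        for line in block.splitlines():
            if "Positively selected sites" in line:
                in_sites = True
                continue
            if not in_sites:
                continue
            if not line.strip():
                if sites:
                    break
                continue
            sm = _BEB_SITE_RE.match(line)
            if sm:
                sites.append((int(sm.group(1)), sm.group(2), float(sm.group(3))))
            else:
                truncated = True
                break
        if truncated:
            rec.beb_sites = None
            rec.beb_truncated = True
        else:
            rec.beb_sites = sites
    return rec


def parse_codeml_result(text: str, template_name: str,
                        source: str = "<text>") -> list:
    """Parse one codeml main output into one record per fitted model."""
    if template_name == "SM-sites":
        records = []
        parts = re.split(r"(?m)^Model\s+(\w+):.*$", text)
        # parts = [preamble, code, block, code, block, ...]
        for code, block in zip(parts[1::2], parts[2::2]):
            model = NS_BLOCK_MODEL.get(code)
            if model is None:
                raise ParseError(f"{source}: unknown NSsites block {code!r}")
            records.append(_parse_block(block, model, source))
        if not records:
            raise ParseError(f"{source}: no model blocks found in SM-sites output")
        return records
    model = TEMPLATE_MODEL.get(template_name)
    if model is None:
        raise ParseError(f"{source}: unknown template {template_name!r}")
    return [_parse_block(text, model, source)]


#: canonical CSV column order; C1..Cn aliases follow this order
CSV_COLUMNS = [
    "path", "gene", "tree_ref", "model_class", "template", "kappa0", "omega0",
    "model", "lnL", "np", "ntime", "kappa_hat", "omegas", "proportions",
    "beb_sites", "n_beb_sites",
]


def _ser_map(d: dict) -> str:
    return ";".join(f"{k}={v:.6f}" for k, v in d.items())


def _ser_beb(sites) -> str:
    if sites is None:
        return ""
    return ";".join(f"{pos}{aa}:{p:.6f}" for pos, aa, p in sites)


def record_to_row(rec: ResultRecord) -> dict:
    return {
        "path": rec.source_path or "",
        "gene": rec.gene or "",
        "tree_ref": rec.tree_ref or "",
        "model_class": rec.model_class or "",
        "template": rec.template or "",
        "kappa0": rec.kappa0,
        "omega0": rec.omega0,
        "model": rec.model,
        "lnL": rec.lnL,
        "np": rec.np,
        "ntime": rec.ntime,
        "kappa_hat": rec.kappa_hat,
        "omegas": _ser_map(rec.omegas),
        "proportions": _ser_map(rec.proportions),
        "beb_sites": _ser_beb(rec.beb_sites),
        "n_beb_sites": len(rec.beb_sites) if rec.beb_sites is not None else "",
    }


def collect_results(root, request, write_csv: bool = True):
    """Aggregate finished task outputs into one table per model family.

    Returns ``(tables, warnings)`` where *tables* maps each requested class
    letter to a DataFrame (empty but with headers when no results exist) and
    *warnings* lists tasks whose output was missing or unparseable.  Row
    order follows the manifest.  When *write_csv* is set, each table is also
    written to ``<root>/results_<letter>.csv``.
    """
    root = str(root)
    tasks = load_manifest(root)
    warnings = []
    rows = {letter: [] for letter in sorted(request.classes)}
    for task in tasks:
        letter = task["letter"]
        if letter not in rows:
            continue
        task_dir = os.path.join(root, task["task_dir"])
        ctl = read_ctl(os.path.join(task_dir, "codeml.ctl"))
        outfile = os.path.join(task_dir, ctl.params.get("outfile", "results.txt"))
        if not os.path.exists(outfile):
            warnings.append(f"{task['task_dir']}: no output file, task skipped")
            continue
        with open(outfile, "r", encoding="utf-8") as fh:
            text = fh.read()
        try:
            records = parse_codeml_result(text, task["template"], source=outfile)
        except ParseError as e:
            warnings.append(str(e))
            continue
        for rec in records:
            rec = replace(
                rec, gene=task["gene"], tree_ref=task["tree_ref"],
                model_class=letter, template=task["template"],
                kappa0=task["kappa"], omega0=task["omega"],
                source_path=outfile,
            )
            rows[letter].append(record_to_row(rec))
    tables = {}
    for letter, lrows in rows.items():
        df = pd.DataFrame(lrows, columns=CSV_COLUMNS)
        tables[letter] = df
        if write_csv:
            df.to_csv(os.path.join(root, f"results_{letter}.csv"), index=False)
    return tables, warnings
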
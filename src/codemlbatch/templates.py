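"""The nine codeml control-file templates and the nested-model comparisons.

Each codon-model family needs its own codeml parameterization.  The package
ships exactly nine templates:

===========  ======  ==============================================
template     family  codeml parameterization
===========  ======  ==============================================
SM-sites     SM      model=0, NSsites enumerating the chosen site
                     models among 0 1 2 3 7 8 (one run, many models)
SM-M8a       SM      model=0, NSsites=8, fix_omega=1, omega=1
BM-M0        BM      model=0, NSsites=0 (one-ratio null)
BM-TrU       BM      model=2, NSsites=0 (per-partition free ω)
BM-TrC       BM      model=2, NSsites=0, fix_omega=1, omega=1
BSM-MA       BSM     model=2, NSsites=2 (branch-site model A)
BSM-MA1      BSM     model=2, NSsites=2, fix_omega=1, omega=1
CM-CmC       CM      model=3, NSsites=2 (clade model C)
CM-M2a_rel   CM      model=0, NSsites=22 (M2a_rel null)
===========  ======  ==============================================

At instantiation the dataset-dependent keys (seqfile, treefile, icode,
NSsites, kappa, omega) are filled in; all other keys carry documented
defaults the user may edit afterwards.  Templates whose role fixes omega at 1
ignore the grid's omega starting value.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

from .errors import ParseError, ValidationError
from .identity import SITE_MODELS

log = logging.getLogger(__name__)

#: dataset-dependent ctl keys filled at instantiation time
AUTO_PARAMS = ("seqfile", "treefile", "icode", "NSsites", "kappa", "omega")

_NS_CODE = {"M0": "0", "M1a": "1", "M2a": "2", "M3": "3", "M7": "7", "M8": "8"}

# shared ctl defaults, editable downstream; order matters for serialization
_COMMON = (
    ("outfile", "results.txt"),
    ("noisy", "3"),
    ("verbose", "1"),
    ("runmode", "0"),
    ("seqtype", "1"),
    ("CodonFreq", "2"),
    ("clock", "0"),
    ("aaDist", "0"),
    ("estFreq", "0"),
    ("ndata", "1"),
    ("fix_kappa", "0"),
    ("fix_alpha", "1"),
    ("alpha", "0"),
    ("Malpha", "0"),
    ("ncatG", "10"),
    ("getSE", "0"),
    ("RateAncestor", "0"),
    ("Small_Diff", ".5e-6"),
    ("cleandata", "0"),
    ("fix_blength", "0"),
    ("method", "0"),
)


@dataclass(frozen=True)
class Template:
    """One named codeml parameter configuration."""

    name: str
    model_class: str          # one of s/b/w/c
    role: str | None          # "null", "alternative", or None (mixed/multi)
    fixed_params: tuple       # ((key, value), ...) beyond the common defaults
    auto_params: tuple = AUTO_PARAMS

    @property
    def fixes_omega(self) -> bool:
        return ("fix_omega", "1") in self.fixed_params

    def params(self) -> dict:
        out = dict(_COMMON)
        out.update(dict(self.fixed_params))
        return out


_REGISTRY = (
    Template("SM-sites", "s", None,
             (("model", "0"), ("fix_omega", "0"))),
    Template("SM-M8a", "s", "null",
             (("model", "0"), ("NSsites", "8"), ("fix_omega", "1"), ("omega", "1"))),
    Template("BM-M0", "b", "null",
             (("model", "0"), ("NSsites", "0"), ("fix_omega", "0"))),
    Template("BM-TrC", "b", "null",
             (("model", "2"), ("NSsites", "0"), ("fix_omega", "1"), ("omega", "1"))),
    Template("BM-TrU", "b", "alternative",
             (("model", "2"), ("NSsites", "0"), ("fix_omega", "0"))),
    Template("BSM-MA", "w", "alternative",
             (("model", "2"), ("NSsites", "2"), ("fix_omega", "0"))),
    Template("BSM-MA1", "w", "null",
             (("model", "2"), ("NSsites", "2"), ("fix_omega", "1"), ("omega", "1"))),
    Template("CM-CmC", "c", "alternative",
             (("model", "3"), ("NSsites", "2"), ("fix_omega", "0"))),
    Template("CM-M2a_rel", "c", "null",
             (("model", "0"), ("NSsites", "22"), ("fix_omega", "0"))),
)


def template_registry() -> list:
    """Return the nine templates (2 SM, 3 BM, 2 BSM, 2 CM)."""
    return list(_REGISTRY)


def get_template(name: str) -> Template:
    for t in _REGISTRY:
        if t.name == name:
            return t
    raise KeyError(f"unknown template {name!r}")


def templates_for_class(letter: str, request=None) -> list:
    """Templates applicable to one model-family letter under a request.

    For the site-model family the multi-model SM-sites template is included
    only when at least one non-M8a site model is requested, and SM-M8a only
    when M8a is.
    """
    out = []
    for t in _REGISTRY:
        if t.model_class != letter:
            continue
        if request is not None and letter == "s":
            if t.name == "SM-sites" and not (set(request.site_models) - {"M8a"}):
                continue
            if t.name == "SM-M8a" and "M8a" not in request.site_models:
                continue
        out.append(t)
    return out


@dataclass(frozen=True)
class LrtComparison:
    """A null/alternative nested-model pairing tested by LRT."""

    null_name: str
    alt_name: str
    label: str
    model_class: str


_COMPARISONS = (
    LrtComparison("M0", "M3", "M0vM3", "s"),
    LrtComparison("M1a", "M2a", "M1avM2a", "s"),
    LrtComparison("M7", "M8", "M7vM8", "s"),
    LrtComparison("M8a", "M8", "M8avM8", "s"),
    LrtComparison("M0", "TrU", "M0vTrU", "b"),
    LrtComparison("TrC", "TrU", "TrCvTrU", "b"),
    LrtComparison("MA1", "MA", "MA1vMA", "w"),
    LrtComparison("M2a_rel", "CmC", "M2a_relvCmC", "c"),
)


def comparisons_registry() -> list:
    """The eight nested-model LRT pairings (4 SM, 2 BM, 1 BSM, 1 CM)."""
    return list(_COMPARISONS)


@dataclass(frozen=True)
class GridSpec:
    """Starting-value grid over kappa and omega to escape local optima."""

    kappas: tuple = (0.5, 2.0, 4.0)
    omegas: tuple = (0.2, 1.0, 2.0)

    def __post_init__(self):
        if not self.kappas or not self.omegas:
            raise ValidationError("grid axes must be non-empty")
        if any(k <= 0 for k in self.kappas) or any(w <= 0 for w in self.omegas):
            raise ValidationError("kappa and omega starting values must be positive")


def expand_grid(grid: GridSpec) -> list:
    """Cartesian product of the grid axes, kappa-major order."""
    return list(itertools.product(grid.kappas, grid.omegas))


@dataclass
class ControlFile:
    """A concrete codeml control file: an ordered key→value mapping."""

    params: dict
    template_name: str = ""

    def __eq__(self, other):
        if not isinstance(other, ControlFile):
            return NotImplemented
        return self.params == other.params


def nssites_value(site_models) -> str:
    """Multi-model NSsites string for SM-sites, e.g. {M0,M3} → "0 3"."""
    codes = sorted(int(_NS_CODE[m]) for m in site_models if m != "M8a")
    if not codes:
        raise ValidationError("SM-sites requires at least one non-M8a site model")
    return " ".join(str(c) for c in codes)


def _fmt(x) -> str:
    if isinstance(x, float) and x == int(x):
        return str(int(x))
    return str(x)


def instantiate_control(t: Template, seqfile, treefile, icode: int,
                        kappa, omega, site_models=None) -> ControlFile:
    """Fill a template's auto parameters for one dataset and grid point.

    Fixed-omega templates (the ω=1 constrained nulls) keep fix_omega=1 and
    omega=1 regardless of the grid's omega; the override is logged, not an
    error.
    """
    params = {"seqfile": str(seqfile), "treefile": str(treefile)}
    base = t.params()
    for key, value in base.items():
        params[key] = value
    params["icode"] = str(int(icode))
    if t.name == "SM-sites":
        params["NSsites"] = nssites_value(site_models or SITE_MODELS)
    params["kappa"] = _fmt(kappa)
    if t.fixes_omega:
        if omega is not None and float(omega) != 1.0:
            log.info("template %s fixes omega=1; grid omega %s ignored", t.name, omega)
        params["omega"] = "1"
    else:
        params["omega"] = _fmt(omega)
    # canonical key order: seqfile/treefile first, then template keys, icode,
    # kappa/omega last
    order = ["seqfile", "treefile"] + [k for k in base if k not in
                                       ("seqfile", "treefile", "kappa", "omega")]
    order += ["icode"] if "icode" not in order else []
    order += ["kappa", "omega"]
    seen = dict.fromkeys(order)
    ordered = {k: params[k] for k in seen if k in params}
    for k in params:
        if k not in ordered:
            ordered[k] = params[k]
    return ControlFile(params=ordered, template_name=t.name)


def write_ctl(cf: ControlFile, dest) -> str:
    """Serialize to codeml's ``key = value`` dialect."""
    lines = [f"{k} = {v}" for k, v in cf.params.items()]
    text = "\n".join(lines) + "\n"
    with open(dest, "w", encoding="utf-8") as fh:
        fh.write(text)
    return str(dest)


def read_ctl(src) -> ControlFile:
    """Parse a ctl file; '*' starts a comment, duplicate keys last-wins."""
    try:
        with open(src, "r", encoding="utf-8") as fh:
            text = fh.read()
    except OSError as e:
        raise ParseError(f"cannot read control file {src}: {e}") from e
    params = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("*", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ParseError(f"{src}:{lineno}: no '=' in line {raw!r}")
        key, value = line.split("=", 1)
        key, value = key.strip(), value.strip()
        if key in params:
            log.warning("%s: duplicate key %r, last value wins", src, key)
        params[key] = value
    return ControlFile(params=params)


#: documented codeml control keys, used to validate batch edits
CODEML_KEYS = frozenset(
    k for k, _ in _COMMON
) | frozenset(AUTO_PARAMS) | frozenset({
    "model", "fix_omega", "aaRatefile", "Mgene", "hkyREV", "fix_rho", "rho",
    "Apendix", "icode", "weighting", "seqfile", "treefile",
})
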
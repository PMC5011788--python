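"""Filename grammar for codon-model batch inputs.

Multiple-sequence alignments and trees carry their routing metadata in the
filename itself:

* MSA:  ``<gene>_<letters><icode>.fas[ta]`` — e.g. ``ATP6_sbwc1.fas`` is gene
  ATP6, to be analysed under all four model families, with genetic-code table
  index 1 (vertebrate mitochondrial).
* Tree: ``<gene>_s.nwk`` for site-model trees (unlabeled, gene-matched), or
  ``<hypothesis>_<letters>.nwk`` for branch-related trees whose letters are
  drawn from ``b`` (branch), ``w`` (branch-site), ``c`` (clade).

The model-family letters are ``s`` (site models, SM), ``b`` (branch models,
BM), ``w`` (branch-site models, BSM) and ``c`` (clade models, CM).  An MSA is
paired with a tree for every letter the two filenames share (site-model
pairing additionally requires the gene name to match the tree name exactly).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import ParseError

#: canonical ordering of the four model-family letters
MODEL_LETTERS = "sbwc"

MODEL_FAMILY = {"s": "SM", "b": "BM", "w": "BSM", "c": "CM"}

#: the seven site models selectable inside the ``s`` family
SITE_MODELS = ("M0", "M1a", "M2a", "M3", "M7", "M8", "M8a")

_SITE_CODE = {"0": "M0", "1": "M1a", "2": "M2a", "3": "M3",
              "7": "M7", "8": "M8", "8a": "M8a"}

MSA_EXTENSIONS = (".fas", ".fasta")
TREE_EXTENSIONS = (".nwk",)

#: genetic-code table indices accepted by codeml (icode 0..10)
ICODE_RANGE = range(0, 11)


def canonical_letters(classes) -> str:
    """Order a set of model letters canonically (s, b, w, c)."""
    return "".join(c for c in MODEL_LETTERS if c in classes)


@dataclass(frozen=True)
class ModelRequest:
    """Which model families (and which site models) a run should cover."""

    classes: frozenset
    site_models: frozenset = frozenset()

    def __post_init__(self):
        if self.site_models and "s" not in self.classes:
            raise ParseError("site models given without the 's' class")
        if "s" in self.classes and not self.site_models:
            raise ParseError("'s' class requires a non-empty site-model set")


@dataclass(frozen=True)
class MsaIdentity:
    gene_name: str
    classes: frozenset
    icode: int
    path: str = ""
    extension: str = ".fas"

    def rebuild_name(self) -> str:
        return f"{self.gene_name}_{canonical_letters(self.classes)}{self.icode}{self.extension}"


@dataclass(frozen=True)
class TreeIdentity:
    ref_name: str
    classes: frozenset
    path: str = ""
    extension: str = ".nwk"

    def rebuild_name(self) -> str:
        return f"{self.ref_name}_{canonical_letters(self.classes)}{self.extension}"


@dataclass(frozen=True)
class DatasetPair:
    """One (MSA, tree) combination under one shared model letter."""

    msa: MsaIdentity
    tree: TreeIdentity
    letter: str

    @property
    def shared_classes(self) -> frozenset:
        return self.msa.classes & self.tree.classes


@dataclass
class PairingWarning:
    msa: MsaIdentity
    letter: str
    message: str = field(default="")

    def __post_init__(self):
        if not self.message:
            self.message = (
                f"MSA {self.msa.gene_name!r}: class {self.letter!r} has no matching tree"
            )


def parse_model_spec(spec: str) -> ModelRequest:
    """Parse a ``-m`` style model request, e.g. ``"s[0:1:2:3:7:8:8a],b,c,w"``.

    A bare ``s`` selects all seven site models; ``s[7:8]`` selects a subset.
    """
    if not spec or not spec.strip():
        raise ParseError("empty model spec")
    classes = set()
    site_models: set = set()
    for token in spec.split(","):
        token = token.strip()
        if not token:
            raise ParseError(f"empty token in model spec {spec!r}")
        m = re.fullmatch(r"s(?:\[([^\]]*)\])?", token)
        if m:
            classes.add("s")
            if m.group(1) is None:
                site_models.update(SITE_MODELS)
            else:
                for code in m.group(1).split(":"):
                    code = code.strip()
                    if code not in _SITE_CODE:
                        raise ParseError(f"unknown site-model code {code!r} in token {token!r}")
                    site_models.add(_SITE_CODE[code])
                if not site_models:
                    raise ParseError(f"empty site-model list in token {token!r}")
        elif token in ("b", "w", "c"):
            classes.add(token)
        else:
            raise ParseError(f"unknown model letter {token!r} in spec {spec!r}")
    return ModelRequest(classes=frozenset(classes), site_models=frozenset(site_models))


def _split_name(name: str, extensions) -> tuple:
    base = name
    ext = ""
    for cand in extensions:
        if name.lower().endswith(cand):
            base = name[: -len(cand)]
            ext = name[-len(cand):]
            break
    else:
        raise ParseError(f"{name!r}: extension not one of {extensions}")
    if "_" not in base:
        raise ParseError(f"{name!r}: no underscore separating name from model suffix")
    stem, suffix = base.rsplit("_", 1)
    if not stem:
        raise ParseError(f"{name!r}: empty gene/reference name")
    return stem, suffix, ext


def parse_msa_filename(name: str, path: str = "") -> MsaIdentity:
    """Decode ``<gene>_<letters><icode>.fas[ta]``.

    The gene name is everything before the LAST underscore, so gene names may
    themselves contain underscores.
    """
    stem, suffix, ext = _split_name(name, MSA_EXTENSIONS)
    m = re.fullmatch(r"([sbwc]+)(\d{1,2})", suffix)
    if not m:
        raise ParseError(f"{name!r}: suffix {suffix!r} is not <letters><icode>")
    letters, icode_s = m.group(1), m.group(2)
    icode = int(icode_s)
    if icode not in ICODE_RANGE:
        raise ParseError(f"{name!r}: icode {icode} outside 0-10")
    return MsaIdentity(gene_name=stem, classes=frozenset(letters), icode=icode,
                       path=path or name, extension=ext.lower())


def parse_tree_filename(name: str, path: str = "") -> TreeIdentity:
    """Decode ``<ref>_<letters>.nwk``; 's' never mixes with branch letters."""
    stem, suffix, ext = _split_name(name, TREE_EXTENSIONS)
    if not re.fullmatch(r"[sbwc]+", suffix):
        raise ParseError(f"{name!r}: suffix {suffix!r} contains non-model letters")
    letters = frozenset(suffix)
    if "s" in letters and letters != {"s"}:
        raise ParseError(
            f"{name!r}: 's' trees are gene-matched and unlabeled; "
            "they cannot combine with branch letters"
        )
    return TreeIdentity(ref_name=stem, classes=letters, path=path or name,
                        extension=ext.lower())


def pair_inputs(msas, trees, request: ModelRequest, warnings=None):
    """Combine MSAs with trees letter-by-letter.

    One :class:`DatasetPair` is produced for every (msa, tree, letter) triple
    where the letter appears in both filenames and in the request; site-model
    pairs additionally require ``msa.gene_name == tree.ref_name``.  Pairs are
    returned sorted by (gene, tree ref, letter).  For every requested MSA
    class with no matching tree a :class:`PairingWarning` is appended to
    *warnings* (if given).
    """
    pairs = []
    for msa in msas:
        for letter in msa.classes & request.classes:
            matched = False
            for tree in trees:
                if letter not in tree.classes:
                    continue
                if letter == "s" and msa.gene_name != tree.ref_name:
                    continue
                pairs.append(DatasetPair(msa=msa, tree=tree, letter=letter))
                matched = True
            if not matched and warnings is not None:
                warnings.append(PairingWarning(msa=msa, letter=letter))
    pairs.sort(key=lambda p: (p.msa.gene_name, p.tree.ref_name, p.letter))
    return pairs
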
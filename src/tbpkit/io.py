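"""Readers and writers for the external formats the TBP pipeline touches.

Capillary-electrophoresis (CE) peak tables, clone label tables, FASTA
(plain and aligned) and newick trees with bootstrap support stored as
internal-node labels.  Taxon names are normalised to a closed canonical
vocabulary on input; hybrid binomials are mapped to a direction-free
token (the cross direction is a property of the plastid, not the name).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import TreeNode

__all__ = [
    "PeakRecord",
    "LabelledClone",
    "TaxonError",
    "PeakTableError",
    "CANONICAL_TAXA",
    "normalize_taxon",
    "read_peak_table",
    "write_peak_table",
    "read_clone_table",
    "write_clone_table",
    "read_fasta",
    "write_fasta",
    "read_newick",
    "write_newick",
]


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeakRecord:
    """One CE peak: a sized amplicon from one intron region of one clone.

    Sizes are in base pairs, heights in relative fluorescence units.
    """

    clone_id: str
    region: int
    size_bp: float
    height_rfu: float

    def __post_init__(self) -> None:
        if self.region not in (1, 2):
            raise ValueError(f"region must be 1 or 2, got {self.region!r}")
        if not self.size_bp > 0:
            raise ValueError(f"size_bp must be positive, got {self.size_bp!r}")
        if self.height_rfu < 0:
            raise ValueError(f"height_rfu must be >= 0, got {self.height_rfu!r}")


@dataclass(frozen=True)
class LabelledClone:
    """A clone with its collection metadata and two species labels.

    ``morph_label`` is the historical morphology-based determination;
    ``tbp_label`` the molecular (TBP) one, empty when not yet assigned.
    """

    clone_id: str
    collection: str
    region_of_origin: str
    country: str
    morph_label: str
    tbp_label: str = ""


class TaxonError(ValueError):
    """Raised for a species token outside the canonical vocabulary."""


class PeakTableError(ValueError):
    """Raised for a malformed peak table (missing columns, bad rows)."""


# ---------------------------------------------------------------------------
# taxon vocabulary
# ---------------------------------------------------------------------------

#: Closed vocabulary of canonical taxon names used throughout the package.
CANONICAL_TAXA: tuple[str, ...] = (
    "L. minor",
    "L. turionifera",
    "L. ×japonica",
    "L. gibba",
    "L. gibba × L. minor",
    "L. disperma",
    "L. obscura",
    "L. trisulca",
    "Landoltia punctata",
)

_SIMPLE_TOKENS = {
    "minor": "L. minor",
    "turionifera": "L. turionifera",
    "japonica": "L. ×japonica",
    "xjaponica": "L. ×japonica",
    "gibba": "L. gibba",
    "disperma": "L. disperma",
    "obscura": "L. obscura",
    "trisulca": "L. trisulca",
    "punctata": "Landoltia punctata",
}

_EPITHET_RE = re.compile(r"(?:lemna|landoltia|l)?\.?\s*×?\s*([a-z]+)$")


def _epithet(token: str) -> str | None:
    """Reduce one binomial-ish token to its specific epithet, if known."""
    token = token.strip().lower().replace("*", "")
    token = re.sub(r"\s+", " ", token)
    # tolerate duplicated genus abbreviations ("L. L. disperma")
    token = re.sub(r"^(l\.\s+)+", "l. ", token)
    m = _EPITHET_RE.match(token)
    if m and m.group(1) in _SIMPLE_TOKENS:
        return m.group(1)
    return None


def normalize_taxon(raw: str) -> str:
    """Map a free-form species label to its canonical taxon name.

    Hybrid binomials (``A × B``, either order, any capitalisation,
    ``x`` or ``×``) map to a direction-free canonical token with parents
    in alphabetical order; the minor × turionifera cross maps to its
    accepted hybrid binomial *L.* ×japonica.  Raises :class:`TaxonError`
    for anything outside the vocabulary.
    """
    if raw is None:
        raise TaxonError("empty taxon token")
    text = raw.replace("*", "").strip()
    if not text:
        raise TaxonError("empty taxon token")
    parts = re.split(r"\s*(?:×|\bx\b)\s*", text.lower())
    parts = [p for p in (q.strip() for q in parts) if p]
    if len(parts) == 2:
        eps = [_epithet(p) for p in parts]
        if all(e is not None for e in eps):
            eps = sorted(eps)
            if eps == ["minor", "turionifera"]:
                return "L. ×japonica"
            return f"{_SIMPLE_TOKENS[eps[0]]} × {_SIMPLE_TOKENS[eps[1]]}"
        # not a cross: a nothotaxon prefix like "×japonica" splits too
    ep = _epithet(text.lower())
    if ep is None:
        raise TaxonError(f"unknown taxon token: {raw!r}")
    return _SIMPLE_TOKENS[ep]


# ---------------------------------------------------------------------------
# peak tables
# ---------------------------------------------------------------------------

_PEAK_COLUMNS = ("clone_id", "region", "size_bp", "height_rfu")


def read_peak_table(path: str | Path, delimiter: str | None = None) -> list[PeakRecord]:
    """Read a delimited CE peak table into :class:`PeakRecord` rows.

    The header must declare ``clone_id, region, size_bp, height_rfu``.
    ``delimiter=None`` sniffs between comma and tab.  Malformed rows are
    reported with their 1-based line numbers.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        first = fh.readline()
        if delimiter is None:
            delimiter = "\t" if first.count("\t") >= first.count(",") else ","
        header = [c.strip() for c in first.rstrip("\n").split(delimiter)]
        missing = [c for c in _PEAK_COLUMNS if c not in header]
        if missing:
            raise PeakTableError(f"{path}: missing column(s) {', '.join(missing)}")
        idx = {c: header.index(c) for c in _PEAK_COLUMNS}
        records: list[PeakRecord] = []
        errors: list[str] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            row = line.rstrip("\n").split(delimiter)
            try:
                records.append(
                    PeakRecord(
                        clone_id=row[idx["clone_id"]].strip(),
                        region=int(row[idx["region"]]),
                        size_bp=float(row[idx["size_bp"]]),
                        height_rfu=float(row[idx["height_rfu"]]),
                    )
                )
            except (ValueError, IndexError) as exc:
                errors.append(f"line {lineno}: {exc}")
        if errors:
            raise PeakTableError(f"{path}: {'; '.join(errors)}")
    return records


def write_peak_table(records: Iterable[PeakRecord], path: str | Path,
                     delimiter: str = ",") -> None:
    """Write peaks as delimited text (inverse of :func:`read_peak_table`)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(_PEAK_COLUMNS)
        for r in records:
            writer.writerow([r.clone_id, r.region, repr(r.size_bp), repr(r.height_rfu)])


# ---------------------------------------------------------------------------
# clone label tables
# ---------------------------------------------------------------------------

_CLONE_COLUMNS = ("clone_id", "collection", "region_of_origin", "country",
                  "morph_label", "tbp_label")


def read_clone_table(path: str | Path, delimiter: str = "\t") -> list[LabelledClone]:
    """Read a clone label table, normalising both species labels.

    Unknown taxon tokens raise :class:`TaxonError` naming the token;
    duplicated clone ids raise ``ValueError``.
    """
    path = Path(path)
    clones: list[LabelledClone] = []
    seen: set[str] = set()
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        missing = [c for c in _CLONE_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")
        for row in reader:
            cid = row["clone_id"].strip()
            if cid in seen:
                raise ValueError(f"{path}: duplicate clone_id {cid!r}")
            seen.add(cid)
            tbp_raw = (row["tbp_label"] or "").strip()
            clones.append(
                LabelledClone(
                    clone_id=cid,
                    collection=row["collection"].strip(),
                    region_of_origin=row["region_of_origin"].strip(),
                    country=row["country"].strip(),
                    morph_label=normalize_taxon(row["morph_label"]),
                    tbp_label=normalize_taxon(tbp_raw) if tbp_raw else "",
                )
            )
    return clones


def write_clone_table(clones: Iterable[LabelledClone], path: str | Path,
                      delimiter: str = "\t") -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(_CLONE_COLUMNS)
        for c in clones:
            writer.writerow([c.clone_id, c.collection, c.region_of_origin,
                             c.country, c.morph_label, c.tbp_label])


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, aligned: bool = False) -> list[SeqRecord]:
    """Read FASTA; with ``aligned=True`` all sequences must be equal length."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if aligned and records:
        lengths = {len(r.seq) for r in records}
        if len(lengths) > 1:
            raise ValueError(
                f"{path}: aligned FASTA has unequal lengths {sorted(lengths)}"
            )
    return records


def write_fasta(records: Iterable[SeqRecord | tuple[str, str]],
                path: str | Path) -> None:
    """Write records (SeqRecord or ``(id, sequence)`` pairs) as FASTA."""
    out = []
    for r in records:
        if isinstance(r, SeqRecord):
            out.append(r)
        else:
            rid, seq = r
            out.append(SeqRecord(Seq(seq), id=rid, description=""))
    SeqIO.write(out, str(path), "fasta")


# ---------------------------------------------------------------------------
# newick with support-as-internal-label
# ---------------------------------------------------------------------------

def write_newick(tree: TreeNode, path: str | Path) -> None:
    """Serialise a tree, writing integer bootstrap supports as the labels
    of internal nodes (the convention consumed by most tree viewers).

    Duplicate leaf labels are rejected.
    """
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        raise ValueError("duplicate leaf labels in tree")
    clone = tree.copy()
    for node in clone.non_tips(include_self=True):
        support = getattr(node, "support", None)
        if support is not None:
            node.name = str(int(round(support)))
            node.support = None  # skbio would otherwise serialise it twice
    clone.write(str(path), format="newick")


def read_newick(path: str | Path) -> TreeNode:
    """Read newick; numeric internal-node labels become ``support`` attributes."""
    tree = TreeNode.read(str(path), format="newick")
    for node in tree.non_tips(include_self=True):
        if node.name is not None:
            try:
                node.support = float(node.name)
            except ValueError:
                pass
            else:
                node.name = None
    return tree
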
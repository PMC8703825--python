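"""Bundled machine-readable fixtures: the published clone label table and
the TUBB2 first-intron haplotype site patterns and clone assignments.

The intron fixtures encode only what was printed — polymorphic-site
positions and per-haplotype states.  :func:`reconstruct_alignment`
rebuilds full-length aligned sequences by placing those states on a
shared constant background, which preserves every quantity the analysis
extracts (site positions, haplotype partition, substitution counts).
The backgrounds are synthetic; the site patterns are not.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from importlib import resources
from itertools import cycle, islice

from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ..io import LabelledClone, read_clone_table

__all__ = [
    "load_clone_table",
    "load_haplotype_patterns",
    "load_haplotype_assignments",
    "published_haplotype_table",
    "reconstruct_alignment",
    "reconstruct_hybrid_subgenomes",
    "HaplotypeAssignment",
]


def _fixture_path(name: str):
    return resources.files(__package__).joinpath(name)


def load_clone_table() -> list[LabelledClone]:
    """The 98-clone survey table (morphology vs TBP labels)."""
    with resources.as_file(_fixture_path("clones.tsv")) as p:
        return read_clone_table(p)


def load_haplotype_patterns() -> dict:
    """Per-species polymorphic-site positions and haplotype state vectors."""
    return json.loads(_fixture_path("haplotype_sites.json").read_text())


@dataclass(frozen=True)
class HaplotypeAssignment:
    species: str
    clone_id: str
    origin: str
    haplotypes: tuple[str, ...]  # one name, or (gibba, minor) pair for hybrids
    resolved: bool               # False for superimposed-chromatogram clones


def load_haplotype_assignments() -> list[HaplotypeAssignment]:
    """Clone-to-haplotype assignments, including the six hybrid clones."""
    out: list[HaplotypeAssignment] = []
    with _fixture_path("haplotype_assignments.tsv").open() as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            hap = (row["haplotype"] or "").strip()
            resolved = hap not in ("", "n.d", "nd")
            out.append(
                HaplotypeAssignment(
                    species=row["species"],
                    clone_id=row["clone_id"],
                    origin=row["origin"],
                    haplotypes=tuple(hap.split()) if resolved else (),
                    resolved=resolved,
                )
            )
    return out


def published_haplotype_table(species: str) -> "HaplotypeTable":
    """A :class:`~tbpkit.haplotypes.HaplotypeTable` carrying the published
    haplotype names (M1–M4 / G1–G3) and clone assignments, built from the
    fixture site patterns rather than rediscovered from sequences."""
    from ..haplotypes import HaplotypeTable, snp_count

    spec = load_haplotype_patterns()[species]
    ref = spec["reference"]
    assignment = {a.clone_id: a.haplotypes[0]
                  for a in load_haplotype_assignments()
                  if a.species == species and a.resolved}
    return HaplotypeTable(
        positions=list(spec["positions"]),
        haplotypes=dict(spec["haplotypes"]),
        assignment=assignment,
        reference=ref,
        snps={name: snp_count(vec, spec["haplotypes"][ref])
              for name, vec in spec["haplotypes"].items()},
    )


def _background(length: int) -> list[str]:
    # arbitrary constant background shared by all sequences of an alignment;
    # only the injected site states can create polymorphism
    return list(islice(cycle("ACGT"), length))


def _sequence_for(species: str, haplotype: str, patterns: dict | None = None) -> str:
    patterns = patterns or load_haplotype_patterns()
    spec = patterns[species]
    seq = _background(spec["alignment_length"])
    states = spec["haplotypes"][haplotype]
    for pos, state in zip(spec["positions"], states):
        seq[pos - 1] = state  # positions are 1-based alignment columns
    return "".join(seq)


def reconstruct_alignment(species: str) -> list[SeqRecord]:
    """Full-length aligned sequences for every sequence-resolved clone of
    ``species``, reconstructed from the fixture site patterns."""
    patterns = load_haplotype_patterns()
    records = []
    for a in load_haplotype_assignments():
        if a.species != species or not a.resolved:
            continue
        seq = _sequence_for(species, a.haplotypes[0], patterns)
        records.append(SeqRecord(Seq(seq), id=a.clone_id, description=""))
    return records


def reconstruct_hybrid_subgenomes() -> dict[str, dict[str, SeqRecord]]:
    """Per-hybrid-clone aligned sequences of the two homoeologous TUBB2
    loci, keyed ``clone_id -> {parental species -> record}``."""
    patterns = load_haplotype_patterns()
    out: dict[str, dict[str, SeqRecord]] = {}
    for a in load_haplotype_assignments():
        if not a.resolved or len(a.haplotypes) != 2:
            continue
        g_hap, m_hap = a.haplotypes
        out[a.clone_id] = {
            "L. gibba": SeqRecord(
                Seq(_sequence_for("L. gibba", g_hap, patterns)),
                id=f"{a.clone_id}|G", description=""),
            "L. minor": SeqRecord(
                Seq(_sequence_for("L. minor", m_hap, patterns)),
                id=f"{a.clone_id}|M", description=""),
        }
    return out
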
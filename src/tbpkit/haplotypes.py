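"""Intron haplotype analysis: polymorphic-site detection, haplotype
partitioning, substitution counting against a reference, and nearest-
haplotype assignment of hybrid subgenome sequences.

Positions are 1-based alignment columns throughout; any 0-based or
half-open conversion happens at I/O boundaries only.  A gap (``-``) is
a bona fide state for site detection (indel columns are polymorphic),
while substitution counting defaults to skipping gapped sites — the two
conventions intron sequence tables customarily mix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio.SeqRecord import SeqRecord

__all__ = ["HaplotypeTable", "SubgenomeAssignment", "polymorphic_sites",
           "call_haplotypes", "snp_count", "assign_subgenomes"]


def _check_aligned(records: Sequence[SeqRecord]) -> int:
    if len(records) < 2:
        raise ValueError("need at least two aligned sequences")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise ValueError(f"unequal alignment lengths: {sorted(lengths)}")
    return lengths.pop()


def polymorphic_sites(aln: Sequence[SeqRecord]) -> list[int]:
    """1-based alignment columns holding ≥2 distinct states.

    Gap counts as a state; ``N`` (ambiguous) characters are ignored, so
    a column varying only in N content is monomorphic.
    """
    length = _check_aligned(aln)
    seqs = [str(r.seq).upper() for r in aln]
    sites = []
    for col in range(length):
        states = {s[col] for s in seqs} - {"N"}
        if len(states) >= 2:
            sites.append(col + 1)
    return sites


@dataclass
class HaplotypeTable:
    """Haplotype partition of an alignment over its polymorphic sites."""

    positions: list[int]                  # 1-based polymorphic columns
    haplotypes: dict[str, str]            # name -> state vector
    assignment: dict[str, str]            # clone id -> haplotype name
    reference: str                        # name of the reference haplotype
    snps: dict[str, int]                  # name -> substitutions vs reference

    def members(self, name: str) -> list[str]:
        return [c for c, h in self.assignment.items() if h == name]


def call_haplotypes(aln: Sequence[SeqRecord], reference_id: str,
                    prefix: str = "H") -> HaplotypeTable:
    """Partition aligned sequences into haplotypes.

    A haplotype is an equivalence class of identical state vectors over
    the polymorphic sites.  Classes are named ``{prefix}1, {prefix}2…``
    in discovery order with the reference sequence's class first, and
    each class's substitution count against the reference (gap-excluded)
    is tabulated.
    """
    ids = [r.id for r in aln]
    if reference_id not in ids:
        raise ValueError(f"reference {reference_id!r} not in alignment")
    positions = polymorphic_sites(aln)
    vectors = {r.id: "".join(str(r.seq).upper()[p - 1] for p in positions)
               for r in aln}
    order = [reference_id] + [i for i in ids if i != reference_id]
    names: dict[str, str] = {}
    for rid in order:
        vec = vectors[rid]
        if vec not in names:
            names[vec] = f"{prefix}{len(names) + 1}"
    ref_vec = vectors[reference_id]
    haplotypes = {name: vec for vec, name in names.items()}
    return HaplotypeTable(
        positions=positions,
        haplotypes=haplotypes,
        assignment={rid: names[vectors[rid]] for rid in ids},
        reference=names[ref_vec],
        snps={name: snp_count(vec, ref_vec) for name, vec in haplotypes.items()},
    )


def snp_count(hap_a: str, hap_b: str,
              indel_mode: str = "exclude_gap_sites") -> int:
    """Substitutions between two state vectors over the same site list.

    ``exclude_gap_sites``: count differing sites where neither state is
    a gap.  ``count_events``: additionally count each maximal run of
    consecutive gap-mismatch sites as a single indel event.
    """
    if len(hap_a) != len(hap_b):
        raise ValueError("state vectors have different lengths")
    if indel_mode not in ("exclude_gap_sites", "count_events"):
        raise ValueError(f"unknown indel_mode {indel_mode!r}")
    subs = 0
    events = 0
    in_gap_run = False
    for x, y in zip(hap_a.upper(), hap_b.upper()):
        gap_mismatch = (x != y) and ("-" in (x, y))
        if x != y and not gap_mismatch:
            subs += 1
        if gap_mismatch and not in_gap_run:
            events += 1
        in_gap_run = gap_mismatch
    return subs + events if indel_mode == "count_events" else subs


@dataclass(frozen=True)
class SubgenomeAssignment:
    """Nearest parental haplotype for one subgenome of a hybrid clone."""

    clone_id: str
    species: str
    haplotype: str | None     # None on a mismatch-count tie
    mismatches: int


def assign_subgenomes(
    hybrid_seqs: Iterable[tuple[str, str, SeqRecord]],
    parental_tables: Mapping[str, HaplotypeTable],
) -> list[SubgenomeAssignment]:
    """Match each hybrid subgenome sequence to its nearest parental
    haplotype.

    ``hybrid_seqs`` yields ``(clone_id, parental species, record)``
    triples; each record must be in the coordinates of that species'
    alignment.  Mismatches are counted over the parental table's
    polymorphic sites; a tie for the minimum leaves the subgenome
    unassigned.
    """
    out: list[SubgenomeAssignment] = []
    for clone_id, species, rec in hybrid_seqs:
        if species not in parental_tables:
            raise ValueError(f"no haplotype table for species {species!r}")
        table = parental_tables[species]
        vec = "".join(str(rec.seq).upper()[p - 1] for p in table.positions)
        scored = sorted(
            ((sum(a != b for a, b in zip(vec, hv)), name)
             for name, hv in table.haplotypes.items()))
        best_mm, best_name = scored[0]
        tie = len(scored) > 1 and scored[1][0] == best_mm
        out.append(SubgenomeAssignment(
            clone_id=clone_id, species=species,
            haplotype=None if tie else best_name, mismatches=best_mm))
    return out
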
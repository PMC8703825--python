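"""Species assignment and interspecific-hybrid detection from the binary
marker matrix, plus plastid-based maternal parent assignment.

A species' *allele pool* is the set of markers carried by (a frequency
threshold of) its reference clones; markers private to one pool are
*diagnostic*.  A hybrid profile is additive: it is covered by the union
of two parental pools while carrying multiple diagnostic markers of
each parent — the explicit, thresholded form of reading two subgenomes
off one electropherogram.  The maternal parent is the reference whose
plastid spacer sequence is nearest to the clone's.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

from Bio import Align
from Bio.SeqRecord import SeqRecord

from .matrix import MarkerMatrix

__all__ = ["AllelePoolSet", "HybridCall", "MaternalCall", "AdditivityStats",
           "build_pools", "assign_species", "additivity", "call_hybrids",
           "assign_maternal"]


# ---------------------------------------------------------------------------
# allele pools
# ---------------------------------------------------------------------------

@dataclass
class AllelePoolSet:
    """Per-species marker pools and their diagnostic (private) subsets."""

    pools: dict[str, frozenset[str]]
    diagnostics: dict[str, frozenset[str]] = field(init=False)
    flagged: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        diag = {}
        for sp, pool in self.pools.items():
            others = frozenset().union(
                *(p for s, p in self.pools.items() if s != sp)) \
                if len(self.pools) > 1 else frozenset()
            diag[sp] = pool - others
        self.diagnostics = diag
        self.flagged = tuple(sorted(s for s, d in diag.items() if not d))

    @property
    def taxa(self) -> list[str]:
        return sorted(self.pools)


def build_pools(m: MarkerMatrix, reference_labels: Mapping[str, str],
                pool_freq: float = 0.8) -> AllelePoolSet:
    """Build per-species pools from labelled reference clones.

    A marker enters a species' pool when present in at least
    ``pool_freq`` of that species' reference clones, so markers private
    to a geographic subgroup do not fragment the pool.  Taxa whose
    diagnostic set comes out empty are flagged on the result.
    """
    if not 0 < pool_freq <= 1:
        raise ValueError("pool_freq must be in (0, 1]")
    missing = [c for c in reference_labels if c not in m.df.index]
    if missing:
        raise ValueError(f"reference clone(s) absent from matrix: {missing}")
    by_taxon: dict[str, list[str]] = {}
    for clone, taxon in reference_labels.items():
        by_taxon.setdefault(taxon, []).append(clone)
    pools = {}
    for taxon, clones in by_taxon.items():
        freq = m.df.loc[clones].mean(axis=0)
        # tiny epsilon so e.g. 4/5 >= 0.8 is not lost to float rounding
        pools[taxon] = frozenset(freq.index[freq >= pool_freq - 1e-12])
    out = AllelePoolSet(pools)
    if out.flagged:
        warnings.warn("taxa with empty diagnostic marker sets: "
                      + ", ".join(out.flagged), stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# species assignment
# ---------------------------------------------------------------------------

def _jaccard_sets(a: frozenset[str], b: frozenset[str]) -> float:
    union = a | b
    if not union:
        return 1.0
    return len(a & b) / len(union)


def assign_species(clone_id: str, m: MarkerMatrix, pools: AllelePoolSet
                   ) -> tuple[str | None, float]:
    """Assign the taxon whose pool is most Jaccard-similar to the clone's
    marker set.  Ties (or an empty profile) yield ``(None, score)``."""
    profile = m.marker_set(clone_id)
    if not profile:
        warnings.warn(f"clone {clone_id!r} has an empty marker profile",
                      stacklevel=2)
        return None, 0.0
    scored = sorted(((sp, _jaccard_sets(profile, pool))
                     for sp, pool in pools.pools.items()),
                    key=lambda t: (-t[1], t[0]))
    best_sp, best = scored[0]
    if len(scored) > 1 and scored[1][1] == best:
        return None, best
    return best_sp, best


# ---------------------------------------------------------------------------
# additivity / hybrid calling
# ---------------------------------------------------------------------------

class AdditivityStats(NamedTuple):
    coverage: float   # fraction of clone markers inside pool(A) ∪ pool(B)
    share_a: int      # diagnostic markers of A carried by the clone
    share_b: int      # diagnostic markers of B carried by the clone


@dataclass(frozen=True)
class HybridCall:
    """Verdict for one clone against its best-covering parent pair."""

    clone_id: str
    parent_a: str
    parent_b: str
    coverage: float
    share_a: int
    share_b: int
    verdict: str                 # "hybrid" | "parental" | "unresolved"
    assigned_taxon: str | None = None   # for parental verdicts
    score: float = 0.0

    @property
    def parent_pair(self) -> frozenset[str]:
        return frozenset((self.parent_a, self.parent_b))


def additivity(clone_id: str, m: MarkerMatrix, pools: AllelePoolSet,
               parent_a: str, parent_b: str) -> AdditivityStats:
    """Coverage of the clone by the union of two parental pools, and the
    counts of each parent's diagnostic markers it carries."""
    for p in (parent_a, parent_b):
        if p not in pools.pools:
            raise ValueError(f"unknown parent taxon {p!r}")
    profile = m.marker_set(clone_id)
    union = pools.pools[parent_a] | pools.pools[parent_b]
    coverage = len(profile & union) / len(profile) if profile else 0.0
    return AdditivityStats(
        coverage=coverage,
        share_a=len(profile & pools.diagnostics[parent_a]),
        share_b=len(profile & pools.diagnostics[parent_b]),
    )


def call_hybrids(m: MarkerMatrix, pools: AllelePoolSet,
                 min_cov: float = 0.9, min_diag: int = 2
                 ) -> list[HybridCall]:
    """Score every clone against every unordered parent pair.

    A clone is called *hybrid* for its best pair when the pair union
    covers ≥ ``min_cov`` of its markers and it carries ≥ ``min_diag``
    diagnostic markers of *each* parent — so a single-parent assignment
    necessarily leaves ≥ ``min_diag`` markers of the second parent
    unexplained.  Otherwise the clone is *parental* (if the single-taxon
    assignment resolves) or *unresolved*.
    """
    taxa = pools.taxa
    if len(taxa) < 2:
        raise ValueError("need pools for at least two taxa")
    calls: list[HybridCall] = []
    pairs = list(itertools.combinations(taxa, 2))
    for clone in m.clone_ids:
        best: tuple | None = None
        for a, b in pairs:
            st = additivity(clone, m, pools, a, b)
            meets = (st.coverage >= min_cov and st.share_a >= min_diag
                     and st.share_b >= min_diag)
            key = (meets, st.coverage, min(st.share_a, st.share_b),
                   st.share_a + st.share_b)
            if best is None or key > best[0]:
                best = (key, a, b, st)
        (meets, *_), a, b, st = best
        if meets:
            calls.append(HybridCall(clone, a, b, st.coverage,
                                    st.share_a, st.share_b, "hybrid"))
        else:
            taxon, score = assign_species(clone, m, pools)
            verdict = "parental" if taxon is not None else "unresolved"
            calls.append(HybridCall(clone, a, b, st.coverage, st.share_a,
                                    st.share_b, verdict,
                                    assigned_taxon=taxon, score=score))
    return calls


# ---------------------------------------------------------------------------
# maternal assignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MaternalCall:
    """Maternal parent from plastid spacer distance; ``None`` on ties or
    when every candidate is farther than ``max_dist``."""

    clone_id: str
    maternal: str | None
    distances: dict[str, float]


def _p_distance(a: str, b: str) -> float:
    """Proportion of mismatching aligned sites, gaps and Ns excluded."""
    if len(a) != len(b):
        aligner = Align.PairwiseAligner(mode="global", match_score=1,
                                        mismatch_score=-1,
                                        open_gap_score=-2,
                                        extend_gap_score=-0.5)
        aln = aligner.align(a.replace("-", ""), b.replace("-", ""))[0]
        a, b = str(aln[0]), str(aln[1])
    pairs = [(x, y) for x, y in zip(a.upper(), b.upper())
             if x not in "-N" and y not in "-N"]
    if not pairs:
        raise ValueError("no comparable aligned sites")
    return sum(x != y for x, y in pairs) / len(pairs)


def assign_maternal(clone_plastid: SeqRecord,
                    parent_refs: Sequence[tuple[str, SeqRecord]] |
                    Mapping[str, SeqRecord],
                    max_dist: float = 0.1) -> MaternalCall:
    """Assign the maternal parent as the unique nearest plastid reference.

    ``parent_refs`` maps candidate parent taxa to their reference spacer
    sequences.  Distance is the mismatch proportion over aligned
    non-gap sites (sequences of unequal length are globally aligned
    first).  A tie for the minimum, or all distances above ``max_dist``,
    yields no call.
    """
    if isinstance(parent_refs, Mapping):
        parent_refs = list(parent_refs.items())
    if len(parent_refs) < 2:
        raise ValueError("need at least two candidate parents")
    query = str(clone_plastid.seq)
    if not query:
        raise ValueError("empty plastid sequence")
    distances = {taxon: _p_distance(query, str(ref.seq))
                 for taxon, ref in parent_refs}
    dmin = min(distances.values())
    nearest = [t for t, d in distances.items() if d == dmin]
    maternal = nearest[0] if len(nearest) == 1 and dmin <= max_dist else None
    return MaternalCall(clone_id=clone_plastid.id, maternal=maternal,
                        distances=distances)
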
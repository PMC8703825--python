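"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates what a TBP fingerprinting experiment on a panel
of duckweed clones produces:

* per-species allele pools over 6 β-tubulin loci × 2 intron regions,
  with every species carrying at least one diagnostic fragment length
  per region once pools have diverged;
* diploid clones emitting one fragment per locus per region, or two
  ("doublets") under length-variant heterozygosity;
* hybrid clones carrying the union of two parental allele sets
  (allotetraploid default) or a per-locus mixture (homoploid option);
* an optional short species-diagnostic extra fragment (a 250 bp
  pseudogene-derived amplicon on one species), after the real situation
  in *L. gibba*;
* maternally inherited plastid spacer sequences, copied verbatim from
  the maternal parent's reference;
* per-species intron alignments with injected haplotype SNP structure;
* CE sizing jitter and peak dropout.

All randomness flows from one integer seed through named
``numpy.random.Generator`` instances; no global state is touched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .io import PeakRecord

__all__ = ["SpeciesPoolSpec", "SimTruth", "SimulatedCohort",
           "simulate_pools", "simulate_clones", "add_ce_noise",
           "N_LOCI", "REGIONS"]

N_LOCI = 6
REGIONS = (1, 2)

# archetypal fragment lengths (bp) per locus per region; species offsets
# are applied on top of these.  Chosen inside the 150–800 bp window CE
# fragment analysis covers for these amplicons.
_BASE_LENGTHS = {
    1: (222.0, 260.0, 301.0, 342.0, 383.0, 424.0),
    2: (210.0, 255.0, 298.0, 352.0, 401.0, 455.0),
}
_LEN_MIN, _LEN_MAX = 150.0, 800.0

_PSEUDOGENE_FRAGMENT = (1, 250.0)  # region, bp — the short diagnostic extra

_PLASTID_LEN = 420
_INTRON_LEN = 410
_SNPS_PER_SPECIES = 6          # plastid substitutions distinguishing species
_HAPLOTYPE_WEIGHTS = (0.6, 0.3, 0.1)   # major / regional / rare haplotype


@dataclass
class SpeciesPoolSpec:
    """Everything that defines one species in the simulator."""

    species: str
    locus_lengths: dict[tuple[int, int], float]        # (locus, region) -> bp
    variant_offsets: dict[tuple[int, int], float]      # doublet partner offset
    variant_prob: float = 0.1
    diagnostic_extras: tuple[tuple[int, float], ...] = ()
    plastid_ref: SeqRecord | None = None
    intron_ref: str = ""
    intron_haplotypes: dict[str, dict[int, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = {(l, r) for l in range(1, N_LOCI + 1) for r in REGIONS}
        if set(self.locus_lengths) != expected:
            raise ValueError("locus_lengths must cover 6 loci × 2 regions")
        if not all(_LEN_MIN <= v <= _LEN_MAX for v in self.locus_lengths.values()):
            raise ValueError(f"lengths must lie in [{_LEN_MIN}, {_LEN_MAX}] bp")
        if not 0 <= self.variant_prob <= 1:
            raise ValueError("variant_prob must be in [0, 1]")

    def region_alleles(self, region: int) -> frozenset[float]:
        base = {v for (l, r), v in self.locus_lengths.items() if r == region}
        base |= {v for (r, v) in self.diagnostic_extras if r == region}
        return frozenset(base)


@dataclass(frozen=True)
class SimTruth:
    """Ground truth for one simulated clone."""

    clone_id: str
    true_taxon: str
    parents: tuple[str, str] | None = None
    maternal_parent: str | None = None
    haplotypes: tuple[tuple[str, str], ...] = ()   # (subgenome species, hap)

    def __post_init__(self) -> None:
        if (self.parents is None) != (self.maternal_parent is None):
            raise ValueError("parents and maternal_parent must co-occur")
        if self.parents and self.maternal_parent not in self.parents:
            raise ValueError("maternal parent must be one of the parents")


@dataclass
class SimulatedCohort:
    """Bundle of everything one simulation run emits."""

    peaks: list[PeakRecord]
    plastid: list[SeqRecord]
    introns: dict[str, list[SeqRecord]]   # species -> aligned records
    truth: list[SimTruth]

    def truth_by_clone(self) -> dict[str, SimTruth]:
        return {t.clone_id: t for t in self.truth}


# ---------------------------------------------------------------------------
# species pools
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _mutate(seq: str, sites: Sequence[int], rng: np.random.Generator) -> str:
    out = list(seq)
    for s in sites:
        out[s] = rng.choice([b for b in "ACGT" if b != out[s]])
    return "".join(out)


def simulate_pools(n_species: int, divergence: float = 8.0,
                   seed: int = 0, pseudogene_extra: bool = True,
                   offset_step: float = 1.0) -> list[SpeciesPoolSpec]:
    """Draw per-species allele pools.

    ``divergence`` is the standard deviation (bp) of the per-locus
    species offsets; at 0 all pools are identical.  For any positive
    divergence the pools are post-checked so that every species keeps at
    least one diagnostic fragment length per region; complete pool
    collisions at small divergence raise a warning, not an error.
    ``offset_step`` quantises the offsets (1 bp default: alleles of
    these introns differ by whole base pairs); a larger step guarantees
    that distinct same-locus alleles are at least that far apart.
    With ``pseudogene_extra`` the third species carries a fixed 250 bp
    region-1 extra fragment, mimicking a retrotransposed pseudogene
    amplicon.
    """
    if n_species < 2:
        raise ValueError("need at least two species")
    if divergence < 0:
        raise ValueError("divergence must be >= 0")
    if offset_step <= 0:
        raise ValueError("offset_step must be > 0")
    rng = np.random.default_rng(seed)

    lengths: list[dict[tuple[int, int], float]] = []
    for _ in range(n_species):
        ll = {}
        for region in REGIONS:
            for locus in range(1, N_LOCI + 1):
                off = (float(np.round(rng.normal(0.0, divergence) / offset_step))
                       * offset_step) if divergence > 0 else 0.0
                ll[(locus, region)] = float(
                    np.clip(_BASE_LENGTHS[region][locus - 1] + off,
                            _LEN_MIN, _LEN_MAX))
        lengths.append(ll)

    if divergence > 0:
        # guarantee ≥1 diagnostic allele per species per region
        for region in REGIONS:
            for i in range(n_species):
                others = {lengths[j][(l, region)]
                          for j in range(n_species) if j != i
                          for l in range(1, N_LOCI + 1)}
                own = {l: lengths[i][(l, region)] for l in range(1, N_LOCI + 1)}
                if not (set(own.values()) - others):
                    locus = 1 + (i % N_LOCI)
                    shift = lengths[i][(locus, region)]
                    while shift in others:
                        shift += offset_step * (1 + i)
                    lengths[i][(locus, region)] = min(shift, _LEN_MAX)
    else:
        warnings.warn("divergence is 0: species pools are identical",
                      stacklevel=2)

    plastid_ancestor = _random_seq(rng, _PLASTID_LEN)
    intron_ancestor = _random_seq(rng, _INTRON_LEN)

    pools: list[SpeciesPoolSpec] = []
    for i in range(n_species):
        # disjoint substitution blocks keep species references distinct
        p_sites = list(range(i * _SNPS_PER_SPECIES, (i + 1) * _SNPS_PER_SPECIES))
        plastid = _mutate(plastid_ancestor, p_sites, rng) if divergence > 0 \
            else plastid_ancestor
        i_sites = list(range(i * 10, i * 10 + 5))
        intron = _mutate(intron_ancestor, i_sites, rng) if divergence > 0 \
            else intron_ancestor
        # three intra-species haplotypes over private late columns
        hap_block = _INTRON_LEN - 40 - i * 12
        hap2 = {hap_block: "A" if intron[hap_block] != "A" else "G",
                hap_block + 1: "C" if intron[hap_block + 1] != "C" else "T"}
        hap3 = {hap_block + k: ("T" if intron[hap_block + k] != "T" else "A")
                for k in range(5)}
        extras: tuple[tuple[int, float], ...] = ()
        if pseudogene_extra and n_species >= 3 and i == 2:
            extras = (_PSEUDOGENE_FRAGMENT,)
        pools.append(SpeciesPoolSpec(
            species=f"sp{i + 1}",
            locus_lengths=lengths[i],
            variant_offsets={k: 3.0 for k in lengths[i]},
            variant_prob=0.1,
            diagnostic_extras=extras,
            plastid_ref=SeqRecord(Seq(plastid), id=f"sp{i + 1}_plastid",
                                  description=""),
            intron_ref=intron,
            intron_haplotypes={"h1": {}, "h2": hap2, "h3": hap3},
        ))
    return pools


# ---------------------------------------------------------------------------
# clones
# ---------------------------------------------------------------------------

def _emit_profile(spec: SpeciesPoolSpec, rng: np.random.Generator,
                  clone_id: str, het_prob: float) -> list[PeakRecord]:
    peaks = []
    for (locus, region), size in sorted(spec.locus_lengths.items(),
                                        key=lambda kv: (kv[0][1], kv[0][0])):
        height = float(rng.uniform(800, 4000))
        peaks.append(PeakRecord(clone_id, region, size, height))
        if rng.random() < het_prob:
            off = spec.variant_offsets[(locus, region)]
            peaks.append(PeakRecord(clone_id, region, size + off,
                                    float(rng.uniform(800, 4000))))
    for region, size in spec.diagnostic_extras:
        peaks.append(PeakRecord(clone_id, region, size,
                                float(rng.uniform(800, 4000))))
    return peaks


def _intron_record(spec: SpeciesPoolSpec, hap: str, rec_id: str) -> SeqRecord:
    seq = list(spec.intron_ref)
    for pos, state in spec.intron_haplotypes[hap].items():
        seq[pos] = state
    return SeqRecord(Seq("".join(seq)), id=rec_id, description="")


def _pick_haplotype(spec: SpeciesPoolSpec, rng: np.random.Generator) -> str:
    names = sorted(spec.intron_haplotypes)
    w = np.array(_HAPLOTYPE_WEIGHTS[:len(names)], dtype=float)
    return str(rng.choice(names, p=w / w.sum()))


def simulate_clones(pools: Sequence[SpeciesPoolSpec], n_per_species: int,
                    hybrids: Sequence[tuple[str, str, str, int]] = (),
                    het_prob: float | None = None,
                    allotetraploid: bool = True,
                    seed: int = 0) -> SimulatedCohort:
    """Emit peak profiles, plastid sequences, intron alignments and truth.

    ``hybrids`` lists ``(parent_a, parent_b, maternal, n)`` tuples;
    each hybrid clone carries the union of both parents' allele sets
    (allotetraploid, the default) or a random one-of-two allele per
    locus (homoploid), copies the maternal parent's plastid reference,
    and contributes one intron sequence per parental subgenome to that
    parent's alignment (record ids ``{clone}|{parent}``).
    """
    rng = np.random.default_rng(seed)
    by_name = {p.species: p for p in pools}
    for pa, pb, mat, _ in hybrids:
        for t in (pa, pb):
            if t not in by_name:
                raise ValueError(f"unknown parent taxon {t!r}")
        if mat not in (pa, pb):
            raise ValueError(f"maternal {mat!r} must be one of the parents")

    peaks: list[PeakRecord] = []
    plastid: list[SeqRecord] = []
    introns: dict[str, list[SeqRecord]] = {p.species: [] for p in pools}
    truth: list[SimTruth] = []

    for spec in pools:
        hp = spec.variant_prob if het_prob is None else het_prob
        for k in range(n_per_species):
            cid = f"{spec.species}_{k:03d}"
            peaks.extend(_emit_profile(spec, rng, cid, hp))
            plastid.append(SeqRecord(spec.plastid_ref.seq, id=cid,
                                     description=""))
            hap = _pick_haplotype(spec, rng)
            introns[spec.species].append(_intron_record(spec, hap, cid))
            truth.append(SimTruth(cid, spec.species,
                                  haplotypes=((spec.species, hap),)))

    for pa, pb, mat, n in hybrids:
        sa, sb = by_name[pa], by_name[pb]
        for k in range(n):
            cid = f"hyb_{pa}x{pb}_{mat}_{k:03d}"
            if allotetraploid:
                for spec in (sa, sb):
                    peaks.extend(_emit_profile(spec, rng, cid, 0.0))
            else:
                for key in sorted(sa.locus_lengths):
                    donor = sa if rng.random() < 0.5 else sb
                    peaks.append(PeakRecord(cid, key[1],
                                            donor.locus_lengths[key],
                                            float(rng.uniform(800, 4000))))
                for spec in (sa, sb):
                    for region, size in spec.diagnostic_extras:
                        peaks.append(PeakRecord(cid, region, size,
                                                float(rng.uniform(800, 4000))))
            plastid.append(SeqRecord(by_name[mat].plastid_ref.seq, id=cid,
                                     description=""))
            haps = []
            for spec in (sa, sb):
                hap = _pick_haplotype(spec, rng)
                introns[spec.species].append(
                    _intron_record(spec, hap, f"{cid}|{spec.species}"))
                haps.append((spec.species, hap))
            truth.append(SimTruth(cid, f"{pa}×{pb}", parents=(pa, pb),
                                  maternal_parent=mat,
                                  haplotypes=tuple(haps)))

    return SimulatedCohort(peaks=peaks, plastid=plastid, introns=introns,
                           truth=truth)


# ---------------------------------------------------------------------------
# CE noise
# ---------------------------------------------------------------------------

def add_ce_noise(peaks: Sequence[PeakRecord], jitter_sd: float = 0.3,
                 dropout_p: float = 0.0, seed: int = 0) -> list[PeakRecord]:
    """Perturb peak sizes with zero-mean Gaussian jitter and drop each
    peak independently with probability ``dropout_p``."""
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    if not 0 <= dropout_p < 1:
        raise ValueError("dropout_p must be in [0, 1)")
    if jitter_sd == 0 and dropout_p == 0:
        return list(peaks)
    rng = np.random.default_rng(seed)
    out = []
    for p in peaks:
        if dropout_p > 0 and rng.random() < dropout_p:
            continue
        size = p.size_bp + (rng.normal(0.0, jitter_sd) if jitter_sd > 0 else 0.0)
        out.append(PeakRecord(p.clone_id, p.region, max(size, 1e-6),
                              p.height_rfu))
    return out
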
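"""End-to-end convenience layer: peaks → matrix → pools → species /
hybrid / maternal calls, plus truth-based recovery statistics for
simulated cohorts and a jitter × dropout degradation grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.SeqRecord import SeqRecord

from .hybrids import (AllelePoolSet, HybridCall, MaternalCall, assign_maternal,
                      build_pools, call_hybrids)
from .matrix import MarkerMatrix, bin_peaks, polymorphic_filter
from .simulate import (SimulatedCohort, add_ce_noise, simulate_clones,
                       simulate_pools)

__all__ = ["CohortResults", "profile_matrix", "classify_cohort",
           "recovery_stats", "accuracy_grid"]


def profile_matrix(peaks, tol_bp: float = 1.0,
                   min_rel_height: float = 0.05) -> MarkerMatrix:
    """Bin CE peaks (both intron regions) and keep polymorphic markers."""
    return polymorphic_filter(bin_peaks(peaks, tol_bp=tol_bp,
                                        min_rel_height=min_rel_height))


@dataclass
class CohortResults:
    matrix: MarkerMatrix
    pools: AllelePoolSet
    calls: dict[str, HybridCall]
    maternal: dict[str, MaternalCall]

    def final_label(self, clone_id: str) -> str | None:
        """Single-string verdict: a taxon name, 'A×B', or None."""
        call = self.calls[clone_id]
        if call.verdict == "hybrid":
            a, b = sorted(call.parent_pair)
            return f"{a}×{b}"
        if call.verdict == "parental":
            return call.assigned_taxon
        return None


def classify_cohort(peaks, reference_labels: Mapping[str, str],
                    plastid: Sequence[SeqRecord] = (),
                    tol_bp: float = 1.0, min_rel_height: float = 0.05,
                    pool_freq: float = 0.8, min_cov: float = 0.9,
                    min_diag: int = 2, max_dist: float = 0.1
                    ) -> CohortResults:
    """Run the full nuclear + plastid classification stack.

    ``reference_labels`` maps curated reference clones to their taxa and
    seeds the allele pools.  Per-species plastid references are taken
    from the first reference clone of each taxon found in ``plastid``;
    maternal parents are then assigned for every clone called hybrid.
    """
    matrix = profile_matrix(peaks, tol_bp=tol_bp, min_rel_height=min_rel_height)
    refs = {c: t for c, t in reference_labels.items() if c in matrix.df.index}
    pools = build_pools(matrix, refs, pool_freq=pool_freq)
    calls = {c.clone_id: c for c in call_hybrids(matrix, pools,
                                                 min_cov=min_cov,
                                                 min_diag=min_diag)}
    plastid_by_clone = {r.id: r for r in plastid}
    species_plastid: dict[str, SeqRecord] = {}
    for clone, taxon in refs.items():
        if taxon not in species_plastid and clone in plastid_by_clone:
            species_plastid[taxon] = plastid_by_clone[clone]

    maternal: dict[str, MaternalCall] = {}
    for cid, call in calls.items():
        if call.verdict != "hybrid" or cid not in plastid_by_clone:
            continue
        candidates = {t: species_plastid[t] for t in call.parent_pair
                      if t in species_plastid}
        if len(candidates) == 2:
            maternal[cid] = assign_maternal(plastid_by_clone[cid], candidates,
                                            max_dist=max_dist)
    return CohortResults(matrix=matrix, pools=pools, calls=calls,
                         maternal=maternal)


def recovery_stats(cohort: SimulatedCohort, results: CohortResults
                   ) -> dict[str, float]:
    """Compare pipeline calls against simulation truth.

    Returns hybrid sensitivity/specificity, parent-pair accuracy (over
    true hybrids), maternal accuracy (over hybrids with a maternal
    call attempt), pure-species assignment accuracy, and the overall
    fraction of clones with a fully correct verdict.
    """
    truth = cohort.truth_by_clone()
    tp = fn = tn = fp = 0
    pair_ok = pair_n = 0
    mat_ok = mat_n = 0
    sp_ok = sp_n = 0
    all_ok = 0
    for cid, t in truth.items():
        call = results.calls.get(cid)
        is_hybrid_call = call is not None and call.verdict == "hybrid"
        if t.parents is not None:
            pair_n += 1
            if is_hybrid_call:
                tp += 1
                good_pair = call.parent_pair == frozenset(t.parents)
                pair_ok += good_pair
                mcall = results.maternal.get(cid)
                mat_n += 1
                if mcall is not None and mcall.maternal == t.maternal_parent:
                    mat_ok += 1
                    if good_pair:
                        all_ok += 1
            else:
                fn += 1
        else:
            sp_n += 1
            if is_hybrid_call:
                fp += 1
            else:
                tn += 1
                if call is not None and call.assigned_taxon == t.true_taxon:
                    sp_ok += 1
                    all_ok += 1
    return {
        "hybrid_sensitivity": tp / pair_n if pair_n else float("nan"),
        "hybrid_specificity": tn / sp_n if sp_n else float("nan"),
        "parent_pair_accuracy": pair_ok / tp if tp else 0.0,
        "maternal_accuracy": mat_ok / mat_n if mat_n else 0.0,
        "species_accuracy": sp_ok / sp_n if sp_n else float("nan"),
        "overall_accuracy": all_ok / len(truth),
    }


def _default_cohort(seed: int, n_species: int = 4, n_per_species: int = 12,
                    divergence: float = 8.0, het_prob: float = 0.1
                    ) -> tuple[SimulatedCohort, dict[str, str]]:
    pools = simulate_pools(n_species, divergence=divergence, seed=seed)
    hybrids = [("sp1", "sp2", "sp1", 3), ("sp1", "sp2", "sp2", 3)]
    cohort = simulate_clones(pools, n_per_species, hybrids=hybrids,
                             het_prob=het_prob, seed=seed + 1)
    refs = {t.clone_id: t.true_taxon for t in cohort.truth
            if t.parents is None}
    return cohort, refs


def accuracy_grid(jitter_values: Sequence[float],
                  dropout_values: Sequence[float],
                  n_seeds: int = 3, seed: int = 0,
                  **cohort_kwargs) -> pd.DataFrame:
    """Mean overall classification accuracy over a jitter × dropout grid,
    averaged over ``n_seeds`` independent cohorts per cell."""
    rows = []
    for jit in jitter_values:
        for drop in dropout_values:
            accs = []
            for s in range(n_seeds):
                base = seed + 1000 * s
                cohort, refs = _default_cohort(base, **cohort_kwargs)
                noisy = add_ce_noise(cohort.peaks, jitter_sd=jit,
                                     dropout_p=drop, seed=base + 7)
                res = classify_cohort(noisy, refs, plastid=cohort.plastid)
                accs.append(recovery_stats(cohort, res)["overall_accuracy"])
            rows.append({"jitter_sd": jit, "dropout_p": drop,
                         "accuracy": float(np.mean(accs))})
    return pd.DataFrame(rows)
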
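"""Morphology-versus-molecular label comparison: the contingency table of
morphological determinations against TBP assignments, with per-row,
per-column and overall misidentification percentages.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import pandas as pd

from .io import LabelledClone

__all__ = ["ContingencyTable", "contingency", "misid_rates"]


@dataclass
class ContingencyTable:
    """Counts of clones by (morphology label, TBP label).

    Rows are morphology, columns TBP; a clone is "correct" when the two
    labels agree.  Clones with a label outside the declared taxon list
    are excluded but reported.
    """

    counts: pd.DataFrame              # rows: morph taxa; cols: TBP taxa
    excluded: tuple[str, ...]         # clone ids left out of the table

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def n_correct(self) -> int:
        return int(sum(self.counts.at[t, t] for t in self.counts.index
                       if t in self.counts.columns))


def contingency(clones: Iterable[LabelledClone],
                taxa: Sequence[str]) -> ContingencyTable:
    """Cross-tabulate morphology labels against TBP labels over ``taxa``.

    Clones whose morphology *or* TBP label falls outside ``taxa`` (or
    whose TBP label is empty) are excluded and listed on the result.
    """
    taxa = list(taxa)
    counts = pd.DataFrame(0, index=taxa, columns=taxa, dtype=int)
    excluded: list[str] = []
    for c in clones:
        if c.morph_label in taxa and c.tbp_label in taxa:
            counts.at[c.morph_label, c.tbp_label] += 1
        else:
            excluded.append(c.clone_id)
    return ContingencyTable(counts=counts, excluded=tuple(excluded))


def _round_half_up(x: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def misid_rates(t: ContingencyTable, decimals: int = 1) -> pd.DataFrame:
    """Misidentification percentages from a contingency table.

    Returns a table with one row per morphology taxon (``row_pct``, the
    percentage of that taxon's clones whose TBP label disagrees), one
    per TBP taxon (``col_pct``), and the overall rate, all rounded
    half-up to ``decimals`` places.  Empty rows/columns report 0.
    """
    if t.total == 0:
        raise ValueError("empty contingency table")
    rows = {}
    for taxon in t.counts.index:
        rt = int(t.counts.loc[taxon].sum())
        diag = int(t.counts.at[taxon, taxon]) if taxon in t.counts.columns else 0
        pct = 100.0 * (rt - diag) / rt if rt else 0.0
        rows[taxon] = {"n": rt, "row_pct": _round_half_up(pct, decimals)}
    cols = {}
    for taxon in t.counts.columns:
        ct = int(t.counts[taxon].sum())
        diag = int(t.counts.at[taxon, taxon]) if taxon in t.counts.index else 0
        pct = 100.0 * (ct - diag) / ct if ct else 0.0
        cols[taxon] = {"n": ct, "col_pct": _round_half_up(pct, decimals)}
    overall = 100.0 * (t.total - t.n_correct) / t.total
    out = pd.DataFrame({
        "n_morph": {k: v["n"] for k, v in rows.items()},
        "row_pct": {k: v["row_pct"] for k, v in rows.items()},
        "n_tbp": {k: v["n"] for k, v in cols.items()},
        "col_pct": {k: v["col_pct"] for k, v in cols.items()},
    })
    out.loc["overall"] = [t.total, _round_half_up(overall, decimals),
                          t.total, _round_half_up(overall, decimals)]
    return out
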
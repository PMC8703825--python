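"""From CE peaks to the binary clones × markers table.

A marker is a fragment-size bin within one intron region, identified as
``R{region}_{size}``.  Peaks are filtered on relative height, clustered
per region by single-linkage with a gap threshold, and scored 1/0 for
presence/absence — the dominant-marker convention of multi-locus
fingerprints.
"""

from __future__ import annotations

import logging
import math
import re
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .io import PeakRecord

__all__ = ["Marker", "MarkerMatrix", "bin_peaks", "merge_regions",
           "polymorphic_filter"]

logger = logging.getLogger(__name__)

_MARKER_RE = re.compile(r"^R(?P<region>[12])_(?P<label>.+)$")


class Marker(NamedTuple):
    """Marker identity: intron region plus bin label (bp, possibly suffixed)."""

    region: int
    label: str

    @property
    def name(self) -> str:
        return f"R{self.region}_{self.label}"

    @classmethod
    def from_name(cls, name: str) -> "Marker":
        m = _MARKER_RE.match(name)
        if not m:
            raise ValueError(f"not a marker name: {name!r}")
        return cls(int(m.group("region")), m.group("label"))


@dataclass
class MarkerMatrix:
    """Binary presence/absence table: rows are clones, columns markers."""

    df: pd.DataFrame  # index: clone ids (str); columns: marker names; values 0/1

    def __post_init__(self) -> None:
        if self.df.index.has_duplicates:
            raise ValueError("duplicate clone ids")
        if self.df.columns.has_duplicates:
            raise ValueError("duplicate markers")
        self.df = self.df.astype(np.uint8)

    # -- accessors ---------------------------------------------------------
    @property
    def clone_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def markers(self) -> list[Marker]:
        return [Marker.from_name(c) for c in self.df.columns]

    @property
    def n_markers(self) -> int:
        return self.df.shape[1]

    def marker_set(self, clone_id: str) -> frozenset[str]:
        """Names of markers present in one clone."""
        row = self.df.loc[clone_id]
        return frozenset(row.index[row.values.astype(bool)])

    def region_marker_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {1: 0, 2: 0}
        for m in self.markers:
            counts[m.region] += 1
        return counts

    # -- serialisation -----------------------------------------------------
    def to_csv(self, path: str | Path, delimiter: str = ",") -> None:
        self.df.to_csv(path, sep=delimiter, index_label="clone_id")

    @classmethod
    def from_csv(cls, path: str | Path, delimiter: str = ",") -> "MarkerMatrix":
        df = pd.read_csv(path, sep=delimiter, index_col="clone_id")
        df.index = df.index.astype(str)
        df.index.name = None
        return cls(df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MarkerMatrix):
            return NotImplemented
        return self.df.equals(other.df)


def _cluster_sizes(sizes: np.ndarray, tol_bp: float) -> list[np.ndarray]:
    """Single-linkage gap clustering of sorted sizes: a gap > tol_bp between
    successive sizes starts a new bin."""
    order = np.argsort(sizes, kind="stable")
    s = sizes[order]
    if len(s) == 0:
        return []
    breaks = np.where(np.diff(s) > tol_bp)[0]
    return [order[idx] for idx in np.split(np.arange(len(s)), breaks + 1)]


def bin_peaks(peaks: Iterable[PeakRecord], tol_bp: float = 1.0,
              min_rel_height: float = 0.05) -> MarkerMatrix:
    """Score CE peaks into a binary marker matrix.

    Peaks below ``min_rel_height`` × (max height of that clone+region
    profile) are discarded as baseline noise.  Surviving sizes are
    clustered per region by single-linkage with gaps > ``tol_bp``
    delimiting bins; the bin label is the rounded mean size.  A clone is
    scored present in a bin if at least one of its surviving peaks falls
    in it.  An empty input yields an empty matrix.
    """
    if not tol_bp > 0:
        raise ValueError("tol_bp must be > 0")
    if not 0 <= min_rel_height < 1:
        raise ValueError("min_rel_height must be in [0, 1)")
    peaks = list(peaks)
    if not peaks:
        return MarkerMatrix(pd.DataFrame(dtype=np.uint8))

    profile_max: dict[tuple[str, int], float] = defaultdict(float)
    for p in peaks:
        key = (p.clone_id, p.region)
        profile_max[key] = max(profile_max[key], p.height_rfu)
    surviving = [p for p in peaks
                 if p.height_rfu >= min_rel_height * profile_max[(p.clone_id, p.region)]]

    clone_ids: list[str] = []
    seen: set[str] = set()
    for p in peaks:  # preserve first-appearance clone order
        if p.clone_id not in seen:
            seen.add(p.clone_id)
            clone_ids.append(p.clone_id)

    columns: dict[str, set[str]] = {}
    for region in (1, 2):
        rp = [p for p in surviving if p.region == region]
        if not rp:
            continue
        sizes = np.array([p.size_bp for p in rp])
        used_labels: set[str] = set()
        for cluster in _cluster_sizes(sizes, tol_bp):
            label = str(int(math.floor(float(np.mean(sizes[cluster])) + 0.5)))
            # adjacent bins can round to the same integer; disambiguate
            suffix, candidate = "", label
            while candidate in used_labels:
                suffix += "b"
                candidate = label + suffix
            used_labels.add(candidate)
            columns[Marker(region, candidate).name] = {rp[i].clone_id for i in cluster}

    names = sorted(columns, key=lambda n: (Marker.from_name(n).region,
                                           float(re.sub(r"b+$", "", n.split("_", 1)[1]))
                                           , n))
    data = np.zeros((len(clone_ids), len(names)), dtype=np.uint8)
    index = {c: i for i, c in enumerate(clone_ids)}
    for j, name in enumerate(names):
        for clone in columns[name]:
            data[index[clone], j] = 1
    return MarkerMatrix(pd.DataFrame(data, index=clone_ids, columns=names))


def merge_regions(m1: MarkerMatrix, m2: MarkerMatrix) -> MarkerMatrix:
    """Concatenate the marker sets of two (region) matrices over the union
    of their clones; clones absent from one matrix get all-zero rows there."""
    clones = list(m1.df.index) + [c for c in m2.df.index if c not in m1.df.index]
    left = m1.df.reindex(clones, fill_value=0)
    right = m2.df.reindex(clones, fill_value=0)
    overlap = set(left.columns) & set(right.columns)
    if overlap:
        raise ValueError(f"marker name collision across matrices: {sorted(overlap)}")
    df = pd.concat([left, right], axis=1)
    df = df[sorted(df.columns, key=lambda n: (Marker.from_name(n).region, n))]
    return MarkerMatrix(df)


def polymorphic_filter(m: MarkerMatrix) -> MarkerMatrix:
    """Drop monomorphic markers (present in every clone or in none).

    The per-region counts of retained markers are logged and available
    via :meth:`MarkerMatrix.region_marker_counts` on the result.
    """
    if m.df.empty:
        return MarkerMatrix(m.df.copy())
    n = len(m.df)
    col_sums = m.df.sum(axis=0)
    keep = (col_sums > 0) & (col_sums < n)
    out = MarkerMatrix(m.df.loc[:, keep].copy())
    logger.info("polymorphic markers retained per region: %s",
                out.region_marker_counts())
    return out
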
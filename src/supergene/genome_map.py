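"""Marker-based scaffold placement on pseudo-chromosomes.

Scaffolds are placed on linkage groups using RAD-style markers from several
family linkage maps. Three rules are applied before placement:

1. *Low-confidence filtering*: a scaffold represented in only one
   single-queen family map with fewer than four markers there is removed
   (single-queen maps cannot separate supergene markers reliably, so sparse
   single-map support is treated as unreliable).
2. *Chimera splitting*: a scaffold whose markers map to two or more linkage
   groups is split, keeping only the portions spanned by each group's
   markers; interleaved marker ranges are an irresolvable chimera and raise.
3. *Placement*: within each linkage group, segments are ordered by mean
   marker cM; orientation is the sign of the cM-vs-bp correlation among a
   segment's markers ("unknown" for a single marker or tied cM).

Internally segment coordinates are 0-based half-open; the marker table and
VCF/GFF positions are 1-based, converted at the boundary by
:func:`to_internal` / :func:`to_external`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Segment",
    "GenomeMap",
    "filter_low_confidence_scaffolds",
    "split_chimeric_scaffolds",
    "build_map",
    "anchor_markers",
    "to_internal",
    "to_external",
]


def to_internal(pos_1based: int) -> int:
    """1-based inclusive coordinate -> 0-based half-open start."""
    return pos_1based - 1


def to_external(pos_0based: int) -> int:
    return pos_0based + 1


@dataclass(frozen=True)
class Segment:
    """A placed scaffold segment: [start, end) 0-based on the scaffold,
    assigned to a linkage group at a pseudo-chromosome offset."""

    scaffold: str
    start: int
    end: int
    linkage_group: str
    order: int
    orientation: str  # '+', '-', or 'unknown'
    pseudo_start: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeMap:
    segments: list[Segment]

    def by_group(self) -> dict[str, list[Segment]]:
        out: dict[str, list[Segment]] = {}
        for s in self.segments:
            out.setdefault(s.linkage_group, []).append(s)
        for group in out.values():
            group.sort(key=lambda s: s.order)
        return out

    @property
    def total_placed(self) -> int:
        return sum(s.length for s in self.segments)

    def locate(self, scaffold: str, pos0: int) -> tuple[str, int] | None:
        """Map a 0-based scaffold position to (linkage group, pseudo-coordinate),
        or None if the position falls outside every placed segment."""
        for s in self.segments:
            if s.scaffold == scaffold and s.start <= pos0 < s.end:
                if s.orientation == "-":
                    return s.linkage_group, s.pseudo_start + (s.end - 1 - pos0)
                return s.linkage_group, s.pseudo_start + (pos0 - s.start)
        return None

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"scaffold": s.scaffold, "seg_start": s.start, "seg_end": s.end,
             "linkage_group": s.linkage_group, "order": s.order,
             "orientation": s.orientation, "pseudo_start": s.pseudo_start}
            for s in self.segments
        ])


def filter_low_confidence_scaffolds(markers: pd.DataFrame) -> pd.DataFrame:
    """Drop scaffolds whose markers all come from exactly one family map,
    that map is from a single-queen family, and there are fewer than four
    markers in it."""
    drop = set()
    for scaf, sub in markers.groupby("scaffold"):
        fams = sub["family_id"].unique()
        if len(fams) != 1:
            continue
        ftype = sub["family_type"].iloc[0]
        if ftype == "single-queen" and len(sub) < 4:
            drop.add(scaf)
    return markers[~markers["scaffold"].isin(drop)].reset_index(drop=True)


def split_chimeric_scaffolds(markers: pd.DataFrame):
    """Split scaffolds with markers on several linkage groups.

    Returns (markers with a ``segment`` column naming the retained
    [min, max] marker range of each linkage group, report DataFrame).
    Markers are never reassigned between linkage groups; scaffold bases
    outside every per-group marker range are dropped from the map.
    """
    out = markers.copy()
    out["segment"] = out["scaffold"]
    report = []
    for scaf, sub in markers.groupby("scaffold"):
        groups = sub["linkage_group"].unique()
        if len(groups) < 2:
            continue
        ranges = {}
        for lg, lg_sub in sub.groupby("linkage_group"):
            ranges[lg] = (int(lg_sub["pos"].min()), int(lg_sub["pos"].max()))
        ordered = sorted(ranges.items(), key=lambda kv: kv[1])
        for (lg1, r1), (lg2, r2) in zip(ordered, ordered[1:]):
            if r2[0] <= r1[1]:
                raise ValueError(
                    f"scaffold {scaf}: marker ranges of {lg1} and {lg2} "
                    "interleave — irresolvable chimera")
        for k, (lg, (lo, hi)) in enumerate(ordered):
            seg = f"{scaf}_part{k + 1}"
            sel = (out["scaffold"] == scaf) & (out["linkage_group"] == lg)
            out.loc[sel, "segment"] = seg
            report.append({"scaffold": scaf, "segment": seg,
                           "linkage_group": lg, "range_start": lo,
                           "range_end": hi})
    return out, pd.DataFrame(report)


def build_map(markers: pd.DataFrame,
              scaffold_lengths: dict[str, int] | None = None) -> GenomeMap:
    """Place (possibly split) scaffold segments on linkage groups.

    Segments are ordered within a linkage group by mean marker cM.
    Orientation is '+' when cM increases with bp among the segment's
    markers, '-' when it decreases, 'unknown' for a single marker or zero
    correlation. Unsplit scaffolds span their full length when
    ``scaffold_lengths`` is given, else their marker range.
    """
    if "segment" not in markers.columns:
        markers = markers.copy()
        markers["segment"] = markers["scaffold"]
    seg_rows = []
    for (seg, scaf, lg), sub in markers.groupby(["segment", "scaffold", "linkage_group"]):
        if seg == scaf and scaffold_lengths and scaf in scaffold_lengths:
            start0, end0 = 0, scaffold_lengths[scaf]
        else:
            start0 = to_internal(int(sub["pos"].min()))
            end0 = int(sub["pos"].max())  # 1-based inclusive == 0-based exclusive
        if len(sub) < 2 or sub["cM"].nunique() < 2 or sub["pos"].nunique() < 2:
            orient = "unknown"
        else:
            r = np.corrcoef(sub["pos"], sub["cM"])[0, 1]
            orient = "+" if r > 0 else ("-" if r < 0 else "unknown")
        seg_rows.append({
            "segment": seg, "scaffold": scaf, "linkage_group": lg,
            "start": start0, "end": end0, "mean_cm": float(sub["cM"].mean()),
            "orientation": orient,
        })
    df = pd.DataFrame(seg_rows)
    segments = []
    for lg, sub in df.groupby("linkage_group"):
        sub = sub.sort_values(["mean_cm", "segment"]).reset_index(drop=True)
        offset = 0
        for order, row in sub.iterrows():
            segments.append(Segment(
                scaffold=row["scaffold"], start=int(row["start"]),
                end=int(row["end"]), linkage_group=lg, order=int(order),
                orientation=row["orientation"], pseudo_start=offset,
            ))
            offset += int(row["end"]) - int(row["start"])
    return GenomeMap(segments)


def anchor_markers(markers: pd.DataFrame,
                   flag_column: str = "cosegregates_gp9") -> set[str]:
    """Scaffolds containing at least one marker cosegregating with the
    anchor locus (Gp-9, the diagnostic supergene marker)."""
    if flag_column not in markers.columns:
        return set()
    flagged = markers[markers[flag_column].astype(bool)]
    return set(flagged["scaffold"].unique())
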
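"""Ago2 CLIP peak overlap and conservation-based site prioritization.

Predicted seed sites are annotated with (a) whether an Ago2 CLIP peak
overlaps them (>= 1 nt intersection under half-open semantics, by default)
and the height of the tallest overlapping peak, and (b) the mean per-base
conservation score over the site span, classified Cons / Noncons at a
strict threshold (default score > 0.6).  Candidates are then ranked:
Ago2-bound first, then by peak height, then conservation, then position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import DataError, ParameterError
from .seedscan import SeedSite

CONS = "Cons"
NONCONS = "Noncons"
DEFAULT_CONS_THRESHOLD = 0.6


@dataclass(frozen=True)
class Peak:
    """A CLIP peak: reference id, 0-based half-open interval, height > 0."""

    ref_id: str
    start: int
    end: int
    height: float

    def __post_init__(self):
        if self.end <= self.start:
            raise DataError(f"empty peak interval [{self.start}, {self.end})")
        if self.height <= 0:
            raise DataError("peak height must be positive")


@dataclass
class ConservationTrack:
    """Per-base conservation scores keyed by reference (UTR) id.

    Bases not covered by the track score 0 (conservative toward Noncons).
    """

    scores: dict[str, np.ndarray] = field(default_factory=dict)

    def mean_over(self, ref_id: str, start: int, end: int) -> float:
        if end <= start:
            raise DataError("empty interval")
        arr = self.scores.get(ref_id)
        if arr is None:
            return 0.0
        padded = np.zeros(end - start)
        lo = max(start, 0)
        hi = min(end, arr.size)
        if hi > lo:
            padded[lo - start : hi - start] = arr[lo:hi]
        return float(padded.mean())


@dataclass
class AnnotatedSite:
    """A seed site plus Ago2-overlap and conservation annotations."""

    site: SeedSite
    ago2: bool = False
    peak_height: float = 0.0
    cons_score: float = float("nan")
    cons_class: str | None = None


def overlap_sites_peaks(
    sites: list[SeedSite],
    peaks: list[Peak],
    min_overlap: int = 1,
    mode: str = "any",
    valid_refs: set[str] | None = None,
) -> list[AnnotatedSite]:
    """Flag each site with Ago2 overlap and max overlapping peak height.

    ``mode="any"`` requires an intersection of at least ``min_overlap`` nt;
    ``mode="within"`` requires the site to lie entirely inside a peak.
    ``valid_refs``, when given, defines the shared coordinate frame: any
    site or peak on an unknown reference raises :class:`DataError`.
    """
    if min_overlap < 1:
        raise ParameterError("min_overlap must be >= 1")
    if mode not in ("any", "within"):
        raise ParameterError(f"unknown overlap mode {mode!r}")
    if valid_refs is not None:
        for s in sites:
            if s.utr_id not in valid_refs:
                raise DataError(f"site on unknown reference {s.utr_id!r}")
        for p in peaks:
            if p.ref_id not in valid_refs:
                raise DataError(f"peak on unknown reference {p.ref_id!r}")

    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        trees.setdefault(p.ref_id, IntervalTree()).addi(p.start, p.end, p.height)

    out: list[AnnotatedSite] = []
    for s in sites:
        tree = trees.get(s.utr_id)
        height = 0.0
        hit = False
        if tree is not None:
            for iv in tree.overlap(s.start, s.end):
                inter = min(iv.end, s.end) - max(iv.begin, s.start)
                if mode == "within":
                    ok = iv.begin <= s.start and iv.end >= s.end
                else:
                    ok = inter >= min_overlap
                if ok:
                    hit = True
                    height = max(height, iv.data)
        out.append(AnnotatedSite(site=s, ago2=hit, peak_height=height))
    return out


def conservation_class(
    site: SeedSite,
    track: ConservationTrack,
    threshold: float = DEFAULT_CONS_THRESHOLD,
) -> tuple[float, str]:
    """Mean per-base conservation over the site; Cons iff score > threshold."""
    score = track.mean_over(site.utr_id, site.start, site.end)
    return score, (CONS if score > threshold else NONCONS)


def annotate_conservation(
    annotated: list[AnnotatedSite],
    track: ConservationTrack,
    threshold: float = DEFAULT_CONS_THRESHOLD,
) -> list[AnnotatedSite]:
    """Fill cons_score / cons_class in place and return the list."""
    for a in annotated:
        a.cons_score, a.cons_class = conservation_class(a.site, track, threshold)
    return annotated


def rank_candidates(annotated: list[AnnotatedSite]) -> list[AnnotatedSite]:
    """Stable-sort candidates by (Ago2, peak height, conservation, position).

    Ago2-overlapped sites come first, then taller peaks, then higher
    conservation; ties break on (utr_id, start) ascending so the order is
    total and deterministic.
    """
    def key(a: AnnotatedSite):
        cons = a.cons_score if np.isfinite(a.cons_score) else 0.0
        return (not a.ago2, -a.peak_height, -cons, a.site.utr_id, a.site.start)

    return sorted(annotated, key=key)


def enrichment_table(
    annotated: list[AnnotatedSite],
    validated: list[bool],
) -> pd.DataFrame:
    """Tabulate validation outcomes by Ago2 overlap and conservation class.

    Returns one row per (ago2, cons_class) cell plus per-Ago2 marginal rows
    (cons_class = "all"), with candidate counts, validated counts, and the
    validated fraction.
    """
    if len(annotated) != len(validated):
        raise DataError("validated flags must align with annotated sites")
    rows = []
    df = pd.DataFrame(
        {
            "ago2": [a.ago2 for a in annotated],
            "cons_class": [a.cons_class if a.cons_class else NONCONS for a in annotated],
            "validated": list(validated),
        }
    )
    for ago2 in (True, False):
        sub_a = df[df["ago2"] == ago2]
        for cons in (CONS, NONCONS):
            sub = sub_a[sub_a["cons_class"] == cons]
            rows.append(_cell(ago2, cons, sub))
        rows.append(_cell(ago2, "all", sub_a))
    return pd.DataFrame(rows)


def _cell(ago2: bool, cons: str, sub: pd.DataFrame) -> dict:
    n = len(sub)
    nv = int(sub["validated"].sum())
    return {
        "ago2": ago2,
        "cons_class": cons,
        "n": n,
        "n_validated": nv,
        "frac_validated": nv / n if n else float("nan"),
    }
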
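"""Ranking of the fragments that drive section-to-section matching.

Canonical fragments are ordered by NO (total matched offset pairs across
all section pairs), fragments with NO <= 10 are dropped, equal-NO groups
keep only their lexicographically smallest member, and the first 50 survive.
The same ranking can be restricted to the catalog of sections that showed a
significant specific FEC-FMF correlation, which is what separates
microsatellite background from the satellite families of interest.  Ranked
fragments are exported as FASTA for external annotation (e.g. BLAST); an
annotation table can be merged back, while the microsatellite class is
detected internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .matching import FragmentCatalog, classify_microsatellite

log = logging.getLogger(__name__)

DEFAULT_MIN_NO = 10
DEFAULT_TOP_K = 50
MICROSATELLITE_CLASS = "microsatellite"
UNKNOWN_CLASS = "other/unknown"


@dataclass(frozen=True)
class RankedFragment:
    fragment: str
    no: int
    motif: str | None  # microsatellite motif, when the fragment is one
    cls: str | None = None


@dataclass
class FragmentRanking:
    L: int
    scope: str  # "all-sections" or a description of the restricted subset
    entries: list[RankedFragment] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


def rank_fragments(
    catalog: FragmentCatalog,
    min_no: int = DEFAULT_MIN_NO,
    top_k: int = DEFAULT_TOP_K,
    scope: str = "all-sections",
) -> FragmentRanking:
    """Top fragments by NO with the tie and threshold rules above."""
    if not catalog.no:
        log.warning("empty fragment catalog: empty ranking")
        return FragmentRanking(L=catalog.L, scope=scope)
    by_no: dict[int, str] = {}
    for frag, no in catalog.no.items():
        if no <= min_no:
            continue
        if no not in by_no or frag < by_no[no]:
            by_no[no] = frag
    entries = [
        RankedFragment(fragment=f, no=no, motif=classify_microsatellite(f))
        for no, f in sorted(by_no.items(), reverse=True)[:top_k]
    ]
    return FragmentRanking(L=catalog.L, scope=scope, entries=entries)


def restrict_catalog(
    catalog: FragmentCatalog,
    subset: set[str] | list[str],
    require_both: bool = False,
) -> FragmentCatalog:
    """Recompute NO over match events touching the section subset.

    By default an event counts when at least one of its two sections is in
    the subset (the subset names anchors of significant correlations);
    ``require_both=True`` demands both.
    """
    if catalog.pair_fragments is None:
        raise ValueError("catalog was built without per-pair fragment lists")
    subset = set(subset)
    if catalog.labels is not None:
        unknown = subset - set(catalog.labels)
        if unknown:
            raise KeyError(f"unknown section labels: {sorted(unknown)}")
    keep = (lambda a, b: a in subset and b in subset) if require_both else (
        lambda a, b: a in subset or b in subset
    )
    no: dict[str, int] = {}
    pair_fragments: dict[tuple[str, str], dict[str, int]] = {}
    for (a, b), frags in catalog.pair_fragments.items():
        if not keep(a, b):
            continue
        pair_fragments[(a, b)] = dict(frags)
        for frag, cnt in frags.items():
            no[frag] = no.get(frag, 0) + cnt
    return FragmentCatalog(
        L=catalog.L, no=no, pair_fragments=pair_fragments, labels=catalog.labels
    )


def export_fasta(ranking: FragmentRanking, path: str | Path) -> None:
    """Write the ranking as FASTA, records named ``frag_<rank>_NO<NO>``."""
    if not ranking.entries:
        log.warning("empty ranking: writing empty FASTA %s", path)
    with open(path, "w") as fh:
        for rank, e in enumerate(ranking.entries, start=1):
            fh.write(f">frag_{rank}_NO{e.no}\n{e.fragment}\n")


def annotate_classes(
    ranking: FragmentRanking, annotation: dict[str, str] | pd.DataFrame | None = None
) -> FragmentRanking:
    """Attach sequence classes: microsatellites are detected internally,
    other classes come from a user-supplied fragment -> class table
    (typically parsed BLAST output); the rest are "other/unknown"."""
    if isinstance(annotation, pd.DataFrame):
        annotation = dict(zip(annotation["fragment"], annotation["class"]))
    annotation = annotation or {}
    entries = []
    for e in ranking.entries:
        if e.motif is not None:
            cls = MICROSATELLITE_CLASS
        else:
            cls = annotation.get(e.fragment, UNKNOWN_CLASS)
        entries.append(RankedFragment(e.fragment, e.no, e.motif, cls))
    return FragmentRanking(L=ranking.L, scope=ranking.scope, entries=entries)


def write_ranking_tsv(ranking: FragmentRanking, path: str | Path) -> None:
    rows = [
        (i, e.fragment, e.no, e.cls or "", e.motif or "")
        for i, e in enumerate(ranking.entries, start=1)
    ]
    pd.DataFrame(rows, columns=["rank", "fragment", "NO", "class", "motif"]).to_csv(
        path, sep="\t", index=False
    )


def read_annotation_tsv(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["fragment"], df["class"]))
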
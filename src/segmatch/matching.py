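"""Exact two-strand fragment matching between chromosome sections.

Every length-``L`` window (step 1 nt) of a section is a *fragment*.  Two
sections match at an ordered offset pair ``(i, j)`` when the fragments are
identical on the same strand or across strands (one equals the reverse
complement of the other); a palindromic coincidence is counted once.  The
count is accumulated with multiplicity, which makes the pair table symmetric
and makes fragment occurrence numbers (NO) an exact conservation law:
``sum(NO) == sum of all pair counts``.

Fragments are keyed by their *canonical* form, the lexicographic minimum of
the fragment and its reverse complement, so the two strands collapse to one
catalog entry.  With that convention the pair count factorizes as::

    count(A, B) = sum_c  dA[c] * dB[c]

where ``dX[c]`` is the number of enumerated windows of X whose canonical
form is ``c`` — the production counter exploits this instead of running a
multi-pattern automaton, which for equal-length patterns reduces to exactly
this dictionary scan.  A naive O(|A|·|B|) oracle in the test suite checks
the equivalence.

Low-complexity (microsatellite-like) fragments can be excluded: a fragment
is dropped when it contains, at any offset, a run of at least
``min_consecutive_units`` identical motifs for some rule — by default four
mononucleotides, three dinucleotides or two trinucleotides.  Fragments
containing ``n`` are always dropped.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .sections import Section, SectionSet

log = logging.getLogger(__name__)

_COMP = str.maketrans("acgt", "tgca")
_COMP_N = str.maketrans("acgtn", "tgcan")

DEFAULT_REPEAT_RULES: tuple[tuple[int, int], ...] = ((1, 4), (2, 3), (3, 2))


@dataclass(frozen=True)
class MatchConfig:
    """Parameters of fragment enumeration and matching."""

    L: int
    exclude_repeats: bool = False
    repeat_rules: tuple[tuple[int, int], ...] = DEFAULT_REPEAT_RULES

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("fragment length L must be >= 1")
        for m, u in self.repeat_rules:
            if m < 1 or u < 2:
                raise ValueError(f"invalid repeat rule ({m}, {u})")


@dataclass
class PairMatchTable:
    """Symmetric raw match counts per section pair (diagonal unused)."""

    sections: SectionSet
    config: MatchConfig
    counts: np.ndarray  # (N, N) int64

    @property
    def L(self) -> int:
        return self.config.L

    def total(self) -> int:
        """Sum of counts over unordered pairs."""
        iu = np.triu_indices(len(self.sections), k=1)
        return int(self.counts[iu].sum())


@dataclass
class FragmentCatalog:
    """Canonical fragment -> NO (matched offset pairs over all section pairs).

    ``pair_fragments`` keeps, when requested, the per-pair breakdown:
    ``(labelA, labelB) -> {canonical fragment: matched pair count}`` with
    ``labelA`` before ``labelB`` in chromosomal order.
    """

    L: int
    no: dict[str, int] = field(default_factory=dict)
    pair_fragments: dict[tuple[str, str], dict[str, int]] | None = None
    labels: tuple[str, ...] | None = None

    def total(self) -> int:
        return sum(self.no.values())


def revcomp(seq: str) -> str:
    """Reverse complement over {a,c,g,t}; other codes are an error."""
    if set(seq) - set("acgt"):
        raise ValueError(f"revcomp: non-acgt characters in {seq!r}")
    return seq.translate(_COMP)[::-1]


def canonical(frag: str) -> str:
    """Lexicographic min of a fragment and its reverse complement."""
    return min(frag, revcomp(frag))


def is_simple_repeat(
    frag: str, rules: Iterable[tuple[int, int]] = DEFAULT_REPEAT_RULES
) -> bool:
    """True iff ``frag`` contains a run of ``u`` identical ``m``-mers in a row
    for some rule ``(m, u)``, at any offset."""
    n = len(frag)
    for m, u in rules:
        r = m * u
        if r > n:
            continue
        for i in range(n - r + 1):
            motif = frag[i : i + m]
            if frag[i : i + r] == motif * u:
                return True
    return False


def _valid_window_mask(seq: str, config: MatchConfig) -> np.ndarray:
    """Boolean mask over window offsets 0..len-L: True where the window is
    enumerated (no ``n``; passes the repeat filter if enabled)."""
    L = config.L
    n = len(seq)
    if n < L:
        return np.zeros(0, dtype=bool)
    a = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    n_offsets = n - L + 1

    # window contains no 'n'
    is_n = (a == ord("n")).astype(np.int64)
    cs = np.concatenate([[0], np.cumsum(is_n)])
    valid = (cs[L:] - cs[:-L]) == 0

    if config.exclude_repeats:
        # positions p where a full repeat run of rule (m, u) starts
        for m, u in config.repeat_rules:
            r = m * u
            if r > n:
                continue
            eq = a[m:] == a[:-m]  # eq[p]: base p repeats m later
            need = r - m  # run needs eq true at p .. p+r-m-1
            ec = np.concatenate([[0], np.cumsum(eq.astype(np.int64))])
            hit = (ec[need:] - ec[:-need]) == need  # length n-m-need+1 = n-r+1
            if r > L:
                continue  # run longer than a window can never be contained
            # window at i is excluded iff some hit p with i <= p <= i+L-r
            hc = np.concatenate([[0], np.cumsum(hit.astype(np.int64))])
            span = L - r + 1
            starts = np.arange(n_offsets)
            ends = np.minimum(starts + span, len(hit))
            ends = np.maximum(ends, starts)
            covered = (hc[ends] - hc[starts]) > 0
            valid &= ~covered
    return valid


def enumerate_fragments(
    section: Section | str, config: MatchConfig
) -> list[tuple[int, str]]:
    """All enumerated ``(offset, fragment)`` windows of a section, step 1 nt."""
    seq = section if isinstance(section, str) else section.sequence
    if len(seq) < config.L:
        log.debug("sequence shorter than L=%d: no fragments", config.L)
        return []
    mask = _valid_window_mask(seq, config)
    L = config.L
    return [(int(i), seq[i : i + L]) for i in np.flatnonzero(mask)]


def _canonical_counts(seq: str, config: MatchConfig) -> Counter[str]:
    """Counter of canonical fragments over the enumerated windows of ``seq``."""
    L = config.L
    counts: Counter[str] = Counter()
    if len(seq) < L:
        return counts
    mask = _valid_window_mask(seq, config)
    rc = seq.translate(_COMP_N)[::-1]
    n = len(seq)
    for i in np.flatnonzero(mask):
        f = seq[i : i + L]
        r = rc[n - L - i : n - i]
        counts[f if f <= r else r] += 1
    return counts


def count_pair_matches(
    seq_a: str, seq_b: str, config: MatchConfig
) -> tuple[int, Counter[str]]:
    """Count matched ordered offset pairs between two sequences.

    Returns the total and the per-canonical-fragment breakdown.  A pair
    ``(i, j)`` matches when the windows are equal on the same strand or
    across strands; a palindromic fragment satisfying both is counted once.
    """
    da = _canonical_counts(seq_a, config)
    db = _canonical_counts(seq_b, config)
    if len(db) < len(da):
        da, db = db, da
    frags = Counter({c: k * db[c] for c, k in da.items() if c in db})
    return sum(frags.values()), frags


def build_match_tables(
    ss: SectionSet,
    config: MatchConfig,
    keep_pair_fragments: bool = True,
) -> tuple[PairMatchTable, FragmentCatalog]:
    """Raw symmetric match-count table and fragment catalog for all pairs.

    Uses a single inverted index canonical fragment -> sections carrying it,
    so sections' unique background fragments cost O(1) each.
    """
    N = len(ss)
    for s in ss:
        if not s.sequence:
            raise ValueError(f"section {s.label!r} has no extracted sequence")

    postings: dict[str, list[tuple[int, int]]] = {}
    for idx, s in enumerate(ss):
        for c, k in _canonical_counts(s.sequence, config).items():
            postings.setdefault(c, []).append((idx, k))

    counts = np.zeros((N, N), dtype=np.int64)
    no: dict[str, int] = {}
    pair_fragments: dict[tuple[str, str], dict[str, int]] | None = (
        {} if keep_pair_fragments else None
    )
    labels = ss.labels
    for c, post in postings.items():
        if len(post) < 2:
            continue
        for x in range(len(post)):
            i, ki = post[x]
            for y in range(x + 1, len(post)):
                j, kj = post[y]
                m = ki * kj
                counts[i, j] += m
                counts[j, i] += m
                no[c] = no.get(c, 0) + m
                if pair_fragments is not None:
                    key = (labels[i], labels[j]) if i < j else (labels[j], labels[i])
                    pair_fragments.setdefault(key, {})[c] = m
    table = PairMatchTable(sections=ss, config=config, counts=counts)
    catalog = FragmentCatalog(
        L=config.L, no=no, pair_fragments=pair_fragments, labels=tuple(labels)
    )
    return table, catalog


def classify_microsatellite(frag: str, max_motif: int = 6) -> str | None:
    """Shortest motif (length <= ``max_motif``) whose tandem repetition spells
    out ``frag`` (at least two complete units), or None."""
    n = len(frag)
    for p in range(1, max_motif + 1):
        if 2 * p > n:
            break
        if all(frag[i] == frag[i - p] for i in range(p, n)):
            return frag[:p]
    return None


def write_pair_fragments_tsv(catalog: FragmentCatalog, path: str | Path) -> None:
    """Per-pair matched-fragment lists: sectionA, sectionB, fragment, count."""
    if catalog.pair_fragments is None:
        raise ValueError("catalog was built without per-pair fragment lists")
    rows = [
        (a, b, frag, cnt)
        for (a, b), frags in sorted(catalog.pair_fragments.items())
        for frag, cnt in sorted(frags.items())
    ]
    pd.DataFrame(rows, columns=["sectionA", "sectionB", "fragment", "count"]).to_csv(
        path, sep="\t", index=False
    )


def write_catalog_tsv(catalog: FragmentCatalog, path: str | Path) -> None:
    rows = sorted(catalog.no.items(), key=lambda kv: (-kv[1], kv[0]))
    pd.DataFrame(rows, columns=["canonical_fragment", "NO"]).to_csv(
        path, sep="\t", index=False
    )
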
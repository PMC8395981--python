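"""Shared fixtures and independent oracles.

The oracles here deliberately use different mechanisms from the production
code: the pair-match oracle is a naive double loop over offset pairs with a
regex-based low-complexity filter, and the Spearman oracle computes
midranks and the Pearson formula by hand.
"""

from __future__ import annotations

import math
import re

import numpy as np
import pytest

from segmatch import ChromosomeSeq, Section, SectionSet

_RC = {"a": "t", "t": "a", "c": "g", "g": "c"}
# default filter rules as a single regex: 4 mono-, 3 di- or 2 trinucleotides
_REPEAT_RE = re.compile(r"(.)\1{3}|(..)\2{2}|(...)\3")


def oracle_rc(s: str) -> str:
    return "".join(_RC[c] for c in reversed(s))


def oracle_pair_count(a: str, b: str, L: int, exclude_repeats: bool = False) -> int:
    """Naive O(|A|·|B|) count of matched ordered offset pairs.

    A pair (i, j) matches when the windows are equal directly or across
    strands; ``or`` counts a palindromic double hit once.
    """

    def windows(s):
        out = []
        for i in range(len(s) - L + 1):
            f = s[i : i + L]
            if "n" in f:
                continue
            if exclude_repeats and _REPEAT_RE.search(f):
                continue
            out.append(f)
        return out

    count = 0
    for f in windows(a):
        for g in windows(b):
            if f == g or f == oracle_rc(g):
                count += 1
    return count


def oracle_midranks(x) -> list[float]:
    order = sorted(range(len(x)), key=lambda i: x[i])
    ranks = [0.0] * len(x)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def oracle_spearman(x, y) -> tuple[float, float]:
    """Spearman rho from midranks + Pearson formula; p from t with n-2 df."""
    rx = oracle_midranks(list(x))
    ry = oracle_midranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    vx = sum((a - mx) ** 2 for a in rx)
    vy = sum((b - my) ** 2 for b in ry)
    rho = cov / math.sqrt(vx * vy)
    from scipy.stats import t as tdist

    if abs(rho) >= 1.0:
        return rho, 0.0
    tstat = rho * math.sqrt((n - 2) / (1 - rho * rho))
    return rho, 2 * tdist.sf(abs(tstat), n - 2)


def make_section_set(seqs: list[str], labels: list[str] | None = None) -> SectionSet:
    """Back-to-back sections from literal sequences."""
    labels = labels or [f"S{i + 1:02d}" for i in range(len(seqs))]
    sections = []
    pos = 0
    for label, s in zip(labels, seqs):
        sections.append(Section(label=label, start=pos, end=pos + len(s), sequence=s))
        pos += len(s)
    return SectionSet(sections=tuple(sections))


def random_dna(rng: np.random.Generator, n: int, with_n: bool = False) -> str:
    alpha = "acgtn" if with_n else "acgt"
    p = [0.23, 0.23, 0.23, 0.23, 0.08] if with_n else None
    return "".join(np.array(list(alpha))[rng.choice(len(alpha), size=n, p=p)])


@pytest.fixture
def toy_sections() -> SectionSet:
    rng = np.random.default_rng(11)
    return make_section_set([random_dna(rng, 400) for _ in range(6)])


@pytest.fixture
def toy_chromosome() -> ChromosomeSeq:
    rng = np.random.default_rng(12)
    return ChromosomeSeq(name="chrT", sequence=random_dna(rng, 2000))
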
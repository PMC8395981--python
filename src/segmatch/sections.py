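"""Chromosome sequences and cytological section tables.

A chromosome is analysed one at a time, subdivided into named cytological
sections (e.g. ``1A`` ... ``20F`` on the Drosophila polytene X).  Section
borders come from an external table; coordinates are 0-based half-open
(BED convention) everywhere in this package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

_VALID = set("acgtn")


class FormatError(ValueError):
    """Malformed input file."""


@dataclass(frozen=True)
class ChromosomeSeq:
    """A single chromosome sequence, lowercased over {a,c,g,t,n}."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"chromosome {self.name!r} has empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Section:
    """A named chromosomal interval; ``sequence`` is filled by extraction."""

    label: str
    start: int
    end: int
    sequence: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"section {self.label!r}: invalid interval [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SectionSet:
    """Ordered, non-overlapping sections in chromosomal order."""

    sections: tuple[Section, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.sections) < 2:
            raise ValueError("a SectionSet needs at least 2 sections")
        labels = [s.label for s in self.sections]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate section labels: {dupes}")
        offenders = [
            f"{a.label}/{b.label}"
            for a, b in zip(self.sections, self.sections[1:])
            if b.start < a.end
        ]
        if offenders:
            raise ValueError(f"overlapping sections: overlap {', '.join(offenders)}")

    def __len__(self) -> int:
        return len(self.sections)

    def __iter__(self) -> Iterator[Section]:
        return iter(self.sections)

    def __getitem__(self, i: int) -> Section:
        return self.sections[i]

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.sections]

    def index_of(self, label: str) -> int:
        for i, s in enumerate(self.sections):
            if s.label == label:
                return i
        raise KeyError(label)


def _normalize(seq: str, name: str) -> str:
    seq = seq.lower()
    bad = set(seq) - _VALID
    if bad:
        log.warning(
            "sequence %s: %d non-acgtn base codes (%s) mapped to n",
            name,
            sum(seq.count(b) for b in bad),
            "".join(sorted(bad)),
        )
        seq = "".join(c if c in _VALID else "n" for c in seq)
    return seq


def read_fasta(path: str | Path, record: str | None = None) -> ChromosomeSeq:
    """Read one chromosome from a FASTA file.

    The first record is used unless ``record`` names a specific one.
    IUPAC ambiguity codes other than N are mapped to ``n`` with a warning.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    if record is None:
        rec = records[0]
    else:
        by_id = {r.id: r for r in records}
        if record not in by_id:
            raise FormatError(f"{path}: no record named {record!r}")
        rec = by_id[record]
    seq = _normalize(str(rec.seq), rec.id)
    chrom = ChromosomeSeq(name=rec.id, sequence=seq)
    log.info("read %s: %d bp", rec.id, len(chrom))
    return chrom


def read_section_table(path: str | Path, bed: bool = False) -> SectionSet:
    """Read a section-border table.

    Default format is a headered TSV with columns ``label``, ``start``,
    ``end`` (0-based half-open).  With ``bed=True`` a headerless BED3+name
    file (``chrom  start  end  label``) is accepted instead.
    """
    if bed:
        df = pd.read_csv(
            path, sep="\t", header=None, usecols=[1, 2, 3], names=["start", "end", "label"]
        )
    else:
        df = pd.read_csv(path, sep="\t")
        missing = {"label", "start", "end"} - set(df.columns)
        if missing:
            raise FormatError(f"{path}: missing columns {sorted(missing)}")
    secs = [
        Section(label=str(r.label), start=int(r.start), end=int(r.end))
        for r in df.itertuples()
    ]
    secs.sort(key=lambda s: s.start)
    return SectionSet(sections=tuple(secs))


def write_section_table(ss: SectionSet, path: str | Path) -> None:
    pd.DataFrame(
        [(s.label, s.start, s.end) for s in ss], columns=["label", "start", "end"]
    ).to_csv(path, sep="\t", index=False)


def extract_sections(chrom: ChromosomeSeq, ss: SectionSet) -> SectionSet:
    """Fill each section with its substring of the chromosome."""
    n = len(chrom)
    out = []
    for s in ss:
        if s.end > n:
            raise ValueError(
                f"section {s.label!r} [{s.start}, {s.end}) exceeds "
                f"chromosome length {n}"
            )
        out.append(replace(s, sequence=chrom.sequence[s.start : s.end]))
    return SectionSet(sections=tuple(out))
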
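"""Synthetic chromosomes with planted satellites and coupled contact counts.

The generator emulates the study design at desk scale: a multi-section
chromosome of i.i.d. background bases with controllable GC content, tandem
satellite monomer arrays planted into chosen sections (monomer lengths
default to the 359/372-nt middle-repeat scale), and a contact-count (FEC)
matrix whose per-pair Poisson intensity is raised by lambda1 whenever the
two sections share a planted monomer:

    FEC(A, B) ~ Poisson(lambda0 + lambda1 * shared(A, B))

The Poisson stand-in reproduces the small, zero-heavy integer matrices the
correlation layer must tolerate.  Ground truth (which sections carry which
monomer, and the shared-pair indicator) is retained so recovery tests can
check that planted sections are flagged and unplanted ones are not.
All randomness flows from a single integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .fec import FecMatrix, write_fec
from .sections import ChromosomeSeq, Section, SectionSet, write_section_table

BASES = np.array(list("acgt"))


@dataclass(frozen=True)
class Monomer:
    """A satellite monomer to plant as a tandem array.

    ``sequence=None`` randomizes a monomer of ``length`` nt at generation
    time (shared verbatim by all its target sections).
    """

    sections: tuple[int, ...]  # 0-based target section indices
    copy_number: int = 10
    length: int = 359
    sequence: str | None = None


@dataclass(frozen=True)
class SynthSpec:
    n_sections: int = 20
    section_length: int = 50_000
    gc_content: float = 0.42
    monomers: tuple[Monomer, ...] = ()
    lambda0: float = 1.0  # baseline Poisson contact rate per pair
    lambda1: float = 10.0  # added rate when a pair shares a planted monomer
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda0 < 0 or self.lambda1 < 0:
            raise ValueError("Poisson rates must be >= 0")
        for m in self.monomers:
            if any(not 0 <= s < self.n_sections for s in m.sections):
                raise ValueError(f"monomer targets {m.sections} outside sections")


@dataclass
class SynthTruth:
    labels: list[str]
    planted: dict[str, set[int]]  # section label -> monomer indices
    shared: np.ndarray  # (N, N) bool, symmetric
    lam: np.ndarray  # (N, N) Poisson intensity
    monomer_seqs: list[str] = field(default_factory=list)


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[rng.choice(4, size=n, p=p)])


def make_genome(spec: SynthSpec) -> tuple[ChromosomeSeq, SectionSet, SynthTruth]:
    """Generate the chromosome, its back-to-back section set and the truth.

    Each planted section receives ``copy_number`` tandem copies of its
    monomer at a uniformly chosen offset, replacing background sequence so
    section lengths are preserved; arrays within one section never overlap.
    Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    N = spec.n_sections
    labels = [f"S{i + 1:02d}" for i in range(N)]
    seqs = [_random_seq(rng, spec.section_length, spec.gc_content) for _ in range(N)]

    monomer_seqs = [
        m.sequence if m.sequence is not None else _random_seq(rng, m.length, spec.gc_content)
        for m in spec.monomers
    ]
    occupied: dict[int, list[tuple[int, int]]] = {i: [] for i in range(N)}
    planted: dict[str, set[int]] = {l: set() for l in labels}
    for mi, m in enumerate(spec.monomers):
        block = monomer_seqs[mi] * m.copy_number
        if len(block) > spec.section_length:
            raise ValueError(
                f"monomer {mi}: array of {len(block)} nt exceeds section "
                f"length {spec.section_length}"
            )
        for si in m.sections:
            for _ in range(1000):
                off = int(rng.integers(0, spec.section_length - len(block) + 1))
                span = (off, off + len(block))
                if all(span[1] <= a or span[0] >= b for a, b in occupied[si]):
                    break
            else:
                raise ValueError(f"cannot place monomer {mi} in section {si}")
            occupied[si].append(span)
            seqs[si] = seqs[si][: span[0]] + block + seqs[si][span[1] :]
            planted[labels[si]].add(mi)

    sections = []
    pos = 0
    for l, s in zip(labels, seqs):
        sections.append(Section(label=l, start=pos, end=pos + len(s), sequence=s))
        pos += len(s)
    ss = SectionSet(sections=tuple(sections))
    chrom = ChromosomeSeq(name="synthetic_chr", sequence="".join(seqs))

    shared = np.zeros((N, N), dtype=bool)
    for i in range(N):
        for j in range(i + 1, N):
            if planted[labels[i]] & planted[labels[j]]:
                shared[i, j] = shared[j, i] = True
    lam = spec.lambda0 + spec.lambda1 * shared
    np.fill_diagonal(lam, 0.0)
    truth = SynthTruth(
        labels=labels, planted=planted, shared=shared, lam=lam, monomer_seqs=monomer_seqs
    )
    return chrom, ss, truth


def make_fec(truth: SynthTruth, seed: int, strain: str = "synthetic") -> FecMatrix:
    """Independent Poisson contact counts per unordered pair."""
    rng = np.random.default_rng(seed)
    N = len(truth.labels)
    counts = np.zeros((N, N), dtype=np.int64)
    iu = np.triu_indices(N, k=1)
    draws = rng.poisson(truth.lam[iu])
    counts[iu] = draws
    counts += counts.T
    return FecMatrix(labels=list(truth.labels), counts=counts, strain=strain)


def write_fixture(spec: SynthSpec, outdir: str | Path) -> dict[str, Path]:
    """Materialize a fixture directory: FASTA, section TSV, FEC TSV, truth
    TSVs and a JSON manifest recording the spec and seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chrom, ss, truth = make_genome(spec)
    fec = make_fec(truth, seed=spec.seed + 1)

    paths = {
        "fasta": outdir / "genome.fasta",
        "sections": outdir / "sections.tsv",
        "fec": outdir / "fec.tsv",
        "truth_sections": outdir / "truth_sections.tsv",
        "truth_pairs": outdir / "truth_pairs.tsv",
        "manifest": outdir / "manifest.json",
    }
    with open(paths["fasta"], "w") as fh:
        fh.write(f">{chrom.name}\n")
        for i in range(0, len(chrom), 80):
            fh.write(chrom.sequence[i : i + 80] + "\n")
    write_section_table(ss, paths["sections"])
    write_fec(fec, paths["fec"])
    with open(paths["truth_sections"], "w") as fh:
        fh.write("label\tmonomers\n")
        for l in truth.labels:
            fh.write(f"{l}\t{','.join(map(str, sorted(truth.planted[l]))) or '-'}\n")
    with open(paths["truth_pairs"], "w") as fh:
        fh.write("sectionA\tsectionB\tshared\tlambda\n")
        N = len(truth.labels)
        for i in range(N):
            for j in range(i + 1, N):
                fh.write(
                    f"{truth.labels[i]}\t{truth.labels[j]}\t"
                    f"{int(truth.shared[i, j])}\t{truth.lam[i, j]:g}\n"
                )
    manifest = {
        "n_sections": spec.n_sections,
        "section_length": spec.section_length,
        "gc_content": spec.gc_content,
        "lambda0": spec.lambda0,
        "lambda1": spec.lambda1,
        "seed": spec.seed,
        "monomers": [
            {
                "sections": list(m.sections),
                "copy_number": m.copy_number,
                "length": m.length,
                "sequence": m.sequence,
            }
            for m in spec.monomers
        ],
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2) + "\n")
    return paths


def read_manifest(path: str | Path) -> SynthSpec:
    d = json.loads(Path(path).read_text())
    return SynthSpec(
        n_sections=d["n_sections"],
        section_length=d["section_length"],
        gc_content=d["gc_content"],
        monomers=tuple(
            Monomer(
                sections=tuple(m["sections"]),
                copy_number=m["copy_number"],
                length=m["length"],
                sequence=m["sequence"],
            )
            for m in d["monomers"]
        ),
        lambda0=d["lambda0"],
        lambda1=d["lambda1"],
        seed=d["seed"],
    )
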
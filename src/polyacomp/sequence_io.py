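"""FASTA input/output, the genome store, and base-composition accounting.

All genomic coordinates in this package are 0-based, half-open, on the
forward strand of the deposited assembly. Whole-genome base content is
the percentage of A, C, G or T in the total number of unambiguous
nucleotides accumulated over all chromosomes (or scaffolds); letters
outside {A, C, G, T} are excluded from both numerator and denominator.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from polyacomp.errors import DegenerateInputError, FastaFormatError

DNA_BASES = "ACGT"


def _open_text(path) -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a (possibly gzipped) multi-record FASTA file.

    Returns an ordered list of ``(id, sequence)`` tuples. The id is the
    header token before the first whitespace; sequences are uppercased
    with folded lines concatenated. CRLF line endings are tolerated.

    Raises :class:`FastaFormatError` (naming the line) on an empty
    file, a missing ``>`` header, or a header with no id token.
    """
    with _open_text(path) as handle:
        text = handle.read()
    lines = text.splitlines()
    first_content = None
    for lineno, line in enumerate(lines, start=1):
        if line.strip():
            first_content = (lineno, line)
            break
    if first_content is None:
        raise FastaFormatError(f"{path}: empty FASTA file (line 1)")
    lineno, line = first_content
    if not line.lstrip().startswith(">"):
        raise FastaFormatError(
            f"{path}: expected '>' FASTA header at line {lineno}, got {line[:30]!r}"
        )
    for lineno, line in enumerate(lines, start=1):
        if line.strip() == ">":
            raise FastaFormatError(f"{path}: header with no id at line {lineno}")
    records = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        records.append((rec.id, str(rec.seq).upper()))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 70) -> None:
    """Write ``(id, sequence)`` pairs as FASTA with ``width``-column folding."""
    with open(path, "wt") as out:
        for rid, seq in records:
            out.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


@dataclass
class BaseComposition:
    """Percent A/C/G/T(U) over ``n_bases`` unambiguous positions.

    ``alphabet_tag`` is ``"DNA"`` for genomic backgrounds (T) and
    ``"RNA"`` for transcript-orientation regions (U); the fourth slot
    ``pct_TU`` holds whichever applies.
    """

    pct_A: float
    pct_C: float
    pct_G: float
    pct_TU: float
    n_bases: int
    alphabet_tag: str = "DNA"

    def __post_init__(self):
        if self.n_bases < 0:
            raise ValueError("n_bases must be >= 0")
        if self.n_bases > 0:
            total = self.pct_A + self.pct_C + self.pct_G + self.pct_TU
            if abs(total - 100.0) > 1e-9:
                raise ValueError(f"percentages sum to {total!r}, expected 100")

    @classmethod
    def from_counts(cls, a: int, c: int, g: int, t: int, alphabet_tag: str = "DNA"):
        n = a + c + g + t
        if n == 0:
            raise DegenerateInputError("no A/C/G/T bases to summarize")
        return cls(100 * a / n, 100 * c / n, 100 * g / n, 100 * t / n, n, alphabet_tag)

    def as_dict(self) -> dict:
        key = "U" if self.alphabet_tag == "RNA" else "T"
        return {"A": self.pct_A, "C": self.pct_C, "G": self.pct_G, key: self.pct_TU}


@dataclass
class GenomeStore:
    """Named chromosome/scaffold sequences plus genome-wide base tallies.

    Any FASTA record counts as a chromosome; soft-masked (lowercase)
    letters are uppercased and counted. ``counted_bases`` tallies
    A+C+G+T only; ``n_excluded`` counts every other letter (N and other
    IUPAC ambiguity codes), so ``counted_bases + n_excluded`` equals
    the total length of all records.
    """

    records: dict[str, str] = field(default_factory=dict)
    base_counts: dict[str, int] = field(default_factory=dict)
    counted_bases: int = 0
    n_excluded: int = 0

    @classmethod
    def from_records(cls, records: Sequence[tuple[str, str]]) -> "GenomeStore":
        store = cls()
        counts = {b: 0 for b in DNA_BASES}
        total_len = 0
        for rid, seq in records:
            seq = seq.upper()
            if rid in store.records:
                raise FastaFormatError(f"duplicate chromosome id {rid!r}")
            store.records[rid] = seq
            total_len += len(seq)
            for b in DNA_BASES:
                counts[b] += seq.count(b)
        store.base_counts = counts
        store.counted_bases = sum(counts.values())
        store.n_excluded = total_len - store.counted_bases
        return store

    @classmethod
    def from_fasta(cls, path) -> "GenomeStore":
        return cls.from_records(read_fasta(path))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.records

    def __getitem__(self, chrom: str) -> str:
        return self.records[chrom]

    def total_length(self) -> int:
        return self.counted_bases + self.n_excluded


def genome_composition(
    genome: GenomeStore, symmetrize_background: bool = False
) -> BaseComposition:
    """Whole-genome percent A/C/G/T over unambiguous bases.

    With ``symmetrize_background`` the A/T and C/G percentages are each
    averaged, giving a strand-symmetric background; default follows the
    single deposited strand.
    """
    c = genome.base_counts
    if genome.counted_bases == 0:
        raise DegenerateInputError("genome contains no A/C/G/T bases")
    comp = BaseComposition.from_counts(c["A"], c["C"], c["G"], c["T"], "DNA")
    if symmetrize_background:
        at = (comp.pct_A + comp.pct_TU) / 2
        cg = (comp.pct_C + comp.pct_G) / 2
        comp = BaseComposition(at, cg, cg, at, comp.n_bases, "DNA")
    return comp


def composition_to_tsv_row(dataset: str, region: str, comp: BaseComposition) -> str:
    """One line of the composition report (dataset, region, A, C, G, T_or_U, n_bases)."""
    return "\t".join(
        [
            dataset,
            region,
            f"{comp.pct_A:.6f}",
            f"{comp.pct_C:.6f}",
            f"{comp.pct_G:.6f}",
            f"{comp.pct_TU:.6f}",
            str(comp.n_bases),
        ]
    )


COMPOSITION_TSV_HEADER = "dataset\tregion\tA\tC\tG\tT_or_U\tn_bases"
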
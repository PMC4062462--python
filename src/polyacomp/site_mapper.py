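"""Zero-mismatch anchor placement and cleavage-junction calling.

Junction-relative coordinates (transcript orientation):

* ``-anchor_len .. -1`` — the 3'UTR window (the anchor itself),
* ``0`` — the site position: the genomic base under the first tail A,
* ``+1 .. +100`` — the 3'COR window (cleaved-off region), downstream of
  and excluding the poly(A) tail starting position.

``junction`` is stored as the 0-based forward-assembly coordinate of
the LAST templated (anchor) base. On the minus strand all reported
window sequences are reverse-complemented so they read 5'->3' in
transcript orientation.

A mapped site whose genomic sequence continues with an A-run of at
least 12 from position 0 is flagged as a potential internal-priming
artifact (an oligo-dT primer can anneal to such genomic stretches and
fake a poly(A) tail). Flagged sites are never silently dropped;
exclusion is a reporting-level filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from polyacomp.errors import IntegrityError
from polyacomp.sequence_io import GenomeStore

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

COR_LEN = 100
IP_RUN_MIN = 12
SIX_BASE_LEN = 6


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AnchorHit:
    """One exact placement of an anchor: junction = last templated base."""

    chrom: str
    strand: str
    junction: int
    anchor: str


@dataclass(frozen=True)
class PolyASite:
    """A unique, stranded genomic cleavage junction with its windows."""

    chrom: str
    strand: str
    junction: int
    anchor: str
    utr_window: str
    site_base: str
    cor_window: str
    downstream_A_run: int
    six_base_A_count: int
    ip_flag: bool
    tail_len: int = 0

    @property
    def sort_key(self) -> tuple:
        return (self.chrom, self.junction, self.strand)


def match_anchor(anchor: str, genome: GenomeStore) -> list[AnchorHit]:
    """Every exact occurrence of ``anchor`` on either strand.

    The anchor and its reverse complement are both searched on the
    deposited forward strand; overlapping occurrences count. Results
    are sorted by (chrom, junction, strand) for determinism. The result
    is contractually identical to a naive scan over every offset.
    """
    if not anchor or not frozenset(anchor) <= frozenset("ACGT"):
        raise ValueError("anchor must be a non-empty pure-ACGT string")
    rc = reverse_complement(anchor)
    L = len(anchor)
    hits: list[AnchorHit] = []
    for chrom, seq in genome.records.items():
        i = seq.find(anchor)
        while i != -1:
            hits.append(AnchorHit(chrom, "+", i + L - 1, anchor))
            i = seq.find(anchor, i + 1)
        i = seq.find(rc)
        while i != -1:
            hits.append(AnchorHit(chrom, "-", i, anchor))
            i = seq.find(rc, i + 1)
    hits.sort(key=lambda h: (h.chrom, h.junction, h.strand))
    return hits


def _a_run_length(genome_seq: str, start: int, step: int, sense_base: str) -> int:
    """Length of the run of ``sense_base`` walking from ``start`` by ``step``."""
    n = 0
    i = start
    while 0 <= i < len(genome_seq) and genome_seq[i] == sense_base:
        n += 1
        i += step
    return n


def call_site(
    hit: AnchorHit,
    genome: GenomeStore,
    tail_len: int = 0,
    cor_len: int = COR_LEN,
) -> Optional[PolyASite]:
    """Extract windows around a placed anchor and flag artifacts.

    Returns None when fewer than ``cor_len + 1`` genomic bases exist
    downstream of the junction in transcript orientation (the site base
    plus a complete 3'COR window are required).
    """
    if hit.chrom not in genome:
        raise IntegrityError(f"chromosome {hit.chrom!r} absent from genome store")
    seq = genome[hit.chrom]
    L = len(hit.anchor)
    j = hit.junction
    if hit.strand == "+":
        if j + 1 + cor_len >= len(seq):
            return None
        utr = seq[j - L + 1 : j + 1]
        site_base = seq[j + 1]
        cor = seq[j + 2 : j + 2 + cor_len]
        run = _a_run_length(seq, j + 1, +1, "A")
    else:
        if j - 1 - cor_len < 0:
            return None
        utr = reverse_complement(seq[j : j + L])
        site_base = reverse_complement(seq[j - 1])
        cor = reverse_complement(seq[j - 1 - cor_len : j - 1])
        run = _a_run_length(seq, j - 1, -1, "T")
    downstream = site_base + cor
    six = downstream[:SIX_BASE_LEN].count("A")
    return PolyASite(
        chrom=hit.chrom,
        strand=hit.strand,
        junction=j,
        anchor=hit.anchor,
        utr_window=utr,
        site_base=site_base,
        cor_window=cor,
        downstream_A_run=run,
        six_base_A_count=six,
        ip_flag=run >= IP_RUN_MIN,
        tail_len=tail_len,
    )


def dedupe_sites(sites: Iterable[PolyASite]) -> tuple[list[PolyASite], int]:
    """One site per distinct 100-base upstream sequence (utr_window).

    The retained representative is the site with the lexicographically
    smallest (chrom, junction, strand) triple; output sorted by locus.
    Returns (unique sites, number of collapsed sites).
    """
    sites = list(sites)
    best: dict[str, PolyASite] = {}
    for s in sites:
        cur = best.get(s.utr_window)
        if cur is None or s.sort_key < cur.sort_key:
            best[s.utr_window] = s
    unique = sorted(best.values(), key=lambda s: s.sort_key)
    return unique, len(sites) - len(unique)


SITES_TSV_HEADER = "\t".join(
    [
        "chrom", "junction", "strand", "tail_len", "downstream_A_run",
        "six_base_A_count", "ip_flag", "utr_window", "cor_window",
    ]
)


def sites_to_tsv(sites: Iterable[PolyASite], path) -> None:
    """Write the unique-sites table (junction 0-based)."""
    with open(path, "wt") as out:
        out.write(SITES_TSV_HEADER + "\n")
        for s in sites:
            out.write(
                "\t".join(
                    [
                        s.chrom, str(s.junction), s.strand, str(s.tail_len),
                        str(s.downstream_A_run), str(s.six_base_A_count),
                        str(int(s.ip_flag)), s.utr_window, s.cor_window,
                    ]
                )
                + "\n"
            )


def sites_to_bed(sites: Iterable[PolyASite], path) -> None:
    """BED6 export of junctions (chromStart = junction, half-open)."""
    with open(path, "wt") as out:
        for k, s in enumerate(sites):
            out.write(
                f"{s.chrom}\t{s.junction}\t{s.junction + 1}\tsite_{k}\t0\t{s.strand}\n"
            )
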
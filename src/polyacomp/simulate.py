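"""Synthetic genomes, transcripts and reads with planted ground truth.

The generator emulates the data model the pipeline assumes: an i.i.d.
background genome into which stranded cleavage junctions are planted at
non-overlapping loci (>= 250 bp apart so analysis windows never
collide). At each site the 100-base upstream (3'UTR) window is drawn
from a U-rich/C-poor multinomial and the downstream (3'COR) window from
its own multinomial, written into the genome in transcript orientation
on a ~50/50 mix of strands. Transcripts are the templated sequence plus
a poly(A) tail of at least 12 A's. Internal-priming artifacts are
emulated by planting a genomic A-run (length uniform in [12, 20]) at
position 0 and ending the transcript inside it, so its apparent tail is
genome-templated. Optional fragmentation produces 3'-terminal reads for
the 80-base mapping mode, plus reads ending inside internal A-runs
(fragmentation-created false tails).

The last upstream base of every planted window is kept non-A so that
maximal-run tail trimming reproduces the planted junction exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from polyacomp.errors import ConfigError, IntegrityError
from polyacomp.sequence_io import GenomeStore, write_fasta
from polyacomp.site_mapper import reverse_complement

BASES = "ACGT"
UTR_LEN = 100
COR_LEN = 100
SITE_FOOTPRINT = UTR_LEN + 1 + COR_LEN  # 201
MIN_SEPARATION = 250


def _check_probs(name: str, probs) -> tuple[float, ...]:
    probs = tuple(float(p) for p in probs)
    if len(probs) != 4 or any(p < 0 for p in probs):
        raise ConfigError(f"{name} must be 4 nonnegative probabilities")
    if abs(sum(probs) - 1.0) > 1e-9:
        raise ConfigError(f"{name} must sum to 1 (got {sum(probs)!r})")
    return probs


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    Probability vectors are over (A, C, G, T) in transcript/forward
    orientation. Defaults plant the qualitative structure seen in real
    3' regions: a U-rich, C-poor 3'UTR (U >> A >> G > C), a slightly
    less U-rich 3'COR, and a balanced genomic background.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_len: int = 60_000
    n_sites: int = 100
    background_probs: tuple = (0.25, 0.25, 0.25, 0.25)
    utr_probs: tuple = (0.25, 0.15, 0.20, 0.40)
    cor_probs: tuple = (0.27, 0.16, 0.20, 0.37)
    tail_len_range: tuple = (12, 30)
    frac_internal_priming: float = 0.0
    frac_duplicates: float = 0.0
    artifact_run_range: tuple = (12, 20)
    body_len: int = 0          # templated mRNA body upstream of the UTR window
    read_mode: str = "off"     # "off" | "fragmented"
    fragment_len_range: tuple = (100, 200)
    min_tail: int = 12

    def __post_init__(self):
        self.background_probs = _check_probs("background_probs", self.background_probs)
        self.utr_probs = _check_probs("utr_probs", self.utr_probs)
        self.cor_probs = _check_probs("cor_probs", self.cor_probs)
        if self.tail_len_range[0] < 12:
            raise ConfigError("minimum tail length must be >= 12")
        if self.artifact_run_range[0] < 12:
            raise ConfigError("artifact A-runs must be >= 12")
        if not 0 <= self.frac_internal_priming <= 1:
            raise ConfigError("frac_internal_priming must be in [0, 1]")
        if not 0 <= self.frac_duplicates < 1:
            raise ConfigError("frac_duplicates must be in [0, 1)")
        footprint = SITE_FOOTPRINT + self.body_len
        if self.n_sites * (footprint + MIN_SEPARATION) >= self.n_chroms * self.chrom_len:
            raise ConfigError(
                f"cannot pack {self.n_sites} sites of footprint {footprint} "
                f"with {MIN_SEPARATION} bp separation into "
                f"{self.n_chroms} x {self.chrom_len} bp"
            )
        if self.read_mode not in ("off", "fragmented"):
            raise ConfigError("read_mode must be 'off' or 'fragmented'")
        if self.read_mode == "fragmented" and self.fragment_len_range[0] < 80 + self.min_tail:
            raise ConfigError(
                "fragment length must cover the 80-base anchor plus a minimal tail"
            )


@dataclass(frozen=True)
class TruthSite:
    """Ground truth for one planted cleavage junction."""

    chrom: str
    strand: str
    junction: int     # forward-assembly coordinate of the last templated base
    utr_window: str   # transcript orientation
    cor_window: str
    is_artifact: bool


@dataclass
class SimResult:
    genome: GenomeStore
    transcripts: list[tuple[str, str]]
    truth: list[TruthSite]
    config: SimConfig
    reads: Optional[list[tuple[str, str]]] = None


def _draw(rng: np.random.Generator, probs, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n, p=list(probs)))


def _validate_truth(genome: GenomeStore, truth: list[TruthSite]) -> None:
    """Self-check: truth windows must match the emitted genome."""
    for t in truth:
        seq = genome[t.chrom]
        j = t.junction
        if t.strand == "+":
            utr = seq[j - UTR_LEN + 1 : j + 1]
            cor = seq[j + 2 : j + 2 + COR_LEN]
        else:
            utr = reverse_complement(seq[j : j + UTR_LEN])
            cor = reverse_complement(seq[j - 1 - COR_LEN : j - 1])
        if utr != t.utr_window or cor != t.cor_window:
            raise IntegrityError(
                f"truth window mismatch at {t.chrom}:{t.junction}{t.strand}"
            )


def generate_dataset(config: SimConfig, outdir=None) -> SimResult:
    """Generate genome + transcripts + truth (fully seeded).

    With ``outdir`` the result is also written as ``genome.fa``,
    ``transcripts.fa``, ``truth.tsv`` (and ``reads.fa`` when
    fragmentation is on).
    """
    rng = np.random.default_rng(config.seed)
    footprint = config.body_len + SITE_FOOTPRINT

    # background chromosomes as mutable letter arrays
    chroms = {
        f"chr{i + 1}": list(_draw(rng, config.background_probs, config.chrom_len))
        for i in range(config.n_chroms)
    }

    # deterministic non-overlapping slots, round-robin across chromosomes
    slots: list[tuple[str, int]] = []
    for name in chroms:
        cursor = 0
        while cursor + footprint + 50 <= config.chrom_len:
            slots.append((name, cursor + int(rng.integers(0, 50))))
            cursor += footprint + MIN_SEPARATION + 50
    if len(slots) < config.n_sites:
        raise ConfigError(
            f"only {len(slots)} site slots available for {config.n_sites} sites"
        )
    slot_idx = rng.choice(len(slots), size=config.n_sites, replace=False)

    n_artifact = round(config.frac_internal_priming * config.n_sites)
    artifact_ids = set(rng.choice(config.n_sites, size=n_artifact, replace=False))

    truth: list[TruthSite] = []
    transcripts: list[tuple[str, str]] = []
    seen_anchors: set[str] = set()
    for i in range(config.n_sites):
        chrom, start = slots[slot_idx[i]]
        strand = "+" if rng.random() < 0.5 else "-"
        is_artifact = i in artifact_ids

        while True:
            utr = _draw(rng, config.utr_probs, UTR_LEN)
            if utr[-1] == "A":
                continue
            if utr[-80:] in seen_anchors:
                continue
            break
        seen_anchors.add(utr[-80:])

        if is_artifact:
            run_len = int(rng.integers(config.artifact_run_range[0],
                                       config.artifact_run_range[1] + 1))
            while True:
                rest = _draw(rng, config.cor_probs, COR_LEN + 1 - run_len)
                if rest[0] != "A":
                    break
            downstream = "A" * run_len + rest
        else:
            while True:
                downstream = _draw(rng, config.cor_probs, COR_LEN + 1)
                run = len(downstream) - len(downstream.lstrip("A"))
                if run < config.min_tail:
                    break

        body = _draw(rng, config.background_probs, config.body_len)
        region = body + utr + downstream  # transcript orientation
        forward = region if strand == "+" else reverse_complement(region)
        chroms[chrom][start : start + len(forward)] = list(forward)
        junction = (start + config.body_len + UTR_LEN - 1 if strand == "+"
                    else start + COR_LEN + 1)

        if is_artifact:
            apparent_tail = int(rng.integers(config.min_tail, run_len + 1))
            tseq = body + utr + "A" * apparent_tail
        else:
            tail = int(rng.integers(config.tail_len_range[0],
                                    config.tail_len_range[1] + 1))
            tseq = body + utr + "A" * tail
        transcripts.append((f"tx_{i:05d}{'_ip' if is_artifact else ''}", tseq))
        truth.append(TruthSite(chrom, strand, junction, utr,
                               downstream[1:], is_artifact))

    # verbatim duplicate copies
    if config.frac_duplicates > 0:
        n_total = round(config.n_sites / (1 - config.frac_duplicates))
        n_extra = n_total - config.n_sites
        picks = rng.integers(0, config.n_sites, size=n_extra)
        for k, p in enumerate(picks):
            transcripts.append((f"dup_{k:05d}_of_{transcripts[p][0]}",
                                transcripts[p][1]))

    genome = GenomeStore.from_records(
        [(name, "".join(letters)) for name, letters in chroms.items()]
    )
    _validate_truth(genome, truth)

    reads = None
    if config.read_mode == "fragmented":
        reads = fragment_reads(transcripts, config, rng=rng)

    result = SimResult(genome=genome, transcripts=transcripts, truth=truth,
                       config=config, reads=reads)
    if outdir is not None:
        write_dataset(result, outdir)
    return result


def fragment_reads(
    transcripts: list[tuple[str, str]],
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> list[tuple[str, str]]:
    """3'-biased fragmentation of transcripts into short reads.

    Every transcript yields its 3'-terminal fragment (tail retained, so
    the true site stays detectable in 80-base mode). In addition, every
    internal A-run of at least ``min_tail`` in the transcript body
    yields a fragment ending inside that run — the fragmentation-created
    false poly(A) tails that make read-based mapping internal-priming
    prone. Fragment lengths are uniform in ``fragment_len_range``,
    truncated at the transcript start.
    """
    if config.read_mode != "fragmented":
        raise ConfigError("fragment_reads requires read_mode='fragmented'")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    lo, hi = config.fragment_len_range
    reads: list[tuple[str, str]] = []
    for tid, seq in transcripts:
        flen = int(rng.integers(lo, hi + 1))
        reads.append((f"{tid}_frag3p", seq[-min(flen, len(seq)):]))
        # internal A-runs (excluding the terminal tail run)
        body_end = len(seq.rstrip("A"))
        pos = 0
        k = 0
        while pos < body_end:
            if seq[pos] == "A":
                run_start = pos
                while pos < body_end and seq[pos] == "A":
                    pos += 1
                run_len = pos - run_start
                if run_len >= config.min_tail:
                    end = run_start + int(rng.integers(config.min_tail, run_len + 1))
                    flen = int(rng.integers(lo, hi + 1))
                    reads.append(
                        (f"{tid}_frag_int{k}", seq[max(0, end - flen) : end])
                    )
                    k += 1
            else:
                pos += 1
    return reads


TRUTH_TSV_HEADER = "chrom\tstrand\tjunction\tutr_window\tcor_window\tis_artifact"


def write_truth(truth: list[TruthSite], path) -> None:
    with open(path, "wt") as out:
        out.write(TRUTH_TSV_HEADER + "\n")
        for t in truth:
            out.write(f"{t.chrom}\t{t.strand}\t{t.junction}\t{t.utr_window}\t"
                      f"{t.cor_window}\t{int(t.is_artifact)}\n")


def write_dataset(result: SimResult, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(result.genome.records.items(), outdir / "genome.fa")
    write_fasta(result.transcripts, outdir / "transcripts.fa")
    write_truth(result.truth, outdir / "truth.tsv")
    if result.reads is not None:
        write_fasta(result.reads, outdir / "reads.fa")
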
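"""Per-position metaprofiles, window compositions and region/genome ratios.

Positions are junction-relative: ``-anchor_len..-1`` (3'UTR window),
``0`` (site base), ``+1..+100`` (3'COR). Region compositions are
reported on the RNA alphabet (U in place of T); backgrounds on DNA.
Region/genome ratios divide a region's base percentage by the
whole-genome percentage of the matched base (U matched to T); they are
computed per species and only then averaged across species, because the
group-comparison unit is the species.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

import numpy as np

from polyacomp.errors import DegenerateInputError
from polyacomp.sequence_io import BaseComposition
from polyacomp.site_mapper import PolyASite

BASES = "ACGT"
RNA_BASES = "ACGU"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round-half-up at the reporting layer (spreadsheet-style)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CompositionProfile:
    """Per-position A/C/G/T counts over all sites of one dataset.

    ``counts[i, j]`` is the number of sites with base ``BASES[j]`` at
    junction-relative position ``lo + i``; every site contributes
    exactly one base per position, so each row sums to ``n_sites``.
    """

    lo: int
    hi: int
    counts: np.ndarray
    n_sites: int

    @property
    def positions(self) -> np.ndarray:
        return np.arange(self.lo, self.hi + 1)

    def row(self, pos: int) -> np.ndarray:
        if not self.lo <= pos <= self.hi:
            raise IndexError(f"position {pos} outside profile range [{self.lo}, {self.hi}]")
        return self.counts[pos - self.lo]


@dataclass(frozen=True)
class WindowSpec:
    """A named junction-relative window with inclusive bounds."""

    name: str
    lo: int
    hi: int

    def __post_init__(self):
        if self.lo > self.hi:
            raise ValueError("window lo must be <= hi")

    def __len__(self) -> int:
        return self.hi - self.lo + 1


def standard_windows(
    anchor_len: int = 100, cor_includes_site: bool = False
) -> dict[str, WindowSpec]:
    """The analysis windows: full UTR, full COR, distal UTR slice, 6-base.

    The site base (position 0) belongs to neither the UTR nor the COR
    window by default; the ``cor_includes_site`` reading shifts the COR
    to 0..+99. The 50-base distal window (the UTR slice 50 bases
    upstream away from the junction, clear of near-site motifs) is only
    defined when the anchor spans at least 100 bases. The 6-base window
    covers the site base and the 5 immediately downstream bases.
    """
    windows = {
        f"UTR{anchor_len}": WindowSpec(f"UTR{anchor_len}", -anchor_len, -1),
        "COR100": WindowSpec("COR100", 0 if cor_includes_site else 1,
                             99 if cor_includes_site else 100),
        "SIXBASE": WindowSpec("SIXBASE", 0, 5),
    }
    if anchor_len >= 100:
        windows["DISTAL50"] = WindowSpec("DISTAL50", -100, -51)
    return windows


def positional_profile(sites: Sequence[PolyASite]) -> CompositionProfile:
    """Count the base composition at each junction-relative position.

    All sites must carry complete windows of identical lengths (the
    pipeline guarantees this after site calling).
    """
    sites = list(sites)
    if not sites:
        raise DegenerateInputError("cannot profile an empty site list")
    anchor_len = len(sites[0].utr_window)
    cor_len = len(sites[0].cor_window)
    for s in sites:
        if len(s.utr_window) != anchor_len or len(s.cor_window) != cor_len:
            raise ValueError("sites have inconsistent window lengths")
    width = anchor_len + 1 + cor_len
    mat = np.frombuffer(
        "".join(s.utr_window + s.site_base + s.cor_window for s in sites).encode(),
        dtype="S1",
    ).reshape(len(sites), width)
    counts = np.zeros((width, 4), dtype=np.int64)
    for j, b in enumerate(BASES):
        counts[:, j] = (mat == b.encode()).sum(axis=0)
    return CompositionProfile(lo=-anchor_len, hi=cor_len, counts=counts,
                              n_sites=len(sites))


def add_profiles(a: CompositionProfile, b: CompositionProfile) -> CompositionProfile:
    """Elementwise sum; the profile of concatenated site sets."""
    if (a.lo, a.hi) != (b.lo, b.hi):
        raise ValueError("profiles cover different position ranges")
    return CompositionProfile(a.lo, a.hi, a.counts + b.counts, a.n_sites + b.n_sites)


def window_composition(
    profile: CompositionProfile, window: WindowSpec
) -> BaseComposition:
    """Base percentages pooled over all window positions and all sites."""
    if window.lo < profile.lo or window.hi > profile.hi:
        raise ValueError(
            f"window {window.name} [{window.lo},{window.hi}] outside profile range"
        )
    sub = profile.counts[window.lo - profile.lo : window.hi - profile.lo + 1]
    a, c, g, t = (int(x) for x in sub.sum(axis=0))
    return BaseComposition.from_counts(a, c, g, t, alphabet_tag="RNA")


@dataclass
class RatioTable:
    """Region/genome base-percentage ratios for one species and region."""

    ratio_A: Optional[float]
    ratio_C: Optional[float]
    ratio_G: Optional[float]
    ratio_TU: Optional[float]
    region_name: str = ""
    species_id: str = ""

    def as_dict(self) -> dict:
        return {
            "A": self.ratio_A, "C": self.ratio_C,
            "G": self.ratio_G, "U": self.ratio_TU,
        }


def region_genome_ratio(
    region: BaseComposition,
    background: BaseComposition,
    region_name: str = "",
    species_id: str = "",
) -> RatioTable:
    """Region percentage divided by genome percentage per base (U vs T).

    A ratio is flagged undefined (None) when the genome percentage of
    the matched base is zero.
    """

    def _ratio(num: float, den: float) -> Optional[float]:
        return None if den == 0 else num / den

    return RatioTable(
        ratio_A=_ratio(region.pct_A, background.pct_A),
        ratio_C=_ratio(region.pct_C, background.pct_C),
        ratio_G=_ratio(region.pct_G, background.pct_G),
        ratio_TU=_ratio(region.pct_TU, background.pct_TU),
        region_name=region_name,
        species_id=species_id,
    )


def per_position_ratio(
    profile: CompositionProfile, background: BaseComposition, base: str
) -> tuple[np.ndarray, np.ndarray]:
    """Region/genome ratio track for one base at every profile position.

    ``track[pos] = (count[pos][base] / n_sites * 100) / genome_pct``.
    Returns (positions, ratios). ``base`` may be U (matched to T).
    """
    if profile.n_sites <= 0:
        raise DegenerateInputError("profile has no sites")
    b = "T" if base.upper() == "U" else base.upper()
    pct = {"A": background.pct_A, "C": background.pct_C,
           "G": background.pct_G, "T": background.pct_TU}[b]
    if pct == 0:
        raise ZeroDivisionError(f"genome percentage of {base} is zero")
    freq = profile.counts[:, _BASE_INDEX[b]] / profile.n_sites * 100.0
    return profile.positions, freq / pct


def ua_ratio(comp: BaseComposition) -> float:
    """U/A ratio of one window composition (full precision).

    Rounding to the 2-decimal reporting convention is the caller's job
    (:func:`round_half_up`). Raises on zero A content.
    """
    if comp.pct_A == 0:
        raise ZeroDivisionError("U/A ratio undefined: A content is zero")
    return comp.pct_TU / comp.pct_A


def profile_to_tsv(profile: CompositionProfile, path) -> None:
    with open(path, "wt") as out:
        out.write("position\tcount_A\tcount_C\tcount_G\tcount_T\tn_sites\n")
        for i, pos in enumerate(profile.positions):
            a, c, g, t = profile.counts[i]
            out.write(f"{pos}\t{a}\t{c}\t{g}\t{t}\t{profile.n_sites}\n")


RATIO_TSV_HEADER = "species\tregion\tbase\tratio"


def ratios_to_tsv(ratios: Iterable[RatioTable], path) -> None:
    with open(path, "wt") as out:
        out.write(RATIO_TSV_HEADER + "\n")
        for r in ratios:
            for base, val in r.as_dict().items():
                sval = "NA" if val is None else f"{val:.6f}"
                out.write(f"{r.species_id}\t{r.region_name}\t{base}\t{sval}\n")
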
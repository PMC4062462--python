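"""Published distal 3'UTR base compositions for 18 animal and plant species.

These are the per-species base compositions (percent A/C/G/U) of the
50-base distal 3'UTR window — the UTR slice 50 bases upstream away from
the poly(A) site, clear of the near-site A/U-rich motifs — determined
from zero-mismatch NCBI-mRNA poly(A)-site mapping, together with the
U/A ratio as printed in the published comparison (two decimals).

They serve as worked-example inputs for :func:`polyacomp.ua_ratio` and
for the plants-vs-animals Student's t-test on U/A ratios.
"""

from __future__ import annotations

import pandas as pd

from polyacomp.composition import round_half_up, ua_ratio
from polyacomp.group_stats import TTestResult, t_test_equal_var
from polyacomp.sequence_io import BaseComposition

# species, lineage group, kingdom, %A, %C, %G, %U, printed U/A ratio
_ROWS = [
    ("Apis mellifera",          "invertebrate", "animal", 36.57, 13.24, 14.93, 35.26, 0.96),
    ("Drosophila melanogaster", "invertebrate", "animal", 34.13, 17.55, 16.45, 31.87, 0.93),
    ("Caenorhabditis elegans",  "invertebrate", "animal", 26.75, 18.15, 13.84, 41.26, 1.54),
    ("Danio rerio",             "nonmammal_vertebrate", "animal", 28.92, 16.91, 18.72, 35.46, 1.23),
    ("Gallus gallus",           "nonmammal_vertebrate", "animal", 27.99, 17.83, 19.88, 34.30, 1.23),
    ("Taeniopygia guttata",     "nonmammal_vertebrate", "animal", 27.17, 19.71, 21.48, 31.64, 1.16),
    ("Bos taurus",              "mammal", "animal", 27.15, 20.17, 20.59, 32.10, 1.18),
    ("Homo sapiens",            "mammal", "animal", 26.95, 20.41, 21.45, 31.19, 1.16),
    ("Mus musculus",            "mammal", "animal", 26.34, 20.96, 21.24, 31.46, 1.19),
    ("Rattus norvegicus",       "mammal", "animal", 26.56, 21.03, 22.10, 30.31, 1.14),
    ("Pongo abelii",            "mammal", "animal", 27.87, 18.92, 21.46, 31.75, 1.14),
    ("Arabidopsis thaliana",    "dicot", "plant", 27.95, 14.59, 17.40, 40.06, 1.43),
    ("Medicago truncatula",     "dicot", "plant", 29.02, 13.53, 17.59, 39.86, 1.37),
    ("Populus trichocarpa",     "dicot", "plant", 25.41, 16.11, 19.73, 38.75, 1.53),
    ("Solanum tuberosum",       "dicot", "plant", 25.47, 15.18, 18.56, 40.79, 1.60),
    ("Oryza sativa",            "monocot", "plant", 25.42, 17.77, 21.58, 35.24, 1.39),
    ("Sorghum bicolor",         "monocot", "plant", 24.30, 18.22, 22.73, 34.75, 1.43),
    ("Zea mays",                "monocot", "plant", 24.77, 18.52, 22.47, 34.23, 1.38),
]


def distal_utr50_table() -> pd.DataFrame:
    """The 18-species distal-window composition table."""
    return pd.DataFrame(
        _ROWS,
        columns=["species", "lineage", "kingdom",
                 "pct_A", "pct_C", "pct_G", "pct_U", "ua_printed"],
    )


def species_composition(species: str) -> BaseComposition:
    """Distal-window composition of one species as a BaseComposition (RNA).

    The four printed percentages are renormalized to sum to exactly 100
    (printed values carry 2-decimal rounding error of order 0.01).
    """
    df = distal_utr50_table()
    row = df[df.species == species]
    if row.empty:
        raise KeyError(f"unknown species {species!r}")
    a, c, g, u = (float(row[k].iloc[0]) for k in ("pct_A", "pct_C", "pct_G", "pct_U"))
    total = a + c + g + u
    scale = 100.0 / total
    return BaseComposition(a * scale, c * scale, g * scale, u * scale,
                           n_bases=1, alphabet_tag="RNA")


def species_ua_ratio(species: str, ndigits: int = 2) -> float:
    """U/A ratio of one species' distal window, reporting precision."""
    return round_half_up(ua_ratio(species_composition(species)), ndigits)


def plants_vs_animals_ttest(use_printed_ratios: bool = True) -> TTestResult:
    """Equal-variance two-tailed t-test of U/A ratios, plants vs animals."""
    df = distal_utr50_table()
    if use_printed_ratios:
        vals = df.ua_printed
    else:
        vals = df.pct_U / df.pct_A
    plants = list(vals[df.kingdom == "plant"])
    animals = list(vals[df.kingdom == "animal"])
    return t_test_equal_var(plants, animals)
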
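"""Shared definition of the synthetic multi-species cohort.

Four species groups mirror the study design: two plant groups (dicot,
monocot) and two animal groups (mammal, non-mammal). Planted window and
background multinomials reproduce the qualitative structure of the real
subkingdoms: a U-rich, C-poor 3'UTR and 3'COR everywhere (U >> A >> G >
C), the strongest UTR U-richness in dicots, and a genomic T content
highest in dicots and lowest in monocots.
"""

from polyacomp.simulate import SimConfig

SIM_DIR = "results/sim"

# group -> (utr_probs, cor_probs, background_probs) over (A, C, G, T)
GROUP_PROBS = {
    "dicot":     ((0.26, 0.14, 0.20, 0.40), (0.28, 0.15, 0.20, 0.37),
                  (0.33, 0.17, 0.17, 0.33)),
    "monocot":   ((0.25, 0.17, 0.225, 0.355), (0.26, 0.18, 0.215, 0.345),
                  (0.28, 0.22, 0.22, 0.28)),
    "mammal":    ((0.28, 0.19, 0.21, 0.32), (0.29, 0.19, 0.205, 0.315),
                  (0.295, 0.205, 0.205, 0.295)),
    "nonmammal": ((0.29, 0.165, 0.195, 0.35), (0.30, 0.165, 0.195, 0.34),
                  (0.31, 0.19, 0.19, 0.31)),
}

SUPERGROUPS = {"dicot": "plant", "monocot": "plant",
               "mammal": "animal", "nonmammal": "animal"}

N_SPECIES_PER_GROUP = 3
N_SITES = 150


def cohort_configs(base_seed: int = 1000):
    """(species_id, group, SimConfig) for every cohort member."""
    out = []
    seed = base_seed
    for group, (utr, cor, bg) in GROUP_PROBS.items():
        for k in range(N_SPECIES_PER_GROUP):
            seed += 1
            out.append((
                f"{group}_{k + 1}",
                group,
                SimConfig(seed=seed, n_sites=N_SITES, n_chroms=2,
                          chrom_len=40_000, utr_probs=utr, cor_probs=cor,
                          background_probs=bg, frac_internal_priming=0.05,
                          frac_duplicates=0.1),
            ))
    return out
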
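#!/usr/bin/env python
"""Cross-species group comparison: ANOVA, Duncan letters, t-test.

Re-runs the per-species pipeline on the simulated cohort, assembles
per-species U contents (UTR, COR, genome) and region/genome U ratios
into region x group units, and writes the ANOVA-Duncan tables plus the
plants-vs-animals t-test of distal-window U/A ratios to
results/group_comparison.{tsv,json}.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from cohort import SIM_DIR, SUPERGROUPS, cohort_configs

from polyacomp.pipeline import PipelineConfig, compare_groups, run_species


def main():
    cfg = PipelineConfig(min_sites=100, supergroups=SUPERGROUPS)
    runs = []
    for species, group, _ in cohort_configs():
        indir = Path(SIM_DIR) / species
        if not (indir / "genome.fa").exists():
            sys.exit(f"missing {indir}; run analysis/01_simulate_cohort.py first")
        runs.append(run_species(indir / "genome.fa", indir / "transcripts.fa",
                                cfg, species_id=species, group=group))
    result = compare_groups(runs, cfg)

    out = Path("results")
    result.to_tsv(out / "group_comparison.tsv")
    result.to_json(out / "group_comparison.json")

    print("U contents (%), region x group units, Duncan letters:")
    d = result.u_content_duncan
    for unit in d.order:
        print(f"  {unit:18s} mean={d.means[unit]:6.2f}  {d.letters[unit]}")
    print("\nregion/genome U ratios:")
    d = result.u_ratio_duncan
    for unit in d.order:
        print(f"  {unit:18s} mean={d.means[unit]:6.3f}  {d.letters[unit]}")
    t = result.ua_ttest
    print(f"\ndistal-window U/A ratio, {result.ua_ttest_groups[0]} vs "
          f"{result.ua_ttest_groups[1]}: t={t.t:.3f}, df={t.df}, p={t.p:.2g}")
    print("\nwrote results/group_comparison.tsv and .json")


if __name__ == "__main__":
    main()
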
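"""Per-species pipeline orchestration and cross-species group comparison.

``run_species`` chains the stages: screen (tail detection, anchor
extraction, dedup) -> zero-mismatch mapping -> site calling -> site
dedup -> artifact flagging -> positional profile -> window compositions
-> region/genome ratios. ``compare_groups`` assembles per-species U
contents and region/genome U ratios into species-group samples and runs
the one-way ANOVA + Duncan letter display across region x group units,
plus the plants-vs-animals style t-test on distal-window U/A ratios.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from polyacomp.composition import (
    CompositionProfile,
    RatioTable,
    positional_profile,
    region_genome_ratio,
    round_half_up,
    standard_windows,
    ua_ratio,
    window_composition,
)
from polyacomp.errors import ConfigError
from polyacomp.group_stats import (
    AnovaResult,
    DuncanResult,
    GroupSample,
    TTestResult,
    anova_oneway,
    duncan_letters_protected,
    t_test_equal_var,
)
from polyacomp.polya_screen import ScreenReport, screen_transcripts
from polyacomp.sequence_io import BaseComposition, GenomeStore, genome_composition, read_fasta
from polyacomp.site_mapper import PolyASite, call_site, dedupe_sites, match_anchor

log = logging.getLogger("polyacomp")

STAGE_ORDER = ["n_input", "n_tailed", "n_unique_anchors", "n_mapped_anchors",
               "n_unique_sites"]


@dataclass
class PipelineConfig:
    """Flat key-value pipeline configuration (YAML-compatible file)."""

    anchor_len: int = 100          # 80 in read mode
    min_tail: int = 12
    cor_includes_site: bool = False
    exclude_ip_sites: bool = False
    min_sites: int = 100
    symmetrize_background: bool = False
    id_exclude: Optional[str] = None
    alpha: float = 0.05
    groups: dict = field(default_factory=dict)       # species -> group label
    supergroups: dict = field(default_factory=dict)  # group label -> supergroup

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a flat key-value mapping")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)


@dataclass
class SpeciesRun:
    """All stage outputs and the summary for one species."""

    species_id: str
    group: str
    mode: str                      # "mrna" | "reads"
    summary: dict
    screen_report: ScreenReport
    excluded: bool
    sites: list[PolyASite]
    profile: Optional[CompositionProfile]
    genome_comp: BaseComposition
    window_comps: dict[str, BaseComposition]
    ratios: dict[str, RatioTable]
    distal_ua: Optional[float]

    def check_monotone(self) -> None:
        vals = [self.summary[k] for k in STAGE_ORDER]
        if any(a < b for a, b in zip(vals, vals[1:])):
            raise AssertionError(f"stage counts not monotone: {self.summary}")


def run_species(
    genome,
    transcripts,
    config: PipelineConfig = PipelineConfig(),
    species_id: str = "species",
    group: str = "",
) -> SpeciesRun:
    """Execute the full per-species analysis.

    ``genome`` is a GenomeStore or FASTA path; ``transcripts`` a list of
    (id, sequence) records or FASTA path. A species whose unique-site
    count falls below ``config.min_sites`` is marked excluded, not
    errored. Anchor length selects the mode (100 = mrna, 80 = reads).
    """
    if not isinstance(genome, GenomeStore):
        genome = GenomeStore.from_fasta(genome)
    if isinstance(transcripts, (str, Path)):
        transcripts = read_fasta(transcripts)
    mode = "reads" if config.anchor_len == 80 else "mrna"

    anchored, report = screen_transcripts(
        transcripts,
        min_tail=config.min_tail,
        anchor_len=config.anchor_len,
        id_exclude=config.id_exclude,
    )

    sites: list[PolyASite] = []
    n_mapped_anchors = 0
    for item in anchored:
        hits = match_anchor(item.anchor, genome)
        if hits:
            n_mapped_anchors += 1
        for hit in hits:
            site = call_site(hit, genome, tail_len=item.tail_len)
            if site is None:
                log.debug("incomplete downstream window for anchor of %s",
                          item.source_id)
                continue
            sites.append(site)
    unique_sites, n_collapsed = dedupe_sites(sites)
    n_ip = sum(s.ip_flag for s in unique_sites)

    summary = {
        "n_input": report.n_input,
        "n_tailed": report.n_tailed,
        "n_unique_anchors": report.n_unique,
        "n_mapped_anchors": n_mapped_anchors,
        "n_sites_called": len(sites),
        "n_unique_sites": len(unique_sites),
        "n_ip_flagged": n_ip,
    }
    excluded = len(unique_sites) < config.min_sites
    if excluded:
        log.warning("%s: %d unique sites < min_sites=%d; species excluded "
                    "from group comparison", species_id,
                    len(unique_sites), config.min_sites)

    profile_sites = ([s for s in unique_sites if not s.ip_flag]
                     if config.exclude_ip_sites else unique_sites)
    genome_comp = genome_composition(
        genome, symmetrize_background=config.symmetrize_background
    )
    profile = None
    window_comps: dict[str, BaseComposition] = {}
    ratios: dict[str, RatioTable] = {}
    distal_ua = None
    if profile_sites:
        profile = positional_profile(profile_sites)
        windows = standard_windows(config.anchor_len, config.cor_includes_site)
        for name, spec in windows.items():
            comp = window_composition(profile, spec)
            window_comps[name] = comp
            ratios[name] = region_genome_ratio(
                comp, genome_comp, region_name=name, species_id=species_id
            )
        if "DISTAL50" in window_comps:
            distal_ua = ua_ratio(window_comps["DISTAL50"])

    run = SpeciesRun(
        species_id=species_id,
        group=group or config.groups.get(species_id, ""),
        mode=mode,
        summary=summary,
        screen_report=report,
        excluded=excluded,
        sites=unique_sites,
        profile=profile,
        genome_comp=genome_comp,
        window_comps=window_comps,
        ratios=ratios,
        distal_ua=distal_ua,
    )
    run.check_monotone()
    log.info("%s: %s", species_id, summary)
    return run


@dataclass
class GroupComparison:
    """Cross-species report bundle (ANOVA-Duncan tables + t-test)."""

    u_content_units: list[GroupSample]
    u_content_anova: AnovaResult
    u_content_duncan: DuncanResult
    u_ratio_units: list[GroupSample]
    u_ratio_anova: AnovaResult
    u_ratio_duncan: DuncanResult
    ua_ttest: Optional[TTestResult]
    ua_ttest_groups: Optional[tuple[str, str]]

    def to_json(self, path) -> None:
        payload = {
            "u_content": _duncan_payload(self.u_content_anova, self.u_content_duncan,
                                         self.u_content_units),
            "u_ratio": _duncan_payload(self.u_ratio_anova, self.u_ratio_duncan,
                                       self.u_ratio_units),
        }
        if self.ua_ttest is not None:
            payload["ua_ttest"] = {
                "groups": list(self.ua_ttest_groups),
                "t": self.ua_ttest.t,
                "df": self.ua_ttest.df,
                "p": self.ua_ttest.p,
            }
        with open(path, "wt") as out:
            json.dump(payload, out, indent=2)
            out.write("\n")

    def to_tsv(self, path) -> None:
        with open(path, "wt") as out:
            out.write("table\tunit\tn\tmean\tduncan\n")
            for tag, units, dres in [
                ("u_content", self.u_content_units, self.u_content_duncan),
                ("u_ratio", self.u_ratio_units, self.u_ratio_duncan),
            ]:
                ns = {u.group_id: u.n for u in units}
                for gid in dres.order:
                    out.write(f"{tag}\t{gid}\t{ns[gid]}\t"
                              f"{round_half_up(dres.means[gid], 2):.2f}\t"
                              f"{dres.letters[gid]}\n")


def _duncan_payload(anova: AnovaResult, duncan: DuncanResult,
                    units: list[GroupSample]) -> dict:
    return {
        "anova": {"F": anova.F, "p": anova.p, "mse": anova.mse,
                  "df_between": anova.df_between, "df_within": anova.df_within},
        "units": [
            {"unit": gid, "n": next(u.n for u in units if u.group_id == gid),
             "mean": duncan.means[gid], "letters": duncan.letters[gid]}
            for gid in duncan.order
        ],
    }


def compare_groups(
    runs: Sequence[SpeciesRun], config: PipelineConfig = PipelineConfig()
) -> GroupComparison:
    """Species-group comparison over region x group units.

    Units are (region, group) pairs — regions UTR, COR and Genome for U
    contents; UTR/genome and COR/genome for U ratios — each holding one
    value per species (the ANOVA unit is the species, unweighted by
    site counts). Excluded species are dropped. The distal-window U/A
    ratios are t-tested between the two configured supergroups when
    every group maps to one.
    """
    active = [r for r in runs if not r.excluded]
    groups = sorted({r.group for r in active})
    counts = {g: sum(1 for r in active if r.group == g) for g in groups}
    if len(groups) < 2 or any(c < 2 for c in counts.values()):
        raise ConfigError(
            "group comparison needs >= 2 groups with >= 2 species each; "
            f"got {counts}"
        )

    utr_key = lambda r: f"UTR{len(r.sites[0].utr_window)}"
    content_units: list[GroupSample] = []
    ratio_units: list[GroupSample] = []
    for g in groups:
        members = [r for r in active if r.group == g]
        content_units.append(GroupSample(
            f"UTR_{g}", [m.window_comps[utr_key(m)].pct_TU for m in members]))
        content_units.append(GroupSample(
            f"COR_{g}", [m.window_comps["COR100"].pct_TU for m in members]))
        content_units.append(GroupSample(
            f"Genome_{g}", [m.genome_comp.pct_TU for m in members]))
        ratio_units.append(GroupSample(
            f"UTR_{g}", [m.ratios[utr_key(m)].ratio_TU for m in members]))
        ratio_units.append(GroupSample(
            f"COR_{g}", [m.ratios["COR100"].ratio_TU for m in members]))

    content_anova = anova_oneway(content_units)
    content_duncan = duncan_letters_protected(content_units, alpha=config.alpha)
    ratio_anova = anova_oneway(ratio_units)
    ratio_duncan = duncan_letters_protected(ratio_units, alpha=config.alpha)

    ttest = None
    ttest_groups = None
    supers = {config.supergroups.get(g) for g in groups}
    if len(supers) == 2 and None not in supers:
        s1, s2 = sorted(supers)
        a = [r.distal_ua for r in active
             if config.supergroups[r.group] == s1 and r.distal_ua is not None]
        b = [r.distal_ua for r in active
             if config.supergroups[r.group] == s2 and r.distal_ua is not None]
        if len(a) >= 2 and len(b) >= 2:
            ttest = t_test_equal_var(a, b)
            ttest_groups = (s1, s2)

    return GroupComparison(
        u_content_units=content_units,
        u_content_anova=content_anova,
        u_content_duncan=content_duncan,
        u_ratio_units=ratio_units,
        u_ratio_anova=ratio_anova,
        u_ratio_duncan=ratio_duncan,
        ua_ttest=ttest,
        ua_ttest_groups=ttest_groups,
    )
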
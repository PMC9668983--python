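"""End-to-end audit orchestration and summary-table assembly.

Builds two headline tables mirroring the usual structure of a trio-QC
report -- a dataset-structure summary (individuals, trios, families, loci,
mismatch counts, derived means and error rates) and a per-class table
(loci, mismatches and fraction, concentration statistics, mean F_IS, and
the allele-drop composition of each class) -- plus the per-locus summary,
event, annotation and filter-scenario tables they are derived from. Every
number in the headline tables is recomputable from the emitted TSVs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import allele_drop, annotate_overlap, filter_eval, locus_stats, mendel_classify
from .io_pedigree import (
    Family,
    GenotypeTable,
    IntervalTrack,
    Pedigree,
    Trio,
    extract_trios_and_families,
    read_bed_track,
    read_litters,
    read_ped_map,
)
from .mendel_classify import ME_CLASSES, MESet

__all__ = [
    "AuditResult",
    "audit",
    "run_audit",
    "derived_structure_stats",
    "class_fractions",
    "build_class_table",
]


def derived_structure_stats(
    n_loci: int,
    n_me_loci: int,
    n_mismatches: int,
    n_trios: int,
    n_families: int,
    n_litters: Optional[int] = None,
    n_individuals: Optional[int] = None,
    n_autosomes: int = 18,
    n_me_loci_table: Optional[int] = None,
    unique_loci: Optional[int] = None,
) -> dict[str, float]:
    """Derived reporting quantities from component counts.

    ``n_me_loci_table`` allows a separately tabulated mismatch-locus count
    to drive the per-autosome mean when it differs from the scan total.
    """
    n_ind = n_individuals if n_individuals is not None else n_trios
    out: dict[str, float] = {
        "mean_me_per_individual": n_mismatches / n_trios,
        "mean_sites_per_autosome": n_loci / n_autosomes,
        "mean_me_sites_per_autosome": (
            (n_me_loci_table if n_me_loci_table is not None else n_me_loci)
            / n_autosomes
        ),
        "mean_offspring_per_family": n_trios / n_families,
    }
    if n_litters:
        out["mean_offspring_per_litter"] = n_trios / n_litters
    rates = locus_stats.error_rates_from_counts(
        m_l=n_me_loci,
        m_a=n_mismatches,
        n_loci_total=n_loci,
        n_individuals=n_ind,
        unique_loci_count=unique_loci or 0,
    )
    out["e_l"] = rates.e_l
    out["e_a"] = rates.e_a
    if unique_loci is not None:
        out["unique_contribution"] = rates.unique_contribution
    return out


def class_fractions(mismatches_per_class: pd.Series) -> pd.Series:
    """Fraction of all mismatches per ME class (sums to 1 when any exist)."""
    total = mismatches_per_class.sum()
    if total == 0:
        return mismatches_per_class.astype(float)
    return mismatches_per_class / total


def build_class_table(
    meset: MESet,
    locus_summaries: pd.DataFrame,
    drop_classes: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Per-ME-class summary: loci, mismatches (count and fraction of the
    total), mean mismatches per affected offspring individual, mean number
    of distinct families per class locus, mean/sd F_IS over class loci, and
    the fraction of class mismatches at ADO / ADI_het / ADI_hom loci."""
    ev = meset.events
    idx = pd.Index(ME_CLASSES, name="me_class")
    cols = [
        "n_loci",
        "n_mismatches",
        "frac_mismatches",
        "mean_mismatches_per_individual",
        "mean_families_per_locus",
        "mean_f_is",
        "sd_f_is",
        "frac_ado",
        "frac_adi_het",
        "frac_adi_hom",
    ]
    table = pd.DataFrame(0.0, index=idx, columns=cols)
    table[["n_loci", "n_mismatches"]] = 0
    if not len(ev):
        return table
    g = ev.groupby("me_class")
    n_loci = g["locus_id"].nunique().reindex(idx, fill_value=0)
    n_mism = g.size().reindex(idx, fill_value=0)
    n_off = g["offspring_id"].nunique().reindex(idx, fill_value=0)
    fam_per_locus = (
        ev.groupby(["me_class", "locus_id"])["family_key"]
        .nunique()
        .groupby("me_class")
        .mean()
        .reindex(idx)
    )
    fis_mean = pd.Series(np.nan, index=idx)
    fis_sd = pd.Series(np.nan, index=idx)
    for mc in idx:
        class_loci = ev.loc[ev["me_class"] == mc, "locus_id"].unique()
        if len(class_loci):
            vals = locus_summaries.loc[class_loci, "f_is"]
            fis_mean[mc] = vals.mean()
            fis_sd[mc] = vals.std()
    table["n_loci"] = n_loci.astype(int)
    table["n_mismatches"] = n_mism.astype(int)
    table["frac_mismatches"] = class_fractions(n_mism)
    with np.errstate(invalid="ignore", divide="ignore"):
        table["mean_mismatches_per_individual"] = np.where(
            n_off > 0, n_mism / n_off.replace(0, 1), np.nan
        )
    table["mean_families_per_locus"] = fam_per_locus
    table["mean_f_is"] = fis_mean
    table["sd_f_is"] = fis_sd
    if drop_classes is not None:
        drops = ev["locus_id"].map(drop_classes)
        for dc, col in (("ADO", "frac_ado"), ("ADI_het", "frac_adi_het"),
                        ("ADI_hom", "frac_adi_hom")):
            hit = ev[drops == dc].groupby("me_class").size().reindex(idx, fill_value=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                table[col] = np.where(n_mism > 0, hit / n_mism.replace(0, 1), 0.0)
    return table


@dataclass
class AuditResult:
    pedigree: Pedigree
    genotypes: GenotypeTable
    trios: list[Trio]
    families: list[Family]
    locus_summaries: pd.DataFrame
    meset: MESet
    counts: mendel_classify.MismatchCounts
    drop_classes: pd.Series
    drop_table: pd.DataFrame
    annotations: Optional[pd.DataFrame]
    feature_table: Optional[annotate_overlap.FeatureTable]
    filter_reports: pd.DataFrame
    structure: dict
    class_table: pd.DataFrame

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.locus_summaries.to_csv(out / "locus_summaries.tsv", sep="\t")
        self.meset.events.to_csv(out / "events.tsv", sep="\t", index=False)
        self.drop_classes.to_frame().to_csv(out / "drop_classes.tsv", sep="\t")
        self.drop_table.to_csv(out / "drop_table.tsv", sep="\t")
        if self.annotations is not None:
            self.annotations.to_csv(out / "annotations.tsv", sep="\t")
        if self.feature_table is not None:
            self.feature_table.loci.to_csv(out / "feature_loci.tsv", sep="\t")
            self.feature_table.mismatches.to_csv(
                out / "feature_mismatches.tsv", sep="\t"
            )
        self.filter_reports.to_csv(out / "filter_reports.tsv", sep="\t")
        self.class_table.to_csv(out / "class_table.tsv", sep="\t")
        (out / "structure.json").write_text(json.dumps(self.structure, indent=1))


def audit(
    genotypes: GenotypeTable,
    pedigree: Pedigree,
    litters: Optional[dict[str, str]] = None,
    tracks: Sequence[IntervalTrack] = (),
    scenarios: Optional[Sequence[filter_eval.FilterScenario]] = None,
) -> AuditResult:
    """Run the whole audit on in-memory objects."""
    trios, families = extract_trios_and_families(
        pedigree, genotyped_ids=genotypes.individuals, litters=litters
    )
    summaries = locus_stats.summarize_table(genotypes)
    meset = mendel_classify.scan_dataset(genotypes, trios, summaries)
    counts = mendel_classify.mismatch_counts(meset, trios, families)
    drop_classes = allele_drop.classify_meset_loci(
        genotypes, pedigree, sorted(meset.loci)
    )
    drop_table = allele_drop.drop_report(meset, drop_classes)

    annotations = feature_table = None
    if tracks:
        annotations = annotate_overlap.annotate_loci(genotypes.loci, list(tracks))
        feature_table = annotate_overlap.class_feature_table(meset, annotations)

    if scenarios is None:
        scenarios = filter_eval.default_scenarios()
    filter_reports = filter_eval.scenario_grid(summaries, meset, scenarios)

    rates = locus_stats.error_rates(meset, genotypes.n_loci, genotypes.n_individuals)
    n_autosomes = len({l.chrom for l in genotypes.loci}) or 1
    n_litters = len(set(litters.values())) if litters else None
    structure: dict = {
        "n_individuals": genotypes.n_individuals,
        "n_trios": len(trios),
        "n_families": len(families),
        "n_litters": n_litters,
        "n_loci": genotypes.n_loci,
        "n_me_loci": len(meset.loci),
        "n_mismatches": meset.n_mismatches,
        "n_unique_loci": len(meset.unique_loci),
        "e_l": rates.e_l,
        "e_a": rates.e_a,
        "unique_contribution": rates.unique_contribution,
        "family_size_pearson_r": counts.pearson_r,
        "family_size_spearman_r": counts.spearman_r,
    }
    if len(trios):
        structure.update(
            derived_structure_stats(
                n_loci=genotypes.n_loci,
                n_me_loci=len(meset.loci),
                n_mismatches=meset.n_mismatches,
                n_trios=len(trios),
                n_families=max(len(families), 1),
                n_litters=n_litters,
                n_individuals=genotypes.n_individuals,
                n_autosomes=n_autosomes,
                unique_loci=len(meset.unique_loci),
            )
        )
    class_table = build_class_table(meset, summaries, drop_classes)
    return AuditResult(
        pedigree=pedigree,
        genotypes=genotypes,
        trios=trios,
        families=families,
        locus_summaries=summaries,
        meset=meset,
        counts=counts,
        drop_classes=drop_classes,
        drop_table=drop_table,
        annotations=annotations,
        feature_table=feature_table,
        filter_reports=filter_reports,
        structure=structure,
        class_table=class_table,
    )


def run_audit(
    ped_path: str | Path,
    map_path: str | Path,
    out_dir: Optional[str | Path] = None,
    cnv_bed: Optional[str | Path] = None,
    sine_bed: Optional[str | Path] = None,
    line_bed: Optional[str | Path] = None,
    litters_path: Optional[str | Path] = None,
    scenarios: Optional[Sequence[filter_eval.FilterScenario]] = None,
) -> AuditResult:
    """File-level audit entry point; writes the report bundle when ``out_dir``
    is given."""
    pedigree, genotypes = read_ped_map(ped_path, map_path)
    litters = read_litters(litters_path) if litters_path else None
    tracks = []
    for path, name in ((cnv_bed, "CNV"), (sine_bed, "SINE"), (line_bed, "LINE")):
        if path:
            tracks.append(read_bed_track(path, name))
    result = audit(genotypes, pedigree, litters=litters, tracks=tracks,
                   scenarios=scenarios)
    if out_dir is not None:
        result.write(out_dir)
    return result
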
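"""Overlap of mismatch-set loci with genomic feature tracks (CNV/SINE/LINE).

SNPs are treated as single-bp points. A SNP at 1-based position p overlaps
a BED interval [start, end) iff start < p <= end in 1-based closed terms,
i.e. start <= p - 1 < end on the 0-based half-open scale. Chromosome
matching is string-based; a name mismatch simply yields no overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io_pedigree import IntervalTrack, LocusRecord
from .mendel_classify import ME_CLASSES, MESet

__all__ = [
    "overlap_loci",
    "annotate_loci",
    "overlap_carriers",
    "class_feature_table",
    "FeatureTable",
]


def _trees(track: IntervalTrack) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in track:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


def overlap_loci(loci: Sequence[LocusRecord], track: IntervalTrack) -> pd.Series:
    """Boolean Series (indexed by locus_id): does the SNP fall in >=1 interval?"""
    trees = _trees(track)
    hits = []
    for loc in loci:
        tree = trees.get(loc.chrom)
        hits.append(bool(tree is not None and tree.at(loc.pos - 1)))
    return pd.Series(
        hits, index=pd.Index([l.locus_id for l in loci], name="locus_id"), name=track.name
    )


def annotate_loci(
    loci: Sequence[LocusRecord], tracks: Sequence[IntervalTrack]
) -> pd.DataFrame:
    """One boolean column per track, plus the CNV kinds hit (comma-joined).

    Multi-membership is allowed: a locus inside both a SINE and a CNV is
    flagged in both columns.
    """
    out = pd.DataFrame(index=pd.Index([l.locus_id for l in loci], name="locus_id"))
    for track in tracks:
        out[track.name] = overlap_loci(loci, track)
    for track in tracks:
        if track.name.upper().startswith("CNV"):
            trees = _trees(track)
            kinds = []
            for loc in loci:
                tree = trees.get(loc.chrom)
                if tree is None:
                    kinds.append("")
                    continue
                ks = sorted({h.data.kind for h in tree.at(loc.pos - 1)})
                kinds.append(",".join(ks))
            out[f"{track.name}_kind"] = kinds
            break
    return out


def overlap_carriers(
    loci: Sequence[LocusRecord], track: IntervalTrack
) -> pd.DataFrame:
    """Per-individual overlap for a carrier-aware CNV track.

    Returns one row per (locus, carrier) pair whose carried interval spans
    the SNP; intervals without a carrier id are skipped.
    """
    trees = _trees(track)
    rows = []
    for loc in loci:
        tree = trees.get(loc.chrom)
        if tree is None:
            continue
        for hit in sorted(tree.at(loc.pos - 1)):
            iv = hit.data
            if iv.carrier_id is not None:
                rows.append((loc.locus_id, iv.carrier_id, iv.kind))
    return pd.DataFrame(rows, columns=["locus_id", "carrier_id", "kind"])


@dataclass(frozen=True)
class FeatureTable:
    """ME class x feature contingency counts.

    ``loci`` and ``mismatches`` have one row per ME class and one column per
    feature plus "none" (in no track). A locus in several tracks counts once
    per feature column, so feature columns may sum past the locus total; the
    "none" column plus the union of the features partitions the loci.
    """

    loci: pd.DataFrame
    mismatches: pd.DataFrame
    locus_feature_fraction: pd.Series  # fraction of mismatch-set loci per feature


def class_feature_table(meset: MESet, annotations: pd.DataFrame) -> FeatureTable:
    """Cross-tabulate events against feature annotations from :func:`annotate_loci`."""
    features = [c for c in annotations.columns if annotations[c].dtype == bool]
    cols = features + ["none"]
    loci_t = pd.DataFrame(0, index=pd.Index(ME_CLASSES, name="me_class"), columns=cols)
    mism_t = loci_t.copy()
    ev = meset.events
    if len(ev):
        missing = set(ev["locus_id"]) - set(annotations.index)
        if missing:
            raise ValueError(
                f"annotations missing for {len(missing)} mismatch-set loci"
            )
        ann = annotations.loc[ev["locus_id"], features].reset_index(drop=True)
        in_none = ~ann.any(axis=1)
        for col in features:
            sub = ev[ann[col].to_numpy()]
            mism_t[col] = sub.groupby("me_class").size().reindex(ME_CLASSES, fill_value=0)
            loci_t[col] = (
                sub.groupby("me_class")["locus_id"].nunique().reindex(ME_CLASSES, fill_value=0)
            )
        sub = ev[in_none.to_numpy()]
        mism_t["none"] = sub.groupby("me_class").size().reindex(ME_CLASSES, fill_value=0)
        loci_t["none"] = (
            sub.groupby("me_class")["locus_id"].nunique().reindex(ME_CLASSES, fill_value=0)
        )
        me_loci = ev["locus_id"].drop_duplicates()
        ann_loci = annotations.loc[me_loci, features]
        frac = ann_loci.mean(axis=0)
        frac["none"] = float((~ann_loci.any(axis=1)).mean())
    else:
        frac = pd.Series(0.0, index=pd.Index(cols))
    return FeatureTable(
        loci=loci_t.fillna(0).astype(int),
        mismatches=mism_t.fillna(0).astype(int),
        locus_feature_fraction=frac.astype(float),
    )
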
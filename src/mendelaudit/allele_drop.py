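"""Allele-Drop-Out / Allele-Drop-In classification of mismatch-set loci.

ADO (allele drop-out, the null-allele signature): no heterozygote anywhere
in the typed population but homozygotes exist for both alleles, with the
second allele segregating among the reproducers themselves (both
homozygote classes present among called reproductive individuals). ADI
(allele drop-in, a "new" allele relative to the parental genotypes): all
called reproductive individuals are homozygous for one same allele while
offspring carry the other allele -- as heterozygotes (ADI_het) or as
opposite homozygotes (ADI_hom). Requiring the ADO allele to segregate in
reproducers is what keeps ADO and ADI_hom distinguishable: an ADI_hom
locus also has both homozygote classes and no heterozygotes, but the
second allele appears only in offspring. Precedence when definitions
could still co-trigger on pathological inputs: ADO > ADI_het > ADI_hom.

"Reproductive" means: has at least one offspring in the pedigree. Missing
calls are ignored throughout.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .io_pedigree import GenotypeTable, Pedigree
from .mendel_classify import ME_CLASSES, MESet

__all__ = ["DROP_CLASSES", "classify_drop", "classify_meset_loci", "drop_report"]

DROP_CLASSES = ("ADO", "ADI_het", "ADI_hom", "none")


def classify_drop(calls_at_locus: np.ndarray, reproductive_mask: np.ndarray) -> str:
    """Classify one locus into ADO / ADI_het / ADI_hom / none.

    ``reproductive_mask`` aligns with the call vector and flags individuals
    with >=1 offspring in the pedigree.
    """
    calls = np.asarray(calls_at_locus)
    repro = np.asarray(reproductive_mask, dtype=bool)
    if calls.shape != repro.shape:
        raise ValueError("calls and reproductive mask must align")
    called = calls >= 0
    if not (called & repro).any():
        warnings.warn("no called reproductive individuals at locus; returning 'none'")
        return "none"
    has_het = bool((calls[called] == 1).any())
    repro_calls = calls[called & repro]
    both_homs_repro = bool((repro_calls == 0).any()) and bool((repro_calls == 2).any())
    if not has_het and both_homs_repro:
        return "ADO"
    fixed_hom = repro_calls[0] in (0, 2) and bool((repro_calls == repro_calls[0]).all())
    if fixed_hom:
        offspring_calls = calls[called & ~repro]
        other = 2 - int(repro_calls[0])
        if (offspring_calls == 1).any():
            return "ADI_het"
        if (offspring_calls == other).any():
            return "ADI_hom"
    return "none"


def classify_meset_loci(
    genotypes: GenotypeTable,
    pedigree: Pedigree,
    loci: Optional[Iterable[str]] = None,
) -> pd.Series:
    """Drop class per locus (default: every locus in the table).

    Typically called on the mismatch-set loci only, per the ADO/ADI
    definitions' scope.
    """
    repro = pedigree.reproductive_mask(genotypes.individuals)
    ids = list(loci) if loci is not None else [l.locus_id for l in genotypes.loci]
    out = pd.Series(
        [classify_drop(genotypes.locus_calls(lid), repro) for lid in ids],
        index=pd.Index(ids, name="locus_id"),
        name="drop_class",
        dtype=object,
    )
    return out


def drop_report(meset: MESet, drop_classes: pd.Series) -> pd.DataFrame:
    """Cross-tabulate loci and mismatches per (ME class x drop class).

    Rows are the eight ME classes; columns are a two-level index of
    (loci|mismatches, drop class). Loci with events in several ME classes
    count once per class row. ADO loci carrying Trio-class events would
    contradict the ADO definition (no heterozygotes implies no Trio event)
    and raise.
    """
    ev = meset.events
    out = pd.DataFrame(
        0,
        index=pd.Index(ME_CLASSES, name="me_class"),
        columns=pd.MultiIndex.from_product(
            [("loci", "mismatches"), DROP_CLASSES], names=["count", "drop_class"]
        ),
        dtype=int,
    )
    if not len(ev):
        return out
    missing = set(ev["locus_id"]) - set(drop_classes.index)
    if missing:
        raise ValueError(f"drop classes missing for {len(missing)} mismatch-set loci")
    drops = ev["locus_id"].map(drop_classes)
    grp = ev.assign(drop_class=drops).groupby(["me_class", "drop_class"], sort=False)
    mism = grp.size()
    loci = grp["locus_id"].nunique()
    for (mc, dc), v in mism.items():
        out.loc[mc, ("mismatches", dc)] = v
    for (mc, dc), v in loci.items():
        out.loc[mc, ("loci", dc)] = v
    trio_ado = int(
        out.loc[["TrioA", "TrioB"], [("mismatches", "ADO")]].to_numpy().sum()
    )
    if trio_ado:
        raise AssertionError(
            "ADO loci carry Trio-class events; ADO requires zero heterozygotes, "
            "which precludes Trio events -- inconsistent inputs"
        )
    return out
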
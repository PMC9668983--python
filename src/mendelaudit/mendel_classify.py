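"""Mendelian-inconsistency detection and eight-class assignment.

A trio genotype configuration is inconsistent when the offspring's two
alleles cannot be formed by taking one allele from each parent. Each
inconsistent (trio, locus) pair yields exactly one event, assigned to a
trio member and a violating allele:

* offspring heterozygous with both parents homozygous for the same allele
  -> the error cannot be placed on any member ("Trio"); the violating
  allele is the one absent from the parents;
* offspring homozygous for allele k with exactly one parent homozygous for
  the other allele -> that parent; violating allele k;
* offspring homozygous for k with both parents homozygous for the other
  allele -> "Offspring"; violating allele k.

The frequency class is A when the violating allele is the locus's major
allele (most frequent over all called genotypes, ties -> allele1) and B
otherwise, giving the eight classes TrioA..OffspringB.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_pedigree import Family, GenotypeTable, Trio, family_key_str
from . import locus_stats

__all__ = [
    "MEMBERS",
    "ME_CLASSES",
    "MendelEvent",
    "MESet",
    "classify_call_triplet",
    "check_trio_locus",
    "scan_dataset",
    "mismatch_counts",
    "MismatchCounts",
]

MEMBERS = ("Trio", "Father", "Mother", "Offspring")
ME_CLASSES = tuple(f"{m}{fc}" for m in MEMBERS for fc in ("A", "B"))

EVENT_COLUMNS = [
    "locus_id",
    "chrom",
    "pos",
    "offspring_id",
    "father_id",
    "mother_id",
    "family_key",
    "member",
    "violating_allele",
    "freq_class",
    "me_class",
]


class StructureError(KeyError):
    """A trio member is absent from the genotype table."""


@dataclass(frozen=True)
class MendelEvent:
    member: str  # Trio | Father | Mother | Offspring
    violating_code: int  # 1 = allele1, 2 = allele2
    freq_class: str  # A | B
    trio: Optional[Trio] = None
    locus_id: Optional[str] = None
    violating_allele: Optional[str] = None

    @property
    def me_class(self) -> str:
        return f"{self.member}{self.freq_class}"


@dataclass(frozen=True)
class MESet:
    """All Mendelian events of a scan plus the derived locus sets."""

    events: pd.DataFrame  # one row per inconsistent (trio, locus)
    loci: frozenset
    unique_loci: frozenset  # loci with events in exactly one trio

    @classmethod
    def from_events(cls, events: pd.DataFrame) -> "MESet":
        if len(events):
            per_locus_trios = events.groupby("locus_id", sort=False)["offspring_id"].nunique()
            loci = frozenset(per_locus_trios.index)
            unique = frozenset(per_locus_trios.index[per_locus_trios == 1])
        else:
            loci = frozenset()
            unique = frozenset()
        return cls(events=events, loci=loci, unique_loci=unique)

    @property
    def n_mismatches(self) -> int:
        return len(self.events)


def classify_call_triplet(
    father: int, mother: int, child: int
) -> Optional[tuple[str, int]]:
    """Classify one call triplet (codes = copies of allele2, all non-missing).

    Returns None when the configuration is Mendelian-consistent, else
    (member, violating allele as 1/2).
    """
    for c in (father, mother, child):
        if c not in (0, 1, 2):
            raise ValueError("calls must be non-missing codes 0, 1 or 2")
    f_gametes = {0: (0,), 1: (0, 1), 2: (1,)}[father]
    m_gametes = {0: (0,), 1: (0, 1), 2: (1,)}[mother]
    if any(a + b == child for a in f_gametes for b in m_gametes):
        return None
    if child == 1:
        # inconsistent het child implies both parents homozygous for the same
        # allele; the violating allele is the one the parents lack
        return ("Trio", 2 if father == 0 else 1)
    k = 2 if child == 2 else 1  # allele the child is homozygous for
    other_hom = 0 if child == 2 else 2
    father_other = father == other_hom
    mother_other = mother == other_hom
    if father_other and mother_other:
        return ("Offspring", k)
    if father_other:
        return ("Father", k)
    return ("Mother", k)


def check_trio_locus(
    father_call: int,
    mother_call: int,
    child_call: int,
    major_allele: int,
    *,
    trio: Optional[Trio] = None,
    locus_id: Optional[str] = None,
    allele_symbols: Optional[tuple[Optional[str], Optional[str]]] = None,
) -> Optional[MendelEvent]:
    """Check one trio at one locus; None means consistent.

    ``major_allele`` is 1 or 2 (which of the locus alleles is the major
    one). Missing calls violate the precondition and raise.
    """
    if min(father_call, mother_call, child_call) < 0:
        raise ValueError("missing call in trio; caller must skip this locus")
    if major_allele not in (1, 2):
        raise ValueError("major_allele must be 1 or 2")
    hit = classify_call_triplet(father_call, mother_call, child_call)
    if hit is None:
        return None
    member, viol = hit
    symbol = None
    if allele_symbols is not None:
        symbol = allele_symbols[viol - 1]
    return MendelEvent(
        member=member,
        violating_code=viol,
        freq_class="A" if viol == major_allele else "B",
        trio=trio,
        locus_id=locus_id,
        violating_allele=symbol,
    )


def _build_luts() -> tuple[np.ndarray, np.ndarray]:
    member_lut = np.full(27, -1, dtype=np.int8)
    viol_lut = np.zeros(27, dtype=np.int8)
    for f in range(3):
        for m in range(3):
            for c in range(3):
                hit = classify_call_triplet(f, m, c)
                if hit is not None:
                    member_lut[f * 9 + m * 3 + c] = MEMBERS.index(hit[0])
                    viol_lut[f * 9 + m * 3 + c] = hit[1]
    return member_lut, viol_lut


_MEMBER_LUT, _VIOL_LUT = _build_luts()


def scan_dataset(
    genotypes: GenotypeTable,
    trios: Sequence[Trio],
    locus_summaries: Optional[pd.DataFrame] = None,
) -> MESet:
    """Scan every (trio, locus) pair for Mendelian inconsistencies.

    ``locus_summaries`` (from :func:`locus_stats.summarize_table`) supplies
    the major allele per locus; computed on the fly when omitted. Trios with
    a missing call at a locus are skipped at that locus. Output rows are
    sorted locus-major, trio-minor; the scan is fully deterministic.
    """
    if locus_summaries is None:
        locus_summaries = locus_stats.summarize_table(genotypes)
    major = locus_summaries["major_allele"].reindex(
        [l.locus_id for l in genotypes.loci]
    ).to_numpy(dtype=np.int8)

    loc_idx_parts: list[np.ndarray] = []
    trio_idx_parts: list[np.ndarray] = []
    member_parts: list[np.ndarray] = []
    viol_parts: list[np.ndarray] = []

    calls = genotypes.calls
    for t_i, trio in enumerate(trios):
        try:
            fi = genotypes.ind_index[trio.father_id]
            mi = genotypes.ind_index[trio.mother_id]
            ci = genotypes.ind_index[trio.offspring_id]
        except KeyError as exc:
            raise StructureError(
                f"trio ({trio.offspring_id}, {trio.father_id}, {trio.mother_id}): "
                f"member {exc.args[0]!r} absent from genotype table"
            ) from exc
        f = calls[:, fi]
        m = calls[:, mi]
        c = calls[:, ci]
        valid = (f >= 0) & (m >= 0) & (c >= 0)
        idx = (f * 9 + m * 3 + c).astype(np.int16)
        member = np.where(valid, _MEMBER_LUT[np.where(valid, idx, 0)], -1)
        hit = member >= 0
        if not hit.any():
            continue
        where = np.flatnonzero(hit)
        loc_idx_parts.append(where)
        trio_idx_parts.append(np.full(len(where), t_i, dtype=np.int32))
        member_parts.append(member[where].astype(np.int8))
        viol_parts.append(_VIOL_LUT[idx[where]])

    if loc_idx_parts:
        loc_idx = np.concatenate(loc_idx_parts)
        trio_idx = np.concatenate(trio_idx_parts)
        member_i = np.concatenate(member_parts)
        viol = np.concatenate(viol_parts)
        order = np.lexsort((trio_idx, loc_idx))
        loc_idx, trio_idx, member_i, viol = (
            loc_idx[order],
            trio_idx[order],
            member_i[order],
            viol[order],
        )
    else:
        loc_idx = np.empty(0, dtype=np.int64)
        trio_idx = np.empty(0, dtype=np.int32)
        member_i = np.empty(0, dtype=np.int8)
        viol = np.empty(0, dtype=np.int8)

    loci = genotypes.loci
    locus_ids = np.array([l.locus_id for l in loci], dtype=object)
    chroms = np.array([l.chrom for l in loci], dtype=object)
    poss = np.array([l.pos for l in loci], dtype=np.int64)
    symbols = np.array(
        [[l.allele1, l.allele2] for l in loci] if loci else np.empty((0, 2)),
        dtype=object,
    ).reshape(len(loci), 2)

    offspring = np.array([t.offspring_id for t in trios] + [""], dtype=object)
    fathers = np.array([t.father_id for t in trios] + [""], dtype=object)
    mothers = np.array([t.mother_id for t in trios] + [""], dtype=object)

    member_s = np.array(MEMBERS, dtype=object)[member_i] if len(member_i) else np.empty(0, dtype=object)
    freq_class = np.where(viol == major[loc_idx], "A", "B") if len(loc_idx) else np.empty(0, dtype=object)
    events = pd.DataFrame(
        {
            "locus_id": locus_ids[loc_idx],
            "chrom": chroms[loc_idx],
            "pos": poss[loc_idx],
            "offspring_id": offspring[trio_idx] if len(trio_idx) else np.empty(0, dtype=object),
            "father_id": fathers[trio_idx] if len(trio_idx) else np.empty(0, dtype=object),
            "mother_id": mothers[trio_idx] if len(trio_idx) else np.empty(0, dtype=object),
            "member": member_s,
            "violating_code": viol,
            "freq_class": freq_class,
        },
        columns=[
            "locus_id",
            "chrom",
            "pos",
            "offspring_id",
            "father_id",
            "mother_id",
            "member",
            "violating_code",
            "freq_class",
        ],
    )
    events["family_key"] = [
        family_key_str(f, m) for f, m in zip(events["father_id"], events["mother_id"])
    ]
    events["violating_allele"] = (
        symbols[loc_idx, viol - 1] if len(loc_idx) else np.empty(0, dtype=object)
    )
    events["me_class"] = events["member"].astype(str) + events["freq_class"].astype(str)
    events = events[EVENT_COLUMNS + ["violating_code"]].reset_index(drop=True)
    return MESet.from_events(events)


@dataclass(frozen=True)
class MismatchCounts:
    per_offspring: pd.Series  # indexed by every trio offspring id (zeros kept)
    per_family: pd.Series  # indexed by family key string
    per_locus: pd.Series
    per_class: pd.Series  # indexed by the eight classes
    family_size: pd.Series
    pearson_r: float
    pearson_p: float
    spearman_r: float
    spearman_p: float


def mismatch_counts(
    meset: MESet, trios: Sequence[Trio], families: Sequence[Family]
) -> MismatchCounts:
    """Count mismatches per offspring, family, locus and class; correlate
    family mismatch counts with family size (Pearson and Spearman).

    Correlations are NaN when undefined (fewer than 3 families, zero
    variance, or an empty event set).
    """
    ev = meset.events
    offspring_ids = [t.offspring_id for t in trios]
    fam_keys = [family_key_str(*f.family_key) for f in families]
    per_off = (
        ev.groupby("offspring_id").size().reindex(offspring_ids, fill_value=0)
        if len(ev)
        else pd.Series(0, index=pd.Index(offspring_ids, name="offspring_id"), dtype=int)
    )
    per_fam = (
        ev.groupby("family_key").size().reindex(fam_keys, fill_value=0)
        if len(ev)
        else pd.Series(0, index=pd.Index(fam_keys, name="family_key"), dtype=int)
    )
    per_locus = ev.groupby("locus_id").size() if len(ev) else pd.Series(dtype=int)
    per_class = (
        ev.groupby("me_class").size().reindex(ME_CLASSES, fill_value=0)
        if len(ev)
        else pd.Series(0, index=pd.Index(ME_CLASSES, name="me_class"), dtype=int)
    )
    sizes = pd.Series([f.size for f in families], index=per_fam.index, dtype=int)

    pr = pp = sr = sp = float("nan")
    if len(families) >= 3 and len(ev) and sizes.nunique() > 1 and per_fam.nunique() > 1:
        pr, pp = stats.pearsonr(sizes, per_fam)
        sr, sp = stats.spearmanr(sizes, per_fam)
    return MismatchCounts(
        per_offspring=per_off,
        per_family=per_fam,
        per_locus=per_locus,
        per_class=per_class,
        family_size=sizes,
        pearson_r=float(pr),
        pearson_p=float(pp),
        spearman_r=float(sr),
        spearman_p=float(sp),
    )
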
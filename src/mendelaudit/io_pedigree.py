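"""Pedigree and genotype input/output.

Reads and writes the PLINK text dialect (whitespace-delimited PED/MAP with
allele pairs, ``0`` = missing), BED3/BED5 interval tracks and a litter side
table; builds the pedigree graph and enumerates parent-offspring trios and
families (all trios sharing the same parental couple).

Coordinate conventions: MAP/PED positions are 1-based; interval tracks are
stored 0-based half-open exactly as BED specifies. Genotype calls are coded
as the number of copies of ``allele2`` (0/1/2), with -1 for missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd

MISSING = np.int8(-1)

MALE = "male"
FEMALE = "female"
UNKNOWN = "unknown"

_SEX_FROM_PED = {"1": MALE, "2": FEMALE}
_SEX_TO_PED = {MALE: "1", FEMALE: "2", UNKNOWN: "0"}


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


class PolyallelicError(FormatError):
    """More than two distinct non-missing alleles observed at a locus."""


class PedigreeError(ValueError):
    """Structural problem in the pedigree graph."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Individual:
    id: str
    sire_id: Optional[str] = None
    dam_id: Optional[str] = None
    sex: str = UNKNOWN
    is_reproductive: bool = False


@dataclass(frozen=True)
class Trio:
    offspring_id: str
    father_id: str
    mother_id: str
    litter_id: Optional[str] = None

    @property
    def family_key(self) -> tuple[str, str]:
        return (self.father_id, self.mother_id)


@dataclass(frozen=True)
class Family:
    family_key: tuple[str, str]
    offspring_ids: tuple[str, ...]

    @property
    def size(self) -> int:
        return len(self.offspring_ids)


@dataclass(frozen=True)
class LocusRecord:
    locus_id: str
    chrom: str
    pos: int  # 1-based
    allele1: Optional[str] = None
    allele2: Optional[str] = None


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int  # 0-based, inclusive
    end: int  # 0-based, exclusive
    kind: str = "other"
    carrier_id: Optional[str] = None


@dataclass
class IntervalTrack:
    name: str
    intervals: list[Interval] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.intervals)


class Pedigree:
    """Acyclic parent map over a set of individuals.

    ``is_reproductive`` flags are recomputed on construction: true iff the
    individual appears as sire or dam of some member.
    """

    def __init__(self, individuals: Iterable[Individual]):
        members: dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in members:
                raise PedigreeError(f"duplicate individual id {ind.id!r}")
            members[ind.id] = ind
        parent_ids = set()
        for ind in members.values():
            if ind.sire_id is not None:
                parent_ids.add(ind.sire_id)
            if ind.dam_id is not None:
                parent_ids.add(ind.dam_id)
        self._members = {
            iid: Individual(
                id=ind.id,
                sire_id=ind.sire_id,
                dam_id=ind.dam_id,
                sex=ind.sex,
                is_reproductive=iid in parent_ids,
            )
            for iid, ind in members.items()
        }
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        # iterative DFS over parent links; colors: 0 unvisited, 1 on stack, 2 done
        color: dict[str, int] = {}
        for start in self._members:
            if color.get(start):
                continue
            stack: list[tuple[str, int]] = [(start, 0)]
            while stack:
                node, _ = stack[-1]
                if color.get(node, 0) == 0:
                    color[node] = 1
                parents = [
                    p
                    for p in (self._members[node].sire_id, self._members[node].dam_id)
                    if p is not None and p in self._members
                ]
                advanced = False
                for p in parents:
                    c = color.get(p, 0)
                    if c == 1:
                        raise PedigreeError(
                            f"pedigree cycle: {node!r} is its own ancestor via {p!r}"
                        )
                    if c == 0:
                        stack.append((p, 0))
                        advanced = True
                        break
                if not advanced:
                    color[node] = 2
                    stack.pop()

    def __contains__(self, iid: str) -> bool:
        return iid in self._members

    def __getitem__(self, iid: str) -> Individual:
        return self._members[iid]

    def __iter__(self) -> Iterator[Individual]:
        return iter(self._members.values())

    def __len__(self) -> int:
        return len(self._members)

    @property
    def ids(self) -> list[str]:
        return list(self._members)

    @property
    def reproductive_ids(self) -> list[str]:
        return [i.id for i in self if i.is_reproductive]

    def reproductive_mask(self, individual_ids: Sequence[str]) -> np.ndarray:
        """Boolean mask over ``individual_ids``: has >=1 offspring in the pedigree."""
        repro = set(self.reproductive_ids)
        return np.array([iid in repro for iid in individual_ids], dtype=bool)


class GenotypeTable:
    """Biallelic calls for ``loci`` x ``individuals``.

    ``calls[l, i]`` is the number of copies of ``loci[l].allele2`` (0, 1 or 2)
    or -1 for missing.
    """

    def __init__(
        self,
        loci: Sequence[LocusRecord],
        individuals: Sequence[str],
        calls: np.ndarray,
    ):
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(loci), len(individuals)):
            raise ValueError(
                f"calls shape {calls.shape} != (n_loci={len(loci)}, "
                f"n_individuals={len(individuals)})"
            )
        bad = (calls < -1) | (calls > 2)
        if bad.any():
            raise ValueError("calls must be in {-1, 0, 1, 2}")
        self.loci = list(loci)
        self.individuals = list(individuals)
        self.calls = calls
        self.locus_index = {l.locus_id: i for i, l in enumerate(self.loci)}
        self.ind_index = {iid: i for i, iid in enumerate(self.individuals)}
        if len(self.locus_index) != len(self.loci):
            raise ValueError("duplicate locus ids")
        if len(self.ind_index) != len(self.individuals):
            raise ValueError("duplicate individual ids")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def locus_calls(self, locus_id: str) -> np.ndarray:
        return self.calls[self.locus_index[locus_id]]

    def loci_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus_id": [l.locus_id for l in self.loci],
                "chrom": [l.chrom for l in self.loci],
                "pos": [l.pos for l in self.loci],
                "allele1": [l.allele1 for l in self.loci],
                "allele2": [l.allele2 for l in self.loci],
            }
        )


def family_key_str(father_id: str, mother_id: str) -> str:
    return f"{father_id}+{mother_id}"


# ---------------------------------------------------------------------------
# PED/MAP


def read_map(map_path: str | Path) -> list[tuple[str, str, int]]:
    """Parse a MAP file into (chrom, locus_id, 1-based pos) tuples.

    Accepts the 4-column PLINK layout (chrom, id, cM, bp) and the 3-column
    variant without the genetic distance.
    """
    out: list[tuple[str, str, int]] = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 4:
                chrom, lid, _cm, pos_s = parts
            elif len(parts) == 3:
                chrom, lid, pos_s = parts
            else:
                raise FormatError(
                    f"{map_path}:{lineno}: expected 3 or 4 columns, got {len(parts)}"
                )
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise FormatError(f"{map_path}:{lineno}: bad position {pos_s!r}") from exc
            if pos < 1:
                raise FormatError(f"{map_path}:{lineno}: position must be >= 1")
            out.append((chrom, lid, pos))
    return out


def read_ped_map(
    ped_path: str | Path, map_path: str | Path
) -> tuple[Pedigree, GenotypeTable]:
    """Read PLINK text PED/MAP into a pedigree and a genotype table.

    Allele symbols are inferred per locus from the observed alleles in file
    order; any call containing the ``0`` allele code is missing. Individuals
    and loci preserve file order.
    """
    loci_meta = read_map(map_path)
    n_loci = len(loci_meta)

    individuals: list[Individual] = []
    rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_loci:
                raise FormatError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_loci} columns "
                    f"for {n_loci} loci, got {len(parts)}"
                )
            _fid, iid, pat, mat, sex_code, _pheno = parts[:6]
            individuals.append(
                Individual(
                    id=iid,
                    sire_id=None if pat == "0" else pat,
                    dam_id=None if mat == "0" else mat,
                    sex=_SEX_FROM_PED.get(sex_code, UNKNOWN),
                )
            )
            rows.append(np.array(parts[6:], dtype=object))

    n_ind = len(individuals)
    loci: list[LocusRecord] = []
    calls = np.full((n_loci, n_ind), MISSING, dtype=np.int8)
    if n_ind:
        alleles = np.vstack(rows)  # (n_ind, 2*n_loci)
        for j, (chrom, lid, pos) in enumerate(loci_meta):
            a = alleles[:, 2 * j]
            b = alleles[:, 2 * j + 1]
            # interleave to preserve within-row order of first appearance
            flat = np.empty(2 * n_ind, dtype=object)
            flat[0::2] = a
            flat[1::2] = b
            seen = [s for s in pd.unique(flat) if s != "0"]
            if len(seen) > 2:
                raise PolyallelicError(
                    f"locus {lid!r}: more than two alleles observed: {sorted(seen)}"
                )
            a1 = seen[0] if len(seen) >= 1 else None
            a2 = seen[1] if len(seen) >= 2 else None
            loci.append(LocusRecord(lid, chrom, pos, a1, a2))
            called = (a != "0") & (b != "0")
            if a2 is not None:
                calls[j, called] = ((a[called] == a2).astype(np.int8)
                                    + (b[called] == a2).astype(np.int8))
            else:
                calls[j, called] = 0
    else:
        loci = [LocusRecord(lid, chrom, pos) for chrom, lid, pos in loci_meta]

    return Pedigree(individuals), GenotypeTable(loci, [i.id for i in individuals], calls)


def write_ped_map(
    ped_path: str | Path,
    map_path: str | Path,
    genotypes: GenotypeTable,
    pedigree: Optional[Pedigree] = None,
    family_id: str = "FAM1",
) -> None:
    """Write the PLINK text dialect back out (inverse of :func:`read_ped_map`)."""
    with open(map_path, "w") as fh:
        for loc in genotypes.loci:
            fh.write(f"{loc.chrom}\t{loc.locus_id}\t0\t{loc.pos}\n")
    with open(ped_path, "w") as fh:
        for i, iid in enumerate(genotypes.individuals):
            if pedigree is not None and iid in pedigree:
                ind = pedigree[iid]
                pat = ind.sire_id or "0"
                mat = ind.dam_id or "0"
                sex = _SEX_TO_PED[ind.sex]
            else:
                pat = mat = sex = "0"
            fields = [family_id, iid, pat, mat, sex, "-9"]
            col = genotypes.calls[:, i]
            for j, loc in enumerate(genotypes.loci):
                c = col[j]
                a1 = loc.allele1 or "0"
                a2 = loc.allele2 or "0"
                if c < 0:
                    fields += ["0", "0"]
                elif c == 0:
                    fields += [a1, a1]
                elif c == 1:
                    fields += [a1, a2]
                else:
                    fields += [a2, a2]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# trios and families


def extract_trios_and_families(
    pedigree: Pedigree,
    genotyped_ids: Optional[Iterable[str]] = None,
    litters: Optional[dict[str, str]] = None,
) -> tuple[list[Trio], list[Family]]:
    """Enumerate trios (offspring with both parents known and genotyped) and
    group them into families by exact parental couple.

    ``genotyped_ids=None`` means every pedigree member counts as genotyped.
    """
    genotyped = set(genotyped_ids) if genotyped_ids is not None else None
    litters = litters or {}
    trios: list[Trio] = []
    for ind in pedigree:
        sire, dam = ind.sire_id, ind.dam_id
        if sire is None or dam is None:
            continue
        if sire not in pedigree or dam not in pedigree:
            continue
        if genotyped is not None and not {ind.id, sire, dam} <= genotyped:
            continue
        if len({ind.id, sire, dam}) != 3:
            raise PedigreeError(f"trio for {ind.id!r} has non-distinct members")
        if pedigree[sire].sex == FEMALE:
            raise PedigreeError(f"sire {sire!r} of {ind.id!r} is recorded female")
        if pedigree[dam].sex == MALE:
            raise PedigreeError(f"dam {dam!r} of {ind.id!r} is recorded male")
        trios.append(Trio(ind.id, sire, dam, litter_id=litters.get(ind.id)))

    by_key: dict[tuple[str, str], list[str]] = {}
    for t in trios:
        by_key.setdefault(t.family_key, []).append(t.offspring_id)
    families = [Family(k, tuple(v)) for k, v in by_key.items()]
    return trios, families


# ---------------------------------------------------------------------------
# BED tracks and litters


def read_bed_track(bed_path: str | Path, name: str) -> IntervalTrack:
    """Read a BED3+ file; optional column 4 = kind, column 5 = carrier id.

    Coordinates are kept 0-based half-open as in the file.
    """
    track = IntervalTrack(name)
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or parts[0].startswith(("#", "track", "browser")):
                continue
            if len(parts) < 3:
                raise FormatError(f"{bed_path}:{lineno}: expected >=3 columns")
            chrom, start_s, end_s = parts[:3]
            start, end = int(start_s), int(end_s)
            if start >= end:
                raise FormatError(
                    f"{bed_path}:{lineno}: invalid interval start={start} end={end}"
                )
            kind = parts[3] if len(parts) > 3 else "other"
            carrier = parts[4] if len(parts) > 4 else None
            track.intervals.append(Interval(chrom, start, end, kind, carrier))
    return track


def write_bed_track(bed_path: str | Path, track: IntervalTrack) -> None:
    with open(bed_path, "w") as fh:
        for iv in track:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.kind != "other" or iv.carrier_id is not None:
                cols.append(iv.kind)
            if iv.carrier_id is not None:
                cols.append(iv.carrier_id)
            fh.write("\t".join(cols) + "\n")


def read_litters(tsv_path: str | Path) -> dict[str, str]:
    """Side table mapping offspring id -> litter id (TSV, 2 columns, optional header)."""
    out: dict[str, str] = {}
    with open(tsv_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if lineno == 1 and parts[0].lower() in {"offspring_id", "individual_id", "id"}:
                continue
            if len(parts) != 2:
                raise FormatError(f"{tsv_path}:{lineno}: expected 2 columns")
            out[parts[0]] = parts[1]
    return out


def write_litters(tsv_path: str | Path, litters: dict[str, str]) -> None:
    with open(tsv_path, "w") as fh:
        fh.write("offspring_id\tlitter_id\n")
        for k, v in litters.items():
            fh.write(f"{k}\t{v}\n")
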
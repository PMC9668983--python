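"""Synthetic trio datasets with known, parameterized error mechanisms.

The generator emulates the structure of a livestock SNP-array QC study: a
multi-family pig-style pedigree (few boars and sows reused across couples,
highly variable family size, litters, occasional recruitment of offspring
as parents of later couples), founder genotypes in Hardy-Weinberg
proportions, Mendelian gene drop, and an observation layer with four
error mechanisms, each attributed exhaustively and exclusively in a truth
table:

* ``null``: a non-amplifying sub-lineage of allele2 at a subset of loci,
  transmitted through the pedigree. A null copy never amplifies: a
  visible/null genotype is called homozygous for the visible allele and a
  null/null genotype becomes missing. The locus's compromised chemistry
  additionally makes a *visible* heterozygote lose one allele (uniformly
  chosen) with probability ``dropout``; at ``dropout = 1`` no heterozygote
  call survives while both homozygote classes do -- the classic
  allele-drop-out signature with F_IS = 1 -- and at ``dropout = 0`` the
  called-heterozygote proportion is exactly 2pq/(1 - r^2) for
  visible-allele frequencies p, q and null frequency r.
* ``cnv``: per-SNP miscalls inside copy-number segments, only for carrier
  individuals, with a genotype-independent per-SNP probability; the
  corrupted value depends on the segment kind (duplication -> spurious
  heterozygote, heterozygous deletion -> one allele dropped, homozygous
  deletion -> missing call).
* ``adi``: rare allele-drop-in miscalls that introduce the locus-minor
  (possibly population-absent) allele into an offspring's call.
* ``base``: a uniform baseline miscall floor.

All randomness comes from a single ``numpy.random.Generator`` stream with
a fixed draw order (pedigree, gene drop, null dropout, CNV, repeat tracks,
ADI, base errors), so a seed makes every run bit-reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .io_pedigree import (
    FEMALE,
    MALE,
    Family,
    GenotypeTable,
    Individual,
    Interval,
    IntervalTrack,
    LocusRecord,
    Pedigree,
    Trio,
    extract_trios_and_families,
    write_bed_track,
    write_litters,
    write_ped_map,
)

__all__ = [
    "NullAlleleConfig",
    "CnvConfig",
    "SimConfig",
    "SimPedigree",
    "TrueGenotypes",
    "TruthTable",
    "SimDataset",
    "simulate_pedigree",
    "gene_drop",
    "apply_error_models",
    "simulate_dataset",
]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class NullAlleleConfig:
    fraction: float = 0.012  # fraction of loci carrying a null sub-lineage
    r: float = 0.25  # population frequency of the null allele
    dropout: float = 0.7  # visible-het allele-drop probability at null loci


@dataclass(frozen=True)
class CnvConfig:
    n_segments: int = 60
    mean_length: float = 5e5  # bp, lognormal around this scale
    length_sigma: float = 0.6
    carrier_fraction: float = 0.01  # per-individual carrier probability
    miscall_p: float = 0.4  # per-SNP miscall probability inside a carried segment
    # duplication / heterozygous deletion / homozygous deletion mix
    kind_probs: tuple[float, float, float] = (0.763, 0.165, 0.072)


@dataclass(frozen=True)
class SimConfig:
    """Study-condition defaults: a 15-boar / 28-sow / 61-couple pedigree with
    family sizes 1-34 averaging ~7.8 offspring (so ~478 trios among ~520
    individuals), 20,000 biallelic autosomal SNPs on 18 autosomes."""

    seed: int = 0
    n_boars: int = 15
    n_sows: int = 28
    n_couples: int = 61
    family_size_min: int = 1
    family_size_max: int = 34
    family_size_mean: float = 7.8
    recruit_fraction: float = 0.15  # couples whose parent is an earlier offspring
    litter_size_mean: float = 5.0
    litter_size_max: int = 12
    n_loci: int = 20_000
    n_chrom: int = 18
    chrom_length: int = 100_000_000
    founder_maf_range: tuple[float, float] = (0.01, 0.5)
    fixed_locus_fraction: float = 0.05  # loci monomorphic in founders
    null_allele: NullAlleleConfig = field(default_factory=NullAlleleConfig)
    cnv: CnvConfig = field(default_factory=CnvConfig)
    adi_rate: float = 2e-4  # per-offspring-genotype novel-allele miscall
    adi_hom_fraction: float = 0.05  # drop-in as opposite homozygote vs heterozygote
    adi_offspring_only: bool = True
    base_error: float = 1e-5
    repeat_cofraction: float = 0.3  # CNV segments also tagged SINE/LINE
    n_sine_background: int = 150
    sine_length: int = 300
    n_line_background: int = 150
    line_length: int = 5_000

    def validate(self) -> None:
        if self.n_couples > self.n_boars * self.n_sows:
            raise ConfigError(
                f"{self.n_couples} couples exceed the {self.n_boars}x{self.n_sows} "
                "possible boar-sow pairs"
            )
        for name in ("recruit_fraction", "fixed_locus_fraction", "adi_rate",
                     "adi_hom_fraction", "base_error", "repeat_cofraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        na = self.null_allele
        if not (0 <= na.fraction <= 1 and 0 < na.r < 1 and 0 <= na.dropout <= 1):
            raise ConfigError("invalid null-allele parameters")
        cv = self.cnv
        if not (0 <= cv.carrier_fraction <= 1 and 0 <= cv.miscall_p <= 1):
            raise ConfigError("invalid CNV parameters")
        if abs(sum(cv.kind_probs) - 1.0) > 1e-6:
            raise ConfigError("cnv.kind_probs must sum to 1")
        if self.family_size_min < 1 or self.family_size_max < self.family_size_min:
            raise ConfigError("invalid family size range")
        lo, hi = self.founder_maf_range
        if not 0.0 <= lo <= hi <= 0.5:
            raise ConfigError("founder_maf_range must satisfy 0 <= lo <= hi <= 0.5")


@dataclass
class SimPedigree:
    pedigree: Pedigree
    trios: list[Trio]
    families: list[Family]
    litters: dict[str, str]  # offspring id -> litter id
    founder_ids: list[str]
    couples: list[tuple[str, str]]
    family_sizes: list[int]


@dataclass
class TrueGenotypes:
    """Error-free gene-drop output plus the hidden per-copy allele identity.

    ``copies[l, i, k]`` codes copy k of individual i at locus l:
    0 = allele1, 1 = allele2 (amplifying), 2 = allele2 null sub-lineage.
    The visible true call is the count of codes >= 1.
    """

    table: GenotypeTable
    copies: np.ndarray  # (n_loci, n_ind, 2) int8
    q_founder: np.ndarray  # total allele2 founder frequency per locus
    p_founder: np.ndarray  # allele1 founder frequency
    q_visible: np.ndarray  # amplifying-allele2 founder frequency
    r_null: np.ndarray  # null sub-lineage founder frequency (0 off null loci)
    null_loci: np.ndarray  # bool per locus
    fixed_loci: np.ndarray  # bool per locus (monomorphic in founders)


@dataclass
class TruthTable:
    """Ground truth: one row per observed-vs-true discrepancy, attributed to
    exactly one mechanism, plus locus labels and CNV carrier segments."""

    cell_errors: pd.DataFrame  # locus_id, individual_id, true_call, observed_call, mechanism
    locus_labels: pd.DataFrame  # locus_id, is_null, is_fixed, q_founder
    segments: pd.DataFrame  # segment_id, chrom, start, end, kind
    carriers: pd.DataFrame  # segment_id, carrier_id


@dataclass
class SimDataset:
    config: SimConfig
    sim_pedigree: SimPedigree
    true: TrueGenotypes
    observed: GenotypeTable
    truth: TruthTable
    tracks: dict[str, IntervalTrack]

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Emit PED/MAP, BED tracks, litter map and truth TSVs."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "ped": out / "sim.ped",
            "map": out / "sim.map",
            "litters": out / "litters.tsv",
            "truth_cells": out / "truth_cells.tsv",
            "truth_loci": out / "truth_loci.tsv",
        }
        write_ped_map(paths["ped"], paths["map"], self.observed,
                      self.sim_pedigree.pedigree)
        write_litters(paths["litters"], self.sim_pedigree.litters)
        self.truth.cell_errors.to_csv(paths["truth_cells"], sep="\t", index=False)
        self.truth.locus_labels.to_csv(paths["truth_loci"], sep="\t", index=False)
        for name, track in self.tracks.items():
            p = out / f"{name.lower()}.bed"
            write_bed_track(p, track)
            paths[name] = p
        (out / "sim_config.json").write_text(json.dumps(asdict(self.config), indent=1))
        return paths


# ---------------------------------------------------------------------------
# pedigree


def _rng(config: SimConfig, rng: Optional[np.random.Generator]) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(config.seed)


def simulate_pedigree(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> SimPedigree:
    """Founder boars/sows plus offspring of sampled couples.

    Family sizes follow 1 + a negative binomial targeting the configured
    mean, truncated to the configured range; a fraction of couples recruits
    one parent among earlier offspring (multi-generation pedigree); each
    family's offspring are split into litters.
    """
    config.validate()
    rng = _rng(config, rng)

    boars = [f"B{i + 1:03d}" for i in range(config.n_boars)]
    sows = [f"S{i + 1:03d}" for i in range(config.n_sows)]
    individuals: list[Individual] = [
        Individual(b, sex=MALE) for b in boars
    ] + [Individual(s, sex=FEMALE) for s in sows]

    pairs = [(b, s) for b in boars for s in sows]
    chosen = rng.choice(len(pairs), size=config.n_couples, replace=False)
    base_couples = [pairs[i] for i in chosen]

    # negative binomial on top of the minimum size, targeting the mean
    mean_extra = max(config.family_size_mean - config.family_size_min, 0.01)
    nb_n = 1.3
    nb_p = nb_n / (nb_n + mean_extra)

    couples: list[tuple[str, str]] = []
    used_keys: set[tuple[str, str]] = set()
    family_sizes: list[int] = []
    litters: dict[str, str] = {}
    male_pool: list[str] = []
    female_pool: list[str] = []
    next_id = 1

    for ci, (boar, sow) in enumerate(base_couples):
        if rng.random() < config.recruit_fraction:
            # swap one founder parent for an earlier-generation offspring
            if rng.random() < 0.5 and male_pool:
                boar = male_pool[int(rng.integers(len(male_pool)))]
            elif female_pool:
                sow = female_pool[int(rng.integers(len(female_pool)))]
        if (boar, sow) in used_keys:
            boar, sow = base_couples[ci]  # fall back to the unused founder pair
        used_keys.add((boar, sow))
        couples.append((boar, sow))

        size = config.family_size_min + int(rng.negative_binomial(nb_n, nb_p))
        size = min(size, config.family_size_max)
        family_sizes.append(size)

        kids: list[str] = []
        for _ in range(size):
            kid = f"P{next_id:04d}"
            next_id += 1
            sex = MALE if rng.random() < 0.5 else FEMALE
            individuals.append(Individual(kid, sire_id=boar, dam_id=sow, sex=sex))
            (male_pool if sex == MALE else female_pool).append(kid)
            kids.append(kid)
        # chunk into litters
        li = 0
        k = 0
        while k < len(kids):
            li += 1
            ls = 1 + int(rng.poisson(max(config.litter_size_mean - 1, 0)))
            ls = min(ls, config.litter_size_max, len(kids) - k)
            for kid in kids[k:k + ls]:
                litters[kid] = f"F{ci + 1:02d}L{li}"
            k += ls

    pedigree = Pedigree(individuals)
    trios, families = extract_trios_and_families(pedigree, litters=litters)
    return SimPedigree(
        pedigree=pedigree,
        trios=trios,
        families=families,
        litters=litters,
        founder_ids=boars + sows,
        couples=couples,
        family_sizes=family_sizes,
    )


# ---------------------------------------------------------------------------
# gene drop


def gene_drop(
    sim_ped: SimPedigree,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> TrueGenotypes:
    """Draw founder genotypes in HWE and transmit one uniformly chosen allele
    per parent down the pedigree; zero Mendelian errors by construction.

    Loci are placed evenly over the autosomes. A configured fraction of loci
    is monomorphic in founders (allele2 absent) and another fraction carries
    a null sub-lineage of allele2 at frequency r (see module docstring).
    """
    config.validate()
    rng = _rng(config, rng)
    n_loci = config.n_loci

    # locus placement: near-even split across autosomes, sorted positions
    per_chrom = np.full(config.n_chrom, n_loci // config.n_chrom, dtype=int)
    per_chrom[: n_loci % config.n_chrom] += 1
    loci: list[LocusRecord] = []
    j = 0
    for c in range(config.n_chrom):
        pos = np.sort(
            rng.choice(config.chrom_length - 1, size=per_chrom[c], replace=False)
        ) + 1
        for p in pos:
            j += 1
            loci.append(LocusRecord(f"SNP{j:06d}", str(c + 1), int(p), "A", "B"))

    lo, hi = config.founder_maf_range
    q = rng.uniform(lo, hi, size=n_loci)  # allele2 founder frequency
    fixed = rng.random(n_loci) < config.fixed_locus_fraction
    q[fixed] = 0.0
    null = (~fixed) & (rng.random(n_loci) < config.null_allele.fraction)
    r = config.null_allele.r
    # at null loci, split frequencies (p, q_visible, r); keep both visible
    # alleles common enough that the drop signature is observable
    u = rng.uniform(0.25, 0.75, size=int(null.sum()))
    p_vec = 1.0 - q
    q_vis = q.copy()
    r_vec = np.zeros(n_loci)
    p_vec[null] = (1.0 - r) * u
    q_vis[null] = (1.0 - r) * (1.0 - u)
    r_vec[null] = r
    q[null] = q_vis[null] + r

    order = sim_ped.pedigree.ids  # construction order: parents precede offspring
    ind_index = {iid: i for i, iid in enumerate(order)}
    n_ind = len(order)
    copies = np.zeros((n_loci, n_ind, 2), dtype=np.int8)

    thr1 = p_vec[:, None]
    thr2 = (p_vec + q_vis)[:, None]
    for iid in order:
        i = ind_index[iid]
        ind = sim_ped.pedigree[iid]
        if ind.sire_id is None or ind.dam_id is None:
            u2 = rng.random((n_loci, 2))
            copies[:, i, :] = (u2 >= thr1).astype(np.int8) + (u2 >= thr2).astype(np.int8)
        else:
            fi = ind_index[ind.sire_id]
            mi = ind_index[ind.dam_id]
            pick_f = rng.integers(0, 2, size=n_loci)
            pick_m = rng.integers(0, 2, size=n_loci)
            rows = np.arange(n_loci)
            copies[:, i, 0] = copies[rows, fi, pick_f]
            copies[:, i, 1] = copies[rows, mi, pick_m]

    calls = (copies >= 1).sum(axis=2).astype(np.int8)
    table = GenotypeTable(loci, order, calls)
    return TrueGenotypes(
        table=table,
        copies=copies,
        q_founder=q,
        p_founder=p_vec,
        q_visible=q_vis,
        r_null=r_vec,
        null_loci=null,
        fixed_loci=fixed,
    )


# ---------------------------------------------------------------------------
# observation layer


def apply_error_models(
    true: TrueGenotypes,
    sim_ped: SimPedigree,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[GenotypeTable, TruthTable, dict[str, IntervalTrack]]:
    """Corrupt the true genotypes with the configured mechanisms.

    Mechanisms are applied in a fixed order (null dropout, CNV miscalls,
    ADI, base errors); a cell already altered by one mechanism is skipped
    by the later ones, so attribution is exhaustive and exclusive.
    """
    config.validate()
    rng = _rng(config, rng)
    gt = true.table
    n_loci, n_ind = gt.n_loci, gt.n_individuals
    obs = gt.calls.copy()
    modified = np.zeros_like(obs, dtype=bool)

    err_loc: list[np.ndarray] = []
    err_ind: list[np.ndarray] = []
    err_mech: list[str] = []

    def record(loc_idx: np.ndarray, ind_idx: np.ndarray, mech: str) -> None:
        err_loc.append(loc_idx.astype(np.int64))
        err_ind.append(ind_idx.astype(np.int64))
        err_mech.extend([mech] * len(loc_idx))

    # --- null / partial-null loci ------------------------------------------
    null_idx = np.flatnonzero(true.null_loci)
    if len(null_idx):
        sub = true.copies[null_idx]  # (n_null, n_ind, 2)
        n_null_copies = (sub == 2).sum(axis=2)
        # the non-null copy of a visible/null genotype (0 = allele1, 1 = allele2)
        other_code = sub.sum(axis=2) - 2
        vis_het = (sub == 0).any(axis=2) & (sub == 1).any(axis=2)
        drop_het = vis_het & (
            rng.random(vis_het.shape) < config.null_allele.dropout
        )
        hom_pick = 2 * rng.integers(0, 2, size=vis_het.shape).astype(np.int8)
        new = np.where(
            n_null_copies == 2,
            np.int8(-1),
            np.where(
                n_null_copies == 1,
                (2 * (other_code >= 1)).astype(np.int8),
                np.where(drop_het, hom_pick, obs[null_idx]),
            ),
        ).astype(np.int8)
        chg = new != obs[null_idx]
        if chg.any():
            li, ii = np.nonzero(chg)
            obs[null_idx[li], ii] = new[li, ii]
            modified[null_idx[li], ii] = True
            record(null_idx[li], ii, "null")

    # --- CNV segments ------------------------------------------------------
    chrom_arr = np.array([int(l.chrom) for l in gt.loci])
    pos0 = np.array([l.pos - 1 for l in gt.loci])
    kinds = ("duplication", "het_deletion", "hom_deletion")
    seg_rows = []
    carrier_rows = []
    cv = config.cnv
    for s in range(cv.n_segments):
        chrom = int(rng.integers(config.n_chrom)) + 1
        length = int(rng.lognormal(math.log(cv.mean_length), cv.length_sigma))
        length = int(np.clip(length, 10_000, config.chrom_length // 2))
        start = int(rng.integers(0, config.chrom_length - length))
        end = start + length
        kind = kinds[int(rng.choice(3, p=cv.kind_probs))]
        carriers = np.flatnonzero(rng.random(n_ind) < cv.carrier_fraction)
        if len(carriers) == 0:
            carriers = np.array([int(rng.integers(n_ind))])
        seg_id = f"CNV{s + 1:03d}"
        seg_rows.append((seg_id, str(chrom), start, end, kind))
        for ci in carriers:
            carrier_rows.append((seg_id, gt.individuals[ci]))

        in_seg = np.flatnonzero(
            (chrom_arr == chrom) & (pos0 >= start) & (pos0 < end)
        )
        if len(in_seg) == 0:
            continue
        hit = rng.random((len(in_seg), len(carriers))) < cv.miscall_p
        hit &= ~modified[np.ix_(in_seg, carriers)]
        if not hit.any():
            continue
        li, ci_ = np.nonzero(hit)
        gl = in_seg[li]
        gi = carriers[ci_]
        cur = obs[gl, gi]
        if kind == "duplication":
            new = np.ones(len(gl), dtype=np.int8)
        elif kind == "het_deletion":
            # a het loses one allele at random; homozygotes are unaffected
            new = np.where(
                cur == 1, 2 * rng.integers(0, 2, size=len(gl)).astype(np.int8), cur
            ).astype(np.int8)
        else:  # hom_deletion
            new = np.full(len(gl), -1, dtype=np.int8)
        chg = new != cur
        if chg.any():
            obs[gl[chg], gi[chg]] = new[chg]
            modified[gl[chg], gi[chg]] = True
            record(gl[chg], gi[chg], "cnv")

    segments = pd.DataFrame(
        seg_rows, columns=["segment_id", "chrom", "start", "end", "kind"]
    )
    carriers_df = pd.DataFrame(carrier_rows, columns=["segment_id", "carrier_id"])

    # --- SINE/LINE tracks (co-located with some CNV + background) ----------
    sine = IntervalTrack("SINE")
    line = IntervalTrack("LINE")
    for _, seg in segments.iterrows():
        if rng.random() < config.repeat_cofraction:
            track, length = (
                (sine, config.sine_length)
                if rng.random() < 0.5
                else (line, config.line_length)
            )
            anchor = int(rng.integers(seg["start"], seg["end"]))
            lo = max(anchor - length // 2, 0)
            track.intervals.append(
                Interval(seg["chrom"], lo, lo + length, track.name)
            )
    for track, n_bg, length in (
        (sine, config.n_sine_background, config.sine_length),
        (line, config.n_line_background, config.line_length),
    ):
        for _ in range(n_bg):
            chrom = str(int(rng.integers(config.n_chrom)) + 1)
            lo = int(rng.integers(0, config.chrom_length - length))
            track.intervals.append(Interval(chrom, lo, lo + length, track.name))

    # --- allele drop-in -----------------------------------------------------
    if config.adi_rate > 0:
        if config.adi_offspring_only:
            elig = np.array(
                [
                    i
                    for i, iid in enumerate(gt.individuals)
                    if sim_ped.pedigree[iid].sire_id is not None
                ]
            )
        else:
            elig = np.arange(n_ind)
        if len(elig):
            hit = rng.random((n_loci, len(elig))) < config.adi_rate
            hit &= ~modified[:, elig]
            li, ei = np.nonzero(hit)
            if len(li):
                gi = elig[ei]
                minor_is_a2 = true.q_founder <= 0.5
                hom = rng.random(len(li)) < config.adi_hom_fraction
                new = np.where(
                    hom, np.where(minor_is_a2[li], 2, 0), 1
                ).astype(np.int8)
                chg = new != obs[li, gi]
                if chg.any():
                    obs[li[chg], gi[chg]] = new[chg]
                    modified[li[chg], gi[chg]] = True
                    record(li[chg], gi[chg], "adi")

    # --- baseline miscalls ---------------------------------------------------
    if config.base_error > 0:
        hit = (rng.random((n_loci, n_ind)) < config.base_error) & ~modified
        li, gi = np.nonzero(hit)
        if len(li):
            shift = 1 + rng.integers(0, 2, size=len(li)).astype(np.int8)
            cur = obs[li, gi]
            new = np.where(cur >= 0, (cur + shift) % 3, cur).astype(np.int8)
            chg = new != cur
            if chg.any():
                obs[li[chg], gi[chg]] = new[chg]
                record(li[chg], gi[chg], "base")

    # --- assemble ------------------------------------------------------------
    locus_ids = np.array([l.locus_id for l in gt.loci], dtype=object)
    ind_ids = np.array(gt.individuals, dtype=object)
    if err_loc:
        el = np.concatenate(err_loc)
        ei = np.concatenate(err_ind)
        cell_errors = pd.DataFrame(
            {
                "locus_id": locus_ids[el],
                "individual_id": ind_ids[ei],
                "true_call": gt.calls[el, ei],
                "observed_call": obs[el, ei],
                "mechanism": np.array(err_mech, dtype=object),
            }
        )
    else:
        cell_errors = pd.DataFrame(
            columns=["locus_id", "individual_id", "true_call", "observed_call", "mechanism"]
        )
    locus_labels = pd.DataFrame(
        {
            "locus_id": locus_ids,
            "is_null": true.null_loci,
            "is_fixed": true.fixed_loci,
            "q_founder": true.q_founder,
            "p_founder": true.p_founder,
            "q_visible": true.q_visible,
            "r_null": true.r_null,
        }
    )
    cnv_track = IntervalTrack(
        "CNV",
        [
            Interval(row["chrom"], int(row["start"]), int(row["end"]), row["kind"])
            for _, row in segments.iterrows()
        ],
    )
    seg_by_id = segments.set_index("segment_id")
    cnv_carrier_track = IntervalTrack(
        "CNV_carrier",
        [
            Interval(
                seg_by_id.loc[row["segment_id"], "chrom"],
                int(seg_by_id.loc[row["segment_id"], "start"]),
                int(seg_by_id.loc[row["segment_id"], "end"]),
                seg_by_id.loc[row["segment_id"], "kind"],
                row["carrier_id"],
            )
            for _, row in carriers_df.iterrows()
        ],
    )
    observed = GenotypeTable(gt.loci, gt.individuals, obs)
    truth = TruthTable(
        cell_errors=cell_errors,
        locus_labels=locus_labels,
        segments=segments,
        carriers=carriers_df,
    )
    tracks = {"CNV": cnv_track, "CNV_carrier": cnv_carrier_track,
              "SINE": sine, "LINE": line}
    return observed, truth, tracks


def simulate_dataset(config: SimConfig) -> SimDataset:
    """Run the three stages on one seeded stream and bundle the results."""
    rng = np.random.default_rng(config.seed)
    sim_ped = simulate_pedigree(config, rng)
    true = gene_drop(sim_ped, config, rng)
    observed, truth, tracks = apply_error_models(true, sim_ped, config, rng)
    return SimDataset(
        config=config,
        sim_pedigree=sim_ped,
        true=true,
        observed=observed,
        truth=truth,
        tracks=tracks,
    )
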
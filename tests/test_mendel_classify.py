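"""Trio inconsistency detection and eight-class assignment.

The classifier is checked against an independent brute-force oracle that
enumerates all four parental-transmission combinations for each of the 27
complete trio configurations.
"""

import itertools

import numpy as np
import pandas as pd
import pytest

from mendelaudit.io_pedigree import (
    Family,
    GenotypeTable,
    Individual,
    LocusRecord,
    Pedigree,
    Trio,
    extract_trios_and_families,
)
from mendelaudit.mendel_classify import (
    ME_CLASSES,
    MendelEvent,
    StructureError,
    check_trio_locus,
    classify_call_triplet,
    mismatch_counts,
    scan_dataset,
    MESet,
)


def transmission_oracle(f: int, m: int, c: int) -> bool:
    """Consistent iff some of the 4 transmission combos reproduces the child."""
    pair = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
    return any(a + b == c for a in pair[f] for b in pair[m])


ALL_TRIPLETS = list(itertools.product(range(3), repeat=3))


class TestDecisionTable:
    def test_matches_transmission_oracle(self):
        """Exactly 12 of the 27 configurations are inconsistent, and the
        classifier flags precisely those."""
        inconsistent = [t for t in ALL_TRIPLETS if not transmission_oracle(*t)]
        assert len(inconsistent) == 12
        for f, m, c in ALL_TRIPLETS:
            hit = classify_call_triplet(f, m, c)
            assert (hit is None) == transmission_oracle(f, m, c)
            if hit is not None:
                member, viol = hit
                assert member in ("Trio", "Father", "Mother", "Offspring")
                assert viol in (1, 2)

    def test_allele_swap_symmetry(self):
        """Relabeling alleles keeps the member and flips the violating allele."""
        for f, m, c in ALL_TRIPLETS:
            a = classify_call_triplet(f, m, c)
            b = classify_call_triplet(2 - f, 2 - m, 2 - c)
            assert (a is None) == (b is None)
            if a is not None:
                assert a[0] == b[0]
                assert a[1] == 3 - b[1]

    def test_parent_swap_symmetry(self):
        swap = {"Father": "Mother", "Mother": "Father",
                "Trio": "Trio", "Offspring": "Offspring"}
        for f, m, c in ALL_TRIPLETS:
            a = classify_call_triplet(f, m, c)
            b = classify_call_triplet(m, f, c)
            assert (a is None) == (b is None)
            if a is not None:
                assert b[0] == swap[a[0]] and b[1] == a[1]

    @pytest.mark.parametrize(
        "f,m,c,member,freq_class",
        [
            (0, 0, 1, "Trio", "B"),  # both parents fixed major, het child
            (0, 0, 2, "Offspring", "B"),  # opposite-homozygote child
            (0, 1, 2, "Father", "B"),
            (1, 0, 2, "Mother", "B"),
            (2, 2, 1, "Trio", "A"),  # parents fixed for minor allele
        ],
    )
    def test_named_examples(self, f, m, c, member, freq_class):
        # allele1 is major (code 1)
        ev = check_trio_locus(f, m, c, major_allele=1, allele_symbols=("A", "B"))
        assert isinstance(ev, MendelEvent)
        assert ev.member == member
        assert ev.freq_class == freq_class
        assert ev.me_class == f"{member}{freq_class}"

    def test_consistent_transmission(self):
        assert check_trio_locus(1, 1, 0, major_allele=1) is None

    def test_missing_call_violates_precondition(self):
        with pytest.raises(ValueError, match="missing"):
            check_trio_locus(-1, 0, 0, major_allele=1)


def _toy_table(calls, n_loci=None):
    calls = np.asarray(calls, dtype=np.int8)
    loci = [
        LocusRecord(f"L{j}", "1", 10 * (j + 1), "A", "B")
        for j in range(calls.shape[0])
    ]
    inds = ["dad", "mum", "kid"]
    return GenotypeTable(loci, inds, calls)


def _toy_trio():
    return Trio("kid", "dad", "mum")


class TestScanDataset:
    def test_clean_gene_drop_has_zero_events(self, clean_dataset):
        meset = scan_dataset(
            clean_dataset.observed, clean_dataset.sim_pedigree.trios
        )
        assert meset.n_mismatches == 0
        assert meset.loci == frozenset()

    def test_single_event(self):
        gt = _toy_table([[0, 0, 1]])  # AA x AA -> AB
        meset = scan_dataset(gt, [_toy_trio()])
        assert meset.n_mismatches == 1
        assert meset.loci == {"L0"} and meset.unique_loci == {"L0"}
        row = meset.events.iloc[0]
        assert row["me_class"] == "TrioB"
        assert row["violating_allele"] == "B"
        assert row["family_key"] == "dad+mum"

    def test_missing_calls_skipped(self):
        gt = _toy_table([[0, -1, 2]])
        assert scan_dataset(gt, [_toy_trio()]).n_mismatches == 0

    def test_absent_member_raises(self):
        gt = _toy_table([[0, 0, 1]])
        with pytest.raises(StructureError, match="ghost"):
            scan_dataset(gt, [Trio("kid", "ghost", "mum")])

    def test_events_recheck_idempotent(self, small_dataset):
        """Every scanned event reproduces its inconsistency when re-checked."""
        gt = small_dataset.observed
        meset = scan_dataset(gt, small_dataset.sim_pedigree.trios)
        assert meset.n_mismatches > 0
        ev = meset.events.head(300)
        for _, row in ev.iterrows():
            li = gt.locus_index[row["locus_id"]]
            f = gt.calls[li, gt.ind_index[row["father_id"]]]
            m = gt.calls[li, gt.ind_index[row["mother_id"]]]
            c = gt.calls[li, gt.ind_index[row["offspring_id"]]]
            hit = classify_call_triplet(int(f), int(m), int(c))
            assert hit is not None and hit[0] == row["member"]

    def test_deterministic_order(self, small_dataset):
        gt = small_dataset.observed
        trios = small_dataset.sim_pedigree.trios
        a = scan_dataset(gt, trios).events
        b = scan_dataset(gt, trios).events
        pd.testing.assert_frame_equal(a, b)
        # locus-major ordering
        locus_order = {l.locus_id: i for i, l in enumerate(gt.loci)}
        idx = a["locus_id"].map(locus_order).to_numpy()
        assert (np.diff(idx) >= 0).all()


class TestMismatchCounts:
    def _families(self):
        ped = Pedigree(
            [Individual("d1"), Individual("m1"), Individual("d2"), Individual("m2")]
            + [Individual(f"k{i}", "d1" if i == 0 else "d2",
                          "m1" if i == 0 else "m2") for i in range(4)]
        )
        return extract_trios_and_families(ped)

    def test_family_additivity(self):
        trios, families = self._families()
        rows = []
        for t in trios:
            for _ in range(5):
                rows.append(
                    {
                        "locus_id": "L0",
                        "chrom": "1",
                        "pos": 10,
                        "offspring_id": t.offspring_id,
                        "father_id": t.father_id,
                        "mother_id": t.mother_id,
                        "family_key": f"{t.father_id}+{t.mother_id}",
                        "member": "Trio",
                        "violating_allele": "B",
                        "freq_class": "B",
                        "me_class": "TrioB",
                        "violating_code": 2,
                    }
                )
        meset = MESet.from_events(pd.DataFrame(rows))
        counts = mismatch_counts(meset, trios, families)
        assert sorted(counts.per_family.tolist()) == [5, 15]
        assert counts.per_class["TrioB"] == 20
        assert counts.per_offspring.sum() == 20

    def test_empty_meset(self):
        trios, families = self._families()
        meset = MESet.from_events(pd.DataFrame())
        counts = mismatch_counts(meset, trios, families)
        assert (counts.per_offspring == 0).all()
        assert (counts.per_family == 0).all()
        assert np.isnan(counts.pearson_r) and np.isnan(counts.spearman_r)

    def test_rate_scales_with_family_size(self, small_dataset):
        """A systematic per-trio error rate makes family counts track size."""
        meset = scan_dataset(small_dataset.observed, small_dataset.sim_pedigree.trios)
        counts = mismatch_counts(
            meset, small_dataset.sim_pedigree.trios, small_dataset.sim_pedigree.families
        )
        assert counts.pearson_r > 0.5
        assert counts.spearman_r > 0.5
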
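"""Generator properties: determinism, design recovery, transmission,
mechanism attribution and the null-allele observation model."""

import numpy as np
import pandas as pd
import pytest

from mendelaudit import (
    CnvConfig,
    NullAlleleConfig,
    SimConfig,
    gene_drop,
    scan_dataset,
    simulate_dataset,
    simulate_pedigree,
)
from mendelaudit.simdata import ConfigError


class TestSimulatePedigree:
    def test_design_counts(self):
        sp = simulate_pedigree(SimConfig(seed=2, n_couples=2, n_boars=2, n_sows=2,
                                         family_size_min=1, family_size_max=4))
        assert len(sp.families) == 2
        assert len(sp.trios) == sum(sp.family_sizes)

    def test_same_seed_identical(self):
        a = simulate_pedigree(SimConfig(seed=9))
        b = simulate_pedigree(SimConfig(seed=9))
        assert a.pedigree.ids == b.pedigree.ids
        assert a.couples == b.couples
        assert a.litters == b.litters

    def test_impossible_design_rejected(self):
        with pytest.raises(ConfigError, match="couples"):
            SimConfig(n_boars=2, n_sows=2, n_couples=5).validate()

    def test_default_scale_mean_family_size(self):
        """The default design reproduces the target structure: 61 couples,
        1-34 offspring each, mean within sampling error of 7.8."""
        sp = simulate_pedigree(SimConfig(seed=0))
        sizes = np.array(sp.family_sizes)
        assert len(sizes) == 61
        assert sizes.min() >= 1 and sizes.max() <= 34
        # sd of the mean at 61 families is ~0.8
        assert abs(sizes.mean() - 7.8) < 2.5

    def test_multigeneration_recruits(self):
        sp = simulate_pedigree(SimConfig(seed=4))
        founders = set(sp.founder_ids)
        recruited = [b for b, s in sp.couples if b not in founders] + [
            s for b, s in sp.couples if s not in founders
        ]
        assert len(recruited) > 0
        # recruits are themselves offspring (have recorded parents)
        for rid in recruited:
            assert sp.pedigree[rid].sire_id is not None


class TestGeneDrop:
    def test_zero_mendel_errors_by_construction(self, clean_dataset):
        meset = scan_dataset(clean_dataset.observed, clean_dataset.sim_pedigree.trios)
        assert meset.n_mismatches == 0

    def test_founder_hwe_mean_fis_near_zero(self):
        """Founders are drawn in HWE; their mean F_IS over loci is ~0 (the
        exact-sample expectation is the small bias -1/(2n-1))."""
        from mendelaudit.io_pedigree import GenotypeTable
        from mendelaudit.locus_stats import summarize_table

        cfg = SimConfig(
            seed=29, n_loci=1200, n_boars=60, n_sows=60, n_couples=12,
            founder_maf_range=(0.1, 0.5), fixed_locus_fraction=0.0,
            null_allele=NullAlleleConfig(fraction=0.0),
            cnv=CnvConfig(n_segments=0), adi_rate=0.0, base_error=0.0,
        )
        ds = simulate_dataset(cfg)
        founder_cols = [
            ds.true.table.ind_index[i] for i in ds.sim_pedigree.founder_ids
        ]
        founders_only = GenotypeTable(
            ds.true.table.loci,
            ds.sim_pedigree.founder_ids,
            ds.true.table.calls[:, founder_cols],
        )
        table = summarize_table(founders_only)
        assert abs(np.nanmean(table["f_is"])) < 0.02

    def test_offspring_frequency_tracks_founders(self, clean_dataset):
        """Transmission neither creates nor destroys alleles on average:
        offspring frequency matches the realized founder frequency with no
        systematic drift across loci."""
        gt = clean_dataset.true.table
        sp = clean_dataset.sim_pedigree
        founder_cols = [gt.ind_index[i] for i in sp.founder_ids]
        off_cols = [i for i in range(gt.n_individuals) if i not in founder_cols]
        q_f = gt.calls[:, founder_cols].mean(axis=1) / 2
        q_o = gt.calls[:, off_cols].mean(axis=1) / 2
        dev = q_o - q_f
        se = dev.std(ddof=1) / np.sqrt(len(dev))
        assert abs(dev.mean()) < 4 * se + 1e-3


class TestErrorModels:
    def test_determinism_end_to_end(self):
        cfg = SimConfig(seed=21, n_loci=600, n_couples=8, n_boars=4, n_sows=6)
        a = simulate_dataset(cfg)
        b = simulate_dataset(cfg)
        np.testing.assert_array_equal(a.observed.calls, b.observed.calls)
        pd.testing.assert_frame_equal(a.truth.cell_errors, b.truth.cell_errors)
        pd.testing.assert_frame_equal(a.truth.segments, b.truth.segments)

    def test_attribution_exhaustive_and_exclusive(self, small_dataset):
        """Every observed != true cell appears exactly once in the truth
        table, with matching values."""
        ds = small_dataset
        diff = ds.observed.calls != ds.true.table.calls
        cells = ds.truth.cell_errors
        assert len(cells) == int(diff.sum())
        assert not cells.duplicated(["locus_id", "individual_id"]).any()
        li = cells["locus_id"].map(ds.observed.locus_index)
        ii = cells["individual_id"].map(ds.observed.ind_index)
        np.testing.assert_array_equal(
            ds.observed.calls[li, ii], cells["observed_call"].to_numpy()
        )
        np.testing.assert_array_equal(
            ds.true.table.calls[li, ii], cells["true_call"].to_numpy()
        )

    def test_cnv_only_run_concentrates_in_trio_classes(self):
        cfg = SimConfig(
            seed=13,
            n_loci=4000,
            null_allele=NullAlleleConfig(fraction=0.0),
            adi_rate=0.0,
            base_error=0.0,
            fixed_locus_fraction=0.0,
            cnv=CnvConfig(n_segments=80, carrier_fraction=0.05, miscall_p=0.5),
        )
        ds = simulate_dataset(cfg)
        meset = scan_dataset(ds.observed, ds.sim_pedigree.trios)
        assert meset.n_mismatches > 20
        frac_trio = meset.events["member"].eq("Trio").mean()
        assert frac_trio > 0.5
        # and the affected loci are inside carried segments
        cnv_loci = set(
            ds.truth.cell_errors.loc[
                ds.truth.cell_errors["mechanism"] == "cnv", "locus_id"
            ]
        )
        assert set(meset.loci) <= cnv_loci

    def test_null_closed_form_called_het_proportion(self):
        """At dropout = 0 the called-heterozygote proportion among called
        genotypes at a null locus is 2pq/(1-r^2); the simulation matches
        within 3 Monte-Carlo standard errors (per-locus deviations averaged,
        empirical SE across loci)."""
        cfg = SimConfig(
            seed=17,
            n_loci=4000,
            adi_rate=0.0,
            base_error=0.0,
            fixed_locus_fraction=0.0,
            cnv=CnvConfig(n_segments=0),
            null_allele=NullAlleleConfig(fraction=0.08, r=0.3, dropout=0.0),
        )
        ds = simulate_dataset(cfg)
        lab = ds.truth.locus_labels
        idx = np.flatnonzero(lab["is_null"].to_numpy())
        assert len(idx) > 100
        p = lab["p_founder"].to_numpy()[idx]
        qv = lab["q_visible"].to_numpy()[idx]
        r = lab["r_null"].to_numpy()[idx]
        expected = 2 * p * qv / (1 - r**2)
        calls = ds.observed.calls[idx]
        called = calls >= 0
        observed = (calls == 1).sum(axis=1) / called.sum(axis=1)
        dev = observed - expected
        se = dev.std(ddof=1) / np.sqrt(len(dev))
        assert abs(dev.mean()) < 3 * se

    def test_adi_truth_labels(self, small_dataset):
        adi = small_dataset.truth.cell_errors.query("mechanism == 'adi'")
        assert len(adi) > 0
        ped = small_dataset.sim_pedigree.pedigree
        # offspring-only injection under the default config
        for iid in adi["individual_id"].unique():
            assert ped[iid].sire_id is not None
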
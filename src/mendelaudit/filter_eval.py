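"""SNP-loss vs mismatch-removal trade-off of marker QC filters.

A scenario enables any subset of three criteria; a SNP is removed when it
fails ANY enabled criterion:

* MAF:   maf <= maf_max (the conventional low-frequency cut);
* HW:    exact Hardy-Weinberg p <= hw_p_max;
* F_IS:  heterozygote deficiency F_IS >= fis_min (undefined F_IS never
         triggers removal).

The report counts SNPs removed/retained over the whole panel and the
mismatches whose locus is removed (direct locus-removal accounting).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .mendel_classify import MESet

__all__ = [
    "FilterScenario",
    "FilterReport",
    "removal_mask",
    "apply_scenario",
    "scenario_grid",
    "default_scenarios",
]


@dataclass(frozen=True)
class FilterScenario:
    name: str
    maf_max: Optional[float] = None
    hw_p_max: Optional[float] = None
    fis_min: Optional[float] = None

    def __post_init__(self):
        if self.maf_max is None and self.hw_p_max is None and self.fis_min is None:
            raise ValueError(f"scenario {self.name!r}: enable at least one criterion")
        if self.maf_max is not None and not 0 <= self.maf_max <= 0.5:
            raise ValueError("maf_max must be in [0, 0.5]")
        if self.hw_p_max is not None and not 0 < self.hw_p_max <= 1:
            raise ValueError("hw_p_max must be in (0, 1]")
        if self.fis_min is not None and not -1 <= self.fis_min <= 1:
            raise ValueError("fis_min must be in [-1, 1]")


@dataclass(frozen=True)
class FilterReport:
    scenario: str
    snps_removed: int
    frac_snps_removed: float
    mismatches_removed: int
    frac_mismatches_removed: float
    me_loci_removed: int
    snps_retained: int


def removal_mask(locus_summaries: pd.DataFrame, scenario: FilterScenario) -> pd.Series:
    """Boolean Series over the panel: True = SNP removed by the scenario."""
    removed = pd.Series(False, index=locus_summaries.index)
    if scenario.maf_max is not None:
        removed |= locus_summaries["maf"] <= scenario.maf_max
    if scenario.hw_p_max is not None:
        removed |= locus_summaries["hw_p"] <= scenario.hw_p_max
    if scenario.fis_min is not None:
        fis = locus_summaries["f_is"]
        removed |= fis.notna() & (fis >= scenario.fis_min)
    return removed


def apply_scenario(
    locus_summaries: pd.DataFrame, meset: MESet, scenario: FilterScenario
) -> FilterReport:
    """Evaluate one scenario over the whole panel.

    ``locus_summaries`` must cover every panel SNP (not just the mismatch
    set); mismatch loci absent from it raise.
    """
    ev = meset.events
    if len(ev):
        missing = set(ev["locus_id"]) - set(locus_summaries.index)
        if missing:
            raise ValueError(f"summaries missing for {len(missing)} mismatch-set loci")
    removed = removal_mask(locus_summaries, scenario)
    n_panel = len(locus_summaries)
    n_removed = int(removed.sum())
    removed_loci = set(locus_summaries.index[removed])
    n_mism_total = len(ev)
    n_mism_removed = int(ev["locus_id"].isin(removed_loci).sum()) if n_mism_total else 0
    me_removed = len(meset.loci & removed_loci)
    return FilterReport(
        scenario=scenario.name,
        snps_removed=n_removed,
        frac_snps_removed=n_removed / n_panel if n_panel else 0.0,
        mismatches_removed=n_mism_removed,
        frac_mismatches_removed=(
            n_mism_removed / n_mism_total if n_mism_total else 0.0
        ),
        me_loci_removed=me_removed,
        snps_retained=n_panel - n_removed,
    )


def scenario_grid(
    locus_summaries: pd.DataFrame,
    meset: MESet,
    scenarios: Sequence[FilterScenario],
) -> pd.DataFrame:
    """Apply every scenario; one row each, sorted by mismatches removed per
    SNP lost (best trade-off first, scenarios removing nothing last)."""
    rows = [apply_scenario(locus_summaries, meset, sc) for sc in scenarios]
    df = pd.DataFrame([r.__dict__ for r in rows]).set_index("scenario")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(
            df["snps_removed"] > 0,
            df["mismatches_removed"] / df["snps_removed"],
            -np.inf,
        )
    df["mismatches_per_snp_removed"] = np.where(np.isfinite(ratio), ratio, np.nan)
    return df.iloc[np.argsort(-np.nan_to_num(ratio, neginf=-np.inf), kind="stable")]


def default_scenarios(
    maf_max: float = 0.05,
    hw_p: float = 1e-3,
    hw_p_strict: float = 1e-4,
    fis_min: float = 0.2,
) -> list[FilterScenario]:
    """The conventional QC grid: MAF, two HW stringencies, heterozygote
    deficiency, and MAF+HW combined."""
    return [
        FilterScenario("maf0.05", maf_max=maf_max),
        FilterScenario("hw1e-3", hw_p_max=hw_p),
        FilterScenario("hw1e-4", hw_p_max=hw_p_strict),
        FilterScenario("fis0.2", fis_min=fis_min),
        FilterScenario("maf0.05+hw1e-3", maf_max=maf_max, hw_p_max=hw_p),
    ]
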
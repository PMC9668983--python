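import numpy as np
import pytest

from mendelaudit import CnvConfig, NullAlleleConfig, SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Small all-mechanisms dataset shared across module tests."""
    cfg = SimConfig(
        seed=7,
        n_loci=1500,
        n_boars=8,
        n_sows=12,
        n_couples=20,
        cnv=CnvConfig(n_segments=25, carrier_fraction=0.03),
        null_allele=NullAlleleConfig(fraction=0.02, r=0.25, dropout=0.7),
        adi_rate=5e-4,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def clean_dataset():
    """Error-free gene-drop dataset (every mechanism switched off)."""
    cfg = SimConfig(
        seed=11,
        n_loci=400,
        n_boars=5,
        n_sows=6,
        n_couples=10,
        null_allele=NullAlleleConfig(fraction=0.0),
        cnv=CnvConfig(n_segments=0),
        adi_rate=0.0,
        base_error=0.0,
    )
    return simulate_dataset(cfg)


@pytest.fixture()
def tiny_ped_map(tmp_path):
    """One trio plus an unrelated founder, 3 loci, written as PED/MAP text."""
    map_text = "1\tsnp1\t0\t100\n1\tsnp2\t0\t200\n2\tsnp3\t0\t150\n"
    ped_rows = [
        # fid iid pat mat sex pheno  snp1  snp2  snp3
        "FAM1 DAD 0 0 1 -9 A A A C G G",
        "FAM1 MUM 0 0 2 -9 A A A A G T",
        "FAM1 KID DAD MUM 1 -9 A A C C 0 0",
        "FAM1 LONER 0 0 0 -9 A A A C T T",
    ]
    ped = tmp_path / "tiny.ped"
    mp = tmp_path / "tiny.map"
    ped.write_text("\n".join(ped_rows) + "\n")
    mp.write_text(map_text)
    return ped, mp
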
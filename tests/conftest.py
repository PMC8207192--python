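import numpy as np
import pandas as pd
import pytest

from m2seq import BulkPairDataset, SimConfig, VariantSite, simulate_populations


def make_dataset(population_id, rows):
    """rows: (chrom, pos, ref, alt, mut_ref, mut_alt, wt_ref, wt_alt[, gene, fc])."""
    sites = []
    for row in rows:
        extra = {}
        if len(row) > 8:
            extra = {"gene_id": row[8], "functional_class": row[9]}
        sites.append(VariantSite(*row[:8], **extra))
    return BulkPairDataset.from_sites(population_id, sites)


@pytest.fixture(scope="session")
def small_config():
    """Down-scaled genome for fast unit tests; densities keep study-like ratios."""
    return SimConfig(
        seed=11,
        n_chromosomes=4,
        chrom_length_bp=10_000_000,
        ems_rate_per_mb=20.0,
        background_shared_per_mb=30.0,
        background_private_per_mb=5.0,
        n_populations=3,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simulate_populations(small_config)


@pytest.fixture
def toy_populations():
    """Three populations engineered so population Mut01 holds exactly one
    variant of every terminal filter status.

    Mut01's six variants: a shared background variant (also in Mut02/Mut03),
    a private high-index variant, a double-low-index variant, a mutant-zero
    variant, a low-depth variant, and one clean EMS variant.
    """
    shared = ("Chr01", 100, "C", "T", 2, 10, 2, 10)  # indices 0.83/0.83, in all pops
    pop1 = make_dataset(
        "Mut01",
        [
            shared,  # -> STEP1
            ("Chr01", 200, "G", "A", 1, 30, 2, 28),  # 0.97/0.93 -> STEP2
            ("Chr01", 300, "A", "G", 10, 1, 12, 2),  # 0.09/0.14 -> STEP3 (double low)
            ("Chr01", 400, "C", "A", 15, 0, 8, 8),  # mutant-zero -> STEP3
            ("Chr01", 500, "T", "C", 3, 2, 20, 20),  # mut depth 5 -> DEPTH_FAIL
            ("Chr01", 600, "G", "T", 0, 20, 10, 5),  # 1.0/0.33 -> PASS
        ],
    )
    pop2 = make_dataset("Mut02", [shared, ("Chr02", 700, "C", "T", 5, 10, 8, 7)])
    pop3 = make_dataset("Mut03", [shared, ("Chr03", 800, "G", "A", 6, 9, 9, 6)])
    return [pop1, pop2, pop3]


def indexed_frame(dsi_values, chrom="Chr01", start=1000, spacing=1000, status="PASS",
                  vclass="SNV"):
    """Minimal indexed-variant frame with prescribed DSI values, for curve tests."""
    n = len(dsi_values)
    dsi = np.asarray(dsi_values, dtype=float)
    return pd.DataFrame(
        {
            "chrom": [chrom] * n,
            "pos": np.arange(start, start + n * spacing, spacing, dtype=np.int64),
            "ref": ["C"] * n,
            "alt": ["T"] * n,
            "vclass": [vclass] * n,
            "mut_ref_depth": [10] * n,
            "mut_alt_depth": [10] * n,
            "wt_ref_depth": [10] * n,
            "wt_alt_depth": [10] * n,
            "gene_id": [None] * n,
            "functional_class": [None] * n,
            "snp_index_mut": 0.5 + dsi / 2,
            "snp_index_wt": 0.5 - dsi / 2,
            "dsi": dsi,
            "adsi": np.abs(dsi),
            "status": [status] * n,
        }
    )
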
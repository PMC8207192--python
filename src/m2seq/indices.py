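"""Per-site SNP-index statistics and the depth-based retention filter.

The SNP index of a bulk at a variant locus is the fraction of reads carrying
the non-reference allele, alt / (ref + alt).  The delta SNP index (DSI) is
the mutant-bulk index minus the wild-type-bulk index, so a recessive causal
locus — homozygous alt in every mutant-bulk individual — trends to +1 while
repulsion-phase linked mutations trend negative.  ADSI is |DSI| (optionally
after zero-centering, see :mod:`m2seq.mapping`).

Sites where either bulk has total depth below ``min_depth`` get status
DEPTH_FAIL and NaN indices; every downstream statistic operates on the
depth-passing subset only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .variants import BulkPairDataset, VariantSite

log = logging.getLogger(__name__)

DEFAULT_MIN_DEPTH = 6


@dataclass(frozen=True)
class IndexedVariant:
    """A VariantSite together with its per-bulk SNP indices and filter status."""

    site: VariantSite
    snp_index_mut: float
    snp_index_wt: float
    dsi: float
    adsi: float
    status: str = "PASS"


def snp_index(ref_depth: int, alt_depth: int) -> float:
    """Fraction of non-reference reads at a locus: alt / (ref + alt).

    Raises ValueError at zero total depth; callers must depth-filter first.
    """
    if ref_depth < 0 or alt_depth < 0:
        raise ValueError("depths must be non-negative")
    total = ref_depth + alt_depth
    if total == 0:
        raise ValueError("SNP index undefined at zero total depth")
    return alt_depth / total


def depth_filter(
    dataset: BulkPairDataset, min_depth: int = DEFAULT_MIN_DEPTH
) -> pd.Series:
    """Boolean pass mask: total depth >= min_depth in *both* bulks.

    The rule is inclusive: a bulk depth exactly at the threshold passes.
    Pass/fail counts are logged.
    """
    frame = dataset.frame
    mut_tot = frame["mut_ref_depth"] + frame["mut_alt_depth"]
    wt_tot = frame["wt_ref_depth"] + frame["wt_alt_depth"]
    ok = (mut_tot >= min_depth) & (wt_tot >= min_depth)
    log.info(
        "%s: depth filter (>=%d both bulks): %d pass, %d fail",
        dataset.population_id, min_depth, int(ok.sum()), int((~ok).sum()),
    )
    return ok


def compute_indices(
    dataset: BulkPairDataset, min_depth: int = DEFAULT_MIN_DEPTH
) -> pd.DataFrame:
    """Return the dataset frame with snp_index_mut/wt, dsi, adsi and status.

    Depth-failing sites get NaN indices and status DEPTH_FAIL; all others
    start as PASS with adsi = |dsi| (zero-centering, when requested, is a
    later adjustment on the retained set).
    """
    frame = dataset.frame.copy()
    ok = depth_filter(dataset, min_depth).to_numpy()
    mut_tot = (frame["mut_ref_depth"] + frame["mut_alt_depth"]).to_numpy(dtype=float)
    wt_tot = (frame["wt_ref_depth"] + frame["wt_alt_depth"]).to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        idx_mut = np.where(ok, frame["mut_alt_depth"].to_numpy(dtype=float) / mut_tot, np.nan)
        idx_wt = np.where(ok, frame["wt_alt_depth"].to_numpy(dtype=float) / wt_tot, np.nan)
    dsi = idx_mut - idx_wt
    frame["snp_index_mut"] = idx_mut
    frame["snp_index_wt"] = idx_wt
    frame["dsi"] = dsi
    frame["adsi"] = np.abs(dsi)
    frame["status"] = np.where(ok, "PASS", "DEPTH_FAIL")
    return frame


def to_indexed_variants(frame: pd.DataFrame) -> list[IndexedVariant]:
    """Materialise IndexedVariant records from an indexed frame (small inputs)."""
    out = []
    for row in frame.itertuples(index=False):
        gene = row.gene_id if isinstance(row.gene_id, str) else None
        fc = row.functional_class if isinstance(row.functional_class, str) else None
        out.append(
            IndexedVariant(
                site=VariantSite(
                    row.chrom, int(row.pos), row.ref, row.alt,
                    int(row.mut_ref_depth), int(row.mut_alt_depth),
                    int(row.wt_ref_depth), int(row.wt_alt_depth),
                    gene_id=gene, functional_class=fc,
                ),
                snp_index_mut=float(row.snp_index_mut),
                snp_index_wt=float(row.snp_index_wt),
                dsi=float(row.dsi),
                adsi=float(row.adsi),
                status=row.status,
            )
        )
    return out
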
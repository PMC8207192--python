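"""Reading and writing bulk-pair variant data.

VCF input is parsed with :mod:`cyvcf2`; per-bulk allele depths come from the
FORMAT/AD field (DP is ignored — the SNP index needs allele-resolved counts).
Only biallelic records are retained by default; multiallelic records can be
split into per-alt records instead (``multiallelic="split"``).

Tabular output is plain TSV with a fixed column order and round-trips
losslessly.  Filtered datasets can be exported back to VCF with a per-record
``M2SEQ_FILTER`` INFO flag carrying the terminal filter status.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .variants import (
    INDEX_COLUMNS,
    SITE_COLUMNS,
    BulkPairDataset,
    VariantSite,
    sites_to_frame,
    variant_class,
)

log = logging.getLogger(__name__)

PathLike = Union[str, Path]

TABLE_COLUMNS = SITE_COLUMNS + INDEX_COLUMNS


def read_bulk_pair(
    path: PathLike,
    mutant_sample: str,
    wt_sample: str,
    population_id: Optional[str] = None,
    multiallelic: str = "skip",
) -> BulkPairDataset:
    """Read one population's bulk pair from a (optionally bgzipped) VCF.

    Parameters
    ----------
    path
        VCF with FORMAT/AD for both named samples.
    mutant_sample, wt_sample
        Sample names of the mutant and wild-type bulks.
    multiallelic
        ``"skip"`` (default) drops multiallelic records; ``"split"`` emits one
        record per alt allele using that allele's AD count.

    Records lacking AD at either sample are dropped with a logged count.
    """
    if multiallelic not in ("skip", "split"):
        raise ValueError(f"multiallelic must be 'skip' or 'split', got {multiallelic!r}")
    path = Path(path)
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise ValueError(f"malformed or unreadable VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    for name in (mutant_sample, wt_sample):
        if name not in samples:
            raise ValueError(
                f"sample {name!r} not in {path.name}; available samples: {samples}"
            )
    i_mut = samples.index(mutant_sample)
    i_wt = samples.index(wt_sample)

    sites: list[VariantSite] = []
    n_multi = n_missing_ad = 0
    for rec in vcf:
        alts = rec.ALT
        if len(alts) == 0:
            continue
        if len(alts) > 1 and multiallelic == "skip":
            n_multi += 1
            continue
        ad = rec.format("AD")
        if ad is None:
            n_missing_ad += 1
            continue
        ad = np.asarray(ad)
        # cyvcf2 encodes missing AD as negative sentinels
        if ad.shape[1] < len(alts) + 1 or (ad[[i_mut, i_wt]] < 0).any():
            n_missing_ad += 1
            continue
        for ai, alt in enumerate(alts, start=1):
            sites.append(
                VariantSite(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=alt,
                    mut_ref_depth=int(ad[i_mut, 0]),
                    mut_alt_depth=int(ad[i_mut, ai]),
                    wt_ref_depth=int(ad[i_wt, 0]),
                    wt_alt_depth=int(ad[i_wt, ai]),
                )
            )
    contigs = {}
    try:
        contigs = dict(zip(vcf.seqnames, vcf.seqlens))
    except Exception:
        pass
    if n_multi:
        log.info("%s: skipped %d multiallelic records", path.name, n_multi)
    if n_missing_ad:
        log.info("%s: dropped %d records with missing AD", path.name, n_missing_ad)
    return BulkPairDataset.from_sites(
        population_id or path.stem.removesuffix(".vcf"),
        sites,
        metadata={
            "mutant_sample": mutant_sample,
            "wt_sample": wt_sample,
            "source": str(path),
            "contigs": contigs,
        },
    )


def attach_annotations(dataset: BulkPairDataset, table: PathLike) -> BulkPairDataset:
    """Join a functional-annotation TSV (chrom, pos, ref, alt, gene_id,
    functional_class) onto the dataset by exact variant key."""
    ann = pd.read_csv(table, sep="\t", dtype={"chrom": str, "pos": np.int64})
    need = {"chrom", "pos", "ref", "alt", "gene_id", "functional_class"}
    if not need.issubset(ann.columns):
        raise ValueError(f"annotation table must have columns {sorted(need)}")
    frame = dataset.frame.drop(columns=["gene_id", "functional_class"]).merge(
        ann[list(["chrom", "pos", "ref", "alt", "gene_id", "functional_class"])],
        on=["chrom", "pos", "ref", "alt"],
        how="left",
    )
    return BulkPairDataset(dataset.population_id, frame, dict(dataset.metadata))


def write_variant_table(frame_or_dataset, path: PathLike) -> None:
    """Write an indexed variant table as TSV with a fixed column order.

    Accepts a BulkPairDataset or a bare frame; index columns that have not
    been computed yet are emitted empty so the header is stable.
    """
    frame = getattr(frame_or_dataset, "frame", frame_or_dataset).copy()
    for col in TABLE_COLUMNS:
        if col not in frame.columns:
            frame[col] = pd.NA
    frame = frame[TABLE_COLUMNS]
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g", na_rep="")


def read_variant_table(path: PathLike, population_id: Optional[str] = None) -> BulkPairDataset:
    """Read back a TSV written by :func:`write_variant_table`."""
    frame = pd.read_csv(
        path,
        sep="\t",
        dtype={"chrom": str, "ref": str, "alt": str, "vclass": str, "status": str,
               "gene_id": str, "functional_class": str},
    )
    for col in ("pos", "mut_ref_depth", "mut_alt_depth", "wt_ref_depth", "wt_alt_depth"):
        frame[col] = frame[col].astype(np.int64)
    for col in ("gene_id", "functional_class"):
        frame[col] = frame[col].where(frame[col].notna(), None)
    if frame["status"].isna().all():
        frame = frame.drop(columns=INDEX_COLUMNS)
    return BulkPairDataset(
        population_id or Path(path).stem, frame, {"source": str(path)}
    )


def _genotype(ref_d: int, alt_d: int) -> str:
    if ref_d == 0 and alt_d == 0:
        return "./."
    if ref_d == 0:
        return "1/1"
    if alt_d == 0:
        return "0/0"
    return "0/1"


def write_vcf(dataset: BulkPairDataset, path: PathLike, statuses=None) -> None:
    """Write the bulk pair as a two-sample VCF with FORMAT GT:AD.

    ``statuses`` (optional, aligned with dataset rows) adds an
    ``M2SEQ_FILTER`` INFO flag per record — the terminal filter status of the
    pipeline (PASS/DEPTH/STEP1/STEP2/STEP3).  Output is deterministic byte
    for byte given the dataset.
    """
    mut = dataset.metadata.get("mutant_sample", "mutant_bulk")
    wt = dataset.metadata.get("wt_sample", "wt_bulk")
    lines = ["##fileformat=VCFv4.2", f"##source=m2seq"]
    for chrom, length in sorted(dataset.contig_lengths().items()):
        lines.append(f"##contig=<ID={chrom},length={length}>")
    if statuses is not None:
        lines.append(
            '##INFO=<ID=M2SEQ_FILTER,Number=1,Type=String,'
            'Description="m2seq filter status (PASS/DEPTH/STEP1/STEP2/STEP3)">'
        )
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">'
    )
    lines.append(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{mut}\t{wt}")
    status_codes = {
        "PASS": "PASS",
        "DEPTH_FAIL": "DEPTH",
        "STEP1_REMOVED": "STEP1",
        "STEP2_REMOVED": "STEP2",
        "STEP3_REMOVED": "STEP3",
    }
    frame = dataset.frame
    stat_list = None if statuses is None else list(statuses)
    if stat_list is not None and len(stat_list) != len(frame):
        raise ValueError("statuses must align with dataset rows")
    for i, row in enumerate(frame.itertuples(index=False)):
        info = "." if stat_list is None else f"M2SEQ_FILTER={status_codes[stat_list[i]]}"
        mut_field = f"{_genotype(row.mut_ref_depth, row.mut_alt_depth)}:{row.mut_ref_depth},{row.mut_alt_depth}"
        wt_field = f"{_genotype(row.wt_ref_depth, row.wt_alt_depth)}:{row.wt_ref_depth},{row.wt_alt_depth}"
        lines.append(
            f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\t.\t{info}\tGT:AD\t{mut_field}\t{wt_field}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_annotation_table(dataset: BulkPairDataset, path: PathLike) -> None:
    """Write the dataset's annotations as the external annotation-table format."""
    frame = dataset.frame[["chrom", "pos", "ref", "alt", "gene_id", "functional_class"]]
    frame.to_csv(path, sep="\t", index=False, na_rep="")
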
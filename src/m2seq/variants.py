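"""Domain types for bulk-pair variant data.

The atom of the pipeline is a biallelic variant observed in a (mutant bulk,
wild-type bulk) pair of pooled DNA samples, carrying the per-bulk allele
depths from which SNP indices are computed.  A population's variants live in
a :class:`BulkPairDataset`, which is backed by a :class:`pandas.DataFrame`
(one row per variant) so that filtering and window statistics stay
vectorised; :class:`VariantSite` objects are lightweight row views.

Coordinates are 1-based inclusive throughout, matching VCF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

PROTEIN_CHANGING_CLASSES = frozenset({"missense", "nonsense", "splice", "frameshift"})
FUNCTIONAL_CLASSES = frozenset(
    {"missense", "nonsense", "synonymous", "splice", "frameshift", "intergenic", "other"}
)

#: Columns of the frame backing a BulkPairDataset, in canonical order.
SITE_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "vclass",
    "mut_ref_depth",
    "mut_alt_depth",
    "wt_ref_depth",
    "wt_alt_depth",
    "gene_id",
    "functional_class",
]

#: Extra columns added once per-site indices have been computed.
INDEX_COLUMNS = ["snp_index_mut", "snp_index_wt", "dsi", "adsi", "status"]

#: Terminal filter statuses.  A variant has exactly one.
STATUSES = ("PASS", "DEPTH_FAIL", "STEP1_REMOVED", "STEP2_REMOVED", "STEP3_REMOVED")


class VariantKey(NamedTuple):
    """Identity of a variant across populations: exact (chrom, pos, ref, alt)."""

    chrom: str
    pos: int
    ref: str
    alt: str


def variant_class(ref: str, alt: str) -> str:
    """SNV iff both alleles are single bases; everything else is an INDEL/MNV record."""
    return "SNV" if len(ref) == 1 and len(alt) == 1 else "INDEL"


@dataclass(frozen=True)
class VariantSite:
    """One biallelic variant with per-bulk allele depths.

    Parameters
    ----------
    chrom, pos, ref, alt
        VCF coordinates (1-based) and allele strings; exactly one alt allele.
    mut_ref_depth, mut_alt_depth, wt_ref_depth, wt_alt_depth
        Non-negative read counts supporting each allele in each bulk (the
        VCF FORMAT/AD values).
    gene_id, functional_class
        Optional functional annotation consumed from an external annotator.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    mut_ref_depth: int
    mut_alt_depth: int
    wt_ref_depth: int
    wt_alt_depth: int
    gene_id: Optional[str] = None
    functional_class: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty allele strings")
        if "," in self.alt:
            raise ValueError(f"multiallelic alt {self.alt!r}: one alt allele per site")
        for name in ("mut_ref_depth", "mut_alt_depth", "wt_ref_depth", "wt_alt_depth"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        fc = self.functional_class
        if fc is not None and fc not in FUNCTIONAL_CLASSES:
            raise ValueError(f"unknown functional_class {fc!r}")

    @property
    def vclass(self) -> str:
        return variant_class(self.ref, self.alt)

    @property
    def key(self) -> VariantKey:
        return VariantKey(self.chrom, self.pos, self.ref, self.alt)

    @property
    def mut_depth(self) -> int:
        return self.mut_ref_depth + self.mut_alt_depth

    @property
    def wt_depth(self) -> int:
        return self.wt_ref_depth + self.wt_alt_depth


def sites_to_frame(sites: Sequence[VariantSite]) -> pd.DataFrame:
    """Build the canonical per-variant frame from VariantSite records."""
    if len(sites) == 0:
        frame = pd.DataFrame(columns=SITE_COLUMNS)
        frame["pos"] = frame["pos"].astype(np.int64)
        return frame
    frame = pd.DataFrame(
        {
            "chrom": [s.chrom for s in sites],
            "pos": np.asarray([s.pos for s in sites], dtype=np.int64),
            "ref": [s.ref for s in sites],
            "alt": [s.alt for s in sites],
            "vclass": [s.vclass for s in sites],
            "mut_ref_depth": np.asarray([s.mut_ref_depth for s in sites], dtype=np.int64),
            "mut_alt_depth": np.asarray([s.mut_alt_depth for s in sites], dtype=np.int64),
            "wt_ref_depth": np.asarray([s.wt_ref_depth for s in sites], dtype=np.int64),
            "wt_alt_depth": np.asarray([s.wt_alt_depth for s in sites], dtype=np.int64),
            "gene_id": [s.gene_id for s in sites],
            "functional_class": [s.functional_class for s in sites],
        }
    )
    return frame


def _row_to_site(row) -> VariantSite:
    gene = row.gene_id if isinstance(row.gene_id, str) else None
    fc = row.functional_class if isinstance(row.functional_class, str) else None
    return VariantSite(
        chrom=row.chrom,
        pos=int(row.pos),
        ref=row.ref,
        alt=row.alt,
        mut_ref_depth=int(row.mut_ref_depth),
        mut_alt_depth=int(row.mut_alt_depth),
        wt_ref_depth=int(row.wt_ref_depth),
        wt_alt_depth=int(row.wt_alt_depth),
        gene_id=gene,
        functional_class=fc,
    )


@dataclass
class BulkPairDataset:
    """All variants of one M2 population's (mutant, wild-type) bulk pair.

    ``frame`` holds one row per variant in the canonical column order and is
    kept strictly sorted by (chrom, pos, ref, alt) with no duplicate keys.
    ``metadata`` records sample names, source path and contig lengths when
    known.
    """

    population_id: str
    frame: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in SITE_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"dataset frame missing columns: {missing}")
        self.frame = self._normalise(self.frame)

    @staticmethod
    def _normalise(frame: pd.DataFrame) -> pd.DataFrame:
        frame = frame.sort_values(
            ["chrom", "pos", "ref", "alt"], kind="mergesort"
        ).reset_index(drop=True)
        dup = frame.duplicated(subset=["chrom", "pos", "ref", "alt"])
        if bool(dup.any()):
            first = frame.loc[dup.idxmax()]
            raise ValueError(
                "duplicate variant key "
                f"({first.chrom}, {first.pos}, {first.ref}, {first.alt})"
            )
        if (frame["pos"] < 1).any():
            raise ValueError("positions must be >= 1")
        return frame

    @classmethod
    def from_sites(
        cls,
        population_id: str,
        sites: Sequence[VariantSite],
        metadata: Optional[dict] = None,
    ) -> "BulkPairDataset":
        return cls(population_id, sites_to_frame(sites), dict(metadata or {}))

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def sites(self) -> Iterator[VariantSite]:
        """Iterate variants as VariantSite records (sorted)."""
        return (_row_to_site(row) for row in self.frame.itertuples(index=False))

    def keys(self) -> list[VariantKey]:
        return [
            VariantKey(c, int(p), r, a)
            for c, p, r, a in zip(
                self.frame["chrom"], self.frame["pos"], self.frame["ref"], self.frame["alt"]
            )
        ]

    def contig_lengths(self) -> dict[str, int]:
        """Contig lengths from metadata, else inferred from the largest position seen."""
        if self.metadata.get("contigs"):
            return dict(self.metadata["contigs"])
        if len(self.frame) == 0:
            return {}
        grouped = self.frame.groupby("chrom", sort=True)["pos"].max()
        return {str(c): int(p) for c, p in grouped.items()}
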
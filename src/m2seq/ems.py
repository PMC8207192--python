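"""Canonical vs noncanonical EMS mutation classification.

EMS alkylates guanine and produces predominantly G:C -> A:T transitions.
On the VCF forward strand that lesion surfaces as either C->T or G->A, so
those two substitutions are the *canonical* EMS class; every other SNV is
noncanonical ("other"), and indels are never canonical.  Roughly 60% of
observed mutagenic SNVs are canonical in practice — the noncanonical rest
must not be discarded when hunting causal mutations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

CANONICAL_PAIRS = {("C", "T"), ("G", "A")}


@dataclass(frozen=True)
class MutationClass:
    is_snv: bool
    is_canonical_ems: bool
    functional_class: Optional[str] = None


def is_canonical_ems(ref: str, alt: str) -> bool:
    return (ref, alt) in CANONICAL_PAIRS


def classify(ref: str, alt: str, functional_class: Optional[str] = None) -> MutationClass:
    """Classify a (ref, alt) substitution.

    C->T and G->A single-base substitutions are canonical; all other SNVs
    are noncanonical.  Length-changing records and multi-nucleotide
    substitutions are classified is_snv=False and never canonical.
    """
    if not ref or not alt:
        raise ValueError("ref and alt must be non-empty")
    if ref == alt:
        raise ValueError(f"ref and alt are identical ({ref!r}): not a variant")
    is_snv = len(ref) == 1 and len(alt) == 1
    return MutationClass(
        is_snv=is_snv,
        is_canonical_ems=is_snv and is_canonical_ems(ref, alt),
        functional_class=functional_class,
    )


def summarize_classes(frame: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Canonical/noncanonical proportions among SNVs plus functional-class table.

    ``frame`` needs columns ref, alt, vclass and optionally functional_class.
    Returns ``{"ems": ..., "functional": ...}`` with counts and percentages
    (percentages sum to 100 within rounding).  Empty input yields empty
    tables.
    """
    if len(frame) == 0:
        return {
            "ems": pd.DataFrame(columns=["category", "count", "percent"]),
            "functional": pd.DataFrame(columns=["functional_class", "count", "percent"]),
        }
    snvs = frame[frame["vclass"] == "SNV"]
    canonical = [
        is_canonical_ems(r, a) for r, a in zip(snvs["ref"], snvs["alt"])
    ]
    n_can = int(sum(canonical))
    n_snv = len(snvs)
    ems = pd.DataFrame(
        {
            "category": ["canonical", "noncanonical"],
            "count": [n_can, n_snv - n_can],
            "percent": [
                100.0 * n_can / n_snv if n_snv else 0.0,
                100.0 * (n_snv - n_can) / n_snv if n_snv else 0.0,
            ],
        }
    )
    if "functional_class" in frame.columns:
        fc = frame["functional_class"].map(
            lambda v: v if isinstance(v, str) else "unannotated"
        )
        counts = fc.value_counts().sort_index()
        functional = pd.DataFrame(
            {
                "functional_class": counts.index,
                "count": counts.to_numpy(),
                "percent": 100.0 * counts.to_numpy() / len(frame),
            }
        ).reset_index(drop=True)
    else:
        functional = pd.DataFrame(columns=["functional_class", "count", "percent"])
    return {"ems": ems, "functional": functional}
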
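"""Three-step purge of background and spurious variants before mapping.

EMS mutations arise independently in each M1 plant, so a true mutagenic
variant is private to one M2 population, heterozygous-derived (intermediate
SNP index), and supported by real reads in the mutant bulk.  The three
filters encode exactly that:

* **Step 1** removes variants whose key occurs in >= 2 populations (shared
  progenitor/reference background, removable without sequencing the
  progenitor).
* **Step 2** removes variants with SNP index above ``hi`` (default 0.7) in
  *both* bulks: population-private background fixed in the progenitor seed
  lot, unlinked to the phenotype.
* **Step 3** removes variants with SNP index below ``lo`` (default 0.3) in
  both bulks (sequencing/alignment noise) and any variant with SNP index
  exactly 0 in the mutant bulk (noncausal-cell chimera variants, which
  segregate only in the wild-type bulk).

Threshold comparisons are strict and carried out in exact rational
arithmetic on the integer depths, so a site at exactly 7/10 is retained
under "> 0.7" with no floating-point ambiguity.  Steps run in fixed order
1 -> 2 -> 3 with first-match-wins statuses, so the per-status counts
partition the input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .indices import DEFAULT_MIN_DEPTH, compute_indices
from .variants import BulkPairDataset, VariantKey

log = logging.getLogger(__name__)

DEFAULT_HI = 0.7
DEFAULT_LO = 0.3


@dataclass
class MultiPopulationSet:
    """Bulk pairs from several M2 populations of the same progenitor line.

    ``occurrence_frame`` holds one row per distinct VariantKey observed
    among depth-passing sites with the number of populations carrying it;
    ``occurrence_index`` exposes the same information as a VariantKey ->
    set-of-population-ids mapping.  Step 1 consumes the former (vectorised).
    """

    populations: list[BulkPairDataset]
    min_depth: int = DEFAULT_MIN_DEPTH
    occurrence_frame: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        if len(self.populations) == 0:
            raise ValueError("at least one population required")
        ids = [p.population_id for p in self.populations]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate population ids: {ids}")
        self.occurrence_frame = self._build_occurrence()

    def _build_occurrence(self) -> pd.DataFrame:
        from .indices import depth_filter

        pieces = []
        for pop in self.populations:
            ok = depth_filter(pop, self.min_depth).to_numpy()
            keys = pop.frame.loc[ok, ["chrom", "pos", "ref", "alt"]].copy()
            keys["population_id"] = pop.population_id
            pieces.append(keys)
        self._combined = pd.concat(pieces, ignore_index=True)
        counts = (
            self._combined.groupby(["chrom", "pos", "ref", "alt"], sort=False)[
                "population_id"
            ]
            .nunique()
            .reset_index(name="n_populations")
        )
        return counts

    @property
    def occurrence_index(self) -> dict:
        index: dict[VariantKey, set] = {}
        for r in self._combined.itertuples(index=False):
            index.setdefault(VariantKey(r.chrom, int(r.pos), r.ref, r.alt), set()).add(
                r.population_id
            )
        return index


def _rational(threshold: float) -> tuple[int, int]:
    frac = Fraction(str(threshold))
    return frac.numerator, frac.denominator


def _exceeds(alt: np.ndarray, tot: np.ndarray, threshold: float) -> np.ndarray:
    """alt/tot > threshold, exactly, on integer depths."""
    num, den = _rational(threshold)
    return alt * den > num * tot


def _below(alt: np.ndarray, tot: np.ndarray, threshold: float) -> np.ndarray:
    """alt/tot < threshold, exactly, on integer depths."""
    num, den = _rational(threshold)
    return alt * den < num * tot


def step1_singleton_filter(
    mps: MultiPopulationSet, frames: dict[str, pd.DataFrame]
) -> dict[str, pd.DataFrame]:
    """Flag variants whose key occurs in >= 2 populations as STEP1_REMOVED.

    Operates in place on the indexed frames (depth-passing rows only).  With
    a single population the step is a logged no-op.
    """
    if len(mps.populations) < 2:
        log.warning("Step 1 skipped: only one population, no cross-population filter")
        return frames
    occ = mps.occurrence_frame[["chrom", "pos", "ref", "alt", "n_populations"]]
    for pop_id, frame in frames.items():
        merged = frame[["chrom", "pos", "ref", "alt"]].merge(
            occ, on=["chrom", "pos", "ref", "alt"], how="left"
        )
        shared = (merged["n_populations"].fillna(0) >= 2).to_numpy()
        mask = shared & (frame["status"] == "PASS").to_numpy()
        frame.loc[mask, "status"] = "STEP1_REMOVED"
        log.info("%s: Step 1 removed %d shared variants", pop_id, int(mask.sum()))
    return frames


def step2_high_index_filter(frame: pd.DataFrame, hi: float = DEFAULT_HI) -> pd.DataFrame:
    """Flag STEP2_REMOVED where SNP index > hi in both bulks (strict)."""
    mut_tot = (frame["mut_ref_depth"] + frame["mut_alt_depth"]).to_numpy()
    wt_tot = (frame["wt_ref_depth"] + frame["wt_alt_depth"]).to_numpy()
    high = _exceeds(frame["mut_alt_depth"].to_numpy(), mut_tot, hi) & _exceeds(
        frame["wt_alt_depth"].to_numpy(), wt_tot, hi
    )
    mask = high & (frame["status"] == "PASS").to_numpy()
    frame.loc[mask, "status"] = "STEP2_REMOVED"
    log.info("Step 2 removed %d high-index variants", int(mask.sum()))
    return frame


def step3_low_index_filter(frame: pd.DataFrame, lo: float = DEFAULT_LO) -> pd.DataFrame:
    """Flag STEP3_REMOVED where SNP index < lo in both bulks, or the mutant
    bulk has exactly zero alt reads (integer test, never a float tolerance)."""
    mut_alt = frame["mut_alt_depth"].to_numpy()
    wt_alt = frame["wt_alt_depth"].to_numpy()
    mut_tot = (frame["mut_ref_depth"] + frame["mut_alt_depth"]).to_numpy()
    wt_tot = (frame["wt_ref_depth"] + frame["wt_alt_depth"]).to_numpy()
    low = _below(mut_alt, mut_tot, lo) & _below(wt_alt, wt_tot, lo)
    zero_mut = mut_alt == 0
    mask = (low | zero_mut) & (frame["status"] == "PASS").to_numpy()
    frame.loc[mask, "status"] = "STEP3_REMOVED"
    log.info("Step 3 removed %d low-index / mutant-zero variants", int(mask.sum()))
    return frame


@dataclass(frozen=True)
class FilterReport:
    """Count partition of one population's variants across filter statuses."""

    population_id: str
    n_input: int
    n_depth_fail: int
    n_step1: int
    n_step2: int
    n_step3: int
    n_retained: int

    def __post_init__(self) -> None:
        total = (
            self.n_depth_fail + self.n_step1 + self.n_step2 + self.n_step3 + self.n_retained
        )
        if total != self.n_input:
            raise ValueError("filter report does not partition the input")

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "population_id": self.population_id,
                "input": self.n_input,
                "depth_fail": self.n_depth_fail,
                "step1_removed": self.n_step1,
                "step2_removed": self.n_step2,
                "step3_removed": self.n_step3,
                "retained": self.n_retained,
            }
        )


def report_from_frame(population_id: str, frame: pd.DataFrame) -> FilterReport:
    counts = frame["status"].value_counts()
    return FilterReport(
        population_id=population_id,
        n_input=len(frame),
        n_depth_fail=int(counts.get("DEPTH_FAIL", 0)),
        n_step1=int(counts.get("STEP1_REMOVED", 0)),
        n_step2=int(counts.get("STEP2_REMOVED", 0)),
        n_step3=int(counts.get("STEP3_REMOVED", 0)),
        n_retained=int(counts.get("PASS", 0)),
    )


def run_filter_pipeline(
    mps: MultiPopulationSet,
    min_depth: Optional[int] = None,
    hi: float = DEFAULT_HI,
    lo: float = DEFAULT_LO,
) -> tuple[dict[str, pd.DataFrame], list[FilterReport]]:
    """Depth filter, index computation and Steps 1 -> 2 -> 3 for every population.

    Returns per-population indexed frames (with terminal ``status``) and one
    FilterReport per population.  Statuses are first-match-wins, so the
    report is an exact partition of the input sites.
    """
    if min_depth is None:
        min_depth = mps.min_depth
    frames = {
        pop.population_id: compute_indices(pop, min_depth) for pop in mps.populations
    }
    frames = step1_singleton_filter(mps, frames)
    reports = []
    for pop in mps.populations:
        frame = frames[pop.population_id]
        step2_high_index_filter(frame, hi)
        step3_low_index_filter(frame, lo)
        reports.append(report_from_frame(pop.population_id, frame))
    return frames, reports


def reports_to_frame(reports: Sequence[FilterReport]) -> pd.DataFrame:
    return pd.DataFrame([r.to_series() for r in reports])
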
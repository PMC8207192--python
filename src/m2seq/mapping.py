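"""Sliding-window genome scan and candidate-mutation screening.

The fitted curve is the moving average of DSI (and of ADSI) over windows of
``window_n`` consecutive retained SNVs, shifted one SNV at a time, with each
window plotted at the midpoint between its first and last SNV.  Because
linked EMS mutations sit in coupling or repulsion phase at random, signed
DSI cancels inside windows near the causal locus while ADSI does not — the
ADSI curve's global peak marks the candidate region.

Zero-centering subtracts the genome-wide mean DSI from every site's DSI
before taking absolute values; it restores the scan when chimeric
contamination of the wild-type bulk shifts all DSIs positive.

Windows never span chromosome boundaries, and only SNVs contribute to
curves; indels re-enter at the screening stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .ems import is_canonical_ems
from .variants import PROTEIN_CHANGING_CLASSES

log = logging.getLogger(__name__)

DEFAULT_REGION_FRACTION = 0.5
DEFAULT_ADSI_SCREEN = 0.5
WINDOW_CHOICES = (10, 20, 40)
ZERO_CENTER_TRIGGER = 0.1

CURVE_COLUMNS = ["midpoint_bp", "mean_dsi", "mean_adsi", "n_snps", "first_bp", "last_bp"]


@dataclass
class WindowCurve:
    """Moving-average DSI/ADSI curve for one chromosome.

    ``points`` has one row per window position: midpoint_bp, mean_dsi,
    mean_adsi, n_snps, first_bp, last_bp.  Consecutive rows shift by exactly
    one SNV.
    """

    chrom: str
    window_n: int
    points: pd.DataFrame

    def __len__(self) -> int:
        return len(self.points)


def retained_snvs(frame: pd.DataFrame) -> pd.DataFrame:
    """Retained (status PASS) single-nucleotide variants, the curve input."""
    return frame[(frame["status"] == "PASS") & (frame["vclass"] == "SNV")]


def _moving_mean(values: np.ndarray, n: int) -> np.ndarray:
    # cumulative-sum moving average; windows of n consecutive values
    c = np.concatenate([[0.0], np.cumsum(values, dtype=float)])
    return (c[n:] - c[:-n]) / n


def fit_windows(frame: pd.DataFrame, window_n: int) -> list[WindowCurve]:
    """Fit the moving-average curve per chromosome.

    ``frame`` must be an indexed variant frame; only PASS SNVs are used.  A
    chromosome with m >= window_n SNVs yields exactly m - window_n + 1
    points; chromosomes with fewer yield an empty curve with a warning.
    """
    if window_n < 2:
        raise ValueError(f"window_n must be >= 2, got {window_n}")
    snvs = retained_snvs(frame)
    curves = []
    for chrom, grp in snvs.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy(dtype=np.int64)
        m = len(grp)
        if m < window_n:
            log.warning("%s: only %d retained SNVs (< window %d), empty curve",
                        chrom, m, window_n)
            points = pd.DataFrame(columns=CURVE_COLUMNS)
        else:
            first = pos[: m - window_n + 1]
            last = pos[window_n - 1:]
            points = pd.DataFrame(
                {
                    "midpoint_bp": (first + last) // 2,
                    "mean_dsi": _moving_mean(grp["dsi"].to_numpy(), window_n),
                    "mean_adsi": _moving_mean(grp["adsi"].to_numpy(), window_n),
                    "n_snps": window_n,
                    "first_bp": first,
                    "last_bp": last,
                }
            )
        curves.append(WindowCurve(chrom=str(chrom), window_n=window_n, points=points))
    return curves


def zero_center(frame: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Recompute ADSI as |dsi - genome_mean_dsi| over retained SNVs.

    The genome mean is taken over retained (PASS) SNVs; the adjustment is
    applied to every row that has a DSI.  Returns the adjusted frame and the
    subtracted mean.
    """
    snvs = retained_snvs(frame)
    if len(snvs) == 0:
        raise ValueError("zero_center: no retained SNVs")
    genome_mean = float(snvs["dsi"].mean())
    frame = frame.copy()
    frame["adsi"] = np.abs(frame["dsi"] - genome_mean)
    return frame, genome_mean


def suggest_zero_centering(frame: pd.DataFrame) -> bool:
    """True when |genome-wide mean DSI| exceeds 0.1 — the chimera signature."""
    snvs = retained_snvs(frame)
    return len(snvs) > 0 and abs(float(snvs["dsi"].mean())) > ZERO_CENTER_TRIGGER


def auto_select_window(n_retained_snvs: int) -> int:
    """Pick the window size from the genome-wide retained-SNV count.

    Denser scans support wider windows: 10 below 2,000 retained SNVs, 20
    below 8,000, else 40.
    """
    if n_retained_snvs < 2000:
        return 10
    if n_retained_snvs < 8000:
        return 20
    return 40


@dataclass
class CandidateRegion:
    """A contiguous window span around an ADSI (or DSI) curve peak."""

    chrom: str
    start_bp: int
    end_bp: int
    peak_midpoint_bp: int
    peak_value: float
    n_windows: int
    variants: Optional[pd.DataFrame] = field(default=None, repr=False)

    @property
    def peak_adsi(self) -> float:
        return self.peak_value


def _region_on_curve(curve: WindowCurve, stat: str, fraction: float) -> Optional[CandidateRegion]:
    pts = curve.points
    if len(pts) == 0:
        return None
    values = pts[stat].to_numpy(dtype=float)
    peak_i = int(np.argmax(values))
    peak = float(values[peak_i])
    above = values >= fraction * peak
    lo = peak_i
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = peak_i
    while hi < len(values) - 1 and above[hi + 1]:
        hi += 1
    return CandidateRegion(
        chrom=curve.chrom,
        start_bp=int(pts["first_bp"].iloc[lo]),
        end_bp=int(pts["last_bp"].iloc[hi]),
        peak_midpoint_bp=int(pts["midpoint_bp"].iloc[peak_i]),
        peak_value=peak,
        n_windows=hi - lo + 1,
    )


def detect_candidate_region(
    curves: Sequence[WindowCurve],
    statistic: str = "adsi",
    fraction: float = DEFAULT_REGION_FRACTION,
    variants: Optional[pd.DataFrame] = None,
) -> list[CandidateRegion]:
    """Locate the global curve peak and its half-peak contiguous span.

    ``statistic`` is ``"adsi"`` (the scan statistic of the method) or
    ``"dsi"`` (the signed curve, kept for comparison).  The region is the
    maximal contiguous run of windows whose fitted value is >= ``fraction``
    of the peak, reported as [first window's first_bp, last window's
    last_bp].  Returns regions for every non-empty chromosome ranked by peak
    value; the primary region is first.  Ties on peak value are broken by
    widest region, then lowest chromosome/position.
    """
    stat = {"adsi": "mean_adsi", "dsi": "mean_dsi"}[statistic]
    regions = [r for c in curves if (r := _region_on_curve(c, stat, fraction))]
    if not regions:
        raise ValueError("no non-empty window curves: cannot detect a region")
    regions.sort(
        key=lambda r: (-r.peak_value, -(r.end_bp - r.start_bp), r.chrom, r.start_bp)
    )
    if variants is not None:
        for r in regions:
            in_r = variants[
                (variants["chrom"] == r.chrom)
                & (variants["pos"] >= r.start_bp)
                & (variants["pos"] <= r.end_bp)
            ]
            r.variants = in_r
    return regions


@dataclass(frozen=True)
class CandidateMutation:
    """A screened causal-mutation candidate inside the detected region."""

    chrom: str
    pos: int
    ref: str
    alt: str
    vclass: str
    snp_index_mut: float
    snp_index_wt: float
    dsi: float
    adsi: float
    gene_id: Optional[str]
    functional_class: Optional[str]
    is_canonical_ems: bool


def screen_candidates(
    region: CandidateRegion,
    frame: pd.DataFrame,
    adsi_threshold: float = DEFAULT_ADSI_SCREEN,
) -> list[CandidateMutation]:
    """Screen region variants for causal-mutation candidates.

    Criteria: SNP index exactly 1 in the mutant bulk (mut_ref_depth == 0 on
    the integer depths, with at least one alt read), per-variant ADSI above
    ``adsi_threshold``, and a protein-changing functional class.  Indels are
    eligible.  When no variant in the region carries an annotation the
    functional criterion is dropped with a warning and screening degrades to
    the two numeric rules.
    """
    retained = frame[frame["status"] == "PASS"]
    in_region = retained[
        (retained["chrom"] == region.chrom)
        & (retained["pos"] >= region.start_bp)
        & (retained["pos"] <= region.end_bp)
    ]
    has_annotation = in_region["functional_class"].map(
        lambda v: isinstance(v, str)
    )
    use_annotation = bool(has_annotation.any())
    if not use_annotation:
        log.warning(
            "no functional annotations in region %s:%d-%d; screening on numeric criteria only",
            region.chrom, region.start_bp, region.end_bp,
        )
    out = []
    for row in in_region.itertuples(index=False):
        if int(row.mut_ref_depth) != 0 or int(row.mut_alt_depth) == 0:
            continue
        if not float(row.adsi) > adsi_threshold:
            continue
        fc = row.functional_class if isinstance(row.functional_class, str) else None
        if use_annotation and fc not in PROTEIN_CHANGING_CLASSES:
            continue
        out.append(
            CandidateMutation(
                chrom=row.chrom,
                pos=int(row.pos),
                ref=row.ref,
                alt=row.alt,
                vclass=row.vclass,
                snp_index_mut=float(row.snp_index_mut),
                snp_index_wt=float(row.snp_index_wt),
                dsi=float(row.dsi),
                adsi=float(row.adsi),
                gene_id=row.gene_id if isinstance(row.gene_id, str) else None,
                functional_class=fc,
                is_canonical_ems=is_canonical_ems(row.ref, row.alt),
            )
        )
    return out


def candidates_to_frame(candidates: Sequence[CandidateMutation]) -> pd.DataFrame:
    cols = [
        "chrom", "pos", "ref", "alt", "vclass", "snp_index_mut", "snp_index_wt",
        "dsi", "adsi", "gene_id", "functional_class", "is_canonical_ems",
    ]
    if not candidates:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([c.__dict__ for c in candidates])[cols]


def curves_to_frame(curves: Sequence[WindowCurve]) -> pd.DataFrame:
    frames = []
    for c in curves:
        pts = c.points.copy()
        pts.insert(0, "chrom", c.chrom)
        pts.insert(1, "window_n", c.window_n)
        frames.append(pts)
    if not frames:
        return pd.DataFrame(columns=["chrom", "window_n"] + CURVE_COLUMNS)
    return pd.concat(frames, ignore_index=True)
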
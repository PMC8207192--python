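"""Model/Results interface for the whole genome scan.

:class:`M2SeqScan` is built from one or more populations' bulk-pair
datasets (or directly from VCFs) plus the scan's tunable thresholds;
``fit()`` runs depth filtering, the three background-filter steps, window
fitting, optional zero-centering, candidate-region detection and
candidate-mutation screening, and returns an :class:`M2SeqScanResults`
carrying per-population mappings, filter reports and a ``summary()`` table.
Plotting and output serialisation hang off the results object.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from . import io as m2io
from .ems import summarize_classes
from .filtering import (DEFAULT_HI, DEFAULT_LO, FilterReport, MultiPopulationSet,
                        reports_to_frame, run_filter_pipeline)
from .indices import DEFAULT_MIN_DEPTH
from .mapping import (DEFAULT_ADSI_SCREEN, DEFAULT_REGION_FRACTION,
                      CandidateMutation, CandidateRegion, WindowCurve,
                      auto_select_window, candidates_to_frame, curves_to_frame,
                      detect_candidate_region, fit_windows, retained_snvs,
                      screen_candidates, suggest_zero_centering, zero_center)
from .variants import BulkPairDataset

log = logging.getLogger(__name__)


@dataclass
class PopulationMapping:
    """Fitted scan for one population."""

    population_id: str
    frame: pd.DataFrame  # indexed variants with terminal statuses
    report: FilterReport
    window_n: int
    zero_centered: bool
    genome_mean_dsi: float
    curves: list[WindowCurve]
    regions: list[CandidateRegion]
    candidates: list[CandidateMutation]

    @property
    def region(self) -> CandidateRegion:
        """The primary (top-peak) candidate region."""
        return self.regions[0]


class M2SeqScan:
    """Genome-scan model over one or more M2 populations' bulk pairs.

    Parameters
    ----------
    populations
        BulkPairDataset per population.  Two or more enable the
        cross-population background filter (Step 1); with one, Step 1 is a
        logged no-op.
    min_depth, hi, lo
        Depth-retention threshold and the strict high/low SNP-index filter
        thresholds.
    window_n
        Sliding-window size in consecutive SNVs, or ``"auto"`` to choose
        10/20/40 from the retained-SNV density.
    zero_centering
        ``"off"``, ``"on"``, or ``"auto"`` (apply when the genome-wide mean
        DSI magnitude exceeds 0.1 — the chimeric-contamination signature).
    region_fraction
        Half-peak fraction bounding the candidate region.
    adsi_screen
        Per-variant ADSI threshold of the candidate screen.
    """

    def __init__(
        self,
        populations: Sequence[BulkPairDataset],
        min_depth: int = DEFAULT_MIN_DEPTH,
        hi: float = DEFAULT_HI,
        lo: float = DEFAULT_LO,
        window_n: Union[int, str] = "auto",
        zero_centering: str = "auto",
        region_fraction: float = DEFAULT_REGION_FRACTION,
        adsi_screen: float = DEFAULT_ADSI_SCREEN,
    ):
        if zero_centering not in ("off", "on", "auto"):
            raise ValueError("zero_centering must be 'off', 'on' or 'auto'")
        if window_n != "auto" and int(window_n) < 2:
            raise ValueError("window_n must be >= 2 or 'auto'")
        self.populations = list(populations)
        self.min_depth = min_depth
        self.hi = hi
        self.lo = lo
        self.window_n = window_n
        self.zero_centering = zero_centering
        self.region_fraction = region_fraction
        self.adsi_screen = adsi_screen

    @classmethod
    def from_vcfs(
        cls,
        paths: Sequence,
        mutant_sample: Optional[str] = None,
        wt_sample: Optional[str] = None,
        annotations: Optional[Sequence] = None,
        **kwargs,
    ) -> "M2SeqScan":
        """Build the model from one VCF per population.

        When sample names are omitted, the first sample of each VCF is
        taken as the mutant bulk and the second as the wild-type bulk.
        ``annotations`` optionally gives one functional-annotation TSV per
        VCF (aligned with ``paths``).
        """
        from cyvcf2 import VCF

        datasets = []
        for i, path in enumerate(paths):
            mut, wt = mutant_sample, wt_sample
            if mut is None or wt is None:
                samples = VCF(str(path)).samples
                if len(samples) < 2:
                    raise ValueError(f"{path}: need two samples, found {samples}")
                mut = mut or samples[0]
                wt = wt or samples[1]
            dataset = m2io.read_bulk_pair(path, mut, wt)
            if annotations is not None and annotations[i] is not None:
                dataset = m2io.attach_annotations(dataset, annotations[i])
            datasets.append(dataset)
        return cls(datasets, **kwargs)

    def fit(self) -> "M2SeqScanResults":
        mps = MultiPopulationSet(self.populations, min_depth=self.min_depth)
        frames, reports = run_filter_pipeline(
            mps, min_depth=self.min_depth, hi=self.hi, lo=self.lo
        )
        mappings = {}
        for pop, report in zip(self.populations, reports):
            frame = frames[pop.population_id]
            snvs = retained_snvs(frame)
            genome_mean = float(snvs["dsi"].mean()) if len(snvs) else float("nan")
            centered = self.zero_centering == "on" or (
                self.zero_centering == "auto" and suggest_zero_centering(frame)
            )
            if centered:
                frame, genome_mean = zero_center(frame)
                log.info(
                    "%s: zero-centering applied (genome mean DSI %.3f)",
                    pop.population_id, genome_mean,
                )
            wn = (
                auto_select_window(len(snvs))
                if self.window_n == "auto"
                else int(self.window_n)
            )
            curves = fit_windows(frame, wn)
            regions = detect_candidate_region(
                curves, "adsi", self.region_fraction, variants=frame
            )
            candidates = screen_candidates(regions[0], frame, self.adsi_screen)
            mappings[pop.population_id] = PopulationMapping(
                population_id=pop.population_id,
                frame=frame,
                report=report,
                window_n=wn,
                zero_centered=centered,
                genome_mean_dsi=genome_mean,
                curves=curves,
                regions=regions,
                candidates=candidates,
            )
        return M2SeqScanResults(self, mappings)


class M2SeqScanResults:
    """Fitted genome-scan results across populations."""

    def __init__(self, model: M2SeqScan, mappings: dict[str, PopulationMapping]):
        self.model = model
        self.mappings = mappings

    def __getitem__(self, population_id: str) -> PopulationMapping:
        return self.mappings[population_id]

    @property
    def filter_report(self) -> pd.DataFrame:
        return reports_to_frame([m.report for m in self.mappings.values()])

    def mutation_spectrum(self, population_id: str) -> dict[str, pd.DataFrame]:
        """Canonical/noncanonical and functional-class tables of the
        population's retained variants."""
        frame = self.mappings[population_id].frame
        return summarize_classes(frame[frame["status"] == "PASS"])

    def summary(self) -> str:
        lines = ["M2-seq genome scan", "=" * 60]
        for m in self.mappings.values():
            r = m.region
            lines.append(
                f"{m.population_id}: retained {m.report.n_retained}/{m.report.n_input} "
                f"variants, window {m.window_n} SNVs"
                + (", zero-centered" if m.zero_centered else "")
            )
            lines.append(
                f"  candidate region {r.chrom}:{r.start_bp:,}-{r.end_bp:,} "
                f"(peak ADSI {r.peak_value:.3f} at {r.peak_midpoint_bp:,})"
            )
            if m.candidates:
                for c in m.candidates:
                    lines.append(
                        f"  candidate {c.chrom}:{c.pos} {c.ref}>{c.alt} "
                        f"[{c.functional_class or 'unannotated'}] "
                        f"index_mut={c.snp_index_mut:.2f} wt={c.snp_index_wt:.2f} "
                        f"ADSI={c.adsi:.2f}"
                    )
            else:
                lines.append("  no candidate mutations passed the screen")
        return "\n".join(lines)

    def plot(self, population_id: str, path=None, chrom: Optional[str] = None):
        """Genome-wide (or single-chromosome) DSI scatter with DSI/ADSI curves."""
        from .plotting import plot_genome_scan

        return plot_genome_scan(self.mappings[population_id], path=path, chrom=chrom)

    def save(self, outdir, plots: bool = True) -> None:
        """Write the fixed output bundle: filter report, per-population
        variant/curve/candidate tables, candidate-region BED (0-based
        half-open), filtered VCF and plots."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.filter_report.to_csv(outdir / "filter_report.tsv", sep="\t", index=False)
        pops = {p.population_id: p for p in self.model.populations}
        for pid, m in self.mappings.items():
            m2io.write_variant_table(m.frame, outdir / f"variants_{pid}.tsv")
            curves_to_frame(m.curves).to_csv(
                outdir / f"curves_{pid}.tsv", sep="\t", index=False, float_format="%.6g"
            )
            with open(outdir / f"region_{pid}.bed", "w") as fh:
                for rank, r in enumerate(m.regions):
                    # BED is 0-based half-open; internal coordinates are 1-based VCF
                    fh.write(
                        f"{r.chrom}\t{r.start_bp - 1}\t{r.end_bp}\t"
                        f"region_rank{rank + 1}\t{r.peak_value:.4f}\n"
                    )
            candidates_to_frame(m.candidates).to_csv(
                outdir / f"candidates_{pid}.tsv", sep="\t", index=False,
                float_format="%.6g",
            )
            m2io.write_vcf(
                pops[pid], outdir / f"filtered_{pid}.vcf", statuses=m.frame["status"]
            )
            if plots:
                self.plot(pid, path=outdir / f"scan_{pid}.png")
        config = {
            "min_depth": self.model.min_depth,
            "hi": self.model.hi,
            "lo": self.model.lo,
            "window_n": self.model.window_n,
            "zero_centering": self.model.zero_centering,
            "region_fraction": self.model.region_fraction,
            "adsi_screen": self.model.adsi_screen,
        }
        (outdir / "run_config.json").write_text(json.dumps(config, indent=2) + "\n")
        (outdir / "summary.txt").write_text(self.summary() + "\n")
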
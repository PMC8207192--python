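"""Segregation-ratio tests for the number of initial mutagenic cells.

A recessive mutation induced in a single cell of the seed embryo segregates
3:1 (wild type : mutant) in the selfed M2.  When the M1 seed derives from k
independently mutagenized initial cells — a chimera — only one cell lineage
carries the causal mutation and the expected ratio inflates to (4k-1):1
(7:1 for two cells, 11:1 for three).  Observed counts are tested against
each model with an uncorrected Pearson chi-square on the two phenotype
classes (df = 1); the best model is the one with the largest p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import pandas as pd
from scipy.stats import chi2

DEFAULT_K_MAX = 3
NO_FIT_ALPHA = 0.05


def expected_ratio(k: int) -> Fraction:
    """Expected wild-type : mutant ratio under k initial cells: (4k-1):1."""
    if k < 1:
        raise ValueError(f"number of initial cells must be >= 1, got {k}")
    return Fraction(4 * k - 1, 1)


def chisq_segregation(n_mutant: int, n_wildtype: int, k: int) -> tuple[float, float]:
    """Pearson chi-square of observed counts against the (4k-1):1 model.

    Expected counts are total/(4k) mutants and total*(4k-1)/(4k) wild types;
    df = 1, no continuity correction, upper-tail p.
    """
    if k < 1:
        raise ValueError(f"number of initial cells must be >= 1, got {k}")
    if n_mutant < 0 or n_wildtype < 0:
        raise ValueError("counts must be non-negative")
    total = n_mutant + n_wildtype
    if total == 0:
        raise ValueError("chi-square undefined for zero total count")
    exp_mut = total / (4 * k)
    exp_wt = total * (4 * k - 1) / (4 * k)
    stat = (n_mutant - exp_mut) ** 2 / exp_mut + (n_wildtype - exp_wt) ** 2 / exp_wt
    return float(stat), float(chi2.sf(stat, df=1))


@dataclass(frozen=True)
class SegregationReport:
    """Per-model chi-square results for one population's phenotype counts."""

    population_id: str
    n_mutant: int
    n_wildtype: int
    observed_ratio: float  # wild type : mutant
    models: dict  # k -> {"expected_ratio": float, "chi2": float, "p": float}
    best_k: int
    fits: bool  # best p > 0.05

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, m in sorted(self.models.items()):
            rows.append(
                {
                    "population_id": self.population_id,
                    "k": k,
                    "expected_ratio": m["expected_ratio"],
                    "chi2": m["chi2"],
                    "p": m["p"],
                    "best": k == self.best_k,
                }
            )
        return pd.DataFrame(rows)


def select_model(
    n_mutant: int,
    n_wildtype: int,
    k_max: int = DEFAULT_K_MAX,
    population_id: str = "",
) -> SegregationReport:
    """Test all k <= k_max and pick the model with maximal p-value.

    Ties break toward smaller k (parsimony).  ``fits`` is False when even
    the best model has p <= 0.05.
    """
    if n_mutant <= 0 or n_wildtype <= 0:
        raise ValueError("both phenotype counts must be positive")
    models = {}
    for k in range(1, k_max + 1):
        stat, p = chisq_segregation(n_mutant, n_wildtype, k)
        models[k] = {"expected_ratio": float(expected_ratio(k)), "chi2": stat, "p": p}
    best_k = max(models, key=lambda k: (models[k]["p"], -k))
    return SegregationReport(
        population_id=population_id,
        n_mutant=n_mutant,
        n_wildtype=n_wildtype,
        observed_ratio=n_wildtype / n_mutant,
        models=models,
        best_k=best_k,
        fits=models[best_k]["p"] > NO_FIT_ALPHA,
    )


class SegregationTest:
    """Model object for phenotype-count segregation analysis.

    Examples
    --------
    >>> res = SegregationTest(n_mutant=16, n_wildtype=69).fit()
    >>> res.best_k
    1
    """

    def __init__(self, n_mutant: int, n_wildtype: int, population_id: str = ""):
        self.n_mutant = int(n_mutant)
        self.n_wildtype = int(n_wildtype)
        self.population_id = population_id

    @classmethod
    def from_counts_frame(cls, frame: pd.DataFrame) -> list["SegregationTest"]:
        """One test per row of a counts table (population_id, n_mutant, n_wildtype)."""
        return [
            cls(int(r.n_mutant), int(r.n_wildtype), str(r.population_id))
            for r in frame.itertuples(index=False)
        ]

    def fit(self, k_max: int = DEFAULT_K_MAX) -> "SegregationResults":
        report = select_model(
            self.n_mutant, self.n_wildtype, k_max, population_id=self.population_id
        )
        return SegregationResults(report)


class SegregationResults:
    """Fitted segregation-model results with a Table-style summary."""

    def __init__(self, report: SegregationReport):
        self.report = report

    @property
    def best_k(self) -> int:
        return self.report.best_k

    @property
    def observed_ratio(self) -> float:
        return self.report.observed_ratio

    def pvalue(self, k: int) -> float:
        return self.report.models[k]["p"]

    def summary(self) -> str:
        r = self.report
        lines = [
            f"Segregation test{' — ' + r.population_id if r.population_id else ''}",
            f"  mutant: {r.n_mutant}   wild type: {r.n_wildtype}   "
            f"observed ratio {r.observed_ratio:.2f}:1",
            "  k  expected   chi2      p",
        ]
        for k, m in sorted(r.models.items()):
            star = " <- best" if k == r.best_k else ""
            lines.append(
                f"  {k}  {m['expected_ratio']:.0f}:1      {m['chi2']:<8.4g}  {m['p']:.3g}{star}"
            )
        if not r.fits:
            lines.append("  no model fits (best p <= 0.05)")
        return "\n".join(lines)


def batch_report(frame: pd.DataFrame, k_max: int = DEFAULT_K_MAX) -> pd.DataFrame:
    """Table-style report for a counts frame: one row per population with
    per-model p-values and the selected best model."""
    rows = []
    for test in SegregationTest.from_counts_frame(frame):
        res = test.fit(k_max)
        row = {
            "population_id": test.population_id,
            "n_mutant": test.n_mutant,
            "n_wildtype": test.n_wildtype,
            "observed_ratio": round(res.observed_ratio, 2),
        }
        for k in range(1, k_max + 1):
            row[f"p_k{k}"] = res.pvalue(k)
        row["best_k"] = res.best_k
        rows.append(row)
    return pd.DataFrame(rows)
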
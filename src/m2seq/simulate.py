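"""Forward simulation of EMS-mutagenized M1 -> M2 populations and bulk reads.

The generator emulates the study design end to end and provides ground
truth for every other module:

* a progenitor line carrying homozygous background variants relative to the
  reference (shared across populations, plus a private set per population);
* per population, one or more independently mutagenized initial cells, each
  with a Poisson number of EMS variants (~ems_rate_per_mb per Mb) placed
  uniformly over the genome, heterozygous in M1 with the mutant allele
  assigned to a random homolog; one variant of the first cell is the causal
  recessive mutation;
* selfing with recombination (Haldane model, crossovers as a Poisson
  process at a uniform cM/Mb rate, no interference) to produce M2 progeny
  genotypes; phenotype is mutant iff homozygous for the causal allele;
* bulks of ``bulk_size`` mutant and wild-type progenies; per site, read
  depth ~ Poisson(depth_mean) per bulk and alt reads ~ Binomial(depth,
  bulk allele frequency), with an optional sequencing-error rate;
* optional chimeric contamination: a fixed fraction of the wild-type bulk
  replaced by progenies of a noncausal initial cell (carrying that cell's
  EMS variants and none of the causal cell's).

The simulation starts at allele-depth level: no reads, no aligner.  A fixed
seed fully determines every output, including exported VCF bytes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .variants import BulkPairDataset, VariantKey

CHIMERA_GRID = tuple(round(0.1 * i, 1) for i in range(10))

# functional-class mixes for planted annotations (coding fraction of a plant
# genome is small; most EMS hits land outside genes)
_SNV_CLASSES = ("intergenic", "missense", "synonymous", "nonsense", "splice", "other")
_SNV_CLASS_P = (0.70, 0.15, 0.09, 0.03, 0.01, 0.02)
_INDEL_CLASSES = ("intergenic", "frameshift", "other")
_INDEL_CLASS_P = (0.72, 0.23, 0.05)

_NONCANONICAL_PAIRS = [
    (r, a)
    for r in "ACGT"
    for a in "ACGT"
    if r != a and (r, a) not in {("C", "T"), ("G", "A")}
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of a simulated M2-seq experiment.

    Defaults follow the soybean-scale design: a ~1 Gb genome (20 x 50 Mb),
    5 EMS mutations/Mb of which 61.4% are canonical C>T / G>A, bulks of 15
    progenies sequenced at ~35x, and a shared homozygous background two
    orders of magnitude denser than the mutagenic signal.
    """

    seed: int = 0
    n_chromosomes: int = 20
    chrom_length_bp: int = 50_000_000
    ems_rate_per_mb: float = 5.0
    canonical_fraction: float = 0.614
    ems_indel_fraction: float = 0.011
    background_shared_per_mb: float = 200.0
    background_private_per_mb: float = 5.0
    n_populations: int = 3
    n_initial_cells: int = 1
    causal_chrom: Optional[str] = None
    causal_pos: Optional[int] = None
    bulk_size: int = 15
    depth_mean: float = 35.0
    recomb_rate_cm_per_mb: float = 2.5
    chimera_fraction: float = 0.0
    seq_error_rate: float = 0.0
    mutant_survival: float = 1.0
    repulsion_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.chrom_length_bp < 1:
            raise ValueError("genome dimensions must be positive")
        for name in ("ems_rate_per_mb", "background_shared_per_mb",
                     "background_private_per_mb", "recomb_rate_cm_per_mb",
                     "depth_mean", "seq_error_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.chimera_fraction <= 0.9:
            raise ValueError("chimera_fraction must be in [0, 0.9]")
        if not 0.0 <= self.canonical_fraction <= 1.0:
            raise ValueError("canonical_fraction must be in [0, 1]")
        if not 0.0 < self.mutant_survival <= 1.0:
            raise ValueError("mutant_survival must be in (0, 1]")
        if self.n_initial_cells < 1:
            raise ValueError("n_initial_cells must be >= 1")
        if self.bulk_size < 1:
            raise ValueError("bulk_size must be >= 1")
        rf = self.repulsion_fraction
        if rf is not None and not 0.0 <= rf <= 1.0:
            raise ValueError("repulsion_fraction must be in [0, 1]")

    @property
    def chrom_names(self) -> list[str]:
        return [f"Chr{i + 1:02d}" for i in range(self.n_chromosomes)]

    @property
    def genome_mb(self) -> float:
        return self.n_chromosomes * self.chrom_length_bp / 1e6

    @property
    def contigs(self) -> dict[str, int]:
        return {c: self.chrom_length_bp for c in self.chrom_names}

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class CellGenome:
    """EMS variant set of one initial mutagenic cell (heterozygous in M1).

    ``frame`` columns: chrom, pos, ref, alt, vclass, homolog (0/1), gene_id,
    functional_class; sorted by (chrom, pos).  ``causal_index`` is the row
    of the causal variant (first cell only); the causal allele always sits
    on homolog 0, so same-chromosome variants on homolog 0 are in coupling
    phase and those on homolog 1 in repulsion.
    """

    frame: pd.DataFrame
    causal_index: Optional[int] = None


@dataclass
class M1Genome:
    population_id: str
    cells: list[CellGenome]
    causal: VariantKey


@dataclass
class M2Population:
    """Selfed progenies of one M1 plant (possibly chimeric seed pool)."""

    m1: M1Genome
    origin: np.ndarray  # cell index per progeny
    dosages: list[np.ndarray]  # per cell: (n_progeny_of_cell, n_sites) dosage
    member_of_cell: list[np.ndarray]  # per cell: progeny indices (into origin)
    phenotype: np.ndarray  # "mutant" / "wildtype" per progeny

    @property
    def n_progeny(self) -> int:
        return len(self.origin)


@dataclass
class GroundTruth:
    """Planted truth for one simulated population.

    ``truth`` has one row per emitted variant: chrom, pos, ref, alt, origin
    (ems_cell<c> / background_shared / background_private), homolog, phase
    (coupling/repulsion relative to the causal homolog for same-chromosome
    EMS variants, unlinked otherwise), is_causal, exp_freq_mut, exp_freq_wt
    (bulk allele frequencies before read sampling).
    """

    population_id: str
    causal: VariantKey
    truth: pd.DataFrame

    @property
    def ems(self) -> pd.DataFrame:
        return self.truth[self.truth["origin"].str.startswith("ems_")]

    @property
    def background(self) -> pd.DataFrame:
        return self.truth[self.truth["origin"].str.startswith("background")]

    def to_json_dict(self) -> dict:
        return {
            "population_id": self.population_id,
            "causal": dict(self.causal._asdict()),
            "n_ems": int(len(self.ems)),
            "n_background": int(len(self.background)),
        }


def _unique_positions(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    pos = np.unique(rng.integers(1, length + 1, size=n))
    return pos


def _draw_alleles(rng: np.random.Generator, n_snv: int, canonical_fraction: float):
    canonical = rng.random(n_snv) < canonical_fraction
    refs = np.empty(n_snv, dtype=object)
    alts = np.empty(n_snv, dtype=object)
    pick_ct = rng.random(n_snv) < 0.5
    refs[canonical & pick_ct] = "C"
    alts[canonical & pick_ct] = "T"
    refs[canonical & ~pick_ct] = "G"
    alts[canonical & ~pick_ct] = "A"
    idx = rng.integers(0, len(_NONCANONICAL_PAIRS), size=n_snv)
    non = ~canonical
    refs[non] = [_NONCANONICAL_PAIRS[i][0] for i in idx[non]]
    alts[non] = [_NONCANONICAL_PAIRS[i][1] for i in idx[non]]
    return refs, alts


def _draw_classes(rng, vclass: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = len(vclass)
    fc = np.empty(n, dtype=object)
    snv = vclass == "SNV"
    fc[snv] = rng.choice(_SNV_CLASSES, size=int(snv.sum()), p=_SNV_CLASS_P)
    fc[~snv] = rng.choice(_INDEL_CLASSES, size=int((~snv).sum()), p=_INDEL_CLASS_P)
    gene = np.where(
        fc == "intergenic",
        None,
        np.array([f"Gene{int(i):06d}" for i in rng.integers(0, 60000, size=n)], dtype=object),
    )
    return gene, fc


def _draw_variant_frame(
    rng: np.random.Generator,
    config: SimConfig,
    rate_per_mb: float,
    homozygous_background: bool,
) -> pd.DataFrame:
    """Uniformly placed variants at the given density, sorted by (chrom, pos)."""
    total = rng.poisson(rate_per_mb * config.genome_mb)
    counts = rng.multinomial(total, np.full(config.n_chromosomes, 1.0 / config.n_chromosomes))
    chroms, positions = [], []
    for name, n in zip(config.chrom_names, counts):
        pos = _unique_positions(rng, int(n), config.chrom_length_bp)
        chroms.extend([name] * len(pos))
        positions.append(pos)
    pos = np.concatenate(positions) if positions else np.array([], dtype=np.int64)
    n = len(pos)
    if homozygous_background:
        vclass = np.full(n, "SNV", dtype=object)
        refs, alts = _draw_alleles(rng, n, 0.0)  # background is not EMS-shaped
        gene = np.full(n, None, dtype=object)
        fc = np.full(n, None, dtype=object)
    else:
        is_indel = rng.random(n) < config.ems_indel_fraction
        vclass = np.where(is_indel, "INDEL", "SNV").astype(object)
        refs, alts = _draw_alleles(rng, n, config.canonical_fraction)
        # 1-bp deletions: REF anchors the deleted base, VCF-style
        bases = "ACGT"
        for i in np.nonzero(is_indel)[0]:
            anchor = bases[rng.integers(0, 4)]
            refs[i] = anchor + bases[rng.integers(0, 4)]
            alts[i] = anchor
        gene, fc = _draw_classes(rng, vclass)
    frame = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": pos.astype(np.int64),
            "ref": refs,
            "alt": alts,
            "vclass": vclass,
            "gene_id": gene,
            "functional_class": fc,
        }
    )
    return frame.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def _assign_homologs(
    rng: np.random.Generator,
    frame: pd.DataFrame,
    causal_chrom: Optional[str],
    repulsion_fraction: Optional[float],
) -> np.ndarray:
    homolog = rng.integers(0, 2, size=len(frame))
    if repulsion_fraction is not None and causal_chrom is not None:
        linked = (frame["chrom"] == causal_chrom).to_numpy()
        forced = rng.random(len(frame)) < repulsion_fraction
        homolog = np.where(linked, np.where(forced, 1, 0), homolog)
    return homolog.astype(np.int8)


def simulate_m1(
    config: SimConfig,
    population_id: str = "Mut01",
    rng: Optional[np.random.Generator] = None,
) -> M1Genome:
    """Simulate the M1 genome of one population.

    Cell 0 carries the causal variant (forced protein-changing, on homolog
    0).  Extra cells (k > 1, plus one noncausal cell when chimeric
    contamination is requested) carry independent EMS sets.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n_cells = config.n_initial_cells
    if config.chimera_fraction > 0 and n_cells == 1:
        n_cells = 2  # a noncausal cell to draw contaminating progenies from
    cells = []
    causal_key = None
    for c in range(n_cells):
        frame = _draw_variant_frame(rng, config, config.ems_rate_per_mb, False)
        if c == 0:
            if len(frame) == 0:
                raise ValueError("no EMS variants simulated; raise ems_rate_per_mb")
            if config.causal_chrom is not None:
                chrom = config.causal_chrom
                pos = config.causal_pos or config.chrom_length_bp // 2
                causal_row = pd.DataFrame(
                    {
                        "chrom": [chrom], "pos": [np.int64(pos)],
                        "ref": ["C"], "alt": ["T"], "vclass": ["SNV"],
                        "gene_id": ["Gene999999"], "functional_class": ["missense"],
                    }
                )
                frame = (
                    pd.concat([frame[~((frame["chrom"] == chrom) & (frame["pos"] == pos))],
                               causal_row])
                    .sort_values(["chrom", "pos"], kind="mergesort")
                    .reset_index(drop=True)
                )
                causal_index = int(
                    frame.index[(frame["chrom"] == chrom) & (frame["pos"] == pos)][0]
                )
            else:
                causal_index = int(rng.integers(0, len(frame)))
                frame.loc[causal_index, "functional_class"] = "missense"
                frame.loc[causal_index, "gene_id"] = "Gene999999"
            homolog = _assign_homologs(
                rng, frame, str(frame["chrom"].iloc[causal_index]), config.repulsion_fraction
            )
            homolog[causal_index] = 0  # causal defines the coupling homolog
            frame["homolog"] = homolog
            causal_key = VariantKey(
                str(frame["chrom"].iloc[causal_index]),
                int(frame["pos"].iloc[causal_index]),
                str(frame["ref"].iloc[causal_index]),
                str(frame["alt"].iloc[causal_index]),
            )
            cells.append(CellGenome(frame=frame, causal_index=causal_index))
        else:
            frame["homolog"] = _assign_homologs(rng, frame, None, None)
            cells.append(CellGenome(frame=frame, causal_index=None))
    return M1Genome(population_id=population_id, cells=cells, causal=causal_key)


def _gamete_haplotypes(
    rng: np.random.Generator,
    pos_by_chrom: list[np.ndarray],
    chrom_length: int,
    rate_per_bp: float,
    n_gametes: int,
) -> np.ndarray:
    """Haplotype indicator (which homolog) per gamete per site.

    Haldane model: crossover count ~ Poisson(rate * L) with breakpoints
    uniform on the chromosome; the homolog indicator alternates at each
    breakpoint starting from a random homolog.
    """
    n_sites = sum(len(p) for p in pos_by_chrom)
    out = np.empty((n_gametes, n_sites), dtype=np.int8)
    lam = rate_per_bp * chrom_length
    for g in range(n_gametes):
        col = 0
        for pos in pos_by_chrom:
            start = rng.integers(0, 2)
            k = rng.poisson(lam)
            if k == 0:
                hap = np.full(len(pos), start, dtype=np.int8)
            else:
                breaks = np.sort(rng.integers(1, chrom_length + 1, size=k))
                hap = ((start + np.searchsorted(breaks, pos)) % 2).astype(np.int8)
            out[g, col: col + len(pos)] = hap
            col += len(pos)
    return out


def simulate_cell_progenies(
    cell: CellGenome, config: SimConfig, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Dosage matrix (n, n_sites) of selfed progenies of one cell's M1."""
    frame = cell.frame
    pos_by_chrom = [
        grp["pos"].to_numpy() for _, grp in frame.groupby("chrom", sort=True)
    ]
    # frame is sorted by (chrom, pos); groupby(sort=True) preserves that order
    homolog = frame["homolog"].to_numpy()
    rate_per_bp = config.recomb_rate_cm_per_mb / 100.0 / 1e6
    haps = _gamete_haplotypes(
        rng, pos_by_chrom, config.chrom_length_bp, rate_per_bp, 2 * n
    )
    alleles = (haps == homolog[None, :]).astype(np.int8)
    return alleles[0::2] + alleles[1::2]


def simulate_m2(
    m1: M1Genome,
    config: SimConfig,
    n_progeny: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> M2Population:
    """Self the M1 plant into an M2 population.

    Seeds derive in equal proportion from each of the k initial cells (the
    extra noncausal chimera cell, when present, contributes no natural
    seeds).  Phenotype is mutant iff the progeny is homozygous for the
    causal allele; mutant zygotes survive with probability
    ``mutant_survival``.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    k = config.n_initial_cells
    if n_progeny is None:
        n_progeny = int(math.ceil(config.bulk_size * 4 * k / config.mutant_survival * 1.7)) + 40
    origin = rng.integers(0, k, size=n_progeny)
    dosages: list[np.ndarray] = []
    member_of_cell: list[np.ndarray] = []
    phenotype = np.full(n_progeny, "wildtype", dtype=object)
    alive = np.ones(n_progeny, dtype=bool)
    for c, cell in enumerate(m1.cells):
        members = np.nonzero(origin == c)[0]
        member_of_cell.append(members)
        if len(members) == 0:
            dosages.append(np.zeros((0, len(cell.frame)), dtype=np.int8))
            continue
        dos = simulate_cell_progenies(cell, config, len(members), rng)
        dosages.append(dos)
        if c == 0 and cell.causal_index is not None:
            mutant = dos[:, cell.causal_index] == 2
            phenotype[members[mutant]] = "mutant"
            if config.mutant_survival < 1.0:
                dead = mutant & (rng.random(len(members)) > config.mutant_survival)
                alive[members[dead]] = False
    keep = np.nonzero(alive)[0]
    remap = -np.ones(n_progeny, dtype=np.int64)
    remap[keep] = np.arange(len(keep))
    return M2Population(
        m1=m1,
        origin=origin[keep],
        dosages=[d[alive[m]] for d, m in zip(dosages, member_of_cell)],
        member_of_cell=[remap[m[alive[m]]] for m in member_of_cell],
        phenotype=phenotype[keep],
    )


def _bulk_freqs_per_cell(
    m2: M2Population, bulk_members: np.ndarray, bulk_size: int
) -> list[np.ndarray]:
    """Per cell, allele frequency of that cell's sites in the bulk."""
    freqs = []
    member_set = {}
    for b in bulk_members:
        member_set[int(b)] = member_set.get(int(b), 0) + 1
    for c, members in enumerate(m2.member_of_cell):
        dos = m2.dosages[c]
        if len(members) == 0:
            freqs.append(np.zeros(dos.shape[1]))
            continue
        weights = np.array([member_set.get(int(p), 0) for p in members], dtype=float)
        freqs.append(weights @ dos / (2.0 * bulk_size))
    return freqs


def make_bulks(
    m2: M2Population,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
    shared_background: Optional[pd.DataFrame] = None,
    private_background: Optional[pd.DataFrame] = None,
) -> tuple[BulkPairDataset, GroundTruth]:
    """Sample the two bulks, draw reads and emit the dataset plus truth.

    The mutant bulk is ``bulk_size`` mutant-phenotype progenies (all from
    the causal cell); the wild-type bulk is ``bulk_size`` wild-type
    progenies from the natural seed pool, with ``round(chimera_fraction *
    bulk_size)`` of them replaced by freshly drawn noncausal-cell progenies
    when chimeric contamination is requested.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    mut_pool = np.nonzero(m2.phenotype == "mutant")[0]
    wt_pool = np.nonzero(m2.phenotype == "wildtype")[0]
    if len(mut_pool) < config.bulk_size:
        raise ValueError(
            f"only {len(mut_pool)} mutant progenies for a bulk of {config.bulk_size}; "
            "simulate a larger M2 population"
        )
    if len(wt_pool) < config.bulk_size:
        raise ValueError(
            f"only {len(wt_pool)} wild-type progenies for a bulk of {config.bulk_size}"
        )
    mut_bulk = rng.choice(mut_pool, size=config.bulk_size, replace=False)
    wt_bulk = rng.choice(wt_pool, size=config.bulk_size, replace=False)

    mut_freqs = _bulk_freqs_per_cell(m2, mut_bulk, config.bulk_size)
    n_replace = int(np.rint(config.chimera_fraction * config.bulk_size))
    if n_replace > 0:
        chimera_cell = m2.m1.cells[1]
        kept = wt_bulk[: config.bulk_size - n_replace]
        wt_freqs = _bulk_freqs_per_cell(m2, kept, config.bulk_size)
        extra = simulate_cell_progenies(chimera_cell, config, n_replace, rng)
        wt_freqs[1] = wt_freqs[1] + extra.sum(axis=0) / (2.0 * config.bulk_size)
    else:
        wt_freqs = _bulk_freqs_per_cell(m2, wt_bulk, config.bulk_size)

    # assemble the union variant frame with EMS sites first (priority on
    # position collisions), then private and shared background
    pieces, freq_mut_parts, freq_wt_parts, origins = [], [], [], []
    for c, cell in enumerate(m2.m1.cells):
        frame = cell.frame[["chrom", "pos", "ref", "alt", "vclass", "gene_id",
                            "functional_class"]].copy()
        pieces.append(frame)
        freq_mut_parts.append(mut_freqs[c])
        freq_wt_parts.append(wt_freqs[c])
        origins.append(np.full(len(frame), f"ems_cell{c}", dtype=object))
    for bg, label in ((private_background, "background_private"),
                      (shared_background, "background_shared")):
        if bg is not None and len(bg):
            frame = bg[["chrom", "pos", "ref", "alt", "vclass", "gene_id",
                        "functional_class"]].copy()
            pieces.append(frame)
            freq_mut_parts.append(np.ones(len(frame)))
            freq_wt_parts.append(np.ones(len(frame)))
            origins.append(np.full(len(frame), label, dtype=object))
    union = pd.concat(pieces, ignore_index=True)
    union["exp_freq_mut"] = np.concatenate(freq_mut_parts)
    union["exp_freq_wt"] = np.concatenate(freq_wt_parts)
    union["origin"] = np.concatenate(origins)
    union = union[~union.duplicated(subset=["chrom", "pos"], keep="first")].reset_index(
        drop=True
    )

    # read sampling: depth ~ Poisson, alt ~ Binomial(depth, p) with optional
    # symmetric sequencing error
    e = config.seq_error_rate
    n_sites = len(union)
    p_mut = union["exp_freq_mut"].to_numpy() * (1 - e) + (1 - union["exp_freq_mut"].to_numpy()) * e
    p_wt = union["exp_freq_wt"].to_numpy() * (1 - e) + (1 - union["exp_freq_wt"].to_numpy()) * e
    mut_depth = rng.poisson(config.depth_mean, size=n_sites)
    wt_depth = rng.poisson(config.depth_mean, size=n_sites)
    mut_alt = rng.binomial(mut_depth, p_mut)
    wt_alt = rng.binomial(wt_depth, p_wt)

    data = union[["chrom", "pos", "ref", "alt", "vclass", "gene_id", "functional_class"]].copy()
    data["mut_ref_depth"] = mut_depth - mut_alt
    data["mut_alt_depth"] = mut_alt
    data["wt_ref_depth"] = wt_depth - wt_alt
    data["wt_alt_depth"] = wt_alt
    dataset = BulkPairDataset(
        m2.m1.population_id,
        data,
        metadata={
            "mutant_sample": f"{m2.m1.population_id}_mut",
            "wt_sample": f"{m2.m1.population_id}_wt",
            "contigs": config.contigs,
        },
    )

    causal = m2.m1.causal
    truth = union.copy()
    homolog = np.full(len(truth), -1, dtype=np.int8)
    phase = np.full(len(truth), "unlinked", dtype=object)
    for c, cell in enumerate(m2.m1.cells):
        merged = truth.merge(
            cell.frame[["chrom", "pos", "homolog"]], on=["chrom", "pos"], how="left"
        )
        mask = (truth["origin"] == f"ems_cell{c}").to_numpy()
        homolog[mask] = merged["homolog"].to_numpy()[mask]
    cell0 = (truth["origin"] == "ems_cell0").to_numpy()
    on_causal_chrom = (truth["chrom"] == causal.chrom).to_numpy()
    phase[cell0 & on_causal_chrom & (homolog == 0)] = "coupling"
    phase[cell0 & on_causal_chrom & (homolog == 1)] = "repulsion"
    truth["homolog"] = homolog
    truth["phase"] = phase
    truth["is_causal"] = (
        (truth["chrom"] == causal.chrom)
        & (truth["pos"] == causal.pos)
        & (truth["ref"] == causal.ref)
        & (truth["alt"] == causal.alt)
    )
    ground_truth = GroundTruth(
        population_id=m2.m1.population_id, causal=causal, truth=truth
    )
    return dataset, ground_truth


def simulate_populations(
    config: SimConfig,
) -> tuple[list[BulkPairDataset], list[GroundTruth]]:
    """Simulate all populations of the experiment under one seed.

    The shared background is drawn once and reused in every population;
    EMS sets and private background are drawn per population from
    independent child streams of the seed.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_populations + 1)
    bg_rng = np.random.default_rng(children[0])
    shared_bg = (
        _draw_variant_frame(bg_rng, config, config.background_shared_per_mb, True)
        if config.background_shared_per_mb > 0
        else None
    )
    datasets, truths = [], []
    for i in range(config.n_populations):
        rng = np.random.default_rng(children[i + 1])
        pop_id = f"Mut{i + 1:02d}"
        m1 = simulate_m1(config, pop_id, rng)
        m2 = simulate_m2(m1, config, rng=rng)
        private_bg = (
            _draw_variant_frame(rng, config, config.background_private_per_mb, True)
            if config.background_private_per_mb > 0
            else None
        )
        dataset, truth = make_bulks(
            m2, config, rng, shared_background=shared_bg, private_background=private_bg
        )
        datasets.append(dataset)
        truths.append(truth)
    return datasets, truths


def simulate_population(
    config: SimConfig, population_id: str = "Mut01", seed: Optional[int] = None
) -> tuple[BulkPairDataset, GroundTruth]:
    """Single-population convenience wrapper (no shared background reuse)."""
    cfg = config if seed is None else replace(config, seed=seed)
    rng = np.random.default_rng(cfg.seed)
    m1 = simulate_m1(cfg, population_id, rng)
    m2 = simulate_m2(m1, cfg, rng=rng)
    private_bg = (
        _draw_variant_frame(rng, cfg, cfg.background_private_per_mb, True)
        if cfg.background_private_per_mb > 0
        else None
    )
    shared_bg = (
        _draw_variant_frame(rng, cfg, cfg.background_shared_per_mb, True)
        if cfg.background_shared_per_mb > 0
        else None
    )
    return make_bulks(m2, cfg, rng, shared_background=shared_bg,
                      private_background=private_bg)


def recombination_fraction(distance_bp: float, recomb_rate_cm_per_mb: float) -> float:
    """Haldane map function: r = (1 - exp(-2d)) / 2 with d in Morgans."""
    d = distance_bp * recomb_rate_cm_per_mb / 100.0 / 1e6
    return 0.5 * (1.0 - math.exp(-2.0 * d))


def expected_bulk_freqs(r: float, phase: str) -> tuple[float, float]:
    """Expected (mutant-bulk, wild-type-bulk) allele frequency of an EMS
    variant at recombination fraction r from the causal locus.

    Coupling: (1 - r, (1 + r) / 3); repulsion: (r, (2 - r) / 3); the causal
    locus itself is coupling at r = 0, giving (1, 1/3).  Unlinked sites are
    r = 1/2 in either phase, giving (1/2, 1/2).
    """
    if phase == "coupling":
        return 1.0 - r, (1.0 + r) / 3.0
    if phase == "repulsion":
        return r, (2.0 - r) / 3.0
    raise ValueError(f"phase must be 'coupling' or 'repulsion', got {phase!r}")


def chimera_grid_experiment(
    config: SimConfig,
    grid: Sequence[float] = CHIMERA_GRID,
    window_n: Optional[int] = None,
    region_fraction: float = 0.5,
) -> pd.DataFrame:
    """Rerun one population's wild-type bulk at each contamination level.

    The M1 genome and the M2 seed pool are simulated once; per level, the
    requested fraction of the wild-type bulk is replaced by noncausal-cell
    progenies and reads are redrawn.  For every level the scan is run with
    raw DSI, raw ADSI and zero-centered ADSI, and the report records
    whether the mapping succeeded, plus the mean wild-type-bulk SNP index
    of causal-cell variants (which should scale as 1 - n).

    A mapping counts as a success when the causal position falls inside
    the detected region *and* the curve still has a distinct peak: when
    contamination lifts the whole DSI baseline, the half-peak span swells
    to cover essentially every window of its chromosome, so a region
    containing >= 95% of the chromosome's windows is scored as a failure
    to localize.
    """
    from .filtering import MultiPopulationSet, run_filter_pipeline
    from .mapping import (auto_select_window, detect_candidate_region,
                          fit_windows, retained_snvs, zero_center)

    base = replace(config, chimera_fraction=max(config.chimera_fraction, 0.9))
    ss = np.random.SeedSequence(config.seed)
    child = ss.spawn(len(grid) + 1)
    rng = np.random.default_rng(child[0])
    m1 = simulate_m1(base, "MutSim", rng)
    m2 = simulate_m2(m1, base, rng=rng)
    rows = []
    for i, level in enumerate(grid):
        cfg = replace(config, chimera_fraction=float(level))
        level_rng = np.random.default_rng(child[i + 1])
        dataset, truth = make_bulks(m2, cfg, level_rng)
        mps = MultiPopulationSet([dataset])
        frames, _ = run_filter_pipeline(mps)
        frame = frames[dataset.population_id]
        n_ret = len(retained_snvs(frame))
        wn = window_n or auto_select_window(n_ret)
        causal = truth.causal
        cell0 = truth.truth["origin"] == "ems_cell0"
        keyed = frame.merge(
            truth.truth.loc[cell0, ["chrom", "pos"]], on=["chrom", "pos"], how="inner"
        )
        mean_wt_index = float(keyed["snp_index_wt"].mean())

        def _hit(fr, statistic):
            curves = fit_windows(fr, wn)
            region = detect_candidate_region(curves, statistic, region_fraction)[0]
            chrom_windows = next(len(c) for c in curves if c.chrom == region.chrom)
            localized = region.n_windows < 0.95 * chrom_windows
            return bool(
                localized
                and region.chrom == causal.chrom
                and region.start_bp <= causal.pos <= region.end_bp
            )

        centered, genome_mean = zero_center(frame)
        rows.append(
            {
                "chimera_fraction": float(level),
                "genome_mean_dsi": float(retained_snvs(frame)["dsi"].mean()),
                "mean_wt_index_causal_cell": mean_wt_index,
                "n_retained_snvs": n_ret,
                "dsi_hit": _hit(frame, "dsi"),
                "adsi_raw_hit": _hit(frame, "adsi"),
                "adsi_centered_hit": _hit(centered, "adsi"),
            }
        )
    return pd.DataFrame(rows)
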
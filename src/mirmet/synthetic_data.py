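"""Seeded synthetic inputs with known ground truth.

Everything downstream of raw data — QC gating, counting, differential
expression, background correction, cell-type analysis, enrichment scoring and
qPCR statistics — is exercised against data produced here, so every generator
is a pure function of its arguments including the seed, and each one emits a
truth record sufficient for recovery testing.

The count model mirrors the assumptions of the analysis: bulk tissue profiles
are mixtures of cell-type expression programs (drawn per-sample from a
Dirichlet, so within-tissue heterogeneity exists), metastasis and
normal-background effects are planted as log2 multipliers, library sizes vary
per sample, and counts are negative binomial with variance mu + alpha*mu^2
(alpha = 0 degenerates to Poisson).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    ALPHABET,
    CountMatrix,
    MiRNAReference,
    ReadRecord,
    SITE_NORMAL,
    SyntheticTruth,
)

__all__ = [
    "MiRNAReference",
    "SyntheticTruth",
    "SimulationDesign",
    "generate_reference",
    "simulate_counts",
    "simulate_reads",
    "simulate_interactions_and_sets",
    "simulate_qpcr",
    "study_design",
    "plant_abundance",
    "background_validation_design",
    "write_fastq",
    "OTHER_RNA_SEQS",
    "DEFAULT_ADAPTER",
    "READ_CATEGORIES",
]

DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

#: hand-written non-miRNA small-RNA fragments (tRNA/rRNA-styled); used both by
#: the read simulator and as the ``other_rna`` reference class during QC.
OTHER_RNA_SEQS = (
    "GCATTGGTGGTTCAGTGGTAGAAT",
    "GTTTCCGTAGTGTAGTGGTTATCAC",
    "CGCGACCTCAGATCAGACGTGG",
    "GGCTGGTCCGATGGTAGTGGGTT",
    "TCCCTGGTGGTCTAGTGGTTAGGA",
    "GCCCGGATAGCTCAGTCGGTAGA",
    "TGGGGGCTCGTCCGGGATCGGG",
    "GACGAGGTGGCCGAGTGGTTAAG",
)

READ_CATEGORIES = ("mirna", "low_quality", "short", "low_complexity",
                   "contaminant", "other_rna")

#: cell types used by the default study design
CELL_TYPES = ("epithelial", "hepatocyte", "pneumocyte",
              "lymphocyte", "myeloid", "erythroid")

#: mean cell-type composition per tissue; rows sum to 1.  Liver and lung
#: normals are dominated by their parenchymal cell type; metastases carry an
#: admixture of the host organ, which is exactly what the background filter
#: must correct for.
TISSUE_MIXING = {
    "pCRC": {"epithelial": 0.62, "hepatocyte": 0.03, "pneumocyte": 0.03,
             "lymphocyte": 0.14, "myeloid": 0.08, "erythroid": 0.10},
    "nCR":  {"epithelial": 0.58, "hepatocyte": 0.03, "pneumocyte": 0.03,
             "lymphocyte": 0.16, "myeloid": 0.08, "erythroid": 0.12},
    "mLi":  {"epithelial": 0.48, "hepatocyte": 0.24, "pneumocyte": 0.02,
             "lymphocyte": 0.10, "myeloid": 0.06, "erythroid": 0.10},
    "nLi":  {"epithelial": 0.04, "hepatocyte": 0.68, "pneumocyte": 0.02,
             "lymphocyte": 0.10, "myeloid": 0.06, "erythroid": 0.10},
    "mLu":  {"epithelial": 0.48, "hepatocyte": 0.02, "pneumocyte": 0.24,
             "lymphocyte": 0.10, "myeloid": 0.06, "erythroid": 0.10},
    "nLu":  {"epithelial": 0.04, "hepatocyte": 0.02, "pneumocyte": 0.62,
             "lymphocyte": 0.14, "myeloid": 0.08, "erythroid": 0.10},
    "PM":   {"epithelial": 0.58, "hepatocyte": 0.04, "pneumocyte": 0.04,
             "lymphocyte": 0.12, "myeloid": 0.08, "erythroid": 0.14},
}

#: post-QC dataset counts of the study the defaults emulate
STUDY_GROUP_SIZES = {"pCRC": 120, "nCR": 25, "mLi": 35, "nLi": 20,
                     "mLu": 28, "nLu": 10, "PM": 30}


# ---------------------------------------------------------------------------
# reference sequences


def _seq_distance(a: str, b: str) -> int:
    """5'-aligned Hamming distance over the first 18 bases.

    18 nt is the smallest window the read classifier can compare, so keeping
    references >= 3 apart on that window guarantees a read with up to 2 nt of
    3' truncation/extension and 1 mismatch can never match a second reference.
    """
    n = min(len(a), len(b), 18)
    return sum(x != y for x, y in zip(a[:n], b[:n]))


def generate_reference(
    n_target: int,
    n_contaminant: int = 0,
    seed: int = 0,
    length_range: tuple[int, int] = (20, 24),
    min_distance: int = 3,
    n_near_duplicates: int = 0,
) -> list[MiRNAReference]:
    """Generate synthetic mature miRNA references.

    All pairwise 5'-aligned distances are >= ``min_distance`` (default 3) so
    annotation merging is controllable; ``n_near_duplicates`` appends, for the
    first k target miRNAs, a variant at Hamming distance 1 (id suffix ``-v2``)
    to exercise the merge relation deliberately.
    """
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    if n_contaminant < 0:
        raise ValueError("n_contaminant must be >= 0")
    if n_near_duplicates > n_target:
        raise ValueError("n_near_duplicates exceeds n_target")
    rng = np.random.default_rng(seed)
    seqs: list[str] = []
    guard = list(OTHER_RNA_SEQS)
    while len(seqs) < n_target + n_contaminant:
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        cand = "".join(ALPHABET[i] for i in rng.integers(0, 4, size=length))
        if all(_seq_distance(cand, s) >= min_distance for s in seqs + guard):
            seqs.append(cand)
    refs = [
        MiRNAReference(f"Mir-{i + 1}_5p", seqs[i], "target")
        for i in range(n_target)
    ] + [
        MiRNAReference(f"Xen-Mir-{i + 1}_5p", seqs[n_target + i], "contaminant")
        for i in range(n_contaminant)
    ]
    for k in range(n_near_duplicates):
        base = refs[k]
        pos = int(rng.integers(0, len(base.mature_seq)))
        repl = ALPHABET[(ALPHABET.index(base.mature_seq[pos]) +
                         int(rng.integers(1, 4))) % 4]
        variant = base.mature_seq[:pos] + repl + base.mature_seq[pos + 1:]
        refs.append(MiRNAReference(f"{base.annotation_id}-v2", variant,
                                   base.clade_tag, base.celltype_label))
    return refs


# ---------------------------------------------------------------------------
# count simulation


@dataclass
class SimulationDesign:
    """Everything needed to simulate a count matrix with planted truth.

    celltype_programs: DataFrame (miRNA x cell type) of baseline expression on
    a mean-RPM scale.  mixing_mean maps each tissue to its mean cell-type
    proportions (summing to 1); each sample draws its own proportions from
    Dirichlet(concentration * mean), so tissues are heterogeneous mixtures.
    planted_met_effects apply only at the metastatic site; planted_bg_effects
    apply at the site AND its adjacent normal (the composition artefact the
    background filter must remove).
    """

    tissues: dict[str, int]
    celltype_programs: pd.DataFrame
    mixing_mean: dict[str, dict[str, float]]
    planted_met_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    planted_bg_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    dispersion: pd.Series | float = 0.15
    libsize_range: tuple[float, float] = (1e6, 5e6)
    concentration: float = 50.0
    celltype_labels: dict[str, str] = field(default_factory=dict)
    study: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.tissues:
            raise ValueError("empty tissue list")
        for t, n in self.tissues.items():
            if n < 2:
                raise ValueError(f"group size for {t} must be >= 2, got {n}")
            if t not in self.mixing_mean:
                raise ValueError(f"no mixing proportions for tissue {t}")
            total = sum(self.mixing_mean[t].values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"mixing proportions for {t} sum to {total}")
        if (self.celltype_programs.to_numpy() < 0).any():
            raise ValueError("negative baseline expression")
        disp = self.dispersion_series()
        if (disp < 0).any():
            raise ValueError("negative dispersion")
        for effects in (self.planted_met_effects, self.planted_bg_effects):
            for m in effects:
                if m not in self.celltype_programs.index:
                    raise ValueError(f"planted effect on unknown miRNA {m}")

    def dispersion_series(self) -> pd.Series:
        if np.isscalar(self.dispersion):
            return pd.Series(float(self.dispersion),
                             index=self.celltype_programs.index)
        return self.dispersion.reindex(self.celltype_programs.index)

    @property
    def mirnas(self) -> list[str]:
        return list(self.celltype_programs.index)


def _effect_lfc(design: SimulationDesign, tissue: str) -> np.ndarray:
    """Summed planted log2 effect per miRNA for samples of one tissue."""
    lfc = pd.Series(0.0, index=design.celltype_programs.index)
    for mirna, per_site in design.planted_met_effects.items():
        for site, effect in per_site.items():
            if tissue == site:
                lfc[mirna] += effect
    for mirna, per_site in design.planted_bg_effects.items():
        for site, effect in per_site.items():
            if tissue == site or tissue == SITE_NORMAL.get(site):
                lfc[mirna] += effect
    return lfc.to_numpy()


def simulate_counts(design: SimulationDesign) -> tuple[CountMatrix, SyntheticTruth]:
    """Draw a count matrix under the design and record the planted truth."""
    rng = np.random.default_rng(design.seed)
    programs = design.celltype_programs
    cell_types = list(programs.columns)
    alpha = design.dispersion_series().to_numpy()
    cols: dict[str, np.ndarray] = {}
    meta_rows = []
    for tissue, n in design.tissues.items():
        mean = np.array([design.mixing_mean[tissue][c] for c in cell_types])
        scale = 2.0 ** _effect_lfc(design, tissue)
        for k in range(n):
            sample_id = f"{tissue}_{k + 1:03d}"
            mix = rng.dirichlet(design.concentration * mean)
            expected = programs.to_numpy() @ mix * scale
            total = expected.sum()
            if total <= 0:
                raise ValueError(f"degenerate expression profile for {tissue}")
            libsize = rng.uniform(*design.libsize_range)
            mu = expected / total * libsize
            y = np.empty(len(mu), dtype=np.int64)
            pois = alpha <= 0
            y[pois] = rng.poisson(mu[pois])
            if (~pois).any():
                shape = 1.0 / alpha[~pois]
                lam = rng.gamma(shape, mu[~pois] * alpha[~pois])
                y[~pois] = rng.poisson(lam)
            cols[sample_id] = y
            meta_rows.append((sample_id, tissue, design.study))
    counts = pd.DataFrame(cols, index=programs.index)
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "tissue", "study"]
                        ).set_index("sample_id")
    truth = SyntheticTruth(
        met_de={(m, site, 1 if e > 0 else -1)
                for m, per in design.planted_met_effects.items()
                for site, e in per.items() if e != 0},
        bg_de={(m, site, 1 if e > 0 else -1)
               for m, per in design.planted_bg_effects.items()
               for site, e in per.items() if e != 0},
        celltype_specific=dict(design.celltype_labels),
    )
    return CountMatrix(counts, meta), truth


def study_design(
    seed: int = 0,
    tissues: dict[str, int] | None = None,
    n_mirnas: int = 180,
    n_celltype_specific: int = 30,
    concentration: float = 50.0,
    dispersion: float | pd.Series | None = None,
    libsize_range: tuple[float, float] = (1e6, 5e6),
    planted_met_effects: dict[str, dict[str, float]] | None = None,
    planted_bg_effects: dict[str, dict[str, float]] | None = None,
) -> SimulationDesign:
    """Build a design emulating the study's conditions.

    Defaults: the seven tissues at their post-QC dataset counts, six cell-type
    expression programs with ``n_celltype_specific`` marker miRNAs expressed
    ~300-fold above their level in other cell types, lognormal baseline
    abundances spanning ~4 orders of magnitude, per-miRNA NB dispersions
    centred on 0.15, and library sizes uniform on [1e6, 5e6].
    """
    rng = np.random.default_rng(seed)
    tissues = dict(tissues or STUDY_GROUP_SIZES)
    mirnas = [f"Mir-{i + 1}_5p" for i in range(n_mirnas)]
    base = np.exp(rng.normal(math.log(400.0), 1.6, size=n_mirnas))
    programs = pd.DataFrame(
        np.repeat(base[:, None], len(CELL_TYPES), axis=1),
        index=mirnas, columns=list(CELL_TYPES),
    )
    labels: dict[str, str] = {}
    specific = rng.choice(n_mirnas, size=min(n_celltype_specific, n_mirnas),
                          replace=False)
    for j, idx in enumerate(specific):
        cell = CELL_TYPES[j % len(CELL_TYPES)]
        m = mirnas[idx]
        high = float(np.exp(rng.normal(math.log(3000.0), 0.5)))
        programs.loc[m] = high / 300.0
        programs.loc[m, cell] = high
        labels[m] = cell
    if dispersion is None:
        dispersion = pd.Series(
            np.exp(rng.normal(math.log(0.15), 0.35, size=n_mirnas)),
            index=mirnas)
    return SimulationDesign(
        tissues=tissues,
        celltype_programs=programs,
        mixing_mean={t: dict(TISSUE_MIXING[t]) for t in tissues},
        planted_met_effects=planted_met_effects or {},
        planted_bg_effects=planted_bg_effects or {},
        dispersion=dispersion,
        libsize_range=libsize_range,
        concentration=concentration,
        celltype_labels=labels,
        seed=seed,
    )


def plant_abundance(design: SimulationDesign,
                    target_rpm: dict[str, float]) -> None:
    """Pin selected miRNAs' baseline abundance to target mean RPM (in place).

    Solves the compositional constraint: with the other rows summing to S and
    planted rows at v_k = rpm_k * T / 1e6, the total is
    T = S / (1 - sum(rpm)/1e6).
    """
    prog = design.celltype_programs
    others = prog.index.difference(list(target_rpm))
    S = prog.loc[others].mean(axis=1).sum()
    frac = sum(target_rpm.values()) / 1e6
    if frac >= 1:
        raise ValueError("target RPMs exceed the library")
    T = S / (1.0 - frac)
    for m, rpm_val in target_rpm.items():
        prog.loc[m] = rpm_val * T / 1e6


def background_validation_design(
    seed: int,
    n_per_category: int = 10,
    effect: float = 1.2,
    dispersion: float = 0.08,
) -> tuple[SimulationDesign, list[str]]:
    """Study-scale design for validating the background filter.

    Plants, at liver and lung, ``n_per_category`` metastasis-only,
    background-only and dual (metastasis + background) effects with
    alternating signs, plus peritoneal (PM) effects on six miRNAs already
    backgrounded at one of the organs — which the PM union rule must
    suppress — and ``n_per_category`` PM metastasis-only effects.  Planted
    miRNAs are pinned to physiologically relevant abundances (300-2500 RPM).
    Returns the design and the list of PM-planted, organ-backgrounded miRNAs.
    """
    design = study_design(seed=seed, n_mirnas=220, dispersion=dispersion)
    free = [m for m in design.mirnas if m not in design.celltype_labels]
    met: dict[str, dict[str, float]] = {}
    bg: dict[str, dict[str, float]] = {}
    rpm_targets: dict[str, float] = {}
    rpm_cycle = (300.0, 600.0, 1200.0, 2500.0)
    idx = 0

    def take(n: int) -> list[str]:
        nonlocal idx
        out = free[idx:idx + n]
        idx += n
        return out

    for site in ("mLi", "mLu"):
        for k, m in enumerate(take(n_per_category)):     # metastasis-only
            met.setdefault(m, {})[site] = effect if k % 2 == 0 else -effect
            rpm_targets[m] = rpm_cycle[k % 4]
        for k, m in enumerate(take(n_per_category)):     # background-only
            bg.setdefault(m, {})[site] = effect if k % 2 == 0 else -effect
            rpm_targets[m] = rpm_cycle[k % 4]
        for k, m in enumerate(take(n_per_category)):     # dual
            sign = 1.0 if k % 2 == 0 else -1.0
            met.setdefault(m, {})[site] = sign
            bg.setdefault(m, {})[site] = sign
            rpm_targets[m] = rpm_cycle[k % 4]
    pm_bg_li = [m for m in bg if "mLi" in bg[m] and m not in met][:3]
    pm_bg_lu = [m for m in bg if "mLu" in bg[m] and m not in met][:3]
    for m in pm_bg_li + pm_bg_lu:
        site = "mLi" if m in pm_bg_li else "mLu"
        met.setdefault(m, {})["PM"] = float(np.sign(bg[m][site]))
    for k, m in enumerate(take(n_per_category)):         # PM metastasis-only
        met.setdefault(m, {})["PM"] = effect if k % 2 == 0 else -effect
        rpm_targets[m] = rpm_cycle[k % 4]
    plant_abundance(design, rpm_targets)
    design.planted_met_effects = met
    design.planted_bg_effects = bg
    return design, pm_bg_li + pm_bg_lu


# ---------------------------------------------------------------------------
# read simulation


def _largest_remainder(fractions: dict[str, float], n: int) -> dict[str, int]:
    keys = sorted(fractions)
    raw = {k: fractions[k] * n for k in keys}
    counts = {k: int(math.floor(raw[k])) for k in keys}
    short = n - sum(counts.values())
    by_remainder = sorted(keys, key=lambda k: (-(raw[k] - counts[k]), k))
    for k in by_remainder[:short]:
        counts[k] += 1
    return counts


def _high_qual(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(35, 41, size=length)


def simulate_reads(
    refs: list[MiRNAReference],
    fractions: dict[str, float],
    n_reads: int,
    adapter: str = DEFAULT_ADAPTER,
    seed: int = 0,
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Simulate a small-RNA read population with a per-read truth table.

    Categories and their construction:

    - ``mirna`` / ``contaminant``: a mature sequence from the target /
      contaminant clade, with up to 2 nt of 3' truncation or templated-random
      extension (final insert never < 18 nt), plus the 3' adapter; high
      quality.
    - ``low_quality``: miRNA-like insert but 60% of bases at Phred <= 20.
    - ``short``: 10-17 nt random insert plus adapter.
    - ``low_complexity``: mono-/di-nucleotide tandem repeat insert.
    - ``other_rna``: a fragment from :data:`OTHER_RNA_SEQS` plus adapter.

    Per-category counts follow largest-remainder rounding of fraction*n_reads
    and sum to ``n_reads`` exactly.  Returns the reads (shuffled) and a truth
    DataFrame with columns read_id, category, trimmed_len (the insert length
    an exact adapter trim should recover).
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    unknown = set(fractions) - set(READ_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown read categories: {sorted(unknown)}")
    total = sum(fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"fractions sum to {total}, expected 1")
    rng = np.random.default_rng(seed)
    targets = [r for r in refs if r.clade_tag == "target"]
    contams = [r for r in refs if r.clade_tag == "contaminant"]
    counts = _largest_remainder({k: v for k, v in fractions.items() if v > 0},
                                n_reads)

    def mirna_insert(pool: list[MiRNAReference]) -> str:
        ref = pool[int(rng.integers(len(pool)))]
        delta = int(rng.integers(-2, 3))
        seq = ref.mature_seq
        if delta < 0:
            delta = max(delta, 18 - len(seq))  # keep insert >= 18 nt
            seq = seq[:len(seq) + delta] if delta < 0 else seq
        elif delta > 0:
            seq = seq + "".join(ALPHABET[i]
                                for i in rng.integers(0, 4, size=delta))
        return seq

    entries: list[tuple[str, str, np.ndarray, int]] = []  # cat, seq, qual, trimmed_len
    for cat in sorted(counts):
        for _ in range(counts[cat]):
            if cat in ("mirna", "contaminant"):
                pool = targets if cat == "mirna" else contams
                if not pool:
                    raise ValueError(f"no {cat} references available")
                insert = mirna_insert(pool)
                seq = insert + adapter
                qual = _high_qual(rng, len(seq))
            elif cat == "low_quality":
                pool = targets or contams
                insert = mirna_insert(pool) if pool else "".join(
                    ALPHABET[i] for i in rng.integers(0, 4, size=22))
                seq = insert + adapter
                n_low = int(math.floor(len(seq) * 0.6))
                qual = _high_qual(rng, len(seq))
                low_pos = rng.choice(len(seq), size=n_low, replace=False)
                qual[low_pos] = rng.integers(2, 11, size=n_low)
            elif cat == "short":
                length = int(rng.integers(10, 18))
                insert = "".join(ALPHABET[i]
                                 for i in rng.integers(0, 4, size=length))
                seq = insert + adapter
                qual = _high_qual(rng, len(seq))
            elif cat == "low_complexity":
                motif = "".join(ALPHABET[i] for i in rng.integers(
                    0, 4, size=int(rng.integers(1, 3))))
                if len(set(motif)) == 2 and motif[0] == motif[1]:
                    motif = motif[0]
                length = int(rng.integers(18, 25))
                insert = (motif * length)[:length]
                seq = insert + adapter
                qual = _high_qual(rng, len(seq))
            else:  # other_rna
                insert = OTHER_RNA_SEQS[int(rng.integers(len(OTHER_RNA_SEQS)))]
                seq = insert + adapter
                qual = _high_qual(rng, len(seq))
            entries.append((cat, seq, qual, len(insert)))
    order = rng.permutation(len(entries))
    reads, rows = [], []
    for rank, idx in enumerate(order):
        cat, seq, qual, tlen = entries[idx]
        read_id = f"read_{rank + 1:06d}"
        reads.append(ReadRecord(read_id, seq, qual))
        rows.append((read_id, cat, tlen))
    truth = pd.DataFrame(rows, columns=["read_id", "category", "trimmed_len"])
    return reads, truth


def write_fastq(reads: list[ReadRecord], path: str | Path) -> None:
    """Write 4-line FASTQ records with Phred+33 qualities."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{r.qual_string()}\n")


# ---------------------------------------------------------------------------
# interactions and gene sets


def simulate_interactions_and_sets(
    n_genes: int,
    refs: list[MiRNAReference] | list[str],
    truth: SyntheticTruth,
    seed: int = 0,
    n_sets: int = 50,
    set_size: int = 20,
    base_rate: float = 0.02,
    enrichment: float = 8.0,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Wire a predicted miRNA->mRNA interaction map and gene-set collection.

    Genes in sets listed in ``truth.suppressed_gene_sets`` are targeted by
    up-regulated miRNAs with ``enrichment``-fold higher probability than
    background, so those sets should surface as suppressed downstream; all
    other links are uniform at random.
    """
    if n_genes < 10:
        raise ValueError("n_genes must be >= 10")
    mirnas = [r.annotation_id if isinstance(r, MiRNAReference) else r
              for r in refs]
    up = {m for m, _site, sign in truth.met_de if sign > 0}
    if truth.suppressed_gene_sets and not up:
        raise ValueError(
            "suppressed gene sets planted without any up-regulated miRNA")
    rng = np.random.default_rng(seed)
    genes = [f"g{i + 1:04d}" for i in range(n_genes)]
    set_ids = [f"SET_{i + 1:02d}" for i in range(n_sets)]
    unknown_sets = truth.suppressed_gene_sets - set(set_ids)
    if unknown_sets:
        raise ValueError(f"suppressed sets not among generated ids: "
                         f"{sorted(unknown_sets)}")
    gene_sets = {
        sid: sorted(rng.choice(genes, size=min(set_size, n_genes),
                               replace=False))
        for sid in set_ids
    }
    suppressed_genes = set()
    for sid in truth.suppressed_gene_sets:
        suppressed_genes |= set(gene_sets[sid])
    weight = np.ones(n_genes)
    for i, g in enumerate(genes):
        if g in suppressed_genes:
            weight[i] = enrichment
    pairs = []
    n_targets = max(1, int(round(base_rate * n_genes)))
    for m in mirnas:
        if m in up and suppressed_genes:
            p = weight / weight.sum()
        else:
            p = np.full(n_genes, 1.0 / n_genes)
        chosen = rng.choice(genes, size=n_targets, replace=False, p=p)
        pairs.extend((m, g) for g in sorted(chosen))
    interactions = pd.DataFrame(pairs, columns=["mirna_id", "gene_id"])
    return interactions, gene_sets


# ---------------------------------------------------------------------------
# qPCR


def simulate_qpcr(
    n_per_group: int,
    delta: float,
    sd: float,
    seed: int = 0,
    baseline_target: float = 25.0,
    baseline_reference: float = 20.0,
    sample_sd: float = 0.8,
    replicate_sd: float = 0.15,
) -> pd.DataFrame:
    """Simulate a two-group qPCR Cq table (target + reference assay).

    Each sample gets a global offset (RNA input; cancels in dCq), the target
    assay additionally carries N(0, sd) biological noise plus ``delta`` in the
    case group, and every assay is measured as 2 PCR replicates with
    N(0, replicate_sd) technical noise.  The expected case-minus-control dCq
    difference is exactly ``delta``.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if sd <= 0:
        raise ValueError("sd must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    for group in ("control", "case"):
        shift = delta if group == "case" else 0.0
        for k in range(n_per_group):
            sample_id = f"{group}_{k + 1:02d}"
            offset = rng.normal(0.0, sample_sd)
            ref_true = baseline_reference + offset
            tgt_true = baseline_target + offset + shift + rng.normal(0.0, sd)
            for assay, level in (("target", tgt_true), ("reference", ref_true)):
                for rep in (1, 2):
                    cq = level + rng.normal(0.0, replicate_sd)
                    rows.append((sample_id, group, assay, rep, round(cq, 4)))
    return pd.DataFrame(
        rows, columns=["sample_id", "group", "assay", "replicate", "cq"])
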
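"""Downstream characterization of a counter-receptor set.

Covers: assembly of the total membrane proteome from lysate and
cell-surface identifications, the counter-receptor fraction of it,
histone-ruler copy-number estimation, N-glycosylation sequon scanning and
sequon-per-Ig-domain comparison, mapping counter-receptors onto an
abundance histogram, and summarization of a glycosylation-gene panel from
normalized RNA-Seq counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, ProxiglycError, RulerError
from .tables_io import AnnotationRecord, CCClass, ProteinQuantTable, annotation_by_id

SOURCES = ("LYSATE", "SURFACE")


@dataclass
class MembraneProteome:
    """Membrane proteins with per-replicate identification evidence."""

    protein_ids: set[str]
    provenance: dict[str, list[tuple[str, int]]]  # protein -> [(source, replicate)]

    def __len__(self) -> int:
        return len(self.protein_ids)


def assemble_membrane_proteome(
    identifications: Mapping[tuple[str, int], set[str]],
    ann: Iterable[AnnotationRecord],
    min_replicates: int = 2,
) -> MembraneProteome:
    """Assemble the total membrane proteome.

    *identifications* maps ``(source, replicate)`` — source ``"LYSATE"`` or
    ``"SURFACE"`` — to the identified protein ids.  Evidence from either
    source counts; a protein is kept when seen in at least *min_replicates*
    distinct replicates and is membrane-annotated.
    """
    for source, _ in identifications:
        if source not in SOURCES:
            raise ConfigurationError(f"unknown identification source {source!r}")
    replicates = {rep for _, rep in identifications}
    if min_replicates > len(replicates):
        raise ConfigurationError(
            f"min_replicates={min_replicates} exceeds the {len(replicates)} "
            "available replicates"
        )
    by_id = annotation_by_id(ann)
    provenance: dict[str, list[tuple[str, int]]] = {}
    for (source, rep), ids in sorted(identifications.items()):
        for pid in ids:
            provenance.setdefault(pid, []).append((source, rep))
    kept = {
        pid
        for pid, ev in provenance.items()
        if len({rep for _, rep in ev}) >= min_replicates
        and pid in by_id
        and by_id[pid].cc_class is CCClass.MEMBRANE
    }
    return MembraneProteome(
        protein_ids=kept, provenance={p: provenance[p] for p in kept}
    )


def counter_receptor_fraction(
    cr_set: set[str], proteome: MembraneProteome
) -> float:
    """Percentage of the membrane proteome made up by the counter-receptor
    set, reported to one decimal.  Counter-receptors outside the proteome
    are excluded from the numerator."""
    if not proteome.protein_ids:
        raise ProxiglycError("membrane proteome is empty; fraction undefined")
    return round(100.0 * len(cr_set & proteome.protein_ids) / len(proteome), 1)


@dataclass(frozen=True)
class RulerConfig:
    """Histone-ruler constants.

    The ruler assumes total histone mass per cell approximates DNA mass per
    cell; 5.9 pg is the standard mouse diploid genome mass.
    """

    dna_mass_per_cell_g: float = 5.9e-12
    avogadro: float = 6.02214076e23
    histone_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.dna_mass_per_cell_g <= 0:
            raise ConfigurationError("dna_mass_per_cell_g must be > 0")
        if not self.histone_ids:
            raise ConfigurationError("histone_ids must be non-empty")


@dataclass
class RulerResult:
    copies_per_cell: dict[str, float]
    n_missing_mw: int  # proteins skipped for lack of a molecular weight
    total_histone_intensity: float


def histone_ruler_copies(
    quant: ProteinQuantTable, sample_id: str, cfg: RulerConfig
) -> RulerResult:
    """Per-protein copies per cell by the proteomic (histone) ruler:

    copies_i = (I_i / sum of histone I) x DNA mass per cell x N_A / MW_i

    with MW in g/mol.  Proteins without a molecular weight are skipped and
    counted in ``n_missing_mw``.
    """
    histone_total = 0.0
    n_histones_seen = 0
    for hid in cfg.histone_ids:
        if hid in quant:
            value = quant[hid].intensity_by_sample.get(sample_id)
            if value is not None:
                histone_total += value
                n_histones_seen += 1
    if n_histones_seen == 0 or histone_total <= 0:
        raise RulerError(
            f"no quantified histone signal in sample {sample_id!r}"
        )
    copies: dict[str, float] = {}
    n_missing_mw = 0
    for rec in quant.records:
        intensity = rec.intensity_by_sample.get(sample_id)
        if intensity is None:
            continue
        if rec.molecular_weight_kda is None:
            n_missing_mw += 1
            continue
        mw_g_per_mol = rec.molecular_weight_kda * 1000.0
        copies[rec.protein_id] = (
            (intensity / histone_total)
            * cfg.dna_mass_per_cell_g
            * cfg.avogadro
            / mw_g_per_mol
        )
    return RulerResult(
        copies_per_cell=copies,
        n_missing_mw=n_missing_mw,
        total_histone_intensity=histone_total,
    )


# ---------------------------------------------------------------------------
# sequons

_AMINO = set("ACDEFGHIKLMNPQRSTVWYX")


def find_sequons(sequence: str) -> list[int]:
    """1-based start positions of N-glycosylation sequons N-X-S/T, X != P.

    Overlapping sequons are all reported; sequences shorter than 3 return
    an empty list.
    """
    seq = sequence.upper()
    bad = set(seq) - _AMINO
    if bad:
        raise ProxiglycError(f"non-amino-acid characters {sorted(bad)} in sequence")
    return [
        i + 1
        for i in range(len(seq) - 2)
        if seq[i] == "N" and seq[i + 1] != "P" and seq[i + 2] in ("S", "T")
    ]


def sequons_from_fasta(path) -> dict[str, int]:
    """Sequon counts per record id of a FASTA file."""
    from Bio import SeqIO

    return {
        record.id: len(find_sequons(str(record.seq)))
        for record in SeqIO.parse(str(path), "fasta")
    }


@dataclass(frozen=True)
class SequonDensityRow:
    """Predicted N-glycosylation sites per Ig-like domain for one protein."""

    protein_id: str
    n_sequons: int
    n_ig_domains: int
    group: str  # "COUNTER_RECEPTOR" or "OTHER"

    def __post_init__(self) -> None:
        if self.n_ig_domains < 1:
            raise ConfigurationError(
                f"{self.protein_id}: sequon density needs n_ig_domains >= 1"
            )
        if self.n_sequons < 0:
            raise ConfigurationError(f"{self.protein_id}: negative sequon count")

    @property
    def density(self) -> float:
        return self.n_sequons / self.n_ig_domains


def sequon_density_rows(
    ann: Iterable[AnnotationRecord], cr_set: set[str]
) -> list[SequonDensityRow]:
    """Rows for every Ig-superfamily protein (n_ig_domains >= 1), grouped
    by counter-receptor membership."""
    return [
        SequonDensityRow(
            protein_id=a.protein_id,
            n_sequons=a.n_sequons,
            n_ig_domains=a.n_ig_domains,
            group="COUNTER_RECEPTOR" if a.protein_id in cr_set else "OTHER",
        )
        for a in ann
        if a.n_ig_domains >= 1
    ]


def sequon_density_comparison(rows: Sequence[SequonDensityRow]) -> dict:
    """Per group: size, median density, and counts of proteins with more
    than one vs at most one sequon per Ig-like domain."""
    if not rows:
        raise ProxiglycError("no sequon-density rows")
    summary: dict[str, dict] = {}
    for group in ("COUNTER_RECEPTOR", "OTHER"):
        densities = sorted(r.density for r in rows if r.group == group)
        if not densities:
            summary[group] = {"present": False}
            continue
        summary[group] = {
            "present": True,
            "n": len(densities),
            "median_density": float(np.median(densities)),
            "n_density_gt1": sum(1 for d in densities if d > 1.0),
            "n_density_le1": sum(1 for d in densities if d <= 1.0),
        }
    return summary


# ---------------------------------------------------------------------------
# abundance histogram


@dataclass
class AbundanceHistogram:
    """log10-spaced histogram of abundances above a threshold, with the
    counter-receptors falling in each bin flagged."""

    bin_edges: list[float]  # length n_bins + 1, in abundance units
    counts: list[int]
    cr_by_bin: list[list[str]]
    n_included: int
    n_below_threshold: int


def map_to_abundance(
    cr_set: set[str],
    abundance: Mapping[str, float],
    threshold: float = 100.0,
    n_bins: int = 20,
) -> AbundanceHistogram:
    """Bin proteins with abundance strictly above *threshold* into
    log10-spaced bins and flag each counter-receptor's bin.

    Bins are half-open [lo, hi) except the last, which is closed, so
    membership is exhaustive and disjoint.
    """
    for pid, value in abundance.items():
        if not (value > 0 and math.isfinite(value)):
            raise ProxiglycError(f"{pid}: abundance must be positive, got {value}")
    included = {p: v for p, v in abundance.items() if v > threshold}
    n_below = len(abundance) - len(included)
    if not included:
        return AbundanceHistogram([], [], [], 0, n_below)
    values = np.log10(np.array(list(included.values())))
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        hi = lo + 1e-9  # all equal: a single degenerate bin
    edges = np.linspace(lo, hi, n_bins + 1)
    counts = [0] * n_bins
    cr_by_bin: list[list[str]] = [[] for _ in range(n_bins)]
    for pid in sorted(included):
        idx = int(np.searchsorted(edges, math.log10(included[pid]), side="right")) - 1
        idx = min(max(idx, 0), n_bins - 1)
        counts[idx] += 1
        if pid in cr_set:
            cr_by_bin[idx].append(pid)
    return AbundanceHistogram(
        bin_edges=[10.0**e for e in edges],
        counts=counts,
        cr_by_bin=cr_by_bin,
        n_included=len(included),
        n_below_threshold=n_below,
    )


# ---------------------------------------------------------------------------
# glycogene panel


@dataclass
class PanelReport:
    """Per-gene summary of a glycosylation-gene panel.

    ``table`` columns: mean_rest, mean_activated, log2_fold_change,
    p_value, q_value (BH across the panel only).
    """

    table: pd.DataFrame
    misses: list[str]


def glycogene_panel_report(
    counts_rest: pd.DataFrame,
    counts_activated: pd.DataFrame,
    panel: Sequence[str],
    pseudocount: float = 1.0,
) -> PanelReport:
    """Summarize a normalized-count matrix over a gene panel.

    Each matrix is genes x replicate columns of normalized counts.  Per
    panel gene: condition means, log2((mean_act + c) / (mean_rest + c))
    with pseudocount c, Welch-free two-sample t p value, and BH q across
    the panel.  Panel genes absent from either matrix are listed under
    ``misses`` and not scored.  This is deliberately a plain panel summary,
    not a differential-expression model fit.
    """
    if counts_rest.shape[1] < 2 or counts_activated.shape[1] < 2:
        raise ConfigurationError("need >= 2 replicate columns per condition")
    rows = []
    misses = []
    for gene in panel:
        if gene not in counts_rest.index or gene not in counts_activated.index:
            misses.append(gene)
            continue
        rest = counts_rest.loc[gene].to_numpy(dtype=float)
        act = counts_activated.loc[gene].to_numpy(dtype=float)
        mean_rest = float(rest.mean())
        mean_act = float(act.mean())
        log2fc = math.log2((mean_act + pseudocount) / (mean_rest + pseudocount))
        if np.allclose(rest, rest[0]) and np.allclose(act, act[0]) and mean_rest == mean_act:
            p = 1.0
        else:
            p = float(stats.ttest_ind(act, rest, equal_var=True).pvalue)
            if math.isnan(p):
                p = 1.0
        rows.append((gene, mean_rest, mean_act, log2fc, p))
    table = pd.DataFrame(
        rows,
        columns=["gene", "mean_rest", "mean_activated", "log2_fold_change", "p_value"],
    ).set_index("gene")
    if len(table):
        table["q_value"] = multipletests(table["p_value"].to_numpy(), method="fdr_bh")[1]
    else:
        table["q_value"] = pd.Series(dtype=float)
    return PanelReport(table=table, misses=misses)
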
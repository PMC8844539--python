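"""Four-stage filtration turning per-sample LFQ tables into a
counter-receptor set.

The stages, in order:

1. **Tail assessment / dataset exclusion.**  For each labelling experiment
   (dataset) the per-protein log2 fold change bait/control is computed and
   the dataset is kept only if its membrane proteins show a *proximity
   labelling tail*: an excess of membrane proteins above the upper tail of
   the non-membrane (null) fold-change distribution.  The visual judgement
   is operationalised as: cutoff = ``tail_quantile`` (default 0.99) of the
   measured non-membrane fold changes; the tail is present when at least
   ``k_min`` membrane proteins lie strictly above the cutoff and the
   one-sided hypergeometric enrichment p value is below ``p_tail``.
2. **Volcano selection.**  Across retained datasets, a paired (one-sample)
   t-test on each protein's fold changes; selection of the positive side
   with p < ``alpha`` and mean log2FC > ``min_log2fc``.
3. **Annotation filter.**  Candidates must be plasma-membrane proteins with
   at least one predicted N-glycosylation site.
4. **Back-mapping.**  Each candidate is mapped back onto every retained
   dataset's fold-change histogram and removed if it falls below the base
   of the labelling tail (``backmap_quantile`` of the measured null,
   default 0.85) in any dataset where it was measured.

Missing intensities are imputed at a per-sample noise floor so that
bait-only proteins — the signal the labelling chemistry is designed to
produce — are retained.  Imputed ratios are flagged: they enter the t-test
(they carry the bait-only evidence) but by default neither the null-quantile
calibration nor the back-mapping judgement, because a dropout-imputed ratio
is a bound on the true ratio, not a measurement.
"""

from __future__ import annotations

import math
import sys
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, InsufficientDataError, PipelineError
from .tables_io import (
    AnnotationRecord,
    Bait,
    CCClass,
    ProteinQuantTable,
    SampleDesign,
    annotation_by_id,
    validate_design,
)

# Audit reasons (exactly one per excluded protein)
UNANNOTATED = "UNANNOTATED"
NO_GLYCOSITES = "NO_GLYCOSITES"
NOT_PLASMA_MEMBRANE = "NOT_PLASMA_MEMBRANE"
OUTSIDE_TAIL = "OUTSIDE_TAIL"
NOT_SIGNIFICANT = "NOT_SIGNIFICANT"
TOO_FEW_PAIRS = "TOO_FEW_PAIRS"
NOT_QUANTIFIED = "NOT_QUANTIFIED"


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds of the four filtration stages.

    The source analysis states the stages but leaves most numeric thresholds
    implicit; every surrogate chosen here is exposed and documented in the
    methods note.

    Parameters
    ----------
    noise_floor_percentile:
        Percentile (0-100) of a sample's quantified intensities used as its
        imputation noise floor for MISSING values.
    tail_quantile:
        Quantile of the measured non-membrane fold-change distribution that
        defines the tail-detection cutoff.
    k_min, p_tail:
        A dataset has a labelling tail when >= ``k_min`` membrane proteins
        exceed the cutoff with hypergeometric enrichment p < ``p_tail``.
    alpha, min_log2fc, use_adjusted_p:
        Volcano selection: p (or BH q when ``use_adjusted_p``) < ``alpha``
        and mean log2FC > ``min_log2fc`` (positive side only).
    backmap_quantile:
        Quantile of the measured non-membrane distribution marking the base
        of the labelling tail, used by the back-mapping stage.
    backmap_use_imputed:
        Judge imputed ratios in back-mapping too (default False).
    backmap_require_all_datasets:
        When True, a candidate absent from a retained dataset is removed;
        default judges proteins only on datasets where they were observed.
    """

    noise_floor_percentile: float = 1.0
    tail_quantile: float = 0.99
    k_min: int = 20
    p_tail: float = 0.01
    alpha: float = 0.05
    min_log2fc: float = 1.0
    use_adjusted_p: bool = False
    backmap_quantile: float = 0.85
    backmap_use_imputed: bool = False
    backmap_require_all_datasets: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.tail_quantile < 1.0):
            raise ConfigurationError("tail_quantile must be in (0, 1)")
        if not (0.0 < self.backmap_quantile < 1.0):
            raise ConfigurationError("backmap_quantile must be in (0, 1)")
        if not (0.0 < self.alpha < 1.0 and 0.0 < self.p_tail < 1.0):
            raise ConfigurationError("alpha and p_tail must be in (0, 1)")
        if self.min_log2fc < 0:
            raise ConfigurationError("min_log2fc must be >= 0")
        if not (0.0 <= self.noise_floor_percentile <= 100.0):
            raise ConfigurationError("noise_floor_percentile must be in [0, 100]")


@dataclass
class Log2FcTable:
    """Per (protein, dataset) log2 fold change with imputation flags.

    ``log2fc`` and ``imputed`` are aligned DataFrames indexed by protein id
    with one column per dataset id; NaN means the protein was missing on
    both sides of that dataset (no entry).
    """

    log2fc: pd.DataFrame
    imputed: pd.DataFrame

    def datasets(self) -> list[str]:
        return list(self.log2fc.columns)

    def values_for(self, dataset_id: str, *, include_imputed: bool = True) -> pd.Series:
        col = self.log2fc[dataset_id]
        if not include_imputed:
            col = col[~self.imputed[dataset_id]]
        return col.dropna()


@dataclass(frozen=True)
class TailAssessment:
    """Labelling-tail verdict for one dataset."""

    dataset_id: str
    cutoff: float
    backmap_cutoff: float
    n_above_cutoff_membrane: int
    n_above_cutoff_other: int
    enrichment_p: float
    has_tail: bool


@dataclass(frozen=True)
class VolcanoRow:
    protein_id: str
    mean_log2fc: float
    t_stat: float
    p_value: float
    q_value: float
    n_pairs: int
    degenerate: bool = False


@dataclass
class CounterReceptorReport:
    """Full audit of a pipeline run.

    ``stage_sets`` maps ``"significant"`` / ``"annotated"`` / ``"final"``
    to the nested protein-id sets after stages 2, 3 and 4.  ``audit`` maps
    every quantified protein that did not reach the final set to the single
    (stage, reason) that removed it.
    """

    assessments: list[TailAssessment]
    retained_datasets: list[str]
    volcano: list[VolcanoRow]
    stage_sets: dict[str, set[str]]
    final_set: set[str]
    audit: dict[str, dict[str, str]]
    config: PipelineConfig

    def to_dict(self) -> dict:
        return {
            "config": asdict(self.config),
            "assessments": [asdict(a) for a in self.assessments],
            "retained_datasets": sorted(self.retained_datasets),
            "volcano": [asdict(v) for v in sorted(self.volcano, key=lambda v: v.protein_id)],
            "stage_sets": {k: sorted(v) for k, v in self.stage_sets.items()},
            "final_set": sorted(self.final_set),
            "audit": {k: self.audit[k] for k in sorted(self.audit)},
            "stage_counts": {
                "quantified": len(self.volcano) + sum(
                    1 for v in self.audit.values() if v["reason"] in (TOO_FEW_PAIRS, NOT_QUANTIFIED)
                ),
                "significant": len(self.stage_sets["significant"]),
                "annotated": len(self.stage_sets["annotated"]),
                "final": len(self.final_set),
            },
        }


# ---------------------------------------------------------------------------
# stage 0: fold changes


def compute_log2fc(
    quant: ProteinQuantTable,
    design: Sequence[SampleDesign],
    cfg: PipelineConfig = PipelineConfig(),
) -> Log2FcTable:
    """log2(bait / control) per protein per dataset after noise-floor
    imputation of MISSING values.

    The noise floor is the ``cfg.noise_floor_percentile`` percentile of the
    quantified intensities of the sample in question.  A protein missing on
    both sides of a dataset gets no entry (NaN); an entry computed with one
    imputed side is flagged in ``imputed``.
    """
    validate_design(design)
    pairs: dict[str, dict[Bait, str]] = {}
    for s in design:
        pairs.setdefault(s.dataset_id, {})[s.bait] = s.sample_id
    for ds_id, sides in pairs.items():
        for bait in (Bait.ACTIVE_SN, Bait.CONTROL_R97A):
            if bait not in sides:
                raise ConfigurationError(f"dataset {ds_id!r} lacks its {bait.value} sample")
            if sides[bait] not in set(quant.sample_ids):
                raise ConfigurationError(
                    f"dataset {ds_id!r}: sample {sides[bait]!r} absent from quant table"
                )

    proteins = quant.protein_ids()
    floors: dict[str, float] = {}
    for sid in quant.sample_ids:
        vals = [
            rec.intensity_by_sample[sid]
            for rec in quant.records
            if rec.intensity_by_sample.get(sid) is not None
        ]
        if vals:
            floors[sid] = float(np.percentile(vals, cfg.noise_floor_percentile))
        else:
            floors[sid] = math.nan

    ds_ids = sorted(pairs)
    fc = np.full((len(proteins), len(ds_ids)), np.nan)
    imp = np.zeros_like(fc, dtype=bool)
    for j, ds_id in enumerate(ds_ids):
        bait_sid = pairs[ds_id][Bait.ACTIVE_SN]
        ctrl_sid = pairs[ds_id][Bait.CONTROL_R97A]
        for i, rec in enumerate(quant.records):
            b = rec.intensity_by_sample.get(bait_sid)
            c = rec.intensity_by_sample.get(ctrl_sid)
            if b is None and c is None:
                continue
            was_imputed = b is None or c is None
            b = floors[bait_sid] if b is None else b
            c = floors[ctrl_sid] if c is None else c
            if not (b > 0 and c > 0):
                continue  # floor undefined or zero intensity with imputation off
            fc[i, j] = math.log2(b / c)
            imp[i, j] = was_imputed
    index = pd.Index(proteins, name="protein_id")
    return Log2FcTable(
        log2fc=pd.DataFrame(fc, index=index, columns=ds_ids),
        imputed=pd.DataFrame(imp, index=index, columns=ds_ids),
    )


# ---------------------------------------------------------------------------
# stage 1: labelling-tail assessment


def assess_tail(
    fc: Log2FcTable,
    ann: Iterable[AnnotationRecord],
    dataset_id: str,
    cfg: PipelineConfig = PipelineConfig(),
    *,
    min_proteins: int = 50,
) -> TailAssessment:
    """Decide whether *dataset_id* shows a proximity labelling tail.

    The cutoff is the ``tail_quantile`` of the measured (non-imputed)
    non-membrane fold changes; proteins strictly above it are counted per
    class and membrane enrichment among them is scored with a one-sided
    hypergeometric test.  ``backmap_cutoff`` (the ``backmap_quantile`` of
    the same null) is recorded for stage 4.
    """
    by_id = annotation_by_id(ann)
    col = fc.log2fc[dataset_id].dropna()
    if len(col) < min_proteins:
        raise InsufficientDataError(
            f"dataset {dataset_id!r}: only {len(col)} proteins with a fold "
            f"change (need >= {min_proteins})"
        )
    is_membrane = pd.Series(
        {
            pid: (pid in by_id and by_id[pid].cc_class is CCClass.MEMBRANE)
            for pid in col.index
        }
    )
    measured = ~fc.imputed[dataset_id].reindex(col.index, fill_value=False)
    null_values = col[~is_membrane & measured]
    if null_values.empty:
        # fall back to all non-membrane entries rather than failing outright
        null_values = col[~is_membrane]
    if null_values.empty:
        raise InsufficientDataError(
            f"dataset {dataset_id!r}: no non-membrane proteins to calibrate on"
        )
    cutoff = float(np.quantile(null_values.to_numpy(), cfg.tail_quantile))
    backmap_cutoff = float(np.quantile(null_values.to_numpy(), cfg.backmap_quantile))

    above = col > cutoff  # strictly greater: ties stay below the tail
    k_membrane = int((above & is_membrane).sum())
    k_other = int((above & ~is_membrane).sum())
    n_total = int(len(col))
    n_membrane = int(is_membrane.sum())
    n_above = k_membrane + k_other
    if n_above == 0:
        enrichment_p = 1.0
    else:
        # P(X >= k_membrane), X ~ Hypergeom(N=n_total, K=n_membrane, n=n_above)
        enrichment_p = float(stats.hypergeom.sf(k_membrane - 1, n_total, n_membrane, n_above))
    has_tail = (k_membrane >= cfg.k_min) and (enrichment_p < cfg.p_tail)
    return TailAssessment(
        dataset_id=dataset_id,
        cutoff=cutoff,
        backmap_cutoff=backmap_cutoff,
        n_above_cutoff_membrane=k_membrane,
        n_above_cutoff_other=k_other,
        enrichment_p=enrichment_p,
        has_tail=has_tail,
    )


# ---------------------------------------------------------------------------
# stage 2: paired-t volcano

_SMALLEST_P = sys.float_info.min * sys.float_info.epsilon  # smallest positive subnormal


def paired_t_volcano(
    fc: Log2FcTable,
    retained: Sequence[str],
    cfg: PipelineConfig = PipelineConfig(),
) -> list[VolcanoRow]:
    """One-sample t-test of each protein's fold changes across retained
    datasets (equivalent to a paired t-test on log2 bait vs control), with
    Benjamini-Hochberg q values over all tested proteins.

    Proteins observed in fewer than two retained datasets are skipped.
    Zero-variance vectors: p is set to the smallest positive float and the
    row flagged degenerate when the mean is nonzero, and to (t=0, p=1)
    when the mean is zero too.
    """
    if len(retained) < 2:
        raise PipelineError("need at least 2 retained datasets for the paired t-test")
    sub = fc.log2fc[list(retained)]
    rows: list[tuple[str, float, float, float, int, bool]] = []
    for pid, series in sub.iterrows():
        x = series.dropna().to_numpy()
        n = len(x)
        if n < 2:
            continue
        mean = float(np.mean(x))
        sd = float(np.std(x, ddof=1))
        degenerate = False
        if sd == 0.0:
            if mean == 0.0:
                t_stat, p = 0.0, 1.0
            else:
                t_stat = math.inf if mean > 0 else -math.inf
                p = _SMALLEST_P
                degenerate = True
        else:
            t_stat = mean / (sd / math.sqrt(n))
            p = 2.0 * float(stats.t.sf(abs(t_stat), df=n - 1))
            p = min(p, 1.0)
        rows.append((pid, mean, t_stat, p, n, degenerate))
    if not rows:
        return []
    pvals = np.array([r[3] for r in rows])
    qvals = multipletests(pvals, method="fdr_bh")[1]
    return [
        VolcanoRow(
            protein_id=pid,
            mean_log2fc=mean,
            t_stat=t_stat,
            p_value=p,
            q_value=float(max(q, p)),  # q >= p by construction of BH
            n_pairs=n,
            degenerate=deg,
        )
        for (pid, mean, t_stat, p, n, deg), q in zip(rows, qvals)
    ]


def select_significant(
    volcano: Sequence[VolcanoRow], cfg: PipelineConfig = PipelineConfig()
) -> set[str]:
    """Positive-side volcano selection: p (or q) < alpha and mean log2FC
    above the fold-change threshold."""
    if not volcano:
        raise PipelineError("empty volcano table")
    selected = set()
    for row in volcano:
        p = row.q_value if cfg.use_adjusted_p else row.p_value
        if p < cfg.alpha and row.mean_log2fc > cfg.min_log2fc:
            selected.add(row.protein_id)
    return selected


# ---------------------------------------------------------------------------
# stage 3: annotation filter


def annotation_filter(
    candidates: set[str], ann: Iterable[AnnotationRecord]
) -> set[str]:
    """Keep candidates that are plasma-membrane proteins with at least one
    predicted N-glycosylation site; unannotated candidates are removed."""
    by_id = annotation_by_id(ann)
    return {
        pid
        for pid in candidates
        if pid in by_id
        and by_id[pid].n_sequons >= 1
        and by_id[pid].plasma_membrane
    }


def _annotation_removal_reason(pid: str, by_id: Mapping[str, AnnotationRecord]) -> str:
    if pid not in by_id:
        return UNANNOTATED
    if by_id[pid].n_sequons < 1:
        return NO_GLYCOSITES
    return NOT_PLASMA_MEMBRANE


# ---------------------------------------------------------------------------
# stage 4: back-mapping


def backmap_filter(
    candidates: set[str],
    fc: Log2FcTable,
    tails: Sequence[TailAssessment],
    cfg: PipelineConfig = PipelineConfig(),
) -> set[str]:
    """Map candidates back onto each retained dataset's histogram; remove a
    protein found below the base of the labelling tail (>= comparison, so a
    value exactly on the boundary is retained) in any dataset where it was
    measured.

    *tails* must be restricted to retained (has_tail) datasets.  Imputed
    ratios are judged only when ``cfg.backmap_use_imputed``; with
    ``cfg.backmap_require_all_datasets`` a candidate missing from any
    retained dataset is removed.
    """
    if any(not t.has_tail for t in tails):
        raise ConfigurationError("backmap_filter expects only retained (has_tail) datasets")
    kept = set()
    for pid in candidates:
        if pid not in fc.log2fc.index:
            continue
        ok = True
        for t in tails:
            value = fc.log2fc.at[pid, t.dataset_id]
            if pd.isna(value):
                if cfg.backmap_require_all_datasets:
                    ok = False
                    break
                continue
            if not cfg.backmap_use_imputed and bool(fc.imputed.at[pid, t.dataset_id]):
                continue
            if value < t.backmap_cutoff:
                ok = False
                break
        if ok:
            kept.add(pid)
    return kept


# ---------------------------------------------------------------------------
# the full pipeline


def run_pipeline(
    quant: ProteinQuantTable,
    design: Sequence[SampleDesign],
    ann: Sequence[AnnotationRecord],
    cfg: PipelineConfig = PipelineConfig(),
) -> CounterReceptorReport:
    """Execute the four filtration stages in order and return a full audit.

    Raises :class:`PipelineError` (``NO_RETAINED_DATASETS``) when fewer than
    two datasets show a labelling tail.
    """
    fc = compute_log2fc(quant, design, cfg)
    assessments = [
        assess_tail(fc, ann, ds_id, cfg) for ds_id in fc.datasets()
    ]
    retained = [a for a in assessments if a.has_tail]
    if len(retained) < 2:
        raise PipelineError(
            f"NO_RETAINED_DATASETS: only {len(retained)} of {len(assessments)} "
            "datasets show a labelling tail (need >= 2)"
        )
    retained_ids = [a.dataset_id for a in retained]

    volcano = paired_t_volcano(fc, retained_ids, cfg)
    significant = select_significant(volcano, cfg)
    annotated = annotation_filter(significant, ann)
    final = backmap_filter(annotated, fc, retained, cfg)

    by_id = annotation_by_id(ann)
    tested = {v.protein_id for v in volcano}
    audit: dict[str, dict[str, str]] = {}
    for pid in quant.protein_ids():
        if pid in final:
            continue
        if pid not in tested:
            has_any = bool(fc.log2fc.loc[pid].notna().any()) if pid in fc.log2fc.index else False
            reason = TOO_FEW_PAIRS if has_any else NOT_QUANTIFIED
            audit[pid] = {"stage": "volcano", "reason": reason}
        elif pid not in significant:
            audit[pid] = {"stage": "volcano", "reason": NOT_SIGNIFICANT}
        elif pid not in annotated:
            audit[pid] = {
                "stage": "annotation",
                "reason": _annotation_removal_reason(pid, by_id),
            }
        else:
            audit[pid] = {"stage": "backmap", "reason": OUTSIDE_TAIL}

    return CounterReceptorReport(
        assessments=assessments,
        retained_datasets=retained_ids,
        volcano=volcano,
        stage_sets={"significant": significant, "annotated": annotated, "final": final},
        final_set=final,
        audit=audit,
        config=cfg,
    )


def final_table(
    report: CounterReceptorReport, quant: ProteinQuantTable
) -> pd.DataFrame:
    """The final set shaped like the published list: gene name, mean log2
    fold change, p value; sorted by descending fold change."""
    rows = [
        {
            "gene_name": quant[v.protein_id].gene_name or v.protein_id,
            "log2_fold_change": v.mean_log2fc,
            "p_value": v.p_value,
        }
        for v in report.volcano
        if v.protein_id in report.final_set
    ]
    return (
        pd.DataFrame(rows, columns=["gene_name", "log2_fold_change", "p_value"])
        .sort_values("log2_fold_change", ascending=False)
        .reset_index(drop=True)
    )
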
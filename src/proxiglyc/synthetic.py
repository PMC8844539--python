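"""Synthetic proximity-labelling experiments with known ground truth.

The generator emulates the study design the pipeline targets: three
biological replicates labelled with two multimer formats (six datasets),
each dataset one active-bait and one non-binding-control LFQ sample over
the same protein background.  A chosen subset of plasma-membrane
glycoproteins is spiked with positive log2 enrichment effects — the
counter-receptors the filtration stages must recover.

Missingness is missing-not-at-random: the probability of a missing LFQ
value follows a logistic censoring curve in log10 intensity whose marginal
rate equals ``missing_rate_base``, so low-intensity values vanish often and
high-intensity values almost never do — the behaviour of real label-free
data that the noise-floor imputation policy has to survive.

All generators are deterministic functions of their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigurationError
from .glyco import GlycanComposition, permethylated_mz
from .tables_io import (
    AnnotationRecord,
    Bait,
    CCClass,
    Multimer,
    PeakList,
    ProteinQuantRecord,
    ProteinQuantTable,
    SampleDesign,
)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of a synthetic labelling experiment.

    Defaults mirror the target design: 2000 quantified proteins of which
    30% are membrane-annotated, 50 spiked counter-receptors with log2
    effects ~ Normal(2.5, 0.5) truncated at 0.5, per-dataset multiplicative
    noise of 0.6 log2 units, log10 baseline intensities ~ Normal(6.5, 0.8),
    10% marginal MNAR missingness, and 3 replicates x 2 multimer formats.
    """

    n_proteins: int = 2000
    membrane_fraction: float = 0.3
    n_spiked: int = 50
    spike_log2_mean: float = 2.5
    spike_log2_sd: float = 0.5
    spike_log2_min: float = 0.5  # truncation: enrichment effects are positive
    replicate_sd: float = 0.6
    baseline_log10_mean: float = 6.5
    baseline_log10_sd: float = 0.8
    missing_rate_base: float = 0.1
    mnar_strength: float = 4.0  # logistic steepness per log10-intensity decade
    n_replicates: int = 3
    multimer_formats: tuple[str, ...] = ("IN_SOLUTION", "ON_BEAD")
    plasma_membrane_fraction: float = 0.8  # of membrane proteins
    n_sticky: int = 0  # cytoplasmic contaminants with small positive effects
    sticky_log2_effect: float = 0.5
    degraded_datasets: tuple[str, ...] = ()  # dataset ids with effects zeroed
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.membrane_fraction <= 1.0):
            raise ConfigurationError("membrane_fraction must be in [0, 1]")
        if not (0.0 <= self.missing_rate_base < 1.0):
            raise ConfigurationError("missing_rate_base must be in [0, 1)")
        if self.n_spiked > int(self.n_proteins * self.membrane_fraction):
            raise ConfigurationError(
                f"n_spiked={self.n_spiked} exceeds the membrane pool "
                f"({int(self.n_proteins * self.membrane_fraction)})"
            )


@dataclass
class SyntheticTruth:
    """Ground truth of one generated experiment."""

    spiked_ids: set[str]
    effects: dict[str, float]  # per spiked protein, log2 units
    config: SimConfig
    seed: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "spiked_ids": sorted(self.spiked_ids),
            "effects": {k: self.effects[k] for k in sorted(self.effects)},
            "config": asdict(self.config),
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _mnar_missing_probability(
    log10_intensity: np.ndarray, rate: float, steepness: float
) -> np.ndarray:
    """Logistic censoring curve 1/(1+exp(s*(x-L))) with L solved so the
    mean probability over the given intensities equals *rate*."""
    if rate == 0.0:
        return np.zeros_like(log10_intensity)
    if steepness == 0.0:
        return np.full_like(log10_intensity, rate)  # MCAR fallback
    lo = log10_intensity.min() - 50.0
    hi = log10_intensity.max() + 50.0
    for _ in range(200):  # bisection: mean(p(L)) is monotone increasing in L
        mid = 0.5 * (lo + hi)
        mean_p = float(
            np.mean(1.0 / (1.0 + np.exp(steepness * (log10_intensity - mid))))
        )
        if mean_p < rate:
            lo = mid
        else:
            hi = mid
    return 1.0 / (1.0 + np.exp(steepness * (log10_intensity - 0.5 * (lo + hi))))


def generate_experiment(
    cfg: SimConfig = SimConfig(),
) -> tuple[ProteinQuantTable, list[SampleDesign], list[AnnotationRecord], SyntheticTruth]:
    """Generate one labelling experiment: quant table, sample design,
    annotations and ground truth, fully reproducible from ``cfg.seed``.

    Per dataset, control intensity is the protein's log-normal baseline and
    bait intensity is control x 2^effect x 2^Normal(0, replicate_sd); the
    effect is the protein's spiked enrichment (0 for background, and 0 in
    datasets listed in ``degraded_datasets``).  MNAR missingness is then
    applied per sample.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_proteins
    n_membrane = int(round(n * cfg.membrane_fraction))
    ids = [f"P{i:05d}" for i in range(1, n + 1)]

    cc = np.array(
        [CCClass.MEMBRANE.value] * n_membrane
        + [CCClass.OTHER.value] * (n - n_membrane),
        dtype=object,
    )
    rest = np.arange(n_membrane, n)
    rng.shuffle(rest)
    third = len(rest) // 3
    cc[rest[:third]] = CCClass.CYTOPLASM.value
    cc[rest[third : 2 * third]] = CCClass.NUCLEUS.value

    plasma = np.zeros(n, dtype=bool)
    plasma[:n_membrane] = rng.random(n_membrane) < cfg.plasma_membrane_fraction
    n_sequons = np.where(
        cc == CCClass.MEMBRANE.value,
        rng.poisson(4.0, n),
        (rng.random(n) < 0.15) * rng.poisson(2.0, n),
    ).astype(int)
    n_ig = np.where(cc == CCClass.MEMBRANE.value, rng.poisson(0.6, n), 0).astype(int)

    # spiked counter-receptors: plasma-membrane glycoproteins only
    eligible = np.flatnonzero(plasma & (n_sequons >= 1))
    if len(eligible) < cfg.n_spiked:
        # force enough eligible proteins rather than failing on an unlucky draw
        shortfall = cfg.n_spiked - len(eligible)
        candidates = np.flatnonzero((cc == CCClass.MEMBRANE.value) & ~(plasma & (n_sequons >= 1)))
        for idx in candidates[:shortfall]:
            plasma[idx] = True
            n_sequons[idx] = max(n_sequons[idx], 1)
        eligible = np.flatnonzero(plasma & (n_sequons >= 1))
    spiked_idx = np.sort(rng.choice(eligible, size=cfg.n_spiked, replace=False))
    effects = np.zeros(n)
    if cfg.n_spiked:
        effects[spiked_idx] = np.clip(
            rng.normal(cfg.spike_log2_mean, cfg.spike_log2_sd, cfg.n_spiked),
            cfg.spike_log2_min,
            None,
        )
    if cfg.n_sticky:
        sticky_pool = np.flatnonzero(cc == CCClass.CYTOPLASM.value)
        sticky_idx = rng.choice(
            sticky_pool, size=min(cfg.n_sticky, len(sticky_pool)), replace=False
        )
        effects[sticky_idx] = cfg.sticky_log2_effect

    baseline = 10.0 ** rng.normal(cfg.baseline_log10_mean, cfg.baseline_log10_sd, n)
    mw = np.round(10.0 ** rng.normal(1.7, 0.25, n), 3)  # kDa, lognormal around 50

    design: list[SampleDesign] = []
    intensity: dict[str, np.ndarray] = {}
    missing: dict[str, np.ndarray] = {}
    for fmt in cfg.multimer_formats:
        for rep in range(1, cfg.n_replicates + 1):
            ds = f"{fmt.lower()}_r{rep}"
            eff = np.zeros(n) if ds in cfg.degraded_datasets else effects
            ctrl = baseline.copy()
            bait = ctrl * (2.0**eff) * (2.0 ** rng.normal(0.0, cfg.replicate_sd, n))
            for bait_role, values in (
                (Bait.ACTIVE_SN, bait),
                (Bait.CONTROL_R97A, ctrl),
            ):
                sid = f"{ds}_{'sn' if bait_role is Bait.ACTIVE_SN else 'r97a'}"
                design.append(
                    SampleDesign(
                        sample_id=sid,
                        dataset_id=ds,
                        bait=bait_role,
                        multimer=Multimer(fmt),
                        replicate=rep,
                    )
                )
                p_miss = _mnar_missing_probability(
                    np.log10(values), cfg.missing_rate_base, cfg.mnar_strength
                )
                intensity[sid] = values
                missing[sid] = rng.random(n) < p_miss

    records = [
        ProteinQuantRecord(
            protein_id=ids[i],
            gene_name=f"Gene{i + 1}",
            molecular_weight_kda=float(mw[i]),
            intensity_by_sample={
                s.sample_id: (
                    None if missing[s.sample_id][i] else float(intensity[s.sample_id][i])
                )
                for s in design
            },
        )
        for i in range(n)
    ]
    quant = ProteinQuantTable(records=records, sample_ids=[s.sample_id for s in design])
    ann = [
        AnnotationRecord(
            protein_id=ids[i],
            cc_class=CCClass(cc[i]),
            plasma_membrane=bool(plasma[i]),
            n_sequons=int(n_sequons[i]),
            n_ig_domains=int(n_ig[i]),
        )
        for i in range(n)
    ]
    truth = SyntheticTruth(
        spiked_ids={ids[i] for i in spiked_idx},
        effects={ids[i]: float(effects[i]) for i in spiked_idx},
        config=cfg,
        seed=cfg.seed,
    )
    return quant, design, ann, truth


def generate_annotation_noise(
    ann: Sequence[AnnotationRecord],
    flip_rate: float,
    seed: int,
    protect_ids: set[str] | None = None,
) -> list[AnnotationRecord]:
    """Corrupt a random fraction of annotations to stress the annotation
    filter: each selected protein has its plasma-membrane flag flipped or
    its sequon count zeroed (chosen at random).  Proteins in *protect_ids*
    (typically the spiked truth) are never touched."""
    if not (0.0 <= flip_rate < 0.5):
        raise ConfigurationError("flip_rate must be in [0, 0.5)")
    protect = protect_ids or set()
    rng = np.random.default_rng(seed)
    out: list[AnnotationRecord] = []
    for a in ann:
        if a.protein_id in protect or rng.random() >= flip_rate:
            out.append(a)
            continue
        # pick a corruption that actually changes the record: flip the
        # plasma-membrane flag (membrane proteins only), zero a positive
        # sequon count, or grant sequons to an unglycosylated protein
        choices = []
        if a.cc_class is CCClass.MEMBRANE:
            choices.append("flip_pm")
        choices.append("zero_sequons" if a.n_sequons > 0 else "grant_sequons")
        action = choices[int(rng.integers(0, len(choices)))]
        out.append(
            AnnotationRecord(
                protein_id=a.protein_id,
                cc_class=a.cc_class,
                plasma_membrane=(
                    not a.plasma_membrane if action == "flip_pm" else a.plasma_membrane
                ),
                n_sequons=(
                    0 if action == "zero_sequons"
                    else 2 if action == "grant_sequons"
                    else a.n_sequons
                ),
                n_ig_domains=a.n_ig_domains,
                sequence=a.sequence,
            )
        )
    return out


def generate_spectrum(
    compositions: Sequence[tuple[GlycanComposition, float]],
    mass_error_sd_da: float = 0.05,
    n_noise_peaks: int = 0,
    seed: int = 0,
    mz_range: tuple[float, float] = (800.0, 3200.0),
    noise_intensity: float = 50.0,
    condition_label: str = "synthetic",
) -> PeakList:
    """A synthetic MALDI peak list: one peak per composition at its
    theoretical sodiated m/z plus Gaussian jitter, and uniform-random noise
    peaks."""
    rng = np.random.default_rng(seed)
    peaks: list[tuple[float, float]] = []
    for comp, abundance in compositions:
        if abundance <= 0:
            raise ConfigurationError(f"{comp}: abundance must be positive")
        mz = permethylated_mz(comp) + rng.normal(0.0, mass_error_sd_da)
        peaks.append((float(mz), float(abundance)))
    for _ in range(n_noise_peaks):
        peaks.append(
            (
                float(rng.uniform(*mz_range)),
                float(rng.exponential(noise_intensity)),
            )
        )
    return PeakList(peaks=peaks, condition_label=condition_label)
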
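"""Permethylated-glycan mass computation and MALDI peak annotation.

Masses are monoisotopic and derived at import time from elemental formulas
of the *permethylated residue increments* — the mass a residue adds to a
growing permethylated chain:

========  ===========  =============
residue   formula      mass (Da)
========  ===========  =============
Hex       C9H16O5      204.0998
HexNAc    C11H19NO5    245.1263
dHex      C8H14O4      174.0892
NeuAc     C16H27NO8    361.1737
NeuGc     C17H29NO9    391.1842
Pent      C7H12O4      160.0736
========  ===========  =============

A free-reducing permethylated glycan closes with end group C2H6O (the
reducing-end and non-reducing-end methyls); the reduced (alditol) convention
closes with C3H10O instead.  Spectra are acquired as sodiated molecular
ions, so the default adduct is Na+ (22.9892 Da).  NeuGc differs from NeuAc
by CH2O = 30.0106 Da — the shift distinguishing N-glycolyl from N-acetyl
sialylation throughout the annotation.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .errors import ProxiglycError
from .tables_io import PeakList

# CODATA monoisotopic atomic masses (Da)
_ATOM = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
}
_ELECTRON = 0.00054857990907
_NA_PLUS = 22.9897692809 - _ELECTRON  # sodium cation

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def formula_mass(formula: str) -> float:
    """Monoisotopic mass of a CHNO elemental formula like ``C9H16O5``."""
    mass = 0.0
    consumed = 0
    for element, count in _FORMULA_RE.findall(formula):
        if not element:
            continue
        if element not in _ATOM:
            raise ProxiglycError(f"unknown element {element!r} in formula {formula!r}")
        mass += _ATOM[element] * (int(count) if count else 1)
        consumed += len(element) + len(count)
    if consumed != len(formula):
        raise ProxiglycError(f"unparseable formula {formula!r}")
    return mass


RESIDUE_FORMULAS: dict[str, str] = {
    "Hex": "C9H16O5",
    "HexNAc": "C11H19NO5",
    "dHex": "C8H14O4",
    "NeuAc": "C16H27NO8",
    "NeuGc": "C17H29NO9",
    "Pent": "C7H12O4",
}
RESIDUES: tuple[str, ...] = tuple(RESIDUE_FORMULAS)

REDUCING_END_FORMULA = "C2H6O"  # free reducing permethylated glycan
ALDITOL_END_FORMULA = "C3H10O"  # reduced (alditol) convention

NEUGC_NEUAC_SHIFT = formula_mass("CH2O")  # 30.0106 Da


@dataclass(frozen=True)
class MassTable:
    """Residue, end-group and adduct masses used for m/z computation."""

    residue_mass: Mapping[str, float] = field(
        default_factory=lambda: {
            name: formula_mass(f) for name, f in RESIDUE_FORMULAS.items()
        }
    )
    reducing_end_mass: float = formula_mass(REDUCING_END_FORMULA)
    adduct_mass: float = _NA_PLUS


DEFAULT_MASS_TABLE = MassTable()


@dataclass(frozen=True)
class GlycanComposition:
    """A monosaccharide count vector (no linkage information).

    Compositions add componentwise and print in the compact glycomics
    shorthand, e.g. ``Hex3HexNAc1NeuAc1``.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for residue, count in self.counts.items():
            if residue not in RESIDUE_FORMULAS:
                raise ProxiglycError(f"unknown residue {residue!r}")
            if count < 0:
                raise ProxiglycError(f"negative count for {residue}")
            if count:
                clean[residue] = int(count)
        object.__setattr__(self, "counts", clean)

    def __getitem__(self, residue: str) -> int:
        return self.counts.get(residue, 0)

    def __hash__(self) -> int:
        return hash(tuple(self[r] for r in RESIDUES))

    def __add__(self, other: "GlycanComposition") -> "GlycanComposition":
        return GlycanComposition(
            {r: self[r] + other[r] for r in RESIDUES if self[r] + other[r]}
        )

    def __str__(self) -> str:
        return "".join(f"{r}{self[r]}" for r in RESIDUES if self[r]) or "empty"

    def total_residues(self) -> int:
        return sum(self.counts.values())

    @classmethod
    def parse(cls, text: str) -> "GlycanComposition":
        """Parse shorthand like ``Hex3HexNAc1NeuAc1`` (order-insensitive).

        Residue names are matched longest-first so ``HexNAc`` is never read
        as ``Hex`` + ``NAc``.
        """
        pattern = re.compile(
            "(" + "|".join(sorted(RESIDUES, key=len, reverse=True)) + r")(\d+)"
        )
        counts: dict[str, int] = {}
        pos = 0
        for match in pattern.finditer(text):
            if match.start() != pos:
                raise ProxiglycError(f"cannot parse composition {text!r}")
            counts[match.group(1)] = counts.get(match.group(1), 0) + int(match.group(2))
            pos = match.end()
        if pos != len(text):
            raise ProxiglycError(f"cannot parse composition {text!r}")
        return cls(counts)


def permethylated_mz(
    composition: GlycanComposition,
    *,
    mass_table: MassTable = DEFAULT_MASS_TABLE,
    reduced: bool = False,
) -> float:
    """Theoretical [M+Na]+ m/z of a permethylated glycan.

    m/z = sum(count x residue mass) + end-group mass + Na+ mass.  With
    ``reduced=True`` the alditol end group is used instead of the
    free-reducing one.
    """
    end = formula_mass(ALDITOL_END_FORMULA) if reduced else mass_table.reducing_end_mass
    mass = end + mass_table.adduct_mass
    for residue, count in composition.counts.items():
        if residue not in mass_table.residue_mass:
            raise ProxiglycError(f"no mass for residue {residue!r}")
        mass += count * mass_table.residue_mass[residue]
    return mass


def nominal_mz(composition: GlycanComposition, **kwargs) -> int:
    """Nearest-integer m/z, matching how spectra peaks are labelled."""
    return round(permethylated_mz(composition, **kwargs))


class GlycanClass(str, Enum):
    N_GLYCAN = "N_GLYCAN"
    GLYCOLIPID = "GLYCOLIPID"


def enumerate_compositions(
    glycan_class: GlycanClass,
    bounds: Mapping[str, int],
    *,
    allow_dhex_on_glycolipid: bool = False,
) -> list[GlycanComposition]:
    """All compositions within per-residue *bounds* obeying biosynthetic
    class constraints, in deterministic lexicographic order of the count
    vector over (Hex, HexNAc, dHex, NeuAc, NeuGc, Pent).

    N-glycans: trimannosyl-chitobiose core requires HexNAc >= 2 and
    Hex >= 3; sialic acids cannot outnumber available antennae plus one
    (NeuAc + NeuGc <= HexNAc - 2 + 1).  Glycolipid glycans: Hex >= 2
    (lactosyl core) and no fucose unless explicitly allowed.
    """
    ranges = [range(0, int(bounds.get(r, 0)) + 1) for r in RESIDUES]
    out: list[GlycanComposition] = []
    for counts in itertools.product(*ranges):
        c = dict(zip(RESIDUES, counts))
        if sum(counts) == 0:
            continue
        if glycan_class is GlycanClass.N_GLYCAN:
            if c["HexNAc"] < 2 or c["Hex"] < 3:
                continue
            if c["NeuAc"] + c["NeuGc"] > c["HexNAc"] - 2 + 1:
                continue
        elif glycan_class is GlycanClass.GLYCOLIPID:
            if c["Hex"] < 2:
                continue
            if c["dHex"] > 0 and not allow_dhex_on_glycolipid:
                continue
        out.append(GlycanComposition(c))
    return out


@dataclass(frozen=True)
class PeakMatch:
    composition: GlycanComposition
    theoretical_mz: float
    error_da: float


@dataclass(frozen=True)
class AnnotatedPeak:
    """One observed peak and its candidate assignments, best first."""

    observed_mz: float
    intensity: float
    matches: tuple[PeakMatch, ...]

    @property
    def best(self) -> PeakMatch | None:
        return self.matches[0] if self.matches else None

    @property
    def matched(self) -> bool:
        return bool(self.matches)


def annotate_peaks(
    peaks: PeakList,
    candidates: Sequence[GlycanComposition],
    tolerance_da: float = 0.5,
    *,
    mass_table: MassTable = DEFAULT_MASS_TABLE,
    reduced: bool = False,
) -> list[AnnotatedPeak]:
    """Match every peak to all candidate compositions within
    ``tolerance_da``, sorted by absolute mass error; unmatched peaks are
    returned with an empty match list."""
    if tolerance_da <= 0:
        raise ProxiglycError(f"tolerance must be positive, got {tolerance_da}")
    if not candidates:
        raise ProxiglycError("no candidate compositions")
    theory = [
        (permethylated_mz(c, mass_table=mass_table, reduced=reduced), c)
        for c in candidates
    ]
    annotated = []
    for mz, intensity in peaks.peaks:
        matches = sorted(
            (
                PeakMatch(composition=c, theoretical_mz=t, error_da=mz - t)
                for t, c in theory
                if abs(mz - t) <= tolerance_da
            ),
            key=lambda m: (abs(m.error_da), str(m.composition)),
        )
        annotated.append(
            AnnotatedPeak(observed_mz=mz, intensity=intensity, matches=tuple(matches))
        )
    return annotated


@dataclass(frozen=True)
class SialylRatio:
    """NeuAc share of a NeuAc/NeuGc counterpart pair's summed intensity."""

    neuac_composition: GlycanComposition
    neugc_composition: GlycanComposition
    neuac_intensity: float
    neugc_intensity: float
    ratio: float | None  # None when both peaks are absent
    one_sided: bool  # exactly one of the two peaks was observed


def _is_neuac_neugc_pair(a: GlycanComposition, b: GlycanComposition) -> bool:
    swap = b["NeuGc"] - a["NeuGc"]
    if swap <= 0 or a["NeuAc"] - b["NeuAc"] != swap:
        return False
    return all(a[r] == b[r] for r in RESIDUES if r not in ("NeuAc", "NeuGc"))


def neuac_neugc_ratio(
    annotated: Sequence[AnnotatedPeak],
    pairs: Sequence[tuple[GlycanComposition, GlycanComposition]],
) -> list[SialylRatio]:
    """Per pair: intensity(NeuAc) / (intensity(NeuAc) + intensity(NeuGc)),
    summing intensities of peaks whose best assignment is the composition.

    Each pair must differ only by a NeuAc -> NeuGc substitution (m/z shift
    an exact multiple of 30.0106 Da); an absent peak contributes zero and a
    pair with both peaks absent is flagged with ``ratio=None``.
    """
    intensity_by_comp: dict[str, float] = {}
    for peak in annotated:
        if peak.best is not None:
            key = str(peak.best.composition)
            intensity_by_comp[key] = intensity_by_comp.get(key, 0.0) + peak.intensity
    out = []
    for ac, gc in pairs:
        if not _is_neuac_neugc_pair(ac, gc):
            raise ProxiglycError(
                f"{ac} / {gc} is not a NeuAc<->NeuGc counterpart pair"
            )
        i_ac = intensity_by_comp.get(str(ac), 0.0)
        i_gc = intensity_by_comp.get(str(gc), 0.0)
        total = i_ac + i_gc
        out.append(
            SialylRatio(
                neuac_composition=ac,
                neugc_composition=gc,
                neuac_intensity=i_ac,
                neugc_intensity=i_gc,
                ratio=None if total == 0 else i_ac / total,
                one_sided=(total > 0) and (i_ac == 0.0 or i_gc == 0.0),
            )
        )
    return out


# Compositions of the published ganglioside-series and N-glycan peaks.
GM1B_NEUAC = GlycanComposition({"Hex": 3, "HexNAc": 1, "NeuAc": 1})
GM1B_NEUGC = GlycanComposition({"Hex": 3, "HexNAc": 1, "NeuGc": 1})
GD1C_2NEUAC = GlycanComposition({"Hex": 3, "HexNAc": 1, "NeuAc": 2})
GD1C_NEUAC_NEUGC = GlycanComposition({"Hex": 3, "HexNAc": 1, "NeuAc": 1, "NeuGc": 1})
GD1C_2NEUGC = GlycanComposition({"Hex": 3, "HexNAc": 1, "NeuGc": 2})
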
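"""Peak-list ingestion, S/N filtering, composition enumeration and
peak <-> composition assignment for MALDI-TOF glycomics spectra.

The annotator re-implements database lookup as constrained enumeration:
every composition inside :class:`CompositionBounds` whose predicted ion
m/z falls within tolerance of an observed peak is a candidate; candidates
are ranked by |mass error| with a parsimony tie-break (fewer residues,
then fewer sulfates, then canonical string).  Peaks with no candidate are
reported unassigned rather than dropped.

Spectra from the neutral/sialylated pool are annotated with positive
sodiated species only; spectra from the sulfated pool with negative
deprotonated/sodium-counterion species only.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from sulfoglyco.composition import ClassificationError, GlycanComposition, classify
from sulfoglyco.masses import (
    CLOSURE_MASS,
    EXTRA_SULFO_SALT,
    RESIDUE_MASSES,
    SULFO_DELTA,
    UNDER_PERMETHYLATION,
    IonSpecies,
    Polarity,
    ion_mz,
)

logger = logging.getLogger(__name__)

DEFAULT_MZ_RANGE = (1000.0, 6000.0)
DEFAULT_MIN_SNR = 2.0
DEFAULT_TOLERANCE_DA = 0.5
SATELLITE_TOLERANCE_DA = 0.3


class Fraction(str, Enum):
    """MAX-column pool the spectrum came from."""

    NEUTRAL_SIALYLATED = "neutral_sialylated"
    SULFATED = "sulfated"


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float
    snr: float

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"peak m/z must be positive, got {self.mz}")
        if self.intensity < 0 or self.snr < 0:
            raise ValueError("peak intensity and S/N must be non-negative")


@dataclass(frozen=True)
class Spectrum:
    """Centroided peak list with acquisition metadata."""

    peaks: tuple[Peak, ...]
    polarity: Polarity
    fraction: Fraction
    mz_range: tuple[float, float] = DEFAULT_MZ_RANGE

    def __post_init__(self) -> None:
        mzs = [p.mz for p in self.peaks]
        if mzs != sorted(mzs):
            object.__setattr__(
                self, "peaks", tuple(sorted(self.peaks, key=lambda p: p.mz))
            )

    def __len__(self) -> int:
        return len(self.peaks)


class PeaklistError(ValueError):
    """Unreadable or malformed peak-list file."""


def read_peaklist(
    path,
    polarity: Polarity | str,
    fraction: Fraction | str,
    mz_range: tuple[float, float] = DEFAULT_MZ_RANGE,
) -> Spectrum:
    """Read a delimited peak list (columns ``mz``, ``intensity``[, ``snr``]).

    The delimiter is sniffed (comma/tab/semicolon/whitespace).  A missing
    ``snr`` column is imputed as intensity / median(intensity) with a
    logged warning.  Rows that do not parse as numbers raise with the
    1-based data line number.
    """
    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise PeaklistError(f"cannot read peak list {path}: {exc}") from exc
    if df.empty:
        raise PeaklistError(f"peak list {path} contains no data rows")
    df.columns = [str(c).strip().lower() for c in df.columns]
    for col in ("mz", "intensity"):
        if col not in df.columns:
            raise PeaklistError(f"peak list {path} lacks required column {col!r}")
    numeric_cols = ["mz", "intensity"] + (["snr"] if "snr" in df.columns else [])
    for col in numeric_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise PeaklistError(
                f"unparseable value {df[col].iloc[line - 1]!r} in column "
                f"{col!r} at data line {line} of {path}"
            )
        if coerced.isna().any():
            line = int(np.flatnonzero(coerced.isna().to_numpy())[0]) + 1
            raise PeaklistError(f"missing {col!r} at data line {line} of {path}")
        df[col] = coerced
    if "snr" not in df.columns:
        med = float(df["intensity"].median())
        df["snr"] = df["intensity"] / med if med > 0 else 0.0
        logger.warning(
            "peak list %s has no snr column; imputed snr = intensity / "
            "median(intensity) (median=%.3g)", path, med,
        )
    peaks = tuple(
        Peak(mz=float(r.mz), intensity=float(r.intensity), snr=float(r.snr))
        for r in df.itertuples()
    )
    return Spectrum(
        peaks=peaks, polarity=Polarity(polarity),
        fraction=Fraction(fraction), mz_range=mz_range,
    )


def filter_peaks(spectrum: Spectrum, min_snr: float = DEFAULT_MIN_SNR) -> Spectrum:
    """Retain peaks with S/N >= ``min_snr`` and m/z inside the recorded range."""
    lo, hi = spectrum.mz_range
    kept = tuple(
        p for p in spectrum.peaks if p.snr >= min_snr and lo <= p.mz <= hi
    )
    return Spectrum(
        peaks=kept, polarity=spectrum.polarity,
        fraction=spectrum.fraction, mz_range=spectrum.mz_range,
    )


@dataclass(frozen=True)
class CompositionBounds:
    """Search space for composition enumeration.

    The plausibility rules prune chemically implausible N-glycan
    candidates: each sialic acid caps an antenna (neuac <= hexnac - 2)
    and each sulfate sits on a (galactose) hexose outside the core
    trimannose (sulfo <= hex - 2).
    """

    max_hex: int = 12
    max_hexnac: int = 10
    max_dhex: int = 4
    max_neuac: int = 6
    max_sulfo: int = 3
    n_glycan_core: bool = True      # require hexnac >= 2 and hex >= 3
    plausibility: bool = True       # neuac <= hexnac - 2; sulfo <= hex - 2

    def admits(self, comp: GlycanComposition) -> bool:
        if (comp.hex > self.max_hex or comp.hexnac > self.max_hexnac
                or comp.dhex > self.max_dhex or comp.neuac > self.max_neuac
                or comp.sulfo > self.max_sulfo):
            return False
        if self.n_glycan_core and not comp.is_n_glycan:
            return False
        if self.plausibility and (
            comp.neuac > comp.hexnac - 2 or comp.sulfo > max(comp.hex - 2, 0)
        ):
            return False
        return True


@dataclass(frozen=True)
class Candidate:
    """One composition explaining a peak, with its ion species and error."""

    composition: GlycanComposition
    species: IonSpecies
    error_da: float
    rank: int = 0

    @property
    def sort_key(self):
        # |error|, then parsimony: fewer residues, fewer sulfates, name.
        return (
            abs(self.error_da),
            self.composition.total_residues,
            self.composition.sulfo,
            self.composition.render(),
        )


@dataclass
class Annotation:
    """Per-peak annotation: ranked candidates plus satellite links."""

    peak: Peak
    candidates: list[Candidate] = field(default_factory=list)
    satellites: list["SatelliteLink"] = field(default_factory=list)

    @property
    def assigned(self) -> bool:
        return bool(self.candidates)

    @property
    def top(self) -> Candidate | None:
        return self.candidates[0] if self.candidates else None


@dataclass(frozen=True)
class SatelliteLink:
    """Directed link between a satellite peak and its parent peak."""

    label: str          # "under_permethylation" or "di_sulfation_candidate"
    partner_mz: float   # m/z of the linked peak
    offset_da: float    # observed spacing (this peak minus partner)


def _sulfo_range(
    polarity: Polarity, bounds: CompositionBounds, fraction: Fraction | None
) -> range:
    if polarity is Polarity.NEGATIVE:
        return range(1, bounds.max_sulfo + 1)
    if fraction is Fraction.NEUTRAL_SIALYLATED:
        return range(0, 1)
    return range(0, bounds.max_sulfo + 1)


def enumerate_compositions(
    target_mz: float,
    species: IonSpecies | Polarity | str,
    tolerance_da: float = DEFAULT_TOLERANCE_DA,
    bounds: CompositionBounds | None = None,
    fraction: Fraction | None = None,
) -> list[Candidate]:
    """All compositions within bounds whose ion m/z is within tolerance.

    ``species`` may fix the adduct (and hence sulfate count), or be a bare
    polarity, in which case each admissible sulfate count contributes its
    own species.  The result is sorted by |error| with the parsimony
    tie-break and is deterministic.
    """
    if tolerance_da <= 0:
        raise ValueError("tolerance must be positive")
    bounds = bounds or CompositionBounds()
    if isinstance(species, IonSpecies):
        polarity = species.polarity
        sulfos = range(species.n_sulfo, species.n_sulfo + 1)
    else:
        polarity = Polarity(species)
        sulfos = _sulfo_range(polarity, bounds, fraction)

    m_hex = RESIDUE_MASSES["hex"]
    m_hexnac = RESIDUE_MASSES["hexnac"]
    m_dhex = RESIDUE_MASSES["dhex"]
    m_neuac = RESIDUE_MASSES["neuac"]

    out: list[Candidate] = []
    for n_sulfo in sulfos:
        if n_sulfo > bounds.max_sulfo:
            continue
        sp = IonSpecies(polarity, n_sulfo=n_sulfo)
        # Neutral residue-sum window for this adduct and sulfate count.
        base = CLOSURE_MASS + n_sulfo * SULFO_DELTA + sp.adduct_shift
        lo = target_mz - tolerance_da - base
        hi = target_mz + tolerance_da - base
        if hi <= 0:
            continue
        hexnac_min = 2 if bounds.n_glycan_core else 0
        hex_min = 3 if bounds.n_glycan_core else 0
        for n_hexnac in range(hexnac_min, bounds.max_hexnac + 1):
            m1 = n_hexnac * m_hexnac
            if m1 + hex_min * m_hex > hi:
                break
            for n_hex in range(hex_min, bounds.max_hex + 1):
                m2 = m1 + n_hex * m_hex
                if m2 > hi:
                    break
                for n_dhex in range(0, bounds.max_dhex + 1):
                    m3 = m2 + n_dhex * m_dhex
                    if m3 > hi:
                        break
                    for n_neuac in range(0, bounds.max_neuac + 1):
                        m4 = m3 + n_neuac * m_neuac
                        if m4 > hi:
                            break
                        if m4 < lo:
                            continue
                        comp = GlycanComposition(
                            hex=n_hex, hexnac=n_hexnac, dhex=n_dhex,
                            neuac=n_neuac, sulfo=n_sulfo,
                        )
                        if not bounds.admits(comp):
                            continue
                        err = (m4 + base) - target_mz
                        out.append(Candidate(comp, sp, error_da=err))
    out.sort(key=lambda c: c.sort_key)
    return [
        Candidate(c.composition, c.species, c.error_da, rank=i + 1)
        for i, c in enumerate(out)
    ]


def annotate_spectrum(
    spectrum: Spectrum,
    bounds: CompositionBounds | None = None,
    tolerance_da: float = DEFAULT_TOLERANCE_DA,
    min_snr: float = DEFAULT_MIN_SNR,
) -> list[Annotation]:
    """Annotate every retained peak of a spectrum.

    Filtering (S/N and m/z range) is applied first.  The fraction label
    dictates the ion chemistry: the neutral/sialylated pool must be a
    positive-mode spectrum and is searched with sodiated unsulfated
    species; the sulfated pool must be negative mode and is searched with
    sulfated negative species.  Unassigned peaks are kept with an empty
    candidate list, then satellite links are attached.
    """
    if spectrum.fraction is Fraction.NEUTRAL_SIALYLATED:
        if spectrum.polarity is not Polarity.POSITIVE:
            raise ValueError(
                "neutral/sialylated-pool spectra are acquired in positive mode"
            )
    elif spectrum.polarity is not Polarity.NEGATIVE:
        raise ValueError("sulfated-pool spectra are acquired in negative mode")
    bounds = bounds or CompositionBounds()
    filtered = filter_peaks(spectrum, min_snr=min_snr)
    annotations = [
        Annotation(
            peak=peak,
            candidates=enumerate_compositions(
                peak.mz, spectrum.polarity, tolerance_da, bounds,
                fraction=spectrum.fraction,
            ),
        )
        for peak in filtered.peaks
    ]
    return flag_satellites(
        annotations, fraction=spectrum.fraction
    )


def flag_satellites(
    annotations: list[Annotation],
    tolerance_da: float = SATELLITE_TOLERANCE_DA,
    fraction: Fraction | None = None,
) -> list[Annotation]:
    """Link peak pairs at the known satellite spacings.

    A peak 14.0157 Da below another is linked to it as an
    under-permethylation satellite.  In the sulfated pool, a peak
    87.9231 Da above another is linked back as a di-sulfation candidate
    (the next sulfation state of the same base composition).  Links are
    annotations only; they never change candidate ranking.
    """
    mzs = np.array([a.peak.mz for a in annotations])
    order = np.argsort(mzs)
    for ii, i in enumerate(order):
        for j in order[ii + 1:]:
            spacing = mzs[j] - mzs[i]
            if spacing > abs(UNDER_PERMETHYLATION) + tolerance_da and (
                fraction is not Fraction.SULFATED
                or spacing > EXTRA_SULFO_SALT + tolerance_da
            ):
                break
            if abs(spacing - abs(UNDER_PERMETHYLATION)) <= tolerance_da:
                annotations[i].satellites.append(SatelliteLink(
                    "under_permethylation", partner_mz=float(mzs[j]),
                    offset_da=float(-spacing),
                ))
            if fraction is Fraction.SULFATED and (
                abs(spacing - EXTRA_SULFO_SALT) <= tolerance_da
            ):
                annotations[j].satellites.append(SatelliteLink(
                    "di_sulfation_candidate", partner_mz=float(mzs[i]),
                    offset_da=float(spacing),
                ))
    return annotations


def annotations_to_table(annotations: list[Annotation]) -> pd.DataFrame:
    """Flatten annotations into the report table (one row per peak).

    Columns carry the rank-1 assignment, its ion species and signed error
    in mDa, the composition-level class fields, satellite links, and a
    JSON column preserving every candidate.
    """
    rows = []
    for a in annotations:
        row = {
            "mz": round(a.peak.mz, 4),
            "intensity": round(a.peak.intensity, 4),
            "snr": round(a.peak.snr, 2),
            "composition": "",
            "ion_species": "",
            "error_mda": "",
            "category": "",
            "antennarity": "",
            "bisect_candidate": "",
            "core_fucosylated": "",
            "sialylation": "",
            "sulfation": "",
            "satellites": ";".join(
                f"{s.label}@{s.partner_mz:.3f}" for s in a.satellites
            ),
            "candidates_json": json.dumps([
                {
                    "composition": c.composition.render(),
                    "species": c.species.label,
                    "error_mda": round(c.error_da * 1000, 1),
                    "rank": c.rank,
                }
                for c in a.candidates
            ]),
        }
        if a.assigned:
            top = a.top
            row.update(
                composition=top.composition.render(),
                ion_species=top.species.label,
                error_mda=round(top.error_da * 1000, 1),
            )
            try:
                cls = classify(top.composition)
                row.update(
                    category=cls.category.value,
                    antennarity=cls.antennarity,
                    bisect_candidate=cls.bisect_candidate,
                    core_fucosylated=cls.core_fucosylated,
                    sialylation=cls.sialylation_count,
                    sulfation=cls.sulfation_count,
                )
            except ClassificationError:
                row["category"] = "non_n_glycan"
        rows.append(row)
    return pd.DataFrame(rows)
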
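"""Synthetic MALDI-TOF spectra, paired tissue cohorts and paired RPKM
expression tables with the statistical structure the pipeline assumes.

The spectrum generator emulates reflector-mode MALDI acquisition of
permethylated N-glycans over m/z 1000-6000: one monoisotopic peak per
library composition with Gaussian m/z error and log-normal abundance,
under-permethylation satellites (-14 Da), di-sulfation salt satellites
(+88 Da, sulfated pool only) at a fixed intensity ratio of the parent,
and sub-threshold noise peaks (S/N < 2) uniform over the range.  No
isotope clusters are generated (the annotator is monoisotopic) and no
raw profile data is emulated.

The cohort generator plants tumor-vs-normal class-level abundance shifts
with the directions observed in papillary thyroid cancer tissue: more
branching and bisection, less sialylation, fewer di-sulfated species,
oligomannose unchanged.  The expression generator plants per-gene tumor
log2-fold-changes on a paired log-normal RPKM model with a shared
patient random effect.

All generators are pure functions of (config, seed): a fixed seed gives
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from sulfoglyco.annotate import (
    DEFAULT_MZ_RANGE,
    Fraction,
    Peak,
    Spectrum,
)
from sulfoglyco.composition import GlycanComposition, classify, parse_composition
from sulfoglyco.masses import (
    EXTRA_SULFO_SALT,
    UNDER_PERMETHYLATION,
    Polarity,
    ion_mz,
)
from sulfoglyco.stats import FEATURE_CLASSES, ExpressionMatrix

# Compositions behind the profiled peaks of normal/tumor thyroid tissue.
_NEUTRAL_LIBRARY = (
    "Hex5HexNAc2", "Hex6HexNAc2", "Hex7HexNAc2", "Hex8HexNAc2", "Hex9HexNAc2",
    "Hex5HexNAc4Fuc1", "Hex5HexNAc4Fuc1NeuAc1", "Hex5HexNAc4Fuc1NeuAc2",
    "Hex6HexNAc5Fuc1NeuAc1", "Hex7HexNAc6Fuc1NeuAc1", "Hex5HexNAc5Fuc1NeuAc2",
)
_SULFATED_LIBRARY = (
    "Hex4HexNAc3Sulf1", "Hex4HexNAc3Fuc1Sulf1", "Hex5HexNAc3Sulf1",
    "Hex5HexNAc3Fuc1Sulf1", "Hex5HexNAc4Sulf1", "Hex5HexNAc4Fuc1Sulf1",
    "Hex5HexNAc4Fuc1NeuAc1Sulf1", "Hex6HexNAc5Fuc1Sulf1",
    "Hex6HexNAc5Fuc1NeuAc1Sulf1", "Hex5HexNAc4Fuc1Sulf2",
    "Hex7HexNAc6Fuc1Sulf2",
)


def default_library(fraction: Fraction | str) -> list[GlycanComposition]:
    """Default composition library for a pool (the profiled tissue peaks)."""
    fraction = Fraction(fraction)
    names = (_NEUTRAL_LIBRARY if fraction is Fraction.NEUTRAL_SIALYLATED
             else _SULFATED_LIBRARY)
    return [parse_composition(n) for n in names]


def _polarity_for(fraction: Fraction) -> Polarity:
    return (Polarity.POSITIVE if fraction is Fraction.NEUTRAL_SIALYLATED
            else Polarity.NEGATIVE)


@dataclass(frozen=True)
class SpectrumSimConfig:
    """Parameters of one simulated spectrum.

    Defaults emulate a well-calibrated reflector MALDI-TOF acquisition:
    0.05 Da m/z error, log-normal abundances spanning ~2 orders of
    magnitude, 30% of peaks with an under-permethylation satellite at 20%
    of the parent intensity, 20% of sulfated peaks with a +88 Da
    di-sulfation satellite, and ~20 sub-threshold noise peaks.
    """

    fraction: Fraction = Fraction.NEUTRAL_SIALYLATED
    library: tuple[GlycanComposition, ...] | None = None
    log_intensity_mean: float = 7.0
    log_intensity_sigma: float = 1.0
    mz_sigma: float = 0.05            # Da
    p_under_permethylation: float = 0.3
    p_di_sulfo: float = 0.2           # sulfated pool only
    satellite_ratio: float = 0.2      # satellite / parent intensity
    noise_lambda: float = 20.0        # Poisson mean of noise-peak count
    signal_snr: tuple[float, float] = (3.0, 50.0)
    noise_snr: tuple[float, float] = (0.5, 1.9)
    mz_range: tuple[float, float] = DEFAULT_MZ_RANGE
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_under_permethylation, self.p_di_sulfo):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.mz_sigma < 0 or self.log_intensity_sigma <= 0:
            raise ValueError("sigma parameters must be positive")

    def resolved_library(self) -> list[GlycanComposition]:
        lib = (list(self.library) if self.library is not None
               else default_library(self.fraction))
        if not lib:
            raise ValueError("composition library is empty")
        polarity = _polarity_for(self.fraction)
        for comp in lib:
            if polarity is Polarity.NEGATIVE and comp.sulfo == 0:
                raise ValueError(
                    f"{comp} has no sulfate but the sulfated pool is "
                    "profiled in negative mode"
                )
            if self.fraction is Fraction.NEUTRAL_SIALYLATED and comp.sulfo:
                raise ValueError(
                    f"{comp} is sulfated but listed in the neutral pool"
                )
        return lib


def simulate_spectrum(
    config: SpectrumSimConfig,
    rng: np.random.Generator | None = None,
    log_intensity_shift: dict[GlycanComposition, float] | None = None,
) -> tuple[Spectrum, pd.DataFrame]:
    """Simulate one spectrum and its ground-truth annotation table.

    Returns the spectrum plus a truth table with one row per generated
    peak (``role`` is ``signal``, ``under_permethylation_satellite``,
    ``di_sulfo_satellite`` or ``noise``; ``composition`` is empty for
    noise peaks).  ``log_intensity_shift`` adds a per-composition offset
    to the log-abundance (used by the cohort generator).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    library = config.resolved_library()
    polarity = _polarity_for(config.fraction)
    peaks: list[Peak] = []
    rows: list[dict] = []

    def emit(mz_true, comp_name, role, intensity, snr):
        mz_obs = mz_true + rng.normal(0.0, config.mz_sigma) \
            if config.mz_sigma > 0 else mz_true
        peaks.append(Peak(mz=mz_obs, intensity=intensity, snr=snr))
        rows.append({
            "mz_true": round(mz_true, 4), "mz_observed": round(mz_obs, 4),
            "composition": comp_name, "role": role,
            "intensity": round(intensity, 4), "snr": round(snr, 2),
        })

    for comp in library:
        mz_true = ion_mz(comp, polarity)
        shift = (log_intensity_shift or {}).get(comp, 0.0)
        intensity = float(np.exp(rng.normal(
            config.log_intensity_mean + shift, config.log_intensity_sigma
        )))
        snr = float(rng.uniform(*config.signal_snr))
        emit(mz_true, comp.render(), "signal", intensity, snr)
        if rng.uniform() < config.p_under_permethylation:
            emit(
                mz_true + UNDER_PERMETHYLATION, comp.render(),
                "under_permethylation_satellite",
                intensity * config.satellite_ratio,
                float(rng.uniform(*config.signal_snr)),
            )
        if (config.fraction is Fraction.SULFATED
                and rng.uniform() < config.p_di_sulfo):
            emit(
                mz_true + EXTRA_SULFO_SALT,
                comp.with_sulfo(comp.sulfo + 1).render(),
                "di_sulfo_satellite",
                intensity * config.satellite_ratio,
                float(rng.uniform(*config.signal_snr)),
            )

    n_noise = int(rng.poisson(config.noise_lambda))
    for _ in range(n_noise):
        emit(
            float(rng.uniform(*config.mz_range)), "", "noise",
            float(np.exp(rng.normal(config.log_intensity_mean - 3.0, 0.5))),
            float(rng.uniform(*config.noise_snr)),
        )

    spectrum = Spectrum(
        peaks=tuple(peaks), polarity=polarity,
        fraction=config.fraction, mz_range=config.mz_range,
    )
    truth = pd.DataFrame(rows).sort_values("mz_observed", kind="stable")
    truth = truth.reset_index(drop=True)
    return spectrum, truth


@dataclass(frozen=True)
class CohortSimConfig:
    """Paired normal/tumor cohort of simulated spectra.

    ``class_multipliers`` scales tumor abundances for compositions in a
    feature class; defaults encode the directions seen in papillary
    thyroid cancer: branching and bisection up, sialylation down,
    di-sulfation sharply down, oligomannose unchanged.  A composition in
    several classes receives the product of the multipliers.

    The paired design shares each glycan's log-abundance baseline between
    the two samples of a patient (drawn with the spectrum config's
    ``log_intensity_sigma``); ``within_sigma`` is the residual
    within-pair log-scatter around that baseline and ``patient_sigma``
    the global per-patient offset.
    """

    n_pairs: int = 5
    fraction: Fraction = Fraction.NEUTRAL_SIALYLATED
    spectrum: SpectrumSimConfig | None = None
    class_multipliers: dict = field(default_factory=lambda: {
        "branched": 1.8,
        "bisect_candidate": 1.8,
        "sialylated": 0.7,
        "di_sulfated": 0.4,
    })
    patient_sigma: float = 0.3   # shared per-patient log-abundance effect
    within_sigma: float = 0.25   # within-pair residual per glycan
    seed: int = 0

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.class_multipliers.values()):
            raise ValueError("class multipliers must be positive")

    def resolved_spectrum_config(self) -> SpectrumSimConfig:
        base = self.spectrum or SpectrumSimConfig(fraction=self.fraction)
        return replace(base, fraction=self.fraction)


def _composition_multiplier(
    comp: GlycanComposition, multipliers: dict
) -> float:
    cls = classify(comp)
    member = {
        "oligomannose": cls.category.value == "oligomannose",
        "paucimannose": cls.category.value == "paucimannose",
        "hybrid": cls.category.value == "hybrid",
        "complex": cls.category.value == "complex",
        "branched": cls.antennarity >= 3,
        "bisect_candidate": cls.bisect_candidate,
        "sialylated": cls.sialylation_count >= 1,
        "core_fucosylated": cls.core_fucosylated,
        "sulfated": cls.sulfation_count >= 1,
        "di_sulfated": cls.sulfation_count >= 2,
    }
    out = 1.0
    for name, mult in multipliers.items():
        if member.get(name, False):
            out *= mult
    return out


def _true_fractions(truth: pd.DataFrame) -> dict[str, float]:
    """Realized feature-class fractions of the signal peaks of one truth table."""
    weights = {c: 0.0 for c in FEATURE_CLASSES}
    total = 0.0
    for row in truth.itertuples():
        if row.role != "signal":
            continue
        cls = classify(parse_composition(row.composition))
        total += row.intensity
        weights[cls.category.value] += row.intensity
        if cls.antennarity >= 3:
            weights["branched"] += row.intensity
        if cls.bisect_candidate:
            weights["bisect_candidate"] += row.intensity
        if cls.sialylation_count >= 1:
            weights["sialylated"] += row.intensity
        if cls.core_fucosylated:
            weights["core_fucosylated"] += row.intensity
        if cls.sulfation_count >= 1:
            weights["sulfated"] += row.intensity
        if cls.sulfation_count >= 2:
            weights["di_sulfated"] += row.intensity
    return {c: (weights[c] / total if total else 0.0) for c in FEATURE_CLASSES}


def simulate_cohort(
    config: CohortSimConfig,
) -> tuple[list[tuple[Spectrum, Spectrum]], pd.DataFrame]:
    """Simulate paired (normal, tumor) spectra for each patient.

    Returns the spectrum pairs and a truth table with one row per sample
    carrying the realized feature-class intensity fractions of its
    planted signal peaks.
    """
    rng = np.random.default_rng(config.seed)
    spec_config = config.resolved_spectrum_config()
    library = spec_config.resolved_library()
    tumor_shift = {
        comp: float(np.log(_composition_multiplier(
            comp, config.class_multipliers
        )))
        for comp in library
    }
    # Per-spectrum draws add only the residual within-pair scatter; the
    # glycan-level abundance spread is a patient-level baseline instead.
    sample_config = replace(spec_config, log_intensity_sigma=config.within_sigma)
    pairs: list[tuple[Spectrum, Spectrum]] = []
    truth_rows = []
    for i in range(config.n_pairs):
        patient = f"P{i + 1:02d}"
        patient_effect = float(rng.normal(0.0, config.patient_sigma))
        base = {
            comp: patient_effect + float(rng.normal(
                0.0, spec_config.log_intensity_sigma
            ))
            for comp in library
        }
        normal_spec, normal_truth = simulate_spectrum(
            sample_config, rng=rng, log_intensity_shift=base,
        )
        tumor_spec, tumor_truth = simulate_spectrum(
            sample_config, rng=rng,
            log_intensity_shift={
                comp: base[comp] + tumor_shift[comp] for comp in library
            },
        )
        pairs.append((normal_spec, tumor_spec))
        for group, truth in (("normal", normal_truth), ("PTC", tumor_truth)):
            row = {
                "sample_id": f"{patient}_{'N' if group == 'normal' else 'T'}",
                "patient": patient, "group": group,
            }
            row.update(_true_fractions(truth))
            truth_rows.append(row)
    return pairs, pd.DataFrame(truth_rows)


_DEFAULT_PANEL = {
    # gene: tumor log2-fold-change (directions from PTC-vs-normal RNAseq)
    "MGAT3": 1.0,
    "MGAT4B": 0.8,
    "ST6GAL1": -1.0,
    "MAN1A1": -1.0,
    "MAN1B1": 0.8,
    "GAL3ST3": 0.0,
    "GAL3ST4": 0.8,
    "B4GALT3": 0.5,
    "B4GALT5": 0.5,
    "B4GALT6": 0.5,
}


@dataclass(frozen=True)
class ExpressionSimConfig:
    """Paired tumor/normal RPKM generator.

    RPKM = exp(log baseline + patient effect + group effect + noise);
    the group effect is lfc * ln(2) in tumor samples.  Defaults: 20
    patient pairs, glycogene panel with the observed effect directions,
    baseline around 30 RPKM, patient and residual standard deviations of
    0.3 on the natural-log scale.
    """

    n_pairs: int = 20
    lfc_log2: dict = field(default_factory=lambda: dict(_DEFAULT_PANEL))
    baseline_log_rpkm: float = float(np.log(30.0))
    baseline_sigma: float = 0.5      # gene-to-gene baseline spread
    patient_sigma: float = 0.3
    residual_sigma: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 2:
            raise ValueError("need at least two pairs")
        if min(self.patient_sigma, self.residual_sigma) <= 0:
            raise ValueError("sigma parameters must be positive")


def simulate_expression(
    config: ExpressionSimConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate a paired RPKM table and its ground truth.

    Truth holds the per-gene planted log2-fold-change and the gene
    baseline actually drawn.
    """
    rng = np.random.default_rng(config.seed)
    genes = list(config.lfc_log2)
    patients = [f"P{i + 1:02d}" for i in range(config.n_pairs)]
    columns = [f"{p}_N" for p in patients] + [f"{p}_T" for p in patients]
    baselines = {
        g: float(rng.normal(config.baseline_log_rpkm, config.baseline_sigma))
        for g in genes
    }
    patient_effects = rng.normal(0.0, config.patient_sigma, config.n_pairs)
    values = np.empty((len(genes), 2 * config.n_pairs))
    for gi, gene in enumerate(genes):
        shift = config.lfc_log2[gene] * np.log(2.0)
        log_normal = (baselines[gene] + patient_effects
                      + rng.normal(0.0, config.residual_sigma, config.n_pairs))
        log_tumor = (baselines[gene] + patient_effects + shift
                     + rng.normal(0.0, config.residual_sigma, config.n_pairs))
        values[gi, :config.n_pairs] = np.exp(log_normal)
        values[gi, config.n_pairs:] = np.exp(log_tumor)
    table = pd.DataFrame(values, index=genes, columns=columns)
    pairing = {p: (f"{p}_N", f"{p}_T") for p in patients}
    truth = pd.DataFrame({
        "gene": genes,
        "lfc_log2": [config.lfc_log2[g] for g in genes],
        "baseline_log_rpkm": [baselines[g] for g in genes],
    })
    return ExpressionMatrix(values=table, pairing=pairing), truth
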
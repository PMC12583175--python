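"""Deterministic generators for MS2 spectra and multi-group feature tables.

Spectra are synthesized from a compound's [M+H]+ and its class-expected
neutral-loss ladders, with configurable m/z jitter (uniform, in ppm), peak
dropout and uniform noise peaks — emulating positive-mode protonated
coumarin/cinnamic-acid spectra. Feature tables carry log-normal baseline
areas with planted fold changes in chosen groups. Every generator is
integer-seeded and fully reproducible; the ground truth it returns is the
benchmark oracle for screening and differential statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .chem import adduct_mz
from .fragments import (
    LossCatalog,
    compound_loss_sequences,
    default_loss_catalog,
    generate_ladder,
)
from .library import Library, LibraryCompound
from .spectra import FeatureTable, Spectrum

__all__ = [
    "SpectrumRecipe",
    "TableRecipe",
    "synth_spectrum",
    "synth_feature_table",
    "synthetic_coumarin_library",
    "decoy_spectrum",
    "screening_benchmark",
]


@dataclass
class SpectrumRecipe:
    """How to synthesize one compound's MS2 spectrum.

    Default loss sequences are the compound's class-expected ladders.
    Rung intensities fall off geometrically down each ladder (earlier,
    fewer-loss rungs are more intense). Noise peaks are uniform over
    [50, precursor - 1] m/z with intensities below the 10th percentile of
    the signal rungs.
    """

    compound: LibraryCompound
    loss_sequences: Optional[Sequence[Sequence[str]]] = None
    base_intensity: float = 1000.0
    intensity_decay: float = 0.75
    mz_jitter_ppm: float = 0.0
    peak_dropout_prob: float = 0.0
    n_noise_peaks: int = 0
    include_precursor_peak: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.peak_dropout_prob <= 1.0):
            raise ValueError("peak_dropout_prob must be in [0, 1]")
        if self.mz_jitter_ppm < 0 or self.n_noise_peaks < 0:
            raise ValueError("jitter and noise-peak count must be non-negative")

    def sequences(self) -> Sequence[Sequence[str]]:
        if self.loss_sequences is not None:
            return self.loss_sequences
        methoxylated = "methoxy" in (self.compound.subclass or "").casefold()
        return compound_loss_sequences(self.compound.compound_class, methoxylated)


def _jitter(mz: np.ndarray, ppm: float, rng: np.random.Generator) -> np.ndarray:
    if ppm <= 0:
        return mz
    return mz * (1.0 + rng.uniform(-ppm, ppm, size=mz.shape) * 1e-6)


def synth_spectrum(
    recipe: SpectrumRecipe,
    catalog: Optional[LossCatalog] = None,
    node_id: Optional[str] = None,
) -> Tuple[Spectrum, str]:
    """Synthesize a spectrum; returns (spectrum, ground-truth compound name).

    The precursor is the compound's [M+H]+. Signal peaks are the union of
    the ladder rungs (duplicate rungs from commuting loss orders merged at
    the higher intensity), subjected to jitter and dropout; the residual
    precursor peak, when included, is never dropped. Identical seeds give
    identical spectra.
    """
    catalog = catalog or default_loss_catalog()
    rng = np.random.default_rng(recipe.seed)
    precursor = recipe.compound.mh_mz

    rung_intensity: Dict[float, float] = {}
    for seq in recipe.sequences():
        ladder = generate_ladder(precursor, seq, catalog)  # raises if losses exceed
        for k, mz in enumerate(ladder.rungs):
            inten = recipe.base_intensity * (recipe.intensity_decay ** k)
            # merge rungs identical across ladders, keeping the higher intensity
            key = next((r for r in rung_intensity if abs(r - mz) < 1e-6), mz)
            rung_intensity[key] = max(rung_intensity.get(key, 0.0), inten)

    mzs = np.array(sorted(rung_intensity))
    intens = np.array([rung_intensity[m] for m in mzs])
    keep = rng.uniform(size=mzs.shape) >= recipe.peak_dropout_prob
    mzs, intens = mzs[keep], intens[keep]
    mzs = _jitter(mzs, recipe.mz_jitter_ppm, rng)

    peaks = list(zip(mzs.tolist(), intens.tolist()))
    if recipe.include_precursor_peak:
        prec_obs = float(_jitter(np.array([precursor]), recipe.mz_jitter_ppm, rng)[0])
        peaks.append((prec_obs, recipe.base_intensity * 0.5))
    if recipe.n_noise_peaks > 0:
        ceiling = (
            np.percentile(intens, 10) if intens.size else recipe.base_intensity * 0.05
        )
        noise_mz = rng.uniform(50.0, precursor - 1.0, size=recipe.n_noise_peaks)
        noise_int = rng.uniform(0.01 * ceiling, ceiling, size=recipe.n_noise_peaks)
        peaks.extend(zip(noise_mz.tolist(), noise_int.tolist()))

    precursor_obs = float(_jitter(np.array([precursor]), recipe.mz_jitter_ppm, rng)[0])
    spec = Spectrum(
        node_id=node_id or recipe.compound.name,
        precursor_mz=precursor_obs,
        peaks=tuple(peaks),
    )
    return spec, recipe.compound.name


def decoy_spectrum(
    precursor_mz: float,
    n_peaks: int,
    seed: int,
    node_id: str,
) -> Spectrum:
    """A structurally unrelated decoy: uniform random peaks under a precursor."""
    rng = np.random.default_rng(seed)
    mzs = rng.uniform(50.0, precursor_mz - 1.0, size=n_peaks)
    intens = rng.uniform(10.0, 1000.0, size=n_peaks)
    return Spectrum(
        node_id=node_id,
        precursor_mz=precursor_mz,
        peaks=tuple(zip(mzs.tolist(), intens.tolist())),
    )


def synthetic_coumarin_library(
    n_compounds: int = 50,
    seed: int = 0,
    min_spacing_da: float = 0.05,
) -> Library:
    """A library of synthetic coumarin-like compounds with CHO formulas.

    Formulas are drawn in the simple-coumarin composition range (C9-C16,
    matching H and O counts); [M+H]+ values are kept at least
    `min_spacing_da` apart so precursor matches are unambiguous. Entirely
    synthetic: names are placeholders, not real natural products.
    """
    rng = np.random.default_rng(seed)
    compounds: List[LibraryCompound] = []
    taken_mz: List[float] = []
    attempts = 0
    while len(compounds) < n_compounds:
        attempts += 1
        if attempts > 100 * n_compounds:
            raise RuntimeError("could not place enough distinct compounds")
        c = int(rng.integers(9, 17))
        h = int(rng.integers(6, 19))
        o = int(rng.integers(3, 10))
        compound = LibraryCompound.from_formula(
            name=f"synthetic coumarin {len(compounds):03d}",
            formula=f"C{c}H{h}O{o}",
            compound_class="coumarin",
            subclass="synthetic",
        )
        if any(abs(compound.mh_mz - m) < min_spacing_da for m in taken_mz):
            continue
        taken_mz.append(compound.mh_mz)
        compounds.append(compound)
    return Library(compounds=compounds)


def screening_benchmark(
    seed: int = 0,
    n_compounds: int = 50,
    n_decoys: int = 150,
    mz_jitter_ppm: float = 5.0,
    peak_dropout_prob: float = 0.2,
    n_noise_peaks: int = 6,
) -> Tuple[List[Spectrum], Dict[str, Optional[str]], Library]:
    """Planted-truth benchmark corpus for the screening pipeline.

    Returns (spectra, truth, library) where truth maps node id to the
    planted compound name, or None for decoys. Decoy precursors are kept
    at least 0.05 Da away from every library [M+H]+.
    """
    rng = np.random.default_rng(seed)
    lib = synthetic_coumarin_library(n_compounds, seed=int(rng.integers(2**31)))
    spectra: List[Spectrum] = []
    truth: Dict[str, Optional[str]] = {}

    for i, compound in enumerate(lib):
        recipe = SpectrumRecipe(
            compound=compound,
            mz_jitter_ppm=mz_jitter_ppm,
            peak_dropout_prob=peak_dropout_prob,
            n_noise_peaks=n_noise_peaks,
            seed=int(rng.integers(2**31)),
        )
        node_id = f"planted_{i:03d}"
        spec, name = synth_spectrum(recipe, node_id=node_id)
        spectra.append(spec)
        truth[node_id] = name

    lib_mzs = np.array([c.mh_mz for c in lib])
    placed = 0
    while placed < n_decoys:
        precursor = float(rng.uniform(180.0, 460.0))
        if np.min(np.abs(lib_mzs - precursor)) < 0.05:
            continue
        node_id = f"decoy_{placed:03d}"
        spec = decoy_spectrum(
            precursor,
            n_peaks=int(rng.integers(8, 16)),
            seed=int(rng.integers(2**31)),
            node_id=node_id,
        )
        spectra.append(spec)
        truth[node_id] = None
        placed += 1
    return spectra, truth, lib


@dataclass
class TableRecipe:
    """How to synthesize a features x samples table with planted effects.

    Baselines are log-normal per feature (`baseline_log_mean`,
    `baseline_log_sd` in natural-log space); each sample value multiplies
    the feature baseline by log-normal noise with coefficient of variation
    `noise_cv`; planted effects multiply one feature in one group by a fold
    factor.
    """

    n_features: int
    groups: Dict[str, int]                       # group -> sample count
    planted_effects: Sequence[Tuple[int, str, float]] = ()
    noise_cv: float = 0.1
    baseline_log_mean: float = 11.5              # ~1e5 area units
    baseline_log_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features < 1 or not self.groups:
            raise ValueError("need at least one feature and one group")
        for idx, group, fold in self.planted_effects:
            if not (0 <= idx < self.n_features):
                raise ValueError(f"planted effect references feature {idx} out of range")
            if group not in self.groups:
                raise ValueError(f"planted effect references unknown group {group!r}")
            if fold <= 0:
                raise ValueError("fold multipliers must be positive")


def synth_feature_table(recipe: TableRecipe) -> Tuple[FeatureTable, np.ndarray]:
    """Synthesize a feature table; returns (table, truth mask).

    The truth mask marks features carrying a planted effect. Identical
    seeds give identical tables.
    """
    rng = np.random.default_rng(recipe.seed)
    baselines = np.exp(
        rng.normal(recipe.baseline_log_mean, recipe.baseline_log_sd, recipe.n_features)
    )
    samples: List[str] = []
    groups_map: Dict[str, str] = {}
    for group in sorted(recipe.groups):
        for k in range(recipe.groups[group]):
            name = f"{group}_{k + 1}"
            samples.append(name)
            groups_map[name] = group

    fold = np.ones((recipe.n_features, len(samples)))
    truth = np.zeros(recipe.n_features, dtype=bool)
    for idx, group, multiplier in recipe.planted_effects:
        truth[idx] = True
        for j, s in enumerate(samples):
            if groups_map[s] == group:
                fold[idx, j] = multiplier

    # multiplicative log-normal noise with the requested CV
    sigma = np.sqrt(np.log1p(recipe.noise_cv**2))
    noise = np.exp(
        rng.normal(-0.5 * sigma**2, sigma, size=(recipe.n_features, len(samples)))
    )
    if recipe.noise_cv == 0:
        noise = np.ones_like(noise)
    areas = baselines[:, None] * fold * noise

    table = FeatureTable(
        feature_ids=[f"F{i:05d}" for i in range(recipe.n_features)],
        feature_mz=[0.0] * recipe.n_features,
        feature_rt=[0.0] * recipe.n_features,
        samples=samples,
        groups=groups_map,
        areas=areas,
    )
    return table, truth
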
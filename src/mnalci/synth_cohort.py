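"""Synthetic dual-matrix LDI-MS cohorts with known ground truth.

The generator emulates the acquisition used for nanomaterial-assisted serum
fingerprinting: each sample is spotted under two matrices (gold nanoshell,
GNS; porous silicon nanowire, SiNW) whose ionization efficiencies favour
different mass bands — GNS enhances 200-300 Da, SiNW enhances below 200 Da.
A sample's serum metabolome is a metabolite panel with per-class
log-fold-change effects; a shot spectrum is the gain-weighted sum of Gaussian
peaks on an m/z grid plus baseline drift, per-shot multiplicative intensity
noise and additive detector noise, with an optional affine mass drift so the
downstream calibration step is testable against a known truth.

Two rendering paths exist:

* :func:`render_spectrum` / :func:`simulate_cohort` — the full shot-level
  path (20 spots x 25 shots by default), feeding the preprocessing pipeline.
* :func:`simulate_feature_cohort` — an analytic shortcut that integrates the
  noise-free rendering + accumulation + TIC normalization + binning chain in
  closed form, adding per-bin detector noise. It produces feature matrices
  directly and is what the classifier-scale experiments run on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import (
    BIOMARKERS,
    CANCER_CLASSES,
    CLASSES,
    DEFAULT_CALIBRANTS,
    FIXED_BIOMARKER_MZ,
    MATRICES,
    MZ_MAX,
    MZ_MIN,
)
from .spectra_io import RawSpectrum

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


class CohortConfigError(ValueError):
    """Invalid panel, effect table or cohort configuration."""


# ---------------------------------------------------------------------------
# panel


@dataclass(frozen=True)
class PanelEntry:
    name: str
    mz: float
    base_abundance: float


@dataclass
class MetabolitePanel:
    """Metabolite names, m/z positions, base abundances and class effects.

    ``effect_table`` is a class-label x metabolite-name table of log-fold
    changes; healthy controls carry all-zero effects.
    """

    entries: list[PanelEntry]
    effect_table: pd.DataFrame

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise CohortConfigError("duplicate metabolite names in panel")
        for e in self.entries:
            if not (MZ_MIN <= e.mz <= MZ_MAX):
                raise CohortConfigError(f"{e.name}: m/z {e.mz} outside [{MZ_MIN}, {MZ_MAX}]")
            if e.base_abundance <= 0:
                raise CohortConfigError(f"{e.name}: base abundance must be > 0")
        self.effect_table = self.effect_table.reindex(columns=names, fill_value=0.0).fillna(0.0)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    @property
    def mzs(self) -> np.ndarray:
        return np.array([e.mz for e in self.entries], dtype=float)

    @property
    def base_abundances(self) -> np.ndarray:
        return np.array([e.base_abundance for e in self.entries], dtype=float)

    def __len__(self) -> int:
        return len(self.entries)


def build_panel(
    size: int = 48,
    rng_seed: int = 0,
    effects: Mapping[str, Mapping[str, float]] | pd.DataFrame | None = None,
    biomarker_mz: Mapping[str, float] | None = None,
    band_quota: Sequence[tuple[float, float, int]] = (),
    abundance_log_mean: float = np.log(50.0),
    abundance_log_sd: float = 0.8,
) -> MetabolitePanel:
    """Build a metabolite panel of the 8 named biomarkers plus background.

    Background metabolites get random m/z in [100, 1000] and lognormal base
    abundances. ``band_quota`` forces at least ``count`` background
    metabolites inside each ``(lo, hi)`` window, so band-specific signal can
    be planted. ``effects`` maps class label -> {metabolite -> logFC}.
    """
    if size < 8:
        raise CohortConfigError(f"panel size must be >= 8 (got {size}); the 8 biomarkers are mandatory")
    rng = np.random.default_rng(rng_seed)
    mz_map = dict(BIOMARKERS)
    if biomarker_mz:
        for name, mz in biomarker_mz.items():
            if name not in mz_map:
                raise CohortConfigError(f"unknown biomarker {name!r}")
            if name in FIXED_BIOMARKER_MZ and not np.isclose(mz, FIXED_BIOMARKER_MZ[name]):
                raise CohortConfigError(f"{name} m/z is fixed at {FIXED_BIOMARKER_MZ[name]}")
            mz_map[name] = float(mz)
    entries = [
        PanelEntry(name, mz_map[name], float(rng.lognormal(abundance_log_mean, abundance_log_sd)))
        for name, _ in BIOMARKERS
    ]
    n_background = size - len(entries)
    quota_mzs: list[float] = []
    for lo, hi, count in band_quota:
        quota_mzs.extend(rng.uniform(lo, hi, size=count))
    if len(quota_mzs) > n_background:
        raise CohortConfigError("band quota exceeds background panel size")
    free_mzs = rng.uniform(MZ_MIN, MZ_MAX, size=n_background - len(quota_mzs))
    for i, mz in enumerate(list(quota_mzs) + list(free_mzs)):
        entries.append(
            PanelEntry(f"bg_{i:03d}", float(mz), float(rng.lognormal(abundance_log_mean, abundance_log_sd)))
        )
    if effects is None:
        table = pd.DataFrame(0.0, index=list(CLASSES), columns=[e.name for e in entries])
    elif isinstance(effects, pd.DataFrame):
        table = effects.astype(float)
    else:
        table = pd.DataFrame(
            {cls: pd.Series(row, dtype=float) for cls, row in effects.items()}
        ).T.reindex(index=list(CLASSES)).fillna(0.0)
    unknown = set(table.columns) - {e.name for e in entries}
    if unknown:
        raise CohortConfigError(f"effects reference unknown metabolites: {sorted(unknown)}")
    if "HC" in table.index and (table.loc["HC"] != 0).any():
        raise CohortConfigError("healthy controls must have zero effects")
    return MetabolitePanel(entries=entries, effect_table=table)


def calibrant_panel(abundance: float = 100.0) -> MetabolitePanel:
    """Panel for the six-component calibration standard (no class effects)."""
    entries = [PanelEntry(name, mz, abundance) for name, mz in DEFAULT_CALIBRANTS]
    table = pd.DataFrame(0.0, index=["HC"], columns=[e.name for e in entries])
    return MetabolitePanel(entries=entries, effect_table=table)


# ---------------------------------------------------------------------------
# matrix efficiency profiles


@dataclass
class MatrixProfile:
    """Matrix tag plus an m/z -> multiplicative gain (>= 0) function."""

    matrix_tag: str
    efficiency: Callable[[np.ndarray], np.ndarray]

    def gain(self, mz: np.ndarray | float) -> np.ndarray:
        return np.maximum(np.asarray(self.efficiency(np.asarray(mz, dtype=float))), 0.0)

    def mean_gain(self, lo: float, hi: float, n: int = 2001) -> float:
        grid = np.linspace(lo, hi, n)
        return float(np.mean(self.gain(grid)))


def raised_cosine_gain(lo: float, hi: float, amplitude: float, baseline: float) -> Callable:
    """Smooth bump: ``baseline`` everywhere plus a raised cosine over [lo, hi]."""
    center, width = 0.5 * (lo + hi), hi - lo

    def gain(mz: np.ndarray) -> np.ndarray:
        mz = np.asarray(mz, dtype=float)
        inside = np.abs(mz - center) < width / 2.0
        bump = np.zeros_like(mz)
        bump[inside] = 0.5 * (1.0 + np.cos(2.0 * np.pi * (mz[inside] - center) / width))
        return baseline + amplitude * bump

    return gain


def gns_profile(baseline: float = 0.05, amplitude: float = 1.0) -> MatrixProfile:
    """GNS efficiency: enhanced in the 200-300 Da band."""
    return MatrixProfile("GNS", raised_cosine_gain(200.0, 300.0, amplitude, baseline))


def sinw_profile(baseline: float = 0.05, amplitude: float = 1.0) -> MatrixProfile:
    """SiNW efficiency: enhanced below 200 Da."""
    return MatrixProfile("SiNW", raised_cosine_gain(100.0, 200.0, amplitude, baseline))


def default_profiles() -> dict[str, MatrixProfile]:
    return {"GNS": gns_profile(), "SiNW": sinw_profile()}


# ---------------------------------------------------------------------------
# acquisition


def default_mz_grid(step: float = 0.05) -> np.ndarray:
    return np.round(np.arange(MZ_MIN, MZ_MAX + step / 2, step), 6)


@dataclass
class AcquisitionConfig:
    """Shot-level acquisition settings.

    20 spots x 25 shots mirrors the random-walk raster acquisition (500
    accumulated shots per sample per matrix). ``mass_drift`` is an affine
    (slope, offset in Da) perturbation of peak positions, recoverable by the
    six-calibrant affine fit in :mod:`mnalci.preprocess`.
    """

    spots_per_sample: int = 20
    shots_per_spot: int = 25
    mz_grid: np.ndarray = field(default_factory=default_mz_grid)
    noise_sd: float = 0.02
    baseline_amplitude: float = 0.5
    mass_drift: tuple[float, float] = (0.0, 0.0)
    fwhm: float = 0.3
    shot_scale_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.mz_grid = np.asarray(self.mz_grid, dtype=float)
        if self.mz_grid.size < 2 or np.any(np.diff(self.mz_grid) <= 0):
            raise CohortConfigError("mz_grid must be strictly increasing")
        if self.spots_per_sample < 1 or self.shots_per_spot < 1:
            raise CohortConfigError("spot and shot counts must be positive")

    @property
    def accumulated_shots(self) -> int:
        return self.spots_per_sample * self.shots_per_spot


@dataclass
class SampleMeta:
    sample_id: str
    class_label: str
    stage: str = "none"
    split: str = "train"

    def __post_init__(self) -> None:
        if self.class_label not in CLASSES:
            raise CohortConfigError(f"unknown class label {self.class_label!r}")
        if self.class_label == "HC" and self.stage != "none":
            raise CohortConfigError("HC samples carry stage 'none'")


# ---------------------------------------------------------------------------
# simulation


def simulate_profile(
    panel: MetabolitePanel,
    meta: SampleMeta | str,
    rng: np.random.Generator,
    bio_sd: float = 0.3,
) -> np.ndarray:
    """Draw one sample's metabolite abundance vector.

    ``abundance_i = base_i * exp(effect_i + N(0, bio_sd))`` — lognormal
    biological variation around class-shifted means.
    """
    label = meta.class_label if isinstance(meta, SampleMeta) else str(meta)
    if label not in panel.effect_table.index:
        raise CohortConfigError(f"class label {label!r} not present in the panel effect table")
    effects = panel.effect_table.loc[label].to_numpy(dtype=float)
    noise = rng.normal(0.0, bio_sd, size=len(panel)) if bio_sd > 0 else np.zeros(len(panel))
    return panel.base_abundances * np.exp(effects + noise)


def _peak_template(
    abundances: np.ndarray,
    panel: MetabolitePanel,
    matrix: MatrixProfile,
    acq: AcquisitionConfig,
) -> np.ndarray:
    slope, offset = acq.mass_drift
    centers = panel.mzs * (1.0 + slope) + offset
    gains = matrix.gain(panel.mzs)
    sigma = acq.fwhm / _FWHM_TO_SIGMA
    grid = acq.mz_grid
    template = np.zeros_like(grid)
    for center, gain, abundance in zip(centers, gains, abundances):
        lo = np.searchsorted(grid, center - 6 * sigma)
        hi = np.searchsorted(grid, center + 6 * sigma)
        if lo >= hi:
            continue
        window = grid[lo:hi]
        template[lo:hi] += gain * abundance * np.exp(-0.5 * ((window - center) / sigma) ** 2)
    return template


def render_spectrum(
    abundances: np.ndarray,
    panel: MetabolitePanel,
    matrix: MatrixProfile,
    acq: AcquisitionConfig,
    rng: np.random.Generator,
    sample_id: str = "sample",
) -> list[RawSpectrum]:
    """Render every laser shot for one sample under one matrix.

    Each shot is the gain-weighted Gaussian peak sum, scaled by a per-shot
    lognormal factor, plus an exponentially decaying baseline and additive
    Gaussian detector noise truncated at zero.
    """
    template = _peak_template(np.asarray(abundances, dtype=float), panel, matrix, acq)
    grid = acq.mz_grid
    baseline = acq.baseline_amplitude * np.exp(-(grid - MZ_MIN) / 200.0)
    shots: list[RawSpectrum] = []
    for spot in range(acq.spots_per_sample):
        for shot in range(acq.shots_per_spot):
            scale = float(np.exp(rng.normal(0.0, acq.shot_scale_sd))) if acq.shot_scale_sd > 0 else 1.0
            y = scale * template + baseline
            if acq.noise_sd > 0:
                y = y + rng.normal(0.0, acq.noise_sd, size=grid.size)
            shots.append(
                RawSpectrum(
                    sample_id=sample_id,
                    matrix_tag=matrix.matrix_tag,
                    mz=grid.copy(),
                    intensity=np.maximum(y, 0.0),
                    spot_index=spot,
                    shot_index=shot,
                )
            )
    return shots


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class CohortConfig:
    """Cohort layout plus the generative parameters used for every sample."""

    class_counts: dict[str, int]
    panel: MetabolitePanel
    profiles: dict[str, MatrixProfile] = field(default_factory=default_profiles)
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    bio_sd: float = 0.3
    train_fraction: float = 0.8

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.class_counts.values()):
            raise CohortConfigError("per-class sample counts must be >= 1")
        if len(self.class_counts) < 2:
            raise CohortConfigError("a cohort needs at least 2 classes")
        unknown = set(self.class_counts) - set(CLASSES)
        if unknown:
            raise CohortConfigError(f"unknown class labels: {sorted(unknown)}")


@dataclass
class GroundTruth:
    """Everything needed to check recovery of planted structure."""

    seed: int
    bio_sd: float
    mass_drift: tuple[float, float]
    effect_table: pd.DataFrame
    panel_entries: list[PanelEntry]
    abundances: dict[str, np.ndarray] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        record = {
            "format_version": 1,
            "seed": self.seed,
            "bio_sd": self.bio_sd,
            "mass_drift": list(self.mass_drift),
            "panel": [[e.name, e.mz, e.base_abundance] for e in self.panel_entries],
            "effect_table": {cls: row.to_dict() for cls, row in self.effect_table.iterrows()},
            "abundances": {sid: list(map(float, a)) for sid, a in self.abundances.items()},
        }
        Path(path).write_text(json.dumps(record, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        record = json.loads(Path(path).read_text())
        return cls(
            seed=record["seed"],
            bio_sd=record["bio_sd"],
            mass_drift=tuple(record["mass_drift"]),
            effect_table=pd.DataFrame(record["effect_table"]).T,
            panel_entries=[PanelEntry(n, mz, a) for n, mz, a in record["panel"]],
            abundances={sid: np.array(a) for sid, a in record["abundances"].items()},
        )


def _assign_meta(
    config: CohortConfig, rng: np.random.Generator
) -> list[SampleMeta]:
    metas: list[SampleMeta] = []
    for label in CLASSES:  # fixed order for determinism
        if label not in config.class_counts:
            continue
        n = config.class_counts[label]
        n_train = int(round(config.train_fraction * n))
        split_flags = np.array(["train"] * n_train + ["internal_validation"] * (n - n_train))
        rng.shuffle(split_flags)
        for i in range(n):
            stage = "none" if label == "HC" else str(rng.choice(["I", "II", "III", "IV"]))
            metas.append(
                SampleMeta(
                    sample_id=f"{label}{i:03d}",
                    class_label=label,
                    stage=stage,
                    split=str(split_flags[i]),
                )
            )
    return metas


def meta_table(metas: Sequence[SampleMeta]) -> pd.DataFrame:
    return pd.DataFrame(
        [[m.sample_id, m.class_label, m.stage, m.split] for m in metas],
        columns=["sample_id", "class_label", "stage", "split"],
    )


def simulate_cohort(
    config: CohortConfig, rng_seed: int
) -> tuple[dict[tuple[str, str], list[RawSpectrum]], pd.DataFrame, GroundTruth]:
    """Render a full shot-level cohort under both matrices.

    Returns a spectra store keyed by ``(sample_id, matrix_tag)``, the sample
    metadata table (stratified train/validation split at the configured
    ratio) and the ground-truth record. Memory scales with samples x shots x
    grid points; use coarse grids / few shots for large cohorts, or
    :func:`simulate_feature_cohort` for classifier-scale work.
    """
    rng = np.random.default_rng(rng_seed)
    metas = _assign_meta(config, rng)
    truth = GroundTruth(
        seed=rng_seed,
        bio_sd=config.bio_sd,
        mass_drift=tuple(config.acquisition.mass_drift),
        effect_table=config.panel.effect_table.copy(),
        panel_entries=list(config.panel.entries),
    )
    store: dict[tuple[str, str], list[RawSpectrum]] = {}
    for m in metas:
        abundances = simulate_profile(config.panel, m, rng, config.bio_sd)
        truth.abundances[m.sample_id] = abundances
        for tag in MATRICES:
            store[(m.sample_id, tag)] = render_spectrum(
                abundances, config.panel, config.profiles[tag], config.acquisition, rng, m.sample_id
            )
    return store, meta_table(metas), truth


def simulate_feature_cohort(
    config: CohortConfig,
    rng_seed: int,
    bin_width: float = 0.5,
    detector_sd: float = 2.0,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, GroundTruth]:
    """Analytic feature-level cohort: the noise-free render -> accumulate ->
    bin -> TIC-normalize chain collapsed into closed form.

    Each metabolite contributes ``gain(mz) * abundance`` to its 0.5-Da bin;
    per-bin detector noise (half-normal, sd ``detector_sd``) is added before
    TIC normalization. Returns one samples x bins DataFrame per matrix
    (columns are bin centers), the metadata table and the ground truth.
    """
    from .preprocess import FeatureGrid  # local import; preprocess does not import us

    grid = FeatureGrid(width=bin_width)
    rng = np.random.default_rng(rng_seed)
    metas = _assign_meta(config, rng)
    truth = GroundTruth(
        seed=rng_seed,
        bio_sd=config.bio_sd,
        mass_drift=(0.0, 0.0),
        effect_table=config.panel.effect_table.copy(),
        panel_entries=list(config.panel.entries),
    )
    bin_idx = grid.bin_index(config.panel.mzs)
    gains = {tag: config.profiles[tag].gain(config.panel.mzs) for tag in MATRICES}
    rows: dict[str, list[np.ndarray]] = {tag: [] for tag in MATRICES}
    for m in metas:
        abundances = simulate_profile(config.panel, m, rng, config.bio_sd)
        truth.abundances[m.sample_id] = abundances
        for tag in MATRICES:
            v = np.zeros(grid.n_bins)
            np.add.at(v, bin_idx, gains[tag] * abundances)
            if detector_sd > 0:
                v = v + np.abs(rng.normal(0.0, detector_sd, size=grid.n_bins))
            rows[tag].append(v / v.sum())
    meta = meta_table(metas)
    features = {
        tag: pd.DataFrame(rows[tag], index=meta["sample_id"].to_numpy(), columns=grid.centers)
        for tag in MATRICES
    }
    return features, meta, truth
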
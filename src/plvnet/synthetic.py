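"""Synthetic cohorts with planted, trait-dependent phase coupling.

No public recordings exist for the study design this pipeline targets, so
every stage is exercised on simulated data.  Each region carries, per band,
a narrowband process (white noise passed through the same 6th-order
zero-phase Butterworth band filter the analysis uses, standardised to unit
variance).  A coupled edge (i, j) with coupling strength kappa in [0, 1]
replaces region j's band component by::

    kappa * (phase-lagged copy of i's component) + sqrt(1 - kappa^2) * (independent process)

so kappa = 0 gives chance-level phase locking and kappa = 1 perfect locking
at a constant lag.  The phase-lagged copy is the real part of i's analytic
signal rotated by ``phase_lag`` (default pi/4, deliberately nonzero so that
zero-lag-specific artifacts would be caught — PLV is lag-invariant).
Band components scaled by per-band amplitudes plus broadband white noise
sum to the region's signal.

Group and trait structure: questionnaire scores are drawn from a discretised
normal (defaults match a trait questionnaire with mean ~16.2, SD ~3.6 on a
5-30 scale), subjects are median-split, and each planted edge's realised
kappa is the subject's group baseline plus ``trait_slope`` times the
standardised trait score, clipped to [0, 1].  The realised values are stored
in a truth table for recovery tests.  Demographic covariates are drawn
independently of the trait, so the two groups are balanced in expectation.

The generator measured nothing: it is a stand-in whose planted effects make
the pipeline's operating characteristics testable, not a model of any
recorded data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .atlas import NetworkAtlas, default_atlas
from .bands import DEFAULT_BANDS, BandSpec
from .spectral import band_sos


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class TraitModel:
    """Discretised-normal questionnaire-score model (integer scores)."""

    mean: float = 16.22
    sd: float = 3.64
    floor: int = 5
    ceiling: int = 30


@dataclass(frozen=True)
class CouplingSpec:
    """Planted coupling on one (edge, band): group baselines + trait slope.

    ``edge`` is an unordered ROI index pair (atlas row order); region
    ``max(edge)`` is the coupling target whose band component is rebuilt
    from region ``min(edge)``.  ``trait_slope`` is the change in kappa per
    standard deviation of the trait score.
    """

    edge: tuple[int, int]
    band: str
    kappa_low: float
    kappa_high: float
    trait_slope: float = 0.0
    phase_lag: float = math.pi / 4

    def __post_init__(self) -> None:
        i, j = self.edge
        if i == j:
            raise SimulationError("coupling edge cannot be a self-pair")
        if i > j:
            object.__setattr__(self, "edge", (j, i))
        for k in (self.kappa_low, self.kappa_high):
            if not (0.0 <= k <= 1.0):
                raise SimulationError(f"kappa {k} outside [0, 1]")


# Default per-band component amplitudes: a coarse 1/f-like resting spectrum
# with the alpha peak preserved.
DEFAULT_BAND_AMPLITUDES: dict[str, float] = {
    "delta": 1.0,
    "theta": 0.9,
    "alpha": 1.0,
    "beta": 0.7,
    "gamma": 0.5,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Complete description of a synthetic cohort.

    The defaults are the desk-scale study conditions: 66 subjects, 40
    regions, 250 Hz sampling, twenty 1024-sample epochs.  The full-scale
    condition (1 kHz, 4096-sample epochs, 150 of which 135 survive
    screening) is reachable by overriding fs/epoch_samples/n_epochs.
    """

    n_subjects: int = 66
    fs: float = 250.0
    epoch_samples: int = 1024
    n_epochs: int = 20
    n_rois: int = 40
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS
    couplings: tuple[CouplingSpec, ...] = ()
    broadband_noise_sd: float = 0.5
    band_amplitudes: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BAND_AMPLITUDES)
    )
    trait_model: TraitModel = TraitModel()
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return self.epoch_samples * self.n_epochs

    def validate(self) -> None:
        if self.n_subjects < 4:
            raise SimulationError("need at least 4 subjects for a median split")
        band_names = {b.name for b in self.bands}
        for b in self.bands:
            b.validate_against_fs(self.fs)
        seen: set[tuple[tuple[int, int], str]] = set()
        for c in self.couplings:
            if c.band not in band_names:
                raise SimulationError(f"coupling references unknown band {c.band!r}")
            if max(c.edge) >= self.n_rois:
                raise SimulationError(f"coupling edge {c.edge} outside ROI range")
            key = (c.edge, c.band)
            if key in seen:
                raise SimulationError(f"duplicate coupling for edge {c.edge}, band {c.band!r}")
            seen.add(key)


@dataclass
class SyntheticCohort:
    """Signals + metadata + ground-truth coupling table for one cohort."""

    signals: list[np.ndarray]  # per subject: (n_rois, n_samples)
    metadata: pd.DataFrame  # subject, mwq_total, age, sex, education, spm_pr
    truth: pd.DataFrame  # subject, roi_i, roi_j, band, kappa, group
    config: SimulationConfig


def draw_trait_scores(
    model: TraitModel, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Integer questionnaire scores: rounded, clipped normal draws."""
    if n < 2:
        raise SimulationError("need n >= 2 scores (median split undefined)")
    rng = np.random.default_rng(seed)
    raw = rng.normal(model.mean, model.sd, size=n)
    return np.clip(np.round(raw), model.floor, model.ceiling).astype(int)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        return np.zeros_like(x, dtype=float)
    return (x - x.mean()) / sd


def _narrowband_noise(
    rng: np.random.Generator, sos, n_rows: int, n_samples: int
) -> np.ndarray:
    """Unit-variance band-limited noise rows."""
    x = sps.sosfiltfilt(sos, rng.standard_normal((n_rows, n_samples)), axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _phase_lagged(x: np.ndarray, lag: float) -> np.ndarray:
    """Copy of a narrowband series with every spectral component rotated by -lag."""
    return np.real(sps.hilbert(x) * np.exp(-1j * lag))


def simulate_subject_signals(
    config: SimulationConfig,
    subject_kappas: Mapping[tuple[tuple[int, int], str], tuple[float, float]],
    seed: int | np.random.Generator,
) -> np.ndarray:
    """One subject's ROI x sample matrix with the given realised couplings.

    ``subject_kappas`` maps (edge, band) to (kappa, phase_lag).  Within one
    band a region can be the target of at most one coupling; its band
    component is rebuilt from the source region's component.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.n_samples
    total = np.zeros((config.n_rois, n))
    by_band: dict[str, list[tuple[tuple[int, int], float, float]]] = {}
    for (edge, band), (kappa, lag) in subject_kappas.items():
        by_band.setdefault(band, []).append((edge, kappa, lag))
    for band in config.bands:
        sos = band_sos(band, config.fs)
        comp = _narrowband_noise(rng, sos, config.n_rois, n)
        targets: set[int] = set()
        for edge, kappa, lag in by_band.get(band.name, []):
            i, j = min(edge), max(edge)
            if j in targets:
                raise SimulationError(
                    f"ROI {j} is the coupling target of two edges in band {band.name!r}"
                )
            targets.add(j)
            if not (0.0 <= kappa <= 1.0):
                raise SimulationError(f"realised kappa {kappa} outside [0, 1]")
            indep = _narrowband_noise(rng, sos, 1, n)[0]
            comp[j] = kappa * _phase_lagged(comp[i], lag) + math.sqrt(
                1.0 - kappa**2
            ) * indep
        total += config.band_amplitudes.get(band.name, 1.0) * comp
    if config.broadband_noise_sd > 0:
        total += config.broadband_noise_sd * rng.standard_normal(total.shape)
    return total


def realized_kappas(
    config: SimulationConfig, scores: np.ndarray
) -> tuple[list[dict[tuple[tuple[int, int], str], tuple[float, float]]], np.ndarray]:
    """Per-subject realised coupling maps given the trait scores.

    Groups follow a median split (scores below the median are Low; ties at
    the median go High).  Realised kappa is the group baseline plus
    ``trait_slope`` times the standardised score, clipped to [0, 1].
    Returns the per-subject maps plus the boolean High-group indicator.
    """
    scores = np.asarray(scores)
    median = float(np.median(scores))
    is_high = scores >= median
    z = _standardize(scores.astype(float))
    maps: list[dict[tuple[tuple[int, int], str], tuple[float, float]]] = []
    for s in range(len(scores)):
        m: dict[tuple[tuple[int, int], str], tuple[float, float]] = {}
        for c in config.couplings:
            base = c.kappa_high if is_high[s] else c.kappa_low
            kappa = float(np.clip(base + c.trait_slope * z[s], 0.0, 1.0))
            m[(c.edge, c.band)] = (kappa, c.phase_lag)
        maps.append(m)
    return maps, is_high


def _draw_demographics(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Covariates drawn independently of the trait (balanced in expectation)."""
    age = np.round(np.clip(rng.normal(22.66, 2.46, n), 18, 35), 1)
    education = np.round(np.clip(rng.normal(15.33, 1.66, n), 10, 22), 1)
    spm = np.round(np.clip(rng.normal(90.46, 2.86, n), 75, 95), 1)
    n_female = round(n * 36 / 66)
    sex = np.array(["F"] * n_female + ["M"] * (n - n_female))
    rng.shuffle(sex)
    return pd.DataFrame(
        {"age": age, "sex": sex, "education": education, "spm_pr": spm}
    )


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full cohort: signals, metadata and the truth table.

    Fully deterministic given ``config`` (including its seed): the master
    seed sequence spawns one stream for trait/demographic draws and one per
    subject for signals, so per-subject output does not depend on cohort
    size ordering quirks.
    """
    config.validate()
    master = np.random.SeedSequence(config.seed)
    cohort_ss, *subject_ss = master.spawn(1 + config.n_subjects)
    cohort_rng = np.random.default_rng(cohort_ss)

    scores = draw_trait_scores(config.trait_model, config.n_subjects, cohort_rng)
    maps, is_high = realized_kappas(config, scores)
    demo = _draw_demographics(cohort_rng, config.n_subjects)

    subjects = [f"sub-{i:03d}" for i in range(config.n_subjects)]
    signals = [
        simulate_subject_signals(config, maps[s], np.random.default_rng(subject_ss[s]))
        for s in range(config.n_subjects)
    ]

    metadata = pd.DataFrame(
        {
            "subject": subjects,
            "mwq_total": scores,
            "age": demo["age"],
            "sex": demo["sex"],
            "education": demo["education"],
            "spm_pr": demo["spm_pr"],
        }
    )
    truth_rows = []
    for s, subject in enumerate(subjects):
        for (edge, band), (kappa, lag) in maps[s].items():
            truth_rows.append(
                (subject, edge[0], edge[1], band, kappa, "High" if is_high[s] else "Low")
            )
    truth = pd.DataFrame(
        truth_rows, columns=["subject", "roi_i", "roi_j", "band", "kappa", "group"]
    )
    return SyntheticCohort(signals, metadata, truth, config)


def signature_couplings(atlas: NetworkAtlas | None = None) -> tuple[CouplingSpec, ...]:
    """The default planted connectivity signature.

    Mirrors the qualitative pattern the pipeline is meant to detect:
    within-DMN coupling in slow bands (delta/theta) *lower* in the
    High-trait group with negative trait slopes, and sensorimotor /
    cingulo-opercular / cross-network coupling in faster bands *higher* in
    the High group with positive slopes.  Baseline strengths are typical
    published group-mean PLV magnitudes for such edges.
    """
    atl = atlas or default_atlas()
    idx = atl.index_of

    def e(a: str, b: str) -> tuple[int, int]:
        i, j = idx(a), idx(b)
        return (min(i, j), max(i, j))

    return (
        # intra-DMN, slow bands: High < Low, negative trait slope
        CouplingSpec(e("Cingulate_Post L", "Precuneus L"), "delta", 0.76, 0.64, -0.05),
        CouplingSpec(e("Cingulate_Post R", "Frontal_Sup_Medial R"), "delta", 0.39, 0.24, -0.05),
        CouplingSpec(e("Frontal_Med_Orb R", "ParaHippocampal R"), "theta", 0.39, 0.23, -0.05),
        CouplingSpec(e("Parietal_Inf R", "Temporal_Mid L"), "theta", 0.31, 0.19, -0.05),
        # intra-SMN / intra-CON, fast bands: High > Low, positive slope
        CouplingSpec(e("Postcentral R", "Precentral R"), "beta", 0.78, 0.85, 0.05),
        CouplingSpec(e("Postcentral R", "Precentral R"), "gamma", 0.69, 0.80, 0.05),
        CouplingSpec(e("Cingulate_Mid L", "Frontal_Inf_Oper R"), "gamma", 0.13, 0.25, 0.05),
        # inter-network: High > Low, positive slope
        CouplingSpec(e("Frontal_Inf_Oper R", "Frontal_Sup L"), "delta", 0.19, 0.36, 0.05),
        CouplingSpec(e("Cingulate_Ant L", "Cingulate_Post R"), "delta", 0.31, 0.48, 0.05),
        CouplingSpec(e("Frontal_Sup L", "Thalamus L"), "theta", 0.46, 0.63, 0.05),
        CouplingSpec(e("Frontal_Sup_Medial L", "Rolandic_Oper L"), "alpha", 0.19, 0.31, 0.05),
    )


def signature_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Desk-scale cohort config carrying the planted signature."""
    cfg = SimulationConfig(couplings=signature_couplings(), seed=seed)
    return replace(cfg, **overrides) if overrides else cfg
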
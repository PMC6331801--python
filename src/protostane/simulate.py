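"""Synthetic instrument data with known ground truth.

Every input the pipeline consumes can be generated here: QTOF feature sets
(accurate masses with ppm-scale Gaussian error, fragment subsets with
Bernoulli dropout), MRM batch areas following the packaged linear
calibrations with multiplicative noise, dilution ladders with an analytically
known signal-to-noise curve, and full method-validation replicate sets.

All generators are pure functions of their inputs and a seed: one global
seed expands into independent per-stage substreams
(:func:`numpy.random.SeedSequence.spawn`), so any stage can be regenerated
on its own and identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

from .annotate import FeatureRecord, FragmentPeak, LibraryEntry
from .chem import HYDROGEN_ATOM, AdductConvention, mz_protonated
from .quant import AreaMeasurement, CalibrationCurve, ContentMatrix, DilutionSeries
from .validation import ValidationDesign

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_qtof_features",
    "generate_content_matrix",
    "simulate_mrm_batch",
    "simulate_dilution_series",
    "simulate_validation_arms",
]


@dataclass(frozen=True)
class SimConfig:
    """Noise model and design parameters of the simulator.

    Defaults mirror the performance envelope of the emulated instruments:
    ~2 ppm MS1 mass error and looser fragment accuracy for the QTOF, ~5%
    multiplicative area noise for the QqQ, and lognormal between-batch
    content variation of ~30%.
    """

    seed: int = 0
    ms1_sigma_ppm: float = 2.0
    fragment_sigma_ppm: float = 5.0
    fragment_dropout_prob: float = 0.2
    rt_jitter_min: float = 0.1
    area_cv: float = 0.05
    is_area_mean: float = 1.0e5
    is_area_cv: float = 0.05
    content_lognormal_cv: float = 0.3
    n_samples_per_group: int = 21
    n_replicates: int = 3
    group_effect: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.fragment_dropout_prob <= 1:
            raise ValueError("dropout probability must be in [0, 1]")
        if min(self.ms1_sigma_ppm, self.fragment_sigma_ppm, self.area_cv,
               self.is_area_cv, self.content_lognormal_cv) < 0:
            raise ValueError("noise scales must be non-negative")

    def substream(self, stage: int) -> np.random.Generator:
        """Independent RNG stream for one pipeline stage."""
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(stage + 1)[stage])


@dataclass(frozen=True)
class GroundTruth:
    """Truth emitted alongside every simulated dataset."""

    seed: int
    feature_compounds: tuple[str, ...] = ()
    true_contents: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        out: dict = {"seed": self.seed, "feature_compounds": list(self.feature_compounds)}
        if self.true_contents is not None:
            # NaN (ND cells) -> null so the side-car is strict JSON
            tc = self.true_contents.astype(object).where(self.true_contents.notna(), None)
            out["true_contents"] = tc.to_dict()
        return out


def simulate_qtof_features(
    library: tuple[LibraryEntry, ...] | list[LibraryEntry],
    cfg: SimConfig = SimConfig(),
    conv: AdductConvention = HYDROGEN_ATOM,
) -> tuple[list[FeatureRecord], GroundTruth]:
    """One noisy feature per library entry.

    Precursor m/z is the theoretical [M+H]+ perturbed by Normal(0,
    ms1_sigma_ppm) relative error; fragments are the entry's expected ions
    with per-peak ppm jitter and Bernoulli dropout; retention time gets
    uniform jitter within ±``rt_jitter_min``; the UV maximum is copied from
    the entry.
    """
    if not library:
        raise ValueError("library must not be empty")
    rng = cfg.substream(0)
    features = []
    truth = []
    for entry in library:
        theo = mz_protonated(entry.formula, conv)
        precursor = theo * (1 + rng.normal(0.0, cfg.ms1_sigma_ppm) * 1e-6)
        frags = []
        for mz in entry.expected_fragments:
            jittered = mz * (1 + rng.normal(0.0, cfg.fragment_sigma_ppm) * 1e-6)
            dropped = rng.random() < cfg.fragment_dropout_prob
            if not dropped:
                frags.append(FragmentPeak(jittered, intensity=float(rng.uniform(1e3, 1e5))))
        rt = entry.retention_time + rng.uniform(-cfg.rt_jitter_min, cfg.rt_jitter_min)
        features.append(
            FeatureRecord(
                retention_time=rt,
                precursor_mz=precursor,
                fragments=tuple(frags),
                uv_lambda_max=entry.uv_lambda_max,
                feature_id=f"sim-{entry.peak}",
            )
        )
        truth.append(entry.name)
    return features, GroundTruth(cfg.seed, feature_compounds=tuple(truth))


def generate_content_matrix(
    template: ContentMatrix, cfg: SimConfig = SimConfig()
) -> ContentMatrix:
    """Draw a synthetic batch of contents shaped like a template matrix.

    Per analyte and origin group, samples are lognormal around the
    template's group mean (ND-excluded) with coefficient of variation
    ``content_lognormal_cv``; an optional per-analyte ``group_effect``
    ratio rescales the second group's means.  Group sizes come from
    ``n_samples_per_group``.
    """
    rng = cfg.substream(1)
    groups = list(dict.fromkeys(template.origins))
    analytes = template.analytes
    rows, origins, ids = [], [], []
    sigma = float(np.sqrt(np.log1p(cfg.content_lognormal_cv**2)))
    base_means = template.values[template.origins == groups[0]].mean()
    for gi, g in enumerate(groups):
        if gi > 0 and cfg.group_effect:
            # explicit effect: second group = first-group means x ratio
            means = base_means * pd.Series(
                {a: cfg.group_effect.get(a, 1.0) for a in analytes}
            )
        else:
            means = template.values[template.origins == g].mean()
        for i in range(cfg.n_samples_per_group):
            mu = np.log(means.to_numpy()) - sigma**2 / 2
            rows.append(np.exp(rng.normal(mu, sigma)))
            origins.append(g)
            ids.append(f"{g[:2].upper()}{i + 1:02d}")
    values = pd.DataFrame(rows, index=ids, columns=analytes)
    nd = pd.DataFrame(False, index=ids, columns=analytes)
    return ContentMatrix(values, nd, pd.Series(origins, index=ids, name="origin"))


def simulate_mrm_batch(
    curves: dict[str, CalibrationCurve],
    true_contents: ContentMatrix,
    cfg: SimConfig = SimConfig(),
) -> tuple[list[AreaMeasurement], GroundTruth]:
    """Replicate MRM areas reproducing a known content matrix.

    For each sample × analyte × replicate the injected concentration is the
    inverse of the content conversion (content / 0.25 at the default
    preparation constants), the area ratio follows the analyte's calibration
    line, and the analyte area is that ratio times a per-injection IS area,
    with independent multiplicative Gaussian noise on both.  ND (missing)
    cells of the truth are not measured.
    """
    rng = cfg.substream(2)
    areas: list[AreaMeasurement] = []
    for sid in true_contents.sample_ids:
        for analyte in true_contents.analytes:
            if analyte not in curves:
                raise KeyError(f"no calibration curve for analyte {analyte!r}")
            content = true_contents.values.loc[sid, analyte]
            if np.isnan(content):
                continue
            x = content / 0.25  # invert content_mg_per_g at default prep constants
            curve = curves[analyte]
            if curve.linear_range is not None and not (
                curve.linear_range[0] <= x <= curve.linear_range[1]
            ):
                logger.warning(
                    "%s in %s: %.3f ug/mL outside linear range %s; generated anyway",
                    analyte, sid, x, curve.linear_range,
                )
            y = curve.slope * x + curve.intercept
            for rep in range(1, cfg.n_replicates + 1):
                is_area = cfg.is_area_mean * (1 + rng.normal(0.0, cfg.is_area_cv))
                area = max(y, 0.0) * is_area * (1 + rng.normal(0.0, cfg.area_cv))
                areas.append(
                    AreaMeasurement(sid, analyte, max(area, 0.0), is_area, replicate=rep)
                )
    return areas, GroundTruth(cfg.seed, true_contents=true_contents.values.copy())


def simulate_dilution_series(
    analyte: str,
    response_per_ug_ml: float,
    noise_floor: float,
    cfg: SimConfig = SimConfig(),
    start_conc_ug_ml: float = 1.0,
    n_levels: int = 12,
) -> DilutionSeries:
    """Two-fold dilution ladder with analytically known S/N.

    The noise-free signal is ``response × concentration`` over a constant
    noise floor, so S/N = response·c/noise_floor and the exact S/N = 3
    crossing sits at ``3·noise_floor/response``.  Multiplicative Gaussian
    noise at ``area_cv`` perturbs the measured signals.
    """
    if noise_floor <= 0:
        raise ValueError("noise floor must be positive")
    rng = cfg.substream(3)
    points = []
    conc = start_conc_ug_ml
    for _ in range(n_levels):
        signal = response_per_ug_ml * conc * (1 + rng.normal(0.0, cfg.area_cv))
        points.append((conc, max(signal, 0.0), noise_floor))
        conc /= 2.0
    return DilutionSeries(analyte, tuple(points))


def simulate_validation_arms(
    true_contents_mg_g: dict[str, float],
    cfg: SimConfig = SimConfig(),
    design: ValidationDesign = ValidationDesign(),
    measurement_cv: float = 0.02,
    stability_drift_per_24h: float = 0.0,
    spike_fraction: float = 1.0,
) -> dict[str, dict[str, list]]:
    """Measurement sets for all validation arms, with known truth.

    Every measured value is the analyte's true content times multiplicative
    Gaussian noise at ``measurement_cv``.  Stability measurements can decay
    linearly by ``stability_drift_per_24h`` over the 24 h window; the
    recovery arm spikes at ``spike_fraction`` of native content.  The return
    value plugs directly into :func:`protostane.validation.validation_report`.
    """
    rng = cfg.substream(4)
    noisy = lambda true, n: [float(true * (1 + rng.normal(0.0, measurement_cv))) for _ in range(n)]
    arms: dict[str, dict[str, list]] = {
        "intra_day": {},
        "inter_day": {},
        "repeatability": {},
        "stability": {},
        "recovery": {},
    }
    for analyte, true in true_contents_mg_g.items():
        arms["intra_day"][analyte] = noisy(true, design.intra_day_n)
        arms["inter_day"][analyte] = noisy(
            true, design.inter_day_per_day * design.inter_day_days
        )
        arms["repeatability"][analyte] = noisy(true, design.repeatability_n)
        arms["stability"][analyte] = [
            float(
                true
                * (1 - stability_drift_per_24h * t / 24.0)
                * (1 + rng.normal(0.0, measurement_cv))
            )
            for t in design.stability_timepoints_h
        ]
        added = spike_fraction * true
        arms["recovery"][analyte] = [
            (float((true + added) * (1 + rng.normal(0.0, measurement_cv))), true, added)
            for _ in range(design.recovery_n)
        ]
    return arms
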
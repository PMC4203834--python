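"""Synthetic instrument-plate generation with controlled statistical
structure.

Real COPAS/BioSorter runs cannot ship with a software package, so every
other module is exercised against plates generated here.  The default
organism model draws TOF (length) from a lognormal with a well-level
random effect, makes EXT proportional to TOF with multiplicative noise —
giving the monotone TOF/EXT cloud characteristic of real worm data — and
draws fluorescence from gamma distributions.  Bubbles are short,
optically thin objects: small TOF and near-zero EXT, which is exactly
the axis on which the bubble classifier separates them.

Scenarios can add bubble contamination at a chosen fraction, deliberately
empty wells, an edge gradient (an additive shift on edge-well means,
parameterized in SD units of the well-mean distribution, for calibrated
power studies of the edge-effect test) and per-well trait multipliers
(for strain-by-dose layouts).  Every draw is driven by the scenario seed,
so the same scenario yields byte-identical files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidScenarioError
from .io_copas import RawPlate, plate_from_records, write_plate
from .summarize import SummarizedPlate
from .wells import ALL_WELL_LABELS, WellID

FLUOR_CHANNELS = ("green", "yellow", "red")


@dataclass(frozen=True)
class PlateScenario:
    """Parameters of one synthetic plate.

    Trait units follow the instrument: TOF and EXT in arbitrary integrated
    instrument units.  ``edge_effect_sd`` shifts the TOF well means of
    edge wells upward by that many SDs of the well-mean distribution; 0
    means a null (exchangeable-wells) plate.
    """

    seed: int = 0
    #: mean objects per well (Poisson), or exact count if ``fixed_n``
    n_per_well: int = 30
    fixed_n: bool = False
    #: organism TOF: lognormal, median ``tof_median``, object-level CV ~ ``tof_cv``
    tof_median: float = 300.0
    tof_cv: float = 0.15
    #: well-level SD of log-mean TOF (well-to-well variation)
    well_sd: float = 0.05
    #: edge-well shift in units of the well-mean SD
    edge_effect_sd: float = 0.0
    edge_depth: int = 1
    #: EXT = ext_per_tof * TOF * lognormal noise
    ext_per_tof: float = 0.5
    ext_noise: float = 0.1
    fluor_shape: float = 2.0
    fluor_scale: tuple[float, float, float] = (15.0, 10.0, 5.0)
    #: contamination
    bubble_fraction: float = 0.0
    bubble_tof: tuple[float, float] = (40.0, 10.0)
    bubble_ext: tuple[float, float] = (5.0, 2.0)
    bubble_fluor_shape: float = 1.0
    bubble_fluor_scale: tuple[float, float, float] = (1.0, 1.0, 1.0)
    #: pure-plate (two-plate training protocol) organism model
    organism_tof: tuple[float, float] = (300.0, 30.0)
    organism_ext: tuple[float, float] = (150.0, 20.0)
    empty_wells: tuple[str, ...] = ()
    #: optional per-well multiplier on the TOF well mean (strain/dose layouts)
    well_tof_multiplier: dict[str, float] = field(default_factory=dict, hash=False)
    #: optional per-well multiplier on the expected population size
    well_n_multiplier: dict[str, float] = field(default_factory=dict, hash=False)
    #: well-mean model used by :func:`generate_summarized_plate`
    summary_well_mean: float = 300.0
    summary_well_sd: float = 15.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.bubble_fraction <= 1.0:
            raise InvalidScenarioError(f"bubble_fraction must be in [0,1], got {self.bubble_fraction}")
        for name in ("n_per_well", "tof_median", "ext_per_tof", "summary_well_sd"):
            if getattr(self, name) <= 0:
                raise InvalidScenarioError(f"{name} must be positive")
        for name in ("tof_cv", "well_sd", "ext_noise"):
            if getattr(self, name) < 0:
                raise InvalidScenarioError(f"{name} must be nonnegative")
        for w in self.empty_wells:
            WellID.from_string(w)  # raises InvalidWellError on bad labels


@dataclass
class GroundTruth:
    """What the generator actually did, for use as a test oracle."""

    objects: pd.DataFrame  # object_id, well, is_bubble
    wells: pd.DataFrame  # well, n_organisms, n_bubbles, tof_well_mean

    @property
    def n_bubbles(self) -> int:
        return int(self.objects["is_bubble"].sum())


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Normal draws resampled (not clipped) to be strictly positive."""
    out = rng.normal(mean, sd, size)
    bad = out <= 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out <= 0
    return out


def _fluorescence(rng: np.random.Generator, scenario: PlateScenario, size: int) -> dict[str, np.ndarray]:
    return {
        ch: rng.gamma(scenario.fluor_shape, scale, size)
        for ch, scale in zip(FLUOR_CHANNELS, scenario.fluor_scale)
    }


def generate_plate(
    scenario: PlateScenario,
    path: str | Path | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[RawPlate, GroundTruth]:
    """Generate one plate of per-object records plus its ground truth.

    Organisms are drawn per well around a well-level TOF mean; bubbles are
    interleaved at ``scenario.bubble_fraction``; wells listed in
    ``empty_wells`` produce no records.  With ``path`` the plate is also
    written as a canonical-dialect instrument file.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    meanlog = math.log(scenario.tof_median)
    records: list[dict] = []
    truth_obj: list[dict] = []
    truth_wells: list[dict] = []
    empty = set(scenario.empty_wells)
    oid = 0
    for well in ALL_WELL_LABELS:
        if well in empty:
            continue
        w = WellID.from_string(well)
        shift = 0.0
        if scenario.edge_effect_sd and w.is_edge(scenario.edge_depth):
            shift = scenario.edge_effect_sd * scenario.well_sd
        well_meanlog = (
            meanlog
            + rng.normal(0.0, scenario.well_sd)
            + shift
            + math.log(scenario.well_tof_multiplier.get(well, 1.0))
        )
        lam = scenario.n_per_well * scenario.well_n_multiplier.get(well, 1.0)
        n = int(round(lam)) if scenario.fixed_n else int(rng.poisson(lam))
        n_bub = int(rng.binomial(n, scenario.bubble_fraction)) if n else 0
        n_org = n - n_bub
        tof = np.exp(rng.normal(well_meanlog, scenario.tof_cv, n_org))
        ext = scenario.ext_per_tof * tof * np.exp(rng.normal(0.0, scenario.ext_noise, n_org))
        fluor = _fluorescence(rng, scenario, n_org)
        btof = _truncated_normal(rng, *scenario.bubble_tof, n_bub)
        bext = _truncated_normal(rng, *scenario.bubble_ext, n_bub)
        bfluor = {
            ch: rng.gamma(scenario.bubble_fluor_shape, s, n_bub)
            for ch, s in zip(FLUOR_CHANNELS, scenario.bubble_fluor_scale)
        }
        is_bubble = np.concatenate([np.zeros(n_org, bool), np.ones(n_bub, bool)])
        all_tof = np.concatenate([tof, btof])
        all_ext = np.concatenate([ext, bext])
        all_fluor = {ch: np.concatenate([fluor[ch], bfluor[ch]]) for ch in FLUOR_CHANNELS}
        order = rng.permutation(n)
        for i in order:
            oid += 1
            records.append(
                {
                    "object_id": oid,
                    "well": well,
                    "sort_status": 0,
                    "tof": float(all_tof[i]),
                    "ext": float(all_ext[i]),
                    **{ch: float(all_fluor[ch][i]) for ch in FLUOR_CHANNELS},
                }
            )
            truth_obj.append({"object_id": oid, "well": well, "is_bubble": bool(is_bubble[i])})
        truth_wells.append(
            {
                "well": well,
                "n_organisms": n_org,
                "n_bubbles": n_bub,
                "tof_well_mean": math.exp(well_meanlog + scenario.tof_cv**2 / 2),
            }
        )
    plate = plate_from_records(records, source=str(path) if path else f"synthetic(seed={scenario.seed})")
    truth = GroundTruth(
        objects=pd.DataFrame(truth_obj, columns=["object_id", "well", "is_bubble"]),
        wells=pd.DataFrame(truth_wells, columns=["well", "n_organisms", "n_bubbles", "tof_well_mean"]),
    )
    if path is not None:
        write_plate(plate, path)
    return plate, truth


def generate_training_pair(
    scenario: PlateScenario, n_each: int = 500
) -> tuple[RawPlate, RawPlate]:
    """Emulate the two-plate classifier-training protocol.

    The object plate holds only organism-model records (bubble trap
    engaged); the bubble plate only bubble-model records (trap
    disengaged).  Organism TOF/EXT use the pure-plate normal model
    (``organism_tof``, ``organism_ext``); both plates spread their records
    round-robin across the 96 wells.  Seeds for the two plates are derived
    independently from the scenario seed.
    """
    root = np.random.SeedSequence(scenario.seed)
    rng_obj, rng_bub = (np.random.default_rng(s) for s in root.spawn(2))

    def _records(rng: np.random.Generator, tof_mu_sd, ext_mu_sd, fluor_fn) -> list[dict]:
        tof = _truncated_normal(rng, *tof_mu_sd, n_each)
        ext = _truncated_normal(rng, *ext_mu_sd, n_each)
        if float(np.std(tof)) == 0.0 or float(np.std(ext)) == 0.0:
            import warnings

            warnings.warn("training scenario has zero trait variation", stacklevel=3)
        fluor = fluor_fn(rng)
        return [
            {
                "object_id": i + 1,
                "well": ALL_WELL_LABELS[i % 96],
                "tof": float(tof[i]),
                "ext": float(ext[i]),
                **{ch: float(fluor[ch][i]) for ch in FLUOR_CHANNELS},
            }
            for i in range(n_each)
        ]

    obj_records = _records(
        rng_obj,
        scenario.organism_tof,
        scenario.organism_ext,
        lambda rng: _fluorescence(rng, scenario, n_each),
    )
    bub_records = _records(
        rng_bub,
        scenario.bubble_tof,
        scenario.bubble_ext,
        lambda rng: {
            ch: rng.gamma(scenario.bubble_fluor_shape, s, n_each)
            for ch, s in zip(FLUOR_CHANNELS, scenario.bubble_fluor_scale)
        },
    )
    return (
        plate_from_records(obj_records, source="synthetic-objects"),
        plate_from_records(bub_records, source="synthetic-bubbles"),
    )


def generate_summarized_plate(
    scenario: PlateScenario, rng: np.random.Generator | None = None
) -> SummarizedPlate:
    """Draw a plate directly at the well level (one mean TOF per well).

    The per-well mean is N(summary_well_mean, summary_well_sd), with edge
    wells shifted by ``edge_effect_sd`` well-mean SDs.  This is the exact
    sampling model of the edge-effect test's exchangeable units, so null
    and power simulations can run thousands of plates cheaply.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    empty = set(scenario.empty_wells)
    rows = []
    for well in ALL_WELL_LABELS:
        if well in empty:
            continue
        w = WellID.from_string(well)
        shift = (
            scenario.edge_effect_sd * scenario.summary_well_sd
            if scenario.edge_effect_sd and w.is_edge(scenario.edge_depth)
            else 0.0
        )
        rows.append(
            {
                "well": well,
                "n": int(rng.poisson(scenario.n_per_well)),
                "mean_tof": float(
                    rng.normal(scenario.summary_well_mean + shift, scenario.summary_well_sd)
                ),
            }
        )
    return SummarizedPlate(
        data=pd.DataFrame(rows), source=f"synthetic-summary(seed={scenario.seed})"
    )


def null_scenario(seed: int = 0) -> PlateScenario:
    """Exchangeable-wells scenario (no edge gradient)."""
    return PlateScenario(seed=seed, edge_effect_sd=0.0)


def edge_scenario(effect_sd: float, seed: int = 0) -> PlateScenario:
    """Scenario with an edge gradient of ``effect_sd`` well-mean SDs."""
    return PlateScenario(seed=seed, edge_effect_sd=effect_sd)


def dose_response_scenario(
    seed: int = 0,
    strains: tuple[str, ...] = ("N2", "CB4856", "JU258", "DL238"),
    doses: tuple[float, ...] = (0.0, 2.5, 5.0, 10.0, 20.0),
    max_inhibition: float = 0.6,
) -> tuple[PlateScenario, list[str], list[float]]:
    """A four-strain, five-dose layout with strain-specific dose effects.

    Strains occupy pairs of rows in blocks; each column pair gets one
    dose.  Higher doses shrink TOF (and population size) multiplicatively,
    with strain-specific sensitivity, giving monotone dose-response curves
    for the summarizer and plots to recover.  Returns the scenario plus
    the 96-element strain and dose vectors in row-major order.
    """
    n_s, n_d = len(strains), len(doses)
    if n_s * n_d > 96:
        raise InvalidScenarioError("too many strain x dose combinations for one plate")
    strain_vec: list[str] = []
    dose_vec: list[float] = []
    for idx, well in enumerate(ALL_WELL_LABELS):
        r, c = divmod(idx, 12)
        strain_vec.append(strains[(r // 2) % n_s])
        dose_vec.append(doses[min(c // 2, n_d - 1)])
    tof_mult: dict[str, float] = {}
    n_mult: dict[str, float] = {}
    max_dose = max(doses) or 1.0
    for well, s, d in zip(ALL_WELL_LABELS, strain_vec, dose_vec):
        sensitivity = 0.5 + 0.5 * (strains.index(s) / max(1, n_s - 1))
        inhibition = max_inhibition * sensitivity * (d / max_dose)
        tof_mult[well] = 1.0 - inhibition
        n_mult[well] = max(0.1, 1.0 - inhibition)
    scenario = replace(
        PlateScenario(seed=seed),
        well_tof_multiplier=tof_mult,
        well_n_multiplier=n_mult,
    )
    return scenario, strain_vec, dose_vec
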
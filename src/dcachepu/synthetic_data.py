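"""Seeded generators for every input the pipeline consumes.

Three generators cover the pipeline's inputs at desk scale:

* planted-motif sequence cohorts with ground truth (emulating, at a few
  hundred sequences, the thousands of sensor-domain homologs a database
  search would return) plus taxonomy/architecture annotations;
* one-site ITC titration series computed from the same binding model the
  fitting code uses, with Gaussian noise and a constant dilution heat;
* two-state thermal melt curves on the 23–85 °C grid.

All generators are pure functions of (config, seed).  Decoy sequences are
rejection-sampled against the motif scanner itself, so a decoy never
contains an admissible motif instance and specificity checks are exact;
positives are likewise re-drawn until the scanner recovers exactly the
planted instance, so the truth table is authoritative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .binding_assays import (
    DEFAULT_CELL_VOLUME,
    MeltCurve,
    TitrationSeries,
    one_site_heats,
)
from .io_formats import AMINO_ACIDS, AnnotationTable, SequenceRecord
from .motif_model import MotifDefinition, MotifMatch, ScanParams, scan_linear

#: background residue frequencies approximating globular-domain composition
DCACHE_COMPOSITION = {
    "A": 0.082, "C": 0.012, "D": 0.055, "E": 0.062, "F": 0.040,
    "G": 0.072, "H": 0.022, "I": 0.060, "K": 0.058, "L": 0.092,
    "M": 0.022, "N": 0.042, "P": 0.048, "Q": 0.040, "R": 0.050,
    "S": 0.066, "T": 0.058, "V": 0.074, "W": 0.013, "Y": 0.032,
}

#: motif-variant frequencies observed across the experimentally tested panel
DEFAULT_VARIANT_WEIGHTS = {
    "YKWFN": 7 / 15,
    "YRWFN": 4 / 15,
    "YKWYN": 1 / 15,
    "YRWFD": 1 / 15,
    "FRFYN": 1 / 15,
    "YHWFN": 1 / 15,
}

DEFAULT_TAXONOMY_POOL = {
    "Bacteria;Pseudomonadota": 5 / 15,
    "Bacteria;Bacillota": 4 / 15,
    "Bacteria;Verrucomicrobiota": 3 / 15,
    "Bacteria;Campylobacterota": 1 / 15,
    "Bacteria;Actinomycetota": 1 / 15,
    "Bacteria;Cyanobacteriota": 1 / 15,
}

DEFAULT_ARCHITECTURE_POOL = {
    "dCache_1|MCPsignal": 4 / 15,
    "dCache_1|GGDEF|EAL": 1 / 15,
    "dCache_1|GGDEF": 4 / 15,
    "dCache_1|HisKA|HATPase_c": 3 / 15,
    "dCache_1|SpoIIE": 3 / 15,
}


@dataclass
class CohortConfig:
    """Conditions for a planted-motif sequence cohort."""

    n_positives: int = 100
    n_decoys: int = 1000
    motif: MotifDefinition = field(default_factory=MotifDefinition.default)
    variant_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_VARIANT_WEIGHTS)
    )
    spacing_jitter: int = 2  # max |offset| per gap, kept within the motif windows
    background: dict[str, float] = field(default_factory=lambda: dict(DCACHE_COMPOSITION))
    domain_length: tuple[int, int] = (180, 260)
    indel_rate: float = 0.0  # per-site flank indel probability
    taxonomy_pool: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TAXONOMY_POOL)
    )
    architecture_pool: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ARCHITECTURE_POOL)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name, weights in (
            ("variant_weights", self.variant_weights),
            ("taxonomy_pool", self.taxonomy_pool),
            ("architecture_pool", self.architecture_pool),
            ("background", self.background),
        ):
            total = sum(weights.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} weights sum to {total}, expected 1")
        if not 0 <= self.indel_rate <= 1:
            raise ValueError("indel_rate must be in [0, 1]")
        if self.n_positives + self.n_decoys < 1:
            raise ValueError("cohort must contain at least one sequence")
        for variant in self.variant_weights:
            if len(variant) != len(self.motif.positions):
                raise ValueError(f"variant {variant!r} length != motif positions")
            for ch, (name, allowed) in zip(variant, self.motif.positions):
                if ch not in allowed:
                    raise ValueError(f"variant {variant!r}: {ch} not allowed at {name}")
        span = len(self.motif.positions) + sum(hi for _, hi in self.motif.spacings) + 1
        if span >= self.domain_length[0]:
            raise ValueError(
                f"motif span {span} does not fit the minimum domain length "
                f"{self.domain_length[0]}"
            )


def _sample_background(rng: np.random.Generator, length: int, background: dict[str, float]) -> str:
    letters = list(background)
    probs = np.array([background[l] for l in letters])
    return "".join(rng.choice(letters, size=length, p=probs))


def _weighted_choice(rng: np.random.Generator, weights: dict[str, float]) -> str:
    keys = list(weights)
    probs = np.array([weights[k] for k in keys])
    return keys[int(rng.choice(len(keys), p=probs))]


def _plant_positive(
    rng: np.random.Generator, config: CohortConfig
) -> tuple[str, str, tuple[int, ...]]:
    """One positive sequence; returns (residues, variant, planted positions)."""
    motif = config.motif
    params = ScanParams(mode="linear", require_companion=motif.companion is not None)
    for _ in range(200):
        variant = _weighted_choice(rng, config.variant_weights)
        gaps = []
        for (lo, hi), center in zip(motif.spacings, motif.centers or []):
            j = int(rng.integers(-config.spacing_jitter, config.spacing_jitter + 1))
            gaps.append(int(np.clip(center + j, lo, hi)))
        span = len(variant) + sum(gaps)
        length = int(rng.integers(config.domain_length[0], config.domain_length[1] + 1))
        # companion sits one residue after its anchor; keep a tail margin
        start = int(rng.integers(1, length - span - 2))
        seq = list(_sample_background(rng, length, config.background))
        positions = []
        pos = start
        for k, ch in enumerate(variant):
            seq[pos - 1] = ch
            positions.append(pos)
            if k < len(gaps):
                pos += gaps[k] + 1
        if motif.companion is not None:
            anchor_idx = motif.names.index(motif.companion.anchor_name)
            cpos = positions[anchor_idx] + motif.companion.offset
            seq[cpos - 1] = sorted(motif.companion.residues)[
                int(rng.integers(len(motif.companion.residues)))
            ]
        residues = "".join(seq)
        if config.indel_rate > 0:
            residues = _apply_flank_indels(rng, residues, positions, config)
            # positions may have shifted; rescan below re-establishes them
            match = scan_linear(SequenceRecord("tmp", residues), motif, params)
            if match.matched and match.variant == variant:
                return residues, variant, match.positions_in_query
            continue
        match = scan_linear(SequenceRecord("tmp", residues), motif, params)
        if match.matched and match.variant == variant and tuple(positions) == match.positions_in_query:
            return residues, variant, tuple(positions)
    raise RuntimeError("could not construct a clean positive; check the configuration")


def _apply_flank_indels(
    rng: np.random.Generator, residues: str, positions: Sequence[int], config: CohortConfig
) -> str:
    """Random single-residue indels outside the planted motif span."""
    lo, hi = positions[0], positions[-1] + 2  # protect motif + companion
    out = []
    for i, ch in enumerate(residues, start=1):
        if lo <= i <= hi or rng.random() >= config.indel_rate:
            out.append(ch)
            continue
        if rng.random() < 0.5:  # deletion
            continue
        out.append(ch)  # insertion
        out.append(_sample_background(rng, 1, config.background))
    return "".join(out)


def _sample_decoy(rng: np.random.Generator, config: CohortConfig) -> str:
    """Background sequence verified motif-free by the scanner (rejection)."""
    motif = config.motif
    params = ScanParams(mode="linear", require_companion=motif.companion is not None)
    for _ in range(500):
        length = int(rng.integers(config.domain_length[0], config.domain_length[1] + 1))
        residues = _sample_background(rng, length, config.background)
        if not scan_linear(SequenceRecord("tmp", residues), motif, params).matched:
            return residues
    raise RuntimeError("rejection sampling failed to produce a motif-free decoy")


def simulate_cohort(
    config: CohortConfig, seed: int | None = None
) -> tuple[list[SequenceRecord], pd.DataFrame, AnnotationTable]:
    """Generate a planted-motif cohort with ground truth and annotations.

    Returns (sequences, truth table, annotation table).  The truth table
    has one row per sequence: protein_id, is_positive, variant, planted
    1-based positions ('|'-joined, empty for decoys).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sequences: list[SequenceRecord] = []
    truth_rows = []
    annotations = AnnotationTable()
    for i in range(config.n_positives):
        residues, variant, positions = _plant_positive(rng, config)
        pid = f"POS{i + 1:05d}"
        sequences.append(SequenceRecord(pid, residues))
        truth_rows.append(
            {
                "protein_id": pid,
                "is_positive": True,
                "variant": variant,
                "positions": "|".join(map(str, positions)),
            }
        )
        annotations.add(
            pid,
            _weighted_choice(rng, config.taxonomy_pool).split(";"),
            _weighted_choice(rng, config.architecture_pool).split("|"),
        )
    for i in range(config.n_decoys):
        pid = f"DEC{i + 1:05d}"
        sequences.append(SequenceRecord(pid, _sample_decoy(rng, config)))
        truth_rows.append(
            {"protein_id": pid, "is_positive": False, "variant": "-", "positions": ""}
        )
        annotations.add(
            pid,
            _weighted_choice(rng, config.taxonomy_pool).split(";"),
            _weighted_choice(rng, config.architecture_pool).split("|"),
        )
    truth = pd.DataFrame(
        truth_rows, columns=["protein_id", "is_positive", "variant", "positions"]
    )
    return sequences, truth, annotations


# ---------------------------------------------------------------------------
# assay generators


@dataclass
class ItcConfig:
    """Ground truth and protocol of a simulated titration.

    Protocol defaults follow a typical single-site experiment on this
    calorimeter class: a 1.6 µl lead-off injection then 27 × 12.8 µl of
    300 µM ligand into 18 µM protein in a 1.4 mL cell.
    """

    true_kd: float = 2.6e-6  # mol/L
    true_dh: float = -8.0  # kcal/mol
    true_n: float = 1.0
    cell_volume: float = DEFAULT_CELL_VOLUME
    cell_conc_M0: float = 18e-6
    syringe_conc_X0: float = 300e-6
    injection_volumes: list[float] = field(
        default_factory=lambda: [1.6e-6] + [12.8e-6] * 27
    )
    noise_sd: float = 0.0  # fraction of the maximum |raw heat|
    dilution_heat_ucal: float = -0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.true_kd, self.true_n, self.cell_volume, self.cell_conc_M0,
               self.syringe_conc_X0) <= 0:
            raise ValueError("physical quantities must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def simulate_itc(config: ItcConfig, seed: int | None = None) -> TitrationSeries:
    """Simulate raw per-injection heats from the one-site model plus noise."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    ndh = one_site_heats(
        config.cell_volume,
        config.cell_conc_M0,
        config.syringe_conc_X0,
        config.injection_volumes,
        config.true_n,
        1.0 / config.true_kd,
        config.true_dh,
    )  # kcal/mol injectant
    vols = np.asarray(config.injection_volumes)
    raw = ndh * config.syringe_conc_X0 * vols * 1e9  # kcal -> µcal
    noise_scale = config.noise_sd * float(np.max(np.abs(raw))) if raw.size else 0.0
    noise = rng.normal(0.0, noise_scale, raw.size) if noise_scale > 0 else 0.0
    raw = raw + config.dilution_heat_ucal + noise
    return TitrationSeries(
        cell_volume=config.cell_volume,
        cell_conc_M0=config.cell_conc_M0,
        syringe_conc_X0=config.syringe_conc_X0,
        injection_volumes=list(config.injection_volumes),
        raw_heats=list(raw),
        dilution_heats=config.dilution_heat_ucal,
    )


@dataclass
class MeltConfig:
    """Ground truth of a simulated two-state melt on the 23–85 °C grid."""

    true_tm: float = 55.0  # °C
    width: float = 1.0  # °C logistic steepness; 10–90% transition over ~4.4 °C
    amplitude: float = 1000.0
    baseline_intercept: float = 100.0
    baseline_slope: float = 0.5  # per °C, pre-transition drift
    post_slope: float = 0.0  # additional drift after unfolding
    noise_sd: float = 0.0  # fraction of amplitude
    t_start: float = 23.0
    t_end: float = 85.0
    t_step: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.t_start < self.true_tm < self.t_end:
            raise ValueError("true_tm must lie inside the temperature grid")
        if self.width <= 0 or self.t_step <= 0 or self.noise_sd < 0:
            raise ValueError("width and t_step must be positive, noise_sd >= 0")


def simulate_melt(config: MeltConfig, seed: int | None = None) -> MeltCurve:
    """F(T) = baseline(T) + amplitude·θ(T) + noise with two-state θ."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    t = np.arange(config.t_start, config.t_end + config.t_step / 2, config.t_step)
    theta = 1.0 / (1.0 + np.exp(-(t - config.true_tm) / config.width))
    f = (
        config.baseline_intercept
        + config.baseline_slope * t
        + config.amplitude * theta
        + config.post_slope * (t - config.true_tm) * theta
    )
    if config.noise_sd > 0:
        f = f + rng.normal(0.0, config.noise_sd * config.amplitude, t.size)
    return MeltCurve(t, f)
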
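"""Synthetic expression-matrix generator with stereotyped temporal archetypes.

Emulates a log2-scale microarray time course in which a subset of genes
follows one of eight named temporal shapes (A-H) on the design grid
(0, 1, 2, 3, 6, 24) hours while the remainder ("NULL" genes) is flat.
Each gene gets a baseline level, an amplitude in log2 units, and i.i.d.
Gaussian noise; an optional per-batch additive offset can be switched on.

Archetype vocabulary (unit-amplitude deviations from baseline):

========  ============================================================
label     shape on the 6-point grid
========  ============================================================
A         hyperacute transient up; peak 2 h, back near baseline by 24 h
B         acute transient up; peak 6 h, back near baseline by 24 h
C         delayed transient up; flat at 1 h, peak 6 h, return by 24 h
D         two peaks (2 h and 6 h) with a dip at 3 h, return by 24 h
E         progressive transient down; trough 6 h, partial recovery
F         progressive down; still decreasing at 24 h
G         steady transient down; low plateau 2-6 h, partial recovery
H         down at 1 h then up with maximum at 3-6 h, return by 24 h
NULL      flat (no time response)
========  ============================================================
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .design import DEFAULT_TIMEPOINTS_H, StudyDesign
from .errors import UserInputError

#: Unit-amplitude deviation from baseline at t = (0, 1, 2, 3, 6, 24) h.
ARCHETYPE_SHAPES: dict[str, tuple[float, ...]] = {
    "A": (0.0, 0.5, 1.0, 0.5, 0.2, 0.0),
    "B": (0.0, 0.3, 0.6, 0.8, 1.0, 0.1),
    "C": (0.0, 0.0, 0.3, 0.6, 1.0, 0.0),
    "D": (0.0, 0.5, 1.0, 0.4, 1.0, 0.0),
    "E": (0.0, -0.3, -0.5, -0.7, -1.0, -0.4),
    "F": (0.0, -0.2, -0.4, -0.5, -0.7, -1.0),
    "G": (0.0, -0.5, -1.0, -1.0, -1.0, -0.3),
    "H": (0.0, -0.5, 0.2, 0.8, 1.0, 0.0),
    "NULL": (0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
}

ARCHETYPE_LABELS: tuple[str, ...] = ("A", "B", "C", "D", "E", "F", "G", "H")

#: Published cluster sizes for the eight clinically interesting shapes.
PUBLISHED_ARCHETYPE_COUNTS: dict[str, int] = {
    "A": 58, "B": 231, "C": 37, "D": 120, "E": 71, "F": 6, "G": 83, "H": 40,
}

#: Fraction of the amplitude within which "transient" shapes sit at 24 h.
RETURN_TOLERANCE = 0.2

DEFAULT_AMPLITUDE = 1.5     # log2 units
DEFAULT_NOISE_SD = 0.25     # log2 units
DEFAULT_BASELINE_RANGE = (4.0, 12.0)  # log2 units


def archetype_profile(label: str, timepoints_h=DEFAULT_TIMEPOINTS_H) -> np.ndarray:
    """Unit-amplitude temporal shape of an archetype at the given hours.

    ``timepoints_h`` must be a subset of the canonical grid
    (0, 1, 2, 3, 6, 24); shapes are defined pointwise on that grid.
    """
    if label not in ARCHETYPE_SHAPES:
        raise UserInputError(
            f"unknown archetype label {label!r}; expected one of "
            f"{sorted(ARCHETYPE_SHAPES)}"
        )
    lookup = dict(zip(DEFAULT_TIMEPOINTS_H, ARCHETYPE_SHAPES[label]))
    try:
        return np.array([lookup[float(t)] for t in timepoints_h])
    except KeyError as exc:
        raise UserInputError(
            f"archetype shapes are defined at {DEFAULT_TIMEPOINTS_H} h only; "
            f"got timepoint {exc.args[0]}"
        ) from None


@dataclass
class SyntheticDataset:
    """A generated expression matrix plus its ground truth.

    Attributes
    ----------
    expression
        genes x samples log2 matrix (rows indexed by gene_id).
    samples
        Sample sheet with sample_id, animal, time_h, batch.
    truth
        One row per gene: gene_id, archetype, amplitude, baseline.
    noise_sd, seed
        Generation settings, kept for provenance.
    """

    expression: pd.DataFrame
    samples: pd.DataFrame
    truth: pd.DataFrame
    noise_sd: float
    seed: int
    design: StudyDesign


def _draw_amplitudes(amplitude_dist, n: int, rng: np.random.Generator) -> np.ndarray:
    if callable(amplitude_dist):
        amp = np.asarray(amplitude_dist(rng, n), dtype=float)
    elif np.isscalar(amplitude_dist):
        amp = np.full(n, float(amplitude_dist))
    else:
        lo, hi = amplitude_dist
        amp = rng.uniform(float(lo), float(hi), size=n)
    if np.any(amp < 0):
        raise UserInputError("amplitudes must be >= 0")
    return amp


def generate_dataset(
    design: StudyDesign | None = None,
    archetype_counts: Mapping[str, int] | None = None,
    n_null: int = 0,
    amplitude_dist: float | tuple[float, float] | Callable = DEFAULT_AMPLITUDE,
    noise_sd: float = DEFAULT_NOISE_SD,
    baseline_range: tuple[float, float] = DEFAULT_BASELINE_RANGE,
    batch_offsets: Mapping[str, float] | None = None,
    seed: int = 0,
) -> SyntheticDataset:
    """Simulate a log2 expression matrix under the study design.

    Each gene's expected value at time t is
    ``baseline + amplitude * shape(t)`` (plus the batch offset when
    configured); observed values add i.i.d. N(0, noise_sd^2) noise.
    Deterministic for a fixed seed.
    """
    design = design or StudyDesign()
    archetype_counts = dict(archetype_counts or {})
    for label, count in archetype_counts.items():
        if label not in ARCHETYPE_LABELS:
            raise UserInputError(f"unknown archetype label {label!r}")
        if count < 0:
            raise UserInputError(f"negative count for archetype {label}")
    if n_null < 0:
        raise UserInputError("n_null must be >= 0")
    if noise_sd < 0:
        raise UserInputError("noise_sd must be >= 0")

    rng = np.random.default_rng(seed)
    sheet = design.sample_sheet()
    times = sheet["time_h"].to_numpy()
    n_samples = len(sheet)

    labels: list[str] = []
    gene_ids: list[str] = []
    for label in ARCHETYPE_LABELS:
        count = archetype_counts.get(label, 0)
        labels += [label] * count
        gene_ids += [f"g{label}{i:04d}" for i in range(1, count + 1)]
    labels += ["NULL"] * n_null
    gene_ids += [f"gN{i:05d}" for i in range(1, n_null + 1)]
    n_genes = len(gene_ids)

    n_signal = n_genes - n_null
    amplitudes = np.zeros(n_genes)
    if n_signal:
        amplitudes[:n_signal] = _draw_amplitudes(amplitude_dist, n_signal, rng)
    baselines = rng.uniform(*baseline_range, size=n_genes)

    # expected value matrix: per-gene shape evaluated at each sample's time
    time_index = {t: i for i, t in enumerate(design.timepoints_h)}
    col_of_sample = np.array([time_index[t] for t in times])
    shape_rows = np.array(
        [archetype_profile(lab, design.timepoints_h) for lab in labels]
    ) if n_genes else np.zeros((0, len(design.timepoints_h)))
    expected = baselines[:, None] + amplitudes[:, None] * shape_rows[:, col_of_sample]

    if batch_offsets:
        offs = np.array([float(batch_offsets.get(b, 0.0)) for b in sheet["batch"]])
        expected = expected + offs[None, :]

    values = expected
    if noise_sd > 0:
        values = expected + rng.normal(0.0, noise_sd, size=expected.shape)

    expression = pd.DataFrame(
        values, index=pd.Index(gene_ids, name="gene_id"),
        columns=sheet["sample_id"].tolist(),
    )
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "archetype": labels,
            "amplitude": amplitudes,
            "baseline": baselines,
        }
    )
    return SyntheticDataset(
        expression=expression, samples=sheet, truth=truth,
        noise_sd=float(noise_sd), seed=int(seed), design=design,
    )


def truth_table(dataset: SyntheticDataset) -> pd.DataFrame:
    """Ground-truth export: one row per gene (label, amplitude, baseline)."""
    return dataset.truth.copy()


def proportional_archetype_counts(n_signal: int) -> dict[str, int]:
    """Apportion ``n_signal`` genes across the archetypes in proportion to
    the published cluster sizes (largest-remainder rounding, ties broken
    by label order)."""
    if n_signal < 0:
        raise UserInputError("n_signal must be >= 0")
    weights = PUBLISHED_ARCHETYPE_COUNTS
    total = sum(weights.values())
    quotas = {k: n_signal * v / total for k, v in weights.items()}
    counts = {k: int(np.floor(q)) for k, q in quotas.items()}
    shortfall = n_signal - sum(counts.values())
    by_remainder = sorted(
        weights, key=lambda k: (counts[k] - quotas[k], k)
    )  # most negative first = largest fractional part
    for k in by_remainder[:shortfall]:
        counts[k] += 1
    return counts


def study_dataset(
    noise_sd: float = DEFAULT_NOISE_SD,
    amplitude: float = DEFAULT_AMPLITUDE,
    n_null: int = 0,
    seed: int = 0,
    n_signal: int | None = None,
) -> SyntheticDataset:
    """Convenience: default design with the published archetype composition.

    With ``n_signal=None`` the published counts (646 signal genes) are used
    verbatim; otherwise ``n_signal`` genes are apportioned proportionally.
    """
    if n_signal is None:
        counts = dict(PUBLISHED_ARCHETYPE_COUNTS)
    else:
        counts = proportional_archetype_counts(n_signal)
    return generate_dataset(
        StudyDesign(), counts, n_null=n_null,
        amplitude_dist=amplitude, noise_sd=noise_sd, seed=seed,
    )
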
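"""Core typed containers shared by every pipeline stage.

The containers enforce the structural invariants the method relies on:
unique probe/sample identifiers, explicit missing-value masks (never
numeric sentinels), beta values strictly inside [0, 1), and unit-norm
principal-axis loadings in the trained model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np


class DataError(ValueError):
    """Structural or semantic problem in input data."""


#: canonical chromosome labels for the sex chromosomes
CHR_X = "X"
CHR_Y = "Y"


def normalize_chromosome(label: str) -> str:
    """Normalize a chromosome label to its canonical form.

    ``"chrX"``, ``"X"``, ``"x"`` all map to ``"X"``; likewise for Y.
    Any other label (``"1"``..``"22"``, ``"chr7"``, ...) is treated as an
    autosome identifier with a ``chr`` prefix stripped.
    """
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if s.upper() in (CHR_X, CHR_Y):
        return s.upper()
    return s


def _check_unique(ids: Sequence[str], kind: str) -> None:
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise DataError(f"duplicate {kind} identifiers: {dups[:5]}")


@dataclass
class IntensityMatrix:
    """Paired methylated (M) / unmethylated (U) signal intensities.

    Both matrices are probes x samples, nonnegative where observed;
    missing entries are flagged in ``missing_mask``, never encoded as 0.
    """

    probe_ids: List[str]
    sample_ids: List[str]
    methylated: np.ndarray
    unmethylated: np.ndarray
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.probe_ids = list(self.probe_ids)
        self.sample_ids = list(self.sample_ids)
        _check_unique(self.probe_ids, "probe")
        _check_unique(self.sample_ids, "sample")
        self.methylated = np.asarray(self.methylated, dtype=float)
        self.unmethylated = np.asarray(self.unmethylated, dtype=float)
        shape = (len(self.probe_ids), len(self.sample_ids))
        if self.methylated.shape != shape or self.unmethylated.shape != shape:
            raise DataError(
                f"intensity shapes {self.methylated.shape}/{self.unmethylated.shape} "
                f"do not match {len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if self.missing_mask is None:
            self.missing_mask = ~(
                np.isfinite(self.methylated) & np.isfinite(self.unmethylated)
            )
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != shape:
            raise DataError("missing_mask shape mismatch")
        obs = ~self.missing_mask
        for name, arr in (("methylated", self.methylated), ("unmethylated", self.unmethylated)):
            vals = arr[obs]
            if not np.all(np.isfinite(vals)):
                raise DataError(f"non-finite observed {name} intensity")
            if np.any(vals < 0):
                p, s = np.argwhere((arr < 0) & obs)[0]
                raise DataError(
                    f"negative {name} intensity at probe {self.probe_ids[p]!r}, "
                    f"sample {self.sample_ids[s]!r}"
                )

    @property
    def shape(self) -> Tuple[int, int]:
        return len(self.probe_ids), len(self.sample_ids)


@dataclass
class BetaMatrix:
    """Probes x samples methylation ratios in [0, 1) with a missing mask."""

    probe_ids: List[str]
    sample_ids: List[str]
    values: np.ndarray
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.probe_ids = list(self.probe_ids)
        self.sample_ids = list(self.sample_ids)
        _check_unique(self.probe_ids, "probe")
        _check_unique(self.sample_ids, "sample")
        self.values = np.asarray(self.values, dtype=float)
        shape = (len(self.probe_ids), len(self.sample_ids))
        if self.values.shape != shape:
            raise DataError(
                f"beta shape {self.values.shape} does not match "
                f"{shape[0]} probes x {shape[1]} samples"
            )
        if self.missing_mask is None:
            self.missing_mask = ~np.isfinite(self.values)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != shape:
            raise DataError("missing_mask shape mismatch")
        obs = self.values[~self.missing_mask]
        if obs.size and (not np.all(np.isfinite(obs)) or obs.min() < 0 or obs.max() >= 1):
            bad = np.argwhere(
                ~self.missing_mask
                & (~np.isfinite(self.values) | (self.values < 0) | (self.values >= 1))
            )[0]
            raise DataError(
                f"beta value {self.values[bad[0], bad[1]]!r} out of [0, 1) at probe "
                f"{self.probe_ids[bad[0]]!r}, sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def shape(self) -> Tuple[int, int]:
        return len(self.probe_ids), len(self.sample_ids)

    @property
    def n_missing(self) -> int:
        return int(self.missing_mask.sum())

    def select_probes(self, probe_ids: Sequence[str]) -> "BetaMatrix":
        """Return the sub-matrix over ``probe_ids`` in the given order."""
        index = {p: i for i, p in enumerate(self.probe_ids)}
        rows = [index[p] for p in probe_ids]
        return BetaMatrix(
            list(probe_ids), self.sample_ids, self.values[rows], self.missing_mask[rows]
        )

    def select_samples(self, sample_ids: Sequence[str]) -> "BetaMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        cols = [index[s] for s in sample_ids]
        return BetaMatrix(
            self.probe_ids, list(sample_ids), self.values[:, cols], self.missing_mask[:, cols]
        )


@dataclass
class ProbeAnnotation:
    """Probe ID -> chromosome label; the basis for probe partitioning.

    Labels are normalized on construction. Partitions (autosomal / X / Y)
    are disjoint and exhaustive by construction: any label that is not
    ``"X"`` or ``"Y"`` counts as autosomal.
    """

    chromosome: Dict[str, str]

    def __post_init__(self) -> None:
        self.chromosome = {
            str(p): normalize_chromosome(c) for p, c in self.chromosome.items()
        }

    def __len__(self) -> int:
        return len(self.chromosome)

    def __contains__(self, probe_id: str) -> bool:
        return probe_id in self.chromosome

    def chromosome_of(self, probe_id: str) -> str:
        return self.chromosome[probe_id]

    def partition(self, probe_ids: Sequence[str]) -> Dict[str, List[str]]:
        """Split ``probe_ids`` into ``{"autosomal": [...], "X": [...], "Y": [...]}``.

        Order within each part follows the input order.
        """
        parts: Dict[str, List[str]] = {"autosomal": [], CHR_X: [], CHR_Y: []}
        for p in probe_ids:
            c = self.chromosome[p]
            key = c if c in (CHR_X, CHR_Y) else "autosomal"
            parts[key].append(p)
        return parts


VALID_SEX = ("female", "male", "unknown")


@dataclass
class SampleSheet:
    """Sample IDs with an optional labelled sex per sample."""

    sample_ids: List[str]
    labelled_sex: List[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        _check_unique(self.sample_ids, "sample")
        if self.labelled_sex is None:
            self.labelled_sex = ["unknown"] * len(self.sample_ids)
        self.labelled_sex = [str(s).strip().lower() for s in self.labelled_sex]
        if len(self.labelled_sex) != len(self.sample_ids):
            raise DataError("labelled_sex length does not match sample_ids")
        aliases = {"f": "female", "m": "male", "": "unknown", "na": "unknown", "nan": "unknown"}
        self.labelled_sex = [aliases.get(s, s) for s in self.labelled_sex]
        bad = sorted(set(self.labelled_sex) - set(VALID_SEX))
        if bad:
            raise DataError(f"unrecognized sex labels: {bad}")

    def sex_of(self, sample_id: str) -> str:
        return self.labelled_sex[self.sample_ids.index(sample_id)]

    def samples_with_sex(self, sex: str) -> List[str]:
        return [s for s, lab in zip(self.sample_ids, self.labelled_sex) if lab == sex]

    def subset(self, sample_ids: Sequence[str]) -> "SampleSheet":
        lut = dict(zip(self.sample_ids, self.labelled_sex))
        return SampleSheet(list(sample_ids), [lut[s] for s in sample_ids])


@dataclass
class ZScoreMatrix:
    """Per-sample standardized beta values (standardized on autosomal probes)."""

    probe_ids: List[str]
    sample_ids: List[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.probe_ids = list(self.probe_ids)
        self.sample_ids = list(self.sample_ids)
        _check_unique(self.probe_ids, "probe")
        _check_unique(self.sample_ids, "sample")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise DataError("z-score shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise DataError("z-score matrix contains non-finite values")

    def select_probes(self, probe_ids: Sequence[str]) -> "ZScoreMatrix":
        index = {p: i for i, p in enumerate(self.probe_ids)}
        rows = [index[p] for p in probe_ids]
        return ZScoreMatrix(list(probe_ids), self.sample_ids, self.values[rows])


@dataclass
class SexModel:
    """Trained two-axis classifier: one PC1 per sex chromosome.

    ``x_center``/``y_center`` are per-probe training means of Z-scores;
    ``x_loadings``/``y_loadings`` are unit-norm first principal axes;
    orientation signs fix the convention that females score higher on the
    ChrX axis and males score higher on the ChrY axis.
    """

    x_probe_ids: List[str]
    y_probe_ids: List[str]
    x_center: np.ndarray
    y_center: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    x_orientation_sign: int
    y_orientation_sign: int
    metadata: Dict[str, object] = field(default_factory=dict)

    UNIT_NORM_TOL = 1e-10

    def __post_init__(self) -> None:
        self.x_probe_ids = list(self.x_probe_ids)
        self.y_probe_ids = list(self.y_probe_ids)
        self.x_center = np.asarray(self.x_center, dtype=float)
        self.y_center = np.asarray(self.y_center, dtype=float)
        self.x_loadings = np.asarray(self.x_loadings, dtype=float)
        self.y_loadings = np.asarray(self.y_loadings, dtype=float)
        self.x_orientation_sign = int(self.x_orientation_sign)
        self.y_orientation_sign = int(self.y_orientation_sign)
        self.validate()

    def validate(self) -> None:
        _check_unique(self.x_probe_ids, "X-axis probe")
        _check_unique(self.y_probe_ids, "Y-axis probe")
        overlap = set(self.x_probe_ids) & set(self.y_probe_ids)
        if overlap:
            raise DataError(f"X and Y axis probe sets overlap: {sorted(overlap)[:5]}")
        for name, ids, center, load in (
            ("X", self.x_probe_ids, self.x_center, self.x_loadings),
            ("Y", self.y_probe_ids, self.y_center, self.y_loadings),
        ):
            if not (len(ids) == center.size == load.size):
                raise DataError(f"{name}-axis probe/center/loading lengths differ")
            norm = float(np.linalg.norm(load))
            if abs(norm - 1.0) > self.UNIT_NORM_TOL:
                raise DataError(f"{name}-axis loadings are not unit norm (|v|={norm!r})")
        if self.x_orientation_sign not in (-1, 1) or self.y_orientation_sign not in (-1, 1):
            raise DataError("orientation signs must be +1 or -1")


KARYOTYPES = ("46,XX", "46,XY", "45,XO", "47,XXY")


@dataclass
class SexPrediction:
    """One sample's scores on the two axes and the resulting calls."""

    sample_id: str
    x_score: float
    y_score: float
    karyotype_call: str
    predicted_sex: str  # female | male | aneuploid
    labelled_sex: Optional[str] = None  # female | male; None if unlabelled
    label_mismatch: Optional[bool] = None
    note: str = ""


def validate_aligned(
    beta: BetaMatrix, annotation: ProbeAnnotation
) -> Tuple[BetaMatrix, List[str]]:
    """Restrict ``beta`` to probes present in ``annotation``.

    Probe order of the input matrix is preserved. Returns the restricted
    matrix and the list of dropped (unannotated) probe IDs. Idempotent.

    Raises
    ------
    DataError
        If no probes overlap the annotation, or no autosomal probes remain
        (per-sample Z-scoring would be impossible).
    """
    if not beta.probe_ids or not len(annotation):
        raise DataError("empty beta matrix or annotation")
    keep = [p for p in beta.probe_ids if p in annotation]
    dropped = [p for p in beta.probe_ids if p not in annotation]
    if not keep:
        raise DataError("no probes in the beta matrix are covered by the annotation")
    parts = annotation.partition(keep)
    if not parts["autosomal"]:
        raise DataError(
            "no autosomal probes after annotation restriction; "
            "per-sample Z-score normalization is impossible"
        )
    if not parts[CHR_X] or not parts[CHR_Y]:
        warnings.warn(
            "annotation restriction leaves no ChrX or ChrY probes; "
            "training/prediction will not be possible on this matrix",
            stacklevel=2,
        )
    if not dropped:
        return beta, []
    return beta.select_probes(keep), dropped
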
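"""Thematic-map accuracy assessment.

Validation follows the standard remote-sensing protocol: stratified random
sampling of cells per mapped class, independent reference labelling, and a
confusion matrix with map classes on rows and reference classes on columns.
Derived statistics:

* user accuracy       UA_i = n_ii / n_i+   (commission complement, row-wise)
* producer accuracy   PA_j = n_jj / n_+j   (omission complement, column-wise)
* overall accuracy    OA   = sum_i n_ii / N
* Cohen's kappa       k    = (p_o - p_e) / (1 - p_e),
  with p_o = OA and chance agreement p_e = sum_i (n_i+ * n_+i) / N^2.

The package ships the 530-point validation sample of a Copernicus land-cover
map of Munich (12 classes) as a worked reference dataset; see
:func:`munich_confusion_matrix`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import numpy as np
import pandas as pd

from .errors import MatrixError, SamplingError
from .grid import CategoricalRaster
from .io import ValidationPoints


@dataclass
class ConfusionMatrix:
    """Square count table; rows = map (predicted) class, columns = reference."""

    labels: list
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise MatrixError(
                f"counts shape {self.counts.shape} does not match {k} labels")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.round(self.counts)):
                raise MatrixError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise MatrixError("counts must be non-negative")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)

    def transpose(self) -> "ConfusionMatrix":
        return ConfusionMatrix(list(self.labels), self.counts.T.copy())


def matrix_from_counts(rows: pd.DataFrame | np.ndarray,
                       labels: list | None = None) -> ConfusionMatrix:
    """Build a ConfusionMatrix from a labelled count table.

    A DataFrame must be square with identical row and column labels (order
    preserved); a plain array needs explicit ``labels``.
    """
    if isinstance(rows, pd.DataFrame):
        if list(rows.index) != list(rows.columns):
            raise MatrixError("count table must have identical row and column labels")
        return ConfusionMatrix(list(rows.index), rows.to_numpy())
    arr = np.asarray(rows)
    if labels is None:
        labels = list(range(arr.shape[0]))
    return ConfusionMatrix(list(labels), arr)


def munich_confusion_matrix() -> ConfusionMatrix:
    """The published 12-class, 530-point Munich validation sample."""
    with resources.files("urbanfuse.data").joinpath(
            "munich_validation_counts.csv").open() as fh:
        df = pd.read_csv(fh, index_col=0)
    return matrix_from_counts(df)


@dataclass
class AssessmentReport:
    """Accuracy statistics at full precision plus printed-precision rounding."""

    labels: list
    user_accuracy: pd.Series
    producer_accuracy: pd.Series
    overall_accuracy: float
    chance_agreement: float
    kappa: float | None
    n: int
    sample_design: dict = field(default_factory=dict)

    def rounded(self, overall_dp: int = 2, class_dp: int = 2) -> dict:
        """Half-up rounding to the conventional printed precision."""
        r = lambda v, dp: (None if v is None or not np.isfinite(v) else
                           float(Decimal(repr(float(v))).quantize(
                               Decimal(10) ** -dp, rounding=ROUND_HALF_UP)))
        return {
            "overall_accuracy": r(self.overall_accuracy, overall_dp),
            "kappa": r(self.kappa, overall_dp) if self.kappa is not None else None,
            "user_accuracy": {str(l): r(v, class_dp)
                              for l, v in self.user_accuracy.items()},
            "producer_accuracy": {str(l): r(v, class_dp)
                                  for l, v in self.producer_accuracy.items()},
            "n": self.n,
        }

    def to_dict(self) -> dict:
        return {
            "overall_accuracy": self.overall_accuracy,
            "chance_agreement": self.chance_agreement,
            "kappa": self.kappa,
            "n": self.n,
            "user_accuracy": {str(l): float(v) if np.isfinite(v) else None
                              for l, v in self.user_accuracy.items()},
            "producer_accuracy": {str(l): float(v) if np.isfinite(v) else None
                                  for l, v in self.producer_accuracy.items()},
            "rounded": self.rounded(),
            "sample_design": self.sample_design,
        }


def compute_report(cm: ConfusionMatrix) -> AssessmentReport:
    """User/producer/overall accuracy and Cohen's kappa for a count matrix.

    Per-class accuracies with a zero marginal are reported as NaN; kappa is
    None (undefined) in the degenerate case p_e = 1.
    """
    if cm.n == 0:
        raise MatrixError("empty confusion matrix")
    counts = cm.counts.astype(float)
    diag = np.diag(counts)
    with np.errstate(invalid="ignore", divide="ignore"):
        ua = diag / cm.row_totals
        pa = diag / cm.col_totals
    oa = float(diag.sum() / cm.n)
    pe = float((cm.row_totals * cm.col_totals).sum() / cm.n ** 2)
    kappa = None if pe >= 1.0 else float((oa - pe) / (1.0 - pe))
    return AssessmentReport(
        labels=list(cm.labels),
        user_accuracy=pd.Series(ua, index=cm.labels),
        producer_accuracy=pd.Series(pa, index=cm.labels),
        overall_accuracy=oa,
        chance_agreement=pe,
        kappa=kappa,
        n=cm.n,
    )


def build_matrix(points: ValidationPoints, classes: list) -> ConfusionMatrix:
    """Cross-tabulate labelled validation points into a confusion matrix."""
    idx = {label: i for i, label in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for _, row in points.table.iterrows():
        if pd.isna(row.ref_class):
            raise MatrixError("validation point without a reference label")
        for label, kind in ((row.map_class, "map"), (row.ref_class, "reference")):
            if label not in idx:
                raise MatrixError(f"{kind} label {label!r} not in the class list")
        counts[idx[row.map_class], idx[row.ref_class]] += 1
    return ConfusionMatrix(list(classes), counts)


def stratified_sample(raster: CategoricalRaster, per_class: dict[int, int],
                      seed: int) -> ValidationPoints:
    """Draw validation points by stratified random sampling without replacement.

    For every requested class, exactly that many distinct cells are drawn
    uniformly from the cells mapped to the class; each point sits at its cell
    centre.  Randomness comes from numpy's seeded PCG64 generator, so a fixed
    seed reproduces the exact point set on any platform.
    """
    rng = np.random.default_rng(seed)
    flat = raster.values.ravel()
    rows = []
    for cid in sorted(per_class):
        want = per_class[cid]
        pool = np.flatnonzero(flat == cid)
        if want > pool.size:
            raise SamplingError(
                f"class {cid}: requested {want} points but only {pool.size} cells")
        chosen = rng.choice(pool, size=want, replace=False)
        for lin in np.sort(chosen):
            r, c = divmod(int(lin), raster.grid.n_cols)
            x, y = raster.grid.cell_center(r, c)
            rows.append({"x": x, "y": y, "map_class": cid, "ref_class": pd.NA})
    df = pd.DataFrame(rows, columns=["x", "y", "map_class", "ref_class"])
    df["ref_class"] = df["ref_class"].astype("Int64")
    return ValidationPoints(df, crs_id=raster.grid.crs_id)


def proportional_allocation(raster: CategoricalRaster, total: int,
                            floor: int = 5) -> dict[int, int]:
    """Convenience allocator: per-class sizes proportional to mapped area.

    Every class present gets at least ``floor`` points (capped at its stratum
    size); the remainder is spread proportionally.
    """
    tally = {k: v for k, v in raster.tally().items() if k != raster.nodata_code}
    n_cells = sum(tally.values())
    alloc = {}
    for cid, cnt in sorted(tally.items()):
        want = max(floor, round(total * cnt / n_cells))
        alloc[cid] = min(want, cnt)
    return alloc
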
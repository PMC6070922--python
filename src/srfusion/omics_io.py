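"""I/O and alignment of omics matrices, survival tables and run configuration.

An omics *view* is one molecular layer (gene expression, DNA methylation
beta values, miRNA expression ...) measured on a shared set of patient
samples.  Views are held sample-major: rows are samples, columns are
features.  Files on disk conventionally store the transpose (rows =
features, columns = samples); both orientations are supported through an
explicit flag — auto-detection is deliberately refused as fragile.

Missing values are refused rather than imputed: imputation silently changes
the downstream Pearson similarities, and the method assumes complete
matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def _sniff_sep(path) -> str:
    """Tab vs comma, decided from the header line (text round-trips need the
    C parser, whose float parsing is exact, and it cannot sniff)."""
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


MIN_SAMPLES = 3  # Pearson correlation and per-pair regression need >= 3 shared samples


@dataclass
class OmicsView:
    """One omics feature matrix over the shared sample set.

    Parameters
    ----------
    name : str
        Short identifier, e.g. ``"mrna"``.
    samples : list of str
        Ordered sample ids (length n).
    features : list of str
        Ordered feature ids (length m).
    values : ndarray of shape (n, m)
        Numeric matrix, sample-major.
    """

    name: str
    samples: list[str]
    features: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, m = self.values.shape
        if n != len(self.samples) or m != len(self.features):
            raise ValueError(
                f"view {self.name!r}: matrix shape {self.values.shape} does not match "
                f"{len(self.samples)} samples x {len(self.features)} features"
            )
        if len(set(self.samples)) != n:
            raise ValueError(f"view {self.name!r}: duplicate sample ids")
        if len(set(self.features)) != m:
            raise ValueError(f"view {self.name!r}: duplicate feature ids")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"view {self.name!r}: non-finite value at sample "
                f"{self.samples[bad[0]]!r}, feature {self.features[bad[1]]!r}; "
                "missing values are refused (impute upstream if you must)"
            )
        if n < MIN_SAMPLES:
            raise ValueError(f"view {self.name!r}: {n} samples < minimum {MIN_SAMPLES}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_features(self) -> int:
        return len(self.features)

    def drop_constant_features(self) -> "OmicsView":
        """Return a copy with zero-variance features removed.

        A constant feature contributes 0/0 to the Pearson correlation and
        carries no between-sample information.
        """
        keep = self.values.std(axis=0) > 0
        dropped = int((~keep).sum())
        if dropped:
            logger.info("view %r: dropped %d constant feature(s)", self.name, dropped)
        return OmicsView(
            name=self.name,
            samples=list(self.samples),
            features=[f for f, k in zip(self.features, keep) if k],
            values=self.values[:, keep],
        )

    def subset(self, sample_ids: Sequence[str]) -> "OmicsView":
        """Restrict to ``sample_ids`` in the given order."""
        index = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise KeyError(f"view {self.name!r}: samples not present: {missing[:5]}")
        rows = [index[s] for s in sample_ids]
        return OmicsView(
            name=self.name,
            samples=list(sample_ids),
            features=list(self.features),
            values=self.values[rows],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.features)


@dataclass
class SurvivalTable:
    """Per-sample follow-up time (days) and event indicator (1 = death observed)."""

    sample_id: list[str]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if len(self.sample_id) != len(self.time) or len(self.time) != len(self.event):
            raise ValueError("sample_id, time and event must have equal length")
        if len(set(self.sample_id)) != len(self.sample_id):
            raise ValueError("duplicate sample ids in survival table")
        if (self.time < 0).any():
            raise ValueError("negative follow-up time")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicator must be 0 or 1")

    def __len__(self) -> int:
        return len(self.sample_id)

    def subset(self, sample_ids: Sequence[str], allow_missing: bool = False) -> "SurvivalTable":
        index = {s: i for i, s in enumerate(self.sample_id)}
        if allow_missing:
            kept = [s for s in sample_ids if s in index]
            n_drop = len(sample_ids) - len(kept)
            if n_drop:
                logger.warning("survival: %d sample(s) without survival rows dropped", n_drop)
            sample_ids = kept
        rows = [index[s] for s in sample_ids]
        return SurvivalTable(list(sample_ids), self.time[rows], self.event[rows])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_id, "time": self.time, "event": self.event}
        )


@dataclass
class RunConfig:
    """Hyper-parameters of a fusion/clustering run.

    mu scales the corrected (Fisher-scale) similarity inside the logistic
    same-subtype map; t shifts the scaled-exponential final transform.  Both
    defaults follow the method's reference configuration.
    """

    n_clusters: int
    weights: Sequence[float] | None = None
    mu: float = 3.0
    t_scale: float = 1.0
    scale_mode: str = "increasing"
    regression_mode: str = "separate"
    grid_step: float = 0.05
    random_seed: int = 0
    fisher_eps: float = 1e-7

    def __post_init__(self) -> None:
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if self.mu <= 0 or self.t_scale <= 0:
            raise ValueError("mu and t_scale must be positive")
        if self.scale_mode not in ("increasing", "as_printed"):
            raise ValueError(f"unknown scale_mode {self.scale_mode!r}")
        if self.regression_mode not in ("separate", "pooled"):
            raise ValueError(f"unknown regression_mode {self.regression_mode!r}")
        if self.grid_step <= 0 or abs(round(1 / self.grid_step) - 1 / self.grid_step) > 1e-9:
            raise ValueError("grid_step must be positive and divide 1")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if (w < 0).any():
                raise ValueError("weights must be non-negative")
            if abs(w.sum() - 1.0) > 1e-9:
                raise ValueError(f"weights must sum to 1 (got {w.sum():.12f})")
            self.weights = w


def load_omics_view(path, name: str, orientation: str = "features_by_samples") -> OmicsView:
    """Read a delimited numeric matrix into an :class:`OmicsView`.

    The file must have one header row and one id column; delimiter is
    sniffed between tab and comma.  ``orientation`` says what the file rows
    are; the returned view is always sample-major.  Constant-variance
    features are dropped (logged); missing or non-numeric cells are an error
    naming the offending row and column.
    """
    if orientation not in ("features_by_samples", "samples_by_features"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = _sniff_sep(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    if len(set(header[1:])) != len(header[1:]):
        raise ValueError(f"{path}: duplicate ids in header row")
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate row ids")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~df.isna()
    if bad.to_numpy().any() or df.isna().to_numpy().any():
        mask = numeric.isna().to_numpy()
        r, c = np.argwhere(mask)[0]
        raise ValueError(
            f"{path}: non-numeric or missing cell at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}"
        )
    if orientation == "features_by_samples":
        numeric = numeric.T
    view = OmicsView(
        name=name,
        samples=[str(s) for s in numeric.index],
        features=[str(f) for f in numeric.columns],
        values=numeric.to_numpy(dtype=float),
    )
    return view.drop_constant_features()


def write_omics_view(view: OmicsView, path, orientation: str = "features_by_samples") -> None:
    """Write a view as TSV (default orientation: rows = features)."""
    df = view.to_frame()
    if orientation == "features_by_samples":
        df = df.T
    df.to_csv(path, sep="\t", float_format="%.17g")


def align_views(views: Sequence[OmicsView]) -> list[OmicsView]:
    """Restrict every view to the sorted intersection of sample ids.

    All downstream matrices then share one canonical sample order.
    Idempotent; errors if fewer than 3 samples are shared.
    """
    if len(views) < 2:
        raise ValueError("need at least 2 views to align")
    shared = set(views[0].samples)
    for v in views[1:]:
        shared &= set(v.samples)
    order = sorted(shared)
    if len(order) < MIN_SAMPLES:
        raise ValueError(
            f"only {len(order)} sample(s) shared across views; need >= {MIN_SAMPLES}"
        )
    logger.info("aligned %d views on %d shared samples", len(views), len(order))
    return [v.subset(order) for v in views]


def load_survival(path) -> SurvivalTable:
    """Read a survival TSV with columns sample_id, time, event.

    Rows with negative time or an event value outside {0, 1} are rejected
    with a message; a death recorded at time 0 (event at enrollment) is
    accepted.
    """
    df = pd.read_csv(path, sep=_sniff_sep(path), float_precision="round_trip")
    required = {"sample_id", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    bad = (df["time"] < 0) | (~df["event"].isin((0, 1)))
    if bad.any():
        rows = df.index[bad].tolist()
        raise ValueError(
            f"{path}: {int(bad.sum())} row(s) with negative time or event not in "
            f"{{0,1}} (first bad row index {rows[0]})"
        )
    return SurvivalTable(
        sample_id=[str(s) for s in df["sample_id"]],
        time=df["time"].to_numpy(dtype=float),
        event=df["event"].to_numpy(dtype=int),
    )


def write_survival(table: SurvivalTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def load_labels(path) -> pd.Series:
    """Read a categorical label TSV (columns sample_id, label) into a Series.

    Samples missing from the table are simply absent; comparisons such as
    the adjusted Rand index are computed on the labeled subset.
    """
    df = pd.read_csv(path, sep=_sniff_sep(path))
    for col in ("sample_id", "label"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    return pd.Series(
        df["label"].to_numpy(), index=[str(s) for s in df["sample_id"]], name="label"
    )
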
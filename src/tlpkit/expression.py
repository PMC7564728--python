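"""Expression profiling of TLP genes.

Two data streams are covered: RNA-seq FPKM matrices over tissue panels
(log2-transformed and hierarchically clustered into heatmap-ready form),
and semi-quantitative RT-PCR band intensities expressed relative to a
reference (housekeeping) gene and compared between groups with a
two-sample t-test.

Gel densitometry and FPKM estimation are upstream; intensities and FPKM
values arrive as numbers.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

#: the barley tissue panel used for spatiotemporal profiling: embryo,
#: shoot, two inflorescence stages, root, tillers, developing grain at
#: 5 and 15 days post anthesis
DEFAULT_TISSUES = ("EMB", "LEA", "INF1", "INF2", "ROO", "NOD",
                   "CAR5", "CAR15")


@dataclasses.dataclass(frozen=True)
class ExpressionMatrix:
    """A genes x tissues matrix of non-negative FPKM values."""

    genes: tuple[str, ...]
    tissues: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.genes), len(self.tissues)):
            raise ValueError("matrix shape does not match labels")
        if np.any(v < 0):
            raise ValueError("FPKM values must be non-negative")
        object.__setattr__(self, "values", v)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.genes),
                            columns=list(self.tissues))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(tuple(df.index), tuple(df.columns),
                   df.to_numpy(dtype=float))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        return cls.from_frame(
            pd.read_csv(path, sep="\t", index_col=0, comment="#"))

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def log2_normalize(matrix: ExpressionMatrix,
                   pseudocount: float = 1.0) -> ExpressionMatrix:
    """Map each FPKM value x to log2(x + pseudocount).

    The default pseudo-count of 1 keeps zeros at zero and the transform
    monotone; it is configurable because no single convention exists.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return ExpressionMatrix(
        matrix.genes, matrix.tissues,
        np.log2(matrix.values + pseudocount))


def minmax_scale_rows(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each row to [0, 1] for display; constant rows map to 0."""
    v = matrix.values
    lo = v.min(axis=1, keepdims=True)
    span = v.max(axis=1, keepdims=True) - lo
    span[span == 0] = 1.0
    return ExpressionMatrix(matrix.genes, matrix.tissues, (v - lo) / span)


@dataclasses.dataclass(frozen=True)
class ClusterResult:
    """Average-linkage clustering of matrix rows.

    linkage is the standard (n-1) x 4 merge table (scipy encoding);
    leaf_order gives gene labels in dendrogram order; merge_heights are
    the linkage heights in merge order.
    """

    leaf_order: tuple[str, ...]
    merge_heights: tuple[float, ...]
    linkage: np.ndarray


def cluster_rows(matrix: ExpressionMatrix,
                 metric: str = "euclidean") -> ClusterResult:
    """Agglomerative average-linkage (UPGMA) clustering of the rows.

    Metric is Euclidean by default; "correlation" (1 - Pearson r) is the
    alternative.  Merge order on tied dissimilarities follows the
    smallest original row index.
    """
    if len(matrix.genes) < 2:
        raise ValueError("clustering needs at least 2 rows")
    if metric not in ("euclidean", "correlation"):
        raise ValueError(f"unsupported metric {metric!r}")
    z = hierarchy.linkage(pdist(matrix.values, metric=metric),
                          method="average")
    order = hierarchy.leaves_list(z)
    return ClusterResult(
        leaf_order=tuple(matrix.genes[i] for i in order),
        merge_heights=tuple(float(h) for h in z[:, 2]),
        linkage=z,
    )


def plot_heatmap(matrix: ExpressionMatrix, path: str | Path,
                 cluster: bool = True) -> None:
    """Render a clustered log-scale heatmap (rows reordered by the
    dendrogram when ``cluster`` is set)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    v = matrix.values
    genes = list(matrix.genes)
    if cluster and len(genes) >= 2:
        order = [matrix.genes.index(g)
                 for g in cluster_rows(matrix).leaf_order]
        v = v[order]
        genes = [genes[i] for i in order]
    fig, ax = plt.subplots(
        figsize=(1 + 0.5 * len(matrix.tissues), 1 + 0.3 * len(genes)))
    im = ax.imshow(v, aspect="auto", cmap="RdYlGn_r")
    ax.set_xticks(range(len(matrix.tissues)), matrix.tissues, rotation=45)
    ax.set_yticks(range(len(genes)), genes, fontsize=7)
    fig.colorbar(im, ax=ax, label="log2(FPKM + 1)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


# ---------------------------------------------------------------------------
# RT-PCR band quantification
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class BandMeasurement:
    """One gel-band intensity with its reference-gene intensity.

    The germination time course samples 16, 48 and 96 h in a malting and
    a feed barley variety; intensities come from external gel software.
    """

    gene: str
    variety: str
    timepoint_h: int
    intensity: float
    reference_intensity: float

    def __post_init__(self) -> None:
        if self.variety not in ("malt", "feed"):
            raise ValueError(f"unknown variety {self.variety!r}")
        if self.timepoint_h not in (16, 48, 96):
            raise ValueError(f"unexpected timepoint {self.timepoint_h} h")
        if self.intensity < 0:
            raise ValueError("negative band intensity")
        if self.reference_intensity <= 0:
            raise ValueError("reference intensity must be positive")


def relative_expression(band: BandMeasurement) -> float:
    """Band intensity relative to the reference (housekeeping) gene."""
    return band.intensity / band.reference_intensity


def read_band_table(path: str | Path) -> list[BandMeasurement]:
    """Read a TSV of band measurements: gene, variety, timepoint_h,
    intensity, reference_intensity (header row required)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene", "variety", "timepoint_h", "intensity",
                "reference_intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"band table missing column(s) {sorted(missing)}")
    return [
        BandMeasurement(row.gene, row.variety, int(row.timepoint_h),
                        float(row.intensity),
                        float(row.reference_intensity))
        for row in df.itertuples()
    ]


@dataclasses.dataclass(frozen=True)
class TTestResult:
    t_statistic: float
    p_value: float
    significant: bool
    df: float


def compare_groups(a: Sequence[float], b: Sequence[float],
                   alpha: float = 0.05, welch: bool = False) -> TTestResult:
    """Two-sample t-test between groups of relative-expression ratios.

    Classic equal-variance (pooled) Student's t with df = n_a + n_b - 2
    and a two-sided p-value; the Welch unequal-variance variant is
    available behind a flag.  Identical constant samples (zero pooled
    variance) are degenerate and rejected.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0 and a.mean() != b.mean():
        raise ValueError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    t = float(res.statistic)
    p = float(res.pvalue)
    if np.isnan(t):  # identical constant samples: no evidence of difference
        t, p = 0.0, 1.0
    df = float(res.df) if hasattr(res, "df") else len(a) + len(b) - 2
    return TTestResult(t, p, bool(p < alpha), df)
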
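"""Expression quantification and cold-response calls, plus 2^-ddCt qPCR.

The RNA-seq path is FPKM -> expressed filter (FPKM > 1 in at least one
sample) -> log2(x+1) -> per-gene centering/scaling -> hierarchical
clustering, with per-timepoint response calls on replicate-averaged FPKM.
The qPCR path is the standard 2^-ddCt relative quantification against a
reference gene and a control timepoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist

TIMEPOINT_ORDER = ("0H", "30M", "1H", "3H", "6H", "12H", "24H", "72H")

UP, DOWN, FLAT = "up", "down", "flat"


@dataclass
class ExpressionMatrix:
    """Gene x sample matrix with a units tag ('counts' or 'FPKM').

    Sample labels are '<timepoint>_r<replicate>'.
    """

    values: pd.DataFrame
    units: str
    lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("expression values must be non-negative")


@dataclass(frozen=True)
class ResponseCall:
    gene: str
    timepoint: str
    log2_fold_change: float
    direction: str


def read_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_lengths(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0]


def read_library_sizes(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0].astype(float)


def fpkm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    library_sizes: pd.Series | None = None,
) -> ExpressionMatrix:
    """FPKM(g, s) = 1e9 * count / (library_size * gene_length_bp).

    ``library_sizes`` defaults to the per-sample column totals.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every gene needs a positive length")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0).astype(float)
    library_sizes = library_sizes.reindex(counts.columns)
    if library_sizes.isna().any() or (library_sizes <= 0).any():
        raise ValueError("library sizes must be positive for every sample")
    vals = 1e9 * counts.div(library_sizes, axis=1).div(lengths, axis=0)
    return ExpressionMatrix(vals, "FPKM", lengths)


def filter_expressed(mat: ExpressionMatrix, min_fpkm: float = 1.0) -> list[str]:
    """Genes with FPKM strictly above ``min_fpkm`` in at least one sample."""
    if mat.units != "FPKM":
        raise ValueError("expression filter operates on FPKM units")
    keep = (mat.values > min_fpkm).any(axis=1)
    return list(mat.values.index[keep])


def log2_center_scale(mat: ExpressionMatrix) -> pd.DataFrame:
    """log2(x + 1), then per-gene centering and scaling to unit variance
    (sample standard deviation, as R's ``scale``); constant genes become
    all-zero rows with a warning."""
    if mat.units != "FPKM":
        raise ValueError("transform operates on FPKM units")
    logged = np.log2(mat.values + 1.0)
    sd = logged.std(axis=1, ddof=1)
    flatliners = sd == 0
    if flatliners.any():
        warnings.warn(
            f"{int(flatliners.sum())} zero-variance genes set to all-zero rows"
        )
    centered = logged.sub(logged.mean(axis=1), axis=0)
    out = centered.div(sd.where(~flatliners, 1.0), axis=0)
    out[flatliners] = 0.0
    return out


def cluster_genes(mat: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    """Average-linkage clustering on 1 - Pearson correlation distances.

    Returns (leaf order of gene ids, scipy linkage matrix).
    """
    if mat.shape[0] < 2:
        raise ValueError("need at least two genes to cluster")
    d = pdist(mat.values, metric="correlation")
    d = np.nan_to_num(d, nan=1.0)  # zero-variance rows have undefined r
    z = average(d)
    order = leaves_list(z)
    return [mat.index[i] for i in order], z


def average_replicates(mat: ExpressionMatrix) -> pd.DataFrame:
    """Mean FPKM per gene and timepoint from '<tp>_r<n>' sample labels."""
    tps = [c.rsplit("_r", 1)[0] for c in mat.values.columns]
    grouped = mat.values.T.groupby(tps).mean().T
    ordered = [t for t in TIMEPOINT_ORDER if t in grouped.columns]
    extra = [t for t in grouped.columns if t not in TIMEPOINT_ORDER]
    return grouped[ordered + extra]


def call_responses(
    mean_fpkm: pd.DataFrame, control: str = "0H", lfc_threshold: float = 1.0
) -> list[ResponseCall]:
    """Per gene and non-control timepoint: LFC = log2((m_t+1)/(m_c+1));
    up when LFC >= threshold, down when <= -threshold, else flat."""
    if control not in mean_fpkm.columns:
        raise ValueError(f"control timepoint {control!r} absent")
    calls = []
    base = mean_fpkm[control]
    for tp in mean_fpkm.columns:
        if tp == control:
            continue
        lfc = np.log2((mean_fpkm[tp] + 1.0) / (base + 1.0))
        for gene, v in lfc.items():
            direction = UP if v >= lfc_threshold else (
                DOWN if v <= -lfc_threshold else FLAT
            )
            calls.append(ResponseCall(gene, tp, float(v), direction))
    return calls


# ---------------------------------------------------------------------------
# qPCR


def read_ct_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "timepoint", "replicate", "ct_target", "ct_reference"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing Ct columns {sorted(missing)}")
    bad = df[(df.ct_target <= 0) | (df.ct_target >= 45)
             | (df.ct_reference <= 0) | (df.ct_reference >= 45)]
    if not bad.empty:
        raise ValueError("Ct values must lie in (0, 45)")
    return df


def delta_delta_ct(table: pd.DataFrame, control: str = "0H") -> pd.DataFrame:
    """2^-ddCt fold changes, genes x timepoints.

    dCt = Ct_target - Ct_reference per replicate; ddCt(t) = mean dCt(t) -
    mean dCt(control); fold = 2^-ddCt.  The control column is exactly 1.
    """
    df = table.copy()
    df["dct"] = df["ct_target"] - df["ct_reference"]
    mean_dct = df.groupby(["gene", "timepoint"])["dct"].mean().unstack()
    if control not in mean_dct.columns:
        raise ValueError(f"control timepoint {control!r} absent from Ct table")
    missing = mean_dct.index[mean_dct[control].isna()]
    if len(missing):
        raise ValueError(
            f"genes without control-timepoint rows: {sorted(missing)}"
        )
    fold = 2.0 ** -(mean_dct.sub(mean_dct[control], axis=0))
    fold[control] = 1.0
    ordered = [t for t in TIMEPOINT_ORDER if t in fold.columns]
    extra = [t for t in fold.columns if t not in TIMEPOINT_ORDER]
    return fold[ordered + extra]


def timepoint_quartiles(mat: ExpressionMatrix) -> pd.DataFrame:
    """Per-timepoint FPKM quartiles over expressed genes (violin summary)."""
    mean = average_replicates(mat)
    qs = mean.quantile([0.25, 0.5, 0.75])
    qs.index = ["q25", "median", "q75"]
    return qs
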
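"""EMT gene-signature derivation, subtype clustering, and EMT scoring.

The molecular arm of the pipeline: starting from a log-scale expression
matrix and a candidate gene set (e.g. the MSigDB hallmark EMT set), genes
correlated with the canonical EMT markers — E-cadherin (CDH1) on the
epithelial side; vimentin (VIM), N-cadherin (CDH2) and fibronectin 1 (FN1)
on the mesenchymal side — form the signature.  Hierarchical clustering of
samples on the signature genes (centered-correlation distance) yields the
two molecular subtypes, Epi and Mes, and a per-sample EMT score (a signed
two-sample Kolmogorov–Smirnov statistic on within-sample expression ranks)
quantifies where each sample sits on the epithelial–mesenchymal axis:
+1 is fully mesenchymal-like, -1 fully epithelial-like.

A companion routine clusters dichotomized DNA-methylation beta values
(hypermethylated at beta >= 0.3) with Jaccard distance and Ward linkage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .stats import benjamini_hochberg

__all__ = [
    "ExpressionMatrix",
    "MarkerSet",
    "SignatureResult",
    "SubtypeAssignment",
    "EMTScoreVector",
    "MethylationMatrix",
    "select_signature_genes",
    "cluster_subtypes",
    "orient_clusters",
    "compute_emt_score",
    "cluster_methylation",
    "EPI",
    "MES",
]

EPI = "Epi"
MES = "Mes"


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Log-scale expression, genes in rows, samples in columns."""

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, genes) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        return np.array([lookup[g] for g in genes], dtype=int)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        idx = self.gene_index(genes)
        return ExpressionMatrix(self.values[idx], [self.gene_ids[i] for i in idx],
                                self.sample_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index.astype(str)),
                   list(df.columns.astype(str)))

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        return cls.from_dataframe(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")


@dataclass(frozen=True)
class MarkerSet:
    """Canonical EMT marker genes used to anchor signature selection."""

    epithelial_markers: tuple[str, ...] = ("CDH1",)
    mesenchymal_markers: tuple[str, ...] = ("VIM", "CDH2", "FN1")

    def __post_init__(self) -> None:
        epi, mes = set(self.epithelial_markers), set(self.mesenchymal_markers)
        if not epi or not mes:
            raise ValueError("both marker sets must be nonempty")
        if epi & mes:
            raise ValueError(f"marker sets overlap: {sorted(epi & mes)}")

    @property
    def all_markers(self) -> tuple[str, ...]:
        return tuple(self.epithelial_markers) + tuple(self.mesenchymal_markers)


@dataclass
class SignatureResult:
    """Selected signature genes with their best marker association."""

    table: pd.DataFrame  # gene, marker, r, q, set
    epi_set: list[str]
    mes_set: list[str]
    r_min: float
    alpha: float

    @property
    def selected_genes(self) -> list[str]:
        return list(self.table["gene"])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class SubtypeAssignment:
    labels: dict[str, str]  # sample id -> cluster label
    linkage_matrix: np.ndarray
    linkage_name: str
    distance_name: str
    oriented: bool = False

    def labels_series(self) -> pd.Series:
        return pd.Series(self.labels, name="subtype")

    def to_tsv(self, path) -> None:
        self.labels_series().rename_axis("sample").to_csv(path, sep="\t")


@dataclass
class EMTScoreVector:
    """Per-sample signed-KS EMT score with its two one-sided components."""

    scores: dict[str, float]
    d_plus: dict[str, float]
    d_minus: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"emt_score": self.scores, "D_plus": self.d_plus, "D_minus": self.d_minus}
        ).rename_axis("sample")

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


@dataclass
class MethylationMatrix:
    """Beta values in [0, 1], probes in rows, samples in columns."""

    beta: np.ndarray
    probe_ids: list[str]
    sample_ids: list[str]
    cutoff: float = 0.3

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.min() < 0 or self.beta.max() > 1:
            raise ValueError("beta values must lie in [0, 1]")
        if self.beta.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError("beta shape does not match probe/sample ids")


# ---------------------------------------------------------------------------
# signature selection
# ---------------------------------------------------------------------------

def select_signature_genes(
    expr: ExpressionMatrix,
    candidates,
    markers: MarkerSet | None = None,
    r_min: float = 0.4,
    alpha: float = 0.05,
) -> SignatureResult:
    """Select candidate genes whose expression tracks at least one EMT marker.

    A gene enters the signature when its Pearson correlation with some marker
    satisfies ``|r| >= r_min`` and the Benjamini–Hochberg adjusted p-value of
    that correlation is at most ``alpha`` (adjustment over all candidate x
    marker pairs).  Each selected gene is assigned to the mesenchymal side
    (``mes_set``) when its strongest association is positive with a
    mesenchymal marker or negative with an epithelial marker, and to the
    epithelial side otherwise.
    """
    markers = markers or MarkerSet()
    if expr.n_samples < 2:
        raise ValueError("need at least 2 samples to compute correlations")
    gene_set = set(expr.gene_ids)
    absent_markers = [m for m in markers.all_markers if m not in gene_set]
    if absent_markers:
        raise ValueError(f"marker genes absent from expression matrix: {absent_markers}")

    candidates = list(dict.fromkeys(candidates))
    missing = [g for g in candidates if g not in gene_set]
    if missing:
        warnings.warn(
            f"dropping {len(missing)} candidate genes absent from the matrix",
            stacklevel=2,
        )
        candidates = [g for g in candidates if g in gene_set]
    if not candidates:
        raise ValueError("no candidate genes present in the expression matrix")

    n = expr.n_samples
    cand = expr.values[expr.gene_index(candidates)]
    mark = expr.values[expr.gene_index(markers.all_markers)]

    def _standardize(x):
        sd = x.std(axis=1, ddof=0, keepdims=True)
        sd[sd == 0] = np.nan  # constant genes correlate with nothing
        return (x - x.mean(axis=1, keepdims=True)) / sd

    r = _standardize(cand) @ _standardize(mark).T / n  # candidates x markers
    r = np.clip(np.nan_to_num(r, nan=0.0), -1.0, 1.0)

    # two-sided p via the t transform of Pearson r
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - r**2))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    q = benjamini_hochberg(p.ravel()).reshape(p.shape)

    passing = (np.abs(r) >= r_min) & (q <= alpha)
    rows = []
    epi_set, mes_set = [], []
    mes_markers = set(markers.mesenchymal_markers)
    for i, gene in enumerate(candidates):
        if not passing[i].any():
            continue
        # strongest association among passing pairs
        j = int(np.argmax(np.where(passing[i], np.abs(r[i]), -np.inf)))
        marker = markers.all_markers[j]
        mesenchymal = (r[i, j] > 0) == (marker in mes_markers)
        side = "mes" if mesenchymal else "epi"
        (mes_set if mesenchymal else epi_set).append(gene)
        rows.append({"gene": gene, "marker": marker, "r": float(r[i, j]),
                     "q": float(q[i, j]), "set": side})

    table = pd.DataFrame(rows, columns=["gene", "marker", "r", "q", "set"])
    return SignatureResult(table=table, epi_set=epi_set, mes_set=mes_set,
                           r_min=r_min, alpha=alpha)


# ---------------------------------------------------------------------------
# subtype clustering
# ---------------------------------------------------------------------------

def cluster_subtypes(expr: ExpressionMatrix, method: str = "average") -> SubtypeAssignment:
    """Agglomerative clustering of samples into two groups.

    Distance between samples is 1 minus the centered Pearson correlation of
    their signature-gene profiles; linkage defaults to average.
    """
    if expr.n_samples < 4:
        raise ValueError("need at least 4 samples to cluster")
    if expr.n_genes < 2:
        raise ValueError("need at least 2 genes to cluster")
    profiles = expr.values.T  # samples x genes
    sd = profiles.std(axis=1)
    flat = np.where(sd == 0)[0]
    if flat.size:
        raise ValueError(
            f"constant expression profile for sample(s): "
            f"{[expr.sample_ids[i] for i in flat]}"
        )
    d = pdist(profiles, metric="correlation")
    z = linkage(d, method=method)
    cut = fcluster(z, 2, criterion="maxclust")
    labels = {s: f"cluster{c}" for s, c in zip(expr.sample_ids, cut)}
    return SubtypeAssignment(labels=labels, linkage_matrix=z, linkage_name=method,
                             distance_name="centered-correlation", oriented=False)


def orient_clusters(
    assignment: SubtypeAssignment,
    expr: ExpressionMatrix,
    markers: MarkerSet | None = None,
) -> SubtypeAssignment:
    """Name the two clusters Epi/Mes from marker expression.

    The cluster with the larger mean mesenchymal-marker z-score minus mean
    epithelial-marker z-score becomes Mes.
    """
    markers = markers or MarkerSet()
    clusters = sorted(set(assignment.labels.values()))
    if len(clusters) != 2:
        raise ValueError(f"expected exactly 2 clusters, got {len(clusters)}")

    def _marker_z(genes):
        x = expr.values[expr.gene_index(genes)]
        sd = x.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        return (x - x.mean(axis=1, keepdims=True)) / sd

    z_mes = _marker_z(markers.mesenchymal_markers)
    z_epi = _marker_z(markers.epithelial_markers)
    col = {s: i for i, s in enumerate(expr.sample_ids)}
    scores = {}
    for c in clusters:
        cols = [col[s] for s, lab in assignment.labels.items() if lab == c]
        scores[c] = float(z_mes[:, cols].mean() - z_epi[:, cols].mean())
    if scores[clusters[0]] == scores[clusters[1]]:
        raise ValueError("marker contrast is tied between clusters; orient manually")
    mes_cluster = max(clusters, key=lambda c: scores[c])
    named = {s: (MES if lab == mes_cluster else EPI)
             for s, lab in assignment.labels.items()}
    return SubtypeAssignment(labels=named, linkage_matrix=assignment.linkage_matrix,
                             linkage_name=assignment.linkage_name,
                             distance_name=assignment.distance_name, oriented=True)


# ---------------------------------------------------------------------------
# EMT score
# ---------------------------------------------------------------------------

def compute_emt_score(expr: ExpressionMatrix, epi_set, mes_set) -> EMTScoreVector:
    """Signed two-sample KS statistic on within-sample expression ranks.

    Per sample: rank the union of signature genes by expression, descending
    (average ranks on ties); build the empirical CDFs of the mesenchymal-set
    and epithelial-set rank positions; then

        D_plus  = max_t ( F_mes(t) - F_epi(t) ), floored at 0
        D_minus = max_t ( F_epi(t) - F_mes(t) ), floored at 0
        score   = D_plus - D_minus

    A sample whose mesenchymal genes all outrank its epithelial genes scores
    exactly +1 (fully mesenchymal-like); the mirror case scores -1.
    """
    epi_set = sorted(dict.fromkeys(epi_set))
    mes_set = sorted(dict.fromkeys(mes_set))
    if len(epi_set) < 2 or len(mes_set) < 2:
        raise ValueError("each gene set needs at least 2 genes")
    overlap = set(epi_set) & set(mes_set)
    if overlap:
        raise ValueError(f"gene sets overlap: {sorted(overlap)}")

    union = epi_set + mes_set  # deterministic gene order: sorted epi then sorted mes
    sub = expr.subset_genes(union)
    is_mes = np.array([g in set(mes_set) for g in union])
    n_mes, n_epi = is_mes.sum(), (~is_mes).sum()

    scores, dplus, dminus = {}, {}, {}
    for j, sample in enumerate(sub.sample_ids):
        ranks = sps.rankdata(-sub.values[:, j], method="average")
        thresholds = np.unique(ranks)
        f_mes = (ranks[is_mes][None, :] <= thresholds[:, None]).mean(axis=1)
        f_epi = (ranks[~is_mes][None, :] <= thresholds[:, None]).mean(axis=1)
        diff = f_mes - f_epi
        dp = max(0.0, float(diff.max()))
        dm = max(0.0, float(-diff.min()))
        scores[sample] = dp - dm
        dplus[sample] = dp
        dminus[sample] = dm
    return EMTScoreVector(scores=scores, d_plus=dplus, d_minus=dminus)


# ---------------------------------------------------------------------------
# methylation clustering
# ---------------------------------------------------------------------------

def cluster_methylation(meth: MethylationMatrix) -> SubtypeAssignment:
    """Cluster samples on dichotomized methylation.

    Probes with beta >= cutoff (default 0.3) are hypermethylated; samples are
    compared by Jaccard distance of their binary probe vectors and clustered
    by Ward agglomeration, cut into two groups.
    """
    if len(meth.probe_ids) < 2:
        raise ValueError("need at least 2 probes")
    if len(meth.sample_ids) < 4:
        raise ValueError("need at least 4 samples")
    binary = meth.beta >= meth.cutoff
    if not binary.any():
        raise ValueError("no hypermethylated probes at the chosen cutoff")
    d = pdist(binary.T.astype(bool), metric="jaccard")
    z = linkage(d, method="ward")
    cut = fcluster(z, 2, criterion="maxclust")
    labels = {s: f"cluster{c}" for s, c in zip(meth.sample_ids, cut)}
    return SubtypeAssignment(labels=labels, linkage_matrix=z, linkage_name="ward",
                             distance_name="jaccard", oriented=False)
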
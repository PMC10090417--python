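"""SNP marker quality control, imputation and genomic relationship matrices.

Markers are biallelic SNP calls coded 0/1/2 (copies of the minor allele) with
missing entries, one row per line.  The genomic relationship matrix (GRM) is
the Gram matrix ``G = M M' / r`` over the marker codes, with an optional
allele-frequency centering; its symmetric square root is what propagates line
relatedness into design-matrix predictors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMatrix",
    "Kernel",
    "FilterLog",
    "filter_snps",
    "impute_markers",
    "compute_grm",
    "matrix_sqrt",
]


@dataclass
class MarkerMatrix:
    """Lines x SNPs marker codes in {0, 1, 2}, NaN for missing.

    Parameters
    ----------
    values : ndarray of float, shape (n_lines, n_snps)
        Marker codes; missing calls are NaN.  After imputation entries may be
        real-valued (dosages).
    line_ids, snp_ids : sequences of str
    """

    values: np.ndarray
    line_ids: list
    snp_ids: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.line_ids = list(self.line_ids)
        self.snp_ids = list(self.snp_ids)
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ValueError("line_ids must be unique")
        if self.values.shape != (len(self.line_ids), len(self.snp_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.snp_ids)} SNPs"
            )
        finite = self.values[np.isfinite(self.values)]
        # integer 0/1/2 codes required pre-imputation; dosages allowed after
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError("marker codes must lie in [0, 2]")

    @property
    def n_lines(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.line_ids, columns=self.snp_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MarkerMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))

    @classmethod
    def from_csv(cls, path) -> "MarkerMatrix":
        """Read a lines x SNPs CSV with line IDs in the first column."""
        return cls.from_frame(pd.read_csv(path, index_col=0))

    @classmethod
    def from_hapmap(cls, path) -> "MarkerMatrix":
        """Read a HapMap-like TSV (SNPs x lines) and transpose to lines x SNPs.

        The first column is the SNP identifier; remaining columns are lines.
        Calls must already be numeric 0/1/2 or NA.
        """
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls.from_frame(df.T)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, na_rep="NA")


@dataclass
class Kernel:
    """A symmetric relationship matrix over an ordered ID set."""

    matrix: np.ndarray
    ids: list = field(default_factory=list)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("kernel matrix must be square")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("kernel matrix must be symmetric to 1e-10")
        if self.ids and len(self.ids) != m.shape[0]:
            raise ValueError("ids length must match matrix dimension")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def to_csv(self, path) -> None:
        pd.DataFrame(self.matrix, index=self.ids or None, columns=self.ids or None).to_csv(path)


@dataclass
class FilterLog:
    """Per-rule SNP rejection counts from :func:`filter_snps`."""

    n_input: int
    n_kept: int
    failed_missing: int
    failed_maf: int
    failed_het: int
    failed_homozygosity: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _snp_rates(values: np.ndarray):
    """Missing rate (over all lines) and MAF/het/hom rates over non-missing calls."""
    n_lines = values.shape[0]
    obs = np.isfinite(values)
    n_obs = obs.sum(axis=0)
    miss_rate = 1.0 - n_obs / n_lines
    with np.errstate(invalid="ignore", divide="ignore"):
        # allele frequency of the "2" allele among non-missing calls
        p = np.nansum(values, axis=0) / (2.0 * np.maximum(n_obs, 1))
        maf = np.minimum(p, 1.0 - p)
        het = np.nansum(values == 1, axis=0) / np.maximum(n_obs, 1)
        hom = np.nansum((values == 0) | (values == 2), axis=0) / np.maximum(n_obs, 1)
    maf = np.where(n_obs > 0, maf, 0.0)
    return miss_rate, maf, het, hom


def filter_snps(
    raw: MarkerMatrix,
    max_missing: float = 0.5,
    min_maf: float = 0.05,
    max_het: float = 0.05,
    min_homozygosity: float = 0.8,
) -> tuple[MarkerMatrix, FilterLog]:
    """Apply the four SNP quality rules simultaneously.

    A SNP is kept iff: missing rate < ``max_missing`` (over all lines),
    minor-allele frequency > ``min_maf``, heterozygous-call rate < ``max_het``
    and homozygous-call rate > ``min_homozygosity`` (the latter three over
    non-missing calls).

    Returns the filtered matrix and a :class:`FilterLog` of per-rule
    rejection counts (a SNP can fail several rules and counts once per rule).
    """
    if raw.n_snps == 0:
        raise ValueError("empty marker matrix")
    miss, maf, het, hom = _snp_rates(raw.values)
    ok_miss = miss < max_missing
    ok_maf = maf > min_maf
    ok_het = het < max_het
    ok_hom = hom > min_homozygosity
    keep = ok_miss & ok_maf & ok_het & ok_hom
    log = FilterLog(
        n_input=raw.n_snps,
        n_kept=int(keep.sum()),
        failed_missing=int((~ok_miss).sum()),
        failed_maf=int((~ok_maf).sum()),
        failed_het=int((~ok_het).sum()),
        failed_homozygosity=int((~ok_hom).sum()),
    )
    if log.n_kept == 0:
        raise ValueError(
            "no SNPs survive filtering: "
            f"{log.failed_missing} fail missing<{max_missing}, "
            f"{log.failed_maf} fail MAF>{min_maf}, "
            f"{log.failed_het} fail het<{max_het}, "
            f"{log.failed_homozygosity} fail homozygosity>{min_homozygosity}"
        )
    out = MarkerMatrix(
        raw.values[:, keep],
        raw.line_ids,
        [s for s, k in zip(raw.snp_ids, keep) if k],
    )
    return out, log


def impute_markers(
    m: MarkerMatrix, method: str = "mean", rank: int = 5, tol: float = 1e-4, max_iter: int = 50
) -> MarkerMatrix:
    """Fill missing marker calls.

    ``mean``
        Each missing entry receives its SNP's mean code (real-valued dosage).
    ``em_lowrank``
        Iterative low-rank completion: mean-fill, then alternate a rank-``rank``
        truncated-SVD reconstruction of the missing cells until the largest
        change is below ``tol`` or ``max_iter`` sweeps.

    Non-missing entries are never altered.
    """
    vals = m.values.copy()
    miss = ~np.isfinite(vals)
    if not miss.any():
        return MarkerMatrix(vals, m.line_ids, m.snp_ids)
    if miss.all(axis=0).any():
        bad = [s for s, b in zip(m.snp_ids, miss.all(axis=0)) if b]
        raise ValueError(f"SNPs with no observed calls (filter first): {bad[:5]}")
    col_mean = np.nanmean(vals, axis=0)
    filled = np.where(miss, col_mean[None, :], vals)
    if method == "mean":
        return MarkerMatrix(filled, m.line_ids, m.snp_ids)
    if method != "em_lowrank":
        raise ValueError(f"unknown imputation method {method!r}")
    k = min(rank, min(filled.shape))
    for _ in range(max_iter):
        u, s, vt = np.linalg.svd(filled, full_matrices=False)
        recon = (u[:, :k] * s[:k]) @ vt[:k]
        new = np.where(miss, recon, vals)
        delta = np.max(np.abs(new - filled)[miss]) if miss.any() else 0.0
        filled = new
        if delta < tol:
            break
    return MarkerMatrix(np.clip(filled, 0.0, 2.0), m.line_ids, m.snp_ids)


def compute_grm(m: MarkerMatrix, center: bool = False) -> Kernel:
    """Genomic relationship matrix ``G = M M' / r`` (r = number of markers).

    With ``center=True`` marker columns are first centered by twice the
    observed allele frequency (``2 p_hat``), the conventional alternative;
    the default uses the raw 0/1/2 codes.
    Requires an imputed (complete) matrix.
    """
    if m.n_snps == 0:
        raise ValueError("cannot compute GRM with zero markers")
    vals = m.values
    if not np.isfinite(vals).all():
        raise ValueError("marker matrix contains missing values; impute first")
    if center:
        p = vals.mean(axis=0) / 2.0
        vals = vals - 2.0 * p[None, :]
    g = vals @ vals.T / m.n_snps
    g = (g + g.T) / 2.0
    return Kernel(g, list(m.line_ids))


def matrix_sqrt(k: Kernel, clip_tol: float = 0.0) -> Kernel:
    """Symmetric PSD square root via eigendecomposition.

    Eigenvalues below ``clip_tol`` (numerical negatives) are clipped to zero,
    so ``L @ L`` reproduces the PSD-repaired input to Frobenius ~1e-8.
    """
    w, v = np.linalg.eigh(k.matrix)
    w = np.clip(w, 0.0, None)
    root = (v * np.sqrt(w)) @ v.T
    return Kernel((root + root.T) / 2.0, list(k.ids))


def psd_repair(matrix: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Clip numerically negative eigenvalues of a symmetric matrix to zero."""
    sym = (matrix + matrix.T) / 2.0
    w, v = np.linalg.eigh(sym)
    if w.min() >= -tol:
        return sym
    w = np.clip(w, 0.0, None)
    return (v * w) @ v.T
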
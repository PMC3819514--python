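"""Ground-truth gene-expression model (MVN-GC).

Synthetic "actual" expression values are drawn from a high-dimensional
multivariate Gaussian with a block compound-symmetry covariance.  Features
fall into four groups:

* **global markers** -- differentially distributed between class 0 and
  class 1 for every class-1 sample: ``N(m_y * 1, sigma_y^2 * Sigma)``;
* **heterogeneous markers** -- one group of ``D_hm`` features per class-1
  subclass; they follow the class-1 distribution only for samples of their
  own subclass (modelling disease subtypes) and the class-0 distribution
  otherwise;
* **high-variance non-markers** -- uncorrelated two-component Gaussian
  mixtures ``p N(m0, sigma0^2) + (1-p) N(m1, sigma1^2)`` with a per-feature
  mixture weight ``p ~ U(0, 1)``; the mixture component is redrawn for every
  sample;
* **low-variance non-markers** -- i.i.d. ``N(m0, sigma0^2)``.

``Sigma`` is block diagonal; each ``l x l`` block is compound symmetric
(unit diagonal, ``rho`` off-diagonal), representing a pathway of mutually
correlated genes.  Blocks, and all non-markers, are mutually independent.

Class labels are i.i.d. equally likely; subclasses within class 1 are, by
default, allocated in balanced (near-equal, randomly permuted) fashion --
see :func:`assign_subclasses`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "ParameterError",
    "ModelConfig",
    "FeatureAnnotation",
    "ExpressionDataset",
    "build_block_covariance",
    "compound_symmetry_cholesky",
    "annotate_features",
    "sample_labels",
    "assign_subclasses",
    "sample_expression",
    "write_expression_tsv",
    "write_annotation_tsv",
]

# Feature role codes (FeatureAnnotation.role).
ROLE_GLOBAL = 0
ROLE_HET = 1
ROLE_HV = 2
ROLE_LV = 3

ROLE_NAMES = {ROLE_GLOBAL: "GLOBAL_MARKER", ROLE_HET: "HET_MARKER",
              ROLE_HV: "HV_NONMARKER", ROLE_LV: "LV_NONMARKER"}


class ParameterError(ValueError):
    """A configuration value violates a model invariant."""


@dataclass(frozen=True)
class ModelConfig:
    """Parameters of one synthetic feature-label distribution.

    Defaults are the reference setting of the simulation study: 20,000
    features of which 10 are global markers, two class-1 subclasses with 50
    heterogeneous markers each, 2,000 high-variance and 17,890 low-variance
    non-markers; class means 0 and 1 with common standard deviation 0.6,
    pathway blocks of 5 genes.
    """

    D: int = 20000
    m0: float = 0.0
    m1: float = 1.0
    sigma0: float = 0.6
    sigma1: float = 0.6
    rho: float = 0.4
    l: int = 5
    D_gm: int = 10
    c: int = 2
    D_hm: int = 50
    D_hv: int = 2000
    D_lv: int = 17890
    cov: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.D_gm + self.c * self.D_hm + self.D_hv + self.D_lv != self.D:
            raise ParameterError(
                "feature groups must tile D exactly: "
                f"D_gm + c*D_hm + D_hv + D_lv = "
                f"{self.D_gm + self.c * self.D_hm + self.D_hv + self.D_lv} != D = {self.D}"
            )
        if self.l < 1:
            raise ParameterError(f"block size l must be >= 1, got {self.l}")
        if self.D_gm % self.l or self.D_hm % self.l:
            raise ParameterError(
                f"D_gm={self.D_gm} and D_hm={self.D_hm} must be divisible by the "
                f"block size l={self.l}"
            )
        if self.c < 1:
            raise ParameterError(f"subclass count c must be >= 1, got {self.c}")
        if self.sigma0 <= 0 or self.sigma1 <= 0:
            raise ParameterError("sigma0 and sigma1 must be positive")
        if self.cov < 0:
            raise ParameterError(f"cov must be >= 0, got {self.cov}")
        _check_rho(self.l, self.rho)

    @property
    def n_marker_features(self) -> int:
        return self.D_gm + self.c * self.D_hm

    def feature_slices(self) -> dict[str, slice]:
        """Column ranges of each group in the fixed feature ordering."""
        off = self.D_gm + self.c * self.D_hm
        return {
            "global": slice(0, self.D_gm),
            "het": slice(self.D_gm, off),
            "hv": slice(off, off + self.D_hv),
            "lv": slice(off + self.D_hv, self.D),
        }


def _check_rho(l: int, rho: float) -> None:
    lo = -1.0 / (l - 1) if l > 1 else -np.inf
    if not (lo < rho < 1.0):
        raise ParameterError(
            f"rho={rho} outside the positive-definite range ({lo}, 1) for block size {l}"
        )


def build_block_covariance(l: int, rho: float, n_blocks: int) -> np.ndarray:
    """Block-diagonal covariance with compound-symmetric ``l x l`` blocks.

    Each block has 1 on the diagonal and ``rho`` off it; distinct blocks are
    independent.  The result is symmetric positive definite for
    ``-1/(l-1) < rho < 1`` (eigenvalues ``1+(l-1)rho`` and ``1-rho``).
    """
    if n_blocks < 1:
        raise ParameterError(f"n_blocks must be >= 1, got {n_blocks}")
    _check_rho(l, rho)
    block = np.full((l, l), rho, dtype=float)
    np.fill_diagonal(block, 1.0)
    return np.kron(np.eye(n_blocks), block)


def compound_symmetry_cholesky(l: int, rho: float, scale2: float,
                               extra_var: float = 0.0) -> np.ndarray:
    """Lower Cholesky factor of ``scale2 * Sigma_rho + extra_var * I``.

    ``extra_var`` lets a downstream layer fold independent per-entry Gaussian
    variance (technical noise) into the draw exactly.
    """
    _check_rho(l, rho)
    block = np.full((l, l), scale2 * rho)
    np.fill_diagonal(block, scale2 + extra_var)
    return np.linalg.cholesky(block)


@dataclass
class FeatureAnnotation:
    """Role of every feature in the fixed ordering.

    Ordering: global markers, then heterogeneous markers of subclass 1..c,
    then high-variance non-markers, then low-variance non-markers.  Markers
    carry a block index (blocks of size ``l``); non-markers do not.  Each
    high-variance non-marker carries its mixture weight ``p``.
    """

    config: ModelConfig
    role: np.ndarray          # int8, ROLE_* codes, length D
    subclass: np.ndarray      # int16, 1..c for het markers, 0 otherwise
    block: np.ndarray         # int32, block id for markers, -1 otherwise
    p: np.ndarray             # float64, mixture weight for hv features, NaN otherwise

    def __post_init__(self) -> None:
        cfg = self.config
        counts = np.bincount(self.role, minlength=4)
        expected = (cfg.D_gm, cfg.c * cfg.D_hm, cfg.D_hv, cfg.D_lv)
        if tuple(counts[:4]) != expected:
            raise ParameterError(f"role counts {tuple(counts[:4])} != {expected}")

    @property
    def global_idx(self) -> np.ndarray:
        return np.flatnonzero(self.role == ROLE_GLOBAL)

    def het_idx(self, k: int) -> np.ndarray:
        return np.flatnonzero((self.role == ROLE_HET) & (self.subclass == k))

    @property
    def hv_idx(self) -> np.ndarray:
        return np.flatnonzero(self.role == ROLE_HV)

    @property
    def lv_idx(self) -> np.ndarray:
        return np.flatnonzero(self.role == ROLE_LV)

    def feature_ids(self) -> list[str]:
        return [f"g{i + 1:06d}" for i in range(self.config.D)]


def annotate_features(config: ModelConfig, rng: np.random.Generator) -> FeatureAnnotation:
    """Assign roles in the fixed ordering and draw the hv mixture weights.

    The only randomness is the i.i.d. ``U(0, 1)`` weight of each
    high-variance non-marker, drawn once per feature per realisation of the
    feature-label distribution.
    """
    cfg = config
    role = np.empty(cfg.D, dtype=np.int8)
    subclass = np.zeros(cfg.D, dtype=np.int16)
    block = np.full(cfg.D, -1, dtype=np.int32)
    p = np.full(cfg.D, np.nan)

    sl = cfg.feature_slices()
    role[sl["global"]] = ROLE_GLOBAL
    role[sl["het"]] = ROLE_HET
    role[sl["hv"]] = ROLE_HV
    role[sl["lv"]] = ROLE_LV
    for k in range(cfg.c):
        lo = cfg.D_gm + k * cfg.D_hm
        subclass[lo:lo + cfg.D_hm] = k + 1
    n_marker = cfg.n_marker_features
    block[:n_marker] = np.arange(n_marker) // cfg.l
    p[sl["hv"]] = rng.random(cfg.D_hv)
    return FeatureAnnotation(cfg, role, subclass, block, p)


@dataclass
class ExpressionDataset:
    """Real-valued expression matrix with labels and feature annotation.

    ``X[i, j]`` is the log-scale expression of gene ``j`` in sample ``i``
    (the Poisson-rate exponent consumed by the sequencing layer).
    ``columns`` names the features present: ``None`` means all ``D`` in the
    canonical order, otherwise the (sorted) original indices of a subset.
    """

    X: np.ndarray
    y: np.ndarray
    subclass: np.ndarray
    annotation: FeatureAnnotation
    config: ModelConfig
    columns: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = self.X.shape[0]
        if len(self.y) != n or len(self.subclass) != n:
            raise ParameterError("labels must match the number of samples")
        if np.isnan(self.X).any():
            raise ParameterError("expression matrix contains missing values")
        if ((self.y == 1) & (self.subclass < 1)).any():
            raise ParameterError("every class-1 sample needs a subclass")

    @property
    def n(self) -> int:
        return self.X.shape[0]


def sample_labels(n: int, rng: np.random.Generator, stratified: bool = False) -> np.ndarray:
    """Class labels: i.i.d. Bernoulli(1/2), or an exact half split.

    The stratified variant is meant for independent test sets, which are
    balanced by construction.
    """
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    if stratified:
        y = np.zeros(n, dtype=np.int8)
        y[n - n // 2:] = 1
        return y
    return rng.integers(0, 2, n).astype(np.int8)


def assign_subclasses(y: np.ndarray, c: int, rng: np.random.Generator,
                      mode: str = "balanced") -> np.ndarray:
    """Subclass labels 1..c for class-1 samples (0 for class 0).

    ``balanced`` allocates the class-1 samples to subclasses in near-equal
    numbers (within one) with a random permutation deciding which samples
    land where; ``iid`` draws each subclass independently and uniformly.
    Balanced allocation is the default: it is what reproduces the reference
    marker-recovery tables (see docs/methods.md).
    """
    sub = np.zeros(len(y), dtype=np.int16)
    idx1 = np.flatnonzero(y == 1)
    n1 = len(idx1)
    if n1 == 0:
        return sub
    if mode == "balanced":
        pool = np.tile(np.arange(1, c + 1, dtype=np.int16), n1 // c + 1)[:n1]
        sub[idx1] = pool[rng.permutation(n1)]
    elif mode == "iid":
        sub[idx1] = rng.integers(1, c + 1, n1).astype(np.int16)
    else:
        raise ParameterError(f"unknown subclass mode {mode!r}")
    return sub


def _subset_info(cfg: ModelConfig, ann: FeatureAnnotation,
                 columns: np.ndarray) -> dict:
    """Group a sorted column subset by role/block for marginal sampling."""
    role = ann.role[columns]
    out = {
        "hv_pos": np.flatnonzero(role == ROLE_HV),
        "lv_pos": np.flatnonzero(role == ROLE_LV),
        "hv_p": ann.p[columns[role == ROLE_HV]],
        "blocks": [],  # (positions in subset, within-block offsets, subclass)
    }
    marker = np.flatnonzero(role <= ROLE_HET)
    for b in np.unique(ann.block[columns[marker]]):
        pos = marker[ann.block[columns[marker]] == b]
        out["blocks"].append((pos, columns[pos] % cfg.l, int(ann.subclass[columns[pos][0]])))
    return out


def sample_expression(config: ModelConfig, n: int, rng: np.random.Generator,
                      annotation: FeatureAnnotation | None = None,
                      stratified: bool = False,
                      subclass_mode: str = "balanced",
                      feature_subset: np.ndarray | None = None,
                      dtype=np.float64,
                      extra_var: float = 0.0) -> ExpressionDataset:
    """Draw ``n`` samples from the feature-label distribution.

    Parameters
    ----------
    annotation
        Reuse an existing :class:`FeatureAnnotation` (so that training and
        test sets share the same hv mixture weights); drawn afresh if None.
    feature_subset
        Sorted original feature indices; only these columns are generated
        (the exact marginal distribution -- sub-blocks of the compound
        symmetric covariance are again compound symmetric).  Used to build
        large test sets restricted to already-selected features.
    dtype
        Floating dtype of the big Gaussian draw; float32 halves memory and
        time and is ample for standard deviations of order one.
    extra_var
        Additional independent Gaussian variance folded into every feature
        (the sequencing layer's technical noise); 0 gives the pure model.

    RNG consumption order is fixed (labels, subclasses, annotation weights
    if drawn here, main Gaussian matrix, hv mixture components), so a given
    seed reproduces the dataset bit for bit.
    """
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    cfg = config
    y = sample_labels(n, rng, stratified=stratified)
    sub = assign_subclasses(y, cfg.c, rng, mode=subclass_mode)
    if annotation is None:
        annotation = annotate_features(cfg, rng)

    chol = {
        0: compound_symmetry_cholesky(cfg.l, cfg.rho, cfg.sigma0 ** 2, extra_var).astype(dtype),
        1: compound_symmetry_cholesky(cfg.l, cfg.rho, cfg.sigma1 ** 2, extra_var).astype(dtype),
    }
    m = {0: cfg.m0, 1: cfg.m1}
    sd0 = np.sqrt(cfg.sigma0 ** 2 + extra_var)
    sd1 = np.sqrt(cfg.sigma1 ** 2 + extra_var)

    if feature_subset is None:
        X = rng.standard_normal((n, cfg.D), dtype=dtype)
        sl = cfg.feature_slices()
        _fill_marker_group(X, sl["global"], y == 1, m, chol, cfg.l)
        for k in range(1, cfg.c + 1):
            lo = cfg.D_gm + (k - 1) * cfg.D_hm
            _fill_marker_group(X, slice(lo, lo + cfg.D_hm), sub == k, m, chol, cfg.l)
        hv = sl["hv"]
        comp = rng.random((n, cfg.D_hv)) < annotation.p[hv]
        Xhv = X[:, hv]
        X[:, hv] = np.where(comp, cfg.m0 + dtype(sd0) * Xhv, cfg.m1 + dtype(sd1) * Xhv)
        lv = sl["lv"]
        X[:, lv] *= dtype(sd0)
        X[:, lv] += dtype(cfg.m0)
        columns = None
    else:
        columns = np.asarray(feature_subset, dtype=np.int64)
        if columns.ndim != 1 or np.any(np.diff(columns) <= 0):
            raise ParameterError("feature_subset must be sorted and unique")
        if columns[0] < 0 or columns[-1] >= cfg.D:
            raise ParameterError("feature_subset index out of range")
        info = _subset_info(cfg, annotation, columns)
        X = rng.standard_normal((n, len(columns)), dtype=dtype)
        for pos, offs, k in info["blocks"]:
            active = (y == 1) if k == 0 else (sub == k)
            for cls, rows in ((1, active), (0, ~active)):
                # marginal of the block: principal submatrix of its covariance
                # (compound symmetry is closed under taking sub-blocks)
                cov = (chol[cls] @ chol[cls].T)[np.ix_(offs, offs)]
                Lm = np.linalg.cholesky(cov).astype(dtype)
                X[np.ix_(rows, pos)] = m[cls] + X[np.ix_(rows, pos)] @ Lm.T
        if len(info["hv_pos"]):
            comp = rng.random((n, len(info["hv_pos"]))) < info["hv_p"]
            Zh = X[:, info["hv_pos"]]
            X[:, info["hv_pos"]] = np.where(comp, cfg.m0 + dtype(sd0) * Zh,
                                            cfg.m1 + dtype(sd1) * Zh)
        if len(info["lv_pos"]):
            X[:, info["lv_pos"]] *= dtype(sd0)
            X[:, info["lv_pos"]] += dtype(cfg.m0)

    return ExpressionDataset(X, y, sub, annotation, cfg, columns)


def _fill_marker_group(X: np.ndarray, cols: slice, active: np.ndarray,
                       m: dict, chol: dict, l: int) -> None:
    """Correlate and shift a tiled marker group in place.

    ``active`` rows get class-1 parameters, the rest class-0.
    """
    width = cols.stop - cols.start
    dtype = X.dtype.type
    for cls, rows in ((1, active), (0, ~active)):
        nr = int(rows.sum())
        if nr == 0:
            continue
        Z = X[rows, cols].reshape(nr, width // l, l)
        X[rows, cols] = dtype(m[cls]) + (Z @ chol[cls].T.astype(X.dtype)).reshape(nr, width)


# ---------------------------------------------------------------------------
# plain-text writers

def write_expression_tsv(ds: ExpressionDataset, path: str | Path) -> None:
    """Samples x features TSV with a feature-id header row."""
    ids = ds.annotation.feature_ids()
    if ds.columns is not None:
        ids = [ids[j] for j in ds.columns]
    with open(path, "w") as fh:
        fh.write("sample\tlabel\tsubclass\t" + "\t".join(ids) + "\n")
        for i in range(ds.n):
            row = "\t".join(f"{v:.6g}" for v in ds.X[i])
            fh.write(f"s{i + 1:05d}\t{ds.y[i]}\t{ds.subclass[i]}\t{row}\n")


def write_annotation_tsv(ann: FeatureAnnotation, path: str | Path) -> None:
    """Sidecar: feature id, role, subclass, block, mixture weight."""
    with open(path, "w") as fh:
        fh.write("feature\trole\tsubclass\tblock\tp\n")
        for i, fid in enumerate(ann.feature_ids()):
            pv = "" if np.isnan(ann.p[i]) else f"{ann.p[i]:.6f}"
            fh.write(f"{fid}\t{ROLE_NAMES[ann.role[i]]}\t{ann.subclass[i]}\t"
                     f"{ann.block[i]}\t{pv}\n")
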
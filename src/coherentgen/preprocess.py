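"""Modality-specific preprocessing, cohort splitting and latent embedding.

Tables are pandas DataFrames (samples x features, unique sample IDs as
index) with missing entries encoded as NaN; they round-trip through
delimited text with a leading sample-ID column.  The transforms follow
the conventions of the cohort the framework targets:

* RNA-seq: log2(count+1) values are exponentiated, normalized to counts
  per million (CPM), re-logged, and low-abundance genes dropped;
* CNA: absolute copy numbers become log2 ratios to the diploid state,
  clipped to [-2, 2], with zeros treated as missing;
* RPPA: per-protein median centering;
* all modalities: features with more than 10% missing values dropped,
  then KNN or feature-median imputation.

Splitting is stratified by cancer type with the test partition drawn
only from samples whose modalities are all observed.  Scalers and
embedding models are fit exclusively on training samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.impute import KNNImputer

from .nn import Autoencoder

__all__ = [
    "RawModalityTable",
    "CohortSplit",
    "EmbeddingModel",
    "read_table",
    "write_table",
    "rnaseq_transform",
    "filter_low_expression",
    "cna_transform",
    "rppa_center",
    "drop_sparse_features",
    "impute",
    "stratified_split",
    "fit_embedding",
    "encode",
    "decode",
]

MODALITY_NAMES = ("cna", "rnaseq", "rppa", "wsi")


@dataclass
class RawModalityTable:
    """A raw numeric table for one modality, with missing-entry markers."""

    values: pd.DataFrame
    modality: str

    def __post_init__(self):
        if self.modality not in MODALITY_NAMES:
            raise ValueError(f"modality must be one of {MODALITY_NAMES}")
        if self.values.index.has_duplicates:
            raise ValueError("sample IDs must be unique")

    @property
    def sample_ids(self):
        return self.values.index

    @property
    def feature_names(self):
        return self.values.columns


def read_table(path) -> pd.DataFrame:
    """Read a delimited table (TSV/CSV by extension) with sample-ID index."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, index_col=0, na_values=["", "NA"])


def write_table(df: pd.DataFrame, path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df.to_csv(path, sep=sep, index_label="sample_id", na_rep="NA")


# ---------------------------------------------------------------------------
# modality transforms

def rnaseq_transform(table: pd.DataFrame) -> pd.DataFrame:
    """log2(count+1) -> log2(CPM+1), per-sample library-size normalization."""
    v = table.to_numpy(dtype=np.float64)
    if np.nanmin(v) < 0:
        raise ValueError("log2(count+1) values must be non-negative")
    counts = np.power(2.0, v) - 1.0
    libsize = np.nansum(counts, axis=1)
    zero = libsize == 0
    if zero.any():
        bad = list(table.index[zero])
        raise ValueError(f"samples with all-zero counts: {bad}")
    cpm = counts / libsize[:, None] * 1e6
    return pd.DataFrame(np.log2(cpm + 1.0), index=table.index, columns=table.columns)


def filter_low_expression(cpm_table: pd.DataFrame, min_cpm: float = 1.0,
                          min_fraction: float = 0.20) -> List[str]:
    """Features with CPM strictly above ``min_cpm`` in at least
    ``min_fraction`` of samples.  Input must be on the CPM scale."""
    frac = (cpm_table > min_cpm).mean(axis=0)
    return list(cpm_table.columns[frac >= min_fraction])


def cna_transform(table: pd.DataFrame) -> pd.DataFrame:
    """Absolute copy number -> log2 ratio to diploid, clipped to [-2, 2].

    Zeros are undefined under the log transform and become missing.
    """
    v = table.to_numpy(dtype=np.float64)
    if np.nanmin(v) < 0:
        raise ValueError("copy-number values must be non-negative")
    out = np.full_like(v, np.nan)
    pos = v > 0
    out[pos] = np.clip(np.log2(v[pos] / 2.0), -2.0, 2.0)
    return pd.DataFrame(out, index=table.index, columns=table.columns)


def rppa_center(table: pd.DataFrame) -> pd.DataFrame:
    """Subtract each protein's median across samples (missing ignored)."""
    if table.isna().all(axis=0).any():
        bad = list(table.columns[table.isna().all(axis=0)])
        raise ValueError(f"features with no observed values: {bad}")
    return table - table.median(axis=0, skipna=True)


def drop_sparse_features(table: pd.DataFrame, max_missing_fraction: float = 0.10) -> pd.DataFrame:
    """Remove features missing in strictly more than the given fraction."""
    frac = table.isna().mean(axis=0)
    return table.loc[:, frac <= max_missing_fraction]


def impute(
    table: pd.DataFrame,
    method: str,
    k: int = 5,
    reference: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Fill missing entries by KNN or feature-wise median.

    ``reference`` supplies the fitting data (the training partition);
    it defaults to ``table`` itself.  KNN fills with the mean of the k
    nearest reference samples under Euclidean distance over co-observed
    features; median mode uses each feature's reference median.
    """
    ref = table if reference is None else reference
    if ref.isna().all(axis=0).any():
        bad = list(ref.columns[ref.isna().all(axis=0)])
        raise ValueError(f"features with no observed values: {bad}")
    if method == "median":
        return table.fillna(ref.median(axis=0, skipna=True))
    if method == "knn":
        imputer = KNNImputer(n_neighbors=k)
        imputer.fit(ref.to_numpy(dtype=np.float64))
        filled = imputer.transform(table.to_numpy(dtype=np.float64))
        return pd.DataFrame(filled, index=table.index, columns=table.columns)
    raise ValueError(f"unknown imputation method {method!r}")


# ---------------------------------------------------------------------------
# splitting

@dataclass
class CohortSplit:
    """Disjoint train/validation/test sample-ID sets with strata."""

    train_ids: List[str]
    val_ids: List[str]
    test_ids: List[str]
    strata: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self):
        sets = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        if sum(len(s) for s in sets) != len(set().union(*sets)):
            raise ValueError("split partitions overlap")


def _largest_remainder(n: int, fractions: Sequence[float]) -> List[int]:
    raw = [n * f for f in fractions]
    base = [int(np.floor(r)) for r in raw]
    short = n - sum(base)
    order = np.argsort([-(r - b) for r, b in zip(raw, base)], kind="stable")
    for i in order[:short]:
        base[i] += 1
    return base


def stratified_split(
    ids: Sequence[str],
    type_labels: Mapping[str, object],
    fractions=(0.80, 0.05, 0.15),
    completeness: Optional[Mapping[str, bool]] = None,
    seed: int = 0,
) -> CohortSplit:
    """Stratified train/val/test split with an all-complete test set.

    Within each stratum, partition sizes follow the fractions via
    largest-remainder rounding; the test quota is drawn only from samples
    flagged complete (all modalities observed).  A stratum with too few
    complete samples gets a reduced test quota and a logged warning.
    Deterministic given the seed.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    ids = list(ids)
    completeness = completeness or {i: True for i in ids}
    rng = np.random.default_rng(seed)
    train, val, test = [], [], []
    strata: Dict[str, object] = {i: type_labels[i] for i in ids}
    for stratum in sorted({str(type_labels[i]) for i in ids}):
        members = np.array([i for i in ids if str(type_labels[i]) == stratum])
        rng.shuffle(members)
        n_tr, n_va, n_te = _largest_remainder(len(members), fractions)
        complete = [i for i in members if completeness.get(i, False)]
        if len(complete) < n_te:
            warnings.warn(
                f"stratum {stratum!r}: only {len(complete)} complete samples for a "
                f"test quota of {n_te}; quota reduced"
            )
            n_te = len(complete)
        test_s = complete[:n_te]
        rest = [i for i in members if i not in set(test_s)]
        # reallocate train/val over what remains (absorbs a reduced test quota)
        f_tr, f_va = fractions[0], fractions[1]
        n_tr, n_va = _largest_remainder(
            len(rest), (f_tr / (f_tr + f_va), f_va / (f_tr + f_va))
        )
        train.extend(rest[:n_tr])
        val.extend(rest[n_tr:])
        test.extend(test_s)
    return CohortSplit(train, val, test, strata)


# ---------------------------------------------------------------------------
# embedding

@dataclass
class EmbeddingModel:
    """A fitted per-modality embedding to the shared latent space.

    Per-feature standardization (center/scale, fit on train) is applied
    before the embedding; ``method`` is either a symmetric autoencoder
    (omics tables) or PCA (already-embedded vectors).
    """

    modality: str
    method: str
    latent_dim: int
    feature_names: List[str]
    center: np.ndarray
    scale: np.ndarray
    _pca: Optional[PCA] = None
    _ae: Optional[Autoencoder] = None

    def _standardize(self, table: pd.DataFrame) -> np.ndarray:
        X = table[self.feature_names].to_numpy(dtype=np.float64)
        return (X - self.center) / self.scale

    def encode_values(self, table: pd.DataFrame) -> np.ndarray:
        Z = self._standardize(table)
        if self.method == "pca":
            return self._pca.transform(Z)
        return self._ae.encode(Z)

    def decode_values(self, latent: np.ndarray) -> np.ndarray:
        latent = np.asarray(latent, dtype=np.float64)
        if self.method == "pca":
            Z = self._pca.inverse_transform(latent)
        else:
            Z = self._ae.decode(latent)
        return Z * self.scale + self.center


def fit_embedding(
    train_table: pd.DataFrame,
    modality: str,
    latent_dim: int = 32,
    method: str = "autoencoder",
    val_table: Optional[pd.DataFrame] = None,
    seed: int = 0,
    **ae_kwargs,
) -> EmbeddingModel:
    """Fit a per-modality embedding on training samples only.

    The per-feature scaler is fit on ``train_table``; the autoencoder
    early-stops on ``val_table`` (a held-out slice of the training data
    when none is supplied).  PCA requires ``latent_dim`` below the
    feature count.
    """
    X = train_table.to_numpy(dtype=np.float64)
    if np.isnan(X).any():
        raise ValueError("impute missing values before embedding")
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    if np.all(scale == 0):
        raise ValueError("degenerate training table: zero variance everywhere")
    scale = np.where(scale == 0, 1.0, scale)
    Z = (X - center) / scale

    model = EmbeddingModel(
        modality=modality,
        method=method,
        latent_dim=latent_dim,
        feature_names=list(train_table.columns),
        center=center,
        scale=scale,
    )
    if method == "pca":
        if latent_dim >= X.shape[1]:
            raise ValueError(
                f"latent_dim={latent_dim} must be below the feature count {X.shape[1]}"
            )
        model._pca = PCA(n_components=latent_dim, random_state=seed).fit(Z)
    elif method == "autoencoder":
        if val_table is not None:
            Zv = (val_table[model.feature_names].to_numpy(float) - center) / scale
            Ztr = Z
        else:
            rng = np.random.default_rng(seed)
            idx = rng.permutation(len(Z))
            n_val = max(1, len(Z) // 10)
            Zv, Ztr = Z[idx[:n_val]], Z[idx[n_val:]]
        ae = Autoencoder(X.shape[1], latent_dim, seed=seed,
                         hidden=ae_kwargs.pop("hidden", 128))
        ae.fit(Ztr, Zv, seed=seed, **ae_kwargs)
        model._ae = ae
    else:
        raise ValueError(f"unknown embedding method {method!r}")
    return model


def encode(model: EmbeddingModel, table: pd.DataFrame) -> pd.DataFrame:
    """Embed a table into the latent space (columns ``<modality>_i``)."""
    latent = model.encode_values(table)
    cols = [f"{model.modality}_{j}" for j in range(model.latent_dim)]
    return pd.DataFrame(latent, index=table.index, columns=cols)


def decode(model: EmbeddingModel, latent: pd.DataFrame) -> pd.DataFrame:
    """Map latent vectors back to the feature space."""
    values = latent.to_numpy(dtype=np.float64) if hasattr(latent, "to_numpy") else latent
    rec = model.decode_values(values)
    idx = latent.index if hasattr(latent, "index") else None
    return pd.DataFrame(rec, index=idx, columns=model.feature_names)
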
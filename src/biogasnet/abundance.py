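"""Protein-group abundance tables: I/O, filtering, normalization, aggregation.

The in-memory convention follows scikit-learn: an abundance table is a
:class:`pandas.DataFrame` with one row per sample and one column per feature
(protein group, species, family or KO).  The row index is a two-level
``MultiIndex`` ``(plant, replicate)``.  On disk the transposed layout is used
(rows = features, header ``feature_id<TAB>plant:replicate ...``), which is the
common exchange format for proteomics abundance matrices.

Absences are encoded as zeros, never as missing values; a cell is "present"
when it is strictly positive.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

SAMPLE_INDEX_NAMES = ("plant", "replicate")
UNASSIGNED = "unassigned"

ANNOTATION_COLUMNS = ("species_id", "species_name", "family", "ko_ids", "ec_ids")


# ---------------------------------------------------------------------------
# validation helpers
# ---------------------------------------------------------------------------

def check_abundance_frame(X: pd.DataFrame) -> pd.DataFrame:
    """Validate an abundance table (samples x features, nonnegative, no NaN)."""
    if not isinstance(X, pd.DataFrame):
        raise TypeError("abundance table must be a pandas DataFrame")
    values = X.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("abundance table contains missing values; encode absence as 0")
    if (values < 0).any():
        i, j = np.argwhere(values < 0)[0]
        raise ValueError(
            f"negative abundance at sample {X.index[i]!r}, feature {X.columns[j]!r}"
        )
    return X


def sample_plants(X: pd.DataFrame) -> pd.Index:
    """Plant id of every sample row."""
    if isinstance(X.index, pd.MultiIndex):
        return X.index.get_level_values(0)
    return X.index


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _parse_sample_label(label: str, lineno_hint: str):
    plant, sep, rep = label.partition(":")
    if not sep or not plant or not rep:
        raise ValueError(
            f"malformed sample header {label!r} in {lineno_hint}: expected 'plant:replicate'"
        )
    try:
        rep_no = int(rep)
    except ValueError as exc:
        raise ValueError(
            f"malformed replicate number in sample header {label!r} ({lineno_hint})"
        ) from exc
    return plant, rep_no


def read_abundance(path) -> pd.DataFrame:
    """Read a feature x sample abundance TSV into the samples x features frame."""
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.index.name != "feature_id":
        raise ValueError(
            f"parse error in {path}, line 1: first header field must be 'feature_id', "
            f"got {raw.index.name!r}"
        )
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise ValueError(f"duplicate feature_id {dup!r} in {path}")
    try:
        values = raw.astype(float)
    except ValueError as exc:
        raise ValueError(f"parse error in {path}: non-numeric abundance value ({exc})") from exc
    tuples = [_parse_sample_label(c, f"{path}, line 1") for c in values.columns]
    X = values.T
    X.index = pd.MultiIndex.from_tuples(tuples, names=SAMPLE_INDEX_NAMES)
    X.columns.name = "feature_id"
    return check_abundance_frame(X)


def _split_ids(cell) -> frozenset:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
        return frozenset()
    return frozenset(tok for tok in str(cell).split(";") if tok)


def read_annotation(path) -> pd.DataFrame:
    """Read the feature annotation TSV (species/family/KO/EC per protein group)."""
    ann = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in ("feature_id",) + ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ValueError(f"annotation {path} missing column(s): {', '.join(missing)}")
    if ann["feature_id"].duplicated().any():
        dup = ann.loc[ann["feature_id"].duplicated(), "feature_id"].iloc[0]
        raise ValueError(f"duplicate feature_id {dup!r} in annotation {path}")
    ann = ann.set_index("feature_id")
    ann["ko_ids"] = ann["ko_ids"].map(_split_ids)
    ann["ec_ids"] = ann["ec_ids"].map(_split_ids)
    by_species = ann.loc[ann["species_id"] != ""].groupby("species_id")["species_name"].nunique()
    if (by_species > 1).any():
        bad = by_species.index[by_species > 1][0]
        raise ValueError(f"species_id {bad!r} maps to more than one species_name")
    return ann


def read_abundance_table(path, annotation_path):
    """Read an abundance table plus its annotation, aligned on feature_id.

    Features present in the abundance table but absent from the annotation are
    retained with an empty annotation (warning logged); annotation rows without
    abundance are dropped (warning logged).
    """
    X = read_abundance(path)
    ann = read_annotation(annotation_path)

    unannotated = X.columns.difference(ann.index)
    if len(unannotated):
        logger.warning(
            "%d feature(s) lack annotation and are retained with empty annotation: %s",
            len(unannotated), ", ".join(map(str, unannotated[:5])),
        )
        filler = pd.DataFrame(
            {"species_id": "", "species_name": "", "family": "",
             "ko_ids": [frozenset()] * len(unannotated),
             "ec_ids": [frozenset()] * len(unannotated)},
            index=unannotated,
        )
        ann = pd.concat([ann, filler])
    orphaned = ann.index.difference(X.columns)
    if len(orphaned):
        logger.warning("%d annotation row(s) have no abundance and were dropped", len(orphaned))
    ann = ann.loc[X.columns]
    ann.index.name = "feature_id"
    return X, ann


def write_abundance(X: pd.DataFrame, path) -> None:
    """Write the on-disk (feature x sample) TSV for an abundance frame."""
    out = X.T.copy()
    out.columns = [f"{p}:{r}" for p, r in X.index]
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


def write_annotation(ann: pd.DataFrame, path) -> None:
    out = ann.copy()
    for col in ("ko_ids", "ec_ids"):
        out[col] = out[col].map(lambda s: ";".join(sorted(s)))
    out.to_csv(path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    """Per-plant process metadata TSV, keyed by plant_id."""
    meta = pd.read_csv(path, sep="\t", index_col="plant_id")
    return meta


# ---------------------------------------------------------------------------
# filtering / normalization / aggregation
# ---------------------------------------------------------------------------

def filter_replicate_presence(
    X: pd.DataFrame, min_present: int = 3, per_plant: bool = False
) -> pd.DataFrame:
    """Drop features not observed in at least ``min_present`` replicates of any plant.

    A feature is observed in a replicate when its abundance is strictly
    positive.  By default the filter keeps a feature for the whole table as
    soon as one plant passes; with ``per_plant=True`` the feature is in
    addition zeroed out within every plant that individually fails the
    threshold.
    """
    check_abundance_frame(X)
    plants = sample_plants(X)
    present = (X > 0).groupby(plants, observed=True).sum()
    passes = present >= min_present               # plants x features
    keep = passes.any(axis=0)
    removed = X.columns[~keep]
    if len(removed):
        logger.info("replicate-presence filter removed %d feature(s)", len(removed))
    out = X.loc[:, keep]
    if per_plant:
        mask = passes.loc[plants, keep.index[keep]].to_numpy()
        out = out.where(mask, 0.0)
    return out


def normalize_relative(X: pd.DataFrame, total: float = 100.0) -> pd.DataFrame:
    """Rescale every sample so its feature abundances sum to ``total`` (percent)."""
    check_abundance_frame(X)
    sums = X.sum(axis=1)
    if (sums <= 0).any():
        bad = sums.index[sums <= 0][0]
        raise ValueError(f"sample {bad!r} has zero total abundance; cannot normalize")
    return X.mul(total / sums, axis=0)


def aggregate(
    X: pd.DataFrame,
    annotation: pd.DataFrame,
    level: str,
    multi_ko: str = "full",
) -> pd.DataFrame:
    """Sum protein-group abundances up to species, family or KO level.

    At ``level='ko'`` a protein group annotated with k KO identifiers
    contributes, under the default ``multi_ko='full'`` convention, its full
    abundance to each of the k KO columns (so KO-level totals may exceed the
    sample total); ``multi_ko='split'`` divides the abundance evenly instead.
    Features without a key at the requested level are collected under the
    reserved ``'unassigned'`` column.
    """
    if level not in ("species", "family", "ko"):
        raise ValueError(f"unknown aggregation level {level!r}")
    if multi_ko not in ("full", "split"):
        raise ValueError(f"multi_ko must be 'full' or 'split', got {multi_ko!r}")
    ann = annotation.loc[X.columns]
    if level == "ko":
        blocks: dict[str, np.ndarray] = {}
        arr = X.to_numpy(dtype=float)
        for j, kos in enumerate(ann["ko_ids"]):
            if not kos:
                keys, w = [UNASSIGNED], 1.0
            else:
                keys = sorted(kos)
                w = 1.0 / len(keys) if multi_ko == "split" else 1.0
            for key in keys:
                if key in blocks:
                    blocks[key] = blocks[key] + arr[:, j] * w
                else:
                    blocks[key] = arr[:, j] * w
        out = pd.DataFrame(blocks, index=X.index)
    else:
        col = "species_id" if level == "species" else "family"
        keys = ann[col].where(ann[col] != "", UNASSIGNED)
        out = X.T.groupby(keys.values).sum().T
    out = out.reindex(sorted(out.columns), axis=1)
    out.columns.name = level
    return out


def plant_means(X: pd.DataFrame, renormalize: bool = True, total: float = 100.0) -> pd.DataFrame:
    """Average replicate rows within each plant; optionally re-close to ``total``."""
    check_abundance_frame(X)
    means = X.groupby(sample_plants(X), observed=True).mean()
    means.index.name = "plant"
    if renormalize:
        means = normalize_relative(means, total=total)
    return means


# ---------------------------------------------------------------------------
# sklearn transformers
# ---------------------------------------------------------------------------

class ReplicatePresenceFilter(TransformerMixin, BaseEstimator):
    """Transformer form of :func:`filter_replicate_presence`.

    Parameters
    ----------
    min_present : int, default=3
        Minimum number of strictly positive replicates a plant must show for a
        feature before the feature counts as observed in that plant.
    per_plant : bool, default=False
        Zero the feature within plants that individually fail the threshold.
    """

    def __init__(self, min_present: int = 3, per_plant: bool = False):
        self.min_present = min_present
        self.per_plant = per_plant

    def fit(self, X: pd.DataFrame, y=None):
        check_abundance_frame(X)
        kept = filter_replicate_presence(X, self.min_present, per_plant=False)
        self.kept_features_ = kept.columns
        self.removed_features_ = X.columns.difference(kept.columns)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self)
        out = X.loc[:, self.kept_features_]
        if self.per_plant:
            out = filter_replicate_presence(out, self.min_present, per_plant=True)
        return out


class RelativeAbundanceNormalizer(TransformerMixin, BaseEstimator):
    """Close every sample to a fixed total (default 100%); stateless, idempotent."""

    def __init__(self, total: float = 100.0):
        self.total = total

    def fit(self, X: pd.DataFrame, y=None):
        check_abundance_frame(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return normalize_relative(X, total=self.total)


class PrevalenceFilter(TransformerMixin, BaseEstimator):
    """Keep features observed in at least a fraction of samples.

    The co-occurrence ensemble only scores taxa seen in >= ``min_fraction`` of
    the replicate set (default 60%), i.e. ``ceil(min_fraction * n_samples)``
    strictly positive cells.
    """

    def __init__(self, min_fraction: float = 0.6):
        self.min_fraction = min_fraction

    def fit(self, X: pd.DataFrame, y=None):
        check_abundance_frame(X)
        if not 0 < self.min_fraction <= 1:
            raise ValueError("min_fraction must be in (0, 1]")
        n_required = int(np.ceil(self.min_fraction * X.shape[0]))
        present = (X > 0).sum(axis=0)
        self.n_required_ = n_required
        self.kept_features_ = X.columns[present >= n_required]
        self.removed_features_ = X.columns[present < n_required]
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self)
        return X.loc[:, self.kept_features_]


def prevalence_filter(X: pd.DataFrame, min_fraction: float = 0.6) -> pd.DataFrame:
    """Functional form of :class:`PrevalenceFilter` (fit and transform on X)."""
    return PrevalenceFilter(min_fraction).fit(X).transform(X)
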
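"""Core containers for multiplatform metabolomics studies.

A study consists of one feature matrix per analytical platform (e.g. LC-MS in
positive and negative ionization modes, GC-MS, CE-MS) plus one clinical
metadata table.  Each feature matrix holds raw (or preprocessed) intensities
for study samples, pooled quality-control (QC) samples and blanks, together
with the injection order of every sample and the identifiers of any spiked
internal-standard (IS) channels.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

VALID_ROLES = ("study", "qc", "blank")

#: strings parsed as missing values in delimited files; zeros are measured values
NA_VALUES = ["", "NA"]


class DataModelError(ValueError):
    """Raised when a container invariant is violated."""


@dataclasses.dataclass
class FeatureMatrix:
    """One platform's samples x features intensity table.

    Parameters
    ----------
    platform_id:
        Label of the analytical platform (e.g. ``"lcms_pos"``).
    values:
        DataFrame of non-negative intensities, rows indexed by sample id,
        columns by feature id.  ``NaN`` encodes a missing measurement.
    sample_roles:
        Per-sample role, one of ``study``, ``qc``, ``blank``.
    injection_order:
        Per-sample positive integer, unique within the matrix.
    is_features:
        Feature ids flagged as internal standards.
    """

    platform_id: str
    values: pd.DataFrame
    sample_roles: pd.Series
    injection_order: pd.Series
    is_features: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.is_features = tuple(self.is_features)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()][0]
            raise DataModelError(
                f"{self.platform_id}: duplicate sample id {dup!r}")
        if v.columns.duplicated().any():
            dup = v.columns[v.columns.duplicated()][0]
            raise DataModelError(
                f"{self.platform_id}: duplicate feature id {dup!r}")
        if not self.sample_roles.index.equals(v.index):
            raise DataModelError(f"{self.platform_id}: sample_roles index mismatch")
        if not self.injection_order.index.equals(v.index):
            raise DataModelError(f"{self.platform_id}: injection_order index mismatch")
        bad_roles = set(self.sample_roles.unique()) - set(VALID_ROLES)
        if bad_roles:
            raise DataModelError(f"{self.platform_id}: invalid roles {bad_roles}")
        if (self.sample_roles == "study").sum() < 1:
            raise DataModelError(f"{self.platform_id}: no study samples")
        order = self.injection_order
        if order.duplicated().any() or (order <= 0).any():
            raise DataModelError(
                f"{self.platform_id}: injection_order must be unique positive integers")
        unknown_is = set(self.is_features) - set(v.columns)
        if unknown_is:
            raise DataModelError(
                f"{self.platform_id}: unknown IS features {sorted(unknown_is)}")
        arr = v.to_numpy(dtype=float)
        neg = np.argwhere(arr < 0)
        if neg.size:
            i, j = neg[0]
            raise DataModelError(
                f"{self.platform_id}: negative intensity at sample "
                f"{v.index[i]!r}, feature {v.columns[j]!r}")

    # -- convenience ------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def role_ids(self, role: str) -> list[str]:
        return list(self.values.index[self.sample_roles == role])

    @property
    def study_ids(self) -> list[str]:
        return self.role_ids("study")

    @property
    def qc_ids(self) -> list[str]:
        return self.role_ids("qc")

    def study_values(self) -> pd.DataFrame:
        return self.values.loc[self.sample_roles == "study"]

    def qc_values(self) -> pd.DataFrame:
        return self.values.loc[self.sample_roles == "qc"]

    def with_values(self, values: pd.DataFrame) -> "FeatureMatrix":
        """New matrix sharing roles/order metadata, with replaced values."""
        is_feats = tuple(f for f in self.is_features if f in values.columns)
        return FeatureMatrix(
            platform_id=self.platform_id,
            values=values,
            sample_roles=self.sample_roles.loc[values.index],
            injection_order=self.injection_order.loc[values.index],
            is_features=is_feats,
        )

    def select_samples(self, sample_ids: Sequence[str]) -> "FeatureMatrix":
        return self.with_values(self.values.loc[list(sample_ids)])

    def select_features(self, feature_ids: Sequence[str]) -> "FeatureMatrix":
        return self.with_values(self.values[list(feature_ids)])

    def drop_features(self, feature_ids: Iterable[str]) -> "FeatureMatrix":
        keep = [f for f in self.values.columns if f not in set(feature_ids)]
        return self.select_features(keep)

    def copy(self) -> "FeatureMatrix":
        return self.with_values(self.values.copy())


@dataclasses.dataclass
class StudyBundle:
    """All platform matrices of one study plus the sample metadata table."""

    matrices: list[FeatureMatrix]
    metadata: pd.DataFrame  # indexed by sample_id

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.matrices:
            raise DataModelError("bundle has no matrices")
        if self.metadata.index.duplicated().any():
            raise DataModelError("duplicate sample_id in metadata")
        meta_ids = set(self.metadata.index)
        for m in self.matrices:
            missing = set(m.study_ids) - meta_ids
            if missing:
                raise DataModelError(
                    f"{m.platform_id}: study samples absent from metadata: "
                    f"{sorted(missing)[:5]}")
        if not self.shared_study_ids():
            raise DataModelError("no study sample shared by all matrices")

    def shared_study_ids(self) -> list[str]:
        """Study sample ids present in every matrix, sorted lexicographically."""
        shared = set(self.matrices[0].study_ids)
        for m in self.matrices[1:]:
            shared &= set(m.study_ids)
        return sorted(shared)

    def matrix(self, platform_id: str) -> FeatureMatrix:
        for m in self.matrices:
            if m.platform_id == platform_id:
                return m
        raise KeyError(platform_id)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_META_COLS = ("sample_id", "role", "injection_order")


def read_feature_matrix(path: str | Path,
                        platform_id: str,
                        is_features: Sequence[str] = ()) -> FeatureMatrix:
    """Read one platform's feature matrix from delimited text.

    Layout: rows are samples; mandatory columns ``sample_id``, ``role``
    (study|qc|blank) and ``injection_order``; every remaining column is a
    feature.  Empty cells and the literal ``NA`` are missing values; zeros
    are measured values (legitimate after blank subtraction).
    """
    df = pd.read_csv(path, sep=None, engine="python",
                     na_values=NA_VALUES, keep_default_na=False, dtype={"sample_id": str})
    for col in _META_COLS:
        if col not in df.columns:
            raise DataModelError(f"{path}: missing mandatory column {col!r}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise DataModelError(f"{path}: duplicate sample id {dup!r}")
    df = df.set_index("sample_id")
    feature_cols = [c for c in df.columns if c not in ("role", "injection_order")]
    values = df[feature_cols].astype(float)
    return FeatureMatrix(
        platform_id=platform_id,
        values=values,
        sample_roles=df["role"].astype(str),
        injection_order=df["injection_order"].astype(int),
        is_features=tuple(is_features),
    )


def write_feature_matrix(m: FeatureMatrix, path: str | Path) -> None:
    """Write a feature matrix in the layout read by :func:`read_feature_matrix`."""
    out = pd.DataFrame(index=m.values.index)
    out.index.name = "sample_id"
    out["role"] = m.sample_roles
    out["injection_order"] = m.injection_order
    out = pd.concat([out, m.values], axis=1)
    out.to_csv(path, na_rep="")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample metadata table (delimited text keyed by ``sample_id``)."""
    df = pd.read_csv(path, sep=None, engine="python",
                     na_values=NA_VALUES, keep_default_na=False, dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise DataModelError(f"{path}: missing column 'sample_id'")
    if df["sample_id"].duplicated().any():
        raise DataModelError(f"{path}: duplicate sample_id in metadata")
    return df.set_index("sample_id")


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, index_label="sample_id")


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def align_study_samples(bundle: StudyBundle) -> StudyBundle:
    """Restrict all matrices to the shared study samples, in one shared order.

    Samples dropped from any platform (e.g. analytical outliers) are thereby
    dropped from every platform.  The shared study samples are placed first,
    in lexicographic order, followed by each matrix's own QC/blank samples in
    their original order.  Idempotent.
    """
    shared = bundle.shared_study_ids()
    if not shared:
        raise DataModelError("no study sample shared by all matrices")
    new_matrices = []
    for m in bundle.matrices:
        other = [s for s in m.sample_ids if m.sample_roles[s] != "study"]
        new_matrices.append(m.select_samples(shared + other))
    return StudyBundle(matrices=new_matrices, metadata=bundle.metadata)
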
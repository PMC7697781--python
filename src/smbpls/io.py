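"""Feature-table data model, TSV/CSV round-trip and multi-block alignment.

A :class:`FeatureTable` holds one block of a multi-omics study: a
samples x features intensity matrix plus per-sample metadata (subject,
class label, time point, injection order, role) and per-feature metadata
(m/z, retention time, ionization mode).  A :class:`MultiBlock` is an
ordered set of feature tables restricted to a common, identically ordered
sample set — the shape required before any joint model can be fitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: reserved sample-metadata columns, in canonical file order
SAMPLE_META_COLUMNS = (
    "sample_id",
    "subject_id",
    "class_label",
    "time_point",
    "injection_order",
    "role",
)

VALID_ROLES = frozenset({"sample", "QC", "blank"})


class ValidationError(ValueError):
    """Raised when an ingested table violates a structural invariant."""


@dataclass
class FeatureTable:
    """One block: intensities indexed by sample_id x feature_id.

    ``intensities`` is a float DataFrame (missing values as NaN, never
    zero-imputed at I/O time); ``sample_meta`` is indexed by sample_id with
    columns subject_id, class_label, time_point, injection_order, role;
    ``var_meta`` is indexed by feature_id with optional columns mz, rt, mode.
    """

    intensities: pd.DataFrame
    sample_meta: pd.DataFrame
    var_meta: pd.DataFrame
    name: str = "block"
    #: relaxed for derived tables (centered/scaled data may go negative)
    allow_negative: bool = False

    def __post_init__(self) -> None:
        self.validate()

    # -- basic accessors ---------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]

    def rows_with_role(self, role: str) -> "FeatureTable":
        mask = self.sample_meta["role"] == role
        return self.subset(sample_ids=list(self.sample_meta.index[mask]))

    def subset(
        self,
        sample_ids: Sequence[str] | None = None,
        feature_ids: Sequence[str] | None = None,
    ) -> "FeatureTable":
        """Return a new table restricted to the given samples/features."""
        sid = list(sample_ids) if sample_ids is not None else self.sample_ids
        fid = list(feature_ids) if feature_ids is not None else self.feature_ids
        return FeatureTable(
            intensities=self.intensities.loc[sid, fid].copy(),
            sample_meta=self.sample_meta.loc[sid].copy(),
            var_meta=self.var_meta.loc[fid].copy(),
            name=self.name,
            allow_negative=self.allow_negative,
        )

    def validate(self) -> None:
        idx = self.intensities.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValidationError(f"duplicate sample_id {dup!r}")
        cols = self.intensities.columns
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise ValidationError(f"duplicate feature_id {dup!r}")
        if not idx.equals(self.sample_meta.index):
            raise ValidationError("sample_meta index does not match intensities")
        if not cols.equals(self.var_meta.index):
            raise ValidationError("var_meta index does not match intensities")
        if not self.allow_negative:
            vals = self.intensities.to_numpy(dtype=float)
            neg = np.argwhere(vals < 0)
            if neg.size:
                i, j = neg[0]
                raise ValidationError(
                    f"negative intensity at sample {idx[i]!r}, feature {cols[j]!r}"
                )
        bad_roles = set(self.sample_meta["role"].unique()) - VALID_ROLES
        if bad_roles:
            raise ValidationError(f"unknown sample role(s): {sorted(bad_roles)}")
        order = self.sample_meta["injection_order"]
        if order.duplicated().any():
            dup = order[order.duplicated()].iloc[0]
            raise ValidationError(f"duplicate injection_order {dup}")
        if (order <= 0).any():
            raise ValidationError("injection_order must be a positive integer")


@dataclass
class MultiBlock:
    """Ordered blocks sharing one sample_id sequence, plus recorded norms.

    ``block_norms`` is filled by Frobenius normalization; before that it
    holds NaN placeholders of the right length.
    """

    blocks: list[FeatureTable]
    block_names: list[str] = field(default_factory=list)
    block_norms: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.block_names:
            self.block_names = [b.name for b in self.blocks]
        if not self.block_norms:
            self.block_norms = [float("nan")] * len(self.blocks)
        if len(self.block_norms) != len(self.blocks):
            raise ValidationError("block_norms length must equal number of blocks")
        ref = self.blocks[0].sample_ids
        for b in self.blocks[1:]:
            if b.sample_ids != ref:
                raise ValidationError(
                    f"block {b.name!r} sample order differs from {self.blocks[0].name!r}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return self.blocks[0].sample_ids

    @property
    def sample_meta(self) -> pd.DataFrame:
        return self.blocks[0].sample_meta

    @property
    def n_samples(self) -> int:
        return self.blocks[0].n_samples

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def feature_counts(self) -> list[int]:
        return [b.n_features for b in self.blocks]

    def concatenated(self) -> np.ndarray:
        """Superblock: horizontal concatenation of all block matrices."""
        return np.hstack([b.intensities.to_numpy(dtype=float) for b in self.blocks])

    def map_blocks(self, fn) -> "MultiBlock":
        """Apply ``fn(block_matrix: ndarray, index) -> ndarray`` per block."""
        new = []
        for i, b in enumerate(self.blocks):
            arr = fn(b.intensities.to_numpy(dtype=float), i)
            new.append(
                FeatureTable(
                    intensities=pd.DataFrame(
                        arr, index=b.intensities.index, columns=b.intensities.columns
                    ),
                    sample_meta=b.sample_meta.copy(),
                    var_meta=b.var_meta.copy(),
                    name=b.name,
                    allow_negative=True,
                )
            )
        return MultiBlock(new, list(self.block_names), list(self.block_norms))


# --------------------------------------------------------------------------
# file I/O
# --------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".vars.tsv")


def read_feature_table(path: str | Path, dialect: str = "TSV", name: str | None = None) -> FeatureTable:
    """Read a feature table from a flat TSV/CSV file.

    The file must contain the reserved metadata columns
    (sample_id, subject_id, class_label, time_point, injection_order, role)
    followed by one column per feature.  Empty cells are missing intensities.
    Feature metadata (mz, rt, mode) is read from an optional sidecar
    ``<file>.vars.tsv`` written by :func:`write_feature_table`.
    """
    path = Path(path)
    sep = "\t" if dialect.upper() == "TSV" else ","
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str, "subject_id": str})
    missing = [c for c in SAMPLE_META_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing reserved metadata column(s): {missing}")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if not dup.empty:
        raise ValidationError(f"duplicate sample_id {dup.iloc[0]!r}")
    df = df.set_index("sample_id")
    meta = df[list(SAMPLE_META_COLUMNS[1:])].copy()
    meta["class_label"] = meta["class_label"].fillna("").astype(str)
    meta["time_point"] = meta["time_point"].fillna("").astype(str)
    meta["injection_order"] = meta["injection_order"].astype(int)
    inten = df.drop(columns=list(SAMPLE_META_COLUMNS[1:])).astype(float)

    side = _sidecar_path(path)
    if side.exists():
        var_meta = pd.read_csv(side, sep="\t", index_col="feature_id")
        var_meta = var_meta.reindex(inten.columns)
    else:
        var_meta = pd.DataFrame(
            {"mz": np.nan, "rt": np.nan, "mode": None}, index=inten.columns
        )
    var_meta.index.name = "feature_id"
    return FeatureTable(
        intensities=inten,
        sample_meta=meta,
        var_meta=var_meta,
        name=name or path.stem,
    )


def write_feature_table(table: FeatureTable, path: str | Path, dialect: str = "TSV") -> None:
    """Write a feature table plus its ``.vars.tsv`` feature-metadata sidecar."""
    path = Path(path)
    sep = "\t" if dialect.upper() == "TSV" else ","
    out = pd.concat([table.sample_meta, table.intensities], axis=1)
    out.index.name = "sample_id"
    out.to_csv(path, sep=sep)
    vm = table.var_meta.copy()
    vm.index.name = "feature_id"
    vm.to_csv(_sidecar_path(path), sep="\t")


# --------------------------------------------------------------------------
# alignment
# --------------------------------------------------------------------------

def align_blocks(tables: Sequence[FeatureTable]) -> MultiBlock:
    """Restrict blocks to their common samples in a canonical shared order.

    QC and blank rows are dropped first; a sample missing from any one block
    is removed from all blocks.  The shared order is lexicographic by
    (subject_id, time_point) and thus deterministic.
    """
    if len(tables) < 2:
        raise ValidationError("alignment requires at least two blocks")
    kept = [t.rows_with_role("sample") for t in tables]
    common: set[str] | None = None
    for t in kept:
        ids = set(t.sample_ids)
        common = ids if common is None else common & ids
    assert common is not None
    if not common:
        raise ValidationError("no common samples across blocks")
    for t in kept:
        dropped = len(t.sample_ids) - len(common)
        if dropped:
            logger.info("align_blocks: dropping %d sample(s) from block %r", dropped, t.name)
    ref = kept[0].sample_meta.loc[sorted(common)]
    order = ref.sort_values(["subject_id", "time_point"]).index.tolist()
    return MultiBlock([t.subset(sample_ids=order) for t in kept])
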
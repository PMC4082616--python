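"""Dataset containers and tab-delimited matrix IO.

A :class:`DatasetBundle` holds one named data source -- an expression matrix
(samples x probes) or a morphometric trait table (samples x traits) -- together
with its sample/feature identifiers and an ordered provenance trail of the
transforms applied to it.

On disk, matrices follow the field convention of feature ids down the first
column and sample ids across the header row; in memory the orientation is
samples x features (a pandas DataFrame indexed by sample id).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["DatasetBundle", "read_matrix", "write_matrix"]


@dataclass
class DatasetBundle:
    """One named data source entering the analysis.

    Parameters
    ----------
    name : str
        Source label (e.g. ``"blood"``, ``"dura"``, ``"cranial"``).
    data : pandas.DataFrame
        Samples x features numeric matrix; index = sample ids,
        columns = feature ids.
    provenance : list of str
        Ordered record of the transforms applied so far.
    """

    name: str
    data: pd.DataFrame
    provenance: list[str] = field(default_factory=list)

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def feature_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: pd.DataFrame, step: str) -> "DatasetBundle":
        """Return a new bundle with ``data`` and ``step`` appended to provenance."""
        return DatasetBundle(self.name, data, [*self.provenance, step])

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


def read_matrix(path: str | Path, name: str | None = None) -> DatasetBundle:
    """Read a tab-delimited matrix (feature ids x sample ids) into a bundle.

    The file must have a header row of sample ids and a first column of
    feature ids; the body is numeric (``NA`` allowed, flagged for
    :func:`~sparsekm.preprocess.drop_incomplete_features` downstream).

    Raises
    ------
    ValueError
        On ragged rows, duplicate sample/feature ids, or non-numeric cells;
        the message names the offending id or line.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise ValueError(f"duplicate feature id {dup!r} in {path}")
    if raw.columns.has_duplicates:
        dup = raw.columns[raw.columns.duplicated()][0]
        raise ValueError(f"duplicate sample id {dup!r} in {path}")
    if raw.isna().to_numpy().all(axis=None) and raw.size:
        raise ValueError(f"{path}: no numeric body parsed")
    try:
        body = raw.apply(pd.to_numeric, errors="raise")
    except (ValueError, TypeError):
        numeric = raw.apply(pd.to_numeric, errors="coerce")
        bad = numeric.isna() & raw.notna() & (raw != "NA")
        rows = np.nonzero(bad.to_numpy())[0]
        line = rows[0] + 2 if rows.size else "?"  # +1 header, +1 one-based
        raise ValueError(f"{path}: non-numeric cell at line {line}") from None
    # transpose: disk is features x samples, memory is samples x features
    data = body.T
    data.index.name = "sample_id"
    return DatasetBundle(name or path.stem, data, [f"read:{path.name}"])


def write_matrix(bundle: DatasetBundle, path: str | Path) -> Path:
    """Write a bundle as a tab-delimited feature ids x sample ids matrix."""
    path = Path(path)
    out = bundle.data.T
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", na_rep="NA")
    return path


def check_aligned(bundles: list[DatasetBundle]) -> None:
    """Require identical, identically ordered sample ids across bundles."""
    if not bundles:
        raise ValueError("no datasets supplied")
    ref = bundles[0].sample_ids
    for b in bundles[1:]:
        if len(b.sample_ids) != len(ref) or not (b.sample_ids == ref).all():
            raise ValueError(
                f"sample ids of dataset {b.name!r} do not match {bundles[0].name!r}; "
                "joint analyses require identical sample ordering"
            )
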
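"""Gene x array signal container shared by the simulator and the preprocessing stages.

A :class:`SignalMatrix` holds nonnegative hybridization signals for a set of
genes across a set of arrays, with ``NaN`` marking missing spots, plus the
assignment of each array to a biological experiment (arrays within one
experiment are replicates).  On disk it is a TSV with a ``gene_id`` column
followed by one column per array, missing values written as ``NA``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING_MARKER = "NA"

# array ids like "exp3_rep2" carry their experiment in the name
_ARRAY_ID_RE = re.compile(r"^(?P<exp>.+)_rep(?P<rep>\d+)$")


def experiment_from_array_id(array_id: str) -> str:
    """Infer the experiment label from an ``<experiment>_rep<k>`` array id."""
    m = _ARRAY_ID_RE.match(array_id)
    if m is None:
        raise ValueError(
            f"array id {array_id!r} does not follow the '<experiment>_rep<k>' "
            "convention; pass experiment_of_array explicitly"
        )
    return m.group("exp")


@dataclass
class SignalMatrix:
    """Nonnegative genes x arrays signals with replicate grouping.

    Parameters
    ----------
    values
        DataFrame indexed by unique ``gene_id`` with one float column per
        array; ``NaN`` marks a missing measurement.
    experiment_of_array
        Mapping array id -> experiment label.  If omitted it is inferred from
        the ``<experiment>_rep<k>`` naming convention.
    """

    values: pd.DataFrame
    experiment_of_array: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate array ids")
        self.values = self.values.astype(float)
        arr = self.values.to_numpy()
        if np.any(arr[np.isfinite(arr)] < 0):
            raise ValueError("signal values must be nonnegative (NaN marks missing)")
        if not self.experiment_of_array:
            self.experiment_of_array = {
                a: experiment_from_array_id(a) for a in self.values.columns
            }
        else:
            unknown = set(self.values.columns) - set(self.experiment_of_array)
            if unknown:
                raise ValueError(f"arrays without experiment assignment: {sorted(unknown)}")

    # -- basic views ---------------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def array_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_arrays(self) -> int:
        return self.values.shape[1]

    @property
    def experiment_ids(self) -> list[str]:
        """Experiment labels in first-appearance order of their arrays."""
        seen: dict[str, None] = {}
        for a in self.values.columns:
            seen.setdefault(self.experiment_of_array[a], None)
        return list(seen)

    def arrays_of_experiment(self, experiment: str) -> list[str]:
        return [a for a in self.values.columns if self.experiment_of_array[a] == experiment]

    def copy(self) -> "SignalMatrix":
        return SignalMatrix(self.values.copy(), dict(self.experiment_of_array))

    def subset_genes(self, gene_ids) -> "SignalMatrix":
        return SignalMatrix(self.values.loc[list(gene_ids)], dict(self.experiment_of_array))

    # -- disk ----------------------------------------------------------------

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "gene_id", out.index)
        out.to_csv(path, sep="\t", index=False, na_rep=MISSING_MARKER)

    @classmethod
    def from_tsv(cls, path, experiment_of_array: dict[str, str] | None = None) -> "SignalMatrix":
        df = pd.read_csv(path, sep="\t", na_values=[MISSING_MARKER], keep_default_na=False)
        if "gene_id" not in df.columns:
            raise ValueError(f"{path}: missing gene_id column")
        df = df.set_index("gene_id")
        return cls(df, experiment_of_array or {})
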
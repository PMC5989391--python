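"""Core in-memory containers: typed sample vectors, omics matrices, annotations.

The package works on two matched matrices over the same cohort: a gene
expression matrix (normalized continuous values) and a CpG methylation
matrix (beta values in [0, 1]).  Both are held samples x variables, each
variable tagged with its kind so downstream steps can tell probes from
genes without parsing identifiers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

Kind = Literal["expression", "methylation"]

EXPRESSION: Kind = "expression"
METHYLATION: Kind = "methylation"


@dataclass
class VariableVector:
    """One variable (gene or probe) observed across samples.

    Parameters
    ----------
    id : str
        Stable identifier (gene symbol or probe id).
    values : ndarray
        One real value per sample; no missing entries.
    kind : {"expression", "methylation"}
        Methylation values must lie in [0, 1] (beta values).
    """

    id: str
    values: np.ndarray
    kind: Kind = EXPRESSION

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValidationError(f"variable {self.id!r}: values must be 1-D")
        if self.values.size < 3:
            raise ValidationError(
                f"variable {self.id!r}: need at least 3 samples, got {self.values.size}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(f"variable {self.id!r}: missing/non-finite values")
        if self.kind == METHYLATION and (
            self.values.min() < 0.0 or self.values.max() > 1.0
        ):
            raise ValidationError(
                f"variable {self.id!r}: methylation beta values must lie in [0, 1]"
            )

    def __len__(self) -> int:
        return self.values.size


@dataclass
class OmicsMatrix:
    """Samples x variables table with a per-variable kind tag.

    ``data`` is indexed by sample id (rows) and variable id (columns);
    ``kinds`` maps every column to "expression" or "methylation".
    """

    data: pd.DataFrame
    kinds: pd.Series

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate variable ids: {dup}")
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dup}")
        self.kinds = pd.Series(self.kinds).reindex(self.data.columns)
        if self.kinds.isna().any():
            missing = self.kinds.index[self.kinds.isna()].tolist()
            raise ValidationError(f"variables without a kind tag: {missing}")
        bad = ~self.kinds.isin([EXPRESSION, METHYLATION])
        if bad.any():
            raise ValidationError(
                f"unknown kind for variables: {self.kinds.index[bad].tolist()}"
            )

    # -- constructors -------------------------------------------------
    @classmethod
    def from_frame(cls, frame: pd.DataFrame, kind: Kind) -> "OmicsMatrix":
        """Wrap a samples x variables frame where every column shares one kind."""
        kinds = pd.Series(kind, index=frame.columns)
        return cls(frame.astype(float), kinds)

    # -- basic accessors ----------------------------------------------
    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    def kind_of(self, var_id: str) -> Kind:
        return self.kinds[var_id]

    def variables_of_kind(self, kind: Kind) -> list[str]:
        return list(self.kinds.index[self.kinds == kind])

    def vector(self, var_id: str) -> VariableVector:
        if var_id not in self.data.columns:
            raise KeyError(f"variable {var_id!r} not in matrix")
        return VariableVector(
            id=var_id, values=self.data[var_id].to_numpy(), kind=self.kinds[var_id]
        )

    def vectors(self, ids: Iterable[str] | None = None) -> list[VariableVector]:
        ids = self.variables if ids is None else list(ids)
        return [self.vector(v) for v in ids]

    def subset(self, ids: Iterable[str]) -> "OmicsMatrix":
        ids = list(ids)
        return OmicsMatrix(self.data[ids].copy(), self.kinds[ids].copy())

    def merge(self, other: "OmicsMatrix") -> "OmicsMatrix":
        """Column-concatenate two matrices over their shared samples.

        The sample intersection is taken (and logged when samples drop);
        duplicate variable ids raise.
        """
        shared = self.data.index.intersection(other.data.index)
        n_lost = max(self.n_samples, other.n_samples) - len(shared)
        if n_lost:
            logger.warning(
                "merge: %d samples not shared between matrices were dropped", n_lost
            )
        if len(shared) == 0:
            raise ValidationError("merge: matrices share no samples")
        overlap = self.data.columns.intersection(other.data.columns)
        if len(overlap):
            raise ValidationError(f"merge: duplicate variable ids: {list(overlap)}")
        data = pd.concat(
            [self.data.loc[shared], other.data.loc[shared]], axis=1
        )
        kinds = pd.concat([self.kinds, other.kinds])
        return OmicsMatrix(data, kinds)

    def drop_incomplete(self) -> "OmicsMatrix":
        """Drop variables with any missing value, with a logged warning."""
        bad = self.data.columns[self.data.isna().any(axis=0)]
        if len(bad):
            logger.warning("dropping %d variables with missing values: %s",
                           len(bad), list(bad[:10]))
            keep = [c for c in self.data.columns if c not in set(bad)]
            return self.subset(keep)
        return self


@dataclass(frozen=True)
class GenomicAnnotation:
    """Genomic anchor of a variable: probe coordinate or gene TSS.

    Positions are 1-based internally.  For genes the position is the TSS
    (interval start on '+', interval end on '-'); for probes it is the
    CpG coordinate (interval midpoint).
    """

    id: str
    chrom: str
    position: int
    kind: Literal["gene", "probe"]
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(
                f"annotation {self.id!r}: position must be >= 1 (1-based)"
            )
        if self.kind == "gene" and self.strand not in {"+", "-"}:
            raise ValidationError(
                f"annotation {self.id!r}: gene strand must be '+' or '-'"
            )


AnnotationMap = Mapping[str, GenomicAnnotation]
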
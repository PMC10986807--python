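"""Protein intensity matrix container and its TSV dialect.

A :class:`ProteinMatrix` holds a samples x proteins table of log2-scale
intensities (NaN marks a missing cell) together with per-sample metadata:
the patient the sample came from, its role (case/control), timepoint
(baseline/month3) and cohort (discovery/validation).

The on-disk dialect is a single TSV with the metadata columns first and
one column per protein; missing cells are written empty.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

META_COLUMNS = ["patient_id", "role", "timepoint", "cohort"]
ROLES = {"case", "control"}
TIMEPOINTS = {"baseline", "month3"}
COHORTS = {"discovery", "validation"}

PROVENANCE_CODES = {"observed", "missing", "imputed_halfmin", "imputed_knn"}


@dataclass
class ProteinMatrix:
    """Samples x proteins intensity table with missingness and sample roles.

    Parameters
    ----------
    values
        Float DataFrame indexed by sample id, one column per protein id.
        NaN encodes a missing cell.
    sample_meta
        DataFrame indexed identically to ``values`` with columns
        ``patient_id``, ``role``, ``timepoint``, ``cohort``.
    log2
        Whether values are on the log2 scale. Guards against double
        transformation.
    shadow
        Optional copy of the pre-masking truth (same shape as ``values``),
        kept by the simulator so imputation error can be measured.
    provenance
        Optional DataFrame of per-cell codes (``observed`` /
        ``imputed_halfmin`` / ``imputed_knn``) filled in by imputation.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    log2: bool = True
    shadow: pd.DataFrame | None = None
    provenance: pd.DataFrame | None = None
    sample_shifts: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("sample ids must be unique")
        if not self.values.columns.is_unique:
            raise ValueError("protein ids must be unique")
        if not self.values.index.equals(self.sample_meta.index):
            raise ValueError("values and sample_meta must share the same sample index")
        missing_meta = [c for c in META_COLUMNS if c not in self.sample_meta.columns]
        if missing_meta:
            raise ValueError(f"sample_meta lacks columns: {missing_meta}")
        bad_roles = set(self.sample_meta["role"]) - ROLES
        if bad_roles:
            raise ValueError(f"unknown sample roles: {sorted(bad_roles)}")
        self.values = self.values.astype(float)

    # -- basic views ---------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_proteins(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def copy(self) -> "ProteinMatrix":
        return ProteinMatrix(
            values=self.values.copy(),
            sample_meta=self.sample_meta.copy(),
            log2=self.log2,
            shadow=None if self.shadow is None else self.shadow.copy(),
            provenance=None if self.provenance is None else self.provenance.copy(),
            sample_shifts=dict(self.sample_shifts),
        )

    def subset(
        self,
        role: str | None = None,
        timepoint: str | None = None,
        cohort: str | None = None,
    ) -> "ProteinMatrix":
        """Row-subset by sample role / timepoint / cohort."""
        keep = pd.Series(True, index=self.values.index)
        if role is not None:
            keep &= self.sample_meta["role"] == role
        if timepoint is not None:
            keep &= self.sample_meta["timepoint"] == timepoint
        if cohort is not None:
            keep &= self.sample_meta["cohort"] == cohort
        return ProteinMatrix(
            values=self.values.loc[keep].copy(),
            sample_meta=self.sample_meta.loc[keep].copy(),
            log2=self.log2,
            shadow=None if self.shadow is None else self.shadow.loc[keep].copy(),
            provenance=None
            if self.provenance is None
            else self.provenance.loc[keep].copy(),
        )

    # -- IO ------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        out = pd.concat([self.sample_meta[META_COLUMNS], self.values], axis=1)
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t", na_rep="", float_format="%.6g")
        if self.provenance is not None:
            prov = self.provenance.copy()
            prov.index.name = "sample_id"
            prov.to_csv(Path(path).with_suffix(".provenance.tsv"), sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, log2: bool = True) -> "ProteinMatrix":
        raw = pd.read_csv(path, sep="\t", index_col="sample_id", dtype={"patient_id": str})
        missing_meta = [c for c in META_COLUMNS if c not in raw.columns]
        if missing_meta:
            raise ValueError(f"matrix TSV lacks metadata columns: {missing_meta}")
        meta = raw[META_COLUMNS].copy()
        vals = raw.drop(columns=META_COLUMNS).astype(float)
        return cls(values=vals, sample_meta=meta, log2=log2)


def rows_for_patients(
    matrix: ProteinMatrix, timepoint: str, patient_ids: list[str]
) -> pd.DataFrame:
    """Case intensity rows at `timepoint`, reindexed to `patient_ids`.

    Raises if any requested patient lacks a sample at that timepoint.
    """
    sel = (matrix.sample_meta["role"] == "case") & (
        matrix.sample_meta["timepoint"] == timepoint
    )
    sub = matrix.values.loc[sel].copy()
    sub.index = matrix.sample_meta.loc[sel, "patient_id"]
    absent = [p for p in patient_ids if p not in sub.index]
    if absent:
        raise KeyError(f"patients without {timepoint} sample: {absent[:5]}")
    block = sub.loc[patient_ids]
    block.index = pd.Index(patient_ids, name="patient_id")
    return block


__all__ = ["ProteinMatrix", "META_COLUMNS", "rows_for_patients"]
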
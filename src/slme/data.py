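"""Long-format sector-level observations with nested patient > eye grouping.

One row per (patient, eye, sector) with the thickness response (micrometres)
plus patient-level and eye-level covariates.  Missing sectors are simply
absent rows; missing covariate values are tolerated at load time and flagged
when a design that uses them is built.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

KEY_COLUMNS = ("patient_id", "eye_id", "sector")


class SchemaError(ValueError):
    """Raised when a long-format table violates the dataset contract."""


@dataclass
class LongDataset:
    """Validated long-format dataset.

    ``df`` keeps one row per (patient_id, eye_id, sector); ``response`` names
    the thickness column.  Eyes are nested in patients: an eye_id may not
    appear under two patients, and a patient has at most two eyes.
    """

    df: pd.DataFrame
    response: str = "thickness"

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        df = self.df
        missing = [c for c in (*KEY_COLUMNS, self.response) if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required columns: {missing}")
        dup = df.duplicated(list(KEY_COLUMNS))
        if dup.any():
            key = df.loc[dup.idxmax(), list(KEY_COLUMNS)].tolist()
            raise SchemaError(
                f"duplicate (patient_id, eye_id, sector) key, first at {key}"
            )
        # eye identity is scoped within its patient: the eye key is the
        # composite (patient_id, eye_id), so laterality labels like OD/OS
        # may repeat across patients while nesting is preserved
        eyes = df[["patient_id", "eye_id"]].drop_duplicates()
        per_patient = eyes.groupby("patient_id").size()
        if (per_patient > 2).any():
            bad = per_patient[per_patient > 2].index[0]
            raise SchemaError(f"patient {bad!r} has more than two eyes")
        per_cell = df.groupby(["patient_id", "eye_id"], sort=False).size()
        if (per_cell > 9).any():
            bad = per_cell[per_cell > 9].index[0]
            raise SchemaError(f"eye {bad!r} has more than nine sectors")
        if df[self.response].isna().any():
            raise SchemaError(
                "missing responses must be absent rows, not NaN values"
            )

    # -- convenience ------------------------------------------------------
    @property
    def n_patients(self) -> int:
        return self.df["patient_id"].nunique()

    @property
    def n_eyes(self) -> int:
        return len(self.df[["patient_id", "eye_id"]].drop_duplicates())

    @property
    def n_obs(self) -> int:
        return len(self.df)

    def check_sectors(self, grid) -> None:
        unknown = set(self.df["sector"]) - set(grid.sector_ids)
        if unknown:
            raise SchemaError(f"sectors not in grid: {sorted(unknown)}")

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_csv(cls, path, response: str = "thickness") -> "LongDataset":
        return cls(pd.read_csv(path), response=response)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)
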
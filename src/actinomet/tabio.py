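"""Readers/writers and in-memory containers for the three pipeline tables.

Three CSV dialects are touched by the workflow:

* **Feature tables** — MZmine-style aligned peak lists, one per ionization
  mode: ``feature_id, mz, rt`` followed by one intensity column per sample.
  Sample roles (isolate group label, ``blank``, ``medium``, ``qc``) live in a
  dedicated ``role`` row directly under the header, so a single file carries
  both intensities and the experiment design.
* **Compound libraries** — named natural products with molecular formulas;
  the monoisotopic neutral mass is computed on load, never stored.
* **Bioactivity tables** — per-isolate inhibition zones (mm) and IC50 values
  (µg/mL), with ``NA`` meaning "no activity observed", never zero.

All writers are exact inverses of the readers (write∘read = identity).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataError, FormatError
from .formulas import monoisotopic_mass, parse_formula

logger = logging.getLogger(__name__)

__all__ = [
    "MZ_MIN",
    "MZ_MAX",
    "ROLE_BLANK",
    "ROLE_MEDIUM",
    "ROLE_QC",
    "FeatureTable",
    "CompoundRecord",
    "CompoundLibrary",
    "BioactivityTable",
    "read_feature_table",
    "write_feature_table",
    "read_compound_library",
    "write_compound_library",
    "read_bioactivity",
    "write_bioactivity",
]

MZ_MIN, MZ_MAX = 100.0, 1500.0  # full-scan acquisition window, Da

ROLE_BLANK = "blank"
ROLE_MEDIUM = "medium"
ROLE_QC = "qc"
_SPECIAL_ROLES = (ROLE_BLANK, ROLE_MEDIUM, ROLE_QC)


@dataclass
class FeatureTable:
    """A features × samples intensity matrix with per-feature m/z and RT.

    Parameters
    ----------
    intensities:
        Non-negative matrix indexed by feature id, one column per sample.
        Zero encodes "feature absent in this sample" (MZmine convention).
    mz, rt:
        Per-feature m/z (Da, within the acquisition window) and retention
        time (minutes), indexed like ``intensities``.
    sample_roles:
        Maps every sample name to exactly one role: an isolate group label,
        or one of ``blank`` / ``medium`` / ``qc``.
    mode:
        ``"positive"``, ``"negative"`` or ``"merged"``.
    """

    intensities: pd.DataFrame
    mz: pd.Series
    rt: pd.Series
    sample_roles: dict[str, str]
    mode: str = "merged"

    def __post_init__(self) -> None:
        if self.mode not in ("positive", "negative", "merged"):
            raise FormatError(f"unknown ionization mode {self.mode!r}")
        ids = self.intensities.index
        if ids.duplicated().any():
            dupes = ids[ids.duplicated()].unique().tolist()
            raise FormatError(f"duplicate feature ids: {dupes}")
        for name, series in (("mz", self.mz), ("rt", self.rt)):
            if not series.index.equals(ids):
                raise FormatError(f"{name} index does not match intensity rows")
        if len(ids) and ((self.mz < MZ_MIN) | (self.mz > MZ_MAX)).any():
            bad = self.mz[(self.mz < MZ_MIN) | (self.mz > MZ_MAX)]
            raise FormatError(
                f"m/z outside [{MZ_MIN}, {MZ_MAX}]: {bad.head().to_dict()}"
            )
        vals = self.intensities.to_numpy()
        if vals.size and (np.isnan(vals).any() or (vals < 0).any()):
            raise FormatError("intensities must be non-negative and finite")
        cols = set(self.intensities.columns)
        if cols != set(self.sample_roles):
            raise FormatError(
                "sample_roles must cover exactly the intensity columns; "
                f"difference: {cols ^ set(self.sample_roles)}"
            )

    # -- structure helpers -------------------------------------------------

    @property
    def feature_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def samples(self) -> list[str]:
        return list(self.intensities.columns)

    def _samples_with_role(self, role: str) -> list[str]:
        return [s for s in self.samples if self.sample_roles[s] == role]

    @property
    def blank_samples(self) -> list[str]:
        return self._samples_with_role(ROLE_BLANK)

    @property
    def medium_samples(self) -> list[str]:
        return self._samples_with_role(ROLE_MEDIUM)

    @property
    def qc_samples(self) -> list[str]:
        return self._samples_with_role(ROLE_QC)

    @property
    def biological_samples(self) -> list[str]:
        return [
            s for s in self.samples if self.sample_roles[s] not in _SPECIAL_ROLES
        ]

    @property
    def groups(self) -> list[str]:
        """Isolate group labels in first-appearance order."""
        seen: list[str] = []
        for s in self.biological_samples:
            g = self.sample_roles[s]
            if g not in seen:
                seen.append(g)
        return seen

    @property
    def n_features(self) -> int:
        return len(self.intensities)

    def subset(self, feature_ids) -> "FeatureTable":
        """Row-subset preserving order of ``feature_ids``."""
        idx = pd.Index(feature_ids)
        missing = idx.difference(self.intensities.index)
        if len(missing):
            raise FormatError(f"unknown feature ids: {list(missing[:5])}")
        return FeatureTable(
            intensities=self.intensities.loc[idx].copy(),
            mz=self.mz.loc[idx].copy(),
            rt=self.rt.loc[idx].copy(),
            sample_roles=dict(self.sample_roles),
            mode=self.mode,
        )

    def to_matrix(self, samples=None) -> pd.DataFrame:
        """Samples × features matrix (the orientation chemometrics expects)."""
        if samples is None:
            samples = self.biological_samples + self.qc_samples
        return self.intensities[list(samples)].T

    def group_means(self) -> pd.DataFrame:
        """Groups × features matrix of replicate-mean intensities."""
        bio = self.biological_samples
        labels = [self.sample_roles[s] for s in bio]
        return self.intensities[bio].T.groupby(pd.Index(labels, name="group")).mean()


@dataclass
class CompoundRecord:
    """A library entry; ``neutral_mass`` is always computed from the formula."""

    name: str
    formula: str
    neutral_mass: float = field(default=0.0)
    source: str = ""
    activity_note: str = ""

    def __post_init__(self) -> None:
        if self.neutral_mass <= 0.0:
            self.neutral_mass = monoisotopic_mass(parse_formula(self.formula))


@dataclass
class CompoundLibrary:
    records: list[CompoundRecord]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i) -> CompoundRecord:
        return self.records[i]

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [r.name for r in self.records],
                "formula": [r.formula for r in self.records],
                "neutral_mass": [r.neutral_mass for r in self.records],
                "source": [r.source for r in self.records],
                "activity_note": [r.activity_note for r in self.records],
            }
        )


@dataclass
class BioactivityTable:
    """Per-isolate inhibition zones (mm) and IC50 values (µg/mL).

    Both frames are indexed by isolate group label; missing readouts are NaN
    (printed as ``NA``), meaning "no inhibition observed", never zero.
    """

    zones: pd.DataFrame
    ic50: pd.DataFrame

    def __post_init__(self) -> None:
        if self.ic50 is None:
            self.ic50 = pd.DataFrame(index=self.zones.index)
        if self.zones is None:
            self.zones = pd.DataFrame(index=self.ic50.index)
        if not self.zones.index.equals(self.ic50.index):
            raise FormatError("zones and ic50 must share the same group index")
        if (self.zones.to_numpy(dtype=float) < 0).any():
            raise DataError("inhibition zones must be >= 0 where present")
        if (self.ic50.to_numpy(dtype=float) <= 0).any():
            raise DataError("IC50 values must be > 0 where present")

    @property
    def groups(self) -> list[str]:
        return list(self.zones.index)

    def activity_columns(self) -> pd.DataFrame:
        """All activity readouts side by side, ``zone:``/``ic50:`` prefixed."""
        z = self.zones.add_prefix("zone:")
        c = self.ic50.add_prefix("ic50:")
        return pd.concat([z, c], axis=1)


# ---------------------------------------------------------------------------
# feature-table CSV dialect
# ---------------------------------------------------------------------------

_META_COLS = ("feature_id", "mz", "rt")


def read_feature_table(path, mode: str) -> FeatureTable:
    """Read an aligned feature table CSV for one ionization mode.

    The file must start with the header ``feature_id,mz,rt,<samples...>``
    followed by a ``role`` row that labels each sample column.
    """
    try:
        raw = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    for col in _META_COLS:
        if col not in raw.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    sample_cols = [c for c in raw.columns if c not in _META_COLS]
    if not sample_cols:
        raise FormatError(f"{path}: no sample columns")
    if raw.empty or str(raw.iloc[0]["feature_id"]) != "role":
        raise FormatError(f"{path}: missing 'role' row under the header")
    roles = {c: str(raw.iloc[0][c]) for c in sample_cols}
    body = raw.iloc[1:]
    ids = body["feature_id"].astype(str)

    def _numeric(frame_or_series, what):
        try:
            out = frame_or_series.apply(pd.to_numeric) if isinstance(
                frame_or_series, pd.DataFrame
            ) else pd.to_numeric(frame_or_series)
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}: non-numeric value in {what}: {exc}") from exc
        return out

    mz = _numeric(body["mz"], "mz")
    rt = _numeric(body["rt"], "rt")
    inten = _numeric(body[sample_cols], "intensities").fillna(0.0).astype(float)
    inten.index = ids
    mz.index = ids
    rt.index = ids
    return FeatureTable(
        intensities=inten, mz=mz.astype(float), rt=rt.astype(float),
        sample_roles=roles, mode=mode,
    )


def write_feature_table(table: FeatureTable, path) -> None:
    """Write a feature table in the dialect that ``read_feature_table`` reads."""
    role_row = pd.DataFrame(
        [["role", "", ""] + [table.sample_roles[s] for s in table.samples]],
        columns=list(_META_COLS) + table.samples,
    )
    body = table.intensities.reset_index()
    body.columns = ["feature_id"] + table.samples
    body.insert(1, "mz", table.mz.to_numpy())
    body.insert(2, "rt", table.rt.to_numpy())
    out = pd.concat([role_row, body], ignore_index=True)
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# compound library CSV
# ---------------------------------------------------------------------------


def read_compound_library(path) -> CompoundLibrary:
    """Read a compound library; neutral masses are computed from formulas.

    Unparseable formulas raise :class:`FormatError` naming the offending line;
    an empty file yields an empty library with a logged warning.
    """
    try:
        raw = pd.read_csv(path, dtype=str).fillna("")
    except pd.errors.EmptyDataError:
        raw = pd.DataFrame(columns=["name", "formula"])
    for col in ("name", "formula"):
        if col not in raw.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    records = []
    for i, row in enumerate(raw.itertuples(index=False), start=2):
        try:
            records.append(
                CompoundRecord(
                    name=row.name,
                    formula=row.formula,
                    source=getattr(row, "source", ""),
                    activity_note=getattr(row, "activity_note", ""),
                )
            )
        except FormatError as exc:
            raise FormatError(f"{path}, line {i}: {exc}") from exc
    if not records:
        warnings.warn(f"{path}: empty compound library", stacklevel=2)
        logger.warning("%s: empty compound library", path)
    return CompoundLibrary(records)


def write_compound_library(lib: CompoundLibrary, path) -> None:
    frame = lib.to_frame().drop(columns=["neutral_mass"])
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# bioactivity CSV
# ---------------------------------------------------------------------------


def read_bioactivity(path) -> BioactivityTable:
    """Read a bioactivity table: ``group`` column plus ``zone:``/``ic50:`` columns."""
    raw = pd.read_csv(path, dtype=str)
    if "group" not in raw.columns:
        raise FormatError(f"{path}: missing 'group' column")
    raw = raw.set_index(raw["group"].astype(str)).drop(columns=["group"])
    zones, ic50 = {}, {}
    for col in raw.columns:
        try:
            values = pd.to_numeric(raw[col].replace({"NA": None, "": None}))
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}: non-numeric value in {col!r}") from exc
        if col.startswith("zone:"):
            zones[col[len("zone:"):]] = values
        elif col.startswith("ic50:"):
            ic50[col[len("ic50:"):]] = values
        else:
            raise FormatError(
                f"{path}: column {col!r} must be 'zone:<organism>' or 'ic50:<cell line>'"
            )
    idx = raw.index.rename("group")
    return BioactivityTable(
        zones=pd.DataFrame(zones, index=idx, dtype=float),
        ic50=pd.DataFrame(ic50, index=idx, dtype=float),
    )


def write_bioactivity(bt: BioactivityTable, path) -> None:
    out = bt.activity_columns()
    out.index.name = "group"
    out.to_csv(path, na_rep="NA")
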
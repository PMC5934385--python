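"""Core in-memory containers shared by every pipeline stage.

Two tables carry almost all state:

* :class:`GenotypeMatrix` — a samples x variants dosage table (minor-allele
  counts in {0, 1, 2}, ``NaN`` for a missing call) plus per-variant metadata.
* :class:`HRSDPanel` — longitudinal 21-item Hamilton Rating Scale for
  Depression (HRSD) assessments at baseline and weeks 2, 4 and 8. A timepoint
  is either fully observed (all 21 items) or fully missing; partially scored
  visits are rejected on construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Assessment timepoints, in temporal order.
TIMEPOINTS = ("bl", "w2", "w4", "w8")

#: Column names of the 21 HRSD items; item_01 is "depressed mood" (0-4).
ITEM_COLUMNS = tuple(f"item_{i:02d}" for i in range(1, 22))

#: Conservative ceiling for an HRSD total score (21 items).
HRSD_TOTAL_MAX = 66


@dataclass
class GenotypeMatrix:
    """Samples x variants minor-allele dosage table.

    Parameters
    ----------
    dosages
        ``float64`` DataFrame indexed by sample id with one column per
        variant id; entries are 0/1/2 or ``NaN`` (missing call).
    variants
        Per-variant metadata indexed by variant id, aligned with the dosage
        columns. Required columns: ``chrom`` and ``pos`` (1-based). Optional
        columns used elsewhere: ``ref``, ``alt``, ``gene``, ``target_maf``.
    """

    dosages: pd.DataFrame
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.dosages.columns) != list(self.variants.index):
            raise ValueError("dosage columns and variant metadata are not aligned")
        for col in ("chrom", "pos"):
            if col not in self.variants.columns:
                raise ValueError(f"variant metadata lacks required column {col!r}")
        if self.variants.index.has_duplicates:
            dupes = self.variants.index[self.variants.index.duplicated()].tolist()
            raise ValueError(f"duplicated variant ids: {dupes[:5]}")
        vals = self.dosages.to_numpy()
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or NaN")

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def sample_ids(self) -> pd.Index:
        return self.dosages.index

    @property
    def variant_ids(self) -> pd.Index:
        return self.dosages.columns

    # -- summaries ------------------------------------------------------
    def allele_freq(self) -> pd.Series:
        """Frequency of the counted allele among non-missing calls."""
        return self.dosages.mean(axis=0, skipna=True) / 2.0

    def maf(self) -> pd.Series:
        """Minor allele frequency, folded to <= 0.5."""
        q = self.allele_freq()
        return np.minimum(q, 1.0 - q)

    def call_rate_samples(self) -> pd.Series:
        return self.dosages.notna().mean(axis=1)

    def call_rate_variants(self) -> pd.Series:
        return self.dosages.notna().mean(axis=0)

    def missing_rate_variants(self) -> pd.Series:
        return self.dosages.isna().mean(axis=0)

    # -- subsetting ------------------------------------------------------
    def subset(self, samples=None, variants=None) -> "GenotypeMatrix":
        d = self.dosages
        v = self.variants
        if samples is not None:
            d = d.loc[list(samples)]
        if variants is not None:
            d = d[list(variants)]
            v = v.loc[list(variants)]
        return GenotypeMatrix(d.copy(), v.copy())

    def sorted_by_position(self) -> "GenotypeMatrix":
        order = self.variants.sort_values(["chrom", "pos"]).index
        return self.subset(variants=order)


class HRSDPanel:
    """Per-subject 21-item HRSD scores at four timepoints.

    ``data`` is a long table with columns ``subject_id``, ``timepoint``
    (one of :data:`TIMEPOINTS`) and ``item_01`` .. ``item_21`` (float,
    ``NaN`` for missing). Every subject carries exactly one row per
    timepoint; a timepoint is missing iff all 21 items are ``NaN``, and
    baseline must be observed for every subject.
    """

    def __init__(self, data: pd.DataFrame):
        required = ["subject_id", "timepoint", *ITEM_COLUMNS]
        missing_cols = [c for c in required if c not in data.columns]
        if missing_cols:
            raise ValueError(f"HRSD panel lacks columns: {missing_cols}")
        bad_tp = set(data["timepoint"]) - set(TIMEPOINTS)
        if bad_tp:
            raise ValueError(f"unknown timepoints: {sorted(bad_tp)}")

        items = data[list(ITEM_COLUMNS)].to_numpy(dtype=float)
        n_nan = np.isnan(items).sum(axis=1)
        partial = (n_nan > 0) & (n_nan < len(ITEM_COLUMNS))
        if partial.any():
            row = data.loc[partial].iloc[0]
            raise ValueError(
                "a timepoint must be fully observed or fully missing; "
                f"subject {row['subject_id']} at {row['timepoint']} is partial"
            )
        observed = items[n_nan == 0]
        if observed.size:
            if (observed < 0).any() or (observed != np.round(observed)).any():
                raise ValueError("item scores must be non-negative integers")
            item1 = data.loc[n_nan == 0, "item_01"].to_numpy(dtype=float)
            if (item1 > 4).any():
                raise ValueError("item 1 (depressed mood) must lie in 0-4")

        counts = data.groupby("subject_id")["timepoint"].nunique()
        if (counts != len(TIMEPOINTS)).any() or len(data) != 4 * counts.size:
            raise ValueError("each subject needs exactly one row per timepoint")
        bl = data[data["timepoint"] == "bl"]
        if bl[list(ITEM_COLUMNS)].isna().any(axis=None):
            raise ValueError("baseline must be observed for every subject")

        self.data = (
            data.assign(
                timepoint=pd.Categorical(data["timepoint"], categories=TIMEPOINTS)
            )
            .sort_values(["subject_id", "timepoint"], kind="stable")
            .reset_index(drop=True)
        )

    # -- views ------------------------------------------------------------
    @property
    def subjects(self) -> pd.Index:
        return pd.Index(self.data["subject_id"].unique(), name="subject_id")

    def totals(self) -> pd.DataFrame:
        """Wide subjects x timepoints table of total scores (NaN = missing)."""
        tot = self.data[list(ITEM_COLUMNS)].sum(axis=1, skipna=False)
        wide = (
            self.data.assign(total=tot)
            .pivot(index="subject_id", columns="timepoint", values="total")
            .loc[self.subjects, list(TIMEPOINTS)]
        )
        wide.columns = list(TIMEPOINTS)
        return wide

    def item(self, number: int) -> pd.DataFrame:
        """Wide subjects x timepoints table of a single item's scores."""
        col = f"item_{number:02d}"
        wide = self.data.pivot(
            index="subject_id", columns="timepoint", values=col
        ).loc[self.subjects, list(TIMEPOINTS)]
        wide.columns = list(TIMEPOINTS)
        return wide

    def observed_mask(self) -> pd.DataFrame:
        """Wide boolean table: True where the timepoint is observed."""
        return self.totals().notna()

    def copy(self) -> "HRSDPanel":
        return HRSDPanel(self.data.copy())

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        return isinstance(other, HRSDPanel) and self.data.equals(other.data)
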
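"""Abundance tables, replicated time series, and TSV input/output.

The central container is :class:`AbundanceTable`: a samples x OTUs matrix
with per-sample metadata (treatment, generation, replicate) and a units flag
distinguishing raw counts from relative abundances.  Replicate-averaged
per-treatment trajectories live in :class:`SeriesSet`, the input to the
local-similarity machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

METADATA_COLUMNS = ("treatment", "generation", "replicate")


class ValidationError(ValueError):
    """Raised when an input table or configuration violates its contract."""


@dataclass
class AbundanceTable:
    """Samples x OTUs abundance matrix with sample metadata.

    Parameters
    ----------
    data:
        DataFrame with sample ids as index and OTU ids as columns; values are
        nonnegative counts or relative abundances.
    metadata:
        DataFrame indexed by sample id with columns ``treatment`` (label),
        ``generation`` (int >= 1) and ``replicate`` (int >= 1); must cover
        every sample in ``data``.
    units:
        ``"counts"`` or ``"relative"``.  Relative rows must sum to 1.
    """

    data: pd.DataFrame
    metadata: pd.DataFrame
    units: str = "counts"

    def __post_init__(self) -> None:
        if self.units not in ("counts", "relative"):
            raise ValidationError(f"units must be 'counts' or 'relative', got {self.units!r}")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate OTU ids: {dups}")
        missing = [c for c in METADATA_COLUMNS if c not in self.metadata.columns]
        if missing:
            raise ValidationError(f"metadata missing required columns: {missing}")
        absent = self.data.index.difference(self.metadata.index)
        if len(absent):
            raise ValidationError(f"metadata missing rows for samples: {sorted(absent)}")
        # keep metadata aligned to the sample order of the matrix
        self.metadata = self.metadata.loc[self.data.index]
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            bad = [
                (r, c)
                for r in self.data.index
                for c in self.data.columns
                if not isinstance(self.data.at[r, c], (int, float, np.number))
            ]
            raise ValidationError(f"non-numeric cells at (sample, OTU): {bad[:10]}")
        if np.any(values < 0):
            raise ValidationError("negative abundances are not allowed")
        if self.units == "relative":
            # full compositions sum to 1; OTU-subset tables (subcompositions)
            # may sum to less, but never more
            sums = values.sum(axis=1)
            off = sums > 1.0 + 1e-9
            if off.any():
                bad_ids = self.data.index[off].tolist()
                raise ValidationError(f"relative rows must sum to at most 1: {bad_ids[:10]}")

    # -- convenience -----------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_otus(self, otus: Iterable[str]) -> "AbundanceTable":
        otus = list(otus)
        unknown = set(otus) - set(self.data.columns)
        if unknown:
            raise ValidationError(f"unknown OTU ids: {sorted(unknown)}")
        return AbundanceTable(self.data[otus].copy(), self.metadata.copy(), self.units)

    def __eq__(self, other: object) -> bool:  # value semantics for round-trip tests
        if not isinstance(other, AbundanceTable):
            return NotImplemented
        return (
            self.units == other.units
            and self.data.equals(other.data)
            and self.metadata[list(METADATA_COLUMNS)].equals(other.metadata[list(METADATA_COLUMNS)])
        )


@dataclass
class SeriesSet:
    """Replicate-summarized per-OTU trajectories for one treatment.

    ``data`` is OTUs x generations (columns ascending); ``replicate_counts``
    records how many replicates were averaged at each generation.
    """

    treatment: str
    data: pd.DataFrame
    replicate_counts: pd.Series

    def __post_init__(self) -> None:
        gens = list(self.data.columns)
        if gens != sorted(gens):
            raise ValidationError("generations must be strictly increasing")
        if len(set(gens)) != len(gens):
            raise ValidationError("duplicate generations in series")
        if self.data.index.duplicated().any():
            raise ValidationError("duplicate OTU ids in series set")

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def generations(self) -> list[int]:
        return list(self.data.columns)

    def series(self, otu: str) -> np.ndarray:
        return self.data.loc[otu].to_numpy(dtype=float)

    def subset_otus(self, otus: Iterable[str]) -> "SeriesSet":
        return SeriesSet(self.treatment, self.data.loc[list(otus)].copy(), self.replicate_counts.copy())


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_abundance(
    table_path: str | Path,
    metadata_path: str | Path,
    units: str = "counts",
    otus_in_rows: bool = False,
) -> AbundanceTable:
    """Read an abundance TSV plus metadata TSV into a validated table.

    The table is samples-in-rows by default; pass ``otus_in_rows=True`` to
    transpose on load.  Non-numeric cells and samples absent from the
    metadata are hard errors naming the offenders.
    """
    raw = pd.read_csv(table_path, sep="\t", index_col=0)
    if otus_in_rows:
        raw = raw.T
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().to_numpy().any() and not raw.isna().to_numpy().any():
        bad = [(r, c) for r in raw.index for c in raw.columns if pd.isna(numeric.at[r, c])]
        raise ValidationError(f"non-numeric cells at (sample, OTU): {bad[:10]}")
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
    return AbundanceTable(numeric, meta, units=units)


def write_abundance(table: AbundanceTable, table_path: str | Path, metadata_path: str | Path) -> None:
    table.data.to_csv(table_path, sep="\t", index_label="sample_id")
    table.metadata[list(METADATA_COLUMNS)].to_csv(metadata_path, sep="\t", index_label="sample_id")


def read_taxonomy(path: str | Path) -> dict[str, str]:
    """Read an OTU -> family TSV (columns: otu_id, family)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    col = "family" if "family" in df.columns else df.columns[0]
    return df[col].astype(str).to_dict()


def write_taxonomy(taxonomy: Mapping[str, str], path: str | Path) -> None:
    pd.Series(dict(taxonomy), name="family").rename_axis("otu_id").to_csv(path, sep="\t")


def taxon_for(taxonomy: Mapping[str, str] | None, otu: str) -> str:
    """Look up an OTU's family; absent OTUs are 'unclassified', never an error."""
    if taxonomy is None:
        return "unclassified"
    return taxonomy.get(otu, "unclassified")


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Convert counts to per-sample relative abundances (rows sum to 1)."""
    if table.units != "counts":
        raise ValidationError("to_relative expects a counts table")
    sums = table.data.sum(axis=1)
    zero = sums.index[sums <= 0].tolist()
    if zero:
        raise ValidationError(f"zero-sum samples cannot be normalized: {zero}")
    rel = table.data.div(sums, axis=0)
    return AbundanceTable(rel, table.metadata.copy(), units="relative")


def filter_prevalent_otus(table: AbundanceTable, threshold: float = 0.01) -> AbundanceTable:
    """Keep OTUs whose maximum relative abundance across all samples is >= threshold.

    This is the node filter for network construction: applied jointly across
    every sample of every treatment so the three networks share one node set.
    """
    if not 0 < threshold < 1:
        raise ValidationError(f"threshold must be in (0, 1), got {threshold}")
    if table.units != "relative":
        raise ValidationError("filter_prevalent_otus expects relative abundances")
    keep = table.data.columns[(table.data.max(axis=0) >= threshold)]
    return AbundanceTable(table.data[list(keep)].copy(), table.metadata.copy(), "relative")


def build_series(table: AbundanceTable, treatment: str, summarizer: str = "mean") -> SeriesSet:
    """Summarize one treatment's replicates into per-OTU trajectories.

    At each generation the summary value of an OTU is the simple average of
    that treatment's replicates; this is the replicate reduction of extended
    LSA.  The generation panel must be balanced across treatments.
    """
    if summarizer != "mean":
        raise ValidationError(f"unsupported summarizer {summarizer!r}; only 'mean'")
    if table.units != "relative":
        raise ValidationError("build_series expects relative abundances")
    treatments = set(table.metadata["treatment"])
    if treatment not in treatments:
        raise ValidationError(f"unknown treatment {treatment!r}; available: {sorted(treatments)}")
    all_gens = set(table.metadata["generation"])
    mask = table.metadata["treatment"] == treatment
    sub = table.data.loc[mask.to_numpy()]
    gens_here = set(table.metadata.loc[mask.to_numpy(), "generation"])
    missing = sorted(all_gens - gens_here)
    if missing:
        raise ValidationError(
            f"treatment {treatment!r} has no replicates at generations {missing} (unbalanced panel)"
        )
    if len(gens_here) < 2:
        raise ValidationError("need at least 2 generations to build a series")
    gen_col = table.metadata.loc[mask.to_numpy(), "generation"]
    means = sub.groupby(gen_col.to_numpy()).mean().sort_index()
    counts = gen_col.value_counts().sort_index()
    return SeriesSet(treatment=treatment, data=means.T, replicate_counts=counts)
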
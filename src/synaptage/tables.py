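"""Protein abundance tables: ingest, normalization and marker-enrichment QC.

The central container is :class:`AbundanceTable`, a proteins x samples matrix
with per-sample metadata (brain region, ordered age group, technical replicate)
and a per-protein unique-peptide count. Label-free intensities are
variance-stabilized with the inverse hyperbolic sine (Arc-Sinh) transform
``arcsinh(x) = ln(x + sqrt(x^2 + 1))``, which is defined at zero and behaves
like ``ln(2x)`` for large intensities, so differences on the normalized scale
read as log fold changes.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

AGE_ORDER: tuple[str, ...] = ("young", "mid", "old")

#: default pattern turning a sample column name into (region, age, replicate)
DEFAULT_SAMPLE_PATTERN = r"(?P<region>[^_]+)_(?P<age>[^_]+)_(?P<replicate>.+)"


class TableStateError(RuntimeError):
    """Raised when an operation is applied to a table in the wrong state."""


@dataclass
class AbundanceTable:
    """Proteins x samples abundance matrix with sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by protein id, one column per sample.
    samples
        DataFrame indexed by sample id with columns ``region``, ``age``
        (one of :data:`AGE_ORDER`) and ``replicate``.
    unique_peptides
        Series of unique-peptide counts per protein (>= 0).
    normalized
        Whether values are on the Arc-Sinh scale.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    unique_peptides: pd.Series
    normalized: bool = False
    age_order: tuple[str, ...] = AGE_ORDER

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate protein id: {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        missing = set(self.values.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        self.samples = self.samples.loc[list(self.values.columns)]
        unknown = set(self.samples["age"]) - set(self.age_order)
        if unknown:
            raise ValueError(
                f"unknown age levels {sorted(unknown)}; expected {self.age_order}"
            )
        for region, sub in self.samples.groupby("region", sort=False):
            found = set(sub["age"])
            absent = [a for a in self.age_order if a not in found]
            if absent:
                raise ValueError(
                    f"region {region!r} is missing age group(s) {absent}; "
                    f"found {sorted(found)}"
                )
        if not self.normalized and (self.values.to_numpy() < 0).any():
            raise ValueError("negative abundances in an unnormalized table")
        if self.values.isna().any().any():
            raise ValueError("missing abundance cells are not supported")
        self.unique_peptides = self.unique_peptides.reindex(self.values.index)
        if self.unique_peptides.isna().any():
            missing_ids = self.unique_peptides.index[self.unique_peptides.isna()]
            raise ValueError(f"unique_peptides missing for {list(missing_ids[:3])}")

    # -- convenience accessors -------------------------------------------------

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def regions(self) -> list[str]:
        seen: list[str] = []
        for r in self.samples["region"]:
            if r not in seen:
                seen.append(r)
        return seen

    def sample_ids(self, region: str | None = None, age: str | None = None) -> list[str]:
        mask = pd.Series(True, index=self.samples.index)
        if region is not None:
            mask &= self.samples["region"] == region
        if age is not None:
            mask &= self.samples["age"] == age
        return list(self.samples.index[mask])

    def replicate_values(self, region: str, age: str) -> pd.DataFrame:
        """Replicate columns for one (region, age) cell, proteins x replicates."""
        cols = self.sample_ids(region, age)
        if not cols:
            raise KeyError(f"no samples for region={region!r}, age={age!r}")
        return self.values[cols]

    def group_means(self, region: str) -> pd.DataFrame:
        """Per-age mean over replicates, proteins x ages (young, mid, old)."""
        return pd.DataFrame(
            {age: self.replicate_values(region, age).mean(axis=1) for age in self.age_order}
        )

    def subset(self, proteins) -> "AbundanceTable":
        proteins = list(proteins)
        missing = [p for p in proteins if p not in self.values.index]
        if missing:
            raise KeyError(f"proteins not in table: {missing[:5]}")
        return replace(
            self,
            values=self.values.loc[proteins].copy(),
            unique_peptides=self.unique_peptides.loc[proteins].copy(),
            samples=self.samples.copy(),
        )

    # -- I/O -------------------------------------------------------------------

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "unique_peptides", self.unique_peptides)
        out.index.name = "protein_id"
        out.to_csv(path, sep="\t")


def parse_sample_name(name: str, pattern: str = DEFAULT_SAMPLE_PATTERN):
    """Split a sample column name into (region, age, replicate), or None."""
    m = re.fullmatch(pattern, name)
    if m is None:
        return None
    d = m.groupdict()
    return d["region"], d["age"], d["replicate"]


def read_abundance(
    path,
    sample_pattern: str = DEFAULT_SAMPLE_PATTERN,
    sep: str = "\t",
    normalized: bool = False,
) -> AbundanceTable:
    """Read an abundance TSV/CSV into an :class:`AbundanceTable`.

    The file has a ``protein_id`` index column, an optional
    ``unique_peptides`` column, and sample columns whose names encode
    ``region_age_replicate`` (configurable via ``sample_pattern``).
    Columns that do not parse are reported with a warning and dropped.
    """
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate protein id in {path}: {dup!r}")
    if "unique_peptides" in df.columns:
        peptides = df.pop("unique_peptides").astype(int)
    else:
        peptides = pd.Series(np.iinfo(np.int32).max, index=df.index, name="unique_peptides")
    meta = {}
    bad = []
    for col in df.columns:
        parsed = parse_sample_name(str(col), sample_pattern)
        if parsed is None:
            bad.append(str(col))
        else:
            meta[col] = parsed
    if bad:
        warnings.warn(f"dropping unparseable sample columns: {bad}", stacklevel=2)
        df = df.drop(columns=bad)
    if not meta:
        raise ValueError("no parseable sample columns found")
    samples = pd.DataFrame.from_dict(
        meta, orient="index", columns=["region", "age", "replicate"]
    )
    samples.index.name = "sample"
    return AbundanceTable(
        values=df.astype(float),
        samples=samples,
        unique_peptides=peptides,
        normalized=normalized,
    )


def arcsinh_normalize(table: AbundanceTable) -> AbundanceTable:
    """Apply Arc-Sinh normalization ``x -> ln(x + sqrt(x^2 + 1))``.

    Strictly increasing, defined at 0 (maps 0 to 0). Raises
    :class:`TableStateError` if the table is already normalized.
    """
    if table.normalized:
        raise TableStateError("table is already Arc-Sinh normalized")
    return replace(table, values=np.arcsinh(table.values), normalized=True)


@dataclass
class MarkerEnrichment:
    """Enrichment of one marker protein in a synaptic prep vs a reference prep."""

    marker: str
    mean_synaptic: float
    mean_reference: float
    ratio: float
    t_statistic: float
    p_value: float
    age: str


def marker_enrichment(
    synaptic: AbundanceTable,
    reference: AbundanceTable,
    markers,
    age: str = "young",
    equal_var: bool = False,
) -> list[MarkerEnrichment]:
    """Compare marker abundance between a synaptic and a reference preparation.

    For each marker, mean normalized abundance at ``age`` in each table, the
    synaptic/reference ratio, and a two-sided t-test on the replicate values
    (Welch by default; set ``equal_var=True`` for the classic Student test).
    Typical markers for a synaptosome prep are SV2A and synapsin-1 against an
    isolated-mitochondria reference.
    """
    if not (synaptic.normalized and reference.normalized):
        raise TableStateError("both tables must be normalized before enrichment")
    out = []
    for marker in markers:
        for tab, label in ((synaptic, "synaptic"), (reference, "reference")):
            if marker not in tab.values.index:
                raise KeyError(f"marker {marker!r} absent from {label} table")
        syn = np.concatenate(
            [synaptic.replicate_values(r, age).loc[marker].to_numpy() for r in synaptic.regions]
        )
        ref = np.concatenate(
            [reference.replicate_values(r, age).loc[marker].to_numpy() for r in reference.regions]
        )
        if np.array_equal(syn, ref) or (np.ptp(syn) == 0 and np.ptp(ref) == 0 and syn[0] == ref[0]):
            t, p = 0.0, 1.0  # identical constant groups: no evidence either way
        else:
            t, p = stats.ttest_ind(syn, ref, equal_var=equal_var)
        ms, mr = float(syn.mean()), float(ref.mean())
        out.append(
            MarkerEnrichment(
                marker=marker,
                mean_synaptic=ms,
                mean_reference=mr,
                ratio=ms / mr if mr != 0 else np.inf,
                t_statistic=float(t),
                p_value=float(p),
                age=age,
            )
        )
    return out


def enrichment_to_frame(results: list[MarkerEnrichment]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results]).set_index("marker")
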
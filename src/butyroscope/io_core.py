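"""Core data model and tab-separated I/O.

The central object is :class:`CommunityProfile`: a sample-by-taxon table of
integer read counts with aligned taxonomy (seven canonical ranks) and
per-sample metadata.  Enzyme content inferred for each taxon is carried in
an :class:`EnzymeContentTable`.  Readers accept the tab-separated layouts
that 16S pipelines and functional-inference tools export; writers emit the
same layouts so that write-then-read is the identity.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .config import PipelineConfig

#: Canonical taxonomy ranks, coarsest to finest.
RANKS: tuple = ("Kingdom", "Phylum", "Class", "Order", "Family", "Genus", "Species")

PathLike = Union[str, Path]


class AlignmentError(ValueError):
    """Sample or taxon identifiers disagree between input tables."""


class FormatError(ValueError):
    """A table cell violates the format contract (e.g. negative count)."""


class DialectError(ValueError):
    """Input columns cannot be mapped onto the expected layout."""


class EmptyResultError(ValueError):
    """A filter removed every taxon (or sample)."""


# --------------------------------------------------------------------------
# EC label handling
# --------------------------------------------------------------------------

_EC_RE = re.compile(r"^EC:(\d+|-)\.(\d+|-)\.(\d+|-)\.(\d+|-)$")


def normalize_ec(label: str) -> str:
    """Normalize an EC label to canonical ``EC:a.b.c.d`` form.

    Accepts ``"2.8.3.8"``, ``"EC 2.8.3.8"``, ``"ec:2.8.3.8"`` and partial
    labels with a trailing ``-`` such as ``"EC:2.8.3.-"``.  Partial labels
    are kept as distinct identifiers, not expanded into wildcards.
    """
    if label is None:
        raise FormatError("EC label is missing")
    s = str(label).strip()
    s = re.sub(r"^(EC|ec|Ec)[:\s_]*", "", s)
    s = f"EC:{s}"
    if not _EC_RE.match(s):
        raise FormatError(f"cannot normalize EC label {label!r}")
    return s


# --------------------------------------------------------------------------
# CommunityProfile
# --------------------------------------------------------------------------


@dataclass
class CommunityProfile:
    """Sample x taxon count matrix with aligned taxonomy and metadata.

    Attributes
    ----------
    counts:
        DataFrame of non-negative integer read counts, rows indexed by
        sample id, columns by taxon id.
    taxonomy:
        DataFrame indexed by taxon id with the columns in :data:`RANKS`;
        missing assignments are ``NaN``.
    sample_meta:
        DataFrame indexed by sample id; conventional columns are
        ``group``, ``timepoint``, ``diet`` and optionally ``animal_id``.
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = self.counts.copy()
        self.taxonomy = self.taxonomy.copy()
        self.sample_meta = self.sample_meta.copy()
        if self.counts.index.has_duplicates:
            raise AlignmentError("duplicate sample ids in counts")
        if self.counts.columns.has_duplicates:
            raise AlignmentError("duplicate taxon ids in counts")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise FormatError("counts must be numeric")
        if np.any(vals < 0):
            raise FormatError("counts must be non-negative")
        if not np.allclose(vals, np.round(vals)):
            raise FormatError("counts must be integers")
        self.counts = self.counts.astype(np.int64)
        missing_tax = self.counts.columns.difference(self.taxonomy.index)
        if len(missing_tax):
            raise AlignmentError(
                f"taxa missing from taxonomy: {sorted(map(str, missing_tax))}"
            )
        missing_meta = self.counts.index.difference(self.sample_meta.index)
        if len(missing_meta):
            raise AlignmentError(
                f"samples missing from metadata: {sorted(map(str, missing_meta))}"
            )
        # align exactly (order included) to the count table
        self.taxonomy = self.taxonomy.loc[self.counts.columns]
        self.sample_meta = self.sample_meta.loc[self.counts.index]
        for rank in RANKS:
            if rank not in self.taxonomy.columns:
                self.taxonomy[rank] = np.nan
        self.taxonomy = self.taxonomy[list(RANKS)]
        self.counts.index.name = "sample_id"
        self.counts.columns.name = None
        self.taxonomy.index.name = "taxon_id"
        self.sample_meta.index.name = "sample_id"

    # -- convenience ------------------------------------------------------

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def taxon_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def proportions(self) -> pd.DataFrame:
        """Per-sample relative abundances (total sum scaling)."""
        totals = self.counts.sum(axis=1)
        if (totals == 0).any():
            bad = list(totals.index[totals == 0])
            raise FormatError(f"samples with zero total count: {bad}")
        return self.counts.div(totals, axis=0)

    def subset_taxa(self, taxon_ids: Sequence) -> "CommunityProfile":
        ids = pd.Index(taxon_ids)
        unknown = ids.difference(self.counts.columns)
        if len(unknown):
            raise AlignmentError(f"unknown taxa: {sorted(map(str, unknown))}")
        return CommunityProfile(
            counts=self.counts[ids],
            taxonomy=self.taxonomy.loc[ids],
            sample_meta=self.sample_meta,
        )

    def subset_samples(self, sample_ids: Sequence) -> "CommunityProfile":
        ids = pd.Index(sample_ids)
        unknown = ids.difference(self.counts.index)
        if len(unknown):
            raise AlignmentError(f"unknown samples: {sorted(map(str, unknown))}")
        return CommunityProfile(
            counts=self.counts.loc[ids],
            taxonomy=self.taxonomy,
            sample_meta=self.sample_meta.loc[ids],
        )


# --------------------------------------------------------------------------
# EnzymeContentTable
# --------------------------------------------------------------------------


@dataclass
class EnzymeContentTable:
    """Per-taxon enzyme content: (taxon_id, ec_label) -> copy value.

    ``data`` holds one row per (taxon, EC) pair with a non-negative
    ``copy_value``; duplicates are summed on construction.  EC labels are
    normalized with :func:`normalize_ec`.
    """

    data: pd.DataFrame  # columns: taxon_id, ec_label, copy_value

    def __post_init__(self) -> None:
        df = self.data.copy()
        required = {"taxon_id", "ec_label", "copy_value"}
        if not required.issubset(df.columns):
            raise DialectError(
                f"enzyme table needs columns {sorted(required)}, got {list(df.columns)}"
            )
        if len(df):
            df["ec_label"] = df["ec_label"].map(normalize_ec)
            df["copy_value"] = pd.to_numeric(df["copy_value"])
            if (df["copy_value"] < 0).any():
                raise FormatError("copy_value must be non-negative")
            df = (
                df.groupby(["taxon_id", "ec_label"], as_index=False, sort=True)[
                    "copy_value"
                ].sum()
            )
        else:
            df = pd.DataFrame(columns=["taxon_id", "ec_label", "copy_value"])
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    def taxa(self) -> pd.Index:
        return pd.Index(self.data["taxon_id"].unique())

    def enzymes_of(self, taxon_id, presence_min: float = 0.0) -> set:
        """EC labels conserved by ``taxon_id`` (copy value > presence_min)."""
        sub = self.data[self.data["taxon_id"] == taxon_id]
        return set(sub.loc[sub["copy_value"] > presence_min, "ec_label"])


# --------------------------------------------------------------------------
# Readers / writers
# --------------------------------------------------------------------------


def _read_tsv(path: PathLike, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col, dtype={0: str}).rename(
        index=str
    )


def read_community_profile(
    counts_path: PathLike,
    taxonomy_path: PathLike,
    metadata_path: PathLike,
    strict: bool = True,
) -> CommunityProfile:
    """Read a profile from three TSV files (counts, taxonomy, metadata).

    The count table has samples as rows and taxa as columns, with ids in
    the first column / header row.  With ``strict`` (default) the three
    id sets must match exactly; otherwise tables are aligned on their
    intersection and extra ids are silently dropped.
    """
    counts = _read_tsv(counts_path)
    counts.columns = counts.columns.map(str)
    taxonomy = _read_tsv(taxonomy_path)
    metadata = _read_tsv(metadata_path)

    for col in counts.columns:
        bad = pd.to_numeric(counts[col], errors="coerce")
        if bad.isna().any():
            rows = list(counts.index[bad.isna()])
            raise FormatError(f"non-numeric count for taxon {col!r} in samples {rows}")
        counts[col] = bad
    vals = counts.to_numpy()
    if np.any(vals < 0):
        raise FormatError("negative counts in count table")
    if not np.allclose(vals, np.round(vals)):
        raise FormatError("non-integer counts in count table")

    if strict:
        miss_t = counts.columns.difference(taxonomy.index.map(str))
        extra_t = taxonomy.index.map(str).difference(counts.columns)
        miss_s = counts.index.difference(metadata.index.map(str))
        extra_s = metadata.index.map(str).difference(counts.index)
        problems = []
        if len(miss_t):
            problems.append(f"taxa absent from taxonomy: {sorted(miss_t)}")
        if len(extra_t):
            problems.append(f"taxonomy-only taxa: {sorted(extra_t)}")
        if len(miss_s):
            problems.append(f"samples absent from metadata: {sorted(miss_s)}")
        if len(extra_s):
            problems.append(f"metadata-only samples: {sorted(extra_s)}")
        if problems:
            raise AlignmentError("; ".join(problems))
    else:
        taxa = counts.columns.intersection(taxonomy.index.map(str))
        samples = counts.index.intersection(metadata.index.map(str))
        counts = counts.loc[samples, taxa]
        taxonomy = taxonomy.loc[taxa]
        metadata = metadata.loc[samples]

    return CommunityProfile(counts=counts, taxonomy=taxonomy, sample_meta=metadata)


def write_community_profile(
    profile: CommunityProfile,
    counts_path: PathLike,
    taxonomy_path: PathLike,
    metadata_path: PathLike,
) -> None:
    profile.counts.rename_axis("sample_id").to_csv(counts_path, sep="\t")
    profile.taxonomy.rename_axis("taxon_id").to_csv(taxonomy_path, sep="\t")
    profile.sample_meta.rename_axis("sample_id").to_csv(metadata_path, sep="\t")


_TAXON_ALIASES = ("taxon", "taxon_id", "taxa", "sequence", "asv", "otu", "feature")
_FUNCTION_ALIASES = ("function", "ec", "ec_label", "ko", "enzyme")
_ABUNDANCE_ALIASES = (
    "copy_value",
    "taxon_function_abun",
    "abundance",
    "copy_number",
    "count",
    "value",
)
_SAMPLE_ALIASES = ("sample", "sample_id")


def read_enzyme_content(
    path: PathLike,
    per_sample: bool = False,
    column_aliases: Optional[Mapping[str, Sequence[str]]] = None,
) -> Union[EnzymeContentTable, pd.DataFrame]:
    """Read per-taxon enzyme content from TSV.

    Two dialects are accepted: the long, sample-stratified contribution
    layout of functional-inference tools (columns mappable to sample /
    function / taxon / abundance), and a wide taxon x EC matrix with
    taxon ids in the first column.  In the long layout, rows are summed
    over samples unless ``per_sample`` is requested, in which case a
    DataFrame with a ``sample`` column is returned.
    """
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    aliases = {
        "taxon": _TAXON_ALIASES,
        "function": _FUNCTION_ALIASES,
        "abundance": _ABUNDANCE_ALIASES,
        "sample": _SAMPLE_ALIASES,
    }
    if column_aliases:
        aliases = {k: tuple(column_aliases.get(k, v)) for k, v in aliases.items()}

    def find(role: str) -> Optional[str]:
        for a in aliases[role]:
            if a.lower() in cols:
                return cols[a.lower()]
        return None

    c_tax, c_fun, c_ab = find("taxon"), find("function"), find("abundance")
    if c_tax is not None and c_fun is not None:
        sub = df.rename(
            columns={c_tax: "taxon_id", c_fun: "ec_label", c_ab: "copy_value"}
        )
        if c_ab is None:
            sub["copy_value"] = 1.0
        c_smp = find("sample")
        if per_sample:
            if c_smp is None:
                raise DialectError("per-sample mode requires a sample column")
            out = sub.rename(columns={c_smp: "sample"})[
                ["sample", "taxon_id", "ec_label", "copy_value"]
            ].copy()
            out["ec_label"] = out["ec_label"].map(normalize_ec)
            return out
        return EnzymeContentTable(sub[["taxon_id", "ec_label", "copy_value"]])

    # wide layout: first column taxon ids, remaining columns EC labels
    first = df.columns[0]
    try:
        ec_cols = {c: normalize_ec(c) for c in df.columns[1:]}
    except FormatError as exc:
        raise DialectError(
            f"no mappable columns in {path}: not a long layout and not a "
            f"taxon x EC matrix ({exc})"
        ) from exc
    if not ec_cols:
        return EnzymeContentTable(
            pd.DataFrame(columns=["taxon_id", "ec_label", "copy_value"])
        )
    long = df.melt(id_vars=[first], var_name="ec_label", value_name="copy_value")
    long = long.rename(columns={first: "taxon_id"})
    long = long[long["copy_value"] > 0]
    return EnzymeContentTable(long)


def write_enzyme_content(table: EnzymeContentTable, path: PathLike) -> None:
    table.data.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# Contaminant / prevalence filtering
# --------------------------------------------------------------------------


def filter_contaminants(
    profile: CommunityProfile, cfg: Optional[PipelineConfig] = None
) -> CommunityProfile:
    """Remove non-bacterial reads, excluded phyla and sparse phyla.

    Three rules, applied in order:

    1. taxa whose Kingdom is not ``Bacteria`` (including unassigned
       kingdoms) are removed;
    2. taxa belonging to an excluded phylum (default ``Cyanobacteria``,
       a common chloroplast-derived contaminant) are removed;
    3. each remaining phylum's mean per-taxon prevalence (mean over its
       taxa of the number of samples with count > 0) is computed, and
       every taxon of a phylum with mean prevalence below
       ``cfg.min_phylum_prevalence`` (default 1) is removed.

    The input is left unmodified.  Raises :class:`EmptyResultError` if no
    taxon survives.
    """
    cfg = cfg or PipelineConfig()
    tax = profile.taxonomy
    kingdom = tax["Kingdom"].astype("string").str.strip().str.casefold()
    keep = kingdom == "bacteria"
    phylum = tax["Phylum"].astype("string")
    keep &= ~phylum.isin({str(p) for p in cfg.excluded_phyla})

    kept = profile.taxon_ids[np.asarray(keep)]
    prevalence = (profile.counts[kept] > 0).sum(axis=0)  # per-taxon sample count
    phy = phylum.loc[kept].fillna("<unassigned>")
    mean_prev = prevalence.groupby(phy).mean()
    bad_phyla = set(mean_prev.index[mean_prev < cfg.min_phylum_prevalence])
    final = [t for t in kept if phy.loc[t] not in bad_phyla]

    if not final:
        raise EmptyResultError("contaminant filtering removed every taxon")
    return profile.subset_taxa(final)
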
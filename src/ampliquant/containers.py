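"""Core in-memory containers for quantitative amplicon experiments.

The central object is the :class:`GenotypeCountTable` — integer read counts of
sequence genotypes (zOTUs/ASVs or 97%-identity OTUs) across sequencing
libraries — bound together with per-genotype taxonomy and per-sample
experimental metadata in an :class:`ExperimentBundle`.

Counts are stored as exact integers; relative abundances are always derived
views, never stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

RANKS = ("domain", "phylum", "class", "order", "family", "genus")
VALID_FLAGS = frozenset({"chloroplast", "mitochondria", "archaea", "chimera"})
ROLES = ("experimental", "blank_extraction", "blank_pcr1", "blank_pcr2")
BLANK_ROLES = ("blank_extraction", "blank_pcr1", "blank_pcr2")
TREATMENTS = ("hotshot", "control")


class TableFormatError(ValueError):
    """A table violates structural requirements (negative counts, duplicates...)."""


class BundleValidationError(ValueError):
    """Cross-table consistency of a bundle is violated."""


class GenotypeCountTable:
    """Genotypes × samples matrix of non-negative integer read counts.

    Parameters
    ----------
    counts : pandas.DataFrame
        Rows are genotype ids, columns are sample ids, cells are read counts.
    level : {"zOTU", "OTU"}
        Classification level of the genotypes.
    """

    def __init__(self, counts: pd.DataFrame, level: str = "zOTU"):
        if level not in ("zOTU", "OTU"):
            raise TableFormatError(f"unknown level {level!r}; expected 'zOTU' or 'OTU'")
        counts = pd.DataFrame(counts).copy()
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise TableFormatError(f"duplicate genotype ids: {dups}")
        if counts.columns.has_duplicates:
            dups = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise TableFormatError(f"duplicate sample ids: {dups}")
        arr = counts.to_numpy()
        if arr.size:
            if not np.issubdtype(arr.dtype, np.number):
                raise TableFormatError("counts must be numeric")
            bad = ~np.isfinite(arr.astype(float)) | (arr.astype(float) < 0) | (
                arr.astype(float) != np.floor(arr.astype(float))
            )
            if bad.any():
                i, j = map(int, np.argwhere(bad)[0])
                raise TableFormatError(
                    f"invalid count {counts.iat[i, j]!r} at genotype "
                    f"{counts.index[i]!r}, sample {counts.columns[j]!r}: "
                    "counts must be non-negative integers"
                )
        self.counts = counts.astype(np.int64)
        self.level = level

    # -- basic views ---------------------------------------------------------
    @property
    def genotype_ids(self) -> list:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list:
        return list(self.counts.columns)

    @property
    def library_sizes(self) -> pd.Series:
        """Per-sample total read count (column sums)."""
        return self.counts.sum(axis=0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def relative_abundance(self) -> pd.DataFrame:
        """Counts divided by library size; zero-total samples give NaN columns."""
        totals = self.library_sizes.astype(float)
        return self.counts.div(totals.where(totals > 0), axis=1)

    # -- subsetting ----------------------------------------------------------
    def subset_genotypes(self, ids: Iterable) -> "GenotypeCountTable":
        ids = [g for g in self.genotype_ids if g in set(ids)]
        return GenotypeCountTable(self.counts.loc[ids], level=self.level)

    def subset_samples(self, ids: Iterable) -> "GenotypeCountTable":
        ids = [s for s in self.sample_ids if s in set(ids)]
        return GenotypeCountTable(self.counts[ids], level=self.level)

    def drop_zero_genotypes(self) -> "GenotypeCountTable":
        keep = self.counts.sum(axis=1) > 0
        return GenotypeCountTable(self.counts.loc[keep], level=self.level)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GenotypeCountTable)
            and self.level == other.level
            and self.counts.equals(other.counts)
        )

    def __repr__(self) -> str:
        g, s = self.shape
        return f"<GenotypeCountTable {g} {self.level} genotypes x {s} samples>"


class TaxonomyTable:
    """Per-genotype taxonomy: six ranked labels plus screening flags.

    Flags mark genotypes that are not targets of a bacterial 16S survey:
    ``chloroplast``, ``mitochondria``, ``archaea``, ``chimera``.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = pd.DataFrame(frame).copy()
        if frame.index.has_duplicates:
            dups = frame.index[frame.index.duplicated()].unique().tolist()
            raise TableFormatError(f"duplicate genotype ids in taxonomy: {dups}")
        for rank in RANKS:
            if rank not in frame.columns:
                frame[rank] = ""
        if "flags" not in frame.columns:
            frame["flags"] = [frozenset()] * len(frame)
        frame["flags"] = frame["flags"].map(self._coerce_flags)
        self.frame = frame[list(RANKS) + ["flags"]]

    @staticmethod
    def _coerce_flags(value) -> frozenset:
        if isinstance(value, frozenset):
            flags = value
        elif isinstance(value, str):
            flags = frozenset(f for f in value.split(",") if f)
        else:
            flags = frozenset(value or ())
        unknown = flags - VALID_FLAGS
        if unknown:
            raise TableFormatError(f"unknown taxonomy flags: {sorted(unknown)}")
        return flags

    @property
    def genotype_ids(self) -> list:
        return list(self.frame.index)

    def flags_of(self, genotype_id) -> frozenset:
        return self.frame.at[genotype_id, "flags"]

    def genus_of(self, genotype_id) -> str:
        return self.frame.at[genotype_id, "genus"]

    def flagged(self) -> list:
        """Genotype ids carrying any non-target flag."""
        return [g for g in self.frame.index if self.frame.at[g, "flags"]]

    def subset(self, ids: Iterable) -> "TaxonomyTable":
        ids = [g for g in self.frame.index if g in set(ids)]
        return TaxonomyTable(self.frame.loc[ids])

    def __eq__(self, other) -> bool:
        return isinstance(other, TaxonomyTable) and self.frame.equals(other.frame)


@dataclass
class SampleMetadata:
    """Experimental descriptors of one sequencing library.

    Experimental samples carry the host line (species × culture line, the unit
    of all per-group comparisons), the treatment arm, a 1–5 body-size class,
    and the spike-in parameters needed for absolute quantification: how many
    plasmid copies were added and to what fraction of the specimen homogenate.
    Blanks (extraction / first-PCR / second-PCR negative controls) carry only
    their role and an optional batch label.
    """

    sample_id: str
    role: str = "experimental"
    species: str | None = None
    line: str | None = None
    treatment: str | None = None
    size_class: int | None = None
    spike_copies_added: float | None = None
    homogenate_proportion: float | None = None
    batch: str | None = None
    excluded: bool = False
    excluded_reason: str = ""

    def __post_init__(self):
        if self.role not in ROLES:
            raise TableFormatError(
                f"sample {self.sample_id!r}: unknown role {self.role!r}"
            )
        if self.role == "experimental":
            if not self.species or not self.line:
                raise TableFormatError(
                    f"experimental sample {self.sample_id!r} needs species and line"
                )
            if self.treatment not in TREATMENTS:
                raise TableFormatError(
                    f"sample {self.sample_id!r}: treatment must be one of "
                    f"{TREATMENTS}, got {self.treatment!r}"
                )
            if self.size_class is not None and self.size_class not in (1, 2, 3, 4, 5):
                raise TableFormatError(
                    f"sample {self.sample_id!r}: size_class must be 1-5"
                )
            if self.spike_copies_added is not None and self.spike_copies_added <= 0:
                raise TableFormatError(
                    f"sample {self.sample_id!r}: spike_copies_added must be > 0"
                )
            if self.homogenate_proportion is not None and not (
                0 < self.homogenate_proportion <= 1
            ):
                raise TableFormatError(
                    f"sample {self.sample_id!r}: homogenate_proportion must be in (0,1]"
                )

    @property
    def is_blank(self) -> bool:
        return self.role != "experimental"

    @property
    def quantifiable(self) -> bool:
        """Spike parameters present — absolute quantification is permitted.

        Missing parameters deliberately do NOT default to the study-wide
        nominal values: quantification is refused for such samples.
        """
        return (
            self.role == "experimental"
            and self.spike_copies_added is not None
            and self.homogenate_proportion is not None
        )


@dataclass
class ExperimentBundle:
    """Validated binding of counts, taxonomy and metadata for one experiment."""

    counts: GenotypeCountTable
    taxonomy: TaxonomyTable
    metadata: list[SampleMetadata]
    spike_genotype_ids: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        self.spike_genotype_ids = frozenset(self.spike_genotype_ids)
        self.validate()

    def validate(self) -> None:
        meta_ids = [m.sample_id for m in self.metadata]
        if len(meta_ids) != len(set(meta_ids)):
            dups = sorted({s for s in meta_ids if meta_ids.count(s) > 1})
            raise BundleValidationError(f"duplicate sample ids in metadata: {dups}")
        missing = [s for s in self.counts.sample_ids if s not in set(meta_ids)]
        if missing:
            raise BundleValidationError(
                f"samples in count table absent from metadata: {missing}"
            )
        tax_ids = set(self.taxonomy.genotype_ids)
        untaxed = [g for g in self.counts.genotype_ids if g not in tax_ids]
        if untaxed:
            raise BundleValidationError(
                f"genotypes without a taxonomy row: {untaxed}"
            )
        stray_spikes = [g for g in self.spike_genotype_ids
                        if g not in set(self.counts.genotype_ids)]
        # stray spike ids are tolerated (recorded with zero reads downstream)
        self._stray_spike_ids = stray_spikes

    @property
    def metadata_by_id(self) -> dict[str, SampleMetadata]:
        return {m.sample_id: m for m in self.metadata}

    def metadata_frame(self) -> pd.DataFrame:
        """Metadata as a DataFrame indexed by sample_id (a derived view)."""
        rows = []
        for m in self.metadata:
            rows.append({
                "sample_id": m.sample_id, "role": m.role, "species": m.species,
                "line": m.line, "treatment": m.treatment, "size_class": m.size_class,
                "spike_copies_added": m.spike_copies_added,
                "homogenate_proportion": m.homogenate_proportion,
                "batch": m.batch, "excluded": m.excluded,
                "excluded_reason": m.excluded_reason,
            })
        return pd.DataFrame(rows).set_index("sample_id") if rows else pd.DataFrame(
            columns=["role", "species", "line", "treatment", "size_class",
                     "spike_copies_added", "homogenate_proportion", "batch",
                     "excluded", "excluded_reason"])

    def blank_samples(self) -> list[SampleMetadata]:
        return [m for m in self.metadata if m.is_blank]

    def experimental_samples(self) -> list[SampleMetadata]:
        return [m for m in self.metadata if not m.is_blank]

    def with_counts(self, counts: GenotypeCountTable) -> "ExperimentBundle":
        """New bundle sharing taxonomy/metadata with a replaced count table."""
        return ExperimentBundle(
            counts=counts,
            taxonomy=self.taxonomy.subset(counts.genotype_ids),
            metadata=self.metadata,
            spike_genotype_ids=self.spike_genotype_ids,
        )
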
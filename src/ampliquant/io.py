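"""Tab-separated readers/writers for count tables, taxonomy and metadata.

Layout conventions (all plain TSV with headers):

* counts: first column ``genotype_id``, remaining columns one per sample.
  Genotypes as rows is the native orientation; ``orientation="samples_as_rows"``
  accepts the transpose and normalizes internally.
* taxonomy: ``genotype_id``, ``lineage`` (semicolon-delimited
  domain;phylum;class;order;family;genus), ``flags`` (comma-delimited subset of
  chloroplast,mitochondria,archaea,chimera; may be empty).
* metadata: one row per sample, keyed by ``sample_id``.

Round-trip ``read_bundle(write_bundle(b))`` is the identity on every field.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    RANKS,
    BundleValidationError,
    ExperimentBundle,
    GenotypeCountTable,
    SampleMetadata,
    TableFormatError,
    TaxonomyTable,
)

_META_COLS = [
    "sample_id", "role", "species", "line", "treatment", "size_class",
    "spike_copies_added", "homogenate_proportion", "batch", "excluded",
    "excluded_reason",
]


def read_counts(path, level: str = "zOTU",
                orientation: str = "genotypes_as_rows") -> GenotypeCountTable:
    """Read a count table, validating every cell with coordinates on failure."""
    raw = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str,
                      keep_default_na=False)
    if orientation == "samples_as_rows":
        raw = raw.T
    elif orientation != "genotypes_as_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    parsed = pd.DataFrame(index=raw.index.astype(str),
                          columns=raw.columns.astype(str), dtype=np.int64)
    for j, col in enumerate(raw.columns):
        vals = pd.to_numeric(raw.iloc[:, j], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals != np.floor(vals.fillna(0)))
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            raise TableFormatError(
                f"{path}: invalid count {raw.iat[i, j]!r} at row "
                f"{raw.index[i]!r} (line {i + 2}), column {col!r}: "
                "counts must be non-negative integers"
            )
        parsed.iloc[:, j] = vals.astype(np.int64)
    return GenotypeCountTable(parsed, level=level)


def read_taxonomy(path) -> TaxonomyTable:
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "genotype_id" not in raw.columns or "lineage" not in raw.columns:
        raise TableFormatError(
            f"{path}: taxonomy needs 'genotype_id' and 'lineage' columns"
        )
    rows = {}
    for _, r in raw.iterrows():
        parts = [p.strip() for p in r["lineage"].split(";")] if r["lineage"] else []
        parts += [""] * (len(RANKS) - len(parts))
        rec = dict(zip(RANKS, parts[: len(RANKS)]))
        rec["flags"] = r.get("flags", "")
        gid = r["genotype_id"]
        if gid in rows:
            raise TableFormatError(f"{path}: duplicate genotype id {gid!r}")
        rows[gid] = rec
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "genotype_id"
    return TaxonomyTable(frame)


def _opt_float(v: str):
    return None if v == "" else float(v)


def read_metadata(path) -> list[SampleMetadata]:
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "sample_id" not in raw.columns:
        raise TableFormatError(f"{path}: metadata needs a 'sample_id' column")
    out = []
    for _, r in raw.iterrows():
        out.append(SampleMetadata(
            sample_id=r["sample_id"],
            role=r.get("role", "experimental") or "experimental",
            species=r.get("species", "") or None,
            line=r.get("line", "") or None,
            treatment=r.get("treatment", "") or None,
            size_class=int(r["size_class"]) if r.get("size_class", "") else None,
            spike_copies_added=_opt_float(r.get("spike_copies_added", "")),
            homogenate_proportion=_opt_float(r.get("homogenate_proportion", "")),
            batch=r.get("batch", "") or None,
            excluded=(r.get("excluded", "") or "false").lower() == "true",
            excluded_reason=r.get("excluded_reason", ""),
        ))
    return out


def read_bundle(counts_path, taxonomy_path, metadata_path, spike_ids=(),
                level: str = "zOTU",
                orientation: str = "genotypes_as_rows") -> ExperimentBundle:
    """Read and cross-validate the three tables into one bundle.

    Raises
    ------
    TableFormatError
        Malformed cells (with row/column coordinates) or duplicate ids.
    BundleValidationError
        Samples or genotypes missing across tables, named individually.
    """
    counts = read_counts(counts_path, level=level, orientation=orientation)
    taxonomy = read_taxonomy(taxonomy_path)
    metadata = read_metadata(metadata_path)
    return ExperimentBundle(counts=counts, taxonomy=taxonomy, metadata=metadata,
                            spike_genotype_ids=frozenset(spike_ids))


def write_counts(table: GenotypeCountTable, path) -> None:
    out = table.counts.copy()
    out.index.name = "genotype_id"
    out.to_csv(path, sep="\t")


def write_taxonomy(taxonomy: TaxonomyTable, path) -> None:
    recs = []
    for gid in taxonomy.genotype_ids:
        row = taxonomy.frame.loc[gid]
        recs.append({
            "genotype_id": gid,
            "lineage": ";".join(row[r] for r in RANKS),
            "flags": ",".join(sorted(row["flags"])),
        })
    pd.DataFrame(recs, columns=["genotype_id", "lineage", "flags"]).to_csv(
        path, sep="\t", index=False)


def write_metadata(metadata: list[SampleMetadata], path) -> None:
    recs = []
    for m in metadata:
        recs.append({
            "sample_id": m.sample_id, "role": m.role,
            "species": m.species or "", "line": m.line or "",
            "treatment": m.treatment or "",
            "size_class": "" if m.size_class is None else m.size_class,
            "spike_copies_added": "" if m.spike_copies_added is None
            else repr(m.spike_copies_added),
            "homogenate_proportion": "" if m.homogenate_proportion is None
            else repr(m.homogenate_proportion),
            "batch": m.batch or "",
            "excluded": "true" if m.excluded else "false",
            "excluded_reason": m.excluded_reason,
        })
    pd.DataFrame(recs, columns=_META_COLS).to_csv(path, sep="\t", index=False)


def write_bundle(bundle: ExperimentBundle, out_dir) -> list[Path]:
    """Write counts/taxonomy/metadata (+ spike ids) as TSV; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = [out_dir / "counts.tsv", out_dir / "taxonomy.tsv",
             out_dir / "metadata.tsv", out_dir / "spike_genotypes.txt"]
    write_counts(bundle.counts, paths[0])
    write_taxonomy(bundle.taxonomy, paths[1])
    write_metadata(bundle.metadata, paths[2])
    paths[3].write_text("".join(f"{g}\n" for g in sorted(bundle.spike_genotype_ids)))
    return paths


def read_bundle_dir(in_dir, level: str = "zOTU") -> ExperimentBundle:
    """Inverse of :func:`write_bundle`."""
    in_dir = Path(in_dir)
    spike_file = in_dir / "spike_genotypes.txt"
    spike_ids = [ln for ln in spike_file.read_text().splitlines() if ln] \
        if spike_file.exists() else []
    return read_bundle(in_dir / "counts.tsv", in_dir / "taxonomy.tsv",
                       in_dir / "metadata.tsv", spike_ids, level=level)
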
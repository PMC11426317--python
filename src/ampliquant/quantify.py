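"""Spike-in based absolute quantification of amplifiable 16S rRNA copies.

A known number of copies of an artificial 16S target (a linearized plasmid)
is added to a known fraction of each specimen's homogenate before DNA
purification. Assuming no amplification bias among template types, read
counts are proportional to template copies within a library, so

    copies_per_insect = (bacterial_reads / spike_reads)
                        * spike_copies_added / homogenate_proportion

where ``bacterial_reads`` counts only symbiont-class genotypes (contaminant
reads are reagent-derived, not insect-derived, and are excluded from the
numerator). The division by the homogenate proportion scales the aliquot
estimate to the whole insect.

Spike parameters are per-sample metadata, never code constants: samples with
missing parameters or zero spike reads are refused (flagged unquantifiable)
rather than silently defaulted.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .containers import ExperimentBundle, GenotypeCountTable


class QuantificationError(ValueError):
    """Absolute quantification is impossible for a sample."""


@dataclass
class AbundanceEstimate:
    """Absolute abundance estimate for one specimen, with its inputs."""

    sample_id: str
    bacterial_reads: int
    spike_reads: int
    ratio: float
    spike_copies_added: float
    homogenate_proportion: float
    copies_per_insect: float


def spike_ratio(bacterial_reads: int, spike_reads: int) -> float:
    """Bacterial-to-spike read ratio; requires spike_reads > 0."""
    if bacterial_reads < 0 or spike_reads < 0:
        raise ValueError("read counts must be non-negative")
    if spike_reads == 0:
        raise QuantificationError(
            "spike_reads is zero: quantification impossible for this sample")
    return bacterial_reads / spike_reads


def copies_from_ratio(ratio: float, spike_copies_added: float,
                      homogenate_proportion: float) -> float:
    """Scale the read ratio to whole-insect 16S copy numbers."""
    if ratio < 0:
        raise ValueError("ratio must be non-negative")
    if spike_copies_added <= 0:
        raise ValueError("spike_copies_added must be positive")
    if not 0 < homogenate_proportion <= 1:
        raise ValueError("homogenate_proportion must be in (0, 1]")
    return ratio * spike_copies_added / homogenate_proportion


def quantify_sample(bacterial_reads: int, spike_reads: int,
                    spike_copies_added: float,
                    homogenate_proportion: float,
                    sample_id: str = "") -> AbundanceEstimate:
    ratio = spike_ratio(bacterial_reads, spike_reads)
    copies = copies_from_ratio(ratio, spike_copies_added, homogenate_proportion)
    return AbundanceEstimate(
        sample_id=sample_id, bacterial_reads=int(bacterial_reads),
        spike_reads=int(spike_reads), ratio=ratio,
        spike_copies_added=spike_copies_added,
        homogenate_proportion=homogenate_proportion, copies_per_insect=copies)


def quantify_all(
    bundle: ExperimentBundle,
    decontaminated: GenotypeCountTable,
    spike_reads: pd.Series,
    sample_ids: list | None = None,
) -> tuple[list[AbundanceEstimate], list[tuple[str, str]]]:
    """Estimate copies per insect for every quantifiable sample.

    Parameters
    ----------
    decontaminated : GenotypeCountTable
        Symbiont-class genotypes only; its column sums are the bacterial-read
        numerators.
    spike_reads : pandas.Series
        Per-sample spike read counts from the screening stage.
    sample_ids : list, optional
        Samples to quantify (default: the decontaminated table's samples, as
        selected by upstream filtering).

    Returns
    -------
    (estimates, unquantifiable)
        ``unquantifiable`` lists ``(sample_id, reason)`` for refused samples;
        those remain usable for compositional analyses.
    """
    if sample_ids is None:
        sample_ids = decontaminated.sample_ids
    meta = bundle.metadata_by_id
    sizes = decontaminated.library_sizes
    estimates, refused = [], []
    for sid in sample_ids:
        m = meta[sid]
        if m.is_blank:
            refused.append((sid, "control"))
            continue
        if not m.quantifiable:
            refused.append((sid, "missing spike parameters"))
            continue
        sr = int(spike_reads.get(sid, 0))
        if sr == 0:
            refused.append((sid, "zero spike reads"))
            continue
        estimates.append(quantify_sample(
            int(sizes[sid]), sr, m.spike_copies_added,
            m.homogenate_proportion, sample_id=sid))
    return estimates, refused


def estimates_frame(estimates: list[AbundanceEstimate]) -> pd.DataFrame:
    """Estimates as a DataFrame indexed by sample_id (for writing/statistics)."""
    cols = ["bacterial_reads", "spike_reads", "ratio", "spike_copies_added",
            "homogenate_proportion", "copies_per_insect"]
    if not estimates:
        return pd.DataFrame(columns=cols)
    frame = pd.DataFrame([e.__dict__ for e in estimates]).set_index("sample_id")
    return frame[cols]
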
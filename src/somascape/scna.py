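"""Somatic copy-number alteration classification and summarization.

Segments are labeled relative to a rounded baseline ploidy: gain at one or
more integer states above baseline, loss at one or more below, LOH whenever
the minor-allele copy number rounds to zero on a non-deleted segment. Labels
are not mutually exclusive — LOH co-occurs with gain or loss. The fraction of
genome altered (FGA) uses the union of bases carrying any of the three
labels, so a multi-labeled segment is never double-counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catastrophe import cn_state
from .io_formats import CNSegment

LABELS = ("gain", "loss", "LOH")


def classify_segment(segment: CNSegment, baseline_ploidy: float = 2.0) -> set[str]:
    """Label one segment with any of {gain, loss, LOH} (empty set = neutral).

    LOH is undetermined (never labeled) when the segment carries no
    minor-allele copy number.
    """
    if baseline_ploidy <= 0:
        raise ValueError("baseline ploidy must be positive")
    base = cn_state(baseline_ploidy)
    state = cn_state(segment.total_cn)
    labels: set[str] = set()
    if state >= base + 1:
        labels.add("gain")
    if state <= base - 1:
        labels.add("loss")
    if segment.minor_cn is not None and cn_state(segment.minor_cn) == 0 and state >= 1:
        labels.add("LOH")
    return labels


@dataclass(frozen=True)
class SCNASummary:
    sample_id: str
    length_gain_bp: int
    length_loss_bp: int
    length_loh_bp: int
    fraction_genome_altered: float
    n_loh_undetermined: int = 0


def _union_length(intervals: list[tuple[int, int]]) -> int:
    if not intervals:
        return 0
    intervals.sort()
    total, cur_s, cur_e = 0, *intervals[0]
    for s, e in intervals[1:]:
        if s > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    return total + (cur_e - cur_s)


def summarize_sample(
    segments: Sequence[CNSegment],
    genome_length: int,
    baseline_ploidy: float = 2.0,
) -> SCNASummary:
    """Per-class altered lengths and fraction of genome altered for one sample.

    Class lengths are sums over segments carrying the label; FGA is the union
    of gain/loss/LOH bases over the genome length.
    """
    covered = sum(s.length for s in segments)
    if genome_length < covered:
        raise ValueError("genome_length smaller than covered bases")
    lengths = {label: 0 for label in LABELS}
    altered: dict[str, list[tuple[int, int]]] = {}
    undetermined = 0
    for seg in segments:
        labels = classify_segment(seg, baseline_ploidy)
        if seg.minor_cn is None:
            undetermined += 1
        for label in labels:
            lengths[label] += seg.length
        if labels:
            altered.setdefault(seg.chrom, []).append((seg.start, seg.end))
    union = sum(_union_length(ivs) for ivs in altered.values())
    sample = segments[0].sample_id if segments else "?"
    return SCNASummary(sample, lengths["gain"], lengths["loss"], lengths["LOH"],
                       union / genome_length, undetermined)


def region_feature_matrix(
    segments_by_sample: Mapping[str, Sequence[CNSegment]],
    regions: Sequence[tuple[str, str, int, int, str]],
    baseline_ploidy: float = 2.0,
    min_overlap: float = 0.5,
) -> pd.DataFrame:
    """Samples x regions matrix in {-1, 0, +1} for clustering.

    ``regions`` are (name, chrom, start, end, tag) with tag ``amp`` or
    ``del`` (0-based half-open). A sample scores +1 on an amp region when its
    gain-labeled bases cover at least ``min_overlap`` of the region (likewise
    -1 for loss on a del region), else 0.
    """
    for name, _c, _s, _e, tag in regions:
        if tag not in ("amp", "del"):
            raise ValueError(f"region {name!r} has unknown tag {tag!r}")
    samples = list(segments_by_sample)
    mat = pd.DataFrame(0, index=samples, columns=[r[0] for r in regions], dtype=int)
    for sample, segs in segments_by_sample.items():
        for name, chrom, start, end, tag in regions:
            want = "gain" if tag == "amp" else "loss"
            overlap = 0
            for seg in segs:
                if seg.chrom != chrom:
                    continue
                if want in classify_segment(seg, baseline_ploidy):
                    overlap += max(0, min(seg.end, end) - max(seg.start, start))
            if overlap >= min_overlap * (end - start):
                mat.at[sample, name] = 1 if tag == "amp" else -1
    return mat
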
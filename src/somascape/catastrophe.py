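"""Detection of catastrophic mutational and structural events.

Kataegis: maximal runs of >= 4 consecutive SNVs with every inter-variant
distance < 2 kb, kept when the cluster's mutation density exceeds the
sample's genome-wide density more than 5-fold (the "hyperscore",
(k/w) / (M/G) with k SNVs over span w in a sample of M SNVs on a G-bp
genome).

Chromothripsis, per chromosome: at least 3x more SV breakpoints per Mb than
expected under a genome-wide uniform null, significant breakpoint clustering
by a one-sample Kolmogorov-Smirnov test against the uniform distribution,
and at least 10 switches between rounded copy-number states.

Breakage-fusion-bridge, per chromosome arm: loss of the telomeric region
with a neighboring highly amplified region, on a chromosome whose
breakpoints cluster.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .io_formats import CNSegment, MutationRecord, SVRecord


def intermutation_distances(
    snvs: Sequence[MutationRecord],
) -> dict[str, np.ndarray]:
    """Per-chromosome successive inter-variant distances for one sample.

    Input must be sorted by (chrom, pos); the first variant on each
    chromosome contributes no distance.
    """
    keys = [(r.chrom, r.pos) for r in snvs]
    if keys != sorted(keys):
        raise ValueError("SNVs must be sorted by (chrom, pos)")
    out: dict[str, np.ndarray] = {}
    by_chrom: dict[str, list[int]] = defaultdict(list)
    for r in snvs:
        by_chrom[r.chrom].append(r.pos)
    for chrom, positions in by_chrom.items():
        out[chrom] = np.diff(np.asarray(positions))
    return out


@dataclass(frozen=True)
class KataegisFocus:
    """One localized-hypermutation cluster."""

    sample_id: str
    chrom: str
    start: int
    end: int
    n_snvs: int
    hyperscore: float
    positions: tuple[int, ...] = field(default_factory=tuple)


def detect_kataegis(
    snvs: Sequence[MutationRecord],
    genome_length_bp: float,
    min_snvs: int = 4,
    max_gap_bp: int = 2000,
    min_hyperscore: float = 5.0,
) -> list[KataegisFocus]:
    """Find kataegis foci in one sample's SNVs.

    Candidate clusters are maximal runs of consecutive SNVs on a chromosome
    with every adjacent gap < ``max_gap_bp`` and at least ``min_snvs``
    members; a cluster is reported when its hyperscore — cluster density
    (k / span) over the sample's genome-wide density (M / G) — exceeds
    ``min_hyperscore``. Foci are maximal, hence disjoint within a sample.
    """
    if genome_length_bp <= 0:
        raise ValueError("genome_length_bp must be positive")
    snvs = sorted(snvs, key=lambda r: (r.chrom, r.pos))
    M = len(snvs)
    if M == 0:
        return []
    rate = M / genome_length_bp
    foci: list[KataegisFocus] = []
    by_chrom: dict[str, list[int]] = defaultdict(list)
    sample = snvs[0].sample_id
    for r in snvs:
        by_chrom[r.chrom].append(r.pos)
    for chrom, positions in by_chrom.items():
        run_start = 0
        for i in range(1, len(positions) + 1):
            at_end = i == len(positions)
            if at_end or positions[i] - positions[i - 1] >= max_gap_bp:
                run = positions[run_start:i]
                run_start = i
                if len(run) < min_snvs:
                    continue
                span = max(run[-1] - run[0], 1)
                hyperscore = (len(run) / span) / rate
                if hyperscore > min_hyperscore:
                    foci.append(
                        KataegisFocus(sample, chrom, run[0], run[-1], len(run),
                                      hyperscore, tuple(run))
                    )
    return foci


def breakpoints_of(svs: Iterable[SVRecord]) -> dict[str, np.ndarray]:
    """Collect per-chromosome sorted breakpoint positions (duplicates kept).

    Every SV contributes pos1 on chrom1 and pos2 on chrom2, so n SVs yield
    exactly 2n breakpoints genome-wide.
    """
    by_chrom: dict[str, list[int]] = defaultdict(list)
    for sv in svs:
        by_chrom[sv.chrom1].append(sv.pos1)
        by_chrom[sv.chrom2].append(sv.pos2)
    return {c: np.sort(np.asarray(p)) for c, p in by_chrom.items()}


def ks_uniformity(positions, chrom_length: float) -> tuple[float, float]:
    """Two-sided one-sample KS test of breakpoint positions against uniformity.

    Positions are scaled by the chromosome length and tested against
    Uniform(0, 1). Requires >= 3 positions; fewer raise ``ValueError`` so an
    under-powered chromosome is never mistaken for clustering evidence.
    """
    positions = np.asarray(positions, dtype=float)
    if len(positions) < 3:
        raise ValueError("KS uniformity test needs at least 3 positions")
    if chrom_length <= 0:
        raise ValueError("chromosome length must be positive")
    res = stats.kstest(positions / chrom_length, "uniform")
    return float(res.statistic), float(res.pvalue)


def cn_state(total_cn: float) -> int:
    """Integer copy-number state: banker's rounding of total copy number."""
    return int(np.rint(total_cn))


def count_cn_switches(segments: Sequence[CNSegment]) -> int:
    """Count adjacent segment pairs whose rounded copy-number states differ.

    ``segments`` is one sample's segments on one chromosome, sorted and
    non-overlapping.
    """
    states = [cn_state(s.total_cn) for s in
              sorted(segments, key=lambda s: s.start)]
    return sum(1 for a, b in zip(states, states[1:]) if a != b)


@dataclass(frozen=True)
class ChromothripsisCall:
    sample_id: str
    chrom: str
    n_breakpoints: int
    breaks_per_mb: float
    fold_enrichment: float
    ks_statistic: float
    ks_p: float
    n_cn_switches: int
    verdict: bool
    reason: str = ""


def detect_chromothripsis(
    svs: Sequence[SVRecord],
    segments: Sequence[CNSegment],
    chrom_lengths: Mapping[str, int],
    alpha: float = 0.01,
    min_breakpoints: int = 10,
    min_fold: float = 3.0,
    min_switches: int = 10,
) -> list[ChromothripsisCall]:
    """Evaluate every chromosome of one sample for chromothripsis.

    The expected breakpoint density is the sample's total breakpoints over
    the total genome length (the uniform "breaks equally distributed" null).
    A chromosome is called when it shows >= ``min_fold`` that density, KS
    clustering at ``alpha``, and >= ``min_switches`` copy-number state
    switches. Chromosomes with fewer than ``min_breakpoints`` breakpoints are
    reported with verdict False and a reason.
    """
    bps = breakpoints_of(svs)
    for chrom in bps:
        if chrom not in chrom_lengths:
            raise ValueError(f"no length provided for chromosome {chrom!r}")
    total_bp = sum(len(p) for p in bps.values())
    genome_length = float(sum(chrom_lengths.values()))
    expected_density = total_bp / genome_length if total_bp else 0.0
    seg_by_chrom: dict[str, list[CNSegment]] = defaultdict(list)
    sample = svs[0].sample_id if svs else (segments[0].sample_id if segments else "?")
    for s in segments:
        seg_by_chrom[s.chrom].append(s)
    calls = []
    for chrom, length in chrom_lengths.items():
        positions = bps.get(chrom, np.array([], dtype=int))
        n = len(positions)
        density = n / length
        fold = density / expected_density if expected_density > 0 else 0.0
        switches = count_cn_switches(seg_by_chrom.get(chrom, []))
        if n < min_breakpoints:
            calls.append(
                ChromothripsisCall(sample, chrom, n, density * 1e6, fold,
                                   float("nan"), float("nan"), switches, False,
                                   f"fewer than {min_breakpoints} breakpoints")
            )
            continue
        ks_stat, ks_p = ks_uniformity(positions, length)
        verdict = fold >= min_fold and ks_p < alpha and switches >= min_switches
        calls.append(
            ChromothripsisCall(sample, chrom, n, density * 1e6, fold,
                               ks_stat, ks_p, switches, verdict)
        )
    return calls


@dataclass(frozen=True)
class BFBCall:
    sample_id: str
    chrom: str
    arm: str  # 'p' | 'q'
    telomeric_loss: bool
    adjacent_amplification: bool
    breakpoint_cluster: bool
    verdict: bool
    reason: str = ""


def detect_bfb(
    svs: Sequence[SVRecord],
    segments: Sequence[CNSegment],
    chrom_lengths: Mapping[str, int],
    centromeres: Mapping[str, int] | None = None,
    tel_window_bp: float = 1e6,
    adj_window_bp: float = 1e7,
    amp_gain: int = 3,
    loss_drop: int = 1,
    baseline: float = 2.0,
    cluster_alpha: float = 0.01,
    min_breakpoints: int = 10,
) -> list[BFBCall]:
    """Evaluate every chromosome arm of one sample for breakage-fusion-bridge.

    Evidence per arm: (1) a segment overlapping the arm's terminal
    ``tel_window_bp`` with state <= baseline - ``loss_drop`` (telomeric loss);
    (2) a segment within ``adj_window_bp`` of the lost region with state >=
    baseline + ``amp_gain``; (3) breakpoint clustering on the chromosome (KS
    p < ``cluster_alpha``, >= ``min_breakpoints`` breakpoints). Verdict is
    the conjunction. Arms with no covering segments at the tested end get
    verdict False with reason ``uncovered``. ``centromeres`` gives the p/q
    boundary per chromosome; by default the chromosome midpoint is used.
    """
    bps = breakpoints_of(svs)
    base_state = cn_state(baseline)
    seg_by_chrom: dict[str, list[CNSegment]] = defaultdict(list)
    for s in segments:
        seg_by_chrom[s.chrom].append(s)
    sample = svs[0].sample_id if svs else (segments[0].sample_id if segments else "?")
    calls = []
    for chrom, length in chrom_lengths.items():
        positions = bps.get(chrom, np.array([], dtype=int))
        if len(positions) >= max(3, min_breakpoints):
            _, ks_p = ks_uniformity(positions, length)
            cluster = bool(ks_p < cluster_alpha)
        else:
            cluster = False
        boundary = centromeres[chrom] if centromeres else length // 2
        segs = sorted(seg_by_chrom.get(chrom, []), key=lambda s: s.start)
        for arm in ("p", "q"):
            if arm == "p":
                tel_lo, tel_hi = 0, int(tel_window_bp)
                arm_segs = [s for s in segs if s.start < boundary]
            else:
                tel_lo, tel_hi = int(length - tel_window_bp), length
                arm_segs = [s for s in segs if s.end > boundary]
            tel_segs = [s for s in arm_segs if s.start < tel_hi and s.end > tel_lo]
            if not tel_segs:
                calls.append(BFBCall(sample, chrom, arm, False, False, cluster,
                                     False, "uncovered arm end"))
                continue
            lost = [s for s in tel_segs
                    if cn_state(s.total_cn) <= base_state - loss_drop]
            tel_loss = bool(lost)
            adjacent_amp = False
            if tel_loss:
                lo = min(s.start for s in lost) - adj_window_bp
                hi = max(s.end for s in lost) + adj_window_bp
                adjacent_amp = any(
                    s.start < hi and s.end > lo
                    and cn_state(s.total_cn) >= base_state + amp_gain
                    for s in segs
                )
            verdict = tel_loss and adjacent_amp and cluster
            calls.append(BFBCall(sample, chrom, arm, tel_loss, adjacent_amp,
                                 cluster, verdict))
    return calls


def recurrent_rearranged_genes(
    svs: Sequence[SVRecord],
    genes: Sequence[tuple[str, str, int, int]],
) -> "tuple[object, object]":
    """Gene-level SV recurrence across a cohort.

    ``genes`` are (name, chrom, start, end) 0-based half-open intervals. A
    gene is hit in a sample iff any breakpoint of any of the sample's SVs
    falls inside the interval (1-based position p is inside [start, end) iff
    start < p <= end under half-open semantics: position p occupies base
    index p - 1). Returns the gene x sample 0/1 incidence DataFrame and the
    per-gene recurrence (number of samples hit).
    """
    import pandas as pd

    for name, _c, s, e in genes:
        if s >= e:
            raise ValueError(f"degenerate gene interval {name}")
    samples: list[str] = []
    for sv in svs:
        if sv.sample_id not in samples:
            samples.append(sv.sample_id)
    incidence = pd.DataFrame(0, index=[g[0] for g in genes], columns=samples, dtype=int)
    by_sample: dict[str, list[SVRecord]] = defaultdict(list)
    for sv in svs:
        by_sample[sv.sample_id].append(sv)
    for sample, recs in by_sample.items():
        for name, chrom, start, end in genes:
            hit = any(
                (sv.chrom1 == chrom and start < sv.pos1 <= end)
                or (sv.chrom2 == chrom and start < sv.pos2 <= end)
                for sv in recs
            )
            if hit:
                incidence.at[name, sample] = 1
    recurrence = incidence.sum(axis=1)
    return incidence, recurrence
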
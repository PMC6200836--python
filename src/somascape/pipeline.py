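"""End-to-end helpers tying the modules together over one cohort.

These are the computations the numbered analysis drivers, the test-suite and
the acceptance script all share: a per-sample metric table (burden, six-type
proportions, A>C-at-AA fraction, kataegis counts, SCNA lengths, event
indicators) and the detector scorecard against a synthetic cohort's planted
truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import catastrophe as cat
from . import scna
from . import spectrum as sp
from .cohort_stats import compare_cohorts
from .synthetic import Cohort

BINARY_METRICS = ("chromothripsis", "bfb")


def cohort_metrics(cohort: Cohort) -> pd.DataFrame:
    """Per-sample metric table for the standard cohort comparisons."""
    samples = cohort.manifest.samples
    spec = sp.build_spectrum(cohort.all_snvs(), samples=samples)
    genome_mb = cohort.genome_length / 1e6
    out = pd.DataFrame(index=samples)
    out["burden_per_mb"] = spec.sum(axis=1) / genome_mb
    nonzero = spec.sum(axis=1) > 0
    props = sp.six_type_proportions(spec.loc[nonzero])
    for t in sp.SIX_TYPES:
        out[f"prop_{t}"] = props[t]
    out["axc_at_aa"] = sp.axc_at_aa_fraction(spec)["overall"]
    kataegis, ct, bfb = {}, {}, {}
    gain, loss, loh = {}, {}, {}
    for s in samples:
        kataegis[s] = len(cat.detect_kataegis(cohort.snvs[s], cohort.genome_length))
        calls = cat.detect_chromothripsis(cohort.svs[s], cohort.segments[s], cohort.genome)
        ct[s] = int(any(c.verdict for c in calls))
        bcalls = cat.detect_bfb(cohort.svs[s], cohort.segments[s], cohort.genome)
        bfb[s] = int(any(c.verdict for c in bcalls))
        summary = scna.summarize_sample(cohort.segments[s], cohort.genome_length)
        gain[s], loss[s], loh[s] = (summary.length_gain_bp, summary.length_loss_bp,
                                    summary.length_loh_bp)
    out["kataegis_foci"] = pd.Series(kataegis)
    out["scna_gain_mb"] = pd.Series(gain) / 1e6
    out["scna_loss_mb"] = pd.Series(loss) / 1e6
    out["scna_loh_mb"] = pd.Series(loh) / 1e6
    out["chromothripsis"] = pd.Series(ct)
    out["bfb"] = pd.Series(bfb)
    return out


def cohort_comparison(cohort: Cohort, metrics: pd.DataFrame | None = None) -> pd.DataFrame:
    """The full two-group comparison table for a cohort."""
    if metrics is None:
        metrics = cohort_metrics(cohort)
    return compare_cohorts(metrics, cohort.manifest, binary_metrics=BINARY_METRICS)


@dataclass
class DetectionScore:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")


def score_kataegis(cohort: Cohort) -> DetectionScore:
    """Focus-level recall/precision of the kataegis detector vs planted truth.

    A detected focus is a true positive when it overlaps a planted focus on
    the same chromosome; planted foci with no overlapping detection are
    false negatives.
    """
    score = DetectionScore()
    for s in cohort.manifest.samples:
        foci = cat.detect_kataegis(cohort.snvs[s], cohort.genome_length)
        truth = cohort.truth[s].kataegis_foci
        matched: set[int] = set()
        for f in foci:
            hits = [i for i, t in enumerate(truth)
                    if t["chrom"] == f.chrom and t["start"] <= f.end and f.start <= t["end"]]
            if hits:
                matched.update(hits)
            else:
                score.fp += 1
        score.tp += len(matched)
        score.fn += len(truth) - len(matched)
    return score


def score_chromothripsis(cohort: Cohort) -> DetectionScore:
    """Chromosome-level sensitivity/specificity vs planted truth."""
    score = DetectionScore()
    for s in cohort.manifest.samples:
        calls = cat.detect_chromothripsis(cohort.svs[s], cohort.segments[s], cohort.genome)
        truth = set(cohort.truth[s].chromothripsis_chroms)
        for c in calls:
            if c.chrom in truth:
                score.tp += int(c.verdict)
                score.fn += int(not c.verdict)
            else:
                score.fp += int(c.verdict)
                score.tn += int(not c.verdict)
    return score


def score_bfb(cohort: Cohort) -> DetectionScore:
    """Arm-level sensitivity/specificity vs planted truth."""
    score = DetectionScore()
    for s in cohort.manifest.samples:
        calls = cat.detect_bfb(cohort.svs[s], cohort.segments[s], cohort.genome)
        truth = {(a["chrom"], a["arm"]) for a in cohort.truth[s].bfb_arms}
        for c in calls:
            if (c.chrom, c.arm) in truth:
                score.tp += int(c.verdict)
                score.fn += int(not c.verdict)
            else:
                score.fp += int(c.verdict)
                score.tn += int(not c.verdict)
    return score
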
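"""Trinucleotide substitution spectra.

Substitutions are collapsed so the mutated base is reported as A or C (the
purine-pyrimidine pair on the reference strand is read from whichever strand
puts an A or C in the middle). Six collapsed types — A>C, A>G, A>T, C>A, C>G,
C>T — times 16 flank combinations give 96 channels. This is the package's
native convention; :func:`to_cosmic_convention` gives the lossless permutation
to the pyrimidine (C/T-reference) convention used by published reference
signature tables, under which an A>C at an AA site reads as T>G at a TT site.

Channel order is fixed: type-major (A>C, A>G, A>T, C>A, C>G, C>T), then 5'
base A<C<G<T, then 3' base A<C<G<T. A sample-by-96 spectrum is carried as a
:class:`pandas.DataFrame` with channel-label columns in that order.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import BASES, COMPLEMENT, MutationRecord

_ORDER = "ACGT"

SIX_TYPES = ("A>C", "A>G", "A>T", "C>A", "C>G", "C>T")

_PYR_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


def _channel_label(five: str, ref: str, alt: str, three: str) -> str:
    return f"{five}[{ref}>{alt}]{three}"


def _make_channels(types: Sequence[str]) -> list[str]:
    out = []
    for t in types:
        ref, alt = t[0], t[2]
        for five in _ORDER:
            for three in _ORDER:
                out.append(_channel_label(five, ref, alt, three))
    return out


#: the 96 channels in the native (A/C-reference) convention, fixed order
NATIVE_CHANNELS: list[str] = _make_channels(SIX_TYPES)

#: the 96 channels in the pyrimidine (COSMIC) convention, fixed order
COSMIC_CHANNELS: list[str] = _make_channels(_PYR_TYPES)


def _revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def collapse_substitution(ref: str, alt: str, context: str) -> str:
    """Collapse a substitution onto its native A/C-reference channel label.

    Records with a G or T reference are reverse-complemented (ref, alt and
    context together), so every channel carries an A or C reference base.
    Ambiguous bases raise :class:`AmbiguousBaseError`, distinct from the
    ``ValueError`` raised for malformed input.
    """
    if any(b not in BASES for b in (ref, alt, *context)):
        raise AmbiguousBaseError(f"ambiguous or invalid base in {context} {ref}>{alt}")
    if len(context) != 3 or context[1] != ref or ref == alt:
        raise ValueError(f"inconsistent substitution {context} {ref}>{alt}")
    if ref in "GT":
        context = _revcomp(context)
        ref = COMPLEMENT[ref]
        alt = COMPLEMENT[alt]
    return _channel_label(context[0], ref, alt, context[2])


class AmbiguousBaseError(ValueError):
    """An N (or other non-ACGT) base where a concrete base is required."""


def build_spectrum(records: Iterable[MutationRecord],
                   samples: Sequence[str] | None = None) -> pd.DataFrame:
    """Tally mutation records into a samples x 96 count matrix (native order).

    ``samples`` fixes the row order (and includes zero-count samples); by
    default rows appear in first-encounter order.
    """
    counts: dict[str, Counter] = {}
    order: list[str] = list(samples) if samples is not None else []
    for rec in records:
        if rec.sample_id not in counts:
            counts[rec.sample_id] = Counter()
            if samples is None:
                order.append(rec.sample_id)
        counts[rec.sample_id][collapse_substitution(rec.ref, rec.alt, rec.context)] += 1
    mat = pd.DataFrame(0, index=order, columns=NATIVE_CHANNELS, dtype=int)
    for sample, ctr in counts.items():
        if sample not in mat.index:
            raise ValueError(f"sample {sample!r} not in declared sample list")
        for ch, n in ctr.items():
            mat.at[sample, ch] = n
    return mat


def _type_of(channel: str) -> str:
    return channel[2:5]


def six_type_proportions(spectrum: pd.DataFrame) -> pd.DataFrame:
    """Per-sample proportions of the six collapsed substitution types.

    Zero-mutation samples are excluded (with a warning); rows sum to 1.
    """
    import warnings

    type_of = np.array([_type_of(c) for c in spectrum.columns])
    counts = pd.DataFrame(
        {t: spectrum.loc[:, type_of == t].sum(axis=1) for t in SIX_TYPES}
    )
    totals = counts.sum(axis=1)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"excluding zero-mutation samples: {list(counts.index[zero])}",
            stacklevel=2,
        )
        counts = counts.loc[~zero]
        totals = totals.loc[~zero]
    return counts.div(totals, axis=0)


def axc_at_aa_fraction(spectrum: pd.DataFrame) -> pd.DataFrame:
    """Per-sample fractions of A>C transversions flanked by a 5' adenine.

    Returns a frame with columns ``overall`` — A[A>C]N mutations over all
    mutations — and ``of_axc`` — the same count over all A>C mutations (the
    conditional "flanked by a 5' adenine" fraction; NaN when the sample has
    no A>C mutations at all).
    """
    aa_cols = [c for c in spectrum.columns if c.startswith("A[A>C]")]
    axc_cols = [c for c in spectrum.columns if _type_of(c) == "A>C"]
    total = spectrum.sum(axis=1)
    aa = spectrum[aa_cols].sum(axis=1)
    axc = spectrum[axc_cols].sum(axis=1)
    overall = aa / total.where(total > 0)
    conditional = aa / axc.where(axc > 0)
    return pd.DataFrame({"overall": overall.fillna(0.0), "of_axc": conditional})


@dataclass(frozen=True)
class BurdenSummary:
    """Mutation counts per sample normalized to mutations per megabase."""

    sample_id: str
    n_mutations: int
    denominator_mb: float
    rate: float
    region_rates: dict[str, float] | None = None


#: default callable-genome denominator in Mb when none is supplied
DEFAULT_DENOMINATOR_MB = 2800.0


def mutation_burden(
    records: Iterable[MutationRecord],
    denominator_mb: float = DEFAULT_DENOMINATOR_MB,
    regions: Mapping[str, list[tuple[str, int, int]]] | None = None,
    region_mb: Mapping[str, float] | None = None,
    samples: Sequence[str] | None = None,
) -> list[BurdenSummary]:
    """Mutations per Mb per sample, optionally split by region class.

    ``regions`` maps a class label (e.g. ``exonic``) to 0-based half-open
    intervals ``(chrom, start, end)``; ``region_mb`` gives each class's
    denominator in Mb. Mutations outside every class count as
    ``unclassified`` (no rate, tallied only).
    """
    if denominator_mb <= 0:
        raise ValueError("denominator_mb must be positive")
    per_sample: dict[str, list[MutationRecord]] = {}
    order = list(samples) if samples is not None else []
    for rec in records:
        if rec.sample_id not in per_sample and samples is None:
            order.append(rec.sample_id)
        per_sample.setdefault(rec.sample_id, []).append(rec)
    out = []
    for sample in order:
        recs = per_sample.get(sample, [])
        n = len(recs)
        region_rates = None
        if regions is not None:
            if region_mb is None:
                raise ValueError("region_mb required when regions are supplied")
            counts = {label: 0 for label in regions}
            counts["unclassified"] = 0
            for rec in recs:
                hit = None
                for label, ivs in regions.items():
                    if any(c == rec.chrom and s < rec.pos <= e for c, s, e in ivs):
                        hit = label
                        break
                counts[hit if hit is not None else "unclassified"] += 1
            region_rates = {
                label: counts[label] / region_mb[label] for label in regions
            }
            region_rates["unclassified_count"] = float(counts["unclassified"])
        out.append(BurdenSummary(sample, n, denominator_mb, n / denominator_mb, region_rates))
    return out


def _native_to_cosmic_permutation() -> dict[str, str]:
    mapping = {}
    for ch in NATIVE_CHANNELS:
        five, ref, alt, three = ch[0], ch[2], ch[4], ch[6]
        if ref == "C":
            mapping[ch] = ch  # already pyrimidine
        else:  # ref == 'A': reverse complement to a T-reference channel
            mapping[ch] = _channel_label(
                COMPLEMENT[three], COMPLEMENT[ref], COMPLEMENT[alt], COMPLEMENT[five]
            )
    return mapping


NATIVE_TO_COSMIC: dict[str, str] = _native_to_cosmic_permutation()
COSMIC_TO_NATIVE: dict[str, str] = {v: k for k, v in NATIVE_TO_COSMIC.items()}


def to_cosmic_convention(spectrum: pd.DataFrame) -> pd.DataFrame:
    """Permute a native-convention spectrum into pyrimidine (COSMIC) channel order.

    Bijective relabeling: counts are conserved, A[A>C]A becomes T[T>G]T, and
    applying the inverse returns the original matrix.
    """
    if list(spectrum.columns) != NATIVE_CHANNELS:
        raise ValueError("spectrum is not in native channel order")
    renamed = spectrum.rename(columns=NATIVE_TO_COSMIC)
    return renamed[COSMIC_CHANNELS]


def to_native_convention(spectrum: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`to_cosmic_convention`."""
    if list(spectrum.columns) != COSMIC_CHANNELS:
        raise ValueError("spectrum is not in COSMIC channel order")
    renamed = spectrum.rename(columns=COSMIC_TO_NATIVE)
    return renamed[NATIVE_CHANNELS]
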
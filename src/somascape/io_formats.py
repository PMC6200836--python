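"""Readers and writers for the somatic call-set formats the pipeline consumes.

Coordinate conventions: VCF/MAF/SEG inputs are 1-based (SEG inclusive); internal
intervals are 0-based half-open; SNV and SV breakpoint positions stay 1-based.
All records are stored on the reference (+) strand — pyrimidine/purine collapsing
happens only in :mod:`somascape.spectrum`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

BASES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

SV_TYPES = ("DEL", "DUP", "INV", "TRA", "INS")


@dataclass(frozen=True)
class MutationRecord:
    """A somatic single-nucleotide variant with its reference-strand 3-mer context."""

    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    context: str

    def __post_init__(self) -> None:
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"non-ACGT allele {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref equals alt at {self.chrom}:{self.pos}")
        if len(self.context) != 3 or self.context[1] != self.ref:
            raise ValueError(
                f"context {self.context!r} inconsistent with ref {self.ref} "
                f"at {self.chrom}:{self.pos}"
            )
        if self.pos < 2:
            raise ValueError(f"position {self.pos} has no 5' flank")


@dataclass(frozen=True)
class CNSegment:
    """A copy-number segment; ``start``/``end`` are 0-based half-open."""

    sample_id: str
    chrom: str
    start: int
    end: int
    total_cn: float
    minor_cn: float | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty segment {self.chrom}:{self.start}-{self.end}")
        if self.total_cn < 0:
            raise ValueError("negative total_cn")
        if self.minor_cn is not None and self.minor_cn > self.total_cn + 1e-9:
            raise ValueError("minor_cn exceeds total_cn")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SVRecord:
    """A structural-variant breakpoint pair (1-based positions)."""

    sample_id: str
    chrom1: str
    pos1: int
    strand1: str
    chrom2: str
    pos2: int
    strand2: str
    svtype: str = "TRA"

    def __post_init__(self) -> None:
        if self.pos1 < 1 or self.pos2 < 1:
            raise ValueError("breakpoint positions must be >= 1")
        if self.chrom1 == self.chrom2 and self.pos1 > self.pos2:
            raise ValueError("intra-chromosomal SV must have pos1 <= pos2")
        if self.svtype not in SV_TYPES:
            raise ValueError(f"unknown svtype {self.svtype}")


@dataclass
class ParseLog:
    """Counters for records dropped while reading a variant file."""

    n_parsed: int = 0
    n_skipped_non_snv: int = 0
    n_rejected_context: int = 0
    n_skipped_filtered: int = 0


def fetch_context(genome, chrom: str, pos: int) -> str:
    """Return the uppercase reference 3-mer centered on 1-based ``pos``.

    ``genome`` is a :class:`pyfaidx.Fasta` (or any mapping of chrom -> sliceable
    sequence with a ``.seq``-free str result on slicing).
    """
    try:
        seq = genome[chrom]
    except KeyError as exc:
        raise ValueError(f"chromosome {chrom!r} missing from reference FASTA") from exc
    tri = seq[pos - 2 : pos + 1]
    tri = tri.seq if hasattr(tri, "seq") else str(tri)
    return tri.upper()


def _looks_like_vcf(path: Path) -> bool:
    with open(path) as fh:
        first = fh.readline()
    return first.startswith("##fileformat=VCF") or path.suffix == ".vcf"


def read_snvs(
    path: str | Path,
    genome,
    sample_id: str | None = None,
    log: ParseLog | None = None,
) -> list[MutationRecord]:
    """Read somatic SNVs from a VCF 4.x or a MAF-like TSV and fill 3-mer contexts.

    VCF: PASS (or unfiltered) biallelic SNVs; multi-allelic sites are split and
    each ALT considered separately; non-SNV alleles are skipped and counted.
    MAF-like TSV: tab-separated with columns ``sample chrom pos ref alt``.

    Records whose reference base disagrees with the FASTA middle base are
    rejected and counted, never silently dropped.
    """
    path = Path(path)
    log = log if log is not None else ParseLog()
    if _looks_like_vcf(path):
        records = _read_vcf(path, genome, sample_id or path.stem, log)
    else:
        records = _read_maf_like(path, genome, log)
    if log.n_skipped_non_snv or log.n_rejected_context:
        logger.info(
            "%s: %d SNVs, %d non-SNV skipped, %d context-mismatch rejected",
            path.name, log.n_parsed, log.n_skipped_non_snv, log.n_rejected_context,
        )
    return records


def _emit(sample, chrom, pos, ref, alt, genome, log) -> MutationRecord | None:
    ref, alt = ref.upper(), alt.upper()
    if len(ref) != 1 or len(alt) != 1 or ref not in BASES or alt not in BASES or ref == alt:
        log.n_skipped_non_snv += 1
        return None
    ctx = fetch_context(genome, chrom, pos)
    if len(ctx) != 3 or ctx[1] != ref or any(b not in BASES for b in ctx):
        log.n_rejected_context += 1
        return None
    log.n_parsed += 1
    return MutationRecord(sample, chrom, int(pos), ref, alt, ctx)


def _read_vcf(path: Path, genome, sample_id: str, log: ParseLog) -> list[MutationRecord]:
    from cyvcf2 import VCF

    out: list[MutationRecord] = []
    for var in VCF(str(path)):
        if var.FILTER is not None:  # None means PASS or '.'
            log.n_skipped_filtered += 1
            continue
        for alt in var.ALT:
            rec = _emit(sample_id, var.CHROM, var.POS, var.REF, alt, genome, log)
            if rec is not None:
                out.append(rec)
    return out


def _read_maf_like(path: Path, genome, log: ParseLog) -> list[MutationRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"sample", "chrom", "pos", "ref", "alt"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out: list[MutationRecord] = []
    for row in df.itertuples(index=False):
        rec = _emit(str(row.sample), str(row.chrom), int(row.pos),
                    str(row.ref), str(row.alt), genome, log)
        if rec is not None:
            out.append(rec)
    return out


def read_segments(path: str | Path) -> list[CNSegment]:
    """Read a SEG-like TSV (1-based inclusive) into 0-based half-open segments.

    Columns: ``sample chrom start end total_cn`` with optional ``minor_cn``.
    Segments are sorted per sample/chromosome and verified non-overlapping.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"sample", "chrom", "start", "end", "total_cn"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    has_minor = "minor_cn" in df.columns
    segs: list[CNSegment] = []
    for row in df.itertuples(index=False):
        minor = None
        if has_minor and pd.notna(row.minor_cn):
            minor = float(row.minor_cn)
        segs.append(
            CNSegment(str(row.sample), str(row.chrom), int(row.start) - 1,
                      int(row.end), float(row.total_cn), minor)
        )
    return sort_and_check_segments(segs)


def sort_and_check_segments(segs: Sequence[CNSegment]) -> list[CNSegment]:
    """Sort segments by (sample, chrom, start) and raise on the first overlap."""
    out = sorted(segs, key=lambda s: (s.sample_id, s.chrom, s.start))
    for a, b in zip(out, out[1:]):
        if a.sample_id == b.sample_id and a.chrom == b.chrom and b.start < a.end:
            raise ValueError(
                f"overlapping segments for {a.sample_id} {a.chrom}: "
                f"[{a.start},{a.end}) and [{b.start},{b.end})"
            )
    return out


def read_bedpe(path: str | Path, sample_id: str | None = None) -> list[SVRecord]:
    """Read SV breakpoint pairs from BEDPE.

    Breakpoint position = interval start + 1 (1-based). ``svtype`` is taken
    from the name column when it is a recognized type, else TRA for
    inter-chromosomal and DEL otherwise. A ``sample`` column 11+ overrides
    ``sample_id`` when present.
    """
    path = Path(path)
    records: list[SVRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: BEDPE needs >= 6 columns, got {len(fields)}")
            c1, s1, _e1, c2, s2, _e2 = fields[:6]
            name = fields[6] if len(fields) > 6 else "."
            strand1 = fields[8] if len(fields) > 8 else "."
            strand2 = fields[9] if len(fields) > 9 else "."
            sample = fields[10] if len(fields) > 10 else (sample_id or path.stem)
            svtype = name.upper() if name.upper() in SV_TYPES else None
            if svtype is None:
                svtype = "TRA" if c1 != c2 else "DEL"
            p1, p2 = int(s1) + 1, int(s2) + 1
            if c1 == c2 and p1 > p2:
                p1, p2 = p2, p1
                strand1, strand2 = strand2, strand1
            records.append(SVRecord(sample, c1, p1, strand1, c2, p2, strand2, svtype))
    return records


# ---------------------------------------------------------------------------
# package TSV dialect (round-trippable)

SNV_COLUMNS = ["sample", "chrom", "pos", "ref", "alt", "context"]


def write_snvs_tsv(records: Iterable[MutationRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.sample_id, r.chrom, r.pos, r.ref, r.alt, r.context) for r in records],
        columns=SNV_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_snvs_tsv(path: str | Path) -> list[MutationRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "context": str})
    return [
        MutationRecord(str(r.sample), str(r.chrom), int(r.pos), r.ref, r.alt, r.context)
        for r in df.itertuples(index=False)
    ]


def write_segments_tsv(segs: Iterable[CNSegment], path: str | Path) -> None:
    """Write segments in the SEG-like dialect (1-based inclusive coordinates)."""
    rows = [
        (s.sample_id, s.chrom, s.start + 1, s.end, s.total_cn,
         "" if s.minor_cn is None else s.minor_cn)
        for s in segs
    ]
    pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "total_cn", "minor_cn"]) \
        .to_csv(path, sep="\t", index=False)


def write_bedpe(svs: Iterable[SVRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in svs:
            fh.write(
                "\t".join(map(str, [
                    r.chrom1, r.pos1 - 1, r.pos1, r.chrom2, r.pos2 - 1, r.pos2,
                    r.svtype, ".", r.strand1, r.strand2, r.sample_id,
                ])) + "\n"
            )


@dataclass
class CohortManifest:
    """Sample -> group assignment with optional per-sample ploidy."""

    groups: dict[str, str] = field(default_factory=dict)
    ploidy: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.groups.values())) < 1 and self.groups:
            raise ValueError("manifest needs at least one group")

    @property
    def samples(self) -> list[str]:
        return list(self.groups)

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == group]

    @property
    def group_labels(self) -> list[str]:
        seen: list[str] = []
        for g in self.groups.values():
            if g not in seen:
                seen.append(g)
        return seen


def read_manifest(path: str | Path) -> CohortManifest:
    df = pd.read_csv(path, sep="\t")
    if not {"sample", "group"} <= set(df.columns):
        raise ValueError(f"{path}: manifest needs 'sample' and 'group' columns")
    if df["sample"].duplicated().any():
        raise ValueError("duplicate sample ids in manifest")
    ploidy = {}
    if "ploidy" in df.columns:
        ploidy = {
            str(r.sample): float(r.ploidy)
            for r in df.itertuples(index=False)
            if pd.notna(r.ploidy)
        }
    return CohortManifest({str(r.sample): str(r.group) for r in df.itertuples(index=False)}, ploidy)


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    rows = [
        (s, g, manifest.ploidy.get(s, ""))
        for s, g in manifest.groups.items()
    ]
    pd.DataFrame(rows, columns=["sample", "group", "ploidy"]).to_csv(path, sep="\t", index=False)
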
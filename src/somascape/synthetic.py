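"""Synthetic two-group tumor cohorts with planted ground truth.

The generator emulates the contrasts a comparative somatic-genome study
measures: per-group mutation burden (lognormal across samples), signature
composition (Dirichlet exposures over a configurable signature set, including
an A>C-at-AA-heavy profile present in only one group), kataegis foci,
chromothriptic chromosomes, breakage-fusion-bridge arms, background SVs, and
group-specific recurrent SCNA regions. Every planted feature is constructed
with a safety margin over the corresponding detector's thresholds, and the
full truth is returned alongside the data.

Mutations are placed by sampling, for each drawn 96-channel, uniformly among
the genome positions whose trinucleotide context matches that channel (a
position index is built once per genome), so every emitted record's context
matches its channel exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    COMPLEMENT,
    CNSegment,
    CohortManifest,
    MutationRecord,
    SVRecord,
    write_bedpe,
    write_manifest,
    write_segments_tsv,
)
from .spectrum import NATIVE_CHANNELS
from .signatures import load_reference_signatures

_BASE = "ACGT"
_ENC = {b: i for i, b in enumerate(_BASE)}


# ---------------------------------------------------------------------------
# genome


def genome_spec(name: str) -> dict[str, int]:
    """Named genome presets: ``mini`` (10 x 10 Mb) and ``toy-24`` (~3 Gb)."""
    if name == "mini":
        return {f"chr{i}": 10_000_000 for i in range(1, 11)}
    if name == "toy-24":
        mb = [249, 243, 198, 191, 181, 171, 159, 146, 141, 136, 135, 134,
              115, 107, 103, 90, 81, 78, 59, 63, 48, 51, 155, 59]
        names = [f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY"]
        return {n: m * 1_000_000 for n, m in zip(names, mb)}
    raise ValueError(f"unknown genome preset {name!r}")


def generate_reference(
    genome: Mapping[str, int], seed: int, gc_fraction: float = 0.41
) -> dict[str, np.ndarray]:
    """I.i.d. random reference sequences as base-code arrays (0..3 = ACGT).

    Base probabilities honor ``gc_fraction`` (C and G each get half of it).
    Deterministic per seed.
    """
    if not 0 <= gc_fraction <= 1:
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    at = (1 - gc_fraction) / 2
    gc = gc_fraction / 2
    p = [at, gc, gc, at]
    return {
        chrom: rng.choice(4, size=length, p=p).astype(np.uint8)
        for chrom, length in genome.items()
    }


def decode_seq(codes: np.ndarray) -> str:
    return "".join(_BASE[c] for c in codes)


def write_fasta(seqs: Mapping[str, np.ndarray], path: str | Path, width: int = 70) -> None:
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    with open(path, "wb") as fh:
        for chrom, codes in seqs.items():
            fh.write(f">{chrom}\n".encode())
            raw = lut[codes].tobytes()
            for i in range(0, len(raw), width):
                fh.write(raw[i : i + width] + b"\n")


class ContextIndex:
    """Per-genome index: collapsed trinucleotide context -> positions.

    The collapsed context reads the strand that puts A or C in the middle, so
    it matches the native channel convention directly. Positions are 0-based
    indices of the middle base.
    """

    def __init__(self, seqs: Mapping[str, np.ndarray]):
        self.chroms = list(seqs)
        self._positions: dict[int, list[tuple[str, np.ndarray]]] = {}
        self._totals: dict[int, int] = {}
        for chrom, codes in seqs.items():
            c = codes.astype(np.int16)
            left, mid, right = c[:-2], c[1:-1], c[2:]
            raw = left * 16 + mid * 4 + right
            flipped = (3 - right) * 16 + (3 - mid) * 4 + (3 - left)
            collapsed = np.where(mid >= 2, flipped, raw)
            for code in np.unique(collapsed):
                pos = np.flatnonzero(collapsed == code).astype(np.int64) + 1
                self._positions.setdefault(int(code), []).append((chrom, pos))
                self._totals[int(code)] = self._totals.get(int(code), 0) + len(pos)

    @staticmethod
    def channel_code(channel: str) -> int:
        five, ref, three = channel[0], channel[2], channel[6]
        return _ENC[five] * 16 + _ENC[ref] * 4 + _ENC[three]

    def count(self, channel: str) -> int:
        return self._totals.get(self.channel_code(channel), 0)

    def sample_positions(
        self, channel: str, m: int, rng: np.random.Generator
    ) -> list[tuple[str, int]]:
        """Draw ``m`` positions (with replacement) matching ``channel``."""
        code = self.channel_code(channel)
        if code not in self._positions:
            raise ValueError(f"no genome position matches channel {channel!r}")
        blocks = self._positions[code]
        sizes = np.array([len(p) for _, p in blocks])
        cum = np.cumsum(sizes)
        draws = rng.integers(0, cum[-1], size=m)
        which = np.searchsorted(cum, draws, side="right")
        offsets = draws - np.concatenate([[0], cum[:-1]])[which]
        return [
            (blocks[b][0], int(blocks[b][1][o])) for b, o in zip(which, offsets)
        ]


# ---------------------------------------------------------------------------
# configuration


@dataclass
class GroupConfig:
    """Generative settings for one cohort group."""

    n_samples: int
    burden_log_mean: float  # natural log of mutations/Mb
    burden_log_sd: float
    signatures: list[str]  # names in the reference catalogue
    exposure_alpha: list[float]  # Dirichlet concentration per signature
    kataegis_mean: float = 0.0  # Poisson mean planted foci per sample
    chromothripsis_prob: float = 0.0
    bfb_prob: float = 0.0
    background_sv_mean: float = 10.0
    cn_baseline: float = 2.0
    scna_regions: list[tuple[str, int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 <= self.chromothripsis_prob <= 1 or not 0 <= self.bfb_prob <= 1:
            raise ValueError("event probabilities must be in [0, 1]")
        if self.kataegis_mean < 0 or self.background_sv_mean < 0:
            raise ValueError("rates must be non-negative")
        if len(self.signatures) != len(self.exposure_alpha):
            raise ValueError("one Dirichlet alpha per signature required")


@dataclass
class SimulationConfig:
    seed: int
    genome: str | dict[str, int] = "mini"
    groups: dict[str, GroupConfig] = field(default_factory=dict)
    gc_fraction: float = 0.41
    signature_table: pd.DataFrame | None = None  # native convention; packaged set if None
    chromothripsis_pool: list[str] = field(default_factory=lambda: ["chr5", "chr6"])
    bfb_pool: list[str] = field(default_factory=lambda: ["chr7", "chr8"])

    def genome_dict(self) -> dict[str, int]:
        return genome_spec(self.genome) if isinstance(self.genome, str) else dict(self.genome)


def eac_contrast_config(seed: int) -> SimulationConfig:
    """Two-group preset mirroring a low-burden vs high-burden EAC contrast.

    Group A ("low"): 10 samples, median ~2.5 mutations/Mb, no A>C-heavy
    signature, no chromothripsis. Group B ("high"): 16 samples, median ~10
    mutations/Mb, S17-like exposure with Dirichlet mean 0.3, chromothripsis
    probability 0.3, more kataegis and BFB. Group-specific recurrent SCNA
    regions are disjoint.
    """
    low = GroupConfig(
        n_samples=10,
        burden_log_mean=float(np.log(2.5)),
        burden_log_sd=0.5,
        signatures=["S1", "S3", "U2"],
        exposure_alpha=[5.0, 3.0, 2.0],
        kataegis_mean=0.5,
        chromothripsis_prob=0.0,
        bfb_prob=0.1,
        background_sv_mean=10.0,
        scna_regions=[("chr1", 2_000_000, 4_000_000, "amp"),
                      ("chr2", 2_000_000, 4_000_000, "del")],
    )
    high = GroupConfig(
        n_samples=16,
        burden_log_mean=float(np.log(10.0)),
        burden_log_sd=0.5,
        signatures=["S1", "S3", "S17", "U2"],
        exposure_alpha=[3.0, 2.0, 3.0, 2.0],  # mean S17 exposure = 0.3
        kataegis_mean=3.0,
        chromothripsis_prob=0.3,
        bfb_prob=0.375,
        background_sv_mean=25.0,
        scna_regions=[("chr3", 2_000_000, 4_000_000, "amp"),
                      ("chr4", 2_000_000, 4_000_000, "del")],
    )
    return SimulationConfig(seed=seed, genome="mini", groups={"low": low, "high": high})


# ---------------------------------------------------------------------------
# truth bookkeeping


@dataclass
class SampleTruth:
    group: str
    exposures: dict[str, float]
    n_background_snvs: int = 0
    kataegis_foci: list[dict] = field(default_factory=list)
    chromothripsis_chroms: list[str] = field(default_factory=list)
    bfb_arms: list[dict] = field(default_factory=list)
    scna_regions: list[dict] = field(default_factory=list)


@dataclass
class Cohort:
    config: SimulationConfig
    genome: dict[str, int]
    seqs: dict[str, np.ndarray]
    index: ContextIndex
    manifest: CohortManifest
    snvs: dict[str, list[MutationRecord]]
    segments: dict[str, list[CNSegment]]
    svs: dict[str, list[SVRecord]]
    truth: dict[str, SampleTruth]

    @property
    def genome_length(self) -> int:
        return sum(self.genome.values())

    def all_snvs(self) -> list[MutationRecord]:
        return [r for recs in self.snvs.values() for r in recs]

    def truth_json(self) -> str:
        payload = {s: asdict(t) for s, t in sorted(self.truth.items())}
        return json.dumps(payload, sort_keys=True, indent=1)


# ---------------------------------------------------------------------------
# mutation simulation


def _record_at(seqs, chrom: str, pos0: int, alt_collapsed: str,
               sample: str) -> MutationRecord:
    """Emit the reference-strand record for a collapsed-channel draw at a
    0-based middle position."""
    codes = seqs[chrom]
    tri = decode_seq(codes[pos0 - 1 : pos0 + 2])
    ref = tri[1]
    alt = alt_collapsed if ref in "AC" else COMPLEMENT[alt_collapsed]
    return MutationRecord(sample, chrom, pos0 + 1, ref, alt, tri)


def simulate_mutations(
    sample_id: str,
    group: GroupConfig,
    profiles: pd.DataFrame,
    index: ContextIndex,
    seqs: Mapping[str, np.ndarray],
    genome_mb: float,
    rng: np.random.Generator,
) -> tuple[list[MutationRecord], dict[str, float]]:
    """Draw one sample's background SNVs from its signature mixture.

    Exposures come from the group's Dirichlet; the total count from the
    lognormal burden times the genome size; channels from the
    exposure-weighted mixture; positions uniformly among context-matching
    genome sites (duplicate positions are dropped).
    """
    alpha = np.asarray(group.exposure_alpha, dtype=float)
    exposures = rng.dirichlet(alpha)
    rate = float(rng.lognormal(group.burden_log_mean, group.burden_log_sd))
    total = int(round(rate * genome_mb))
    mix = exposures @ profiles.loc[group.signatures].to_numpy()
    mix = mix / mix.sum()
    records: dict[tuple[str, int], MutationRecord] = {}
    if total > 0:
        channel_counts = rng.multinomial(total, mix)
        for ch, m in zip(NATIVE_CHANNELS, channel_counts):
            if m == 0:
                continue
            alt = ch[4]
            for chrom, pos0 in index.sample_positions(ch, int(m), rng):
                records[(chrom, pos0 + 1)] = _record_at(seqs, chrom, pos0, alt, sample_id)
    recs = sorted(records.values(), key=lambda r: (r.chrom, r.pos))
    return recs, dict(zip(group.signatures, map(float, exposures)))


def plant_kataegis(
    sample_id: str,
    records: list[MutationRecord],
    seqs: Mapping[str, np.ndarray],
    genome: Mapping[str, int],
    n_foci: int,
    rng: np.random.Generator,
    min_hyperscore_margin: float = 15.0,
) -> tuple[list[MutationRecord], list[dict]]:
    """Append ``n_foci`` tight SNV clusters, each 6-12 SNVs with adjacent
    gaps in [50, 1500) bp, re-drawn until the hyperscore clears the detection
    threshold with margin. Returns the augmented (sorted, deduplicated)
    records and the truth foci."""
    genome_length = sum(genome.values())
    chroms = list(genome)
    truth: list[dict] = []
    planted: list[MutationRecord] = []
    used: list[tuple[str, int, int]] = []
    m_after = len(records) + 9 * n_foci  # approximate final total for the margin check
    for _ in range(n_foci):
        for _attempt in range(100):
            chrom = chroms[int(rng.integers(len(chroms)))]
            n = int(rng.integers(6, 13))
            gaps = rng.integers(50, 1500, size=n - 1)
            span = int(gaps.sum())
            start = int(rng.integers(2, genome[chrom] - span - 2))
            end = start + span
            if any(c == chrom and s - 5000 < end and start < e + 5000 for c, s, e in used):
                continue
            rate = max(m_after, 1) / genome_length
            hyperscore = (n / max(span, 1)) / rate
            if hyperscore <= min_hyperscore_margin:
                continue
            positions = start + np.concatenate([[0], np.cumsum(gaps)])
            focus_recs = []
            for pos in positions:
                tri = decode_seq(seqs[chrom][pos - 2 : pos + 1])
                ref = tri[1]
                alt = _BASE[(int(_ENC[ref]) + int(rng.integers(1, 4))) % 4]
                focus_recs.append(MutationRecord(sample_id, chrom, int(pos), ref, alt, tri))
            planted.extend(focus_recs)
            used.append((chrom, start, end))
            truth.append({
                "chrom": chrom, "start": int(positions[0]), "end": int(positions[-1]),
                "n_snvs": n, "positions": [int(p) for p in positions],
            })
            break
        else:
            raise RuntimeError("could not place kataegis focus")
    merged: dict[tuple[str, int], MutationRecord] = {
        (r.chrom, r.pos): r for r in records
    }
    for r in planted:  # planted records win position collisions
        merged[(r.chrom, r.pos)] = r
    out = sorted(merged.values(), key=lambda r: (r.chrom, r.pos))
    return out, truth


# ---------------------------------------------------------------------------
# CN / SV simulation


def _fill_baseline(sample: str, chrom: str, lo: int, hi: int, baseline: float,
                   rng: np.random.Generator) -> list[CNSegment]:
    """Partition [lo, hi) into baseline-state segments with lognormal lengths."""
    segs = []
    pos = lo
    while pos < hi:
        length = int(min(max(rng.lognormal(np.log(2e6), 0.6), 100_000), hi - pos))
        segs.append(CNSegment(sample, chrom, pos, pos + length, baseline, baseline / 2))
        pos += length
    return segs


def simulate_cn_and_sv(
    sample_id: str,
    group: GroupConfig,
    genome: Mapping[str, int],
    rng: np.random.Generator,
    chromothripsis_pool: Sequence[str],
    bfb_pool: Sequence[str],
    truth: SampleTruth,
) -> tuple[list[CNSegment], list[SVRecord]]:
    """One sample's CN segments and SV breakpoints with planted catastrophes.

    A chromothriptic chromosome carries 40-80 breakpoints confined to a
    random 20% window plus a 16-segment two-state copy-number oscillation
    (15 switches). A BFB q-arm carries a terminal 1-Mb segment at
    baseline - 1 (floored at 0), an amplified segment at baseline + 4 within
    10 Mb, and 30 breakpoints confined to a 1.2-Mb window beside the
    amplification. Background SVs are uniform.
    """
    baseline = group.cn_baseline
    segments: list[CNSegment] = []
    svs: list[SVRecord] = []

    ct_chrom = None
    if rng.random() < group.chromothripsis_prob:
        ct_chrom = chromothripsis_pool[int(rng.integers(len(chromothripsis_pool)))]
        truth.chromothripsis_chroms.append(ct_chrom)
    bfb_chrom = None
    if rng.random() < group.bfb_prob:
        bfb_chrom = bfb_pool[int(rng.integers(len(bfb_pool)))]
        truth.bfb_arms.append({"chrom": bfb_chrom, "arm": "q"})

    region_by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for chrom, start, end, tag in group.scna_regions:
        region_by_chrom.setdefault(chrom, []).append((start, end, tag))
        truth.scna_regions.append({"chrom": chrom, "start": start, "end": end, "tag": tag})

    for chrom, length in genome.items():
        events: list[CNSegment] = []
        if chrom == ct_chrom:
            window = int(0.2 * length)
            w_start = int(rng.integers(1_000_000, length - window - 1_000_000))
            edges = np.linspace(w_start, w_start + window, 17).astype(int)
            for i in range(16):
                state = baseline if i % 2 == 0 else baseline + 1
                events.append(CNSegment(sample_id, chrom, int(edges[i]),
                                        int(edges[i + 1]), state, baseline / 2))
            nb = int(rng.integers(40, 81))
            positions = np.sort(rng.integers(w_start, w_start + window, size=nb))
            for i in range(0, nb - 1, 2):
                p1, p2 = int(positions[i]) + 1, int(positions[i + 1]) + 1
                svs.append(SVRecord(sample_id, chrom, p1, "+", chrom, max(p2, p1 + 1), "-", "DEL"))
        if chrom == bfb_chrom:
            tel_cn = max(baseline - 1.0, 0.0)
            events.append(CNSegment(sample_id, chrom, length - 1_000_000, length, tel_cn, 0.0))
            events.append(CNSegment(sample_id, chrom, length - 4_000_000,
                                    length - 2_000_000, baseline + 4, 1.0))
            positions = np.sort(rng.integers(length - 2_200_000, length - 1_000_000, size=30))
            for i in range(0, 29, 2):
                p1, p2 = int(positions[i]) + 1, int(positions[i + 1]) + 1
                svs.append(SVRecord(sample_id, chrom, p1, "+", chrom, max(p2, p1 + 1), "-", "DEL"))
        for start, end, tag in region_by_chrom.get(chrom, []):
            if tag == "amp":
                events.append(CNSegment(sample_id, chrom, start, end, baseline + 1, 1.0))
            else:
                events.append(CNSegment(sample_id, chrom, start, end,
                                        max(baseline - 1.0, 0.0), 0.0))
        events.sort(key=lambda s: s.start)
        for a, b in zip(events, events[1:]):
            if b.start < a.end:
                raise ValueError(f"planted events overlap on {chrom}")
        pos = 0
        for ev in events:
            if ev.start > pos:
                segments.extend(_fill_baseline(sample_id, chrom, pos, ev.start, baseline, rng))
            segments.append(ev)
            pos = ev.end
        if pos < length:
            segments.extend(_fill_baseline(sample_id, chrom, pos, length, baseline, rng))

    chroms = list(genome)
    n_bg = int(rng.poisson(group.background_sv_mean))
    for _ in range(n_bg):
        if rng.random() < 0.2 and len(chroms) > 1:
            c1, c2 = rng.choice(len(chroms), size=2, replace=False)
            svs.append(SVRecord(
                sample_id, chroms[c1], int(rng.integers(1, genome[chroms[c1]])), "+",
                chroms[c2], int(rng.integers(1, genome[chroms[c2]])), "-", "TRA"))
        else:
            chrom = chroms[int(rng.integers(len(chroms)))]
            span = int(min(max(rng.lognormal(np.log(1e5), 1.0), 100), genome[chrom] / 2))
            p1 = int(rng.integers(1, genome[chrom] - span))
            svs.append(SVRecord(sample_id, chrom, p1, "+", chrom, p1 + span, "-", "DEL"))
    return segments, svs


# ---------------------------------------------------------------------------
# cohort orchestration


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Generate a full two-group cohort with ground truth, in memory.

    Deterministic per ``config.seed``: the genome, every sample's mutations,
    segments, SVs, and the truth table are all drawn from one seeded stream.
    """
    genome = config.genome_dict()
    rng = np.random.default_rng(config.seed)
    seqs = generate_reference(genome, int(rng.integers(2**31 - 1)), config.gc_fraction)
    index = ContextIndex(seqs)
    if config.signature_table is not None:
        profiles = config.signature_table
    else:
        profiles = load_reference_signatures(convention="native")
    genome_mb = sum(genome.values()) / 1e6

    groups_map: dict[str, str] = {}
    snvs: dict[str, list[MutationRecord]] = {}
    segments: dict[str, list[CNSegment]] = {}
    svs: dict[str, list[SVRecord]] = {}
    truth: dict[str, SampleTruth] = {}
    for group_name, gcfg in config.groups.items():
        missing = set(gcfg.signatures) - set(profiles.index)
        if missing:
            raise ValueError(f"unknown signatures {sorted(missing)} in group {group_name}")
        for i in range(gcfg.n_samples):
            sample = f"{group_name}_{i + 1:02d}"
            groups_map[sample] = group_name
            srng = np.random.default_rng(int(rng.integers(2**31 - 1)))
            recs, exposures = simulate_mutations(
                sample, gcfg, profiles, index, seqs, genome_mb, srng)
            st = SampleTruth(group=group_name, exposures=exposures,
                            n_background_snvs=len(recs))
            n_foci = int(srng.poisson(gcfg.kataegis_mean))
            if n_foci:
                recs, foci = plant_kataegis(sample, recs, seqs, genome, n_foci, srng)
                st.kataegis_foci = foci
            segs, sample_svs = simulate_cn_and_sv(
                sample, gcfg, genome, srng,
                config.chromothripsis_pool, config.bfb_pool, st)
            snvs[sample] = recs
            segments[sample] = segs
            svs[sample] = sample_svs
            truth[sample] = st
    manifest = CohortManifest(groups_map,
                              {s: config.groups[g].cn_baseline for s, g in groups_map.items()})
    return Cohort(config, genome, seqs, index, manifest, snvs, segments, svs, truth)


def _write_vcf(records: Sequence[MutationRecord], genome: Mapping[str, int],
               path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in genome.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in records:
            fh.write(f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t.\n")


def generate_cohort(config: SimulationConfig, outdir: str | Path,
                    force: bool = False) -> Cohort:
    """Simulate a cohort and write the on-disk bundle.

    Layout: ``genome.fa`` (+ ``.fai``), ``snvs/<sample>.vcf``,
    ``segments.seg.tsv``, ``svs.bedpe``, ``manifest.tsv``, ``truth.json``.
    Refuses to write into an existing non-empty directory unless ``force``.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} exists and is not empty (use force=True)")
    cohort = simulate_cohort(config)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(cohort.seqs, outdir / "genome.fa")
    import pyfaidx

    pyfaidx.Faidx(str(outdir / "genome.fa"))
    snv_dir = outdir / "snvs"
    snv_dir.mkdir(exist_ok=True)
    for sample, recs in cohort.snvs.items():
        _write_vcf(recs, cohort.genome, snv_dir / f"{sample}.vcf")
    write_segments_tsv(
        [s for segs in cohort.segments.values() for s in segs],
        outdir / "segments.seg.tsv")
    write_bedpe([v for recs in cohort.svs.values() for v in recs], outdir / "svs.bedpe")
    write_manifest(cohort.manifest, outdir / "manifest.tsv")
    (outdir / "truth.json").write_text(cohort.truth_json())
    lengths = pd.DataFrame(cohort.genome.items(), columns=["chrom", "length"])
    lengths.to_csv(outdir / "chrom_lengths.tsv", sep="\t", index=False)
    return cohort
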
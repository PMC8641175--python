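"""Synthetic long-read deletion benchmark.

Generates a random reference, implants non-overlapping deletions, and
emits pre-aligned long reads whose CIGARs are constructed exactly from
the known donor-to-reference mapping: a read spanning an implanted
deletion carries a D operation of the true size at the true location.
Sequencing noise is emulated by spurious small D operations (1–30 bp by
default) and base mismatches at configurable rates.  Because alignments
are constructed rather than produced by an aligner, every downstream
expectation is exact and the whole pipeline is testable without
downloads; an optional FASTQ export supports real-aligner integration.

Reads are drawn uniformly along the donor (deletion-applied) genome at a
target coverage, with log-uniform lengths (default 1–20 kb).  Deletions
are homozygous by default; heterozygous mode routes half the reads
through the unmodified reference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import ConfigError, SimulationConfig
from .features import partition_reference
from .labels import TruthDeletion, WindowLabel, label_windows

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulatedTruth:
    """Ground truth of one simulated genome."""

    contig: str
    reference_length: int
    deletions: list[TruthDeletion]
    window_labels: list[WindowLabel]
    reference: str = ""
    read_records: list[dict] = field(default_factory=list)


def _random_sequence(rng, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def simulate_genome(cfg: SimulationConfig) -> SimulatedTruth:
    """Random reference plus implanted, well-separated deletions.

    Deletion sizes are uniform in ``deletion_size_range``; positions are
    uniform subject to a minimum separation of two window sizes between
    deletions (and from the contig ends), so no window ever overlaps two
    deletions.
    """
    rng = np.random.default_rng(cfg.seed)
    sizes = rng.integers(cfg.deletion_size_range[0],
                         cfg.deletion_size_range[1] + 1,
                         size=cfg.n_deletions)
    spacing = 2 * cfg.window_size
    slack = cfg.genome_length - int(sizes.sum()) - spacing * (cfg.n_deletions + 1)
    if slack < 0:
        raise ConfigError(
            f"cannot place {cfg.n_deletions} deletions totalling "
            f"{int(sizes.sum())} bp with {spacing} bp spacing in a "
            f"{cfg.genome_length} bp genome")
    offsets = np.sort(rng.integers(0, slack + 1, size=cfg.n_deletions))
    deletions = []
    consumed = 0
    for i, size in enumerate(sizes):
        start = spacing * (i + 1) + consumed + int(offsets[i])
        deletions.append(TruthDeletion(cfg.contig, start, int(size)))
        consumed += int(size)
    reference = _random_sequence(rng, cfg.genome_length)
    windows = partition_reference({cfg.contig: cfg.genome_length},
                                  cfg.window_size)
    labels = label_windows(windows, deletions)
    return SimulatedTruth(cfg.contig, cfg.genome_length, deletions, labels,
                          reference.tobytes().decode())


def _build_cigar(hap_start: int, hap_len: int,
                 events: list[tuple[int, int, int]]) -> list[tuple[int, int]]:
    """CIGAR from deletion events along one haplotype span.

    ``events`` are ``(hap_pos, hap_skip, d_size)`` sorted by position:
    an implanted deletion is a zero-width point in the donor haplotype
    (``hap_skip == 0``) whose D size is the excised reference length; a
    noise deletion drops ``hap_skip == d_size`` haplotype bases from the
    read (the read is shorter, the reference span is unchanged).
    """
    cigar = []
    cur = hap_start
    for pos, skip, d_size in events:
        if pos > cur:
            cigar.append((0, pos - cur))  # M
        cigar.append((2, d_size))  # D
        cur = pos + skip
    end = hap_start + hap_len
    if end > cur:
        cigar.append((0, end - cur))
    return cigar


def simulate_alignments(cfg: SimulationConfig, truth: SimulatedTruth,
                        out_path: str | Path, sort_and_index: bool = True,
                        fastq_path: str | Path | None = None) -> Path:
    """Write simulated reads as a coordinate-sorted alignment file.

    ``out_path`` ending in .bam produces a sorted, indexed BAM; .sam
    produces a coordinate-sorted SAM (no index).  Returns the path.
    """
    import pysam

    rng = np.random.default_rng(cfg.seed + 1)
    dels = sorted(truth.deletions, key=lambda d: d.start)
    ref = np.frombuffer(truth.reference.encode(), dtype=np.uint8)
    # donor genome: reference with deletions excised
    keep = np.ones(truth.reference_length, dtype=bool)
    for d in dels:
        keep[d.start:d.end] = False
    donor = ref[keep]
    donor_len = len(donor)
    # donor coordinate at which each deletion sits, and cumulative excised bp
    donor_points = []
    removed = 0
    for d in dels:
        donor_points.append(d.start - removed)
        removed += d.size
    donor_points = np.asarray(donor_points, dtype=np.int64)
    del_sizes = np.asarray([d.size for d in dels], dtype=np.int64)
    cum_sizes = np.concatenate([[0], np.cumsum(del_sizes)])

    target_bases = cfg.coverage * donor_len
    lo, hi = cfg.read_length_range
    reads = []
    total = 0
    read_records = []
    i = 0
    while total < target_bases:
        length = int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
        length = min(max(length, 1), donor_len)
        from_reference = cfg.heterozygous and rng.random() < 0.5
        hap_len = truth.reference_length if from_reference else donor_len
        length = min(length, hap_len)
        start = int(rng.integers(0, hap_len - length + 1))
        total += length

        hap = ref if from_reference else donor
        events = []  # (hap_pos, hap_skip, d_size, kind)
        if from_reference:
            ref_start = start
        else:
            # implanted deletions strictly inside the read span become D ops
            n_before = int(np.searchsorted(donor_points, start, side="right"))
            ref_start = start + int(cum_sizes[n_before])
            inside = np.flatnonzero((donor_points > start) &
                                    (donor_points < start + length))
            for di in inside:
                events.append((int(donor_points[di]), 0,
                               int(del_sizes[di]), "implanted"))

        # spurious small deletions: the read loses hap bases, the reference
        # span is unchanged, so true deletion coordinates stay anchored
        n_noise = rng.binomial(length, cfg.noise_deletion_rate)
        for _ in range(n_noise):
            size = int(rng.integers(cfg.noise_deletion_size_range[0],
                                    cfg.noise_deletion_size_range[1] + 1))
            if length - size < 3:
                continue
            for _attempt in range(5):
                p = int(rng.integers(start + 1, start + length - size))
                if all(p + size <= e[0] or p >= e[0] + e[1] + 1
                       for e in events):
                    events.append((p, size, size, "noise"))
                    break
        events.sort(key=lambda e: e[0])
        cigar = _build_cigar(start, length, [e[:3] for e in events])

        # read sequence: haplotype bases minus the noise-dropped intervals
        keep_mask = np.ones(length, dtype=bool)
        for pos, skip, _, _ in events:
            if skip:
                keep_mask[pos - start:pos - start + skip] = False
        seq = hap[start:start + length][keep_mask].copy()

        # base mismatches (CIGAR M covers both matches and mismatches)
        n_mm = rng.binomial(len(seq), cfg.mismatch_rate)
        if n_mm:
            pos = rng.integers(0, len(seq), size=n_mm)
            seq[pos] = _BASES[(np.searchsorted(_BASES, seq[pos]) +
                               rng.integers(1, 4, size=n_mm)) % 4]

        name = f"read{i:06d}"
        reads.append((ref_start, name, cigar, seq.tobytes().decode()))
        read_records.append({
            "read": name, "reference_start": ref_start, "length": length,
            "haplotype": "reference" if from_reference else "donor",
            "implanted": [(e[0], e[2]) for e in events if e[3] == "implanted"],
            "noise": [(e[0], e[2]) for e in events if e[3] == "noise"]})
        i += 1

    truth.read_records = read_records
    reads.sort(key=lambda r: r[0])

    out_path = Path(out_path)
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": truth.contig, "LN": truth.reference_length}]}
    is_bam = out_path.suffix == ".bam"
    mode = "wb" if is_bam else "w"
    with pysam.AlignmentFile(str(out_path), mode, header=header) as af:
        for ref_start, name, cigar, seq in reads:
            a = pysam.AlignedSegment(af.header)
            a.query_name = name
            a.reference_id = 0
            a.reference_start = ref_start
            a.mapping_quality = 60
            a.cigartuples = cigar
            a.query_sequence = seq
            a.flag = 0
            af.write(a)
    if is_bam and sort_and_index:
        pysam.index(str(out_path))
    if fastq_path is not None:
        with open(fastq_path, "w") as fq:
            for _, name, _, seq in reads:
                fq.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
    return out_path


def write_reference_fasta(truth: SimulatedTruth, path: str | Path,
                          width: int = 80) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f">{truth.contig}\n")
        for i in range(0, len(truth.reference), width):
            fh.write(truth.reference[i:i + width] + "\n")
    return path


def write_truth_vcf(truth: SimulatedTruth, path: str | Path) -> Path:
    """Truth deletions as symbolic <DEL> VCF (same convention as the caller)."""
    from .caller import CandidateRegion, DeletionCall, write_vcf

    calls = [DeletionCall(d.contig, d.start, d.size, 0,
                          CandidateRegion(d.contig, d.start, d.end, 1))
             for d in truth.deletions]
    return write_vcf(calls, {truth.contig: truth.reference_length}, path,
                     min_report_size=1, sample="TRUTH")


def write_truth_bed(truth: SimulatedTruth, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for d in truth.deletions:
            fh.write(f"{d.contig}\t{d.start}\t{d.end}\n")
    return path


def simulate_split(cfg: SimulationConfig, out_dir: str | Path,
                   name: str = "sim", n: int = 18, T: int = 100,
                   write_fasta: bool = False) -> dict:
    """Simulate one genome end-to-end: BAM, truth files, feature container.

    Returns a dict with paths, the truth object, and labeled RegionBatches
    ready for training or evaluation.
    """
    from .features import (extract_region_matrices, make_batches,
                           save_feature_container)

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth = simulate_genome(cfg)
    bam = simulate_alignments(cfg, truth, out_dir / f"{name}.bam")
    vcf = write_truth_vcf(truth, out_dir / f"{name}.truth.vcf")
    bed = write_truth_bed(truth, out_dir / f"{name}.truth.bed")
    fasta = write_reference_fasta(truth, out_dir / f"{name}.fa") \
        if write_fasta else None
    matrices = list(extract_region_matrices(bam, cfg.contig,
                                            truth.reference_length,
                                            cfg.window_size, n))
    labels = np.asarray([wl.label for wl in truth.window_labels],
                        dtype=np.int8)
    container = save_feature_container(out_dir / f"{name}.features", cfg.contig,
                                       matrices, cfg.window_size, n, T, labels)
    batches = build_labeled_batches(matrices, labels, T)
    manifest = {"name": name, "config": cfg.to_dict(),
                "n_reads": len(truth.read_records),
                "n_windows": len(matrices),
                "n_positive_windows": int(labels.sum()),
                "paths": {"bam": str(bam), "truth_vcf": str(vcf),
                          "truth_bed": str(bed),
                          "features": str(container),
                          "fasta": str(fasta) if fasta else None}}
    (out_dir / f"{name}.manifest.json").write_text(json.dumps(manifest, indent=1))
    return {"truth": truth, "batches": batches, "matrices": matrices,
            "labels": labels, "bam": bam, "vcf": vcf, "bed": bed,
            "manifest": manifest, "dir": out_dir}


def build_labeled_batches(matrices, labels, T: int = 100):
    """Attach per-window labels to batched matrices (padding labelled 0)."""
    from .features import make_batches

    batches = make_batches(matrices, T)
    labels = np.asarray(labels, dtype=np.float32)
    for b in batches:
        lab = np.zeros(b.mask.shape[0], dtype=np.float32)
        idx = [r.index for r in b.regions]
        lab[:len(idx)] = labels[idx]
        b.labels = lab
    return batches


def make_dataset(cfg_train: SimulationConfig, cfg_val: SimulationConfig,
                 cfg_test: SimulationConfig, out_dir: str | Path,
                 n: int = 18, T: int = 100) -> dict:
    """Three disjoint simulated genomes (train/validation/test).

    Seeds should differ between splits; identical seeds are allowed but
    warned about, since they defeat the held-out design.
    """
    import warnings

    seeds = [cfg_train.seed, cfg_val.seed, cfg_test.seed]
    if len(set(seeds)) < 3:
        warnings.warn("simulation seeds overlap across splits; the "
                      "validation/test genomes will not be independent")
    out_dir = Path(out_dir)
    return {split: simulate_split(cfg, out_dir, name=split, n=n, T=T)
            for split, cfg in (("train", cfg_train), ("val", cfg_val),
                               ("test", cfg_test))}
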
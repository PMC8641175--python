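"""From per-window probabilities to refined deletion calls.

Windows scoring above the cutoff (strictly greater than 0.5 by default)
are merged into candidate regions when index-consecutive.  Within each
region, every D operation longer than 20 bp in an overlapping read yields
a (location, size) signature; signatures are clustered on location with a
40 bp linkage radius, the largest cluster wins, and its mean location and
size (rounded half-up) become the call.  A region with no qualifying
signatures falls back to the region bounds, flagged IMPRECISE.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .config import AlignmentFilter
from .features import SubRegion, deletion_intervals


@dataclass
class CandidateRegion:
    """One or more merged positive windows."""

    contig: str
    start: int
    end: int
    window_count: int

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("CandidateRegion must be non-empty")


@dataclass(frozen=True)
class DeletionSignature:
    """One read's D operation inside a candidate region."""

    location: int
    size: int
    read_id: str


@dataclass
class DeletionCall:
    contig: str
    start: int
    size: int
    support: int
    region: CandidateRegion
    imprecise: bool = False


def threshold_and_merge(scored_windows: Sequence[tuple[SubRegion, float]],
                        cutoff: float = 0.5) -> list[CandidateRegion]:
    """Keep windows with probability strictly above ``cutoff`` and merge
    maximal runs of index-consecutive positives into candidate regions."""
    positives = [(r, p) for r, p in scored_windows if p > cutoff]
    regions: list[CandidateRegion] = []
    run: list[SubRegion] = []
    for r, _ in positives:
        if run and r.contig == run[-1].contig and r.index == run[-1].index + 1:
            run.append(r)
        else:
            if run:
                regions.append(CandidateRegion(run[0].contig, run[0].start,
                                               run[-1].end, len(run)))
            run = [r]
    if run:
        regions.append(CandidateRegion(run[0].contig, run[0].start,
                                       run[-1].end, len(run)))
    return regions


def collect_signatures(region: CandidateRegion, alignment_source,
                       min_size: int = 20,
                       filters: AlignmentFilter | None = None,
                       ) -> list[DeletionSignature]:
    """Signatures from every D op larger than ``min_size`` bp of reads
    aligned in the region.  ``location`` is the reference coordinate where
    the D op begins; one read can contribute several signatures."""
    import pysam

    if filters is None:
        filters = AlignmentFilter()
    own = False
    if isinstance(alignment_source, (str, Path)):
        alignment_source = pysam.AlignmentFile(str(alignment_source))
        own = True
    try:
        sigs = []
        for aln in alignment_source.fetch(region.contig, region.start,
                                          region.end):
            if not filters.accepts(aln) or aln.cigartuples is None:
                continue
            for d_start, d_end in deletion_intervals(
                    aln.reference_start, aln.cigartuples, aln.query_name):
                if d_end - d_start > min_size:
                    sigs.append(DeletionSignature(d_start, d_end - d_start,
                                                  aln.query_name))
        return sigs
    finally:
        if own:
            alignment_source.close()


def cluster_signatures(signatures: Sequence[DeletionSignature],
                       radius: int = 40, linkage: str = "single",
                       ) -> list[list[DeletionSignature]]:
    """Deterministic location clustering.

    ``single`` (default): sort by location, chain a signature into the
    current cluster when it is within ``radius`` of the previous member
    (transitive closure of the pairwise |Li - Lj| < radius relation on
    sorted locations).  ``centroid``: compare against the running mean
    location of the current cluster instead.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if linkage not in ("single", "centroid"):
        raise ValueError(f"unknown linkage {linkage!r}")
    ordered = sorted(signatures, key=lambda s: (s.location, s.size, s.read_id))
    clusters: list[list[DeletionSignature]] = []
    for sig in ordered:
        if clusters:
            cur = clusters[-1]
            if linkage == "single":
                ref = cur[-1].location
            else:
                ref = sum(s.location for s in cur) / len(cur)
            if abs(sig.location - ref) < radius:
                cur.append(sig)
                continue
        clusters.append([sig])
    return clusters


def _round_half_up(x: float) -> int:
    import math
    return int(math.floor(x + 0.5))


def refine_call(clusters: Sequence[Sequence[DeletionSignature]],
                region: CandidateRegion) -> DeletionCall:
    """Largest cluster (tie: smallest mean location) averaged into a call.

    With no signatures at all, falls back to the region bounds with
    support 0, flagged IMPRECISE.
    """
    clusters = [c for c in clusters if c]
    if not clusters:
        return DeletionCall(region.contig, region.start,
                            region.end - region.start, 0, region,
                            imprecise=True)
    best = max(clusters,
               key=lambda c: (len(c), -sum(s.location for s in c) / len(c)))
    loc = _round_half_up(sum(s.location for s in best) / len(best))
    size = _round_half_up(sum(s.size for s in best) / len(best))
    return DeletionCall(region.contig, loc, size, len(best), region)


def call_deletions(scored_windows, alignment_source, cutoff: float = 0.5,
                   cluster_radius: int = 40, min_signature_size: int = 20,
                   linkage: str = "single",
                   filters: AlignmentFilter | None = None,
                   ) -> list[DeletionCall]:
    """Full calling stage: threshold, merge, collect, cluster, refine."""
    calls = []
    for region in threshold_and_merge(scored_windows, cutoff):
        sigs = collect_signatures(region, alignment_source,
                                  min_signature_size, filters)
        clusters = cluster_signatures(sigs, cluster_radius, linkage)
        calls.append(refine_call(clusters, region))
    return calls


def write_vcf(calls: Sequence[DeletionCall], contig_lengths: dict[str, int],
              out: str | Path, min_report_size: int = 50,
              sample: str = "SAMPLE") -> Path:
    """Write calls as VCF 4.2 symbolic <DEL> records.

    Internal 0-based starts become 1-based POS; INFO carries SVTYPE=DEL,
    END=POS+size, SVLEN=-size, SUPPORT, and IMPRECISE for fallback calls.
    Calls smaller than ``min_report_size`` (default 50 bp) are dropped.
    Genotypes are reported as missing (./.) — calls are not genotyped.
    """
    out = Path(out)
    lines = [
        "##fileformat=VCFv4.2",
        "##source=deepdel",
        '##ALT=<ID=DEL,Description="Deletion">',
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">',
        '##INFO=<ID=SUPPORT,Number=1,Type=Integer,'
        'Description="Supporting signature count">',
        '##INFO=<ID=IMPRECISE,Number=0,Type=Flag,'
        'Description="No CIGAR signature support; region bounds reported">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for contig, length in contig_lengths.items():
        lines.append(f"##contig=<ID={contig},length={length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + sample)
    kept = [c for c in calls if c.size >= min_report_size]
    kept.sort(key=lambda c: (c.contig, c.start))
    for i, c in enumerate(kept):
        pos = c.start + 1
        info = (f"SVTYPE=DEL;END={pos + c.size};SVLEN={-c.size};"
                f"SUPPORT={c.support}")
        if c.imprecise:
            info = "IMPRECISE;" + info
        lines.append(f"{c.contig}\t{pos}\tDEL{i + 1}\tN\t<DEL>\t.\tPASS\t"
                     f"{info}\tGT\t./.")
    out.write_text("\n".join(lines) + "\n")
    return out


def read_vcf_calls(path: str | Path) -> list[DeletionCall]:
    """Parse a VCF written by :func:`write_vcf` back into calls."""
    import pysam

    calls = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            size = rec.info.get("SVLEN")
            if isinstance(size, (tuple, list)):
                size = size[0]
            size = abs(int(size)) if size is not None else rec.stop - rec.pos
            start = rec.pos - 1  # POS encodes the 0-based start + 1
            support = int(rec.info.get("SUPPORT", 0))
            region = CandidateRegion(rec.contig, start, start + size, 1)
            calls.append(DeletionCall(rec.contig, start, size, support,
                                      region,
                                      imprecise="IMPRECISE" in rec.info))
    return calls
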
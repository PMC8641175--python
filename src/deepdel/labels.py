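"""Truth deletion sets and per-window binary labels.

A window is labelled 1 iff its half-open interval intersects any truth
deletion interval ``[start, start + size)`` — any nonzero overlap counts,
with no minimum reciprocal-overlap requirement.  Genotype in truth VCFs is
ignored; the presence of a deletion record suffices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .features import SubRegion


@dataclass(frozen=True)
class TruthDeletion:
    """One known deletion: contig, 0-based start, size in bp."""

    contig: str
    start: int
    size: int

    def __post_init__(self):
        if self.size < 1 or self.start < 0:
            raise ValueError("TruthDeletion requires start >= 0 and size >= 1")

    @property
    def end(self) -> int:
        return self.start + self.size


@dataclass(frozen=True)
class WindowLabel:
    region: SubRegion
    label: int

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


def _vcf_deletion_size(rec) -> int | None:
    """Deletion size of a VCF record, or None if it is not a deletion."""
    svtype = rec.info.get("SVTYPE")
    alts = rec.alts or ()
    symbolic = any(a == "<DEL>" for a in alts)
    if svtype == "DEL" or symbolic:
        svlen = rec.info.get("SVLEN")
        if svlen is not None:
            if isinstance(svlen, (tuple, list)):
                svlen = svlen[0]
            return abs(int(svlen))
        size = rec.stop - rec.pos  # size = END - POS
        return size if size > 0 else None
    # sequence-resolved deletion: REF longer than ALT
    if alts and all(a is not None and a.isalpha() for a in alts):
        diff = len(rec.ref) - min(len(a) for a in alts)
        if diff > 0:
            return diff
    return None


def load_truth(path: str | Path, format: str | None = None,
               min_size: int = 50) -> list[TruthDeletion]:
    """Load deletions from a VCF (plain or bgzip) or BED file.

    Only deletion records are kept (VCF: SVTYPE=DEL, symbolic ``<DEL>``,
    or REF/ALT length difference; BED: every interval), and only those of
    ``size >= min_size`` (default 50 bp).
    """
    path = Path(path)
    if format is None:
        name = path.name.lower()
        if name.endswith((".vcf", ".vcf.gz")):
            format = "vcf"
        elif name.endswith((".bed", ".bed.gz")):
            format = "bed"
        else:
            raise ValueError(f"cannot infer format of {path}")
    if format == "vcf":
        return _load_truth_vcf(path, min_size)
    if format == "bed":
        return _load_truth_bed(path, min_size)
    raise ValueError(f"unknown truth format {format!r}")


def _load_truth_vcf(path: Path, min_size: int) -> list[TruthDeletion]:
    import pysam

    out = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            try:
                size = _vcf_deletion_size(rec)
            except (ValueError, TypeError):
                skipped += 1
                continue
            if size is None:
                continue
            start = rec.start
            # sequence-resolved records carry a padding base before the event
            if rec.alts and not any(a == "<DEL>" for a in rec.alts) \
                    and len(rec.ref) > 1:
                start = rec.start + 1
            if size >= min_size:
                out.append(TruthDeletion(rec.contig, start, size))
    if skipped:
        warnings.warn(f"skipped {skipped} VCF records with unparseable SV length")
    return out


def _load_truth_bed(path: Path, min_size: int) -> list[TruthDeletion]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"BED line with <3 columns: {line!r}")
            contig, start, end = fields[0], int(fields[1]), int(fields[2])
            size = end - start
            if size >= min_size:
                out.append(TruthDeletion(contig, start, size))
    return out


def label_windows(windows: Sequence[SubRegion],
                  truths: Sequence[TruthDeletion]) -> list[WindowLabel]:
    """Label each window 1 iff it intersects any truth deletion interval."""
    by_contig: dict[str, list[TruthDeletion]] = {}
    for t in truths:
        by_contig.setdefault(t.contig, []).append(t)
    for lst in by_contig.values():
        lst.sort(key=lambda t: t.start)
    out = []
    for w in windows:
        label = 0
        for t in by_contig.get(w.contig, ()):
            if t.start >= w.end:
                break
            if t.end > w.start:  # half-open intersection
                label = 1
                break
        out.append(WindowLabel(w, label))
    return out
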
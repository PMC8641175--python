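"""Per-window deletion feature matrices from long-read alignments.

The reference is tiled into fixed-size windows (default 200 bp).  Every
read whose alignment span intersects a window contributes one binary
bitmap row: position ``j`` is 1 iff the CIGAR places a deletion (``D``)
operation over reference base ``window.start + j``.  Rows are sorted by
deletion count (descending, read name as tie-break), truncated or
zero-padded to ``n`` rows, and consecutive windows are grouped into
fixed-length sequences consumed by the recurrent classifier.

Only ``D`` operations count as deletion evidence; ``N`` (skip) operations
consume reference but are not deletions.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .config import AlignmentFilter, ConfigError, MATRIX_ORIENTATION

# SAM numeric op codes
_OP_CHARS = "MIDNSHP=X"
_REF_CONSUMING = {0, 2, 3, 7, 8}  # M, D, N, =, X
_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


class CigarError(ValueError):
    """Malformed CIGAR string, with the offending read named."""


@dataclass(frozen=True)
class SubRegion:
    """One fixed-size window of the reference (0-based, half-open)."""

    contig: str
    start: int
    end: int
    index: int

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("SubRegion must be non-empty")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SimpleAlignment:
    """Minimal alignment record: a start coordinate plus a CIGAR.

    ``cigar`` may be a SAM CIGAR string or a sequence of
    ``(op_code, length)`` tuples using SAM numeric codes (as pysam's
    ``cigartuples``).
    """

    reference_start: int
    cigar: object
    read_name: str = "read"


@dataclass
class DeletionBitmap:
    """Length-m indicator row for one read in one window."""

    values: np.ndarray
    read_name: str = "read"

    @property
    def deletion_count(self) -> int:
        return int(self.values.sum())


@dataclass
class FeatureMatrix:
    """n x m binary matrix for one window; ``p`` reads were aligned in it."""

    region: SubRegion
    rows: np.ndarray  # (n, m) uint8
    p: int


@dataclass
class RegionBatch:
    """T consecutive windows' matrices: one input sample for the network.

    ``mask[t]`` is True for real windows and False for zero-padding added
    when a contig tail leaves fewer than T windows; padded positions are
    excluded from the loss and never reported as calls.
    """

    matrices: np.ndarray  # (T, n, m) uint8
    contig: str
    first_index: int
    mask: np.ndarray  # (T,) bool
    regions: list = field(default_factory=list)
    labels: np.ndarray | None = None  # (T,) float, padded positions 0


def parse_cigar(cigar, read_name: str = "read") -> list[tuple[int, int]]:
    """Normalise a CIGAR (string or tuples) to ``[(op_code, length), ...]``."""
    if isinstance(cigar, str):
        ops = [(_OP_CHARS.index(op), int(num))
               for num, op in _CIGAR_RE.findall(cigar)]
        consumed = "".join(f"{n}{_OP_CHARS[o]}" for o, n in ops)
        if consumed != cigar:
            raise CigarError(f"malformed CIGAR {cigar!r} for read {read_name!r}")
        if not ops:
            raise CigarError(f"empty CIGAR for read {read_name!r}")
        return ops
    ops = []
    for op, num in cigar:
        if not (0 <= op <= 8) or num < 1:
            raise CigarError(f"malformed CIGAR tuple ({op},{num}) for read {read_name!r}")
        ops.append((int(op), int(num)))
    if not ops:
        raise CigarError(f"empty CIGAR for read {read_name!r}")
    return ops


def deletion_intervals(reference_start: int, cigar,
                       read_name: str = "read") -> list[tuple[int, int]]:
    """Reference-coordinate half-open intervals covered by D operations."""
    pos = reference_start
    out = []
    for op, num in parse_cigar(cigar, read_name):
        if op == 2:  # D
            out.append((pos, pos + num))
        if op in _REF_CONSUMING:
            pos += num
    return out


def reference_span(reference_start: int, cigar,
                   read_name: str = "read") -> tuple[int, int]:
    """Half-open reference interval consumed by the alignment."""
    length = sum(num for op, num in parse_cigar(cigar, read_name)
                 if op in _REF_CONSUMING)
    return reference_start, reference_start + length


def partition_reference(contig_lengths: dict[str, int],
                        window_size: int = 200) -> list[SubRegion]:
    """Tile each contig left to right into windows of ``window_size`` bp.

    The last window of a contig may be shorter; its bitmaps are
    zero-padded on the right to full length downstream.
    """
    if window_size < 1:
        raise ConfigError("window_size must be >= 1")
    windows = []
    for contig, length in contig_lengths.items():
        if length < 1:
            raise ConfigError(f"contig {contig!r} has non-positive length")
        for idx, start in enumerate(range(0, length, window_size)):
            windows.append(SubRegion(contig, start,
                                     min(start + window_size, length), idx))
    return windows


def extract_deletion_bitmap(alignment, region: SubRegion,
                            m: int | None = None) -> DeletionBitmap:
    """Bitmap of deletion evidence one alignment places inside one window.

    Works with any object exposing ``reference_start`` and either
    ``cigartuples`` or ``cigar`` (pysam records and :class:`SimpleAlignment`
    both qualify).  A non-overlapping alignment yields an all-zero bitmap.
    The bitmap has length ``m`` (default: the window size); a short final
    window is zero-padded on the right.
    """
    if m is None:
        m = region.length
    name = getattr(alignment, "read_name", None) or \
        getattr(alignment, "query_name", "read")
    cigar = getattr(alignment, "cigartuples", None)
    if cigar is None:
        cigar = alignment.cigar
    values = np.zeros(m, dtype=np.uint8)
    for d_start, d_end in deletion_intervals(alignment.reference_start, cigar, name):
        lo = max(d_start, region.start)
        hi = min(d_end, region.end)
        if lo < hi:
            values[lo - region.start:hi - region.start] = 1
    return DeletionBitmap(values, name)


def build_feature_matrix(bitmaps: Sequence[DeletionBitmap], region: SubRegion,
                         n: int = 18) -> FeatureMatrix:
    """Sort rows by deletion count (desc), truncate to n or zero-pad to n.

    The sort is stable with read name as a secondary key so that output is
    deterministic.  ``p`` records how many reads were aligned in the window
    before truncation/padding.
    """
    p = len(bitmaps)
    if p == 0:
        m = region.length
        return FeatureMatrix(region, np.zeros((n, m), dtype=np.uint8), 0)
    ordered = sorted(bitmaps, key=lambda b: (-b.deletion_count, b.read_name))
    m = len(ordered[0].values)
    rows = np.zeros((n, m), dtype=np.uint8)
    for i, b in enumerate(ordered[:n]):
        rows[i] = b.values
    return FeatureMatrix(region, rows, p)


def _check_sorted_header(af) -> None:
    hd = af.header.to_dict().get("HD", {})
    if hd.get("SO") != "coordinate":
        raise ValueError(
            "alignment file is not coordinate-sorted; sort it first "
            "(e.g. samtools sort)")


def extract_region_matrices(alignment_source, contig: str,
                            contig_length: int,
                            window_size: int = 200, n: int = 18,
                            filters: AlignmentFilter | None = None,
                            ) -> Iterator[FeatureMatrix]:
    """Yield one FeatureMatrix per window of ``contig``, in order.

    ``alignment_source`` is a pysam.AlignmentFile (or a path to one),
    coordinate-sorted; an index enables a region fetch, otherwise a single
    linear pass is used.  Each accepted read contributes a bitmap row to
    every window its reference span intersects, including all-zero rows.
    """
    import pysam

    if filters is None:
        filters = AlignmentFilter()
    own = False
    if isinstance(alignment_source, (str, Path)):
        alignment_source = pysam.AlignmentFile(str(alignment_source))
        own = True
    try:
        _check_sorted_header(alignment_source)
        windows = partition_reference({contig: contig_length}, window_size)
        if contig not in alignment_source.references:
            warnings.warn(f"contig {contig!r} absent from alignment file; "
                          "emitting all-zero matrices")
            reads = iter(())
        else:
            try:
                reads = alignment_source.fetch(contig)
            except ValueError:  # no index: linear pass
                reads = (a for a in alignment_source
                         if a.reference_name == contig)
        pending: dict[int, list[DeletionBitmap]] = {}
        next_to_yield = 0
        last_start = -1

        def flush_until(limit: int):
            nonlocal next_to_yield
            while next_to_yield < limit:
                w = windows[next_to_yield]
                yield build_feature_matrix(pending.pop(next_to_yield, []), w, n)
                next_to_yield += 1

        for aln in reads:
            if not filters.accepts(aln) or aln.cigartuples is None:
                continue
            if aln.reference_start < last_start:
                raise ValueError("alignments out of order; sort the file first")
            last_start = aln.reference_start
            span_lo, span_hi = reference_span(
                aln.reference_start, aln.cigartuples, aln.query_name)
            span_hi = min(span_hi, contig_length)
            if span_hi <= span_lo:
                continue
            first_w = span_lo // window_size
            last_w = min((span_hi - 1) // window_size, len(windows) - 1)
            # windows strictly left of this read's start can never gain rows
            yield from flush_until(min(first_w, len(windows)))
            d_ivals = deletion_intervals(aln.reference_start, aln.cigartuples,
                                         aln.query_name)
            for wi in range(first_w, last_w + 1):
                w = windows[wi]
                values = np.zeros(window_size, dtype=np.uint8)
                for d_start, d_end in d_ivals:
                    lo = max(d_start, w.start)
                    hi = min(d_end, w.end)
                    if lo < hi:
                        values[lo - w.start:hi - w.start] = 1
                pending.setdefault(wi, []).append(
                    DeletionBitmap(values, aln.query_name))
        yield from flush_until(len(windows))
    finally:
        if own:
            alignment_source.close()


def make_batches(matrices: Sequence[FeatureMatrix], T: int = 100,
                 ) -> list[RegionBatch]:
    """Chunk ordered window matrices into non-overlapping runs of T.

    A final short chunk is zero-padded and carries a validity mask.
    Short last windows (contig tails) are zero-padded on the right to m.
    """
    if T < 1:
        raise ConfigError("T must be >= 1")
    matrices = list(matrices)
    if not matrices:
        return []
    n, m = matrices[0].rows.shape[0], matrices[0].region.length
    m = max(mx.rows.shape[1] for mx in matrices)
    contig = matrices[0].region.contig
    batches = []
    for i0 in range(0, len(matrices), T):
        chunk = matrices[i0:i0 + T]
        arr = np.zeros((T, n, m), dtype=np.uint8)
        mask = np.zeros(T, dtype=bool)
        regions = []
        for t, mx in enumerate(chunk):
            arr[t, :, :mx.rows.shape[1]] = mx.rows
            mask[t] = True
            regions.append(mx.region)
        batches.append(RegionBatch(arr, contig, chunk[0].region.index,
                                   mask, regions))
    return batches


# ---------------------------------------------------------------------------
# on-disk tensor container (one file per contig + JSON sidecar)

def save_feature_container(prefix: str | Path, contig: str,
                           matrices: Sequence[FeatureMatrix],
                           m: int, n: int, T: int,
                           labels: np.ndarray | None = None) -> Path:
    """Write extracted matrices to ``<prefix>.npz`` + ``<prefix>.json``.

    The sidecar records m, n, T, the window coordinates and the matrix
    orientation so the train/call stages can verify compatibility.
    """
    prefix = Path(prefix)
    matrices = list(matrices)
    arr = np.zeros((len(matrices), n, m), dtype=np.uint8)
    starts, ends = [], []
    for i, mx in enumerate(matrices):
        arr[i, :, :mx.rows.shape[1]] = mx.rows
        starts.append(mx.region.start)
        ends.append(mx.region.end)
    payload = {"matrices": arr,
               "window_starts": np.asarray(starts, dtype=np.int64),
               "window_ends": np.asarray(ends, dtype=np.int64),
               "p": np.asarray([mx.p for mx in matrices], dtype=np.int64)}
    if labels is not None:
        payload["labels"] = np.asarray(labels, dtype=np.int8)
    np.savez_compressed(prefix.with_suffix(".npz"), **payload)
    sidecar = {"contig": contig, "m": m, "n": n, "T": T,
               "num_windows": len(matrices),
               "orientation": MATRIX_ORIENTATION}
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return prefix.with_suffix(".npz")


def load_feature_container(prefix: str | Path):
    """Load a container written by :func:`save_feature_container`.

    Returns ``(matrices, regions, labels_or_None, sidecar_dict)``.
    """
    prefix = Path(prefix)
    sidecar = json.loads(prefix.with_suffix(".json").read_text())
    with np.load(prefix.with_suffix(".npz")) as z:
        arr = z["matrices"]
        starts = z["window_starts"]
        ends = z["window_ends"]
        p = z["p"]
        labels = z["labels"] if "labels" in z else None
    if sidecar.get("orientation") != MATRIX_ORIENTATION:
        raise ValueError("feature container orientation mismatch")
    regions = [SubRegion(sidecar["contig"], int(s), int(e), i)
               for i, (s, e) in enumerate(zip(starts, ends))]
    matrices = [FeatureMatrix(r, arr[i], int(p[i]))
                for i, r in enumerate(regions)]
    return matrices, regions, labels, sidecar
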
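"""Alignment and track I/O: MAF reading, region chunking, and writers.

Alignments come in as MAF blocks with a designated reference species.
Columns where the reference row carries a gap are dropped, so all
downstream coordinates are 0-based half-open positions on the
ungapped reference sequence.  Species absent from a block are treated
as gapped over that block's extent.  Overlapping blocks on the
reference are resolved first-block-wins with a warning.

Score tracks are written as the two-column ``neutral_rate<TAB>rs_score``
text layout (one line per reference position, six decimals, zeros for
unscored positions); elements as BED6+1 with the p-value in a seventh
column.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .rate_scoring import GAP_CODE, AlignmentColumn, ScoredTrack, symbol_to_code

logger = logging.getLogger("gerppy")

_CODE_TO_SYMBOL = np.array(list("ACGT-"), dtype="U1")


def _species_of(src: str) -> str:
    """MAF row sources look like ``species.chrom``; return the species."""
    return src.split(".", 1)[0]


def _contig_of(src: str) -> str:
    parts = src.split(".", 1)
    return parts[1] if len(parts) == 2 else parts[0]


@dataclass
class ReferenceProjectedAlignment:
    """A multiple alignment compressed to reference coordinates.

    ``codes`` is an ``(n_species, n_positions)`` int8 matrix of base
    codes (0..3 = ACGT, 4 = gap/ambiguous/absent) over the dense
    extent ``[start, start + n_positions)`` on the reference;
    ``covered`` marks positions touched by at least one MAF block.
    The reference row is never a gap at a covered position.
    """

    reference: str
    species: List[str]
    codes: np.ndarray
    covered: np.ndarray
    chrom: str = "chr1"
    start: int = 0

    def __post_init__(self):
        if self.reference not in self.species:
            raise ValueError("reference species missing from species list")
        if self.codes.shape != (len(self.species), len(self.covered)):
            raise ValueError("codes shape does not match species/positions")

    @property
    def n_positions(self) -> int:
        return self.codes.shape[1]

    @property
    def end(self) -> int:
        return self.start + self.n_positions

    def covered_intervals(self) -> List[Tuple[int, int]]:
        """Half-open reference intervals covered by alignment blocks."""
        return _mask_to_intervals(self.covered, self.start)

    def columns(self) -> Iterator[AlignmentColumn]:
        """Iterate AlignmentColumns over covered positions only."""
        for j in range(self.n_positions):
            if not self.covered[j]:
                continue
            bases = {
                sp: str(_CODE_TO_SYMBOL[min(self.codes[i, j], 4)])
                for i, sp in enumerate(self.species)
            }
            yield AlignmentColumn(bases, position=self.start + j)

    def base_frequencies(self) -> np.ndarray:
        """Empirical A,C,G,T frequencies over all aligned bases."""
        counts = np.array([(self.codes == b).sum() for b in range(4)],
                          dtype=float)
        total = counts.sum()
        if total == 0:
            return np.full(4, 0.25)
        freqs = counts / total
        # keep frequencies valid for the substitution model
        freqs = np.maximum(freqs, 1e-6)
        return freqs / freqs.sum()


def _mask_to_intervals(mask: np.ndarray, offset: int) -> List[Tuple[int, int]]:
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    diff = np.diff(mask.astype(np.int8))
    starts = list(np.nonzero(diff == 1)[0] + 1)
    ends = list(np.nonzero(diff == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size)
    return [(offset + s, offset + e) for s, e in zip(starts, ends)]


def read_maf(path, reference_species: str) -> ReferenceProjectedAlignment:
    """Read a MAF file and project it onto the reference sequence.

    Columns with a reference gap are removed; species missing from a
    block are gaps at all of that block's positions.  When blocks
    overlap on the reference, the first block wins and a warning is
    logged.
    """
    block_data = []   # (ref_start, length, {species: codes array}, chrom)
    species_seen = set()
    with open(path) as fh:
        for block in AlignIO.parse(fh, "maf"):
            ref_rec = None
            for rec in block:
                if _species_of(rec.id) == reference_species:
                    ref_rec = rec
                    break
            if ref_rec is None:
                warnings.warn(
                    f"MAF block without reference row "
                    f"({reference_species!r}) skipped")
                continue
            ref_seq = np.frombuffer(
                str(ref_rec.seq).upper().encode(), dtype="S1")
            keep = ref_seq != b"-"
            if not keep.any():
                continue
            ref_start = int(ref_rec.annotations.get("start", 0))
            chrom = _contig_of(ref_rec.id)
            cols = {}
            for rec in block:
                sp = _species_of(rec.id)
                if sp == reference_species and rec is not ref_rec:
                    continue  # secondary reference rows are ignored
                seq = np.frombuffer(
                    str(rec.seq).upper().encode(), dtype="S1")[keep]
                codes = np.full(len(seq), GAP_CODE, dtype=np.int8)
                for sym, code in (("A", 0), ("C", 1), ("G", 2), ("T", 3)):
                    codes[seq == sym.encode()] = code
                cols[sp] = codes
                species_seen.add(sp)
            block_data.append((ref_start, int(keep.sum()), cols, chrom))

    if not block_data:
        return ReferenceProjectedAlignment(
            reference=reference_species, species=[reference_species],
            codes=np.zeros((1, 0), dtype=np.int8),
            covered=np.zeros(0, dtype=bool))

    species = [reference_species] + sorted(
        species_seen - {reference_species})
    sp_index = {sp: i for i, sp in enumerate(species)}
    start = min(b[0] for b in block_data)
    end = max(b[0] + b[1] for b in block_data)
    codes = np.full((len(species), end - start), GAP_CODE, dtype=np.int8)
    covered = np.zeros(end - start, dtype=bool)
    chrom = block_data[0][3]

    for ref_start, length, cols, _ in block_data:
        lo = ref_start - start
        sel = ~covered[lo:lo + length]
        if not sel.all():
            logger.warning(
                "overlapping MAF blocks at %s:%d-%d; first block wins",
                chrom, ref_start, ref_start + length)
        if not sel.any():
            continue
        idx = lo + np.nonzero(sel)[0]
        for sp, arr in cols.items():
            codes[sp_index[sp], idx] = arr[sel]
        covered[idx] = True

    return ReferenceProjectedAlignment(
        reference=reference_species, species=species, codes=codes,
        covered=covered, chrom=chrom, start=start)


def write_maf(aln: ReferenceProjectedAlignment, path,
              block_size: int = 100000) -> None:
    """Write a reference-projected alignment back out as MAF blocks."""
    alignments = []
    for lo, hi in aln.covered_intervals():
        for bs in range(lo, hi, block_size):
            be = min(bs + block_size, hi)
            i, j = bs - aln.start, be - aln.start
            records = []
            for s, sp in enumerate(aln.species):
                text = "".join(_CODE_TO_SYMBOL[np.minimum(
                    aln.codes[s, i:j], 4)])
                rec = SeqRecord(Seq(text), id=f"{sp}.{aln.chrom}",
                                description="")
                rec.annotations.update({
                    "start": bs, "size": (j - i) - text.count("-"),
                    "strand": 1, "srcSize": aln.end})
                records.append(rec)
            alignments.append(MultipleSeqAlignment(records))
    with open(path, "w") as fh:
        AlignIO.write(alignments, fh, "maf")


# ---------------------------------------------------------------------------
# region chunking
# ---------------------------------------------------------------------------

@dataclass
class Region:
    """Half-open reference interval with its contained track slice."""

    start: int       # genome coordinate
    end: int
    track: ScoredTrack

    def __len__(self) -> int:
        return self.end - self.start


def chunk_regions(track: ScoredTrack, target_size: int = 2_000_000,
                  boundary_gap: int = 10) -> List[Region]:
    """Tile a scored track into regions of roughly `target_size`.

    Boundaries are placed inside the longest unscored run (length at
    least `boundary_gap`) near each multiple of `target_size`, falling
    back to the exact multiple when no such run exists nearby.
    Constrained elements are later confined to single regions, so no
    element can span a boundary.
    """
    if target_size <= 0:
        raise ValueError("target_size must be positive")
    n = len(track)
    runs = [(s - track.start, e - track.start)
            for s, e in _mask_to_intervals(~track.scored, track.start)
            if e - s >= boundary_gap]

    regions = []
    pos = 0
    while n - pos > 1.5 * target_size:
        target = pos + target_size
        lo_w, hi_w = target - target_size // 2, target + target_size // 2
        best = None
        for s, e in runs:
            centre = (s + e) // 2
            if centre <= pos or not (lo_w <= centre <= hi_w):
                continue
            cand = (e - s, -abs(centre - target), centre)
            if best is None or cand > best:
                best = cand
        cut = best[2] if best is not None else target
        regions.append(Region(track.start + pos, track.start + cut,
                              track.slice(pos, cut)))
        pos = cut
    regions.append(Region(track.start + pos, track.start + n,
                          track.slice(pos, n)))
    return regions


# ---------------------------------------------------------------------------
# plain-text writers / readers
# ---------------------------------------------------------------------------

def write_rates(track: ScoredTrack, path) -> None:
    """Two tab-separated columns per position: neutral rate, RS score."""
    n = np.where(track.scored, track.neutral_rate, 0.0)
    rs = np.where(track.scored, track.rs, 0.0)
    with open(path, "w") as fh:
        for i in range(len(track)):
            fh.write(f"{n[i]:.6f}\t{rs[i]:.6f}\n")


def read_rates(path, chrom: str = "chr1", start: int = 0) -> ScoredTrack:
    """Read a rates file back into a ScoredTrack (rescaling unknown)."""
    data = np.loadtxt(path, dtype=float, ndmin=2)
    if data.size == 0:
        data = np.zeros((0, 2))
    if data.shape[1] != 2:
        raise ValueError("rates file must have exactly two columns")
    n = data[:, 0]
    rs = data[:, 1]
    scored = n > 0.0
    return ScoredTrack(n, np.full(len(n), np.nan), rs, scored,
                       chrom=chrom, start=start)


def write_elements(elements: Sequence, path) -> None:
    """Elements as BED6+1: chrom, start, end, name, score, strand, p-value."""
    elements = sorted(elements, key=lambda e: (e.chrom, e.start))
    with open(path, "w") as fh:
        for el in elements:
            fh.write(f"{el.chrom}\t{el.start}\t{el.end}\telem_{el.rank}\t"
                     f"{el.score:.6g}\t.\t{el.pvalue:.1e}\n")


def read_elements(path) -> List[Tuple[str, int, int, str, float, float]]:
    """Read a BED6+1 elements file; returns raw tuples for round-trips."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            chrom, s, e, name, score, _strand, p = line.split("\t")
            out.append((chrom, int(s), int(e), name, float(score), float(p)))
    return out


def write_bedgraph(track: ScoredTrack, path) -> None:
    """RS scores as bedGraph for genome-browser display."""
    with open(path, "w") as fh:
        for i in range(len(track)):
            if track.scored[i]:
                pos = track.start + i
                fh.write(f"{track.chrom}\t{pos}\t{pos + 1}\t"
                         f"{track.rs[i]:.4f}\n")


def write_fpr_report(rows: Iterable[Tuple[float, float, float, int]],
                     path) -> None:
    """Tab-separated FPR table: threshold, expected false predictions,
    expected false bases, observed predictions."""
    with open(path, "w") as fh:
        fh.write("pvalue_threshold\texpected_false_predictions\t"
                 "expected_false_bases\tobserved_predictions\n")
        for thr, fp, fb, obs in rows:
            fh.write(f"{thr:.6e}\t{fp:.4f}\t{fb:.2f}\t{obs}\n")


def write_detection_curve(curve, path) -> None:
    """Detection curve as TSV: cutoff, B, F, B*."""
    with open(path, "w") as fh:
        fh.write("cutoff\tpredicted_bases\texpected_false_bases\t"
                 "adjusted_bases\n")
        for c, b, f, bstar in zip(curve.cutoffs, curve.predicted_bases,
                                  curve.false_bases, curve.adjusted_bases):
            fh.write(f"{c:.4f}\t{b:.0f}\t{f:.2f}\t{bstar:.2f}\n")
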
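"""Demultiplexing and isoform classification of barcoded amplicon reads.

Reads carry a fixed-length plate barcode as a prefix of the insert and a
well-specific index pair in the header comment (``i7+i5``). Classification
uses exact junction-spanning k-mer matching instead of full alignment: the
amplicons differ only by a short intron, so a read is assigned to an isoform
iff it contains the corresponding junction with at least ``junction_flank_k``
matching bases on each side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence, TextIO

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from splicescreen.simdata import BarcodeScheme, TargetSpec

__all__ = [
    "ReadRecord",
    "DemuxReport",
    "read_fastq",
    "demultiplex",
    "classify_read",
    "count_isoforms",
]

SPLICED = "spliced"
UNSPLICED = "unspliced"
AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read: id, sequence, and its well index pair."""

    id: str
    sequence: str
    well_index: tuple[str, str]


@dataclass
class DemuxReport:
    """Run-level bookkeeping: every input read is assigned or tallied here."""

    total: int = 0
    assigned: int = 0
    unassigned: dict[str, int] = field(
        default_factory=lambda: {"bad_plate": 0, "bad_index": 0, "not_in_layout": 0}
    )
    ambiguous: int = 0
    no_target: int = 0

    @property
    def n_unassigned(self) -> int:
        return sum(self.unassigned.values())


def read_fastq(handle: TextIO) -> Iterator[ReadRecord]:
    """Parse FASTQ records, taking the index pair from the ``i7+i5`` comment."""
    for title, seq, _qual in FastqGeneralIterator(handle):
        name, _, comment = title.partition(" ")
        i7, _, i5 = comment.partition("+")
        yield ReadRecord(id=name, sequence=seq, well_index=(i7, i5))


def _match_one(query: str, codes: Sequence[str], max_mismatch: int) -> str | None:
    """Best barcode within max_mismatch, None if none qualifies.

    The scheme invariant (pairwise distance > 2*max_mismatch) makes any
    qualifying match unique.
    """
    for code in codes:
        if len(code) == len(query):
            d = sum(a != b for a, b in zip(query, code))
            if d <= max_mismatch:
                return code
    return None


def demultiplex(
    reads: Iterable[ReadRecord],
    scheme: BarcodeScheme,
    layout: pd.DataFrame,
    report: DemuxReport | None = None,
) -> Iterator[tuple[ReadRecord, str, str]]:
    """Assign reads to (physical plate, well) positions.

    A read is assigned iff its plate-barcode prefix matches a known barcode
    within ``max_mismatch_plate`` and its index pair matches a known well
    within ``max_mismatch_index`` (per index). Unassigned reads are tallied in
    the report with a reason code. The yielded read has the barcode stripped.
    """
    if report is None:
        report = DemuxReport()
    plen = scheme.plate_len
    plate_exact = scheme._plate_lookup
    pair_exact = scheme._pair_lookup
    positions = {
        (r.plate_id, r.well) for r in layout.itertuples(index=False)
    }
    plate_codes = list(plate_exact)
    mmp = scheme.max_mismatch_plate
    mmi = scheme.max_mismatch_index

    for read in reads:
        report.total += 1
        prefix = read.sequence[:plen]
        plate = plate_exact.get(prefix)
        if plate is None and mmp > 0:
            code = _match_one(prefix, plate_codes, mmp)
            plate = plate_exact.get(code) if code else None
        if plate is None:
            report.unassigned["bad_plate"] += 1
            continue
        well = pair_exact.get(read.well_index)
        if well is None and mmi > 0:
            i7 = _match_one(read.well_index[0], scheme._i7_set, mmi)
            i5 = _match_one(read.well_index[1], scheme._i5_set, mmi)
            if i7 and i5:
                well = pair_exact.get((i7, i5))
        if well is None:
            report.unassigned["bad_index"] += 1
            continue
        if (plate, well) not in positions:
            report.unassigned["not_in_layout"] += 1
            continue
        report.assigned += 1
        stripped = ReadRecord(read.id, read.sequence[plen:], read.well_index)
        yield stripped, plate, well


def classify_read(read: ReadRecord | str, target: TargetSpec) -> str:
    """Classify a (barcode-stripped) read against one target.

    ``unspliced`` if it contains an exact 2k-mer spanning either exon-intron
    boundary, ``spliced`` if it spans the exon5-exon3 junction; ``ambiguous``
    if neither or both.
    """
    seq = read if isinstance(read, str) else read.sequence
    k = target.junction_flank_k
    spliced_j = target.exon5[-k:] + target.exon3[:k]
    up_j = target.exon5[-k:] + target.intron[:k]
    down_j = target.intron[-k:] + target.exon3[:k]
    is_spliced = spliced_j in seq
    is_unspliced = up_j in seq or down_j in seq
    if is_spliced == is_unspliced:
        return AMBIGUOUS
    return SPLICED if is_spliced else UNSPLICED


def _attribute(seq: str, junctions: dict[str, tuple[str, str, str]]) -> tuple[str | None, str | None]:
    """(target_name, class) for a stripped read, or (None, reason)."""
    hits: list[tuple[str, str]] = []
    for name, (spliced_j, up_j, down_j) in junctions.items():
        is_spliced = spliced_j in seq
        is_unspliced = up_j in seq or down_j in seq
        if is_spliced and is_unspliced:
            hits.append((name, AMBIGUOUS))
        elif is_spliced:
            hits.append((name, SPLICED))
        elif is_unspliced:
            hits.append((name, UNSPLICED))
    if len(hits) == 1:
        return hits[0]
    if len(hits) > 1:
        return None, "multi_target"
    return None, "no_target"


def count_isoforms(
    reads: Iterable[ReadRecord],
    scheme: BarcodeScheme,
    layout: pd.DataFrame,
    targets: Sequence[TargetSpec],
) -> tuple[pd.DataFrame, DemuxReport]:
    """Demultiplex and classify reads into a per-sample count table.

    Returns one row per (layout position, target) — zero rows included so the
    table shape is layout-determined — plus the run-level report. Reads whose
    junction content matches no target, or more than one, are tallied as
    ``no_target`` (never silently dropped).
    """
    junctions = {}
    for t in targets:
        k = t.junction_flank_k
        junctions[t.name] = (
            t.exon5[-k:] + t.exon3[:k],
            t.exon5[-k:] + t.intron[:k],
            t.intron[-k:] + t.exon3[:k],
        )
    counters: dict[tuple[str, str, str], list[int]] = {}  # (plate_id, well, target) -> [s, u, a]
    for t in targets:
        for row in layout.itertuples(index=False):
            counters[(row.plate_id, row.well, t.name)] = [0, 0, 0]

    report = DemuxReport()
    slot = {SPLICED: 0, UNSPLICED: 1, AMBIGUOUS: 2}
    for read, plate, well in demultiplex(reads, scheme, layout, report):
        name, cls = _attribute(read.sequence, junctions)
        if name is None:
            report.no_target += 1
            continue
        c = counters[(plate, well, name)]
        c[slot[cls]] += 1
        if cls == AMBIGUOUS:
            report.ambiguous += 1

    meta = layout.set_index(["plate_id", "well"])
    rows = []
    for (plate_id, well, target), (s, u, a) in counters.items():
        m = meta.loc[(plate_id, well)]
        rows.append(
            (m["strain_id"], m["plate"], well, int(m["replicate"]), target, s, u, a)
        )
    counts = pd.DataFrame(
        rows,
        columns=[
            "strain_id",
            "plate",
            "well",
            "replicate",
            "target",
            "spliced",
            "unspliced",
            "ambiguous",
        ],
    )
    counts = counts.sort_values(
        ["target", "plate", "well", "replicate"], kind="stable"
    ).reset_index(drop=True)
    return counts, report
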
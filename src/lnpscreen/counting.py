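"""Barcode and UMI extraction from amplicon FASTQ reads.

Reads begin with a variable-length stagger (0–7 nt by default) followed by
the universal forward anchor; the 8-nt barcode and the 7-nt random region
sit at fixed layout offsets downstream of the anchor. Counting therefore
proceeds anchor-first: locate the forward anchor near the read start
(mismatch-tolerant, leftmost best match), slice the barcode and UMI at the
layout offsets, then assign the observed 8-mer to the nearest barcode in the
designed set. Because the set is built with minimum pairwise Hamming
distance 3, one-mismatch assignment is unambiguous.

Raw read counts (not UMI-collapsed) are the downstream delivery statistic;
distinct-UMI counts are reported alongside as PCR-amplification-bias QC.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .barcodes import BarcodeSet, PrimerSet, ScaffoldLayout, reverse_complement


@dataclass(frozen=True)
class CountParams:
    anchor_max_mismatch: int = 1
    barcode_max_mismatch: int = 1
    try_reverse_complement: bool = True
    #: bases from the read start within which the anchor must lie; default is
    #: max stagger + adapter + anchor, covering reads with a residual adapter.
    search_window: int | None = None


@dataclass
class CountsTable:
    """Per-sample barcode counts with read-conservation bookkeeping."""

    sample_id: str
    counts: pd.DataFrame            # index barcode_id; raw_reads, distinct_umis
    unassigned_reads: int
    total_reads: int

    def __post_init__(self) -> None:
        assigned = int(self.counts["raw_reads"].sum())
        if assigned + self.unassigned_reads != self.total_reads:
            raise ValueError(
                f"count conservation violated in {self.sample_id}: "
                f"{assigned} assigned + {self.unassigned_reads} unassigned "
                f"!= {self.total_reads} total"
            )
        if (self.counts["distinct_umis"] > self.counts["raw_reads"]).any():
            raise ValueError("distinct_umis cannot exceed raw_reads")

    @property
    def assigned_fraction(self) -> float:
        if self.total_reads == 0:
            return 0.0
        return 1.0 - self.unassigned_reads / self.total_reads

    def to_frame(self) -> pd.DataFrame:
        df = self.counts.reset_index()
        df.insert(0, "sample_id", self.sample_id)
        return df

    def write_tsv(self, path: str | Path,
                  extra_meta: dict | None = None) -> None:
        with open(path, "w") as fh:
            for key, value in (extra_meta or {}).items():
                fh.write(f"# {key}={value}\n")
            fh.write(f"# total_reads={self.total_reads}\n")
            fh.write(f"# unassigned_reads={self.unassigned_reads}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CountsTable":
        meta = {}
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                key, _, value = line[1:].strip().partition("=")
                try:
                    meta[key.strip()] = int(value)
                except ValueError:
                    pass
        df = pd.read_csv(path, sep="\t", comment="#")
        sample_id = df["sample_id"].iloc[0] if len(df) else ""
        counts = df.set_index("barcode_id")[["raw_reads", "distinct_umis"]]
        return cls(
            sample_id=sample_id,
            counts=counts,
            unassigned_reads=meta["unassigned_reads"],
            total_reads=meta["total_reads"],
        )


# ---------------------------------------------------------------------------
# Per-read primitives
# ---------------------------------------------------------------------------


def locate_anchor(
    read: str,
    primer_set: PrimerSet,
    max_mismatch: int = 1,
    window: int | None = None,
) -> int | None:
    """Find the forward anchor near the read start.

    Returns the position immediately after the best (fewest-mismatch) match
    of the anchor whose start lies within ``window`` bases of the read start;
    the leftmost best match wins ties. ``None`` means not found (the read is
    counted as unassigned, never an error).
    """
    anchor = primer_set.fwd_anchor
    alen = len(anchor)
    if window is None:
        window = primer_set.max_fwd_stagger + len(primer_set.fwd_adapter) + alen
    limit = min(window, len(read)) - alen
    if limit < 0:
        return None
    # exact match is always the leftmost-best outcome
    pos = read.find(anchor, 0, limit + alen)
    if pos != -1:
        return pos + alen
    if max_mismatch <= 0:
        return None
    best_pos, best_d = None, max_mismatch + 1
    for p in range(limit + 1):
        d = 0
        for a, b in zip(anchor, read[p:p + alen]):
            if a != b:
                d += 1
                if d >= best_d:
                    break
        if d < best_d:
            best_pos, best_d = p, d
            if d == 0:
                break
    if best_pos is None:
        return None
    return best_pos + alen


def extract_barcode_umi(
    read: str, offset: int, layout: ScaffoldLayout
) -> tuple[str, str] | None:
    """Slice the observed barcode and UMI at layout offsets past the anchor.

    Returns ``None`` if the read is truncated before the UMI ends.
    """
    b0 = offset + layout.barcode_offset_from_anchor()
    u0 = offset + layout.umi_offset_from_anchor()
    u1 = u0 + layout.umi_length
    if u1 > len(read):
        return None
    return read[b0:b0 + layout.barcode_length], read[u0:u1]


def assign_barcode(
    observed: str,
    bset: BarcodeSet,
    max_mismatch: int = 1,
    _lookup: dict[str, str] | None = None,
) -> str | None:
    """Assign an observed 8-mer to a designed barcode.

    An exact match wins; otherwise the unique member within ``max_mismatch``
    substitutions. If the set's minimum pairwise distance cannot guarantee
    unambiguous assignment (< 2*max_mismatch + 1), tolerance falls back to
    exact matching with a warning. Ambiguous or distant observations return
    ``None`` (unassigned).
    """
    if bset.min_pairwise_hamming < 2 * max_mismatch + 1 and max_mismatch > 0:
        warnings.warn(
            f"barcode set min distance {bset.min_pairwise_hamming} cannot "
            f"support {max_mismatch}-mismatch assignment; using exact match",
            stacklevel=2,
        )
        max_mismatch = 0
    lookup = _lookup if _lookup is not None else dict(zip(bset.barcodes, bset.ids))
    hit = lookup.get(observed)
    if hit is not None or max_mismatch == 0:
        return hit
    if len(observed) != bset.length:
        return None
    best_id, best_d, ties = None, max_mismatch + 1, 0
    for seq, bid in lookup.items():
        d = sum(a != b for a, b in zip(observed, seq))
        if d < best_d:
            best_id, best_d, ties = bid, d, 1
        elif d == best_d:
            ties += 1
    if best_id is None or ties > 1:
        return None
    return best_id


# ---------------------------------------------------------------------------
# Sample-level counting
# ---------------------------------------------------------------------------


def parse_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (id, sequence) from a FASTQ file, gzipped or plain.

    Malformed records raise with the approximate record number.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    n = 0
    with opener(path, "rt") as fh:
        try:
            for title, seq, _qual in FastqGeneralIterator(fh):
                n += 1
                yield title.split()[0], seq.upper()
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ record ~{n + 1} in {path}: {exc}")


def count_reads(
    reads: Iterable[str],
    bset: BarcodeSet,
    primer_set: PrimerSet,
    layout: ScaffoldLayout | None = None,
    params: CountParams = CountParams(),
    sample_id: str = "",
) -> CountsTable:
    """Stream read sequences through locate → extract → assign and tally."""
    layout = layout or ScaffoldLayout()
    if bset.min_pairwise_hamming < 2 * params.barcode_max_mismatch + 1:
        barcode_mm = 0
        if params.barcode_max_mismatch > 0:
            warnings.warn(
                f"barcode set min distance {bset.min_pairwise_hamming} cannot "
                f"support {params.barcode_max_mismatch}-mismatch assignment; "
                "using exact match",
                stacklevel=2,
            )
    else:
        barcode_mm = params.barcode_max_mismatch
    lookup = dict(zip(bset.barcodes, bset.ids))
    raw: dict[str, int] = {bid: 0 for bid in bset.ids}
    umis: dict[str, set[str]] = {bid: set() for bid in bset.ids}
    total = 0
    unassigned = 0
    for seq in reads:
        total += 1
        hit = _process_read(seq, lookup, bset, primer_set, layout, params, barcode_mm)
        if hit is None and params.try_reverse_complement:
            hit = _process_read(
                reverse_complement(seq), lookup, bset, primer_set, layout,
                params, barcode_mm,
            )
        if hit is None:
            unassigned += 1
        else:
            bid, umi = hit
            raw[bid] += 1
            umis[bid].add(umi)
    counts = pd.DataFrame(
        {
            "raw_reads": [raw[bid] for bid in bset.ids],
            "distinct_umis": [len(umis[bid]) for bid in bset.ids],
        },
        index=pd.Index(bset.ids, name="barcode_id"),
    )
    return CountsTable(
        sample_id=sample_id, counts=counts,
        unassigned_reads=unassigned, total_reads=total,
    )


def _process_read(
    seq: str,
    lookup: dict[str, str],
    bset: BarcodeSet,
    primer_set: PrimerSet,
    layout: ScaffoldLayout,
    params: CountParams,
    barcode_mm: int,
) -> tuple[str, str] | None:
    offset = locate_anchor(
        seq, primer_set, params.anchor_max_mismatch, params.search_window
    )
    if offset is None:
        return None
    extracted = extract_barcode_umi(seq, offset, layout)
    if extracted is None:
        return None
    observed, umi = extracted
    # exact fast path, then tolerant scan
    bid = lookup.get(observed)
    if bid is None and barcode_mm > 0:
        bid = assign_barcode(observed, bset, barcode_mm, _lookup=lookup)
    if bid is None:
        return None
    return bid, umi


def count_sample(
    fastq: str | Path,
    bset: BarcodeSet,
    primer_set: PrimerSet,
    layout: ScaffoldLayout | None = None,
    params: CountParams = CountParams(),
    sample_id: str | None = None,
) -> CountsTable:
    """Count one sample's FASTQ file."""
    fastq = Path(fastq)
    if sample_id is None:
        sample_id = fastq.name.removesuffix(".gz").removesuffix(".fastq")
    return count_reads(
        (seq for _rid, seq in parse_fastq(fastq)),
        bset, primer_set, layout, params, sample_id=sample_id,
    )


def qc_summary(tables: Iterable[CountsTable]) -> pd.DataFrame:
    """Run-level QC: assigned fraction and UMI saturation per sample.

    UMI saturation (distinct UMIs / raw reads, aggregated over barcodes) near
    1 means little PCR duplication; near 0 means heavy amplification bias.
    """
    rows = []
    for t in tables:
        raw = int(t.counts["raw_reads"].sum())
        umi = int(t.counts["distinct_umis"].sum())
        rows.append(
            {
                "sample_id": t.sample_id,
                "total_reads": t.total_reads,
                "assigned_fraction": t.assigned_fraction,
                "umi_saturation": (umi / raw) if raw else float("nan"),
            }
        )
    return pd.DataFrame(rows)
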
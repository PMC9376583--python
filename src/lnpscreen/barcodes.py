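"""Design of DNA barcodes, amplicon scaffolds, and nested-PCR primer sets.

Each nanoparticle in a pooled delivery screen carries a unique single-stranded
91-nt DNA oligo built from fixed functional segments: universal forward and
reverse primer-binding regions (so every species amplifies with the same
primers), a ddPCR probe site, a 7-nt random region used as a per-molecule tag
to monitor PCR amplification bias, and the 8-nt barcode that identifies the
particle. This module generates barcode sets with a guaranteed minimum
pairwise Hamming distance and per-position base diversity (so no sequencing
cycle is dominated by one base), assembles full scaffolds, and parses the
staggered nested-PCR primer tables used for amplification.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Default ddPCR probe-site and spacer sequences used by the standard
#: 91-nt layout.  Chosen to be balanced in composition, homopolymer-free,
#: and Hamming-far (>= 6 at every offset) from the forward anchor so they
#: cannot be mistaken for it during read anchoring.
DEFAULT_PROBE_SITE = "GGCTCATATGAACAAGTCTT"
DEFAULT_SPACER = "TGCGCCCATAAATGTA"

SCAFFOLD_LENGTH = 91
BARCODE_LENGTH = 8
UMI_LENGTH = 7


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Hamming distance between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def barcode_space_size(length: int) -> int:
    """Number of distinct DNA sequences of the given length (4**length).

    An 8-nt barcode addresses 4**8 = 65,536 distinct species, far more than
    any practical nanoparticle pool.
    """
    if int(length) != length or length < 1:
        raise ValueError(f"barcode length must be a positive integer, got {length!r}")
    return 4 ** int(length)


# ---------------------------------------------------------------------------
# Primer sets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PrimerSet:
    """A staggered nested-PCR primer panel.

    All primers of one orientation share a sequencing-adapter prefix and a
    3'-terminal anchor (the scaffold-binding region); between the two sits a
    variable-length stagger that desynchronises sequencing cycles across the
    pool. Anchors and staggers are derived, not supplied.
    """

    forward: tuple[str, ...]
    reverse: tuple[str, ...]
    fwd_anchor: str = field(init=False)
    rvs_anchor: str = field(init=False)
    fwd_adapter: str = field(init=False)
    rvs_adapter: str = field(init=False)
    fwd_staggers: tuple[str, ...] = field(init=False)
    rvs_staggers: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        for name, seqs in (("forward", self.forward), ("reverse", self.reverse)):
            if not seqs:
                raise ValueError(f"no {name} primers supplied")
            bad = [s for s in seqs if set(s) - set(BASES)]
            if bad:
                raise ValueError(f"non-ACGT characters in {name} primers: {bad}")
        f_anchor = _longest_common_suffix(self.forward)
        r_anchor = _longest_common_suffix(self.reverse)
        if not f_anchor or not r_anchor:
            raise ValueError("primers of one orientation share no common 3' anchor")
        f_adapter = _longest_common_prefix(self.forward)
        r_adapter = _longest_common_prefix(self.reverse)
        f_stag = _staggers(self.forward, f_adapter, f_anchor, "forward")
        r_stag = _staggers(self.reverse, r_adapter, r_anchor, "reverse")
        object.__setattr__(self, "fwd_anchor", f_anchor)
        object.__setattr__(self, "rvs_anchor", r_anchor)
        object.__setattr__(self, "fwd_adapter", f_adapter)
        object.__setattr__(self, "rvs_adapter", r_adapter)
        object.__setattr__(self, "fwd_staggers", f_stag)
        object.__setattr__(self, "rvs_staggers", r_stag)

    @property
    def stagger_lengths(self) -> dict[str, tuple[int, ...]]:
        return {
            "forward": tuple(len(s) for s in self.fwd_staggers),
            "reverse": tuple(len(s) for s in self.rvs_staggers),
        }

    @property
    def max_fwd_stagger(self) -> int:
        return max(len(s) for s in self.fwd_staggers)


def _longest_common_suffix(seqs: Sequence[str]) -> str:
    n = min(len(s) for s in seqs)
    i = 0
    while i < n and len({s[len(s) - i - 1] for s in seqs}) == 1:
        i += 1
    return seqs[0][len(seqs[0]) - i:] if i else ""


def _longest_common_prefix(seqs: Sequence[str]) -> str:
    n = min(len(s) for s in seqs)
    i = 0
    while i < n and len({s[i] for s in seqs}) == 1:
        i += 1
    return seqs[0][:i]


def _staggers(
    seqs: Sequence[str], adapter: str, anchor: str, orientation: str
) -> tuple[str, ...]:
    staggers = tuple(s[len(adapter): len(s) - len(anchor)] for s in seqs)
    lengths = [len(s) for s in staggers]
    if len(set(lengths)) != len(lengths):
        raise ValueError(
            f"{orientation} primers do not have distinct stagger lengths: {lengths}"
        )
    return staggers


def load_primer_set(source: str | Path | None = None) -> PrimerSet:
    """Load a primer panel from a 2-column (name, sequence) table.

    Sequences may be written in the space-grouped triplet style commonly used
    in methods listings; internal whitespace is stripped. Names starting with
    FWD/RVS (case-insensitive, also F_/R_ or FORWARD/REVERSE) set orientation.
    With no argument, loads the packaged 8+8 staggered Nextera-style panel.
    """
    if source is None:
        source = Path(__file__).parent / "data" / "primers.tsv"
    forward: list[str] = []
    reverse: list[str] = []
    for lineno, line in enumerate(Path(source).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split(None, 1)
        if len(parts) != 2:
            raise ValueError(f"{source}:{lineno}: expected 'name<TAB>sequence'")
        name, seq = parts[0].strip(), "".join(parts[1].split()).upper()
        upper = name.upper()
        if upper.startswith(("FWD", "FORWARD", "F_")):
            forward.append(seq)
        elif upper.startswith(("RVS", "REV", "REVERSE", "R_")):
            reverse.append(seq)
        else:
            raise ValueError(f"{source}:{lineno}: cannot tell orientation of {name!r}")
    return PrimerSet(forward=tuple(forward), reverse=tuple(reverse))


# ---------------------------------------------------------------------------
# Barcode sets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BarcodeSet:
    """A set of equal-length DNA barcodes with distance and diversity stats.

    ``min_pairwise_hamming`` is always recomputed from the members by an
    all-pairs scan, never trusted from a constructor argument.
    """

    barcodes: tuple[str, ...]
    ids: tuple[str, ...] = ()
    min_pairwise_hamming: int = field(init=False)
    per_position_base_counts: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.barcodes:
            raise ValueError("empty barcode set")
        length = len(self.barcodes[0])
        if any(len(b) != length for b in self.barcodes):
            raise ValueError("barcodes differ in length")
        if any(set(b) - set(BASES) for b in self.barcodes):
            raise ValueError("barcodes must be over the alphabet ACGT")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("barcodes are not all distinct")
        if not self.ids:
            width = max(2, len(str(len(self.barcodes))))
            object.__setattr__(
                self,
                "ids",
                tuple(f"BC{i + 1:0{width}d}" for i in range(len(self.barcodes))),
            )
        if len(self.ids) != len(self.barcodes):
            raise ValueError("ids and barcodes differ in length")
        object.__setattr__(
            self, "min_pairwise_hamming", _min_pairwise_hamming(self.barcodes)
        )
        counts = np.zeros((length, 4), dtype=int)
        for b in self.barcodes:
            for pos, base in enumerate(b):
                counts[pos, _BASE_INDEX[base]] += 1
        object.__setattr__(self, "per_position_base_counts", counts)

    def __len__(self) -> int:
        return len(self.barcodes)

    @property
    def length(self) -> int:
        return len(self.barcodes[0])

    def id_of(self, barcode: str) -> str:
        return self.ids[self.barcodes.index(barcode)]

    def sequence_of(self, barcode_id: str) -> str:
        return self.barcodes[self.ids.index(barcode_id)]


def _min_pairwise_hamming(codes: Sequence[str]) -> int:
    if len(codes) < 2:
        return len(codes[0])
    return min(hamming(a, b) for a, b in itertools.combinations(codes, 2))


def generate_barcode_set(
    n: int,
    length: int = BARCODE_LENGTH,
    min_hamming: int = 3,
    seed: int = 0,
    diversity_ceiling: float = 0.75,
    max_attempts: int | None = None,
) -> BarcodeSet:
    """Sample ``n`` distinct barcodes with pairwise Hamming >= ``min_hamming``.

    Greedy rejection sampling: candidate codes are drawn uniformly and kept
    only if they are far enough from every accepted code. After the set is
    complete, a per-position diversity rule is enforced: at no position may a
    single base occupy more than ``ceil(diversity_ceiling * n)`` members
    (guards against low per-cycle base diversity on the sequencer). A set
    violating the rule is rediscarded and resampled. Deterministic per seed.

    Raises
    ------
    ValueError
        If ``n`` exceeds the space, or no conforming set is found within
        ``max_attempts`` candidate draws (default ``2000 * n``). The failure
        is always explicit; a smaller set is never returned silently.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if min_hamming < 1 or min_hamming > length:
        raise ValueError(f"min_hamming must be in [1, {length}], got {min_hamming}")
    if not 0.0 < diversity_ceiling <= 1.0:
        raise ValueError("diversity_ceiling must be in (0, 1]")
    if n > barcode_space_size(length):
        raise ValueError(
            f"requested {n} barcodes but only {barcode_space_size(length)} "
            f"sequences of length {length} exist"
        )
    budget = max_attempts if max_attempts is not None else 2000 * n
    max_per_position = int(np.ceil(diversity_ceiling * n))
    rng = np.random.default_rng(seed)
    attempts = 0
    while attempts < budget:
        accepted: list[str] = []
        while len(accepted) < n and attempts < budget:
            attempts += 1
            cand = "".join(BASES[i] for i in rng.integers(0, 4, size=length))
            if all(hamming(cand, a) >= min_hamming for a in accepted):
                accepted.append(cand)
        if len(accepted) < n:
            break
        counts = np.zeros((length, 4), dtype=int)
        for b in accepted:
            for pos, base in enumerate(b):
                counts[pos, _BASE_INDEX[base]] += 1
        if counts.max() <= max_per_position:
            return BarcodeSet(barcodes=tuple(accepted))
    raise ValueError(
        f"could not generate {n} barcodes of length {length} with "
        f"min Hamming {min_hamming} and diversity ceiling {diversity_ceiling} "
        f"within {budget} attempts"
    )


def write_barcode_fasta(bset: BarcodeSet, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=bid, description="")
        for bid, seq in zip(bset.ids, bset.barcodes)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_barcode_fasta(path: str | Path) -> BarcodeSet:
    records = list(SeqIO.parse(str(path), "fasta"))
    return BarcodeSet(
        barcodes=tuple(str(r.seq) for r in records),
        ids=tuple(r.id for r in records),
    )


# ---------------------------------------------------------------------------
# Scaffold assembly
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScaffoldLayout:
    """Segment plan for the 91-nt amplicon scaffold.

    Segment order is fixed (forward primer region, probe site, barcode,
    random 7-mer, spacer, reverse primer region); the probe-site and spacer
    sequences, and the total length, are configurable. The primer regions
    are taken from the primer set at assembly time.
    """

    probe_site: str = DEFAULT_PROBE_SITE
    spacer: str = DEFAULT_SPACER
    total_length: int = SCAFFOLD_LENGTH
    barcode_length: int = BARCODE_LENGTH
    umi_length: int = UMI_LENGTH

    def segment_lengths(self, primer_set: PrimerSet) -> list[tuple[str, int]]:
        return [
            ("fwd_primer_region", len(primer_set.fwd_anchor)),
            ("probe_site", len(self.probe_site)),
            ("barcode8", self.barcode_length),
            ("umi7", self.umi_length),
            ("spacer", len(self.spacer)),
            ("rvs_primer_region", len(primer_set.rvs_anchor)),
        ]

    def barcode_offset_from_anchor(self) -> int:
        """Distance from the end of the forward anchor to the barcode start."""
        return len(self.probe_site)

    def umi_offset_from_anchor(self) -> int:
        return len(self.probe_site) + self.barcode_length


@dataclass(frozen=True)
class BarcodeScaffold:
    """One assembled 91-nt scaffold with annotated segments.

    The 7-nt random region is stored as ``N`` wildcards; the simulator
    instantiates it per molecule. ``phosphorothioate_ends`` records how many
    terminal nucleotides carry exonuclease-resistant backbone modifications
    (synthesis metadata; it affects no computation).
    """

    barcode_id: str
    sequence: str
    segments: tuple[tuple[str, int, int], ...]
    phosphorothioate_ends: int = 2

    def __post_init__(self) -> None:
        if len(self.sequence) != self.segments[-1][2]:
            raise ValueError("segments do not cover the sequence")
        pos = 0
        for name, start, end in self.segments:
            if start != pos or end <= start:
                raise ValueError("segments must be contiguous and non-empty")
            pos = end
        if pos != len(self.sequence):
            raise ValueError("segments do not cover the sequence")

    def segment(self, name: str) -> str:
        for seg, start, end in self.segments:
            if seg == name:
                return self.sequence[start:end]
        raise KeyError(name)

    def with_umi(self, umi: str) -> str:
        """Concrete molecule sequence with the random region instantiated."""
        for seg, start, end in self.segments:
            if seg == "umi7":
                if len(umi) != end - start:
                    raise ValueError("UMI length mismatch")
                return self.sequence[:start] + umi + self.sequence[end:]
        raise KeyError("umi7")


def assemble_scaffold(
    barcode8: str,
    primer_set: PrimerSet,
    layout: ScaffoldLayout | None = None,
    barcode_id: str | None = None,
    phosphorothioate_ends: int = 2,
) -> BarcodeScaffold:
    """Assemble the full single-stranded scaffold around an 8-nt barcode.

    The 5' end carries the forward-anchor sequence (the forward primer's
    scaffold-binding region) and the 3' end the reverse complement of the
    reverse anchor, so both universal primers amplify every scaffold equally.
    """
    layout = layout or ScaffoldLayout()
    if len(barcode8) != layout.barcode_length:
        raise ValueError(
            f"barcode must be {layout.barcode_length} nt, got {len(barcode8)}"
        )
    if set(barcode8) - set(BASES):
        raise ValueError("barcode must be over the alphabet ACGT")
    parts = {
        "fwd_primer_region": primer_set.fwd_anchor,
        "probe_site": layout.probe_site,
        "barcode8": barcode8,
        "umi7": "N" * layout.umi_length,
        "spacer": layout.spacer,
        "rvs_primer_region": reverse_complement(primer_set.rvs_anchor),
    }
    lengths = layout.segment_lengths(primer_set)
    total = sum(n for _, n in lengths)
    if total != layout.total_length:
        raise ValueError(
            f"layout segments sum to {total}, expected {layout.total_length}"
        )
    segments = []
    pos = 0
    seq = []
    for name, seg_len in lengths:
        seq.append(parts[name])
        segments.append((name, pos, pos + seg_len))
        pos += seg_len
    return BarcodeScaffold(
        barcode_id=barcode_id or barcode8,
        sequence="".join(seq),
        segments=tuple(segments),
        phosphorothioate_ends=phosphorothioate_ends,
    )


def assemble_scaffolds(
    bset: BarcodeSet,
    primer_set: PrimerSet,
    layout: ScaffoldLayout | None = None,
) -> dict[str, BarcodeScaffold]:
    """Assemble one scaffold per barcode in the set, keyed by barcode id."""
    layout = layout or ScaffoldLayout()
    return {
        bid: assemble_scaffold(seq, primer_set, layout, barcode_id=bid)
        for bid, seq in zip(bset.ids, bset.barcodes)
    }
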
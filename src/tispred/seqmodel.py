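"""Domain model for annotated mRNA molecules and candidate start codons.

An mRNA molecule carries exactly one annotated translation initiation site
(TIS): the ATG at which the ribosome initiates.  Every other ATG occurrence on
the molecule is a candidate that must be discriminated from the true start.
This module defines the record/candidate types, enumerates candidate ATGs with
their region (upstream / TIS / downstream) and reading-frame class relative to
the annotated start, extracts fixed windows around candidates, and encodes
windows with the classic one-hot nucleotide scheme (A=1000, C=0100, G=0010,
T=0001).

Positions are 1-based on the public surface, matching the biological
convention in which the TIS occupies +1/+2/+3 and there is no position 0;
0-based indices are used only internally.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

ALPHABET = frozenset("ACGT")
STOP_CODONS = ("TAA", "TAG", "TGA")
START_CODON = "ATG"

#: one-hot code per nucleotide, in the fixed order A, C, G, T
NUC_BITS = {
    "A": (1, 0, 0, 0),
    "C": (0, 1, 0, 0),
    "G": (0, 0, 1, 0),
    "T": (0, 0, 0, 1),
}
_BITS_NUC = {bits: nuc for nuc, bits in NUC_BITS.items()}


class Region(str, Enum):
    upstream = "upstream"
    tis = "tis"
    downstream = "downstream"


class Frame(str, Enum):
    in_frame = "in_frame"
    out_of_frame = "out_of_frame"


class Label(str, Enum):
    positive = "positive"
    negative = "negative"
    unlabeled = "unlabeled"


class InvalidRecordError(ValueError):
    """Raised when an mRNA record violates its structural invariants."""


@dataclass(frozen=True)
class MrnaRecord:
    """One annotated mRNA: identifier, sequence, and 1-based TIS position.

    The TIS position points at the A of the annotated start ATG.  Sequences
    are upper-cased on construction; characters outside {A, C, G, T} and
    annotations that do not land on an ATG are rejected.
    """

    id: str
    sequence: str
    tis_pos: int

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise InvalidRecordError(f"{self.id}: empty sequence")
        bad = set(seq) - ALPHABET
        if bad:
            raise InvalidRecordError(
                f"{self.id}: characters outside A/C/G/T: {sorted(bad)}"
            )
        if not (1 <= self.tis_pos <= len(seq) - 2):
            raise InvalidRecordError(
                f"{self.id}: tis_pos {self.tis_pos} out of range for length {len(seq)}"
            )
        if seq[self.tis_pos - 1 : self.tis_pos + 2] != START_CODON:
            raise InvalidRecordError(
                f"{self.id}: no ATG at annotated position {self.tis_pos} "
                f"(found {seq[self.tis_pos - 1:self.tis_pos + 2]!r})"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class WindowSpec:
    """Extraction window: U nucleotides upstream, D downstream.

    D counts from the A of the candidate ATG inclusive, so the ATG occupies
    window positions +1..+3 and a -10+30 window is 40 nt long.  (Some earlier
    work centres windows on the ATG instead; this convention is not that.)
    """

    upstream: int = 10
    downstream: int = 30

    def __post_init__(self) -> None:
        if self.upstream < 0:
            raise ValueError("upstream length must be non-negative")
        if self.downstream < 3:
            raise ValueError("downstream length must be >= 3 (must contain the ATG)")

    @property
    def length(self) -> int:
        return self.upstream + self.downstream

    @classmethod
    def from_string(cls, text: str) -> "WindowSpec":
        """Parse the conventional notation, e.g. ``-10+30``."""
        m = re.fullmatch(r"-(\d+)\+(\d+)", text.strip())
        if m is None:
            raise ValueError(f"window spec {text!r} is not of the form -U+D")
        return cls(upstream=int(m.group(1)), downstream=int(m.group(2)))

    def __str__(self) -> str:
        return f"-{self.upstream}+{self.downstream}"


@dataclass(frozen=True)
class CandidateSite:
    """One ATG occurrence, placed relative to the molecule's annotated TIS."""

    record_id: str
    atg_pos: int  # 1-based position of the A
    region: Region
    frame: Frame
    label: Label


@dataclass
class EncodedSample:
    """A candidate's window one-hot bits plus optional binary feature flags.

    ``label`` is +1 for the TIS, -1 for a negative, 0 for an unlabeled
    downstream candidate awaiting the acquired-knowledge step.
    """

    site: CandidateSite
    bits: np.ndarray
    features: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.uint8))
    label: int = 0

    @property
    def vector(self) -> np.ndarray:
        """Bits and feature flags concatenated, as passed to the classifier."""
        return np.concatenate([self.bits, self.features]).astype(np.float64)


def frame_of(atg_pos: int, tis_pos: int) -> Frame:
    """Reading-frame class of a candidate relative to the annotated TIS."""
    return Frame.in_frame if (atg_pos - tis_pos) % 3 == 0 else Frame.out_of_frame


def enumerate_candidates(record: MrnaRecord, mode: str = "plain") -> list[CandidateSite]:
    """Enumerate every ATG occurrence as a candidate site, 5' to 3'.

    Overlapping occurrences are all counted.  The site at the annotated TIS is
    labelled positive and upstream sites negative.  Downstream sites are
    negative under ``mode="plain"``; under ``mode="inaknow"`` they are
    unlabeled, reflecting that the ribosome scanning model never evaluates
    ATGs past the start and their class is unknown a priori.
    """
    if mode not in ("plain", "inaknow"):
        raise ValueError(f"unknown mode {mode!r}")
    sites: list[CandidateSite] = []
    seq = record.sequence
    start = 0
    while True:
        i = seq.find(START_CODON, start)
        if i < 0:
            break
        pos = i + 1  # 1-based
        if pos == record.tis_pos:
            region, label = Region.tis, Label.positive
        elif pos < record.tis_pos:
            region, label = Region.upstream, Label.negative
        else:
            region = Region.downstream
            label = Label.unlabeled if mode == "inaknow" else Label.negative
        sites.append(
            CandidateSite(
                record_id=record.id,
                atg_pos=pos,
                region=region,
                frame=frame_of(pos, record.tis_pos),
                label=label,
            )
        )
        start = i + 1
    return sites


def extract_window(
    record: MrnaRecord, atg_pos: int, spec: WindowSpec
) -> str | None:
    """Window of U upstream + D downstream nucleotides around a candidate A.

    Returns ``None`` when the molecule does not fully cover the window on
    either side; windows are never padded.
    """
    i = atg_pos - 1  # 0-based index of the A
    if record.sequence[i : i + 3] != START_CODON:
        raise ValueError(
            f"{record.id}: position {atg_pos} is not the A of an ATG codon"
        )
    lo = i - spec.upstream
    hi = i + spec.downstream
    if lo < 0 or hi > len(record.sequence):
        return None
    return record.sequence[lo:hi]


@dataclass
class FilterReport:
    """Bookkeeping for discarded molecules, by reason."""

    total: int = 0
    kept: int = 0
    discarded: dict[str, int] = field(default_factory=dict)

    def fraction(self, reason: str) -> float:
        return self.discarded.get(reason, 0) / self.total if self.total else 0.0


def filter_records(
    records: list[MrnaRecord], spec: WindowSpec
) -> tuple[list[MrnaRecord], FilterReport]:
    """Keep molecules whose positive (TIS) window is extractable.

    A molecule is discarded when fewer than U nucleotides precede its TIS
    (``insufficient_upstream``) or the molecule ends before +D
    (``insufficient_downstream``).  Records that fail construction-time
    invariants (no ATG at the annotation, ambiguity codes) never reach this
    function; the I/O layer counts those.
    """
    kept: list[MrnaRecord] = []
    report = FilterReport(total=len(records))
    for rec in records:
        if rec.tis_pos - 1 < spec.upstream:
            report.discarded["insufficient_upstream"] = (
                report.discarded.get("insufficient_upstream", 0) + 1
            )
        elif rec.tis_pos - 1 + spec.downstream > len(rec.sequence):
            report.discarded["insufficient_downstream"] = (
                report.discarded.get("insufficient_downstream", 0) + 1
            )
        else:
            kept.append(rec)
    report.kept = len(kept)
    return kept, report


def encode_4bit(window: str) -> np.ndarray:
    """One-hot encode a nucleotide string, 4 bits per position (A,C,G,T order)."""
    out = np.zeros(4 * len(window), dtype=np.uint8)
    for i, nuc in enumerate(window):
        try:
            out[4 * i : 4 * i + 4] = NUC_BITS[nuc]
        except KeyError:
            raise ValueError(
                f"invalid nucleotide {nuc!r} at position {i + 1}"
            ) from None
    return out


def decode_4bit(bits: np.ndarray) -> str:
    """Inverse of :func:`encode_4bit`."""
    bits = np.asarray(bits)
    if bits.size % 4:
        raise ValueError("bit vector length must be a multiple of 4")
    nucs = []
    for i in range(bits.size // 4):
        group = tuple(int(b) for b in bits[4 * i : 4 * i + 4])
        try:
            nucs.append(_BITS_NUC[group])
        except KeyError:
            raise ValueError(f"group {i} is not one-hot: {group}") from None
    return "".join(nucs)
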
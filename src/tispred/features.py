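"""Binary biological feature flags appended to encoded candidate windows.

Beyond the raw window sequence, a few coarse properties of the molecule carry
signal about whether a candidate ATG is the true start:

* ``UP_ATG`` — an ATG upstream and in frame with the candidate.  Under the
  ribosome scanning model an earlier in-frame start in adequate context would
  have captured initiation, so its presence argues against the candidate.
* ``STOP100`` — an in-frame stop codon within the next 100 nt.  A true start
  this close to a stop would encode a protein of at most 33 residues, shorter
  than almost all real proteins.
* ``CTG`` / ``GAC`` / ``GAG`` / ``GCC`` — presence of these codons in frame in
  the candidate's downstream window region; their frequencies differ between
  coding and non-coding frames.

All flags are computed relative to the candidate being scored (the putative
TIS), since at prediction time the true start is unknown.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .seqmodel import (
    CandidateSite,
    EncodedSample,
    Label,
    MrnaRecord,
    Region,
    Frame,
    STOP_CODONS,
    WindowSpec,
    encode_4bit,
    enumerate_candidates,
    extract_window,
)


class Feature(str, Enum):
    UP_ATG = "UP_ATG"
    STOP100 = "STOP100"
    CTG = "CTG"
    GAC = "GAC"
    GAG = "GAG"
    GCC = "GCC"


_CODON_FEATURES = {Feature.CTG: "CTG", Feature.GAC: "GAC",
                   Feature.GAG: "GAG", Feature.GCC: "GCC"}

# names used in the conventional combo notation, e.g. "ATG+STOP+GAG"
_COMBO_ALIASES = {
    "ATG": Feature.UP_ATG,
    "UP_ATG": Feature.UP_ATG,
    "STOP": Feature.STOP100,
    "STOP100": Feature.STOP100,
    "CTG": Feature.CTG,
    "GAC": Feature.GAC,
    "GAG": Feature.GAG,
    "GCC": Feature.GCC,
}


@dataclass(frozen=True)
class FeatureComboSpec:
    """Ordered feature selection; the order defines the vector layout.

    ``codon_scope`` selects the search region for the CTG/GAC/GAG/GCC flags:
    ``"window"`` scans the window's downstream portion (+4..+D), ``"horizon"``
    uses the same 100-nt horizon as the stop flag.
    """

    features: tuple[Feature, ...] = ()
    stop_horizon: int = 100
    codon_scope: str = "window"

    def __post_init__(self) -> None:
        if len(set(self.features)) != len(self.features):
            raise ValueError("duplicate features in combo")
        if self.stop_horizon < 3:
            raise ValueError("stop_horizon must be >= 3")
        if self.codon_scope not in ("window", "horizon"):
            raise ValueError(f"unknown codon_scope {self.codon_scope!r}")

    def __len__(self) -> int:
        return len(self.features)

    @classmethod
    def from_string(cls, text: str, **kwargs) -> "FeatureComboSpec":
        """Parse combo notation such as ``ATG+STOP+GAG`` (case-insensitive)."""
        text = text.strip()
        if not text or text.lower() in ("no", "none"):
            return cls(features=(), **kwargs)
        feats = []
        for tok in text.split("+"):
            key = tok.strip().upper()
            if key not in _COMBO_ALIASES:
                raise ValueError(f"unknown feature token {tok!r}")
            feats.append(_COMBO_ALIASES[key])
        return cls(features=tuple(feats), **kwargs)

    def __str__(self) -> str:
        names = {Feature.UP_ATG: "ATG", Feature.STOP100: "STOP"}
        return "+".join(names.get(f, f.value) for f in self.features) or "none"


def has_upstream_inframe_atg(record: MrnaRecord, atg_pos: int) -> int:
    """1 iff an ATG occurs upstream of and in frame with the candidate.

    The whole available upstream of the molecule is searched, not just the
    extraction window.
    """
    seq = record.sequence
    for p in range(atg_pos - 3, 0, -3):  # 1-based, same frame as candidate
        if seq[p - 1 : p + 2] == "ATG":
            return 1
    return 0


def has_downstream_inframe_stop(
    record: MrnaRecord, atg_pos: int, horizon: int = 100
) -> int:
    """1 iff an in-frame stop codon starts within `horizon` nt past the A.

    Offsets +4, +7, ... relative to the candidate (the codons following the
    ATG itself) are scanned; scanning ends at the molecule's 3' end.
    """
    seq = record.sequence
    k = 1
    while True:
        start0 = atg_pos - 1 + 3 * k  # 0-based codon start
        if start0 > atg_pos - 1 + horizon - 1 or start0 + 3 > len(seq):
            return 0
        if seq[start0 : start0 + 3] in STOP_CODONS:
            return 1
        k += 1


def has_downstream_inframe_codon(
    record: MrnaRecord,
    atg_pos: int,
    codon: str,
    spec: WindowSpec,
    scope: str = "window",
    horizon: int = 100,
) -> int:
    """1 iff `codon` occurs in frame in the candidate's downstream region.

    With ``scope="window"`` the region is the window's +4..+D downstream
    portion; with ``scope="horizon"`` it is the first `horizon` nt, as for the
    stop-codon flag.
    """
    if codon not in _CODON_FEATURES.values():
        raise ValueError(f"unsupported codon feature {codon!r}")
    limit = spec.downstream if scope == "window" else horizon
    seq = record.sequence
    k = 1
    while True:
        start0 = atg_pos - 1 + 3 * k
        # codon must lie entirely within the region and the molecule
        if start0 + 3 > atg_pos - 1 + limit or start0 + 3 > len(seq):
            return 0
        if seq[start0 : start0 + 3] == codon:
            return 1
        k += 1


def compute_feature(
    record: MrnaRecord,
    atg_pos: int,
    feature: Feature,
    combo: FeatureComboSpec,
    spec: WindowSpec,
) -> int:
    if feature is Feature.UP_ATG:
        return has_upstream_inframe_atg(record, atg_pos)
    if feature is Feature.STOP100:
        return has_downstream_inframe_stop(record, atg_pos, combo.stop_horizon)
    return has_downstream_inframe_codon(
        record,
        atg_pos,
        _CODON_FEATURES[feature],
        spec,
        scope=combo.codon_scope,
        horizon=combo.stop_horizon,
    )


def build_feature_vector(
    record: MrnaRecord,
    atg_pos: int,
    combo: FeatureComboSpec,
    spec: WindowSpec,
) -> np.ndarray:
    """Feature flags in combo order, as a uint8 vector (possibly empty)."""
    return np.array(
        [compute_feature(record, atg_pos, f, combo, spec) for f in combo.features],
        dtype=np.uint8,
    )


_LABEL_NUM = {Label.positive: 1, Label.negative: -1, Label.unlabeled: 0}


def encode_candidates(
    records: list[MrnaRecord],
    spec: WindowSpec,
    combo: FeatureComboSpec,
    mode: str = "plain",
    include_in_frame_negatives: bool = False,
) -> list[EncodedSample]:
    """Enumerate, window, and encode every usable candidate of `records`.

    Candidates whose window cannot be extracted are dropped.  Non-TIS
    candidates in frame with the TIS are excluded by default (training and
    evaluation use out-of-frame negatives); set
    ``include_in_frame_negatives=True`` to keep them.
    """
    samples: list[EncodedSample] = []
    for rec in records:
        for site in enumerate_candidates(rec, mode=mode):
            if (
                site.region is not Region.tis
                and site.frame is Frame.in_frame
                and not include_in_frame_negatives
            ):
                continue
            window = extract_window(rec, site.atg_pos, spec)
            if window is None:
                continue
            samples.append(
                EncodedSample(
                    site=site,
                    bits=encode_4bit(window),
                    features=build_feature_vector(rec, site.atg_pos, combo, spec),
                    label=_LABEL_NUM[site.label],
                )
            )
    return samples
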
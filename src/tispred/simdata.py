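"""Synthetic mRNA generator with a controllable start-codon context signal.

Each simulated molecule has the anatomy the extraction pipeline assumes: a
5'UTR, a true TIS whose context carries the Kozak consensus gcc[a/g]ccATGg
(GCC-purine-CC immediately upstream, G at +4; the -3 purine and +4 G are its
strongest determinants) with tunable probability, an open reading frame free
of internal in-frame stops and closed by a stop codon, and a 3'UTR.  Decoy
ATGs are planted in the UTRs and at out-of-frame positions inside the CDS at
a tunable density, in deliberately weak context (pyrimidine at -3, non-G at
+4).  Optionally, a fraction of the downstream out-of-frame ATGs is upgraded
to the strong-context template — purine at -3, G at +4, and a reading frame
kept open for 100 nt where the molecule permits — emulating downstream
candidates that genuinely look like starts; a ground-truth table records
which ATGs were planted that way.

These planted-strong downstream ATGs are exactly what the acquired-knowledge
procedure should relabel as positive, so the truth table supports recovery
experiments.  They are never labelled positive for supervised training.

Sequences are drawn from a position-independent base composition: there is no
organism-specific codon usage or GC structure, and no splice/intron model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqmodel import MrnaRecord, STOP_CODONS, frame_of, Frame

_NUCS = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimSpec:
    """Generator knobs.  Lengths in nucleotides; rates as documented."""

    n_molecules: int = 100
    utr5_len: tuple[int, int] = (10, 150)
    cds_len: tuple[int, int] = (90, 600)  # includes start ATG and terminal stop
    utr3_len: tuple[int, int] = (20, 200)
    kozak_strength: float = 0.9
    decoy_rate: float = 1.0  # expected planted decoys per 100 nt
    context_positive_downstream_frac: float = 0.0
    base_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.utr5_len
        if not (0 <= lo <= hi):
            raise ValueError("invalid utr5_len range")
        lo, hi = self.cds_len
        if not (9 <= lo <= hi) or lo % 3 or hi % 3:
            raise ValueError("cds_len bounds must be multiples of 3, >= 9")
        lo, hi = self.utr3_len
        if not (0 <= lo <= hi):
            raise ValueError("invalid utr3_len range")
        for p in (self.kozak_strength, self.context_positive_downstream_frac):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.decoy_rate < 0:
            raise ValueError("decoy_rate must be non-negative")
        if abs(sum(self.base_probs) - 1.0) > 1e-9 or min(self.base_probs) < 0:
            raise ValueError("base_probs must be a probability vector")


class _Molecule:
    """Mutable sequence under construction, with constraint-checked writes."""

    def __init__(self, seq: list[str], utr5: int, cds: int):
        self.seq = seq
        self.utr5 = utr5  # 0-based index of the A of the TIS
        self.cds = cds
        self.protected: set[int] = set()

    def cds_codon_safe(self, pos: int, nt: str) -> bool:
        """Would writing `nt` at `pos` keep every CDS-frame codon non-stop?

        The terminal stop codon is protected and never rewritten, so only
        internal codons need the check.  Positions outside the CDS are safe.
        """
        if not (self.utr5 <= pos < self.utr5 + self.cds - 3):
            return True
        codon_start = self.utr5 + 3 * ((pos - self.utr5) // 3)
        codon = "".join(
            nt if p == pos else self.seq[p]
            for p in range(codon_start, codon_start + 3)
        )
        return codon not in STOP_CODONS

    def write(self, pos: int, nts: str) -> bool:
        """Write if every touched position is unprotected and CDS-safe."""
        if pos < 0 or pos + len(nts) > len(self.seq):
            return False
        span = range(pos, pos + len(nts))
        if any(p in self.protected for p in span):
            return False
        for p, nt in zip(span, nts):
            if not self.cds_codon_safe(p, nt):
                return False
        for p, nt in zip(span, nts):
            self.seq[p] = nt
        return True


def _build_backbone(spec: SimSpec, rng: np.random.Generator) -> _Molecule:
    utr5 = int(rng.integers(spec.utr5_len[0], spec.utr5_len[1] + 1))
    n_codons = int(rng.integers(spec.cds_len[0] // 3, spec.cds_len[1] // 3 + 1))
    utr3 = int(rng.integers(spec.utr3_len[0], spec.utr3_len[1] + 1))
    p = np.asarray(spec.base_probs)

    def draw(n: int) -> list[str]:
        return list(_NUCS[rng.choice(4, size=n, p=p)])

    codons: list[str] = []
    for _ in range(n_codons - 2):  # internal codons: anything but a stop
        while True:
            c = "".join(draw(3))
            if c not in STOP_CODONS:
                codons.append(c)
                break
    stop = STOP_CODONS[int(rng.integers(3))]
    seq = draw(utr5) + list("ATG") + list("".join(codons)) + list(stop) + draw(utr3)
    mol = _Molecule(seq, utr5, 3 * n_codons)
    # protect the start codon and the terminal stop
    mol.protected.update(range(utr5, utr5 + 3))
    mol.protected.update(range(utr5 + 3 * (n_codons - 1), utr5 + 3 * n_codons))
    return mol


def _apply_strong_context(mol: _Molecule, pos: int, rng: np.random.Generator) -> bool:
    """Write the Kozak consensus around the A at 0-based `pos`.

    Positions -6..-1 receive G,C,C,R,C,C (R a random purine) and +4 receives
    G, as far as the molecule extends and constraint-checked writes permit.
    The -3 purine and +4 G — the consensus's critical determinants — are
    mandatory: failing to write either fails the whole application.  The
    flanking C/G positions are best-effort.
    """
    ok = True
    if pos - 3 >= 0 and mol.seq[pos - 3] not in "AG":
        first, second = ("A", "G") if rng.integers(2) else ("G", "A")
        ok = mol.write(pos - 3, first) or mol.write(pos - 3, second)
    if ok and mol.seq[pos + 3] != "G":
        ok = mol.write(pos + 3, "G")
    if ok:
        for off, nt in ((-6, "G"), (-5, "C"), (-4, "C"), (-2, "C"), (-1, "C")):
            if pos + off >= 0 and mol.seq[pos + off] != nt:
                mol.write(pos + off, nt)  # best effort
    return ok


def _apply_weak_context(mol: _Molecule, pos: int, rng: np.random.Generator) -> None:
    """Pyrimidine at -3 and non-G at +4; best effort (C is always CDS-safe)."""
    if pos - 3 >= 0 and mol.seq[pos - 3] not in "CT":
        nt = "CT"[int(rng.integers(2))]
        mol.write(pos - 3, nt) or mol.write(pos - 3, "C")
    if pos + 3 < len(mol.seq) and mol.seq[pos + 3] == "G":
        nt = "ACT"[int(rng.integers(3))]
        mol.write(pos + 3, nt) or mol.write(pos + 3, "C")


def _clear_decoy_frame_stops(mol: _Molecule, pos: int, horizon: int = 100) -> bool:
    """Remove stops in the decoy's frame within `horizon` nt of its A.

    Each offending stop codon gets a C written into it (no stop codon and no
    ATG contains a C, so the write can neither create a stop in any frame nor
    spawn a new candidate).  Returns False if a stop could not be cleared.
    """
    k = 1
    while True:
        start = pos + 3 * k
        if start - pos > horizon - 1 or start + 3 > len(mol.seq):
            return True
        if "".join(mol.seq[start : start + 3]) in STOP_CODONS:
            if not (mol.write(start + 2, "C") or mol.write(start, "C")):
                return False
        k += 1


def _find_atgs(seq: str) -> list[int]:
    out, i = [], seq.find("ATG")
    while i >= 0:
        out.append(i)
        i = seq.find("ATG", i + 1)
    return out


def _plant_decoys(mol: _Molecule, spec: SimSpec, rng: np.random.Generator) -> None:
    n = int(rng.poisson(spec.decoy_rate * len(mol.seq) / 100))
    if n == 0:
        return
    cds_end = mol.utr5 + mol.cds
    allowed = [
        p for p in range(len(mol.seq) - 2)
        if not (mol.utr5 <= p < cds_end and (p - mol.utr5) % 3 == 0)
    ]
    for p in rng.permutation(len(allowed))[:n]:
        pos = allowed[p]
        if mol.write(pos, "ATG"):
            _apply_weak_context(mol, pos, rng)
            # keep later plants from overwriting this decoy or its context
            mol.protected.update(range(pos, pos + 3))


def _upgrade_downstream(mol: _Molecule, spec: SimSpec,
                        rng: np.random.Generator) -> set[int]:
    """Give a random share of downstream out-of-frame ATGs the strong template."""
    frac = spec.context_positive_downstream_frac
    upgraded: set[int] = set()
    if frac == 0.0:
        return upgraded
    for pos in _find_atgs("".join(mol.seq)):
        if pos <= mol.utr5 or (pos - mol.utr5) % 3 == 0:
            continue
        if pos + 3 >= len(mol.seq):
            continue
        if rng.random() >= frac:
            continue
        mol.protected.update(range(pos, pos + 3))
        if _apply_strong_context(mol, pos, rng) and _clear_decoy_frame_stops(mol, pos):
            mol.protected.update(set(range(pos - 6, pos + 4)) & set(range(len(mol.seq))))
            upgraded.add(pos)
    return upgraded


def _validate(mol: _Molecule) -> bool:
    seq = "".join(mol.seq)
    if seq[mol.utr5 : mol.utr5 + 3] != "ATG":
        return False
    cds = seq[mol.utr5 : mol.utr5 + mol.cds]
    if cds[-3:] not in STOP_CODONS:
        return False
    return all(cds[i : i + 3] not in STOP_CODONS for i in range(0, len(cds) - 3, 3))


def simulate(spec: SimSpec) -> tuple[list[MrnaRecord], pd.DataFrame]:
    """Generate molecules and the per-ATG ground-truth table.

    Returns the records plus a DataFrame with one row per ATG occurrence in
    the final sequences: ``record_id``, ``atg_pos`` (1-based), ``is_tis``,
    and ``planted_context`` (True for downstream ATGs that received the
    strong-context template).  Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[MrnaRecord] = []
    rows: list[dict] = []
    for i in range(spec.n_molecules):
        for _attempt in range(50):
            mol = _build_backbone(spec, rng)
            if rng.random() < spec.kozak_strength:
                if not _apply_strong_context(mol, mol.utr5, rng):
                    continue
                mol.protected.update(
                    set(range(mol.utr5 - 6, mol.utr5 + 4)) & set(range(len(mol.seq)))
                )
            _plant_decoys(mol, spec, rng)
            upgraded = _upgrade_downstream(mol, spec, rng)
            if _validate(mol):
                break
        else:  # pragma: no cover - generation is overwhelmingly feasible
            raise RuntimeError(f"could not generate molecule {i} under {spec}")
        rec = MrnaRecord(id=f"sim{i:05d}", sequence="".join(mol.seq),
                         tis_pos=mol.utr5 + 1)
        records.append(rec)
        for pos in _find_atgs(rec.sequence):
            rows.append({
                "record_id": rec.id,
                "atg_pos": pos + 1,
                "is_tis": pos == mol.utr5,
                "planted_context": pos in upgraded,
            })
    truth = pd.DataFrame(rows, columns=["record_id", "atg_pos", "is_tis",
                                        "planted_context"])
    return records, truth
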
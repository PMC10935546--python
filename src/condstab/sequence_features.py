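"""Sequence-level inputs to the condensate stability model.

The stability model consumes a protein sequence only through a handful of
counts: how many titratable groups of each kind it carries (for the
Henderson-Hasselbalch net charge), how many aromatic/cation-pi "sticker"
motifs it contains (FG and RG motifs), and, for diagnostics, the local net
charge per residue along the chain.  This module computes those counts.

Conventions
-----------
* Residue positions are reported 1-based everywhere (NMR convention).
* Charged-residue counts come in two flavours: ``simple`` counts only
  Arg/Lys (positive) and Asp/Glu (negative); ``full`` titrates all nine
  ionizable group types (both termini, Asp, Glu, His, Cys, Tyr, Lys, Arg).
* No automatic trimming of cloning tags is performed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping

from Bio import SeqIO

__all__ = [
    "STANDARD_AA",
    "SequenceRecord",
    "PkaTable",
    "IonizableCounts",
    "StickerCounts",
    "ChargeProfile",
    "read_fasta",
    "count_ionizable_groups",
    "titrated_counts",
    "net_charge",
    "sticker_counts",
    "ncpr_profile",
]

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: Acid groups carry 0/-1 charge; base groups carry +1/0.
_ACID_GROUPS = ("C-term", "Asp", "Glu", "Cys", "Tyr")
_BASE_GROUPS = ("N-term", "His", "Lys", "Arg")

_RESIDUE_TO_GROUP = {
    "D": "Asp",
    "E": "Glu",
    "H": "His",
    "C": "Cys",
    "Y": "Tyr",
    "K": "Lys",
    "R": "Arg",
}


@dataclass(frozen=True)
class SequenceRecord:
    """A protein chain with an identifier and free-text description."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        for pos, aa in enumerate(self.residues, start=1):
            if aa not in STANDARD_AA:
                raise ValueError(
                    f"sequence {self.id!r}: unknown residue code {aa!r} "
                    f"at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class PkaTable:
    """pKa values and acid/base polarity for the nine ionizable group types.

    Defaults are the fixed literature values used throughout: C-term 3.6,
    Asp 4.0, Glu 4.5, His 6.4, N-term 7.8, Cys 8.14, Tyr 9.6, Lys 10.4,
    Arg 12.5.  Overriding a value is explicit (``with_overrides``), never
    silent.
    """

    pka: Mapping[str, float] = field(
        default_factory=lambda: {
            "C-term": 3.6,
            "Asp": 4.0,
            "Glu": 4.5,
            "His": 6.4,
            "N-term": 7.8,
            "Cys": 8.14,
            "Tyr": 9.6,
            "Lys": 10.4,
            "Arg": 12.5,
        }
    )

    def with_overrides(self, **overrides: float) -> "PkaTable":
        unknown = set(overrides) - set(self.pka)
        if unknown:
            raise KeyError(f"unknown ionizable groups: {sorted(unknown)}")
        merged = dict(self.pka)
        merged.update(overrides)
        return PkaTable(pka=merged)

    def is_acid(self, group: str) -> bool:
        if group in _ACID_GROUPS:
            return True
        if group in _BASE_GROUPS:
            return False
        raise KeyError(f"unknown ionizable group {group!r}")


@dataclass(frozen=True)
class IonizableCounts:
    """Per-group tallies of titratable sites in one chain.

    ``x_p0``/``x_n0`` are the *simple* base/acid counts (Arg+Lys and
    Asp+Glu) that the sticker model uses; the full nine-group tallies feed
    the full-mode net charge.
    """

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        for group, n in self.counts.items():
            if n < 0 or n != int(n):
                raise ValueError(f"count for {group} must be a nonnegative integer")
        for term in ("N-term", "C-term"):
            if self.counts.get(term, 0) not in (0, 1):
                raise ValueError(f"{term} count must be 0 or 1")

    def __getitem__(self, group: str) -> int:
        return int(self.counts.get(group, 0))

    @property
    def x_p0(self) -> int:
        return self["Arg"] + self["Lys"]

    @property
    def x_n0(self) -> int:
        return self["Asp"] + self["Glu"]


@dataclass(frozen=True)
class StickerCounts:
    """Counts of the four sticker types entering the pairwise model.

    ``x_FG``/``x_RG`` are integer motif counts; ``x_p``/``x_n`` are
    effective charge counts that may be fractional after pH titration and
    ion binding, and ``x_n`` may even turn negative under strong
    charge-inverting occupancy (flagged by ``charge_inverted_past_zero``).
    """

    x_FG: int
    x_RG: int
    x_p: float
    x_n: float
    charge_inverted_past_zero: bool = False

    def __post_init__(self) -> None:
        if self.x_FG < 0 or self.x_RG < 0:
            raise ValueError("motif counts must be nonnegative")
        if self.x_p < 0:
            raise ValueError("x_p must be nonnegative")

    @property
    def net_charge(self) -> float:
        return self.x_p - self.x_n


@dataclass(frozen=True)
class ChargeProfile:
    """Sliding-window net charge per residue (NCPR) profile."""

    seq_id: str
    positions: tuple[int, ...]
    ncpr: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.ncpr):
            raise ValueError("positions and ncpr must have equal length")
        if any(not -1.0 <= v <= 1.0 for v in self.ncpr):
            raise ValueError("NCPR values must lie in [-1, 1]")


def read_fasta(path) -> list[SequenceRecord]:
    """Read a (multi-)FASTA file into validated :class:`SequenceRecord` s."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            SequenceRecord(
                id=rec.id,
                residues=str(rec.seq).upper(),
                description=rec.description,
            )
        )
    return records


def count_ionizable_groups(
    seq: SequenceRecord, include_termini: bool = True
) -> IonizableCounts:
    """Tally titratable groups in a chain.

    The two chain termini each contribute one group when
    ``include_termini`` is set (the default), as appropriate for a free
    polypeptide with unmodified ends.
    """
    counts = {g: 0 for g in (*_ACID_GROUPS, *_BASE_GROUPS)}
    for aa in seq.residues:
        group = _RESIDUE_TO_GROUP.get(aa)
        if group is not None:
            counts[group] += 1
    if include_termini:
        counts["N-term"] = 1
        counts["C-term"] = 1
    return IonizableCounts(counts=counts)


def _acid_fraction(pka: float, pH: float) -> float:
    """Deprotonated (charged) fraction of an acid group."""
    return 1.0 / (1.0 + 10.0 ** (pka - pH))


def _base_fraction(pka: float, pH: float) -> float:
    """Protonated (charged) fraction of a base group."""
    return 1.0 / (1.0 + 10.0 ** (pH - pka))


def titrated_counts(
    counts: IonizableCounts,
    pH: float,
    pka: PkaTable | None = None,
    groups: Iterable[str] | None = None,
) -> tuple[float, float]:
    """Henderson-Hasselbalch charged-site counts ``(x_n', x_p')`` at a pH.

    Each acid group contributes ``n_group / (1 + 10^(pKa - pH))`` to the
    negative count and each base group ``n_group / (1 + 10^(pH - pKa))``
    to the positive count.  Restricting ``groups`` (e.g. to Asp/Glu and
    Arg/Lys) yields the simple-mode counts the sticker model titrates.
    """
    if not math.isfinite(pH):
        raise ValueError("pH must be finite")
    pka = pka or PkaTable()
    selected = set(groups) if groups is not None else set(pka.pka)
    x_n = 0.0
    x_p = 0.0
    for group in selected:
        n = counts[group]
        if n == 0:
            continue
        if pka.is_acid(group):
            x_n += n * _acid_fraction(pka.pka[group], pH)
        else:
            x_p += n * _base_fraction(pka.pka[group], pH)
    return x_n, x_p


def net_charge(
    counts: IonizableCounts,
    pH: float,
    pka: PkaTable | None = None,
    mode: Literal["full", "simple"] = "full",
) -> float:
    """Net charge of the chain in elementary-charge units.

    ``full`` mode titrates all nine group types and returns
    ``x_p' - x_n'``; ``simple`` mode returns the fixed tally
    ``(Arg + Lys) - (Asp + Glu)`` that dominates near-physiological pH.
    """
    if mode == "simple":
        return float(counts.x_p0 - counts.x_n0)
    if mode != "full":
        raise ValueError(f"unknown mode {mode!r}")
    x_n, x_p = titrated_counts(counts, pH, pka)
    return x_p - x_n


def sticker_counts(
    seq: SequenceRecord, motif_rule: Literal["fig6A", "gs_adjacent"] = "fig6A"
) -> StickerCounts:
    """Count FG/RG sticker motifs and simple charged residues.

    Two motif definitions are supported:

    * ``fig6A`` (default): F, Y or R with a Gly on at least one side.
      F/Y motifs feed ``x_FG``; R motifs feed ``x_RG``.
    * ``gs_adjacent``: F or R adjacent to at least one Gly or Ser.

    A residue may legitimately contribute to several counts: every Arg
    counts in ``x_p`` and, when Gly-adjacent, additionally in ``x_RG``.
    """
    if motif_rule == "fig6A":
        aromatic, donors, neighbours = set("FY"), set("R"), set("G")
    elif motif_rule == "gs_adjacent":
        aromatic, donors, neighbours = set("F"), set("R"), set("GS")
    else:
        raise ValueError(f"unknown motif rule {motif_rule!r}")

    res = seq.residues
    x_fg = x_rg = 0
    for i, aa in enumerate(res):
        if aa not in aromatic and aa not in donors:
            continue
        left = res[i - 1] if i > 0 else ""
        right = res[i + 1] if i + 1 < len(res) else ""
        if left in neighbours or right in neighbours:
            if aa in aromatic:
                x_fg += 1
            else:
                x_rg += 1
    x_p = res.count("R") + res.count("K")
    x_n = res.count("D") + res.count("E")
    return StickerCounts(x_FG=x_fg, x_RG=x_rg, x_p=float(x_p), x_n=float(x_n))


def ncpr_profile(
    seq: SequenceRecord, window: int = 10, step: int = 1
) -> ChargeProfile:
    """Net charge per residue over a sliding window.

    Charge is the simple tally (+1 for R/K, -1 for D/E) divided by the
    window length; the reported position is the 1-based window midpoint.
    """
    if window < 1 or step < 1:
        raise ValueError("window and step must be positive")
    if len(seq) < window:
        raise ValueError(
            f"sequence {seq.id!r} ({len(seq)} aa) shorter than window {window}"
        )
    charges = [1 if aa in "RK" else -1 if aa in "DE" else 0 for aa in seq.residues]
    positions = []
    values = []
    for start in range(0, len(charges) - window + 1, step):
        total = sum(charges[start : start + window])
        # midpoint of residues start+1 .. start+window, 1-based
        positions.append(start + (window + 1) // 2)
        values.append(total / window)
    return ChargeProfile(
        seq_id=seq.id, positions=tuple(positions), ncpr=tuple(values)
    )
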
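"""LIR-motif scanning, positional frequencies, and MSA conservation classes.

The canonical LC3-interacting region (LIR) core is the four-residue pattern
Theta-X-X-Gamma with an aromatic anchor Theta in {Y, F, W} and a
hydrophobic anchor Gamma in {V, I, L}; X is any residue.  Interactors
exclusive to one ATG8 family member are scanned for this pattern and the
relative amino-acid usage at each of the four positions is tabulated per
ATG8 group.

Conservation classes on a multiple sequence alignment follow the Clustal
symbol convention: '*' identical column, ':' all residues within one strong
group, '.' within one weak group; any gap voids the column.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AMINO_ACIDS",
    "LIR_PATTERN",
    "STRONG_GROUPS",
    "WEAK_GROUPS",
    "ProteinRecord",
    "LirMatch",
    "PositionalFrequencyMatrix",
    "Msa",
    "ColumnClassification",
    "scan_lir",
    "positional_frequencies",
    "classify_columns",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_ALPHABET = set(AMINO_ACIDS) | {"X"}
LIR_ANCHOR1 = set("YFW")
LIR_ANCHOR4 = set("VIL")
# lookahead so overlapping windows are all reported
LIR_PATTERN = re.compile(r"(?=([YFW])(..)([VIL]))", flags=0)

STRONG_GROUPS = tuple(frozenset(g) for g in
                      ("STA", "NEQK", "NHQK", "NDEQ", "QHRK",
                       "MILV", "MILF", "HY", "FYW"))
WEAK_GROUPS = tuple(frozenset(g) for g in
                    ("CSA", "ATV", "SAG", "STNK", "STPA", "SGND",
                     "SNDEQK", "NDEQHK", "NEQHRK", "FVLIM", "HFY"))


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence, optionally tagged with its exclusive ATG8 partner."""

    id: str
    sequence: str
    group: str | None = None

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(seq) - _ALPHABET
        if bad:
            raise ValueError(f"{self.id}: invalid residues {sorted(bad)}")


@dataclass(frozen=True)
class LirMatch:
    """One LIR core hit; ``start`` is 1-based inclusive."""

    protein_id: str
    start: int
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) != 4:
            raise ValueError("LIR core must be 4 residues")
        if self.residues[0] not in LIR_ANCHOR1 or self.residues[3] not in LIR_ANCHOR4:
            raise ValueError(f"invalid anchors in {self.residues!r}")


def scan_lir(record: ProteinRecord) -> list[LirMatch]:
    """All (possibly overlapping) LIR-core windows, ascending start order.

    Sequences shorter than four residues yield an empty list.  'X' may
    occupy the two variable positions but never an anchor.
    """
    seq = record.sequence
    out = []
    for m in LIR_PATTERN.finditer(seq):
        window = m.group(1) + m.group(2) + m.group(3)
        out.append(LirMatch(record.id, m.start() + 1, window))
    return out


@dataclass
class PositionalFrequencyMatrix:
    """Per-group 4 x 20 relative amino-acid frequencies over LIR matches.

    Rows are motif positions 1-4, columns the 20 amino acids in
    ``AMINO_ACIDS`` order.  'X' residues are excluded from the position's
    denominator, so each row with at least one counted residue sums to 1.
    Groups with zero matches keep an all-zero matrix and count 0.
    """

    frequencies: dict[str, np.ndarray] = field(default_factory=dict)
    match_counts: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for group in sorted(self.frequencies):
            mat = self.frequencies[group]
            for pos in range(4):
                for j, aa in enumerate(AMINO_ACIDS):
                    if mat[pos, j] > 0:
                        rows.append({"group": group, "position": pos + 1,
                                     "aa": aa, "frequency": mat[pos, j]})
        return pd.DataFrame(rows, columns=["group", "position", "aa", "frequency"])


def positional_frequencies(matches_by_group: dict[str, list[LirMatch]]) -> PositionalFrequencyMatrix:
    """Relative occurrence of each amino acid at the four LIR positions."""
    col = {aa: j for j, aa in enumerate(AMINO_ACIDS)}
    pfm = PositionalFrequencyMatrix()
    for group, matches in matches_by_group.items():
        counts = np.zeros((4, 20), dtype=float)
        for m in matches:
            for pos, aa in enumerate(m.residues):
                if aa != "X":
                    counts[pos, col[aa]] += 1
        totals = counts.sum(axis=1, keepdims=True)
        freqs = np.divide(counts, totals, out=np.zeros_like(counts),
                          where=totals > 0)
        pfm.frequencies[group] = freqs
        pfm.match_counts[group] = len(matches)
    return pfm


@dataclass
class Msa:
    """A gapped multiple sequence alignment ('-' gaps, equal row lengths)."""

    ids: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.sequences) < 2:
            raise ValueError("an alignment needs at least 2 sequences")
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences differ in length")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError("ragged alignment: unequal row lengths")
        self.sequences = [s.upper() for s in self.sequences]

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def column(self, i: int) -> list[str]:
        return [s[i] for s in self.sequences]

    def subset(self, ids: list[str], *, drop_all_gap_columns: bool = True) -> "Msa":
        """Row subset; columns gapped in every kept row are removed by default."""
        index = {sid: k for k, sid in enumerate(self.ids)}
        missing = [sid for sid in ids if sid not in index]
        if missing:
            raise KeyError(f"ids not in alignment: {missing}")
        rows = [self.sequences[index[sid]] for sid in ids]
        if drop_all_gap_columns:
            keep = [i for i in range(len(rows[0]))
                    if any(r[i] != "-" for r in rows)]
            rows = ["".join(r[i] for i in keep) for r in rows]
        return Msa(list(ids), rows)


@dataclass
class ColumnClassification:
    classes: list[str]  # per column: identical | strong | weak | none
    n_identical: int
    n_strong: int
    n_weak: int
    n_none: int
    percent_identity: float  # 100 * identical / alignment length

    @property
    def n_similar(self) -> int:
        """Conserved + semi-conserved columns (':' plus '.')."""
        return self.n_strong + self.n_weak

    @property
    def symbols(self) -> str:
        return "".join({"identical": "*", "strong": ":", "weak": ".",
                        "none": " "}[c] for c in self.classes)


def _classify_column(residues: list[str]) -> str:
    rs = set(residues)
    if "-" in rs:
        return "none"
    if len(rs) == 1:
        return "identical"
    if any(rs <= g for g in STRONG_GROUPS):
        return "strong"
    if any(rs <= g for g in WEAK_GROUPS):
        return "weak"
    return "none"


def classify_columns(msa: Msa) -> ColumnClassification:
    """Clustal-style per-column conservation classes and percent identity."""
    classes = [_classify_column(msa.column(i)) for i in range(msa.length)]
    n_id = classes.count("identical")
    return ColumnClassification(
        classes=classes,
        n_identical=n_id,
        n_strong=classes.count("strong"),
        n_weak=classes.count("weak"),
        n_none=classes.count("none"),
        percent_identity=100.0 * n_id / msa.length,
    )
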
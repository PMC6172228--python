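"""Fixed-length aligned antibody sequences: data model, I/O and encodings.

Antibody variable domains aligned under the AHo numbering scheme occupy a
fixed frame of 149 positions per chain (298 for a joined VH+VL pair), with
``'-'`` marking empty framework positions.  Everything downstream — Hamming
distances, one-hot encodings for the Gaussian model, CDR masks for
humanization — operates on these fixed coordinates, so this module is the
single place where alphabets, lengths and position conventions are defined.

Coordinates are 1-based alignment positions.  In the combined VHVL frame the
light chain occupies positions 150–298.  The amino-acid alphabet is ordered
alphabetically by one-letter code; the gap is encoded as an all-zero one-hot
block, so a sequence of length L maps to a binary vector of N = Q·L bits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Alphabetical ordering of the 20 standard amino-acid one-letter codes.
#: This ordering defines the one-hot block layout and is serialized with
#: every fitted model.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"

#: AHo framework length of a single variable domain.
AHO_CHAIN_LENGTH = 149
CHAIN_LENGTHS = {"VH": 149, "VL": 149, "VHVL": 298}

# IMGT CDR boundaries expressed in AHo alignment coordinates.  The VL ranges
# are printed in combined-frame coordinates (VL at 150-298); the standalone VL
# mask is the same ranges shifted down by 149.
VH_CDR_RANGES: tuple[tuple[int, int], ...] = ((27, 40), (58, 68), (107, 138))
VHVL_CDR_RANGES: tuple[tuple[int, int], ...] = VH_CDR_RANGES + (
    (176, 189),
    (207, 217),
    (257, 287),
)
VL_CDR_RANGES: tuple[tuple[int, int], ...] = ((27, 40), (58, 68), (108, 138))


def _validate_residues(residues: str, alphabet: str, seq_id: str) -> None:
    allowed = set(alphabet) | {GAP}
    for i, ch in enumerate(residues, start=1):
        if ch not in allowed:
            raise ValueError(
                f"sequence {seq_id!r}: illegal character {ch!r} at position {i}"
            )


@dataclass(frozen=True)
class AlignedSequence:
    """A gapped, fixed-length aligned amino-acid sequence.

    ``chain`` may be one of ``"VH"``, ``"VL"``, ``"VHVL"`` (which pin the
    length to 149/149/298) or ``None`` for arbitrary-length alignments such
    as synthetic ensembles and toy models.
    """

    id: str
    residues: str
    chain: str | None = None
    species: str | None = None
    alphabet: str = AA_ALPHABET

    def __post_init__(self) -> None:
        if self.chain is not None:
            if self.chain not in CHAIN_LENGTHS:
                raise ValueError(f"unknown chain {self.chain!r}")
            expected = CHAIN_LENGTHS[self.chain]
            if len(self.residues) != expected:
                raise ValueError(
                    f"sequence {self.id!r}: chain {self.chain} requires length "
                    f"{expected}, got {len(self.residues)}"
                )
        _validate_residues(self.residues, self.alphabet, self.id)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class SequenceDatabase:
    """An ensemble of equal-length aligned sequences (a learning or test set)."""

    sequences: list[AlignedSequence]
    chain: str | None = None
    L: int = 0
    label: str = ""
    alphabet: str = AA_ALPHABET

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("a SequenceDatabase must contain at least one sequence")
        if self.L == 0:
            self.L = len(self.sequences[0])
        seen: set[str] = set()
        for s in self.sequences:
            if len(s) != self.L:
                raise ValueError(
                    f"sequence {s.id!r}: length {len(s)} != database length {self.L}"
                )
            if s.chain != self.chain and s.chain is not None and self.chain is not None:
                raise ValueError(
                    f"sequence {s.id!r}: chain {s.chain} != database chain {self.chain}"
                )
            if s.id in seen:
                raise ValueError(f"duplicate sequence id {s.id!r}")
            seen.add(s.id)

    @property
    def M(self) -> int:
        return len(self.sequences)

    def __iter__(self) -> Iterator[AlignedSequence]:
        return iter(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)

    def indices_matrix(self) -> np.ndarray:
        """(M, L) integer matrix; alphabet index per residue, -1 for gaps."""
        return np.stack(
            [seq_to_indices(s.residues, self.alphabet) for s in self.sequences]
        )

    @classmethod
    def from_residues(
        cls,
        residues: Sequence[str],
        chain: str | None = None,
        label: str = "",
        alphabet: str = AA_ALPHABET,
        ids: Sequence[str] | None = None,
    ) -> "SequenceDatabase":
        if ids is None:
            width = max(4, len(str(len(residues))))
            ids = [f"{label or 'seq'}_{i:0{width}d}" for i in range(len(residues))]
        seqs = [
            AlignedSequence(i, r, chain=chain, alphabet=alphabet)
            for i, r in zip(ids, residues)
        ]
        return cls(seqs, chain=chain, label=label, alphabet=alphabet)


@dataclass(frozen=True)
class CDRMask:
    """Set of 1-based alignment positions held fixed during humanization
    (and excluded in framework-only scoring)."""

    positions: tuple[int, ...]
    scheme: str = "imgt-aho"

    def __post_init__(self) -> None:
        pos = self.positions
        if any(p < 1 for p in pos):
            raise ValueError("mask positions must be >= 1")
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("mask positions must be strictly increasing")

    def __contains__(self, position: int) -> bool:
        return position in set(self.positions)

    def __len__(self) -> int:
        return len(self.positions)

    @classmethod
    def from_ranges(
        cls, ranges: Iterable[tuple[int, int]], scheme: str = "imgt-aho"
    ) -> "CDRMask":
        pos: list[int] = []
        for a, b in ranges:
            pos.extend(range(a, b + 1))
        return cls(tuple(sorted(set(pos))), scheme=scheme)

    def membership(self, L: int) -> np.ndarray:
        """Boolean length-L array, True at masked positions."""
        if self.positions and self.positions[-1] > L:
            raise ValueError(f"mask position {self.positions[-1]} exceeds L={L}")
        out = np.zeros(L, dtype=bool)
        out[np.array(self.positions, dtype=int) - 1] = True
        return out

    def to_json(self) -> str:
        return json.dumps(
            {"scheme": self.scheme, "positions": list(self.positions)}
        )

    def to_bed_tsv(self, path: str | Path) -> None:
        """Write contiguous runs as 1-based inclusive (start, end, name) rows."""
        rows = []
        run_start = None
        prev = None
        for p in self.positions:
            if run_start is None:
                run_start = p
            elif p != prev + 1:
                rows.append((run_start, prev))
                run_start = p
            prev = p
        if run_start is not None:
            rows.append((run_start, prev))
        with open(path, "w") as fh:
            fh.write("start\tend\tname\n")
            for i, (a, b) in enumerate(rows, start=1):
                fh.write(f"{a}\t{b}\t{self.scheme}_region{i}\n")


def cdr_mask(chain: str) -> CDRMask:
    """IMGT CDR positions in AHo coordinates for a VH, VL or combined VHVL frame."""
    ranges = {
        "VH": VH_CDR_RANGES,
        "VL": VL_CDR_RANGES,
        "VHVL": VHVL_CDR_RANGES,
    }.get(chain)
    if ranges is None:
        raise ValueError(f"unknown chain {chain!r}; expected VH, VL or VHVL")
    return CDRMask.from_ranges(ranges)


def hamming_distance(
    a: AlignedSequence | str,
    b: AlignedSequence | str,
    mask: CDRMask | None = None,
) -> int:
    """Number of positions at which two aligned sequences differ.

    The gap character is an ordinary 21st symbol: a gap against any amino
    acid counts as one mismatch.  ``mask`` positions, when given, are
    excluded from the count (framework-only distance).
    """
    ra = a.residues if isinstance(a, AlignedSequence) else a
    rb = b.residues if isinstance(b, AlignedSequence) else b
    if len(ra) != len(rb):
        raise ValueError(f"length mismatch: {len(ra)} vs {len(rb)}")
    if mask is None:
        return sum(x != y for x, y in zip(ra, rb))
    excluded = set(mask.positions)
    return sum(
        x != y for i, (x, y) in enumerate(zip(ra, rb), start=1) if i not in excluded
    )


# ---------------------------------------------------------------------------
# One-hot encoding


def seq_to_indices(residues: str, alphabet: str = AA_ALPHABET) -> np.ndarray:
    """Map residues to alphabet indices; the gap maps to -1."""
    lut = {ch: i for i, ch in enumerate(alphabet)}
    out = np.empty(len(residues), dtype=np.int64)
    for i, ch in enumerate(residues):
        if ch == GAP:
            out[i] = -1
        else:
            try:
                out[i] = lut[ch]
            except KeyError:
                raise ValueError(
                    f"illegal character {ch!r} at position {i + 1}"
                ) from None
    return out


def indices_to_seq(idx: np.ndarray, alphabet: str = AA_ALPHABET) -> str:
    symbols = alphabet + GAP  # index -1 wraps to the gap
    return "".join(symbols[int(i)] for i in idx)


def encode_onehot(
    seq: AlignedSequence | str, alphabet: str = AA_ALPHABET
) -> np.ndarray:
    """One-hot encode into N = Q*L bits; gaps become all-zero blocks."""
    if isinstance(seq, AlignedSequence):
        alphabet = seq.alphabet
        seq = seq.residues
    idx = seq_to_indices(seq, alphabet)
    Q = len(alphabet)
    v = np.zeros(Q * len(idx), dtype=np.float64)
    hot = idx >= 0
    v[np.arange(len(idx))[hot] * Q + idx[hot]] = 1.0
    return v


def decode_onehot(v: np.ndarray, L: int, alphabet: str = AA_ALPHABET) -> str:
    """Inverse of :func:`encode_onehot`; rejects vectors violating the
    one-bit-per-block invariant."""
    Q = len(alphabet)
    v = np.asarray(v)
    if v.shape != (Q * L,):
        raise ValueError(f"expected length {Q * L}, got {v.shape}")
    if not np.isin(v, (0.0, 1.0)).all():
        raise ValueError("one-hot vector must be binary")
    blocks = v.reshape(L, Q)
    sums = blocks.sum(axis=1)
    if (sums > 1).any():
        bad = int(np.argmax(sums > 1)) + 1
        raise ValueError(f"block at position {bad} has sum > 1")
    out = []
    for i in range(L):
        if sums[i] == 0:
            out.append(GAP)
        else:
            out.append(alphabet[int(np.argmax(blocks[i]))])
    return "".join(out)


def encode_database(db: SequenceDatabase) -> np.ndarray:
    """(M, N) one-hot matrix for a database."""
    return np.stack([encode_onehot(s.residues, db.alphabet) for s in db])


# ---------------------------------------------------------------------------
# Gapped FASTA I/O


def read_aligned_fasta(
    path: str | Path,
    chain: str | None = None,
    L: int | None = None,
    label: str | None = None,
    alphabet: str = AA_ALPHABET,
) -> SequenceDatabase:
    """Read a gapped FASTA file of pre-aligned sequences.

    Every record must have the same length: ``CHAIN_LENGTHS[chain]`` when a
    chain tag is given, else ``L`` when given, else the length of the first
    record.  Record order and duplicate residue strings are preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    expected = CHAIN_LENGTHS.get(chain) if chain else L
    seqs = []
    for rec in records:
        residues = str(rec.seq).upper()
        if not rec.id:
            raise ValueError(f"{path}: record with empty id")
        if expected is None:
            expected = len(residues)
        if len(residues) != expected:
            raise ValueError(
                f"{path}: record {rec.id!r} has length {len(residues)}, "
                f"expected {expected}"
            )
        seqs.append(
            AlignedSequence(rec.id, residues, chain=chain, alphabet=alphabet)
        )
    return SequenceDatabase(
        seqs, chain=chain, L=expected, label=label or path.stem, alphabet=alphabet
    )


def write_fasta(db: SequenceDatabase | Iterable[AlignedSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in db
    ]
    SeqIO.write(records, str(path), "fasta")
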
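"""Aligned DNA-binding-domain families.

The central container is :class:`AlignedFamily`, a fixed-width multiple
sequence alignment of transcription-factor DNA-binding domains with one row
per TF.  One record may be designated the *seed*: its ungapped residue
numbering (1-based) provides the coordinate system used when reporting
alignment columns in domain coordinates, mirroring the convention of
seed-anchored family alignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}


@dataclass
class AlignedFamily:
    """An MSA of DBD sequences with TF identifiers and a seed record."""

    ids: list[str]
    seqs: np.ndarray  # (n_seq, n_col) array of single characters
    seed_id: str | None = None
    _row_of: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.seqs = np.asarray(self.seqs, dtype="<U1")
        if self.seqs.ndim != 2:
            raise ValueError("alignment must be a 2-D character array")
        if len(self.ids) != self.seqs.shape[0]:
            raise ValueError("one identifier per alignment row required")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate TF identifiers in alignment")
        if self.seed_id is None and self.ids:
            self.seed_id = self.ids[0]
        if self.seed_id is not None and self.seed_id not in self.ids:
            raise ValueError(f"seed record {self.seed_id!r} not in alignment")
        self._row_of = {t: i for i, t in enumerate(self.ids)}

    # -- construction ------------------------------------------------------

    @classmethod
    def from_sequences(
        cls, ids: list[str], sequences: list[str], seed_id: str | None = None
    ) -> "AlignedFamily":
        lengths = {len(s) for s in sequences}
        if len(lengths) > 1:
            raise ValueError("sequences are not aligned (unequal lengths)")
        arr = np.array([list(s.upper()) for s in sequences], dtype="<U1")
        return cls(list(ids), arr, seed_id)

    @classmethod
    def from_fasta(cls, path, seed_id: str | None = None) -> "AlignedFamily":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no records in {path}")
        return cls.from_sequences(
            [r.id for r in records], [str(r.seq) for r in records], seed_id
        )

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq("".join(row)), id=tf, description="")
            for tf, row in zip(self.ids, self.seqs)
        ]
        SeqIO.write(records, str(path), "fasta")

    # -- basic geometry ----------------------------------------------------

    @property
    def n_seq(self) -> int:
        return self.seqs.shape[0]

    @property
    def n_col(self) -> int:
        return self.seqs.shape[1]

    def row(self, tf_id: str) -> np.ndarray:
        return self.seqs[self._row_of[tf_id]]

    def sequence(self, tf_id: str, ungapped: bool = False) -> str:
        row = self.row(tf_id)
        s = "".join(row)
        return s.replace(GAP, "") if ungapped else s

    # -- per-column metadata -----------------------------------------------

    def gap_fraction(self) -> np.ndarray:
        return (self.seqs == GAP).mean(axis=0)

    def invariant_mask(self) -> np.ndarray:
        """True for columns whose non-gap residues are all identical.

        All-gap columns are also flagged (they carry no information).
        """
        mask = np.zeros(self.n_col, dtype=bool)
        for c in range(self.n_col):
            col = self.seqs[:, c]
            residues = set(col[col != GAP])
            mask[c] = len(residues) <= 1
        return mask

    def all_gap_mask(self) -> np.ndarray:
        return (self.seqs == GAP).all(axis=0)

    def seed_column_map(self) -> dict[int, int]:
        """Alignment column -> 1-based residue number in the ungapped seed."""
        if self.seed_id is None:
            return {}
        row = self.row(self.seed_id)
        mapping: dict[int, int] = {}
        pos = 0
        for c, ch in enumerate(row):
            if ch != GAP:
                pos += 1
                mapping[c] = pos
        return mapping

    def encoded(self) -> np.ndarray:
        """Integer encoding: 0..19 for amino acids, -1 for gap/unknown."""
        enc = np.full(self.seqs.shape, -1, dtype=np.int8)
        for a, i in AA_INDEX.items():
            enc[self.seqs == a] = i
        return enc
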